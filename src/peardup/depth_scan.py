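"""Sliding-window ΔDP scanning for segmental duplications.

The scan compares read depth (DP) between a test individual and a diploid
reference at a shared locus set.  A duplicated (three-copy) segment raises
the test individual's depth by ~50%, so the per-locus depth difference ΔDP
averages ~mean/2 inside the segment and ~0 outside.  Window means of ΔDP are
compared against an empirical null built by resampling window-mean depths of
the two individuals independently (unpaired): because locus- and
region-specific depth biases are largely shared between libraries, unpairing
the windows inflates the null relative to the paired observed track, which
makes the resulting 95%/99% thresholds conservative.

Windows are either ``snp_count`` (a fixed number of consecutive loci, the
ddRAD design: 20 SNPs advancing by 10) or ``physical`` (fixed-width tiles,
the WGS design: 1 Mb advancing by 0.5 Mb).
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .variant_io import VariantTable


@dataclasses.dataclass(frozen=True)
class WindowSpec:
    """Sliding-window definition.

    mode
        ``"snp_count"`` — *size*/*step* count loci; window coordinates span
        the first to last locus.  ``"physical"`` — *size*/*step* are base
        pairs; windows tile ``[k*step, k*step + size)``.
    """

    mode: str
    size: int
    step: int

    def __post_init__(self) -> None:
        if self.mode not in ("snp_count", "physical"):
            raise ValueError(f"unknown window mode {self.mode!r}")
        if self.size <= 0:
            raise ValueError("window size must be > 0")
        if self.step <= 0 or self.step > self.size:
            raise ValueError("require 0 < step <= size")


@dataclasses.dataclass
class WindowTrack:
    """Windowed means of a per-locus statistic.

    ``windows`` has columns chrom, start, end (1-based half-open), n_loci,
    mean, partial; rows are ordered by chrom then start.
    """

    windows: pd.DataFrame
    statistic: str
    spec: WindowSpec | None = None

    def __len__(self) -> int:
        return len(self.windows)

    def values(self) -> np.ndarray:
        return self.windows["mean"].to_numpy()

    def to_tsv(self, path: str) -> None:
        df = self.windows.rename(columns={"mean": f"mean_{self.statistic}"})
        df.to_csv(str(path), sep="\t", index=False)


@dataclasses.dataclass
class CIThresholds:
    """Upper resampling quantiles of the null ΔDP distribution."""

    ci95: float
    ci99: float
    n_iter: int
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_iter < 1:
            raise ValueError("n_iter must be >= 1")
        if self.ci99 < self.ci95:
            raise ValueError("ci99 < ci95")


@dataclasses.dataclass
class RegionCall:
    """A classified genomic interval (1-based half-open)."""

    chrom: str
    start: int
    end: int
    region_class: str
    mean_stat: float = float("nan")
    n_windows: int = 0
    n_loci: int = 0
    flags: tuple = ()
    evidence: dict = dataclasses.field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError("region end must exceed start")

    @property
    def length(self) -> int:
        return self.end - self.start


def depth_series(vt: VariantTable, sample: str) -> pd.DataFrame:
    """Per-locus DP for one sample (loci with missing DP dropped)."""
    j = vt.sample_index(sample)
    ok = vt.dp[:, j] >= 0
    return pd.DataFrame(
        {"chrom": vt.chrom[ok], "pos": vt.pos[ok], "value": vt.dp[ok, j].astype(float)}
    )


def compute_delta_dp(
    vt: VariantTable, target: str, reference: str, normalize: bool = False
) -> pd.DataFrame:
    """Per-locus ΔDP = DP(target) − DP(reference) over the shared locus set.

    Loci with missing depth in either sample are dropped.  With
    ``normalize=True`` target depths are rescaled by
    ``median(dp_ref)/median(dp_target)`` before subtraction (off by default:
    raw depths are subtracted).
    """
    ti = vt.sample_index(target)
    ri = vt.sample_index(reference)
    ok = (vt.dp[:, ti] >= 0) & (vt.dp[:, ri] >= 0)
    if not np.any(ok):
        raise ValueError("no shared loci with depth in both samples")
    dt = vt.dp[ok, ti].astype(float)
    dr = vt.dp[ok, ri].astype(float)
    if normalize:
        dt = dt * (np.median(dr) / np.median(dt))
    return pd.DataFrame({"chrom": vt.chrom[ok], "pos": vt.pos[ok], "value": dt - dr})


def sliding_window(series: pd.DataFrame, spec: WindowSpec, statistic: str = "value") -> WindowTrack:
    """Window means of a per-locus series (columns chrom, pos, value).

    ``snp_count`` mode emits full windows of *size* loci advancing by *step*
    loci; if loci remain beyond the last full window one trailing partial
    window is emitted with its actual locus count and ``partial`` flag.
    ``physical`` mode tiles each chromosome with ``[k*step, k*step + size)``
    intervals and omits windows containing no loci.
    """
    rows = []
    for chrom, grp in series.groupby("chrom", sort=False):
        pos = grp["pos"].to_numpy()
        val = grp["value"].to_numpy()
        order = np.argsort(pos, kind="stable")
        pos, val = pos[order], val[order]
        n = len(pos)
        if spec.mode == "snp_count":
            i0, last_end = 0, 0
            while i0 + spec.size <= n:
                j = i0 + spec.size
                rows.append((chrom, int(pos[i0]), int(pos[j - 1]) + 1, spec.size, val[i0:j].mean(), False))
                last_end = j
                i0 += spec.step
            if last_end < n and i0 < n:
                rows.append((chrom, int(pos[i0]), int(pos[-1]) + 1, n - i0, val[i0:].mean(), True))
        else:
            max_pos = int(pos[-1])
            k = 0
            while k * spec.step < max_pos:
                start = k * spec.step + 1
                end = start + spec.size
                lo = np.searchsorted(pos, start, side="left")
                hi = np.searchsorted(pos, end, side="left")
                if hi > lo:
                    rows.append((chrom, start, end, hi - lo, val[lo:hi].mean(), False))
                k += 1
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "n_loci", "mean", "partial"])
    return WindowTrack(windows=df, statistic=statistic, spec=spec)


def resample_ci(
    target_track: WindowTrack,
    reference_track: WindowTrack,
    n_iter: int = 10_000,
    quantiles: Sequence[float] = (0.95, 0.99),
    seed: int | None = None,
    exclude_chroms: Iterable[str] | None = None,
) -> CIThresholds:
    """Resampling thresholds for ΔDP window means.

    Each iteration draws one window-mean DP from the target and one from the
    reference, independently and uniformly with replacement over all windows
    (optionally excluding *exclude_chroms*, e.g. the chromosome under test);
    the difference forms the null.  Thresholds are the 95th/99th percentiles
    with linear interpolation between order statistics.
    """
    if n_iter < 100:
        warnings.warn("n_iter < 100 gives unstable resampling quantiles", stacklevel=2)
    tv = target_track.windows
    rv = reference_track.windows
    if exclude_chroms is not None:
        excl = set(exclude_chroms)
        tv = tv[~tv["chrom"].isin(excl)]
        rv = rv[~rv["chrom"].isin(excl)]
    t = tv["mean"].to_numpy()
    r = rv["mean"].to_numpy()
    if len(t) == 0 or len(r) == 0:
        raise ValueError("empty window track in resampling")
    rng = np.random.default_rng(seed)
    diffs = t[rng.integers(0, len(t), n_iter)] - r[rng.integers(0, len(r), n_iter)]
    q = np.quantile(diffs, sorted(quantiles), method="linear")
    return CIThresholds(ci95=float(q[0]), ci99=float(q[-1]), n_iter=n_iter, seed=seed)


def call_duplicated_regions(
    track: WindowTrack, ci: CIThresholds, min_run: int = 3
) -> list[RegionCall]:
    """Segment windows whose mean exceeds the 99% threshold into regions.

    Consecutive/overlapping marked windows merge; merged runs shorter than
    *min_run* windows are still reported but flagged ``short_run`` (isolated
    exceedances are suspect but should stay visible).  Region start/end are
    the first/last marked window's start/end.
    """
    df = track.windows
    marked = df[df["mean"] > ci.ci99]
    regions: list[RegionCall] = []
    run: list = []

    def flush(run_rows: list) -> None:
        if not run_rows:
            return
        flags = []
        if len(run_rows) < min_run:
            flags.append("short_run")
        if any(r.partial for r in run_rows):
            flags.append("partial_window")
        regions.append(
            RegionCall(
                chrom=run_rows[0].chrom,
                start=int(run_rows[0].start),
                end=int(run_rows[-1].end),
                region_class="duplicated",
                mean_stat=float(np.mean([r.mean for r in run_rows])),
                n_windows=len(run_rows),
                n_loci=int(sum(r.n_loci for r in run_rows)),
                flags=tuple(flags),
                evidence={"ci99": ci.ci99, "ci95": ci.ci95},
            )
        )

    for row in marked.itertuples(index=False):
        if run and row.chrom == run[-1].chrom and row.start <= run[-1].end:
            run.append(row)
        else:
            flush(run)
            run = [row]
    flush(run)
    return regions


def scan_duplications(
    vt: VariantTable,
    target: str,
    reference: str,
    spec: WindowSpec,
    n_iter: int = 5_000,
    seed: int | None = None,
    min_run: int = 3,
    loco: bool = True,
    normalize: bool = False,
) -> dict:
    """End-to-end ΔDP duplication scan for one target/reference pair.

    Builds per-sample DP window tracks and the ΔDP track over the shared
    locus set, estimates thresholds by resampling, and segments windows above
    the 99% threshold into region calls.  With ``loco=True`` (default) each
    chromosome is thresholded against a null resampled from the *other*
    chromosomes only (leave-one-chromosome-out), so a large duplication
    cannot inflate its own threshold; ``loco=False`` uses a single
    genome-wide null including every window.

    Returns a dict with keys ``regions``, ``delta_track``, ``thresholds``
    (per-chromosome when LOCO) and the parameters used.
    """
    delta = compute_delta_dp(vt, target, reference, normalize=normalize)
    shared = delta[["chrom", "pos"]]
    ti, ri = vt.sample_index(target), vt.sample_index(reference)
    ok = (vt.dp[:, ti] >= 0) & (vt.dp[:, ri] >= 0)
    t_series = pd.DataFrame({"chrom": vt.chrom[ok], "pos": vt.pos[ok], "value": vt.dp[ok, ti].astype(float)})
    r_series = pd.DataFrame({"chrom": vt.chrom[ok], "pos": vt.pos[ok], "value": vt.dp[ok, ri].astype(float)})
    t_track = sliding_window(t_series, spec, statistic="dp")
    r_track = sliding_window(r_series, spec, statistic="dp")
    d_track = sliding_window(delta, spec, statistic="delta_dp")

    rng = np.random.default_rng(seed)
    regions: list[RegionCall] = []
    thresholds: dict[str, CIThresholds] = {}
    chroms = list(pd.unique(d_track.windows["chrom"]))
    if loco and len(chroms) > 1:
        for c in chroms:
            sub_seed = int(rng.integers(0, 2**31 - 1))
            ci = resample_ci(t_track, r_track, n_iter=n_iter, seed=sub_seed, exclude_chroms=[c])
            thresholds[c] = ci
            sub = WindowTrack(
                windows=d_track.windows[d_track.windows["chrom"] == c].reset_index(drop=True),
                statistic=d_track.statistic,
                spec=spec,
            )
            regions.extend(call_duplicated_regions(sub, ci, min_run=min_run))
    else:
        ci = resample_ci(t_track, r_track, n_iter=n_iter, seed=int(rng.integers(0, 2**31 - 1)))
        thresholds["genome"] = ci
        regions = call_duplicated_regions(d_track, ci, min_run=min_run)
    return {
        "regions": regions,
        "delta_track": d_track,
        "target_track": t_track,
        "reference_track": r_track,
        "thresholds": thresholds,
        "params": {
            "target": target,
            "reference": reference,
            "mode": spec.mode,
            "window": spec.size,
            "step": spec.step,
            "n_iter": n_iter,
            "seed": seed,
            "min_run": min_run,
            "loco": loco,
        },
    }


def regions_to_bed(regions: Iterable[RegionCall], path: str) -> None:
    """Write region calls as BED (0-based half-open; explicit conversion)."""
    with open(str(path), "w") as fh:
        for r in regions:
            name = r.region_class + ("|" + ",".join(r.flags) if r.flags else "")
            fh.write(f"{r.chrom}\t{r.start - 1}\t{r.end - 1}\t{name}\t{r.mean_stat:.3f}\n")
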