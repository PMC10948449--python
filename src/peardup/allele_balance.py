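"""SNP-index / ΔSNP-index allele-balance analyses and zygosity windows.

The SNP index of a locus is the reference-allele read depth divided by total
depth.  Diploid heterozygotes centre on 0.5; in a three-copy (partially
triploid) region heterozygous loci centre on 1/3 or 2/3 depending on how many
of the three chromosome copies carry the reference allele.  The ΔSNP index —
|index difference| between two individuals at shared loci — is near zero
where the two share a genotype, which delineates shared haplotype segments.

Homozygosity windows follow the fixed-width rule used for the parental maps:
a window with at least one locus and no heterozygous genotype is homozygous,
a window with at least one heterozygous genotype is heterozygous, and a
window without loci carries no data.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from .depth_scan import RegionCall, WindowSpec, WindowTrack, sliding_window
from .variant_io import VariantTable


def snp_index(vt: VariantTable, sample: str) -> pd.DataFrame:
    """Per-locus SNP index for one sample.

    Returns columns chrom, pos, ref_depth, total_depth, snp_index.  Loci with
    missing AD or zero total allelic depth are dropped.
    """
    j = vt.sample_index(sample)
    ad = vt.ad[:, j, :].astype(float)
    present = ad >= 0
    if not present.any():
        raise ValueError(f"sample {sample!r} carries no AD data")
    total = np.where(present, ad, 0.0).sum(axis=1)
    has = present[:, 0] & (total > 0)
    ref_depth = ad[has, 0]
    total = total[has]
    return pd.DataFrame(
        {
            "chrom": vt.chrom[has],
            "pos": vt.pos[has],
            "ref_depth": ref_depth.astype(int),
            "total_depth": total.astype(int),
            "snp_index": ref_depth / total,
        }
    )


def delta_snp_index(a: pd.DataFrame, b: pd.DataFrame, spec: WindowSpec) -> WindowTrack:
    """Windowed |SNP index difference| between two samples at shared loci."""
    merged = a.merge(b, on=["chrom", "pos"], suffixes=("_a", "_b"))
    if merged.empty:
        raise ValueError("no shared loci between the two SNP-index series")
    series = pd.DataFrame(
        {
            "chrom": merged["chrom"],
            "pos": merged["pos"],
            "value": (merged["snp_index_a"] - merged["snp_index_b"]).abs(),
        }
    )
    return sliding_window(series, spec, statistic="delta_snp_index")


JOINT_CLASSES = ("2parents_homo", "2parents_hetero", "p1_only_hetero", "p2_only_hetero")


@dataclasses.dataclass
class ZygosityWindowMap:
    """Fixed-width zygosity classification of two parents.

    ``windows`` columns: chrom, start, end, n_loci_p1, n_loci_p2, class_p1,
    class_p2, joint (NaN where either parent lacks data).  ``fractions`` are
    joint-class shares over windows classified in both parents; with
    ``include_no_data`` the denominator is all windows and a ``no_data``
    share is reported.
    """

    windows: pd.DataFrame
    fractions: dict
    window_bp: int

    def to_tsv(self, path: str) -> None:
        self.windows.to_csv(str(path), sep="\t", index=False)


def _parent_window_class(het: np.ndarray, n: np.ndarray) -> np.ndarray:
    out = np.where(n == 0, "no_data", np.where(het > 0, "heterozygous", "homozygous"))
    return out.astype(object)


def classify_zygosity_windows(
    vt: VariantTable,
    p1: str,
    p2: str,
    window_bp: int = 200_000,
    include_no_data: bool = False,
) -> ZygosityWindowMap:
    """Classify fixed windows as homozygous/heterozygous per parent.

    A parent is heterozygous in a window iff it has at least one called
    heterozygous genotype there; homozygous iff it has at least one called
    locus and none heterozygous; otherwise the window has no data for that
    parent.  Windows tile ``[k*window_bp, (k+1)*window_bp)`` out to the last
    locus on each chromosome.
    """
    i1, i2 = vt.sample_index(p1), vt.sample_index(p2)
    rows = []
    df = pd.DataFrame({"chrom": vt.chrom, "pos": vt.pos})
    for chrom, grp in df.groupby("chrom", sort=False):
        pos = grp["pos"].to_numpy()
        idx = grp.index.to_numpy()
        n_win = int((pos.max() - 1) // window_bp) + 1
        win = (pos - 1) // window_bp
        for k in range(n_win):
            sel = idx[win == k]
            stats = []
            for si in (i1, i2):
                g = vt.gt[sel, si]
                called = g[:, 0] >= 0
                het = called & (g[:, 0] != g[:, 1])
                stats.append((int(called.sum()), int(het.sum())))
            rows.append(
                (chrom, k * window_bp + 1, (k + 1) * window_bp + 1, stats[0][0], stats[1][0], stats[0][1], stats[1][1])
            )
    w = pd.DataFrame(rows, columns=["chrom", "start", "end", "n_loci_p1", "n_loci_p2", "n_het_p1", "n_het_p2"])
    w["class_p1"] = _parent_window_class(w["n_het_p1"].to_numpy(), w["n_loci_p1"].to_numpy())
    w["class_p2"] = _parent_window_class(w["n_het_p2"].to_numpy(), w["n_loci_p2"].to_numpy())

    both = (w["class_p1"] != "no_data") & (w["class_p2"] != "no_data")
    joint = np.full(len(w), None, dtype=object)
    h1 = w["class_p1"] == "heterozygous"
    h2 = w["class_p2"] == "heterozygous"
    joint[(both & ~h1 & ~h2).to_numpy()] = "2parents_homo"
    joint[(both & h1 & h2).to_numpy()] = "2parents_hetero"
    joint[(both & h1 & ~h2).to_numpy()] = "p1_only_hetero"
    joint[(both & ~h1 & h2).to_numpy()] = "p2_only_hetero"
    w["joint"] = joint

    n_both = int(both.sum())
    fractions = {}
    denom = len(w) if include_no_data else n_both
    if denom > 0:
        for c in JOINT_CLASSES:
            fractions[c] = float((w["joint"] == c).sum() / denom)
        if include_no_data:
            fractions["no_data"] = float((len(w) - n_both) / denom)
    return ZygosityWindowMap(windows=w, fractions=fractions, window_bp=window_bp)


def classify_ploidy_regions(
    idx: pd.DataFrame,
    candidate_regions: list[RegionCall],
    het_gate: tuple = (0.1, 0.9),
    min_loci: int = 20,
) -> list[RegionCall]:
    """Classify candidate regions as triploid or heterozygous-diploid.

    Within each candidate interval, loci in the heterozygous spectrum
    (``het_gate``, exclusive) are scored by mean distance of their SNP index
    to the diploid expectation {0.5} versus the triploid expectations
    {1/3, 2/3}; the nearer model wins.  Regions with fewer than *min_loci*
    usable loci are returned as ``no_data``.
    """
    lo, hi = het_gate
    out = []
    for r in candidate_regions:
        sel = (idx["chrom"] == r.chrom) & (idx["pos"] >= r.start) & (idx["pos"] < r.end)
        x = idx.loc[sel, "snp_index"].to_numpy()
        x = x[(x > lo) & (x < hi)]
        if len(x) < min_loci:
            out.append(
                dataclasses.replace(
                    r, region_class="no_data", evidence={**r.evidence, "n_het_loci": int(len(x))}
                )
            )
            continue
        d_di = float(np.mean(np.abs(x - 0.5)))
        d_tri = float(np.mean(np.minimum(np.abs(x - 1 / 3), np.abs(x - 2 / 3))))
        cls = "triploid" if d_tri < d_di else "diploid_het"
        out.append(
            dataclasses.replace(
                r,
                region_class=cls,
                evidence={**r.evidence, "d_di": d_di, "d_tri": d_tri, "n_het_loci": int(len(x))},
            )
        )
    return out
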