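"""Multi-sample variant tables and VCFtools-style filtering.

The central container is :class:`VariantTable`, a columnar in-memory model of
a multi-sample VCF restricted to the FORMAT fields the depth and allele-balance
analyses consume (GT, DP, AD).  :func:`filter_variants` reimplements the
VCFtools filter semantics used throughout the study (per-genotype depth
masking, indel removal, allele-count caps, site mean-depth and call-rate
bounds, allele-frequency bounds and greedy coordinate thinning) with a fixed,
documented order of application.

Coordinates are 1-based inclusive everywhere in this package; window and
region intervals are half-open ``[start, end)``.  BED output converts to
0-based half-open explicitly.
"""

from __future__ import annotations

import dataclasses
import gzip
import io
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

#: Sentinel for missing integer data (genotype allele index, DP, AD).
MISSING = -1


@dataclasses.dataclass
class VariantTable:
    """Per-locus, per-sample genotype calls with total and per-allele depths.

    Attributes
    ----------
    chrom : (n,) array of str
        Chromosome identifier per locus.
    pos : (n,) array of int
        1-based coordinate; strictly increasing within each chromosome.
    ref : (n,) array of str
        Reference allele sequence.
    alt : list of tuple of str
        Alternate allele sequences per locus (multi-allelic sites unsplit).
    samples : list of str
    gt : (n, s, 2) int8 array
        Unphased allele-index pairs; ``MISSING`` marks uncalled alleles.
    dp : (n, s) int32 array
        Total read depth; ``MISSING`` where absent.
    ad : (n, s, A) int32 array
        Per-allele read depths padded to the table-wide maximum allele count;
        ``MISSING`` marks padding and absent AD.  ``sum(ad)`` is not assumed
        to equal ``dp`` (callers disagree), but a called genotype always has
        positive allelic depth in data produced by :mod:`peardup.synthetic`.
    """

    chrom: np.ndarray
    pos: np.ndarray
    ref: np.ndarray
    alt: list
    samples: list
    gt: np.ndarray
    dp: np.ndarray
    ad: np.ndarray

    def __post_init__(self) -> None:
        self.pos = np.asarray(self.pos, dtype=np.int64)
        self.chrom = np.asarray(self.chrom, dtype=object)
        self.ref = np.asarray(self.ref, dtype=object)
        if len(self.alt) != len(self.pos):
            raise ValueError("alt list length does not match locus count")
        # strict positional ordering within chromosome
        same = self.chrom[1:] == self.chrom[:-1]
        if np.any(same & (np.diff(self.pos) <= 0)):
            raise ValueError("pos must be strictly increasing within each chrom")

    # -- basic introspection -------------------------------------------------

    @property
    def n_loci(self) -> int:
        return len(self.pos)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def sample_index(self, name: str) -> int:
        try:
            return self.samples.index(name)
        except ValueError:
            raise KeyError(f"sample {name!r} not present in table") from None

    def n_alleles(self) -> np.ndarray:
        """Total allele count (ref + alts) per locus."""
        return np.array([1 + len(a) for a in self.alt], dtype=np.int64)

    def is_indel(self) -> np.ndarray:
        """True where any ref/alt allele is not a single base."""
        out = np.empty(self.n_loci, dtype=bool)
        for i in range(self.n_loci):
            out[i] = len(self.ref[i]) != 1 or any(len(a) != 1 for a in self.alt[i])
        return out

    def called(self) -> np.ndarray:
        """(n, s) boolean mask of called genotypes."""
        return self.gt[:, :, 0] >= 0

    # -- subsetting ----------------------------------------------------------

    def take(self, mask: np.ndarray) -> "VariantTable":
        """Return a copy restricted to loci where *mask* is true."""
        idx = np.flatnonzero(np.asarray(mask))
        return VariantTable(
            chrom=self.chrom[idx].copy(),
            pos=self.pos[idx].copy(),
            ref=self.ref[idx].copy(),
            alt=[self.alt[i] for i in idx],
            samples=list(self.samples),
            gt=self.gt[idx].copy(),
            dp=self.dp[idx].copy(),
            ad=self.ad[idx].copy(),
        )

    def copy(self) -> "VariantTable":
        return self.take(np.ones(self.n_loci, dtype=bool))

    def equals(self, other: "VariantTable") -> bool:
        return (
            self.samples == other.samples
            and np.array_equal(self.chrom, other.chrom)
            and np.array_equal(self.pos, other.pos)
            and np.array_equal(self.ref, other.ref)
            and self.alt == other.alt
            and np.array_equal(self.gt, other.gt)
            and np.array_equal(self.dp, other.dp)
            and np.array_equal(self.ad, other.ad)
        )

    # -- site summaries ------------------------------------------------------

    def site_mean_dp(self) -> np.ndarray:
        """Mean DP per site over genotypes with depth data; NaN if none."""
        dp = self.dp.astype(float)
        has = self.dp >= 0
        with np.errstate(invalid="ignore"):
            out = np.where(has, dp, 0.0).sum(axis=1) / has.sum(axis=1)
        return out

    def call_rate(self) -> np.ndarray:
        return self.called().sum(axis=1) / max(self.n_samples, 1)

    def allele_freqs(self) -> list:
        """Per-site allele frequencies from called genotypes (post-masking)."""
        freqs = []
        for i in range(self.n_loci):
            g = self.gt[i]
            alleles = g[g >= 0]
            k = 1 + len(self.alt[i])
            if alleles.size == 0:
                freqs.append(np.full(k, np.nan))
            else:
                counts = np.bincount(alleles, minlength=k)[:k]
                freqs.append(counts / alleles.size)
        return freqs

    def minor_allele_freq(self) -> np.ndarray:
        return np.array([np.min(f) for f in self.allele_freqs()])


@dataclasses.dataclass(frozen=True)
class FilterParams:
    """VCFtools-style filter thresholds; ``None`` disables a rule.

    ``max_missing`` follows the VCFtools convention: it is the minimum
    fraction of called genotypes required, so 1 allows no missing data and 0
    allows any amount.
    """

    min_dp: int | None = None
    max_dp: int | None = None
    min_mean_dp: float | None = None
    max_mean_dp: float | None = None
    max_missing: float | None = None
    maf: float | None = None
    max_maf: float | None = None
    max_alleles: int | None = None
    remove_indels: bool = False
    thin_bp: int = 0

    def __post_init__(self) -> None:
        if self.min_dp is not None and self.max_dp is not None and self.min_dp > self.max_dp:
            raise ValueError("min_dp > max_dp")
        if (
            self.min_mean_dp is not None
            and self.max_mean_dp is not None
            and self.min_mean_dp > self.max_mean_dp
        ):
            raise ValueError("min_mean_dp > max_mean_dp")
        if self.max_missing is not None and not 0.0 <= self.max_missing <= 1.0:
            raise ValueError("max_missing must be in [0, 1]")
        if self.thin_bp < 0:
            raise ValueError("thin_bp must be >= 0")


def read_vcf(path: str, samples: Sequence[str] | None = None) -> VariantTable:
    """Read a VCF 4.x file (plain or gzipped) into a :class:`VariantTable`.

    Multi-allelic sites are retained unsplit.  If *samples* is given, columns
    are returned in that order; a requested sample absent from the file is a
    hard error.  A missing FORMAT/GT declaration is a hard error; missing AD
    leaves ``ad`` flagged :data:`MISSING`.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    if "##FORMAT=<ID=GT" not in vcf.raw_header:
        raise ValueError(f"{path}: VCF lacks FORMAT/GT definition")
    file_samples = list(vcf.samples)
    if samples is None:
        samples = file_samples
    else:
        missing = [s for s in samples if s not in file_samples]
        if missing:
            raise KeyError(f"sample(s) not in VCF: {', '.join(missing)}")
    cols = np.array([file_samples.index(s) for s in samples])
    has_ad = "##FORMAT=<ID=AD" in vcf.raw_header

    chrom, pos, ref, alt = [], [], [], []
    gt_rows, dp_rows, ad_rows = [], [], []
    max_al = 1
    for v in vcf:
        chrom.append(v.CHROM)
        pos.append(v.POS)
        ref.append(v.REF)
        alts = tuple(v.ALT)
        alt.append(alts)
        max_al = max(max_al, 1 + len(alts))
        g = np.array([row[:2] for row in v.genotypes], dtype=np.int64)[cols]
        g[g < 0] = MISSING
        gt_rows.append(g)
        d = v.format("DP")
        if d is None:
            dp_rows.append(np.full(len(cols), MISSING, dtype=np.int64))
        else:
            d = d.reshape(len(file_samples), -1)[:, 0].astype(np.int64)[cols]
            d[d < 0] = MISSING
            dp_rows.append(d)
        if has_ad:
            a = v.format("AD")
            if a is None:
                ad_rows.append(None)
            else:
                a = a.astype(np.int64)[cols]
                a[a < 0] = MISSING
                ad_rows.append(a)
        else:
            ad_rows.append(None)
    n = len(pos)
    s = len(cols)
    gt = np.full((n, s, 2), MISSING, dtype=np.int8)
    dp = np.full((n, s), MISSING, dtype=np.int32)
    ad = np.full((n, s, max_al), MISSING, dtype=np.int32)
    for i in range(n):
        gt[i] = gt_rows[i]
        dp[i] = dp_rows[i]
        if ad_rows[i] is not None:
            a = ad_rows[i]
            ad[i, :, : a.shape[1]] = a
    return VariantTable(
        chrom=np.array(chrom, dtype=object),
        pos=np.array(pos, dtype=np.int64),
        ref=np.array(ref, dtype=object),
        alt=alt,
        samples=list(samples),
        gt=gt,
        dp=dp,
        ad=ad,
    )


def write_vcf(vt: VariantTable, path: str, contigs: dict | None = None) -> None:
    """Write *vt* as a minimal VCF 4.2 text file with GT:DP:AD genotypes.

    Gzip-compressed output is selected by a ``.gz`` suffix.
    """
    if contigs is None:
        contigs = {}
        for c in pd.unique(vt.chrom):
            contigs[c] = int(vt.pos[vt.chrom == c].max())
    opener = gzip.open if str(path).endswith(".gz") else open
    with opener(str(path), "wt") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=peardup\n")
        for name, length in contigs.items():
            fh.write(f"##contig=<ID={name},length={length}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n')
        fh.write('##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(vt.samples) + "\n")
        for i in range(vt.n_loci):
            alts = ",".join(vt.alt[i]) if vt.alt[i] else "."
            k = 1 + len(vt.alt[i])
            fields = [vt.chrom[i], str(vt.pos[i]), ".", vt.ref[i], alts, ".", "PASS", ".", "GT:DP:AD"]
            for j in range(vt.n_samples):
                a, b = vt.gt[i, j]
                g = "./." if a < 0 else f"{a}/{b}"
                d = "." if vt.dp[i, j] < 0 else str(vt.dp[i, j])
                adv = vt.ad[i, j, :k]
                ads = "." if np.all(adv < 0) else ",".join(str(max(x, 0)) for x in adv)
                fields.append(f"{g}:{d}:{ads}")
            fh.write("\t".join(fields) + "\n")


def filter_variants(vt: VariantTable, p: FilterParams) -> VariantTable:
    """Apply the VCFtools-style filter set to *vt*; returns a new table.

    Rules are applied in a fixed order (genotype-level before site-level, as
    VCFtools does): (1) per-genotype DP bounds mask the genotype's GT/DP/AD;
    (2) indel removal; (3) allele-count cap; (4) site mean-DP bounds over
    genotypes retaining depth data; (5) call-rate bound (``max_missing``);
    (6) minor/major allele-frequency bounds computed from called genotypes
    after DP masking (VCFtools ``--maf`` semantics, not AD-based); (7) greedy
    coordinate thinning in ascending order per chromosome.  Sites whose mean
    DP is undefined (no genotype retains depth) are dropped when a mean-DP
    bound is set; allele-frequency bounds do not apply to sites with zero
    called genotypes.
    """
    out = vt.copy()

    # (1) per-genotype depth mask
    if p.min_dp is not None or p.max_dp is not None:
        dp = out.dp
        bad = np.zeros(dp.shape, dtype=bool)
        has = dp >= 0
        if p.min_dp is not None:
            bad |= has & (dp < p.min_dp)
        if p.max_dp is not None:
            bad |= has & (dp > p.max_dp)
        out.gt[bad] = MISSING
        out.dp[bad] = MISSING
        out.ad[bad] = MISSING

    keep = np.ones(out.n_loci, dtype=bool)

    # (2) indels
    if p.remove_indels:
        keep &= ~out.is_indel()

    # (3) allele count
    if p.max_alleles is not None:
        keep &= out.n_alleles() <= p.max_alleles

    # (4) site mean depth
    if p.min_mean_dp is not None or p.max_mean_dp is not None:
        mean_dp = out.site_mean_dp()
        defined = ~np.isnan(mean_dp)
        ok = defined.copy()
        if p.min_mean_dp is not None:
            ok &= mean_dp >= p.min_mean_dp
        if p.max_mean_dp is not None:
            ok &= mean_dp <= p.max_mean_dp
        keep &= ok

    # (5) call rate
    if p.max_missing is not None:
        keep &= out.call_rate() >= p.max_missing

    # (6) allele frequency
    if p.maf is not None or p.max_maf is not None:
        for i in np.flatnonzero(keep):
            g = out.gt[i]
            alleles = g[g >= 0]
            if alleles.size == 0:
                continue
            k = 1 + len(out.alt[i])
            counts = np.bincount(alleles, minlength=k)[:k]
            freqs = counts / alleles.size
            if p.maf is not None and freqs.min() < p.maf:
                keep[i] = False
            if p.max_maf is not None and freqs.max() > p.max_maf:
                keep[i] = False

    # (7) thinning: greedy per chromosome in ascending coordinate order
    if p.thin_bp > 0:
        last_kept: dict = {}
        for i in np.flatnonzero(keep):
            c = out.chrom[i]
            prev = last_kept.get(c)
            if prev is not None and out.pos[i] - prev < p.thin_bp:
                keep[i] = False
            else:
                last_kept[c] = out.pos[i]

    return out.take(keep)


def locus_summary(vt: VariantTable) -> pd.DataFrame:
    """Per-site summary (chrom, pos, mean_dp, call_rate, maf)."""
    return pd.DataFrame(
        {
            "chrom": vt.chrom,
            "pos": vt.pos,
            "mean_dp": vt.site_mean_dp(),
            "call_rate": vt.call_rate(),
            "maf": vt.minor_allele_freq(),
        }
    )


def write_locus_summary(vt: VariantTable, path: str) -> None:
    locus_summary(vt).to_csv(str(path), sep="\t", index=False)
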