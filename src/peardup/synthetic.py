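"""Synthetic data generators emulating the study's sequencing designs.

Three generators cover every input the analyses consume, each a pure
function of its parameters and a seed, and each returning a truth table so
downstream recovery tests never re-derive truth from the data they check:

* :func:`simulate_cross` — an F1 population from a S1S3 female and a
  duplication-carrying S4dS5/S5 male with configurable gamete-class
  probabilities and an optional recombination fraction between two linked
  S-locus markers.
* :func:`simulate_variant_table` — ddRAD-like (sparse, clustered) or
  WGS-like (dense) marker sets on a multi-chromosome genome, with per-locus
  depths drawn negative-binomially around a mean scaled by local copy number
  and allelic depths drawn from copy-proportional probabilities (1/3 : 2/3
  in three-copy regions).
* :func:`simulate_amplicon_reads` — amplicon read sets whose haplotype
  proportions follow copy number × amplification bias, with per-base
  substitution errors.

Depth biases are modelled as shared between samples (a lognormal regional
factor for WGS, a per-locus amplification factor for ddRAD) plus a small
sample-specific regional factor: locus-specific coverage biases in real
libraries (GC content, mappability, restriction-site amplification) affect
every individual similarly.  This structure is what the ΔDP resampling
threshold implicitly relies on — shared bias cancels in the paired, observed
ΔDP but inflates the unpaired resampling null.
"""

from __future__ import annotations

import dataclasses
import json
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .variant_io import MISSING, VariantTable

BASES = np.array(list("ACGT"))


# ---------------------------------------------------------------------------
# layouts, profiles, models
# ---------------------------------------------------------------------------


@dataclasses.dataclass(frozen=True)
class GenomeLayout:
    """Chromosome names/lengths and marker densities for both designs."""

    chromosomes: tuple  # of (name, length_bp)
    wgs_loci_per_kb: float = 1.0
    ddrad_loci_per_mb: float = 20.0
    ddrad_cluster_loci: float = 4.0  # mean loci per restriction-site cluster
    ddrad_cluster_span: int = 400    # bp spanned by one cluster

    def __post_init__(self) -> None:
        if any(l <= 0 for _, l in self.chromosomes):
            raise ValueError("chromosome lengths must be positive")
        if self.wgs_loci_per_kb <= 0 or self.ddrad_loci_per_mb <= 0:
            raise ValueError("marker densities must be positive")

    @classmethod
    def toy(cls, n_chrom: int = 3, length: int = 30_000_000, **kw) -> "GenomeLayout":
        """Small default genome: three 30-Mb chromosomes."""
        return cls(tuple((f"chr{i + 1:02d}", length) for i in range(n_chrom)), **kw)

    @classmethod
    def pear_like(cls, length: int = 30_000_000, **kw) -> "GenomeLayout":
        """17 chromosomes of 30 Mb — the scale of the pear reference genome."""
        return cls.toy(n_chrom=17, length=length, **kw)


@dataclasses.dataclass(frozen=True)
class CopyNumberProfile:
    """Copy-number segments for one individual; copy 2 everywhere else."""

    sample: str
    segments: tuple = ()  # of (chrom, start, end, copy_number), 1-based half-open

    def __post_init__(self) -> None:
        by_chrom: dict = {}
        for chrom, start, end, cn in self.segments:
            if cn not in (1, 2, 3):
                raise ValueError("copy_number must be 1, 2 or 3")
            by_chrom.setdefault(chrom, []).append((start, end))
        for ivs in by_chrom.values():
            ivs.sort()
            for (s1, e1), (s2, e2) in zip(ivs, ivs[1:]):
                if s2 < e1:
                    raise ValueError("copy-number segments overlap")

    def copy_number(self, chrom: str, pos: np.ndarray) -> np.ndarray:
        out = np.full(len(pos), 2, dtype=np.int8)
        for c, start, end, cn in self.segments:
            if c == chrom:
                out[(pos >= start) & (pos < end)] = cn
        return out


#: Male gamete-class probabilities matching the observed segregation
#: 107:7:3:1:22 over (S5, S5dS5, S4, S4dS4, S4dS5).
PAPER_GAMETE_COUNTS = {"S5": 107, "S5dS5": 7, "S4": 3, "S4dS4": 1, "S4dS5": 22}


def _normalize(d: Mapping[str, float]) -> dict:
    t = sum(d.values())
    return {k: v / t for k, v in d.items()}


@dataclasses.dataclass(frozen=True)
class CrossModel:
    """F1 cross between a diploid female and a duplication-carrying male."""

    female_genotype: tuple = ("S1", "S3")
    male_alleles: tuple = ("S4", "S5")
    gamete_probs: tuple = tuple(sorted(_normalize(PAPER_GAMETE_COUNTS).items()))
    recombination_fraction: float = 0.02
    n_seedlings: int = 140

    def __post_init__(self) -> None:
        probs = dict(self.gamete_probs)
        if abs(sum(probs.values()) - 1.0) > 1e-9:
            raise ValueError("gamete-class probabilities must sum to 1")
        if not 0.0 <= self.recombination_fraction <= 0.5:
            raise ValueError("recombination fraction must be in [0, 0.5]")

    def probs(self) -> dict:
        return dict(self.gamete_probs)


@dataclasses.dataclass(frozen=True)
class NoiseModel:
    """Depth and amplicon noise parameters.

    mean_depth
        genome-wide mean per-locus depth for a diploid sample (reads).
    dispersion
        negative-binomial size parameter k; variance = m + m^2/k.
    regional_cv / regional_block_bp
        lognormal coefficient of variation of the depth bias shared between
        samples, piecewise constant over blocks of this size (WGS mode).
    sample_cv
        small sample-specific regional lognormal CV (library-to-library).
    locus_cv
        per-locus shared amplification bias CV (ddRAD mode).
    base_error
        per-base substitution probability for amplicon reads.
    """

    mean_depth: float = 50.0
    dispersion: float = 20.0
    regional_cv: float = 0.10
    regional_block_bp: int = 500_000
    sample_cv: float = 0.015
    locus_cv: float = 0.15
    base_error: float = 0.005

    def __post_init__(self) -> None:
        if self.mean_depth <= 0 or self.dispersion <= 0:
            raise ValueError("mean_depth and dispersion must be positive")
        if not 0.0 <= self.base_error <= 0.1:
            raise ValueError("base_error must be in [0, 0.1]")


# ---------------------------------------------------------------------------
# cross simulation
# ---------------------------------------------------------------------------

_GAMETE_ALLELES = {
    "S5": ("S5",), "S5dS5": ("S5", "S5"), "S4": ("S4",),
    "S4dS4": ("S4", "S4"), "S4dS5": ("S4", "S5"),
}


def gamete_alleles(gamete_class: str) -> tuple:
    """Allele multiset carried by a paternal gamete class."""
    if gamete_class in _GAMETE_ALLELES:
        return _GAMETE_ALLELES[gamete_class]
    if "d" in gamete_class:
        a, b = gamete_class.split("d")
        return (a, b)
    return (gamete_class,)


def simulate_cross(model: CrossModel, seed: int | None = None) -> pd.DataFrame:
    """Draw seedling genotypes and gamete truth labels for one cross.

    The maternal allele is Bernoulli(0.5) at the primary marker; at the
    second linked marker it recombines with probability
    ``model.recombination_fraction`` (the paternal contribution is assumed
    intact at both markers).  Returns one row per seedling with the true
    female gamete at both markers, the true male gamete class, the seedling
    allele multiset and a recombinant flag.
    """
    rng = np.random.default_rng(seed)
    probs = model.probs()
    classes = list(probs)
    male = rng.choice(len(classes), size=model.n_seedlings, p=[probs[c] for c in classes])
    fem_idx = rng.integers(0, 2, size=model.n_seedlings)
    recomb = rng.random(model.n_seedlings) < model.recombination_fraction
    rows = []
    for i in range(model.n_seedlings):
        mg = classes[male[i]]
        fa = model.female_genotype[fem_idx[i]]
        fb = model.female_genotype[1 - fem_idx[i]] if recomb[i] else fa
        alleles = tuple(sorted((fa,) + gamete_alleles(mg)))
        rows.append(
            {
                "seedling": f"Seedling{i + 1:03d}",
                "female_gamete": fa,
                "female_gamete_marker2": fb,
                "male_gamete": mg,
                "alleles": alleles,
                "is_duplicated": len(alleles) == 3,
                "is_recombinant": bool(recomb[i]),
            }
        )
    return pd.DataFrame(rows)


def seedling_amplicon_genotype(alleles: Sequence[str]) -> dict:
    """Copy-number mapping (haplotype -> copies) from an allele multiset."""
    out: dict = {}
    for a in alleles:
        out[a] = out.get(a, 0) + 1
    return out


# ---------------------------------------------------------------------------
# variant-table simulation
# ---------------------------------------------------------------------------


def _lognormal_factor(rng: np.random.Generator, cv: float, size) -> np.ndarray:
    if cv <= 0:
        return np.ones(size)
    sigma = np.sqrt(np.log1p(cv * cv))
    return rng.lognormal(mean=-0.5 * sigma * sigma, sigma=sigma, size=size)


def _positions(layout: GenomeLayout, mode: str, rng: np.random.Generator):
    chroms, pos = [], []
    for name, length in layout.chromosomes:
        if mode == "wgs":
            spacing = 1000.0 / layout.wgs_loci_per_kb
            gaps = rng.exponential(spacing, size=int(2 * length / spacing) + 10)
            p = np.unique(np.cumsum(gaps).astype(np.int64) + 1)
            p = p[p <= length]
        elif mode == "ddrad":
            clusters_per_mb = layout.ddrad_loci_per_mb / layout.ddrad_cluster_loci
            spacing = 1e6 / clusters_per_mb
            gaps = rng.exponential(spacing, size=int(2 * length / spacing) + 10)
            starts = np.cumsum(gaps).astype(np.int64) + 1
            starts = starts[starts <= length - layout.ddrad_cluster_span]
            plist = []
            for s in starts:
                k = 1 + rng.poisson(layout.ddrad_cluster_loci - 1)
                plist.append(s + np.sort(rng.choice(layout.ddrad_cluster_span, size=min(k, layout.ddrad_cluster_span), replace=False)))
            p = np.unique(np.concatenate(plist)) if plist else np.array([], dtype=np.int64)
        else:
            raise ValueError(f"unknown mode {mode!r}")
        chroms.append(np.full(len(p), name, dtype=object))
        pos.append(p)
    return np.concatenate(chroms), np.concatenate(pos)


def simulate_variant_table(
    layout: GenomeLayout,
    profiles: Mapping[str, CopyNumberProfile],
    noise: NoiseModel,
    mode: str = "wgs",
    seed: int | None = None,
    het_rate: float = 0.5,
) -> tuple:
    """Simulate a multi-sample :class:`VariantTable` plus its truth table.

    Loci are placed by the layout's density for *mode*; per locus and sample
    the depth is NegBin(mean_depth · copy/2 · bias, dispersion) and allelic
    depths are binomial with reference proportion equal to the fraction of
    chromosome copies carrying the reference allele (drawn uniformly from
    the configurations compatible with a heterozygous genotype: 1/2 at copy
    two; 1/3 or 2/3 at copy three).  Genotypes with zero depth are missing.

    Returns ``(table, truth)`` where ``truth`` contains per-locus/per-sample
    arrays (copy_number, genotype_code with 0=hom-ref/1=het/2=hom-alt,
    ref_copies, p_ref) and the generator parameters.
    """
    rng = np.random.default_rng(seed)
    samples = list(profiles)
    chrom, pos = _positions(layout, mode, rng)
    n, s = len(pos), len(samples)

    ref_idx = rng.integers(0, 4, size=n)
    alt_idx = (ref_idx + rng.integers(1, 4, size=n)) % 4
    ref = BASES[ref_idx].astype(object)
    alt = [(a,) for a in BASES[alt_idx]]

    # shared per-locus depth bias
    block = np.zeros(n, dtype=np.int64)
    chrom_codes, chrom_unique = pd.factorize(chrom)
    shared = np.ones(n)
    blocks_per_chrom = {
        name: int(length // noise.regional_block_bp) + 1 for name, length in layout.chromosomes
    }
    block_local = (pos - 1) // noise.regional_block_bp
    offset = 0
    block_offsets = {}
    for name, _ in layout.chromosomes:
        block_offsets[name] = offset
        offset += blocks_per_chrom[name]
    for i, name in enumerate(chrom_unique):
        block[chrom_codes == i] = block_offsets[str(name)]
    block = block + block_local
    n_blocks = offset
    regional = _lognormal_factor(rng, noise.regional_cv, n_blocks)
    shared = regional[block]
    if mode == "ddrad":
        shared = shared * _lognormal_factor(rng, noise.locus_cv, n)

    gt = np.full((n, s, 2), MISSING, dtype=np.int8)
    dp = np.zeros((n, s), dtype=np.int32)
    ad = np.full((n, s, 2), MISSING, dtype=np.int32)
    cn_truth = np.full((n, s), 2, dtype=np.int8)
    code_truth = np.zeros((n, s), dtype=np.int8)
    rc_truth = np.zeros((n, s), dtype=np.int8)
    pref_truth = np.zeros((n, s))

    for j, name in enumerate(samples):
        prof = profiles[name]
        cn = np.full(n, 2, dtype=np.int8)
        for i, cname in enumerate(chrom_unique):
            m = chrom_codes == i
            cn[m] = prof.copy_number(str(cname), pos[m])
        u = rng.random(n)
        code = np.where(u < het_rate, 1, np.where(u < het_rate + (1 - het_rate) / 2, 0, 2))
        # reference-copy count: hom-ref carries cn copies, hom-alt none; a
        # heterozygote draws uniformly from the compatible configurations
        rc = np.where(code == 0, cn, 0).astype(np.int8)
        het = code == 1
        rc_het = np.where(cn[het] == 3, rng.integers(1, 3, size=int(het.sum())), 1)
        rc[het] = rc_het
        p_ref = rc / cn
        sample_factor = _lognormal_factor(rng, noise.sample_cv, n_blocks)[block]
        mean = noise.mean_depth * (cn / 2.0) * shared * sample_factor
        k = noise.dispersion
        d = rng.negative_binomial(k, k / (k + mean)).astype(np.int32)
        a_ref = rng.binomial(d, p_ref).astype(np.int32)
        gt[:, j, 0] = np.where(code == 2, 1, 0)
        gt[:, j, 1] = np.where(code == 0, 0, 1)
        gt[d == 0, j] = MISSING
        dp[:, j] = d
        ad[:, j, 0] = a_ref
        ad[:, j, 1] = d - a_ref
        cn_truth[:, j] = cn
        code_truth[:, j] = code
        rc_truth[:, j] = rc
        pref_truth[:, j] = p_ref

    vt = VariantTable(chrom=chrom, pos=pos, ref=ref, alt=alt, samples=samples, gt=gt, dp=dp, ad=ad)
    truth = {
        "copy_number": cn_truth,
        "genotype_code": code_truth,
        "ref_copies": rc_truth,
        "p_ref": pref_truth,
        "profiles": dict(profiles),
        "params": {
            "mode": mode,
            "seed": seed,
            "het_rate": het_rate,
            "noise": dataclasses.asdict(noise),
            "layout": {
                "chromosomes": list(layout.chromosomes),
                "wgs_loci_per_kb": layout.wgs_loci_per_kb,
                "ddrad_loci_per_mb": layout.ddrad_loci_per_mb,
            },
        },
    }
    return vt, truth


def duplication_benchmark(seed: int | None = None, mode: str = "wgs") -> tuple:
    """The standard duplication-recovery scenario at study scale.

    A 17 × 30 Mb pear-like genome with a diploid reference ('515-20') and a
    target ('415-1') carrying a copy-3 segment at 15.3–26.3 Mb of chr17 — the
    coordinates and ~11-Mb extent of the duplication this package is built to
    detect — under the default depth/noise model.  Returns ``(table, truth)``
    from :func:`simulate_variant_table`.
    """
    layout = GenomeLayout.pear_like()
    dup_chrom = layout.chromosomes[-1][0]
    profiles = {
        "515-20": CopyNumberProfile("515-20"),
        "415-1": CopyNumberProfile("415-1", ((dup_chrom, 15_300_001, 26_300_001, 3),)),
    }
    return simulate_variant_table(layout, profiles, NoiseModel(), mode=mode, seed=seed)


# ---------------------------------------------------------------------------
# amplicon simulation
# ---------------------------------------------------------------------------


def make_haplotype_refs(
    names: Sequence[str] = ("S1", "S3", "S4", "S5"),
    length: int = 180,
    n_diffs: int = 8,
    seed: int = 0,
) -> dict:
    """Deterministic reference haplotype sequences for the S-locus markers.

    Each haplotype mutates its own disjoint block of *n_diffs* positions of a
    common random backbone, so pairwise edit distance is 2 · *n_diffs* —
    comfortably beyond the stack-matching tolerance.
    """
    if length < n_diffs * len(names):
        raise ValueError("length too short for the requested divergence")
    rng = np.random.default_rng(seed)
    backbone = rng.integers(0, 4, size=length)
    refs = {}
    for i, name in enumerate(names):
        seq = backbone.copy()
        sl = slice(i * n_diffs, (i + 1) * n_diffs)
        seq[sl] = (seq[sl] + 1 + rng.integers(0, 3, size=n_diffs)) % 4
        refs[name] = "".join(BASES[seq])
    return refs


def haplotype_probs(genotype: Mapping[str, int], bias: Mapping[str, float] | None = None) -> dict:
    """Read-origin probabilities proportional to copy number × bias."""
    w = {h: c * (bias.get(h, 1.0) if bias else 1.0) for h, c in genotype.items()}
    t = sum(w.values())
    if t <= 0:
        raise ValueError("genotype has no positive-copy haplotype")
    return {h: v / t for h, v in w.items()}


def expected_haplotype_ratio(
    genotype: Mapping[str, int], bias: Mapping[str, float] | None = None
) -> float:
    """Expected most-frequent / second-most-frequent haplotype read ratio."""
    p = sorted(haplotype_probs(genotype, bias).values(), reverse=True)
    if len(p) < 2:
        raise ValueError("need at least two haplotypes")
    return p[0] / p[1]


def simulate_amplicon_reads(
    genotype: Mapping[str, int],
    refs: Mapping[str, str],
    n_reads: int,
    bias: Mapping[str, float] | None = None,
    error_rate: float = 0.0,
    seed: int | None = None,
) -> tuple:
    """Simulate merged amplicon reads for one individual and marker.

    Each read's haplotype of origin is drawn with probability proportional
    to copy number × amplification bias; substitution errors are applied
    independently per base.  Returns ``(reads, truth_counts)`` where
    ``truth_counts`` maps haplotype name to the number of reads drawn from
    it (before errors).
    """
    if n_reads < 1:
        raise ValueError("n_reads must be >= 1")
    rng = np.random.default_rng(seed)
    probs = haplotype_probs(genotype, bias)
    names = sorted(probs)
    counts = rng.multinomial(n_reads, [probs[h] for h in names])
    reads: list = []
    for name, c in zip(names, counts):
        base = refs[name]
        if error_rate <= 0:
            reads.extend([base] * c)
            continue
        arr = np.frombuffer(base.encode(), dtype=np.uint8)
        n_err = rng.binomial(len(base), error_rate, size=c)
        for k in n_err:
            if k == 0:
                reads.append(base)
            else:
                m = arr.copy()
                sites = rng.choice(len(base), size=k, replace=False)
                subs = BASES[(np.searchsorted(np.frombuffer(b"ACGT", dtype=np.uint8), m[sites]) + rng.integers(1, 4, size=k)) % 4]
                m[sites] = np.frombuffer("".join(subs).encode(), dtype=np.uint8)
                reads.append(m.tobytes().decode())
    order = rng.permutation(len(reads))
    reads = [reads[i] for i in order]
    return reads, dict(zip(names, (int(c) for c in counts)))


# ---------------------------------------------------------------------------
# writers
# ---------------------------------------------------------------------------


def write_reads_fasta(reads: Sequence[str], path: str, prefix: str = "read") -> None:
    with open(str(path), "w") as fh:
        for i, r in enumerate(reads):
            fh.write(f">{prefix}{i + 1}\n{r}\n")


def write_refs_fasta(refs: Mapping[str, str], path: str) -> None:
    with open(str(path), "w") as fh:
        for name, seq in refs.items():
            fh.write(f">{name}\n{seq}\n")


def write_truth_segments(profiles: Mapping[str, CopyNumberProfile], path: str) -> None:
    """Copy-number truth as BED-like TSV (0-based half-open, explicit)."""
    with open(str(path), "w") as fh:
        fh.write("#chrom\tstart0\tend0\tsample\tcopy_number\n")
        for name, prof in profiles.items():
            for chrom, start, end, cn in prof.segments:
                fh.write(f"{chrom}\t{start - 1}\t{end - 1}\t{name}\t{cn}\n")


def write_params_json(params: Mapping, path: str) -> None:
    with open(str(path), "w") as fh:
        json.dump(params, fh, indent=2, default=str)
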