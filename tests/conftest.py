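"""Shared fixtures and builders for the test suite."""

from __future__ import annotations

import numpy as np
import pytest

from peardup.variant_io import MISSING, VariantTable


def build_table(records, samples):
    """Construct a VariantTable from a list of per-site dicts.

    Each record: ``{"chrom", "pos", "ref", "alt": tuple, "gt": [(a,b)|None],
    "dp": [int|None], "ad": [tuple|None]}``.
    """
    n = len(records)
    s = len(samples)
    max_al = max((1 + len(r["alt"]) for r in records), default=1)
    gt = np.full((n, s, 2), MISSING, dtype=np.int8)
    dp = np.full((n, s), MISSING, dtype=np.int32)
    ad = np.full((n, s, max_al), MISSING, dtype=np.int32)
    for i, r in enumerate(records):
        for j in range(s):
            g = r["gt"][j]
            if g is not None:
                gt[i, j] = g
            d = r.get("dp", [None] * s)[j]
            if d is not None:
                dp[i, j] = d
            a = r.get("ad", [None] * s)[j]
            if a is not None:
                ad[i, j, : len(a)] = a
    return VariantTable(
        chrom=np.array([r["chrom"] for r in records], dtype=object),
        pos=np.array([r["pos"] for r in records], dtype=np.int64),
        ref=np.array([r.get("ref", "A") for r in records], dtype=object),
        alt=[tuple(r["alt"]) for r in records],
        samples=list(samples),
        gt=gt,
        dp=dp,
        ad=ad,
    )


def random_table(seed, n_sites=100, n_samples=4):
    """Randomized table exercising missing data, indels and multi-allelics."""
    rng = np.random.default_rng(seed)
    records = []
    pos = {"chrA": 0, "chrB": 0}
    for _ in range(n_sites):
        chrom = "chrA" if rng.random() < 0.6 else "chrB"
        pos[chrom] += int(rng.integers(1, 20_000))
        n_alt = int(rng.integers(1, 4))
        is_indel = rng.random() < 0.2
        ref = "A" if not is_indel else "AT"
        alts = tuple(("C", "G", "TTG")[k] if not (is_indel and k == 0) else "T" for k in range(n_alt))
        gts, dps, ads = [], [], []
        for _ in range(n_samples):
            if rng.random() < 0.15:
                gts.append(None)
            else:
                gts.append((int(rng.integers(0, n_alt + 1)), int(rng.integers(0, n_alt + 1))))
            dps.append(None if rng.random() < 0.1 else int(rng.integers(0, 120)))
            ads.append(None)
        records.append(
            {"chrom": chrom, "pos": pos[chrom], "ref": ref, "alt": alts, "gt": gts, "dp": dps, "ad": ads}
        )
    records.sort(key=lambda r: (r["chrom"], r["pos"]))
    return build_table(records, [f"s{i}" for i in range(n_samples)])


@pytest.fixture(scope="session")
def hap_refs():
    from peardup.synthetic import make_haplotype_refs

    return make_haplotype_refs(seed=0)


def calls_from_frequencies(freqs, total=10_000, individual="i", marker="SFBB18"):
    """A HaplotypeCountTable whose matched frequencies equal *freqs*."""
    from peardup.amplicon import HaplotypeCountTable, StackEntry

    entries = [
        StackEntry(sequence=f"SEQ_{name}", count=int(round(f * total)), haplotype=name, distance=0)
        for name, f in freqs.items()
    ]
    entries.sort(key=lambda e: (-e.count, e.sequence))
    return HaplotypeCountTable(individual=individual, marker=marker, entries=entries, total_reads=total)


def table1_calls():
    """Seedling calls reproducing the printed segregation-table cell counts.

    Cells (female allele, male gamete class) -> count: S1 row 60/3/2/0/7 and
    S3 row 47/4/1/1/15.
    """
    from peardup.amplicon import SGenotypeCall

    cells = {
        ("S1", ("S5",)): 60, ("S1", ("S5", "S5")): 3, ("S1", ("S4",)): 2,
        ("S1", ("S4", "S4")): 0, ("S1", ("S4", "S5")): 7,
        ("S3", ("S5",)): 47, ("S3", ("S5", "S5")): 4, ("S3", ("S4",)): 1,
        ("S3", ("S4", "S4")): 1, ("S3", ("S4", "S5")): 15,
    }
    calls = []
    k = 0
    for (fem, male), n in cells.items():
        alleles = sorted((fem,) + male)
        for _ in range(n):
            k += 1
            if len(alleles) == 2:
                h1, h2 = alleles
                call = SGenotypeCall(
                    individual=f"sdl{k}", marker="SFBB18", h1=h1, h2=h2, h3=None,
                    f1=0.45, f2=0.4, f3=0.0, call_class="diploid",
                    genotype_string="".join(alleles),
                )
            elif len(set(alleles)) == 2 and len(alleles) == 3:
                # one haplotype twice: duplicated_first with h1 = the doubled one
                doubled = [a for a in set(alleles) if alleles.count(a) == 2][0]
                single = [a for a in set(alleles) if alleles.count(a) == 1][0]
                call = SGenotypeCall(
                    individual=f"sdl{k}", marker="SFBB18", h1=doubled, h2=single, h3=None,
                    f1=0.6, f2=0.3, f3=0.0, call_class="duplicated_first",
                    genotype_string=f"{single}{doubled}d{doubled}",
                )
            else:
                h1, h2, h3 = alleles
                call = SGenotypeCall(
                    individual=f"sdl{k}", marker="SFBB18", h1=h1, h2=h2, h3=h3,
                    f1=0.35, f2=0.3, f3=0.25, call_class="three_haplotype",
                    genotype_string="".join(alleles),
                )
            calls.append(call)
    return calls
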