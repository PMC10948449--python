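"""Amplicon-based S-haplotype genotyping with duplication calling.

Merged amplicon reads for an S-locus marker (S-RNase or an SFBB pollen gene)
are stacked into identical-sequence groups, assigned to reference haplotypes
by edit distance, and the frequencies of the three most common haplotypes
determine the call:

* third haplotype frequency >= 0.2            -> three distinct S-haplotypes
* otherwise first/second frequency ratio > 1.5 -> the first haplotype is
  carried twice (duplicated), a partially triploid genotype
* otherwise                                   -> ordinary diploid

Frequencies are computed against *all* stacked reads — including unmatched
error stacks — so sequencing-error stacks deflate rather than inflate allele
frequencies (this is also why reported frequencies need not sum to 1).

Gamete bookkeeping subtracts the maternally inherited allele from each
seedling call and maps the remainder onto the paternal gamete classes
(e.g. S5, S5dS5, S4, S4dS4, S4dS5 for a S4dS5/S5 pollen parent), from which
the segregation table and chi-square tests are built.
"""

from __future__ import annotations

import dataclasses
from collections import Counter
from typing import Iterable, Mapping, Sequence

import edlib
import numpy as np
import pandas as pd
from scipy import stats


@dataclasses.dataclass
class StackEntry:
    sequence: str
    count: int
    haplotype: str | None  # matched reference haplotype name
    distance: int | None   # edit distance to the matched reference


@dataclasses.dataclass
class HaplotypeCountTable:
    """Ranked identical-read stacks for one individual and marker."""

    individual: str
    marker: str
    entries: list  # of StackEntry, by count desc then sequence
    total_reads: int

    def matched_counts(self) -> dict:
        """Summed read counts per matched reference haplotype."""
        agg: dict = {}
        for e in self.entries:
            if e.haplotype is not None:
                agg[e.haplotype] = agg.get(e.haplotype, 0) + e.count
        return agg


@dataclasses.dataclass
class SGenotypeCall:
    """Top-three haplotype frequencies and the categorical S-genotype call."""

    individual: str
    marker: str
    h1: str | None
    h2: str | None
    h3: str | None
    f1: float
    f2: float
    f3: float
    call_class: str  # diploid | duplicated_first | three_haplotype | uncallable
    genotype_string: str

    def allele_multiset(self) -> tuple:
        """Haplotype names with multiplicity implied by the call class."""
        if self.call_class == "diploid":
            return tuple(sorted((self.h1, self.h2)))
        if self.call_class == "duplicated_first":
            return tuple(sorted((self.h1, self.h1, self.h2)))
        if self.call_class == "three_haplotype":
            return tuple(sorted((self.h1, self.h2, self.h3)))
        return ()


def stack_reads(
    reads: Sequence[str],
    refs: Mapping[str, str],
    max_mismatch: int = 2,
    individual: str = "",
    marker: str = "",
) -> HaplotypeCountTable:
    """Collapse identical reads into counted stacks and assign haplotypes.

    Each stack is matched to the reference it equals exactly, else to the
    nearest reference within *max_mismatch* edit distance (ties broken by
    reference name order), else left unmatched.  Ranking is by count
    descending with lexicographic sequence order as the deterministic
    tie-break.
    """
    if len(reads) == 0:
        raise ValueError("empty read list")
    if len(set(refs.values())) != len(refs):
        raise ValueError("reference haplotype sequences must be pairwise distinct")
    by_seq = {seq: name for name, seq in refs.items()}
    counts = Counter(reads)
    entries = []
    for seq, n in sorted(counts.items(), key=lambda kv: (-kv[1], kv[0])):
        if seq in by_seq:
            entries.append(StackEntry(seq, n, by_seq[seq], 0))
            continue
        best_name, best_d = None, None
        for name in sorted(refs):
            res = edlib.align(seq, refs[name], mode="NW", task="distance", k=max_mismatch)
            d = res["editDistance"]
            if d != -1 and (best_d is None or d < best_d):
                best_name, best_d = name, d
        entries.append(StackEntry(seq, n, best_name, best_d))
    return HaplotypeCountTable(
        individual=individual, marker=marker, entries=entries, total_reads=len(reads)
    )


def call_s_genotype(
    hc: HaplotypeCountTable,
    third_allele_min: float = 0.2,
    dup_ratio_min: float = 1.5,
) -> SGenotypeCall:
    """Call the S-genotype from ranked haplotype frequencies.

    Rules (thresholds verbatim from the genotyping protocol): a third
    haplotype at frequency >= *third_allele_min* (inclusive) indicates three
    distinct S-haplotypes; otherwise a first/second frequency ratio strictly
    greater than *dup_ratio_min* indicates the first haplotype is duplicated;
    otherwise the individual is an ordinary diploid.  Frequencies use all
    stacked reads as the denominator.  Fewer than two matched haplotypes
    yields an ``uncallable`` result rather than an exception.
    """
    agg = hc.matched_counts()
    ranked = sorted(agg.items(), key=lambda kv: (-kv[1], kv[0]))
    base = dict(
        individual=hc.individual, marker=hc.marker, h1=None, h2=None, h3=None,
        f1=0.0, f2=0.0, f3=0.0,
    )
    if len(ranked) < 2:
        return SGenotypeCall(call_class="uncallable", genotype_string="", **base)
    total = hc.total_reads
    (h1, c1), (h2, c2) = ranked[0], ranked[1]
    f1, f2 = c1 / total, c2 / total
    h3, f3 = None, 0.0
    if len(ranked) >= 3:
        h3, f3 = ranked[2][0], ranked[2][1] / total
    base.update(h1=h1, h2=h2, h3=h3, f1=f1, f2=f2, f3=f3)
    if f3 >= third_allele_min:
        gs = "".join(sorted((h1, h2, h3)))
        return SGenotypeCall(call_class="three_haplotype", genotype_string=gs, **base)
    if f2 > 0 and f1 / f2 > dup_ratio_min:
        return SGenotypeCall(
            call_class="duplicated_first", genotype_string=f"{h2}{h1}d{h1}", **base
        )
    return SGenotypeCall(
        call_class="diploid", genotype_string="".join(sorted((h1, h2))), **base
    )


@dataclasses.dataclass
class GameteInference:
    female_gamete: str | None
    male_gamete: str | None  # class name such as "S4dS5"
    status: str  # ok | incompatible_with_cross | indeterminate


def male_gamete_classes(male_alleles: Sequence[str] = ("S4", "S5")) -> list:
    """Canonical paternal gamete classes for a duplication-carrying parent.

    For alleles (a, b) sorted by name the order mirrors the segregation
    table: [b, bdb, a, ada, adb].
    """
    a, b = sorted(male_alleles)
    return [b, f"{b}d{b}", a, f"{a}d{a}", f"{a}d{b}"]


def _gamete_class(alleles: Sequence[str]) -> str:
    alleles = sorted(alleles)
    if len(alleles) == 1:
        return alleles[0]
    a, b = alleles
    return f"{a}d{b}"


def infer_male_gamete(
    call: SGenotypeCall,
    female_genotype: Sequence[str] = ("S1", "S3"),
    male_alleles: Sequence[str] = ("S4", "S5"),
) -> GameteInference:
    """Subtract the maternal allele from a seedling call.

    The seedling must carry exactly one of the two maternal alleles; zero or
    both flags possible selfing/contamination (``incompatible_with_cross``).
    The remaining one- or two-allele multiset maps onto a paternal gamete
    class; alleles outside the paternal genotype are likewise incompatible.
    """
    if call.call_class == "uncallable":
        return GameteInference(None, None, "indeterminate")
    ms = list(call.allele_multiset())
    present = [a for a in female_genotype if a in ms]
    if len(present) != 1:
        return GameteInference(None, None, "incompatible_with_cross")
    female = present[0]
    ms.remove(female)
    if not ms or any(a not in male_alleles for a in ms):
        return GameteInference(female, None, "incompatible_with_cross")
    return GameteInference(female, _gamete_class(ms), "ok")


@dataclasses.dataclass
class SegregationTable:
    """Female-gamete × male-gamete-class seedling counts for one cross."""

    counts: pd.DataFrame  # index: female alleles; columns: male gamete classes
    chi2_female: float    # 1-df goodness of fit against 1:1; NaN if no data
    p_female: float
    n_incompatible: int = 0
    n_indeterminate: int = 0

    @property
    def female_totals(self) -> pd.Series:
        return self.counts.sum(axis=1)

    @property
    def male_totals(self) -> pd.Series:
        return self.counts.sum(axis=0)

    @property
    def total(self) -> int:
        return int(self.counts.to_numpy().sum())

    @property
    def duplicated_total(self) -> int:
        dup_cols = [c for c in self.counts.columns if "d" in c]
        return int(self.counts[dup_cols].to_numpy().sum())

    def to_tsv(self, path: str) -> None:
        self.counts.to_csv(str(path), sep="\t")


def tabulate_segregation(
    calls: Iterable[SGenotypeCall],
    female_genotype: Sequence[str] = ("S1", "S3"),
    male_alleles: Sequence[str] = ("S4", "S5"),
) -> SegregationTable:
    """Build the gamete-combination count table for one cross.

    The chi-square statistic tests the female gametes against the 1:1 ratio
    expected for monogenic inheritance; with no classifiable seedlings it is
    undefined (NaN).
    """
    classes = male_gamete_classes(male_alleles)
    females = list(female_genotype)
    counts = pd.DataFrame(0, index=females, columns=classes, dtype=int)
    n_inc = n_ind = 0
    for call in calls:
        inf = infer_male_gamete(call, female_genotype, male_alleles)
        if inf.status == "indeterminate":
            n_ind += 1
        elif inf.status != "ok" or inf.male_gamete not in classes:
            n_inc += 1
        else:
            counts.loc[inf.female_gamete, inf.male_gamete] += 1
    fem = counts.sum(axis=1).to_numpy()
    if fem.sum() > 0:
        chi2, p = stats.chisquare(fem)
        chi2, p = float(chi2), float(p)
    else:
        chi2, p = float("nan"), float("nan")
    return SegregationTable(
        counts=counts, chi2_female=chi2, p_female=p,
        n_incompatible=n_inc, n_indeterminate=n_ind,
    )


def detect_marker_recombinant(call_a: SGenotypeCall, call_b: SGenotypeCall) -> bool | None:
    """Flag discordant haplotype sets between two linked markers.

    Returns True if the inferred allele multisets differ (a putative
    recombinant between the markers), False if identical, and None
    (indeterminate) if either call is uncallable.
    """
    if call_a.call_class == "uncallable" or call_b.call_class == "uncallable":
        return None
    return call_a.allele_multiset() != call_b.allele_multiset()


def calls_to_frame(calls: Iterable[SGenotypeCall]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "individual": c.individual,
                "marker": c.marker,
                "h1": c.h1, "h2": c.h2, "h3": c.h3,
                "f1": c.f1, "f2": c.f2, "f3": c.f3,
                "call_class": c.call_class,
                "genotype": c.genotype_string,
            }
            for c in calls
        ]
    )
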