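"""Tests for amplicon stacking, S-genotype calling and gamete bookkeeping."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import calls_from_frequencies, table1_calls

from peardup import synthetic
from peardup.amplicon import (
    GameteInference,
    SGenotypeCall,
    call_s_genotype,
    detect_marker_recombinant,
    infer_male_gamete,
    male_gamete_classes,
    stack_reads,
    tabulate_segregation,
)


class TestStacking:
    def test_exact_stacks_ranked_by_count(self, hap_refs):
        reads = [hap_refs["S1"]] * 10 + [hap_refs["S3"]] * 5
        hc = stack_reads(reads, hap_refs)
        assert [(e.count, e.haplotype) for e in hc.entries] == [(10, "S1"), (5, "S3")]
        assert hc.total_reads == 15

    def test_near_match_within_tolerance(self, hap_refs):
        mutant = "T" + hap_refs["S1"][1:] if hap_refs["S1"][0] != "T" else "A" + hap_refs["S1"][1:]
        reads = [hap_refs["S1"]] * 10 + [mutant]
        hc = stack_reads(reads, hap_refs)
        assert [(e.count, e.haplotype, e.distance) for e in hc.entries] == [
            (10, "S1", 0), (1, "S1", 1)
        ]

    def test_distant_stack_unmatched_but_in_denominator(self, hap_refs):
        junk = "A" * len(hap_refs["S1"])
        reads = [hap_refs["S1"]] * 6 + [hap_refs["S3"]] * 3 + [junk] * 3
        hc = stack_reads(reads, hap_refs)
        assert hc.entries[-1].haplotype is None or any(e.haplotype is None for e in hc.entries)
        assert hc.total_reads == 12
        call = call_s_genotype(hc)
        assert call.f1 == pytest.approx(6 / 12) and call.f2 == pytest.approx(3 / 12)

    def test_empty_reads_error(self, hap_refs):
        with pytest.raises(ValueError):
            stack_reads([], hap_refs)

    def test_binomial_recovery_with_errors(self, hap_refs):
        """2,000 reads at true 2:1 with 1% per-base error recover the ratio."""
        reads, truth = synthetic.simulate_amplicon_reads(
            {"S3": 2, "S1": 1}, hap_refs, 2_000, error_rate=0.01, seed=21
        )
        hc = stack_reads(reads, hap_refs)
        agg = hc.matched_counts()
        p = 2 / 3
        sd = np.sqrt(2_000 * p * (1 - p))
        assert abs(truth["S3"] - 2_000 * p) < 3 * sd
        # only reads with <=2 substitutions match a reference; the loss is
        # unbiased so the matched count ratio still recovers the 2:1 dosage
        from scipy import stats

        p_match = stats.binom.cdf(2, len(hap_refs["S1"]), 0.01)
        n_matched = agg["S3"] + agg["S1"]
        assert abs(n_matched - 2_000 * p_match) < 4 * np.sqrt(2_000 * p_match * (1 - p_match))
        assert agg["S3"] / agg["S1"] == pytest.approx(truth["S3"] / truth["S1"], rel=0.15)


class TestGenotypeCalling:
    @pytest.mark.parametrize(
        "freqs, expected_class, expected_string",
        [
            # the duplication carrier: 0.61/0.26 = 2.35 > 1.5
            ({"S4": 0.26, "S5": 0.61}, "duplicated_first", "S4S5dS5"),
            # the diploid parent: 0.49/0.42 = 1.17 <= 1.5
            ({"S1": 0.42, "S3": 0.49}, "diploid", "S1S3"),
            # symmetric tie: ratio exactly 1.0
            ({"S1": 0.5, "S5": 0.5}, "diploid", "S1S5"),
            # third allele exactly at the inclusive 0.2 bound
            ({"S1": 0.40, "S4": 0.30, "S5": 0.20}, "three_haplotype", "S1S4S5"),
            # third allele just under the bound, ratio under 1.5
            ({"S1": 0.40, "S4": 0.35, "S5": 0.19}, "diploid", "S1S4"),
        ],
    )
    def test_calling_rules(self, freqs, expected_class, expected_string):
        call = call_s_genotype(calls_from_frequencies(freqs))
        assert call.call_class == expected_class
        assert call.genotype_string == expected_string

    def test_ratio_rule_is_strict(self):
        call = call_s_genotype(calls_from_frequencies({"S4": 0.30, "S5": 0.45}))
        assert call.f1 / call.f2 == pytest.approx(1.5)
        assert call.call_class == "diploid"

    def test_uncallable_with_single_matched_haplotype(self, hap_refs):
        hc = stack_reads([hap_refs["S1"]] * 5, hap_refs)
        assert call_s_genotype(hc).call_class == "uncallable"

    @settings(derandomize=True, max_examples=30, deadline=None)
    @given(scale=st.integers(min_value=1, max_value=1000))
    def test_scale_invariance(self, scale):
        """Multiplying all stack counts by a constant leaves the call unchanged."""
        base = calls_from_frequencies({"S4": 0.26, "S5": 0.61}, total=100)
        scaled = calls_from_frequencies({"S4": 0.26, "S5": 0.61}, total=100 * scale)
        for e in scaled.entries:
            e.count *= 1  # counts already scaled through total
        a, b = call_s_genotype(base), call_s_genotype(scaled)
        assert (a.call_class, a.genotype_string) == (b.call_class, b.genotype_string)
        assert a.f1 == pytest.approx(b.f1) and a.f2 == pytest.approx(b.f2)

    def test_caller_confusion_under_amplification_bias(self, hap_refs):
        """Bias within [0.8, 1.25] at deep coverage keeps the miscall rate < 1%."""
        n_miscall = n_total = 0
        for bias in (0.8, 1.0, 1.25):
            for seed in range(60):
                reads, _ = synthetic.simulate_amplicon_reads(
                    {"S4": 1, "S5": 2}, hap_refs, 10_000,
                    bias={"S5": bias}, seed=seed,
                )
                dup_call = call_s_genotype(stack_reads(reads, hap_refs))
                n_miscall += dup_call.call_class != "duplicated_first"
                reads, _ = synthetic.simulate_amplicon_reads(
                    {"S1": 1, "S5": 1}, hap_refs, 10_000,
                    bias={"S5": bias}, seed=seed,
                )
                dip_call = call_s_genotype(stack_reads(reads, hap_refs))
                n_miscall += dip_call.call_class != "diploid"
                n_total += 2
        assert n_miscall / n_total < 0.01


class TestGameteInference:
    def test_duplicated_seedling_subtraction(self):
        call = SGenotypeCall("s", "m", "S4", "S3", None, 0.6, 0.3, 0.0, "duplicated_first", "S3S4dS4")
        inf = infer_male_gamete(call)
        assert (inf.female_gamete, inf.male_gamete, inf.status) == ("S3", "S4dS4", "ok")

    def test_diploid_subtraction(self):
        call = SGenotypeCall("s", "m", "S5", "S1", None, 0.5, 0.45, 0.0, "diploid", "S1S5")
        inf = infer_male_gamete(call)
        assert (inf.female_gamete, inf.male_gamete) == ("S1", "S5")

    def test_heteroallelic_gamete(self):
        call = SGenotypeCall("s", "m", "S1", "S4", "S5", 0.35, 0.3, 0.25, "three_haplotype", "S1S4S5")
        assert infer_male_gamete(call).male_gamete == "S4dS5"

    @pytest.mark.parametrize(
        "alleles, call_class",
        [(("S1", "S3"), "diploid"), (("S4", "S5"), "diploid")],
    )
    def test_incompatible_with_cross(self, alleles, call_class):
        call = SGenotypeCall("s", "m", alleles[0], alleles[1], None, 0.5, 0.4, 0.0, call_class, "")
        assert infer_male_gamete(call).status == "incompatible_with_cross"

    def test_truth_recovery_over_simulated_population(self, hap_refs):
        """Inferred gamete classes equal the generator's truth labels."""
        truth = synthetic.simulate_cross(synthetic.CrossModel(n_seedlings=80), seed=5)
        for _, row in truth.iterrows():
            geno = synthetic.seedling_amplicon_genotype(row["alleles"])
            reads, _ = synthetic.simulate_amplicon_reads(geno, hap_refs, 1_500, seed=int(row.name))
            call = call_s_genotype(stack_reads(reads, hap_refs))
            inf = infer_male_gamete(call)
            assert inf.status == "ok"
            assert inf.male_gamete == row["male_gamete"]
            assert inf.female_gamete == row["female_gamete"]


class TestSegregation:
    def test_printed_table_bookkeeping(self):
        seg = tabulate_segregation(table1_calls())
        assert seg.female_totals.to_dict() == {"S1": 72, "S3": 68}
        assert seg.male_totals.tolist() == [107, 7, 3, 1, 22]
        assert seg.duplicated_total == 30
        assert seg.total == 140
        # 72:68 is not significantly different from 1:1
        assert seg.chi2_female == pytest.approx((72 - 68) ** 2 / 140, rel=1e-9)
        assert seg.p_female > 0.05

    def test_empty_input(self):
        seg = tabulate_segregation([])
        assert seg.total == 0 and np.isnan(seg.chi2_female)
        assert seg.counts.to_numpy().sum() == 0

    def test_row_column_sums_conserve_callable_seedlings(self):
        calls = table1_calls()
        seg = tabulate_segregation(calls)
        assert seg.female_totals.sum() == seg.male_totals.sum() == len(calls)

    def test_male_gamete_class_order(self):
        assert male_gamete_classes(("S4", "S5")) == ["S5", "S5dS5", "S4", "S4dS4", "S4dS5"]


class TestRecombinants:
    def test_discordant_marker_calls_flag_recombinant(self):
        a = SGenotypeCall("s", "SFBB18", "S5", "S1", None, 0.5, 0.4, 0.0, "diploid", "S1S5")
        b = SGenotypeCall("s", "S-RNase", "S5", "S3", None, 0.5, 0.4, 0.0, "diploid", "S3S5")
        assert detect_marker_recombinant(a, b) is True
        assert detect_marker_recombinant(a, a) is False
        u = SGenotypeCall("s", "S-RNase", None, None, None, 0, 0, 0, "uncallable", "")
        assert detect_marker_recombinant(a, u) is None

    def test_recombinant_count_within_binomial_interval(self, hap_refs):
        """With r=0.02 between markers, recombinants over 140 seedlings stay
        inside the 95% binomial envelope of 140·r."""
        from scipy import stats

        model = synthetic.CrossModel(recombination_fraction=0.02, n_seedlings=140)
        truth = synthetic.simulate_cross(model, seed=17)
        n_rec = 0
        for _, row in truth.iterrows():
            g1 = synthetic.seedling_amplicon_genotype(row["alleles"])
            alleles2 = tuple(sorted(
                (row["female_gamete_marker2"],) + synthetic.gamete_alleles(row["male_gamete"])
            ))
            g2 = synthetic.seedling_amplicon_genotype(alleles2)
            reads1, _ = synthetic.simulate_amplicon_reads(g1, hap_refs, 1_000, seed=int(row.name))
            reads2, _ = synthetic.simulate_amplicon_reads(g2, hap_refs, 1_000, seed=10_000 + int(row.name))
            c1 = call_s_genotype(stack_reads(reads1, hap_refs, marker="SFBB18"))
            c2 = call_s_genotype(stack_reads(reads2, hap_refs, marker="S-RNase"))
            if detect_marker_recombinant(c1, c2):
                n_rec += 1
        lo, hi = stats.binom.interval(0.95, 140, 0.02)
        assert lo <= n_rec <= hi
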