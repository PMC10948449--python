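# Methods

This note documents the statistical models behind `peardup`, the choices
made where the procedures admit more than one reading, the assumptions of
the synthetic-data generators, and the limits of what passing tests
demonstrate about real data.

## Variant filtering

`filter_variants` reimplements the VCFtools filter semantics with a fixed
order of application, because flag lists alone do not define one:

1. per-genotype depth bounds (`min_dp`/`max_dp`) mask the genotype *and its
   depth and allelic depths* (the genotype's data is treated as absent
   thereafter);
2. indel removal (any ref/alt allele not a single base);
3. allele-count cap;
4. site mean depth over genotypes retaining depth data (sites with no depth
   data are dropped when a mean-depth bound is set);
5. call rate against `max_missing` (VCFtools convention: 1 = no missing
   genotypes allowed, 0 = anything goes);
6. minor/major allele frequency computed from called genotypes *after* DP
   masking — VCFtools `--maf` counts genotypes, not allelic depths. Sites
   with zero called genotypes are not evaluated by this rule (they are
   normally removed by rule 5);
7. greedy thinning in ascending coordinate order per chromosome: a site is
   kept iff it lies ≥ `thin_bp` beyond the last *kept* site.

Genotype-level filters precede site-level ones, as in VCFtools. Filtering is
idempotent and is verified against an independently written per-site oracle
on randomized tables. Multi-allelic sites are retained unsplit; minor/major
frequency is the min/max over all listed alleles. The published parameter
sets are frozen in `peardup.presets` and asserted literally by tests.

## The ΔDP duplication scan

**Statistic.** ΔDP(ℓ) = DP_target(ℓ) − DP_reference(ℓ) over the locus set
with depth in both samples. A three-copy segment multiplies expected depth
by 1.5, so at 50× the in-segment ΔDP mean is ≈ +25 reads. Raw depths are
subtracted by default (median-ratio normalisation is available but off, and
region calls are invariant under a constant depth offset applied to both
samples).

**Windows.** `snp_count` windows (ddRAD design: 20 loci advancing by 10)
span their first to last locus; a trailing partial window is emitted with
its actual locus count and flagged. `physical` windows (WGS design: 1 Mb
advancing by 0.5 Mb) tile `[k·step, k·step+size)`; empty windows are
omitted. Internally all intervals are 1-based half-open; BED output is
0-based half-open by explicit conversion.

**Resampling threshold.** Window-mean DP values of target and reference are
drawn independently, uniformly with replacement, `n_iter` times (10,000
ddRAD / 5,000 WGS); the 95th/99th percentiles of the differences (linear
interpolation between order statistics) form the thresholds. Windows above
the 99% threshold are merged into regions when consecutive windows touch or
overlap; merged runs shorter than `min_run = 3` windows are reported but
flagged `short_run` rather than suppressed — isolated exceedances are
suspect (ddRAD data produced exactly one such single-window artifact on
another chromosome) but should stay visible.

**Why unpaired resampling works — and what it assumes.** Real per-locus
coverage is biased by GC content, mappability and (for ddRAD)
restriction-fragment amplification, and these biases are largely *shared*
between libraries of the same genome. In the observed track the windows are
paired, so shared bias cancels and ΔDP window means are tight around 0.
The resampling null destroys the pairing: its spread includes the full
between-window variance of each sample, so the 99% threshold sits well
above the observed diploid noise floor yet — provided the duplication
signal (+mean/2) exceeds it — below the signal. The scan therefore
*requires* window-to-window depth heterogeneity to be meaningfully
conservative; on idealised homogeneous coverage the threshold collapses to
sampling noise and every window grazing the segment is called.

**Leave-one-chromosome-out thresholds.** The windows of a large duplication
contribute to their own null: whenever they exceed ~1% of all windows, the
99th percentile of the null climbs into the duplicated-window cloud and the
threshold approaches the signal itself, destroying detection (on a
three-chromosome toy genome an 11-Mb segment is ~12% of windows; even at
whole-genome scale it is ~2%). `scan_duplications` therefore thresholds
each chromosome against a null resampled from the *other* chromosomes only.
`resample_ci` itself keeps the include-everything behaviour (and an
`exclude_chroms` argument) so both procedures are available; the
orchestrated scan and all benchmarks use the leave-one-out form.

**Boundary resolution.** A called region extends from the first to the last
window whose mean exceeds the threshold, so boundary error is bounded by
one window step in the direction of each boundary plus the overlap needed
to clear the threshold; with 1-Mb/0.5-Mb windows and a threshold near a
third of the signal this lands within ±0.5 Mb of the truth. No breakpoint
refinement below window resolution is attempted.

## Amplicon S-genotyping

Reads are stacked exactly (identical sequences collapsed, ranked by count
with lexicographic tie-break) and each stack is assigned to the reference
haplotype it matches exactly, else the nearest by edit distance within 2
mismatches, else left unmatched. Frequencies aggregate matched stacks per
haplotype and divide by **all** stacked reads, so error stacks deflate
rather than inflate frequencies — which is also why reported frequency
pairs need not sum to 1. The calling rules are applied verbatim: third
haplotype ≥ 0.2 (inclusive) → three haplotypes; else first/second ratio
strictly > 1.5 → duplicated first haplotype; else diploid (a tie f1 = f2
is diploid). Calls with fewer than two matched haplotypes are `uncallable`,
never an exception.

A `duplicated_first` call fixes the allele multiset {h1, h1, h2} but not
which chromosome carries the extra copy; the genotype string is written
h2 + h1 + "d" + h1 (e.g. S3S5dS5), matching the seedling-level notation.
Which *gamete* carried the duplication (e.g. S4dS5 vs S5dS5) is resolved by
`infer_male_gamete` from the cross structure: the single maternally
inherited allele is subtracted and the remaining one- or two-allele multiset
maps onto the paternal gamete classes. Seedlings carrying zero or two
maternal alleles are flagged incompatible (possible selfing or
contamination) and excluded from the segregation table, whose female
marginal is tested against 1:1 by a 1-df chi-square.

Calling accuracy depends on read depth and amplification bias jointly: the
expected observed ratio for a duplicated genotype is 2b, so bias b = 0.8
places the expectation at 1.6, only 0.1 above the 1.5 cutoff. At 10,000
reads per marker the miscall rate across b ∈ [0.8, 1.25] is below 1%
(verified by simulation); at 1,000 reads the b = 0.8 case alone would
misclassify ~17% of duplication carriers, so deep amplicon coverage is a
real requirement of the rule set, not a convenience.

## Allele balance and zygosity

The SNP index is AD_ref / ΣAD per locus (loci with zero total allelic depth
dropped). Ploidy classification of a candidate region uses only loci in the
heterozygous spectrum (index in (0.1, 0.9), exclusive): the mean distance
to the diploid expectation {0.5} is compared with the mean distance to the
nearer of the triploid expectations {1/3, 2/3}; the smaller wins, and fewer
than 20 usable loci yields `no_data`. The distance rule is a deterministic
formalisation of "the index clusters near 0.33/0.67 rather than 0.5"; at
depth ≥ 40 and ≥ 20 loci the two hypotheses are separated by many standard
errors, giving a false-triploid rate well under 2% on diploid data.

ΔSNP index series are windowed like ΔDP. Two individuals sharing a
genotype at depth n have E|p̂₁ − p̂₂| = √(2/π)·√(2pq/n) ≈ 0.08 at 50× —
the "same genotype" noise floor; the ~0.1 reading heuristic is exposed as a
parameter, not asserted.

Zygosity windows (200 kb): a parent is heterozygous in a window iff ≥ 1
called heterozygous genotype, homozygous iff ≥ 1 locus and none
heterozygous, `no_data` otherwise. Joint fractions are computed over
windows classified in both parents by default; windows without data can be
included in the denominator via an option, since either convention is
defensible for genome-fraction summaries.

## Synthetic data

The generators are pure functions of (parameters, seed) and always emit
truth tables; recovery tests compare against truth, never against
re-derived quantities.

* **Genome**: toy default of three 30-Mb chromosomes for unit tests; a
  17 × 30 Mb pear-like genome (~510 Mb, the scale of the real assembly) for
  duplication-recovery benchmarks. The benchmark target carries copy
  number 3 over 15.3–26.3 Mb of the last chromosome; copy 2 elsewhere.
* **Markers**: WGS mode ~1 locus/kb (exponential spacings); ddRAD mode
  places ~5 clusters/Mb of ~4 loci within 400 bp, emulating
  restriction-site stacks with uneven physical span.
* **Depth**: NegBin(mean·copy/2·bias, k) with mean 50 (the study's 40–50×
  range) and dispersion k = 20 (CV ≈ 25% at 50×, moderate overdispersion
  representative of depth-filtered data). The bias term is the product of a
  *shared* regional lognormal factor (CV 0.10, piecewise constant over
  0.5-Mb blocks), a shared per-locus amplification factor in ddRAD mode
  (CV 0.15) and a small sample-specific regional factor (CV 0.015). Shared
  bias is what gives the resampling null its realistic width (see above);
  the defaults were set so that the published filter sets leave the
  duplication signal clearly separated from the null, the regime the
  original ddRAD and WGS scans evidently operated in. Zero-depth genotypes
  are missing.
* **Allelic depths**: binomial at the copy fraction of reference alleles —
  1/2 for diploid heterozygotes; 1/3 or 2/3 (drawn uniformly) at copy
  three. No sequencing error is added to AD.
* **Cross**: maternal allele Bernoulli(0.5); paternal gamete class drawn
  from configurable probabilities defaulting to the observed
  107:7:3:1:22 segregation; an optional recombination fraction (default
  0.02) decouples the maternal allele between two linked markers.
* **Amplicon reads**: haplotype of origin ∝ copies × bias; per-base
  substitution errors (default 0.5%) applied independently. Reference
  haplotypes are synthetic sequences at pairwise edit distance 16,
  far beyond the 2-mismatch matching tolerance.

**What the generators do not model** — and hence what passing tests do not
establish about real data: alignment and variant-calling artifacts
(mapping bias toward the reference allele, paralog collapse), linkage
between loci within a sample (genotypes are drawn independently per locus),
indel-rich amplicons, chimeric/PCR-duplicate amplicon reads, and depth
heterogeneity with heavier-than-lognormal tails. Boundary precision beyond
one window step and deletions (lower-tail thresholds) are out of scope.

## Benchmark problem sizes

The duplication-recovery benchmark runs the full pipeline (generation →
depth filter → windowing → 5,000-iteration thresholds → segmentation) on
~510,000 simulated loci × 2 samples in a few seconds; the test suite
repeats it across 50 seeds. The triploid allele-balance benchmark uses
~4,000 copy-3 loci at 60× (≥ 1,000 with one reference copy). The amplicon
dosage benchmark simulates 10,000 reads. These sizes keep every statistic's
Monte-Carlo error an order of magnitude below the tested tolerances.

## Numerical conventions

Quantiles use linear interpolation between order statistics. Ranking
tie-breaks are lexicographic (stack sequences, haplotype names) so all
outputs are deterministic. Missing integer data uses a single sentinel
(−1); genotype, depth and allelic-depth missingness are masked jointly by
the depth filter. Seeds are threaded explicitly through every stochastic
stage; per-chromosome resampling seeds are spawned from the top-level seed
via the generator stream, so a report's seed reproduces the run bit for
bit.
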