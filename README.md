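# peardup

Detecting a segmental S-haplotype duplication — a partial triploidy — and its
inheritance in pear (*Pyrus*) from three kinds of sequencing data.

## The problem

Gametophytic self-incompatibility in pear is controlled by the S-locus, where
the pistil gene *S-RNase* and the linked pollen *SFBB* F-box genes determine
pollen rejection. A breeding line carrying a duplicated S-haplotype (genotype
S4dS5S5: the S4 chromosome carries an attached duplicate of the S5 segment)
produces heteroallelic S4dS5 pollen that escapes rejection and confers
self-compatibility. Characterising such a line requires answering three
questions, each with its own data type:

1. **Which seedlings inherited the duplication?** Deep amplicon sequencing of
   an S-locus marker gives per-haplotype read frequencies. With copies
   `c_h` and amplification bias `b_h`, the expected frequency of haplotype
   *h* is `c_h·b_h / Σ c·b`, so an unbiased duplicated genotype (copies 2:1)
   shows a first/second frequency ratio of 2.00. The calling rules: a third
   haplotype at frequency ≥ 0.2 → three S-haplotypes; otherwise a
   first/second ratio > 1.5 → the first haplotype is duplicated; otherwise
   diploid.
2. **Where is the duplication and how long is it?** For a test individual
   *t* and a diploid reference *r*, the per-locus depth difference
   ΔDP = DP_t − DP_r averages ≈ mean/2 inside a three-copy segment and ≈ 0
   elsewhere. Sliding-window means of ΔDP (20-SNP/10-SNP windows for
   ddRAD-seq; 1-Mb/0.5-Mb for whole-genome sequencing) are compared against
   resampling thresholds: window-mean depths of the two individuals are
   drawn independently 10,000 (ddRAD) or 5,000 (WGS) times and the 95th/99th
   percentiles of the differences form the confidence bounds.
3. **Is the extra copy really there (allele balance)?** The SNP index —
   reference-allele depth over total depth — sits near 0.5 at diploid
   heterozygous loci but near 1/3 or 2/3 inside a three-copy region
   (one or two of three copies carry the reference allele). The ΔSNP index
   (|index difference| between individuals at shared loci) is near its
   binomial noise floor (~0.1 at 50×) where two individuals share a
   genotype, which delineates shared haplotype segments. 200-kb windows with
   no heterozygous genotype classify parental homozygous regions.

The package implements all of this — VCF filtering with VCFtools semantics,
amplicon stacking/calling, the ΔDP scan with region segmentation, allele
balance and zygosity classification, gamete-segregation bookkeeping — plus
synthetic-data generators that emulate each sequencing design with truth
tables, so every analysis is testable end to end.

## Worked example

```python
from peardup import synthetic, variant_io, depth_scan, presets

# a 17 x 30 Mb pear-like genome: diploid '515-20' vs '415-1' carrying a
# copy-3 segment at 15.3-26.3 Mb of chr17, ~50x with shared coverage biases
vt, truth = synthetic.duplication_benchmark(seed=1, mode="wgs")

filtered = variant_io.filter_variants(vt, presets.FILTER_PRESETS["wgs_ddp"])
scan = depth_scan.scan_duplications(
    filtered, "415-1", "515-20", presets.WINDOW_PRESETS["wgs"],
    n_iter=5000, seed=1,
)
for r in scan["regions"]:
    print(r.chrom, r.start, r.end, r.length / 1e6, r.region_class, r.flags)
print(round(scan["thresholds"]["chr17"].ci99, 2))
```

prints

```
chr17 15000001 26500001 11.5 duplicated ()
8.42
```

— a single unflagged duplicated region whose extent (15.0–26.5 Mb, 11.5 Mb)
brackets the true 15.3–26.3 Mb segment to within one 0.5-Mb window step, and
the chr17 99% threshold (≈ 8 reads) sitting well above the diploid noise
floor yet far below the ≈ +25-read signal of the three-copy segment.

The same scan is available from the shell:

```bash
peardup synth --preset paper-wgs --seed 1 --out data/
peardup dup-scan --vcf data/synthetic.vcf --target target --reference reference \
    --mode wgs --seed 1 --out scan_out/
```

Amplicon genotyping of an F1 population, with segregation bookkeeping
(female gametes tested against 1:1; paternal gamete classes S5, S5dS5, S4,
S4dS4, S4dS5 counted, duplication carriers summed):

```bash
peardup synth --preset cross140 --seed 7 --out cross/
peardup ampli-call --reads-dir cross/reads --refs cross/refs.fasta \
    --female S1,S3 --male S4,S5 --out calls/
```

## Layout

| module                  | contents |
| ----------------------- | -------- |
| `peardup.variant_io`    | `VariantTable`, VCF read/write, VCFtools-style `filter_variants` |
| `peardup.amplicon`      | read stacking, S-genotype calling, gamete inference, segregation tables, recombinant detection |
| `peardup.depth_scan`    | ΔDP series, sliding windows (SNP-count and physical), resampling thresholds, region segmentation |
| `peardup.allele_balance`| SNP index, ΔSNP index, 200-kb zygosity windows, diploid/triploid region classification |
| `peardup.synthetic`     | cross, variant-table and amplicon generators with truth tables |
| `peardup.presets`       | the frozen filter/window/iteration parameter sets |
| `peardup.pipeline` / `peardup.cli` | orchestration, reports, `peardup` console script |

Coordinates are 1-based inclusive internally (half-open `[start, end)` for
windows and regions); BED outputs are 0-based half-open with explicit
conversion. See `docs/methods.md` for the statistical model, the generator's
assumptions and known limitations.
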