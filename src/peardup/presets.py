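"""Frozen parameter sets for the study's analysis configurations.

Each filter preset mirrors one VCFtools invocation used in the original
workflows; the window presets mirror the ddRAD (20-SNP/10-SNP) and WGS
(1-Mb/0.5-Mb) sliding-window designs, plus the fine 20-kb/10-kb track used
for visual boundary reading.
"""

from __future__ import annotations

from .depth_scan import WindowSpec
from .variant_io import FilterParams

FILTER_PRESETS: dict = {
    # ddRAD ΔDP scan: --minDP 20 --maxDP 100 --min-meanDP 30 --max-meanDP 80
    "ddrad_ddp": FilterParams(min_dp=20, max_dp=100, min_mean_dp=30, max_mean_dp=80),
    # WGS ΔDP scan: --minDP 20 --maxDP 80 --min-meanDP 30 --max-meanDP 70 --max-missing 1
    "wgs_ddp": FilterParams(
        min_dp=20, max_dp=80, min_mean_dp=30, max_mean_dp=70, max_missing=1.0
    ),
    # SNP index: + --maf 0.05 --max-maf 0.95 --remove-indels --thin 10000
    "snp_index": FilterParams(
        min_dp=20, max_dp=80, min_mean_dp=30, max_mean_dp=70, max_missing=1.0,
        maf=0.05, max_maf=0.95, remove_indels=True, thin_bp=10_000,
    ),
    # ΔSNP index: + --remove-indels --maf 0.2 --max-maf 0.8
    "delta_snp_index": FilterParams(
        min_dp=20, max_dp=80, min_mean_dp=30, max_mean_dp=70, max_missing=1.0,
        maf=0.2, max_maf=0.8, remove_indels=True,
    ),
    # genetic map input: --minDP 15 --max-alleles 2 --max-missing 0.9 --maf 0.05 --max-maf 0.95
    "genetic_map": FilterParams(
        min_dp=15, max_alleles=2, max_missing=0.9, maf=0.05, max_maf=0.95
    ),
}

WINDOW_PRESETS: dict = {
    "ddrad": WindowSpec(mode="snp_count", size=20, step=10),
    "wgs": WindowSpec(mode="physical", size=1_000_000, step=500_000),
    "wgs_fine": WindowSpec(mode="physical", size=20_000, step=10_000),
}

#: resampling iterations per design
CI_ITERATIONS = {"ddrad": 10_000, "wgs": 5_000}

ZYGOSITY_WINDOW_BP = 200_000
THIRD_ALLELE_MIN = 0.2
DUP_RATIO_MIN = 1.5
MIN_RUN_WINDOWS = 3
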