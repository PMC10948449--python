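"""End-to-end orchestration of the scan, balance and genotyping workflows.

Each ``run_*`` function is a library-level pipeline stage returning a
machine-readable report dict; :func:`run_pipeline` dispatches on the config's
``mode``.  Every report embeds the fully resolved configuration and seed, so
a report suffices to reproduce the run.  Results go to files; logging goes to
stderr — stdout stays clean.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import sys
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__, allele_balance, amplicon, depth_scan, presets, synthetic, variant_io

logger = logging.getLogger("peardup")


@dataclasses.dataclass
class RunConfig:
    """Resolved configuration for one pipeline run."""

    mode: str                       # wgs_scan | ddrad_scan | balance | zygosity | amplicon
    vcf: str | None = None
    target: str | None = None
    reference: str | None = None
    parents: tuple | None = None
    pair: tuple | None = None
    filter_preset: str | None = None
    window_preset: str | None = None
    n_iter: int | None = None
    min_run: int = presets.MIN_RUN_WINDOWS
    third_allele_min: float = presets.THIRD_ALLELE_MIN
    dup_ratio_min: float = presets.DUP_RATIO_MIN
    reads_dir: str | None = None
    refs_fasta: str | None = None
    female: tuple = ("S1", "S3")
    male_alleles: tuple = ("S4", "S5")
    seed: int | None = None
    out_dir: str = "peardup_out"

    def resolved(self) -> dict:
        d = dataclasses.asdict(self)
        d["version"] = __version__
        return d


def _require_samples(vt: variant_io.VariantTable, names) -> None:
    missing = [n for n in names if n and n not in vt.samples]
    if missing:
        raise ValueError(f"sample role(s) not present in VCF: {', '.join(missing)}")


def _region_records(regions) -> list:
    return [
        {
            "chrom": r.chrom, "start": r.start, "end": r.end, "length": r.length,
            "class": r.region_class, "mean_stat": r.mean_stat,
            "n_windows": r.n_windows, "flags": list(r.flags), "evidence": r.evidence,
        }
        for r in regions
    ]


def run_depth_scan(vt: variant_io.VariantTable, config: RunConfig, design: str) -> dict:
    """Shared ΔDP scan driver for the ddRAD and WGS designs."""
    _require_samples(vt, [config.target, config.reference])
    fp = presets.FILTER_PRESETS[config.filter_preset or f"{design}_ddp"]
    spec = presets.WINDOW_PRESETS[config.window_preset or design]
    n_iter = config.n_iter or presets.CI_ITERATIONS[design]
    filtered = variant_io.filter_variants(vt, fp)
    logger.info("filtered %d -> %d loci", vt.n_loci, filtered.n_loci)
    scan = depth_scan.scan_duplications(
        filtered, config.target, config.reference, spec,
        n_iter=n_iter, seed=config.seed, min_run=config.min_run,
    )
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    scan["delta_track"].to_tsv(out / "delta_dp_windows.tsv")
    depth_scan.regions_to_bed(scan["regions"], out / "duplicated_regions.bed")
    thresholds = {
        c: {"ci95": t.ci95, "ci99": t.ci99, "n_iter": t.n_iter, "seed": t.seed}
        for c, t in scan["thresholds"].items()
    }
    with open(out / "ci_thresholds.json", "w") as fh:
        json.dump(thresholds, fh, indent=2)
    return {
        "mode": f"{design}_scan",
        "config": config.resolved(),
        "n_loci_input": vt.n_loci,
        "n_loci_filtered": filtered.n_loci,
        "thresholds": thresholds,
        "regions": _region_records(scan["regions"]),
    }


def run_balance(vt: variant_io.VariantTable, config: RunConfig) -> dict:
    """SNP-index / ΔSNP-index analysis for a pair of individuals."""
    a, b = config.pair
    _require_samples(vt, [a, b])
    filtered = variant_io.filter_variants(
        vt, presets.FILTER_PRESETS[config.filter_preset or "delta_snp_index"]
    )
    spec = presets.WINDOW_PRESETS[config.window_preset or "wgs"]
    idx_a = allele_balance.snp_index(filtered, a)
    idx_b = allele_balance.snp_index(filtered, b)
    track = allele_balance.delta_snp_index(idx_a, idx_b, spec)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    idx_a.to_csv(out / f"snp_index_{a}.tsv", sep="\t", index=False)
    idx_b.to_csv(out / f"snp_index_{b}.tsv", sep="\t", index=False)
    track.to_tsv(out / "delta_snp_index_windows.tsv")
    return {
        "mode": "balance",
        "config": config.resolved(),
        "n_loci_filtered": filtered.n_loci,
        "n_shared_loci": int(len(idx_a.merge(idx_b, on=["chrom", "pos"]))),
        "n_windows": len(track),
        "mean_delta_snp_index": float(track.values().mean()) if len(track) else None,
    }


def run_zygosity(vt: variant_io.VariantTable, config: RunConfig) -> dict:
    p1, p2 = config.parents
    _require_samples(vt, [p1, p2])
    zmap = allele_balance.classify_zygosity_windows(
        vt, p1, p2, window_bp=presets.ZYGOSITY_WINDOW_BP
    )
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    zmap.to_tsv(out / "zygosity_windows.tsv")
    with open(out / "zygosity_fractions.json", "w") as fh:
        json.dump(zmap.fractions, fh, indent=2)
    return {"mode": "zygosity", "config": config.resolved(), "fractions": zmap.fractions}


def _read_marker_reads(path: Path) -> list:
    from Bio import SeqIO

    fmt = "fastq" if path.suffix.lower() in (".fastq", ".fq") else "fasta"
    return [str(rec.seq) for rec in SeqIO.parse(str(path), fmt)]


def run_amplicon(config: RunConfig) -> dict:
    """Genotype a directory of per-individual/marker amplicon read files.

    Files are named ``<individual>.<marker>.fasta`` (or ``.fastq``).  Calls,
    the segregation table and the recombinant list are written as TSV.
    """
    from Bio import SeqIO

    refs = {rec.id: str(rec.seq) for rec in SeqIO.parse(config.refs_fasta, "fasta")}
    reads_dir = Path(config.reads_dir)
    calls = []
    for path in sorted(reads_dir.iterdir()):
        parts = path.name.split(".")
        if len(parts) < 3 or parts[-1].lower() not in ("fasta", "fa", "fastq", "fq"):
            continue
        individual, marker = parts[0], parts[1]
        reads = _read_marker_reads(path)
        hc = amplicon.stack_reads(reads, refs, individual=individual, marker=marker)
        calls.append(
            amplicon.call_s_genotype(
                hc, third_allele_min=config.third_allele_min, dup_ratio_min=config.dup_ratio_min
            )
        )
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    frame = amplicon.calls_to_frame(calls)
    frame.to_csv(out / "s_genotype_calls.tsv", sep="\t", index=False)

    markers = sorted(frame["marker"].unique()) if len(frame) else []
    primary = markers[0] if markers else None
    seg = None
    if primary is not None:
        primary_calls = [c for c in calls if c.marker == primary]
        seg = amplicon.tabulate_segregation(primary_calls, config.female, config.male_alleles)
        seg.to_tsv(out / "segregation.tsv")
    recombinants = []
    if len(markers) == 2:
        by_ind: dict = {}
        for c in calls:
            by_ind.setdefault(c.individual, {})[c.marker] = c
        for ind, mk in sorted(by_ind.items()):
            if len(mk) == 2:
                a, b = (mk[m] for m in markers)
                if amplicon.detect_marker_recombinant(a, b):
                    recombinants.append(ind)
        pd.Series(recombinants, name="individual").to_csv(
            out / "recombinants.tsv", sep="\t", index=False
        )
    report = {
        "mode": "amplicon",
        "config": config.resolved(),
        "n_calls": len(calls),
        "call_classes": frame["call_class"].value_counts().to_dict() if len(frame) else {},
        "recombinants": recombinants,
    }
    if seg is not None:
        report["segregation"] = {
            "counts": {f: seg.counts.loc[f].to_dict() for f in seg.counts.index},
            "female_totals": seg.female_totals.to_dict(),
            "male_totals": seg.male_totals.to_dict(),
            "duplicated_total": seg.duplicated_total,
            "total": seg.total,
            "chi2_female": seg.chi2_female,
            "p_female": seg.p_female,
            "n_incompatible": seg.n_incompatible,
        }
    return report


def run_pipeline(config: RunConfig) -> dict:
    """Dispatch a configured run and write the report JSON."""
    if config.mode in ("wgs_scan", "ddrad_scan", "balance", "zygosity"):
        if not config.vcf:
            raise ValueError(f"mode {config.mode!r} requires a VCF input")
        vt = variant_io.read_vcf(config.vcf)
        if config.mode == "wgs_scan":
            report = run_depth_scan(vt, config, "wgs")
        elif config.mode == "ddrad_scan":
            report = run_depth_scan(vt, config, "ddrad")
        elif config.mode == "balance":
            report = run_balance(vt, config)
        else:
            report = run_zygosity(vt, config)
    elif config.mode == "amplicon":
        report = run_amplicon(config)
    else:
        raise ValueError(f"unknown pipeline mode {config.mode!r}")
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, default=str)
    return report
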