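"""Independent, deliberately naive re-implementation of the filter rules.

Used as the oracle for filter_variants: every rule is applied per site with
explicit python loops over dict records, sharing no code with the package.
"""

from __future__ import annotations


def table_to_records(vt):
    records = []
    for i in range(vt.n_loci):
        gts = []
        for j in range(vt.n_samples):
            a, b = int(vt.gt[i, j, 0]), int(vt.gt[i, j, 1])
            gts.append(None if a < 0 else (a, b))
        dps = [int(d) if d >= 0 else None for d in vt.dp[i]]
        records.append(
            {
                "chrom": str(vt.chrom[i]),
                "pos": int(vt.pos[i]),
                "ref": str(vt.ref[i]),
                "alt": tuple(vt.alt[i]),
                "gt": gts,
                "dp": dps,
            }
        )
    return records


def oracle_filter(records, p):
    """Return the surviving (chrom, pos) list under FilterParams *p*."""
    recs = [dict(r, gt=list(r["gt"]), dp=list(r["dp"])) for r in records]

    # rule 1: genotype depth bounds mask the genotype and its depth
    for r in recs:
        for j in range(len(r["gt"])):
            d = r["dp"][j]
            if d is None:
                continue
            too_low = p.min_dp is not None and d < p.min_dp
            too_high = p.max_dp is not None and d > p.max_dp
            if too_low or too_high:
                r["gt"][j] = None
                r["dp"][j] = None

    survivors = []
    for r in recs:
        # rule 2: indels
        if p.remove_indels:
            alleles = [r["ref"], *r["alt"]]
            if any(len(a) != 1 for a in alleles):
                continue
        # rule 3: allele count
        if p.max_alleles is not None and 1 + len(r["alt"]) > p.max_alleles:
            continue
        # rule 4: site mean depth
        if p.min_mean_dp is not None or p.max_mean_dp is not None:
            depths = [d for d in r["dp"] if d is not None]
            if not depths:
                continue
            mean = sum(depths) / len(depths)
            if p.min_mean_dp is not None and mean < p.min_mean_dp:
                continue
            if p.max_mean_dp is not None and mean > p.max_mean_dp:
                continue
        # rule 5: call rate
        if p.max_missing is not None:
            called = sum(1 for g in r["gt"] if g is not None)
            if called / len(r["gt"]) < p.max_missing:
                continue
        # rule 6: allele frequencies
        if p.maf is not None or p.max_maf is not None:
            alleles = []
            for g in r["gt"]:
                if g is not None:
                    alleles.extend(g)
            if alleles:
                k = 1 + len(r["alt"])
                freqs = [alleles.count(a) / len(alleles) for a in range(k)]
                if p.maf is not None and min(freqs) < p.maf:
                    continue
                if p.max_maf is not None and max(freqs) > p.max_maf:
                    continue
        survivors.append(r)

    # rule 7: thinning
    if p.thin_bp > 0:
        kept = []
        last = {}
        for r in survivors:
            prev = last.get(r["chrom"])
            if prev is None or r["pos"] - prev >= p.thin_bp:
                kept.append(r)
                last[r["chrom"]] = r["pos"]
        survivors = kept

    return [(r["chrom"], r["pos"]) for r in survivors]
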