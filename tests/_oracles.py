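"""Independent brute-force oracles: naive per-site pure-Python recomputation
of the site-pattern statistics, kept deliberately separate from the package's
vectorized implementations."""


def brute_group_frequency(genotypes_for_group):
    """Derived-allele... no: ALT-allele frequency from a list of genotype
    codes (0/1/2 ALT dosage, -1 missing); None when no called alleles."""
    alt = 0
    called = 0
    for g in genotypes_for_group:
        if g >= 0:
            alt += g
            called += 2
    if called == 0:
        return None
    return alt / called


def brute_site_frequencies(geno, pops, p1g, p2g, p3g, og):
    """Per-site derived frequencies, outgroup-minor polarization, ALT tie."""
    out = []
    for i in range(geno.n_sites):
        freqs = []
        ok = True
        for grp in (p1g, p2g, p3g, og):
            cols = [geno.samples.index(m) for m in pops.members(grp)]
            f = brute_group_frequency([int(geno.genotypes[i, c]) for c in cols])
            if f is None:
                ok = False
                break
            freqs.append(f)
        if not ok:
            continue
        derived_is_alt = freqs[3] <= 0.5
        if not derived_is_alt:
            freqs = [1.0 - f for f in freqs]
        out.append(tuple(freqs))
    return out


def brute_d(sites):
    """D from a list of (p1, p2, p3, p4) tuples."""
    abba = baba = 0.0
    for p1, p2, p3, p4 in sites:
        abba += (1 - p1) * p2 * p3 * (1 - p4)
        baba += p1 * (1 - p2) * p3 * (1 - p4)
    if abba + baba == 0:
        return float("nan")
    return (abba - baba) / (abba + baba)


def brute_fd(sites):
    """f_d with the donor-like (max of p2, p3) denominator; floored at 0."""
    num = den = 0.0
    for p1, p2, p3, p4 in sites:
        abba = (1 - p1) * p2 * p3 * (1 - p4)
        baba = p1 * (1 - p2) * p3 * (1 - p4)
        pd = max(p2, p3)
        abba_d = (1 - p1) * pd * pd * (1 - p4)
        baba_d = p1 * (1 - pd) * pd * (1 - p4)
        num += abba - baba
        den += abba_d - baba_d
    if num <= 0:
        return 0.0
    if den == 0:
        return float("nan")
    return num / den


def brute_f4(pa, pb, pc, pd):
    return sum((a - b) * (c - d) for a, b, c, d in zip(pa, pb, pc, pd))


def brute_jackknife(block_values_num, block_values_den):
    """Delete-one jackknife (theta, se) from per-block numerator and
    denominator sums of a ratio statistic."""
    import math

    n = len(block_values_num)
    num_tot = sum(block_values_num)
    den_tot = sum(block_values_den)
    theta = num_tot / den_tot
    loo = [
        (num_tot - bn) / (den_tot - bd)
        for bn, bd in zip(block_values_num, block_values_den)
    ]
    mean = sum(loo) / n
    se = math.sqrt((n - 1) / n * sum((x - mean) ** 2 for x in loo))
    return theta, se
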