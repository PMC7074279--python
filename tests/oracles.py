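"""Independent brute-force oracles used by the test suite.

These transcribe the Weir & Cockerham (1984) definitions directly with
plain Python loops and fractions of counts, deliberately sharing no code
with the package implementation.
"""

from __future__ import annotations


def wc_components_biallelic(countsA, countsB):
    """(a, b, c) for the alt allele from genotype counts.

    ``counts* = (n_hom_ref, n_het, n_hom_alt)`` per group.
    """
    pops = []
    for n00, n01, n11 in (countsA, countsB):
        n = n00 + n01 + n11
        p = (n01 + 2 * n11) / (2 * n)
        h = n01 / n
        pops.append((n, p, h))
    r = 2
    nbar = sum(n for n, _, _ in pops) / r
    nc = (r * nbar - sum(n * n for n, _, _ in pops) / (r * nbar)) / (r - 1)
    pbar = sum(n * p for n, p, _ in pops) / (r * nbar)
    s2 = sum(n * (p - pbar) ** 2 for n, p, _ in pops) / ((r - 1) * nbar)
    hbar = sum(n * h for n, _, h in pops) / (r * nbar)
    a = (nbar / nc) * (
        s2 - (1 / (nbar - 1)) * (pbar * (1 - pbar) - ((r - 1) / r) * s2 - hbar / 4)
    )
    b = (nbar / (nbar - 1)) * (
        pbar * (1 - pbar) - ((r - 1) / r) * s2 - ((2 * nbar - 1) / (4 * nbar)) * hbar
    )
    c = hbar / 2
    return a, b, c


def wc_sums_multiallelic(genosA, genosB):
    """(sum_a, sum_abc) over alleles at one multiallelic locus from
    genotype lists (unordered allele pairs)."""
    alleles = sorted({x for g in list(genosA) + list(genosB) for x in g}, key=str)
    num = den = 0.0
    for allele in alleles:
        pops = []
        for genos in (genosA, genosB):
            n = len(genos)
            p = sum(g.count(allele) for g in genos) / (2 * n)
            h = sum(1 for g in genos if g.count(allele) == 1) / n
            pops.append((n, p, h))
        r = 2
        nbar = sum(n for n, _, _ in pops) / r
        nc = (r * nbar - sum(n * n for n, _, _ in pops) / (r * nbar)) / (r - 1)
        pbar = sum(n * p for n, p, _ in pops) / (r * nbar)
        s2 = sum(n * (p - pbar) ** 2 for n, p, _ in pops) / ((r - 1) * nbar)
        hbar = sum(n * h for n, _, h in pops) / (r * nbar)
        a = (nbar / nc) * (
            s2 - (1 / (nbar - 1)) * (pbar * (1 - pbar) - ((r - 1) / r) * s2 - hbar / 4)
        )
        b = (nbar / (nbar - 1)) * (
            pbar * (1 - pbar) - ((r - 1) / r) * s2 - ((2 * nbar - 1) / (4 * nbar)) * hbar
        )
        num += a
        den += a + b + hbar / 2
    return num, den


def wc_theta_multiallelic(genosA, genosB):
    """Ratio-of-sums theta at one locus; None if the denominator is 0."""
    num, den = wc_sums_multiallelic(genosA, genosB)
    return None if den == 0 else num / den
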