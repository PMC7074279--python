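"""Weir & Cockerham (1984) variance components for F-statistics.

The fixation index between populations is estimated as theta,
``theta = sum(a) / sum(a + b + c)``, where a, b and c are the
among-population, among-individual-within-population and within-individual
variance components of allele frequency.  Components are computed per
allele (and summed over alleles at multiallelic loci) from three
per-population summaries: sample size ``n_i`` (diploid individuals),
allele frequency ``p_i`` and the proportion of individuals heterozygous
for the allele, ``h_i``.

Two entry points are provided: a scalar routine for arbitrary multiallelic
genotype lists (used for inversion karyotypes) and a vectorised biallelic
routine over whole genotype matrices (used for genome-wide SNV scans).
"""

from __future__ import annotations

from collections import Counter
from typing import Hashable, Sequence

import numpy as np

__all__ = [
    "allele_components",
    "locus_components",
    "theta_from_components",
    "multilocus_theta",
    "biallelic_components_matrix",
]


def allele_components(
    n: Sequence[float], p: Sequence[float], h: Sequence[float]
) -> tuple[float, float, float]:
    """(a, b, c) for one allele from per-population (n_i, p_i, h_i).

    ``n_i`` are diploid sample sizes, ``p_i`` allele frequencies and
    ``h_i`` observed heterozygote proportions for this allele.  Requires
    at least two populations and a mean sample size above one individual.
    """
    n = np.asarray(n, dtype=float)
    p = np.asarray(p, dtype=float)
    h = np.asarray(h, dtype=float)
    r = n.size
    if r < 2:
        raise ValueError("need at least two populations")
    nbar = n.mean()
    if nbar <= 1:
        raise ValueError("mean sample size must exceed one diploid individual")
    rn = r * nbar
    nc = (rn - (n**2).sum() / rn) / (r - 1)
    pbar = (n * p).sum() / rn
    s2 = (n * (p - pbar) ** 2).sum() / ((r - 1) * nbar)
    hbar = (n * h).sum() / rn
    inner = pbar * (1 - pbar) - (r - 1) / r * s2
    a = nbar / nc * (s2 - (inner - hbar / 4) / (nbar - 1))
    b = nbar / (nbar - 1) * (inner - (2 * nbar - 1) / (4 * nbar) * hbar)
    c = hbar / 2
    return float(a), float(b), float(c)


def locus_components(
    genotypes_by_pop: Sequence[Sequence[tuple[Hashable, Hashable]]],
) -> tuple[float, float, float]:
    """Summed per-allele (a, b, c) at one multiallelic diploid locus.

    ``genotypes_by_pop[i]`` is the list of unordered allele pairs observed
    in population i (missing genotypes simply absent).
    """
    ns = [len(g) for g in genotypes_by_pop]
    if any(n == 0 for n in ns):
        raise ValueError("every population needs at least one genotype")
    alleles = sorted(
        {a for pop in genotypes_by_pop for pair in pop for a in pair}, key=str
    )
    a_tot = b_tot = c_tot = 0.0
    for allele in alleles:
        p, h = [], []
        for pop, n in zip(genotypes_by_pop, ns):
            copies = sum(pair.count(allele) for pair in pop)
            hets = sum(pair.count(allele) == 1 for pair in pop)
            p.append(copies / (2 * n))
            h.append(hets / n)
        da, db, dc = allele_components(ns, p, h)
        a_tot += da
        b_tot += db
        c_tot += dc
    return a_tot, b_tot, c_tot


def theta_from_components(a: float, b: float, c: float) -> float:
    """theta = a / (a + b + c); NaN when the denominator is zero."""
    denom = a + b + c
    return float("nan") if denom == 0 else a / denom


def multilocus_theta(
    per_locus_genotypes: Sequence[Sequence[Sequence[tuple[Hashable, Hashable]]]],
) -> float:
    """Ratio-of-sums theta over several multiallelic loci.

    ``per_locus_genotypes[l][i]`` = genotype list of population i at locus
    l.  Loci monomorphic across all populations contribute zero to both
    sums; theta is NaN if every locus is monomorphic.
    """
    num = den = 0.0
    for locus in per_locus_genotypes:
        a, b, c = locus_components(locus)
        num += a
        den += a + b + c
    return theta_from_components(num, den, 0.0) if den else float("nan")


def _group_summaries(G: np.ndarray):
    """Per-site (n, p, h) for a genotype matrix coded 0/1/2, -1 missing."""
    obs = G >= 0
    n = obs.sum(axis=1).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        alt = np.where(obs, G, 0).sum(axis=1)
        p = alt / (2 * n)
        h = np.where(obs, G == 1, False).sum(axis=1) / n
    return n, p, h


def biallelic_components_matrix(
    GA: np.ndarray, GB: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorised two-population (a, b, c) for the alternate allele.

    ``GA``/``GB`` are (n_sites, n_samples) genotype matrices coded as alt
    allele counts 0/1/2 with -1 for missing.  Components are returned per
    site for the alternate allele only (at a biallelic site using both
    alleles doubles numerator and denominator alike, so per-site weights
    in ratio-of-sums stay consistent).  Sites where either group has no
    data or the mean sample size is <= 1 come back NaN.
    """
    GA = np.atleast_2d(np.asarray(GA))
    GB = np.atleast_2d(np.asarray(GB))
    nA, pA, hA = _group_summaries(GA)
    nB, pB, hB = _group_summaries(GB)
    r = 2.0
    nbar = (nA + nB) / r
    bad = (nA == 0) | (nB == 0) | (nbar <= 1)
    with np.errstate(invalid="ignore", divide="ignore"):
        rn = r * nbar
        nc = (rn - (nA**2 + nB**2) / rn) / (r - 1)
        pbar = (nA * pA + nB * pB) / rn
        s2 = (nA * (pA - pbar) ** 2 + nB * (pB - pbar) ** 2) / ((r - 1) * nbar)
        hbar = (nA * hA + nB * hB) / rn
        inner = pbar * (1 - pbar) - (r - 1) / r * s2
        a = nbar / nc * (s2 - (inner - hbar / 4) / (nbar - 1))
        b = nbar / (nbar - 1) * (inner - (2 * nbar - 1) / (4 * nbar) * hbar)
        c = hbar / 2
    a = np.where(bad, np.nan, a)
    b = np.where(bad, np.nan, b)
    c = np.where(bad, np.nan, c)
    return a, b, c
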