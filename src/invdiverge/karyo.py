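"""Population genetics of polytene-chromosome inversion karyotypes.

Inversion arrangements are scored per chromosome arm (X, 2R, 3R, 3L) using
the conventional digit nomenclature: 0 is the standard arrangement,
numbered digits are inverted variants, and a diploid genotype is an
unordered digit pair (``01`` = heterokaryotype, ``14`` = heterokaryotype of
two inverted variants).  Males are hemizygous for the X and carry a single
digit there.

On parsed records the module computes arrangement/allele frequencies,
permutation tests of Hardy-Weinberg equilibrium (via Fis), pairwise
Weir-Cockerham theta between population samples with permutation p-values
and a Bonferroni flag, and a covariance PCA on population-level inversion
frequencies.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import wc

__all__ = [
    "ARMS",
    "AUTOSOMAL_ARMS",
    "ALLELE_SETS",
    "KaryotypeRecord",
    "AlleleFreqTable",
    "HWEResult",
    "FstResult",
    "FreqPCAResult",
    "KaryotypeParseError",
    "parse_karyotype",
    "read_karyotype_table",
    "write_karyotype_table",
    "allele_frequencies",
    "hwe_permutation_test",
    "pairwise_fst",
    "bonferroni_adjust",
    "inverted_frequency_matrix",
    "inversion_frequency_pca",
    "arrangement_summary",
    "group_records",
]

ARMS = ("X", "2R", "3R", "3L")
AUTOSOMAL_ARMS = ("2R", "3R", "3L")

#: Digits allowed per arm; 0 always denotes the standard arrangement.
ALLELE_SETS: dict[str, frozenset[int]] = {
    "X": frozenset({0, 1, 2, 4}),
    "2R": frozenset({0, 1, 4}),
    "3R": frozenset({0, 1}),
    "3L": frozenset({0, 1}),
}


class KaryotypeParseError(ValueError):
    pass


@dataclass(frozen=True)
class KaryotypeRecord:
    """One karyotyped specimen; X genotype is a single digit for males."""

    specimen_id: str
    population: str
    species: str
    sex: str  # "F" | "M"
    genotypes: dict[str, tuple[int, ...] | None] = field(default_factory=dict)

    def genotype(self, arm: str) -> tuple[int, ...] | None:
        return self.genotypes.get(arm)


def _parse_arm_token(arm: str, token: str, sex: str) -> tuple[int, ...] | None:
    if token.upper() == "NA":
        return None
    if not re.fullmatch(r"\d{1,2}", token):
        raise KaryotypeParseError(f"malformed genotype token {arm}{token!r}")
    alleles = tuple(int(ch) for ch in token)
    expected = 1 if (arm == "X" and sex == "M") else 2
    if len(alleles) != expected:
        kind = "hemizygous male X" if expected == 1 else f"diploid {arm}"
        raise KaryotypeParseError(
            f"{kind} requires {expected} digit(s), got {arm}{token!r}"
        )
    bad = [a for a in alleles if a not in ALLELE_SETS[arm]]
    if bad:
        raise KaryotypeParseError(f"allele {bad[0]} not allowed on {arm} ({arm}{token!r})")
    return tuple(sorted(alleles))


def parse_karyotype(row: str) -> KaryotypeRecord:
    """Parse a comma-separated karyotype row.

    Format: ``id, population, species, sex, X<g> 2R<g> 3R<g> 3L<g>`` where
    each ``<g>`` is a digit pair (one digit for the male X), e.g.
    ``"ME21, Yegoryevsk, hybrid, F, X04 2R01 3R00 3L00"``.  Allele pairs
    are stored unordered (``01`` and ``10`` are the same genotype).
    """
    parts = [p.strip() for p in row.split(",")]
    if len(parts) != 5:
        raise KaryotypeParseError(f"expected 5 comma-separated fields, got {len(parts)}")
    specimen_id, population, species, sex, karyo = parts
    sex = sex.upper()
    if sex not in ("F", "M"):
        raise KaryotypeParseError(f"sex must be F or M, got {sex!r}")
    genotypes: dict[str, tuple[int, ...] | None] = {}
    for token in karyo.split():
        m = re.fullmatch(r"(X|2R|3R|3L)(\S+)", token)
        if not m:
            raise KaryotypeParseError(f"unrecognised arm token {token!r}")
        arm, geno = m.groups()
        if arm in genotypes:
            raise KaryotypeParseError(f"duplicate arm {arm}")
        genotypes[arm] = _parse_arm_token(arm, geno, sex)
    return KaryotypeRecord(specimen_id, population, species, sex, genotypes)


def read_karyotype_table(path) -> list[KaryotypeRecord]:
    """Read the TSV karyotype table (header ``specimen_id population species
    sex X 2R 3R 3L``; ``NA`` for unreadable arms)."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    required = ["specimen_id", "population", "species", "sex", *ARMS]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise KaryotypeParseError(f"missing column(s): {', '.join(missing)}")
    records = []
    for _, r in df.iterrows():
        sex = r["sex"].upper()
        if sex not in ("F", "M"):
            raise KaryotypeParseError(f"sex must be F or M, got {r['sex']!r}")
        genotypes = {arm: _parse_arm_token(arm, r[arm], sex) for arm in ARMS}
        records.append(
            KaryotypeRecord(r["specimen_id"], r["population"], r["species"], sex, genotypes)
        )
    return records


def write_karyotype_table(records: list[KaryotypeRecord], path) -> None:
    rows = []
    for rec in records:
        row = {
            "specimen_id": rec.specimen_id,
            "population": rec.population,
            "species": rec.species,
            "sex": rec.sex,
        }
        for arm in ARMS:
            g = rec.genotype(arm)
            row[arm] = "NA" if g is None else "".join(str(a) for a in g)
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def group_records(records) -> dict[tuple[str, str], list[KaryotypeRecord]]:
    """Group records into (population, species) samples — the unit of the
    per-sample statistics."""
    groups: dict[tuple[str, str], list[KaryotypeRecord]] = {}
    for r in records:
        groups.setdefault((r.population, r.species), []).append(r)
    return groups


# ---------------------------------------------------------------------------
# Frequencies
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class AlleleFreqTable:
    locus: str
    frequencies: dict[int, float]
    allele_count_total: int

    def frequency(self, allele: int) -> float:
        return self.frequencies.get(allele, 0.0)

    @property
    def monomorphic(self) -> bool:
        return len(self.frequencies) == 1


def allele_frequencies(records, arm: str) -> AlleleFreqTable:
    """Allele frequencies at one arm; X males contribute one allele copy,
    everything else two."""
    counts: dict[int, int] = {}
    total = 0
    for r in records:
        g = r.genotype(arm)
        if g is None:
            continue
        for a in g:
            counts[a] = counts.get(a, 0) + 1
            total += 1
    if total == 0:
        raise ValueError(f"no usable records for arm {arm}")
    freqs = {a: c / total for a, c in sorted(counts.items())}
    return AlleleFreqTable(arm, freqs, total)


def _diploid_genotypes(records, arm: str) -> list[tuple[int, int]]:
    """Diploid genotypes entering HWE: females only on the X (hemizygous
    males cannot be heterozygous)."""
    out = []
    for r in records:
        if arm == "X" and r.sex == "M":
            continue
        g = r.genotype(arm)
        if g is not None and len(g) == 2:
            out.append(g)
    return out


# ---------------------------------------------------------------------------
# Hardy-Weinberg permutation test
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class HWEResult:
    locus: str
    status: str  # "tested" | "monomorphic"
    fis: float = float("nan")
    p_value: float = float("nan")
    n_permutations: int = 0
    n_genotypes: int = 0
    seed: int | None = None


def _fis(het_count: int, n: int, expected_het: float) -> float:
    return 1.0 - (het_count / n) / expected_het


def hwe_permutation_test(
    records, arm: str, n_perm: int = 10_000, seed: int | None = None
) -> HWEResult:
    """Permutation test of Hardy-Weinberg equilibrium at one arm.

    Fis = 1 - Ho/He with Ho the observed heterozygote proportion and
    He = 1 - sum(p_a^2) from the same diploid genotypes (plug-in
    estimator; the permutation null uses the identical statistic so the
    small-sample bias cancels).  The null re-pairs the pooled alleles into
    diploids ``n_perm`` times; the two-sided p-value is the proportion of
    permutations with |Fis| >= |observed| under the +1/(n+1) correction,
    so deficits and excesses of heterozygotes are both detected and p is
    never exactly zero.
    """
    genotypes = _diploid_genotypes(records, arm)
    if len(genotypes) < 2:
        raise ValueError("insufficient data: fewer than 2 diploid genotypes")
    # sorted pool => permutation stream independent of input row order
    alleles = np.sort(np.array([a for g in genotypes for a in g]))
    n = len(genotypes)
    uniq, counts = np.unique(alleles, return_counts=True)
    if uniq.size == 1:
        return HWEResult(arm, "monomorphic", n_genotypes=n, seed=seed)
    p = counts / counts.sum()
    he = 1.0 - (p**2).sum()
    obs_het = sum(g[0] != g[1] for g in genotypes)
    fis_obs = _fis(obs_het, n, he)

    rng = np.random.default_rng(seed)
    perm = rng.permuted(np.tile(alleles, (n_perm, 1)), axis=1).reshape(n_perm, n, 2)
    het_counts = (perm[:, :, 0] != perm[:, :, 1]).sum(axis=1)
    fis_perm = 1.0 - (het_counts / n) / he
    extreme = np.abs(fis_perm) >= abs(fis_obs) - 1e-12
    p_value = (extreme.sum() + 1) / (n_perm + 1)
    return HWEResult(arm, "tested", float(fis_obs), float(p_value), n_perm, n, seed)


# ---------------------------------------------------------------------------
# Pairwise Fst
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class FstResult:
    pair: tuple[str, str]
    theta: float
    p_value: float
    n_permutations: int
    loci: tuple[str, ...]
    seed: int | None = None
    significant_after_bonferroni: bool | None = None


def _theta_for_partition(genos_by_locus, assignment, n_a):
    """Ratio-of-sums theta for one specimen partition.

    ``genos_by_locus[l]`` lists (specimen_index, genotype); ``assignment``
    maps pooled specimen index -> True if in group A.
    """
    num = den = 0.0
    for pairs in genos_by_locus:
        ga = [g for i, g in pairs if assignment[i]]
        gb = [g for i, g in pairs if not assignment[i]]
        if not ga or not gb:
            continue
        a, b, c = wc.locus_components([ga, gb])
        num += a
        den += a + b + c
    return float("nan") if den == 0 else num / den


def pairwise_fst(
    records_a,
    records_b,
    arms: tuple[str, ...] = AUTOSOMAL_ARMS,
    n_perm: int = 10_000,
    seed: int | None = None,
    labels: tuple[str, str] = ("A", "B"),
) -> FstResult:
    """Weir-Cockerham theta between two population samples with a
    permutation p-value.

    Theta is the multiallelic ratio-of-sums over the given arms (autosomal
    by default: hemizygous males make the X incomparable between sexes).
    The null shuffles whole specimens between the two samples, keeping
    genotypes intact; p is the one-sided proportion of permuted theta >=
    observed, +1/(n+1) corrected.
    """
    records_a, records_b = list(records_a), list(records_b)
    if not records_a or not records_b:
        raise ValueError("both populations must be non-empty")

    # Canonical specimen order (genotype signature, then source group) so
    # permutation p-values do not depend on input row order.
    def signature(item):
        r, in_a = item
        return (tuple(str(r.genotype(arm)) for arm in arms), in_a)

    tagged = [(r, True) for r in records_a] + [(r, False) for r in records_b]
    tagged.sort(key=signature)
    pooled = [r for r, _ in tagged]
    in_group_a = np.array([flag for _, flag in tagged])
    n_a = len(records_a)
    genos_by_locus = []
    for arm in arms:
        pairs = []
        for i, r in enumerate(pooled):
            g = r.genotype(arm)
            if g is not None and len(g) == 2:
                pairs.append((i, g))
        genos_by_locus.append(pairs)

    theta = _theta_for_partition(genos_by_locus, in_group_a, n_a)
    if np.isnan(theta):
        raise ValueError("theta undefined: all arms monomorphic across both samples")

    rng = np.random.default_rng(seed)
    hits = 0
    idx = np.arange(len(pooled))
    for _ in range(n_perm):
        perm = rng.permutation(idx)
        assign = np.zeros(len(pooled), dtype=bool)
        assign[perm[:n_a]] = True
        t = _theta_for_partition(genos_by_locus, assign, n_a)
        if not np.isnan(t) and t >= theta - 1e-12:
            hits += 1
    p_value = (hits + 1) / (n_perm + 1)
    return FstResult(labels, float(theta), float(p_value), n_perm, tuple(arms), seed)


def bonferroni_adjust(p_values, alpha: float = 0.05) -> list[bool]:
    """Significance flags under the Bonferroni correction: p < alpha/m."""
    p_values = list(p_values)
    m = len(p_values)
    if m < 1:
        raise ValueError("need at least one p-value")
    return [p < alpha / m for p in p_values]


# ---------------------------------------------------------------------------
# PCA on population-level inversion frequencies
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class FreqPCAResult:
    scores: pd.DataFrame  # rows = samples, columns = PC1..
    loadings: pd.DataFrame  # rows = variables
    percent_variance: np.ndarray


def inverted_frequency_matrix(records, arms: tuple[str, ...] = AUTOSOMAL_ARMS) -> pd.DataFrame:
    """Per-(population, species) frequencies of every non-standard
    arrangement on the given arms — the input of the frequency PCA."""
    groups = group_records(records)
    columns = [
        (arm, allele) for arm in arms for allele in sorted(ALLELE_SETS[arm] - {0})
    ]
    rows = {}
    for key, recs in sorted(groups.items()):
        row = {}
        for arm, allele in columns:
            try:
                row[f"{arm}{allele}"] = allele_frequencies(recs, arm).frequency(allele)
            except ValueError:
                row[f"{arm}{allele}"] = np.nan
        rows[", ".join(key)] = row
    return pd.DataFrame.from_dict(rows, orient="index")


def inversion_frequency_pca(freq_matrix: pd.DataFrame, scale: bool = False) -> FreqPCAResult:
    """Covariance PCA of population-level inversion frequencies.

    Columns are centered; with ``scale=True`` they are also divided by
    their standard deviation (correlation PCA).  Percent variance per
    component always sums to 100.
    """
    X = freq_matrix.to_numpy(dtype=float)
    if X.shape[0] < 2:
        raise ValueError("need at least two rows for PCA")
    Xc = X - X.mean(axis=0)
    if scale:
        sd = Xc.std(axis=0, ddof=1)
        sd[sd == 0] = 1.0
        Xc = Xc / sd
    if not np.any(Xc):
        warnings.warn("zero total variance: all rows identical", stacklevel=2)
        k = min(X.shape) - 1 or 1
        scores = pd.DataFrame(
            np.zeros((X.shape[0], k)),
            index=freq_matrix.index,
            columns=[f"PC{i+1}" for i in range(k)],
        )
        loadings = pd.DataFrame(
            np.zeros((X.shape[1], k)), index=freq_matrix.columns, columns=scores.columns
        )
        return FreqPCAResult(scores, loadings, np.zeros(k))
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    keep = s > s[0] * 1e-12
    U, s, Vt = U[:, keep], s[keep], Vt[keep]
    pve = 100.0 * s**2 / (s**2).sum()
    cols = [f"PC{i+1}" for i in range(s.size)]
    scores = pd.DataFrame(U * s, index=freq_matrix.index, columns=cols)
    loadings = pd.DataFrame(Vt.T, index=freq_matrix.columns, columns=cols)
    return FreqPCAResult(scores, loadings, pve)


# ---------------------------------------------------------------------------
# Arrangement class summaries
# ---------------------------------------------------------------------------


def arrangement_summary(records) -> pd.DataFrame:
    """Proportions of karyotype classes per arm and (population, species).

    Classes are the observed genotype strings (``00`` standard homozygote,
    ``01`` heterozygote, ``11`` inverted homozygote, rare-variant classes
    like ``04``/``14``, and single digits for the male X, reported
    separately by sex on the X).
    """
    rows = []
    for (pop, sp), recs in sorted(group_records(records).items()):
        for arm in ARMS:
            strata = (
                [("F", [r for r in recs if r.sex == "F"]), ("M", [r for r in recs if r.sex == "M"])]
                if arm == "X"
                else [("*", recs)]
            )
            for sex, sub in strata:
                classes: dict[str, int] = {}
                for r in sub:
                    g = r.genotype(arm)
                    if g is None:
                        continue
                    cls = "".join(str(a) for a in g)
                    classes[cls] = classes.get(cls, 0) + 1
                total = sum(classes.values())
                for cls, count in sorted(classes.items()):
                    rows.append(
                        {
                            "population": pop,
                            "species": sp,
                            "arm": arm,
                            "sex": sex,
                            "karyotype_class": cls,
                            "count": count,
                            "proportion": count / total,
                        }
                    )
    return pd.DataFrame(rows)
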