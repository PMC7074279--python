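"""Genome-scale divergence between two population samples.

The pipeline starts at a VCF of biallelic SNV calls with site QUAL and
per-genotype GQ: variants are filtered (site quality, genotype-quality
masking, missingness, per-contig thinning), lifted from scaffold to
chromosome coordinates through an offset map, and summarised as
Weir-Cockerham theta in nonoverlapping 5-kb windows.  Individual-level
structure is estimated by a K-cluster admixture EM on the genotype matrix
and by PCA with Patterson normalisation.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import wc

__all__ = [
    "VariantRecord",
    "VariantFilterSpec",
    "ChromosomeMap",
    "WindowFst",
    "AncestryEstimate",
    "GenotypePCAResult",
    "read_vcf",
    "filter_variants",
    "read_chromosome_map",
    "lift_coordinates",
    "lift_records",
    "wc_theta_site",
    "windowed_fst",
    "windows_to_frame",
    "mean_fst",
    "genotype_matrix",
    "admixture_em",
    "genotype_pca",
]

UNPLACED = "unplaced"


@dataclass(frozen=True, eq=False)
class VariantRecord:
    """One SNV: genotypes are alt-allele counts 0/1/2 with -1 = missing.

    Equality is identity (the genotype arrays make field-wise comparison
    ambiguous); compare fields explicitly where needed.
    """

    contig: str
    position: int  # 1-based
    ref: str
    alts: tuple[str, ...]
    quality: float
    genotypes: np.ndarray
    genotype_quality: np.ndarray

    @property
    def biallelic_snv(self) -> bool:
        return (
            len(self.alts) == 1
            and len(self.ref) == 1
            and len(self.alts[0]) == 1
            and self.ref != self.alts[0]
        )


def read_vcf(path) -> tuple[list[str], list[VariantRecord]]:
    """Read a (plain or bgzipped) VCF into sample names + variant records."""
    from cyvcf2 import VCF

    vcf = VCF(str(path), gts012=True)
    samples = list(vcf.samples)
    records = []
    for v in vcf:
        gt = np.asarray(v.gt_types, dtype=np.int8)
        gt = np.where(gt == 3, -1, gt)  # gts012: 3 = unknown
        gq = np.asarray(v.gt_quals, dtype=float)
        records.append(
            VariantRecord(
                contig=v.CHROM,
                position=v.POS,
                ref=v.REF,
                alts=tuple(v.ALT),
                quality=float(v.QUAL) if v.QUAL is not None else 0.0,
                genotypes=gt,
                genotype_quality=gq,
            )
        )
    return samples, records


@dataclass(frozen=True)
class VariantFilterSpec:
    """Filtering thresholds (defaults reproduce the published pipeline:
    site QUAL >= 400, GQ >= 10 masking, <= 1 missing genotype per site,
    10-kb per-contig thinning, biallelic SNVs only)."""

    min_site_quality: float = 400.0
    min_genotype_quality: float = 10.0
    max_missing_count: int = 1
    thin_bp: int = 10_000
    biallelic_only: bool = True

    def __post_init__(self):
        for name in ("min_site_quality", "min_genotype_quality", "max_missing_count", "thin_bp"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


def filter_variants(
    records: list[VariantRecord], spec: VariantFilterSpec = VariantFilterSpec()
) -> list[VariantRecord]:
    """Apply the filter cascade in its stated order.

    1. drop non-biallelic / non-SNV sites; 2. drop sites with
    QUAL < ``min_site_quality``; 3. mask genotypes with
    GQ < ``min_genotype_quality`` to missing; 4. drop sites with more than
    ``max_missing_count`` missing genotypes; 5. thin greedily left to
    right per contig, keeping a site only if at least ``thin_bp`` from the
    last kept site on the same contig.  Thinning is order-dependent, so
    unsorted input is an error, and the cascade is idempotent.
    """
    last_pos: dict[str, int] = {}
    seen_order: dict[str, int] = {}
    out = []
    for i, rec in enumerate(records):
        prev = seen_order.get(rec.contig)
        if prev is not None and rec.position < prev:
            raise ValueError(
                f"records not sorted by position on contig {rec.contig} "
                f"(pos {rec.position} after {prev})"
            )
        seen_order[rec.contig] = rec.position
        if spec.biallelic_only and not rec.biallelic_snv:
            continue
        if rec.quality < spec.min_site_quality:
            continue
        mask = (rec.genotype_quality < spec.min_genotype_quality) & (rec.genotypes >= 0)
        if mask.any():
            gt = np.where(mask, np.int8(-1), rec.genotypes)
            rec = replace(rec, genotypes=gt)
        if int((rec.genotypes < 0).sum()) > spec.max_missing_count:
            continue
        last = last_pos.get(rec.contig)
        if last is not None and rec.position - last < spec.thin_bp:
            continue
        last_pos[rec.contig] = rec.position
        out.append(rec)
    return out


# ---------------------------------------------------------------------------
# Coordinate lifting
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ContigPlacement:
    chromosome: str
    offset: int
    orientation: str  # "+" | "-"
    length: int


@dataclass
class ChromosomeMap:
    placements: dict[str, ContigPlacement] = field(default_factory=dict)

    def __post_init__(self):
        # lifted intervals of distinct contigs on a chromosome must not overlap
        by_chrom: dict[str, list[tuple[int, int, str]]] = {}
        for name, p in self.placements.items():
            by_chrom.setdefault(p.chromosome, []).append(
                (p.offset + 1, p.offset + p.length, name)
            )
        for chrom, spans in by_chrom.items():
            spans.sort()
            for (s1, e1, n1), (s2, e2, n2) in zip(spans, spans[1:]):
                if s2 <= e1:
                    raise ValueError(
                        f"contigs {n1} and {n2} overlap on chromosome {chrom}"
                    )


def read_chromosome_map(path) -> ChromosomeMap:
    """Read the TSV map: ``contig  chromosome  offset  orientation  length``."""
    df = pd.read_csv(path, sep="\t", dtype={"contig": str, "chromosome": str})
    placements = {
        r.contig: ContigPlacement(r.chromosome, int(r.offset), str(r.orientation), int(r.length))
        for r in df.itertuples()
    }
    return ChromosomeMap(placements)


def lift_coordinates(record: VariantRecord, cmap: ChromosomeMap) -> VariantRecord:
    """Convert a scaffold-based record to chromosome coordinates.

    Forward placements: chrom_pos = offset + pos.  Reverse placements:
    chrom_pos = offset + (length - pos + 1), so a contig's last base lands
    first.  Unmapped contigs are routed to the ``unplaced`` bin (contig
    renamed, position kept) rather than raising.
    """
    p = cmap.placements.get(record.contig)
    if p is None:
        return replace(record, contig=UNPLACED)
    if p.orientation == "+":
        pos = p.offset + record.position
    else:
        pos = p.offset + (p.length - record.position + 1)
    return replace(record, contig=p.chromosome, position=pos)


def lift_records(
    records: list[VariantRecord], cmap: ChromosomeMap
) -> tuple[list[VariantRecord], list[VariantRecord]]:
    """Lift all records; returns (placed sorted by chrom/pos, unplaced)."""
    placed, unplaced = [], []
    for rec in records:
        lifted = lift_coordinates(rec, cmap)
        (unplaced if lifted.contig == UNPLACED else placed).append(lifted)
    placed.sort(key=lambda r: (r.contig, r.position))
    return placed, unplaced


# ---------------------------------------------------------------------------
# Weir-Cockerham theta, sites and windows
# ---------------------------------------------------------------------------


def wc_theta_site(gtA, gtB) -> tuple[float, float, float, float]:
    """Two-group WC84 components (a, b, c) and theta at one biallelic site.

    ``gtA``/``gtB`` are alt-allele-count genotype vectors (missing = -1).
    Theta is NaN when both groups are monomorphic for the same allele
    (zero denominator).
    """
    a, b, c = wc.biallelic_components_matrix(
        np.asarray(gtA)[None, :], np.asarray(gtB)[None, :]
    )
    a, b, c = float(a[0]), float(b[0]), float(c[0])
    return a, b, c, wc.theta_from_components(a, b, c)


@dataclass(frozen=True)
class WindowFst:
    chromosome: str
    start: int  # 0-based half-open
    end: int
    n_snvs: int
    numerator: float
    denominator: float

    @property
    def fst(self) -> float:
        return float("nan") if self.denominator == 0 else self.numerator / self.denominator


def windowed_fst(
    records: list[VariantRecord],
    samples: list[str],
    group_a: list[str],
    group_b: list[str],
    window_bp: int = 5_000,
) -> list[WindowFst]:
    """Ratio-of-sums Weir-Cockerham Fst in nonoverlapping windows.

    Windows tile each chromosome from coordinate 0 in ``window_bp`` steps
    (0-based half-open); a 1-based position p falls in window
    ``(p - 1) // window_bp``.  Per window, fst = sum(a) / sum(a+b+c) over
    contained SNVs; windows without SNVs are omitted.  Negative values are
    reported as computed.
    """
    index = {s: i for i, s in enumerate(samples)}
    unknown = [s for s in (*group_a, *group_b) if s not in index]
    if unknown:
        raise ValueError(f"unknown sample id(s): {', '.join(unknown)}")
    ia = [index[s] for s in group_a]
    ib = [index[s] for s in group_b]
    if not records:
        return []
    G = np.stack([r.genotypes for r in records])
    a, b, c = wc.biallelic_components_matrix(G[:, ia], G[:, ib])
    abc = a + b + c

    acc: dict[tuple[str, int], list[float]] = {}
    for i, rec in enumerate(records):
        if np.isnan(abc[i]):
            continue
        w = (rec.position - 1) // window_bp
        cell = acc.setdefault((rec.contig, w), [0, 0.0, 0.0])
        cell[0] += 1
        cell[1] += a[i]
        cell[2] += abc[i]
    return [
        WindowFst(chrom, w * window_bp, (w + 1) * window_bp, n, num, den)
        for (chrom, w), (n, num, den) in sorted(acc.items())
    ]


def windows_to_frame(windows: list[WindowFst]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "chromosome": [w.chromosome for w in windows],
            "start": [w.start for w in windows],
            "end": [w.end for w in windows],
            "n_snvs": [w.n_snvs for w in windows],
            "fst": [w.fst for w in windows],
            "numerator": [w.numerator for w in windows],
            "denominator": [w.denominator for w in windows],
        }
    )


def mean_fst(
    windows: list[WindowFst],
    chromosomes: set[str] | None = None,
    interval: tuple[int, int] | None = None,
    weighting: str = "mean_of_windows",
) -> float:
    """Mean Fst over a window scope.

    ``weighting="mean_of_windows"`` averages per-window fst values
    (windows with zero denominator skipped); ``"ratio_of_sums"`` pools the
    variance components before dividing, which weights windows by their
    information content and is the consistent estimator of the generating
    Fst.  ``chromosomes`` restricts the scope; ``interval`` additionally
    keeps windows fully inside [start, end) of each selected chromosome.
    """
    sel = [
        w
        for w in windows
        if (chromosomes is None or w.chromosome in chromosomes)
        and (interval is None or (w.start >= interval[0] and w.end <= interval[1]))
    ]
    if not sel:
        raise ValueError("empty scope: no windows selected")
    if weighting == "ratio_of_sums":
        den = sum(w.denominator for w in sel)
        if den == 0:
            return float("nan")
        return sum(w.numerator for w in sel) / den
    if weighting == "mean_of_windows":
        vals = [w.fst for w in sel if w.denominator != 0]
        if not vals:
            return float("nan")
        return float(np.mean(vals))
    raise ValueError(f"unknown weighting {weighting!r}")


# ---------------------------------------------------------------------------
# Admixture EM
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class AncestryEstimate:
    q: np.ndarray  # (n_individuals, K), rows sum to 1
    cluster_frequencies: np.ndarray  # (K, n_loci)
    log_likelihood: float
    log_likelihood_trace: np.ndarray
    converged: bool
    n_iterations: int


def genotype_matrix(records: list[VariantRecord]) -> np.ndarray:
    """(n_samples, n_loci) alt-allele-count matrix from variant records."""
    return np.stack([r.genotypes for r in records]).T.astype(np.int8)


def _em_once(G, obs, K, rng, tol, max_iter, eps=1e-9):
    n, L = G.shape
    Gf = np.where(obs, G, 0).astype(float)
    Cf = np.where(obs, 2.0 - Gf, 0.0)  # reference-allele copies
    # q starts uniform and F random: initialisation then depends only on
    # the loci, so permuting individuals permutes q rows and nothing else
    q = np.full((n, K), 1.0 / K)
    F = rng.uniform(0.05, 0.95, size=(K, L))
    copies = obs.sum(axis=1) * 2.0
    trace = []
    converged = False
    for _ in range(max_iter):
        P = np.clip(q @ F, eps, 1 - eps)  # (n, L) expected alt frequency
        ll = float((Gf * np.log(P) + Cf * np.log1p(-P)).sum())
        trace.append(ll)
        if len(trace) > 1 and trace[-1] - trace[-2] < tol:
            converged = True
            break
        # E/M fused: expected allele copies drawn from each cluster
        WG = Gf / P  # (n, L)
        WC = Cf / (1 - P)
        new_q = np.empty_like(q)
        new_F = np.empty_like(F)
        for k in range(K):
            qk = q[:, k][:, None]
            ak = (WG * F[k]) * qk  # alt copies from cluster k
            bk = (WC * (1 - F[k])) * qk  # ref copies from cluster k
            new_q[:, k] = (ak.sum(axis=1) + bk.sum(axis=1)) / copies
            asum = ak.sum(axis=0)
            new_F[k] = asum / np.maximum(asum + bk.sum(axis=0), eps)
        q = new_q / new_q.sum(axis=1, keepdims=True)
        F = np.clip(new_F, eps, 1 - eps)
    return q, F, np.asarray(trace), converged


def admixture_em(
    G: np.ndarray,
    K: int = 2,
    seed: int | None = None,
    tol: float = 1e-6,
    max_iter: int = 2000,
    n_restarts: int = 4,
) -> AncestryEstimate:
    """Maximum-likelihood admixture proportions by EM.

    Under the admixture model each genotype is Binomial(2, sum_k q_ik
    f_kj): individual i draws each allele copy from cluster k with
    probability q_ik, where the cluster's alt-allele frequency is f_kj.
    Plain EM on this binomial likelihood is monotone in log-likelihood and
    shares its stationary points with the block-relaxation solvers used by
    dedicated ancestry tools.  Multiple seeded restarts guard against
    local optima; the best likelihood is kept.  For determinism, clusters
    are relabelled so that cluster 0 is the majority ancestry of the first
    individual.
    """
    G = np.asarray(G)
    n, L = G.shape
    if n < K:
        raise ValueError(f"need at least K={K} individuals, got {n}")
    obs = G >= 0
    rng = np.random.default_rng(seed)
    best = None
    for _ in range(max(1, n_restarts)):
        q, F, trace, converged = _em_once(G, obs, K, rng, tol, max_iter)
        if best is None or trace[-1] > best[2][-1]:
            best = (q, F, trace, converged)
    q, F, trace, converged = best
    order = np.argsort(-q[0])  # anchor labels to the first individual
    q, F = q[:, order], F[order]
    return AncestryEstimate(
        q=q,
        cluster_frequencies=F,
        log_likelihood=float(trace[-1]),
        log_likelihood_trace=trace,
        converged=converged,
        n_iterations=len(trace),
    )


# ---------------------------------------------------------------------------
# Genotype PCA
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GenotypePCAResult:
    scores: np.ndarray  # (n_samples, n_components)
    percent_variance: np.ndarray
    n_loci_used: int


def genotype_pca(G: np.ndarray) -> GenotypePCAResult:
    """PCA of a genotype matrix with Patterson normalisation.

    Missing genotypes are mean-imputed per locus; each locus is centered
    by twice its sample allele frequency and scaled by
    sqrt(p(1-p)) — the binomial standard deviation, which equalises
    per-locus drift variance.  Monomorphic loci are dropped.
    """
    G = np.asarray(G, dtype=float)
    n = G.shape[0]
    if n < 2:
        raise ValueError("need at least two samples")
    obs = G >= 0
    with np.errstate(invalid="ignore"):
        locus_mean = np.where(obs, G, 0).sum(axis=0) / obs.sum(axis=0)
    X = np.where(obs, G, locus_mean)
    p = locus_mean / 2.0
    poly = (p > 0) & (p < 1) & (X.std(axis=0) > 0)
    if not poly.any():
        raise ValueError("all loci monomorphic")
    X = (X[:, poly] - 2 * p[poly]) / np.sqrt(p[poly] * (1 - p[poly]))
    X = X - X.mean(axis=0)
    U, s, _ = np.linalg.svd(X, full_matrices=False)
    keep = s > s[0] * 1e-12
    U, s = U[:, keep], s[keep]
    pve = 100.0 * s**2 / (s**2).sum()
    return GenotypePCAResult(scores=U * s, percent_variance=pve, n_loci_used=int(poly.sum()))
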