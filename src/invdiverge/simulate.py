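"""Synthetic data generators for every stage of the pipeline.

The generators emulate the statistical structure the analysis assumes —
not real mosquitoes: ITS2 amplicons carry the documented diagnostic
genotype classes verbatim (double peaks as IUPAC letters); karyotype
samples are drawn from per-group arrangement frequencies with an optional
inbreeding-style departure from Hardy-Weinberg; and the two-population
genotype matrix follows the Balding-Nichols model, in which population
allele frequencies are Beta-distributed around an ancestral frequency
with variance p(1-p)Fst, so a target Fst profile can be planted along
the genome (autosomal baseline, an elevated X "inversion" region,
elevated centromeres) and later recovered by the estimators.

All generators are deterministic given (spec, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .its2 import DEFAULT_FORWARD_PRIMER, DEFAULT_REVERSE_PRIMER, DEFAULT_SITES
from .iupac import reverse_complement
from .karyo import ALLELE_SETS, ARMS, KaryotypeRecord

__all__ = [
    "ITS2SimSpec",
    "KaryoGroupSpec",
    "KaryoSimSpec",
    "GenomeSimSpec",
    "GENOTYPE_CLASSES",
    "DEFAULT_KARYO_GROUPS",
    "synthetic_reference",
    "simulate_its2",
    "simulate_karyotypes",
    "simulate_genotypes",
    "write_fasta",
    "write_vcf",
]

AMPLICON_LENGTH = 613

#: Observed six-site genotype classes (positions 150, 211, 215, 217, 412,
#: 432) with their within-species sampling weights: one messeae class, the
#: three daciae variants in their observed 115:2:2 proportions, and the
#: all-double-peak hybrid class.
GENOTYPE_CLASSES: dict[str, list[tuple[tuple[str, ...], float]]] = {
    "messeae": [(("M", "T", "T", "C", "G", "G"), 1.0)],
    "daciae": [
        (("C", "W", "W", "Y", "A", "C"), 115 / 119),
        (("C", "W", "W", "T", "A", "C"), 2 / 119),
        (("M", "W", "W", "Y", "A", "C"), 2 / 119),
    ],
    "hybrid": [(("M", "W", "W", "Y", "R", "S"), 1.0)],
}

_SITE_POSITIONS = tuple(s.position for s in DEFAULT_SITES)


def synthetic_reference(seed: int = 20_200_205) -> str:
    """Synthetic 613-bp stand-in for the ITS2 reference record.

    A random GC-balanced amplicon whose first/last bases are the two
    primer footprints (forward primer verbatim; reverse-complemented
    reverse primer at the 3' end) and whose six diagnostic positions carry
    the reference-record bases C, T, T, C, G, G.  It is a synthetic
    sequence, not the deposited GenBank record; coordinates are 1-based
    within the amplicon so the diagnostic positions keep their published
    numbering.
    """
    rng = np.random.default_rng(seed)
    fwd = DEFAULT_FORWARD_PRIMER
    rev_site = reverse_complement(DEFAULT_REVERSE_PRIMER)
    body_len = AMPLICON_LENGTH - len(fwd) - len(rev_site)
    body = rng.choice(list("ACGT"), size=body_len)
    seq = list(fwd) + list(body) + list(rev_site)
    for pos, base in zip(_SITE_POSITIONS, "CTTCGG"):
        seq[pos - 1] = base
    return "".join(seq)


@dataclass(frozen=True)
class ITS2SimSpec:
    """Sample sizes, genotype-class mixture and error rate for ITS2 reads."""

    n_messeae: int = 160
    n_daciae: int = 119
    n_hybrid: int = 1
    error_rate: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if min(self.n_messeae, self.n_daciae, self.n_hybrid) < 0:
            raise ValueError("counts must be >= 0")
        if not 0 <= self.error_rate <= 0.05:
            raise ValueError("error rate must be in [0, 0.05]")


def simulate_its2(
    spec: ITS2SimSpec, reference: str | None = None
) -> tuple[list[tuple[str, str]], pd.DataFrame]:
    """Generate FASTA-ready ITS2 records plus a truth table.

    Each record is the reference with one species' diagnostic genotype
    planted verbatim at the six sites (ambiguity letters included) and
    random substitution errors sprinkled elsewhere at ``error_rate``.
    Diagnostic sites are protected by construction, so the intended
    genotype survives any error rate.
    """
    if reference is None:
        reference = synthetic_reference()
    rng = np.random.default_rng(spec.seed)
    protected = {p - 1 for p in _SITE_POSITIONS}
    bases = np.array(list("ACGT"))

    records: list[tuple[str, str]] = []
    truth_rows = []
    plan = (
        [("messeae", spec.n_messeae), ("daciae", spec.n_daciae), ("hybrid", spec.n_hybrid)]
    )
    counter = 0
    for label, count in plan:
        classes = GENOTYPE_CLASSES[label]
        weights = np.array([w for _, w in classes])
        weights = weights / weights.sum()
        for _ in range(count):
            counter += 1
            genotype = classes[rng.choice(len(classes), p=weights)][0]
            seq = list(reference)
            for pos, base in zip(_SITE_POSITIONS, genotype):
                seq[pos - 1] = base
            if spec.error_rate > 0:
                hits = np.flatnonzero(rng.random(len(seq)) < spec.error_rate)
                for i in hits:
                    if i in protected:
                        continue
                    seq[i] = rng.choice(bases[bases != seq[i]])
            rec_id = f"SIM{counter:04d}"
            records.append((rec_id, "".join(seq)))
            truth_rows.append(
                {"id": rec_id, "label": label, "genotype": "".join(genotype)}
            )
    return records, pd.DataFrame(truth_rows)


def write_fasta(records: list[tuple[str, str]], path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in records:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# Karyotypes
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class KaryoGroupSpec:
    """One population x species sample: size, sex ratio and per-arm
    allele frequencies, with an optional per-arm Fis."""

    population: str
    species: str
    n: int
    allele_freqs: dict[str, dict[int, float]]
    fis: dict[str, float] = field(default_factory=dict)
    female_fraction: float = 0.5

    def __post_init__(self):
        if self.n < 0:
            raise ValueError("n must be >= 0")
        if not 0 <= self.female_fraction <= 1:
            raise ValueError("female_fraction must be in [0, 1]")
        for arm, freqs in self.allele_freqs.items():
            if arm not in ALLELE_SETS:
                raise ValueError(f"unknown arm {arm}")
            bad = set(freqs) - ALLELE_SETS[arm]
            if bad:
                raise ValueError(f"alleles {sorted(bad)} not allowed on {arm}")
            if abs(sum(freqs.values()) - 1.0) > 1e-9:
                raise ValueError(f"frequencies on {arm} must sum to 1")
        for arm, f in self.fis.items():
            if not -1 <= f <= 1:
                raise ValueError("Fis must be in [-1, 1]")


@dataclass(frozen=True)
class KaryoSimSpec:
    groups: tuple[KaryoGroupSpec, ...]
    seed: int = 0


# Frequency presets for the six population x species samples.  Shapes
# follow the study system qualitatively: X1 effectively fixed in messeae
# (with the rare X4 variant), X0/X1 near-equal in daciae; autosomal
# inverted variants common in messeae, rare in daciae; 3L1 only in
# messeae; 2R4 a rare daciae variant in one population.  Sample sizes are
# the per-population species counts of the ITS2 survey.
def _mg(pop, n, x4=0.03):
    return KaryoGroupSpec(
        population=pop,
        species="messeae",
        n=n,
        allele_freqs={
            "X": {1: 1 - x4, 4: x4},
            "2R": {0: 0.45, 1: 0.55},
            "3R": {0: 0.60, 1: 0.40},
            "3L": {0: 0.95, 1: 0.05},
        },
    )


def _dg(pop, n, r4=0.0):
    return KaryoGroupSpec(
        population=pop,
        species="daciae",
        n=n,
        allele_freqs={
            "X": {0: 0.5, 1: 0.5},
            "2R": {0: 0.85 - r4, 1: 0.15, 4: r4} if r4 else {0: 0.85, 1: 0.15},
            "3R": {0: 0.90, 1: 0.10},
            "3L": {0: 1.0},
        },
    )


DEFAULT_KARYO_GROUPS: tuple[KaryoGroupSpec, ...] = (
    _mg("Novokosino", 73),
    _dg("Novokosino", 26),
    _mg("Noginsk", 63),
    _dg("Noginsk", 31),
    _mg("Yegoryevsk", 24),
    _dg("Yegoryevsk", 62, r4=0.02),
)


def _genotype_distribution(freqs: dict[int, float], fis: float):
    """Unordered diploid genotype distribution with inbreeding coefficient.

    P(aa) = p_a^2 + f p_a (1 - p_a);  P(ab) = 2 p_a p_b (1 - f).
    Validity of all probabilities is checked (strong heterozygote excess
    can be infeasible for skewed frequencies).
    """
    alleles = sorted(freqs)
    genos, probs = [], []
    for i, a in enumerate(alleles):
        pa = freqs[a]
        for b in alleles[i:]:
            if a == b:
                genos.append((a, a))
                probs.append(pa * pa + fis * pa * (1 - pa))
            else:
                genos.append((a, b))
                probs.append(2 * pa * freqs[b] * (1 - fis))
    probs = np.array(probs)
    if (probs < -1e-12).any():
        raise ValueError(f"Fis={fis} infeasible for frequencies {freqs}")
    probs = np.clip(probs, 0, None)
    return genos, probs / probs.sum()


def simulate_karyotypes(spec: KaryoSimSpec) -> list[KaryotypeRecord]:
    """Draw karyotype records for every group in the spec.

    Females are diploid everywhere; males carry a single X allele drawn
    from the allele frequencies (so the hemizygous X never shows Fis).
    """
    rng = np.random.default_rng(spec.seed)
    records = []
    counter = 0
    for g in spec.groups:
        for _ in range(g.n):
            counter += 1
            sex = "F" if rng.random() < g.female_fraction else "M"
            genotypes: dict[str, tuple[int, ...] | None] = {}
            for arm in ARMS:
                freqs = g.allele_freqs.get(arm)
                if freqs is None:
                    genotypes[arm] = None
                    continue
                alleles = sorted(freqs)
                p = np.array([freqs[a] for a in alleles])
                if arm == "X" and sex == "M":
                    genotypes[arm] = (alleles[rng.choice(len(alleles), p=p)],)
                else:
                    genos, probs = _genotype_distribution(freqs, g.fis.get(arm, 0.0))
                    genotypes[arm] = genos[rng.choice(len(genos), p=probs)]
            records.append(
                KaryotypeRecord(f"SIM{counter:04d}", g.population, g.species, sex, genotypes)
            )
    return records


# ---------------------------------------------------------------------------
# Genomes (Balding-Nichols two-population model)
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GenomeSimSpec:
    """Two-population genotype simulation with a divergence profile.

    Chromosome lengths are synthetic (scaled so that 10-kb thinning of the
    default SNV density leaves roughly 45k SNVs genome-wide).  The
    divergence profile plants a baseline Fst on the autosomes, a high-Fst
    "inversion" interval in the middle half of the X, and elevated
    centromeric intervals at the right end of each autosome.  A fraction
    of sites/genotypes is written with low QUAL/GQ, and a fraction as
    triallelic, so the filtering stage has real work to do.
    """

    chromosomes: dict[str, int] = field(
        default_factory=lambda: {"X": 150_000_000, "2": 330_000_000, "3": 270_000_000}
    )
    snv_spacing_bp: int = 5_000  # mean spacing before thinning
    baseline_fst: float = 0.027
    x_region_fst: float = 0.331
    x_region: tuple[float, float] = (0.25, 0.75)  # fraction of X length
    centromere_fst: float = 0.15
    centromere_fraction: float = 0.05  # right end of each autosome
    n_per_population: int = 5
    admixed_q: tuple[float, ...] = ()  # ancestry fraction of extra individuals
    ancestral_freq_range: tuple[float, float] = (0.05, 0.95)
    scaffolds_per_chromosome: int = 4
    low_qual_fraction: float = 0.02
    low_gq_fraction: float = 0.01
    triallelic_fraction: float = 0.01
    seed: int = 0

    def __post_init__(self):
        for f in (self.baseline_fst, self.x_region_fst, self.centromere_fst):
            if not 0 <= f < 1:
                raise ValueError("Fst parameters must be in [0, 1)")
        if not 0 <= self.x_region[0] < self.x_region[1] <= 1:
            raise ValueError("x_region must be an increasing fraction pair in [0, 1]")
        for q in self.admixed_q:
            if not 0 <= q <= 1:
                raise ValueError("admixed q must be in [0, 1]")


def _target_fst(spec: GenomeSimSpec, chrom: str, pos: np.ndarray) -> np.ndarray:
    L = spec.chromosomes[chrom]
    fst = np.full(pos.shape, spec.baseline_fst)
    if chrom == "X":
        lo, hi = (int(spec.x_region[0] * L), int(spec.x_region[1] * L))
        fst[(pos > lo) & (pos <= hi)] = spec.x_region_fst
    else:
        fst[pos > int((1 - spec.centromere_fraction) * L)] = spec.centromere_fst
    return fst


def _region_label(spec: GenomeSimSpec, chrom: str, pos: np.ndarray) -> np.ndarray:
    L = spec.chromosomes[chrom]
    lab = np.full(pos.shape, "baseline", dtype=object)
    if chrom == "X":
        lo, hi = (int(spec.x_region[0] * L), int(spec.x_region[1] * L))
        lab[(pos > lo) & (pos <= hi)] = "x_region"
    else:
        lab[pos > int((1 - spec.centromere_fraction) * L)] = "centromere"
    return lab


def simulate_genotypes(spec: GenomeSimSpec):
    """Simulate the two-population SNV panel.

    Returns ``(samples, records, chrom_map, truth)`` where ``records`` are
    scaffold-coordinate :class:`~invdiverge.genome.VariantRecord` objects
    (sorted per scaffold, ready for filtering), ``chrom_map`` lifts them
    back to chromosomes, and ``truth`` is a per-SNV DataFrame with the
    generating parameters (chromosome position, target Fst, region label,
    population frequencies).

    Model: per SNV an ancestral frequency p ~ U(0.05, 0.95); each
    population's frequency ~ Beta(p(1-F)/F, (1-p)(1-F)/F) so that
    Var = F p(1-p) (Balding-Nichols); genotypes ~ Binomial(2, p_pop).
    Admixed individuals draw from the q-weighted frequency
    q p1 + (1-q) p2.
    """
    from .genome import ChromosomeMap, ContigPlacement, VariantRecord

    rng = np.random.default_rng(spec.seed)
    nA = nB = spec.n_per_population
    samples = (
        [f"mes{i+1}" for i in range(nA)]
        + [f"dac{i+1}" for i in range(nB)]
        + [f"adm{i+1}" for i in range(len(spec.admixed_q))]
    )

    # Scaffold layout: each chromosome cut into equal scaffolds, every
    # second one placed in reverse orientation.
    placements: dict[str, ContigPlacement] = {}
    for chrom, L in spec.chromosomes.items():
        k = spec.scaffolds_per_chromosome
        bounds = np.linspace(0, L, k + 1, dtype=int)
        for j in range(k):
            name = f"scf_{chrom}_{j+1}"
            length = int(bounds[j + 1] - bounds[j])
            orient = "+" if j % 2 == 0 else "-"
            placements[name] = ContigPlacement(chrom, int(bounds[j]), orient, length)
    cmap = ChromosomeMap(placements)

    records: list[VariantRecord] = []
    truth_rows = []
    for chrom, L in spec.chromosomes.items():
        # SNV positions by exponential waiting times (mean = snv_spacing_bp)
        n_draw = int(L / spec.snv_spacing_bp * 1.3) + 10
        gaps = rng.exponential(spec.snv_spacing_bp, size=n_draw)
        pos = np.unique(np.cumsum(gaps).astype(int) + 1)
        pos = pos[pos <= L]
        m = pos.size
        fst = _target_fst(spec, chrom, pos)
        region = _region_label(spec, chrom, pos)

        p_anc = rng.uniform(*spec.ancestral_freq_range, size=m)
        with np.errstate(divide="ignore"):
            alpha = p_anc * (1 - fst) / np.where(fst > 0, fst, 1)
            beta = (1 - p_anc) * (1 - fst) / np.where(fst > 0, fst, 1)
        pA = np.where(fst > 0, rng.beta(np.maximum(alpha, 1e-12), np.maximum(beta, 1e-12)), p_anc)
        pB = np.where(fst > 0, rng.beta(np.maximum(alpha, 1e-12), np.maximum(beta, 1e-12)), p_anc)

        GA = rng.binomial(2, pA[:, None], size=(m, nA))
        GB = rng.binomial(2, pB[:, None], size=(m, nB))
        blocks = [GA, GB]
        for q in spec.admixed_q:
            pq = q * pA + (1 - q) * pB
            blocks.append(rng.binomial(2, pq[:, None], size=(m, 1)))
        G = np.concatenate(blocks, axis=1).astype(np.int8)

        qual = 400.0 + rng.exponential(300.0, size=m)
        low_q = rng.random(m) < spec.low_qual_fraction
        qual[low_q] = rng.uniform(50, 399.9, size=int(low_q.sum()))
        gq = rng.integers(30, 99, size=G.shape).astype(float)
        low_gq = rng.random(G.shape) < spec.low_gq_fraction
        gq[low_gq] = rng.integers(0, 10, size=int(low_gq.sum()))
        tri = rng.random(m) < spec.triallelic_fraction

        base_choices = np.array(list("ACGT"))
        refs = base_choices[rng.integers(0, 4, size=m)]
        for i in range(m):
            ref = refs[i]
            others = [b for b in "ACGT" if b != ref]
            alts = tuple(others[:2]) if tri[i] else (others[0],)
            chrom_pos = int(pos[i])
            # back-convert to scaffold coordinates
            for name, pl in placements.items():
                if pl.chromosome == chrom and pl.offset < chrom_pos <= pl.offset + pl.length:
                    if pl.orientation == "+":
                        scf_pos = chrom_pos - pl.offset
                    else:
                        scf_pos = pl.length - (chrom_pos - pl.offset) + 1
                    break
            records.append(
                VariantRecord(
                    contig=name,
                    position=scf_pos,
                    ref=ref,
                    alts=alts,
                    quality=float(qual[i]),
                    genotypes=G[i],
                    genotype_quality=gq[i],
                )
            )
            truth_rows.append(
                {
                    "chromosome": chrom,
                    "chrom_position": chrom_pos,
                    "contig": name,
                    "position": scf_pos,
                    "target_fst": float(fst[i]),
                    "region": region[i],
                    "pA": float(pA[i]),
                    "pB": float(pB[i]),
                }
            )

    records.sort(key=lambda r: (r.contig, r.position))
    truth = pd.DataFrame(truth_rows).sort_values(["contig", "position"]).reset_index(drop=True)
    return samples, records, cmap, truth


def write_vcf(samples, records, path) -> None:
    """Write records as a minimal plain-text VCF (GT:GQ per sample)."""
    contigs = sorted({r.contig for r in records})
    gt_strings = {0: "0/0", 1: "0/1", 2: "1/1", -1: "./."}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="Genotype quality">\n')
        for c in contigs:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(samples) + "\n")
        for r in records:
            cells = [
                f"{gt_strings[int(g)]}:{int(q)}"
                for g, q in zip(r.genotypes, r.genotype_quality)
            ]
            fh.write(
                f"{r.contig}\t{r.position}\t.\t{r.ref}\t{','.join(r.alts)}\t"
                f"{r.quality:.1f}\t.\t.\tGT:GQ\t" + "\t".join(cells) + "\n"
            )


def write_chromosome_map(cmap, path) -> None:
    rows = [
        {
            "contig": name,
            "chromosome": p.chromosome,
            "offset": p.offset,
            "orientation": p.orientation,
            "length": p.length,
        }
        for name, p in sorted(cmap.placements.items())
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
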