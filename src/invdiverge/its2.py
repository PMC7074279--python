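"""Species and hybrid diagnosis from ITS2 amplicon sequences.

*Anopheles messeae* and *An. daciae* are cryptic sibling species separated
by six diagnostic nucleotide positions in the rDNA internal transcribed
spacer 2 (numbered against the reference record of the *An. messeae* ITS2).
Because rDNA is multicopy, intragenomic variants appear in Sanger traces as
double peaks, encoded as IUPAC ambiguity letters.  The two substitutions at
positions 412 and 432 (G,G in *An. messeae*; A,C in *An. daciae*) are fixed
between the species and carry the species call; a specimen showing double
peaks at *both* of them (R at 412 and S at 432) is diagnosed as an
interspecific hybrid.  The four remaining positions (150, 211, 215, 217)
are secondary: discordance there is reported but never overrides the
primary sites.

The module works on base-called sequences (FASTA with ambiguity codes),
not chromatograms: an in-silico PCR step excises the amplicon delimited by
the published universal primer pair, a semiglobal alignment anchors each
query to the reference coordinate system, and the six diagnostic bases are
read off through the resulting coordinate map.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from decimal import Decimal, ROUND_HALF_UP

import pandas as pd
from Bio import Align, SeqIO
from Bio.Align import substitution_matrices

from .iupac import BASE_SETS, base_set, bases_match, is_double_peak, reverse_complement

__all__ = [
    "DEFAULT_FORWARD_PRIMER",
    "DEFAULT_REVERSE_PRIMER",
    "DEFAULT_PRIMERS",
    "DEFAULT_SITES",
    "PrimerPair",
    "DiagnosticSite",
    "Amplicon",
    "CoordinateMap",
    "SpeciesCall",
    "NoAmpliconError",
    "UnalignableQueryError",
    "UntypeableSpecimenError",
    "in_silico_pcr",
    "anchor_to_reference",
    "extract_diagnostic_genotype",
    "call_species",
    "classify_sequence",
    "species_composition",
    "read_fasta",
]

# Published universal ITS2 primer pair (forward 22-mer, reverse 20-mer);
# against the reference record they delimit a 613-bp amplicon.
DEFAULT_FORWARD_PRIMER = "ATCACTCGGCTCTCGTGGATCG"
DEFAULT_REVERSE_PRIMER = "ATGCTTAAATTTAGGGGGTA"

#: Minimum primer overlap accepted when a template starts/ends inside a
#: primer footprint (deposited records are often trimmed into the primer).
MIN_TRUNCATED_PRIMER_OVERLAP = 15


class NoAmpliconError(ValueError):
    """In-silico PCR found no amplicon; ``.primer`` names the missing site."""

    def __init__(self, primer: str):
        self.primer = primer
        super().__init__(f"no amplicon: {primer}")


class UnalignableQueryError(ValueError):
    """Query/reference alignment identity below the acceptance threshold."""


class UntypeableSpecimenError(ValueError):
    """Both primary diagnostic sites unreadable for a specimen."""


@dataclass(frozen=True)
class PrimerPair:
    """A PCR primer pair, both given 5'->3'."""

    forward: str = DEFAULT_FORWARD_PRIMER
    reverse: str = DEFAULT_REVERSE_PRIMER
    max_mismatch: int = 0

    def __post_init__(self):
        if not self.forward or not self.reverse:
            raise ValueError("primers must be non-empty")
        if self.max_mismatch < 0:
            raise ValueError("max_mismatch must be >= 0")


DEFAULT_PRIMERS = PrimerPair()


@dataclass(frozen=True)
class DiagnosticSite:
    """One diagnostic ITS2 position in reference (1-based) numbering."""

    position: int
    messeae_allele: str
    daciae_allele: str
    reliability: str  # "primary" | "secondary"


#: The six diagnostic sites.  412/432 are the fixed, species-defining
#: substitutions; the others vary within *An. daciae* (tolerated variants
#: are handled in :func:`call_species`).
DEFAULT_SITES: tuple[DiagnosticSite, ...] = (
    DiagnosticSite(150, "M", "C", "secondary"),
    DiagnosticSite(211, "T", "W", "secondary"),
    DiagnosticSite(215, "T", "W", "secondary"),
    DiagnosticSite(217, "C", "Y", "secondary"),
    DiagnosticSite(412, "G", "A", "primary"),
    DiagnosticSite(432, "G", "C", "primary"),
)

PRIMARY_POSITIONS = (412, 432)


@dataclass(frozen=True)
class Amplicon:
    """Result of in-silico PCR: the excised subsequence and its span."""

    sequence: str
    start: int  # 0-based inclusive, on the template
    end: int  # 0-based exclusive

    @property
    def length(self) -> int:
        return self.end - self.start


def _mismatches(site: str, primer: str) -> int:
    return sum(not bases_match(a, b) for a, b in zip(site, primer))


def _find_primer(template: str, primer: str, max_mismatch: int, *, start_at: int = 0):
    """Leftmost (start, end) of a primer site at/after ``start_at``.

    Accepts a site truncated by the template start (primer suffix) or the
    template end (primer prefix) when the overlap is at least
    ``MIN_TRUNCATED_PRIMER_OVERLAP`` nucleotides.
    """
    m = len(primer)
    n = len(template)
    # Truncated at the template start: the template begins inside the primer.
    if start_at == 0:
        for ov in range(m - 1, MIN_TRUNCATED_PRIMER_OVERLAP - 1, -1):
            if ov <= n and _mismatches(template[:ov], primer[-ov:]) <= max_mismatch:
                return 0, ov
    # Full-length site anywhere in range.
    for i in range(start_at, n - m + 1):
        if _mismatches(template[i : i + m], primer) <= max_mismatch:
            return i, i + m
    # Truncated at the template end.
    for ov in range(m - 1, MIN_TRUNCATED_PRIMER_OVERLAP - 1, -1):
        i = n - ov
        if i >= start_at and _mismatches(template[i:], primer[:ov]) <= max_mismatch:
            return i, n
    return None


def in_silico_pcr(template: str, primers: PrimerPair = DEFAULT_PRIMERS) -> Amplicon:
    """Excise the amplicon delimited by a primer pair from a template.

    The forward primer is matched on the given strand, the reverse primer
    as its reverse complement downstream of the forward site; the amplicon
    spans both primer footprints inclusively (so its length is what a gel
    would show).  Matching is IUPAC-aware with at most
    ``primers.max_mismatch`` mismatching positions per primer.

    Raises
    ------
    NoAmpliconError
        If either primer has no acceptable site, or the reverse site does
        not lie downstream of the forward site.
    """
    template = template.upper()
    fwd = _find_primer(template, primers.forward.upper(), primers.max_mismatch)
    if fwd is None:
        raise NoAmpliconError("forward")
    rev_site = reverse_complement(primers.reverse)
    rev = _find_primer(template, rev_site, primers.max_mismatch, start_at=fwd[1])
    if rev is None:
        raise NoAmpliconError("reverse")
    start, end = fwd[0], rev[1]
    return Amplicon(sequence=template[start:end], start=start, end=end)


# ---------------------------------------------------------------------------
# Anchoring to the reference coordinate system
# ---------------------------------------------------------------------------

_IUPAC_ALPHABET = "".join(BASE_SETS)


def _iupac_matrix(match: float = 1.0, mismatch: float = -1.0):
    """Substitution matrix scoring IUPAC set-intersection as a match."""
    mat = substitution_matrices.Array(_IUPAC_ALPHABET, dims=2)
    for a in _IUPAC_ALPHABET:
        for b in _IUPAC_ALPHABET:
            mat[a, b] = match if bases_match(a, b) else mismatch
    return mat


_ALIGNER = Align.PairwiseAligner()
_ALIGNER.substitution_matrix = _iupac_matrix()
_ALIGNER.open_gap_score = -2.0
_ALIGNER.extend_gap_score = -1.0
# Semiglobal: overhangs on either sequence are free.
try:
    _ALIGNER.end_insertion_score = 0.0
    _ALIGNER.end_deletion_score = 0.0
except AttributeError:  # older PairwiseAligner naming
    _ALIGNER.target_end_gap_score = 0.0
    _ALIGNER.query_end_gap_score = 0.0


@dataclass
class CoordinateMap:
    """Mapping between a (possibly reoriented) query and reference positions.

    ``oriented_query`` is the query in the orientation that aligned best
    (Sanger reads may be reverse-strand); ``query_to_ref[i]`` gives the
    1-based reference position of oriented-query index ``i``, or ``None``
    for insertions relative to the reference.
    """

    oriented_query: str
    reverse_complemented: bool
    query_to_ref: list[int | None]
    identity: float
    score: float
    _ref_to_query: dict[int, int] = field(default_factory=dict, repr=False)

    def __post_init__(self):
        if not self._ref_to_query:
            self._ref_to_query = {
                r: q for q, r in enumerate(self.query_to_ref) if r is not None
            }

    def query_index(self, ref_position: int) -> int | None:
        """Oriented-query index aligned to a 1-based reference position."""
        return self._ref_to_query.get(ref_position)

    def base_at(self, ref_position: int) -> str:
        """Query base (IUPAC letter) at a reference position, or ``N``."""
        i = self.query_index(ref_position)
        return "N" if i is None else self.oriented_query[i]


def _align_one(query: str, reference: str):
    aln = _ALIGNER.align(reference, query)[0]
    ref_blocks, q_blocks = aln.aligned
    q2r: list[int | None] = [None] * len(query)
    matched = columns = 0
    prev = None
    for (rs, re), (qs, qe) in zip(ref_blocks, q_blocks):
        if prev is not None:
            # internal gap columns (indels between aligned blocks) count
            # against identity; end overhangs do not
            columns += (rs - prev[0]) + (qs - prev[1])
        prev = (re, qe)
        for k in range(re - rs):
            q2r[qs + k] = rs + k + 1  # 1-based reference coordinate
            columns += 1
            if bases_match(query[qs + k], reference[rs + k]):
                matched += 1
    identity = matched / columns if columns else 0.0
    return q2r, identity, aln.score


def anchor_to_reference(query: str, reference: str) -> CoordinateMap:
    """Semiglobal-align a query to the reference and build a coordinate map.

    Both orientations of the query are tried and the higher-scoring one is
    kept.  IUPAC ambiguity codes score as matches against any member of
    their base set, so double peaks do not degrade the anchoring.

    Raises
    ------
    UnalignableQueryError
        If identity over aligned columns is below 70% in both orientations.
    """
    if not query or not reference:
        raise ValueError("query and reference must be non-empty")
    query = query.upper()
    reference = reference.upper()
    fwd = _align_one(query, reference)
    rc_query = reverse_complement(query)
    rev = _align_one(rc_query, reference)
    use_rc = rev[2] > fwd[2]
    q2r, identity, score = rev if use_rc else fwd
    if identity < 0.70:
        raise UnalignableQueryError(
            f"unalignable query: identity {identity:.2f} < 0.70"
        )
    return CoordinateMap(
        oriented_query=rc_query if use_rc else query,
        reverse_complemented=use_rc,
        query_to_ref=q2r,
        identity=identity,
        score=score,
    )


def extract_diagnostic_genotype(
    coord_map: CoordinateMap,
    sites: tuple[DiagnosticSite, ...] = DEFAULT_SITES,
) -> tuple[str, ...]:
    """Read the query base at each diagnostic reference position.

    Unreadable sites (deleted or outside the aligned span) are reported as
    ``N``.  If both primary sites are unreadable the specimen cannot be
    typed at all.
    """
    genotype = tuple(coord_map.base_at(s.position) for s in sites)
    primary = [g for s, g in zip(sites, genotype) if s.reliability == "primary"]
    if primary and all(g == "N" for g in primary):
        raise UntypeableSpecimenError(
            "untypeable specimen: both primary sites unreadable"
        )
    return genotype


# ---------------------------------------------------------------------------
# Species calling
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SpeciesCall:
    """Outcome of the six-site diagnosis for one specimen."""

    label: str  # messeae | daciae | hybrid | other
    site_genotype: tuple[str, ...]
    confidence_note: str = ""


# Secondary-site expectations per label (sets of tolerated IUPAC letters).
_SECONDARY_EXPECTED = {
    "messeae": {150: {"M"}, 211: {"T"}, 215: {"T"}, 217: {"C"}},
    # Observed daciae variation: C or M at 150, W throughout 211/215, Y or T at 217.
    "daciae": {150: {"C", "M"}, 211: {"W"}, 215: {"W"}, 217: {"Y", "T"}},
    "hybrid": {150: {"M"}, 211: {"W"}, 215: {"W"}, 217: {"Y"}},
}


def _is_double_peak_of(code: str, pair: set[str]) -> bool:
    return is_double_peak(code) and base_set(code) == frozenset(pair)


def call_species(
    genotype: tuple[str, ...],
    sites: tuple[DiagnosticSite, ...] = DEFAULT_SITES,
) -> SpeciesCall:
    """Diagnose species from a six-site genotype.

    The decision rests entirely on the primary sites 412/432: (G,G) is
    *An. messeae*, (A,C) is *An. daciae*, and double peaks at both
    (A+G = R at 412 and C+G = S at 432) indicate a hybrid.  Any other
    combination — including a single-site double peak or a
    messeae-like/daciae-like conflict — is ``other``.  Secondary sites are
    compared against the per-label expectations and discordances listed in
    the note, but they never change the label.
    """
    by_pos = {s.position: g.upper() for s, g in zip(sites, genotype)}
    g412, g432 = by_pos[412], by_pos[432]

    if g412 == "G" and g432 == "G":
        label = "messeae"
    elif g412 == "A" and g432 == "C":
        label = "daciae"
    elif _is_double_peak_of(g412, {"A", "G"}) and _is_double_peak_of(g432, {"C", "G"}):
        label = "hybrid"
    else:
        label = "other"

    notes: list[str] = []
    if label == "other":
        if "N" in (g412, g432):
            notes.append("primary site unreadable")
        else:
            notes.append(f"primary-site conflict: 412={g412}, 432={g432}")
    else:
        expected = _SECONDARY_EXPECTED[label]
        for pos, allowed in expected.items():
            g = by_pos.get(pos, "N")
            if g not in allowed:
                notes.append(f"secondary-site discordance: {pos}={g} (expected {'/'.join(sorted(allowed))})")
    return SpeciesCall(label=label, site_genotype=tuple(by_pos[s.position] for s in sites), confidence_note="; ".join(notes))


def classify_sequence(
    sequence: str,
    reference: str,
    primers: PrimerPair = DEFAULT_PRIMERS,
    sites: tuple[DiagnosticSite, ...] = DEFAULT_SITES,
    *,
    run_pcr: bool = False,
) -> SpeciesCall:
    """End-to-end diagnosis of one sequence: (PCR) -> anchor -> extract -> call."""
    if run_pcr:
        sequence = in_silico_pcr(sequence, primers).sequence
    cmap = anchor_to_reference(sequence, reference)
    genotype = extract_diagnostic_genotype(cmap, sites)
    return call_species(genotype, sites)


# ---------------------------------------------------------------------------
# Composition tables
# ---------------------------------------------------------------------------

COMPOSITION_CATEGORIES = ("messeae", "daciae", "hybrid", "beklemishevi", "maculipennis", "other")


def round_half_up(x: float, decimals: int = 1) -> float:
    """Round half away from zero (matches hand-rounded percentages)."""
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def species_composition(
    labelled: list[tuple[str, str]],
    external: dict[str, dict[str, int]] | None = None,
) -> pd.DataFrame:
    """Per-population species composition (counts and percentages).

    Parameters
    ----------
    labelled
        ``(population, category)`` pairs for sequence-diagnosed specimens.
    external
        Extra per-population category counts for specimens identified by
        other means (karyotype / amplicon length), e.g. congeners that the
        six-site assay does not type.

    Returns
    -------
    DataFrame indexed by population with ``n_<cat>`` count columns,
    ``pct_<cat>`` percentage columns (one decimal, half away from zero) and
    a ``total`` column; the denominator of every percentage is the
    population's total specimen count across all categories.
    """
    counts: dict[str, dict[str, int]] = {}
    for pop, cat in labelled:
        counts.setdefault(pop, {c: 0 for c in COMPOSITION_CATEGORIES})
        if cat not in COMPOSITION_CATEGORIES:
            raise ValueError(f"unknown category {cat!r}")
        counts[pop][cat] += 1
    for pop, extra in (external or {}).items():
        counts.setdefault(pop, {c: 0 for c in COMPOSITION_CATEGORIES})
        for cat, n in extra.items():
            if cat not in COMPOSITION_CATEGORIES:
                raise ValueError(f"unknown category {cat!r}")
            if n < 0:
                raise ValueError("external counts must be nonnegative")
            counts[pop][cat] += n

    rows = []
    for pop in sorted(counts):
        c = counts[pop]
        total = sum(c.values())
        row: dict[str, object] = {"population": pop, "total": total}
        for cat in COMPOSITION_CATEGORIES:
            row[f"n_{cat}"] = c[cat]
            row[f"pct_{cat}"] = (
                round_half_up(100.0 * c[cat] / total) if total else float("nan")
            )
        if total == 0:
            row["note"] = "empty population"
        rows.append(row)
    return pd.DataFrame(rows).set_index("population")


def read_fasta(source) -> list[tuple[str, str]]:
    """Read a (multi-)FASTA path or handle as ``(id, sequence)`` pairs,
    ambiguity codes kept."""
    if isinstance(source, str) and "\n" in source:
        source = io.StringIO(source)
    return [(r.id, str(r.seq).upper()) for r in SeqIO.parse(source, "fasta")]
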