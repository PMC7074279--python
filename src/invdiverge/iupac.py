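"""IUPAC nucleotide ambiguity codes and base-set semantics.

Sanger base calling of a multicopy marker (here the rDNA ITS2) reports
intragenomic variants as "double peaks": a single chromatogram position
showing two bases at once, encoded by the IUPAC one-letter ambiguity
alphabet (W = A/T, Y = C/T, M = A/C, R = A/G, S = C/G, ...).  Throughout
this package a base is treated as the *set* of nucleotides it may
represent, and two bases match whenever their sets intersect.
"""

from __future__ import annotations

# Full one-letter code -> base-set table (the three-base codes and N are
# included so arbitrary Sanger calls are representable).
BASE_SETS: dict[str, frozenset[str]] = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "T": frozenset("T"),
    "R": frozenset("AG"),
    "Y": frozenset("CT"),
    "S": frozenset("CG"),
    "W": frozenset("AT"),
    "K": frozenset("GT"),
    "M": frozenset("AC"),
    "B": frozenset("CGT"),
    "D": frozenset("AGT"),
    "H": frozenset("ACT"),
    "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}

_COMPLEMENT = {
    "A": "T", "T": "A", "C": "G", "G": "C",
    "R": "Y", "Y": "R", "S": "S", "W": "W", "K": "M", "M": "K",
    "B": "V", "V": "B", "D": "H", "H": "D", "N": "N",
}

#: Codes representing exactly two bases, i.e. a Sanger double peak.
DOUBLE_PEAK_CODES = frozenset("RYSWKM")


def base_set(code: str) -> frozenset[str]:
    """Return the set of plain bases an IUPAC letter may represent."""
    try:
        return BASE_SETS[code.upper()]
    except KeyError:
        raise ValueError(f"not an IUPAC nucleotide code: {code!r}") from None


def bases_match(a: str, b: str) -> bool:
    """True if the base sets of two IUPAC letters intersect."""
    return not base_set(a).isdisjoint(base_set(b))


def is_double_peak(code: str) -> bool:
    """True for the six two-base ambiguity codes (chromatogram double peaks)."""
    return code.upper() in DOUBLE_PEAK_CODES


def reverse_complement(seq: str) -> str:
    """Reverse complement honouring ambiguity codes (e.g. R <-> Y)."""
    try:
        return "".join(_COMPLEMENT[c] for c in reversed(seq.upper()))
    except KeyError as exc:
        raise ValueError(f"cannot complement {exc.args[0]!r}") from None
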