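"""Canonical representation and enumeration of microsatellite repeat-unit classes.

A microsatellite locus is reported on duplex DNA, so a repeat unit, all of its
cyclic rotations, and all rotations of its reverse complement describe the same
locus: (AC)n, (CA)n and (GT)n are one class.  The canonical representative of a
class is the lexicographically smallest string (A < C < G < T) among those
candidates.  Only *primitive* units — units that are not a whole-number power of
a shorter unit — name a class of their own: an "ACAC" hit is a dinucleotide AC
locus, not a tetranucleotide one.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product

__all__ = [
    "InvalidAlphabetError",
    "Motif",
    "MotifClassSet",
    "at_richness",
    "canonical_motif",
    "enumerate_motif_classes",
    "is_primitive",
    "primitive_unit",
    "reverse_complement",
]

_COMPLEMENT = str.maketrans("ACGT", "TGCA")
_ALPHABET = frozenset("ACGT")

MAX_UNIT_LENGTH = 6


class InvalidAlphabetError(ValueError):
    """Raised when a motif contains characters outside {A, C, G, T}."""


def _validate(sequence: str) -> str:
    if not sequence:
        raise InvalidAlphabetError("motif must be a non-empty DNA string")
    seq = sequence.upper()
    if not _ALPHABET.issuperset(seq):
        bad = sorted(set(seq) - _ALPHABET)
        raise InvalidAlphabetError(f"non-ACGT characters in motif {sequence!r}: {bad}")
    return seq


def reverse_complement(sequence: str) -> str:
    """Watson–Crick reverse complement of a DNA string."""
    return _validate(sequence).translate(_COMPLEMENT)[::-1]


def _rotations(sequence: str) -> list[str]:
    return [sequence[i:] + sequence[:i] for i in range(len(sequence))]


def canonical_motif(sequence: str) -> str:
    """Canonical class representative of a repeat unit.

    The representative is the lexicographic minimum over all rotations of
    ``sequence`` and all rotations of its reverse complement, so that a unit
    and its duplex-strand equivalents map to a single name.  Idempotent, and
    invariant under reverse complementation.
    """
    seq = _validate(sequence)
    if len(seq) > MAX_UNIT_LENGTH:
        raise ValueError(f"unit length {len(seq)} exceeds {MAX_UNIT_LENGTH}")
    return min(_rotations(seq) + _rotations(reverse_complement(seq)))


def is_primitive(sequence: str) -> bool:
    """True unless the motif is a whole-number power of a shorter motif."""
    seq = _validate(sequence)
    n = len(seq)
    return not any(n % d == 0 and seq == seq[:d] * (n // d) for d in range(1, n))


def primitive_unit(sequence: str) -> str:
    """Shortest motif whose tandem power equals ``sequence`` ("ACAC" -> "AC")."""
    seq = _validate(sequence)
    n = len(seq)
    for d in range(1, n + 1):
        if n % d == 0 and seq == seq[:d] * (n // d):
            return seq[:d]
    raise AssertionError("unreachable")  # pragma: no cover


@dataclass(frozen=True)
class Motif:
    """A repeat unit together with its canonical class representative."""

    sequence: str
    canonical: str = field(init=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "canonical", canonical_motif(self.sequence))

    @property
    def unit_length(self) -> int:
        return len(self.sequence)


@dataclass
class MotifClassSet:
    """The complete set of canonical primitive motif classes of one unit length."""

    unit_length: int
    classes: list[str]
    counts_by_class: dict[str, int] | None = None

    @property
    def n_classes(self) -> int:
        return len(self.classes)

    def to_dict(self) -> dict:
        out = {
            "unit_length": self.unit_length,
            "n_classes": self.n_classes,
            "classes": list(self.classes),
        }
        if self.counts_by_class is not None:
            out["counts_by_class"] = dict(self.counts_by_class)
        return out


def enumerate_motif_classes(unit_length: int) -> MotifClassSet:
    """Enumerate all canonical classes of primitive motifs of a given length.

    Walks every string in {A,C,G,T}^k, drops non-primitive ones, and buckets
    the rest by canonical representative.  For k = 1..6 this yields
    2, 4, 10, 33, 102 and 350 classes; e.g. the four dinucleotide classes are
    AC, AG, AT and CG.
    """
    if not 1 <= unit_length <= MAX_UNIT_LENGTH:
        raise ValueError(
            f"unit_length must be in 1..{MAX_UNIT_LENGTH}, got {unit_length}"
        )
    seen: set[str] = set()
    for letters in product("ACGT", repeat=unit_length):
        seq = "".join(letters)
        if is_primitive(seq):
            seen.add(canonical_motif(seq))
    return MotifClassSet(unit_length=unit_length, classes=sorted(seen))


def at_richness(motif: str) -> tuple[int, str]:
    """Count of A/T bases in a unit and its composition category label.

    Returns ``(p, "[(A/T)_p, X_q]")`` where p is the number of A or T letters
    and q the number of remaining letters.  Genome surveys bin repeat classes
    by these categories; AT-rich classes (q <= 1) dominate most eukaryotic
    genomes.
    """
    seq = _validate(motif)
    p = sum(1 for c in seq if c in "AT")
    q = len(seq) - p
    return p, f"[(A/T)_{p}, X_{q}]"


def is_at_rich(motif: str) -> bool:
    """AT-rich: at most one base of the unit is G or C."""
    p, _ = at_richness(motif)
    return len(_validate(motif)) - p <= 1
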