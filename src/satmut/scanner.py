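"""Detection of short tandem repeats in DNA and genome composition summaries.

The scanner finds perfect and imperfect tandem arrays of 2–6 bp units with at
least three copies, using a deterministic seed–extend–score procedure:

1. *Seed.* For each candidate period p, positions where the sequence matches
   itself at distance p (``s[i] == s[i+p]``) are collected; maximal runs of
   such self-matches mark candidate arrays, and nearby runs are merged so a
   substitution or a short indel does not split an array.
2. *Extend/score.* Each candidate region is aligned against the tandem perfect
   extension of its unit (wraparound dynamic programming over the cyclic
   pattern), scoring ``+match_weight`` per matched base, ``−mismatch_weight``
   per mismatched base and ``−indel_weight`` per inserted or deleted base.
   The best-scoring local segment is reported, so a perfect array of span L
   scores exactly ``match_weight × L``.
3. *Filter.* A locus is emitted when its score reaches ``min_score`` and its
   copy number reaches ``min_copies``; among loci sharing at least half their
   span the highest score wins (ties: smaller unit, then leftmost).

Two packaged parameter regimes mirror the screening conventions of the
Tandem Repeats Finder ecosystem: a *strict* regime (weights {2,3,5}, score
threshold 50) that favours short, perfect arrays, and a *loose* regime
(weights {2,7,7}, threshold 20) that admits longer, more degenerate ones.
The scanner is scoring-compatible with that ecosystem but is its own
deterministic algorithm, not a reimplementation of the TRF probabilistic
model.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .motifs import (
    canonical_motif,
    enumerate_motif_classes,
    is_at_rich,
    is_primitive,
)

__all__ = [
    "LOOSE",
    "STRICT",
    "CompositionSummary",
    "RepeatLocus",
    "ScanParams",
    "at_rich_share",
    "missing_classes",
    "scan",
    "scan_fasta",
    "summarize_composition",
]


class ScanConfigError(ValueError):
    """Invalid scanner parameters."""


@dataclass(frozen=True)
class ScanParams:
    """Alignment weights and thresholds for one scanning regime."""

    match_weight: int = 2
    mismatch_weight: int = 7
    indel_weight: int = 7
    min_score: int = 20
    min_copies: float = 3
    unit_lengths: tuple[int, ...] = (2, 3, 4, 5, 6)
    regime_name: str = "custom"

    def __post_init__(self) -> None:
        if min(self.match_weight, self.mismatch_weight, self.indel_weight) <= 0:
            raise ScanConfigError("alignment weights must be positive")
        if self.min_score <= 0:
            raise ScanConfigError("min_score must be positive")
        if self.min_copies < 3:
            raise ScanConfigError("min_copies must be at least 3")
        if not self.unit_lengths or not all(1 <= p <= 6 for p in self.unit_lengths):
            raise ScanConfigError("unit_lengths must lie within 1..6")


#: Strict screening regime: weights {2,3,5}, score threshold 50.
STRICT = ScanParams(2, 3, 5, 50, regime_name="strict")
#: Loose screening regime: weights {2,7,7}, score threshold 20.
LOOSE = ScanParams(2, 7, 7, 20, regime_name="loose")

PRESETS: dict[str, ScanParams] = {"strict": STRICT, "loose": LOOSE}


@dataclass
class RepeatLocus:
    """A located tandem array (0-based, half-open coordinates)."""

    sequence_id: str
    start: int
    end: int
    unit: str
    canonical_class: str
    copy_number: float
    percent_match: int
    percent_indels: int
    score: int

    @property
    def unit_length(self) -> int:
        return len(self.unit)

    @property
    def span(self) -> int:
        return self.end - self.start

    @property
    def is_perfect(self) -> bool:
        return self.percent_match == 100 and self.percent_indels == 0


# ---------------------------------------------------------------------------
# seed detection


def _self_match_runs(seq: str, p: int) -> list[tuple[int, int]]:
    """Maximal runs [a, b) of positions i with seq[i] == seq[i+p]."""
    runs: list[tuple[int, int]] = []
    a = None
    limit = len(seq) - p
    for i in range(limit):
        if seq[i] == seq[i + p]:
            if a is None:
                a = i
        elif a is not None:
            runs.append((a, i))
            a = None
    if a is not None:
        runs.append((a, limit))
    return runs


def _merge_runs(runs: list[tuple[int, int]], max_gap: int) -> list[tuple[int, int]]:
    merged: list[tuple[int, int]] = []
    for a, b in runs:
        if merged and a - merged[-1][1] <= max_gap:
            merged[-1] = (merged[-1][0], b)
        else:
            merged.append((a, b))
    return merged


# ---------------------------------------------------------------------------
# wraparound alignment

_DIAG, _UP, _LEFT, _STOP = 0, 1, 2, 3


def _wraparound_align(
    text: str, unit: str, params: ScanParams
) -> tuple[int, int, int, int, int, int]:
    """Best local alignment of ``text`` against the cyclic extension of ``unit``.

    Returns ``(score, start, end, matched, mismatched, indel_bases)`` where
    [start, end) is the aligned slice of ``text``.  Local in the text and in
    the cyclic pattern: the alignment may start and end at any pattern phase.
    """
    n, p = len(text), len(unit)
    mw, xw, iw = params.match_weight, params.mismatch_weight, params.indel_weight
    # score[i][j]: best alignment ending with text[:i] consumed at pattern phase j
    # (unit[j] is the next pattern char).  Cells may reset to 0 (local).
    prev = [0] * p
    move = [[_STOP] * p for _ in range(n + 1)]
    best, best_i, best_j = 0, 0, 0
    for i in range(1, n + 1):
        cur = [0] * p
        c = text[i - 1]
        row_move = move[i]
        for j in range(p):
            jm1 = j - 1 if j else p - 1
            diag = prev[jm1] + (mw if c == unit[jm1] else -xw)
            up = prev[j] - iw  # insertion in text
            left = cur[jm1] - iw  # deletion from pattern
            s, m = diag, _DIAG
            if up > s:
                s, m = up, _UP
            if left > s:
                s, m = left, _LEFT
            if s < 0:
                s, m = 0, _STOP
            cur[j] = s
            row_move[j] = m
            if s > best:
                best, best_i, best_j = s, i, j
        prev = cur
    # traceback to count operation bases and find the aligned start
    i, j = best_i, best_j
    matched = mismatched = indels = 0
    # recompute row scores on the fly is costly; instead follow stored moves
    while i > 0 and move[i][j] != _STOP:
        m = move[i][j]
        if m == _DIAG:
            jm1 = j - 1 if j else p - 1
            if text[i - 1] == unit[jm1]:
                matched += 1
            else:
                mismatched += 1
            i, j = i - 1, jm1
        elif m == _UP:
            indels += 1
            i -= 1
        else:  # _LEFT: deletion, consumes pattern only
            indels += 1
            j = j - 1 if j else p - 1
    return best, i, best_i, matched, mismatched, indels


# ---------------------------------------------------------------------------
# scanning


def _scan_chunk(
    chunk: str, offset: int, seq_id: str, params: ScanParams
) -> list[RepeatLocus]:
    candidates: list[RepeatLocus] = []
    for p in sorted(params.unit_lengths):
        if len(chunk) < 2 * p:
            continue
        runs = [(a, b) for a, b in _self_match_runs(chunk, p) if b - a >= p]
        for a, b in _merge_runs(runs, max_gap=p + 3):
            lo = max(0, a - p)
            hi = min(len(chunk), b + 2 * p)
            region = chunk[lo:hi]
            # unit read off the start of the seed run: by construction that
            # window repeats perfectly at distance p
            unit = chunk[a : a + p]
            if not is_primitive(unit):
                continue  # the primitive period scan reports this array
            score, ra, rb, matched, mismatched, indels = _wraparound_align(
                region, unit, params
            )
            span = rb - ra
            if span <= 0 or score < params.min_score:
                continue
            copy_number = round(span / p, 1)
            if copy_number < params.min_copies:
                continue
            aligned = matched + mismatched
            percent_match = round(100 * matched / aligned) if aligned else 0
            percent_indels = round(100 * indels / (aligned + indels)) if indels else 0
            candidates.append(
                RepeatLocus(
                    sequence_id=seq_id,
                    start=offset + lo + ra,
                    end=offset + lo + rb,
                    unit=unit,
                    canonical_class=canonical_motif(unit),
                    copy_number=copy_number,
                    percent_match=percent_match,
                    percent_indels=percent_indels,
                    score=score,
                )
            )
    return candidates


def _resolve_overlaps(candidates: list[RepeatLocus]) -> list[RepeatLocus]:
    """Keep the best locus among candidates sharing >= 50% of their span."""
    order = sorted(candidates, key=lambda r: (-r.score, r.unit_length, r.start))
    kept: list[RepeatLocus] = []
    for cand in order:
        clash = False
        for acc in kept:
            ov = min(cand.end, acc.end) - max(cand.start, acc.start)
            if ov > 0 and ov >= 0.5 * min(cand.span, acc.span):
                clash = True
                break
        if not clash:
            kept.append(cand)
    kept.sort(key=lambda r: (r.start, r.unit_length))
    return kept


def scan(sequence: str, sequence_id: str = "seq", params: ScanParams = STRICT) -> list[RepeatLocus]:
    """Scan one sequence for tandem repeats under the given regime.

    ``N`` runs never participate in loci: the sequence is split at them and
    each N-free chunk is scanned independently.  Returns loci sorted by start
    coordinate.
    """
    if not isinstance(params, ScanParams):
        raise ScanConfigError(f"params must be ScanParams, got {type(params)!r}")
    seq = sequence.upper()
    if seq and not set(seq) <= set("ACGTN"):
        bad = sorted(set(seq) - set("ACGTN"))
        raise ValueError(f"sequence contains non-ACGTN characters: {bad}")
    candidates: list[RepeatLocus] = []
    for m in re.finditer(r"[ACGT]+", seq):
        candidates.extend(_scan_chunk(m.group(), m.start(), sequence_id, params))
    return _resolve_overlaps(candidates)


def scan_fasta(path, params: ScanParams = STRICT) -> list[RepeatLocus]:
    """Scan every record of a FASTA file (plain or gzip-compressed)."""
    from .io import read_fasta

    loci: list[RepeatLocus] = []
    for name, seq in read_fasta(path):
        loci.extend(scan(seq, name, params))
    return loci


# ---------------------------------------------------------------------------
# composition summaries


@dataclass
class CompositionSummary:
    """Per-class locus tallies and genome-wide repeat composition figures."""

    genome_length_bp: int
    n_loci: int
    loci_per_megabase: float
    genome_fraction_percent: float
    #: unit_length -> canonical class -> {"perfect": n, "imperfect": n}
    per_class: dict[int, dict[str, dict[str, int]]] = field(default_factory=dict)
    #: unit_length -> percent of loci whose class is AT-rich (<= 1 G/C base)
    at_rich_share_by_unit_length: dict[int, float] = field(default_factory=dict)

    def perfect_classes(self, unit_length: int) -> set[str]:
        return {
            cls
            for cls, tally in self.per_class.get(unit_length, {}).items()
            if tally["perfect"] > 0
        }

    def to_dict(self) -> dict:
        return {
            "genome_length_bp": self.genome_length_bp,
            "n_loci": self.n_loci,
            "loci_per_megabase": self.loci_per_megabase,
            "genome_fraction_percent": self.genome_fraction_percent,
            "per_class": {
                str(k): {cls: dict(t) for cls, t in v.items()}
                for k, v in self.per_class.items()
            },
            "at_rich_share_by_unit_length": {
                str(k): v for k, v in self.at_rich_share_by_unit_length.items()
            },
        }

    @classmethod
    def from_class_counts(
        cls, counts_by_class: Mapping[str, int], perfect: bool = True
    ) -> "CompositionSummary":
        """Build a tallies-only summary from per-class locus counts.

        Used when the loci themselves are not available, only a published
        count per motif class (genome figures are then reported as zero).
        Motif labels are canonicalized on entry.
        """
        per_class: dict[int, dict[str, dict[str, int]]] = {}
        kind = "perfect" if perfect else "imperfect"
        other = "imperfect" if perfect else "perfect"
        for motif, n in counts_by_class.items():
            canon = canonical_motif(motif)
            bucket = per_class.setdefault(len(canon), {})
            tally = bucket.setdefault(canon, {"perfect": 0, "imperfect": 0})
            tally[kind] += int(n)
            tally[other] += 0
        summary = cls(
            genome_length_bp=0,
            n_loci=sum(int(n) for n in counts_by_class.values()),
            loci_per_megabase=0.0,
            genome_fraction_percent=0.0,
            per_class=per_class,
        )
        summary.at_rich_share_by_unit_length = _at_rich_by_length(per_class)
        return summary


def _at_rich_by_length(
    per_class: dict[int, dict[str, dict[str, int]]],
) -> dict[int, float]:
    shares: dict[int, float] = {}
    for k, classes in per_class.items():
        total = sum(t["perfect"] + t["imperfect"] for t in classes.values())
        if total == 0:
            continue
        rich = sum(
            t["perfect"] + t["imperfect"]
            for cls, t in classes.items()
            if is_at_rich(cls)
        )
        shares[k] = 100.0 * rich / total
    return shares


def _collapsed_span(loci: Iterable[RepeatLocus]) -> int:
    """Total bases covered by loci, with overlaps counted once."""
    by_seq: dict[str, list[tuple[int, int]]] = {}
    for loc in loci:
        by_seq.setdefault(loc.sequence_id, []).append((loc.start, loc.end))
    total = 0
    for intervals in by_seq.values():
        intervals.sort()
        cur_a, cur_b = intervals[0]
        for a, b in intervals[1:]:
            if a > cur_b:
                total += cur_b - cur_a
                cur_a, cur_b = a, b
            else:
                cur_b = max(cur_b, b)
        total += cur_b - cur_a
    return total


def summarize_composition(
    loci: Sequence[RepeatLocus], genome_length_bp: int
) -> CompositionSummary:
    """Summarize a locus list into genome-composition statistics.

    ``loci_per_megabase`` is the locus count divided by the genome length in
    Mb; ``genome_fraction_percent`` is the overlap-collapsed repeat span as a
    percentage of the genome.
    """
    if genome_length_bp < 0:
        raise ValueError("genome_length_bp must be non-negative")
    for loc in loci:
        if loc.start < 0 or loc.end > genome_length_bp:
            raise ValueError(
                f"locus {loc.sequence_id}:{loc.start}-{loc.end} exceeds genome "
                f"length {genome_length_bp}"
            )
    per_class: dict[int, dict[str, dict[str, int]]] = {}
    for loc in loci:
        bucket = per_class.setdefault(loc.unit_length, {})
        tally = bucket.setdefault(loc.canonical_class, {"perfect": 0, "imperfect": 0})
        tally["perfect" if loc.is_perfect else "imperfect"] += 1
    n = len(loci)
    mb = genome_length_bp / 1e6
    return CompositionSummary(
        genome_length_bp=genome_length_bp,
        n_loci=n,
        loci_per_megabase=(n / mb) if mb else 0.0,
        genome_fraction_percent=(
            100.0 * _collapsed_span(loci) / genome_length_bp if n and genome_length_bp else 0.0
        ),
        per_class=per_class,
        at_rich_share_by_unit_length=_at_rich_by_length(per_class),
    )


def missing_classes(summary: CompositionSummary, unit_length: int) -> list[str]:
    """Canonical classes of a unit length with no perfect locus in the summary.

    The set difference between the complete class enumeration and the classes
    observed with at least one perfect locus; e.g. genomes frequently lack
    perfect CG dinucleotide arrays entirely.
    """
    all_classes = set(enumerate_motif_classes(unit_length).classes)
    return sorted(all_classes - summary.perfect_classes(unit_length))


def at_rich_share(counts_by_class: Mapping[str, int]) -> float:
    """Percent of loci in AT-rich classes (at most one G/C base per unit)."""
    total = sum(counts_by_class.values())
    if total == 0:
        return 0.0
    rich = sum(n for motif, n in counts_by_class.items() if is_at_rich(motif))
    return 100.0 * rich / total
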