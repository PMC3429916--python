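"""Mutation calling and spectrum statistics for mutation-accumulation lines.

Mutation-accumulation (MA) lines descend from a single homozygous progenitor
through repeated single-individual bottlenecks, so at a microsatellite marker
each line carries one allele and any size difference from the progenitor is a
fixed spontaneous mutation.  Calls are expressed in signed repeat units:
``delta_units = (allele_bp − progenitor_bp) / unit_length``.  A difference
that is not a whole number of units is flagged *off-ladder* and suppressed
rather than called, mirroring the bench practice of re-verifying anomalous
fragment sizes before accepting them.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd

from .motifs import canonical_motif

__all__ = [
    "GenotypeTable",
    "MarkerDef",
    "MutationCall",
    "MutationSpectrum",
    "OffLadderError",
    "SchemaError",
    "call_mutations",
    "delta_units",
    "spectrum",
    "stratify",
]

logger = logging.getLogger(__name__)


class OffLadderError(ValueError):
    """Allele size difference is not a whole number of repeat units."""


class SchemaError(ValueError):
    """Genotype data references unknown markers or violates the table schema."""


@dataclass(frozen=True)
class MarkerDef:
    """A genotyped microsatellite marker and its progenitor allele."""

    marker_id: str
    chromosome: str
    unit: str
    repeat_count: float
    percent_match: int
    progenitor_bp: int

    def __post_init__(self) -> None:
        if self.percent_match > 100 or self.percent_match < 0:
            raise ValueError(f"{self.marker_id}: percent_match must be 0..100")

    @property
    def unit_length(self) -> int:
        return len(self.unit)

    @property
    def canonical_class(self) -> str:
        return canonical_motif(self.unit)

    @property
    def is_perfect(self) -> bool:
        return self.percent_match == 100


@dataclass
class GenotypeTable:
    """Per-marker, per-line allele sizes (bp) from an MA experiment.

    ``alleles`` is indexed by marker_id with one column per line; entries are
    allele sizes in bp, NaN where a line was not assessed at that marker.  All
    genotypes are haploid-equivalent (selfing lines, homozygous loci).
    """

    markers: list[MarkerDef]
    alleles: pd.DataFrame
    n_generations: int

    def __post_init__(self) -> None:
        ids = [m.marker_id for m in self.markers]
        if len(set(ids)) != len(ids):
            raise SchemaError("duplicate marker_id in marker list")
        known = set(ids)
        unknown = [m for m in self.alleles.index if m not in known]
        if unknown:
            raise SchemaError(f"genotypes reference undefined markers: {unknown}")
        if self.n_generations < 1:
            raise ValueError("n_generations must be >= 1")

    @property
    def lines(self) -> list[str]:
        return list(self.alleles.columns)

    def marker(self, marker_id: str) -> MarkerDef:
        for m in self.markers:
            if m.marker_id == marker_id:
                return m
        raise SchemaError(f"unknown marker {marker_id!r}")

    def lines_assessed(self, marker_id: str) -> int:
        """Number of lines with a non-missing genotype at the marker (l)."""
        if marker_id not in self.alleles.index:
            return 0
        return int(self.alleles.loc[marker_id].notna().sum())


@dataclass(frozen=True)
class MutationCall:
    """One fixed mutation: a signed change in repeat units at a marker."""

    marker_id: str
    line_id: str
    delta_units: int

    def __post_init__(self) -> None:
        if self.delta_units == 0:
            raise ValueError("a mutation call must have nonzero delta_units")

    @property
    def kind(self) -> Literal["insertion", "deletion"]:
        return "insertion" if self.delta_units > 0 else "deletion"

    @property
    def step(self) -> Literal["single", "multi"]:
        return "single" if abs(self.delta_units) == 1 else "multi"


def delta_units(allele_bp: int, progenitor_bp: int, unit_length: int) -> int:
    """Signed repeat-unit change of an allele relative to the progenitor.

    Returns 0 when the sizes agree (no mutation).  Raises
    :class:`OffLadderError` when the size difference is not divisible by the
    unit length — such fragments sit off the expected allele ladder and need
    independent verification before they can be interpreted.
    """
    if not 1 <= unit_length <= 6:
        raise ValueError(f"unit_length must be in 1..6, got {unit_length}")
    if allele_bp <= 0 or progenitor_bp <= 0:
        raise ValueError("allele sizes must be positive")
    diff = allele_bp - progenitor_bp
    if diff % unit_length:
        raise OffLadderError(
            f"size difference {diff} bp is not a multiple of the "
            f"{unit_length} bp unit"
        )
    return diff // unit_length


def call_mutations(table: GenotypeTable) -> list[MutationCall]:
    """Call mutations for every (marker, line) genotype differing from the progenitor.

    Missing genotypes yield no call (and reduce the marker's assessed-line
    count used downstream); off-ladder sizes are logged and suppressed.
    """
    calls: list[MutationCall] = []
    for marker in table.markers:
        if marker.marker_id not in table.alleles.index:
            continue
        row = table.alleles.loc[marker.marker_id]
        for line_id, allele in row.items():
            if pd.isna(allele):
                continue
            try:
                d = delta_units(int(allele), marker.progenitor_bp, marker.unit_length)
            except OffLadderError as err:
                logger.warning(
                    "off-ladder allele at %s/%s: %s", marker.marker_id, line_id, err
                )
                continue
            if d:
                calls.append(MutationCall(marker.marker_id, str(line_id), d))
    return calls


@dataclass
class MutationSpectrum:
    """Tallies of mutation events and per-locus size trends."""

    total_events: int
    n_loci_mutated: int
    single_step_total: int
    single_step_insertions: int
    single_step_deletions: int
    multi_step_total: int
    insertion_events_total: int
    deletion_events_total: int
    per_locus_net_units: dict[str, int]
    per_locus_trend: dict[str, Literal["growth", "decrease", "none"]]
    #: distinct mutated lines per marker — the n used by the rate estimator
    n_per_marker: dict[str, int] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "total_events": self.total_events,
            "n_loci_mutated": self.n_loci_mutated,
            "single_step_total": self.single_step_total,
            "single_step_insertions": self.single_step_insertions,
            "single_step_deletions": self.single_step_deletions,
            "multi_step_total": self.multi_step_total,
            "insertion_events_total": self.insertion_events_total,
            "deletion_events_total": self.deletion_events_total,
            "per_locus_net_units": dict(self.per_locus_net_units),
            "per_locus_trend": dict(self.per_locus_trend),
            "n_per_marker": dict(self.n_per_marker),
        }


def spectrum(
    calls: Sequence[MutationCall], markers: Sequence[MarkerDef]
) -> MutationSpectrum:
    """Classify calls into the mutation spectrum of the experiment.

    Events are split by step size (single = one repeat unit) and direction
    (insertion/deletion); per-locus net change and its sign give each locus a
    growth/decrease/none trend.  ``n_per_marker`` counts distinct mutated
    lines per marker, which is the zero-class estimator's n.
    """
    known = {m.marker_id for m in markers}
    for c in calls:
        if c.marker_id not in known:
            raise SchemaError(f"call references unknown marker {c.marker_id!r}")
    net: dict[str, int] = {}
    mutated_lines: dict[str, set[str]] = {}
    ss = ss_ins = ss_del = ins = dels = 0
    for c in calls:
        net[c.marker_id] = net.get(c.marker_id, 0) + c.delta_units
        mutated_lines.setdefault(c.marker_id, set()).add(c.line_id)
        if c.kind == "insertion":
            ins += 1
        else:
            dels += 1
        if c.step == "single":
            ss += 1
            if c.kind == "insertion":
                ss_ins += 1
            else:
                ss_del += 1
    trend = {
        mid: ("growth" if v > 0 else "decrease" if v < 0 else "none")
        for mid, v in net.items()
    }
    return MutationSpectrum(
        total_events=len(calls),
        n_loci_mutated=len({c.marker_id for c in calls}),
        single_step_total=ss,
        single_step_insertions=ss_ins,
        single_step_deletions=ss_del,
        multi_step_total=len(calls) - ss,
        insertion_events_total=ins,
        deletion_events_total=dels,
        per_locus_net_units=net,
        per_locus_trend=trend,
        n_per_marker={mid: len(lines) for mid, lines in mutated_lines.items()},
    )


def stratify(
    calls: Sequence[MutationCall],
    markers: Sequence[MarkerDef],
    by: Literal["perfection", "repeat_count", "perfect_long"],
    repeat_count_threshold: float | None = None,
) -> dict[str, int]:
    """Event counts within marker strata.

    ``perfection`` splits markers into perfect (100% match) vs imperfect;
    ``repeat_count`` splits at the given threshold (> threshold vs <=);
    ``perfect_long`` isolates perfect markers above the threshold — the class
    in which nearly all MA mutations are observed — against everything else.
    """
    if by in ("repeat_count", "perfect_long") and repeat_count_threshold is None:
        raise ValueError(f"stratifier {by!r} requires repeat_count_threshold")
    defs = {m.marker_id: m for m in markers}
    missing = {c.marker_id for c in calls} - set(defs)
    if missing:
        raise SchemaError(f"calls reference unknown markers: {sorted(missing)}")

    def stratum(m: MarkerDef) -> str:
        if by == "perfection":
            return "perfect" if m.is_perfect else "imperfect"
        if by == "repeat_count":
            return "long" if m.repeat_count > repeat_count_threshold else "short"
        if by == "perfect_long":
            long_ = m.repeat_count > repeat_count_threshold
            return "perfect_long" if (m.is_perfect and long_) else "other"
        raise ValueError(f"unknown stratifier {by!r}")

    out: dict[str, int] = {}
    for c in calls:
        out[stratum(defs[c.marker_id])] = out.get(stratum(defs[c.marker_id]), 0) + 1
    return out
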