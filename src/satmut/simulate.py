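"""Synthetic data with the statistical structure the pipeline assumes.

Two generators cover the pipeline's two inputs:

* :func:`plant_repeats` builds random-background genomes with tandem arrays
  planted at known coordinates, for exercising and benchmarking the scanner
  against exact truth intervals.
* :func:`simulate_ma_lines` propagates selfing mutation-accumulation lines
  under a stepwise mutation model: at each locus, each line mutates with
  probability µ per generation; a mutation changes the repeat count by ±1
  with probability ``p_single_step``, otherwise by a multistep magnitude
  1 + Geometric(q) ≥ 2; the sign is an insertion with probability
  ``p_insertion``.  Fixation is instantaneous (one homozygous allele per
  line), matching propagation through single-offspring bottlenecks of a
  self-fertilizing hermaphrodite.

Defaults mirror the design of the MA experiment the package ships as a
fixture: 82 surviving lines, 142 generations, step-type and direction
probabilities taken from the observed spectrum (26/31 single-step, 23/31
insertions), and 58% background A+T content.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .calling import GenotypeTable, MarkerDef
from .io import (
    _FLANK_BP,
    fixture_genotype_table,
    load_genome_survey_strict_perfect,
    load_ma_marker_panel,
)
from .motifs import _validate

__all__ = [
    "LocusSpec",
    "PlantedInterval",
    "PlantedRepeat",
    "SimConfig",
    "TruthEvent",
    "TruthSet",
    "fixture_genotype_table",
    "load_genome_survey_strict_perfect",
    "load_ma_marker_panel",
    "plant_repeats",
    "simulate_ma_lines",
]

REPEAT_COUNT_FLOOR = 3


@dataclass(frozen=True)
class LocusSpec:
    """One simulated microsatellite locus: unit, starting copies, true rate."""

    unit: str
    initial_repeat_count: int
    true_mu: float

    def __post_init__(self) -> None:
        _validate(self.unit)
        if self.initial_repeat_count < REPEAT_COUNT_FLOOR:
            raise ValueError(f"initial_repeat_count must be >= {REPEAT_COUNT_FLOOR}")
        if not 0 <= self.true_mu < 1:
            raise ValueError("true_mu must lie in [0, 1)")


@dataclass
class SimConfig:
    """Parameters of the MA-line stepwise-mutation simulation."""

    loci: list[LocusSpec]
    n_lines: int = 82
    n_generations: int = 142
    p_single_step: float = 26 / 31
    p_insertion: float = 23 / 31
    multistep_tail: float = 1 / 3  # geometric q; mean multistep |step| = 1 + 1/q
    n_initial_lines: int | None = None  # enables uniform-random line attrition
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_lines < 1 or self.n_generations < 1:
            raise ValueError("n_lines and n_generations must be >= 1")
        for name in ("p_single_step", "p_insertion", "multistep_tail"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.n_initial_lines is not None and self.n_initial_lines < self.n_lines:
            raise ValueError("n_initial_lines must be >= n_lines")
        if not self.loci:
            raise ValueError("at least one locus is required")


@dataclass(frozen=True)
class TruthEvent:
    marker_id: str
    line_id: str
    generation: int
    delta_units: int


@dataclass(frozen=True)
class PlantedInterval:
    sequence_id: str
    start: int
    end: int
    unit: str
    copies: float


@dataclass
class TruthSet:
    """Ground truth of a simulation; never consumed by the pipeline under test."""

    events: list[TruthEvent] = field(default_factory=list)
    planted: list[PlantedInterval] = field(default_factory=list)

    def events_per_marker(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for e in self.events:
            out[e.marker_id] = out.get(e.marker_id, 0) + 1
        return out

    def mutated_lines_per_marker(self) -> dict[str, int]:
        seen: dict[str, set[str]] = {}
        for e in self.events:
            seen.setdefault(e.marker_id, set()).add(e.line_id)
        return {k: len(v) for k, v in seen.items()}


def _draw_step(rng: np.random.Generator, cfg: SimConfig) -> int:
    magnitude = 1
    if rng.random() >= cfg.p_single_step:
        magnitude = 1 + rng.geometric(cfg.multistep_tail)
    sign = 1 if rng.random() < cfg.p_insertion else -1
    return sign * magnitude


def simulate_ma_lines(config: SimConfig) -> tuple[GenotypeTable, TruthSet]:
    """Simulate an MA experiment and return its genotype table plus ground truth.

    Alleles are reported as PCR-product-like sizes:
    ``progenitor_bp + unit_length × (net repeat-unit change)`` where the
    progenitor size is the repeat-tract length plus a fixed flank.  Repeat
    counts never drop below three units — a deletion that would cross the
    floor is redrawn, so loci cannot die during the run.  Deterministic for a
    given config and seed.
    """
    rng = np.random.default_rng(config.seed)
    n_sim = config.n_initial_lines or config.n_lines
    line_ids = [f"L{i:03d}" for i in range(1, n_sim + 1)]
    markers: list[MarkerDef] = []
    events: list[TruthEvent] = []
    alleles: dict[str, dict[str, float]] = {}

    for idx, locus in enumerate(config.loci, start=1):
        mid = f"S{idx:03d}"
        p = len(locus.unit)
        progenitor = p * locus.initial_repeat_count + _FLANK_BP
        markers.append(
            MarkerDef(
                marker_id=mid,
                chromosome="sim",
                unit=locus.unit,
                repeat_count=float(locus.initial_repeat_count),
                percent_match=100,
                progenitor_bp=progenitor,
            )
        )
        row: dict[str, float] = {}
        # number of mutation events per line over the run, then their
        # generations; events are rare (mu*t << 1), so the per-event loop is cheap
        n_events = rng.binomial(config.n_generations, locus.true_mu, size=n_sim)
        for line_i, k in enumerate(n_events):
            line = line_ids[line_i]
            count = locus.initial_repeat_count
            if k:
                gens = np.sort(
                    rng.choice(config.n_generations, size=k, replace=False)
                )
                for g in gens:
                    while True:
                        step = _draw_step(rng, config)
                        if count + step >= REPEAT_COUNT_FLOOR:
                            break
                    count += step
                    events.append(TruthEvent(mid, line, int(g) + 1, int(step)))
            row[line] = float(progenitor + p * (count - locus.initial_repeat_count))
        alleles[mid] = row

    table = pd.DataFrame.from_dict(alleles, orient="index")[line_ids]
    table = table.loc[[m.marker_id for m in markers]]
    if config.n_initial_lines is not None:
        survivors = sorted(
            rng.choice(n_sim, size=config.n_lines, replace=False).tolist()
        )
        keep = [line_ids[i] for i in survivors]
        table = table[keep]
        kept = set(keep)
        events = [e for e in events if e.line_id in kept]
    genotypes = GenotypeTable(
        markers=markers, alleles=table, n_generations=config.n_generations
    )
    return genotypes, TruthSet(events=events)


# ---------------------------------------------------------------------------
# planted-repeat genomes


@dataclass(frozen=True)
class PlantedRepeat:
    """Specification of one array to plant: unit, copies, optional position."""

    unit: str
    copies: int
    start: int | None = None
    percent_match: int = 100

    def __post_init__(self) -> None:
        _validate(self.unit)
        if self.copies < 3:
            raise ValueError("planted arrays need at least 3 copies")
        if not 0 < self.percent_match <= 100:
            raise ValueError("percent_match must be in 1..100")

    @property
    def span(self) -> int:
        return len(self.unit) * self.copies


def _background(rng: np.random.Generator, n: int, at_fraction: float) -> np.ndarray:
    p_at = at_fraction / 2
    p_gc = (1 - at_fraction) / 2
    return rng.choice(
        np.array(list("ACGT")), size=n, p=[p_at, p_gc, p_gc, p_at]
    )


def _corrupt(rng: np.random.Generator, array: np.ndarray, percent_match: int) -> None:
    """Substitute bases in-place so copy-to-copy identity ≈ percent_match."""
    span = len(array)
    n_sub = int(round((1 - percent_match / 100) * span))
    if n_sub == 0:
        return
    pos = rng.choice(span, size=min(n_sub, span), replace=False)
    for i in pos:
        others = [b for b in "ACGT" if b != array[i]]
        array[i] = others[rng.integers(len(others))]


def plant_repeats(
    genome_length: int,
    loci_spec: Sequence[PlantedRepeat],
    background_at_fraction: float = 0.58,
    seed: int = 0,
    sequence_id: str = "synth1",
) -> tuple[list[tuple[str, str]], TruthSet]:
    """Generate a synthetic genome with tandem arrays at known coordinates.

    The background is i.i.d. with the given A+T fraction (default 58%, a
    typical AT-rich nematode genome); planted arrays are inserted verbatim
    when perfect, or with random substitutions targeting the requested
    copy-to-copy percent match.  Returns FASTA-ready records and the exact
    truth intervals.  Arrays must fit without overlapping (10 bp margin).
    """
    if genome_length < 0:
        raise ValueError("genome_length must be non-negative")
    if not 0 <= background_at_fraction <= 1:
        raise ValueError("background_at_fraction must lie in [0, 1]")
    if genome_length == 0:
        if loci_spec:
            raise ValueError("cannot plant arrays in an empty genome")
        return [], TruthSet()
    rng = np.random.default_rng(seed)
    genome = _background(rng, genome_length, background_at_fraction)

    margin = 10
    placed: list[tuple[int, int]] = []
    intervals: list[PlantedInterval] = []

    def overlaps(a: int, b: int) -> bool:
        return any(a - margin < pb and b + margin > pa for pa, pb in placed)

    for spec in loci_spec:
        span = spec.span
        if span > genome_length:
            raise ValueError(f"array {spec.unit}x{spec.copies} exceeds the genome")
        if spec.start is not None:
            a = spec.start
            if a < 0 or a + span > genome_length or overlaps(a, a + span):
                raise ValueError(
                    f"array {spec.unit}x{spec.copies} at {a} overlaps or exceeds bounds"
                )
        else:
            for _ in range(1000):
                a = int(rng.integers(0, genome_length - span + 1))
                if not overlaps(a, a + span):
                    break
            else:
                raise ValueError("could not place arrays without overlap")
        array = np.array(list(spec.unit * spec.copies))
        if spec.percent_match < 100:
            _corrupt(rng, array, spec.percent_match)
        genome[a : a + span] = array
        placed.append((a, a + span))
        intervals.append(
            PlantedInterval(sequence_id, a, a + span, spec.unit, float(spec.copies))
        )

    records = [(sequence_id, "".join(genome))]
    return records, TruthSet(planted=sorted(intervals, key=lambda iv: iv.start))
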