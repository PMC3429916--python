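"""Per-locus mutation-rate estimation from MA-line outcomes.

Under a Poisson mutation process at rate µ per allele per generation, a line
propagated for t generations is unmutated at a locus with probability
e^(−µt).  Inverting the observed fraction of unmutated lines gives the
zero-class estimator

    µ̂ = −ln(1 − n/l) / t

where n is the number of mutated lines and l the number of lines assessed at
the locus.  For small n/l this reduces to the naive n/(l·t); the logarithm
corrects for lines that mutated more than once.  The estimator is undefined
at saturation (n = l), where the zero class is empty.

Uncertainty is quantified by transforming an exact (Clopper–Pearson) binomial
interval on the mutated-line fraction through the same map, which preserves
coverage because the map is monotone.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import TYPE_CHECKING, Sequence

from scipy.stats import beta as _beta

if TYPE_CHECKING:  # pragma: no cover
    from .calling import GenotypeTable, MutationSpectrum

__all__ = [
    "RateEstimate",
    "SaturationError",
    "estimate_all",
    "estimate_rate",
    "rate_ci",
    "suggested_rate",
]


class SaturationError(ValueError):
    """Every assessed line mutated (n = l); the zero-class estimator is undefined."""


@dataclass
class RateEstimate:
    """A per-marker mutation-rate estimate with its inputs and flags."""

    marker_id: str
    n: int
    l: int
    t: int
    mu: float
    ci_low: float | None = None
    ci_high: float | None = None
    single_event_flag: bool = False
    uninformative: bool = False
    error: str | None = None

    def to_dict(self) -> dict:
        return {
            "marker_id": self.marker_id,
            "n": self.n,
            "l": self.l,
            "t": self.t,
            "mu": self.mu,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "single_event_flag": self.single_event_flag,
            "uninformative": self.uninformative,
            "error": self.error,
        }


def _check(n: int, l: int, t: int) -> None:
    if l < 1:
        raise ValueError("l (lines assessed) must be >= 1")
    if t < 1:
        raise ValueError("t (generations) must be >= 1")
    if n < 0:
        raise ValueError("n (mutated lines) must be >= 0")
    if n > l:
        raise ValueError(f"n = {n} exceeds the number of lines l = {l}")
    if n == l:
        raise SaturationError(
            f"all {l} lines mutated; the zero-class estimator is undefined"
        )


def estimate_rate(n: int, l: int, t: int) -> float:
    """Zero-class estimate µ̂ = −ln(1 − n/l)/t, per allele per generation."""
    _check(n, l, t)
    if n == 0:
        return 0.0
    return -math.log1p(-n / l) / t


def rate_ci(n: int, l: int, t: int, confidence: float = 0.95) -> tuple[float, float]:
    """Exact binomial (Clopper–Pearson) confidence interval for µ.

    The interval on the mutated-line fraction f = n/l is pushed through the
    monotone map µ = −ln(1 − f)/t; it always contains the point estimate.
    The upper bound is finite because f's upper bound is below 1 whenever
    n < l.
    """
    _check(n, l, t)
    if not 0 < confidence < 1:
        raise ValueError("confidence must lie strictly between 0 and 1")
    alpha = 1 - confidence
    f_low = 0.0 if n == 0 else _beta.ppf(alpha / 2, n, l - n + 1)
    f_high = _beta.ppf(1 - alpha / 2, n + 1, l - n)
    return (-math.log1p(-f_low) / t, -math.log1p(-f_high) / t)


def estimate_all(
    spectrum: "MutationSpectrum",
    table: "GenotypeTable",
    confidence: float | None = 0.95,
) -> list[RateEstimate]:
    """One rate estimate per marker of the experiment.

    l is the marker's assessed-line count (non-missing genotypes), n the
    number of distinct mutated lines from the spectrum, t the experiment's
    generation count.  Markers with n = 0 are reported with µ = 0 and an
    ``uninformative`` flag; single-event markers (n = 1) are flagged because
    one mutation cannot support a proper frequency.  Saturated markers are
    recorded as errors without aborting the batch.
    """
    t = table.n_generations
    out: list[RateEstimate] = []
    for marker in table.markers:
        mid = marker.marker_id
        l = table.lines_assessed(mid)
        n = spectrum.n_per_marker.get(mid, 0)
        est = RateEstimate(marker_id=mid, n=n, l=l, t=t, mu=0.0)
        if n == 0:
            est.uninformative = True
            out.append(est)
            continue
        try:
            est.mu = estimate_rate(n, l, t)
            if confidence is not None:
                est.ci_low, est.ci_high = rate_ci(n, l, t, confidence)
        except (SaturationError, ValueError) as err:
            est.mu = float("nan")
            est.error = str(err)
        est.single_event_flag = n == 1
        out.append(est)
    return out


def suggested_rate(
    estimates: Sequence[RateEstimate],
    markers,
    min_repeat_count: float = 30,
    min_events: int = 2,
) -> float | None:
    """Mean µ̂ over perfect, long markers with at least ``min_events`` mutated lines.

    A reporting convention, not a statistical estimator: it averages the
    per-marker rates of the marker population recommended for divergence
    dating (perfect arrays of >= 30 units with multiple observed events).
    Returns None when no marker qualifies.
    """
    defs = {m.marker_id: m for m in markers}
    vals = [
        e.mu
        for e in estimates
        if e.n >= min_events
        and e.error is None
        and e.marker_id in defs
        and defs[e.marker_id].is_perfect
        and defs[e.marker_id].repeat_count >= min_repeat_count
    ]
    return sum(vals) / len(vals) if vals else None
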