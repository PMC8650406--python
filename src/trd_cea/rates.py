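"""Rate/probability conversions for decision-model transition inputs.

Event proportions reported by source trials refer to heterogeneous
follow-up windows (four weeks, six months, one year, ...).  A Markov
model with 30-day cycles needs them on a common per-cycle scale.  The
standard conversion assumes a constant hazard: a proportion ``P``
observed over ``t`` days implies rate ``r = -ln(1 - P) / t`` per day,
and a rate ``r`` applied for ``t`` days implies probability
``p = 1 - exp(-r t)``.

Time conventions used throughout this package (days): one cycle = 30,
one month = 30, six months = 182.5, one year = 365, one week = 7.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = [
    "EvidenceSummary",
    "prob_to_rate",
    "rate_to_prob",
    "rescale_prob",
    "mortality_with_relative_risk",
]

DAYS_PER_CYCLE = 30.0
DAYS_PER_WEEK = 7.0
DAYS_PER_YEAR = 365.0
DAYS_PER_HALF_YEAR = 182.5


@dataclass(frozen=True)
class EvidenceSummary:
    """Event proportion over a follow-up window, as reported by a source study.

    ``relative_risk`` multiplies the implied hazard before re-scaling
    (used for the excess all-cause mortality of treatment-resistant
    depression relative to depression, a hazard ratio of 1.35).
    """

    proportion: float
    window_days: float
    relative_risk: float = 1.0
    label: str = ""

    def per_cycle(self, cycle_days: float = DAYS_PER_CYCLE) -> float:
        return mortality_with_relative_risk(
            self.proportion, self.window_days, self.relative_risk, cycle_days
        )


def prob_to_rate(p: float, t_days: float) -> float:
    """Constant daily hazard implied by proportion ``p`` over ``t_days``."""
    if not 0.0 <= p < 1.0:
        raise ValueError(f"proportion must be in [0, 1), got {p}")
    if t_days <= 0:
        raise ValueError(f"follow-up must be positive, got {t_days}")
    return -math.log1p(-p) / t_days


def rate_to_prob(r: float, t_days: float) -> float:
    """Probability of at least one event in ``t_days`` at daily hazard ``r``."""
    if r < 0:
        raise ValueError(f"rate must be non-negative, got {r}")
    if t_days <= 0:
        raise ValueError(f"time must be positive, got {t_days}")
    return -math.expm1(-r * t_days)


def rescale_prob(p: float, t_source_days: float, t_target_days: float) -> float:
    """Re-express a proportion over one window as a probability over another."""
    return rate_to_prob(prob_to_rate(p, t_source_days), t_target_days)


def mortality_with_relative_risk(
    p: float, t_days: float, rr: float, t_target_days: float
) -> float:
    """Re-scale a proportion after multiplying its hazard by ``rr``."""
    if rr <= 0:
        raise ValueError(f"relative risk must be positive, got {rr}")
    return rate_to_prob(rr * prob_to_rate(p, t_days), t_target_days)
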