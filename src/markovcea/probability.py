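"""Rate/probability calculus for constant-hazard transitions.

A monthly transition probability ``p`` over an interval of ``t`` months and
the corresponding constant hazard ``r`` are linked by ``p = 1 - exp(-r t)``.
Published cumulative probabilities are moved between time bases by passing
through the rate scale, and a total death probability is split into
cause-specific components on that same scale so that the component hazards
sum exactly to the total hazard.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .constants import TOL_INVARIANT

__all__ = [
    "RateProbPair",
    "DeathSplit",
    "cumprob_to_rate",
    "rate_to_prob",
    "rescale_prob",
    "split_death_prob",
]


@dataclass(frozen=True)
class RateProbPair:
    """A probability and the hazard it implies over a fixed interval."""

    prob: float
    rate: float
    interval: float = 1.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.prob < 1.0:
            raise ValueError(f"prob must be in [0, 1), got {self.prob}")
        if self.rate < 0.0:
            raise ValueError(f"rate must be >= 0, got {self.rate}")
        if self.interval <= 0.0:
            raise ValueError(f"interval must be > 0, got {self.interval}")
        implied = 1.0 - math.exp(-self.rate * self.interval)
        if abs(implied - self.prob) > TOL_INVARIANT:
            raise ValueError(
                f"inconsistent pair: prob={self.prob} but rate {self.rate} over "
                f"{self.interval} months implies {implied}"
            )


@dataclass(frozen=True)
class DeathSplit:
    """Attribution of total deaths to background incidence vs progression.

    The base case attributes 13% of deaths to incidence (deaths out of the
    progression-free state) and 87% to disease progression (deaths out of
    the progressed state).
    """

    f_incidence: float = 0.13
    f_progression: float = 0.87

    def __post_init__(self) -> None:
        for name, f in (("f_incidence", self.f_incidence),
                        ("f_progression", self.f_progression)):
            if not 0.0 <= f <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {f}")
        if abs(self.f_incidence + self.f_progression - 1.0) > TOL_INVARIANT:
            raise ValueError(
                "death-split fractions must sum to 1, got "
                f"{self.f_incidence} + {self.f_progression}"
            )


def cumprob_to_rate(p: float, t: float = 1.0) -> float:
    """Convert a cumulative probability over ``t`` months to a hazard.

    ``r = -ln(1 - p) / t``; ``p = 1`` has no finite rate and is rejected.
    """
    if not 0.0 <= p < 1.0:
        raise ValueError(f"probability must be in [0, 1), got {p}")
    if t <= 0.0:
        raise ValueError(f"interval must be > 0, got {t}")
    return -math.log1p(-p) / t


def rate_to_prob(r: float, t: float = 1.0) -> float:
    """Convert a hazard per month to a probability over ``t`` months."""
    if r < 0.0:
        raise ValueError(f"rate must be >= 0, got {r}")
    if t <= 0.0:
        raise ValueError(f"interval must be > 0, got {t}")
    return -math.expm1(-r * t)


def rescale_prob(p: float, t1: float, t2: float) -> float:
    """Re-express a probability over ``t1`` months on a ``t2``-month basis.

    Composition of the two conversions: ``1 - (1 - p)**(t2 / t1)``.
    """
    return rate_to_prob(cumprob_to_rate(p, t1), t2)


def split_death_prob(
    p_death_total: float,
    split: DeathSplit = DeathSplit(),
    scale: str = "rate",
) -> tuple[float, float]:
    """Split a total monthly death probability into cause components.

    With ``scale="rate"`` (default) the split fractions are applied to the
    hazard, then each component hazard is converted back to a monthly
    probability; the component hazards sum exactly to the total hazard and
    the component probabilities sum to at most ``p_death_total``.  With
    ``scale="probability"`` the fractions multiply the probability directly
    (the components then sum exactly to ``p_death_total``).
    """
    if scale not in ("rate", "probability"):
        raise ValueError(f"unknown split scale {scale!r}")
    if scale == "probability":
        if not 0.0 <= p_death_total < 1.0:
            raise ValueError(
                f"probability must be in [0, 1), got {p_death_total}"
            )
        return (split.f_incidence * p_death_total,
                split.f_progression * p_death_total)
    r = cumprob_to_rate(p_death_total, 1.0)
    return (rate_to_prob(split.f_incidence * r, 1.0),
            rate_to_prob(split.f_progression * r, 1.0))
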