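"""Synthetic arms and closed-form scenarios for testing every stage.

Random arms carry the statistical structure the analysis assumes — valid
probability vectors, positive tiered costs, utilities in (0, 1] — with
sampling ranges bracketing the base-case magnitudes by roughly an order of
magnitude either way (costs log-uniform on [500, 50,000] QAR per cycle,
utilities uniform on (0.3, 0.95], monthly transition probabilities uniform
on [0, 0.1], adverse-event probabilities uniform on [0, 0.06]).  Generation
is reproducible from a single explicit seed; no global randomness.

Closed-form scenarios pair degenerate inputs with the analytically exact
totals the engine must reproduce; they drive engine-equivalence tests.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field as dc_field

import numpy as np

from .constants import MONTHS_PER_YEAR
from .inputs import (
    UTILITY_BEARING_AES,
    AdverseEventProfile,
    DoseTierCost,
    ModelInputs,
    ModelSettings,
    TreatmentArm,
    is_probability_path,
    set_path,
    get_path,
    validate_arm,
)

__all__ = [
    "ScenarioSpec",
    "GenerationError",
    "PerturbationError",
    "gen_random_arm",
    "gen_random_inputs",
    "gen_closed_form_scenario",
    "perturb_inputs",
]

_DEFAULT_RANGES = {
    "cost": (500.0, 50_000.0),        # log-uniform, QAR per cycle
    "utility": (0.3, 0.95),           # uniform
    "transition_prob": (0.0, 0.1),    # uniform, per month
    "ae_prob": (0.0, 0.06),           # uniform, per month
}


class GenerationError(RuntimeError):
    """Rejection sampling failed to produce a valid arm (bad ranges)."""


class PerturbationError(ValueError):
    """A perturbation pushed a probability outside [0, 1]."""


@dataclass(frozen=True)
class ScenarioSpec:
    """Reproducible sampling specification for synthetic arms."""

    seed: int
    n_arms: int = 4
    ranges: dict = dc_field(default_factory=lambda: dict(_DEFAULT_RANGES))
    immortal: bool = False     # all death probabilities forced to zero
    max_attempts: int = 1000


def _loguniform(rng: np.random.Generator, lo: float, hi: float) -> float:
    return float(np.exp(rng.uniform(np.log(lo), np.log(hi))))


def gen_random_arm(spec: ScenarioSpec, index: int = 0) -> TreatmentArm:
    """Sample one valid synthetic arm, deterministically in (seed, index).

    Rejection-samples until :func:`markovcea.inputs.validate_arm` returns
    no diagnostics, up to ``spec.max_attempts`` attempts.
    """
    rng = np.random.default_rng([spec.seed, index])
    c_lo, c_hi = spec.ranges["cost"]
    u_lo, u_hi = spec.ranges["utility"]
    t_lo, t_hi = spec.ranges["transition_prob"]
    a_lo, a_hi = spec.ranges["ae_prob"]
    for _ in range(spec.max_attempts):
        # Reduced tiers cost at most the full dose, never below the floor.
        tier0 = _loguniform(rng, c_lo, c_hi)
        tier1 = _loguniform(rng, c_lo, tier0)
        tier2 = _loguniform(rng, c_lo, tier1)
        death = 0.0 if spec.immortal else None
        arm = TreatmentArm(
            name=f"synthetic_{spec.seed}_{index}",
            tier_costs=[DoseTierCost(tier=t, cycle_cost=c)
                        for t, c in enumerate((tier0, tier1, tier2))],
            pd_cycle_cost=_loguniform(rng, c_lo, c_hi),
            u_pfs=float(rng.uniform(u_lo, u_hi)),
            u_pd=float(rng.uniform(u_lo, u_hi)),
            p_prog=float(rng.uniform(t_lo, t_hi)),
            p_pfs_death=(death if death is not None
                         else float(rng.uniform(t_lo, t_hi))),
            p_pd_death=(death if death is not None
                        else float(rng.uniform(t_lo, t_hi))),
            p_reduce1=float(rng.uniform(t_lo, t_hi)),
            p_reduce2=float(rng.uniform(t_lo, t_hi)),
            p_disc=float(rng.uniform(t_lo, t_hi)),
            ae_profiles=[
                AdverseEventProfile(
                    name=name,
                    monthly_prob=float(rng.uniform(a_lo, a_hi)),
                    utility=float(rng.uniform(u_lo, u_hi)),
                )
                for name in UTILITY_BEARING_AES
            ],
        )
        if not validate_arm(arm):
            return arm
    raise GenerationError(
        f"no valid arm after {spec.max_attempts} attempts; sampling ranges "
        "are pathological"
    )


def gen_random_inputs(spec: ScenarioSpec,
                      settings: ModelSettings | None = None) -> ModelInputs:
    """A full synthetic configuration with ``spec.n_arms`` arms."""
    return ModelInputs(
        settings=settings or ModelSettings(),
        arms=[gen_random_arm(spec, i) for i in range(spec.n_arms)],
    )


def gen_closed_form_scenario(
    kind: str,
) -> tuple[TreatmentArm, ModelSettings, dict]:
    """A degenerate scenario plus its analytically exact totals.

    Kinds:

    * ``immortal_full_health`` — no transitions, utility 1, no discounting,
      120 cycles: exactly 10 QALYs and 120x the cycle cost.
    * ``two_state_geometric`` — a single PFS state emptying into death with
      monthly probability q = 0.05, no correction, no discounting: expected
      person-months follow the geometric series
      ``(1 - q)(1 - (1 - q)^T) / q``.
    * ``single_cycle`` — one cycle with the half-cycle correction and 3%
      annual discounting: totals are a one-step hand calculation.
    """
    if kind == "immortal_full_health":
        cost = 1_000.0
        arm = TreatmentArm(
            name="immortal_full_health",
            tier_costs=[DoseTierCost(tier=0, cycle_cost=cost)],
            pd_cycle_cost=1_000.0,
            u_pfs=1.0, u_pd=1.0,
            p_prog=0.0, p_pfs_death=0.0, p_pd_death=0.0,
            p_reduce1=0.0, p_reduce2=0.0, p_disc=0.0,
        )
        settings = ModelSettings(horizon_cycles=120,
                                 annual_discount_rate=0.0,
                                 wcc_method="half_cycle")
        expected = {"total_qaly": 10.0, "total_cost": 120 * cost}
        return arm, settings, expected
    if kind == "two_state_geometric":
        q, horizon, cost, u = 0.05, 120, 2_000.0, 0.8
        arm = TreatmentArm(
            name="two_state_geometric",
            tier_costs=[DoseTierCost(tier=0, cycle_cost=cost)],
            pd_cycle_cost=1.0,
            u_pfs=u, u_pd=0.5,
            p_prog=0.0, p_pfs_death=q, p_pd_death=0.0,
            p_reduce1=0.0, p_reduce2=0.0, p_disc=0.0,
        )
        settings = ModelSettings(horizon_cycles=horizon,
                                 annual_discount_rate=0.0,
                                 wcc_method="none")
        person_months = (1 - q) * (1 - (1 - q) ** horizon) / q
        expected = {
            "person_months_pfs": person_months,
            "total_cost": person_months * cost,
            "total_qaly": person_months * u / MONTHS_PER_YEAR,
        }
        return arm, settings, expected
    if kind == "single_cycle":
        cost_pfs, cost_pd, u_pfs, u_pd = 3_000.0, 1_500.0, 0.9, 0.5
        p_prog, p_death, rate = 0.2, 0.1, 0.03
        arm = TreatmentArm(
            name="single_cycle",
            tier_costs=[DoseTierCost(tier=0, cycle_cost=cost_pfs)],
            pd_cycle_cost=cost_pd,
            u_pfs=u_pfs, u_pd=u_pd,
            p_prog=p_prog, p_pfs_death=p_death, p_pd_death=0.3,
            p_reduce1=0.0, p_reduce2=0.0, p_disc=0.0,
        )
        settings = ModelSettings(horizon_cycles=1,
                                 annual_discount_rate=rate,
                                 wcc_method="half_cycle")
        d = (1 + rate) ** (-1 / MONTHS_PER_YEAR)
        stay = 1 - p_prog - p_death
        credit_pfs = (1 + stay) / 2
        credit_pd = p_prog / 2
        expected = {
            "total_cost": d * (credit_pfs * cost_pfs + credit_pd * cost_pd),
            "total_qaly": d * (credit_pfs * u_pfs + credit_pd * u_pd)
                          / MONTHS_PER_YEAR,
        }
        return arm, settings, expected
    raise ValueError(f"unknown closed-form scenario kind {kind!r}")


def perturb_inputs(
    base: ModelInputs,
    path: str,
    factor: float | None = None,
    value: float | None = None,
) -> ModelInputs:
    """Deep-copied inputs with one scalar scaled (``factor``) or replaced
    (``value``); the original is untouched.  A probability pushed outside
    [0, 1] raises :class:`PerturbationError`.
    """
    if (factor is None) == (value is None):
        raise ValueError("pass exactly one of factor= or value=")
    base = copy.deepcopy(base)
    new = get_path(base, path) * factor if factor is not None else value
    if is_probability_path(path) and not 0.0 <= new <= 1.0:
        raise PerturbationError(
            f"perturbing {path!r} yields probability {new:.6g} outside [0, 1]"
        )
    return set_path(base, path, new)
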