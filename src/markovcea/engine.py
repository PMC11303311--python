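"""Cohort-trace engine: transition structure, trace, accumulation.

State space per arm: one progression-free state per dose tier
(``PFS_T0`` full dose, ``PFS_T1``/``PFS_T2`` after the first/second
mandated reduction; a single ``PFS_T0`` for the letrozole-monotherapy arm),
a progressed-disease state ``PD`` and an absorbing ``DEAD`` state.
Transitions are unidirectional in the coarse ordering PFS -> PD -> DEAD and
dose tiers only move downward.

Routing conventions (single multinomial row per state, probabilities used
as printed, never renormalized):

* from every PFS tier, to ``DEAD`` with ``p_pfs_death`` and to ``PD`` with
  ``p_prog + p_disc`` — toxicity-driven discontinuation moves the patient
  to the next treatment line, which lives in the PD state's costs and
  utility;
* among survivors in PFS, tier hops ``T0 -> T1`` with ``p_reduce1`` and
  ``T1 -> T2`` with ``p_reduce2`` (no further reduction from T2);
* residual mass stays in the current tier; if the explicit outflows exceed
  one the arm is infeasible and an error names the tier.

The cohort starts fully in ``PFS_T0``.  Per-cycle credit under the
half-cycle correction is the average of the adjacent occupancy rows
(end-of-cycle occupancy when the correction is off); the discount factor
for cycle ``k`` (0-based) is ``(1 + annual_rate) ** (-(k + 1) / 12)``
(end-of-cycle timing).  QALYs credit utility-weighted person-time at 1/12
year per one-month cycle.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .constants import MONTHS_PER_YEAR, TOL_OCCUPANCY, TOL_ROW_SUM
from .inputs import ModelSettings, TreatmentArm, validate_arm

__all__ = [
    "PD",
    "DEAD",
    "InfeasibleArmError",
    "StateSpace",
    "TransitionMatrix",
    "CohortTrace",
    "ArmResult",
    "state_space",
    "build_transition_matrix",
    "effective_cycle_utility",
    "run_trace",
    "accumulate",
    "run_arm",
    "trace_frame",
]

PD = "PD"
DEAD = "DEAD"


class InfeasibleArmError(ValueError):
    """An arm's explicit outflow probabilities exceed one somewhere."""


@dataclass(frozen=True)
class StateSpace:
    """Ordered state labels for one arm."""

    labels: tuple[str, ...]

    @property
    def n(self) -> int:
        return len(self.labels)

    @property
    def pfs_indices(self) -> tuple[int, ...]:
        return tuple(i for i, s in enumerate(self.labels)
                     if s.startswith("PFS"))

    @property
    def pd_index(self) -> int:
        return self.labels.index(PD)

    @property
    def dead_index(self) -> int:
        return self.labels.index(DEAD)

    def index(self, label: str) -> int:
        return self.labels.index(label)


def state_space(arm: TreatmentArm) -> StateSpace:
    pfs = tuple(f"PFS_T{t}" for t in range(arm.n_tiers))
    return StateSpace(labels=pfs + (PD, DEAD))


@dataclass(frozen=True)
class TransitionMatrix:
    """One-cycle stochastic kernel over an arm's state space."""

    states: StateSpace
    matrix: np.ndarray

    def __post_init__(self) -> None:
        m = self.matrix
        if m.shape != (self.states.n, self.states.n):
            raise ValueError("matrix shape does not match state space")
        if (m < 0).any():
            raise ValueError("transition probabilities must be non-negative")
        if np.abs(m.sum(axis=1) - 1.0).max() > TOL_ROW_SUM:
            raise ValueError("transition-matrix rows must sum to 1")


def build_transition_matrix(arm: TreatmentArm) -> TransitionMatrix:
    """Assemble the one-cycle kernel for an arm.

    Raises :class:`InfeasibleArmError` (naming the tier) when a row's
    explicit outflow exceeds one; rows are never silently rescaled.
    """
    ss = state_space(arm)
    n = ss.n
    m = np.zeros((n, n))
    n_tiers = arm.n_tiers
    for tier in range(n_tiers):
        row = tier
        to_pd = arm.p_prog + arm.p_disc
        hop = 0.0
        if tier == 0 and n_tiers > 1:
            hop = arm.p_reduce1
        elif tier == 1 and n_tiers > 2:
            hop = arm.p_reduce2
        out = to_pd + arm.p_pfs_death + hop
        if out > 1.0:
            raise InfeasibleArmError(
                f"arm {arm.name!r}: outflow from PFS tier {tier} is "
                f"{out:.6g} > 1"
            )
        if hop:
            m[row, tier + 1] = hop
        m[row, ss.pd_index] = to_pd
        m[row, ss.dead_index] = arm.p_pfs_death
        m[row, row] = 1.0 - out
    if arm.p_pd_death > 1.0:  # unreachable under field validation; explicit
        raise InfeasibleArmError(f"arm {arm.name!r}: p_pd_death > 1")
    m[ss.pd_index, ss.dead_index] = arm.p_pd_death
    m[ss.pd_index, ss.pd_index] = 1.0 - arm.p_pd_death
    m[ss.dead_index, ss.dead_index] = 1.0
    return TransitionMatrix(states=ss, matrix=m)


def effective_cycle_utility(arm: TreatmentArm, state: str) -> float:
    """Utility credited per cycle spent in ``state``.

    Progression-free tiers mix the baseline PFS utility with the absolute
    utilities of the grade-3/4 adverse events, treating the utility-bearing
    events as mutually exclusive within a cycle:
    ``(1 - sum_j p_j) * u_pfs + sum_j p_j * u_j``.  Events without a
    utility value (QTc prolongation) never enter the mixture.  The
    progressed state credits ``u_pd``; death credits zero.
    """
    if state == DEAD:
        return 0.0
    if state == PD:
        return arm.u_pd
    if not state.startswith("PFS"):
        raise KeyError(f"unknown state {state!r}")
    aes = list(arm.utility_bearing_aes())
    mass = sum(p.monthly_prob for p in aes)
    if mass >= 1.0:
        raise InfeasibleArmError(
            f"arm {arm.name!r}: utility-bearing AE probabilities sum to "
            f"{mass:.6g} >= 1"
        )
    return (1.0 - mass) * arm.u_pfs + sum(
        p.monthly_prob * p.utility for p in aes
    )


@dataclass
class CohortTrace:
    """Occupancy and discounted per-cycle accumulators for one arm."""

    states: StateSpace
    occupancy: np.ndarray          # (horizon + 1, n_states); row 0 = entry
    cycle_state_cost: np.ndarray   # (horizon, n_states), discounted QAR
    cycle_state_qaly: np.ndarray   # (horizon, n_states), discounted QALYs
    settings: ModelSettings

    @property
    def cycle_cost(self) -> np.ndarray:
        return self.cycle_state_cost.sum(axis=1)

    @property
    def cycle_qaly(self) -> np.ndarray:
        return self.cycle_state_qaly.sum(axis=1)

    def check_mass(self) -> None:
        err = np.abs(self.occupancy.sum(axis=1) - 1.0).max()
        if err > TOL_OCCUPANCY:
            raise AssertionError(f"occupancy mass drift {err:g}")


@dataclass
class ArmResult:
    """Discounted totals (and per-state splits) for one arm."""

    name: str
    total_cost: float
    total_qaly: float
    pfs_cost: float
    pd_cost: float
    pfs_qaly: float
    pd_qaly: float
    trace: CohortTrace = field(repr=False)
    settings: ModelSettings = field(repr=False, default=None)


def run_trace(arm: TreatmentArm, settings: ModelSettings) -> CohortTrace:
    """Run the cohort trace over the full horizon.

    The arm must be feasible (see :func:`markovcea.inputs.validate_arm`);
    infeasibility raises rather than renormalizes.
    """
    diags = validate_arm(arm, settings)
    infeasible = [d for d in diags if d.rule == "outflow_feasibility"]
    if infeasible:
        raise InfeasibleArmError("; ".join(d.message for d in infeasible))
    tm = build_transition_matrix(arm)
    ss = tm.states
    horizon = settings.horizon_cycles
    occ = np.zeros((horizon + 1, ss.n))
    occ[0, 0] = 1.0
    for k in range(horizon):
        occ[k + 1] = occ[k] @ tm.matrix

    costs = np.array(
        [arm.tier_cost(t) for t in range(arm.n_tiers)]
        + [arm.pd_cycle_cost, 0.0]
    )
    utils = np.array([effective_cycle_utility(arm, s) for s in ss.labels])

    k = np.arange(horizon)
    discount = (1.0 + settings.annual_discount_rate) ** (
        -(k + 1) * settings.cycle_length_months / MONTHS_PER_YEAR
    )
    if settings.wcc_method == "half_cycle":
        credit = 0.5 * (occ[:-1] + occ[1:])
    else:
        credit = occ[1:]
    months_per_cycle = settings.cycle_length_months
    cycle_state_cost = discount[:, None] * credit * costs[None, :]
    cycle_state_qaly = (
        discount[:, None] * credit * utils[None, :]
        * months_per_cycle / MONTHS_PER_YEAR
    )
    return CohortTrace(states=ss, occupancy=occ,
                       cycle_state_cost=cycle_state_cost,
                       cycle_state_qaly=cycle_state_qaly,
                       settings=settings)


def accumulate(trace: CohortTrace, arm: TreatmentArm) -> ArmResult:
    """Sum cycle contributions into per-arm totals; PFS pools all tiers."""
    ss = trace.states
    pfs = list(ss.pfs_indices)
    pdx = ss.pd_index
    pfs_cost = float(trace.cycle_state_cost[:, pfs].sum())
    pd_cost = float(trace.cycle_state_cost[:, pdx].sum())
    pfs_qaly = float(trace.cycle_state_qaly[:, pfs].sum())
    pd_qaly = float(trace.cycle_state_qaly[:, pdx].sum())
    return ArmResult(
        name=arm.name,
        total_cost=float(trace.cycle_state_cost.sum()),
        total_qaly=float(trace.cycle_state_qaly.sum()),
        pfs_cost=pfs_cost,
        pd_cost=pd_cost,
        pfs_qaly=pfs_qaly,
        pd_qaly=pd_qaly,
        trace=trace,
        settings=trace.settings,
    )


def run_arm(arm: TreatmentArm, settings: ModelSettings) -> ArmResult:
    """Convenience: trace then accumulate."""
    return accumulate(run_trace(arm, settings), arm)


def trace_frame(trace: CohortTrace) -> pd.DataFrame:
    """Tabulate a trace: occupancy, per-cycle and cumulative cost/QALY."""
    horizon = trace.cycle_state_cost.shape[0]
    df = pd.DataFrame(trace.occupancy[1:], columns=list(trace.states.labels))
    df.insert(0, "cycle", np.arange(1, horizon + 1))
    df["cycle_cost"] = trace.cycle_cost
    df["cycle_qaly"] = trace.cycle_qaly
    df["cum_cost"] = df["cycle_cost"].cumsum()
    df["cum_qaly"] = df["cycle_qaly"].cumsum()
    return df
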