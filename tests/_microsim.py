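"""Per-individual microsimulation oracle for the cohort engine.

Deliberately independent of the engine: per-state outcome distributions
and the adverse-event utility mixture are re-derived here directly from
the arm fields, and expectations are estimated by simulating individual
patient paths rather than by cohort linear algebra.  Run with the
within-cycle correction off (end-of-cycle state credit), which is the
convention an individual-path simulation realizes naturally.
"""

from __future__ import annotations

import numpy as np

from markovcea.inputs import ModelSettings, TreatmentArm


def _state_rows(arm: TreatmentArm) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(cumulative outcome matrix, cycle costs, cycle utilities) per state."""
    nt = arm.n_tiers
    n = nt + 2
    pd_i, dead_i = nt, nt + 1
    rows = np.zeros((n, n))
    for tier in range(nt):
        hop = 0.0
        if tier == 0 and nt > 1:
            hop = arm.p_reduce1
        elif tier == 1 and nt > 2:
            hop = arm.p_reduce2
        if hop:
            rows[tier, tier + 1] = hop
        rows[tier, pd_i] = arm.p_prog + arm.p_disc
        rows[tier, dead_i] = arm.p_pfs_death
        rows[tier, tier] = 1.0 - hop - rows[tier, pd_i] - arm.p_pfs_death
    rows[pd_i, dead_i] = arm.p_pd_death
    rows[pd_i, pd_i] = 1.0 - arm.p_pd_death
    rows[dead_i, dead_i] = 1.0

    aes = [p for p in arm.ae_profiles if p.utility is not None]
    mass = sum(p.monthly_prob for p in aes)
    u_pfs = (1.0 - mass) * arm.u_pfs + sum(
        p.monthly_prob * p.utility for p in aes
    )
    costs = np.array([arm.tier_cost(t) for t in range(nt)]
                     + [arm.pd_cycle_cost, 0.0])
    utils = np.array([u_pfs] * nt + [arm.u_pd, 0.0])
    return np.cumsum(rows, axis=1), costs, utils


def simulate_total_qaly(
    arm: TreatmentArm,
    settings: ModelSettings,
    n_patients: int,
    seed: int,
) -> tuple[float, float]:
    """Monte-Carlo estimate of discounted total QALYs per patient.

    Returns ``(mean, standard_error)``.  Requires
    ``settings.wcc_method == "none"`` (end-of-cycle credit).
    """
    assert settings.wcc_method == "none"
    cum, _costs, utils = _state_rows(arm)
    rng = np.random.default_rng(seed)
    horizon = settings.horizon_cycles
    state = np.zeros(n_patients, dtype=np.int64)
    qaly = np.zeros(n_patients)
    n_states = cum.shape[0]
    for k in range(horizon):
        u = rng.random(n_patients)
        new = np.empty_like(state)
        for s in range(n_states):
            mask = state == s
            if mask.any():
                new[mask] = np.searchsorted(cum[s], u[mask], side="right")
        np.clip(new, 0, n_states - 1, out=new)
        state = new
        disc = (1.0 + settings.annual_discount_rate) ** (-(k + 1) / 12.0)
        qaly += disc * utils[state] / 12.0
    return float(qaly.mean()), float(qaly.std(ddof=1) / np.sqrt(n_patients))
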