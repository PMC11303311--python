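"""Incremental cost-effectiveness analysis: ICERs, dominance, league table.

For an intervention *a* against a comparator *b*, the incremental cost
``dC = C_a - C_b`` and incremental effectiveness ``dE = E_a - E_b`` define
the ICER ``dC / dE`` whenever the two increments share a sign and the
effectiveness difference is above reporting precision.  An intervention
that is cheaper and more effective dominates; costlier and less effective
is dominated.  In the "cheaper but less effective" quadrant the ICER is
reported from the costlier arm's perspective (cost per QALY gained by the
costlier arm), and the costlier arm is preferred iff that ICER is at or
below the willingness-to-pay.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from itertools import combinations
from typing import Optional, Sequence

import pandas as pd

from .constants import EPS_COST, EPS_QALY
from .engine import ArmResult

__all__ = [
    "Dominance",
    "Decision",
    "ComparisonResult",
    "SettingsMismatchError",
    "compare",
    "league_table",
    "league_frame",
    "arm_results_frame",
]


class Dominance(str, Enum):
    DOMINANT = "dominant"
    DOMINATED = "dominated"
    ICER_DEFINED = "icer_defined"
    EQUAL = "equal"


class Decision(str, Enum):
    COST_EFFECTIVE = "cost_effective"
    NOT_COST_EFFECTIVE = "not_cost_effective"
    DOMINANT = "dominant"
    DOMINATED = "dominated"


class SettingsMismatchError(ValueError):
    """Compared arm results were produced under different model settings."""


@dataclass(frozen=True)
class ComparisonResult:
    """Incremental comparison of one ordered pair of arms."""

    intervention: str
    comparator: str
    delta_cost: float
    delta_qaly: float
    icer: Optional[float]
    dominance: Dominance
    decision_at_wtp: Decision
    wtp: float

    @property
    def preferred(self) -> str:
        """Arm chosen at the willingness-to-pay threshold."""
        if self.decision_at_wtp in (Decision.DOMINANT,
                                    Decision.COST_EFFECTIVE):
            return self.intervention
        return self.comparator


def compare(a: ArmResult, b: ArmResult, wtp: float) -> ComparisonResult:
    """Compare intervention ``a`` against comparator ``b`` at a WTP.

    Both results must stem from identical model settings.
    """
    if a.settings is not None and b.settings is not None \
            and a.settings != b.settings:
        raise SettingsMismatchError(
            f"arm results {a.name!r} and {b.name!r} were run under "
            "different model settings"
        )
    d_cost = a.total_cost - b.total_cost
    d_qaly = a.total_qaly - b.total_qaly
    cost_tie = abs(d_cost) <= EPS_COST
    qaly_tie = abs(d_qaly) <= EPS_QALY

    icer: Optional[float] = None
    if cost_tie and qaly_tie:
        dom = Dominance.EQUAL
        decision = Decision.COST_EFFECTIVE  # either arm; intervention kept
    elif qaly_tie:
        # Equal effectiveness: the cheaper arm (weakly) dominates.
        dom = Dominance.DOMINANT if d_cost < 0 else Dominance.DOMINATED
        decision = (Decision.DOMINANT if d_cost < 0 else Decision.DOMINATED)
    elif d_qaly > EPS_QALY and d_cost < EPS_COST:
        dom = Dominance.DOMINANT
        decision = Decision.DOMINANT
    elif d_qaly < -EPS_QALY and d_cost > -EPS_COST:
        dom = Dominance.DOMINATED
        decision = Decision.DOMINATED
    else:
        # Same-sign increments: a genuine trade-off with a defined ICER.
        dom = Dominance.ICER_DEFINED
        icer = d_cost / d_qaly
        if d_qaly > 0:
            # More effective, more costly: worth it iff ICER <= WTP.
            decision = (Decision.COST_EFFECTIVE if icer <= wtp
                        else Decision.NOT_COST_EFFECTIVE)
        else:
            # Cheaper, less effective: the ICER reads as the costlier
            # comparator's cost per QALY gained; the savings justify the
            # forgone QALYs iff that ICER exceeds the WTP.
            decision = (Decision.COST_EFFECTIVE if icer > wtp
                        else Decision.NOT_COST_EFFECTIVE)
    return ComparisonResult(
        intervention=a.name, comparator=b.name,
        delta_cost=d_cost, delta_qaly=d_qaly,
        icer=icer, dominance=dom, decision_at_wtp=decision, wtp=wtp,
    )


def league_table(
    results: Sequence[ArmResult],
    wtp: float,
    reference: str = "letrozole",
) -> list[ComparisonResult]:
    """All vs-reference comparisons plus pairwise non-reference comparisons.

    Mirrors the published layout: each active arm against the reference
    strategy, then every ordered-by-input pair among the active arms.
    """
    if len(results) < 2:
        raise ValueError("league_table needs at least two arm results")
    by_name = {r.name: r for r in results}
    rows: list[ComparisonResult] = []
    if reference is not None and reference in by_name:
        ref = by_name[reference]
        for r in results:
            if r.name != reference:
                rows.append(compare(r, ref, wtp))
        others = [r for r in results if r.name != reference]
    else:
        others = list(results)
    for a, b in combinations(others, 2):
        rows.append(compare(a, b, wtp))
    return rows


def league_frame(rows: Sequence[ComparisonResult]) -> pd.DataFrame:
    """Tabulate comparison rows with report rounding (whole QAR)."""
    from .reporting import round_qar

    recs = []
    for r in rows:
        recs.append({
            "intervention": r.intervention,
            "comparator": r.comparator,
            "delta_cost": round_qar(r.delta_cost),
            "delta_qaly": round(r.delta_qaly, 4),
            "icer": round_qar(r.icer) if r.icer is not None else None,
            "dominance": r.dominance.value,
            "decision_at_wtp": r.decision_at_wtp.value,
            "preferred": r.preferred,
        })
    return pd.DataFrame.from_records(recs)


def arm_results_frame(results: Sequence[ArmResult]) -> pd.DataFrame:
    """Per-arm totals in the published row structure (whole-QAR costs)."""
    from .reporting import round_qar

    recs = []
    for r in results:
        recs.append({
            "arm": r.name,
            "total_cost": round_qar(r.total_cost),
            "pfs_cost": round_qar(r.pfs_cost),
            "pd_cost": round_qar(r.pd_cost),
            "total_qaly": round(r.total_qaly, 4),
            "pfs_qaly": round(r.pfs_qaly, 4),
            "pd_qaly": round(r.pd_qaly, 4),
        })
    return pd.DataFrame.from_records(recs)
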