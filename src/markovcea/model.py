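"""Model/results facade over the cohort engine.

:class:`MarkovCohortCEA` bundles the treatment arms and model settings;
``fit()`` evaluates the cohort trace for every arm and returns a
:class:`CEAResults` carrying the discounted totals, the pairwise league
table, the sensitivity-analysis entry points and a printable summary.
The evaluation is deterministic — "fitting" here means running the
decision-analytic model, not estimating parameters from data.

Example
-------
>>> from markovcea import MarkovCohortCEA
>>> model = MarkovCohortCEA.base_case()
>>> res = model.fit()
>>> print(res.summary())            # doctest: +SKIP
"""

from __future__ import annotations

from pathlib import Path
from typing import Optional, Sequence

import pandas as pd

from .cea import (
    ComparisonResult,
    arm_results_frame,
    compare,
    league_frame,
    league_table,
)
from .engine import ArmResult, run_arm, trace_frame
from .inputs import (
    ModelInputs,
    ModelSettings,
    TreatmentArm,
    load_model_inputs,
    packaged_base_case,
    validate_arm,
)
from .reporting import discount_scan, round_qar, round_qaly
from .sensitivity import (
    DSAParameter,
    DSAReport,
    ThresholdResult,
    run_dsa,
    threshold_search,
    tornado,
)

__all__ = ["MarkovCohortCEA", "CEAResults"]


class MarkovCohortCEA:
    """A multi-arm Markov cohort cost-effectiveness model."""

    def __init__(
        self,
        arms: Sequence[TreatmentArm],
        settings: ModelSettings | None = None,
        reference: Optional[str] = "letrozole",
    ) -> None:
        self.settings = settings or ModelSettings()
        self.arms = list(arms)
        if len(self.arms) < 1:
            raise ValueError("at least one treatment arm is required")
        self.reference = reference if reference in [a.name for a in self.arms] \
            else None
        diagnostics = {
            a.name: validate_arm(a, self.settings) for a in self.arms
        }
        bad = {n: d for n, d in diagnostics.items() if d}
        if bad:
            msgs = "; ".join(
                f"{n}: {', '.join(map(str, d))}" for n, d in bad.items()
            )
            raise ValueError(f"invalid arms: {msgs}")

    # -- constructors ----------------------------------------------------

    @classmethod
    def from_inputs(cls, inputs: ModelInputs,
                    reference: Optional[str] = "letrozole"
                    ) -> "MarkovCohortCEA":
        return cls(arms=inputs.arms, settings=inputs.settings,
                   reference=reference)

    @classmethod
    def from_yaml(cls, path: str | Path,
                  reference: Optional[str] = "letrozole"
                  ) -> "MarkovCohortCEA":
        return cls.from_inputs(load_model_inputs(path), reference=reference)

    @classmethod
    def base_case(cls) -> "MarkovCohortCEA":
        """The packaged base case: three CDK4/6 inhibitor arms (each with
        letrozole) versus letrozole monotherapy, published inputs."""
        return cls.from_inputs(packaged_base_case())

    # -- evaluation ------------------------------------------------------

    @property
    def inputs(self) -> ModelInputs:
        return ModelInputs(settings=self.settings, arms=self.arms)

    def fit(self) -> "CEAResults":
        """Evaluate every arm's cohort trace and build the results."""
        results = [run_arm(a, self.settings) for a in self.arms]
        return CEAResults(self, results)

    run = fit  # alias: this model is evaluated, not estimated


class CEAResults:
    """Fitted (evaluated) model results."""

    def __init__(self, model: MarkovCohortCEA,
                 arm_results: Sequence[ArmResult]) -> None:
        self.model = model
        self.settings = model.settings
        self.arm_results = {r.name: r for r in arm_results}

    # -- accessors -------------------------------------------------------

    def __getitem__(self, arm_name: str) -> ArmResult:
        return self.arm_results[arm_name]

    def totals_frame(self) -> pd.DataFrame:
        return arm_results_frame(list(self.arm_results.values()))

    def trace_frame(self, arm_name: str) -> pd.DataFrame:
        return trace_frame(self.arm_results[arm_name].trace)

    # -- comparisons -----------------------------------------------------

    def compare(self, intervention: str, comparator: str,
                wtp: Optional[float] = None) -> ComparisonResult:
        return compare(self.arm_results[intervention],
                       self.arm_results[comparator],
                       wtp if wtp is not None else self.settings.wtp)

    def league_table(self, wtp: Optional[float] = None
                     ) -> list[ComparisonResult]:
        return league_table(
            list(self.arm_results.values()),
            wtp if wtp is not None else self.settings.wtp,
            reference=self.model.reference,
        )

    def league_frame(self, wtp: Optional[float] = None) -> pd.DataFrame:
        return league_frame(self.league_table(wtp))

    # -- sensitivity -----------------------------------------------------

    def run_dsa(self, params: Sequence[DSAParameter],
                comparison: tuple[str, str],
                wtp: Optional[float] = None) -> DSAReport:
        return run_dsa(self.model.inputs, params, comparison, wtp)

    def tornado(self, params: Sequence[DSAParameter],
                comparison: tuple[str, str],
                wtp: Optional[float] = None) -> pd.DataFrame:
        return tornado(self.model.inputs, params, comparison, wtp)

    def threshold_search(self, path: str, comparison: tuple[str, str],
                         lo: float, hi: float,
                         wtp: Optional[float] = None) -> ThresholdResult:
        return threshold_search(self.model.inputs, path, comparison, lo, hi,
                                wtp)

    def discount_scan(self, rates: Sequence[float] = (0.0, 0.03, 0.035)
                      ) -> pd.DataFrame:
        return discount_scan(self.model.inputs, rates)

    # -- presentation ----------------------------------------------------

    def summary(self, wtp: Optional[float] = None) -> str:
        """A printable report: per-arm totals and the league table."""
        wtp = wtp if wtp is not None else self.settings.wtp
        s = self.settings
        lines = [
            "Markov cohort cost-effectiveness results",
            "=" * 56,
            f"horizon: {s.horizon_cycles} cycles of "
            f"{s.cycle_length_months:g} month(s); discount "
            f"{s.annual_discount_rate:.1%}/yr; correction: {s.wcc_method}",
            f"willingness-to-pay: {round_qar(wtp):,} "
            f"{s.currency_label}/QALY",
            "",
            "Per-arm discounted totals",
            "-" * 56,
        ]
        for r in self.arm_results.values():
            lines.append(
                f"{r.name:<14s} cost {round_qar(r.total_cost):>12,} "
                f"{s.currency_label}   QALYs {round_qaly(r.total_qaly):.4f}"
            )
        lines += ["", "Pairwise comparisons", "-" * 56]
        for c in self.league_table(wtp):
            icer = (f"{round_qar(c.icer):,} {s.currency_label}/QALY"
                    if c.icer is not None else c.dominance.value)
            lines.append(
                f"{c.intervention} vs {c.comparator}: "
                f"dCost {round_qar(c.delta_cost):,}, "
                f"dQALY {c.delta_qaly:.4f}, ICER {icer} "
                f"-> {c.decision_at_wtp.value} (prefer {c.preferred})"
            )
        return "\n".join(lines)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        arms = ", ".join(self.arm_results)
        return f"<CEAResults arms=[{arms}]>"
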