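"""One-way deterministic sensitivity analysis, threshold search, tornado.

Each parameter is moved to its low and high bound with everything else at
base case (endpoint-only evaluation, matching the published tables), the
comparison of interest is re-evaluated, and the conclusion is *robust*
when the strategy preferred at the willingness-to-pay is unchanged at both
bounds and *sensitive* otherwise.  Costs vary by +/-15% of base case,
utilities and transition probabilities by +/-10% (or published confidence
bounds, entered as absolute bounds).  Transition/adverse-event
probabilities below 1% of base-case value are excluded from the analysis.

A conclusion-flip threshold is located by bisection on a single parameter,
with the flip verified on both sides of the cutoff.  The tornado table
ranks parameters by the span of the ICER across their bounds; a bound at
which the comparison is dominant/dominated carries a categorical flag
instead of a fabricated ICER.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd
import yaml

from .cea import ComparisonResult, Dominance, compare
from .engine import run_arm
from .inputs import ModelInputs, get_path, is_probability_path, set_path

__all__ = [
    "DSAParameter",
    "DSAResult",
    "DSAReport",
    "ThresholdResult",
    "NoCrossingError",
    "evaluate_comparison",
    "run_dsa",
    "threshold_search",
    "tornado",
    "load_dsa_spec",
]

#: Probability parameters below this base value are excluded from the DSA.
MIN_PROBABILITY_FOR_DSA = 0.01


@dataclass(frozen=True)
class DSAParameter:
    """One parameter to vary: a dot-path plus bounds.

    ``mode="percent"`` reads ``low``/``high`` as percent deviations from
    the base value (e.g. -15/+15); ``mode="absolute_bounds"`` reads them as
    the bound values themselves (used for published confidence intervals).
    """

    path: str
    mode: str = "percent"
    low: float = -10.0
    high: float = 10.0
    label: Optional[str] = None

    def __post_init__(self) -> None:
        if self.mode not in ("percent", "absolute_bounds"):
            raise ValueError(f"unknown DSA mode {self.mode!r}")
        if not self.low < self.high:
            raise ValueError(
                f"DSA parameter {self.path!r}: low must be < high"
            )

    def bound_values(self, base_value: float) -> tuple[float, float]:
        if self.mode == "percent":
            return (base_value * (1.0 + self.low / 100.0),
                    base_value * (1.0 + self.high / 100.0))
        return (self.low, self.high)

    @property
    def display(self) -> str:
        return self.label or self.path


@dataclass
class DSAResult:
    """Base and bound evaluations of one parameter, with the conclusion."""

    parameter: DSAParameter
    base_value: float
    value_low: float
    value_high: float
    result_low: ComparisonResult
    result_high: ComparisonResult
    conclusion: str  # "robust" | "sensitive"
    narrative: str
    clip_diagnostics: list[str] = dc_field(default_factory=list)


@dataclass
class DSAReport:
    """Full one-way DSA output for one comparison."""

    comparison: tuple[str, str]
    base: ComparisonResult
    rows: list[DSAResult]
    excluded: list[tuple[DSAParameter, str]]

    def to_frame(self) -> pd.DataFrame:
        recs = []
        for r in self.rows:
            for side, val, res in (("low", r.value_low, r.result_low),
                                   ("high", r.value_high, r.result_high)):
                recs.append({
                    "parameter": r.parameter.display,
                    "path": r.parameter.path,
                    "bound": side,
                    "value": val,
                    "delta_cost": res.delta_cost,
                    "delta_qaly": res.delta_qaly,
                    "icer": res.icer,
                    "decision": res.decision_at_wtp.value,
                    "preferred": res.preferred,
                    "conclusion": r.conclusion,
                    "narrative": r.narrative,
                })
        return pd.DataFrame.from_records(recs)


@dataclass
class ThresholdResult:
    """A verified conclusion-flip cutoff on one parameter."""

    path: str
    cutoff: float
    direction: str            # "low_to_high" decision change orientation
    icer_at_cutoff: Optional[float]
    decision_low: str
    decision_high: str


class NoCrossingError(ValueError):
    """The decision class is identical at both ends of the bracket."""


def evaluate_comparison(
    inputs: ModelInputs,
    comparison: tuple[str, str],
    wtp: Optional[float] = None,
) -> ComparisonResult:
    """Run both arms of a comparison and compare at the WTP."""
    a_name, b_name = comparison
    settings = inputs.settings
    a = run_arm(inputs.arm(a_name), settings)
    b = run_arm(inputs.arm(b_name), settings)
    return compare(a, b, wtp if wtp is not None else settings.wtp)


def _perturbed(inputs: ModelInputs, path: str, value: float
               ) -> tuple[ModelInputs, list[str]]:
    """Set a path, clipping probabilities to [0, 1] with a diagnostic."""
    diags: list[str] = []
    if is_probability_path(path):
        clipped = min(max(value, 0.0), 1.0)
        if clipped != value:
            diags.append(
                f"{path}: perturbed probability {value:.6g} clipped to "
                f"{clipped:.6g}"
            )
            value = clipped
    return set_path(inputs, path, value), diags


def _conclusion(base: ComparisonResult,
                bounds: Sequence[ComparisonResult]) -> tuple[str, str]:
    """Robust iff the preferred strategy matches base at every bound."""
    flips = [r for r in bounds if r.preferred != base.preferred]
    if not flips:
        return "robust", f"{base.preferred} remains preferred"
    labels = ", ".join(
        f"{r.preferred} preferred ({r.decision_at_wtp.value})" for r in flips
    )
    return "sensitive", f"conclusion flips at a bound: {labels}"


def run_dsa(
    inputs: ModelInputs,
    params: Sequence[DSAParameter],
    comparison: tuple[str, str],
    wtp: Optional[float] = None,
) -> DSAReport:
    """Endpoint-only one-way DSA over ``params`` for one comparison."""
    base = evaluate_comparison(inputs, comparison, wtp)
    rows: list[DSAResult] = []
    excluded: list[tuple[DSAParameter, str]] = []
    for p in params:
        base_value = get_path(inputs, p.path)  # raises PathError if bad
        if is_probability_path(p.path) and \
                base_value < MIN_PROBABILITY_FOR_DSA:
            excluded.append(
                (p, f"base probability {base_value:.6g} < "
                    f"{MIN_PROBABILITY_FOR_DSA}")
            )
            continue
        v_low, v_high = p.bound_values(base_value)
        clip_diags: list[str] = []
        results = []
        for v in (v_low, v_high):
            pert, diags = _perturbed(inputs, p.path, v)
            clip_diags.extend(diags)
            results.append(evaluate_comparison(pert, comparison, wtp))
        conclusion, narrative = _conclusion(base, results)
        rows.append(DSAResult(
            parameter=p, base_value=base_value,
            value_low=v_low, value_high=v_high,
            result_low=results[0], result_high=results[1],
            conclusion=conclusion, narrative=narrative,
            clip_diagnostics=clip_diags,
        ))
    return DSAReport(comparison=comparison, base=base, rows=rows,
                     excluded=excluded)


def threshold_search(
    inputs: ModelInputs,
    path: str,
    comparison: tuple[str, str],
    lo: float,
    hi: float,
    wtp: Optional[float] = None,
    rel_tol: float = 1e-6,
    max_iter: int = 80,
) -> ThresholdResult:
    """Bisect for the parameter value at which the preferred arm flips.

    ``lo`` and ``hi`` are parameter *values* bracketing a decision change;
    the cutoff is refined to ``rel_tol`` relative width and verified by
    evaluating just inside each side.
    """
    if not lo < hi:
        raise ValueError("threshold bracket must have lo < hi")

    def preferred_at(value: float) -> ComparisonResult:
        pert, _ = _perturbed(inputs, path, value)
        return evaluate_comparison(pert, comparison, wtp)

    res_lo = preferred_at(lo)
    res_hi = preferred_at(hi)
    if res_lo.preferred == res_hi.preferred:
        raise NoCrossingError(
            f"no decision change for {path!r} on [{lo:g}, {hi:g}]: "
            f"{res_lo.preferred} preferred at both ends"
        )
    a, b = lo, hi
    pref_a = res_lo.preferred
    for _ in range(max_iter):
        if (b - a) <= rel_tol * max(1.0, abs(b)):
            break
        mid = 0.5 * (a + b)
        res_mid = preferred_at(mid)
        if res_mid.preferred == pref_a:
            a = mid
        else:
            b = mid
    cutoff = 0.5 * (a + b)
    width = max(b - a, rel_tol * max(1.0, abs(cutoff)))
    below = preferred_at(cutoff - width)
    above = preferred_at(cutoff + width)
    if below.preferred == above.preferred:  # pragma: no cover - defensive
        raise NoCrossingError(
            f"bisection converged at {cutoff:g} but the flip did not verify"
        )
    at = preferred_at(cutoff)
    return ThresholdResult(
        path=path, cutoff=cutoff,
        direction=f"{below.preferred}->{above.preferred}",
        icer_at_cutoff=at.icer,
        decision_low=below.decision_at_wtp.value,
        decision_high=above.decision_at_wtp.value,
    )


#: Sentinel used in tornado tables where a bound has no defined ICER.
TORNADO_FLAGS = {
    Dominance.DOMINANT: "dominant",
    Dominance.DOMINATED: "dominated",
    Dominance.EQUAL: "equal",
}


def tornado(
    inputs: ModelInputs,
    params: Sequence[DSAParameter],
    comparison: tuple[str, str],
    wtp: Optional[float] = None,
) -> pd.DataFrame:
    """Per-parameter ICER at both bounds, sorted by descending span.

    Bounds where the comparison is dominant/dominated (no ICER) carry a
    flag in ``flag_low``/``flag_high`` and do not fabricate an ICER; their
    span uses only the defined side (zero when neither is defined, sorted
    last among equals).
    """
    if not params:
        raise ValueError("tornado needs at least one parameter")
    report = run_dsa(inputs, params, comparison, wtp)
    base_icer = report.base.icer
    recs = []
    for r in report.rows:
        icer_low, icer_high = r.result_low.icer, r.result_high.icer
        flag_low = (TORNADO_FLAGS.get(r.result_low.dominance)
                    if icer_low is None else None)
        flag_high = (TORNADO_FLAGS.get(r.result_high.dominance)
                     if icer_high is None else None)
        defined = [v for v in (icer_low, icer_high) if v is not None]
        if len(defined) == 2:
            span = abs(icer_high - icer_low)
        elif len(defined) == 1 and base_icer is not None:
            span = abs(defined[0] - base_icer)
        else:
            span = 0.0
        recs.append({
            "parameter": r.parameter.display,
            "path": r.parameter.path,
            "icer_low": icer_low,
            "icer_high": icer_high,
            "flag_low": flag_low,
            "flag_high": flag_high,
            "span": span,
            "conclusion": r.conclusion,
        })
    df = pd.DataFrame.from_records(recs)
    return (df.sort_values(["span", "parameter"],
                           ascending=[False, True], kind="mergesort")
              .reset_index(drop=True))


def load_dsa_spec(path: str | Path) -> list[DSAParameter]:
    """Load a DSA parameter set from a YAML spec file."""
    raw = yaml.safe_load(Path(path).read_text())
    if not isinstance(raw, dict) or "parameters" not in raw:
        raise ValueError("DSA spec must be a mapping with a 'parameters' list")
    params = []
    for entry in raw["parameters"]:
        params.append(DSAParameter(
            path=entry["path"],
            mode=entry.get("mode", "percent"),
            low=float(entry["low"]),
            high=float(entry["high"]),
            label=entry.get("label"),
        ))
    if not params:
        raise ValueError("DSA spec lists no parameters")
    return params
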