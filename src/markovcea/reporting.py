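"""Report-layer rounding conventions, CSV/JSON writers, run manifests.

All internal arithmetic runs at full double precision; rounding happens
only here.  Monetary amounts are reported in whole QAR (half away from
zero, the usual commercial convention), QALYs to four decimals.
"""

from __future__ import annotations

import datetime as _dt
import json
import math
from dataclasses import dataclass, field as dc_field
from importlib.metadata import PackageNotFoundError, version as _pkg_version
from pathlib import Path
from typing import Optional, Sequence

from .cea import arm_results_frame, league_frame, league_table
from .engine import ArmResult, run_arm, trace_frame
from .inputs import ModelInputs

__all__ = [
    "round_qar",
    "round_qaly",
    "RunManifest",
    "write_base_case_reports",
    "discount_scan",
]


def round_qar(x: float) -> int:
    """Round a monetary amount to whole QAR, half away from zero."""
    return int(math.floor(abs(x) + 0.5)) * (1 if x >= 0 else -1)


def round_qaly(x: float, ndigits: int = 4) -> float:
    return round(x, ndigits)


def _tool_version() -> str:
    try:
        return _pkg_version("markovcea")
    except PackageNotFoundError:  # pragma: no cover - dev tree only
        return "unknown"


@dataclass
class RunManifest:
    """What a CLI run consumed and produced."""

    command: str
    config_path: str
    settings: dict
    outputs: list[str] = dc_field(default_factory=list)
    seed: Optional[int] = None
    tool_version: str = dc_field(default_factory=_tool_version)
    timestamp: str = dc_field(
        default_factory=lambda: _dt.datetime.now(_dt.timezone.utc).isoformat()
    )

    def write(self, path: Path) -> None:
        payload = {
            "command": self.command,
            "config_path": self.config_path,
            "settings": self.settings,
            "tool_version": self.tool_version,
            "timestamp": self.timestamp,
            "seed": self.seed,
            "outputs": self.outputs,
        }
        path.write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")

    def verify(self, base_dir: Path) -> list[str]:
        """Names of declared outputs missing on disk (empty when complete)."""
        return [f for f in self.outputs if not (base_dir / f).exists()]


def discount_scan(
    inputs: ModelInputs,
    rates: Sequence[float] = (0.0, 0.03, 0.035),
):
    """Per-arm totals at several annual discount rates (transparency scan).

    The published evaluation does not state its discount rate, so base-case
    reports always carry this side table.
    """
    import pandas as pd

    recs = []
    for rate in rates:
        settings = inputs.settings.model_copy(
            update={"annual_discount_rate": rate}
        )
        for arm in inputs.arms:
            r = run_arm(arm, settings)
            recs.append({
                "annual_discount_rate": rate,
                "arm": r.name,
                "total_cost": round_qar(r.total_cost),
                "total_qaly": round_qaly(r.total_qaly),
            })
    return pd.DataFrame.from_records(recs)


def write_base_case_reports(
    inputs: ModelInputs,
    out_dir: Path,
    config_path: str = "<in-memory>",
    reference: str = "letrozole",
    seed: Optional[int] = None,
) -> tuple[list[ArmResult], RunManifest]:
    """Run every arm and write the league table, traces and manifest.

    Writes ``arm_results.csv`` (per-arm totals), ``league_table.csv``
    (pairwise comparisons), one ``trace_<arm>.csv`` per arm,
    ``discount_scan.csv`` and ``manifest.json``.  CSV output is
    deterministic for identical inputs.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    settings = inputs.settings
    results = [run_arm(arm, settings) for arm in inputs.arms]
    outputs: list[str] = []

    arm_results_frame(results).to_csv(out_dir / "arm_results.csv", index=False)
    outputs.append("arm_results.csv")

    ref = reference if reference in inputs.arm_names else None
    rows = league_table(results, wtp=settings.wtp, reference=ref)
    league_frame(rows).to_csv(out_dir / "league_table.csv", index=False)
    outputs.append("league_table.csv")

    for r in results:
        name = f"trace_{r.name}.csv"
        trace_frame(r.trace).to_csv(out_dir / name, index=False,
                                    float_format="%.10g")
        outputs.append(name)

    discount_scan(inputs).to_csv(out_dir / "discount_scan.csv", index=False)
    outputs.append("discount_scan.csv")

    manifest = RunManifest(
        command="run",
        config_path=str(config_path),
        settings=settings.model_dump(),
        outputs=outputs,
        seed=seed,
    )
    manifest.write(out_dir / "manifest.json")
    return results, manifest
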