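"""Model inputs: treatment arms, settings, config loading and validation.

The model consumes a flat, explicit YAML (or JSON-equivalent) configuration
with top-level keys ``schema_version``, ``settings`` and ``arms``.  Each arm
carries per-cycle costs for up to three dose tiers (full dose, first and
second mandated reduction) plus the progressed-disease state, utility
values for the progression-free and progressed states and for the
utility-bearing grade-3/4 adverse events, and the monthly transition
probabilities driving the cohort model.  The packaged base case
(``data/base_case_inputs.yaml``) holds the published inputs of the Qatari
payer-perspective evaluation of palbociclib, ribociclib and abemaciclib
(each with letrozole) versus letrozole monotherapy, exactly as printed.

Hard range constraints (probabilities in [0, 1], positive costs) are
enforced at construction and raise validation errors naming the offending
field; softer feasibility rules (per-tier outflow, utility positivity,
adverse-event mixture mass) are reported as structured diagnostics by
:func:`validate_arm` rather than thrown.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterator, Literal, Optional

import yaml
from pydantic import BaseModel, ConfigDict, Field, ValidationError

__all__ = [
    "AE_NAMES",
    "UTILITY_BEARING_AES",
    "DoseTierCost",
    "AdverseEventProfile",
    "TreatmentArm",
    "ModelSettings",
    "ModelInputs",
    "Diagnostic",
    "load_inputs",
    "load_model_inputs",
    "loads_model_inputs",
    "packaged_base_case",
    "packaged_data_path",
    "validate_arm",
    "get_path",
    "set_path",
]

#: Adverse events tracked per arm.  QTc-prolongation events carry no
#: utility value and never enter QALY weighting; they are kept for
#: completeness and future discontinuation-logic extensions.
AE_NAMES = (
    "neutropenia_g34",
    "diarrhea_g34",
    "hepatotox_g3",
    "hepatotox_g4",
    "qtc_480_500",
    "qtc_gt_500",
)
UTILITY_BEARING_AES = (
    "neutropenia_g34",
    "diarrhea_g34",
    "hepatotox_g3",
    "hepatotox_g4",
)

AEName = Literal[
    "neutropenia_g34",
    "diarrhea_g34",
    "hepatotox_g3",
    "hepatotox_g4",
    "qtc_480_500",
    "qtc_gt_500",
]


class DoseTierCost(BaseModel):
    """Per-cycle cost of one dose tier (0 = full dose, 1/2 = reductions)."""

    model_config = ConfigDict(frozen=True)

    tier: int = Field(ge=0, le=2)
    cycle_cost: float = Field(gt=0.0, description="QAR per one-month cycle")


class AdverseEventProfile(BaseModel):
    """Monthly incidence and (optional) health-state utility of one AE."""

    model_config = ConfigDict(frozen=True)

    name: AEName
    monthly_prob: float = Field(ge=0.0, le=1.0)
    utility: Optional[float] = Field(default=None, gt=0.0, le=1.0)


class TreatmentArm(BaseModel):
    """All per-arm model inputs.

    ``p_prog``/``p_pfs_death``/``p_pd_death`` are the monthly state
    transition probabilities; ``p_reduce1``/``p_reduce2`` the monthly
    probabilities of the first (tier 0 -> 1) and second (tier 1 -> 2)
    mandated dose reduction; ``p_disc`` the monthly probability of
    toxicity-driven treatment discontinuation (which routes the patient to
    the next treatment line, i.e. the progressed-disease state).
    """

    model_config = ConfigDict(frozen=True)

    name: str
    tier_costs: list[DoseTierCost]
    pd_cycle_cost: float = Field(gt=0.0)
    u_pfs: float = Field(ge=0.0, le=1.0)
    u_pd: float = Field(ge=0.0, le=1.0)
    p_prog: float = Field(ge=0.0, le=1.0)
    p_pfs_death: float = Field(ge=0.0, le=1.0)
    p_pd_death: float = Field(ge=0.0, le=1.0)
    p_reduce1: float = Field(ge=0.0, le=1.0)
    p_reduce2: float = Field(ge=0.0, le=1.0)
    p_disc: float = Field(ge=0.0, le=1.0)
    ae_profiles: list[AdverseEventProfile] = Field(default_factory=list)

    @property
    def n_tiers(self) -> int:
        return len(self.tier_costs)

    def tier_cost(self, tier: int) -> float:
        for tc in self.tier_costs:
            if tc.tier == tier:
                return tc.cycle_cost
        raise KeyError(f"arm {self.name!r} has no tier {tier}")

    def ae(self, name: str) -> AdverseEventProfile:
        for p in self.ae_profiles:
            if p.name == name:
                return p
        raise KeyError(f"arm {self.name!r} has no adverse event {name!r}")

    def utility_bearing_aes(self) -> Iterator[AdverseEventProfile]:
        for p in self.ae_profiles:
            if p.utility is not None:
                yield p


class ModelSettings(BaseModel):
    """Global model settings.

    The base case runs 120 one-month cycles (10 years), applies the
    trapezoidal half-cycle correction, discounts at 3% per year (a
    conventional rate for cost-effectiveness analyses; configurable) and
    judges cost-effectiveness against a willingness-to-pay of 448,785 QAR
    per QALY (1.5x Qatari GDP per capita).
    """

    model_config = ConfigDict(frozen=True)

    horizon_cycles: int = Field(default=120, ge=1)
    cycle_length_months: float = Field(default=1.0, gt=0.0)
    annual_discount_rate: float = Field(default=0.03, ge=0.0, le=0.2)
    wcc_method: Literal["none", "half_cycle"] = "half_cycle"
    wtp: float = Field(default=448_785.0, gt=0.0)
    currency_label: str = "QAR"


class ModelInputs(BaseModel):
    """A full model configuration: settings plus one or more arms."""

    model_config = ConfigDict(frozen=True)

    schema_version: int = 1
    settings: ModelSettings
    arms: list[TreatmentArm]

    def arm(self, name: str) -> TreatmentArm:
        for a in self.arms:
            if a.name == name:
                return a
        raise KeyError(f"no arm named {name!r}")

    @property
    def arm_names(self) -> list[str]:
        return [a.name for a in self.arms]

    # -- config-dict (YAML) round trip -----------------------------------

    def to_config(self) -> dict:
        """Serialize to the documented flat config-dict schema."""
        arms = []
        for a in self.arms:
            costs = {f"tier{tc.tier}": tc.cycle_cost for tc in a.tier_costs}
            costs["pd"] = a.pd_cycle_cost
            ae_u = {p.name: p.utility for p in a.ae_profiles
                    if p.utility is not None}
            ae_p = {p.name: p.monthly_prob for p in a.ae_profiles}
            arms.append({
                "name": a.name,
                "costs": costs,
                "utilities": {"pfs": a.u_pfs, "pd": a.u_pd, "ae": ae_u},
                "probabilities": {
                    "prog": a.p_prog,
                    "pfs_death": a.p_pfs_death,
                    "pd_death": a.p_pd_death,
                    "reduce1": a.p_reduce1,
                    "reduce2": a.p_reduce2,
                    "disc": a.p_disc,
                    "ae": ae_p,
                },
            })
        return {
            "schema_version": self.schema_version,
            "settings": self.settings.model_dump(),
            "arms": arms,
        }

    @classmethod
    def from_config(cls, cfg: dict) -> "ModelInputs":
        """Build from the documented config-dict schema."""
        if not isinstance(cfg, dict):
            raise ConfigError("config root must be a mapping")
        for key in ("settings", "arms"):
            if key not in cfg:
                raise ConfigError(f"config is missing top-level key {key!r}")
        try:
            settings = ModelSettings(**cfg["settings"])
        except ValidationError as exc:
            raise ConfigError(f"invalid settings: {exc}") from exc
        arms = [_arm_from_config(a) for a in cfg["arms"]]
        return cls(schema_version=int(cfg.get("schema_version", 1)),
                   settings=settings, arms=arms)


class ConfigError(ValueError):
    """A configuration file violates the documented schema."""


def _arm_from_config(a: dict) -> TreatmentArm:
    for key in ("name", "costs", "utilities", "probabilities"):
        if key not in a:
            raise ConfigError(
                f"arm entry {a.get('name', '<unnamed>')!r} is missing {key!r}"
            )
    name = a["name"]
    costs = a["costs"]
    if "pd" not in costs:
        raise ConfigError(f"arm {name!r}: costs.pd is missing")
    tier_keys = sorted(k for k in costs if k.startswith("tier"))
    if not tier_keys:
        raise ConfigError(f"arm {name!r}: no tier costs present")
    tiers = []
    for k in tier_keys:
        try:
            idx = int(k.removeprefix("tier"))
        except ValueError as exc:
            raise ConfigError(f"arm {name!r}: bad cost key {k!r}") from exc
        tiers.append((idx, costs[k]))
    tiers.sort()
    expected = list(range(len(tiers)))
    if [t for t, _ in tiers] != expected:
        raise ConfigError(
            f"arm {name!r}: tiers must be contiguous from 0, got "
            f"{[t for t, _ in tiers]}"
        )
    util = a["utilities"]
    probs = a["probabilities"]
    ae_u = util.get("ae", {}) or {}
    ae_p = probs.get("ae", {}) or {}
    for src, kind in ((ae_u, "utility"), (ae_p, "probability")):
        for ae_name in src:
            if ae_name not in AE_NAMES:
                raise ConfigError(
                    f"arm {name!r}: unknown adverse event {ae_name!r} "
                    f"in {kind} block"
                )
    profiles = [
        AdverseEventProfile(
            name=ae_name,
            monthly_prob=ae_p.get(ae_name, 0.0),
            utility=ae_u.get(ae_name),
        )
        for ae_name in AE_NAMES
        if ae_name in ae_p or ae_name in ae_u
    ]
    try:
        return TreatmentArm(
            name=name,
            tier_costs=[DoseTierCost(tier=t, cycle_cost=c) for t, c in tiers],
            pd_cycle_cost=costs["pd"],
            u_pfs=util["pfs"],
            u_pd=util["pd"],
            p_prog=probs["prog"],
            p_pfs_death=probs["pfs_death"],
            p_pd_death=probs["pd_death"],
            p_reduce1=probs.get("reduce1", 0.0),
            p_reduce2=probs.get("reduce2", 0.0),
            p_disc=probs.get("disc", 0.0),
            ae_profiles=profiles,
        )
    except ValidationError as exc:
        raise ConfigError(f"arm {name!r}: {exc}") from exc


# -- loading ------------------------------------------------------------


def loads_model_inputs(text: str) -> ModelInputs:
    """Parse a YAML/JSON config string into validated model inputs."""
    cfg = yaml.safe_load(text)
    return ModelInputs.from_config(cfg)


def load_model_inputs(path: str | Path) -> ModelInputs:
    """Load and validate a config file."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    return loads_model_inputs(path.read_text())


def load_inputs(path: str | Path) -> tuple[list[TreatmentArm], ModelSettings]:
    """Load a config file, returning ``(arms, settings)``."""
    mi = load_model_inputs(path)
    return mi.arms, mi.settings


def packaged_data_path(filename: str) -> Path:
    """Filesystem path of a packaged data file."""
    return Path(str(resources.files("markovcea.data") / filename))


def packaged_base_case() -> ModelInputs:
    """The packaged base-case inputs (published values, as printed)."""
    return load_model_inputs(packaged_data_path("base_case_inputs.yaml"))


# -- semantic validation -------------------------------------------------


@dataclass(frozen=True)
class Diagnostic:
    """One semantic-validation finding on an arm (field, rule, value)."""

    field: str
    rule: str
    value: float
    message: str

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"{self.field}: {self.message} (rule={self.rule}, value={self.value})"


def _tier_outflows(arm: TreatmentArm) -> list[float]:
    """Total monthly outflow probability from each progression-free tier."""
    outflows = []
    for tier in range(arm.n_tiers):
        out = arm.p_prog + arm.p_disc + arm.p_pfs_death
        if tier == 0 and arm.n_tiers > 1:
            out += arm.p_reduce1
        elif tier == 1 and arm.n_tiers > 2:
            out += arm.p_reduce2
        outflows.append(out)
    return outflows


def validate_arm(arm: TreatmentArm,
                 settings: ModelSettings | None = None) -> list[Diagnostic]:
    """Check an arm's semantic invariants; returns diagnostics, never throws.

    An empty list means the arm is feasible: every progression-free tier's
    total outflow probability is at most 1, state utilities are positive,
    the utility-bearing adverse-event probabilities leave room for the
    baseline progression-free utility, and a single-tier arm carries no
    dose-reduction probabilities.
    """
    diags: list[Diagnostic] = []
    for tier, out in enumerate(_tier_outflows(arm)):
        if out > 1.0:
            diags.append(Diagnostic(
                field=f"tier{tier}", rule="outflow_feasibility", value=out,
                message=f"total outflow probability from PFS tier {tier} "
                        f"is {out:.6g} > 1",
            ))
    for field, u in (("u_pfs", arm.u_pfs), ("u_pd", arm.u_pd)):
        if u <= 0.0:
            diags.append(Diagnostic(
                field=field, rule="utility_positivity", value=u,
                message=f"{field} must be positive, got {u}",
            ))
    ae_mass = sum(p.monthly_prob for p in arm.utility_bearing_aes())
    if ae_mass >= 1.0:
        diags.append(Diagnostic(
            field="ae_profiles", rule="ae_mixture_mass", value=ae_mass,
            message=f"utility-bearing AE probabilities sum to {ae_mass:.6g} "
                    ">= 1; the mixture leaves no mass for the baseline "
                    "utility",
        ))
    if arm.n_tiers == 1:
        for field, p in (("p_reduce1", arm.p_reduce1),
                         ("p_reduce2", arm.p_reduce2)):
            if p != 0.0:
                diags.append(Diagnostic(
                    field=field, rule="single_tier_no_reduction", value=p,
                    message=f"single-tier arm must have {field} = 0, got {p}",
                ))
    return diags


# -- dot-path access (used by sensitivity analysis and perturbation) -----

_ARM_SCALAR_PATHS = {
    "utilities.pfs": "u_pfs",
    "utilities.pd": "u_pd",
    "probabilities.prog": "p_prog",
    "probabilities.pfs_death": "p_pfs_death",
    "probabilities.pd_death": "p_pd_death",
    "probabilities.reduce1": "p_reduce1",
    "probabilities.reduce2": "p_reduce2",
    "probabilities.disc": "p_disc",
}

PROBABILITY_PATH_PREFIXES = ("probabilities.",)


class PathError(KeyError):
    """A dot-path does not resolve inside the model inputs."""


def _resolve_arm_paths(inputs: ModelInputs, path: str) -> list[tuple[str, str]]:
    """Expand a dot-path into concrete ``(arm_name, field_path)`` pairs.

    Paths follow the config schema, e.g. ``arms.ribociclib.costs.tier0`` or
    ``arms.*.utilities.pd`` (the wildcard addresses a value shared across
    arms, such as the progressed-disease utility).
    """
    parts = path.split(".")
    if len(parts) < 4 or parts[0] != "arms":
        raise PathError(f"unresolvable path {path!r}")
    arm_sel = parts[1]
    field = ".".join(parts[2:])
    if arm_sel == "*":
        names = inputs.arm_names
    else:
        if arm_sel not in inputs.arm_names:
            raise PathError(f"unknown arm {arm_sel!r} in path {path!r}")
        names = [arm_sel]
    return [(n, field) for n in names]


def _arm_field_get(cfg_arm: dict, field: str, path: str) -> float:
    node: object = cfg_arm
    for part in field.split("."):
        if not isinstance(node, dict) or part not in node:
            raise PathError(f"unresolvable path {path!r}")
        node = node[part]
    if not isinstance(node, (int, float)):
        raise PathError(f"path {path!r} does not address a scalar")
    return float(node)


def _arm_field_set(cfg_arm: dict, field: str, value: float, path: str) -> None:
    parts = field.split(".")
    node: object = cfg_arm
    for part in parts[:-1]:
        if not isinstance(node, dict) or part not in node:
            raise PathError(f"unresolvable path {path!r}")
        node = node[part]
    if not isinstance(node, dict) or parts[-1] not in node:
        raise PathError(f"unresolvable path {path!r}")
    node[parts[-1]] = value


def get_path(inputs: ModelInputs, path: str) -> float:
    """Read the scalar addressed by a dot-path (wildcards must agree)."""
    if path.startswith("settings."):
        field = path.removeprefix("settings.")
        if not hasattr(inputs.settings, field):
            raise PathError(f"unresolvable path {path!r}")
        value = getattr(inputs.settings, field)
        if not isinstance(value, (int, float)):
            raise PathError(f"path {path!r} does not address a scalar")
        return float(value)
    cfg = inputs.to_config()
    by_name = {a["name"]: a for a in cfg["arms"]}
    values = {
        _arm_field_get(by_name[n], f, path)
        for n, f in _resolve_arm_paths(inputs, path)
    }
    if len(values) != 1:
        raise PathError(
            f"wildcard path {path!r} addresses differing values {sorted(values)}"
        )
    return values.pop()


def set_path(inputs: ModelInputs, path: str, value: float) -> ModelInputs:
    """Return a deep copy of the inputs with one scalar replaced."""
    if path.startswith("settings."):
        field = path.removeprefix("settings.")
        if not hasattr(inputs.settings, field):
            raise PathError(f"unresolvable path {path!r}")
        settings = inputs.settings.model_copy(update={field: value})
        return ModelInputs(schema_version=inputs.schema_version,
                           settings=settings, arms=list(inputs.arms))
    cfg = copy.deepcopy(inputs.to_config())
    by_name = {a["name"]: a for a in cfg["arms"]}
    for n, f in _resolve_arm_paths(inputs, path):
        _arm_field_set(by_name[n], f, value, path)
    return ModelInputs.from_config(cfg)


def is_probability_path(path: str) -> bool:
    """Whether a dot-path addresses a transition/AE probability."""
    tail = path.split(".", 2)[-1] if path.startswith("arms.") else path
    return tail.startswith(PROBABILITY_PATH_PREFIXES)
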