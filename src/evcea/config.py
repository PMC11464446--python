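"""Run configuration: the single source of truth for every model input.

A :class:`RunConfig` carries everything the pipeline consumes -- model
settings, survival parameters, regimens, costs, utilities, adverse-event
profiles, sensitivity ranges, subgroup and scenario declarations -- and can
be round-tripped through YAML/JSON. Unknown keys are rejected so typos fail
loudly. No numeric input is hard-coded in the engine modules.

Uncertain parameters are addressed by dotted *parameter paths* used by the
one-way and probabilistic sensitivity machinery, e.g.::

    settings.discount_rate     patient.weight_kg      utilities.pfs
    costs.bsc_per_cycle        costs.ae_management.anemia
    drug_price.enfortumab_vedotin        ae_incidence.chemotherapy.anemia
    rules.bsc_proportion
"""

from __future__ import annotations

import copy
import dataclasses
import hashlib
import importlib.resources
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import yaml

from .cohort import ModelSettings
from .economics import (
    AccrualRules,
    ArmDefinition,
    Comparison,
    CostTable,
    DrugSpec,
    PatientProfile,
    UtilitySet,
    compare,
    evaluate_arm,
)
from .survival import ParametricSurvival

__all__ = [
    "ParamRange", "SubgroupSpec", "ScenarioSpec", "RunConfig",
    "load_config", "default_config", "run_model",
    "get_param", "apply_param",
]


@dataclass
class ParamRange:
    """One uncertain parameter: its path, range and PSA distribution."""

    path: str
    low: float
    high: float
    dist: str = "gamma"  # beta | gamma | normal | fixed

    def __post_init__(self) -> None:
        if self.low > self.high:
            raise ValueError(f"{self.path}: low > high")
        if self.dist not in ("beta", "gamma", "normal", "fixed"):
            raise ValueError(f"{self.path}: unknown distribution {self.dist!r}")


@dataclass
class SubgroupSpec:
    """Hazard ratios (intervention vs comparator) defining a subgroup."""

    name: str
    pfs_hr: float
    os_hr: float
    pfs_hr_ci: tuple[float, float] | None = None
    os_hr_ci: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if self.pfs_hr <= 0 or self.os_hr <= 0:
            raise ValueError("hazard ratios must be positive")
        for nm in ("pfs_hr_ci", "os_hr_ci"):
            v = getattr(self, nm)
            if v is not None:
                setattr(self, nm, (float(v[0]), float(v[1])))


@dataclass
class ScenarioSpec:
    """A named transform of the base configuration.

    ``overrides`` maps parameter paths to replacement values; a ``cure``
    block switches on the cure model (progression frozen at ``cure_time
    _months``, treatment stopped, one tests item per cycle continued, death
    among the cured driven by background mortality only).
    """

    name: str
    overrides: dict[str, Any] = field(default_factory=dict)
    cure: dict[str, float] | None = None


_ARM_KEYS = {"drugs"}


def _check_keys(mapping: Mapping, allowed, where: str) -> None:
    unknown = set(mapping) - set(allowed)
    if unknown:
        raise ValueError(f"unknown key(s) {sorted(unknown)} in {where}")


def _dataclass_from(cls, data: Mapping, where: str):
    names = [f.name for f in dataclasses.fields(cls)]
    _check_keys(data, names, where)
    return cls(**data)


@dataclass
class RunConfig:
    settings: ModelSettings
    patient: PatientProfile
    costs: CostTable
    utilities: UtilitySet
    rules: AccrualRules
    survival: dict[str, dict[str, ParametricSurvival]]
    drugs: dict[str, list[DrugSpec]]
    adverse_events: dict[str, dict[str, float]]
    intervention: str
    comparator: str
    sensitivity: list[ParamRange] = field(default_factory=list)
    subgroups: list[SubgroupSpec] = field(default_factory=list)
    scenarios: list[ScenarioSpec] = field(default_factory=list)
    seed: int = 2024

    def __post_init__(self) -> None:
        for arm in (self.intervention, self.comparator):
            if arm not in self.survival:
                raise ValueError(f"no survival parameters for arm {arm!r}")
            if arm not in self.drugs:
                raise ValueError(f"no regimen for arm {arm!r}")
            for ep in ("pfs", "os"):
                if ep not in self.survival[arm]:
                    raise ValueError(f"arm {arm!r} lacks {ep} parameters")

    # -- building domain objects -------------------------------------------
    def arm_definition(self, arm: str) -> ArmDefinition:
        return ArmDefinition(
            name=arm,
            pfs=self.survival[arm]["pfs"],
            os=self.survival[arm]["os"],
            drugs=self.drugs[arm],
            ae_incidence=dict(self.adverse_events.get(arm, {})),
        )

    # -- (de)serialisation --------------------------------------------------
    @classmethod
    def from_dict(cls, d: Mapping) -> "RunConfig":
        _check_keys(
            d,
            ["settings", "patient", "costs", "utilities", "rules", "survival",
             "arms", "adverse_events", "sensitivity", "subgroups", "scenarios",
             "seed"],
            "config root",
        )
        arms = d["arms"]
        _check_keys(
            arms, ["intervention", "comparator",
                   *(k for k in arms if k not in ("intervention", "comparator"))],
            "arms",
        )
        drugs: dict[str, list[DrugSpec]] = {}
        for arm_name, block in arms.items():
            if arm_name in ("intervention", "comparator"):
                continue
            _check_keys(block, _ARM_KEYS, f"arms.{arm_name}")
            drugs[arm_name] = [
                _dataclass_from(DrugSpec, spec, f"arms.{arm_name}.drugs[{i}]")
                for i, spec in enumerate(block["drugs"])
            ]
        survival = {
            arm: {
                ep: ParametricSurvival.from_dict(sp)
                for ep, sp in endpoints.items()
            }
            for arm, endpoints in d["survival"].items()
        }
        return cls(
            settings=_dataclass_from(ModelSettings, d["settings"], "settings"),
            patient=_dataclass_from(PatientProfile, d["patient"], "patient"),
            costs=CostTable(
                **{k: v for k, v in d["costs"].items() if k != "ae_management"},
                ae_management=dict(d["costs"].get("ae_management", {})),
            ),
            utilities=_dataclass_from(UtilitySet, d["utilities"], "utilities"),
            rules=_dataclass_from(AccrualRules, d["rules"], "rules"),
            survival=survival,
            drugs=drugs,
            adverse_events={a: dict(v) for a, v in d["adverse_events"].items()},
            intervention=arms["intervention"],
            comparator=arms["comparator"],
            sensitivity=[
                _dataclass_from(ParamRange, r, "sensitivity") for r in d.get("sensitivity", [])
            ],
            subgroups=[
                _dataclass_from(SubgroupSpec, s, "subgroups") for s in d.get("subgroups", [])
            ],
            scenarios=[
                _dataclass_from(ScenarioSpec, s, "scenarios") for s in d.get("scenarios", [])
            ],
            seed=int(d.get("seed", 2024)),
        )

    def to_dict(self) -> dict:
        arms: dict[str, Any] = {
            "intervention": self.intervention,
            "comparator": self.comparator,
        }
        for arm, specs in self.drugs.items():
            arms[arm] = {"drugs": [dataclasses.asdict(s) for s in specs]}
        return {
            "settings": dataclasses.asdict(self.settings),
            "patient": dataclasses.asdict(self.patient),
            "costs": dataclasses.asdict(self.costs),
            "utilities": dataclasses.asdict(self.utilities),
            "rules": dataclasses.asdict(self.rules),
            "survival": {
                arm: {ep: sp.to_dict() for ep, sp in endpoints.items()}
                for arm, endpoints in self.survival.items()
            },
            "arms": arms,
            "adverse_events": {a: dict(v) for a, v in self.adverse_events.items()},
            "sensitivity": [dataclasses.asdict(r) for r in self.sensitivity],
            "subgroups": [dataclasses.asdict(s) for s in self.subgroups],
            "scenarios": [dataclasses.asdict(s) for s in self.scenarios],
            "seed": self.seed,
        }

    def dump_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    def config_hash(self) -> str:
        text = json.dumps(self.to_dict(), sort_keys=True, default=float)
        return hashlib.sha256(text.encode()).hexdigest()[:16]

    def copy(self) -> "RunConfig":
        return copy.deepcopy(self)


def load_config(path: str | Path) -> RunConfig:
    """Load a YAML or JSON configuration file."""
    text = Path(path).read_text()
    data = yaml.safe_load(text)
    return RunConfig.from_dict(data)


def default_config() -> RunConfig:
    """The shipped, calibrated base-case configuration."""
    ref = importlib.resources.files("evcea.data") / "base_config.yaml"
    return RunConfig.from_dict(yaml.safe_load(ref.read_text()))


# ---------------------------------------------------------------------------
# parameter paths


def _resolve(cfg: RunConfig, path: str):
    """Return (container, final_key_or_callback) for a parameter path."""
    parts = path.split(".")
    head = parts[0]
    if head in ("settings", "patient", "utilities", "rules"):
        if len(parts) != 2:
            raise KeyError(path)
        obj = getattr(cfg, head)
        if not hasattr(obj, parts[1]):
            raise KeyError(path)
        return obj, parts[1]
    if head == "costs":
        if len(parts) == 2 and parts[1] != "ae_management":
            if not hasattr(cfg.costs, parts[1]):
                raise KeyError(path)
            return cfg.costs, parts[1]
        if len(parts) == 3 and parts[1] == "ae_management":
            if parts[2] not in cfg.costs.ae_management:
                raise KeyError(path)
            return cfg.costs.ae_management, parts[2]
        raise KeyError(path)
    if head == "ae_incidence":
        if len(parts) != 3 or parts[1] not in cfg.adverse_events:
            raise KeyError(path)
        if parts[2] not in cfg.adverse_events[parts[1]]:
            raise KeyError(path)
        return cfg.adverse_events[parts[1]], parts[2]
    if head == "drug_price":
        if len(parts) != 2:
            raise KeyError(path)
        specs = [s for arm_specs in cfg.drugs.values() for s in arm_specs
                 if s.name == parts[1]]
        if not specs:
            raise KeyError(path)
        return specs, "vial_price"
    raise KeyError(path)


def get_param(cfg: RunConfig, path: str) -> float:
    container, key = _resolve(cfg, path)
    if isinstance(container, list):
        return float(getattr(container[0], key))
    if isinstance(container, dict):
        return float(container[key])
    return float(getattr(container, key))


def _set_inplace(cfg: RunConfig, path: str, value: float) -> None:
    container, key = _resolve(cfg, path)
    if isinstance(container, list):
        for spec in container:
            setattr(spec, key, float(value))
    elif isinstance(container, dict):
        container[key] = float(value)
    else:
        setattr(container, key, float(value))


def apply_param(cfg: RunConfig, path: str, value: float) -> RunConfig:
    """Return a copy of ``cfg`` with the addressed parameter replaced."""
    out = cfg.copy()
    _set_inplace(out, path, value)
    return out


def apply_params(cfg: RunConfig, values: Mapping[str, float]) -> RunConfig:
    out = cfg.copy()
    for path, value in values.items():
        _set_inplace(out, path, value)
    return out


# ---------------------------------------------------------------------------
# the pipeline


def run_model(cfg: RunConfig, overrides: Mapping[str, float] | None = None) -> Comparison:
    """Evaluate both strategies under ``cfg`` and compare them."""
    if overrides:
        cfg = apply_params(cfg, overrides)
    results = {}
    for arm in (cfg.intervention, cfg.comparator):
        _, results[arm] = evaluate_arm(
            cfg.arm_definition(arm), cfg.settings, cfg.patient,
            cfg.costs, cfg.utilities, cfg.rules,
        )
    return compare(results[cfg.intervention], results[cfg.comparator],
                   cfg.settings.wtp)


def run_metadata(cfg: RunConfig) -> dict:
    """Provenance record written next to every artifact."""
    from . import __version__

    return {
        "package_version": __version__,
        "config_hash": cfg.config_hash(),
        "seed": cfg.seed,
        "half_cycle_correction": cfg.settings.half_cycle_correction,
        "accrual_timing": cfg.settings.accrual_timing,
        "vial_rounding": cfg.rules.vial_rounding,
        "drug_duration_rules": {
            arm: {s.name: s.accrual for s in specs}
            for arm, specs in cfg.drugs.items()
        },
    }
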