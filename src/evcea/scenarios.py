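"""Subgroup and scenario analyses as transforms of the base configuration.

Subgroups re-use the comparator's fitted curves for both arms and apply the
subgroup's hazard ratios on the cumulative-hazard scale to obtain the
intervention curves: ``S_sub(t) = S_ref(t)**hr``. The log-logistic is not a
proportional-hazards family, so this is a modelling convention (the one the
source methodology prescribes), not a refit.

Scenarios apply declared overrides (horizon, BSC uptake, drug price) and
re-run the standard pipeline. The cure scenario freezes progression at a
configurable time: patients still progression free then are considered
cured -- treatment stops, one routine-tests item per cycle continues, and
their subsequent mortality follows the background rate only.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .cohort import CohortTrace, ModelSettings
from .config import (
    RunConfig,
    ScenarioSpec,
    SubgroupSpec,
    apply_params,
    run_model,
)
from .economics import (
    ArmDefinition,
    ArmResult,
    Comparison,
    accumulate,
    administration_cost,
    compare,
    discount_factor,
    dose_per_administration,
    evaluate_arm,
    on_treatment_weights,
)
from .survival import ParametricSurvival, survival_at

__all__ = [
    "PowerTransformedSurvival", "apply_hazard_ratio",
    "run_subgroup", "run_scenario", "run_all_subgroups", "run_all_scenarios",
]


class PowerTransformedSurvival:
    """S_ref(t)**hr -- a hazard ratio applied on the cumulative-hazard
    scale to a fitted reference curve."""

    def __init__(self, base: ParametricSurvival, hr: float):
        if hr <= 0:
            raise ValueError("hazard ratio must be positive")
        self.base = base
        self.hr = float(hr)

    def survival(self, t):
        return survival_at(self.base, t) ** self.hr

    @property
    def shape(self) -> float:
        return self.base.shape

    def median(self) -> float:
        return float(self.quantile(0.5))

    def quantile(self, s):
        s = np.asarray(s, dtype=float)
        out = self.base.quantile(s ** (1.0 / self.hr))
        return out if np.ndim(out) else float(out)


def apply_hazard_ratio(
    reference: ParametricSurvival, hr: float
) -> ParametricSurvival | PowerTransformedSurvival:
    """Survival law of a group whose hazard is ``hr`` times the reference's."""
    if hr == 1.0:
        return reference
    return PowerTransformedSurvival(reference, hr)


def run_subgroup(
    cfg: RunConfig,
    spec: SubgroupSpec,
    overrides: Mapping[str, float] | None = None,
) -> Comparison:
    """Full pipeline with HR-transformed comparator curves as the
    intervention arm's survival; costs and utilities unchanged."""
    if overrides:
        cfg = apply_params(cfg, overrides)
    ref = cfg.survival[cfg.comparator]
    arm_int = cfg.arm_definition(cfg.intervention)
    arm_int = ArmDefinition(
        name=arm_int.name,
        pfs=apply_hazard_ratio(ref["pfs"], spec.pfs_hr),
        os=apply_hazard_ratio(ref["os"], spec.os_hr),
        drugs=arm_int.drugs,
        ae_incidence=arm_int.ae_incidence,
    )
    arm_comp = cfg.arm_definition(cfg.comparator)
    _, res_int = evaluate_arm(arm_int, cfg.settings, cfg.patient, cfg.costs,
                              cfg.utilities, cfg.rules)
    _, res_comp = evaluate_arm(arm_comp, cfg.settings, cfg.patient, cfg.costs,
                               cfg.utilities, cfg.rules)
    return compare(res_int, res_comp, cfg.settings.wtp)


def run_all_subgroups(cfg: RunConfig) -> pd.DataFrame:
    rows = []
    for spec in cfg.subgroups:
        cmp = run_subgroup(cfg, spec)
        rows.append({
            "subgroup": spec.name,
            "pfs_hr": spec.pfs_hr,
            "os_hr": spec.os_hr,
            "cost_intervention": cmp.intervention.cost,
            "cost_comparator": cmp.comparator.cost,
            "qalys_intervention": cmp.intervention.qalys,
            "qalys_comparator": cmp.comparator.qalys,
            "icer": np.nan if cmp.icer is None else cmp.icer,
            "cost_effective": cmp.cost_effective,
        })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# cure model (scenario 4)


def _cure_trace(
    arm: ArmDefinition, settings: ModelSettings, cure_cycle: int, q_annual: float
) -> CohortTrace:
    n = settings.n_cycles
    c = settings.cycle_length_months
    t = np.arange(n + 1) * c
    s_os = survival_at(arm.os, t)
    s_pfs = np.minimum(survival_at(arm.pfs, t), s_os)
    pfs = s_pfs.copy()
    pdo = s_os - s_pfs
    q_cycle = 1.0 - (1.0 - q_annual) ** (settings.cycle_length_days / 365.0)
    for k in range(cure_cycle + 1, n + 1):
        pfs[k] = pfs[k - 1] * (1.0 - q_cycle)
        h = 1.0 - (s_os[k] / s_os[k - 1] if s_os[k - 1] > 0 else 0.0)
        pdo[k] = pdo[k - 1] * (1.0 - h)
    return CohortTrace(t, pfs, pdo, 1.0 - pfs - pdo)


def _cure_arm_result(
    cfg: RunConfig, arm_name: str, cure_time_months: float, q_annual: float
) -> ArmResult:
    arm = cfg.arm_definition(arm_name)
    settings, costs, utilities, rules = (
        cfg.settings, cfg.costs, cfg.utilities, cfg.rules,
    )
    n = settings.n_cycles
    cure_cycle = int(round(cure_time_months / settings.cycle_length_months))
    trace = _cure_trace(arm, settings, cure_cycle, q_annual)
    k = np.arange(1, n + 1)
    disc = discount_factor(k, settings.discount_rate, settings.cycle_length_days)
    pfs_w, pd_w, _ = trace.at_timing(settings.accrual_timing)
    alive_w = pfs_w + pd_w
    post = k > cure_cycle

    breakdown: dict[str, float] = {}
    for drug in arm.drugs:
        dose = dose_per_administration(drug, cfg.patient)
        per_cycle = drug.administrations_per_cycle * administration_cost(
            dose, drug.vial_mg, drug.vial_price, rules.vial_rounding
        )
        w = on_treatment_weights(drug, arm, trace, settings) * (~post)
        breakdown[f"drug:{drug.name}"] = float(np.sum(disc * per_cycle * w))
    # cured patients keep one tests item per cycle; progressed keep the
    # base-case PD care package (scaled by the BSC uptake proportion)
    pd_care = rules.bsc_proportion * pd_w
    breakdown["tests"] = float(
        np.sum(disc * costs.tests_per_cycle * (pfs_w + pd_care))
    )
    fu_w = np.where(post, pd_care, pfs_w + pd_care)
    breakdown["followup"] = float(np.sum(disc * costs.followup_per_cycle * fu_w))
    breakdown["bsc"] = float(np.sum(disc * costs.bsc_per_cycle * pd_care))
    breakdown["terminal"] = float(
        np.sum(disc * costs.terminal_care * np.diff(trace.dead))
    )
    ae_burden = sum(arm.ae_incidence.values())
    breakdown["ae"] = float(disc[0]) * sum(
        inc * costs.ae_management.get(nm, 0.0)
        for nm, inc in arm.ae_incidence.items()
    )
    qalys = float(np.sum(
        disc * settings.cycle_length_years
        * (utilities.pfs * pfs_w + utilities.pd * pd_w)
    ))
    qalys -= ae_burden * utilities.ae_disutility * settings.cycle_length_years \
        * float(disc[0])
    life_years = float(np.sum(settings.cycle_length_years * alive_w))
    return ArmResult(arm_name, sum(breakdown.values()), qalys, life_years,
                     breakdown)


def run_cure_model(
    cfg: RunConfig, cure_time_months: float = 20.0,
    background_mortality: float = 0.02,
) -> Comparison:
    res_int = _cure_arm_result(cfg, cfg.intervention, cure_time_months,
                               background_mortality)
    res_comp = _cure_arm_result(cfg, cfg.comparator, cure_time_months,
                                background_mortality)
    return compare(res_int, res_comp, cfg.settings.wtp)


def run_scenario(cfg: RunConfig, spec: ScenarioSpec) -> Comparison:
    """Apply a scenario's overrides (and cure block, if any), then run the
    standard pipeline."""
    try:
        if spec.overrides:
            cfg = apply_params(cfg, spec.overrides)
    except KeyError as exc:
        raise ValueError(f"scenario {spec.name!r}: unknown override {exc}") from exc
    if spec.cure is not None:
        allowed = {"cure_time_months", "background_mortality"}
        unknown = set(spec.cure) - allowed
        if unknown:
            raise ValueError(f"scenario {spec.name!r}: unknown cure key(s) {unknown}")
        return run_cure_model(cfg, **spec.cure)
    return run_model(cfg)


def run_all_scenarios(cfg: RunConfig) -> pd.DataFrame:
    rows = []
    for spec in cfg.scenarios:
        cmp = run_scenario(cfg, spec)
        rows.append({
            "scenario": spec.name,
            "cost_intervention": cmp.intervention.cost,
            "cost_comparator": cmp.comparator.cost,
            "qalys_intervention": cmp.intervention.qalys,
            "qalys_comparator": cmp.comparator.qalys,
            "icer": np.nan if cmp.icer is None else cmp.icer,
            "cost_effective": cmp.cost_effective,
        })
    return pd.DataFrame(rows)
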