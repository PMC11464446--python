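"""Costing and outcome accrual: from a cohort trace to discounted totals.

Each strategy accrues, per 21-day cycle:

* drug acquisition cost on its on-treatment fraction (whole vials by
  default, no sharing), subject to each drug's maximum-cycle cap and its
  accrual rule -- progression-free occupancy, alive occupancy, or an
  explicit time-on-treatment curve anchored at the trial's reported median
  treatment duration;
* routine tests and follow-up on all alive patients;
* best supportive care on the progressed-disease occupancy (times the
  proportion of progressed patients assumed to receive it);
* a one-time terminal-care cost on incident deaths;
* a one-time adverse-event management cost (incidence-weighted sum over
  grade >=3 events) at the first cycle.

Utilities accrue as occupancy x state utility x cycle length, minus a
one-time incidence-weighted disutility for grade >=3 adverse events lasting
one cycle. Everything is discounted continuously at ``(1+r)**(t/365)``
with t in days at the cycle's end.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .cohort import CohortTrace, ModelSettings, build_occupancy
from .survival import ParametricSurvival, survival_at

__all__ = [
    "PatientProfile", "DrugSpec", "CostTable", "UtilitySet", "ArmDefinition",
    "AccrualRules", "ArmResult", "Comparison",
    "dose_per_administration", "administration_cost", "discount_factor",
    "on_treatment_weights", "cycle_cost", "accumulate", "compare",
    "evaluate_arm",
]


@dataclass
class PatientProfile:
    """Reference patient used for all dose arithmetic (point values)."""

    weight_kg: float = 65.0
    body_surface_area_m2: float = 1.72
    creatinine_clearance_ml_min: float = 70.0

    def __post_init__(self) -> None:
        if min(self.weight_kg, self.body_surface_area_m2,
               self.creatinine_clearance_ml_min) <= 0:
            raise ValueError("patient measurements must be positive")


@dataclass
class DrugSpec:
    """One drug of a regimen and how its cost accrues.

    dosing_rule: "per_kg" (mg/kg with optional cap), "flat" (mg),
        "per_bsa" (mg/m2) or "calvert" (dose = AUC x (CrCl + 25)).
    accrual: which cohort fraction is on this drug each cycle --
        "pfs" (until progression), "alive" (until death; treatment beyond
        progression), or "duration_curve" (a log-logistic time-on-treatment
        curve with median ``median_duration_months``; its shape defaults to
        the arm's PFS shape).
    max_cycles: treatment cap in cycles (None = no maximum).
    cohort_fraction: share of the cohort receiving this drug (used for the
        cisplatin/carboplatin split).
    """

    name: str
    vial_mg: float
    vial_price: float
    dosing_rule: str
    dose_value: float  # mg/kg, mg, mg/m2 or AUC depending on the rule
    dose_cap_mg: float | None = None
    administrations_per_cycle: int = 1
    max_cycles: int | None = None
    accrual: str = "pfs"
    median_duration_months: float | None = None
    duration_shape: float | None = None
    cohort_fraction: float = 1.0

    def __post_init__(self) -> None:
        if self.dosing_rule not in ("per_kg", "flat", "per_bsa", "calvert"):
            raise ValueError(f"unknown dosing rule {self.dosing_rule!r}")
        if self.accrual not in ("pfs", "alive", "duration_curve"):
            raise ValueError(f"unknown accrual rule {self.accrual!r}")
        if self.accrual == "duration_curve" and not self.median_duration_months:
            raise ValueError("duration_curve accrual needs a median duration")
        if self.vial_mg <= 0 or self.vial_price < 0:
            raise ValueError("vial size must be positive, price non-negative")


@dataclass
class CostTable:
    """Non-drug cost inputs (USD), mirroring the published cost table."""

    bsc_per_cycle: float = 182.8
    followup_per_cycle: float = 73.9
    tests_per_cycle: float = 358.4
    terminal_care: float = 1494.0
    ae_management: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        vals = [self.bsc_per_cycle, self.followup_per_cycle,
                self.tests_per_cycle, self.terminal_care,
                *self.ae_management.values()]
        if any(v < 0 for v in vals):
            raise ValueError("costs must be non-negative")


@dataclass
class UtilitySet:
    pfs: float = 0.84
    pd: float = 0.80
    ae_disutility: float = 0.28

    def __post_init__(self) -> None:
        if not (0.0 <= self.pfs <= 1.0 and 0.0 <= self.pd <= 1.0):
            raise ValueError("utilities must lie in [0, 1]")
        if self.ae_disutility < 0:
            raise ValueError("disutility must be non-negative")


@dataclass
class AccrualRules:
    """Calibrated conventions for which state each recurring cost follows."""

    tests_on: str = "alive"        # "alive" | "pfs" | "on_treatment"
    followup_on: str = "alive"
    #: share of progressed patients who keep receiving care after
    #: progression; scales the whole PD package (BSC plus the PD share of
    #: tests and follow-up)
    bsc_proportion: float = 1.0
    vial_rounding: str = "whole"   # "whole" | "linear"

    def __post_init__(self) -> None:
        for v in (self.tests_on, self.followup_on):
            if v not in ("alive", "pfs", "on_treatment"):
                raise ValueError(f"unknown accrual state {v!r}")
        if not 0.0 <= self.bsc_proportion <= 1.0:
            raise ValueError("bsc_proportion must lie in [0, 1]")
        if self.vial_rounding not in ("whole", "linear"):
            raise ValueError("vial_rounding must be 'whole' or 'linear'")


@dataclass
class ArmDefinition:
    """A strategy: its survival curves, regimen and adverse-event profile."""

    name: str
    pfs: ParametricSurvival
    os: ParametricSurvival
    drugs: list[DrugSpec]
    ae_incidence: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for k, v in self.ae_incidence.items():
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"AE incidence for {k} must lie in [0, 1]")


@dataclass
class ArmResult:
    strategy: str
    cost: float                    # total discounted cost, USD
    qalys: float                   # total discounted QALYs
    life_years: float              # undiscounted life expectancy in horizon
    breakdown: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.breakdown:
            total = sum(self.breakdown.values())
            if not math.isclose(total, self.cost, rel_tol=1e-6, abs_tol=1e-6):
                raise ValueError("cost breakdown does not sum to the total")


@dataclass
class Comparison:
    intervention: ArmResult
    comparator: ArmResult
    wtp: float
    delta_cost: float
    delta_qalys: float
    icer: float | None             # None when undefined (delta QALYs == 0)
    dominance: str                 # "", "dominant" or "dominated"
    nmb_intervention: float
    nmb_comparator: float

    @property
    def cost_effective(self) -> bool:
        if self.dominance == "dominant":
            return True
        if self.dominance == "dominated":
            return False
        return self.icer is not None and self.icer < self.wtp

    def summary_frame(self) -> pd.DataFrame:
        rows = []
        for r, inc in ((self.intervention, True), (self.comparator, False)):
            rows.append({
                "strategy": r.strategy,
                "cost_usd": r.cost,
                "qalys": r.qalys,
                "life_years": r.life_years,
                "nmb": self.nmb_intervention if inc else self.nmb_comparator,
            })
        return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# dose and price arithmetic


def dose_per_administration(spec: DrugSpec, profile: PatientProfile) -> float:
    """Dose in mg for one administration of ``spec`` to ``profile``."""
    if spec.dosing_rule == "per_kg":
        dose = spec.dose_value * profile.weight_kg
        if spec.dose_cap_mg is not None:
            dose = min(dose, spec.dose_cap_mg)
        return dose
    if spec.dosing_rule == "flat":
        return spec.dose_value
    if spec.dosing_rule == "per_bsa":
        return spec.dose_value * profile.body_surface_area_m2
    # Calvert formula: dose = AUC x (GFR + 25), CrCl standing in for GFR
    return spec.dose_value * (profile.creatinine_clearance_ml_min + 25.0)


def administration_cost(
    dose_mg: float, vial_mg: float, vial_price: float, rounding_policy: str = "whole"
) -> float:
    """Acquisition cost of one administration under the vial policy."""
    if vial_mg <= 0:
        raise ValueError("vial size must be positive")
    n_vials = dose_mg / vial_mg
    if rounding_policy == "whole":
        n_vials = math.ceil(n_vials - 1e-12)
    elif rounding_policy != "linear":
        raise ValueError(f"unknown rounding policy {rounding_policy!r}")
    return n_vials * vial_price


def discount_factor(cycle, annual_rate: float, cycle_length_days: float = 21.0):
    """``1 / (1 + r)**(days/365)`` at the end of cycle k (exact exponent)."""
    if annual_rate < 0:
        raise ValueError("discount rate must be non-negative")
    k = np.asarray(cycle, dtype=float)
    out = (1.0 + annual_rate) ** (-(cycle_length_days * k) / 365.0)
    return out if out.ndim else float(out)


# ---------------------------------------------------------------------------
# per-cycle accrual


def on_treatment_weights(
    drug: DrugSpec,
    arm: ArmDefinition,
    trace: CohortTrace,
    settings: ModelSettings,
) -> np.ndarray:
    """Fraction of the cohort receiving ``drug`` during cycles 1..K."""
    pfs_w, pd_w, _ = trace.at_timing(settings.accrual_timing)
    n = trace.n_cycles
    k = np.arange(1, n + 1)
    if drug.accrual == "pfs":
        w = pfs_w.copy()
    elif drug.accrual == "alive":
        w = pfs_w + pd_w
    else:  # duration_curve
        shape = drug.duration_shape if drug.duration_shape else arm.pfs.shape
        dur = ParametricSurvival.log_logistic(
            1.0 / drug.median_duration_months, shape
        )
        offset = {"start": -1.0, "end": 0.0, "half": -0.5}[settings.accrual_timing]
        t = (k + offset) * settings.cycle_length_months
        w = survival_at(dur, t)
    if drug.max_cycles is not None:
        w = w * (k <= drug.max_cycles)
    return w * drug.cohort_fraction


def cycle_cost(
    arm: ArmDefinition,
    trace: CohortTrace,
    settings: ModelSettings,
    profile: PatientProfile,
    costs: CostTable,
    rules: AccrualRules,
) -> pd.DataFrame:
    """Undiscounted cost components for cycles 1..K (one column each)."""
    pfs_w, pd_w, _ = trace.at_timing(settings.accrual_timing)
    alive_w = pfs_w + pd_w
    n = trace.n_cycles
    out = {}
    any_treatment = np.zeros(n)
    for drug in arm.drugs:
        dose = dose_per_administration(drug, profile)
        per_cycle = drug.administrations_per_cycle * administration_cost(
            dose, drug.vial_mg, drug.vial_price, rules.vial_rounding
        )
        w = on_treatment_weights(drug, arm, trace, settings)
        out[f"drug:{drug.name}"] = per_cycle * w
        any_treatment = np.maximum(any_treatment, w / max(drug.cohort_fraction, 1e-12))
    pd_care = rules.bsc_proportion * pd_w  # progressed patients still in care
    state = {"alive": pfs_w + pd_care, "pfs": pfs_w, "on_treatment": any_treatment}
    out["tests"] = costs.tests_per_cycle * state[rules.tests_on]
    out["followup"] = costs.followup_per_cycle * state[rules.followup_on]
    out["bsc"] = costs.bsc_per_cycle * pd_care
    new_deaths = np.diff(trace.dead)
    out["terminal"] = costs.terminal_care * new_deaths
    ae = np.zeros(n)
    ae[0] = sum(
        inc * costs.ae_management.get(name, 0.0)
        for name, inc in arm.ae_incidence.items()
    )
    out["ae"] = ae
    df = pd.DataFrame(out)
    df.insert(0, "cycle", np.arange(1, n + 1))
    return df


def accumulate(
    arm: ArmDefinition,
    trace: CohortTrace,
    settings: ModelSettings,
    profile: PatientProfile,
    costs: CostTable,
    utilities: UtilitySet,
    rules: AccrualRules,
) -> ArmResult:
    """Discount and total the per-cycle cost and utility streams."""
    n = trace.n_cycles
    k = np.arange(1, n + 1)
    disc = discount_factor(k, settings.discount_rate, settings.cycle_length_days)
    comp = cycle_cost(arm, trace, settings, profile, costs, rules)
    breakdown = {
        c: float(np.sum(disc * comp[c].to_numpy()))
        for c in comp.columns
        if c != "cycle"
    }
    total_cost = sum(breakdown.values())

    pfs_w, pd_w, _ = trace.at_timing(settings.accrual_timing)
    cyr = settings.cycle_length_years
    qalys = float(np.sum(disc * cyr * (utilities.pfs * pfs_w + utilities.pd * pd_w)))
    ae_burden = sum(arm.ae_incidence.values())
    qalys -= ae_burden * utilities.ae_disutility * cyr * float(disc[0])
    life_years = float(np.sum(cyr * (pfs_w + pd_w)))
    return ArmResult(arm.name, total_cost, qalys, life_years, breakdown)


def evaluate_arm(
    arm: ArmDefinition,
    settings: ModelSettings,
    profile: PatientProfile,
    costs: CostTable,
    utilities: UtilitySet,
    rules: AccrualRules,
) -> tuple[CohortTrace, ArmResult]:
    """Build the arm's occupancy and accrue its economics."""
    trace = build_occupancy(arm.pfs, arm.os, settings)
    return trace, accumulate(arm, trace, settings, profile, costs, utilities, rules)


def compare(
    intervention: ArmResult, comparator: ArmResult, wtp: float
) -> Comparison:
    """Incremental comparison: ICER, dominance flags and net monetary
    benefit (NMB = wtp x QALYs - cost)."""
    if intervention.strategy == comparator.strategy:
        raise ValueError("compare() needs two distinct strategies")
    dc = intervention.cost - comparator.cost
    de = intervention.qalys - comparator.qalys
    dominance = ""
    icer: float | None
    if de > 0 and dc < 0:
        dominance, icer = "dominant", None
    elif de < 0 and dc > 0:
        dominance, icer = "dominated", None
    elif de == 0:
        icer = None
    else:
        icer = dc / de
    return Comparison(
        intervention=intervention,
        comparator=comparator,
        wtp=wtp,
        delta_cost=dc,
        delta_qalys=de,
        icer=icer,
        dominance=dominance,
        nmb_intervention=wtp * intervention.qalys - intervention.cost,
        nmb_comparator=wtp * comparator.qalys - comparator.cost,
    )
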