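"""Dosing arithmetic, vial costing, accrual, discounting, comparison."""

import numpy as np
import pytest

import evcea
from evcea import (
    AccrualRules,
    ArmResult,
    CostTable,
    DrugSpec,
    ModelSettings,
    PatientProfile,
    UtilitySet,
    administration_cost,
    compare,
    discount_factor,
    dose_per_administration,
    evaluate_arm,
)
from evcea.config import apply_params, get_param, run_model
from evcea.economics import cycle_cost
from evcea.cohort import build_occupancy

from conftest import dist

PROFILE = PatientProfile()  # 65 kg, 1.72 m2, CrCl 70


def _ev_spec(**kw):
    base = dict(name="enfortumab_vedotin", vial_mg=30.0, vial_price=1593.2,
                dosing_rule="per_kg", dose_value=1.25, dose_cap_mg=125.0,
                administrations_per_cycle=2)
    base.update(kw)
    return DrugSpec(**base)


class TestDosing:
    def test_per_kg_dose(self):
        assert dose_per_administration(_ev_spec(), PROFILE) == pytest.approx(81.25)

    def test_per_kg_cap_binds(self):
        heavy = PatientProfile(weight_kg=120.0)
        assert dose_per_administration(_ev_spec(), heavy) == pytest.approx(125.0)

    def test_flat_dose(self):
        spec = DrugSpec("pembrolizumab", 100.0, 2548.8, "flat", 200.0)
        assert dose_per_administration(spec, PROFILE) == pytest.approx(200.0)

    def test_per_bsa_dose(self):
        spec = DrugSpec("gemcitabine", 1000.0, 48.1, "per_bsa", 1000.0)
        assert dose_per_administration(spec, PROFILE) == pytest.approx(1720.0)

    def test_calvert_formula(self):
        spec = DrugSpec("carboplatin", 100.0, 9.2, "calvert", 5.0)
        assert dose_per_administration(spec, PROFILE) == pytest.approx(475.0)

    def test_unknown_rule_rejected(self):
        with pytest.raises(ValueError):
            DrugSpec("x", 10.0, 1.0, "per_furlong", 1.0)


class TestVialCosting:
    def test_whole_vial_rounds_up(self):
        # 81.25 mg in 30 mg vials -> 3 vials
        assert administration_cost(81.25, 30.0, 1593.2) == pytest.approx(4779.6)

    def test_pembrolizumab_administration(self):
        assert administration_cost(200.0, 100.0, 2548.8) == pytest.approx(5097.6)

    def test_exact_multiple_identical_under_both_policies(self):
        whole = administration_cost(200.0, 100.0, 2548.8, "whole")
        linear = administration_cost(200.0, 100.0, 2548.8, "linear")
        assert whole == pytest.approx(linear)

    def test_linear_policy_prorates(self):
        assert administration_cost(81.25, 30.0, 1593.2, "linear") == pytest.approx(
            81.25 / 30.0 * 1593.2
        )


class TestDiscounting:
    def test_zero_rate_is_unity(self):
        assert discount_factor(100, 0.0) == 1.0

    def test_cycle_zero_is_unity(self):
        assert discount_factor(0, 0.05) == 1.0

    def test_final_cycle_value(self):
        # 261 cycles x 21 d = 15.0 years: 1/1.05^15.016
        assert discount_factor(261, 0.05) == pytest.approx(0.480631, abs=1e-6)

    def test_negative_rate_rejected(self):
        with pytest.raises(ValueError):
            discount_factor(1, -0.01)


class TestCycleCost:
    def test_chemo_drug_cost_stops_at_cap(self, cfg):
        arm = cfg.arm_definition("chemotherapy")
        trace = build_occupancy(arm.pfs, arm.os, cfg.settings)
        comp = cycle_cost(arm, trace, cfg.settings, cfg.patient, cfg.costs,
                          cfg.rules)
        for drug in ("gemcitabine", "cisplatin", "carboplatin"):
            col = comp[f"drug:{drug}"].to_numpy()
            assert np.all(col[:6] > 0)
            assert np.all(col[6:] == 0.0)

    def test_chemo_ae_cost_at_first_cycle_only(self, cfg):
        arm = cfg.arm_definition("chemotherapy")
        trace = build_occupancy(arm.pfs, arm.os, cfg.settings)
        comp = cycle_cost(arm, trace, cfg.settings, cfg.patient, cfg.costs,
                          cfg.rules)
        ae = comp["ae"].to_numpy()
        # incidence-weighted sum over the chemo AE rows; anemia alone
        # contributes 0.314 x 533.3 = 167.5
        assert ae[0] == pytest.approx(474.226, abs=1e-3)
        assert 0.314 * 533.3 == pytest.approx(167.46, abs=0.02)
        assert np.all(ae[1:] == 0.0)

    def test_zero_bsc_proportion_removes_pd_care(self, cfg):
        cfg2 = apply_params(cfg, {"rules.bsc_proportion": 0.0})
        arm = cfg2.arm_definition("ev_pemb")
        trace = build_occupancy(arm.pfs, arm.os, cfg2.settings)
        comp = cycle_cost(arm, trace, cfg2.settings, cfg2.patient, cfg2.costs,
                          cfg2.rules)
        assert np.all(comp["bsc"].to_numpy() == 0.0)


class TestAccumulate:
    def test_zero_utilities_give_zero_qalys(self, cfg):
        cfg.utilities = UtilitySet(pfs=0.0, pd=0.0, ae_disutility=0.0)
        arm = cfg.arm_definition("ev_pemb")
        _, res = evaluate_arm(arm, cfg.settings, cfg.patient, cfg.costs,
                              cfg.utilities, cfg.rules)
        assert res.qalys == 0.0

    def test_breakdown_sums_to_total(self, base_comparison):
        for res in (base_comparison.intervention, base_comparison.comparator):
            assert sum(res.breakdown.values()) == pytest.approx(res.cost, rel=1e-9)

    def test_discounting_monotonicity(self, cfg):
        undisc = run_model(apply_params(cfg, {"settings.discount_rate": 0.0}))
        disc = run_model(cfg)
        for arm in ("intervention", "comparator"):
            assert getattr(undisc, arm).cost >= getattr(disc, arm).cost
            assert getattr(undisc, arm).qalys >= getattr(disc, arm).qalys

    def test_qalys_bounded_by_discounted_life_years(self, cfg):
        arm = cfg.arm_definition("ev_pemb")
        _, res = evaluate_arm(arm, cfg.settings, cfg.patient, cfg.costs,
                              cfg.utilities, cfg.rules)
        assert 0.0 < res.qalys < res.life_years * max(cfg.utilities.pfs,
                                                      cfg.utilities.pd)

    def test_doubling_prices_doubles_cost_not_qalys(self, cfg):
        base = run_model(cfg)
        price_paths = [r.path for r in cfg.sensitivity
                       if r.path.startswith(("drug_price", "costs"))]
        doubled = apply_params(
            cfg, {p: 2.0 * get_param(cfg, p) for p in price_paths}
        )
        res = run_model(doubled)
        for arm in ("intervention", "comparator"):
            assert getattr(res, arm).cost == pytest.approx(
                2.0 * getattr(base, arm).cost, rel=1e-9
            )
            assert getattr(res, arm).qalys == pytest.approx(
                getattr(base, arm).qalys, rel=1e-12
            )

    def test_equal_traces_make_delta_cost_invariant_to_shared_items(self, cfg):
        """With identical curves in both arms, a shared recurring cost
        accrues identically and cancels out of the increment."""
        cfg.survival["ev_pemb"] = {k: v for k, v in
                                   cfg.survival["chemotherapy"].items()}
        base = run_model(cfg)
        bumped = run_model(apply_params(cfg, {"costs.tests_per_cycle": 999.9}))
        assert bumped.delta_cost == pytest.approx(base.delta_cost, abs=1e-6)

    def test_unequal_traces_do_not_cancel_shared_items(self, cfg):
        base = run_model(cfg)
        bumped = run_model(apply_params(cfg, {"costs.tests_per_cycle": 999.9}))
        assert abs(bumped.delta_cost - base.delta_cost) > 1.0


class TestCompare:
    def _arm(self, name, cost, qalys):
        return ArmResult(name, cost, qalys, qalys)

    def test_icer_matches_hand_division(self):
        # dividing the published rounded totals gives 231,612; the model's
        # own ICER must come from unrounded internals instead
        cmp = compare(self._arm("a", 375420.24, 3.22),
                      self._arm("b", 23369.67, 1.70), 38133.0)
        assert cmp.icer == pytest.approx(352050.57 / 1.52, rel=1e-4)
        assert cmp.icer == pytest.approx(231612.2, rel=1e-4)

    def test_identical_arms_undefined_icer(self):
        cmp = compare(self._arm("a", 100.0, 1.0), self._arm("b", 100.0, 1.0),
                      38133.0)
        assert cmp.icer is None and cmp.dominance == ""

    def test_dominant_and_dominated_flags(self):
        dom = compare(self._arm("a", 50.0, 2.0), self._arm("b", 100.0, 1.0),
                      38133.0)
        assert dom.dominance == "dominant" and dom.icer is None
        assert dom.cost_effective
        ded = compare(self._arm("a", 200.0, 0.5), self._arm("b", 100.0, 1.0),
                      38133.0)
        assert ded.dominance == "dominated" and not ded.cost_effective

    def test_nmb(self):
        cmp = compare(self._arm("a", 100.0, 2.0), self._arm("b", 50.0, 1.0),
                      1000.0)
        assert cmp.nmb_intervention == pytest.approx(1900.0)
        assert cmp.nmb_comparator == pytest.approx(950.0)

    def test_same_strategy_rejected(self):
        with pytest.raises(ValueError):
            compare(self._arm("a", 1.0, 1.0), self._arm("a", 2.0, 2.0), 1.0)
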