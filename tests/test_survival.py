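"""Survival distributions: evaluation, medians, transitions, fitting."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from lifelines import LogLogisticFitter, WeibullFitter

from evcea import (
    Family,
    KMCurve,
    ParametricSurvival,
    fit_ipd,
    fit_parametric,
    median_time,
    rank_fits,
    survival_at,
    transition_probability,
)
from evcea.survival import FitError, FitResult
from evcea.synthetic import km_estimate, simulate_ipd

from conftest import dist

CYCLE_MONTHS = 21.0 / 30.4375

ALL_FAMILIES = [
    ParametricSurvival(Family.EXPONENTIAL, (0.05,)),
    ParametricSurvival(Family.WEIBULL, (0.06, 1.3)),
    ParametricSurvival(Family.LOG_NORMAL, (2.5, 0.8)),
    ParametricSurvival(Family.LOG_LOGISTIC, (0.0766, 1.268)),
    ParametricSurvival(Family.GOMPERTZ, (0.03, 0.05)),
    ParametricSurvival(Family.GENERALIZED_GAMMA, (2.7, 0.9, 0.5)),
]


@pytest.mark.parametrize("d", ALL_FAMILIES, ids=lambda d: d.family.value)
def test_survival_basics_every_family(d):
    assert survival_at(d, 0.0) == pytest.approx(1.0)
    t = np.linspace(0.0, 120.0, 400)
    s = survival_at(d, t)
    assert np.all(np.diff(s) <= 1e-14)
    assert np.all((s > 0) & (s <= 1))
    # S(median) = 1/2
    assert survival_at(d, median_time(d)) == pytest.approx(0.5, abs=1e-9)


def test_survival_rejects_bad_inputs():
    d = dist("ev_pemb", "os")
    with pytest.raises(ValueError):
        survival_at(d, -1.0)
    with pytest.raises(ValueError):
        ParametricSurvival(Family.LOG_LOGISTIC, (-0.1, 1.2))
    with pytest.raises(ValueError):
        ParametricSurvival(Family.WEIBULL, (0.1, 0.0))


def test_log_logistic_evaluation_matches_closed_form():
    # independent hand evaluation of S(t) = 1/(1 + (lambda t)^gamma)
    assert survival_at(dist("ev_pemb", "os"), 12.0) == pytest.approx(
        0.7853147, abs=1e-6
    )


def test_log_logistic_median_is_reciprocal_scale():
    # chemotherapy OS: 1/lambda = 15.993, against the trial's 16.1 months
    d = dist("chemotherapy", "os")
    assert median_time(d) == pytest.approx(15.992981, abs=1e-5)
    assert survival_at(d, 1.0 / d.scale) == pytest.approx(0.5, abs=1e-12)
    # chemotherapy PFS: 6.388 against the trial's 6.3 months
    assert median_time(dist("chemotherapy", "pfs")) == pytest.approx(6.388, abs=1e-3)


def test_exponential_median_closed_form():
    lam = 0.11
    d = ParametricSurvival(Family.EXPONENTIAL, (lam,))
    assert median_time(d) == pytest.approx(np.log(2) / lam, rel=1e-12)


def test_transition_probability_first_cycle_chemo_pfs():
    d = dist("chemotherapy", "pfs")
    p1 = transition_probability(d, 1, CYCLE_MONTHS)
    assert p1 == pytest.approx(0.0115914, abs=1e-6)


def test_transition_probability_vanishes_with_cycle_length():
    d = dist("ev_pemb", "pfs")
    assert transition_probability(d, 1, 1e-9) < 1e-8


def test_exponential_transitions_are_memoryless():
    lam = 0.08
    d = ParametricSurvival(Family.EXPONENTIAL, (lam,))
    expected = 1.0 - np.exp(-lam * CYCLE_MONTHS)
    for k in (1, 7, 200):
        assert transition_probability(d, k, CYCLE_MONTHS) == pytest.approx(
            expected, rel=1e-12
        )


@pytest.mark.parametrize("d", ALL_FAMILIES, ids=lambda d: d.family.value)
def test_transition_probabilities_telescope_to_survival(d):
    """Compounding per-cycle exit probabilities reconstructs S(t) exactly."""
    surv = 1.0
    for k in range(1, 262):
        surv *= 1.0 - transition_probability(d, k, CYCLE_MONTHS)
        assert surv == pytest.approx(
            survival_at(d, k * CYCLE_MONTHS), abs=1e-12
        )


@given(
    lam=st.floats(0.01, 0.5),
    gam=st.floats(0.5, 4.0),
    t1=st.floats(0.0, 200.0),
    t2=st.floats(0.0, 200.0),
)
@settings(max_examples=60, deadline=None, derandomize=True)
def test_log_logistic_monotone_property(lam, gam, t1, t2):
    d = ParametricSurvival.log_logistic(lam, gam)
    lo, hi = sorted((t1, t2))
    assert survival_at(d, lo) >= survival_at(d, hi)


def test_quantile_inverts_survival():
    for d in ALL_FAMILIES:
        for s in (0.9, 0.5, 0.1):
            assert survival_at(d, d.quantile(s)) == pytest.approx(s, abs=1e-8)


# ---------------------------------------------------------------------------
# fitting


def _exact_curve(d, n_points=40, t_max=60.0):
    t = np.linspace(0.5, t_max, n_points)
    return KMCurve(t, survival_at(d, t))


def test_wls_fit_recovers_exact_log_logistic_curve():
    truth = ParametricSurvival.log_logistic(0.0766, 1.268)
    res = fit_parametric(_exact_curve(truth), Family.LOG_LOGISTIC, method="wls")
    assert res.dist.scale == pytest.approx(truth.scale, rel=0.01)
    assert res.dist.shape == pytest.approx(truth.shape, rel=0.01)
    # idempotence: refitting the fitted curve reproduces the parameters
    res2 = fit_parametric(_exact_curve(res.dist), Family.LOG_LOGISTIC, method="wls")
    assert res2.dist.scale == pytest.approx(res.dist.scale, rel=1e-3)


@pytest.mark.parametrize("family", [Family.WEIBULL, Family.EXPONENTIAL,
                                    Family.LOG_NORMAL, Family.GOMPERTZ])
def test_wls_fit_recovers_other_families(family):
    truth = {
        Family.WEIBULL: ParametricSurvival(Family.WEIBULL, (0.06, 1.4)),
        Family.EXPONENTIAL: ParametricSurvival(Family.EXPONENTIAL, (0.05,)),
        Family.LOG_NORMAL: ParametricSurvival(Family.LOG_NORMAL, (2.8, 0.9)),
        Family.GOMPERTZ: ParametricSurvival(Family.GOMPERTZ, (0.02, 0.04)),
    }[family]
    res = fit_parametric(_exact_curve(truth), family, method="wls")
    assert np.allclose(res.dist.params, truth.params, rtol=0.02)


def test_mle_matches_lifelines_oracle_log_logistic():
    """Our likelihood maximiser against lifelines' on the same data."""
    truth = dist("chemotherapy", "os")
    ipd = simulate_ipd(truth, 600, seed=7)
    ours = fit_ipd(ipd.time, ipd.event, Family.LOG_LOGISTIC)
    llf = LogLogisticFitter().fit(ipd.time, ipd.event)
    assert ours.dist.scale == pytest.approx(1.0 / llf.alpha_, rel=1e-3)
    assert ours.dist.shape == pytest.approx(llf.beta_, rel=1e-3)
    assert ours.loglik == pytest.approx(llf.log_likelihood_, rel=1e-6)


def test_mle_matches_lifelines_oracle_weibull():
    truth = ParametricSurvival(Family.WEIBULL, (0.07, 1.4))
    ipd = simulate_ipd(truth, 600, seed=11)
    ours = fit_ipd(ipd.time, ipd.event, Family.WEIBULL)
    wf = WeibullFitter().fit(ipd.time, ipd.event)
    assert ours.dist.scale == pytest.approx(1.0 / wf.lambda_, rel=1e-3)
    assert ours.dist.shape == pytest.approx(wf.rho_, rel=1e-3)


def test_exponential_mle_closed_form():
    ipd = simulate_ipd(
        ParametricSurvival(Family.EXPONENTIAL, (0.09,)), 400, seed=3
    )
    res = fit_ipd(ipd.time, ipd.event, Family.EXPONENTIAL)
    assert res.dist.scale == pytest.approx(
        ipd.event.sum() / ipd.time.sum(), rel=1e-5
    )


def test_parameter_recovery_improves_with_sample_size():
    truth = dist("chemotherapy", "os")
    errs = {}
    for n in (100, 2000):
        rel = []
        for seed in (1, 2, 3):
            ipd = simulate_ipd(truth, n, seed=seed)
            fit = fit_ipd(ipd.time, ipd.event, Family.LOG_LOGISTIC)
            rel.append(abs(fit.dist.scale / truth.scale - 1.0)
                       + abs(fit.dist.shape / truth.shape - 1.0))
        errs[n] = np.mean(rel)
    assert errs[2000] < errs[100]
    assert errs[2000] < 0.08


def test_fit_rejects_degenerate_curve():
    flat = KMCurve(np.arange(1.0, 8.0), np.ones(7))
    with pytest.raises(FitError, match="degenerate"):
        fit_parametric(flat, Family.LOG_LOGISTIC)


def test_curve_cleaning_enforces_monotonicity():
    noisy = KMCurve(np.array([1.0, 2.0, 3.0, 4.0]),
                    np.array([0.9, 0.95, 0.6, 0.65]))
    clean = noisy.cleaned()
    assert np.all(np.diff(clean.survival) <= 0)


def _fr(aic, bic, k=2):
    fam = Family.LOG_LOGISTIC if k == 2 else Family.EXPONENTIAL
    d = (ParametricSurvival.log_logistic(0.1, 1.0) if k == 2
         else ParametricSurvival(Family.EXPONENTIAL, (0.1,)))
    return FitResult(d, 0.0, aic, bic, 10)


def test_rank_fits_orders_by_aic_then_bic_then_parsimony():
    a, b = _fr(100, 200), _fr(110, 150)
    assert rank_fits([b, a])[0] is a
    c, d_ = _fr(100, 105), _fr(100, 102)
    assert rank_fits([c, d_])[0] is d_
    e, f = _fr(100, 100, k=2), _fr(100, 100, k=1)
    assert rank_fits([e, f])[0] is f
    with pytest.raises(ValueError):
        rank_fits([])


def test_model_selection_prefers_generating_family():
    """Six-family fits on log-logistic data should rank log-logistic first
    most of the time (the information criteria recover the generator)."""
    truth = dist("ev_pemb", "os")
    wins = 0
    reps = 8
    for seed in range(reps):
        # complete follow-up: the heavy log-logistic tail is what separates
        # the families, so the whole curve must be observed
        ipd = simulate_ipd(truth, 1000, seed=100 + seed,
                           admin_censor_months=None, annual_dropout=0.0)
        curve = km_estimate(ipd)
        fits = []
        for fam in Family:
            try:
                fits.append(fit_parametric(curve, fam))
            except FitError:
                continue
        if rank_fits(fits)[0].dist.family == Family.LOG_LOGISTIC:
            wins += 1
    assert wins >= reps * 0.6


def test_fit_result_serialization_roundtrip(tmp_path):
    truth = dist("ev_pemb", "pfs")
    res = fit_parametric(_exact_curve(truth), Family.LOG_LOGISTIC, method="wls")
    path = tmp_path / "fit.json"
    res.to_json(path)
    import json

    d = json.loads(path.read_text())
    assert d["family"] == "log-logistic"
    assert d["aic"] == pytest.approx(res.aic)
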