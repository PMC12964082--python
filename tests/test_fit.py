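"""Support functions, maximum-likelihood estimation, grid search, bootstrap."""

import numpy as np
import pytest

from dextral.fit import (
    NAMED_STARTS,
    bootstrap_ci,
    fit_mle,
    grid_search,
    loglik_extended,
    loglik_M,
    loglik_T,
)
from dextral.io import FamilialStudy, SexStratifiedStudy
from dextral.model import BaseParams, ExtendedParams, equilibrium
from dextral.simulate import (
    SyntheticConfig,
    simulate_familial,
    simulate_sex_stratified,
)
from conftest import make_study

STARTS = [np.array(s) for s in NAMED_STARTS]


def test_loglik_T_single_class_arithmetic():
    # RxR only, 9 right / 1 left at p = 0.9
    study = make_study([[9, 1], [0, 0], [0, 0]])
    val = loglik_T(BaseParams(0.262, 0.138), [study])
    assert val == pytest.approx(9 * np.log(0.9) + np.log(0.1), abs=1e-10)
    assert val == pytest.approx(-3.2510, abs=5e-4)


def test_loglik_T_cross_entropy_identity():
    """At the observed proportion, the support equals -n H(p-hat)."""
    study = make_study([[80, 20], [0, 0], [0, 0]])
    p_hat = 0.8
    val = loglik_T(BaseParams(p_hat - 0.5 - 0.1, 0.1), [study])
    entropy = -(p_hat * np.log(p_hat) + (1 - p_hat) * np.log(1 - p_hat))
    assert val == pytest.approx(-100 * entropy, abs=1e-9)


def test_loglik_binom_coefficient_flag():
    study = make_study([[9, 1], [3, 1], [1, 1]])
    bare = loglik_T(BaseParams(0.2, 0.1), [study])
    full = loglik_T(BaseParams(0.2, 0.1), [study], include_binom_coef=True)
    expected_const = np.log(10) + np.log(4) + np.log(2)
    assert full - bare == pytest.approx(expected_const, abs=1e-9)


def test_loglik_M_equals_T_when_incidences_match(rng):
    """With every measured incidence at the model's t, M = T exactly."""
    from dextral.fit import _measured_tables
    from dextral.model import transmission_table

    for _ in range(50):
        rho = rng.uniform(0.1, 0.35)
        alpha = rng.uniform(0.02, min(0.14, 0.5 - rho))
        params = BaseParams(rho, alpha)
        t = equilibrium(params).true_incidence
        m_tab = _measured_tables(params, np.array([t]), np.array([t]))[0]
        assert m_tab == pytest.approx(transmission_table(params).matrix, abs=1e-12)


def test_loglik_M_cross_checks_shift_module(familial_fixture):
    """Vectorised per-study M agrees with the explicit matrix product."""
    from dextral.fit import _measured_tables
    from dextral.io import compute_offspring_incidence, compute_parent_incidence
    from dextral.model import transmission_table
    from dextral.shift import adjust_familial, build_adjustment

    params = BaseParams(0.25, 0.12)
    t = equilibrium(params).true_incidence
    m_p = np.array([compute_parent_incidence(s) for s in familial_fixture])
    m_o = np.array([compute_offspring_incidence(s) for s in familial_fixture])
    fast = _measured_tables(params, m_p, m_o)
    table = transmission_table(params)
    for i in range(len(familial_fixture)):
        slow = adjust_familial(table, build_adjustment(t, m_p[i], m_o[i]))
        assert fast[i] == pytest.approx(slow.matrix, abs=1e-12)


def test_scenario_a_and_b_estimates_coincide(familial_fixture):
    fit_a = fit_mle(familial_fixture, scenario="A", model="two", starts=STARTS)
    fit_b = fit_mle(familial_fixture, scenario="B", model="two", starts=STARTS)
    assert fit_a.params.rho == pytest.approx(fit_b.params.rho, abs=1e-8)
    assert fit_a.params.alpha == pytest.approx(fit_b.params.alpha, abs=1e-8)


def test_fit_recovers_truth_on_shift_free_data():
    truth = BaseParams(0.277, 0.138)
    cfg = SyntheticConfig(true_params=truth, shift=None, n_datasets=1, seed=10,
                          study_sizes=(40000,))
    (dataset,) = simulate_familial(cfg)
    fit = fit_mle(dataset, scenario="A", model="two", starts=STARTS)
    assert fit.params.rho == pytest.approx(truth.rho, abs=0.01)
    assert fit.params.alpha == pytest.approx(truth.alpha, abs=0.01)


def test_scenario_c_equals_a_on_shift_free_data():
    truth = BaseParams(0.277, 0.138)
    # large studies so the measured incidences sit close to t and the
    # adjustment approaches the identity (it reacts to any m != t, including
    # pure sampling noise)
    cfg = SyntheticConfig(true_params=truth, shift=None, n_datasets=1, seed=11,
                          study_sizes=(20000, 20000, 20000))
    (dataset,) = simulate_familial(cfg)
    fit_a = fit_mle(dataset, scenario="A", model="two", starts=STARTS)
    fit_c = fit_mle(dataset, scenario="C", model="two", starts=STARTS)
    assert fit_c.params.rho == pytest.approx(fit_a.params.rho, abs=0.01)
    assert fit_c.params.alpha == pytest.approx(fit_a.params.alpha, abs=0.02)


def test_three_parameter_support_never_below_two(familial_fixture):
    fit2 = fit_mle(familial_fixture, scenario="B", model="two", starts=STARTS)
    fit3 = fit_mle(familial_fixture, scenario="B", model="three", n_starts=40,
                   seed=3)
    assert fit3.loglik >= fit2.loglik - 1e-6


def test_grid_search_agrees_with_simplex(familial_fixture):
    fit = fit_mle(familial_fixture, scenario="B", model="two", starts=STARTS)
    grid = grid_search(familial_fixture, scenario="B", model="two", n_points=501)
    step = 0.5 / 500
    assert abs(grid.params.rho - fit.params.rho) <= step
    assert abs(grid.params.alpha - fit.params.alpha) <= step
    assert grid.loglik <= fit.loglik + 1e-9
    assert grid.loglik == pytest.approx(np.max(grid.surface))


def test_grid_search_degenerate_two_points(familial_fixture):
    grid = grid_search(familial_fixture, scenario="B", model="two", n_points=2)
    assert grid.params is not None
    assert grid.surface.shape == (2, 2)


def test_grid_search_scenario_c_small(familial_fixture):
    grid = grid_search(familial_fixture, scenario="C", model="two", n_points=11)
    assert np.isfinite(grid.loglik)


def test_bootstrap_interval_nesting_and_repro(familial_fixture):
    fit = fit_mle(familial_fixture, scenario="B", model="two", starts=STARTS)
    boot = bootstrap_ci(familial_fixture, scenario="B", model="two", n_boot=30,
                        levels=(0.5, 0.9, 0.99), seed=7, fit0=fit)
    iv = boot["intervals"]
    for name in ("rho", "alpha"):
        assert iv[0.5][name][0] >= iv[0.9][name][0] >= iv[0.99][name][0]
        assert iv[0.5][name][1] <= iv[0.9][name][1] <= iv[0.99][name][1]
    boot2 = bootstrap_ci(familial_fixture, scenario="B", model="two", n_boot=30,
                         levels=(0.5, 0.9, 0.99), seed=7, fit0=fit)
    assert np.array_equal(boot["estimates"], boot2["estimates"])


def test_bootstrap_degenerate_all_right():
    study = make_study([[300, 0], [90, 0], [30, 0]])
    fit = fit_mle([study], scenario="B", model="two", n_starts=30, seed=1)
    boot = bootstrap_ci([study], scenario="B", model="two", n_boot=10, seed=2,
                        fit0=fit, levels=(0.95,))
    lo, hi = boot["intervals"][0.95]["rho"]
    # every resample reproduces the all-right data: interval collapses
    assert hi - lo == pytest.approx(0.0, abs=1e-6)


def test_extended_loglik_reduces_to_base_on_collapsed_data():
    ext_truth = ExtendedParams(0.25, 0.1, 0.1, 0.02, 0.02, 0.02, 0.02, model_id="II")
    sex_study = simulate_sex_stratified(ext_truth, 2000, seed=5)
    base = BaseParams(0.25, 0.1, 0.02)
    val_ext = loglik_extended(ext_truth, [sex_study], adjusted=False)
    counts4 = sex_study.offspring_counts.sum(axis=1)  # pool sexes
    collapsed = np.array(
        [counts4[0], counts4[1] + counts4[2], counts4[3]]
    )
    fam = FamilialStudy(study_id="collapsed", offspring_counts=collapsed)
    val_base = loglik_T(base, [fam])
    assert val_ext == pytest.approx(val_base, abs=1e-9)


def test_extended_nesting_monotonicity():
    truth = ExtendedParams(0.25, 0.1, 0.06, 0.05, 0.01, -0.03, -0.08, model_id="V")
    sex = simulate_sex_stratified(truth, 8000, seed=9)
    logliks = {}
    for m in ("I", "II", "III", "IV", "V"):
        logliks[m] = fit_mle([sex], scenario="C", model=m, n_starts=8,
                             seed=4).loglik
    tol = 1e-4
    assert logliks["I"] <= logliks["II"] + tol
    assert logliks["II"] <= logliks["III"] + tol
    assert logliks["II"] <= logliks["IV"] + tol
    assert logliks["III"] <= logliks["V"] + tol
    assert logliks["IV"] <= logliks["V"] + tol


def test_fit_rejects_bad_inputs(familial_fixture):
    with pytest.raises(ValueError):
        fit_mle([], scenario="B", model="two")
    with pytest.raises(ValueError):
        fit_mle(familial_fixture, scenario="D", model="two")
    with pytest.raises(ValueError):
        fit_mle(familial_fixture, scenario="B", model="seven")
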