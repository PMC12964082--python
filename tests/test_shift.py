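"""Criterion-shift nuisance parameters, transition matrices and adjustment."""

import numpy as np
import pytest
from scipy.optimize import brentq

from dextral.model import BaseParams, equilibrium, transmission_table
from dextral.shift import (
    adjust_familial,
    adjust_twin,
    build_adjustment,
    offspring_matrix,
    offspring_nuisance,
    parent_matrix,
    parent_matrix_ordered,
    parent_nuisance,
    twin_pair_matrix,
)


def _solve_parent_flip(t, m_p):
    """Independent numeric oracle: flip rate making the measured->true map
    carry measured incidence m_p onto true incidence t."""
    if m_p > t:  # measured L -> true R with prob u: true-left = m_p (1 - u)
        return brentq(lambda u: m_p * (1 - u) - t, 0, 1), 0.0
    if m_p < t:  # measured R -> true L with prob v
        return 0.0, brentq(lambda v: m_p + (1 - m_p) * v - t, 0, 1)
    return 0.0, 0.0


def _solve_offspring_flip(t, m_o):
    if m_o > t:  # true R -> measured L with prob w: measured-left = t + (1-t) w
        return brentq(lambda w: t + (1 - t) * w - m_o, 0, 1), 0.0
    if m_o < t:
        return 0.0, brentq(lambda x: t * (1 - x) - m_o, 0, 1)
    return 0.0, 0.0


@pytest.mark.parametrize("t, m", [(0.1, 0.2), (0.2, 0.1), (0.15, 0.15), (0.117, 0.0356)])
def test_nuisance_against_numeric_solver(t, m):
    assert parent_nuisance(t, m) == pytest.approx(_solve_parent_flip(t, m), abs=1e-12)
    assert offspring_nuisance(t, m) == pytest.approx(_solve_offspring_flip(t, m), abs=1e-12)


def test_nuisance_known_values():
    assert parent_nuisance(0.1, 0.2) == pytest.approx((0.5, 0.0))
    assert parent_nuisance(0.2, 0.1) == pytest.approx((0.0, 1 / 9))
    assert offspring_nuisance(0.1, 0.2) == pytest.approx((1 / 9, 0.0))
    assert offspring_nuisance(0.2, 0.1) == pytest.approx((0.0, 0.5))


def test_nuisance_rejects_boundary():
    for bad in (0.0, 1.0):
        with pytest.raises(ValueError):
            parent_nuisance(bad, 0.5)
        with pytest.raises(ValueError):
            offspring_nuisance(0.5, bad)


def test_marginal_consistency_random_draws(rng):
    """Defining property: the maps carry measured onto true incidence (and
    the equilibrium phenotype distribution onto the measured one) exactly."""
    for _ in range(1000):
        t, m = rng.uniform(0.01, 0.99, size=2)
        u, v = parent_nuisance(t, m)
        q = np.array([[1 - v, v], [u, 1 - u]])  # measured -> true
        true_dist = np.array([1 - m, m]) @ q
        assert true_dist[1] == pytest.approx(t, abs=1e-12)
        w, x = offspring_nuisance(t, m)
        o = offspring_matrix(w, x)              # true -> measured
        measured = np.array([1 - t, t]) @ o
        assert measured[1] == pytest.approx(m, abs=1e-12)


def _parent_matrix_bruteforce(u, v):
    """Expand the per-parent map over ordered parent pairs, then pool."""
    q = np.array([[1 - v, v], [u, 1 - u]])
    unordered = {("R", "R"): 0, ("R", "L"): 1, ("L", "R"): 1, ("L", "L"): 2}
    P = np.zeros((3, 3))
    hands = ("R", "L")
    for m1 in (0, 1):
        for m2 in (0, 1):
            row = unordered[(hands[m1], hands[m2])]
            weight = 0.5 if row == 1 else 1.0  # two ordered cells pool into 'mixed'
            for t1 in (0, 1):
                for t2 in (0, 1):
                    col = unordered[(hands[t1], hands[t2])]
                    P[row, col] += weight * q[m1, t1] * q[m2, t2]
    return P


@pytest.mark.parametrize("u, v", [(0.5, 0.0), (0.0, 0.2), (0.0, 0.0), (0.123, 0.0)])
def test_parent_matrix_matches_independent_expansion(u, v):
    P = parent_matrix(u, v)
    assert P == pytest.approx(_parent_matrix_bruteforce(u, v), abs=1e-12)
    assert P.sum(axis=1) == pytest.approx(np.ones(3), abs=1e-12)


def test_parent_matrix_known_rows():
    assert parent_matrix(0.5, 0.0) == pytest.approx(
        np.array([[1, 0, 0], [0.5, 0.5, 0], [0.25, 0.5, 0.25]])
    )
    assert parent_matrix(0.0, 0.2) == pytest.approx(
        np.array([[0.64, 0.32, 0.04], [0, 0.8, 0.2], [0, 0, 1]])
    )
    assert parent_matrix(0.0, 0.0) == pytest.approx(np.eye(3))


def test_both_errors_active_rejected():
    with pytest.raises(ValueError):
        parent_matrix(0.1, 0.1)
    with pytest.raises(ValueError):
        offspring_matrix(0.1, 0.1)


def test_offspring_matrix_forms():
    assert offspring_matrix(0.1, 0.0) == pytest.approx(
        np.array([[0.9, 0.1], [0.0, 1.0]])
    )
    assert offspring_matrix(0.0, 0.3) == pytest.approx(
        np.array([[1.0, 0.0], [0.3, 0.7]])
    )


def test_adjust_familial_identity_when_no_shift(laland_params):
    t = equilibrium(laland_params).true_incidence
    table = transmission_table(laland_params)
    adj = build_adjustment(t, t, t)
    m = adjust_familial(table, adj)
    assert m.matrix == pytest.approx(table.matrix, abs=1e-12)


def test_adjust_familial_matches_bruteforce_sum(laland_params):
    table = transmission_table(laland_params)
    t = equilibrium(laland_params).true_incidence
    adj = build_adjustment(t, 2 * t, t + 0.05)  # u and w active
    m = adjust_familial(table, adj).matrix
    brute = np.zeros((3, 2))
    for i in range(3):
        for l in range(2):
            brute[i, l] = sum(
                adj.P[i, j] * table.matrix[j, k] * adj.O[k, l]
                for j in range(3)
                for k in range(2)
            )
    assert m == pytest.approx(brute, abs=1e-14)
    assert m.sum(axis=1) == pytest.approx(np.ones(3), abs=1e-12)


def test_adjusted_offspring_marginal_hits_measured_incidence(rng):
    """Pushing the equilibrium through M reproduces m_o at the mating mix."""
    for _ in range(200):
        rho = rng.uniform(0.05, 0.4)
        alpha = rng.uniform(0.01, min(0.2, 0.5 - rho))
        params = BaseParams(rho, alpha)
        f = equilibrium(params).f_dr
        t = 1 - f
        m_o = rng.uniform(0.02, 0.4)
        o = offspring_matrix(*offspring_nuisance(t, m_o))
        measured = np.array([1 - t, t]) @ o
        assert measured[1] == pytest.approx(m_o, abs=1e-12)


def test_adjust_twin_identity_and_example():
    probs = np.array([0.81, 0.18, 0.01])
    assert adjust_twin(probs, 0.1, 0.1) == pytest.approx(probs, abs=1e-12)
    out = adjust_twin(probs, 0.1, 0.19)  # w = 0.1
    assert out == pytest.approx([0.6561, 0.3078, 0.0361], abs=1e-12)
    assert out.sum() == pytest.approx(1.0, abs=1e-12)


def test_adjust_twin_matches_ordered_pair_expansion(rng):
    """Oracle: misclassify the two ordered twins independently, then pool."""
    for _ in range(50):
        t = rng.uniform(0.05, 0.3)
        m_o = rng.uniform(0.05, 0.4)
        w, x = offspring_nuisance(t, m_o)
        o = offspring_matrix(w, x)
        p = rng.dirichlet(np.ones(3))
        expected = np.zeros(3)
        # unordered (RR, RL, LL) -> ordered with RL split evenly
        ordered = {(0, 0): p[0], (0, 1): p[1] / 2, (1, 0): p[1] / 2, (1, 1): p[2]}
        for (a, b), mass in ordered.items():
            for ma in (0, 1):
                for mb in (0, 1):
                    idx = ma + mb  # 0=RR, 1=RL, 2=LL
                    expected[idx] += mass * o[a, ma] * o[b, mb]
        assert adjust_twin(p, t, m_o) == pytest.approx(expected, abs=1e-12)


def test_twin_marginal_consistency(laland_params):
    from dextral.model import twin_expectations

    t = equilibrium(laland_params).true_incidence
    pairs = twin_expectations(laland_params)
    for m_o in (0.05, 0.138, 0.25):
        out = adjust_twin(pairs, t, m_o)
        left_rate = (out[1] + 2 * out[2]) / 2
        # input individual-level marginal equals t, output must equal m_o
        in_rate = (pairs[1] + 2 * pairs[2]) / 2
        assert in_rate == pytest.approx(t, abs=1e-12)
        assert left_rate == pytest.approx(m_o, abs=1e-12)


def test_ordered_parent_matrix_is_kron_square():
    P4 = parent_matrix_ordered(0.3, 0.0)
    q = np.array([[1.0, 0.0], [0.3, 0.7]])
    assert P4 == pytest.approx(np.kron(q, q), abs=1e-14)
    assert P4.sum(axis=1) == pytest.approx(np.ones(4), abs=1e-12)
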