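import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from mutatorqs import (CompositePart, MutatorParams, classify_phase,
                       linear_border_slope, make_composite, make_landscape,
                       mean_fitness_general, mixed_phase_fitness,
                       multidim_potential, mutator_phase_fitness, potential,
                       single_peak_solution, small_a_asymptotics,
                       steady_state, surplus_and_ratio, wkb_mutator_fraction)

rates = st.floats(min_value=0.01, max_value=5.0)


# ---------------------------------------------------------------------------
# potential branches

@settings(max_examples=60, deadline=None, derandomize=True)
@given(x=st.floats(min_value=-0.999, max_value=0.999),
       mu1=rates, mu2=rates, a1=rates, a2=rates, k=rates)
def test_potential_branches_match_quadratic_formula_oracle(x, mu1, mu2,
                                                           a1, a2, k):
    """V+- are the roots of the 2x2 characteristic polynomial."""
    land = make_landscape("linear", k=k)
    p = MutatorParams(L=100, mu1=mu1, mu2=mu2, alpha1=a1, alpha2=a2)
    curve = potential(p, land, x_grid=np.array([x]))
    loss = 1.0 - math.sqrt(1.0 - x * x)
    d1 = k * x - mu1 * loss - a1
    d2 = k * x - mu2 * loss - a2
    # independent quadratic-formula root oracle
    tr, det = d1 + d2, d1 * d2 - a1 * a2
    root = math.sqrt(tr * tr - 4 * det)
    vp, vm = 0.5 * (tr + root), 0.5 * (tr - root)
    assert curve.V_plus[0] == pytest.approx(vp, abs=1e-14, rel=1e-12)
    assert curve.V_minus[0] == pytest.approx(vm, abs=1e-14, rel=1e-12)
    assert curve.V_plus[0] >= curve.V_minus[0]


@settings(max_examples=30, deadline=None, derandomize=True)
@given(mu=rates, alpha=rates, c=rates)
def test_symmetric_case_alpha_independence(mu, alpha, c):
    """With mu1 = mu2, f = g, alpha1 = alpha2 the upper branch is the
    classical single-chain potential, independent of alpha, and the
    branch gap is exactly 2 alpha."""
    land = make_landscape("quadratic", c=c)
    x = np.linspace(-0.99, 0.99, 41)
    p = MutatorParams(L=100, mu1=mu, mu2=mu, alpha1=alpha, alpha2=alpha)
    curve = potential(p, land, x_grid=x)
    classical = 0.5 * c * x ** 2 - mu * (1.0 - np.sqrt(1.0 - x ** 2))
    assert np.allclose(curve.V_plus, classical, atol=1e-12)
    assert np.allclose(curve.V_plus - curve.V_minus, 2 * alpha, atol=1e-12)


def test_symmetric_quadratic_closed_form_maximum():
    # c x^2/2 - (1 - sqrt(1-x^2)) with c = 3 peaks at x^2 = 8/9, value 2/3
    land = make_landscape("quadratic", c=3.0)
    p = MutatorParams(L=100, mu1=1.0, mu2=1.0, alpha1=1.0, alpha2=1.0)
    assert mean_fitness_general(p, land) == pytest.approx(2.0 / 3.0,
                                                          abs=1e-12)


def test_mean_fitness_unidirectional_closed_form():
    land = make_landscape("linear", k=1.0)
    p = MutatorParams(L=100, mu1=1.0, mu2=10.0, alpha1=0.3)
    R = mean_fitness_general(p, land)
    assert R == pytest.approx(math.sqrt(2.0) - 1.0 - 0.3, abs=1e-10)
    assert mixed_phase_fitness(p, land) == pytest.approx(R, abs=1e-12)


def test_mutator_phase_linear_closed_form():
    """R_mu for f = kx is sqrt(k^2 + mu^2) - mu (stationarity oracle)."""
    land = make_landscape("linear", k=1.0)
    p = MutatorParams(L=100, mu1=1.0, mu2=10.0, alpha1=0.3)
    assert mutator_phase_fitness(p, land) == pytest.approx(
        math.sqrt(101.0) - 10.0, abs=1e-10)
    p0 = MutatorParams(L=100, mu1=1.0, mu2=0.0, alpha1=0.0)
    assert mutator_phase_fitness(p0, land) == pytest.approx(1.0, abs=1e-12)


def test_mixed_phase_as_limit_of_coupled_potential():
    """R_mix equals the alpha2 -> 0 limit of the general potential max
    shifted by alpha1 (quadratic landscape limit oracle)."""
    land = make_landscape("quadratic", c=2.0)
    p0 = MutatorParams(L=100, mu1=1.0, mu2=6.0, alpha1=0.05)
    direct = mixed_phase_fitness(p0, land)
    eps = 1e-9
    p_eps = MutatorParams(L=100, mu1=1.0, mu2=6.0, alpha1=0.05, alpha2=eps)
    assert mean_fitness_general(p_eps, land) == pytest.approx(direct,
                                                              abs=1e-7)


# ---------------------------------------------------------------------------
# surplus and phases

def test_surplus_symmetric_switching():
    """f = g with alpha1 = alpha2: R = f(s) and q = 1/2."""
    land = make_landscape("quadratic", c=3.0)
    p = MutatorParams(L=400, mu1=1.0, mu2=3.5, alpha1=1.0, alpha2=1.0)
    R = mean_fitness_general(p, land)
    s, ratio, q = surplus_and_ratio(p, land, R)
    assert q == pytest.approx(0.5, abs=1e-10)
    assert 1.5 * s * s == pytest.approx(R, abs=1e-9)  # f(s) = R
    # recovered surplus reproduces R through the stationarity condition
    assert ratio == pytest.approx(1.0, abs=1e-8)


def test_surplus_matches_eigenvector_bulk():
    """The analytic surplus matches the eigenvector bulk location.  Even
    landscapes make the linear problem parity-symmetric (the eigenvector
    may split mass between the +-s peaks), so compare E|x|."""
    from mutatorqs import class_grid

    land = make_landscape("quadratic", c=3.0)
    p = MutatorParams(L=400, mu1=1.0, mu2=2.0, alpha1=1.0, alpha2=1.0)
    R = mean_fitness_general(p, land)
    s, _, _ = surplus_and_ratio(p, land, R)
    res = steady_state(p, land)
    x = np.abs(class_grid(400))
    s_abs = float(x @ (res.state.P + res.state.Q))
    assert s_abs == pytest.approx(s, abs=0.02)


@pytest.mark.parametrize("J, a, mu, phase, R", [
    (1.05, 0.001, 10.0, "mixed", 0.049),
    (1.05, 0.2, 0.5, "mutator", 0.55),
    (1.0, 0.5, 2.0, "non_selective", 0.0),
])
def test_single_peak_phases(J, a, mu, phase, R):
    r = single_peak_solution(J, a, mu)
    assert r.phase == phase
    assert r.R == pytest.approx(R, abs=1e-12)


def test_single_peak_borders_return_border_labels():
    J, mu = 2.0, 1.4
    r = single_peak_solution(J, mu - 1.0, mu)  # a + 1 = mu
    assert r.phase.startswith("border:")
    assert "mixed" in r.phase and "mutator" in r.phase
    r2 = single_peak_solution(J, J - 1.0, 5.0)  # a = J - 1, mu > J
    assert r2.phase.startswith("border:")


def test_single_peak_q_against_finite_L():
    """Closed-form q (L -> infinity) against the L = 5000 eigenvector."""
    r = single_peak_solution(1.05, 0.001, 10.0)
    assert r.q == pytest.approx(0.0201089, abs=1e-6)
    land = make_landscape("single_peak", J=1.05)
    p = MutatorParams(L=5000, mu1=1.0, mu2=10.0, alpha1=0.001)
    q_num = steady_state(p, land).observables.q
    assert q_num == pytest.approx(r.q, rel=5e-3)


def test_classify_phase_delegates_single_peak():
    land = make_landscape("single_peak", J=1.05)
    p = MutatorParams(L=100, mu1=1.0, mu2=10.0, alpha1=0.001)
    r = classify_phase(p, land)
    ref = single_peak_solution(1.05, 0.001, 10.0)
    assert (r.phase, r.R, r.q) == (ref.phase, ref.R, ref.q)


def test_linear_border_and_phase_labels():
    kc = linear_border_slope(1.0, 10.0, 0.02)
    assert kc == pytest.approx(0.212, abs=1e-3)
    # exact crossing at the computed border
    assert (math.sqrt(kc ** 2 + 1) - 1 - 0.02) == pytest.approx(
        math.sqrt(kc ** 2 + 100) - 10, abs=1e-9)
    for k, expected in ((kc * 1.2, "mixed"), (kc * 0.8, "mutator")):
        land = make_landscape("linear", k=k)
        p = MutatorParams(L=100, mu1=1.0, mu2=10.0, alpha1=0.02)
        assert classify_phase(p, land).phase == expected


def test_single_peak_region_adjacency():
    """The (a, mu) plane splits into three connected regions whose
    pairwise contacts happen only along the predicted border lines."""
    J = 2.0
    # grid offsets chosen off the rational border lines
    a_values = np.linspace(0.02, 1.8, 45) + 0.0007
    mu_values = np.linspace(1.02, 3.5, 45) + 0.0003
    labels = np.empty((45, 45), dtype=object)
    for i, a in enumerate(a_values):
        for j, mu in enumerate(mu_values):
            labels[i, j] = single_peak_solution(J, a, mu).phase
    assert set(labels.ravel()) == {"mixed", "mutator", "non_selective"}
    for i in range(45):
        for j in range(45):
            here = labels[i, j]
            for di, dj in ((1, 0), (0, 1)):
                if i + di >= 45 or j + dj >= 45:
                    continue
                there = labels[i + di, j + dj]
                if here == there:
                    continue
                a0, a1 = a_values[i], a_values[i + di]
                m0, m1 = mu_values[j], mu_values[j + dj]
                pair = {here, there}
                if pair == {"mixed", "non_selective"}:
                    assert min(a0, a1) <= J - 1.0 <= max(a0, a1)
                elif pair == {"mutator", "non_selective"}:
                    assert min(m0, m1) <= J <= max(m0, m1)
                else:  # mixed-mutator: a + 1 = mu crossing
                    d0 = a0 + 1.0 - m0
                    d1 = a1 + 1.0 - m1
                    assert d0 * d1 <= 0.0


# ---------------------------------------------------------------------------
# WKB mutator fraction and small-a asymptotics

def test_wkb_no_switching_keeps_wild_type(linear_k03):
    p = MutatorParams(L=1000, mu1=1.0, mu2=10.0, alpha1=0.0)
    r = wkb_mutator_fraction(p, linear_k03)
    assert r.one_minus_q == 1.0 and r.K == 1.0


def test_wkb_matching_point_location(linear_k03):
    p = MutatorParams(L=1000, mu1=1.0, mu2=10.0, alpha1=0.01)
    r = wkb_mutator_fraction(p, linear_k03)
    assert r.validity
    assert r.s2 < r.s1 < r.s3
    # s3 solves f(s3) = R + mu2 a/(mu2 - mu1)
    R = math.sqrt(1.09) - 1.0 - 0.01
    assert 0.3 * r.s3 == pytest.approx(R + 10.0 * 0.01 / 9.0, abs=1e-10)


def test_wkb_fraction_against_eigenvector(linear_k03, table4_params):
    """The WKB 1-q tracks the finite-L eigenvector: absolute agreement in
    the wild-dominated columns, log10 agreement within 0.5 in the
    mutator-dominated column (prefactor-level accuracy)."""
    for (p, k) in table4_params:
        land = make_landscape("linear", k=k)
        wkb = wkb_mutator_fraction(p, land)
        num = 1.0 - steady_state(p, land).observables.q
        if num > 0.2:
            assert wkb.one_minus_q == pytest.approx(num, abs=0.05)
        else:
            assert abs(math.log10(wkb.one_minus_q) - math.log10(num)) < 0.5


def test_wkb_exponent_matches_finite_L_slope():
    """L d/dL ln(q/(1-q)) measured from eigenvectors approaches the WKB
    exponent rate W for the strongly mutator-dominated column."""
    land = make_landscape("linear", k=1.0)
    p = MutatorParams(L=1000, mu1=1.0, mu2=10.0, alpha1=0.3)
    W = wkb_mutator_fraction(p, land).exponent / 1000.0
    vals = {}
    for L in (800, 1200):
        pl = MutatorParams(L=L, mu1=1.0, mu2=10.0, alpha1=0.3)
        o = steady_state(pl, land).observables
        vals[L] = math.log(o.q / (1.0 - o.q))
    slope = (vals[1200] - vals[800]) / 400.0
    # subtract the sqrt(L) prefactor drift before comparing
    slope -= 0.5 / 1000.0
    assert slope == pytest.approx(W, rel=0.05)


def test_small_a_asymptotics_regimes(linear_k03):
    out = small_a_asymptotics(k=0.3, a=0.0001, mu=10.0, L=1000)
    assert out["validity"]
    p = MutatorParams(L=1000, mu1=1.0, mu2=10.0, alpha1=0.0001)
    num = 1.0 - steady_state(p, linear_k03).observables.q
    assert num == pytest.approx(0.9945, abs=1e-3)
    assert out["one_minus_q"] == pytest.approx(num, abs=0.01)
    # tiny L: exponent negligible, 1-q approaches the a-proportional regime
    small = small_a_asymptotics(k=0.3, a=0.0001, mu=10.0, L=10)
    assert small["exponent"] < 1e-5
    assert small["one_minus_q"] == pytest.approx(out["one_minus_q"], abs=1e-3)
    assert out["L_crossover"] > 1e6  # far from the takeover regime


def test_small_a_tracks_finite_L_scan(linear_k03):
    """q(L) rises with L and the closed form follows the eigenvector."""
    qs_num, qs_asym = [], []
    for L in (200, 400, 800, 1600, 3200):
        p = MutatorParams(L=L, mu1=1.0, mu2=10.0, alpha1=0.001)
        qs_num.append(steady_state(p, linear_k03).observables.q)
        qs_asym.append(1.0 - small_a_asymptotics(0.3, 0.001, 10.0, L)
                       ["one_minus_q"])
    assert all(b > a for a, b in zip(qs_num, qs_num[1:]))
    assert all(b > a for a, b in zip(qs_asym, qs_asym[1:]))
    assert np.allclose(qs_num, qs_asym, atol=0.05)


# ---------------------------------------------------------------------------
# d-dimensional potential

def _part(k, mu, nu, y=1.0, pinned=False):
    fit = lambda x: k * np.asarray(x, dtype=float)
    return CompositePart(y=y, f=fit, g=fit, mu=mu, nu=nu, pinned=pinned)


def test_multidim_reduces_to_1d():
    parts = make_composite([_part(1.0, 1.0, 10.0)])
    R, xopt, _ = multidim_potential(parts, alpha1=0.3, alpha2=0.0)
    land = make_landscape("linear", k=1.0)
    p = MutatorParams(L=100, mu1=1.0, mu2=10.0, alpha1=0.3)
    assert R == pytest.approx(mean_fitness_general(p, land), abs=1e-9)


def test_multidim_separable_parts_match_independent_maximization():
    """Two identical additive halves: R equals the sum of independent
    1-D maximizations (separability oracle)."""
    parts = make_composite([_part(0.5, 0.5, 0.5, y=0.5),
                            _part(0.5, 0.5, 0.5, y=0.5)])
    R, xopt, _ = multidim_potential(parts, alpha1=0.2, alpha2=0.2)
    # single part oracle: max of 0.5x - 0.5(1-sqrt(1-x^2))
    xs = np.linspace(-1, 1, 200001)
    one = (0.5 * xs - 0.5 * (1 - np.sqrt(1 - xs ** 2))).max()
    assert R == pytest.approx(2 * one - 0.2 + 0.2, abs=1e-7)
    assert np.allclose(xopt, xopt[::-1], atol=1e-5)


def test_multidim_lethal_part_confines_maximization():
    lethal = CompositePart(y=0.5, f=lambda x: 0.0 * np.asarray(x),
                           g=lambda x: 0.0 * np.asarray(x),
                           mu=0.4, nu=0.4, pinned=True)
    decreasing = CompositePart(y=0.5,
                               f=lambda x: 2.0 * (1.0 - np.asarray(x, float)),
                               g=lambda x: 2.0 * (1.0 - np.asarray(x, float)),
                               mu=0.7, nu=0.7)
    R, xopt, _ = multidim_potential(make_composite([lethal, decreasing]),
                                    alpha1=0.1, alpha2=0.1)
    assert xopt[0] == 1.0
    # 1-D oracle over the free coordinate, with the pinned part's full
    # mutational loss mu*(1 - sqrt(1-1)) = mu
    xs = np.linspace(-1, 1, 200001)
    vals = (2.0 * (1 - xs) - 0.7 * (1 - np.sqrt(1 - xs ** 2))) - 0.4
    assert R == pytest.approx(vals.max(), abs=1e-6)
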