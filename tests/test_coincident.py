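"""Gamma-rate coincident-SNP theory against independent oracles.

The quadrature path is checked against closed-form gamma moments
(E[g^k e^{-c g}] for a mean-one gamma has an elementary closed form),
against Monte-Carlo sampling of the kernel, and against small-divergence
limits that reduce to raw gamma moments.
"""

import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

import mutvar as mv
from mutvar.coincident import CPG_DIVERGENCE, NON_CPG_DIVERGENCE


# ---- independent closed-form oracle -------------------------------------

def gamma_moment(alpha: float, k: int, c: float) -> float:
    """E[g**k * exp(-c*g)] for g ~ Gamma(alpha, scale=1/alpha)."""
    out = 1.0
    for i in range(k):
        out *= (alpha + i) / alpha
    return out * (1.0 + c / alpha) ** -(alpha + k)


def kernel_mean_cf(alpha: float, v: float) -> float:
    return gamma_moment(alpha, 2, v) + 1.0 - gamma_moment(alpha, 0, 2 * v)


def q_cf(alpha: float, v: float) -> float:
    numer = gamma_moment(alpha, 3, v) + 1.0 - gamma_moment(alpha, 0, 2 * v)
    return numer / kernel_mean_cf(alpha, v)


# ---- kernel --------------------------------------------------------------

def test_kernel_scalar_values():
    assert mv.kernel(0.0, 0.01) == 0.0
    expected = math.exp(-0.01) + 1.0 - math.exp(-0.02)
    assert mv.kernel(1.0, 0.01) == pytest.approx(expected, abs=1e-15)
    assert mv.kernel(1e6, 0.01) == pytest.approx(1.0, abs=1e-12)
    with pytest.raises(ValueError):
        mv.kernel(1.0, 0.0)


# ---- coincident integral -------------------------------------------------

@pytest.mark.parametrize("alpha", [0.5, 1.0, 2.0])
@pytest.mark.parametrize("v", [NON_CPG_DIVERGENCE, CPG_DIVERGENCE])
def test_integral_matches_closed_form(alpha, v):
    model = mv.GammaRateModel(alpha, v)
    assert mv.coincident_integral(model) == pytest.approx(
        kernel_mean_cf(alpha, v), rel=1e-8
    )


def test_integral_degenerate_distribution():
    """shape -> inf collapses the mixing density onto gamma = 1."""
    model = mv.GammaRateModel(1e9, NON_CPG_DIVERGENCE)
    assert mv.coincident_integral(model) == pytest.approx(
        mv.kernel(1.0, NON_CPG_DIVERGENCE), abs=1e-6
    )


def test_integral_small_v_second_moment():
    """As v -> 0 the integral is E[gamma**2] = (alpha+1)/alpha."""
    model = mv.GammaRateModel(1.0, 1e-8)
    assert mv.coincident_integral(model) == pytest.approx(2.0, abs=1e-6)


def test_integral_against_monte_carlo():
    rng = np.random.default_rng(5)
    alpha, v = 1.0, NON_CPG_DIVERGENCE
    draws = rng.gamma(alpha, 1.0 / alpha, size=10 ** 6)
    vals = mv.kernel(draws, v)
    se = vals.std(ddof=1) / math.sqrt(vals.size)
    quad = mv.coincident_integral(mv.GammaRateModel(alpha, v))
    assert abs(quad - vals.mean()) < 3 * se


def test_density_self_check():
    for alpha in (0.3, 1.0, 50.0):
        mv.GammaRateModel(alpha, 0.01).density_self_check()


# ---- excess ratio --------------------------------------------------------

def test_excess_ratio_no_variation_limit():
    assert mv.excess_ratio(mv.GammaRateModel(1e9, 0.0092)) == pytest.approx(
        1.0, abs=1e-6
    )


def test_excess_ratio_exponential_rates_small_v():
    """alpha=1, v -> 0: excess -> E[gamma**2] = 2 with O(v) corrections."""
    got = mv.excess_ratio(mv.GammaRateModel(1.0, NON_CPG_DIVERGENCE))
    # small-v expansion oracle: (E[g^2] - v E[g^3] + 2 v E[g]) / (1 + v)
    v = NON_CPG_DIVERGENCE
    approx = (2.0 - v * 6.0 + 2.0 * v) / (1.0 + v)
    assert got == pytest.approx(approx, rel=5e-3)
    assert 1.9 < got < 2.0


def test_excess_ratio_monotone_decreasing_in_shape():
    for v in (NON_CPG_DIVERGENCE, CPG_DIVERGENCE):
        vals = [mv.excess_ratio(mv.GammaRateModel(a, v))
                for a in (0.5, 1.0, 2.0, 4.0, 8.0)]
        assert all(x > y for x, y in zip(vals, vals[1:]))
        assert all(x >= 1.0 for x in vals)


# ---- shape inversion -----------------------------------------------------

@pytest.mark.parametrize("alpha0", [0.5, 1.0, 2.0])
def test_fit_shape_small_v_closed_form(alpha0):
    """At v ~ 0 the excess is 1 + 1/alpha, trivially invertible."""
    got = mv.fit_shape(1.0 + 1.0 / alpha0, v=1e-8)
    assert got == pytest.approx(alpha0, rel=1e-4)


def test_fit_shape_grid_scan_oracle():
    """Dense grid scan brackets the root the solver must find."""
    v, excess = NON_CPG_DIVERGENCE, 1.83
    grid = np.logspace(-0.5, 1.0, 120)
    vals = np.array([mv.excess_ratio(mv.GammaRateModel(a, v)) for a in grid])
    crossing = grid[np.nonzero(np.diff(np.sign(vals - excess)))[0]]
    fitted = mv.fit_shape(excess, v)
    assert crossing.size == 1
    assert crossing[0] <= fitted <= grid[np.searchsorted(grid, crossing[0]) + 1]
    assert fitted == pytest.approx(1.14, abs=0.05)


@pytest.mark.parametrize("excess,v", [(1.16, CPG_DIVERGENCE),
                                      (1.83, NON_CPG_DIVERGENCE),
                                      (1.16, CPG_DIVERGENCE * 0.1)])
def test_fit_shape_round_trip(excess, v):
    alpha = mv.fit_shape(excess, v)
    assert mv.excess_ratio(mv.GammaRateModel(alpha, v)) == pytest.approx(
        excess, abs=1e-8
    )


@given(st.floats(min_value=1.01, max_value=2.5))
def test_fit_shape_round_trip_property(excess):
    v = NON_CPG_DIVERGENCE
    alpha = mv.fit_shape(excess, v)
    assert mv.excess_ratio(mv.GammaRateModel(alpha, v)) == pytest.approx(
        excess, abs=1e-8
    )


def test_fit_shape_rejects_unattainable():
    with pytest.raises(ValueError):
        mv.fit_shape(1.0, NON_CPG_DIVERGENCE)
    with pytest.raises(ValueError):
        mv.fit_shape(0.9, NON_CPG_DIVERGENCE)
    # at CpG divergence the destruction term caps the attainable excess
    with pytest.raises(ValueError):
        mv.fit_shape(5.0, CPG_DIVERGENCE)


# ---- mean fold Q ---------------------------------------------------------

def test_q_limits():
    assert mv.mean_fold_q(mv.GammaRateModel(1e9, 0.0092)) == pytest.approx(
        1.0, abs=1e-6
    )
    # v -> 0: Q -> E[g^3]/E[g^2] = 6/2 = 3 for exponential rates
    assert mv.mean_fold_q(mv.GammaRateModel(1.0, 1e-8)) == pytest.approx(
        3.0, abs=1e-5
    )


@pytest.mark.parametrize("alpha", [0.5, 1.0, 2.0])
@pytest.mark.parametrize("v", [NON_CPG_DIVERGENCE, CPG_DIVERGENCE])
def test_q_matches_closed_form(alpha, v):
    model = mv.GammaRateModel(alpha, v)
    assert mv.mean_fold_q(model) == pytest.approx(q_cf(alpha, v), rel=1e-8)


def test_q_monotone_decreasing_in_shape():
    for v in (NON_CPG_DIVERGENCE, CPG_DIVERGENCE):
        vals = [mv.mean_fold_q(mv.GammaRateModel(a, v))
                for a in (0.5, 1.0, 2.0, 4.0, 8.0)]
        assert all(x > y for x, y in zip(vals, vals[1:]))
        assert all(x >= 1.0 for x in vals)


def test_q_full_weighting_variant():
    """Size-biasing the whole kernel gives a slightly larger fold."""
    model = mv.GammaRateModel(1.1426, NON_CPG_DIVERGENCE)
    q_default = mv.mean_fold_q(model)
    q_full = mv.mean_fold_q(model, weighting="full")
    assert q_full > q_default >= 1.0
    with pytest.raises(ValueError):
        mv.mean_fold_q(model, weighting="nope")


# ---- full inference chain ------------------------------------------------

def test_fold_from_excess_cpg_headline():
    """16% CpG excess at v=0.092 -> 1.40-fold (1.35, 1.43)."""
    est = mv.fold_from_excess(1.16, CPG_DIVERGENCE, excess_ci=(1.14, 1.17))
    assert round(est.q_fold, 2) == 1.40
    assert round(est.ci_low, 2) == 1.35
    assert round(est.ci_high, 2) == 1.43
    assert est.ci_low <= est.q_fold <= est.ci_high


def test_fold_from_excess_non_cpg_headline():
    """83% non-CpG excess at v=0.0092 -> 2.71-fold (2.65, 2.77)."""
    est = mv.fold_from_excess(1.83, NON_CPG_DIVERGENCE, excess_ci=(1.80, 1.86))
    assert round(est.q_fold, 2) == 2.71
    assert round(est.ci_low, 2) == 2.65
    assert round(est.ci_high, 2) == 2.77


def test_fold_continuity_at_no_variation():
    est = mv.fold_from_excess(1.0005, NON_CPG_DIVERGENCE)
    assert est.q_fold == pytest.approx(1.0, abs=0.01)


def test_fold_monotone_in_excess():
    folds = [mv.fold_from_excess(e, NON_CPG_DIVERGENCE).q_fold
             for e in (1.1, 1.4, 1.7, 2.0)]
    assert all(x < y for x, y in zip(folds, folds[1:]))


# ---- regression-predicted folds and MI comparison ------------------------

def _fit(slope, intercept=-9.0, base=10.0):
    return mv.RegressionFit(slope=slope, intercept=intercept, se_slope=1e-3,
                            se_intercept=1e-2, log_base=base, r=0.99)


def test_predicted_fold_identical_sets():
    fit = _fit(0.01)
    assert mv.predicted_fold_from_fit(fit, [10, 20, 30], [10, 20, 30]) == 1.0


def test_predicted_fold_singletons_closed_form():
    b = 0.01
    fit = _fit(b)
    got = mv.predicted_fold_from_fit(fit, [91.6], [81.4])
    assert got == pytest.approx(10 ** (10.2 * b), rel=1e-12)


def test_predicted_fold_jensen_bound():
    """A wider-spread MI set beats the pure mean-shift fold."""
    rng = np.random.default_rng(3)
    b, delta = 0.01, 10.0
    mi_b = rng.normal(0.0, 5.0, size=2000)
    mi_a = rng.normal(delta, 15.0, size=2000)  # shifted and wider
    fit = _fit(b)
    got = mv.predicted_fold_from_fit(fit, mi_a, mi_b)
    assert got >= 10 ** (b * (mi_a.mean() - mi_b.mean()))


def test_predicted_fold_empty_set_errors():
    with pytest.raises(ValueError):
        mv.predicted_fold_from_fit(_fit(0.01), [], [1.0])


def test_compare_mi_sets_identical():
    a = list(range(50))
    mean_a, mean_b, p = mv.compare_mi_sets(a, a, n_perm=500, seed=0)
    assert mean_a == mean_b
    assert p > 0.5


def test_compare_mi_sets_power_and_determinism():
    rng = np.random.default_rng(7)
    a = rng.normal(10.0, 1.0, size=1000)
    b = rng.normal(0.0, 1.0, size=1000)
    *_, p1 = mv.compare_mi_sets(a, b, n_perm=10_000, seed=1)
    *_, p2 = mv.compare_mi_sets(a, b, n_perm=10_000, seed=1)
    assert p1 <= 0.001
    assert p1 == p2
    with pytest.raises(ValueError):
        mv.compare_mi_sets(a, b, n_perm=50)
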