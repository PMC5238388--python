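import numpy as np
import pytest

from tdca import model, tdcf
from tdca.tdcf import (AlignmentError, TDCFCurve, ZeroVarianceError,
                       convergence_check, extremum, fluctuations,
                       laplace_transform, pearson, tail_exponent, tdcf_estimate,
                       tdcf_pair)
from tdca.trajio import AngleSeries


def series(vals, dt=1.0, residue=1, dof="phi"):
    vals = np.asarray(vals, dtype=float)
    return AngleSeries(residue=residue, dof=dof,
                       times=np.arange(vals.size) * dt, angles=vals)


def analytic_curve(values, lags, direction="forward"):
    return TDCFCurve(pair=((1, "x"), (2, "y")), direction=direction, lags=lags,
                     values=np.asarray(values, float),
                     counts=np.full(len(lags), 10 ** 9))


# ---------------------------------------------------------------------------
# fluctuations

def test_constant_series_raises():
    with pytest.raises(ZeroVarianceError):
        fluctuations(series(np.full(10, 42.0)))


def test_branch_cut_deviations():
    """Angles straddling the +/-180 seam: circular mean 180, deviations +/-1."""
    f = fluctuations(series([179.0, -179.0] * 8))
    assert f.mean_deg == pytest.approx(180.0)
    assert np.allclose(np.sort(np.unique(f.dev)), [-1.0, 1.0])
    assert f.var == pytest.approx(1.0)


def test_two_point_symmetric_case():
    f = fluctuations(series([0.0, 90.0]))
    assert f.mean_deg == pytest.approx(45.0)
    assert np.allclose(np.sort(f.dev), [-45.0, 45.0])


def test_unwrap_policy_handles_winding():
    """A steadily winding angle is constant-slope after unwrapping."""
    raw = np.linspace(0, 720, 100)  # two full turns
    f = fluctuations(series(raw), detrend="unwrap")
    assert np.allclose(np.diff(f.dev), raw[1] - raw[0], atol=1e-9)


# ---------------------------------------------------------------------------
# estimator

def test_zero_lag_autocorrelation_is_one(rng):
    f = fluctuations(series(rng.uniform(-50, 50, 200)))
    c = tdcf_estimate(f, f, max_lag=20.0)
    assert c.values[0] == pytest.approx(1.0, abs=1e-12)
    g = fluctuations(series(-rng.uniform(-50, 50, 200)))
    # negated copy of the same fluctuations
    neg = tdcf.FluctuationSeries(2, "psi", 0.0, -f.dev, f.var, f.dt)
    c2 = tdcf_estimate(f, neg, max_lag=20.0)
    assert c2.values[0] == pytest.approx(-1.0, abs=1e-12)


def test_counts_decrease_and_cauchy_schwarz(rng):
    fi = fluctuations(series(rng.normal(0, 20, 300)))
    fj = fluctuations(series(rng.normal(0, 20, 300), residue=2))
    fwd, rev = tdcf_pair(fi, fj, max_lag=50.0)
    assert np.all(np.diff(fwd.counts) == -1)
    assert abs(fwd.values[0]) <= 1.0 and abs(rev.values[0]) <= 1.0
    assert fwd.values[0] == pytest.approx(rev.values[0])  # both equal C(0)
    assert fwd.values[0] == pytest.approx(pearson(fi, fj), abs=1e-12)


def test_matches_brute_force(rng):
    a = rng.normal(0, 10, 64)
    b = rng.normal(0, 10, 64)
    fi = fluctuations(series(a))
    fj = fluctuations(series(b, residue=2))
    fwd, rev = tdcf_pair(fi, fj, max_lag=10.0, min_count=1)
    norm = np.sqrt(fi.var * fj.var)
    for l in range(11):
        bf_f = np.sum(fi.dev[: 64 - l] * fj.dev[l:]) / ((64 - l) * norm)
        bf_r = np.sum(fj.dev[: 64 - l] * fi.dev[l:]) / ((64 - l) * norm)
        assert fwd.values[l] == pytest.approx(bf_f, abs=1e-12)
        assert rev.values[l] == pytest.approx(bf_r, abs=1e-12)


def test_white_noise_null_level():
    """Independent series: |C| stays below 3/sqrt(N) at ~99% of (seed, lag)."""
    n, n_lags, exceed, total = 2000, 100, 0, 0
    for seed in range(20):
        rng = np.random.default_rng(seed)
        fi = fluctuations(series(rng.normal(0, 10, n)))
        fj = fluctuations(series(rng.normal(0, 10, n), residue=2))
        fwd = tdcf_estimate(fi, fj, max_lag=float(n_lags - 1))
        exceed += int(np.sum(np.abs(fwd.values) > 3 / np.sqrt(n)))
        total += fwd.values.size
    assert exceed / total < 0.01


def test_mismatched_grids_raise(rng):
    fi = fluctuations(series(rng.normal(0, 10, 100)))
    fj = fluctuations(series(rng.normal(0, 10, 90), residue=2))
    with pytest.raises(AlignmentError):
        tdcf_estimate(fi, fj)


def test_exchange_identity(simulated_pair):
    """The forward (i,j) curve equals the reverse (j,i) curve, and the two
    directions genuinely differ for an asymmetrically coupled pair."""
    fi, fj = simulated_pair
    fwd_ij, rev_ij = tdcf_pair(fi, fj, max_lag=40.0)
    fwd_ji, rev_ji = tdcf_pair(fj, fi, max_lag=40.0)
    assert np.allclose(fwd_ij.values, rev_ji.values, atol=1e-12)
    assert np.allclose(rev_ij.values, fwd_ji.values, atol=1e-12)
    assert np.max(np.abs(fwd_ij.values - rev_ij.values)) > 0.02


# ---------------------------------------------------------------------------
# convergence

def test_convergence_orders_with_fraction(simulated_pair):
    fi, fj = simulated_pair
    curves, table = convergence_check(fi, fj, (0.5, 0.9, 1.0), max_lag=40.0)
    get = lambda a, b: float(table.query("fraction_a == @a and fraction_b == @b")
                             ["sup_diff"].iloc[0])
    assert get(0.9, 1.0) < get(0.5, 1.0)


def test_convergence_identical_prefix_zero(simulated_pair):
    fi, fj = simulated_pair
    curves, _ = convergence_check(fi, fj, (1.0,), max_lag=40.0)
    again, _ = convergence_check(fi, fj, (1.0,), max_lag=40.0)
    assert np.allclose(curves[1.0].values, again[1.0].values, atol=0)


def test_convergence_flags_regime_switch(simulated_pair):
    fi, fj = simulated_pair
    shifted = fj.dev.copy()
    shifted[shifted.size // 2:] += 60.0
    s = AngleSeries(2, "phi", np.arange(shifted.size) * fj.dt, shifted)
    fj2 = fluctuations(s)
    _, table = convergence_check(fi, fj2, (0.5, 1.0), max_lag=40.0)
    _, table0 = convergence_check(fi, fj, (0.5, 1.0), max_lag=40.0)
    assert table["sup_diff"].iloc[0] > 5 * table0["sup_diff"].iloc[0]


# ---------------------------------------------------------------------------
# Laplace transform

def test_exponential_laplace_pair():
    a = 0.5
    t = np.arange(0, 60, 0.01)
    lc = laplace_transform(analytic_curve(np.exp(-a * t), t),
                           s_grid=np.geomspace(0.1, 10, 50))
    expected = 1.0 / (lc.s + a)
    assert np.max(np.abs(lc.F - expected) / expected) < 0.01


def test_damped_cosine_laplace_pair():
    a, b = 0.5, 2.0
    t = np.arange(0, 40, 0.005)
    lc = laplace_transform(analytic_curve(np.exp(-a * t) * np.cos(b * t), t),
                           s_grid=np.geomspace(0.1, 10, 50))
    expected = (lc.s + a) / ((lc.s + a) ** 2 + b ** 2)
    assert np.max(np.abs(lc.F - expected) / np.abs(expected)) < 0.01


def test_zero_curve_and_linearity(rng):
    t = np.arange(0, 30, 0.01)
    zero = laplace_transform(analytic_curve(np.zeros_like(t), t))
    assert np.allclose(zero.F, 0.0)
    c1 = np.exp(-0.3 * t)
    c2 = np.exp(-1.1 * t) * np.cos(1.7 * t)
    s = np.geomspace(0.05, 20, 60)
    F1 = laplace_transform(analytic_curve(c1, t), s).F
    F2 = laplace_transform(analytic_curve(c2, t), s).F
    F12 = laplace_transform(analytic_curve(2.5 * c1 - 1.25 * c2, t), s).F
    assert np.allclose(F12, 2.5 * F1 - 1.25 * F2, rtol=1e-10, atol=1e-12)


def test_rejects_nonpositive_s():
    t = np.arange(0, 10, 0.1)
    with pytest.raises(ValueError):
        laplace_transform(analytic_curve(np.exp(-t), t), s_grid=[-1.0, 1.0])


# ---------------------------------------------------------------------------
# extremum

def test_interior_extremum_of_damped_cosine_transform():
    a, b = 0.1, 1.0
    s = np.geomspace(1e-3, 50, 400)
    F = (s + a) / ((s + a) ** 2 + b ** 2)
    ext = extremum(tdcf.LaplaceCurve(s=s, F=F))
    assert not ext.boundary
    # dF/ds = 0 at (s+a)^2 = b^2, i.e. s = b - a
    assert ext.s_peak == pytest.approx(b - a, rel=0.02)
    assert ext.tau == pytest.approx(1.0 / ext.s_peak)


def test_monotone_curve_flags_boundary():
    s = np.geomspace(0.01, 10, 100)
    ext = extremum(tdcf.LaplaceCurve(s=s, F=1.0 / (s + 0.2)))
    assert ext.boundary and ext.s_peak == pytest.approx(s[0])


def test_negated_curve_flips_sign_only():
    s = np.geomspace(1e-3, 50, 300)
    F = (s + 0.1) / ((s + 0.1) ** 2 + 1.0)
    e1 = extremum(tdcf.LaplaceCurve(s=s, F=F))
    e2 = extremum(tdcf.LaplaceCurve(s=s, F=-F))
    assert e2.F_ext == pytest.approx(-e1.F_ext)
    assert e2.s_peak == pytest.approx(e1.s_peak)


# ---------------------------------------------------------------------------
# tail exponent

def test_tail_exponent_of_simple_pole():
    a = 0.2
    s = np.geomspace(1e-2 * a, 1e4 * a, 600)
    lc = tdcf.LaplaceCurve(s=s, F=1.0 / (s + a))
    # over [10a, 100a] the least-squares log-log slope is ~0.96 (still
    # feeling the pole); two decades up it reaches the asymptotic 1.0
    fit_near = tail_exponent(lc, window=(10 * a, 100 * a))
    assert fit_near.kappa == pytest.approx(0.963, abs=0.01)
    fit_far = tail_exponent(lc, window=(1000 * a, 10000 * a))
    assert fit_far.kappa == pytest.approx(1.0, abs=0.02)


def test_tail_exponent_two_when_zero_lag_vanishes():
    """C(0) = 0 (C = t e^{-at}) gives F = 1/(s+a)^2, an s^-2 tail."""
    a = 0.3
    t = np.arange(0, 120, 0.002)
    lc = laplace_transform(analytic_curve(t * np.exp(-a * t), t),
                           s_grid=np.geomspace(0.01, 200, 300))
    fit = tail_exponent(lc, window=(30 * a, 200 * a))
    assert fit.kappa == pytest.approx(2.0, abs=0.05)


def test_tail_window_respects_quadrature_cap():
    t = np.arange(0, 100, 0.05)
    lc = laplace_transform(analytic_curve(np.exp(-0.2 * t), t),
                           s_grid=np.geomspace(0.01, 1000, 300))
    lo, hi = tdcf.tail_window(lc)
    assert hi <= 0.5 / 0.05 * 1.0001


def test_tail_sign_change_shrinks_window():
    s = np.geomspace(0.1, 100, 200)
    F = 1.0 / s - 0.05  # crosses zero at s = 20
    with pytest.warns(UserWarning, match="sign"):
        fit = tail_exponent(tdcf.LaplaceCurve(s=s, F=F), window=(1.0, 100.0))
    assert fit.shrunk
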