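import numpy as np
import pytest

from tdca import model, tdcf
from tdca.model import (AnalyticCorrelation, OscillatorSystem, StabilityError,
                        relaxation_matrix, rotational_time,
                        simulate_linear_sde, stationary_covariance)


def random_stable_system(rng, coupling_scale=0.7, relax_ns=(1.0, 50.0)):
    tau_i, tau_j = np.exp(rng.uniform(np.log(relax_ns[0]), np.log(relax_ns[1]), 2))
    a = coupling_scale / tau_i * rng.uniform(-1, 1)
    b = coupling_scale / tau_j * rng.uniform(-1, 1)
    return OscillatorSystem.from_relaxation_times(tau_i, tau_j, a, b)


# ---------------------------------------------------------------------------
# relaxation matrix and stationary covariance

def test_decoupled_matrix_is_diagonal():
    sys_ = OscillatorSystem(omega_i=2.0, omega_j=1.0, gamma_i=4.0, gamma_j=2.0)
    A = relaxation_matrix(sys_)
    assert np.allclose(A, np.diag([-1.0, -0.5]))


def test_symmetric_parameters_give_symmetric_matrix():
    sys_ = OscillatorSystem(1.0, 1.0, 2.0, 2.0, alpha=0.3, beta=0.3)
    A = relaxation_matrix(sys_)
    assert np.allclose(A, A.T)


def test_overcritical_coupling_raises():
    # alpha*beta > omega_i^2 omega_j^2 makes det(A) < 0: unstable
    sys_ = OscillatorSystem(1.0, 1.0, 1.0, 1.0, alpha=1.2, beta=1.1)
    with pytest.raises(StabilityError):
        relaxation_matrix(sys_)


def test_scalar_ou_stationary_variance():
    """Decoupled: sigma^2 = D gamma / (2 omega^2) per variable."""
    sys_ = OscillatorSystem(1.5, 0.8, 3.0, 2.0, noise=np.diag([0.7, 0.4]))
    A = relaxation_matrix(sys_)
    Sigma = stationary_covariance(A, sys_.noise)
    assert Sigma[0, 0] == pytest.approx(0.7 * 3.0 / (2 * 1.5 ** 2))
    assert Sigma[1, 1] == pytest.approx(0.4 * 2.0 / (2 * 0.8 ** 2))
    assert Sigma[0, 1] == pytest.approx(0.0, abs=1e-14)


def test_zero_noise_gives_zero_covariance():
    A = relaxation_matrix(OscillatorSystem(1.0, 1.0, 1.0, 1.0))
    assert np.allclose(stationary_covariance(A, np.zeros((2, 2))), 0.0)


def test_lyapunov_residual_on_random_systems(rng):
    for _ in range(10):
        sys_ = random_stable_system(rng)
        A = relaxation_matrix(sys_)
        L = rng.normal(size=(2, 2))
        D = L @ L.T
        Sigma = stationary_covariance(A, D)
        assert np.linalg.norm(A @ Sigma + Sigma @ A.T + D) < 1e-10 * np.linalg.norm(D)


# ---------------------------------------------------------------------------
# analytic correlation

def test_zero_lag_is_pearson(coupled_system):
    ac = AnalyticCorrelation.from_system(coupled_system)
    assert ac.tdcf(0.0)[0] == pytest.approx(ac.pearson)
    assert ac.tdcf(0.0, "reverse")[0] == pytest.approx(ac.pearson)


def test_decoupled_cross_correlation_vanishes():
    ac = AnalyticCorrelation.from_system(OscillatorSystem(1.0, 0.7, 2.0, 1.0))
    assert np.allclose(ac.tdcf([0.0, 1.0, 5.0, 20.0]), 0.0, atol=1e-14)


def test_correlation_decays_to_zero(coupled_system):
    ac = AnalyticCorrelation.from_system(coupled_system)
    assert abs(ac.tdcf(500.0)[0]) < 1e-8


def test_resolvent_equals_quadrature(rng):
    """Central oracle: the resolvent F(s) against direct quadrature of C.

    Agreement to < 0.5% relative, with the relative scale floored at 1% of
    the curve maximum where F passes through zero (pointwise relative
    error is ill-posed at a sign change)."""
    for _ in range(20):
        sys_ = random_stable_system(rng)
        ac = AnalyticCorrelation.from_system(sys_)
        tau_slow = 1.0 / np.min(-ac.eigenvalues.real)
        h = 1.0 / (160 * np.max(np.abs(ac.eigenvalues)))
        t = np.arange(0, 14 * tau_slow, h)
        s = np.geomspace(0.5 / t[-1], 0.2 / h, 30)
        for direction in ("forward", "reverse"):
            C = ac.tdcf(t, direction)
            curve = tdcf.TDCFCurve(pair=((1, "x"), (2, "y")), direction=direction,
                                   lags=t, values=C,
                                   counts=np.full(t.size, 10 ** 9))
            F_num = tdcf.laplace_transform(curve, s).F
            F_an = ac.laplace(s, direction)
            scale = np.maximum(np.abs(F_an), 1e-2 * np.max(np.abs(F_an)))
            assert np.max(np.abs(F_num - F_an) / scale) < 0.005


def test_exchange_symmetry_and_asymmetry():
    sym = OscillatorSystem(1.0, 1.0, 2.0, 2.0, alpha=0.3, beta=0.3)
    ac = AnalyticCorrelation.from_system(sym)
    s = np.geomspace(1e-3, 1e2, 50)
    assert np.allclose(ac.laplace(s, "forward"), ac.laplace(s, "reverse"),
                       rtol=1e-10)
    asym = OscillatorSystem(1.0, 1.0, 2.0, 2.0, alpha=0.05, beta=0.4)
    ac2 = AnalyticCorrelation.from_system(asym)
    assert np.max(np.abs(ac2.laplace(s) - ac2.laplace(s, "reverse"))) > 1e-3


def test_asymmetry_grows_with_coupling_difference():
    from scipy.stats import spearmanr

    s = np.geomspace(1e-3, 1e2, 100)
    deltas = [0.0, 0.1, 0.2, 0.3, 0.4]
    sups = []
    for d in deltas:
        sys_ = OscillatorSystem(1.0, 1.0, 2.0, 2.0, alpha=0.05, beta=0.05 + d)
        ac = AnalyticCorrelation.from_system(sys_)
        sups.append(np.max(np.abs(ac.laplace(s) - ac.laplace(s, "reverse"))))
    assert spearmanr(deltas, sups).statistic == pytest.approx(1.0)


def test_low_s_extremum_sign_follows_pearson():
    pos = AnalyticCorrelation.from_system(
        OscillatorSystem(1.0, 1.0, 2.0, 2.0, alpha=0.2, beta=0.3))
    neg = AnalyticCorrelation.from_system(
        OscillatorSystem(1.0, 1.0, 2.0, 2.0, alpha=-0.2, beta=-0.3))
    assert pos.pearson > 0 and pos.laplace_zero() > 0
    assert neg.pearson < 0 and neg.laplace_zero() < 0


def test_tail_law_from_resolvent_expansion():
    """kappa = 1 when the equal-time cross term is nonzero, else 2."""
    coupled = AnalyticCorrelation.from_system(
        OscillatorSystem(1.0, 1.0, 2.0, 2.0, alpha=0.1, beta=0.3))
    assert coupled.tail_exponent() == 1
    # engineered Sigma = I (zero cross term) with nonzero coupling:
    # D = -(A + A^T) is PSD for this A, so Sigma = I solves the Lyapunov eq.
    A = np.array([[-1.0, 0.3], [0.2, -1.0]])
    ac0 = AnalyticCorrelation(A, np.eye(2))
    assert ac0.tail_exponent() == 2
    # and the fitted log-log slope on the analytic F agrees in both cases
    for ac, expect in ((coupled, 1.0), (ac0, 2.0)):
        rate = np.max(-ac.eigenvalues.real)
        s = np.geomspace(100 * rate, 1000 * rate, 80)
        lc = tdcf.LaplaceCurve(s=s, F=ac.laplace(s))
        fit = tdcf.tail_exponent(lc, window=(s[0], s[-1]))
        assert fit.kappa == pytest.approx(expect, abs=0.05)


def test_drag_moves_timescale_not_pearson():
    """Scaling all relaxation times at fixed coupling ratio leaves the
    equal-time correlation unchanged while the frequency scale of F(s)
    stretches proportionally — timescale and Pearson carry independent
    information.  (The model's F is extremal in the s -> 0 limit, so the
    timescale is probed by the half-height frequency of F.)"""
    pearsons, s_half, scales = [], [], [1.0, 2.0, 4.0, 8.0]
    s = np.geomspace(1e-5, 1e2, 2000)
    for scale in scales:
        sys_ = OscillatorSystem.from_relaxation_times(
            3.0 * scale, 5.0 * scale, coupling_ij=0.05 / scale,
            coupling_ji=0.15 / scale)
        ac = AnalyticCorrelation.from_system(sys_)
        F = ac.laplace(s)
        k = int(np.argmin(np.abs(F - 0.5 * ac.laplace_zero())))
        pearsons.append(ac.pearson)
        s_half.append(s[k])
    assert np.ptp(pearsons) < 1e-9
    assert s_half[0] / s_half[1] == pytest.approx(2.0, rel=0.05)
    assert s_half[0] / s_half[3] == pytest.approx(8.0, rel=0.05)


# ---------------------------------------------------------------------------
# simulator

def test_simulation_is_deterministic(coupled_system):
    t1, x1 = model.simulate(coupled_system, 5000, 0.05, seed=9)
    t2, x2 = model.simulate(coupled_system, 5000, 0.05, seed=9)
    assert np.array_equal(x1, x2)
    _, x3 = model.simulate(coupled_system, 5000, 0.05, seed=10)
    assert not np.array_equal(x1, x3)


def test_euler_requires_resolved_timestep(coupled_system):
    with pytest.raises(ValueError, match="dt"):
        model.simulate(coupled_system, 100, 5.0, seed=0)


@pytest.mark.parametrize("method", ["euler", "exact"])
def test_empirical_moments_match_stationary_law(coupled_system, method):
    A = relaxation_matrix(coupled_system)
    Sigma = stationary_covariance(A, coupled_system.noise)
    n = 2 ** 17
    x = simulate_linear_sde(A, coupled_system.noise, n, 0.05, seed=2,
                            method=method)
    ac = AnalyticCorrelation(A, Sigma)
    tau_slow = 1.0 / np.min(-ac.eigenvalues.real)
    n_eff = n * 0.05 / (2 * tau_slow)
    for k in range(2):
        se = Sigma[k, k] * np.sqrt(2 / n_eff)
        assert x[:, k].var() == pytest.approx(Sigma[k, k], abs=3 * se)


def test_empirical_lagged_correlation_matches_analytic(simulated_pair,
                                                       coupled_system):
    fi, fj = simulated_pair
    ac = AnalyticCorrelation.from_system(coupled_system)
    fwd, rev = tdcf.tdcf_pair(fi, fj, max_lag=30.0)
    lags = np.array([0.0, 2.0, 5.0, 10.0, 20.0])
    idx = (lags / fi.dt).astype(int)
    n_eff = fi.n * fi.dt / (2 * 8.0)  # span over twice the slowest relaxation
    tol = 3 / np.sqrt(n_eff)
    assert np.allclose(fwd.values[idx], ac.tdcf(lags), atol=tol)
    assert np.allclose(rev.values[idx], ac.tdcf(lags, "reverse"), atol=tol)


# ---------------------------------------------------------------------------
# rotational timescale

def test_rotational_time_scaling_and_value():
    t1 = rotational_time(2.4, 310.0, 0.69, rank=1)
    # hand evaluation of 4 pi eta R^3 / (k_B T) for these inputs
    expected = 4 * np.pi * 0.69e-3 * (2.4e-9) ** 3 / (1.380649e-23 * 310.0) * 1e9
    assert t1 == pytest.approx(expected, rel=1e-9)
    assert rotational_time(4.8, 310.0, 0.69) == pytest.approx(8 * t1, rel=1e-9)
    assert rotational_time(2.4, 310.0, 0.69, rank=2) == pytest.approx(t1 / 3, rel=1e-9)
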