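"""Coupled overdamped-oscillator model of dihedral cross-correlations.

Two angular degrees of freedom theta_i, theta_j relax in a harmonic well
(stiffness omega^2) under solvent drag gamma, each additionally pulled by
the other with coupling strengths alpha (action of j on i) and beta
(action of i on j).  In the overdamped (long-time) limit the equations of
motion reduce to a linear relaxation

    d theta / dt = A theta + noise,
    A = [[-omega_i^2/gamma_i, alpha/gamma_i],
         [ beta/gamma_j,     -omega_j^2/gamma_j]].

Everything downstream of A is available in closed form: the stationary
covariance Sigma (Lyapunov equation), the lagged cross-correlation
C(dt) = [Sigma e^{A^T dt}]_{ij} / sqrt(Sigma_ii Sigma_jj), and its Laplace
transform F(s) via the resolvent (sI - A)^{-1}.  These closed forms are
the oracles against which the numerical TDCF estimator is validated, and
the stochastic simulator below supplies synthetic stationary angular time
series with exactly known statistics.

Directions follow the estimator convention: the *forward* curve puts
variable i at the earlier time, C_fwd(dt) = <x_i(t) x_j(t+dt)>; the
reverse curve swaps i and j.  Whenever alpha != beta the two differ.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import expm, solve_continuous_lyapunov
from scipy.signal import lfilter

__all__ = [
    "StabilityError",
    "OscillatorSystem",
    "relaxation_matrix",
    "stationary_covariance",
    "AnalyticCorrelation",
    "simulate",
    "simulate_linear_sde",
    "rotational_time",
]

BOLTZMANN_KJ_MOL_K = 0.008314462618  # kJ/(mol K), unused below but handy for callers
_KB_J_PER_K = 1.380649e-23


class StabilityError(ValueError):
    """Relaxation matrix has an eigenvalue with non-negative real part."""


@dataclass(frozen=True)
class OscillatorSystem:
    """Parameters of the two-variable overdamped coupled oscillator.

    omega_i, omega_j : characteristic frequencies (stiffness^1/2), units such
        that omega^2/gamma is a relaxation rate in 1/ns.
    gamma_i, gamma_j : drag coefficients, > 0.
    alpha : coupling strength, action of variable j on variable i.
    beta  : coupling strength, action of variable i on variable j.
    noise : 2x2 symmetric PSD matrix D entering the Lyapunov equation
        A Sigma + Sigma A^T + D = 0 (stochastic variant).
    sigma0 : optional initial-condition covariance for the deterministic
        relaxation variant (average over initial conditions); when None the
        stationary covariance of the noisy variant is used.
    """

    omega_i: float
    omega_j: float
    gamma_i: float
    gamma_j: float
    alpha: float = 0.0
    beta: float = 0.0
    noise: np.ndarray = field(default_factory=lambda: np.eye(2))
    sigma0: np.ndarray | None = None

    def __post_init__(self):
        if self.gamma_i <= 0 or self.gamma_j <= 0:
            raise ValueError("drag coefficients must be positive")
        D = np.asarray(self.noise, dtype=float)
        if D.shape != (2, 2) or not np.allclose(D, D.T):
            raise ValueError("noise matrix must be symmetric 2x2")
        object.__setattr__(self, "noise", D)

    @classmethod
    def from_relaxation_times(cls, tau_i, tau_j, coupling_ij=0.0,
                              coupling_ji=0.0, noise=None):
        """Build a system from relaxation times (ns) instead of omega/gamma.

        Sets gamma = 1 and omega^2 = 1/tau; coupling_ij is the action of j
        on i (alpha), coupling_ji of i on j (beta), in rate units (1/ns).
        """
        kw = {}
        if noise is not None:
            kw["noise"] = noise
        return cls(omega_i=math.sqrt(1.0 / tau_i), omega_j=math.sqrt(1.0 / tau_j),
                   gamma_i=1.0, gamma_j=1.0, alpha=coupling_ij, beta=coupling_ji, **kw)


def relaxation_matrix(sys: OscillatorSystem, check_stability: bool = True) -> np.ndarray:
    """2x2 relaxation matrix A of the overdamped equations of motion."""
    A = np.array([
        [-sys.omega_i ** 2 / sys.gamma_i, sys.alpha / sys.gamma_i],
        [sys.beta / sys.gamma_j, -sys.omega_j ** 2 / sys.gamma_j],
    ])
    if check_stability:
        assert_stable(A)
    return A


def assert_stable(A: np.ndarray) -> np.ndarray:
    """Eigenvalues of A, raising StabilityError unless all Re < 0."""
    eig = np.linalg.eigvals(A)
    if np.any(eig.real >= 0):
        raise StabilityError(f"relaxation matrix is not stable; eigenvalues {eig}")
    return eig


def stationary_covariance(A: np.ndarray, D: np.ndarray) -> np.ndarray:
    """Solve A Sigma + Sigma A^T + D = 0 for the stationary covariance.

    A must be stable and D symmetric PSD.  The residual of the Lyapunov
    identity is checked to < 1e-10 (relative to ||D||).
    """
    A = np.asarray(A, dtype=float)
    D = np.asarray(D, dtype=float)
    assert_stable(A)
    if not np.allclose(D, D.T):
        raise ValueError("noise matrix D must be symmetric")
    if np.any(np.linalg.eigvalsh(D) < -1e-12 * max(1.0, np.linalg.norm(D))):
        raise ValueError("noise matrix D must be positive semi-definite")
    Sigma = solve_continuous_lyapunov(A, -D)
    Sigma = 0.5 * (Sigma + Sigma.T)
    resid = np.linalg.norm(A @ Sigma + Sigma @ A.T + D)
    scale = max(1.0, np.linalg.norm(D))
    if resid > 1e-10 * scale:
        raise RuntimeError(f"Lyapunov residual {resid:.3e} exceeds tolerance")
    return Sigma


class AnalyticCorrelation:
    """Closed-form TDCF and Laplace transform for a stable linear system.

    Works for any dimension: pass the relaxation matrix A and a covariance
    (stationary Sigma for the noisy variant, or an initial-condition Sigma0
    for the deterministic-relaxation variant — the two variants share every
    formula once the covariance is fixed).  ``i`` and ``j`` select the pair.
    """

    def __init__(self, A: np.ndarray, Sigma: np.ndarray, i: int = 0, j: int = 1):
        self.A = np.asarray(A, dtype=float)
        self.Sigma = np.asarray(Sigma, dtype=float)
        self.i, self.j = i, j
        self.eigenvalues = assert_stable(self.A)
        vi, vj = self.Sigma[i, i], self.Sigma[j, j]
        if vi <= 0 or vj <= 0:
            raise ValueError("zero marginal variance: correlation undefined")
        self._norm = math.sqrt(vi * vj)

    @classmethod
    def from_system(cls, sys: OscillatorSystem) -> "AnalyticCorrelation":
        A = relaxation_matrix(sys)
        if sys.sigma0 is not None:
            Sigma = np.asarray(sys.sigma0, dtype=float)
        else:
            Sigma = stationary_covariance(A, sys.noise)
        return cls(A, Sigma)

    @property
    def pearson(self) -> float:
        """Equal-time (statistical) correlation coefficient."""
        return self.Sigma[self.i, self.j] / self._norm

    def _entry(self, direction: str):
        if direction == "forward":
            return self.i, self.j
        if direction == "reverse":
            return self.j, self.i
        raise ValueError(f"direction must be 'forward' or 'reverse', got {direction!r}")

    def tdcf(self, dt, direction: str = "forward") -> np.ndarray:
        """Normalized lagged cross-correlation C(dt).

        forward: first index at the earlier time, C(dt) = <x_i(t) x_j(t+dt)>
        / sqrt(Sigma_ii Sigma_jj) = [Sigma e^{A^T dt}]_{ij} / norm.
        """
        a, b = self._entry(direction)
        dt = np.atleast_1d(np.asarray(dt, dtype=float))
        if np.any(dt < 0):
            raise ValueError("lags must be non-negative")
        out = np.empty(dt.shape)
        for k, t in enumerate(dt.ravel()):
            out.ravel()[k] = (self.Sigma @ expm(self.A.T * t))[a, b]
        return (out / self._norm).reshape(dt.shape)

    def laplace(self, s, direction: str = "forward") -> np.ndarray:
        """Resolvent Laplace transform F(s) of the lagged correlation.

        F(s) = [Sigma (sI - A^T)^{-1}]_{entry} / norm, valid for s > 0
        (A stable).  F_ij != F_ji whenever the coupling is asymmetric.
        """
        a, b = self._entry(direction)
        s = np.atleast_1d(np.asarray(s, dtype=float))
        if np.any(s <= 0):
            raise ValueError("Laplace frequencies must be positive")
        n = self.A.shape[0]
        out = np.empty(s.shape)
        for k, sv in enumerate(s.ravel()):
            R = np.linalg.solve(sv * np.eye(n) - self.A.T, np.eye(n))
            out.ravel()[k] = (self.Sigma @ R)[a, b]
        return (out / self._norm).reshape(s.shape)

    def laplace_zero(self, direction: str = "forward") -> float:
        """s -> 0 limit of F(s); its sign equals the sign of the net correlation."""
        a, b = self._entry(direction)
        return (self.Sigma @ np.linalg.inv(-self.A.T))[a, b] / self._norm

    def tail_coefficients(self, direction: str = "forward", order: int = 3) -> np.ndarray:
        """Coefficients P_k of the large-s expansion F(s) = sum_k P_k / s^k.

        P_1 = C(0); the leading algebraic tail exponent is 1 when the
        equal-time cross-correlation is nonzero, else 2 (next term).
        """
        a, b = self._entry(direction)
        coeffs = []
        M = self.Sigma.copy()
        for _ in range(order):
            coeffs.append(M[a, b] / self._norm)
            M = M @ self.A.T
        return np.array(coeffs)

    def tail_exponent(self, atol: float = 1e-12) -> int:
        """Leading algebraic tail exponent from the resolvent expansion."""
        P = self.tail_coefficients(order=4)
        for k, c in enumerate(P, start=1):
            if abs(c) > atol:
                return k
        raise ValueError("all tail coefficients vanish")


def simulate_linear_sde(A, D, n_steps, dt, seed, method="euler",
                        burn_in="auto", Sigma=None):
    """Simulate dx = A x dt + noise with stationary covariance Sigma.

    Noise increments have covariance D*dt (Euler-Maruyama) or the exact
    one-step covariance Sigma - M Sigma M^T (method='exact', M = e^{A dt}).
    The linear recursion x_{n+1} = M x_n + w_n is evaluated per eigenmode
    of M with scipy.signal.lfilter, so long runs cost O(n d^2) vectorized
    work instead of a Python-level time loop.

    burn_in='auto' discards ten times the slowest relaxation time (the run
    starts from the origin); an integer gives the number of discarded
    steps directly.  Returns an (n_steps, d) array.
    """
    A = np.asarray(A, dtype=float)
    D = np.asarray(D, dtype=float)
    d = A.shape[0]
    eig = assert_stable(A)
    rate_fast = float(np.max(-eig.real))
    rate_slow = float(np.min(-eig.real))
    if method == "euler":
        if dt * rate_fast > 0.1:
            raise ValueError(
                f"dt={dt} too coarse for fastest relaxation rate {rate_fast:.3g}/ns; "
                f"use dt <= {0.1 / rate_fast:.3g}")
        M = np.eye(d) + A * dt
        Q = D * dt
    elif method == "exact":
        if Sigma is None:
            Sigma = stationary_covariance(A, D)
        M = expm(A * dt)
        Q = Sigma - M @ Sigma @ M.T
        Q = 0.5 * (Q + Q.T)
    else:
        raise ValueError(f"unknown method {method!r}")

    if burn_in == "auto":
        burn_in = int(np.ceil(10.0 / (rate_slow * dt)))
    n_total = n_steps + burn_in

    rng = np.random.default_rng(seed)
    # innovations with covariance Q via eigen square root (Q may be singular)
    w, V = np.linalg.eigh(Q)
    w = np.clip(w, 0.0, None)
    noise = rng.standard_normal((n_total, d)) @ (V * np.sqrt(w)).T

    lam, U = np.linalg.eig(M)
    z = np.linalg.solve(U, noise.T)  # innovations in eigenbasis, shape (d, n)
    for k in range(d):
        z[k] = lfilter([1.0], [1.0, -lam[k]], z[k])
    x = (U @ z).T.real
    return x[burn_in:]


def simulate(sys: OscillatorSystem, n_steps: int, dt: float, seed,
             method: str = "euler", amplitude_deg: float = 10.0):
    """Stochastic realization of the coupled-oscillator equations of motion.

    Returns (times_ns, angles_deg) with angles_deg of shape (n_steps, 2),
    rescaled so the stationary standard deviation of each variable is
    ``amplitude_deg`` degrees (small-angle regime: wrapping is inert).
    """
    A = relaxation_matrix(sys)
    Sigma = stationary_covariance(A, sys.noise)
    x = simulate_linear_sde(A, sys.noise, n_steps, dt, seed, method=method,
                            Sigma=Sigma)
    scale = amplitude_deg / np.sqrt(np.diag(Sigma))
    times = np.arange(n_steps) * dt
    return times, x * scale


def rotational_time(radius_nm: float, temperature_K: float,
                    viscosity_mPas: float, rank: int = 1) -> float:
    """Stokes-Einstein-Debye rotational correlation time, in ns.

    D_r = k_B T / (8 pi eta R^3); tau_l = 1 / (l (l+1) D_r) for correlation
    functions of rank-l spherical harmonics (rank 1: dipole/first Legendre;
    rank 2: e.g. NMR relaxation; tau_2 = tau_1 / 3).
    """
    if radius_nm <= 0 or temperature_K <= 0 or viscosity_mPas <= 0:
        raise ValueError("radius, temperature and viscosity must be positive")
    if rank not in (1, 2):
        raise ValueError("rank must be 1 or 2")
    eta = viscosity_mPas * 1e-3  # Pa s
    R = radius_nm * 1e-9  # m
    Dr = _KB_J_PER_K * temperature_K / (8.0 * math.pi * eta * R ** 3)  # 1/s
    tau_s = 1.0 / (rank * (rank + 1) * Dr)
    return tau_s * 1e9
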