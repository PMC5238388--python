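"""The time-dependent dihedral cross-correlation function (TDCF) and its
Laplace-domain summaries.

For two dihedral fluctuation series the lagged, normalized cross-correlation

    C_ij(dt_l) = sum_{t} dθ_i(t) dθ'_j(t + dt_l) / (N_l sqrt(var_i var_j)),

with N_l = N - l observation pairs per lag, generalizes the Pearson
coefficient (the dt = 0 value) into the time domain.  The forward curve
puts series i at the earlier time; the reverse curve swaps the roles and
is in general different — that exchange asymmetry is what carries the
directional information.

The numerical Laplace transform F(s) = ∫ C(dt) e^{-s dt} d dt (composite
trapezoid on the lag grid) condenses each curve into three numbers: the
extremum strength F_ext (a maximum for net-correlated, a minimum for
net-anticorrelated pairs), the characteristic timescale tau = 1/s_peak,
and the algebraic tail exponent kappa of |F| ~ s^-kappa at large s.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from .trajio import AngleSeries, wrap_angles

__all__ = [
    "ZeroVarianceError",
    "AlignmentError",
    "FluctuationSeries",
    "TDCFCurve",
    "LaplaceCurve",
    "ExtremumResult",
    "TailFit",
    "circular_mean",
    "fluctuations",
    "tdcf_pair",
    "tdcf_estimate",
    "pearson",
    "convergence_check",
    "default_s_grid",
    "laplace_transform",
    "extremum",
    "tail_exponent",
]


class ZeroVarianceError(ValueError):
    """Constant series: the normalized correlation is undefined."""


class AlignmentError(ValueError):
    """The two series do not share a common time grid."""


@dataclass
class FluctuationSeries:
    """Deviations of one dihedral from its circular mean.

    dev holds minimal-image deviations (degrees, wrapped to (-180, +180]
    and arithmetically re-centred), var their plain variance.
    """

    residue: int
    dof: str
    mean_deg: float
    dev: np.ndarray
    var: float
    dt: float

    @property
    def n(self) -> int:
        return self.dev.size

    @property
    def key(self):
        return (self.residue, self.dof)


@dataclass
class TDCFCurve:
    """Normalized lagged cross-correlation for one directed pair."""

    pair: tuple  # ((i, dof_i), (j, dof_j)), i's dihedral at the earlier time
    direction: str  # 'forward' (i earlier) or 'reverse' (j earlier)
    lags: np.ndarray  # ns, uniform from 0
    values: np.ndarray
    counts: np.ndarray  # N_l per lag

    @property
    def dt(self) -> float:
        return float(self.lags[1] - self.lags[0])

    @property
    def max_lag(self) -> float:
        return float(self.lags[-1])


@dataclass
class LaplaceCurve:
    """Numerical Laplace transform of a TDCF on a log-spaced s grid.

    lag_spacing is the quadrature step h of the source curve (None for
    analytically evaluated curves); c_end the terminal |C| used for the
    truncation-bias bound |C(dt_max)|/s.
    """

    s: np.ndarray  # 1/ns
    F: np.ndarray  # ns
    pair: tuple = None
    direction: str = ""
    lag_spacing: float | None = None
    max_lag: float | None = None
    c_end: float = 0.0

    def truncation_bias(self) -> np.ndarray:
        """Bound on the truncation error of the finite-lag quadrature."""
        return self.c_end / self.s


@dataclass
class ExtremumResult:
    F_ext: float
    s_peak: float
    tau: float
    boundary: bool
    tie: bool = False


@dataclass
class TailFit:
    kappa: float
    stderr: float
    window: tuple
    n_points: int
    shrunk: bool = False


# ---------------------------------------------------------------------------

def circular_mean(angles_deg) -> float:
    """Circular mean of angles in degrees, in (-180, +180]."""
    a = np.radians(np.asarray(angles_deg, dtype=float))
    m = math.degrees(math.atan2(np.mean(np.sin(a)), np.mean(np.cos(a))))
    return float(wrap_angles(m))


def fluctuations(series: AngleSeries, detrend: str = "wrap") -> FluctuationSeries:
    """Deviations from the circular mean, wrapped to the principal branch.

    detrend='wrap' (default, parameter-free): minimal-image deviation from
    the circular mean.  detrend='unwrap': np.unwrap the series first, then
    subtract the arithmetic mean — for series that hop branches often.
    The small residual arithmetic mean of the wrapped deviations is removed
    so that the zero-lag autocorrelation is exactly 1.
    """
    if series.n < 2:
        raise ValueError("need at least two samples")
    if detrend == "wrap":
        mean = circular_mean(series.angles)
        dev = wrap_angles(series.angles - mean)
    elif detrend == "unwrap":
        unwrapped = np.degrees(np.unwrap(np.radians(series.angles)))
        mean = float(unwrapped.mean())
        dev = unwrapped - mean
        mean = float(wrap_angles(mean))
    else:
        raise ValueError(f"unknown detrend policy {detrend!r}")
    dev = dev - dev.mean()
    var = float(np.mean(dev ** 2))
    if var <= 0.0:
        raise ZeroVarianceError(
            f"series (residue {series.residue}, {series.dof}) is constant; "
            "normalization undefined")
    return FluctuationSeries(residue=series.residue, dof=series.dof,
                             mean_deg=mean, dev=dev, var=var, dt=series.dt)


def _check_aligned(fi: FluctuationSeries, fj: FluctuationSeries):
    if fi.n != fj.n or not math.isclose(fi.dt, fj.dt, rel_tol=1e-9):
        raise AlignmentError(
            f"series not on a common grid: n={fi.n}/{fj.n}, dt={fi.dt}/{fj.dt}")


def _resolve_lags(fi, max_lag, min_count):
    n = fi.n
    if max_lag is None:
        max_lag = 0.25 * (n - 1) * fi.dt
    n_lags = int(np.floor(max_lag / fi.dt + 1e-9)) + 1
    n_lags = min(n_lags, max(n - min_count + 1, 1))
    if n_lags < 1:
        raise ValueError("max_lag leaves no usable lags")
    return n_lags


def cross_correlation_raw(a: np.ndarray, b: np.ndarray, n_lags: int):
    """(r_ab, r_ba): r_ab[l] = sum_t a[t] b[t+l] for l = 0..n_lags-1, via FFT."""
    n = a.size
    nfft = 1
    while nfft < 2 * n:
        nfft *= 2
    fa = np.fft.rfft(a, nfft)
    fb = np.fft.rfft(b, nfft)
    c = np.fft.irfft(np.conj(fa) * fb, nfft)
    r_ab = c[:n_lags].copy()
    r_ba = np.concatenate([c[:1], c[-1:-n_lags:-1]]) if n_lags > 1 else c[:1].copy()
    return r_ab, r_ba


def tdcf_pair(fi: FluctuationSeries, fj: FluctuationSeries,
              max_lag: float | None = None, min_count: int = 10,
              per_window_norm: bool = False):
    """Forward and reverse TDCF curves for one pair, in one pass.

    Forward: fi at the earlier time.  Normalization uses the full-series
    variances (the default); per_window_norm=True instead normalizes each
    lag by the variances over its own N_l-sample windows.
    """
    _check_aligned(fi, fj)
    n = fi.n
    n_lags = _resolve_lags(fi, max_lag, min_count)
    if n_lags > n:
        raise ValueError("max_lag exceeds the series span")
    counts = n - np.arange(n_lags)
    r_fwd, r_rev = cross_correlation_raw(fi.dev, fj.dev, n_lags)
    if per_window_norm:
        ai2 = np.cumsum(fi.dev ** 2)
        aj2 = np.cumsum(fj.dev ** 2)
        tot_i, tot_j = ai2[-1], aj2[-1]
        l = np.arange(n_lags)
        # var of fi over [0, n-l) and of fj over [l, n), and vice versa
        head_i = np.where(l > 0, ai2[n - 1 - l], tot_i) / counts
        tail_j = (tot_j - np.where(l > 0, aj2[l - 1], 0.0)) / counts
        head_j = np.where(l > 0, aj2[n - 1 - l], tot_j) / counts
        tail_i = (tot_i - np.where(l > 0, ai2[l - 1], 0.0)) / counts
        norm_fwd = np.sqrt(head_i * tail_j)
        norm_rev = np.sqrt(head_j * tail_i)
    else:
        norm_fwd = norm_rev = math.sqrt(fi.var * fj.var)
    lags = np.arange(n_lags) * fi.dt
    pair = ((fi.residue, fi.dof), (fj.residue, fj.dof))
    fwd = TDCFCurve(pair=pair, direction="forward", lags=lags,
                    values=r_fwd / (counts * norm_fwd), counts=counts)
    rev = TDCFCurve(pair=pair, direction="reverse", lags=lags,
                    values=r_rev / (counts * norm_rev), counts=counts.copy())
    return fwd, rev


def tdcf_estimate(fi: FluctuationSeries, fj: FluctuationSeries,
                  max_lag: float | None = None, min_count: int = 10,
                  per_window_norm: bool = False) -> TDCFCurve:
    """Forward TDCF curve (fi at the earlier time); see tdcf_pair."""
    fwd, _ = tdcf_pair(fi, fj, max_lag=max_lag, min_count=min_count,
                       per_window_norm=per_window_norm)
    return fwd


def pearson(fi: FluctuationSeries, fj: FluctuationSeries) -> float:
    """Equal-time correlation coefficient: the TDCF at zero lag, exactly."""
    _check_aligned(fi, fj)
    return float(np.mean(fi.dev * fj.dev) / math.sqrt(fi.var * fj.var))


def convergence_check(fi: FluctuationSeries, fj: FluctuationSeries,
                      fractions=(0.5, 0.9, 1.0), max_lag: float | None = None,
                      min_count: int = 10):
    """TDCF recomputed on leading prefixes, with pairwise sup-norm differences.

    Returns (curves, table): curves maps fraction -> forward TDCFCurve, and
    table is a pandas DataFrame of sup-norm differences over the common lag
    range so the caller can assert saturation.  Fractions whose prefix
    cannot cover max_lag are skipped with a warning.
    """
    import pandas as pd

    _check_aligned(fi, fj)
    if max_lag is None:
        max_lag = 0.25 * min(fractions) * (fi.n - 1) * fi.dt
    curves = {}
    for frac in sorted(fractions):
        if not 0 < frac <= 1:
            raise ValueError("fractions must lie in (0, 1]")
        m = int(round(frac * fi.n))
        if (m - min_count) * fi.dt < max_lag:
            warnings.warn(f"fraction {frac} too short to cover max_lag; skipped")
            continue
        sub_i = FluctuationSeries(fi.residue, fi.dof, fi.mean_deg,
                                  fi.dev[:m] - fi.dev[:m].mean(),
                                  float(np.var(fi.dev[:m])), fi.dt)
        sub_j = FluctuationSeries(fj.residue, fj.dof, fj.mean_deg,
                                  fj.dev[:m] - fj.dev[:m].mean(),
                                  float(np.var(fj.dev[:m])), fj.dt)
        curves[frac] = tdcf_estimate(sub_i, sub_j, max_lag=max_lag,
                                     min_count=min_count)
    fracs = sorted(curves)
    n_common = min(c.values.size for c in curves.values())
    rows = []
    for a in fracs:
        for b in fracs:
            if a < b:
                diff = np.max(np.abs(curves[a].values[:n_common]
                                     - curves[b].values[:n_common]))
                rows.append({"fraction_a": a, "fraction_b": b,
                             "sup_diff": float(diff)})
    return curves, pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Laplace domain

def default_s_grid(curve: TDCFCurve, n_points: int = 200) -> np.ndarray:
    """Log-spaced s grid spanning [1/(2 max_lag), 10/dt] 1/ns.

    Brackets both the low-s extremum (timescales up to twice the lag window)
    and the algebraic tail (an order of magnitude above the frame rate).
    """
    return np.geomspace(1.0 / (2.0 * curve.max_lag), 10.0 / curve.dt, n_points)


def laplace_transform(curve: TDCFCurve, s_grid=None) -> LaplaceCurve:
    """F(s) = ∫_0^{dt_max} C(dt) e^{-s dt} d dt by composite trapezoid."""
    s = default_s_grid(curve) if s_grid is None else np.asarray(s_grid, dtype=float)
    if np.any(s <= 0):
        raise ValueError("Laplace frequencies must be positive")
    t = curve.lags
    h = curve.dt
    w = np.full(t.size, h)
    w[0] = w[-1] = 0.5 * h
    cw = curve.values * w
    F = np.empty(s.size)
    # chunk the outer product so huge lag grids stay within memory
    step = max(1, int(4e6 // t.size))
    for k in range(0, s.size, step):
        F[k:k + step] = np.exp(-np.outer(s[k:k + step], t)) @ cw
    return LaplaceCurve(s=s, F=F, pair=curve.pair, direction=curve.direction,
                        lag_spacing=h, max_lag=curve.max_lag,
                        c_end=float(abs(curve.values[-1])))


def extremum(lc: LaplaceCurve) -> ExtremumResult:
    """Interior extremum of F(s): strength F_ext, position s_peak, tau = 1/s_peak.

    A maximum is sought when the low-s end of F is positive (net-correlated
    pair), a minimum when it is negative.  Boundary extrema are flagged and
    tau is then only a bound.  Ties resolve to the smallest s (longest
    timescale) and are flagged.
    """
    if lc.s.size < 10:
        raise ValueError("need at least 10 grid points to locate an extremum")
    vals = lc.F if lc.F[0] >= 0 else -lc.F
    best = float(np.max(vals))
    hits = np.nonzero(np.isclose(vals, best, rtol=1e-12, atol=0.0))[0]
    k = int(hits[0])
    tie = hits.size > 1
    boundary = k == 0 or k == lc.s.size - 1
    s_peak = float(lc.s[k])
    return ExtremumResult(F_ext=float(lc.F[k]), s_peak=s_peak, tau=1.0 / s_peak,
                          boundary=boundary, tie=tie)


def tail_window(lc: LaplaceCurve, bias_factor: float = 5.0,
                quad_cap: float = 0.5) -> tuple:
    """High-s fit window (s_lo, s_hi) for the algebraic tail.

    s_hi is the top of the highest decade where |F| exceeds bias_factor x
    the truncation-bias bound |C(dt_max)|/s and, for quadrature-derived
    curves, where s*h <= quad_cap so the trapezoid rule still resolves
    e^{-s dt} (relative error (s h)^2 / 12); the window is the decade
    [s_hi/10, s_hi].
    """
    ok = np.abs(lc.F) > bias_factor * lc.c_end / lc.s
    if lc.lag_spacing is not None:
        ok &= lc.s * lc.lag_spacing <= quad_cap
    if not np.any(ok):
        raise ValueError("no s range above the truncation-bias floor")
    s_hi = float(lc.s[np.nonzero(ok)[0][-1]])
    return (s_hi / 10.0, s_hi)


def tail_exponent(lc: LaplaceCurve, window: tuple | None = None,
                  min_points: int = 5) -> TailFit:
    """kappa = -slope of the least-squares fit of ln|F| vs ln s over the
    high-s window, with its standard error.

    Sign changes of F inside the window shrink it to the largest
    sign-constant upper part, with a warning.
    """
    if window is None:
        window = tail_window(lc)
    lo, hi = window
    mask = (lc.s >= lo) & (lc.s <= hi)
    s = lc.s[mask]
    F = lc.F[mask]
    shrunk = False
    signs = np.sign(F)
    if signs.size and np.any(signs != signs[-1]):
        last_flip = np.nonzero(signs != signs[-1])[0][-1]
        s, F = s[last_flip + 1:], F[last_flip + 1:]
        shrunk = True
        warnings.warn("F changes sign inside the tail window; window shrunk")
    if s.size < min_points:
        raise ValueError(f"tail window holds {s.size} points; need >= {min_points}")
    x = np.log(s)
    y = np.log(np.abs(F))
    coef, cov = np.polyfit(x, y, 1, cov=True)
    return TailFit(kappa=float(-coef[0]), stderr=float(np.sqrt(cov[0, 0])),
                   window=(float(s[0]), float(s[-1])), n_points=int(s.size),
                   shrunk=shrunk)


def summarize(lc: LaplaceCurve, pearson_value: float | None = None) -> dict:
    """JSON-ready summary of one Laplace curve: strength, timescale, tail."""
    ext = extremum(lc)
    try:
        tail = tail_exponent(lc)
        kappa, kappa_err = tail.kappa, tail.stderr
    except ValueError:
        kappa, kappa_err = float("nan"), float("nan")
    return {"F_ext": ext.F_ext, "s_peak": ext.s_peak, "tau_ns": ext.tau,
            "boundary": ext.boundary, "kappa": kappa, "kappa_stderr": kappa_err,
            "pearson": pearson_value, "direction": lc.direction}
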