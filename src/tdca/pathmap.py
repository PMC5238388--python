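"""Directional residue-residue correlation map and the downstream-correlated path.

For every residue pair (i, j) the TDCF is computed for all defined dihedral
degree-of-freedom pairs (phi/psi/chi1 against phi/psi/chi1) in both time
orders.  The dof pair with the largest Laplace-peak magnitude defines the
cell; whichever direction carries the larger peak defines *downstream*:
residue j is downstream of i when the forward curve (i's dihedral at the
earlier time) wins, i.e. perturbations at i precede responses at j.

Significance is decided against a block-shuffle null: one residue's series
are circularly shifted by random offsets at least a correlation window
long, and the cell statistic (the maximum peak magnitude over all dof
pairs and directions) is recomputed per shuffle; a cell is correlated when
its real statistic exceeds the null's upper quantile.

The correlated path starts from a chosen residue and repeatedly steps to
the spatially closest (mean Calpha-Calpha distance) downstream-correlated
residue — an operational construction of an allosteric communication route.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path as FsPath

import numpy as np
import pandas as pd

from . import tdcf as _tdcf
from .trajio import DistanceStats

__all__ = [
    "MapConfig",
    "DirectedCorrelation",
    "CorrelationMap",
    "Path",
    "pair_table",
    "best_dof_pair",
    "build_map",
    "downstream_set",
    "build_path",
    "amplitude_vs_variance",
    "peak_vs_pearson",
    "write_edge_table",
    "write_matrix",
]

DOF_ORDER = ("phi", "psi", "chi1")
BACKBONE_DOFS = {"phi", "psi"}


@dataclass(frozen=True)
class MapConfig:
    """Knobs of the map construction.

    max_lag: lag window in ns (None: 25% of the series span);
    n_s: Laplace grid size; n_shuffles/sig_level: block-shuffle null;
    min_shift: smallest circular shift in frames (None: the lag window,
    i.e. at least a correlation window); seed feeds the shuffle draws.
    """

    max_lag: float | None = None
    n_s: int = 200
    min_count: int = 10
    n_shuffles: int = 200
    sig_level: float = 0.95
    min_shift: int | None = None
    seed: int = 0


@dataclass
class DirectedCorrelation:
    """One cell of the map: best dof pair, both directions retained."""

    i: int
    j: int
    status: str  # 'ok' | 'uncorrelated' | 'missing'
    dof_i: str | None = None
    dof_j: str | None = None
    upstream: int | None = None
    downstream: int | None = None
    f_fwd: float = math.nan  # peak magnitude, i at the earlier time
    f_rev: float = math.nan
    tau_fwd: float = math.nan
    tau_rev: float = math.nan
    pearson: float = math.nan
    threshold: float = math.nan
    tie: bool = False
    table: pd.DataFrame | None = None  # full per-dof-pair table, both directions

    @property
    def f_best(self) -> float:
        return max(self.f_fwd, self.f_rev)

    @property
    def significant(self) -> bool:
        return self.status == "ok"


@dataclass
class CorrelationMap:
    """Upper-triangular collection of DirectedCorrelation cells."""

    residues: list
    cells: dict  # (i, j) with i < j -> DirectedCorrelation
    config: MapConfig

    @property
    def n_res(self) -> int:
        return len(self.residues)

    def cell(self, i: int, j: int) -> DirectedCorrelation:
        return self.cells[(min(i, j), max(i, j))]

    def edge_table(self) -> pd.DataFrame:
        rows = []
        for (i, j), c in sorted(self.cells.items()):
            rows.append({
                "i": i, "j": j, "status": c.status, "dof_i": c.dof_i,
                "dof_j": c.dof_j, "upstream": c.upstream,
                "downstream": c.downstream, "f_fwd": c.f_fwd, "f_rev": c.f_rev,
                "tau_fwd_ns": c.tau_fwd, "tau_rev_ns": c.tau_rev,
                "pearson": c.pearson, "threshold": c.threshold,
                "significant": c.significant, "tie": c.tie,
            })
        return pd.DataFrame(rows)

    def matrix(self) -> pd.DataFrame:
        """Square matrix; cell (i, j), i < j holds the signed best peak
        (positive when j is downstream of i, negative when upstream)."""
        n = self.n_res
        m = np.zeros((n, n))
        slot = {r: k for k, r in enumerate(self.residues)}
        for (i, j), c in self.cells.items():
            if c.significant:
                sign = 1.0 if c.downstream == j else -1.0
                m[slot[i], slot[j]] = sign * c.f_best
        return pd.DataFrame(m, index=self.residues, columns=self.residues)


@dataclass
class Path:
    """Ordered downstream-correlated residue chain."""

    residues: list
    steps: pd.DataFrame  # from, to, dof_from, dof_to, f_max, tau_ns, d_mean_nm, tie
    truncated_by_cycle_guard: bool = False

    def __len__(self):
        return len(self.residues)


# ---------------------------------------------------------------------------

def _fluctuate_all(series: dict) -> dict:
    out = {}
    for key, s in series.items():
        out[key] = s if isinstance(s, _tdcf.FluctuationSeries) else _tdcf.fluctuations(s)
    return out


def pair_table(flucts: dict, i: int, j: int, max_lag=None, min_count=10,
               s_grid=None) -> pd.DataFrame:
    """Per-dof-pair Laplace summaries for residues i and j, both directions.

    Rows: dof_i, dof_j, direction ('forward' = i earlier), f_mag (peak
    magnitude max_s |F|), F_ext, s_peak, tau_ns, boundary, pearson.
    Undefined dofs (missing from ``flucts``) are skipped.
    """
    rows = []
    for dof_i in DOF_ORDER:
        fi = flucts.get((i, dof_i))
        if fi is None:
            continue
        for dof_j in DOF_ORDER:
            fj = flucts.get((j, dof_j))
            if fj is None:
                continue
            fwd, rev = _tdcf.tdcf_pair(fi, fj, max_lag=max_lag, min_count=min_count)
            r = _tdcf.pearson(fi, fj)
            for curve in (fwd, rev):
                lc = _tdcf.laplace_transform(curve, s_grid=s_grid)
                ext = _tdcf.extremum(lc)
                rows.append({"dof_i": dof_i, "dof_j": dof_j,
                             "direction": curve.direction,
                             "f_mag": float(np.max(np.abs(lc.F))),
                             "F_ext": ext.F_ext, "s_peak": ext.s_peak,
                             "tau_ns": ext.tau, "boundary": ext.boundary,
                             "pearson": r})
    return pd.DataFrame(rows)


def best_dof_pair(i: int, j: int, table: pd.DataFrame,
                  threshold: float = -math.inf) -> DirectedCorrelation:
    """Reduce a pair table to one DirectedCorrelation cell.

    The winning dof pair maximizes the peak magnitude over all dof pairs
    and directions; the winning direction (forward: j downstream of i)
    is the one with the larger magnitude for that dof pair.  Cells whose
    best magnitude does not exceed ``threshold`` are marked uncorrelated.
    Exact ties resolve to the earlier dof in (phi, psi, chi1) order and to
    the forward direction, and are flagged.
    """
    if table.empty:
        return DirectedCorrelation(i=i, j=j, status="missing")
    tbl = table.sort_values(
        ["dof_i", "dof_j", "direction"],
        key=lambda col: col.map({d: k for k, d in enumerate(DOF_ORDER)})
        if col.name in ("dof_i", "dof_j") else col.map({"forward": 0, "reverse": 1}),
        kind="stable").reset_index(drop=True)
    best_idx = int(tbl["f_mag"].idxmax())
    best = tbl.loc[best_idx]
    tie = bool(np.sum(np.isclose(tbl["f_mag"], best["f_mag"], rtol=1e-12)) > 1)
    sel = (tbl["dof_i"] == best["dof_i"]) & (tbl["dof_j"] == best["dof_j"])
    fwd = tbl[sel & (tbl["direction"] == "forward")].iloc[0]
    rev = tbl[sel & (tbl["direction"] == "reverse")].iloc[0]
    forward_wins = fwd["f_mag"] >= rev["f_mag"]
    cell = DirectedCorrelation(
        i=i, j=j,
        status="ok" if best["f_mag"] > threshold else "uncorrelated",
        dof_i=str(best["dof_i"]), dof_j=str(best["dof_j"]),
        upstream=i if forward_wins else j,
        downstream=j if forward_wins else i,
        f_fwd=float(fwd["f_mag"]), f_rev=float(rev["f_mag"]),
        tau_fwd=float(fwd["tau_ns"]), tau_rev=float(rev["tau_ns"]),
        pearson=float(best["pearson"]), threshold=threshold, tie=tie,
        table=table)
    return cell


def _null_max_stats(flucts: dict, i: int, j: int, n_lags: int, s_grid,
                    n_shuffles: int, min_shift: int, rng) -> np.ndarray:
    """Null distribution of the cell statistic under circular shifts of j.

    All of residue j's dof series are shifted by the same random offset per
    shuffle (the block shuffle preserves each series' autocorrelation while
    destroying the cross-correlation); the statistic is the max over dof
    pairs and directions of max_s |F(s)|.

    A circular shift of one series shifts the *circular* cross-correlation
    by the same offset, so the full set of shuffles needs only one FFT
    correlation per dof pair; each shuffle is then an index slice.  The
    circular estimator differs from the zero-padded one used for the real
    statistic only in the O(n_lags/N) seam terms, which under the null are
    ordinary samples.
    """
    dofs_i = [d for d in DOF_ORDER if (i, d) in flucts]
    dofs_j = [d for d in DOF_ORDER if (j, d) in flucts]
    n = flucts[(i, dofs_i[0])].n
    lags = np.arange(n_lags) * flucts[(i, dofs_i[0])].dt
    h = lags[1] - lags[0] if n_lags > 1 else 1.0
    w = np.full(n_lags, h)
    if n_lags > 1:
        w[0] = w[-1] = 0.5 * h
    E = np.exp(-np.outer(s_grid, lags)) * w  # (n_s, n_lags)
    offsets = rng.integers(min_shift, n - min_shift, size=n_shuffles)
    lag_idx = np.arange(n_lags)
    out = np.zeros(n_shuffles)
    for di in dofs_i:
        fa = np.conj(np.fft.rfft(flucts[(i, di)].dev))
        for dj in dofs_j:
            c = np.fft.irfft(fa * np.fft.rfft(flucts[(j, dj)].dev), n)
            norm = n * math.sqrt(flucts[(i, di)].var * flucts[(j, dj)].var)
            c = c / norm  # circular correlation, N terms at every lag
            idx_f = (lag_idx[None, :] - offsets[:, None]) % n
            idx_r = (-lag_idx[None, :] - offsets[:, None]) % n
            f_f = np.abs(c[idx_f] @ E.T).max(axis=1)
            f_r = np.abs(c[idx_r] @ E.T).max(axis=1)
            np.maximum(out, np.maximum(f_f, f_r), out=out)
    return out


def build_map(series: dict, residues=None, config: MapConfig | None = None) -> CorrelationMap:
    """Directional correlation map over all residue pairs.

    series maps (residue, dof) to AngleSeries or FluctuationSeries;
    residues defaults to every residue appearing in the keys.  Cells of
    residues with no series at all are marked 'missing', never silently
    zero.
    """
    config = config or MapConfig()
    flucts = _fluctuate_all(series)
    if residues is None:
        residues = sorted({r for (r, _) in flucts})
    residues = list(residues)
    some = next(iter(flucts.values()))
    n = some.n
    max_lag = config.max_lag if config.max_lag is not None else 0.25 * (n - 1) * some.dt
    n_lags = min(int(np.floor(max_lag / some.dt + 1e-9)) + 1,
                 n - config.min_count + 1)
    s_grid = np.geomspace(1.0 / (2.0 * (n_lags - 1) * some.dt),
                          10.0 / some.dt, config.n_s)
    min_shift = config.min_shift if config.min_shift is not None else n_lags
    min_shift = min(min_shift, n // 2 - 1)

    cells = {}
    for a, i in enumerate(residues):
        for j in residues[a + 1:]:
            if not any((i, d) in flucts for d in DOF_ORDER) or \
               not any((j, d) in flucts for d in DOF_ORDER):
                cells[(i, j)] = DirectedCorrelation(i=i, j=j, status="missing")
                continue
            tbl = pair_table(flucts, i, j, max_lag=max_lag,
                             min_count=config.min_count, s_grid=s_grid)
            rng = np.random.default_rng([config.seed, i, j])
            null = _null_max_stats(flucts, i, j, n_lags, s_grid,
                                   config.n_shuffles, min_shift, rng)
            thr = float(np.quantile(null, config.sig_level))
            cells[(i, j)] = best_dof_pair(i, j, tbl, threshold=thr)
    return CorrelationMap(residues=residues, cells=cells, config=config)


def downstream_set(cmap: CorrelationMap, r: int) -> list:
    """Residues downstream-correlated to r (perturbations at r precede them)."""
    out = []
    for (i, j), c in cmap.cells.items():
        if c.significant and c.upstream == r:
            out.append(c.downstream)
    return sorted(out)


def build_path(cmap: CorrelationMap, distances, start: int) -> Path:
    """Greedy downstream-correlated path from ``start``.

    distances: mapping (i, j) [i < j] -> DistanceStats or mean Calpha-Calpha
    distance in nm, or a callable (i, j) -> mean distance.  Each step picks
    the spatially closest unvisited downstream residue; equal distances
    resolve to the lower residue index (flagged).  Terminates when the
    downstream set is exhausted or after n_res steps (cycle guard).
    """
    if start not in cmap.residues:
        raise ValueError(f"start residue {start} not in the map")

    def dist(i, j):
        key = (min(i, j), max(i, j))
        if callable(distances):
            return float(distances(*key))
        d = distances[key]
        return float(d.mean_nm) if isinstance(d, DistanceStats) else float(d)

    visited = [start]
    rows = []
    guard = cmap.n_res
    truncated = False
    current = start
    for _ in range(guard + 1):
        candidates = [r for r in downstream_set(cmap, current) if r not in visited]
        if not candidates:
            break
        if len(rows) >= guard:
            truncated = True
            break
        dvals = np.array([dist(current, r) for r in candidates])
        best = float(np.min(dvals))
        hits = [r for r, d in zip(candidates, dvals) if np.isclose(d, best, rtol=1e-12)]
        nxt = min(hits)
        cell = cmap.cell(current, nxt)
        rows.append({"from": current, "to": nxt,
                     "dof_from": cell.dof_i if cell.upstream == cell.i else cell.dof_j,
                     "dof_to": cell.dof_j if cell.upstream == cell.i else cell.dof_i,
                     "f_max": cell.f_best,
                     "tau_ns": cell.tau_fwd if cell.upstream == cell.i else cell.tau_rev,
                     "d_mean_nm": best, "tie": len(hits) > 1})
        visited.append(nxt)
        current = nxt
    return Path(residues=visited, steps=pd.DataFrame(rows),
                truncated_by_cycle_guard=truncated)


def _pair_kind(dof_i: str, dof_j: str) -> str:
    bi = dof_i in BACKBONE_DOFS
    bj = dof_j in BACKBONE_DOFS
    if bi and bj:
        return "alpha-alpha"
    if bi or bj:
        return "alpha-beta"
    return "beta-beta"


def amplitude_vs_variance(cmap: CorrelationMap, stats) -> pd.DataFrame:
    """Peak amplitude against distance variance per cell.

    stats: mapping (i, j, kind) -> DistanceStats (or variance in nm^2).
    The dof-pair kind of the winning pair chooses which distance variance
    applies (backbone-backbone: var(d_alpha-alpha), backbone-side:
    var(d_alpha-beta), side-side: var(d_beta-beta)).
    """
    rows = []
    for (i, j), c in sorted(cmap.cells.items()):
        if c.status != "ok":
            continue
        kind = _pair_kind(c.dof_i, c.dof_j)
        st = stats[(i, j, kind)]
        var = float(st.var_nm2) if isinstance(st, DistanceStats) else float(st)
        rows.append({"i": i, "j": j, "kind": kind, "f_max": c.f_best,
                     "var_nm2": var})
    return pd.DataFrame(rows, columns=["i", "j", "kind", "f_max", "var_nm2"])


def peak_vs_pearson(cmap: CorrelationMap, significant_only: bool = True):
    """Table of (F_max, tau, |Pearson|) per cell, plus rank correlations.

    Returns (table, stats) where stats holds Spearman rank correlations of
    the peak strength and of the timescale against |C(0)| — the strength
    tracks the equal-time correlation, the timescale need not.
    """
    from scipy.stats import spearmanr

    rows = []
    for (i, j), c in sorted(cmap.cells.items()):
        if c.status == "missing" or (significant_only and not c.significant):
            continue
        rows.append({"i": i, "j": j, "f_max": c.f_best,
                     "tau_ns": c.tau_fwd if c.downstream == c.j else c.tau_rev,
                     "abs_pearson": abs(c.pearson)})
    table = pd.DataFrame(rows, columns=["i", "j", "f_max", "tau_ns", "abs_pearson"])
    stats = {"rho_fmax_pearson": math.nan, "rho_tau_pearson": math.nan}
    if len(table) >= 3:
        stats["rho_fmax_pearson"] = float(
            spearmanr(table["f_max"], table["abs_pearson"]).statistic)
        stats["rho_tau_pearson"] = float(
            spearmanr(table["tau_ns"], table["abs_pearson"]).statistic)
    return table, stats


def write_edge_table(cmap: CorrelationMap, path) -> FsPath:
    path = FsPath(path)
    cmap.edge_table().to_csv(path, sep="\t", index=False, float_format="%.6g")
    return path


def write_matrix(cmap: CorrelationMap, path) -> FsPath:
    path = FsPath(path)
    cmap.matrix().to_csv(path, sep="\t", float_format="%.6g")
    return path
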