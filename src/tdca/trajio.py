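"""Structures, trajectories, dihedral time series and distance statistics.

Readers accept a PDB topology plus DCD/XTC coordinates (via MDAnalysis) or
pre-extracted per-residue dihedral series as delimited text.  Internally
everything is nm and ns; angles are degrees on the principal branch
(-180, +180].  Residues keep their 1-based PDB author numbering; the
``Structure.residues`` array is the explicit mapping to contiguous 0-based
storage.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "DegenerateGeometryError",
    "UndefinedDihedralError",
    "MissingAtomError",
    "NoEquilibrationWarning",
    "AngleSeries",
    "Structure",
    "Trajectory",
    "DistanceStats",
    "BurninResult",
    "wrap_angles",
    "dihedral_angle",
    "extract_series",
    "backbone_rmsd",
    "burnin_from_rmsd",
    "backbone_rmsd_burnin",
    "burnin_fraction",
    "distance_stats",
    "distance_stats_from_positions",
    "load_structure",
    "load_trajectory",
    "read_angle_series",
    "read_series_dir",
    "write_angle_series",
    "write_distance_stats",
]


class DegenerateGeometryError(ValueError):
    """Collinear or coincident points make a dihedral undefined."""


class UndefinedDihedralError(ValueError):
    """Requested dihedral does not exist for this residue (chain terminus, Gly/Ala chi1)."""


class MissingAtomError(KeyError):
    """A named atom required by an operation is absent from the structure."""


class NoEquilibrationWarning(UserWarning):
    """Backbone RMSD never saturated within tolerance."""


def wrap_angles(x):
    """Wrap angles in degrees onto the principal branch (-180, +180]."""
    x = np.asarray(x, dtype=float)
    w = -(((-x) + 180.0) % 360.0 - 180.0)
    return w


@dataclass
class AngleSeries:
    """One dihedral degree of freedom sampled uniformly in time.

    residue: 1-based residue index; dof: 'phi' | 'psi' | 'chi1';
    times in ns (uniform spacing), angles in degrees on (-180, +180].
    """

    residue: int
    dof: str
    times: np.ndarray
    angles: np.ndarray

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.angles = wrap_angles(self.angles)
        if self.times.shape != self.angles.shape:
            raise ValueError("times and angles must have equal length")
        if self.times.size >= 2:
            steps = np.diff(self.times)
            if np.any(steps <= 0) or not np.allclose(steps, steps[0], rtol=1e-6, atol=1e-12):
                raise ValueError("times must be uniform and strictly increasing")

    @property
    def n(self) -> int:
        return self.times.size

    @property
    def dt(self) -> float:
        if self.times.size < 2:
            raise ValueError("series too short to define a sampling interval")
        return float(self.times[1] - self.times[0])

    @property
    def key(self):
        return (self.residue, self.dof)


@dataclass
class Structure:
    """Atom table of a reference structure; coordinates in nm."""

    names: np.ndarray
    elements: np.ndarray
    resids: np.ndarray  # 1-based author numbering
    resnames: np.ndarray
    chains: np.ndarray
    coords: np.ndarray  # (n_atoms, 3) nm

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("structure coordinates must be finite")
        self._index = {(int(r), str(n)): k
                       for k, (r, n) in enumerate(zip(self.resids, self.names))}
        # preserve file order of residues (mapping 1-based id -> 0-based slot)
        seen = {}
        for r in self.resids:
            seen.setdefault(int(r), len(seen))
        self._res_slot = seen

    @property
    def residues(self) -> np.ndarray:
        """Residue ids in order of appearance (0-based slot -> 1-based id)."""
        return np.fromiter(self._res_slot.keys(), dtype=int)

    @property
    def n_residues(self) -> int:
        return len(self._res_slot)

    def atom_index(self, resid: int, name: str) -> int:
        try:
            return self._index[(int(resid), name)]
        except KeyError:
            raise MissingAtomError(f"atom {name} of residue {resid} not in structure") from None

    def has_atom(self, resid: int, name: str) -> bool:
        return (int(resid), name) in self._index

    def resname(self, resid: int) -> str:
        k = np.nonzero(self.resids == resid)[0]
        if k.size == 0:
            raise MissingAtomError(f"residue {resid} not in structure")
        return str(self.resnames[k[0]])


@dataclass
class Trajectory:
    """Reference structure plus per-frame coordinates (nm) on a uniform time grid (ns)."""

    structure: Structure
    times: np.ndarray
    coords: np.ndarray  # (n_frames, n_atoms, 3) nm

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[0] != self.times.size:
            raise ValueError("coords must be (n_frames, n_atoms, 3) matching times")
        if self.times.size < 2:
            raise ValueError("a trajectory needs at least two frames")
        steps = np.diff(self.times)
        if np.any(steps <= 0) or not np.allclose(steps, steps[0], rtol=1e-6, atol=1e-12):
            raise ValueError("frame spacing must be positive and constant")

    @property
    def n_frames(self) -> int:
        return self.times.size

    @property
    def dt(self) -> float:
        return float(self.times[1] - self.times[0])


@dataclass
class DistanceStats:
    """Mean and variance of an inter-residue atom-atom distance."""

    i: int
    j: int
    kind: str  # 'alpha-alpha' | 'alpha-beta' | 'beta-beta'
    mean_nm: float
    var_nm2: float
    n_frames: int

    def __post_init__(self):
        if self.mean_nm <= 0:
            raise ValueError("mean distance must be positive")
        if self.var_nm2 < 0:
            raise ValueError("distance variance cannot be negative")


@dataclass
class BurninResult:
    frame_index: int
    equilibrated: bool


# ---------------------------------------------------------------------------
# dihedral geometry

def dihedral_angle(p1, p2, p3, p4, atoms: str = ""):
    """Signed dihedral angle in degrees for four consecutive atoms.

    The torsion about the p2->p3 axis, IUPAC convention: looking from p2
    towards p3, a clockwise rotation of p3->p4 relative to p1->p2 is
    positive (the convention of MDAnalysis, mdtraj and biotite).  Accepts
    single points or (n, 3) stacks; returns a scalar or a length-n array
    in (-180, +180].
    """
    p1, p2, p3, p4 = (np.asarray(p, dtype=float) for p in (p1, p2, p3, p4))
    b1 = p2 - p1
    b2 = p3 - p2
    b3 = p4 - p3
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    nb2 = np.linalg.norm(b2, axis=-1)
    n1n = np.linalg.norm(n1, axis=-1)
    n2n = np.linalg.norm(n2, axis=-1)
    scale = max(float(np.max(nb2)), 1.0)
    bad = (nb2 < 1e-12) | (n1n < 1e-9 * scale ** 2) | (n2n < 1e-9 * scale ** 2)
    if np.any(bad):
        where = f" ({atoms})" if atoms else ""
        raise DegenerateGeometryError(
            f"collinear or coincident points: dihedral undefined{where}")
    x = np.sum(n1 * n2, axis=-1)
    y = np.sum(np.cross(n1, n2) * (b2 / nb2[..., None]), axis=-1)
    ang = wrap_angles(np.degrees(np.arctan2(y, x)))
    return float(ang) if ang.ndim == 0 else ang


# IUPAC chi1 terminal (gamma) atom per residue type; None -> chi1 undefined
CHI1_GAMMA = {
    "ALA": None, "GLY": None,
    "ILE": "CG1", "VAL": "CG1",
    "SER": "OG", "THR": "OG1", "CYS": "SG",
}
_CHI1_DEFAULT = "CG"


def chi1_gamma_atom(resname: str):
    return CHI1_GAMMA.get(resname.upper(), _CHI1_DEFAULT)


def _dihedral_quadruple(structure: Structure, residue: int, dof: str):
    """Atom indices of the four atoms defining phi/psi/chi1 of a residue."""
    resids = structure.residues
    slot = {int(r): k for k, r in enumerate(resids)}
    if residue not in slot:
        raise MissingAtomError(f"residue {residue} not in structure")
    if dof == "phi":
        if slot[residue] == 0:
            raise UndefinedDihedralError(
                f"phi undefined for the first residue ({residue}): no C of residue i-1")
        prev = int(resids[slot[residue] - 1])
        quad = [(prev, "C"), (residue, "N"), (residue, "CA"), (residue, "C")]
    elif dof == "psi":
        if slot[residue] == len(resids) - 1:
            raise UndefinedDihedralError(
                f"psi undefined for the last residue ({residue}): no N of residue i+1")
        nxt = int(resids[slot[residue] + 1])
        quad = [(residue, "N"), (residue, "CA"), (residue, "C"), (nxt, "N")]
    elif dof == "chi1":
        resname = structure.resname(residue)
        gamma = chi1_gamma_atom(resname)
        if gamma is None:
            raise UndefinedDihedralError(
                f"chi1 undefined for {resname}{residue}: no gamma-position atom")
        quad = [(residue, "N"), (residue, "CA"), (residue, "CB"), (residue, gamma)]
    else:
        raise ValueError(f"unknown dof {dof!r}; expected phi, psi or chi1")
    try:
        return [structure.atom_index(r, n) for r, n in quad]
    except MissingAtomError as err:
        raise UndefinedDihedralError(
            f"{dof} of residue {residue}: {err.args[0]}") from None


def extract_series(traj: Trajectory, residue: int, dof: str,
                   start: int = 0) -> AngleSeries:
    """Dihedral angle time series for one residue/dof over frames >= start."""
    idx = _dihedral_quadruple(traj.structure, residue, dof)
    c = traj.coords[start:]
    label = "-".join(f"{traj.structure.names[k]}{traj.structure.resids[k]}" for k in idx)
    ang = dihedral_angle(c[:, idx[0]], c[:, idx[1]], c[:, idx[2]], c[:, idx[3]],
                         atoms=label)
    return AngleSeries(residue=residue, dof=dof, times=traj.times[start:],
                       angles=np.atleast_1d(ang))


# ---------------------------------------------------------------------------
# burn-in detection

_BACKBONE = ("N", "CA", "C", "O")


def backbone_rmsd(traj: Trajectory, ref_frame: int = 0) -> np.ndarray:
    """Backbone RMSD (nm) per frame after optimal rigid-body superposition."""
    from scipy.spatial.transform import Rotation

    st = traj.structure
    idx = [k for k, n in enumerate(st.names) if n in _BACKBONE]
    if not idx:
        raise MissingAtomError("no backbone atoms (N, CA, C, O) in structure")
    X = traj.coords[:, idx, :]
    ref = X[ref_frame] - X[ref_frame].mean(axis=0)
    out = np.empty(traj.n_frames)
    for f in range(traj.n_frames):
        mob = X[f] - X[f].mean(axis=0)
        _, rssd = Rotation.align_vectors(ref, mob)
        out[f] = rssd / np.sqrt(len(idx))
    return out


def burnin_from_rmsd(rmsd, window: int, tol: float) -> BurninResult:
    """First frame index after which window-mean RMSD changes by < tol per window.

    The RMSD profile is averaged over consecutive non-overlapping windows;
    the result is the start of the first window from which on every
    window-to-window change stays below tol.  A never-saturating profile
    triggers NoEquilibrationWarning and returns frame 0 flagged.
    """
    rmsd = np.asarray(rmsd, dtype=float)
    if window < 1:
        raise ValueError("window must be >= 1 frame")
    n_win = rmsd.size // window
    if n_win < 2:
        raise ValueError("need at least two full windows of frames")
    means = rmsd[: n_win * window].reshape(n_win, window).mean(axis=1)
    deltas = np.abs(np.diff(means))
    bad = np.nonzero(deltas >= tol)[0]
    if bad.size == 0:
        return BurninResult(frame_index=0, equilibrated=True)
    first_good_win = bad[-1] + 1
    if first_good_win >= n_win - 1:
        warnings.warn("backbone RMSD never saturates within tolerance; "
                      "using the trajectory start", NoEquilibrationWarning)
        return BurninResult(frame_index=0, equilibrated=False)
    return BurninResult(frame_index=int(first_good_win * window), equilibrated=True)


def backbone_rmsd_burnin(traj: Trajectory, window: int, tol: float) -> BurninResult:
    if traj.n_frames < 2 * window:
        raise ValueError("trajectory shorter than two burn-in windows")
    return burnin_from_rmsd(backbone_rmsd(traj), window, tol)


def burnin_fraction(n_frames: int, fraction: float = 0.05) -> int:
    """Fixed-fraction burn-in (default 5% of frames), used when RMSD
    detection is not requested."""
    if not 0 <= fraction < 1:
        raise ValueError("fraction must be in [0, 1)")
    return int(np.ceil(n_frames * fraction))


# ---------------------------------------------------------------------------
# distance statistics

_KIND_ATOMS = {"alpha-alpha": ("CA", "CA"), "alpha-beta": ("CA", "CB"),
               "beta-beta": ("CB", "CB")}


def distance_stats_from_positions(pi, pj, i: int, j: int, kind: str) -> DistanceStats:
    """Mean/variance of |pi - pj| over frames; positions are (n, 3) in nm."""
    d = np.linalg.norm(np.asarray(pi, float) - np.asarray(pj, float), axis=-1)
    return DistanceStats(i=i, j=j, kind=kind, mean_nm=float(d.mean()),
                         var_nm2=float(d.var()), n_frames=d.size)


def distance_stats(traj: Trajectory, i: int, j: int, kind: str,
                   start: int = 0) -> DistanceStats:
    """Inter-residue distance statistics over post-burn-in frames.

    kind selects the atoms: alpha-alpha -> CA_i/CA_j, alpha-beta ->
    CA_i/CB_j, beta-beta -> CB_i/CB_j.  Glycine lacks CB, so beta kinds
    raise MissingAtomError for it.
    """
    if kind not in _KIND_ATOMS:
        raise ValueError(f"unknown kind {kind!r}; expected one of {sorted(_KIND_ATOMS)}")
    ai, aj = _KIND_ATOMS[kind]
    st = traj.structure
    ki, kj = st.atom_index(i, ai), st.atom_index(j, aj)
    return distance_stats_from_positions(traj.coords[start:, ki],
                                         traj.coords[start:, kj], i, j, kind)


# ---------------------------------------------------------------------------
# readers / writers

def load_structure(pdb_path) -> Structure:
    """Read a PDB file into a Structure (coordinates converted A -> nm)."""
    import MDAnalysis as mda

    u = mda.Universe(str(pdb_path))
    ag = u.atoms
    try:
        elements = ag.elements.astype(str)
    except Exception:
        elements = np.array([n[0] for n in ag.names])
    try:
        chains = ag.chainIDs.astype(str)
    except Exception:
        chains = np.array(["A"] * len(ag))
    return Structure(names=ag.names.astype(str), elements=elements,
                     resids=ag.resids.astype(int), resnames=ag.resnames.astype(str),
                     chains=chains, coords=ag.positions.astype(float) / 10.0)


def load_trajectory(topology, coordinates=None, dt_ns: float | None = None) -> Trajectory:
    """Read topology (PDB) plus coordinates (DCD/XTC/PDB) into a Trajectory.

    dt_ns overrides the frame spacing when the file lacks reliable times.
    """
    import MDAnalysis as mda

    u = mda.Universe(str(topology)) if coordinates is None \
        else mda.Universe(str(topology), str(coordinates))
    structure = load_structure(topology)
    n = len(u.trajectory)
    coords = np.empty((n, len(u.atoms), 3))
    times_ps = np.empty(n)
    for k, ts in enumerate(u.trajectory):
        coords[k] = u.atoms.positions / 10.0
        times_ps[k] = ts.time
    if dt_ns is not None:
        times = np.arange(n) * dt_ns
    else:
        times = times_ps / 1000.0
        if n >= 2 and np.ptp(np.diff(times)) > 1e-9:
            raise ValueError("non-uniform frame times; pass dt_ns explicitly")
        if n >= 2 and times[1] == times[0]:
            raise ValueError("file carries no frame times; pass dt_ns")
    return Trajectory(structure=structure, times=times, coords=coords)


def series_filename(residue: int, dof: str) -> str:
    return f"res{residue}_{dof}.tsv"


def write_angle_series(directory, series) -> list[Path]:
    """Write AngleSeries objects as res<idx>_<dof>.tsv (columns time_ns, value_deg)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = []
    for s in series:
        p = directory / series_filename(s.residue, s.dof)
        pd.DataFrame({"time_ns": s.times, "value_deg": s.angles}).to_csv(
            p, sep="\t", index=False, float_format="%.8g")
        paths.append(p)
    return paths


def read_angle_series(path) -> AngleSeries:
    """Read one res<idx>_<dof>.tsv file back into an AngleSeries."""
    path = Path(path)
    stem = path.stem
    if not stem.startswith("res") or "_" not in stem:
        raise ValueError(f"cannot parse residue/dof from filename {path.name!r}")
    res_part, dof = stem.split("_", 1)
    df = pd.read_csv(path, sep="\t")
    return AngleSeries(residue=int(res_part[3:]), dof=dof,
                       times=df["time_ns"].to_numpy(),
                       angles=df["value_deg"].to_numpy())


def read_series_dir(directory) -> dict:
    """Read every res*_*.tsv in a directory, keyed by (residue, dof)."""
    out = {}
    for p in sorted(Path(directory).glob("res*_*.tsv")):
        s = read_angle_series(p)
        out[s.key] = s
    return out


def write_distance_stats(path, stats) -> Path:
    path = Path(path)
    rows = [{"i": s.i, "j": s.j, "kind": s.kind, "mean_nm": s.mean_nm,
             "var_nm2": s.var_nm2, "n_frames": s.n_frames} for s in stats]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, float_format="%.8g")
    return path
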