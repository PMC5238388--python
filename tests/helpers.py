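"""Shared builders for geometric test fixtures (all generated in memory)."""

import numpy as np

from tdca.trajio import Structure, Trajectory


def rotation_about_axis(axis, angle_deg):
    from scipy.spatial.transform import Rotation

    axis = np.asarray(axis, dtype=float)
    return Rotation.from_rotvec(np.radians(angle_deg) * axis / np.linalg.norm(axis))


def make_structure(atom_rows):
    """Structure from rows of (name, resid, resname, xyz)."""
    names, resids, resnames, coords = [], [], [], []
    for name, resid, resname, xyz in atom_rows:
        names.append(name)
        resids.append(resid)
        resnames.append(resname)
        coords.append(xyz)
    n = len(names)
    return Structure(names=np.array(names), elements=np.array([s[0] for s in names]),
                     resids=np.array(resids), resnames=np.array(resnames),
                     chains=np.array(["A"] * n), coords=np.array(coords, dtype=float))


def tripeptide_structure(phi2_deg=0.0):
    """Minimal 3-residue backbone (plus a chi1-capable residue 2).

    Residue 2's C atom is placed so that phi(res2) equals ``phi2_deg``
    exactly, using the construction p1=(d,0,0), p2=0, p3=(0,d,0),
    p4=d*(cos g, 1, sin g) whose dihedral is -g in the clockwise-positive
    (IUPAC) convention.
    """
    d = 0.15
    g = -np.radians(phi2_deg)
    rows = [
        ("N", 1, "ALA", (0.5, 0.1, 0.4)),
        ("CA", 1, "ALA", (0.4, 0.1, 0.3)),
        ("C", 1, "ALA", (d, 0.0, 0.0)),      # p1 of phi2
        ("N", 2, "LEU", (0.0, 0.0, 0.0)),    # p2
        ("CA", 2, "LEU", (0.0, d, 0.0)),     # p3
        ("CB", 2, "LEU", (0.11, d + 0.05, 0.05)),
        ("CG", 2, "LEU", (0.20, d + 0.12, 0.02)),
        ("C", 2, "LEU", (d * np.cos(g), d, d * np.sin(g))),  # p4
        ("N", 3, "GLY", (0.3, 0.35, 0.1)),
        ("CA", 3, "GLY", (0.42, 0.42, 0.1)),
        ("C", 3, "GLY", (0.55, 0.40, 0.2)),
    ]
    return make_structure(rows)


def phi_rotation_trajectory(increments_deg, dt_ns=0.1):
    """Frames in which residue 2's phi steps through known increments."""
    frames = [tripeptide_structure(g).coords for g in increments_deg]
    st = tripeptide_structure(0.0)
    return Trajectory(structure=st, times=np.arange(len(frames)) * dt_ns,
                      coords=np.array(frames))


def static_trajectory(structure, n_frames=5, dt_ns=0.1):
    coords = np.repeat(structure.coords[None, :, :], n_frames, axis=0)
    return Trajectory(structure=structure, times=np.arange(n_frames) * dt_ns,
                      coords=coords)


def two_atom_trajectory(separations_nm, dt_ns=0.1):
    """Two CA-only residues on the x axis at given per-frame separations."""
    st = make_structure([("CA", 1, "ALA", (0.0, 0.0, 0.0)),
                         ("CA", 2, "ALA", (float(separations_nm[0]), 0.0, 0.0))])
    n = len(separations_nm)
    coords = np.zeros((n, 2, 3))
    coords[:, 1, 0] = separations_nm
    return Trajectory(structure=st, times=np.arange(n) * dt_ns, coords=coords)
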