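"""Geometric kernels for the per-frame observables.

These are the receptor-specific measurements used downstream: minimum
heavy-atom contact distances between chemically equivalent atom sets
(carboxylate oxygen pairs, amine nitrogens), signed side-chain torsions,
helix rotation measured as an XY-plane angle, and vertical (membrane-normal)
displacement.  All functions assume coordinates in Å; frames passed to the
frame-level helpers must already be superposed onto the reference.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
from scipy.spatial.distance import cdist

from .traj import Frame, ResidueMap

#: Atom sets for the chemical groups named by the observables.  Carboxylates
#: contribute both oxygens; distances take the minimum over equivalent atoms.
GROUP_ATOMS = {
    "ASP_carboxylate": ("OD1", "OD2"),
    "GLU_carboxylate": ("OE1", "OE2"),
    "THR_hydroxyl": ("OG1",),
    "LYS_amine": ("NZ",),
    "TRP_ring": ("CG", "CD1", "CD2", "NE1", "CE2", "CE3", "CZ2", "CZ3", "CH2"),
    "GLN_dihedral": ("C", "CA", "CG", "CD"),
}


class DegenerateGeometryError(ValueError):
    """Raised when input points cannot define the requested quantity."""


def min_pair_distance(set_a: np.ndarray, set_b: np.ndarray) -> float:
    """Minimum Euclidean distance over all pairs between two point sets (Å)."""
    a = np.atleast_2d(np.asarray(set_a, dtype=float))
    b = np.atleast_2d(np.asarray(set_b, dtype=float))
    if a.size == 0 or b.size == 0:
        raise ValueError("point sets must be non-empty")
    return float(cdist(a, b).min())


def dihedral(p1, p2, p3, p4) -> float:
    """Signed torsion angle (degrees, in (−180, +180]) of four points.

    IUPAC sign convention: looking down the p2→p3 axis, positive when the far
    bond is rotated clockwise from the near bond.
    """
    p1, p2, p3, p4 = (np.asarray(p, dtype=float) for p in (p1, p2, p3, p4))
    b1 = p2 - p1
    b2 = p3 - p2
    b3 = p4 - p3
    if np.linalg.norm(b2) < 1e-10:
        raise DegenerateGeometryError("central axis points are coincident")
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    if np.linalg.norm(n1) < 1e-10 or np.linalg.norm(n2) < 1e-10:
        raise DegenerateGeometryError("collinear points leave the torsion undefined")
    x = n1 @ n2
    y = np.cross(n1, n2) @ (b2 / np.linalg.norm(b2))
    ang = float(np.degrees(np.arctan2(y, x)))
    return 180.0 if np.isclose(ang, -180.0) else ang


def signed_xy_angle(v_ref: np.ndarray, v_frame: np.ndarray) -> float:
    """Signed angle (degrees) from ``v_ref`` to ``v_frame`` in the XY plane.

    Positive = counter-clockwise when viewed down the +z axis, i.e. from the
    extracellular side under the OPM convention.
    """
    v_ref = np.asarray(v_ref, dtype=float)[:2]
    v_frame = np.asarray(v_frame, dtype=float)[:2]
    if np.linalg.norm(v_ref) < 1e-10 or np.linalg.norm(v_frame) < 1e-10:
        raise DegenerateGeometryError("zero-length XY projection")
    cross = v_ref[0] * v_frame[1] - v_ref[1] * v_frame[0]
    dot = v_ref @ v_frame
    return float(np.degrees(np.arctan2(cross, dot)))


def xy_rotation_angle(
    frame: Frame,
    reference: Frame,
    rmap: ResidueMap,
    res_a: str = "7.47",
    res_b: str = "7.48",
    clockwise_positive: bool = False,
) -> float:
    """Helix rotation at ``res_a``: angle between frame and reference tangent vectors.

    The tangent is the XY difference of the Cα positions of ``res_a`` and
    ``res_b`` (consecutive helix residues).  The frame must already be
    superposed to the reference.  ``clockwise_positive`` flips the sign
    convention (default: counter-clockwise positive viewed from extracellular).
    """
    v_frame = rmap.resolve(res_b, "CA", frame) - rmap.resolve(res_a, "CA", frame)
    v_ref = rmap.resolve(res_b, "CA", reference) - rmap.resolve(res_a, "CA", reference)
    ang = signed_xy_angle(v_ref, v_frame)
    return -ang if clockwise_positive else ang


def z_displacement(
    frame: Frame,
    reference: Frame,
    rmap: ResidueMap,
    atom_selection: Sequence[tuple[str, str]],
) -> float:
    """Mean z of selected atoms in the frame minus the same in the reference (Å).

    ``atom_selection`` is a list of (BW code, atom name) pairs.  Negative values
    mean displacement toward the intracellular side.
    """
    if not atom_selection:
        raise ValueError("atom selection must be non-empty")
    z_f = np.mean([rmap.resolve(code, name, frame)[2] for code, name in atom_selection])
    z_r = np.mean([rmap.resolve(code, name, reference)[2] for code, name in atom_selection])
    return float(z_f - z_r)
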