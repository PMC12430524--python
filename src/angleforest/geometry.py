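"""Backbone geometry: torsion angles, phi/psi extraction, chain building,
and optimal superposition.

Sign convention for torsions is the IUPAC one: cis = 0, trans = 180, the
sign given by the right-hand rule about the central bond.  All angles are
degrees in (-180, 180].
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .circular import wrap_angle
from .ensembles import FrameSet, phi_psi_feature_names

__all__ = [
    "torsion_angle",
    "extract_phi_psi",
    "build_backbone_from_torsions",
    "kabsch_rmsd",
    "PEPTIDE_GEOMETRY",
]

# Standard trans-peptide geometry (Engh & Huber averages), Angstrom / degrees.
PEPTIDE_GEOMETRY = {
    "bond_N_CA": 1.458,
    "bond_CA_C": 1.525,
    "bond_C_N": 1.329,
    "angle_N_CA_C": 111.2,
    "angle_CA_C_N": 116.2,
    "angle_C_N_CA": 121.7,
    "omega": 180.0,
}

_COLLINEAR_EPS = 1e-10


def _torsion_batch(p1, p2, p3, p4):
    """Vectorized signed dihedral (degrees) for stacked point quadruples."""
    b1 = np.asarray(p2, float) - np.asarray(p1, float)
    b2 = np.asarray(p3, float) - np.asarray(p2, float)
    b3 = np.asarray(p4, float) - np.asarray(p3, float)
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    n1_norm = np.linalg.norm(n1, axis=-1)
    n2_norm = np.linalg.norm(n2, axis=-1)
    b2_norm = np.linalg.norm(b2, axis=-1)
    scale = (np.linalg.norm(b1, axis=-1) * b2_norm,
             b2_norm * np.linalg.norm(b3, axis=-1))
    if np.any(b2_norm < _COLLINEAR_EPS) or \
            np.any(n1_norm < _COLLINEAR_EPS * np.maximum(scale[0], 1.0)) or \
            np.any(n2_norm < _COLLINEAR_EPS * np.maximum(scale[1], 1.0)):
        raise ValueError(
            "torsion undefined: three consecutive points are (near-)collinear")
    b2_hat = b2 / b2_norm[..., None]
    x = np.sum(n1 * n2, axis=-1)
    y = np.sum(np.cross(n1, n2) * b2_hat, axis=-1)
    return wrap_angle(np.rad2deg(np.arctan2(y, x)))


def torsion_angle(p1, p2, p3, p4) -> float:
    """Signed dihedral angle of four 3-D points, degrees in (-180, 180].

    Raises ValueError if either plane is undefined (collinear points).
    """
    return float(_torsion_batch(p1, p2, p3, p4))


def extract_phi_psi(frames, residue_ids=None) -> pd.DataFrame:
    """Backbone phi/psi angles for every frame of a coordinate set.

    phi(i) = torsion(C(i-1), N(i), CA(i), C(i)) for residues 2..N and
    psi(i) = torsion(N(i), CA(i), C(i), N(i+1)) for residues 1..N-1, giving
    2N - 2 features named by biological residue number (phi columns first).

    Parameters
    ----------
    frames : FrameSet or np.ndarray
        Either a FrameSet with coordinates, or an array of shape
        (n_frames, n_residues, 3, 3) / (n_residues, 3, 3).
    residue_ids : sequence of int, optional
        Residue numbers for feature naming (required for bare arrays).
    """
    if isinstance(frames, FrameSet):
        if frames.coords is None:
            raise ValueError("FrameSet has no coordinates to extract from")
        coords = frames.coords
        residue_ids = frames.residue_ids
    else:
        coords = np.asarray(frames, dtype=float)
        if coords.ndim == 3:
            coords = coords[None]
        if residue_ids is None:
            residue_ids = np.arange(1, coords.shape[1] + 1)
    n_res = coords.shape[1]
    if len(residue_ids) != n_res:
        raise ValueError("residue_ids length does not match coordinates")
    if n_res < 2:
        raise ValueError("need at least 2 residues for any backbone torsion")
    N, CA, C = coords[:, :, 0], coords[:, :, 1], coords[:, :, 2]
    try:
        phi = _torsion_batch(C[:, :-1], N[:, 1:], CA[:, 1:], C[:, 1:])
        psi = _torsion_batch(N[:, :-1], CA[:, :-1], C[:, :-1], N[:, 1:])
    except ValueError as err:
        raise ValueError(f"degenerate backbone geometry: {err}") from err
    data = np.concatenate([phi, psi], axis=1)
    return pd.DataFrame(data, columns=phi_psi_feature_names(residue_ids))


def _place_atom(a, b, c, bond, angle_deg, torsion_deg):
    """NeRF extension: position of atom D from A-B-C internal coordinates."""
    theta = np.deg2rad(angle_deg)
    chi = np.deg2rad(torsion_deg)
    bc = c - b
    bc_hat = bc / np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc_hat)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc_hat)
    d = (-np.cos(theta) * bc_hat
         + np.sin(theta) * np.cos(chi) * m
         + np.sin(theta) * np.sin(chi) * n)
    return c + bond * d


def build_backbone_from_torsions(phi, psi, geometry=None) -> np.ndarray:
    """Build N/CA/C coordinates of a chain realizing the given phi/psi.

    ``phi`` has one value per residue 2..N and ``psi`` one per residue
    1..N-1 (a single concatenated vector of length 2N - 2, phi block first,
    is also accepted with ``psi=None``).  Bond lengths/angles come from
    ``geometry`` (default standard trans-peptide values, omega frozen at
    180).  Recomputing phi/psi from the returned coordinates reproduces the
    inputs to numerical precision, which makes this the round-trip fixture
    for the torsion extractor.

    Returns an array of shape (n_residues, 3, 3) (N, CA, C per residue).
    """
    if psi is None:
        vec = np.asarray(phi, dtype=float)
        if vec.size % 2 != 0:
            raise ValueError("concatenated phi/psi vector must have even length")
        half = vec.size // 2
        phi, psi = vec[:half], vec[half:]
    phi = np.asarray(phi, dtype=float)
    psi = np.asarray(psi, dtype=float)
    if phi.size != psi.size:
        raise ValueError("phi (residues 2..N) and psi (1..N-1) must have equal length")
    n_res = phi.size + 1
    if n_res < 2:
        raise ValueError("chain must have at least 2 residues")
    geo = dict(PEPTIDE_GEOMETRY)
    if geometry:
        geo.update(geometry)

    coords = np.empty((n_res, 3, 3), dtype=float)
    # seed the first residue in the xy-plane
    coords[0, 0] = np.array([0.0, 0.0, 0.0])                      # N1
    coords[0, 1] = np.array([geo["bond_N_CA"], 0.0, 0.0])         # CA1
    ang = np.deg2rad(geo["angle_N_CA_C"])
    coords[0, 2] = coords[0, 1] + geo["bond_CA_C"] * np.array(
        [-np.cos(ang), np.sin(ang), 0.0])                          # C1
    for i in range(1, n_res):
        n_prev, ca_prev, c_prev = coords[i - 1]
        n_i = _place_atom(n_prev, ca_prev, c_prev,
                          geo["bond_C_N"], geo["angle_CA_C_N"], psi[i - 1])
        ca_i = _place_atom(ca_prev, c_prev, n_i,
                           geo["bond_N_CA"], geo["angle_C_N_CA"], geo["omega"])
        c_i = _place_atom(c_prev, n_i, ca_i,
                          geo["bond_CA_C"], geo["angle_N_CA_C"], phi[i - 1])
        coords[i] = (n_i, ca_i, c_i)
    return coords


def kabsch_rmsd(X, Y):
    """Optimal superposition of two matched point sets (Kabsch).

    Removes centroids, finds the proper rotation (det = +1) minimizing the
    least-squares deviation via SVD of the covariance, and returns
    ``(rotation, rmsd)`` where ``rotation @ (X - centroid_X)`` superposes X
    onto centered Y.

    Raises ValueError for fewer than 3 points or (near-)collinear
    configurations, where the optimal rotation is not unique.
    """
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if X.shape != Y.shape or X.ndim != 2 or X.shape[1] != 3:
        raise ValueError("X and Y must be matched (n, 3) coordinate sets")
    n = X.shape[0]
    if n < 3:
        raise ValueError("superposition needs at least 3 points")
    Xc = X - X.mean(axis=0)
    Yc = Y - Y.mean(axis=0)
    scale = max(np.abs(Xc).max(), np.abs(Yc).max(), 1e-30)
    if np.linalg.matrix_rank(Xc, tol=1e-8 * scale) < 2 or \
            np.linalg.matrix_rank(Yc, tol=1e-8 * scale) < 2:
        raise ValueError("degenerate (collinear) configuration: rotation not unique")
    H = Xc.T @ Yc
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    diff = Xc @ R.T - Yc
    rmsd = float(np.sqrt(np.mean(np.sum(diff ** 2, axis=1))))
    return R, rmsd
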