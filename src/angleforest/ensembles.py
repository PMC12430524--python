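"""In-memory containers for per-variant conformational samples.

A :class:`FrameSet` holds the frames of one variant, either as backbone
coordinates (N, CA, C per residue) or as already-extracted phi/psi dihedral
vectors, together with per-frame trajectory provenance.  A
:class:`VariantEnsemble` additionally carries the variant's clinical label
for the drug under study ('S' sensitive, 'R' resistant, 'unknown').

Feature columns are named ``phi{resid}`` / ``psi{resid}`` using the
biological residue numbering of the chain (e.g. phi600 for the kinase
numbering of BRAF), phi columns first in ascending residue order, then psi.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

__all__ = [
    "FrameSet",
    "VariantEnsemble",
    "phi_psi_feature_names",
    "parse_feature_name",
    "canonical_feature_order",
]

_FEATURE_RE = re.compile(r"^(phi|psi)(-?\d+)$")


def phi_psi_feature_names(residue_ids) -> list[str]:
    """Feature names for a chain: phi for residues 2..N, psi for 1..N-1.

    Terminal residues lack one torsion each, so a chain of N residues
    yields 2N - 2 features.
    """
    residue_ids = list(residue_ids)
    if len(residue_ids) < 2:
        raise ValueError("a chain needs at least 2 residues to define torsions")
    phis = [f"phi{r}" for r in residue_ids[1:]]
    psis = [f"psi{r}" for r in residue_ids[:-1]]
    return phis + psis


def parse_feature_name(name: str) -> tuple[str, int]:
    """Split 'phi600' into ('phi', 600); raise on anything else."""
    m = _FEATURE_RE.match(name)
    if m is None:
        raise ValueError(f"not a phi/psi feature name: {name!r}")
    return m.group(1), int(m.group(2))


def canonical_feature_order(names) -> list[str]:
    """Sort feature names by residue number, phi before psi at equal residue.

    This is the deterministic tie-break order used whenever two features
    score identically in a tree split.
    """
    def key(n):
        kind, resid = parse_feature_name(n)
        return (resid, 0 if kind == "phi" else 1)

    return sorted(names, key=key)


@dataclass
class FrameSet:
    """Frames of one variant: coordinates and/or dihedral vectors.

    Parameters
    ----------
    variant : str
        Variant name (e.g. "V600E", "WT").
    residue_ids : np.ndarray
        Biological residue numbers of the chain, ascending.
    coords : np.ndarray, optional
        Backbone coordinates, shape (n_frames, n_residues, 3, 3): the third
        axis indexes the atoms N, CA, C; last axis is x/y/z in Angstrom.
    angles : pd.DataFrame, optional
        Frames x dihedral features in degrees, columns named phi{r}/psi{r}.
    traj_id : np.ndarray
        Trajectory index of each frame (0-based).
    frame_idx : np.ndarray
        Frame index of each frame within its trajectory (0-based, in the
        original, pre-retention numbering).
    """

    variant: str
    residue_ids: np.ndarray
    coords: Optional[np.ndarray] = None
    angles: Optional[pd.DataFrame] = None
    traj_id: np.ndarray = field(default=None)
    frame_idx: np.ndarray = field(default=None)

    def __post_init__(self):
        self.residue_ids = np.asarray(self.residue_ids, dtype=int)
        n = self.n_frames
        if self.traj_id is None:
            self.traj_id = np.zeros(n, dtype=int)
        else:
            self.traj_id = np.asarray(self.traj_id, dtype=int)
        if self.frame_idx is None:
            self.frame_idx = np.arange(n, dtype=int)
        else:
            self.frame_idx = np.asarray(self.frame_idx, dtype=int)
        if self.coords is not None:
            self.coords = np.asarray(self.coords, dtype=float)
            if self.coords.ndim != 4 or self.coords.shape[1:] != (
                len(self.residue_ids), 3, 3):
                raise ValueError(
                    "coords must have shape (n_frames, n_residues, 3, 3); "
                    f"got {self.coords.shape}")
            if not np.isfinite(self.coords).all():
                raise ValueError("non-finite coordinates in FrameSet")
        if self.angles is not None and list(self.angles.columns) != \
                phi_psi_feature_names(self.residue_ids):
            raise ValueError("angle columns do not match residue_ids")
        if len(self.traj_id) != n or len(self.frame_idx) != n:
            raise ValueError("traj_id/frame_idx length mismatch with frames")

    @property
    def n_frames(self) -> int:
        if self.coords is not None:
            return self.coords.shape[0]
        if self.angles is not None:
            return len(self.angles)
        return 0

    @property
    def n_residues(self) -> int:
        return len(self.residue_ids)

    def retained(self, retain_last: int, frames_per_trajectory: int) -> "FrameSet":
        """Keep only the final ``retain_last`` frames of each trajectory."""
        keep = self.frame_idx >= frames_per_trajectory - retain_last
        return self._subset(keep)

    def _subset(self, mask) -> "FrameSet":
        return type(self)(
            **{**self.__dict__,
               "coords": None if self.coords is None else self.coords[mask],
               "angles": None if self.angles is None
               else self.angles.loc[mask].reset_index(drop=True),
               "traj_id": self.traj_id[mask],
               "frame_idx": self.frame_idx[mask]},
        )


@dataclass
class VariantEnsemble(FrameSet):
    """A FrameSet with the variant's clinical drug-response label."""

    label: str = "unknown"

    def __post_init__(self):
        super().__post_init__()
        if self.label not in ("S", "R", "unknown"):
            raise ValueError(f"label must be 'S', 'R' or 'unknown': {self.label!r}")
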