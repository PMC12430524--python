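"""The frame-level data matrix: frames x named dihedral features.

This is the central object of the pipeline: one row per retained frame,
550 angle columns for a 276-residue chain, plus the variant name and its
drug-response status.  Rows with status 'unknown' never enter a training
matrix; :func:`build_data_matrix` returns them in a separate prediction
matrix.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["DihedralMatrix", "build_data_matrix"]

STATUS_TO_CLASS = {"S": 0, "R": 1}


@dataclass
class DihedralMatrix:
    """Frames x dihedral features with per-row variant/status/provenance.

    ``angles`` is a DataFrame in degrees (columns phi{r}/psi{r});
    ``variant``/``status`` are aligned Series; ``traj_id``/``frame_idx``
    record where each frame came from.  ``status`` values are 'S', 'R' or
    'unknown'; class codes are S=0, R=1.
    """

    angles: pd.DataFrame
    variant: pd.Series
    status: pd.Series
    traj_id: np.ndarray = field(default=None)
    frame_idx: np.ndarray = field(default=None)

    def __post_init__(self):
        n = len(self.angles)
        self.variant = pd.Series(np.asarray(self.variant), name="variant")
        self.status = pd.Series(np.asarray(self.status), name="status")
        if len(self.variant) != n or len(self.status) != n:
            raise ValueError("variant/status length mismatch with angle rows")
        bad = set(self.status.unique()) - {"S", "R", "unknown"}
        if bad:
            raise ValueError(f"invalid status values: {sorted(bad)}")
        if self.traj_id is None:
            self.traj_id = np.zeros(n, dtype=int)
        if self.frame_idx is None:
            self.frame_idx = np.arange(n, dtype=int)
        self.traj_id = np.asarray(self.traj_id, dtype=int)
        self.frame_idx = np.asarray(self.frame_idx, dtype=int)
        self.angles = self.angles.reset_index(drop=True)
        self.variant = self.variant.reset_index(drop=True)
        self.status = self.status.reset_index(drop=True)

    # -- basic properties -------------------------------------------------
    @property
    def n_rows(self) -> int:
        return len(self.angles)

    @property
    def feature_names(self) -> list[str]:
        return list(self.angles.columns)

    @property
    def variants(self) -> list[str]:
        return list(pd.unique(self.variant))

    @property
    def y(self) -> np.ndarray:
        """Class codes (S=0, R=1); raises if any row is 'unknown'."""
        if (self.status == "unknown").any():
            raise ValueError("matrix contains unlabeled rows; no class codes")
        return self.status.map(STATUS_TO_CLASS).to_numpy(dtype=int)

    # -- views ------------------------------------------------------------
    def subset_rows(self, mask) -> "DihedralMatrix":
        mask = np.asarray(mask)
        return DihedralMatrix(
            angles=self.angles.loc[mask],
            variant=self.variant.loc[mask],
            status=self.status.loc[mask],
            traj_id=self.traj_id[mask],
            frame_idx=self.frame_idx[mask],
        )

    def select_variants(self, names) -> "DihedralMatrix":
        return self.subset_rows(self.variant.isin(list(names)).to_numpy())

    def drop_variants(self, names) -> "DihedralMatrix":
        return self.subset_rows(~self.variant.isin(list(names)).to_numpy())

    def frame_window(self, start: int, stop: int) -> "DihedralMatrix":
        """Rows whose original frame index lies in [start, stop)."""
        return self.subset_rows((self.frame_idx >= start) & (self.frame_idx < stop))

    def X(self, features=None) -> np.ndarray:
        cols = self.feature_names if features is None else list(features)
        missing = set(cols) - set(self.angles.columns)
        if missing:
            raise KeyError(f"unknown features: {sorted(missing)}")
        return self.angles[cols].to_numpy(dtype=float)

    def variant_labels(self) -> dict[str, str]:
        """Variant -> status map (one status per variant, validated)."""
        out = {}
        for v, grp in self.status.groupby(self.variant, sort=False):
            statuses = set(grp)
            if len(statuses) != 1:
                raise ValueError(f"variant {v} carries conflicting statuses")
            out[v] = statuses.pop()
        return out

    def to_frame(self) -> pd.DataFrame:
        """Angle columns plus trailing status and variant columns."""
        return pd.concat(
            [self.angles,
             self.status.rename("resistance_status"),
             self.variant.rename("variant")],
            axis=1,
        )


def build_data_matrix(ensembles, labels, drug,
                      retain_last=None, frames_per_trajectory=None):
    """Assemble the training and prediction matrices for one drug.

    Parameters
    ----------
    ensembles : list of FrameSet / VariantEnsemble
        Must carry angles (extract first if they hold coordinates).
    labels : pd.DataFrame
        Label table with columns variant/drug/status.
    drug : str
        Which drug's labels to use.
    retain_last, frames_per_trajectory : int, optional
        If given, apply the retention rule (keep the final ``retain_last``
        frames of each trajectory) to raw-length inputs before assembly.

    Returns
    -------
    (known, unknown) : tuple of DihedralMatrix
        Frames of variants with an S/R label, and frames of
        unknown-status variants kept apart for later prediction
        (``unknown`` may be empty).
    """
    table = labels[labels["drug"] == drug]
    if table["variant"].duplicated().any():
        dups = sorted(table.loc[table["variant"].duplicated(), "variant"])
        raise ValueError(f"duplicate variants in label table for {drug}: {dups}")
    status_of = dict(zip(table["variant"], table["status"]))

    names = [e.variant for e in ensembles]
    if len(set(names)) != len(names):
        raise ValueError("duplicate variant names among ensembles")
    missing = [n for n in names if n not in status_of]
    if missing:
        raise ValueError(f"label table has no entry for {drug}: {missing}")

    known_items, unknown_items = [], []
    for ens in ensembles:
        if ens.angles is None:
            raise ValueError(
                f"ensemble {ens.variant} has no angles; run extract_phi_psi first")
        fs = ens
        if retain_last is not None:
            if frames_per_trajectory is None:
                raise ValueError("retention needs frames_per_trajectory")
            fs = fs.retained(retain_last, frames_per_trajectory)
        status = status_of[ens.variant]
        (known_items if status in ("S", "R") else unknown_items).append((fs, status))

    def assemble(items):
        if not items:
            return DihedralMatrix(
                angles=pd.DataFrame(columns=ensembles[0].angles.columns),
                variant=pd.Series([], dtype=object),
                status=pd.Series([], dtype=object))
        return DihedralMatrix(
            angles=pd.concat([fs.angles for fs, _ in items], ignore_index=True),
            variant=np.concatenate(
                [np.repeat(fs.variant, fs.n_frames) for fs, _ in items]),
            status=np.concatenate(
                [np.repeat(st, fs.n_frames) for fs, st in items]),
            traj_id=np.concatenate([fs.traj_id for fs, _ in items]),
            frame_idx=np.concatenate([fs.frame_idx for fs, _ in items]),
        )

    known = assemble(known_items)
    unknown = assemble(unknown_items)
    return known, unknown
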