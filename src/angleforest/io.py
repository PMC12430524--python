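"""File formats: multi-model PDB ensembles, angle-matrix TSV, label tables.

Conventions (normative for this package):

* PDB: one MODEL per frame, backbone atoms N/CA/C of a single protein
  chain; biological residue numbering is authoritative for feature names.
* Angle TSV: tab-separated, one row per frame, angle columns named
  phi{resid}/psi{resid} in degrees; matrices additionally carry trailing
  ``resistance_status`` and ``variant`` columns.
* Label table TSV: columns ``variant``, ``drug``, ``status`` with status
  in {S, R, unknown}.

Angle payloads are written with 6 decimal places; write-then-read
round-trips are exact at that precision.
"""

from __future__ import annotations

import re
from pathlib import Path

import numpy as np
import pandas as pd
import biotite.structure as struc
from biotite.structure.io.pdb import PDBFile

from .ensembles import FrameSet, phi_psi_feature_names
from .matrix import DihedralMatrix

__all__ = [
    "read_ensemble",
    "write_ensemble_pdb",
    "write_angles_tsv",
    "write_matrix",
    "read_matrix",
    "read_label_table",
    "write_label_table",
]

ANGLE_PRECISION = 6
_BACKBONE = ("N", "CA", "C")


def read_ensemble(path, fmt=None, variant=None) -> FrameSet:
    """Read a conformational ensemble from multi-model PDB or angle TSV.

    ``fmt`` is 'pdb' or 'tsv'; inferred from the file extension when
    omitted.  ``variant`` defaults to the file stem.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if fmt is None:
        fmt = "pdb" if path.suffix.lower() in (".pdb", ".ent") else \
              "tsv" if path.suffix.lower() in (".tsv", ".csv", ".txt") else None
    if fmt not in ("pdb", "tsv"):
        raise ValueError(f"unrecognized ensemble format for {path.name}")
    variant = variant or path.stem
    if fmt == "pdb":
        return _read_pdb_ensemble(path, variant)
    return _read_tsv_ensemble(path, variant)


def _read_pdb_ensemble(path, variant) -> FrameSet:
    pdb = PDBFile.read(str(path))
    try:
        stack = pdb.get_structure(model=None, altloc="occupancy")
    except Exception as err:  # unequal atom counts across models, bad records
        raise ValueError(
            f"{path.name}: inconsistent or malformed MODEL records ({err})"
        ) from err
    if isinstance(stack, struc.AtomArray):  # single-model file
        stack = struc.stack([stack])
    chains = np.unique(stack.chain_id)
    if len(chains) > 1:
        raise ValueError(
            f"{path.name}: multiple chains {list(chains)}; only single-chain "
            "ensembles are supported")
    mask = np.isin(stack.atom_name, _BACKBONE) & ~stack.hetero
    sub = stack[:, mask]
    res_ids = sub.res_id[:]
    unique_res = np.unique(res_ids)
    coords = np.empty((sub.stack_depth(), len(unique_res), 3, 3), dtype=float)
    for j, rid in enumerate(unique_res):
        for k, atom in enumerate(_BACKBONE):
            sel = (res_ids == rid) & (sub.atom_name == atom)
            n_hit = int(sel.sum())
            if n_hit == 0:
                raise ValueError(
                    f"{path.name}: residue {rid} is missing backbone atom "
                    f"{atom} (all models)")
            if n_hit > 1:
                raise ValueError(
                    f"{path.name}: residue {rid} has {n_hit} copies of atom "
                    f"{atom}")
            coords[:, j, k] = sub.coord[:, sel, :][:, 0, :]
    if not np.isfinite(coords).all():
        raise ValueError(f"{path.name}: non-finite coordinates")
    return FrameSet(variant=variant, residue_ids=unique_res, coords=coords)


_ANGLE_COL = re.compile(r"^(phi|psi)-?\d+$")


def _read_tsv_ensemble(path, variant) -> FrameSet:
    df = pd.read_csv(path, sep="\t")
    angle_cols = [c for c in df.columns if _ANGLE_COL.match(c)]
    if not angle_cols:
        raise ValueError(f"{path.name}: no phi/psi angle columns found")
    # a complete feature set for residues first..last is phi(first+1..last)
    # plus psi(first..last-1); recover the residue range from the names
    ids = sorted({int(c[3:]) for c in angle_cols})
    for first in (ids[0], ids[0] - 1):
        for last in (ids[-1], ids[-1] + 1):
            rr = np.arange(first, last + 1)
            if len(rr) >= 2 and set(phi_psi_feature_names(rr)) == set(angle_cols):
                angles = df[phi_psi_feature_names(rr)].astype(float)
                traj = df["traj_id"].to_numpy(int) if "traj_id" in df else None
                fidx = df["frame_idx"].to_numpy(int) if "frame_idx" in df else None
                return FrameSet(variant=variant, residue_ids=rr,
                                angles=angles, traj_id=traj, frame_idx=fidx)
    raise ValueError(
        f"{path.name}: angle columns do not form a contiguous phi/psi set")


def write_ensemble_pdb(frames: FrameSet, path):
    """Write backbone coordinates as a multi-model PDB (one MODEL per frame)."""
    if frames.coords is None:
        raise ValueError("FrameSet has no coordinates to write")
    n_frames, n_res = frames.coords.shape[:2]
    n_atoms = n_res * 3
    template = struc.AtomArray(n_atoms)
    template.chain_id = np.full(n_atoms, "A")
    template.res_id = np.repeat(frames.residue_ids, 3)
    template.res_name = np.full(n_atoms, "ALA")
    template.atom_name = np.tile(np.array(_BACKBONE), n_res)
    template.element = np.tile(np.array(["N", "C", "C"]), n_res)
    template.hetero = np.zeros(n_atoms, dtype=bool)
    stack = struc.stack([template] * n_frames)
    stack.coord = frames.coords.reshape(n_frames, n_atoms, 3)
    pdb = PDBFile()
    pdb.set_structure(stack)
    pdb.write(str(path))


def write_angles_tsv(frames: FrameSet, path):
    """Write a FrameSet's angle payload (plus provenance columns) as TSV."""
    if frames.angles is None:
        raise ValueError("FrameSet has no angles to write")
    df = frames.angles.round(ANGLE_PRECISION).copy()
    df["traj_id"] = frames.traj_id
    df["frame_idx"] = frames.frame_idx
    df.to_csv(path, sep="\t", index=False,
              float_format=f"%.{ANGLE_PRECISION}f")


def write_matrix(matrix: DihedralMatrix, path):
    """Write a data matrix as TSV: angle columns + resistance_status + variant.

    For the 276-residue study design this yields exactly 552 columns.
    """
    if matrix.n_rows == 0:
        raise ValueError("refusing to write an empty matrix")
    matrix.to_frame().to_csv(path, sep="\t", index=False,
                             float_format=f"%.{ANGLE_PRECISION}f")


def read_matrix(path) -> DihedralMatrix:
    """Read a matrix written by :func:`write_matrix`."""
    df = pd.read_csv(path, sep="\t")
    for col in ("resistance_status", "variant"):
        if col not in df.columns:
            raise ValueError(f"{Path(path).name}: missing column {col!r}")
    angle_cols = [c for c in df.columns if _ANGLE_COL.match(c)]
    return DihedralMatrix(
        angles=df[angle_cols].astype(float),
        variant=df["variant"],
        status=df["resistance_status"],
    )


def read_label_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    required = {"variant", "drug", "status"}
    if not required.issubset(df.columns):
        raise ValueError(f"label table must have columns {sorted(required)}")
    bad = set(df["status"]) - {"S", "R", "unknown"}
    if bad:
        raise ValueError(f"invalid status values in label table: {sorted(bad)}")
    return df


def write_label_table(labels: pd.DataFrame, path):
    labels.to_csv(path, sep="\t", index=False)
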