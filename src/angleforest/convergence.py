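"""Convergence diagnostics for conformational ensembles.

Three complementary checks that a sampled ensemble is equilibrated:

* RMSD plateau — the root-mean-square deviation to a reference frame
  (after Kabsch superposition) levels off once the structure stops
  drifting; :func:`rmsd_plateau` locates the earliest frame from which
  both the rolling slope and the rolling SD stay small.
* Ramachandran window agreement — the pooled 2-D (phi, psi) histogram of
  one frame window is compared to another via the Jensen-Shannon
  distance; stationary sampling gives near-zero distances.
* Selection stability — the tree-based feature selection is repeated on
  frame windows; a converged ensemble yields similar selected angle sets
  (high Jaccard overlap) across windows and against the full retention.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import jensenshannon

from .ensembles import FrameSet, parse_feature_name
from .geometry import kabsch_rmsd
from .matrix import DihedralMatrix
from .selection import iterative_selection

__all__ = [
    "kabsch_rmsd",
    "rmsd_series",
    "rmsd_plateau",
    "ramachandran_window_agreement",
    "windowed_selection_stability",
    "SelectionStabilityReport",
]


def rmsd_series(frames: FrameSet, reference: int = 0,
                atom: str = "CA") -> pd.DataFrame:
    """Per-frame RMSD (Angstrom) to a reference frame after superposition.

    Computed on CA atoms by default.  Returns columns traj_id, frame_idx,
    rmsd.
    """
    if frames.coords is None:
        raise ValueError("FrameSet has no coordinates")
    atom_idx = {"N": 0, "CA": 1, "C": 2}[atom]
    pts = frames.coords[:, :, atom_idx, :]
    ref = pts[reference]
    values = np.empty(len(pts))
    for i, p in enumerate(pts):
        _, values[i] = kabsch_rmsd(p, ref)
    return pd.DataFrame({"traj_id": frames.traj_id,
                         "frame_idx": frames.frame_idx,
                         "rmsd": values})


def rmsd_plateau(series, window: int = 500, slope_tol: float = 1e-4,
                 sd_tol: float = 0.15):
    """Earliest frame index from which an RMSD series has leveled off.

    The series is scanned with rolling windows of ``window`` frames; a
    window is quiet when the magnitude of its least-squares slope is below
    ``slope_tol`` (Angstrom/frame) and its SD is below ``sd_tol``
    (Angstrom).  The plateau starts at the earliest index such that every
    window from there to the end is quiet.  Returns None (with a warning)
    when the series is too short or never levels off.
    """
    if window < 2:
        raise ValueError("window must be at least 2")
    v = np.asarray(series, dtype=float)
    n = v.size
    if n < window:
        warnings.warn("series shorter than the rolling window; cannot assess")
        return None
    n_win = n - window + 1
    t = np.arange(window, dtype=float)
    t -= t.mean()
    denom = np.sum(t * t)
    # rolling mean / slope / sd via cumulative sums
    c1 = np.concatenate([[0.0], np.cumsum(v)])
    c2 = np.concatenate([[0.0], np.cumsum(v * v)])
    win_sum = c1[window:] - c1[:-window]
    win_sq = c2[window:] - c2[:-window]
    mean = win_sum / window
    var = np.maximum(win_sq / window - mean ** 2, 0.0)
    sd = np.sqrt(var)
    # slope: sum(t * v_window) / sum(t^2), computed by correlation
    tv = np.correlate(v, t, mode="valid")
    slope = tv / denom
    quiet = (np.abs(slope) < slope_tol) & (sd < sd_tol)
    if not quiet[-1]:
        return None
    # earliest start so that all windows from there on are quiet
    suffix_ok = np.flip(np.logical_and.accumulate(np.flip(quiet)))
    first = int(np.argmax(suffix_ok))
    if not suffix_ok[first]:
        return None
    return first


def _rama_hist(matrix: DihedralMatrix, rows, bin_width: float):
    """Pooled (phi, psi) histogram over all residues of the selected rows."""
    feats = matrix.feature_names
    by_resid = {}
    for f in feats:
        kind, resid = parse_feature_name(f)
        by_resid.setdefault(resid, {})[kind] = f
    pairs = [(v["phi"], v["psi"]) for v in by_resid.values()
             if "phi" in v and "psi" in v]
    if not pairs:
        raise ValueError("no residues with both phi and psi features")
    sub = matrix.subset_rows(rows)
    if sub.n_rows == 0:
        raise ValueError("empty frame window")
    phi = np.concatenate([sub.angles[p].to_numpy() for p, _ in pairs])
    psi = np.concatenate([sub.angles[s].to_numpy() for _, s in pairs])
    n_bins = int(round(360.0 / bin_width))
    edges = np.linspace(-180.0, 180.0, n_bins + 1)
    hist, _, _ = np.histogram2d(phi, psi, bins=[edges, edges])
    return hist.ravel() / hist.sum()


def ramachandran_window_agreement(matrix: DihedralMatrix, window_a,
                                  window_b, bin_width: float = 10.0) -> float:
    """Jensen-Shannon distance between two windows' Ramachandran histograms.

    ``window_a``/``window_b`` are (start, stop) original frame-index
    ranges (half-open) or boolean row masks.  Distance is in [0, 1]
    (base-2): 0 for identical distributions, 1 for disjoint support.
    """
    def rows_of(w):
        if isinstance(w, tuple):
            return (matrix.frame_idx >= w[0]) & (matrix.frame_idx < w[1])
        return np.asarray(w, dtype=bool)

    ra, rb = rows_of(window_a), rows_of(window_b)
    if isinstance(window_a, tuple) and isinstance(window_b, tuple) and \
            max(window_a[0], window_b[0]) < min(window_a[1], window_b[1]):
        warnings.warn("frame windows overlap")
    pa = _rama_hist(matrix, ra, bin_width)
    pb = _rama_hist(matrix, rb, bin_width)
    return float(jensenshannon(pa, pb, base=2))


@dataclass
class SelectionStabilityReport:
    windows: list[tuple]
    selected_per_window: list[list[str]]
    selected_full: list[str]
    jaccard_matrix: np.ndarray          # pairwise between windows
    jaccard_vs_full: list[float]

    def to_dict(self) -> dict:
        return {
            "windows": [list(w) for w in self.windows],
            "selected_per_window": self.selected_per_window,
            "selected_full": self.selected_full,
            "jaccard_matrix": self.jaccard_matrix.tolist(),
            "jaccard_vs_full": self.jaccard_vs_full,
        }


def _jaccard(a, b) -> float:
    a, b = set(a), set(b)
    if not a and not b:
        return 1.0
    return len(a & b) / len(a | b)


def windowed_selection_stability(matrix: DihedralMatrix, windows,
                                 n_rounds: int = 3, max_depth: int = 2,
                                 min_leaf: int = 5,
                                 min_rows: int = 50) -> SelectionStabilityReport:
    """Repeat feature selection per frame window and measure overlap.

    ``windows`` is a list of (start, stop) original frame-index ranges.
    Windows with fewer than ``min_rows`` usable rows are skipped with a
    warning.  Reports pairwise Jaccard overlap of the selected angle sets
    and each window's overlap with the full-retention selection.
    """
    if len(windows) < 2:
        raise ValueError("need at least 2 windows")
    kept, selections = [], []
    for w in windows:
        sub = matrix.frame_window(*w)
        if sub.n_rows < min_rows or len(set(sub.status)) < 2:
            warnings.warn(f"window {w}: too few frames or one class; skipped")
            continue
        sel = iterative_selection(sub, n_rounds=n_rounds, max_depth=max_depth,
                                  min_leaf=min_leaf)
        kept.append(w)
        selections.append(sel.all_selected)
    if len(kept) < 2:
        raise ValueError("fewer than 2 usable windows")
    full = iterative_selection(matrix, n_rounds=n_rounds, max_depth=max_depth,
                               min_leaf=min_leaf).all_selected
    m = len(kept)
    jac = np.ones((m, m))
    for i in range(m):
        for j in range(i + 1, m):
            jac[i, j] = jac[j, i] = _jaccard(selections[i], selections[j])
    return SelectionStabilityReport(
        windows=kept,
        selected_per_window=selections,
        selected_full=full,
        jaccard_matrix=jac,
        jaccard_vs_full=[_jaccard(s, full) for s in selections],
    )
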