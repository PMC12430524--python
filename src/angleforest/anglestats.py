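"""Per-angle differences between resistant and sensitive ensembles.

For every backbone dihedral, the circular mean over the sensitive frames
and over the resistant frames is computed; the wrapped signed difference,
a Welch two-sample t-test (on values unwrapped about the pooled circular
mean, so the linear test is meaningful for concentrated angular data),
and a magnitude gate flag angles whose group averages differ by more than
a threshold AND are statistically significant.

The magnitude threshold defaults to 15 degrees, the dispersion scale of
the wild-type reference ensemble; :func:`wt_threshold` recomputes that
scale from data as the mean over angles of the per-angle circular SD of
the wild-type frames.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .circular import (circular_mean, circular_sd_from_resultant,
                       unwrap_about, wrap_difference)
from .ensembles import parse_feature_name
from .matrix import DihedralMatrix

__all__ = ["wt_threshold", "group_angle_analysis", "profile_series",
           "DEFAULT_MAGNITUDE_THRESHOLD"]

#: Published dispersion scale of the wild-type reference ensemble, degrees.
DEFAULT_MAGNITUDE_THRESHOLD = 15.0


def wt_threshold(wt_matrix: DihedralMatrix) -> float:
    """Data-driven magnitude threshold from a reference (wild-type) ensemble.

    Per angle, the circular SD over the reference frames; then the mean of
    that dispersion across angles, in degrees.  If every angle has the
    same dispersion c, the threshold is c.
    """
    if wt_matrix.n_rows == 0:
        raise ValueError("reference ensemble is empty")
    if len(wt_matrix.feature_names) < 2:
        raise ValueError("dispersion across residues needs at least 2 angles")
    rad = np.deg2rad(wt_matrix.X())
    r = np.hypot(np.sin(rad).mean(axis=0), np.cos(rad).mean(axis=0))
    sds = circular_sd_from_resultant(r)
    return float(np.mean(sds))


def _class_circular_means(matrix, per_variant: bool):
    """Per-class circular means per angle, pooling frames or variant means."""
    out = {}
    for cls in ("S", "R"):
        sub = matrix.subset_rows((matrix.status == cls).to_numpy())
        if sub.n_rows == 0:
            raise ValueError(f"class {cls} absent from matrix")
        if per_variant:
            per_var = [circular_mean(sub.select_variants([v]).X(), axis=0)
                       for v in sub.variants]
            # circular mean of the per-variant mean directions
            rad = np.deg2rad(np.vstack(per_var))
            out[cls] = np.rad2deg(np.arctan2(np.sin(rad).mean(axis=0),
                                             np.cos(rad).mean(axis=0)))
        else:
            out[cls] = np.asarray(circular_mean(sub.X(), axis=0))
    return out


def group_angle_analysis(matrix: DihedralMatrix,
                         threshold: float = DEFAULT_MAGNITUDE_THRESHOLD,
                         alpha: float = 0.05,
                         bonferroni: bool = False,
                         per_variant_means: bool = False) -> pd.DataFrame:
    """Angle-difference table between the resistant and sensitive groups.

    Returns one row per dihedral with columns: feature, kind, resid,
    mean_S, mean_R, diff (wrapped signed R - S difference), t, p,
    significant (p below alpha, Bonferroni-adjusted if requested),
    exceeds (|diff| > threshold), and flag (both conditions).

    Frames are pooled within each class by default;
    ``per_variant_means=True`` averages per-variant mean angles instead.
    """
    means = _class_circular_means(matrix, per_variant_means)
    features = matrix.feature_names
    X = matrix.X()
    is_r = (matrix.status == "R").to_numpy()
    is_s = (matrix.status == "S").to_numpy()
    if not is_r.any() or not is_s.any():
        raise ValueError("both classes must be present")

    diff = wrap_difference(means["R"], means["S"])
    # Welch t-test on values unwrapped about the pooled circular mean
    pooled = circular_mean(X, axis=0)
    t_vals = np.empty(len(features))
    p_vals = np.empty(len(features))
    for j in range(len(features)):
        unwrapped = unwrap_about(X[:, j], pooled[j])
        t, p = stats.ttest_ind(unwrapped[is_r], unwrapped[is_s],
                               equal_var=False)
        t_vals[j], p_vals[j] = t, p
    alpha_eff = alpha / len(features) if bonferroni else alpha
    significant = p_vals < alpha_eff
    exceeds = np.abs(diff) > threshold

    kinds, resids = zip(*(parse_feature_name(f) for f in features))
    return pd.DataFrame({
        "feature": features,
        "kind": kinds,
        "resid": resids,
        "mean_S": means["S"],
        "mean_R": means["R"],
        "diff": diff,
        "t": t_vals,
        "p": p_vals,
        "significant": significant,
        "exceeds": exceeds,
        "flag": significant & exceeds,
    })


def profile_series(table: pd.DataFrame, kind: str) -> pd.DataFrame:
    """Residue-indexed difference profile for one torsion kind (phi or psi).

    The per-residue series underlying the classic paired difference plots.
    """
    if kind not in ("phi", "psi"):
        raise ValueError("kind must be 'phi' or 'psi'")
    sub = table[table["kind"] == kind].sort_values("resid")
    return sub[["resid", "diff", "p", "flag"]].reset_index(drop=True)
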