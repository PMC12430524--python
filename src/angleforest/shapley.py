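"""Exact interventional Shapley attribution for small-feature forests.

The selected feature sets of this pipeline hold at most a handful of
angles, so Shapley values can be computed by exhaustive coalition
enumeration rather than sampling.  The explained model output is the
continuous resistant-vote fraction of the forest: positive attributions
push toward the resistant class, negative toward sensitive.

The value of a coalition S for a frame x is the interventional
(background-marginal) expectation: features in S take x's values, the
rest are drawn from a background set of training frames, and the model
outputs are averaged over the background.  By construction the values
satisfy efficiency (base value + attributions = model output per frame),
symmetry, and the null-player axiom.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .forest import ForestModel
from .matrix import DihedralMatrix

__all__ = ["exact_shapley", "shap_summary", "ShapSummary"]

MAX_EXACT_FEATURES = 16


def _coalition_values(model: ForestModel, X: np.ndarray,
                      background: np.ndarray) -> np.ndarray:
    """v[c, i] = mean model output for frame i under coalition bitmask c."""
    k = len(model.features)
    n_rows = X.shape[0]
    n_bg = background.shape[0]
    values = np.empty((2 ** k, n_rows))
    for c in range(2 ** k):
        in_coalition = np.array([(c >> j) & 1 for j in range(k)], dtype=bool)
        # hybrid rows: (n_rows * n_bg, k); background varies fastest
        hybrid = np.repeat(X, n_bg, axis=0)
        bg_tiled = np.tile(background, (n_rows, 1))
        hybrid[:, ~in_coalition] = bg_tiled[:, ~in_coalition]
        out = model.vote_fraction(hybrid)
        values[c] = out.reshape(n_rows, n_bg).mean(axis=1)
    return values


def _shapley_from_values(values: np.ndarray, k: int) -> np.ndarray:
    """Shapley values per frame from the 2^k coalition value table."""
    n_rows = values.shape[1]
    phi = np.zeros((n_rows, k))
    fact = [math.factorial(i) for i in range(k + 1)]
    for c in range(2 ** k):
        size = bin(c).count("1")
        for j in range(k):
            if (c >> j) & 1:
                continue
            weight = fact[size] * fact[k - size - 1] / fact[k]
            phi[:, j] += weight * (values[c | (1 << j)] - values[c])
    return phi


def exact_shapley(model: ForestModel, frame, background):
    """Exact Shapley attribution of one frame's resistant-vote fraction.

    Parameters
    ----------
    model : ForestModel
    frame : 1-D array in the model's feature order.
    background : 2-D array of background frames (same feature order).

    Returns
    -------
    (phi, base) : (np.ndarray of shape (k,), float)
        Per-feature attributions and the base value (mean model output
        over the background); ``base + phi.sum()`` equals the model output
        for the frame.
    """
    k = len(model.features)
    if k > MAX_EXACT_FEATURES:
        raise ValueError(
            f"{k} features: exhaustive coalition enumeration is intractable "
            f"beyond {MAX_EXACT_FEATURES}; use a sampling approximation")
    background = np.atleast_2d(np.asarray(background, dtype=float))
    if background.shape[0] == 0:
        raise ValueError("background set is empty")
    X = np.atleast_2d(np.asarray(frame, dtype=float))
    values = _coalition_values(model, X, background)
    phi = _shapley_from_values(values, k)
    base = float(values[0, 0])
    return phi[0], base


@dataclass
class ShapSummary:
    """Per-frame, per-feature Shapley attributions with raw feature values."""

    features: list[str]
    shapley: np.ndarray        # (n_frames, k)
    raw: np.ndarray            # (n_frames, k) raw angle values
    base: float                # expected model output over the background
    output: np.ndarray         # (n_frames,) model output per frame

    def ranking(self) -> pd.DataFrame:
        """Features ranked by mean |Shapley| (descending)."""
        imp = np.abs(self.shapley).mean(axis=0)
        order = np.argsort(-imp, kind="stable")
        return pd.DataFrame({
            "feature": [self.features[i] for i in order],
            "mean_abs_shapley": imp[order],
        })

    def to_long_frame(self) -> pd.DataFrame:
        """(frame, feature, raw value, shapley) triples for beeswarm export."""
        n, k = self.shapley.shape
        return pd.DataFrame({
            "frame": np.repeat(np.arange(n), k),
            "feature": np.tile(np.array(self.features, dtype=object), n),
            "value": self.raw.ravel(),
            "shapley": self.shapley.ravel(),
        })


def shap_summary(model: ForestModel, matrix, background,
                 max_rows=None, seed: int = 0) -> ShapSummary:
    """Exact Shapley attributions for (a sample of) the matrix rows.

    ``background`` may be a DihedralMatrix or array; ``max_rows`` caps the
    number of attributed frames (sampled without replacement, seeded).
    Local accuracy holds for every attributed frame.
    """
    X = matrix.X(model.features) if isinstance(matrix, DihedralMatrix) \
        else np.atleast_2d(np.asarray(matrix, dtype=float))
    bg = background.X(model.features) \
        if isinstance(background, DihedralMatrix) \
        else np.atleast_2d(np.asarray(background, dtype=float))
    if max_rows is not None and X.shape[0] > max_rows:
        rng = np.random.default_rng(seed)
        rows = np.sort(rng.choice(X.shape[0], size=max_rows, replace=False))
        X = X[rows]
    k = len(model.features)
    if k > MAX_EXACT_FEATURES:
        raise ValueError("too many features for exact enumeration")
    values = _coalition_values(model, X, bg)
    phi = _shapley_from_values(values, k)
    return ShapSummary(features=list(model.features), shapley=phi, raw=X,
                       base=float(values[0, 0]),
                       output=model.vote_fraction(X))
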