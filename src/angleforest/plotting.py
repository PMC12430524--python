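"""Basic matplotlib renderings of the pipeline's result tables."""

from __future__ import annotations

import numpy as np

from .anglestats import profile_series
from .shapley import ShapSummary


def plot_shap_summary(summary: ShapSummary, ax=None):
    """Beeswarm-style scatter: one row per feature, x = Shapley value,
    color = raw angle value (red high, blue low)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(7, 0.6 * len(summary.features) + 1))
    rng = np.random.default_rng(0)
    order = summary.ranking()["feature"].tolist()[::-1]
    for i, feat in enumerate(order):
        j = summary.features.index(feat)
        y = i + rng.uniform(-0.25, 0.25, summary.shapley.shape[0])
        sc = ax.scatter(summary.shapley[:, j], y, c=summary.raw[:, j],
                        cmap="coolwarm", s=8, alpha=0.7)
    ax.set_yticks(range(len(order)), order)
    ax.axvline(0.0, color="grey", lw=0.8)
    ax.set_xlabel("Shapley value (toward resistant →)")
    cb = ax.figure.colorbar(sc, ax=ax)
    cb.set_label("angle value (deg)")
    return ax


def plot_angle_profiles(table, kind: str = "phi", ax=None):
    """Per-residue group-mean angle difference profile with flagged residues."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(8, 3))
    prof = profile_series(table, kind)
    ax.plot(prof["resid"], prof["diff"], lw=0.8, color="tab:blue")
    flagged = prof[prof["flag"]]
    ax.scatter(flagged["resid"], flagged["diff"], color="tab:red", s=18,
               zorder=3, label="flagged")
    ax.axhline(0.0, color="grey", lw=0.6)
    ax.set_xlabel("residue")
    ax.set_ylabel(f"mean {kind} difference R - S (deg)")
    if len(flagged):
        ax.legend()
    return ax
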