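"""Random-forest classification with leave-one-variant-out evaluation.

The forest is an ensemble of the package's own Gini trees fit on bootstrap
resamples of the training frames over a fixed (selected) feature list.
Per-frame prediction is the majority vote over trees; a variant-level call
is the majority vote over its frames.  Ties at either level go to the
sensitive class: a resistant call triggers clinical action and should
require a strict majority.

Leave-one-variant-out (LOVO) holds out every frame of one variant per
fold, which is what prevents frame-level leakage between training and
test ensembles of the same variant.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .ensembles import canonical_feature_order
from .matrix import DihedralMatrix
from .selection import DecisionTree, SelectionResult, fit_tree

__all__ = [
    "ForestModel",
    "VariantPrediction",
    "LovoResult",
    "train_forest",
    "predict_variant",
    "lovo_evaluate",
    "subset_comparison",
    "predict_unknowns",
    "permute_variant_labels",
    "permutation_null",
]


@dataclass
class ForestModel:
    """Bagged ensemble of decision trees over a fixed feature list."""

    trees: list[DecisionTree]
    features: list[str]
    seed: int

    @property
    def n_trees(self) -> int:
        return len(self.trees)

    def vote_fraction(self, X: np.ndarray) -> np.ndarray:
        """Fraction of trees voting resistant, per row of X.

        X columns must follow ``self.features``.  This is the continuous
        model output that Shapley attribution explains.
        """
        X = np.atleast_2d(np.asarray(X, dtype=float))
        votes = np.zeros(X.shape[0])
        for tree in self.trees:
            votes += tree.predict(X, self.features)
        return votes / self.n_trees

    def predict_frames(self, X: np.ndarray) -> np.ndarray:
        """Hard per-frame labels (0/1); vote ties go to sensitive (0)."""
        return (self.vote_fraction(X) > 0.5).astype(int)

    def predict_matrix(self, matrix: DihedralMatrix) -> np.ndarray:
        return self.predict_frames(matrix.X(self.features))


@dataclass
class VariantPrediction:
    """Frame votes of one variant aggregated to a variant-level call."""

    variant: str
    n_frames: int
    n_resistant_frames: int
    label: str                    # 'S' or 'R'
    vote_fraction: float          # majority share, in [0.5, 1]
    tie: bool = False

    @property
    def frame_fraction_resistant(self) -> float:
        return self.n_resistant_frames / self.n_frames


@dataclass
class LovoResult:
    """Per-variant leave-one-variant-out predictions and overall accuracy."""

    predictions: list[VariantPrediction]
    truth: dict[str, str]
    features: list[str]

    @property
    def accuracy(self) -> float:
        correct = sum(p.label == self.truth[p.variant] for p in self.predictions)
        return correct / len(self.predictions)

    def to_table(self) -> pd.DataFrame:
        """Variant / known status / prediction layout."""
        return pd.DataFrame(
            [{"variant": p.variant, "status": self.truth[p.variant],
              "prediction": p.label,
              "vote_fraction": round(p.vote_fraction, 4)}
             for p in self.predictions])


def train_forest(matrix: DihedralMatrix, features, n_trees: int = 100,
                 seed: int = 0, max_depth=None, min_leaf: int = 5,
                 bootstrap: bool = True) -> ForestModel:
    """Fit ``n_trees`` Gini trees on bootstrap resamples of the rows.

    With ``bootstrap=False`` and ``n_trees=1`` the forest degenerates to a
    single :func:`fit_tree` fit.  Reproducible for a fixed seed.
    """
    features = canonical_feature_order(features) if features else []
    if not features:
        raise ValueError("empty feature list")
    X = matrix.X(features)
    y = matrix.y
    if len(np.unique(y)) < 2:
        raise ValueError("training matrix contains a single class")
    depth = np.iinfo(np.int32).max if max_depth is None else max_depth
    rng = np.random.default_rng(seed)
    n = X.shape[0]
    trees = []
    for _ in range(n_trees):
        rows = rng.integers(0, n, n) if bootstrap else np.arange(n)
        trees.append(fit_tree((X[rows], y[rows], features),
                              max_depth=depth, min_leaf=min_leaf))
    return ForestModel(trees=trees, features=features, seed=seed)


def predict_variant(model: ForestModel, frames) -> VariantPrediction:
    """Aggregate a variant's frame votes into one variant-level call.

    ``frames`` is a DihedralMatrix (single variant) or an (n, k) array in
    the model's feature order.  An exact 50/50 frame split is called
    sensitive and flagged low-confidence.
    """
    if isinstance(frames, DihedralMatrix):
        variants = frames.variants
        if len(variants) != 1:
            raise ValueError(f"expected frames of one variant, got {variants}")
        name = variants[0]
        X = frames.X(model.features)
    else:
        name = "?"
        X = np.atleast_2d(np.asarray(frames, dtype=float))
    if X.shape[0] == 0:
        raise ValueError("no frames to predict")
    frame_labels = model.predict_frames(X)
    n = len(frame_labels)
    n_r = int(frame_labels.sum())
    tie = (2 * n_r == n)
    label = "R" if n_r > n - n_r else "S"
    vote = max(n_r, n - n_r) / n
    return VariantPrediction(variant=name, n_frames=n, n_resistant_frames=n_r,
                             label=label, vote_fraction=vote, tie=tie)


def lovo_evaluate(matrix: DihedralMatrix, features, n_trees: int = 100,
                  seed: int = 0, **forest_kwargs) -> LovoResult:
    """Leave-one-variant-out evaluation over the known-label variants.

    Each fold trains a fresh forest on all other variants' frames and
    predicts the held-out variant; accuracy is the fraction of correctly
    called variants.
    """
    truth = matrix.variant_labels()
    unknown = [v for v, s in truth.items() if s == "unknown"]
    if unknown:
        raise ValueError(f"matrix contains unlabeled variants: {unknown}")
    by_class = {"S": [], "R": []}
    for v, s in truth.items():
        by_class[s].append(v)
    for cls, members in by_class.items():
        if len(members) < 2:
            raise ValueError(
                f"class {cls} has {len(members)} variant(s); every fold "
                "needs both classes in training, so each class must have "
                "at least 2 variants")
    fold_seeds = np.random.SeedSequence(seed).spawn(len(truth))
    predictions = []
    for v, fseed in zip(truth, fold_seeds):
        train = matrix.drop_variants([v])
        test = matrix.select_variants([v])
        assert not set(test.variants) & set(train.variants)  # no leakage
        model = train_forest(train, features, n_trees=n_trees,
                             seed=int(fseed.generate_state(1)[0] % (2 ** 31)),
                             **forest_kwargs)
        predictions.append(predict_variant(model, test))
    return LovoResult(predictions=predictions, truth=truth,
                      features=canonical_feature_order(features))


def subset_comparison(matrix: DihedralMatrix, selection: SelectionResult,
                      subsets, n_trees: int = 100, seed: int = 0,
                      **forest_kwargs) -> pd.DataFrame:
    """LOVO accuracy for unions of selection rounds' feature sets.

    ``subsets`` is a list of round-index tuples (1-based), e.g.
    ``[(1, 2, 3), (2, 3), (1, 3), (1, 2)]``.  Duplicate requests are
    deduplicated with order preserved; empty unions are skipped with a
    warning.  Returns rows (features, rounds, accuracy_pct).
    """
    seen = set()
    rows = []
    for subset in subsets:
        key = tuple(sorted(subset))
        if key in seen:
            continue
        seen.add(key)
        feats = selection.features_of_rounds(subset)
        if not feats:
            warnings.warn(f"rounds {subset} select no features; skipping")
            continue
        res = lovo_evaluate(matrix, feats, n_trees=n_trees, seed=seed,
                            **forest_kwargs)
        rows.append({"features": ", ".join(feats),
                     "rounds": ", ".join(str(i) for i in subset),
                     "accuracy_pct": round(100.0 * res.accuracy, 2)})
    return pd.DataFrame(rows, columns=["features", "rounds", "accuracy_pct"])


def permute_variant_labels(matrix: DihedralMatrix,
                           rng: np.random.Generator) -> DihedralMatrix:
    """Shuffle the variant -> status assignment (class sizes preserved).

    Every frame of a variant receives the permuted label, so the
    permutation acts at the variant level — the exchangeability unit of
    the LOVO design.
    """
    truth = matrix.variant_labels()
    variants = list(truth)
    labels = [truth[v] for v in variants]
    perm = rng.permutation(len(variants))
    mapping = {variants[i]: labels[perm[i]] for i in range(len(variants))}
    return DihedralMatrix(
        angles=matrix.angles, variant=matrix.variant,
        status=matrix.variant.map(mapping),
        traj_id=matrix.traj_id, frame_idx=matrix.frame_idx)


def permutation_null(matrix: DihedralMatrix, features,
                     n_permutations: int = 20, n_trees: int = 25,
                     seed: int = 0, **forest_kwargs) -> list[float]:
    """LOVO accuracies under variant-level label permutation.

    Estimates the no-signal baseline: with labels shuffled across
    variants, accuracy should fall to about the majority-class base
    rate.  Returns one accuracy per permutation (fixed seeds).
    """
    rng = np.random.default_rng(seed)
    accs = []
    for p in range(n_permutations):
        permuted = permute_variant_labels(matrix, rng)
        res = lovo_evaluate(permuted, features, n_trees=n_trees,
                            seed=seed + 1000 + p, **forest_kwargs)
        accs.append(res.accuracy)
    return accs


def predict_unknowns(matrix: DihedralMatrix, features,
                     unknown: DihedralMatrix, n_trees: int = 100,
                     seed: int = 0, **forest_kwargs) -> list[VariantPrediction]:
    """Classify unknown-status variants with a model trained on all known frames.

    Returns one VariantPrediction per unknown variant (empty list for an
    empty prediction matrix).
    """
    if unknown.n_rows == 0:
        return []
    model = train_forest(matrix, features, n_trees=n_trees, seed=seed,
                         **forest_kwargs)
    out = []
    for v in unknown.variants:
        out.append(predict_variant(model, unknown.select_variants([v])))
    return out
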