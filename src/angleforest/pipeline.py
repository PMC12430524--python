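"""End-to-end orchestration: simulate-or-load ensembles, build the data
matrix, select features, classify (LOVO + unknowns), evaluate, attribute,
run the angle-difference analysis and the convergence battery, and write
every table with a manifest.

Configuration is a nested dataclass tree, loadable from YAML; unknown
keys are rejected.  All stochastic stages derive their seeds from the
single top-level seed, so re-running a config reproduces identical
outputs byte for byte.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import anglestats, datasets, io
from .convergence import ramachandran_window_agreement, windowed_selection_stability
from .forest import lovo_evaluate, predict_unknowns, subset_comparison, train_forest
from .matrix import build_data_matrix
from .metrics import confusion_and_metrics
from .selection import iterative_selection
from .shapley import shap_summary
from .synthetic import generate_study, make_planted_study

__all__ = ["PipelineConfig", "run_pipeline", "load_config"]

log = logging.getLogger("angleforest")


def _from_dict(cls, data: dict):
    allowed = {f.name for f in fields(cls)}
    unknown = set(data) - allowed
    if unknown:
        raise ValueError(f"unknown {cls.__name__} keys: {sorted(unknown)}")
    return cls(**data)


@dataclass
class StudyConfig:
    n_residues: int = 276
    residue_offset: int = 448
    frames_per_trajectory: int = 10_000
    trajectories_per_variant: int = 3
    retain_last: int = 1000
    concentration: float = 15.0
    variant_jitter_sd: float = 8.0
    planted_offset: float = 60.0
    planted: Optional[list] = None    # default: the published angle set
    include_unknown: bool = True


@dataclass
class SelectionConfig:
    n_rounds: int = 3
    max_depth: int = 2
    min_leaf: int = 5


@dataclass
class ForestConfig:
    n_trees: int = 100
    min_leaf: int = 5
    max_depth: Optional[int] = None


@dataclass
class ShapConfig:
    background_size: int = 100
    max_rows: int = 200


@dataclass
class AngleStatsConfig:
    alpha: float = 0.05
    magnitude_threshold: float = anglestats.DEFAULT_MAGNITUDE_THRESHOLD
    bonferroni: bool = False


@dataclass
class ConvergenceConfig:
    bin_width: float = 10.0
    n_windows: int = 3
    window_size: int = 200


@dataclass
class PipelineConfig:
    drug: str = "dabrafenib"
    seed: int = 0
    labels_path: Optional[str] = None       # TSV label table; default roster
    ensembles_dir: Optional[str] = None     # load .tsv/.pdb ensembles if set
    study: StudyConfig = field(default_factory=StudyConfig)
    selection: SelectionConfig = field(default_factory=SelectionConfig)
    forest: ForestConfig = field(default_factory=ForestConfig)
    shap: ShapConfig = field(default_factory=ShapConfig)
    angle_stats: AngleStatsConfig = field(default_factory=AngleStatsConfig)
    convergence: ConvergenceConfig = field(default_factory=ConvergenceConfig)

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        data = dict(data)
        nested = {"study": StudyConfig, "selection": SelectionConfig,
                  "forest": ForestConfig, "shap": ShapConfig,
                  "angle_stats": AngleStatsConfig,
                  "convergence": ConvergenceConfig}
        for key, sub_cls in nested.items():
            if key in data and isinstance(data[key], dict):
                data[key] = _from_dict(sub_cls, data[key])
        cfg = _from_dict(cls, data)
        datasets._check_drug(cfg.drug)
        return cfg

    def to_dict(self) -> dict:
        return asdict(self)


def load_config(path) -> PipelineConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    return PipelineConfig.from_dict(data)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _get_ensembles(cfg: PipelineConfig):
    if cfg.ensembles_dir is not None:
        paths = sorted(Path(cfg.ensembles_dir).glob("*"))
        paths = [p for p in paths if p.suffix.lower() in (".pdb", ".tsv")]
        if not paths:
            raise ValueError(f"no .pdb/.tsv ensembles in {cfg.ensembles_dir}")
        ensembles = [io.read_ensemble(p) for p in paths]
    else:
        s = cfg.study
        spec = make_planted_study(
            drug=cfg.drug, planted=s.planted,
            offset=s.planted_offset, seed=cfg.seed,
            include_unknown=s.include_unknown,
            n_residues=s.n_residues, residue_offset=s.residue_offset,
            frames_per_trajectory=s.frames_per_trajectory,
            trajectories_per_variant=s.trajectories_per_variant,
            retain_last=s.retain_last, concentration=s.concentration,
            variant_jitter_sd=s.variant_jitter_sd)
        ensembles = generate_study(spec)
    if cfg.labels_path is not None:
        labels = io.read_label_table(cfg.labels_path)
    else:
        labels = datasets.variant_roster()
    return ensembles, labels


def run_pipeline(cfg: PipelineConfig, outdir) -> dict:
    """Execute the full workflow and write all result tables to ``outdir``.

    Returns a summary dict (also written as ``manifest.json``) with the
    config hash, per-stage timings, headline numbers, and output
    checksums.  Any stage failure aborts with the stage name attached.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}
    summary: dict = {}
    timings: dict[str, float] = {}
    seeds = np.random.SeedSequence(cfg.seed).spawn(4)
    seed_of = {name: int(s.generate_state(1)[0] % (2 ** 31))
               for name, s in zip(("lovo", "subsets", "unknowns", "shap"), seeds)}

    stage = "setup"
    try:
        t0 = time.perf_counter()
        ensembles, labels = _get_ensembles(cfg)
        known, unknown = build_data_matrix(ensembles, labels, cfg.drug)
        timings[stage] = time.perf_counter() - t0
        log.info("built matrix: %d rows x %d angles (+%d unknown rows)",
                 known.n_rows, len(known.feature_names), unknown.n_rows)

        stage = "selection"
        t0 = time.perf_counter()
        sel = iterative_selection(known, n_rounds=cfg.selection.n_rounds,
                                  max_depth=cfg.selection.max_depth,
                                  min_leaf=cfg.selection.min_leaf)
        p = outdir / "selection.json"
        sel.to_json(p)
        written["selection"] = p
        (outdir / "trees.txt").write_text(
            "\n\n".join(f"# round {r.index}\n{r.tree.dump()}"
                        for r in sel.rounds) + "\n")
        written["trees"] = outdir / "trees.txt"
        features = sel.all_selected
        summary["selected_features"] = features
        timings[stage] = time.perf_counter() - t0
        log.info("selected %s", features)

        stage = "classification"
        t0 = time.perf_counter()
        n_rounds = len(sel.rounds)
        subsets = [tuple(range(1, n_rounds + 1))] + [
            tuple(i for i in range(1, n_rounds + 1) if i != drop)
            for drop in range(n_rounds, 0, -1)] if n_rounds > 1 else [(1,)]
        comparison = subset_comparison(
            known, sel, subsets, n_trees=cfg.forest.n_trees,
            seed=seed_of["subsets"], min_leaf=cfg.forest.min_leaf,
            max_depth=cfg.forest.max_depth)
        p = outdir / "subset_comparison.tsv"
        comparison.to_csv(p, sep="\t", index=False)
        written["subset_comparison"] = p

        lovo = lovo_evaluate(known, features, n_trees=cfg.forest.n_trees,
                             seed=seed_of["lovo"], min_leaf=cfg.forest.min_leaf,
                             max_depth=cfg.forest.max_depth)
        p = outdir / "lovo.tsv"
        lovo.to_table().to_csv(p, sep="\t", index=False)
        written["lovo"] = p
        summary["lovo_accuracy"] = lovo.accuracy
        timings[stage] = time.perf_counter() - t0
        log.info("LOVO accuracy %.4f", lovo.accuracy)

        stage = "evaluation"
        t0 = time.perf_counter()
        table = lovo.to_table()
        cm, report = confusion_and_metrics(table["status"], table["prediction"])
        (outdir / "metrics.json").write_text(report.to_json() + "\n")
        written["metrics"] = outdir / "metrics.json"
        report.to_table().to_csv(outdir / "metrics.tsv", sep="\t", index=False)
        written["metrics_tsv"] = outdir / "metrics.tsv"
        summary["metrics"] = report.to_dict()
        summary["confusion"] = vars(cm).copy()
        timings[stage] = time.perf_counter() - t0

        stage = "unknown_prediction"
        t0 = time.perf_counter()
        vus = predict_unknowns(known, features, unknown,
                               n_trees=cfg.forest.n_trees,
                               seed=seed_of["unknowns"],
                               min_leaf=cfg.forest.min_leaf,
                               max_depth=cfg.forest.max_depth)
        if vus:
            p = outdir / "vus_predictions.tsv"
            pd.DataFrame(
                [{"variant": v.variant, "prediction": v.label,
                  "vote_fraction": round(v.vote_fraction, 4)} for v in vus]
            ).to_csv(p, sep="\t", index=False)
            written["vus_predictions"] = p
            summary["vus_predictions"] = {v.variant: v.label for v in vus}
        timings[stage] = time.perf_counter() - t0

        stage = "attribution"
        t0 = time.perf_counter()
        model = train_forest(known, features, n_trees=cfg.forest.n_trees,
                             seed=seed_of["shap"], min_leaf=cfg.forest.min_leaf,
                             max_depth=cfg.forest.max_depth)
        rng = np.random.default_rng(seed_of["shap"])
        bg_rows = rng.choice(known.n_rows,
                             size=min(cfg.shap.background_size, known.n_rows),
                             replace=False)
        background = known.X(model.features)[np.sort(bg_rows)]
        shap = shap_summary(model, known, background,
                            max_rows=cfg.shap.max_rows, seed=seed_of["shap"])
        shap.to_long_frame().to_csv(outdir / "shap_values.tsv", sep="\t",
                                    index=False, float_format="%.6f")
        written["shap_values"] = outdir / "shap_values.tsv"
        ranking = shap.ranking()
        (outdir / "shap_ranking.json").write_text(
            json.dumps(ranking.to_dict(orient="records"), indent=2) + "\n")
        written["shap_ranking"] = outdir / "shap_ranking.json"
        summary["shap_top_feature"] = ranking["feature"].iloc[0]
        timings[stage] = time.perf_counter() - t0

        stage = "angle_stats"
        t0 = time.perf_counter()
        diff = anglestats.group_angle_analysis(
            known, threshold=cfg.angle_stats.magnitude_threshold,
            alpha=cfg.angle_stats.alpha,
            bonferroni=cfg.angle_stats.bonferroni)
        diff.to_csv(outdir / "angle_differences.tsv", sep="\t", index=False,
                    float_format="%.6g")
        written["angle_differences"] = outdir / "angle_differences.tsv"
        summary["flagged_angles"] = diff.loc[diff["flag"], "feature"].tolist()
        if "WT" in known.variants:
            summary["wt_threshold_deg"] = anglestats.wt_threshold(
                known.select_variants(["WT"]))
        timings[stage] = time.perf_counter() - t0

        stage = "convergence"
        t0 = time.perf_counter()
        fpt = cfg.study.frames_per_trajectory
        retain = cfg.study.retain_last
        half = retain // 2
        conv: dict = {}
        if half >= 1:
            conv["ramachandran_jsd_last_vs_penultimate"] = \
                ramachandran_window_agreement(
                    known, (fpt - half, fpt), (fpt - 2 * half, fpt - half),
                    bin_width=cfg.convergence.bin_width)
        size = cfg.convergence.window_size
        windows = [(fpt - (i + 1) * size, fpt - i * size)
                   for i in range(cfg.convergence.n_windows)][::-1]
        try:
            stab = windowed_selection_stability(
                known, windows, n_rounds=cfg.selection.n_rounds,
                max_depth=cfg.selection.max_depth,
                min_leaf=cfg.selection.min_leaf)
            conv["selection_stability"] = stab.to_dict()
        except ValueError as err:
            conv["selection_stability"] = {"skipped": str(err)}
        (outdir / "convergence.json").write_text(
            json.dumps(conv, indent=2) + "\n")
        written["convergence"] = outdir / "convergence.json"
        summary["convergence"] = conv
        timings[stage] = time.perf_counter() - t0
    except Exception as err:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {err}") from err

    config_blob = json.dumps(cfg.to_dict(), sort_keys=True)
    manifest = {
        "config": cfg.to_dict(),
        "config_sha256": hashlib.sha256(config_blob.encode()).hexdigest(),
        "seed": cfg.seed,
        "stage_seeds": seed_of,
        "timings_s": {k: round(v, 3) for k, v in timings.items()},
        "outputs": {k: {"path": p.name, "sha256": _sha256(p)}
                    for k, p in written.items()},
        "summary": summary,
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2,
                                                     default=str) + "\n")
    return manifest
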