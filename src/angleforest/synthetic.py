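"""Synthetic conformational-ensemble generator.

The generator emulates the statistical structure of the BRAF REST2 study
design without running any molecular dynamics: per variant, three
independent trajectories of 10,000 frames each, of which the final 1000
frames per trajectory are retained (3000 frames/variant); a 276-residue
chain yielding 550 backbone phi/psi features; per-angle unimodal circular
(von Mises) fluctuations; and a small set of planted angles whose class
means differ between resistant and sensitive variants.

Within-class variants are not identical: each variant perturbs its mean
angles by a jitter drawn once per variant, which is what makes
leave-one-variant-out evaluation a meaningful generalization test.

An optional equilibration transient (class signal and variant jitter
ramping in with a time constant) supports the convergence diagnostics on
full-length trajectories.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from . import datasets
from .circular import wrap_angle
from .ensembles import VariantEnsemble, phi_psi_feature_names
from .geometry import build_backbone_from_torsions

__all__ = [
    "VariantSpec",
    "StudySpec",
    "generate_study",
    "make_planted_study",
    "synthetic_rmsd_series",
    "attach_coordinates",
]


@dataclass
class VariantSpec:
    """One variant of a synthetic study.

    ``mean_shift`` maps feature names (e.g. 'phi600') to this variant's
    signed offset (degrees) from the shared base mean of that angle —
    the mechanism by which class-discriminative angles are planted.
    ``concentration`` (von Mises kappa) and ``variant_jitter_sd`` override
    the study-wide defaults when set.
    """

    name: str
    label: str = "unknown"
    mean_shift: dict = field(default_factory=dict)
    concentration: Optional[float] = None
    variant_jitter_sd: Optional[float] = None

    def __post_init__(self):
        if self.label not in ("S", "R", "unknown"):
            raise ValueError(f"{self.name}: label must be S/R/unknown")
        for k, v in self.mean_shift.items():
            if not math.isfinite(v):
                raise ValueError(f"{self.name}: non-finite mean shift for {k}")
        if self.concentration is not None and not (
                math.isfinite(self.concentration) and self.concentration > 0):
            raise ValueError(f"{self.name}: concentration must be positive")


@dataclass
class StudySpec:
    """Design of a synthetic multi-variant ensemble study.

    Defaults follow the BRAF study design: 276 residues numbered from 448
    (so features are named phi449..psi722 in kinase numbering), three
    trajectories of 10,000 frames per variant with the final 1000 frames
    of each retained.

    ``concentration`` = 15 gives per-angle circular SDs of ~15 degrees,
    the dispersion scale reported for the wild-type ensemble;
    ``variant_jitter_sd`` = 8 degrees perturbs each variant's mean angles
    within its class.  ``equilibration_tau`` (frames) ramps class signal
    and jitter in as 1 - exp(-t/tau) when full trajectories are generated,
    emulating relaxation away from the shared starting structure.
    """

    variants: list
    n_residues: int = 276
    residue_offset: int = 448
    frames_per_trajectory: int = 10_000
    trajectories_per_variant: int = 3
    retain_last: int = 1000
    concentration: float = 15.0
    variant_jitter_sd: float = 8.0
    base_mean_range: float = 120.0
    equilibration_tau: Optional[float] = None
    seed: int = 0

    def __post_init__(self):
        if self.n_residues < 4:
            raise ValueError("n_residues must be at least 4")
        if not (1 <= self.retain_last <= self.frames_per_trajectory):
            raise ValueError("retain_last must be in [1, frames_per_trajectory]")
        if self.trajectories_per_variant < 1:
            raise ValueError("need at least one trajectory per variant")
        for val, name in ((self.concentration, "concentration"),
                          (self.variant_jitter_sd, "variant_jitter_sd"),
                          (self.base_mean_range, "base_mean_range")):
            if not math.isfinite(val):
                raise ValueError(f"non-finite {name}")
        if self.concentration <= 0:
            raise ValueError("concentration must be positive")
        if not self.variants:
            raise ValueError("study has no variants")
        names = [v.name for v in self.variants]
        if len(set(names)) != len(names):
            raise ValueError("duplicate variant names in study")
        labels = {v.label for v in self.variants}
        planted = any(v.mean_shift for v in self.variants)
        if planted and not {"S", "R"}.issubset(labels):
            raise ValueError(
                "class-discriminative shifts are planted but the study does "
                "not contain variants of both classes")
        feats = set(self.feature_names)
        for v in self.variants:
            unknown = set(v.mean_shift) - feats
            if unknown:
                raise ValueError(
                    f"{v.name}: mean shifts reference unknown features "
                    f"{sorted(unknown)}")

    @property
    def residue_ids(self) -> np.ndarray:
        return np.arange(self.residue_offset,
                         self.residue_offset + self.n_residues)

    @property
    def feature_names(self) -> list[str]:
        return phi_psi_feature_names(self.residue_ids)

    @property
    def n_features(self) -> int:
        return 2 * self.n_residues - 2

    def label_table(self, drug: str) -> pd.DataFrame:
        return pd.DataFrame(
            [{"variant": v.name, "drug": drug, "status": v.label}
             for v in self.variants])


def generate_study(spec: StudySpec, retain: bool = True) -> list[VariantEnsemble]:
    """Draw one ensemble per variant of the study.

    Each angle of each frame is drawn from a von Mises distribution
    centered on the variant's mean for that angle (shared base mean +
    planted shift + per-variant jitter), wrapped to (-180, 180].  With
    ``retain=True`` (default) only the final ``retain_last`` frames of
    each trajectory are generated and returned, with frame indices
    numbered as in the full trajectory; with ``retain=False`` full
    trajectories are produced (including any equilibration transient).

    Identical seeds yield identical ensembles.
    """
    seq = np.random.SeedSequence(spec.seed)
    base_rng = np.random.default_rng(seq.spawn(1)[0])
    variant_seeds = seq.spawn(len(spec.variants))

    features = spec.feature_names
    k = len(features)
    feat_index = {f: i for i, f in enumerate(features)}
    # base circular means shared by all variants, kept away from the +/-180
    # wrap so that unimodal fluctuations stay on one branch of the circle
    base_means = base_rng.uniform(-spec.base_mean_range, spec.base_mean_range, k)

    n_traj = spec.trajectories_per_variant
    n_keep = spec.retain_last if retain else spec.frames_per_trajectory
    first_idx = spec.frames_per_trajectory - n_keep

    ensembles = []
    for v, vseed in zip(spec.variants, variant_seeds):
        rng = np.random.default_rng(vseed)
        kappa = v.concentration if v.concentration is not None \
            else spec.concentration
        jitter_sd = v.variant_jitter_sd if v.variant_jitter_sd is not None \
            else spec.variant_jitter_sd
        jitter = rng.normal(0.0, jitter_sd, k)  # drawn once per variant
        shift = np.zeros(k)
        for fname, off in v.mean_shift.items():
            shift[feat_index[fname]] = off
        structured = shift + jitter

        frame_idx = np.tile(np.arange(first_idx, spec.frames_per_trajectory),
                            n_traj)
        traj_id = np.repeat(np.arange(n_traj), n_keep)
        noise = rng.vonmises(0.0, kappa, size=(n_traj * n_keep, k))
        if spec.equilibration_tau is not None:
            ramp = 1.0 - np.exp(-frame_idx / spec.equilibration_tau)
        else:
            ramp = np.ones(len(frame_idx))
        means = base_means[None, :] + ramp[:, None] * structured[None, :]
        angles = wrap_angle(means + np.rad2deg(noise))
        ensembles.append(VariantEnsemble(
            variant=v.name,
            residue_ids=spec.residue_ids,
            angles=pd.DataFrame(angles, columns=features),
            traj_id=traj_id,
            frame_idx=frame_idx,
            label=v.label,
        ))
    return ensembles


def make_planted_study(drug: str = "dabrafenib", planted=None,
                       offset: float = 60.0, seed: int = 0,
                       include_unknown: bool = True,
                       **overrides) -> StudySpec:
    """Study spec mirroring the published variant roster for one drug.

    Uses the 16-variant clinical roster; the planted class-discriminative
    angles default to those the published feature selection retained for
    the drug.  Resistant variants are shifted +offset/2 and sensitive ones
    -offset/2 on each planted angle, so the class-conditional circular
    means differ by ``offset`` degrees.  Unknown-status (VUS) variants are
    planted on the side of their reported call, so that their predicted
    labels have a ground truth.  Extra keyword arguments override
    StudySpec fields (e.g. retain_last=100 for a quick run).
    """
    datasets._check_drug(drug)
    if planted is None:
        planted = [f for rnd in datasets.REPORTED_SELECTION_ROUNDS[drug]
                   for f in rnd]
        # down-scaled chains may not cover the published angles; keep the
        # ones in range (explicit `planted` lists are still validated
        # strictly by StudySpec)
        probe = StudySpec(variants=[VariantSpec("probe", "S", {})],
                          seed=0, **overrides)
        available = set(probe.feature_names)
        planted = [f for f in planted if f in available]
        if not planted:
            raise ValueError(
                "none of the published discriminative angles fall inside "
                "the requested chain; pass `planted` explicitly")
    planted = list(dict.fromkeys(planted))
    roster = datasets.variant_roster()
    status_of = dict(zip(roster[roster["drug"] == drug]["variant"],
                         roster[roster["drug"] == drug]["status"]))
    vus_side = dict(zip(datasets.vus_calls(drug)["variant"],
                        datasets.vus_calls(drug)["prediction"]))
    variants = []
    for name, status in status_of.items():
        if status == "unknown" and not include_unknown:
            continue
        side = status if status in ("S", "R") else vus_side.get(name)
        if side == "R":
            shift = {f: +offset / 2.0 for f in planted}
        elif side == "S":
            shift = {f: -offset / 2.0 for f in planted}
        else:
            shift = {}
        variants.append(VariantSpec(name=name, label=status, mean_shift=shift))
    return StudySpec(variants=variants, seed=seed, **overrides)


def synthetic_rmsd_series(n_frames: int = 10_000, changepoint: int = 6000,
                          plateau: float = 2.5, noise_sd: float = 0.05,
                          seed: int = 0) -> np.ndarray:
    """RMSD-to-reference series that stabilizes after ``changepoint`` frames.

    Linear rise from 0 to ``plateau`` Angstrom over the first
    ``changepoint`` frames, constant thereafter, plus Gaussian noise —
    the shape of a trajectory whose structural fluctuations level off
    once equilibrated.
    """
    rng = np.random.default_rng(seed)
    t = np.arange(n_frames, dtype=float)
    base = np.where(t < changepoint, plateau * t / changepoint, plateau)
    return np.abs(base + rng.normal(0.0, noise_sd, n_frames))


def attach_coordinates(ensemble: VariantEnsemble) -> VariantEnsemble:
    """Build backbone coordinates realizing each frame's phi/psi vector.

    Intended for small ensembles (PDB round-trip fixtures); the chain is
    built with standard peptide geometry, omega frozen trans.
    """
    if ensemble.angles is None:
        raise ValueError("ensemble has no angles")
    n_res = ensemble.n_residues
    coords = np.empty((ensemble.n_frames, n_res, 3, 3))
    vals = ensemble.angles.to_numpy(dtype=float)
    half = n_res - 1
    for i in range(ensemble.n_frames):
        coords[i] = build_backbone_from_torsions(vals[i, :half], vals[i, half:])
    out = VariantEnsemble(
        variant=ensemble.variant, residue_ids=ensemble.residue_ids,
        coords=coords, angles=ensemble.angles,
        traj_id=ensemble.traj_id, frame_idx=ensemble.frame_idx,
        label=ensemble.label)
    return out
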