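"""RMSD plateau detection, Ramachandran window agreement, selection stability."""

import numpy as np
import pytest

import angleforest as af
from angleforest.convergence import (ramachandran_window_agreement,
                                     rmsd_plateau, rmsd_series,
                                     windowed_selection_stability)
from angleforest.synthetic import (StudySpec, VariantSpec,
                                   synthetic_rmsd_series)


class TestRmsdPlateau:
    def test_rise_then_constant_detected_at_tail_start(self):
        series = np.concatenate([np.linspace(0, 2, 1000), np.full(1500, 2.0)])
        idx = rmsd_plateau(series, window=200, slope_tol=1e-4, sd_tol=0.1)
        assert idx is not None
        assert 800 <= idx <= 1100

    def test_monotonic_rise_never_converges(self):
        series = np.linspace(0, 5, 2000)
        assert rmsd_plateau(series, window=200, slope_tol=1e-4,
                            sd_tol=0.1) is None

    def test_short_series_warns_and_returns_none(self):
        with pytest.warns(UserWarning):
            assert rmsd_plateau(np.ones(10), window=50) is None

    def test_emulated_stabilization_located_near_changepoint(self):
        series = synthetic_rmsd_series(n_frames=10_000, changepoint=6000,
                                       plateau=2.5, noise_sd=0.05, seed=4)
        idx = rmsd_plateau(series, window=500, slope_tol=1e-4, sd_tol=0.15)
        assert idx is not None
        assert abs(idx - 6000) <= 500


def test_rmsd_series_zero_at_reference():
    spec = StudySpec(variants=[VariantSpec("demo", "S", {})],
                     n_residues=8, residue_offset=1,
                     frames_per_trajectory=5, retain_last=5,
                     trajectories_per_variant=1, seed=2)
    ens = af.attach_coordinates(af.generate_study(spec)[0])
    series = rmsd_series(ens, reference=0)
    assert series["rmsd"].iloc[0] == pytest.approx(0.0, abs=1e-9)
    assert (series["rmsd"] >= 0).all()
    assert len(series) == 5


class TestRamachandranWindows:
    def test_identical_windows_give_zero(self, small_known):
        mask = small_known.frame_idx >= 100
        d = ramachandran_window_agreement(small_known, mask, mask.copy())
        assert d == pytest.approx(0.0, abs=1e-12)

    def test_disjoint_modes_give_near_one(self, rng):
        from angleforest.matrix import DihedralMatrix
        import pandas as pd
        cols = af.phi_psi_feature_names(range(1, 4))
        a = pd.DataFrame(rng.normal(-90, 3, size=(300, 4)), columns=cols)
        b = pd.DataFrame(rng.normal(90, 3, size=(300, 4)), columns=cols)
        m = DihedralMatrix(angles=pd.concat([a, b], ignore_index=True),
                           variant=["v"] * 600, status=["S"] * 600,
                           frame_idx=np.arange(600))
        d = ramachandran_window_agreement(m, (0, 300), (300, 600))
        assert d > 0.95

    def test_stationary_windows_below_null_scale(self):
        spec = af.make_planted_study(
            "dabrafenib", planted=["phi455"], offset=60.0, seed=21,
            n_residues=30, residue_offset=448,
            frames_per_trajectory=2000, retain_last=2000,
            trajectories_per_variant=1, include_unknown=False)
        known, _ = af.build_data_matrix(
            af.generate_study(spec), spec.label_table("dabrafenib"),
            "dabrafenib")
        d = ramachandran_window_agreement(known, (1000, 2000), (0, 1000),
                                          bin_width=10.0)
        assert d < 0.05

    def test_empty_window_rejected(self, small_known):
        with pytest.raises(ValueError):
            ramachandran_window_agreement(small_known, (0, 1), (1, 2))


@pytest.fixture(scope="module")
def stationary():
    spec = af.make_planted_study(
        "dabrafenib", planted=["phi455", "psi460"], offset=60.0,
        seed=31, n_residues=30, residue_offset=448,
        frames_per_trajectory=600, retain_last=600,
        trajectories_per_variant=1, include_unknown=False)
    known, _ = af.build_data_matrix(
        af.generate_study(spec), spec.label_table("dabrafenib"),
        "dabrafenib")
    return known


class TestSelectionStability:
    def test_identical_windows_have_jaccard_one(self, stationary):
        rep = windowed_selection_stability(
            stationary, [(400, 600), (400, 600)], n_rounds=1)
        assert rep.jaccard_matrix[0, 1] == 1.0

    def test_stationary_windows_overlap_full_selection(self, stationary):
        rep = windowed_selection_stability(
            stationary, [(0, 200), (200, 400), (400, 600)], n_rounds=1)
        assert min(rep.jaccard_vs_full) >= 0.5
        assert rep.selected_full == ["phi455", "psi460"]

    def test_drifted_early_window_degrades_overlap(self):
        spec = af.make_planted_study(
            "dabrafenib", planted=["phi455", "psi460"], offset=60.0,
            seed=32, n_residues=30, residue_offset=448,
            frames_per_trajectory=600, retain_last=600,
            trajectories_per_variant=1, include_unknown=False,
            equilibration_tau=250.0)
        known, _ = af.build_data_matrix(
            af.generate_study(spec, retain=False),
            spec.label_table("dabrafenib"), "dabrafenib")
        rep = windowed_selection_stability(
            known, [(0, 100), (400, 500), (500, 600)], n_rounds=1)
        late = af.iterative_selection(known.frame_window(400, 600),
                                      n_rounds=1).all_selected
        # the equilibrated windows agree with each other
        assert rep.jaccard_matrix[1, 2] >= 0.5
        # the non-equilibrated head agrees less with the equilibrated tail
        early_vs_late = rep.jaccard_matrix[0, 1]
        assert early_vs_late <= rep.jaccard_matrix[1, 2]
        assert set(late) <= {"phi455", "psi460"}

    def test_too_few_windows_rejected(self, stationary):
        with pytest.raises(ValueError):
            windowed_selection_stability(stationary, [(0, 200)])
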