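"""Shared small-scale synthetic fixtures.

All fixtures are generated programmatically with fixed seeds; the
"small study" mirrors the real study design (12 labeled variants, two
classes, planted discriminative angles) at a fraction of the frame count
and chain length so the whole suite stays fast.
"""

import numpy as np
import pytest

import angleforest as af

SMALL_PLANTED = ["phi455", "psi460"]


@pytest.fixture(scope="session")
def small_spec():
    return af.make_planted_study(
        "dabrafenib", planted=SMALL_PLANTED, offset=60.0, seed=11,
        n_residues=30, residue_offset=448,
        frames_per_trajectory=120, retain_last=40)


@pytest.fixture(scope="session")
def small_ensembles(small_spec):
    return af.generate_study(small_spec)


@pytest.fixture(scope="session")
def small_matrices(small_spec, small_ensembles):
    labels = small_spec.label_table("dabrafenib")
    return af.build_data_matrix(small_ensembles, labels, "dabrafenib")


@pytest.fixture(scope="session")
def small_known(small_matrices):
    return small_matrices[0]


@pytest.fixture(scope="session")
def small_unknown(small_matrices):
    return small_matrices[1]


@pytest.fixture(scope="session")
def small_forest(small_known):
    return af.train_forest(small_known, SMALL_PLANTED, n_trees=25, seed=3)


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
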