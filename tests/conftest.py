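"""Shared fixtures: one small rendered dataset and one cross-validated
scorer run, built once per session."""

from __future__ import annotations

import pytest

import slofgrade.model as mdl
import slofgrade.synthetic as syn


@pytest.fixture(scope="session")
def small_dataset(tmp_path_factory):
    """A 200-image rendered dataset: 10 train vessels, 3 test vessels."""
    root = tmp_path_factory.mktemp("small_dataset")
    manifest = syn.generate_dataset(
        (100, 60, 40),
        test_per_class=(25, 15, 10),
        n_expert_group=20,
        n_train_vessels=10,
        n_test_vessels=3,
        image_size=64,
        out_dir=root,
        seed=11,
        render=True,
    )
    return manifest, root


@pytest.fixture(scope="session")
def train_images(small_dataset):
    manifest, root = small_dataset
    return mdl.load_images(manifest.subset("train"), root, size=48)


@pytest.fixture(scope="session")
def cv_result(small_dataset, train_images):
    manifest, _ = small_dataset
    config = mdl.TrainConfig(seed=11, folds=5, epochs=10)
    return mdl.crossval_scores(manifest.subset("train"), config, train_images)
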