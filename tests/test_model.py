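"""Class weights, regression losses, fold assignment, training,
ensembling and Sobol hyperparameter draws."""

import dataclasses

import numpy as np
import pytest
import scipy.stats

import slofgrade.classifier as clf
import slofgrade.model as mdl
import slofgrade.synthetic as syn
from slofgrade.exceptions import ValidationError
from slofgrade.synthetic import LabelSet, ScoreSet


class TestClassWeights:
    def test_balanced_counts_give_unit_weights(self):
        assert mdl.class_weights((10, 10, 10)).w == (1.0, 1.0, 1.0)

    def test_published_dataset_counts(self):
        # the full survey totals: 7822 / 1696 / 745 images per grade
        w = mdl.class_weights((7822, 1696, 745)).w
        assert w == pytest.approx((0.4374, 2.0171, 4.5919), abs=1e-3)

    def test_reweighted_total_is_preserved(self):
        counts = (123, 45, 7)
        w = mdl.class_weights(counts).w
        assert sum(c * wi for c, wi in zip(counts, w)) == pytest.approx(sum(counts))

    def test_zero_count_class_rejected(self):
        with pytest.raises(ValidationError):
            mdl.class_weights((10, 0, 5))


class TestRegressionLoss:
    def test_zero_at_perfect_prediction(self):
        x = np.array([0.0, 1.0, 2.0])
        for kind in ("mse", "smooth_l1"):
            assert mdl.weighted_regression_loss(x, x, np.ones(3), kind) == 0.0

    @pytest.mark.parametrize(
        "residual,weight,expected",
        [(2.0, 1.0, 1.5), (0.5, 2.0, 0.25)],
    )
    def test_smooth_l1_hand_values(self, residual, weight, expected):
        got = mdl.weighted_regression_loss(
            np.array([residual]), np.array([0.0]), np.array([weight]), "smooth_l1"
        )
        assert got == pytest.approx(expected)

    def test_unit_weights_match_unweighted(self):
        rng = np.random.default_rng(0)
        pred, targ = rng.normal(size=50), rng.integers(0, 3, size=50).astype(float)
        w = np.ones(50)
        mse = mdl.weighted_regression_loss(pred, targ, w, "mse")
        assert mse == pytest.approx(np.mean((pred - targ) ** 2))

    def test_weight_scaling_is_exact(self):
        rng = np.random.default_rng(1)
        pred, targ = rng.normal(size=30), rng.normal(size=30)
        w = rng.uniform(0.5, 2.0, size=30)
        base = mdl.weighted_regression_loss(pred, targ, w, "smooth_l1")
        scaled = mdl.weighted_regression_loss(pred, targ, 3.0 * w, "smooth_l1")
        assert scaled == pytest.approx(3.0 * base, rel=1e-12)

    def test_smooth_l1_continuous_at_unit_residual(self):
        just_below = mdl.weighted_regression_loss(
            np.array([1.0 - 1e-9]), np.array([0.0]), np.array([1.0]), "smooth_l1"
        )
        at_one = mdl.weighted_regression_loss(
            np.array([1.0]), np.array([0.0]), np.array([1.0]), "smooth_l1"
        )
        assert at_one == pytest.approx(0.5) == pytest.approx(just_below, abs=1e-8)

    def test_non_finite_rejected(self):
        with pytest.raises(ValidationError):
            mdl.weighted_regression_loss(
                np.array([np.nan]), np.array([0.0]), np.array([1.0]), "mse"
            )


class TestSplitFolds:
    def _manifest(self, n_vessels, per_vessel=6, seed=0):
        n = n_vessels * per_vessel
        per_cls = (n - 2 * (n // 3), n // 3, n // 3)
        return syn.generate_dataset(
            per_cls, test_per_class=(0, 0, 0), n_expert_group=0,
            n_train_vessels=n_vessels, n_test_vessels=0, seed=seed, render=False,
        )

    def test_partition_of_manifest(self):
        m = self._manifest(10)
        fold_of = mdl.split_folds(m, 5, seed=1)
        assert set(fold_of) == {r.image_id for r in m.records}
        assert set(fold_of.values()) == set(range(5))

    def test_vessels_do_not_span_folds(self):
        m = self._manifest(10)
        fold_of = mdl.split_folds(m, 5, seed=1)
        per_vessel = {}
        for r in m.records:
            per_vessel.setdefault(r.vessel_id, set()).add(fold_of[r.image_id])
        assert all(len(folds) == 1 for folds in per_vessel.values())
        # 10 vessels over 5 folds -> 2 vessels each
        vessels_per_fold = {}
        for v, folds in per_vessel.items():
            vessels_per_fold.setdefault(next(iter(folds)), set()).add(v)
        assert all(len(vs) == 2 for vs in vessels_per_fold.values())

    def test_approximate_stratification(self):
        m = self._manifest(20, per_vessel=10, seed=2)
        fold_of = mdl.split_folds(m, 5, seed=3)
        global_props = np.array(m.class_counts()) / len(m)
        for fold in range(5):
            recs = [r for r in m.records if fold_of[r.image_id] == fold]
            counts = np.bincount([r.slof for r in recs], minlength=3)
            props = counts / counts.sum()
            assert np.abs(props - global_props).max() <= 0.10

    def test_deterministic_given_seed(self):
        m = self._manifest(10)
        assert mdl.split_folds(m, 5, seed=9) == mdl.split_folds(m, 5, seed=9)

    def test_fewer_vessels_than_folds_rejected(self):
        m = self._manifest(3)
        with pytest.raises(ValidationError):
            mdl.split_folds(m, 5, seed=0)


class TestTraining:
    def test_out_of_fold_scores_cover_train_split_once(self, small_dataset, cv_result):
        manifest, _ = small_dataset
        train = manifest.subset("train")
        assert set(cv_result.combined.scores) == {r.image_id for r in train.records}
        seen = set()
        for ss in cv_result.per_fold:
            assert not (seen & set(ss.scores))
            seen |= set(ss.scores)

    def test_scores_come_from_foreign_fold_models(self, cv_result):
        for ss in cv_result.per_fold:
            assert all(cv_result.fold_of[i] == ss.fold for i in ss.scores)

    def test_trained_model_learns_the_fixture(self, small_dataset, cv_result):
        manifest, _ = small_dataset
        train = manifest.subset("train")
        truth = LabelSet("t", {r.image_id: r.slof for r in train.records})
        assert clf.mean_average_precision(cv_result.combined, truth) >= 0.85
        rho = scipy.stats.spearmanr(
            [r.coverage for r in train.records],
            [cv_result.combined.scores[r.image_id] for r in train.records],
        ).statistic
        assert rho >= 0.6

    def test_untrained_model_near_prevalence_baseline(
        self, small_dataset, train_images, cv_result
    ):
        manifest, _ = small_dataset
        train = manifest.subset("train")
        truth = LabelSet("t", {r.image_id: r.slof for r in train.records})
        null_cfg = mdl.TrainConfig(seed=11, folds=5, epochs=0)
        null = mdl.crossval_scores(train, null_cfg, train_images)
        counts = np.bincount([r.slof for r in train.records], minlength=3)
        baseline = ((counts[1] + counts[2]) / counts.sum() + counts[2] / counts.sum()) / 2
        null_map = clf.mean_average_precision(null.combined, truth)
        trained_map = clf.mean_average_precision(cv_result.combined, truth)
        assert abs(null_map - baseline) <= 0.15
        assert trained_map > null_map

    def test_training_is_deterministic(self, small_dataset, train_images):
        manifest, _ = small_dataset
        train = manifest.subset("train")
        cfg = mdl.TrainConfig(seed=4, folds=5, epochs=2)
        a = mdl.train_scorer(train, cfg, fold=0, images=train_images)
        b = mdl.train_scorer(train, cfg, fold=0, images=train_images)
        assert a.scores == b.scores

    def test_checkpoint_and_log_written(self, small_dataset, train_images, tmp_path):
        manifest, _ = small_dataset
        train = manifest.subset("train")
        cfg = mdl.TrainConfig(seed=4, folds=5, epochs=2)
        mdl.train_scorer(train, cfg, fold=1, images=train_images, run_dir=tmp_path)
        assert (tmp_path / "fold1_checkpoint.npz").exists()
        log = (tmp_path / "fold1_train.log").read_text().strip().splitlines()
        assert log[0].split("\t") == ["epoch", "train_loss", "val_mean_ap"]
        assert len(log) == 3


class TestEnsembles:
    def test_single_input_is_identity(self):
        ss = ScoreSet({"a": 1.0, "b": 2.0})
        assert mdl.ensemble_scores([ss]).scores == ss.scores

    def test_two_member_mean(self):
        ens = mdl.ensemble_scores([ScoreSet({"a": 1.0}), ScoreSet({"a": 2.0})])
        assert ens.scores == {"a": 1.5}

    def test_self_ensemble_preserves_mean_ap(self):
        rng = np.random.default_rng(5)
        truth = LabelSet("t", {f"i{k}": int(rng.integers(0, 3)) for k in range(100)})
        ss = ScoreSet(
            {i: v + rng.normal(0, 0.5) for i, v in truth.labels.items()}
        )
        single = clf.mean_average_precision(ss, truth)
        doubled = clf.mean_average_precision(mdl.ensemble_scores([ss, ss]), truth)
        assert doubled == pytest.approx(single)

    def test_id_mismatch_rejected(self):
        with pytest.raises(ValidationError):
            mdl.ensemble_scores([ScoreSet({"a": 1.0}), ScoreSet({"b": 1.0})])

    def test_best_subset_keeps_the_strong_scorer(self):
        rng = np.random.default_rng(6)
        truth = LabelSet("t", {f"i{k}": int(rng.integers(0, 3)) for k in range(150)})
        strong = ScoreSet({i: v + rng.normal(0, 0.3) for i, v in truth.labels.items()})
        noise = [
            ScoreSet({i: rng.normal() for i in truth.labels}) for _ in range(3)
        ]
        subset, score = mdl.best_subset_ensemble([strong] + noise, truth)
        assert 0 in subset
        assert score >= clf.mean_average_precision(strong, truth) - 1e-9

    def test_identical_scorers_tie_break_to_single_member(self):
        truth = LabelSet("t", {"a": 0, "b": 1, "c": 2})
        ss = ScoreSet({"a": 0.0, "b": 1.0, "c": 2.0})
        subset, _ = mdl.best_subset_ensemble([ss, ScoreSet(dict(ss.scores))], truth)
        assert subset == (0,)

    def test_combinatorial_guard(self):
        truth = LabelSet("t", {"a": 0, "b": 1, "c": 2})
        ss = ScoreSet({"a": 0.0, "b": 1.0, "c": 2.0})
        with pytest.raises(ValidationError):
            mdl.best_subset_ensemble([ss] * 21, truth)


class TestSobol:
    SPACE = {
        "learning_rate": (1e-4, 1e-1, "log"),
        "weight_decay": (1e-6, 1e-2, "log"),
        "momentum": (0.5, 0.99, "linear"),
    }

    def test_all_candidates_within_bounds(self):
        for cfg in mdl.sobol_candidates(self.SPACE, 32, seed=1):
            assert 1e-4 <= cfg.learning_rate <= 1e-1
            assert 1e-6 <= cfg.weight_decay <= 1e-2
            assert 0.5 <= cfg.momentum <= 0.99

    def test_deterministic_given_seed(self):
        a = mdl.sobol_candidates(self.SPACE, 16, seed=2)
        b = mdl.sobol_candidates(self.SPACE, 16, seed=2)
        assert [dataclasses.astuple(x) for x in a] == [dataclasses.astuple(x) for x in b]

    def test_lower_discrepancy_than_random_draws(self):
        from scipy.stats import qmc

        space = {"learning_rate": (0.0, 1.0, "linear"), "momentum": (0.0, 1.0, "linear")}
        pts = np.array(
            [(c.learning_rate, c.momentum) for c in mdl.sobol_candidates(space, 64, seed=3)]
        )
        sobol_disc = qmc.discrepancy(pts)
        rng = np.random.default_rng(4)
        random_discs = [qmc.discrepancy(rng.random((64, 2))) for _ in range(20)]
        assert sobol_disc < np.mean(random_discs)

    def test_invalid_space_rejected(self):
        with pytest.raises(ValidationError):
            mdl.sobol_candidates({"learning_rate": (0.1, 0.01, "linear")}, 4, seed=0)
        with pytest.raises(ValidationError):
            mdl.sobol_candidates({"nonexistent": (0, 1, "linear")}, 4, seed=0)
        with pytest.raises(ValidationError):
            mdl.sobol_candidates({"learning_rate": (-1, 1, "log")}, 4, seed=0)
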