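"""PR curves, average precision, threshold selection and evaluation."""

import numpy as np
import pytest
from sklearn.metrics import average_precision_score

import slofgrade.classifier as clf
from slofgrade.agreement import BinaryTask
from slofgrade.exceptions import ValidationError
from slofgrade.synthetic import LabelSet, ScoreSet


def make_instance(n: int, seed: int):
    rng = np.random.default_rng(seed)
    ids = [f"i{k}" for k in range(n)]
    truth = {i: int(rng.integers(0, 2)) for i in ids}
    if len(set(truth.values())) < 2:  # force both classes
        truth[ids[0]], truth[ids[1]] = 0, 1
    # ties are common on purpose: scores drawn from a small grid
    scores = ScoreSet({i: float(rng.choice([0.0, 0.25, 0.5, 0.75, 1.0])) for i in ids})
    return scores, truth


def brute_force_pr(scores: ScoreSet, truth: dict) -> tuple[list, list, list]:
    """Per-threshold confusion counting, independent of the implementation."""
    ids = list(scores.scores)
    thresholds = sorted(set(scores.scores.values()), reverse=True)
    precision, recall = [], []
    n_pos = sum(truth.values())
    for t in thresholds:
        tp = sum(1 for i in ids if scores.scores[i] >= t and truth[i] == 1)
        fp = sum(1 for i in ids if scores.scores[i] >= t and truth[i] == 0)
        precision.append(tp / (tp + fp))
        recall.append(tp / n_pos)
    return thresholds, precision, recall


class TestPRCurve:
    def test_two_item_hand_enumeration(self):
        scores = ScoreSet({"pos": 0.9, "neg": 0.1})
        curve = clf.pr_curve(scores, {"pos": 1, "neg": 0})
        assert curve.thresholds.tolist() == [0.9, 0.1]
        assert curve.precision.tolist() == [1.0, 0.5]
        assert curve.recall.tolist() == [1.0, 1.0]

    def test_total_tie_collapses_to_prevalence_point(self):
        scores = ScoreSet({f"i{k}": 1.0 for k in range(10)})
        truth = {f"i{k}": int(k < 3) for k in range(10)}
        curve = clf.pr_curve(scores, truth)
        assert len(curve) == 1
        assert curve.precision[0] == pytest.approx(0.3)
        assert curve.recall[0] == 1.0

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force_confusion_counting(self, seed):
        scores, truth = make_instance(50, seed)
        curve = clf.pr_curve(scores, truth)
        t_ref, p_ref, r_ref = brute_force_pr(scores, truth)
        assert curve.thresholds.tolist() == t_ref
        assert curve.precision.tolist() == pytest.approx(p_ref)
        assert curve.recall.tolist() == pytest.approx(r_ref)

    def test_recall_monotone_and_terminal(self):
        scores, truth = make_instance(80, 9)
        curve = clf.pr_curve(scores, truth)
        assert (np.diff(curve.recall) >= 0).all()
        assert curve.recall[-1] == 1.0

    def test_single_class_rejected(self):
        scores = ScoreSet({"a": 1.0, "b": 0.5})
        with pytest.raises(ValidationError):
            clf.pr_curve(scores, {"a": 1, "b": 1})


class TestAveragePrecision:
    def test_perfect_separation(self):
        scores = ScoreSet({"a": 2.0, "b": 1.0, "c": 0.1})
        assert clf.average_precision(scores, {"a": 1, "b": 1, "c": 0}) == 1.0

    def test_negative_ranked_above_positive(self):
        scores = ScoreSet({"neg": 0.9, "pos": 0.1})
        assert clf.average_precision(scores, {"neg": 0, "pos": 1}) == 0.5

    def test_constant_scores_give_prevalence(self):
        scores = ScoreSet({f"i{k}": 0.5 for k in range(20)})
        truth = {f"i{k}": int(k < 7) for k in range(20)}
        assert clf.average_precision(scores, truth) == pytest.approx(7 / 20)

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_sklearn_oracle(self, seed):
        scores, truth = make_instance(40, seed)
        ids = list(scores.scores)
        ours = clf.average_precision(scores, truth)
        ref = average_precision_score(
            [truth[i] for i in ids], [scores.scores[i] for i in ids]
        )
        assert ours == pytest.approx(ref, abs=1e-12)

    def test_invariant_under_monotone_transform(self):
        scores, truth = make_instance(60, 3)
        base = clf.average_precision(scores, truth)
        for f in (lambda s: 3 * s + 1, np.exp, lambda s: np.arctan(s) * 2):
            warped = ScoreSet({i: float(f(s)) for i, s in scores.scores.items()})
            assert clf.average_precision(warped, truth) == pytest.approx(base, abs=1e-12)


class TestMeanAveragePrecision:
    def test_exact_scores_give_one(self):
        labels = LabelSet("t", {"a": 0, "b": 1, "c": 2, "d": 1})
        scores = ScoreSet({i: float(v) for i, v in labels.labels.items()})
        assert clf.mean_average_precision(scores, labels) == 1.0

    def test_constant_scores_give_mean_prevalence_on_test_mix(self):
        # the published test split: 494 / 193 / 154 images per grade
        labels = {}
        k = 0
        for grade, count in enumerate((494, 193, 154)):
            for _ in range(count):
                labels[f"i{k}"] = grade
                k += 1
        truth = LabelSet("t", labels)
        scores = ScoreSet({i: 0.0 for i in labels})
        expected = ((193 + 154) / 841 + 154 / 841) / 2
        got = clf.mean_average_precision(scores, truth)
        assert got == pytest.approx(expected, abs=1e-12)
        assert got == pytest.approx(0.298, abs=5e-4)

    def test_decomposes_into_single_task_aps(self):
        rng = np.random.default_rng(8)
        labels = LabelSet("t", {f"i{k}": int(rng.integers(0, 3)) for k in range(200)})
        scores = ScoreSet({i: float(rng.normal()) for i in labels.labels})
        from slofgrade.agreement import binarise

        aps = [
            clf.average_precision(
                scores, {i: binarise(v, task) for i, v in labels.labels.items()}
            )
            for task in BinaryTask
        ]
        assert clf.mean_average_precision(scores, labels) == pytest.approx(np.mean(aps))

    def test_degenerate_task_named_in_error(self):
        labels = LabelSet("t", {"a": 0, "b": 1})  # heavy task has no positive
        scores = ScoreSet({"a": 0.0, "b": 1.0})
        with pytest.raises(ValidationError, match="heavy"):
            clf.mean_average_precision(scores, labels)


class TestSelectThreshold:
    def _curve(self):
        scores = ScoreSet({"p1": 2.0, "p2": 1.0, "n1": 0.5})
        return clf.pr_curve(scores, {"p1": 1, "p2": 1, "n1": 0})

    def test_enumerated_targets(self):
        curve = self._curve()
        assert clf.select_threshold(curve, 0.8) == 1.0
        assert clf.select_threshold(curve, 0.5) == 2.0

    def test_full_recall_threshold_at_or_below_minimum_positive(self):
        curve = self._curve()
        assert clf.select_threshold(curve, 1.0) <= 1.0

    @pytest.mark.parametrize("seed", range(5))
    def test_recall_floor_met_exactly_on_own_curve(self, seed):
        scores, truth = make_instance(60, seed + 100)
        curve = clf.pr_curve(scores, truth)
        for target in (0.5, 0.8, 0.95, 1.0):
            t = clf.select_threshold(curve, target)
            idx = np.flatnonzero(curve.thresholds == t)[0]
            assert curve.recall[idx] >= target

    @pytest.mark.parametrize("seed", range(5))
    def test_lower_target_never_lowers_precision(self, seed):
        scores, truth = make_instance(60, seed + 200)
        curve = clf.pr_curve(scores, truth)
        precisions = []
        for target in (0.95, 0.8, 0.5):
            t = clf.select_threshold(curve, target)
            idx = np.flatnonzero(curve.thresholds == t)[0]
            precisions.append(curve.precision[idx])
        assert precisions[0] <= precisions[1] <= precisions[2] or (
            np.diff(precisions) >= -1e-12
        ).all()


class TestApplyThresholds:
    def test_published_balanced_cutoffs(self):
        # the 80%-recall policy cutoffs from the study: 0.413 and 1.242
        th = clf.ClassifierThresholds(0.413, 1.242, 0.8)
        scores = ScoreSet({"a": 0.2, "b": 0.9, "c": 1.3})
        labels = clf.apply_thresholds(scores, th)
        assert labels.labels == {"a": 0, "b": 1, "c": 2}

    def test_boundary_score_takes_higher_class(self):
        th = clf.ClassifierThresholds(0.5, 1.5, 0.8)
        scores = ScoreSet({"a": 0.5, "b": 1.5})
        labels = clf.apply_thresholds(scores, th)
        assert labels.labels == {"a": 1, "b": 2}

    def test_crossed_thresholds_heavy_wins_with_warning(self):
        with pytest.warns(UserWarning, match="heavy"):
            th = clf.ClassifierThresholds(1.5, 0.5, 0.8)
        scores = ScoreSet({"a": 1.0})
        assert clf.apply_thresholds(scores, th).labels == {"a": 2}


class TestEvaluateClassifier:
    def test_identity_prediction(self):
        truth = LabelSet("t", {"a": 0, "b": 1, "c": 2, "d": 1})
        ev = clf.evaluate_classifier(truth, truth)
        assert (ev.confusion == np.diag([1, 2, 1])).all()
        for task in BinaryTask:
            assert ev.precision[task].estimate == 1.0
            assert ev.recall[task].estimate == 1.0

    def test_confusion_conserves_image_count(self):
        rng = np.random.default_rng(2)
        truth = LabelSet("t", {f"i{k}": int(rng.integers(0, 3)) for k in range(37)})
        pred = LabelSet("p", {i: int(rng.integers(0, 3)) for i in truth.labels})
        ev = clf.evaluate_classifier(pred, truth)
        assert ev.confusion.sum() == 37

    def test_hand_built_six_image_case(self):
        truth = LabelSet("t", dict(zip("abcdef", [0, 0, 1, 1, 2, 2])))
        pred = LabelSet("p", dict(zip("abcdef", [0, 1, 1, 2, 2, 0])))
        ev = clf.evaluate_classifier(pred, truth)
        expected = np.array([[1, 1, 0], [0, 1, 1], [1, 0, 1]])
        assert (ev.confusion == expected).all()
        # fouling: truth pos {c,d,e,f}; predicted pos {b,c,d,e}
        assert ev.precision[BinaryTask.FOULING].estimate == pytest.approx(3 / 4)
        assert ev.recall[BinaryTask.FOULING].estimate == pytest.approx(3 / 4)
        # heavy: truth pos {e,f}; predicted pos {d,e}
        assert ev.precision[BinaryTask.HEAVY].estimate == pytest.approx(1 / 2)
        assert ev.recall[BinaryTask.HEAVY].estimate == pytest.approx(1 / 2)

    def test_id_mismatch_rejected(self):
        with pytest.raises(ValidationError):
            clf.evaluate_classifier(LabelSet("p", {"a": 0}), LabelSet("t", {"b": 0}))


class TestFileInterfaces:
    def test_scores_csv_roundtrip(self, tmp_path):
        sets = [
            ScoreSet({"a": 0.5, "b": 1.25}, fold=0),
            ScoreSet({"c": 2.0}, fold=1),
        ]
        path = tmp_path / "scores.csv"
        clf.write_scores_csv(sets, path)
        back = clf.read_scores_csv(path)
        assert [ss.scores for ss in back] == [ss.scores for ss in sets]
        assert [ss.fold for ss in back] == [0, 1]

    def test_thresholds_json_roundtrip(self, tmp_path):
        th = clf.ClassifierThresholds(0.413, 1.242, 0.8)
        path = tmp_path / "th.json"
        clf.write_thresholds_json(th, path)
        assert clf.read_thresholds_json(path) == th
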