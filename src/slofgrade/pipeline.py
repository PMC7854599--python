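"""End-to-end orchestration: generate -> rate -> score -> threshold ->
evaluate -> compare, with report tables.

The report bundle mirrors the study's outputs:

* a threshold table (split, task, recall target, threshold, precision,
  recall) for the three classifier policies on the out-of-fold validation
  scores and on the held-out test split;
* a label-pairs table (candidate, task, n pairs, agreement, recall,
  precision with Wilson CIs, Fisher p-values against the expert group and
  the non-inferiority p-value at the 5% margin);
* 3x3 confusion matrices between the expert group and each candidate.

Every artefact carries the seed and a hash of the configuration.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import classifier as clf
from . import model as mdl
from . import synthetic as syn
from .agreement import (
    BinaryTask,
    binarise,
    make_group_pairs,
    make_rater_vs_group_pairs,
    summarise_pairs,
)
from .exceptions import ValidationError
from .stats import fisher_exact_two_sided, tost_noninferiority_prop
from .synthetic import LabelSet, ScoreSet

__all__ = ["RunConfig", "demo_config", "run_pipeline"]

log = logging.getLogger("slofgrade")


@dataclass
class RunConfig:
    """One pipeline run, reproducible from this object and nothing else."""

    seed: int = 0
    out_dir: str = "slofgrade_run"
    # dataset structure
    n_per_class: tuple[int, int, int] = (300, 180, 120)
    test_per_class: tuple[int, int, int] = (75, 45, 30)
    n_expert_group: int = 60
    n_train_vessels: int = 25
    n_test_vessels: int = 5
    image_size: int = 64
    # raters
    n_raters: int = 3
    # scoring: "train" fits the CNN; "simulate" draws noisy scores;
    # "external" reads scores_path (CSV written by a previous run)
    score_source: str = "train"
    noise_sd: float = 0.25
    scores_path: str | None = None
    train: mdl.TrainConfig = field(default_factory=mdl.TrainConfig)
    # decision policy
    recall_targets: tuple[float, ...] = (0.5, 0.8, 0.95)
    margin: float = 0.05
    alpha: float = 0.05

    def __post_init__(self) -> None:
        if not all(0.0 < r <= 1.0 for r in self.recall_targets):
            raise ValidationError("recall targets must lie in (0, 1]")
        if not 0.0 < self.margin < 1.0:
            raise ValidationError("margin must lie in (0, 1)")
        if not 0.0 < self.alpha < 1.0:
            raise ValidationError("alpha must lie in (0, 1)")
        if self.score_source not in ("train", "simulate", "external"):
            raise ValidationError(f"unknown score_source {self.score_source!r}")
        if self.score_source == "external" and not self.scores_path:
            raise ValidationError("score_source 'external' requires scores_path")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "RunConfig":
        d = dict(d)
        if "train" in d and isinstance(d["train"], Mapping):
            d["train"] = mdl.TrainConfig(**d["train"])
        for key in ("n_per_class", "test_per_class", "recall_targets"):
            if key in d and d[key] is not None:
                d[key] = tuple(d[key])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def demo_config(seed: int = 0, out_dir: str | Path = "slofgrade_demo") -> RunConfig:
    """The desk-scale reference run: 600 synthetic images, tiny CNN,
    5-fold vessel-grouped CV, thresholds at 50/80/95% recall, comparison
    against three simulated experts."""
    return RunConfig(
        seed=seed,
        out_dir=str(out_dir),
        n_per_class=(300, 180, 120),
        test_per_class=(75, 45, 30),
        n_expert_group=60,
        n_train_vessels=25,
        n_test_vessels=5,
        image_size=64,
        score_source="train",
        train=mdl.TrainConfig(seed=seed, epochs=24, folds=5, image_size=48),
        recall_targets=(0.5, 0.8, 0.95),
    )


def _fmt(x: float | None, digits: int = 4) -> float | str:
    return "" if x is None else round(float(x), digits)


def _scores_subset(scores: Mapping[str, float], ids: Sequence[str],
                   provenance: str) -> ScoreSet:
    missing = [i for i in ids if i not in scores]
    if missing:
        raise ValidationError(f"no scores for images {missing[:5]}")
    return ScoreSet(scores={i: scores[i] for i in ids}, provenance=provenance)


def _threshold_rows(
    split_name: str,
    scores: ScoreSet,
    truth: Mapping[str, int],
    thresholds: Mapping[float, clf.ClassifierThresholds],
) -> list[dict]:
    rows = []
    for target, th in thresholds.items():
        for task, cutoff in (
            (BinaryTask.FOULING, th.fouling_threshold),
            (BinaryTask.HEAVY, th.heavy_threshold),
        ):
            t = np.array([binarise(truth[i], task) for i in sorted(scores.scores)])
            c = np.array(
                [int(scores.scores[i] >= cutoff) for i in sorted(scores.scores)]
            )
            tp = int(np.sum(t & c))
            fp = int(np.sum((1 - t) & c))
            fn = int(np.sum(t & (1 - c)))
            rows.append(
                {
                    "split": split_name,
                    "task": task.value,
                    "recall_target": target,
                    "threshold": round(cutoff, 6),
                    "precision": _fmt(tp / (tp + fp) if tp + fp else None),
                    "recall": _fmt(tp / (tp + fn) if tp + fn else None),
                }
            )
    return rows


def _pair_confusion(pairs) -> np.ndarray:
    m = np.zeros((3, 3), dtype=int)
    for p in pairs:
        m[p.reference, p.candidate] += 1
    return m


def _comparison_rows(
    group_sets: Sequence[LabelSet],
    candidates: Mapping[str, LabelSet],
    margin: float,
) -> tuple[list[dict], dict[str, np.ndarray]]:
    group_pairs = make_group_pairs(group_sets)
    group_summary = summarise_pairs(group_pairs)
    rows = []
    confusions = {"expert_group": _pair_confusion(group_pairs)}

    for task in BinaryTask:
        agree = group_summary.agreement[task]
        rec = group_summary.recall[task]
        prec = group_summary.precision[task]
        rows.append(
            {
                "labels": "expert_group",
                "task": task.value,
                "n_pairs": group_summary.n_pairs,
                "agreement": _fmt(agree.estimate),
                "agreement_lo": _fmt(agree.ci[0]),
                "agreement_hi": _fmt(agree.ci[1]),
                "tost_p": "",
                "recall": _fmt(rec.estimate),
                "recall_lo": _fmt(rec.ci[0]),
                "recall_hi": _fmt(rec.ci[1]),
                "recall_fisher_p": "",
                "precision": _fmt(prec.estimate),
                "precision_lo": _fmt(prec.ci[0]),
                "precision_hi": _fmt(prec.ci[1]),
                "precision_fisher_p": "",
            }
        )

    for name, cand in candidates.items():
        pairs = make_rater_vs_group_pairs(cand, group_sets)
        summary = summarise_pairs(pairs)
        confusions[name] = _pair_confusion(pairs)
        for task in BinaryTask:
            g_agree = group_summary.agreement[task]
            agree = summary.agreement[task]
            tost = tost_noninferiority_prop(
                g_agree.successes, g_agree.trials,
                agree.successes, agree.trials, margin=margin,
            )
            row = {
                "labels": name,
                "task": task.value,
                "n_pairs": summary.n_pairs,
                "agreement": _fmt(agree.estimate),
                "agreement_lo": _fmt(agree.ci[0]),
                "agreement_hi": _fmt(agree.ci[1]),
                "tost_p": _fmt(tost.p),
            }
            for metric in ("recall", "precision"):
                g: "BinomialEstimate" = getattr(group_summary, metric)[task]
                c = getattr(summary, metric)[task]
                if c.defined and g.defined:
                    p, _ = fisher_exact_two_sided(
                        ((g.successes, g.trials - g.successes),
                         (c.successes, c.trials - c.successes))
                    )
                    row.update(
                        {
                            metric: _fmt(c.estimate),
                            f"{metric}_lo": _fmt(c.ci[0]),
                            f"{metric}_hi": _fmt(c.ci[1]),
                            f"{metric}_fisher_p": _fmt(p),
                        }
                    )
                else:
                    row.update(
                        {metric: "", f"{metric}_lo": "", f"{metric}_hi": "",
                         f"{metric}_fisher_p": ""}
                    )
            rows.append(row)
    return rows, confusions


def run_pipeline(config: RunConfig) -> dict:
    """Execute every stage and write the report bundle under out_dir.

    Returns a summary dict with the key numbers (out-of-fold and test mean
    AP, thresholds per policy, comparison rows) for programmatic use.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report_dir = out / "report"
    report_dir.mkdir(exist_ok=True)
    logging.basicConfig(
        stream=sys.stderr,
        level=logging.INFO,
        format="%(asctime)s [%(name)s] %(message)s",
    )

    # --- stage: generate -------------------------------------------------
    render = config.score_source == "train"
    log.info("stage=generate n=%s render=%s", sum(config.n_per_class), render)
    manifest = syn.generate_dataset(
        config.n_per_class,
        test_per_class=config.test_per_class,
        n_expert_group=config.n_expert_group,
        n_train_vessels=config.n_train_vessels,
        n_test_vessels=config.n_test_vessels,
        image_size=config.image_size,
        out_dir=out / "data",
        seed=config.seed,
        render=render,
    )
    train_split = manifest.subset("train")
    test_split = manifest.subset("test")
    eg_split = manifest.subset("expert_group")
    truth = manifest.true_labels()

    # --- stage: simulate raters ------------------------------------------
    log.info("stage=rate experts=%d images=%d", config.n_raters, len(eg_split))
    profiles = syn.default_expert_profiles(config.n_raters + 1, seed=config.seed)
    group_profiles, expert_profile = profiles[: config.n_raters], profiles[-1]
    group_sets = syn.simulate_raters(eg_split, group_profiles, seed=config.seed)
    expert_set = syn.simulate_raters(eg_split, [expert_profile], seed=config.seed)[0]
    expert_set = LabelSet(rater_id="expert", labels=expert_set.labels)
    syn.write_labels(group_sets + [expert_set], out / "labels.csv")

    # --- stage: scores ----------------------------------------------------
    log.info("stage=score source=%s", config.score_source)
    if config.score_source == "train":
        images = mdl.load_images(manifest, out / "data", size=config.train.image_size)
        cv = mdl.crossval_scores(train_split, config.train, images, run_dir=out / "runs")
        oof_scores = cv.combined
        final = mdl.Scorer(config.train, syn.derive_seed(config.train.seed, "final"))
        rng = np.random.default_rng(syn.derive_seed(config.train.seed, "final", "train"))
        final.fit(train_split.records, images, rng)
        held_ids = [r.image_id for r in test_split.records + eg_split.records]
        held_scores = final.predict(held_ids, images)
        clf.write_scores_csv(cv.per_fold + [held_scores], out / "scores.csv")
    elif config.score_source == "simulate":
        all_scores = syn.simulate_scores(manifest, config.noise_sd, seed=config.seed)
        oof_scores = _scores_subset(
            all_scores.scores, [r.image_id for r in train_split.records], "simulated"
        )
        held_scores = _scores_subset(
            all_scores.scores,
            [r.image_id for r in test_split.records + eg_split.records],
            "simulated",
        )
        clf.write_scores_csv([all_scores], out / "scores.csv")
    else:  # external
        sets = clf.read_scores_csv(config.scores_path)
        merged: dict[str, float] = {}
        for ss in sets:
            merged.update(ss.scores)
        oof_scores = _scores_subset(
            merged, [r.image_id for r in train_split.records], "single_model"
        )
        held_scores = _scores_subset(
            merged,
            [r.image_id for r in test_split.records + eg_split.records],
            "single_model",
        )

    # --- stage: thresholds ------------------------------------------------
    log.info("stage=thresholds targets=%s", config.recall_targets)
    curves = {
        task: clf.pr_curve(
            oof_scores,
            {r.image_id: binarise(r.slof, task) for r in train_split.records},
            task=task,
        )
        for task in BinaryTask
    }
    thresholds: dict[float, clf.ClassifierThresholds] = {}
    for target in config.recall_targets:
        th = clf.ClassifierThresholds(
            fouling_threshold=clf.select_threshold(curves[BinaryTask.FOULING], target),
            heavy_threshold=clf.select_threshold(curves[BinaryTask.HEAVY], target),
            recall_target=target,
        )
        thresholds[target] = th
        clf.write_thresholds_json(th, out / f"thresholds_r{int(round(target * 100))}.json")

    # --- stage: evaluate --------------------------------------------------
    log.info("stage=evaluate")
    oof_map = clf.mean_average_precision(
        oof_scores, LabelSet("truth", {r.image_id: truth[r.image_id]
                                       for r in train_split.records})
    )
    test_scores = _scores_subset(
        held_scores.scores, [r.image_id for r in test_split.records],
        held_scores.provenance,
    )
    test_map = clf.mean_average_precision(
        test_scores, LabelSet("truth", {r.image_id: truth[r.image_id]
                                        for r in test_split.records})
    )
    table4 = _threshold_rows("validation", oof_scores, truth, thresholds)
    table4 += _threshold_rows("test", test_scores, truth, thresholds)
    pd.DataFrame(table4).to_csv(report_dir / "thresholds_table.csv", index=False)

    # --- stage: compare ---------------------------------------------------
    log.info("stage=compare pairs=%dx%d", len(eg_split), config.n_raters)
    eg_scores = _scores_subset(
        held_scores.scores, [r.image_id for r in eg_split.records],
        held_scores.provenance,
    )
    candidates: dict[str, LabelSet] = {"expert": expert_set}
    for target, th in thresholds.items():
        name = f"classifier_r{int(round(target * 100))}"
        candidates[name] = LabelSet(name, clf.apply_thresholds(eg_scores, th).labels)
    table5, confusions = _comparison_rows(group_sets, candidates, config.margin)
    pd.DataFrame(table5).to_csv(report_dir / "label_pairs_table.csv", index=False)
    for name, m in confusions.items():
        pd.DataFrame(
            m,
            index=[f"ref_slof{i}" for i in range(3)],
            columns=[f"cand_slof{i}" for i in range(3)],
        ).to_csv(report_dir / f"confusion_{name}.csv")

    meta = {
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "oof_mean_ap": round(oof_map, 6),
        "test_mean_ap": round(test_map, 6),
    }
    (out / "run_meta.json").write_text(json.dumps(meta, indent=2, sort_keys=True) + "\n")
    with open(out / "config.yaml", "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=True)

    log.info("done oof_mean_ap=%.3f test_mean_ap=%.3f", oof_map, test_map)
    return {
        "oof_mean_ap": oof_map,
        "test_mean_ap": test_map,
        "thresholds": {t: dataclasses.asdict(th) for t, th in thresholds.items()},
        "table4": table4,
        "table5": table5,
        "confusions": confusions,
        "out_dir": str(out),
    }
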