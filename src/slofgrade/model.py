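"""Ordinal-regression scorer networks for fouling severity.

The grading problem is ordinal (mistaking heavy fouling for a clean hull
is worse than mistaking it for patchy fouling), so instead of a softmax
classifier the model regresses a single raw score against the SLoF class
index, with per-sample weights inversely proportional to class frequency
to undo the heavy class imbalance of survey data.  Scores are produced
out-of-fold under vessel-grouped cross-validation, ensembled by averaging,
and handed to :mod:`slofgrade.classifier` for thresholding.

The trainable network is implemented directly in numpy:

* ``tiny_cnn`` — one 5x5 convolution (8 filters), ReLU, 4x4 average
  pooling, then a small fully connected head; trained by minibatch
  gradient descent with manual backpropagation;
* ``linear`` — a linear map on the downsampled pixels, as a floor
  baseline.

Both support MSE and smooth-L1 losses, SGD-with-momentum and AdamW
updates, multistep / cosine / one-cycle learning-rate schedules and two
augmentation pipelines (flips and crops; plus rotations and colour /
contrast jitter).  Training is single-threaded and a pure function of the
configuration seed.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from PIL import Image

from .classifier import mean_average_precision
from .exceptions import ValidationError
from .synthetic import DatasetManifest, ImageRecord, LabelSet, ScoreSet, derive_seed

__all__ = [
    "TrainConfig",
    "ClassWeights",
    "CrossvalResult",
    "class_weights",
    "weighted_regression_loss",
    "split_folds",
    "load_images",
    "Scorer",
    "train_scorer",
    "crossval_scores",
    "ensemble_scores",
    "best_subset_ensemble",
    "sobol_candidates",
]


@dataclass(frozen=True)
class TrainConfig:
    """Everything that determines one training run."""

    loss_kind: str = "smooth_l1"          # mse | smooth_l1
    image_size: int = 48                  # network input side in pixels
    batch_size: int = 64
    epochs: int = 24
    folds: int = 5
    optimiser_name: str = "adamw"         # sgd | adamw
    learning_rate: float = 3e-3
    weight_decay: float = 1e-4
    momentum: float = 0.9
    schedule: str = "cosine"              # multistep | onecycle | cosine
    augmentation: str = "basic"           # basic | complex
    freeze_batch_norm: bool = True        # no-op for the numpy nets (no BN layers)
    seed: int = 0
    architecture: str = "tiny_cnn"        # tiny_cnn | linear

    def __post_init__(self) -> None:
        if self.loss_kind not in ("mse", "smooth_l1"):
            raise ValidationError(f"unknown loss_kind {self.loss_kind!r}")
        if self.optimiser_name not in ("sgd", "adamw"):
            raise ValidationError(f"unknown optimiser {self.optimiser_name!r}")
        if self.schedule not in ("multistep", "onecycle", "cosine"):
            raise ValidationError(f"unknown schedule {self.schedule!r}")
        if self.augmentation not in ("basic", "complex"):
            raise ValidationError(f"unknown augmentation {self.augmentation!r}")
        if self.architecture not in ("tiny_cnn", "linear"):
            raise ValidationError(f"unknown architecture {self.architecture!r}")
        if self.epochs < 0:
            raise ValidationError("epochs must be non-negative")
        if self.folds < 2:
            raise ValidationError("folds must be at least 2")
        if self.batch_size < 1:
            raise ValidationError("batch_size must be positive")
        if self.image_size < 16:
            raise ValidationError("image_size must be at least 16")


@dataclass(frozen=True)
class ClassWeights:
    """Per-class loss weights ``w_c = N / (K * n_c)``; re-weighted samples
    contribute as if the classes were balanced (sum_c n_c w_c = N)."""

    w: tuple[float, float, float]


def class_weights(counts: Sequence[int]) -> ClassWeights:
    counts = [int(c) for c in counts]
    if len(counts) != 3:
        raise ValidationError("counts must have three entries")
    if any(c <= 0 for c in counts):
        raise ValidationError(
            f"every class must be present in the training fold, got counts {counts}"
        )
    n = sum(counts)
    return ClassWeights(w=tuple(n / (3 * c) for c in counts))


def weighted_regression_loss(
    predictions: np.ndarray,
    targets: np.ndarray,
    weights: np.ndarray,
    loss_kind: str,
) -> float:
    """Mean over samples of ``w_i * l(pred_i - target_i)``.

    ``l(r)`` is ``r**2`` for MSE and the Huber-style smooth-L1
    (``0.5 r**2`` for |r| < 1, else ``|r| - 0.5``).
    """
    predictions = np.asarray(predictions, dtype=float)
    targets = np.asarray(targets, dtype=float)
    weights = np.asarray(weights, dtype=float)
    if not (predictions.shape == targets.shape == weights.shape):
        raise ValidationError("predictions, targets and weights must align")
    if not (np.isfinite(predictions).all() and np.isfinite(targets).all()
            and np.isfinite(weights).all()):
        raise ValidationError("inputs must be finite")
    if (weights <= 0).any():
        raise ValidationError("weights must be positive")
    r = predictions - targets
    if loss_kind == "mse":
        l = r * r
    elif loss_kind == "smooth_l1":
        a = np.abs(r)
        l = np.where(a < 1.0, 0.5 * r * r, a - 0.5)
    else:
        raise ValidationError(f"unknown loss_kind {loss_kind!r}")
    return float(np.mean(weights * l))


def _loss_grad(r: np.ndarray, loss_kind: str) -> np.ndarray:
    if loss_kind == "mse":
        return 2.0 * r
    return np.clip(r, -1.0, 1.0)


# ---------------------------------------------------------------------------
# vessel-grouped, class-stratified fold assignment

def split_folds(
    manifest: DatasetManifest, folds: int, seed: int
) -> dict[str, int]:
    """Assign each image a fold such that no vessel spans folds.

    Vessels are assigned greedily (largest first, seeded shuffle breaking
    ties): each goes to the fold where it least unbalances the per-fold
    class counts and fold sizes.  This keeps the class mix of each fold
    close to the global mix while keeping every vessel intact.
    """
    if folds < 2:
        raise ValidationError("folds must be at least 2")
    by_vessel: dict[str, list[ImageRecord]] = {}
    for rec in manifest.records:
        by_vessel.setdefault(rec.vessel_id, []).append(rec)
    vessels = sorted(by_vessel)
    if len(vessels) < folds:
        raise ValidationError(
            f"{len(vessels)} vessels cannot fill {folds} folds without leakage"
        )
    rng = np.random.default_rng(derive_seed(seed, "folds"))
    order = list(rng.permutation(vessels))
    order.sort(key=lambda v: -len(by_vessel[v]))

    global_props = np.bincount(
        [r.slof for r in manifest.records], minlength=3
    ) / len(manifest.records)
    fold_counts = np.zeros((folds, 3))
    fold_sizes = np.zeros(folds)
    assignment: dict[str, int] = {}
    for vessel in order:
        v_counts = np.bincount([r.slof for r in by_vessel[vessel]], minlength=3)
        v_size = v_counts.sum()
        # least-filled folds first (keeps sizes balanced and every fold
        # populated); among those, the fold whose class mix the vessel
        # best restores towards the global mix
        candidates = np.flatnonzero(fold_sizes == fold_sizes.min())
        class_dev = [
            float(
                np.sum(
                    (fold_counts[f] + v_counts
                     - (fold_sizes[f] + v_size) * global_props) ** 2
                )
            )
            for f in candidates
        ]
        f = int(candidates[int(np.argmin(class_dev))])
        fold_counts[f] += v_counts
        fold_sizes[f] += v_size
        for rec in by_vessel[vessel]:
            assignment[rec.image_id] = f
    return assignment


# ---------------------------------------------------------------------------
# pixel I/O

def _area_resize(img: np.ndarray, size: int) -> np.ndarray:
    """Mean-pooling (area) resize to ``size x size``; nearest when upsizing."""
    h, w = img.shape[:2]
    if h < size or w < size:
        yi = (np.arange(size) * h) // size
        xi = (np.arange(size) * w) // size
        return img[yi][:, xi]
    ye = (np.arange(size + 1) * h) // size
    xe = (np.arange(size + 1) * w) // size
    t = np.add.reduceat(img, ye[:-1], axis=0)
    t = np.add.reduceat(t, xe[:-1], axis=1)
    counts = np.outer(np.diff(ye), np.diff(xe)).astype(img.dtype)
    return t / counts[..., None]


def load_images(
    manifest: DatasetManifest, root: str | Path, size: int = 48
) -> dict[str, np.ndarray]:
    """Load and area-resize every manifest image to ``size x size x 3`` floats."""
    root = Path(root)
    out = {}
    for rec in manifest.records:
        arr = np.asarray(Image.open(root / rec.path).convert("RGB"), dtype=np.float32)
        out[rec.image_id] = _area_resize(arr / 255.0, size)
    return out


# ---------------------------------------------------------------------------
# networks

class _TinyCNN:
    """conv(3->8, 5x5) + ReLU + 4x4 mean pool + fc(32) + ReLU + fc(1)."""

    FILTERS = 8
    KERNEL = 5
    POOL = 4
    HIDDEN = 32

    def __init__(self, image_size: int, rng: np.random.Generator):
        k, f = self.KERNEL, self.FILTERS
        self.image_size = image_size
        self.conv_out = image_size - k + 1
        if self.conv_out % self.POOL:
            raise ValidationError(
                f"image_size {image_size} must give a conv output divisible by "
                f"{self.POOL} (e.g. 48)"
            )
        self.pooled = self.conv_out // self.POOL
        flat = self.pooled * self.pooled * f
        he = lambda fan_in: math.sqrt(2.0 / fan_in)
        self.params = {
            "W1": rng.normal(0, he(k * k * 3), size=(k * k * 3, f)).astype(np.float32),
            "b1": np.zeros(f, dtype=np.float32),
            "W2": rng.normal(0, he(flat), size=(flat, self.HIDDEN)).astype(np.float32),
            "b2": np.zeros(self.HIDDEN, dtype=np.float32),
            "W3": rng.normal(0, he(self.HIDDEN), size=(self.HIDDEN, 1)).astype(np.float32),
            "b3": np.zeros(1, dtype=np.float32),
        }

    def _patches(self, x: np.ndarray) -> np.ndarray:
        k = self.KERNEL
        win = sliding_window_view(x, (k, k, 3), axis=(1, 2, 3))
        b, oh, ow = x.shape[0], self.conv_out, self.conv_out
        return win.reshape(b, oh, ow, k * k * 3)

    def forward(self, x: np.ndarray, want_cache: bool = False):
        p = self.params
        b = x.shape[0]
        patches = self._patches(x)
        conv = patches @ p["W1"] + p["b1"]
        relu1 = conv > 0
        conv *= relu1
        s = self.pooled
        pool = conv.reshape(b, s, self.POOL, s, self.POOL, self.FILTERS).mean(axis=(2, 4))
        flat = pool.reshape(b, -1)
        h = flat @ p["W2"] + p["b2"]
        relu2 = h > 0
        h = h * relu2
        out = (h @ p["W3"] + p["b3"]).ravel()
        if not want_cache:
            return out, None
        return out, (patches, relu1, flat, relu2, h)

    def backward(self, cache, dout: np.ndarray) -> dict[str, np.ndarray]:
        p = self.params
        patches, relu1, flat, relu2, h = cache
        b = dout.shape[0]
        dout = dout.reshape(b, 1).astype(np.float32)
        grads = {
            "W3": h.T @ dout,
            "b3": dout.sum(axis=0),
        }
        dh = (dout @ p["W3"].T) * relu2
        grads["W2"] = flat.T @ dh
        grads["b2"] = dh.sum(axis=0)
        dflat = dh @ p["W2"].T
        s, pl, f = self.pooled, self.POOL, self.FILTERS
        dpool = dflat.reshape(b, s, s, f) / (pl * pl)
        dconv = np.repeat(np.repeat(dpool, pl, axis=1), pl, axis=2) * relu1
        grads["W1"] = patches.reshape(-1, patches.shape[-1]).T @ dconv.reshape(-1, f)
        grads["b1"] = dconv.sum(axis=(0, 1, 2))
        return grads


class _LinearNet:
    """Linear regression on 8x8 mean-pooled pixels; the floor baseline."""

    SIDE = 8

    def __init__(self, image_size: int, rng: np.random.Generator):
        self.image_size = image_size
        d = self.SIDE * self.SIDE * 3
        self.params = {
            "W": rng.normal(0, math.sqrt(1.0 / d), size=(d, 1)).astype(np.float32),
            "b": np.zeros(1, dtype=np.float32),
        }

    def _features(self, x: np.ndarray) -> np.ndarray:
        b = x.shape[0]
        side = self.SIDE
        step = self.image_size // side
        usable = side * step
        pooled = (
            x[:, :usable, :usable]
            .reshape(b, side, step, side, step, 3)
            .mean(axis=(2, 4))
        )
        return pooled.reshape(b, -1)

    def forward(self, x: np.ndarray, want_cache: bool = False):
        feats = self._features(x)
        out = (feats @ self.params["W"] + self.params["b"]).ravel()
        return out, (feats if want_cache else None)

    def backward(self, cache, dout: np.ndarray) -> dict[str, np.ndarray]:
        feats = cache
        dout = dout.reshape(-1, 1).astype(np.float32)
        return {"W": feats.T @ dout, "b": dout.sum(axis=0)}


def _make_net(config: TrainConfig, rng: np.random.Generator):
    if config.architecture == "tiny_cnn":
        return _TinyCNN(config.image_size, rng)
    return _LinearNet(config.image_size, rng)


# ---------------------------------------------------------------------------
# optimisers and schedules

class _SGD:
    def __init__(self, params, momentum, weight_decay):
        self.momentum = momentum
        self.weight_decay = weight_decay
        self.v = {k: np.zeros_like(v) for k, v in params.items()}

    def step(self, params, grads, lr):
        for k in params:
            g = grads[k] + self.weight_decay * params[k]
            self.v[k] = self.momentum * self.v[k] - lr * g
            params[k] += self.v[k]


class _AdamW:
    def __init__(self, params, weight_decay, beta1=0.9, beta2=0.999, eps=1e-8):
        self.weight_decay = weight_decay
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, params, grads, lr):
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for k in params:
            g = grads[k]
            self.m[k] = b1 * self.m[k] + (1 - b1) * g
            self.v[k] = b2 * self.v[k] + (1 - b2) * g * g
            mhat = self.m[k] / (1 - b1 ** self.t)
            vhat = self.v[k] / (1 - b2 ** self.t)
            params[k] -= lr * (mhat / (np.sqrt(vhat) + self.eps)
                               + self.weight_decay * params[k])


def _lr_multiplier(epoch: int, total: int, schedule: str) -> float:
    if total <= 1:
        return 1.0
    frac = epoch / total
    if schedule == "multistep":
        return 1.0 if frac < 0.6 else (0.1 if frac < 0.85 else 0.01)
    if schedule == "cosine":
        return 0.5 * (1.0 + math.cos(math.pi * epoch / total))
    # onecycle: linear warm-up over the first 30%, cosine decay to 1% after
    warm = 0.3
    if frac < warm:
        return 0.1 + 0.9 * frac / warm
    t = (frac - warm) / (1 - warm)
    return 0.01 + 0.99 * 0.5 * (1.0 + math.cos(math.pi * t))


# ---------------------------------------------------------------------------
# augmentation

def _augment_batch(
    x: np.ndarray, kind: str, rng: np.random.Generator
) -> np.ndarray:
    """Label-preserving augmentations: flips + padded random crops, plus
    right-angle rotations and colour/contrast jitter in the complex set."""
    b, s = x.shape[0], x.shape[1]
    out = x.copy()
    flip_lr = rng.random(b) < 0.5
    flip_ud = rng.random(b) < 0.5
    out[flip_lr] = out[flip_lr, :, ::-1]
    out[flip_ud] = out[flip_ud, ::-1]

    pad = 4
    padded = np.pad(out, ((0, 0), (pad, pad), (pad, pad), (0, 0)), mode="reflect")
    oy = rng.integers(0, 2 * pad + 1, size=b)
    ox = rng.integers(0, 2 * pad + 1, size=b)
    out = np.stack([padded[i, oy[i]:oy[i] + s, ox[i]:ox[i] + s] for i in range(b)])

    if kind == "complex":
        k = rng.integers(0, 4, size=b)
        for i in range(b):
            if k[i]:
                out[i] = np.rot90(out[i], k=int(k[i]), axes=(0, 1))
        bright = rng.uniform(0.85, 1.15, size=(b, 1, 1, 1)).astype(np.float32)
        contrast = rng.uniform(0.85, 1.15, size=(b, 1, 1, 1)).astype(np.float32)
        mean = out.mean(axis=(1, 2, 3), keepdims=True)
        out = np.clip((out - mean) * contrast + mean * bright, 0.0, 1.0)
    return out


# ---------------------------------------------------------------------------
# training

class Scorer:
    """A trained (or untrained) scorer network bound to its configuration."""

    def __init__(self, config: TrainConfig, rng_seed: int):
        self.config = config
        self._net = _make_net(config, np.random.default_rng(rng_seed))

    def fit(
        self,
        records: Sequence[ImageRecord],
        images: Mapping[str, np.ndarray],
        rng: np.random.Generator,
        log_lines: list[str] | None = None,
        val_records: Sequence[ImageRecord] | None = None,
    ) -> None:
        cfg = self.config
        counts = [0, 0, 0]
        for r in records:
            counts[r.slof] += 1
        weights_by_class = class_weights(counts).w

        ids = [r.image_id for r in records]
        x_all = np.stack([images[i] for i in ids]).astype(np.float32)
        y_all = np.array([r.slof for r in records], dtype=np.float32)
        w_all = np.array([weights_by_class[r.slof] for r in records], dtype=np.float32)

        opt = (
            _SGD(self._net.params, cfg.momentum, cfg.weight_decay)
            if cfg.optimiser_name == "sgd"
            else _AdamW(self._net.params, cfg.weight_decay)
        )
        n = len(records)
        for epoch in range(cfg.epochs):
            lr = cfg.learning_rate * _lr_multiplier(epoch, cfg.epochs, cfg.schedule)
            perm = rng.permutation(n)
            epoch_loss = 0.0
            for start in range(0, n, cfg.batch_size):
                idx = perm[start:start + cfg.batch_size]
                xb = _augment_batch(x_all[idx], cfg.augmentation, rng) - 0.5
                yb, wb = y_all[idx], w_all[idx]
                pred, cache = self._net.forward(xb, want_cache=True)
                r = pred - yb
                loss = weighted_regression_loss(pred, yb, wb, cfg.loss_kind)
                if not np.isfinite(loss):
                    raise RuntimeError(
                        f"training loss became non-finite at epoch {epoch} "
                        f"(lr={lr:g}); lower the learning rate"
                    )
                dout = wb * _loss_grad(r, cfg.loss_kind) / len(idx)
                grads = self._net.backward(cache, dout)
                opt.step(self._net.params, grads, lr)
                epoch_loss += loss * len(idx)
            epoch_loss /= n
            if log_lines is not None:
                val_map = math.nan
                if val_records:
                    try:
                        val_map = mean_average_precision(
                            self.predict([r.image_id for r in val_records], images),
                            LabelSet("truth", {r.image_id: r.slof for r in val_records}),
                        )
                    except ValidationError:
                        pass
                log_lines.append(f"{epoch}\t{epoch_loss:.6f}\t{val_map:.4f}")

    def predict(
        self, ids: Sequence[str], images: Mapping[str, np.ndarray],
        fold: int | None = None, provenance: str = "single_model",
    ) -> ScoreSet:
        if not ids:
            raise ValidationError("no image ids to score")
        x = np.stack([images[i] for i in ids]).astype(np.float32) - 0.5
        preds, _ = self._net.forward(x)
        return ScoreSet(
            scores={i: float(p) for i, p in zip(ids, preds)},
            provenance=provenance,
            fold=fold,
        )

    def save(self, path: str | Path) -> None:
        np.savez(path, **self._net.params)

    def load(self, path: str | Path) -> None:
        with np.load(path) as data:
            for k in self._net.params:
                self._net.params[k] = data[k]


def train_scorer(
    manifest: DatasetManifest,
    config: TrainConfig,
    fold: int,
    images: Mapping[str, np.ndarray],
    fold_of: Mapping[str, int] | None = None,
    run_dir: str | Path | None = None,
) -> ScoreSet:
    """Train on every fold but ``fold`` and score the held-out fold.

    Per-sample weights come from the class counts of the training portion
    only.  With ``epochs=0`` the randomly initialised network scores the
    held-out fold, which is the null model for the trained/untrained
    comparison.  A checkpoint and a per-epoch loss log are written when
    ``run_dir`` is given.
    """
    if fold_of is None:
        fold_of = split_folds(manifest, config.folds, config.seed)
    if fold not in set(fold_of.values()):
        raise ValidationError(f"fold {fold} has no images")
    train_recs = [r for r in manifest.records if fold_of[r.image_id] != fold]
    val_recs = [r for r in manifest.records if fold_of[r.image_id] == fold]
    if not train_recs or not val_recs:
        raise ValidationError(f"fold {fold} leaves an empty train or validation set")

    scorer = Scorer(config, derive_seed(config.seed, "init", str(fold)))
    rng = np.random.default_rng(derive_seed(config.seed, "train", str(fold)))
    log_lines: list[str] = []
    scorer.fit(train_recs, images, rng, log_lines=log_lines, val_records=val_recs)

    if run_dir is not None:
        run_dir = Path(run_dir)
        run_dir.mkdir(parents=True, exist_ok=True)
        scorer.save(run_dir / f"fold{fold}_checkpoint.npz")
        (run_dir / f"fold{fold}_train.log").write_text(
            "epoch\ttrain_loss\tval_mean_ap\n" + "\n".join(log_lines) + "\n"
        )
    return scorer.predict([r.image_id for r in val_recs], images, fold=fold)


@dataclass
class CrossvalResult:
    combined: ScoreSet
    per_fold: list[ScoreSet]
    fold_of: dict[str, int]


def crossval_scores(
    manifest: DatasetManifest,
    config: TrainConfig,
    images: Mapping[str, np.ndarray],
    run_dir: str | Path | None = None,
) -> CrossvalResult:
    """Out-of-fold scores for every image: each image is scored by the one
    model whose training folds exclude its vessel."""
    fold_of = dict(split_folds(manifest, config.folds, config.seed))
    per_fold = [
        train_scorer(manifest, config, fold, images, fold_of=fold_of, run_dir=run_dir)
        for fold in range(config.folds)
    ]
    combined: dict[str, float] = {}
    for ss in per_fold:
        overlap = set(combined) & set(ss.scores)
        if overlap:
            raise ValidationError(f"images scored twice across folds: {sorted(overlap)[:5]}")
        combined.update(ss.scores)
    if set(combined) != {r.image_id for r in manifest.records}:
        raise ValidationError("out-of-fold scores do not cover the manifest")
    return CrossvalResult(
        combined=ScoreSet(scores=combined, provenance="single_model", fold=None),
        per_fold=per_fold,
        fold_of=fold_of,
    )


def ensemble_scores(score_sets: Sequence[ScoreSet]) -> ScoreSet:
    """Per-image arithmetic mean of raw scores across networks."""
    if not score_sets:
        raise ValidationError("ensemble requires at least one score set")
    ids = set(score_sets[0].scores)
    for ss in score_sets[1:]:
        if set(ss.scores) != ids:
            raise ValidationError("ensemble members must score identical image sets")
    return ScoreSet(
        scores={
            i: float(np.mean([ss.scores[i] for ss in score_sets])) for i in ids
        },
        provenance="ensemble",
    )


def best_subset_ensemble(
    score_sets: Sequence[ScoreSet], slof_truth: LabelSet
) -> tuple[tuple[int, ...], float]:
    """Exhaustively search score-set subsets for the best mean-AP ensemble.

    Ties break towards the smallest subset, then lexicographic member
    order, so the search is deterministic.  Refuses more than 20 members
    (2^20 subsets is past desk scale).
    """
    m = len(score_sets)
    if m == 0:
        raise ValidationError("no score sets to search")
    if m > 20:
        raise ValidationError(f"{m} score sets exceed the exhaustive-search guard (20)")
    best: tuple[float, int, tuple[int, ...]] | None = None
    for size in range(1, m + 1):
        for subset in itertools.combinations(range(m), size):
            score = mean_average_precision(
                ensemble_scores([score_sets[i] for i in subset]), slof_truth
            )
            key = (-score, size, subset)
            if best is None or key < best:
                best = key
    neg_score, _, subset = best
    return subset, -neg_score


def sobol_candidates(
    param_space: Mapping[str, tuple[float, float, str]],
    n: int,
    seed: int,
    base: TrainConfig | None = None,
) -> list[TrainConfig]:
    """Draw ``n`` hyperparameter candidates from a scrambled Sobol sequence.

    ``param_space`` maps TrainConfig field names to ``(low, high, scale)``
    with scale "linear" or "log"; log-scaled dimensions are sampled
    uniformly in log space.  A low-discrepancy sequence covers the search
    box more evenly than independent uniform draws.
    """
    from scipy.stats import qmc

    if n < 1:
        raise ValidationError("n must be at least 1")
    if not param_space:
        raise ValidationError("param_space is empty")
    base = base or TrainConfig()
    names = list(param_space)
    for name, (lo, hi, scale) in param_space.items():
        if not hasattr(base, name):
            raise ValidationError(f"unknown TrainConfig field {name!r}")
        if not lo < hi:
            raise ValidationError(f"{name}: bounds must satisfy low < high")
        if scale == "log" and lo <= 0:
            raise ValidationError(f"{name}: log scale requires positive bounds")
        if scale not in ("linear", "log"):
            raise ValidationError(f"{name}: unknown scale {scale!r}")

    sampler = qmc.Sobol(d=len(names), scramble=True, seed=seed)
    unit = sampler.random(n)
    configs = []
    for row in unit:
        fields = {}
        for u, name in zip(row, names):
            lo, hi, scale = param_space[name]
            if scale == "log":
                val = math.exp(math.log(lo) + u * (math.log(hi) - math.log(lo)))
            else:
                val = lo + u * (hi - lo)
            fields[name] = val
        configs.append(replace(base, **fields))
    return configs
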