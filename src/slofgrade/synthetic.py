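"""Seeded synthetic stand-ins for hull-inspection survey data.

The published imagery behind the SLoF grading study is held by biosecurity
agencies and is not publicly available, so this module generates
ground-truthed substitutes for every input the pipeline consumes:

* procedural hull images with a known macrofouling mask, hence an exact
  coverage fraction and an exact SLoF grade;
* dataset manifests reproducing the published dataset structure
  (class imbalance, vessel grouping, train / test / expert-group splits);
* simulated expert raters drawn from per-class confusion profiles, tuned so
  that agreement is high on clean (SLoF 0) and heavily fouled (SLoF 2)
  hulls and lower on patchy fouling (SLoF 1); and
* simulated raw regression scores, for exercising the thresholding and
  benchmarking stages without training a network.

Everything is a pure function of its arguments and a seed.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from PIL import Image
from scipy.ndimage import gaussian_filter

from .exceptions import GenerationError, ValidationError

__all__ = [
    "FoulingStyle",
    "ImageRecord",
    "DatasetManifest",
    "RaterProfile",
    "LabelSet",
    "ScoreSet",
    "coverage_to_slof",
    "generate_hull_image",
    "generate_dataset",
    "simulate_raters",
    "expected_pairwise_agreement",
    "simulate_scores",
    "default_expert_profiles",
    "sample_style",
    "read_manifest",
    "write_manifest",
    "read_labels",
    "write_labels",
]

#: Published dataset structure: per-class image totals, the test-split
#: class counts, the expert-group subset size, and the vessel counts
#: (about 300 vessels surveyed, 14 of them reserved for the test split).
TABLE2_TOTALS = (7822, 1696, 745)
TABLE2_TEST = (494, 193, 154)
EXPERT_GROUP_SIZE = 120
DEFAULT_TRAIN_VESSELS = 286
DEFAULT_TEST_VESSELS = 14

_SPLITS = ("train", "test", "expert_group")


def coverage_to_slof(coverage: float) -> int:
    """Map a macrofouling coverage fraction to its SLoF grade.

    Coverage is first rounded to the nearest integer percent ``p`` (half
    away from zero); the grade is 0 when ``p == 0`` (no macrofouling —
    biofilm or slime does not count), 1 when ``1 <= p <= 15`` (patchy
    fouling), and 2 when ``p >= 16`` (heavy fouling).  Rounding first makes
    the 15% / 16% band edges exact and the rule total on [0, 1].
    """
    coverage = float(coverage)
    if not 0.0 <= coverage <= 1.0:
        raise ValidationError(f"coverage must lie in [0, 1], got {coverage}")
    p = int(np.floor(coverage * 100.0 + 0.5))
    if p == 0:
        return 0
    return 1 if p <= 15 else 2


@dataclass(frozen=True)
class FoulingStyle:
    """Per-vessel appearance of the hull coating and its fouling.

    One style is shared by every image of a vessel, so grouped
    cross-validation has a real style signal to guard against.
    """

    base_coat_rgb: tuple[float, float, float]
    seam_count: int
    lighting_gradient_strength: float
    turbidity_blur_sigma: float
    colour_cast_strength: float
    blob_radius_range: tuple[int, int]
    blob_texture: str  # barnacle | algae | mixed

    def __post_init__(self) -> None:
        if not all(0.0 <= c <= 1.0 for c in self.base_coat_rgb):
            raise ValidationError("base_coat_rgb channels must lie in [0, 1]")
        if self.seam_count < 0:
            raise ValidationError("seam_count must be non-negative")
        if self.lighting_gradient_strength < 0:
            raise ValidationError("lighting_gradient_strength must be non-negative")
        if self.turbidity_blur_sigma < 0:
            raise ValidationError("turbidity_blur_sigma must be non-negative")
        if not 0.0 <= self.colour_cast_strength <= 1.0:
            raise ValidationError("colour_cast_strength must lie in [0, 1]")
        lo, hi = self.blob_radius_range
        if not (1 <= lo <= hi):
            raise ValidationError("blob_radius_range must satisfy 1 <= lo <= hi")
        if self.blob_texture not in ("barnacle", "algae", "mixed"):
            raise ValidationError(f"unknown blob_texture {self.blob_texture!r}")


@dataclass(frozen=True)
class ImageRecord:
    image_id: str
    path: str
    vessel_id: str
    split: str
    coverage: float
    slof: int

    def __post_init__(self) -> None:
        if self.split not in _SPLITS:
            raise ValidationError(f"split must be one of {_SPLITS}, got {self.split!r}")
        if self.slof != coverage_to_slof(self.coverage):
            raise ValidationError(
                f"{self.image_id}: slof {self.slof} inconsistent with "
                f"coverage {self.coverage}"
            )


@dataclass
class DatasetManifest:
    records: list[ImageRecord]
    seed: int
    class_mix: tuple[float, float, float]

    def __post_init__(self) -> None:
        ids = [r.image_id for r in self.records]
        if len(set(ids)) != len(ids):
            raise ValidationError("image_id values must be unique")
        if abs(sum(self.class_mix) - 1.0) > 1e-9:
            raise ValidationError("class_mix must sum to 1")

    def __len__(self) -> int:
        return len(self.records)

    def subset(self, split: str) -> "DatasetManifest":
        recs = [r for r in self.records if r.split == split]
        return DatasetManifest(recs, self.seed, self.class_mix)

    def true_labels(self) -> dict[str, int]:
        return {r.image_id: r.slof for r in self.records}

    def class_counts(self) -> tuple[int, int, int]:
        counts = [0, 0, 0]
        for r in self.records:
            counts[r.slof] += 1
        return tuple(counts)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "image_id": [r.image_id for r in self.records],
                "path": [r.path for r in self.records],
                "vessel_id": [r.vessel_id for r in self.records],
                "split": [r.split for r in self.records],
                "coverage": [r.coverage for r in self.records],
                "slof": [r.slof for r in self.records],
            }
        )


@dataclass(frozen=True)
class RaterProfile:
    """A simulated grader: ``confusion[t][o]`` is P(label = o | truth = t)."""

    rater_id: str
    confusion: tuple[tuple[float, float, float], ...]

    def __post_init__(self) -> None:
        m = np.asarray(self.confusion, dtype=float)
        if m.shape != (3, 3):
            raise ValidationError("confusion must be a 3x3 table")
        if (m < 0).any():
            raise ValidationError("confusion entries must be non-negative")
        rowsums = m.sum(axis=1)
        if np.abs(rowsums - 1.0).max() > 1e-9:
            raise ValidationError(
                f"confusion rows must each sum to 1 (got {rowsums.tolist()})"
            )

    @property
    def matrix(self) -> np.ndarray:
        return np.asarray(self.confusion, dtype=float)


@dataclass
class LabelSet:
    """One grader's SLoF assignment for a set of images."""

    rater_id: str
    labels: dict[str, int]

    def __post_init__(self) -> None:
        for iid, lab in self.labels.items():
            if lab not in (0, 1, 2):
                raise ValidationError(f"label for {iid} must be in {{0,1,2}}, got {lab}")

    def __len__(self) -> int:
        return len(self.labels)


@dataclass
class ScoreSet:
    """Continuous raw scores per image (single network, ensemble or simulated)."""

    scores: dict[str, float]
    provenance: str = "simulated"
    fold: int | None = None

    def __post_init__(self) -> None:
        bad = [iid for iid, s in self.scores.items() if not np.isfinite(s)]
        if bad:
            raise ValidationError(f"non-finite scores for images {bad[:5]}")

    def __len__(self) -> int:
        return len(self.scores)


# ---------------------------------------------------------------------------
# seeding

def derive_seed(master_seed: int, *parts: str) -> int:
    """Stable per-item substream seed from (master seed, string parts)."""
    h = hashlib.sha256(("|".join((str(master_seed),) + parts)).encode())
    return int.from_bytes(h.digest()[:4], "big") % (2**31)


# ---------------------------------------------------------------------------
# procedural imagery

def sample_style(rng: np.random.Generator, image_size: int = 256) -> FoulingStyle:
    """Draw one vessel's appearance parameters."""
    palettes = [
        (0.55, 0.15, 0.12),  # red antifoul
        (0.35, 0.12, 0.10),  # oxblood
        (0.15, 0.20, 0.35),  # navy
        (0.35, 0.35, 0.38),  # grey
        (0.10, 0.10, 0.12),  # black
    ]
    base = palettes[int(rng.integers(len(palettes)))]
    base = tuple(float(np.clip(c + rng.normal(0, 0.03), 0, 1)) for c in base)
    r_hi = max(6, image_size // 6)
    return FoulingStyle(
        base_coat_rgb=base,
        seam_count=int(rng.integers(0, 5)),
        lighting_gradient_strength=float(rng.uniform(0.0, 0.5)),
        turbidity_blur_sigma=float(rng.uniform(0.0, 1.5)),
        colour_cast_strength=float(rng.uniform(0.0, 0.4)),
        blob_radius_range=(2, r_hi),
        blob_texture=str(rng.choice(["barnacle", "algae", "mixed"])),
    )


_MAX_BLOB_ITER = 10_000
_COVERAGE_TOL = 0.005


def _place_fouling_mask(
    height: int, width: int, coverage_target: float, style: FoulingStyle,
    rng: np.random.Generator,
) -> np.ndarray:
    """Rejection-sample textured ellipses until |achieved - target| <= 0.5%."""
    mask = np.zeros((height, width), dtype=bool)
    n_px = height * width
    target_px = coverage_target * n_px
    tol_px = _COVERAGE_TOL * n_px
    if target_px <= tol_px and coverage_target == 0.0:
        return mask

    yy, xx = np.mgrid[0:height, 0:width]
    r_lo, r_hi = style.blob_radius_range
    covered = 0
    for _ in range(_MAX_BLOB_ITER):
        if covered >= target_px - tol_px:
            return mask
        remaining = target_px - covered
        # cap the radius so one blob cannot blow far past the band
        r_cap = int(np.sqrt(max(remaining, 1.0) * 1.2 / np.pi))
        hi = max(r_lo, min(r_hi, r_cap))
        if hi > min(height, width) // 2:
            hi = max(r_lo, min(height, width) // 2)
        rx = float(rng.uniform(r_lo, hi + 1))
        ry = rx * float(rng.uniform(0.6, 1.0))
        theta = float(rng.uniform(0, np.pi))
        # bias the centre towards uncovered hull so progress is guaranteed
        free = np.flatnonzero(~mask)
        if free.size == 0:
            return mask
        centre = free[int(rng.integers(free.size))]
        cy, cx = divmod(int(centre), width)
        ct, st = np.cos(theta), np.sin(theta)
        u = (xx - cx) * ct + (yy - cy) * st
        v = -(xx - cx) * st + (yy - cy) * ct
        blob = (u / rx) ** 2 + (v / ry) ** 2 <= 1.0
        new = blob & ~mask
        added = int(new.sum())
        if covered + added > target_px + tol_px:
            continue  # reject: would overshoot the band
        mask |= new
        covered += added
    raise GenerationError(
        f"could not reach coverage {coverage_target:.3f} within "
        f"{_MAX_BLOB_ITER} blob placements (radius range {style.blob_radius_range}, "
        f"image {height}x{width})"
    )


def _fouling_texture(
    shape: tuple[int, int], style: FoulingStyle, rng: np.random.Generator
) -> np.ndarray:
    barnacle = np.array([0.72, 0.68, 0.60])
    algae = np.array([0.16, 0.42, 0.18])
    if style.blob_texture == "barnacle":
        base = barnacle
    elif style.blob_texture == "algae":
        base = algae
    else:
        w = rng.uniform(0, 1, size=shape)[..., None]
        base = w * barnacle + (1 - w) * algae
    tex = np.broadcast_to(base, shape + (3,)).copy()
    tex += rng.normal(0, 0.08, size=tex.shape)
    return tex


def generate_hull_image(
    height: int,
    width: int,
    coverage_target: float,
    style: FoulingStyle,
    seed: int,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Render one synthetic hull image with a known macrofouling mask.

    Returns ``(rgb_image, fouling_mask, achieved_coverage)`` where the
    uint8 image is ``height x width x 3``, the boolean mask marks
    macrofouling pixels, and ``achieved_coverage`` is exactly the mask's
    positive fraction, within 0.005 of ``coverage_target``.  Identical
    arguments and seed reproduce the arrays bit for bit.
    """
    if not 0.0 <= coverage_target <= 1.0:
        raise ValidationError(f"coverage_target must lie in [0, 1], got {coverage_target}")
    if height < 32 or width < 32:
        raise ValidationError("image must be at least 32x32 pixels")

    rng = np.random.default_rng(seed)

    # hull coating: base coat + plate seams + lighting gradient + grain
    img = np.empty((height, width, 3), dtype=float)
    img[:] = np.asarray(style.base_coat_rgb)
    for _ in range(style.seam_count):
        x0 = int(rng.integers(0, width))
        w = int(rng.integers(1, 3))
        img[:, x0:x0 + w] *= 0.75
    grad = 1.0 - style.lighting_gradient_strength * (
        np.linspace(0.0, 1.0, height)[:, None, None]
    )
    img *= grad
    img += rng.normal(0, 0.02, size=img.shape)
    # slime veil on the coating (texture only; never counted as coverage)
    slime = rng.normal(0, 0.015, size=(height, width))
    img[..., 1] += np.abs(slime)

    mask = _place_fouling_mask(height, width, coverage_target, style, rng)
    achieved = float(mask.sum()) / (height * width)

    if mask.any():
        img[mask] = _fouling_texture((height, width), style, rng)[mask]

    if style.turbidity_blur_sigma > 0:
        for c in range(3):
            img[..., c] = gaussian_filter(img[..., c], style.turbidity_blur_sigma)
    cast = style.colour_cast_strength
    if cast > 0:
        tint = np.array([0.05, 0.35, 0.45])
        img = (1 - cast) * img + cast * tint

    rgb = (np.clip(img, 0.0, 1.0) * 255.0 + 0.5).astype(np.uint8)
    return rgb, mask, achieved


# ---------------------------------------------------------------------------
# dataset manifests

def _draw_coverage(slof: int, rng: np.random.Generator) -> float:
    if slof == 0:
        return 0.0
    if slof == 1:
        return float(rng.uniform(0.01, 0.15))
    return float(rng.uniform(0.16, 1.0))


def _stratified_counts(counts: Sequence[int], n_take: int) -> list[int]:
    """Largest-remainder apportionment of ``n_take`` across class counts."""
    total = sum(counts)
    quotas = [n_take * c / total for c in counts]
    take = [int(np.floor(q)) for q in quotas]
    rem = n_take - sum(take)
    order = np.argsort([t - q for t, q in zip(take, quotas)])
    for i in range(rem):
        take[order[i]] += 1
    return take


def _chunk_vessels(
    n_records: int, n_vessels: int, prefix: str
) -> list[str]:
    """Assign ``n_records`` shuffled records to ``n_vessels`` balanced groups."""
    sizes = np.full(n_vessels, n_records // n_vessels, dtype=int)
    sizes[: n_records % n_vessels] += 1
    ids: list[str] = []
    for v, size in enumerate(sizes):
        ids.extend([f"{prefix}{v:04d}"] * size)
    return ids


def generate_dataset(
    n_per_class: Sequence[int] = TABLE2_TOTALS,
    *,
    test_per_class: Sequence[int] | None = None,
    n_expert_group: int | None = None,
    n_train_vessels: int | None = None,
    n_test_vessels: int | None = None,
    image_size: int = 256,
    out_dir: str | Path | None = None,
    seed: int = 0,
    render: bool = True,
) -> DatasetManifest:
    """Generate a ground-truthed dataset with the published survey structure.

    Per-class record counts equal ``n_per_class`` exactly.  Coverage is 0
    for class 0, uniform on the 1–15% band for class 1 and on the 16–100%
    band for class 2.  Records are grouped into vessels (one fouling style
    per vessel); the test region holds ``sum(test_per_class)`` images on
    dedicated test vessels, of which a SLoF-stratified subset of
    ``n_expert_group`` images forms the expert-group split.  The defaults
    reproduce the published arithmetic: 10,263 images, an 841-image test
    split of which 120 are the expert group, 286 + 14 vessels.

    With ``render=True`` and an ``out_dir``, PNGs are written under
    ``out_dir/images`` and the manifest CSV at ``out_dir/manifest.csv``;
    ``render=False`` produces the manifest only (paths are declared but no
    files are written), which keeps structure checks at full scale cheap.
    """
    n_per_class = tuple(int(c) for c in n_per_class)
    if any(c < 0 for c in n_per_class) or len(n_per_class) != 3:
        raise ValidationError("n_per_class must be three non-negative integers")
    n_total = sum(n_per_class)
    if n_total == 0:
        raise ValidationError("dataset must contain at least one image")

    if test_per_class is None:
        if n_per_class == TABLE2_TOTALS:
            test_per_class = TABLE2_TEST
        else:
            test_per_class = tuple(
                _stratified_counts([max(c, 1) for c in n_per_class],
                                   max(1, round(0.15 * n_total)))[i]
                if n_per_class[i] > 0 else 0
                for i in range(3)
            )
            test_per_class = tuple(min(t, c) for t, c in zip(test_per_class, n_per_class))
    test_per_class = tuple(int(c) for c in test_per_class)
    if any(t > c for t, c in zip(test_per_class, n_per_class)):
        raise ValidationError("test_per_class cannot exceed n_per_class")
    n_test_total = sum(test_per_class)

    if n_expert_group is None:
        n_expert_group = EXPERT_GROUP_SIZE if n_per_class == TABLE2_TOTALS else max(
            1, round(n_test_total / 7)
        )
    if n_expert_group > n_test_total:
        raise ValidationError("expert group cannot exceed the test region")

    n_train_total = n_total - n_test_total
    if n_train_vessels is None:
        n_train_vessels = (
            DEFAULT_TRAIN_VESSELS
            if n_per_class == TABLE2_TOTALS
            else max(1, n_train_total // 20)
        )
    if n_test_vessels is None:
        n_test_vessels = (
            DEFAULT_TEST_VESSELS
            if n_per_class == TABLE2_TOTALS
            else max(1, n_test_total // 20) if n_test_total else 0
        )
    if n_train_total > 0 and n_train_vessels < 1:
        raise ValidationError("need at least one training vessel")
    if n_test_total > 0 and n_test_vessels < 1:
        raise ValidationError("need at least one test vessel")

    rng = np.random.default_rng(derive_seed(seed, "manifest"))

    # per-class labels, split between test region and train region
    labels = []
    regions = []
    for cls in range(3):
        labels.extend([cls] * n_per_class[cls])
        regions.extend(["test"] * test_per_class[cls]
                       + ["train"] * (n_per_class[cls] - test_per_class[cls]))
    labels = np.asarray(labels)
    regions = np.asarray(regions)

    # expert-group subset: SLoF-stratified within the test region
    eg_take = _stratified_counts([max(t, 0) or 1 for t in test_per_class], n_expert_group) \
        if n_test_total else [0, 0, 0]
    eg_take = [min(t, c) for t, c in zip(eg_take, test_per_class)]
    deficit = n_expert_group - sum(eg_take)
    if deficit:
        for cls in np.argsort([-c for c in test_per_class]):
            room = test_per_class[cls] - eg_take[cls]
            add = min(room, deficit)
            eg_take[cls] += add
            deficit -= add
            if deficit == 0:
                break

    splits = regions.astype(object).copy()
    for cls in range(3):
        idx = np.flatnonzero((labels == cls) & (regions == "test"))
        chosen = rng.choice(idx, size=eg_take[cls], replace=False)
        splits[chosen] = "expert_group"

    # shuffle within each region, then chunk into vessels
    order = np.arange(n_total)
    train_idx = order[regions == "train"]
    test_idx = order[regions == "test"]
    rng.shuffle(train_idx)
    rng.shuffle(test_idx)
    ordered = np.concatenate([train_idx, test_idx])
    vessel_ids = (
        _chunk_vessels(len(train_idx), n_train_vessels, "tr") if len(train_idx) else []
    ) + (
        _chunk_vessels(len(test_idx), n_test_vessels, "te") if len(test_idx) else []
    )

    records: list[ImageRecord] = []
    for pos, idx in enumerate(ordered):
        cls = int(labels[idx])
        image_id = f"img_{pos:06d}"
        cov = _draw_coverage(cls, np.random.default_rng(derive_seed(seed, "cov", image_id)))
        records.append(
            ImageRecord(
                image_id=image_id,
                path=f"images/{image_id}.png",
                vessel_id=vessel_ids[pos],
                split=str(splits[idx]),
                coverage=cov,
                slof=cls,
            )
        )
    records.sort(key=lambda r: r.image_id)

    class_mix = tuple(c / n_total for c in n_per_class)
    manifest = DatasetManifest(records=records, seed=seed, class_mix=class_mix)

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        if render:
            render_images(manifest, out_dir, image_size=image_size)
        write_manifest(manifest, out_dir / "manifest.csv")
    elif render:
        raise ValidationError("render=True requires an out_dir")
    return manifest


def vessel_style(manifest_seed: int, vessel_id: str, image_size: int = 256) -> FoulingStyle:
    """The (deterministic) fouling style of one vessel."""
    rng = np.random.default_rng(derive_seed(manifest_seed, "style", vessel_id))
    return sample_style(rng, image_size=image_size)


def render_images(
    manifest: DatasetManifest, out_dir: str | Path, image_size: int = 256
) -> None:
    """Write every manifest record's PNG under ``out_dir``."""
    out_dir = Path(out_dir)
    styles: dict[str, FoulingStyle] = {}
    for rec in manifest.records:
        style = styles.get(rec.vessel_id)
        if style is None:
            style = vessel_style(manifest.seed, rec.vessel_id, image_size)
            styles[rec.vessel_id] = style
        rgb, _, _ = generate_hull_image(
            image_size, image_size, rec.coverage, style,
            derive_seed(manifest.seed, "image", rec.image_id),
        )
        path = out_dir / rec.path
        path.parent.mkdir(parents=True, exist_ok=True)
        Image.fromarray(rgb).save(path)


# ---------------------------------------------------------------------------
# simulated raters and scores

def default_expert_profiles(n: int = 3, seed: int = 0) -> list[RaterProfile]:
    """Simulated experts: near-certain on SLoF 0 and 2, noisier on SLoF 1."""
    base = np.array(
        [
            [0.95, 0.05, 0.00],
            [0.12, 0.78, 0.10],
            [0.00, 0.07, 0.93],
        ]
    )
    rng = np.random.default_rng(derive_seed(seed, "raters"))
    profiles = []
    for i in range(n):
        jitter = rng.uniform(-0.02, 0.02, size=(3, 3))
        m = np.clip(base + jitter, 1e-4, None)
        m /= m.sum(axis=1, keepdims=True)
        profiles.append(
            RaterProfile(
                rater_id=f"expert_{i + 1}",
                confusion=tuple(tuple(float(x) for x in row) for row in m),
            )
        )
    return profiles


def simulate_raters(
    manifest: DatasetManifest,
    profiles: Sequence[RaterProfile],
    seed: int,
) -> list[LabelSet]:
    """Draw each rater's label for every image from its confusion row.

    Conditional on an image's true class ``t``, a rater's label is an
    independent draw from ``confusion[t]``; raters are conditionally
    independent of one another given the truth.
    """
    if not profiles:
        raise ValidationError("at least one rater profile is required")
    if not manifest.records:
        raise ValidationError("manifest is empty")

    out = []
    for profile in profiles:
        rng = np.random.default_rng(derive_seed(seed, "rater", profile.rater_id))
        m = profile.matrix
        truths = np.array([r.slof for r in manifest.records])
        u = rng.random(len(truths))
        cdf = np.cumsum(m, axis=1)[truths]  # (n, 3)
        drawn = (u[:, None] > cdf).sum(axis=1)
        labels = {
            rec.image_id: int(lab) for rec, lab in zip(manifest.records, drawn)
        }
        out.append(LabelSet(rater_id=profile.rater_id, labels=labels))
    return out


def expected_pairwise_agreement(
    profile_a: RaterProfile,
    profile_b: RaterProfile,
    class_prior: Sequence[float],
) -> float:
    """Probability two conditionally independent raters emit the same label.

    ``sum_t prior[t] * sum_o A[t][o] * B[t][o]`` — the analytic oracle the
    rater simulator is calibrated against.
    """
    prior = np.asarray(class_prior, dtype=float)
    if prior.shape != (3,):
        raise ValidationError("class_prior must have three entries")
    if abs(prior.sum() - 1.0) > 1e-9:
        raise ValidationError(f"class_prior must sum to 1, got {prior.sum()}")
    return float(np.sum(prior[:, None] * profile_a.matrix * profile_b.matrix))


def simulate_scores(
    manifest: DatasetManifest, noise_sd: float, seed: int
) -> ScoreSet:
    """Gaussian-perturbed true grades, standing in for raw network output."""
    if noise_sd < 0:
        raise ValidationError(f"noise_sd must be non-negative, got {noise_sd}")
    rng = np.random.default_rng(derive_seed(seed, "scores"))
    vals = np.array([r.slof for r in manifest.records], dtype=float)
    vals += rng.normal(0.0, noise_sd, size=vals.size) if noise_sd > 0 else 0.0
    return ScoreSet(
        scores={r.image_id: float(v) for r, v in zip(manifest.records, vals)},
        provenance="simulated",
    )


# ---------------------------------------------------------------------------
# CSV interfaces

def write_manifest(manifest: DatasetManifest, path: str | Path) -> None:
    # %.17g round-trips doubles exactly through the CSV
    manifest.to_frame().to_csv(path, index=False, float_format="%.17g")


def read_manifest(path: str | Path, seed: int = 0) -> DatasetManifest:
    df = pd.read_csv(path, float_precision="round_trip")
    required = {"image_id", "path", "vessel_id", "split", "coverage", "slof"}
    missing = required - set(df.columns)
    if missing:
        raise ValidationError(f"manifest is missing columns {sorted(missing)}")
    records = [
        ImageRecord(
            image_id=str(row.image_id),
            path=str(row.path),
            vessel_id=str(row.vessel_id),
            split=str(row.split),
            coverage=float(row.coverage),
            slof=int(row.slof),
        )
        for row in df.itertuples()
    ]
    counts = [0, 0, 0]
    for r in records:
        counts[r.slof] += 1
    mix = tuple(c / len(records) for c in counts)
    return DatasetManifest(records=records, seed=seed, class_mix=mix)


def write_labels(label_sets: Sequence[LabelSet], path: str | Path) -> None:
    rows = [
        {"image_id": iid, "rater_id": ls.rater_id, "slof": lab}
        for ls in label_sets
        for iid, lab in sorted(ls.labels.items())
    ]
    pd.DataFrame(rows, columns=["image_id", "rater_id", "slof"]).to_csv(path, index=False)


def read_labels(path: str | Path) -> list[LabelSet]:
    df = pd.read_csv(path)
    required = {"image_id", "rater_id", "slof"}
    missing = required - set(df.columns)
    if missing:
        raise ValidationError(f"label table is missing columns {sorted(missing)}")
    out = []
    for rater_id, grp in df.groupby("rater_id", sort=True):
        out.append(
            LabelSet(
                rater_id=str(rater_id),
                labels={str(r.image_id): int(r.slof) for r in grp.itertuples()},
            )
        )
    return out
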