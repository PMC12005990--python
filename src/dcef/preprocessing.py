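"""Image standardization, augmentation, and class-imbalance handling.

The pipeline mirrors the usual recipe for a small two-class cohort with a
scarce benign class: min-max normalization and resampling to a common
resolution; rotation/flip/translation augmentation of the minority class;
SMOTE interpolation in feature space; selective undersampling of the
majority; 2:1 class weighting in the loss; and a stratified, source-level
50/20/30 train/validation/test split (grouping by ``source_id`` so that no
source leaks across splits).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.transform import resize as _sk_resize
from skimage.transform import rotate as _sk_rotate
from sklearn.neighbors import NearestNeighbors

BENIGN, MALIGNANT = 0, 1


@dataclass(frozen=True)
class LabeledImage:
    """A grayscale image with an optional ROI mask and a binary label."""

    image: np.ndarray
    label: int
    roi_mask: np.ndarray | None = None
    source_id: str = ""

    def __post_init__(self):
        img = np.asarray(self.image, dtype=float)
        if img.ndim != 2 or img.size == 0:
            raise ValueError("image must be a nonempty 2-D array")
        if not np.all(np.isfinite(img)):
            raise ValueError("image contains non-finite pixels")
        object.__setattr__(self, "image", img)
        if self.label not in (BENIGN, MALIGNANT):
            raise ValueError("label must be 0 (benign) or 1 (malignant)")
        if self.roi_mask is not None:
            mask = np.asarray(self.roi_mask).astype(bool)
            if mask.shape != img.shape:
                raise ValueError("mask shape must match image shape")
            object.__setattr__(self, "roi_mask", mask)


@dataclass(frozen=True)
class SplitPlan:
    """Stratified split fractions plus optional explicit per-class counts.

    ``per_class_counts`` maps class -> (train+validation, test) source
    counts; when given it overrides the fractional test size for that
    class.
    """

    fractions: tuple[float, float, float] = (0.5, 0.2, 0.3)
    per_class_counts: Mapping[int, tuple[int, int]] | None = None
    seed: int = 0

    def __post_init__(self):
        if abs(sum(self.fractions) - 1.0) > 1e-9:
            raise ValueError("fractions must sum to 1")
        if any(f < 0 for f in self.fractions):
            raise ValueError("fractions must be nonnegative")


def normalize_and_resize(
    img: LabeledImage, target: tuple[int, int]
) -> LabeledImage:
    """Min-max scale pixels to [0, 1] and resample to ``target``.

    The mask (if any) is resampled with nearest-neighbor so it stays
    binary. A constant image maps to all zeros with a warning rather than
    an error (a blank frame should not kill a batch job).
    """
    arr = img.image
    lo, hi = float(arr.min()), float(arr.max())
    if hi == lo:
        warnings.warn(
            f"constant image {img.source_id!r}: normalized to all zeros",
            stacklevel=2,
        )
        scaled = np.zeros_like(arr)
    else:
        scaled = (arr - lo) / (hi - lo)
    out = _sk_resize(scaled, target, order=1, anti_aliasing=True, mode="reflect")
    out = np.clip(out, 0.0, 1.0)
    mask = None
    if img.roi_mask is not None:
        mask = (
            _sk_resize(
                img.roi_mask.astype(float), target, order=0, mode="edge"
            )
            > 0.5
        )
    return replace(img, image=out, roi_mask=mask)


def crop_to_roi(img: LabeledImage, margin: float = 0.25) -> LabeledImage:
    """Crop to the ROI bounding box plus a proportional margin.

    Lesion classification operates on the annotated patch, not the whole
    frame: cropping removes background gain variation that carries no
    class information. No-op when the image has no mask.
    """
    if img.roi_mask is None or not img.roi_mask.any():
        return img
    rows = np.any(img.roi_mask, axis=1)
    cols = np.any(img.roi_mask, axis=0)
    r0, r1 = np.where(rows)[0][[0, -1]]
    c0, c1 = np.where(cols)[0][[0, -1]]
    mr = int(round(margin * (r1 - r0 + 1)))
    mc = int(round(margin * (c1 - c0 + 1)))
    r0, r1 = max(0, r0 - mr), min(img.image.shape[0], r1 + 1 + mr)
    c0, c1 = max(0, c0 - mc), min(img.image.shape[1], c1 + 1 + mc)
    return replace(
        img,
        image=img.image[r0:r1, c0:c1],
        roi_mask=img.roi_mask[r0:r1, c0:c1],
    )


def flip_image(img: LabeledImage, axis: int = 1) -> LabeledImage:
    """Mirror along an axis (1 = horizontal); an involution."""
    mask = None if img.roi_mask is None else np.flip(img.roi_mask, axis=axis)
    return replace(img, image=np.flip(img.image, axis=axis), roi_mask=mask)


def rotate_image(img: LabeledImage, angle_deg: float) -> LabeledImage:
    """Rotate counterclockwise; right angles are exact, others reflect-pad."""
    angle = angle_deg % 360
    if angle % 90 == 0:
        k = int(angle // 90)
        image = np.rot90(img.image, k)
        mask = None if img.roi_mask is None else np.rot90(img.roi_mask, k)
        return replace(img, image=image, roi_mask=mask)
    image = _sk_rotate(img.image, angle_deg, mode="reflect", order=1)
    mask = None
    if img.roi_mask is not None:
        mask = _sk_rotate(
            img.roi_mask.astype(float), angle_deg, mode="reflect", order=0
        ) > 0.5
    return replace(img, image=image, roi_mask=mask)


def translate_image(img: LabeledImage, shift: tuple[int, int]) -> LabeledImage:
    """Integer-pixel shift with reflection padding; mask moves identically."""
    image = ndimage.shift(img.image, shift, order=0, mode="reflect")
    mask = None
    if img.roi_mask is not None:
        mask = ndimage.shift(
            img.roi_mask.astype(float), shift, order=0, mode="reflect"
        ) > 0.5
    return replace(img, image=image, roi_mask=mask)


#: Default augmentation geometry: right angles plus a small random tilt,
#: and translations within +/-10% of each spatial dimension.
RIGHT_ANGLES = (90.0, 180.0, 270.0)
SMALL_ANGLE = 15.0
TRANSLATE_FRACTION = 0.10


def augment(
    img: LabeledImage,
    ops: Sequence[str] = ("rotate", "flip", "translate"),
    seed: int = 0,
) -> list[LabeledImage]:
    """Expand one image into augmented variants (label and mask preserved).

    ``rotate`` yields the three right angles plus one small random tilt in
    [-15, 15] degrees; ``flip`` yields horizontal and vertical mirrors;
    ``translate`` yields two random shifts within 10% of each dimension.
    Deterministic under ``seed``.
    """
    if not ops:
        raise ValueError("ops must be non-empty")
    unknown = set(ops) - {"rotate", "flip", "translate"}
    if unknown:
        raise ValueError(f"unknown augmentation ops: {sorted(unknown)}")
    rng = np.random.default_rng(seed)
    out: list[LabeledImage] = []
    if "rotate" in ops:
        for angle in RIGHT_ANGLES:
            out.append(rotate_image(img, angle))
        tilt = float(rng.uniform(-SMALL_ANGLE, SMALL_ANGLE))
        out.append(rotate_image(img, tilt))
    if "flip" in ops:
        out.append(flip_image(img, axis=1))
        out.append(flip_image(img, axis=0))
    if "translate" in ops:
        h, w = img.image.shape
        max_dr = max(1, int(round(TRANSLATE_FRACTION * h)))
        max_dc = max(1, int(round(TRANSLATE_FRACTION * w)))
        for _ in range(2):
            dr = int(rng.integers(-max_dr, max_dr + 1))
            dc = int(rng.integers(-max_dc, max_dc + 1))
            out.append(translate_image(img, (dr, dc)))
    return out


def smote_oversample(
    minority_features: np.ndarray,
    target_count: int,
    k_neighbors: int = 5,
    seed: int = 0,
) -> np.ndarray:
    """Synthetic minority rows by convex interpolation to nearest neighbors.

    Each synthetic row is ``x_i + gamma (x_j - x_i)`` for a uniformly drawn
    minority row ``x_i``, one of its ``k_neighbors`` nearest minority
    neighbors ``x_j``, and ``gamma ~ U(0, 1)`` — so every row lies on a
    segment between two minority points. Returns the synthetic rows only
    (``target_count - n`` of them).
    """
    x = np.asarray(minority_features, dtype=float)
    if x.ndim != 2:
        raise ValueError("minority_features must be 2-D")
    n = x.shape[0]
    if n < k_neighbors + 1:
        raise ValueError(
            f"need at least k_neighbors+1={k_neighbors + 1} minority samples "
            f"(got {n}); consider augmentation-only balancing"
        )
    n_new = target_count - n
    if n_new < 0:
        raise ValueError("target_count below current minority count")
    if n_new == 0:
        return np.empty((0, x.shape[1]))
    nn = NearestNeighbors(n_neighbors=k_neighbors + 1).fit(x)
    _, idx = nn.kneighbors(x)  # column 0 is the point itself
    rng = np.random.default_rng(seed)
    base = rng.integers(0, n, size=n_new)
    pick = rng.integers(1, k_neighbors + 1, size=n_new)
    gamma = rng.uniform(0.0, 1.0, size=n_new)
    neighbors = idx[base, pick]
    return x[base] + gamma[:, None] * (x[neighbors] - x[base])


def undersample_majority(
    items: Sequence, target_count: int, seed: int = 0
) -> list:
    """Uniform random subset (without replacement), original order kept."""
    if target_count > len(items):
        raise ValueError(
            f"target_count {target_count} exceeds available {len(items)}"
        )
    rng = np.random.default_rng(seed)
    keep = np.sort(rng.choice(len(items), size=target_count, replace=False))
    return [items[i] for i in keep]


def class_weights(
    counts: Mapping[int, int], ratio: tuple[float, float] = (2.0, 1.0)
) -> dict[int, float]:
    """Per-class loss weights at the requested benign:malignant ratio.

    Weights are proportional to ``ratio`` and normalized to mean 1, so the
    overall loss scale is unchanged: the default 2:1 gives (4/3, 2/3).
    """
    if any(c <= 0 for c in counts.values()):
        raise ValueError("every class must have a positive count")
    if set(counts) != {BENIGN, MALIGNANT}:
        raise ValueError("expected exactly the two classes {0, 1}")
    raw = {BENIGN: float(ratio[0]), MALIGNANT: float(ratio[1])}
    mean = (raw[BENIGN] + raw[MALIGNANT]) / 2.0
    return {c: w / mean for c, w in raw.items()}


def sample_weights_for(
    labels: np.ndarray, weights: Mapping[int, float]
) -> np.ndarray:
    """Expand per-class weights to a per-sample vector."""
    return np.array([weights[int(y)] for y in labels])


def _counts_for_class(
    n: int, plan: SplitPlan, cls: int
) -> tuple[int, int, int]:
    f_train, f_val, f_test = plan.fractions
    if plan.per_class_counts is not None and cls in plan.per_class_counts:
        trainval, n_test = plan.per_class_counts[cls]
        if trainval + n_test != n:
            raise ValueError(
                f"class {cls}: plan counts {trainval}+{n_test} != {n} available"
            )
    else:
        n_test = int(round(n * f_test))
        trainval = n - n_test
    denom = f_train + f_val
    n_train = trainval if denom == 0 else int(round(trainval * f_train / denom))
    n_val = trainval - n_train
    return n_train, n_val, n_test


def stratified_split(
    items: Sequence[LabeledImage], plan: SplitPlan
) -> tuple[list[LabeledImage], list[LabeledImage], list[LabeledImage]]:
    """Source-level stratified partition into train/validation/test.

    Items sharing a ``source_id`` always land in the same split (no
    leakage); stratification and the plan's counts apply to sources. The
    result is an exact partition, deterministic under ``plan.seed``.
    """
    by_source: dict[str, list[LabeledImage]] = {}
    source_label: dict[str, int] = {}
    for i, item in enumerate(items):
        sid = item.source_id or f"_anon{i}"
        by_source.setdefault(sid, []).append(item)
        source_label.setdefault(sid, item.label)
    rng = np.random.default_rng(plan.seed)
    train: list[LabeledImage] = []
    val: list[LabeledImage] = []
    test: list[LabeledImage] = []
    for cls in sorted({lab for lab in source_label.values()}):
        sources = sorted(s for s, lab in source_label.items() if lab == cls)
        if not sources:
            raise ValueError(f"class {cls} has no items")
        rng.shuffle(sources)
        n_train, n_val, n_test = _counts_for_class(len(sources), plan, cls)
        if min(n_train, n_val, n_test) < 0:
            raise ValueError(f"class {cls}: infeasible split counts")
        for split, chunk in (
            (train, sources[:n_train]),
            (val, sources[n_train : n_train + n_val]),
            (test, sources[n_train + n_val :]),
        ):
            for sid in chunk:
                split.extend(by_source[sid])
    return train, val, test


# ---------------------------------------------------------------------------
# Manifest I/O: CSV with columns (image_path, mask_path, label); images and
# masks as PNG or NIfTI.


def _read_image_file(path: Path) -> np.ndarray:
    if path.suffix == ".nii" or path.name.endswith(".nii.gz"):
        import nibabel as nib

        data = np.asanyarray(nib.load(str(path)).dataobj).astype(float)
        if data.ndim == 3:
            data = data[:, :, 0]
        return data
    from PIL import Image

    return np.asarray(Image.open(path).convert("L")).astype(float)


def read_manifest(manifest_csv: str | Path) -> list[LabeledImage]:
    """Load a dataset from a manifest CSV (paths relative to the CSV)."""
    manifest_csv = Path(manifest_csv)
    df = pd.read_csv(manifest_csv)
    required = {"image_path", "label"}
    if not required <= set(df.columns):
        raise ValueError(f"manifest must have columns {sorted(required)}")
    root = manifest_csv.parent
    items = []
    for _, row in df.iterrows():
        img = _read_image_file(root / str(row["image_path"]))
        mask = None
        if "mask_path" in df.columns and isinstance(row["mask_path"], str):
            from dcef.roi_ppm import load_mask

            mask = load_mask(root / row["mask_path"])
        sid = str(row["source_id"]) if "source_id" in df.columns else ""
        items.append(
            LabeledImage(
                image=img, label=int(row["label"]), roi_mask=mask, source_id=sid
            )
        )
    return items


def write_manifest(
    items: Sequence[LabeledImage], directory: str | Path, nifti: bool = False
) -> Path:
    """Write images (+ masks) as PNG (or NIfTI) plus a manifest CSV."""
    from PIL import Image

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    rows = []
    for i, item in enumerate(items):
        stem = f"img_{i:04d}"
        arr = np.clip(item.image, 0.0, 1.0)
        if nifti:
            import nibabel as nib

            img_name = f"{stem}.nii"
            nib.save(
                nib.Nifti1Image(arr.astype(np.float32), np.eye(4)),
                str(directory / img_name),
            )
        else:
            img_name = f"{stem}.png"
            Image.fromarray((arr * 255).round().astype(np.uint8)).save(
                directory / img_name
            )
        mask_name = ""
        if item.roi_mask is not None:
            mask_name = f"{stem}_mask.png"
            Image.fromarray(
                (item.roi_mask.astype(np.uint8) * 255)
            ).save(directory / mask_name)
        rows.append(
            {
                "image_path": img_name,
                "mask_path": mask_name if mask_name else np.nan,
                "label": item.label,
                "source_id": item.source_id,
            }
        )
    out = directory / "manifest.csv"
    pd.DataFrame(rows).to_csv(out, index=False)
    return out
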