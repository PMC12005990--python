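"""Seeded generator of two-class speckled grayscale images with ROI masks.

Emulates the statistical structure the pipeline assumes in real
lesion-bearing ultrasound frames, at desk scale and with no downloads:

* a smooth background field carrying multiplicative Rayleigh speckle (the
  standard first-order ultrasound texture model);
* one bright elliptical lesion per image, with boundary irregularity from
  radial harmonic perturbation — stronger for the malignant class, echoing
  the irregular morphology of malignant nodules;
* class-dependent lesion statistics (mean intensity, equivalent diameter,
  irregularity) whose between-class gaps all scale with a single
  ``separability`` knob: at 0 the class-conditional distributions are
  identical (a classifier must perform at chance), at the default 3 the
  classes are cleanly separable;
* an ROI mask equal to the exact lesion support;
* the cohort's class imbalance (27 benign / 68 malignant) by default.

Also provides a direct feature-space fixture for the fusion optimizer:
ensembles where chosen sub-networks carry a Gaussian class shift and the
rest are pure noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from dcef.fusion_core import FeatureBatch, LabelBatch
from dcef.preprocessing import BENIGN, MALIGNANT, LabeledImage

#: Within-class SD of the per-image lesion mean intensity; the between-class
#: intensity gap is ``separability`` times this, so separability is a
#: standardized effect size.
LESION_INTENSITY_SD = 0.05
_BASE_LESION_MEAN = 0.55
_IRREGULARITY_BASE = 0.04
_IRREGULARITY_GAIN = 0.03
_SIZE_SD = 2.0


@dataclass(frozen=True)
class SyntheticConfig:
    """Cohort-shaped defaults: 27 benign / 68 malignant, 64x64 frames,
    benign mean equivalent diameter 22.4 px vs malignant 23.8 px."""

    n_benign: int = 27
    n_malignant: int = 68
    image_size: tuple[int, int] = (64, 64)
    lesion_size_mean: tuple[float, float] = (22.4, 23.8)  # (benign, malignant)
    separability: float = 3.0
    noise_level: float = 0.3
    seed: int = 0

    def __post_init__(self):
        if self.n_benign < 0 or self.n_malignant < 0:
            raise ValueError("counts must be nonnegative")
        if self.separability < 0 or self.noise_level < 0:
            raise ValueError("separability and noise_level must be >= 0")
        if max(self.lesion_size_mean) >= min(self.image_size):
            raise ValueError("lesion diameter exceeds image size")


def _class_params(cfg: SyntheticConfig, label: int) -> tuple[float, float, float]:
    """(mean diameter, mean lesion intensity, irregularity amplitude).

    All three between-class gaps scale with separability; the configured
    size means are realized at separability >= 1.
    """
    size_b, size_m = cfg.lesion_size_mean
    center = 0.5 * (size_b + size_m)
    size_scale = min(cfg.separability, 1.0)
    intensity = _BASE_LESION_MEAN
    irregularity = _IRREGULARITY_BASE
    if label == MALIGNANT:
        diameter = center + 0.5 * (size_m - size_b) * size_scale
        intensity += cfg.separability * LESION_INTENSITY_SD
        irregularity += _IRREGULARITY_GAIN * min(cfg.separability, 3.0)
    else:
        diameter = center - 0.5 * (size_m - size_b) * size_scale
    return diameter, intensity, irregularity


def _render_image(
    cfg: SyntheticConfig, label: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray, dict]:
    h, w = cfg.image_size
    # smooth background field in [0.15, 0.40]
    background = gaussian_filter(rng.uniform(size=(h, w)), sigma=8.0)
    lo, hi = background.min(), background.max()
    background = 0.15 + 0.25 * (background - lo) / max(hi - lo, 1e-12)

    diameter_mean, intensity_mean, irregularity = _class_params(cfg, label)
    diameter = float(
        np.clip(rng.normal(diameter_mean, _SIZE_SD), 8.0, min(h, w) - 4.0)
    )
    radius = diameter / 2.0
    margin = radius * (1.0 + irregularity * 3.0) + 2.0
    if 2 * margin >= min(h, w):
        raise ValueError("lesion does not fit inside the image")
    cy = rng.uniform(margin, h - margin)
    cx = rng.uniform(margin, w - margin)
    aspect = rng.uniform(0.75, 1.0)
    tilt = rng.uniform(0.0, np.pi)

    # radial boundary perturbation: low harmonics, class-dependent amplitude
    n_harmonics = 4
    amps = irregularity * rng.uniform(0.3, 1.0, size=n_harmonics)
    phases = rng.uniform(0.0, 2 * np.pi, size=n_harmonics)

    yy, xx = np.mgrid[0:h, 0:w]
    dy, dx = yy - cy, xx - cx
    ry = dy * np.cos(tilt) - dx * np.sin(tilt)
    rx = dy * np.sin(tilt) + dx * np.cos(tilt)
    theta = np.arctan2(ry, rx)
    wobble = np.ones_like(theta)
    for k in range(n_harmonics):
        wobble += amps[k] * np.cos((k + 2) * theta + phases[k])
    boundary = radius * wobble
    rho = np.sqrt((rx / aspect) ** 2 + ry**2)
    mask = rho <= boundary

    lesion_mean = rng.normal(intensity_mean, LESION_INTENSITY_SD)
    texture = gaussian_filter(rng.normal(0.0, 1.0, size=(h, w)), sigma=1.5)
    image = background.copy()
    image[mask] = lesion_mean + 0.03 * texture[mask]

    if cfg.noise_level > 0:
        # Rayleigh speckle with unit mean, blended by noise_level
        speckle = rng.rayleigh(scale=np.sqrt(2 / np.pi), size=(h, w))
        image = image * (1.0 + cfg.noise_level * (speckle - 1.0))
    image = np.clip(image, 0.0, 1.0)
    info = {
        "diameter": diameter,
        "lesion_mean": lesion_mean,
        "mask_area": int(mask.sum()),
    }
    return image, mask, info


def generate_dataset(
    cfg: SyntheticConfig,
) -> tuple[list[LabeledImage], pd.DataFrame]:
    """Generate the dataset plus a manifest of per-image ground truth.

    Deterministic under ``cfg.seed`` (byte-identical across calls). The
    manifest records label, source id, and the drawn lesion statistics.
    """
    rng = np.random.default_rng(cfg.seed)
    items: list[LabeledImage] = []
    rows = []
    labels = [BENIGN] * cfg.n_benign + [MALIGNANT] * cfg.n_malignant
    for i, label in enumerate(labels):
        image, mask, info = _render_image(cfg, label, rng)
        sid = f"case_{i:04d}"
        items.append(
            LabeledImage(image=image, label=label, roi_mask=mask, source_id=sid)
        )
        rows.append({"source_id": sid, "label": label, **info})
    return items, pd.DataFrame(rows)


def generate_feature_ensembles(
    k: int,
    n: int,
    informative: Iterable[int] = (1,),
    separability: float = 3.0,
    dim: int = 8,
    seed: int = 0,
) -> tuple[list[FeatureBatch], LabelBatch]:
    """Direct feature-space fixture for the fusion optimizer.

    Builds ``k`` feature batches over the same ``n`` samples (balanced
    binary labels). Networks whose 1-based index is in ``informative``
    carry a Gaussian class shift of size ``separability`` along a random
    unit direction; the rest are pure standard-normal noise, so their
    heads can never beat chance and the fusion weights should starve them.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    informative = set(informative)
    if informative - set(range(1, k + 1)):
        raise ValueError("informative indices must lie in 1..k")
    rng = np.random.default_rng(seed)
    labels = np.arange(n) % 2
    rng.shuffle(labels)
    batches = []
    for j in range(1, k + 1):
        x = rng.standard_normal((n, dim))
        if j in informative:
            direction = rng.standard_normal(dim)
            direction /= np.linalg.norm(direction)
            x += np.outer(np.where(labels == 1, 0.5, -0.5) * separability, direction)
        batches.append(FeatureBatch(x, network_index=j - 1))
    return batches, LabelBatch(labels)
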