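"""Region-of-interest attention weighting and pyramid pooling.

Two feature-map refinements used around the backbone/classifier boundary:

* **ROI weight enhancement** — softmax attention over the feature responses
  inside a lesion mask: ``W_i = exp(F_i) / sum_j exp(F_j)`` over ROI
  locations, then a weighted sum ``sum_i W_i F_i`` per channel. Without a
  mask the whole map is treated as the ROI.
* **Pyramid pooling** — parallel adaptive average (or max) poolings at grid
  sizes (1, 2, 3, 6 by default), concatenated per channel into a
  multi-scale descriptor of ``channels * 50`` cells.

Both operate per channel; weights are computed with the max-shift trick so
large responses never overflow.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np


@dataclass(frozen=True)
class FeatureMap:
    """A ``(channels, H, W)`` response array with an optional binary ROI mask."""

    values: np.ndarray
    roi_mask: np.ndarray | None = None

    def __post_init__(self):
        vals = np.asarray(self.values, dtype=float)
        if vals.ndim == 2:
            vals = vals[None]
        if vals.ndim != 3:
            raise ValueError(f"values must be (C, H, W), got {vals.shape}")
        if not np.all(np.isfinite(vals)):
            raise ValueError("feature map contains non-finite entries")
        object.__setattr__(self, "values", vals)
        if self.roi_mask is not None:
            mask = np.asarray(self.roi_mask).astype(bool)
            if mask.shape != vals.shape[1:]:
                raise ValueError(
                    f"mask shape {mask.shape} != spatial shape {vals.shape[1:]}"
                )
            if not mask.any():
                raise ValueError("ROI mask is empty")
            object.__setattr__(self, "roi_mask", mask)

    @property
    def channels(self) -> int:
        return self.values.shape[0]


def _roi_values(fmap: FeatureMap) -> np.ndarray:
    """ROI responses as (channels, m) with m the number of ROI cells."""
    if fmap.roi_mask is None:
        return fmap.values.reshape(fmap.channels, -1)
    return fmap.values[:, fmap.roi_mask]


def roi_softmax_weights(fmap: FeatureMap) -> np.ndarray:
    """Attention weights over ROI locations, per channel: (channels, m).

    Each row sums to 1 and is invariant to adding a constant to the map.
    """
    roi = _roi_values(fmap)
    shifted = roi - roi.max(axis=1, keepdims=True)
    expd = np.exp(shifted)
    return expd / expd.sum(axis=1, keepdims=True)


def roi_enhance(fmap: FeatureMap) -> np.ndarray:
    """Attention-weighted response ``sum_i W_i F_i`` per channel.

    A convex combination of the ROI responses, so each channel's result
    lies in ``[min F, max F]`` over its ROI; adding a constant to the map
    shifts the result by that constant.
    """
    roi = _roi_values(fmap)
    return np.sum(roi_softmax_weights(fmap) * roi, axis=1)


def _adaptive_pool_1d(length: int, bins: int) -> list[slice]:
    # same bin-edge convention as standard adaptive pooling
    return [
        slice((i * length) // bins, -(-((i + 1) * length) // bins))
        for i in range(bins)
    ]


def pyramid_pool(
    fmap: FeatureMap,
    bin_sizes: Sequence[int] = (1, 2, 3, 6),
    operator: str = "average",
) -> np.ndarray:
    """Concatenated multi-scale pooled descriptor, length channels * sum(b^2).

    For each bin size ``b``, the map is adaptively pooled to a ``b x b``
    grid per channel (average by default, max optionally) and the grids are
    concatenated channel-major. Bin size 1 reproduces the global per-channel
    mean.
    """
    if operator not in ("average", "max"):
        raise ValueError(f"unknown pooling operator {operator!r}")
    _, h, w = fmap.values.shape
    if any(b < 1 for b in bin_sizes):
        raise ValueError("bin sizes must be >= 1")
    if max(bin_sizes) > min(h, w):
        raise ValueError(
            f"bin size {max(bin_sizes)} exceeds spatial dims ({h}, {w})"
        )
    reduce = np.mean if operator == "average" else np.max
    parts = []
    for ch in fmap.values:
        for b in bin_sizes:
            rows = _adaptive_pool_1d(h, b)
            cols = _adaptive_pool_1d(w, b)
            grid = np.array(
                [[reduce(ch[r, c]) for c in cols] for r in rows]
            )
            parts.append(grid.ravel())
    return np.concatenate(parts)


def load_mask(path: str | Path) -> np.ndarray:
    """Read a binary ROI mask from PNG (0/255) or a NIfTI label volume.

    For NIfTI with a third dimension, the first slice is used (the pipeline
    is 2-D).
    """
    path = Path(path)
    if path.suffix in (".nii", ".gz") or path.name.endswith(".nii.gz"):
        import nibabel as nib

        data = np.asanyarray(nib.load(str(path)).dataobj)
        if data.ndim == 3:
            data = data[:, :, 0]
        return data > 0
    from PIL import Image

    return np.asarray(Image.open(path).convert("L")) > 127
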