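"""Registry of sub-network feature extractors.

The ensemble treats a sub-network as an opaque map from an image batch to a
feature batch. Three desk-scale families are implemented in pure NumPy:

* ``identity`` — flattens pixels (useful for oracle tests);
* ``tiny-conv`` — two layers of fixed, seeded random 3x3 filters with ReLU
  and 2x2 average pooling, pyramid-pooled and randomly projected;
* ``tiny-attention`` — patch embedding followed by one softmax
  self-attention layer with fixed seeded projections, mean-pooled.

The random-feature extractors are frozen at construction: all learning
happens in the linear softmax heads, which is exactly the part of the model
the fused objective's gradients cover. The five conventional slot names
(vgg16, resnet18, resnet50, densenet121, inceptionv3, vit) are registered
as aliases of tiny stand-ins with distinct parameter draws, so ablation
tables over the named slots run on any CPU without downloads.
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
from scipy import ndimage
from skimage.transform import resize

from dcef.fusion_core import ClassifierWeights, FeatureBatch
from dcef.roi_ppm import FeatureMap, pyramid_pool

logger = logging.getLogger(__name__)

FAMILIES = ("convolutional", "attention", "tiny-conv", "tiny-attention", "identity")


@dataclass(frozen=True)
class BackboneSpec:
    """Declared contract of a feature extractor."""

    name: str
    input_size: tuple[int, int, int]  # (H, W, channels)
    feature_dim: int
    family: str

    def __post_init__(self):
        if self.feature_dim < 1:
            raise ValueError("feature_dim must be >= 1")
        if any(s < 1 for s in self.input_size):
            raise ValueError("input_size must be positive")
        if self.family not in FAMILIES:
            raise ValueError(f"unknown family {self.family!r}")


class RegistryError(KeyError):
    pass


def _stable_offset(name: str) -> int:
    # crc32 is stable across processes (unlike hash()); keeps seeds < 2^31
    return zlib.crc32(name.encode()) % (2**20)


def _prep_batch(images: np.ndarray, hw: tuple[int, int]) -> np.ndarray:
    """Coerce to (n, H, W) float at the extractor's declared spatial size."""
    arr = np.asarray(images, dtype=float)
    if arr.ndim == 2:
        arr = arr[None]
    if arr.ndim == 4:  # trailing channel axis: average to grayscale
        arr = arr.mean(axis=3)
    if arr.ndim != 3:
        raise ValueError(f"expected image batch, got shape {arr.shape}")
    if arr.shape[1:] != hw:
        arr = np.stack(
            [resize(im, hw, order=1, anti_aliasing=True) for im in arr]
        )
    return arr


class Backbone:
    """A frozen extractor: image batch -> (n, feature_dim) FeatureBatch."""

    def __init__(self, spec: BackboneSpec, seed: int):
        self.spec = spec
        self.seed = int(seed)
        self._rng_seed = (self.seed + _stable_offset(spec.name)) % (2**31)
        self._build(np.random.default_rng(self._rng_seed))

    def _build(self, rng: np.random.Generator) -> None:
        raise NotImplementedError

    def _features(self, batch: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def __call__(self, images: np.ndarray, network_index: int = 0) -> FeatureBatch:
        batch = _prep_batch(images, self.spec.input_size[:2])
        feats = self._features(batch)
        if feats.shape[1] != self.spec.feature_dim:
            raise RuntimeError(
                f"{self.spec.name}: produced {feats.shape[1]} dims, "
                f"declared {self.spec.feature_dim}"
            )
        return FeatureBatch(feats, network_index=network_index)

    def head_init(self, n_classes: int = 2) -> ClassifierWeights:
        return ClassifierWeights(np.zeros((self.spec.feature_dim, n_classes)))


class IdentityBackbone(Backbone):
    def _build(self, rng):
        pass

    def _features(self, batch):
        return batch.reshape(batch.shape[0], -1)


class TinyConvBackbone(Backbone):
    """Two fixed random conv layers + pyramid pooling + random projection."""

    def __init__(self, spec: BackboneSpec, seed: int, n_filters: tuple[int, int] = (6, 12)):
        self.n_filters = n_filters
        super().__init__(spec, seed)

    def _build(self, rng):
        f1, f2 = self.n_filters
        self.filters1 = rng.standard_normal((f1, 3, 3)) / 3.0
        self.filters2 = rng.standard_normal((f2, f1, 3, 3)) / (3.0 * np.sqrt(f1))
        pooled_cells = f2 * 50  # pyramid bins (1,2,3,6) -> 50 cells/channel
        self.proj = rng.standard_normal(
            (pooled_cells, self.spec.feature_dim)
        ) / np.sqrt(pooled_cells)

    @staticmethod
    def _pool2(maps: np.ndarray) -> np.ndarray:
        c, h, w = maps.shape
        h2, w2 = h - h % 2, w - w % 2
        m = maps[:, :h2, :w2]
        return 0.25 * (
            m[:, 0::2, 0::2] + m[:, 1::2, 0::2] + m[:, 0::2, 1::2] + m[:, 1::2, 1::2]
        )

    def _features(self, batch):
        out = []
        for img in batch:
            maps = np.stack(
                [ndimage.correlate(img, f, mode="reflect") for f in self.filters1]
            )
            maps = self._pool2(np.maximum(maps, 0.0))
            maps2 = np.stack(
                [
                    sum(
                        ndimage.correlate(maps[c], f[c], mode="reflect")
                        for c in range(maps.shape[0])
                    )
                    for f in self.filters2
                ]
            )
            maps2 = self._pool2(np.maximum(maps2, 0.0))
            pooled = pyramid_pool(FeatureMap(maps2), (1, 2, 3, 6))
            out.append(pooled @ self.proj)
        return np.vstack(out)


class TinyAttentionBackbone(Backbone):
    """Patch embedding + one frozen self-attention layer, mean-pooled."""

    patch = 8
    embed = 24

    def _build(self, rng):
        p, e = self.patch, self.embed
        self.w_embed = rng.standard_normal((p * p, e)) / p
        self.w_q = rng.standard_normal((e, e)) / np.sqrt(e)
        self.w_k = rng.standard_normal((e, e)) / np.sqrt(e)
        self.w_v = rng.standard_normal((e, e)) / np.sqrt(e)
        self.proj = rng.standard_normal((2 * e, self.spec.feature_dim)) / np.sqrt(2 * e)

    def _features(self, batch):
        n, h, w = batch.shape
        p = self.patch
        hp, wp = h // p, w // p
        patches = (
            batch[:, : hp * p, : wp * p]
            .reshape(n, hp, p, wp, p)
            .transpose(0, 1, 3, 2, 4)
            .reshape(n, hp * wp, p * p)
        )
        tokens = patches @ self.w_embed  # (n, P, e)
        q, k_, v = tokens @ self.w_q, tokens @ self.w_k, tokens @ self.w_v
        scores = q @ k_.transpose(0, 2, 1) / np.sqrt(self.embed)
        scores -= scores.max(axis=2, keepdims=True)
        attn = np.exp(scores)
        attn /= attn.sum(axis=2, keepdims=True)
        mixed = (attn @ v).mean(axis=1)  # (n, e)
        summary = np.concatenate([mixed, tokens.mean(axis=1)], axis=1)
        return summary @ self.proj


_DEFAULT_HW = (64, 64, 1)

_REGISTRY: dict[str, tuple[BackboneSpec, Callable[..., Backbone]]] = {}


def register(spec: BackboneSpec, factory: Callable[..., Backbone]) -> None:
    _REGISTRY[spec.name] = (spec, factory)


def registered_names() -> list[str]:
    return sorted(_REGISTRY)


def _register_defaults() -> None:
    register(
        BackboneSpec("identity", _DEFAULT_HW, 64 * 64, "identity"),
        IdentityBackbone,
    )
    register(
        BackboneSpec("tiny-conv", _DEFAULT_HW, 192, "tiny-conv"),
        TinyConvBackbone,
    )
    register(
        BackboneSpec("tiny-attention", _DEFAULT_HW, 128, "tiny-attention"),
        TinyAttentionBackbone,
    )
    # Conventional slot names: tiny stand-ins with distinct parameter draws
    # (the name enters the seed), so each slot is a genuinely different
    # extractor and ablations over the slots are meaningful at desk scale.
    for alias in ("vgg16", "resnet18", "resnet50", "densenet121", "inceptionv3"):
        register(
            BackboneSpec(alias, _DEFAULT_HW, 192, "convolutional"),
            TinyConvBackbone,
        )
    register(
        BackboneSpec("vit", _DEFAULT_HW, 128, "attention"),
        TinyAttentionBackbone,
    )


_register_defaults()


def build_backbone(spec: BackboneSpec | str, seed: int = 0) -> Backbone:
    """Instantiate an extractor from a spec or a registered name."""
    if isinstance(spec, str):
        if spec not in _REGISTRY:
            raise RegistryError(
                f"unknown backbone {spec!r}; registered: {registered_names()}"
            )
        spec_obj, factory = _REGISTRY[spec]
        return factory(spec_obj, seed)
    if spec.name in _REGISTRY:
        factory = _REGISTRY[spec.name][1]
    elif spec.family in ("tiny-conv", "convolutional"):
        factory = TinyConvBackbone
    elif spec.family in ("tiny-attention", "attention"):
        factory = TinyAttentionBackbone
    elif spec.family == "identity":
        factory = IdentityBackbone
    else:
        raise RegistryError(f"no factory for family {spec.family!r}")
    return factory(spec, seed)


def ensemble_from_names(
    names: Sequence[str], seed: int = 0
) -> tuple[list[Backbone], list[Callable[[int], ClassifierWeights]]]:
    """Build K extractors (order preserved) plus head initializers.

    Duplicate names are allowed (each gets the same frozen parameters) and
    logged; an empty list is an error.
    """
    if not names:
        raise ValueError("need at least one backbone name")
    seen = set()
    for nm in names:
        if nm in seen:
            logger.warning("duplicate backbone name %r in ensemble", nm)
        seen.add(nm)
    extractors = [build_backbone(nm, seed) for nm in names]
    return extractors, [bb.head_init for bb in extractors]
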