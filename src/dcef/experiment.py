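"""End-to-end experiment runner: preprocess, train, evaluate, ablate.

A run takes a ``RunConfig`` (YAML-serializable), builds or loads a
dataset, applies the imbalance pipeline to the training split only
(augment -> SMOTE -> undersample -> class weights), extracts features with
every requested backbone once, trains the fused ensemble, and evaluates on
all three splits. The ablation runner reuses the same encoded dataset
across network subsets so rows differ only in the ensemble composition.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from dcef.backbones import Backbone, ensemble_from_names
from dcef.fusion_core import FeatureBatch, LabelBatch
from dcef.fusion_optimizer import FitResult, TrainConfig, fit
from dcef.metrics import (
    ScoredPredictions,
    classification_metrics,
    confusion,
    roc_auc,
    youden_threshold,
)
from dcef.preprocessing import (
    BENIGN,
    MALIGNANT,
    LabeledImage,
    SplitPlan,
    augment,
    class_weights,
    crop_to_roi,
    normalize_and_resize,
    read_manifest,
    sample_weights_for,
    smote_oversample,
    stratified_split,
    undersample_majority,
)
from dcef.roi_ppm import FeatureMap, roi_enhance
from dcef.schedule import cosine_lr  # noqa: F401  (public surface)
from dcef.synthetic_data import SyntheticConfig, generate_dataset

DEFAULT_NETWORKS = ("vgg16", "resnet18", "densenet121", "inceptionv3", "vit")


@dataclass
class RunConfig:
    """Full experiment configuration with conventional defaults.

    The optimizer block defaults to the standard recipe (lr 0.1, momentum
    0.9, weight decay 5e-4, batch 128, 100 epochs, cosine period 100); the
    split is 50/20/30 and the class-weight ratio 2:1 benign:malignant.
    """

    networks: list[str] = field(default_factory=lambda: list(DEFAULT_NETWORKS))
    # optimizer block
    lr: float = 0.1
    momentum: float = 0.9
    weight_decay: float = 5e-4
    batch_size: int = 128
    epochs: int = 100
    t_max: int = 100
    # balancing block
    smote: bool = True
    augment_minority: bool = True
    class_weight_ratio: tuple[float, float] = (2.0, 1.0)
    undersample_target: int | None = None
    # split plan
    split_fractions: tuple[float, float, float] = (0.5, 0.2, 0.3)
    # data source: either a manifest CSV or the synthetic generator
    manifest: str | None = None
    synthetic: bool = True
    n_benign: int = 27
    n_malignant: int = 68
    separability: float = 3.0
    noise_level: float = 0.3
    image_size: tuple[int, int] = (64, 64)
    roi_crop: bool = True
    roi_feature: bool = True
    seed: int = 0
    out_dir: str | None = None

    def to_dict(self) -> dict:
        d = asdict(self)
        for key in ("class_weight_ratio", "split_fractions", "image_size"):
            d[key] = list(d[key])
        return d

    @staticmethod
    def from_dict(d: dict) -> "RunConfig":
        d = dict(d)
        for key in ("class_weight_ratio", "split_fractions", "image_size"):
            if key in d:
                d[key] = tuple(d[key])
        return RunConfig(**d)

    def save(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict()))

    @staticmethod
    def load(path: str | Path) -> "RunConfig":
        return RunConfig.from_dict(yaml.safe_load(Path(path).read_text()))

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:16]

    def train_config(self) -> TrainConfig:
        return TrainConfig(
            lr=self.lr,
            momentum=self.momentum,
            weight_decay=self.weight_decay,
            batch_size=self.batch_size,
            epochs=self.epochs,
            t_max=self.t_max,
            seed=self.seed,
        )


def _load_items(cfg: RunConfig) -> list[LabeledImage]:
    if cfg.manifest is not None:
        items = read_manifest(cfg.manifest)
    elif cfg.synthetic:
        items, _ = generate_dataset(
            SyntheticConfig(
                n_benign=cfg.n_benign,
                n_malignant=cfg.n_malignant,
                image_size=cfg.image_size,
                separability=cfg.separability,
                noise_level=cfg.noise_level,
                seed=cfg.seed,
            )
        )
    else:
        raise ValueError("no manifest given and synthetic mode disabled")
    if cfg.roi_crop:
        items = [crop_to_roi(it) for it in items]
    return [normalize_and_resize(it, cfg.image_size) for it in items]


def _augment_to(
    minority: list[LabeledImage], target: int, seed: int
) -> list[LabeledImage]:
    """Grow the minority list to ``target`` with randomized augmentations."""
    rng = np.random.default_rng(seed)
    out = list(minority)
    pool = ("rotate", "flip", "translate")
    while len(out) < target:
        base = minority[int(rng.integers(len(minority)))]
        op = pool[int(rng.integers(3))]
        variants = augment(base, (op,), seed=int(rng.integers(2**31)))
        out.append(variants[int(rng.integers(len(variants)))])
    return out


def _roi_summary(item: LabeledImage) -> np.ndarray:
    """ROI descriptors: attention-weighted response, mean, fill fraction.

    The first is the decoding-phase weight enhancement (softmax attention
    over ROI responses); the mean and the ROI's areal fraction summarize
    lesion brightness and boundary compactness.
    """
    if item.roi_mask is None:
        mean = float(item.image.mean())
        enhanced = roi_enhance(FeatureMap(item.image[None]))[0]
        return np.array([enhanced, mean, 1.0])
    fmap = FeatureMap(item.image[None], roi_mask=item.roi_mask)
    return np.array(
        [
            roi_enhance(fmap)[0],
            float(item.image[item.roi_mask].mean()),
            float(item.roi_mask.mean()),
        ]
    )


def _extract(
    backbones: Sequence[Backbone],
    items: Sequence[LabeledImage],
    roi_feature: bool,
) -> list[np.ndarray]:
    images = np.stack([it.image for it in items])
    feats = [bb(images, network_index=j).features for j, bb in enumerate(backbones)]
    if roi_feature:
        cols = np.stack([_roi_summary(it) for it in items])
        feats = [np.hstack([f, cols]) for f in feats]
    return feats


@dataclass
class EncodedDataset:
    """Split, balanced, and feature-encoded data ready for training."""

    train_features: list[np.ndarray]  # per network, (n_train, d_k)
    train_labels: np.ndarray
    train_weights: np.ndarray
    eval_features: dict[str, list[np.ndarray]]  # split -> per-network
    eval_labels: dict[str, np.ndarray]
    network_names: list[str]
    # per-network (mean, std) of the balanced training features; applied to
    # every split so the SGD step size is well-scaled across backbones
    scalers: list[tuple[np.ndarray, np.ndarray]] = field(default_factory=list)


def encode_dataset(cfg: RunConfig) -> EncodedDataset:
    """Split the dataset, balance the training split, extract features.

    Balancing order: augmentation of the benign minority up to 80% of the
    malignant count, SMOTE in (joint) feature space for the remainder,
    optional undersampling of the malignant majority, then 2:1 class
    weights. Evaluation splits are never balanced or augmented.
    """
    items = _load_items(cfg)
    plan = SplitPlan(fractions=cfg.split_fractions, seed=cfg.seed)
    train, val, test = stratified_split(items, plan)
    backbones, _ = ensemble_from_names(cfg.networks, seed=cfg.seed)

    benign = [it for it in train if it.label == BENIGN]
    malignant = [it for it in train if it.label == MALIGNANT]
    if cfg.undersample_target is not None:
        malignant = undersample_majority(
            malignant, cfg.undersample_target, seed=cfg.seed
        )
    if cfg.augment_minority and benign and len(benign) < len(malignant):
        target = max(len(benign), int(round(0.8 * len(malignant))))
        benign = _augment_to(benign, target, seed=cfg.seed)

    train_items = benign + malignant
    train_feats = _extract(backbones, train_items, cfg.roi_feature)
    train_labels = np.array([it.label for it in train_items])

    if cfg.smote and 0 < np.sum(train_labels == BENIGN) < np.sum(
        train_labels == MALIGNANT
    ):
        minority_rows = np.where(train_labels == BENIGN)[0]
        joint = np.hstack([f[minority_rows] for f in train_feats])
        k_nn = min(5, len(minority_rows) - 1)
        synth = smote_oversample(
            joint,
            target_count=int(np.sum(train_labels == MALIGNANT)),
            k_neighbors=k_nn,
            seed=cfg.seed,
        )
        offset = 0
        for j, f in enumerate(train_feats):
            d = f.shape[1]
            train_feats[j] = np.vstack([f, synth[:, offset : offset + d]])
            offset += d
        train_labels = np.concatenate(
            [train_labels, np.full(synth.shape[0], BENIGN)]
        )

    scalers = []
    for j, f in enumerate(train_feats):
        mean = f.mean(axis=0)
        std = np.maximum(f.std(axis=0), 1e-8)
        scalers.append((mean, std))
        train_feats[j] = (f - mean) / std

    weights = class_weights(
        {
            BENIGN: max(int(np.sum(train_labels == BENIGN)), 1),
            MALIGNANT: max(int(np.sum(train_labels == MALIGNANT)), 1),
        },
        ratio=cfg.class_weight_ratio,
    )
    train_weights = sample_weights_for(train_labels, weights)

    eval_features = {}
    eval_labels = {}
    for name, split in (("train", train), ("validation", val), ("test", test)):
        if split:
            feats = _extract(backbones, split, cfg.roi_feature)
            eval_features[name] = [
                (f - m) / s for f, (m, s) in zip(feats, scalers)
            ]
            eval_labels[name] = np.array([it.label for it in split])
    return EncodedDataset(
        train_features=train_feats,
        train_labels=train_labels,
        train_weights=train_weights,
        eval_features=eval_features,
        eval_labels=eval_labels,
        network_names=list(cfg.networks),
        scalers=scalers,
    )


def _evaluate_split(
    result: FitResult, feats: list[np.ndarray], labels: np.ndarray
) -> dict:
    batches = [FeatureBatch(f, network_index=j) for j, f in enumerate(feats)]
    scores = result.predict_proba(batches)[:, MALIGNANT]
    scored = ScoredPredictions(scores, labels)
    report = classification_metrics(confusion(scored, 0.5))
    out = {f"{k}": v for k, v in report.as_dict().items()}
    out["error_rate"] = 1.0 - out["accuracy"]
    if len(set(labels.tolist())) == 2:
        points, auc = roc_auc(scored)
        out["auc"] = auc
        out["youden_threshold"] = youden_threshold(scored)
        out["_roc_points"] = points
    out["_scores"] = scores
    return out


def _train_on(
    encoded: EncodedDataset, cfg: RunConfig, network_indices: Sequence[int]
) -> tuple[FitResult, dict[str, dict]]:
    feats = [encoded.train_features[j] for j in network_indices]
    batches = [FeatureBatch(f, network_index=j) for j, f in enumerate(feats)]
    result = fit(
        batches,
        LabelBatch(encoded.train_labels),
        config=cfg.train_config(),
        sample_weights=encoded.train_weights,
    )
    evals = {
        split: _evaluate_split(
            result,
            [encoded.eval_features[split][j] for j in network_indices],
            encoded.eval_labels[split],
        )
        for split in encoded.eval_features
    }
    return result, evals


def run_experiment(
    cfg: RunConfig, encoded: EncodedDataset | None = None
) -> dict:
    """Execute preprocessing -> training -> evaluation; write artifacts.

    Returns a results dict with per-split metrics, the fitted bundle, and
    the training trajectories. If ``cfg.out_dir`` is set, writes metrics
    JSON, per-split ROC CSVs, a predictions CSV, the model bundle, and a
    log with seed, config hash, fused-loss and pi trajectories.
    """
    if encoded is None:
        encoded = encode_dataset(cfg)
    result, evals = _train_on(encoded, cfg, range(len(cfg.networks)))

    metrics_out = {
        split: {k: v for k, v in ev.items() if not k.startswith("_")}
        for split, ev in evals.items()
    }
    results = {
        "metrics": metrics_out,
        "fit": result,
        "pi": result.fusion.pi.tolist(),
        "config_hash": cfg.config_hash(),
    }

    if cfg.out_dir is not None:
        out = Path(cfg.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "metrics.json").write_text(json.dumps(metrics_out, indent=2))
        pred_rows = []
        for split, ev in evals.items():
            labels = encoded.eval_labels[split]
            for i, (score, lab) in enumerate(zip(ev["_scores"], labels)):
                pred_rows.append(
                    {
                        "source_id": f"{split}_{i:04d}",
                        "score": score,
                        "label": int(lab),
                        "split": split,
                    }
                )
            if "_roc_points" in ev:
                pd.DataFrame(
                    ev["_roc_points"], columns=["fpr", "tpr"]
                ).to_csv(out / f"roc_{split}.csv", index=False)
        pd.DataFrame(pred_rows).to_csv(out / "predictions.csv", index=False)
        result.save(out / "bundle")
        (out / "bundle" / "features.json").write_text(
            json.dumps(
                {
                    "networks": list(cfg.networks),
                    "roi_crop": cfg.roi_crop,
                    "roi_feature": cfg.roi_feature,
                    "image_size": list(cfg.image_size),
                    "backbone_seed": cfg.seed,
                }
            )
        )
        np.savez(
            out / "bundle" / "scalers.npz",
            **{
                f"mean{j}": m
                for j, (m, _) in enumerate(encoded.scalers)
            },
            **{f"std{j}": s for j, (_, s) in enumerate(encoded.scalers)},
        )
        log = {
            "seed": cfg.seed,
            "config_hash": cfg.config_hash(),
            "config": cfg.to_dict(),
            "fused_loss_history": result.fused_loss_history,
            "pi_history": result.pi_history.tolist(),
            "artifacts": [
                "metrics.json",
                "predictions.csv",
                "bundle/heads.npz",
                "bundle/bundle.json",
            ]
            + [f"roc_{s}.csv" for s in evals if "_roc_points" in evals[s]],
        }
        (out / "log.json").write_text(json.dumps(log, indent=2))
    return results


def default_ablation_subsets(networks: Sequence[str]) -> list[list[str]]:
    """Singletons of every network plus nested prefixes of length >= 2.

    For the five conventional slots this yields the familiar nine-row
    ablation design (5 singletons + 4 nested combinations).
    """
    singles = [[nm] for nm in networks]
    nested = [list(networks[:k]) for k in range(2, len(networks) + 1)]
    return singles + nested


def run_ablation(
    cfg: RunConfig, subsets: Sequence[Sequence[str]] | None = None
) -> pd.DataFrame:
    """One training run per network subset on shared data and features.

    Emits a checkmark-matrix table with test error rate and F1 (percent),
    one row per subset.
    """
    if subsets is None:
        subsets = default_ablation_subsets(cfg.networks)
    for sub in subsets:
        unknown = set(sub) - set(cfg.networks)
        if not sub or unknown:
            raise ValueError(f"invalid subset {sub!r}")
    encoded = encode_dataset(cfg)
    rows = []
    for sub in subsets:
        indices = [cfg.networks.index(nm) for nm in sub]
        _, evals = _train_on(encoded, cfg, indices)
        ev = evals.get("test", next(iter(evals.values())))
        row = {nm: ("✓" if nm in sub else "") for nm in cfg.networks}
        row["error_rate_pct"] = 100.0 * ev["error_rate"]
        row["f1_pct"] = 100.0 * ev["f1"]
        rows.append(row)
    table = pd.DataFrame(rows)
    if cfg.out_dir is not None:
        out = Path(cfg.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        table.to_csv(out / "ablation.csv", index=False)
    return table
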