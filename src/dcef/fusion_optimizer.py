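"""Alternating optimization of heads, fusion weights, and multipliers.

The constrained problem

    min_{w, pi}  sum_k pi_k CE_k(w_k)   s.t.  sum_k pi_k = 1, pi_k > 0

is handled with an augmented Lagrangian: a multiplier ``eta`` for the
equality constraint, a multiplier vector ``xi`` for positivity, and a
quadratic penalty with coefficient ``tau``. Each epoch alternates

  (a) minibatch SGD on every head ``w_k`` with ``pi`` fixed (momentum,
      weight decay, cosine-annealed step size),
  (b) a closed-form update of ``pi``: the stationary point of the
      Lagrangian in ``pi`` solves the K x K system
      ``tau (11^T + I) pi = tau 1 - (losses + eta 1 + xi)``,
      then Euclidean projection onto the simplex,
  (c) first-order multiplier updates and a penalty increase.

The projection is not cosmetic: restricted to the simplex the objective is
``pi . (losses + xi) + (tau/2)||pi||^2`` up to a constant, i.e. a scaled
squared distance to ``-(losses + xi)/tau``, and the unconstrained
stationary point differs from that center by a multiple of the ones vector
— to which simplex projection is invariant. Projecting the closed-form
point therefore lands exactly on the constrained minimizer, which is
anti-monotone in the per-network losses: high-loss networks get small
weights.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np

from dcef.fusion_core import (
    PI_EPS,
    ClassifierWeights,
    FeatureBatch,
    FusionWeights,
    LabelBatch,
    cross_entropy,
    softmax_probs,
)
from dcef.schedule import cosine_lr


class TrainingError(RuntimeError):
    """Raised when the fused loss becomes non-finite; carries the history."""

    def __init__(self, message: str, history: list[float]):
        super().__init__(message)
        self.history = history


@dataclass(frozen=True)
class LagrangeState:
    """Multipliers and penalty of the augmented Lagrangian.

    ``eta`` pairs with the equality constraint ``1^T pi = 1``; ``xi`` (one
    entry per network) with positivity; ``tau`` is the quadratic-penalty
    coefficient and must stay positive. ``step_sizes`` are the multiplier
    step lengths (theta1, theta2, theta3).
    """

    eta: float = 0.0
    xi: np.ndarray = field(default_factory=lambda: np.zeros(1))
    tau: float = 1.0
    step_sizes: tuple[float, float, float] = (0.1, 0.1, 0.1)

    def __post_init__(self):
        object.__setattr__(self, "xi", np.asarray(self.xi, dtype=float))
        if self.tau <= 0:
            raise ValueError("tau must be positive")
        if any(s <= 0 for s in self.step_sizes):
            raise ValueError("step sizes must be positive")

    @staticmethod
    def initial(k: int, step_sizes=(0.1, 0.1, 0.1)) -> "LagrangeState":
        return LagrangeState(eta=0.0, xi=np.zeros(k), tau=1.0, step_sizes=step_sizes)


@dataclass(frozen=True)
class PerNetworkLossSummary:
    """Per-network cross-entropy summaries for one epoch (length K)."""

    loss_terms: np.ndarray

    def __post_init__(self):
        lt = np.asarray(self.loss_terms, dtype=float)
        if lt.ndim != 1 or lt.size < 1:
            raise ValueError("loss_terms must be a nonempty vector")
        if not np.all(np.isfinite(lt)) or np.any(lt < 0):
            raise ValueError("loss_terms must be finite and nonnegative")
        object.__setattr__(self, "loss_terms", lt)


def grad_classifier(
    features: FeatureBatch,
    weights: ClassifierWeights,
    labels: LabelBatch,
    pi_k: float,
    sample_weights: np.ndarray | None = None,
) -> np.ndarray:
    """Gradient of ``pi_k * CE_k`` w.r.t. the head: ``-pi_k X^T (Y - P)``.

    ``Y`` is the one-hot label matrix and ``P`` the softmax output; the
    result has shape ``(d_k, C)`` and is summed over samples. Exactly
    linear in ``pi_k``; zero when predictions match the labels exactly.
    """
    if not 0 < pi_k <= 1:
        raise ValueError("pi_k must be in (0, 1]")
    labels.validate_against(weights.n_classes)
    probs = softmax_probs(features, weights)
    onehot = np.zeros_like(probs)
    onehot[np.arange(features.n), labels.labels] = 1.0
    resid = probs - onehot
    if sample_weights is not None:
        resid = resid * np.asarray(sample_weights, dtype=float)[:, None]
    return pi_k * (features.features.T @ resid)


def project_simplex(v: np.ndarray, eps: float = PI_EPS) -> np.ndarray:
    """Euclidean projection onto the simplex, floored to the open simplex.

    Sort-based algorithm; afterwards entries are floored at ``eps`` and
    renormalized so every coordinate is strictly positive (perturbation at
    most ``K * eps``).
    """
    v = np.asarray(v, dtype=float)
    u = np.sort(v)[::-1]
    css = np.cumsum(u) - 1.0
    idx = np.arange(1, v.size + 1)
    rho = np.nonzero(u - css / idx > 0)[0][-1]
    theta = css[rho] / (rho + 1.0)
    pi = np.maximum(v - theta, 0.0)
    pi = np.maximum(pi, eps)
    return pi / pi.sum()


def update_pi(
    losses: PerNetworkLossSummary, lagrange: LagrangeState
) -> FusionWeights:
    """Closed-form fusion-weight update followed by simplex projection.

    Solves ``tau (11^T + I) pi = tau 1 - (losses + eta 1 + xi)`` (the
    stationarity condition of the augmented Lagrangian in ``pi``) and
    projects onto the simplex. For fixed multipliers the result orders the
    networks inversely to their losses.
    """
    ell = losses.loss_terms
    k = ell.size
    if lagrange.xi.shape != (k,):
        raise ValueError(f"xi has shape {lagrange.xi.shape}, expected ({k},)")
    if k == 1:
        return FusionWeights(np.array([1.0]))
    system = lagrange.tau * (np.ones((k, k)) + np.eye(k))
    rhs = lagrange.tau - ell - lagrange.eta - lagrange.xi
    raw = np.linalg.solve(system, rhs)
    return FusionWeights(project_simplex(raw))


def update_multipliers(
    pi: FusionWeights, lagrange: LagrangeState
) -> LagrangeState:
    """First-order multiplier steps plus the penalty increase.

    ``eta += theta1 (1^T pi - 1)``; ``xi += theta2 pi`` elementwise;
    ``tau += (theta3/2)(|1^T pi - 1|^2 + ||pi||^2)`` — strictly increasing
    for any nonzero ``pi``.
    """
    t1, t2, t3 = lagrange.step_sizes
    resid = float(pi.pi.sum() - 1.0)
    return LagrangeState(
        eta=lagrange.eta + t1 * resid,
        xi=lagrange.xi + t2 * pi.pi,
        tau=lagrange.tau + 0.5 * t3 * (resid**2 + float(pi.pi @ pi.pi)),
        step_sizes=lagrange.step_sizes,
    )


@dataclass
class TrainConfig:
    """SGD and fusion hyperparameters.

    Defaults are the full-scale training recipe (initial rate 0.1 with
    momentum 0.9, weight decay 5e-4, batch 128, 100 epochs, cosine period
    100); desk-scale tests shrink epochs and batch size only.
    """

    lr: float = 0.1
    momentum: float = 0.9
    weight_decay: float = 5e-4
    batch_size: int = 128
    epochs: int = 100
    t_max: int = 100
    lr_min: float = 0.0
    theta: tuple[float, float, float] = (0.1, 0.1, 0.1)
    seed: int = 0

    def to_dict(self) -> dict:
        d = asdict(self)
        d["theta"] = list(self.theta)
        return d


@dataclass
class FitResult:
    """Trained bundle: K heads, final fusion weights, multipliers, history."""

    heads: list[ClassifierWeights]
    fusion: FusionWeights
    lagrange: LagrangeState
    fused_loss_history: list[float]
    per_network_loss_history: np.ndarray  # (epochs+1, K)
    pi_history: np.ndarray  # (epochs+1, K)
    config: TrainConfig

    def save(self, directory: str | Path) -> Path:
        """Serialize to a directory: weight tensors + a JSON sidecar."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        np.savez(
            directory / "heads.npz",
            **{f"w{k}": h.weights for k, h in enumerate(self.heads)},
        )
        sidecar = {
            "pi": self.fusion.pi.tolist(),
            "eta": self.lagrange.eta,
            "xi": self.lagrange.xi.tolist(),
            "tau": self.lagrange.tau,
            "theta": list(self.lagrange.step_sizes),
            "fused_loss_history": self.fused_loss_history,
            "per_network_loss_history": self.per_network_loss_history.tolist(),
            "pi_history": self.pi_history.tolist(),
            "config": self.config.to_dict(),
        }
        (directory / "bundle.json").write_text(json.dumps(sidecar, indent=2))
        return directory

    @staticmethod
    def load(directory: str | Path) -> "FitResult":
        directory = Path(directory)
        sidecar = json.loads((directory / "bundle.json").read_text())
        with np.load(directory / "heads.npz") as npz:
            heads = [
                ClassifierWeights(npz[f"w{k}"]) for k in range(len(npz.files))
            ]
        cfg_d = dict(sidecar["config"])
        cfg_d["theta"] = tuple(cfg_d["theta"])
        return FitResult(
            heads=heads,
            fusion=FusionWeights(np.array(sidecar["pi"])),
            lagrange=LagrangeState(
                eta=sidecar["eta"],
                xi=np.array(sidecar["xi"]),
                tau=sidecar["tau"],
                step_sizes=tuple(sidecar["theta"]),
            ),
            fused_loss_history=list(sidecar["fused_loss_history"]),
            per_network_loss_history=np.array(
                sidecar["per_network_loss_history"]
            ),
            pi_history=np.array(sidecar["pi_history"]),
            config=TrainConfig(**cfg_d),
        )

    def predict_proba(
        self, feature_batches: Sequence[FeatureBatch]
    ) -> np.ndarray:
        """Fusion-weighted average of per-network softmax outputs, (n, C)."""
        probs = [
            softmax_probs(fb, h) * p
            for fb, h, p in zip(feature_batches, self.heads, self.fusion.pi)
        ]
        # pi sums to 1 only within float tolerance; keep rows inside [0, 1]
        return np.clip(np.sum(probs, axis=0), 0.0, 1.0)

    def predict(self, feature_batches: Sequence[FeatureBatch]) -> np.ndarray:
        return self.predict_proba(feature_batches).argmax(axis=1)


def _epoch_losses(
    batches: Sequence[FeatureBatch],
    heads: Sequence[ClassifierWeights],
    labels: LabelBatch,
    sample_weights: np.ndarray | None,
) -> np.ndarray:
    return np.array(
        [
            cross_entropy(fb, h, labels, sample_weights, reduction="mean")
            for fb, h in zip(batches, heads)
        ]
    )


def fit(
    feature_batches: Sequence[FeatureBatch],
    labels: LabelBatch,
    config: TrainConfig | None = None,
    n_classes: int = 2,
    sample_weights: np.ndarray | None = None,
) -> FitResult:
    """Train the ensemble under the fused objective.

    ``feature_batches`` holds one FeatureBatch per sub-network over the same
    samples. Heads start at zero (the objective is convex in each head, so
    no symmetry needs breaking) and ``pi`` starts uniform. Per epoch: SGD
    minibatch passes over all heads with ``pi`` fixed, then one ``pi``
    update on the epoch-mean per-network losses, then one multiplier
    update. A final ``pi``/multiplier update on losses at the final weights
    makes the reported ``pi`` consistent with the reported heads.

    Fully deterministic for a fixed config (seeded shuffling only).
    """
    if config is None:
        config = TrainConfig()
    k = len(feature_batches)
    if k < 1:
        raise ValueError("need at least one sub-network")
    n = feature_batches[0].n
    if any(fb.n != n for fb in feature_batches):
        raise ValueError("all feature batches must cover the same samples")
    if labels.n != n:
        raise ValueError("labels and features disagree on n")

    rng = np.random.default_rng(config.seed)
    heads = [
        ClassifierWeights(np.zeros((fb.dim, n_classes)))
        for fb in feature_batches
    ]
    velocity = [np.zeros_like(h.weights) for h in heads]
    fusion = FusionWeights.uniform(k)
    lagrange = LagrangeState.initial(k, config.theta)

    pi_rows = [fusion.pi.copy()]
    loss_rows = [_epoch_losses(feature_batches, heads, labels, sample_weights)]
    fused_history: list[float] = []

    for epoch in range(config.epochs):
        lr = cosine_lr(
            min(epoch, config.t_max), config.lr, config.t_max, config.lr_min
        )
        order = rng.permutation(n)
        for start in range(0, n, config.batch_size):
            sel = order[start : start + config.batch_size]
            sub_labels = LabelBatch(labels.labels[sel])
            sub_sw = None if sample_weights is None else sample_weights[sel]
            for j in range(k):
                sub = FeatureBatch(
                    feature_batches[j].features[sel], network_index=j
                )
                g = grad_classifier(
                    sub, heads[j], sub_labels, float(fusion.pi[j]), sub_sw
                ) / len(sel)
                g = g + config.weight_decay * heads[j].weights
                velocity[j] = config.momentum * velocity[j] - lr * g
                heads[j] = ClassifierWeights(heads[j].weights + velocity[j])

        ell = _epoch_losses(feature_batches, heads, labels, sample_weights)
        fusion = update_pi(PerNetworkLossSummary(ell), lagrange)
        lagrange = update_multipliers(fusion, lagrange)
        loss_rows.append(ell)
        pi_rows.append(fusion.pi.copy())
        fused = float(fusion.pi @ ell)
        fused_history.append(fused)
        if not np.isfinite(fused):
            raise TrainingError(
                f"fused loss diverged at epoch {epoch}", fused_history
            )

    return FitResult(
        heads=heads,
        fusion=fusion,
        lagrange=lagrange,
        fused_loss_history=fused_history,
        per_network_loss_history=np.vstack(loss_rows),
        pi_history=np.vstack(pi_rows),
        config=config,
    )
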