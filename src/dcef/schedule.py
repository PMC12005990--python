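"""Cosine-annealed learning-rate schedule."""

from __future__ import annotations

import math


def cosine_lr(
    epoch: int, lr_max: float = 0.1, t_max: int = 100, lr_min: float = 0.0
) -> float:
    """Cosine annealing: ``lr_min + (lr_max - lr_min)(1 + cos(pi e/T))/2``.

    Starts at ``lr_max`` (epoch 0), ends at ``lr_min`` (epoch ``t_max``),
    and passes through the midpoint at ``t_max / 2``.
    """
    if t_max <= 0:
        raise ValueError("t_max must be positive")
    if not 0 <= epoch <= t_max:
        raise ValueError(f"epoch {epoch} outside [0, {t_max}]")
    return lr_min + (lr_max - lr_min) * (1 + math.cos(math.pi * epoch / t_max)) / 2
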