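"""Combined BCE–Dice training objective.

The training loss is the convex combination

    L = alpha * L_dice + beta * L_bce

with the soft Dice loss

    L_dice = 1 - 2 * sum(p_i g_i) / (sum(p_i^2) + sum(g_i^2) + eps)

and the pixel-mean binary cross-entropy

    L_bce = -mean( g_i log p_i + (1 - g_i) log(1 - p_i) )

where p_i are predicted foreground probabilities, g_i the binary reference
labels, and eps a small stabilizer against empty masks.  Probabilities are
clamped to [eps, 1 - eps] before the logarithms.  The defaults alpha = 0.7,
beta = 0.3 are the weights the network is trained with; the five sweep
configurations (1,0), (0,1), (0.3,0.7), (0.5,0.5), (0.7,0.3) are provided for
the loss-weight study helper.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor

EPS = 1e-6

#: (alpha, beta) rows of the loss-weight study.
SWEEP_CONFIGS = ((1.0, 0.0), (0.0, 1.0), (0.3, 0.7), (0.5, 0.5), (0.7, 0.3))


@dataclass(frozen=True)
class LossWeights:
    """Dice weight `alpha` and BCE weight `beta`; defaults 0.7 / 0.3."""

    alpha: float = 0.7
    beta: float = 0.3

    def __post_init__(self):
        if not (0.0 <= self.alpha <= 1.0 and 0.0 <= self.beta <= 1.0):
            raise ValueError(f"weights must lie in [0, 1], got {self}")


def _check_shapes(p, g) -> None:
    if tuple(np.shape(p.data if isinstance(p, Tensor) else p)) != tuple(
            np.shape(g.data if isinstance(g, Tensor) else g)):
        raise ValueError(
            f"prediction/mask shape mismatch: {np.shape(p.data if isinstance(p, Tensor) else p)}"
            f" vs {np.shape(g.data if isinstance(g, Tensor) else g)}")


def dice_loss(p, g, eps: float = EPS) -> Tensor:
    """Soft Dice loss; accepts Tensors (differentiable) or arrays."""
    p = ad.as_tensor(p)
    g = ad.as_tensor(g)
    _check_shapes(p, g)
    num = (p * g).sum()
    den = (p * p).sum() + (g * g).sum() + eps
    return 1.0 - (2.0 * num) / den


def bce_loss(p, g, eps: float = EPS) -> Tensor:
    """Mean binary cross-entropy with probability clamping."""
    p = ad.as_tensor(p)
    g = ad.as_tensor(g)
    _check_shapes(p, g)
    pc = ad.clip(p, eps, 1.0 - eps)
    ll = g * ad.log(pc) + (1.0 - g) * ad.log(1.0 - pc)
    return -ll.mean()


def combined_loss(p, g, weights: LossWeights = LossWeights(),
                  eps: float = EPS) -> Tensor:
    """alpha * dice + beta * bce."""
    return (weights.alpha * dice_loss(p, g, eps)
            + weights.beta * bce_loss(p, g, eps))
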