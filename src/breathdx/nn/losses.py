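"""Training losses: focal loss, binary cross-entropy, and their sum.

The combined objective is L = L_focal + L_BCE averaged over the batch, with
L_focal = -(1 - p_t)^gamma * log(p_t) (natural log) and p_t the predicted
probability of the true class.  The focal term down-weights easy cases so
borderline profiles dominate the gradient; gamma = 0 recovers plain
cross-entropy and makes the combined loss exactly 2x BCE.  Probabilities are
clamped to [eps, 1 - eps] with eps = 1e-7 before any logarithm.
"""

from __future__ import annotations

import numpy as np

from .autodiff import Tensor

__all__ = ["EPS", "focal_loss", "bce_loss", "combined_loss"]

EPS = 1e-7


def _lift(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _p_true(y: np.ndarray, p: Tensor) -> Tensor:
    p = p.clip(EPS, 1.0 - EPS)
    y = np.asarray(y, dtype=float)
    return p * y + (1.0 - p) * (1.0 - y)


def focal_loss(y, p, gamma: float = 2.0):
    """Per-example focal loss -(1 - p_t)^gamma log(p_t).

    ``y`` are hard labels in {0, 1}; ``p`` predicted probabilities (Tensor or
    array).  Returns a Tensor when ``p`` is a Tensor, else a numpy array.
    """
    if gamma < 0:
        raise ValueError("gamma must be >= 0")
    was_tensor = isinstance(p, Tensor)
    pt = _p_true(np.asarray(y, dtype=float), _lift(p))
    out = -(1.0 - pt).pow(float(gamma)) * pt.log()
    return out if was_tensor else out.data


def bce_loss(y, p):
    """Per-example binary cross-entropy -(y log p + (1-y) log(1-p))."""
    was_tensor = isinstance(p, Tensor)
    pt = _p_true(np.asarray(y, dtype=float), _lift(p))
    out = -pt.log()  # identical to the two-term form for hard labels
    return out if was_tensor else out.data


def combined_loss(y, p, gamma: float = 2.0):
    """Batch mean of focal + binary cross-entropy.

    With gamma = 0 the focal term equals the BCE term, so the loss is exactly
    twice the mean binary cross-entropy.
    """
    y = np.asarray(y, dtype=float)
    p_arr = p.data if isinstance(p, Tensor) else np.asarray(p, dtype=float)
    if y.shape != p_arr.shape:
        raise ValueError(f"label batch {y.shape} and prediction batch {p_arr.shape} differ")
    was_tensor = isinstance(p, Tensor)
    p = _lift(p)
    total = focal_loss(y, p, gamma) + bce_loss(y, p)
    out = total.mean()
    return out if was_tensor else float(out.data)
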