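"""Building blocks of the breath classifier: convolution + ReLU, channel
squeeze-and-excitation gating, residual attention, and capsule-style dynamic
routing by agreement.

Every block accepts/returns autodiff Tensors (numpy arrays are lifted), so
each is differentiable end to end and individually gradient-checkable.
"""

from __future__ import annotations

import numpy as np

from .autodiff import Tensor, conv1d, softmax

__all__ = [
    "conv_block",
    "squeeze",
    "excite",
    "apply_attention",
    "attention_mask",
    "squash",
    "dynamic_routing",
]


def _lift(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def conv_block(x, weights, bias, padding: str = "same") -> Tensor:
    """ReLU(w * x + b): 1-D cross-correlation followed by rectification."""
    return conv1d(_lift(x), _lift(weights), _lift(bias), padding=padding).relu()


def squeeze(x) -> Tensor:
    """Global average over spatial positions: z_c = (1/(H*W)) sum_ij X_c(i,j).

    For 1-D feature maps (B, C, L) the height collapses to 1, so this is the
    per-channel mean over positions.
    """
    x = _lift(x)
    if x.data.ndim < 2:
        raise ValueError("squeeze expects at least (channels, positions)")
    # (B, C, *spatial) -> mean over spatial axes; (C, L) -> mean over L
    if x.data.ndim == 2:
        return x.mean(axis=-1)
    return x.mean(axis=tuple(range(2, x.data.ndim)))


def excite(z, W1, W2, activation_order: str = "sigmoid_outer") -> Tensor:
    """Two-layer bottleneck producing per-channel gates from squeezed features.

    The default computes sigmoid(W2 . relu(W1 . z)) — bounded gates in (0, 1)
    as multiplicative channel attention requires.  ``'relu_outer'``
    computes relu(W2 . sigmoid(W1 . z)), the published symbol assignment with
    the activations in the opposite order.
    """
    z, W1, W2 = _lift(z), _lift(W1), _lift(W2)
    C = z.data.shape[-1]
    if W1.data.shape[1] != C or W2.data.shape[0] != C or W2.data.shape[1] != W1.data.shape[0]:
        raise ValueError(
            f"excite: expected W1 (C/r, C) and W2 (C, C/r) for C={C}; got "
            f"{W1.data.shape} and {W2.data.shape}"
        )
    W1t = W1.transpose((1, 0))
    W2t = W2.transpose((1, 0))
    if activation_order == "sigmoid_outer":
        return ((z @ W1t).relu() @ W2t).sigmoid()
    if activation_order == "relu_outer":
        return ((z @ W1t).sigmoid() @ W2t).relu()
    raise ValueError(f"unknown activation_order {activation_order!r}")


def attention_mask(e, W_down, b_down, W_up, b_up) -> Tensor:
    """Mask branch M(E): per-position bottleneck (1x1 convs) with sigmoid output."""
    h = conv1d(_lift(e), _lift(W_down), _lift(b_down), padding="same").relu()
    return conv1d(h, _lift(W_up), _lift(b_up), padding="same").sigmoid()


def apply_attention(e, mask, variant: str = "mask_product") -> Tensor:
    """Modulate the feature branch by the attention mask.

    ``mask_product`` is the literal RA = M(E) . E; ``residual_mask`` is the
    (1 + M(E)) . E form common in residual-attention networks.
    """
    e, mask = _lift(e), _lift(mask)
    if e.data.shape != mask.data.shape:
        raise ValueError(
            f"attention mask shape {mask.data.shape} must match features {e.data.shape}"
        )
    if variant == "mask_product":
        return mask * e
    if variant == "residual_mask":
        return (1.0 + mask) * e
    raise ValueError(f"unknown attention variant {variant!r}")


def squash(s, axis: int = -1, eps: float = 1e-12) -> Tensor:
    """Capsule squash: (||s||^2 / (1 + ||s||^2)) * s / ||s||.

    Maps the zero vector to itself and bounds every output norm below 1.
    """
    s = _lift(s)
    n2 = (s * s).sum(axis=axis, keepdims=True)
    scale = n2 / (1.0 + n2)
    return s * scale * (n2 + eps).pow(-0.5)


def dynamic_routing(prediction_vectors, iterations: int = 3, return_couplings: bool = False):
    """Routing by agreement over prediction vectors u_hat (B, N_in, N_out, D).

    Logits start at zero; each round computes coupling coefficients by a
    softmax over output capsules, forms weighted sums, squashes them, and
    reinforces logits by the scalar agreement u_hat . v.  Returns the output
    capsules (B, N_out, D) after ``iterations`` rounds.
    """
    u_hat = _lift(prediction_vectors)
    if not np.all(np.isfinite(u_hat.data)):
        raise ValueError("dynamic_routing: non-finite prediction vectors")
    if iterations < 1:
        raise ValueError("routing needs at least one iteration")
    if u_hat.data.ndim != 4:
        raise ValueError("prediction vectors must have shape (B, N_in, N_out, D)")
    B, n_in, n_out, dim = u_hat.data.shape
    logits = Tensor(np.zeros((B, n_in, n_out, 1)))
    v = None
    couplings = None
    for it in range(iterations):
        couplings = softmax(logits, axis=2)
        s = (couplings * u_hat).sum(axis=1)  # (B, N_out, D)
        v = squash(s)
        if it < iterations - 1:
            v_b = v.reshape(B, 1, n_out, dim)
            agreement = (u_hat * v_b).sum(axis=-1, keepdims=True)
            logits = logits + agreement
    if return_couplings:
        return v, couplings
    return v
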