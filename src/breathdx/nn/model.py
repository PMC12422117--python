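"""The breath-signal classifier: convolution -> squeeze-and-excitation ->
residual attention -> dynamic routing -> regularized dense head -> sigmoid.

The network reads a 1-D input (a PCA-weighted feature vector or a raw
waveform) as a single-channel signal.  Convolutional blocks extract local
patterns; squeeze-and-excitation recalibrates channels; a residual-attention
mask highlights informative positions; positions are then treated as input
capsules whose prediction vectors are combined by routing-by-agreement; and
a stochastic-depth-wrapped dense layer, spatial dropout (train mode only),
global average pooling and a sigmoid head produce the asthmatic-probability
output.  Eval-mode inference is a pure function of (weights, input):
dropout is off and stochastic-depth layers run scaled by their survival
probability.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Literal

import numpy as np
from pydantic import BaseModel, ConfigDict, Field, model_validator

from .autodiff import Tensor, conv1d
from .blocks import apply_attention, attention_mask, conv_block, dynamic_routing, excite, squeeze

__all__ = ["ModelConfig", "Prediction", "ADENA"]


class ModelConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    conv_layers: list[tuple[int, int, int]] = [(16, 5, 1), (32, 5, 1)]  # (filters, kernel, stride)
    se_reduction: int = Field(default=4, ge=1)
    attention_variant: Literal["mask_product", "residual_mask"] = "mask_product"
    capsule_count: int = Field(default=8, ge=1)
    capsule_dim: int = Field(default=8, ge=1)
    routing_iterations: int = Field(default=3, ge=1)
    stochastic_depth_survival: float = Field(default=0.8, ge=0.0, le=1.0)
    spatial_dropout_rate: float = Field(default=0.2, ge=0.0, le=1.0)
    gamma: float = Field(default=2.0, ge=0.0)  # focal-loss focusing parameter
    head_hidden_units: list[int] = [32]
    activation_order: Literal["sigmoid_outer", "relu_outer"] = "sigmoid_outer"

    @model_validator(mode="after")
    def _strides(self) -> "ModelConfig":
        if any(stride != 1 for _f, _k, stride in self.conv_layers):
            raise ValueError("only stride-1 convolutions are supported")
        if not self.conv_layers:
            raise ValueError("at least one convolutional layer is required")
        return self


@dataclass(frozen=True)
class Prediction:
    probability: float
    logit: float

    def __post_init__(self) -> None:
        expected = 1.0 / (1.0 + np.exp(-self.logit))
        if abs(self.probability - expected) > 1e-9:
            raise ValueError("probability must equal sigmoid(logit)")


class ADENA:
    """Asthma classifier over 1-D breath inputs.  See module docstring."""

    def __init__(self, config: ModelConfig | None = None, n_input_channels: int = 1, seed: int = 0):
        self.config = config or ModelConfig()
        self.n_input_channels = n_input_channels
        self.params: dict[str, Tensor] = {}
        self._init_params(seed)

    # -- parameters --------------------------------------------------------
    def _add(self, name: str, array: np.ndarray) -> None:
        self.params[name] = Tensor(array, requires_grad=True, name=name)

    def _init_params(self, seed: int) -> None:
        rng = np.random.default_rng(seed)
        cfg = self.config

        def he(*shape):
            fan_in = int(np.prod(shape[1:])) or 1
            return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape)

        c_in = self.n_input_channels
        for i, (filters, kernel, _stride) in enumerate(cfg.conv_layers):
            self._add(f"conv{i}_w", he(filters, c_in, kernel))
            self._add(f"conv{i}_b", np.zeros(filters))
            c_in = filters
        c = c_in
        r = max(c // cfg.se_reduction, 1)
        self._add("se_w1", he(r, c))
        self._add("se_w2", he(c, r))
        self._add("attn_down_w", he(r, c, 1))
        self._add("attn_down_b", np.zeros(r))
        self._add("attn_up_w", he(c, r, 1))
        self._add("attn_up_b", np.zeros(c))
        self._add("caps_w", he(cfg.capsule_count * cfg.capsule_dim, c))
        self._add("sd_w", he(cfg.capsule_count, cfg.capsule_count, 1))
        self._add("sd_b", np.zeros(cfg.capsule_count))
        prev = cfg.capsule_count
        for j, units in enumerate(cfg.head_hidden_units):
            self._add(f"head{j}_w", he(units, prev))
            self._add(f"head{j}_b", np.zeros(units))
            prev = units
        self._add("final_w", he(1, prev))
        self._add("final_b", np.zeros(1))

    def parameters(self) -> list[Tensor]:
        return list(self.params.values())

    # -- forward -----------------------------------------------------------
    @staticmethod
    def _as_batch(x) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        if x.ndim == 1:
            x = x[None, None, :]
        elif x.ndim == 2:
            x = x[:, None, :]
        elif x.ndim != 3:
            raise ValueError("input must be (F,), (B, F) or (B, C, L)")
        return x

    def forward(self, x, mode: str = "eval", rng: np.random.Generator | None = None):
        """Run the network; returns (probabilities, logits) as Tensors of shape (B,).

        ``mode='train'`` activates stochastic depth and spatial dropout (an
        ``rng`` is then required); ``mode='eval'`` is deterministic.
        """
        if mode not in ("train", "eval"):
            raise ValueError(f"mode must be 'train' or 'eval', got {mode!r}")
        if mode == "train" and rng is None:
            raise ValueError("train-mode forward requires an rng for its stochastic layers")
        cfg = self.config
        p = self.params
        xb = self._as_batch(x)
        if xb.shape[1] != self.n_input_channels:
            raise ValueError(
                f"layer input: expected {self.n_input_channels} channel(s), got {xb.shape[1]}"
            )
        B = xb.shape[0]
        h = Tensor(xb)
        stage = "conv"
        try:
            for i in range(len(cfg.conv_layers)):
                h = conv_block(h, p[f"conv{i}_w"], p[f"conv{i}_b"])
            stage = "squeeze_excite"
            gates = excite(squeeze(h), p["se_w1"], p["se_w2"], cfg.activation_order)
            C = h.data.shape[1]
            h = h * gates.reshape(B, C, 1)
            stage = "residual_attention"
            mask = attention_mask(
                h, p["attn_down_w"], p["attn_down_b"], p["attn_up_w"], p["attn_up_b"]
            )
            h = apply_attention(h, mask, cfg.attention_variant)
            stage = "dynamic_routing"
            L = h.data.shape[2]
            u = h.transpose((0, 2, 1)).reshape(B * L, C)  # positions as input capsules
            u_hat = (u @ p["caps_w"].transpose((1, 0))).reshape(
                B, L, cfg.capsule_count, cfg.capsule_dim
            )
            v = dynamic_routing(u_hat, iterations=cfg.routing_iterations)  # (B, N, D)
            stage = "stochastic_depth_dense"
            f = conv1d(v, p["sd_w"], p["sd_b"], padding="same").relu()
            if mode == "train":
                gate = float(rng.random() < cfg.stochastic_depth_survival)
            else:
                gate = cfg.stochastic_depth_survival
            v = v + f * gate
            stage = "spatial_dropout"
            if mode == "train" and cfg.spatial_dropout_rate > 0:
                keep = 1.0 - cfg.spatial_dropout_rate
                mask_drop = (
                    rng.random((B, cfg.capsule_count, 1)) < keep
                ).astype(float) / max(keep, 1e-12)
                v = v * Tensor(mask_drop)
            stage = "pooling_head"
            pooled = v.mean(axis=2)  # spatial average pooling -> (B, N)
            for j in range(len(cfg.head_hidden_units)):
                pooled = (
                    pooled @ p[f"head{j}_w"].transpose((1, 0)) + p[f"head{j}_b"]
                ).relu()
            logits = (pooled @ p["final_w"].transpose((1, 0)) + p["final_b"]).reshape(B)
            probs = logits.sigmoid()
        except ValueError as err:
            raise ValueError(f"[{stage}] {err}") from err
        return probs, logits

    def predict_proba(self, x) -> np.ndarray:
        """Deterministic eval-mode probabilities as a numpy array."""
        probs, _ = self.forward(x, mode="eval")
        return probs.data

    def predict_one(self, x) -> Prediction:
        probs, logits = self.forward(np.atleast_2d(np.asarray(x, dtype=float)), mode="eval")
        return Prediction(probability=float(probs.data[0]), logit=float(logits.data[0]))

    # -- serialization -----------------------------------------------------
    def save(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "model_config.json").write_text(self.config.model_dump_json(indent=1))
        np.savez(out / "weights.npz", **{k: v.data for k, v in self.params.items()})

    @classmethod
    def load(cls, in_dir: str | Path, n_input_channels: int = 1) -> "ADENA":
        src = Path(in_dir)
        config = ModelConfig.model_validate_json((src / "model_config.json").read_text())
        model = cls(config, n_input_channels=n_input_channels)
        with np.load(src / "weights.npz") as blob:
            for key in model.params:
                model.params[key].data = blob[key].astype(float)
        return model
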