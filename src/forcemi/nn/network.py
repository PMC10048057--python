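"""The force-MI decoding network: multi-scale temporal convolution,
spatial convolution with pooling, channel attention, softmax classifier.

Architecture for an input trial of N electrodes x M time points:

====================  =========================  ==================
stage                 operation                  output shape
====================  =========================  ==================
input                 reshape                    (1, N, M)
multi-scale temporal  conv (1,S)+BN per branch,  (8B, N, M)
                      S in {3, 5, 7}, concat     (24, N, M) default
spatial               conv (N,1) -> BN -> ELU    (48, 1, M)
                      avg-pool (1,64) -> drop    (48, 1, M/64)
attention             channel recalibration      (48, 1, M/64)
classifier            flatten -> dense           (3,) softmax
====================  =========================  ==================

Temporal kernels use symmetric 'same' padding (odd widths keep M exact);
temporal and spatial convolutions have linear activations (the only
nonlinearities are the ELU after the spatial stage, the attention
sigmoid, and the softmax head).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .layers import (AvgPoolWidth, BatchNorm, ChannelAttention, Concat, Dense,
                     Dropout, ELU, Flatten, Sequential, SpatialConv,
                     TemporalConv)

EPS_PROB = 1e-12


@dataclass(frozen=True)
class ModelConfig:
    """Architecture hyperparameters of the force-MI network."""

    n_electrodes: int
    n_timepoints: int
    branch_kernel_widths: tuple[int, ...] = (3, 5, 7)
    branch_filters: int = 8
    spatial_filters: int = 48
    pool_width: int = 64
    dropout_p: float = 0.5
    attention_reduction: int = 8
    n_classes: int = 3

    def __post_init__(self) -> None:
        if self.n_electrodes < 1 or self.n_timepoints < 1:
            raise ValueError("n_electrodes and n_timepoints must be positive")
        if len(self.branch_kernel_widths) < 1:
            raise ValueError("need at least one temporal branch")
        if any(s % 2 == 0 or s < 1 for s in self.branch_kernel_widths):
            raise ValueError("branch kernel widths must be odd and positive")
        if self.n_timepoints % self.pool_width:
            raise ValueError(
                f"n_timepoints={self.n_timepoints} must be divisible by "
                f"pool_width={self.pool_width}")
        if self.spatial_filters % self.attention_reduction:
            raise ValueError(
                f"spatial_filters={self.spatial_filters} must be divisible by "
                f"attention_reduction={self.attention_reduction}; pick a "
                "reduction ratio dividing the channel count")
        if not 0 <= self.dropout_p < 1:
            raise ValueError("dropout_p must lie in [0, 1)")

    @property
    def concat_channels(self) -> int:
        return self.branch_filters * len(self.branch_kernel_widths)

    @property
    def pooled_width(self) -> int:
        return self.n_timepoints // self.pool_width

    @property
    def n_features(self) -> int:
        """Flattened feature count feeding the classifier head."""
        return self.spatial_filters * self.pooled_width


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def cross_entropy(probs: np.ndarray, labels: np.ndarray) -> float:
    """Mean cross-entropy of class probabilities against integer labels.

    For one-hot targets this is the mean of -log(P_true); probabilities
    of exactly zero for the true class are clamped at 1e-12 with a
    warning rather than producing an infinite loss.
    """
    probs = np.asarray(probs, dtype=float)
    labels = np.asarray(labels, dtype=int)
    p_true = probs[np.arange(len(labels)), labels]
    if np.any(p_true <= 0):
        warnings.warn("zero probability for a true class; clamping at 1e-12",
                      stacklevel=2)
        p_true = np.maximum(p_true, EPS_PROB)
    return float(-np.mean(np.log(p_true)))


class MSTCNAMNetwork:
    """Forward/backward network instance for a fixed :class:`ModelConfig`."""

    def __init__(self, cfg: ModelConfig, rng: np.random.Generator | None = None,
                 dtype=np.float32) -> None:
        self.cfg = cfg
        self.rng = rng if rng is not None else np.random.default_rng()
        self.dtype = dtype
        branches = [
            Sequential(TemporalConv(cfg.branch_filters, s, self.rng, dtype),
                       BatchNorm(cfg.branch_filters, dtype=dtype))
            for s in cfg.branch_kernel_widths
        ]
        self.mstcn = Concat(*branches)
        self.spatial = Sequential(
            SpatialConv(cfg.concat_channels, cfg.spatial_filters,
                        cfg.n_electrodes, self.rng, dtype),
            BatchNorm(cfg.spatial_filters, dtype=dtype),
            ELU(),
            AvgPoolWidth(cfg.pool_width),
            Dropout(cfg.dropout_p, self.rng),
        )
        self.attention = ChannelAttention(cfg.spatial_filters,
                                          cfg.attention_reduction,
                                          self.rng, dtype)
        self.head = Sequential(Flatten(),
                               Dense(cfg.n_features, cfg.n_classes,
                                     self.rng, dtype))
        self._stages = Sequential(self.mstcn, self.spatial, self.attention,
                                  self.head)

    # -- forward -----------------------------------------------------------

    def _as_input(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=self.dtype)
        if x.ndim == 2:
            x = x[None]
        if x.ndim == 3:
            x = x[:, None]  # reshape (B, N, M) -> (B, 1, N, M)
        cfg = self.cfg
        if x.shape[1:] != (1, cfg.n_electrodes, cfg.n_timepoints):
            raise ValueError(
                f"input shape {x.shape[1:]} does not match config "
                f"(1, {cfg.n_electrodes}, {cfg.n_timepoints})")
        return x

    def logits(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        return self._stages.forward(self._as_input(x), train)

    def predict_proba(self, x: np.ndarray, train: bool = False,
                      validate: bool = True) -> np.ndarray:
        """Class probabilities, shape (B, n_classes); rows sum to 1."""
        xi = self._as_input(x)
        if validate:
            if not np.all(np.isfinite(xi)):
                raise ValueError("input contains non-finite values")
            sd = xi.reshape(xi.shape[0], -1).std(axis=1)
            if np.any(sd < 1e-3) or np.any(sd > 1e3):
                raise ValueError(
                    "input does not look z-normalized (per-trial std far "
                    "from 1); normalize trials first")
        return softmax(self.logits(xi, train))

    def forward_intermediates(self, x: np.ndarray) -> dict[str, np.ndarray]:
        """Eval-mode forward returning each stage output (for inspection)."""
        xi = self._as_input(x)
        xc = self.mstcn.forward(xi, train=False)
        xs = self.spatial.forward(xc, train=False)
        xf = self.attention.forward(xs, train=False)
        probs = softmax(self.head.forward(xf, train=False))
        return {"input": xi, "concat": xc, "spatial": xs,
                "attended": xf, "probs": probs}

    # -- training step -----------------------------------------------------

    def train_step(self, x: np.ndarray, y: np.ndarray) -> float:
        """Forward + backward on one batch; returns the batch loss.

        Gradients are left in the layers for the optimizer to consume.
        """
        logits = self.logits(x, train=True)
        probs = softmax(logits)
        B = len(y)
        onehot = np.zeros_like(probs)
        onehot[np.arange(B), np.asarray(y, dtype=int)] = 1.0
        self._stages.backward((probs - onehot) / B)
        return cross_entropy(probs, y)

    def parameters(self):
        yield from self._stages.parameters()

    def n_parameters(self) -> int:
        return sum(layer.params[name].size for layer, name in self.parameters())

    def get_weights(self) -> list[np.ndarray]:
        return [layer.params[name].copy() for layer, name in self.parameters()]

    def set_weights(self, weights) -> None:
        for (layer, name), w in zip(self.parameters(), weights, strict=True):
            layer.params[name] = np.asarray(w, dtype=layer.params[name].dtype)


def count_parameters(cfg: ModelConfig) -> int:
    """Trainable parameter count of the architecture, computed analytically.

    Per temporal branch of width S: 8S conv weights + 8 biases + 2*8 BN;
    spatial stage: 48*(24*N) weights + 48 biases + 2*48 BN; attention:
    2*C^2/r shared-MLP weights; head: 3*(48*M/64) weights + 3 biases.
    """
    total = 0
    for s in cfg.branch_kernel_widths:
        total += cfg.branch_filters * s + cfg.branch_filters      # conv
        total += 2 * cfg.branch_filters                           # BN
    total += cfg.spatial_filters * cfg.concat_channels * cfg.n_electrodes
    total += cfg.spatial_filters                                  # bias
    total += 2 * cfg.spatial_filters                              # BN
    hidden = cfg.spatial_filters // cfg.attention_reduction
    total += 2 * hidden * cfg.spatial_filters                     # W0, W1
    total += cfg.n_classes * cfg.n_features + cfg.n_classes       # head
    return total
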