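"""Tied-weight denoising autoencoders for [0,1]-scaled omics matrices.

Two architectures are provided:

* **one-input** — a single sigmoid encode layer of 100 units whose weight
  matrix ``W`` (genes x 100) is reused, transposed, by the decode layer::

      encode = sigmoid(W' x + b)
      decode = sigmoid(W encode + b_dec)

* **two-input** — one 1000-unit sigmoid encode per source, concatenation to
  2000 units, a second 100-unit encode, then a tied decode path that runs
  the second encode backwards (100 -> 2000), splits the result, and runs
  each source's first encode backwards (1000 -> genes).

Training is plain mini-batch SGD on the binary cross-entropy between the
*clean* input and the reconstruction of a *corrupted* copy (the denoising
objective): a fixed fraction of each patient's gene values is zeroed at
random each epoch.  Inverted dropout is applied after the feature layer
during training only.  Forward and backward passes are explicit NumPy;
gradients are exact (they pass a central finite-difference check), and the
tied weight matrices accumulate gradient from both their encode and decode
uses.

The feature layer's sigmoid outputs on the clean inputs, in inference mode,
are the "activity values" used by the downstream association and survival
analyses.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .preprocess import ScaledMatrix

__all__ = [
    "TrainConfig",
    "OneInputDA",
    "TwoInputDA",
    "FeatureSet",
    "sigmoid",
    "corrupt",
    "bce_loss",
    "train_one_input",
    "train_two_input",
]

log = logging.getLogger(__name__)

_EPS = 1e-12


@dataclass(frozen=True)
class TrainConfig:
    """Training hyper-parameters.

    Defaults: 25% of gene values zeroed per patient per epoch, SGD with
    learning rate 0.1, batch size 64, 100 epochs, 50% inverted dropout after
    the feature layer.
    """

    noise_factor: float = 0.25
    learning_rate: float = 0.1
    batch_size: int = 64
    epochs: int = 100
    dropout_rate: float = 0.5
    seed: int = 0
    fixed_mask: bool = False          # corrupt once before training instead of per epoch
    corrupt_rows: bool = False        # zero whole gene rows instead of per-patient cells

    def validate(self) -> None:
        if not 0.0 <= self.noise_factor < 1.0:
            raise ValueError("noise_factor must lie in [0, 1)")
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ValueError("dropout_rate must lie in [0, 1)")
        if self.learning_rate <= 0 or self.batch_size <= 0 or self.epochs < 0:
            raise ValueError("invalid learning_rate / batch_size / epochs")


@dataclass
class FeatureSet:
    """Patient x feature activity values from a trained model."""

    activity: pd.DataFrame            # patients x n_features, entries in (0,1)
    source_tag: str                   # expression | cna | concatenated
    model: object = None              # the model that produced the activities

    @property
    def feature_ids(self) -> pd.Index:
        return self.activity.columns

    @property
    def patient_ids(self) -> pd.Index:
        return self.activity.index


def _feature_names(n: int) -> list[str]:
    return [f"F{i + 1:03d}" for i in range(n)]


def sigmoid(x: np.ndarray | float) -> np.ndarray | float:
    """Numerically stable logistic function 1 / (1 + exp(-x))."""
    out = np.empty_like(x, dtype=float) if isinstance(x, np.ndarray) else None
    x = np.asarray(x, dtype=float)
    pos = x >= 0
    if out is None:
        out = np.empty_like(x)
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    # keep the open interval: saturated values round to the nearest
    # representable neighbour of 0/1 instead of the exact endpoints
    np.clip(out, np.nextafter(0.0, 1.0), np.nextafter(1.0, 0.0), out=out)
    if out.ndim == 0:
        return float(out)
    return out


def corrupt(
    values: np.ndarray,
    noise_factor: float,
    rng: np.random.Generator | int,
    rows: bool = False,
) -> tuple[np.ndarray, np.ndarray]:
    """Masking corruption of a genes x patients matrix.

    For each patient column independently, exactly ``round(noise_factor *
    n_genes)`` gene positions are drawn without replacement and set to zero.
    With ``rows=True`` whole gene rows are zeroed instead (one draw shared by
    all patients).  Returns the corrupted copy and a boolean mask of zeroed
    positions.
    """
    if not 0.0 <= noise_factor < 1.0:
        raise ValueError("noise_factor must lie in [0, 1)")
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(int(rng))
    g, p = values.shape
    k = int(round(noise_factor * g))
    mask = np.zeros((g, p), dtype=bool)
    if k:
        if rows:
            idx = rng.choice(g, size=k, replace=False)
            mask[idx, :] = True
        else:
            for j in range(p):
                idx = rng.choice(g, size=k, replace=False)
                mask[idx, j] = True
    corrupted = values.copy()
    corrupted[mask] = 0.0
    return corrupted, mask


def bce_loss(target: np.ndarray, output: np.ndarray) -> float:
    """Mean binary cross-entropy over all entries.

    Outputs at exactly 0 or 1 are clamped by a small epsilon (and the event
    logged) so the loss stays finite.
    """
    target = np.asarray(target, dtype=float)
    output = np.asarray(output, dtype=float)
    if target.shape != output.shape:
        raise ValueError(f"shape mismatch {target.shape} vs {output.shape}")
    if ((output <= 0) | (output >= 1)).any():
        log.warning("bce_loss: output values at 0/1 clamped by epsilon")
        output = np.clip(output, _EPS, 1.0 - _EPS)
    return float(-np.mean(target * np.log(output) + (1 - target) * np.log(1 - output)))


def _glorot(rng: np.random.Generator, fan_in: int, fan_out: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=(fan_in, fan_out))


def _dropout_mask(
    rng: np.random.Generator, shape: tuple[int, ...], rate: float
) -> np.ndarray:
    """Inverted-dropout multiplier: 0 with probability `rate`, else 1/(1-rate)."""
    if rate == 0.0:
        return np.ones(shape)
    return (rng.random(shape) >= rate) / (1.0 - rate)


class OneInputDA:
    """Single-source DA: genes -> n_features sigmoid encode, tied decode.

    Parameters are ``W`` (genes x n_features), encode bias ``b`` and decode
    bias ``b_dec``; the decode weight is always the current transpose of
    ``W`` (no separate decode matrix exists).
    """

    def __init__(self, input_dim: int, n_features: int = 100, seed: int = 0):
        rng = np.random.default_rng(seed)
        self.input_dim = input_dim
        self.n_features = n_features
        self.W = _glorot(rng, input_dim, n_features)
        self.b = np.zeros(n_features)
        self.b_dec = np.zeros(input_dim)

    def n_params(self) -> int:
        return self.W.size + self.b.size + self.b_dec.size

    def forward(
        self,
        x: np.ndarray,
        train_mode: bool = False,
        dropout_rate: float = 0.5,
        dropout_rng: np.random.Generator | int | None = None,
    ) -> tuple[np.ndarray, np.ndarray]:
        """Encode + reconstruct a batch (patients x genes) or single vector.

        In inference mode dropout is the identity and the pass is
        deterministic.
        """
        x = np.atleast_2d(np.asarray(x, dtype=float))
        if x.shape[1] != self.input_dim:
            raise ValueError(f"expected {self.input_dim} genes, got {x.shape[1]}")
        h = sigmoid(x @ self.W + self.b)
        if train_mode:
            if isinstance(dropout_rng, (int, np.integer)) or dropout_rng is None:
                dropout_rng = np.random.default_rng(dropout_rng)
            m = _dropout_mask(dropout_rng, h.shape, dropout_rate)
            hd = h * m
        else:
            hd = h
        recon = sigmoid(hd @ self.W.T + self.b_dec)
        return h, recon

    def loss_and_grads(
        self,
        x_clean: np.ndarray,
        x_noisy: np.ndarray,
        dropout_mult: np.ndarray | None = None,
    ) -> tuple[float, dict[str, np.ndarray]]:
        """Batch mean BCE and its exact gradients w.r.t. W, b, b_dec.

        ``dropout_mult`` is the (inverted-dropout) multiplier applied to the
        encode layer; ``None`` means no dropout.  The tied matrix ``W``
        accumulates gradient from both its encode and decode uses.
        """
        B, G = x_clean.shape
        h = sigmoid(x_noisy @ self.W + self.b)
        m = np.ones_like(h) if dropout_mult is None else dropout_mult
        hd = h * m
        out = sigmoid(hd @ self.W.T + self.b_dec)
        loss = bce_loss(x_clean, out)

        # d(mean BCE)/d(pre-sigmoid output) = (out - target) / n_entries
        d_zout = (np.clip(out, _EPS, 1 - _EPS) - x_clean) / (B * G)
        g_bdec = d_zout.sum(axis=0)
        g_W = d_zout.T @ hd                       # decode use of W
        d_h = (d_zout @ self.W) * m
        d_zh = d_h * h * (1 - h)
        g_b = d_zh.sum(axis=0)
        g_W += x_noisy.T @ d_zh                   # encode use of W (tied)
        return loss, {"W": g_W, "b": g_b, "b_dec": g_bdec}

    def _step(
        self,
        x_clean: np.ndarray,
        x_noisy: np.ndarray,
        lr: float,
        dropout_rate: float,
        rng: np.random.Generator,
    ) -> float:
        """One SGD step on a batch; returns the batch mean BCE."""
        m = _dropout_mask(rng, (x_clean.shape[0], self.n_features), dropout_rate)
        loss, g = self.loss_and_grads(x_clean, x_noisy, m)
        self.W -= lr * g["W"]
        self.b -= lr * g["b"]
        self.b_dec -= lr * g["b_dec"]
        return loss


class TwoInputDA:
    """Two-source concatenated DA with tied decode path.

    Encode: each source through its own ``W1`` (genes x hidden1) sigmoid
    layer, concatenate, then ``W2`` (2*hidden1 x hidden2) sigmoid layer whose
    outputs are the concatenated deep features.  Decode: transpose of ``W2``
    back to the concatenation width, split in half, transpose of each
    source's ``W1`` back to gene space.  Each weight matrix accumulates
    gradient from both its uses.
    """

    def __init__(
        self,
        input_dim_a: int,
        input_dim_b: int,
        hidden1: int = 1000,
        hidden2: int = 100,
        seed: int = 0,
    ):
        rng = np.random.default_rng(seed)
        self.input_dim_a = input_dim_a
        self.input_dim_b = input_dim_b
        self.hidden1 = hidden1
        self.hidden2 = hidden2
        self.W1_a = _glorot(rng, input_dim_a, hidden1)
        self.W1_b = _glorot(rng, input_dim_b, hidden1)
        self.b1_a = np.zeros(hidden1)
        self.b1_b = np.zeros(hidden1)
        self.W2 = _glorot(rng, 2 * hidden1, hidden2)
        self.b2 = np.zeros(hidden2)
        self.b_dec_mid = np.zeros(2 * hidden1)
        self.b_dec_a = np.zeros(input_dim_a)
        self.b_dec_b = np.zeros(input_dim_b)

    @property
    def n_features(self) -> int:
        return self.hidden2

    def forward(
        self,
        x_a: np.ndarray,
        x_b: np.ndarray,
        train_mode: bool = False,
        dropout_rate: float = 0.5,
        dropout_rng: np.random.Generator | int | None = None,
    ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Return (features, reconstruction_a, reconstruction_b)."""
        x_a = np.atleast_2d(np.asarray(x_a, dtype=float))
        x_b = np.atleast_2d(np.asarray(x_b, dtype=float))
        if x_a.shape[0] != x_b.shape[0]:
            raise ValueError("sources must cover the same patients")
        if x_a.shape[1] != self.input_dim_a or x_b.shape[1] != self.input_dim_b:
            raise ValueError("gene dimension mismatch")
        h_a = sigmoid(x_a @ self.W1_a + self.b1_a)
        h_b = sigmoid(x_b @ self.W1_b + self.b1_b)
        cc = np.concatenate([h_a, h_b], axis=1)
        e2 = sigmoid(cc @ self.W2 + self.b2)
        if train_mode:
            if isinstance(dropout_rng, (int, np.integer)) or dropout_rng is None:
                dropout_rng = np.random.default_rng(dropout_rng)
            e2d = e2 * _dropout_mask(dropout_rng, e2.shape, dropout_rate)
        else:
            e2d = e2
        mid = sigmoid(e2d @ self.W2.T + self.b_dec_mid)
        mid_a, mid_b = mid[:, : self.hidden1], mid[:, self.hidden1:]
        recon_a = sigmoid(mid_a @ self.W1_a.T + self.b_dec_a)
        recon_b = sigmoid(mid_b @ self.W1_b.T + self.b_dec_b)
        return e2, recon_a, recon_b

    def _step(
        self,
        xa_clean: np.ndarray,
        xb_clean: np.ndarray,
        xa_noisy: np.ndarray,
        xb_noisy: np.ndarray,
        lr: float,
        dropout_rate: float,
        rng: np.random.Generator,
    ) -> float:
        """One SGD step; loss is the sum of the two reconstruction BCEs."""
        B = xa_clean.shape[0]
        Ga, Gb, H1 = self.input_dim_a, self.input_dim_b, self.hidden1

        h_a = sigmoid(xa_noisy @ self.W1_a + self.b1_a)
        h_b = sigmoid(xb_noisy @ self.W1_b + self.b1_b)
        cc = np.concatenate([h_a, h_b], axis=1)
        e2 = sigmoid(cc @ self.W2 + self.b2)
        m = _dropout_mask(rng, e2.shape, dropout_rate)
        e2d = e2 * m
        mid = sigmoid(e2d @ self.W2.T + self.b_dec_mid)
        mid_a, mid_b = mid[:, :H1], mid[:, H1:]
        out_a = sigmoid(mid_a @ self.W1_a.T + self.b_dec_a)
        out_b = sigmoid(mid_b @ self.W1_b.T + self.b_dec_b)
        loss = bce_loss(xa_clean, out_a) + bce_loss(xb_clean, out_b)

        d_zoa = (np.clip(out_a, _EPS, 1 - _EPS) - xa_clean) / (B * Ga)
        d_zob = (np.clip(out_b, _EPS, 1 - _EPS) - xb_clean) / (B * Gb)
        g_bdec_a = d_zoa.sum(axis=0)
        g_bdec_b = d_zob.sum(axis=0)
        g_W1a = d_zoa.T @ mid_a                    # decode use
        g_W1b = d_zob.T @ mid_b
        d_mid = np.concatenate([d_zoa @ self.W1_a, d_zob @ self.W1_b], axis=1)
        d_zmid = d_mid * mid * (1 - mid)
        g_bmid = d_zmid.sum(axis=0)
        g_W2 = d_zmid.T @ e2d                      # decode use of W2
        d_e2 = (d_zmid @ self.W2) * m
        d_ze2 = d_e2 * e2 * (1 - e2)
        g_b2 = d_ze2.sum(axis=0)
        g_W2 += cc.T @ d_ze2                       # encode use of W2
        d_cc = d_ze2 @ self.W2.T
        d_zha = d_cc[:, :H1] * h_a * (1 - h_a)
        d_zhb = d_cc[:, H1:] * h_b * (1 - h_b)
        g_b1a = d_zha.sum(axis=0)
        g_b1b = d_zhb.sum(axis=0)
        g_W1a += xa_noisy.T @ d_zha                # encode use (tied)
        g_W1b += xb_noisy.T @ d_zhb

        self.W1_a -= lr * g_W1a
        self.W1_b -= lr * g_W1b
        self.b1_a -= lr * g_b1a
        self.b1_b -= lr * g_b1b
        self.W2 -= lr * g_W2
        self.b2 -= lr * g_b2
        self.b_dec_mid -= lr * g_bmid
        self.b_dec_a -= lr * g_bdec_a
        self.b_dec_b -= lr * g_bdec_b
        return loss


def _epoch_batches(
    n: int, batch_size: int, rng: np.random.Generator
) -> list[np.ndarray]:
    order = rng.permutation(n)
    if batch_size >= n:
        return [order]
    return [order[i : i + batch_size] for i in range(0, n, batch_size)]


def _train(
    model,
    clean_list: list[np.ndarray],      # patients x genes, one per source
    config: TrainConfig,
) -> list[float]:
    """Shared SGD loop; returns the per-epoch batch-weighted mean loss."""
    config.validate()
    n = clean_list[0].shape[0]
    if config.batch_size > n:
        log.warning(
            "batch_size %d exceeds %d patients; falling back to a single batch",
            config.batch_size, n,
        )
    ss = np.random.SeedSequence(config.seed)
    s_corrupt, s_shuffle, s_dropout = ss.spawn(3)
    rng_shuffle = np.random.default_rng(s_shuffle)
    rng_dropout = np.random.default_rng(s_dropout)
    corrupt_children = s_corrupt.spawn(max(config.epochs, 1))

    fixed_noisy = None
    if config.fixed_mask and config.epochs > 0:
        rng_c = np.random.default_rng(corrupt_children[0])
        fixed_noisy = [
            corrupt(x.T, config.noise_factor, rng_c, rows=config.corrupt_rows)[0].T
            for x in clean_list
        ]

    history: list[float] = []
    for epoch in range(config.epochs):
        if fixed_noisy is not None:
            noisy_list = fixed_noisy
        else:
            rng_c = np.random.default_rng(corrupt_children[epoch])
            noisy_list = [
                corrupt(x.T, config.noise_factor, rng_c, rows=config.corrupt_rows)[0].T
                for x in clean_list
            ]
        total, count = 0.0, 0
        for batch in _epoch_batches(n, config.batch_size, rng_shuffle):
            clean_b = [x[batch] for x in clean_list]
            noisy_b = [x[batch] for x in noisy_list]
            if len(clean_list) == 1:
                loss = model._step(
                    clean_b[0], noisy_b[0],
                    config.learning_rate, config.dropout_rate, rng_dropout,
                )
            else:
                loss = model._step(
                    clean_b[0], clean_b[1], noisy_b[0], noisy_b[1],
                    config.learning_rate, config.dropout_rate, rng_dropout,
                )
            total += loss * len(batch)
            count += len(batch)
        history.append(total / count)
    return history


def train_one_input(
    scaled: ScaledMatrix,
    config: TrainConfig | None = None,
    n_features: int = 100,
) -> tuple[OneInputDA, list[float], FeatureSet]:
    """Train a one-input DA on a scaled matrix; extract clean activities."""
    config = config or TrainConfig()
    x = scaled.values.to_numpy(dtype=float).T          # patients x genes
    model = OneInputDA(x.shape[1], n_features=n_features, seed=config.seed)
    history = _train(model, [x], config)
    h, _ = model.forward(x, train_mode=False)
    activity = pd.DataFrame(
        h, index=scaled.patient_ids, columns=_feature_names(n_features)
    )
    return model, history, FeatureSet(activity, scaled.source_tag, model)


def train_two_input(
    scaled_a: ScaledMatrix,
    scaled_b: ScaledMatrix,
    config: TrainConfig | None = None,
    hidden1: int = 1000,
    hidden2: int = 100,
) -> tuple[TwoInputDA, list[float], FeatureSet]:
    """Train the concatenated two-input DA on a matched pair of matrices."""
    config = config or TrainConfig()
    if not scaled_a.patient_ids.equals(scaled_b.patient_ids):
        raise ValueError("the two sources must share an identical patient order")
    xa = scaled_a.values.to_numpy(dtype=float).T
    xb = scaled_b.values.to_numpy(dtype=float).T
    model = TwoInputDA(
        xa.shape[1], xb.shape[1], hidden1=hidden1, hidden2=hidden2, seed=config.seed
    )
    history = _train(model, [xa, xb], config)
    e2, _, _ = model.forward(xa, xb, train_mode=False)
    activity = pd.DataFrame(
        e2, index=scaled_a.patient_ids, columns=_feature_names(hidden2)
    )
    return model, history, FeatureSet(activity, "concatenated", model)
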