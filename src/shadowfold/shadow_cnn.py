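"""Convolutional shadow predictor.

A deliberately simple CNN that maps a one-hot RNA sequence (4 x L) to
per-nucleotide pairing probabilities — the structure's *shadow* — the kind of
model that looks excellent under intra-family cross-validation and collapses
under family-fold evaluation.  Two same-padded 1D convolution layers (256
filters, kernel 3) with ReLU and spatial dropout feed a fully connected block
(two 512-unit layers, dropout, final sigmoid).  Training uses Adam, binary
cross-entropy over all padded positions, mini-batches of 256 and early
stopping on validation loss with patience 5.

The network is implemented directly in numpy (forward and backward passes,
Adam update) so that training is fully deterministic under a fixed seed and
runs on a single CPU.
"""

from __future__ import annotations

import io
import json
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np

from .scoring_stats import auc_shadow
from .structure_io import RnaRecord, encode

__all__ = [
    "ModelConfig",
    "TrainedShadowModel",
    "build_model",
    "train_shadow_model",
    "predict_shadow",
    "save_model",
    "load_model",
]


@dataclass(frozen=True)
class ModelConfig:
    """Architecture and optimizer hyperparameters.

    The defaults are the demonstrative model's published settings; every field
    can be overridden (e.g. from a YAML experiment config) to scale the model
    down for quick CPU runs.
    """

    conv_layers: int = 2
    conv_filters: int = 256
    kernel_length: int = 3
    stride: int = 1
    spatial_dropout: float = 0.25
    fc_layers: int = 2
    fc_units: int = 512
    fc_dropout: float = 0.25
    learning_rate: float = 1e-3
    adam_beta1: float = 0.9
    adam_beta2: float = 0.999
    adam_epsilon: float = 1e-8
    batch_size: int = 256
    patience: int = 5
    max_epochs: int = 100
    pad_to: int = 512
    # "flatten": dense layers act on the flattened conv output so the final
    # 512 units align 1:1 with the padded target.  "per_position" applies the
    # dense block independently at each position (non-default alternative).
    fc_mode: str = "flatten"

    def __post_init__(self) -> None:
        if self.fc_mode not in ("flatten", "per_position"):
            raise ValueError(f"unknown fc_mode {self.fc_mode!r}")
        if self.conv_layers != 2 or self.fc_layers != 2:
            raise ValueError("architecture is fixed at 2 conv + 2 fc layers")
        if self.stride != 1:
            raise ValueError("only stride 1 is supported")


def _conv_same(x: np.ndarray, w: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Length-preserving 1D convolution.  x: (B,Cin,L), w: (Cout,Cin,K)."""
    k = w.shape[2]
    half = k // 2
    xp = np.pad(x, ((0, 0), (0, 0), (half, half)))
    L = x.shape[2]
    out = np.zeros((x.shape[0], w.shape[0], L), dtype=np.float32)
    for t in range(k):
        out += np.einsum("oi,bil->bol", w[:, :, t], xp[:, :, t : t + L],
                         optimize=True)
    return out + b[None, :, None]


def _conv_same_backward(
    dout: np.ndarray, x: np.ndarray, w: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Gradients of :func:`_conv_same` w.r.t. input, weights and bias."""
    k = w.shape[2]
    half = k // 2
    L = x.shape[2]
    xp = np.pad(x, ((0, 0), (0, 0), (half, half)))
    dxp = np.zeros_like(xp)
    dw = np.zeros_like(w)
    for t in range(k):
        dw[:, :, t] = np.einsum("bol,bil->oi", dout, xp[:, :, t : t + L],
                                optimize=True)
        dxp[:, :, t : t + L] += np.einsum("oi,bol->bil", w[:, :, t], dout,
                                          optimize=True)
    db = dout.sum(axis=(0, 2))
    return dxp[:, :, half : half + L], dw, db


class _Net:
    """Parameter store plus forward/backward for one architecture instance."""

    def __init__(self, config: ModelConfig, seed: int = 0):
        self.config = config
        rng = np.random.default_rng(seed)
        c, k, p, u = (config.conv_filters, config.kernel_length,
                      config.pad_to, config.fc_units)
        flat = c * p if config.fc_mode == "flatten" else c
        out = p if config.fc_mode == "flatten" else 1
        def he(shape, fan_in):
            return (rng.standard_normal(shape) *
                    np.sqrt(2.0 / fan_in)).astype(np.float32)

        self.params: dict[str, np.ndarray] = {
            "w_conv1": he((c, 4, k), 4 * k),
            "b_conv1": np.zeros(c, dtype=np.float32),
            "w_conv2": he((c, c, k), c * k),
            "b_conv2": np.zeros(c, dtype=np.float32),
            "w_fc1": he((flat, u), flat),
            "b_fc1": np.zeros(u, dtype=np.float32),
            "w_fc2": (rng.standard_normal((u, out)) *
                      np.sqrt(1.0 / u)).astype(np.float32),
            "b_fc2": np.zeros(out, dtype=np.float32),
        }

    def n_params(self) -> int:
        return sum(a.size for a in self.params.values())

    def forward(
        self, x: np.ndarray, train: bool = False,
        rng: np.random.Generator | None = None,
    ) -> tuple[np.ndarray, dict]:
        """Probabilities of shape (B, pad_to), plus a cache for backprop."""
        cfg, P = self.config, self.params
        cache: dict = {"x": x}
        h1 = _conv_same(x, P["w_conv1"], P["b_conv1"])
        a1 = np.maximum(h1, 0.0)
        if train and cfg.spatial_dropout > 0:
            keep = 1.0 - cfg.spatial_dropout
            mask = (rng.random((x.shape[0], a1.shape[1], 1)) < keep) / keep
            a1 = a1 * mask.astype(np.float32)
            cache["sd_mask"] = mask
        h2 = _conv_same(a1, P["w_conv2"], P["b_conv2"])
        a2 = np.maximum(h2, 0.0)
        cache.update(h1=h1, a1=a1, h2=h2, a2=a2)

        B = x.shape[0]
        if cfg.fc_mode == "flatten":
            flat = a2.reshape(B, -1)
        else:  # per-position: positions become batch rows
            flat = a2.transpose(0, 2, 1).reshape(B * cfg.pad_to, -1)
        z1 = flat @ P["w_fc1"] + P["b_fc1"]
        f1 = np.maximum(z1, 0.0)
        if train and cfg.fc_dropout > 0:
            keep = 1.0 - cfg.fc_dropout
            fmask = (rng.random(f1.shape) < keep) / keep
            f1 = f1 * fmask.astype(np.float32)
            cache["fc_mask"] = fmask
        z2 = f1 @ P["w_fc2"] + P["b_fc2"]
        prob = 0.5 * (1.0 + np.tanh(0.5 * z2))  # numerically stable sigmoid
        if cfg.fc_mode == "per_position":
            prob = prob.reshape(B, cfg.pad_to)
        cache.update(flat=flat, z1=z1, f1=f1, prob=prob)
        return prob, cache

    def backward(self, cache: dict, y: np.ndarray) -> dict[str, np.ndarray]:
        """Gradients of mean binary cross-entropy over batch x positions."""
        cfg, P = self.config, self.params
        B = cache["x"].shape[0]
        prob = cache["prob"]
        dz2 = (prob - y) / prob.size  # sigmoid + BCE
        if cfg.fc_mode == "per_position":
            dz2 = dz2.reshape(B * cfg.pad_to, 1)
        grads: dict[str, np.ndarray] = {}
        grads["w_fc2"] = cache["f1"].T @ dz2
        grads["b_fc2"] = dz2.sum(axis=0)
        df1 = dz2 @ P["w_fc2"].T
        if "fc_mask" in cache:
            df1 = df1 * cache["fc_mask"]
        dz1 = df1 * (cache["z1"] > 0)
        grads["w_fc1"] = cache["flat"].T @ dz1
        grads["b_fc1"] = dz1.sum(axis=0)
        dflat = dz1 @ P["w_fc1"].T
        if cfg.fc_mode == "flatten":
            da2 = dflat.reshape(cache["a2"].shape)
        else:
            da2 = dflat.reshape(B, cfg.pad_to, -1).transpose(0, 2, 1)
        dh2 = da2 * (cache["h2"] > 0)
        da1, grads["w_conv2"], grads["b_conv2"] = _conv_same_backward(
            dh2, cache["a1"], P["w_conv2"])
        if "sd_mask" in cache:
            da1 = da1 * cache["sd_mask"]
        dh1 = da1 * (cache["h1"] > 0)
        _, grads["w_conv1"], grads["b_conv1"] = _conv_same_backward(
            dh1, cache["x"], P["w_conv1"])
        return grads


class _Adam:
    def __init__(self, params: dict[str, np.ndarray], config: ModelConfig):
        self.cfg = config
        self.t = 0
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}

    def step(self, params: dict[str, np.ndarray], grads: dict[str, np.ndarray]):
        c = self.cfg
        self.t += 1
        b1t = 1.0 - c.adam_beta1 ** self.t
        b2t = 1.0 - c.adam_beta2 ** self.t
        for k, g in grads.items():
            g = g.astype(np.float32)
            self.m[k] = c.adam_beta1 * self.m[k] + (1 - c.adam_beta1) * g
            self.v[k] = c.adam_beta2 * self.v[k] + (1 - c.adam_beta2) * g * g
            params[k] -= (c.learning_rate * (self.m[k] / b1t) /
                          (np.sqrt(self.v[k] / b2t) + c.adam_epsilon))


@dataclass
class TrainedShadowModel:
    """A (possibly still untrained) shadow model plus its training history.

    ``history`` holds one dict per epoch with train/val loss, validation AUC
    and, when a test set was tracked, test AUC — enough to reproduce per-epoch
    generalization curves.
    """

    net: _Net
    config: ModelConfig
    history: list[dict] = field(default_factory=list)
    seed: int = 0

    def predict(self, x: np.ndarray, batch_size: int = 64) -> np.ndarray:
        outs = []
        for lo in range(0, x.shape[0], batch_size):
            prob, _ = self.net.forward(x[lo : lo + batch_size], train=False)
            outs.append(prob)
        return np.concatenate(outs, axis=0)


def build_model(config: ModelConfig = ModelConfig(), seed: int = 0) -> TrainedShadowModel:
    """Instantiate an untrained model with seeded parameter initialization."""
    return TrainedShadowModel(net=_Net(config, seed=seed), config=config, seed=seed)


def _stack(records: Sequence[RnaRecord], pad_to: int):
    xs = np.stack([encode(r, pad_to).x for r in records])
    ys = np.stack([encode(r, pad_to).y for r in records])
    lens = np.array([len(r) for r in records])
    return xs, ys, lens


def _eval_loss(model: TrainedShadowModel, x: np.ndarray, y: np.ndarray) -> float:
    p = np.clip(model.predict(x), 1e-7, 1 - 1e-7)
    return float(-(y * np.log(p) + (1 - y) * np.log(1 - p)).mean())


def _mean_auc(model: TrainedShadowModel, x, y, lens) -> float:
    """Per-record shadow AUC averaged over records where it is defined
    (padding positions excluded)."""
    probs = model.predict(x)
    aucs = []
    for p, t, n in zip(probs, y, lens):
        roc = auc_shadow(p[:n], t[:n].astype(np.int8))
        if roc.defined:
            aucs.append(roc.auc)
    return float(np.mean(aucs)) if aucs else float("nan")


def train_shadow_model(
    records: Sequence[RnaRecord],
    plan,
    config: ModelConfig = ModelConfig(),
    seed: int = 0,
    track_test: bool = False,
) -> TrainedShadowModel:
    """Train on a split plan's train set, early-stopping on its validation set.

    The loss is binary cross-entropy over all ``pad_to`` output positions
    (padding targets are zero, i.e. labelled unpaired); evaluation AUC excludes
    padding.  Early stopping monitors validation loss with the configured
    patience and restores the best-epoch parameters.  With ``track_test`` the
    per-epoch test-set AUC is recorded too — for diagnostics only, never for
    stopping.
    """
    by_id = {r.id: r for r in records}
    train = [by_id[i] for i in sorted(plan.train_ids)]
    val = [by_id[i] for i in sorted(plan.val_ids)]
    if not train:
        raise ValueError("empty training set")
    if not val:
        raise ValueError("empty validation set: cannot early-stop")
    test = [by_id[i] for i in sorted(plan.test_ids)] if track_test else []

    x_tr, y_tr, l_tr = _stack(train, config.pad_to)
    x_va, y_va, l_va = _stack(val, config.pad_to)
    x_te = y_te = l_te = None
    if test:
        x_te, y_te, l_te = _stack(test, config.pad_to)

    rng = np.random.default_rng(seed)
    model = build_model(config, seed=int(rng.integers(2**31)))
    opt = _Adam(model.net.params, config)

    best_loss, best_params, since_best = np.inf, None, 0
    for epoch in range(config.max_epochs):
        order = rng.permutation(len(train))
        batch_losses = []
        for lo in range(0, len(train), config.batch_size):
            idx = order[lo : lo + config.batch_size]
            xb, yb = x_tr[idx], y_tr[idx]
            prob, cache = model.net.forward(xb, train=True, rng=rng)
            p = np.clip(prob, 1e-7, 1 - 1e-7)
            batch_losses.append(
                float(-(yb * np.log(p) + (1 - yb) * np.log(1 - p)).mean()))
            grads = model.net.backward(cache, yb)
            opt.step(model.net.params, grads)
        entry = {
            "epoch": epoch,
            "train_loss": float(np.mean(batch_losses)),
            "val_loss": _eval_loss(model, x_va, y_va),
            "val_auc": _mean_auc(model, x_va, y_va, l_va),
        }
        if test:
            entry["test_auc"] = _mean_auc(model, x_te, y_te, l_te)
        model.history.append(entry)

        if entry["val_loss"] < best_loss:
            best_loss = entry["val_loss"]
            best_params = {k: v.copy() for k, v in model.net.params.items()}
            since_best = 0
        else:
            since_best += 1
            if since_best >= config.patience:
                break
    if best_params is not None:
        model.net.params = best_params
    model.seed = seed
    return model


def predict_shadow(
    model: TrainedShadowModel, records: Sequence[RnaRecord]
) -> list[np.ndarray]:
    """Pairing-probability vector per record, truncated to its true length."""
    xs, _, lens = _stack(records, model.config.pad_to)
    probs = model.predict(xs)
    return [p[:n].copy() for p, n in zip(probs, lens)]


def history_frame(model: TrainedShadowModel):
    """Training history as a pandas DataFrame (epoch, losses, AUCs)."""
    import pandas as pd

    return pd.DataFrame(model.history)


def save_model(model: TrainedShadowModel, path: str | Path) -> None:
    """Save parameters, config and history to a single .npz archive."""
    meta = json.dumps({
        "config": asdict(model.config),
        "history": model.history,
        "seed": model.seed,
    })
    np.savez_compressed(path, __meta__=np.frombuffer(meta.encode(), dtype=np.uint8),
                        **model.net.params)


def load_model(path: str | Path) -> TrainedShadowModel:
    with np.load(path) as data:
        meta = json.loads(bytes(data["__meta__"]).decode())
        config = ModelConfig(**meta["config"])
        model = build_model(config, seed=meta["seed"])
        model.net.params = {k: data[k] for k in data.files if k != "__meta__"}
        model.history = meta["history"]
    return model
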