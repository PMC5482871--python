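"""Small convolutional backbone with embedding + classifier heads, trained
by SGD with momentum on the combined softmax / distance-constraint loss.

The network is implemented directly on :mod:`numpy` (im2col convolutions,
hand-written backward passes): no GPU framework is available in the target
environment, and the desk-scale inputs (small synthetic images, a few
hundred samples) make this entirely adequate.  Convolution filter sizes are
restricted to {3, 5, 7}; hidden pooling is overlapping 3x3/stride-2 max
pooling and the final stage is a global average pool, so the backbone
accepts any input size >= 32.  Weights start from Gaussians with standard
deviation 0.01 (final conv block 0.0001).

The embedding head is l2-normalized; the classifier head produces subclass
logits.  The four quadruplet branches share one forward pass (shared
weights), with the constraint gradient scattered back onto the batch
embeddings by index.
"""

from __future__ import annotations

import copy
import json
import math
import warnings
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from PIL import Image

from hiercls.data_io import Manifest
from hiercls.hierarchy import Taxonomy
from hiercls.losses import (
    MarginConfig,
    constraint_satisfied,
    hinge_constraint_loss,
    hinge_constraint_loss_grad,
    softmax_loss,
    softmax_loss_grad,
)
from hiercls.metrics import MetricsReport, PredictionRecord, PredictionSet, compute_report
from hiercls.sampling import hierarchy_balanced_batch, mine_quadruplets

__all__ = [
    "BackboneConfig",
    "TrainConfig",
    "Network",
    "TrainedModel",
    "train",
    "evaluate",
    "margin_satisfaction",
    "save_checkpoint",
    "load_checkpoint",
]


def _seed_for(base: int, *parts) -> int:
    tag = zlib.crc32("|".join(str(p) for p in parts).encode())
    return int(np.random.SeedSequence([base, tag]).generate_state(1)[0])


# ---------------------------------------------------------------------------
# layers
# ---------------------------------------------------------------------------

def _init_scale(init_std, fan_in: int) -> float:
    """Resolve an init spec: a float std, or "auto" for He scaling
    (sqrt(2/fan_in)); a from-scratch net under the l2-norm head stalls with
    very small fixed stds."""
    if init_std == "auto":
        return math.sqrt(2.0 / fan_in)
    return float(init_std)


class _Conv2d:
    def __init__(self, in_c, out_c, k, stride, init_std, rng):
        if k not in (3, 5, 7):
            raise ValueError(f"filter size must be 3, 5 or 7, got {k}")
        self.k, self.stride, self.pad = k, stride, k // 2
        self.W = rng.normal(scale=_init_scale(init_std, in_c * k * k), size=(out_c, in_c * k * k))
        self.b = np.zeros(out_c)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)

    def forward(self, x):
        n, c, h, w = x.shape
        k, s, p = self.k, self.stride, self.pad
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
        win = sliding_window_view(xp, (k, k), axis=(2, 3))[:, :, ::s, ::s]
        ho, wo = win.shape[2], win.shape[3]
        col = win.transpose(0, 2, 3, 1, 4, 5).reshape(n, ho * wo, c * k * k)
        out = col @ self.W.T + self.b
        self._cache = (col, x.shape, ho, wo)
        return out.transpose(0, 2, 1).reshape(n, -1, ho, wo)

    def backward(self, dout):
        col, xshape, ho, wo = self._cache
        n, c, h, w = xshape
        k, s, p = self.k, self.stride, self.pad
        dflat = dout.reshape(n, -1, ho * wo).transpose(0, 2, 1)  # (n, ho*wo, out_c)
        self.dW = np.einsum("npo,npi->oi", dflat, col)
        self.db = dflat.sum(axis=(0, 1))
        dcol = (dflat @ self.W).reshape(n, ho, wo, c, k, k)
        dxp = np.zeros((n, c, h + 2 * p, w + 2 * p))
        for i in range(k):
            for j in range(k):
                dxp[:, :, i : i + s * ho : s, j : j + s * wo : s] += dcol[
                    :, :, :, :, i, j
                ].transpose(0, 3, 1, 2)
        return dxp[:, :, p : p + h, p : p + w]


class _ReLU:
    def forward(self, x):
        self._mask = x > 0
        return x * self._mask

    def backward(self, dout):
        return dout * self._mask


class _MaxPool:
    """Overlapping 3x3 stride-2 max pooling."""

    k, stride = 3, 2

    def forward(self, x):
        n, c, h, w = x.shape
        win = sliding_window_view(x, (self.k, self.k), axis=(2, 3))[
            :, :, :: self.stride, :: self.stride
        ]
        ho, wo = win.shape[2], win.shape[3]
        flat = win.reshape(n, c, ho, wo, self.k * self.k)
        self._idx = flat.argmax(axis=-1)
        self._xshape = x.shape
        return flat.max(axis=-1)

    def backward(self, dout):
        n, c, ho, wo = dout.shape
        dx = np.zeros(self._xshape)
        ng, cg, hg, wg = np.indices((n, c, ho, wo))
        h = hg * self.stride + self._idx // self.k
        w = wg * self.stride + self._idx % self.k
        np.add.at(dx, (ng, cg, h, w), dout)
        return dx


class _GlobalAvgPool:
    def forward(self, x):
        self._xshape = x.shape
        return x.mean(axis=(2, 3))

    def backward(self, dout):
        n, c, h, w = self._xshape
        return np.broadcast_to(dout[:, :, None, None], self._xshape) / (h * w)


class _Linear:
    def __init__(self, in_d, out_d, init_std, rng):
        self.W = rng.normal(scale=_init_scale(init_std, in_d), size=(out_d, in_d))
        self.b = np.zeros(out_d)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)

    def forward(self, x):
        self._x = x
        return x @ self.W.T + self.b

    def backward(self, dout):
        self.dW = dout.T @ self._x
        self.db = dout.sum(axis=0)
        return dout @ self.W


class _L2Norm:
    eps = 1e-12

    def forward(self, x):
        nrm = np.maximum(np.linalg.norm(x, axis=1, keepdims=True), self.eps)
        self._y, self._nrm = x / nrm, nrm
        return self._y

    def backward(self, dout):
        y = self._y
        return (dout - y * np.sum(y * dout, axis=1, keepdims=True)) / self._nrm


# ---------------------------------------------------------------------------
# network
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BackboneConfig:
    """Architecture description: conv blocks as (filter_size, channels,
    stride) with 3x3/stride-2 max pooling between blocks and a global
    average pool after the last."""

    input_size: int = 64
    conv_blocks: tuple[tuple[int, int, int], ...] = ((5, 12, 2), (3, 24, 1), (3, 32, 1))
    embedding_dim: int = 64
    init_std: "float | str" = "auto"
    final_conv_init_std: "float | str" = "auto"

    def __post_init__(self) -> None:
        if self.input_size < 32:
            raise ValueError("input_size must be >= 32")
        if self.embedding_dim < 2:
            raise ValueError("embedding_dim must be >= 2")
        for k, ch, s in self.conv_blocks:
            if k not in (3, 5, 7):
                raise ValueError(f"filter size must be in {{3,5,7}}, got {k}")

    def to_dict(self) -> dict:
        return {
            "input_size": self.input_size,
            "conv_blocks": [list(b) for b in self.conv_blocks],
            "embedding_dim": self.embedding_dim,
            "init_std": self.init_std,
            "final_conv_init_std": self.final_conv_init_std,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "BackboneConfig":
        d = dict(d)
        d["conv_blocks"] = tuple(tuple(b) for b in d["conv_blocks"])
        return cls(**d)


class Network:
    """Backbone + l2-normalized embedding head + softmax classifier head."""

    def __init__(self, cfg: BackboneConfig, n_classes: int, rng_seed: int = 0):
        self.cfg = cfg
        self.n_classes = n_classes
        rng = np.random.default_rng(rng_seed)
        self.layers: list = []
        in_c = 3
        n_blocks = len(cfg.conv_blocks)
        for i, (k, ch, stride) in enumerate(cfg.conv_blocks):
            std = cfg.final_conv_init_std if i == n_blocks - 1 else cfg.init_std
            self.layers.append(_Conv2d(in_c, ch, k, stride, std, rng))
            self.layers.append(_ReLU())
            if i < n_blocks - 1:
                self.layers.append(_MaxPool())
            in_c = ch
        self.layers.append(_GlobalAvgPool())
        self.embed = _Linear(in_c, cfg.embedding_dim, cfg.init_std, rng)
        self.norm = _L2Norm()
        self.classifier = _Linear(cfg.embedding_dim, n_classes, cfg.init_std, rng)
        self.channel_means = np.zeros(3)

    # -- parameter plumbing -------------------------------------------------
    def _param_layers(self):
        return [l for l in self.layers if isinstance(l, _Conv2d)] + [
            self.embed,
            self.classifier,
        ]

    def get_params(self) -> list[np.ndarray]:
        out = []
        for l in self._param_layers():
            out += [l.W.copy(), l.b.copy()]
        return out

    def set_params(self, params: list[np.ndarray]) -> None:
        it = iter(params)
        for l in self._param_layers():
            l.W = next(it).copy()
            l.b = next(it).copy()

    # -- forward / backward -------------------------------------------------
    def forward(self, images: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Images are (N, H, W, 3) floats in [0, 1]; returns unit-norm
        embeddings (N, d) and logits (N, k)."""
        images = np.asarray(images, dtype=np.float64)
        if images.ndim != 4 or images.shape[-1] != 3:
            raise ValueError(f"expected (N, H, W, 3) RGB images, got {images.shape}")
        x = (images - self.channel_means).transpose(0, 3, 1, 2)
        for l in self.layers:
            x = l.forward(x)
        emb = self.norm.forward(self.embed.forward(x))
        logits = self.classifier.forward(emb)
        return emb, logits

    def backward(self, d_logits: np.ndarray, d_emb: np.ndarray | None = None) -> None:
        g = self.classifier.backward(d_logits)
        if d_emb is not None:
            g = g + d_emb
        g = self.embed.backward(self.norm.backward(g))
        for l in reversed(self.layers):
            g = l.backward(g)

    def sgd_step(self, lr: float, momentum: float, velocity: list[np.ndarray]) -> None:
        i = 0
        for l in self._param_layers():
            for name in ("W", "b"):
                v = velocity[i]
                v *= momentum
                v -= lr * getattr(l, "d" + name)
                getattr(l, name).__iadd__(v)
                i += 1

    def zero_velocity(self) -> list[np.ndarray]:
        out = []
        for l in self._param_layers():
            out += [np.zeros_like(l.W), np.zeros_like(l.b)]
        return out


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TrainConfig:
    base_lr: float = 0.01
    momentum: float = 0.9
    iterations: int = 5000
    batch_size: int = 32
    margins: MarginConfig = field(default_factory=MarginConfig)
    per_anchor: int = 1
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.base_lr <= 0:
            raise ValueError("base_lr must be > 0")
        if self.iterations < 1:
            raise ValueError("iterations must be >= 1")


@dataclass
class TrainedModel:
    network: Network
    taxonomy: Taxonomy
    backbone_cfg: BackboneConfig
    train_cfg: TrainConfig
    log: list[dict]
    best_val_image_rate: float
    best_step: int


def _load_split_arrays(m: Manifest, split: str, input_size: int):
    recs = [r for r in m.records if r.split == split]
    if not recs:
        raise ValueError(f"split {split!r} is empty")
    root = Path(m.root)
    imgs = np.empty((len(recs), input_size, input_size, 3))
    for i, r in enumerate(recs):
        im = Image.open(root / r.path).convert("RGB")
        if im.size != (input_size, input_size):
            im = im.resize((input_size, input_size), Image.BILINEAR)
        imgs[i] = np.asarray(im, dtype=np.float64) / 255.0
    labels = [m.taxonomy.canonical(r.subclass) for r in recs]
    return imgs, labels, recs


def train(
    manifest: Manifest,
    backbone_cfg: BackboneConfig | None = None,
    train_cfg: TrainConfig | None = None,
    taxonomy: Taxonomy | None = None,
) -> TrainedModel:
    """Train on the manifest's train split, selecting the checkpoint with the
    best validation image-level rate at each epoch boundary.

    One epoch is one pass over the training manifest
    (``ceil(n_train / batch_size)`` steps).  Every step draws a
    hierarchy-balanced batch, mines quadruplets, and takes one SGD step on
    ``E = lam * J + (1 - lam) * E_t``.  Fully seeded and deterministic.
    """
    backbone_cfg = backbone_cfg or BackboneConfig()
    train_cfg = train_cfg or TrainConfig()
    taxonomy = taxonomy or manifest.taxonomy
    m = train_cfg.margins
    seed = train_cfg.rng_seed

    tr_imgs, tr_labels, _ = _load_split_arrays(manifest, "train", backbone_cfg.input_size)
    va_imgs, va_labels, _ = _load_split_arrays(manifest, "val", backbone_cfg.input_size)
    label_idx = np.array([taxonomy.index(l) for l in tr_labels])
    va_idx = np.array([taxonomy.index(l) for l in va_labels])

    net = Network(backbone_cfg, taxonomy.k, rng_seed=_seed_for(seed, "init"))
    net.channel_means = tr_imgs.mean(axis=(0, 1, 2))
    velocity = net.zero_velocity()

    steps_per_epoch = max(1, math.ceil(len(tr_imgs) / train_cfg.batch_size))
    log: list[dict] = []
    best_rate, best_step, best_params = -1.0, 0, net.get_params()

    for step in range(train_cfg.iterations):
        batch = hierarchy_balanced_batch(
            tr_labels, taxonomy, train_cfg.batch_size, rng_seed=_seed_for(seed, "batch", step)
        )
        imgs = tr_imgs[batch]
        labels = label_idx[batch]
        batch_label_strs = [tr_labels[i] for i in batch]

        emb, logits = net.forward(imgs)
        if not (np.isfinite(logits).all() and np.isfinite(emb).all()):
            raise FloatingPointError(
                f"non-finite forward outputs at step {step} (diverged; lower base_lr)"
            )
        j_val = softmax_loss(logits, labels)
        d_logits = m.lam * softmax_loss_grad(logits, labels)

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            quads = mine_quadruplets(
                batch_label_strs,
                taxonomy,
                per_anchor=train_cfg.per_anchor,
                rng_seed=_seed_for(seed, "mine", step),
            )
        d_emb = None
        et_val = 0.0
        if quads:
            qidx = np.array([q.as_tuple() for q in quads])
            qemb = emb[qidx]  # (Q, 4, d)
            et_val = hinge_constraint_loss(qemb, m)
            if m.lam < 1.0:
                g_quads = (1.0 - m.lam) * hinge_constraint_loss_grad(qemb, m)
                d_emb = np.zeros_like(emb)
                np.add.at(d_emb, qidx.ravel(), g_quads.reshape(-1, emb.shape[1]))

        e_val = m.lam * j_val + (1.0 - m.lam) * et_val
        if not np.isfinite(e_val):
            raise FloatingPointError(
                f"non-finite loss at step {step}: J={j_val}, E_t={et_val}"
            )
        net.backward(d_logits, d_emb)
        net.sgd_step(train_cfg.base_lr, train_cfg.momentum, velocity)
        row = {
            "step": step,
            "J": j_val,
            "E_t": et_val,
            "E": e_val,
            "lr": train_cfg.base_lr,
            "n_quadruplets": len(quads),
        }

        if (step + 1) % steps_per_epoch == 0 or step == train_cfg.iterations - 1:
            preds = _predict_logits(net, va_imgs)
            rate = float(np.mean(preds.argmax(axis=1) == va_idx))
            row["val_image_rate"] = rate
            if rate > best_rate:
                best_rate, best_step, best_params = rate, step, net.get_params()
        log.append(row)

    net.set_params(best_params)
    return TrainedModel(
        network=net,
        taxonomy=taxonomy,
        backbone_cfg=backbone_cfg,
        train_cfg=train_cfg,
        log=log,
        best_val_image_rate=best_rate,
        best_step=best_step,
    )


def _predict_logits(net: Network, imgs: np.ndarray, chunk: int = 64) -> np.ndarray:
    out = []
    for i in range(0, len(imgs), chunk):
        _, logits = net.forward(imgs[i : i + chunk])
        out.append(logits)
    return np.concatenate(out)


def _embed(net: Network, imgs: np.ndarray, chunk: int = 64) -> np.ndarray:
    out = []
    for i in range(0, len(imgs), chunk):
        emb, _ = net.forward(imgs[i : i + chunk])
        out.append(emb)
    return np.concatenate(out)


def evaluate(
    model: TrainedModel, manifest: Manifest, split: str
) -> tuple[PredictionSet, MetricsReport]:
    """Argmax-of-logits predictions on a split plus the full metrics report."""
    imgs, labels, recs = _load_split_arrays(manifest, split, model.backbone_cfg.input_size)
    logits = _predict_logits(model.network, imgs)
    order = model.taxonomy.subclasses
    preds = PredictionSet(
        tuple(
            PredictionRecord(
                patient_id=r.patient_id,
                true_subclass=model.taxonomy.canonical(r.subclass),
                predicted_subclass=order[int(i)],
                magnification=r.magnification,
            )
            for r, i in zip(recs, logits.argmax(axis=1))
        )
    )
    return preds, compute_report(preds, model.taxonomy)


def margin_satisfaction(
    model: TrainedModel,
    manifest: Manifest,
    split: str,
    rng_seed: int = 0,
    per_anchor: int = 2,
) -> dict:
    """Mine quadruplets on a split and measure how the embedding respects the
    tiered constraint: satisfaction fraction and the mean of each distance
    tier."""
    imgs, labels, _ = _load_split_arrays(manifest, split, model.backbone_cfg.input_size)
    emb = _embed(model.network, imgs)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        quads = mine_quadruplets(labels, model.taxonomy, per_anchor=per_anchor, rng_seed=rng_seed)
    if not quads:
        return {"n_quadruplets": 0, "satisfied_fraction": float("nan")}
    m = model.train_cfg.margins
    d_pp, d_pm, d_n, sat = [], [], [], 0
    for q in quads:
        x, pp, pm, n = (emb[i] for i in q.as_tuple())
        dpp, dpm, dn = (float(np.linalg.norm(x - v)) for v in (pp, pm, n))
        d_pp.append(dpp)
        d_pm.append(dpm)
        d_n.append(dn)
        if dpp + m.m1 < dpm + m.m2 < dn:
            sat += 1
    return {
        "n_quadruplets": len(quads),
        "satisfied_fraction": sat / len(quads),
        "mean_d_same_subclass": float(np.mean(d_pp)),
        "mean_d_same_superclass": float(np.mean(d_pm)),
        "mean_d_cross_superclass": float(np.mean(d_n)),
    }


# ---------------------------------------------------------------------------
# checkpoints
# ---------------------------------------------------------------------------

def save_checkpoint(model: TrainedModel, path) -> None:
    """Single-file checkpoint: parameters + configs + normalization stats."""
    path = Path(path)
    params = model.network.get_params()
    meta = {
        "backbone": model.backbone_cfg.to_dict(),
        "taxonomy": model.taxonomy.to_config(),
        "n_classes": model.taxonomy.k,
        "best_val_image_rate": model.best_val_image_rate,
        "best_step": model.best_step,
        "margins": {
            "m1": model.train_cfg.margins.m1,
            "m2": model.train_cfg.margins.m2,
            "lam": model.train_cfg.margins.lam,
        },
    }
    arrays = {f"p{i}": p for i, p in enumerate(params)}
    arrays["channel_means"] = model.network.channel_means
    np.savez(path, meta=json.dumps(meta), **arrays)


def load_checkpoint(path) -> TrainedModel:
    data = np.load(path, allow_pickle=False)
    meta = json.loads(str(data["meta"]))
    cfg = BackboneConfig.from_dict(meta["backbone"])
    taxonomy = Taxonomy.from_config(meta["taxonomy"])
    net = Network(cfg, meta["n_classes"])
    n_params = len([k for k in data.files if k.startswith("p")])
    net.set_params([data[f"p{i}"] for i in range(n_params)])
    net.channel_means = data["channel_means"]
    mm = meta["margins"]
    tc = TrainConfig(margins=MarginConfig(mm["m1"], mm["m2"], mm["lam"], allow_boundary=True))
    return TrainedModel(
        network=net,
        taxonomy=taxonomy,
        backbone_cfg=cfg,
        train_cfg=tc,
        log=[],
        best_val_image_rate=meta["best_val_image_rate"],
        best_step=meta["best_step"],
    )
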