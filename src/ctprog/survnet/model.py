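"""The CRNN risk model (Rad-D) and its baseline-only ablation (Rad-S).

Architecture, per patient: every selected 2D slice passes through one shared
convolutional backbone to a d-dimensional embedding; the three slice embeddings of
each (organ, timepoint) scan are averaged (the slice mean makes the model
invariant to slice order); for Rad-D a per-organ LSTM runs over the
(baseline, follow-up) sequence and its last hidden state represents the organ,
while Rad-S uses the baseline embedding directly; the liver and lung
representations are concatenated and a two-layer linear head maps them to a
scalar log-relative-hazard score. Training minimizes the event-normalized
negative log Cox partial likelihood over minibatch risk sets with Adam.
"""

from __future__ import annotations

import pickle
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from skimage.transform import resize as _sk_resize

from ctprog.phantom import ORGANS, TIMEPOINTS, ClinicalRecord
from ctprog.preprocess import SlicePack
from ctprog.survnet.loss import ZeroEventsError, cox_partial_likelihood_loss
from ctprog.survnet import nn

VARIANTS = ("cln", "rad_s", "rad_d", "radcln_s", "radcln_d")


@dataclass(frozen=True)
class RiskScore:
    """Scalar log-relative-hazard prediction for one patient, tagged by model."""

    patient_id: str
    score: float
    variant: str

    def __post_init__(self):
        if not np.isfinite(self.score):
            raise ValueError("risk score must be finite")
        if self.variant not in VARIANTS:
            raise ValueError(f"unknown variant {self.variant!r}")


@dataclass
class NetConfig:
    """Hyperparameters of the risk network.

    The defaults follow the original training recipe (batch 16, Adam at 5e-5,
    200 epochs, flip augmentation at 0.5); desk-scale experiments typically lower
    ``epochs`` and raise ``learning_rate``. ``backbone`` selects the convolutional
    feature extractor; the default is a small 4-layer CNN with ``channels`` ending
    in the embedding dimension d. ``input_size`` is the square resolution slices
    are downsampled to before entering the backbone.
    """

    variant: str = "rad_d"
    backbone: str = "small_cnn"
    channels: tuple[int, ...] = (8, 16, 32, 64)
    input_size: int = 64
    recurrent_hidden: int = 32
    head_dims: tuple[int, ...] = (32, 1)
    learning_rate: float = 5e-5
    batch_size: int = 16
    epochs: int = 200
    augment_p: float = 0.5
    weight_decay: float = 0.0
    seed: int = 0
    dtype: str = "float32"
    full_batch: bool = False
    shared_backbone: bool = True

    def __post_init__(self):
        if self.variant not in ("rad_s", "rad_d"):
            raise ValueError("variant must be rad_s or rad_d")
        if self.head_dims[-1] != 1:
            raise ValueError("head must end in a scalar output")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.batch_size < 2:
            raise ValueError("batch_size must be >= 2 (risk sets need pairs)")
        if self.input_size % (2 ** len(self.channels)) != 0:
            raise ValueError("input_size must be divisible by 2^(number of conv blocks)")

    @property
    def embed_dim(self) -> int:
        return self.channels[-1]

    @property
    def n_images(self) -> int:
        return 12 if self.variant == "rad_d" else 6

    @property
    def np_dtype(self):
        return np.float64 if self.dtype == "float64" else np.float32


def _pack_keys(variant: str) -> list[tuple[str, str]]:
    tps = TIMEPOINTS if variant == "rad_d" else ("baseline",)
    return [(organ, tp) for organ in ORGANS for tp in tps]


def pack_to_array(pack: SlicePack, config: NetConfig) -> np.ndarray:
    """Flatten a SlicePack to the model input array (n_images, s, s).

    Image order is organ-major, timepoint-minor, three slices each:
    liver-baseline, liver-followup, lung-baseline, lung-followup (Rad-D), or the
    two baseline scans only (Rad-S).
    """
    s = config.input_size
    imgs = []
    for key in _pack_keys(config.variant):
        arr = pack.images[key]
        if arr.shape[0] != 3:
            raise ValueError(f"expected 3 slices for {key}, got {arr.shape[0]}")
        for i in range(3):
            img = arr[i]
            if img.shape != (s, s):
                img = _sk_resize(img.astype(float), (s, s), order=1,
                                 anti_aliasing=img.shape[0] > s, preserve_range=True)
            imgs.append(img)
    return np.stack(imgs).astype(config.np_dtype)


class _Backbone:
    """Small 4-layer CNN: [conv3x3 -> ReLU -> maxpool2] x4, then global average pool."""

    def __init__(self, config: NetConfig, rng: np.random.Generator):
        dtype = config.np_dtype
        self.layers: list[nn.Layer] = []
        c_in = 1
        for c_out in config.channels:
            self.layers += [nn.Conv2d(c_in, c_out, rng, dtype), nn.ReLU(), nn.MaxPool2()]
            c_in = c_out
        self.gap = nn.GlobalAvgPool()

    def params(self):
        return [p for layer in self.layers for p in layer.params()]

    def forward(self, x: np.ndarray) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x)
        self.last_feature_maps = x  # post-ReLU maps of the last conv block
        return self.gap.forward(x)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        dx = self.gap.backward(dout)
        for layer in reversed(self.layers):
            dx = layer.backward(dx)
        return dx

    def feature_map_grad(self, dout_embedding: np.ndarray) -> np.ndarray:
        """Gradient at the last conv feature maps for a given embedding gradient."""
        return self.gap.backward(dout_embedding)


class RiskModel:
    """Deterministic forward/backward risk scorer; weights fixed at construction."""

    def __init__(self, config: NetConfig):
        if config.backbone != "small_cnn":
            raise ValueError(f"unknown backbone {config.backbone!r}")
        self.config = config
        rng = np.random.default_rng(config.seed)
        dtype = config.np_dtype
        self.backbone = _Backbone(config, rng)
        d = config.embed_dim
        h = config.recurrent_hidden
        if config.variant == "rad_d":
            self.lstm = {organ: nn.LSTM(d, h, rng, dtype) for organ in ORGANS}
            head_in = 2 * h
        else:
            self.lstm = {}
            head_in = 2 * d
        self.head: list[nn.Layer] = []
        prev = head_in
        for i, width in enumerate(config.head_dims):
            self.head.append(nn.Linear(prev, width, rng, dtype))
            if i < len(config.head_dims) - 1:
                # leaky activation: with few hidden units a plain ReLU layer can
                # start (and stay) entirely dead, cutting all gradient flow to
                # the recurrent and convolutional stages
                self.head.append(nn.LeakyReLU(0.1))
            prev = width

    # -- parameters --------------------------------------------------------
    def parameters(self) -> list[nn.Param]:
        ps = self.backbone.params()
        for organ in ORGANS:
            if organ in self.lstm:
                ps += self.lstm[organ].params()
        for layer in self.head:
            ps += layer.params()
        return ps

    # -- forward / backward -------------------------------------------------
    def forward_array(self, X: np.ndarray) -> np.ndarray:
        """Score a batch. X has shape (N, n_images, s, s); returns (N,)."""
        cfg = self.config
        n, k, s1, s2 = X.shape
        if k != cfg.n_images or s1 != cfg.input_size or s2 != cfg.input_size:
            raise ValueError(
                f"expected input (N, {cfg.n_images}, {cfg.input_size}, {cfg.input_size})")
        flat = X.reshape(n * k, 1, s1, s2).astype(cfg.np_dtype)
        emb = self.backbone.forward(flat)  # (n*k, d)
        d = cfg.embed_dim
        n_tp = 2 if cfg.variant == "rad_d" else 1
        E = emb.reshape(n, 2, n_tp, 3, d)
        self._E_mean = E.mean(axis=3)  # (n, organ, tp, d)
        reps = []
        if cfg.variant == "rad_d":
            for oi, organ in enumerate(ORGANS):
                reps.append(self.lstm[organ].forward(self._E_mean[:, oi]))
        else:
            for oi in range(2):
                reps.append(self._E_mean[:, oi, 0])
        z = np.concatenate(reps, axis=1)
        for layer in self.head:
            z = layer.forward(z)
        self._n = n
        return z[:, 0]

    def backward_array(self, dscores: np.ndarray, *, to_feature_maps: bool = False):
        """Backpropagate dL/dscores; accumulates parameter gradients.

        With ``to_feature_maps`` the backbone weights are not descended into and
        the gradient at the last conv feature maps is returned instead (used by
        Grad-CAM).
        """
        cfg = self.config
        n = self._n
        dz = np.asarray(dscores, dtype=cfg.np_dtype).reshape(n, 1)
        for layer in reversed(self.head):
            dz = layer.backward(dz)
        d = cfg.embed_dim
        n_tp = 2 if cfg.variant == "rad_d" else 1
        dE_mean = np.zeros_like(self._E_mean)
        if cfg.variant == "rad_d":
            h = cfg.recurrent_hidden
            for oi, organ in enumerate(ORGANS):
                dE_mean[:, oi] = self.lstm[organ].backward(dz[:, oi * h:(oi + 1) * h])
        else:
            for oi in range(2):
                dE_mean[:, oi, 0] = dz[:, oi * d:(oi + 1) * d]
        demb = np.repeat(dE_mean[:, :, :, None, :] / 3.0, 3, axis=3).reshape(-1, d)
        if to_feature_maps:
            return self.backbone.feature_map_grad(demb)
        return self.backbone.backward(demb)

    # -- public scoring -----------------------------------------------------
    def score_pack(self, pack: SlicePack) -> RiskScore:
        X = pack_to_array(pack, self.config)[None]
        return RiskScore(patient_id=pack.patient_id,
                         score=float(self.forward_array(X)[0]),
                         variant=self.config.variant)

    def score_packs(self, packs: Sequence[SlicePack], batch: int = 32) -> list[RiskScore]:
        out = []
        for start in range(0, len(packs), batch):
            chunk = packs[start:start + batch]
            X = np.stack([pack_to_array(p, self.config) for p in chunk])
            scores = self.forward_array(X)
            out += [RiskScore(p.patient_id, float(sc), self.config.variant)
                    for p, sc in zip(chunk, scores)]
        return out

    # -- persistence ---------------------------------------------------------
    def save(self, path: str | Path) -> None:
        state = {"config": self.config, "params": [p.value for p in self.parameters()]}
        with open(path, "wb") as fh:
            pickle.dump(state, fh)

    @classmethod
    def load(cls, path: str | Path) -> "RiskModel":
        with open(path, "rb") as fh:
            state = pickle.load(fh)
        model = cls(state["config"])
        for p, v in zip(model.parameters(), state["params"]):
            p.value[...] = v
        return model


def _augment_batch(X: np.ndarray, p: float, rng: np.random.Generator) -> np.ndarray:
    """Horizontal flips, independent per image."""
    if p <= 0:
        return X
    flips = rng.random(X.shape[:2]) < p
    Xa = X.copy()
    Xa[flips] = Xa[flips][..., ::-1]
    return Xa


def train(packs: Sequence[SlicePack], records: Sequence[ClinicalRecord],
          config: NetConfig) -> tuple[RiskModel, pd.DataFrame]:
    """Fit the risk network on a training cohort.

    Minibatch Adam on the Cox partial-likelihood loss computed within each
    batch's risk sets; batches that happen to contain no event are skipped.
    Flip augmentation is applied only here. Returns the trained model and the
    unaugmented training-set scores (columns patient_id, score, variant).
    """
    if len(packs) < 2:
        raise ValueError("need at least 2 patients")
    by_id = {r.patient_id: r for r in records}
    times = np.array([by_id[p.patient_id].os_days for p in packs])
    events = np.array([by_id[p.patient_id].event for p in packs])
    if events.sum() == 0:
        raise ZeroEventsError("cohort has no events; cannot train")

    X = np.stack([pack_to_array(p, config) for p in packs])
    model = RiskModel(config)
    opt = nn.Adam(model.parameters(), lr=config.learning_rate,
                  weight_decay=config.weight_decay)
    rng = np.random.default_rng(config.seed + 1)

    n = len(packs)
    bs = n if config.full_batch else config.batch_size
    for _epoch in range(config.epochs):
        order = rng.permutation(n)
        for start in range(0, n, bs):
            idx = order[start:start + bs]
            if len(idx) < 2 or events[idx].sum() == 0:
                continue
            Xb = _augment_batch(X[idx], config.augment_p, rng)
            scores = model.forward_array(Xb)
            _, grad = cox_partial_likelihood_loss(scores, times[idx], events[idx],
                                                  return_grad=True)
            opt.zero_grad()
            model.backward_array(grad)
            opt.step()

    final = []
    for start in range(0, n, 32):
        final.append(model.forward_array(X[start:start + 32]))
    scores = np.concatenate(final)
    df = pd.DataFrame({
        "patient_id": [p.patient_id for p in packs],
        "score": scores,
        "variant": config.variant,
    })
    return model, df


def scores_frame(scores: Sequence[RiskScore]) -> pd.DataFrame:
    return pd.DataFrame({
        "patient_id": [s.patient_id for s in scores],
        "score": [s.score for s in scores],
        "variant": [s.variant for s in scores],
    })
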