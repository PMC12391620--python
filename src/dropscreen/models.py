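"""Outlier-exclusion and cell-count classifiers for droplet crops.

Two models mirror the screening pipeline: a binary *outlier exclusion* model
that works on the brightfield frame alone and flags unusable droplet images
(bubble overlay, edge cut-off, double-layer blur), and a four-headed *cell
count* model that reads brightfield plus the three fluorescence channels and
predicts live/dead × effector/target counts per droplet as a classification
over ``0..c_max`` (the top class meaning "c_max or more").  Both are small
NumPy convolutional networks (:mod:`dropscreen.nn`) trained with Adam under
right-angle rotation/flip augmentation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .config import BRIGHTFIELD, DEFAULT_CHANNELS, TrainingConfig
from .nn import Adam, ConvNet, cross_entropy_grad

__all__ = [
    "HEADS",
    "CountPrediction",
    "OutlierModel",
    "CellCountModel",
    "train_outlier_model",
    "train_cellcount_model",
    "accuracy_report",
    "relative_count_error",
    "stack_crops",
    "counts_to_labels",
]

#: head order used everywhere a (N, 4) count array appears
HEADS = ("live_targets", "dead_targets", "live_effectors", "dead_effectors")

_MAX_COUNT = 65535.0  # fixed 16-bit intensity scale used for normalisation

# Fixed per-channel standardisation constants (fractions of the 16-bit range).
# These are dataset-independent design constants, not per-image statistics:
# brightfield sits near 30% of full scale, fluorescence near 1%, and the
# scales bring both channel families to O(1) activations.
_CHANNEL_NORM = {"brightfield": (0.30, 0.05), "default": (0.010, 0.012)}


@dataclass
class CountPrediction:
    """Predicted per-droplet counts with per-head class scores."""

    live_targets: int
    dead_targets: int
    live_effectors: int
    dead_effectors: int
    scores: dict[str, np.ndarray] = field(default_factory=dict)

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, h) for h in HEADS], dtype=int)


def stack_crops(crops, channels: tuple[str, ...]) -> np.ndarray:
    """Stack crops (dicts channel→2-D, or ImageStacks) into (N, C, H, W) float32.

    Channels are selected *by name* so a permuted channel dict cannot be
    silently mis-read; a missing channel raises.
    """
    arrays = []
    for crop in crops:
        chans = crop.channels if hasattr(crop, "channels") else crop
        try:
            arrays.append(np.stack([np.asarray(chans[ch]) for ch in channels]))
        except KeyError as e:
            raise ValueError(f"crop is missing channel {e.args[0]!r}") from None
    return np.asarray(arrays, dtype=np.float32)


def counts_to_labels(counts: np.ndarray, c_max: int) -> np.ndarray:
    """Clip raw counts into the 0..c_max classification buckets."""
    return np.clip(np.asarray(counts, dtype=int), 0, c_max)


def _downsample(x: np.ndarray, factor: int) -> np.ndarray:
    if factor == 1:
        return x
    n, c, h, w = x.shape
    return x.reshape(n, c, h // factor, factor, w // factor, factor).mean(axis=(3, 5))


def _prepare(x: np.ndarray, config: TrainingConfig, channels: tuple[str, ...]) -> np.ndarray:
    """Fixed-scale normalisation (bit depth + per-channel constants) and downsampling."""
    z = _downsample(x.astype(np.float32) / _MAX_COUNT, config.downsample)
    for k, ch in enumerate(channels):
        mu, sd = _CHANNEL_NORM.get(ch, _CHANNEL_NORM["default"])
        z[:, k] = (z[:, k] - mu) / sd
    return z


def _augment(x: np.ndarray, config: TrainingConfig, rng: np.random.Generator) -> np.ndarray:
    out = x
    if config.augment_rotations:
        k = int(rng.integers(4))
        if k:
            out = np.rot90(out, k=k, axes=(2, 3))
    if config.augment_flips and rng.integers(2):
        out = out[:, :, :, ::-1]
    return np.ascontiguousarray(out)


def _train_net(
    net: ConvNet,
    x: np.ndarray,
    labels: list[np.ndarray],
    config: TrainingConfig,
    rng: np.random.Generator,
) -> list[float]:
    """Mini-batch Adam training; returns the per-epoch mean loss log."""
    opt = Adam(net.params(), lr=config.learning_rate)
    n = len(x)
    log = []
    for _epoch in range(config.epochs):
        order = rng.permutation(n)
        losses = []
        for i in range(0, n, config.batch_size):
            idx = order[i : i + config.batch_size]
            xb = _augment(x[idx], config, rng)
            yb = [lab[idx] for lab in labels]
            net.zero_grad()
            logits = net.forward(xb)
            loss = 0.0
            grads = []
            for lg, lab in zip(logits, yb):
                l, g = cross_entropy_grad(lg, lab)
                loss += l
                grads.append(g)
            net.backward(grads)
            opt.step()
            losses.append(loss / len(logits))
        log.append(float(np.mean(losses)))
    return log


@dataclass
class OutlierModel:
    """Binary usable/outlier classifier on the brightfield crop."""

    net: ConvNet
    config: TrainingConfig
    training_log: list[float] = field(default_factory=list)
    channels: tuple[str, ...] = (BRIGHTFIELD,)

    def predict_scores(self, crops) -> np.ndarray:
        x = _prepare(stack_crops(crops, self.channels), self.config, self.channels)
        return self.net.predict_proba(x)[0][:, 1]

    def predict(self, crop) -> tuple[bool, float]:
        """(is_outlier, outlier probability) for one crop."""
        score = float(self.predict_scores([crop])[0])
        return score > 0.5, score

    def save(self, path: str | Path) -> None:
        _save_model(self, path, kind="outlier")

    @classmethod
    def load(cls, path: str | Path) -> "OutlierModel":
        return _load_model(path, expect_kind="outlier")


@dataclass
class CellCountModel:
    """Four-headed live/dead × effector/target count classifier."""

    net: ConvNet
    config: TrainingConfig
    training_log: list[float] = field(default_factory=list)
    channels: tuple[str, ...] = DEFAULT_CHANNELS

    def predict_counts_array(self, crops) -> np.ndarray:
        """(N, 4) argmax counts in :data:`HEADS` order."""
        x = _prepare(stack_crops(crops, self.channels), self.config, self.channels)
        probas = self.net.predict_proba(x)
        return np.stack([p.argmax(axis=1) for p in probas], axis=1)

    def predict(self, crop) -> CountPrediction:
        x = _prepare(stack_crops([crop], self.channels), self.config, self.channels)
        probas = self.net.predict_proba(x)
        counts = [int(p[0].argmax()) for p in probas]
        scores = {h: p[0] for h, p in zip(HEADS, probas)}
        return CountPrediction(*counts, scores=scores)

    def save(self, path: str | Path) -> None:
        _save_model(self, path, kind="counts")

    @classmethod
    def load(cls, path: str | Path) -> "CellCountModel":
        return _load_model(path, expect_kind="counts")


def train_outlier_model(crops, labels, config: TrainingConfig) -> OutlierModel:
    """Train the binary outlier-exclusion model on brightfield crops.

    ``labels`` are booleans (True = outlier).  Both classes must be present.
    """
    labels = np.asarray(labels, dtype=int)
    if len(np.unique(labels)) < 2:
        raise ValueError("outlier training requires both classes in the labels")
    x = _prepare(stack_crops(crops, (BRIGHTFIELD,)), config, (BRIGHTFIELD,))
    rng = np.random.default_rng(config.seed)
    net = ConvNet(
        in_channels=1,
        input_size=x.shape[-1],
        conv_channels=config.conv_channels,
        head_classes=(2,),
        rng=rng,
        shared_trunk=True,
    )
    log = _train_net(net, x, [labels], config, rng)
    return OutlierModel(net=net, config=config, training_log=log)


def train_cellcount_model(crops, counts, config: TrainingConfig) -> CellCountModel:
    """Train the four-headed count model on multi-channel crops.

    ``counts`` is (N, 4) true counts in :data:`HEADS` order; each head must
    see at least two distinct classes.
    """
    labels = counts_to_labels(counts, config.c_max)
    for k, head in enumerate(HEADS):
        if len(np.unique(labels[:, k])) < 2:
            raise ValueError(f"head {head!r} sees a single class; cannot train")
    x = _prepare(stack_crops(crops, DEFAULT_CHANNELS), config, DEFAULT_CHANNELS)
    rng = np.random.default_rng(config.seed)
    net = ConvNet(
        in_channels=len(DEFAULT_CHANNELS),
        input_size=x.shape[-1],
        conv_channels=config.conv_channels,
        head_classes=(config.c_max + 1,) * 4,
        rng=rng,
        shared_trunk=config.shared_trunk,
    )
    log = _train_net(net, x, [labels[:, k] for k in range(4)], config, rng)
    return CellCountModel(net=net, config=config, training_log=log)


def accuracy_report(predictions, truths, c_max: int = 5):
    """Exact-match accuracy per head, overall and stratified by true count.

    ``predictions``/``truths`` are (N, 4) arrays (or CountPrediction lists)
    in :data:`HEADS` order.  Returns ``(overall, stratified)``: a dict head →
    accuracy and a tidy DataFrame (head, true_count, n, accuracy).
    """
    if hasattr(predictions, "__len__") and len(predictions) and isinstance(
        predictions[0], CountPrediction
    ):
        predictions = np.stack([p.as_array() for p in predictions])
    pred = np.asarray(predictions, dtype=int)
    true = counts_to_labels(truths, c_max)
    if len(pred) == 0 or len(pred) != len(true):
        raise ValueError("predictions and truths must be equal-length and non-empty")
    overall = {h: float((pred[:, k] == true[:, k]).mean()) for k, h in enumerate(HEADS)}
    rows = []
    for k, h in enumerate(HEADS):
        for cls in range(c_max + 1):
            sel = true[:, k] == cls
            if sel.any():
                rows.append(
                    dict(
                        head=h,
                        true_count=cls,
                        n=int(sel.sum()),
                        accuracy=float((pred[sel, k] == cls).mean()),
                    )
                )
    return overall, pd.DataFrame(rows, columns=["head", "true_count", "n", "accuracy"])


def relative_count_error(true: int, predicted: int) -> float:
    """|predicted − true| / true as a percentage; ``nan`` when true = 0.

    The undefined true-zero case is returned as ``nan`` so it drops out of
    ``nanmean``-style aggregates.
    """
    if true < 0 or predicted < 0:
        raise ValueError("counts must be non-negative")
    if true == 0:
        return float("nan")
    return abs(predicted - true) / true * 100.0


# -- checkpoints ------------------------------------------------------------

def _save_model(model, path: str | Path, kind: str) -> None:
    meta = dict(
        kind=kind,
        channels=list(model.channels),
        training_log=model.training_log,
        config=model.config.__dict__.copy(),
    )
    meta["config"]["conv_channels"] = list(model.config.conv_channels)
    np.savez(
        path,
        meta=np.frombuffer(json.dumps(meta, default=float).encode(), dtype=np.uint8),
        **model.net.state_arrays(),
    )


def _load_model(path: str | Path, expect_kind: str):
    with np.load(path) as data:
        meta = json.loads(bytes(data["meta"].tobytes()).decode())
        if meta["kind"] != expect_kind:
            raise ValueError(f"checkpoint is a {meta['kind']!r} model, not {expect_kind!r}")
        cfg_dict = meta["config"]
        cfg_dict["conv_channels"] = tuple(cfg_dict["conv_channels"])
        for int_key in ("crop_size", "downsample", "c_max", "epochs", "batch_size", "seed"):
            cfg_dict[int_key] = int(cfg_dict[int_key])
        config = TrainingConfig(**cfg_dict)
        rng = np.random.default_rng(config.seed)
        size = config.crop_size // config.downsample
        if expect_kind == "outlier":
            net = ConvNet(1, size, config.conv_channels, (2,), rng, shared_trunk=True)
            model = OutlierModel(net=net, config=config, training_log=meta["training_log"])
        else:
            net = ConvNet(
                len(DEFAULT_CHANNELS),
                size,
                config.conv_channels,
                (config.c_max + 1,) * 4,
                rng,
                shared_trunk=config.shared_trunk,
            )
            model = CellCountModel(net=net, config=config, training_log=meta["training_log"])
        net.load_state_arrays({k: data[k] for k in data.files if k != "meta"})
    return model
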