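"""Artifact-rejection and spkHFO classifiers: training protocol, metrics,
pruning and event prediction.

Two binary CNNs act in cascade: the artifact model sees the time-frequency
image alone (1 input channel) and separates artifacts from real HFOs; the
spk model sees the time-frequency and amplitude-coding images stacked
(2 channels) and splits real HFOs into spkHFO vs non-spkHFO.  Events whose
window touches the first or last second of the recording are labelled
artifact regardless of model output, since recording edges generate
filter/detector artifacts.

Training follows a fixed protocol: Adam (lr 3e-4), batch size 128, 30
epochs, checkpoint = epoch with minimum validation loss, optional
time-domain augmentation on the training split only.  Evaluation uses
5-fold cross-validation: each sample serves in exactly one test fold; the
remaining 80% splits 7:1 into train/validation (70%/10% of the whole set).
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field, asdict
from typing import Callable

import numpy as np
import pandas as pd

from . import nn
from .events import EventSet
from .features import GEOMETRIES, ImageGeometry, event_images
from .io import Recording


@dataclass(frozen=True)
class ModelSpec:
    """Architecture contract: input channels/size and block widths."""

    input_channels: int = 1  # 1 = artifact model, 2 = spk model
    input_size: int = 128
    conv_widths: tuple[int, ...] = (8, 16, 32)
    head_width: int = 32
    pools: tuple[int, ...] = (4, 4, 2)

    def __post_init__(self) -> None:
        if self.input_channels not in (1, 2):
            raise ValueError("input_channels must be 1 or 2")
        if len(self.pools) != len(self.conv_widths):
            raise ValueError("need one pool factor per conv block")
        side = self.input_size
        for p in self.pools:
            if side % p:
                raise ValueError(f"input size {self.input_size} incompatible with pools")
            side //= p


@dataclass(frozen=True)
class TrainConfig:
    """The training protocol's knobs."""

    epochs: int = 30
    batch_size: int = 128
    learning_rate: float = 3e-4
    folds: int = 5
    train_frac: float = 0.70
    val_frac: float = 0.10
    seed: int = 0
    augment_flip_prob: float = 0.5
    max_shift_ms: float = 50.0

    def __post_init__(self) -> None:
        if self.folds < 2:
            raise ValueError("folds must be >= 2")
        test_frac = 1.0 - self.train_frac - self.val_frac
        if not np.isclose(self.train_frac + self.val_frac + test_frac, 1.0):
            raise ValueError("split fractions must sum to 1")
        if test_frac <= 0:
            raise ValueError("train + val fractions leave no test data")


def build_model(spec: ModelSpec, seed: int = 0) -> nn.Network:
    """Compact convolutional classifier; deterministic given the seed."""
    rng = np.random.default_rng(seed)
    layers: list[nn.Layer] = []
    c_in = spec.input_channels
    side = spec.input_size
    for width, pool in zip(spec.conv_widths, spec.pools):
        layers += [nn.Conv2d(c_in, width, rng=rng), nn.ReLU(), nn.MaxPool(pool)]
        c_in = width
        side //= pool
    layers += [
        nn.Flatten(),
        nn.Dense(c_in * side * side, spec.head_width, rng=rng),
        nn.ReLU(),
        nn.Dense(spec.head_width, 2, rng=rng),
    ]
    return nn.Network(layers, input_shape=(spec.input_channels,
                                           spec.input_size, spec.input_size))


def count_macs(model: nn.Network, input_shape: tuple | None = None) -> int:
    return nn.count_macs(model, input_shape)


# ---------------------------------------------------------------------------
# training


def train(x: np.ndarray, y: np.ndarray, config: TrainConfig,
          spec: ModelSpec | None = None,
          x_val: np.ndarray | None = None, y_val: np.ndarray | None = None,
          augment_fn: Callable[[np.ndarray, np.ndarray, np.random.Generator],
                               np.ndarray] | None = None,
          model: nn.Network | None = None) -> tuple[nn.Network, pd.DataFrame]:
    """Train a binary model; return the minimum-validation-loss checkpoint.

    ``augment_fn(x_batch, indices, rng) -> images`` is applied to training
    batches only, once per sample per epoch; validation data is never
    augmented.  ``history`` holds per-epoch train/val loss and val accuracy.
    """
    y = np.asarray(y, dtype=np.int64)
    if len(np.unique(y)) < 2:
        raise ValueError("training data must contain both classes")
    rng = np.random.default_rng(config.seed)
    if model is None:
        if spec is None:
            spec = ModelSpec(input_channels=x.shape[1], input_size=x.shape[2])
        model = build_model(spec, seed=config.seed)
    if x_val is None:
        # carve a validation split out of the provided data
        idx = rng.permutation(len(y))
        n_val = max(1, int(round(len(y) * config.val_frac)))
        val_idx, tr_idx = idx[:n_val], idx[n_val:]
        x, y, x_val, y_val = x[tr_idx], y[tr_idx], x[val_idx], y[val_idx]
    if len(y_val) == 0 or len(y) == 0:
        raise ValueError("empty train or validation split")

    opt = nn.Adam(model, lr=config.learning_rate)
    best_loss, best_state = np.inf, model.state_dict()
    rows = []
    for epoch in range(config.epochs):
        order = rng.permutation(len(y))
        train_losses = []
        for i in range(0, len(order), config.batch_size):
            batch = order[i:i + config.batch_size]
            xb = x[batch]
            if augment_fn is not None:
                xb = augment_fn(xb, batch, rng)
            train_losses.append(model.loss_and_grads(xb, y[batch]))
            opt.step()
        val_loss = model.evaluate_loss(x_val, y_val)
        val_acc = float((model.predict_proba(x_val).argmax(1) == y_val).mean())
        rows.append({"epoch": epoch, "train_loss": float(np.mean(train_losses)),
                     "val_loss": val_loss, "val_acc": val_acc})
        if val_loss < best_loss:
            best_loss = val_loss
            best_state = {k: v.copy() for k, v in model.state_dict().items()}
    model.load_state_dict(best_state)
    return model, pd.DataFrame(rows)


def compute_metrics(y_true: np.ndarray, y_pred: np.ndarray) -> dict[str, float]:
    """Precision, recall, accuracy and F1 for binary labels.

    Zero-denominator cases return NaN ("undefined", distinct from 0).
    """
    y_true = np.asarray(y_true).astype(np.int64)
    y_pred = np.asarray(y_pred).astype(np.int64)
    if y_true.shape != y_pred.shape:
        raise ValueError("label vectors must have equal length")
    tp = int(np.sum((y_true == 1) & (y_pred == 1)))
    fp = int(np.sum((y_true == 0) & (y_pred == 1)))
    fn = int(np.sum((y_true == 1) & (y_pred == 0)))
    tn = int(np.sum((y_true == 0) & (y_pred == 0)))
    precision = tp / (tp + fp) if tp + fp else float("nan")
    recall = tp / (tp + fn) if tp + fn else float("nan")
    accuracy = (tp + tn) / len(y_true) if len(y_true) else float("nan")
    if np.isnan(precision) or np.isnan(recall) or precision + recall == 0:
        f1 = float("nan")
    else:
        f1 = 2 * precision * recall / (precision + recall)
    return {"precision": precision, "recall": recall,
            "accuracy": accuracy, "f1": f1}


def fold_assignment(n: int, folds: int, seed: int) -> np.ndarray:
    """Shuffled fold index per sample; deterministic in (n, folds, seed)."""
    rng = np.random.default_rng(seed)
    idx = rng.permutation(n)
    assign = np.empty(n, dtype=np.int64)
    for f, chunk in enumerate(np.array_split(idx, folds)):
        assign[chunk] = f
    return assign


def cross_validate(x: np.ndarray, y: np.ndarray, config: TrainConfig,
                   spec: ModelSpec | None = None,
                   augment_fn=None) -> tuple[pd.DataFrame, pd.DataFrame]:
    """K-fold cross-validation following the 70/10/20 protocol.

    Returns (per-fold metric table, summary with mean and normal-based 95%
    confidence interval over folds).
    """
    y = np.asarray(y, dtype=np.int64)
    if len(y) < config.folds:
        raise ValueError("fewer samples than folds")
    assign = fold_assignment(len(y), config.folds, config.seed)
    rows = []
    for f in range(config.folds):
        test = assign == f
        rest = np.flatnonzero(~test)
        rng = np.random.default_rng(config.seed + 1000 + f)
        rest = rng.permutation(rest)
        # 70/10 of the whole set = 7/8 vs 1/8 of the remaining 80%
        n_val = int(round(len(y) * config.val_frac))
        val_idx, tr_idx = rest[:n_val], rest[n_val:]
        model, _ = train(x[tr_idx], y[tr_idx], config, spec=spec,
                         x_val=x[val_idx], y_val=y[val_idx],
                         augment_fn=augment_fn)
        pred = model.predict_proba(x[test]).argmax(1)
        rows.append({"fold": f, **compute_metrics(y[test], pred)})
    table = pd.DataFrame(rows)
    metrics = [c for c in table.columns if c != "fold"]
    k = len(table)
    summary = pd.DataFrame({
        "metric": metrics,
        "mean": [table[m].mean() for m in metrics],
        "ci95": [1.96 * table[m].std(ddof=1) / np.sqrt(k) for m in metrics],
    })
    return table, summary


# ---------------------------------------------------------------------------
# pruning


def prune(model: nn.Network, x: np.ndarray, y: np.ndarray,
          iterations: int = 5000, fine_tune_every: int = 250,
          fine_tune_epochs: int = 5, config: TrainConfig | None = None,
          min_channels: int = 2) -> nn.Network:
    """Iterative structured pruning with periodic fine-tuning.

    Each iteration removes the convolution channel with the smallest filter
    norm (dependencies propagated to the consumer layer); every
    ``fine_tune_every`` iterations the model is fine-tuned for
    ``fine_tune_epochs`` epochs on (x, y).  Stops early when no channel can
    be removed without dropping below ``min_channels``.  The returned model
    has strictly fewer MACs and the same input/output contract.
    """
    config = config or TrainConfig(epochs=fine_tune_epochs)
    macs_before = nn.count_macs(model)
    done = 0
    for it in range(1, iterations + 1):
        try:
            li, ci = nn.smallest_channel(model, min_channels=min_channels)
        except ValueError:
            break
        nn.prune_channel(model, li, ci)
        done += 1
        if it % fine_tune_every == 0:
            ft = TrainConfig(epochs=fine_tune_epochs,
                             batch_size=config.batch_size,
                             learning_rate=config.learning_rate,
                             seed=config.seed + it)
            train(x, y, ft, model=model)
    if done == 0:
        raise ValueError("nothing to prune at the requested minimum width")
    # final fine-tune so the last removals are compensated
    ft = TrainConfig(epochs=fine_tune_epochs, batch_size=config.batch_size,
                     learning_rate=config.learning_rate, seed=config.seed + 7)
    train(x, y, ft, model=model)
    assert nn.count_macs(model) < macs_before
    return model


# ---------------------------------------------------------------------------
# event prediction


def predict_events(rec: Recording, events: EventSet,
                   artifact_model: nn.Network, spk_model: nn.Network | None = None,
                   geometry: ImageGeometry = GEOMETRIES[128],
                   edge_seconds: float = 1.0, batch_size: int = 128) -> EventSet:
    """Label every event artifact / spkHFO / non-spkHFO.

    The artifact model (time-frequency input) rejects artifacts; surviving
    events go to the spk model (time-frequency + amplitude coding).  Events
    within ``edge_seconds`` of either recording edge are labelled artifact
    unconditionally.
    """
    if not len(events):
        return EventSet([], sample_rate=events.sample_rate, meta=dict(events.meta))
    fs = rec.sample_rate
    edge = int(round(edge_seconds * fs))
    tf_list, ac_list = [], []
    for ev in events:
        tf, ac = event_images(rec, ev, geometry=geometry)
        tf_list.append(tf)
        ac_list.append(ac)
    tf_arr = np.stack(tf_list)[:, None].astype(np.float32)
    p_art = artifact_model.predict_proba(tf_arr, batch_size=batch_size)[:, 1]

    labelled = []
    spk_input, spk_slots = [], []
    for i, ev in enumerate(events):
        at_edge = ev.start < edge or ev.end > rec.n_samples - edge
        if at_edge or p_art[i] >= 0.5:
            prob = 1.0 if at_edge else float(p_art[i])
            labelled.append(ev.with_label("artifact", prob))
        else:
            labelled.append(ev)  # placeholder, resolved below
            spk_slots.append(i)
            spk_input.append(np.stack([tf_list[i], ac_list[i]]))
    if spk_slots:
        if spk_model is not None:
            p_spk = spk_model.predict_proba(
                np.stack(spk_input).astype(np.float32), batch_size=batch_size)[:, 1]
        else:
            p_spk = np.full(len(spk_slots), np.nan)
        for j, i in enumerate(spk_slots):
            if spk_model is None:
                labelled[i] = labelled[i].with_label("non-spkHFO", None)
            elif p_spk[j] >= 0.5:
                labelled[i] = labelled[i].with_label("spkHFO", float(p_spk[j]))
            else:
                labelled[i] = labelled[i].with_label("non-spkHFO", float(1 - p_spk[j]))
    return EventSet(labelled, sample_rate=events.sample_rate,
                    meta={**events.meta, "classified": True})


# ---------------------------------------------------------------------------
# weight persistence


def save_model(path: str | os.PathLike, model: nn.Network, spec: ModelSpec,
               geometry: ImageGeometry = GEOMETRIES[128]) -> None:
    """Weights to NPZ plus a JSON sidecar recording the spec and geometry."""
    path = os.fspath(path)
    np.savez(path, **model.state_dict())
    sidecar = {
        "spec": asdict(spec),
        "geometry": asdict(geometry),
        "widths": [l.out_ch for l in model.layers if isinstance(l, nn.Conv2d)],
        "head": [l.w.shape for l in model.layers if isinstance(l, nn.Dense)][0][1]
                if any(isinstance(l, nn.Dense) for l in model.layers) else None,
    }
    with open(path + ".json", "w") as fh:
        json.dump(sidecar, fh, indent=2, default=list)


def load_model(path: str | os.PathLike) -> tuple[nn.Network, ModelSpec, ImageGeometry]:
    path = os.fspath(path)
    with open(path + ".json") as fh:
        sidecar = json.load(fh)
    sd = sidecar["spec"]
    spec = ModelSpec(input_channels=sd["input_channels"], input_size=sd["input_size"],
                     conv_widths=tuple(sidecar["widths"]),
                     head_width=sd["head_width"], pools=tuple(sd["pools"]))
    geometry = ImageGeometry(**sidecar["geometry"])
    model = build_model(spec)
    with np.load(path) as z:
        model.load_state_dict({k: z[k] for k in z.files})
    return model, spec, geometry
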