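"""CNN classifiers over delta x C windows, training and grouped cross-validation.

Three configurable families are provided:

* ``vgg_like`` — stacks of 3-wide convolutions with max pooling after every
  second conv, widths 32-32-64-64-128-128-256 truncated to ``depth - 1``
  conv layers plus the final fully-connected softmax layer (depth counts
  conv + FC weight layers);
* ``resnet`` — an initial conv followed by residual conv pairs with pooling
  between stages;
* ``densenet`` — three densely-connected blocks separated by 1x1-conv +
  pool transitions.

``filter_mode='1D'`` uses (3 x 1) kernels and (2 x 1) pooling exclusively:
the network never mixes adjacent m/z channels, reflecting that ion channels
are only weakly correlated locally, unlike image pixels.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
from sklearn.model_selection import GroupKFold

from ..dataset import VocDataPoint
from ..errors import ConfigError, DataError, ValidationError
from .layers import (Adam, AvgPoolRTFlatten, Conv, Dense, DenseLayer, Layer,
                     MaxPool, Param, ReLU, ResidualBlock, softmax,
                     softmax_cross_entropy)

_VGG_WIDTHS = (32, 32, 64, 64, 128, 128, 256)


@dataclass
class ModelConfig:
    family: str = "vgg_like"           # vgg_like | resnet | densenet
    depth: int = 8
    filter_mode: str = "1D"            # 1D | 2D
    n_classes: int = 31
    widths: tuple[int, ...] | None = None   # conv widths; None -> family default
    growth: int = 12                   # densenet growth rate
    epochs: int = 20
    batch_size: int = 64
    learning_rate: float = 1e-3
    val_fraction: float = 0.0          # >0 enables early stopping on val accuracy
    patience: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.family not in ("vgg_like", "resnet", "densenet"):
            raise ConfigError(f"unknown model family {self.family!r}")
        if self.filter_mode not in ("1D", "2D"):
            raise ConfigError(f"filter_mode must be '1D' or '2D'")
        if self.n_classes < 2:
            raise ConfigError("n_classes must be >= 2")
        if self.family == "vgg_like" and self.depth not in (4, 6, 8):
            raise ConfigError("vgg_like depth must be 4, 6 or 8")
        if self.family == "resnet" and (self.depth < 4 or (self.depth - 2) % 2):
            raise ConfigError("resnet depth must be even and >= 4")
        if self.family == "densenet" and (self.depth < 7 or (self.depth - 4) % 3):
            raise ConfigError("densenet depth must be 4 + 3k, k >= 1")


class CNN:
    """A feed-forward stack of layers ending in a linear softmax head."""

    def __init__(self, layers: list[Layer], config: ModelConfig):
        self.layers = layers
        self.config = config

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, train)
        return x

    def backward(self, dlogits: np.ndarray) -> None:
        d = dlogits
        for layer in reversed(self.layers):
            d = layer.backward(d)

    def params(self) -> list[Param]:
        return [p for layer in self.layers for p in layer.params()]

    def zero_cache(self) -> None:
        for layer in self.layers:
            layer.zero_cache()

    def predict_proba(self, windows: np.ndarray, batch_size: int = 256) -> np.ndarray:
        """Class probabilities for (n, delta, C) windows in [0, 1]."""
        x = np.asarray(windows, dtype=np.float32)
        if x.ndim != 3:
            raise ValidationError(f"expected (n, delta, C) windows, got {x.shape}")
        out = np.empty((x.shape[0], self.config.n_classes), dtype=np.float32)
        for i in range(0, x.shape[0], batch_size):
            logits = self.forward(x[i:i + batch_size, None])
            out[i:i + batch_size] = softmax(logits)
        return out

    def conv_layers(self) -> list[Conv]:
        found: list[Conv] = []
        for layer in self.layers:
            if isinstance(layer, Conv):
                found.append(layer)
            elif hasattr(layer, "sublayers"):
                found.extend(l for l in layer.sublayers() if isinstance(l, Conv))
        return found

    def pool_layers(self) -> list[MaxPool]:
        return [l for l in self.layers if isinstance(l, MaxPool)]


def build_model(cfg: ModelConfig) -> CNN:
    """Construct an untrained network for the requested (family, depth, filters)."""
    rng = np.random.default_rng(cfg.seed)
    km = 1 if cfg.filter_mode == "1D" else 3
    pm = 1 if cfg.filter_mode == "1D" else 2
    layers: list[Layer] = []

    if cfg.family == "vgg_like":
        n_conv = cfg.depth - 1
        widths = cfg.widths or _VGG_WIDTHS[:n_conv]
        if len(widths) != n_conv:
            raise ConfigError(f"vgg_like depth {cfg.depth} needs {n_conv} widths")
        c_in = 1
        for i, w in enumerate(widths):
            layers += [Conv(c_in, w, 3, km, rng), ReLU()]
            c_in = w
            if i % 2 == 1:
                layers.append(MaxPool(2, pm))
        feat = c_in
    elif cfg.family == "resnet":
        n_blocks = (cfg.depth - 2) // 2
        widths = cfg.widths or tuple(min(16 * 2 ** (i // 2), 128)
                                     for i in range(n_blocks))
        if len(widths) != n_blocks:
            raise ConfigError(f"resnet depth {cfg.depth} needs {n_blocks} widths")
        c_in = widths[0]
        layers += [Conv(1, c_in, 3, km, rng), ReLU()]
        for i, w in enumerate(widths):
            layers.append(ResidualBlock(c_in, w, km, rng))
            c_in = w
            if i % 2 == 1:
                layers.append(MaxPool(2, pm))
        feat = c_in
    else:  # densenet
        per_block = (cfg.depth - 4) // 3
        c_in = 2 * cfg.growth
        layers += [Conv(1, c_in, 3, km, rng), ReLU()]
        for b in range(3):
            for _ in range(per_block):
                layers.append(DenseLayer(c_in, cfg.growth, km, rng))
                c_in += cfg.growth
            if b < 2:   # transition: 1x1 conv halving channels + pool
                c_out = c_in // 2
                layers += [Conv(c_in, c_out, 1, 1, rng), ReLU(), MaxPool(2, pm)]
                c_in = c_out
        feat = c_in

    layers += [AvgPoolRTFlatten(), Dense(None, cfg.n_classes, rng)]
    return CNN(layers, cfg)


@dataclass
class TrainedModel:
    """A fitted network plus its config, class count and training log."""

    model: CNN
    config: ModelConfig
    history: list[dict] = field(default_factory=list)

    @property
    def n_classes(self) -> int:
        return self.config.n_classes

    def predict_proba(self, windows: np.ndarray) -> np.ndarray:
        return self.model.predict_proba(windows)

    def save(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        params = self.model.params()
        if not params or self.model.layers[-1].W is None:
            raise ValueError("cannot save a model before its head is materialised")
        np.savez_compressed(directory / "params.npz",
                            **{f"p{i}": p.val for i, p in enumerate(params)})
        (directory / "config.json").write_text(json.dumps(
            {"config": _config_dict(self.config), "history": self.history,
             "head_n_in": int(self.model.layers[-1].W.val.shape[0])}, indent=1))

    @classmethod
    def load(cls, directory: str | Path) -> "TrainedModel":
        directory = Path(directory)
        blob = json.loads((directory / "config.json").read_text())
        cfgd = blob["config"]
        if cfgd.get("widths") is not None:
            cfgd["widths"] = tuple(cfgd["widths"])
        cfg = ModelConfig(**cfgd)
        model = build_model(cfg)
        model.layers[-1].materialise(int(blob["head_n_in"]))
        with np.load(directory / "params.npz") as data:
            for i, p in enumerate(model.params()):
                p.val[...] = data[f"p{i}"]
        return cls(model=model, config=cfg, history=blob["history"])


def _config_dict(cfg: ModelConfig) -> dict:
    d = asdict(cfg)
    if d.get("widths") is not None:
        d["widths"] = list(d["widths"])
    return d


def _to_arrays(dataset: Sequence[VocDataPoint], n_classes: int
               ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    if not dataset:
        raise DataError("empty training dataset")
    y = np.array([p.label for p in dataset])
    if y.min() < 0 or y.max() >= n_classes:
        raise DataError(f"labels must be in 0..{n_classes - 1}, "
                        f"got range [{y.min()}, {y.max()}]")
    X = np.stack([p.window for p in dataset]).astype(np.float32)
    if X.min() < 0.0 or X.max() > 1.0 + 1e-6:
        raise DataError("windows must be min-max normalised to [0, 1]")
    groups = np.array([p.participant_id for p in dataset])
    return X, y, groups


def _accuracy(model: CNN, X: np.ndarray, y: np.ndarray) -> float:
    probs = model.predict_proba(X)
    return float((probs.argmax(axis=1) == y).mean())


def train_model(model: CNN, dataset: Sequence[VocDataPoint],
                cfg: ModelConfig | None = None) -> TrainedModel:
    """Minimise softmax cross-entropy with Adam; deterministic under cfg.seed.

    When ``val_fraction > 0`` a random split is held out and training stops
    early once validation accuracy has not improved for ``patience`` epochs
    (best parameters are restored).
    """
    cfg = cfg or model.config
    X, y, _ = _to_arrays(dataset, cfg.n_classes)
    rng = np.random.default_rng(cfg.seed)

    n_val = int(round(cfg.val_fraction * len(X))) if cfg.val_fraction > 0 else 0
    perm = rng.permutation(len(X))
    val_idx, tr_idx = perm[:n_val], perm[n_val:]
    Xtr, ytr = X[tr_idx, None], y[tr_idx]
    Xval, yval = X[val_idx], y[val_idx]

    model.forward(Xtr[:1])          # materialise the lazy head
    opt = Adam(model.params(), lr=cfg.learning_rate)
    trained = TrainedModel(model=model, config=cfg)
    best_val, best_params, stale = -1.0, None, 0
    for epoch in range(cfg.epochs):
        order = rng.permutation(len(Xtr))
        total_loss, total_correct = 0.0, 0
        for i in range(0, len(order), cfg.batch_size):
            idx = order[i:i + cfg.batch_size]
            xb, yb = Xtr[idx], ytr[idx]
            logits = model.forward(xb, train=True)
            loss, dlogits = softmax_cross_entropy(logits, yb)
            opt.zero_grad()
            model.backward(dlogits)
            opt.step()
            total_loss += loss * len(idx)
            total_correct += int((logits.argmax(axis=1) == yb).sum())
        model.zero_cache()
        entry = {"epoch": epoch, "loss": total_loss / len(Xtr),
                 "accuracy": total_correct / len(Xtr)}
        if n_val:
            entry["val_accuracy"] = _accuracy(model, Xval, yval)
            if entry["val_accuracy"] > best_val:
                best_val, stale = entry["val_accuracy"], 0
                best_params = [p.val.copy() for p in model.params()]
            else:
                stale += 1
        trained.history.append(entry)
        if n_val and stale >= cfg.patience:
            break
    if best_params is not None:
        for p, v in zip(model.params(), best_params):
            p.val[...] = v
    return trained


def cross_validate(dataset: Sequence[VocDataPoint], cfg: ModelConfig,
                   k: int = 5) -> tuple[float, float, list[float]]:
    """Participant-grouped k-fold CV; no participant spans train and validation."""
    X, y, groups = _to_arrays(dataset, cfg.n_classes)
    n_participants = len(set(groups.tolist()))
    if n_participants < k:
        raise ConfigError(f"need >= {k} participants for {k}-fold grouped CV, "
                          f"got {n_participants}")
    accs: list[float] = []
    for fold, (tr, va) in enumerate(GroupKFold(n_splits=k).split(X, y, groups)):
        assert not set(groups[tr]) & set(groups[va]), "participant leakage"
        model = build_model(cfg)
        train_model(model, [dataset[i] for i in tr], cfg)
        accs.append(_accuracy(model, X[va], y[va]))
    return float(np.mean(accs)), float(np.std(accs)), accs


def classify_batch(model: TrainedModel | CNN, windows: Sequence[np.ndarray] | np.ndarray
                   ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Labels (argmax; ties -> lowest index), confidences (max) and distributions."""
    net = model.model if isinstance(model, TrainedModel) else model
    x = np.stack(list(windows)) if not isinstance(windows, np.ndarray) else windows
    probs = net.predict_proba(x)
    return probs.argmax(axis=1), probs.max(axis=1), probs
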