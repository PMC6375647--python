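"""The 3D-CNN pocket classifier: architecture, training, cross-validation.

The default architecture mirrors the VoxNet-lineage network used for pocket
classification: two valid stride-1 convolutions (64 filters each, kernels 5
then 3) with leaky-ReLU activations — a 32-per-side input therefore leaves
the second convolution as 64 feature maps of side 26 — followed by dropout,
2x max pooling, dropout, one hidden dense layer and a softmax output.
Training uses Adam (learning rate 1e-5, decay 0, beta1 0.9, beta2 0.999),
categorical cross-entropy, batch size 32 and 50 epochs by default.

Cross-validation comes in two protocols: stratified k-fold (default k=5) and
leave-one-group-out, which holds out one annotated group (e.g. one enzyme
family) per round.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

import h5py
import numpy as np
import pandas as pd
from sklearn.model_selection import LeaveOneGroupOut, StratifiedKFold

from . import nn


@dataclass
class NetworkConfig:
    input_side: int = 32
    input_channels: int = 14
    conv_filters: tuple[int, int] = (64, 64)
    conv_kernels: tuple[int, int] = (5, 3)
    leaky_alpha: float = 0.1
    dropout1: float = 0.2
    dropout2: float = 0.4
    dense_width: int = 128
    n_classes: int = 3
    head: str = "fc"          # "fc" (default) or "gap" (GAP + linear, plain-CAM capable)

    @property
    def conv_output_side(self) -> int:
        return self.input_side - sum(k - 1 for k in self.conv_kernels)

    #: index in the layer stack of the activation after the last convolution,
    #: i.e. the feature maps that class-activation mapping weighs.
    CAM_LAYER_INDEX = 3


@dataclass
class TrainConfig:
    learning_rate: float = 1e-5
    decay: float = 0.0
    beta1: float = 0.9
    beta2: float = 0.999
    batch_size: int = 32
    epochs: int = 50
    standardize: bool = False
    seed: int = 0


def build_network(cfg: NetworkConfig, rng: np.random.Generator | None = None) -> nn.Network:
    """Instantiate the (untrained) network for a given configuration."""
    if cfg.conv_output_side <= 0:
        raise ValueError(
            f"input side {cfg.input_side} too small for kernels {cfg.conv_kernels}")
    if rng is None:
        rng = np.random.default_rng(0)
    f1, f2 = cfg.conv_filters
    k1, k2 = cfg.conv_kernels
    layers: list[nn.Layer] = [
        nn.Conv3D(cfg.input_channels, f1, k1, rng),
        nn.LeakyReLU(cfg.leaky_alpha),
        nn.Conv3D(f1, f2, k2, rng),
        nn.LeakyReLU(cfg.leaky_alpha),
    ]
    if cfg.head == "gap":
        layers += [nn.GlobalAvgPool(), nn.Dense(f2, cfg.n_classes, rng)]
    elif cfg.head == "fc":
        pooled = cfg.conv_output_side // 2
        layers += [
            nn.Dropout(cfg.dropout1),
            nn.MaxPool3D(2),
            nn.Dropout(cfg.dropout2),
            nn.Flatten(),
            nn.Dense(pooled**3 * f2, cfg.dense_width, rng),
            nn.LeakyReLU(cfg.leaky_alpha),
            nn.Dense(cfg.dense_width, cfg.n_classes, rng),
        ]
    else:
        raise ValueError(f"unknown head {cfg.head!r}")
    return nn.Network(layers)


@dataclass
class TrainedModel:
    """A fitted network plus everything needed to reproduce its predictions."""

    network: nn.Network
    config: NetworkConfig
    train_config: TrainConfig
    history: pd.DataFrame                      # epoch, loss, accuracy
    channel_mean: np.ndarray | None = None     # standardization stats (per channel)
    channel_std: np.ndarray | None = None
    class_names: tuple[str, ...] | None = None

    def _prepare(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, float)
        if x.ndim == 4:
            x = x[None]
        if x.shape[1:] != (self.config.input_side,) * 3 + (self.config.input_channels,):
            raise ValueError(
                f"input shape {x.shape[1:]} does not match model "
                f"{(self.config.input_side,) * 3 + (self.config.input_channels,)}")
        if self.channel_mean is not None:
            x = (x - self.channel_mean) / self.channel_std
        return x

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        return self.network.predict_proba(self._prepare(x))


def predict(model: TrainedModel, x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Class probabilities and argmax labels for one tensor or a batch."""
    probs = model.predict_proba(x)
    return probs, probs.argmax(axis=-1)


def train(
    x: np.ndarray,
    labels: np.ndarray,
    net_cfg: NetworkConfig | None = None,
    train_cfg: TrainConfig | None = None,
    class_names: tuple[str, ...] | None = None,
) -> TrainedModel:
    """Fit the network on (tensor, label) pairs.

    ``x`` is (n_samples, side, side, side, channels); integer labels must
    cover at least two classes.  Fully deterministic for a fixed seed.
    """
    x = np.asarray(x, float)
    labels = np.asarray(labels, int)
    if x.ndim != 5:
        raise ValueError("expected a (n, side, side, side, channels) array")
    if len(x) != len(labels):
        raise ValueError("sample/label count mismatch")
    if len(np.unique(labels)) < 2:
        raise ValueError("training requires at least two classes")
    net_cfg = net_cfg or NetworkConfig(input_side=x.shape[1], input_channels=x.shape[-1])
    train_cfg = train_cfg or TrainConfig()

    mean = std = None
    if train_cfg.standardize:
        mean = x.mean(axis=(0, 1, 2, 3))
        std = x.std(axis=(0, 1, 2, 3))
        std[std == 0] = 1.0
        x = (x - mean) / std

    rng = np.random.default_rng(train_cfg.seed)
    net = build_network(net_cfg, rng)
    opt = nn.Adam(net.params, lr=train_cfg.learning_rate, decay=train_cfg.decay,
                  beta1=train_cfg.beta1, beta2=train_cfg.beta2)
    history = []
    n = len(x)
    for epoch in range(train_cfg.epochs):
        order = rng.permutation(n)
        losses = []
        for start in range(0, n, train_cfg.batch_size):
            batch = order[start:start + train_cfg.batch_size]
            loss = net.train_step(x[batch], labels[batch], rng)
            opt.step(net.grads)
            losses.append(loss)
        probs = net.predict_proba(x)
        acc = float((probs.argmax(axis=1) == labels).mean())
        history.append((epoch + 1, float(np.mean(losses)), acc))
    return TrainedModel(net, net_cfg, train_cfg,
                        pd.DataFrame(history, columns=["epoch", "loss", "accuracy"]),
                        mean, std, class_names)


@dataclass
class CVReport:
    """Out-of-fold predictions plus per-class metric summaries."""

    predictions: pd.DataFrame     # sample, fold, true, prob_<c>...
    metrics: pd.DataFrame         # class, ACC, PPV, TNR, TPR, FPR, MCC, AUC
    seed: int
    protocol: str

    @property
    def n_classes(self) -> int:
        return sum(c.startswith("prob_") for c in self.predictions.columns)


def _fit_and_score(x, labels, train_idx, test_idx, fold, net_cfg, train_cfg, rows):
    model = train(x[train_idx], labels[train_idx], net_cfg, train_cfg)
    probs = model.predict_proba(x[test_idx])
    for sample, true, p in zip(test_idx, labels[test_idx], probs):
        rows.append((int(sample), fold, int(true), *map(float, p)))


def _report(rows, n_classes, seed, protocol) -> CVReport:
    from .evaluation import summarize_predictions

    cols = ["sample", "fold", "true"] + [f"prob_{c}" for c in range(n_classes)]
    preds = pd.DataFrame(rows, columns=cols).sort_values("sample").reset_index(drop=True)
    return CVReport(preds, summarize_predictions(preds), seed, protocol)


def crossvalidate(
    x: np.ndarray,
    labels: np.ndarray,
    k: int = 5,
    seed: int = 0,
    net_cfg: NetworkConfig | None = None,
    train_cfg: TrainConfig | None = None,
) -> CVReport:
    """Stratified k-fold cross-validation; every sample is predicted exactly once."""
    labels = np.asarray(labels, int)
    if k > len(labels):
        raise ValueError(f"k={k} exceeds dataset size {len(labels)}")
    if train_cfg is None:
        train_cfg = TrainConfig(seed=seed)
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    rows: list = []
    for fold, (tr, te) in enumerate(skf.split(np.zeros(len(labels)), labels)):
        _fit_and_score(x, labels, tr, te, fold, net_cfg, train_cfg, rows)
    return _report(rows, len(np.unique(labels)), seed, f"stratified_{k}fold")


def logo_crossvalidate(
    x: np.ndarray,
    labels: np.ndarray,
    groups: np.ndarray,
    seed: int = 0,
    net_cfg: NetworkConfig | None = None,
    train_cfg: TrainConfig | None = None,
) -> CVReport:
    """Leave-one-group-out CV: one round per distinct group annotation."""
    labels = np.asarray(labels, int)
    groups = np.asarray(groups)
    if len(np.unique(groups)) < 2:
        raise ValueError("leave-one-group-out needs at least two groups")
    if train_cfg is None:
        train_cfg = TrainConfig(seed=seed)
    rows: list = []
    for fold, (tr, te) in enumerate(LeaveOneGroupOut().split(x, labels, groups)):
        _fit_and_score(x, labels, tr, te, fold, net_cfg, train_cfg, rows)
    return _report(rows, len(np.unique(labels)), seed, "leave_one_group_out")


def read_manifest(path) -> pd.DataFrame:
    """Dataset manifest CSV: columns id, voxel_path, label[, group]."""
    df = pd.read_csv(path)
    required = {"id", "voxel_path", "label"}
    if not required.issubset(df.columns):
        raise ValueError(f"manifest must have columns {sorted(required)}")
    return df


def save_model(path, model: TrainedModel) -> None:
    """Persist weights (HDF5) plus JSON-encoded configuration."""
    with h5py.File(path, "w") as fh:
        cfg = {"network": asdict(model.config), "training": asdict(model.train_config)}
        if model.class_names:
            cfg["class_names"] = list(model.class_names)
        fh.attrs["config"] = json.dumps(cfg)
        for i, p in enumerate(model.network.params):
            fh.create_dataset(f"weights/{i}", data=p)
        if model.channel_mean is not None:
            fh.create_dataset("standardize/mean", data=model.channel_mean)
            fh.create_dataset("standardize/std", data=model.channel_std)
        fh.create_dataset("history", data=model.history.to_numpy())


def load_model(path) -> TrainedModel:
    with h5py.File(path, "r") as fh:
        cfg = json.loads(fh.attrs["config"])
        net_cfg_dict = dict(cfg["network"])
        net_cfg_dict["conv_filters"] = tuple(net_cfg_dict["conv_filters"])
        net_cfg_dict["conv_kernels"] = tuple(net_cfg_dict["conv_kernels"])
        net_cfg = NetworkConfig(**net_cfg_dict)
        train_cfg = TrainConfig(**cfg["training"])
        net = build_network(net_cfg)
        for i, p in enumerate(net.params):
            p[...] = fh[f"weights/{i}"][...]
        mean = std = None
        if "standardize" in fh:
            mean = fh["standardize/mean"][...]
            std = fh["standardize/std"][...]
        history = pd.DataFrame(fh["history"][...], columns=["epoch", "loss", "accuracy"])
        names = tuple(cfg["class_names"]) if "class_names" in cfg else None
    return TrainedModel(net, net_cfg, train_cfg, history, mean, std, names)
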