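"""Network architectures for nucleosome/linker classification.

Three architectures are provided:

``build_corenup``
    The hybrid network: a shared convolutional feature extractor
    (Conv1D 50x5, same padding, ReLU -> MaxPool 2/2 -> Dropout) feeding
    two parallel paths -- a sequence-output LSTM (periodic features) and
    a second convolutional block (localized, non-periodic features) --
    whose flattened outputs are concatenated and classified by
    Dense(370, ReLU) -> Dropout -> Dense(1, sigmoid).  With the default
    147-bp input the path widths are 3650 (LSTM) and 1800 (conv), a
    5450-wide concatenation, and 2,063,541 trainable parameters in
    total.

``build_convnet_baseline``
    Two stacked convolutional blocks with the same dense head -- the
    hybrid network without its recurrent path.

``build_lstm_baseline``
    One convolutional block feeding the sequence-output LSTM with the
    same dense head -- the hybrid network without its second
    convolutional path.

All layer widths come from :class:`ModelConfig`; the defaults reproduce
the published architecture exactly, and every width is configurable
(scaled-down variants are used throughout the test-suite).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict, replace
from typing import Callable

import numpy as np

from . import layers as nn
from .sequence_io import one_hot_encode, DnaSequence

PATH_FEATURES = "Features extraction path"
PATH_LSTM = "LSTM path"
PATH_CONV = "Convolutional path"
PATH_DENSE = "Dense path"


@dataclass
class ModelConfig:
    """Architecture hyperparameters (defaults = published network)."""

    input_length: int = 147
    input_channels: int = 4
    conv1_filters: int = 50
    conv1_kernel: int = 5
    conv1_stride: int = 1
    pool_size: int = 2
    pool_stride: int = 2
    lstm_units: int = 50
    conv2_filters: int = 50
    conv2_kernel: int = 10
    conv2_stride: int = 1
    dense_units: int = 370
    dropout_rate: float = 0.5
    l2_lambda: float = 1e-3
    #: apply the L2 penalty to conv/dense kernels only (the conventional
    #: reading); set False to disable weight decay entirely.
    l2_on_kernels: bool = True

    def __post_init__(self) -> None:
        counts = ("input_length", "input_channels", "conv1_filters",
                  "conv1_kernel", "conv1_stride", "pool_size", "pool_stride",
                  "lstm_units", "conv2_filters", "conv2_kernel",
                  "conv2_stride", "dense_units")
        for name in counts:
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be a positive integer")
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ValueError("dropout_rate must lie in [0, 1)")
        if self.l2_lambda < 0:
            raise ValueError("l2_lambda must be non-negative")

    def scaled(self, **overrides) -> "ModelConfig":
        """A copy with some fields replaced (e.g. a scaled-down variant)."""
        return replace(self, **overrides)

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ModelConfig":
        return cls(**d)


@dataclass
class NetworkSummary:
    """Per-layer output shapes and parameter counts, grouped by path."""

    layers: list[tuple[str, tuple, int]]      # (name, output shape, params)
    path_totals: dict[str, int]
    grand_total: int
    rows: list[dict]                          # full table rows for display

    def __str__(self) -> str:
        header = ["Path", "Layer", "Kernel", "Units", "Stride",
                  "Output dim", "# Params"]
        table = [header]
        for r in self.rows:
            table.append([
                r["path"], r["layer"],
                "-" if r["kernel"] is None else str(r["kernel"]),
                "-" if r["units"] is None else str(r["units"]),
                "-" if r["stride"] is None else str(r["stride"]),
                "x".join(str(d) for d in r["output"]),
                f"{r['params']:,}",
            ])
        widths = [max(len(row[i]) for row in table) for i in range(len(header))]
        lines = ["  ".join(cell.ljust(w) for cell, w in zip(row, widths))
                 for row in table]
        lines.append("-" * len(lines[0]))
        for path, total in self.path_totals.items():
            lines.append(f"{path}: {total:,}")
        lines.append(f"Total trainable parameters: {self.grand_total:,}")
        return "\n".join(lines)

    def summary(self) -> str:
        return str(self)


class Network:
    """A built architecture: root layer graph plus metadata."""

    def __init__(self, root: nn.Sequential, config: ModelConfig, name: str):
        self.root = root
        self.config = config
        self.name = name

    def forward(self, x, training=False, rng=None):
        return self.root.forward(x, training=training, rng=rng)

    def backward(self, grad, skip_last_activation=False):
        return self.root.backward(grad, skip_last_activation=skip_last_activation)

    def parameters(self):
        return list(nn.iter_parameters(self.root))

    def l2_penalty(self) -> float:
        return sum(layer.l2_penalty() for layer in self.root.walk())

    def predict(self, batch, batch_size: int = 256) -> np.ndarray:
        return predict(self, batch, batch_size=batch_size)

    # -- persistence ---------------------------------------------------
    def save(self, weights_path: str, sidecar_path: str | None = None) -> None:
        """Write weights (npz) plus a JSON sidecar describing the model."""
        arrays = {key: layer.params[pname]
                  for key, layer, pname in self.parameters()}
        np.savez(weights_path, **arrays)
        sidecar = sidecar_path or str(weights_path) + ".json"
        with open(sidecar, "w") as fh:
            json.dump({"model": self.name, "config": self.config.to_dict()},
                      fh, indent=2)

    @classmethod
    def load(cls, weights_path: str, sidecar_path: str | None = None) -> "Network":
        sidecar = sidecar_path or str(weights_path) + ".json"
        with open(sidecar) as fh:
            meta = json.load(fh)
        builder = _BUILDERS[meta["model"]]
        net, _ = builder(ModelConfig.from_dict(meta["config"]))
        with np.load(weights_path) as data:
            for key, layer, pname in net.parameters():
                layer.params[pname] = data[key].copy()
        return net


def _summarize(net: Network) -> NetworkSummary:
    """Measure shapes by propagating a dummy batch; enumerate parameters."""
    x = np.zeros((1, net.config.input_length, net.config.input_channels))
    net.forward(x, training=False)
    rows, layers_out = [], []
    path_totals: dict[str, int] = {}
    def visit(layer):
        count = layer.param_count()
        shape = tuple(layer.last_output_shape[1:])
        rows.append({"path": layer.path, "layer": layer.name,
                     "kernel": layer.kernel, "units": layer.units,
                     "stride": layer.stride, "output": shape,
                     "params": count})
        layers_out.append((layer.name, shape, count))
        path_totals[layer.path] = path_totals.get(layer.path, 0) + count
    concat = next((l for l in net.root.layers
                   if isinstance(l, nn.ParallelPaths)), None)
    for layer in net.root.walk():
        visit(layer)
        if (concat is not None and isinstance(layer, nn.Flatten)
                and layer.path == PATH_CONV):
            # Concatenation row follows the last branch in display order.
            rows.append({"path": PATH_DENSE, "layer": "concatenate",
                         "kernel": None, "units": None, "stride": None,
                         "output": concat.last_output_shape[1:], "params": 0})
            layers_out.append(("concatenate", concat.last_output_shape[1:], 0))
    grand = sum(path_totals.values())
    return NetworkSummary(layers=layers_out, path_totals=path_totals,
                          grand_total=grand, rows=rows)


def _tag(layer, path):
    layer.path = path
    return layer


def _pooled(length: int, pool: int) -> int:
    out = length // pool
    if out < 1:
        raise ValueError(
            f"pooling a length-{length} signal with pool size {pool} "
            "leaves no output positions")
    return out


def build_corenup(cfg: ModelConfig | None = None,
                  init_seed: int = 0) -> tuple[Network, NetworkSummary]:
    """Build the hybrid conv+LSTM network; returns (network, summary)."""
    cfg = cfg or ModelConfig()
    rng = np.random.default_rng(init_seed)
    l2 = cfg.l2_lambda if cfg.l2_on_kernels else 0.0
    L1 = cfg.input_length if cfg.conv1_stride == 1 else \
        (cfg.input_length - 1) // cfg.conv1_stride + 1
    Lp = _pooled(L1, cfg.pool_size)

    stem = [
        _tag(nn.Conv1D(cfg.input_channels, cfg.conv1_filters, cfg.conv1_kernel,
                       stride=cfg.conv1_stride, padding="same",
                       activation="relu", l2=l2, rng=rng, name="conv1d_1"),
             PATH_FEATURES),
        _tag(nn.MaxPool1D(cfg.pool_size, cfg.pool_stride, name="maxpool_1"),
             PATH_FEATURES),
        _tag(nn.Dropout(cfg.dropout_rate, name="dropout_1"), PATH_FEATURES),
    ]
    lstm_branch = nn.Sequential([
        _tag(nn.LSTM(cfg.conv1_filters, cfg.lstm_units, rng=rng, name="lstm"),
             PATH_LSTM),
        _tag(nn.Dropout(cfg.dropout_rate, name="dropout_lstm"), PATH_LSTM),
        _tag(nn.Flatten(name="flatten_lstm"), PATH_LSTM),
    ], name="lstm_path")
    conv_branch = nn.Sequential([
        _tag(nn.Conv1D(cfg.conv1_filters, cfg.conv2_filters, cfg.conv2_kernel,
                       stride=cfg.conv2_stride, padding="same",
                       activation="relu", l2=l2, rng=rng, name="conv1d_2"),
             PATH_CONV),
        _tag(nn.MaxPool1D(cfg.pool_size, cfg.pool_stride, name="maxpool_2"),
             PATH_CONV),
        _tag(nn.Dropout(cfg.dropout_rate, name="dropout_conv"), PATH_CONV),
        _tag(nn.Flatten(name="flatten_conv"), PATH_CONV),
    ], name="conv_path")
    concat_width = Lp * cfg.lstm_units + \
        _pooled(Lp, cfg.pool_size) * cfg.conv2_filters
    head = [
        nn.ParallelPaths([lstm_branch, conv_branch], name="parallel"),
        _tag(nn.Dense(concat_width, cfg.dense_units, activation="relu",
                      l2=l2, rng=rng, name="dense_1"), PATH_DENSE),
        _tag(nn.Dropout(cfg.dropout_rate, name="dropout_dense"), PATH_DENSE),
        _tag(nn.Dense(cfg.dense_units, 1, activation="sigmoid", l2=l2,
                      rng=rng, name="dense_out"), PATH_DENSE),
    ]
    net = Network(nn.Sequential(stem + head, name="corenup"), cfg, "corenup")
    return net, _summarize(net)


def build_convnet_baseline(cfg: ModelConfig | None = None,
                           init_seed: int = 0) -> tuple[Network, NetworkSummary]:
    """Two stacked conv blocks + dense head (no recurrent path)."""
    cfg = cfg or ModelConfig()
    rng = np.random.default_rng(init_seed)
    l2 = cfg.l2_lambda if cfg.l2_on_kernels else 0.0
    Lp = _pooled(cfg.input_length, cfg.pool_size)
    Lp2 = _pooled(Lp, cfg.pool_size)
    seq = [
        _tag(nn.Conv1D(cfg.input_channels, cfg.conv1_filters, cfg.conv1_kernel,
                       padding="same", activation="relu", l2=l2, rng=rng,
                       name="conv1d_1"), PATH_FEATURES),
        _tag(nn.MaxPool1D(cfg.pool_size, cfg.pool_stride, name="maxpool_1"),
             PATH_FEATURES),
        _tag(nn.Dropout(cfg.dropout_rate, name="dropout_1"), PATH_FEATURES),
        _tag(nn.Conv1D(cfg.conv1_filters, cfg.conv2_filters, cfg.conv2_kernel,
                       padding="same", activation="relu", l2=l2, rng=rng,
                       name="conv1d_2"), PATH_CONV),
        _tag(nn.MaxPool1D(cfg.pool_size, cfg.pool_stride, name="maxpool_2"),
             PATH_CONV),
        _tag(nn.Dropout(cfg.dropout_rate, name="dropout_2"), PATH_CONV),
        _tag(nn.Flatten(name="flatten"), PATH_CONV),
        _tag(nn.Dense(Lp2 * cfg.conv2_filters, cfg.dense_units,
                      activation="relu", l2=l2, rng=rng, name="dense_1"),
             PATH_DENSE),
        _tag(nn.Dropout(cfg.dropout_rate, name="dropout_dense"), PATH_DENSE),
        _tag(nn.Dense(cfg.dense_units, 1, activation="sigmoid", l2=l2,
                      rng=rng, name="dense_out"), PATH_DENSE),
    ]
    net = Network(nn.Sequential(seq, name="convnet"), cfg, "convnet")
    return net, _summarize(net)


def build_lstm_baseline(cfg: ModelConfig | None = None,
                        init_seed: int = 0) -> tuple[Network, NetworkSummary]:
    """One conv block feeding an LSTM + dense head (no second conv path)."""
    cfg = cfg or ModelConfig()
    rng = np.random.default_rng(init_seed)
    l2 = cfg.l2_lambda if cfg.l2_on_kernels else 0.0
    Lp = _pooled(cfg.input_length, cfg.pool_size)
    seq = [
        _tag(nn.Conv1D(cfg.input_channels, cfg.conv1_filters, cfg.conv1_kernel,
                       padding="same", activation="relu", l2=l2, rng=rng,
                       name="conv1d_1"), PATH_FEATURES),
        _tag(nn.MaxPool1D(cfg.pool_size, cfg.pool_stride, name="maxpool_1"),
             PATH_FEATURES),
        _tag(nn.Dropout(cfg.dropout_rate, name="dropout_1"), PATH_FEATURES),
        _tag(nn.LSTM(cfg.conv1_filters, cfg.lstm_units, rng=rng, name="lstm"),
             PATH_LSTM),
        _tag(nn.Dropout(cfg.dropout_rate, name="dropout_lstm"), PATH_LSTM),
        _tag(nn.Flatten(name="flatten"), PATH_LSTM),
        _tag(nn.Dense(Lp * cfg.lstm_units, cfg.dense_units, activation="relu",
                      l2=l2, rng=rng, name="dense_1"), PATH_DENSE),
        _tag(nn.Dropout(cfg.dropout_rate, name="dropout_dense"), PATH_DENSE),
        _tag(nn.Dense(cfg.dense_units, 1, activation="sigmoid", l2=l2,
                      rng=rng, name="dense_out"), PATH_DENSE),
    ]
    net = Network(nn.Sequential(seq, name="lstm_net"), cfg, "lstm")
    return net, _summarize(net)


_BUILDERS: dict[str, Callable] = {
    "corenup": build_corenup,
    "convnet": build_convnet_baseline,
    "lstm": build_lstm_baseline,
}


def get_builder(name: str) -> Callable:
    try:
        return _BUILDERS[name]
    except KeyError:
        raise ValueError(
            f"unknown model {name!r}; choose from {sorted(_BUILDERS)}")


def count_parameters(net: Network) -> NetworkSummary:
    """Per-layer/per-path parameter counts by direct weight enumeration."""
    return _summarize(net)


def predict(net: Network, batch, batch_size: int = 256) -> np.ndarray:
    """Class-1 (nucleosome) probability for each sequence in ``batch``.

    ``batch`` may be a one-hot tensor (N, L, 4), a single (L, 4) matrix,
    or a list of sequences/strings.  Dropout is inactive; output is
    deterministic given the weights and invariant to batch partitioning.
    """
    if isinstance(batch, np.ndarray):
        x = batch[None] if batch.ndim == 2 else batch
    else:
        x = one_hot_encode(batch)
    L = net.config.input_length
    if x.shape[1] != L or x.shape[2] != net.config.input_channels:
        raise ValueError(
            f"input length/channels {x.shape[1:]} do not match the model "
            f"(expected ({L}, {net.config.input_channels}))")
    probs = np.concatenate([
        net.forward(x[i:i + batch_size], training=False).ravel()
        for i in range(0, x.shape[0], batch_size)])
    return probs


# ---------------------------------------------------------------------
# Model-class surface: a model is constructed from (optional) data and a
# config; fit() trains a fresh network and returns a results object.
# ---------------------------------------------------------------------

class _ClassifierModel:
    """Base class for the three architectures.

    Parameters
    ----------
    data : LabeledDataset, optional
        Training data; required before :meth:`fit`.
    config : ModelConfig, optional
        Architecture hyperparameters (defaults reproduce the published
        network).
    """

    _builder_name: str

    def __init__(self, data=None, config: ModelConfig | None = None):
        self.data = data
        self.config = config or ModelConfig()

    @classmethod
    def from_fasta(cls, positives: str, negatives: str,
                   config: ModelConfig | None = None, policy: str = "strict"):
        from .sequence_io import LabeledDataset
        return cls(LabeledDataset.from_fasta(positives, negatives,
                                             policy=policy), config)

    def build(self, init_seed: int = 0) -> tuple[Network, NetworkSummary]:
        """Instantiate the (untrained) network and its summary."""
        return get_builder(self._builder_name)(self.config, init_seed=init_seed)

    def summary(self) -> NetworkSummary:
        """Architecture summary (shapes and parameter counts)."""
        return self.build()[1]

    def fit(self, train_config=None):
        """Train a fresh network on ``self.data``.

        Returns a :class:`~corenup.training.TrainingResults` carrying the
        fitted network, the per-epoch loss history, the stopping epoch
        and evaluation helpers.
        """
        if self.data is None:
            raise ValueError("model has no data; construct with a "
                             "LabeledDataset or use from_fasta()")
        from .training import TrainConfig, train
        tcfg = train_config or TrainConfig()
        net, _ = self.build(init_seed=tcfg.seed)
        return train(net, self.data, tcfg)


class CORENup(_ClassifierModel):
    """The hybrid convolutional + recurrent classifier."""
    _builder_name = "corenup"


class ConvNetBaseline(_ClassifierModel):
    """Purely convolutional baseline (two conv blocks)."""
    _builder_name = "convnet"


class LSTMBaseline(_ClassifierModel):
    """Convolutional-stem + LSTM baseline (no second conv path)."""
    _builder_name = "lstm"
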