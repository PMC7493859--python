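"""Training loop and evaluation protocols.

Training follows the published recipe: Adam (learning rate 3e-4) on
binary cross-entropy with L2 weight decay (lambda = 1e-3 on conv/dense
kernels), at most 200 epochs, early stopping when the validation loss
fails to decrease for 5 consecutive epochs, validation split = a
stratified random 10% of the training set.  Class-1 probabilities are
thresholded at 0.5 for label prediction.

Two evaluation protocols are provided:

* :func:`cross_validate` -- stratified k-fold (default k=20): train on
  k-1 folds, evaluate ACC/SENS/SPEC/MCC/AUC on the held-out fold,
  report per-fold values and mean +/- standard deviation;
* :func:`resample_evaluate` -- draw (with replacement) ``n_samples``
  samples of ``sample_size`` sequences from a held-out pool and report
  the AUC of each draw plus the mean over draws.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, asdict, field, replace

import numpy as np
import pandas as pd

from .sequence_io import LabeledDataset
from .models import Network, ModelConfig, get_builder
from .metrics import compute_metrics, roc_auc

logger = logging.getLogger(__name__)

METRIC_NAMES = ("ACC", "SENS", "SPEC", "MCC", "AUC")


@dataclass
class TrainConfig:
    """Optimization protocol parameters (defaults = published recipe)."""

    learning_rate: float = 3e-4
    max_epochs: int = 200
    early_stop_patience: int = 5
    validation_fraction: float = 0.10
    batch_size: int = 32
    decision_threshold: float = 0.5
    seed: int = 0
    restore_best_weights: bool = False
    adam_beta1: float = 0.9
    adam_beta2: float = 0.999
    adam_eps: float = 1e-8

    def __post_init__(self) -> None:
        if not 0.0 < self.validation_fraction < 1.0:
            raise ValueError("validation_fraction must lie in (0, 1)")
        if self.early_stop_patience < 1:
            raise ValueError("early_stop_patience must be >= 1")
        if not 0.0 < self.decision_threshold < 1.0:
            raise ValueError("decision_threshold must lie in (0, 1)")
        if self.batch_size < 1 or self.max_epochs < 1:
            raise ValueError("batch_size and max_epochs must be positive")

    def to_dict(self) -> dict:
        return asdict(self)


class Adam:
    """Adam optimizer updating network parameters in place."""

    def __init__(self, params, lr, beta1=0.9, beta2=0.999, eps=1e-8):
        self.params = params          # list of (key, layer, pname)
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.t = 0
        self.m = {k: np.zeros_like(layer.params[p]) for k, layer, p in params}
        self.v = {k: np.zeros_like(layer.params[p]) for k, layer, p in params}

    def step(self):
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for key, layer, pname in self.params:
            g = layer.grads[pname]
            m = self.m[key] = b1 * self.m[key] + (1 - b1) * g
            v = self.v[key] = b2 * self.v[key] + (1 - b2) * g * g
            mhat = m / (1 - b1 ** self.t)
            vhat = v / (1 - b2 ** self.t)
            layer.params[pname] -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


def _bce(probs: np.ndarray, y: np.ndarray) -> float:
    p = np.clip(probs, 1e-12, 1 - 1e-12)
    return float(-np.mean(y * np.log(p) + (1 - y) * np.log(1 - p)))


def _stratified_split(labels: np.ndarray, fraction: float,
                      rng: np.random.Generator):
    """Seeded stratified holdout; returns (train_idx, val_idx)."""
    val_idx = []
    for cls in (0, 1):
        members = np.flatnonzero(labels == cls)
        rng.shuffle(members)
        n_val = max(1, round(fraction * members.size))
        if n_val >= members.size:
            raise ValueError("validation split would consume an entire class")
        val_idx.append(members[:n_val])
    val_idx = np.concatenate(val_idx)
    mask = np.ones(labels.size, dtype=bool)
    mask[val_idx] = False
    return np.flatnonzero(mask), np.sort(val_idx)


class TrainingResults:
    """Results of one training run.

    Carries the fitted network, the per-epoch loss history, the stopping
    epoch and the training-sequence ids (used by
    :func:`resample_evaluate` to assert train/test disjointness).
    """

    def __init__(self, network: Network, history: list[dict],
                 stopping_epoch: int, stopped_early: bool,
                 config: TrainConfig, train_ids: list[str],
                 n_train: int, n_val: int):
        self.network = network
        self.history = history
        self.stopping_epoch = stopping_epoch
        self.stopped_early = stopped_early
        self.config = config
        self.train_ids = train_ids
        self.n_train = n_train
        self.n_val = n_val

    @property
    def history_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.history)

    def predict(self, batch) -> np.ndarray:
        """Class-1 probability per sequence."""
        return self.network.predict(batch)

    def predict_labels(self, batch) -> np.ndarray:
        return (self.predict(batch) >= self.config.decision_threshold
                ).astype(int)

    def evaluate(self, ds: LabeledDataset) -> dict[str, float]:
        """ACC/SENS/SPEC/MCC/AUC of the fitted network on ``ds``."""
        scores = self.predict(ds.encode())
        return compute_metrics(scores, ds.labels,
                               self.config.decision_threshold)

    def summary(self) -> str:
        h = self.history
        lines = [
            f"Model: {self.network.name}",
            f"Training sequences: {self.n_train} (+{self.n_val} validation)",
            f"Epochs run: {self.stopping_epoch}"
            + (" (early stopping)" if self.stopped_early else ""),
            f"Final train loss: {h[-1]['train_loss']:.4f}",
            f"Final validation loss: {h[-1]['val_loss']:.4f}",
            f"Best validation loss: {min(e['val_loss'] for e in h):.4f}",
        ]
        return "\n".join(lines)


def train(network: Network, train_ds: LabeledDataset,
          cfg: TrainConfig | None = None) -> TrainingResults:
    """Fit ``network`` on ``train_ds`` under the published protocol.

    The dataset is split into a stratified 90/10 train/validation part;
    minibatch Adam minimizes binary cross-entropy plus the network's L2
    penalty; training stops at ``max_epochs`` or when the validation
    loss has not decreased below its best value for
    ``early_stop_patience`` consecutive epochs.  Fully reproducible from
    ``cfg.seed``.
    """
    cfg = cfg or TrainConfig()
    labels = train_ds.labels
    if labels.min() == labels.max():
        raise ValueError("training set contains a single class")
    if train_ds.length != network.config.input_length:
        raise ValueError(
            f"dataset length {train_ds.length} does not match model input "
            f"length {network.config.input_length}")

    rng = np.random.default_rng(cfg.seed)
    x = train_ds.encode().astype(np.float64)
    y = labels.astype(np.float64)
    tr_idx, val_idx = _stratified_split(labels, cfg.validation_fraction, rng)
    if val_idx.size == 0:
        raise ValueError("validation split is empty")
    x_tr, y_tr = x[tr_idx], y[tr_idx]
    x_val, y_val = x[val_idx], y[val_idx]

    opt = Adam(network.parameters(), cfg.learning_rate,
               cfg.adam_beta1, cfg.adam_beta2, cfg.adam_eps)

    history: list[dict] = []
    best_val = np.inf
    best_weights = None
    wait = 0
    stopped_early = False
    epoch = 0
    for epoch in range(1, cfg.max_epochs + 1):
        order = rng.permutation(x_tr.shape[0])
        epoch_loss = 0.0
        for start in range(0, order.size, cfg.batch_size):
            idx = order[start:start + cfg.batch_size]
            xb, yb = x_tr[idx], y_tr[idx]
            probs = network.forward(xb, training=True, rng=rng).ravel()
            epoch_loss += _bce(probs, yb) * idx.size
            # Fused sigmoid+BCE gradient w.r.t. the output pre-activation.
            delta = ((probs - yb) / idx.size)[:, None]
            network.backward(delta, skip_last_activation=True)
            opt.step()
        train_loss = epoch_loss / order.size + network.l2_penalty()
        val_probs = network.predict(x_val)
        val_loss = _bce(val_probs, y_val) + network.l2_penalty()
        history.append({"epoch": epoch, "train_loss": train_loss,
                        "val_loss": val_loss})
        logger.debug("epoch %d: train %.4f val %.4f", epoch, train_loss,
                     val_loss)
        if val_loss < best_val:
            best_val = val_loss
            wait = 0
            if cfg.restore_best_weights:
                best_weights = [(layer, p, layer.params[p].copy())
                                for _, layer, p in network.parameters()]
        else:
            wait += 1
            if wait >= cfg.early_stop_patience:
                stopped_early = True
                break
    if cfg.restore_best_weights and best_weights is not None:
        for layer, pname, arr in best_weights:
            layer.params[pname] = arr

    return TrainingResults(
        network=network, history=history, stopping_epoch=epoch,
        stopped_early=stopped_early, config=cfg,
        train_ids=[train_ds.sequences[i].id for i in tr_idx] +
                  [train_ds.sequences[i].id for i in val_idx],
        n_train=tr_idx.size, n_val=val_idx.size)


# ---------------------------------------------------------------------
# k-fold cross-validation
# ---------------------------------------------------------------------

@dataclass
class FoldPlan:
    """A k-fold partition: ``assignments[i]`` is the fold of item i."""

    k: int
    assignments: np.ndarray
    stratified: bool = True

    def __post_init__(self) -> None:
        self.assignments = np.asarray(self.assignments, dtype=int)
        sizes = np.bincount(self.assignments, minlength=self.k)
        if sizes.size != self.k or sizes.min() == 0:
            raise ValueError("every fold index in [0, k) must be used")
        if sizes.max() - sizes.min() > 1:
            raise ValueError("fold sizes must differ by at most 1")

    def fold_sizes(self) -> np.ndarray:
        return np.bincount(self.assignments, minlength=self.k)

    def test_indices(self, fold: int) -> np.ndarray:
        return np.flatnonzero(self.assignments == fold)

    def train_indices(self, fold: int) -> np.ndarray:
        return np.flatnonzero(self.assignments != fold)


def make_folds(ds, k: int, stratified: bool = True,
               seed: int = 0) -> FoldPlan:
    """Seeded (optionally stratified) k-fold partition.

    ``ds`` may be a :class:`LabeledDataset` or a 0/1 label array.  Fold
    sizes differ by at most one; under stratification each fold's class
    counts deviate from proportionality by at most one.
    """
    labels = ds.labels if isinstance(ds, LabeledDataset) else \
        np.asarray(ds, dtype=int)
    n = labels.size
    if k < 2:
        raise ValueError("k must be >= 2")
    if k > n:
        raise ValueError(f"k={k} exceeds the dataset size {n}")
    rng = np.random.default_rng(seed)
    assignments = np.empty(n, dtype=int)
    if stratified:
        # One running round-robin counter across classes keeps both the
        # per-class and the overall fold sizes within 1 of each other.
        fold_order = rng.permutation(k)
        counter = 0
        for cls in np.unique(labels):
            members = np.flatnonzero(labels == cls)
            if members.size < k:
                raise ValueError(
                    f"class {cls} has only {members.size} members for k={k}")
            rng.shuffle(members)
            assignments[members] = fold_order[
                (counter + np.arange(members.size)) % k]
            counter += members.size
    else:
        order = rng.permutation(n)
        assignments[order] = np.arange(n) % k
    return FoldPlan(k=k, assignments=assignments, stratified=stratified)


class CrossValidationResults:
    """Per-fold metrics plus mean +/- standard deviation aggregates."""

    def __init__(self, fold_metrics: list[dict[str, float]],
                 fold_results: list[TrainingResults] | None = None):
        self.fold_metrics = fold_metrics
        self.fold_results = fold_results or []

    @property
    def frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.fold_metrics)
        df.insert(0, "fold", range(len(self.fold_metrics)))
        return df

    @property
    def mean(self) -> dict[str, float]:
        return {m: float(np.mean([f[m] for f in self.fold_metrics]))
                for m in METRIC_NAMES}

    @property
    def std(self) -> dict[str, float]:
        return {m: float(np.std([f[m] for f in self.fold_metrics]))
                for m in METRIC_NAMES}

    def to_frame_with_aggregates(self) -> pd.DataFrame:
        df = self.frame
        mean_row = {"fold": "mean", **self.mean}
        std_row = {"fold": "std", **self.std}
        return pd.concat([df, pd.DataFrame([mean_row, std_row])],
                         ignore_index=True)

    def summary(self) -> str:
        mean, std = self.mean, self.std
        lines = [f"{len(self.fold_metrics)}-fold cross-validation"]
        for m in METRIC_NAMES:
            lines.append(f"  {m:5s} {mean[m]:.3f} +/- {std[m]:.3f}")
        return "\n".join(lines)


def cross_validate(ds: LabeledDataset, model_builder, train_cfg: TrainConfig,
                   fold_plan: FoldPlan | None = None, k: int = 20,
                   keep_fold_results: bool = False) -> CrossValidationResults:
    """k-fold cross-validation of a model builder.

    ``model_builder`` is a callable ``(fold_seed) -> Network`` (a fresh,
    untrained network per fold).  For each fold, the model is trained on
    the other k-1 folds and all five metrics are computed on the
    held-out fold.
    """
    plan = fold_plan or make_folds(ds, k, stratified=True,
                                   seed=train_cfg.seed)
    fold_metrics, fold_results = [], []
    for fold in range(plan.k):
        net = model_builder(train_cfg.seed + fold)
        res = train(net, ds.subset(plan.train_indices(fold)),
                    replace(train_cfg, seed=train_cfg.seed + fold))
        fold_metrics.append(res.evaluate(ds.subset(plan.test_indices(fold))))
        if keep_fold_results:
            fold_results.append(res)
        logger.info("fold %d/%d: %s", fold + 1, plan.k,
                    {k: round(v, 3) for k, v in fold_metrics[-1].items()})
    return CrossValidationResults(fold_metrics, fold_results)


# ---------------------------------------------------------------------
# Bootstrap resample evaluation
# ---------------------------------------------------------------------

class ResampleResults:
    """Per-draw AUCs of the bootstrap resample protocol."""

    def __init__(self, aucs: list[float], n_redrawn: int,
                 sample_size: int):
        self.aucs = aucs
        self.n_redrawn = n_redrawn
        self.sample_size = sample_size

    @property
    def mean_auc(self) -> float:
        return float(np.mean(self.aucs))

    @property
    def std_auc(self) -> float:
        return float(np.std(self.aucs))

    def summary(self) -> str:
        return (f"{len(self.aucs)} resamples of {self.sample_size}: "
                f"AUC {self.mean_auc:.3f} +/- {self.std_auc:.3f}"
                + (f" ({self.n_redrawn} single-class draws redrawn)"
                   if self.n_redrawn else ""))


def resample_evaluate(fitted: TrainingResults | Network,
                      pool: LabeledDataset, n_samples: int = 100,
                      sample_size: int = 100, seed: int = 0,
                      train_ids: list[str] | None = None) -> ResampleResults:
    """AUC over repeated with-replacement samples from a held-out pool.

    Draws ``n_samples`` samples of ``sample_size`` sequences (with
    replacement) from ``pool`` and computes the ROC AUC of the fitted
    model on each; the headline statistic is the mean AUC over draws.
    A draw containing a single class (AUC undefined) is redrawn and the
    event logged.  The pool must be disjoint from the training
    sequences, asserted by id overlap against ``train_ids`` (taken from
    ``fitted`` when it is a :class:`TrainingResults`).
    """
    if isinstance(fitted, TrainingResults):
        network = fitted.network
        train_ids = train_ids if train_ids is not None else fitted.train_ids
    else:
        network = fitted
    if pool is None or len(pool) < sample_size:
        raise ValueError("pool smaller than sample_size")
    if train_ids:
        overlap = set(train_ids) & set(pool.ids)
        if overlap:
            raise ValueError(
                f"test pool overlaps training data: "
                f"{sorted(overlap)[:5]}{'...' if len(overlap) > 5 else ''}")

    rng = np.random.default_rng(seed)
    scores = network.predict(pool.encode())
    labels = pool.labels
    aucs: list[float] = []
    n_redrawn = 0
    while len(aucs) < n_samples:
        idx = rng.integers(0, len(pool), size=sample_size)
        drawn = labels[idx]
        if drawn.min() == drawn.max():
            n_redrawn += 1
            logger.info("resample draw %d was single-class; redrawing",
                        len(aucs))
            continue
        aucs.append(roc_auc(scores[idx], drawn)[0])
    return ResampleResults(aucs, n_redrawn, sample_size)


def scaled_builder(model: str = "corenup",
                   config: ModelConfig | None = None):
    """Convenience: a ``(seed) -> Network`` builder for cross_validate."""
    cfg = config or ModelConfig()
    b = get_builder(model)
    def build(seed: int) -> Network:
        return b(cfg, init_seed=seed)[0]
    return build
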