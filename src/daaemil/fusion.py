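"""Multimodal fusion and the MLP risk predictor.

Selected feature blocks from the three modalities — clinical/dosimetric
(CD), engineered image features (RF) and deep CT features (CT) — are
concatenated per patient in that fixed order, W_i = X_CD (+) X_RF (+) X_CT,
and fed to a one-hidden-layer perceptron with sigmoid output trained with
binary cross-entropy (Adam, the same optimizer protocol as stage-1).
Blocks arrive on different scales, so the predictor re-standardizes inputs
with train-fold statistics by default.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_is_fitted

from .exceptions import DomainError
from .nn import Adam, Linear, Module, Tensor
from .nn.autodiff import bce_with_logits
from .tabular import FeatureTable

__all__ = ["FusedFeatures", "PredictorParams", "fuse", "train_mlp", "predict",
           "FusionMlpClassifier"]

BLOCK_ORDER = ("clinical", "radiomics", "deep")


@dataclass
class FusedFeatures:
    """Per-patient fused vectors with a named block layout."""

    patient_ids: np.ndarray
    values: np.ndarray                    # n x total_width
    layout: dict                          # block name -> (start, stop) or None

    @property
    def width(self) -> int:
        return self.values.shape[1]


def fuse(clinical: FeatureTable | None, radiomics: FeatureTable | None,
         deep: FeatureTable | None, allow_missing: bool = False) -> FusedFeatures:
    """Row-wise concatenation of selected blocks in fixed CD, RF, CT order.

    Rows are aligned on patient id, so input row order does not matter.
    A missing modality is only allowed under the explicit ablation flag;
    the layout records the absent block as None.
    """
    blocks = dict(zip(BLOCK_ORDER, (clinical, radiomics, deep)))
    present = {n: t for n, t in blocks.items() if t is not None}
    if not present:
        raise DomainError("at least one modality required")
    if len(present) < len(blocks) and not allow_missing:
        raise DomainError("missing modality; pass allow_missing=True for ablations")
    id_sets = [frozenset(t.patient_ids.tolist()) for t in present.values()]
    if len(set(id_sets)) != 1:
        raise DomainError("patient id sets differ across modalities")
    ids = np.sort(list(present.values())[0].patient_ids)
    parts, layout, offset = [], {}, 0
    for name in BLOCK_ORDER:
        table = blocks[name]
        if table is None:
            layout[name] = None
            continue
        frame = table.data.copy()
        frame.index = table.patient_ids
        aligned = frame.loc[ids]
        width = aligned.shape[1]
        layout[name] = (offset, offset + width)
        offset += width
        parts.append(aligned.to_numpy(dtype=float))
    values = np.hstack(parts) if parts else np.empty((len(ids), 0))
    return FusedFeatures(np.asarray(ids), values, layout)


@dataclass
class PredictorParams:
    """A sigmoid MLP: one hidden layer by default, or a single sigmoid
    neuron when ``w2`` is None (the degenerate perceptron case)."""

    w1: np.ndarray
    b1: np.ndarray
    w2: np.ndarray | None = None
    b2: np.ndarray | None = None
    threshold: float = 0.5
    feature_mean: np.ndarray | None = None
    feature_scale: np.ndarray | None = None

    @property
    def layer_sizes(self):
        if self.w2 is None:
            return (self.w1.shape[1], 1)
        return (self.w1.shape[1], self.w1.shape[0], 1)

    def logits(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != self.w1.shape[1]:
            raise DomainError("feature width does not match the input layer")
        if self.feature_mean is not None:
            X = (X - self.feature_mean) / self.feature_scale
        if self.w2 is None:
            return (X @ self.w1.T + self.b1).ravel()
        h = expit(X @ self.w1.T + self.b1)
        return (h @ self.w2.T + self.b2).ravel()


class _Mlp(Module):
    def __init__(self, n_in, hidden, rng):
        self.fc1 = Linear(n_in, hidden, rng)
        self.fc2 = Linear(hidden, 1, rng)

    def __call__(self, x: Tensor) -> Tensor:
        return self.fc2(self.fc1(x).sigmoid())


@dataclass
class MlpTrainConfig:
    hidden: int = 32
    lr: float = 1e-4
    weight_decay: float = 1e-5
    batch_size: int = 4
    max_epochs: int = 100
    patience: int = 15
    val_fraction: float = 0.2
    standardize: bool = True
    threshold: float = 0.5
    seed: int = 0
    log: dict = field(default_factory=dict)


def train_mlp(features, labels, config: MlpTrainConfig | None = None) -> PredictorParams:
    """Train the sigmoid MLP predictor with BCE and early stopping."""
    config = config or MlpTrainConfig()
    X = features.values if isinstance(features, FusedFeatures) else \
        np.atleast_2d(np.asarray(features, dtype=float))
    y = np.asarray(labels, dtype=int)
    if len(np.unique(y)) < 2:
        raise DomainError("training needs both classes present")
    mean = scale = None
    if config.standardize:
        mean = X.mean(axis=0)
        scale = X.std(axis=0, ddof=1)
        scale[scale == 0] = 1.0
        X = (X - mean) / scale

    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 23]))
    net = _Mlp(X.shape[1], config.hidden, rng)
    opt = Adam(net.parameters(), lr=config.lr, weight_decay=config.weight_decay)

    # stratified early-stopping holdout
    val_idx = []
    for cls in np.unique(y):
        idx = rng.permutation(np.flatnonzero(y == cls))
        n_val = max(1, int(math.floor(len(idx) * config.val_fraction + 0.5)))
        val_idx.extend(idx[:n_val])
    val_mask = np.zeros(len(y), dtype=bool)
    val_mask[val_idx] = True
    tr = np.flatnonzero(~val_mask)
    va = np.flatnonzero(val_mask)

    def loss_on(idx):
        logits = net(Tensor(X[idx]))
        return bce_with_logits(logits.reshape(len(idx)), y[idx]).mean()

    best_val, best_state, since_best = np.inf, net.state_arrays(), 0
    config.log.setdefault("train_loss", [])
    config.log.setdefault("val_loss", [])
    for epoch in range(config.max_epochs):
        order = rng.permutation(tr)
        epoch_losses = []
        for lo in range(0, len(order), config.batch_size):
            batch = order[lo:lo + config.batch_size]
            opt.zero_grad()
            loss = loss_on(batch)
            loss.backward()
            opt.step()
            epoch_losses.append(float(loss.data))
        val_loss = float(loss_on(va).data)
        config.log["train_loss"].append(float(np.mean(epoch_losses)))
        config.log["val_loss"].append(val_loss)
        if val_loss < best_val - 1e-12:
            best_val, since_best = val_loss, 0
            best_state = net.state_arrays()
        else:
            since_best += 1
            if since_best >= config.patience:
                break
    net.load_state_arrays(best_state)
    return PredictorParams(net.fc1.weight.data.copy(), net.fc1.bias.data.copy(),
                           net.fc2.weight.data.copy(), net.fc2.bias.data.copy(),
                           threshold=config.threshold,
                           feature_mean=mean, feature_scale=scale)


def predict(params: PredictorParams, features):
    """Per-patient probability in (0,1) and class (1 iff p >= threshold)."""
    X = features.values if isinstance(features, FusedFeatures) else features
    p = expit(params.logits(X))
    return p, (p >= params.threshold).astype(int)


class FusionMlpClassifier(BaseEstimator, ClassifierMixin):
    """scikit-learn facade over the fused-feature MLP predictor."""

    def __init__(self, hidden=32, lr=1e-4, weight_decay=1e-5, batch_size=4,
                 max_epochs=100, patience=15, val_fraction=0.2,
                 standardize=True, threshold=0.5, random_state=0):
        self.hidden = hidden
        self.lr = lr
        self.weight_decay = weight_decay
        self.batch_size = batch_size
        self.max_epochs = max_epochs
        self.patience = patience
        self.val_fraction = val_fraction
        self.standardize = standardize
        self.threshold = threshold
        self.random_state = random_state

    def fit(self, X, y):
        y = np.asarray(y, dtype=int)
        self.classes_ = np.unique(y)
        cfg = MlpTrainConfig(hidden=self.hidden, lr=self.lr,
                             weight_decay=self.weight_decay,
                             batch_size=self.batch_size,
                             max_epochs=self.max_epochs, patience=self.patience,
                             val_fraction=self.val_fraction,
                             standardize=self.standardize,
                             threshold=self.threshold, seed=self.random_state)
        self.params_ = train_mlp(X, y, cfg)
        self.train_log_ = cfg.log
        return self

    def predict_proba(self, X):
        check_is_fitted(self, "params_")
        p, _ = predict(self.params_, X)
        return np.column_stack([1 - p, p])

    def decision_function(self, X):
        check_is_fitted(self, "params_")
        return predict(self.params_, X)[0]

    def predict(self, X):
        check_is_fitted(self, "params_")
        return predict(self.params_, X)[1]
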