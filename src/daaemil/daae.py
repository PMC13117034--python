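"""Dual-layer attention with adaptive bag embedding for multiple-instance
learning, plus bag-level (stage-1) training.

Given a bag of k instance vectors h_1..h_k (one per slice window of a
volume), the model:

1. scores every instance with gated-tanh attention,
       a_k = softmax_k( w^T tanh(V h_k^T) ),
   and pools Z = sum_k a_k h_k (first attention layer);
2. selects the top-M instances by a (hard selection, no gradient through
   the indices), where M itself is adapted by a small controller MLP fed
   with the softmax of the top-M scores: M' = clamp(round(sigma(MLP(p))·k), 1, k);
3. projects instances to queries and values, q_k = Wq h_k, v_k = Wv h_k,
   and calibrates a second attention weight from the average softmax
   similarity between each instance and the selected critical instances,
       D_k = (1/k) * sum_{m in critical} softmax_n(<q_n, q_cm>)[k],
   so sum_k D_k = M/k under this printed normalizer (a 1/M variant making
   the weights sum to 1 is selectable);
4. forms the bag embedding B = sum_k D_k v_k, whose flattened form is the
   patient's deep feature vector.

Stage-1 training fits the 3D-conv extractor, both attention layers and a
linear-sigmoid head end to end with binary cross-entropy on bag labels.
The head reads the concatenation of the pooled representation Z and the
flattened bag embedding B: hard top-M selection carries no gradient, so Z
is the path through which the first-layer attention receives its learning
signal while B trains the projection/calibration layer.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_is_fitted

from .backbone import (BackboneConfig, C3dFeatureExtractor, InstanceFeatureSet,
                       build_backbone, minmax_normalize)
from .exceptions import DomainError
from .nn import Adam, Linear, Module, Tensor, concat, softmax
from .nn.autodiff import bce_with_logits
from .tabular import CONTINUOUS, FeatureTable

__all__ = [
    "AttentionParams", "ProjectionParams", "MController", "AttentionState",
    "BagEmbedding", "TrainConfig", "MilModel",
    "attention_pool", "top_m_select", "update_m", "project_qv",
    "distance_weights", "bag_embed", "forward_bag", "train_stage1",
    "extract_deep_features", "DaaeMilClassifier",
]

CONTROLLER_INPUT = 8  # fixed controller input length (p padded/truncated)


# ---------------------------------------------------------------------------
# parameter containers
# ---------------------------------------------------------------------------

class AttentionParams(Module):
    """Gated-tanh attention parameters: w (L x 1) and V (L x d)."""

    def __init__(self, d: int, L: int, rng: np.random.Generator):
        from .nn import glorot_uniform
        self.V = glorot_uniform(rng, (L, d), d, L)
        self.w = glorot_uniform(rng, (L, 1), L, 1)
        self.L = L
        self.d = d


class ProjectionParams(Module):
    """Per-head query/value projections Wq, Wv (d' x d)."""

    def __init__(self, d: int, d_proj: int, rng: np.random.Generator,
                 heads: int = 1):
        from .nn import glorot_uniform
        if heads < 1:
            raise DomainError("head count must be >= 1")
        self.Wq = [glorot_uniform(rng, (d_proj, d), d, d_proj)
                   for _ in range(heads)]
        self.Wv = [glorot_uniform(rng, (d_proj, d), d, d_proj)
                   for _ in range(heads)]
        self.heads = heads
        self.d_proj = d_proj


class MController(Module):
    """One-hidden-layer MLP emitting the logit of M/k."""

    def __init__(self, rng: np.random.Generator, hidden: int = 16,
                 zero_init: bool = False):
        self.fc1 = Linear(CONTROLLER_INPUT, hidden, rng)
        self.fc2 = Linear(hidden, 1, rng)
        if zero_init:
            for p in self.parameters():
                p.data[...] = 0.0

    def logit(self, p: np.ndarray) -> float:
        x = Tensor(p[None, :])
        h = self.fc1(x).tanh()
        return float(self.fc2(h).data.ravel()[0])


@dataclass
class AttentionState:
    a: np.ndarray                 # first-layer weights, length k
    top_indices: list             # critical instance indices, |.| = M
    m: int
    m_proposed: int
    D: np.ndarray                 # second-layer weights, length k
    k: int


@dataclass
class BagEmbedding:
    B: np.ndarray

    @property
    def flattened(self) -> np.ndarray:
        return np.asarray(self.B, dtype=float).ravel()


# ---------------------------------------------------------------------------
# the individual operations (tensor versions + numpy-facing wrappers)
# ---------------------------------------------------------------------------

def _attention_pool_t(H: Tensor, params: AttentionParams):
    if H.shape[1] != params.d:
        raise DomainError("feature dimension does not match attention params")
    scores = (H @ params.V.T).tanh() @ params.w          # (k, 1)
    a = softmax(scores, axis=0)                          # (k, 1)
    Z = a.T @ H                                          # (1, d)
    return a, Z


def attention_pool(features, params: AttentionParams):
    """First-layer attention: weights a over instances and pooled Z."""
    H = Tensor(np.atleast_2d(np.asarray(features, dtype=float)))
    a, Z = _attention_pool_t(H, params)
    return a.data.ravel(), Z.data.ravel()


def top_m_select(a, M: int) -> list:
    """Indices of the M largest attention weights, descending; stable ties."""
    a = np.asarray(a, dtype=float).ravel()
    k = a.size
    if not 1 <= M <= k:
        raise DomainError(f"M={M} outside [1, {k}]")
    order = np.lexsort((np.arange(k), -a))  # primary: -a asc, tie: index asc
    return [int(j) for j in order[:M]]


def _controller_probability(top_scores) -> np.ndarray:
    s = np.asarray(top_scores, dtype=float).ravel()
    e = np.exp(s - s.max())
    p = e / e.sum()
    if p.size >= CONTROLLER_INPUT:
        p = p[:CONTROLLER_INPUT]
        p = p / p.sum()           # renormalize after truncation
    else:
        p = np.concatenate([p, np.zeros(CONTROLLER_INPUT - p.size)])
    return p


def update_m(top_scores, k: int, controller: MController) -> int:
    """Adapt the critical-instance count from the top attention scores."""
    if k < 1:
        raise DomainError("bag size must be positive")
    if np.asarray(top_scores).size < 1:
        raise DomainError("need at least one top score")
    p = _controller_probability(top_scores)
    logit = controller.logit(p)
    sig = 1.0 / (1.0 + math.exp(-logit)) if logit >= 0 else \
        math.exp(logit) / (1.0 + math.exp(logit))
    m_new = int(math.floor(sig * k + 0.5))  # round half up
    return int(min(max(m_new, 1), k))


def _project_qv_t(H: Tensor, params: ProjectionParams, head: int = 0):
    Q = H @ params.Wq[head].T
    Vv = H @ params.Wv[head].T
    return Q, Vv


def project_qv(features, params: ProjectionParams, head: int = 0):
    """Row-wise linear query/value maps (no nonlinearity)."""
    H = Tensor(np.atleast_2d(np.asarray(features, dtype=float)))
    if H.shape[1] != params.Wq[head].shape[1]:
        raise DomainError("feature dimension does not match projections")
    Q, Vv = _project_qv_t(H, params, head)
    return Q.data, Vv.data


def _distance_weights_t(Q: Tensor, critical, normalizer: str = "bag") -> Tensor:
    critical = list(critical)
    if len(critical) == 0:
        raise DomainError("critical set must be nonempty")
    k = Q.shape[0]
    if any(not 0 <= c < k for c in critical):
        raise DomainError("critical index out of range")
    Qc = Q.gather_rows(critical)                 # (M, d')
    S = Q @ Qc.T                                 # (k, M)
    col = softmax(S, axis=0)                     # softmax over instances n
    denom = float(k) if normalizer == "bag" else float(len(critical))
    if normalizer not in ("bag", "critical"):
        raise DomainError(f"unknown normalizer {normalizer!r}")
    return col.sum(axis=1, keepdims=True) * (1.0 / denom)   # (k, 1)


def distance_weights(Q, critical, normalizer: str = "bag") -> np.ndarray:
    """Second-layer calibration weights D over all k instances.

    Under the default ("bag", prefactor 1/k) normalizer sum(D) = M/k;
    under "critical" (prefactor 1/M) sum(D) = 1.
    """
    Qt = Tensor(np.atleast_2d(np.asarray(Q, dtype=float)))
    return _distance_weights_t(Qt, critical, normalizer).data.ravel()


def _bag_embed_t(D: Tensor, Vv: Tensor) -> Tensor:
    return D.T @ Vv                               # (1, d')


def bag_embed(D, Vvals) -> BagEmbedding:
    """Weighted sum of value vectors, B = sum_k D_k v_k."""
    D = np.asarray(D, dtype=float).ravel()
    Vvals = np.atleast_2d(np.asarray(Vvals, dtype=float))
    if D.size != Vvals.shape[0]:
        raise DomainError("weight/value length mismatch")
    return BagEmbedding(D @ Vvals)


# ---------------------------------------------------------------------------
# full model
# ---------------------------------------------------------------------------

class MilModel(Module):
    """Extractor + MIL pooling + linear sigmoid head.

    ``pooling='daae'`` is the dual-layer adaptive bag embedding;
    ``pooling='mean'`` is the mean-pooling baseline used for ablations.
    """

    def __init__(self, extractor: C3dFeatureExtractor, pooling: str = "daae",
                 attention_dim: int = 16, proj_dim: int = 32, heads: int = 1,
                 distance_normalizer: str = "bag", seed: int = 0):
        if pooling not in ("daae", "mean"):
            raise DomainError(f"unknown pooling {pooling!r}")
        rng = np.random.default_rng(np.random.SeedSequence([seed, 7]))
        d = extractor.config.feature_dim
        self.extractor = extractor
        self.pooling = pooling
        self.distance_normalizer = distance_normalizer
        if pooling == "daae":
            self.attention = AttentionParams(d, attention_dim, rng)
            self.projection = ProjectionParams(d, proj_dim, rng, heads)
            self.controller = MController(rng)
            self.head = Linear(d + proj_dim, 1, rng)
            self.embed_dim = proj_dim
        else:
            self.head = Linear(d, 1, rng)
            self.embed_dim = d
        self.m_current: int | None = None
        self.m_trajectory: list = []
        self.m_inference: int | None = None
        self.trained = False

    # -- single-bag forward -------------------------------------------------
    def forward_features(self, H: Tensor, update_m_state: bool = False):
        """Instance features (k, d) -> (logit Tensor, embedding Tensor, state)."""
        k = H.shape[0]
        if self.pooling == "mean":
            Z = H.mean(axis=0, keepdims=True)
            logit = self.head(Z)
            return logit, Z, None

        a_t, Z = _attention_pool_t(H, self.attention)
        a = a_t.data.ravel()
        if update_m_state:
            m = self.m_current if self.m_current is not None else math.ceil(k / 2)
        else:
            m = self.m_inference if self.m_inference is not None else \
                (self.m_current if self.m_current is not None else math.ceil(k / 2))
        m = int(min(max(m, 1), k))
        crit = top_m_select(a, m)                     # hard selection, no grad
        m_next = update_m(a[crit], k, self.controller)
        if update_m_state:
            self.m_current = m_next
            self.m_trajectory.append(m_next)

        # average the calibration weights across heads before embedding
        embeds, D_heads = [], []
        for h in range(self.projection.heads):
            Q, Vv = _project_qv_t(H, self.projection, h)
            D = _distance_weights_t(Q, crit, self.distance_normalizer)
            D_heads.append(D)
            embeds.append(_bag_embed_t(D, Vv))
        B = embeds[0] if len(embeds) == 1 else \
            concat(embeds, axis=0).mean(axis=0, keepdims=True)
        D_mean = D_heads[0] if len(D_heads) == 1 else \
            concat(D_heads, axis=1).mean(axis=1, keepdims=True)
        logit = self.head(concat([Z, B], axis=1))
        state = AttentionState(a=a, top_indices=crit, m=m, m_proposed=m_next,
                               D=D_mean.data.ravel(), k=k)
        return logit, B, state

    def forward_volume(self, volume: np.ndarray, update_m_state: bool = False):
        x = Tensor(np.asarray(volume, dtype=float)[None, None])
        H = self.extractor.instance_features(x)[0]
        return self.forward_features(H, update_m_state=update_m_state)


def forward_bag(features: InstanceFeatureSet | np.ndarray, model: MilModel,
                update_m_state: bool = False):
    """Chain the full dual-attention pipeline on one bag of features.

    Returns (BagEmbedding, AttentionState, bag score in (0, 1)).
    """
    feats = features.features if isinstance(features, InstanceFeatureSet) \
        else np.atleast_2d(np.asarray(features, dtype=float))
    H = Tensor(feats)
    logit, B, state = model.forward_features(H, update_m_state=update_m_state)
    score = float(expit(logit.data.ravel()[0]))
    return BagEmbedding(B.data.ravel()), state, score


# ---------------------------------------------------------------------------
# stage-1 training
# ---------------------------------------------------------------------------

@dataclass
class TrainConfig:
    lr: float = 1e-4
    weight_decay: float = 1e-5
    batch_size: int = 4
    max_epochs: int = 100
    patience: int = 15
    val_fraction: float = 0.2
    seed: int = 0
    normalize: bool = True
    log: dict = field(default_factory=dict)


def _stratified_holdout(labels, fraction, rng):
    labels = np.asarray(labels)
    train_idx, val_idx = [], []
    for cls in np.unique(labels):
        idx = np.flatnonzero(labels == cls)
        idx = rng.permutation(idx)
        n_val = max(1, int(math.floor(len(idx) * fraction + 0.5)))
        val_idx.extend(idx[:n_val])
        train_idx.extend(idx[n_val:])
    return np.sort(train_idx), np.sort(val_idx)


def _batch_loss(model: MilModel, volumes, labels, update_m_state: bool):
    x = Tensor(np.asarray(volumes, dtype=float)[:, None])
    feats = model.extractor.instance_features(x)
    losses = []
    for H, y in zip(feats, labels):
        logit, _, _ = model.forward_features(H, update_m_state=update_m_state)
        losses.append(bce_with_logits(logit.reshape(1), float(y)))
    return concat(losses, axis=0).mean()


def train_stage1(volumes, bag_labels, model: MilModel,
                 config: TrainConfig | None = None):
    """Train extractor + attention layers + head with BCE on bag labels.

    Early stopping halts training once the validation loss has not improved
    for the configured patience; the final parameters are kept (on bag-level
    data the validation loss saturates long before the attention layers
    finish sharpening, so a best-snapshot restore would discard them).  The
    per-forward adaptive-M proposals are recorded and their median becomes
    the frozen inference M.  Returns (model, log dict).
    """
    config = config or TrainConfig()
    volumes = np.asarray(volumes, dtype=float)
    bag_labels = np.asarray(bag_labels, dtype=int)
    if volumes.shape[0] == 0:
        raise DomainError("empty cohort")
    if config.normalize:
        volumes = np.stack([minmax_normalize(v).data for v in volumes])

    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 11]))
    tr, va = _stratified_holdout(bag_labels, config.val_fraction, rng)
    params = model.parameters()
    opt = Adam(params, lr=config.lr, weight_decay=config.weight_decay)

    log = {"train_loss": [], "val_loss": [], "m_per_epoch": [],
           "stopped_epoch": None, "best_epoch": None}
    best_val, since_best = np.inf, 0
    for epoch in range(config.max_epochs):
        order = rng.permutation(tr)
        epoch_losses = []
        for lo in range(0, len(order), config.batch_size):
            batch = order[lo:lo + config.batch_size]
            opt.zero_grad()
            loss = _batch_loss(model, volumes[batch], bag_labels[batch],
                               update_m_state=True)
            loss.backward()
            opt.step()
            epoch_losses.append(float(loss.data))
        # freeze M at the running median for evaluation passes
        if model.pooling == "daae" and model.m_trajectory:
            model.m_inference = int(np.median(model.m_trajectory))
        with np.errstate(all="ignore"):
            val_loss = float(_batch_loss(model, volumes[va], bag_labels[va],
                                         update_m_state=False).data)
        log["train_loss"].append(float(np.mean(epoch_losses)))
        log["val_loss"].append(val_loss)
        log["m_per_epoch"].append(model.m_inference)
        if val_loss < best_val - 1e-12:
            best_val, since_best = val_loss, 0
            log["best_epoch"] = epoch + 1
        else:
            since_best += 1
            if since_best >= config.patience:
                log["stopped_epoch"] = epoch + 1
                break
    model.trained = True
    return model, log


def extract_deep_features(model: MilModel, volumes, patient_ids=None,
                          normalize: bool = True) -> FeatureTable:
    """One flattened bag-embedding row per patient."""
    import warnings
    if not model.trained:
        warnings.warn("extracting features from an untrained model "
                      "(random-feature baseline)")
    volumes = np.asarray(volumes, dtype=float)
    rows = []
    for v in volumes:
        vol = minmax_normalize(v).data if normalize else v
        _, B, _ = model.forward_volume(vol, update_m_state=False)
        rows.append(B.data.ravel())
    X = np.vstack(rows)
    names = [f"ct_deep_{j:04d}" for j in range(X.shape[1])]
    ids = patient_ids if patient_ids is not None else \
        np.array([f"P{i:04d}" for i in range(len(volumes))])
    return FeatureTable(np.asarray(ids), pd.DataFrame(X, columns=names),
                        {c: CONTINUOUS for c in names})


# ---------------------------------------------------------------------------
# estimator facade
# ---------------------------------------------------------------------------

class DaaeMilClassifier(BaseEstimator, ClassifierMixin):
    """Bag-level classifier over 3D volumes with MIL attention pooling.

    Parameters follow scikit-learn conventions; ``X`` in :meth:`fit` is an
    (n_patients, H, W, D) array of raw volumes and ``y`` the binary bag
    labels.  ``transform`` returns per-patient deep feature rows
    (the flattened bag embeddings).
    """

    def __init__(self, pooling="daae", widths=(8, 16, 32),
                 pools=((2, 2, 2), (2, 2, 1), (2, 2, 1)), feature_dim=32,
                 attention_dim=16, proj_dim=32, heads=1,
                 distance_normalizer="bag", lr=1e-4, weight_decay=1e-5,
                 batch_size=4, max_epochs=100, patience=15, val_fraction=0.2,
                 random_state=0):
        self.pooling = pooling
        self.widths = widths
        self.pools = pools
        self.feature_dim = feature_dim
        self.attention_dim = attention_dim
        self.proj_dim = proj_dim
        self.heads = heads
        self.distance_normalizer = distance_normalizer
        self.lr = lr
        self.weight_decay = weight_decay
        self.batch_size = batch_size
        self.max_epochs = max_epochs
        self.patience = patience
        self.val_fraction = val_fraction
        self.random_state = random_state

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=int)
        if X.ndim != 4:
            raise DomainError("X must be (n_patients, H, W, D)")
        self.classes_ = np.unique(y)
        cfg = BackboneConfig(widths=tuple(self.widths),
                             pools=tuple(tuple(p) for p in self.pools),
                             feature_dim=self.feature_dim,
                             seed=self.random_state)
        extractor = build_backbone(cfg, input_shape=X.shape[1:])
        model = MilModel(extractor, pooling=self.pooling,
                         attention_dim=self.attention_dim,
                         proj_dim=self.proj_dim, heads=self.heads,
                         distance_normalizer=self.distance_normalizer,
                         seed=self.random_state)
        tcfg = TrainConfig(lr=self.lr, weight_decay=self.weight_decay,
                           batch_size=self.batch_size,
                           max_epochs=self.max_epochs, patience=self.patience,
                           val_fraction=self.val_fraction,
                           seed=self.random_state)
        self.model_, self.train_log_ = train_stage1(X, y, model, tcfg)
        self.m_inference_ = self.model_.m_inference
        return self

    def _scores(self, X):
        check_is_fitted(self, "model_")
        out = []
        for v in np.asarray(X, dtype=float):
            vol = minmax_normalize(v).data
            logit, _, _ = self.model_.forward_volume(vol, update_m_state=False)
            out.append(float(expit(logit.data.ravel()[0])))
        return np.asarray(out)

    def predict_proba(self, X):
        p = self._scores(X)
        return np.column_stack([1 - p, p])

    def decision_function(self, X):
        return self._scores(X)

    def predict(self, X, threshold: float = 0.5):
        return (self._scores(X) >= threshold).astype(int)

    def transform(self, X):
        check_is_fitted(self, "model_")
        return extract_deep_features(self.model_, np.asarray(X, dtype=float)).values

    def attention_state(self, volume) -> AttentionState:
        check_is_fitted(self, "model_")
        vol = minmax_normalize(np.asarray(volume, dtype=float)).data
        _, _, state = self.model_.forward_volume(vol, update_m_state=False)
        return state
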