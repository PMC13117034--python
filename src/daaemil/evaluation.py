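"""Patient-level splitting, cross-validation, metrics and the ablation harness.

All splitting is stratified and executed strictly at the patient level, so
every slice, table row and feature vector belonging to one patient lives
entirely on one side of any split.  AUC is the Mann-Whitney statistic
(ties get half credit) and its confidence interval comes from a stratified
percentile bootstrap.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold

from .exceptions import ConfigurationError, DomainError

__all__ = ["SplitPlan", "EvalReport", "stratified_patient_split", "kfold_plan",
           "compute_metrics", "bootstrap_auc_ci", "run_ablation",
           "export_attention_report", "ABLATION_VARIANTS"]

ABLATION_VARIANTS = ("cd", "rf", "ct-mil", "ct-daae", "fusion-mil", "fusion-daae")


@dataclass
class SplitPlan:
    train_ids: np.ndarray
    test_ids: np.ndarray
    labels: dict
    seed: int
    folds: dict | None = None     # id -> fold index, over train ids


@dataclass
class EvalReport:
    confusion: tuple              # (TP, FP, TN, FN)
    accuracy: float
    precision: float
    recall: float
    f1: float
    auc: float | None
    auc_ci: tuple | None = None

    def as_dict(self) -> dict:
        tp, fp, tn, fn = self.confusion
        out = {"TP": tp, "FP": fp, "TN": tn, "FN": fn,
               "accuracy": self.accuracy, "precision": self.precision,
               "recall": self.recall, "f1": self.f1, "auc": self.auc}
        if self.auc_ci is not None:
            out["auc_ci_low"], out["auc_ci_high"] = self.auc_ci
        return out


def stratified_patient_split(labels, test_fraction: float, seed: int = 0,
                             ids=None) -> SplitPlan:
    """Disjoint stratified train/test split of patient ids.

    Per stratum the test count is round-half-up of stratum_size * fraction.
    """
    labels = np.asarray(labels)
    if not 0 < test_fraction < 1:
        raise DomainError("test_fraction must lie in (0, 1)")
    if ids is None:
        ids = np.arange(len(labels))
    ids = np.asarray(ids)
    rng = np.random.default_rng(seed)
    train_ids, test_ids = [], []
    for cls in np.unique(labels):
        stratum = ids[labels == cls]
        if len(stratum) < 2:
            raise DomainError(f"stratum {cls!r} smaller than 2")
        n_test = int(math.floor(len(stratum) * test_fraction + 0.5))
        n_test = min(max(n_test, 1), len(stratum) - 1)
        perm = rng.permutation(stratum)
        test_ids.extend(perm[:n_test])
        train_ids.extend(perm[n_test:])
    label_map = {i: l for i, l in zip(ids.tolist(), labels.tolist())}
    return SplitPlan(np.sort(np.asarray(train_ids)),
                     np.sort(np.asarray(test_ids)), label_map, seed)


def kfold_plan(train_ids, labels, K: int = 5, seed: int = 0) -> dict:
    """Stratified K-fold assignment over training ids.

    Fold sizes differ by at most one and per-fold class counts stay within
    one of proportionality.
    """
    train_ids = np.asarray(train_ids)
    labels = np.asarray(labels)
    if K > len(train_ids):
        raise DomainError("more folds than patients")
    _, counts = np.unique(labels, return_counts=True)
    if K > counts.min():
        raise DomainError("fold count exceeds the smallest stratum")
    skf = StratifiedKFold(n_splits=K, shuffle=True, random_state=seed)
    assignment = {}
    for fold, (_, val_idx) in enumerate(skf.split(train_ids, labels)):
        for j in val_idx:
            assignment[train_ids[j]] = fold
    return assignment


def compute_metrics(y_true, scores, threshold: float = 0.5,
                    ci: bool = False, ci_reps: int = 2000,
                    ci_seed: int = 0) -> EvalReport:
    """Threshold (>=) classification metrics plus Mann-Whitney AUC."""
    y_true = np.asarray(y_true, dtype=int)
    scores = np.asarray(scores, dtype=float)
    pred = (scores >= threshold).astype(int)
    tp = int(((pred == 1) & (y_true == 1)).sum())
    fp = int(((pred == 1) & (y_true == 0)).sum())
    tn = int(((pred == 0) & (y_true == 0)).sum())
    fn = int(((pred == 0) & (y_true == 1)).sum())
    acc = (tp + tn) / len(y_true)
    prec = tp / (tp + fp) if tp + fp else 0.0
    rec = tp / (tp + fn) if tp + fn else 0.0
    f1 = 2 * prec * rec / (prec + rec) if prec + rec else 0.0
    if len(np.unique(y_true)) < 2:
        raise DomainError(
            "AUC undefined for single-class labels; "
            f"threshold metrics: acc={acc:.3f}")
    auc = float(roc_auc_score(y_true, scores))
    interval = bootstrap_auc_ci(y_true, scores, reps=ci_reps,
                                seed=ci_seed) if ci else None
    return EvalReport((tp, fp, tn, fn), acc, prec, rec, f1, auc, interval)


def bootstrap_auc_ci(y_true, scores, reps: int = 2000, level: float = 0.95,
                     seed: int = 0):
    """Stratified percentile-bootstrap CI for the AUC."""
    y_true = np.asarray(y_true, dtype=int)
    scores = np.asarray(scores, dtype=float)
    if len(np.unique(y_true)) < 2:
        raise DomainError("both classes required for an AUC interval")
    if reps < 100:
        warnings.warn("fewer than 100 bootstrap replicates is unreliable")
    rng = np.random.default_rng(seed)
    pos = np.flatnonzero(y_true == 1)
    neg = np.flatnonzero(y_true == 0)
    stats = np.empty(reps)
    for r in range(reps):
        ip = rng.choice(pos, size=len(pos), replace=True)
        ineg = rng.choice(neg, size=len(neg), replace=True)
        idx = np.concatenate([ip, ineg])
        stats[r] = roc_auc_score(y_true[idx], scores[idx])
    lo = float(np.percentile(stats, 100 * (1 - level) / 2))
    hi = float(np.percentile(stats, 100 * (1 + level) / 2))
    return lo, hi


def export_attention_report(model, volume, patient_id,
                            path=None) -> pd.DataFrame:
    """Per-instance attention table for one patient.

    Columns: instance index, source depth interval, first-layer weight a,
    calibration weight D, and whether the instance was selected as critical.
    """
    from .backbone import minmax_normalize
    if not getattr(model, "trained", False):
        warnings.warn("attention report from an untrained model")
    vol = minmax_normalize(np.asarray(volume, dtype=float)).data
    _, _, state = model.forward_volume(vol, update_m_state=False)
    if state is None:
        raise DomainError("attention reports need the dual-attention pooling")
    prov = model.extractor.provenance(vol.shape[2])
    rows = pd.DataFrame({
        "patient_id": patient_id,
        "instance": np.arange(state.k),
        "depth_start": [p[0] for p in prov],
        "depth_stop": [p[1] for p in prov],
        "attention": state.a,
        "calibration": state.D,
        "selected": [int(i in set(state.top_indices)) for i in range(state.k)],
    })
    if path is not None:
        rows.to_csv(path, index=False)
    return rows


# ---------------------------------------------------------------------------
# ablation harness
# ---------------------------------------------------------------------------

def _tabular_block(table, labels, train_mask, screen_alpha=None, lam="cv", seed=0):
    """Leakage-free screen (optional) + z-score + lasso on the train side.

    Returns the selected-column sub-tables for all patients, or None when
    nothing survives selection.
    """
    from .tabular import (CONTINUOUS, FeatureTable, lasso_fit, select_lambda_cv,
                          univariate_screen, zscore)
    train_tab = FeatureTable(table.patient_ids[train_mask],
                             table.data.iloc[train_mask].reset_index(drop=True),
                             dict(table.kinds))
    y_tr = labels[train_mask]
    candidates = table.columns
    if screen_alpha is not None:
        candidates = univariate_screen(train_tab, y_tr, alpha=screen_alpha).selected
        candidates = [c for c in candidates if table.kind_of(c) == CONTINUOUS]
        if not candidates:
            warnings.warn("screening kept no feature; falling back to all "
                          "continuous columns")
            candidates = [c for c in table.columns
                          if table.kind_of(c) == CONTINUOUS]
    ztr = zscore(train_tab.select(candidates))
    cols = ztr.columns
    if not cols:
        return None
    X = ztr.values
    lam_val = select_lambda_cv(X, y_tr, seed=seed) if lam == "cv" else float(lam)
    result = lasso_fit(X, y_tr, lam_val, columns=cols)
    keep = result.selected_columns
    if not keep:
        warnings.warn("lasso kept no feature; falling back to the screened "
                      "candidate set")
        keep = cols
    # apply train-fold standardization to everybody
    mu = train_tab.data[keep].mean()
    sd = train_tab.data[keep].std(ddof=1)
    frame = (table.data[keep] - mu) / sd
    return FeatureTable(table.patient_ids.copy(), frame,
                        {c: CONTINUOUS for c in keep})


def run_ablation(volumes, clinical, radiomics, bag_labels, variants=None,
                 seed: int = 0, test_fraction: float = 0.2,
                 train_config=None, mlp_config=None, screen_alpha: float = 0.05,
                 models=None, backbone_config=None):
    """Train and evaluate the six standard variants on one shared split.

    Variants: clinical-only (cd), radiomics-only (rf), CT with mean-pooling
    MIL (ct-mil), CT with dual-attention MIL (ct-daae), and the two fused
    models (fusion-mil, fusion-daae).  Pre-trained MIL models can be passed
    via ``models={'daae': ..., 'mean': ...}`` to share stage-1 training.
    Returns (DataFrame of metric rows, SplitPlan, models dict).
    """
    from .daae import (MilModel, TrainConfig, extract_deep_features,
                       train_stage1)
    from .backbone import BackboneConfig, build_backbone
    from .fusion import MlpTrainConfig, fuse, predict, train_mlp

    variants = list(variants or ABLATION_VARIANTS)
    unknown = set(variants) - set(ABLATION_VARIANTS)
    if unknown:
        raise ConfigurationError(f"unknown ablation variants: {sorted(unknown)}")

    bag_labels = np.asarray(bag_labels, dtype=int)
    n = len(bag_labels)
    ids = np.arange(n)
    plan = stratified_patient_split(bag_labels, test_fraction, seed=seed, ids=ids)
    train_mask = np.isin(ids, plan.train_ids)
    test_mask = ~train_mask
    y_tr, y_te = bag_labels[train_mask], bag_labels[test_mask]

    train_config = train_config or TrainConfig(seed=seed)
    mlp_config = mlp_config or MlpTrainConfig(seed=seed)
    models = dict(models or {})

    def get_model(kind):
        if kind not in models:
            if volumes is None:
                raise DomainError("volumes required for CT variants")
            cfg = backbone_config or BackboneConfig(seed=seed)
            model = MilModel(build_backbone(cfg, input_shape=volumes.shape[1:]),
                             pooling="daae" if kind == "daae" else "mean",
                             seed=seed)
            model, _ = train_stage1(volumes[train_mask], y_tr, model, train_config)
            models[kind] = model
        return models[kind]

    def deep_block(kind):
        model = get_model(kind)
        table = extract_deep_features(model, volumes,
                                      patient_ids=np.array([f"P{i:04d}" for i in ids]))
        return _tabular_block(table, bag_labels, train_mask, screen_alpha=None,
                              lam="cv", seed=seed)

    def clinical_block():
        return _tabular_block(clinical, bag_labels, train_mask,
                              screen_alpha=screen_alpha, lam="cv", seed=seed)

    def radiomics_block():
        return _tabular_block(radiomics, bag_labels, train_mask,
                              screen_alpha=None, lam="cv", seed=seed)

    def eval_scores(scores):
        return compute_metrics(y_te, np.asarray(scores)[test_mask])

    cache = {}

    def block(name):
        if name not in cache:
            if name == "cd":
                cache[name] = clinical_block()
            elif name == "rf":
                cache[name] = radiomics_block()
            else:
                cache[name] = deep_block(name)
        return cache[name]

    def mlp_scores(tables_dict):
        fused = fuse(tables_dict.get("clinical"), tables_dict.get("radiomics"),
                     tables_dict.get("deep"), allow_missing=True)
        cfg = MlpTrainConfig(**{**mlp_config.__dict__, "log": {}})
        params = train_mlp(fused.values[train_mask], bag_labels[train_mask], cfg)
        p, _ = predict(params, fused.values)
        return p

    rows = []
    for variant in variants:
        if variant == "cd":
            tables = {"clinical": block("cd")}
        elif variant == "rf":
            tables = {"radiomics": block("rf")}
        elif variant == "ct-mil":
            tables = {"deep": block("mean")}
        elif variant == "ct-daae":
            tables = {"deep": block("daae")}
        elif variant == "fusion-mil":
            tables = {"clinical": block("cd"), "radiomics": block("rf"),
                      "deep": block("mean")}
        else:
            tables = {"clinical": block("cd"), "radiomics": block("rf"),
                      "deep": block("daae")}
        tables = {k: v for k, v in tables.items() if v is not None}
        if not tables:
            raise DomainError(f"no features survive selection for {variant!r}")
        report = eval_scores(mlp_scores(tables))
        row = {"variant": variant, **report.as_dict()}
        rows.append(row)
    table = pd.DataFrame(rows)
    table.attrs["test_ids"] = plan.test_ids.tolist()
    return table, plan, models
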