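"""Tabular feature handling: standardization, univariate screening and
L1-penalized (lasso) feature selection.

The selection chain mirrors the usual radiomics workflow: continuous
features are z-scored, screened by a two-sample t-test (chi-square for
categorical features), and the survivors enter a lasso whose penalty is
chosen by K-fold cross-validated mean squared error.  The lasso objective is

    (1 / 2M) * sum_m (y_m - b0 - x_m . beta)^2 + lam * ||beta||_1

with M the sample count and an unpenalized intercept; scikit-learn's
coordinate-descent ``Lasso`` minimizes exactly this form and backs
:func:`lasso_fit`.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.linear_model import Lasso
from sklearn.model_selection import KFold
from sklearn.utils.validation import check_is_fitted

from .exceptions import ConfigurationError, DomainError

__all__ = [
    "FeatureTable", "ScreenResult", "LassoResult", "RadiomicsSchema",
    "zscore", "univariate_screen", "lasso_fit", "select_lambda_cv",
    "default_lambda_grid", "enumerate_radiomics_space", "extract_radiomics",
    "ZScoreScaler", "UnivariateScreener", "LassoSelector",
]

CONTINUOUS = "continuous"
CATEGORICAL = "categorical"


@dataclass
class FeatureTable:
    """A patients x features table with per-column kind annotations."""

    patient_ids: np.ndarray
    data: pd.DataFrame
    kinds: dict = field(default_factory=dict)

    def __post_init__(self):
        self.patient_ids = np.asarray(self.patient_ids)
        if len(self.patient_ids) != len(self.data):
            raise DomainError("patient id count does not match row count")
        if len(np.unique(self.patient_ids)) != len(self.patient_ids):
            raise DomainError("duplicate patient ids")
        for col in self.data.columns:
            self.kinds.setdefault(col, CONTINUOUS)

    @property
    def columns(self) -> list:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    def kind_of(self, col) -> str:
        return self.kinds[col]

    def select(self, cols) -> "FeatureTable":
        return FeatureTable(self.patient_ids.copy(), self.data[list(cols)].copy(),
                            {c: self.kinds[c] for c in cols})

    def to_csv(self, path):
        out = self.data.copy()
        out.insert(0, "patient_id", self.patient_ids)
        out.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, kinds=None) -> "FeatureTable":
        df = pd.read_csv(path)
        if "patient_id" not in df.columns:
            raise DomainError("CSV must carry a patient_id first column")
        ids = df["patient_id"].to_numpy()
        df = df.drop(columns=["patient_id"])
        return cls(ids, df, dict(kinds or {}))


@dataclass
class ScreenResult:
    pvalues: dict
    tests: dict
    alpha: float
    selected: list


@dataclass
class LassoResult:
    intercept: float
    coef: np.ndarray
    lam: float
    n_samples: int
    selected: list
    columns: list | None = None

    @property
    def selected_columns(self) -> list:
        if self.columns is None:
            return list(self.selected)
        return [self.columns[j] for j in self.selected]


# ---------------------------------------------------------------------------
# standardization
# ---------------------------------------------------------------------------

def zscore(table: FeatureTable) -> FeatureTable:
    """Standardize continuous columns to mean 0 and sample SD 1 (ddof=1).

    Categorical columns pass through untouched.  Zero-variance continuous
    columns are dropped with a warning.
    """
    if len(table.data) < 2:
        raise DomainError("z-scoring needs at least two rows")
    out = {}
    kinds = {}
    for col in table.columns:
        x = table.data[col].to_numpy(dtype=float)
        if table.kind_of(col) == CATEGORICAL:
            out[col] = table.data[col].to_numpy()
            kinds[col] = CATEGORICAL
            continue
        sd = x.std(ddof=1)
        if sd == 0.0 or not np.isfinite(sd):
            warnings.warn(f"dropping zero-variance column {col!r}")
            continue
        out[col] = (x - x.mean()) / sd
        kinds[col] = CONTINUOUS
    return FeatureTable(table.patient_ids.copy(), pd.DataFrame(out), kinds)


class ZScoreScaler(BaseEstimator, TransformerMixin):
    """Array z-scoring with sample (ddof=1) standard deviation."""

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        self.mean_ = X.mean(axis=0)
        self.scale_ = X.std(axis=0, ddof=1)
        self.keep_ = self.scale_ > 0
        if not self.keep_.all():
            warnings.warn("dropping zero-variance columns")
        return self

    def transform(self, X):
        check_is_fitted(self, "mean_")
        X = np.asarray(X, dtype=float)
        Z = (X - self.mean_)[:, self.keep_] / self.scale_[self.keep_]
        return Z


# ---------------------------------------------------------------------------
# univariate screening
# ---------------------------------------------------------------------------

def univariate_screen(table: FeatureTable, labels, alpha: float = 0.05,
                      inclusive: bool = False, welch: bool = False,
                      continuity: bool = False) -> ScreenResult:
    """Per-feature association test against a binary outcome.

    Continuous columns get a two-sample t-test (pooled variance by default,
    Welch optional); categorical columns get a chi-square test on the
    class x level contingency table (no continuity correction by default).
    Selection keeps features with p < alpha (p <= alpha when ``inclusive``).
    """
    labels = np.asarray(labels)
    if len(labels) != len(table.data):
        raise DomainError("labels do not align with table rows")
    classes = np.unique(labels)
    if len(classes) < 2:
        raise DomainError("both classes must be present for screening")
    pos = labels == classes.max()
    pvalues, tests = {}, {}
    for col in table.columns:
        x = table.data[col].to_numpy()
        if table.kind_of(col) == CONTINUOUS:
            a, b = x[pos].astype(float), x[~pos].astype(float)
            if a.std(ddof=1) == 0 and b.std(ddof=1) == 0 and a.mean() == b.mean():
                p = 1.0  # identical groups: no evidence of association
            else:
                p = stats.ttest_ind(a, b, equal_var=not welch).pvalue
            tests[col] = "t"
        else:
            ct = pd.crosstab(labels, x).to_numpy()
            if (ct.sum(axis=0) == 0).any() or (ct.sum(axis=1) == 0).any() or ct.shape[1] < 2:
                warnings.warn(f"skipping degenerate contingency table for {col!r}")
                pvalues[col] = np.nan
                tests[col] = "chi-square"
                continue
            p = stats.chi2_contingency(ct, correction=continuity)[1]
            tests[col] = "chi-square"
        pvalues[col] = float(p)
    if inclusive:
        selected = [c for c in table.columns
                    if np.isfinite(pvalues[c]) and pvalues[c] <= alpha]
    else:
        selected = [c for c in table.columns
                    if np.isfinite(pvalues[c]) and pvalues[c] < alpha]
    return ScreenResult(pvalues, tests, alpha, selected)


class UnivariateScreener(BaseEstimator, TransformerMixin):
    """Column screener over a numeric matrix (all-continuous by default)."""

    def __init__(self, alpha=0.05, kinds=None, inclusive=False, welch=False):
        self.alpha = alpha
        self.kinds = kinds
        self.inclusive = inclusive
        self.welch = welch

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        cols = list(range(X.shape[1]))
        kinds = {j: (self.kinds[j] if self.kinds is not None else CONTINUOUS)
                 for j in cols}
        table = FeatureTable(np.arange(len(X)), pd.DataFrame(X, columns=cols), kinds)
        self.result_ = univariate_screen(table, y, alpha=self.alpha,
                                         inclusive=self.inclusive, welch=self.welch)
        self.support_ = np.zeros(X.shape[1], dtype=bool)
        self.support_[self.result_.selected] = True
        return self

    def transform(self, X):
        check_is_fitted(self, "support_")
        return np.asarray(X, dtype=float)[:, self.support_]

    def get_support(self):
        check_is_fitted(self, "support_")
        return self.support_


# ---------------------------------------------------------------------------
# lasso
# ---------------------------------------------------------------------------

def lasso_fit(X, y, lam: float, columns=None, tol: float = 1e-10,
              max_iter: int = 200000) -> LassoResult:
    """Fit the L1-penalized squared-error objective at a fixed penalty."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if lam < 0:
        raise DomainError("penalty must be non-negative")
    if not (np.isfinite(X).all() and np.isfinite(y).all()):
        raise DomainError("non-finite values in design or response")
    if X.ndim != 2 or len(y) != X.shape[0]:
        raise DomainError("design rows must align with response")
    model = Lasso(alpha=lam, fit_intercept=True, tol=tol, max_iter=max_iter)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model.fit(X, y)
    coef = np.asarray(model.coef_, dtype=float)
    selected = [int(j) for j in np.flatnonzero(coef)]
    return LassoResult(float(model.intercept_), coef, float(lam),
                       int(X.shape[0]), selected,
                       list(columns) if columns is not None else None)


def default_lambda_grid(X, y, n_points: int = 100, ratio: float = 1e-4,
                        always_include: float = 0.002) -> np.ndarray:
    """Log-spaced penalty path from lambda_max down to ratio*lambda_max.

    lambda_max is the smallest penalty that zeroes every coefficient for
    the centered problem; 0.002 is appended so the grid always contains it.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    lam_max = np.abs(X.T @ (y - y.mean())).max() / len(y)
    if lam_max <= 0:
        lam_max = 1.0
    grid = np.geomspace(lam_max, lam_max * ratio, n_points)
    grid = np.unique(np.concatenate([grid, [always_include]]))[::-1]
    return grid


def select_lambda_cv(X, y, K: int = 5, grid=None, seed: int = 0) -> float:
    """Pick the penalty with minimum mean K-fold validation MSE.

    Ties are broken toward the larger penalty (the sparser model).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if K < 2:
        raise DomainError("K must be at least 2")
    if K > len(y):
        raise DomainError("more folds than samples")
    if grid is None:
        grid = default_lambda_grid(X, y)
    grid = np.asarray(list(grid), dtype=float)
    if grid.size == 0:
        raise DomainError("empty penalty grid")
    splits = list(KFold(n_splits=K, shuffle=True, random_state=seed).split(X))
    order = np.argsort(grid)[::-1]          # descending: warm starts follow
    mse = np.zeros((grid.size, K))          # the regularization path
    for f, (tr, va) in enumerate(splits):
        model = Lasso(alpha=float(grid[order[0]]), fit_intercept=True,
                      max_iter=50000, tol=1e-5, warm_start=True)
        for i in order:
            model.set_params(alpha=float(grid[i]))
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                model.fit(X[tr], y[tr])
            resid = y[va] - model.predict(X[va])
            mse[i, f] = float(np.mean(resid ** 2))
    mean_mse = mse.mean(axis=1)
    best = mean_mse.min()
    return float(grid[mean_mse == best].max())


class LassoSelector(BaseEstimator, TransformerMixin):
    """Lasso-based column selector; penalty fixed or chosen by CV."""

    def __init__(self, lam="cv", K=5, grid=None, random_state=0):
        self.lam = lam
        self.K = K
        self.grid = grid
        self.random_state = random_state

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        if self.lam == "cv":
            lam = select_lambda_cv(X, y, K=self.K, grid=self.grid,
                                   seed=self.random_state)
        else:
            lam = float(self.lam)
        self.lambda_ = lam
        self.result_ = lasso_fit(X, y, lam)
        self.support_ = np.zeros(X.shape[1], dtype=bool)
        self.support_[self.result_.selected] = True
        return self

    def transform(self, X):
        check_is_fitted(self, "support_")
        return np.asarray(X, dtype=float)[:, self.support_]

    def get_support(self):
        check_is_fitted(self, "support_")
        return self.support_


# ---------------------------------------------------------------------------
# radiomics feature-space schema
# ---------------------------------------------------------------------------

@dataclass
class RadiomicsSchema:
    """Category counts of the engineered-image-feature space.

    Shape descriptors exist for the original image only; first-order and
    texture families are enumerated once per wavelet sub-band (all 2^3
    high/low-pass combinations along the three axes).
    """

    shape: int = 14
    firstorder: int = 18
    glcm: int = 24
    glrlm: int = 16
    glszm: int = 16
    ngtdm: int = 5
    gldm: int = 14
    wavelet_axes: int = 3

    @property
    def texture_total(self) -> int:
        return self.glcm + self.glrlm + self.glszm + self.ngtdm + self.gldm

    @property
    def wavelet_subbands(self) -> list:
        return ["".join(c) for c in itertools.product("LH", repeat=self.wavelet_axes)]

    @property
    def total(self) -> int:
        return self.shape + len(self.wavelet_subbands) * (self.firstorder
                                                          + self.texture_total)


def enumerate_radiomics_space(schema: RadiomicsSchema | None = None) -> list:
    """Emit one deterministic identifier per feature in the schema."""
    schema = schema or RadiomicsSchema()
    for count in (schema.shape, schema.firstorder, schema.glcm, schema.glrlm,
                  schema.glszm, schema.ngtdm, schema.gldm):
        if count < 0:
            raise ConfigurationError("category counts must be non-negative")
    names = [f"original_shape_{i:02d}" for i in range(1, schema.shape + 1)]
    per_band = ([("firstorder", i) for i in range(1, schema.firstorder + 1)]
                + [("glcm", i) for i in range(1, schema.glcm + 1)]
                + [("glrlm", i) for i in range(1, schema.glrlm + 1)]
                + [("glszm", i) for i in range(1, schema.glszm + 1)]
                + [("ngtdm", i) for i in range(1, schema.ngtdm + 1)]
                + [("gldm", i) for i in range(1, schema.gldm + 1)])
    for band in schema.wavelet_subbands:
        names.extend(f"wavelet-{band}_{cat}_{i:02d}" for cat, i in per_band)
    if len(set(names)) != len(names):
        raise ConfigurationError("feature identifiers are not unique")
    return names


def extract_radiomics(volume, mask):
    """Adapter hook for image-based engineered-feature extraction.

    Computing these features from real volumes is delegated to external
    tooling; this package only fixes the feature-space schema and provides
    synthetic feature tables for testing.
    """
    raise NotImplementedError(
        "image-based radiomics extraction is delegated to an external tool; "
        "plug a FeatureTable produced by such a tool into the selection chain")
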