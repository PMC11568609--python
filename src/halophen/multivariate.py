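"""Multivariate statistics: correlation, PCA, and discriminant classification.

This layer mirrors the classical phenotyping workflow: a Pearson correlation
matrix with t-based significance, PCA on the correlation matrix (standardized
variables) with eigenvalues, factor loadings and per-variable contributions,
and a linear ("multivariate") discriminant classifier with pooled
within-class covariance, class-size-proportional priors, confusion matrices
and leave-one-out cross-validation.
"""

from __future__ import annotations

import dataclasses
import warnings
from decimal import ROUND_HALF_UP, Decimal
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ConfusionMatrix",
    "CorrelationPCA",
    "PooledCovarianceLDA",
    "pearson_matrix",
    "pca",
    "lda_fit",
    "lda_classify",
    "loo_cross_validate",
    "accuracy_from_matrix",
]


def _round2(x: float) -> float:
    """Round half-up to 2 decimals, matching tabular percent reporting."""
    return float(Decimal(repr(float(x))).quantize(Decimal("0.01"), ROUND_HALF_UP))


def _numeric(table: pd.DataFrame, columns: Sequence[str]) -> np.ndarray:
    missing = [c for c in columns if c not in table.columns]
    if missing:
        raise ValueError(f"missing columns: {missing}")
    X = table.loc[:, list(columns)].to_numpy(dtype=float)
    if np.isnan(X).any():
        raise ValueError("missing values in analysis columns")
    return X


def pearson_matrix(
    table: pd.DataFrame, columns: Sequence[str], alpha: float = 0.05
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Pearson correlation matrix with two-sided p-values.

    Returns ``(r, p, significant)`` DataFrames indexed by the column names.
    P-values come from the t-distribution with n−2 degrees of freedom;
    ``significant`` flags |r| different from 0 at the given alpha.  A
    zero-variance column makes its correlations undefined and is rejected.
    """
    X = _numeric(table, columns)
    n = X.shape[0]
    if n < 3:
        raise ValueError("need at least 3 rows for correlation p-values")
    sd = X.std(axis=0, ddof=1)
    constant = [c for c, s in zip(columns, sd) if s == 0]
    if constant:
        raise ValueError(f"zero-variance columns have undefined correlation: {constant}")
    r = np.corrcoef(X, rowvar=False)
    r = np.clip(r, -1.0, 1.0)
    with np.errstate(divide="ignore"):
        t = r * np.sqrt((n - 2) / (1.0 - r**2))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    np.fill_diagonal(p, 0.0)
    idx = list(columns)
    rdf = pd.DataFrame(r, index=idx, columns=idx)
    pdf = pd.DataFrame(p, index=idx, columns=idx)
    return rdf, pdf, pdf <= alpha


class CorrelationPCA:
    """PCA of the correlation matrix of standardized variables.

    Fitted attributes
    -----------------
    eigenvalues_ : descending eigenvalues; they sum to the number of variables
    variance_percent_ : 100·eigenvalue/p per component
    loadings_ : DataFrame (variables × components) of eigenvector·sqrt(eigenvalue)
    contributions_ : DataFrame of 100·loading²/eigenvalue; columns sum to 100
    """

    def get_params(self, deep: bool = True) -> dict:
        return {}

    def set_params(self, **params) -> "CorrelationPCA":
        return self

    def fit(self, table: pd.DataFrame, columns: Sequence[str] | None = None):
        columns = list(columns if columns is not None else table.columns)
        X = _numeric(table, columns)
        n, p = X.shape
        if p < 2:
            raise ValueError("PCA needs at least 2 variables")
        if n <= p:
            raise ValueError("PCA needs more rows than variables")
        sd = X.std(axis=0, ddof=1)
        if np.any(sd == 0):
            bad = [c for c, s in zip(columns, sd) if s == 0]
            raise ValueError(f"constant columns cannot be standardized: {bad}")
        self.mean_ = X.mean(axis=0)
        self.scale_ = sd
        corr = np.corrcoef(X, rowvar=False)
        eigval, eigvec = np.linalg.eigh(corr)
        order = np.argsort(eigval)[::-1]
        eigval = np.clip(eigval[order], 0.0, None)
        eigvec = eigvec[:, order]
        # deterministic sign: largest-magnitude element of each axis positive
        flip = np.sign(eigvec[np.argmax(np.abs(eigvec), axis=0), np.arange(p)])
        eigvec = eigvec * np.where(flip == 0, 1.0, flip)
        comps = [f"PC{k + 1}" for k in range(p)]
        loadings = eigvec * np.sqrt(eigval)
        with np.errstate(divide="ignore", invalid="ignore"):
            contrib = np.where(eigval > 0, 100.0 * loadings**2 / eigval, 0.0)
        self.columns_ = columns
        self.eigenvalues_ = eigval
        self.variance_percent_ = 100.0 * eigval / p
        self.components_ = eigvec
        self.loadings_ = pd.DataFrame(loadings, index=columns, columns=comps)
        self.contributions_ = pd.DataFrame(contrib, index=columns, columns=comps)
        return self

    def transform(self, table: pd.DataFrame) -> np.ndarray:
        """Project rows onto the principal axes (standardized scores)."""
        X = _numeric(table, self.columns_)
        return (X - self.mean_) / self.scale_ @ self.components_

    def fit_transform(self, table: pd.DataFrame, columns=None) -> np.ndarray:
        return self.fit(table, columns).transform(table)


def pca(table: pd.DataFrame, columns: Sequence[str]) -> CorrelationPCA:
    """Fit a correlation-matrix PCA (thin wrapper)."""
    return CorrelationPCA().fit(table, columns)


@dataclasses.dataclass
class ConfusionMatrix:
    """Square true × predicted count matrix with class labels."""

    counts: np.ndarray
    labels: tuple[str, ...]

    def __post_init__(self):
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2 or self.counts.shape[0] != self.counts.shape[1]:
            raise ValueError("confusion matrix must be square")
        if self.counts.shape[0] != len(self.labels):
            raise ValueError("label count must match matrix size")
        if (self.counts < 0).any():
            raise ValueError("counts must be non-negative")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=list(self.labels), columns=list(self.labels))


def accuracy_from_matrix(m: ConfusionMatrix) -> tuple[float, dict[str, float]]:
    """Overall and per-class percent correct, rounded half-up to 2 decimals.

    Overall = 100·trace/total; per-class = 100·diagonal/row-sum (NaN for an
    empty row, where the class rate is undefined).
    """
    counts = np.asarray(m.counts, dtype=float)
    total = counts.sum()
    if total == 0:
        raise ValueError("empty confusion matrix")
    overall = _round2(100.0 * np.trace(counts) / total)
    per_class = {}
    for i, lab in enumerate(m.labels):
        row = counts[i].sum()
        per_class[lab] = _round2(100.0 * counts[i, i] / row) if row > 0 else float("nan")
    return overall, per_class


class PooledCovarianceLDA:
    """Linear discriminant classifier with pooled within-class covariance.

    The classical Gaussian discriminant with a shared covariance matrix:
    class k scores  δ_k(x) = xᵀΣ⁻¹μ_k − ½μ_kᵀΣ⁻¹μ_k + log π_k,  with priors
    π_k proportional to class sizes.  A singular pooled covariance is ridge-
    regularized by 1e-6·trace(Σ)/p on the diagonal, with a warning.

    Fitted attributes: ``classes_``, ``means_``, ``covariance_``, ``priors_``,
    ``coef_``, ``intercept_``, ``feature_names_``.
    """

    def __init__(self, ridge: float = 1e-6):
        self.ridge = ridge

    def get_params(self, deep: bool = True) -> dict:
        return {"ridge": self.ridge}

    def set_params(self, **params) -> "PooledCovarianceLDA":
        for k, v in params.items():
            if not hasattr(self, k):
                raise ValueError(f"unknown parameter {k!r}")
            setattr(self, k, v)
        return self

    def fit(self, X, y, feature_names: Sequence[str] | None = None):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        if X.ndim != 2:
            raise ValueError("X must be 2-D")
        if np.isnan(X).any():
            raise ValueError("missing values in features")
        classes, y_idx = np.unique(y, return_inverse=True)
        if classes.size < 2:
            raise ValueError("discriminant analysis needs at least 2 classes")
        n, p = X.shape
        counts = np.bincount(y_idx, minlength=classes.size)
        if counts.min() < 2:
            small = classes[counts < 2]
            raise ValueError(f"each class needs at least 2 rows; too small: {list(small)}")
        means = np.vstack([X[y_idx == k].mean(axis=0) for k in range(classes.size)])
        centred = X - means[y_idx]
        cov = centred.T @ centred / (n - classes.size)
        # ridge fallback for a singular pooled covariance
        try:
            prec = np.linalg.inv(cov)
            if not np.all(np.isfinite(prec)):
                raise np.linalg.LinAlgError
            cond = np.linalg.cond(cov)
            if cond > 1e12:
                raise np.linalg.LinAlgError
        except np.linalg.LinAlgError:
            warnings.warn(
                "singular pooled covariance; applying ridge regularization",
                RuntimeWarning,
                stacklevel=2,
            )
            cov = cov + self.ridge * (np.trace(cov) / p) * np.eye(p)
            prec = np.linalg.inv(cov)
        priors = counts / n
        self.classes_ = classes
        self.means_ = means
        self.covariance_ = cov
        self.priors_ = priors
        self.coef_ = means @ prec
        self.intercept_ = -0.5 * np.einsum("kp,kp->k", self.coef_, means) + np.log(priors)
        self.feature_names_ = None if feature_names is None else list(feature_names)
        return self

    def decision_function(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        return X @ self.coef_.T + self.intercept_

    def predict(self, X) -> np.ndarray:
        return self.classes_[np.argmax(self.decision_function(X), axis=1)]

    def predict_proba(self, X) -> np.ndarray:
        scores = self.decision_function(X)
        scores -= scores.max(axis=1, keepdims=True)
        expd = np.exp(scores)
        return expd / expd.sum(axis=1, keepdims=True)

    def score(self, X, y) -> float:
        return float(np.mean(self.predict(X) == np.asarray(y)))

    def confusion(self, X, y) -> ConfusionMatrix:
        """Confusion matrix (true × predicted) over the model's classes."""
        pred = self.predict(X)
        labels = tuple(str(c) for c in self.classes_)
        lut = {c: i for i, c in enumerate(self.classes_)}
        counts = np.zeros((len(labels), len(labels)), dtype=int)
        for t, q in zip(np.asarray(y), pred):
            if t not in lut:
                raise ValueError(f"unknown true label {t!r}")
            counts[lut[t], lut[q]] += 1
        return ConfusionMatrix(counts, labels)


def _xy(table: pd.DataFrame, feature_columns, label_column):
    X = _numeric(table, feature_columns)
    if label_column not in table.columns:
        raise ValueError(f"missing label column {label_column!r}")
    return X, table[label_column].to_numpy()


def lda_fit(
    table: pd.DataFrame, feature_columns: Sequence[str], label_column: str
) -> PooledCovarianceLDA:
    """Fit the discriminant classifier on named feature columns."""
    X, y = _xy(table, feature_columns, label_column)
    return PooledCovarianceLDA().fit(X, y, feature_names=feature_columns)


def lda_classify(
    model: PooledCovarianceLDA, rows: pd.DataFrame
) -> tuple[np.ndarray, pd.DataFrame]:
    """Predicted labels and per-class posteriors for new rows."""
    if model.feature_names_ is None:
        X = np.asarray(rows, dtype=float)
    else:
        X = _numeric(rows, model.feature_names_)
    posteriors = pd.DataFrame(
        model.predict_proba(X), columns=[str(c) for c in model.classes_]
    )
    return model.predict(X), posteriors


def loo_cross_validate(
    table: pd.DataFrame, feature_columns: Sequence[str], label_column: str
) -> ConfusionMatrix:
    """Leave-one-out cross-validation confusion matrix.

    Each row is predicted by a model trained on all other rows; a fold that
    would lose a whole class (a singleton class) is an error.
    """
    X, y = _xy(table, feature_columns, label_column)
    classes, y_idx = np.unique(y, return_inverse=True)
    counts = np.bincount(y_idx, minlength=classes.size)
    if counts.min() < 2:
        raise ValueError("leave-one-out would drop a singleton class entirely")
    n = X.shape[0]
    labels = tuple(str(c) for c in classes)
    lut = {c: i for i, c in enumerate(classes)}
    cm = np.zeros((classes.size, classes.size), dtype=int)
    for i in range(n):
        keep = np.ones(n, dtype=bool)
        keep[i] = False
        model = PooledCovarianceLDA().fit(X[keep], y[keep])
        pred = model.predict(X[i : i + 1])[0]
        cm[lut[y[i]], lut[pred]] += 1
    return ConfusionMatrix(cm, labels)
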