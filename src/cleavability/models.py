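"""Susceptibility scoring models and their evaluation.

The scorer is two-class linear discriminant analysis: class means, a pooled
within-class covariance (maximum-likelihood form, so the fit depends on the
data only through sufficient statistics), and a log prior ratio. The
posterior probability of cleavage is the logistic of the linear discriminant

    w = Sigma^-1 (mu1 - mu0),   b = -(mu0 + mu1)' w / 2 + log(n1 / n0),
    p(x) = 1 / (1 + exp(-(w'x + b))).

A small ridge on the covariance keeps it invertible in the presence of the
one-hot secondary-structure binaries. Quality is the area under the ROC
curve, equal to the Mann-Whitney probability that a random cleaved bond
outscores a random uncleaved one. Cross-validation is grouped by structure:
normalization bounds and the model are fitted on training folds only, and
each test fold is scored in full (all of its negatives), so training-time
negative sampling ratios remain comparable.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.metrics import auc as _trapezoid_auc
from sklearn.metrics import roc_curve
from sklearn.naive_bayes import GaussianNB

from .dataset import group_kfold
from .features import NormalizationBounds, build_feature_vectors, fit_normalization

__all__ = [
    "LDAModel",
    "RocResult",
    "lda_fit",
    "lda_predict",
    "roc_auc",
    "LDAScorer",
    "GaussianNBScorer",
    "SCORERS",
    "cross_validate",
    "ratio_sweep",
    "save_model",
    "load_model",
]


@dataclass
class LDAModel:
    mu0: np.ndarray
    mu1: np.ndarray
    covariance: np.ndarray  # pooled within-class, ridge-regularized
    log_prior_ratio: float  # log(n1 / n0)
    feature_names: list[str]
    bounds: NormalizationBounds | None = None

    @property
    def w(self) -> np.ndarray:
        return np.linalg.solve(self.covariance, self.mu1 - self.mu0)

    @property
    def b(self) -> float:
        return float(-0.5 * (self.mu0 + self.mu1) @ self.w + self.log_prior_ratio)


def lda_fit(
    X: np.ndarray,
    y: np.ndarray,
    ridge: float = 1e-6,
    feature_names: list[str] | None = None,
    bounds: NormalizationBounds | None = None,
) -> LDAModel:
    """Fit two-class LDA with a ridge-regularized pooled covariance."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y).astype(int)
    if X.ndim != 2 or len(X) != len(y):
        raise ValueError("X must be 2-D with one label per row")
    if not np.all(np.isfinite(X)):
        raise ValueError("missing or non-finite feature values")
    classes = np.unique(y)
    if set(classes) != {0, 1}:
        raise ValueError("both classes (0 and 1) must be present")
    X0, X1 = X[y == 0], X[y == 1]
    mu0, mu1 = X0.mean(axis=0), X1.mean(axis=0)
    n = len(X)
    scatter = (X0 - mu0).T @ (X0 - mu0) + (X1 - mu1).T @ (X1 - mu1)
    cov = scatter / n + ridge * np.eye(X.shape[1])
    # symmetry is exact up to floating error; enforce it
    cov = 0.5 * (cov + cov.T)
    if not np.all(np.isfinite(np.linalg.solve(cov, mu1 - mu0))):
        raise np.linalg.LinAlgError("singular pooled covariance after ridge")
    return LDAModel(
        mu0=mu0,
        mu1=mu1,
        covariance=cov,
        log_prior_ratio=float(np.log(len(X1) / len(X0))),
        feature_names=list(feature_names) if feature_names else
        [f"f{i}" for i in range(X.shape[1])],
        bounds=bounds,
    )


def lda_predict(model: LDAModel, X: np.ndarray) -> np.ndarray:
    """Posterior cleavage probabilities in (0, 1)."""
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[1] != len(model.mu0):
        raise ValueError(
            f"feature dimension {X.shape[1] if X.ndim == 2 else X.shape} does not "
            f"match model dimension {len(model.mu0)}"
        )
    z = X @ model.w + model.b
    return 1.0 / (1.0 + np.exp(-z))


@dataclass
class RocResult:
    fpr: np.ndarray
    tpr: np.ndarray
    auc: float


def roc_auc(scores: np.ndarray, labels: np.ndarray) -> RocResult:
    """ROC curve and its trapezoidal area.

    Equals the Mann-Whitney statistic: the fraction of positive-negative
    pairs where the positive outscores the negative, ties counted half.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    if len(set(labels)) < 2:
        raise ValueError("both classes required to compute a ROC curve")
    fpr, tpr, _ = roc_curve(labels, scores, drop_intermediate=False)
    return RocResult(fpr=fpr, tpr=tpr, auc=float(_trapezoid_auc(fpr, tpr)))


# ---------------------------------------------------------------------------
# Pluggable scorers
# ---------------------------------------------------------------------------

class LDAScorer:
    """Default scorer: the LDA model above."""

    def __init__(self, ridge: float = 1e-6):
        self.ridge = ridge
        self.model: LDAModel | None = None

    def fit(self, X, y, feature_names=None, bounds=None):
        self.model = lda_fit(X, y, ridge=self.ridge, feature_names=feature_names,
                             bounds=bounds)
        return self

    def score(self, X) -> np.ndarray:
        if self.model is None:
            raise RuntimeError("scorer not fitted")
        return lda_predict(self.model, X)


class GaussianNBScorer:
    """Gaussian naive-Bayes alternative (independent-feature baseline)."""

    def __init__(self):
        self._nb = GaussianNB()
        self._fitted = False

    def fit(self, X, y, feature_names=None, bounds=None):
        self._nb.fit(np.asarray(X, dtype=float), np.asarray(y).astype(int))
        self._fitted = True
        return self

    def score(self, X) -> np.ndarray:
        if not self._fitted:
            raise RuntimeError("scorer not fitted")
        return self._nb.predict_proba(np.asarray(X, dtype=float))[:, 1]


SCORERS = {"lda": LDAScorer, "gnb": GaussianNBScorer}


# ---------------------------------------------------------------------------
# Cross-validation
# ---------------------------------------------------------------------------

def _normalize_fold(sub: pd.DataFrame, bounds, feature_columns, source_kind,
                    bfactor_mode) -> pd.DataFrame:
    norm = build_feature_vectors(sub, bounds, source_kind=source_kind,
                                 bfactor_mode=bfactor_mode)
    norm = norm[norm["complete"]].copy()
    kept = sub.loc[sub["complete"].to_numpy(dtype=bool)]
    norm["label"] = kept["label"].to_numpy()
    norm["group"] = kept["group"].to_numpy()
    return norm


def _fit_fold_bounds(train: pd.DataFrame, bfactor_mode: str) -> NormalizationBounds:
    ok = train["complete"].to_numpy(dtype=bool)
    raw = {
        "rel_acc": train.loc[ok, "rel_acc_raw"].to_numpy(),
        "loop_len": train.loc[ok, "loop_len_raw"].to_numpy(),
    }
    if bfactor_mode == "per_corpus":
        raw["bfactor"] = train.loc[ok, "bfactor_raw"].to_numpy()
    return fit_normalization(raw)


def cross_validate(
    table: pd.DataFrame,
    feature_columns: list[str],
    k: int = 10,
    neg_ratio: float | str = 1.0,
    seed: int = 0,
    scorer: str = "lda",
    source_kind: str = "experimental",
    bfactor_mode: str = "per_structure",
    row_level: bool = False,
) -> dict:
    """Grouped k-fold cross-validated AUC.

    ``table`` carries raw (unnormalized) features plus ``label`` and ``group``
    columns. Per fold, normalization bounds and the scorer are fitted on
    training rows only; training negatives are subsampled to ``neg_ratio``
    negatives per positive; the test fold is evaluated in full. With
    ``row_level=True`` folds partition rows instead of structures (kept for
    comparability with ungrouped protocols).
    """
    groups = (np.arange(len(table)) if row_level else table["group"].to_numpy())
    fold_aucs = []
    rng = np.random.default_rng(seed)
    for fold_i, (train_idx, test_idx) in enumerate(group_kfold(groups, k=k, seed=seed)):
        train = table.iloc[train_idx]
        test = table.iloc[test_idx]
        assert not set(train["group"]) & set(test["group"]) or row_level, \
            "leakage: group present in both train and test"
        if train["label"].nunique() < 2 or test["label"].nunique() < 2:
            continue
        bounds = _fit_fold_bounds(train, bfactor_mode)
        norm_train = _normalize_fold(train, bounds, feature_columns, source_kind,
                                     bfactor_mode)
        norm_test = _normalize_fold(test, bounds, feature_columns, source_kind,
                                    bfactor_mode)
        pos = norm_train[norm_train["label"] == 1]
        neg = norm_train[norm_train["label"] == 0]
        if neg_ratio != "all":
            n_neg = min(int(round(float(neg_ratio) * len(pos))), len(neg))
            take = rng.choice(len(neg), size=n_neg, replace=False)
            neg = neg.iloc[np.sort(take)]
        fit_df = pd.concat([pos, neg], ignore_index=True)
        sc = SCORERS[scorer]() if isinstance(scorer, str) else scorer()
        sc.fit(fit_df[feature_columns].to_numpy(), fit_df["label"].to_numpy(),
               feature_names=list(feature_columns), bounds=bounds)
        test_scores = sc.score(norm_test[feature_columns].to_numpy())
        fold_aucs.append(roc_auc(test_scores, norm_test["label"].to_numpy()).auc)
    if not fold_aucs:
        raise ValueError("no fold had both classes; cannot cross-validate")
    return {
        "fold_aucs": fold_aucs,
        "mean_auc": float(np.mean(fold_aucs)),
        "median_auc": float(np.median(fold_aucs)),
        "k": k,
        "neg_ratio": neg_ratio,
        "seed": seed,
        "scorer": scorer if isinstance(scorer, str) else scorer.__name__,
    }


def ratio_sweep(
    table: pd.DataFrame,
    feature_columns: list[str],
    ratios=(1.0, 2.0, 5.0, 10.0),
    k: int = 10,
    seeds=(0, 1, 2),
    **kwargs,
) -> pd.DataFrame:
    """Mean CV AUC per training positives:negatives ratio, across seeds.

    The evaluation set is the full test fold at every ratio, so differences
    reflect the training composition alone.
    """
    rows = []
    for ratio in ratios:
        for seed in seeds:
            res = cross_validate(table, feature_columns, k=k, neg_ratio=ratio,
                                 seed=seed, **kwargs)
            rows.append({"neg_ratio": ratio, "seed": seed,
                         "mean_auc": res["mean_auc"],
                         "median_auc": res["median_auc"]})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Serialization
# ---------------------------------------------------------------------------

_FORMAT_VERSION = 1


def save_model(model: LDAModel, path: str | Path) -> None:
    doc = {
        "format_version": _FORMAT_VERSION,
        "kind": "lda",
        "mu0": model.mu0.tolist(),
        "mu1": model.mu1.tolist(),
        "covariance": model.covariance.tolist(),
        "log_prior_ratio": model.log_prior_ratio,
        "feature_names": model.feature_names,
        "bounds": model.bounds.to_dict() if model.bounds else None,
    }
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1, sort_keys=True)
        fh.write("\n")


def load_model(path: str | Path) -> LDAModel:
    with open(path) as fh:
        doc = json.load(fh)
    if doc.get("kind") != "lda":
        raise ValueError(f"not an LDA model file: {path}")
    return LDAModel(
        mu0=np.array(doc["mu0"]),
        mu1=np.array(doc["mu1"]),
        covariance=np.array(doc["covariance"]),
        log_prior_ratio=float(doc["log_prior_ratio"]),
        feature_names=list(doc["feature_names"]),
        bounds=NormalizationBounds.from_dict(doc["bounds"]) if doc["bounds"] else None,
    )
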