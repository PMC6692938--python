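"""Carcinoma-vs-papilloma prediction with nested leave-one-out validation.

The key methodological point is leakage control: inside every LOO fold the
differential-methylation signature is re-derived from the 33 retained
samples only, optional correlation-based feature selection (CFS) runs on
that fold signature, and the model is trained before the held-out sample is
ever touched. Performance is aggregated over pooled held-out scores.

CFS subset merit is ``k * r_cf / sqrt(k + k(k-1) * r_ff)`` with ``r_cf`` the
mean absolute feature-class correlation of the subset and ``r_ff`` the mean
absolute pairwise feature-feature correlation; the search is forward
best-first with a bounded non-improvement stop. Correlations are absolute
Pearson (point-biserial against the binary class).
"""

from __future__ import annotations

import heapq
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score
from sklearn.naive_bayes import GaussianNB

from .diffmeth import (CARCINOMA, PAPILLOMA, TIER2_DELTA, TIER2_Q,
                       differential_methylation, extract_signature)
from .io import BetaMatrix

logger = logging.getLogger("cptmethsig")


# ---------------------------------------------------------------- CFS ------

def cfs_merit(selected: list[int] | tuple[int, ...],
              feature_class_corr: np.ndarray,
              feature_feature_corr: np.ndarray) -> float:
    """Merit of a feature subset: relevance over redundancy."""
    sel = list(selected)
    k = len(sel)
    if k == 0:
        raise ValueError("empty feature subset has no merit")
    r_cf = float(np.mean(feature_class_corr[sel]))
    if k == 1:
        return r_cf
    sub = feature_feature_corr[np.ix_(sel, sel)]
    r_ff = float((sub.sum() - np.trace(sub)) / (k * (k - 1)))
    return k * r_cf / np.sqrt(k + k * (k - 1) * r_ff)


def correlation_inputs(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Absolute Pearson feature-class and feature-feature correlations.

    Constant features get zero class correlation and zero correlation with
    everything (they carry no information either way).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    Xc = X - X.mean(axis=0)
    yc = y - y.mean()
    sx = np.sqrt((Xc ** 2).sum(axis=0))
    sy = np.sqrt((yc ** 2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        r_cf = np.abs(Xc.T @ yc / (sx * sy))
        denom = np.outer(sx, sx)
        r_ff = np.abs(Xc.T @ Xc / denom)
    r_cf = np.nan_to_num(r_cf)
    r_ff = np.nan_to_num(r_ff)
    np.fill_diagonal(r_ff, 1.0)
    return r_cf, r_ff


def best_first_search(feature_class_corr: np.ndarray,
                      feature_feature_corr: np.ndarray,
                      stop_after: int = 5) -> list[int]:
    """Forward best-first subset search over the CFS merit surface.

    Maintains an open list ordered by merit, expands the best unexpanded
    state by single-feature additions, and stops after ``stop_after``
    consecutive expansions that fail to improve the best merit seen.
    Deterministic: ties break toward the lexicographically smallest subset.
    """
    n = len(feature_class_corr)
    if n == 0:
        raise ValueError("no features to search")
    merit = lambda s: cfs_merit(s, feature_class_corr, feature_feature_corr)
    # heap entries: (-merit, subset tuple) so ties pick the smallest subset
    start = [(-merit((j,)), (j,)) for j in range(n)]
    heapq.heapify(start)
    open_list = start
    best_subset = min(((m, s) for m, s in open_list))
    best_merit, best = -best_subset[0], best_subset[1]
    seen = {s for _, s in open_list}
    stagnation = 0
    while open_list and stagnation < stop_after:
        neg_m, state = heapq.heappop(open_list)
        improved = False
        for j in range(n):
            if j in state:
                continue
            child = tuple(sorted(state + (j,)))
            if child in seen:
                continue
            seen.add(child)
            m = merit(child)
            heapq.heappush(open_list, (-m, child))
            if m > best_merit + 1e-12:
                best_merit, best = m, child
                improved = True
        stagnation = 0 if improved else stagnation + 1
    return list(best)


# ------------------------------------------------------------- models ------

@dataclass
class LogisticModel:
    intercept: float
    coefficients: np.ndarray
    feature_names: list[str]
    ridge_lambda: float
    _clf: LogisticRegression = field(repr=False, default=None)

    @property
    def odds_ratios(self) -> np.ndarray:
        """exp(coefficient): multiplicative odds change per unit beta."""
        return np.exp(self.coefficients)

    def predict_score(self, X: np.ndarray) -> np.ndarray:
        return self._clf.predict_proba(np.asarray(X, dtype=float))[:, 1]


@dataclass
class NaiveBayesModel:
    feature_names: list[str]
    _clf: GaussianNB = field(repr=False, default=None)

    def predict_score(self, X: np.ndarray) -> np.ndarray:
        return self._clf.predict_proba(np.asarray(X, dtype=float))[:, 1]


def _check_two_classes(y: np.ndarray) -> None:
    if len(np.unique(y)) < 2:
        raise ValueError("training data contains a single class")


def fit_logistic(X, y, ridge_lambda: float = 1e-8,
                 feature_names: list[str] | None = None) -> LogisticModel:
    """Ridge-penalized logistic regression (near-unpenalized by default).

    The tiny default penalty guards against complete separation, which is
    the norm for a well-separated methylation signature.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    if ridge_lambda < 0:
        raise ValueError("ridge penalty must be >= 0")
    _check_two_classes(y)
    clf = LogisticRegression(C=1.0 / max(ridge_lambda, 1e-12),
                             solver="lbfgs", max_iter=10_000)
    clf.fit(X, y)
    names = feature_names or [f"f{j}" for j in range(X.shape[1])]
    return LogisticModel(float(clf.intercept_[0]), clf.coef_[0].copy(),
                         names, ridge_lambda, clf)


def fit_naive_bayes(X, y, feature_names: list[str] | None = None) -> NaiveBayesModel:
    """Gaussian class-conditional naive Bayes with empirical class priors."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    _check_two_classes(y)
    clf = GaussianNB()
    clf.fit(X, y)
    names = feature_names or [f"f{j}" for j in range(X.shape[1])]
    return NaiveBayesModel(names, clf)


_MODEL_FITTERS = {"logistic": fit_logistic, "nb": fit_naive_bayes}


# ----------------------------------------------------------------- LOO -----

@dataclass
class CVReport:
    """Pooled leave-one-out results; carcinoma is the positive class."""
    folds: pd.DataFrame  # sample_id, true_label, predicted, score, n_features
    model: str
    feature_mode: str

    @property
    def confusion(self) -> dict[str, int]:
        f = self.folds
        pos = f["true_label"] == CARCINOMA
        pred_pos = f["predicted"] == CARCINOMA
        return {
            "tp": int((pos & pred_pos).sum()),
            "fn": int((pos & ~pred_pos).sum()),
            "tn": int((~pos & ~pred_pos).sum()),
            "fp": int((~pos & pred_pos).sum()),
        }

    @property
    def sensitivity(self) -> float:
        c = self.confusion
        return c["tp"] / (c["tp"] + c["fn"])

    @property
    def specificity(self) -> float:
        c = self.confusion
        return c["tn"] / (c["tn"] + c["fp"])

    @property
    def auroc(self) -> float:
        y = (self.folds["true_label"] == CARCINOMA).astype(int)
        return float(roc_auc_score(y, self.folds["score"]))

    def summary(self) -> dict:
        return {"model": self.model, "feature_mode": self.feature_mode,
                **self.confusion, "sensitivity": self.sensitivity,
                "specificity": self.specificity, "auroc": self.auroc}


def loo_cross_validate(matrix: BetaMatrix, labels: pd.Series,
                       model: str = "logistic",
                       features: str | list[str] = "signature",
                       q_threshold: float = TIER2_Q,
                       delta_threshold: float = TIER2_DELTA,
                       fold_callback=None) -> CVReport:
    """Leakage-free LOO: the signature is re-derived inside every fold.

    ``features`` is 'signature' (all fold-signature CpGs), 'cfs'
    (best-first CFS on the fold signature), or an explicit probe list (a
    fixed minimal signature; the per-fold re-derivation is then skipped and
    only model training is cross-validated). ``fold_callback`` receives
    (held_out_sample, training_sample_ids) per fold, for instrumentation.
    """
    if model not in _MODEL_FITTERS:
        raise ValueError(f"unknown model {model!r}")
    labels = labels.reindex(matrix.sample_ids)
    y_all = (labels == CARCINOMA).astype(int)
    if (y_all.sum() < 2) or ((1 - y_all).sum() < 2):
        raise ValueError("need >= 2 samples per class")
    prior_pos = float(y_all.mean())
    rows = []
    for held in matrix.sample_ids:
        train_ids = [s for s in matrix.sample_ids if s != held]
        if fold_callback is not None:
            fold_callback(held, train_ids)
        train = matrix.restrict_samples(train_ids)
        if isinstance(features, str):
            dm = differential_methylation(train, labels.loc[train_ids])
            sig = extract_signature(dm, "tier2", q_threshold=q_threshold,
                                    delta_threshold=delta_threshold)
            probes = sig.probe_ids
        else:
            probes = [p for p in features if p in matrix.values.index]
        n_sig = len(probes)
        if n_sig == 0:
            # degenerate fold: fall back to the class prior
            logger.info("loo: empty signature for fold %s; predicting prior", held)
            pred = CARCINOMA if prior_pos > 0.5 else PAPILLOMA
            rows.append({"sample_id": held, "true_label": labels[held],
                         "predicted": pred, "score": prior_pos,
                         "n_features": 0})
            continue
        Xtr = train.values.loc[probes].to_numpy().T
        ytr = y_all.loc[train_ids].to_numpy()
        if features == "cfs" and Xtr.shape[1] > 1:
            r_cf, r_ff = correlation_inputs(Xtr, ytr)
            chosen = best_first_search(r_cf, r_ff)
            probes = [probes[j] for j in chosen]
            Xtr = Xtr[:, chosen]
        fitted = _MODEL_FITTERS[model](Xtr, ytr, feature_names=probes)
        x_held = matrix.values.loc[probes, [held]].to_numpy().T
        score = float(fitted.predict_score(x_held)[0])
        pred = CARCINOMA if score >= 0.5 else PAPILLOMA
        rows.append({"sample_id": held, "true_label": labels[held],
                     "predicted": pred, "score": score,
                     "n_features": len(probes)})
    folds = pd.DataFrame(rows)
    mode = features if isinstance(features, str) else "fixed"
    return CVReport(folds, model, mode)
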