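"""All-PRS longevity prediction with repeated cross-validated model selection.

Combines many per-trait polygenic scores into one feature matrix and
compares standard classifier families (regularized logistic regression,
linear-margin SVM, k-nearest neighbours, naive Bayes, decision tree,
random forest) by repeated stratified k-fold cross-validation with
grid-searched hyper-parameters. The winning family is refit on an 80%
stratified split and evaluated on the held-out 20% (AUC and Nagelkerke
pseudo-R²). Deliberately thin glue around scikit-learn.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import clone
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import accuracy_score, roc_auc_score
from sklearn.model_selection import StratifiedKFold, train_test_split
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.svm import LinearSVC
from sklearn.tree import DecisionTreeClassifier
from sklearn.ensemble import RandomForestClassifier

from .stats import nagelkerke_r2

logger = logging.getLogger(__name__)

__all__ = ["PredictionReport", "assemble_prs_matrix", "model_selection_cv",
           "default_model_grid"]


def default_model_grid() -> dict:
    """Candidate classifier families and their hyper-parameter grids."""
    return {
        "logistic": (LogisticRegression(max_iter=2000, solver="liblinear"),
                     [{"l1_ratio": r, "C": c}
                      for r in (1.0, 0.0)  # lasso / ridge penalty
                      for c in (0.01, 0.1, 1.0)]),
        "svm": (LinearSVC(), [{"C": c} for c in (0.01, 0.1, 1.0)]),
        "knn": (KNeighborsClassifier(),
                [{"n_neighbors": k} for k in (5, 15, 25)]),
        "naive_bayes": (GaussianNB(), [{}]),
        "decision_tree": (DecisionTreeClassifier(),
                          [{"max_depth": d} for d in (3, 5, None)]),
        "random_forest": (RandomForestClassifier(),
                          [{"n_estimators": 100, "max_depth": d}
                           for d in (5, None)]),
    }


@dataclass
class PredictionReport:
    """Model-comparison summary plus the final held-out evaluation."""

    per_model: pd.DataFrame
    best_model: str
    best_params: dict
    final_auc: float
    final_pseudo_r2: float
    coefficients: pd.Series | None
    n_train: int
    n_test: int
    cv_auc_mean: float = field(default=np.nan)
    cv_auc_sd: float = field(default=np.nan)


def assemble_prs_matrix(per_trait_scores: dict) -> tuple[pd.DataFrame, list]:
    """Column-standardized matrix of per-trait scores (inner join on ids).

    Traits whose score is constant across the joined individuals are
    dropped with a warning; individuals missing from any trait are dropped
    with a log entry.
    """
    if not per_trait_scores:
        raise ValueError("no per-trait scores supplied")
    frames = {t: pd.Series(s) for t, s in per_trait_scores.items()}
    mat = pd.DataFrame(frames).dropna()
    n_before = max(len(s) for s in frames.values())
    if len(mat) < n_before:
        logger.info("dropped %d individuals missing from some trait",
                    n_before - len(mat))
    if len(mat) < 2:
        raise ValueError("fewer than 2 individuals after joining traits")
    keep = []
    for col in mat.columns:
        if mat[col].std() == 0:
            logger.warning("trait %s has constant scores; column dropped", col)
        else:
            keep.append(col)
    mat = mat[keep]
    mat = (mat - mat.mean()) / mat.std(ddof=0)
    return mat, list(mat.columns)


def _decision_scores(model, X):
    if hasattr(model, "predict_proba"):
        return model.predict_proba(X)[:, 1]
    return model.decision_function(X)


def model_selection_cv(matrix, y, model_grid: dict | None = None,
                       k: int = 10, iterations: int = 100, seed: int = 0,
                       test_fraction: float = 0.2) -> PredictionReport:
    """Grid-searched, repeated stratified k-fold model comparison.

    Every candidate (family, hyper-parameters) pair is scored by mean
    validation accuracy over ``iterations`` re-randomized stratified
    k-fold splits; AUC is tracked alongside. The best pair is refit on a
    stratified 80/20 split (both the folds and the split re-randomize from
    the single ``seed``), and the held-out AUC and Nagelkerke pseudo-R²
    are reported, with coefficients for linear winners.
    """
    X = np.asarray(matrix, dtype=float)
    y = np.asarray(y, dtype=float)
    classes, counts = np.unique(y, return_counts=True)
    if classes.size != 2:
        raise ValueError("phenotype must be binary and non-constant")
    if k < 2 or k > counts.min():
        raise ValueError("k must be >= 2 and <= the smallest class count")
    grid = model_grid if model_grid is not None else default_model_grid()
    ss = np.random.SeedSequence(seed)
    fold_seeds = ss.spawn(iterations)

    records = []
    for name, (proto, param_list) in grid.items():
        for params in param_list:
            accs, aucs = [], []
            for it in range(iterations):
                rs = int(fold_seeds[it].generate_state(1)[0] % (2**31))
                skf = StratifiedKFold(n_splits=k, shuffle=True,
                                      random_state=rs)
                for tr, va in skf.split(X, y):
                    model = clone(proto).set_params(**params)
                    if hasattr(model, "random_state"):
                        model.set_params(random_state=rs)
                    model.fit(X[tr], y[tr])
                    accs.append(accuracy_score(y[va], model.predict(X[va])))
                    aucs.append(roc_auc_score(y[va],
                                              _decision_scores(model, X[va])))
            records.append({"model": name, "params": repr(params),
                            "mean_accuracy": float(np.mean(accs)),
                            "mean_auc": float(np.mean(aucs)),
                            "sd_auc": float(np.std(aucs)),
                            "_params": params})

    per_model = pd.DataFrame(records)
    best_idx = per_model["mean_accuracy"].idxmax()
    best_name = per_model.loc[best_idx, "model"]
    best_params = per_model.loc[best_idx, "_params"]
    cv_auc_mean = float(per_model.loc[best_idx, "mean_auc"])
    cv_auc_sd = float(per_model.loc[best_idx, "sd_auc"])

    split_seed = int(ss.spawn(1)[0].generate_state(1)[0] % (2**31))
    Xtr, Xte, ytr, yte = train_test_split(
        X, y, test_size=test_fraction, stratify=y, random_state=split_seed)
    final = clone(grid[best_name][0]).set_params(**best_params)
    if hasattr(final, "random_state"):
        final.set_params(random_state=split_seed)
    final.fit(Xtr, ytr)
    scores = _decision_scores(final, Xte)
    final_auc = float(roc_auc_score(yte, scores))

    # pseudo-R² on the held-out set from predicted probabilities
    if hasattr(final, "predict_proba"):
        probs = np.clip(final.predict_proba(Xte)[:, 1], 1e-12, 1 - 1e-12)
        ll_full = float(np.sum(yte * np.log(probs)
                               + (1 - yte) * np.log(1 - probs)))
        base = np.clip(yte.mean(), 1e-12, 1 - 1e-12)
        ll_null = float(np.sum(yte * np.log(base)
                               + (1 - yte) * np.log(1 - base)))
        pseudo = nagelkerke_r2(ll_null, max(ll_full, ll_null), len(yte))
    else:
        pseudo = np.nan

    coefs = None
    if hasattr(final, "coef_"):
        cols = list(matrix.columns) if isinstance(matrix, pd.DataFrame) \
            else [f"x{i}" for i in range(X.shape[1])]
        coefs = pd.Series(final.coef_.ravel(), index=cols, name="coefficient")

    return PredictionReport(
        per_model=per_model.drop(columns="_params"),
        best_model=best_name, best_params=dict(best_params),
        final_auc=final_auc, final_pseudo_r2=pseudo, coefficients=coefs,
        n_train=len(ytr), n_test=len(yte),
        cv_auc_mean=cv_auc_mean, cv_auc_sd=cv_auc_sd)
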