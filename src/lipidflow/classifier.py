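"""Biomarker classification with leakage-free evaluation.

Candidate lipids are filtered by information gain (entropy reduction of
the binary label after equal-frequency discretization of the feature) on
the training portion only, then a classifier is tuned by stratified
cross-validation on the training portion and evaluated on the held-out
test split.  The split/tune/test cycle is repeated (default 10 times at
an 80/20 ratio, base split seed 1996) and metrics are aggregated as mean
with standard error.  A specificity check re-scores the trained models
against alternative clinical labels: low performance there supports the
markers being specific to the outcome rather than to a confounder.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import GradientBoostingClassifier, RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import (balanced_accuracy_score, f1_score,
                             precision_recall_curve, roc_auc_score)
from sklearn.model_selection import (GridSearchCV, StratifiedKFold,
                                     train_test_split)
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler


def _entropy(labels: np.ndarray) -> float:
    _, counts = np.unique(labels, return_counts=True)
    p = counts / counts.sum()
    return float(-(p * np.log2(p)).sum())


def information_gain(features: pd.DataFrame, labels, n_bins: int = 10) -> pd.Series:
    """Information gain of each continuous feature about a binary label.

    ``IG = H(label) - sum_b p(b) H(label | bin b)`` with equal-frequency
    binning (duplicate bin edges collapsed); in bits.  Constant features
    have zero gain.
    """
    y = np.asarray(labels)
    if len(np.unique(y)) != 2:
        raise ValueError("labels must be binary")
    h = _entropy(y)
    out = {}
    for col in features.columns:
        x = features[col]
        if x.nunique() <= 1:
            out[col] = 0.0
            continue
        if x.nunique() <= n_bins:
            # effectively discrete: each distinct value is its own bin
            bins = x.factorize()[0]
        else:
            bins = pd.qcut(x, q=n_bins, labels=False, duplicates="drop")
        cond = 0.0
        for b in np.unique(bins):
            idx = bins == b
            cond += idx.mean() * _entropy(y[idx])
        out[col] = max(0.0, h - cond)
    return pd.Series(out, name="information_gain")


def _make_model(model: str, cv_seed: int, cv_folds: int):
    cv = StratifiedKFold(n_splits=cv_folds, shuffle=True, random_state=cv_seed)
    if model == "random_forest":
        est = RandomForestClassifier(n_estimators=200, random_state=cv_seed)
        grid = {"max_features": ["sqrt", None]}
    elif model == "gradient_boosting":
        est = GradientBoostingClassifier(random_state=cv_seed)
        grid = {"max_depth": [2, 3], "n_estimators": [100]}
    elif model == "logistic_elastic_net":
        est = Pipeline([
            ("scale", StandardScaler()),
            ("clf", LogisticRegression(penalty="elasticnet", solver="saga",
                                       max_iter=5000, random_state=cv_seed)),
        ])
        grid = {"clf__l1_ratio": [0.2, 0.8], "clf__C": [0.1, 1.0]}
    else:
        raise ValueError(f"unknown model {model!r}")
    return GridSearchCV(est, grid, cv=cv, scoring="f1", n_jobs=1)


def _scores(fitted, X: np.ndarray) -> np.ndarray:
    if hasattr(fitted, "predict_proba"):
        return fitted.predict_proba(X)[:, 1]
    return fitted.decision_function(X)


def pr_area(y_true: np.ndarray, scores: np.ndarray) -> tuple[float, np.ndarray, np.ndarray]:
    """Trapezoidal area under the precision-recall curve.

    Integration follows the threshold order of the curve so points sharing
    a recall value (vertical segments) contribute zero width.
    """
    precision, recall, _ = precision_recall_curve(y_true, scores)
    area = float(np.trapezoid(precision[::-1], recall[::-1]))
    return area, precision, recall


@dataclass
class ClassifierReport:
    """Per-repeat metrics plus aggregates.

    ``importances`` are scaled to sum to one (scaling recorded in
    ``importance_scaling``).  Fitted models and their test indices are
    kept for the confounder-specificity check.
    """
    repeats: list
    aggregate: pd.DataFrame
    importances: pd.Series
    importance_scaling: str
    models: list = field(repr=False, default_factory=list)
    notes: list = field(default_factory=list)

    def metric(self, name: str) -> tuple[float, float]:
        return (float(self.aggregate.loc[name, "mean"]),
                float(self.aggregate.loc[name, "se"]))


def train_evaluate(features: pd.DataFrame, labels: pd.Series,
                   candidates: list[str] | None = None,
                   train_frac: float = 0.8, repeats: int = 10,
                   cv_folds: int = 10, model: str = "random_forest",
                   seed: int = 1996, ig_cut: float = 0.1,
                   n_bins: int = 10) -> ClassifierReport:
    """Repeated stratified split / tune / test evaluation.

    Feature selection (information gain above ``ig_cut``) and
    hyperparameter tuning see only the training portion of each repeat.
    """
    y_all = labels.loc[features.index].to_numpy()
    if candidates is None:
        candidates = list(features.columns)
    rows, models, notes = [], [], []
    imp_acc = pd.Series(0.0, index=pd.Index(candidates))
    for rep in range(repeats):
        split_seed = (seed + 7919 * rep) % (2 ** 31)
        for attempt in range(10):
            tr_idx, te_idx = train_test_split(
                np.arange(len(y_all)), test_size=1.0 - train_frac,
                stratify=y_all, random_state=(split_seed + attempt) % (2 ** 31))
            if len(np.unique(y_all[te_idx])) == 2 and \
               len(np.unique(y_all[tr_idx])) == 2:
                if attempt:
                    notes.append(f"repeat {rep}: split re-drawn {attempt}x")
                break
        else:
            raise RuntimeError("could not produce a two-class split")
        X = features[candidates]
        ig = information_gain(X.iloc[tr_idx], y_all[tr_idx], n_bins=n_bins)
        selected = ig.index[ig > ig_cut].tolist()
        if not selected:
            selected = [ig.idxmax()]
            notes.append(f"repeat {rep}: no feature passed IG>{ig_cut}; "
                         "kept the single best")
        search = _make_model(model, cv_seed=split_seed, cv_folds=cv_folds)
        Xtr = X.iloc[tr_idx][selected].to_numpy()
        Xte = X.iloc[te_idx][selected].to_numpy()
        search.fit(Xtr, y_all[tr_idx])
        fitted = search.best_estimator_
        s = _scores(fitted, Xte)
        yhat = fitted.predict(Xte)
        area, precision, recall = pr_area(y_all[te_idx], s)
        rows.append({
            "repeat": rep, "split_seed": split_seed, "selected": selected,
            "f1": f1_score(y_all[te_idx], yhat, pos_label=1),
            "balanced_accuracy": balanced_accuracy_score(y_all[te_idx], yhat),
            "auroc": roc_auc_score(y_all[te_idx], s),
            "pr_area": area,
            "pr_points": np.column_stack([recall, precision]),
        })
        models.append({"model": fitted, "selected": selected,
                       "test_index": features.index[te_idx]})
        est = fitted.named_steps["clf"] if isinstance(fitted, Pipeline) else fitted
        raw = np.abs(est.coef_[0]) if hasattr(est, "coef_") \
            else est.feature_importances_
        w = pd.Series(raw, index=selected)
        if w.sum() > 0:
            imp_acc = imp_acc.add(w / w.sum(), fill_value=0.0)

    metrics = ["f1", "balanced_accuracy", "auroc", "pr_area"]
    vals = pd.DataFrame(rows)[metrics]
    aggregate = pd.DataFrame({
        "mean": vals.mean(),
        "se": vals.std(ddof=1) / math.sqrt(len(vals)) if len(vals) > 1 else 0.0,
    })
    imp = imp_acc / imp_acc.sum() if imp_acc.sum() > 0 else imp_acc
    return ClassifierReport(repeats=rows, aggregate=aggregate,
                            importances=imp.sort_values(ascending=False),
                            importance_scaling="sum-to-1",
                            models=models, notes=notes)


def specificity_check(report: ClassifierReport, features: pd.DataFrame,
                      other_labels: pd.DataFrame) -> pd.DataFrame:
    """Score the outcome-trained models against alternative labels.

    For each alternative binary label, every repeat's fitted model scores
    its own test samples and AUROC / PR-area are computed against that
    label; repeats where the label is constant in the test split are
    skipped.  Low values relative to the outcome metrics indicate that
    the markers are specific to the outcome.
    """
    rows = []
    for label_name in other_labels.columns:
        lab = other_labels[label_name]
        aurocs, areas, used = [], [], 0
        for m in report.models:
            y = lab.loc[m["test_index"]].to_numpy()
            if len(np.unique(y)) != 2:
                continue
            X = features.loc[m["test_index"], m["selected"]].to_numpy()
            s = _scores(m["model"], X)
            aurocs.append(roc_auc_score(y, s))
            areas.append(pr_area(y, s)[0])
            used += 1
        if used == 0:
            rows.append({"label": label_name, "auroc": math.nan,
                         "pr_area": math.nan, "repeats_used": 0})
        else:
            rows.append({"label": label_name, "auroc": float(np.mean(aurocs)),
                         "pr_area": float(np.mean(areas)), "repeats_used": used})
    return pd.DataFrame(rows).set_index("label")
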