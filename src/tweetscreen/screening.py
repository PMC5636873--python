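"""Supervised screening: random-forest classification of observations.

Protocol: a stratified 70/30 split at the observation level, median
imputation of missing features (training statistics only), stratified
five-fold cross-validated grid search over a small hyperparameter grid
maximizing F1, a final 1200-tree forest refit on the full training split,
and a five-metric battery (recall, specificity, precision, NPV, F1)
averaged over five independently seeded runs.  "Affected" is the positive
class throughout; the confusion matrix uses a 0.5 probability threshold
and the ROC sweeps all thresholds.

Observation-level splitting lets one user's days land in both train and
test, which leaks user identity when features are user-identifiable.  It
is kept as the default for fidelity with the protocol this package
mirrors; ``by_user=True`` selects a leakage-free user-level split.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Any

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import auc, roc_curve
from sklearn.model_selection import GridSearchCV, StratifiedKFold, train_test_split

from .features import feature_columns

logger = logging.getLogger(__name__)

POSITIVE_LABEL = "affected"

DEFAULT_GRID: dict[str, list] = {
    "max_depth": [None, 10, 20],
    "max_features": ["sqrt", "log2"],
    "min_samples_leaf": [1, 5],
}


@dataclass
class ScreeningConfig:
    train_fraction: float = 0.70
    n_trees: int = 1200
    cv_folds: int = 5
    n_runs: int = 5
    hyperparameter_grid: dict[str, list] | None = field(
        default_factory=lambda: dict(DEFAULT_GRID))
    search_n_trees: int = 200          # forest size during grid search
    seeds: list[int] | None = None     # one per run; derived from master seed if None
    by_user: bool = False

    def __post_init__(self) -> None:
        if not (0.0 < self.train_fraction < 1.0):
            raise ValueError("train_fraction must be in (0, 1)")
        if self.cv_folds < 2:
            raise ValueError("cv_folds must be >= 2")
        if self.seeds is not None and len(set(self.seeds)) != len(self.seeds):
            raise ValueError("seeds must be distinct")


@dataclass
class FittedScreeningModel:
    forest: RandomForestClassifier
    feature_names: list[str]
    medians: pd.Series
    best_params: dict[str, Any]

    def _matrix(self, observations: pd.DataFrame) -> np.ndarray:
        X = observations[self.feature_names].copy()
        return X.fillna(self.medians).to_numpy(dtype=float)

    def predict_proba(self, observations: pd.DataFrame) -> np.ndarray:
        """P(affected) per observation."""
        proba = self.forest.predict_proba(self._matrix(observations))
        pos = list(self.forest.classes_).index(1)
        return proba[:, pos]


def metrics_from_confusion(tp: int, fp: int, fn: int, tn: int) -> dict[str, float]:
    """Closed-form metric battery from a confusion matrix with "affected"
    as the positive class.  Undefined ratios (zero denominator) are NaN."""
    def ratio(num, den):
        return num / den if den else float("nan")

    precision = ratio(tp, tp + fp)
    recall = ratio(tp, tp + fn)
    f1 = (2 * precision * recall / (precision + recall)
          if (precision + recall) and not np.isnan(precision + recall) else
          (0.0 if (tp + fp) and (tp + fn) else float("nan")))
    return {
        "recall": recall,
        "specificity": ratio(tn, tn + fp),
        "precision": precision,
        "npv": ratio(tn, tn + fn),
        "f1": f1,
    }


def _xy(observations: pd.DataFrame) -> tuple[np.ndarray, np.ndarray, list[str]]:
    names = feature_columns(observations)
    X = observations[names].to_numpy(dtype=float)
    y = (observations["label"] == POSITIVE_LABEL).to_numpy(dtype=int)
    return X, y, names


def split_observations(
    observations: pd.DataFrame,
    fraction: float = 0.70,
    seed: int = 0,
    by_user: bool = False,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Random stratified train/test split.

    Default is observation-level (protocol-faithful; leaks users across
    the split).  ``by_user=True`` splits whole users instead, stratified
    by user class.
    """
    if not (0.0 < fraction < 1.0):
        raise ValueError("fraction must be in (0, 1)")
    labels = observations["label"]
    if labels.nunique() < 2:
        raise ValueError("both classes must be present to split")
    if by_user:
        users = observations.groupby("user_id")["label"].first()
        tr_users, te_users = train_test_split(
            users.index.to_numpy(), train_size=fraction,
            random_state=seed, stratify=users.to_numpy())
        train = observations[observations["user_id"].isin(tr_users)]
        test = observations[observations["user_id"].isin(te_users)]
    else:
        train, test = train_test_split(
            observations, train_size=fraction, random_state=seed,
            stratify=labels.to_numpy())
    return train, test


def train_classifier(
    train: pd.DataFrame, config: ScreeningConfig, seed: int = 0
) -> FittedScreeningModel:
    """Median-impute, grid-search by stratified CV (F1), refit the final
    ``n_trees`` forest on the full training split."""
    if train.empty:
        raise ValueError("empty training set")
    X, y, names = _xy(train)
    if len(np.unique(y)) < 2:
        raise ValueError("training set must contain both classes")

    medians = pd.Series(np.nanmedian(X, axis=0), index=names).fillna(0.0)
    X = pd.DataFrame(X, columns=names).fillna(medians).to_numpy(dtype=float)

    const = [n for n, v in zip(names, X.var(axis=0)) if v == 0.0]
    if const:
        logger.info("zero-variance features kept: %s", const)

    best_params: dict[str, Any] = {}
    min_class = int(np.bincount(y).min())
    grid = config.hyperparameter_grid
    if grid and min_class >= config.cv_folds and len(y) >= 2 * config.cv_folds:
        search = GridSearchCV(
            RandomForestClassifier(
                n_estimators=config.search_n_trees, random_state=seed),
            param_grid=grid,
            scoring="f1",
            cv=StratifiedKFold(config.cv_folds, shuffle=True, random_state=seed),
            n_jobs=None,
        )
        search.fit(X, y)
        best_params = dict(search.best_params_)
    elif grid:
        logger.warning("too few observations for %d-fold CV; grid search skipped",
                       config.cv_folds)

    forest = RandomForestClassifier(
        n_estimators=config.n_trees, random_state=seed, **best_params)
    forest.fit(X, y)
    return FittedScreeningModel(forest, names, medians, best_params)


def evaluate(model: FittedScreeningModel, test: pd.DataFrame) -> dict:
    """Metric battery, confusion matrix, and ROC on a held-out split."""
    if test.empty:
        raise ValueError("empty test set")
    y = (test["label"] == POSITIVE_LABEL).to_numpy(dtype=int)
    p = model.predict_proba(test)
    pred = (p >= 0.5).astype(int)
    tp = int(((pred == 1) & (y == 1)).sum())
    fp = int(((pred == 1) & (y == 0)).sum())
    fn = int(((pred == 0) & (y == 1)).sum())
    tn = int(((pred == 0) & (y == 0)).sum())
    metrics = metrics_from_confusion(tp, fp, fn, tn)
    result = {
        "confusion": {"tp": tp, "fp": fp, "fn": fn, "tn": tn},
        **metrics,
    }
    if len(np.unique(y)) == 2:
        fpr, tpr, thr = roc_curve(y, p)
        result["roc"] = {"fpr": fpr.tolist(), "tpr": tpr.tolist()}
        result["auc"] = float(auc(fpr, tpr))
    else:
        logger.warning("test split lacks a class; ROC/AUC undefined")
        result["auc"] = float("nan")
    return result


def feature_importances(model: FittedScreeningModel) -> pd.DataFrame:
    """Impurity-based importances, descending.  These rank the relevance
    of predictors but carry no directionality."""
    imp = pd.DataFrame({
        "feature": model.feature_names,
        "importance": model.forest.feature_importances_,
    }).sort_values("importance", ascending=False, kind="mergesort")
    return imp.reset_index(drop=True)


@dataclass
class MetricReport:
    """Per-run metrics plus mean (sd) aggregates over the seeded runs."""

    runs: list[dict]
    mean: dict[str, float]
    sd: dict[str, float]
    importances: pd.DataFrame

    METRICS = ("recall", "specificity", "precision", "npv", "f1", "auc")

    def to_dict(self) -> dict:
        return {
            "runs": [
                {k: v for k, v in r.items() if k != "roc"} for r in self.runs
            ],
            "mean": self.mean,
            "sd": self.sd,
            "importances": self.importances.to_dict("records"),
        }


def run_screening(
    observations: pd.DataFrame,
    config: ScreeningConfig | None = None,
    master_seed: int = 0,
) -> MetricReport:
    """The full multi-run protocol: split / fit / evaluate ``n_runs``
    times with independent seeds, then average."""
    config = config or ScreeningConfig()
    if config.seeds is not None:
        seeds = list(config.seeds)
    else:
        rng = np.random.default_rng(master_seed)
        seeds = [int(s) for s in rng.integers(0, 2**31 - 1, config.n_runs)]

    runs = []
    imp_acc = None
    for seed in seeds:
        train, test = split_observations(
            observations, config.train_fraction, seed, config.by_user)
        model = train_classifier(train, config, seed)
        res = evaluate(model, test)
        res["seed"] = seed
        runs.append(res)
        imp = feature_importances(model).set_index("feature")["importance"]
        imp_acc = imp if imp_acc is None else imp_acc.add(imp, fill_value=0.0)

    mean = {m: float(np.nanmean([r[m] for r in runs])) for m in MetricReport.METRICS}
    sd = {m: float(np.nanstd([r[m] for r in runs], ddof=0)) for m in MetricReport.METRICS}
    imp_df = (imp_acc / len(runs)).sort_values(ascending=False).rename("importance")
    return MetricReport(runs, mean, sd, imp_df.reset_index())
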