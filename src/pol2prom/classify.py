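"""Ensemble classification of promoter vs non-promoter windows, with the
evaluation metrics used in promoter-prediction benchmarking.

The model object follows the statsmodels convention: build a
:class:`PromoterClassifier` from a feature matrix and labels, call
:meth:`~PromoterClassifier.fit` to obtain a
:class:`PromoterClassifierResults`, and use the results object for
prediction, evaluation, persistence and summary tables.

Metrics (the standard promoter-prediction evaluation set), from a
confusion matrix with TP/FP/TN/FN counts::

    SN  = 100 * TP / (TP + FN)            sensitivity, %
    PPV = 100 * TP / (TP + FP)            positive predictive value, %
    MCC = (TP*TN - FP*FN) / sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN))
    TPC = FP / TP                         false positives paid per true positive

A metric whose denominator is zero is reported as 0 and flagged.

Variable importance follows the classic random-forest out-of-bag
permutation procedure: for each tree, the drop in accuracy on its
out-of-bag sample after permuting one predictor is recorded; the drop is
averaged over trees and normalised by its standard error, and the whole
procedure is repeated over independently seeded forests and averaged.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import joblib
import numpy as np
import pandas as pd
from sklearn.ensemble import (
    BaggingClassifier,
    GradientBoostingClassifier,
    RandomForestClassifier,
)
from sklearn.metrics import roc_curve
from sklearn.model_selection import StratifiedKFold
from sklearn.tree import DecisionTreeClassifier

POSITIVE_LABEL = "promoter"
ALGORITHMS = ("random_forest", "bagging", "boosting")
_PERSIST_VERSION = 1

__all__ = [
    "ConfusionMatrix",
    "EvalReport",
    "metrics",
    "PromoterClassifier",
    "PromoterClassifierResults",
    "CrossValResult",
    "cross_validate",
    "roc_points",
    "variable_importance",
    "plot_roc",
]


@dataclass(frozen=True)
class ConfusionMatrix:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def positives(self) -> int:
        return self.tp + self.fn

    @property
    def negatives(self) -> int:
        return self.tn + self.fp

    def scaled(self, factor: int) -> "ConfusionMatrix":
        return ConfusionMatrix(
            self.tp * factor, self.fp * factor, self.tn * factor, self.fn * factor
        )

    def __add__(self, other: "ConfusionMatrix") -> "ConfusionMatrix":
        return ConfusionMatrix(
            self.tp + other.tp, self.fp + other.fp, self.tn + other.tn, self.fn + other.fn
        )


@dataclass(frozen=True)
class EvalReport:
    sn: float  # %
    ppv: float  # %
    mcc: float
    tpc: float
    auc: float | None = None
    undefined: tuple[str, ...] = ()

    def as_dict(self) -> dict[str, float]:
        out = {"sn": self.sn, "ppv": self.ppv, "mcc": self.mcc, "tpc": self.tpc}
        if self.auc is not None:
            out["auc"] = self.auc
        return out

    def __str__(self) -> str:
        parts = [f"SN={self.sn:.2f}%", f"PPV={self.ppv:.2f}%", f"MCC={self.mcc:.2f}",
                 f"TPC={self.tpc:.2f}"]
        if self.auc is not None:
            parts.append(f"AUC={self.auc:.3f}")
        return "  ".join(parts)


def metrics(cm: ConfusionMatrix, auc: float | None = None) -> EvalReport:
    """SN/PPV/MCC/TPC from confusion counts (zero denominators -> 0,
    flagged in ``undefined``)."""
    undefined = []

    def ratio(num, den, name):
        if den == 0:
            undefined.append(name)
            return 0.0
        return num / den

    sn = 100.0 * ratio(cm.tp, cm.tp + cm.fn, "sn")
    ppv = 100.0 * ratio(cm.tp, cm.tp + cm.fp, "ppv")
    tpc = ratio(cm.fp, cm.tp, "tpc")
    denom2 = (
        float(cm.tp + cm.fp) * (cm.tp + cm.fn) * (cm.tn + cm.fp) * (cm.tn + cm.fn)
    )
    if denom2 == 0:
        undefined.append("mcc")
        mcc = 0.0
    else:
        mcc = (float(cm.tp) * cm.tn - float(cm.fp) * cm.fn) / np.sqrt(denom2)
    return EvalReport(sn=sn, ppv=ppv, mcc=mcc, tpc=tpc, auc=auc,
                      undefined=tuple(undefined))


# ---------------------------------------------------------------------------
# model / results
# ---------------------------------------------------------------------------


def _as_xy(X, y, feature_names=None):
    if isinstance(X, pd.DataFrame):
        feature_names = list(X.columns)
        X = X.to_numpy(dtype=np.float64)
    else:
        X = np.asarray(X, dtype=np.float64)
        if feature_names is None:
            feature_names = [f"x{i}" for i in range(X.shape[1])]
    y = np.asarray(y)
    if y.dtype.kind in "UO":
        y = y == POSITIVE_LABEL
    y = y.astype(bool)
    return X, y, feature_names


def _make_estimator(algorithm: str, n_estimators: int, max_depth, seed: int):
    if algorithm == "random_forest":
        return RandomForestClassifier(
            n_estimators=n_estimators, max_depth=max_depth, random_state=seed, n_jobs=1
        )
    if algorithm == "bagging":
        return BaggingClassifier(
            estimator=DecisionTreeClassifier(max_depth=max_depth),
            n_estimators=n_estimators,
            random_state=seed,
        )
    if algorithm == "boosting":  # optional LogitBoost-style adapter
        return GradientBoostingClassifier(
            n_estimators=n_estimators,
            max_depth=3 if max_depth is None else max_depth,
            random_state=seed,
        )
    raise ValueError(f"unknown algorithm {algorithm!r}; choose from {ALGORITHMS}")


class PromoterClassifier:
    """Ensemble classifier model over a feature matrix.

    Parameters
    ----------
    X : DataFrame or array, shape (n, p)
        Feature matrix; column order is recorded and enforced at predict
        time.
    y : array-like
        Labels; strings are mapped to the positive class ``"promoter"``.
    algorithm : {"random_forest", "bagging", "boosting"}
    n_estimators, max_depth :
        Ensemble size (default 100 trees) and tree depth (default
        unlimited).
    """

    def __init__(self, X, y, algorithm: str = "random_forest",
                 n_estimators: int = 100, max_depth: int | None = None):
        self.X, self.y, self.feature_names = _as_xy(X, y)
        if len(np.unique(self.y)) < 2:
            raise ValueError("need both classes present to train")
        if algorithm not in ALGORITHMS:
            raise ValueError(f"unknown algorithm {algorithm!r}")
        self.algorithm = algorithm
        self.n_estimators = n_estimators
        self.max_depth = max_depth
        const = np.all(self.X == self.X[0], axis=0)
        if const.any():
            import logging

            logging.getLogger(__name__).info(
                "constant feature columns: %s",
                [self.feature_names[i] for i in np.nonzero(const)[0]],
            )

    @classmethod
    def from_dataframe(cls, frame: pd.DataFrame, label_col: str = "label",
                       feature_cols: Sequence[str] | None = None, **kwargs):
        """Build from a table carrying features plus a label column."""
        if feature_cols is None:
            from .features import FEATURE_NAMES

            feature_cols = [c for c in FEATURE_NAMES if c in frame.columns]
            if not feature_cols:
                feature_cols = [
                    c for c in frame.columns
                    if c != label_col and pd.api.types.is_numeric_dtype(frame[c])
                ]
        return cls(frame[list(feature_cols)], frame[label_col].to_numpy(), **kwargs)

    def fit(self, seed: int = 0) -> "PromoterClassifierResults":
        est = _make_estimator(self.algorithm, self.n_estimators, self.max_depth, seed)
        est.fit(self.X, self.y)
        return PromoterClassifierResults(model=self, estimator=est, seed=seed)


@dataclass
class PromoterClassifierResults:
    """Fitted classifier with prediction, evaluation and persistence."""

    model: PromoterClassifier
    estimator: object
    seed: int

    @property
    def feature_names(self) -> list[str]:
        return self.model.feature_names

    def _check(self, X):
        if isinstance(X, pd.DataFrame):
            if list(X.columns) != self.feature_names:
                raise ValueError(
                    "feature column order mismatch: expected "
                    f"{self.feature_names}, got {list(X.columns)}"
                )
            X = X.to_numpy(dtype=np.float64)
        else:
            X = np.asarray(X, dtype=np.float64)
            if X.ndim == 1:
                X = X.reshape(1, -1)
            if X.shape[1] != len(self.feature_names):
                raise ValueError("wrong number of feature columns")
        return X

    def predict_proba(self, X) -> np.ndarray:
        """Promoter probability in [0, 1] per row."""
        X = self._check(X)
        proba = self.estimator.predict_proba(X)
        pos = list(self.estimator.classes_).index(True)
        return proba[:, pos]

    def predict(self, X, threshold: float = 0.5) -> np.ndarray:
        """Boolean promoter calls: score >= threshold."""
        return self.predict_proba(X) >= threshold

    def evaluate(self, X, y, threshold: float = 0.5) -> tuple[ConfusionMatrix, EvalReport]:
        X_arr = self._check(X)
        _, y, _ = _as_xy(X_arr, y, self.feature_names)
        scores = self.predict_proba(X_arr)
        pred = scores >= threshold
        cm = ConfusionMatrix(
            tp=int(np.sum(pred & y)),
            fp=int(np.sum(pred & ~y)),
            tn=int(np.sum(~pred & ~y)),
            fn=int(np.sum(~pred & y)),
        )
        _, _, auc = roc_points(scores, y)
        return cm, metrics(cm, auc=auc)

    def summary(self, X=None, y=None, threshold: float = 0.5) -> str:
        lines = [
            "Promoter classifier results",
            "=" * 43,
            f"algorithm:      {self.model.algorithm}",
            f"n_estimators:   {self.model.n_estimators}",
            f"max_depth:      {self.model.max_depth}",
            f"seed:           {self.seed}",
            f"n_obs (train):  {len(self.model.y)}",
            f"  promoters:    {int(self.model.y.sum())}",
            f"  nonpromoters: {int((~self.model.y).sum())}",
            f"n_features:     {len(self.feature_names)}",
        ]
        if X is not None and y is not None:
            cm, rep = self.evaluate(X, y, threshold)
            lines += [
                "-" * 43,
                f"evaluation (threshold={threshold}):",
                f"  TP={cm.tp}  FN={cm.fn}  TN={cm.tn}  FP={cm.fp}",
                f"  {rep}",
            ]
        return "\n".join(lines)

    def save(self, path: str | Path) -> None:
        joblib.dump(
            {
                "format_version": _PERSIST_VERSION,
                "algorithm": self.model.algorithm,
                "hyperparameters": {
                    "n_estimators": self.model.n_estimators,
                    "max_depth": self.model.max_depth,
                },
                "feature_names": self.feature_names,
                "seed": self.seed,
                "estimator": self.estimator,
            },
            path,
        )

    @classmethod
    def load(cls, path: str | Path) -> "PromoterClassifierResults":
        blob = joblib.load(path)
        if blob.get("format_version") != _PERSIST_VERSION:
            raise ValueError("unsupported model archive version")
        shell = PromoterClassifier.__new__(PromoterClassifier)
        shell.feature_names = blob["feature_names"]
        shell.algorithm = blob["algorithm"]
        shell.n_estimators = blob["hyperparameters"]["n_estimators"]
        shell.max_depth = blob["hyperparameters"]["max_depth"]
        shell.X = np.empty((0, len(blob["feature_names"])))
        shell.y = np.empty(0, dtype=bool)
        return cls(model=shell, estimator=blob["estimator"], seed=blob["seed"])


# ---------------------------------------------------------------------------
# cross-validation / ROC / importance
# ---------------------------------------------------------------------------


@dataclass
class CrossValResult:
    cm: ConfusionMatrix
    report: EvalReport
    fold_reports: list[EvalReport]
    oof_scores: np.ndarray
    y: np.ndarray


def cross_validate(
    X,
    y,
    k: int = 10,
    algorithm: str = "random_forest",
    seed: int = 0,
    threshold: float = 0.5,
    n_estimators: int = 100,
    max_depth: int | None = None,
) -> CrossValResult:
    """Stratified k-fold cross-validation; confusion counts pooled over
    folds, plus out-of-fold scores for the pooled ROC."""
    if k < 2:
        raise ValueError("k must be >= 2")
    X, y, names = _as_xy(X, y)
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    pooled = ConfusionMatrix(0, 0, 0, 0)
    fold_reports = []
    oof = np.zeros(len(y))
    for fold, (tr, te) in enumerate(skf.split(X, y)):
        est = _make_estimator(algorithm, n_estimators, max_depth, seed + fold)
        est.fit(X[tr], y[tr])
        pos = list(est.classes_).index(True)
        scores = est.predict_proba(X[te])[:, pos]
        oof[te] = scores
        pred = scores >= threshold
        cm = ConfusionMatrix(
            tp=int(np.sum(pred & y[te])),
            fp=int(np.sum(pred & ~y[te])),
            tn=int(np.sum(~pred & ~y[te])),
            fn=int(np.sum(~pred & y[te])),
        )
        pooled = pooled + cm
        fold_reports.append(metrics(cm))
    _, _, auc = roc_points(oof, y)
    return CrossValResult(
        cm=pooled, report=metrics(pooled, auc=auc), fold_reports=fold_reports,
        oof_scores=oof, y=y,
    )


def roc_points(scores, labels) -> tuple[np.ndarray, np.ndarray, float]:
    """(FPR, TPR) points over sorted thresholds and the trapezoid AUC."""
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels)
    if labels.dtype.kind in "UO":
        labels = labels == POSITIVE_LABEL
    fpr, tpr, _ = roc_curve(labels.astype(int), scores)
    auc = float(np.trapezoid(tpr, fpr))
    return fpr, tpr, auc


def plot_roc(fpr, tpr, auc=None, ax=None, label=None, **kwargs):
    """Plot one ROC curve; returns the axes."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(4.5, 4.5))
    if label is None and auc is not None:
        label = f"AUC = {auc:.3f}"
    ax.plot(fpr, tpr, label=label, **kwargs)
    ax.plot([0, 1], [0, 1], ls=":", color="grey", lw=0.8)
    ax.set_xlabel("false positive rate")
    ax.set_ylabel("true positive rate")
    if label:
        ax.legend(loc="lower right", frameon=False)
    return ax


def variable_importance(
    X,
    y,
    n_repeats: int = 100,
    n_estimators: int = 100,
    seed: int = 0,
    max_features: str | int | float = "sqrt",
) -> pd.DataFrame:
    """Out-of-bag permutation importance, averaged over ``n_repeats``
    independently seeded forests.

    Per forest: for every tree, accuracy on the untouched out-of-bag
    sample minus accuracy on the same sample with one predictor permuted;
    the per-tree decreases are averaged over trees and normalised by their
    standard error (mean decrease in accuracy).  Mean decrease in Gini is
    the average impurity-based importance of the trees.  Returns a
    DataFrame indexed by feature with both columns, sorted by mean
    decrease in accuracy.
    """
    X, y, names = _as_xy(X, y)
    n, p = X.shape
    mda_runs = np.zeros((n_repeats, p))
    gini_runs = np.zeros((n_repeats, p))
    for r in range(n_repeats):
        run_seed = seed + 1000 * r
        rng = np.random.default_rng(run_seed)
        forest = BaggingClassifier(
            estimator=DecisionTreeClassifier(max_features=max_features),
            n_estimators=n_estimators,
            bootstrap=True,
            random_state=run_seed,
        )
        forest.fit(X, y)
        decreases = np.full((n_estimators, p), np.nan)
        ginis = np.zeros((n_estimators, p))
        for t, (tree, samples) in enumerate(
            zip(forest.estimators_, forest.estimators_samples_)
        ):
            ginis[t] = tree.feature_importances_
            inbag = np.zeros(n, dtype=bool)
            inbag[samples] = True
            oob = ~inbag
            if not oob.any():
                continue
            X_oob, y_oob = X[oob], y[oob]
            base = np.mean(tree.predict(X_oob) == y_oob)
            for j in range(p):
                perm = rng.permutation(len(y_oob))
                X_perm = X_oob.copy()
                X_perm[:, j] = X_oob[perm, j]
                decreases[t, j] = base - np.mean(tree.predict(X_perm) == y_oob)
        mean = np.nanmean(decreases, axis=0)
        sd = np.nanstd(decreases, axis=0, ddof=1)
        n_trees = np.sum(~np.isnan(decreases[:, 0]))
        se = sd / np.sqrt(max(n_trees, 1))
        mda_runs[r] = np.where(se > 0, mean / np.where(se > 0, se, 1.0), mean)
        gini_runs[r] = ginis.mean(axis=0)
    table = pd.DataFrame(
        {
            "mean_decrease_accuracy": mda_runs.mean(axis=0),
            "mean_decrease_gini": gini_runs.mean(axis=0),
        },
        index=pd.Index(names, name="feature"),
    )
    return table.sort_values("mean_decrease_accuracy", ascending=False)
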