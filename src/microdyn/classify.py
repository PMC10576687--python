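"""SVM recursive feature elimination inside stratified five-fold CV.

Within each training fold, features are z-scored with training statistics
only, a linear SVM is fitted, and the single feature with the smallest
squared weight is removed; repeating to one feature yields a full ranking
and a nested family of subsets.  Every nested subset is scored on the
held-out fold; the per-fold "best" subset is the one with maximal test
accuracy (smallest subset on ties).  Selection counts tally how often a
feature appears in fold-best subsets across the five folds.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC


@dataclass
class ClassificationReport:
    fold_accuracy: list[float]
    fold_sensitivity: list[float]
    fold_specificity: list[float]
    fold_best_subsets: list[list[str]]
    rankings: list[list[str]]          # per fold, best feature first
    selection_counts: dict[str, int]
    best_accuracy: float               # mean over folds of the fold-best accuracy
    sensitivity: float
    specificity: float
    fold_assignments: np.ndarray
    seed: int

    def to_dict(self) -> dict:
        return {
            "best_accuracy": self.best_accuracy,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "fold_accuracy": self.fold_accuracy,
            "fold_sensitivity": self.fold_sensitivity,
            "fold_specificity": self.fold_specificity,
            "fold_best_subsets": self.fold_best_subsets,
            "selection_counts": self.selection_counts,
            "seed": self.seed,
        }


def _rfe_ranking(
    x: np.ndarray, y: np.ndarray, feature_names: list[str], c: float
) -> tuple[list[int], dict[frozenset, SVC]]:
    """Backward elimination by smallest squared linear-SVM weight.

    Returns the feature indices ordered best-first and the fitted model
    for every active subset encountered on the way down.
    """
    active = list(range(x.shape[1]))
    eliminated: list[int] = []
    models: dict[frozenset, SVC] = {}
    while active:
        clf = SVC(kernel="linear", C=c)
        clf.fit(x[:, active], y)
        models[frozenset(active)] = clf
        if len(active) == 1:
            break
        weights = clf.coef_.ravel() ** 2
        drop = int(np.argmin(weights))
        eliminated.append(active.pop(drop))
    ranking = active + eliminated[::-1]
    return ranking, models


def svm_rfe_cv(
    features: pd.DataFrame,
    labels: pd.Series,
    n_folds: int = 5,
    seed: int = 0,
    c: float = 1.0,
    positive_class=1,
    balance: str = "stratified",
) -> ClassificationReport:
    """SVM-RFE feature ranking and metrics under balanced K-fold CV.

    ``labels`` must be binary; ``positive_class`` (the patient class)
    defines sensitivity, the other class specificity.  ``balance`` chooses
    how class imbalance is handled: ``"stratified"`` preserves the class
    ratio in every fold (the default), ``"subsample"`` additionally
    subsamples the majority class of each *training* fold to parity
    (seeded); evaluation folds are never altered.
    """
    if balance not in ("stratified", "subsample"):
        raise ValueError(f"unknown balance mode {balance!r}")
    x_all = features.to_numpy(dtype=float)
    names = list(features.columns)
    y_all = np.asarray(labels)
    classes = np.unique(y_all)
    if classes.size != 2:
        raise ValueError(f"labels must be binary, got classes {classes.tolist()}")
    if positive_class not in classes:
        raise ValueError("positive_class not present in labels")
    if x_all.shape[1] < 2:
        raise ValueError("need at least two features")
    y_bin = (y_all == positive_class).astype(int)

    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    fold_assignments = np.full(y_bin.size, -1)
    fold_acc, fold_sens, fold_spec = [], [], []
    fold_best_subsets: list[list[str]] = []
    rankings: list[list[str]] = []
    counts = {name: 0 for name in names}

    balance_rng = np.random.default_rng(seed)
    for fold_idx, (train, test) in enumerate(skf.split(x_all, y_bin)):
        fold_assignments[test] = fold_idx
        if len(np.unique(y_bin[train])) < 2 or len(np.unique(y_bin[test])) < 2:
            raise ValueError(f"fold {fold_idx} does not contain both classes")
        if balance == "subsample":
            per_class = [train[y_bin[train] == k] for k in (0, 1)]
            n_min = min(len(g) for g in per_class)
            train = np.sort(
                np.concatenate(
                    [
                        balance_rng.choice(g, size=n_min, replace=False)
                        for g in per_class
                    ]
                )
            )
        mu = x_all[train].mean(axis=0)
        sd = x_all[train].std(axis=0, ddof=0)
        sd[sd == 0] = 1.0
        x_train = (x_all[train] - mu) / sd
        x_test = (x_all[test] - mu) / sd
        y_train, y_test = y_bin[train], y_bin[test]

        ranking, models = _rfe_ranking(x_train, y_train, names, c)
        rankings.append([names[i] for i in ranking])

        best = None  # (accuracy, subset_size, subset, sens, spec)
        for size in range(1, len(ranking) + 1):
            subset = ranking[:size]
            clf = models[frozenset(subset)]
            pred = clf.predict(x_test[:, subset])
            acc = float(np.mean(pred == y_test))
            pos, neg = y_test == 1, y_test == 0
            sens = float(np.mean(pred[pos] == 1))
            spec = float(np.mean(pred[neg] == 0))
            if best is None or acc > best[0]:
                best = (acc, size, subset, sens, spec)
        acc, size, subset, sens, spec = best
        fold_acc.append(acc)
        fold_sens.append(sens)
        fold_spec.append(spec)
        subset_names = [names[i] for i in subset]
        fold_best_subsets.append(subset_names)
        for name in subset_names:
            counts[name] += 1

    return ClassificationReport(
        fold_accuracy=fold_acc,
        fold_sensitivity=fold_sens,
        fold_specificity=fold_spec,
        fold_best_subsets=fold_best_subsets,
        rankings=rankings,
        selection_counts=counts,
        best_accuracy=float(np.mean(fold_acc)),
        sensitivity=float(np.mean(fold_sens)),
        specificity=float(np.mean(fold_spec)),
        fold_assignments=fold_assignments,
        seed=seed,
    )


def assemble_inputs(
    microstate_features: pd.DataFrame, *loading_tables: pd.DataFrame
) -> pd.DataFrame:
    """Join the 24 microstate features with selected component loadings.

    All tables must cover exactly the same subjects (by index); a mismatch
    raises with the offending ids.
    """
    merged = microstate_features.copy()
    for table in loading_tables:
        missing = sorted(set(merged.index).symmetric_difference(table.index))
        if missing:
            raise ValueError(f"subject mismatch between feature tables: {missing}")
        overlap = [c for c in table.columns if c in merged.columns]
        renamed = table.rename(
            columns={c: f"{c}_x" for c in overlap}
        )
        merged = merged.join(renamed.reindex(merged.index))
    return merged
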