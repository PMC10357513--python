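"""Per-subject 4-class linear-SVM evaluation with session-grouped 4-fold CV.

Windows from one session never span the train/test split: folds are built by
distributing each class's sessions round-robin across folds, which also
guarantees every training fold contains all classes as long as each class
has at least two sessions.  Features are standardized with training-fold
statistics only.  The SVM is a linear-kernel machine (libsvm one-vs-one
multiclass decomposition) with C = 1 by default and no inner tuning;
one-vs-rest was tried and discards most of the single-band signal on these
small unbalanced per-class session counts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .features import FeatureDataset

__all__ = ["AccuracyTable", "make_group_folds", "crossval_svm", "evaluate_grid"]


@dataclass
class AccuracyTable:
    """Long-format accuracy grid: (subject, feature, band, pattern, condition)."""

    table: pd.DataFrame  # columns: subject, feature, band, pattern, condition, accuracy

    COLUMNS = ("subject", "feature", "band", "pattern", "condition", "accuracy")

    def __post_init__(self) -> None:
        missing = set(self.COLUMNS) - set(self.table.columns)
        if missing:
            raise ValueError(f"accuracy table missing columns {sorted(missing)}")
        acc = self.table["accuracy"].to_numpy(float)
        if acc.size and (np.nanmin(acc) < 0 or np.nanmax(acc) > 100):
            raise ValueError("accuracies must lie in [0, 100]")

    def subject_accuracies(self, feature: str, band: str, pattern: str,
                           condition: str) -> pd.Series:
        t = self.table
        sel = t[(t.feature == feature) & (t.band == band)
                & (t.pattern == pattern) & (t.condition == condition)]
        return sel.set_index("subject")["accuracy"].sort_index()

    def mean_accuracy(self, feature: str, band: str, pattern: str,
                      condition: str) -> float:
        return float(self.subject_accuracies(feature, band, pattern, condition).mean())

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


def make_group_folds(y: np.ndarray, groups: np.ndarray, k: int,
                     rng: np.random.Generator) -> list[np.ndarray]:
    """Assign session groups to k folds, stratified by class.

    Each class's sessions are shuffled and dealt round-robin so no training
    fold can lose a class (requires >= 2 sessions per class for k >= 2).
    Returns, per fold, the array of held-out group ids.
    """
    sess_label: dict = {}
    for g, lab in zip(groups, y):
        if g in sess_label and sess_label[g] != lab:
            raise ValueError(f"session {g} carries multiple labels")
        sess_label[g] = lab
    n_groups = len(sess_label)
    if k > n_groups:
        raise ValueError(f"{k} folds but only {n_groups} sessions")
    by_class: dict = {}
    for g, lab in sess_label.items():
        by_class.setdefault(lab, []).append(g)
    for lab, sess in by_class.items():
        if k >= 2 and len(sess) < 2:
            raise ValueError(f"class {lab!r} has a single session; grouped "
                             f"{k}-fold CV would lose it from training")
    folds: list[list] = [[] for _ in range(k)]
    offset = 0
    for lab in sorted(by_class, key=str):
        sess = sorted(by_class[lab])
        rng.shuffle(sess)
        for i, g in enumerate(sess):
            folds[(offset + i) % k].append(g)
        offset += len(sess)  # stagger classes across folds
    return [np.array(f) for f in folds]


def crossval_svm(ds: FeatureDataset, k: int = 4, seed: int = 0,
                 C: float = 1.0, n_classes_expected: int = 4) -> float:
    """Mean held-out accuracy (percent) of the linear SVM over k grouped folds."""
    classes = np.unique(ds.y)
    if len(classes) != n_classes_expected:
        raise ValueError(f"expected {n_classes_expected} classes, found "
                         f"{len(classes)}: {classes.tolist()}")
    rng = np.random.default_rng(seed)
    folds = make_group_folds(ds.y, ds.groups, k, rng)
    accs = []
    for held_out in folds:
        test_mask = np.isin(ds.groups, held_out)
        X_tr, y_tr = ds.X[~test_mask], ds.y[~test_mask]
        X_te, y_te = ds.X[test_mask], ds.y[test_mask]
        if len(np.unique(y_tr)) != n_classes_expected:
            raise ValueError("a training fold lost a class; need more sessions")
        scaler = StandardScaler().fit(X_tr)
        clf = SVC(kernel="linear", C=C, random_state=seed)
        clf.fit(scaler.transform(X_tr), y_tr)
        accs.append(clf.score(scaler.transform(X_te), y_te))
    return float(np.mean(accs) * 100.0)


def evaluate_grid(datasets: list[FeatureDataset], k: int = 4, seed: int = 0,
                  C: float = 1.0) -> AccuracyTable:
    """One accuracy per (subject, feature, band, pattern, condition) dataset."""
    rows = []
    for ds in datasets:
        rows.append({
            "subject": ds.subject, "feature": ds.kind,
            "band": ds.band_selection, "pattern": ds.pattern,
            "condition": ds.condition,
            "accuracy": crossval_svm(ds, k=k, seed=seed, C=C),
        })
    return AccuracyTable(pd.DataFrame(rows, columns=list(AccuracyTable.COLUMNS)))
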