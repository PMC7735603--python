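"""Model selection by classification accuracy and phylogenetic signal.

Two grids drive the choice of map combination and low-pass filter size:

* a supervised grid — for every (combo, filter size, learner) the mean
  stratified cross-validated classification accuracy of labelled
  specimens (accuracy = 1 - mean CV classification loss);
* an unsupervised grid — for every (combo, filter size) the
  multivariate Blomberg's K of species-mean features on a phylogeny.

The classifier bank mirrors a multiclass error-correcting-output-codes
setup: binary learners (linear SVM, regularized LDA) are wrapped
one-vs-one with vote decoding, while the decision tree, multinomial
logistic regression and k-nearest-neighbour (k = 1, 3, 5) learners are
natively multiclass.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import InputError
from .phylostats import k_mult, phylo_covariance, tip_labels
from .spectral import COMBOS, assemble_features

__all__ = [
    "LEARNERS",
    "MLGridResult",
    "KGridResult",
    "make_classifier",
    "cv_accuracy_grid",
    "select_parsimonious_model",
    "phylo_signal_grid",
]

#: learner identifiers in the canonical (tie-break) order
LEARNERS = ("tree", "linear", "discriminant", "svm", "knn1", "knn3", "knn5")


def make_classifier(name: str, seed: int = 0):
    """Build one of the seven classifier configurations.

    Distance- and margin-based learners are preceded by per-dimension
    z-scoring fit on the training folds only; the decision tree is
    scale-invariant and runs on raw features.
    """
    from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
    from sklearn.linear_model import LogisticRegression
    from sklearn.multiclass import OneVsOneClassifier
    from sklearn.neighbors import KNeighborsClassifier
    from sklearn.pipeline import make_pipeline
    from sklearn.preprocessing import StandardScaler
    from sklearn.svm import SVC
    from sklearn.tree import DecisionTreeClassifier

    if name == "tree":
        return DecisionTreeClassifier(random_state=seed)
    if name == "linear":
        return make_pipeline(
            StandardScaler(), LogisticRegression(max_iter=2000, random_state=seed)
        )
    if name == "discriminant":
        return make_pipeline(
            StandardScaler(),
            OneVsOneClassifier(
                LinearDiscriminantAnalysis(solver="lsqr", shrinkage="auto")
            ),
        )
    if name == "svm":
        return make_pipeline(
            StandardScaler(), OneVsOneClassifier(SVC(kernel="linear", C=1.0))
        )
    if name.startswith("knn"):
        return make_pipeline(
            StandardScaler(), KNeighborsClassifier(n_neighbors=int(name[3:]))
        )
    raise InputError(f"unknown learner {name!r}")


@dataclass
class MLGridResult:
    """Accuracy per (combo, filter size, learner), long format."""

    table: pd.DataFrame  # columns: combo, f, learner, accuracy
    cv_folds: int
    seed: int

    def best(self):
        t = self.table.dropna(subset=["accuracy"])
        return t.loc[t["accuracy"].idxmax()]


@dataclass
class KGridResult:
    """Multivariate K per (combo, filter size), long format."""

    table: pd.DataFrame  # columns: combo, f, k

    def best(self):
        t = self.table.dropna(subset=["k"])
        return t.loc[t["k"].idxmax()]


def _cv_accuracy(X, y, clf, folds, seed):
    from sklearn.model_selection import StratifiedKFold, cross_val_score

    cv = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    return float(np.mean(cross_val_score(clf, X, y, cv=cv)))


def cv_accuracy_grid(
    mapsets,
    combos=tuple(COMBOS),
    f_range=range(1, 51),
    learners=LEARNERS,
    folds: int = 10,
    seed: int = 0,
) -> MLGridResult:
    """Cross-validated accuracy over the (combo, filter, learner) grid.

    Specimens are labelled by ``MapSet.group``.  Folds are stratified
    with a fixed seed; when the smallest class has fewer members than
    ``folds`` the fold count is reduced to that size (with a warning).
    Grid cells whose fit fails numerically are recorded as NaN.
    """
    y = np.array([ms.group for ms in mapsets])
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise InputError("need at least 2 classes")
    if counts.min() < 2:
        raise InputError(
            f"class {classes[counts.argmin()]!r} has fewer than 2 specimens"
        )
    eff_folds = int(min(folds, counts.min()))
    if eff_folds < folds:
        warnings.warn(
            f"reducing CV folds from {folds} to {eff_folds} (smallest class)"
        )

    rows = []
    for combo in combos:
        for f in f_range:
            feats, _ = assemble_features(mapsets, combo, f)
            X = np.stack([fv.values for fv in feats])
            for learner in learners:
                try:
                    acc = _cv_accuracy(X, y, make_classifier(learner, seed), eff_folds, seed)
                except Exception:  # noqa: BLE001 - record cell as failed
                    acc = np.nan
                rows.append((combo, int(f), learner, acc))
    table = pd.DataFrame(rows, columns=["combo", "f", "learner", "accuracy"])
    return MLGridResult(table=table, cv_folds=eff_folds, seed=seed)


def select_parsimonious_model(grid: MLGridResult, tolerance: float = 0.0):
    """Most parsimonious cell within ``tolerance`` of the best accuracy.

    Among qualifying cells, prefer the smallest filter size, then the
    fewest map variables, then the canonical learner order.
    """
    t = grid.table.dropna(subset=["accuracy"])
    if len(t) == 0:
        raise InputError("empty accuracy grid")
    best = t["accuracy"].max()
    cand = t[t["accuracy"] >= best - tolerance].copy()
    cand["n_maps"] = cand["combo"].map(lambda c: len(COMBOS[c]))
    cand["l_order"] = cand["learner"].map(list(LEARNERS).index)
    cand = cand.sort_values(["f", "n_maps", "l_order"], kind="stable")
    row = cand.iloc[0]
    return str(row["combo"]), int(row["f"]), str(row["learner"])


def phylo_signal_grid(
    mapsets, tree, combos=tuple(COMBOS), f_range=range(1, 101)
) -> KGridResult:
    """Multivariate K over the (combo, filter) grid for a phylogeny.

    ``mapsets`` carry a species label in ``group`` (one or more
    specimens per species).  For each cell, features are assembled and
    rotationally aligned across all specimens, averaged per species,
    matched to the tree tips, and scored with the multivariate K.
    """
    tips = tip_labels(tree)
    species = [ms.group for ms in mapsets]
    missing = set(tips) - set(species)
    extra = set(species) - set(tips)
    if missing or extra:
        raise InputError(
            f"tip/label mismatch: missing species {sorted(missing)}, "
            f"unmatched labels {sorted(extra)}"
        )
    C, order = phylo_covariance(tree, order=tips)

    rows = []
    for combo in combos:
        for f in f_range:
            feats, _ = assemble_features(mapsets, combo, f)
            F = np.stack([fv.values for fv in feats])
            means = np.stack(
                [F[np.array(species) == sp].mean(axis=0) for sp in order]
            )
            try:
                k = k_mult(means, C)
            except Exception:  # noqa: BLE001
                k = np.nan
            rows.append((combo, int(f), k))
    return KGridResult(table=pd.DataFrame(rows, columns=["combo", "f", "k"]))
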