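"""Physicochemical descriptor analyses.

Operations on a compounds x descriptors matrix (128 named descriptors
including LogP and pKa): the cationic-amphiphilic-drug (CAD) filter
(LogP > 3 and pKa > 7.4, both strict), a standardized PCA variance summary,
and a balanced random-forest classifier of signature-positive compounds
with out-of-bag error and impurity-based feature importances.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA
from sklearn.preprocessing import StandardScaler
from sklearn.tree import DecisionTreeClassifier

CAD_LOGP_THRESHOLD = 3.0
CAD_PKA_THRESHOLD = 7.4


def cad_filter(matrix: pd.DataFrame) -> set[str]:
    """Compounds with LogP > 3 and pKa > 7.4 (strict inequalities)."""
    missing = [c for c in ("LogP", "pKa") if c not in matrix.columns]
    if missing:
        raise ValueError(f"descriptor matrix lacks required columns: {missing}")
    mask = (matrix["LogP"] > CAD_LOGP_THRESHOLD) & (matrix["pKa"] > CAD_PKA_THRESHOLD)
    return set(matrix.index[mask].astype(str))


def pca_summary(matrix: pd.DataFrame, n_components: int = 5) -> np.ndarray:
    """Explained-variance fractions of the standardized descriptor matrix.

    Columns are scaled to zero mean / unit variance first; zero-variance
    columns are dropped with a warning. Fractions are non-increasing and sum
    to at most 1.
    """
    if matrix.shape[0] < 2 or matrix.shape[1] < 2:
        raise ValueError("need at least 2 compounds and 2 descriptors")
    variances = matrix.var(axis=0)
    dead = list(matrix.columns[variances == 0])
    if dead:
        warnings.warn(f"dropping zero-variance descriptors: {dead[:5]}")
        matrix = matrix.drop(columns=dead)
    x = StandardScaler().fit_transform(matrix.to_numpy(dtype=float))
    k = min(n_components, min(x.shape) - 1) if min(x.shape) > 1 else 1
    pca = PCA(n_components=k)
    pca.fit(x)
    return pca.explained_variance_ratio_


@dataclass
class ClassifierReport:
    oob_error: float
    importances: pd.Series
    n_trees: int
    m_try: int
    seed: int
    oob_predictions: pd.Series = field(repr=False, default=None)


def train_pld_classifier(
    matrix: pd.DataFrame,
    positives: set[str],
    n_trees: int = 500,
    m_try: int = 11,
    seed: int = 0,
    importance: str = "impurity",
) -> ClassifierReport:
    """Balanced random forest for signature-positive vs negative compounds.

    Each tree is grown on a bootstrap of the minority-class size drawn from
    both classes (per-tree downsampling of the majority class), with
    ``m_try`` features tried at each split. Out-of-bag error is the
    misclassification rate of majority-vote OOB predictions; importances are
    mean decrease in impurity averaged over trees (normalized to sum to 1),
    or permutation importances on the OOB-style full matrix when
    ``importance="permutation"``.
    """
    ids = list(matrix.index.astype(str))
    pos = {str(d) for d in positives}
    if not pos or not pos < set(ids):
        raise ValueError("positives must be a non-empty proper subset of the compounds")
    if n_trees < 1:
        raise ValueError("n_trees must be >= 1")
    n_features = matrix.shape[1]
    if not 1 <= m_try <= n_features:
        raise ValueError(f"m_try must lie in 1..{n_features}")

    x = matrix.to_numpy(dtype=float)
    y = np.array([i in pos for i in ids], dtype=int)
    idx_pos = np.flatnonzero(y == 1)
    idx_neg = np.flatnonzero(y == 0)
    n_min = min(len(idx_pos), len(idx_neg))
    rng = np.random.default_rng(seed)

    votes = np.zeros((len(ids), 2), dtype=np.int64)
    imp_sum = np.zeros(n_features)
    trees = []
    for t in range(n_trees):
        boot = np.concatenate([
            rng.choice(idx_pos, size=n_min, replace=True),
            rng.choice(idx_neg, size=n_min, replace=True),
        ])
        tree = DecisionTreeClassifier(
            max_features=m_try,
            random_state=int(rng.integers(0, 2**31 - 1)),
        )
        tree.fit(x[boot], y[boot])
        trees.append(tree)
        imp_sum += tree.feature_importances_
        oob = np.setdiff1d(np.arange(len(ids)), boot, assume_unique=False)
        if len(oob):
            pred = tree.predict(x[oob]).astype(int)
            votes[oob, pred] += 1

    voted = votes.sum(axis=1) > 0
    oob_pred = np.where(votes[:, 1] > votes[:, 0], 1, 0)
    # break exact vote ties towards the majority class (0)
    oob_error = float(np.mean(oob_pred[voted] != y[voted])) if voted.any() else float("nan")

    if importance == "impurity":
        imp = imp_sum / max(imp_sum.sum(), 1e-300)
    elif importance == "permutation":
        def _vote_predict(xx):
            p = np.zeros((xx.shape[0], 2))
            for tr in trees:
                pr = tr.predict(xx).astype(int)
                p[np.arange(len(pr)), pr] += 1
            return (p[:, 1] > p[:, 0]).astype(int)

        baseline = float(np.mean(_vote_predict(x) == y))
        perm_rng = np.random.default_rng(seed)
        imp = np.zeros(n_features)
        for j in range(n_features):
            drops = []
            for _ in range(10):
                xp = x.copy()
                xp[:, j] = xp[perm_rng.permutation(len(ids)), j]
                drops.append(baseline - float(np.mean(_vote_predict(xp) == y)))
            imp[j] = np.mean(drops)
        imp = np.maximum(imp, 0)
        imp = imp / max(imp.sum(), 1e-300)
    else:
        raise ValueError("importance must be 'impurity' or 'permutation'")

    return ClassifierReport(
        oob_error=oob_error,
        importances=pd.Series(imp, index=matrix.columns).sort_values(ascending=False),
        n_trees=n_trees,
        m_try=m_try,
        seed=seed,
        oob_predictions=pd.Series(oob_pred, index=ids),
    )
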