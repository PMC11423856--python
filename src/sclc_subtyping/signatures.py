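"""Subtype signature proteins and the random-forest subtype classifier.

Signatures are one-vs-rest: a protein marks a subtype when its mean FOT in
that subtype exceeds the pooled mean of all other samples by a fold-change
threshold (3 for the two better-prognosis subtypes, 10 for the worst) with a
two-sided Wilcoxon rank-sum p below alpha.  Fold changes are ratios of
arithmetic means of imputed FOT so that "FC > 3" reads as a 3-fold abundance
ratio.

The classifier panel is tighter but broader: one-vs-rest Welch t-tests on
log10 FOT over the abundant-protein candidate pool, Benjamini–Hochberg
adjusted per contrast, keeping proteins with any contrast at FC > 1.5 and
adjusted p < 0.05.  A random forest on log10 FOT of that panel, tuned by
stratified 10-fold cross-validation over a small candidate-features-per-split
grid, provides the transferable subtype caller.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import StratifiedKFold
from statsmodels.stats.multitest import multipletests

from .quantify import AbundanceMatrix

__all__ = [
    "SignatureSet",
    "ClassifierModel",
    "subtype_signatures",
    "classifier_features",
    "train_classifier",
    "predict_subtypes",
]


@dataclass
class SignatureSet:
    """Signature proteins of one subtype with their selection statistics."""

    subtype: object
    entries: pd.DataFrame  # protein_id index; fold_change, p_value, adjusted_p, detect_fraction


@dataclass
class ClassifierModel:
    feature_ids: list[str]
    forest: RandomForestClassifier
    classes: list
    n_trees: int
    max_features: object
    seed: int
    fold_assignments: np.ndarray
    cv_accuracy: float
    per_class_metrics: pd.DataFrame
    grid_scores: dict = field(default_factory=dict)


def _group_means(fot: np.ndarray, mask: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    return fot[:, mask].mean(axis=1), fot[:, ~mask].mean(axis=1)


def subtype_signatures(
    m: AbundanceMatrix,
    labels: np.ndarray | pd.Series,
    fc_thresholds: dict | None = None,
    alpha: float = 0.05,
) -> dict:
    """One-vs-rest Wilcoxon + fold-change signature proteins per subtype.

    ``fc_thresholds`` maps subtype label to its strict fold-change cutoff;
    unlisted subtypes default to 3.  Returns ``{subtype: SignatureSet}``.
    """
    labels = np.asarray(labels)
    if len(labels) != m.n_samples:
        raise ValueError("labels must align with samples")
    fc_thresholds = fc_thresholds or {}
    fot = m.fot.to_numpy(dtype=float)
    det = m.detected.to_numpy(dtype=bool)
    out: dict = {}
    for subtype in np.unique(labels):
        mask = labels == subtype
        if mask.sum() < 2 or (~mask).sum() < 2:
            raise ValueError(f"subtype {subtype!r} needs >= 2 samples on each side")
        mean_in, mean_out = _group_means(fot, mask)
        with np.errstate(divide="ignore", invalid="ignore"):
            fc = np.where(mean_out > 0, mean_in / mean_out, np.inf)
        _, pvals = sps.mannwhitneyu(
            fot[:, mask], fot[:, ~mask], axis=1, alternative="two-sided"
        )
        adjusted = multipletests(pvals, method="fdr_bh")[1]
        threshold = float(fc_thresholds.get(subtype, 3.0))
        keep = (fc > threshold) & (pvals < alpha)
        entries = pd.DataFrame(
            {
                "fold_change": fc[keep],
                "p_value": pvals[keep],
                "adjusted_p": adjusted[keep],
                "detect_fraction": det[keep].mean(axis=1),
            },
            index=m.fot.index[keep],
        ).sort_values("fold_change", ascending=False)
        out[subtype] = SignatureSet(subtype=subtype, entries=entries)
    return out


def classifier_features(
    m: AbundanceMatrix,
    labels: np.ndarray | pd.Series,
    candidates: set[str],
    fc_min: float = 1.5,
    alpha: float = 0.05,
) -> list[str]:
    """Welch t-test (log10 FOT) + BH + fold-change panel over the candidates.

    A candidate protein enters the panel when any one-vs-rest contrast has
    fold change > ``fc_min`` and BH-adjusted p < ``alpha``.  Output order is
    deterministic: ascending minimum adjusted p, then protein id.
    """
    if not candidates:
        raise ValueError("empty candidate set")
    labels = np.asarray(labels)
    ids = [pid for pid in m.protein_ids if pid in candidates]
    fot = m.fot.loc[ids].to_numpy(dtype=float)
    log_fot = np.log10(np.maximum(fot, 1e-300))
    best_adj = np.full(len(ids), np.inf)
    hit = np.zeros(len(ids), dtype=bool)
    for subtype in np.unique(labels):
        mask = labels == subtype
        mean_in, mean_out = _group_means(fot, mask)
        with np.errstate(divide="ignore", invalid="ignore"):
            fc = np.where(mean_out > 0, mean_in / mean_out, np.inf)
        _, pvals = sps.ttest_ind(
            log_fot[:, mask], log_fot[:, ~mask], axis=1, equal_var=False
        )
        pvals = np.nan_to_num(pvals, nan=1.0)
        adjusted = multipletests(pvals, method="fdr_bh")[1]
        keep = (fc > fc_min) & (adjusted < alpha)
        hit |= keep
        best_adj = np.minimum(best_adj, np.where(keep, adjusted, np.inf))
    order = sorted(
        (i for i in range(len(ids)) if hit[i]), key=lambda i: (best_adj[i], ids[i])
    )
    return [ids[i] for i in order]


def _log_matrix(m: AbundanceMatrix, features: list[str]) -> np.ndarray:
    missing = [f for f in features if f not in m.fot.index]
    if missing:
        raise ValueError(f"features missing from matrix: {missing[:10]}")
    X = m.fot.loc[features].to_numpy(dtype=float).T  # samples x features
    return np.log10(np.maximum(X, 1e-300))


def train_classifier(
    m: AbundanceMatrix,
    labels: np.ndarray | pd.Series,
    features: list[str],
    seed: int,
    n_trees: int = 500,
    n_folds: int = 10,
) -> ClassifierModel:
    """Random forest on log10 FOT, tuned by stratified k-fold CV.

    The candidate-features-per-split grid is {sqrt(p), p/4, p/2}; the grid
    point with the best mean held-out accuracy wins (ties: first in grid
    order) and the forest is refit on all samples.  Fully deterministic for
    a fixed seed, including the fold assignment.
    """
    labels = np.asarray(labels)
    X = _log_matrix(m, features)
    if X.shape[0] < n_folds:
        raise ValueError(f"need at least {n_folds} samples")
    p = X.shape[1]
    grid = []
    for mf in ("sqrt", max(1, p // 4), max(1, p // 2)):
        if mf not in grid:
            grid.append(mf)
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    # record fold assignment once; identical across grid points
    fold_assign = np.empty(len(labels), dtype=int)
    splits = list(skf.split(X, labels))
    for fold, (_, test_idx) in enumerate(splits):
        fold_assign[test_idx] = fold

    classes = list(np.unique(labels))
    grid_scores: dict = {}
    cv_pred = {}
    for mf in grid:
        pred = np.empty(len(labels), dtype=object)
        correct = 0
        for train_idx, test_idx in splits:
            rf = RandomForestClassifier(
                n_estimators=n_trees, max_features=mf, random_state=seed
            )
            rf.fit(X[train_idx], labels[train_idx])
            yhat = rf.predict(X[test_idx])
            pred[test_idx] = yhat
            correct += int((yhat == labels[test_idx]).sum())
        grid_scores[mf] = correct / len(labels)
        cv_pred[mf] = pred
    best_mf = max(grid, key=lambda mf: grid_scores[mf])
    cv_accuracy = grid_scores[best_mf]

    pred = cv_pred[best_mf]
    per_class = pd.DataFrame(
        {
            "n": [int((labels == c).sum()) for c in classes],
            "recall": [
                float((pred[labels == c] == c).mean()) for c in classes
            ],
        },
        index=classes,
    )
    forest = RandomForestClassifier(
        n_estimators=n_trees, max_features=best_mf, random_state=seed
    )
    forest.fit(X, labels)
    return ClassifierModel(
        feature_ids=list(features),
        forest=forest,
        classes=classes,
        n_trees=n_trees,
        max_features=best_mf,
        seed=seed,
        fold_assignments=fold_assign,
        cv_accuracy=float(cv_accuracy),
        per_class_metrics=per_class,
        grid_scores=grid_scores,
    )


def predict_subtypes(
    model: ClassifierModel, m_external: AbundanceMatrix
) -> pd.DataFrame:
    """Apply a trained panel to an external cohort.

    Panel proteins absent from the external matrix are filled per sample with
    the below-detection imputation rule (minimum positive FOT of the sample
    divided by 10).  Errors out if more than half the panel is entirely
    absent — the panel is then not transferable.  Returns one row per sample
    with the predicted label and one probability column per class.
    """
    present = [f for f in model.feature_ids if f in m_external.fot.index]
    n_absent = len(model.feature_ids) - len(present)
    if n_absent > len(model.feature_ids) / 2:
        raise ValueError(
            f"{n_absent}/{len(model.feature_ids)} panel proteins absent from the "
            "external cohort; panel not transferable"
        )
    fot = m_external.fot
    fill = fot.where(fot > 0).min(axis=0).to_numpy() / 10.0
    X = np.empty((m_external.n_samples, len(model.feature_ids)))
    for j, f in enumerate(model.feature_ids):
        if f in fot.index:
            X[:, j] = fot.loc[f].to_numpy(dtype=float)
        else:
            X[:, j] = fill
    X = np.log10(np.maximum(X, 1e-300))
    proba = model.forest.predict_proba(X)
    labels = [model.forest.classes_[i] for i in proba.argmax(axis=1)]
    out = pd.DataFrame(proba, columns=[str(c) for c in model.forest.classes_])
    out.insert(0, "predicted", labels)
    out.index = pd.Index(m_external.sample_ids, name="sample_id")
    return out
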