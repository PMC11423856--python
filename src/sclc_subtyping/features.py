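"""Two-stage feature selection for clustering and classification.

Stage one collects, for each sample, its N most abundant detected proteins
and takes the union across samples (abundance filter).  Stage two keeps
proteins detected in strictly more than a given fraction of samples and — for
the clustering panel — with a coefficient of variation strictly above a
threshold (variability filter).  Defaults reproduce the discovery settings:
top 1100 per sample, detection > 10% of samples, CV > 1.9 for clustering;
top 500 and detection > 25% for the classifier candidate pool.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .quantify import AbundanceMatrix

__all__ = [
    "FeatureSet",
    "top_n_union",
    "compute_cv",
    "select_clustering_features",
    "select_classifier_candidates",
]


@dataclass
class FeatureSet:
    """A retained protein panel plus the per-protein statistics behind it."""

    stage: str  # "clustering" or "classifier"
    protein_ids: list[str]
    per_protein_stats: pd.DataFrame  # detection count/fraction, CV, mean FOT


def top_n_union(m: AbundanceMatrix, n: int) -> set[str]:
    """Union over samples of each sample's n highest-FOT detected proteins.

    Ties at the rank-n boundary are all included, so the result does not
    depend on protein order.  Samples with fewer than n detected proteins
    contribute all of them.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if m.fot.size == 0:
        raise ValueError("empty abundance matrix")
    fot = m.fot.to_numpy(dtype=float)
    det = m.detected.to_numpy(dtype=bool)
    proteins = np.asarray(m.protein_ids)
    out: set[str] = set()
    for j in range(fot.shape[1]):
        vals = np.where(det[:, j], fot[:, j], -np.inf)
        n_det = int(det[:, j].sum())
        if n_det == 0:
            continue
        if n_det <= n:
            out.update(proteins[det[:, j]])
            continue
        order = np.sort(vals)[::-1]
        cutoff = order[n - 1]  # include everything tied with rank n
        out.update(proteins[vals >= cutoff])
    return out


def compute_cv(values: np.ndarray) -> float:
    """Coefficient of variation: sample standard deviation (n-1) over mean."""
    values = np.asarray(values, dtype=float)
    mean = values.mean()
    if mean <= 0:
        raise ValueError("CV undefined for non-positive mean")
    if values.size < 2:
        return 0.0
    return float(values.std(ddof=1) / mean)


def _stats_table(m: AbundanceMatrix) -> pd.DataFrame:
    fot = m.fot.to_numpy(dtype=float)
    det = m.detected.to_numpy(dtype=bool)
    n_samples = fot.shape[1]
    mean = fot.mean(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        cv = np.where(mean > 0, fot.std(axis=1, ddof=1) / mean, np.nan)
    return pd.DataFrame(
        {
            "detect_count": det.sum(axis=1),
            "detect_fraction": det.sum(axis=1) / n_samples,
            "cv": cv,
            "mean_fot": mean,
        },
        index=m.fot.index,
    )


def select_clustering_features(
    m: AbundanceMatrix,
    top_n: int = 1100,
    min_detect_fraction: float = 0.10,
    cv_threshold: float = 1.9,
) -> FeatureSet:
    """Abundance union, then strict detection-frequency and CV filters.

    A protein is retained if it lies in the per-sample top-``top_n`` union,
    is detected in strictly more than ``min_detect_fraction`` of samples, and
    its CV across all samples (imputed values included) is strictly greater
    than ``cv_threshold``.
    """
    candidates = top_n_union(m, top_n)
    stats = _stats_table(m)
    in_union = stats.index.isin(candidates)
    keep = (
        in_union
        & (stats["detect_fraction"] > min_detect_fraction).to_numpy()
        & (stats["cv"] > cv_threshold).to_numpy()
    )
    ids = list(stats.index[keep])
    if not ids:
        raise ValueError(
            "no proteins pass the clustering filters; relax top_n, "
            "min_detect_fraction or cv_threshold"
        )
    return FeatureSet("clustering", ids, stats.loc[ids])


def select_classifier_candidates(
    m: AbundanceMatrix,
    top_n: int = 500,
    min_detect_fraction: float = 0.25,
) -> set[str]:
    """Abundance union plus strict detection-frequency filter (no CV filter)."""
    candidates = top_n_union(m, top_n)
    stats = _stats_table(m)
    keep = stats.index.isin(candidates) & (
        stats["detect_fraction"] > min_detect_fraction
    ).to_numpy()
    return set(stats.index[keep])
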