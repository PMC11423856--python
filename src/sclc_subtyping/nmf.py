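"""Consensus NMF subtyping with Brunet multiplicative updates.

The clustering engine is the classic KL-divergence non-negative matrix
factorisation of Brunet-style molecular subtyping: V (proteins x samples) is
approximated by W H with W >= 0 (proteins x k metagenes) and H >= 0
(k x samples), minimising the generalised Kullback–Leibler divergence

    D(V || WH) = sum_ij [ V_ij log(V_ij / (WH)_ij) - V_ij + (WH)_ij ]

by alternating multiplicative updates, which provably never increase D.
Each random restart assigns every sample to its dominant metagene (argmax
over the column of H); co-clustering indicators averaged over restarts give
the consensus matrix, whose entries estimate the probability that two
samples land in the same cluster.  Final labels come from average-linkage
hierarchical clustering of the dissimilarity (1 - consensus), and clustering
quality is the average silhouette width under that same dissimilarity.

The number of clusters k is chosen jointly on stability (average silhouette
above a threshold, minimum class size) and prognostic association
(multi-group log-rank on overall survival across the k labels).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from sklearn.metrics import silhouette_samples

from .survival import logrank_test

__all__ = [
    "NMFFactorization",
    "ConsensusResult",
    "KSelection",
    "nmf_brunet",
    "consensus_cluster",
    "select_k",
    "minmax_scale_rows",
]

_EPS = 1e-12


@dataclass
class NMFFactorization:
    W: np.ndarray
    H: np.ndarray
    k: int
    divergence_trace: np.ndarray
    seed: int
    n_iterations: int

    @property
    def divergence(self) -> float:
        return float(self.divergence_trace[-1])


@dataclass
class ConsensusResult:
    k: int
    consensus: np.ndarray  # samples x samples, in [0, 1]
    labels: np.ndarray  # cluster index per sample, 0..k-1
    average_silhouette: float
    per_sample_silhouette: np.ndarray
    min_class_size: int
    n_runs: int


@dataclass
class KSelection:
    """Outcome of the joint stability/prognosis choice of k."""

    chosen_k: int | None
    labels: np.ndarray | None
    report: pd.DataFrame  # one row per k: silhouette, min class, log-rank p, eligible
    results: dict[int, ConsensusResult] = field(default_factory=dict)

    @property
    def valid(self) -> bool:
        return self.chosen_k is not None


def _kl_divergence(V: np.ndarray, WH: np.ndarray) -> float:
    WH = np.maximum(WH, _EPS)
    pos = V > 0
    div = float(WH.sum() - V.sum())
    div += float((V[pos] * np.log(V[pos] / WH[pos])).sum())
    return div


def nmf_brunet(
    V: np.ndarray,
    k: int,
    seed: int,
    max_iter: int = 2000,
    tol: float = 1e-6,
    tol_window: int = 10,
) -> NMFFactorization:
    """KL-divergence NMF by Brunet multiplicative updates.

    Stops when the relative divergence change over ``tol_window`` iterations
    falls below ``tol`` or at ``max_iter``.  W and H start uniform-random in
    (0, 1] from ``seed``; the divergence trace is recorded every iteration
    and is non-increasing.
    """
    V = np.asarray(V, dtype=float)
    if (V < 0).any():
        raise ValueError("V must be non-negative")
    n, m = V.shape
    if not 1 <= k <= min(n, m):
        raise ValueError(f"k={k} out of range for a {n}x{m} matrix")
    if (V.sum(axis=1) == 0).any() or (V.sum(axis=0) == 0).any():
        raise ValueError("V must have no all-zero rows or columns")
    rng = np.random.default_rng(seed)
    W = 1.0 - rng.random((n, k))  # uniform in (0, 1]
    H = 1.0 - rng.random((k, m))
    trace = []
    WH = np.maximum(W @ H, _EPS)
    trace.append(_kl_divergence(V, WH))
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        # H update: H <- H * (W^T (V/WH)) / (W^T 1)
        H *= (W.T @ (V / WH)) / np.maximum(W.sum(axis=0)[:, None], _EPS)
        WH = np.maximum(W @ H, _EPS)
        # W update: W <- W * ((V/WH) H^T) / (1 H^T)
        W *= ((V / WH) @ H.T) / np.maximum(H.sum(axis=1)[None, :], _EPS)
        WH = np.maximum(W @ H, _EPS)
        trace.append(_kl_divergence(V, WH))
        if n_iter >= tol_window:
            prev = trace[-1 - tol_window]
            if abs(prev - trace[-1]) <= tol * max(abs(prev), _EPS):
                break
    return NMFFactorization(
        W=W, H=H, k=k, divergence_trace=np.asarray(trace), seed=seed,
        n_iterations=n_iter,
    )


def minmax_scale_rows(V: np.ndarray) -> np.ndarray:
    """Scale each row (protein) to [0, 1] across samples.

    FOT spans orders of magnitude; without per-feature scaling the KL
    objective is dominated by the handful of most abundant proteins.
    Constant rows (zero range) would become all-zero and are rejected.
    """
    V = np.asarray(V, dtype=float)
    lo = V.min(axis=1, keepdims=True)
    rng = V.max(axis=1, keepdims=True) - lo
    if (rng == 0).any():
        raise ValueError("constant rows cannot be min-max scaled; filter them first")
    return (V - lo) / rng


def consensus_cluster(
    V: np.ndarray,
    k: int,
    n_runs: int = 50,
    base_seed: int = 0,
    max_iter: int = 2000,
    tol: float = 1e-6,
) -> ConsensusResult:
    """Average co-clustering over random restarts and extract stable labels.

    Run r uses seed ``base_seed + r``; samples co-cluster in a run when they
    share the argmax row of H.  Labels come from average-linkage hierarchical
    clustering of (1 - consensus) cut at k; silhouettes use the same
    dissimilarity, with singleton clusters scored 0.
    """
    if n_runs < 1:
        raise ValueError("n_runs must be >= 1")
    V = np.asarray(V, dtype=float)
    m = V.shape[1]
    consensus = np.zeros((m, m))
    for r in range(n_runs):
        fit = nmf_brunet(V, k, seed=base_seed + r, max_iter=max_iter, tol=tol)
        assign = fit.H.argmax(axis=0)
        conn = (assign[:, None] == assign[None, :]).astype(float)
        consensus += conn
    consensus /= n_runs
    np.fill_diagonal(consensus, 1.0)
    consensus = (consensus + consensus.T) / 2.0

    dist = 1.0 - consensus
    np.fill_diagonal(dist, 0.0)
    if m > 1:
        Z = linkage(squareform(dist, checks=False), method="average")
        labels = fcluster(Z, t=k, criterion="maxclust") - 1
    else:
        labels = np.zeros(1, dtype=int)

    if len(np.unique(labels)) > 1:
        sil = silhouette_samples(dist, labels, metric="precomputed")
        # singleton clusters: silhouette 0 by convention
        counts = np.bincount(labels)
        sil[counts[labels] == 1] = 0.0
    else:
        sil = np.zeros(m)
    class_sizes = np.bincount(labels, minlength=int(labels.max()) + 1)
    class_sizes = class_sizes[class_sizes > 0]
    return ConsensusResult(
        k=k,
        consensus=consensus,
        labels=labels,
        average_silhouette=float(sil.mean()),
        per_sample_silhouette=sil,
        min_class_size=int(class_sizes.min()),
        n_runs=n_runs,
    )


def select_k(
    results: dict[int, ConsensusResult],
    clinical: pd.DataFrame,
    silhouette_min: float = 0.8,
    min_class: int = 10,
    prognostic_alpha: float = 0.01,
) -> KSelection:
    """Joint stability/prognosis selection of the cluster number.

    A value of k is eligible when average silhouette > ``silhouette_min``,
    the smallest class has >= ``min_class`` members, and the multi-group
    log-rank test of overall survival across the k labels has
    p < ``prognostic_alpha``.  Among eligible k the one with maximum average
    silhouette wins (ties: smallest k).  With no eligible k, the per-k report
    is returned with ``chosen_k = None`` rather than raising.
    """
    if not {"os_years", "os_event"}.issubset(clinical.columns):
        raise ValueError("clinical table must carry os_years and os_event")
    times = clinical["os_years"].to_numpy(dtype=float)
    events = clinical["os_event"].to_numpy(dtype=bool)
    rows = []
    for k in sorted(results):
        res = results[k]
        if len(res.labels) != len(clinical):
            raise ValueError("consensus labels do not align with the clinical table")
        n_classes = len(np.unique(res.labels))
        if n_classes >= 2 and events.sum() > 0:
            p = logrank_test(times, events, res.labels).p_value
        else:
            p = np.nan
        eligible = (
            res.average_silhouette > silhouette_min
            and res.min_class_size >= min_class
            and (not np.isnan(p) and p < prognostic_alpha)
        )
        rows.append(
            {
                "k": k,
                "average_silhouette": res.average_silhouette,
                "min_class_size": res.min_class_size,
                "logrank_p": p,
                "eligible": eligible,
            }
        )
    report = pd.DataFrame(rows).set_index("k")
    eligible_k = report.index[report["eligible"]]
    if len(eligible_k) == 0:
        return KSelection(chosen_k=None, labels=None, report=report, results=results)
    best = report.loc[eligible_k, "average_silhouette"]
    chosen = int(best.index[np.argmax(best.to_numpy())])  # ties -> smallest k (sorted)
    return KSelection(
        chosen_k=chosen, labels=results[chosen].labels, report=report, results=results
    )
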