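"""K-means sweep and bootstrap cluster-stability selection.

Patients are partitioned with K-means (k-means++, best of ``n_init``
restarts) for each K in a sweep, and each K is scored for reproducibility
with a clusterwise bootstrap in the spirit of Hennig's clusterboot: resample
patients with replacement, refit at the same K, and record for every
reference cluster the best Jaccard match among bootstrap clusters (both
restricted to the unique patients drawn).  A value of K is *stable* when its
least-stable cluster's mean best-match Jaccard clears a threshold
(default 0.75 over B=100 replicates).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

from .vectorize import TfidfMatrix

DEFAULT_N_INIT = 10
DEFAULT_MAX_ITER = 300
DEFAULT_TOL = 1e-4
DEFAULT_N_BOOTSTRAP = 100
DEFAULT_STABILITY_THRESHOLD = 0.75
DEFAULT_BOOTSTRAP_N_INIT = 5


def derive_seed(master_seed: int, *key: int) -> int:
    """Deterministic child seed in [0, 2**31) from a master seed and a key."""
    ss = np.random.SeedSequence([int(master_seed), *map(int, key)])
    return int(ss.generate_state(1, dtype=np.uint32)[0] % (2**31))


@dataclass(frozen=True)
class ClusteringResult:
    """A K-means partition at one K."""

    K: int
    labels: np.ndarray = field(repr=False)
    centroids: np.ndarray = field(repr=False)
    inertia: float
    seed: int

    def __post_init__(self) -> None:
        sizes = np.bincount(self.labels, minlength=self.K)
        if (sizes == 0).any():
            raise ValueError("empty cluster in clustering result")
        if self.labels.min() < 0 or self.labels.max() >= self.K:
            raise ValueError("labels out of range [0, K)")

    @property
    def cluster_sizes(self) -> np.ndarray:
        return np.bincount(self.labels, minlength=self.K)

    def members(self, cluster_id: int) -> np.ndarray:
        return np.flatnonzero(self.labels == cluster_id)


@dataclass(frozen=True)
class StabilityReport:
    """Bootstrap stability of one K's reference partition."""

    K: int
    per_cluster_stability: np.ndarray = field(repr=False)
    n_bootstrap: int
    threshold: float

    def __post_init__(self) -> None:
        s = self.per_cluster_stability
        if len(s) != self.K:
            raise ValueError("need one stability value per cluster")
        if (s < 0).any() or (s > 1).any():
            raise ValueError("stability values must lie in [0, 1]")

    @property
    def min_stability(self) -> float:
        return float(self.per_cluster_stability.min())

    @property
    def stable(self) -> bool:
        return self.min_stability >= self.threshold


def fit_kmeans(
    X: TfidfMatrix | np.ndarray,
    K: int,
    seed: int,
    n_init: int = DEFAULT_N_INIT,
    max_iter: int = DEFAULT_MAX_ITER,
    tol: float = DEFAULT_TOL,
) -> ClusteringResult:
    """Lloyd's K-means with k-means++ init, best of ``n_init`` restarts.

    Deterministic given (X, K, seed, n_init).  K must satisfy
    2 <= K <= n_patients.
    """
    values = X.values if isinstance(X, TfidfMatrix) else np.asarray(X)
    n = values.shape[0]
    if K < 2:
        raise ValueError(f"K must be >= 2, got {K}")
    if K > n:
        raise ValueError(f"K={K} exceeds number of patients ({n})")
    km = KMeans(
        n_clusters=K,
        init="k-means++",
        n_init=n_init,
        max_iter=max_iter,
        tol=tol,
        random_state=seed,
    ).fit(values)
    return ClusteringResult(
        K=K,
        labels=km.labels_.astype(np.int64),
        centroids=km.cluster_centers_,
        inertia=float(km.inertia_),
        seed=seed,
    )


def result_from_labels(
    X: TfidfMatrix | np.ndarray, labels: np.ndarray, seed: int = -1
) -> ClusteringResult:
    """Reconstruct a :class:`ClusteringResult` from a persisted label
    vector (centroids = cluster means; inertia recomputed)."""
    values = X.values if isinstance(X, TfidfMatrix) else np.asarray(X)
    labels = np.asarray(labels, dtype=np.int64)
    K = int(labels.max()) + 1
    centroids = np.vstack([values[labels == k].mean(axis=0) for k in range(K)])
    inertia = float(((values - centroids[labels]) ** 2).sum())
    return ClusteringResult(K=K, labels=labels, centroids=centroids, inertia=inertia, seed=seed)


def sweep_kmeans(
    X: TfidfMatrix | np.ndarray,
    K_values: Sequence[int],
    seed: int,
    **kmeans_kwargs,
) -> dict[int, ClusteringResult]:
    """Fit K-means for each K; per-K seeds derived from the master seed."""
    ks = list(K_values)
    if any(b <= a for a, b in zip(ks, ks[1:])):
        raise ValueError("K_values must be strictly increasing")
    if ks and ks[0] < 2:
        raise ValueError("all K values must be >= 2")
    return {K: fit_kmeans(X, K, derive_seed(seed, K), **kmeans_kwargs) for K in ks}


def _max_jaccard_per_reference(
    ref_labels: np.ndarray, boot_labels: np.ndarray, K_ref: int, K_boot: int
) -> np.ndarray:
    """For each reference cluster, the max Jaccard over bootstrap clusters.

    Both label vectors are defined on the same (unique) patient subset.
    Reference clusters with no member in the subset score 0 (the cluster
    dissolved in this replicate).
    """
    contingency = np.zeros((K_ref, K_boot), dtype=np.int64)
    np.add.at(contingency, (ref_labels, boot_labels), 1)
    ref_sizes = contingency.sum(axis=1)
    boot_sizes = contingency.sum(axis=0)
    union = ref_sizes[:, None] + boot_sizes[None, :] - contingency
    with np.errstate(invalid="ignore", divide="ignore"):
        jac = np.where(union > 0, contingency / union, 0.0)
    best = jac.max(axis=1)
    best[ref_sizes == 0] = 0.0
    return best


def bootstrap_stability(
    X: TfidfMatrix | np.ndarray,
    reference: ClusteringResult,
    B: int = DEFAULT_N_BOOTSTRAP,
    seed: int = 0,
    threshold: float = DEFAULT_STABILITY_THRESHOLD,
    n_init: int = DEFAULT_BOOTSTRAP_N_INIT,
) -> StabilityReport:
    """Clusterwise bootstrap stability of a reference partition.

    For each of B resamples of patients (with replacement): refit K-means at
    the same K with a fresh derived seed, then score each reference cluster
    by its best Jaccard match among the bootstrap clusters, both patient
    sets restricted to the unique patients drawn.  Per-cluster stability is
    the mean best-match Jaccard over replicates.
    """
    if B < 1:
        raise ValueError(f"B must be >= 1, got {B}")
    if not 0.0 < threshold < 1.0:
        raise ValueError(f"threshold must lie in (0, 1), got {threshold}")
    values = X.values if isinstance(X, TfidfMatrix) else np.asarray(X)
    n = values.shape[0]
    K = reference.K
    rng = np.random.default_rng(derive_seed(seed, K, 0xB007))
    totals = np.zeros(K)
    for b in range(B):
        idx = rng.integers(0, n, size=n)
        refit = fit_kmeans(
            values[idx], K, derive_seed(seed, K, b + 1), n_init=n_init
        )
        uniq, first_pos = np.unique(idx, return_index=True)
        totals += _max_jaccard_per_reference(
            reference.labels[uniq], refit.labels[first_pos], K, K
        )
    return StabilityReport(
        K=K, per_cluster_stability=totals / B, n_bootstrap=B, threshold=threshold
    )


def select_stable(reports: Sequence[StabilityReport]) -> list[int]:
    """Ascending list of K values whose report is flagged stable."""
    ks = [r.K for r in reports]
    if len(set(ks)) != len(ks):
        raise ValueError("reports must cover distinct K values")
    return sorted(r.K for r in reports if r.stable)


# ---------------------------------------------------------------------------
# Persistence helpers (TSV dialects)


def labels_frame(
    clusterings: Mapping[int, ClusteringResult], patient_index: Sequence[str]
) -> pd.DataFrame:
    """Long-format (patient_id, K, cluster) table across a sweep."""
    rows = []
    for K in sorted(clusterings):
        for pid, lab in zip(patient_index, clusterings[K].labels):
            rows.append((pid, K, int(lab)))
    return pd.DataFrame(rows, columns=["patient_id", "K", "cluster"])


def stability_frame(reports: Sequence[StabilityReport]) -> pd.DataFrame:
    rows = []
    for r in sorted(reports, key=lambda r: r.K):
        for cid, s in enumerate(r.per_cluster_stability):
            rows.append((r.K, cid, float(s), r.stable))
    return pd.DataFrame(rows, columns=["K", "cluster", "stability", "stable_K"])


def load_labels(path: str | Path) -> tuple[dict[int, np.ndarray], list[str]]:
    """Inverse of :func:`labels_frame` written to TSV: per-K label vectors
    plus the patient order."""
    t = pd.read_csv(path, sep="\t", dtype={"patient_id": str})
    first_k = t["K"].min()
    patients = t.loc[t["K"] == first_k, "patient_id"].tolist()
    out = {}
    for K, grp in t.groupby("K"):
        if grp["patient_id"].tolist() != patients:
            raise ValueError("inconsistent patient order across K blocks")
        out[int(K)] = grp["cluster"].to_numpy(np.int64)
    return out, patients
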