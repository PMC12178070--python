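"""Integration benchmarking: batch-effect-removal and biological-conservation
scores, each mapped to [0, 1], with the standard 0.4/0.6 aggregate.

Batch removal: iLISI (local inverse Simpson's index of batch composition,
rescaled) and a kBET-style chi-squared acceptance rate.  Bio conservation:
KMeans ARI against true labels and the mean silhouette of labels rescaled
from [-1, 1].  ``overall = 0.4 * batch_score + 0.6 * bio_score``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from sklearn.cluster import KMeans
from sklearn.metrics import adjusted_rand_score, silhouette_samples
from sklearn.neighbors import NearestNeighbors

__all__ = [
    "MetricsReport",
    "kmeans_ari",
    "silhouette_label",
    "ilisi",
    "kbet_acceptance",
    "aggregate",
    "benchmark_embedding",
]


@dataclass
class MetricsReport:
    kmeans_ari: float
    silhouette_label: float
    ilisi: float
    kbet_acceptance: float
    batch_score: float
    bio_score: float
    overall: float
    parameters: dict = field(default_factory=dict)

    def as_dict(self) -> dict:
        return {k: getattr(self, k) for k in
                ("kmeans_ari", "silhouette_label", "ilisi", "kbet_acceptance",
                 "batch_score", "bio_score", "overall")}


def kmeans_ari(embedding: np.ndarray, true_labels, seed: int = 0) -> float:
    """ARI between a seeded KMeans (k = number of true labels) and the labels,
    truncated at zero so the score lies in [0, 1]."""
    embedding = np.asarray(embedding, dtype=np.float64)
    labels = np.asarray(true_labels)
    k = len(np.unique(labels))
    if k < 2:
        raise ValueError("need at least two distinct true labels")
    if len(embedding) < k:
        raise ValueError("fewer cells than clusters")
    km = KMeans(n_clusters=k, n_init=10, random_state=seed).fit(embedding)
    return float(max(0.0, adjusted_rand_score(labels, km.labels_)))


def silhouette_label(embedding: np.ndarray, true_labels) -> float:
    """Mean silhouette of the labels rescaled from [-1, 1] to [0, 1]."""
    labels = np.asarray(true_labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("silhouette undefined for a single label")
    s = silhouette_samples(np.asarray(embedding, dtype=np.float64), labels)
    return float((np.mean(s) + 1.0) / 2.0)


def ilisi(embedding: np.ndarray, batch_ids, k: int = 90) -> float:
    """Distance-weighted local inverse Simpson's index of batch mixing.

    For each cell, neighbor batch proportions are weighted with a Gaussian
    kernel (bandwidth = median neighbor distance); the per-cell inverse
    Simpson index (effective batch number) is averaged and rescaled to
    [0, 1] via ``(LISI - 1) / (B - 1)``.
    """
    embedding = np.asarray(embedding, dtype=np.float64)
    batches = np.asarray(batch_ids)
    uniq = np.unique(batches)
    B = len(uniq)
    if B == 1:
        return 1.0
    codes = np.searchsorted(uniq, batches)
    k = min(k, len(embedding) - 1)
    nn = NearestNeighbors(n_neighbors=k + 1).fit(embedding)
    dist, idx = nn.kneighbors(embedding)
    dist, idx = dist[:, 1:], idx[:, 1:]  # drop self
    lisi = np.empty(len(embedding))
    for c in range(len(embedding)):
        d = dist[c]
        bw = np.median(d)
        w = np.exp(-(d / bw) ** 2) if bw > 0 else np.ones_like(d)
        w = w / w.sum()
        p = np.bincount(codes[idx[c]], weights=w, minlength=B)
        lisi[c] = 1.0 / np.sum(p ** 2)
    return float(np.clip((lisi.mean() - 1.0) / (B - 1.0), 0.0, 1.0))


def kbet_acceptance(embedding: np.ndarray, batch_ids, k: int = 50,
                    n_samples: int = 500, seed: int = 0) -> float:
    """Fraction of sampled neighborhoods whose batch composition is
    statistically indistinguishable (chi-squared, alpha = 0.05) from the
    global batch proportions."""
    embedding = np.asarray(embedding, dtype=np.float64)
    batches = np.asarray(batch_ids)
    uniq = np.unique(batches)
    B = len(uniq)
    if B == 1:
        return 1.0
    codes = np.searchsorted(uniq, batches)
    global_prop = np.bincount(codes, minlength=B) / len(codes)
    n = len(embedding)
    k = min(k, n - 1)
    rng = np.random.default_rng(seed)
    sample = rng.choice(n, size=min(n_samples, n), replace=False)
    nn = NearestNeighbors(n_neighbors=k + 1).fit(embedding)
    _, idx = nn.kneighbors(embedding[sample])
    accepted, tested = 0, 0
    for row in idx:
        kk = k
        neigh = row[1:kk + 1]
        expected = global_prop * kk
        if expected.min() < 5:
            kk = min(n - 1, int(np.ceil(5 / max(global_prop.min(), 1e-12))))
            expected = global_prop * kk
            if expected.min() < 5:
                continue  # cannot form a valid test; skip (logged via tested)
            neigh = NearestNeighbors(n_neighbors=kk + 1).fit(embedding) \
                .kneighbors(embedding[row[0]][None, :])[1][0][1:]
        observed = np.bincount(codes[neigh], minlength=B)
        chi2 = float(np.sum((observed - expected) ** 2 / expected))
        pval = stats.chi2.sf(chi2, df=B - 1)
        tested += 1
        if pval >= 0.05:
            accepted += 1
    if tested == 0:
        warnings.warn("no valid kBET neighborhoods; returning 0")
        return 0.0
    return accepted / tested


def aggregate(kmeans_ari_score: float, silhouette_score: float,
              ilisi_score: float, kbet_score: float,
              parameters: dict | None = None) -> MetricsReport:
    """Combine the four part scores into the weighted report.

    ``batch = mean(iLISI, kBET)``, ``bio = mean(ARI, silhouette)``,
    ``overall = 0.4 * batch + 0.6 * bio``.
    """
    batch = float(np.mean([ilisi_score, kbet_score]))
    bio = float(np.mean([kmeans_ari_score, silhouette_score]))
    return MetricsReport(
        kmeans_ari=kmeans_ari_score, silhouette_label=silhouette_score,
        ilisi=ilisi_score, kbet_acceptance=kbet_score,
        batch_score=batch, bio_score=bio,
        overall=0.4 * batch + 0.6 * bio,
        parameters=dict(parameters or {}))


def benchmark_embedding(embedding: np.ndarray, true_labels, batch_ids,
                        seed: int = 0, k_ilisi: int = 90, k_kbet: int = 50,
                        n_samples_kbet: int = 500) -> MetricsReport:
    """Compute all four metrics on one embedding and aggregate them."""
    return aggregate(
        kmeans_ari(embedding, true_labels, seed=seed),
        silhouette_label(embedding, true_labels),
        ilisi(embedding, batch_ids, k=k_ilisi),
        kbet_acceptance(embedding, batch_ids, k=k_kbet,
                        n_samples=n_samples_kbet, seed=seed),
        parameters={"k_ilisi": k_ilisi, "k_kbet": k_kbet,
                    "n_samples_kbet": n_samples_kbet, "seed": seed})
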