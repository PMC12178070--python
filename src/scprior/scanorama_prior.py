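"""Panorama-style multi-batch embedding integration modulated by a
cell-type prior-similarity matrix.

The integrator follows the classic panorama recipe — a shared randomized-SVD
embedding, mutual-nearest-neighbor (MNN) anchors between batches, and
Gaussian-smoothed displacement vectors — with two prior-informed changes:

* MNN search runs on similarity-weighted distances ``d'_ij = d_ij / M_IJ``,
  where ``M_IJ`` is the prior similarity of the two cells' type labels, so
  anchors between same/similar types are favoured over cross-type anchors.
* Each matched pair's displacement receives a group-cohesive correction
  ``M_IJ * (v_i - v_I - v_j + v_J)`` built from the type centroids, which
  moves source groups as units toward their target groups and preserves the
  relative position of each cell within its cluster.

With ``M=None`` the module runs its prior-free code path: unweighted MNN
plus the centroid correction at full (unit) weight; passing an all-ones
matrix reproduces it exactly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist

from .similarity import PriorSimilarityMatrix, normalize_label

__all__ = [
    "PanoramaEmbedding",
    "CentroidTable",
    "MnnMatchSet",
    "reduce_dimensions",
    "prior_weighted_mnn",
    "alignment_scores",
    "compute_bias",
    "integrate",
]

SIGMA_DEFAULT = 15.0  # Gaussian smoothing: w = exp(-0.5 * sigma * d^2)


@dataclass
class PanoramaEmbedding:
    """Shared low-dimensional coordinates for one batch (or a panorama)."""

    coords: np.ndarray
    batch: np.ndarray
    labels: np.ndarray

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=np.float64)
        self.batch = np.asarray(self.batch, dtype=object)
        self.labels = np.asarray(self.labels, dtype=object)
        if self.coords.ndim != 2:
            raise ValueError("coords must be 2-D")
        if not (len(self.coords) == len(self.batch) == len(self.labels)):
            raise ValueError("coords, batch and labels must align")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("coords contain non-finite values")

    @property
    def n_cells(self) -> int:
        return self.coords.shape[0]

    def copy(self) -> "PanoramaEmbedding":
        return PanoramaEmbedding(self.coords.copy(), self.batch.copy(),
                                 self.labels.copy())


class CentroidTable:
    """Mean embedding vector and cell count per cell-type label."""

    def __init__(self, coords: np.ndarray, labels: np.ndarray) -> None:
        coords = np.asarray(coords, dtype=np.float64)
        labels = np.asarray(labels, dtype=object)
        self.centroids: dict[str, np.ndarray] = {}
        self.counts: dict[str, int] = {}
        self._by_norm: dict[str, str] = {}
        for lab in sorted(set(map(str, labels))):
            mask = labels == lab
            self.centroids[lab] = coords[mask].mean(axis=0)
            self.counts[lab] = int(mask.sum())
            self._by_norm[normalize_label(lab)] = lab

    def centroid(self, label: str) -> np.ndarray:
        key = str(label) if str(label) in self.centroids \
            else self._by_norm[normalize_label(label)]
        return self.centroids[key]

    def __contains__(self, label: str) -> bool:
        return str(label) in self.centroids or \
            normalize_label(label) in self._by_norm


@dataclass
class MnnMatchSet:
    """Mutual matches between a source batch A and a target batch B."""

    i: np.ndarray            # indices into A
    j: np.ndarray            # indices into B
    dist_raw: np.ndarray     # d_ij
    dist_weighted: np.ndarray  # d'_ij = d_ij / M_IJ

    def __len__(self) -> int:
        return len(self.i)


def reduce_dimensions(datasets, d: int = 100, seed: int = 0,
                      label_key: str = "label_given",
                      batch_key: str = "batch",
                      layer: str | None = "lognorm") -> list[PanoramaEmbedding]:
    """Embed all batches into one randomized-SVD space.

    Uses the intersection of highly variable genes (falling back to all
    shared genes when no HVG flags are present), L2-normalizes each cell,
    stacks the batches, and reduces to ``d`` components with a seeded
    truncated SVD.
    """
    from sklearn.decomposition import TruncatedSVD

    gene_sets = []
    for adata in datasets:
        genes = set(adata.var_names[adata.var["highly_variable"]]) \
            if "highly_variable" in adata.var else set(adata.var_names)
        gene_sets.append(genes)
    shared = sorted(set.intersection(*gene_sets))
    if not shared:
        raise ValueError("empty gene intersection across datasets; per-dataset "
                         f"gene counts: {[len(s) for s in gene_sets]}")
    blocks, batches, labels = [], [], []
    for adata in datasets:
        sub = adata[:, shared]
        X = sub.layers[layer] if layer and layer in sub.layers else sub.X
        X = np.asarray(X.todense()) if hasattr(X, "todense") else np.asarray(X)
        X = X.astype(np.float64)
        norms = np.linalg.norm(X, axis=1, keepdims=True)
        norms[norms == 0] = 1.0
        blocks.append(X / norms)
        batches.append(np.asarray(adata.obs[batch_key], dtype=object))
        labels.append(np.asarray(adata.obs[label_key], dtype=object))
    stacked = np.vstack(blocks)
    n_comp = min(d, stacked.shape[1] - 1, stacked.shape[0] - 1)
    svd = TruncatedSVD(n_components=n_comp, random_state=seed)
    coords = svd.fit_transform(stacked)
    out, offset = [], 0
    for block, bat, lab in zip(blocks, batches, labels):
        n = block.shape[0]
        out.append(PanoramaEmbedding(coords[offset:offset + n], bat, lab))
        offset += n
    return out


def _similarity_lookup(labels_a: np.ndarray, labels_b: np.ndarray,
                       M: PriorSimilarityMatrix | None
                       ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-cell label codes plus the (types_a x types_b) similarity block."""
    uniq_a = sorted(set(map(str, labels_a)))
    uniq_b = sorted(set(map(str, labels_b)))
    code_a = np.array([uniq_a.index(str(l)) for l in labels_a])
    code_b = np.array([uniq_b.index(str(l)) for l in labels_b])
    sim = np.ones((len(uniq_a), len(uniq_b)))
    if M is not None:
        for ia, la in enumerate(uniq_a):
            for ib, lb in enumerate(uniq_b):
                sim[ia, ib] = M.lookup(la, lb)
    return code_a, code_b, sim


def _knn_from_dist(dist: np.ndarray, k: int) -> list[np.ndarray]:
    k = min(k, dist.shape[1])
    idx = np.argpartition(dist, k - 1, axis=1)[:, :k]
    return [set(row.tolist()) for row in idx]


def prior_weighted_mnn(A: PanoramaEmbedding, B: PanoramaEmbedding,
                       M: PriorSimilarityMatrix | None, k: int = 30,
                       approx: bool = False, pool_factor: int = 5
                       ) -> MnnMatchSet:
    """Mutual nearest neighbors under similarity-weighted distances.

    Exact mode divides the full pairwise Euclidean distance matrix by
    ``M_IJ`` entrywise before the k-NN search in both directions.  The
    approximate (two-stage) mode first retrieves ``pool_factor * k``
    candidates by raw distance through an index, then re-ranks the pool by
    weighted distance to pick ``k``; cross-type anchors outside the raw
    candidate pool are unreachable by design.
    """
    if k >= min(A.n_cells, B.n_cells):
        k_new = max(1, min(A.n_cells, B.n_cells) - 1)
        if k_new != k:
            warnings.warn(f"k={k} >= batch size; clamping to {k_new}")
        k = k_new
    code_a, code_b, sim = _similarity_lookup(A.labels, B.labels, M)
    pair_sim_rows = sim[code_a]  # (nA, n_types_b)

    if not approx:
        dist = cdist(A.coords, B.coords)
        weighted = dist / pair_sim_rows[:, code_b]
        nn_a = _knn_from_dist(weighted, k)       # for each a: set of b
        nn_b = _knn_from_dist(weighted.T, k)     # for each b: set of a
        pairs_i, pairs_j = [], []
        for a, neigh in enumerate(nn_a):
            for b in neigh:
                if a in nn_b[b]:
                    pairs_i.append(a)
                    pairs_j.append(b)
        pairs_i = np.asarray(pairs_i, dtype=np.int64)
        pairs_j = np.asarray(pairs_j, dtype=np.int64)
        d_raw = dist[pairs_i, pairs_j]
        d_w = weighted[pairs_i, pairs_j]
        order = np.lexsort((pairs_j, pairs_i))
        return MnnMatchSet(pairs_i[order], pairs_j[order],
                           d_raw[order], d_w[order])

    from sklearn.neighbors import NearestNeighbors

    pool = min(pool_factor * k, B.n_cells)
    pool_rev = min(pool_factor * k, A.n_cells)
    nn_idx_b = NearestNeighbors(n_neighbors=pool).fit(B.coords)
    d_ab, cand_ab = nn_idx_b.kneighbors(A.coords)
    nn_idx_a = NearestNeighbors(n_neighbors=pool_rev).fit(A.coords)
    d_ba, cand_ba = nn_idx_a.kneighbors(B.coords)

    def rerank(dists, cands, sim_of):
        out = []
        for row in range(len(cands)):
            w = dists[row] / sim_of(row, cands[row])
            keep = cands[row][np.argsort(w, kind="stable")[:k]]
            out.append(set(keep.tolist()))
        return out

    nn_a = rerank(d_ab, cand_ab, lambda r, c: pair_sim_rows[r, code_b[c]])
    sim_t = sim.T
    pair_sim_rows_b = sim_t[code_b]
    nn_b = rerank(d_ba, cand_ba, lambda r, c: pair_sim_rows_b[r, code_a[c]])
    pairs_i, pairs_j, d_raw, d_w = [], [], [], []
    for a, neigh in enumerate(nn_a):
        for b in neigh:
            if a in nn_b[b]:
                d = float(np.linalg.norm(A.coords[a] - B.coords[b]))
                pairs_i.append(a)
                pairs_j.append(b)
                d_raw.append(d)
                d_w.append(d / sim[code_a[a], code_b[b]])
    order = np.lexsort((pairs_j, pairs_i))
    return MnnMatchSet(np.asarray(pairs_i, dtype=np.int64)[order],
                       np.asarray(pairs_j, dtype=np.int64)[order],
                       np.asarray(d_raw)[order], np.asarray(d_w)[order])


def alignment_scores(embeddings, M: PriorSimilarityMatrix | None,
                     k: int = 30, approx: bool = False) -> np.ndarray:
    """Pairwise batch alignability: the fraction of the smaller batch's
    cells that participate in at least one mutual match."""
    n = len(embeddings)
    if n < 2:
        raise ValueError("need at least two batches")
    scores = np.zeros((n, n))
    for a in range(n):
        for b in range(a + 1, n):
            matches = prior_weighted_mnn(embeddings[a], embeddings[b], M,
                                         k=k, approx=approx)
            small = min(embeddings[a].n_cells, embeddings[b].n_cells)
            if embeddings[a].n_cells <= embeddings[b].n_cells:
                matched = len(set(matches.i.tolist()))
            else:
                matched = len(set(matches.j.tolist()))
            scores[a, b] = scores[b, a] = matched / small
    return scores


def pair_bias(matches: MnnMatchSet, A: PanoramaEmbedding, B: PanoramaEmbedding,
              centroids_a: CentroidTable, centroids_b: CentroidTable,
              M: PriorSimilarityMatrix | None) -> np.ndarray:
    """Per-matched-pair displacement with the group-cohesive correction.

    ``bias'_p = (v_j - v_i) + M_IJ * (v_i - v_I - v_j + v_J)``; with
    ``M=None`` the correction weight is 1 (prior-free group-cohesive path).
    """
    vi = A.coords[matches.i]
    vj = B.coords[matches.j]
    vI = np.vstack([centroids_a.centroid(l) for l in A.labels[matches.i]]) \
        if len(matches) else np.zeros_like(vi)
    vJ = np.vstack([centroids_b.centroid(l) for l in B.labels[matches.j]]) \
        if len(matches) else np.zeros_like(vj)
    if M is None:
        weights = np.ones(len(matches))
    else:
        weights = np.array([M.lookup(la, lb) for la, lb in
                            zip(A.labels[matches.i], B.labels[matches.j])])
    return (vj - vi) + weights[:, None] * (vi - vI - vj + vJ)


def _smooth(coords: np.ndarray, anchor_coords: np.ndarray,
            anchor_bias: np.ndarray, sigma: float) -> tuple[np.ndarray, np.ndarray]:
    """Gaussian-kernel smoothing of anchor displacements over all cells."""
    d2 = cdist(coords, anchor_coords, "sqeuclidean")
    w = np.exp(-0.5 * sigma * d2)
    wsum = w.sum(axis=1)
    safe = wsum > 1e-300
    bias = np.zeros((len(coords), anchor_bias.shape[1]))
    bias[safe] = (w[safe] @ anchor_bias) / wsum[safe, None]
    return bias, wsum


def compute_bias(matches: MnnMatchSet, A: PanoramaEmbedding,
                 B: PanoramaEmbedding, centroids_a: CentroidTable,
                 centroids_b: CentroidTable,
                 M: PriorSimilarityMatrix | None,
                 sigma: float = SIGMA_DEFAULT) -> np.ndarray:
    """Per-cell displacement matrix shifting batch A toward batch B.

    Matched-pair biases (including the centroid correction) are smoothed over
    all of A's cells with a Gaussian kernel.  Cells without any mutual match
    inherit the displacement of their expression-nearest matched same-label
    cells (top 10, inverse-distance weighted), keeping unmatched cells close
    to their own group instead of drifting toward foreign displacement
    fields.
    """
    if len(matches) == 0:
        warnings.warn("empty match set; returning zero displacement")
        return np.zeros_like(A.coords)
    pb = pair_bias(matches, A, B, centroids_a, centroids_b, M)
    anchor_coords = A.coords[matches.i]
    bias, _ = _smooth(A.coords, anchor_coords, pb, sigma)

    matched_cells = np.unique(matches.i)
    unmatched = np.setdiff1d(np.arange(A.n_cells), matched_cells)
    if len(unmatched):
        matched_labels = A.labels[matched_cells]
        for cell in unmatched:
            same = matched_cells[matched_labels == A.labels[cell]]
            if len(same) == 0:
                continue  # keep the globally smoothed displacement
            d = np.linalg.norm(A.coords[same] - A.coords[cell], axis=1)
            top = same[np.argsort(d, kind="stable")[:10]]
            dd = np.linalg.norm(A.coords[top] - A.coords[cell], axis=1)
            w = 1.0 / (dd + 1e-12)
            bias[cell] = (w[:, None] * bias[top]).sum(axis=0) / w.sum()
    return bias


def integrate(embeddings, M: PriorSimilarityMatrix | None = None,
              k: int = 30, sigma: float = SIGMA_DEFAULT,
              approx: bool = False, seed: int = 0,
              min_alignment: float = 0.0) -> PanoramaEmbedding:
    """Greedy panorama assembly over all batches.

    Batches join the panorama in descending alignment-score order; each
    incoming batch is anchored to the current panorama with prior-weighted
    MNN and shifted by the smoothed, centroid-corrected displacement.  The
    output preserves the input cell order and is deterministic in exact
    mode under a fixed seed.
    """
    embeddings = [e.copy() for e in embeddings]
    n = len(embeddings)
    if n < 2:
        raise ValueError("need at least two batches to integrate")
    scores = alignment_scores(embeddings, M, k=k, approx=approx)
    start = int(np.argmax(scores.sum(axis=1)))
    in_pan = [start]
    remaining = [i for i in range(n) if i != start]
    while remaining:
        best_scores = [max(scores[r, p] for p in in_pan) for r in remaining]
        pick = int(np.argmax(best_scores))
        batch_idx = remaining.pop(pick)
        if best_scores[pick] <= min_alignment:
            warnings.warn(f"batch index {batch_idx} has no alignment to the "
                          "panorama; appended uncorrected")
            in_pan.append(batch_idx)
            continue
        pan = PanoramaEmbedding(
            np.vstack([embeddings[p].coords for p in in_pan]),
            np.concatenate([embeddings[p].batch for p in in_pan]),
            np.concatenate([embeddings[p].labels for p in in_pan]))
        src = embeddings[batch_idx]
        matches = prior_weighted_mnn(src, pan, M, k=k, approx=approx)
        cent_a = CentroidTable(src.coords, src.labels)
        cent_b = CentroidTable(pan.coords, pan.labels)
        bias = compute_bias(matches, src, pan, cent_a, cent_b, M, sigma=sigma)
        src.coords = src.coords + bias
        in_pan.append(batch_idx)
    return PanoramaEmbedding(
        np.vstack([e.coords for e in embeddings]),
        np.concatenate([e.batch for e in embeddings]),
        np.concatenate([e.labels for e in embeddings]))
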