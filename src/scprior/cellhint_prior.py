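"""Cross-dataset cell-type harmonization blending expression evidence with
label priors, weighted per cell by an entropy-derived uncertainty.

For each cell the distance to every target cell-type centroid is converted
to a similarity ``S = exp(-D / mean(D))``.  A per-cell uncertainty
``alpha = H(p) / log(K)`` (normalized Shannon entropy of the cell's
similarity distribution over the K target types; the inversion of the
clarity score) modulates how much of the label prior ``M`` is blended in:

    S'_iJ = beta * [(1 - alpha_i) S_iJ + alpha_i M_IJ] + (1 - beta) S_iJ

so confident cells (alpha ~ 0) rely on expression while ambiguous cells
lean on the prior, and the overall prior influence is bounded by ``beta``
(default 0.1) — a deliberately conservative incorporation.  Type-level
assignment fractions between dataset pairs are classified into one-to-one /
split / merge / novel relationships and merged into harmonization groups.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from .scanorama_prior import CentroidTable
from .similarity import PriorSimilarityMatrix, normalize_label

__all__ = [
    "SoftAssignment",
    "HarmonizationTable",
    "cell_type_distances",
    "normalize_to_similarity",
    "clarity_alpha",
    "adjust_similarity",
    "harmonize",
]


@dataclass
class SoftAssignment:
    """Cell-by-target-type matrices for one dataset pair direction."""

    target_types: list[str]
    D: np.ndarray
    S: np.ndarray
    S_adj: np.ndarray
    alpha: np.ndarray
    beta: float


def cell_type_distances(coords: np.ndarray, centroids: CentroidTable
                        ) -> tuple[np.ndarray, list[str]]:
    """Euclidean distance from each cell to each target-type centroid."""
    types = sorted(centroids.centroids)
    if not types:
        raise ValueError("no target cell types")
    C = np.vstack([centroids.centroids[t] for t in types])
    return cdist(np.asarray(coords, dtype=np.float64), C), types


def normalize_to_similarity(D: np.ndarray) -> np.ndarray:
    """``S = exp(-D / mean(D))`` with the mean over all matrix entries."""
    D = np.asarray(D, dtype=np.float64)
    if D.min() < 0:
        raise ValueError("distances must be non-negative")
    mean = D.mean()
    if mean == 0.0:
        warnings.warn("all distances are zero; similarity is all-ones")
        return np.ones_like(D)
    return np.exp(-D / mean)


def clarity_alpha(S_row: np.ndarray) -> float:
    """Normalized entropy of one cell's similarity distribution.

    ``alpha = H(p) / log(K)`` with ``p = S_row / sum(S_row)`` and natural-log
    Shannon entropy; the clarity score is ``1 - alpha``.  With a single
    target type no uncertainty is possible and alpha is 0.
    """
    S_row = np.asarray(S_row, dtype=np.float64)
    if S_row.min() < 0 or S_row.sum() <= 0:
        raise ValueError("similarity row must be non-negative with positive sum")
    K = S_row.size
    if K == 1:
        return 0.0
    p = S_row / S_row.sum()
    nz = p[p > 0]
    H = float(-(nz * np.log(nz)).sum())
    return H / np.log(K)


def adjust_similarity(S: np.ndarray, alphas: np.ndarray,
                      M: PriorSimilarityMatrix | None,
                      source_labels: np.ndarray, target_types: list[str],
                      beta: float = 0.1) -> np.ndarray:
    """Blend the prior into the expression similarity, per cell.

    ``S'_iJ = beta * [(1 - a_i) S_iJ + a_i M_IJ] + (1 - beta) S_iJ`` where
    ``I`` is cell i's source label and ``J`` the target type.  ``M=None``
    (or ``beta=0``) returns ``S`` unchanged — the prior-free path.
    """
    S = np.asarray(S, dtype=np.float64)
    alphas = np.asarray(alphas, dtype=np.float64)
    if not (0.0 <= beta <= 1.0):
        raise ValueError("beta must lie in [0, 1]")
    if alphas.min() < -1e-12 or alphas.max() > 1 + 1e-12:
        raise ValueError("alpha values must lie in [0, 1]")
    if M is None or beta == 0.0:
        return S.copy()
    uniq = sorted(set(map(str, source_labels)))
    Mblock = np.array([[M.lookup(la, tb) for tb in target_types] for la in uniq])
    rows = Mblock[[uniq.index(str(l)) for l in source_labels]]
    a = alphas[:, None]
    return beta * ((1.0 - a) * S + a * rows) + (1.0 - beta) * S


def soft_assign(coords: np.ndarray, labels: np.ndarray,
                target_centroids: CentroidTable,
                M: PriorSimilarityMatrix | None, beta: float) -> SoftAssignment:
    """Full soft-assignment of one dataset's cells to another's types."""
    D, types = cell_type_distances(coords, target_centroids)
    S = normalize_to_similarity(D)
    alphas = np.array([clarity_alpha(row) for row in S])
    S_adj = adjust_similarity(S, alphas, M, labels, types, beta=beta)
    return SoftAssignment(target_types=types, D=D, S=S, S_adj=S_adj,
                          alpha=alphas, beta=beta)


@dataclass
class HarmonizationTable:
    """Cross-dataset alignment groups and revised labels."""

    table: pd.DataFrame                     # group_id, dataset, label, relationship, harmonized
    groups: list[list[tuple[int, str]]]     # (dataset index, label) nodes per group
    revised_labels: list[np.ndarray]        # per input dataset, per cell
    group_labels: dict[int, str] = field(default_factory=dict)

    def group_partition(self) -> set[frozenset]:
        """The partition of (dataset, normalized label) nodes — structure only."""
        return {frozenset((d, normalize_label(l)) for d, l in g) for g in self.groups}

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


class _UnionFind:
    def __init__(self) -> None:
        self.parent: dict = {}

    def find(self, x):
        self.parent.setdefault(x, x)
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a, b) -> None:
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[rb] = ra


def _assignment_fractions(assign: SoftAssignment, labels: np.ndarray
                          ) -> dict[str, dict[str, float]]:
    """fraction of source-type-I cells whose argmax target type is J."""
    argmax = np.asarray(assign.S_adj).argmax(axis=1)
    out: dict[str, dict[str, float]] = {}
    labels = np.asarray(labels, dtype=object)
    for lab in sorted(set(map(str, labels))):
        mask = labels == lab
        hits = argmax[mask]
        frac: dict[str, float] = {}
        for t_idx, t in enumerate(assign.target_types):
            frac[t] = float(np.mean(hits == t_idx))
        out[lab] = frac
    return out


def harmonize(datasets, M: PriorSimilarityMatrix | None = None,
              beta: float = 0.1, order: list[int] | None = None,
              majority: float = 0.5) -> HarmonizationTable:
    """Align cell types across datasets into harmonization groups.

    ``datasets`` is a list of ``(labels, coords)`` pairs (or AnnData objects
    carrying ``obs['label_given']`` and ``obsm['X_pca']``) sharing one
    embedding space.  For every dataset pair, cells of one dataset are
    soft-assigned to the other's type centroids via the prior-adjusted
    similarity; type-level assignment fractions at the ``majority``
    threshold classify each type pair as one-to-one (reciprocal majority),
    split/merge (one-directional majority) or unrelated.  Union-find over
    accepted edges yields groups; group labels join the distinct member
    names with " = ", and per-cell labels are revised to the group label.
    """
    pairs = []
    for ds in datasets:
        if hasattr(ds, "obs"):
            pairs.append((np.asarray(ds.obs["label_given"], dtype=object),
                          np.asarray(ds.obsm["X_pca"], dtype=np.float64)))
        else:
            labels, coords = ds
            pairs.append((np.asarray(labels, dtype=object),
                          np.asarray(coords, dtype=np.float64)))
    n = len(pairs)
    if n < 2:
        raise ValueError("need at least two datasets to harmonize")
    keep = [i for i in range(n) if len(pairs[i][0]) > 0]
    if len(keep) < n:
        warnings.warn("skipping empty datasets")
    if order is None:
        order = sorted(keep, key=lambda i: -len(pairs[i][0]))
    centroids = {i: CentroidTable(pairs[i][1], pairs[i][0]) for i in keep}

    uf = _UnionFind()
    nodes: list[tuple[int, str]] = []
    for i in keep:
        for lab in sorted(set(map(str, pairs[i][0]))):
            nodes.append((i, lab))
            uf.find((i, lab))

    one_way: list[tuple[tuple[int, str], tuple[int, str]]] = []
    reciprocal: set[frozenset] = set()
    for pos_a in range(len(order)):
        for pos_b in range(pos_a + 1, len(order)):
            a, b = order[pos_a], order[pos_b]
            labels_a, coords_a = pairs[a]
            labels_b, coords_b = pairs[b]
            assign_ab = soft_assign(coords_a, labels_a, centroids[b], M, beta)
            assign_ba = soft_assign(coords_b, labels_b, centroids[a], M, beta)
            frac_ab = _assignment_fractions(assign_ab, labels_a)
            frac_ba = _assignment_fractions(assign_ba, labels_b)
            for la, fa in frac_ab.items():
                for lb, f in fa.items():
                    fwd = f >= majority
                    rev = frac_ba.get(lb, {}).get(la, 0.0) >= majority
                    if fwd and rev:
                        reciprocal.add(frozenset(((a, la), (b, lb))))
                        uf.union((a, la), (b, lb))
                    elif fwd:
                        one_way.append(((a, la), (b, lb)))
                        uf.union((a, la), (b, lb))
                    elif rev:
                        one_way.append(((b, lb), (a, la)))
                        uf.union((a, la), (b, lb))

    # relationship per node
    target_in_degree: dict[tuple[int, str], int] = {}
    for _, tgt in one_way:
        target_in_degree[tgt] = target_in_degree.get(tgt, 0) + 1
    relationship: dict[tuple[int, str], str] = {}
    for node in nodes:
        relationship[node] = "novel"
    for edge in reciprocal:
        for node in edge:
            if relationship[node] == "novel":
                relationship[node] = "one_to_one"
    for src, tgt in one_way:
        relationship[tgt] = "merge" if target_in_degree[tgt] >= 2 else "split"
        if relationship[src] == "novel":
            relationship[src] = "merge" if target_in_degree[tgt] >= 2 else "split"

    # groups in deterministic first-seen order (dataset order, then label)
    group_of: dict = {}
    groups: list[list[tuple[int, str]]] = []
    for i in order:
        for lab in sorted(set(map(str, pairs[i][0]))):
            root = uf.find((i, lab))
            if root not in group_of:
                group_of[root] = len(groups)
                groups.append([])
            groups[group_of[root]].append((i, lab))

    group_labels: dict[int, str] = {}
    for gi, members in enumerate(groups):
        seen_norm: set[str] = set()
        parts: list[str] = []
        for _, lab in members:
            norm = normalize_label(lab)
            if norm not in seen_norm:
                seen_norm.add(norm)
                parts.append(lab)
        group_labels[gi] = " = ".join(parts)

    rows = []
    node_group = {}
    for gi, members in enumerate(groups):
        for node in members:
            node_group[node] = gi
            rows.append({"group_id": gi, "dataset": node[0], "label": node[1],
                         "relationship": relationship[node],
                         "harmonized_label": group_labels[gi]})
    table = pd.DataFrame(rows)

    revised = []
    for i in range(n):
        labels_i = pairs[i][0]
        revised.append(np.array([
            group_labels[node_group[(i, str(l))]] if (i, str(l)) in node_group else str(l)
            for l in labels_i], dtype=object))
    return HarmonizationTable(table=table, groups=groups,
                              revised_labels=revised, group_labels=group_labels)
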