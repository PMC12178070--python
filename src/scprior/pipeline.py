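"""The two-step integration pipeline and the label-robustness harness.

Two-step integration first harmonizes cell-type nomenclature across
datasets (uncertainty-weighted, prior-informed soft assignment), rebuilds
the label prior-similarity matrix on the harmonized names, and only then
performs the prior-weighted embedding integration.  Harmonizing first makes
the embedding step robust to aliasing and even biased mislabeling, which is
exercised here by the corruption experiment harness (fuzzy alias / unbiased
novel-token / biased existing-type replacement schemes).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import (adjusted_rand_score, normalized_mutual_info_score,
                             silhouette_score)
from sklearn.neighbors import kneighbors_graph

from . import cellhint_prior, scanorama_prior
from ._lexicon import normalize_label
from .process import cluster_graph
from .similarity import (EmbeddingProvider, PriorSimilarityMatrix, embed_labels,
                         prior_matrix_from_labels)
from .synthetic import alias_table

__all__ = [
    "TwoStepResult",
    "two_step_integrate",
    "ConsensusResult",
    "major_vote",
    "CorruptionSpec",
    "corrupt_labels",
    "corruption_experiment",
    "leiden_on_coords",
]


def leiden_on_coords(coords: np.ndarray, resolution: float = 0.7,
                     n_neighbors: int = 15, seed: int = 0) -> np.ndarray:
    """Leiden community detection on a kNN graph built from coordinates."""
    coords = np.asarray(coords, dtype=np.float64)
    n_neighbors = min(n_neighbors, len(coords) - 1)
    adj = kneighbors_graph(coords, n_neighbors=n_neighbors, mode="connectivity")
    adj = adj.maximum(adj.T)
    return cluster_graph(adj, "leiden", resolution, seed=seed)


@dataclass
class TwoStepResult:
    """All intermediates of the two-step integration."""

    harmonization: cellhint_prior.HarmonizationTable | None
    prior_initial: PriorSimilarityMatrix
    prior_rebuilt: PriorSimilarityMatrix
    embeddings: list[scanorama_prior.PanoramaEmbedding]
    corrected: scanorama_prior.PanoramaEmbedding
    harmonized_labels: list[np.ndarray]


def two_step_integrate(datasets, provider: EmbeddingProvider,
                       beta: float = 0.1, knn: int = 30,
                       sigma: float = scanorama_prior.SIGMA_DEFAULT,
                       d: int = 100, floor: float = 0.05,
                       approx: bool = False, seed: int = 0,
                       label_key: str = "label_given") -> TwoStepResult:
    """Harmonize labels, rebuild the prior on harmonized names, integrate.

    Steps: (1) build the initial prior matrix from the raw per-cell labels;
    (2) harmonize cell types across datasets with the uncertainty-weighted
    prior blend; (3) rebuild the prior matrix from the harmonized group
    labels; (4) run the prior-weighted panorama integration with the
    rebuilt prior and harmonized labels.
    """
    if len(datasets) < 2:
        warnings.warn("single dataset: harmonization and integration skipped")
        emb = scanorama_prior.reduce_dimensions(datasets, d=d, seed=seed,
                                                label_key=label_key)
        raw_labels = [np.asarray(ds.obs[label_key], dtype=object) for ds in datasets]
        M0 = prior_matrix_from_labels(
            sorted(set(np.concatenate(raw_labels).tolist())), provider, floor=floor)
        return TwoStepResult(harmonization=None, prior_initial=M0,
                             prior_rebuilt=M0, embeddings=emb,
                             corrected=emb[0], harmonized_labels=raw_labels)

    raw_labels = [np.asarray(ds.obs[label_key], dtype=object) for ds in datasets]
    all_raw = sorted(set(np.concatenate(raw_labels).tolist()))
    M0 = prior_matrix_from_labels(all_raw, provider, floor=floor)

    embeddings = scanorama_prior.reduce_dimensions(datasets, d=d, seed=seed,
                                                   label_key=label_key)
    harm = cellhint_prior.harmonize(
        [(labels, emb.coords) for labels, emb in zip(raw_labels, embeddings)],
        M=M0, beta=beta)
    harmonized = harm.revised_labels
    all_harm = sorted(set(np.concatenate(harmonized).tolist()))
    M1 = prior_matrix_from_labels(all_harm, provider, floor=floor)

    relabeled = [scanorama_prior.PanoramaEmbedding(e.coords, e.batch, labs)
                 for e, labs in zip(embeddings, harmonized)]
    corrected = scanorama_prior.integrate(relabeled, M=M1, k=knn, sigma=sigma,
                                          approx=approx, seed=seed)
    return TwoStepResult(harmonization=harm, prior_initial=M0,
                         prior_rebuilt=M1, embeddings=embeddings,
                         corrected=corrected, harmonized_labels=harmonized)


@dataclass
class ConsensusResult:
    """Fuzzy-majority-vote consensus annotation per cluster."""

    per_cluster: pd.DataFrame     # cluster, winner, vote_fraction, group members
    revised_labels: np.ndarray


def major_vote(cluster_ids, source_annotations, provider: EmbeddingProvider,
               fuzzy_threshold: float = 0.85) -> ConsensusResult:
    """Consensus labels per cluster with embedding-fuzzy vote pooling.

    Within each cluster, labels whose pairwise embedding cosine reaches
    ``fuzzy_threshold`` pool their votes (transitively); the largest pooled
    group wins and its most frequent member string becomes the cluster
    label.  Ties break by larger top-member count, then lexicographically.
    """
    clusters = np.asarray(cluster_ids)
    labels = np.asarray(source_annotations, dtype=object)
    if clusters.shape != labels.shape:
        raise ValueError("cluster ids and labels must have the same length")
    uniq_labels = sorted(set(map(str, labels)))
    merged_group: dict[str, int] = {}
    if fuzzy_threshold <= 1.0:
        embs = embed_labels(uniq_labels, provider)
        vecs = {normalize_label(e.label): e.vector for e in embs}
        parent = {l: l for l in uniq_labels}

        def find(x):
            while parent[x] != x:
                parent[x] = parent[parent[x]]
                x = parent[x]
            return x

        for i, la in enumerate(uniq_labels):
            for lb in uniq_labels[i + 1:]:
                cos = float(vecs[normalize_label(la)] @ vecs[normalize_label(lb)])
                if cos >= fuzzy_threshold:
                    parent[find(lb)] = find(la)
        roots = sorted({find(l) for l in uniq_labels})
        merged_group = {l: roots.index(find(l)) for l in uniq_labels}
    else:
        merged_group = {l: i for i, l in enumerate(uniq_labels)}

    rows = []
    revised = labels.copy()
    for cl in sorted(set(map(str, clusters))):
        mask = np.asarray([str(c) == cl for c in clusters])
        if not mask.any():
            continue
        counts = pd.Series([str(l) for l in labels[mask]]).value_counts()
        group_votes: dict[int, int] = {}
        for lab, cnt in counts.items():
            g = merged_group[lab]
            group_votes[g] = group_votes.get(g, 0) + int(cnt)
        # winner group: votes desc, then top-member count desc, then lexicographic
        def group_key(g: int):
            members = [l for l in counts.index if merged_group[l] == g]
            top = max(members, key=lambda l: (counts[l], l))
            return (-group_votes[g], -counts[top], top)

        winner_group = min(group_votes, key=group_key)
        members = [l for l in counts.index if merged_group[l] == winner_group]
        winner = sorted(members, key=lambda l: (-counts[l], l))[0]
        rows.append({"cluster": cl, "winner": winner,
                     "vote_fraction": group_votes[winner_group] / int(mask.sum()),
                     "group_members": ";".join(sorted(members))})
        revised[mask] = winner
    return ConsensusResult(per_cluster=pd.DataFrame(rows), revised_labels=revised)


@dataclass
class CorruptionSpec:
    """One label-corruption scheme applied to chosen target types.

    ``fuzzy`` replaces a type name by an alias; ``unbiased`` by a novel
    token absent from the label set (default "unknown"); ``biased`` by a
    different *existing* label.  ``replacement`` maps target type ->
    replacement string (optional for fuzzy, which falls back to the built-in
    alias table).  ``dataset_indices`` selects which datasets are corrupted
    in :func:`corruption_experiment` (``None`` corrupts all of them);
    corrupting only some datasets leaves correctly labeled cells of the
    same types elsewhere, which is what harmonization and majority voting
    can exploit.
    """

    scheme: str
    target_types: list[str]
    replacement: dict[str, str] = field(default_factory=dict)
    fraction: float = 1.0
    seed: int = 0
    dataset_indices: list[int] | None = None

    def __post_init__(self) -> None:
        if self.scheme not in ("fuzzy", "unbiased", "biased"):
            raise ValueError("scheme must be fuzzy | unbiased | biased")
        if not (0.0 <= self.fraction <= 1.0):
            raise ValueError("fraction must lie in [0, 1]")


def corrupt_labels(labels, spec: CorruptionSpec
                   ) -> tuple[np.ndarray, np.ndarray]:
    """Apply the corruption scheme; returns (corrupted labels, change mask)."""
    labels = np.asarray(labels, dtype=object)
    existing = {normalize_label(l) for l in labels}
    for t in spec.target_types:
        if normalize_label(t) not in existing:
            raise ValueError(f"target type {t!r} not present in labels")
    aliases = alias_table(spec.target_types, seed=spec.seed) \
        if spec.scheme == "fuzzy" else {}
    replacements: dict[str, str] = {}
    for t in spec.target_types:
        if spec.scheme == "fuzzy":
            replacements[t] = spec.replacement.get(t, aliases[t])
        elif spec.scheme == "unbiased":
            rep = spec.replacement.get(t, "unknown")
            if normalize_label(rep) in existing:
                raise ValueError(f"unbiased replacement {rep!r} collides with "
                                 "an existing label")
            replacements[t] = rep
        else:  # biased
            rep = spec.replacement.get(t)
            if rep is None or normalize_label(rep) not in existing \
                    or normalize_label(rep) == normalize_label(t):
                raise ValueError("biased scheme needs an existing, different "
                                 f"replacement for {t!r}")
            replacements[t] = rep
    rng = np.random.default_rng(spec.seed)
    corrupted = labels.copy()
    mask = np.zeros(len(labels), dtype=bool)
    for t, rep in replacements.items():
        idx = np.flatnonzero(np.asarray(
            [normalize_label(l) == normalize_label(t) for l in labels]))
        n_change = int(round(spec.fraction * len(idx)))
        chosen = rng.choice(idx, size=n_change, replace=False) \
            if n_change < len(idx) else idx
        corrupted[chosen] = rep
        mask[chosen] = True
    return corrupted, mask


def _integrate_variant(method: str, datasets, corrupted_labels,
                       provider, beta, knn, seed, d=100
                       ) -> scanorama_prior.PanoramaEmbedding:
    """One integration variant under (possibly corrupted) labels."""
    embeddings = scanorama_prior.reduce_dimensions(datasets, d=d, seed=seed)
    relabeled = [scanorama_prior.PanoramaEmbedding(e.coords, e.batch, labs)
                 for e, labs in zip(embeddings, corrupted_labels)]
    if method == "no_prior":
        return scanorama_prior.integrate(relabeled, M=None, k=knn, seed=seed)
    if method == "prior":
        all_labels = sorted(set(np.concatenate(corrupted_labels).tolist()))
        M = prior_matrix_from_labels(all_labels, provider)
        return scanorama_prior.integrate(relabeled, M=M, k=knn, seed=seed)
    if method == "two_step":
        adatas = []
        for ds, labs in zip(datasets, corrupted_labels):
            ds = ds.copy()
            ds.obs["label_given"] = labs
            adatas.append(ds)
        return two_step_integrate(adatas, provider, beta=beta, knn=knn,
                                  seed=seed, d=d).corrected
    raise ValueError(f"unknown integration variant {method!r}")


def _labels_close(a: str, b: str, provider, threshold: float) -> bool:
    if normalize_label(a) == normalize_label(b):
        return True
    ea, eb = embed_labels([a, b], provider)
    return float(ea.vector @ eb.vector) >= threshold


def _evaluate_embedding(pan, mask_all, true_all, corrupted_all, provider,
                        leiden_resolution, fuzzy_threshold, seed
                        ) -> tuple[dict, pd.DataFrame]:
    """Cluster the full embedding, score the masked cells, vote labels."""
    clusters = leiden_on_coords(pan.coords, resolution=leiden_resolution,
                                seed=seed)
    coords_m = pan.coords[mask_all]
    truth_m = true_all[mask_all]
    clusters_m = clusters[mask_all]
    sil = float(silhouette_score(coords_m, truth_m)) \
        if len(set(truth_m)) > 1 else float("nan")
    ari = float(adjusted_rand_score(truth_m, clusters_m))
    nmi = float(normalized_mutual_info_score(truth_m, clusters_m))
    vote = major_vote(clusters, corrupted_all, provider,
                      fuzzy_threshold=fuzzy_threshold)
    voted_m = vote.revised_labels[mask_all]
    close_cache: dict[tuple[str, str], bool] = {}

    def close(a, b):
        key = (normalize_label(a), normalize_label(b))
        if key not in close_cache:
            close_cache[key] = _labels_close(a, b, provider, fuzzy_threshold)
        return close_cache[key]

    recovery = float(np.mean([close(v, t) for v, t in zip(voted_m, truth_m)]))
    confusion = pd.crosstab(pd.Series(voted_m, name="voted"),
                            pd.Series(truth_m, name="true"))
    return {"silhouette": sil, "ari": ari, "nmi": nmi,
            "vote_recovery": recovery}, confusion


def corruption_experiment(datasets, spec: CorruptionSpec,
                          provider: EmbeddingProvider,
                          methods=("two_step", "prior", "no_prior"),
                          beta: float = 0.1, knn: int = 30, seed: int = 0,
                          leiden_resolution: float = 0.7,
                          fuzzy_threshold: float = 0.85,
                          with_clean_baseline: bool = False
                          ) -> tuple[pd.DataFrame, dict[str, pd.DataFrame]]:
    """Integrate under corrupted labels and evaluate on the changed cells.

    Per integration variant: corrupt each dataset's given labels, integrate,
    Leiden-cluster the full corrected embedding at the stated resolution,
    then score the masked (changed) cells: silhouette of the true types,
    ARI / NMI of the clustering against the true types, and a majority-vote
    recovery rate (fraction of masked cells whose cluster-voted label
    matches their true type, alias-tolerantly) with the voted-vs-true
    confusion matrix.  With ``with_clean_baseline`` each variant is also run
    on the uncorrupted labels and scored on the same masked cells
    (``clean_*`` columns).  A failing variant is recorded as a failed row
    and the experiment continues.
    """
    true_labels = [np.asarray(ds.obs["label_true"], dtype=object) for ds in datasets]
    given = [np.asarray(ds.obs["label_given"], dtype=object) for ds in datasets]
    corrupted, masks = [], []
    for i, labs in enumerate(given):
        # corruption targets only the types present in the affected datasets
        present = {normalize_label(l) for l in labs}
        targets = [t for t in spec.target_types if normalize_label(t) in present]
        if spec.dataset_indices is not None and i not in spec.dataset_indices:
            targets = []
        if targets:
            spec_i = CorruptionSpec(scheme=spec.scheme, target_types=targets,
                                    replacement=spec.replacement,
                                    fraction=spec.fraction, seed=spec.seed + i)
            c, m = corrupt_labels(labs, spec_i)
        else:
            c, m = labs.copy(), np.zeros(len(labs), dtype=bool)
        corrupted.append(c)
        masks.append(m)
    mask_all = np.concatenate(masks)
    true_all = np.concatenate(true_labels)
    corrupted_all = np.concatenate(corrupted)
    given_all = np.concatenate(given)
    if not mask_all.any():  # zero-fraction control: evaluate on all cells
        mask_all = np.ones(len(true_all), dtype=bool)

    rows, confusions = [], {}
    for method in methods:
        row = {"method": method, "scheme": spec.scheme,
               "n_masked": int(mask_all.sum()), "failed": False}
        try:
            pan = _integrate_variant(method, datasets, corrupted, provider,
                                     beta, knn, seed)
            scores, confusion = _evaluate_embedding(
                pan, mask_all, true_all, corrupted_all, provider,
                leiden_resolution, fuzzy_threshold, seed)
            row.update(scores)
            confusions[method] = confusion
            if with_clean_baseline:
                pan_clean = _integrate_variant(method, datasets, given,
                                               provider, beta, knn, seed)
                clean_scores, _ = _evaluate_embedding(
                    pan_clean, mask_all, true_all, given_all, provider,
                    leiden_resolution, fuzzy_threshold, seed)
                row.update({f"clean_{k}": v for k, v in clean_scores.items()})
        except Exception as exc:  # noqa: BLE001
            warnings.warn(f"integration variant {method!r} failed: {exc}")
            row.update({"silhouette": float("nan"), "ari": float("nan"),
                        "nmi": float("nan"), "vote_recovery": float("nan"),
                        "failed": True})
        rows.append(row)
    return pd.DataFrame(rows), confusions
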