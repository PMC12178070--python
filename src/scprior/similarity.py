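"""Cell-type label similarity resources.

This module builds the prior-similarity matrix ``M`` that drives the
prior-informed integration and harmonization steps, and provides the two
annotation-accuracy metrics used for benchmarking: cosine similarity of
label text embeddings and Jaccard similarity of cell-ontology ancestor sets.

Embeddings come from a pluggable provider contract.  The bundled
:class:`HashingEmbeddingProvider` is fully offline and deterministic: it
hashes character n-grams of the (lowercased) label into a fixed-dimension
vector and L2-normalizes.  Labels that are known synonyms of each other
(see :mod:`scprior._lexicon`) are additionally blended toward a shared
canonical vector so that, like a semantic text-embedding model, alternative
nomenclature for the same cell type scores high cosine similarity.
"""

from __future__ import annotations

import hashlib
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Mapping, Protocol, Sequence

import numpy as np
import pandas as pd

from ._lexicon import CANONICAL, canonical_form, normalize_label

logger = logging.getLogger(__name__)

__all__ = [
    "LabelEmbedding",
    "EmbeddingProvider",
    "HashingEmbeddingProvider",
    "EmbeddingProviderError",
    "embed_labels",
    "build_prior_matrix",
    "prior_matrix_from_labels",
    "PriorSimilarityMatrix",
    "OntologyGraph",
    "ontology_jaccard",
    "annotation_accuracy",
]


class EmbeddingProviderError(RuntimeError):
    """Raised when an embedding provider fails; carries the offending label."""

    def __init__(self, label: str, message: str = "") -> None:
        self.label = label
        super().__init__(message or f"embedding provider failed on label {label!r}")


@dataclass(frozen=True)
class LabelEmbedding:
    """A unit-norm text embedding of one cell-type label."""

    label: str
    vector: np.ndarray
    provider_id: str

    def __post_init__(self) -> None:
        norm = float(np.linalg.norm(self.vector))
        if not np.isfinite(norm) or abs(norm - 1.0) > 1e-6:
            raise ValueError(f"embedding for {self.label!r} is not unit-norm (|v|={norm})")


class EmbeddingProvider(Protocol):
    """Contract for text-embedding backends.

    ``embed`` maps a batch of strings to a (n, dim) array of unit-norm rows;
    the mapping must be deterministic per provider so results are cacheable.
    """

    provider_id: str

    def embed(self, texts: Sequence[str]) -> np.ndarray:  # pragma: no cover - protocol
        ...


class HashingEmbeddingProvider:
    """Offline character n-gram hashing embedder.

    Each n-gram (n in ``ngram_range``) of the lowercased, whitespace-padded
    label is hashed with BLAKE2b into a bucket of a ``dim``-dimensional
    vector with a hash-derived sign, and the result is L2-normalized.  The
    hash is keyed only by the n-gram bytes, so vectors are bitwise
    reproducible across processes.

    Known synonym pairs (e.g. "T cell" / "T lymphocyte") would be nearly
    orthogonal under pure n-gram hashing; to emulate the semantic closeness a
    trained text-embedding model assigns them, aliases are blended 2:1 toward
    their canonical form's n-gram vector, giving cosine ~0.9 within a synonym
    group while distinct types stay dissimilar.
    """

    def __init__(self, dim: int = 256, ngram_range: tuple[int, int] = (2, 4),
                 blend_synonyms: bool = True) -> None:
        if dim < 8:
            raise ValueError("dim must be >= 8")
        self.dim = int(dim)
        self.ngram_range = ngram_range
        self.blend_synonyms = bool(blend_synonyms)
        self.provider_id = f"ngram-hash-d{self.dim}-n{ngram_range[0]}-{ngram_range[1]}"

    def _raw_vector(self, text: str) -> np.ndarray:
        padded = f" {normalize_label(text)} "
        vec = np.zeros(self.dim, dtype=np.float64)
        lo, hi = self.ngram_range
        for n in range(lo, hi + 1):
            for i in range(len(padded) - n + 1):
                gram = padded[i:i + n].encode("utf-8")
                digest = hashlib.blake2b(gram, digest_size=8).digest()
                bucket = int.from_bytes(digest[:4], "little") % self.dim
                sign = 1.0 if digest[4] & 1 else -1.0
                vec[bucket] += sign
        norm = np.linalg.norm(vec)
        if norm == 0.0:
            raise EmbeddingProviderError(text, f"label {text!r} produced an empty n-gram set")
        return vec / norm

    def embed_one(self, text: str) -> np.ndarray:
        norm = normalize_label(text)
        vec = self._raw_vector(norm)
        if self.blend_synonyms:
            canon = canonical_form(norm)
            if canon != norm:
                vec = 2.0 * self._raw_vector(canon) + vec
                vec = vec / np.linalg.norm(vec)
        return vec

    def embed(self, texts: Sequence[str]) -> np.ndarray:
        return np.vstack([self.embed_one(t) for t in texts])


def embed_labels(labels: Sequence[str], provider: EmbeddingProvider) -> list[LabelEmbedding]:
    """Embed distinct normalized labels through ``provider``.

    Labels that normalize (trim / collapse whitespace / lowercase) to the
    same key share one embedding.  Original casing of the first occurrence
    is preserved for display.
    """
    if len(labels) == 0:
        raise ValueError("labels must be non-empty")
    seen: dict[str, str] = {}
    for lab in labels:
        norm = normalize_label(lab)
        if not norm:
            raise ValueError(f"empty label after normalization: {lab!r}")
        seen.setdefault(norm, str(lab).strip())
    keys = list(seen)
    try:
        vectors = np.asarray(provider.embed(keys), dtype=np.float64)
    except EmbeddingProviderError:
        raise
    except Exception:
        # retry one-by-one to identify the offending label
        for key in keys:
            try:
                provider.embed([key])
            except Exception as exc:  # noqa: BLE001
                raise EmbeddingProviderError(key, str(exc)) from exc
        raise
    out = []
    for key, vec in zip(keys, vectors):
        out.append(LabelEmbedding(label=seen[key], vector=vec, provider_id=provider.provider_id))
    return out


@dataclass
class PriorSimilarityMatrix:
    """Symmetric label-by-label similarity matrix M with unit diagonal.

    Entries live in ``[floor, 1]``; the floor keeps the ``d / M`` weighting
    used during integration away from division blow-ups for unrelated types.
    """

    labels: list[str]
    values: np.ndarray
    floor: float = 0.05
    _index: dict[str, int] = field(init=False, repr=False)
    _warned: set = field(init=False, repr=False, default_factory=set)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise ValueError("values must be square and match labels")
        if not (0.0 < self.floor < 1.0):
            raise ValueError("floor must lie in (0, 1)")
        if not np.allclose(self.values, self.values.T, atol=1e-12):
            raise ValueError("similarity matrix must be symmetric")
        if not np.allclose(np.diag(self.values), 1.0):
            raise ValueError("diagonal must be exactly 1")
        if self.values.min() < self.floor - 1e-12 or self.values.max() > 1.0 + 1e-12:
            raise ValueError("entries must lie in [floor, 1]")
        self._index = {normalize_label(l): i for i, l in enumerate(self.labels)}

    def index_of(self, label: str) -> int | None:
        return self._index.get(normalize_label(label))

    def lookup(self, label_a: str, label_b: str) -> float:
        """Similarity of two labels; unknown labels fall back to the floor."""
        ia = self.index_of(label_a)
        ib = self.index_of(label_b)
        if ia is None or ib is None:
            missing = label_a if ia is None else label_b
            key = normalize_label(missing)
            if key not in self._warned:
                self._warned.add(key)
                logger.warning("label %r absent from prior matrix; using floor %.3g",
                               missing, self.floor)
            return self.floor
        return float(self.values[ia, ib])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t")

    @classmethod
    def from_tsv(cls, path: str | Path, floor: float = 0.05) -> "PriorSimilarityMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(labels=list(df.index), values=df.to_numpy(), floor=floor)


def build_prior_matrix(
    embeddings: Sequence[LabelEmbedding],
    floor: float = 0.05,
    descriptions: Mapping[str, str] | None = None,
    provider: EmbeddingProvider | None = None,
) -> PriorSimilarityMatrix:
    """Build M from label embeddings: ``M[i, j] = max(floor, cos(e_i, e_j))``.

    When ``descriptions`` is given (label -> free text), embeddings are
    recomputed on ``"label: description"`` strings through ``provider``;
    the matrix stays keyed by the bare labels.
    """
    if len(embeddings) == 0:
        raise ValueError("need at least one label embedding")
    if not (0.0 < floor < 1.0):
        raise ValueError("floor must lie in (0, 1)")
    labels: list[str] = []
    vectors: list[np.ndarray] = []
    seen: set[str] = set()
    for emb in embeddings:
        key = normalize_label(emb.label)
        if key in seen:
            warnings.warn(f"duplicate label {emb.label!r} after normalization; collapsing",
                          stacklevel=2)
            continue
        seen.add(key)
        labels.append(emb.label)
        vectors.append(np.asarray(emb.vector, dtype=np.float64))
    if descriptions is not None:
        if provider is None:
            raise ValueError("descriptions require a provider to re-embed")
        texts = []
        for lab in labels:
            desc = descriptions.get(lab) or descriptions.get(normalize_label(lab))
            texts.append(f"{lab}: {desc}" if desc else lab)
        vectors = list(np.asarray(provider.embed(texts), dtype=np.float64))
    V = np.vstack(vectors)
    V = V / np.linalg.norm(V, axis=1, keepdims=True)
    cos = V @ V.T
    M = np.clip(cos, floor, 1.0)
    np.fill_diagonal(M, 1.0)
    M = (M + M.T) / 2.0
    return PriorSimilarityMatrix(labels=labels, values=M, floor=floor)


def prior_matrix_from_labels(
    labels: Sequence[str],
    provider: EmbeddingProvider,
    floor: float = 0.05,
    descriptions: Mapping[str, str] | None = None,
) -> PriorSimilarityMatrix:
    """Convenience: embed labels then build the prior matrix."""
    return build_prior_matrix(embed_labels(labels, provider), floor=floor,
                              descriptions=descriptions, provider=provider)


# ---------------------------------------------------------------------------
# Ontology


class OntologyGraph:
    """A DAG of ontology terms with directed child -> parent (is_a) edges.

    Ancestor sets are reflexive-transitive: a term is its own ancestor.
    """

    def __init__(self, parents: Mapping[str, Iterable[str]],
                 names: Mapping[str, str] | None = None) -> None:
        self.parents: dict[str, tuple[str, ...]] = {}
        nodes = set(parents)
        for child, ps in parents.items():
            ps = tuple(ps)
            nodes.update(ps)
            self.parents[child] = ps
        for node in nodes:
            self.parents.setdefault(node, ())
        self.names = {n: (names or {}).get(n, n) for n in self.parents}
        self._ancestors: dict[str, frozenset[str]] = {}
        self._check_acyclic()

    def _check_acyclic(self) -> None:
        import networkx as nx

        g = nx.DiGraph()
        g.add_nodes_from(self.parents)
        for child, ps in self.parents.items():
            for p in ps:
                g.add_edge(child, p)
        if not nx.is_directed_acyclic_graph(g):
            raise ValueError("ontology graph contains a cycle")

    @property
    def nodes(self) -> list[str]:
        return list(self.parents)

    @property
    def roots(self) -> list[str]:
        return [n for n, ps in self.parents.items() if not ps]

    def __contains__(self, term: str) -> bool:
        return term in self.parents

    def ancestors(self, term: str) -> frozenset[str]:
        """All transitive parents of ``term``, including ``term`` itself."""
        if term not in self.parents:
            raise KeyError(f"unknown ontology term: {term!r}")
        cached = self._ancestors.get(term)
        if cached is not None:
            return cached
        acc = {term}
        stack = list(self.parents[term])
        while stack:
            node = stack.pop()
            if node not in acc:
                acc.add(node)
                stack.extend(self.parents[node])
        out = frozenset(acc)
        self._ancestors[term] = out
        return out

    @classmethod
    def from_edges(cls, edges: Iterable[tuple[str, str]],
                   names: Mapping[str, str] | None = None) -> "OntologyGraph":
        parents: dict[str, list[str]] = {}
        for child, parent in edges:
            parents.setdefault(child, []).append(parent)
            parents.setdefault(parent, [])
        return cls(parents, names)

    @classmethod
    def from_obo(cls, path: str | Path) -> "OntologyGraph":
        """Read an OBO flat file (id / name / is_a stanza lines)."""
        import obonet

        g = obonet.read_obo(str(path))
        parents: dict[str, list[str]] = {n: [] for n in g.nodes}
        for child, parent, key in g.edges(keys=True):
            if key == "is_a":
                parents[child].append(parent)
        names = {n: data.get("name", n) for n, data in g.nodes(data=True)}
        return cls(parents, names)

    def name_index(self) -> dict[str, str]:
        """Normalized term name -> term id (first wins on collisions)."""
        idx: dict[str, str] = {}
        for term, name in self.names.items():
            idx.setdefault(normalize_label(name), term)
        return idx


def ontology_jaccard(term_a: str, term_b: str, graph: OntologyGraph) -> float:
    """Jaccard similarity of the reflexive ancestor sets of two terms."""
    anc_a = graph.ancestors(term_a)
    anc_b = graph.ancestors(term_b)
    union = anc_a | anc_b
    if not union:
        return 0.0
    return len(anc_a & anc_b) / len(union)


def load_synonym_table(path: str | Path) -> dict[str, str]:
    """Read a two-column delimited label-pair table (alias -> canonical).

    Lines are ``alias<TAB>canonical`` (comma also accepted); keys are
    normalized.  Useful to extend the built-in synonym map with
    project-specific nomenclature.
    """
    table: dict[str, str] = {}
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t") if "\t" in line else line.split(",")
        if len(parts) < 2:
            continue
        table[normalize_label(parts[0])] = parts[1].strip()
    return table


def default_term_resolver(graph: OntologyGraph,
                          synonyms: Mapping[str, str] | None = None
                          ) -> Callable[[str], str | None]:
    """Exact-name then synonym-table lookup of label strings to term ids."""
    idx = graph.name_index()
    extra = {normalize_label(k): v for k, v in (synonyms or {}).items()}

    def resolve(label: str) -> str | None:
        norm = normalize_label(label)
        if norm in idx:
            return idx[norm]
        canon = extra.get(norm) or CANONICAL.get(norm)
        if canon is not None:
            return idx.get(normalize_label(canon))
        return None

    return resolve


# ---------------------------------------------------------------------------
# Annotation accuracy


def _per_cell_embedding_scores(predicted: np.ndarray, reference: np.ndarray,
                               provider: EmbeddingProvider) -> np.ndarray:
    uniq = sorted(set(map(normalize_label, predicted)) | set(map(normalize_label, reference)))
    embs = {normalize_label(e.label): e.vector for e in embed_labels(uniq, provider)}
    pred_v = np.vstack([embs[normalize_label(l)] for l in predicted])
    ref_v = np.vstack([embs[normalize_label(l)] for l in reference])
    cos = np.einsum("ij,ij->i", pred_v, ref_v)
    clipped = np.clip(cos, 0.0, 1.0)
    n_clip = int(np.sum(cos != clipped))
    if n_clip:
        logger.info("clipped %d/%d embedding cosines into [0, 1]", n_clip, len(cos))
    return clipped


def _per_cell_ontology_scores(predicted: np.ndarray, reference: np.ndarray,
                              graph: OntologyGraph,
                              term_map: Mapping[str, str] | Callable[[str], str | None] | None,
                              fallback: float) -> np.ndarray:
    if term_map is None:
        resolver: Callable[[str], str | None] = default_term_resolver(graph)
    elif callable(term_map):
        resolver = term_map
    else:
        mapping = {normalize_label(k): v for k, v in term_map.items()}
        resolver = lambda lab: mapping.get(normalize_label(lab))  # noqa: E731
    cache: dict[tuple[str, str], float] = {}
    scores = np.empty(len(predicted), dtype=np.float64)
    for i, (p, r) in enumerate(zip(predicted, reference)):
        key = (normalize_label(p), normalize_label(r))
        if key not in cache:
            tp, tr = resolver(p), resolver(r)
            if tp is None or tr is None or tp not in graph or tr not in graph:
                unmapped = p if tp is None else r
                logger.warning("label %r not mapped to an ontology term; scoring %.3g",
                               unmapped, fallback)
                cache[key] = float(fallback)
            else:
                cache[key] = ontology_jaccard(tp, tr, graph)
        scores[i] = cache[key]
    return scores


def annotation_accuracy(
    predicted: Sequence[str],
    reference: Sequence[str],
    mode: str = "embedding",
    level: str = "cell",
    provider: EmbeddingProvider | None = None,
    graph: OntologyGraph | None = None,
    term_map: Mapping[str, str] | Callable[[str], str | None] | None = None,
    fallback: float = 0.0,
) -> float:
    """Mean per-cell similarity between predicted and reference labels.

    ``level="cell"`` averages over cells; ``level="cluster"`` averages the
    per-reference-cluster means, weighting every reference type equally so
    rare populations count as much as abundant ones.
    """
    predicted = np.asarray(predicted, dtype=object)
    reference = np.asarray(reference, dtype=object)
    if predicted.shape != reference.shape:
        raise ValueError("predicted and reference must have the same length")
    if len(predicted) == 0:
        raise ValueError("empty label vectors")
    if mode == "embedding":
        if provider is None:
            raise ValueError("embedding mode requires a provider")
        scores = _per_cell_embedding_scores(predicted, reference, provider)
    elif mode == "ontology":
        if graph is None:
            raise ValueError("ontology mode requires an OntologyGraph")
        scores = _per_cell_ontology_scores(predicted, reference, graph, term_map, fallback)
    else:
        raise ValueError(f"unknown mode: {mode!r}")
    if level == "cell":
        return float(np.mean(scores))
    if level == "cluster":
        ref_norm = np.asarray([normalize_label(r) for r in reference])
        return float(np.mean([scores[ref_norm == g].mean() for g in np.unique(ref_norm)]))
    raise ValueError(f"unknown level: {level!r}")
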