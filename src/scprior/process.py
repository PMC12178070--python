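"""Per-dataset processing: QC filtering, preprocessing, clustering to a
target group number, marker ranking, and two-round cluster annotation.

All analysis decisions that would normally come from reading the source
article (thresholds, cluster count, cluster identities) are injected through
the :class:`AnnotatorContract`; the bundled :class:`MockAnnotator` is a pure
function of its inputs, so the whole pipeline runs deterministically
offline.  Every decision is appended to a structured processing log.
"""

from __future__ import annotations

import json
import random
import warnings
from dataclasses import dataclass, field, asdict, replace
from pathlib import Path
from typing import Mapping, Protocol, Sequence

import anndata as ad
import numpy as np
import pandas as pd
import scanpy as sc

__all__ = [
    "ProcessingConfig",
    "ProcessingLog",
    "AnnotationRecord",
    "AnnotatorContract",
    "MockAnnotator",
    "apply_qc_filters",
    "preprocess",
    "cluster_to_target",
    "rank_markers",
    "annotate",
    "summarize_expression",
    "reannotate",
    "process_dataset",
]

CONFIDENCE_LEVELS = ("low", "medium", "high")


@dataclass
class ProcessingConfig:
    """Per-dataset analysis parameters.

    Optional thresholds stay ``None`` unless explicitly decided, in which
    case the corresponding filter is simply not applied.
    """

    min_genes_per_cell: int = 300
    max_genes_per_cell: int | None = None
    min_cells_per_gene: int = 3
    max_mito_frac: float | None = None
    max_ribo_frac: float | None = None
    n_hvg: int = 2000
    n_neighbors: int = 15
    n_pcs: int = 50
    batch_correct: bool = False
    cluster_method: str = "leiden"
    target_k: int | None = None
    normalize_target: float = 1e4

    def __post_init__(self) -> None:
        for name in ("min_genes_per_cell", "min_cells_per_gene", "n_hvg",
                     "n_neighbors", "n_pcs"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.cluster_method not in ("leiden", "louvain"):
            raise ValueError("cluster_method must be 'leiden' or 'louvain'")


class ProcessingLog:
    """Ordered record of every parameter choice and annotation decision."""

    def __init__(self) -> None:
        self.entries: list[dict] = []

    def add(self, step: str, message: str, params: Mapping | None = None) -> None:
        self.entries.append({"step": step, "message": message,
                             "params": dict(params or {})})

    def render(self) -> str:
        lines = []
        for e in self.entries:
            lines.append(f"[{e['step']}] {e['message']}")
            if e["params"]:
                lines.append("    " + json.dumps(e["params"], sort_keys=True, default=str))
        return "\n".join(lines) + "\n"

    def write(self, path: str | Path) -> None:
        Path(path).write_text(self.render())

    def __contains__(self, text: str) -> bool:
        return text in self.render()


@dataclass
class AnnotationRecord:
    cluster_id: str
    cell_type: str
    confidence: str = "low"
    tissue: str = ""
    disease: str = ""
    stage: str = ""
    rationale: str = ""

    def __post_init__(self) -> None:
        if self.confidence not in CONFIDENCE_LEVELS:
            raise ValueError(f"confidence must be one of {CONFIDENCE_LEVELS}")


class AnnotatorContract(Protocol):
    """Decision provider abstracting the article-reading agent."""

    def decide_config(self, context: str) -> ProcessingConfig: ...

    def annotate(self, markers: Mapping[str, pd.DataFrame],
                 context: str) -> list[AnnotationRecord]: ...

    def select_query_genes(self, records: Sequence[AnnotationRecord],
                           context: str) -> list[str]: ...

    def reannotate(self, records: Sequence[AnnotationRecord],
                   expression_summary: Mapping[str, Mapping[str, str]]
                   ) -> list[AnnotationRecord]: ...


class MockAnnotator:
    """Deterministic annotator driven by a marker -> cell-type dictionary.

    * ``decide_config`` parses ``key=value`` lines from the context string.
    * ``annotate`` assigns each cluster the type whose dictionary markers
      are best represented in the cluster's top genes, with confidence set
      by the fraction of that type's markers hit.
    * ``reannotate`` applies optional refinement rules of the form
      ``type -> (gene, label_if_expressed, label_if_absent)``.
    """

    def __init__(self, marker_dict: Mapping[str, Sequence[str]],
                 refine_rules: Mapping[str, tuple[str, str, str]] | None = None,
                 config_overrides: Mapping | None = None) -> None:
        self.marker_dict = {t: list(genes) for t, genes in marker_dict.items()}
        self.refine_rules = dict(refine_rules or {})
        self.config_overrides = dict(config_overrides or {})

    @classmethod
    def from_tsv(cls, path: str | Path, **kwargs) -> "MockAnnotator":
        df = pd.read_csv(path, sep="\t", header=None, names=["gene", "cell_type"])
        marker_dict: dict[str, list[str]] = {}
        for _, row in df.iterrows():
            marker_dict.setdefault(row["cell_type"], []).append(row["gene"])
        return cls(marker_dict, **kwargs)

    def decide_config(self, context: str) -> ProcessingConfig:
        cfg = ProcessingConfig(**self.config_overrides)
        fields = ProcessingConfig.__dataclass_fields__
        for line in str(context).splitlines():
            line = line.strip()
            if "=" not in line or line.startswith("#"):
                continue
            key, val = (s.strip() for s in line.split("=", 1))
            if key not in fields:
                continue
            typ = fields[key].type
            parsed: object
            if val.lower() in ("none", "null"):
                parsed = None
            elif val.lower() in ("true", "false"):
                parsed = val.lower() == "true"
            elif "int" in str(typ):
                parsed = int(float(val))
            elif "float" in str(typ):
                parsed = float(val)
            else:
                parsed = val
            cfg = replace(cfg, **{key: parsed})
        return cfg

    def annotate(self, markers: Mapping[str, pd.DataFrame],
                 context: str = "") -> list[AnnotationRecord]:
        records = []
        for cluster_id in sorted(markers, key=str):
            top = set(markers[cluster_id]["gene"])
            best_type, best_frac, best_hits = None, 0.0, []
            for cell_type in sorted(self.marker_dict):
                genes = self.marker_dict[cell_type]
                hits = [g for g in genes if g in top]
                frac = len(hits) / len(genes) if genes else 0.0
                if frac > best_frac:
                    best_type, best_frac, best_hits = cell_type, frac, hits
            if best_type is None or best_frac == 0.0:
                records.append(AnnotationRecord(
                    cluster_id=str(cluster_id), cell_type="Unknown",
                    confidence="low", rationale="no dictionary markers matched"))
                continue
            confidence = "high" if best_frac >= 0.75 else \
                "medium" if best_frac >= 0.5 else "low"
            records.append(AnnotationRecord(
                cluster_id=str(cluster_id), cell_type=best_type,
                confidence=confidence,
                rationale=f"markers hit: {', '.join(best_hits)} "
                          f"({best_frac:.0%} of dictionary)"))
        return records

    def select_query_genes(self, records: Sequence[AnnotationRecord],
                           context: str = "") -> list[str]:
        genes: set[str] = set()
        present = {r.cell_type for r in records}
        for cell_type, (gene, _, _) in self.refine_rules.items():
            if cell_type in present:
                genes.add(gene)
        for r in records:
            if r.confidence == "low" and r.cell_type in self.marker_dict:
                genes.update(self.marker_dict[r.cell_type])
        return sorted(genes)

    def reannotate(self, records: Sequence[AnnotationRecord],
                   expression_summary: Mapping[str, Mapping[str, str]]
                   ) -> list[AnnotationRecord]:
        out = []
        for r in records:
            rule = self.refine_rules.get(r.cell_type)
            if rule is None:
                out.append(r)
                continue
            gene, hi_label, lo_label = rule
            level = expression_summary.get(r.cluster_id, {}).get(gene, "not detected")
            new_type = hi_label if level in ("medium", "high") else lo_label
            out.append(replace(r, cell_type=new_type,
                               rationale=r.rationale +
                               f"; refined on {gene} ({level})"))
        return out


# ---------------------------------------------------------------------------


def _counts_matrix(adata: ad.AnnData) -> np.ndarray:
    mat = adata.layers.get("counts", adata.X)
    return np.asarray(mat.todense()) if hasattr(mat, "todense") else np.asarray(mat)


def apply_qc_filters(adata: ad.AnnData, cfg: ProcessingConfig,
                     log: ProcessingLog | None = None
                     ) -> tuple[ad.AnnData, dict[str, int]]:
    """Remove low-quality cells and rarely detected genes.

    Cells are dropped by minimum/maximum genes detected and, only when the
    corresponding threshold is set, by mitochondrial / ribosomal fraction.
    Genes detected in fewer than ``min_cells_per_gene`` surviving cells are
    dropped.  Returns the filtered view (copied) plus a per-rule report.
    """
    counts = _counts_matrix(adata)
    detected = (counts > 0).sum(axis=1)
    total = counts.sum(axis=1)
    mito_mask = np.array([g.upper().startswith("MT-") for g in adata.var_names])
    ribo_mask = np.array([g.upper().startswith(("RPS", "RPL")) for g in adata.var_names])
    with np.errstate(invalid="ignore", divide="ignore"):
        mito_frac = np.where(total > 0, counts[:, mito_mask].sum(axis=1) / total, 0.0)
        ribo_frac = np.where(total > 0, counts[:, ribo_mask].sum(axis=1) / total, 0.0)

    keep = np.ones(adata.n_obs, dtype=bool)
    report: dict[str, int] = {}

    def apply_rule(name: str, fail: np.ndarray) -> None:
        newly = fail & keep
        report[name] = int(newly.sum())
        keep[newly] = False

    apply_rule("min_genes_per_cell", detected < cfg.min_genes_per_cell)
    if cfg.max_genes_per_cell is not None:
        apply_rule("max_genes_per_cell", detected > cfg.max_genes_per_cell)
    if cfg.max_mito_frac is not None:
        apply_rule("max_mito_frac", mito_frac > cfg.max_mito_frac)
    if cfg.max_ribo_frac is not None:
        apply_rule("max_ribo_frac", ribo_frac > cfg.max_ribo_frac)
    if not keep.any():
        raise ValueError("all cells removed by QC filters; review thresholds")

    out = adata[keep].copy()
    gene_cells = (_counts_matrix(out) > 0).sum(axis=0)
    gene_keep = gene_cells >= cfg.min_cells_per_gene
    report["min_cells_per_gene"] = int((~gene_keep).sum())
    out = out[:, gene_keep].copy()
    if log is not None:
        log.add("qc_filter", "applied QC filters",
                {"removed": report,
                 "thresholds": {k: v for k, v in asdict(cfg).items()
                                if k.startswith(("min_", "max_"))}})
    return out, report


def preprocess(adata: ad.AnnData, cfg: ProcessingConfig,
               log: ProcessingLog | None = None,
               batch_correct_hook=None) -> ad.AnnData:
    """Normalize, select HVGs, compute PCA and the kNN graph in place.

    Total-count normalization to ``cfg.normalize_target`` followed by log1p
    (kept in ``layers['lognorm']`` and ``X``); dispersion-based HVG
    selection; PCA on scaled HVGs; symmetric kNN graph.  When
    ``cfg.batch_correct`` is set, an external hook (e.g. an harmony wrapper)
    may adjust ``obsm['X_pca']``; no internal correction is performed here.
    """
    n_hvg = min(cfg.n_hvg, adata.n_vars)
    if cfg.n_pcs >= min(adata.n_obs, n_hvg):
        raise ValueError(f"n_pcs={cfg.n_pcs} must be < min(cells, HVGs)="
                         f"{min(adata.n_obs, n_hvg)}")
    if "counts" not in adata.layers:
        adata.layers["counts"] = adata.X.copy()
    adata.X = adata.layers["counts"].copy()
    sc.pp.normalize_total(adata, target_sum=cfg.normalize_target)
    adata.layers["norm"] = adata.X.copy()
    sc.pp.log1p(adata)
    adata.layers["lognorm"] = adata.X.copy()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        sc.pp.highly_variable_genes(adata, n_top_genes=n_hvg, flavor="seurat")
    scaled = adata[:, adata.var["highly_variable"]].copy()
    sc.pp.scale(scaled, max_value=10)
    sc.tl.pca(scaled, n_comps=cfg.n_pcs, svd_solver="arpack")
    adata.obsm["X_pca"] = scaled.obsm["X_pca"]
    if cfg.batch_correct:
        if batch_correct_hook is not None:
            adata.obsm["X_pca"] = np.asarray(
                batch_correct_hook(adata.obsm["X_pca"], adata.obs))
        else:
            warnings.warn("batch_correct requested but no hook supplied; skipping")
    sc.pp.neighbors(adata, n_neighbors=cfg.n_neighbors, n_pcs=cfg.n_pcs,
                    use_rep="X_pca", random_state=0)
    if log is not None:
        log.add("preprocess", "normalized, selected HVGs, computed PCA and kNN graph",
                {"normalize_target": cfg.normalize_target, "n_hvg": n_hvg,
                 "n_pcs": cfg.n_pcs, "n_neighbors": cfg.n_neighbors,
                 "batch_correct": cfg.batch_correct})
    return adata


def cluster_graph(adjacency, method: str, resolution: float, seed: int = 0
                  ) -> np.ndarray:
    """Community detection on a (sparse) symmetric adjacency matrix."""
    import igraph
    import leidenalg
    from scipy import sparse

    adj = sparse.csr_matrix(adjacency)
    sources, targets = adj.nonzero()
    upper = sources < targets
    g = igraph.Graph(n=adj.shape[0],
                     edges=list(zip(sources[upper].tolist(), targets[upper].tolist())),
                     edge_attrs={"weight": np.asarray(adj[sources[upper],
                                                          targets[upper]]).ravel().tolist()})
    if method == "leiden":
        part = leidenalg.find_partition(
            g, leidenalg.RBConfigurationVertexPartition,
            weights="weight", resolution_parameter=resolution, seed=seed,
            n_iterations=2)
        membership = part.membership
    elif method == "louvain":
        random.seed(seed)  # python-igraph delegates its RNG to the random module
        part = g.community_multilevel(weights="weight", resolution=resolution)
        membership = part.membership
    else:
        raise ValueError(f"unknown clustering method {method!r}")
    return np.asarray(membership, dtype=np.int64)


def cluster_to_target(adata: ad.AnnData, method: str = "leiden",
                      target_k: int | None = None,
                      resolution_bounds: tuple[float, float] = (0.1, 3.0),
                      max_iter: int = 20, seed: int = 0,
                      log: ProcessingLog | None = None,
                      key_added: str = "cluster") -> dict:
    """Find a resolution whose cluster count matches ``target_k`` by bisection.

    Returns a dict with the labels, achieved resolution and count, and a
    warning flag when the target was unreachable within the bounds (the
    nearest count wins; on ties the lower resolution is preferred).
    """
    adj = adata.obsp["connectivities"]

    def run(res: float) -> np.ndarray:
        return cluster_graph(adj, method, res, seed=seed)

    lo, hi = resolution_bounds
    if target_k is None:
        labels = run(1.0)
        result = {"labels": labels, "resolution": 1.0,
                  "n_clusters": int(labels.max()) + 1, "warning": False}
    else:
        if target_k < 1:
            raise ValueError("target_k must be >= 1")
        best = None  # (|k - target|, resolution, labels, k)
        labels_lo, labels_hi = run(lo), run(hi)
        candidates = [(lo, labels_lo), (hi, labels_hi)]
        for _ in range(max_iter):
            k_lo = labels_lo.max() + 1
            k_hi = labels_hi.max() + 1
            if k_lo == target_k or k_hi == target_k or hi - lo < 1e-4:
                break
            mid = (lo + hi) / 2.0
            labels_mid = run(mid)
            candidates.append((mid, labels_mid))
            if labels_mid.max() + 1 < target_k:
                lo, labels_lo = mid, labels_mid
            else:
                hi, labels_hi = mid, labels_mid
        for res, labs in candidates:
            k = int(labs.max()) + 1
            key = (abs(k - target_k), res)
            if best is None or key < best[0]:
                best = (key, res, labs, k)
        _, res, labels, k = best
        result = {"labels": labels, "resolution": res, "n_clusters": k,
                  "warning": k != target_k}
        if result["warning"]:
            warnings.warn(f"target_k={target_k} unreachable; returning nearest "
                          f"count {k} at resolution {res:.3f}")
    adata.obs[key_added] = pd.Categorical([str(c) for c in result["labels"]])
    if log is not None:
        log.add("cluster", f"{method} clustering to target_k={target_k}",
                {"achieved_k": result["n_clusters"],
                 "resolution": result["resolution"],
                 "target_reached": not result["warning"],
                 "tie_break": "nearest count, lower resolution preferred"})
    return result


def rank_markers(adata: ad.AnnData, groupby: str = "cluster",
                 n_top: int = 10) -> dict[str, pd.DataFrame]:
    """Top one-vs-rest Wilcoxon rank-sum marker genes per cluster.

    Uses the log-normalized layer; clusters with fewer than two cells are
    skipped with a warning.  Returns per-cluster DataFrames with gene,
    test statistic and p-value, ranked by the statistic.
    """
    labels = adata.obs[groupby].astype(str)
    sizes = labels.value_counts()
    groups = sorted(sizes.index[sizes >= 2], key=str)
    skipped = sorted(set(sizes.index) - set(groups))
    if skipped:
        warnings.warn(f"skipping clusters with <2 cells: {skipped}")
    if len(groups) < 2:
        raise ValueError("need at least two clusters of size >= 2")
    tmp = adata.copy()
    tmp.X = tmp.layers["lognorm"] if "lognorm" in tmp.layers else tmp.X
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        sc.tl.rank_genes_groups(tmp, groupby=groupby, groups=groups,
                                method="wilcoxon", n_genes=n_top, tie_correct=False)
    res = tmp.uns["rank_genes_groups"]
    out = {}
    for g in groups:
        out[str(g)] = pd.DataFrame({
            "gene": res["names"][g][:n_top],
            "score": res["scores"][g][:n_top],
            "pval": res["pvals"][g][:n_top],
        })
    return out


def annotate(markers: Mapping[str, pd.DataFrame], context: str,
             annotator: AnnotatorContract,
             log: ProcessingLog | None = None) -> list[AnnotationRecord]:
    """First-round cluster annotation through the annotator contract."""
    try:
        records = annotator.annotate(markers, context)
    except Exception as exc:  # noqa: BLE001
        warnings.warn(f"annotator failed ({exc}); falling back to Unknown")
        records = [AnnotationRecord(cluster_id=str(c), cell_type="Unknown",
                                    confidence="low", rationale="annotator failure")
                   for c in sorted(markers, key=str)]
    if log is not None:
        for r in records:
            log.add("annotate", f"cluster {r.cluster_id} -> {r.cell_type} "
                    f"({r.confidence})", {"rationale": r.rationale})
    return records


def summarize_expression(adata: ad.AnnData, genes: Sequence[str],
                         groupby: str = "cluster"
                         ) -> dict[str, dict[str, str]]:
    """Discretize cluster-mean expression of ``genes`` into ordinal levels.

    Zero cluster means are "absent"; positive means are binned low / medium /
    high by tertiles of the positive cluster means of that gene.  Genes not
    present in the matrix report "not detected".
    """
    X = adata.layers["lognorm"] if "lognorm" in adata.layers else adata.X
    X = np.asarray(X.todense()) if hasattr(X, "todense") else np.asarray(X)
    clusters = adata.obs[groupby].astype(str)
    cluster_ids = sorted(clusters.unique(), key=str)
    var_index = {g: i for i, g in enumerate(adata.var_names)}
    summary: dict[str, dict[str, str]] = {c: {} for c in cluster_ids}
    for gene in genes:
        if gene not in var_index:
            for c in cluster_ids:
                summary[c][gene] = "not detected"
            continue
        col = X[:, var_index[gene]]
        means = np.array([col[(clusters == c).to_numpy()].mean() for c in cluster_ids])
        positive = means[means > 0]
        if positive.size:
            t1, t2 = np.quantile(positive, [1 / 3, 2 / 3])
        for c, m in zip(cluster_ids, means):
            if m <= 0:
                summary[c][gene] = "absent"
            elif m <= t1:
                summary[c][gene] = "low"
            elif m <= t2:
                summary[c][gene] = "medium"
            else:
                summary[c][gene] = "high"
    return summary


def reannotate(adata: ad.AnnData, records: Sequence[AnnotationRecord],
               annotator: AnnotatorContract, context: str = "",
               groupby: str = "cluster",
               log: ProcessingLog | None = None) -> list[AnnotationRecord]:
    """Second-round annotation from discretized expression of queried genes."""
    genes = annotator.select_query_genes(records, context)
    if not genes:
        if log is not None:
            log.add("reannotate", "no genes queried; records unchanged", {})
        return list(records)
    summary = summarize_expression(adata, genes, groupby=groupby)
    revised = annotator.reannotate(records, summary)
    if log is not None:
        log.add("reannotate", f"queried genes: {', '.join(genes)}",
                {c: summary[c] for c in summary})
        for old, new in zip(records, revised):
            if old.cell_type != new.cell_type:
                log.add("reannotate", f"cluster {new.cluster_id}: "
                        f"{old.cell_type} -> {new.cell_type}",
                        {"rationale": new.rationale})
    return revised


def process_dataset(adata: ad.AnnData, annotator: AnnotatorContract,
                    context: str = "", seed: int = 0,
                    do_reannotate: bool = True
                    ) -> tuple[ad.AnnData, list[AnnotationRecord], ProcessingLog]:
    """Full single-dataset pipeline: config -> QC -> preprocess -> cluster ->
    annotate (-> re-annotate).  Writes per-cell cluster ids and cell types to
    ``obs`` and returns the annotation records plus the processing log."""
    log = ProcessingLog()
    cfg = annotator.decide_config(context)
    log.add("config", "processing parameters decided", asdict(cfg))
    adata, _ = apply_qc_filters(adata, cfg, log=log)
    preprocess(adata, cfg, log=log)
    cluster_to_target(adata, method=cfg.cluster_method, target_k=cfg.target_k,
                      seed=seed, log=log)
    markers = rank_markers(adata, groupby="cluster")
    records = annotate(markers, context, annotator, log=log)
    if do_reannotate:
        records = reannotate(adata, records, annotator, context=context, log=log)
    type_of = {r.cluster_id: r.cell_type for r in records}
    conf_of = {r.cluster_id: r.confidence for r in records}
    clusters = adata.obs["cluster"].astype(str)
    adata.obs["cell_type"] = [type_of.get(c, "Unknown") for c in clusters]
    adata.obs["annotation_confidence"] = [conf_of.get(c, "low") for c in clusters]
    adata.obs["label_given"] = adata.obs["cell_type"]
    return adata, records, log
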