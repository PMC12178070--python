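"""Multi-batch single-cell simulator with known cell types and batch effects.

The generator emulates the structure of cross-platform experiments: several
batches share a panel of cell types, each type over-expresses a set of
marker genes, and every batch applies its own gene-wise multiplicative
factor (the batch effect).  Counts are negative-binomial (gamma-Poisson)
with a per-cell log-normal library-size factor, so QC filters, HVG
selection, marker ranking and batch-integration methods all have realistic
signal to work with.  Every draw is governed by one seed and is bitwise
reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import anndata as ad
import numpy as np
import pandas as pd

from ._lexicon import SYNONYMS, normalize_label
from .similarity import OntologyGraph

__all__ = [
    "CellTypeSpec",
    "SimConfig",
    "default_cell_types",
    "generate_batches",
    "generate_ontology",
    "alias_table",
    "write_mtx_triple",
]

#: default type names, chosen to overlap the synonym table so alias
#: experiments have realistic alternative nomenclature available
_DEFAULT_TYPE_NAMES = [
    "T cell", "B cell", "NK cell", "monocyte", "fibroblast",
    "endothelial cell", "dendritic cell", "keratinocyte",
]


@dataclass(frozen=True)
class CellTypeSpec:
    """One simulated cell type: name, mixing proportion and marker program."""

    name: str
    proportion: float
    markers: tuple[int, ...]
    fold_change: float = 8.0


def default_cell_types(n_types: int = 6, n_genes: int = 300,
                       markers_per_type: int = 20, fold_change: float = 8.0,
                       n_reserved: int = 10) -> list[CellTypeSpec]:
    """Equal-proportion types with disjoint marker blocks.

    The first ``n_reserved`` gene slots are left marker-free (they hold the
    mitochondrial genes), markers start right after.
    """
    if n_types > len(_DEFAULT_TYPE_NAMES):
        raise ValueError(f"at most {len(_DEFAULT_TYPE_NAMES)} default types available")
    needed = n_reserved + n_types * markers_per_type
    if needed > n_genes:
        raise ValueError(f"{needed} marker/reserved genes exceed n_genes={n_genes}")
    types = []
    for t in range(n_types):
        start = n_reserved + t * markers_per_type
        types.append(CellTypeSpec(
            name=_DEFAULT_TYPE_NAMES[t],
            proportion=1.0 / n_types,
            markers=tuple(range(start, start + markers_per_type)),
            fold_change=fold_change,
        ))
    return types


@dataclass
class SimConfig:
    """Simulation parameters; the seed fixes the full output bitwise."""

    n_batches: int = 3
    cells_per_batch: int | Sequence[int] = 500
    n_genes: int = 300
    cell_types: list[CellTypeSpec] = field(default_factory=default_cell_types)
    batch_effect_sd: float = 0.5
    nb_dispersion: float = 10.0
    library_sd: float = 0.3
    private_types: dict[int, list[CellTypeSpec]] = field(default_factory=dict)
    n_mito_genes: int = 10
    seed: int = 0

    def cells_for_batch(self, b: int) -> int:
        if isinstance(self.cells_per_batch, (int, np.integer)):
            return int(self.cells_per_batch)
        return int(self.cells_per_batch[b])

    def validate(self) -> None:
        total = sum(t.proportion for t in self.cell_types)
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"shared type proportions sum to {total}, not 1")
        if self.n_batches < 1 or self.n_genes < 1:
            raise ValueError("n_batches and n_genes must be positive")
        all_types = list(self.cell_types)
        for extra in self.private_types.values():
            all_types.extend(extra)
        for t in all_types:
            if t.proportion <= 0:
                raise ValueError(f"non-positive proportion for {t.name!r}")
            if t.markers and (min(t.markers) < 0 or max(t.markers) >= self.n_genes):
                raise ValueError(f"marker index out of range for {t.name!r}")
        if self.n_mito_genes >= self.n_genes:
            raise ValueError("n_mito_genes must be smaller than n_genes")


def _gene_names(cfg: SimConfig) -> list[str]:
    names = [f"MT-{i + 1}" for i in range(cfg.n_mito_genes)]
    names += [f"G{i:04d}" for i in range(cfg.n_mito_genes, cfg.n_genes)]
    return names


def generate_batches(config: SimConfig) -> list[ad.AnnData]:
    """Simulate one :class:`anndata.AnnData` per batch.

    Per batch: cell types are drawn by proportion; gene means are
    ``baseline x marker fold-change (type) x batch factor x library factor``
    with the batch factor log-normal (sd ``batch_effect_sd``); counts are
    gamma-Poisson with shape ``nb_dispersion`` (Poisson in the limit of
    infinite dispersion).  ``obs`` carries ``batch``, ``label_true``,
    ``label_given`` (initialized to the truth) and QC fields.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    baseline = rng.gamma(shape=2.0, scale=0.5, size=config.n_genes)
    baseline = np.maximum(baseline, 1e-3)
    gene_names = _gene_names(config)
    datasets = []
    for b in range(config.n_batches):
        types = list(config.cell_types) + list(config.private_types.get(b, []))
        props = np.array([t.proportion for t in types], dtype=np.float64)
        props = props / props.sum()
        n_cells = config.cells_for_batch(b)
        type_idx = rng.choice(len(types), size=n_cells, p=props)
        fold = np.ones((len(types), config.n_genes))
        for ti, t in enumerate(types):
            if t.markers:
                fold[ti, list(t.markers)] = t.fold_change
        if config.batch_effect_sd > 0:
            batch_factor = rng.lognormal(mean=0.0, sigma=config.batch_effect_sd,
                                         size=config.n_genes)
        else:
            batch_factor = np.ones(config.n_genes)
        lib = rng.lognormal(mean=0.0, sigma=config.library_sd, size=n_cells) \
            if config.library_sd > 0 else np.ones(n_cells)
        mu = fold[type_idx] * (baseline * batch_factor)[None, :] * lib[:, None]
        if np.isfinite(config.nb_dispersion):
            lam = rng.gamma(shape=config.nb_dispersion, scale=mu / config.nb_dispersion)
        else:
            lam = mu
        counts = rng.poisson(lam).astype(np.int64)
        labels = np.array([types[i].name for i in type_idx], dtype=object)
        total = counts.sum(axis=1)
        detected = (counts > 0).sum(axis=1)
        mito = counts[:, :config.n_mito_genes].sum(axis=1)
        obs = pd.DataFrame({
            "batch": f"batch{b}",
            "label_true": labels,
            "label_given": labels.copy(),
            "total_counts": total,
            "n_genes_detected": detected,
            "mito_frac": np.divide(mito, total, out=np.zeros(len(total)),
                                   where=total > 0),
        }, index=[f"batch{b}_cell{i}" for i in range(n_cells)])
        var = pd.DataFrame(index=pd.Index(gene_names, name="gene"))
        var["mito"] = [n.startswith("MT-") for n in gene_names]
        adata = ad.AnnData(X=counts.astype(np.float32), obs=obs, var=var)
        adata.layers["counts"] = adata.X.copy()
        adata.uns["sim"] = {"batch": b, "seed": config.seed,
                            "batch_effect_sd": config.batch_effect_sd,
                            "nb_dispersion": config.nb_dispersion}
        datasets.append(adata)
    return datasets


def generate_ontology(depth: int, branching: int) -> OntologyGraph:
    """A perfect tree ontology with ``branching ** d`` nodes at depth ``d``.

    Term ids encode the path from the root ("CT:0", "CT:0.1", "CT:0.1.0",
    ...), so the generated ids are deterministic.
    """
    if depth < 0 or branching < 1:
        raise ValueError("depth must be >= 0 and branching >= 1")
    edges: list[tuple[str, str]] = []
    names = {"CT:0": "cell"}
    frontier = ["CT:0"]
    for _ in range(depth):
        nxt = []
        for parent in frontier:
            for c in range(branching):
                child = f"{parent}.{c}"
                edges.append((child, parent))
                names[child] = f"cell type {child[3:]}"
                nxt.append(child)
        frontier = nxt
    if not edges:
        return OntologyGraph({"CT:0": ()}, names)
    return OntologyGraph.from_edges(edges, names)


def alias_table(types: Sequence[str], seed: int = 0) -> dict[str, str]:
    """Deterministic alias for each type name.

    Known types get a synonym from the built-in dictionary (chosen by the
    seed when several exist); unknown types get a case variant.  The alias
    always differs from the original as a string.
    """
    if len(types) == 0:
        raise ValueError("types must be non-empty")
    rng = np.random.default_rng(seed)
    lower_syn = {normalize_label(k): v for k, v in SYNONYMS.items()}
    out: dict[str, str] = {}
    for name in types:
        name = str(name)
        candidates = [a for a in lower_syn.get(normalize_label(name), ())
                      if a != name]
        if candidates:
            alias = candidates[int(rng.integers(len(candidates)))]
        else:
            alias = name.capitalize()
            if alias == name:
                alias = name.upper()
            if alias == name:
                alias = name.swapcase()
            if alias == name:  # no cased characters at all
                alias = name + "-type"
        out[name] = alias
    return out


def write_mtx_triple(adata: ad.AnnData, outdir: str | Path) -> None:
    """Write (matrix.mtx, genes.tsv, metadata.tsv) for interchange."""
    from scipy import io as spio
    from scipy import sparse

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    mat = adata.layers.get("counts", adata.X)
    spio.mmwrite(str(outdir / "matrix.mtx"), sparse.csr_matrix(mat))
    pd.Series(adata.var_names).to_csv(outdir / "genes.tsv", sep="\t",
                                      index=False, header=False)
    adata.obs.to_csv(outdir / "metadata.tsv", sep="\t")


def load_sim_config(path: str | Path) -> SimConfig:
    """Read a SimConfig from a YAML or flat key=value file (CLI helper)."""
    import yaml

    text = Path(path).read_text()
    try:
        data = yaml.safe_load(text)
        if not isinstance(data, Mapping):
            raise ValueError
    except Exception:
        data = {}
        for line in text.splitlines():
            line = line.strip()
            if not line or line.startswith("#") or "=" not in line:
                continue
            k, v = line.split("=", 1)
            data[k.strip()] = yaml.safe_load(v.strip())
    known = {k: v for k, v in data.items()
             if k in SimConfig.__dataclass_fields__ and k != "cell_types"}
    cfg = SimConfig(**known)
    if "n_types" in data or "fold_change" in data:
        cfg.cell_types = default_cell_types(
            n_types=int(data.get("n_types", 6)), n_genes=cfg.n_genes,
            fold_change=float(data.get("fold_change", 8.0)))
    cfg.validate()
    return cfg
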