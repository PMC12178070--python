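# scprior

Prior-informed integration and cell-type harmonization for multi-batch
single-cell RNA-seq data.

When many independently annotated scRNA-seq datasets are merged, two
problems compound each other: technical batch effects displace the same
cell type across datasets, and the annotations themselves disagree —
aliases ("T cell" vs. "T lymphocyte"), different granularity (one atlas's
"T cell" is another's "CD4 T" + "CD8 T"), or outright mislabeling.
Conventional mutual-nearest-neighbor (MNN) batch correction ignores the
labels entirely; strict string matching breaks on the first alias.
`scprior` treats cell-type names as *soft* prior information: labels are
embedded as text vectors, their pairwise cosine similarities form a prior
matrix **M**, and every step of integration consumes M instead of exact
string identity.

## The model

**Prior matrix.** For cell types *I*, *J* with text embeddings
*e<sub>I</sub>*, *e<sub>J</sub>*:
`M_IJ = max(floor, cos(e_I, e_J))`, `M_II = 1`, floor 0.05.
A deterministic offline hashing provider is bundled; any embedding backend
can be plugged in through the provider contract.

**Prior-weighted MNN integration** (`scprior.scanorama_prior`).
Panorama-style assembly with two label-aware changes:

- MNN search runs on weighted distances `d'_ij = d_ij / M_IJ`, favouring
  anchors between identically/similarly named types. The approximate path
  retrieves a 5×k candidate pool by raw distance, then re-ranks by
  weighted distance.
- Each anchor's displacement gets a group-cohesive correction
  `Bias'_ij = Bias_ij + M_IJ (v_i − v_I − v_j + v_J)`, where *v<sub>I</sub>*,
  *v<sub>J</sub>* are the type centroids, so source clusters move as units
  and keep their internal structure.

**Uncertainty-modulated harmonization** (`scprior.cellhint_prior`).
Cells are soft-assigned to another dataset's type centroids. Raw distances
D become similarities `S = exp(−D / mean D)`; each cell's normalized
entropy `α_i = H(p_i)/log K` (the inversion of its clarity score) controls
how much prior is blended in:

    S'_iJ = β[(1 − α_i) S_iJ + α_i M_IJ] + (1 − β) S_iJ,   β = 0.1

Confident cells rely on expression; ambiguous cells lean on the prior, and
the prior's total influence is bounded by β. Type-level assignment
fractions are classified into one-to-one / split / merge / novel
relationships and merged into harmonization groups.

**Two-step pipeline** (`scprior.pipeline`). Harmonize first, rebuild M on
the harmonized names, then integrate — making the embedding step robust to
aliases and even biased mislabeling. Consensus annotation uses fuzzy
majority voting: labels whose embedding cosine exceeds a threshold pool
their votes before the majority is taken.

Supporting modules: a per-dataset processing pipeline (QC → normalize →
cluster-to-target-k → Wilcoxon markers → two-round annotation through a
mock-able annotator contract, `scprior.process`), a negative-binomial
multi-batch simulator with known ground truth (`scprior.synthetic`), and
integration metrics — KMeans ARI, silhouette, iLISI, kBET, with
`overall = 0.4·batch + 0.6·bio` (`scprior.metrics`).

## Worked example

```python
import numpy as np, scanpy as sc
from scprior import synthetic, scanorama_prior, metrics
from scprior.similarity import HashingEmbeddingProvider, prior_matrix_from_labels

# three simulated batches, six shared cell types, gene-wise batch effects
cfg = synthetic.SimConfig(n_batches=3, cells_per_batch=500, seed=0)
batches = synthetic.generate_batches(cfg)
for adata in batches:
    sc.pp.normalize_total(adata, target_sum=1e4)
    sc.pp.log1p(adata)
    adata.layers["lognorm"] = adata.X.copy()

provider = HashingEmbeddingProvider()
labels = sorted({l for a in batches for l in a.obs["label_given"]})
M = prior_matrix_from_labels(labels, provider)
print("M[T cell, B cell]     =", round(M.lookup("T cell", "B cell"), 3))
print("M[T cell, fibroblast] =", round(M.lookup("T cell", "fibroblast"), 3))

embeddings = scanorama_prior.reduce_dimensions(batches, d=100, seed=0)
corrected = scanorama_prior.integrate(embeddings, M=M, k=30, seed=0)

truth = np.concatenate([e.labels for e in embeddings])
batch = np.concatenate([e.batch for e in embeddings])
before = metrics.benchmark_embedding(
    np.vstack([e.coords for e in embeddings]), truth, batch, seed=0)
after = metrics.benchmark_embedding(corrected.coords, truth, batch, seed=0)
for name, rep in (("unintegrated", before), ("scanorama-prior", after)):
    d = rep.as_dict()
    print(f"{name:16s} batch={d['batch_score']:.3f} "
          f"bio={d['bio_score']:.3f} overall={d['overall']:.3f}")
```

prints

```
M[T cell, B cell]     = 0.589
M[T cell, fibroblast] = 0.05
unintegrated     batch=0.129 bio=0.780 overall=0.520
scanorama-prior  batch=0.966 bio=0.786 overall=0.858
```

Related type names score a moderate prior similarity, unrelated ones sit
at the floor (synonyms like "T cell" / "T lymphocyte" score ≈ 0.91).
Integration lifts the batch-mixing score from 0.13 to 0.97 while the
bio-conservation score is preserved, so the weighted overall rises from
0.52 to 0.86.

A command-line interface mirrors the library:
`scprior simulate | process | integrate | harmonize | two-step | vote |
corrupt | experiment | benchmark` (see `scprior --help`).

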