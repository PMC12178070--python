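# Methods

This note documents the models, the synthetic study conditions, and the
numerical choices behind `scprior`. Nothing here states an empirical
result that the test suite or `scripts/acceptance.py` does not itself
compute.

## Label priors

Cell-type names are mapped to unit vectors by an embedding provider and
compared by cosine. The prior matrix is

    M_IJ = max(floor, cos(e_I, e_J)),   M_II = 1,   floor = 0.05.

The floor guards the `d / M` division used during matching: unrelated
names should down-weight an anchor, not delete it with a near-zero
denominator. General-purpose text embeddings keep distinct cell-type names
well apart (similarities of unrelated types typically land below ~0.7),
so a floor of 0.05 is far from the informative range.

The bundled `HashingEmbeddingProvider` hashes character n-grams (n = 2–4)
of the lowercased, whitespace-normalized label into a 256-dimensional
vector with BLAKE2b-derived buckets and signs, then L2-normalizes. It is
bitwise deterministic across processes (no interpreter hash seed
involved). Pure n-gram hashing is blind to synonymy, so labels found in
the built-in synonym lexicon are blended 2:1 toward their canonical form's
n-gram vector; synonym pairs then score cosine ≈ 0.9 while unrelated
types stay dissimilar. This mimics the property of trained text-embedding
models that the alias experiments rely on, without any network dependency.
Any real embedding backend can replace it through the provider contract
(`embed(texts) -> unit-norm rows`, deterministic per provider).

Label keying normalizes by trimming, collapsing internal whitespace and
lowercasing; the original casing of the first occurrence is kept for
display. Embedding cosines used as accuracy scores are clipped to [0, 1]
(clipping is logged); the choice is conservative — anti-correlated name
vectors carry no evidence of partial correctness.

Ontology similarity is the Jaccard coefficient of reflexive-transitive
ancestor sets (a term is its own ancestor), computed on a child→parent
is_a DAG read either from an OBO flat file or generated as a toy tree.
Reflexivity makes an exact match score 1 and keeps the measure granular
down the tree. Label→term resolution is pluggable; the default resolver
tries exact (normalized) name match, then the synonym table.

## Prior-weighted panorama integration

Batches are embedded jointly: the intersection of highly variable genes,
L2-normalized per cell, stacked, and reduced to d = 100 components by a
seeded randomized SVD. Integration then follows the panorama recipe:

1. **Anchors.** Mutual nearest neighbors (k = 30) between a batch and the
   growing panorama, searched under weighted distances
   `d'_ij = d_ij / M_IJ`. Exact mode weights the full distance matrix; the
   approximate mode retrieves `pool_factor × k` (default 5×) candidates by
   raw distance through a nearest-neighbor index and re-ranks the pool by
   weighted distance. Cross-type anchors outside the raw pool are
   unreachable by construction — an accepted fidelity trade-off of the
   two-stage scheme.
2. **Displacements.** Each anchor pair contributes
   `(v_j − v_i) + M_IJ (v_i − v_I − v_j + v_J)` with v_I, v_J the
   per-batch type centroids. At M = 1 the pair bias reduces to
   `v_J − v_I`: the whole group translates while each cell keeps its
   offset from its centroid. Pair biases are smoothed over the batch with
   a Gaussian kernel `w = exp(−0.5 σ d²)`, σ = 15, matching the reference
   integrator's kernel convention.
3. **Unmatched cells** inherit the displacement of their ten
   expression-nearest matched cells *of the same label*, inverse-distance
   weighted, so they follow their own group rather than foreign
   displacement fields. Cells of a label with no matched member keep the
   globally smoothed displacement.
4. **Assembly** is greedy: batches join in descending alignment score
   (fraction of the smaller side's cells participating in a mutual
   match); a batch with no alignment is appended uncorrected with a
   warning.

The prior-free code path (`M=None`) uses unweighted distances and the
centroid correction at unit weight; an explicit all-ones M reproduces it
exactly, which the tests assert to 1e-6. M enters exactly where the two
equations place it — it does not modulate the smoothing weights; that
choice is deliberate and keeps the prior's role interpretable.

## Uncertainty-modulated harmonization

For a pair of datasets, each cell is scored against the other dataset's
type centroids (Euclidean distances in the shared embedding; the pipeline
uses the joint SVD coordinates, 50 dimensions by default):

    S = exp(−D / mean(D)),          mean over all entries of D
    α_i = H(p_i) / log K,           p_i = S_i / Σ_J S_iJ  (natural log)
    S'_iJ = β[(1−α_i) S_iJ + α_i M_IJ] + (1−β) S_iJ,     β = 0.1

α is normalized by log K so it is scale-free in the number of candidate
types; K = 1 defines α = 0. The prior's influence is bounded:
|S' − S| ≤ β·α_i·|M − S| ≤ β, a deliberately cautious incorporation.
"mean(D)" is read as the mean of the computed cell×type distance matrix
(the alternative reading — mean over cell–cell pairs — is not computed
anywhere in this pipeline); α is computed on the full similarity row.

Type-level assignment fractions (`fraction of type-I cells whose argmax
target is J`) are thresholded at 0.5: reciprocal majority ⇒ one-to-one;
one-directional majority ⇒ split (one source) or merge (several sources
into one target); no majority either way ⇒ novel. Union-find over
accepted edges yields the harmonization groups; the group label joins
member names with " = " in first-seen order; per-cell labels are revised
to the group label. Dataset pairs are processed in descending dataset
size (a recorded, overridable parameter); β = 0 or `M=None` runs the
identical prior-free path.

## Two-step pipeline, voting, corruption experiments

`two_step_integrate` chains: initial M from raw labels → harmonization →
M rebuilt from harmonized group labels → prior-weighted integration under
the harmonized labels. All intermediates are returned.

`major_vote` pools, within each cluster, labels whose embedding cosine
reaches the fuzzy threshold (default 0.85 — above unrelated-type
similarities, below the ≈0.9 of synonyms) using transitive closure; the
largest pooled group wins and its most frequent member string becomes the
cluster label (ties: larger count, then lexicographic).

The corruption harness implements three schemes: *fuzzy* (alias from the
built-in table), *unbiased* (a novel token, default "unknown", that must
not collide with existing labels), *biased* (an existing different
label). Corruption applies to a stated fraction (default 1.0 — whole
types are relabeled) of the target types in selected datasets;
`fraction = 0` is allowed as a control and reproduces the clean run
exactly. Corrupting only some datasets is essential: it leaves correctly
labeled cells of the same types elsewhere, which is precisely what
harmonization and majority voting exploit. The experiment integrates
under corrupted labels with three variants (two-step harmonized, prior
only, no prior), Leiden-clusters the full corrected embedding at
resolution 0.7, and evaluates on the changed cells: silhouette of true
types, ARI/NMI of clustering vs. truth, majority-vote recovery
(alias-tolerant label match), and a voted-vs-true confusion matrix.

## Synthetic study conditions

The simulator draws, per batch: cell types by proportion; gene means =
baseline (gamma(2, 0.5) per gene, shared across batches) × marker
fold-change × gene-wise log-normal batch factor × per-cell log-normal
library factor; counts are gamma-Poisson.

Defaults, chosen once for realism: 6 shared types named from the synonym
lexicon, equal proportions; 20 marker genes per type at fold-change 8
(real type programs span dozens of genes); NB dispersion θ = 10
(biological CV ≈ 0.3, typical of UMI data); batch factor SD 0.5 on the
log scale (a strong but correctable batch effect); library SD 0.3 so QC
has depth variation to filter; 300 genes, the first 10 named `MT-*` to
exercise mitochondrial QC. At these settings k-nearest-neighbor
neighborhoods are ≈98% type-pure before integration within a batch —
mirroring real data, where major cell types are separable — while
concatenated batches cluster by batch until corrected.

What the simulator does **not** emulate: zero inflation, doublets,
ambient RNA, nested subtype continua, transcriptome-scale gene counts, or
non-multiplicative batch effects. Passing tests therefore demonstrate the
mechanics and the relative behavior of the methods under controlled
corruption, not performance on atlas-scale real data.

Experiment sizes used by the suite and the acceptance script (chosen to
exercise each property at comfortable statistical resolution): equation
oracles on ≥1000 random instances; prior-free reduction on 5×1000 cells
(tests) / 3×500 (script); integration benchmark on 3×1500 (tests) /
3×1000 (script); corruption experiments on five seeded replicates of
3×400 cells with unequal proportions (0.25 for the biased-corruption
source type, 0.15 elsewhere) so that biased relabeling creates a
majority-conflicted merged group.

## Numerical choices and edge cases

- Resolution search for a target cluster count: bisection on [0.1, 3.0],
  ≤ 20 iterations, exact match accepted early; otherwise the nearest
  count wins, ties prefer the lower resolution (flagged in the log).
  Leiden (leidenalg, seeded) is the default; louvain uses igraph's
  multilevel algorithm with a seeded RNG.
- QC thresholds: minimum genes per cell 300 (inclusive ≥); optional
  upper-bound and mitochondrial/ribosomal filters apply only when set.
  Removing all cells is a hard error.
- Normalization: counts-per-10k + log1p; HVGs by dispersion; PCA on
  scaled HVGs (arpack); these standard-practice defaults are recorded in
  the per-run config and log.
- Expression discretization for re-annotation: cluster means of a queried
  gene are "absent" at zero, else low/medium/high by tertiles of the
  positive cluster means; absent genes report "not detected".
- Confidence scale is the ordinal {low, medium, high}, assigned by the
  mock annotator from the fraction of a type's dictionary markers found
  (≥0.75 high, ≥0.5 medium).
- iLISI uses Gaussian distance weights with a per-cell bandwidth equal to
  the median neighbor distance, k = 90, rescaled by (LISI−1)/(B−1); kBET
  is the fixed-k acceptance-rate variant (chi-squared, α = 0.05, k = 50)
  with neighborhood enlargement when expected counts fall below 5.
  A single batch scores 1 by definition in both.
- Aggregate weights 0.4 (batch) / 0.6 (bio) follow the common
  single-cell integration benchmarking convention.
- All stochastic steps (SVD, KMeans, Leiden, subsampling, simulation)
  take explicit seeds; the full pipeline is bitwise reproducible under a
  fixed seed.

## Known limitations

- The offline provider's synonym awareness is only as good as its small
  built-in lexicon; unknown aliases degrade to surface-string similarity.
- Harmonization aligns type nodes, not individual cells: cells hidden
  inside a mislabeled group are re-labeled only through their group.
- The alignment-order heuristic (size-descending, greedy panorama) can
  matter for marginal alignments; both orders are recorded parameters.
- Exact-mode matching is O(n_A · n_B) per merge; the approximate path
  trades completeness of cross-type anchors for speed.
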