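"""QC filtering, preprocessing, resolution search, markers, mock annotation."""

import anndata as ad
import numpy as np
import pandas as pd
import pytest

from scprior import process, synthetic
from scprior.process import (AnnotationRecord, MockAnnotator, ProcessingConfig,
                             ProcessingLog, apply_qc_filters, cluster_to_target,
                             preprocess, rank_markers, summarize_expression)
from scprior.similarity import annotation_accuracy, HashingEmbeddingProvider
from tests.conftest import prep_lognorm, simulate_prepped


def _toy_counts(detected_per_cell, n_genes=1200, seed=0):
    """Cells expressing exactly the requested number of genes (1 count each)."""
    rng = np.random.default_rng(seed)
    X = np.zeros((len(detected_per_cell), n_genes), dtype=np.float32)
    for i, k in enumerate(detected_per_cell):
        X[i, rng.choice(n_genes, size=k, replace=False)] = 1.0
    adata = ad.AnnData(X=X)
    adata.layers["counts"] = X.copy()
    adata.var_names = [f"G{j}" for j in range(n_genes)]
    return adata


class TestQcFilters:
    def test_min_genes_threshold_is_inclusive(self):
        adata = _toy_counts([100, 300, 400, 50, 1000])
        cfg = ProcessingConfig(min_genes_per_cell=300, min_cells_per_gene=0)
        out, report = apply_qc_filters(adata, cfg)
        assert out.n_obs == 3  # 300 kept (>=), 100 and 50 removed
        assert report["min_genes_per_cell"] == 2

    def test_null_mito_rule_skipped_even_when_fractions_high(self):
        adata = _toy_counts([500, 500])
        adata.var_names = [f"MT-{j}" if j < 600 else f"G{j}"
                           for j in range(adata.n_vars)]
        cfg = ProcessingConfig(min_genes_per_cell=0, min_cells_per_gene=0,
                               max_mito_frac=None)
        out, report = apply_qc_filters(adata, cfg)
        assert out.n_obs == 2
        assert "max_mito_frac" not in report

    def test_mito_rule_applies_when_set(self):
        adata = _toy_counts([500, 500], seed=1)
        adata.var_names = [f"MT-{j}" if j < 600 else f"G{j}"
                           for j in range(adata.n_vars)]
        cfg = ProcessingConfig(min_genes_per_cell=0, min_cells_per_gene=0,
                               max_mito_frac=0.2)
        with pytest.raises(ValueError, match="all cells removed"):
            apply_qc_filters(adata, cfg)

    def test_planted_low_depth_cells_removed_at_boundary(self):
        rng = np.random.default_rng(0)
        n = 2000
        low = rng.random(n) < 0.05
        detected = np.where(low, rng.integers(20, 100, n),
                            rng.integers(300, 800, n))
        adata = _toy_counts(detected.tolist())
        cfg = ProcessingConfig(min_genes_per_cell=150, min_cells_per_gene=0)
        out, _ = apply_qc_filters(adata, cfg)
        removed_frac = 1 - out.n_obs / n
        assert removed_frac == pytest.approx(low.mean(), abs=0.02)

    def test_rare_genes_dropped(self):
        adata = _toy_counts([400] * 10)
        adata.X[:, 0] = 0.0
        adata.layers["counts"][:, 0] = 0.0
        cfg = ProcessingConfig(min_genes_per_cell=0, min_cells_per_gene=3)
        out, report = apply_qc_filters(adata, cfg)
        assert "G0" not in out.var_names
        assert report["min_cells_per_gene"] >= 1


class TestPreprocess:
    def test_normalized_row_sums_hit_target(self):
        ds = simulate_prepped(n_batches=1, cells_per_batch=100, seed=0)[0]
        # rebuild from counts to exercise preprocess itself
        ds.X = ds.layers["counts"].copy()
        cfg = ProcessingConfig(n_hvg=100, n_pcs=20, n_neighbors=10)
        preprocess(ds, cfg)
        sums = np.asarray(ds.layers["norm"]).sum(axis=1)
        assert np.allclose(sums, cfg.normalize_target, atol=1e-3)

    def test_constant_gene_never_selected_as_hvg(self):
        ds = simulate_prepped(n_batches=1, cells_per_batch=120, seed=1)[0]
        ds.X = ds.layers["counts"].copy()
        ds.X[:, 5] = 7.0  # constant across cells
        ds.layers["counts"] = ds.X.copy()
        cfg = ProcessingConfig(n_hvg=100, n_pcs=20, n_neighbors=10)
        preprocess(ds, cfg)
        assert not bool(ds.var["highly_variable"].iloc[5])

    def test_first_pc_separates_two_planted_types(self):
        types = [
            synthetic.CellTypeSpec("T cell", 0.5, tuple(range(20, 40)), 8.0),
            synthetic.CellTypeSpec("B cell", 0.5, tuple(range(40, 60)), 8.0),
        ]
        cfg_sim = synthetic.SimConfig(n_batches=1, cells_per_batch=400,
                                      cell_types=types, batch_effect_sd=0.0,
                                      seed=2)
        ds = synthetic.generate_batches(cfg_sim)[0]
        preprocess(ds, ProcessingConfig(n_hvg=150, n_pcs=20, n_neighbors=10))
        pc1 = ds.obsm["X_pca"][:, 0]
        is_t = (np.asarray(ds.obs["label_true"]) == "T cell").astype(float)
        r = np.corrcoef(pc1, is_t)[0, 1]
        assert abs(r) > 0.9

    def test_excessive_n_pcs_rejected(self):
        ds = simulate_prepped(n_batches=1, cells_per_batch=50, seed=3)[0]
        with pytest.raises(ValueError, match="n_pcs"):
            preprocess(ds, ProcessingConfig(n_hvg=100, n_pcs=60))


@pytest.fixture(scope="module")
def clustered_dataset():
    ds = simulate_prepped(n_batches=1, cells_per_batch=600, seed=4)[0]
    ds.X = ds.layers["counts"].copy()
    preprocess(ds, ProcessingConfig(n_hvg=150, n_pcs=20, n_neighbors=15))
    return ds


class TestClusterToTarget:
    def test_target_one_yields_single_cluster_on_connected_graph(self):
        # single cell type -> fully connected kNN graph
        types = [synthetic.CellTypeSpec("T cell", 1.0, tuple(range(20, 40)), 8.0)]
        cfg_sim = synthetic.SimConfig(n_batches=1, cells_per_batch=200,
                                      cell_types=types, seed=13)
        ds = synthetic.generate_batches(cfg_sim)[0]
        preprocess(ds, ProcessingConfig(n_hvg=100, n_pcs=10, n_neighbors=15))
        res = cluster_to_target(ds, target_k=1, resolution_bounds=(1e-4, 3.0))
        assert res["n_clusters"] == 1

    def test_planted_blobs_recovered_at_target(self, clustered_dataset):
        from sklearn.metrics import adjusted_rand_score

        ds = clustered_dataset.copy()
        res = cluster_to_target(ds, target_k=6, seed=0)
        assert res["n_clusters"] == 6
        ari = adjusted_rand_score(ds.obs["label_true"], res["labels"])
        assert ari > 0.95

    @pytest.mark.parametrize("method", ["leiden", "louvain"])
    def test_same_seed_gives_identical_labels(self, clustered_dataset, method):
        ds = clustered_dataset.copy()
        r1 = cluster_to_target(ds, method=method, target_k=6, seed=1)
        r2 = cluster_to_target(ds, method=method, target_k=6, seed=1)
        assert np.array_equal(r1["labels"], r2["labels"])

    def test_unreachable_target_warns_and_returns_nearest(self, clustered_dataset):
        ds = clustered_dataset.copy()
        with pytest.warns(UserWarning, match="unreachable"):
            res = cluster_to_target(ds, target_k=200, max_iter=4)
        assert res["warning"]


class TestRankMarkers:
    def test_exclusive_gene_ranks_first(self):
        rng = np.random.default_rng(0)
        X = rng.poisson(2.0, size=(200, 50)).astype(np.float32)
        labels = np.array(["A"] * 100 + ["B"] * 100)
        X[labels == "A", 7] += 40.0  # gene expressed only/strongly in A
        adata = ad.AnnData(X=np.log1p(X))
        adata.layers["lognorm"] = adata.X.copy()
        adata.var_names = [f"G{j}" for j in range(50)]
        adata.obs["cluster"] = pd.Categorical(labels)
        markers = rank_markers(adata, n_top=10)
        assert markers["A"]["gene"].iloc[0] == "G7"

    def test_label_permutation_destroys_enrichment(self, clustered_dataset):
        ds = clustered_dataset.copy()
        cluster_to_target(ds, target_k=6, seed=0)
        markers_true = rank_markers(ds, n_top=10)
        planted = {f"MT-{i}" for i in range(1, 11)} | \
            {v for v in ds.var_names if v.startswith("G")}
        rng = np.random.default_rng(1)
        ds.obs["cluster"] = pd.Categorical(
            rng.permutation(np.asarray(ds.obs["cluster"])))
        markers_perm = rank_markers(ds, n_top=10)
        # permuted labels: top-10 "markers" become insignificant
        min_p_true = min(m["pval"].min() for m in markers_true.values())
        min_p_perm = min(m["pval"].min() for m in markers_perm.values())
        assert min_p_true < 1e-20
        assert min_p_perm > min_p_true

    def test_identical_clusters_yield_no_significant_genes(self):
        rng = np.random.default_rng(2)
        X = np.log1p(rng.poisson(2.0, size=(300, 80)).astype(np.float32))
        adata = ad.AnnData(X=X)
        adata.layers["lognorm"] = X.copy()
        adata.obs["cluster"] = pd.Categorical(
            np.array(["A", "B"])[rng.integers(2, size=300)])
        markers = rank_markers(adata, n_top=10)
        n_sig = sum((m["pval"] * adata.n_vars < 0.01).sum()
                    for m in markers.values())
        assert n_sig == 0

    def test_singleton_cluster_skipped_with_warning(self):
        rng = np.random.default_rng(3)
        X = np.log1p(rng.poisson(2.0, size=(101, 30)).astype(np.float32))
        adata = ad.AnnData(X=X)
        adata.layers["lognorm"] = X.copy()
        adata.obs["cluster"] = pd.Categorical(["A"] * 50 + ["B"] * 50 + ["C"])
        with pytest.warns(UserWarning, match="<2 cells"):
            markers = rank_markers(adata)
        assert "C" not in markers


class TestMockAnnotator:
    def test_dictionary_hit_gives_type_and_high_confidence(self):
        annotator = MockAnnotator({"T cell": ["CD3D", "CD3E"]})
        markers = {"0": pd.DataFrame({"gene": ["CD3D", "CD3E", "GZMB"],
                                      "score": [5, 4, 3], "pval": [0] * 3})}
        rec = annotator.annotate(markers)[0]
        assert rec.cell_type == "T cell"
        assert rec.confidence == "high"

    def test_no_match_falls_back_to_unknown(self):
        annotator = MockAnnotator({"T cell": ["CD3D"]})
        markers = {"0": pd.DataFrame({"gene": ["ALB", "APOA1"],
                                      "score": [2, 1], "pval": [0] * 2})}
        rec = annotator.annotate(markers)[0]
        assert rec.cell_type == "Unknown"
        assert rec.confidence == "low"

    def test_decide_config_parses_context_lines(self):
        annotator = MockAnnotator({})
        cfg = annotator.decide_config(
            "min_genes_per_cell=500\nmax_mito_frac=0.2\ntarget_k=7\n"
            "cluster_method=leiden\nmax_genes_per_cell=None")
        assert cfg.min_genes_per_cell == 500
        assert cfg.max_mito_frac == pytest.approx(0.2)
        assert cfg.target_k == 7
        assert cfg.max_genes_per_cell is None

    def test_failing_annotator_yields_unknown_records(self):
        class Broken:
            def annotate(self, markers, context):
                raise RuntimeError("provider down")

        markers = {"0": pd.DataFrame({"gene": ["X"], "score": [1], "pval": [0]})}
        with pytest.warns(UserWarning, match="annotator failed"):
            records = process.annotate(markers, "", Broken())
        assert records[0].cell_type == "Unknown"


class TestReannotate:
    def test_no_query_genes_leaves_records_unchanged(self):
        annotator = MockAnnotator({"T cell": ["CD3D"]})
        records = [AnnotationRecord("0", "T cell", "high")]
        ds = simulate_prepped(n_batches=1, cells_per_batch=60, seed=5)[0]
        ds.obs["cluster"] = pd.Categorical(["0"] * ds.n_obs)
        out = process.reannotate(ds, records, annotator)
        assert out == records

    def test_constant_zero_gene_is_absent_everywhere(self):
        ds = simulate_prepped(n_batches=1, cells_per_batch=60, seed=6)[0]
        ds.layers["lognorm"][:, 3] = 0.0
        ds.obs["cluster"] = pd.Categorical(["0"] * 30 + ["1"] * 30)
        gene = str(ds.var_names[3])
        summary = summarize_expression(ds, [gene])
        assert all(summary[c][gene] == "absent" for c in summary)

    def test_missing_gene_reported_not_detected(self):
        ds = simulate_prepped(n_batches=1, cells_per_batch=40, seed=7)[0]
        ds.obs["cluster"] = pd.Categorical(["0"] * ds.n_obs)
        summary = summarize_expression(ds, ["NOT_A_GENE"])
        assert summary["0"]["NOT_A_GENE"] == "not detected"

    def test_planted_subtypes_split_by_refinement_rule(self):
        # two subtypes share a program; one also expresses a switch gene
        base = tuple(range(20, 40))
        other = tuple(range(70, 90))
        switch_program = tuple(range(60, 65))  # subtype-A-specific program
        types = [
            synthetic.CellTypeSpec("intercalated A", 0.3, base + switch_program, 8.0),
            synthetic.CellTypeSpec("intercalated B", 0.3, base, 8.0),
            synthetic.CellTypeSpec("B cell", 0.4, other, 8.0),
        ]
        cfg_sim = synthetic.SimConfig(n_batches=1, cells_per_batch=500,
                                      cell_types=types, batch_effect_sd=0.0,
                                      seed=8)
        ds = synthetic.generate_batches(cfg_sim)[0]
        switch = str(ds.var_names[60])
        shared = [str(ds.var_names[i]) for i in base[:6]]
        preprocess(ds, ProcessingConfig(n_hvg=150, n_pcs=15, n_neighbors=15))
        cluster_to_target(ds, target_k=3, seed=0)
        markers = rank_markers(ds)
        annotator = MockAnnotator(
            {"intercalated cell": shared,
             "B cell": [str(ds.var_names[i]) for i in other[:6]]},
            refine_rules={"intercalated cell":
                          (switch, "intercalated A", "intercalated B")})
        records = annotator.annotate(markers)
        revised = process.reannotate(ds, records, annotator)
        revised_types = {r.cell_type for r in revised}
        assert revised_types == {"intercalated A", "intercalated B", "B cell"}
        # the refined labels match the planted truth cluster-wise
        type_of = {r.cluster_id: r.cell_type for r in revised}
        per_cell = [type_of[c] for c in ds.obs["cluster"].astype(str)]
        acc = np.mean(np.asarray(per_cell) ==
                      np.asarray(ds.obs["label_true"], dtype=object))
        assert acc > 0.95


class TestFullPipeline:
    @pytest.fixture(scope="class", name="processed")
    @staticmethod
    def _processed():
        cfg = synthetic.SimConfig(n_batches=1, cells_per_batch=500, seed=9)
        adata = synthetic.generate_batches(cfg)[0]
        marker_dict = {t.name: [str(adata.var_names[i]) for i in t.markers[:8]]
                       for t in cfg.cell_types}
        annotator = MockAnnotator(marker_dict, config_overrides={
            "min_genes_per_cell": 50, "n_hvg": 150, "n_pcs": 20, "target_k": 6})
        return process.process_dataset(adata.copy(), annotator, seed=0), \
            adata, annotator

    def test_cluster_level_annotation_accuracy_is_perfect(self, processed,
                                                          provider):
        (out, records, _), _, _ = processed
        acc = annotation_accuracy(out.obs["cell_type"], out.obs["label_true"],
                                  level="cluster", provider=provider)
        assert acc == pytest.approx(1.0)

    def test_rerun_is_bitwise_reproducible(self, processed):
        (out1, rec1, log1), adata, annotator = processed
        out2, rec2, log2 = process.process_dataset(adata.copy(), annotator,
                                                   seed=0)
        assert (out1.obs["cell_type"] == out2.obs["cell_type"]).all()
        assert rec1 == rec2
        assert log1.render() == log2.render()

    def test_every_decision_is_logged(self, processed):
        (_, records, log), _, _ = processed
        text = log.render()
        for step in ("config", "qc_filter", "preprocess", "cluster", "annotate"):
            assert f"[{step}]" in text
        for r in records:
            assert r.cell_type in text

    def test_confidence_tracks_accuracy(self):
        # a deliberately degraded dictionary for one type lowers both its
        # confidence and its accuracy: high-confidence records must not be
        # less accurate than low-confidence ones
        cfg = synthetic.SimConfig(n_batches=1, cells_per_batch=500, seed=10)
        adata = synthetic.generate_batches(cfg)[0]
        marker_dict = {}
        for t in cfg.cell_types:
            genes = [str(adata.var_names[i]) for i in t.markers[:8]]
            if t.name == "fibroblast":  # mostly wrong markers
                genes = genes[:1] + ["G0299", "G0298", "G0297"] * 2 + genes[:1]
            marker_dict[t.name] = genes
        annotator = MockAnnotator(marker_dict, config_overrides={
            "min_genes_per_cell": 50, "n_hvg": 150, "n_pcs": 20, "target_k": 6})
        out, records, _ = process.process_dataset(adata, annotator, seed=0)
        truth = out.obs.groupby("cluster", observed=True)["label_true"] \
            .agg(lambda s: s.mode()[0])
        acc = {r.cluster_id: float(r.cell_type == truth[r.cluster_id])
               for r in records}
        by_conf = {}
        for r in records:
            by_conf.setdefault(r.confidence, []).append(acc[r.cluster_id])
        if "high" in by_conf and "low" in by_conf:
            assert np.mean(by_conf["high"]) >= np.mean(by_conf["low"])
        else:  # degraded dictionary must at least lower that type's confidence
            assert any(r.confidence != "high" for r in records)


def test_processing_log_round_trip(tmp_path):
    log = ProcessingLog()
    log.add("config", "chose thresholds", {"min_genes": 300})
    path = tmp_path / "run.log"
    log.write(path)
    assert "min_genes" in path.read_text()
    assert "chose thresholds" in log
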