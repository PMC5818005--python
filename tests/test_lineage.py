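"""PCA, clustering (with brute-force oracle), POU5F1 extraction, ratio
calls, pseudotime and the composite blastocyst workflow."""

import numpy as np
import pandas as pd
import pytest
import scipy.stats

import embryolin as e
from _oracles import brute_force_average_linkage
from embryolin.core import ValidationError
from embryolin.lineage import (
    Embedding,
    assign_late_icm,
    classify_blastocyst,
    diffusion_pseudotime,
    extract_pou5f1_classes,
    find_early_icm,
    hierarchical_clusters,
    pca,
    ratio_classify,
)


def _matrix(values, genes=None, cells=None, unit="log2FPKM"):
    values = np.asarray(values, dtype=float)
    genes = genes or [f"g{i}" for i in range(values.shape[0])]
    cells = cells or [f"c{i:02d}" for i in range(values.shape[1])]
    return e.ExpressionMatrix(pd.DataFrame(values, index=genes, columns=cells), unit)


class TestPca:
    def test_anticorrelated_pair_is_one_component(self):
        x = np.array([[1, 2, 3, 4], [4, 3, 2, 1]], dtype=float)
        emb = pca(_matrix(x))
        assert emb.variance_explained[0] == pytest.approx(1.0)

    def test_duplicated_cells_share_coordinates(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=(5, 4))
        x = np.hstack([x, x[:, :1]])  # duplicate first cell as the last
        emb = pca(_matrix(x))
        np.testing.assert_allclose(emb.coordinates[0], emb.coordinates[-1], atol=1e-10)

    def test_reconstruction_from_all_components(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=(6, 10))
        emb = pca(_matrix(x))
        recon = emb.coordinates @ emb.component_loadings.T
        centred = x.T - x.T.mean(axis=0)
        np.testing.assert_allclose(recon, centred, atol=1e-8)

    def test_loadings_are_orthonormal(self):
        rng = np.random.default_rng(2)
        emb = pca(_matrix(rng.normal(size=(8, 12))))
        gram = emb.component_loadings.T @ emb.component_loadings
        np.testing.assert_allclose(gram, np.eye(gram.shape[0]), atol=1e-8)

    def test_variance_explained_non_increasing(self):
        rng = np.random.default_rng(3)
        emb = pca(_matrix(rng.normal(size=(10, 20))))
        assert (np.diff(emb.variance_explained) <= 1e-12).all()

    def test_constant_matrix_degenerates_to_zero(self):
        emb = pca(_matrix(np.ones((4, 5))))
        assert np.allclose(emb.variance_explained, 0)
        assert np.allclose(emb.coordinates, 0)

    def test_marker_panel_separates_lineages(self, late_sim):
        from sklearn.metrics import silhouette_score

        cfg, m, ann, truth = late_sim
        logm = e.log_transform(m)
        emb = pca(logm, genes=cfg.marker_panel.genes)
        labels = np.array([truth.labels[c] for c in emb.cell_ids])
        keep = labels != "intermediate"
        assert silhouette_score(emb.coordinates[keep, :2], labels[keep]) > 0.5


class TestHierarchicalClusters:
    def test_two_separated_clouds(self):
        rng = np.random.default_rng(0)
        x = np.vstack([rng.normal(0, 0.1, (10, 2)), rng.normal(10, 0.1, (10, 2))])
        cells = [f"c{i:02d}" for i in range(20)]
        emb = Embedding(cells, [], x, np.zeros((0, 2)), np.ones(2) / 2)
        labels = hierarchical_clusters(emb, 2)
        first = {labels[c] for c in cells[:10]}
        second = {labels[c] for c in cells[10:]}
        assert len(first) == len(second) == 1 and first != second

    def test_k_equals_one_and_k_too_large(self):
        emb = Embedding(["a", "b"], [], np.array([[0.0], [1.0]]), np.zeros((0, 1)), np.ones(1))
        assert set(hierarchical_clusters(emb, 1).values()) == {1}
        with pytest.raises(ValidationError):
            hierarchical_clusters(emb, 3)

    def test_three_planted_gaussians_ari_one(self):
        from sklearn.metrics import adjusted_rand_score

        rng = np.random.default_rng(1)
        centroids = np.array([[0, 0], [10, 0], [0, 10]])
        x = np.vstack([rng.normal(c, 0.1, (15, 2)) for c in centroids])
        truth = np.repeat([0, 1, 2], 15)
        cells = [f"c{i:02d}" for i in range(45)]
        emb = Embedding(cells, [], x, np.zeros((0, 2)), np.ones(2) / 2)
        labels = hierarchical_clusters(emb, 3)
        assert adjusted_rand_score(truth, [labels[c] for c in cells]) == 1.0

    @pytest.mark.parametrize("n,dim,seed", [(8, 2, 0), (15, 3, 1), (20, 4, 2)])
    def test_merge_sequence_matches_brute_force_oracle(self, n, dim, seed):
        """scipy's average linkage reproduces the O(n^3) oracle exactly."""
        import scipy.cluster.hierarchy as sch

        rng = np.random.default_rng(seed)
        x = rng.normal(size=(n, dim))
        z = sch.linkage(x, method="average")
        oracle = brute_force_average_linkage(x)
        # replay scipy's merge list into member sets
        members = {i: frozenset([i]) for i in range(n)}
        for step, (row, (oa, ob, oh)) in enumerate(zip(z, oracle)):
            a, b = int(row[0]), int(row[1])
            sa, sb = members[a], members[b]
            assert {sa, sb} == {oa, ob}, f"merge {step} differs"
            assert row[2] == pytest.approx(oh, rel=1e-9)
            members[n + step] = sa | sb


class TestPou5f1Classes:
    def test_constant_pou5f1_warns(self):
        x = np.vstack([np.ones(6), np.arange(6, dtype=float)])
        m = _matrix(x, genes=["POU5F1", "other"])
        emb = pca(m, n_components=None)
        with pytest.warns(UserWarning, match="constant"):
            extract_pou5f1_classes(m, emb, n_classes=2, component=1)

    def test_two_classes_use_high_low(self):
        rng = np.random.default_rng(0)
        pou = np.concatenate([np.full(10, 8.0), np.full(10, 1.0)])
        other = rng.normal(size=20)
        m = _matrix(np.vstack([pou, other]), genes=["POU5F1", "g"])
        emb = Embedding(m.cell_ids, [], pou.reshape(-1, 1) + 0.0, np.zeros((0, 1)), np.ones(1))
        classes = extract_pou5f1_classes(m, emb, n_classes=2, component=1)
        assert set(classes.values()) == {"high", "low"}
        assert all(classes[c] == "high" for c in m.cell_ids[:10])

    def test_te_lands_in_low_class(self, late_sim):
        """TE cells (POU5F1 off) fall into the low class with >= 95% purity."""
        cfg, m, ann, truth = late_sim
        logm = e.log_transform(m)
        sets = e.per_study_variable_genes(m, ann)
        genes = sorted(e.intersect_variable_genes(list(sets.values())).gene_ids)
        emb = pca(logm, genes=genes)
        classes = extract_pou5f1_classes(logm, emb, component="auto")
        low = [c for c, cl in classes.items() if cl == "low"]
        te = {c for c, s in truth.labels.items() if s == "TE"}
        purity = len(set(low) & te) / len(low)
        capture = len(set(low) & te) / len(te)
        assert purity >= 0.95 and capture >= 0.95


class TestRatioClassify:
    def test_symmetry_and_examples(self):
        m = _matrix(np.array([[6.0, 3.0, 0.0], [0.0, 3.0, 6.0]]),
                    genes=["NANOG", "PDGFRA"])
        out = ratio_classify(m).set_index("cell_id")
        assert out.loc["c00", "call"] == "EPI"
        assert out.loc["c01", "call"] == "intermediate"
        assert out.loc["c02", "call"] == "PrE"

    def test_antisymmetric_under_gene_swap(self):
        rng = np.random.default_rng(0)
        m = _matrix(rng.uniform(0, 8, size=(2, 30)), genes=["NANOG", "PDGFRA"])
        fwd = ratio_classify(m, nanog="NANOG", pdgfra="PDGFRA").set_index("cell_id")
        rev = ratio_classify(m, nanog="PDGFRA", pdgfra="NANOG").set_index("cell_id")
        swap = {"EPI": "PrE", "PrE": "EPI", "intermediate": "intermediate"}
        for c in m.cell_ids:
            assert rev.loc[c, "call"] == swap[fwd.loc[c, "call"]]
            assert rev.loc[c, "ratio_nanog_pdgfra"] == pytest.approx(
                -fwd.loc[c, "ratio_nanog_pdgfra"])

    def test_mature_cells_called_correctly(self):
        """Ratio calls match truth for >= 95% of mature ICM cells when the
        marker transcripts are reliably detected (low-dropout libraries)."""
        import dataclasses

        cfg = dataclasses.replace(e.late_blastocyst_config(0), n_studies=1,
                                  dropout_rates=(0.02,), batch_scale_sd=0.0)
        m, ann, truth = e.simulate_dataset(cfg)
        logm = e.log_transform(m)
        mature = [c for c, s in truth.labels.items() if s in ("EPI", "PrE")]
        out = ratio_classify(logm, cells=mature).set_index("cell_id")
        acc = np.mean([out.loc[c, "call"] == truth.labels[c] for c in mature])
        assert acc >= 0.95


class TestAssignLateIcm:
    def test_degenerate_identical_cells(self, late_sim):
        cfg, *_ = late_sim
        x = np.ones((12, 6))
        m = _matrix(x, genes=cfg.marker_panel.genes)
        ann = e.make_annotation(m.cell_ids, stage="EPI")
        classes = {c: "high" for c in m.cell_ids}
        out = assign_late_icm(m, ann, cfg.marker_panel, classes)
        assert set(out["call"]) == {"intermediate"}

    def test_too_few_cells_unassigned(self, late_sim):
        cfg, *_ = late_sim
        m = _matrix(np.ones((12, 2)), genes=cfg.marker_panel.genes)
        ann = e.make_annotation(m.cell_ids, stage="EPI")
        out = assign_late_icm(m, ann, cfg.marker_panel, {c: "high" for c in m.cell_ids[:1]})
        assert set(out["call"]) == {"unassigned"}

    def test_epi_pre_recall_on_default_config(self, late_sim):
        cfg, m, ann, truth = late_sim
        calls = classify_blastocyst(m, ann, cfg.marker_panel).set_index("cell_id")
        for lin in ("EPI", "PrE"):
            cells = [c for c, s in truth.labels.items() if s == lin]
            recall = np.mean([calls.loc[c, "call"] == lin for c in cells])
            assert recall >= 0.95

    def test_icm_calls_restricted_to_high_medium(self, late_sim):
        cfg, m, ann, truth = late_sim
        calls = classify_blastocyst(m, ann, cfg.marker_panel)
        icm = calls[calls["call"].isin(["EPI", "PrE", "intermediate"])]
        assert set(icm["pou5f1_class"]) <= {"high", "medium"}


class TestPseudotime:
    def _gradient_matrix(self, n=60):
        pos = np.linspace(0, 10, n)
        x = np.vstack([pos, 2 * pos, 20 - pos])
        return _matrix(np.abs(x)), pos

    def test_monotone_on_noiseless_gradient(self):
        m, pos = self._gradient_matrix()
        pt = diffusion_pseudotime(m, n_neighbors=10)
        rho = scipy.stats.spearmanr(pt.values, pos).statistic
        assert abs(rho) == pytest.approx(1.0)

    def test_duplicated_cells_get_equal_pseudotime(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=(4, 20))
        x[:, -1] = x[:, 0]
        m = _matrix(x)
        pt = diffusion_pseudotime(m, n_neighbors=5)
        assert pt.iloc[0] == pytest.approx(pt.iloc[-1], abs=1e-9)

    def test_too_few_cells_rejected(self):
        m, _ = self._gradient_matrix(10)
        with pytest.raises(ValidationError):
            diffusion_pseudotime(m, n_neighbors=15)

    def test_range_in_unit_interval(self):
        m, _ = self._gradient_matrix()
        pt = diffusion_pseudotime(m, n_neighbors=10)
        assert pt.min() >= 0 and pt.max() <= 1


class TestFindEarlyIcm:
    def test_no_e5_cells_gives_empty(self, late_sim):
        cfg, m, ann, truth = late_sim
        logm = e.log_transform(m)
        ann2 = ann.copy()
        ann2["embryonic_day"] = "E6"
        genes = [g for g in e.simulate.EARLY_ICM_MARKERS if g in set(m.gene_ids)]
        assert find_early_icm(logm, ann2, genes) == set()

    def test_missing_markers_rejected(self, e5_sim):
        cfg, m, ann, truth = e5_sim
        with pytest.raises(ValidationError):
            find_early_icm(e.log_transform(m), ann, ["NOT_A_GENE"])

    def test_planted_early_icm_recovered(self, e5_sim):
        cfg, m, ann, truth = e5_sim
        logm = e.log_transform(m)
        found = find_early_icm(logm, ann, e.simulate.EARLY_ICM_MARKERS)
        planted = {c for c, s in truth.labels.items() if s == "earlyICM"}
        tp = len(found & planted)
        assert tp / len(planted) >= 0.9
        assert tp / len(found) >= 0.9

    def test_early_cells_rank_early_on_a_maturation_gradient(self):
        """On a continuum from the early-ICM programme toward EPI, cells
        near the early end get the smallest pseudotime (5 seeds)."""
        pvals = []
        cfg = e.e5_config(0)
        a = cfg.programs["earlyICM"].values[:300]
        b = cfg.programs["EPI"].values[:300]
        genes = list(cfg.programs.index[:300])
        for seed in range(5):
            rng = np.random.default_rng(seed)
            w = np.sort(rng.uniform(0, 1, 120))
            x = np.outer(a, 1 - w) + np.outer(b, w) + rng.normal(0, 0.4, (300, 120))
            cells = [f"c{i:03d}" for i in range(120)]
            m = _matrix(x, genes=genes, cells=cells)
            roots = cells[:10]
            pt = diffusion_pseudotime(m, n_neighbors=15, root_cells=roots)
            early = [pt[c] for c, wi in zip(cells, w) if wi < 0.25]
            other = [pt[c] for c, wi in zip(cells, w) if wi >= 0.25]
            pvals.append(scipy.stats.mannwhitneyu(early, other, alternative="less").pvalue)
        assert all(p < 0.01 for p in pvals)
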