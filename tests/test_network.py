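"""Adjacency, TOM (with brute-force oracle), module detection, eigengenes,
merging and hub ranking."""

import numpy as np
import pandas as pd
import pytest

import embryolin as e
from embryolin.core import ValidationError
from embryolin.network import (
    adjacency,
    build_modules,
    detect_modules,
    hub_genes,
    merge_modules,
    module_eigengene,
    tom_similarity,
)


def _matrix(values, genes=None):
    values = np.asarray(values, dtype=float)
    genes = genes or [f"g{i}" for i in range(values.shape[0])]
    cells = [f"c{i:02d}" for i in range(values.shape[1])]
    return e.ExpressionMatrix(pd.DataFrame(values, index=genes, columns=cells), "log2FPKM")


class TestAdjacency:
    def test_beta_one_is_absolute_correlation(self):
        rng = np.random.default_rng(0)
        m = _matrix(rng.normal(size=(4, 30)))
        a = adjacency(m, beta=1.0)
        cor = np.abs(np.corrcoef(m.values))
        np.testing.assert_allclose(a.values, cor, atol=1e-12)

    def test_perfect_pair_is_one_for_any_beta(self):
        x = np.arange(10, dtype=float)
        m = _matrix(np.vstack([x, 2 * x + 1, x[::-1]]))
        for beta in (1, 6, 10):
            a = adjacency(m, beta=beta)
            assert a.values[0, 1] == pytest.approx(1.0)
            assert a.values[0, 2] == pytest.approx(1.0)  # anticorrelated, unsigned

    def test_half_correlation_to_the_tenth(self):
        # construct two genes with exact sample correlation 0.5
        x = np.array([1.0, -1.0, 1.0, -1.0])
        y = np.array([1.0, -1.0, -1.0, 1.0])
        g2 = x + y  # cor(x, x+y) = 1/sqrt(2)... use direct construction instead
        rng = np.random.default_rng(1)
        for _ in range(50):
            a_ = rng.normal(size=40)
            b_ = 0.5 * (a_ - a_.mean()) / a_.std() + np.sqrt(0.75) * rng.normal(size=40)
            m = _matrix(np.vstack([a_, b_]))
            cor = np.corrcoef(a_, b_)[0, 1]
            a = adjacency(m, beta=10.0)
            assert a.values[0, 1] == pytest.approx(abs(cor) ** 10, rel=1e-9)

    def test_zero_variance_gene_dropped_with_warning(self):
        m = _matrix(np.vstack([np.ones(10), np.arange(10), np.arange(10)[::-1]]))
        with pytest.warns(UserWarning, match="zero-variance"):
            a = adjacency(m)
        assert a.shape == (2, 2)


class TestTom:
    def test_isolated_pair_zero_and_twins_one(self):
        a = pd.DataFrame(np.eye(4), index=list("abcd"), columns=list("abcd"))
        tom = tom_similarity(a)
        assert tom.values[0, 1] == 0.0
        # twins fully connected to the same neighbourhood (binary weights)
        b = np.ones((3, 3))
        tomb = tom_similarity(pd.DataFrame(b, index=list("xyz"), columns=list("xyz")))
        assert tomb.values[0, 1] == pytest.approx(1.0)

    @pytest.mark.parametrize("seed", range(3))
    def test_matches_brute_force_on_random_instances(self, seed):
        rng = np.random.default_rng(seed)
        a = rng.uniform(0, 1, (6, 6))
        a = (a + a.T) / 2
        np.fill_diagonal(a, 1.0)
        A = pd.DataFrame(a, index=list("abcdef"), columns=list("abcdef"))
        tom = tom_similarity(A).values
        brute = np.eye(6)
        for i in range(6):
            for j in range(6):
                if i == j:
                    continue
                num = sum(a[i, u] * a[u, j] for u in range(6) if u not in (i, j)) + a[i, j]
                ki = sum(a[i, u] for u in range(6) if u != i)
                kj = sum(a[j, u] for u in range(6) if u != j)
                brute[i, j] = num / (min(ki, kj) + 1 - a[i, j])
        np.testing.assert_allclose(tom, brute, atol=1e-12)

    def test_symmetric_and_bounded(self, module_sim):
        cfg, logm, ann, truth = module_sim
        genes = truth.genes_with_role("module")[:80]
        tom = tom_similarity(adjacency(logm, genes=genes)).values
        assert np.abs(tom - tom.T).max() < 1e-12
        assert tom.min() >= 0 and tom.max() <= 1 + 1e-12


class TestDetectModules:
    def test_planted_blocks_recovered(self, module_sim):
        from sklearn.metrics import adjusted_rand_score

        cfg, logm, ann, truth = module_sim
        planted = {g: r["module"] for g, r in truth.roles.items()
                   if r.get("role") == "module"}
        genes = sorted(planted)
        tom = tom_similarity(adjacency(logm, genes=genes))
        assignment = detect_modules(1.0 - tom, min_size=50)
        ari = adjusted_rand_score([planted[g] for g in genes],
                                  [assignment[g] for g in genes])
        assert ari == 1.0

    @pytest.mark.parametrize("seed", range(5))
    def test_pure_noise_gives_no_modules(self, seed):
        cfg = e.module_config(100, seed, n_genes=300)
        m, _, _ = e.simulate_dataset(cfg)
        logm = e.log_transform(m)
        genes = logm.gene_ids[:200]
        tom = tom_similarity(adjacency(logm, genes=genes))
        assignment = detect_modules(1.0 - tom, min_size=50)
        assert set(assignment.values()) == {0}

    def test_min_size_one_on_two_pairs(self):
        x = np.arange(30, dtype=float)
        rng = np.random.default_rng(0)
        y = rng.normal(size=30)
        m = _matrix(np.vstack([x, x + rng.normal(0, 0.01, 30),
                               y, y + rng.normal(0, 0.01, 30)]))
        tom = tom_similarity(adjacency(m))
        assignment = detect_modules(1.0 - tom, min_size=1)
        assert len({v for v in assignment.values() if v != 0}) == 2

    def test_too_few_genes_all_unassigned(self):
        m = _matrix(np.random.default_rng(0).normal(size=(5, 20)))
        tom = tom_similarity(adjacency(m))
        with pytest.warns(UserWarning, match="unassigned"):
            assignment = detect_modules(1.0 - tom, min_size=50)
        assert set(assignment.values()) == {0}


class TestEigengene:
    def test_identical_genes_give_shared_profile(self):
        x = np.arange(20, dtype=float)
        m = _matrix(np.vstack([x, x, x]))
        eg = module_eigengene(m, m.gene_ids)
        z = (x - x.mean()) / x.std(ddof=1)
        cor = np.corrcoef(eg, z)[0, 1]
        assert abs(cor) == pytest.approx(1.0)
        assert np.linalg.norm(eg) == pytest.approx(1.0)

    def test_orientation_positive_mean_member_correlation(self):
        rng = np.random.default_rng(0)
        base = rng.normal(size=50)
        x = np.vstack([base + rng.normal(0, 0.1, 50) for _ in range(5)])
        m = _matrix(x)
        eg = module_eigengene(m, m.gene_ids)
        m2 = _matrix(-x)
        eg2 = module_eigengene(m2, m2.gene_ids)
        for mat, vec in ((m, eg), (m2, eg2)):
            cors = [np.corrcoef(vec, row)[0, 1] for row in mat.values]
            assert np.mean(cors) > 0

    def test_recovers_planted_latent_factor(self, module_sim):
        cfg, logm, ann, truth = module_sim
        b0 = [g for g, r in truth.roles.items()
              if r.get("role") == "module" and r["module"] == 0]
        eg = module_eigengene(logm, b0)
        cor = abs(np.corrcoef(eg, truth.module_factors[0])[0, 1])
        assert cor >= 0.95

    def test_constant_members_rejected(self):
        m = _matrix(np.ones((3, 10)))
        with pytest.raises(ValidationError):
            module_eigengene(m, m.gene_ids)


class TestMergeModules:
    def test_artificially_split_block_merges(self, module_sim):
        cfg, logm, ann, truth = module_sim
        b0 = sorted(g for g, r in truth.roles.items()
                    if r.get("role") == "module" and r["module"] == 0)
        b1 = sorted(g for g, r in truth.roles.items()
                    if r.get("role") == "module" and r["module"] == 1)
        assignment = {g: 1 for g in b0[:30]}
        assignment.update({g: 2 for g in b0[30:]})   # two halves of one block
        assignment.update({g: 3 for g in b1})
        gms = merge_modules(logm, assignment, threshold=0.35)
        assert len(gms.module_ids) == 2
        merged = {gms.assignment[g] for g in b0}
        assert len(merged) == 1

    def test_orthogonal_blocks_do_not_merge(self, module_sim):
        cfg, logm, ann, truth = module_sim
        assignment = {g: r["module"] + 1 for g, r in truth.roles.items()
                      if r.get("role") == "module"}
        gms = merge_modules(logm, assignment, threshold=0.35)
        assert len(gms.module_ids) == 3

    def test_zero_threshold_is_identity_and_idempotent(self, module_sim):
        cfg, logm, ann, truth = module_sim
        assignment = {g: r["module"] + 1 for g, r in truth.roles.items()
                      if r.get("role") == "module"}
        gms = merge_modules(logm, assignment, threshold=0.0)
        assert len(gms.module_ids) == 3
        again = merge_modules(logm, gms.assignment, threshold=0.35)
        assert len(again.module_ids) <= len(gms.module_ids)
        third = merge_modules(logm, again.assignment, threshold=0.35)
        assert third.assignment == again.assignment


class TestHubs:
    def test_small_module_returns_all_and_h_zero_empty(self, module_sim):
        cfg, logm, ann, truth = module_sim
        genes = truth.genes_with_role("module")
        gms = build_modules(logm, genes=genes, min_size=50)
        tiny = hub_genes(gms, h=3)
        for mod, hubs in tiny.items():
            assert len(hubs) == 3
        assert all(not v for v in hub_genes(gms, h=0).values())
        full = hub_genes(gms, h=500)
        for mod in gms.module_ids:
            assert len(full[mod]) == len(gms.members(mod))

    @pytest.mark.parametrize("seed", range(5))
    def test_boosted_hub_ranks_first(self, seed):
        cfg = e.plant_module_blocks(e.module_config(200, seed, n_genes=400),
                                    [60], 0.8, boost_first=2.0)
        m, _, truth = e.simulate_dataset(cfg)
        logm = e.log_transform(m)
        members = truth.genes_with_role("module")
        background = truth.genes_with_role("background")[:100]
        gms = build_modules(logm, genes=members + background, min_size=50)
        planted_hub = cfg.module_blocks[0][0][0]
        assert gms.module_ids == [1]
        assert gms.hubs[1][0] == planted_hub

    def test_eigengene_correlation_separates_lineage_groups(self, late_sim):
        """Module eigengenes cluster cells by planted lineage."""
        cfg, m, ann, truth = late_sim
        logm = e.log_transform(m)
        panel = cfg.marker_panel
        modules = {1: panel.genes_for("EPI"), 2: panel.genes_for("PrE"),
                   3: panel.genes_for("TE")}
        eigs = {k: module_eigengene(logm, v) for k, v in modules.items()}
        # each lineage's cells score highest on its own module eigengene
        for mod, lin in ((1, "EPI"), (2, "PrE"), (3, "TE")):
            cells = [i for i, c in enumerate(logm.cell_ids) if truth.labels[c] == lin]
            others = [i for i, c in enumerate(logm.cell_ids)
                      if truth.labels[c] in ("EPI", "PrE", "TE") and truth.labels[c] != lin]
            assert eigs[mod][cells].mean() > eigs[mod][others].mean()
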