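import numpy as np
import pandas as pd
import pytest

from plastevo import coexpression
from plastevo.coexpression import (
    StageAssociation,
    detect_modules,
    gene_significance,
    hub_genes,
    merge_and_associate,
    module_eigengene,
)

from conftest import make_matrix


def _codes(matrix):
    return matrix.design["stage"].map(
        {"ancestral": 0.0, "plastic": 1.0, "colonized": 2.0}
    ).to_numpy()


class TestGeneSignificance:
    def test_expression_equal_to_stage_code(self):
        m = make_matrix(np.array([[0.0, 0, 1, 1, 2, 2]]))
        gs = gene_significance(m)
        assert gs.loc["g0", "GS"] == pytest.approx(1.0)

    def test_constant_gene_zero_gs(self):
        m = make_matrix(np.full((1, 6), 3.0))
        gs = gene_significance(m)
        assert gs.loc["g0", "GS"] == 0.0
        assert gs.loc["g0", "p"] == 1.0

    def test_monotone_profile_perfect_gs(self):
        m = make_matrix(np.array([[1.0, 1, 2, 2, 3, 3]]))
        gs = gene_significance(m)
        assert gs.loc["g0", "GS"] == pytest.approx(1.0)
        assert gs.loc["g0", "p"] < 0.001

    def test_needs_three_samples(self):
        m = make_matrix(np.ones((2, 6)))
        sub = coexpression.ExpressionMatrix(
            m.values.iloc[:, :2], m.design.iloc[:2]
        )
        with pytest.raises(ValueError):
            gene_significance(sub)


def _planted_modules(rng, n_modules=3, genes_per_module=15, n_samples=12, noise=0.15):
    profiles = rng.standard_normal((n_modules, n_samples))
    rows, labels = [], []
    for k in range(n_modules):
        for _ in range(genes_per_module):
            rows.append(profiles[k] + noise * rng.standard_normal(n_samples))
            labels.append(k)
    return np.array(rows), np.array(labels)


class TestDetectModules:
    def test_two_perfect_blocks(self):
        base = np.array([1.0, 2, 3, 4, 5, 6])
        other = np.array([2.0, 1, 2, 1, 2, 1])  # near-zero correlation with base
        values = np.vstack([np.outer([1, 2, 3], base), np.outer([1, 2, 3], other)])
        m = make_matrix(values)
        modules = detect_modules(m, beta=2, min_size=3, cut_height=0.5)
        assert len(modules.modules) == 2
        assert set(modules.sizes()) == {3}

    def test_uncorrelated_genes_unassigned(self):
        rng = np.random.default_rng(5)
        m = make_matrix(np.exp(rng.standard_normal((40, 6))))
        modules = detect_modules(m, beta=6, min_size=5, cut_height=0.25)
        assert len(modules.modules) == 0
        assert (modules.labels == "unassigned").all()

    def test_planted_three_modules_recovered(self):
        from sklearn.metrics import adjusted_rand_score

        rng = np.random.default_rng(11)
        values, truth = _planted_modules(rng)
        m = make_matrix(np.exp(values), per_stage=4)
        modules = detect_modules(m, beta=2, min_size=5, cut_height=0.5)
        pred = pd.factorize(modules.labels)[0]
        assert adjusted_rand_score(truth, pred) >= 0.9

    def test_rejects_nonpositive_beta(self):
        m = make_matrix(np.exp(np.random.default_rng(0).standard_normal((10, 6))))
        with pytest.raises(ValueError):
            detect_modules(m, beta=0, min_size=2)


class TestModuleEigengene:
    def test_shared_profile_recovered(self):
        profile = np.array([1.0, 3, 2, 5, 4, 6])
        m = make_matrix(np.outer([1, 2, 5], profile))
        eig = module_eigengene(m, m.genes)
        z = (profile - profile.mean()) / profile.std(ddof=1)
        assert abs(np.corrcoef(eig, z)[0, 1]) == pytest.approx(1.0)
        assert np.corrcoef(eig, z)[0, 1] > 0  # sign convention

    def test_sign_fix_invariant_to_global_negation(self):
        rng = np.random.default_rng(2)
        values = np.exp(rng.standard_normal((4, 6)))
        m = make_matrix(values)
        eig = module_eigengene(m, m.genes)
        z = (values - values.mean(axis=1, keepdims=True)) / values.std(axis=1, ddof=1, keepdims=True)
        assert float(eig @ z.mean(axis=0)) >= 0

    def test_two_gene_closed_form(self):
        # for two positively correlated z-profiles the first PC is z1 + z2
        rng = np.random.default_rng(3)
        x = rng.standard_normal(6)
        y = x + 0.3 * rng.standard_normal(6)
        m = make_matrix(np.vstack([x - x.min() + 1, y - y.min() + 1]))
        eig = module_eigengene(m, m.genes)
        z = m.values.sub(m.values.mean(axis=1), axis=0).div(m.values.std(axis=1, ddof=1), axis=0)
        expected = (z.iloc[0] + z.iloc[1]).to_numpy()
        r = np.corrcoef(eig, expected)[0, 1]
        assert abs(r) == pytest.approx(1.0, abs=1e-10)

    def test_requires_two_genes(self):
        m = make_matrix(np.ones((2, 6)))
        with pytest.raises(ValueError):
            module_eigengene(m, m.genes[:1])


class TestMergeAndAssociate:
    def test_identical_modules_merged(self):
        profile = np.array([1.0, 2, 1.5, 3, 2.5, 4])
        rng = np.random.default_rng(4)
        values = np.vstack(
            [profile * s + 0.01 * rng.standard_normal(6) for s in (1, 2, 3, 4, 5, 6)]
        )
        m = make_matrix(values)
        labels = pd.Series(["A"] * 3 + ["B"] * 3, index=m.genes)
        modules = coexpression.ModuleAssignment(labels=labels, min_size=2)
        assoc = merge_and_associate(m, modules, merge_p=0.1)
        assert len(assoc.modules.modules) == 1

    def test_stage_tracking_eigengene_is_associated(self):
        codes = np.array([0.0, 0, 1, 1, 2, 2])
        rng = np.random.default_rng(6)
        values = np.vstack([codes + 0.01 * rng.standard_normal(6) for _ in range(4)])
        m = make_matrix(values + 1.0)
        labels = pd.Series(["A"] * 4, index=m.genes)
        modules = coexpression.ModuleAssignment(labels=labels, min_size=2)
        assoc = merge_and_associate(m, modules, assoc_p=0.01)
        assert assoc.associated == ["M1"]

    def test_planted_associated_module_reported(self):
        # 1 stage-tracking + 2 independent null modules, many replicates
        rng = np.random.default_rng(8)
        hits = 0
        n_rep = 50
        codes = np.repeat([0.0, 1.0, 2.0], 4)
        for _ in range(n_rep):
            blocks = []
            signal = codes + 0.2 * rng.standard_normal(12)
            blocks.append(np.vstack([signal + 0.1 * rng.standard_normal(12) for _ in range(8)]))
            for _k in range(2):
                null_profile = rng.standard_normal(12)
                blocks.append(
                    np.vstack([null_profile + 0.1 * rng.standard_normal(12) for _ in range(8)])
                )
            m = make_matrix(np.exp(np.vstack(blocks) * 0.3), per_stage=4)
            labels = pd.Series(
                ["A"] * 8 + ["B"] * 8 + ["C"] * 8, index=m.genes
            )
            modules = coexpression.ModuleAssignment(labels=labels, min_size=2)
            assoc = merge_and_associate(m, modules, merge_p=0.001, assoc_p=0.01)
            reported = set(assoc.associated)
            planted = assoc.modules.labels[m.genes[0]]
            if reported == {planted}:
                hits += 1
        assert hits / n_rep >= 0.95


class TestHubGenes:
    def _assoc(self, matrix, labels, associated):
        modules = coexpression.ModuleAssignment(
            labels=pd.Series(labels, index=matrix.genes), min_size=1
        )
        stats = pd.DataFrame(
            {"r": 1.0, "p": 0.0, "associated": [m in associated for m in modules.modules]},
            index=pd.Index(modules.modules, name="module"),
        )
        return StageAssociation(modules=modules, eigengenes=pd.DataFrame(), stats=stats)

    def test_hand_quartile_example(self):
        m = make_matrix(np.ones((4, 6)))
        gs = pd.DataFrame({"GS": [0.1, 0.2, 0.3, 0.4], "p": [0.01] * 4}, index=m.genes)
        assoc = self._assoc(m, ["M1"] * 4, {"M1"})
        hubs = hub_genes(gs, assoc)
        # Q1 (linear interpolation) = 0.175 -> strict inequality keeps 0.2, 0.3, 0.4
        assert set(hubs) == {"g1", "g2", "g3"}

    def test_all_tied_gs_gives_empty_set(self):
        m = make_matrix(np.ones((4, 6)))
        gs = pd.DataFrame({"GS": [0.3] * 4, "p": [0.01] * 4}, index=m.genes)
        assert len(hub_genes(gs, self._assoc(m, ["M1"] * 4, {"M1"}))) == 0

    def test_insignificant_correlation_excluded(self):
        m = make_matrix(np.ones((4, 6)))
        gs = pd.DataFrame(
            {"GS": [0.1, 0.2, 0.3, 0.9], "p": [0.01, 0.01, 0.01, 0.2]}, index=m.genes
        )
        hubs = hub_genes(gs, self._assoc(m, ["M1"] * 4, {"M1"}))
        assert "g3" not in hubs

    def test_hubs_subset_of_associated_modules(self):
        rng = np.random.default_rng(9)
        m = make_matrix(np.exp(rng.standard_normal((10, 6))))
        gs = pd.DataFrame(
            {"GS": rng.uniform(0, 1, 10), "p": rng.uniform(0, 0.04, 10)}, index=m.genes
        )
        assoc = self._assoc(m, ["M1"] * 5 + ["M2"] * 5, {"M1"})
        hubs = hub_genes(gs, assoc)
        assert set(hubs) <= set(m.genes[:5])
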