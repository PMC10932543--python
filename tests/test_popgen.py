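import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from plastevo import popgen, synthetic
from plastevo.popgen import (
    GeneAnnotation,
    GenotypeData,
    PopgenError,
    assign_regions,
    fst_permutation_test,
    mean_fst,
    read_annotation_bed,
    read_pop_map,
    read_variants,
    site_components,
    wc_fst_site,
)


class TestWcFstSite:
    def test_fixed_difference_theta_one(self):
        a, b, c, theta = wc_fst_site(1.0, 0.0, 10, 0.0, 0.0, 10)
        assert a == pytest.approx(0.5, abs=1e-12)
        assert b == pytest.approx(0.0, abs=1e-12)
        assert c == pytest.approx(0.0, abs=1e-12)
        assert theta == pytest.approx(1.0, abs=1e-12)

    def test_no_divergence_negative_theta(self):
        # identical frequencies: the unbiased estimator goes slightly negative
        *_, theta = wc_fst_site(0.5, 0.5, 10, 0.5, 0.5, 10)
        assert theta == pytest.approx(-1.0 / 18.0, abs=1e-12)

    def test_pooled_monomorphic_undefined(self):
        a, b, c, theta = wc_fst_site(0.0, 0.0, 10, 0.0, 0.0, 10)
        assert np.isnan(theta)

    @given(
        p1=st.floats(0.05, 0.95),
        p2=st.floats(0.05, 0.95),
        h1=st.floats(0, 0.5),
        h2=st.floats(0, 0.5),
        n1=st.integers(2, 40),
        n2=st.integers(2, 40),
    )
    @settings(derandomize=True, max_examples=100)
    def test_allele_label_swap_invariance(self, p1, p2, h1, h2, n1, n2):
        *_, t1 = wc_fst_site(p1, h1, n1, p2, h2, n2)
        *_, t2 = wc_fst_site(1 - p1, h1, n1, 1 - p2, h2, n2)
        assert t1 == pytest.approx(t2, rel=1e-9, abs=1e-12)
        assert t1 <= 1.0 + 1e-12


class TestMeanFst:
    def test_single_site_equals_theta(self):
        a, b, c, theta = wc_fst_site(0.9, 0.1, 12, 0.2, 0.3, 11)
        assert mean_fst([a], [b], [c]) == pytest.approx(theta)

    def test_weighted_ratio_of_sums(self):
        # sites with (a, a+b+c) = (0.5, 0.5) and (0, 0.25)
        assert mean_fst([0.5, 0.0], [0.0, 0.1], [0.0, 0.15]) == pytest.approx(2 / 3)

    def test_all_fixed_differences_mean_one(self):
        a = np.full(5, 0.5)
        z = np.zeros(5)
        assert mean_fst(a, z, z) == pytest.approx(1.0)

    def test_no_defined_sites_errors(self):
        with pytest.raises(PopgenError):
            mean_fst([np.nan], [np.nan], [np.nan])


def _genotype_data(pos, genotypes, pops=("lowland", "highland"), chrom="chr1"):
    genotypes = np.asarray(genotypes, dtype=np.int8)
    n_ind = genotypes.shape[1]
    half = n_ind // 2
    return GenotypeData(
        chrom=np.repeat(chrom, len(pos)),
        pos=np.asarray(pos, dtype=np.int64),
        ref=np.repeat("A", len(pos)),
        alt=np.repeat("G", len(pos)),
        genotypes=genotypes,
        samples=[f"s{i}" for i in range(n_ind)],
        populations=np.array([pops[0]] * half + [pops[1]] * (n_ind - half)),
    )


class TestAssignRegions:
    def _annotation(self, strand="+"):
        return GeneAnnotation(
            genes=pd.DataFrame(
                {"gene": ["gA"], "chrom": ["chr1"], "start": [1000], "end": [2000], "strand": [strand]}
            )
        )

    def test_genic_and_flank_intervals_plus_strand(self):
        g = _genotype_data([1500, 999, 2500], np.zeros((3, 4)))
        mapping = assign_regions(self._annotation("+"), g)
        by_snp = mapping.set_index("snp_index")["region"]
        assert by_snp[0] == "genic"  # 1-based 1500 -> 0-based 1499 in [1000,2000)
        assert by_snp[1] == "upstream"  # 0-based 998, just left of the gene body
        assert by_snp[2] == "downstream"

    def test_minus_strand_mirrors_flanks(self):
        g = _genotype_data([2500, 999], np.zeros((2, 4)))
        mapping = assign_regions(self._annotation("-"), g)
        by_snp = mapping.set_index("snp_index")["region"]
        assert by_snp[0] == "upstream"  # [2000, 4000) is 5' of a minus-strand gene
        assert by_snp[1] == "downstream"

    def test_upstream_truncated_at_zero(self):
        ann = self._annotation("+")
        regions = ann.regions()
        up = regions[regions["region"] == "upstream"].iloc[0]
        assert up["start"] == 0 and up["end"] == 1000

    def test_snp_outside_all_regions_unmapped(self):
        g = _genotype_data([9000], np.zeros((1, 4)))
        assert len(assign_regions(self._annotation(), g)) == 0


class TestReadVariants:
    @pytest.fixture()
    def vcf_inputs(self, tmp_path):
        cfg = synthetic.SyntheticConfig(seed=4, n_genes=40, n_snps=400)
        _, truth = synthetic.generate_expression(cfg)
        genotypes, annotation = synthetic.generate_genotypes(truth, cfg)
        vcf = tmp_path / "v.vcf"
        popmap = tmp_path / "pops.tsv"
        bed = tmp_path / "genes.bed"
        synthetic.write_vcf(genotypes, vcf)
        synthetic.write_pop_map(genotypes, popmap)
        synthetic.write_bed(annotation, bed)
        return genotypes, vcf, popmap, bed

    def test_round_trip_preserves_genotypes(self, vcf_inputs):
        genotypes, vcf, popmap, _ = vcf_inputs
        loaded = read_variants(vcf, read_pop_map(popmap), min_spacing=1)
        assert loaded.n_snps == genotypes.n_snps
        assert (loaded.genotypes == genotypes.genotypes).all()
        assert (loaded.pos == genotypes.pos).all()

    def test_spacing_filter_keeps_first_of_close_pair(self, tmp_path, vcf_inputs):
        genotypes, *_ = vcf_inputs
        g = _genotype_data([100, 103, 200], np.zeros((3, 4)))
        vcf = tmp_path / "close.vcf"
        synthetic.write_vcf(g, vcf)
        pop_map = {s: p for s, p in zip(g.samples, g.populations)}
        # genotypes all hom-ref would leave nothing polymorphic; fill one alt
        g.genotypes[:, 0] = 1
        synthetic.write_vcf(g, vcf)
        loaded = read_variants(vcf, pop_map, min_spacing=5)
        assert list(loaded.pos) == [100, 200]
        assert loaded.filter_log["spacing"] == 1

    def test_bed_round_trip(self, vcf_inputs):
        *_, bed = vcf_inputs
        ann = read_annotation_bed(bed)
        assert {"gene", "chrom", "start", "end", "strand"} <= set(ann.genes.columns)
        assert (ann.genes["end"] - ann.genes["start"] == 3000).all()

    def test_unknown_pop_map_sample_errors(self, vcf_inputs):
        _, vcf, popmap, _ = vcf_inputs
        pm = read_pop_map(popmap)
        pm["ghost"] = "lowland"
        with pytest.raises(PopgenError, match="ghost"):
            read_variants(vcf, pm)


class TestSiteComponents:
    def test_matches_scalar_formula_with_missing_data(self):
        rng = np.random.default_rng(1)
        G = rng.integers(0, 3, size=(50, 20)).astype(np.int8)
        G[rng.random(G.shape) < 0.1] = -1
        g = _genotype_data(np.arange(50) * 10 + 1, G)
        a, b, c, theta = site_components(g)
        # recompute one site by hand
        i = 7
        stats = []
        for cols in (range(10), range(10, 20)):
            vals = [G[i, j] for j in cols if G[i, j] >= 0]
            n = len(vals)
            stats.append((sum(vals) / (2 * n), sum(v == 1 for v in vals) / n, n))
        (p1, h1, n1), (p2, h2, n2) = stats
        exp_a, exp_b, exp_c, exp_t = wc_fst_site(p1, h1, n1, p2, h2, n2)
        if np.isnan(exp_t):
            assert np.isnan(theta[i])
        else:
            assert theta[i] == pytest.approx(exp_t, abs=1e-12)


class TestPermutationTest:
    def test_candidate_equals_background_p_one(self):
        rng = np.random.default_rng(2)
        n = 50
        a = rng.uniform(0, 0.2, n)
        b = rng.uniform(0, 0.1, n)
        c = rng.uniform(0, 0.1, n)
        idx = np.arange(n)
        res = fst_permutation_test(
            a, b, c, idx, idx, n_perm=20, fluctuation=0.0, seed=0, exclude_candidates=False
        )
        assert res.p == pytest.approx(1.0)
        assert not res.significant

    def test_background_smaller_than_draw_errors(self):
        a = np.full(30, 0.1)
        z = np.zeros(30)
        with pytest.raises(PopgenError):
            fst_permutation_test(a, z, z, np.arange(20), np.arange(30), fluctuation=0.05)

    def test_elevated_candidates_detected(self):
        rng = np.random.default_rng(3)
        n_bg, n_cand = 1000, 100
        a = np.concatenate([rng.uniform(0, 0.05, n_bg), rng.uniform(0.3, 0.5, n_cand)])
        b = rng.uniform(0, 0.05, n_bg + n_cand)
        c = rng.uniform(0.1, 0.2, n_bg + n_cand)
        cand = np.arange(n_bg, n_bg + n_cand)
        res = fst_permutation_test(a, b, c, cand, np.arange(n_bg), seed=1)
        assert res.significant
        assert res.p == pytest.approx(1 / 101)


class TestBaldingNicholsCalibration:
    @pytest.mark.parametrize("F", [0.05, 0.2])
    def test_mean_fst_tracks_divergence_parameter(self, F):
        cfg = synthetic.SyntheticConfig(
            seed=10,
            n_genes=10,
            n_snps=10_000,
            frac_reinforcement=0.0,
            frac_reversion=0.0,
            regulator_fraction=0.0,
            fst_background=F,
            fst_candidate_flank=F,
            n_individuals_per_pop=(25, 25),
            gene_spacing=50_000,
        )
        _, truth = synthetic.generate_expression(cfg)
        genotypes, _ = synthetic.generate_genotypes(truth, cfg)
        a, b, c, _ = site_components(genotypes)
        assert mean_fst(a, b, c) == pytest.approx(F, abs=0.03)

    def test_near_fixation_limit(self):
        cfg = synthetic.SyntheticConfig(
            seed=11,
            n_genes=10,
            n_snps=3000,
            frac_reinforcement=0.0,
            frac_reversion=0.0,
            regulator_fraction=0.0,
            fst_background=0.99,
            fst_candidate_flank=0.99,
            gene_spacing=20_000,
        )
        _, truth = synthetic.generate_expression(cfg)
        genotypes, _ = synthetic.generate_genotypes(truth, cfg)
        a, b, c, _ = site_components(genotypes)
        assert mean_fst(a, b, c) > 0.9
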