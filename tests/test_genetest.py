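"""Gene-based simulation test and weighted-KS enrichment."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from snpset import (CohortConfig, PhenotypeVector, gene_table, gwas,
                    gsea_enrichment, make_annotation_fixture,
                    make_background_panel, make_candidate_panel,
                    map_snps_to_genes, meta_inverse_variance, simulate_cohort,
                    vegas_gene_p)
from snpset.candidates import CANDIDATE_GENES
from snpset.genetest import enrichment_score


class TestVegas:
    def test_single_snp_matches_chi2_tail(self):
        gs = vegas_gene_p([2.0], np.eye(1), n_sim=100000, seed=1)
        expected = stats.chi2.sf(4.0, 1)
        assert gs.p_gene == pytest.approx(expected, abs=3 * 0.00066)

    def test_perfect_ld_collapses_to_one_chi2(self):
        # two fully correlated SNPs carry one degree of freedom, not two
        gs = vegas_gene_p([2.0, 2.0], np.ones((2, 2)), n_sim=100000, seed=2)
        perfect = stats.chi2.sf(4.0, 1)      # P(2 Z^2 >= 8)
        independent = stats.chi2.sf(8.0, 2)
        assert gs.p_gene == pytest.approx(perfect, abs=3 * 0.00066)
        assert abs(gs.p_gene - independent) > 0.02

    def test_identity_ld_matches_chi2_k(self):
        k = 5
        z = np.full(k, 1.3)
        gs = vegas_gene_p(z, np.eye(k), n_sim=200000, seed=3)
        expected = stats.chi2.sf(float(z @ z), k)
        mc_se = np.sqrt(expected * (1 - expected) / 200000)
        assert gs.p_gene == pytest.approx(expected, abs=4 * mc_se)

    def test_null_z_gives_p_one(self):
        gs = vegas_gene_p([0.0, 0.0], np.eye(2), n_sim=2000, seed=4)
        assert gs.p_gene == 1.0

    def test_input_validation(self):
        with pytest.raises(ValueError):
            vegas_gene_p([1.0, 2.0], np.eye(3))
        with pytest.raises(ValueError):
            vegas_gene_p([np.inf], np.eye(1))

    def test_non_positive_definite_ld_repaired(self):
        ld = np.array([[1.0, 0.7, 0.7], [0.7, 1.0, -0.7], [0.7, -0.7, 1.0]])
        gs = vegas_gene_p([1.0, 1.0, 1.0], ld, n_sim=2000, seed=5)
        assert 0 < gs.p_gene <= 1


def ks_walk_oracle(membership, weights):
    """Literal step-by-step running sum, kept independent of the vectorised
    implementation."""
    m_w = sum(w for inside, w in zip(membership, weights) if inside)
    miss = sum(1 for inside in membership if not inside)
    best, cur = 0.0, 0.0
    for inside, w in zip(membership, weights):
        cur += w / m_w if inside else -1.0 / miss
        if abs(cur) > abs(best):
            best = cur
    return best


class TestEnrichmentScore:
    def test_hand_walk_example(self):
        es, walk = enrichment_score([True, False, True, False], np.ones(4))
        assert np.allclose(walk, [0.5, 0.0, 0.5, 0.0])
        assert es == 0.5

    def test_top_ranked_candidates_reach_maximal_score(self):
        membership = [True] * 3 + [False] * 7
        es, _ = enrichment_score(membership, np.ones(10))
        assert es == pytest.approx(1.0)

    @pytest.mark.parametrize("seed", range(6))
    def test_unit_weight_score_matches_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 21))
        m = int(rng.integers(1, n))
        membership = np.zeros(n, dtype=bool)
        membership[rng.choice(n, m, replace=False)] = True
        es, _ = enrichment_score(membership, np.ones(n))
        assert es == pytest.approx(ks_walk_oracle(membership, np.ones(n)),
                                   abs=1e-12)

    def test_weighted_score_matches_brute_force(self):
        rng = np.random.default_rng(9)
        membership = np.array([True, False, False, True, True, False, False])
        w = rng.uniform(0.1, 3.0, size=7)
        es, _ = enrichment_score(membership, w)
        assert es == pytest.approx(ks_walk_oracle(membership, w), abs=1e-12)


class TestGseaEnrichment:
    @staticmethod
    def _gene_p(n, seed):
        rng = np.random.default_rng(seed)
        return pd.DataFrame({"gene": [f"G{i:03d}" for i in range(n)],
                             "p_gene": rng.uniform(size=n)})

    def test_deterministic_and_bounded(self):
        gp = self._gene_p(60, 1)
        cand = gp["gene"].tolist()[:8]
        a = gsea_enrichment(gp, cand, n_perm=500, seed=7)
        b = gsea_enrichment(gp, cand, n_perm=500, seed=7)
        assert (a.ES_obs, a.p_enrich) == (b.ES_obs, b.p_enrich)
        assert abs(a.ES_obs) <= 1.0
        assert 1 / 501 <= a.p_enrich <= 1.0

    def test_enriched_set_detected(self):
        gp = self._gene_p(200, 2)
        gp.loc[:9, "p_gene"] = gp.loc[:9, "p_gene"] / 500.0
        cand = gp["gene"].tolist()[:10]
        res = gsea_enrichment(gp, cand, n_perm=1000, seed=8)
        assert res.p_enrich < 0.01

    def test_null_p_approximately_uniform(self):
        gp = self._gene_p(80, 3)
        rng = np.random.default_rng(4)
        ps = []
        for rep in range(200):
            cand = list(rng.choice(gp["gene"], size=10, replace=False))
            ps.append(gsea_enrichment(gp, cand, n_perm=200,
                                      seed=int(rng.integers(2**31))).p_enrich)
        assert stats.kstest(ps, "uniform").pvalue > 0.01

    def test_invariant_to_noncandidate_relabelling(self):
        gp = self._gene_p(50, 5)
        cand = gp["gene"].tolist()[:6]
        renamed = gp.copy()
        renamed["gene"] = [
            g if g in cand else f"X{g}" for g in renamed["gene"]]
        a = gsea_enrichment(gp, cand, n_perm=300, seed=6)
        b = gsea_enrichment(renamed, cand, n_perm=300, seed=6)
        assert a.ES_obs == pytest.approx(b.ES_obs, abs=1e-12)
        assert a.p_enrich == b.p_enrich

    def test_improper_sets_rejected(self):
        gp = self._gene_p(10, 6)
        with pytest.raises(ValueError):
            gsea_enrichment(gp, [], n_perm=10)
        with pytest.raises(ValueError):
            gsea_enrichment(gp, gp["gene"].tolist(), n_perm=10)
        with pytest.raises(ValueError):
            gsea_enrichment(gp, ["NOSUCH"], n_perm=10)


@pytest.fixture(scope="module")
def pipeline_bits():
    ann, _ = make_annotation_fixture(40, seed=12)
    panel = make_candidate_panel(120, seed=12) + \
        make_background_panel(ann, mean_snps_per_gene=4, seed=12)
    cohorts = [
        simulate_cohort(CohortConfig(name=f"c{i}", n_individuals=150,
                                     panel=panel, seed=50 + i))
        for i in range(2)
    ]
    rng = np.random.default_rng(13)
    tabs = []
    for c in cohorts:
        y = PhenotypeVector(c.genotypes.individual_ids,
                            rng.standard_normal(c.n_individuals), "null")
        tabs.append(gwas(c, y))
    meta = meta_inverse_variance(tabs)
    wide = map_snps_to_genes(panel, ann, symmetric_flank=50000)
    from snpset.pipeline import _pool_genotypes
    pooled = _pool_genotypes([c.genotypes for c in cohorts])
    return meta, wide, pooled


class TestGeneTable:
    def test_candidate_roster_present(self, pipeline_bits):
        meta, wide, pooled = pipeline_bits
        genes = gene_table(meta, wide, pooled, n_sim=500, seed=14)
        present = set(genes["gene"])
        assert set(CANDIDATE_GENES) <= present
        assert (genes["p_gene"] >= 1 / 501).all()

    def test_null_gene_pvalues_calibrated(self, pipeline_bits):
        meta, wide, pooled = pipeline_bits
        genes = gene_table(meta, wide, pooled, n_sim=500, seed=15)
        frac = (genes["p_gene"] < 0.05).mean()
        n = len(genes)
        assert abs(frac - 0.05) < 2.576 * np.sqrt(0.05 * 0.95 / n) + 0.01

    def test_monte_carlo_stability_when_doubling_sims(self, pipeline_bits):
        meta, wide, pooled = pipeline_bits
        g1 = gene_table(meta, wide, pooled, n_sim=1000, seed=16)
        g2 = gene_table(meta, wide, pooled, n_sim=2000, seed=17)
        joined = g1.merge(g2, on="gene", suffixes=("_1", "_2"))
        p = joined[["p_gene_1", "p_gene_2"]].mean(axis=1)
        se = np.sqrt(p * (1 - p) / 1000) + np.sqrt(p * (1 - p) / 2000)
        assert (np.abs(joined["p_gene_1"] - joined["p_gene_2"])
                <= 3 * se + 1e-9).mean() > 0.95
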