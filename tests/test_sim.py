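"""Synthetic genotype/cohort generator: distributional and structural checks."""

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy import stats

from snpset import (CohortConfig, SnpSpec, make_annotation_fixture,
                    make_background_panel, make_candidate_panel,
                    simulate_cohort, simulate_genotypes)
from snpset.candidates import CANDIDATE_GENES, GENE_TEMPLATE
from snpset.pheno import hwe_exact_test


def _snp(i, maf=0.25, gene=None, pos=None):
    return SnpSpec(f"s{i}", "1", pos or i + 1, maf=maf, gene=gene)


class TestSimulateGenotypes:
    def test_dosages_in_range_and_deterministic(self):
        g = simulate_genotypes(4, [_snp(0, maf=0.5)], seed=1)
        assert g.dosages.shape == (4, 1)
        assert set(np.unique(g.dosages)) <= {0.0, 1.0, 2.0}
        g2 = simulate_genotypes(4, [_snp(0, maf=0.5)], seed=1)
        assert np.array_equal(g.dosages, g2.dosages)

    def test_allele_frequency_recovered_without_ld(self):
        panel = [_snp(i, maf=0.2) for i in range(20)]
        g = simulate_genotypes(10000, panel, ld_rho=0.0, seed=2)
        freqs = g.dosages.mean(axis=0) / 2
        assert np.all(np.abs(freqs - 0.2) < 0.015)

    def test_hardy_weinberg_holds_without_ld(self):
        # exact-test p should exceed 0.001 for essentially every SNP
        panel = [_snp(i, maf=0.1 + 0.3 * (i % 7) / 7) for i in range(200)]
        g = simulate_genotypes(2000, panel, ld_rho=0.0, seed=3)
        ps = []
        for j in range(g.n_snps):
            col = g.dosages[:, j]
            ps.append(hwe_exact_test(int((col == 0).sum()),
                                     int((col == 1).sum()),
                                     int((col == 2).sum())))
        assert np.mean(np.asarray(ps) > 0.001) >= 0.985

    def test_ld_induces_dosage_correlation(self):
        panel = [_snp(0, gene="g"), _snp(1, gene="g")]
        g = simulate_genotypes(10000, panel, ld_rho=0.9, seed=4)
        r = np.corrcoef(g.dosages.T)[0, 1]
        assert r > 0.5

    def test_ld_does_not_leak_across_blocks(self):
        panel = [_snp(0, gene="a"), _snp(1, gene="b")]
        g = simulate_genotypes(20000, panel, ld_rho=0.9, seed=5)
        assert abs(np.corrcoef(g.dosages.T)[0, 1]) < 0.03

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            simulate_genotypes(0, [_snp(0)])
        with pytest.raises(ValueError):
            SnpSpec("bad", "1", 10, maf=0.7)
        with pytest.raises(ValueError):
            SnpSpec("bad", "1", 0, maf=0.2)

    @given(st.integers(1, 40), st.floats(0.01, 0.5), st.floats(0.0, 0.95),
           st.integers(0, 10_000))
    def test_entries_always_valid(self, n, maf, rho, seed):
        panel = [_snp(i, maf=maf, gene="g") for i in range(3)]
        g = simulate_genotypes(n, panel, ld_rho=rho, seed=seed,
                               missing_rate=0.1)
        ok = np.isnan(g.dosages) | np.isin(g.dosages, (0.0, 1.0, 2.0))
        assert ok.all()


class TestSimulateCohort:
    def test_high_loadings_track_latent_ability(self, small_panel):
        c = simulate_cohort(CohortConfig(
            name="hi", n_individuals=500, panel=small_panel,
            loadings=(0.99,) * 4, seed=6))
        for col in ("test1", "test2", "test3", "test4"):
            r = np.corrcoef(c.battery[col], c.latent_g)[0, 1]
            assert r > 0.9

    def test_no_structure_means_no_genotype_subpop_correlation(self, small_panel):
        c = simulate_cohort(CohortConfig(
            name="flat", n_individuals=5000, panel=small_panel,
            structure_shift=0.0, seed=7))
        mean_dose = np.nanmean(c.genotypes.dosages, axis=1)
        r = np.corrcoef(mean_dose, c.covariates["subpop"])[0, 1]
        assert abs(r) < 0.05

    def test_structure_shift_raises_subpop_allele_frequency(self, small_panel):
        c = simulate_cohort(CohortConfig(
            name="strat", n_individuals=4000, panel=small_panel,
            structure_shift=0.1, seed=8))
        sp = c.covariates["subpop"].to_numpy()
        f0 = c.genotypes.dosages[sp == 0].mean()
        f1 = c.genotypes.dosages[sp == 1].mean()
        assert f1 - f0 > 0.1

    def test_seed_reproducibility_is_bitwise(self, small_panel):
        cfg = CohortConfig(name="det", n_individuals=200, panel=small_panel,
                           seed=9)
        a, b = simulate_cohort(cfg), simulate_cohort(cfg)
        assert np.array_equal(a.genotypes.dosages, b.genotypes.dosages)
        assert a.covariates.equals(b.covariates)
        assert a.battery.equals(b.battery)
        assert np.array_equal(a.latent_g, b.latent_g)

    def test_rejects_out_of_range_loadings(self, small_panel):
        with pytest.raises(ValueError):
            CohortConfig(name="bad", n_individuals=10, panel=small_panel,
                         loadings=(1.2, 0.5, 0.5, 0.5))


class TestFixture:
    def test_candidate_set_has_27_genes(self):
        annotation, candidates = make_annotation_fixture(0, seed=1)
        assert len(candidates) == 27
        assert len(annotation) == 27
        assert candidates == CANDIDATE_GENES

    def test_template_counts_match_published_panel(self):
        counts = {g: n for g, _, n, _, _, _ in GENE_TEMPLATE}
        assert counts["GNAZ"] == 138
        assert counts["GNAQ"] == 271
        starts = {g: s for g, _, _, s, _, _ in GENE_TEMPLATE}
        assert starts["GNA11"] == 3045407

    def test_candidate_panel_totals_470_snps(self, candidate_panel):
        assert len(candidate_panel) == 470
        genes = {s.gene for s in candidate_panel}
        assert genes == set(CANDIDATE_GENES)
        mafs = np.array([s.maf for s in candidate_panel])
        assert mafs.min() >= 0.05 and mafs.max() <= 0.45

    def test_background_genes_do_not_overlap(self):
        annotation, _ = make_annotation_fixture(100, seed=2)
        bg = annotation.records[
            annotation.records["gene"].str.startswith("BGENE")]
        for _, sub in bg.groupby("chrom"):
            sub = sub.sort_values("start")
            gaps = sub["start"].to_numpy()[1:] - sub["stop"].to_numpy()[:-1]
            assert (gaps > 100_000).all()

    def test_background_panel_covers_every_background_gene(self):
        annotation, _ = make_annotation_fixture(30, seed=3)
        panel = make_background_panel(annotation, seed=3)
        covered = {s.gene for s in panel}
        assert covered == {f"BGENE{i:04d}" for i in range(30)}


def test_hwe_chisq_like_behaviour_at_equilibrium():
    # equilibrium counts give high p, gross excess homozygosity gives low p
    assert hwe_exact_test(25, 50, 25) > 0.5
    assert hwe_exact_test(90, 0, 10) < 1e-6
    # agrees with scipy's chi-square in the large-count regime
    n_aa, n_ab, n_bb = 500, 390, 110
    n = n_aa + n_ab + n_bb
    q = (2 * n_bb + n_ab) / (2 * n)
    exp = np.array([n * (1 - q) ** 2, 2 * n * q * (1 - q), n * q**2])
    chi2 = (((np.array([n_aa, n_ab, n_bb]) - exp) ** 2) / exp).sum()
    p_chi = stats.chi2.sf(chi2, 1)
    p_exact = hwe_exact_test(n_aa, n_ab, n_bb)
    assert abs(p_exact - p_chi) < 0.05
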