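"""QC filters, ancestry axes, factor extraction and residualisation."""

import math

import numpy as np
import pandas as pd
import pytest

from snpset import (CohortConfig, GenotypeMatrix, QcThresholds, SnpSpec,
                    age11_iq, compute_structure_axes, derive_fluid_factor,
                    qc_genotypes, residualise, simulate_cohort,
                    simulate_genotypes)
from snpset.pheno import hwe_exact_test


def _matrix(dosages, n_ind=None):
    dosages = np.asarray(dosages, dtype=float)
    n, m = dosages.shape
    snps = [SnpSpec(f"s{j}", "1", j + 1, maf=0.25) for j in range(m)]
    return GenotypeMatrix([f"i{i}" for i in range(n)], snps, dosages)


def hwe_exact_oracle(n_aa, n_ab, n_bb):
    """Independent enumeration: exact conditional probability of every
    heterozygote count given the allele counts, via log-factorials."""
    n = n_aa + n_ab + n_bb
    n_a = 2 * n_aa + n_ab
    rare = min(n_a, 2 * n - n_a)
    logfact = [math.lgamma(x + 1) for x in range(2 * n + 1)]

    def logprob(het):
        hom_r = (rare - het) // 2
        hom_c = n - het - hom_r
        return (logfact[n] - logfact[het] - logfact[hom_r] - logfact[hom_c]
                + het * math.log(2)
                + logfact[rare] + logfact[2 * n - rare] - logfact[2 * n])

    hets = range(rare % 2, rare + 1, 2)
    probs = {h: math.exp(logprob(h)) for h in hets}
    total = sum(probs.values())
    obs = probs[n_ab] / total
    return sum(p / total for p in probs.values() if p / total <= obs * (1 + 1e-12))


@pytest.mark.parametrize("counts", [(90, 0, 10), (25, 50, 25), (57, 14, 4),
                                    (0, 3, 100), (10, 10, 10)])
def test_hwe_exact_matches_enumeration_oracle(counts):
    assert hwe_exact_test(*counts) == pytest.approx(hwe_exact_oracle(*counts),
                                                    rel=1e-9)


class TestQc:
    def test_low_maf_snp_removed(self):
        d = np.zeros((200, 2))
        d[:, 0] = np.tile([0, 1, 2, 1], 50)  # common
        d[0, 1] = 1  # singleton heterozygote: maf 0.0025
        kept, report = qc_genotypes(_matrix(d))
        assert kept.n_snps == 1
        assert report.iloc[0]["reason"] == "maf"

    def test_low_call_rate_individual_removed(self):
        rng = np.random.default_rng(0)
        d = rng.integers(0, 3, size=(50, 100)).astype(float)
        d[0, :6] = np.nan  # call rate 0.94 < 0.95
        kept, report = qc_genotypes(_matrix(d))
        assert "i0" not in kept.individual_ids
        ind = report[report["kind"] == "individual"]
        assert list(ind["id"]) == ["i0"]

    def test_hwe_violating_snp_removed(self):
        rng = np.random.default_rng(1)
        good = rng.binomial(2, 0.3, size=(100, 2)).astype(float)
        bad = np.concatenate([np.zeros(90), np.full(10, 2.0)])  # AA=90, BB=10
        d = np.column_stack([good, bad])
        assert hwe_exact_test(90, 0, 10) < 0.001
        kept, report = qc_genotypes(_matrix(d))
        assert kept.n_snps == 2
        assert report.iloc[-1]["reason"] == "hwe"

    def test_qc_is_idempotent(self, small_cohort):
        g = simulate_genotypes(300, small_cohort.genotypes.snps,
                               ld_rho=0.2, seed=12, missing_rate=0.03)
        once, _ = qc_genotypes(g)
        twice, report2 = qc_genotypes(once)
        assert report2.empty
        assert np.array_equal(once.dosages, twice.dosages, equal_nan=True)

    def test_error_when_every_snp_fails(self):
        # monomorphic SNPs all fall to the MAF filter
        with pytest.raises(ValueError, match="every SNP"):
            qc_genotypes(_matrix(np.zeros((10, 2))))


class TestStructureAxes:
    def test_axes_orthogonal_and_centred(self, small_cohort):
        axes = compute_structure_axes(small_cohort.genotypes, k=4)
        assert axes.shape == (400, 4)
        for a in range(4):
            assert abs(axes[:, a].mean()) < 1e-8
            for b in range(a + 1, 4):
                na = axes[:, a] / np.linalg.norm(axes[:, a])
                nb = axes[:, b] / np.linalg.norm(axes[:, b])
                assert abs(na @ nb) < 1e-6

    def test_first_axis_separates_subpopulations(self, small_panel):
        c = simulate_cohort(CohortConfig(
            name="strat", n_individuals=1000, panel=small_panel,
            structure_shift=0.1, seed=14))
        axes = compute_structure_axes(c.genotypes, k=4)
        r = np.corrcoef(axes[:, 0], c.covariates["subpop"])[0, 1]
        assert abs(r) > 0.5

    def test_no_axis_tracks_subpop_without_structure(self, small_panel):
        c = simulate_cohort(CohortConfig(
            name="flat", n_individuals=2000, panel=small_panel,
            structure_shift=0.0, seed=15))
        axes = compute_structure_axes(c.genotypes, k=4)
        sp = c.covariates["subpop"].to_numpy()
        for j in range(4):
            assert abs(np.corrcoef(axes[:, j], sp)[0, 1]) < 0.1

    def test_k_must_be_below_n(self, small_cohort):
        with pytest.raises(ValueError):
            compute_structure_axes(small_cohort.genotypes, k=400)


class TestFluidFactor:
    def test_single_test_returns_zscores(self):
        rng = np.random.default_rng(2)
        battery = pd.DataFrame({"individual_id": [f"i{i}" for i in range(50)],
                                "only": rng.normal(10, 3, 50)})
        scores = derive_fluid_factor(battery)
        z = (battery["only"] - battery["only"].mean()) / battery["only"].std(ddof=0)
        assert np.allclose(scores.to_numpy(), z.to_numpy())

    def test_recovers_latent_ability(self, small_panel):
        c = simulate_cohort(CohortConfig(
            name="fa", n_individuals=1000, panel=small_panel, seed=16))
        scores = derive_fluid_factor(c.battery)
        assert np.corrcoef(scores.to_numpy(), c.latent_g)[0, 1] > 0.85

    def test_recovery_improves_with_loadings(self, small_panel):
        rs = []
        for lo in (0.4, 0.6, 0.8):
            c = simulate_cohort(CohortConfig(
                name=f"l{lo}", n_individuals=1500, panel=small_panel,
                loadings=(lo,) * 4, seed=17))
            scores = derive_fluid_factor(c.battery)
            rs.append(abs(np.corrcoef(scores.to_numpy(), c.latent_g)[0, 1]))
        assert rs[0] < rs[1] < rs[2]

    def test_row_permutation_equivariance(self, small_cohort):
        scores = derive_fluid_factor(small_cohort.battery)
        perm = np.random.default_rng(3).permutation(len(small_cohort.battery))
        shuffled = small_cohort.battery.iloc[perm].reset_index(drop=True)
        scores_p = derive_fluid_factor(shuffled)
        assert np.allclose(scores.to_numpy()[perm], scores_p.to_numpy())


class TestResidualise:
    def test_matches_ols_oracle_on_worked_example(self):
        y = np.array([1.0, 2, 3, 4, 5, 6])
        cov = pd.DataFrame({"individual_id": list("abcdef"),
                            "x": [1.0, 1, 2, 2, 3, 3]})
        out = residualise(y, cov)
        design = np.column_stack([np.ones(6), cov["x"]])
        resid = y - design @ np.linalg.lstsq(design, y, rcond=None)[0]
        expected = (resid - resid.mean()) / resid.std()
        assert np.allclose(out.values, expected, atol=1e-10)
        assert abs(out.values.mean()) < 1e-8
        assert abs(out.values.std() - 1) < 1e-8

    def test_residuals_uncorrelated_with_covariates(self, small_cohort):
        y = small_cohort.battery["test1"].to_numpy()
        cov = small_cohort.covariates[["individual_id", "age", "sex"]]
        out = residualise(y, cov)
        for col in ("age", "sex"):
            assert abs(np.corrcoef(out.values, cov[col])[0, 1]) < 1e-10

    def test_projector_property(self, small_cohort):
        y = small_cohort.battery["test2"].to_numpy()
        cov = small_cohort.covariates[["individual_id", "age", "sex"]]
        once = residualise(y, cov)
        twice = residualise(once.values, cov)
        assert np.allclose(once.values, twice.values, atol=1e-10)

    def test_collinear_covariates_named(self):
        n = 30
        rng = np.random.default_rng(4)
        cov = pd.DataFrame({"individual_id": [str(i) for i in range(n)],
                            "a": rng.normal(size=n)})
        cov["b"] = 2 * cov["a"]
        with pytest.raises(ValueError, match="collinear"):
            residualise(rng.normal(size=n), cov)

    def test_exact_linear_function_rejected(self):
        n = 20
        cov = pd.DataFrame({"individual_id": [str(i) for i in range(n)],
                            "x": np.arange(n, dtype=float)})
        with pytest.raises(ValueError, match="residual variance"):
            residualise(3.0 + 2.0 * cov["x"].to_numpy(), cov)


class TestAge11Iq:
    def test_mean_100_sd_15_exactly(self):
        rng = np.random.default_rng(5)
        score = rng.normal(30, 8, 500)
        age = rng.uniform(10.5, 11.9, 500)
        iq = age11_iq(score, age)
        assert abs(iq.mean() - 100) < 1e-8
        assert abs(iq.std() - 15) < 1e-8

    def test_age_uncorrelated_gives_plain_rescaling(self):
        rng = np.random.default_rng(6)
        score = rng.normal(size=300)
        age = np.full(300, 11.0)  # constant age: slope forced to zero
        iq = age11_iq(score, age)
        z = (score - score.mean()) / score.std()
        assert np.allclose(iq, 100 + 15 * z, atol=1e-8)

    def test_perfect_collinearity_rejected(self):
        age = np.linspace(10, 12, 50)
        with pytest.raises(ValueError):
            age11_iq(5.0 * age - 2.0, age)
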