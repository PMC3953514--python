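"""Power simulation for the meta-analysed self-contained set test.

The design mirrors the replication study's power analysis.  A sparse additive
effect vector is drawn: k effect SNPs chosen uniformly from the candidate set,
effects i.i.d. N(0, 1).  Each cohort's predicted genetic score is the centred
dosage matrix times that vector; phenotype replicates add Gaussian noise
scaled so the genetic score explains a target fraction v of the phenotypic
variance (noise variance = var(g) * (1 - v)/v, with var(g) the empirical
within-cohort variance of the predicted score).  Every replicate is tested in
every cohort with the permutation set test over the full SNP set (the signal
lives on a subset, the statistic uses all set SNPs), cohorts are combined by
sqrt(N)-weighted Stouffer, and power is the fraction of replicates whose
combined p falls below alpha.

Effects are re-allocated ``n_allocations`` times; the pooled power is the
mean over allocations and the per-allocation breakdown is retained, since the
spread across allocations is itself informative about how much power depends
on where the effect lands.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm

from .settest import batch_set_test, prepare_set_matrix
from .sim import Cohort

__all__ = [
    "PowerConfig",
    "PowerEstimate",
    "allocate_effects",
    "simulate_power_phenotypes",
    "estimate_power",
    "power_grid",
]


@dataclass(frozen=True)
class PowerConfig:
    """One cell of the power study.

    Defaults are the desk-scale settings used by the analyses here (400
    phenotype replicates split over 4 allocations, B = 999); the full-scale
    design of record is 1000 phenotypes x 100 allocations at B = 10000.
    """

    k_effect: int = 30
    v: float = 0.033
    n_phenotypes: int = 100
    n_allocations: int = 4
    alpha: float = 0.05
    B: int = 999
    seed: int = 0
    #: "stouffer" = per-cohort permutation tests combined by sqrt(N)-weighted
    #: Stouffer (the replication design); "pooled" = one permutation test on
    #: the row-concatenated cohorts.  The pooled variant is markedly more
    #: powerful because the set statistic's signal grows with sample size
    #: within a single test, a gain the Z-combination cannot recover.
    combine: str = "stouffer"

    def __post_init__(self) -> None:
        if self.combine not in ("stouffer", "pooled"):
            raise ValueError("combine must be 'stouffer' or 'pooled'")
        if not (0.0 <= self.v < 1.0):
            raise ValueError("v must lie in [0, 1)")
        if not (0.0 < self.alpha < 1.0):
            raise ValueError("alpha must lie in (0, 1)")
        if self.k_effect < 0:
            raise ValueError("k_effect must be >= 0")
        if self.B < 99:
            raise ValueError("B >= 99 required so (B+1)*alpha >= 5 at alpha 0.05")
        if self.n_phenotypes < 1 or self.n_allocations < 1:
            raise ValueError("replicate counts must be positive")


@dataclass
class PowerEstimate:
    config: PowerConfig
    power: float
    mc_se: float
    allocation_powers: list[float] = field(default_factory=list)
    n_replicates: int = 0


def _standardise(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    sd = x.std(axis=0)
    keep = sd > 0
    out = (x[:, keep] - x[:, keep].mean(axis=0)) / sd[keep]
    return np.ascontiguousarray(out), keep


def allocate_effects(
    set_snps: list[str], k_effect: int, seed: int | np.random.Generator = 0
) -> np.ndarray:
    """Sparse N(0,1) effect vector over the set (exactly k_effect nonzero)."""
    m = len(set_snps)
    if k_effect > m:
        raise ValueError(f"k_effect {k_effect} exceeds set size {m}")
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)
    beta = np.zeros(m)
    if k_effect > 0:
        idx = rng.choice(m, size=k_effect, replace=False)
        beta[idx] = rng.standard_normal(k_effect)
    return beta


def simulate_power_phenotypes(
    cohort: Cohort | np.ndarray,
    beta: np.ndarray,
    v: float,
    n_phenotypes: int,
    seed: int | np.random.Generator = 0,
    set_snps: list[str] | None = None,
) -> np.ndarray:
    """Phenotype replicate matrix (n x n_phenotypes) at variance fraction v.

    ``cohort`` may be a Cohort (then ``set_snps`` selects and centres the
    dosages) or a pre-centred dosage matrix aligned to ``beta``.  With v = 0
    the genetic score is ignored and the columns are pure noise.
    """
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)
    if isinstance(cohort, Cohort):
        if set_snps is None:
            raise ValueError("set_snps required when passing a Cohort")
        d = cohort.genotypes.subset_snps(set_snps).dosages.copy()
        nan = np.isnan(d)
        if nan.any():
            means = np.nanmean(d, axis=0)
            d = np.where(nan, means[None, :], d)
        x = d - d.mean(axis=0)
    else:
        x = np.asarray(cohort, dtype=float)
    if x.shape[1] != len(beta):
        raise ValueError("beta length does not match SNP count")
    n = x.shape[0]
    if v == 0.0:
        return rng.standard_normal((n, n_phenotypes))
    g = x @ beta
    var_g = g.var()
    if var_g == 0:
        raise ValueError("all effects zero but v > 0: no signal to scale")
    sigma = np.sqrt(var_g * (1.0 - v) / v)
    return g[:, None] + sigma * rng.standard_normal((n, n_phenotypes))


def estimate_power(
    cohorts: list[Cohort],
    set_snps: list[str],
    config: PowerConfig,
) -> PowerEstimate:
    """Monte-Carlo power of the Stouffer-combined permutation set test.

    All cohorts must carry the shared SNP panel.  Fully seeded: the master
    seed spawns independent streams for effect allocation, phenotype noise
    and the per-cohort permutation batches.
    """
    if not cohorts:
        raise ValueError("no cohorts supplied")
    master = np.random.SeedSequence(config.seed)
    ss_alloc, ss_pheno, ss_perm = master.spawn(3)
    rng_alloc = np.random.default_rng(ss_alloc)
    pheno_rngs = [np.random.default_rng(s) for s in ss_pheno.spawn(
        config.n_allocations * len(cohorts))]
    perm_rngs = [np.random.default_rng(s) for s in ss_perm.spawn(
        config.n_allocations * len(cohorts))]

    prep = [prepare_set_matrix(c.genotypes, set_snps) for c in cohorts]
    kept = prep[0][1]
    for (_, k2) in prep[1:]:
        if k2 != kept:
            raise ValueError("cohorts disagree on testable set SNPs")
    xs_list = [xs for xs, _ in prep]
    # centred (unstandardised) dosages drive the genetic score
    cent = []
    for c in cohorts:
        d = c.genotypes.subset_snps(set_snps).dosages.copy()
        nan = np.isnan(d)
        if nan.any():
            means = np.nanmean(d, axis=0)
            d = np.where(nan, means[None, :], d)
        cent.append(d - d.mean(axis=0))

    ns = np.array([c.n_individuals for c in cohorts], dtype=float)
    w = np.sqrt(ns)
    wnorm = np.sqrt(ns.sum())
    if config.combine == "pooled":
        pooled_raw = np.vstack([d for d in cent])
        xs_pooled, _ = _standardise(pooled_raw)

    alloc_powers: list[float] = []
    rejected_total = 0
    idx = 0
    for _ in range(config.n_allocations):
        beta = allocate_effects(set_snps, config.k_effect, rng_alloc)
        # some set SNPs may be constant in a cohort; align beta to full set
        Ys = []
        for ci, cohort in enumerate(cohorts):
            if config.v == 0.0:
                Y = pheno_rngs[idx + ci].standard_normal(
                    (cohort.n_individuals, config.n_phenotypes))
            else:
                Y = simulate_power_phenotypes(
                    cent[ci], beta, config.v, config.n_phenotypes,
                    pheno_rngs[idx + ci])
            Ys.append(Y)
        if config.combine == "pooled":
            p_meta = batch_set_test(
                xs_pooled, np.vstack(Ys), config.B, perm_rngs[idx])
        else:
            p_cohort = np.empty((len(cohorts), config.n_phenotypes))
            for ci in range(len(cohorts)):
                p_cohort[ci] = batch_set_test(
                    xs_list[ci], Ys[ci], config.B, perm_rngs[idx + ci])
            pc = np.clip(p_cohort, 1e-15, 1.0 - 1e-15)
            z = norm.isf(pc)
            z_meta = w @ z / wnorm
            p_meta = norm.sf(z_meta)
        idx += len(cohorts)
        rej = int(np.count_nonzero(p_meta < config.alpha))
        rejected_total += rej
        alloc_powers.append(rej / config.n_phenotypes)

    n_rep = config.n_allocations * config.n_phenotypes
    power = rejected_total / n_rep
    mc_se = float(np.sqrt(power * (1.0 - power) / n_rep))
    return PowerEstimate(config, power, mc_se, alloc_powers, n_rep)


def power_grid(
    cohorts: list[Cohort],
    set_snps: list[str],
    k_list: list[int],
    v_list: list[float],
    n_phenotypes: int = 100,
    n_allocations: int = 4,
    B: int = 999,
    alpha: float = 0.05,
    seed: int = 0,
) -> pd.DataFrame:
    """PowerEstimate per (k, v) cell, as a tidy table.

    Cell seeds are spawned deterministically from the master seed, so the
    grid is reproducible and any single cell can be recomputed in isolation
    via its recorded seed.
    """
    if not k_list or not v_list:
        raise ValueError("k_list and v_list must be non-empty")
    seeds = np.random.SeedSequence(seed).generate_state(len(k_list) * len(v_list))
    rows = []
    i = 0
    for k in k_list:
        for v in v_list:
            cell_seed = int(seeds[i] % (2**31))
            i += 1
            est = estimate_power(
                cohorts, set_snps,
                PowerConfig(k_effect=k, v=v, n_phenotypes=n_phenotypes,
                            n_allocations=n_allocations, alpha=alpha, B=B,
                            seed=cell_seed),
            )
            rows.append(
                {"k_effect": k, "v": v, "n_phenotypes": n_phenotypes,
                 "n_allocations": n_allocations, "B": B, "power": est.power,
                 "mc_se": est.mc_se, "seed": cell_seed}
            )
    return pd.DataFrame(rows)


def plot_power_grid(grid: pd.DataFrame, path: str) -> None:
    """Mean power vs variance explained, one line per effect-SNP count."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    for k, sub in grid.groupby("k_effect"):
        sub = sub.sort_values("v")
        ax.errorbar(sub["v"] * 100, sub["power"], yerr=sub["mc_se"],
                    marker="o", capsize=3, label=f"{k} effect SNPs")
    ax.set_xlabel("variance explained by the SNP set (%)")
    ax.set_ylabel("power at alpha = 0.05")
    ax.set_ylim(0, 1.02)
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
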