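"""Power of the meta-analysed set test, and why the published band differs.

Three computations on the five fluid-N cohorts with the 470-SNP set:

1. the headline cell — 30 effect SNPs explaining 3.3% of variance, B = 999,
   400 phenotype replicates, per-cohort tests combined by sqrt(N)-weighted
   Stouffer (the procedure the replication describes);
2. the same cell with the pooled-sample variant (one permutation test on the
   concatenated cohorts), which is where the published 0.775-0.867 band
   actually lives: the set statistic's signal grows with N inside a single
   test, a gain the per-cohort Z-combination cannot recover;
3. a (k_effect, v) grid at reduced replicates showing that power tracks the
   variance fraction, not the number of SNPs carrying it.

Writes results/power_headline.tsv, results/power_grid.tsv and a figure.
"""

from pathlib import Path

import pandas as pd

from snpset import PowerConfig, estimate_power, power_grid
from snpset.pipeline import RunConfig, simulate_default_cohorts
from snpset.power import plot_power_grid

OUT = Path("results")
OUT.mkdir(exist_ok=True)

cfg = RunConfig(seed=1)
cohorts, panel, annotation = simulate_default_cohorts(cfg)
set_snps = [s.snp_id for s in panel if not s.gene.startswith("BGENE")]

rows = []
for combine in ("stouffer", "pooled"):
    est = estimate_power(
        cohorts, set_snps,
        PowerConfig(k_effect=30, v=0.033, n_phenotypes=100, n_allocations=4,
                    B=999, seed=17, combine=combine))
    rows.append({"combine": combine, "k_effect": 30, "v": 0.033,
                 "power": est.power, "mc_se": round(est.mc_se, 4),
                 "n_replicates": est.n_replicates})
    print(f"{combine:>8}: power = {est.power:.3f} +/- {est.mc_se:.3f}")
head = pd.DataFrame(rows)
head.to_csv(OUT / "power_headline.tsv", sep="\t", index=False)

grid = power_grid(cohorts, set_snps,
                  k_list=[10, 30, 100, 300],
                  v_list=[0.01, 0.03, 0.05, 0.10],
                  n_phenotypes=50, n_allocations=2, B=499, seed=19)
grid.to_csv(OUT / "power_grid.tsv", sep="\t", index=False)
Path("scratch").mkdir(exist_ok=True)
plot_power_grid(grid, "scratch/power_grid.png")

at3 = grid[grid["v"] == 0.03]
print(f"\nspread across k at v=3%: "
      f"{at3['power'].max() - at3['power'].min():.3f} (k barely matters)")
print(grid.pivot(index='v', columns='k_effect', values='power').to_string())
print("-> results/power_headline.tsv, results/power_grid.tsv, "
      "scratch/power_grid.png")
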