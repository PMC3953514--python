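"""End-to-end pipeline: simulate -> QC -> phenotypes -> set tests -> meta ->
gene tests -> enrichment -> (optional) power, from a single config.

The pipeline exists so the whole analysis chain runs reproducibly from one
seed and one config file, writing tab-separated result tables plus a
machine-readable manifest of every threshold and seed used.
"""

from __future__ import annotations

import json
import logging
import sys
import zlib
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .assoc import gwas, meta_inverse_variance
from .candidates import CANDIDATE_GENES, FLUID_COHORT_SIZES
from .genetest import gene_table, gsea_enrichment
from .io import write_cohort, write_gmt
from .pheno import (QcThresholds, age11_iq, compute_structure_axes,
                    derive_fluid_factor, qc_genotypes, residualise)
from .power import PowerConfig, estimate_power
from .setmap import build_set_snplist, map_snps_to_genes
from .settest import self_contained_test, stouffer_meta
from .sim import (Cohort, CohortConfig, GenotypeMatrix,
                  make_annotation_fixture, make_background_panel,
                  make_candidate_panel, simulate_cohort)

log = logging.getLogger("snpset")

__all__ = ["RunConfig", "run_pipeline", "simulate_default_cohorts"]


@dataclass
class RunConfig:
    """Pipeline settings; defaults give a desk-scale but complete run."""

    outdir: str = "results"
    seed: int = 1
    cohort_sizes: dict[str, int] = field(
        default_factory=lambda: dict(FLUID_COHORT_SIZES))
    n_background_genes: int = 150
    ld_rho: float = 0.2
    candidate_snps: int = 470
    missing_rate: float = 0.0
    qc: QcThresholds = field(default_factory=QcThresholds)
    boundary_up: int = 2000
    boundary_down: int = 500
    symmetric_flank: int = 50000
    impute_quality_min: float = 0.3  # exposed for real imputed data; unused here
    B: int = 2000
    n_sim: int = 1000
    n_perm: int = 4000
    n_mds_axes: int = 4
    run_power: bool = False
    power_k_effect: int = 30
    power_v: float = 0.033
    power_n_phenotypes: int = 50
    power_n_allocations: int = 2
    power_B: int = 999
    write_cohorts: bool = False

    @classmethod
    def from_file(cls, path: str) -> "RunConfig":
        import yaml

        raw = yaml.safe_load(Path(path).read_text()) or {}
        qc = raw.pop("qc", None)
        cfg = cls(**raw)
        if qc:
            cfg.qc = QcThresholds(**qc)
        return cfg


def simulate_default_cohorts(cfg: RunConfig) -> tuple[list[Cohort], list, object]:
    """Five cohorts on the shared candidate + background panel."""
    ss = np.random.SeedSequence(cfg.seed)
    s_panel, s_bg, s_ann, *s_cohorts = ss.generate_state(3 + len(cfg.cohort_sizes))
    annotation, candidate_genes = make_annotation_fixture(
        cfg.n_background_genes, seed=int(s_ann % 2**31))
    panel = make_candidate_panel(cfg.candidate_snps, seed=int(s_panel % 2**31),
                                 boundary_up=cfg.boundary_up,
                                 boundary_down=cfg.boundary_down)
    panel = panel + make_background_panel(annotation, seed=int(s_bg % 2**31))
    cohorts = []
    for (name, n), s in zip(cfg.cohort_sizes.items(), s_cohorts):
        cohorts.append(
            simulate_cohort(
                CohortConfig(name=name, n_individuals=n, panel=panel,
                             ld_rho=cfg.ld_rho, missing_rate=cfg.missing_rate,
                             seed=int(s % 2**31))
            )
        )
    return cohorts, panel, annotation


def _build_phenotypes(cohort: Cohort, g: GenotypeMatrix, n_axes: int,
                      with_age11: bool) -> dict[str, object]:
    """Fluid factor, crystallised proxy and optional age-11 score, each
    residualised on age, sex and the MDS axes and standardised."""
    axes = compute_structure_axes(g, k=n_axes)
    keep = set(g.individual_ids)
    mask = cohort.covariates["individual_id"].isin(keep).to_numpy()
    cov = cohort.covariates.loc[mask].reset_index(drop=True)
    battery = cohort.battery.loc[mask].reset_index(drop=True)
    base = pd.DataFrame(
        {"individual_id": cov["individual_id"], "age": cov["age"], "sex": cov["sex"]}
    )
    for j in range(axes.shape[1]):
        base[f"mds{j + 1}"] = axes[:, j]

    out: dict[str, object] = {}
    fluid_raw = derive_fluid_factor(battery)
    out["fluid"] = residualise(fluid_raw.to_numpy(), base, label="fluid")
    # crystallised proxy: a single vocabulary-style test (first battery column)
    crys_raw = battery.iloc[:, 1].to_numpy(dtype=float)
    out["crystallised"] = residualise(crys_raw, base, label="crystallised")
    if with_age11:
        iq = age11_iq(battery.iloc[:, 1].to_numpy(dtype=float),
                      cov["age"].to_numpy(dtype=float))
        no_age = base.drop(columns=["age"])
        out["age11_iq"] = residualise(iq, no_age, label="age11_iq")
    return out


def run_pipeline(cfg: RunConfig) -> Path:
    """Run every stage; returns the output directory.

    Deterministic given ``cfg.seed``: reruns produce byte-identical tables.
    """
    out = Path(cfg.outdir)
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(stream=sys.stderr, level=logging.INFO,
                        format="%(levelname)s %(name)s: %(message)s")

    log.info("simulating %d cohorts", len(cfg.cohort_sizes))
    cohorts, panel, annotation = simulate_default_cohorts(cfg)
    write_gmt({"G_protein_candidates": CANDIDATE_GENES}, out / "candidate_set.gmt")
    if cfg.write_cohorts:
        for c in cohorts:
            write_cohort(c, out / "cohorts" / c.name)

    log.info("QC")
    qcd: dict[str, GenotypeMatrix] = {}
    qc_reports = []
    for c in cohorts:
        g, report = qc_genotypes(c.genotypes, cfg.qc)
        report.insert(0, "cohort", c.name)
        qc_reports.append(report)
        qcd[c.name] = g
    nonempty = [r for r in qc_reports if not r.empty]
    qc_all = (pd.concat(nonempty, ignore_index=True) if nonempty
              else qc_reports[0])
    qc_all.to_csv(out / "qc_report.tsv", sep="\t", index=False)

    log.info("phenotypes")
    phenos: dict[str, dict[str, object]] = {}
    for i, c in enumerate(cohorts):
        phenos[c.name] = _build_phenotypes(c, qcd[c.name], cfg.n_mds_axes,
                                           with_age11=i < 2)

    log.info("SNP-to-gene mapping")
    snp_map = map_snps_to_genes(panel, annotation,
                                boundary_up=cfg.boundary_up,
                                boundary_down=cfg.boundary_down)
    set_snps, map_report = build_set_snplist(CANDIDATE_GENES, snp_map)
    (out / "set_map_report.json").write_text(json.dumps(map_report, indent=2))

    log.info("self-contained set tests (B=%d)", cfg.B)
    rows = []
    meta_rows = []
    for label in ("fluid", "crystallised", "age11_iq"):
        ps, ns, names = [], [], []
        for c in cohorts:
            if label not in phenos[c.name]:
                continue
            y = phenos[c.name][label]
            present = set(qcd[c.name].snp_ids)
            snps = [s for s in set_snps if s in present]
            # stable per-(cohort, phenotype) stream derived from the master seed
            tag = zlib.crc32(f"{c.name}:{label}".encode())
            seed = int(np.random.SeedSequence(
                [cfg.seed, tag]).generate_state(1)[0] % 2**31)
            res = self_contained_test(qcd[c.name], y, snps, B=cfg.B, seed=seed)
            rows.append(
                {"cohort": c.name, "phenotype": label, "n": res.n,
                 "n_snps": len(res.snp_ids), "T_obs": res.T_obs, "B": res.B,
                 "p_emp": res.p_emp, "seed": res.seed}
            )
            ps.append(res.p_emp)
            ns.append(res.n)
            names.append(c.name)
        if ps:
            meta = stouffer_meta(ps, ns, cohorts=names)
            meta_rows.append(
                {"phenotype": label, "k_cohorts": len(ps),
                 "Z_meta": meta.Z_meta, "p_meta": meta.p_meta}
            )
    pd.DataFrame(rows).to_csv(out / "settest_results.tsv", sep="\t", index=False)
    pd.DataFrame(meta_rows).to_csv(out / "settest_meta.tsv", sep="\t", index=False)

    log.info("per-SNP GWAS and inverse-variance meta (fluid)")
    studies = []
    for c in cohorts:
        y = phenos[c.name]["fluid"]
        studies.append(gwas(qcd[c.name], y))
    meta_snp = meta_inverse_variance(studies)
    meta_snp.to_csv(out / "meta_gwas_fluid.tsv", sep="\t", index=False)

    log.info("gene-based tests and enrichment")
    wide_map = map_snps_to_genes(panel, annotation,
                                 symmetric_flank=cfg.symmetric_flank)
    pooled = _pool_genotypes([qcd[c.name] for c in cohorts])
    genes = gene_table(meta_snp, wide_map, pooled, n_sim=cfg.n_sim,
                       seed=int(np.random.SeedSequence(
                           [cfg.seed, 11]).generate_state(1)[0] % 2**31))
    genes.to_csv(out / "gene_stats_fluid.tsv", sep="\t", index=False)
    present_candidates = [g for g in CANDIDATE_GENES if g in set(genes["gene"])]
    enr = gsea_enrichment(genes, present_candidates, n_perm=cfg.n_perm,
                          seed=int(np.random.SeedSequence(
                              [cfg.seed, 13]).generate_state(1)[0] % 2**31))
    pd.DataFrame([{
        "ES_obs": enr.ES_obs, "n_perm": enr.n_perm, "p_enrich": enr.p_enrich,
        "set_size": enr.set_size, "genome_size": enr.genome_size,
        "weight_scheme": enr.weight_scheme, "seed": enr.seed,
    }]).to_csv(out / "gsea_fluid.tsv", sep="\t", index=False)

    power_row = None
    if cfg.run_power:
        log.info("power cell (k=%d, v=%.3f)", cfg.power_k_effect, cfg.power_v)
        est = estimate_power(
            cohorts, set_snps,
            PowerConfig(k_effect=cfg.power_k_effect, v=cfg.power_v,
                        n_phenotypes=cfg.power_n_phenotypes,
                        n_allocations=cfg.power_n_allocations,
                        B=cfg.power_B,
                        seed=int(np.random.SeedSequence(
                            [cfg.seed, 17]).generate_state(1)[0] % 2**31)))
        power_row = {"k_effect": cfg.power_k_effect, "v": cfg.power_v,
                     "power": est.power, "mc_se": est.mc_se,
                     "n_replicates": est.n_replicates}
        pd.DataFrame([power_row]).to_csv(out / "power.tsv", sep="\t", index=False)

    manifest = {
        "version": __version__,
        "seed": cfg.seed,
        "config": _jsonable(asdict(cfg)),
        "n_set_snps": len(set_snps),
        "stages": ["simulate", "qc", "pheno", "map", "settest", "gwas", "meta",
                   "genetest", "gsea"] + (["power"] if cfg.run_power else []),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    log.info("done -> %s", out)
    return out


def _pool_genotypes(mats: list[GenotypeMatrix]) -> GenotypeMatrix:
    """Row-concatenate cohorts on the intersection of their SNP panels."""
    common = [s for s in mats[0].snp_ids
              if all(s in set(m.snp_ids) for m in mats[1:])]
    subs = [m.subset_snps(common) for m in mats]
    ids = [i for m in subs for i in m.individual_ids]
    return GenotypeMatrix(ids, subs[0].snps, np.vstack([m.dosages for m in subs]))


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    return obj
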