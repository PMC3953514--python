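"""Synthetic multi-cohort genotype and phenotype simulation.

The generator emulates the statistical structure the set-association pipeline
assumes: additive dosage genotypes at common SNPs with within-gene linkage
disequilibrium, a latent general-ability factor measured by a small cognitive
test battery, basic covariates (age, sex) and an optional two-subpopulation
stratification component.

Genotypes come from a Gaussian-copula model: each of the two allele draws of an
individual is a latent standard-normal vector with first-order autoregressive
(AR(1)) correlation ``ld_rho`` between adjacent SNPs of the same gene, and the
allele indicator is the event that the latent value falls below the
minor-allele-frequency quantile.  At ``ld_rho = 0`` this reduces to independent
binomial sampling, so Hardy-Weinberg equilibrium holds by construction; at
``ld_rho > 0`` neighbouring SNPs show the positive dosage correlation that
inflates naive sums of per-SNP statistics and that the gene-based null
simulation has to account for.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .candidates import CANDIDATE_PANEL_SIZE, GENE_TEMPLATE

__all__ = [
    "SnpSpec",
    "GenotypeMatrix",
    "CohortConfig",
    "Cohort",
    "AnnotationTable",
    "simulate_genotypes",
    "simulate_cohort",
    "make_annotation_fixture",
    "make_candidate_panel",
    "make_background_panel",
]


@dataclass(frozen=True)
class SnpSpec:
    """A single biallelic SNP: identifier, position and minor allele frequency.

    ``gene`` is an optional block label: SNPs in a contiguous run with the same
    label share the AR(1) latent correlation during simulation.
    """

    snp_id: str
    chrom: str
    pos: int  # 1-based
    allele_ref: str = "A"
    allele_alt: str = "G"
    maf: float = 0.25
    gene: str | None = None

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"SNP {self.snp_id}: pos must be >= 1, got {self.pos}")
        if not (0.0 < self.maf <= 0.5):
            raise ValueError(
                f"SNP {self.snp_id}: maf must lie in (0, 0.5], got {self.maf}"
            )


@dataclass
class GenotypeMatrix:
    """Individuals x SNPs additive dosage matrix.

    ``dosages`` is a float array with entries in {0, 1, 2} counting minor
    alleles; missing genotypes are ``nan``.
    """

    individual_ids: list[str]
    snps: list[SnpSpec]
    dosages: np.ndarray

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        n, m = self.dosages.shape
        if n != len(self.individual_ids) or m != len(self.snps):
            raise ValueError(
                f"dosage shape {self.dosages.shape} does not match "
                f"{len(self.individual_ids)} individuals x {len(self.snps)} SNPs"
            )
        if len(set(self.individual_ids)) != n:
            raise ValueError("duplicate individual ids")
        ids = [s.snp_id for s in self.snps]
        if len(set(ids)) != m:
            raise ValueError("duplicate SNP ids")
        valid = np.isnan(self.dosages) | np.isin(self.dosages, (0.0, 1.0, 2.0))
        if not valid.all():
            raise ValueError("dosage entries must be 0, 1, 2 or missing")

    @property
    def n_individuals(self) -> int:
        return len(self.individual_ids)

    @property
    def n_snps(self) -> int:
        return len(self.snps)

    @property
    def snp_ids(self) -> list[str]:
        return [s.snp_id for s in self.snps]

    def subset_snps(self, snp_ids: list[str]) -> "GenotypeMatrix":
        """Column subset in the given order."""
        index = {s: j for j, s in enumerate(self.snp_ids)}
        cols = [index[s] for s in snp_ids]
        return GenotypeMatrix(
            list(self.individual_ids),
            [self.snps[j] for j in cols],
            self.dosages[:, cols].copy(),
        )

    def subset_individuals(self, keep: np.ndarray) -> "GenotypeMatrix":
        """Row subset by boolean mask or index array."""
        ids = list(np.asarray(self.individual_ids, dtype=object)[keep])
        return GenotypeMatrix(ids, list(self.snps), self.dosages[keep].copy())


@dataclass(frozen=True)
class CohortConfig:
    """Recipe for one synthetic cohort."""

    name: str
    n_individuals: int
    panel: list[SnpSpec] = field(default_factory=list)
    ld_rho: float = 0.2
    n_test_battery: int = 4
    loadings: tuple[float, ...] = (0.7, 0.7, 0.7, 0.7)
    structure_shift: float = 0.0
    missing_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_individuals <= 0:
            raise ValueError("n_individuals must be positive")
        if not (0.0 <= self.ld_rho < 1.0):
            raise ValueError("ld_rho must lie in [0, 1)")
        if len(self.loadings) != self.n_test_battery:
            raise ValueError("need one loading per battery test")
        if any(not (0.0 < l < 1.0) for l in self.loadings):
            raise ValueError("loadings must lie in (0, 1)")
        if self.structure_shift < 0:
            raise ValueError("structure_shift must be >= 0")


@dataclass
class Cohort:
    """One study sample: genotypes, covariates, test battery and latent truth.

    All tables share the ordering of ``genotypes.individual_ids``.  ``latent_g``
    is the simulated general-ability factor, retained so recovery tests can
    compare derived phenotypes against the truth.
    """

    name: str
    genotypes: GenotypeMatrix
    covariates: pd.DataFrame  # individual_id, age, sex, subpop
    battery: pd.DataFrame  # individual_id + test columns
    latent_g: np.ndarray

    def __post_init__(self) -> None:
        ids = self.genotypes.individual_ids
        for tab, label in ((self.covariates, "covariates"), (self.battery, "battery")):
            if list(tab["individual_id"]) != list(ids):
                raise ValueError(f"{label} individual ordering differs from genotypes")
        if len(self.latent_g) != len(ids):
            raise ValueError("latent_g length mismatch")

    @property
    def n_individuals(self) -> int:
        return self.genotypes.n_individuals


@dataclass
class AnnotationTable:
    """Gene annotation records with 1-based inclusive coordinates."""

    records: pd.DataFrame  # gene, chrom, start, stop, strand

    def __post_init__(self) -> None:
        req = ["gene", "chrom", "start", "stop", "strand"]
        missing = [c for c in req if c not in self.records.columns]
        if missing:
            raise ValueError(f"annotation missing columns {missing}")
        if self.records["gene"].duplicated().any():
            dup = self.records["gene"][self.records["gene"].duplicated()].tolist()
            raise ValueError(f"duplicate gene names: {dup}")
        bad = self.records["start"] > self.records["stop"]
        if bad.any():
            raise ValueError("start > stop for genes "
                             f"{self.records.loc[bad, 'gene'].tolist()}")

    def __len__(self) -> int:
        return len(self.records)


def _ar1_latent(rng: np.random.Generator, n: int, blocks: list[int],
                rho: float) -> np.ndarray:
    """n x m latent Gaussians, AR(1) with parameter rho within each block."""
    m = sum(blocks)
    z = rng.standard_normal((n, m))
    if rho > 0:
        carry = np.sqrt(1.0 - rho * rho)
        start = 0
        for size in blocks:
            for j in range(start + 1, start + size):
                z[:, j] = rho * z[:, j - 1] + carry * z[:, j]
            start += size
    return z


def _block_sizes(panel: list[SnpSpec]) -> list[int]:
    """Contiguous runs of the same (non-null) gene label; None -> singleton."""
    sizes: list[int] = []
    prev: str | None = None
    for s in panel:
        if s.gene is not None and s.gene == prev and sizes:
            sizes[-1] += 1
        else:
            sizes.append(1)
        prev = s.gene
    return sizes


def simulate_genotypes(
    n_ind: int,
    panel: list[SnpSpec],
    ld_rho: float = 0.0,
    seed: int = 0,
    missing_rate: float = 0.0,
    individual_ids: list[str] | None = None,
) -> GenotypeMatrix:
    """Draw additive dosages from the Gaussian-copula LD model.

    Each SNP's dosage is the sum of two allele indicators; each indicator is
    thresholded from a latent AR(1) Gaussian at the quantile implied by the
    SNP's minor allele frequency.  With ``ld_rho = 0`` genotype counts are in
    Hardy-Weinberg equilibrium by construction.
    """
    if n_ind <= 0:
        raise ValueError("n_ind must be positive")
    if not panel:
        raise ValueError("panel must be non-empty")
    if not (0.0 <= ld_rho < 1.0):
        raise ValueError("ld_rho must lie in [0, 1)")
    if not (0.0 <= missing_rate < 1.0):
        raise ValueError("missing_rate must lie in [0, 1)")
    rng = np.random.default_rng(seed)
    blocks = _block_sizes(panel)
    thresh = stats.norm.ppf([s.maf for s in panel])
    a1 = _ar1_latent(rng, n_ind, blocks, ld_rho) < thresh
    a2 = _ar1_latent(rng, n_ind, blocks, ld_rho) < thresh
    dos = (a1.astype(float) + a2.astype(float))
    if missing_rate > 0:
        dos[rng.random(dos.shape) < missing_rate] = np.nan
    if individual_ids is None:
        individual_ids = [f"ind{i:05d}" for i in range(n_ind)]
    return GenotypeMatrix(individual_ids, list(panel), dos)


def simulate_cohort(config: CohortConfig) -> Cohort:
    """Simulate one cohort: genotypes, latent ability, battery and covariates.

    The latent ability is ``g ~ N(0,1) + structure_shift * subpop``; test ``j``
    of the battery scores ``loading_j * g + N(0, 1 - loading_j^2)`` noise, the
    implicit single-factor model behind extracting a general factor from a
    battery.  When ``structure_shift > 0`` the second subpopulation also has
    all minor-allele frequencies shifted upward by ``structure_shift``,
    confounding ancestry with the phenotype — the scenario the MDS covariates
    exist to absorb.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_individuals
    ids = [f"{config.name}_{i:05d}" for i in range(n)]
    subpop = rng.integers(0, 2, size=n)

    if config.structure_shift > 0:
        # subpop 1 allele frequencies shifted up; may exceed 0.5, so threshold
        # the latent Gaussians directly rather than build a shifted panel
        g0 = simulate_genotypes(n, config.panel, config.ld_rho,
                                seed=int(rng.integers(2**31)))
        freq1 = np.clip(
            np.array([s.maf for s in config.panel]) + config.structure_shift,
            1e-3, 0.999,
        )
        thresh = stats.norm.ppf(freq1)
        blocks = _block_sizes(config.panel)
        rng1 = np.random.default_rng(int(rng.integers(2**31)))
        a1 = _ar1_latent(rng1, n, blocks, config.ld_rho) < thresh
        a2 = _ar1_latent(rng1, n, blocks, config.ld_rho) < thresh
        dos1 = a1.astype(float) + a2.astype(float)
        dosages = np.where(subpop[:, None] == 1, dos1, g0.dosages)
        if config.missing_rate > 0:
            dosages = dosages.copy()
            dosages[rng.random(dosages.shape) < config.missing_rate] = np.nan
        genotypes = GenotypeMatrix(ids, list(config.panel), dosages)
    else:
        genotypes = simulate_genotypes(
            n, config.panel, config.ld_rho, seed=int(rng.integers(2**31)),
            missing_rate=config.missing_rate, individual_ids=ids,
        )

    latent_g = rng.standard_normal(n) + config.structure_shift * subpop
    loadings = np.asarray(config.loadings)
    noise = rng.standard_normal((n, len(loadings))) * np.sqrt(1.0 - loadings**2)
    scores = latent_g[:, None] * loadings + noise
    battery = pd.DataFrame(
        scores, columns=[f"test{j + 1}" for j in range(len(loadings))]
    )
    battery.insert(0, "individual_id", ids)
    covariates = pd.DataFrame(
        {
            "individual_id": ids,
            "age": rng.uniform(64.0, 80.0, size=n),
            "sex": rng.integers(0, 2, size=n),
            "subpop": subpop,
        }
    )
    return Cohort(config.name, genotypes, covariates, battery, latent_g)


def _largest_remainder(weights: np.ndarray, total: int) -> np.ndarray:
    """Integer allocation proportional to weights, summing exactly to total."""
    raw = weights / weights.sum() * total
    counts = np.floor(raw).astype(int)
    short = total - counts.sum()
    order = np.argsort(-(raw - counts))
    counts[order[:short]] += 1
    return counts


def make_annotation_fixture(
    n_background: int = 0, seed: int = 0
) -> tuple[AnnotationTable, list[str]]:
    """Annotation table of the 27 candidate genes plus invented background genes.

    Candidate genes carry the published coordinates of the G-protein subunit
    genes; background genes are placed on synthetic chromosomes with
    non-overlapping windows and realistic size spread, so competitive
    (enrichment) analyses have a genome-wide panel to rank against.
    """
    if n_background < 0:
        raise ValueError("n_background must be >= 0")
    rows = [
        {"gene": g, "chrom": c, "start": start, "stop": stop, "strand": strand}
        for g, c, _, start, stop, strand in GENE_TEMPLATE
    ]
    rng = np.random.default_rng(seed)
    # per-chromosome cursors; the 150 kb minimum gap keeps even +/-50 kb
    # flanking windows of neighbouring genes disjoint
    cursor: dict[str, int] = {}
    for i in range(n_background):
        chrom = f"bg{i % 20 + 1}"
        length = int(rng.integers(5_000, 150_000))
        start = cursor.get(chrom, 1_000_000) + int(rng.integers(150_000, 400_000))
        cursor[chrom] = start + length
        rows.append(
            {
                "gene": f"BGENE{i:04d}",
                "chrom": chrom,
                "start": start,
                "stop": cursor[chrom],
                "strand": "+" if rng.random() < 0.5 else "-",
            }
        )
    table = AnnotationTable(pd.DataFrame(rows))
    return table, [g for g, *_ in GENE_TEMPLATE]


def make_candidate_panel(
    total_snps: int = CANDIDATE_PANEL_SIZE,
    seed: int = 0,
    maf_range: tuple[float, float] = (0.05, 0.45),
    boundary_up: int = 2000,
    boundary_down: int = 500,
) -> list[SnpSpec]:
    """Genotyped-style SNP panel for the candidate set, ~470 SNPs total.

    Per-gene counts follow the published per-gene SNP-count template by
    largest-remainder allocation so the panel mirrors the relative SNP density
    of the real set while summing to the genotyped total.  Positions fall
    uniformly inside each gene's upstream/downstream test window so that
    position-based mapping recovers the panel.
    """
    rng = np.random.default_rng(seed)
    template = np.array([n for _, _, n, _, _, _ in GENE_TEMPLATE], dtype=float)
    counts = _largest_remainder(template, total_snps)
    panel: list[SnpSpec] = []
    for (gene, chrom, _, start, stop, strand), k in zip(GENE_TEMPLATE, counts):
        if strand == "+":
            lo, hi = start - boundary_up, stop + boundary_down
        else:
            lo, hi = start - boundary_down, stop + boundary_up
        lo = max(lo, 1)
        positions = np.sort(rng.choice(np.arange(lo, hi + 1), size=k, replace=False))
        mafs = rng.uniform(*maf_range, size=k)
        for pos, maf in zip(positions, mafs):
            panel.append(
                SnpSpec(
                    snp_id=f"rs_{gene}_{pos}",
                    chrom=chrom,
                    pos=int(pos),
                    maf=float(maf),
                    gene=gene,
                )
            )
    return panel


def make_background_panel(
    annotation: AnnotationTable,
    mean_snps_per_gene: float = 8.0,
    seed: int = 0,
    maf_range: tuple[float, float] = (0.05, 0.45),
) -> list[SnpSpec]:
    """SNPs for the invented background genes (gene-body positions).

    Per-gene counts are 1 + Poisson(mean - 1) so every background gene is
    testable in the gene-based stage.
    """
    rng = np.random.default_rng(seed)
    panel: list[SnpSpec] = []
    bg = annotation.records[annotation.records["gene"].str.startswith("BGENE")]
    for row in bg.itertuples():
        k = 1 + rng.poisson(max(mean_snps_per_gene - 1.0, 0.0))
        positions = np.sort(
            rng.choice(np.arange(row.start, row.stop + 1), size=k, replace=False)
        )
        mafs = rng.uniform(*maf_range, size=k)
        for pos, maf in zip(positions, mafs):
            panel.append(
                SnpSpec(
                    snp_id=f"rs_{row.gene}_{pos}",
                    chrom=row.chrom,
                    pos=int(pos),
                    maf=float(maf),
                    gene=row.gene,
                )
            )
    return panel
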