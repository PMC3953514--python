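"""Genotype quality control and phenotype construction.

QC mirrors standard GWAS practice: individuals are dropped first (call rate),
then SNPs by call rate, minor allele frequency and an exact Hardy-Weinberg
equilibrium test recomputed on the retained individuals.  Phenotypes are built
the way the cohort analyses define them: a general fluid-ability factor as the
Bartlett scores of a single-factor maximum-likelihood fit to the test battery,
crystallised ability as a single vocabulary-style score, and an age-corrected
IQ-type score (mean 100, SD 15); each is then residualised on age, sex and
ancestry (MDS) axes and standardised.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.decomposition import FactorAnalysis
from sklearn.metrics import pairwise_distances

from .sim import GenotypeMatrix

__all__ = [
    "QcThresholds",
    "PhenotypeVector",
    "hwe_exact_test",
    "qc_genotypes",
    "compute_structure_axes",
    "derive_fluid_factor",
    "residualise",
    "age11_iq",
]


@dataclass(frozen=True)
class QcThresholds:
    """Inclusion thresholds; comparisons are strict (>)."""

    snp_call_rate: float = 0.98
    ind_call_rate: float = 0.95
    maf_min: float = 0.01
    hwe_p_min: float = 0.001

    def __post_init__(self) -> None:
        for name in ("snp_call_rate", "ind_call_rate", "maf_min", "hwe_p_min"):
            v = getattr(self, name)
            if not (0.0 < v < 1.0):
                raise ValueError(f"{name} must lie in (0, 1), got {v}")


@dataclass
class PhenotypeVector:
    """Analysis-ready standardised residual scores (mean 0, SD 1)."""

    individual_ids: list[str]
    values: np.ndarray
    label: str
    covariates_removed: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if len(self.values) != len(self.individual_ids):
            raise ValueError("values length does not match individual_ids")


def hwe_exact_test(n_aa: int, n_ab: int, n_bb: int) -> float:
    """Exact Hardy-Weinberg equilibrium p-value from genotype counts.

    Mid-point-free exact test: sums the probabilities of all heterozygote
    counts (given the allele counts) no more likely than the observed one.
    Stable at low counts where the chi-square approximation breaks down.
    """
    if min(n_aa, n_ab, n_bb) < 0:
        raise ValueError("genotype counts must be non-negative")
    n = n_aa + n_ab + n_bb
    if n == 0:
        return 1.0
    # work with the minor allele
    n_rare = 2 * min(n_aa, n_bb) + n_ab
    # heterozygote count must share parity with the rare-allele count
    het_probs = np.zeros(n_rare + 1)
    mid = n_rare * (2 * n - n_rare) // (2 * n)
    if mid % 2 != n_rare % 2:
        mid += 1
    het_probs[mid] = 1.0
    # downward recurrence: P(het-2)/P(het) = het(het-1) / ((rare-het+2)(common-het+2))
    het = mid
    hom_r = (n_rare - mid) // 2
    hom_c = n - het - hom_r
    while het > 1:
        het_probs[het - 2] = (
            het_probs[het] * het * (het - 1.0)
            / (4.0 * (hom_r + 1.0) * (hom_c + 1.0))
        )
        het -= 2
        hom_r += 1
        hom_c += 1
    het = mid
    hom_r = (n_rare - mid) // 2
    hom_c = n - het - hom_r
    while het <= n_rare - 2:
        het_probs[het + 2] = (
            het_probs[het] * 4.0 * hom_r * hom_c
            / ((het + 2.0) * (het + 1.0))
        )
        het += 2
        hom_r -= 1
        hom_c -= 1
    het_probs /= het_probs.sum()
    obs = n_ab
    return float(min(1.0, het_probs[het_probs <= het_probs[obs] * (1 + 1e-12)].sum()))


def _snp_maf(dosages: np.ndarray) -> np.ndarray:
    freq = np.nanmean(dosages, axis=0) / 2.0
    return np.minimum(freq, 1.0 - freq)


def qc_genotypes(
    g: GenotypeMatrix, t: QcThresholds = QcThresholds()
) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Filter individuals then SNPs; returns the retained matrix and a report.

    Filter order: individual call rate, SNP call rate, MAF, exact HWE — the
    SNP statistics are computed on the retained individuals.  The report has
    one row per removal with columns (kind, id, reason, value).
    """
    if g.n_individuals == 0 or g.n_snps == 0:
        raise ValueError("empty genotype matrix")
    removals: list[dict] = []

    obs = ~np.isnan(g.dosages)
    ind_rate = obs.mean(axis=1)
    keep_ind = ind_rate > t.ind_call_rate
    for i in np.nonzero(~keep_ind)[0]:
        removals.append(
            {"kind": "individual", "id": g.individual_ids[i],
             "reason": "call_rate", "value": float(ind_rate[i])}
        )
    if not keep_ind.any():
        raise ValueError("QC removed every individual")
    d = g.dosages[keep_ind]

    obs = ~np.isnan(d)
    snp_rate = obs.mean(axis=0)
    maf = _snp_maf(d)
    keep_snp = np.ones(g.n_snps, dtype=bool)
    for j in range(g.n_snps):
        sid = g.snps[j].snp_id
        if snp_rate[j] <= t.snp_call_rate:
            removals.append({"kind": "snp", "id": sid, "reason": "call_rate",
                             "value": float(snp_rate[j])})
            keep_snp[j] = False
        elif not maf[j] > t.maf_min:
            removals.append({"kind": "snp", "id": sid, "reason": "maf",
                             "value": float(maf[j])})
            keep_snp[j] = False
        else:
            col = d[:, j]
            col = col[~np.isnan(col)]
            n_bb = int((col == 2).sum())
            n_ab = int((col == 1).sum())
            n_aa = int((col == 0).sum())
            p_hwe = hwe_exact_test(n_aa, n_ab, n_bb)
            if not p_hwe > t.hwe_p_min:
                removals.append({"kind": "snp", "id": sid, "reason": "hwe",
                                 "value": p_hwe})
                keep_snp[j] = False
    if not keep_snp.any():
        raise ValueError("QC removed every SNP")

    kept = GenotypeMatrix(
        list(np.asarray(g.individual_ids, dtype=object)[keep_ind]),
        [s for s, k in zip(g.snps, keep_snp) if k],
        d[:, keep_snp].copy(),
    )
    report = pd.DataFrame(removals, columns=["kind", "id", "reason", "value"])
    return kept, report


def _mean_imputed(dosages: np.ndarray) -> np.ndarray:
    d = dosages.copy()
    nan = np.isnan(d)
    if nan.any():
        means = np.nanmean(d, axis=0)
        d[nan] = np.take(means, np.nonzero(nan)[1])
    return d


def compute_structure_axes(g: GenotypeMatrix, k: int = 4) -> np.ndarray:
    """Leading k classical-MDS axes of the allele-sharing distance matrix.

    Distance between individuals is 1 - IBS proportion, i.e. the mean absolute
    dosage difference divided by 2, on mean-imputed dosages.  Classical
    (Torgerson) scaling: double-centre the squared distances and take the top-k
    eigenvectors scaled by the root eigenvalue.  Axes are centred and defined
    up to sign.
    """
    if k >= g.n_individuals:
        raise ValueError("k must be smaller than the number of individuals")
    d = _mean_imputed(g.dosages)
    dist = pairwise_distances(d, metric="manhattan") / (2.0 * g.n_snps)
    sq = dist**2
    sq -= sq.mean(axis=0)
    sq -= sq.mean(axis=1)[:, None]
    b = -0.5 * sq
    vals, vecs = np.linalg.eigh(b)
    order = np.argsort(vals)[::-1][:k]
    axes = vecs[:, order] * np.sqrt(np.maximum(vals[order], 0.0))
    # sign convention: largest-magnitude coordinate positive
    for j in range(axes.shape[1]):
        i = np.argmax(np.abs(axes[:, j]))
        if axes[i, j] < 0:
            axes[:, j] = -axes[:, j]
    return axes


def _zscore(x: np.ndarray) -> np.ndarray:
    sd = x.std()
    if sd == 0:
        raise ValueError("zero-variance column")
    return (x - x.mean()) / sd


def derive_fluid_factor(battery: pd.DataFrame) -> pd.Series:
    """First-factor Bartlett scores from the cognitive test battery.

    Fits a single-factor maximum-likelihood model to the standardised test
    scores (complete cases) and returns Bartlett regression scores, which
    weight each test by loading over uniqueness.  With one test the factor is
    degenerate and the standardised column is returned.  The factor sign is
    fixed so that the mean loading is positive.
    """
    cols = [c for c in battery.columns if c != "individual_id"]
    if not cols:
        raise ValueError("battery has no test columns")
    data = battery[cols].to_numpy(dtype=float)
    complete = ~np.isnan(data).any(axis=1)
    x = data[complete]
    if x.shape[0] < 3:
        raise ValueError("too few complete cases")
    x = np.column_stack([_zscore(x[:, j]) for j in range(x.shape[1])])
    ids = battery["individual_id"].to_numpy()[complete] if "individual_id" in battery \
        else np.arange(len(battery))[complete]
    if x.shape[1] == 1:
        return pd.Series(x[:, 0], index=ids, name="fluid_factor")
    fa = FactorAnalysis(n_components=1, svd_method="lapack", random_state=0)
    fa.fit(x)
    lam = fa.components_[0]
    if lam.mean() < 0:
        lam = -lam
    psi = np.maximum(fa.noise_variance_, 1e-8)
    w = lam / psi
    scores = x @ w / (lam @ w)
    return pd.Series(scores, index=ids, name="fluid_factor")


def residualise(
    y: pd.Series | np.ndarray,
    covariates: pd.DataFrame,
    label: str = "phenotype",
) -> PhenotypeVector:
    """OLS residuals of y on the covariates (plus intercept), standardised.

    Listwise deletion of rows with any missing value.  Raises on collinear
    covariates (naming the offending columns) and on zero residual variance.
    """
    cov_cols = [c for c in covariates.columns if c != "individual_id"]
    yv = np.asarray(y, dtype=float)
    if len(yv) != len(covariates):
        raise ValueError("y and covariates have different lengths")
    x = covariates[cov_cols].to_numpy(dtype=float)
    ok = ~np.isnan(yv) & ~np.isnan(x).any(axis=1)
    yv, x = yv[ok], x[ok]
    if "individual_id" in covariates:
        ids = list(covariates["individual_id"].to_numpy()[ok])
    else:
        ids = [str(i) for i in np.nonzero(ok)[0]]
    design = np.column_stack([np.ones(len(yv)), x])
    rank = np.linalg.matrix_rank(design)
    if rank < design.shape[1]:
        offending = [
            cov_cols[j] for j in range(len(cov_cols))
            if np.linalg.matrix_rank(np.delete(design, j + 1, axis=1)) == rank
        ]
        raise ValueError(f"collinear covariates: {offending}")
    beta, *_ = np.linalg.lstsq(design, yv, rcond=None)
    resid = yv - design @ beta
    sd = resid.std()
    if sd < 1e-12 * max(yv.std(), 1.0):
        raise ValueError("zero residual variance: y is a linear function of covariates")
    return PhenotypeVector(ids, (resid - resid.mean()) / sd, label, cov_cols)


def age11_iq(score: np.ndarray, age: np.ndarray) -> np.ndarray:
    """Age-corrected IQ-type rescaling: residual of score on age, mean 100 SD 15."""
    score = np.asarray(score, dtype=float)
    age = np.asarray(age, dtype=float)
    if len(score) != len(age):
        raise ValueError("score and age have different lengths")
    design = np.column_stack([np.ones(len(age)), age])
    if age.std() == 0:
        resid = score - score.mean()
    else:
        beta, *_ = np.linalg.lstsq(design, score, rcond=None)
        resid = score - design @ beta
    sd = resid.std()
    if sd < 1e-10 * max(score.std(), 1.0):
        raise ValueError("zero residual variance after age correction")
    return 100.0 + 15.0 * (resid - resid.mean()) / sd
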