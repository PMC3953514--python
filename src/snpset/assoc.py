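"""Per-SNP additive association and fixed-effects meta-analysis.

Each SNP is tested by ordinary least squares of the (already residualised and
standardised) phenotype on the 0/1/2 dosage with an intercept; sporadically
missing dosages are mean-imputed per SNP.  Two-sided p-values come from the t
distribution at n - 2 degrees of freedom.  Cohorts are combined per SNP with
the standard inverse-variance fixed-effects model: w_i = 1/se_i^2,
beta = sum(w b)/sum(w), se = 1/sqrt(sum(w)).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import stdtr
from scipy.stats import norm

from .pheno import PhenotypeVector
from .sim import Cohort, GenotypeMatrix

__all__ = ["SnpAssoc", "MetaAssoc", "snp_regression", "gwas",
           "meta_inverse_variance"]


@dataclass(frozen=True)
class SnpAssoc:
    snp_id: str
    beta: float
    se: float
    z: float
    p: float
    n: int
    flagged: bool = False  # constant dosage; excluded from set statistics


@dataclass(frozen=True)
class MetaAssoc:
    snp_id: str
    beta_meta: float
    se_meta: float
    z_meta: float
    p_meta: float
    k_studies: int


def _impute_mean(x: np.ndarray) -> np.ndarray:
    x = np.asarray(x, dtype=float).copy()
    nan = np.isnan(x)
    if nan.all():
        raise ValueError("dosage entirely missing")
    if nan.any():
        x[nan] = x[~nan].mean()
    return x


def snp_regression(dosage: np.ndarray, y: np.ndarray | PhenotypeVector,
                   snp_id: str = "snp") -> SnpAssoc:
    """OLS slope of y on one SNP's dosage, with intercept.

    A constant dosage cannot be tested; the result is flagged with beta 0,
    infinite se and p 1 so downstream set statistics can drop it.
    """
    if isinstance(y, PhenotypeVector):
        y = y.values
    y = np.asarray(y, dtype=float)
    x = _impute_mean(dosage)
    if len(x) != len(y):
        raise ValueError("dosage and phenotype lengths differ")
    n = len(x)
    if n < 3:
        raise ValueError("need at least 3 observations")
    xc = x - x.mean()
    sxx = xc @ xc
    if sxx == 0:
        return SnpAssoc(snp_id, 0.0, np.inf, 0.0, 1.0, n, flagged=True)
    yc = y - y.mean()
    beta = (xc @ yc) / sxx
    resid = yc - beta * xc
    df = n - 2
    sigma2 = (resid @ resid) / df
    se = float(np.sqrt(sigma2 / sxx))
    if se == 0:
        return SnpAssoc(snp_id, float(beta), 0.0, np.inf, 0.0, n)
    z = beta / se
    p = float(2.0 * stdtr(df, -abs(z)))
    return SnpAssoc(snp_id, float(beta), se, float(z), max(p, 5e-324), n)


def gwas(
    cohort: Cohort | GenotypeMatrix,
    y: PhenotypeVector,
    snp_ids: list[str] | None = None,
) -> pd.DataFrame:
    """Vectorised per-SNP regression over a panel; matches snp_regression.

    The phenotype is aligned to the genotype matrix on individual id; an empty
    intersection is an error.  Returns one row per SNP with columns
    (snp_id, beta, se, z, p, n, flagged).
    """
    g = cohort.genotypes if isinstance(cohort, Cohort) else cohort
    if snp_ids is not None:
        g = g.subset_snps(snp_ids)
    pos = {ind: i for i, ind in enumerate(g.individual_ids)}
    rows = [pos[i] for i in y.individual_ids if i in pos]
    if not rows:
        raise ValueError("no overlapping individuals between genotypes and phenotype")
    keep_y = [i in pos for i in y.individual_ids]
    yv = np.asarray(y.values, dtype=float)[keep_y]
    d = g.dosages[rows]
    n = len(yv)

    nan = np.isnan(d)
    if nan.any():
        means = np.nanmean(d, axis=0)
        d = np.where(nan, means[None, :], d)
    xc = d - d.mean(axis=0)
    sxx = (xc * xc).sum(axis=0)
    yc = yv - yv.mean()
    syy = yc @ yc
    flagged = sxx == 0
    sxx_safe = np.where(flagged, 1.0, sxx)
    beta = xc.T @ yc / sxx_safe
    df = n - 2
    rss = syy - beta**2 * sxx_safe
    sigma2 = np.maximum(rss, 0.0) / df
    se = np.sqrt(sigma2 / sxx_safe)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(se > 0, beta / se, np.inf * np.sign(beta))
    p = 2.0 * stdtr(df, -np.abs(z))
    p = np.clip(p, 5e-324, 1.0)
    out = pd.DataFrame(
        {
            "snp_id": g.snp_ids,
            "beta": np.where(flagged, 0.0, beta),
            "se": np.where(flagged, np.inf, se),
            "z": np.where(flagged, 0.0, z),
            "p": np.where(flagged, 1.0, p),
            "n": n,
            "flagged": flagged,
        }
    )
    return out


def meta_inverse_variance(studies: list[pd.DataFrame]) -> pd.DataFrame:
    """Fixed-effects inverse-variance meta-analysis per SNP across cohorts.

    Studies with infinite se for a SNP are skipped for that SNP; a SNP with no
    usable study is an error.  SNPs are matched on snp_id (union).
    """
    if not studies:
        raise ValueError("no studies supplied")
    index = pd.Index([], name="snp_id", dtype=object)
    for s in studies:
        index = index.union(pd.Index(s["snp_id"]), sort=False)
    betas = np.full((len(studies), len(index)), np.nan)
    ws = np.zeros_like(betas)
    for i, s in enumerate(studies):
        f = s.set_index("snp_id").reindex(index)
        se = f["se"].to_numpy(dtype=float)
        ok = np.isfinite(se) & (se > 0)
        betas[i, ok] = f["beta"].to_numpy(dtype=float)[ok]
        ws[i, ok] = 1.0 / se[ok] ** 2
    k = (ws > 0).sum(axis=0)
    if (k == 0).any():
        bad = index[k == 0].tolist()
        raise ValueError(f"SNPs with no finite-se study: {bad[:5]}")
    wsum = ws.sum(axis=0)
    beta = np.nansum(betas * ws, axis=0) / wsum
    se = 1.0 / np.sqrt(wsum)
    z = beta / se
    return pd.DataFrame(
        {
            "snp_id": index.to_numpy(),
            "beta_meta": beta,
            "se_meta": se,
            "z_meta": z,
            "p_meta": 2.0 * norm.sf(np.abs(z)),
            "k_studies": k,
        }
    )
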