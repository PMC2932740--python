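"""The generalized Bourgain retrospective association test.

The test regresses the genotype count vector Y_j of SNP j on case-control
status with generalized least squares under Cov(Y_j) = sigma_j^2 * K:

    beta^ = (C' K^-1 C)^-1 C' K^-1 Y_j,      C = [1, case-indicator]
    sigma^_j^2 = (Y_j - C beta^)' K^-1 (Y_j - C beta^) / (N - 2)
    W = beta^_1^2 / (sigma^_j^2 [(C' K^-1 C)^-1]_22)   ~  chi^2_1 under H0.

With K = I this is the ordinary (Armitage-type) allele-count regression;
with K the (estimated, smoothed) kinship it absorbs population structure
and relatedness.  Multiplying K by a positive constant leaves W unchanged:
the per-SNP scale sigma_j^2 soaks it up.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.linalg import cho_factor, cho_solve
from scipy.stats import chi2

from .kinship import SmoothedKinship
from .models import InvalidParameterError, KinshipMatrix
from .sim import GenotypeMatrix, StudyDesign

__all__ = [
    "AssociationResult",
    "SingularKinshipError",
    "bourgain_wald_test",
    "run_scan",
    "inflation_diagnostics",
]

logger = logging.getLogger(__name__)

# run_scan filters, mirroring standard GWAS QC
MIN_MAF = 0.01
MIN_CALL_RATE = 0.95

CHI2_MEDIAN_1DF = float(chi2.ppf(0.5, 1))  # 0.4549...


class SingularKinshipError(ValueError):
    """K could not be factorized; eigen-smoothing produces a usable matrix."""


@dataclass
class AssociationResult:
    """Per-SNP test output on the allele-count scale."""

    snp_id: str
    beta1: float  # case-control difference in mean allele count
    var_beta1: float
    wald: float
    p_value: float
    sigma2_hat: float
    n_used: int
    flag: str = ""  # "" | "monomorphic"


def _kinship_values(k: KinshipMatrix | SmoothedKinship) -> np.ndarray:
    return k.values if isinstance(k, KinshipMatrix) else k.matrix.values


def _cholesky(kv: np.ndarray):
    try:
        return cho_factor(kv, lower=True)
    except np.linalg.LinAlgError as err:
        raise SingularKinshipError(
            "kinship matrix is singular or indefinite; smooth it "
            "(smooth_kinship) before testing"
        ) from err


def _gls_stats(y: np.ndarray, c: np.ndarray, factor) -> tuple[float, float, float]:
    """(beta1, var_beta1, sigma2_hat) for one SNP via a shared Cholesky."""
    n = y.size
    kin_c = cho_solve(factor, c)
    kin_y = cho_solve(factor, y)
    a = c.T @ kin_c
    ainv = np.linalg.inv(a)
    b = c.T @ kin_y
    beta = ainv @ b
    rss = float(y @ kin_y - b @ beta)
    sigma2 = rss / (n - 2)
    return float(beta[1]), sigma2 * float(ainv[1, 1]), sigma2


def bourgain_wald_test(
    genotypes: np.ndarray,
    design: StudyDesign,
    k: KinshipMatrix | SmoothedKinship,
    snp_id: str = "snp",
) -> AssociationResult:
    """Test one SNP for case-control allele-count difference under kinship K.

    ``genotypes`` is the length-N count vector (NaN = missing); samples with
    missing genotypes are dropped together with the matching rows/columns
    of K.  A monomorphic SNP is flagged and returned with W = 0, p = 1.
    """
    y = np.asarray(genotypes, dtype=float)
    kv = _kinship_values(k)
    if y.size != design.n or kv.shape[0] != design.n:
        raise InvalidParameterError("genotypes/K/design dimensions disagree")
    keep = ~np.isnan(y)
    if not keep.any():
        raise InvalidParameterError("genotypes: all values missing")
    status = design.status[keep]
    if status.sum() == 0 or status.sum() == status.size:
        raise InvalidParameterError("design: need >=1 case and >=1 control after missingness")
    y = y[keep]
    kv = kv[np.ix_(keep, keep)]
    n = y.size
    if np.all(y == y[0]):
        return AssociationResult(snp_id, 0.0, np.nan, 0.0, 1.0, 0.0, n, flag="monomorphic")
    c = np.column_stack([np.ones(n), status.astype(float)])
    beta1, var_beta1, sigma2 = _gls_stats(y, c, _cholesky(kv))
    wald = beta1**2 / var_beta1
    return AssociationResult(
        snp_id, beta1, var_beta1, wald, float(chi2.sf(wald, 1)), sigma2, n
    )


def run_scan(
    panel: GenotypeMatrix,
    design: StudyDesign,
    k: KinshipMatrix | SmoothedKinship,
    min_maf: float = MIN_MAF,
    min_call_rate: float = MIN_CALL_RATE,
) -> pd.DataFrame:
    """Test every SNP passing MAF/call-rate filters; returns a tidy table.

    SNPs with pooled MAF below ``min_maf`` or call rate below
    ``min_call_rate`` are excluded (counts logged).  Complete SNPs share a
    single Cholesky factorization of K and are solved in one batched pass;
    SNPs with missing genotypes fall back to the exact per-SNP path on the
    observed subset.
    """
    if panel.n_samples != design.n:
        raise InvalidParameterError(
            f"panel has {panel.n_samples} samples but design has {design.n}"
        )
    kv = _kinship_values(k)
    if kv.shape[0] != design.n:
        raise InvalidParameterError("kinship dimension does not match design")
    g = panel.dosages()
    call_rate = 1.0 - np.isnan(g).mean(axis=0)
    af = np.nanmean(g, axis=0) / 2.0
    maf = np.minimum(af, 1.0 - af)
    keep = (maf >= min_maf) & (call_rate >= min_call_rate)
    n_maf = int((maf < min_maf).sum())
    n_call = int((call_rate < min_call_rate).sum())
    logger.info(
        "scan filters: %d of %d SNPs kept (%d MAF<%g, %d call rate<%g)",
        int(keep.sum()),
        panel.n_snps,
        n_maf,
        min_maf,
        n_call,
        min_call_rate,
    )
    factor = _cholesky(kv)
    n = design.n
    c = design.design_matrix()
    kin_c = cho_solve(factor, c)
    a = c.T @ kin_c
    ainv = np.linalg.inv(a)

    rows = []
    idx = np.flatnonzero(keep)
    complete = ~np.isnan(g[:, idx]).any(axis=0)
    # batched path: all complete SNPs in one triangular solve
    comp_idx = idx[complete]
    if comp_idx.size:
        yc = g[:, comp_idx]
        kin_y = cho_solve(factor, yc)  # N x Mc
        b = c.T @ kin_y  # 2 x Mc
        beta = ainv @ b
        yky = np.einsum("ij,ij->j", yc, kin_y)
        rss = yky - np.einsum("ij,ij->j", b, beta)
        sigma2 = rss / (n - 2)
        var1 = sigma2 * ainv[1, 1]
        mono = np.all(yc == yc[0], axis=0)
        for pos, j in enumerate(comp_idx):
            if mono[pos]:
                rows.append(
                    AssociationResult(panel.snp_ids[j], 0.0, np.nan, 0.0, 1.0, 0.0, n, "monomorphic")
                )
            else:
                w = beta[1, pos] ** 2 / var1[pos]
                rows.append(
                    AssociationResult(
                        panel.snp_ids[j],
                        float(beta[1, pos]),
                        float(var1[pos]),
                        float(w),
                        float(chi2.sf(w, 1)),
                        float(sigma2[pos]),
                        n,
                    )
                )
    for j in idx[~complete]:
        rows.append(bourgain_wald_test(g[:, j], design, k, panel.snp_ids[j]))

    order = {s: i for i, s in enumerate(panel.snp_ids)}
    rows.sort(key=lambda r: order[r.snp_id])
    return pd.DataFrame([r.__dict__ for r in rows])


def inflation_diagnostics(p_values: np.ndarray) -> tuple[float, pd.DataFrame]:
    """Genomic-control lambda and QQ coordinates for a vector of p-values.

    lambda_GC is the median of the implied chi-square(1) statistics divided
    by the null median 0.4549; the QQ table pairs sorted -log10 expected
    uniform quantiles with observed ones.
    """
    p = np.asarray(p_values, dtype=float)
    p = p[~np.isnan(p)]
    if p.size == 0:
        raise InvalidParameterError("p_values: empty input")
    stats = chi2.isf(p, 1)
    lam = float(np.median(stats) / CHI2_MEDIAN_1DF)
    m = p.size
    expected = np.sort(-np.log10((np.arange(1, m + 1) - 0.5) / m))
    observed = np.sort(-np.log10(p))
    qq = pd.DataFrame({"expected": expected, "observed": observed})
    return lam, qq
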