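"""Design-stage power calculators for the Bourgain test under structure.

All effect sizes ``delta`` are on the genotype-count scale: delta = 0.2
means a 10-percentage-point case-control allele-frequency difference
(roughly an odds ratio of 1.5 per copy at frequency 0.4).  Every
non-centrality parameter (NCP) is the chi-square(1) offset

    lambda = delta^2 / Var(beta^_1),

with Var(beta^_1) = 2p(1-p) * [(C' K^-1 C)^-1]_22 the GLS variance of the
case-control difference under genotype covariance 2p(1-p)*K.  For the
isolated-pair and completely-admixed models the compound-symmetric K gives
closed forms, exact at every sample size; both carry large-N bounds beyond
which no sample size helps.

Fixation indices F are present-day-vs-ancestral; a *pairwise*
between-population index (e.g. a published FST of 0.153) must be halved to
be on this scale (see ``--from-pairwise-fst`` in the CLI).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy.stats import chi2, ncx2

from .kinship import SmoothedKinship, eigendecompose, smooth_kinship
from .models import (
    InvalidParameterError,
    KinshipMatrix,
    beta_shape_from_mean_het,
)
from .sim import StudyDesign

__all__ = [
    "PowerResult",
    "ncp_homogeneous",
    "ncp_isolated",
    "ncp_complete_admixture",
    "ncp_beta_admixture",
    "ncp_from_structure",
    "power_from_ncp",
    "expected_variance_under_adjustment",
    "effective_n_one_to_m",
]

logger = logging.getLogger(__name__)


@dataclass
class PowerResult:
    """NCP, its large-N bound, and power at a significance level."""

    ncp: float
    ncp_bound: float
    power: float | None = None
    alpha: float | None = None
    effective_n_ratio: float | None = None
    ncp_se: float | None = None  # Monte-Carlo standard error, when applicable


def _check_common(n_per_arm: int, p: float, delta: float) -> None:
    if n_per_arm < 1:
        raise InvalidParameterError(f"n_per_arm: must be >= 1, got {n_per_arm}")
    if not 0.0 < p < 1.0:
        raise InvalidParameterError(f"p: frequency must be in (0,1), got {p}")


def ncp_homogeneous(n_per_arm: int, p: float, delta: float) -> PowerResult:
    """NCP with no structure: lambda = n*delta^2/(4p(1-p)); unbounded in n."""
    _check_common(n_per_arm, p, delta)
    lam = n_per_arm * delta**2 / (4.0 * p * (1.0 - p))
    return PowerResult(lam, math.inf)


def ncp_isolated(n_per_arm: int, p: float, delta: float, F: float) -> PowerResult:
    """NCP when all cases come from one isolated population, controls another.

    Var(beta^_1) = (2/n) * [2p(1-p)(1+F) + (n-1)*4F*p(1-p)]; as n grows the
    drift term dominates and lambda is capped at delta^2/(8F*p(1-p)).
    """
    _check_common(n_per_arm, p, delta)
    if not 0.0 <= F < 1.0:
        raise InvalidParameterError(f"F: fixation index must be in [0,1), got {F}")
    n = n_per_arm
    pq = p * (1.0 - p)
    var = (2.0 / n) * (2.0 * pq * (1.0 + F) + (n - 1) * 4.0 * F * pq)
    lam = delta**2 / var
    bound = delta**2 / (8.0 * F * pq) if F > 0.0 else math.inf
    return PowerResult(lam, bound)


def ncp_complete_admixture(
    n_per_arm: int, p: float, delta: float, F: float, nu1: float, nu2: float
) -> PowerResult:
    """NCP for two completely admixed populations (case ancestry nu1, control nu2).

    With V_k = F*p(1-p)*(nu_k^2 + (1-nu_k)^2) the variance of each group
    mean is [2p(1-p) + 2V_k + (n-1)*4V_k]/n and the group means covary by
    4F*p(1-p)*(nu1*nu2 + (1-nu1)(1-nu2)).  The large-N bound is
    delta^2 / (8F*p(1-p)*(nu1-nu2)^2), infinite when nu1 = nu2 or F = 0.
    """
    _check_common(n_per_arm, p, delta)
    if not 0.0 <= F < 1.0:
        raise InvalidParameterError(f"F: fixation index must be in [0,1), got {F}")
    for name, nu in (("nu1", nu1), ("nu2", nu2)):
        if not 0.0 <= nu <= 1.0:
            raise InvalidParameterError(f"{name}: ancestry fraction must be in [0,1], got {nu}")
    n = n_per_arm
    pq = p * (1.0 - p)
    v1 = F * pq * (nu1**2 + (1.0 - nu1) ** 2)
    v2 = F * pq * (nu2**2 + (1.0 - nu2) ** 2)
    cov = 4.0 * F * pq * (nu1 * nu2 + (1.0 - nu1) * (1.0 - nu2))
    var_m1 = (2.0 * pq + 2.0 * v1 + (n - 1) * 4.0 * v1) / n
    var_m2 = (2.0 * pq + 2.0 * v2 + (n - 1) * 4.0 * v2) / n
    var = var_m1 + var_m2 - 2.0 * cov
    lam = delta**2 / var
    if F > 0.0 and nu1 != nu2:
        bound = delta**2 / (8.0 * F * pq * (nu1 - nu2) ** 2)
    else:
        bound = math.inf
    return PowerResult(lam, bound)


def _woodbury_a22(d: np.ndarray, u: np.ndarray, c: np.ndarray) -> float:
    """[(C'K^-1 C)^-1]_22 for K = diag(d) + U U' via the Woodbury identity."""
    dc = c / d[:, None]
    du = u / d[:, None]
    cap = np.eye(u.shape[1]) + u.T @ du
    kin_c = dc - du @ np.linalg.solve(cap, u.T @ dc)
    a = c.T @ kin_c
    return float(np.linalg.inv(a)[1, 1])


def _admixed_a22(fractions: np.ndarray, F: float, status: np.ndarray, dense: bool) -> float:
    """[(C'K^-1 C)^-1]_22 under the admixed kinship for given fractions."""
    a = fractions
    c = np.column_stack([np.ones(a.size), status.astype(float)])
    if dense:
        from .models import kinship_admixed

        kv = kinship_admixed(a, F).values
        kin_c = np.linalg.solve(kv, c)
        return float(np.linalg.inv(c.T @ kin_c)[1, 1])
    d = 1.0 - F * (a**2 + (1.0 - a) ** 2)
    u = math.sqrt(2.0 * F) * np.column_stack([a, 1.0 - a])
    return _woodbury_a22(d, u, c)


def ncp_beta_admixture(
    n_per_arm: int,
    p: float,
    delta: float,
    F: float,
    nu1: float,
    nu2: float,
    h: float,
    n_replicates: int = 50,
    seed: int = 0,
    dense: bool = False,
) -> PowerResult:
    """Monte-Carlo NCP for incompletely admixed case/control populations.

    Each replicate draws per-individual ancestry fractions (cases
    Beta(mean nu1, het h), controls Beta(mean nu2, het h)), builds the
    admixed kinship K, and evaluates the exact matrix NCP
    lambda = delta^2 / (2p(1-p) * [(C'K^-1 C)^-1]_22).  The rank-2-plus-
    diagonal structure of K is inverted in O(N) by the Woodbury identity
    (``dense=True`` forces the dense path; both agree to 1e-8).
    ``n_replicates=1`` gives the NCP of a single fixed ancestry draw.
    Returns the replicate mean with its Monte-Carlo standard error.
    """
    _check_common(n_per_arm, p, delta)
    if not 0.0 < F < 1.0:
        raise InvalidParameterError(f"F: fixation index must be in (0,1) here, got {F}")
    a1, b1 = beta_shape_from_mean_het(nu1, h)
    a2, b2 = beta_shape_from_mean_het(nu2, h)
    if n_replicates < 1:
        raise InvalidParameterError(f"n_replicates: must be >= 1, got {n_replicates}")
    rng = np.random.default_rng(seed)
    n = n_per_arm
    status = np.r_[np.ones(n, dtype=int), np.zeros(n, dtype=int)]
    pq = p * (1.0 - p)
    lams = []
    rejected = 0
    for _ in range(n_replicates):
        fr = np.r_[rng.beta(a1, b1, size=n), rng.beta(a2, b2, size=n)]
        try:
            a22 = _admixed_a22(fr, F, status, dense)
        except np.linalg.LinAlgError:  # pragma: no cover - theoretical K is PD
            rejected += 1
            continue
        lams.append(delta**2 / (2.0 * pq * a22))
    if rejected:
        logger.info("ncp_beta_admixture rejected %d non-PSD replicates", rejected)
    if not lams:
        raise InvalidParameterError("n_replicates: all replicates rejected")
    lams = np.asarray(lams)
    se = float(lams.std(ddof=1) / math.sqrt(lams.size)) if lams.size > 1 else 0.0
    return PowerResult(float(lams.mean()), math.inf, ncp_se=se)


def ncp_from_structure(
    k: KinshipMatrix | SmoothedKinship, design: StudyDesign, p: float, delta: float
) -> PowerResult:
    """Exact matrix NCP for an arbitrary kinship matrix and design.

    lambda = delta^2 / (2p(1-p) * [(C'K^-1 C)^-1]_22).  On the theoretical
    isolated-pair / completely-admixed matrices this reproduces the closed
    forms to machine precision.
    """
    if not 0.0 < p < 1.0:
        raise InvalidParameterError(f"p: frequency must be in (0,1), got {p}")
    kv = k.values if isinstance(k, KinshipMatrix) else k.matrix.values
    if kv.shape[0] != design.n:
        raise InvalidParameterError("kinship dimension does not match design")
    c = design.design_matrix()
    kin_c = np.linalg.solve(kv, c)
    a22 = float(np.linalg.inv(c.T @ kin_c)[1, 1])
    lam = delta**2 / (2.0 * p * (1.0 - p) * a22)
    return PowerResult(lam, math.inf)


def power_from_ncp(ncp: float, alpha: float) -> float:
    """Power of the 1-df chi-square test at level alpha under NCP ``ncp``."""
    if ncp < 0.0:
        raise InvalidParameterError(f"ncp: must be >= 0, got {ncp}")
    if not 0.0 < alpha < 1.0:
        raise InvalidParameterError(f"alpha: must be in (0,1), got {alpha}")
    crit = chi2.isf(alpha, 1)
    if ncp == 0.0:
        return float(alpha)
    return float(ncx2.sf(crit, 1, ncp))


def expected_variance_under_adjustment(
    k_true: KinshipMatrix, design: StudyDesign, L: int, p: float, eig=None
) -> tuple[float, float]:
    """Expected estimated Var(beta^_1) when adjusting with L eigenvectors.

    Smooths an eigendecomposition of ``k_true`` at rank ``L`` and evaluates
    the expectation of the per-SNP GLS variance estimator under the true
    genotype covariance 2p(1-p)*K_true:

        E[Var^(beta^_1)] = [(C'K~^-1 C)^-1]_22 * 2p(1-p)*tr(P K_true)/(N-2),
        P = K~^-1 - K~^-1 C (C'K~^-1 C)^-1 C'K~^-1.

    Returns (expected variance, effective-n ratio), the ratio being the
    homogeneous-design variance 2p(1-p)*[(C'C)^-1]_22 over the expected
    variance (1 when nothing needs correcting, smaller as structure costs
    power).  A precomputed eigendecomposition of ``k_true`` may be passed as
    ``eig`` to amortize the spectral cost over several L values.
    """
    if not 0.0 < p < 1.0:
        raise InvalidParameterError(f"p: frequency must be in (0,1), got {p}")
    n = design.n
    if k_true.n != n:
        raise InvalidParameterError("kinship dimension does not match design")
    if eig is None:
        eig = eigendecompose(k_true)
    sk = smooth_kinship(k_true, L, eig=eig)
    kt_inv = np.linalg.inv(sk.values)
    c = design.design_matrix()
    a = c.T @ kt_inv @ c
    ainv = np.linalg.inv(a)
    proj = kt_inv - kt_inv @ c @ ainv @ c.T @ kt_inv
    pq = p * (1.0 - p)
    e_sigma2 = 2.0 * pq * float(np.trace(proj @ k_true.values)) / (n - 2)
    e_var = float(ainv[1, 1]) * e_sigma2
    var_homog = 2.0 * pq * float(np.linalg.inv(c.T @ c)[1, 1])
    return e_var, var_homog / e_var


def effective_n_one_to_m(n_cases: int, m: float) -> float:
    """Equivalent 1:1 case-control pairs of a 1:m matched design.

    A study with m controls per case has the estimator variance of a 1:1
    study with n_cases * 2m/(m+1) pairs; the increment from adding controls
    is governed by m/(m+1), approaching twice the cases as m -> infinity.
    """
    if n_cases < 1:
        raise InvalidParameterError(f"n_cases: must be >= 1, got {n_cases}")
    if m <= 0:
        raise InvalidParameterError(f"m: matching ratio must be > 0, got {m}")
    return n_cases * 2.0 * m / (m + 1.0)
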