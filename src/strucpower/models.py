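"""Population-structure models and their theoretical kinship matrices.

The models here parameterize how cases and controls may differ in genetic
ancestry: two isolated populations drifted from a shared ancestor
(Balding-Nichols), two completely admixed populations mixing the same two
ancestral sources in different proportions, and incompletely admixed
populations where each individual's ancestry fraction is beta-distributed.
Each model implies a kinship matrix K such that the genotype covariance for
a SNP with ancestral allele frequency p is 2p(1-p)*K; that matrix feeds both
the association test (GLS weighting) and the design-stage power calculators.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "InvalidParameterError",
    "BaldingNicholsParams",
    "HomogeneousModel",
    "IsolatedPairModel",
    "CompleteAdmixtureModel",
    "BetaAdmixtureModel",
    "BetaAdmixturePairModel",
    "KinshipMatrix",
    "beta_shape_from_mean_het",
    "kinship_isolated_pair",
    "kinship_admixed",
]

# Absolute tolerance for symmetry / reduction identities on constructed matrices.
MATRIX_ATOL = 1e-10


class InvalidParameterError(ValueError):
    """A model parameter is outside its valid range (names the field)."""


def _check(cond: bool, field_name: str, msg: str) -> None:
    if not cond:
        raise InvalidParameterError(f"{field_name}: {msg}")


@dataclass(frozen=True)
class BaldingNicholsParams:
    """Drift of a modern population from its ancestor.

    The modern-day allele frequency of a SNP with ancestral frequency ``p``
    is Beta-distributed with mean ``p`` and variance ``F*p*(1-p)``,
    i.e. Beta(p(1-F)/F, (1-p)(1-F)/F).
    """

    F: float
    p: float

    def __post_init__(self) -> None:
        _check(0.0 <= self.F < 1.0, "F", f"fixation index must be in [0,1), got {self.F}")
        _check(0.0 < self.p < 1.0, "p", f"ancestral frequency must be in (0,1), got {self.p}")

    @property
    def shapes(self) -> tuple[float, float]:
        """Beta shape parameters (a, b) of the modern-day frequency."""
        if self.F == 0.0:
            raise InvalidParameterError("F: degenerate (F=0) distribution has no beta shapes")
        r = (1.0 - self.F) / self.F
        return self.p * r, (1.0 - self.p) * r


@dataclass(frozen=True)
class HomogeneousModel:
    """Cases and controls drawn from one freely mixing population."""

    n_cases: int
    n_controls: int

    def __post_init__(self) -> None:
        _check(self.n_cases >= 1, "n_cases", "need at least one case")
        _check(self.n_controls >= 1, "n_controls", "need at least one control")


@dataclass(frozen=True)
class IsolatedPairModel:
    """All cases from one isolated population, all controls from another.

    Both populations drifted independently from a shared ancestral
    population, each with fixation index ``F`` (optionally a different
    ``F2`` for the control population).
    """

    F: float
    n_cases: int
    n_controls: int
    F2: float | None = None

    def __post_init__(self) -> None:
        _check(0.0 <= self.F < 1.0, "F", f"fixation index must be in [0,1), got {self.F}")
        if self.F2 is not None:
            _check(0.0 <= self.F2 < 1.0, "F2", f"fixation index must be in [0,1), got {self.F2}")
        _check(self.n_cases >= 1, "n_cases", "need at least one case")
        _check(self.n_controls >= 1, "n_controls", "need at least one control")

    @property
    def f_controls(self) -> float:
        return self.F if self.F2 is None else self.F2


@dataclass(frozen=True)
class CompleteAdmixtureModel:
    """Two admixed populations mixing the same two ancestral sources.

    Every case has ancestry fraction ``nu1`` from ancestral population 1
    (and 1-nu1 from population 2); every control has fraction ``nu2``.
    The two ancestral populations each drifted with fixation index ``F``
    from a single earlier common ancestor.
    """

    F: float
    nu1: float
    nu2: float
    n_cases: int
    n_controls: int

    def __post_init__(self) -> None:
        _check(0.0 <= self.F < 1.0, "F", f"fixation index must be in [0,1), got {self.F}")
        _check(0.0 <= self.nu1 <= 1.0, "nu1", f"ancestry fraction must be in [0,1], got {self.nu1}")
        _check(0.0 <= self.nu2 <= 1.0, "nu2", f"ancestry fraction must be in [0,1], got {self.nu2}")
        _check(self.n_cases >= 1, "n_cases", "need at least one case")
        _check(self.n_controls >= 1, "n_controls", "need at least one control")


def beta_shape_from_mean_het(nu: float, h: float) -> tuple[float, float]:
    """Beta shape parameters (a, b) from mean ``nu`` and heterogeneity ``h``.

    The heterogeneity parameterization sets h = 1/(a+b+1) so the variance of
    the distribution is h*nu*(1-nu).  (nu=0.5, h=1/3) is the uniform
    distribution; h -> 0 degenerates to a point mass at nu.
    """
    _check(0.0 < nu < 1.0, "nu", f"mean ancestry fraction must be in (0,1), got {nu}")
    _check(0.0 < h < 1.0, "h", f"heterogeneity must be in (0,1), got {h}")
    s = 1.0 / h - 1.0  # a + b
    return nu * s, (1.0 - nu) * s


@dataclass(frozen=True)
class BetaAdmixtureModel:
    """Beta-distributed individual ancestry: mean ``nu``, variance ``h*nu*(1-nu)``."""

    nu: float
    h: float

    def __post_init__(self) -> None:
        # delegates range checks; also guarantees a, b > 0
        beta_shape_from_mean_het(self.nu, self.h)

    @property
    def shapes(self) -> tuple[float, float]:
        return beta_shape_from_mean_het(self.nu, self.h)


@dataclass(frozen=True)
class BetaAdmixturePairModel:
    """Incompletely admixed case and control populations.

    Case ancestry fractions are Beta with mean ``nu_cases``, control
    fractions Beta with mean ``nu_controls``, sharing heterogeneity ``h``.
    Both ancestral sources drifted with fixation index ``F`` from a common
    earlier ancestor.
    """

    F: float
    nu_cases: float
    nu_controls: float
    h: float
    n_cases: int
    n_controls: int

    def __post_init__(self) -> None:
        _check(0.0 <= self.F < 1.0, "F", f"fixation index must be in [0,1), got {self.F}")
        beta_shape_from_mean_het(self.nu_cases, self.h)
        beta_shape_from_mean_het(self.nu_controls, self.h)
        _check(self.n_cases >= 1, "n_cases", "need at least one case")
        _check(self.n_controls >= 1, "n_controls", "need at least one control")

    @property
    def case_model(self) -> BetaAdmixtureModel:
        return BetaAdmixtureModel(self.nu_cases, self.h)

    @property
    def control_model(self) -> BetaAdmixtureModel:
        return BetaAdmixtureModel(self.nu_controls, self.h)


PopulationModel = (
    HomogeneousModel | IsolatedPairModel | CompleteAdmixtureModel | BetaAdmixturePairModel
)


@dataclass
class KinshipMatrix:
    """Symmetric PSD N x N relatedness matrix with sample identifiers.

    Diagonal entries are 1 + f_i (f_i the inbreeding coefficient); each
    off-diagonal entry is twice the kinship coefficient of the pair.
    """

    values: np.ndarray
    sample_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[0] != self.values.shape[1]:
            raise InvalidParameterError("values: kinship matrix must be square")
        if not self.sample_ids:
            self.sample_ids = [f"S{i}" for i in range(self.values.shape[0])]
        if len(self.sample_ids) != self.values.shape[0]:
            raise InvalidParameterError("sample_ids: length does not match matrix dimension")

    @property
    def n(self) -> int:
        return self.values.shape[0]

    def validate(self, *, psd: bool = True) -> None:
        """Assert symmetry and (optionally) positive semidefiniteness."""
        v = self.values
        if not np.isfinite(v).all():
            raise InvalidParameterError("values: non-finite entries in kinship matrix")
        asym = np.abs(v - v.T).max() if v.size else 0.0
        if asym > MATRIX_ATOL:
            raise InvalidParameterError(f"values: matrix asymmetry {asym:.3e} exceeds {MATRIX_ATOL}")
        if psd:
            w = np.linalg.eigvalsh(0.5 * (v + v.T))
            floor = -1e-8 * np.trace(v) / self.n
            if w.min() < floor:
                raise InvalidParameterError(
                    f"values: smallest eigenvalue {w.min():.3e} below PSD tolerance {floor:.3e}"
                )

    def copy(self) -> "KinshipMatrix":
        return KinshipMatrix(self.values.copy(), list(self.sample_ids))


def _default_ids(n_cases: int, n_controls: int) -> list[str]:
    return [f"case{i}" for i in range(n_cases)] + [f"ctrl{i}" for i in range(n_controls)]


def kinship_isolated_pair(model: IsolatedPairModel) -> KinshipMatrix:
    """Theoretical kinship for two isolated Balding-Nichols populations.

    Cases first, then controls.  Within a population the diagonal is 1+F and
    every off-diagonal entry 2F; pairs spanning the two populations are
    unrelated (entry 0).
    """
    n1, n2 = model.n_cases, model.n_controls
    f1, f2 = model.F, model.f_controls
    n = n1 + n2
    k = np.zeros((n, n))
    k[:n1, :n1] = 2.0 * f1
    k[n1:, n1:] = 2.0 * f2
    np.fill_diagonal(k, np.r_[np.full(n1, 1.0 + f1), np.full(n2, 1.0 + f2)])
    return KinshipMatrix(k, _default_ids(n1, n2))


def kinship_admixed(
    fractions: np.ndarray, F: float, sample_ids: list[str] | None = None
) -> KinshipMatrix:
    """Theoretical kinship for admixed individuals with ancestry fractions a_i.

    Each individual draws fraction ``a_i`` of ancestry from ancestral
    population 1 and ``1-a_i`` from population 2, the two sources having
    drifted independently (each with fixation index ``F``) from a common
    ancestor.  Entries:

        K_ii = 1 + F*(a_i^2 + (1-a_i)^2)
        K_ij = 2F*(a_i*a_j + (1-a_i)*(1-a_j))      (i != j)

    With all case fractions nu1 and control fractions nu2 this reduces to
    the completely-admixed two-population covariance; with all fractions 0
    or 1 it reduces to a single isolated population (diag 1+F, off-diag 2F).
    """
    a = np.asarray(fractions, dtype=float)
    if a.ndim != 1:
        raise InvalidParameterError("fractions: expected a 1-D array of ancestry fractions")
    if a.size and (a.min() < 0.0 or a.max() > 1.0):
        raise InvalidParameterError(
            f"fractions: ancestry fractions must lie in [0,1]; range [{a.min()}, {a.max()}]"
        )
    _check(0.0 <= F < 1.0, "F", f"fixation index must be in [0,1), got {F}")
    u = np.column_stack([a, 1.0 - a])  # N x 2 loadings onto the two ancestral sources
    k = 2.0 * F * (u @ u.T)
    np.fill_diagonal(k, 1.0 + F * (a**2 + (1.0 - a) ** 2))
    ids = sample_ids if sample_ids is not None else [f"S{i}" for i in range(a.size)]
    return KinshipMatrix(k, list(ids))


def kinship_beta_pair_expected(model: BetaAdmixturePairModel) -> KinshipMatrix:
    """Marginal kinship of the incompletely admixed pair model (cases first).

    Averages the admixed kinship over independent per-individual beta
    ancestry draws: within-arm off-diagonals use E[a_i a_j] = nu^2 (so they
    equal the completely-admixed elements at the arm means), while each
    diagonal picks up the within-arm ancestry variance h*nu*(1-nu) through
    E[a^2] = nu^2 + h*nu*(1-nu).
    """
    n1, n2, F, h = model.n_cases, model.n_controls, model.F, model.h
    nus = (model.nu_cases, model.nu_controls)
    n = n1 + n2
    k = np.zeros((n, n))
    blocks = (slice(0, n1), slice(n1, n))
    for bi, nu in zip(blocks, nus):
        k[bi, bi] = 2.0 * F * (nu**2 + (1.0 - nu) ** 2)
    cross = 2.0 * F * (nus[0] * nus[1] + (1.0 - nus[0]) * (1.0 - nus[1]))
    k[blocks[0], blocks[1]] = cross
    k[blocks[1], blocks[0]] = cross
    diag = [
        1.0 + F * (nu**2 + (1.0 - nu) ** 2 + 2.0 * h * nu * (1.0 - nu)) for nu in nus
    ]
    np.fill_diagonal(k, np.r_[np.full(n1, diag[0]), np.full(n2, diag[1])])
    return KinshipMatrix(k, _default_ids(n1, n2))


def kinship_for_model(model: PopulationModel) -> KinshipMatrix:
    """Theoretical kinship implied by a structure model (cases first).

    For the beta-admixture pair model this is the marginal (expected-over-
    ancestry-draws) kinship; for a realized draw of fractions use
    :func:`kinship_admixed` directly.
    """
    if isinstance(model, HomogeneousModel):
        n = model.n_cases + model.n_controls
        return KinshipMatrix(np.eye(n), _default_ids(model.n_cases, model.n_controls))
    if isinstance(model, IsolatedPairModel):
        return kinship_isolated_pair(model)
    if isinstance(model, CompleteAdmixtureModel):
        fr = np.r_[np.full(model.n_cases, model.nu1), np.full(model.n_controls, model.nu2)]
        return kinship_admixed(fr, model.F, _default_ids(model.n_cases, model.n_controls))
    if isinstance(model, BetaAdmixturePairModel):
        return kinship_beta_pair_expected(model)
    raise InvalidParameterError(f"model: unsupported model type {type(model).__name__}")


def dataclass_fields(model) -> dict:
    """Flat dict of a model's parameters (for logging / config echo)."""
    return dataclasses.asdict(model)
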