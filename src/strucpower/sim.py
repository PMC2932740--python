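"""Synthetic case-control genotype panels under population-structure models.

Every downstream module (kinship estimation, association testing, power
checks) is testable against panels generated here, with known truth:
per-SNP ancestral and population-specific allele frequencies and
per-individual ancestry fractions.

Sampling scheme, per SNP j with ancestral frequency p_j:

* each ancestral source k draws a modern frequency p_kj ~ Beta with mean
  p_j and variance F*p_j*(1-p_j) (Balding-Nichols drift);
* individual i with ancestry fraction a_i has SNP frequency
  q_ij = a_i*p_1j + (1-a_i)*p_2j;
* the genotype count is Binomial(2, q_ij) (Hardy-Weinberg given q_ij).

This reproduces the genotype covariance 2p(1-p)*K of the theoretical
kinship constructions in :mod:`strucpower.models`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .models import (
    BetaAdmixturePairModel,
    CompleteAdmixtureModel,
    HomogeneousModel,
    InvalidParameterError,
    IsolatedPairModel,
    PopulationModel,
    beta_shape_from_mean_het,
)

__all__ = [
    "GenotypeMatrix",
    "StudyDesign",
    "CausalSpec",
    "simulate_null_snps",
    "add_causal_snp",
    "simulate_causal_panel",
]

logger = logging.getLogger(__name__)

# Panels are regenerated until every SNP clears this pooled minor-allele
# frequency, mirroring the standard GWAS exclusion of rare variants.
MIN_POOLED_MAF = 0.01

# Causal-SNP frequency shifts are clipped into this interval per individual.
CLIP_LO, CLIP_HI = 0.01, 0.99


@dataclass
class GenotypeMatrix:
    """N samples x M SNPs allele-count matrix with an explicit missing mask."""

    counts: np.ndarray  # int8, {0,1,2}; entries under `missing` are arbitrary
    missing: np.ndarray  # bool, True where the genotype is missing
    snp_ids: list[str]
    sample_ids: list[str]
    ref: list[str] = field(default_factory=list)
    alt: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int8)
        self.missing = np.asarray(self.missing, dtype=bool)
        n, m = self.counts.shape
        if self.missing.shape != (n, m):
            raise InvalidParameterError("missing: mask shape must match counts")
        if len(self.sample_ids) != n or len(self.snp_ids) != m:
            raise InvalidParameterError("ids: id list lengths must match matrix shape")
        if not self.ref:
            self.ref = ["A"] * m
        if not self.alt:
            self.alt = ["G"] * m
        ok = np.isin(self.counts[~self.missing], (0, 1, 2)).all()
        if not ok:
            raise InvalidParameterError("counts: non-missing genotypes must be 0, 1 or 2")

    @property
    def n_samples(self) -> int:
        return self.counts.shape[0]

    @property
    def n_snps(self) -> int:
        return self.counts.shape[1]

    def dosages(self) -> np.ndarray:
        """Float counts with NaN at missing entries."""
        g = self.counts.astype(float)
        g[self.missing] = np.nan
        return g


@dataclass
class StudyDesign:
    """Case/control labels (1 = case) and optional site strata, length N."""

    status: np.ndarray
    site_label: list[str] | None = None

    def __post_init__(self) -> None:
        self.status = np.asarray(self.status, dtype=np.int64)
        if not np.isin(self.status, (0, 1)).all():
            raise InvalidParameterError("status: entries must be 0 or 1")
        if self.status.sum() == 0 or self.status.sum() == self.status.size:
            raise InvalidParameterError("status: need at least one case and one control")
        if self.site_label is not None and len(self.site_label) != self.status.size:
            raise InvalidParameterError("site_label: length must match status")

    @property
    def n(self) -> int:
        return self.status.size

    def design_matrix(self) -> np.ndarray:
        """The N x 2 regression design C = [1, case-indicator]."""
        return np.column_stack([np.ones(self.n), self.status.astype(float)])


@dataclass(frozen=True)
class CausalSpec:
    """A causal SNP: ancestral frequency ``p`` and count-scale effect ``delta``.

    ``delta`` is the case-minus-control difference in mean allele count, so
    the allele-frequency difference is delta/2 (cases shifted +delta/4,
    controls -delta/4).
    """

    p: float
    delta: float

    def __post_init__(self) -> None:
        if not 0.0 < self.p < 1.0:
            raise InvalidParameterError(f"p: ancestral frequency must be in (0,1), got {self.p}")
        for arm, shift in (("case", self.delta / 4.0), ("control", -self.delta / 4.0)):
            q = self.p + shift
            if not 0.0 < q < 1.0:
                raise InvalidParameterError(
                    f"delta: implied {arm} frequency {q} outside (0,1) at p={self.p}"
                )


def _model_layout(model: PopulationModel, rng: np.random.Generator):
    """Ancestry fractions (N,), drift F, and the study design for a model."""
    if isinstance(model, HomogeneousModel):
        n = model.n_cases + model.n_controls
        fractions = np.ones(n)
        F = 0.0
    elif isinstance(model, IsolatedPairModel):
        if model.F2 is not None and model.F2 != model.F:
            raise InvalidParameterError(
                "F2: the simulator draws both populations at a shared F; "
                "unequal drift is supported only by the kinship construction"
            )
        fractions = np.r_[np.ones(model.n_cases), np.zeros(model.n_controls)]
        F = model.F
    elif isinstance(model, CompleteAdmixtureModel):
        fractions = np.r_[
            np.full(model.n_cases, model.nu1), np.full(model.n_controls, model.nu2)
        ]
        F = model.F
    elif isinstance(model, BetaAdmixturePairModel):
        a1, b1 = beta_shape_from_mean_het(model.nu_cases, model.h)
        a2, b2 = beta_shape_from_mean_het(model.nu_controls, model.h)
        fractions = np.r_[
            rng.beta(a1, b1, size=model.n_cases), rng.beta(a2, b2, size=model.n_controls)
        ]
        F = model.F
    else:
        raise InvalidParameterError(f"model: unsupported model type {type(model).__name__}")
    status = np.r_[np.ones(model.n_cases, dtype=int), np.zeros(model.n_controls, dtype=int)]
    return fractions, F, StudyDesign(status)


def _draw_pop_freqs(p: np.ndarray, F: float, rng: np.random.Generator) -> np.ndarray:
    """Modern-day frequencies Beta(mean p, var F*p*(1-p)); p unchanged at F=0."""
    if F == 0.0:
        return p.copy()
    r = (1.0 - F) / F
    return rng.beta(p * r, (1.0 - p) * r)


def _draw_panel(
    fractions: np.ndarray,
    F: float,
    p_anc: np.ndarray,
    rng: np.random.Generator,
    shift: np.ndarray | None = None,
):
    """Genotype counts (N x M) plus the two per-SNP population frequencies.

    ``shift`` (N,) optionally offsets each individual's SNP frequency (used
    for causal SNPs); shifted frequencies are clipped to [CLIP_LO, CLIP_HI].
    Returns (counts, p1, p2, n_clipped).
    """
    p1 = _draw_pop_freqs(p_anc, F, rng)
    p2 = _draw_pop_freqs(p_anc, F, rng)
    q = np.outer(fractions, p1) + np.outer(1.0 - fractions, p2)  # N x M
    n_clipped = 0
    if shift is not None:
        q = q + shift[:, None]
        clipped = (q < CLIP_LO) | (q > CLIP_HI)
        n_clipped = int(clipped.sum())
        q = np.clip(q, CLIP_LO, CLIP_HI)
    counts = rng.binomial(2, q).astype(np.int8)
    return counts, p1, p2, n_clipped


def _uniform_freq_sampler(rng: np.random.Generator, size: int) -> np.ndarray:
    return rng.uniform(0.1, 0.9, size=size)


def simulate_null_snps(
    model: PopulationModel,
    n_snps: int,
    seed: int,
    freq_sampler=None,
    missing_rate: float = 0.0,
) -> tuple[GenotypeMatrix, StudyDesign, dict[str, pd.DataFrame]]:
    """Simulate a panel of null SNPs under a structure model.

    Parameters
    ----------
    model
        One of the population models (cases first, then controls).
    n_snps
        Number of SNPs to simulate.
    seed
        Single seed for all randomness (identical seed => identical output).
    freq_sampler
        Callable ``(rng, size) -> ancestral frequencies``; default
        Uniform(0.1, 0.9).  Must return values strictly inside (0, 1).
    missing_rate
        Per-genotype probability of being masked missing (default 0).

    Returns
    -------
    (panel, design, truth) where ``truth`` holds two DataFrames: ``snps``
    (snp_id, ancestral_freq, pop1_freq, pop2_freq, is_causal) and
    ``samples`` (sample_id, status, ancestry_fraction).

    SNPs whose pooled minor-allele frequency falls below 1% are redrawn, so
    the returned panel contains no rare variants.
    """
    if n_snps < 1:
        raise InvalidParameterError(f"n_snps: need at least one SNP, got {n_snps}")
    if not 0.0 <= missing_rate < 1.0:
        raise InvalidParameterError(f"missing_rate: must be in [0,1), got {missing_rate}")
    rng = np.random.default_rng(seed)
    sampler = freq_sampler or _uniform_freq_sampler
    fractions, F, design = _model_layout(model, rng)
    n = fractions.size

    p_anc = np.asarray(sampler(rng, n_snps), dtype=float)
    if p_anc.shape != (n_snps,) or p_anc.min() <= 0.0 or p_anc.max() >= 1.0:
        raise InvalidParameterError(
            "freq_sampler: ancestral frequencies must be n_snps values strictly in (0,1)"
        )
    counts, p1, p2, _ = _draw_panel(fractions, F, p_anc, rng)

    # redraw rare SNPs (pooled MAF < 1%) until none remain
    for _ in range(1000):
        af = counts.mean(axis=0) / 2.0
        bad = np.minimum(af, 1.0 - af) < MIN_POOLED_MAF
        if not bad.any():
            break
        k = int(bad.sum())
        p_anc[bad] = np.asarray(sampler(rng, k), dtype=float)
        counts[:, bad], p1[bad], p2[bad], _ = _draw_panel(fractions, F, p_anc[bad], rng)
    else:  # pragma: no cover - only reachable with a pathological sampler
        raise InvalidParameterError("freq_sampler: could not draw common SNPs after 1000 rounds")

    missing = np.zeros_like(counts, dtype=bool)
    if missing_rate > 0.0:
        missing = rng.random(counts.shape) < missing_rate

    snp_ids = [f"snp{j}" for j in range(n_snps)]
    sample_ids = [
        f"case{i}" if s else f"ctrl{i - model.n_cases}" for i, s in enumerate(design.status)
    ]
    panel = GenotypeMatrix(counts, missing, snp_ids, sample_ids)
    truth = {
        "snps": pd.DataFrame(
            {
                "snp_id": snp_ids,
                "ancestral_freq": p_anc,
                "pop1_freq": p1,
                "pop2_freq": p2,
                "is_causal": np.zeros(n_snps, dtype=bool),
            }
        ),
        "samples": pd.DataFrame(
            {
                "sample_id": sample_ids,
                "status": design.status,
                "ancestry_fraction": fractions,
            }
        ),
    }
    return panel, design, truth


def _causal_columns(
    fractions: np.ndarray,
    F: float,
    design: StudyDesign,
    spec: CausalSpec,
    n_snps: int,
    rng: np.random.Generator,
):
    """N x n_snps causal genotype draws: case freqs +delta/4, controls -delta/4."""
    shift = np.where(design.status == 1, spec.delta / 4.0, -spec.delta / 4.0)
    p_anc = np.full(n_snps, spec.p)
    counts, p1, p2, n_clipped = _draw_panel(fractions, F, p_anc, rng, shift=shift)
    frac_clipped = n_clipped / counts.size
    if frac_clipped > 0.01:
        logger.warning(
            "causal SNP frequency clipping affected %.1f%% of individual frequencies",
            100.0 * frac_clipped,
        )
    return counts, p1, p2


def add_causal_snp(
    panel: GenotypeMatrix,
    design: StudyDesign,
    spec: CausalSpec,
    seed: int,
    model: PopulationModel | None = None,
    truth: dict[str, pd.DataFrame] | None = None,
) -> GenotypeMatrix:
    """Append one causal SNP to a panel.

    The SNP is drawn under the same structure as the panel (``model``; the
    homogeneous model when omitted) with each case's frequency shifted by
    +delta/4 and each control's by -delta/4, a total count-scale
    case-control difference of ``delta``.  If a ``truth`` dict from
    :func:`simulate_null_snps` is passed, the SNP is recorded there as
    causal.
    """
    rng = np.random.default_rng(seed)
    if model is None:
        model = HomogeneousModel(int(design.status.sum()), int((1 - design.status).sum()))
    fractions, F, model_design = _model_layout(model, rng)
    if model_design.n != panel.n_samples or not np.array_equal(model_design.status, design.status):
        raise InvalidParameterError("model: case/control layout does not match the panel design")
    counts, p1, p2 = _causal_columns(fractions, F, design, spec, 1, rng)

    snp_id = f"causal{panel.n_snps}"
    new = GenotypeMatrix(
        np.hstack([panel.counts, counts]),
        np.hstack([panel.missing, np.zeros((panel.n_samples, 1), dtype=bool)]),
        panel.snp_ids + [snp_id],
        list(panel.sample_ids),
        panel.ref + ["A"],
        panel.alt + ["G"],
    )
    if truth is not None:
        truth["snps"] = pd.concat(
            [
                truth["snps"],
                pd.DataFrame(
                    {
                        "snp_id": [snp_id],
                        "ancestral_freq": [spec.p],
                        "pop1_freq": p1,
                        "pop2_freq": p2,
                        "is_causal": [True],
                    }
                ),
            ],
            ignore_index=True,
        )
    return new


def simulate_causal_panel(
    model: PopulationModel, spec: CausalSpec, n_snps: int, seed: int
) -> tuple[GenotypeMatrix, StudyDesign]:
    """Panel of independent causal SNPs (each its own frequency draw).

    Convenience wrapper over the :func:`add_causal_snp` sampling scheme for
    power-calibration experiments; equivalent to appending ``n_snps`` causal
    SNPs one at a time but drawn in one vectorized pass.
    """
    if n_snps < 1:
        raise InvalidParameterError(f"n_snps: need at least one SNP, got {n_snps}")
    rng = np.random.default_rng(seed)
    fractions, F, design = _model_layout(model, rng)
    counts, _, _ = _causal_columns(fractions, F, design, spec, n_snps, rng)
    snp_ids = [f"causal{j}" for j in range(n_snps)]
    sample_ids = [
        f"case{i}" if s else f"ctrl{i - model.n_cases}" for i, s in enumerate(design.status)
    ]
    panel = GenotypeMatrix(counts, np.zeros_like(counts, dtype=bool), snp_ids, sample_ids)
    return panel, design
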