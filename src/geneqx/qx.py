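"""The QX statistic: genetic values, the VA scaling factor, the quadratic
form against the neutral covariance F, and its single-locus ("FST-like") vs
cross-locus ("LD-like") decomposition.

For a gene with L regulatory variants of effect size alpha_l and frequency
p_ml in population m, the population genetic value is

    z_m = 2 * sum_l alpha_l * p_ml

and the test statistic is

    QX = Z'^T F^{-1} Z' / (2 * VA),      VA = 2 * sum_l alpha_l^2 eps_l (1 - eps_l)

where Z' is the mean-centered genetic-value vector with its last entry
dropped, eps_l the mean frequency across the M populations, and F the
(M-1)x(M-1) expected neutral covariance of standardized frequencies. Under
neutrality (multivariate-normal frequency drift) QX ~ chi^2 with M-1 degrees
of freedom. The statistic is invariant to rescaling all effect sizes, to
allele flips (alpha -> -alpha, p -> 1-p), and to which entry is dropped,
provided F uses the same convention.

Numerics: the quadratic form is evaluated through a symmetric
positive-definite (Cholesky) solve, never an explicit inverse; a
condition-number warning is emitted above 1e10.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import scipy.linalg

from .errors import DegenerateGeneError, SingularCovarianceError
from .models import FrequencyPanel, GeneModel

logger = logging.getLogger(__name__)

COND_WARN_THRESHOLD = 1e10


@dataclass
class GeneticValueVector:
    """Raw genetic values z_m and the transformed vector Z' (centered, last
    entry dropped)."""

    raw: np.ndarray
    transformed: np.ndarray
    population_order: tuple[str, ...]
    dropped_index: int


@dataclass
class QxResult:
    """Per-gene QX with its decomposition and (optionally) P-values."""

    gene_id: str
    qx: float
    va: float
    fst_component: float
    ld_component: float
    n_variants: int
    p_gamma: float | None = None
    p_freqperm: float | None = None
    p_effperm: float | None = None
    q_fdr: float | None = None
    status: str = "ok"


# ---------------------------------------------------------------------------
# array-level primitives (used directly by the permutation and power code)
# ---------------------------------------------------------------------------

def genetic_values(weights: np.ndarray, freqs: np.ndarray) -> np.ndarray:
    """z_m = 2 * sum_l alpha_l p_ml for a (L,) weight vector and (L, M)
    frequency matrix."""
    weights = np.asarray(weights, dtype=float)
    freqs = np.asarray(freqs, dtype=float)
    return 2.0 * weights @ freqs


def center_and_drop(z: np.ndarray) -> np.ndarray:
    """Mean-center along the last axis and drop the final entry."""
    z = np.asarray(z, dtype=float)
    return (z - z.mean(axis=-1, keepdims=True))[..., :-1]


def additive_variance(weights: np.ndarray, mean_freqs: np.ndarray) -> float:
    """VA = 2 * sum_l alpha_l^2 eps_l (1 - eps_l).

    Raises :class:`DegenerateGeneError` when VA is zero (every variant fixed
    across all populations); callers must skip such genes.
    """
    weights = np.asarray(weights, dtype=float)
    eps = np.asarray(mean_freqs, dtype=float)
    va = 2.0 * float(np.sum(weights**2 * eps * (1.0 - eps)))
    if va <= 0.0:
        raise DegenerateGeneError(
            "VA is zero: all model variants are fixed across populations"
        )
    return va


def _cho_factor(F: np.ndarray):
    F = np.asarray(F, dtype=float)
    try:
        c, low = scipy.linalg.cho_factor(F, check_finite=False)
    except scipy.linalg.LinAlgError as exc:
        raise SingularCovarianceError(
            "F is singular or not positive definite; use more matched neutral variants"
        ) from exc
    cond = np.linalg.cond(F)
    if cond > COND_WARN_THRESHOLD:
        logger.warning("F is ill-conditioned (cond=%.3g)", cond)
    return c, low


def qx_statistic(transformed: np.ndarray, F: np.ndarray, va: float) -> float:
    """QX = Z'^T F^{-1} Z' / (2 VA), via a Cholesky solve."""
    zt = np.asarray(transformed, dtype=float)
    c = _cho_factor(F)
    sol = scipy.linalg.cho_solve(c, zt, check_finite=False)
    return float(zt @ sol) / (2.0 * va)


def qx_statistic_many(
    transformed: np.ndarray, F: np.ndarray, va: np.ndarray | float
) -> np.ndarray:
    """Row-wise QX for an (n, M-1) batch of transformed vectors."""
    zt = np.atleast_2d(np.asarray(transformed, dtype=float))
    c = _cho_factor(F)
    sol = scipy.linalg.cho_solve(c, zt.T, check_finite=False)
    quad = np.einsum("ij,ji->i", zt, sol)
    return quad / (2.0 * np.asarray(va, dtype=float))


def decompose_qx_arrays(
    weights: np.ndarray, freqs: np.ndarray, F: np.ndarray, va: float
) -> tuple[float, float]:
    """Split QX into its single-locus (FST-like) and cross-locus (LD-like)
    parts.

    With per-locus transformed contributions c_l = center_and_drop(2 alpha_l
    p_l.), QX = sum_{l,l'} c_l^T F^{-1} c_{l'} / (2 VA); the diagonal terms
    form the FST-like component and the off-diagonal terms the LD-like
    component. The two sum to QX exactly (same floating-point path).
    """
    weights = np.asarray(weights, dtype=float)
    freqs = np.asarray(freqs, dtype=float)
    contrib = center_and_drop(2.0 * weights[:, None] * freqs)  # (L, M-1)
    c = _cho_factor(F)
    sol = scipy.linalg.cho_solve(c, contrib.T, check_finite=False)  # (M-1, L)
    G = contrib @ sol  # (L, L) Gram matrix in the F^{-1} metric
    denom = 2.0 * va
    fst = float(np.trace(G)) / denom
    ld = float(G.sum() - np.trace(G)) / denom
    return fst, ld


# ---------------------------------------------------------------------------
# typed wrappers over GeneModel / FrequencyPanel
# ---------------------------------------------------------------------------

def genetic_value_vector(model: GeneModel, panel: FrequencyPanel) -> GeneticValueVector:
    """Genetic values of a gene model across the panel's populations."""
    freqs = panel.freq_matrix(model.variant_ids)
    raw = genetic_values(model.weights, freqs)
    return GeneticValueVector(
        raw=raw,
        transformed=center_and_drop(raw),
        population_order=panel.populations,
        dropped_index=panel.n_populations - 1,
    )


def gene_qx(model: GeneModel, panel: FrequencyPanel, F: np.ndarray) -> QxResult:
    """QX and its decomposition for one gene model against a frequency panel.

    ``F`` may be a plain (M-1)x(M-1) array or a
    :class:`geneqx.neutral.NeutralCovariance`.
    """
    Fm = getattr(F, "matrix", F)
    freqs = panel.freq_matrix(model.variant_ids)
    va = additive_variance(model.weights, freqs.mean(axis=1))
    zt = center_and_drop(genetic_values(model.weights, freqs))
    qx = qx_statistic(zt, Fm, va)
    fst, ld = decompose_qx_arrays(model.weights, freqs, Fm, va)
    return QxResult(
        gene_id=model.gene_id,
        qx=qx,
        va=va,
        fst_component=fst,
        ld_component=ld,
        n_variants=model.n_variants,
    )
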