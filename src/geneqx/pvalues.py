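"""P-value schemes for the gene-level QX scan.

Three schemes are provided:

``freqPerm``
    The original QX null: each permutation replaces every model variant's
    across-population frequency vector with that of one of its
    frequency-matched neutral variants (drawn uniformly, independently per
    variant), holding effect sizes constant. QX is recomputed with the same
    F; VA is recomputed from the permuted mean frequencies. Because this
    breaks any LD structure among a gene's variants, it is poorly calibrated
    for models with correlated frequencies.

``gamma``
    A two-parameter gamma distribution (location pinned at 0) is fit by
    maximum likelihood to the genome-wide QX scores; each gene's P-value is
    the upper-tail probability at its score. The gamma map is monotone, so
    gene ordering equals ordering by raw QX.

``effPerm``
    Each permutation assigns every model variant an effect-size magnitude
    drawn from the pool of all models' |weights| while keeping the variant's
    original sign; QX is recomputed (Z' and VA both change). This conditions
    on allele frequencies and tests for coordinated multi-variant shifts;
    by scale invariance it returns P = 1 for single-variant genes.

Empirical P-values use the (r+1)/(n+1) convention and escalate from
``n_initial`` (default 100,000) to ``n_max`` (default 1,000,000) fresh
permutations whenever P falls below ``escalate_below`` (default 1e-4).
FDR control is Benjamini-Hochberg.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd
import scipy.linalg
import scipy.stats

from . import qx as qxm
from .errors import (
    DegenerateGeneError,
    MissingVariantError,
    SingularCovarianceError,
    ValidationError,
)
from .models import FrequencyPanel, GeneModel
from .neutral import NeutralCovariance, build_bin_index, match_neutral_variants, estimate_F_arrays

logger = logging.getLogger(__name__)

#: relative tolerance when counting null draws >= observed (absorbs float
#: rounding so exact invariances, e.g. single-variant effPerm, give P = 1)
_GE_RTOL = 1e-9


@dataclass
class PermutationConfig:
    n_initial: int = 100_000
    n_max: int = 1_000_000
    escalate_below: float = 1e-4
    seed: int = 0

    def __post_init__(self):
        if self.n_initial > self.n_max:
            raise ValidationError("n_initial must be <= n_max")
        if not (0.0 < self.escalate_below < 1.0):
            raise ValidationError("escalate_below must be in (0,1)")


@dataclass
class GammaFit:
    shape: float
    scale: float
    n_scores: int
    fit_log_likelihood: float
    n_excluded: int = 0
    method: str = "mle"


# ---------------------------------------------------------------------------
# empirical permutation machinery
# ---------------------------------------------------------------------------

def _empirical_pvalue(
    qx_obs: float,
    draw_null: Callable[[int, np.random.Generator], np.ndarray],
    cfg: PermutationConfig,
    rng: np.random.Generator,
) -> float:
    """(r+1)/(n+1) empirical P with adaptive escalation to n_max fresh draws."""
    thresh = qx_obs * (1.0 - _GE_RTOL) - 1e-12
    n = cfg.n_initial
    r = int(np.sum(draw_null(n, rng) >= thresh))
    p = (1.0 + r) / (1.0 + n)
    if p < cfg.escalate_below and cfg.n_max > n:
        n = cfg.n_max
        r = int(np.sum(draw_null(n, rng) >= thresh))
        p = (1.0 + r) / (1.0 + n)
    return p


def _chunked(total: int, chunk: int):
    done = 0
    while done < total:
        take = min(chunk, total - done)
        yield take
        done += take


def freqperm_pvalue(
    weights: np.ndarray,
    obs_freqs: np.ndarray,
    F: np.ndarray | NeutralCovariance,
    matched_freqs: np.ndarray,
    cfg: PermutationConfig | None = None,
    rng: np.random.Generator | int | None = None,
) -> float:
    """freqPerm empirical P-value for one gene.

    Parameters
    ----------
    weights : (L,) effect sizes.
    obs_freqs : (L, M) observed frequencies.
    matched_freqs : (L, k, M) frequency vectors of the k matched neutral
        variants for each model variant.
    """
    cfg = cfg or PermutationConfig()
    rng = np.random.default_rng(cfg.seed if rng is None else rng)
    w = np.asarray(weights, dtype=float)
    P = np.asarray(obs_freqs, dtype=float)
    A = np.asarray(matched_freqs, dtype=float)
    L, k, M = A.shape
    Fm = getattr(F, "matrix", F)
    cho = scipy.linalg.cho_factor(Fm, check_finite=False)

    va_obs = qxm.additive_variance(w, P.mean(axis=1))
    zt = qxm.center_and_drop(qxm.genetic_values(w, P))
    qx_obs = float(zt @ scipy.linalg.cho_solve(cho, zt, check_finite=False)) / (2 * va_obs)

    lidx = np.arange(L)
    chunk = max(256, int(4e6 / max(L * M, 1)))

    def draw_null(n: int, rng: np.random.Generator) -> np.ndarray:
        out = np.empty(n)
        pos = 0
        for take in _chunked(n, chunk):
            idx = rng.integers(0, k, size=(take, L))
            Pp = A[lidx[None, :], idx, :]  # (take, L, M)
            z = 2.0 * np.einsum("l,nlm->nm", w, Pp)
            eps = Pp.mean(axis=2)
            va = 2.0 * (w**2 * eps * (1.0 - eps)).sum(axis=1)
            x = z - z.mean(axis=1, keepdims=True)
            xd = x[:, :-1]
            quad = np.einsum(
                "ij,ji->i", xd, scipy.linalg.cho_solve(cho, xd.T, check_finite=False)
            )
            with np.errstate(divide="ignore", invalid="ignore"):
                q = np.where(va > 0, quad / (2.0 * va), 0.0)
            out[pos : pos + take] = q
            pos += take
        return out

    return _empirical_pvalue(qx_obs, draw_null, cfg, rng)


def effperm_pvalue(
    weights: np.ndarray,
    obs_freqs: np.ndarray,
    F: np.ndarray | NeutralCovariance,
    effect_pool: np.ndarray,
    cfg: PermutationConfig | None = None,
    rng: np.random.Generator | int | None = None,
) -> float:
    """effPerm empirical P-value for one gene.

    ``effect_pool`` is the pool of effect sizes from all models; magnitudes
    are sampled from |pool| with replacement, independently per variant per
    permutation, and each variant keeps its original effect direction.
    """
    cfg = cfg or PermutationConfig()
    rng = np.random.default_rng(cfg.seed if rng is None else rng)
    w = np.asarray(weights, dtype=float)
    P = np.asarray(obs_freqs, dtype=float)
    pool = np.abs(np.asarray(effect_pool, dtype=float))
    pool = pool[np.isfinite(pool) & (pool > 0)]
    if pool.size == 0:
        raise ValidationError("effect pool is empty")
    L, M = P.shape
    sign = np.sign(w)
    eps = P.mean(axis=1)
    het = eps * (1.0 - eps)
    Fm = getattr(F, "matrix", F)
    cho = scipy.linalg.cho_factor(Fm, check_finite=False)

    va_obs = qxm.additive_variance(w, eps)
    zt = qxm.center_and_drop(qxm.genetic_values(w, P))
    qx_obs = float(zt @ scipy.linalg.cho_solve(cho, zt, check_finite=False)) / (2 * va_obs)

    chunk = max(1024, int(8e6 / max(L, 1)))

    def draw_null(n: int, rng: np.random.Generator) -> np.ndarray:
        out = np.empty(n)
        pos = 0
        for take in _chunked(n, chunk):
            mags = pool[rng.integers(0, pool.size, size=(take, L))]
            alpha = sign[None, :] * mags
            z = 2.0 * alpha @ P  # (take, M)
            va = 2.0 * (alpha**2) @ het
            x = z - z.mean(axis=1, keepdims=True)
            xd = x[:, :-1]
            quad = np.einsum(
                "ij,ji->i", xd, scipy.linalg.cho_solve(cho, xd.T, check_finite=False)
            )
            with np.errstate(divide="ignore", invalid="ignore"):
                q = np.where(va > 0, quad / (2.0 * va), 0.0)
            out[pos : pos + take] = q
            pos += take
        return out

    return _empirical_pvalue(qx_obs, draw_null, cfg, rng)


# ---------------------------------------------------------------------------
# gamma correction and FDR
# ---------------------------------------------------------------------------

def gamma_pvalues(
    qx_scores: np.ndarray | Sequence[float], min_scores: int = 50
) -> tuple[GammaFit, np.ndarray]:
    """Fit a gamma (location pinned at 0) to the QX scores by maximum
    likelihood and return each score's upper-tail probability.

    Non-positive scores are excluded from the fit (with the count reported)
    and receive P = 1. A method-of-moments fit is the logged fallback when
    the MLE does not converge.
    """
    scores = np.asarray(qx_scores, dtype=float)
    pos = scores[np.isfinite(scores) & (scores > 0)]
    n_excluded = scores.size - pos.size
    if pos.size < min_scores:
        raise ValidationError(
            f"need at least {min_scores} positive QX scores to fit the gamma; got {pos.size}"
        )
    if np.ptp(pos) == 0.0:
        raise ValidationError("all QX scores identical; gamma fit is degenerate")
    method = "mle"
    try:
        shape, loc, scale = scipy.stats.gamma.fit(pos, floc=0)
        if not (np.isfinite(shape) and np.isfinite(scale) and shape > 0 and scale > 0):
            raise ValueError("non-finite MLE")
    except Exception as exc:  # pragma: no cover - scipy MLE rarely fails
        logger.warning("gamma MLE failed (%s); falling back to method of moments", exc)
        mean, var = pos.mean(), pos.var(ddof=1)
        if var <= 0:
            raise ValidationError("gamma fit failed: zero variance in scores") from exc
        shape, scale = mean**2 / var, var / mean
        method = "mom"
    loglik = float(np.sum(scipy.stats.gamma.logpdf(pos, shape, scale=scale)))
    fit = GammaFit(
        shape=float(shape),
        scale=float(scale),
        n_scores=int(pos.size),
        fit_log_likelihood=loglik,
        n_excluded=int(n_excluded),
        method=method,
    )
    with np.errstate(invalid="ignore"):
        pvals = np.where(
            np.isfinite(scores) & (scores > 0),
            scipy.stats.gamma.sf(scores, fit.shape, scale=fit.scale),
            1.0,
        )
    return fit, pvals


def bh_fdr(pvalues: np.ndarray | Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values (monotone in P-rank)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any(~np.isfinite(p)) or np.any(p <= 0) or np.any(p > 1):
        raise ValidationError("P-values must lie in (0, 1]")
    return scipy.stats.false_discovery_control(p, method="bh")


# ---------------------------------------------------------------------------
# genome scan orchestration
# ---------------------------------------------------------------------------

RESULT_COLUMNS = [
    "gene_id",
    "n_variants",
    "qx",
    "va",
    "fst_component",
    "ld_component",
    "p_gamma",
    "p_freqperm",
    "p_effperm",
    "q_gamma",
    "status",
]


@dataclass
class ScanConfig:
    schemes: tuple[str, ...] = ("gamma",)
    k_matched: int = 100
    folded_bins: bool = True
    perm: PermutationConfig = field(default_factory=PermutationConfig)
    seed: int = 0
    gamma_min_scores: int = 10
    shared_f: bool = False  # one genome-wide F from the full neutral panel

    def __post_init__(self):
        bad = set(self.schemes) - {"gamma", "freqperm", "effperm"}
        if bad:
            raise ValidationError(f"unknown P-value scheme(s): {sorted(bad)}")


@dataclass
class ScanResult:
    table: pd.DataFrame
    gamma_fit: GammaFit | None
    diagnostics: dict


def scan(
    models: Sequence[GeneModel],
    panel: FrequencyPanel,
    neutral_panel: FrequencyPanel | None,
    cfg: ScanConfig | None = None,
) -> ScanResult:
    """Per-gene QX scan with the requested P-value schemes and BH FDR.

    Degenerate genes (zero VA, missing variants, singular F) are emitted
    with status flags rather than silently dropped; the scan continues past
    per-gene failures. Deterministic under ``cfg.seed``. The Spearman rank
    correlation between each pair of computed P-value schemes is reported in
    ``diagnostics``.
    """
    cfg = cfg or ScanConfig()
    if neutral_panel is None:
        raise ValidationError("scan requires a neutral panel to estimate F")

    bin_index = build_bin_index(neutral_panel, folded=cfg.folded_bins)
    # reference frequencies for binning the *model* variants
    if panel.ref_freq is not None and not panel.ref_freq.isna().all():
        model_ref = panel.ref_freq
    else:
        model_ref = panel.mean_freq
    # a sample frequency of exactly 0/1 still belongs in the extreme bin
    model_ref = model_ref.clip(1e-9, 1.0 - 1e-9)
    shared_F = estimate_F_arrays(
        neutral_panel.freqs.to_numpy(dtype=float), neutral_panel.populations
    ) if cfg.shared_f else None

    ss = np.random.SeedSequence(cfg.seed)
    child_seeds = ss.spawn(len(models))

    effect_pool = np.concatenate([m.weights for m in models]) if models else np.array([])

    rows: list[dict] = []
    for model, child in zip(models, child_seeds):
        rng = np.random.default_rng(child)
        row: dict = {
            "gene_id": model.gene_id,
            "n_variants": model.n_variants,
            "qx": np.nan,
            "va": np.nan,
            "fst_component": np.nan,
            "ld_component": np.nan,
            "p_gamma": np.nan,
            "p_freqperm": np.nan,
            "p_effperm": np.nan,
            "q_gamma": np.nan,
            "status": "ok",
        }
        try:
            freqs = panel.freq_matrix(model.variant_ids)
            va = qxm.additive_variance(model.weights, freqs.mean(axis=1))
            matched = match_neutral_variants(
                model, bin_index, model_ref, k=cfg.k_matched, rng=rng
            )
            matched_ids = [vid for v in model.variant_ids for vid in matched[v]]
            if shared_F is not None:
                F = shared_F
            else:
                F = estimate_F_arrays(
                    neutral_panel.freqs.loc[matched_ids].to_numpy(dtype=float),
                    neutral_panel.populations,
                )
            zt = qxm.center_and_drop(qxm.genetic_values(model.weights, freqs))
            row["qx"] = qxm.qx_statistic(zt, F.matrix, va)
            fst, ld = qxm.decompose_qx_arrays(model.weights, freqs, F.matrix, va)
            row.update(va=va, fst_component=fst, ld_component=ld)
            if "freqperm" in cfg.schemes:
                A = np.stack(
                    [
                        neutral_panel.freqs.loc[matched[v]].to_numpy(dtype=float)
                        for v in model.variant_ids
                    ]
                )
                row["p_freqperm"] = freqperm_pvalue(
                    model.weights, freqs, F.matrix, A, cfg.perm, rng
                )
            if "effperm" in cfg.schemes:
                row["p_effperm"] = effperm_pvalue(
                    model.weights, freqs, F.matrix, effect_pool, cfg.perm, rng
                )
        except MissingVariantError as exc:
            row["status"] = "missing_variants"
            logger.warning("gene %s: %s", model.gene_id, exc)
        except DegenerateGeneError as exc:
            row["status"] = "degenerate_va"
            logger.warning("gene %s: %s", model.gene_id, exc)
        except SingularCovarianceError as exc:
            row["status"] = "singular_f"
            logger.warning("gene %s: %s", model.gene_id, exc)
        rows.append(row)

    table = pd.DataFrame(rows, columns=RESULT_COLUMNS)

    gamma_fit = None
    if "gamma" in cfg.schemes:
        ok = table["status"].eq("ok") & table["qx"].notna()
        if ok.sum() >= cfg.gamma_min_scores:
            gamma_fit, pvals = gamma_pvalues(
                table.loc[ok, "qx"].to_numpy(), min_scores=cfg.gamma_min_scores
            )
            table.loc[ok, "p_gamma"] = pvals
            table.loc[ok, "q_gamma"] = bh_fdr(table.loc[ok, "p_gamma"].to_numpy())
        else:
            logger.warning(
                "gamma scheme skipped: only %d usable genes (< %d)",
                int(ok.sum()),
                cfg.gamma_min_scores,
            )

    diagnostics: dict = {}
    schemes_present = [
        c for c in ("p_gamma", "p_freqperm", "p_effperm") if table[c].notna().any()
    ]
    for i, a in enumerate(schemes_present):
        for b in schemes_present[i + 1 :]:
            both = table[a].notna() & table[b].notna()
            if both.sum() >= 3:
                rho = scipy.stats.spearmanr(table.loc[both, a], table.loc[both, b]).statistic
                diagnostics[f"spearman_{a[2:]}_{b[2:]}"] = float(rho)
    return ScanResult(table=table, gamma_fit=gamma_fit, diagnostics=diagnostics)


def write_results(
    table: pd.DataFrame, path, provenance: str | None = None
) -> None:
    """Write a results table as TSV with an optional commented provenance line."""
    with open(path, "w") as fh:
        if provenance:
            fh.write(f"# {provenance}\n")
        table.to_csv(fh, sep="\t", index=False)


def read_results(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")
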