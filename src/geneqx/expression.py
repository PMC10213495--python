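"""Predicted expression per individual, population summaries, per-variant
contribution matrices, and the observed-vs-predicted agreement test.

Prediction is the weights-only linear model: for individual i with
effect-allele dosages g_il in [0, 2], prediction_i = sum_l alpha_l g_il
(no intercept; missing dosages are mean-imputed from the cohort). Population
summaries are per-population medians; for display a per-gene z-scored copy
across populations is kept.

The agreement statistic is the sum over genes of the Spearman correlation
between observed and predicted per-population medians; its null is built by
shuffling the observed medians' population labels (independently per gene by
default) and its P-value is empirical, (1 + #{null >= observed})/(1 + n).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats

from .errors import ValidationError
from .models import FrequencyPanel, GeneModel

logger = logging.getLogger(__name__)


@dataclass
class ExpressionMatrix:
    """individuals x genes expression values with a population assignment."""

    values: pd.DataFrame
    population_of: pd.Series

    def __post_init__(self):
        missing = self.values.index.difference(self.population_of.index)
        if len(missing):
            raise ValidationError(
                f"individuals without population assignment: {list(missing[:5])}"
            )
        self.population_of = self.population_of.loc[self.values.index]


@dataclass
class PopulationSummary:
    """Per-population medians (populations x genes) and a per-gene
    standardized copy (z-scored across populations; zero where sd = 0)."""

    medians: pd.DataFrame
    standardized: pd.DataFrame


def predict_expression(model: GeneModel, dosages: pd.DataFrame) -> pd.Series:
    """Predicted expression per individual from a dosage matrix whose
    columns cover the model's variants."""
    ids = model.variant_ids
    missing = [v for v in ids if v not in dosages.columns]
    if missing:
        raise ValidationError(f"dosage matrix lacks model variants: {missing[:5]}")
    D = dosages[ids].to_numpy(dtype=float)
    finite = np.isfinite(D)
    if ((D < 0) | (D > 2))[finite].any():
        raise ValidationError("dosages must lie in [0, 2]")
    n_missing = int((~finite).sum())
    if n_missing:
        logger.info("predict_expression: mean-imputing %d missing dosages", n_missing)
        col_mean = np.nanmean(np.where(finite, D, np.nan), axis=0)
        col_mean = np.where(np.isfinite(col_mean), col_mean, 0.0)
        D = np.where(finite, D, col_mean[None, :])
    pred = D @ model.weights
    return pd.Series(pred, index=dosages.index, name=model.gene_id)


def predict_matrix(
    models: list[GeneModel], dosages: pd.DataFrame, population_of: pd.Series
) -> ExpressionMatrix:
    cols = {m.gene_id: predict_expression(m, dosages) for m in models}
    return ExpressionMatrix(values=pd.DataFrame(cols), population_of=population_of)


def summarize_populations(expr: ExpressionMatrix) -> PopulationSummary:
    """Per-population median expression per gene, plus the standardized
    (per-gene z-scored) copy. Errors on empty populations."""
    groups = expr.values.groupby(expr.population_of)
    sizes = groups.size()
    declared = pd.unique(expr.population_of)
    empty = [p for p in declared if p not in sizes.index or sizes[p] == 0]
    if empty:
        raise ValidationError(f"empty population(s): {empty}")
    med = groups.median()
    sd = med.std(axis=0, ddof=1)
    centered = med - med.mean(axis=0)
    std = centered.div(sd.replace(0.0, np.nan), axis=1).fillna(0.0)
    return PopulationSummary(medians=med, standardized=std)


def contribution_matrix(model: GeneModel, panel: FrequencyPanel) -> pd.DataFrame:
    """Per-variant, per-population contribution alpha_l * p_ml, mean-centered
    within each variant (row sums are zero)."""
    P = panel.freq_matrix(model.variant_ids)
    C = model.weights[:, None] * P
    C = C - C.mean(axis=1, keepdims=True)
    return pd.DataFrame(C, index=model.variant_ids, columns=panel.populations)


def _rank_rows(X: np.ndarray) -> np.ndarray:
    return np.apply_along_axis(scipy.stats.rankdata, 1, X)


def agreement_test(
    observed: PopulationSummary,
    predicted: PopulationSummary,
    n_shuffles: int = 10_000,
    seed: int | None = None,
    per_gene_shuffle: bool = True,
) -> tuple[float, float]:
    """Summed per-gene Spearman correlation between observed and predicted
    population medians, with an empirical permutation P-value.

    Genes whose medians are constant in either matrix (undefined rank
    correlation) are skipped with a warning. Requires >= 3 shared
    populations. Returns (sum_of_correlations, empirical_p).
    """
    genes = observed.medians.columns.intersection(predicted.medians.columns)
    pops = observed.medians.index.intersection(predicted.medians.index)
    if len(pops) < 3:
        raise ValidationError("agreement test needs at least 3 shared populations")
    if len(genes) == 0:
        raise ValidationError("no shared genes")
    O = observed.medians.loc[pops, genes].to_numpy(dtype=float).T  # genes x pops
    Pr = predicted.medians.loc[pops, genes].to_numpy(dtype=float).T
    keep = (np.ptp(O, axis=1) > 0) & (np.ptp(Pr, axis=1) > 0)
    n_skipped = int((~keep).sum())
    if n_skipped:
        logger.warning(
            "agreement_test: skipped %d gene(s) with constant medians", n_skipped
        )
    O, Pr = O[keep], Pr[keep]
    if O.shape[0] == 0:
        raise ValidationError("no genes with non-constant medians")
    RO = _rank_rows(O)
    RP = _rank_rows(Pr)
    RO = RO - RO.mean(axis=1, keepdims=True)
    RP = RP - RP.mean(axis=1, keepdims=True)
    denom = np.sqrt((RO**2).sum(axis=1) * (RP**2).sum(axis=1))
    stat = float(((RO * RP).sum(axis=1) / denom).sum())

    rng = np.random.default_rng(seed)
    G, M = RO.shape
    null = np.empty(n_shuffles)
    chunk = max(1, int(2e6 / (G * M)))
    done = 0
    while done < n_shuffles:
        take = min(chunk, n_shuffles - done)
        if per_gene_shuffle:
            perm = rng.permuted(
                np.broadcast_to(RO, (take, G, M)).copy(), axis=2
            )  # shuffle pop labels independently per gene
        else:
            cols = np.argsort(rng.random((take, M)), axis=1)
            perm = RO[None, :, :][np.zeros(take, int)[:, None, None],
                                  np.arange(G)[None, :, None],
                                  cols[:, None, :]]
        rho = (perm * RP[None, :, :]).sum(axis=2) / denom[None, :]
        null[done : done + take] = rho.sum(axis=1)
        done += take
    p = (1.0 + np.sum(null >= stat - 1e-12)) / (1.0 + n_shuffles)
    return stat, float(p)
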