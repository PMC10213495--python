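"""Tiered gene-set enrichment over a ranked scan.

Genes are ranked by ascending P-value (ties broken by gene_id so tiers are
deterministic); for each tier size N the enrichment is the proportion of
set members among the top N divided by the overall set proportion, with a
two-sided exact binomial P-value (success probability = overall proportion)
and a 95% Agresti-Coull interval on the top-N proportion.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import scipy.stats

from .errors import ValidationError

logger = logging.getLogger(__name__)

DEFAULT_TIERS = (10, 20, 30, 50, 75, 100, 150, 200, 300, 500,
                 1000, 2000, 3000, 5000, 10000)

#: two-sided 97.5% normal quantile used by the 95% Agresti-Coull interval
AC_Z = 1.959964


@dataclass
class EnrichmentTier:
    n: int
    in_set: int
    enrichment: float
    p: float
    ci_low: float
    ci_high: float


def agresti_coull(x: int, n: int, z: float = AC_Z) -> tuple[float, float]:
    """Agresti-Coull adjusted-count binomial interval, clipped to [0, 1]."""
    if not (0 <= x <= n) or n <= 0:
        raise ValidationError("need 0 <= x <= n, n > 0")
    n_t = n + z**2
    p_t = (x + z**2 / 2.0) / n_t
    half = z * np.sqrt(p_t * (1.0 - p_t) / n_t)
    return max(0.0, p_t - half), min(1.0, p_t + half)


def rank_genes(table: pd.DataFrame, p_column: str = "p_gamma") -> list[str]:
    """Gene ids ordered by ascending P (NaN last), ties broken by gene_id."""
    t = table[["gene_id", p_column]].copy()
    t = t.sort_values([p_column, "gene_id"], na_position="last", kind="mergesort")
    return t["gene_id"].astype(str).tolist()


def read_gene_set(path: str | Path) -> set[str]:
    """Gene-set file: one gene_id per line; blank lines and # comments
    ignored."""
    out = set()
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            out.add(line)
    return out


def tiered_enrichment(
    ranked_genes: Sequence[str],
    gene_set: Iterable[str],
    tiers: Sequence[int] = DEFAULT_TIERS,
) -> list[EnrichmentTier]:
    """Enrichment of ``gene_set`` within the top N of ``ranked_genes`` for
    each tier size N. Tiers larger than the ranked list are skipped with a
    warning."""
    ranked = [str(g) for g in ranked_genes]
    gene_set = {str(g) for g in gene_set}
    members = np.array([g in gene_set for g in ranked])
    total_in = int(members.sum())
    if total_in == 0:
        raise ValidationError("gene set does not intersect the ranked gene list")
    overall = total_in / len(ranked)
    cum = np.cumsum(members)
    out: list[EnrichmentTier] = []
    for n in tiers:
        if n > len(ranked):
            logger.warning("tier %d exceeds the %d ranked genes; skipped", n, len(ranked))
            continue
        x = int(cum[n - 1])
        enr = (x / n) / overall
        p = float(scipy.stats.binomtest(x, n, overall, alternative="two-sided").pvalue)
        lo, hi = agresti_coull(x, n)
        out.append(EnrichmentTier(n=n, in_set=x, enrichment=enr, p=p, ci_low=lo, ci_high=hi))
    return out


def enrichment_table(tiers: list[EnrichmentTier], set_name: str = "") -> pd.DataFrame:
    df = pd.DataFrame([t.__dict__ for t in tiers])
    if set_name:
        df.insert(0, "gene_set", set_name)
    return df
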