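"""Frequency-matched neutral variants and the neutral covariance matrix F.

The null model for drift is the (M-1)x(M-1) covariance of standardized,
centered neutral allele frequencies. For each model variant we draw k
(default 100) neutral variants from the same reference-frequency bin
(25 bins of width 0.02 on folded frequency by default), and estimate

    F = (1/(K-1)) * sum_i y_i y_i^T,   y_i = T[(p_i. - eps_i)/sqrt(eps_i(1-eps_i))]

over the K usable matched variants, where T centers (the standardized vector
already sums to ~0 because eps_i is the variant's own across-population mean)
and drops the last entry. Variants fixed across all populations are skipped
and counted.

Binning is on folded frequency (minor-allele frequency) by default: 25 bins
of width 0.02 exactly tile (0, 0.5]. An unfolded mode with 50 bins over
(0, 1] is available.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import SingularCovarianceError, ValidationError
from .models import FrequencyPanel, GeneModel

logger = logging.getLogger(__name__)

BIN_WIDTH = 0.02
N_BINS_FOLDED = 25
N_BINS_UNFOLDED = 50

#: warn when fewer matched variants than this multiple of (M-1) are available
MIN_NEUTRAL_FACTOR = 10


@dataclass
class NeutralCovariance:
    """Estimated neutral covariance F with its population convention."""

    matrix: np.ndarray
    population_order: tuple[str, ...]
    dropped_index: int
    n_neutral: int

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=float)
        m = self.matrix
        if m.ndim != 2 or m.shape[0] != m.shape[1]:
            raise ValidationError("F must be square")
        if not np.allclose(m, m.T, atol=1e-12):
            raise ValidationError("F must be symmetric")
        if self.n_neutral < MIN_NEUTRAL_FACTOR * m.shape[0]:
            logger.warning(
                "F estimated from only %d neutral variants for %d populations",
                self.n_neutral,
                m.shape[0] + 1,
            )


@dataclass
class FrequencyBinIndex:
    """Assignment of neutral variants to reference-frequency bins."""

    bin_edges: np.ndarray
    members: list[list[str]]
    folded: bool = True

    @property
    def n_bins(self) -> int:
        return len(self.members)

    def bin_sizes(self) -> np.ndarray:
        return np.array([len(m) for m in self.members])


def assign_bin(freq: float, folded: bool = True) -> int:
    """Bin index for a reference frequency: floor(min(f, 1-f)/0.02) folded
    (capped at 24), or floor(f/0.02) unfolded (capped at 49)."""
    if not (0.0 < freq < 1.0):
        raise ValidationError(f"reference frequency must be in (0,1), got {freq}")
    f = min(freq, 1.0 - freq) if folded else freq
    n_bins = N_BINS_FOLDED if folded else N_BINS_UNFOLDED
    return min(int(f / BIN_WIDTH), n_bins - 1)


def build_bin_index(
    neutral_panel: FrequencyPanel,
    ref_freqs: pd.Series | None = None,
    folded: bool = True,
) -> FrequencyBinIndex:
    """Index the neutral panel's variants by reference-frequency bin.

    ``ref_freqs`` defaults to the panel's ``ref_freq`` column if present,
    else the across-population mean frequency.
    """
    if len(neutral_panel) == 0:
        raise ValidationError("neutral panel is empty")
    if ref_freqs is None:
        ref_freqs = (
            neutral_panel.ref_freq
            if neutral_panel.ref_freq is not None and not neutral_panel.ref_freq.isna().any()
            else neutral_panel.mean_freq
        )
    n_bins = N_BINS_FOLDED if folded else N_BINS_UNFOLDED
    members: list[list[str]] = [[] for _ in range(n_bins)]
    for vid, f in ref_freqs.items():
        f = float(f)
        if not (0.0 < f < 1.0):
            continue  # fixed in the reference: unusable for matching
        members[assign_bin(f, folded)].append(str(vid))
    edges = np.arange(n_bins + 1) * BIN_WIDTH
    return FrequencyBinIndex(bin_edges=edges, members=members, folded=folded)


def _nearest_nonempty(index: FrequencyBinIndex, b: int) -> int:
    sizes = index.bin_sizes()
    if sizes[b] > 0:
        return b
    order = np.argsort(np.abs(np.arange(index.n_bins) - b), kind="stable")
    for cand in order:
        if sizes[cand] > 0:
            logger.warning("bin %d empty; falling back to nearest non-empty bin %d", b, cand)
            return int(cand)
    raise ValidationError("all frequency bins are empty")


def match_neutral_variants(
    model: GeneModel,
    index: FrequencyBinIndex,
    ref_freqs: Mapping[str, float] | pd.Series,
    k: int = 100,
    rng: np.random.Generator | int | None = None,
) -> dict[str, list[str]]:
    """For each model variant, k neutral variants sampled uniformly from its
    reference-frequency bin.

    Sampling is without replacement, falling back to with-replacement (with a
    warning) when the bin holds fewer than k variants; empty bins fall back
    to the nearest non-empty bin. Reproducible under a seed.
    """
    rng = np.random.default_rng(rng)
    matched: dict[str, list[str]] = {}
    for v in model.variants:
        if v.variant_id not in ref_freqs:
            raise ValidationError(
                f"no reference frequency for model variant {v.variant_id}"
            )
        b = _nearest_nonempty(index, assign_bin(float(ref_freqs[v.variant_id]), index.folded))
        pool = index.members[b]
        if len(pool) >= k:
            picks = rng.choice(len(pool), size=k, replace=False)
        else:
            logger.warning(
                "bin %d has only %d variants (< k=%d); sampling with replacement",
                b,
                len(pool),
                k,
            )
            picks = rng.integers(0, len(pool), size=k)
        matched[v.variant_id] = [pool[i] for i in picks]
    return matched


def estimate_F_arrays(
    freqs: np.ndarray, population_order: Sequence[str] | None = None
) -> NeutralCovariance:
    """Estimate F from a (K, M) matrix of neutral-variant frequencies.

    Each usable variant (0 < eps < 1) contributes the standardized vector
    y = ((p - eps)/sqrt(eps(1-eps)))[:-1]; F = Y^T Y / (K_use - 1). Variants
    fixed across all populations are skipped and counted in the log.
    """
    P = np.asarray(freqs, dtype=float)
    if P.ndim != 2 or P.shape[1] < 2:
        raise ValidationError("need a (K, M>=2) frequency matrix")
    M = P.shape[1]
    eps = P.mean(axis=1)
    usable = (eps > 0.0) & (eps < 1.0)
    n_skipped = int((~usable).sum())
    if n_skipped:
        logger.info("estimate_F: skipped %d variants fixed across all populations", n_skipped)
    K = int(usable.sum())
    if K < M:
        raise SingularCovarianceError(
            f"only {K} usable neutral variants for {M} populations; F would be singular"
        )
    Pu = P[usable]
    epsu = eps[usable]
    Y = (Pu - epsu[:, None]) / np.sqrt(epsu * (1.0 - epsu))[:, None]
    Yd = Y[:, :-1]
    F = (Yd.T @ Yd) / (K - 1)
    F = (F + F.T) / 2.0  # exact symmetry
    eig = np.linalg.eigvalsh(F)
    if eig[-1] <= 0 or eig[0] <= 1e-10 * eig[-1]:
        raise SingularCovarianceError(
            "estimated F is singular beyond tolerance; use more matched neutral variants"
        )
    pops = tuple(population_order) if population_order is not None else tuple(
        f"P{i+1}" for i in range(M)
    )
    return NeutralCovariance(
        matrix=F, population_order=pops, dropped_index=M - 1, n_neutral=K
    )


def estimate_F(panel: FrequencyPanel) -> NeutralCovariance:
    """Estimate F from a frequency panel restricted to matched neutral
    variants."""
    return estimate_F_arrays(panel.freqs.to_numpy(dtype=float), panel.populations)


def matched_F(
    model: GeneModel,
    neutral_panel: FrequencyPanel,
    index: FrequencyBinIndex,
    ref_freqs: Mapping[str, float] | pd.Series,
    k: int = 100,
    rng: np.random.Generator | int | None = None,
) -> tuple[NeutralCovariance, dict[str, list[str]]]:
    """Convenience: match neutral variants for a model and estimate F from
    the pooled k*L matched set."""
    matched = match_neutral_variants(model, index, ref_freqs, k=k, rng=rng)
    ids: list[str] = [vid for lst in matched.values() for vid in lst]
    F = estimate_F_arrays(
        neutral_panel.freqs.loc[ids].to_numpy(dtype=float), neutral_panel.populations
    )
    return F, matched
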