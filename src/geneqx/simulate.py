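"""Forward Wright-Fisher simulation of a gene under stabilizing selection on
expression, with a population split and a fitness-optimum shift (FOS) in the
last subpopulation, plus a power-evaluation harness.

The default parameterization is the full study design: an ancestral
population of 10,000 diploids carrying a 1 Mb "gene" (eQTL mutations with
standard-normal effect sizes) and a disjoint 100 kb neutral segment, evolved
for 20,000 burn-in generations (mu = 8e-9/bp/gen, r = 1e-7) under Gaussian
stabilizing selection (optimum 0, sd 1), then split into 5 subpopulations of
10,000 that evolve independently for 400 generations with rates lowered to
mu = 1e-10 and r = 1e-8; the optimum is shifted by ``fos`` in the last
subpopulation only. That parameterization is cluster-scale; the ``rescale``
knob divides N and all generation counts by a factor and multiplies the
per-generation rates by the same factor, preserving N*mu and N*r (selection
coefficients are not rescaled, as the fitness function is part of the study
design).

At the end of a run the position, per-subpopulation frequency, and effect
size of every mutation still segregating somewhere are reported.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import qx as qxm
from ._wf import count_occupancy, run_wf
from .errors import DegenerateGeneError, SingularCovarianceError, ValidationError
from .neutral import estimate_F_arrays

logger = logging.getLogger(__name__)


@dataclass
class SimulationConfig:
    n_diploid: int = 10_000
    burn_in_generations: int = 20_000
    post_split_generations: int = 400
    n_subpops: int = 5
    gene_length_bp: int = 1_000_000
    neutral_length_bp: int = 100_000
    mu_burn_in: float = 8e-9
    r_burn_in: float = 1e-7
    mu_post_split: float = 1e-10
    r_post_split: float = 1e-8
    fitness_sd: float = 1.0
    fos: float = 0.0
    effect_sd: float = 1.0  # eQTL effects ~ Normal(0, effect_sd^2)
    seed: int = 0
    rescale: float = 1.0

    def __post_init__(self):
        for name in ("mu_burn_in", "r_burn_in", "mu_post_split", "r_post_split"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0")
        if self.fos < 0:
            raise ValidationError("fos must be >= 0")
        if self.rescale <= 0:
            raise ValidationError("rescale must be positive")
        if self.n_subpops < 2:
            raise ValidationError("need at least 2 subpopulations")

    def resolved(self) -> dict:
        """Population-scaled parameters after applying ``rescale``."""
        c = self.rescale
        n = max(2, int(round(self.n_diploid / c)))
        burn = max(1, int(round(self.burn_in_generations / c)))
        post = max(1, int(round(self.post_split_generations / c)))
        return dict(
            n_diploid=n,
            burn_in=burn,
            post_split=post,
            mu_burn=self.mu_burn_in * c,
            r_burn=self.r_burn_in * c,
            mu_post=self.mu_post_split * c,
            r_post=self.r_post_split * c,
        )

    @property
    def population_labels(self) -> tuple[str, ...]:
        return tuple(f"P{i+1}" for i in range(self.n_subpops))


@dataclass
class SimulatedGene:
    """End-of-simulation variants: eQTLs (with effects) and neutral-segment
    mutations, with per-subpopulation frequencies."""

    eqtl: pd.DataFrame  # columns: position, effect, <pop labels>
    neutral: pd.DataFrame  # columns: position, <pop labels>
    fos: float
    seed: int
    populations: tuple[str, ...]

    def to_tsv(self, path: str | Path) -> None:
        e = self.eqtl.copy()
        e.insert(0, "segment", "gene")
        n = self.neutral.copy()
        n.insert(0, "segment", "neutral")
        n.insert(2, "effect", np.nan)
        pd.concat([e, n], ignore_index=True).to_csv(path, sep="\t", index=False, na_rep="NA")


def _capacities(cfg: SimulationConfig) -> tuple[int, int]:
    p = cfg.resolved()
    theta = 4.0 * p["n_diploid"] * (
        p["mu_burn"] * cfg.gene_length_bp + p["mu_burn"] * cfg.neutral_length_bp
    )
    hap_cap = int(4 * theta + 512)
    mut_cap = int(6 * theta * np.log(2.0 * p["n_diploid"] + 2) + 8192)
    return hap_cap, mut_cap


def simulate_gene(cfg: SimulationConfig) -> SimulatedGene:
    """Run one replicate "gene" and return its segregating variants."""
    p = cfg.resolved()
    H = 2 * p["n_diploid"]
    hap_cap, mut_cap = _capacities(cfg)
    gene_len = float(cfg.gene_length_bp)
    neu_start = gene_len
    neu_len = float(cfg.neutral_length_bp)

    ss = np.random.SeedSequence(cfg.seed)
    seeds = [int(s) for s in ss.generate_state(1 + cfg.n_subpops) % np.uint32(2**31 - 1)]

    mpos = np.zeros(mut_cap)
    meff = np.zeros(mut_cap)
    alive = np.zeros(mut_cap, dtype=np.bool_)
    free_ids = np.zeros(mut_cap, dtype=np.int32)
    state = np.zeros(2, dtype=np.int64)  # [n_mut, n_free]
    occ = np.zeros(mut_cap, dtype=np.int32)
    baseline = np.zeros(1)

    par = np.zeros((H, hap_cap), dtype=np.int32)
    parc = np.zeros(H, dtype=np.int32)
    bufA = np.zeros((H, hap_cap), dtype=np.int32)
    bufAc = np.zeros(H, dtype=np.int32)
    bufB = np.zeros((H, hap_cap), dtype=np.int32)
    bufBc = np.zeros(H, dtype=np.int32)

    err = run_wf(
        par, parc, bufA, bufAc, bufB, bufBc,
        mpos, meff, alive, free_ids, state, occ, baseline,
        p["burn_in"], gene_len, neu_start, neu_len,
        p["mu_burn"], p["mu_burn"], p["r_burn"], p["r_burn"],
        cfg.effect_sd, 0.0, cfg.fitness_sd, 1, seeds[0],
    )
    _check_err(err)
    if p["burn_in"] % 2 == 1:
        anc, ancc = bufA, bufAc
    else:
        anc, ancc = bufB, bufBc
    n_anc = int(state[0])
    anc_alive = alive.copy()

    pop_tables = []  # (occ_m, n_mut_m, mpos_m, meff_m)
    for m in range(cfg.n_subpops):
        mpos_m = mpos.copy()
        meff_m = meff.copy()
        alive_m = alive.copy()
        free_m = np.zeros(mut_cap, dtype=np.int32)  # no id reuse post-split
        state_m = np.array([n_anc, 0], dtype=np.int64)
        base_m = baseline.copy()
        sA = np.zeros((H, hap_cap), dtype=np.int32)
        sAc = np.zeros(H, dtype=np.int32)
        sB = np.zeros((H, hap_cap), dtype=np.int32)
        sBc = np.zeros(H, dtype=np.int32)
        opt = cfg.fos if m == cfg.n_subpops - 1 else 0.0
        err = run_wf(
            anc, ancc, sA, sAc, sB, sBc,
            mpos_m, meff_m, alive_m, free_m, state_m, occ, base_m,
            p["post_split"], gene_len, neu_start, neu_len,
            p["mu_post"], p["mu_post"], p["r_post"], p["r_post"],
            cfg.effect_sd, opt, cfg.fitness_sd, 0, seeds[1 + m],
        )
        _check_err(err)
        if p["post_split"] % 2 == 1:
            fin, finc = sA, sAc
        else:
            fin, finc = sB, sBc
        n_mut_m = int(state_m[0])
        occ_m = count_occupancy(fin, finc, n_mut_m)
        pop_tables.append((occ_m, n_mut_m, mpos_m, meff_m))

    # assemble the union of variants across subpopulations
    M = cfg.n_subpops
    rows_pos, rows_eff, rows_freq = [], [], []
    anc_ids = np.flatnonzero(anc_alive[:n_anc])
    for i in anc_ids:
        f = np.array([pt[0][i] / H for pt in pop_tables])
        rows_pos.append(mpos[i])
        rows_eff.append(meff[i])
        rows_freq.append(f)
    for m, (occ_m, n_mut_m, mpos_m, meff_m) in enumerate(pop_tables):
        for i in range(n_anc, n_mut_m):
            if occ_m[i] == 0:
                continue
            f = np.zeros(M)
            f[m] = occ_m[i] / H
            rows_pos.append(mpos_m[i])
            rows_eff.append(meff_m[i])
            rows_freq.append(f)

    pops = cfg.population_labels
    if rows_pos:
        freq = np.vstack(rows_freq)
        pos = np.asarray(rows_pos)
        eff = np.asarray(rows_eff)
        seg = ~(np.all(freq == 0.0, axis=1) | np.all(freq == 1.0, axis=1))
        freq, pos, eff = freq[seg], pos[seg], eff[seg]
        order = np.argsort(pos)
        freq, pos, eff = freq[order], pos[order], eff[order]
    else:
        freq = np.zeros((0, M))
        pos = np.zeros(0)
        eff = np.zeros(0)

    is_gene = pos < gene_len
    eqtl = pd.DataFrame({"position": pos[is_gene], "effect": eff[is_gene]})
    for j, lab in enumerate(pops):
        eqtl[lab] = freq[is_gene, j]
    neutral = pd.DataFrame({"position": pos[~is_gene]})
    for j, lab in enumerate(pops):
        neutral[lab] = freq[~is_gene, j]
    return SimulatedGene(
        eqtl=eqtl, neutral=neutral, fos=cfg.fos, seed=cfg.seed, populations=pops
    )


def _check_err(err: int) -> None:
    if err == 1:
        raise ValidationError(
            "haplotype capacity exceeded; increase rescale or lower mutation rates"
        )
    if err == 2:
        raise ValidationError("mutation-table capacity exceeded")


# ---------------------------------------------------------------------------
# QX on simulated genes
# ---------------------------------------------------------------------------

def qx_from_simulation(sim: SimulatedGene, min_maf: float = 0.0) -> qxm.QxResult:
    """QX for a simulated gene: the segregating eQTL mutations are the gene
    model (alpha = simulated effects), the subpopulations are the
    populations, and F is estimated directly from the neutral-segment
    variants (no frequency matching: the neutral segment is the
    simulation's own matched null)."""
    pops = list(sim.populations)
    P = sim.eqtl[pops].to_numpy(dtype=float)
    alpha = sim.eqtl["effect"].to_numpy(dtype=float)
    if min_maf > 0 and len(P):
        eps = P.mean(axis=1)
        keep = np.minimum(eps, 1 - eps) >= min_maf
        P, alpha = P[keep], alpha[keep]
    if P.shape[0] < 1:
        raise DegenerateGeneError("no segregating eQTL variants")
    N = sim.neutral[pops].to_numpy(dtype=float)
    if N.shape[0] < len(pops):
        raise SingularCovarianceError(
            f"only {N.shape[0]} neutral variants for {len(pops)} subpopulations"
        )
    F = estimate_F_arrays(N, pops)
    eps = P.mean(axis=1)
    va = qxm.additive_variance(alpha, eps)
    zt = qxm.center_and_drop(qxm.genetic_values(alpha, P))
    qx = qxm.qx_statistic(zt, F.matrix, va)
    fst, ld = qxm.decompose_qx_arrays(alpha, P, F.matrix, va)
    return qxm.QxResult(
        gene_id=f"sim_seed{sim.seed}",
        qx=qx,
        va=va,
        fst_component=fst,
        ld_component=ld,
        n_variants=int(P.shape[0]),
    )


# ---------------------------------------------------------------------------
# power harness
# ---------------------------------------------------------------------------

DEFAULT_FOS_GRID = (0.0, 0.01, 0.02, 0.05, 0.1, 0.2, 0.5, 1.0)


def simulate_replicates(
    cfg: SimulationConfig, fos: float, n_reps: int, seed: int
) -> list[SimulatedGene]:
    """n_reps independent replicate genes at one FOS (deterministic under
    seed)."""
    seeds = np.random.SeedSequence(seed).generate_state(n_reps) % np.uint32(2**31 - 1)
    return [
        simulate_gene(replace(cfg, fos=fos, seed=int(s))) for s in seeds
    ]


def power_curve(
    fos_grid: Sequence[float] = DEFAULT_FOS_GRID,
    n_reps: int = 100,
    scheme: str = "gamma",
    alpha: float = 1e-4,
    cfg: SimulationConfig | None = None,
    n_perm: int = 10_000,
    min_maf: float = 0.0,
) -> pd.DataFrame:
    """Power (fraction of non-degenerate replicates with P <= alpha) per FOS.

    Schemes: ``gamma`` fits the gamma null to the FOS=0 condition's scores
    when the grid includes it (the neutral reference; otherwise the pooled
    scores of the whole run) and evaluates every condition's upper-tail
    probabilities against that fit; ``effperm_matched`` draws effect
    magnitudes from same-FOS replicates; ``effperm_neutral`` draws them
    from the FOS=0 replicates (which must be part of the grid).
    """
    from .enrichment import agresti_coull
    from .pvalues import PermutationConfig, effperm_pvalue, gamma_pvalues

    if scheme not in ("gamma", "effperm_matched", "effperm_neutral"):
        raise ValidationError(f"unknown power scheme {scheme!r}")
    if n_reps < 20:
        raise ValidationError("need at least 20 replicates per condition")
    cfg = cfg or SimulationConfig()
    ss = np.random.SeedSequence(cfg.seed)
    cond_seeds = ss.generate_state(len(fos_grid)) % np.uint32(2**31 - 1)

    per_cond: dict[float, dict] = {}
    for fos, cseed in zip(fos_grid, cond_seeds):
        sims = simulate_replicates(cfg, float(fos), n_reps, int(cseed))
        scores, effects, payload = [], [], []
        n_degenerate = 0
        for sim in sims:
            try:
                res = qx_from_simulation(sim, min_maf=min_maf)
            except (DegenerateGeneError, SingularCovarianceError):
                n_degenerate += 1
                continue
            scores.append(res.qx)
            pops = list(sim.populations)
            eff = sim.eqtl["effect"].to_numpy(dtype=float)
            effects.append(eff)
            payload.append(
                (eff, sim.eqtl[pops].to_numpy(dtype=float), sim.neutral[pops].to_numpy(dtype=float))
            )
        if not scores:
            raise ValidationError(f"all replicates degenerate at FOS={fos}")
        per_cond[float(fos)] = dict(
            scores=np.asarray(scores),
            effect_pool=np.concatenate(effects) if effects else np.array([]),
            payload=payload,
            n_degenerate=n_degenerate,
            seed=int(cseed),
        )

    rows = []
    if scheme == "gamma":
        if 0.0 in per_cond:
            ref = per_cond[0.0]["scores"]
        else:
            ref = np.concatenate([c["scores"] for c in per_cond.values()])
        fit, _ = gamma_pvalues(ref, min_scores=10)
        import scipy.stats

        for fos, c in per_cond.items():
            pv = scipy.stats.gamma.sf(c["scores"], fit.shape, scale=fit.scale)
            rows.append(_power_row(fos, scheme, pv, alpha, c["n_degenerate"]))
    else:
        pcfg = PermutationConfig(n_initial=n_perm, n_max=n_perm)
        if scheme == "effperm_neutral" and 0.0 not in per_cond:
            raise ValidationError("effperm_neutral requires FOS=0 in the grid")
        for fos, c in per_cond.items():
            pool = (
                c["effect_pool"] if scheme == "effperm_matched" else per_cond[0.0]["effect_pool"]
            )
            rng = np.random.default_rng(np.random.SeedSequence([c["seed"], 17]))
            pv = []
            for eff, P, _N in c["payload"]:
                Fm = estimate_F_arrays(_N).matrix
                pv.append(effperm_pvalue(eff, P, Fm, pool, pcfg, rng))
            rows.append(_power_row(fos, scheme, np.asarray(pv), alpha, c["n_degenerate"]))
    return pd.DataFrame(rows)


def _power_row(fos, scheme, pvals, alpha, n_degenerate):
    from .enrichment import agresti_coull

    hits = int(np.sum(pvals <= alpha))
    n = len(pvals)
    lo, hi = agresti_coull(hits, n)
    return dict(
        fos=fos,
        scheme=scheme,
        n=n,
        n_degenerate=n_degenerate,
        power=hits / n,
        ci_low=lo,
        ci_high=hi,
    )


# ---------------------------------------------------------------------------
# drift-only sanity helper (used by tests): heterozygosity decay
# ---------------------------------------------------------------------------

def drift_heterozygosity(
    n_diploid: int,
    n_variants: int,
    n_gens: int,
    seed: int = 0,
    fitness_sd: float = 1e9,
) -> tuple[float, float]:
    """Evolve standing variation (freq 1/2, zero effects, no mutation) and
    return (initial, final) mean heterozygosity 2p(1-p).

    Under pure drift E[H_t] = H_0 (1 - 1/(2N))^t.
    """
    H = 2 * n_diploid
    gene_len = 1e6
    rng = np.random.default_rng(seed)
    hap_cap = n_variants + 8
    mut_cap = n_variants + 8
    mpos = np.zeros(mut_cap)
    meff = np.zeros(mut_cap)
    alive = np.zeros(mut_cap, dtype=np.bool_)
    pos = np.sort(rng.uniform(0, gene_len, size=n_variants))
    mpos[:n_variants] = pos
    alive[:n_variants] = True
    carriers = [rng.choice(H, size=H // 2, replace=False) for _ in range(n_variants)]
    lists: list[list[int]] = [[] for _ in range(H)]
    for vid, carr in enumerate(carriers):
        for h in carr:
            lists[h].append(vid)  # vids already in position order
    par = np.zeros((H, hap_cap), dtype=np.int32)
    parc = np.zeros(H, dtype=np.int32)
    for h, lst in enumerate(lists):
        par[h, : len(lst)] = lst
        parc[h] = len(lst)
    state = np.array([n_variants, 0], dtype=np.int64)
    free_ids = np.zeros(mut_cap, dtype=np.int32)
    occ = np.zeros(mut_cap, dtype=np.int32)
    baseline = np.zeros(1)
    bufA = np.zeros((H, hap_cap), dtype=np.int32)
    bufAc = np.zeros(H, dtype=np.int32)
    bufB = np.zeros((H, hap_cap), dtype=np.int32)
    bufBc = np.zeros(H, dtype=np.int32)
    err = run_wf(
        par, parc, bufA, bufAc, bufB, bufBc,
        mpos, meff, alive, free_ids, state, occ, baseline,
        n_gens, gene_len, gene_len, 1.0,
        0.0, 0.0, 1e-8, 0.0,
        1.0, 0.0, fitness_sd, 0, int(rng.integers(2**31 - 1)),
    )
    _check_err(err)
    fin, finc = (bufA, bufAc) if n_gens % 2 == 1 else (bufB, bufBc)
    occ_f = count_occupancy(fin, finc, n_variants)
    p = occ_f / H
    h0 = 0.5  # 2 * 0.5 * 0.5
    hT = float(np.mean(2.0 * p * (1.0 - p)))
    return h0, hT
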