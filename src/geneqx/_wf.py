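"""Numba kernels for the forward Wright-Fisher engine.

Haplotypes are sparse: each row of a (H, cap) int32 array lists the mutation
ids carried by that haplotype, sorted by genomic position; ``counts[h]`` is
the number of entries used. Mutation ids index into flat position/effect
tables. The simulated chromosome holds two segments: the "gene"
[0, gene_len), whose mutations carry Gaussian expression effects, and a
disjoint neutral segment [neu_start, neu_start + neu_len) with zero-effect
mutations; the segments assort independently (a fresh starting phase per
segment each meiosis), with Poisson crossovers inside each.

Selection is stabilizing on the genetic value (sum of effects over both
haplotypes plus the fixed-mutation baseline): relative fitness
exp(-(z - optimum)^2 / (2 fitness_sd^2)), normalized implicitly by sampling
parents proportional to fitness. With ``prune`` enabled, lost mutations are
recycled and fixed mutations are folded into the baseline each generation.

Error codes returned by ``run_wf``: 0 ok, 1 haplotype capacity exceeded,
2 mutation-table capacity exceeded.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True)
def _make_gamete(
    par,
    parc,
    hA,
    hB,
    mpos,
    meff,
    alive,
    free_ids,
    state,
    child,
    crow,
    gene_len,
    neu_start,
    neu_len,
    r_gene,
    r_neu,
    mu_gene,
    mu_neu,
    eff_sd,
    bps_buf,
):
    """Build one recombinant, mutated gamete into child[crow]; returns
    (count, err)."""
    cap = child.shape[1]
    mut_cap = mpos.shape[0]
    out = child[crow]
    oc = 0
    ai = 0
    bi = 0
    A = par[hA]
    nA = parc[hA]
    B = par[hB]
    nB = parc[hB]
    # two segments, independent starting phase each (free recombination
    # between the gene and the neutral segment)
    for seg in range(2):
        if seg == 0:
            lo = 0.0
            hi = gene_len
            lam = r_gene * gene_len
        else:
            lo = neu_start
            hi = neu_start + neu_len
            lam = r_neu * neu_len
        nb = np.random.poisson(lam)
        if nb > bps_buf.shape[0]:
            nb = bps_buf.shape[0]  # cap pathological crossover counts
        bps = bps_buf[:nb]
        for ii in range(nb):  # draw and insertion-sort breakpoints
            v = lo + np.random.random() * (hi - lo)
            jj = ii
            while jj > 0 and bps[jj - 1] > v:
                bps[jj] = bps[jj - 1]
                jj -= 1
            bps[jj] = v
        phase = 0 if np.random.random() < 0.5 else 1
        for k in range(nb + 1):
            nxt = hi if k == nb else bps[k]
            if phase == 0:
                while ai < nA and mpos[A[ai]] < nxt:
                    if oc >= cap:
                        return 0, 1
                    out[oc] = A[ai]
                    oc += 1
                    ai += 1
                while bi < nB and mpos[B[bi]] < nxt:
                    bi += 1
            else:
                while bi < nB and mpos[B[bi]] < nxt:
                    if oc >= cap:
                        return 0, 1
                    out[oc] = B[bi]
                    oc += 1
                    bi += 1
                while ai < nA and mpos[A[ai]] < nxt:
                    ai += 1
            phase = 1 - phase
    # new mutations (infinite sites within each segment)
    for seg in range(2):
        if seg == 0:
            lo = 0.0
            span = gene_len
            lam = mu_gene * gene_len
        else:
            lo = neu_start
            span = neu_len
            lam = mu_neu * neu_len
        nm = np.random.poisson(lam)
        for _ in range(nm):
            pos = lo + np.random.random() * span
            if state[1] > 0:
                state[1] -= 1
                mid = free_ids[state[1]]
            else:
                mid = state[0]
                if mid >= mut_cap:
                    return 0, 2
                state[0] += 1
            mpos[mid] = pos
            meff[mid] = np.random.normal(0.0, eff_sd) if seg == 0 else 0.0
            alive[mid] = True
            if oc >= cap:
                return 0, 1
            j = oc
            while j > 0 and mpos[out[j - 1]] > pos:
                out[j] = out[j - 1]
                j -= 1
            out[j] = mid
            oc += 1
    return oc, 0


@njit(cache=True)
def run_wf(
    par,
    parc,
    bufA,
    bufAc,
    bufB,
    bufBc,
    mpos,
    meff,
    alive,
    free_ids,
    state,
    occ,
    baseline,
    n_gens,
    gene_len,
    neu_start,
    neu_len,
    mu_gene,
    mu_neu,
    r_gene,
    r_neu,
    eff_sd,
    opt,
    fit_sd,
    prune,
    seed,
):
    """Evolve ``n_gens`` discrete WF generations.

    Generation 0 samples parents from ``par``; later generations sample from
    the previous offspring buffer. The final generation lives in ``bufA``
    when ``n_gens`` is odd, ``bufB`` when even. Returns an error code.
    """
    np.random.seed(seed)
    cur = par
    curc = parc
    use_A = True
    bps_buf = np.empty(256)
    for gen in range(n_gens):
        Hp = cur.shape[0]
        npar = Hp // 2
        w = np.empty(npar)
        for i in range(npar):
            s = baseline[0]
            for h in range(2):
                hh = 2 * i + h
                for t in range(curc[hh]):
                    s += meff[cur[hh, t]]
            d = (s - opt) / fit_sd
            w[i] = np.exp(-0.5 * d * d)
        cum = np.cumsum(w)
        tot = cum[npar - 1]
        child = bufA if use_A else bufB
        childc = bufAc if use_A else bufBc
        Ho = child.shape[0]
        for kid in range(Ho // 2):
            for s2 in range(2):
                if tot > 0.0 and np.isfinite(tot):
                    r = np.random.random() * tot
                    j = np.searchsorted(cum, r)
                    if j >= npar:
                        j = npar - 1
                else:
                    j = np.random.randint(0, npar)
                cc, err = _make_gamete(
                    cur,
                    curc,
                    2 * j,
                    2 * j + 1,
                    mpos,
                    meff,
                    alive,
                    free_ids,
                    state,
                    child,
                    2 * kid + s2,
                    gene_len,
                    neu_start,
                    neu_len,
                    r_gene,
                    r_neu,
                    mu_gene,
                    mu_neu,
                    eff_sd,
                    bps_buf,
                )
                if err != 0:
                    return err
                childc[2 * kid + s2] = cc
        cur = child
        curc = childc
        use_A = not use_A
        if prune == 1:
            nm = state[0]
            occ[:nm] = 0
            for hh in range(Ho):
                for t in range(childc[hh]):
                    occ[child[hh, t]] += 1
            anyfixed = False
            for mid in range(nm):
                if alive[mid]:
                    c = occ[mid]
                    if c == 0:
                        alive[mid] = False
                        free_ids[state[1]] = mid
                        state[1] += 1
                    elif c == Ho:
                        anyfixed = True
            if anyfixed:
                for hh in range(Ho):
                    n0 = childc[hh]
                    k2 = 0
                    for t in range(n0):
                        mid = child[hh, t]
                        if occ[mid] != Ho:
                            child[hh, k2] = mid
                            k2 += 1
                    childc[hh] = k2
                for mid in range(nm):
                    if alive[mid] and occ[mid] == Ho:
                        baseline[0] += 2.0 * meff[mid]
                        alive[mid] = False
                        free_ids[state[1]] = mid
                        state[1] += 1
    return 0


@njit(cache=True)
def count_occupancy(haps, counts, n_mut):
    """Per-mutation derived-allele counts over a haplotype block."""
    occ = np.zeros(n_mut, dtype=np.int64)
    for hh in range(haps.shape[0]):
        for t in range(counts[hh]):
            occ[haps[hh, t]] += 1
    return occ
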