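"""Hierarchical AMOVA on pairwise sequence distances, pairwise Fst with
permutation significance, Markov-chain exact tests of haplotype
differentiation, migrant-number estimates, and the Holm (sequential
Bonferroni) step-down adjustment.

Distances are pairwise nucleotide difference counts over the complete-case
columns.  Negative variance components and negative Fst are reported as
computed, never truncated to zero.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .alignment import HaplotypeTable, PopAlignment


def difference_matrix(aln: PopAlignment) -> np.ndarray:
    """(n, n) matrix of pairwise nucleotide difference counts."""
    m = aln.matrix()[:, aln.complete_case_columns()]
    n = aln.n
    d = np.zeros((n, n))
    for i in range(n):
        diff = (m[i + 1:] != m[i]).sum(axis=1)
        d[i, i + 1:] = diff
        d[i + 1:, i] = diff
    return d


@dataclass
class AmovaResult:
    sigma_a: float              # among groups
    sigma_b: float              # among populations within groups
    sigma_c: float              # within populations
    percentages: tuple          # (a, b, c) as % of total, may be negative
    phi_ct: float
    phi_sc: float
    phi_st: float
    p_values: dict              # component -> permutation p (may be empty)
    n_permutations: int = 0


def _ssd_within(d2: np.ndarray, groups: Sequence[int]) -> float:
    """Sum over classes of (1/n_c) * sum of squared distances within class."""
    groups = np.asarray(groups)
    total = 0.0
    for gid in np.unique(groups):
        idx = np.flatnonzero(groups == gid)
        sub = d2[np.ix_(idx, idx)]
        total += sub.sum() / (2 * len(idx))
    return total


def _amova_components(d2: np.ndarray, pops: np.ndarray, grps: np.ndarray):
    """Excoffier-style variance decomposition with unequal-size coefficients.

    Returns (sigma_a, sigma_b, sigma_c). With a single group sigma_a = 0 and
    the decomposition reduces to the two-level AMOVA.
    """
    N = len(pops)
    pop_ids, pop_inv = np.unique(pops, return_inverse=True)
    grp_ids, grp_inv = np.unique(grps, return_inverse=True)
    P, G = len(pop_ids), len(grp_ids)
    ssd_total = d2.sum() / (2 * N)
    ssd_wp = _ssd_within(d2, pop_inv)
    ssd_wg = _ssd_within(d2, grp_inv)
    ssd_ap = ssd_wg - ssd_wp          # among populations within groups
    ssd_ag = ssd_total - ssd_wg       # among groups
    df_wp = N - P
    df_ap = P - G
    df_ag = G - 1
    sizes = np.bincount(pop_inv)
    grp_of_pop = np.array([grp_inv[np.flatnonzero(pop_inv == p)[0]] for p in range(P)])
    grp_sizes = np.bincount(grp_inv)
    sum_n2_by_grp = np.array([
        (sizes[grp_of_pop == g] ** 2).sum() / grp_sizes[g] for g in range(G)
    ])
    sigma_c = ssd_wp / df_wp if df_wp > 0 else 0.0
    if df_ap > 0:
        n_prime = (N - sum_n2_by_grp.sum()) / df_ap
        sigma_b = (ssd_ap / df_ap - sigma_c) / n_prime
    else:
        sigma_b = 0.0
    if df_ag > 0:
        n_pp = (sum_n2_by_grp.sum() - (sizes**2).sum() / N) / df_ag
        n_ppp = (N - (grp_sizes**2).sum() / N) / df_ag
        sigma_a = (ssd_ag / df_ag - sigma_c - n_pp * sigma_b) / n_ppp
    else:
        sigma_a = 0.0
    return sigma_a, sigma_b, sigma_c


def amova(aln: PopAlignment, grouping: Optional[dict] = None,
          n_perm: int = 10_100, seed: int = 0) -> AmovaResult:
    """Hierarchical analysis of molecular variance.

    ``grouping`` maps population -> group; with no grouping (or one group)
    the analysis is two-level (among/within populations) and only Phi_ST is
    meaningful.  Permutation schemes: Phi_ST permutes haplotypes across the
    whole sample; Phi_SC permutes haplotypes among populations within their
    group; Phi_CT permutes whole populations among groups.  Populations with
    fewer than two members are excluded with a warning note in the result.
    """
    sizes: dict = {}
    for p in aln.populations:
        sizes[p] = sizes.get(p, 0) + 1
    keep_pops = {p for p, c in sizes.items() if c >= 2}
    if len(keep_pops) < 2:
        raise ValueError("AMOVA needs at least two populations with n >= 2")
    if keep_pops != set(sizes):
        aln = aln.restrict_populations(sorted(keep_pops))
    pops = np.asarray(aln.populations)
    if grouping:
        grps = np.asarray([grouping[p] for p in pops])
    else:
        grps = np.zeros(len(pops), dtype=int)
    d2 = difference_matrix(aln)  # squared Euclidean distances == difference counts
    sigma_a, sigma_b, sigma_c = _amova_components(d2, pops, grps)
    total = sigma_a + sigma_b + sigma_c
    if total == 0:
        pct = (math.nan, math.nan, math.nan)
    else:
        pct = tuple(100.0 * s / total for s in (sigma_a, sigma_b, sigma_c))
    phi_st = (sigma_a + sigma_b) / total if total else math.nan
    phi_ct = sigma_a / total if total else math.nan
    phi_sc = sigma_b / (sigma_b + sigma_c) if (sigma_b + sigma_c) else math.nan
    p_values: dict = {}
    if n_perm > 0:
        rng = np.random.default_rng(seed)
        multi_group = len(np.unique(grps)) > 1
        cnt_st = cnt_sc = cnt_ct = 0
        pop_ids = np.unique(pops)
        grp_of_pop = {p: grps[np.flatnonzero(pops == p)[0]] for p in pop_ids}
        for _ in range(n_perm):
            # Phi_ST: haplotypes among populations (whole sample)
            perm = rng.permutation(len(pops))
            a, b, c = _amova_components(d2[np.ix_(perm, perm)], pops, grps)
            t = a + b + c
            if t and (a + b) / t >= phi_st - 1e-12:
                cnt_st += 1
            if multi_group:
                # Phi_SC: haplotypes among populations within groups
                perm2 = np.arange(len(pops))
                for g in np.unique(grps):
                    idx = np.flatnonzero(grps == g)
                    perm2[idx] = idx[rng.permutation(len(idx))]
                a2_, b2_, c2_ = _amova_components(d2[np.ix_(perm2, perm2)], pops, grps)
                if (b2_ + c2_) and b2_ / (b2_ + c2_) >= phi_sc - 1e-12:
                    cnt_sc += 1
                # Phi_CT: populations among groups
                labels = [grp_of_pop[p] for p in pop_ids]
                shuffled = rng.permutation(labels)
                gmap = dict(zip(pop_ids, shuffled))
                grps_p = np.asarray([gmap[p] for p in pops])
                a3_, b3_, c3_ = _amova_components(d2, pops, grps_p)
                t3 = a3_ + b3_ + c3_
                if t3 and a3_ / t3 >= phi_ct - 1e-12:
                    cnt_ct += 1
        p_values["phi_st"] = (cnt_st + 1) / (n_perm + 1)
        if multi_group:
            p_values["phi_sc"] = (cnt_sc + 1) / (n_perm + 1)
            p_values["phi_ct"] = (cnt_ct + 1) / (n_perm + 1)
    return AmovaResult(sigma_a, sigma_b, sigma_c, pct,
                       phi_ct, phi_sc, phi_st, p_values, n_perm)


@dataclass
class PairwiseStructure:
    populations: list
    fst: np.ndarray
    fst_p: np.ndarray
    exact_p: Optional[np.ndarray] = None
    exact_se: Optional[np.ndarray] = None
    M: Optional[np.ndarray] = None


def pairwise_fst(aln: PopAlignment, n_perm: int = 10_000,
                 seed: int = 0) -> PairwiseStructure:
    """Pairwise Fst = Phi_ST from two-population AMOVA, with one-tailed
    permutation p-values (fraction of permuted Fst >= observed)."""
    pops = aln.population_ids
    P = len(pops)
    if P < 2:
        raise ValueError("need at least two populations")
    fst = np.full((P, P), np.nan)
    fst_p = np.full((P, P), np.nan)
    rng = np.random.default_rng(seed)
    for i in range(P):
        for j in range(i + 1, P):
            sub = aln.restrict_populations([pops[i], pops[j]])
            res = amova(sub, n_perm=0)
            d2 = difference_matrix(sub)
            labels = np.asarray(sub.populations)
            obs = res.phi_st
            cnt = 0
            for _ in range(n_perm):
                perm = rng.permutation(len(labels))
                a, b, c = _amova_components(d2[np.ix_(perm, perm)], labels,
                                            np.zeros(len(labels), dtype=int))
                t = a + b + c
                if t and (a + b) / t >= obs - 1e-12:
                    cnt += 1
            fst[i, j] = fst[j, i] = obs
            fst_p[i, j] = fst_p[j, i] = (cnt + 1) / (n_perm + 1)
    M = np.array([[migration_from_fst(f) if np.isfinite(f) else np.nan
                   for f in row] for row in fst])
    return PairwiseStructure(pops, fst, fst_p, M=M)


def migration_from_fst(fst: float) -> float:
    """Absolute migrant number for haploid gene copies:
    M = (1/Fst - 1)/2; infinite when Fst <= 0."""
    if fst <= 0:
        return math.inf
    return (1.0 / fst - 1.0) / 2.0


# -- exact test of differentiation ----------------------------------------

def _log_table_prob(table: np.ndarray) -> float:
    """Log conditional probability of a contingency table given its margins
    (up to a constant): -sum log(cell!)."""
    from scipy.special import gammaln
    return float(-gammaln(table + 1).sum())


def exact_test_table(table: np.ndarray, chain_steps: int = 400_000,
                     burn_in: int = 100_000, seed: int = 0):
    """Raymond & Rousset Markov-chain exact test on a haplotype x population
    contingency table.

    The chain proposes the classic two-row/two-column switch and accepts by
    the hypergeometric probability ratio; p is the visited-state fraction
    with conditional probability no greater than the observed table's.
    Returns (p, standard error of p).
    """
    rng = np.random.default_rng(seed)
    t = np.array(table, dtype=int)
    if t.ndim != 2 or (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
        raise ValueError("table must be 2-D with positive margins")
    r, c = t.shape
    logp_obs = _log_table_prob(t)
    cur = t.copy()
    logp = logp_obs
    hits = []
    total_steps = burn_in + chain_steps
    for step in range(total_steps):
        i1, i2 = rng.integers(r), rng.integers(r)
        j1, j2 = rng.integers(c), rng.integers(c)
        if i1 == i2 or j1 == j2:
            if step >= burn_in:
                hits.append(logp <= logp_obs + 1e-12)
            continue
        if rng.random() < 0.5:
            # move a unit from (i1,j2),(i2,j1) to (i1,j1),(i2,j2)
            if cur[i1, j2] == 0 or cur[i2, j1] == 0:
                if step >= burn_in:
                    hits.append(logp <= logp_obs + 1e-12)
                continue
            ratio = (cur[i1, j2] * cur[i2, j1]) / ((cur[i1, j1] + 1) * (cur[i2, j2] + 1))
            delta = np.array([[1, -1], [-1, 1]])
        else:
            if cur[i1, j1] == 0 or cur[i2, j2] == 0:
                if step >= burn_in:
                    hits.append(logp <= logp_obs + 1e-12)
                continue
            ratio = (cur[i1, j1] * cur[i2, j2]) / ((cur[i1, j2] + 1) * (cur[i2, j1] + 1))
            delta = np.array([[-1, 1], [1, -1]])
        if rng.random() < min(1.0, ratio):
            cur[np.ix_([i1, i2], [j1, j2])] += delta
            logp += math.log(ratio)
        if step >= burn_in:
            hits.append(logp <= logp_obs + 1e-12)
    hits = np.asarray(hits, dtype=float)
    p = float(hits.mean())
    # batch-means standard error (autocorrelated chain)
    nb = 50
    batches = np.array_split(hits, nb)
    means = np.array([b.mean() for b in batches])
    se = float(means.std(ddof=1) / math.sqrt(nb))
    return p, se


def exact_test(hap_table: HaplotypeTable, chain_steps: int = 400_000,
               burn_in: int = 100_000, seed: int = 0) -> dict:
    """Exact test of population differentiation per population pair and
    overall.  Returns {'pairs': {(popA, popB): (p, se)}, 'overall': (p, se)}
    or flags 'n/a' when haplotype phase is unavailable."""
    if not hap_table.available:
        return {"pairs": {}, "overall": None, "note": "n/a: haplotypes unavailable"}
    pops = hap_table.populations
    counts = hap_table.counts
    out: dict = {"pairs": {}, "note": ""}
    rng = np.random.default_rng(seed)
    for i in range(len(pops)):
        for j in range(i + 1, len(pops)):
            sub = counts[:, [i, j]]
            sub = sub[sub.sum(axis=1) > 0]
            out["pairs"][(pops[i], pops[j])] = exact_test_table(
                sub, chain_steps, burn_in, seed=int(rng.integers(2**31)))
    nz = counts[counts.sum(axis=1) > 0]
    out["overall"] = exact_test_table(nz, chain_steps, burn_in,
                                      seed=int(rng.integers(2**31)))
    return out


def holm_adjust(p_values: Sequence[float], alpha: float = 0.05) -> np.ndarray:
    """Holm step-down (sequential Bonferroni): sort ascending, reject while
    p_(i) <= alpha / (m - i + 1), stop at the first failure.  Returns a
    boolean rejection mask in the input order."""
    p = np.asarray(p_values, dtype=float)
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = len(p)
    order = np.argsort(p, kind="stable")
    reject = np.zeros(m, dtype=bool)
    for rank, idx in enumerate(order):
        if p[idx] <= alpha / (m - rank):
            reject[idx] = True
        else:
            break
    return reject
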