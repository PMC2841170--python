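"""Infinite-sites neutral coalescent with a three-parameter expansion
demography, in the ms time convention (units of 4N0 generations).

The demographic model: looking backward from the present, the population
shrinks exponentially at coalescent-scaled rate ``g`` until the onset of
expansion ``t_b`` (given in generations, converted through N0), and is
constant at the ancestral size ``N0 * exp(-g * t_b / (4 N0))`` earlier.
``g = 0`` reduces to the constant-size model.

Scaling conventions used throughout (and verified against closed forms in
the test suite):

* pair coalescence rate ``2 / lambda(t)`` where ``lambda`` is the population
  size relative to N0, so E[TMRCA] for n = 2 is 0.5 under constant size;
* mutations per genealogy ~ Poisson(theta0 * T_total), giving
  E[S] = theta0 * a1 and E[pi] = theta0 per locus.

Waiting times under exponential growth are drawn by analytic inverse
transform of the time-varying hazard; no time discretization is involved.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .diversity import harmonic, r2_value, tajimas_d_value


@dataclass(frozen=True)
class ExpansionModel:
    """Three-parameter expansion demography.

    Parameters
    ----------
    theta0 : float
        Population-scaled mutation rate 4*N0*mu per locus (modern size).
    t_b : float
        Onset of expansion, in generations before present.
    g : float
        Exponential growth rate per 4*N0 generations (coalescent-scaled);
        0 means constant size.
    N0 : float
        Assumed modern effective size; used only to convert ``t_b`` between
        generations and coalescent units.
    """

    theta0: float
    t_b: float = 0.0
    g: float = 0.0
    N0: float = 100_000.0

    def __post_init__(self):
        if self.theta0 < 0:
            raise ValueError("theta0 must be >= 0")
        if self.t_b < 0 or self.g < 0:
            raise ValueError("t_b and g must be >= 0")

    @property
    def t_b_coal(self) -> float:
        """Expansion onset in units of 4*N0 generations."""
        return self.t_b / (4.0 * self.N0)

    @property
    def ancestral_ratio(self) -> float:
        """N_ancestral / N0 = exp(-g * t_b / (4 N0))."""
        return math.exp(-self.g * self.t_b_coal)


def growth_rate_for_expansion(N0: float, N_anc: float, t_b: float) -> float:
    """The coalescent-scaled growth rate implied by an expansion from N_anc
    to N0 over t_b generations: g = (4 N0 / t_b) * ln(N0 / N_anc)."""
    return (4.0 * N0 / t_b) * math.log(N0 / N_anc)


@dataclass
class SimulatedSample:
    """One infinite-sites sample: binary haplotypes (rows = chromosomes,
    columns = mutations, 1 = derived), mutation positions in [0, 1), and the
    TMRCA in 4*N0 units."""

    haplotypes: np.ndarray
    positions: np.ndarray
    tmrca: float
    seed: Optional[int] = None

    @property
    def n(self) -> int:
        return self.haplotypes.shape[0]

    @property
    def S(self) -> int:
        return self.haplotypes.shape[1]


# -- genealogy machinery ---------------------------------------------------

def _draw_event_time(total_rate: float, s: float, g: float, t_b: float,
                     rng: np.random.Generator) -> float:
    """First event time after s for hazard total_rate * e^{g t} (t <= t_b)
    then total_rate / lambda_anc, by inversion of an Exp(1) draw."""
    E = rng.exponential()
    if g == 0.0:
        return s + E / total_rate
    lam_anc = math.exp(-g * t_b)
    if s < t_b:
        # hazard integral from s to t_b under growth
        H1 = total_rate * (math.exp(g * t_b) - math.exp(g * s)) / g
        if E <= H1:
            return math.log(math.exp(g * s) + g * E / total_rate) / g
        E -= H1
        s = t_b
    return s + E * lam_anc / total_rate


def simulate_genealogy(n: int, g: float = 0.0, t_b_coal: float = 0.0,
                       rng: Optional[np.random.Generator] = None):
    """Single-population coalescent genealogy.

    Returns ``(lengths, masks, tmrca)`` where ``lengths[i]`` is the branch
    length (4*N0 units) of branch i and ``masks[i]`` a leaf bitmask of its
    descendants.  There are 2n - 2 branches.
    """
    if n < 2:
        raise ValueError("need n >= 2 chromosomes")
    rng = rng or np.random.default_rng()
    masks = [1 << i for i in range(n)]
    births = [0.0] * n
    out_len: list = []
    out_mask: list = []
    t = 0.0
    j = n
    while j > 1:
        t = _draw_event_time(j * (j - 1), t, g, t_b_coal, rng)
        a, b = rng.choice(j, size=2, replace=False)
        a, b = int(a), int(b)
        for idx in (a, b):
            out_len.append(t - births[idx])
            out_mask.append(masks[idx])
        merged = masks[a] | masks[b]
        hi, lo = max(a, b), min(a, b)
        for lst in (masks, births):
            lst.pop(hi)
            lst.pop(lo)
        masks.append(merged)
        births.append(t)
        j -= 1
    return np.array(out_len), out_mask, t


def _drop_mutations(lengths: np.ndarray, masks, n: int, S: int,
                    rng: np.random.Generator):
    """Place S mutations on branches with probability proportional to length;
    returns (sfs_counts, ext_counts) — the unfolded spectrum and per-leaf
    external-singleton counts (including complements of (n-1)-branches)."""
    sfs = np.zeros(n - 1, dtype=int)
    ext = np.zeros(n, dtype=int)
    if S == 0:
        return sfs, ext
    total = lengths.sum()
    hits = rng.multinomial(S, lengths / total)
    full = (1 << n) - 1
    for bi in np.flatnonzero(hits):
        mask = masks[bi]
        d = mask.bit_count()
        sfs[d - 1] += hits[bi]
        if d == 1:
            ext[mask.bit_length() - 1] += hits[bi]
        elif d == n - 1:
            comp = full & ~mask
            ext[comp.bit_length() - 1] += hits[bi]
    return sfs, ext


def simulate_sample(model: ExpansionModel, n: int,
                    seed: Optional[int] = None,
                    rng: Optional[np.random.Generator] = None) -> SimulatedSample:
    """Draw one sample of n chromosomes under the expansion model; mutation
    count is Poisson(theta0 * total branch length)."""
    rng = rng if rng is not None else np.random.default_rng(seed)
    lengths, masks, tmrca = simulate_genealogy(n, model.g, model.t_b_coal, rng)
    total = lengths.sum()
    S = int(rng.poisson(model.theta0 * total)) if model.theta0 > 0 else 0
    haps = np.zeros((n, S), dtype=np.int8)
    if S:
        hits = rng.multinomial(S, lengths / total)
        col = 0
        for bi in np.flatnonzero(hits):
            mask = masks[bi]
            carriers = [i for i in range(n) if mask >> i & 1]
            for _ in range(hits[bi]):
                haps[carriers, col] = 1
                col += 1
    positions = np.sort(rng.random(S))
    return SimulatedSample(haps, positions, tmrca, seed=seed)


def simulate_fixed_s_branch_stats(n: int, S: int,
                                  rng: np.random.Generator):
    """Constant-size genealogy with exactly S mutations dropped uniformly on
    branches (fixed-S conditioning); returns (sfs_counts, ext_counts)."""
    lengths, masks, _ = simulate_genealogy(n, 0.0, 0.0, rng)
    return _drop_mutations(lengths, masks, n, S, rng)


def simulate_fixed_s(n: int, S: int, seed: Optional[int] = None) -> SimulatedSample:
    """Fixed-S sample with full haplotypes (constant size)."""
    rng = np.random.default_rng(seed)
    lengths, masks, tmrca = simulate_genealogy(n, 0.0, 0.0, rng)
    haps = np.zeros((n, S), dtype=np.int8)
    if S:
        hits = rng.multinomial(S, lengths / lengths.sum())
        col = 0
        for bi in np.flatnonzero(hits):
            carriers = [i for i in range(n) if masks[bi] >> i & 1]
            for _ in range(hits[bi]):
                haps[carriers, col] = 1
                col += 1
    return SimulatedSample(haps, np.sort(rng.random(S)), tmrca, seed=seed)


# -- summary statistics for ABC -------------------------------------------

def _branch_summaries(n: int, L: int, sfs: np.ndarray, ext: np.ndarray):
    """(theta_w per site, pi per site, r2 or nan) from branch-level output."""
    S = int(sfs.sum())
    i = np.arange(1, n)
    k = float((sfs * 2.0 * i * (n - i)).sum() / (n * (n - 1)))
    theta_w = S / (harmonic(n) * L)
    pi = k / L
    r2 = r2_value(n, S, k, ext.astype(float)) if S > 0 else math.nan
    return theta_w, pi, r2


def simulate_locus_summaries(model: ExpansionModel, n: int, L: int,
                             rng: np.random.Generator):
    """Fast path for ABC reference tables: one locus, summaries only."""
    lengths, masks, _ = simulate_genealogy(n, model.g, model.t_b_coal, rng)
    total = lengths.sum()
    S = int(rng.poisson(model.theta0 * total)) if model.theta0 > 0 else 0
    sfs, ext = _drop_mutations(lengths, masks, n, S, rng)
    return _branch_summaries(n, L, sfs, ext)


def summaries_for_abc(samples: Sequence, lengths: Sequence[int]):
    """Length-weighted (theta_w, pi, r2) across loci.

    ``samples`` are :class:`SimulatedSample` objects (or anything with a
    binary ``haplotypes`` matrix).  Monomorphic loci contribute no R2; if
    every locus is monomorphic the replicate is flagged invalid (None).
    """
    tw, pi, r2, w_all, w_r2 = [], [], [], [], []
    for smp, L in zip(samples, lengths):
        h = smp.haplotypes
        n = h.shape[0]
        counts = h.sum(axis=0)
        seg = (counts > 0) & (counts < n)
        S = int(seg.sum())
        c = counts[seg]
        k = float((2.0 * c * (n - c)).sum() / (n * (n - 1)))
        tw.append(S / (harmonic(n) * L))
        pi.append(k / L)
        w_all.append(L)
        if S > 0:
            minor = np.minimum(c, n - c)
            U = np.zeros(n)
            for j in np.flatnonzero(minor == 1):
                col = h[:, np.flatnonzero(seg)[j]]
                rare = 1 if c[j] == 1 else 0
                U[np.flatnonzero(col == rare)[0]] += 1
            r2.append(r2_value(n, S, k, U))
            w_r2.append(L)
    if not w_r2:
        return None
    w_all = np.asarray(w_all, dtype=float)
    w_r2 = np.asarray(w_r2, dtype=float)
    return (
        float(np.average(tw, weights=w_all)),
        float(np.average(pi, weights=w_all)),
        float(np.average(r2, weights=w_r2)),
    )


# -- island-model extension (used by the synthetic-data generator) ---------

def simulate_island_genealogy(n_per_deme: Sequence[int], M: float,
                              g: float = 0.0, t_b_coal: float = 0.0,
                              merge_time: Optional[float] = None,
                              rng: Optional[np.random.Generator] = None):
    """Symmetric n-island coalescent with optional expansion.

    Each deme has modern relative size 1 (so coalescence within a deme runs
    at pair rate 2/lambda(t), like the single-population model); lineages
    migrate at total rate M/2 each, uniformly to the other demes.  If
    ``merge_time`` is given, all lineages fall into one deme at that time
    (ancient panmixia — required when M = 0).

    Returns (lengths, masks, tmrca).
    """
    rng = rng or np.random.default_rng()
    demes = []
    i = 0
    for d, nd in enumerate(n_per_deme):
        for _ in range(nd):
            demes.append(d)
            i += 1
    n = i
    if n < 2:
        raise ValueError("need at least two chromosomes in total")
    n_demes = len(n_per_deme)
    if M <= 0 and n_demes > 1 and merge_time is None:
        raise ValueError("M = 0 with several demes requires a merge_time")
    masks = [1 << i for i in range(n)]
    births = [0.0] * n
    out_len: list = []
    out_mask: list = []
    t = 0.0
    merged_pool = False
    while len(masks) > 1:
        if merge_time is not None and t >= merge_time and not merged_pool:
            demes = [0] * len(masks)
            merged_pool = True
        counts = np.bincount(demes, minlength=n_demes)
        A = float((counts * (counts - 1)).sum())  # total coalescence weight
        k = len(masks)
        # competing risks: growth-scaled coalescence vs constant migration
        t_coal = _draw_event_time(A, t, g, t_b_coal, rng) if A > 0 else math.inf
        mig_rate = k * M / 2.0 if (M > 0 and not merged_pool and n_demes > 1) else 0.0
        t_mig = t + rng.exponential() / mig_rate if mig_rate > 0 else math.inf
        if merge_time is not None and not merged_pool and min(t_coal, t_mig) >= merge_time:
            t = merge_time
            continue
        if t_coal <= t_mig:
            t = t_coal
            w = counts * (counts - 1)
            deme = int(rng.choice(n_demes, p=w / w.sum()))
            members = [idx for idx, dd in enumerate(demes) if dd == deme]
            a, b = rng.choice(len(members), size=2, replace=False)
            ia, ib = members[int(a)], members[int(b)]
            for idx in (ia, ib):
                out_len.append(t - births[idx])
                out_mask.append(masks[idx])
            merged = masks[ia] | masks[ib]
            for lst in (masks, births, demes):
                for idx in sorted((ia, ib), reverse=True):
                    lst.pop(idx)
            masks.append(merged)
            births.append(t)
            demes.append(deme)
        else:
            t = t_mig
            idx = int(rng.integers(len(masks)))
            choices = [d for d in range(n_demes) if d != demes[idx]]
            demes[idx] = int(rng.choice(choices))
    return np.array(out_len), out_mask, t


def simulate_island_sample(model: ExpansionModel, n_per_deme: Sequence[int],
                           M: float, merge_time: Optional[float] = None,
                           rng: Optional[np.random.Generator] = None) -> SimulatedSample:
    """Island-model sample with binary haplotypes; rows are ordered deme by
    deme in the order of ``n_per_deme``."""
    rng = rng or np.random.default_rng()
    lengths, masks, tmrca = simulate_island_genealogy(
        n_per_deme, M, model.g, model.t_b_coal, merge_time, rng)
    n = sum(n_per_deme)
    total = lengths.sum()
    S = int(rng.poisson(model.theta0 * total)) if model.theta0 > 0 else 0
    haps = np.zeros((n, S), dtype=np.int8)
    if S:
        hits = rng.multinomial(S, lengths / total)
        col = 0
        for bi in np.flatnonzero(hits):
            carriers = [i for i in range(n) if masks[bi] >> i & 1]
            for _ in range(hits[bi]):
                haps[carriers, col] = 1
                col += 1
    return SimulatedSample(haps, np.sort(rng.random(S)), tmrca)
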