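"""Within-sample diversity summaries and site-frequency-spectrum neutrality
statistics (Tajima's D, Fu & Li's D and D*, Fay & Wu's H, R2, Fu's Fs), with
coalescent-simulation p-values conditioned on the observed number of
segregating sites.

All statistics use the listwise complete-case columns of the alignment (see
:mod:`popgenkit.alignment`).  Per-site quantities are divided by the number
of analysed sites, which is reported alongside every statistic.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Optional

import numpy as np

from .alignment import PopAlignment, collapse_haplotypes
from .codon import codon_diffs, codon_sites, translate

# -- harmonic sums and test constants -------------------------------------

def harmonic(n: int) -> float:
    """a1 = sum_{i=1}^{n-1} 1/i."""
    return sum(1.0 / i for i in range(1, n))


def harmonic2(n: int) -> float:
    """a2 = sum_{i=1}^{n-1} 1/i^2."""
    return sum(1.0 / i**2 for i in range(1, n))


def tajima_constants(n: int) -> dict:
    """Tajima (1989) normalizing constants, derived fresh from n."""
    a1 = harmonic(n)
    a2 = harmonic2(n)
    b1 = (n + 1) / (3 * (n - 1))
    b2 = 2 * (n**2 + n + 3) / (9 * n * (n - 1))
    c1 = b1 - 1 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    return {"a1": a1, "a2": a2, "b1": b1, "b2": b2,
            "c1": c1, "c2": c2, "e1": e1, "e2": e2}


def fu_li_constants(n: int) -> dict:
    """Fu & Li (1993) constants for D (with outgroup) and D* (without)."""
    a = harmonic(n)
    b = harmonic2(n)
    if n == 2:
        c = 1.0
    else:
        c = 2 * (n * a - 2 * (n - 1)) / ((n - 1) * (n - 2))
    vD = 1 + (a**2 / (b + a**2)) * (c - (n + 1) / (n - 1))
    uD = a - 1 - vD
    an1 = a + 1.0 / n
    if n == 2:
        d = 2.0
    else:
        d = c + (n - 2) / (n - 1) ** 2 + (2 / (n - 1)) * (
            1.5 - (2 * an1 - 3) / (n - 2) - 1.0 / n
        )
    nn = n / (n - 1)
    vDs = (nn**2 * b + a**2 * d - 2 * (n * a * (a + 1)) / (n - 1) ** 2) / (a**2 + b)
    uDs = nn * (a - nn) - vDs
    return {"a": a, "b": b, "c": c, "uD": uD, "vD": vD, "uDs": uDs, "vDs": vDs}


def watterson_theta(S: int, n: int, L: int) -> float:
    """Per-site Watterson estimate S / (a1 * L)."""
    if n < 2:
        raise ValueError("need n >= 2")
    return S / (harmonic(n) * L)


# -- result containers -----------------------------------------------------

@dataclass
class DiversitySummary:
    locus_name: str
    n: int
    L: int                      # analysed (complete-case) sites
    L_total: int                # total alignment columns
    S: int
    eta: int
    k: float                    # mean pairwise differences (absolute)
    pi: float
    theta_w: float
    singletons: int
    pi_syn: Optional[float] = None
    pi_nonsyn: Optional[float] = None
    ns_ss: Optional[float] = None
    syn_sites: Optional[float] = None
    nonsyn_sites: Optional[float] = None
    n_haplotypes: Optional[int] = None  # None when phase is unavailable


@dataclass
class SFS:
    """Site frequency spectrum; ``counts[i]`` is the number of sites whose
    (minor or derived) allele count equals ``i + 1``."""
    n: int
    counts: np.ndarray
    polarized: bool

    @property
    def S(self) -> int:
        return int(self.counts.sum())


@dataclass
class NeutralityResult:
    statistic_name: str
    value: float                 # nan when undefined
    p_value: Optional[float] = None
    n_simulations: int = 0
    note: str = ""

    @property
    def defined(self) -> bool:
        return math.isfinite(self.value)


# -- site scans ------------------------------------------------------------

def _site_columns(aln: PopAlignment) -> np.ndarray:
    """(n, L_cc) character matrix of the complete-case columns."""
    m = aln.matrix()
    return m[:, aln.complete_case_columns()]


def _allele_counts(col: np.ndarray) -> dict:
    vals, cnt = np.unique(col, return_counts=True)
    return dict(zip(vals.tolist(), cnt.tolist()))


def site_spectrum(aln: PopAlignment):
    """Per complete-case column allele-count dicts (internal scan)."""
    m = _site_columns(aln)
    return [_allele_counts(m[:, j]) for j in range(m.shape[1])]


def _pairwise_k(aln: PopAlignment) -> float:
    """Mean pairwise difference count over complete-case columns."""
    m = _site_columns(aln)
    n = aln.n
    npairs = n * (n - 1) / 2
    total = 0.0
    for j in range(m.shape[1]):
        counts = np.unique(m[:, j], return_counts=True)[1]
        total += npairs - (counts * (counts - 1) / 2).sum()
    return total / npairs


def _syn_nonsyn_pi(aln: PopAlignment):
    """Nei-Gojobori synonymous / nonsynonymous per-site diversity.

    Codons with any non-complete-case column, or containing a stop in any
    sequence, are dropped whole.  Site counts are averaged over sequences;
    pairwise difference counts average over all minimal pathways.
    """
    cc = aln.complete_case_columns()
    m = aln.matrix()
    n = aln.n
    npairs = n * (n - 1) / 2
    syn_sites = np.zeros(n)
    nonsyn_sites = np.zeros(n)
    syn_diffs = 0.0
    nonsyn_diffs = 0.0
    n_codons = aln.length // 3
    used = 0
    for ci in range(n_codons):
        cols = slice(3 * ci, 3 * ci + 3)
        if not cc[cols].all():
            continue
        codons = ["".join(m[i, cols]) for i in range(n)]
        if any(translate(c) in (None, "*") for c in codons):
            continue
        used += 1
        uniq = {}
        for i, c in enumerate(codons):
            uniq.setdefault(c, []).append(i)
        for c, idx in uniq.items():
            s, ns = codon_sites(c)
            for i in idx:
                syn_sites[i] += s
                nonsyn_sites[i] += ns
        keys = list(uniq)
        for a in range(len(keys)):
            for b in range(a + 1, len(keys)):
                d = codon_diffs(keys[a], keys[b])
                if d is None:
                    continue
                w = len(uniq[keys[a]]) * len(uniq[keys[b]])
                syn_diffs += w * d[0]
                nonsyn_diffs += w * d[1]
    if used == 0:
        return None
    mean_syn_sites = syn_sites.mean()
    mean_nonsyn_sites = nonsyn_sites.mean()
    pi_syn = (syn_diffs / npairs) / mean_syn_sites if mean_syn_sites > 0 else math.nan
    pi_nonsyn = (nonsyn_diffs / npairs) / mean_nonsyn_sites if mean_nonsyn_sites > 0 else math.nan
    return pi_syn, pi_nonsyn, mean_syn_sites, mean_nonsyn_sites


def diversity_summary(aln: PopAlignment, coding: bool = False) -> DiversitySummary:
    """Per-sample-set diversity record: S, eta, k, pi, Watterson's theta and,
    for coding alignments, synonymous / nonsynonymous diversity."""
    if aln.n < 2:
        raise ValueError("diversity requires at least two sequences")
    spec = site_spectrum(aln)
    L = len(spec)
    S = sum(1 for s in spec if len(s) > 1)
    eta = sum(len(s) - 1 for s in spec)
    singles = sum(
        sum(1 for v in s.values() if v == 1)
        for s in spec if len(s) > 1
    )
    k = _pairwise_k(aln)
    pi = k / L if L else math.nan
    theta = watterson_theta(S, aln.n, L) if L else math.nan
    out = DiversitySummary(
        locus_name=aln.locus_name, n=aln.n, L=L, L_total=aln.length,
        S=S, eta=eta, k=k, pi=pi, theta_w=theta, singletons=singles,
    )
    if coding:
        if aln.length % 3 != 0:
            raise ValueError("coding statistics need a frame-aligned alignment")
        r = _syn_nonsyn_pi(aln)
        if r is not None:
            out.pi_syn, out.pi_nonsyn, out.syn_sites, out.nonsyn_sites = r
            if out.pi_syn and out.pi_syn > 0:
                out.ns_ss = out.pi_nonsyn / out.pi_syn
    hap = collapse_haplotypes(aln)
    out.n_haplotypes = hap.n_haplotypes if hap.available else None
    return out


# -- SFS -------------------------------------------------------------------

def build_sfs(aln: PopAlignment, outgroup_polarize: bool = False) -> SFS:
    """Folded (minor-allele) or outgroup-polarized (derived-allele) spectrum.

    Only biallelic complete-case sites enter the spectrum.  When polarizing,
    sites where the outgroup is gapped/ambiguous or carries a third state are
    dropped.
    """
    n = aln.n
    if outgroup_polarize and aln.outgroup is None:
        raise ValueError("outgroup polarization requested without an outgroup")
    cc = np.flatnonzero(aln.complete_case_columns())
    m = aln.matrix()
    og = aln.outgroup[1] if aln.outgroup is not None else None
    if outgroup_polarize:
        counts = np.zeros(n - 1, dtype=int)
    else:
        counts = np.zeros(n // 2, dtype=int)
    for c in cc:
        alle = _allele_counts(m[:, c])
        if len(alle) != 2:
            continue
        (b1, c1), (b2, c2) = sorted(alle.items())
        if outgroup_polarize:
            anc = og[c]
            if anc == b1:
                derived = c2
            elif anc == b2:
                derived = c1
            else:
                continue  # third state or ambiguous outgroup
            counts[derived - 1] += 1
        else:
            counts[min(c1, c2) - 1] += 1
    return SFS(n=n, counts=counts, polarized=outgroup_polarize)


# -- neutrality statistics -------------------------------------------------

def tajimas_d_value(n: int, S: int, k: float) -> float:
    """Tajima's D from n, segregating sites and mean pairwise differences."""
    if S < 1:
        return math.nan
    c = tajima_constants(n)
    denom = math.sqrt(c["e1"] * S + c["e2"] * S * (S - 1))
    return (k - S / c["a1"]) / denom


def tajimas_d(summary: DiversitySummary) -> NeutralityResult:
    v = tajimas_d_value(summary.n, summary.S, summary.k)
    note = "undefined: S = 0" if summary.S < 1 else ""
    return NeutralityResult("tajima_d", v, note=note)


def fu_li_d_value(n: int, eta: int, eta_e: int) -> float:
    """Fu & Li's D from total mutations and external (derived singleton)
    mutations, outgroup-polarized."""
    if eta < 1:
        return math.nan
    c = fu_li_constants(n)
    denom = math.sqrt(c["uD"] * eta + c["vD"] * eta**2)
    return (eta - c["a"] * eta_e) / denom


def fu_li_d_star_value(n: int, eta: int, eta_s: int) -> float:
    """Fu & Li's D* from total mutations and singleton mutations (unpolarized)."""
    if eta < 1:
        return math.nan
    c = fu_li_constants(n)
    nn = n / (n - 1)
    denom = math.sqrt(c["uDs"] * eta + c["vDs"] * eta**2)
    return (nn * eta - c["a"] * eta_s) / denom


def _singleton_mutations(aln: PopAlignment) -> int:
    """eta_s: alleles carried by exactly one sequence, over all sites."""
    total = 0
    for s in site_spectrum(aln):
        if len(s) < 2:
            continue
        total += sum(1 for v in s.values() if v == 1)
    return total


def fu_li_d(aln: PopAlignment, use_outgroup: bool = True) -> NeutralityResult:
    """Fu & Li's D (with outgroup) or D* (without).

    With an outgroup, external mutations are derived singletons from the
    unfolded spectrum; eta is then counted on the polarizable sites, keeping
    numerator terms consistent.  Without, singletons are alleles seen once.
    """
    if use_outgroup:
        if aln.outgroup is None:
            raise ValueError("Fu & Li's D with outgroup requires an outgroup")
        sfs = build_sfs(aln, outgroup_polarize=True)
        eta = int(sfs.counts.sum())
        eta_e = int(sfs.counts[0]) if len(sfs.counts) else 0
        v = fu_li_d_value(aln.n, eta, eta_e)
        return NeutralityResult("fu_li_d", v,
                                note="" if eta else "undefined: no mutations")
    spec = site_spectrum(aln)
    eta = sum(len(s) - 1 for s in spec if len(s) > 1)
    eta_s = _singleton_mutations(aln)
    v = fu_li_d_star_value(aln.n, eta, eta_s)
    return NeutralityResult("fu_li_d_star", v,
                            note="" if eta else "undefined: no mutations")


def fay_wu_h_value(sfs: SFS) -> float:
    if not sfs.polarized:
        raise ValueError("Fay & Wu's H needs an unfolded (polarized) SFS")
    n = sfs.n
    i = np.arange(1, len(sfs.counts) + 1)
    k = float((sfs.counts * 2.0 * i * (n - i)).sum() / (n * (n - 1)))
    theta_h = float((sfs.counts * 2.0 * i**2).sum() / (n * (n - 1)))
    return k - theta_h


def fay_wu_h(sfs: SFS) -> NeutralityResult:
    v = fay_wu_h_value(sfs)
    note = "degenerate: empty SFS" if sfs.S == 0 else ""
    return NeutralityResult("fay_wu_h", v, note=note)


def r2_value(n: int, S: int, k: float, U: np.ndarray) -> float:
    """Ramos-Onsins & Rozas R2 from per-sequence singleton counts U."""
    if S < 1:
        return math.nan
    return math.sqrt(float(((U - k / 2) ** 2).sum()) / n) / S


def singletons_per_sequence(aln: PopAlignment) -> np.ndarray:
    """U_i: number of sites where sequence i carries an allele seen once."""
    m = _site_columns(aln)
    n = aln.n
    U = np.zeros(n)
    for j in range(m.shape[1]):
        col = m[:, j]
        vals, cnt = np.unique(col, return_counts=True)
        if len(vals) < 2:
            continue
        for v, c in zip(vals, cnt):
            if c == 1:
                U[np.flatnonzero(col == v)[0]] += 1
    return U


def r2_stat(aln: PopAlignment) -> NeutralityResult:
    spec = site_spectrum(aln)
    S = sum(1 for s in spec if len(s) > 1)
    k = _pairwise_k(aln)
    U = singletons_per_sequence(aln)
    v = r2_value(aln.n, S, k, U)
    return NeutralityResult("r2", v, note="" if S else "undefined: S = 0")


# -- Fu's Fs ---------------------------------------------------------------

@lru_cache(maxsize=None)
def _stirling_row(n: int) -> tuple:
    """Unsigned Stirling numbers of the first kind |s(n, k)|, k = 0..n,
    by exact big-integer recurrence."""
    row = [1]
    for m in range(1, n + 1):
        new = [0] * (m + 1)
        for k in range(1, m + 1):
            new[k] = row[k - 1] if k - 1 < len(row) else 0
            if k < len(row):
                new[k] += (m - 1) * row[k]
        new[0] = 0 if m > 0 else 1
        row = new
    return tuple(row)


def ewens_k_distribution(n: int, theta: float) -> np.ndarray:
    """P(K = k | theta) under the Ewens sampling formula, k = 1..n.

    Stirling numbers are exact integers; the normalizing rising factorial is
    accumulated in log space.
    """
    if theta <= 0:
        raise ValueError("theta must be positive")
    row = _stirling_row(n)
    log_rising = sum(math.log(theta + i) for i in range(n))
    logs = np.array([
        math.log(row[k]) + k * math.log(theta) - log_rising
        for k in range(1, n + 1)
    ])
    p = np.exp(logs - logs.max())
    return p / p.sum()


def fu_fs_value(n: int, k_pairwise: float, n_haplotypes: int) -> float:
    """Fu's Fs: S' = P(K >= K_obs | theta = k); Fs = ln(S'/(1 - S'))."""
    if k_pairwise <= 0:
        return math.nan
    if n_haplotypes <= 1:
        return math.inf
    p = ewens_k_distribution(n, k_pairwise)
    s_prime = float(p[n_haplotypes - 1:].sum())
    if s_prime >= 1.0:
        return math.inf
    if s_prime <= 0.0:
        return -math.inf
    return math.log(s_prime / (1 - s_prime))


def fu_fs(summary: DiversitySummary, n_haplotypes: Optional[int] = None) -> NeutralityResult:
    k_hap = n_haplotypes if n_haplotypes is not None else summary.n_haplotypes
    if k_hap is None:
        return NeutralityResult("fu_fs", math.nan, note="haplotypes unavailable")
    if summary.k <= 0:
        return NeutralityResult("fu_fs", math.nan, note="undefined: k = 0")
    v = fu_fs_value(summary.n, summary.k, k_hap)
    note = "boundary: single haplotype" if math.isinf(v) else ""
    return NeutralityResult("fu_fs", v, note=note)


# -- mismatch distribution -------------------------------------------------

def mismatch_distribution(aln: PopAlignment) -> np.ndarray:
    """Histogram of all C(n,2) pairwise difference counts; index = number of
    differences over complete-case columns.  Its mean equals k."""
    m = _site_columns(aln)
    n = aln.n
    diffs = []
    for i in range(n):
        for j in range(i + 1, n):
            diffs.append(int((m[i] != m[j]).sum()))
    hist = np.bincount(diffs) if diffs else np.array([0])
    return hist


# -- coalescent p-values ---------------------------------------------------

def statistic_from_branch_stats(name: str, n: int, sfs_counts: np.ndarray,
                                ext_counts: np.ndarray) -> float:
    """Evaluate a neutrality statistic on simulator output (unfolded spectrum
    plus per-leaf external mutation counts) under infinite sites."""
    i = np.arange(1, n)
    S = int(sfs_counts.sum())
    k = float((sfs_counts * 2.0 * i * (n - i)).sum() / (n * (n - 1)))
    if name == "tajima_d":
        return tajimas_d_value(n, S, k)
    if name == "fu_li_d":
        return fu_li_d_value(n, S, int(sfs_counts[0]))
    if name == "fu_li_d_star":
        # singleton mutations: derived count 1 or n-1 (rarer allele seen once)
        eta_s = int(sfs_counts[0]) + (int(sfs_counts[n - 2]) if n > 2 else 0)
        return fu_li_d_star_value(n, S, eta_s)
    if name == "fay_wu_h":
        theta_h = float((sfs_counts * 2.0 * i**2).sum() / (n * (n - 1)))
        return k - theta_h
    if name == "r2":
        U = ext_counts.astype(float).copy()
        if n > 2:
            # mutations of derived count n-1: the non-carrier holds the rare allele
            U = U + 0.0  # ext_counts already counts derived singletons per leaf
        return r2_value(n, S, k, U)
    raise ValueError(f"unknown statistic {name!r}")


def coalescent_pvalue(stat: NeutralityResult, n: int, S: int,
                      n_sims: int = 10_000, seed: int = 0,
                      tail: str = "two") -> NeutralityResult:
    """Empirical p-value from the fixed-S constant-size neutral coalescent
    null distribution.  The default two-tailed p is
    2 min(P(X <= obs), P(X >= obs)) capped at 1; ``tail`` may also be
    "lower" or "upper".  Undefined statistics get no p-value."""
    from .coalescent import simulate_fixed_s_branch_stats

    if not stat.defined:
        return NeutralityResult(stat.statistic_name, stat.value,
                                p_value=None, n_simulations=0,
                                note="p-value absent: statistic undefined")
    if n_sims < 1:
        raise ValueError("need at least one simulation")
    rng = np.random.default_rng(seed)
    null = np.empty(n_sims)
    for r in range(n_sims):
        bs = simulate_fixed_s_branch_stats(n, S, rng)
        null[r] = statistic_from_branch_stats(stat.statistic_name, n, *bs)
    null = null[np.isfinite(null)]
    lo = float((null <= stat.value).mean())
    hi = float((null >= stat.value).mean())
    if tail == "lower":
        p = lo
    elif tail == "upper":
        p = hi
    else:
        p = min(1.0, 2 * min(lo, hi))
    return NeutralityResult(stat.statistic_name, stat.value, p_value=p,
                            n_simulations=n_sims)
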