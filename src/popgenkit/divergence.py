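"""Between-species contrasts: Nei-Gojobori pairwise dN/dS with Jukes-Cantor
correction, the McDonald-Kreitman test, the standard multilocus HKA test,
and the exon-distribution G-test.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import optimize, stats

from .alignment import PopAlignment
from .codon import codon_diffs, codon_sites, split_codons, translate
from .diversity import harmonic, harmonic2

# -- pairwise dN/dS --------------------------------------------------------

@dataclass
class DnDsResult:
    dS: float
    dN: float
    omega: float                # nan when dS == 0 or a correction failed
    syn_sites: float
    nonsyn_sites: float
    syn_diffs: float
    nonsyn_diffs: float
    note: str = ""


def jukes_cantor(p: float) -> float:
    """JC69 distance d = -(3/4) ln(1 - 4p/3); nan when p >= 3/4."""
    if p < 0:
        raise ValueError("proportion must be >= 0")
    if p == 0:
        return 0.0
    if p >= 0.75:
        return math.nan
    return -0.75 * math.log(1 - 4 * p / 3)


def ng86_dnds(seq_a: str, seq_b: str) -> DnDsResult:
    """Nei & Gojobori (1986) counting estimate of dN and dS for one aligned
    coding sequence pair, Jukes-Cantor corrected.

    Site counts are averaged over the two sequences; multi-hit codons
    average over all minimal substitution pathways with stop-containing
    pathways excluded.  Codons with a gap/ambiguity in either sequence are
    skipped; an internal stop codon is an input error.
    """
    seq_a, seq_b = seq_a.upper(), seq_b.upper()
    if len(seq_a) != len(seq_b):
        raise ValueError("sequences must be aligned to equal length")
    syn_sites_a = syn_sites_b = 0.0
    nonsyn_sites_a = nonsyn_sites_b = 0.0
    syn_d = nonsyn_d = 0.0
    notes = []
    for ca, cb in zip(split_codons(seq_a), split_codons(seq_b)):
        if not (set(ca) | set(cb)) <= set("ACGT"):
            continue
        aa_a, aa_b = translate(ca), translate(cb)
        if aa_a == "*" or aa_b == "*":
            raise ValueError("internal stop codon in coding sequence")
        sa, na = codon_sites(ca)
        sb, nb = codon_sites(cb)
        d = codon_diffs(ca, cb)
        if d is None:
            notes.append(f"codon pair {ca}/{cb} skipped: all pathways hit stops")
            continue
        syn_sites_a += sa
        nonsyn_sites_a += na
        syn_sites_b += sb
        nonsyn_sites_b += nb
        syn_d += d[0]
        nonsyn_d += d[1]
    S_sites = (syn_sites_a + syn_sites_b) / 2
    N_sites = (nonsyn_sites_a + nonsyn_sites_b) / 2
    pS = syn_d / S_sites if S_sites > 0 else 0.0
    pN = nonsyn_d / N_sites if N_sites > 0 else 0.0
    dS = jukes_cantor(pS)
    dN = jukes_cantor(pN)
    if math.isnan(dS) or math.isnan(dN):
        notes.append("Jukes-Cantor correction undefined (p >= 3/4)")
    omega = dN / dS if (dS and not math.isnan(dS) and not math.isnan(dN)) else math.nan
    return DnDsResult(dS, dN, omega, S_sites, N_sites, syn_d, nonsyn_d,
                      note="; ".join(notes))


def dnds_distribution(pairs: Sequence[tuple]) -> dict:
    """Distribution summaries (mean, sd, range, central 95% interval) of dS,
    dN and omega over a collection of coding sequence pairs; non-finite
    omegas are excluded and counted."""
    if len(pairs) < 2:
        raise ValueError("need at least two sequence pairs")
    res = [ng86_dnds(a, b) for a, b in pairs]
    out = {"n_pairs": len(res)}
    for name in ("dS", "dN", "omega"):
        vals = np.array([getattr(r, name) for r in res], dtype=float)
        finite = vals[np.isfinite(vals)]
        out[f"n_excluded_{name}"] = int(len(vals) - len(finite))
        if len(finite) == 0:
            continue
        out[name] = {
            "mean": float(finite.mean()),
            "sd": float(finite.std(ddof=1)) if len(finite) > 1 else 0.0,
            "min": float(finite.min()),
            "max": float(finite.max()),
            "q2.5": float(np.percentile(finite, 2.5)),
            "q97.5": float(np.percentile(finite, 97.5)),
        }
    return out


# -- McDonald-Kreitman -----------------------------------------------------

@dataclass
class MKTable:
    Dn: int
    Ds: int
    Pn: int
    Ps: int
    neutrality_index: float     # (Pn/Ps)/(Dn/Ds); nan when undefined
    fisher_p: Optional[float] = None
    g_p: Optional[float] = None
    note: str = ""


def _mk_classify_site(codons: list, out_codon: str, pos: int):
    """Classify one variable codon position as (kind, category).

    kind: 'polymorphic' if the ingroup segregates there, 'fixed' if the
    ingroup is monomorphic and differs from the outgroup, else None.
    category: 'syn' or 'nonsyn', judged by exchanging the variant base in
    the majority ingroup codon context.
    """
    ing = [c[pos] for c in codons]
    alleles = set(ing)
    out_base = out_codon[pos]
    ctx = max(set(codons), key=codons.count)
    def effect(b1, b2):
        c1 = ctx[:pos] + b1 + ctx[pos + 1:]
        c2 = ctx[:pos] + b2 + ctx[pos + 1:]
        t1, t2 = translate(c1), translate(c2)
        if t1 in (None, "*") or t2 in (None, "*"):
            return None
        return "syn" if t1 == t2 else "nonsyn"
    if len(alleles) > 1:
        # polymorphic: one entry per derived-vs-major segregating allele
        major = max(alleles, key=ing.count)
        cats = []
        for b in alleles - {major}:
            c = effect(major, b)
            if c is not None:
                cats.append(("polymorphic", c))
        return cats
    base = next(iter(alleles))
    if out_base != base and out_base in "ACGT":
        c = effect(base, out_base)
        return [("fixed", c)] if c is not None else []
    return []


def mk_test(polymorphism: PopAlignment, outgroup_consensus: str,
            min_frequency: int = 0) -> MKTable:
    """McDonald-Kreitman 2x2 test of a frame-aligned coding alignment
    against an aligned outgroup coding sequence.

    Fixed difference: site monomorphic within the ingroup and different from
    the outgroup.  Sites polymorphic in the ingroup count as polymorphic
    only, regardless of the outgroup state.  ``min_frequency`` (> 0) removes
    polymorphisms whose minor allele occurs ``min_frequency`` times or
    fewer (the low-frequency-variant filter).
    """
    if polymorphism.length % 3 != 0 or len(outgroup_consensus) != polymorphism.length:
        raise ValueError("need a frame-aligned coding alignment plus aligned outgroup")
    cc = polymorphism.complete_case_columns()
    m = polymorphism.matrix()
    n = polymorphism.n
    og = outgroup_consensus.upper()
    counts = {"fixed": {"syn": 0, "nonsyn": 0}, "polymorphic": {"syn": 0, "nonsyn": 0}}
    for ci in range(polymorphism.length // 3):
        cols = slice(3 * ci, 3 * ci + 3)
        if not cc[cols].all():
            continue
        out_codon = og[3 * ci:3 * ci + 3]
        codons = ["".join(m[i, cols]) for i in range(n)]
        if any(translate(c) in (None, "*") for c in codons):
            continue
        for pos in range(3):
            bases = [c[pos] for c in codons]
            if min_frequency > 0 and len(set(bases)) > 1:
                cnt = {b: bases.count(b) for b in set(bases)}
                if min(cnt.values()) <= min_frequency and len(cnt) == 2:
                    continue
            for kind, cat in _mk_classify_site(codons, out_codon, pos):
                counts[kind][cat] += 1
    Dn, Ds = counts["fixed"]["nonsyn"], counts["fixed"]["syn"]
    Pn, Ps = counts["polymorphic"]["nonsyn"], counts["polymorphic"]["syn"]
    return mk_table_from_counts(Dn, Ds, Pn, Ps)


def mk_table_from_counts(Dn: int, Ds: int, Pn: int, Ps: int) -> MKTable:
    """Assemble an MK table with Fisher and G-test p-values from counts."""
    ni = math.nan
    if Ps > 0 and Ds > 0 and Dn > 0:
        ni = (Pn / Ps) / (Dn / Ds)
    table = np.array([[Pn, Ps], [Dn, Ds]])
    note = ""
    fisher_p = g_p = None
    if (table.sum(axis=0) > 0).all() and (table.sum(axis=1) > 0).all():
        fisher_p = float(stats.fisher_exact(table)[1])
        g_p = float(stats.chi2_contingency(table, lambda_="log-likelihood",
                                           correction=False)[1])
    else:
        note = "p undefined: a marginal total is zero"
    return MKTable(Dn, Ds, Pn, Ps, ni, fisher_p, g_p, note)


# -- HKA -------------------------------------------------------------------

@dataclass
class HKAInput:
    """Per-locus polymorphism/divergence data for the HKA test."""
    locus_names: list
    S: np.ndarray               # within-species segregating sites
    D: np.ndarray               # between-species differences
    L_poly: np.ndarray          # sites analysed for polymorphism
    L_div: np.ndarray           # sites analysed for divergence
    n: np.ndarray               # sample sizes

    def __post_init__(self):
        self.S = np.asarray(self.S, dtype=float)
        self.D = np.asarray(self.D, dtype=float)
        self.L_poly = np.asarray(self.L_poly, dtype=float)
        self.L_div = np.asarray(self.L_div, dtype=float)
        self.n = np.asarray(self.n, dtype=int)

    @property
    def n_loci(self) -> int:
        return len(self.S)


@dataclass
class HKAResult:
    X2: float
    df: int
    p: float
    T_hat: float
    theta_hats: np.ndarray
    expected_S: np.ndarray
    expected_D: np.ndarray


def hka_expectations(theta: np.ndarray, T: float, inputs: HKAInput):
    """E[S_i], Var[S_i], E[D_i], Var[D_i] under the one-species-plus-
    divergence HKA model (equal species sizes, f = 1): per-locus theta
    applies to the polymorphism length; divergence counts are rescaled to
    that length before fitting."""
    a1 = np.array([harmonic(int(ni)) for ni in inputs.n])
    a2 = np.array([harmonic2(int(ni)) for ni in inputs.n])
    ES = theta * a1
    VS = ES + (theta**2) * a2
    ED = theta * (T + 1.0)
    VD = ED + theta**2
    return ES, VS, ED, VD


def _hka_scaled_D(inputs: HKAInput) -> np.ndarray:
    return inputs.D * inputs.L_poly / inputs.L_div


def _hka_solve(inputs: HKAInput):
    """Method-of-moments system: totals of S and D, plus per-locus sums for
    all but the last locus, determine (theta_1..theta_L, T)."""
    L = inputs.n_loci
    a1 = np.array([harmonic(int(ni)) for ni in inputs.n])
    Dsc = _hka_scaled_D(inputs)
    S = inputs.S

    def equations(x):
        theta = np.exp(x[:L])
        T = x[L]
        eqs = np.empty(L + 1)
        eqs[0] = theta @ a1 - S.sum()
        eqs[1] = (theta * (T + 1.0)).sum() - Dsc.sum()
        for i in range(L - 1):
            eqs[2 + i] = theta[i] * (a1[i] + T + 1.0) - (S[i] + Dsc[i])
        return eqs

    # moment-style starting point
    total = S.sum() + Dsc.sum()
    theta0 = np.maximum((S + Dsc) / (a1 + 2.0), 1e-6)
    T0 = max(Dsc.sum() / max(theta0.sum(), 1e-9) - 1.0, 0.1)
    x0 = np.concatenate([np.log(theta0), [T0]])
    sol = optimize.fsolve(equations, x0, full_output=True)
    x, info, ier, msg = sol
    if ier != 1 or not np.all(np.isfinite(x)):
        raise RuntimeError(f"HKA solver failed: {msg}; residual={info['fvec']}")
    return np.exp(x[:L]), float(x[L])


def _hka_x2(theta: np.ndarray, T: float, inputs: HKAInput) -> float:
    ES, VS, ED, VD = hka_expectations(theta, T, inputs)
    Dsc = _hka_scaled_D(inputs)
    return float((((inputs.S - ES) ** 2) / VS + ((Dsc - ED) ** 2) / VD).sum())


def hka_test(inputs: HKAInput) -> HKAResult:
    """Standard multilocus HKA goodness-of-fit test.

    X2 sums squared deviations of S and (length-rescaled) D from their
    neutral expectations over loci, each scaled by its variance; per-locus
    theta and the shared divergence time T are fitted by minimizing X2,
    started from the moment-equation solution (with a multi-start fallback
    when the moment system fails).  The null distribution is chi-square with
    (loci - 1) degrees of freedom; a single locus is saturated and X2 = 0.
    """
    L = inputs.n_loci
    if L < 1:
        raise ValueError("need at least one locus")
    starts = []
    try:
        theta0, T0 = _hka_solve(inputs)
        starts.append(np.concatenate([np.log(theta0), [T0]]))
    except RuntimeError:
        pass
    a1 = np.array([harmonic(int(ni)) for ni in inputs.n])
    Dsc = _hka_scaled_D(inputs)
    rough = np.maximum((inputs.S + Dsc) / (a1 + 2.0), 1e-6)
    for T0 in (0.5, 2.0, 5.0, 10.0):
        starts.append(np.concatenate([np.log(rough), [T0]]))

    def objective(x):
        return _hka_x2(np.exp(x[:L]), x[L], inputs)

    best = None
    for x0 in starts:
        res = optimize.minimize(objective, x0, method="Nelder-Mead",
                                options={"maxiter": 40_000, "maxfev": 40_000,
                                         "xatol": 1e-12, "fatol": 1e-14})
        if best is None or res.fun < best.fun:
            best = res
    if best is None or not np.all(np.isfinite(best.x)):
        raise RuntimeError("HKA fit failed from every start")
    theta, T = np.exp(best.x[:L]), float(best.x[L])
    ES, VS, ED, VD = hka_expectations(theta, T, inputs)
    X2 = float(best.fun)
    df = L - 1
    p = float(stats.chi2.sf(X2, df)) if df > 0 else 1.0
    return HKAResult(X2, df, p, T, theta, ES, ED)


# -- G-test ----------------------------------------------------------------

def gtest_pvalue(G: float, df: int) -> float:
    """Upper-tail chi-square p-value for a G statistic."""
    return float(stats.chi2.sf(G, df))


def exon_gtest(observed: Sequence[float], expected_weights: Sequence[float]):
    """Goodness-of-fit G-test of counts against expectations proportional to
    category weights (e.g. polymorphism counts against exon lengths).

    Returns (G, df, p); zero-observation categories contribute 0 to G and
    df = categories - 1.
    """
    obs = np.asarray(observed, dtype=float)
    w = np.asarray(expected_weights, dtype=float)
    if len(obs) < 2:
        raise ValueError("need at least two categories")
    if (w <= 0).any():
        raise ValueError("expected weights must be positive")
    if obs.sum() < 1:
        raise ValueError("observed total must be >= 1")
    expected = obs.sum() * w / w.sum()
    nz = obs > 0
    G = float(2.0 * (obs[nz] * np.log(obs[nz] / expected[nz])).sum())
    df = len(obs) - 1
    return G, df, gtest_pvalue(G, df)
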