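"""Two-step rejection + local-linear-regression Approximate Bayesian
Computation for the expansion demography, conditioned on (theta_W, pi, R2).

The rejection step standardizes each summary statistic by its reference-
table standard deviation and accepts the draws closest (Euclidean) to the
observed summaries.  The regression step is the Beaumont local-linear
adjustment: Epanechnikov weights on distance, weighted least squares of
log-transformed parameters on the summaries, and residual translation to
the observed summary values, with adjusted draws clamped to the prior
support.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .coalescent import ExpansionModel, simulate_locus_summaries

LOG_EPS = 1e-8


@dataclass(frozen=True)
class PriorSpec:
    """Independent uniform priors, one (lower, upper) pair per parameter."""

    bounds: dict  # name -> (lower, upper)

    def __post_init__(self):
        for name, (lo, hi) in self.bounds.items():
            if not lo < hi:
                raise ValueError(f"prior for {name!r}: lower must be < upper")

    @property
    def names(self) -> list:
        return list(self.bounds)

    def sample(self, n: int, rng: np.random.Generator) -> pd.DataFrame:
        cols = {
            name: rng.uniform(lo, hi, size=n)
            for name, (lo, hi) in self.bounds.items()
        }
        return pd.DataFrame(cols)


@dataclass
class SamplingDesign:
    """Per-locus sample sizes and lengths of the dataset being emulated.

    ``theta0`` in the prior is per site; each locus is simulated with
    theta0 * L.  ``generations_per_year`` converts year-based priors on the
    expansion onset into generations (the simulator's native unit).
    """

    loci: list                  # list of (n_chromosomes, L_sites)
    N0: float = 100_000.0
    generations_per_year: float = 2.0


@dataclass
class ABCResult:
    parameter_names: list
    n_sims: int
    tolerance: float
    accepted: pd.DataFrame      # accepted draws + summaries + distance
    adjusted: pd.DataFrame      # regression-adjusted posterior samples
    summary: dict               # name -> (mean, lower, upper) [2.5%, 97.5%]
    regression_ok: bool = True
    note: str = ""


SUMMARY_COLS = ("theta_w", "pi", "r2")


def build_reference_table(priors: PriorSpec, n_sims: int,
                          design: SamplingDesign, seed: int = 0) -> pd.DataFrame:
    """Simulate i.i.d. prior draws through the coalescent at the study's
    sampling design, reduced to length-weighted (theta_W, pi, R2).

    Replicates where every locus is monomorphic have no R2 and are flagged
    invalid (kept in the table with ``valid = False``).
    """
    rng = np.random.default_rng(seed)
    params = priors.sample(n_sims, rng)
    lengths = np.array([L for _, L in design.loci], dtype=float)
    tw = np.empty(n_sims)
    pi = np.empty(n_sims)
    r2 = np.empty(n_sims)
    valid = np.ones(n_sims, dtype=bool)
    for s in range(n_sims):
        theta_site = params.at[s, "theta0"]
        t_b = params.at[s, "t_b"] if "t_b" in params else 0.0
        g = params.at[s, "g"] if "g" in params else 0.0
        tws, pis, r2s, w_r2 = [], [], [], []
        for n_chr, L in design.loci:
            model = ExpansionModel(theta0=theta_site * L, t_b=t_b, g=g,
                                   N0=design.N0)
            t, p, r = simulate_locus_summaries(model, n_chr, L, rng)
            tws.append(t)
            pis.append(p)
            if math.isfinite(r):
                r2s.append(r)
                w_r2.append(L)
        tw[s] = np.average(tws, weights=lengths)
        pi[s] = np.average(pis, weights=lengths)
        if w_r2:
            r2[s] = np.average(r2s, weights=np.asarray(w_r2, dtype=float))
        else:
            r2[s] = np.nan
            valid[s] = False
    table = params.copy()
    table["theta_w"], table["pi"], table["r2"] = tw, pi, r2
    table["valid"] = valid
    return table


def abc_reject(table: pd.DataFrame, observed: Sequence[float],
               tolerance: float) -> pd.DataFrame:
    """Rejection step: accept the ceil(tolerance * n_sims) draws closest to
    the observed summaries in SD-standardized Euclidean distance."""
    if not 0 < tolerance <= 1:
        raise ValueError("tolerance must be in (0, 1]")
    obs = np.asarray(observed, dtype=float)
    if not np.all(np.isfinite(obs)):
        raise ValueError("observed summaries contain undefined values")
    valid = table[table["valid"]].copy() if "valid" in table else table.copy()
    stats_ = valid[list(SUMMARY_COLS)].to_numpy()
    sd = stats_.std(axis=0, ddof=0)
    sd[sd == 0] = 1.0
    dist = np.sqrt((((stats_ - obs) / sd) ** 2).sum(axis=1))
    valid["distance"] = dist
    n_accept = math.ceil(tolerance * len(table))
    return valid.nsmallest(n_accept, "distance")


def _weighted_quantile(x: np.ndarray, w: np.ndarray, q: float) -> float:
    order = np.argsort(x)
    x, w = x[order], w[order]
    cw = np.cumsum(w)
    cw /= cw[-1]
    return float(np.interp(q, cw, x))


def abc_regress(accepted: pd.DataFrame, observed: Sequence[float],
                parameter_names: Sequence[str],
                priors: Optional[PriorSpec] = None,
                n_sims: int = 0, tolerance: float = float("nan"),
                transform: str = "log") -> ABCResult:
    """Beaumont local-linear regression adjustment of the accepted draws.

    With ``transform="log"`` (the default, suited to the positive
    demographic parameters) parameters are log(x + eps)-transformed before
    the weighted regression and back-transformed after residual
    translation, keeping adjusted draws positive; ``transform="none"``
    regresses on the raw scale (needed when the prior support includes
    negative values).  Draws are then clamped to the prior support.  A
    singular design falls back to the unadjusted rejection posterior with a
    warning note.
    """
    obs = np.asarray(observed, dtype=float)
    names = list(parameter_names)
    if len(accepted) < len(SUMMARY_COLS) + 2:
        raise ValueError("too few accepted draws for the regression")
    S = accepted[list(SUMMARY_COLS)].to_numpy()
    dist = accepted["distance"].to_numpy()
    dmax = dist.max()
    if dmax == 0:
        w = np.ones(len(dist))
    else:
        w = 1.0 - (dist / (dmax * (1 + 1e-12))) ** 2  # Epanechnikov
    if transform == "log":
        P = np.log(accepted[names].to_numpy() + LOG_EPS)
    elif transform == "none":
        P = accepted[names].to_numpy().astype(float)
    else:
        raise ValueError("transform must be 'log' or 'none'")
    X = np.column_stack([np.ones(len(S)), S - obs])
    W = np.sqrt(w)[:, None]
    ok = True
    note = ""
    try:
        beta, *_ = np.linalg.lstsq(X * W, P * W, rcond=None)
        cond = np.linalg.cond(X * W)
        if not np.isfinite(cond) or cond > 1e10:
            raise np.linalg.LinAlgError("ill-conditioned design")
        fitted = X @ beta
        adjusted_log = beta[0] + (P - fitted)
    except np.linalg.LinAlgError:
        ok = False
        note = "singular regression design; unadjusted rejection posterior"
        adjusted_log = P
    if transform == "log":
        adj = np.exp(adjusted_log) - LOG_EPS
    else:
        adj = adjusted_log
    if priors is not None:
        for j, name in enumerate(names):
            lo, hi = priors.bounds[name]
            adj[:, j] = np.clip(adj[:, j], lo, hi)
    adjusted = pd.DataFrame(adj, columns=names)
    adjusted["weight"] = w
    summary = {}
    for name in names:
        x = adjusted[name].to_numpy()
        mean = float(np.average(x, weights=w))
        lower = _weighted_quantile(x, w, 0.025)
        upper = _weighted_quantile(x, w, 0.975)
        summary[name] = (mean, lower, upper)
    return ABCResult(names, n_sims, tolerance, accepted, adjusted, summary,
                     regression_ok=ok, note=note)


def abc_run(priors: PriorSpec, observed: Sequence[float], n_sims: int,
            tolerance: float, design: SamplingDesign, seed: int = 0,
            table: Optional[pd.DataFrame] = None) -> ABCResult:
    """One full rejection + regression pass (reference table may be reused)."""
    if table is None:
        table = build_reference_table(priors, n_sims, design, seed=seed)
    accepted = abc_reject(table, observed, tolerance)
    return abc_regress(accepted, observed, priors.names, priors,
                       n_sims=len(table), tolerance=tolerance)


def derive_run2_priors(run1: ABCResult, fixed: Optional[dict] = None) -> PriorSpec:
    """Run-2 priors from run-1 posterior means: [0, 3 * mean] per parameter
    (the mean plus two means above it, floored at zero).

    Parameters listed in ``fixed`` keep their run-1 bounds.  A degenerate
    (zero-mean) run-1 posterior aborts.
    """
    bounds = {}
    for name in run1.parameter_names:
        mean = run1.summary[name][0]
        if fixed and name in fixed:
            bounds[name] = fixed[name]
            continue
        if mean <= 0:
            raise ValueError(
                f"degenerate run-1 posterior for {name!r} (mean {mean}); "
                "cannot derive run-2 priors")
        bounds[name] = (0.0, 3.0 * mean)
    return PriorSpec(bounds)


def two_step_abc(priors_run1: PriorSpec, observed: Sequence[float],
                 design: SamplingDesign, n_sims: int = 1_000_000,
                 tol1: float = 0.01, tol2: float = 0.001,
                 seed: int = 0, fixed: Optional[dict] = None):
    """The two-step scheme: a liberal first pass over broad priors, then a
    second pass with priors narrowed to [0, 3 x run-1 posterior mean] and a
    tighter tolerance.  Returns (run1 result, run2 result)."""
    run1 = abc_run(priors_run1, observed, n_sims, tol1, design, seed=seed)
    priors2 = derive_run2_priors(run1, fixed=fixed)
    run2 = abc_run(priors2, observed, n_sims, tol2, design, seed=seed + 1)
    return run1, run2
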