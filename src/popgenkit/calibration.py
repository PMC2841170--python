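"""Calibration experiments for the ABC machinery: a linear-Gaussian toy
with a known posterior, and a parameter-recovery (coverage) experiment on
synthetic data simulated at known demographic parameters.

These are the package's own validation instruments; the test suite and the
reproduction script both run them rather than freezing their outcomes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .abc import (PriorSpec, SamplingDesign, abc_regress, abc_reject,
                  build_reference_table)
from .coalescent import ExpansionModel, simulate_locus_summaries


def linear_gaussian_toy(n_sims: int = 200_000, tolerance: float = 0.005,
                        s_obs: float = 0.0, seed: int = 0) -> dict:
    """mu ~ U(-10, 10), s = mu + N(0, 1), observe s_obs.

    The true posterior is N(s_obs, 1) (up to negligible truncation), so the
    adjusted posterior mean should sit within ~0.1 of s_obs and its sd near
    1.  Only the first summary carries signal; the other two are pure
    noise, mimicking uninformative statistics.
    """
    rng = np.random.default_rng(seed)
    mu = rng.uniform(-10, 10, n_sims)
    table = pd.DataFrame({
        "mu": mu,
        "theta_w": mu + rng.normal(size=n_sims),
        "pi": rng.normal(size=n_sims),
        "r2": rng.normal(size=n_sims),
        "valid": True,
    })
    obs = [s_obs, 0.0, 0.0]
    accepted = abc_reject(table, obs, tolerance)
    res = abc_regress(accepted, obs, ["mu"], None, n_sims=n_sims,
                      tolerance=tolerance, transform="none")
    x = res.adjusted["mu"].to_numpy()
    w = res.adjusted["weight"].to_numpy()
    mean = float(np.average(x, weights=w))
    sd = float(math.sqrt(np.average((x - mean) ** 2, weights=w)))
    rej = accepted["mu"].to_numpy()
    return {"posterior_mean": mean, "posterior_sd": sd,
            "rejection_mean": float(rej.mean()),
            "rejection_sd": float(rej.std(ddof=0)),
            "analytic_mean": s_obs, "analytic_sd": 1.0}


@dataclass
class RecoveryTruth:
    theta0_site: float = 0.01
    t_b: float = 942.0
    g: float = 2.85
    N0: float = 10_000.0


def _observed_at_truth(truth: RecoveryTruth, design: SamplingDesign,
                       rng: np.random.Generator):
    lengths = np.array([L for _, L in design.loci], dtype=float)
    tws, pis, r2s, w_r2 = [], [], [], []
    for n_chr, L in design.loci:
        model = ExpansionModel(theta0=truth.theta0_site * L, t_b=truth.t_b,
                               g=truth.g, N0=truth.N0)
        t, p, r = simulate_locus_summaries(model, n_chr, L, rng)
        tws.append(t)
        pis.append(p)
        if math.isfinite(r):
            r2s.append(r)
            w_r2.append(L)
    if not w_r2:
        return None
    return (float(np.average(tws, weights=lengths)),
            float(np.average(pis, weights=lengths)),
            float(np.average(r2s, weights=np.asarray(w_r2, dtype=float))))


def recovery_experiment(n_table: int = 100_000, n_reps: int = 50,
                        tolerance: float = 0.01, seed: int = 0,
                        truth: RecoveryTruth = None,
                        design: SamplingDesign = None) -> dict:
    """Coverage of the 95% adjusted-posterior interval at known truth.

    One reference table of ``n_table`` prior draws is built, then for each
    repetition fresh pseudo-observed summaries are simulated at the truth
    and put through rejection + regression against the shared table; a
    repetition scores when the true value falls inside the [2.5%, 97.5%]
    weighted interval.  Returns per-parameter coverage fractions.
    """
    truth = truth or RecoveryTruth()
    design = design or SamplingDesign(loci=[(20, 500), (20, 400)],
                                      N0=truth.N0)
    priors = PriorSpec({
        "theta0": (1e-4, 3 * truth.theta0_site),
        "t_b": (0.0, 4 * truth.t_b),
        "g": (0.0, 3.5 * truth.g),
    })
    table = build_reference_table(priors, n_table, design, seed=seed)
    rng = np.random.default_rng(seed + 1)
    true_vals = {"theta0": truth.theta0_site, "t_b": truth.t_b, "g": truth.g}
    inside = {k: 0 for k in true_vals}
    done = 0
    while done < n_reps:
        obs = _observed_at_truth(truth, design, rng)
        if obs is None:
            continue
        accepted = abc_reject(table, obs, tolerance)
        res = abc_regress(accepted, obs, priors.names, priors,
                          n_sims=n_table, tolerance=tolerance)
        for k, v in true_vals.items():
            lo, hi = res.summary[k][1], res.summary[k][2]
            if lo <= v <= hi:
                inside[k] += 1
        done += 1
    return {k: inside[k] / n_reps for k in true_vals}
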