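"""Diversity summaries and neutrality statistics against brute-force
oracles, hand-computed examples and published worked values."""

import math

import numpy as np
import pytest

from popgenkit.alignment import PopAlignment
from popgenkit.diversity import (NeutralityResult, build_sfs,
                                 coalescent_pvalue, diversity_summary,
                                 ewens_k_distribution, fay_wu_h, fu_fs,
                                 fu_fs_value, fu_li_d, harmonic,
                                 mismatch_distribution, r2_stat, tajimas_d,
                                 tajimas_d_value, watterson_theta)
from tests.conftest import random_alignment

# ---------------------------------------------------------------- oracles

def oracle_stats(aln):
    """Brute-force S, k, pi, theta_W, singleton counts over complete-case
    columns, written independently of the library internals."""
    seqs = aln.sequences
    n, L = len(seqs), len(seqs[0])
    cols = [c for c in range(L)
            if all(s[c] in "ACGT" for s in seqs)]
    S = 0
    eta = 0
    eta_s = 0
    U = [0.0] * n
    for c in cols:
        alleles = {}
        for i, s in enumerate(seqs):
            alleles.setdefault(s[c], []).append(i)
        if len(alleles) > 1:
            S += 1
            eta += len(alleles) - 1
            for b, idx in alleles.items():
                if len(idx) == 1:
                    eta_s += 1
                    U[idx[0]] += 1
    # k by explicit all-pairs count
    tot = 0
    for i in range(n):
        for j in range(i + 1, n):
            tot += sum(1 for c in cols if seqs[i][c] != seqs[j][c])
    k = tot / (n * (n - 1) / 2)
    a1 = sum(1 / i for i in range(1, n))
    return {"S": S, "eta": eta, "k": k, "pi": k / len(cols),
            "theta_w": S / (a1 * len(cols)),
            "eta_s": eta_s, "U": np.array(U), "L": len(cols)}


def oracle_tajima(n, S, k):
    a1 = sum(1 / i for i in range(1, n))
    a2 = sum(1 / i**2 for i in range(1, n))
    b1 = (n + 1) / (3 * (n - 1))
    b2 = 2 * (n * n + n + 3) / (9 * n * (n - 1))
    c1 = b1 - 1 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    var = (c1 / a1) * S + (c2 / (a1**2 + a2)) * S * (S - 1)
    return (k - S / a1) / math.sqrt(var)


def oracle_r2(n, S, k, U):
    return math.sqrt(sum((u - k / 2) ** 2 for u in U) / n) / S


def oracle_d_star(n, eta, eta_s):
    a = sum(1 / i for i in range(1, n))
    b = sum(1 / i**2 for i in range(1, n))
    c = 2 * (n * a - 2 * (n - 1)) / ((n - 1) * (n - 2))
    an1 = a + 1 / n
    d = c + (n - 2) / (n - 1) ** 2 + (2 / (n - 1)) * (
        1.5 - (2 * an1 - 3) / (n - 2) - 1 / n)
    nn = n / (n - 1)
    v = (nn**2 * b + a**2 * d - 2 * (n * a * (a + 1)) / (n - 1) ** 2) / (a**2 + b)
    u = nn * (a - nn) - v
    return (nn * eta - a * eta_s) / math.sqrt(u * eta + v * eta**2)


# ------------------------------------------------------------- summaries

class TestDiversitySummary:
    def test_hand_counted_toy(self, toy3):
        s = diversity_summary(toy3)
        assert s.S == 2
        assert s.k == pytest.approx(4 / 3)
        assert s.pi == pytest.approx(4 / 3 / 10)

    def test_identical_sequences(self):
        aln = PopAlignment("t", ["a", "b"], ["P", "P"], ["ACGT", "ACGT"])
        s = diversity_summary(aln)
        assert (s.S, s.pi, s.theta_w) == (0, 0.0, 0.0)

    def test_published_watterson_values(self):
        # reference-gene sample: n=12, 260 sites, S=5
        assert watterson_theta(5, 12, 260) == pytest.approx(0.00637, abs=5e-6)
        # candidate-gene coding region: n=80, 594 sites, S=31
        assert watterson_theta(31, 80, 594) == pytest.approx(0.01054, abs=5e-6)

    def test_matches_bruteforce_oracle_on_random_alignments(self, rng):
        for _ in range(120):
            aln = random_alignment(rng)
            o = oracle_stats(aln)
            s = diversity_summary(aln)
            assert s.S == o["S"]
            assert s.k == pytest.approx(o["k"], abs=1e-10)
            assert s.pi == pytest.approx(o["pi"], abs=1e-10)
            assert s.theta_w == pytest.approx(o["theta_w"], abs=1e-10)

    def test_ambiguity_columns_are_excluded_listwise(self):
        aln = PopAlignment("t", ["a", "b", "c"], ["P"] * 3,
                           ["ANGT", "ATGT", "ATGT"])
        s = diversity_summary(aln)
        assert s.L == 3 and s.S == 0

    def test_syn_nonsyn_partition(self):
        # GGA->GGG is synonymous (Gly), AAA->GAA nonsynonymous (Lys->Glu)
        aln = PopAlignment("t", ["a", "b"], ["P", "P"],
                           ["GGAAAA", "GGGGAA"])
        s = diversity_summary(aln, coding=True)
        assert s.pi_syn > 0 and s.pi_nonsyn > 0
        # one syn diff over mean syn sites; one nonsyn over mean nonsyn sites
        assert s.pi_syn == pytest.approx(1 / s.syn_sites)
        assert s.pi_nonsyn == pytest.approx(1 / s.nonsyn_sites)


# ------------------------------------------------------------------- SFS

class TestSFS:
    def outgrouped(self):
        return PopAlignment(
            "t", list("abcd"), ["P"] * 4,
            ["TAAA", "AAAA", "AAAA", "TAAT"],
            outgroup=("og", "AAAT"),
        )
        # col0: T in a,d (count 2... adjust below)

    def test_no_segregating_sites(self):
        aln = PopAlignment("t", ["a", "b"], ["P", "P"], ["ACGT", "ACGT"])
        assert build_sfs(aln).S == 0

    def test_hand_polarized_counts(self):
        # site 0: derived T count 1; site 3: ancestral T (outgroup), derived A count 3
        aln = PopAlignment(
            "t", list("abcd"), ["P"] * 4,
            ["TAAA", "AAAA", "AAAA", "AAAT"],
            outgroup=("og", "AAAT"),
        )
        sfs = build_sfs(aln, outgroup_polarize=True)
        assert sfs.counts.tolist() == [1, 0, 1]

    def test_hand_folded_counts(self):
        aln = PopAlignment(
            "t", list("abcd"), ["P"] * 4,
            ["TAAA", "AAAA", "AAAA", "AAAT"],
        )
        sfs = build_sfs(aln)
        assert sfs.counts.tolist() == [2, 0]

    def test_polarization_without_outgroup_raises(self, toy3):
        with pytest.raises(ValueError):
            build_sfs(toy3, outgroup_polarize=True)


# ---------------------------------------------------------- Tajima's D

class TestTajimasD:
    def test_published_worked_example(self):
        # n=12, 260 sites, S=5, pi=0.00321 -> D = -1.83
        d = tajimas_d_value(12, 5, 0.00321 * 260)
        assert d == pytest.approx(-1.83, abs=0.005)

    def test_zero_when_k_equals_watterson(self):
        n, S = 10, 7
        assert tajimas_d_value(n, S, S / harmonic(n)) == pytest.approx(0.0, abs=1e-12)

    def test_undefined_at_s_zero(self):
        aln = PopAlignment("t", ["a", "b"], ["P", "P"], ["AC", "AC"])
        assert not tajimas_d(diversity_summary(aln)).defined

    def test_matches_formula_oracle(self, rng):
        for _ in range(100):
            aln = random_alignment(rng)
            s = diversity_summary(aln)
            if s.S < 1:
                continue
            assert tajimas_d(s).value == pytest.approx(
                oracle_tajima(s.n, s.S, s.k), abs=1e-12)


# ----------------------------------------------------------- Fu & Li

class TestFuLi:
    def test_all_external_singletons_negative(self):
        aln = PopAlignment(
            "t", list("abcd"), ["P"] * 4,
            ["TCAA", "AAAA", "AAAA", "AAAA"],
            outgroup=("og", "AAAA"),
        )
        assert fu_li_d(aln, use_outgroup=True).value < 0

    def test_no_singletons_positive(self):
        aln = PopAlignment(
            "t", list("abcd"), ["P"] * 4,
            ["TTAA", "TTAA", "AAAA", "AAAA"],
            outgroup=("og", "AAAA"),
        )
        assert fu_li_d(aln, use_outgroup=True).value > 0
        assert fu_li_d(aln, use_outgroup=False).value > 0

    def test_d_star_matches_formula_oracle(self, rng):
        checked = 0
        for _ in range(100):
            aln = random_alignment(rng, n=int(rng.integers(5, 13)))
            o = oracle_stats(aln)
            if o["S"] < 1:
                continue
            got = fu_li_d(aln, use_outgroup=False).value
            want = oracle_d_star(aln.n, o["eta"], o["eta_s"])
            assert got == pytest.approx(want, abs=1e-10)
            checked += 1
        assert checked > 50


# ----------------------------------------------------------- Fay & Wu H

class TestFayWuH:
    def test_hand_evaluation(self):
        from popgenkit.diversity import SFS
        sfs = SFS(n=4, counts=np.array([1, 0, 1]), polarized=True)
        assert fay_wu_h(sfs).value == pytest.approx(-2 / 3)

    def test_all_singletons_nonnegative(self):
        from popgenkit.diversity import SFS
        sfs = SFS(n=6, counts=np.array([4, 0, 0, 0, 0]), polarized=True)
        assert fay_wu_h(sfs).value >= 0

    def test_empty_sfs_degenerate(self):
        from popgenkit.diversity import SFS
        sfs = SFS(n=5, counts=np.zeros(4, dtype=int), polarized=True)
        res = fay_wu_h(sfs)
        assert res.value == 0.0 and "degenerate" in res.note

    def test_folded_sfs_rejected(self):
        from popgenkit.diversity import SFS
        with pytest.raises(ValueError):
            fay_wu_h(SFS(n=4, counts=np.array([1, 1]), polarized=False))


# ------------------------------------------------------------------- R2

class TestR2:
    def test_hand_evaluation(self):
        aln = PopAlignment(
            "t", list("abcd"), ["P"] * 4,
            ["TTAA", "AAAA", "AAAA", "AAAA"],
        )
        # S=2 singletons both on sequence a; k = 1
        assert r2_stat(aln).value == pytest.approx(math.sqrt(0.75) / 2)

    def test_invariant_to_sequence_order(self, rng):
        aln = random_alignment(rng, n=8, L=40)
        v1 = r2_stat(aln).value
        perm = rng.permutation(8)
        aln2 = aln.subset(perm.tolist())
        v2 = r2_stat(aln2).value
        if math.isnan(v1):
            assert math.isnan(v2)
        else:
            assert v1 == pytest.approx(v2, abs=1e-12)

    def test_matches_formula_oracle(self, rng):
        for _ in range(100):
            aln = random_alignment(rng)
            o = oracle_stats(aln)
            if o["S"] < 1:
                continue
            assert r2_stat(aln).value == pytest.approx(
                oracle_r2(aln.n, o["S"], o["k"], o["U"]), abs=1e-10)


# --------------------------------------------------------------- Fu's Fs

class TestFuFs:
    def test_single_haplotype_boundary(self):
        assert fu_fs_value(10, 2.0, 1) == math.inf

    def test_matches_sympy_ewens_enumeration(self):
        from sympy.functions.combinatorial.numbers import stirling
        for n, theta in [(5, 1.3), (8, 2.7), (10, 0.8)]:
            dist = ewens_k_distribution(n, theta)
            # independent oracle: unsigned Stirling numbers from sympy
            num = [float(stirling(n, k, kind=1, signed=False)) * theta**k
                   for k in range(1, n + 1)]
            oracle = np.array(num) / sum(num)
            assert np.allclose(dist, oracle, atol=1e-12)

    def test_expansion_gives_negative_mean_fs(self, rng):
        from popgenkit.coalescent import ExpansionModel, simulate_sample
        model = ExpansionModel(theta0=5.0, t_b=4000, g=8.0, N0=1000)
        vals = []
        for _ in range(300):
            smp = simulate_sample(model, 12, rng=rng)
            if smp.S == 0:
                continue
            haps = len({row.tobytes() for row in smp.haplotypes})
            counts = smp.haplotypes.sum(axis=0)
            n = smp.n
            k = float((2.0 * counts * (n - counts)).sum() / (n * (n - 1)))
            v = fu_fs_value(n, k, haps)
            if math.isfinite(v):
                vals.append(v)
        assert np.mean(vals) < 0


# ------------------------------------------------------ mismatch & p-values

class TestMismatch:
    def test_point_mass_for_identical(self):
        aln = PopAlignment("t", list("abc"), ["P"] * 3, ["ACGT"] * 3)
        assert mismatch_distribution(aln).tolist() == [3]

    def test_hand_histogram_and_mean(self, toy3):
        hist = mismatch_distribution(toy3)
        assert hist.tolist() == [0, 2, 1]  # diffs {1:2, 2:1}
        s = diversity_summary(toy3)
        mean = np.average(np.arange(len(hist)), weights=hist)
        assert mean == pytest.approx(s.k)


class TestCoalescentPvalue:
    def test_null_median_gives_large_p(self):
        stat = NeutralityResult("tajima_d", 0.0)
        res = coalescent_pvalue(stat, 12, 5, n_sims=2000, seed=1)
        assert res.p_value > 0.5

    def test_published_significance(self):
        stat = NeutralityResult("tajima_d", -1.83)
        res = coalescent_pvalue(stat, 12, 5, n_sims=10_000, seed=7,
                                tail="lower")
        assert res.p_value < 0.05

    def test_deterministic_under_seed(self):
        stat = NeutralityResult("r2", 0.12)
        a = coalescent_pvalue(stat, 10, 6, n_sims=500, seed=42)
        b = coalescent_pvalue(stat, 10, 6, n_sims=500, seed=42)
        assert a.p_value == b.p_value

    def test_undefined_statistic_gets_no_p(self):
        stat = NeutralityResult("tajima_d", math.nan)
        res = coalescent_pvalue(stat, 10, 0, n_sims=10, seed=0)
        assert res.p_value is None
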