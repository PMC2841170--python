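"""dN/dS counting, McDonald-Kreitman, HKA and the G-test, each against an
independent oracle or closed form."""

import itertools
import math

import numpy as np
import pytest

from popgenkit.alignment import PopAlignment
from popgenkit.codon import codon_diffs, codon_sites
from popgenkit.divergence import (HKAInput, dnds_distribution, exon_gtest,
                                  gtest_pvalue, hka_expectations, hka_test,
                                  jukes_cantor, mk_table_from_counts,
                                  mk_test, ng86_dnds)
from popgenkit.diversity import harmonic


class TestNG86:
    def test_identical_sequences(self):
        r = ng86_dnds("ATGGCT", "ATGGCT")
        assert r.dN == r.dS == 0.0
        assert math.isnan(r.omega)

    def test_jukes_cantor_closed_form(self):
        # d = -(3/4) ln(1 - 4*0.3/3) = 0.383119...
        assert jukes_cantor(0.3) == pytest.approx(-0.75 * math.log(0.6), abs=1e-12)

    def test_site_counts_partition_codons(self):
        for codon in ("ATG", "GGG", "AAA", "TTA", "CGA"):
            s, n = codon_sites(codon)
            assert s + n == pytest.approx(3.0)

    def test_hand_tabulated_worksheet(self):
        # 30-codon pair: 2 synonymous diffs (GGA->GGG Gly, CTT->CTC Leu) and
        # 1 nonsynonymous (AAA->GAA Lys->Glu); all single-hit codons
        base = ["ATG"] + ["GCT"] * 26 + ["GGA", "CTT", "AAA"]
        other = ["ATG"] + ["GCT"] * 26 + ["GGG", "CTC", "GAA"]
        a, b = "".join(base), "".join(other)
        r = ng86_dnds(a, b)
        assert r.syn_diffs == pytest.approx(2.0)
        assert r.nonsyn_diffs == pytest.approx(1.0)
        # hand-summed NG86 site counts over both sequences
        sites_a = [codon_sites(c) for c in base]
        sites_b = [codon_sites(c) for c in other]
        syn_sites = (sum(s for s, _ in sites_a) + sum(s for s, _ in sites_b)) / 2
        assert r.syn_sites == pytest.approx(syn_sites)
        assert r.dS == pytest.approx(jukes_cantor(2.0 / syn_sites))

    def test_symmetry(self):
        a = "ATGGCTAAGCGATTA"
        b = "ATGGGTAAACGGTTA"
        ra, rb = ng86_dnds(a, b), ng86_dnds(b, a)
        assert ra.dS == pytest.approx(rb.dS)
        assert ra.dN == pytest.approx(rb.dN)

    def test_internal_stop_rejected(self):
        with pytest.raises(ValueError):
            ng86_dnds("ATGTAA", "ATGAAA")

    def test_multihit_pathway_average(self):
        # TTT (Phe) vs GTA (Val): 2 diffs, 2 pathways, no stops involved
        d = codon_diffs("TTT", "GTA")
        assert d is not None
        assert d[0] + d[1] == pytest.approx(2.0)


class TestDnDsDistribution:
    def test_identical_pairs(self):
        pairs = [("ATGGCT", "ATGGCT")] * 3
        out = dnds_distribution(pairs)
        assert out["dS"]["mean"] == 0.0 and out["dN"]["mean"] == 0.0

    def test_known_rate_ratio_recovered(self, rng):
        # simulate coding pairs with 10:1 synonymous:nonsynonymous hit rates
        from popgenkit.codon import split_codons, translate
        codons = [c for c in map("".join, itertools.product("ACGT", repeat=3))
                  if translate(c) not in (None, "*")]
        pairs = []
        for _ in range(60):
            seq = [str(rng.choice(codons)) for _ in range(120)]
            mutated = list(seq)
            for i, c in enumerate(seq):
                if rng.random() < 0.35:
                    syn = [m for m in codons
                           if sum(x != y for x, y in zip(m, c)) == 1
                           and translate(m) == translate(c)]
                    non = [m for m in codons
                           if sum(x != y for x, y in zip(m, c)) == 1
                           and translate(m) != translate(c)]
                    # per-site 10:1 ratio: weight classes by their site counts
                    from popgenkit.codon import codon_sites
                    s_sites, n_sites = codon_sites(c)
                    w_syn = 10.0 * s_sites if syn else 0.0
                    w_non = 1.0 * n_sites if non else 0.0
                    if w_syn + w_non == 0:
                        continue
                    if rng.random() < w_syn / (w_syn + w_non):
                        mutated[i] = str(rng.choice(syn))
                    else:
                        mutated[i] = str(rng.choice(non))
            pairs.append(("".join(seq), "".join(mutated)))
        out = dnds_distribution(pairs)
        assert out["omega"]["mean"] == pytest.approx(0.1, abs=0.05)

    def test_requires_two_pairs(self):
        with pytest.raises(ValueError):
            dnds_distribution([("ATG", "ATG")])


def fisher_two_tailed_oracle(a, b, c, d):
    """Exhaustive hypergeometric enumeration of the two-tailed Fisher p."""
    def log_comb(n, k):
        return (math.lgamma(n + 1) - math.lgamma(k + 1)
                - math.lgamma(n - k + 1))
    r1, r2 = a + b, c + d
    c1 = a + c
    N = r1 + r2
    def prob(x):
        return math.exp(log_comb(r1, x) + log_comb(r2, c1 - x) - log_comb(N, c1))
    p_obs = prob(a)
    total = 0.0
    for x in range(max(0, c1 - r2), min(r1, c1) + 1):
        p = prob(x)
        if p <= p_obs * (1 + 1e-9):
            total += p
    return total


class TestMK:
    def test_neutrality_index_arithmetic(self):
        t = mk_table_from_counts(10, 10, 2, 10)
        assert t.neutrality_index == pytest.approx(0.2)

    def test_fisher_matches_enumeration(self, rng):
        for _ in range(50):
            a, b, c, d = (int(x) for x in rng.integers(0, 11, size=4))
            if (a + b) == 0 or (c + d) == 0 or (a + c) == 0 or (b + d) == 0:
                continue
            t = mk_table_from_counts(c, d, a, b)
            assert t.fisher_p == pytest.approx(
                fisher_two_tailed_oracle(a, b, c, d), rel=1e-9)

    def test_no_fixed_differences_flags_undefined(self):
        t = mk_table_from_counts(0, 0, 3, 5)
        assert t.fisher_p is None and "undefined" in t.note

    def test_balanced_table_p_one(self):
        t = mk_table_from_counts(5, 5, 5, 5)
        assert t.fisher_p == pytest.approx(1.0)

    def test_classification_from_alignment(self):
        # ingroup: fixed syn diff at codon 2 (GGA vs outgroup GGG), polymorphic
        # nonsyn at codon 3 (AAA/GAA), polymorphic syn at codon 4 (CTT/CTC)
        seqs = ["ATGGGAAAACTT", "ATGGGAGAACTT", "ATGGGAAAACTC"]
        aln = PopAlignment("t", list("abc"), ["P"] * 3, seqs)
        out = "ATGGGGAAACTT"
        t = mk_test(aln, out)
        assert (t.Dn, t.Ds, t.Pn, t.Ps) == (0, 1, 1, 1)

    def test_low_frequency_filter(self):
        seqs = ["ATGAAA"] * 5 + ["ATGGAA"]  # nonsyn singleton
        aln = PopAlignment("t", [f"s{i}" for i in range(6)], ["P"] * 6, seqs)
        out = "ATGAAG"  # fixed syn difference
        strict = mk_test(aln, out)
        filtered = mk_test(aln, out, min_frequency=1)
        assert strict.Pn == 1 and filtered.Pn == 0
        assert strict.Ds == filtered.Ds == 1


def hka_x2_oracle(inputs, grid=80):
    """Brute-force grid/Nelder-Mead minimization of the HKA X2 surface."""
    from scipy.optimize import minimize
    a1 = np.array([harmonic(int(n)) for n in inputs.n])
    Dsc = inputs.D * inputs.L_poly / inputs.L_div

    def x2(params):
        theta = np.abs(params[:-1])
        T = params[-1]
        ES, VS, ED, VD = hka_expectations(theta, T, inputs)
        return float((((inputs.S - ES) ** 2) / VS
                      + ((Dsc - ED) ** 2) / VD).sum())

    best = None
    for T0 in np.linspace(0.5, 15, 8):
        x0 = np.concatenate([(inputs.S + Dsc) / (a1 + 2.0), [T0]])
        res = minimize(x2, x0, method="Nelder-Mead",
                       options={"maxiter": 20000, "xatol": 1e-10, "fatol": 1e-12})
        if best is None or res.fun < best:
            best = res.fun
    return best


class TestHKA:
    def test_single_locus_saturated(self):
        res = hka_test(HKAInput(["a"], [12], [20], [500], [500], [20]))
        assert res.X2 == pytest.approx(0.0, abs=1e-8)
        assert res.df == 0

    def test_proportional_loci_fit_perfectly(self):
        res = hka_test(HKAInput(["a", "b"], [10, 20], [15, 30],
                                [500, 1000], [500, 1000], [20, 20]))
        assert res.X2 == pytest.approx(0.0, abs=1e-8)

    def test_three_locus_matches_minimization_oracle(self):
        inputs = HKAInput(["a", "b", "c"], [10, 25, 8], [15, 20, 30],
                          [500, 1000, 700], [500, 1000, 700], [20, 16, 20])
        res = hka_test(inputs)
        oracle = hka_x2_oracle(inputs)
        assert res.X2 == pytest.approx(oracle, abs=1e-6)
        assert 0.0 <= res.p <= 1.0

    def test_invariant_to_locus_order(self):
        fwd = HKAInput(["a", "b", "c"], [10, 25, 8], [15, 20, 30],
                       [500, 1000, 700], [500, 1000, 700], [20, 16, 20])
        rev = HKAInput(["c", "b", "a"], [8, 25, 10], [30, 20, 15],
                       [700, 1000, 500], [700, 1000, 500], [20, 16, 20])
        assert hka_test(fwd).X2 == pytest.approx(hka_test(rev).X2, rel=1e-6)


class TestGTest:
    def test_published_pvalue_mapping(self):
        assert gtest_pvalue(5.99, 1) == pytest.approx(0.014, abs=5e-4)
        assert gtest_pvalue(0.43, 1) == pytest.approx(0.512, abs=5e-4)

    def test_proportional_counts_give_zero(self):
        G, df, p = exon_gtest([20, 40], [1, 2])
        assert G == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_zero_observation_categories_allowed(self):
        G, df, p = exon_gtest([10, 0], [1, 1])
        assert math.isfinite(G) and 0 <= p <= 1

    def test_nonpositive_weights_rejected(self):
        with pytest.raises(ValueError):
            exon_gtest([1, 2], [1, 0])
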