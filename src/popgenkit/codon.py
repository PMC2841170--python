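"""Codon-level counting used by both polymorphism and divergence statistics.

Implements the Nei & Gojobori (1986) bookkeeping: the fraction of synonymous
sites per codon position, and synonymous/nonsynonymous difference counts for
a codon pair averaged over all minimal substitution pathways, with pathways
passing through stop codons excluded.
"""

from __future__ import annotations

import itertools
from functools import lru_cache

from Bio.Data.CodonTable import standard_dna_table

BASES = "ACGT"
CODON_TABLE = dict(standard_dna_table.forward_table)
STOP_CODONS = frozenset(standard_dna_table.stop_codons)


def translate(codon: str):
    """Amino acid for a codon, ``*`` for stop, None if not a plain codon."""
    if codon in STOP_CODONS:
        return "*"
    return CODON_TABLE.get(codon)


@lru_cache(maxsize=None)
def syn_fraction(codon: str) -> tuple:
    """Per-position fraction of the 3 possible single-base changes that are
    synonymous; mutations creating stops are excluded from the denominator.

    Returns a 3-tuple f_i; the number of synonymous sites in the codon is
    sum(f_i), nonsynonymous sites 3 - sum(f_i).
    """
    aa = translate(codon)
    if aa is None or aa == "*":
        raise ValueError(f"cannot count sites for codon {codon!r}")
    fracs = []
    for pos in range(3):
        syn = 0
        total = 0
        for b in BASES:
            if b == codon[pos]:
                continue
            mut = codon[:pos] + b + codon[pos + 1:]
            if mut in STOP_CODONS:
                continue
            total += 1
            if translate(mut) == aa:
                syn += 1
        fracs.append(syn / total if total else 0.0)
    return tuple(fracs)


def codon_sites(codon: str) -> tuple:
    """(synonymous sites, nonsynonymous sites) of one codon."""
    f = syn_fraction(codon)
    s = sum(f)
    return s, 3.0 - s


@lru_cache(maxsize=None)
def codon_diffs(codon_a: str, codon_b: str) -> tuple:
    """(synonymous, nonsynonymous) difference counts between two codons.

    Codons differing at k positions are connected by k! minimal pathways of
    single-base steps; each step is classified by whether it preserves the
    amino acid.  Pathways through a stop codon are excluded; counts are the
    average over remaining pathways.  If every pathway passes through a stop
    the codon pair is uncountable and ``None`` is returned.
    """
    if codon_a == codon_b:
        return 0.0, 0.0
    diff_pos = [i for i in range(3) if codon_a[i] != codon_b[i]]
    syn_tot, nonsyn_tot, n_paths = 0.0, 0.0, 0
    for order in itertools.permutations(diff_pos):
        cur = codon_a
        syn, nonsyn = 0, 0
        ok = True
        for pos in order:
            nxt = cur[:pos] + codon_b[pos] + cur[pos + 1:]
            if nxt in STOP_CODONS:
                ok = False
                break
            if translate(cur) in (None, "*"):
                ok = False
                break
            if translate(nxt) == translate(cur):
                syn += 1
            else:
                nonsyn += 1
            cur = nxt
        if ok:
            syn_tot += syn
            nonsyn_tot += nonsyn
            n_paths += 1
    if n_paths == 0:
        return None
    return syn_tot / n_paths, nonsyn_tot / n_paths


def split_codons(seq: str):
    """Yield successive 3-mers of a coding sequence (length must be %3==0)."""
    if len(seq) % 3 != 0:
        raise ValueError("coding sequence length not divisible by 3")
    for i in range(0, len(seq), 3):
        yield seq[i:i + 3]
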