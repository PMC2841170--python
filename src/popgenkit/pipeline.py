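"""Batch orchestration: run the full within-species analysis on an input
bundle (per-locus FASTA + popmap + annotations) and emit fixed-layout TSV
tables plus a JSON run manifest.

Output tables (all floats at 5 decimals):

* ``diversity.tsv``   — per locus x population (and pooled total) diversity
  summary: n, analysed sites, S, pi, theta_W, pi_syn, pi_nonsyn, ns/ss,
  haplotype count.
* ``amova.tsv``       — per locus variance-component percentages and
  permutation p-values.
* ``fst.tsv`` / ``exact.tsv`` / ``migration.tsv`` — pairwise matrices.
* ``neutrality.tsv``  — Tajima's D, Fu & Li's D*, R2, Fu's Fs with
  fixed-S coalescent p-values.
* ``manifest.json``   — seed, versions, per-locus status.

A failing locus is reported in the manifest and skipped; the exit status of
the CLI reflects partial failure.
"""

from __future__ import annotations

import json
import sys
from pathlib import Path

import numpy as np

from . import __version__
from .alignment import (PopAlignment, collapse_haplotypes, extract_coding,
                        read_alignment, read_annotation)
from .diversity import (coalescent_pvalue, diversity_summary, fu_fs,
                        r2_stat, tajimas_d, fu_li_d)
from .structure import amova, exact_test, pairwise_fst

F = "{:.5f}"


def _fmt(x) -> str:
    if x is None:
        return "n/a"
    if isinstance(x, float):
        if np.isnan(x):
            return "n/a"
        if np.isinf(x):
            return "inf"
        return F.format(x)
    return str(x)


def discover_bundle(bundle_dir) -> list:
    """Find (locus_name, fasta, annotation_or_None) entries in a bundle
    directory; the popmap is ``popmap.tsv``."""
    d = Path(bundle_dir)
    loci = []
    for fasta in sorted(d.glob("*.fasta")):
        if fasta.stem.endswith(".outgroup"):
            continue
        ann = d / f"{fasta.stem}.annotation.tsv"
        og = d / f"{fasta.stem}.outgroup.fasta"
        loci.append((fasta.stem, fasta, ann if ann.exists() else None,
                     og if og.exists() else None))
    return loci


def load_bundle(bundle_dir) -> dict:
    """Read every locus of a bundle into PopAlignments keyed by name."""
    d = Path(bundle_dir)
    popmap = d / "popmap.tsv"
    if not popmap.exists():
        raise FileNotFoundError(f"no popmap.tsv in {bundle_dir}")
    out = {}
    for name, fasta, ann_path, og_path in discover_bundle(d):
        ann = read_annotation(ann_path) if ann_path else None
        out[name] = read_alignment(fasta, popmap, annotation=ann,
                                   outgroup_fasta=og_path, locus_name=name)
    return out


def run_full_analysis(bundle_dir, out_dir, seed: int = 0,
                      n_perm: int = 1_000, n_sims: int = 2_000,
                      exact_steps: int = 40_000, exact_burn: int = 10_000) -> int:
    """Run diversity, neutrality and structure analyses on every locus.

    Permutation/simulation counts are parameters so that quick looks and
    full-scale runs (10,100 permutations, 10,000 coalescent replicates,
    400,000 chain steps) use the same code path.  Returns the number of
    failed loci (also the suggested exit code).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    alns = load_bundle(bundle_dir)
    rng = np.random.default_rng(seed)
    manifest = {"seed": seed, "version": __version__, "loci": {},
                "n_perm": n_perm, "n_sims": n_sims}
    div_rows, neu_rows, amova_rows = [], [], []
    fst_rows, exact_rows, mig_rows = [], [], []
    failures = 0
    for name, aln in alns.items():
        try:
            coding = extract_coding(aln) if aln.annotation else aln
            pops = aln.population_ids
            for label, sub in [(p, coding.restrict_populations([p])) for p in pops] + [
                    ("total", coding)]:
                s = diversity_summary(sub, coding=True)
                div_rows.append([name, label, s.n, s.L, s.S,
                                 _fmt(s.pi), _fmt(s.theta_w), _fmt(s.pi_syn),
                                 _fmt(s.pi_nonsyn), _fmt(s.ns_ss),
                                 s.n_haplotypes if s.n_haplotypes is not None else "n/a"])
            s_tot = diversity_summary(coding, coding=False)
            d_stat = tajimas_d(s_tot)
            d_stat = coalescent_pvalue(d_stat, s_tot.n, s_tot.S, n_sims=n_sims,
                                       seed=int(rng.integers(2**31)))
            ds_stat = fu_li_d(coding, use_outgroup=False)
            ds_stat = coalescent_pvalue(ds_stat, s_tot.n, s_tot.S, n_sims=n_sims,
                                        seed=int(rng.integers(2**31)))
            r2 = r2_stat(coding)
            r2 = coalescent_pvalue(r2, s_tot.n, s_tot.S, n_sims=n_sims,
                                   seed=int(rng.integers(2**31)))
            fs = fu_fs(s_tot)
            for st in (d_stat, ds_stat, r2, fs):
                neu_rows.append([name, st.statistic_name, _fmt(st.value),
                                 _fmt(st.p_value), st.n_simulations, st.note])
            groups = _groups_from_popmap(Path(bundle_dir) / "popmap.tsv")
            am = amova(coding, grouping=groups or None, n_perm=n_perm,
                       seed=int(rng.integers(2**31)))
            amova_rows.append([name] + [_fmt(x) for x in am.percentages] +
                              [_fmt(am.phi_st), _fmt(am.p_values.get("phi_st")),
                               _fmt(am.p_values.get("phi_sc")),
                               _fmt(am.p_values.get("phi_ct"))])
            ps = pairwise_fst(coding, n_perm=n_perm,
                              seed=int(rng.integers(2**31)))
            hap = collapse_haplotypes(aln)
            ex = exact_test(hap, chain_steps=exact_steps, burn_in=exact_burn,
                            seed=int(rng.integers(2**31))) if hap.available else None
            for i in range(len(ps.populations)):
                for j in range(i + 1, len(ps.populations)):
                    pa, pb = ps.populations[i], ps.populations[j]
                    fst_rows.append([name, pa, pb, _fmt(ps.fst[i, j]),
                                     _fmt(ps.fst_p[i, j])])
                    mig_rows.append([name, pa, pb, _fmt(ps.M[i, j])])
                    if ex is not None:
                        p_se = ex["pairs"].get((pa, pb)) or ex["pairs"].get((pb, pa))
                        exact_rows.append([name, pa, pb, _fmt(p_se[0]), _fmt(p_se[1])])
                    else:
                        exact_rows.append([name, pa, pb, "n/a", "n/a"])
            manifest["loci"][name] = "ok"
        except Exception as exc:  # partial-failure policy: report and skip
            manifest["loci"][name] = f"failed: {exc}"
            failures += 1
    _write_tsv(out / "diversity.tsv",
               ["locus", "population", "n", "sites", "S", "pi", "theta_w",
                "pi_syn", "pi_nonsyn", "ns_ss", "n_haplotypes"], div_rows)
    _write_tsv(out / "neutrality.tsv",
               ["locus", "statistic", "value", "p", "n_simulations", "note"],
               neu_rows)
    _write_tsv(out / "amova.tsv",
               ["locus", "pct_among_groups", "pct_among_pops", "pct_within_pops",
                "phi_st", "p_phi_st", "p_phi_sc", "p_phi_ct"], amova_rows)
    _write_tsv(out / "fst.tsv", ["locus", "pop_a", "pop_b", "fst", "p"], fst_rows)
    _write_tsv(out / "exact.tsv", ["locus", "pop_a", "pop_b", "p", "se"], exact_rows)
    _write_tsv(out / "migration.tsv", ["locus", "pop_a", "pop_b", "M"], mig_rows)
    # family-wise flags for the pairwise Fst tests, per locus
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return failures


def _groups_from_popmap(path) -> dict:
    groups = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) >= 3:
                groups[parts[1]] = parts[2]
    return groups


def _write_tsv(path, header, rows):
    with open(path, "w") as fh:
        fh.write("\t".join(header) + "\n")
        for row in rows:
            fh.write("\t".join(str(x) for x in row) + "\n")
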