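"""Generate complete study-shaped datasets (per-locus FASTA, population map,
coding annotation, truth record) so the whole analysis pipeline can run
without any external download.

The default design emulates a four-population survey (DE, FR, IT, US; two
continental groups) of ten diploid individuals per population at seven
nuclear loci of 211-943 bp, one of which carries an intron/exon structure.
Cloned loci emit two haploid sequences per individual; directly sequenced
loci emit one unphased sequence per individual with IUPAC codes at
heterozygous sites.  Demography is a neutral n-island coalescent with
recent exponential expansion; the generator never simulates selection, so
every dataset is a draw from the demographic null.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np

from .alignment import (CodingAnnotation, IUPAC_FROM_PAIR, PopAlignment,
                        write_alignment, write_annotation)
from .coalescent import ExpansionModel, simulate_island_sample

BASES = "ACGT"


@dataclass(frozen=True)
class LocusDesign:
    name: str
    length: int
    coding_intervals: tuple      # 0-based half-open column ranges
    cloned: bool = True          # False = direct-sequenced (unphased)
    theta_site: float = 0.01     # per-site scaled mutation rate

    @property
    def annotation(self) -> CodingAnnotation:
        return CodingAnnotation(self.coding_intervals)


def default_loci() -> list:
    """Seven loci mirroring the study's layout: one intron-bearing candidate
    segment plus mostly exonic references; lengths span 211-943 bp."""
    return [
        # candidate gene segment: 943 columns of which 594 are coding
        LocusDesign("nspD2", 943, ((0, 174), (349, 594), (768, 943)),
                    cloned=True, theta_site=0.018),
        LocusDesign("nspD3", 705, ((0, 231), (474, 705)),
                    cloned=True, theta_site=0.015),
        LocusDesign("idh", 291, ((0, 291),), cloned=True, theta_site=0.007),
        LocusDesign("ga3pdh", 351, ((0, 351),), cloned=True, theta_site=0.006),
        LocusDesign("coi", 753, ((0, 753),), cloned=True, theta_site=0.009),
        LocusDesign("argkinase", 261, ((0, 261),), cloned=False, theta_site=0.005),
        LocusDesign("wingless", 211, ((1, 211),), cloned=False, theta_site=0.015),
    ]


@dataclass
class StudyDesign:
    populations: tuple = ("DE", "FR", "IT", "US")
    groups: dict = field(default_factory=lambda: {
        "DE": "EU", "FR": "EU", "IT": "EU", "US": "NA"})
    individuals_per_pop: int = 10
    loci: list = field(default_factory=default_loci)
    # recent expansion comparable to the inferred posterior, scaled down 10x
    # in N0 so simulated genealogies stay cheap
    demography: ExpansionModel = field(default_factory=lambda: ExpansionModel(
        theta0=1.0, t_b=942.0, g=2.85, N0=10_000.0))
    migration: float = 20.0      # scaled migrant number 4*N0*m (weak structure)
    merge_time: Optional[float] = None   # required when migration == 0
    selection_free: bool = True  # the generator is strictly neutral


def _mutate_sequences(haplotypes: np.ndarray, L: int,
                      rng: np.random.Generator) -> list:
    """Translate binary infinite-sites haplotypes into nucleotide sequences:
    a random ancestral base per column, mutations at distinct random columns
    with a random distinct derived base."""
    n, S = haplotypes.shape
    ancestral = rng.integers(4, size=L)
    seqs = np.tile(ancestral, (n, 1))
    if S > L:
        raise ValueError("more mutations than columns; increase locus length")
    cols = rng.choice(L, size=S, replace=False)
    for m, c in enumerate(cols):
        derived = (ancestral[c] + 1 + rng.integers(3)) % 4
        carriers = haplotypes[:, m] == 1
        seqs[carriers, c] = derived
    lut = np.array(list(BASES))
    return ["".join(lut[row]) for row in seqs]


def _collapse_diploid(seq_a: str, seq_b: str) -> str:
    """IUPAC-collapse two phased haploid sequences into one unphased call."""
    out = []
    for x, y in zip(seq_a, seq_b):
        if x == y:
            out.append(x)
        else:
            out.append(IUPAC_FROM_PAIR[frozenset((x, y))])
    return "".join(out)


def generate_locus(design: StudyDesign, locus: LocusDesign,
                   rng: np.random.Generator) -> PopAlignment:
    """Simulate one locus for every individual in the design.

    Two chromosomes per individual are always simulated; cloned loci report
    both phased copies, direct-sequenced loci report the IUPAC-collapsed
    diploid consensus.
    """
    n_pops = len(design.populations)
    chroms_per_pop = 2 * design.individuals_per_pop
    model = ExpansionModel(
        theta0=locus.theta_site * locus.length,
        t_b=design.demography.t_b, g=design.demography.g,
        N0=design.demography.N0)
    sample = simulate_island_sample(
        model, [chroms_per_pop] * n_pops, design.migration,
        merge_time=design.merge_time, rng=rng)
    seqs = _mutate_sequences(sample.haplotypes, locus.length, rng)
    ids, pops, out_seqs = [], [], []
    row = 0
    for p, pop in enumerate(design.populations):
        for ind in range(design.individuals_per_pop):
            a, b = seqs[row], seqs[row + 1]
            row += 2
            if locus.cloned:
                for copy, s in (("a", a), ("b", b)):
                    ids.append(f"{pop}{ind + 1:02d}{copy}")
                    pops.append(pop)
                    out_seqs.append(s)
            else:
                ids.append(f"{pop}{ind + 1:02d}")
                pops.append(pop)
                out_seqs.append(_collapse_diploid(a, b))
    return PopAlignment(locus.name, ids, pops, out_seqs,
                        annotation=locus.annotation)


def generate_dataset(design: StudyDesign, seed: int, out_dir) -> dict:
    """Write the full bundle: per-locus FASTA + annotation TSV, one shared
    population map, and a JSON truth record of all generator parameters.
    Returns a manifest dict (also written as ``truth.json``)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    manifest = {
        "seed": seed,
        "populations": list(design.populations),
        "groups": design.groups,
        "individuals_per_pop": design.individuals_per_pop,
        "migration": design.migration,
        "demography": {
            "theta0_per_site": None,  # per locus, see loci
            "t_b": design.demography.t_b,
            "g": design.demography.g,
            "N0": design.demography.N0,
        },
        "loci": [],
    }
    for locus in design.loci:
        aln = generate_locus(design, locus, rng)
        fasta = out / f"{locus.name}.fasta"
        popmap = out / "popmap.tsv"
        write_alignment(aln, fasta)
        # popmap must cover every sample id across loci (cloned ids differ
        # from direct-sequenced ids), so append any unseen ids
        mode = "a" if popmap.exists() else "w"
        seen = set()
        if popmap.exists():
            with open(popmap) as fh:
                seen = {line.split("\t")[0] for line in fh if line.strip()}
        with open(popmap, mode) as fh:
            for sid, pop in zip(aln.sample_ids, aln.populations):
                if sid not in seen:
                    fh.write(f"{sid}\t{pop}\t{design.groups[pop]}\n")
                    seen.add(sid)
        write_annotation(locus.annotation, out / f"{locus.name}.annotation.tsv")
        manifest["loci"].append({
            "name": locus.name, "length": locus.length,
            "coding_intervals": [list(x) for x in locus.coding_intervals],
            "cloned": locus.cloned, "theta_site": locus.theta_site,
            "fasta": fasta.name,
        })
    with open(out / "truth.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest
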