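"""Alignment containers and I/O for multi-population sequence data.

A :class:`PopAlignment` holds aligned haploid gene copies (one sequence per
sampled chromosome) together with a sample -> population map, an optional
coding annotation and an optional single outgroup sequence.  All coordinates
are 0-based, half-open, on alignment columns.

Polymorphism statistics downstream use a listwise complete-case convention:
any column containing a gap, ``N`` or IUPAC ambiguity code in *any* ingroup
sequence is excluded from analysis (the outgroup does not participate in this
mask).  :meth:`PopAlignment.complete_case_columns` exposes the mask.
"""

from __future__ import annotations

import collections
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

UNAMBIGUOUS = frozenset("ACGT")

#: IUPAC ambiguity code -> set of bases (heterozygote calls in directly
#: sequenced, unphased loci are stored with these codes).
IUPAC_AMBIGUITY = {
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}
IUPAC_FROM_PAIR = {frozenset(v): k for k, v in IUPAC_AMBIGUITY.items() if len(v) == 2}


class AlignmentError(ValueError):
    """Raised when sequences do not form a valid alignment."""


class MetadataError(KeyError):
    """Raised when a sample is missing from the population map."""


class AnnotationError(ValueError):
    """Raised for inconsistent coding annotations."""


@dataclass(frozen=True)
class CodingAnnotation:
    """Coding structure of a locus on alignment columns.

    Parameters
    ----------
    intervals : list of (start, end)
        Non-overlapping, sorted, 0-based half-open column ranges of exons.
    frame_offset : int
        Number of leading coding columns to drop so that the concatenated
        coding sequence starts on a codon boundary (0-2).
    labels : list of str, optional
        One label per interval (e.g. exon names).
    """

    intervals: tuple
    frame_offset: int = 0
    labels: Optional[tuple] = None

    def __post_init__(self):
        ivals = tuple((int(a), int(b)) for a, b in self.intervals)
        object.__setattr__(self, "intervals", ivals)
        if self.labels is not None:
            object.__setattr__(self, "labels", tuple(self.labels))
            if len(self.labels) != len(ivals):
                raise AnnotationError("one label per interval required")
        last = -1
        for a, b in ivals:
            if a < 0 or b <= a:
                raise AnnotationError(f"bad interval [{a}, {b})")
            if a < last:
                raise AnnotationError("intervals must be sorted and non-overlapping")
            last = b
        if not 0 <= self.frame_offset <= 2:
            raise AnnotationError("frame_offset must be 0, 1 or 2")
        if (self.coding_length - self.frame_offset) % 3 != 0:
            raise AnnotationError(
                "coding length after frame adjustment not divisible by 3"
            )

    @property
    def coding_length(self) -> int:
        return sum(b - a for a, b in self.intervals)

    def coding_columns(self) -> np.ndarray:
        """All coding column indices, frame-adjusted, in ascending order."""
        cols = np.concatenate([np.arange(a, b) for a, b in self.intervals])
        return cols[self.frame_offset:]

    def column_labels(self) -> dict:
        """Map column index -> interval label (identity index if unlabeled)."""
        out = {}
        for i, (a, b) in enumerate(self.intervals):
            lab = self.labels[i] if self.labels is not None else str(i)
            for c in range(a, b):
                out[c] = lab
        return out


@dataclass
class PopAlignment:
    """Aligned haploid gene copies with population labels.

    ``sample_ids``, ``populations`` and ``sequences`` are parallel, ordered
    lists; the outgroup is never counted in the sample size ``n``.
    """

    locus_name: str
    sample_ids: list
    populations: list
    sequences: list
    annotation: Optional[CodingAnnotation] = None
    outgroup: Optional[tuple] = None  # (id, sequence)
    _cc_cache: Optional[np.ndarray] = field(default=None, repr=False, compare=False)

    def __post_init__(self):
        if len(self.sequences) < 2:
            raise AlignmentError("an alignment needs at least 2 sequences")
        if not (len(self.sample_ids) == len(self.populations) == len(self.sequences)):
            raise AlignmentError("ids, populations and sequences must be parallel")
        self.sequences = [s.upper() for s in self.sequences]
        L = len(self.sequences[0])
        for sid, s in zip(self.sample_ids, self.sequences):
            if len(s) != L:
                raise AlignmentError(
                    f"sequence {sid!r} has length {len(s)}, expected {L}"
                )
        if self.outgroup is not None:
            oid, oseq = self.outgroup
            oseq = oseq.upper()
            if len(oseq) != L:
                raise AlignmentError("outgroup length differs from alignment")
            self.outgroup = (oid, oseq)

    # -- basic properties -------------------------------------------------
    @property
    def n(self) -> int:
        return len(self.sequences)

    @property
    def length(self) -> int:
        return len(self.sequences[0])

    @property
    def population_ids(self) -> list:
        seen = dict.fromkeys(self.populations)
        return list(seen)

    def matrix(self) -> np.ndarray:
        """(n, L) array of single characters."""
        return np.array([list(s) for s in self.sequences])

    def complete_case_columns(self) -> np.ndarray:
        """Boolean mask of columns with only A/C/G/T in every ingroup sequence."""
        if self._cc_cache is None:
            m = self.matrix()
            ok = np.isin(m, list(UNAMBIGUOUS)).all(axis=0)
            self._cc_cache = ok
        return self._cc_cache

    def subset(self, indices: Sequence[int], locus_name: Optional[str] = None) -> "PopAlignment":
        """Row subset (by sequence index), keeping annotation and outgroup."""
        idx = list(indices)
        return PopAlignment(
            locus_name=locus_name or self.locus_name,
            sample_ids=[self.sample_ids[i] for i in idx],
            populations=[self.populations[i] for i in idx],
            sequences=[self.sequences[i] for i in idx],
            annotation=self.annotation,
            outgroup=self.outgroup,
        )

    def restrict_populations(self, pops: Sequence[str]) -> "PopAlignment":
        keep = [i for i, p in enumerate(self.populations) if p in set(pops)]
        return self.subset(keep)

    def take_columns(self, cols: np.ndarray, locus_name: Optional[str] = None,
                     annotation: Optional[CodingAnnotation] = None) -> "PopAlignment":
        cols = np.asarray(cols, dtype=int)
        seqs = ["".join(s[c] for c in cols) for s in self.sequences]
        og = None
        if self.outgroup is not None:
            oid, oseq = self.outgroup
            og = (oid, "".join(oseq[c] for c in cols))
        return PopAlignment(
            locus_name=locus_name or self.locus_name,
            sample_ids=list(self.sample_ids),
            populations=list(self.populations),
            sequences=seqs,
            annotation=annotation,
            outgroup=og,
        )


@dataclass
class HaplotypeTable:
    """Distinct haplotypes with per-population occurrence counts.

    ``available`` is False for unphased loci where more than 10% of columns
    were excluded by the complete-case rule; counts are then meaningless and
    downstream exact tests report "n/a".
    """

    haplotypes: list
    populations: list
    counts: np.ndarray  # (n_haplotypes, n_populations)
    available: bool = True

    @property
    def n_haplotypes(self) -> int:
        return len(self.haplotypes)


# -- I/O -------------------------------------------------------------------

def read_popmap(path) -> dict:
    """Read a tab-delimited sample->population(->group) map.

    Returns ``{sample_id: (population, group_or_None)}``.
    """
    out = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise MetadataError(f"malformed popmap line: {line!r}")
            out[parts[0]] = (parts[1], parts[2] if len(parts) > 2 else None)
    return out


def read_alignment(fasta_path, popmap_path, annotation: Optional[CodingAnnotation] = None,
                   outgroup_fasta=None, locus_name: Optional[str] = None) -> PopAlignment:
    """Read a per-locus FASTA plus a population map into a :class:`PopAlignment`.

    Every FASTA record id must be present in the population map.  Input order
    is preserved and letters are upper-cased.  An optional outgroup FASTA must
    contain exactly one aligned record.
    """
    records = list(SeqIO.parse(str(fasta_path), "fasta"))
    if not records:
        raise AlignmentError(f"no records in {fasta_path}")
    popmap = read_popmap(popmap_path)
    ids, pops, seqs = [], [], []
    for rec in records:
        if rec.id not in popmap:
            raise MetadataError(f"sample {rec.id!r} missing from population map")
        ids.append(rec.id)
        pops.append(popmap[rec.id][0])
        seqs.append(str(rec.seq).upper())
    outgroup = None
    if outgroup_fasta is not None:
        og = list(SeqIO.parse(str(outgroup_fasta), "fasta"))
        if len(og) != 1:
            raise AlignmentError("outgroup FASTA must contain exactly one record")
        outgroup = (og[0].id, str(og[0].seq).upper())
    name = locus_name or Path(str(fasta_path)).stem
    return PopAlignment(name, ids, pops, seqs, annotation=annotation, outgroup=outgroup)


def write_alignment(aln: PopAlignment, fasta_path, popmap_path=None,
                    groups: Optional[dict] = None) -> None:
    """Write FASTA (and optionally the popmap) round-trippably."""
    recs = [
        SeqRecord(Seq(s), id=sid, description="")
        for sid, s in zip(aln.sample_ids, aln.sequences)
    ]
    SeqIO.write(recs, str(fasta_path), "fasta")
    if popmap_path is not None:
        with open(popmap_path, "w") as fh:
            for sid, pop in zip(aln.sample_ids, aln.populations):
                grp = (groups or {}).get(pop)
                if grp is not None:
                    fh.write(f"{sid}\t{pop}\t{grp}\n")
                else:
                    fh.write(f"{sid}\t{pop}\n")


def read_annotation(path) -> CodingAnnotation:
    """Read a BED-like TSV (``label<TAB>start<TAB>end``, 0-based half-open)
    with an optional ``#frame_offset=K`` header line."""
    intervals, labels, frame = [], [], 0
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                if line.startswith("#frame_offset="):
                    frame = int(line.split("=", 1)[1])
                continue
            lab, a, b = line.split("\t")[:3]
            intervals.append((int(a), int(b)))
            labels.append(lab)
    return CodingAnnotation(tuple(intervals), frame_offset=frame, labels=tuple(labels))


def write_annotation(ann: CodingAnnotation, path) -> None:
    with open(path, "w") as fh:
        if ann.frame_offset:
            fh.write(f"#frame_offset={ann.frame_offset}\n")
        for i, (a, b) in enumerate(ann.intervals):
            lab = ann.labels[i] if ann.labels is not None else str(i)
            fh.write(f"{lab}\t{a}\t{b}\n")


# -- derived views ---------------------------------------------------------

def extract_coding(aln: PopAlignment) -> PopAlignment:
    """Concatenate the coding columns into a frame-correct new alignment."""
    if aln.annotation is None:
        raise AnnotationError("no coding annotation on alignment")
    cols = aln.annotation.coding_columns()
    if len(cols) % 3 != 0:
        raise AnnotationError("coding length not divisible by 3")
    new_ann = CodingAnnotation(((0, len(cols)),), frame_offset=0)
    return aln.take_columns(cols, locus_name=f"{aln.locus_name}:coding",
                            annotation=new_ann)


def extract_noncoding(aln: PopAlignment) -> PopAlignment:
    """Complementary view: all columns not inside a coding interval."""
    if aln.annotation is None:
        raise AnnotationError("no coding annotation on alignment")
    coding = set()
    for a, b in aln.annotation.intervals:
        coding.update(range(a, b))
    cols = np.array([c for c in range(aln.length) if c not in coding], dtype=int)
    return aln.take_columns(cols, locus_name=f"{aln.locus_name}:noncoding")


def collapse_haplotypes(aln: PopAlignment, max_excluded_fraction: float = 0.10) -> HaplotypeTable:
    """Collapse sequences to distinct haplotypes over complete-case columns.

    Haplotype identity is decided on the complete-case columns only, so the
    haplotype count is consistent with the listwise polymorphism statistics.
    If more than ``max_excluded_fraction`` of columns are excluded (typical
    for unphased, directly sequenced loci carrying IUPAC heterozygote codes)
    the table is flagged unavailable.
    """
    cc = aln.complete_case_columns()
    excluded = 1.0 - cc.sum() / aln.length
    cols = np.flatnonzero(cc)
    keys = ["".join(s[c] for c in cols) for s in aln.sequences]
    pops = aln.population_ids
    pop_index = {p: i for i, p in enumerate(pops)}
    order = list(dict.fromkeys(keys))
    counts = np.zeros((len(order), len(pops)), dtype=int)
    hap_index = {h: i for i, h in enumerate(order)}
    for key, pop in zip(keys, aln.populations):
        counts[hap_index[key], pop_index[pop]] += 1
    return HaplotypeTable(order, pops, counts,
                          available=excluded <= max_excluded_fraction)


def pop_sample_sizes(aln: PopAlignment) -> "collections.OrderedDict":
    sizes = collections.OrderedDict()
    for p in aln.populations:
        sizes[p] = sizes.get(p, 0) + 1
    return sizes
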