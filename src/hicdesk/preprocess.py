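"""Pair separately aligned read-ends, filter ligation artefacts, count interactions.

Hi-C read-ends are aligned independently (single-end) to the reference;
this module joins the two alignment files by read name, keeps only pairs
where both ends align uniquely, optionally removes short inward/outward
pairs (uncut DNA and self-ligation artefacts), and aggregates the
surviving pairs into a symmetric fragment x fragment contact matrix.

The "position" of an end, used both for the artefact-filter span and for
fragment assignment, is the 5'-most aligned base: the leftmost mapped
base on the + strand, the rightmost on the - strand.  This is the
ligation-informative coordinate.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pysam
import scipy.sparse as sp

from .genome_model import FragmentSet, HicdeskError

_MATE_SUFFIX = re.compile(r"(/[12]|\s.*)$")


def _canonical_name(name: str) -> str:
    """Strip trailing /1, /2 or a whitespace-delimited mate tag from a read name."""
    return _MATE_SUFFIX.sub("", name)


@dataclass(frozen=True)
class AlignedEnd:
    name: str
    chrom: str
    position: int  # 5'-most aligned base, 0-based
    strand: str  # '+' or '-'
    unique: bool = True


@dataclass(frozen=True)
class ReadPair:
    """Two unique-mapping ends of one read, order-normalized.

    ``end1`` is the end with the lower (chromosome-order, position) key so
    that swapping the input files yields identical pairs.
    """

    end1: AlignedEnd
    end2: AlignedEnd

    @staticmethod
    def make(a: AlignedEnd, b: AlignedEnd, chrom_order: dict[str, int]) -> "ReadPair":
        ka = (chrom_order.get(a.chrom, len(chrom_order)), a.position)
        kb = (chrom_order.get(b.chrom, len(chrom_order)), b.position)
        return ReadPair(a, b) if ka <= kb else ReadPair(b, a)


@dataclass
class PairingStats:
    ends_seen_forward: int = 0
    ends_seen_reverse: int = 0
    non_unique_discarded: int = 0
    pairs: int = 0
    orphans: int = 0
    inward_removed: int = 0
    outward_removed: int = 0
    unknown_chrom_skipped: int = 0

    def __add__(self, other: "PairingStats") -> "PairingStats":
        return PairingStats(*(getattr(self, f) + getattr(other, f)
                              for f in self.__dataclass_fields__))


def _read_unique_ends(
    path: str, mapq_min: int
) -> tuple[dict[str, AlignedEnd], int, int, list[tuple[str, int]]]:
    """One best end per canonical read name; names seen more than once or
    below the MAPQ threshold are recorded as non-unique (value None)."""
    ends: dict[str, Optional[AlignedEnd]] = {}
    seen = 0
    nonunique = 0
    with pysam.AlignmentFile(path, check_sq=False) as fh:
        refs = list(zip(fh.references, fh.lengths))
        for aln in fh:
            if aln.is_unmapped or aln.is_secondary or aln.is_supplementary:
                continue
            seen += 1
            name = _canonical_name(aln.query_name)
            if aln.mapping_quality < mapq_min or name in ends:
                # multiple primary records under one name cannot be unique
                if name in ends and ends[name] is not None:
                    nonunique += 1
                ends[name] = None
                nonunique += 1
                continue
            strand = "-" if aln.is_reverse else "+"
            pos = aln.reference_end - 1 if aln.is_reverse else aln.reference_start
            ends[name] = AlignedEnd(name, aln.reference_name, pos, strand)
    unique = {k: v for k, v in ends.items() if v is not None}
    return unique, seen, nonunique, refs


def pair_alignments(
    forward_path: str,
    reverse_path: str,
    mapq_min: int = 1,
) -> tuple[list[ReadPair], PairingStats]:
    """Join two single-end alignment files (SAM/BAM) by read name.

    Only ends that align uniquely in both files (primary, MAPQ >=
    ``mapq_min``, one record per name) are paired; everything else is
    counted as orphan or non-unique.  The two files must carry identical
    sequence dictionaries.
    """
    fwd, seen_f, nonuniq_f, refs_f = _read_unique_ends(forward_path, mapq_min)
    rev, seen_r, nonuniq_r, refs_r = _read_unique_ends(reverse_path, mapq_min)
    if refs_f and refs_r and refs_f != refs_r:
        raise HicdeskError(
            "forward and reverse alignment files have different genome headers"
        )
    chrom_order = {name: i for i, (name, _len) in enumerate(refs_f or refs_r)}

    common = fwd.keys() & rev.keys()
    pairs = [ReadPair.make(fwd[n], rev[n], chrom_order) for n in sorted(common)]
    stats = PairingStats(
        ends_seen_forward=seen_f,
        ends_seen_reverse=seen_r,
        non_unique_discarded=nonuniq_f + nonuniq_r,
        pairs=len(pairs),
        orphans=(len(fwd) - len(common)) + (len(rev) - len(common)),
    )
    return pairs, stats


def classify_pair(pair: ReadPair) -> str:
    """'inward', 'outward', 'same_strand' or 'inter' for one pair.

    Inward: same chromosome, ends on opposite strands pointing toward each
    other (upstream end on +).  Outward: pointing away (upstream end on -).
    """
    a, b = pair.end1, pair.end2
    if a.chrom != b.chrom:
        return "inter"
    if a.strand == b.strand:
        return "same_strand"
    up, down = (a, b) if a.position <= b.position else (b, a)
    return "inward" if up.strand == "+" else "outward"


def filter_close_pairs(
    pairs: Sequence[ReadPair],
    inward_threshold: int = 1000,
    outward_threshold: int = 25000,
) -> tuple[list[ReadPair], PairingStats]:
    """Remove short inward pairs (uncut DNA) and short outward pairs (self-ligation).

    The span is the distance between the two 5' positions; inward pairs
    with span below ``inward_threshold`` and outward pairs with span below
    ``outward_threshold`` are dropped.  Inter-chromosomal and same-strand
    pairs always pass.
    """
    if inward_threshold < 0 or outward_threshold < 0:
        raise HicdeskError("filter thresholds must be non-negative")
    kept: list[ReadPair] = []
    stats = PairingStats()
    for p in pairs:
        kind = classify_pair(p)
        span = abs(p.end2.position - p.end1.position)
        if kind == "inward" and span < inward_threshold:
            stats.inward_removed += 1
        elif kind == "outward" and span < outward_threshold:
            stats.outward_removed += 1
        else:
            kept.append(p)
    stats.pairs = len(kept)
    return kept, stats


class InteractionMatrix:
    """Symmetric fragment x fragment contact counts, upper-triangle sparse.

    Counts are stored as triplets with i <= j; dense symmetric views are
    materialized per chromosome or genome-wide on demand.
    """

    def __init__(self, fragments: FragmentSet, counts: sp.spmatrix):
        n = len(fragments)
        counts = sp.csr_matrix(counts, shape=(n, n))
        lower = sp.tril(counts, k=-1)
        if lower.nnz:
            # fold any lower-triangle input into the upper triangle
            counts = sp.triu(counts) + lower.T
        self.fragments = fragments
        self.counts = sp.csr_matrix(counts)

    @classmethod
    def empty(cls, fragments: FragmentSet) -> "InteractionMatrix":
        n = len(fragments)
        return cls(fragments, sp.csr_matrix((n, n)))

    @classmethod
    def from_triplets(
        cls, fragments: FragmentSet, i: np.ndarray, j: np.ndarray,
        values: np.ndarray,
    ) -> "InteractionMatrix":
        i, j = np.minimum(i, j), np.maximum(i, j)
        n = len(fragments)
        m = sp.coo_matrix((values, (i, j)), shape=(n, n))
        return cls(fragments, m.tocsr())

    @property
    def total(self) -> float:
        return float(self.counts.sum())

    def dense(self, chrom: Optional[str] = None) -> np.ndarray:
        """Dense symmetric counts, genome-wide or for one chromosome block."""
        if chrom is None:
            u = self.counts.toarray().astype(float)
        else:
            lo, hi = self.fragments.chrom_slice(chrom)
            u = self.counts[lo:hi, lo:hi].toarray().astype(float)
        return u + u.T - np.diag(np.diag(u))

    def coverage(self) -> np.ndarray:
        """Per-fragment total contact count (symmetric row sums)."""
        u = self.counts
        cov = np.asarray(u.sum(axis=0)).ravel() + np.asarray(u.sum(axis=1)).ravel()
        cov -= u.diagonal()
        return cov

    def scaled(self, factor: float) -> "InteractionMatrix":
        return InteractionMatrix(self.fragments, self.counts * factor)

    def to_tsv(self, path: str, header: str = "") -> None:
        coo = sp.triu(self.counts).tocoo()
        order = np.lexsort((coo.col, coo.row))
        with open(path, "w") as fh:
            if header:
                for line in header.rstrip("\n").split("\n"):
                    fh.write(f"# {line}\n")
            fh.write("fragmentID1\tfragmentID2\tcount\n")
            for i, j, v in zip(coo.row[order], coo.col[order], coo.data[order]):
                v = int(v) if float(v).is_integer() else v
                fh.write(f"{i}\t{j}\t{v}\n")

    @classmethod
    def from_tsv(cls, path: str, fragments: FragmentSet) -> "InteractionMatrix":
        import pandas as pd

        df = pd.read_csv(path, sep="\t", comment="#")
        return cls.from_triplets(
            fragments,
            df["fragmentID1"].to_numpy(),
            df["fragmentID2"].to_numpy(),
            df["count"].to_numpy(float),
        )


def count_interactions(
    pairs: Sequence[ReadPair],
    fragments: FragmentSet,
    stats: Optional[PairingStats] = None,
) -> InteractionMatrix:
    """Aggregate read pairs into per-fragment-pair interaction counts.

    Each pair's two 5' positions are located to fragments and the count of
    the unordered fragment pair is incremented.  Pairs touching a
    chromosome absent from the fragment set are skipped and counted in
    ``stats.unknown_chrom_skipped``.
    """
    known = set(fragments.genome.names)
    ii, jj = [], []
    skipped = 0
    for p in pairs:
        if p.end1.chrom not in known or p.end2.chrom not in known:
            skipped += 1
            continue
        a = fragments.locate(p.end1.chrom, p.end1.position)
        b = fragments.locate(p.end2.chrom, p.end2.position)
        ii.append(min(a, b))
        jj.append(max(a, b))
    if stats is not None:
        stats.unknown_chrom_skipped += skipped
    if not ii:
        return InteractionMatrix.empty(fragments)
    return InteractionMatrix.from_triplets(
        fragments, np.array(ii), np.array(jj), np.ones(len(ii))
    )
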