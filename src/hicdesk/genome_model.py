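"""Genome representation and the fragment coordinate system.

Everything downstream (interaction counting, tracks, normalization,
compartment calling) is keyed to a :class:`FragmentSet`: an ordered,
gap-free tiling of the genome into either restriction fragments (from an
in-silico digest) or fixed-size bins.  Fragment IDs are consecutive
integers ordered by (chromosome order, start); chromosome order is fixed
by the :class:`GenomeIndex` and reused for every matrix axis.

Coordinates are 0-based half-open internally.  File readers/writers
convert at the boundary (GFF and the exported fragment table are 1-based
inclusive).
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
from Bio import SeqIO


class HicdeskError(ValueError):
    """Base class for user-facing errors raised by hicdesk."""


@dataclass(frozen=True)
class RestrictionEnzyme:
    """A restriction enzyme as a plain DNA motif plus a cut offset.

    The digest cuts at ``occurrence_start + cut_offset`` for every exact,
    case-insensitive occurrence of ``site`` on the forward strand.  The
    usual Hi-C enzymes have palindromic sites, which makes forward-strand
    scanning sufficient; non-palindromic motifs are accepted but scanned
    on the forward strand only.
    """

    name: str
    site: str
    cut_offset: int

    def __post_init__(self) -> None:
        site = self.site.upper()
        object.__setattr__(self, "site", site)
        if len(site) < 4:
            raise HicdeskError(f"enzyme {self.name}: motif shorter than 4 bp")
        if set(site) - set("ACGT"):
            raise HicdeskError(
                f"enzyme {self.name}: motif {site!r} contains non-ACGT symbols"
            )
        if not 0 <= self.cut_offset <= len(site):
            raise HicdeskError(
                f"enzyme {self.name}: cut offset {self.cut_offset} outside motif"
            )


#: Enzymes shipped with the package; others can be given as NAME:SITE:OFFSET.
BUILTIN_ENZYMES: dict[str, RestrictionEnzyme] = {
    "HindIII": RestrictionEnzyme("HindIII", "AAGCTT", 1),
    "DpnII": RestrictionEnzyme("DpnII", "GATC", 0),
}


def parse_enzyme(spec: str) -> RestrictionEnzyme:
    """Resolve an enzyme from its builtin name or a ``NAME:SITE:OFFSET`` spec."""
    if spec in BUILTIN_ENZYMES:
        return BUILTIN_ENZYMES[spec]
    parts = spec.split(":")
    if len(parts) != 3:
        raise HicdeskError(
            f"unknown enzyme {spec!r}; use a builtin name "
            f"({', '.join(BUILTIN_ENZYMES)}) or NAME:SITE:OFFSET"
        )
    return RestrictionEnzyme(parts[0], parts[1], int(parts[2]))


class GenomeIndex:
    """Ordered chromosome names and lengths; the coordinate frame for everything."""

    def __init__(self, names: Sequence[str], lengths: Sequence[int]):
        names = list(names)
        lengths = [int(x) for x in lengths]
        if len(names) != len(lengths):
            raise HicdeskError("names and lengths differ in length")
        if len(set(names)) != len(names):
            raise HicdeskError("duplicate chromosome names")
        if not names:
            raise HicdeskError("empty genome")
        if any(n < 1 for n in lengths):
            raise HicdeskError("chromosome lengths must be >= 1")
        self.names: tuple[str, ...] = tuple(names)
        self.lengths: dict[str, int] = dict(zip(names, lengths))

    def __len__(self) -> int:
        return len(self.names)

    def __eq__(self, other: object) -> bool:
        return (
            isinstance(other, GenomeIndex)
            and self.names == other.names
            and self.lengths == other.lengths
        )

    def __repr__(self) -> str:
        return f"GenomeIndex({len(self.names)} chromosomes, {sum(self.lengths.values())} bp)"


@dataclass(frozen=True)
class Fragment:
    id: int
    chrom: str
    start: int
    end: int

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> float:
        return (self.start + self.end) / 2


class FragmentSet:
    """Ordered, gap-free tiling of a genome into fragments or bins.

    Parameters
    ----------
    genome:
        The genome the fragments tile.
    starts, ends:
        Per-fragment coordinates (0-based half-open), ordered by
        (chromosome order, start).
    chrom_codes:
        Integer index into ``genome.names`` per fragment.
    mode:
        ``"restriction"`` or ``"binned"``.
    provenance:
        Bin size or enzyme list, recorded for output headers.
    """

    def __init__(
        self,
        genome: GenomeIndex,
        chrom_codes: np.ndarray,
        starts: np.ndarray,
        ends: np.ndarray,
        mode: str,
        provenance: str = "",
    ):
        self.genome = genome
        self.chrom_codes = np.asarray(chrom_codes, dtype=np.int64)
        self.starts = np.asarray(starts, dtype=np.int64)
        self.ends = np.asarray(ends, dtype=np.int64)
        if mode not in ("restriction", "binned"):
            raise HicdeskError(f"unknown fragment mode {mode!r}")
        self.mode = mode
        self.provenance = provenance
        self._validate()
        # per-chromosome [lo, hi) slice into the fragment arrays
        self._chrom_slices: dict[str, tuple[int, int]] = {}
        for ci, name in enumerate(genome.names):
            idx = np.flatnonzero(self.chrom_codes == ci)
            if idx.size:
                self._chrom_slices[name] = (int(idx[0]), int(idx[-1]) + 1)

    def _validate(self) -> None:
        if np.any(self.starts >= self.ends):
            raise HicdeskError("fragment with start >= end")
        prev_code = -1
        for ci in range(len(self.genome)):
            name = self.genome.names[ci]
            sel = self.chrom_codes == ci
            if not sel.any():
                raise HicdeskError(f"chromosome {name} has no fragments")
            idx = np.flatnonzero(sel)
            if not np.array_equal(idx, np.arange(idx[0], idx[-1] + 1)):
                raise HicdeskError("fragments of one chromosome are not contiguous")
            if idx[0] <= prev_code:
                raise HicdeskError("fragments not ordered by chromosome order")
            prev_code = idx[-1]
            s, e = self.starts[sel], self.ends[sel]
            if s[0] != 0 or e[-1] != self.genome.lengths[name]:
                raise HicdeskError(f"fragments do not span chromosome {name}")
            if np.any(s[1:] != e[:-1]):
                raise HicdeskError(f"fragments do not tile chromosome {name}")

    def __len__(self) -> int:
        return len(self.starts)

    def __getitem__(self, i: int) -> Fragment:
        return Fragment(
            int(i),
            self.genome.names[self.chrom_codes[i]],
            int(self.starts[i]),
            int(self.ends[i]),
        )

    def __iter__(self) -> Iterator[Fragment]:
        for i in range(len(self)):
            yield self[i]

    @property
    def lengths(self) -> np.ndarray:
        return self.ends - self.starts

    @property
    def midpoints(self) -> np.ndarray:
        return (self.starts + self.ends) / 2.0

    def chrom_slice(self, chrom: str) -> tuple[int, int]:
        """[lo, hi) fragment-id range of one chromosome."""
        try:
            return self._chrom_slices[chrom]
        except KeyError:
            raise HicdeskError(f"unknown chromosome {chrom!r}") from None

    def locate(self, chrom: str, position: int) -> int:
        """Fragment id containing ``position`` (0-based) on ``chrom``; O(log n)."""
        lo, hi = self.chrom_slice(chrom)
        if not 0 <= position < self.genome.lengths[chrom]:
            raise HicdeskError(
                f"position {position} outside {chrom} "
                f"[0, {self.genome.lengths[chrom]})"
            )
        i = int(np.searchsorted(self.starts[lo:hi], position, side="right")) - 1
        return lo + i

    def locate_many(self, chroms: Sequence[str], positions: np.ndarray) -> np.ndarray:
        """Vectorized :meth:`locate` for equal-length chrom/position arrays."""
        out = np.empty(len(positions), dtype=np.int64)
        for i, (c, p) in enumerate(zip(chroms, positions)):
            out[i] = self.locate(c, int(p))
        return out

    def assign_to(self, coarse: "FragmentSet") -> np.ndarray:
        """Map each fragment to the coarse fragment containing its midpoint."""
        if self.genome != coarse.genome:
            raise HicdeskError("fragment sets are on different genomes")
        out = np.empty(len(self), dtype=np.int64)
        for i in range(len(self)):
            c = self.genome.names[self.chrom_codes[i]]
            mid = int(self.midpoints[i])
            out[i] = coarse.locate(c, min(mid, self.genome.lengths[c] - 1))
        return out


def _as_records(genome: "str | os.PathLike | Mapping[str, str] | Iterable") -> list[tuple[str, str]]:
    """Normalize FASTA input (path, mapping, or SeqRecord iterable) to (name, seq)."""
    if isinstance(genome, (str, os.PathLike)):
        return [(r.id, str(r.seq)) for r in SeqIO.parse(str(genome), "fasta")]
    if isinstance(genome, Mapping):
        return [(k, str(v)) for k, v in genome.items()]
    out = []
    for r in genome:
        if isinstance(r, tuple):
            out.append((r[0], str(r[1])))
        else:  # SeqRecord
            out.append((r.id, str(r.seq)))
    return out


def _find_occurrences(seq: str, motif: str) -> list[int]:
    """All (overlapping) start positions of motif in seq, case-insensitive."""
    hits = []
    i = seq.find(motif)
    while i != -1:
        hits.append(i)
        i = seq.find(motif, i + 1)
    return hits


def digest_genome(
    genome: "str | os.PathLike | Mapping[str, str] | Iterable",
    enzymes: Sequence[RestrictionEnzyme],
) -> FragmentSet:
    """In-silico digest: fragments between the union of enzyme cut positions.

    Cut positions are ``occurrence_start + cut_offset`` for every exact
    occurrence of an enzyme motif on the forward strand (case-insensitive;
    ambiguity codes such as N never match).  Cuts falling on a chromosome
    end are collapsed into the end.
    """
    records = _as_records(genome)
    if not records:
        raise HicdeskError("empty genome: no FASTA records")
    for enz in enzymes:
        if set(enz.site) - set("ACGT"):
            raise HicdeskError(f"enzyme {enz.name}: non-ACGT motif")
    if not enzymes:
        raise HicdeskError("no enzymes given")

    names = [name for name, _ in records]
    lengths = [len(seq) for _, seq in records]
    if any(l == 0 for l in lengths):
        raise HicdeskError("empty chromosome sequence")
    gi = GenomeIndex(names, lengths)

    codes, starts, ends = [], [], []
    for ci, (name, seq) in enumerate(records):
        seq = seq.upper()
        cuts: set[int] = set()
        for enz in enzymes:
            for occ in _find_occurrences(seq, enz.site):
                cuts.add(occ + enz.cut_offset)
        bounds = sorted({0, len(seq)} | {c for c in cuts if 0 < c < len(seq)})
        for s, e in zip(bounds[:-1], bounds[1:]):
            codes.append(ci)
            starts.append(s)
            ends.append(e)
    prov = "+".join(f"{e.name}({e.site}/{e.cut_offset})" for e in enzymes)
    return FragmentSet(gi, np.array(codes), np.array(starts), np.array(ends),
                       "restriction", prov)


def bin_genome(genome: GenomeIndex, bin_size: int) -> FragmentSet:
    """Tile each chromosome into ``[0,b), [b,2b), ...`` with a truncated last bin."""
    if bin_size <= 0:
        raise HicdeskError(f"bin size must be positive, got {bin_size}")
    codes, starts, ends = [], [], []
    for ci, name in enumerate(genome.names):
        L = genome.lengths[name]
        edges = list(range(0, L, bin_size)) + [L]
        for s, e in zip(edges[:-1], edges[1:]):
            codes.append(ci)
            starts.append(s)
            ends.append(e)
    return FragmentSet(genome, np.array(codes), np.array(starts), np.array(ends),
                       "binned", f"bin={bin_size}")


def genome_index_from_fasta(path: "str | os.PathLike") -> GenomeIndex:
    records = _as_records(path)
    return GenomeIndex([n for n, _ in records], [len(s) for _, s in records])
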