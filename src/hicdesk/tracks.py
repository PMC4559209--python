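"""Per-fragment genomic and epigenomic tracks.

Four track kinds with distinct counting semantics:

- ``annotation_count``: long features (genes, transposons) from GFF/GTF.
  A feature spanning a whole fragment adds 1 to it; a feature that only
  partly overlaps a fragment (or lies strictly inside it) adds 0.5.
- ``short_count``: short reads (RNA-seq, smallRNA-seq); each read counts
  once, in the fragment containing its 5' base.
- ``density``: percentage of fragment bases covered by at least one
  element (union coverage, not depth), e.g. ChIP-seq.
- ``methylation_density``: percentage of methylated cytosines per
  fragment, pooled as 100 * sum(methylated) / sum(total); fragments with
  no covered cytosine carry a missing value (NaN), not 0.

When aggregating to a coarser fragment set, counts are summed and
densities are length-weighted averages.  Count tracks are log2(x+1)
transformed at analysis time only, never at storage time.  Strand is
ignored throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
import pysam

from .genome_model import FragmentSet, HicdeskError

COUNT_KINDS = ("annotation_count", "short_count")
DENSITY_KINDS = ("density", "methylation_density")
TRACK_KINDS = COUNT_KINDS + DENSITY_KINDS


@dataclass
class Track:
    name: str
    kind: str
    values: np.ndarray

    def __post_init__(self) -> None:
        if self.kind not in TRACK_KINDS:
            raise HicdeskError(f"unknown track kind {self.kind!r}")
        self.values = np.asarray(self.values, dtype=float)
        finite = self.values[np.isfinite(self.values)]
        if self.kind in COUNT_KINDS and np.any(finite < 0):
            raise HicdeskError(f"track {self.name}: negative counts")
        if self.kind in DENSITY_KINDS and (
            np.any(finite < 0) or np.any(finite > 100)
        ):
            raise HicdeskError(f"track {self.name}: densities outside [0, 100]")

    @property
    def is_count(self) -> bool:
        return self.kind in COUNT_KINDS

    def analysis_values(self) -> np.ndarray:
        """Values on the analysis scale: log2(x+1) for counts, raw for densities."""
        return np.log2(self.values + 1.0) if self.is_count else self.values


@dataclass(frozen=True)
class FeatureInterval:
    chrom: str
    start: int  # 0-based half-open
    end: int
    feature_type: str = ""

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise HicdeskError(
                f"feature {self.chrom}:{self.start}-{self.end} has start >= end"
            )


@dataclass(frozen=True)
class MethylationCall:
    chrom: str
    position: int
    methylated: int
    total: int

    def __post_init__(self) -> None:
        if self.methylated > self.total:
            raise HicdeskError(
                f"methylation call at {self.chrom}:{self.position}: "
                f"methylated ({self.methylated}) > total ({self.total})"
            )


def annotate_features(
    fragments: FragmentSet,
    features: Iterable[FeatureInterval],
    feature_type: str = "",
) -> Track:
    """1/0.5 annotation counting: +1 per feature covering a whole fragment,
    +0.5 per feature overlapping it only partly (or lying inside it)."""
    values = np.zeros(len(fragments))
    skipped = 0
    for feat in features:
        try:
            lo, hi = fragments.chrom_slice(feat.chrom)
        except HicdeskError:
            skipped += 1
            continue
        starts = fragments.starts[lo:hi]
        ends = fragments.ends[lo:hi]
        first = int(np.searchsorted(ends, feat.start, side="right"))
        last = int(np.searchsorted(starts, feat.end, side="left"))
        for k in range(first, last):
            full = feat.start <= starts[k] and feat.end >= ends[k]
            values[lo + k] += 1.0 if full else 0.5
    track = Track(feature_type or "annotation", "annotation_count", values)
    track.skipped_features = skipped  # type: ignore[attr-defined]
    return track


def _iter_read_intervals(path: str):
    """(chrom, start, end, five_prime) per mapped primary alignment."""
    with pysam.AlignmentFile(path, check_sq=False) as fh:
        for aln in fh:
            if aln.is_unmapped or aln.is_secondary or aln.is_supplementary:
                continue
            five = aln.reference_end - 1 if aln.is_reverse else aln.reference_start
            yield aln.reference_name, aln.reference_start, aln.reference_end, five


def count_short_features(
    fragments: FragmentSet, alignments: "str | Iterable[tuple]", name: str = "reads"
) -> Track:
    """One count per read, assigned to the fragment containing its 5' base."""
    values = np.zeros(len(fragments))
    it = _iter_read_intervals(alignments) if isinstance(alignments, str) else alignments
    known = set(fragments.genome.names)
    for chrom, _s, _e, five in it:
        if chrom not in known:
            continue
        values[fragments.locate(chrom, five)] += 1
    return Track(name, "short_count", values)


def compute_density(
    fragments: FragmentSet,
    elements: "str | Iterable[tuple]",
    name: str = "density",
) -> Track:
    """Percent of fragment bases covered by the union of the elements."""
    if isinstance(elements, str):
        elements = ((c, s, e) for c, s, e, _f in _iter_read_intervals(elements))
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for item in elements:
        chrom, start, end = item[0], item[1], item[2]
        by_chrom.setdefault(chrom, []).append((start, end))

    values = np.zeros(len(fragments))
    for chrom, ivals in by_chrom.items():
        try:
            lo, hi = fragments.chrom_slice(chrom)
        except HicdeskError:
            continue
        # merge to disjoint intervals, then intersect with each fragment
        ivals.sort()
        merged: list[list[int]] = []
        for s, e in ivals:
            if merged and s <= merged[-1][1]:
                merged[-1][1] = max(merged[-1][1], e)
            else:
                merged.append([s, e])
        ms = np.array([m[0] for m in merged])
        me = np.array([m[1] for m in merged])
        for k in range(lo, hi):
            fs, fe = fragments.starts[k], fragments.ends[k]
            overlap = np.minimum(me, fe) - np.maximum(ms, fs)
            covered = int(overlap[overlap > 0].sum())
            values[k] = 100.0 * covered / (fe - fs)
    return Track(name, "density", values)


def methylation_density(
    fragments: FragmentSet,
    calls: Iterable[MethylationCall],
    name: str = "methylation",
) -> Track:
    """Pooled methylation percentage per fragment: 100 * sum(m) / sum(t)."""
    meth = np.zeros(len(fragments))
    tot = np.zeros(len(fragments))
    known = set(fragments.genome.names)
    for call in calls:
        if call.methylated > call.total:
            raise HicdeskError("methylated count exceeds total")
        if call.chrom not in known:
            continue
        idx = fragments.locate(call.chrom, call.position)
        meth[idx] += call.methylated
        tot[idx] += call.total
    with np.errstate(invalid="ignore", divide="ignore"):
        values = np.where(tot > 0, 100.0 * meth / np.where(tot > 0, tot, 1), np.nan)
    return Track(name, "methylation_density", values)


def aggregate_track(
    track: Track, fine: FragmentSet, coarse: FragmentSet
) -> Track:
    """Re-key a track from a fine to a coarse fragment set.

    Each fine fragment belongs to the coarse fragment containing its
    midpoint.  Counts are summed; densities are length-weighted means over
    the non-missing members (all-missing bins stay missing).
    """
    if fine.genome != coarse.genome:
        raise HicdeskError("fine and coarse fragment sets are on different genomes")
    if len(track.values) != len(fine):
        raise HicdeskError("track length does not match fine fragment set")
    assign = fine.assign_to(coarse)
    if track.is_count:
        out = np.zeros(len(coarse))
        np.add.at(out, assign, np.nan_to_num(track.values))
    else:
        num = np.zeros(len(coarse))
        den = np.zeros(len(coarse))
        w = fine.lengths.astype(float)
        ok = np.isfinite(track.values)
        np.add.at(num, assign[ok], (w * np.nan_to_num(track.values))[ok])
        np.add.at(den, assign[ok], w[ok])
        with np.errstate(invalid="ignore", divide="ignore"):
            out = np.where(den > 0, num / np.where(den > 0, den, 1), np.nan)
    return Track(track.name, track.kind, out)


# ---------------------------------------------------------------------------
# file readers / writers

def read_gff_features(path: str) -> dict[str, list[FeatureInterval]]:
    """GFF3/GTF -> features grouped by feature type (column 3).

    Coordinates are converted from 1-based inclusive to 0-based half-open.
    """
    import pyranges as pr

    reader = pr.read_gtf if path.endswith((".gtf", ".gtf.gz")) else pr.read_gff3
    df = reader(path).df
    out: dict[str, list[FeatureInterval]] = {}
    for row in df.itertuples(index=False):
        ft = str(row.Feature)
        out.setdefault(ft, []).append(
            FeatureInterval(str(row.Chromosome), int(row.Start), int(row.End), ft)
        )
    return out


def read_methylation_tsv(path: str) -> list[MethylationCall]:
    """TSV with columns chrom, pos (1-based), methylated, total."""
    df = pd.read_csv(path, sep="\t", comment="#")
    cols = list(df.columns[:4])
    return [
        MethylationCall(str(r[cols[0]]), int(r[cols[1]]) - 1,
                        int(r[cols[2]]), int(r[cols[3]]))
        for _, r in df.iterrows()
    ]


def write_tracks_tsv(path: str, fragments: FragmentSet, tracks: Sequence[Track],
                     header: str = "") -> None:
    """Fragment annotation table: one row per fragment, one column per track.

    A ``# kinds:`` header line records each track's kind so the analysis
    modules can pick the right transformation/aggregation semantics.
    Coordinates are written 1-based inclusive.
    """
    with open(path, "w") as fh:
        if header:
            for line in header.rstrip("\n").split("\n"):
                fh.write(f"# {line}\n")
        fh.write("# kinds: " + ",".join(f"{t.name}={t.kind}" for t in tracks) + "\n")
        names = "\t".join(t.name for t in tracks)
        fh.write(f"fragmentID\tchromosome\tstart\tend\t{names}\n")
        for i in range(len(fragments)):
            f = fragments[i]
            vals = "\t".join(
                "NA" if not np.isfinite(t.values[i]) else f"{t.values[i]:g}"
                for t in tracks
            )
            fh.write(f"{f.id}\t{f.chrom}\t{f.start + 1}\t{f.end}\t{vals}\n")


def read_tracks_tsv(path: str) -> list[Track]:
    kinds: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            if line.startswith("# kinds:"):
                for part in line.split(":", 1)[1].strip().split(","):
                    k, v = part.split("=")
                    kinds[k] = v
            if not line.startswith("#"):
                break
    df = pd.read_csv(path, sep="\t", comment="#", na_values=["NA"])
    tracks = []
    for col in df.columns[4:]:
        tracks.append(Track(col, kinds.get(col, "short_count"),
                            df[col].to_numpy(float)))
    return tracks
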