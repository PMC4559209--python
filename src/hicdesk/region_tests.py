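"""Balanced-resampling tests on genomic regions of interest.

Because interaction frequency and most genomic features depend strongly
on chromosomal position (arm vs pericentromere, chromosome identity),
the null distribution is built from *balanced* random region sets: each
random set contains, for every region of interest, one interval of the
same length on the same chromosome (and, optionally, within the same
region class such as a chromosome arm).  The empirical one-sided p-value
uses the (k+1)/(n+1) rule and therefore never reaches zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .genome_model import FragmentSet, GenomeIndex, HicdeskError
from .tracks import Track


class RegionSet:
    """Labelled genomic intervals (0-based half-open internally)."""

    def __init__(self, table: pd.DataFrame):
        required = {"chrom", "start", "end"}
        if not required <= set(table.columns):
            raise HicdeskError(f"region table needs columns {sorted(required)}")
        table = table.copy().reset_index(drop=True)
        if "label" not in table.columns:
            table["label"] = [f"region{i}" for i in range(len(table))]
        if (table["end"] - table["start"] <= 0).any():
            raise HicdeskError("region with non-positive length")
        self.table = table

    def __len__(self) -> int:
        return len(self.table)

    def __iter__(self):
        return self.table.itertuples(index=False)

    @classmethod
    def from_bed(cls, path: str) -> "RegionSet":
        df = pd.read_csv(path, sep="\t", comment="#", header=None)
        df = df.iloc[:, :4] if df.shape[1] >= 4 else df.iloc[:, :3]
        df.columns = ["chrom", "start", "end", "label"][: df.shape[1]]
        return cls(df)

    @classmethod
    def from_tsv(cls, path: str) -> "RegionSet":
        """Header-carrying 1-based inclusive table (chrom, start, end[, label])."""
        df = pd.read_csv(path, sep="\t", comment="#")
        df = df.rename(columns={c: c.lower() for c in df.columns})
        df["start"] = df["start"] - 1
        return cls(df)

    def validate_against(self, genome: GenomeIndex) -> None:
        for r in self:
            if r.chrom not in genome.lengths:
                raise HicdeskError(f"region on unknown chromosome {r.chrom!r}")
            if r.start < 0 or r.end > genome.lengths[r.chrom]:
                raise HicdeskError(
                    f"region {r.label} outside chromosome {r.chrom}")


@dataclass
class SamplingTestResult:
    observed: float
    null: np.ndarray
    p_value: float
    n_sets: int
    seed: int
    side: str
    balancing: str

    @property
    def null_mean(self) -> float:
        return float(np.mean(self.null))

    @property
    def null_sd(self) -> float:
        return float(np.std(self.null, ddof=1)) if len(self.null) > 1 else 0.0


def _placement_window(
    region, genome: GenomeIndex, class_table: Optional[RegionSet]
) -> tuple[int, int]:
    """Interval within which a random interval for this region must lie."""
    if class_table is None:
        return 0, genome.lengths[region.chrom]
    mid = (region.start + region.end) / 2
    for c in class_table:
        if c.chrom == region.chrom and c.start <= mid < c.end:
            return int(c.start), int(c.end)
    raise HicdeskError(
        f"region {region.label} falls in no class interval on {region.chrom}")


def sample_balanced_sets(
    regions: RegionSet,
    genome: GenomeIndex,
    n_sets: int,
    seed: int,
    class_table: Optional[RegionSet] = None,
) -> list[RegionSet]:
    """Draw ``n_sets`` random region sets balanced for number, length and location.

    For every region of interest, each random set holds one interval of
    identical length on the same chromosome, uniform over valid start
    positions — restricted to the region's class interval when a class
    table (e.g. arms vs pericentromeres) is supplied.  Random intervals
    may overlap each other and the observed regions.
    """
    if n_sets < 1:
        raise HicdeskError("n_sets must be >= 1")
    regions.validate_against(genome)
    rng = np.random.default_rng(seed)
    windows = []
    for r in regions:
        lo, hi = _placement_window(r, genome, class_table)
        length = int(r.end - r.start)
        if hi - lo < length:
            raise HicdeskError(
                f"region {r.label} (length {length}) does not fit its "
                f"placement window on {r.chrom}")
        windows.append((r.chrom, lo, hi, length, r.label))

    out = []
    for _ in range(n_sets):
        rows = []
        for chrom, lo, hi, length, label in windows:
            start = int(rng.integers(lo, hi - length + 1))
            rows.append({"chrom": chrom, "start": start,
                         "end": start + length, "label": label})
        out.append(RegionSet(pd.DataFrame(rows)))
    return out


def region_fragment_ids(
    regions: "RegionSet | pd.DataFrame", fragments: FragmentSet
) -> list[np.ndarray]:
    """Per region: ids of fragments whose midpoint lies inside the region."""
    if isinstance(regions, pd.DataFrame):
        regions = RegionSet(regions)
    mids = fragments.midpoints
    out = []
    for r in regions:
        try:
            lo, hi = fragments.chrom_slice(r.chrom)
        except HicdeskError:
            out.append(np.array([], dtype=int))
            continue
        sel = (mids[lo:hi] >= r.start) & (mids[lo:hi] < r.end)
        out.append(np.arange(lo, hi)[sel])
    return out


def _empirical_p(observed: float, null: np.ndarray, side: str) -> float:
    if side == "enrichment":
        k = int(np.sum(null >= observed))
    elif side == "depletion":
        k = int(np.sum(null <= observed))
    else:
        raise HicdeskError(f"unknown side {side!r}")
    return (k + 1) / (len(null) + 1)


def _between_region_mean(dense: np.ndarray, frag_ids: list[np.ndarray]) -> float:
    """Mean matrix entry over all between-region fragment pairs."""
    vals = []
    for a in range(len(frag_ids)):
        for b in range(a + 1, len(frag_ids)):
            if frag_ids[a].size and frag_ids[b].size:
                sub = dense[np.ix_(frag_ids[a], frag_ids[b])]
                vals.append(sub[np.isfinite(sub)].ravel())
    if not vals or not sum(v.size for v in vals):
        raise HicdeskError("no between-region fragment pairs")
    return float(np.concatenate(vals).mean())


def test_interaction_enrichment(
    matrix,
    regions: RegionSet,
    n_sets: int = 999,
    seed: int = 0,
    class_table: Optional[RegionSet] = None,
) -> SamplingTestResult:
    """One-sided empirical test for elevated interaction frequency between
    the regions of interest.

    The statistic is the mean (normalized) interaction frequency over all
    fragment pairs whose two members lie in two *different* regions of
    interest; within-region pairs are excluded.  The null recomputes the
    statistic on each balanced random set.
    """
    from .matrix_analysis import _as_dense

    dense, fragments, _ = _as_dense(matrix)
    regions.validate_against(fragments.genome)
    observed = _between_region_mean(dense, region_fragment_ids(regions, fragments))
    null = np.empty(n_sets)
    for i, rnd in enumerate(
        sample_balanced_sets(regions, fragments.genome, n_sets, seed, class_table)
    ):
        null[i] = _between_region_mean(dense, region_fragment_ids(rnd, fragments))
    p = _empirical_p(observed, null, "enrichment")
    return SamplingTestResult(observed, null, p, n_sets, seed, "enrichment",
                              "chromosome+class" if class_table is not None
                              else "chromosome")


def _region_track_stat(
    track: Track, fragments: FragmentSet, frag_ids: list[np.ndarray]
) -> float:
    """Sum for count tracks, length-weighted mean for density tracks."""
    ids = np.concatenate([f for f in frag_ids]) if frag_ids else np.array([], int)
    if ids.size == 0:
        raise HicdeskError("regions contain no fragments")
    v = track.values[ids]
    if track.is_count:
        return float(np.nansum(v))
    w = fragments.lengths[ids].astype(float)
    ok = np.isfinite(v)
    if not ok.any():
        return float("nan")
    return float(np.sum(v[ok] * w[ok]) / np.sum(w[ok]))


def test_feature_enrichment(
    track: Track,
    fragments: FragmentSet,
    regions: RegionSet,
    n_sets: int = 999,
    seed: int = 0,
    side: str = "enrichment",
    class_table: Optional[RegionSet] = None,
) -> SamplingTestResult:
    """One-sided empirical test for enrichment/depletion of a feature track
    within the regions of interest, against balanced random sets."""
    if len(track.values) != len(fragments):
        raise HicdeskError("track length does not match fragment set")
    regions.validate_against(fragments.genome)
    observed = _region_track_stat(track, fragments,
                                  region_fragment_ids(regions, fragments))
    null = np.empty(n_sets)
    for i, rnd in enumerate(
        sample_balanced_sets(regions, fragments.genome, n_sets, seed, class_table)
    ):
        null[i] = _region_track_stat(track, fragments,
                                     region_fragment_ids(rnd, fragments))
    p = _empirical_p(observed, null, side)
    return SamplingTestResult(observed, null, p, n_sets, seed, side,
                              "chromosome+class" if class_table is not None
                              else "chromosome")
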