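"""Distance-decay exponents and PCA-based compartment structure.

The interaction decay exponent (IDE) is the slope of an ordinary
least-squares fit of log10(mean contact frequency) on log10(genomic
distance): around -1 for a fractal-globule-like polymer, with deviations
characterizing sub-compartments or conditions.

Compartments are called per chromosome from the first principal
component (FPC) of the Pearson-correlated, distance-normalized
intra-chromosomal map; the FPC sign splits fragments into two structural
groups (A-like / B-like), whose association with genomic and epigenomic
tracks is quantified by correlation tests and by sign-group enrichment
ratios with a two-sided Wilcoxon rank-sum test.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .genome_model import FragmentSet, HicdeskError
from .matrix_analysis import NormalizedMatrix, _as_dense, expected_by_distance
from .tracks import Track


@dataclass
class IDEResult:
    slope: float
    intercept: float
    distances: np.ndarray  # bp, class representative
    means: np.ndarray  # mean interaction frequency per class
    r_squared: float
    fit_range: tuple[float, float]

    @property
    def ide(self) -> float:
        return self.slope


def compute_ide(
    matrix,
    regions: Optional["pd.DataFrame"] = None,
    fit_range: Optional[tuple[float, float]] = None,
    n_classes: int = 50,
) -> IDEResult:
    """IDE: OLS slope of log10 mean contact frequency vs log10 distance.

    For binned fragment sets the distance classes are exact multiples of
    the bin size (|i - j| * bin); for restriction fragments, midpoint
    distances are pooled into ``n_classes`` log-spaced classes.  The fit
    range defaults to [2 bins (or the smallest observed midpoint
    distance), half the longest chromosome].  ``regions`` (columns chrom,
    start, end) restricts both pair endpoints to fragments whose midpoint
    lies inside a region.
    """
    dense, fragments, mask = _as_dense(matrix)
    keep = ~mask
    if regions is not None:
        from .region_tests import region_fragment_ids

        in_region = np.zeros(len(fragments), bool)
        for ids in region_fragment_ids(regions, fragments):
            in_region[ids] = True
        keep = keep & in_region

    dists: list[np.ndarray] = []
    vals: list[np.ndarray] = []
    mids = fragments.midpoints
    for name in fragments.genome.names:
        lo, hi = fragments.chrom_slice(name)
        idx = np.arange(lo, hi)[keep[lo:hi]]
        if idx.size < 2:
            continue
        ii, jj = np.triu_indices(idx.size, k=1)
        gi, gj = idx[ii], idx[jj]
        v = dense[gi, gj]
        ok = np.isfinite(v)
        dists.append(np.abs(mids[gj] - mids[gi])[ok])
        vals.append(v[ok])
    if not dists:
        raise HicdeskError("no intra-chromosomal data for IDE")
    dist = np.concatenate(dists)
    val = np.concatenate(vals)

    binned = fragments.mode == "binned"
    bin_size = int(fragments.lengths.max()) if binned else None
    if fit_range is None:
        max_len = max(fragments.genome.lengths.values())
        low = 2 * bin_size if binned else float(dist[dist > 0].min())
        fit_range = (low, max_len / 2)

    sel = (dist >= fit_range[0]) & (dist <= fit_range[1]) & (dist > 0)
    dist, val = dist[sel], val[sel]
    if dist.size == 0:
        raise HicdeskError("no pairs inside the IDE fit range")

    if binned:
        classes = np.unique(dist)
        reps = classes
        means = np.array([val[dist == c].mean() for c in classes])
    else:
        edges = np.geomspace(dist.min(), dist.max() * (1 + 1e-12), n_classes + 1)
        which = np.clip(np.digitize(dist, edges) - 1, 0, n_classes - 1)
        reps, means = [], []
        for c in range(n_classes):
            m = which == c
            if m.any():
                reps.append(np.sqrt(edges[c] * edges[c + 1]))
                means.append(val[m].mean())
        reps = np.array(reps)
        means = np.array(means)

    pos = means > 0
    reps, means = reps[pos], means[pos]
    if reps.size < 3:
        raise HicdeskError(
            f"only {reps.size} usable distance classes in the fit range; need >= 3")
    fit = stats.linregress(np.log10(reps), np.log10(means))
    return IDEResult(float(fit.slope), float(fit.intercept), reps, means,
                     float(fit.rvalue ** 2), fit_range)


@dataclass
class CompartmentResult:
    fragments: FragmentSet
    fpc: np.ndarray  # NaN where masked
    labels: np.ndarray  # 'A', 'B', or 'masked'
    variance_explained: dict  # chrom -> fraction
    orientation: str  # 'track:<name>' | 'loading'
    flagged: list = field(default_factory=list)  # chromosomes with weak structure

    def sign_groups(self) -> tuple[np.ndarray, np.ndarray]:
        """(indices with FPC > 0, indices with FPC < 0); zero/masked excluded."""
        ok = np.isfinite(self.fpc)
        return np.flatnonzero(ok & (self.fpc > 0)), np.flatnonzero(ok & (self.fpc < 0))

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame({
            "fragmentID": np.arange(len(self.fragments)),
            "chromosome": [self.fragments.genome.names[c]
                           for c in self.fragments.chrom_codes],
            "start": self.fragments.starts + 1,
            "end": self.fragments.ends,
            "FPC": self.fpc,
            "label": self.labels,
        })


def compartment_fpc(
    matrix,
    orientation_track: Optional[Track] = None,
    min_fragments: int = 10,
    weak_threshold: float = 0.1,
) -> CompartmentResult:
    """Per-chromosome FPC of the correlated, distance-normalized intra map.

    Per chromosome: (1) divide each entry by the pooled mean at its
    diagonal offset (observed/expected), (2) Pearson-correlate the columns
    of the result, (3) take the first principal component of the
    correlation matrix.  Fragments are labelled by FPC sign.  The
    eigenvector sign is anchored to positive correlation with
    ``orientation_track`` when given, else the largest-|score| fragment is
    made positive.  Chromosomes with fewer than ``min_fragments`` unmasked
    fragments are fully masked; chromosomes whose FPC explains less than
    ``weak_threshold`` of the variance are flagged as unstable.
    """
    from sklearn.decomposition import PCA

    dense, fragments, mask = _as_dense(matrix)
    n = len(fragments)
    fpc = np.full(n, np.nan)
    varexp: dict[str, float] = {}
    flagged: list[str] = []

    for name in fragments.genome.names:
        lo, hi = fragments.chrom_slice(name)
        block = np.nan_to_num(dense[lo:hi, lo:hi])
        cov = block.sum(axis=1)
        keep = (~mask[lo:hi]) & (cov > 0)
        if keep.sum() < min_fragments:
            flagged.append(name)
            continue
        sub = block[np.ix_(keep, keep)]
        m = sub.shape[0]
        # observed / expected per diagonal offset within this chromosome
        d = np.abs(np.subtract.outer(np.arange(m), np.arange(m)))
        exp = np.array([np.mean(np.diagonal(sub, k)) for k in range(m)])
        e = exp[d]
        with np.errstate(invalid="ignore", divide="ignore"):
            oe = np.where(e > 0, sub / np.where(e > 0, e, 1), 0.0)
        with np.errstate(invalid="ignore"):
            corr = np.corrcoef(oe, rowvar=False)
        bad = ~np.isfinite(corr).all(axis=0)
        if bad.all() or np.allclose(corr[~bad][:, ~bad], corr[~bad][0, 0]):
            raise HicdeskError(f"degenerate correlation matrix on {name}")
        good = ~bad
        corr_g = corr[np.ix_(good, good)]
        pca = PCA(n_components=min(5, corr_g.shape[0]))
        scores = pca.fit_transform(corr_g)[:, 0]
        if scores[np.argmax(np.abs(scores))] < 0:
            scores = -scores
        varexp[name] = float(pca.explained_variance_ratio_[0])
        if varexp[name] < weak_threshold:
            flagged.append(name)
        idx = np.arange(lo, hi)[keep][good]
        fpc[idx] = scores

    orientation = "loading"
    if orientation_track is not None:
        ok = np.isfinite(fpc) & np.isfinite(orientation_track.values)
        if ok.sum() >= 3 and np.ptp(orientation_track.values[ok]) > 0:
            # flip per chromosome so FPC correlates positively with the track
            for name in fragments.genome.names:
                lo, hi = fragments.chrom_slice(name)
                sel = ok[lo:hi]
                if sel.sum() < 3:
                    continue
                r = np.corrcoef(fpc[lo:hi][sel],
                                orientation_track.values[lo:hi][sel])[0, 1]
                if np.isfinite(r) and r < 0:
                    fpc[lo:hi] = -fpc[lo:hi]
            orientation = f"track:{orientation_track.name}"

    labels = np.where(np.isnan(fpc), "masked", np.where(fpc > 0, "A", "B"))
    return CompartmentResult(fragments, fpc, labels, varexp, orientation, flagged)


@dataclass
class EnrichmentResult:
    table: pd.DataFrame  # one row per track
    kind: str  # 'correlation' | 'sign_ratio'


def fpc_track_correlation(
    compartments: CompartmentResult, tracks: Sequence[Track]
) -> EnrichmentResult:
    """Pearson correlation of FPC with each track (counts log2(x+1)-scaled),
    with the standard two-sided test of zero correlation."""
    rows = []
    fpc = compartments.fpc
    for t in tracks:
        if len(t.values) != len(fpc):
            raise HicdeskError(f"track {t.name} length mismatch")
        v = t.analysis_values()
        ok = np.isfinite(fpc) & np.isfinite(v)
        if ok.sum() < 3 or np.ptp(v[ok]) == 0:
            rows.append({"track": t.name, "r": np.nan, "p_value": np.nan,
                         "n": int(ok.sum())})
            continue
        res = stats.pearsonr(fpc[ok], v[ok])
        rows.append({"track": t.name, "r": float(res.statistic),
                     "p_value": float(res.pvalue), "n": int(ok.sum())})
    return EnrichmentResult(pd.DataFrame(rows), "correlation")


def fpc_sign_enrichment(
    compartments: CompartmentResult, tracks: Sequence[Track]
) -> EnrichmentResult:
    """Sign-split enrichment: mean(track | FPC>0) / mean(track | FPC<0),
    tested with a two-sided Wilcoxon rank-sum (Mann-Whitney) test."""
    pos, neg = compartments.sign_groups()
    if pos.size == 0 or neg.size == 0:
        raise HicdeskError("one FPC sign group is empty")
    rows = []
    for t in tracks:
        vp = t.values[pos]
        vn = t.values[neg]
        vp, vn = vp[np.isfinite(vp)], vn[np.isfinite(vn)]
        mp, mn = float(np.mean(vp)), float(np.mean(vn))
        if mn == 0:
            ratio = np.inf if mp > 0 else np.nan
        else:
            ratio = mp / mn
        if vp.size and vn.size and (np.ptp(np.concatenate([vp, vn])) > 0):
            # exact null distribution when feasible and tie-free (as in R's
            # wilcox.test); normal approximation otherwise
            no_ties = np.unique(np.concatenate([vp, vn])).size == vp.size + vn.size
            method = "exact" if (no_ties and max(vp.size, vn.size) < 50) else "asymptotic"
            p = float(stats.mannwhitneyu(vp, vn, alternative="two-sided",
                                         method=method).pvalue)
        else:
            p = 1.0
        rows.append({"track": t.name, "mean_positive": mp, "mean_negative": mn,
                     "ratio": ratio, "p_value": p,
                     "n_positive": int(vp.size), "n_negative": int(vn.size)})
    return EnrichmentResult(pd.DataFrame(rows), "sign_ratio")
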