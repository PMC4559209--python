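"""Normalization, sample correlation, and sample-comparison matrices.

Three normalization strategies are provided:

- ``normalize_distance_coverage``: intra-chromosomal entries are divided
  by the mean contact frequency at their genomic distance (observed over
  expected); inter-chromosomal entries by the product of their row and
  column coverage means over the overall inter mean.
- ``normalize_iterative`` (ICE): matrix balancing that factors the
  observed map as W = B^-1 M B^-1 with a multiplicative per-fragment
  bias vector B, iterated until all unmasked row sums agree.
- ``normalize_poisson`` (HiCNorm-style): a per-chromosome log-linear
  Poisson regression of counts on fragment length and GC products, with
  mappability as a fixed offset; the fitted systematic part (intercept
  excluded) is divided out.

Sample similarity is the mean (or median) Pearson correlation of the
per-bin interaction profiles ("virtual 4C tracks").  Two samples are
compared through relative differences, correlated differences, and
signed difference matrices (SDMs) with an empirical significance test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import scipy.sparse as sp
from scipy import stats

from .genome_model import FragmentSet, HicdeskError
from .preprocess import InteractionMatrix


class ConvergenceError(HicdeskError):
    def __init__(self, message: str, residual: float):
        super().__init__(message)
        self.residual = residual


@dataclass
class NormalizedMatrix:
    """Dense symmetric normalized map plus provenance.

    ``mask`` marks fragments excluded from normalization (their rows and
    columns are NaN).  ``meta`` carries method-specific results (bias
    vector, iteration count, regression coefficients).
    """

    fragments: FragmentSet
    matrix: np.ndarray
    method: str
    mask: np.ndarray = None  # True = excluded fragment
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        n = len(self.fragments)
        if self.matrix.shape != (n, n):
            raise HicdeskError("matrix shape does not match fragment set")
        if self.mask is None:
            self.mask = np.zeros(n, dtype=bool)

    def dense(self, chrom: Optional[str] = None) -> np.ndarray:
        if chrom is None:
            return self.matrix
        lo, hi = self.fragments.chrom_slice(chrom)
        return self.matrix[lo:hi, lo:hi]

    def to_tsv(self, path: str, header: str = "") -> None:
        iu, ju = np.triu_indices(len(self.fragments))
        vals = self.matrix[iu, ju]
        keep = np.isfinite(vals) & (vals != 0)
        with open(path, "w") as fh:
            if header:
                for line in header.rstrip("\n").split("\n"):
                    fh.write(f"# {line}\n")
            fh.write("fragmentID1\tfragmentID2\tcount\n")
            for i, j, v in zip(iu[keep], ju[keep], vals[keep]):
                fh.write(f"{i}\t{j}\t{v:.8g}\n")


@dataclass
class FragmentCovariates:
    """Per-fragment length (bp), GC fraction and mappability in [0, 1]."""

    length: np.ndarray
    gc: np.ndarray
    mappability: np.ndarray = None

    def __post_init__(self) -> None:
        self.length = np.asarray(self.length, dtype=float)
        self.gc = np.asarray(self.gc, dtype=float)
        if self.mappability is None:
            self.mappability = np.ones_like(self.length)
        self.mappability = np.asarray(self.mappability, dtype=float)
        if np.any((self.gc < 0) | (self.gc > 1)):
            raise HicdeskError("GC fractions must lie in [0, 1]")
        if np.any((self.mappability < 0) | (self.mappability > 1)):
            raise HicdeskError("mappability must lie in [0, 1]")

    @classmethod
    def from_fasta(cls, fragments: FragmentSet, genome) -> "FragmentCovariates":
        from .genome_model import _as_records

        seqs = dict(_as_records(genome))
        gc = np.empty(len(fragments))
        for i in range(len(fragments)):
            f = fragments[i]
            s = seqs[f.chrom][f.start:f.end].upper()
            acgt = sum(s.count(b) for b in "ACGT")
            gc[i] = (s.count("G") + s.count("C")) / acgt if acgt else 0.0
        return cls(fragments.lengths.astype(float), gc)


@dataclass
class ComparisonResult:
    matrix: np.ndarray
    kind: str  # relative_difference | correlated_difference | signed_difference
    statistic: Optional[float] = None
    p_value: Optional[float] = None
    meta: dict = field(default_factory=dict)


def _as_dense(matrix) -> tuple[np.ndarray, FragmentSet, np.ndarray]:
    """Accept InteractionMatrix or NormalizedMatrix; return (dense, fragments, mask)."""
    if isinstance(matrix, InteractionMatrix):
        return matrix.dense(), matrix.fragments, np.zeros(len(matrix.fragments), bool)
    if isinstance(matrix, NormalizedMatrix):
        return matrix.matrix.copy(), matrix.fragments, matrix.mask.copy()
    raise HicdeskError(f"unsupported matrix type {type(matrix).__name__}")


def _chrom_blocks(fragments: FragmentSet):
    for name in fragments.genome.names:
        yield name, fragments.chrom_slice(name)


def expected_by_distance(dense: np.ndarray, fragments: FragmentSet) -> np.ndarray:
    """Mean intra-chromosomal contact per diagonal offset, pooled over chromosomes.

    Index d of the returned vector is the mean of all entries at diagonal
    offset d (in fragments) across all chromosomes; NaN where no pairs exist.
    """
    max_d = max(hi - lo for _n, (lo, hi) in _chrom_blocks(fragments))
    sums = np.zeros(max_d)
    counts = np.zeros(max_d)
    for _name, (lo, hi) in _chrom_blocks(fragments):
        block = dense[lo:hi, lo:hi]
        for d in range(hi - lo):
            diag = np.diagonal(block, offset=d)
            ok = np.isfinite(diag)
            sums[d] += diag[ok].sum()
            counts[d] += ok.sum()
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(counts > 0, sums / np.where(counts > 0, counts, 1), np.nan)


def normalize_distance_coverage(matrix) -> NormalizedMatrix:
    """Observed/expected for intra-, coverage product for inter-chromosomal entries.

    Intra entries at diagonal offset d are divided by the pooled mean at
    that offset (so every distance class has mean exactly 1 afterwards);
    inter entries are divided by row_mean * col_mean / overall_mean of the
    inter-chromosomal submatrix.  All-zero distance classes become NaN and
    are counted in ``meta['undefined_classes']``.
    """
    dense, fragments, mask = _as_dense(matrix)
    if not np.any(dense):
        raise HicdeskError("empty matrix")
    out = np.full_like(dense, np.nan)
    exp = expected_by_distance(dense, fragments)
    undefined = 0
    for _name, (lo, hi) in _chrom_blocks(fragments):
        n = hi - lo
        d = np.abs(np.subtract.outer(np.arange(n), np.arange(n)))
        e = exp[d]
        with np.errstate(invalid="ignore", divide="ignore"):
            out[lo:hi, lo:hi] = np.where(e > 0, dense[lo:hi, lo:hi] / e, np.nan)
        undefined += int(np.sum(~(exp[: n] > 0)))

    codes = fragments.chrom_codes
    inter = codes[:, None] != codes[None, :]
    if inter.any():
        inter_vals = np.where(inter, dense, np.nan)
        row_mean = np.nanmean(inter_vals, axis=1)
        overall = np.nanmean(inter_vals)
        with np.errstate(invalid="ignore", divide="ignore"):
            denom = np.outer(row_mean, row_mean) / overall if overall > 0 else None
        if denom is not None:
            out[inter] = np.where(denom[inter] > 0, dense[inter] / denom[inter], np.nan)
    out[mask, :] = np.nan
    out[:, mask] = np.nan
    return NormalizedMatrix(fragments, out, "distance_coverage", mask,
                            {"undefined_classes": undefined, "expected": exp})


def normalize_iterative(
    matrix,
    tolerance: float = 1e-5,
    max_iterations: int = 200,
    mask_percentile: float = 2.0,
) -> NormalizedMatrix:
    """Iterative correction (ICE): equalize row sums via a multiplicative bias.

    Fragments whose total coverage falls at or below ``mask_percentile``
    percent of the nonzero-coverage distribution (plus all zero-coverage
    fragments) are masked out.  Converges when the relative spread of row
    sums drops below ``tolerance``; raises :class:`ConvergenceError`
    otherwise, carrying the last residual.
    """
    dense, fragments, mask = _as_dense(matrix)
    cov = np.nansum(np.where(np.isfinite(dense), dense, 0.0), axis=1)
    mask = mask | (cov <= 0)
    nz = cov[~mask]
    if nz.size == 0:
        raise HicdeskError("matrix has no unmasked fragments")
    if mask_percentile > 0:
        cut = np.percentile(nz, mask_percentile)
        mask = mask | (cov < cut)
    keep = ~mask
    W = np.nan_to_num(dense[np.ix_(keep, keep)]).astype(float)
    if W.shape[0] == 0 or not np.any(W):
        raise HicdeskError("matrix has no unmasked fragments")

    bias = np.ones(W.shape[0])
    residual = np.inf
    for iteration in range(1, max_iterations + 1):
        s = W.sum(axis=1)
        s = s / s.mean()
        residual = float(np.max(np.abs(s - 1.0)))
        if residual < tolerance:
            break
        # square-root damping: same fixed point (equal row sums), but
        # avoids the two-cycle that the undamped update falls into on
        # block-diagonal (zero inter-chromosomal) matrices
        s = np.sqrt(s)
        s[s == 0] = 1.0
        bias *= s
        W /= np.outer(s, s)
    else:
        raise ConvergenceError(
            f"iterative correction did not converge in {max_iterations} "
            f"iterations (residual {residual:.3g})", residual)

    out = np.full_like(dense, np.nan)
    out[np.ix_(keep, keep)] = W
    full_bias = np.full(len(fragments), np.nan)
    full_bias[keep] = bias
    return NormalizedMatrix(fragments, out, "iterative", mask,
                            {"bias": full_bias, "iterations": iteration,
                             "residual": residual})


def normalize_poisson(
    matrix, covariates: FragmentCovariates
) -> NormalizedMatrix:
    """HiCNorm-style Poisson regression normalization, fitted per chromosome.

    For each chromosome the upper triangle (diagonal excluded) of the raw
    count map is modelled as Poisson with
    ``log mu_ij = const + b_len log(len_i len_j) + b_gc log(gc_i gc_j)
    + log(map_i map_j)``; the normalized entry is the observed count
    divided by the fitted systematic part, keeping the intercept.
    Zero-variance covariates are dropped with a warning.  Inter-
    chromosomal entries and the diagonal pass through unchanged.
    """
    import statsmodels.api as sm

    dense, fragments, mask = _as_dense(matrix)
    out = dense.copy()
    coef: dict[str, dict] = {}
    for name, (lo, hi) in _chrom_blocks(fragments):
        n = hi - lo
        if n < 3:
            continue
        sub = dense[lo:hi, lo:hi]
        length = covariates.length[lo:hi]
        gc = covariates.gc[lo:hi]
        mapp = covariates.mappability[lo:hi]
        iu, ju = np.triu_indices(n, k=1)
        y = sub[iu, ju]
        ok = np.isfinite(y) & (length[iu] > 0) & (length[ju] > 0) \
            & (gc[iu] > 0) & (gc[ju] > 0) & (mapp[iu] > 0) & (mapp[ju] > 0)
        if ok.sum() < 10:
            continue
        x_len = np.log(length[iu] * length[ju])[ok]
        x_gc = np.log(gc[iu] * gc[ju])[ok]
        offset = np.log(mapp[iu] * mapp[ju])[ok]
        cols, names = [], []
        for arr, label in ((x_len, "log_len"), (x_gc, "log_gc")):
            if np.ptp(arr) > 1e-12:
                cols.append(arr)
                names.append(label)
            else:
                warnings.warn(
                    f"{name}: covariate {label} has zero variance; dropped",
                    stacklevel=2)
        X = sm.add_constant(np.column_stack(cols) if cols
                            else np.empty((ok.sum(), 0)), has_constant="add")
        model = sm.GLM(y[ok], X, family=sm.families.Poisson(), offset=offset)
        res = model.fit()
        params = dict(zip(["const"] + names, res.params))
        bse = dict(zip(["const"] + names, res.bse))
        coef[name] = {"params": params, "bse": bse}
        # systematic part without the intercept
        systematic = np.exp(
            sum(params[label] * arr for label, arr in
                zip(names, cols)) + offset
        )
        norm_vals = np.full(iu.shape, np.nan)
        norm_vals[ok] = y[ok] / systematic
        block = out[lo:hi, lo:hi]
        block[iu, ju] = norm_vals
        block[ju, iu] = norm_vals
    out[mask, :] = np.nan
    out[:, mask] = np.nan
    return NormalizedMatrix(fragments, out, "poisson_regression", mask,
                            {"coefficients": coef})


def sample_correlation(
    matrices: Sequence, statistic: str = "mean"
) -> np.ndarray:
    """Sample x sample similarity: mean/median per-bin virtual-4C correlation.

    For each pair of samples, every matrix row (the interaction profile of
    one bin against the genome) is Pearson-correlated between the two
    samples; the summary over bins is the mean or median.  Constant rows
    are skipped for that pair.
    """
    if statistic not in ("mean", "median"):
        raise HicdeskError(f"unknown statistic {statistic!r}")
    denses = [_as_dense(m)[0] for m in matrices]
    n = len(denses)
    shape = denses[0].shape
    if any(d.shape != shape for d in denses):
        raise HicdeskError("matrices are on different fragment sets")
    out = np.eye(n)
    for a in range(n):
        for b in range(a + 1, n):
            rs = []
            for row in range(shape[0]):
                x, y = denses[a][row], denses[b][row]
                ok = np.isfinite(x) & np.isfinite(y)
                if ok.sum() < 3 or np.ptp(x[ok]) == 0 or np.ptp(y[ok]) == 0:
                    continue
                rs.append(stats.pearsonr(x[ok], y[ok]).statistic)
            if not rs:
                raise HicdeskError("no usable bins for sample correlation")
            val = float(np.mean(rs) if statistic == "mean" else np.median(rs))
            out[a, b] = out[b, a] = val
    return out


def relative_difference(a, b) -> ComparisonResult:
    """Entrywise (A - B) / ((A + B) / 2); both-zero entries are 0, range [-2, 2]."""
    da, fa, ma = _as_dense(a)
    db, fb, mb = _as_dense(b)
    if da.shape != db.shape:
        raise HicdeskError("matrices have different shapes")
    mean = (da + db) / 2.0
    with np.errstate(invalid="ignore", divide="ignore"):
        rel = np.where(mean != 0, (da - db) / np.where(mean != 0, mean, 1), 0.0)
    rel[~(np.isfinite(da) & np.isfinite(db))] = np.nan
    return ComparisonResult(rel, "relative_difference")


def correlated_difference(relative: ComparisonResult) -> ComparisonResult:
    """Row-by-row Pearson correlation of a relative-difference matrix."""
    if relative.kind != "relative_difference":
        raise HicdeskError("input must be a relative_difference result")
    m = relative.matrix
    n = m.shape[0]
    out = np.full((n, n), np.nan)
    finite = np.isfinite(m)
    for i in range(n):
        out[i, i] = 1.0
        for j in range(i + 1, n):
            ok = finite[i] & finite[j]
            if ok.sum() < 3 or np.ptp(m[i, ok]) == 0 or np.ptp(m[j, ok]) == 0:
                continue
            r = stats.pearsonr(m[i, ok], m[j, ok]).statistic
            out[i, j] = out[j, i] = r
    return ComparisonResult(out, "correlated_difference")


def _sdm_statistic(signs: np.ndarray) -> float:
    ok = np.isfinite(signs)
    if not ok.any():
        raise HicdeskError("no finite entries for SDM statistic")
    return float(abs(np.mean(signs[ok])))


def signed_difference(
    a,
    b,
    replicates_a: Optional[Sequence] = None,
    replicates_b: Optional[Sequence] = None,
    permutations: int = 999,
    seed: int = 0,
    n_blocks: int = 20,
) -> ComparisonResult:
    """Signed difference matrix sign(A - B) with an empirical significance test.

    The summary statistic is |mean sign| over the finite upper-triangle
    entries: 0 for a balanced difference, 1 for a wholly one-sided one.
    The null distribution is built by permuting replicate labels when
    per-sample replicate matrices are supplied, and by random sign flips
    of ``n_blocks`` contiguous entry blocks otherwise; the p-value uses
    the (k+1)/(n+1) rule and is one-sided (large statistic = difference).
    """
    if permutations < 1:
        raise HicdeskError("permutations must be >= 1")
    da, fa, _ = _as_dense(a)
    db, _, _ = _as_dense(b)
    if da.shape != db.shape:
        raise HicdeskError("matrices have different shapes")
    sdm = np.sign(da - db)
    sdm[~(np.isfinite(da) & np.isfinite(db))] = np.nan
    iu, ju = np.triu_indices(da.shape[0], k=1)
    signs = sdm[iu, ju]
    observed = _sdm_statistic(signs)
    rng = np.random.default_rng(seed)

    null = np.empty(permutations)
    if replicates_a and replicates_b:
        reps = [
            _as_dense(m)[0] for m in list(replicates_a) + list(replicates_b)
        ]
        na = len(replicates_a)
        idx = np.arange(len(reps))
        for k in range(permutations):
            perm = rng.permutation(idx)
            ga = np.mean([reps[i] for i in perm[:na]], axis=0)
            gb = np.mean([reps[i] for i in perm[na:]], axis=0)
            s = np.sign(ga - gb)[iu, ju]
            null[k] = _sdm_statistic(s)
        mode = "replicate_permutation"
    else:
        ok = np.isfinite(signs)
        vals = signs[ok]
        blocks = np.array_split(np.arange(vals.size), min(n_blocks, vals.size))
        for k in range(permutations):
            flipped = vals.copy()
            for blk in blocks:
                if rng.random() < 0.5:
                    flipped[blk] = -flipped[blk]
            null[k] = abs(flipped.mean())
        mode = "block_sign_flip"
    k_ge = int(np.sum(null >= observed))
    p = (k_ge + 1) / (permutations + 1)
    return ComparisonResult(sdm, "signed_difference", statistic=observed,
                            p_value=p, meta={"null": null, "mode": mode,
                                             "permutations": permutations})


def render_heatmap(matrix, path: str, title: str = "") -> None:
    """Write a heatmap PNG: sequential palette for maps, diverging (centred
    at 0) for comparison results; NaNs in grey; chromosome boundaries drawn
    when fragment information is available."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fragments = None
    if isinstance(matrix, ComparisonResult):
        data = matrix.matrix
        cmap = plt.get_cmap("RdBu_r").copy()
        finite = data[np.isfinite(data)]
        vmax = float(np.max(np.abs(finite))) if finite.size else 1.0
        vmin = -vmax
    else:
        data, fragments, _ = _as_dense(matrix)
        cmap = plt.get_cmap("viridis").copy()
        finite = data[np.isfinite(data)]
        vmin = float(finite.min()) if finite.size else 0.0
        vmax = float(finite.max()) if finite.size else 1.0
    if not np.all(np.isfinite(data)) or finite.size == 0:
        pass
    cmap.set_bad("0.7")
    fig, ax = plt.subplots(figsize=(6, 5.5))
    im = ax.imshow(np.ma.masked_invalid(data), cmap=cmap, vmin=vmin, vmax=vmax,
                   interpolation="nearest")
    if fragments is not None:
        for name in fragments.genome.names[:-1]:
            _lo, hi = fragments.chrom_slice(name)
            ax.axhline(hi - 0.5, color="black", lw=0.5)
            ax.axvline(hi - 0.5, color="black", lw=0.5)
    fig.colorbar(im, ax=ax, shrink=0.8)
    if title:
        ax.set_title(title)
    fig.savefig(path, dpi=120)
    plt.close(fig)
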