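# Methods

This note documents the models, conventions and numerical choices behind
`hicdesk`, and what the synthetic fixtures do and do not emulate.

## Coordinate system and fragments

All coordinates are 0-based half-open internally. File boundaries convert:
GFF/GTF input (1-based inclusive) is converted by the reader, SAM
positions come through pysam already 0-based, and the exported fragment
and track tables are written 1-based inclusive with a `#` header that
records provenance (tool version, parameters, seed).

A `FragmentSet` tiles each chromosome exactly — first fragment starts at
0, last ends at the chromosome length, no gaps or overlaps — and fragment
IDs are consecutive integers ordered by (chromosome order, start). The
restriction digest scans each enzyme motif exactly and case-insensitively
on the forward strand and cuts at `occurrence_start + cut_offset`. The
common Hi-C enzymes (HindIII `A^AGCTT`, DpnII `^GATC`, both packaged) have
palindromic sites, so reverse-strand scanning would be redundant;
non-palindromic motifs are accepted but are scanned forward-only, which is
documented at the type. Ambiguity codes (N runs) never match a motif, so
no cut sites are fabricated in unresolved sequence. The cut position is
the enzyme's biochemical cut offset, not the motif start; the offset is
part of the enzyme definition and therefore configurable.

## Read-end processing

Hi-C read-ends are aligned independently and joined by read name, with a
trailing `/1`, `/2` or whitespace-delimited mate tag stripped (real FASTQ
naming requires this). "Unique" means a primary, non-supplementary
alignment with MAPQ ≥ 1 (threshold configurable) and a single record per
name; anything else makes the read an orphan or non-unique.

The *position* of an end — used both for the proximity-filter span and
for fragment assignment — is its 5′-most aligned base (leftmost on `+`,
rightmost on `−`). This is the ligation-informative coordinate.

The optional proximity filter classifies same-chromosome opposite-strand
pairs as *inward* (upstream end on `+`, ends pointing toward each other)
or *outward* (upstream end on `−`). Inward pairs with span below the
inward threshold are removed as likely uncut DNA; outward pairs below the
outward threshold as likely self-ligation. Defaults are 1 000 bp (inward)
and 25 000 bp (outward), both configurable, and the filter is off unless
requested. Inter-chromosomal and same-strand pairs always pass.

Interaction matrices are stored as upper-triangle sparse triplets keyed by
unordered fragment pairs; dense symmetric per-chromosome (or genome-wide)
views are materialized on demand. The matrix total always equals the
number of pairs counted.

## Tracks

Four track kinds with distinct semantics:

| kind                  | per-fragment value                                   | aggregation |
|-----------------------|------------------------------------------------------|-------------|
| `annotation_count`    | +1 per feature spanning the whole fragment, +0.5 per partial overlap (including features inside the fragment) | sum |
| `short_count`         | one count per read, in the fragment holding its 5′ base | sum |
| `density`             | 100 × bases covered by the union of elements / fragment length | length-weighted mean |
| `methylation_density` | 100 × Σ methylated / Σ total over contained cytosines; no covered cytosine → missing (NaN), not 0 | length-weighted mean |

Density uses union coverage, not depth, so duplicated elements change
nothing. Methylation is pooled (Σm/Σt) rather than averaged per site, so
deeply covered cytosines carry proportionally more weight. Aggregation to
a coarser fragment set assigns each fine fragment to the coarse fragment
containing its midpoint; count kinds sum (conserving totals exactly),
density kinds take the length-weighted mean of non-missing members — for
equal-size bins this coincides with the plain average. Count tracks are
log2(x+1)-transformed at analysis time only (FPC correlation tests), never
at storage time; the pseudo-count of 1 keeps zeros at zero. Strand is
read but ignored for every track kind.

## Normalization

**Distance/coverage.** Intra-chromosomal entries are divided by the mean
contact frequency at their diagonal offset, pooled across chromosomes by
default (the per-diagonal arithmetic mean, including zeros). By
construction every distance class has mean exactly 1 afterwards. All-zero
classes become missing and are flagged. Inter-chromosomal entries are
divided by `row_mean × col_mean / overall_mean` computed over the
inter-chromosomal submatrix. Both parts are invariant to scaling the
counts.

**Iterative correction (ICE).** Fragments whose coverage is below the
2nd percentile of the nonzero-coverage distribution (configurable), plus
all zero-coverage fragments, are masked. The bias update is square-root
damped: `s = sqrt(rowsum / mean rowsum)`, `W ← W / (s sᵀ)`. The fixed
point (all unmasked row sums equal) is identical to the undamped update,
but the damping avoids the two-cycle the undamped iteration falls into on
block-diagonal matrices — which Hi-C maps effectively are when
inter-chromosomal counts are sparse or zero. Convergence is declared when
the relative row-sum spread drops below 1e−5 (default), with a hard cap
of 200 iterations; non-convergence raises an error carrying the last
residual. Note that ICE factors *all* multiplicative row structure into
the bias: on a map whose true expectation has unequal row sums (edge
effects, irregular fragment spacing), the recovered bias is the planted
one times that structural component. Bias-recovery checks therefore use a
circulant (wrap-around) decay matrix, whose true row sums are equal.

**Poisson regression (HiCNorm-style).** Fitted per chromosome on the
upper triangle excluding the main diagonal:
`O_ij ~ Poisson(μ_ij)`, `log μ_ij = β₀ + β_len log(l_i l_j) + β_gc
log(g_i g_j) + log(m_i m_j)`, with mappability as a fixed offset
(defaulting to 1 when no track is supplied). The normalized entry is
`O_ij / exp(β_len x_len + β_gc x_gc + offset)` — the intercept is *not*
removed, so the count scale is preserved. Zero-variance covariates are
dropped with a warning; inter-chromosomal entries and the diagonal pass
through unchanged.

## Sample correlation and comparison

Sample similarity is the mean (or median) over bins of the Pearson
correlation between the two samples' virtual 4C tracks (matrix rows);
constant rows are skipped per pair. Relative differences are
`(A−B)/((A+B)/2)`, bounded by [−2, 2]; both-zero entries are defined as 0
(no evidence of difference) rather than missing. Correlated differences
are the row-by-row Pearson correlations of the relative-difference
matrix.

The SDM is `sign(A−B)` entrywise. Its summary statistic is |mean sign|
over the finite upper-triangle entries: 0 when increases and decreases
balance, 1 when the difference is wholly one-sided. Significance is
empirical and one-sided with `p = (k+1)/(n+1)`: when per-sample replicate
matrices are available the null permutes replicate labels and recomputes
group means; otherwise it flips the signs of 20 contiguous blocks of
upper-triangle entries independently (blocks approximate the spatial
dependence of neighbouring pairs; the count is configurable). The
statistic and both null constructions are deliberately kept behind one
small interface so alternative operationalizations can be swapped in.

## Distance decay (IDE)

Mean contact frequency is computed per distance class — exact multiples
of the bin size for binned maps, 50 log-spaced midpoint-distance classes
for restriction-fragment maps — and the IDE is the OLS slope of
log₁₀(mean) on log₁₀(distance) over the fit range, by default [2 bins
(or the smallest observed distance), half the longest chromosome]. At
least 3 positive classes are required. The slope is invariant to scaling
the matrix; the intercept shifts by log₁₀ of the factor. Supplying
regions restricts both pair endpoints to fragments whose midpoints lie
inside a region.

When compartment structure is present, the block contrast mixes into the
per-distance means; the planted exponent is recovered without bias only
when the fit range spans several block periods so the within-block
fraction oscillates around a constant. The joint-recovery checks use 300
bins with 15-bin blocks for this reason.

## Compartments (FPC)

Per chromosome: zero-coverage and masked fragments are dropped row-and-
column-wise; the intra map is distance-normalized (observed over the
within-chromosome per-diagonal mean); the columns of the result are
Pearson-correlated; and the first principal component of the correlation
matrix gives one score per fragment. Chromosomes with fewer than 10
usable fragments are fully masked; a first-component variance-explained
fraction below 0.1 flags the chromosome as having weak or unstable
structure. Restriction-fragment maps should be re-binned to a uniform bin
before compartment calling, since PCA on variable-size fragments
conflates fragment length with signal.

The eigenvector sign is arbitrary; by default the largest-|score|
fragment is made positive (stable under resimulation), and when an
orientation track is supplied (typically gene counts) the sign is flipped
per chromosome so that the FPC correlates positively with it. Labels are
assigned by sign (`A` for positive). Sign-group enrichment reports
`mean(track | FPC>0) / mean(track | FPC<0)` on raw values, tested with a
two-sided Wilcoxon rank-sum; the exact null distribution is used when the
groups are tie-free and small (< 50 per group, mirroring R's
`wilcox.test`), the normal approximation otherwise. A zero denominator
with positive numerator is reported as infinite and flagged by the
consumer-facing table.

## Balanced region resampling

Random region sets are balanced for number, length and location: each
random set holds, for every region of interest, one interval of the same
length on the same chromosome, uniform over valid start positions, and —
when a class table (e.g. arms vs pericentromeres) is supplied — within
the class interval containing the region's midpoint. Random intervals may
overlap each other and the observed regions; no exclusion is applied.
Fragment membership uses the fragment-midpoint-in-region rule. The
interaction statistic is the mean matrix entry over all *between*-region
fragment pairs; within-region (self) pairs are excluded so that the test
asks about contacts among distinct regions. The feature statistic is the
sum for count tracks and the length-weighted mean for density tracks.
One-sided p-values use `p = (k+1)/(n+1)` with ties counted against the
alternative, so p is conservative and never 0. With integer-valued count
statistics and few regions, ties between the observed value and null
draws make the null p distribution slightly conservative; calibration
checks therefore use continuous (density) statistics.

## Synthetic fixtures

The generators plant known ground truth in every supported input format:

- **Genome**: uniform-composition random sequence with enzyme sites at
  Poisson-spaced positions (mean gap configurable, 4 kb in the packaged
  presets); accidental motif occurrences are mutated away so the digest
  truth is exactly the planted site list.
- **Pairs**: contacts drawn multinomially over fragment pairs with weight
  `b_i b_j ρ^[same block] d_ij^−α` (intra; midpoint distance, α = 0.85
  default) or `b_i b_j × inter_level` (inter); end positions uniform
  within fragments, strands random. A configurable fraction of short
  inward and outward artefact pairs is injected with truth-labelled read
  names. `protect_from_filter` gives genuine short-span contacts
  same-strand orientation so that proximity filtering removes the
  injected artefacts and nothing else — used by the exactness checks.
  Alignments are written as minimal single-end SAM (MAPQ 60 unique, 0 for
  planted non-unique ends; placeholder sequences, since alignment is
  upstream of this package).
- **Tracks**: GFF features strictly inside fragments (each contributes
  0.5), short-read SAM counts, one coverage element per fragment, and
  binomial methylation calls every 100 bp, with 'A'-block levels scaled
  by the requested effect size (base levels: 5 features/reads per
  fragment, 30 % coverage, 30 % methylation at 20 reads/site).

Every generator is seed-deterministic (same seed → byte-identical
files). The fixtures emulate the statistical structure the analyses
assume — power-law decay, block compartments, multiplicative bias,
compartment-correlated tracks — but not sequencing errors, PCR
duplicates, mappability variation, ligation-junction chimeras or
realistic read sequences. Passing tests therefore demonstrate
correctness of the computations under the stated generative model, not
robustness to every artefact of real libraries.

## Problem sizes used in the checks

The packaged verification runs use deliberately compact configurations:
two-chromosome genomes of 30–80 kb for exactness checks, a 200 × 200
circulant matrix for ICE bias recovery, 142 bins (≈10⁴ fragment pairs)
for the Poisson-regression checks, 10⁶ multinomially sampled pairs on 300
× 10 kb bins for IDE recovery, 80 bins in two blocks for compartment
recovery, and 200 repetitions × 99 balanced sets for resampling
calibration. These sizes were chosen so the statistical targets (2 SE
coefficient recovery, ±0.05 on the decay slope, 95 % label accuracy,
KS < 0.1 calibration) are comfortably identifiable.

## Known limitations

- No PCR-duplicate removal, ligation-junction trimming, or
  effective-length fragment modelling.
- Poisson normalization needs user-provided GC/mappability tracks for
  real genomes (`FragmentCovariates.from_fasta` computes GC only).
- The SDM statistic and its null are one reasonable operationalization of
  "extent and significance of the difference"; they are interface-stable
  but not canonical.
- TAD-style two-dimensional segmentation is out of scope; compartment
  calling stops at the FPC sign.
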