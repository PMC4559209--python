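# hicdesk

Hi-C contact-map construction and structural analysis for comparative
chromatin-organization studies.

Hi-C read pairs report which pairs of genomic loci were spatially close in
the nucleus. `hicdesk` takes the two *separately aligned* read-end files of
a Hi-C experiment and turns them into fragment-level interaction matrices,
annotates the fragments with genomic and epigenomic tracks (gene
annotation, RNA-seq counts, ChIP-seq densities, bisulfite methylation), and
provides the higher-level analyses used to describe and compare nuclear
architecture:

- **Fragments.** The genome is tiled either into restriction fragments (an
  in-silico digest with one or more enzymes, e.g. HindIII `A^AGCTT`) or
  into fixed-size bins. All matrices and tracks are keyed to this tiling.
- **Pairing and filtering.** Read-ends are joined by read name; only
  unique alignments are kept. Short *inward* pairs (uncut DNA) and short
  *outward* pairs (self-ligation) can be removed with configurable span
  thresholds.
- **Normalization.** Three methods: observed/expected by genomic distance
  with coverage normalization of inter-chromosomal entries; iterative
  correction (ICE), which factors the map as `W = B⁻¹ M B⁻¹` with a
  multiplicative per-fragment bias `B`; and HiCNorm-style Poisson
  regression, `log μᵢⱼ = β₀ + β₁ log(lᵢlⱼ) + β₂ log(gᵢgⱼ) + log(mᵢmⱼ)`,
  on fragment length, GC and mappability.
- **Distance decay.** The interaction decay exponent (IDE) is the OLS
  slope of `log₁₀(mean contact)` on `log₁₀(distance)`; around −1 for a
  fractal-globule-like polymer.
- **Compartments.** Per chromosome, the first principal component (FPC)
  of the Pearson-correlated observed/expected intra-chromosomal map splits
  fragments into two structural groups (A/B-like); their association with
  tracks is tested by correlation and by sign-group enrichment ratios with
  a two-sided Wilcoxon rank-sum test.
- **Sample comparison.** Relative differences `(A−B)/((A+B)/2)`,
  correlated differences, and signed difference matrices (SDMs) with an
  empirical permutation test.
- **Region tests.** Balanced resampling: regions of interest are compared
  against random region sets matched in number, length and chromosomal
  location, giving one-sided empirical p-values `p = (k+1)/(n+1)`.
- **Synthetic fixtures.** Every input can be generated with known ground
  truth (planted restriction sites, a planted contact model with power-law
  decay, compartment blocks and per-fragment bias, tracks with planted
  compartment effects), so the whole pipeline is testable offline.

## Worked example

Simulate a two-chromosome fixture and run the pipeline end to end:

```bash
hicdesk simulate --preset full --seed 7 --n-pairs 20000 -o fixture
hicdesk pair -f fixture/ends_fwd.sam -r fixture/ends_rev.sam -o pairs.tsv
hicdesk map --pairs pairs.tsv --fragments fixture/fragments.tsv --filter -o matrix.tsv
hicdesk normalize --matrix matrix.tsv --fragments fixture/fragments.tsv --method ice -o norm.tsv
hicdesk ide --matrix matrix.tsv --fragments fixture/fragments.tsv -o ide.tsv
hicdesk compartments --matrix matrix.tsv --fragments fixture/fragments.tsv -o comp.tsv
```

which prints:

```
[hicdesk] simulate: genome with 184 planted HindIII sites -> fixture/genome.fa
[hicdesk] simulate: 20000 pairs (400 artefacts) -> fixture/ends_fwd.sam, fixture/ends_rev.sam
[hicdesk] simulate: tracks written to fixture
[hicdesk] pair: 20400 pairs, 0 orphans, 0 non-unique ends discarded
[hicdesk] filter: 644 inward and 3290 outward pairs removed
[hicdesk] map: 20400 pairs in, 16466 counted, 0 skipped (unknown chromosome)
[hicdesk] normalize: method=iterative, 4 fragments masked
[hicdesk] ide: slope=-0.8001 (r^2=0.989)
[hicdesk] compartments: variance explained chr1=0.16, chr2=0.15
```

Reading the output: all 20 400 simulated read pairs (20 000 genuine
contacts plus 400 injected proximity artefacts) are paired by name; the
inward/outward filter removes the artefacts together with genuine
short-range opposite-strand pairs; ICE balances the counts after masking
the 4 lowest-coverage fragments; and the fitted decay slope of −0.80 sits
near the planted exponent of −0.85 (restriction fragments at this shallow
depth retain some short-range bias from the filtered pairs). The
`comp.tsv` table lists the per-fragment FPC value and A/B-like label.

All stages are also available as a library:

```python
import hicdesk as hd
fs = hd.digest_genome("fixture/genome.fa", [hd.BUILTIN_ENZYMES["HindIII"]])
pairs, stats = hd.pair_alignments("fixture/ends_fwd.sam", "fixture/ends_rev.sam")
matrix = hd.count_interactions(pairs, fs)
ide = hd.compute_ide(matrix)
```

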