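# Methods

This note documents the statistical model behind `cistrans-mpra`, the
defaults it ships with, what the synthetic-data generator does and does not
emulate, and the numerical choices that matter when reading its output.

## Measurement model

An MPRA library attaches `k` barcodes to each regulatory sequence (13 for
TSS tiles, 3 for random negative controls, 60 for positive-control tiles).
The generator draws a latent gamma abundance `w_b` per barcode, a pooled
input DNA count `D_b ~ NB(mean = dna_depth * w_b / Σw, dispersion φ)`
(variance `μ + φμ²`), and RNA counts per environment × replicate with mean
proportional to `D_b * 2^{α*(s,e)}`, rescaled so each sample's expected
total equals `rna_depth`. Tying RNA means to the *realized* DNA count — RNA
is transcribed from the DNA that actually entered the cells — means the
per-barcode log ratio has expectation `α*` for every barcode and no
barcode-level random effect; this is what makes the downstream OLS F-test
exact (null p-values are uniform, verified by KS test at 1000 null pairs).

The true activity surface is additive in log2 units:

```
α*(human seq, hESC) = base + activity-motif contributions
α*(mouse seq, hESC) = ... + cis shift        (same shift in both environments)
α*(·, mESC)         = α*(·, hESC) + trans shift   (same shift for both members)
```

so `native* = cis* + trans*` holds exactly for every pair, and compensatory
pairs (opposite cis/trans signs) have `|native*| ≤ max(|cis*|, |trans*|)`.

## Defaults and why

| parameter | default | rationale |
| --- | --- | --- |
| `n_pairs` | 500 | enough pairs for stable fraction estimates at desk scale |
| `barcodes_per_class` | 13 / 3 / 60 | the library's TSS / negative / positive multiplicities |
| `n_negative_controls` | 200 | empirical activity p-values resolve to 1/201 |
| `n_positive_controls` | 4 | four 60-barcode tiles → 200 null pairs at 50 draws each |
| `n_replicates` | 3 | three biological replicates per environment |
| `dna_depth`, `rna_depth` | 5×10⁶ | a few hundred counts per barcode, realistic for MPRA |
| `nb_dispersion` | 0.05 | overdispersion dominating shot noise at these depths |
| `frac_cis`, `frac_trans` | 0.40, 0.18 | the divergence rates the study design anticipates |
| `cis_effect_sd`, `trans_effect_sd` | 1.0, 0.6 | cis effects larger than trans, both in log2 units |
| `frac_compensatory` | 0.5 | co-occurring effects split between sign patterns |
| `redundancy_correlation` | 0.8 | clearly separated from the null correlation mode |
| `n_expression_samples` | 200 | desk-scale stand-in for a ~1800-sample atlas |

Planted cis/trans effects have magnitude `0.3 + |N(0, sd)|`: the configured
fractions describe real, detectable divergence (≥ 1.2-fold), not
arbitrarily small shifts that no assay could call.

## Activity estimation and its identifiability

`alpha = mean over replicates of (median over barcodes of log2((rna_cpm+1)/(dna_cpm+1)))`.

Because both samples are scaled to counts per million, activity is
identified only up to a library-composition constant
`log2(Σ d·2^α / Σ d)`: estimates recover the planted surface with r > 0.95
but sit a constant below it (the library's average activity is absorbed by
the normalisation, as in any ratio-based MPRA quantification). Absolute
recovery within 0.1 log2 units is demonstrated on a composition-balanced
library where that constant is zero by construction. All downstream
contrasts are differences of alphas, so the constant cancels within an
environment.

One consequence of global scaling remains visible across environments: by
Jensen's inequality the mESC totals are inflated by `E[2^τ] > 1` even for
sign-symmetric trans shifts, so sequences without a planted trans effect
acquire a small negative apparent shift (~0.2 log2 at defaults). The null
controls share exactly this shift, so the empirical-FDR calibration treats
it as the no-effect level; detected trans fractions therefore exceed planted
ones by roughly the calibrated null call rate, which is the designed
trade-off of the empirical-FDR approach.

## Differential testing and calibration

Each contrast is a two-group OLS on barcode-level log ratios with a
categorical replicate covariate; the reported effect is the raw difference
of group means and the p-value comes from the F-test of the group term.
BH q-values are computed jointly over real and null units per axis so both
live on one scale. Calibration is per axis family (cis, trans, native): a
null pseudo-pair is "called significant" the way a real pair is — through
either of the family's two models — so its unit-level q is the minimum over
the two axes. The cutoff is the largest threshold keeping the fraction of
significant null units below 0.10 (an order statistic of the null q's), and
the effect floor is the smallest |effect| among significant null results.
A real pair is significant on a model iff `q < cutoff` and
`|effect| > floor`; its assigned effect is the significant model's effect,
or the larger-|·| one when both or neither are significant (ties to the
hESC/human-sequence model).

Null pseudo-pairs traverse every axis: within-environment subsets for cis,
cross-environment disjoint subsets for trans and native (positive-control
activity is environment-independent, so these are true nulls).

## Motif scanner

PWMs are scored as log2 odds against a uniform 0.25 background on both
strands. The null distribution of the window score is computed exactly by
dynamic-programming convolution of the per-column score distributions on a
1/1000 lattice (each position contributes one of four scores with
probability 1/4); a window is a hit when its score's survival probability is
≤ 1e-4. The DP lattice null matches brute-force enumeration of all `4^w`
words to 1e-12 at small widths, and the empirical hit rate on random
sequence matches the achievable tail probability. A FIMO-style TSV is
accepted as an alternative hit source; both collapse to a per-element binary
presence matrix.

In the generator, activity motifs contribute their coefficient to every
sequence carrying them and are disrupted (planted in one pair member only)
only inside cis-effect pairs, so disruption genuinely drives sequence
divergence. Trans motifs are associational: they are planted preferentially
(probability 0.5 vs 0.1 background) in trans-effect pairs whose shift
matches the motif's direction, always in both members — this yields a
recoverable signed association without inflating the number of trans pairs.

## Redundancy and conservation

Correlations between a focal element and its TAD-co-resident enhancers
(TADs from either cell type count) are computed on `log1p` expression,
clipped to [0, 1] (the histogram the thresholding assumes; negative
correlations carry no redundancy signal), binned into 100 equal bins, and
thresholded at the bin edge maximising the between-class variance
`ω₀ω₁(μ₀−μ₁)²` with ties broken to the lowest edge. The threshold is
computed per element; enhancers strictly above it are "redundant". The
expression generator emits `expm1` of a latent Gaussian so the `log1p`
transform recovers planted correlations exactly.

Conservation calls use a closed ±50 bp window (101 positions) around the
mapped TSS on a per-position maximum-CAGE-coverage track; ≥ 10 reads
anywhere in the window means conserved, and an enhancer is conserved if
either of its two TSS windows passes. Orthology mapping itself is consumed
as a finished table, not computed.

## What the generator does not emulate

Raw reads, PCR duplicates and UMI structure; barcode sequence biases;
batch effects between replicates beyond independent NB noise;
position-specific motif grammar (planted motifs are exact consensus
insertions on a mutated common ancestor); TAD boundary differences between
cell types (both sources share one partition); and normalisation artifacts
beyond global scaling. Passing tests therefore validate the statistical
machinery against a faithful but idealised data-generating process, not
robustness to every real-data pathology.

## Problem sizes

The shipped tests run the full pipeline at 120–500 pairs with 200 null
controls, 1000 null pairs for p-value uniformity, and 100–400 observations
per linear-model recovery check; the acceptance script uses the 500-pair
default. These sizes give stable estimates of every reported quantity while
keeping a complete run in seconds.

## Other design choices

* Config validation is a plain dataclass with explicit checks; YAML configs
  reject unknown keys rather than silently defaulting.
* "Percentage of shared motifs" between pair members is the Jaccard index of
  their motif sets (symmetric, bounded, denominator well-defined).
* The mean activity entering the motif-activity model is the mean of an
  element's alphas over the environments in which it was measured.
* The DNA-representation filter (≥ 50% of barcodes at ≥ 10 counts) is
  evaluated on the single pooled input DNA library.
* Exact-zero effects with significance inherit the other effect's sign in
  compensation classification; exact double zeros are excluded.
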