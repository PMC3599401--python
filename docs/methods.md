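# Methods

This note documents the statistical model behind `dmh`, what the
synthetic-study generator does and does not emulate, the numerical
choices, and the package's known limitations.

## The measurement model

DMH produces, per probe *p* and array, two channel intensities whose raw
log ratio we model as

    M_raw = o · M_true(fragment(p), sample) + d_p + c(A_p) + ε

where *o* = ±1 is the dye orientation (tumor in channel 1 or 2), *d_p*
is a probe-specific additive dye bias (a property of the dye–probe
pair, shared across arrays), *c(A)* is a smooth intensity-dependent
trend, and ε is Gaussian noise with SD `noise_sd`. The mean log2
intensity A is modeled as a per-probe hybridization affinity drawn from
a right-skewed distribution (a Beta(2,5) scaled over a 4-log2 range
above `a_mean`), optionally with a small per-array jitter
(`a_jitter`, default 0). Making A a probe property is deliberate:
affinity is sequence-driven, replicate arrays are strongly correlated
probe-wise, and it makes the dye-swap identity exact — with zero noise,
(M_fwd − M_rev)/2 equals the true fragment M for every probe even when
curvature and dye bias are planted, because both terms enter the two
raw ratios with the same sign.

The trend is a cubic pivoted at the middle of the intensity range,
`c(A) = amp·((A − mid)/half)³`, bounded within ±amp over the support of
A, i.e. a shape a LOESS normalization is expected to remove.

## True methylation structure

True per-fragment log2 tumor/normal differences are additive:

    M_true = tumor_effect·1[tumor region]
           + dmr_effect·1[CIMP region]·1[sample CIMP+]
           + dmr_effect·1[BRAF region]·1[sample BRAF-mutant]
           + CN shift·1[sample has a loss over the fragment]

Defaults mirror the cohort the analysis was designed around: 11
wildtype + 8 mutant samples, 11 CIMP-positive with the mutation and the
phenotype co-occurring in all 8 mutants; group effect 0.8 log2; 95% of
planted group regions hypermethylated (80% for tumor regions);
copy-number losses only in wildtype samples, as contiguous intervals
covering 5–20% of the genome in 70% of wildtypes, shifting covered
fragments by N(−0.26, 0.12²) log2. The −0.26/0.12 pair reproduces the
wildtype-group moments that motivate the copy-number exclusion rule, so
the planted cut sits at −0.38.

Because the mutation and the phenotype co-occur, a region planted for
one group contrast genuinely differs between the other contrast's
groups as well (by 0.8·(8/11) ≈ 0.58 log2). Benchmark bookkeeping
therefore scores a two-group contrast against the true between-group
mean difference of the noiseless matrix: such cross-contrast regions
are real differences, not false positives, and only unplanted regions
count against the observed FDR. The same co-occurrence produces the
large CIMP/BRAF Venn overlap the pipeline reports.

## Normalization

Order: within-array LOESS of M on A → between-array aquantile (A only,
M untouched) → dye-swap half-difference → median per fragment. No
background correction is applied, and dye-swap pairs are combined
before modeling rather than entering the linear model as replicates.

The LOESS implementation is a grid-evaluated local polynomial with
tricube weights over the `span` nearest neighbours (default span 0.3,
4 robustness iterations), interpolated from ~300 grid points placed on
A-quantiles plus a uniform mesh (so sparse intensity tails are not
bridged linearly). Two choices deserve justification:

- **Local cubic basis.** Even-degree local fits lose an order of bias
  at the support boundary; against a cubic intensity trend, local
  linear and local quadratic fits both leave boundary residuals of a
  few times 0.01 log2 that no probe count repairs. An odd-degree
  (cubic) basis keeps its interior bias order at the boundary and
  absorbs the strongest trend a scanner produces. With `span=1` on
  linear data the fit still reduces exactly to ordinary regression.
- **Guarded bisquare robustness.** Residuals are reweighted by the
  bisquare of r/(6·median|r|), which keeps strong differential signals
  from bending the trend. Bisquare presumes minority contamination; on
  near-noiseless data the median residual collapses and the rule would
  discard most points, so reweighting is skipped whenever it would
  down-weight more than 30% of probes.

With these defaults a noise-free experiment with planted dye bias and
curvature is recovered to ~1e-4 max absolute error end to end, and the
dye-swap combination alone is exact to machine precision when the
curvature is off.

## Differential testing

Per fragment, ordinary least squares against an intercept-only design
(tumor-vs-normal; the matrix already holds tumor/normal ratios) or an
intercept + group-indicator design (CIMP, BRAF). Missing entries are
handled by refitting on the available samples per missingness pattern
with reduced residual df; fragments left with d < 1 are dropped and
counted. The moderation prior (d₀, s₀²) is estimated by matching
moments of log s²: Var[log s²] ≈ mean trigamma(d/2) + trigamma(d₀/2),
inverted by Newton iteration on the monotone trigamma; when the
empirical variance does not exceed the sampling term, d₀ = ∞ and the
posterior variance is s₀² everywhere. Tests are two-sided; selection
uses BH FDR ≤ 0.01, inclusive. Parameter recovery is verified on
50,000 scaled-chi² draws (d₀ within 15%, s₀² within 5%), and null
P-values pass a KS uniformity check at 20,000 fragments.

## Annotation, classification, downstream statistics

- Overlap requires ≥20 bp against a *single* track interval (the
  stricter reading; two shorter overlaps do not sum). The relation is
  asymmetric between region and track roles, which is tested.
- Enrichment is Pearson χ², df 1, two-sided, no continuity correction:
  of the three finitely printed contingency-table P-values in the
  source analysis, two (0.000001, 0.000035) are reproduced exactly at
  the printed precision and one (printed 0.000012) computes to
  1.1488e-5 — one unit in the last printed digit, with the original
  rounding convention unknown; the corresponding CIMP H3K4me³ cell is
  consistent only with a continuity-corrected test and is excluded.
- Promoter windows default to TSS −2,000/+500 bp, strand-aware, and are
  configurable; the source analysis never defines "promoter".
- CIMP calls: positive iff ≥2 CIMP1 or ≥3 CIMP2 markers, else negative
  iff ≥2 negative markers, else undetermined; the positive rule is
  evaluated first; unknown marker states never count; contradictory
  (methylated and unmethylated) states raise. The rule system is
  verified by exhaustive enumeration of all 2¹⁵ profiles.
- Copy-number filter: per region the statistic is the median log2 ratio
  across wildtype samples; the cut is the population median minus one
  sample SD (n−1). "Below one standard deviation of the median" is
  read as m − s, the reading consistent with the rule's purpose of
  trimming the low tail; s itself as an absolute bound would be
  nonsensical for negative medians.
- Gene-set enrichment is an exact binomial upper tail with expected
  hits n_q·|set|/U. The source's pathway P-values came from a
  proprietary annotation engine whose statistic is not recoverable;
  they are not asserted numerically — only the expected-hits column
  arithmetic is.
- Mann–Whitney is one-sided (mutant > wildtype), exact by enumerating
  group assignments of pooled midranks when n₁·n₂ ≤ 400 (C(20,8) ≈
  1.3e5 assignments at the 12-vs-8 design), asymptotic with tie
  correction beyond.

## Problem sizes

The synthetic studies are scaled down from the 244k-probe array: the
main analysis run uses a 1 Mbp genome (~3,900 fragments, ~1,900
informative, ~7,000 probes, 38 scans), chosen so a complete pipeline
run takes seconds and the full validation suite minutes on one CPU.
Planted-recovery benchmarks run 10 seeds at 1.2 Mbp with copy-number
losses disabled (the loss confound is exercised separately through the
copy-number filter); null calibration uses 50 seeds of 2,000-fragment
pure-noise matrices at the fragment level, which isolates the testing
machinery from the (separately validated) preprocessing.

## What the generator does not emulate

No sequence realism beyond motif densities (no repeats, no real genome
coordinates); no PCR amplification biology of the DMH protocol; no
spatial array artifacts; chromatin tracks are fragment-anchored
Bernoulli memberships rather than real ChIP-seq peak geometry; marker
panels are generated consistent with the truth rather than from a
methylation model of the marker loci. Passing tests therefore
demonstrate correctness of the analysis machinery under the stated
measurement model — not robustness to artifacts the model excludes
(saturation, spatial gradients, probe cross-hybridization).

## Known limitations

- The dye-bias correction is the dye-swap half-difference; a
  probe-level dye-bias estimator for designs without complete swap
  pairs is not implemented (pairs are required).
- The moderation prior assumes a common d per missingness group and no
  variance trend in intensity.
- With per-array intensity jitter enabled (`a_jitter > 0`), the exact
  dye-swap identity no longer holds and normalization error grows with
  the jitter-to-density ratio at the intensity extremes.
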