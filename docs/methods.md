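# Methods

## Generative model for the synthetic experiment

Each gene g has a baseline expected count μ_g (log-normal, median 200),
a cis effect c and a trans effect t on the log2 scale, drawn per the
gene's true category with the constraints cis ⇒ t = 0, trans ⇒ c = 0,
conserved ⇒ c = t = 0. Parameterising on the log2 scale makes the two
observable ratios exact functions of the effects:

- parental means: species 1 = μ·2^(c+t), species 2 = μ, so the true
  parental log2 ratio is X = c + t;
- F1 allele split: at every ss-SNP site the species-1-allele read count
  is Binomial(depth, 2^c/(1+2^c)), so the true allelic log2 ratio is
  Y = c.

Counts are negative binomial with var = μ + α·μ², one dispersion α
shared across genes (default 0.05, a typical bulk-RNA-seq biological CV²
at n = 4 — the smallest model that yields realistic overdispersion; the
spread of parental expression across individuals is otherwise
unconstrained by the design and is exposed through this single knob).
F1 total expression is set to μ·(1+2^c)/2·2^(t/2): both alleles in a
mid-parent trans environment. This quantity only feeds the eligibility
filter, not the classification, so the choice of hybrid trans dosage is
inert to the main results.

Reciprocal-cross labels (ZO/OZ) are recorded but distribution-identical:
the model contains no genomic imprinting, matching the absence of
parental bias in the real crosses. Defaults follow the study design:
4 parental birds per species, 8 F1 hybrids, 4 ss-SNP sites per gene at
50 reads per site, effect magnitudes of 2 log2 units with random sign,
1 kb genes, 1e6-read libraries. Genotype panels emit true ss-SNP sites,
sites broken by intraspecies polymorphism (default rate 0.1 among
divergent sites), and monomorphic sites, with truth labels retained.

What the generator does **not** emulate: read-level sequencing (mapping
bias, positional coverage), gene-length variation, correlated
dispersions, linkage between genes, allelic imbalance varying across
sites of one gene, and real acoustic variability of song. Passing tests
therefore demonstrate correctness of the statistical machinery under the
stated model, not robustness to alignment artifacts in real data.

## Filters and quantification

RPKM = count·1e9/(length·library). Detectability keeps genes with
species-average RPKM ≥ 1 in either species. ASE eligibility requires
(i) ≥ 1 ss-SNP with allele counts, (ii) ≥ 5 reads at every ss-SNP site
in every F1 (a strict > 5 mode is available; the two published wordings
differ and the inclusive reading is the default), and (iii) median
RPKM ≥ 10 across all 16 individuals. Y uses a pseudocount of 0.5 on both
alleles before log2 — finite at monoallelic genes, bias vanishing with
depth; configurable.

The differential-expression contrast is a negative-binomial Wald test
written for this package: median-of-ratios size factors (robust to a
minority of strongly differential genes, where total-count scaling
shows composition bias), per-gene method-of-moments dispersion pooled
across the two groups and floored at zero, and a delta-method standard
error on the log2 fold change, var(log μ̂) ≈ (1/μ + α)/n. It differs
from shrinkage-based DE packages in having no dispersion shrinkage
toward a trend and no outlier refitting; at n = 4 with strong effects
this is conservative but calibrated (empirical FDR checked by
simulation in the test suite).

## Classification

Cis arm: one-sample two-sided Student t of the split's four Y values
against 0. Trans arm (default): two-sample pooled-variance Student t of
the 16 pairwise parental log2 ratios (each ZF individual's RPKM over
each OF individual's) against the other four Y values. The pairwise
construction gives the parental side a sample rather than a scalar; its
16 values derive from 8 birds, so the trans test's effective degrees of
freedom are optimistic — acceptable here because SGoF's binomial
meta-test, not the per-gene p-value, gates significance. The literal
alternative — testing the four Y values against the scalar X — ships as
`trans_mode="scalar-x"`.

SGoF: with n p-values, R = #{p ≤ γ} (γ = 0.05); while the one-sided
exact binomial tail Pr(Bin(n, γ) ≥ R') ≤ α for the current count R',
the smallest remaining p is declared significant. Flags are monotone in
p. Adjustment pools across genes within one test family — the cis arm
and trans arm separately, per split — since SGoF is defined over a set
of simultaneous tests.

Consensus over the 70 split categories: chi-squared goodness-of-fit of
the four counts against equiprobability (17.5 each), and Fisher's exact
test on [[n1, 70−n1], [n2, 70−n2]] for the two most frequent categories
(ties broken by the fixed order cis, trans, cis_and_trans, conserved).
Both families BH-adjusted across genes; the final call is the top
category only if both reach 0.05, else ambiguous. The chi-squared null
and the Fisher table are the simplest faithful constructions consistent
with naming the two tests and their comparands; both are isolated in
`consensus()` and easy to swap.

Degenerate inputs: zero-variance t tests return p = 1 when the means
coincide and p = 0 otherwise (flagged); genes with no evaluated splits
are ambiguous; all-zero genes in the DE test get p = 1.

## Song scoring

Syllable type centroids are mutually orthogonalised trajectories
(frames × features), so at zero noise within-type similarity is exactly
1 and between-type similarity exactly 0.5 — cleanly on either side of
the 0.595 binarization threshold, which is applied inclusively (≥) on
the [0, 1] scale. Similarity is the Pearson correlation of
time-resampled (20-frame) trajectories mapped affinely from [−1, 1] to
[0, 1]; the function is pluggable. The 2×2 window patterns are
motif = [[1,0],[0,1]] and repetition = [[1,1],[1,1]] — the only two
window patterns that uniquely encode a paired transition versus a
repeated syllable; windows slide with stride 1 and no wraparound.
Waveform synthesis (harmonic stacks per type) is optional; feature
tables are the primary song representation. Acoustic features follow
sound-analysis practice: Wiener entropy = log(geometric/arithmetic mean
of spectral power), AM from the frame derivative of log power, FM as
the angle of temporal against spectral energy change, pitch and pitch
goodness from the cepstral peak; spectrograms use a 1024-sample Hann
window at ~1 ms hop.

## Problem sizes and seeds

The benchmark analyses use 2,000 genes (500 per category) for parameter
recovery, 1,000 all-conserved genes for the null control, and 20
replicate simulations of 300 null genes for the artifact comparison —
sizes at which the binomial/NB sampling error is small against the
tested margins while a full run stays in the tens of seconds. All
randomness flows through `numpy.random.default_rng` seeded from the
config; identical config + seed reproduces outputs bit-for-bit.

## Known limitations

- The t test on 16 correlated parental ratios overstates df (see above).
- SGoF's declared-significant count is capped by the binomial critical
  excess, so with many strong effects a few true effects go unflagged;
  the 70-split consensus largely rescues these, which is visible in the
  per-category recovery rates.
- Method-of-moments dispersion at n = 4 is noisy; no shrinkage is
  applied.
- Song segmentation is amplitude-threshold based and untested against
  field recordings with noise floors.
- The pipeline classifies regulatory divergence; it does not decompose
  compensatory cis/trans interactions beyond the four categories plus
  ambiguous.
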