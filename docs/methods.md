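# Methods

This note documents the statistical model behind `methconcord`, the choices
made where the design was genuinely open, and what the synthetic cohorts do
and do not establish about real methylation array data.

## The scientific problem

Epigenetic studies of brain disorders usually measure DNA methylation (DNAm)
in accessible surrogate tissues — whole blood, saliva, buccal swabs — because
brain tissue is rarely available from living subjects. Whether a surrogate is
informative depends on how well its methylation tracks brain methylation *at
the CpG of interest, within a person*. The package quantifies that
concordance in two complementary senses and provides the supporting machinery
(probe QC, stratification by genomic context, ordination, cell-composition
adjustment) plus a generator of synthetic multi-tissue cohorts with known
ground truth, so that every stage is testable without protected human data.

## Two correlation frameworks

**Across-subject.** For each tissue, beta values are averaged over subjects
per probe; the concordance of tissues *s* and *t* is the Pearson correlation
of the two mean profiles over probes. This measures global similarity of
methylomes and is dominated by the bimodal probe-level architecture shared by
all tissues; it is therefore always high. Stratified variants recompute it on
probe subsets (genic class, regulatory context, mQTL status, gene sets).

**Within-subject.** For each probe, the Spearman rank correlation is taken
over subjects between the paired values in the two tissues. Rank correlation
is used because per-probe sample sizes are small (tens of subjects) and
beta-value distributions are bounded and often skewed. P-values:

- n ≤ 7 complete pairs: the exact permutation null — all n! pairings of the
  (average) ranks are enumerated, and the two-sided p is the fraction of
  permutations with |ρ| at least the observed (observed included). The
  enumeration conditions on the observed tie pattern.
- n > 7: the t approximation, t = ρ√((n−2)/(1−ρ²)) with df = n−2.
  This differs from the AS89-style estimates some array pipelines use in the
  deep tails, but is standard, fast, and calibrated at nominal levels (the
  test suite verifies a 5% ± 1% rejection rate under a 10,000-probe null).

Pairing is pairwise-complete per probe; probes with fewer than 5 complete
pairs or a constant vector yield null records that are excluded from summary
denominators (and counted). Family-wise control is plain Bonferroni, α/m
with m defaulting to the number of evaluable probes.

**Variable CpGs.** Most CpGs barely vary between people, so their
cross-tissue correlations are noise. Following the interpercentile-range
convention, a probe is *variable* if, after discarding values outside its
10th–90th percentile (linear-interpolation quantiles), the remaining range is
at least 0.05 beta units; the boundary is inclusive ("at least"). Summaries
can be restricted to probes variable in the peripheral tissue, the reference
tissue, or both — published analyses are ambiguous on which denominator is
meant, so both are exposed.

**Comparing dependent correlations.** Whether, say, saliva tracks brain
better than blood does is a comparison of two correlations sharing a common
variable (brain), computed on the same subjects. The package implements the
Steiger z with the Meng–Rosenthal–Rubin covariance correction:
z = (z₁ − z₂)·√((n−3) / (2(1−r_ab)h)), where z₁, z₂ are Fisher transforms of
the two brain-peripheral correlations, r_ab the peripheral-peripheral
correlation, r̄² the mean squared compared correlation,
f = min((1−r_ab)/(2(1−r̄²)), 1), and h = (1−f·r̄²)/(1−r̄²). Two-sided p from
the normal; when p underflows double precision it is floored at the smallest
positive float and is then an upper bound. Monte-Carlo calibration (trivariate
normal null, n = 50, 10,000 reps) confirms a 5% ± 1% type-I rate.

## Probe QC

Three filter rules, applied in order with first-rule attribution: (1) probe
within 5 bp of a SNP (annotation flag; supplied by the manifest/dbSNP
upstream, not recomputed); (2) unreliable detection — detection p > 0.01
(strict) in any retained sample, after an iterative greedy-cut has removed
pathologically bad probes and samples; (3) context-specific (non-CpG) probes.
The kept set is independent of rule order; only attribution depends on it.

The greedy-cut here is a defined surrogate, not a clone of any published
implementation: repeatedly remove the row or column with the highest fraction
of unreliable calls (ties broken rows-first, then lexicographically) until the
worst remaining fraction is ≤ 0.05. The test suite holds it to an
independently implemented oracle.

Sample identity is verified on the 65 genotyping (SNP) control probes, whose
betas are trimodal (≈0, 0.5, 1 for the three genotypes): Pearson similarity
over the SNP probes should approach 1 for same-subject sample pairs and be
markedly lower for unrelated pairs. Defaults flag same-subject pairs below
0.9 and different-subject pairs above 0.8; published workflows used visual
heatmap clustering, so these numeric thresholds are this package's own.

## Ordination and per-subject structure

Classical (Torgerson) MDS: square the distances, double-center, eigendecompose;
coordinates are top-k eigenvectors scaled by √λ, axis signs fixed by making
each axis's largest-magnitude loading positive. The distance metric is not
dictated by the science; Euclidean distance over filtered probes is the
default with `one_minus_r` available, and the choice is recorded in output
metadata. Paired subject-level distances (e.g. each subject's buccal-to-brain
distance) are measured in the *full-rank* embedding — all positive
eigenvalues — to avoid projection artifacts; k = 2 is for plotting only.
Per-subject concordance is the Spearman correlation across all probes between
one subject's two tissue vectors, and the distance–correlation relationship
is an ordinary least squares fit (slope, intercept, r², F with df (1, n−2)).

## Cell-composition adjustment

Bulk methylation is a mixture over cell types, so composition differences can
masquerade as (or mask) concordance. Given reference per-cell-type beta
profiles, proportions are estimated per sample by least squares constrained
to the simplex (nonnegative, sum to one), solved by nonnegative least squares
on a system augmented with a heavily weighted sum-to-one row, then
renormalised; noiseless mixtures are recovered to ~1e-6 and the solution is
verified against a brute-force grid over the simplex. Adjustment regresses
each probe on the proportions (one column dropped — the simplex makes the
full set collinear), keeps residual + probe mean, and clips to [0, 1]
(clipped-entry count logged; pre-clipping means are preserved exactly). The
per-probe R² of that regression is the "variance explained by composition";
after adjustment, re-fitting the composition model explains ≤ 1% of variance
at ≥ 95% of probes under the tested noise model. Betas (not M-values) are
adjusted; the M-value alternative would behave similarly for mid-range
probes and differ near the boundaries.

## The synthetic cohort generator

Per probe j, subject i, tissue t:

    beta_ijt = expit( logit( Σ_c w_itc · expit(μ_j + δ_cj) ) + s_j·(u_ij + e_ijt) )

- μ_j — probe base mean on the logit scale, a 50/50 mixture of N(−2.5, 1)
  and N(+2.5, 1): the familiar bimodal (hypo/hyper-methylated) architecture.
- δ_cj ~ N(0, (1.2·κ_c)²) — cell-type deviation. κ_c = 1 except the
  epithelial lineage, κ = 1.5: epithelial methylomes diverge more from the
  common baseline than leukocyte or neural lineages. This asymmetry is what
  makes the predominantly epithelial buccal tissue the worst brain surrogate
  while the leukocyte/epithelial *mixture* (saliva) is the best — mixing
  averages deviations away. A closed-form correlation calculation under
  these defaults puts the across-subject correlations near 0.89/0.87/0.83
  (saliva/blood/buccal vs brain) and 0.98/0.94/0.85 for the peripheral
  pairs, the qualitative ordering the emulated study design produces.
- w_it· — Dirichlet mixture proportions per sample. Defaults: brain
  Dir(49, 21) over glia/neuron (glia-dominated bulk tissue); blood
  Dir(95, 5) leukocyte/epithelial (nearly pure); saliva Dir(14, 6)
  (mean 0.7/0.3 with the widest spread — saliva composition genuinely varies
  between donors); buccal Dir(8, 32) (mean 0.2/0.8). Mixing happens on the
  beta scale because bulk methylation is linear in cell proportions.
- u_ij ~ N(0, σ_u²) — subject effect shared across that subject's tissues;
  the *only* source of cross-tissue correlation. e_ijt ~ N(0, σ_e²) is
  independent per tissue. The latent cross-tissue correlation is
  ρ = σ_u²/(σ_u²+σ_e²); a requested `target_rho` is converted to σ_u with
  σ_e fixed (ρ = 1 with σ_e > 0 is rejected as unattainable). Defaults
  σ_u = σ_e = 0.5.
- s_j — spread multiplier: a `variable_fraction` (default 0.5) of probes get
  s = 1, the rest s = 0.1, giving distinct variable/invariable populations
  for the interpercentile-range classifier.

Detection p-values are U(0, 0.005) for passing entries and U(0.02, 1) for
failures (per-entry failure probability 0.002 by default). SNP control
probes: per-subject genotypes Binomial(2, maf) under Hardy–Weinberg
(default maf 0.3), betas genotype/2 plus N(0, 0.02) beta-scale noise,
identical genotypes across a subject's samples.

All draws come from named substreams of one root seed, generated in
fixed-size probe blocks, so cohorts are bit-reproducible and the first k
probes are unchanged when n_probes grows.

**What the generator does not emulate:** Infinium I/II chemistry and probe-
type intensity differences, spatial/batch effects, age and sex effects,
genotype-dependent methylation (mQTL flags are annotation labels, not causal
in the simulation), and realistic linkage between annotation categories and
methylation level. Passing tests therefore demonstrate correctness of the
statistical machinery and the qualitative mixture logic — not that any real
tissue attains a particular correlation with brain.

## Problem sizes and numerical choices

Test and verification workloads use scaled designs chosen to make Monte-Carlo
error small relative to the tolerance checked: 10,000 probes for null
calibration (binomial SE ≈ 0.002 on a 0.05 rate), 5,000 probes × 50 subjects
for correlation recovery (tolerance 0.05), 10,000 replicates for type-I
calibration of the dependent-correlation test, 6,000 probes × 10 seeds for
the tissue-ordering check (an across-probe Pearson at 6,000 probes has
sampling error ≈ 0.01, far below the ordering gaps), and one full pipeline
run at 50,000 probes × 4 tissues × 21 subjects. Exact Spearman enumeration
is capped at n = 7 (5,040 permutations); beta values are clipped to
[1e-6, 1−1e-6] before logit transforms; constrained least squares uses a
sum-to-one row weight of 1000 (objective converged to ~1e-9 relative);
eigenvalues below n·ε·|λ₁| are treated as zero in MDS.

## Known limitations

- The nominal-significance critical value is derived from the two-sided
  test at the realized n per probe; no fixed |r| cutoff is hard-coded.
- Cross-platform harmonization (e.g. mixing 450K and EPIC cohorts) is out of
  scope; runs are single-platform.
- Reference-free deconvolution is not provided; composition adjustment needs
  reference profiles (for synthetic data these come from the generator truth).
- The dependent-correlation test treats the genome-wide correlation pair as
  one observation per probe set; spatial correlation among CpGs is ignored,
  as it is in the analyses this mirrors.
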