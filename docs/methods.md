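# Methods

This note records the models, assumptions, parameter choices, and numerical
conventions behind `metseed`, in the order the pipeline runs.

## Synthetic-data generators

The generators define the conditions under which the statistical machinery is
validated; they are first-class, tested code, not test scaffolding.

**Randomness.** One root seed; each generator draws from an independent
substream via `numpy.random.SeedSequence(seed, spawn_key=(stream_id,))` with a
fixed stream id per generator (cohort = 1, pairs = 2, counts = 3, driver
evidence = 4). Adding a call to one generator therefore never perturbs
another's output, and identical config + seed is byte-reproducible.

**Clinical cohort.** Defaults are calibrated to the reference cohort the
package targets: 440 subjects, 76.1% female, ages clipped to 10–45.6 years
(mean 28), 18.4% unexposed with dose 0, and exposed thyroid doses lognormal
(ln-scale μ = 4.789, σ = 1.2, giving a mean near 247 mGy) clipped to
[11, 8800] mGy. Driver categories are drawn at the observed 428-tumor mix
(BRAF mutation 45.3%, other mutation 13.6%, RET fusion 17.1%, other RTK
fusion 15.0%, other fusion 9.1%). cLNM arises from one of two truth models:
*logistic* — per-category log-odds at the observed per-driver cLNM
frequencies, with optional sex/age terms (default 0 so the marginals match
the calibration frequencies); or *eor* — odds = baseline·(1 + θ₁·d) with
baseline odds 0.3 and θ₁ = 1.5 per Gy on the truncated modelling dose. The
EOR truth is defined on the truncated dose so that parameter-recovery
experiments are well-specified under the same truncation convention the
fitted model uses.

**Paired met/PT variants.** Variants are placed uniformly on a miniature
genome (10 contigs × 10 Mb) and assigned one of six clone classes
(trunk-shared-clonal, shared-subclonal, and private clonal/subclonal per
sample). Clonal variants have CCF 1; subclonal CCFs are uniform on
[0.2, 0.5]. Observation: expected VAF = CCF·ρ·m / (ρ·CN + (1 − ρ)·2) with
CN = 2, m = 1, and alt reads drawn Binomial(depth, VAF) at depth 89 (the
study's mean WGS coverage); variants with zero sampled alt reads are not
emitted. Each emitted variant is seen independently by each of three callers
with sensitivity 0.95 (at least one caller guaranteed), and injected false
positives carry single-caller support at VAF ≲ 0.06, so the two-caller
consensus rule has a measurable effect. The truth record marks a pair
polyclonal iff ≥ 10 shared-subclonal SNVs were generated. What this does not
emulate: caller-specific error profiles, mapping artifacts, indels/MBS in the
paired generator, or spatial intratumor structure beyond private-clone
abundance — pipeline tests therefore validate the statistics, not caller
behavior.

**Count matrices.** Negative-binomial counts with var = μ + αμ² (default
α = 0.1, the mid range for bulk RNA-seq), lognormal gene base means (ln-mean
ln 50, ln-sd 1), lognormal relative library sizes (sd 0.25), and per-gene
batch effects (log2-sd 0.2, first level reference). Spiked genes receive a
direct tissue log2FC (the validation suite uses +3.4 and −3.6, the magnitude
of the strongest signals the method is expected to detect) on an elevated
base mean of 200, mirroring the strongly expressed loci where such fold
changes occur in practice and keeping the +1 pseudocount bias well inside the
±0.3 recovery tolerance. For conditional-adjustment experiments a latent
factor L = 3.4·tissue + N(0, 1) drives a focal gene (loading 1.0) and a
mediated block (loading 0.6) with no direct tissue term, so the mediated
genes' marginal effect vanishes once the focal gene's expression is adjusted
for, up to the focal gene's own counting noise.

## Consensus filtering and genome metrics

SSVs: kept iff ≥ 2 callers; an optional `flags` column represents upstream
artifact filters (8-oxoG, panel-of-normals, contamination) that require raw
reads and are out of scope — any non-empty flag rejects. SVs: ≥ 2 algorithms,
tumor alt reads ≥ 4, normal alt reads ≤ 1, VAF ≥ 0.05 (all bounds inclusive,
as stated), breakpoints outside exclusion regions. The hotspot exclusion list
ships empty; any BED can be supplied. Coordinates: variants 1-based (VCF),
segments/regions 0-based half-open (BED); conversion only in readers.
Filters are pure functions returning a (kept, rejected-with-reason)
partition. FGA merges overlapping segments per chromosome (interval union)
before summing, which keeps the fraction ≤ 1 and avoids double counting;
a per-base bitmap oracle checks this on small genomes.

## Purity, CCF, and seeding

Purity = min(1, 2·peak VAF), where the peak is found by Gaussian KDE with an
absolute bandwidth of 0.02 on the VAF scale — narrow enough to separate a
subclonal cluster from a clonal peak 0.1 VAF away at 500 variants, wide
enough to smooth binomial noise at depth ~89. The search is restricted to
VAF ≤ 0.6 to avoid LOH/homozygous artifacts; among local maxima whose basin
of attraction holds ≥ 5% of variants, the highest-VAF peak is taken as
clonal (subclones sit below the clonal cluster). Fewer than 20 VAFs is an
error directing the user to supply a purity. QC threshold: purity ≥ 0.20
passes (the exclusion is "< 20%", so exactly 0.20 passes).

CCF uses the purity/CN-corrected expression above with defaults CN = 2,
m = 1 — appropriate for a near-diploid cohort without whole-genome
duplication; per-variant CN/multiplicity columns override the defaults.
Values above 1 arise from sampling noise; the pre-clamp value is kept in a
`ccf_raw` diagnostic column and `ccf_hat` is clamped to [0, 1]. Clonal means
`ccf_hat >= 0.6`, an exact inclusive comparison (no tolerance), so the
boundary behaves identically across the package.

Shared-variant clonality: a shared variant is "shared clonal" only when
clonal in **both** samples (config switch `both|either`). The source
convention is unstated, so this was a genuinely open choice: requiring both
routes clonality disagreements into the subclonal bin, which could in
principle inflate the shared-subclonal count, but at depth 89 and purity
≥ 0.5 a genuinely clonal trunk variant is misclassified subclonal in well
under 1% of cases (binomial VAF noise against the 0.6 boundary), so the
N ≥ 10 verdict is stable under either convention at validation scale. The
rescue rule (reclassify a private variant as shared when the other sample
shows ≥ k alt reads) is off by default (k = 0), since the upstream pipeline
filters first and the default mirrors that behavior. Seeding: polyclonal iff
shared-subclonal SNVs ≥ 10 (inclusive); otherwise indeterminate with the
private-clonal counts reported as sampling-bias evidence.

## Driver designation

Gene lists are frozen, editable TSVs packaged with the repo (no live
database queries, keeping designation deterministic). Mutation candidates
must be frameshift/missense/nonsense/splice-site in a listed gene; fusion
candidates need either partner listed. With several candidates the most
cohort-recurrent gene wins; exact recurrence ties go to the
lexicographically first gene and set `ambiguous_tie` — the tie-break is our
convention, stated rather than hidden. Symbols are uppercased before
matching; alias resolution is not attempted (documented limitation). MYC
amplification and TERT-promoter events are secondary annotations, never the
final driver.

## Association models

Dose enters models in Gy (mGy/1000) so θ₁ is "EOR per Gy", with truncation
at 1000 mGy applied on the mGy scale first; categorical analyses default to
the bins 0 / 1–99 / 100–199 / ≥ 200 mGy. Age adjusts continuously; sex as an
indicator. Logistic fits use IRLS (statsmodels) with a pre-fit
complete-separation check; ORs get Wald 95% CIs (the standard software
convention). LRT statistics are clamped at 0 and referred to the upper
chi-square tail; no multiplicity adjustment is applied to association
p-values (only the expression module uses FDR).

EOR likelihood: odds = exp(x'β)(1 + θ₁d + θ₂d²), maximized with analytic
gradients (L-BFGS-B) from a warm start at the logistic solution with θ = 0.
For a single dose term the positivity constraint is exactly a box bound
(θ > −1/d_max^k + 1e−6), enforced directly; for linear-quadratic both terms
are free and a quadratic barrier activates only if the factor approaches 0.
If the optimizer lands below the θ = 0 submodel's log-likelihood (possible
only through numerical failure) the submodel solution is returned, preserving
the nesting invariant. Profile 95% bounds for θ₁ solve
profile(θ₁) = max − χ²₁(0.95)/2 (a drop of 1.9207) by bisection to 1e−4 in
θ, re-maximizing over the remaining parameters at each probe; when the drop
is never reached inside the feasible region the lower bound is reported at
the constraint edge. Calibration at the validation scale (200 cohorts of
n = 5000, true θ₁ = 1.5/Gy; 500 null cohorts of n = 1000) shows mean
recovery within 10%, profile-CI coverage ~95%, and type-I error ~4–5%; these
sizes were chosen to keep Monte-Carlo error on the coverage estimate below
~2 percentage points while the whole suite stays interactive.

## Differential expression

Upper-quartile size factors use the linear-interpolation percentile
convention (numpy default) — the common choice in scientific software; it is
configurable in the sense that any positive per-sample factors can be
supplied. The normalization Y = log2((K+1)/s) is applied literally, with no
rescaling of s to its cohort mean: that changes Y per sample by an additive
constant which the model intercept absorbs, leaving fold changes and tests
identical. Per-gene OLS is vectorized through one shared hat matrix;
log2FC is the tissue-indicator coefficient (already in log2 units), p-values
are two-sided t with residual df, and no moderation/shrinkage is applied —
with ~175 samples per-gene variance estimates are stable. Zero-variance
genes are flagged `degenerate` and excluded from testing. BH adjustment is
the plain step-up with enforced monotonicity, cross-checked in tests against
an independent implementation. The conditional model adds the focal gene's Y
row as a covariate and drops the gene from the tested set. The miRNA path
uses median-of-ratios size factors (geometric-mean reference over genes
nonzero in every sample) and removes rows with mean **normalized** count
< 1; raw-mean filtering is available via `filter_on="raw"` since either
reading of the filter is defensible. Genes expressed in only a few samples
are tested unless degenerate (no minimum-expression filter by default).

## Pipeline

Stage outputs are manifest-tracked with SHA-256 checksums; a rerun with the
same parameter hash verifies checksums and skips, a corrupted file fails
naming the file, and a failing stage aborts naming the stage. Problem sizes
in the default config (200–440 subjects, 2–8 pairs, 400 genes) are chosen so
a full run completes in seconds; every size scales through the config.

## Known limitations

- The purity estimator assumes a detectable CN-neutral clonal peak; heavily
  rearranged genomes or purity < ~0.15 at depth 89 push the peak into the
  noise floor.
- The CCF estimator is the stated closed form, not a joint purity/ploidy
  grid search; equivalence with ABSOLUTE-style estimators is not claimed.
- Driver matching is symbol-based without alias resolution.
- The paired generator's sensitivity model is caller-agnostic; conclusions
  about specific caller stacks are out of reach by design.
- Absolute quantities from real cohorts (mutation burden levels, specific
  differentially expressed gene lists) are validated only structurally, on
  synthetic data emulating the study design.
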