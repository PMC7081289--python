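# Methods

`neofit` implements a neoepitope-based tumor-fitness score, the immune and
viral-epitope comparisons built around it, and a survival prediction-error
evaluation of the resulting patient covariates.  This note records the
models, the defaults and why they were chosen, the numerical conventions,
and what the synthetic cohorts do and do not establish.

## The fitness model

For each tumor neoepitope *s*, Smith-Waterman local alignment scores
|s,e| are computed against every peptide *e* of a viral epitope database
(BLOSUM62; affine gaps with the protein-BLAST defaults, a gap of length g
costing 11 + g).  The TCR recognition potential is the logistic
saturation

    R = Z / (1 + Z),     Z = Σ_e exp(−k (α − |s,e|))

over the hits that pass a BLAST-style e-value filter.  α (binding-curve
displacement) is the score at which a single hit yields R = 1/2; k sets
the steepness.  Defaults α = 26, k = 4.87 — the published melanoma fit of
the original fitness model, pinned so runs are reproducible; the CLI logs
the constants on every run.  The sum runs over **all** hits passing the
e-value threshold (default ≤ 10); a best-hit-only mode exists because the
upstream description of the original procedure ("the best hits … were
retained") can also be read that way.

The e-value attached to a hit of score S is the Karlin-Altschul form
`evalue = m·n·2^(−bit)`, `bit = (λS − ln K)/ln 2`, with the gapped
BLOSUM62 constants λ = 0.267, K = 0.041, m the query length and n the
total residue count of the database.  Because the database is a set of
short peptides (≤ ~10⁵ residues), the search is an exhaustive
Smith-Waterman over every entry — exact, and with no dependence on an
external BLAST: the heuristic seeding step would only risk missing the
very short, marginal alignments that matter here.  Edge-effect
corrections to m and n are deliberately omitted.

The MHC-I amplitude of a neoepitope compares mutant and wild-type binding
(ic50 in nM, smaller = stronger):

    A = (ic50_wt / ic50_mt) · (ic50_wt / max_wt)      (default)

where max_wt is the maximum wild-type ic50 among the patient's epitopes.
The second factor is a dissociation-constant bias correction that
down-weights epitopes whose wild type already binds well; the plain ratio
(`amplitude_normalization="none"`) is available because the published
description of the correction ("multiplying by the reciprocal max among
all wild type epitopes") does not fully pin down its algebra — per-patient
vs per-cohort scope, and what the reciprocal multiplies.  We chose the
per-patient reading in which the correction rescales A itself; both modes
are unit-tested, and results that depend on the choice should be checked
under both.

Per patient, the maximal clonal immunogenicity is Ϊ = max_j (R_j · A_j)
over qualifying neoepitopes (ic50_mt < 500 nM strict), and tumor fitness
is 1/Ϊ.  Patients with no qualifying epitope get Ϊ = 0 and an explicit
flag; their tumor fitness is undefined (not infinite) and they are
excluded from score-based survival grouping.  Clone labels are carried as
metadata only: the maximum is taken over epitopes, not weighted by clone
frequency.

## Admission rules

All binding-affinity thresholds are strict (`<`): 10,000 nM to remove
prediction noise, 500 nM to qualify epitopes for the fitness model,
200 nM for "strong binder" burden counts.  Neoepitopes whose mutated
positions all fall on MHC anchor residues are excluded — the side chains
at position 2 and the C-terminal position are buried in the binding
groove and invisible to the TCR, so such a mutation cannot create a
neoantigen even if it binds.  The {2, C-terminus} rule is the canonical
9-mer anchor pair generalized to lengths 8–11; the position set is
configurable because anchor usage is allele-dependent.  A patient is
called "viral-like" when at least one neoepitope simultaneously binds
below 500 nM and has a database hit with e-value < 10; we require the two
conditions on the same epitope, since a strong binder without homology
says nothing about TCR cross-reactivity.

## Immune scores and associations

CYT = √((GZMA + ε)(PRF1 + ε)) on RPKM expression, ε = 0.01 so
zero-expression samples stay finite (the measure is conventionally
reported without a pseudocount; ε only matters at zeros).  Associations
among {Ϊ, CYT, TMB, TIL burden, TIL clonality} use Spearman rank
correlation — robust to outliers and invariant to monotone normalization
choices (library-size scaling of TIL burden therefore cannot change the
result).  Missing Ϊ is handled pairwise-complete.  The significance mask
is raw p > 0.05 per pair, matching the way such matrices are usually
displayed; a Benjamini-Hochberg mode is available but off by default.

## Viral vs neoepitope binding comparison

The hypothesis "neoepitopes bind MHC-I better than the viral epitopes in
the same tumors" is encoded on ic50 ECDFs: smaller ic50 = stronger
binding, so dominance means the neoepitope ECDF lies above the viral one,
and the one-sided two-sample KS statistic is D⁺ = sup[F_neo − F_viral].
The p-value is the classical tail bound exp(−2mnD⁺²/(m+n)), capped at 1;
at the sample sizes this comparison is meant for (10³–10⁴ per arm) the
higher-order small-sample corrections are negligible, and an exact
permutation mode exists for small samples (< 50 per arm by default).
Because the two epitope sets can differ greatly in size, a subsampling
scheme draws m epitopes from each population (without replacement when
the population allows, otherwise with replacement and a warning) and
reports the rejection fraction across replicates.  Calibration of this
scheme assumes the populations are large relative to m; when a
"population" is itself a modest sample, its fixed ECDF gap adds to the
subsample noise and the nominal level is exceeded.

## Contig filtering and ORF calling

Viral-derived contigs are admitted when Shannon base entropy ≥ 1.0 bits
(homopolymer artifacts score 0; typical viral sequence ≈ 1.9), length
≥ 100 bp and read support ≥ 20 — the two count thresholds inclusive, per
their "at least" phrasing.  The entropy default is our choice; no
published value exists.  ORFs are called in all six frames as ATG-to-stop
spans (stop required; the longest ORF is reported when several share a
stop), with reverse-strand calls mapped back to forward-strand 1-based
coordinates.  The default minimum protein length is 100 aa; a strict
300-aa preset reproduces a published excision rule that conflicts with
the 100-bp contig threshold (a 100-bp contig cannot host a 300-aa ORF) —
the two thresholds are exposed separately rather than silently
reconciled.

## Survival prediction error

Model series: `reference` (intercept only — the marginal Kaplan-Meier
curve), and Cox proportional-hazards models `tmb`, `tmb_i` (TMB + Ϊ),
`cyt_tmb`, each additionally adjusted for tumor stage (ordinal integer
codes).  Positive right-skewed covariates (CYT, TMB, Ϊ, TIL burden) enter
on the log scale — the conventional scale for expression-like measures,
and the one on which a single extreme patient cannot dominate the linear
predictor — then all covariates are z-scored with the training mean/SD,
so coefficients are per-SD log hazard ratios.  A proportional-hazards
diagnostic reports the correlation of scaled Schoenfeld residuals with
event time per covariate.

Prediction error is the IPCW Brier score

    BS(t) = n⁻¹ Σ_i [ Ŝ(t|x_i)² · 1(t_i ≤ t, δ_i=1)/Ĝ(t_i⁻)
                    + (1−Ŝ(t|x_i))² · 1(t_i > t)/Ĝ(t) ]

with Ĝ the Kaplan-Meier estimator of the censoring distribution (left
limits for the event terms, the standard IPCW convention).  With no
censoring Ĝ ≡ 1 and the curve reduces exactly to the mean squared error —
a property the tests assert to machine precision.  The time grid is the
distinct event times up to the horizon t₈₀ (the 80% exit quantile), with
t = 0 prepended; the integrated Brier score is the time-normalized
trapezoidal integral over [0, t₈₀].  Grid points where Ĝ = 0 are
truncated with a warning.

Out-of-sample error uses the 0.632+ bootstrap: per model, the apparent
curve (fit and evaluate on the full cohort) and the mean out-of-bag curve
over B resamples are blended pointwise with w = 0.632/(1 − 0.368·R̂),
where R̂ = (err_oob − err_app)/(γ − err_app) clipped to [0, 1] and γ is
the no-information error computed over all (patient, prediction) cross
pairs; err_oob is capped at γ.  Ĝ for out-of-bag scoring is estimated on
the out-of-bag patients.  Resamples leaving too few events in-bag or
out-of-bag are redrawn (counted in the result).  Models are compared with
a paired Wilcoxon signed-rank test, by default over the per-resample
out-of-bag IBS values ("Wilcoxon test for IBS"); a pointwise mode pairing
the blended curves over the grid exists but is far more sensitive — the
apparent-error share of the blend always favors the larger model, so the
pointwise test can declare a pure-noise covariate "significantly better".
A cross-validated comparison repeatedly splits the cohort in half, fits
on one half, collects test-half IBS values per model, and applies the
one-sided KS test (first model's IBS distribution below the second's).

Kaplan-Meier grouping for univariable views uses the bottom/top 15%
nearest-rank quantiles (low group = ⌈0.15n⌉ smallest scores, high group
symmetric; boundary ties included on the boundary side; middle excluded),
with a standard two-group log-rank test.

## Synthetic cohorts

The generator emulates the joint structure the analysis assumes, not any
particular dataset: log-normal ic50 for neoepitopes (default
ln ic50 ~ N(6.0, 1.5²)) and viral epitopes (N(7.0, 1.5²) — one log-unit
weaker, planting the dominance direction); a 30% fraction of neoepitopes
that are single-substitution copies of database entries (driving
recognition potential and viral-likeness); ~30 neoepitopes and ~20 viral
epitopes per patient; exponential survival with baseline hazard 1/1500
per day and per-SD log hazard ratios (default β_CYT = −0.8,
β_TMB = −0.2, β_Ϊ = 0, β_stage = 0.3 — a protective cytolytic-activity
effect and a null fitness effect); independent uniform censoring with its
window solved numerically to hit the target 30% censoring rate; CYT and
TIL burden tied by a Gaussian copula whose Pearson parameter
2 sin(πρ/6) hits the planted Spearman ρ (default 0.5) exactly in
distribution; TMB as the count of generated MAF-like records (log-normal
around 120); and contigs with planted ORFs of 120–350 codons plus
homopolymer, low-entropy, short, and low-support decoys.  GZMA and PRF1
are emitted so that their geometric mean reproduces the patient's CYT
exactly.  Everything is deterministic under the config seed.

What these cohorts do **not** contain: real HLA-restricted binding
structure (ic50 is independent of peptide sequence), realistic mutation
signatures or clonal architecture, correlated censoring, or any
batch/cohort effects.  Tests passing on them establish that the
*machinery* is correct and calibrated — exact alignment scores, unbiased
coefficient recovery, nominal type-I error, the expected qualitative
model ranking under planted effects — not that the biological conclusions
transfer to any real cohort.

## Problem sizes and determinism

Default verification sizes: 1,000 random peptide pairs against the
alignment oracle; KS calibration with populations of 5×10⁴, subsamples of
500 and 200 replicates; survival-pattern recovery on n = 300 with B = 100
bootstrap iterations; coefficient recovery at n = 500 averaged over three
independent cohorts (a single realization carries sampling noise of
SD ≈ 0.06 around the planted value); copula recovery at n = 300.  All
stochastic stages take explicit integer seeds and reproduce bit-identical
results under a fixed seed.

## Known limitations

* Karlin-Altschul constants are treated as fixed inputs, not re-estimated
  for the chosen scoring scheme; e-values are therefore comparable within
  a run but approximate in absolute terms.
* The asymptotic one-sided KS p-value is the plain exponential bound; it
  is mildly anti-conservative for samples of a few hundred (the
  permutation mode is exact).
* lifelines' Efron tie handling means duplicating every patient perturbs
  Cox coefficients slightly; exact duplication invariance holds only for
  the untied partial likelihood.
* The paired Wilcoxon on out-of-bag IBS values measures generalization
  *within* the cohort; a chance association between a noise covariate and
  survival in one realized cohort can legitimately look predictive there.
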