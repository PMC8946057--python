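# Methods

## Scope and model

`cinscore` quantifies two phenotypes of chromosomal instability from
segmented somatic copy-number profiles and carries the resulting per-sample
scores through the downstream analyses of a pan-cancer study: association
with molecular features, survival, therapy response and drug sensitivity.

All scores are computed on the 22 human autosomes (GRCh37 lengths) from
integer-rounded absolute copy numbers. Ploidy is an input — the package
expects an ABSOLUTE-style per-sample ploidy (and optionally a whole-genome
doubling flag) and never re-estimates it.

**NCS (numerical complexity score).** Round the sample ploidy and every
segment copy number to the nearest integer (ties at .5 away from zero). A
chromosome counts as a whole-chromosome change when at least 75% of its
*covered* length carries an integer copy number different from the integer
ploidy; the NCS is the count of such autosomes (0–22). The 75% fraction is
taken over covered rather than assembly length because array and
sequencing segmentations never cover acrocentric arms; an assembly-length
denominator would make whole-chromosome calls unreachable on those
chromosomes.

**SCS (structural complexity score).** After rounding, contiguous
equal-copy-number segments are merged, so the score cannot depend on how
finely an upstream segmenter happened to cut a constant region. Each merged
segment of length ≥ 1 Mb whose integer copy number differs from its
chromosome's length-weighted modal copy number counts one; the SCS is the
total over autosomes. Ploidy does not enter the definition; it is used only
to break exact ties between modal states (toward the ploidy, so a 50/50
chromosome never has its backbone called aberrant; without ploidy, toward
the smaller state).

**WGII (weighted genome instability index).** Per autosome, the fraction of
covered length deviating from integer ploidy; WGII is the unweighted mean
over autosomes with nonzero coverage, stored as a fraction in [0, 1].
Chromosomes with zero coverage are excluded from the denominator.

Because NCS and WGII are ploidy-relative, a clean whole-genome doubling
(all copy numbers and the ploidy doubled) leaves both invariant — a
property test asserts this.

## Coordinates and input handling

Internal coordinates are 0-based half-open. SEG dialects (TCGA 1-based
inclusive is the default; BED-style and a log2-ratio variant are available)
are declared at the read boundary and converted once. Copy numbers are
absolute; the log2-ratio dialect converts via CN = ploidy·2^ratio and
requires per-sample ploidy at read time. Sex chromosomes and other
contigs absent from the build are dropped on read with a logged count, as
are segments with missing copy number (no imputation). Overlapping segments
within a sample and chromosome are a hard error. Segments spanning
centromeres or assembly gaps receive no special treatment: every covered
base counts equally.

## The synthetic cohort generator

The generator produces multi-cohort datasets with the statistical structure
the analysis assumes, and emits exact ground truth for every planted
quantity. Default conditions (22 cohorts × 30 samples):

| parameter | default | meaning |
| --- | --- | --- |
| `p_wgd` | linspace(0.05, 0.75) per cohort | WGD mixture across cohorts |
| `lambda_whole` / `lambda_whole_wgd` | 1.0 / 6.0 | Poisson mean whole-chromosome changes (non-WGD / WGD) |
| `struct_mean`, `struct_dispersion` | 5.0, 1.2 | negative-binomial structural event count (right-skewed) |
| `focal_length_range` | 0.3–20 Mb, log-uniform | focal event lengths, including sub-1 Mb events |
| `noise_sd` | 0.2 | segment copy-number jitter |
| `baseline_hazard`, `log_hazard_high` | 3e-4 /day, log 2 | exponential survival; doubled hazard above the cohort-median score |
| `censor_max` | 3650 days | independent uniform censoring |
| `response_slope` | −0.8 | log-odds of response per SD of score (responders have lower NCS) |
| planted alteration | TP53-like, ΔNCS 4, ΔSCS 11, 35% carriers | carrier event rates shifted before profile realisation |
| planted compounds | potent (AUC baseline 0.25) and weak (0.85), slope 0.12 | both positively score-correlated; only the potent one is potent enough to be a candidate |

A sample is built as: base ploidy 2 (4 under WGD) plus small jitter; k
chromosomes set wholly to ploidy±1 (k Poisson, capped at 20 so a couple of
autosomes always remain available for focal events); m focal events placed
without overlap, at modal±{1,2}, only on chromosomes not selected for
whole-chromosome change and covering at most 40% of any chromosome — so the
backbone remains the modal state, whole-chromosome calls cannot arise from
focal events, and the planted NCS and SCS truths are non-interacting and
exactly recoverable.

Noise is Gaussian clipped to (−0.499, 0.499): it models residual
segment-mean jitter that never flips the rounded integer state. This is
what makes the planted-event recovery exact by construction; an unbounded
noise law would flip ~1% of segments at σ = 0.2 and turn an exactness claim
into a probabilistic one.

Event placement samples a chromosome with probability proportional to its
remaining admissible start positions and then a start uniformly among them,
so placement succeeds whenever room exists. In extreme tail draws (many
whole-chromosome changes plus a large event count) an event may have no
room anywhere; it is then dropped, and the truth tables record realised
events only, keeping recovery guarantees intact. `strict_placement=True`
turns this into a hard error instead.

Planted alteration effects are stated in score units. For the structural
score only events ≥ 1 Mb count, while the focal length law also draws
shorter events, so the carrier event-rate shift is inflated by the inverse
probability of drawing a countable length; the cohort-adjusted regression
coefficient then recovers the planted ΔSCS directly. Alteration status is
drawn before profiles are realised (`generate_alterations` returns the
per-sample rate shifts that `simulate_cohort` feeds into
`generate_profiles`); this is what makes "carriers have higher scores" a
causal statement inside the generator rather than a post-hoc relabelling.

What the generator does *not* emulate: allele-specific copy number, purity
or contamination, clonal substructure, segmentation noise at breakpoints,
correlated features beyond the planted ones, and informative censoring.
Passing tests therefore demonstrate the correctness and calibration of the
pipeline's arithmetic and statistics under the stated generative model —
not robustness to the artefacts of real array or sequencing data.

## Statistical stages

*Correlation screens.* Spearman rank correlation per feature,
pairwise-complete, per cohort or pan-cancer; Benjamini–Hochberg FDR within
each screen's family (per cohort in the per-cohort mode), delegated to
`statsmodels.stats.multitest`. Constant features produce records with
missing estimates and are excluded from the FDR family. The recurrence
filter keeps features with rho ≥ 0.3 and FDR < 5% in at least seven
cohorts, counting positive correlations only; both thresholds are exposed.

*Alteration regression.* Ordinary least squares of a score on a binary
alteration indicator plus cohort fixed effects, with classical two-sided
t-tests, for every alteration with ≥ 20 samples in both the altered and
wild-type groups. The coefficient is the cohort-adjusted mean score
difference attributable to the alteration. A moderated (empirical-Bayes)
variance estimator would pool information across thousands of models;
with a single continuous response per score and ample residual degrees of
freedom the classical estimator is adequate, and its confidence intervals
are what the recovery tests check. Alterations perfectly confounded with
cohort membership (detected by projecting the indicator onto the cohort
design) are flagged and excluded from the FDR family. Hypermutated
microsatellite-instable samples can be excluded by boolean flag or by a
user-supplied score cutoff — no universal cutoff exists, so the score-based
mode requires one explicitly.

*Survival.* Samples are stratified at their cohort's median score; ties at
the median go to the low group (configurable). The two-group log-rank test
is implemented in-package in its standard chi-squared form; the univariate
Cox hazard ratio with 95% CI and the Kaplan–Meier curves (five-year
survival read at 1826 days) are delegated to `lifelines`. Stratification
uses all scored samples of a cohort, after which the comparison subsets to
records complete for the endpoint. A group with zero observed events makes
the HR unidentifiable; the result row is flagged unreliable. Note one tie
subtlety: under Efron's tie correction (the Cox fitter's convention)
duplicating every sample shifts the HR at the third decimal; the
"duplication leaves the HR unchanged" property is exact only under
Breslow's convention and is asserted at 1%.

*Therapy response.* Two-sided Wilcoxon rank-sum (Mann–Whitney) comparison
of scores between responders and non-responders, with group medians
reported. Degenerate all-tied inputs return p = 1.

*Drug screen.* Sensitivity index = 1 − min–max-normalised AUC. The min and
range are taken over the whole screen by default — one common [0, 1] scale,
so per-compound median sensitivities are comparable across compounds; a
per-compound normalisation is config-exposed since the narrower reading is
also defensible. The index is a strictly decreasing affine map of AUC, so
rank correlations against a score flip sign exactly and nothing else
changes. Candidates require FDR ≤ 5% *and* median sensitivity > 0.5;
compounds overlapping fewer than three scored cell lines are reported
untested rather than null.

## Numerical choices

- Rounding ties (x.5) go away from zero — "nearest integer" needs a fixed
  tie rule to be bit-reproducible.
- Modal-state ties break toward the integer ploidy, else the smaller state.
- The 75% whole-chromosome threshold is inclusive (≥).
- The SCS length rule is inclusive at exactly 1 Mb.
- BH-adjusted values and p-values are never clipped beyond [0, 1].
- SEG files are written with shortest-repr floats so write→read round-trips
  restore copy numbers bit-exactly.
- All randomness flows from a single integer seed through
  `numpy.random.default_rng`; fixed seed ⇒ byte-identical pipeline outputs.

## Verification design

Scores are verified against an independent oracle that rasterises every
profile to one integer per base and recomputes all three scores from first
principles, sharing no code with the implementation. The oracle runs on a
1:1000-scaled autosome build (50–250 kb chromosomes, SCS minimum scaled to
1 kb) so that tallying literally every base of 200 random ragged profiles —
coverage gaps, exact .5 ties, ragged breakpoints — stays under a minute;
the score functions take the build and length threshold as parameters, so
the scaled run exercises the identical code path as the full genome.

Simulation sizes used by the acceptance checks (chosen as the package's own
default verification budget): 200 oracle profiles; ~500 samples for exact
planted-event recovery; the default 660-sample cohort for the WGD/score
structure; 1000 null replicates per statistical stage for type-I
calibration (empirical rejection within [3.5%, 6.5%] at nominal 5%); 200
cohort replicates (n = 500, ~125 carriers) for TP53-like ΔNCS CI coverage;
300 replicates (n = 500) for hazard-ratio recovery; 20 seeded screens for
the potent/weak compound calls.

## Known limitations

- Scores are genome-build-agnostic but ship only GRCh37 autosome lengths;
  other builds must be supplied as (name, length) tables. No liftover.
- The log2-ratio dialect assumes the ratio is relative to sample ploidy;
  callers whose ratios are diploid-relative need pre-conversion.
- The alteration regression models scores as conditionally Gaussian;
  for very low-count cohorts a count model would be more faithful.
- `survival_by_cohort` fits each cohort independently; no shared baseline
  or multivariate adjustment (deliberately out of scope).
- The pipeline cache reuses a previous run only on an exact config-hash
  match, and at whole-run granularity.
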