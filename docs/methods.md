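# Methods

## The measurement model

Each token of a C1-V pseudoword contributes two 100-point midsagittal
tongue contours in raw scanner coordinates, one at the consonant
midpoint and one at the vowel midpoint. The analysis variable is the
x-coordinate of the contour's highest point (the tongue-dorsum
position on the anterior–posterior axis). If several points tie at the
maximal y, the mean of their x values is taken — a symmetric,
deterministic tie-break. The raw x convention is configurable
(`anterior_low`, the default, means x grows front-to-back;
`anterior_high` is sign-flipped on ingestion) and all internal math uses
anterior = low.

Per speaker, the vowel-midpoint positions define a linear normalization
z ↦ (z − v_min)/(v_max − v_min), so each speaker's vowel space spans
exactly [0, 1]. Consonant positions pass through the same map and are
**not clamped**: truncation would bias the regression slope toward
zero. The map cancels any per-speaker affine transform of raw
coordinates, which is the formal sense in which normalization removes
anatomy. Speakers with zero vowel range are excluded (not imputed) and
counted in the run report.

## Coarticulation degree

Coarticulation degree is the OLS slope of normalized consonant position
on normalized vowel position, computed in closed form
(slope = cov(v, c)/var(v)); a per-speaker/consonant fit requires at
least 3 tokens, and pooled fits use all rows. Slope 1 means the
consonant's dorsum fully anticipates the vowel target; slope 0 means
the consonant is immune to vocalic context.

The pooled inferential model is a Gaussian linear mixed model

    peak_c_x ~ peak_v_x * consonant + peak_v_x * cohort
               + (0 + peak_v_x : consonant | speaker)   [3 variance comps]
               + (0 + peak_v_x | word)

with treatment coding (reference consonant /b/, reference cohort K1 —
matching the direction of the reported contrasts) and "word" = the C1+V
pseudoword identity, the only word-level unit in the design. Age enters
as the categorical cohort factor (K1/K2/P1), not as continuous age,
since the pairwise cohort contrasts are the quantity of interest. The
crossed random slopes are expressed as independent variance components
in a single-group statsmodels `MixedLM`, fitted by REML (Powell search;
singular/boundary and non-convergence conditions are flagged on the
result, never fatal). Cohort and consonant contrasts on the slope are
linear combinations of fixed effects with normal-approximation p-values
by default; `p_method="residual"` substitutes a t reference with n − p
degrees of freedom. Full Satterthwaite degrees of freedom would need
the REML-variance Hessian, which the backend does not expose; this is a
known limitation, and with ~4400 observations the normal approximation
is mild.

## Behavioral scoring

Rhyme production: 1 point per target word (of 12) with at least one
correct rhyme — fluency on a few targets does not inflate the score.
Onset deletion and phoneme synthesis: correct counts of 12 items each.
Composite phonemic awareness: their sum (0–24). A missing sub-score
makes the composite missing — never silently 0 — and all downstream
statistics drop pairwise-incomplete cases. Correctness judgments
(is *Muppe* a valid rhyme of *Puppe*?) are upstream human decisions;
the package consumes pre-judged flags. Group descriptives are Welch t
tests (unequal variances, Welch–Satterthwaite df) and Pearson
correlations, both via scipy.

Two printed-source inconsistencies were resolved as follows: composite
PA is capped at 24 (12 + 12 by construction) even though one figure
caption mentions 25; the vocabulary maximum is exposed as a parameter
(default 36, consistent with the observed score range) rather than
fixed at the nominal 20-item count.

## Tensor-product smooths

Per consonant, `peak_c_x ~ intercept + f(score, peak_v_x)` with f a
tensor-product smooth. Construction:

* marginal cubic B-spline bases of rank 5 (per margin; small samples do
  not support more) on the observed range, with the exact integrated
  squared second derivative as marginal penalty (its null space is
  exactly {1, x});
* the tensor basis is reparametrized into a functional-ANOVA layout:
  linear main effects, nonlinear main effects (penalty eigenvectors
  scaled to unit curvature), a linear×linear interaction, and the
  remaining interaction block;
* every component, including the penalty null space, carries its own
  smoothing parameter (full-rank shrinkage). Smoothing parameters are
  chosen by minimizing the profiled Gaussian REML criterion (GCV
  optional) with a bounded Nelder–Mead search from a fixed start, which
  makes fits deterministic.

Because the null space is shrinkable, purely linear data yield edf ≈ 1
for the whole smooth rather than the dimension of the unpenalized
polynomial space; edf > 1 therefore directly signals nonlinearity, the
convention used in the reports. edf is tr[(XᵀX + S_λ)⁻¹XᵀX] over the
smooth's columns. Significance uses a truncated-Wald F approximation:
the Wald statistic of the smooth's coefficients restricted to its
leading edf-many eigendirections of the posterior covariance, referred
to F(r, n − edf_total). Besides the whole-smooth test, the fit reports
a *score-direction* test of the score main effect plus interaction —
the right null when asking whether skill matters at all (the
vowel-position effect is always overwhelmingly significant).

The fit refuses constant scores, fewer than 50 rows, or vowel spans
below 0.5. Prediction grids span the observed score range × [0, 1] in
vowel position; extrapolation beyond the observed score range must be
requested explicitly. Speaker-level scores repeat over tokens; an
optional per-speaker intercept exists and is off by default, keeping
the default model the plain interaction surface.

On blending-only simulations (no skill link), the surface's mean
vowel-direction gradient agrees with the pooled OLS slope, tying the
smooth back to the slope statistic; this is tested, as is agreement of
the fitted surface with an independent implementation of tensor-product
smoothing (R mgcv) on common data.

## The simulator

The generator emulates the cross-sectional study design the analysis
expects: cohorts K1 (n=10, ~4.5 y), K2 (n=13, ~5.5 y), P1 (n=18, ~7 y);
3 consonants /b, d, g/ × 6 tense vowels /i, y, e, a, o, u/ × 6
repetitions per child; two contours per token.

Articulation is gestural blending in a normalized gesture space
(0 anterior … 1 posterior): the vowel contour is a Gaussian dorsum bump
centered on the vowel target T_v, the consonant contour on
(1 − w)·D_c + w·T_v. Defaults: vowel targets i 0.05, y 0.15, e 0.30,
a 0.60, o 0.78, u 0.95 (the anterior-to-posterior ordering of the
vowel set); consonant targets d 0.20 (anterior constriction), b 0.50
(neutral — a labial has no lingual target of its own), g 0.70 (back);
base weights b 0.80, d 0.35, g 0.60, encoding coarticulatory
resistance (alveolar high, labial low). The skill link
w = w_max·(1 − γ·g(s)) with g ∈ {0, s, logistic((s − s0)/τ)} encodes
the hypothesis that proficiency lowers coarticulation degree; defaults
γ = 0.4, s0 = 0.5, τ = 0.08 (a sharp transition at the skill midpoint).
Skill is the logistic-squashed latent ability by default, so recovery
tests have a clean ground truth; linking to the realized composite PA
is an option.

Positional noise (sd 0.05 normalized units by default) is added to the
bump center *before* the per-speaker anatomy transform
(x ↦ offset + scale·x, offset ~ U(20, 40), scale ~ U(25, 35) raw
units), keeping `noise_sd` interpretable across speakers; centers are
clipped to [0, 1]. Contours are sampled on a uniform 100-point grid, so
dorsum positions are attained only up to one grid step (1/99 normalized
units, ~0.011 after the vowel-range map) — tolerances in the tests
respect this quantization.

Behavioral scores derive from a per-child latent ability (cohort means
−1.0/−0.5/+1.0, sd 0.5): rhyme and vocabulary are binomial in logistic
transforms of ability (easiness constants chosen so cohort means sit in
the realistic ranges: rhyme ≈ 8–11 of 12, vocabulary ≈ 25–32 of 36);
the two phonemic tasks share one phonemic latent factor (sd 0.8 around
ability, task-specific sd 1.0) so their population correlation is ≈ 0.9
— the documented target, mirroring the near-collinearity such task
pairs show — and kindergarten cohorts are floored at a near-zero
per-item success probability (0.01), reproducing the phonemic floor
that motivates the composite's cohort structure. The task-specific sd
was calibrated once against the 0.9 target by Monte Carlo.

Randomness uses one seed with keyed per-speaker substreams
(`SeedSequence(seed, spawn_key=(cohort, index))`), so a speaker's data
is invariant to the sizes of other cohorts and the whole dataset is a
byte-deterministic function of (config, cohort sizes, seed).

What the simulator does **not** emulate: ultrasound image formation and
tracing error (contours are ideal Gaussian bumps; an optional y-noise
knob exists but defaults to 0), temporal dynamics within segments
(only midpoints, as analyzed), probe misalignment or head movement,
token-level attrition, and any dependence of articulation on lexical
content. Passing tests therefore validate the *statistical machinery*
under the stated generative assumptions, not robustness to real imaging
artifacts.

## Problem sizes and numerical choices

The validation suite uses the study's design size where the property
concerns the design (41 speakers × 108 tokens; 20 replicate seeds for
stochastic properties, with thresholds of 18/20 for orderings and 16/20
for significance-based checks, trading strictness for robustness to
solver differences), and reduced sizes (10 speakers, 2 repetitions)
for structural unit tests. Degenerate inputs are errors, not silent
fixes: unknown consonants, skills outside [0, 1], zero vowel variance,
constant scores, missing segments (reported with the offending token
id). Zero-noise data are handled by bounded smoothing-parameter
searches (log λ ∈ [−18, 18]) and a floor on the profiled variance.

## Known limitations

* The mixed model treats the consonant-specific speaker slopes as
  independent variance components (no covariances across consonants).
* Contrast p-values use normal/residual approximations, not
  Satterthwaite.
* The smooth's shrinkage construction differs from unpenalized-null-
  space tensor smooths: edf values are comparable in spirit but not
  numerically identical to implementations without null-space
  shrinkage, which also makes its significance test approximate.
* Scores enter the smooths as speaker-level constants; within-child
  measurement error in the assessments is not modeled.
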