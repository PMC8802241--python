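# Methods

## Preprocessing into standardized trait space

Raw measurements pass through four sequential, individually recorded
transforms:

1. **Absence substitution.** Structures whose absence is a common
   polymorphism (first dorsal spine, pelvic spine, pelvic girdle) are
   recorded as 0 mm; they receive 0.1 mm so the subsequent log is defined.
   A zero in any other linear trait is an error, not a silent fix.
2. **Allometric size correction.** Each linear trait is replaced by the
   residual of ln(trait) on ln(standard length), fitted once, pooled over
   the entire dataset (a per-population option exists but is off by
   default). Count traits pass through. If all fish share one standard
   length the slope is indeterminate and the trait is mean-centered on the
   log scale instead, with a warning — downstream geometry needs only
   centered values.
3. **Fixation correction.** Gape width, snout length and head length are
   affected by how wide the mouth was fixed open (categories 0/1/2); the
   category means of the size-corrected values are removed. This is
   sequential residualization (size first, then fixation), not a joint
   model; the two give identical results when fixation category and size
   are uncorrelated, and the sequential form keeps each step invertible
   from its transform record.
4. **Standardization.** Every trait is z-scored across the full dataset
   (parents and hybrids pooled) using the sample SD (n−1 denominator, the
   default of the statistical environments this field uses). One unit of
   any trait thereafter means one grand SD.

The transform record (allometric intercept/slope, fixation category
effects, grand mean/SD per trait) is serialized so a held-out fish can be
projected into the same space.

Complete trait vectors are required for mismatch; fish with a missing
second dorsal spine (extreme outliers) or an uninflated swim bladder are
excluded up front, and all drops are logged per individual.

## Geometry

Divergence is the Euclidean distance between parental mean phenotypes;
population means are unweighted means of family means throughout, so a
family of 10 and a family of 1 count equally. Mismatch is the perpendicular
distance to the **infinite** line through the parental means, not the
segment: transgressive hybrids legitimately project beyond either parent.
When the parental means coincide within 1e-10 standardized units the line
is undefined and the distance to the parental point is returned with a
warning.

The decomposition of a generation's mean mismatch:

* dominance effect = mismatch of the generation's mean phenotype;
* variance effect = average of (individual mismatch − dominance effect),
  averaged within family first and then unweighted across families
  (default), or straight across individuals.

Under individual-level averaging the decomposition is exactly additive
(mean mismatch = dominance + variance effect) and the variance effect is
nonnegative by Jensen's inequality; both properties also hold under
family-then-population averaging because the family average is still a
convex combination.

Parental individuals deviate from their own line purely through
within-population variation; their family-then-population averaged
"mismatch" is reported per cross as the baseline against which hybrid
mismatch is judged. Pairwise (2-trait) mismatch is the same statistic
restricted to two named trait axes.

## Line-cross genetics

Per cross and trait, standardized values are regressed on an additive
index a ∈ {0 (marine parent), ½ (F1, F2), 1 (freshwater parent)} and a
heterozygosity index ζ ∈ {0 (parents), 1 (F1), ½ (F2)} with a random
intercept per family (REML). Dominance coefficients — the hybrid mean
rescaled so the marine parent is 0 and the freshwater parent is 1 — are
only computed for traits on which the parents are statistically
distinguishable (Welch t-test on individuals at α = 0.05; a family-means
option is exposed). No multiple-testing correction is applied across
traits, matching per-trait α usage. Within-family trait variances use the
sample variance per family averaged unweighted across families; singleton
families are skipped with a warning.

## Mixed-model inference

The divergence regressions model one mean value per cross × hybrid
generation:

    response ~ divergence * generation + (1 | freshwater population)

with response ∈ {mean mismatch, dominance effect, variance effect}. Each
freshwater population appears in exactly one cross, so the random intercept
is grouped by cross. Three parametrizations of the same model supply the
interaction test, the per-generation slopes with CIs, and the pooled slope.

Wald t tests use **between-within (containment) denominator df**:
coefficients constant within groups are tested against
(groups − between-coefficients) df and within-group coefficients against
(N − groups − within-coefficients). For the default 12-cross layout this
gives df = 10 for both the divergence slope and the interaction, which is
exact for this balanced between/within design. Satterthwaite or
Kenward–Roger approximations would require numerical derivatives of the
REML criterion that statsmodels does not expose; for this design all three
rules coincide. When the mixed fit is singular or fails to converge
(checked against a scale-aware SE cap, because optimizers can report
convergence at a degenerate point), the fit falls back to OLS with residual
df and a warning.

The snowball analysis counts, per cross × generation, trait pairs whose
mean hybrid pairwise mismatch exceeds the pooled parental baseline for the
same pair (one-sided Welch t-test at α = 0.05, uncorrected — an
interpretation, exposed as a parameter), then fits count ~ D and
count ~ D + D² on the identity scale and reports the added-term t-test for
the quadratic coefficient. Note the statistical caveat: D and D² are nearly
collinear over the observed divergence range (3–10), so power for the
quadratic term is intrinsically modest (~0.5 at the strongest realistic
effect with 12 crosses).

F2 trait correlations are computed within cross by default (pooling F2
fish across crosses would inflate correlations through between-cross mean
differences) and summarized as the median |r| and the percentage of pairs
with P < 0.05.

## The synthetic-data generator

`simulate_study` emulates the study design: one shared marine population
(6 families × 17 fish) and 12 crosses at divergences evenly spaced from 3
to 10 standardized units, each contributing a freshwater parental sample
(5 families × 6), an F1 generation (6 families × 5) and an F2 generation
(3 families × 20). Per cross, a random unit direction u places the
freshwater mean at D·u. Defaults:

| parameter | default | meaning |
|---|---|---|
| `sigma_parental` | 0.5 | within-family SD per trait (standardized units) |
| `family_sd` | 0.15 | family intercept SD per trait |
| `dominance_mean`, `dominance_sd` | 0.4, 0.2 | per-trait dominance coefficients (mild bias toward marine-like recessivity) |
| `h_perp` | 0.16 | F1 mean's off-line displacement per unit divergence |
| `n_effective_factors` | 1.2030 | Castle–Wright segregation knob |

Within-population SDs default well below 1 because the analysis space is
standardized to total SD 1 over a dataset whose population means span 3–10
units — unit within-population SDs would be internally inconsistent with
that space.

The F1 mean sits at the midparent plus a displacement whose perpendicular
component is rescaled to exactly `h_perp`·D, so the population-level F1
dominance effect is linear in divergence by construction; the F2 mean is
the midparent plus half that displacement (F2 heterozygosity is half the
F1's), so the F2 dominance effect is `h_perp`/2 per unit divergence. F2
trait variance gains a segregation term (D·u_t)²/(8·n_e) per trait.
`calibrate_effective_factors()` solves for n_e so the expected F2
variance-effect slope over the divergence grid hits a target (0.12 for the
shipped default), either from an isotropic delta-method approximation or a
seeded Monte-Carlo expectation of the generative model; the default was
frozen from the Monte-Carlo route.

A raw-measurement mode maps analysis-space values onto mm-scale traits
with per-trait allometric exponents against a simulated standard length
(~40 mm), fixation-posture offsets, integer counts, optional absent spines
and exclusion flags; it exists to exercise the preprocessing chain. Because
preprocessing re-standardizes each trait by its own grand SD, raw-mode
round trips preserve the ordering and approximate proportions of
divergences rather than their exact values.

### What the generator does and does not emulate

It reproduces the design's family structure, the dominance and
segregation mechanisms, and divergence-dependent variance scaling. It does
not simulate genotypes, linkage, selection, trait correlations (traits are
conditionally independent given population and family), measurement error,
or the heavy-tailed trait distributions of real meristic counts. Passing
recovery tests therefore demonstrate that the estimators do what they claim
under the stated model, not that the model captures every feature of real
stickleback data.

### Estimator bias worth knowing about

The dominance effect is the norm of an estimated mean vector, and norms of
noisy vectors are biased upward — more strongly (in relative terms) for
weakly diverged crosses, because the noise floor is divergence-independent
while the signal grows with D. At the study's sample sizes this attenuates
the estimated F1 dominance-effect slope by roughly one regression SE below
the generative value, and, because mean mismatch is concave in the off-line
offset, it pushes the F1 variance-effect slope slightly negative even
though F1 phenotypic variance is divergence-independent. The test suite
validates the estimator against a distribution-level Monte-Carlo oracle
that reproduces these sampling properties exactly, and validates the
planted slopes themselves in a low-noise configuration where the bias
vanishes.

## Numerical choices

* Coincident-parent tolerance: 1e-10 standardized units.
* Standardization invariants enforced to 1e-8; zero-variance traits are an
  error naming the trait.
* Degenerate mixed fits are detected by non-finite or scale-implausible
  standard errors and retried with a different optimizer before the OLS
  fallback.
* Seeding: one master seed per study; per-cross child seeds derive from a
  `numpy` `SeedSequence` spawn, so adding a cross never perturbs the others.
* Problem sizes in the validation suite (replicate counts, Monte-Carlo
  sample sizes) were chosen to keep Monte-Carlo standard errors several
  times smaller than the effects being checked.

## Known limitations

* Mismatch deliberately ignores trait covariance (no Mahalanobis variant);
  the field motivation is that F2 trait correlations are weak.
* P-values for mixed models rely on the containment df rule; for severely
  unbalanced designs a parametric bootstrap would be preferable.
* The pairwise-mismatch significance rule (hybrid vs pooled-parent Welch
  test) is one reasonable operationalization among several; it is a
  parameter, not a claim.
* With 12 crosses the quadratic snowball test has modest power, so a
  non-significant quadratic term is weak evidence of linearity.
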