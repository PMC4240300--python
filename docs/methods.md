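# Methods

This note documents the models, numerical choices and design decisions
behind flankcrowd, and what the synthetic-data tests do and do not show.

## Stimulus geometry and rendering

All sizes convert between screen millimetres and degrees of visual angle by
the exact relation `deg = 2·atan(mm / (2·distance))`; at the canonical 500 mm
viewing distance the 10.5 mm glyph height subtends 1.20°.  The display is
modelled as a square pixel grid (default pitch 0.25 mm/px, configurable);
glyph rasters are signed-contrast images with background 0 and ink ±1, the
sign being the polarity.  This representation makes reverse-polarity
composites attenuate naturally: opposite-sign ink cancels in a per-pixel
average.

Glyphs come from a deterministic 5×7 dot-matrix font defined in source
(A–Z, digits 2–9) upscaled by integer nearest-neighbour replication, plus
equilateral triangle outlines at 0°/120°/240° whose height and stroke width
match the letters.  The font is deliberately simple — identical rasters on
every platform — and swappable via the renderer's `font_table` argument.
Anti-aliased or outline-font rendering is out of scope.  Flanked arrays are
composed ink-aware: the edge-to-edge blank gap between neighbouring ink
bounding boxes equals the requested gap (0.1° condensed, 1.0° spaced) to
within one pixel.  Arrays must fit the 6.4° × 2.9° fixation box (3.2° wide
for unflanked letters); overflow is an error, not a silent crop.

## Pixel-overlap similarity

The similarity of two rasters is a fuzzy Jaccard index on ink magnitude,
`Σ min(|A|,|B|) / Σ max(|A|,|B|)`, computed after zero-padding to a common
canvas and integer centre-of-mass alignment (ties rounded toward the zero
shift).  Rationale for each choice:

* *Jaccard normalisation* bounds scores in [0, 1], makes them symmetric and
  size-invariant, and reduces exactly to intersection-over-union on binary
  masks; the raw intersection mass is available as an alternative metric.
* *min/max fuzzy operators* extend the metric to the non-binary composites
  produced by averaging (ink magnitudes ⅓, ⅔, 1).
* *Alignment* removes position as a similarity cue — letter identity, not
  placement, is the construct — and is disabled in oracle comparisons.
* *Polarity* enters only through composite formation; the metric itself sees
  |contrast|, so a reverse-polarity array influences scores via its
  attenuated composite, not via a sign convention in the metric.

Perceptual confusability norms and filter-bank image descriptors are
explicitly not modelled.

## Error taxonomy, trimming, indices

Flanked trials partition into correct / Type A (no response) / Type B
(flanker named) / Type C (any other permitted letter); the classification is
order-invariant in the flankers and rejects symbols outside the permitted
alphabet.  Latency analysis is two-stage: stage 1 drops latencies of
erroneous, prompted or distracted trials; stage 2 computes each
participant's mean and sample SD (n−1 denominator) once — no iterative
re-trimming — and drops latencies beyond 2 SD.  A conservation ledger
(removed₁ + removed₂ + retained = total) accompanies every run, and
participants with fewer than two surviving latencies skip stage 2 and are
flagged.  Latencies enter linear models as reciprocal rates (1000/ms), which
stabilises the residual distribution.  A prompt marks the trial's latency
invalid but its accuracy is retained, except in the crowding indices, which
count unprompted first responses only.

Crowding indices are **raw correct-count differences** (not percentages):
spaced − condensed within the shape task, the digit task and both combined,
and reverse − same polarity overall and in the condensed condition only.  A
missing task yields a missing index, never zero.  Behavioural covariates are
standardised to 0–100 anchored at the observed patient minimum and maximum;
domain composites are means of standardised member tests; a constant score
vector is an explicit error.

## The crossed random-intercepts logistic model

Each Type B/C error trial expands to one row per candidate letter — the
permitted alphabet minus the trial's target, since reporting the target
would not be an error; the flankers remain candidates so flanker naming is
predictable.  The outcome marks the reported letter and the fixed effects
are the model's similarity features (Model 1 `sim_avg`; Model 2 `sim_left`,
`sim_right`; Model 3 adds `sim_target`).  Random intercepts on participant
and on candidate letter are *crossed*, so the marginal likelihood does not
factor by cluster; it is evaluated by a single joint Laplace expansion
around the penalised-likelihood mode over all random effects, found by
damped Newton iterations exploiting the arrow-free two-factor structure of
the Hessian (diagonal blocks from per-level weight sums, a participant ×
letter cross block).  The outer optimisation over fixed effects and the two
log-SDs uses L-BFGS-B from fixed starts (coefficients 0, variances 1), with
the log-SDs bounded in [−6, 3]; fits are deterministic.  Wald standard
errors condition on the estimated variance parameters (the Schur complement
of the joint (β, u) information at the mode), the convention of standard
mixed-model software; p-values are two-sided normal.  Quasi-separation
(a coefficient drifting past 10) triggers a warning and a ridge-penalised
(λ = 10⁻³) refit flagged on the results object.

**Accuracy of the Laplace approximation.**  Against exhaustive
tensor-product Gauss–Hermite integration on small crossed designs the
Laplace log-likelihood agrees to ~10⁻⁵ at random-effect SD 0.05, ~10⁻⁴ at
0.1, ~6×10⁻⁴ at 0.15, degrading roughly as SD⁴ (≈0.006 at 0.3, ≈0.02 at
0.5 on 30-row designs).  The test suite asserts 10⁻³ agreement in the
near-Gaussian regime (SD ≤ 0.15), where any error in the mode search,
curvature or normalising constants is visible, and loose agreement beyond.

**Model comparison.**  Both accounts predict *positive* similarity effects,
so "support" means a significantly positive coefficient at α = 0.05:
averaging via Model 1's `sim_avg`, substitution via any individual-flanker
term in Models 2–3.  When both reach significance the verdict goes to the
larger Wald z; both flags are always reported.  A caveat the comparison
cannot escape: flanker ink is part of the composite, so under genuine
substitution `sim_avg` is also significant — the discriminating signal is
the flanker terms and the relative strength of evidence, and the package
reports it that way.  The candidate-expansion construction itself (chosen
vs. not-chosen per candidate letter) is the package's reading of "predicting
error identity and frequency"; per-letter aggregate counts would be an
alternative, and the design tables are exported so either can be inspected.

## The synthetic cohort generator

The generator exists to give the analysis code data with the structure it
assumes, with known ground truth.  Per flanked trial a crowding strength

`s(gap, polarity) = max(0, 1 − gap/critical_spacing)^k · (ρ if reverse polarity)`

multiplies three mechanism weights into event probabilities: masking
(→ no response), substitution (→ a flanker named; non-letter flankers map to
the most similar permitted letter, since participants answer with letters),
averaging (→ an integration error), else a correct response.  Functional
form notes:

* The linear ramp (k = 1) between gap 0 and the critical spacing is the
  simplest monotone choice given that only two gaps are ever probed; the
  exponent is configurable.  The default central critical spacing of 1.2°
  places the condensed gap (0.1°) deep inside and the spaced gap (1.0°) near
  the edge of the interference zone, reproducing the condensed ≪ spaced
  accuracy ordering.  The classical Bouma fraction (0.5 of eccentricity) is
  carried on the parameter object for peripheral-target configurations.
* ρ (default 0.5) implements the reverse-polarity release from crowding.
* **The averaging channel names a letter *not* present in the array**,
  sampled ∝ exp(β_avg · similarity to the averaged composite) with
  β_avg = 4.  This is the package's operationalisation of feature
  integration: a pooled percept is named as a letter *combining* target and
  flanker features, whereas a verbatim flanker report is the signature of
  the substitution channel (and a target report of the correct channel).
  Without this restriction the two mechanisms are partially confounded by
  construction — flankers top the composite-similarity ranking because their
  ink is in the composite — and the Type B proportion no longer tracks the
  substitution weight.
* Group defaults: the PCA-like group engages crowding on 30% of maximally
  crowded trials, split ~evenly across masking/substitution/averaging
  (condensed accuracy ≈ 72–74%, overall flanked error rate ≈ 15%, roughly
  balanced Type A/B/C on letter-flanker tasks); the tAD-like group is near
  ceiling (weights summing to 0.01); controls never err on flanked trials.
  A lognormal participant frailty (SD 0.3) scales mechanism engagement.
* Latencies are base + crowding-cost·s + lognormal noise (scale 150 ms,
  σ = 0.6), with scale-5 outlier contamination at probability 0.02; group
  bases/costs (600/1500 ms PCA-like, 400/100 tAD-like, 350/80 controls)
  give unflanked means near 0.5–0.8 s and strongly crowding-inflated
  condensed latencies in the PCA-like group.
* Task structure: 20 unflanked letters; Tasks 2–6 at 24 items each, 12
  targets (drawn without replacement) probed under both spacings with the
  same flanker pair, presented in blocks of six in an ABBA spacing order.

What the generator does **not** emulate: cognitive process detail (no
drift-diffusion latencies, no eyetracking), attentional or executive
covariate structure, item-level letter-frequency effects, learning or
fatigue across blocks, and any real-patient heterogeneity beyond a scalar
frailty.  Passing tests therefore show that the pipeline recovers planted
mechanisms and satisfies its contracts — not that the mechanisms themselves
are validated against patient data, which is unavailable here.

`simulate_error_trials` is a focused sub-generator producing only Type B/C
error trials under one pure mechanism ("averaging", "substitution" — a
flanker with probability 0.9 — or "null", uniform over non-target letters);
it drives the mechanism-recovery and calibration simulations.
`sample_design_choices` resamples responses from the candidate-expansion
model family itself and is the right tool for estimator calibration
(type-I error at β = 0; parameter recovery at β = 4, where the mean
estimate lands within a few percent of truth).  Mechanism recovery under
the integration-style averaging generator is assessed by sign and power,
not coefficient magnitude: the never-chosen flanker candidate rows
attenuate the fitted coefficient below the generating β by construction.

## Group-level contrasts

Accuracy contrasts use logistic regression, latency contrasts a linear model
on reciprocal latency with accuracy as a covariate; both take point
estimates from the ordinary (quasi-)likelihood fit and standard errors from
the participant-clustered sandwich.  The default flavour is CR0 (no
small-sample correction), with CR1 available; with one observation per
cluster CR0 reduces to HC0.  Factor-by-group interactions are optional; the
group (diagnosis) main effect always enters when several groups are present.
Near-ceiling cells can quasi-separate the logistic fit; this is detected and
warned about rather than silently reported.  Wilcoxon rank-sum and
signed-rank utilities use exact null distributions for n ≤ 25 without ties.
No multiple-testing correction is applied by default, matching the
unadjusted reporting style of the paradigm's literature; Holm adjustment is
available as a helper.

## Simulation scales

The test suite and the acceptance script keep simulations at desk scale:
mechanism recovery uses cohorts of 20 participants × 15 errors (100
replicates in the suite, 40 in the script), null calibration 500 and 300
replicates respectively on a fixed 150-trial design with resampled
responses.  These sizes put Monte-Carlo error comfortably inside the
asserted bounds (a binomial SE of ~2 points at 100 replicates for a 5–95%
rate) while each fit takes a fraction of a second.

## Known limitations

* The pixel-overlap metric is one defensible reading of "overlap in pixels";
  published figures derived from a different normalisation will differ
  numerically even where rankings agree.
* The bundled dot-matrix font is not the (unnamed) typeface of any
  particular study; similarity values are font-dependent.
* The Laplace likelihood is biased at large random-effect variances
  (documented above); with the letter/participant heterogeneity typical of
  these designs the estimated SDs are small and the bias immaterial, but
  variance components themselves should not be over-interpreted.
* Group-level Table-style means of a real cohort are not reproducible from
  synthetic data; the generator targets qualitative orderings (condensed <
  spaced, reverse-polarity advantage in the condensed condition, ceiling
  controls), not printed group statistics.
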