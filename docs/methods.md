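# Methods

## The instrument and its scoring model

SeMaS screens for patient-level barriers to chronic-disease self-management
with 27 items: self-efficacy (2 items), coping (2 items per style: problem
solving P, expressing emotions E, looking for distraction D), depression
(3), anxiety (4), locus of control (2: one internal, one external), social
support (6 subitems), perceived burden of disease (1 VAS item), and three
guidance items. Guidance items steer the choice of intervention and are
recorded verbatim, never categorised or counted as barriers.

Scoring is entirely table-driven from a declarative instrument definition
(YAML, schema v1): response scales map raw Likert codes to item scores,
constructs sum their items, and closed integer bands map sums to
no/minor/major barrier categories. Two recoding rules are notable:

- the 5-point coping scale collapses its top two codes ('often' and 'very
  often/continuously') onto the same score, so coping items still span 0–3;
- social-support responses recode as no/completely false/somewhat false → 0,
  somewhat true → 1, completely true → 2 (construct range 0–12).

Missing data: a respondent with any missing item is *not scorable* on that
construct, **except** social support, where a missing subitem means "not
applicable" and scores 0; only a fully missing social-support block is not
scorable. The burden VAS accepts one decimal place and is rounded half-up
before banding, because the bands are stated as integer intervals.

Composite categorisation:

- **Coping** uses style dominance: the argmax of the three per-style sums.
  A single dominant problem-solving style is no barrier; a single dominant
  E or D style is a minor barrier; ties (multiple dominant styles) are a
  minor barrier. Both mappings are configurable; the defaults follow the
  behaviour-change framing in which active problem-solving is the
  favourable style. If any style is not scorable the whole construct is not
  scorable (conservative; the alternative — dominance among scorable styles
  — would categorise on partial information).
- **Locus of control** is dichotomised: internal if the internal item's
  score is at least the external item's (ties break internal, configurable);
  an external orientation maps to a minor barrier by default. No published
  mapping of orientation to barrier severity exists, so this is exposed in
  the instrument config rather than hard-coded.

The anxiety and depression cut-offs belong to the source symptom
questionnaire (4DSQ) and are not republished here. The packaged default
ships placeholder bands explicitly marked `authoritative: false`
(depression 0–2/3–5/6–12, anxiety 0–3/4–7/8–16, i.e. barriers in roughly
the top three quarters of each range split at one and two quarters); any
deployment that will interpret these categories clinically must supply the
questionnaire's own cut-offs via the `external_table` rule. Item scores for
these subscales use a linear 0–4 map of the 5-point frequency scale.

One composition ambiguity is resolved in favour of the 6-subitem reading of
social support (five short-scale items plus a neighbour-support item), which
is what makes the instrument total 27 items (2+6+3+4+2+6+1+3) and the
social-support maximum 12.

## Validation statistics

- **Cronbach's alpha**: `k/(k−1)·(1 − Σ item variances / variance of item
  sums)` with sample (n−1) variances, on complete cases per construct.
  Undefined (with a reason) for zero total variance or fewer than two
  complete cases. For the locus dichotomy, alpha is computed over its two
  items; heterogeneous or opposed items can legitimately push it to ≈ 0 or
  below, which is informative, not an error.
- **PPV/NPV**: contingency table of the screener's dichotomised barrier
  flag (minor or major = barrier) against the criterion instrument's flag;
  respondents not scorable on either side are excluded and counted. A zero
  denominator yields an undefined value, never 0. Social support and burden
  have no criterion flag rule and report N.A., as in the instrument's
  published validation design.
- **Correlation**: Pearson when both sum-score vectors pass Shapiro–Wilk at
  α = 0.05, otherwise Spearman with average ranks. The normality test is
  not fixed by convention for this design; Shapiro–Wilk was chosen as the
  standard, well-powered test at n ≈ 200 and is configurable.
- **Criterion rules** are mandatory configuration: the criterion
  instruments' own barrier thresholds are licensed/unpublished, so the
  package ships only illustrative rules (generated alongside synthetic
  cohorts) that mirror the screener's banding style — proportional sum
  thresholds, style dominance over the full coping list, orientation
  comparison for locus. These are labelled illustrative wherever they
  appear.
- **Convergent validity**: each construct's flag is screened by one-way
  ANOVA on PAM-13 (retained if p < 0.05, the conventional default; the
  screen threshold is a parameter), then a forced-entry OLS regresses
  PAM-13 on the retained flags coded 1 = no barrier. Standardised betas are
  `β·σₓ/σᵧ`. Complete-case handling is pairwise for correlations and
  listwise for the regression. No multiple-testing correction is applied,
  matching the original analysis design; the report carries raw p values.

## Synthetic cohort generator

The generator exists so the full pipeline is testable without patient data.
It emulates:

- **Latent traits**: one standard-normal trait per construct family (nine:
  the seven barrier constructs with coping split into P/E/D and one shared
  locus "internality" trait), correlated via a fixed positive-definite
  matrix (anxiety–depression 0.55; self-efficacy moderately aligned with
  favourable traits; all values between |0.15| and |0.55|).
- **Item responses**: graded-threshold (ordinal probit) model — response
  category = position of `λ·trait + σ·ε` among ordered cut-points, default
  discrimination λ = 1.2 and σ = 1 on both channels. Default cut-points are
  equiprobable for a standard respondent, shifted by a per-construct offset;
  explicit per-item cut-points can be supplied. The locus external item
  loads −λ on the internality trait. Burden is continuous:
  `5 + spread·slope·trait + σ·ε`, clipped to [0,10], one decimal.
- **Criterion channel**: full-length instruments (e.g. 12 anxiety items, 18
  locus items, 14 coping items) driven by the same traits with independent
  noise; a `mirror` design replicates the screener item-for-item so that
  with zero noise the two channels agree exactly.
- **PAM-13**: `intercept + Σ coeffᵤ·(no-barrier truth)ᵤ + noise`, clipped to
  [0,100]. Defaults use the published regression estimates as effect sizes
  (self-efficacy 16.43 points, social support 6.64, …, coping 0) with
  intercept 34.5 and noise SD 12 — chosen as the study-condition defaults,
  not as a claim that the synthetic cohort reproduces the published tables.
- **Missingness**: independent per-item Bernoulli, defaults echoing the
  reported pattern (burden 0.15, social support 0.08, locus 0.06, coping
  0.04, others ≤ 0.02).
- **Prevalence**: default threshold offsets were fixed once by running
  `calibrate_prevalence` (bisection on a shared per-construct offset — or,
  for the u-shaped burden band, on its signal spread — against the
  prevalence observed in an n = 10 000 simulated cohort) at the default
  scenario targets: self-efficacy 0.18, coping 0.65, depression 0.12,
  anxiety 0.05, locus 0.55, social support 0.10, burden 0.30. These echo
  the published cohort's spread (coping and external locus common, anxiety
  rare) and are illustrative, not a reproduction.

A single seed drives all channels through independent named substreams, so
cohorts are byte-reproducible. The truth channel (traits and noiseless
barrier flags, computed by the generator's own banding arithmetic,
independent of the scoring engine) is consumed only by tests.

**What passing tests show — and don't.** The generator produces symmetric,
unimodal latent traits, independent missingness (MCAR) and a linear PAM
channel. Real questionnaire data has skewed traits, informative
missingness, response styles (acquiescence, extreme responding) and
ceiling effects; agreement of the pipeline with its oracles on synthetic
data validates the *computations*, not the instrument's clinical
performance, and the published cohort's exact PPV/NPV/alpha values are not
reproducible without the original data.

## Numerical choices and problem sizes

- Half-up rounding (`floor(x+0.5)`) everywhere a printed value is rounded:
  VAS banding, report percentages (1 decimal) and ratios (3 decimals).
- Coping/locus ties break as documented above; band intervals are closed.
- Exhaustive categorisation checks enumerate every attainable response
  combination (the largest construct, social support, has 5⁶ = 15 625).
- Monte-Carlo checks use n = 5000 for the Spearman–Brown reliability
  identity (tolerance 0.03, ≈ 4× its sampling SD), 1000 replicates for the
  ANOVA type-I error (tolerance 3 percentage points around 5%), and
  n = 1000 seeded cohorts for regression recovery (within 2 SE per
  coefficient). The Spearman–Brown check uses a fine 41-level response
  scale with linear cut-points because coarse equiprobable categorisation
  uniformises the latent scale and attenuates inter-item correlation by
  several hundredths — a property of ordinal data, not an implementation
  error; the attenuated value is what real 4-point items would show.
- Illegal codes are treated as missing and logged in lenient mode (default)
  and abort in strict mode; degenerate statistics (zero variance, empty
  denominators, sub-minimal groups) return explicit undefined results with
  reasons rather than NaNs.

## Known limitations

- The anxiety/depression default bands are placeholders (see above).
- Shipped criterion rules are illustrative; PPV/NPV computed with them
  characterise the synthetic channel, not the real criterion instruments.
- PAM-13 is consumed as a precomputed 0–100 column; its licensed scoring is
  out of scope.
- The renderer is a faithful-in-spirit redesign of the published graphic
  profile; the original figure's exact visual encoding is not reproduced.
- No test–retest reliability, longitudinal change scores, or counselling
  logic.
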