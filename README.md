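# semas

A scoring engine and psychometric validation pipeline for **SeMaS**
(Self-Management Screening), a 27-item generic questionnaire that screens
patients with chronic conditions for personal barriers to self-management in
primary care. The instrument measures seven psychosocial characteristics —
self-efficacy, coping style, depression, anxiety, locus of control, social
support and perceived burden of disease — plus three guidance items
(computer skills, functioning in groups, willingness to self-monitor), and
classifies each characteristic as **no / minor / major barrier** so a
practice nurse can see a patient's profile at a glance.

The package is for health-services researchers and instrument maintainers
who need (1) reproducible, table-driven scoring of SeMaS response data,
(2) the graphic patient profile, and (3) the standard validation toolkit for
short screening instruments — runnable end-to-end on synthetic cohorts.

## What it computes

**Scoring.** Each construct's sum score `S = Σᵢ sᵢ` over its recoded item
scores is classified by closed integer bands, e.g. self-efficacy (2 items
scored 0–3): `S ∈ [4,6]` → none, `[2,3]` → minor, `[0,1]` → major; social
support (6 subitems recoded 0/0/0/1/2): `[3,12]` / `{2}` / `[0,1]`; burden
(VAS 0–10, half-up rounded) is U-shaped: `[0,2]` and `[8,10]` are minor,
`[3,7]` none. Coping is categorised by style dominance (problem solving P,
emotions E, distraction D; single dominant P → no barrier, otherwise minor),
locus of control by the internal-vs-external dichotomy. Respondents with a
missing item are not scorable on that construct, except social support,
where missing means "not applicable" and scores 0.

**Validation.** Against full-length criterion instruments and the PAM-13
activation score (0–100):

- criterion validity: `PPV = TP/(TP+FP)`, `NPV = TN/(TN+FN)` of the barrier
  flags, plus sum-score correlations (Pearson if both vectors pass
  Shapiro–Wilk at α = 0.05, else Spearman);
- reliability: Cronbach's `α = k/(k−1) · (1 − Σσ²ᵢ / σ²ₜₒₜ)` per construct;
- convergent construct validity: univariate ANOVA screen of each
  dichotomised barrier flag on PAM-13, then forced-entry OLS
  `PAM = β₀ + Σ βᵤ·(no barrier)ᵤ + ε` reporting β, SE β, standardised β, p
  and r².

**Simulation.** A graded-threshold (ordinal probit) generator produces
correlated latent traits, Likert responses for SeMaS and the criterion
instruments, a PAM-13 channel driven by the true barrier flags, and
realistic item missingness — with a truth channel used only by tests.

## Worked example

```bash
semas simulate --seed 11 --n 80 --out demo/
semas score --responses demo/semas_responses.csv --out demo/scored/
semas profile --responses demo/semas_responses.csv --respondent r0001 --format text
```

The profile command prints (for one synthetic respondent):

```
SeMaS profile: r0001
=====================
perceived burden                 -  not scorable
self-efficacy                  6/6  [=====-------........#]  none
locus of control (internal)      1  [.............#.......]  none
anxiety                       0/16  [#...-----============]  none
depression                    0/12  [#...-----============]  none
coping style (E)               4/6  [.............#.......]  minor
social support               12/12  [==--................#]  none
guidance:
  computer skills: 3
  functioning in groups: 2
  willing to self-monitor: 2
```

Each row places the construct's sum score (the `#` marker) inside its
attainable range; `.` spans the no-barrier zone, `-` minor and `=` major.
This respondent left the burden VAS blank (not scorable, shown as a gap)
and has one barrier — a dominant expressing-emotions coping style — so
`barrier_count = 1` in `scored/profiles.csv`.

A validation run needs the criterion tables and a criterion rule set (the
simulator writes illustrative ones):

```bash
semas validate --responses demo/semas_responses.csv \
  --criterion demo/criterion_responses.csv --pam demo/pam_scores.csv \
  --rules demo/criterion_rules.yaml --out demo/report.csv
```

`report.csv` has one row per barrier construct (n, PPV, NPV, alpha,
correlation and method) plus a regression block with β, SE β, standardised
β, p and r².

## Layout

- `src/semas/instrument.py` — declarative instrument model (YAML-defined
  scales, constructs, bands, composites); packaged default under
  `src/semas/data/`
- `src/semas/scoring.py` — recoding, sum scores, categorisation, profiles
- `src/semas/render.py` — text/SVG graphic profile
- `src/semas/psychometrics.py` — PPV/NPV, alpha, correlations, ANOVA screen,
  forced-entry regression, report assembly
- `src/semas/simulate.py` — synthetic cohort generator and prevalence
  calibration
- `src/semas/io.py`, `src/semas/cli.py` — file formats, manifests, CLI

See `docs/methods.md` for the statistical model, parameter defaults and
known limitations.
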