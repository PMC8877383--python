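# Methods

## The problem

Coronary atherosclerosis is diagnosed definitively by invasive angiography,
typically summarised with the Gensini score (GS): each lesion's stenosis band
earns severity points (25% → 1, 50% → 2, 75% → 4, 90% → 8, 99% → 16, total
occlusion → 32) multiplied by a segment-importance weight (left main 5,
proximal LAD/LCx 2.5, mid LAD 1.5, RCA and most major branches 1, small or
distal branches 0.5), summed over lesions. GS = 0 means angiographically
unaffected arteries; GS ≥ 35 is taken as severe disease; 0 < GS < 35 is
called subclinical. The package's subject is a *non-invasive* composite —
the i-BIO integrated biomarker — built from carotid duplex ultrasound and
routine blood tests, intended to predict those two angiographic endpoints:
presence of any disease (GS > 0) and severe disease (GS ≥ 35).

## The i-BIO score

i-BIO is an integer point sum, range 0–17:

| component | bands → points |
|---|---|
| sex | female 0, male 1 |
| carotid ultrasound composite | CIMT > 0.9 mm → +1; plaque count ≥ 3 → +2; maximal stenosis > 45% → +4 (a 3-bit code, 0–7) |
| triglycerides (mmol/L) | < 1.7 → 0; 1.7 ≤ TG < 2.0 → 1; ≥ 2.0 → 2 |
| glucose (mmol/L) | ≤ 5.5 → 0; > 5.5–6.0 → 1; > 6.0–< 7.0 → 2; ≥ 7.0 → 3 |
| fibrinogen (g/L) | ≤ 4.0 → 0; > 4.0 → 1 |
| hsCRP (mg/L) | < 1.0 → 0; 1.0 ≤ x < 3.0 → 1; ≥ 3.0 → 2 |
| adiponectin (µg/mL) | ≥ 8.0 → 0; < 8.0 → 1 (inverted: low levels are adverse) |

The operating thresholds are total > 4 (strict) for the presence endpoint
and total ≥ 9 (non-strict) for the severity endpoint. Inputs are never
rounded before banding, and boundary equalities follow the inequality
directions above exactly. A missing component is an error, never a silent 0:
a partial total would be biased downward. The whole table lives in
`src/ibioscore/data/ibio_definition.json`; the scoring code evaluates that
file, so the score definition is auditable and versionable in one place.
Where source descriptions of the banding disagree (prose ranges written as
"1.8–1.9" style), the tabulated inequalities are treated as normative —
they are the score definition.

"Extent of carotid stenosis" is interpreted as the maximal stenosis across
carotid segments (a summed measure is the plausible alternative; maximum is
the common sonographic report and is what the record field stores).

## Gensini implementation choices

Published Gensini weight tables differ in small branches (first diagonal,
posterolateral). One table is adopted — diagonals and distal circumflex
0.5, posterolateral and posterior descending 1 — and isolated in the
editable file `src/ibioscore/data/gensini_segments.csv`. Band edges are
lower-inclusive (75.0% earns 4 points, 74.9% earns 2). Stenoses below 25%
are not scored, preserving "GS = 0 ⇔ unaffected". Duplicate lesions in one
segment keep the maximal stenosis with a warning, avoiding double-counting
an anatomical segment. A record may carry a precomputed GS instead of
lesions; if both are present and disagree beyond 1e-6 that is a hard error.

## Diagnostic evaluation

For a threshold t, subjects are called positive when score > t (presence
convention) or score ≥ t (severity convention, and the convention for ROC
points). From the 2×2 table: sensitivity = TP/(TP+FN), specificity =
TN/(TN+FP), odds ratio OR = (TP·TN)/(FN·FP). The 95% CI uses Woolf's logit
method, exp(ln OR ± 1.96·√(1/TP+1/FN+1/FP+1/TN)) — standard for 2×2 tables
and validated here by a seeded coverage simulation (93–97% empirical
coverage at true OR = 1). The p-value is the two-sided Pearson chi-square
without continuity correction; Fisher's exact test is available behind a
flag for small integer cells. Any zero cell triggers the Haldane–Anscombe
+0.5 correction to all cells, flagged in the output.

ROC curves place one point per distinct score value (non-strict calls) plus
the (0,0) and (1,1) anchors; the AUC is the trapezoidal area, which equals
the tie-corrected Mann–Whitney rank statistic U/(n₊·n₋) — that identity is
the test oracle. Threshold selection offers the Youden index
(max sensitivity + specificity − 1) and rate-constrained criteria
(maximise one rate subject to a floor on the other); ties break toward the
higher threshold, i.e. fewer positive calls. The marker direction is fixed
as high-score-positive.

### Reconstruction from printed rates

Study reports often print only sensitivity, specificity and group sizes.
`reconstruct_table` rebuilds the cells as TP = sens·n₊, TN = spec·n₋,
leaving them fractional so the printed rates are reproduced exactly; the OR
is computed on the fractional cells and only *displayed* rounded half-up to
one decimal (half-up, with binary-float noise suppressed at 12 significant
digits first — 0.84·144 is stored as 120.96000000000001 and would otherwise
corrupt the rounding). This is the rule under which all four published
operating points round to their printed ORs (7.3, 3.1, 3.1, 5.3)
simultaneously.

## Synthetic cohorts

No patient-level data are available, so the generator emulates what the
published group summaries determine, and nothing more:

* **Stratum structure.** Presets `initial` (free/subclinical/severe =
  39/73/93, n = 205) and `tested` (73/71/72, n = 216), matching the
  published margins (initial: 39/166 presence split, 112/93 severity split;
  tested: 73/143 and 144/72).
* **Blood markers** (`provenance: "reported"` in the preset files).
  Variables published as mean ± SD (TC, LDL-C, HDL-C, apoAI, apoB, glucose,
  age) are truncated normals at 0; variables published as median (Q25–Q75)
  (TG, hsCRP, fibrinogen, insulin, adiponectin, leptin) are lognormals with
  location = ln median and scale = (ln Q75 − ln Q25)/(2·0.6745). A
  two-parameter lognormal reproduces the median exactly and the quartiles
  exactly when they are log-symmetric; otherwise it preserves median and
  IQR ratio. The subclinical stratum reuses the published GS < 35 column
  (which it dominates); the corrupt adiponectin cell in one published
  margin (median printed below Q25) is never used, because strata are
  parameterised from the GS = 0 / GS < 35 / GS ≥ 35 columns only.
* **Imaging variables** (`provenance: "synthetic"`). CIMT, plaque count and
  carotid stenosis have no published per-stratum parameters. Defaults —
  CIMT normal (0.80/0.95/1.05 mm, SD 0.12/0.15/0.18), plaque count Poisson
  (0.8/2.2/3.2), stenosis truncated normal (15/35/48%, SD 15/18/20) — were
  chosen once, from the band probabilities they imply, so that the
  free-stratum mean total sits near the presence threshold (matching the
  ≈50% published specificity) and the initial-preset presence sensitivity
  falls in the 0.75–0.95 design window. They are calibration values, not
  reported data, and are flagged as such in the preset files and in every
  cohort's truth metadata.
* **Gensini score.** Drawn as 0 (free), uniform(0.5, 34.5) (subclinical) or
  35 + lognormal with median 30 (severe) — only the stratum membership is
  scientifically meaningful.
* **Independence.** Biomarkers are drawn independently within a stratum;
  the published tables contain no correlation structure to emulate. All
  marker–endpoint association therefore flows through stratum membership.
  `effect_scale` multiplies every between-stratum parameter difference
  relative to the free stratum; at 0 all strata share the free stratum's
  parameters, giving an exact null cohort (AUC ≈ 0.5, OR CIs covering 1 at
  the nominal rate) used for calibration tests.

Sampling uses numpy `SeedSequence` spawning per stratum, a fixed
alphabetical draw order over variables and a seeded final shuffle, so a
cohort is fully determined by (preset, seed, effect_scale, overrides). The
package default seed is 20220202.

**What passing tests show — and don't.** Recovery and null tests
demonstrate that the generator is calibrated to the published marginals and
that the diagnostics are unbiased under the null. Because within-stratum
correlations are absent and the imaging margins are synthetic, the
simulated operating characteristics (e.g. presence sensitivity ≈ 0.90 on
the initial preset at seed 1) characterise the simulation, not new evidence
about patients; real-data performance is represented only by the published
rates, which the reconstruction path consumes directly.

## Numerical and testing choices

* Normality gate for summary tables: Shapiro–Wilk per group at α = 0.05,
  both groups required to pass → mean ± SD with Welch's t-test; otherwise
  median (Q25–Q75) with the two-sided Mann–Whitney U. Zero-range groups
  skip the Shapiro test and take the median branch. Welch is used rather
  than the pooled-variance t-test as the safer default.
* Missing data: records lacking any i-BIO input are excluded from scoring
  and evaluation and counted in the report's audit log; no imputation.
* Marginal-recovery tests oversample each stratum ×200 and require sample
  means (medians) within 0.5·SD/√n (0.5·IQR/√n) of every reported cell,
  n being the stratum size — about seven standard errors of the oversampled
  estimator, so the check detects genuine generator bias while being
  insensitive to single-draw noise.
* Stochastic tests are all seeded; hypothesis runs derandomised.
* Problem sizes in the test suite (1,000 Woolf tables, 200 null-cohort
  replicates, 500 ROC oracle instances, ×200 oversampling) keep the whole
  suite under half a minute while leaving each check statistically sharp.

## Known limitations

* The component selection and point weights of the score are taken as
  given; the package does not re-derive them, and offers no recalibration.
* No calibration/reclassification analysis (no outcome follow-up exists to
  support it), and no SYNTAX or other angiographic scores.
* The synthetic cohorts cannot validate the published sensitivities,
  specificities, CIs or AUCs — those depend on unpublished joint
  distributions; only the reconstruction path touches the published
  operating points.
* Units are fixed to the published conventions; no unit inference.
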