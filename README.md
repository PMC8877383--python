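# ibioscore

Scoring and diagnostic evaluation of **i-BIO**, an integrated non-invasive
biomarker of coronary atherosclerosis, against angiographic **Gensini
score** endpoints — plus seeded synthetic cohorts so the whole pipeline can
be exercised without patient data.

Intended users: biostatisticians and cardiovascular researchers who want to
apply the published point score to their own tabular cohorts, audit or vary
its banding, or reproduce its published diagnostic statistics.

## The science in brief

The Gensini score (GS) summarises an angiogram: per-lesion severity points
(doubling by stenosis band: 25% → 1 … total occlusion → 32) times a
segment-importance multiplier (left main 5 … small branches 0.5), summed.
GS = 0 means unaffected arteries; GS ≥ 35 severe disease.

i-BIO is a 0–17 integer sum over seven components — sex (male = 1), a
carotid-ultrasound 3-bit composite (CIMT > 0.9 mm → +1, plaques ≥ 3 → +2,
stenosis > 45% → +4), and banded triglycerides (0–2), glucose (0–3),
fibrinogen (0–1), hsCRP (0–2) and adiponectin (0–1, low = adverse). A total
**> 4** calls presence of any coronary atherosclerosis (GS > 0); a total
**≥ 9** calls severe disease (GS ≥ 35). Performance is evaluated with ROC
curves (trapezoidal AUC ≡ tie-corrected Mann–Whitney statistic), and odds
ratios OR = (TP·TN)/(FN·FP) with Woolf 95% CIs,
exp(ln OR ± 1.96·√(1/TP + 1/FN + 1/FP + 1/TN)).

See `docs/methods.md` for the full model, parameter tables and design
choices.

## Worked example

```python
from ibioscore import IBIOInputs, ibio_total, SegmentLesion, gensini_score

gs = gensini_score([SegmentLesion("lad_prox", 50.0),
                    SegmentLesion("rca_mid", 25.0)])
print(gs.total, gs.category.label.value)      # 6.0 subclinical

b = ibio_total(IBIOInputs(
    sex="male", cimt_mm=1.0, plaque_count=3, carotid_stenosis_pct=50.0,
    tg=1.8, glucose=5.8, fibrinogen=4.2, hscrp=1.5, adiponectin=6.0))
print(b.total, b.presence_positive, b.severity_positive)  # 13 True True
```

The Gensini total is 2 pts × 2.5 (proximal LAD at 50%) + 1 pt × 1 (mid RCA
at 25%) = 6.0 — subclinical (0 < GS < 35). The i-BIO patient scores
1 (male) + 7 (all three ultrasound criteria) + 1 (TG band) + 1 (glucose
band) + 1 (fibrinogen) + 1 (hsCRP) + 1 (low adiponectin) = 13, positive at
both thresholds.

End-to-end on a synthetic cohort, from the shell:

```sh
ibio simulate --preset initial --seed 1 --out sim/
ibio evaluate sim/cohort.csv --out eval/
# presence: score > 4  sens=0.904 spec=0.538 OR=10.9 AUC=0.891
# severity: score >= 9  sens=0.613 spec=0.777 OR=5.5 AUC=0.745
```

`ibio score` emits per-patient component points as TSV; `ibio reconstruct`
recomputes odds ratios from printed sensitivity/specificity and group sizes
alone; `ibio run --config cfg.json` drives everything from one declarative
file. Each evaluation writes `report.json` (versioned schema), per-patient
`scores.tsv`, ROC point TSVs and the cohort CSV, atomically.

## Layout

| path | contents |
|---|---|
| `src/ibioscore/cohort.py` | patient records, GS categories, cohort IO, group summaries |
| `src/ibioscore/gensini.py` | Gensini banding, segment weights, per-patient totals |
| `src/ibioscore/ibio.py` | the i-BIO point table and scoring |
| `src/ibioscore/diagnostics.py` | 2×2 tables, odds ratios, ROC, threshold selection |
| `src/ibioscore/simulate.py` | seeded synthetic cohorts (presets `initial`, `tested`) |
| `src/ibioscore/pipeline.py`, `cli.py` | end-to-end runs and the `ibio` command |
| `src/ibioscore/data/` | editable score definition, segment table, cohort presets |
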