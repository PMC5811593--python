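# iarisk — image-adjusted preoperative prostate-cancer risk stratification

Preoperative risk tools for prostate cancer — UCSF-CAPRA and the D'Amico
classification — decide who is offered radical treatment and who can be
followed by active surveillance, but they use no imaging. `iarisk`
implements an *image-adjusted* (IA) stratifier that folds two
multiparametric-MRI features of the index lesion into those tools, plus the
complete time-to-event machinery needed to evaluate it against biochemical
recurrence (BCR) after radical prostatectomy.

## The model

Each patient's base risk group contributes points (low = 1,
intermediate = 2, high = 3). The lesion's apparent diffusion coefficient
(ADC, in 10⁻⁶ mm²/s; lower ADC means denser, typically higher-grade tumour)
adds

| ADC | points |
|---|---|
| > 950 | 0 |
| 800 – 950 | +1 |
| 650 – 799 | +2 |
| < 650 | +3 |

and radiological extraprostatic extension (rEPE, Likert 1–5, positive at
≥ 4) adds +2 when present. The composite score

&nbsp;&nbsp;&nbsp;&nbsp;S = base points + ADC points + rEPE points ∈ {1, …, 8}

is re-thresholded into three groups: 1–2 low, 3–5 intermediate, 6–8 high.
The construction is deliberately conservative: imaging can move a low-risk
patient all the way to high risk only when ADC < 650 *and* rEPE is positive.

Around the scoring rule the package provides:

- a **synthetic-cohort generator** whose marginals are quantile-matched to a
  published prostatectomy cohort (median PSA 8.4 ng/ml, median lesion ADC
  767, 36% rEPE-positive, ≈ 6.3% two-and-a-half-year BCR incidence) with a
  Weibull proportional-hazards recurrence process and accrual censoring;
- **endpoint derivation** (BCR = serum PSA > 0.2 ng/ml after the
  post-operative nadir), stepwise STARD-style exclusion filtering,
  Kaplan–Meier estimation, Cox proportional-hazards fitting (Breslow ties,
  Newton iteration) and backward stepwise model selection by AIC;
- **evaluation**: ROC/AUC with DeLong confidence intervals, the DeLong test
  for correlated AUCs, decision-curve analysis (net benefit), risk-group
  reallocation matrices and per-group outcome tables;
- a **CLI** (`iarisk simulate | score | evaluate | report | run`) over a
  plain-CSV cohort schema and flat TOML configs.

## Worked example

```python
from iarisk import ClinicalRecord, GleasonInfo, ImagingRecord, score_patient

clinical = ClinicalRecord(patient_id="example", age_years=62, psa_ng_ml=4.6,
                          gleason=GleasonInfo(3, 4), pct_positive_cores=25,
                          clinical_t_stage="T1c")
imaging = ImagingRecord(adc_value=629, repe_likert=4)
s = score_patient(clinical, imaging)
print(f"CAPRA score:        {s.capra} ({s.capra_group.label})")
print(f"ADC points:         {s.ia_capra.adc_points}")
print(f"rEPE points:        {s.ia_capra.repe_points}")
print(f"IA composite:       {s.ia_capra.composite_score}")
print(f"IA-adjusted group:  {s.ia_capra.adjusted_group.label}")
```

prints

```
CAPRA score:        2 (low)
ADC points:         3
rEPE points:        2
IA composite:       6
IA-adjusted group:  high
```

— a clinically low-risk patient whose MRI shows a markedly restricted
lesion (ADC 629) with probable capsular breach is escalated to the
high-risk group: base 1 + ADC 3 + rEPE 2 = 6 ≥ 6.

The full pipeline on a synthetic cohort:

```bash
iarisk simulate --n 1000 --seed 7 --out demo.csv
iarisk evaluate --input demo.csv --outdir demo_out
iarisk report  --indir demo_out
```

```
cohort: 960 analysed (70 events) of 1000 input
exclusions: {'persistent PSA': 0, 'follow-up < 180 days': 40, 'missing data': 0}

AUC (BCR within follow-up):
  capra        0.555 [0.478, 0.631]
  ia_capra     0.706 [0.643, 0.768]
  damico       0.550 [0.479, 0.620]
  ia_damico    0.710 [0.647, 0.773]
DeLong ia_capra vs capra: z = 4.07, p = 0.0000
DeLong ia_damico vs damico: z = 4.88, p = 0.0000

BCR by risk group:
  capra        low           15/195 (7.7%)
  ...
  ia_capra     low           4/199 (2.0%)
  ia_capra     high          39/265 (14.7%)
```

On cohorts where the recurrence process is truly driven by ADC, rEPE and
grade group, image adjustment raises discrimination (AUC 0.55 → 0.71 here)
and sharpens the group separation: the IA low-risk group's observed BCR
rate drops (7.7% → 2.0%) while the trimmed high-risk group's rises
(11.9% → 14.7%).

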