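# Methods

## Scoring rules

**Image-adjusted (IA) composite.** The base group's points (low 1 /
intermediate 2 / high 3) are added to the ADC-bin points (cut-offs 650, 800,
950 × 10⁻⁶ mm²/s → 3/2/1/0 points) and the rEPE points (2 if Likert ≥ 4,
else 0); the 1–8 composite is re-grouped at 1–2 / 3–5 / 6–8. Boundary
convention: the +1 bin is the closed interval [800, 950] (its label reads
"950–800"), so ADC exactly 950 or 800 earns +1; 650 earns +2 because
"less than 650" is strict. ADC exactly at 800 is the one genuinely
ambiguous boundary (the neighbouring bin label reads "799–650"); we place
it in the +1 bin and expose the cut-offs as configuration
(`RunConfig.adc_cutoffs`) so the other convention is one keyword away.
Boundaries are measure-zero for continuous ADC, so the choice cannot affect
cohort-level results.

**CAPRA.** Points: PSA (ng/ml) ≤ 6 → 0, 6.01–10 → 1, 10.01–20 → 2,
20.01–30 → 3, > 30 → 4; Gleason primary pattern 4/5 → 3, else secondary
4/5 → 1, else 0; clinical stage T3a → 1 (T1/T2 → 0); ≥ 34% positive
cores → 1; age ≥ 50 → 1. Groups: 0–2 low, 3–5 intermediate, 6–10 high.
**D'Amico.** High if PSA > 20 or Gleason sum ≥ 8 or stage ≥ T2c;
intermediate if PSA ∈ (10, 20] or Gleason sum 7 or stage T2b; else low.
Stages T3b/T3c, which appear in pathology-style staging, are accepted on
input and treated as ≥ T2c (D'Amico) and T3a-equivalent (CAPRA).

**Missing lesions.** The scoring operations require an `ImagingRecord`; a
patient with no visible index lesion has no defined IA adjustment. A cohort
wrapper that assigns 0 ADC and 0 rEPE points (no image evidence → no added
points) would be conservative, but we do not silently default: absence of
imaging is an input error at the record level.

## Biochemical-recurrence endpoint

BCR is serum PSA strictly above 0.2 ng/ml after the post-operative nadir.
The nadir is the measurement inside a configurable 28–42-day window
(default 4–6 weeks); when none falls there, the minimum over the first 90
days. A nadir at or above 0.2 flags *persistent* PSA — such patients are
excluded, not counted as events. The exclusion filter applies, in order:
persistent PSA, event-free follow-up < 180 days (180/365.25 years), missing
fields; it is idempotent and reports a per-reason tally so the cohort flow
can be reconstructed from logs.

## Survival machinery

Kaplan–Meier estimation delegates to lifelines (deaths processed before
censorings at tied times) and is reported only at observed event times.

The Cox model maximises the **Breslow-tie** partial likelihood by Newton
iteration with step-halving: gradient ∞-norm tolerance 1e-8, at most 100
iterations. Breslow was chosen over Efron because simulated event times are
continuous (ties essentially absent) and the Breslow risk-set sums reduce
to cumulative sums over the descending-time ordering, which keeps each
iteration O(n·p²). Complete separation makes the partial likelihood
monotone; the fit is then returned with `converged=False` (detected as a
coefficient drifting past |β| = 15, i.e. a hazard ratio above 3×10⁶ —
never a plausible clinical effect) rather than raising, mirroring the
warning behaviour of established survival software. Rank-deficient or
constant covariates and zero-event data are input errors.

Backward stepwise selection is **pure greedy AIC**: from the full model,
repeatedly drop the single covariate whose removal most decreases
AIC = −2 logPL + 2k, stopping when no removal decreases it; the empty model
(AIC = −2 × null log partial likelihood) is a legal endpoint. No p-value
thresholds are involved, so covariates with Wald p > 0.05 can legitimately
remain in the final model. The full trace (per-step candidate AICs, drops,
final Wald p-values) is exposed and is checked against brute-force
recomputation in the tests.

## Evaluation

AUC is the normalised pairwise concordance P(score_case > score_control) +
½ P(tie), computed through midranks (exact under heavy ties, as with
ordinal 1–8 or 0–10 markers); its variance and the paired-AUC test use the
DeLong structural components, also in the midrank formulation. The ROC
outcome is binary "BCR within observed follow-up" — no time-dependent ROC,
since the comparison of interest is a rank ordering of coarse ordinal
scores. Decision curves use NB(pt) = TP/n − (FP/n)·pt/(1−pt); ordinal
groups are placed on the probability scale via each group's Kaplan–Meier
cumulative incidence at a 2-year horizon (most recurrences occur within two
years of surgery; the horizon is configurable). Reallocation matrices are
3×3 base-vs-adjusted cross-tabulations with moved-up/down fractions.

## Synthetic cohorts

The generator's defaults are the study conditions; they are frozen in
`default_spec()` and are not tuned per analysis.

- **PSA**: lognormal, log-median ln 8.4, log-sd ln(12.0/6.1)/(2·0.6745) ≈
  0.5016 (IQR-matched).
- **ADC**: shifted lognormal, ADC = 472.22 + exp(N(ln 294.78, 0.74966²)).
  A three-parameter shifted lognormal matches the printed quartiles
  650/767/961 *exactly* in closed form (the shift solves
  (961−s)(650−s) = (767−s)²); a truncated skew-normal was tried first but
  its quantile fit degenerates to the half-normal limit and still misses
  each quartile by ~10 units.
- **Age**: normal(63.6, 5.115); **% positive cores**: 100·Beta(1.916,
  3.284), least-squares quantile fit to 21/36/50.
- **Grade groups** (195, 256, 81, 47, 12)/591 and **cT stage**
  (427, 91, 45, 17, 11, 0)/591; the printed "T3a/b 11" is assigned wholly
  to T3a. Grade groups map back to representative Gleason patterns
  (1→3+3, 2→3+4, 3→4+3, 4→4+4, 5→4+5).
- **rEPE**: logistic in centred ADC (+0.40 log-odds per −100 units) and
  grade group ≥ 3 (+0.50); the intercept is solved at sampling time by
  quadrature over the ADC marginal so the marginal positive rate is 36.2%
  regardless of overrides. The Likert rendering of a positive call is 4
  w.p. 0.65 / 5 w.p. 0.35; of a negative call 1/2/3 w.p. 0.45/0.35/0.20
  (the source summary reports only the dichotomised rate).
- **Event process**: Weibull proportional hazards,
  S(t|x) = exp(−(t/λ)^k · e^lp), shape k = 0.8 (mildly decreasing hazard —
  most recurrences occur early), linear predictor 0.3·(767−ADC)/100 +
  0.7·1[rEPE+] + 1.0·1[GG ≥ 3]. The baseline scale λ = 182.64 years was
  fixed by bisection (`calibrate_baseline_scale`, fixed internal seed) so
  the marginal 2.5-year cumulative incidence is 6.3%; the calibration
  function remains public and the frozen value is regression-tested
  against it.
- **Censoring**: uniform accrual over 4.4 years with administrative close
  at 4.7 years, i.e. censor ~ U[0.3, 4.7] — chosen to reproduce the
  reported follow-up median/IQ of 2.5 (1.5–3.7) years rather than the
  literal accrual calendar. Observed event fraction ≈ 6%.
- **Dependence structure**: PSA, age, cores, grade group and stage are
  mutually independent; only rEPE depends on ADC and grade group. No joint
  distribution is reported for the source cohort, so the dependence
  strengths are free parameters with the stated defaults. All randomness
  flows from one `numpy` Generator seeded explicitly; PSA series use a
  per-patient sub-stream derived from (seed, patient index).

**What the simulator does not emulate**: correlation of PSA/stage/cores
with grade or imaging, scanner-to-scanner ADC shifts, adjuvant therapy,
competing mortality, informative censoring, and lesion-level image content.
Passing tests therefore demonstrate the *machinery* — calibration,
estimator correctness, and the qualitative gain from informative imaging
features — not clinical performance on real patients; institutional-cohort
quantities (observed AUCs, per-group rates) are not desk-reproducible.

## Problem sizes and numerical choices

Calibration checks use n = 10 000 cohorts; parameter-recovery and
discrimination-ordering checks use 50 replicates of n = 2000; the DeLong
size check uses 200 null replicates at n = 300 — sizes at which
Monte-Carlo error is comfortably inside the asserted bands while the whole
suite runs in well under a minute. AUC/KM/stepwise estimators are verified
against independent oracles (O(n²) concordance, hand product-limit,
brute-force candidate enumeration) exactly; Cox fits are verified against
lifelines and scikit-survival to 1e-6.

## Known limitations

- The stepwise predictor set in the pipeline is preoperative + imaging
  only; histopathology-based models are out of scope.
- The "adjusted" intermediate stage of a published selection table is not
  reproduced (its co-adjustment set is unspecified); the full trace is
  exposed instead.
- Net reclassification/IDI statistics, penalised-Cox nomogram derivation,
  time-dependent ROC and ANOVA tool comparisons are deliberately not
  implemented.
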