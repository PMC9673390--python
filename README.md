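# ergrisk

Risk modelling of severe mental illness (SMI — schizophrenia or bipolar
disorder, pooled) from photopic cone electroretinogram (ERG) parameters.
`ergrisk` packages the complete decision-tool workflow as a tested, reusable
pipeline for biostatisticians and psychiatric-biomarker researchers:

1. **Cohort** — a subject-level table of group label, eight cone ERG
   parameters (a-/b-wave amplitude and latency, at a fixed 7.5 cd·s/m²
   flash and at Vmax), age, sex and pupil size. Because the original
   clinical cohort is not publicly deposited, a synthetic-cohort generator
   with the same statistical structure (301 cases / 200 controls, matched
   covariate moments, correlated Gaussian ERG features) is a first-class
   module.
2. **Model development** — stratified 80:20 split; maximum-likelihood
   logistic regression `logit P(SMI | x) = β₀ + βᵀx`; bidirectional
   AIC-stepwise term selection starting from the full model.
3. **Validation** — Brier score, Nagelkerke pseudo-R², Hosmer–Lemeshow
   calibration test and risk-decile calibration bins, leave-one-out
   cross-validation, ROC/AUC with a DeLong confidence interval.
4. **Decision curve analysis** — net benefit
   `NB(pt) = TP/n − (FP/n)·pt/(1−pt)` across threshold probabilities,
   against treat-all and treat-none, with the superiority range.
5. **Trichotomization** — two methods that insert an *uncertain* zone
   between "most likely SMI" and "most likely not SMI": two-graph ROC
   (TG-ROC, cutoffs at a preselected Se/Sp level of 0.90) and the
   uncertain-interval method (exhaustive search around the point where the
   case and control score densities intersect, keeping within-interval
   Se/Sp ≤ 0.55). Certain-zone performance is scored from the 3×2 table:
   Se = a/(a+c), Sp = d/(b+d), accuracy = (a+d)/(a+b+c+d).

## Worked example

```python
from ergrisk import (reference_config, generate_cohort, split_data,
                     stepwise_select, predict, roc_auc, decision_curve,
                     trichotomize, FULL_TERMS)

cohort = generate_cohort(reference_config(seed=3))   # 301 SMI + 200 controls
train, test = split_data(cohort, ratio=0.8, seed=1)  # 241/160 and 60/40
best = stepwise_select(train, list(FULL_TERMS))
pred = predict(best, test)

roc = roc_auc(pred)
print(f"external AUC {roc.auc:.3f} [{roc.ci_low:.3f}-{roc.ci_high:.3f}]")
lo, hi = decision_curve(pred).superior_range
print(f"net benefit superior for pt in [{lo:.2f}, {hi:.2f}]")
tg = trichotomize(pred, "tgroc", theta=0.90)
print(f"TG-ROC cutoffs [{tg.t_low:.2f}, {tg.t_high:.2f}], "
      f"Se {tg.sensitivity:.2f}, Sp {tg.specificity:.2f}")
```

prints

```
external AUC 0.882 [0.815-0.949]
net benefit superior for pt in [0.01, 0.99]
TG-ROC cutoffs [0.54, 0.86], Se 0.85, Sp 0.88
```

The AUC is the probability that a randomly chosen case receives a higher
predicted risk than a randomly chosen control; the superiority interval is
the range of decision thresholds over which acting on the model beats both
intervening on everyone and on no one; the TG-ROC line reads: scores below
0.54 are called "most likely not SMI", above 0.86 "most likely SMI", and the
certain calls achieve 85% sensitivity and 88% specificity.

The same workflow is available from the shell:

```bash
ergrisk simulate --seed 1 --out cohort.csv
ergrisk run --input cohort.csv --seed 1 --out results/
```

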