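# ventmp — mechanical power of ventilation and ICU mortality

`ventmp` is a research pipeline for studying the relationship between the
**mechanical power (MP)** delivered by pressure-controlled mechanical
ventilation and ICU mortality, and for exploring model-guided
individualization of ventilator settings. It is aimed at critical-care data
scientists who work with admission-level tables and ventilation time series
extracted from an ICU database.

## What it computes

**Surrogate mechanical power.** For pressure-controlled ventilation the
energy delivered per minute is approximated as

```
MP [J/min] = 0.098 · TV · RR · (PEEP + ΔP)
```

with tidal volume TV in liters, respiratory rate RR in breaths/min, and
PEEP + inspiratory driving pressure ΔP equal to the peak pressure in cmH2O.
MP is computed per time point from the currently-held settings, averaged as
a **time-weighted average (TWA)** over the first 24 h and 48 h of
ventilation (sample-and-hold integration), and normalized to the **ideal
body weight** (Devine: `50 + 0.91·(height − 152.4)` kg for males, 45.5
intercept for females).

**Hypoxemia-stratified safe upper limits.** Within each PaO2/FiO2-ratio
stratum (nonhypoxemic > 300, mild 200–300, moderate 100–199, severe < 100),
a one-sided Mann–Whitney test asks whether MP/IBW is stochastically greater
among nonsurvivors. Only when that test rejects at level α is a "safe upper
limit" reported: the survivors' (1−α)·100th percentile. The test is exact
(full enumeration, tie-aware) for arms of ≤ 8 observations.

**Mortality prediction.** Correlation pruning (|r| > 0.9), random-forest
top-10 feature selection on top of seven mandatory ventilation features,
SMOTE-style minority oversampling inside training folds only, and six
classifiers (logistic regression, random forest, SVM, AdaBoost, XGBoost,
stacking) under stratified 5-fold CV, with TreeSHAP attribution ranking for
the boosted-trees model.

**Closed-loop individualization.** For a patient the frozen model predicts
to die, candidate (TV, RR, ΔP) settings on a lung-protective grid
(4–8 mL/kg IBW; ΔP tied to TV through an estimated compliance; PEEP held
fixed) are fed into the model in objective order — descending minute
ventilation when respiratory acidosis is present (PaCO2 > 45 mmHg and
pH < 7.35), ascending MP otherwise — until the prediction flips to
survival.

Because the source ICU database is access-restricted, the package ships a
**synthetic cohort generator** with a configurable logistic mortality model
linking death probability to 48 h TWA MP/IBW, age, and highest lactate, so
every stage is testable end to end.

## Worked example

```bash
ventmp generate --n 500 --seed 1 --out data/
ventmp preprocess --in data/ --out work/
ventmp metrics --in work/ --out work/
ventmp limits --in work/ --alpha 0.05 --out work/
ventmp train --in work/ --folds 5 --seed 1 --out work/
ventmp individualize --in work/ --seed 1 --out work/
```

or in Python:

```python
>>> from ventmp.metrics import ibw, mechanical_power
>>> round(ibw(175, "male"), 2)          # median-height male
70.57
>>> mechanical_power(0.5, 15, 5, 15)    # TV 0.5 L, RR 15, PEEP 5, dP 15
14.7
>>> from ventmp.stats import to_absolute_mp
>>> to_absolute_mp(0.22, 70.57)         # per-kg limit at the median IBW
15.53
```

`70.57` is the ideal body weight (kg) of a 175 cm male; `14.7` J/min is the
surrogate MP of those settings (0.098 · 0.5 · 15 · 20); `15.53` J/min is
the absolute MP corresponding to a per-kg limit of 0.22 J/min/kg at that
IBW. On the synthetic demo above, `ventmp limits` prints how many
stratum × variable × window limits pass the rank-test gate, and
`ventmp individualize` reports the fraction of predicted nonsurvivors whose
prediction flips — the run above prints
`flipped 23/135 (17.0%) predicted nonsurvivors` (the exact numbers depend
on the seed and generator settings).

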