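# miprofile

Multiple imputation and random-forest classification of reading
profiles in multi-site behavioral data with missingness.

Retrospective multi-site studies of reading disability pool
standardized test scores collected under different assessment plans, so
many children are missing exactly the variables that distinguish one
reading profile from another. `miprofile` implements the full
simulation-and-classification machinery for studying that problem:

* a **synthetic cohort generator** that emulates an expert-labeled
  training sample (198 children, 8 sites; 58 Poor Decoders, 27 Poor
  Comprehenders, 14 Generally Poor Readers, 99 Controls) and a
  synthpop-style **sequential conditional synthesizer** that produces
  fresh N = 500 datasets preserving the cohort's correlational
  structure;
* a **missing-at-random mechanism** — logistic in sex and research
  site, never in the score values — inducing 0–50% missingness in 3 of
  the 6 classification-side variables, with logistic-regression
  verification (Wald/LR p-values, Nagelkerke R²);
* three competing **imputation methods**: mean replacement, multiple
  imputation by predictive mean matching (chained equations with
  donor matching), and missForest-style iterative random-forest
  imputation with the Δ stopping rule, each run as m = 10 imputations
  where applicable;
* the **random-forest profile classifier** (500 trees, mtry = 2,
  optional 5-fold × 10-repeat tuning) with consensus labels and
  per-profile mean ± SD counts across imputations;
* **Rubin's-rules pooling** with Barnard–Rubin fractional degrees of
  freedom: pooled Welch t-tests, Fisher-z-pooled correlations, one-way
  ANOVAs with η² (mean-F summary, D1 multivariate rule optional), and
  pooled profile means;
* an **experiment orchestrator** crossing missingness rates × methods
  over replicate synthetic datasets, scoring imputation *efficiency*
  (variance of the imputed column over the variance of the original
  column) and the reduction in classification accuracy, sensitivity,
  and specificity relative to each replicate's complete data, including
  the per-(profile, missing-variable) conditional accuracy analysis.

The key statistics, in the field's notation: for m imputed estimates
Q̂₁…Q̂ₘ with variances U₁…Uₘ, the pooled estimate is Q̄ = mean(Q̂ⱼ),
within-variance W = mean(Uⱼ), between-variance B = var(Q̂ⱼ), total
T = W + (1 + 1/m)B, with small-sample adjusted df
ν̃ = ν_large·ν_obs/(ν_large + ν_obs). Efficiency of an imputed variable
is E_v = Var(imputed v)/Var(original v). missForest's stopping
statistic is Δ = Σ(x_new − x_old)²/Σx_new² over imputed cells,
iterating until Δ first increases.

## Worked example

```python
from miprofile import (
    generate_profile_cohort, synthesize_dataset, default_mechanism,
    induce_mar, impute, efficiency, train_classifier, classify,
    confusion_metrics,
)
from miprofile.cohort import calibrate_separability, default_cohort_config

# calibrate the generator so the 198-row training cohort supports ~94%
# leave-one-out accuracy, then train the 500-tree classifier on it
config, loo = calibrate_separability(default_cohort_config(seed=1), 0.94)
training = generate_profile_cohort(config)
model = train_classifier(training, seed=1, tune=False, mtry=2)
print(f"LOO accuracy {loo:.3f}")

# one simulation replicate: synthesize, mask 30% MAR, impute, classify
synth = synthesize_dataset(training, n_per_profile=125, seed=2)
truth = synth.labels.to_numpy()
base = confusion_metrics(classify(model, synth), truth).accuracy
masked, mask = induce_mar(synth, default_mechanism(0.3, synth.site_levels, seed=3))
imps = impute(masked, "missforest", m=10, seed=4, ntree=20, max_iter=5)
acc = sum(confusion_metrics(classify(model, t), truth).accuracy for t in imps.tables) / imps.m
sel = list(mask.mechanism.selected_variables)
print(f"selected missing variables: {sel}")
print(f"baseline accuracy {base:.3f}, imputed {acc:.3f}, "
      f"reduction {100 * (base - acc):.2f} points")
print(f"efficiency of selected variables: {efficiency(imps, synth)[sel].mean():.3f}")
```

Output from this exact script (seeds included):

```
LOO accuracy 0.939
selected missing variables: ['passage_comp', 'verbal_iq', 'ran']
baseline accuracy 0.876, imputed 0.835, reduction 4.10 points
efficiency of selected variables: 0.946
```

The calibrated cohort reproduces the ~94% leave-one-out anchor. On
this single replicate — with 30% of passage comprehension, verbal IQ,
and rapid naming missing at random — missForest imputation costs about
4 points of classification accuracy while the imputed variables retain
~95% of their original variance; averaged over 100 replicate datasets
(as `scripts/acceptance.py` does) the mean reduction settles near 2–3
points, comfortably inside the ~5-point envelope the method is
expected to stay within at this missingness level.

A command-line layer wraps the same functions:

```bash
miprofile simulate --calibrate --out out/ --n-datasets 3 --seed 1
miprofile mask out/synthetic_0000.csv --rate 0.3 --seed 2 --out masked/
miprofile impute masked/masked.csv --method missforest --m 10 --out imputed/
miprofile run-grid --n-datasets 100 --seed 1 --out results/
```

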