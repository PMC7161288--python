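# gllrasch

Polytomous Rasch (Partial Credit) models and **Graphical Log-linear Rasch
Models** (GLLRMs) for validating ordinal rating scales, estimated by
conditional maximum likelihood — with the complete item-analysis toolkit
around them: conditional likelihood-ratio tests of parameter invariance,
conditional infit/outfit statistics, Kelderman likelihood-ratio screening
of local dependence (LD) and differential item functioning (DIF), partial
Goodman–Kruskal γ effect sizes, Warm's weighted likelihood person
estimates, targeting, LD-adjusted Monte Carlo reliability, person
separation, DIF score-adjustment conversion tables, and a config-driven
stepwise analysis pipeline.  A synthetic-data generator emulating a
two-subscale perceived-stress instrument (PSS-14-like: 14 five-category
items, sex/education covariates, calibrated LD/DIF structure, deliberately
misfitting items) makes the whole workflow testable end to end.

## Who this is for

Psychometricians and epidemiologists validating Likert-type scales in the
Rasch framework who need to go beyond "does it fit the Rasch model":
catalogue *why* items depart (uniform LD, uniform DIF, flat characteristic
curves), keep items whose departures are modellable, and adjust total
scores so subgroup comparisons are not confounded by measurement bias.

## The model

For items with categories y = 0..m_i, the GLLRM specifies

    log P(Y = y | θ, C) = λ0(θ,C) + Σ_i (α_iy_i + y_i θ)
                          + Σ_{(i,j)∈LD} λ_ij(y_i, y_j)
                          + Σ_{(i,g)∈DIF} δ_ig(y_i, c_g)

The first sum is the Partial Credit model; λ terms are uniform LD
interactions between item pairs, δ terms uniform DIF interactions between
an item and a categorical covariate ("uniform": constant across the
trait).  The total score R = Σ Y_i is sufficient for θ (within
DIF-defined subgroups), so all estimation and testing condition on R and
the person parameters are never estimated jointly — the normaliser
λ0(θ,C) is never needed.  Elementary symmetric functions are computed in
log space with locally dependent pairs handled as exact composite items.

## Worked example

Simulate the five-item "Perceived Stress" structure (one LD pair, DIF by
sex on two items and by education on one) at n = 3857 and fit the
generating model:

```python
from gllrasch import GLLRM
from gllrasch.diagnostics import clr_test, conditional_item_fit, partial_gamma_ld
from gllrasch.scoring import (adjusted_group_comparison, dif_conversion_table,
                              estimate_person_dist, mc_reliability, target_index)
from gllrasch.simulate import stress_scenario, simulate_dataset

cfg = stress_scenario(n=3857)
data, truth = simulate_dataset(cfg, seed=7)

res = GLLRM(data, items=["item1", "item2", "item3", "item11", "item14"],
            ld=[("item1", "item2")],
            dif=[("item1", "sex"), ("item3", "sex"),
                 ("item1", "education")]).fit()

print(clr_test(res, "score"))     # overall fit (homogeneity)
print(clr_test(res, "sex"))       # global DIF by sex
```

```
chi2(25) = 25.3, p = 0.4455  [score (2 groups)]
chi2(30) = 36.0, p = 0.2071  [sex (2 groups)]
```

The model fits: item parameters are invariant across low/high scorers and
across sex once the uniform DIF terms are in the model.  Item-level fit
(conditional parametric bootstrap; expectation 1 under the model):

```python
print(conditional_item_fit(res, n_boot=200, seed=1).round(3))
```

```
  item    n  outfit  outfit_se  outfit_p  infit  infit_se  infit_p
 item1 3854   1.016      0.018     0.273  1.015     0.016    0.221
 item2 3854   0.990      0.017     0.859  0.996     0.016    0.842
 item3 3854   0.990      0.017     0.629  0.991     0.016    0.664
item11 3854   1.017      0.015     0.240  1.017     0.015    0.239
item14 3854   0.987      0.018     0.545  0.988     0.017    0.563
```

Effect size of the local dependence, person-side summaries, and the
DIF-adjusted comparison of sex groups:

```python
g = partial_gamma_ld(data, "item1", "item2", res.model.item_names)
print(f"partial gamma LD(1,2): {g.gamma:.3f} (SE {g.se:.3f})")

dist = estimate_person_dist(res)
ti = target_index(res, dist)
print(f"target index {ti['index']:.2f}, target score {ti['target_score']:.1f}")
print(f"MC reliability: {mc_reliability(res, dist, 100_000, seed=2):.3f}")

table = dif_conversion_table(res)
print(adjusted_group_comparison(data, res, table, "sex").round(2))
```

```
partial gamma LD(1,2): 0.191 (SE 0.019)
target index 0.66, target score 13.9
MC reliability: 0.708
 level    n  observed_mean  adjusted_mean  bias
  Male 1470           8.00           8.10 -0.11
Female 2387           9.32           8.77  0.54
```

Read: the instrument is mistargeted for this population (mean score ≈ 8 of
20 against a target of ≈ 14, so only 66% of the attainable information is
used); the LD pair shows a partial γ of 0.19 after conditioning on the
restscores; and about 0.5 points of the raw 1.3-point sex difference is
measurement bias that the conversion table removes — comparing unadjusted
totals between sexes would overstate the group difference.

The stepwise pipeline automates the whole loop (fit → test → screen → add
term or exclude item → repeat), logs every decision, and emits CSV tables
plus a report; see `gllrasch.pipeline.run_item_analysis` or the `gllrasch`
command-line interface (`simulate`, `fit`, `screen`, `pipeline`,
`report`).

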