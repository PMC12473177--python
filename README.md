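# ordshift

Proportional-odds **shift analysis** for two-arm randomized trials with an
ordinal outcome — the modified Rankin Scale (mRS), the Glasgow Outcome Scale
Extended (GOS-E), and scales like them. Built for trial statisticians and
methods researchers who need the full recommended workflow in one place:

- the **proportional-odds (PO) cumulative-logit model** with the common odds
  ratio (cOR), Wald and likelihood-ratio tests of the treatment effect, and
  the LR test of the PO assumption against the saturated two-arm multinomial;
- **cut-point odds-ratio diagnostics** — the K−1 dichotomization ORs with
  CIs behind the cumulative-OR plot, the graphical check of proportionality;
- the **competing tests**: Mann-Whitney U (midranks, tie-corrected normal
  approximation), linear-by-linear (Cochran-Armitage) trend, Pearson χ²,
  and Welch's t on integer scores — plus the deliberately implemented,
  *invalid* pretest "hybrid" strategy, kept only to demonstrate its
  type-I-error inflation;
- **win statistics** (probabilistic index, net benefit, win ratio, win odds)
  and **utility-weighted** mean contrasts;
- a seeded **Monte-Carlo engine** for power and type-I-error experiments;
- **Grotta bars** and the cumulative-OR plot, and a `ordshift` CLI.

## The model

For an outcome with K ordered categories and treatment indicator x ∈ {0, 1},
let γ_j(x) be the probability of an outcome *at or better than* category j
(the package applies the scale's clinical orientation, so "better" always
means better). The PO model is

```
logit γ_j(x) = α_j + β·x ,   j = 1, …, K−1,   α_1 < … < α_{K−1}
```

with a single slope β shared by all K−1 dichotomizations. exp(β) is the
**common odds ratio**: the PO assumption says every cut-point OR equals it,
and the MLE pools the observed cut-point ORs into one weighted average.
cOR > 1 always means a shift toward clinically better categories. Fitting
is Newton–Raphson on the multinomial likelihood with analytic gradient and
Hessian; the inverse observed information supplies Wald CIs.

Two points the package is built around: testing "cOR = 1" is **valid whether
or not the PO assumption holds** (under the null both arms are identical, so
proportionality holds automatically), but *pretesting* the PO assumption to
choose between the cOR test and the χ² test is invalid — it amounts to
picking the smaller p-value and inflates the type-I error. And when the PO
assumption is substantially violated, no single number (cOR, win odds, …)
faithfully summarizes the effect; report the full distributions and the
cut-point ORs.

## Worked example

`trial.csv` holds aggregated counts (`arm,category,count`) for a 6-category
mRS-like outcome, 100 participants per arm:

```bash
ordshift analyze --input trial.csv --scale 0,1,2,3,4,5 \
    --orientation lower-better --control-arm "usual care" --test po-lr
```

```
Proportional-odds (cumulative logit) model
==========================================================
Arms: usual care (n=100) vs intervention (n=100)
Categories (K=6): 0, 1, 2, 3, 4, 5
Orientation: lower_better
Log-likelihood: -353.3338   converged: True (5 iter)
----------------------------------------------------------
param         estimate   std err        z     P>|z|
alpha_1        -2.1359    0.2474   -8.633 5.995e-18
alpha_2        -1.2276    0.2076   -5.914 3.334e-09
alpha_3        -0.5188    0.1916   -2.708  0.006773
alpha_4         0.2379    0.1892    1.258    0.2085
alpha_5         1.0983    0.2097    5.237  1.63e-07
beta            0.7174    0.2527    2.839  0.004523
----------------------------------------------------------
Common odds ratio: 2.0492  (95% CI 1.2488 to 3.3625)
PO assumption LR test: stat = 0.427, df = 4, p = 0.9802
----------------------------------------------------------
PO model LR test (common OR = 1): statistic = 8.1679, df = 1, p = 0.004264
```

Reading: the intervention roughly doubles the odds of a better outcome at
every cut-point (cOR 2.05, CI 1.25–3.36; LR p = 0.004), and the cut-point
ORs are consistent with a common value (PO test p = 0.98 — though a
nonsignificant test is not proof; inspect the plot from `--plot-cor` or
`ordshift check-po`). The same library calls are available in Python:

```python
from ordshift import OrdinalScale, TwoArmCounts, ProportionalOddsModel

scale = OrdinalScale(("0", "1", "2", "3", "4", "5"), "lower_better")
data = TwoArmCounts(scale, [[10, 12, 15, 20, 18, 25], [20, 18, 17, 16, 15, 14]],
                    ("usual care", "intervention"))
res = ProportionalOddsModel(data).fit()
print(res.summary())
```

The simulation engine demonstrates why the pretest strategy is invalid —
under a pure null (5 equiprobable categories, both arms):

```bash
ordshift simulate --builtin sim3 --reps 2000 --n-per-arm 100 --seed 42 --out sim3.csv
```

```
            scenario strategy  alpha  n_sims  n_reject  rejection_rate    mc_se  seed
null: identical arms    po_lr   0.05    2000       106          0.0530 0.005010    42
null: identical arms    chisq   0.05    2000        92          0.0460 0.004684    42
null: identical arms   hybrid   0.05    2000       169          0.0845 0.006219    42
```

Each fixed test sits at the nominal 0.05; the hybrid (pretest the PO
assumption, then choose χ² or PO-LR) rejects in 8.5% of null trials.

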