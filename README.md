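# activelab

Active-learning (Bayesian-optimization) workflow for optimizing
multi-factor biological systems — cell-free transcription–translation
mixes, genetic circuits, multi-enzyme cascades — where the search space is
combinatorial (every reagent varied over a handful of concentrations,
every part over a set of variants) but the experimental budget is tens of
conditions per round.

It is written for experimentalists and their computational collaborators:
you declare *factors* and their allowed *levels*, feed in each round's
measured objective values, and the workflow suggests the next round of
experiments. Everything is also runnable with no laboratory at all, via a
simulation harness with synthetic landscapes of known optimum.

## The method

A round's surrogate model is an **ensemble of gradient-boosted tree
regressors** (XGBoost), the members differing by randomly searched
hyperparameters (ensemble size 20 by default). For a candidate condition
*x* the ensemble provides a mean μ(x) and a population standard deviation
σ(x) across members. Candidates — up to 100 000 drawn uniformly from the
untested space — are ranked by the **upper confidence bound**

    UCB(x) = exploitation · μ(x) + exploration · σ(x)

and the top-*n* become the next round. μ rewards conditions predicted to
perform well, σ rewards conditions the model is unsure about; the
exploration weight should decay over rounds (a linear schedule is
shipped). The model is always retrained on the union of all rounds so far.

Beyond the optimization loop the package implements the companion
analyses:

- **Feature importance** — per-factor percentages (gain-based, one-hot
  columns folded back onto their factor, normalized to 100%).
- **K most informative combinations** — random size-K subsets of the
  tested conditions, each scored by the Spearman rank correlation of a
  model trained on the subset against the held-out remainder; the top 5
  subsets summarize which experiments carry the knowledge.
- **Mutual interaction scan** — in-sample R² gain of an OLS model when a
  single F_i·F_j product term is added to the additive baseline, for every
  factor pair.
- **Objective transforms** — blank-subtracted normalized yield,
  fold-change × dynamic range for circuits, efficiency (yield per total
  enzyme) and fixed-CO₂ equivalents for carbon-fixation cascades.
- **Prediction mode** — acquisition by σ alone (exploitation = 0), which
  maximizes model quality on unseen conditions instead of the objective.
- **Simulation** — "gold regressor" oracles fitted to pre-existing
  datasets, synthetic landscapes with known optima, paired benchmarking of
  surrogate families (tree ensembles, linear, shallow/deep networks), and
  full campaign simulation.
- **Lab plumbing** — CSV round files, YAML space configs, and
  ascending-volume worklist export for acoustic liquid handlers (25 nL
  resolution by default).

## Worked example

```python
import numpy as np
from activelab import (Factor, SearchSpace, LabeledDataset, AcquisitionConfig,
                       suggest_round, feature_importance, mutual_interactions)

space = SearchSpace([
    Factor("mg_glutamate", "numeric", (2.0, 4.0, 6.0, 8.0), "mM"),
    Factor("k_glutamate", "numeric", (40.0, 80.0, 120.0, 160.0), "mM"),
    Factor("dna_plasmid", "numeric", (5.0, 10.0, 20.0, 30.0), "nM"),
])

rng = np.random.default_rng(0)
day1 = space.sample(20, seed=1)                      # random Day 1
def measure(c):                                      # plate reader stand-in
    return (0.1 * c["mg_glutamate"] * c["dna_plasmid"]
            + 0.01 * c["k_glutamate"] + rng.normal(0, 0.2))
data = LabeledDataset(space).with_round(day1, [measure(c) for c in day1])

config = AcquisitionConfig(exploitation=1.0, exploration=1.0,
                           n_candidates=100_000, n_suggest=5, seed=2)
plan = suggest_round(data, space, config)
for comb, mu, sd, score in zip(plan.suggestions, plan.mu, plan.sigma, plan.scores):
    print(f"{comb}  mu={mu:.2f}  sigma={sd:.2f}  UCB={score:.2f}")
```

prints the five suggested Day-2 conditions, best UCB first:

```
{'mg_glutamate': 8.0, 'k_glutamate': 160.0, 'dna_plasmid': 30.0}  mu=21.16  sigma=5.30  UCB=26.46
{'mg_glutamate': 8.0, 'k_glutamate': 40.0, 'dna_plasmid': 30.0}   mu=20.19  sigma=5.43  UCB=25.62
{'mg_glutamate': 6.0, 'k_glutamate': 160.0, 'dna_plasmid': 30.0}  mu=17.71  sigma=3.25  UCB=20.96
{'mg_glutamate': 6.0, 'k_glutamate': 80.0, 'dna_plasmid': 30.0}   mu=17.00  sigma=3.55  UCB=20.55
{'mg_glutamate': 6.0, 'k_glutamate': 40.0, 'dna_plasmid': 30.0}   mu=16.77  sigma=3.43  UCB=20.20
```

The model has already pushed magnesium and DNA toward their upper levels —
the two factors that multiply in the simulated ground truth. The
diagnostics agree:

```python
imp = feature_importance(data, seed=0)
# {'mg_glutamate': 35.2, 'k_glutamate': 3.9, 'dna_plasmid': 60.9}   (percent)

scan = mutual_interactions(data)
# baseline R2=0.893, top pair=('mg_glutamate', 'dna_plasmid'), delta=0.107
```

The interaction scan flags the mg_glutamate × dna_plasmid pair as the
only factor pair whose product term improves the additive linear model.

The same workflow is available from the shell:

```bash
activelab init --out space.yaml
activelab suggest --space space.yaml --results Day_1_results.csv \
    --n-suggest 20 --seed 1 --out Day_2_suggestions.csv
activelab analyze importance --space space.yaml --results Day_1_results.csv --out imp.csv
activelab worklist --space space.yaml --plan Day_2_suggestions.csv \
    --stocks stocks.yaml --out worklist.csv
```

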