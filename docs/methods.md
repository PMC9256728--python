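# Methods

## Model and procedure

The package frames experiment planning as Bayesian optimization over a
finite combinatorial space. Each *factor* (a reagent concentration, an
enzyme amount, a part variant) takes one of a finite, ordered set of
levels; a *combination* assigns a level to every factor. Numeric factors
are treated as discrete levels by construction — continuous ranges must be
pre-discretized by the user. This keeps the space size an exact integer
(spaces beyond 10²⁵ members are handled with Python integers), makes
uniform candidate sampling well defined, and matches how such campaigns
are actually run: stock solutions are prepared at a fixed set of
dilutions.

One optimization round proceeds as:

1. Randomized hyperparameter search for the tree-ensemble surrogate on all
   data accumulated so far (rounds 1…r).
2. Fit one XGBoost regressor per selected configuration (ensemble size 20
   by default).
3. Draw up to 100 000 distinct random candidates from the untested space.
4. Compute per-candidate ensemble mean μ and population standard deviation
   σ (divisor = member count, so σ = 0 exactly when members agree).
5. Rank by UCB = exploitation·μ + exploration·σ; suggest the top *n*.
6. Append user-pinned control conditions ("specials") unscored.

Round 1 has no model and is uniform random. Ties in UCB are broken by
candidate pool order (a stable sort), which makes round plans fully
deterministic given the seed.

### Surrogate ensemble

Uncertainty comes from hyperparameter diversity (and, by default, from
per-member fit seeds as well; `vary_seed=False` disables the latter, in
which case duplicated configurations collapse to σ = 0). "The best
*k* hyperparameters" are taken as the *k* best-scoring distinct
configurations of a single randomized search, scored by 3-fold
cross-validated squared Pearson correlation. When the number of draws
equals the ensemble size the search degenerates to a pure
random-hyperparameter ensemble with no selection pressure — this is the
default inside simulated campaigns, where per-round budgets are small and
selection adds cost without measurably changing behaviour.

Two hyperparameter grids ship with the package:

| grid | n_estimators | learning rate | max depth | min child wt | subsample |
|---|---|---|---|---|---|
| `DEFAULT_GRID` | 100–800 | 0.005–0.3 (log) | 2–10 | 1–10 | 0.5–1.0 |
| `CAMPAIGN_GRID` | 100–300 | 0.01–0.3 (log) | 2–6 | 1–5 | 0.6–1.0 |

`CAMPAIGN_GRID` is the simulation harness's default: with tens of training
points per round, several hundred shallow trees saturate fit quality, and
capping the tree count keeps a 10-round × 5-seed benchmark to tens of
seconds on one CPU. Both grids are plain mappings and overridable at every
entry point.

The reference single-model configuration (used for the gold regressor,
cross-validation and as fallback) is: objective `reg:squarederror`,
500 trees, learning rate 0.01, depth 6, min child weight 1, subsample 0.8.

### Cross-validation metric

`cross_validate` reports the k-fold (k = 5 default) average of the
*squared Pearson correlation* between held-out truth and predictions, not
the coefficient of determination. The two differ for biased predictors;
squared Pearson is the convention adopted here because it measures ranking
fidelity, which is what acquisition consumes. A fold with constant truth
has no defined correlation and scores 0 with a warning, keeping averages
finite.

### Acquisition details

- Already-tested combinations are excluded from the candidate pool by
  default (`exclude_tested=False` restores re-suggestion): re-measuring a
  known condition wastes a well.
- Candidate pools are de-duplicated; the pool size is effectively
  min(n_candidates, space − tested).
- The shipped exploration schedule decreases linearly from its start value
  (default 1.0) at round 2 to its end value (default 0.0) at the final
  round: explorative early, exploitative late.
- *Prediction mode* (`uncertainty_suggest`, `simulate_prediction_mode`)
  sets exploitation to 0 and ranks by σ alone; its product is the fitted
  ensemble rather than the suggestions, so the plan carries the ensemble.
- *Batch UCB* (`batch_ucb_suggest`) is an optional, off-by-default greedy
  variant: after each pick the candidate is added to the training set with
  its predicted mean as a provisional label ("constant liar") and the
  ensemble is refitted, suppressing near-duplicate picks within one batch.
  It is a standard sequential-batch heuristic, one refit per pick, and is
  not part of the core loop.

## Diagnostics

**Feature importance** fits one tuned model on the cumulative data, reads
gain-based per-column importances, sums one-hot indicator columns back
onto their parent factor via the encoding column map, and normalizes to
percentages summing to 100 (uniform with a warning if all importances are
zero). Gain — not split count — is used because it reflects loss
reduction, the quantity of scientific interest.

**K most informative combinations** draws up to `n_subsets` (default
2000) *distinct* random size-K subsets of the N tested conditions —
exhaustive when C(N,K) ≤ n_subsets — fits a model (one configuration,
tuned once on the full data) on each subset and scores it by Spearman
rank correlation (average ranks on ties) on the complementary records.
"Unseen combinations" are taken as the complement of the subset within
the tested set: the only labeled data available. Subsets whose complement
has constant truth are excluded with a warning.

**Mutual interaction scan** uses in-sample R² of OLS as baseline; per
unordered factor pair it refits with the pair's product feature added — a
single x_i·x_j column for numeric×numeric, the joint block of indicator
products when a categorical factor is involved (a product of raw category
codes would be meaningless). Deltas are non-negative up to numerical
tolerance because adding a regressor cannot lower in-sample OLS R²; a
singular design falls back to a tiny-α ridge with a warning. Only
pairwise products are scanned; higher-order interaction search is out of
scope.

**Objective transforms** are pure arithmetic: normalized yield
(raw − blank)/(reference − reference blank); fold-change FC = on/off,
dynamic range DR = on − off, circuit objective FC·DR; efficiency =
yield / total enzyme concentration (returning a new dataset with rounds
and combinations untouched, so a campaign can switch objective mid-way);
CO₂ equivalents = (product/acceptor)·(CO₂ fixed per product molecule).

## Simulation harness

Oracles are pure deterministic functions; measurement noise is Gaussian,
applied by the harness at labeling time with its own derived seed. This
separation mirrors replicate noise in plate-based experiments without
contaminating oracle determinism, and makes campaigns reproducible bit
for bit from (oracle, seed).

**Gold regressor**: 80/20 seeded split of a pre-existing labeled table;
the reference configuration with early stopping (50 rounds, monitored on
the 20% split; the patience value is a package default since only the
split fractions are inherent to the procedure).

**Synthetic landscapes**: objective = Σ numeric main effects (weight ×
level value) + Σ categorical level effects + Σ pairwise interaction terms
(coefficient × effect × effect). The known optimum is computed by
exhaustive enumeration for spaces ≤ 10⁶, by coordinate-wise argmax for
larger purely additive specs, and omitted with a warning otherwise.

**Reference landscape** (`reference_landscape()`): five numeric factors at
four levels (1024 combinations), graded main effects of both signs
(1.0, 0.8, 0.6, −0.5, 0.4), one strong synergistic pair (+1.5 · f1 · f2),
and measurement noise at 5% of the landscape's value spread. It emulates a
small multi-component reaction with one dominant synergy. It does *not*
emulate heteroscedastic noise, batch effects between rounds (e.g. new
enzyme stocks), level sets that drift mid-campaign, or spaces where most
factors are irrelevant — passing benchmarks here show the machinery
optimizes a low-dimensional interacting landscape under mild noise, not
that any wet-lab system will improve at the same rate.

**Benchmark scale.** Simulated campaigns in the test suite and the
acceptance script run 10 rounds × 20 points (or × 10 for the small-budget
arm) with ensembles of 20, 5 seeds, against an equal-budget
random-sampling control; prediction mode runs 5 rounds × 20 points with
ensembles of 10 against a fixed 100-point probe set. These sizes are the
package's benchmark conditions for a 1024-member space — about a fifth of
it measured — chosen so a practitioner can re-run the whole benchmark in
under a minute.

**Model families** for algorithm comparison (5 members each): the tree
ensemble; ordinary least squares duplicated five times (deterministic, so
σ ≡ 0 and UCB degenerates to exploitation ranking — a property the tests
assert); five four-hidden-layer perceptrons with hidden sizes
(10,100,100,20), (20,100,100,10), (20,100,100,20), (10,100,100,10),
(20,100,100,50); and a deeper feed-forward family of five (100,100,20)
networks differing by initialization seed. Networks are standardized
pipelines (`StandardScaler` + `MLPRegressor`, ReLU, Adam, max 500
epochs — documented defaults, since only the architectures are inherent
to the comparison). Benchmarks are paired: per seed, every family starts
from the identical random Day-1 set, and candidate pools depend only on
(seed, tested set), so arms are exactly matched through round 2 and
seed-matched after their picks diverge.

## Numerical and interface choices

- Population (divisor-n) standard deviation throughout.
- Stable sorts everywhere a ranking is taken; ties resolve to pool order.
- Sub-seeds are derived from the user seed via `numpy.random.SeedSequence`
  and masked to 31 bits.
- Encoding: numeric factor → one column with the level value; categorical
  factor → one indicator column per level. The column map is returned so
  importances can be folded back per factor; decoding validates one-hot
  blocks and matches numeric values back to unique levels.
- Round files: comma-separated UTF-8, header row, factor columns in space
  order then `mu`, `sigma`, `score`, `special`; floats formatted `%.10g`
  so identical plans are byte-identical. Replicate rows in results files
  are averaged on read.
- Worklists: volume = final volume × level / stock, rounded **half-up** to
  the dispenser resolution (default 25 nL); a deviation beyond two
  resolution units warns. Rows are grouped by component and sorted by
  ascending volume (minimizes pipette re-setting); a buffer `fill` row
  tops each well up, and per-well conservation (components + fill = final
  volume) is enforced. Only numeric factors have dilution semantics;
  categorical factors must be dispensed via the master mix and are
  rejected with a clear error.
- Zero-level components are skipped by default (`keep_zero_rows` emits
  explicit zero-volume rows instead).

## Known limitations

- Single-objective only; the efficiency switch is an objective transform,
  not multi-objective acquisition.
- No constraint handling beyond the level sets themselves.
- The informative-subset search refits one model per subset; exhaustive
  mode is only practical for small C(N,K).
- Batch UCB is a generic constant-liar heuristic, not a calibrated batch
  acquisition.
- Gold regressors extrapolate like any boosted tree: poorly outside the
  convex hull of their training data; treat simulated absolute yields with
  caution and rely on orderings.
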