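"""Lab-free simulation harness: oracles, synthetic landscapes, campaigns.

Instead of wet-lab measurements, simulated campaigns label suggested
conditions with an *oracle*: either a "gold regressor" — a gradient-boosted
model fitted once to a pre-existing labeled table and then treated as
ground truth — or a synthetic landscape with known structure (main
effects, level effects, pairwise interactions) and hence a known optimum.
The harness drives full active-learning campaigns against an oracle,
benchmarks surrogate model families under a paired design, and runs the
uncertainty-driven "prediction mode" that optimizes model quality instead
of the objective.

Measurement noise is applied by the harness at labeling time, never by
the oracle itself: oracles are pure functions, which keeps campaigns
bit-reproducible and lets the same landscape be reused across noise
settings.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.base import clone
from sklearn.linear_model import LinearRegression
from sklearn.neural_network import MLPRegressor
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler

from .acquisition import AcquisitionConfig, exploration_schedule, ucb_score
from .space import Combination, Factor, LabeledDataset, SearchSpace
from .surrogate import (
    CAMPAIGN_GRID,
    GOLD_CONFIG,
    EnsembleRegressor,
    PredictionSummary,
    squared_pearson,
)

__all__ = [
    "OracleFunction",
    "SyntheticLandscapeSpec",
    "Trajectory",
    "build_gold_regressor",
    "generate_landscape",
    "simulate_campaign",
    "benchmark_algorithms",
    "simulate_prediction_mode",
    "reference_landscape",
    "FAMILIES",
]

_OPTIMUM_ENUMERATION_CAP = 10**6


@dataclass(frozen=True)
class OracleFunction:
    """Deterministic ground-truth objective for simulated experiments."""

    evaluate: Callable[[Combination], float]
    provenance: str  # "fitted_gold_regressor" | "synthetic"
    known_optimum: tuple[Combination, float] | None = None

    def __call__(self, combination: Combination) -> float:
        return float(self.evaluate(combination))

    def label(self, combinations: Sequence[Combination]) -> np.ndarray:
        return np.array([self(c) for c in combinations], dtype=float)


@dataclass(frozen=True)
class SyntheticLandscapeSpec:
    """Declarative synthetic objective over a search space.

    The objective of a combination is

        sum_i  w_i * x_i          (numeric main effects)
      + sum_c  e_c[level_c]       (categorical level effects)
      + sum_(i,j)  c_ij * x_i * x_j   (pairwise interactions)

    where x_i is the numeric level value, or the level effect when a
    categorical factor takes part in an interaction.  ``noise_sd`` is the
    measurement-noise standard deviation the *harness* adds at labeling
    time; the landscape itself stays deterministic.
    """

    space: SearchSpace
    main_effects: Mapping[str, float] = field(default_factory=dict)
    categorical_effects: Mapping[str, Mapping] = field(default_factory=dict)
    interactions: Sequence[tuple[tuple[str, str], float]] = ()
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self):
        for name in self.main_effects:
            if name not in self.space or self.space[name].kind != "numeric":
                raise ValueError(f"main effect on unknown/non-numeric factor {name!r}")
        for name, table in self.categorical_effects.items():
            if name not in self.space or self.space[name].kind != "categorical":
                raise ValueError(f"level effects on unknown/non-categorical factor {name!r}")
            missing = set(self.space[name].levels) - set(table)
            if missing:
                raise ValueError(f"factor {name!r}: missing level effects for {missing}")
        for (a, b), _ in self.interactions:
            for name in (a, b):
                if name not in self.space:
                    raise ValueError(f"interaction references unknown factor {name!r}")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")


def _landscape_value(spec: SyntheticLandscapeSpec, comb: Combination) -> float:
    def effect(name: str) -> float:
        f = spec.space[name]
        if f.kind == "numeric":
            return float(comb[name])
        return float(spec.categorical_effects.get(name, {}).get(comb[name], 0.0))

    total = 0.0
    for name, w in spec.main_effects.items():
        total += w * float(comb[name])
    for name, table in spec.categorical_effects.items():
        total += float(table[comb[name]])
    for (a, b), coeff in spec.interactions:
        total += coeff * effect(a) * effect(b)
    return total


def generate_landscape(spec: SyntheticLandscapeSpec) -> OracleFunction:
    """Build a synthetic oracle with its optimum computed when feasible.

    The optimum comes from exhaustive enumeration for spaces up to 10^6
    combinations; purely additive landscapes over larger spaces use the
    coordinate-wise argmax instead.  For large spaces with interactions the
    optimum is omitted with a warning.
    """
    space = spec.space
    evaluate = lambda comb: _landscape_value(spec, comb)  # noqa: E731

    known = None
    if space.size() <= _OPTIMUM_ENUMERATION_CAP:
        best_comb, best_val = None, -np.inf
        for comb in space.enumerate():
            v = evaluate(comb)
            if v > best_val:
                best_comb, best_val = comb, v
        known = (best_comb, float(best_val))
    elif not spec.interactions:
        comb = {}
        for f in space.factors:
            if f.kind == "numeric":
                w = spec.main_effects.get(f.name, 0.0)
                comb[f.name] = max(f.levels, key=lambda lv: w * lv)
            else:
                table = spec.categorical_effects.get(f.name)
                comb[f.name] = (max(f.levels, key=lambda lv: table[lv])
                                if table else f.levels[0])
        known = (comb, float(evaluate(comb)))
    else:
        warnings.warn("space too large to enumerate and landscape is not "
                      "additive; known optimum omitted", UserWarning)

    return OracleFunction(evaluate=evaluate, provenance="synthetic",
                          known_optimum=known)


def build_gold_regressor(table: pd.DataFrame, space: SearchSpace,
                         seed: int = 0, min_rows: int = 50,
                         early_stopping_rounds: int = 50) -> OracleFunction:
    """Fit a gold-regressor oracle to a pre-existing labeled table.

    The table (factor columns + ``objective``) is split 80/20; a
    gradient-boosted regressor with the fixed reference configuration
    (500 trees, learning rate 0.01, depth 6, min child weight 1, subsample
    0.8) is trained on the 80% with early stopping monitored on the 20%.
    The fitted model, evaluated deterministically, then stands in for the
    laboratory when benchmarking algorithms.
    """
    if len(table) < min_rows:
        raise ValueError(f"gold regressor needs >= {min_rows} rows, got {len(table)}")
    combos = [{n: row[n] for n in space.names} for _, row in table.iterrows()]
    X, _ = space.encode(combos)
    y = table["objective"].to_numpy(dtype=float)

    rng = np.random.default_rng(seed)
    idx = rng.permutation(len(y))
    n_val = max(1, int(round(0.2 * len(y))))
    val, train = idx[:n_val], idx[n_val:]

    model = GOLD_CONFIG.make_regressor(seed=seed)
    model.set_params(early_stopping_rounds=early_stopping_rounds)
    model.fit(X[train], y[train], eval_set=[(X[val], y[val])], verbose=False)

    def evaluate(comb: Combination) -> float:
        Xc, _ = space.encode([comb])
        return float(model.predict(Xc)[0])

    return OracleFunction(evaluate=evaluate, provenance="fitted_gold_regressor")


def reference_landscape() -> tuple[OracleFunction, SearchSpace, float]:
    """The package's reference benchmark landscape.

    Five numeric factors at four levels each (1024 combinations), graded
    main effects of both signs and one strong positive pairwise
    interaction — the qualitative structure of a multi-component reaction
    where two components act synergistically.  Returns the oracle, its
    space and the measurement-noise standard deviation used by the
    benchmark conditions: 5% of the landscape's value spread.
    """
    space = SearchSpace([
        Factor(name, "numeric", (0.25, 0.5, 0.75, 1.0), "mM")
        for name in ("f1", "f2", "f3", "f4", "f5")])
    spec = SyntheticLandscapeSpec(
        space=space,
        main_effects={"f1": 1.0, "f2": 0.8, "f3": 0.6, "f4": -0.5, "f5": 0.4},
        interactions=[(("f1", "f2"), 1.5)])
    oracle = generate_landscape(spec)
    values = oracle.label(space.enumerate())
    noise_sd = 0.05 * float(values.std())
    return oracle, space, noise_sd


# -- campaign machinery -------------------------------------------------------------


@dataclass
class Trajectory:
    """Per-round record of a simulated campaign."""

    algorithm: str
    per_round: int
    rounds: list[dict] = field(default_factory=list)
    dataset: LabeledDataset | None = None

    def record(self, round_index: int, values: np.ndarray) -> None:
        prev_best = self.rounds[-1]["cumulative_best"] if self.rounds else -np.inf
        self.rounds.append({
            "round": round_index,
            "values": np.asarray(values, dtype=float),
            "cumulative_best": float(max(prev_best, np.max(values))),
            "median": float(np.median(values)),
        })

    @property
    def cumulative_best(self) -> list[float]:
        return [r["cumulative_best"] for r in self.rounds]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([
            {"algorithm": self.algorithm, "round": r["round"],
             "n": len(r["values"]), "best": float(np.max(r["values"])),
             "cumulative_best": r["cumulative_best"], "median": r["median"]}
            for r in self.rounds
        ])


class _SklearnFamilyEnsemble:
    """Fixed list of sklearn regressors acting as an uncertainty ensemble."""

    def __init__(self, estimators):
        self.estimators = estimators

    def fit(self, X, y):
        self.members_ = []
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            for est in self.estimators:
                self.members_.append(clone(est).fit(X, y))
        return self

    def predict_summary(self, X) -> PredictionSummary:
        preds = np.vstack([m.predict(X) for m in self.members_])
        return PredictionSummary(mu=preds.mean(axis=0), sigma=preds.std(axis=0))


def _mlp(hidden, seed):
    return make_pipeline(
        StandardScaler(),
        MLPRegressor(hidden_layer_sizes=hidden, activation="relu",
                     max_iter=500, random_state=seed))


#: Surrogate model families for algorithm benchmarking (5 members each, as
#: in the reference benchmark).  The linear family duplicates one ordinary
#: least-squares model five times — its spread is identically zero, so UCB
#: degenerates to exploitation ranking.
FAMILIES = ("tree-ensemble", "linear", "shallow-network", "deep-network")

_SHALLOW_HIDDEN = [(10, 100, 100, 20), (20, 100, 100, 10), (20, 100, 100, 20),
                   (10, 100, 100, 10), (20, 100, 100, 50)]


def _make_family(family: str, size: int, grid, seed: int):
    if family == "tree-ensemble":
        return EnsembleRegressor(n_members=size, grid=grid, random_state=seed)
    if family == "linear":
        return _SklearnFamilyEnsemble([LinearRegression() for _ in range(size)])
    if family == "shallow-network":
        hidden = (_SHALLOW_HIDDEN * size)[:size]
        return _SklearnFamilyEnsemble([_mlp(h, seed + i)
                                       for i, h in enumerate(hidden)])
    if family == "deep-network":
        return _SklearnFamilyEnsemble([_mlp((100, 100, 20), seed + i)
                                       for i in range(size)])
    raise ValueError(f"unknown model family {family!r}; choose from {FAMILIES}")


def _round_seeds(seed: int, rounds: int) -> np.ndarray:
    """Deterministic per-round 31-bit sub-seeds derived from the campaign seed."""
    state = np.random.SeedSequence(seed).generate_state(3 * rounds + 3)
    return (state & 0x7FFFFFFF).astype(np.int64)


def simulate_campaign(oracle: OracleFunction, space: SearchSpace,
                      rounds: int = 10, per_round: int = 100, seed: int = 0,
                      algorithm: str = "tree-ensemble", ensemble_size: int = 20,
                      grid=CAMPAIGN_GRID, n_candidates: int = 100_000,
                      exploitation: float = 1.0,
                      exploration_start: float = 1.0,
                      exploration_end: float = 0.0,
                      noise_sd: float = 0.0) -> Trajectory:
    """Run one simulated active-learning campaign against an oracle.

    Round 1 is uniform random; each later round fits the chosen surrogate
    family on all data so far, scores a fresh candidate pool (tested
    combinations excluded) by UCB with a linearly decaying exploration
    weight, and "performs" the top ``per_round`` suggestions by querying
    the oracle (plus optional Gaussian measurement noise).  ``algorithm``
    may also be ``"random"`` for the equal-budget random-sampling control.
    Fully reproducible: (oracle, seed) determine the trajectory bit for bit.
    """
    if per_round < 1:
        raise ValueError("per_round must be >= 1")
    seeds = _round_seeds(seed, rounds)
    noise_rng = np.random.default_rng(int(seeds[-1]))

    def label(combos):
        y = oracle.label(combos)
        if noise_sd > 0:
            y = y + noise_rng.normal(0.0, noise_sd, size=len(y))
        return y

    traj = Trajectory(algorithm=algorithm, per_round=per_round)
    combos = space.sample(per_round, seed=int(seeds[0]))
    dataset = LabeledDataset(space).with_round(combos, label(combos))
    traj.record(1, dataset.objectives())

    for r in range(2, rounds + 1):
        cand_seed, model_seed = int(seeds[3 * r]), int(seeds[3 * r + 1])
        if algorithm == "random":
            chosen = space.sample(per_round, seed=cand_seed,
                                  exclude=dataset.combinations())
        else:
            candidates = space.sample(n_candidates, seed=cand_seed,
                                      exclude=dataset.combinations())
            model = _make_family(algorithm, ensemble_size, grid, model_seed)
            X, y, _ = dataset.encoded()
            model.fit(X, y)
            Xc, _ = space.encode(candidates)
            summary = model.predict_summary(Xc)
            cfg = AcquisitionConfig(
                exploitation=exploitation,
                exploration=exploration_schedule(r, rounds, exploration_start,
                                                 exploration_end),
                n_candidates=n_candidates,
                n_suggest=min(per_round, len(candidates)), seed=cand_seed)
            scores = ucb_score(summary, cfg)
            order = np.argsort(-scores, kind="stable")[:cfg.n_suggest]
            chosen = [candidates[i] for i in order]
        new_y = label(chosen)
        dataset = dataset.with_round(chosen, new_y)
        traj.record(r, new_y)

    traj.dataset = dataset
    return traj


def benchmark_algorithms(oracle: OracleFunction, space: SearchSpace,
                         families: Sequence[str] = FAMILIES,
                         rounds: int = 10, per_round: int = 100,
                         seeds: Sequence[int] = (0, 1, 2, 3, 4),
                         ensemble_size: int = 5, grid=CAMPAIGN_GRID,
                         n_candidates: int = 100_000,
                         noise_sd: float = 0.0) -> dict:
    """Paired benchmark of surrogate families on one oracle.

    For each seed, every family runs a campaign from the identical Day-1
    random set and identical per-round candidate pools (the pools depend
    only on the seed and the tested set, so arms differing in their picks
    diverge from round 3 onward — the pairing is exact at rounds 1–2 and
    seed-matched after).  Ensemble size defaults to 5, as in small-scale
    algorithm benchmarking.  A family whose backend fails is skipped with a
    warning rather than failing the run.
    """
    unknown = set(families) - set(FAMILIES) - {"random"}
    if unknown:
        raise ValueError(f"unknown families {sorted(unknown)}")
    results: dict[tuple[str, int], Trajectory] = {}
    for s in seeds:
        for family in families:
            try:
                results[(family, s)] = simulate_campaign(
                    oracle, space, rounds=rounds, per_round=per_round,
                    seed=s, algorithm=family, ensemble_size=ensemble_size,
                    grid=grid, n_candidates=n_candidates, noise_sd=noise_sd)
            except Exception as exc:  # pragma: no cover - defensive
                warnings.warn(f"family {family!r} failed on seed {s}: {exc}",
                              UserWarning)
    return results


def benchmark_table(results: dict) -> pd.DataFrame:
    """Long-format comparison table for a :func:`benchmark_algorithms` result."""
    frames = []
    for (family, seed), traj in results.items():
        frame = traj.to_frame()
        frame["seed"] = seed
        frames.append(frame)
    return pd.concat(frames, ignore_index=True)


def simulate_prediction_mode(oracle: OracleFunction, space: SearchSpace,
                             rounds: int = 5, per_round: int = 20,
                             seed: int = 0, probe_size: int = 100,
                             ensemble_size: int = 10, grid=CAMPAIGN_GRID,
                             n_candidates: int = 100_000,
                             noise_sd: float = 0.0) -> list[float]:
    """Uncertainty-driven sampling, scored by held-out probe R² per round.

    A fixed probe set (disjoint from all training data) is drawn first;
    each round picks the max-spread candidates, labels them via the
    oracle, refits, and records the squared Pearson correlation between
    ensemble predictions and truth on the probe.  Returns the per-round R²
    list, which should improve over rounds on a learnable landscape.
    """
    seeds = _round_seeds(seed, rounds + 1)
    probe = space.sample(min(probe_size, max(space.size() - rounds * per_round, 1)),
                         seed=int(seeds[1]))
    probe_truth = oracle.label(probe)
    Xp, _ = space.encode(probe)
    noise_rng = np.random.default_rng(int(seeds[-1]))

    def label(combos):
        y = oracle.label(combos)
        if noise_sd > 0:
            y = y + noise_rng.normal(0.0, noise_sd, size=len(y))
        return y

    combos = space.sample(per_round, seed=int(seeds[0]), exclude=probe)
    dataset = LabeledDataset(space).with_round(combos, label(combos))

    r2_per_round: list[float] = []
    for r in range(1, rounds + 1):
        model_seed = int(seeds[3 * r])
        model = EnsembleRegressor(n_members=ensemble_size, grid=grid,
                                  random_state=model_seed)
        X, y, _ = dataset.encoded()
        model.fit(X, y)
        mu = model.predict(Xp)
        r2_per_round.append(squared_pearson(probe_truth, mu))
        if r == rounds:
            break
        cand_seed = int(seeds[3 * r + 1])
        exclude = dataset.combinations() + list(probe)
        candidates = space.sample(n_candidates, seed=cand_seed, exclude=exclude)
        Xc, _ = space.encode(candidates)
        summary = model.predict_summary(Xc)
        order = np.argsort(-summary.sigma, kind="stable")[:per_round]
        chosen = [candidates[i] for i in order]
        dataset = dataset.with_round(chosen, label(chosen))
    return r2_per_round
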