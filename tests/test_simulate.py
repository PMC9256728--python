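"""Oracles, synthetic landscapes and simulated campaigns."""

import numpy as np
import pandas as pd
import pytest

from activelab import (Factor, SearchSpace, SyntheticLandscapeSpec,
                       benchmark_algorithms, build_gold_regressor,
                       generate_landscape, reference_landscape,
                       simulate_campaign, simulate_prediction_mode)
from activelab.surrogate import CAMPAIGN_GRID

SMALL_GRID = {"n_estimators": (50, 80), "learning_rate": (0.05, 0.1),
              "max_depth": (2, 3), "min_child_weight": (1.0,),
              "subsample": (0.8, 1.0)}


class TestGenerateLandscape:
    def test_additive_optimum_is_per_factor_argmax(self):
        space = SearchSpace([Factor("a", "numeric", (1.0, 2.0)),
                             Factor("b", "numeric", (3.0, 4.0))])
        spec = SyntheticLandscapeSpec(space=space,
                                      main_effects={"a": 1.0, "b": -1.0})
        oracle = generate_landscape(spec)
        comb, value = oracle.known_optimum
        assert comb == {"a": 2.0, "b": 3.0}
        assert value == pytest.approx(2.0 - 3.0)

    def test_interaction_optimum_matches_brute_force(self):
        space = SearchSpace([
            Factor("a", "numeric", (0.0, 1.0, 2.0, 3.0, 4.0)),
            Factor("b", "numeric", (0.0, 1.0, 2.0, 3.0, 4.0))])
        spec = SyntheticLandscapeSpec(
            space=space, main_effects={"a": 1.0, "b": -2.0},
            interactions=[(("a", "b"), 1.0)])
        oracle = generate_landscape(spec)
        values = {space.key(c): oracle(c) for c in space.enumerate()}
        best_key = max(values, key=values.get)
        comb, value = oracle.known_optimum
        assert space.key(comb) == best_key
        assert value == pytest.approx(values[best_key])

    def test_zero_weights_constant_zero(self, tiny_space):
        oracle = generate_landscape(SyntheticLandscapeSpec(space=tiny_space))
        assert all(oracle(c) == 0.0 for c in tiny_space.enumerate())

    def test_categorical_effects(self):
        space = SearchSpace([Factor("p", "categorical", ("x", "y"))])
        spec = SyntheticLandscapeSpec(
            space=space, categorical_effects={"p": {"x": 1.0, "y": 5.0}})
        oracle = generate_landscape(spec)
        assert oracle({"p": "y"}) == 5.0
        assert oracle.known_optimum[0] == {"p": "y"}

    def test_oracle_purity(self):
        oracle, space, _ = reference_landscape()
        comb = space.enumerate()[100]
        values = {oracle(comb) for _ in range(1000)}
        assert len(values) == 1

    def test_unknown_factor_rejected(self, tiny_space):
        with pytest.raises(ValueError, match="non-numeric|unknown"):
            SyntheticLandscapeSpec(space=tiny_space, main_effects={"zz": 1.0})


class TestGoldRegressor:
    def make_table(self, space, n=80, seed=0):
        rng = np.random.default_rng(seed)
        combos = [space.sample(1, seed=int(s))[0]
                  for s in rng.integers(0, 2**31 - 1, size=n)]
        rows = [{**c, "objective": 2 * c["a"] + c["b"] + rng.normal(0, 0.1)}
                for c in combos]
        return pd.DataFrame(rows)

    def test_deterministic_oracle(self, tiny_space):
        table = self.make_table(tiny_space)
        gold = build_gold_regressor(table, tiny_space, seed=0)
        probe = tiny_space.enumerate()[5]
        assert gold(probe) == gold(probe)

    def test_refit_same_seed_identical(self, tiny_space):
        table = self.make_table(tiny_space)
        a = build_gold_regressor(table, tiny_space, seed=1)
        b = build_gold_regressor(table, tiny_space, seed=1)
        probes = tiny_space.enumerate()
        assert np.array_equal(a.label(probes), b.label(probes))

    def test_beats_mean_baseline_on_holdout(self, tiny_space):
        table = self.make_table(tiny_space, n=100, seed=2)
        gold = build_gold_regressor(table, tiny_space, seed=2)
        # same 80/20 split as the builder
        idx = np.random.default_rng(2).permutation(len(table))
        val = table.iloc[idx[:20]]
        combos = [{"a": r["a"], "b": r["b"]} for _, r in val.iterrows()]
        pred = gold.label(combos)
        truth = val["objective"].to_numpy()
        sse_model = np.sum((truth - pred) ** 2)
        sse_mean = np.sum((truth - truth.mean()) ** 2)
        assert sse_model < sse_mean

    def test_too_few_rows_rejected(self, tiny_space):
        with pytest.raises(ValueError, match=">= 50"):
            build_gold_regressor(self.make_table(tiny_space, n=10),
                                 tiny_space, seed=0)


class TestSimulateCampaign:
    def test_single_round_is_random_sampling(self, five_factor_space):
        oracle, space, _ = reference_landscape()
        traj = simulate_campaign(oracle, space, rounds=1, per_round=15, seed=0)
        assert len(traj.rounds) == 1
        assert len(traj.dataset) == 15

    def test_cumulative_best_non_decreasing(self):
        oracle, space, noise = reference_landscape()
        traj = simulate_campaign(oracle, space, rounds=4, per_round=10, seed=1,
                                 ensemble_size=3, grid=SMALL_GRID,
                                 n_candidates=200, noise_sd=noise)
        best = traj.cumulative_best
        assert all(b >= a for a, b in zip(best, best[1:]))

    def test_bit_reproducible(self):
        oracle, space, noise = reference_landscape()
        kwargs = dict(rounds=3, per_round=8, seed=7, ensemble_size=3,
                      grid=SMALL_GRID, n_candidates=100, noise_sd=noise)
        a = simulate_campaign(oracle, space, **kwargs)
        b = simulate_campaign(oracle, space, **kwargs)
        assert a.to_frame().equals(b.to_frame())
        assert a.dataset.records == b.dataset.records

    def test_rounds_are_disjoint_conditions(self):
        oracle, space, _ = reference_landscape()
        traj = simulate_campaign(oracle, space, rounds=3, per_round=10, seed=2,
                                 ensemble_size=3, grid=SMALL_GRID,
                                 n_candidates=200)
        keys = [space.key(c) for c in traj.dataset.combinations()]
        assert len(set(keys)) == len(keys)


class TestBenchmark:
    def test_paired_day1_and_linear_sigma(self):
        oracle, space, noise = reference_landscape()
        results = benchmark_algorithms(
            oracle, space, families=("tree-ensemble", "linear"), rounds=2,
            per_round=8, seeds=(0,), ensemble_size=3, grid=SMALL_GRID,
            n_candidates=100, noise_sd=noise)
        tree = results[("tree-ensemble", 0)]
        linear = results[("linear", 0)]
        # identical random Day-1 conditions across families
        assert [space.key(c) for c in tree.dataset.upto_round(1).combinations()] == \
            [space.key(c) for c in linear.dataset.upto_round(1).combinations()]

    def test_linear_family_has_zero_spread(self):
        from activelab.simulate import _make_family
        oracle, space, _ = reference_landscape()
        fam = _make_family("linear", 5, None, seed=0)
        combos = space.sample(30, seed=0)
        X, _ = space.encode(combos)
        fam.fit(X, oracle.label(combos))
        summary = fam.predict_summary(X)
        assert np.allclose(summary.sigma, 0.0)

    def test_unknown_family_rejected(self):
        oracle, space, _ = reference_landscape()
        with pytest.raises(ValueError, match="unknown"):
            benchmark_algorithms(oracle, space, families=("boltzmann",),
                                 rounds=1, per_round=5, seeds=(0,))


class TestPredictionMode:
    def test_single_round_single_r2(self):
        oracle, space, noise = reference_landscape()
        r2 = simulate_prediction_mode(oracle, space, rounds=1, per_round=15,
                                      seed=0, probe_size=40, ensemble_size=3,
                                      grid=SMALL_GRID, n_candidates=200,
                                      noise_sd=noise)
        assert len(r2) == 1 and 0.0 <= r2[0] <= 1.0

    def test_reproducible(self):
        oracle, space, noise = reference_landscape()
        kwargs = dict(rounds=2, per_round=10, seed=3, probe_size=30,
                      ensemble_size=3, grid=SMALL_GRID, n_candidates=150,
                      noise_sd=noise)
        assert simulate_prediction_mode(oracle, space, **kwargs) == \
            simulate_prediction_mode(oracle, space, **kwargs)
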