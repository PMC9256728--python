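"""UCB scoring, round suggestion and its exhaustive-scoring equivalence."""

import numpy as np
import pytest

from activelab import (AcquisitionConfig, LabeledDataset, PredictionSummary,
                       batch_ucb_suggest, initialize_round, suggest_round,
                       ucb_score, uncertainty_suggest)
from activelab.acquisition import exploration_schedule
from activelab.surrogate import CAMPAIGN_GRID
from conftest import make_signal_dataset

FAST = dict(ensemble_size=4, n_draws=4, grid=CAMPAIGN_GRID)


def small_dataset(space, seed=0, n=30):
    return make_signal_dataset(
        space, n, seed=seed,
        signal=lambda c: 2.0 * c[space.names[0]] + c[space.names[1]])


class TestUcbScore:
    @pytest.mark.parametrize("mu,sigma,w_mu,w_sd,expected", [
        (10.0, 2.0, 1.0, 0.0, 10.0),    # pure exploitation
        (0.0, 3.0, 0.0, 2.0, 6.0),      # pure exploration
        (1.5, 0.5, 1.0, 1.41, 2.205),   # mixed weights
    ])
    def test_arithmetic(self, mu, sigma, w_mu, w_sd, expected):
        summary = PredictionSummary(mu=[mu], sigma=[sigma])
        config = AcquisitionConfig(exploitation=w_mu, exploration=w_sd)
        assert ucb_score(summary, config)[0] == pytest.approx(expected)

    def test_weights_must_not_both_vanish(self):
        with pytest.raises(ValueError):
            AcquisitionConfig(exploitation=0.0, exploration=0.0)

    def test_raising_exploration_never_demotes_max_sigma_candidate(self):
        rng = np.random.default_rng(0)
        summary = PredictionSummary(mu=rng.normal(size=50),
                                    sigma=rng.random(50))
        i_max = int(np.argmax(summary.sigma))
        last_rank = None
        for w in (0.0, 0.5, 1.0, 2.0, 5.0):
            scores = ucb_score(summary, AcquisitionConfig(exploitation=1.0,
                                                          exploration=w))
            rank = int(np.where(np.argsort(-scores) == i_max)[0][0])
            if last_rank is not None:
                assert rank <= last_rank
            last_rank = rank


class TestSuggestRound:
    def test_exploration_zero_ranks_by_mu(self, tiny_space):
        ds = small_dataset(tiny_space, n=8)
        cfg = AcquisitionConfig(exploitation=1.0, exploration=0.0,
                                n_candidates=100, n_suggest=4, seed=1)
        plan = suggest_round(ds, tiny_space, cfg, **FAST)
        assert np.allclose(plan.scores, plan.mu)
        assert np.all(np.diff(plan.scores) <= 1e-12)

    def test_matches_exhaustive_scoring_on_enumerable_space(self, tiny_space):
        """With the candidate pool covering the whole untested space, the
        suggestions must equal the top-n of exhaustive UCB scoring."""
        ds = small_dataset(tiny_space, n=6)
        cfg = AcquisitionConfig(exploitation=1.0, exploration=1.0,
                                n_candidates=1000, n_suggest=3, seed=2)
        plan = suggest_round(ds, tiny_space, cfg, **FAST)

        tested = ds.keys()
        pool = [c for c in tiny_space.enumerate()
                if tiny_space.key(c) not in tested]
        X, _ = tiny_space.encode(pool)
        summary = plan.ensemble.predict_summary(X)
        scores = ucb_score(summary, cfg)
        want = sorted(scores)[-3:]
        assert np.allclose(sorted(plan.scores), want)
        top_keys = {tiny_space.key(pool[i]) for i in np.argsort(-scores)[:3]}
        assert {tiny_space.key(c) for c in plan.suggestions} == top_keys

    def test_deterministic_given_seed(self, tiny_space):
        ds = small_dataset(tiny_space, n=8)
        cfg = AcquisitionConfig(n_candidates=50, n_suggest=3, seed=5)
        a = suggest_round(ds, tiny_space, cfg, **FAST)
        b = suggest_round(ds, tiny_space, cfg, **FAST)
        assert a.suggestions == b.suggestions
        assert np.array_equal(a.scores, b.scores)

    def test_excludes_tested_by_default(self, tiny_space):
        ds = small_dataset(tiny_space, n=8)
        cfg = AcquisitionConfig(n_candidates=1000, n_suggest=4, seed=0)
        plan = suggest_round(ds, tiny_space, cfg, **FAST)
        assert not ({tiny_space.key(c) for c in plan.suggestions} & ds.keys())

    def test_pool_smaller_than_request_warns(self, tiny_space):
        ds = small_dataset(tiny_space, n=8)
        cfg = AcquisitionConfig(n_candidates=1000, n_suggest=10, seed=0)
        with pytest.warns(UserWarning, match="remain"):
            plan = suggest_round(ds, tiny_space, cfg, **FAST)
        assert len(plan.suggestions) == 12 - len(ds.keys())

    def test_specials_appended_unscored(self, tiny_space):
        ds = small_dataset(tiny_space, n=8)
        control = {"a": 2.0, "b": 1.0}
        cfg = AcquisitionConfig(n_candidates=20, n_suggest=2, seed=0)
        plan = suggest_round(ds, tiny_space, cfg, specials=[control], **FAST)
        assert plan.specials == [control]
        assert len(plan.scores) == 2


class TestInitializeRound:
    def test_n_equals_space_size_returns_all(self):
        from activelab import Factor, SearchSpace
        space = SearchSpace([Factor(n, "numeric", (0.0, 1.0)) for n in "ab"])
        plan = initialize_round(space, 4, seed=0)
        assert {space.key(c) for c in plan.suggestions} == \
            {space.key(c) for c in space.enumerate()}
        assert plan.round_index == 1

    def test_seeded_repeatability(self, tiny_space):
        a = initialize_round(tiny_space, 5, seed=11)
        b = initialize_round(tiny_space, 5, seed=11)
        assert a.suggestions == b.suggestions

    def test_per_level_frequencies_uniform(self):
        from activelab import Factor, SearchSpace
        space = SearchSpace([
            Factor("a", "numeric", (0.0, 1.0, 2.0, 3.0)),
            Factor("b", "numeric", tuple(float(i) for i in range(50))),
            Factor("c", "numeric", tuple(float(i) for i in range(50))),
        ])
        plan = initialize_round(space, 10_000, seed=0)
        counts = np.zeros(4)
        for c in plan.suggestions:
            counts[int(c["a"])] += 1
        freqs = counts / counts.sum()
        assert np.all(np.abs(freqs - 0.25) < 0.02)


class TestUncertaintySuggest:
    def test_equivalent_to_sigma_only_ucb(self, tiny_space):
        ds = small_dataset(tiny_space, n=8)
        cfg = AcquisitionConfig(exploitation=1.0, exploration=1.0,
                                n_candidates=100, n_suggest=3, seed=4)
        plan = uncertainty_suggest(ds, tiny_space, cfg, **FAST)
        sigma_cfg = AcquisitionConfig(exploitation=0.0, exploration=1.0,
                                      n_candidates=100, n_suggest=3, seed=4)
        ref = suggest_round(ds, tiny_space, sigma_cfg, **FAST)
        assert plan.suggestions == ref.suggestions
        assert np.allclose(plan.scores, plan.sigma)

    def test_returns_fitted_ensemble(self, tiny_space):
        ds = small_dataset(tiny_space, n=8)
        cfg = AcquisitionConfig(n_candidates=50, n_suggest=2, seed=0)
        plan = uncertainty_suggest(ds, tiny_space, cfg, **FAST)
        assert plan.ensemble is not None and hasattr(plan.ensemble, "members_")

    def test_suggested_sigma_above_random_baseline(self, five_factor_space):
        ds = small_dataset(five_factor_space, n=40)
        cfg = AcquisitionConfig(n_candidates=300, n_suggest=10, seed=3)
        plan = uncertainty_suggest(ds, five_factor_space, cfg, **FAST)
        pool = five_factor_space.sample(10, seed=99, exclude=ds.combinations())
        X, _ = five_factor_space.encode(pool)
        random_sigma = plan.ensemble.predict_summary(X).sigma
        assert plan.sigma.mean() >= random_sigma.mean()


class TestBatchUcb:
    def test_batch_of_one_matches_plain_top_pick(self, tiny_space):
        ds = small_dataset(tiny_space, n=8)
        cfg = AcquisitionConfig(n_candidates=100, n_suggest=1, seed=6)
        batch = batch_ucb_suggest(ds, tiny_space, cfg, **FAST)
        plain = suggest_round(ds, tiny_space, cfg, **FAST)
        assert batch.suggestions == plain.suggestions

    def test_deterministic_and_distinct(self, tiny_space):
        ds = small_dataset(tiny_space, n=6)
        cfg = AcquisitionConfig(n_candidates=100, n_suggest=3, seed=7)
        a = batch_ucb_suggest(ds, tiny_space, cfg, **FAST)
        b = batch_ucb_suggest(ds, tiny_space, cfg, **FAST)
        assert a.suggestions == b.suggestions
        keys = {tiny_space.key(c) for c in a.suggestions}
        assert len(keys) == 3


def test_exploration_schedule_decreases():
    values = [exploration_schedule(r, 10, start=1.0, end=0.0)
              for r in range(2, 11)]
    assert values[0] == 1.0 and values[-1] == 0.0
    assert all(b <= a for a, b in zip(values, values[1:]))
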