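"""UCB acquisition: scoring candidates and assembling round plans.

Each active-learning round scores a random candidate pool with the upper
confidence bound

    UCB = exploitation * mu + exploration * sigma

where mu/sigma are the surrogate ensemble's mean and spread.  A high mean
weighs conditions predicted to perform well (exploitation); a high spread
weighs conditions the model is uncertain about (exploration).  The ratio
of the two weights is scheduled per round and should in general decrease
towards the late rounds.  "Prediction mode" replaces UCB with sigma alone:
it maximizes model quality rather than the objective.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .space import Combination, LabeledDataset, SearchSpace
from .surrogate import (
    DEFAULT_GRID,
    EnsembleRegressor,
    PredictionSummary,
    fit_ensemble,
    tune_hyperparameters,
)

__all__ = [
    "AcquisitionConfig",
    "RoundPlan",
    "ucb_score",
    "suggest_round",
    "initialize_round",
    "uncertainty_suggest",
    "batch_ucb_suggest",
    "exploration_schedule",
]


@dataclass(frozen=True)
class AcquisitionConfig:
    """Exploration/exploitation weights and pool sizes for one round."""

    exploitation: float = 1.0
    exploration: float = 1.0
    n_candidates: int = 100_000
    n_suggest: int = 20
    seed: int = 0

    def __post_init__(self):
        if self.exploitation < 0 or self.exploration < 0:
            raise ValueError("acquisition weights must be non-negative")
        if self.exploitation + self.exploration <= 0:
            raise ValueError("at least one acquisition weight must be positive")
        if self.n_suggest < 1:
            raise ValueError("n_suggest must be >= 1")


@dataclass
class RoundPlan:
    """Suggested experiments for one round.

    ``suggestions`` are distinct valid combinations sorted by non-increasing
    UCB score, with their predicted mean, spread and score; ``specials`` are
    user-pinned control conditions appended unscored.  The fitted ensemble
    that produced the scores is kept on the plan (``ensemble``) for
    downstream use; it is never written to round files.
    """

    round_index: int
    suggestions: list[Combination]
    mu: np.ndarray
    sigma: np.ndarray
    scores: np.ndarray
    specials: list[Combination] = field(default_factory=list)
    replicates: int = 1
    ensemble: EnsembleRegressor | None = None

    def __post_init__(self):
        self.mu = np.asarray(self.mu, dtype=float)
        self.sigma = np.asarray(self.sigma, dtype=float)
        self.scores = np.asarray(self.scores, dtype=float)
        n = len(self.suggestions)
        if not (len(self.mu) == len(self.sigma) == len(self.scores) == n):
            raise ValueError("mu/sigma/scores must match the suggestion count")
        if np.any(np.diff(self.scores) > 1e-12):
            raise ValueError("suggestions must be sorted by non-increasing score")

    def all_combinations(self) -> list[Combination]:
        return list(self.suggestions) + list(self.specials)


def ucb_score(summary: PredictionSummary, config: AcquisitionConfig) -> np.ndarray:
    """Elementwise ``exploitation * mu + exploration * sigma``."""
    return config.exploitation * summary.mu + config.exploration * summary.sigma


def exploration_schedule(round_index: int, total_rounds: int,
                         start: float = 1.0, end: float = 0.0) -> float:
    """Default linearly decreasing exploration weight across a campaign.

    Early rounds explore; late rounds exploit.  ``round_index`` counts from
    2 (round 1 is random initialization and uses no acquisition).
    """
    if total_rounds <= 2:
        return end
    t = (round_index - 2) / (total_rounds - 2)
    return float(start + (end - start) * min(max(t, 0.0), 1.0))


def _rank_and_take(candidates: list[Combination], summary: PredictionSummary,
                   scores: np.ndarray, n_suggest: int):
    """Top-n by score; ties broken by candidate pool order (stable sort)."""
    order = np.argsort(-scores, kind="stable")[:n_suggest]
    return ([candidates[i] for i in order], summary.mu[order],
            summary.sigma[order], scores[order])


def _prepare(dataset: LabeledDataset, space: SearchSpace,
             config: AcquisitionConfig, ensemble_size: int, n_draws: int | None,
             grid, exclude_tested: bool):
    """Shared tune → fit → sample pipeline for the suggestion operations."""
    if len(dataset) == 0:
        raise ValueError("dataset is empty; use initialize_round for round 1")
    n_draws = ensemble_size if n_draws is None else n_draws
    configs = tune_hyperparameters(dataset, n_configs=ensemble_size,
                                   n_draws=n_draws, seed=config.seed, grid=grid)
    ensemble = fit_ensemble(dataset, configs, seed=config.seed)
    exclude = dataset.combinations() if exclude_tested else ()
    candidates = space.sample(config.n_candidates, seed=config.seed,
                              exclude=exclude)
    X, _ = space.encode(candidates)
    summary = ensemble.predict_summary(X)
    return ensemble, candidates, summary


def suggest_round(dataset: LabeledDataset, space: SearchSpace,
                  config: AcquisitionConfig,
                  specials: Sequence[Combination] = (),
                  ensemble_size: int = 20, n_draws: int | None = None,
                  grid=DEFAULT_GRID, exclude_tested: bool = True,
                  replicates: int = 1) -> RoundPlan:
    """One full acquisition round: tune, fit, sample, score, rank.

    Tunes hyperparameters on all data so far, fits the ensemble, samples up
    to ``config.n_candidates`` distinct candidates (excluding already
    tested combinations by default), scores them by UCB and returns the top
    ``config.n_suggest`` plus the unscored `specials`.  Fully deterministic
    given ``config.seed``.
    """
    ensemble, candidates, summary = _prepare(
        dataset, space, config, ensemble_size, n_draws, grid, exclude_tested)
    n_suggest = config.n_suggest
    if n_suggest > len(candidates):
        warnings.warn(f"requested {n_suggest} suggestions but only "
                      f"{len(candidates)} candidates remain; returning all",
                      UserWarning)
        n_suggest = len(candidates)
    scores = ucb_score(summary, config)
    top, mu, sigma, sc = _rank_and_take(candidates, summary, scores, n_suggest)
    return RoundPlan(round_index=dataset.n_rounds + 1, suggestions=top,
                     mu=mu, sigma=sigma, scores=sc, specials=list(specials),
                     replicates=replicates, ensemble=ensemble)


def initialize_round(space: SearchSpace, n: int, seed: int = 0,
                     specials: Sequence[Combination] = (),
                     replicates: int = 1) -> RoundPlan:
    """Round 1: n distinct uniform-random combinations, unscored."""
    combos = space.sample(n, seed=seed)
    zeros = np.zeros(len(combos))
    return RoundPlan(round_index=1, suggestions=combos, mu=zeros,
                     sigma=zeros.copy(), scores=zeros.copy(),
                     specials=list(specials), replicates=replicates)


def uncertainty_suggest(dataset: LabeledDataset, space: SearchSpace,
                        config: AcquisitionConfig,
                        ensemble_size: int = 20, n_draws: int | None = None,
                        grid=DEFAULT_GRID,
                        exclude_tested: bool = True) -> RoundPlan:
    """Prediction-mode acquisition: rank candidates by sigma alone.

    Equivalent to :func:`suggest_round` with exploitation 0 and exploration
    1; the fitted ensemble rides along on the returned plan, since in
    prediction mode the trained model — not the suggestions — is the
    product of interest.
    """
    cfg = replace(config, exploitation=0.0, exploration=1.0)
    return suggest_round(dataset, space, cfg, ensemble_size=ensemble_size,
                         n_draws=n_draws, grid=grid,
                         exclude_tested=exclude_tested)


def batch_ucb_suggest(dataset: LabeledDataset, space: SearchSpace,
                      config: AcquisitionConfig,
                      ensemble_size: int = 20, n_draws: int | None = None,
                      grid=DEFAULT_GRID,
                      exclude_tested: bool = True) -> RoundPlan:
    """Greedy batch UCB ("constant liar"): re-estimate spread after each pick.

    Optional variant of :func:`suggest_round` for batched rounds: after
    each pick the chosen candidate is added to the training set with its
    predicted mean as a provisional label and the ensemble is refitted, so
    the spread collapses around picked points and near-duplicate picks are
    avoided.  Noticeably more expensive than plain UCB (one ensemble refit
    per pick).  This is a standard sequential-batch heuristic, not a
    canonical part of the core loop; default entry points keep it off.
    """
    ensemble, candidates, summary = _prepare(
        dataset, space, config, ensemble_size, n_draws, grid, exclude_tested)
    configs = ensemble.configs_
    work = dataset
    remaining = list(candidates)
    picked, mus, sigmas, scores = [], [], [], []
    n_suggest = min(config.n_suggest, len(remaining))
    for _ in range(n_suggest):
        X, _ = space.encode(remaining)
        summary = ensemble.predict_summary(X)
        sc = ucb_score(summary, config)
        i = int(np.argsort(-sc, kind="stable")[0])
        picked.append(remaining[i])
        mus.append(summary.mu[i])
        sigmas.append(summary.sigma[i])
        scores.append(sc[i])
        work = work.with_round([remaining[i]], [summary.mu[i]],
                               round_index=work.n_rounds)  # provisional label
        del remaining[i]
        if remaining:
            ensemble = fit_ensemble(work, configs, seed=config.seed)
    order = np.argsort(-np.asarray(scores), kind="stable")
    return RoundPlan(round_index=dataset.n_rounds + 1,
                     suggestions=[picked[i] for i in order],
                     mu=np.asarray(mus)[order], sigma=np.asarray(sigmas)[order],
                     scores=np.asarray(scores)[order], ensemble=ensemble)
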