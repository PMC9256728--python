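"""Gradient-boosted tree surrogate ensembles with uncertainty estimates.

The surrogate for the active-learning loop is an *ensemble* of XGBoost
regressors whose members differ by hyperparameters (and optionally by
random seed).  The spread of member predictions at a candidate condition
is the model's uncertainty estimate: the per-candidate mean feeds
exploitation and the per-candidate standard deviation feeds exploration
in the UCB acquisition score.

:class:`EnsembleRegressor` is a scikit-learn estimator (``fit`` /
``predict`` / ``get_params``) so it composes with sklearn model selection;
the module-level functions (:func:`tune_hyperparameters`,
:func:`fit_ensemble`, :func:`predict`, :func:`cross_validate`,
:func:`feature_importance`) are thin wrappers operating on
:class:`~activelab.space.LabeledDataset`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, asdict
from typing import Mapping, Sequence

import numpy as np
from scipy import stats
from sklearn.base import BaseEstimator, RegressorMixin, clone
from sklearn.model_selection import KFold
from sklearn.utils.validation import check_is_fitted, validate_data
from xgboost import XGBRegressor

from .space import LabeledDataset, Combination

__all__ = [
    "HyperparameterConfig",
    "GOLD_CONFIG",
    "DEFAULT_GRID",
    "CAMPAIGN_GRID",
    "EnsembleRegressor",
    "PredictionSummary",
    "FeatureImportanceReport",
    "tune_hyperparameters",
    "fit_ensemble",
    "predict",
    "cross_validate",
    "feature_importance",
    "squared_pearson",
]


@dataclass(frozen=True)
class HyperparameterConfig:
    """One XGBoost regressor configuration."""

    n_estimators: int = 500
    learning_rate: float = 0.01
    max_depth: int = 6
    min_child_weight: float = 1.0
    subsample: float = 0.8
    objective_name: str = "reg:squarederror"

    def __post_init__(self):
        if self.n_estimators < 1 or self.max_depth < 1:
            raise ValueError("n_estimators and max_depth must be positive")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if not 0 < self.subsample <= 1:
            raise ValueError("subsample must lie in (0, 1]")

    def make_regressor(self, seed: int = 0) -> XGBRegressor:
        return XGBRegressor(
            objective=self.objective_name,
            n_estimators=self.n_estimators,
            learning_rate=self.learning_rate,
            max_depth=self.max_depth,
            min_child_weight=self.min_child_weight,
            subsample=self.subsample,
            tree_method="hist",
            n_jobs=1,
            random_state=int(seed) % (2**31 - 1),
            importance_type="gain",
        )


#: Fixed configuration used for the gold-regressor oracle and as the
#: fallback/default single model.
GOLD_CONFIG = HyperparameterConfig()

#: Randomized-search grid for the optimization loop (overridable).
DEFAULT_GRID: Mapping[str, Sequence] = {
    "n_estimators": (100, 200, 300, 400, 500, 600, 700, 800),
    "learning_rate": tuple(np.geomspace(0.005, 0.3, 8).round(5)),
    "max_depth": tuple(range(2, 11)),
    "min_child_weight": (1.0, 2.0, 3.0, 5.0, 8.0, 10.0),
    "subsample": (0.5, 0.6, 0.7, 0.8, 0.9, 1.0),
}

#: Lighter grid sized for small per-round budgets (tens of points per
#: round); used by the simulation harness.
CAMPAIGN_GRID: Mapping[str, Sequence] = {
    "n_estimators": (100, 150, 200, 300),
    "learning_rate": tuple(np.geomspace(0.01, 0.3, 6).round(5)),
    "max_depth": (2, 3, 4, 5, 6),
    "min_child_weight": (1.0, 2.0, 3.0, 5.0),
    "subsample": (0.6, 0.7, 0.8, 0.9, 1.0),
}


@dataclass(frozen=True)
class PredictionSummary:
    """Per-candidate ensemble mean and spread.

    ``sigma`` is the population standard deviation over ensemble members
    (divisor = member count), so it is exactly 0 when all members agree.
    """

    mu: np.ndarray
    sigma: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "mu", np.asarray(self.mu, dtype=float))
        object.__setattr__(self, "sigma", np.asarray(self.sigma, dtype=float))
        if self.mu.shape != self.sigma.shape:
            raise ValueError("mu and sigma must have identical shape")
        if np.any(self.sigma < 0):
            raise ValueError("sigma must be non-negative")


@dataclass(frozen=True)
class FeatureImportanceReport:
    """Per-factor importance percentages for one cumulative round.

    Percentages are non-negative and sum to 100: one-hot indicator columns
    are folded back onto their parent factor before normalization.
    """

    percentages: Mapping[str, float]
    round_index: int

    def __post_init__(self):
        total = sum(self.percentages.values())
        if abs(total - 100.0) > 1e-6:
            raise ValueError(f"importance percentages sum to {total}, not 100")
        if any(v < 0 for v in self.percentages.values()):
            raise ValueError("importance percentages must be non-negative")


def squared_pearson(y_true: np.ndarray, y_pred: np.ndarray) -> float:
    """Squared Pearson correlation between predictions and truth.

    Returns 0.0 (with a warning upstream where relevant) when either
    argument is constant, where the correlation is undefined.
    """
    y_true = np.asarray(y_true, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    if y_true.size < 2 or np.ptp(y_true) == 0 or np.ptp(y_pred) == 0:
        return 0.0
    r = stats.pearsonr(y_true, y_pred).statistic
    return float(r * r)


class EnsembleRegressor(RegressorMixin, BaseEstimator):
    """Ensemble of gradient-boosted tree regressors with predictive spread.

    Members are built either from an explicit list of
    :class:`HyperparameterConfig` (``configs``) or drawn at random from a
    hyperparameter grid (``n_members`` draws from ``grid``).  ``predict``
    returns the member mean; with ``return_std=True`` it also returns the
    population standard deviation across members, the uncertainty signal
    consumed by the UCB acquisition.

    Parameters
    ----------
    configs : sequence of HyperparameterConfig, optional
        Explicit member configurations.  When omitted, ``n_members``
        configurations are drawn uniformly from ``grid``.
    n_members : int, default 20
        Ensemble size when drawing configs from the grid.
    grid : mapping, optional
        Hyperparameter grid; defaults to :data:`DEFAULT_GRID`.
    vary_seed : bool, default True
        Give each member its own fit seed in addition to its
        hyperparameters (members with identical configs then still differ).
    random_state : int, default 0

    Attributes
    ----------
    members_ : list of fitted XGBRegressor
    configs_ : list of HyperparameterConfig actually used
    n_features_in_ : int
    """

    def __init__(self, configs=None, n_members: int = 20, grid=None,
                 vary_seed: bool = True, random_state: int = 0):
        self.configs = configs
        self.n_members = n_members
        self.grid = grid
        self.vary_seed = vary_seed
        self.random_state = random_state

    def fit(self, X, y):
        X, y = validate_data(self, X, y, y_numeric=True)
        if not np.all(np.isfinite(y)):
            bad = np.flatnonzero(~np.isfinite(np.asarray(y, dtype=float)))
            raise ValueError(f"non-finite objective values at rows {bad.tolist()}")
        if self.configs is not None:
            configs = list(self.configs)
            if not configs:
                raise ValueError("configs must be non-empty when given")
        else:
            rng = np.random.default_rng(self.random_state)
            configs = draw_configs(self.n_members, rng,
                                   self.grid if self.grid is not None else DEFAULT_GRID)
        seed_rng = np.random.default_rng(self.random_state)
        seeds = (seed_rng.integers(0, 2**31 - 1, size=len(configs))
                 if self.vary_seed else np.full(len(configs), self.random_state))
        self.configs_ = configs
        self.members_ = []
        for cfg, seed in zip(configs, seeds):
            member = cfg.make_regressor(seed=int(seed))
            member.fit(X, y)
            self.members_.append(member)
        return self

    def _member_matrix(self, X) -> np.ndarray:
        check_is_fitted(self, "members_")
        X = validate_data(self, X, reset=False)
        return np.vstack([m.predict(X) for m in self.members_])

    def predict(self, X, return_std: bool = False):
        preds = self._member_matrix(X)
        mu = preds.mean(axis=0)
        if not return_std:
            return mu
        sigma = preds.std(axis=0)  # population std: zero iff members agree
        return mu, sigma

    def predict_summary(self, X) -> PredictionSummary:
        mu, sigma = self.predict(X, return_std=True)
        return PredictionSummary(mu=mu, sigma=sigma)

    def feature_importances_per_column(self) -> np.ndarray:
        """Mean gain-based importance per encoded column across members."""
        check_is_fitted(self, "members_")
        imps = np.vstack([m.feature_importances_ for m in self.members_])
        return imps.mean(axis=0)


def draw_configs(n: int, rng: np.random.Generator,
                 grid: Mapping[str, Sequence] = DEFAULT_GRID) -> list[HyperparameterConfig]:
    """Draw `n` random configurations uniformly from `grid` (with repeats)."""
    out = []
    for _ in range(n):
        out.append(HyperparameterConfig(
            n_estimators=int(rng.choice(grid["n_estimators"])),
            learning_rate=float(rng.choice(grid["learning_rate"])),
            max_depth=int(rng.choice(grid["max_depth"])),
            min_child_weight=float(rng.choice(grid["min_child_weight"])),
            subsample=float(rng.choice(grid["subsample"])),
        ))
    return out


def _cv_score_config(cfg: HyperparameterConfig, X: np.ndarray, y: np.ndarray,
                     seed: int, k: int = 3) -> float:
    """Mean squared-Pearson CV score of one config (internal tuning metric)."""
    k = min(k, len(y))
    scores = []
    for train, test in KFold(n_splits=k, shuffle=True, random_state=seed).split(X):
        model = cfg.make_regressor(seed=seed)
        model.fit(X[train], y[train])
        scores.append(squared_pearson(y[test], model.predict(X[test])))
    return float(np.mean(scores))


def tune_hyperparameters(dataset: LabeledDataset, n_configs: int = 20,
                         n_draws: int = 40, seed: int = 0,
                         grid: Mapping[str, Sequence] = DEFAULT_GRID,
                         ) -> list[HyperparameterConfig]:
    """Randomized hyperparameter search: the `n_configs` best of `n_draws`.

    Draws ``n_draws`` random configurations from `grid`, scores each by
    internal 3-fold cross-validation (squared Pearson) on the dataset, and
    returns the best-scoring distinct configurations, ties broken by draw
    order.  With ``n_draws == n_configs`` all draws are returned unscored
    (a pure random-hyperparameter ensemble).  On datasets too small for
    internal CV the fixed default configuration list is returned with a
    warning.
    """
    if n_configs < 1:
        raise ValueError("n_configs must be >= 1")
    if n_draws < n_configs:
        raise ValueError("n_draws must be >= n_configs")
    rng = np.random.default_rng(seed)
    drawn = draw_configs(n_draws, rng, grid)
    # distinct, keeping first occurrence (draw order)
    distinct: list[HyperparameterConfig] = []
    for cfg in drawn:
        if cfg not in distinct:
            distinct.append(cfg)

    if len(dataset) < 5:
        warnings.warn("dataset too small for internal cross-validation; "
                      "returning default configurations", UserWarning)
        return [GOLD_CONFIG] * n_configs

    if n_draws == n_configs:
        return drawn

    X, y, _ = dataset.encoded()
    scores = [_cv_score_config(cfg, X, y, seed=int(seed)) for cfg in distinct]
    order = sorted(range(len(distinct)), key=lambda i: (-scores[i], i))
    chosen = [distinct[i] for i in order[:n_configs]]
    while len(chosen) < n_configs:  # fewer distinct draws than requested
        chosen.append(chosen[len(chosen) % len(distinct)])
    return chosen


def fit_ensemble(dataset: LabeledDataset, configs: Sequence[HyperparameterConfig],
                 seed: int = 0, vary_seed: bool = True) -> EnsembleRegressor:
    """Fit one ensemble member per config on the full encoded dataset."""
    if not configs:
        raise ValueError("configs must be non-empty")
    X, y, _ = dataset.encoded()
    est = EnsembleRegressor(configs=list(configs), vary_seed=vary_seed,
                            random_state=seed)
    return est.fit(X, y)


def predict(ensemble: EnsembleRegressor, dataset_space,
            combinations: Sequence[Combination]) -> PredictionSummary:
    """Ensemble mean/std summary for a list of combinations."""
    X, _ = dataset_space.encode(combinations)
    return ensemble.predict_summary(X)


def cross_validate(dataset: LabeledDataset, k: int = 5, seed: int = 0,
                   config: HyperparameterConfig = GOLD_CONFIG) -> float:
    """k-fold cross-validated squared Pearson correlation.

    The tested combinations are shuffled into k folds; per fold a fresh
    model is trained on the other k-1 folds and scored on the held-out one
    by the squared Pearson correlation between predictions and truth; the
    fold average is returned.  A fold with constant truth scores 0 with a
    warning (the correlation is undefined there).
    """
    if len(dataset) < k:
        raise ValueError(f"dataset has {len(dataset)} records, fewer than k={k}")
    X, y, _ = dataset.encoded()
    scores = []
    for train, test in KFold(n_splits=k, shuffle=True, random_state=seed).split(X):
        model = config.make_regressor(seed=seed)
        model.fit(X[train], y[train])
        if np.ptp(y[test]) == 0:
            warnings.warn("fold with constant truth: correlation undefined, "
                          "scoring 0", UserWarning)
            scores.append(0.0)
        else:
            scores.append(squared_pearson(y[test], model.predict(X[test])))
    return float(np.mean(scores))


def feature_importance(dataset: LabeledDataset, upto_round: int | None = None,
                       seed: int = 0, n_draws: int = 20,
                       grid: Mapping[str, Sequence] = DEFAULT_GRID,
                       ) -> FeatureImportanceReport:
    """Per-factor importance percentages from a tuned model.

    One model is tuned (best of `n_draws` random configs) and fitted on the
    data accumulated up to ``upto_round``; gain-based importances of the
    encoded columns are summed back onto their parent factors via the
    column map and normalized to percentages summing to 100.  A constant
    objective (all-zero importances) yields uniform percentages with a
    warning.
    """
    r = dataset.n_rounds if upto_round is None else int(upto_round)
    subset = dataset.upto_round(r)
    if len(subset) == 0:
        raise ValueError(f"no records up to round {r}")
    best = tune_hyperparameters(subset, n_configs=1, n_draws=max(n_draws, 1),
                                seed=seed, grid=grid)[0]
    X, y, cmap = subset.encoded()
    model = best.make_regressor(seed=seed)
    model.fit(X, y)
    col_imp = np.asarray(model.feature_importances_, dtype=float)
    per_factor = {name: float(col_imp[list(cols)].sum())
                  for name, cols in cmap.factor_columns.items()}
    total = sum(per_factor.values())
    if total <= 0:
        warnings.warn("all feature importances are zero (constant objective?); "
                      "reporting uniform percentages", UserWarning)
        n = len(per_factor)
        pct = {name: 100.0 / n for name in per_factor}
    else:
        pct = {name: 100.0 * v / total for name, v in per_factor.items()}
    # exact renormalization against accumulated float error
    s = sum(pct.values())
    pct = {name: v * 100.0 / s for name, v in pct.items()}
    return FeatureImportanceReport(percentages=pct, round_index=r)
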