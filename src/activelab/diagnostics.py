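"""Post-hoc analyses: informative subsets, interaction scans, objective transforms.

These are the interpretation tools of the workflow: which K tested
conditions carry the knowledge (to port it to a modified system), which
factor pairs interact non-additively (a hint at mechanism), and the pure
arithmetic transforms that define the objective functions used across
applications — normalized expression yield, fold-change × dynamic range
for gene circuits, catalytic efficiency and fixed-CO2 equivalents for the
CO2-fixation cycle.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from itertools import combinations as iter_combinations
from typing import Sequence

import numpy as np
from scipy import stats
from sklearn.linear_model import LinearRegression, Ridge
from sklearn.metrics import r2_score

from .space import LabeledDataset
from .surrogate import DEFAULT_GRID, tune_hyperparameters

__all__ = [
    "InformativeSubsetQuery",
    "InformativeSubsetReport",
    "InteractionScanResult",
    "binomial_count",
    "k_most_informative",
    "mutual_interactions",
    "normalize_yield",
    "efficiency_transform",
    "co2_equivalents",
    "fold_change_dr_objective",
]


@dataclass(frozen=True)
class InformativeSubsetQuery:
    """Search parameters for the K-most-informative-subset analysis."""

    K: int
    n_subsets: int = 2000
    seed: int = 0

    def __post_init__(self):
        if self.K < 1:
            raise ValueError("K must be >= 1")
        if self.n_subsets < 1:
            raise ValueError("n_subsets must be >= 1")


@dataclass(frozen=True)
class InformativeSubsetReport:
    """Top subsets by Spearman validation score.

    Each entry is ``(member_indices, score)``: a size-K tuple of record
    indices into the tested set and the Spearman rank correlation of a
    model trained on that subset against the truth on the complementary
    (unseen) records.  Sorted by non-increasing score, at most 5 entries.
    """

    top_subsets: tuple
    n_evaluated: int
    K: int

    def __post_init__(self):
        scores = [s for _, s in self.top_subsets]
        if any(b > a for a, b in zip(scores, scores[1:])):
            raise ValueError("top subsets must be sorted by non-increasing score")


@dataclass(frozen=True)
class InteractionScanResult:
    """Baseline linear-model fit and per-pair product-term gains.

    ``deltas`` maps each unordered factor pair ``(i_name, j_name)`` with
    ``i`` before ``j`` in space order to the gain in in-sample R² from
    adding the pair's product feature(s) to the linear baseline.  Since
    adding a regressor cannot lower in-sample OLS R², deltas are
    non-negative up to numerical tolerance; a large delta flags a
    non-additive (mutual) interaction.
    """

    baseline: float
    deltas: dict


def binomial_count(N: int, K: int) -> int:
    """Exact C(N, K) = N!/(K!(N-K)!) as an arbitrary-precision integer."""
    if K > N:
        raise ValueError(f"K={K} exceeds N={N}")
    if K < 0 or N < 0:
        raise ValueError("N and K must be non-negative")
    return math.comb(N, K)


def k_most_informative(dataset: LabeledDataset, query: InformativeSubsetQuery,
                       top: int = 5, grid=DEFAULT_GRID,
                       n_draws: int = 20) -> InformativeSubsetReport:
    """Find size-K subsets of the tested conditions that best predict the rest.

    One set of hyperparameters is tuned on the full dataset; then up to
    ``min(n_subsets, C(N, K))`` distinct random size-K subsets are drawn.
    Per subset a fresh model is trained on the subset alone and validated
    on the complementary (unseen) records by the Spearman rank correlation
    between predictions and truth (ties → average ranks).  The top-`top`
    subsets are reported.  Deterministic given ``query.seed``.

    A subset whose complement has constant truth cannot be scored
    (correlation undefined); it is excluded with a warning.
    """
    N = len(dataset)
    if N < query.K + 2:
        raise ValueError(f"need at least K+2={query.K + 2} records, have {N}")
    total = binomial_count(N, query.K)
    n_subsets = min(query.n_subsets, total)

    best = tune_hyperparameters(dataset, n_configs=1, n_draws=n_draws,
                                seed=query.seed, grid=grid)[0]
    X, y, _ = dataset.encoded()

    rng = np.random.default_rng(query.seed)
    if n_subsets >= total:
        subsets = [tuple(s) for s in iter_combinations(range(N), query.K)]
    else:
        chosen: set[tuple] = set()
        subsets = []
        while len(subsets) < n_subsets:
            s = tuple(sorted(rng.choice(N, size=query.K, replace=False).tolist()))
            if s not in chosen:
                chosen.add(s)
                subsets.append(s)

    scored = []
    for s in subsets:
        mask = np.zeros(N, dtype=bool)
        mask[list(s)] = True
        y_hold = y[~mask]
        if np.ptp(y_hold) == 0:
            warnings.warn(f"subset {s}: complement truth is constant; "
                          "Spearman undefined, subset excluded", UserWarning)
            continue
        model = best.make_regressor(seed=query.seed)
        model.fit(X[mask], y[mask])
        pred = model.predict(X[~mask])
        if np.ptp(pred) == 0:
            rho = 0.0
        else:
            rho = float(stats.spearmanr(y_hold, pred).statistic)
        scored.append((s, rho))

    scored.sort(key=lambda t: (-t[1], t[0]))
    return InformativeSubsetReport(top_subsets=tuple(scored[:top]),
                                   n_evaluated=len(subsets), K=query.K)


def _pair_product_columns(X: np.ndarray, cols_i: Sequence[int],
                          cols_j: Sequence[int]) -> np.ndarray:
    """Product features for one factor pair (all cross products of their
    encoded columns; a single column for numeric×numeric)."""
    return np.column_stack([X[:, a] * X[:, b] for a in cols_i for b in cols_j])


def _linear_r2(X: np.ndarray, y: np.ndarray) -> float:
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = LinearRegression().fit(X, y)
        pred = model.predict(X)
    if not np.all(np.isfinite(pred)):
        warnings.warn("singular design; falling back to ridge regression",
                      UserWarning)
        model = Ridge(alpha=1e-8).fit(X, y)
        pred = model.predict(X)
    return float(r2_score(y, pred))


def mutual_interactions(dataset: LabeledDataset) -> InteractionScanResult:
    """Scan all factor pairs for non-additive (mutual) interactions.

    An ordinary least-squares model on the encoded features gives the
    baseline in-sample R².  For each unordered factor pair the model is
    refitted with the pair's product feature(s) added — a single F_i × F_j
    column for two numeric factors, the joint block of indicator products
    when a categorical factor is involved — and the pair's delta is the
    refitted R² minus the baseline.
    """
    if len(dataset.space) < 2:
        raise ValueError("interaction scan needs at least two factors")
    if len(dataset) < 10:
        raise ValueError("interaction scan needs at least 10 records")
    X, y, cmap = dataset.encoded()
    baseline = _linear_r2(X, y)
    deltas = {}
    names = dataset.space.names
    for i, j in iter_combinations(range(len(names)), 2):
        cols_i = cmap.factor_columns[names[i]]
        cols_j = cmap.factor_columns[names[j]]
        prod = _pair_product_columns(X, cols_i, cols_j)
        score = _linear_r2(np.column_stack([X, prod]), y)
        deltas[(names[i], names[j])] = score - baseline
    return InteractionScanResult(baseline=baseline, deltas=deltas)


# -- objective transforms -----------------------------------------------------------


def normalize_yield(raw: float, blank: float, reference_raw: float,
                    reference_blank: float) -> float:
    """Blank-subtracted fluorescence relative to a reference composition.

    The reference is typically the composition with every variable factor
    at mid-range; the blank is the extract with no DNA.
    """
    denom = reference_raw - reference_blank
    if denom <= 0:
        raise ValueError("reference signal must exceed its blank")
    return (raw - blank) / denom


def efficiency_transform(dataset: LabeledDataset,
                         enzyme_totals: Sequence[float]) -> LabeledDataset:
    """Switch the objective from yield to yield per total enzyme.

    Divides each record's objective by its total enzyme concentration and
    returns a new dataset with rounds and combinations unchanged — ready to
    feed back into the loop for further rounds optimizing *efficiency*
    instead of raw yield (an objective switch mid-campaign).
    """
    totals = np.asarray(list(enzyme_totals), dtype=float)
    if len(totals) != len(dataset):
        raise ValueError("one enzyme total per record required")
    bad = np.flatnonzero(totals <= 0)
    if bad.size:
        raise ValueError(f"non-positive enzyme totals at rows {bad.tolist()}")
    recs = [(r, c, y / t) for (r, c, y), t in zip(dataset.records, totals)]
    return LabeledDataset(dataset.space, recs)


def co2_equivalents(product_conc: float, acceptor_conc: float,
                    co2_per_product: int = 2) -> float:
    """Fixed CO2 equivalents per acceptor molecule.

    ``(product / acceptor) * co2_per_product``; e.g. each glycolate made by
    the CO2-fixation cycle carries two fixed CO2, so product and acceptor
    concentrations in the same unit give equivalents per acceptor.
    """
    if acceptor_conc <= 0:
        raise ValueError("acceptor concentration must be positive")
    return (product_conc / acceptor_conc) * co2_per_product


def fold_change_dr_objective(on_signal: float, off_signal: float
                             ) -> tuple[float, float, float]:
    """Fold-change, dynamic range and their product for a genetic circuit.

    FC = on/off, DR = on − off, objective = FC · DR.  Using the product
    rewards circuits that are both strongly induced and bright in absolute
    terms.
    """
    if off_signal <= 0:
        raise ValueError("off signal must be positive")
    fc = on_signal / off_signal
    dr = on_signal - off_signal
    return fc, dr, fc * dr
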