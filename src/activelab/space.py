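"""Combinatorial search spaces of experimental conditions.

An experiment is described by *factors* — reagent concentrations, part
choices, enzyme amounts — each restricted to a finite, ordered set of
allowed levels.  A :class:`Combination` assigns one level to every factor;
the :class:`SearchSpace` is the Cartesian product of the level sets.
Spaces are finite by construction: continuous ranges must be discretized
by the user before declaring a factor, which keeps the space size exact
and makes uniform candidate sampling well defined even for spaces with
well over 10^25 members.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Factor",
    "SearchSpace",
    "Combination",
    "ColumnMap",
    "LabeledDataset",
    "space_size",
    "enumerate_space",
    "sample_candidates",
    "encode",
    "decode",
]

#: One fully specified experimental condition: factor name -> chosen level.
Combination = Mapping[str, object]

_ENUMERATION_CAP = 10**6


@dataclass(frozen=True)
class Factor:
    """A single experimental variable with a finite set of allowed levels.

    Parameters
    ----------
    name : str
        Identifier; becomes a column name in every table.
    kind : {"numeric", "categorical"}
        Numeric levels are real values on a shared unit scale (strictly
        increasing); categorical levels are labels (e.g. promoter variants).
    levels : tuple
        Allowed values, at least one, pairwise distinct.
    unit : str
        Unit string for numeric factors (e.g. ``"mM"``); empty for
        categorical factors.
    """

    name: str
    kind: str
    levels: tuple = ()
    unit: str = ""

    def __post_init__(self) -> None:
        if not self.name or not isinstance(self.name, str):
            raise ValueError("factor name must be a non-empty string")
        if self.kind not in ("numeric", "categorical"):
            raise ValueError(f"factor {self.name!r}: kind must be 'numeric' or "
                             f"'categorical', got {self.kind!r}")
        levels = tuple(self.levels)
        if len(levels) < 1:
            raise ValueError(f"factor {self.name!r}: needs at least one level")
        if len(set(levels)) != len(levels):
            raise ValueError(f"factor {self.name!r}: levels must be pairwise distinct")
        if self.kind == "numeric":
            vals = [float(v) for v in levels]
            if any(b <= a for a, b in zip(vals, vals[1:])):
                raise ValueError(f"factor {self.name!r}: numeric levels must be "
                                 "strictly increasing")
            levels = tuple(vals)
        object.__setattr__(self, "levels", levels)

    @property
    def n_levels(self) -> int:
        return len(self.levels)


@dataclass(frozen=True)
class ColumnMap:
    """Mapping between encoded feature-matrix columns and factors.

    ``columns`` holds one ``(factor_name, level)`` pair per matrix column;
    ``level`` is ``None`` for the single column of a numeric factor and the
    indicator's level for a one-hot column.  ``factor_columns`` gives, per
    factor, the list of column indices belonging to it — used to fold
    one-hot importances back onto their parent factor.
    """

    columns: tuple
    factor_columns: Mapping[str, tuple] = field(default_factory=dict)

    @property
    def n_columns(self) -> int:
        return len(self.columns)

    def names(self) -> list[str]:
        return [f"{f}={lv}" if lv is not None else f for f, lv in self.columns]


class SearchSpace:
    """Ordered collection of factors; the product of their level sets.

    Factor order is stable and defines the column order of every table and
    feature matrix produced from the space.
    """

    def __init__(self, factors: Sequence[Factor]):
        factors = tuple(factors)
        if not factors:
            raise ValueError("a search space needs at least one factor")
        names = [f.name for f in factors]
        if len(set(names)) != len(names):
            raise ValueError(f"factor names must be unique, got {names}")
        self.factors = factors
        self._by_name = {f.name: f for f in factors}

    @property
    def names(self) -> list[str]:
        return [f.name for f in self.factors]

    def __getitem__(self, name: str) -> Factor:
        return self._by_name[name]

    def __contains__(self, name: str) -> bool:
        return name in self._by_name

    def __len__(self) -> int:
        return len(self.factors)

    def __eq__(self, other) -> bool:
        return isinstance(other, SearchSpace) and self.factors == other.factors

    def __repr__(self) -> str:
        inner = ", ".join(f"{f.name}[{f.n_levels}]" for f in self.factors)
        return f"SearchSpace({inner}; size={self.size()})"

    def size(self) -> int:
        """Exact number of combinations (Python integers, no overflow)."""
        return math.prod(f.n_levels for f in self.factors)

    def validate(self, combination: Combination) -> None:
        """Raise ``ValueError`` unless `combination` assigns a valid level
        to every factor, and nothing else."""
        extra = set(combination) - set(self._by_name)
        if extra:
            raise ValueError(f"unknown factors in combination: {sorted(extra)}")
        for f in self.factors:
            if f.name not in combination:
                raise ValueError(f"combination missing factor {f.name!r}")
            value = combination[f.name]
            if f.kind == "numeric":
                if not any(math.isclose(float(value), lv, rel_tol=1e-9, abs_tol=1e-12)
                           for lv in f.levels):
                    raise ValueError(
                        f"factor {f.name!r}: value {value!r} is not an allowed level")
            elif value not in f.levels:
                raise ValueError(
                    f"factor {f.name!r}: value {value!r} is not an allowed level")

    def key(self, combination: Combination) -> tuple:
        """Hashable identity of a combination (values in factor order)."""
        return tuple(combination[f.name] for f in self.factors)

    def from_key(self, key: Sequence) -> dict:
        return {f.name: v for f, v in zip(self.factors, key)}

    # -- enumeration and sampling -------------------------------------------------

    def enumerate(self, cap: int = _ENUMERATION_CAP) -> list[dict]:
        """All combinations in lexicographic (factor-major) order.

        Refuses spaces larger than `cap` — enumeration of a 10^25 space is
        never what the caller wants.
        """
        n = self.size()
        if n > cap:
            raise ValueError(
                f"space has {n} combinations, above the enumeration cap {cap}")
        out = []
        for values in itertools.product(*(f.levels for f in self.factors)):
            out.append({f.name: v for f, v in zip(self.factors, values)})
        return out

    def sample(
        self,
        n: int,
        seed: int | np.random.Generator,
        exclude: Iterable[Combination] = (),
    ) -> list[dict]:
        """Draw `n` distinct uniform-random combinations.

        The returned list is de-duplicated and disjoint from `exclude`.  If
        the space minus `exclude` holds fewer than `n` distinct members, all
        of them are returned (in enumeration order when the space is small
        enough to enumerate).  Identical seed and inputs give an identical
        list, in draw order.
        """
        if n < 1:
            raise ValueError("n must be >= 1")
        rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
        excluded = {self.key(c) for c in exclude}
        remaining = self.size() - len(excluded)
        if remaining <= 0:
            raise ValueError("search space minus excluded combinations is empty")
        if remaining <= n and self.size() <= _ENUMERATION_CAP:
            return [c for c in self.enumerate() if self.key(c) not in excluded]

        level_counts = [f.n_levels for f in self.factors]
        seen: set[tuple] = set()
        out: list[dict] = []
        draws = 0
        max_draws = max(50 * n, 10_000)
        while len(out) < n and draws < max_draws:
            batch = max(2 * (n - len(out)), 64)
            idx = np.column_stack(
                [rng.integers(0, k, size=batch) for k in level_counts])
            draws += batch
            for row in idx:
                key = tuple(f.levels[i] for f, i in zip(self.factors, row))
                if key in seen or key in excluded:
                    continue
                seen.add(key)
                out.append(self.from_key(key))
                if len(out) == n:
                    break
        return out

    # -- encoding -----------------------------------------------------------------

    def column_map(self) -> ColumnMap:
        columns: list[tuple] = []
        factor_columns: dict[str, tuple] = {}
        for f in self.factors:
            start = len(columns)
            if f.kind == "numeric":
                columns.append((f.name, None))
            else:
                columns.extend((f.name, lv) for lv in f.levels)
            factor_columns[f.name] = tuple(range(start, len(columns)))
        return ColumnMap(tuple(columns), factor_columns)

    def encode(self, combinations: Sequence[Combination]) -> tuple[np.ndarray, ColumnMap]:
        """Encode combinations as a numeric feature matrix.

        Numeric factors occupy one column holding the level value; each
        categorical factor expands to one 0/1 indicator column per level.
        """
        cmap = self.column_map()
        X = np.zeros((len(combinations), cmap.n_columns), dtype=float)
        for i, comb in enumerate(combinations):
            self.validate(comb)
            for f in self.factors:
                cols = cmap.factor_columns[f.name]
                if f.kind == "numeric":
                    X[i, cols[0]] = float(comb[f.name])
                else:
                    X[i, cols[f.levels.index(comb[f.name])]] = 1.0
        return X, cmap

    def decode(self, X: np.ndarray) -> list[dict]:
        """Map encoded rows back to combinations (inverse of :meth:`encode`)."""
        cmap = self.column_map()
        out = []
        for row in np.atleast_2d(X):
            comb = {}
            for f in self.factors:
                cols = cmap.factor_columns[f.name]
                if f.kind == "numeric":
                    value = row[cols[0]]
                    matches = [lv for lv in f.levels
                               if math.isclose(value, lv, rel_tol=1e-9, abs_tol=1e-12)]
                    if len(matches) != 1:
                        raise ValueError(
                            f"factor {f.name!r}: encoded value {value} does not "
                            "match exactly one level")
                    comb[f.name] = matches[0]
                else:
                    hot = [j for j, c in enumerate(cols) if row[c] == 1.0]
                    if len(hot) != 1 or any(row[c] not in (0.0, 1.0) for c in cols):
                        raise ValueError(
                            f"factor {f.name!r}: indicator block is not one-hot")
                    comb[f.name] = f.levels[hot[0]]
            out.append(comb)
        return out


class LabeledDataset:
    """Measured results: combinations with objective values, split by round.

    Rounds model the day-by-day structure of an active-learning campaign
    (Day_1, Day_2, ...): indices are integers forming a contiguous range
    that starts at 1, and models are always trained on the union of all
    rounds up to the current one.
    """

    def __init__(self, space: SearchSpace,
                 records: Sequence[tuple[int, Combination, float]] = ()):
        self.space = space
        self._records: list[tuple[int, dict, float]] = []
        for round_index, comb, y in records:
            self._append(round_index, comb, y)
        self._check_rounds()

    def _append(self, round_index: int, comb: Combination, y: float) -> None:
        round_index = int(round_index)
        if round_index < 1:
            raise ValueError("round indices start at 1")
        self.space.validate(comb)
        self._records.append((round_index, dict(comb), float(y)))

    def _check_rounds(self) -> None:
        if not self._records:
            return
        rounds = sorted({r for r, _, _ in self._records})
        if rounds != list(range(1, rounds[-1] + 1)):
            raise ValueError(
                f"round indices must form a contiguous range from 1, got {rounds}")

    @property
    def records(self) -> list[tuple[int, dict, float]]:
        return list(self._records)

    @property
    def n_rounds(self) -> int:
        return max((r for r, _, _ in self._records), default=0)

    def __len__(self) -> int:
        return len(self._records)

    def combinations(self) -> list[dict]:
        return [c for _, c, _ in self._records]

    def objectives(self) -> np.ndarray:
        return np.array([y for _, _, y in self._records], dtype=float)

    def keys(self) -> set[tuple]:
        return {self.space.key(c) for _, c, _ in self._records}

    def upto_round(self, round_index: int) -> "LabeledDataset":
        recs = [(r, c, y) for r, c, y in self._records if r <= round_index]
        return LabeledDataset(self.space, recs)

    def with_round(self, combinations: Sequence[Combination],
                   objectives: Sequence[float],
                   round_index: int | None = None) -> "LabeledDataset":
        """New dataset with one more round appended."""
        if len(combinations) != len(objectives):
            raise ValueError("combinations and objectives must have equal length")
        r = self.n_rounds + 1 if round_index is None else int(round_index)
        recs = self._records + [(r, dict(c), float(y))
                                for c, y in zip(combinations, objectives)]
        return LabeledDataset(self.space, recs)

    def encoded(self) -> tuple[np.ndarray, np.ndarray, ColumnMap]:
        """Feature matrix, objective vector and column map for model fitting."""
        X, cmap = self.space.encode(self.combinations())
        y = self.objectives()
        bad = np.flatnonzero(~np.isfinite(y))
        if bad.size:
            raise ValueError(f"non-finite objective values at rows {bad.tolist()}")
        return X, y, cmap

    def to_frame(self) -> pd.DataFrame:
        rows = [{"round": r, **c, "objective": y} for r, c, y in self._records]
        cols = ["round", *self.space.names, "objective"]
        return pd.DataFrame(rows, columns=cols)

    @classmethod
    def from_frame(cls, space: SearchSpace, frame: pd.DataFrame) -> "LabeledDataset":
        recs = []
        for _, row in frame.iterrows():
            comb = {name: row[name] for name in space.names}
            recs.append((int(row["round"]), comb, float(row["objective"])))
        return cls(space, recs)


# -- module-level functional surface ------------------------------------------------


def space_size(space: SearchSpace) -> int:
    """Exact number of combinations in the space."""
    return space.size()


def enumerate_space(space: SearchSpace, cap: int = _ENUMERATION_CAP) -> list[dict]:
    """All combinations in lexicographic order (refuses spaces above `cap`)."""
    return space.enumerate(cap=cap)


def sample_candidates(space: SearchSpace, n: int, seed: int | np.random.Generator,
                      exclude: Iterable[Combination] = ()) -> list[dict]:
    """Uniform random distinct combinations, disjoint from `exclude`."""
    return space.sample(n, seed, exclude=exclude)


def encode(space: SearchSpace, combinations: Sequence[Combination]):
    """Feature matrix + column map for a list of combinations."""
    return space.encode(combinations)


def decode(space: SearchSpace, X: np.ndarray) -> list[dict]:
    """Inverse of :func:`encode`."""
    return space.decode(X)
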