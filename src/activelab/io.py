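"""File formats and worklist export — the lab-facing plumbing.

Conventions: UTF-8 comma-separated tables with a header row, ``.`` decimal
point, columns in search-space order.  Round files follow the ``Day_<n>``
naming convention of campaign bookkeeping (``Day_1_results.csv``,
``Day_2_suggestions.csv``, ...).  All writers format floats identically
(``%.10g``), so identical inputs produce byte-identical files.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .acquisition import RoundPlan
from .space import Factor, LabeledDataset, SearchSpace

__all__ = [
    "read_space_config",
    "write_space_config",
    "read_round_results",
    "write_round_plan",
    "StockTable",
    "Worklist",
    "make_worklist",
    "read_stock_table",
]

_FLOAT_FORMAT = "%.10g"


# -- search-space config ------------------------------------------------------------


def read_space_config(path: str | Path) -> SearchSpace:
    """Load a search space from a YAML/JSON config.

    Expected structure: ``{"factors": [{"name", "kind", "unit", "levels"}, ...]}``;
    factor order in the file is significant and becomes the table column order.
    """
    with open(path, "r", encoding="utf-8") as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, dict) or "factors" not in doc:
        raise ValueError(f"{path}: expected a mapping with a 'factors' list")
    factors = [Factor(name=f["name"], kind=f["kind"],
                      levels=tuple(f["levels"]), unit=f.get("unit", ""))
               for f in doc["factors"]]
    return SearchSpace(factors)


def write_space_config(space: SearchSpace, path: str | Path) -> None:
    doc = {"factors": [
        {"name": f.name, "kind": f.kind, "unit": f.unit, "levels": list(f.levels)}
        for f in space.factors]}
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


# -- round results ------------------------------------------------------------------


def read_round_results(path: str | Path, space: SearchSpace,
                       round_index: int = 1) -> LabeledDataset:
    """Read one round's measured results into a dataset fragment.

    The header must contain every factor name (any column order) plus
    ``objective``.  When a ``replicate`` column is present, replicate rows
    of the same combination are averaged into a single record.  Rows whose
    level is not in the factor's declared set are rejected with their
    location.
    """
    frame = pd.read_csv(path)
    missing = [n for n in space.names if n not in frame.columns]
    if missing:
        raise ValueError(f"{path}: missing factor columns {missing}")
    if "objective" not in frame.columns:
        raise ValueError(f"{path}: missing 'objective' column")

    records = []
    for row_no, row in frame.iterrows():
        comb = {}
        for f in space.factors:
            value = row[f.name]
            if f.kind == "numeric":
                value = float(value)
                matches = [lv for lv in f.levels
                           if math.isclose(value, lv, rel_tol=1e-9, abs_tol=1e-12)]
                if not matches:
                    raise ValueError(
                        f"{path}, row {row_no + 2}, column {f.name!r}: value "
                        f"{value!r} is not an allowed level")
                value = matches[0]
            elif value not in f.levels:
                raise ValueError(
                    f"{path}, row {row_no + 2}, column {f.name!r}: value "
                    f"{value!r} is not an allowed level")
            comb[f.name] = value
        records.append((space.key(comb), float(row["objective"])))

    if "replicate" in frame.columns:
        merged: dict[tuple, list[float]] = {}
        order: list[tuple] = []
        for key, y in records:
            if key not in merged:
                merged[key] = []
                order.append(key)
            merged[key].append(y)
        records = [(key, float(np.mean(merged[key]))) for key in order]

    return LabeledDataset(space, [(round_index, space.from_key(k), y)
                                  for k, y in records])


def write_round_plan(plan: RoundPlan, path: str | Path,
                     space: SearchSpace) -> None:
    """Write a round plan: factor columns in space order, then mu/sigma/score.

    Suggestion rows come first (sorted by score, descending, as in the
    plan); specials follow, flagged by the ``special`` column with empty
    prediction fields.  Output is byte-stable for identical plans.
    """
    rows = []
    for comb, mu, sigma, score in zip(plan.suggestions, plan.mu, plan.sigma,
                                      plan.scores):
        rows.append({**{n: comb[n] for n in space.names},
                     "mu": mu, "sigma": sigma, "score": score, "special": 0})
    for comb in plan.specials:
        rows.append({**{n: comb[n] for n in space.names},
                     "mu": np.nan, "sigma": np.nan, "score": np.nan,
                     "special": 1})
    frame = pd.DataFrame(rows, columns=[*space.names, "mu", "sigma", "score",
                                        "special"])
    frame.to_csv(path, index=False, float_format=_FLOAT_FORMAT)


# -- worklist export ----------------------------------------------------------------


@dataclass(frozen=True)
class StockTable:
    """Stock concentrations and dispensing geometry for worklist export.

    ``stocks`` maps each numeric factor to its stock concentration in the
    factor's own unit; a stock below the factor's top level would make
    that level unreachable and is rejected at worklist time.
    ``master_mix`` components are dispensed at a fixed volume per well.
    Volumes are in µL; ``resolution`` is the dispenser's minimal increment
    (25 nL = 0.025 µL for an acoustic liquid handler).
    """

    stocks: Mapping[str, float]
    final_volume: float
    resolution: float = 0.025
    master_mix: Sequence[tuple[str, float]] = ()

    def __post_init__(self):
        if self.final_volume <= 0 or self.resolution <= 0:
            raise ValueError("final_volume and resolution must be positive")
        for name, conc in self.stocks.items():
            if conc <= 0:
                raise ValueError(f"stock for {name!r} must be positive")


@dataclass
class Worklist:
    """Dispensing rows: (destination well, component, volume in µL).

    Rows are grouped by component and sorted by ascending volume within
    each component — the ordering that minimizes pipette-volume changes —
    and each well receives a final buffer-fill row topping it up to the
    final volume.
    """

    rows: list[tuple[str, str, float]] = field(default_factory=list)
    final_volume: float = 0.0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.rows, columns=["well", "component", "volume"])

    def write(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False, float_format=_FLOAT_FORMAT)

    def well_totals(self) -> dict[str, float]:
        totals: dict[str, float] = {}
        for well, _, vol in self.rows:
            totals[well] = totals.get(well, 0.0) + vol
        return totals


def _round_to_resolution(volume: float, resolution: float) -> float:
    # half-up, not banker's rounding: 0.5 increments always round away from 0
    steps = math.floor(volume / resolution + 0.5)
    return steps * resolution


def make_worklist(plan: RoundPlan, stocks: StockTable, space: SearchSpace,
                  wells: Sequence[str] | None = None,
                  keep_zero_rows: bool = False) -> Worklist:
    """Convert a round plan into a dispensing worklist.

    Per component, volume = final_volume × level / stock, rounded half-up
    to the dispenser resolution.  Only numeric factors have dilution
    semantics; a categorical factor in the space is an error here.  A
    buffer ``fill`` row tops each well to the final volume; a well whose
    component volumes exceed the final volume is an error naming the well.
    """
    for f in space.factors:
        if f.kind != "numeric":
            raise ValueError(
                f"worklist export requires numeric factors; {f.name!r} is "
                "categorical (dispense it via the master mix instead)")
        if f.name not in stocks.stocks:
            raise ValueError(f"no stock concentration for factor {f.name!r}")
        if stocks.stocks[f.name] < max(f.levels):
            raise ValueError(
                f"stock for {f.name!r} ({stocks.stocks[f.name]} {f.unit}) is below "
                f"its top level {max(f.levels)} {f.unit}: level unreachable")

    combos = plan.all_combinations()
    if wells is None:
        wells = [f"W{i + 1}" for i in range(len(combos))]
    if len(wells) != len(combos):
        raise ValueError("one destination well per combination required")

    rows: list[tuple[str, str, float]] = []
    fills: list[tuple[str, float]] = []
    for well, comb in zip(wells, combos):
        total = 0.0
        for f in space.factors:
            exact = stocks.final_volume * float(comb[f.name]) / stocks.stocks[f.name]
            vol = _round_to_resolution(exact, stocks.resolution)
            if abs(vol - exact) > 2 * stocks.resolution:
                warnings.warn(f"well {well}, component {f.name!r}: rounding "
                              f"error {abs(vol - exact):.4g} µL exceeds two "
                              "resolution units", UserWarning)
            if vol > 0 or keep_zero_rows:
                rows.append((well, f.name, vol))
            total += vol
        for name, vol in stocks.master_mix:
            vol = _round_to_resolution(vol, stocks.resolution)
            rows.append((well, name, vol))
            total += vol
        fill = stocks.final_volume - total
        if fill < -1e-9:
            raise ValueError(f"well {well}: component volumes ({total:.4g} µL) "
                             f"exceed the final volume {stocks.final_volume} µL")
        fills.append((well, max(fill, 0.0)))

    # ascending volume within each component minimizes pipette adjustments
    by_component: dict[str, list[tuple[str, str, float]]] = {}
    component_order: list[str] = []
    for row in rows:
        if row[1] not in by_component:
            by_component[row[1]] = []
            component_order.append(row[1])
        by_component[row[1]].append(row)
    ordered = []
    for name in component_order:
        ordered.extend(sorted(by_component[name], key=lambda r: (r[2], r[0])))
    ordered.extend((well, "fill", vol)
                   for well, vol in sorted(fills, key=lambda t: (t[1], t[0])))
    return Worklist(rows=ordered, final_volume=stocks.final_volume)


def read_stock_table(path: str | Path) -> StockTable:
    """Load a stock table from YAML: stocks, final_volume, resolution, master_mix."""
    with open(path, "r", encoding="utf-8") as fh:
        doc = yaml.safe_load(fh)
    return StockTable(
        stocks={k: float(v) for k, v in doc["stocks"].items()},
        final_volume=float(doc["final_volume"]),
        resolution=float(doc.get("resolution", 0.025)),
        master_mix=tuple((str(n), float(v))
                         for n, v in doc.get("master_mix", [])),
    )
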