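"""Reading, validation, filtering and pooling of single-cell tables.

The pipeline starts from long-format per-cell per-frame tables as produced
by a segmentation pipeline (or by :mod:`dmscc.synthetic_data`).  Because the
square-wave fidelity degrades along each cultivation array, only the
chambers nearest the inlet are analysed (the first 10 by default), and all
chambers of one condition are pooled into a single table before any
population statistic is computed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

__all__ = [
    "ConditionKey",
    "REQUIRED_COLUMNS",
    "MIN_CHAMBERS",
    "read_cell_table",
    "filter_chambers",
    "pool_condition",
]

logger = logging.getLogger(__name__)

REQUIRED_COLUMNS = [
    "strain",
    "condition_id",
    "array_index",
    "chamber_index",
    "frame",
    "time_h",
    "cell_id",
    "area_um2",
]

#: minimum number of cultivation chambers an analysed condition should pool
MIN_CHAMBERS = 5

_ROLES = ("dynamic", "excess_control", "limitation_control")


@dataclass(frozen=True)
class ConditionKey:
    """Identity of one cultivation condition within one experiment."""

    strain: str
    excess_s: float
    limitation_s: float
    role: str = "dynamic"
    experiment_id: str = ""

    def __post_init__(self) -> None:
        if self.role not in _ROLES:
            raise ValueError(f"role must be one of {_ROLES}, got {self.role!r}")
        period = self.excess_s + self.limitation_s
        if period <= 0:
            raise ValueError("excess_s + limitation_s must be positive")
        duty = self.excess_s / period
        if self.role == "excess_control" and duty < 1.0 - 1e-12:
            raise ValueError("excess_control requires duty cycle 1")
        if self.role == "limitation_control" and duty > 1e-12:
            raise ValueError("limitation_control requires duty cycle 0")

    @property
    def duty_cycle(self) -> float:
        return self.excess_s / (self.excess_s + self.limitation_s)


def read_cell_table(path: str | Path) -> pd.DataFrame:
    """Read and validate a cell-table CSV.

    Rows with non-positive area are rejected (their count is logged); the
    time axis is expected in hours.  Missing fluorescence values (empty
    fields at non-fluorescence frames) become NaN.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        table = pd.read_csv(path)
    except Exception as exc:  # pragma: no cover - pandas reports the row
        raise ValueError(f"unparseable cell table {path}: {exc}") from exc
    missing = [c for c in REQUIRED_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"cell table {path} is missing column(s): {', '.join(missing)}")
    if table.empty:
        raise ValueError(f"cell table {path} contains no rows")
    bad = ~(table["area_um2"] > 0)
    if bad.any():
        logger.warning("rejected %d rows with non-positive area from %s", int(bad.sum()), path)
        table = table[~bad].reset_index(drop=True)
    if table.empty:
        raise ValueError(f"cell table {path} has no rows with positive area")
    return table


def filter_chambers(table: pd.DataFrame, max_chamber_index: int = 10) -> pd.DataFrame:
    """Keep only chambers nearest the inlet (index <= ``max_chamber_index``).

    These chambers see the highest pulse fidelity; chambers further along
    the array experience smoothed profiles and are excluded from analysis.
    """
    if "chamber_index" not in table.columns:
        raise ValueError("cell table is missing 'chamber_index'")
    out = table[table["chamber_index"] <= max_chamber_index].reset_index(drop=True)
    if out.empty:
        logger.warning("chamber filter removed every row")
        return out
    kept = out.groupby("array_index")["chamber_index"].nunique()
    for array_idx, n in kept.items():
        logger.info("array %s: %d chambers retained", array_idx, int(n))
    return out


def pool_condition(
    tables: Sequence[pd.DataFrame] | pd.DataFrame, key: ConditionKey
) -> pd.DataFrame:
    """Concatenate all chambers of one condition into a single table.

    Chamber provenance (array_index, chamber_index) is preserved.  Pooling
    fewer than :data:`MIN_CHAMBERS` chambers is allowed but logged as a
    warning; conflicting strain labels under one key are an error.
    """
    if isinstance(tables, pd.DataFrame):
        tables = [tables]
    if not tables:
        raise ValueError("nothing to pool")
    pooled = pd.concat(tables, ignore_index=True)
    strains = pooled["strain"].unique()
    if len(strains) > 1 or (len(strains) == 1 and strains[0] != key.strain):
        raise ValueError(
            f"conflicting strain labels {sorted(map(str, strains))} under condition "
            f"key for strain {key.strain!r}"
        )
    n_chambers = pooled.groupby("array_index")["chamber_index"].nunique().sum()
    if n_chambers < MIN_CHAMBERS:
        logger.warning(
            "condition %s pools only %d chambers (< %d recommended)",
            key, int(n_chambers), MIN_CHAMBERS,
        )
    return pooled
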