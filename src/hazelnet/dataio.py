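"""Experiment-table I/O and the random train/test partition."""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .datagen import INPUT_COLUMNS, RESPONSE_COLUMNS, TABLE_COLUMNS


class TableFormatError(ValueError):
    """A CSV table does not conform to the fixed experiment-table schema."""


def read_table(path) -> pd.DataFrame:
    """Read an experiment table from CSV.

    Input columns (ce_conc, cf_conc, adding_day, harvest_day) are
    mandatory and must be numeric.  Response cells may be blank
    (incomplete observations); the indices of incomplete rows are
    recorded in ``table.attrs["incomplete_rows"]`` (see
    :func:`incomplete_rows`).
    """
    table = pd.read_csv(path)
    for col in INPUT_COLUMNS:
        if col not in table.columns:
            raise TableFormatError(f"missing required column {col!r}")
        if table[col].isna().any():
            row = int(table.index[table[col].isna()][0])
            raise TableFormatError(f"blank value in required column {col!r}, row {row}")
    for col in [c for c in TABLE_COLUMNS if c in table.columns]:
        coerced = pd.to_numeric(table[col], errors="coerce")
        bad = coerced.isna() & table[col].notna()
        if bad.any():
            row = int(table.index[bad][0])
            raise TableFormatError(f"non-numeric value in column {col!r}, row {row}")
        # measurements and doses are continuous; block labels stay integral
        table[col] = coerced if col == "replicate" else coerced.astype(float)
    table.attrs["incomplete_rows"] = incomplete_rows(table)
    return table


def incomplete_rows(table: pd.DataFrame) -> list[int]:
    """Row indices with at least one missing response value."""
    present = [c for c in RESPONSE_COLUMNS if c in table.columns]
    if not present:
        return list(range(len(table)))
    mask = table[present].isna().any(axis=1)
    return [int(i) for i in table.index[mask]]


def write_table(table: pd.DataFrame, path) -> None:
    """Write an experiment table as CSV with the fixed column order."""
    cols = [c for c in TABLE_COLUMNS if c in table.columns]
    extra = [c for c in table.columns if c not in cols]
    table[cols + extra].to_csv(path, index=False, float_format="%.10g")


@dataclass(frozen=True)
class SplitIndex:
    """A random train/test partition of table rows."""

    train_rows: tuple[int, ...]
    test_rows: tuple[int, ...]
    fraction: float
    seed: int

    def __post_init__(self):
        train, test = set(self.train_rows), set(self.test_rows)
        if train & test:
            raise ValueError("train and test rows overlap")
        n = len(train) + len(test)
        if train | test != set(range(n)):
            raise ValueError("partition does not cover rows 0..n-1 exactly")

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps({
            "train_rows": list(self.train_rows),
            "test_rows": list(self.test_rows),
            "fraction": self.fraction,
            "seed": self.seed,
        }, indent=1))

    @classmethod
    def from_json(cls, path) -> "SplitIndex":
        d = json.loads(Path(path).read_text())
        return cls(tuple(d["train_rows"]), tuple(d["test_rows"]),
                   d["fraction"], d["seed"])


def split_train_test(table: pd.DataFrame, fraction: float = 0.7,
                     seed: int = 0) -> SplitIndex:
    """Uniform random partition of rows into train and test subsets.

    The train size is round-half-up of ``fraction * n`` (504 of 720 rows
    at the default 70 %).  Deterministic for a given seed.
    """
    n = len(table)
    if not 0.0 < fraction < 1.0:
        raise ValueError(f"fraction must lie in (0, 1), got {fraction}")
    if n < 2:
        raise ValueError("need at least 2 rows to split")
    n_train = int(math.floor(fraction * n + 0.5))
    perm = np.random.default_rng(seed).permutation(n)
    return SplitIndex(
        train_rows=tuple(sorted(int(i) for i in perm[:n_train])),
        test_rows=tuple(sorted(int(i) for i in perm[n_train:])),
        fraction=fraction,
        seed=seed,
    )
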