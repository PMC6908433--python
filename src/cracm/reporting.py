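"""Descriptive aggregation: incidence percentages and group tables.

Rounding is half-up to match common printed style; full-precision values
are retained alongside.  Inferential statistics are deliberately out of
scope — only descriptive summaries (n, mean, SD, SEM) are produced.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd

__all__ = ["CountRecord", "GroupSummary", "proportion_summary",
           "group_table", "save_report"]


@dataclass
class CountRecord:
    """A labelled numerator/denominator count pair."""

    label: str
    numerator: int
    denominator: int

    def __post_init__(self) -> None:
        if self.denominator <= 0:
            raise ValueError("denominator must be positive")
        if not 0 <= self.numerator <= self.denominator:
            raise ValueError("numerator must lie in [0, denominator]")


@dataclass
class GroupSummary:
    n: int
    mean: float
    sd: float | None
    sem: float | None


def _round_half_up(x: float, decimals: int) -> float:
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def proportion_summary(record: CountRecord | tuple, decimals: int = 1) -> float:
    """Incidence as a percentage, half-up rounded to ``decimals``.

    Accepts a :class:`CountRecord` or a (numerator, denominator) pair.
    ``proportion_summary((254, 885), 1)`` → 28.7.
    """
    if not isinstance(record, CountRecord):
        num, den = record
        record = CountRecord("", int(num), int(den))
    pct = 100.0 * record.numerator / record.denominator
    return _round_half_up(pct, decimals)


def group_table(values_per_group: dict,
                column_order=("n", "mean", "sd", "sem")) -> pd.DataFrame:
    """n / mean / SD / SEM per group, one row per group label.

    SD uses n-1 degrees of freedom; SD and SEM are null for single-value
    groups.  Raises on an empty group.
    """
    rows = {}
    for label, values in values_per_group.items():
        v = np.asarray(list(values), dtype=float)
        if v.size == 0:
            raise ValueError(f"group {label!r} is empty")
        if v.size > 1:
            sd = float(v.std(ddof=1))
            summ = GroupSummary(v.size, float(v.mean()), sd, sd / np.sqrt(v.size))
        else:
            summ = GroupSummary(1, float(v.mean()), None, None)
        rows[label] = {c: getattr(summ, c) for c in column_order}
    return pd.DataFrame.from_dict(rows, orient="index")[list(column_order)]


def save_report(tables: dict, out_dir) -> None:
    """Serialise a dict of DataFrames / dicts to CSV + JSON under a
    directory."""
    import os

    os.makedirs(out_dir, exist_ok=True)
    summary = {}
    for name, obj in tables.items():
        if isinstance(obj, pd.DataFrame):
            obj.to_csv(os.path.join(out_dir, f"{name}.csv"))
            summary[name] = f"{name}.csv"
        else:
            summary[name] = obj
    with open(os.path.join(out_dir, "report.json"), "w") as fh:
        json.dump(summary, fh, indent=2, default=str)
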