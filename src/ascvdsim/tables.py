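"""Derived statistics over lifetime projection tables.

Operates interchangeably on the packaged reference projection tables
(life expectancy/QALYs by ratio stratum, by LDL-C group, and lifetime event
counts per 100,000 births) or on tables built from simulated cohort
summaries.  All rounding is half-away-from-zero, the convention under which
a QALY gap of 13.68 prints as 13.7 at one decimal.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from importlib import resources
from typing import Dict, Optional, Sequence, Tuple

import pandas as pd

__all__ = [
    "PrintedTables",
    "load_printed_tables",
    "round_half_away",
    "le_gap",
    "qaly_gap",
    "lifetime_risk_pct",
    "case_fatality_range",
    "attributable_fraction",
    "cumulative_exposure_estimate",
    "derived_statistics",
]

_EVENT_COLS = {"HF": "hf", "IHD": "ihd", "MI": "mi", "IS": "is"}


def round_half_away(x: float, decimals: int = 0) -> float:
    """Round half away from zero to the requested number of decimals."""
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass
class PrintedTables:
    """The three lifetime projection tables as tidy frames.

    ``table1``: sex x ratio stratum -> LE, QALYs, mean LDL-C, mean HDL-C.
    ``table2``: sex x LDL-C group -> LE, QALYs (plus a pooled LDL>4 row).
    ``table3``: sex x ratio stratum -> total/fatal counts per 100,000 births.
    """

    table1: pd.DataFrame
    table2: pd.DataFrame
    table3: pd.DataFrame

    def __post_init__(self) -> None:
        t3 = self.table3
        for ev in _EVENT_COLS.values():
            if (t3[f"{ev}_fatal"] > t3[f"{ev}_total"]).any():
                raise ValueError(f"fatal exceeds total for {ev}")
            if (t3[[f"{ev}_total", f"{ev}_fatal"]] < 0).any().any():
                raise ValueError(f"negative counts for {ev}")

    def _row(self, table: pd.DataFrame, key_col: str, key, sex: str) -> pd.Series:
        sel = table[(table["sex"] == sex) & (table[key_col].astype(str) == str(key))]
        if sel.empty:
            raise KeyError(f"no row for sex={sex!r}, {key_col}={key!r}")
        return sel.iloc[0]

    def stratum_row(self, stratum, sex: str = "all", which: str = "table1") -> pd.Series:
        if which == "table2":
            return self._row(self.table2, "ldl_group", stratum, sex)
        table = self.table1 if which == "table1" else self.table3
        return self._row(table, "stratum", stratum, sex)


def load_printed_tables() -> PrintedTables:
    """Load the packaged reference projection tables."""
    base = resources.files("ascvdsim.data")
    return PrintedTables(
        table1=pd.read_csv(base / "table1.csv"),
        table2=pd.read_csv(base / "table2.csv"),
        table3=pd.read_csv(base / "table3.csv"),
    )


def _gap(
    tables: PrintedTables,
    col: str,
    a,
    b,
    decimals: int,
    grouping: str,
    sex: str,
) -> float:
    which = "table2" if grouping == "ldl" else "table1"
    va = float(tables.stratum_row(a, sex, which)[col])
    vb = float(tables.stratum_row(b, sex, which)[col])
    # subtract on the printed decimal values so 79.58 - 66.23 is exactly 13.35
    diff = float(Decimal(repr(va)) - Decimal(repr(vb)))
    return round_half_away(diff, decimals)


def le_gap(
    tables: PrintedTables,
    stratum_a,
    stratum_b,
    decimals: int = 2,
    grouping: str = "ratio",
    sex: str = "all",
) -> float:
    """Life-expectancy difference LE(a) - LE(b) in years, rounded.

    ``grouping`` selects the ratio-stratum table ("ratio") or the LDL-C group
    table ("ldl").
    """
    return _gap(tables, "life_expectancy", stratum_a, stratum_b, decimals, grouping, sex)


def qaly_gap(
    tables: PrintedTables,
    stratum_a,
    stratum_b,
    decimals: int = 2,
    grouping: str = "ratio",
    sex: str = "all",
) -> float:
    """Lifetime QALY difference QALY(a) - QALY(b), rounded."""
    return _gap(tables, "lifetime_qalys", stratum_a, stratum_b, decimals, grouping, sex)


def lifetime_risk_pct(
    tables: PrintedTables, event_type: str, stratum, sex: str = "all"
) -> float:
    """Lifetime risk of an event type as a percentage of births."""
    col = _EVENT_COLS[event_type]
    row = tables.stratum_row(stratum, sex, "table3")
    return float(row[f"{col}_total"]) / 100_000.0 * 100.0


def case_fatality_range(tables: PrintedTables, event_type: str) -> Tuple[int, int]:
    """(min%, max%) case fatality over the 8 sex-by-stratum cells, whole percents.

    Pooled cells are excluded: the sex-specific cells are the scope over
    which the published fatality ranges are defined.
    """
    col = _EVENT_COLS[event_type]
    cells = tables.table3[tables.table3["sex"].isin(["female", "male"])]
    totals = cells[f"{col}_total"]
    if (totals <= 0).any():
        raise ValueError(f"zero {event_type} totals in a sex-specific cell")
    pct = cells[f"{col}_fatal"] / totals * 100.0
    return (
        int(round_half_away(float(pct.min()))),
        int(round_half_away(float(pct.max()))),
    )


def attributable_fraction(
    tables: PrintedTables, event_type: str, index_stratum, reference_stratum, sex: str = "all"
) -> int:
    """Excess fraction (%) of events in the index stratum relative to the reference.

    ``(1 - total_ref / total_index) * 100``, floored at 0 and rounded to a
    whole percent — the share of the index stratum's events in excess of the
    low-risk background.
    """
    col = _EVENT_COLS[event_type]
    idx = float(tables.stratum_row(index_stratum, sex, "table3")[f"{col}_total"])
    ref = float(tables.stratum_row(reference_stratum, sex, "table3")[f"{col}_total"])
    if idx <= 0:
        raise ValueError("index stratum has no events")
    return int(round_half_away(max(0.0, (1.0 - ref / idx) * 100.0)))


def cumulative_exposure_estimate(mean_ldl: float, life_expectancy: float) -> float:
    """Cumulative LDL-C exposure in mmol/L-years from mean level and years lived."""
    if mean_ldl <= 0 or life_expectancy <= 0:
        raise ValueError("inputs must be positive")
    return mean_ldl * life_expectancy


def derived_statistics(tables: PrintedTables) -> Dict[str, object]:
    """All headline derived statistics as a JSON-serialisable report."""
    row1 = tables.stratum_row(1, "all", "table1")
    mi_cf = case_fatality_range(tables, "MI")
    ihd_cf = case_fatality_range(tables, "IHD")
    return {
        "le_gap_ratio_1_vs_4_years": le_gap(tables, 1, 4, 2),
        "qaly_gap_ratio_1_vs_4": qaly_gap(tables, 1, 4, 1),
        "le_gap_ldl_1_vs_4_years": le_gap(tables, 1, 4, 1, grouping="ldl"),
        "lifetime_mi_risk_stratum1_pct": lifetime_risk_pct(tables, "MI", 1),
        "lifetime_mi_risk_stratum4_pct": lifetime_risk_pct(tables, "MI", 4),
        "mi_case_fatality_range_pct": list(mi_cf),
        "ihd_case_fatality_range_pct": list(ihd_cf),
        "ihd_attributable_fraction_pct": attributable_fraction(tables, "IHD", 4, 1),
        "cumulative_exposure_stratum1_mmol_years": round_half_away(
            cumulative_exposure_estimate(
                float(row1["mean_ldl"]), float(row1["life_expectancy"])
            ),
            2,
        ),
    }
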