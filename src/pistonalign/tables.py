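"""Packaged summary-table fixtures and their statistical reproduction.

The study deposited no raw images, but its two summary tables print, for every
group (shape x region x day), the four angle-class percentages, the group size
``n``, and the p-values of the piston-vs-control comparisons.  Because every
consistent row's percentages invert exactly to integer counts (``round(pct *
n / 100)`` sums to ``n``), the full statistical analysis is recomputable from
the printed numbers alone.  One control row (circle control, Day 2) is garbled
as printed — its percentages are inconsistent with its printed ``n`` — and is
flagged ``reconstructs = False`` and excluded from reproduction.
"""

from __future__ import annotations

from importlib import resources
from typing import Optional, Tuple

import pandas as pd

from .errors import IrreconcilableRowError
from .scoring import BIN_ORDER
from .stats import FrequencyTable, chi_square_test, counts_from_percentages, t_test_between_percents

__all__ = [
    "load_printed_tables",
    "load_printed_chisq",
    "row_frequency_table",
    "parse_printed_p",
    "printed_tolerance",
    "reproduce_t_tests",
    "reproduce_chi_square",
    "reproduce_tables",
]

_PCT_COLS = ["pct_radial", "pct_peripheral", "pct_oblique_near", "pct_oblique_far"]
_P_COLS = ["p_radial", "p_peripheral", "p_oblique_near", "p_oblique_far"]


def _data_path(name: str):
    return resources.files("pistonalign.data").joinpath(name)


def load_printed_tables() -> pd.DataFrame:
    """The printed frequency tables, one row per group, with a ``reconstructs``
    flag marking rows whose percentages invert cleanly to counts."""
    with _data_path("printed_tables.csv").open() as fh:
        df = pd.read_csv(fh, dtype={c: str for c in _P_COLS})
    flags = []
    for _, row in df.iterrows():
        try:
            counts_from_percentages([row[c] for c in _PCT_COLS], int(row["n"]))
            flags.append(True)
        except IrreconcilableRowError:
            flags.append(False)
    df["reconstructs"] = flags
    return df


def load_printed_chisq() -> pd.DataFrame:
    """Printed chi-square p-values (numeric values and significance bounds)."""
    with _data_path("printed_chisq.csv").open() as fh:
        return pd.read_csv(fh, dtype={"printed_p": str})


def row_frequency_table(row: pd.Series) -> FrequencyTable:
    """Reconstruct a :class:`FrequencyTable` from one printed row."""
    counts = counts_from_percentages([row[c] for c in _PCT_COLS], int(row["n"]))
    return FrequencyTable(group_label=str(row["group"]), day=int(row["day"]), counts=counts)


def parse_printed_p(text: str) -> Tuple[float, bool]:
    """Parse a printed p-value; returns ``(value, is_upper_bound)``."""
    text = text.strip()
    if text.startswith("<"):
        return float(text[1:]), True
    return float(text), False


def printed_tolerance(text: str) -> float:
    """+/- one unit in the last printed decimal place."""
    text = text.strip().lstrip("<")
    decimals = len(text.split(".")[1]) if "." in text else 0
    return 10.0 ** -decimals


def _match(computed: float, printed: str) -> bool:
    value, is_bound = parse_printed_p(printed)
    if is_bound:
        return computed < value
    return abs(computed - value) <= printed_tolerance(printed) + 1e-12


def reproduce_t_tests(printed: Optional[pd.DataFrame] = None) -> pd.DataFrame:
    """Recompute every printed t-between-percents p-value from reconstructed rows.

    Piston rows are paired with the control row of the same table/group family
    and day.  Pairs involving a non-reconstructing row are skipped.
    """
    df = load_printed_tables() if printed is None else printed
    rows = []
    for (table, day), grp in df.groupby(["table", "day"]):
        pistons = grp[grp["region"] == "piston"]
        controls = grp[grp["region"] == "control"]
        for _, prow in pistons.iterrows():
            crow = controls[controls["group"] == prow["group"] + "R"]
            if len(crow) != 1:
                continue
            crow = crow.iloc[0]
            if not (prow["reconstructs"] and crow["reconstructs"]):
                continue
            for pct_col, p_col, bin_ in zip(_PCT_COLS, _P_COLS, BIN_ORDER):
                printed_p = prow[p_col]
                if not isinstance(printed_p, str) or not printed_p.strip():
                    continue
                res = t_test_between_percents(
                    float(prow[pct_col]), int(prow["n"]), float(crow[pct_col]), int(crow["n"])
                )
                rows.append({
                    "table": table, "group": prow["group"], "day": day, "bin": bin_.value,
                    "method": "t_between_percents", "statistic": res.statistic,
                    "df": res.df, "p_computed": res.p_two_sided,
                    "p_printed": printed_p.strip(), "match": _match(res.p_two_sided, printed_p),
                })
    return pd.DataFrame(rows)


def reproduce_chi_square(printed: Optional[pd.DataFrame] = None) -> pd.DataFrame:
    """Recompute the printed chi-square comparisons from reconstructed rows."""
    df = load_printed_tables() if printed is None else printed
    plan = load_printed_chisq()
    rows = []
    for _, cmp_row in plan.iterrows():
        sub = df[df["table"] == cmp_row["table"]]
        a = sub[(sub["group"] == cmp_row["group_a"]) & (sub["day"] == cmp_row["day_a"])]
        b = sub[(sub["group"] == cmp_row["group_b"]) & (sub["day"] == cmp_row["day_b"])]
        arow, brow = a.iloc[0], b.iloc[0]
        if not (arow["reconstructs"] and brow["reconstructs"]):
            continue
        res = chi_square_test(row_frequency_table(arow), row_frequency_table(brow))
        printed_p = str(cmp_row["printed_p"]).strip()
        rows.append({
            "table": cmp_row["table"],
            "pair": f"{cmp_row['group_a']}-d{cmp_row['day_a']} vs {cmp_row['group_b']}-d{cmp_row['day_b']}",
            "method": "chi_square", "statistic": res.statistic, "df": res.df,
            "p_computed": res.p_two_sided, "p_printed": printed_p,
            "match": _match(res.p_two_sided, printed_p),
        })
    return pd.DataFrame(rows)


def reproduce_tables() -> pd.DataFrame:
    """All printed p-values (t and chi-square) recomputed, with match flags."""
    t = reproduce_t_tests()
    c = reproduce_chi_square()
    return pd.concat([t, c], ignore_index=True, sort=False)
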