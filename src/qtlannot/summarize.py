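"""Descriptive summaries of annotation results and chord-plot data prep.

Compositions count unique database records (by ``qtl_id``), not join rows:
a QTL hit by many markers still contributes once, so the pie/bar summaries
reflect database representativeness rather than marker density. The
alternative (counting join rows) is exposed via ``unique_records=False``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd

from .annotate import AnnotationResult

logger = logging.getLogger("qtlannot")

__all__ = [
    "CompositionTable",
    "ChordData",
    "qtl_type_composition",
    "trait_composition",
    "relationship_data",
]


@dataclass
class CompositionTable:
    """Label/count/percent composition; percents sum to 100 over the scope."""

    table: pd.DataFrame  # columns: label, count, percent

    @property
    def labels(self) -> list[str]:
        return self.table["label"].tolist()

    def __len__(self) -> int:
        return len(self.table)


@dataclass
class ChordData:
    """Bipartite incidence between two grouping columns, for a chord plot."""

    left: list[str]
    right: list[str]
    weights: pd.DataFrame  # columns: x, y, weight (> 0)


def _frame(annotation) -> pd.DataFrame:
    if isinstance(annotation, AnnotationResult):
        return annotation.rows
    return annotation


def _composition(df: pd.DataFrame, label_col: str, unique_records: bool) -> CompositionTable:
    if unique_records:
        df = df.drop_duplicates(subset="qtl_id")
    counts = df.groupby(label_col).size().sort_values(ascending=False)
    counts = counts.sort_index(kind="mergesort").sort_values(
        ascending=False, kind="mergesort"
    )  # descending count, alphabetical ties
    total = counts.sum()
    out = pd.DataFrame(
        {
            "label": counts.index,
            "count": counts.to_numpy(),
            "percent": 100.0 * counts.to_numpy() / total,
        }
    ).reset_index(drop=True)
    return CompositionTable(table=out)


def qtl_type_composition(annotation, unique_records: bool = True) -> CompositionTable:
    """Composition of QTL classes (Milk, Reproduction, ...) in the annotation."""
    df = _frame(annotation)
    if df.empty:
        logger.warning("empty annotation: empty composition table")
        return CompositionTable(pd.DataFrame(columns=["label", "count", "percent"]))
    for col in ("qtl_class", "qtl_id"):
        if col not in df.columns:
            raise KeyError(f"annotation lacks required column {col!r}")
    return _composition(df, "qtl_class", unique_records)


def trait_composition(annotation, qtl_class: str, unique_records: bool = True) -> CompositionTable:
    """Per-trait composition within one QTL class, sorted descending."""
    df = _frame(annotation)
    available = sorted(df["qtl_class"].astype(str).unique()) if not df.empty else []
    if qtl_class not in available:
        raise ValueError(
            f"QTL class {qtl_class!r} not present in annotation; available: {available}"
        )
    return _composition(df[df["qtl_class"] == qtl_class], "trait_name", unique_records)


def relationship_data(rows: pd.DataFrame, x_col: str, y_col: str) -> ChordData:
    """Unique (x, y) incidence counts linking two grouping columns.

    Label ordering is alphabetical on both sides; every emitted pair has
    weight > 0 and marginal sums equal per-group row counts in the source.
    """
    if x_col == y_col:
        raise ValueError("x_col and y_col must differ")
    for col in (x_col, y_col):
        if col not in rows.columns:
            raise KeyError(f"column {col!r} not in table ({list(rows.columns)})")
    weights = (
        rows.groupby([x_col, y_col])
        .size()
        .reset_index(name="weight")
        .rename(columns={x_col: "x", y_col: "y"})
        .sort_values(["x", "y"], kind="mergesort")
        .reset_index(drop=True)
    )
    return ChordData(
        left=sorted(weights["x"].astype(str).unique()),
        right=sorted(weights["y"].astype(str).unique()),
        weights=weights,
    )
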