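"""Sharing of annotated genes/QTLs between grouping factors.

For groups A and B the shared count is the size of the intersection of
their unique-ID sets; the percentage cell (A, B) is that count divided by
the size of A's set, times 100. The count matrix is therefore symmetric
while the percentage matrix generally is not: if A has 10 unique IDs, B has
5, and they share 5, then percent(A, B) = 50 but percent(B, A) = 100.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd

logger = logging.getLogger("qtlannot")

__all__ = ["OverlapMatrices", "overlap_among_groups", "overlap_heatmap_data"]


@dataclass
class OverlapMatrices:
    groups: list[str]
    counts: pd.DataFrame    # symmetric; diagonal = group set sizes
    percents: pd.DataFrame  # asymmetric; cell (A,B) = 100*|A∩B|/|A|
    combined: pd.DataFrame  # "count (percent%)" labels


def overlap_among_groups(
    rows: pd.DataFrame, group_col: str, id_col: str
) -> OverlapMatrices:
    """Count and percentage matrices of unique-ID sharing between groups.

    IDs are deduplicated within each group before intersection (set, not
    multiset, semantics). Groups are ordered by sorted distinct label. An
    empty group yields a zero count row and a zero percent row with a
    warning.
    """
    if group_col == id_col:
        raise ValueError("group_col and id_col must differ")
    for col in (group_col, id_col):
        if col not in rows.columns:
            raise KeyError(f"column {col!r} not in table ({list(rows.columns)})")

    sets: dict[str, set] = {}
    for label, sub in rows.groupby(group_col, sort=True):
        sets[label] = set(sub[id_col].dropna())
    groups = sorted(sets, key=str)

    counts = pd.DataFrame(0, index=groups, columns=groups, dtype=int)
    percents = pd.DataFrame(0.0, index=groups, columns=groups)
    combined = pd.DataFrame("", index=groups, columns=groups, dtype=object)
    for a in groups:
        if not sets[a]:
            logger.warning("group %r has no IDs; its percent row is reported as 0", a)
        for b in groups:
            shared = len(sets[a] & sets[b])
            counts.loc[a, b] = shared
            pct = 100.0 * shared / len(sets[a]) if sets[a] else 0.0
            percents.loc[a, b] = pct
            combined.loc[a, b] = f"{shared} ({pct:.2f}%)"
    return OverlapMatrices(groups=groups, counts=counts, percents=percents, combined=combined)


def overlap_heatmap_data(m: OverlapMatrices) -> dict:
    """Plot-ready grid for the overlap heat map.

    Fill values are the (asymmetric) percentages; cell text is the combined
    "count (percent%)" label. Rendering is a thin layer over this grid.
    """
    return {
        "labels": list(m.groups),
        "fill": m.percents.to_numpy(copy=True),
        "text": m.combined.to_numpy(copy=True),
    }
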