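"""Cohort composition summaries.

A labeled cohort is usually described by its taxonomic makeup — how
many strains per class/phylum and what share of the cohort each group
represents.  These helpers do that arithmetic from a plain count table.
"""

from __future__ import annotations

from typing import Mapping

import pandas as pd


def composition_percentages(
    counts: Mapping[str, int] | pd.Series, total: int | None = None, decimals: int = 2
) -> pd.Series:
    """Percentage share per group from raw counts.

    ``total`` defaults to the sum of counts; pass it explicitly when
    the table covers only part of the cohort.  Rounded to ``decimals``
    (two, matching how such tables are conventionally printed).
    """
    s = pd.Series(dict(counts), dtype=float)
    if (s < 0).any():
        raise ValueError("negative counts")
    denom = float(total) if total is not None else float(s.sum())
    if denom <= 0:
        raise ValueError("total must be positive")
    return (100.0 * s / denom).round(decimals)


def group_percentages(
    class_counts: Mapping[str, int],
    group_of: Mapping[str, str],
    total: int | None = None,
    decimals: int = 2,
) -> pd.Series:
    """Roll class-level counts up to groups (e.g. classes -> phyla) and
    return each group's percentage of the cohort."""
    rolled: dict[str, int] = {}
    for cls, n in class_counts.items():
        grp = group_of.get(cls, cls)
        rolled[grp] = rolled.get(grp, 0) + int(n)
    return composition_percentages(rolled, total=total, decimals=decimals)
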