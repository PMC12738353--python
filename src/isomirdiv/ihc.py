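"""Immunohistochemistry readout quantification: IRS and H-score.

Staining intensity is an ordinal 0 (negative) to 3 (strong); the fraction of
positive tumor cells is binned into an ordinal 0-4 (0%, 1-25%, 26-50%,
51-75%, 76-100%).  IRS is intensity x proportion bin (0-12); the H-score is
the standard weighted sum over intensity levels, sum(intensity x percent of
cells at that intensity), range 0-300.  Slides scored independently by two
raters are merged with an explicit agreement report — discordant ordinals are
never averaged silently.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "IHCObservation",
    "proportion_category",
    "irs",
    "h_score",
    "group_compare",
    "merge_raters",
]


@dataclass(frozen=True)
class IHCObservation:
    """One slide's scoring: intensity ordinal and percent positive cells.

    ``per_intensity_percent`` optionally gives the percent of cells at each
    intensity 1..3 (for the H-score); they may sum to less than 100, the
    remainder being negative cells.
    """

    sample_id: str
    intensity: int
    positive_fraction: float
    per_intensity_percent: tuple[float, float, float] | None = None

    def __post_init__(self) -> None:
        if self.intensity not in (0, 1, 2, 3):
            raise ValueError(f"intensity must be 0-3, got {self.intensity}")
        if not (0 <= self.positive_fraction <= 100):
            raise ValueError(
                f"positive_fraction must be in [0, 100], got {self.positive_fraction}"
            )
        if self.per_intensity_percent is not None:
            p = self.per_intensity_percent
            if any(x < 0 for x in p) or sum(p) > 100 + 0.01:
                raise ValueError(f"per-intensity percentages invalid: {p}")


def proportion_category(percent: float) -> int:
    """Bin percent positive cells into the ordinal 0-4 scale.

    0% -> 0; (0,25] -> 1; (25,50] -> 2; (50,75] -> 3; (75,100] -> 4.
    Fractional percentages round half-up to an integer before binning, since
    the bins are defined on integer percents.
    """
    if not (0 <= percent <= 100):
        raise ValueError(f"percent must be in [0, 100], got {percent}")
    # round half-up (Python's round is banker's rounding)
    p = int(np.floor(percent + 0.5))
    if p == 0:
        return 0
    if p <= 25:
        return 1
    if p <= 50:
        return 2
    if p <= 75:
        return 3
    return 4


def irs(intensity: int, proportion_cat: int) -> int:
    """Immunoreactivity score: intensity ordinal (0-3) x proportion ordinal (0-4)."""
    if intensity not in (0, 1, 2, 3):
        raise ValueError(f"intensity must be 0-3, got {intensity}")
    if proportion_cat not in (0, 1, 2, 3, 4):
        raise ValueError(f"proportion category must be 0-4, got {proportion_cat}")
    return intensity * proportion_cat


def h_score(p1: float, p2: float, p3: float) -> float:
    """H-score from the percent of cells at intensities 1, 2 and 3.

    1*p1 + 2*p2 + 3*p3, in [0, 300]; the remainder to 100% is negative cells.
    """
    if min(p1, p2, p3) < 0:
        raise ValueError("per-intensity percentages must be >= 0")
    if p1 + p2 + p3 > 100 + 1e-9:
        raise ValueError(f"per-intensity percentages sum to {p1 + p2 + p3} > 100")
    return 1.0 * p1 + 2.0 * p2 + 3.0 * p3


def group_compare(scores, labels) -> tuple[float, float]:
    """Compare score distributions across groups.

    Two groups: Welch two-sample t-test.  Three or more: one-way ANOVA.
    Returns (statistic, p_value).
    """
    s = pd.Series(np.asarray(scores, dtype=float))
    lab = pd.Series(list(labels))
    if len(s) != len(lab):
        raise ValueError("scores and labels differ in length")
    groups = [s[lab.values == g].to_numpy() for g in lab.unique()]
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    for g, name in zip(groups, lab.unique()):
        if len(g) < 2:
            raise ValueError(f"group {name!r} has fewer than 2 observations")
    if len(groups) == 2:
        t, p = stats.ttest_ind(groups[0], groups[1], equal_var=False)
        return float(t), float(p)
    f, p = stats.f_oneway(*groups)
    return float(f), float(p)


def merge_raters(
    table: pd.DataFrame,
    score_col: str,
    rater_col: str = "rater",
    sample_col: str = "sample_id",
    rule: str = "consensus",
) -> tuple[pd.DataFrame, float]:
    """Merge two raters' score tables and report exact agreement.

    Returns (merged table, exact-match agreement rate).  Under the default
    ``consensus`` rule discordant samples get a NaN score and a ``discordant``
    flag; ``rule='max'``/``'min'`` resolve them to the extreme score instead.
    Ordinals are never averaged.
    """
    raters = sorted(table[rater_col].unique())
    if len(raters) != 2:
        raise ValueError(f"expected exactly 2 raters, found {raters}")
    wide = table.pivot(index=sample_col, columns=rater_col, values=score_col)
    if wide.isna().any().any():
        missing = wide[wide.isna().any(axis=1)].index.tolist()
        raise ValueError(f"samples missing one rater's score: {missing}")
    a, b = wide[raters[0]], wide[raters[1]]
    agree = a == b
    agreement = float(agree.mean())
    if rule == "consensus":
        merged_score = a.where(agree, np.nan)
    elif rule == "max":
        merged_score = np.maximum(a, b)
    elif rule == "min":
        merged_score = np.minimum(a, b)
    else:
        raise ValueError(f"unknown reconciliation rule {rule!r}")
    merged = pd.DataFrame(
        {score_col: merged_score, "discordant": ~agree}, index=wide.index
    )
    return merged, agreement
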