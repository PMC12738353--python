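"""Isoform-diversity analysis of isomiR count tables.

The pipeline: filter low-abundance isomiRs (>100 reads in at least one sample
by default, ~12 RPM at 8.9M-read depth), count distinct isoforms per miRNA per
sample, restrict to miRNAs whose across-sample median isoform count is >= 3,
split samples into "more"/"less" diversity groups at the median, test isoform
counts between tissue or histology groups, and keep miRNAs that are both
significant and beyond a two-fold change.  The intersection of the
tumor/normal and unfavorable/favorable hit lists gives the final candidates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "IsomirCountTable",
    "DiversityComparison",
    "filter_low_abundance",
    "rpm",
    "diversity_matrix",
    "pooled_category_counts",
    "contingency_chi_square",
    "eligible_mirnas",
    "diversity_grouping",
    "differential_diversity",
    "select_candidates",
    "intersect_comparisons",
]

CATEGORY_LABELS = ("1", "2-9", ">=10")


@dataclass
class IsomirCountTable:
    """Raw isomiR read counts plus per-sample annotations.

    ``counts``: DataFrame indexed by (mirna, offset5, offset3), one column per
    sample, non-negative integer reads.  ``samples``: DataFrame indexed by
    sample_id with at least a ``tissue`` column (tumor/normal) and, for tumor
    samples, ``histology`` (favorable/unfavorable, or NA).
    """

    counts: pd.DataFrame
    samples: pd.DataFrame = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.counts.index.duplicated().any():
            raise ValueError("duplicate isomiR rows in count table")
        if self.counts.columns.duplicated().any():
            raise ValueError("duplicate sample columns in count table")
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("negative read counts")
        if self.samples is None:
            self.samples = pd.DataFrame(index=self.counts.columns)
        missing = set(self.counts.columns) - set(self.samples.index)
        if missing:
            raise ValueError(f"samples without annotation: {sorted(missing)[:5]}")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    def tissue_samples(self, tissue: str) -> list[str]:
        if "tissue" not in self.samples.columns:
            raise ValueError("sample annotation has no 'tissue' column")
        sel = self.samples.index[self.samples["tissue"] == tissue]
        return [s for s in self.counts.columns if s in set(sel)]

    def depths(self) -> pd.Series:
        """Per-sample library depth (column sums of raw counts)."""
        return self.counts.sum(axis=0)


@dataclass(frozen=True)
class DiversityComparison:
    """Per-miRNA two-group comparison of isoform counts."""

    mirna_name: str
    mean_a: float
    mean_b: float
    fold_change: float
    p_value: float
    significant: bool


def filter_low_abundance(
    table: IsomirCountTable, min_reads: int = 100, min_samples: int = 1
) -> IsomirCountTable:
    """Keep isomiRs with strictly more than ``min_reads`` reads in at least
    ``min_samples`` samples; the sample set is unchanged."""
    if min_reads < 0:
        raise ValueError("min_reads must be >= 0")
    if min_samples < 1:
        raise ValueError("min_samples must be >= 1")
    keep = (table.counts > min_reads).sum(axis=1) >= min_samples
    return IsomirCountTable(table.counts.loc[keep], table.samples)


def rpm(count: float, depth: float) -> float:
    """Reads per million: count / depth * 1e6."""
    if depth <= 0:
        raise ValueError(f"library depth must be positive, got {depth}")
    if count < 0:
        raise ValueError("count must be non-negative")
    return count / depth * 1e6


def diversity_matrix(table: IsomirCountTable, presence_min: int = 1) -> pd.DataFrame:
    """Distinct-isoform counts: rows = miRNA, columns = sample.

    Entry (m, s) is the number of isomiRs of miRNA m with at least
    ``presence_min`` reads in sample s.  Apply after abundance filtering.
    """
    present = table.counts >= presence_min
    return present.groupby(level="mirna").sum().astype(int)


def pooled_category_counts(table: IsomirCountTable, tissue: str) -> pd.Series:
    """Tally miRNAs by pooled isoform diversity within one tissue.

    A miRNA's pooled diversity is the number of distinct isomiRs observed
    (count >= 1) in any sample of that tissue; miRNAs with zero observed
    isoforms are not tallied.  Categories: exactly 1, 2-9, and >=10 isoforms
    (the bands partition all positive counts).
    """
    cols = table.tissue_samples(tissue)
    if not cols:
        raise ValueError(f"no samples with tissue {tissue!r}")
    observed = (table.counts[cols] >= 1).any(axis=1)
    pooled = (
        observed.groupby(level="mirna").sum().astype(int)
    )
    pooled = pooled[pooled > 0]
    cats = pd.cut(
        pooled,
        bins=[0, 1, 9, np.inf],
        labels=CATEGORY_LABELS,
    )
    counts = cats.value_counts().reindex(list(CATEGORY_LABELS)).fillna(0).astype(int)
    counts.name = tissue
    return counts


def contingency_chi_square(counts_a, counts_b) -> tuple[float, float]:
    """Pearson chi-square on a 2 x k contingency table (df = k - 1)."""
    a = np.asarray(counts_a, dtype=float)
    b = np.asarray(counts_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or a.size < 2:
        raise ValueError("need two category-count vectors of equal length >= 2")
    tbl = np.vstack([a, b])
    expected = stats.contingency.expected_freq(tbl)
    if (expected <= 0).any():
        raise ValueError(
            "a category has zero expected count; merge sparse categories first"
        )
    chi2, p, _, _ = stats.chi2_contingency(tbl, correction=False)
    return float(chi2), float(p)


def eligible_mirnas(div: pd.DataFrame, min_median: float = 3) -> list[str]:
    """miRNAs whose across-sample median isoform count is >= ``min_median``."""
    med = div.median(axis=1)
    return list(div.index[med >= min_median])


def diversity_grouping(div_row: pd.Series, tie: str = "less") -> pd.Series:
    """Split samples into "more"/"less" diversity at the median isoform count.

    Counts above the median are "more", below are "less"; ties at the median
    go to ``tie`` ("less" by default — conservative for a protective-diversity
    interpretation).  A degenerate all-equal row triggers a warning.
    """
    if tie not in ("less", "more"):
        raise ValueError(f"tie rule must be 'less' or 'more', got {tie!r}")
    vals = pd.Series(div_row, dtype=float)
    if len(vals) < 2:
        raise ValueError("need at least 2 samples to split")
    med = vals.median()
    labels = pd.Series(
        np.where(vals > med, "more", np.where(vals < med, "less", tie)),
        index=vals.index,
    )
    if vals.nunique() == 1:
        warnings.warn(
            "all isoform counts equal; the more/less split is degenerate",
            stacklevel=2,
        )
    return labels


def _welch_p(x: np.ndarray, y: np.ndarray, equal_var: bool) -> float:
    # identical constant groups carry no evidence: p = 1 by convention
    if np.var(x) == 0 and np.var(y) == 0:
        return 1.0 if np.mean(x) == np.mean(y) else 0.0
    _, p = stats.ttest_ind(x, y, equal_var=equal_var)
    return float(p)


def differential_diversity(
    div: pd.DataFrame,
    groups: pd.Series,
    alpha: float = 0.01,
    group_a: str | None = None,
    group_b: str | None = None,
    equal_var: bool = False,
) -> list[DiversityComparison]:
    """Per-miRNA two-sample t-test of isoform counts between two sample groups.

    ``groups`` maps sample id -> group label; ``group_a``/``group_b`` fix the
    fold-change orientation (mean_a / mean_b), defaulting to the two labels in
    sorted order.  Welch's unequal-variance test by default; set
    ``equal_var=True`` for the pooled-variance flavor.
    """
    groups = pd.Series(groups)
    labels = sorted(groups.dropna().unique())
    if group_a is None or group_b is None:
        if len(labels) != 2:
            raise ValueError(f"expected exactly 2 group labels, found {labels}")
        group_a, group_b = labels
    cols_a = [s for s in div.columns if groups.get(s) == group_a]
    cols_b = [s for s in div.columns if groups.get(s) == group_b]
    if len(cols_a) < 2 or len(cols_b) < 2:
        raise ValueError(
            f"each group needs >= 2 samples (got {len(cols_a)} {group_a!r}, "
            f"{len(cols_b)} {group_b!r})"
        )
    out = []
    for mirna, row in div.iterrows():
        x = row[cols_a].to_numpy(dtype=float)
        y = row[cols_b].to_numpy(dtype=float)
        p = _welch_p(x, y, equal_var)
        ma, mb = float(np.mean(x)), float(np.mean(y))
        fc = ma / mb if mb > 0 else np.inf if ma > 0 else np.nan
        out.append(
            DiversityComparison(
                mirna_name=str(mirna),
                mean_a=ma,
                mean_b=mb,
                fold_change=fc,
                p_value=p,
                significant=bool(p < alpha),
            )
        )
    return out


def select_candidates(
    comparisons: list[DiversityComparison], fc_threshold: float = 2.0
) -> list[str]:
    """Significant miRNAs whose fold change is beyond ``fc_threshold``.

    Two-sided band: FC > fc_threshold or FC < 1/fc_threshold (strict), so
    candidates with fewer isoforms in the numerator group also qualify.
    """
    if fc_threshold <= 1:
        raise ValueError("fc_threshold must be > 1")
    hits = []
    for c in comparisons:
        if not c.significant or not np.isfinite(c.fold_change):
            continue
        if c.fold_change > fc_threshold or c.fold_change < 1.0 / fc_threshold:
            hits.append(c.mirna_name)
    return hits


def intersect_comparisons(set_tn, set_uf) -> list[str]:
    """miRNAs shared by the tumor/normal and unfavorable/favorable hit lists,
    sorted by name."""
    return sorted(set(set_tn) & set(set_uf))


def comparisons_to_frame(comparisons: list[DiversityComparison]) -> pd.DataFrame:
    """Tabulate comparisons for reporting."""
    return pd.DataFrame(
        {
            "mirna": [c.mirna_name for c in comparisons],
            "mean_a": [c.mean_a for c in comparisons],
            "mean_b": [c.mean_b for c in comparisons],
            "fold_change": [c.fold_change for c in comparisons],
            "p_value": [c.p_value for c in comparisons],
            "significant": [c.significant for c in comparisons],
        }
    ).set_index("mirna")
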