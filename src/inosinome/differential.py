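"""Per-site differential editing between two sample groups.

The comparison follows the standard site-calling recipe for count-derived
editing levels: a sample *supports* a site when the site has >= 10 reads and
>= 1% editing in that sample; a site is *informative* when it is supported by
at least two samples in each group.  Informative sites are compared with a
two-tailed Mann-Whitney U test on per-sample frequencies and corrected across
sites with Benjamini-Hochberg; direction calls (over-/under-edited in group 1)
require the corrected q to pass the significance gate.

Unsupported cells are missing data in the medians, never zeros — a site that
was not measured is not an unedited site.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .model import EditingMatrix

OVER_EDITED = "over_edited"
UNDER_EDITED = "under_edited"
UNCHANGED = "unchanged"

#: largest pooled sample size for which the exact U distribution is used
EXACT_MAX_N = 20


def _resolve_groups(groups: Mapping[str, Sequence[str]],
                    samples: Sequence[str]) -> tuple[tuple[str, list[str]], tuple[str, list[str]]]:
    if len(groups) != 2:
        raise ValueError(f"exactly two groups required, got {len(groups)}")
    (name1, s1), (name2, s2) = groups.items()
    s1 = [s for s in s1 if s in set(samples)]
    s2 = [s for s in s2 if s in set(samples)]
    if not s1 or not s2:
        raise ValueError("both groups must contain at least one matrix sample")
    if set(s1) & set(s2):
        raise ValueError("groups must be disjoint")
    return (name1, s1), (name2, s2)


def support_mask(matrix: EditingMatrix, min_coverage: int = 10,
                 min_frequency: float = 0.01) -> pd.DataFrame:
    """Boolean samples x sites mask of cells passing the support rule."""
    cov_ok = matrix.cov >= min_coverage
    freq_ok = matrix.freq >= min_frequency  # NaN compares False
    return cov_ok & freq_ok & matrix.freq.notna()


def filter_informative_sites(matrix: EditingMatrix,
                             groups: Mapping[str, Sequence[str]],
                             min_coverage: int = 10,
                             min_frequency: float = 0.01,
                             min_per_group: int = 2) -> list[str]:
    """Site labels supported by >= ``min_per_group`` samples in *each* group."""
    (_, s1), (_, s2) = _resolve_groups(groups, matrix.samples)
    mask = support_mask(matrix, min_coverage, min_frequency)
    n1 = mask.loc[s1].sum(axis=0)
    n2 = mask.loc[s2].sum(axis=0)
    keep = (n1 >= min_per_group) & (n2 >= min_per_group)
    return list(matrix.freq.columns[keep])


def mann_whitney_u_two_tailed(x: Sequence[float],
                              y: Sequence[float]) -> tuple[float, float]:
    """Two-tailed Mann-Whitney U with the min(U_x, U_y) reporting convention.

    The exact null distribution is used when the pooled size is small and the
    data carry no ties; otherwise a tie-corrected normal approximation with
    continuity correction.  Two identical samples return p = 1 rather than a
    zero-variance failure.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 1 or y.size < 1:
        raise ValueError("both groups need at least one observation")
    pooled = np.concatenate([x, y])
    if np.all(pooled == pooled[0]):
        return (x.size * y.size / 2.0, 1.0)
    has_ties = np.unique(pooled).size < pooled.size
    method = "exact" if (pooled.size <= EXACT_MAX_N and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method,
                             use_continuity=True)
    u = min(res.statistic, x.size * y.size - res.statistic)
    p = min(float(res.pvalue), 1.0)
    return (float(u), max(p, np.nextafter(0, 1)))


def benjamini_hochberg(pvals: Sequence[float]) -> np.ndarray:
    """Step-up FDR q-values, in the input order."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


@dataclass(frozen=True)
class DifferentialResult:
    site_label: str
    region_class: str
    median_group1: float
    median_group2: float
    delta_median: float
    u_statistic: float
    p_value: float
    q_value: float
    direction: str
    n1: int
    n2: int


def differential_editing_table(matrix: EditingMatrix,
                               groups: Mapping[str, Sequence[str]],
                               alpha: float = 0.05,
                               min_coverage: int = 10,
                               min_frequency: float = 0.01,
                               min_per_group: int = 2,
                               sites: Sequence[str] | None = None) -> pd.DataFrame:
    """Per-site two-group comparison over informative sites.

    Group 1 is the first key of ``groups`` (tumor, by the usual convention);
    ``delta_median`` is group1 − group2 and the direction labels read as
    "over/under-edited in group 1".  Returns one row per tested site with the
    columns of :class:`DifferentialResult`, q-corrected across all tested
    sites.
    """
    (name1, s1), (name2, s2) = _resolve_groups(groups, matrix.samples)
    if sites is None:
        sites = filter_informative_sites(matrix, {name1: s1, name2: s2},
                                         min_coverage, min_frequency,
                                         min_per_group)
    mask = support_mask(matrix, min_coverage, min_frequency)
    by_label = matrix.site_by_label()

    records = []
    for label in sites:
        col = matrix.freq[label]
        m = mask[label]
        v1 = col.loc[s1][m.loc[s1]].to_numpy(dtype=float)
        v2 = col.loc[s2][m.loc[s2]].to_numpy(dtype=float)
        if v1.size < min_per_group or v2.size < min_per_group:
            continue  # lost support after restriction; excluded
        u, p = mann_whitney_u_two_tailed(v1, v2)
        records.append({
            "site_label": label,
            "region_class": by_label[label].region_class,
            "median_group1": float(np.median(v1)),
            "median_group2": float(np.median(v2)),
            "u_statistic": u,
            "p_value": p,
            "n1": int(v1.size),
            "n2": int(v2.size),
        })
    table = pd.DataFrame(records, columns=["site_label", "region_class",
                                           "median_group1", "median_group2",
                                           "u_statistic", "p_value", "n1", "n2"])
    if table.empty:
        table["delta_median"] = []
        table["q_value"] = []
        table["direction"] = []
        return table
    table["delta_median"] = table["median_group1"] - table["median_group2"]
    table["q_value"] = benjamini_hochberg(table["p_value"].to_numpy())
    significant = table["q_value"] <= alpha
    table["direction"] = UNCHANGED
    table.loc[significant & (table["delta_median"] > 0), "direction"] = OVER_EDITED
    table.loc[significant & (table["delta_median"] < 0), "direction"] = UNDER_EDITED
    order = ["site_label", "region_class", "median_group1", "median_group2",
             "delta_median", "u_statistic", "p_value", "q_value", "direction",
             "n1", "n2"]
    return table[order]


def direction_summary(table: pd.DataFrame) -> pd.DataFrame:
    """Counts of direction calls by region class (the headline tally)."""
    if table.empty:
        return pd.DataFrame(columns=["region_class", "direction", "n"])
    out = (table.groupby(["region_class", "direction"], observed=True)
           .size().rename("n").reset_index())
    return out


def top_sites(table: pd.DataFrame, min_abs_delta: float = 0.15,
              alpha: float = 0.05) -> pd.DataFrame:
    """Significant sites with |Δ median| at or above the top-site gate (15%)."""
    keep = (table["q_value"] <= alpha) & (table["delta_median"].abs() >= min_abs_delta)
    return table[keep].sort_values("delta_median", key=lambda s: s.abs(),
                                   ascending=False).reset_index(drop=True)


def correlate_index_with_covariate(values: Sequence[float],
                                   covariate: Sequence[float],
                                   method: str = "pearson") -> tuple[float, float]:
    """Pairwise-complete correlation between a per-sample index and a covariate.

    Returns ``(r, p)``; undefined (NaN, NaN) with a warning when either vector
    is constant after dropping incomplete pairs.
    """
    v = np.asarray(values, dtype=float)
    c = np.asarray(covariate, dtype=float)
    if v.shape != c.shape:
        raise ValueError("index and covariate vectors must align")
    ok = ~(np.isnan(v) | np.isnan(c))
    v, c = v[ok], c[ok]
    if v.size < 3:
        raise ValueError("need at least 3 complete pairs")
    if np.ptp(v) == 0 or np.ptp(c) == 0:
        warnings.warn("constant vector: correlation undefined", stacklevel=2)
        return (math.nan, math.nan)
    if method == "pearson":
        r, p = stats.pearsonr(v, c)
    elif method == "spearman":
        r, p = stats.spearmanr(v, c)
    else:
        raise ValueError(f"unknown correlation method {method!r}")
    return (float(r), float(p))
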