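"""Condition-level nonparametric comparisons and effect-size exports.

Pairwise comparisons use the two-sided Mann–Whitney U test (exact for
small samples without ties, normal approximation with tie correction
otherwise); multi-group comparisons use Kruskal–Wallis.  Star codes
follow the figure-legend thresholds: * p < 0.05, ** p < 0.005,
*** p < 0.0001.  No multiple-testing correction is applied.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = ["ComparisonResult", "mann_whitney", "kruskal_wallis",
           "percent_change", "star_code"]

STAR_THRESHOLDS = ((0.0001, "***"), (0.005, "**"), (0.05, "*"))


@dataclass
class ComparisonResult:
    groups: tuple
    statistic: float
    p_value: float
    test: str
    n: tuple
    effect: float | None = None

    @property
    def stars(self) -> str:
        return star_code(self.p_value)


def star_code(p: float) -> str:
    for thr, code in STAR_THRESHOLDS:
        if p < thr:
            return code
    return "ns"


def mann_whitney(a, b, group_names=("a", "b")) -> ComparisonResult:
    """Two-sided Mann–Whitney U; exact when both n ≤ 8 and there are no ties."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([a, b])
    ties = len(np.unique(pooled)) < len(pooled)
    method = "exact" if (len(a) <= 8 and len(b) <= 8 and not ties) else "asymptotic"
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return ComparisonResult(groups=tuple(group_names), statistic=float(res.statistic),
                            p_value=float(res.pvalue), test="mann_whitney_u",
                            n=(len(a), len(b)))


def kruskal_wallis(samples: list, group_names=None) -> ComparisonResult:
    """Kruskal–Wallis H with tie correction; chi-square p-value."""
    if len(samples) < 2:
        raise ValueError("need at least 2 groups")
    arrays = [np.asarray(s, dtype=float) for s in samples]
    if any(len(s) == 0 for s in arrays):
        raise ValueError("every group must be non-empty")
    res = sps.kruskal(*arrays)
    names = tuple(group_names) if group_names else tuple(f"g{i}" for i in range(len(arrays)))
    return ComparisonResult(groups=names, statistic=float(res.statistic),
                            p_value=float(res.pvalue), test="kruskal_wallis",
                            n=tuple(len(s) for s in arrays))


def percent_change(summaries: pd.DataFrame | dict, baseline: str) -> pd.DataFrame:
    """100 × (condition − baseline) / baseline, per feature.

    ``summaries`` is condition × feature (e.g. per-condition medians);
    the baseline row maps to 0 by construction.  Features with a zero
    baseline report NaN.
    """
    df = pd.DataFrame(summaries).astype(float)
    if baseline not in df.index:
        raise ValueError(f"baseline condition {baseline!r} not in summaries")
    base = df.loc[baseline]
    with np.errstate(divide="ignore", invalid="ignore"):
        out = 100.0 * (df - base) / base
    out[base.index[base == 0]] = np.nan
    return out


def comparisons_to_frame(results: list[ComparisonResult]) -> pd.DataFrame:
    """Tidy export: one row per comparison with stars."""
    return pd.DataFrame([{
        "comparison": " vs ".join(map(str, r.groups)),
        "test": r.test, "n": "/".join(map(str, r.n)),
        "statistic": r.statistic, "p_value": r.p_value, "stars": r.stars,
    } for r in results])
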