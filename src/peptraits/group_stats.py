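"""Group-wise feature summaries and rank-based significance tests.

Feature distributions (hydrophobicity, net charge, helix length, ...) are
compared between functional groups with two-sided Wilcoxon rank-sum
(Mann–Whitney U) tests over all unordered group pairs, with Holm step-down
correction for the family of pairwise comparisons. Peptides with no detected
amphiphilic helix contribute no value to helix features and are excluded from
those summaries and tests.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu
from statsmodels.stats.multitest import multipletests

ALPHA = 0.05  # significance threshold used for stars throughout


def pairwise_wilcoxon(values_by_group: dict[str, np.ndarray]) -> pd.DataFrame:
    """Holm-adjusted two-sided rank-sum p-values for all group pairs.

    Returns a symmetric matrix (groups × groups) with NaN on the diagonal.
    scipy's ``mannwhitneyu(method="auto")`` uses the exact distribution for
    small tie-free samples and the tie-corrected normal approximation
    otherwise; groups with all-identical values are handled via midranks.
    """
    groups = list(values_by_group)
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    arrays = {}
    for g in groups:
        arr = np.asarray(values_by_group[g], dtype=float)
        arr = arr[~np.isnan(arr)]
        if arr.size == 0:
            raise ValueError(f"group {g!r} has no defined values")
        arrays[g] = arr
    pairs = list(combinations(groups, 2))
    raw = []
    for a, b in pairs:
        if np.array_equal(arrays[a], arrays[b]):
            raw.append(1.0)  # identical samples: no evidence by construction
        else:
            raw.append(float(mannwhitneyu(arrays[a], arrays[b], alternative="two-sided").pvalue))
    adjusted = multipletests(raw, method="holm")[1] if pairs else []
    mat = pd.DataFrame(np.nan, index=groups, columns=groups)
    for (a, b), p in zip(pairs, adjusted):
        mat.loc[a, b] = mat.loc[b, a] = p
    return mat


def holm_adjust(pvalues) -> np.ndarray:
    """Holm step-down adjustment (monotone in the raw p, capped at 1)."""
    return multipletests(np.asarray(pvalues, dtype=float), method="holm")[1]


def summarize(features: pd.DataFrame, groups: pd.Series) -> pd.DataFrame:
    """Per group × feature: n (defined values), mean, median, quartiles."""
    rows = []
    grp = groups.loc[features.index]
    for g, idx in grp.groupby(grp).groups.items():
        sub = features.loc[idx]
        for col in features.columns:
            vals = sub[col].dropna()
            rows.append(
                {
                    "group": g,
                    "feature": col,
                    "n": int(vals.size),
                    "mean": float(vals.mean()) if vals.size else np.nan,
                    "median": float(vals.median()) if vals.size else np.nan,
                    "q1": float(vals.quantile(0.25)) if vals.size else np.nan,
                    "q3": float(vals.quantile(0.75)) if vals.size else np.nan,
                }
            )
    return pd.DataFrame(rows)


def feature_tests(features: pd.DataFrame, groups: pd.Series) -> dict[str, pd.DataFrame]:
    """Pairwise Holm-adjusted Wilcoxon matrices for every feature column."""
    grp = groups.loc[features.index]
    out = {}
    for col in features.columns:
        by_group = {
            str(g): features.loc[idx, col].dropna().to_numpy()
            for g, idx in grp.groupby(grp).groups.items()
        }
        by_group = {g: v for g, v in by_group.items() if v.size > 0}
        if len(by_group) >= 2:
            out[col] = pairwise_wilcoxon(by_group)
    return out


def stars(p: float) -> str:
    """Significance marker at the package-wide 0.05 threshold."""
    if np.isnan(p):
        return ""
    return "*" if p < ALPHA else "ns"
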