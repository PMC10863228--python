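"""Per-protein group comparisons with FDR control.

The group test is the two-sided Wilcoxon rank-sum (Mann-Whitney U with
average ranks for ties): exact null distribution when min(n) <= 25 and
there are no ties, otherwise the normal approximation with tie and
continuity corrections. Multiplicity is controlled with Benjamini-
Hochberg; a protein is significant at adjusted p < 0.05. The volcano
effect size is the log2 ratio of group medians (A+T+ over A-T-).
"""
from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

SIGNIFICANCE_Q = 0.05


def wilcoxon_rank_sum(x, y) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum test; returns (U of x, p)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both groups must be nonempty")
    pooled = np.concatenate([x, y])
    if np.ptp(pooled) == 0.0:
        return float(len(x) * len(y) / 2.0), 1.0
    has_ties = len(np.unique(pooled)) < len(pooled)
    method = "exact" if (min(len(x), len(y)) <= 25 and not has_ties) \
        else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method,
                             use_continuity=True)
    return float(res.statistic), float(res.pvalue)


def bh_adjust(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (original order)."""
    pvals = np.asarray(pvals, dtype=float)
    if pvals.ndim != 1 or len(pvals) == 0:
        raise ValueError("pvals must be a nonempty 1-d array")
    if np.isnan(pvals).any() or (pvals < 0).any() or (pvals > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(pvals, method="fdr_bh")[1]


def volcano_table(matrix: pd.DataFrame, groups: pd.Series,
                  neg_label: str = "A-T-",
                  pos_label: str = "A+T+") -> pd.DataFrame:
    """Effect (log2 median ratio pos/neg), Wilcoxon p and BH q per protein,
    sorted by q. Effect is missing (flagged) when the neg median is zero."""
    neg_ids = groups.index[groups == neg_label]
    pos_ids = groups.index[groups == pos_label]
    if len(neg_ids) < 3 or len(pos_ids) < 3:
        raise ValueError("both groups need >= 3 samples")
    neg = matrix.loc[neg_ids]
    pos = matrix.loc[pos_ids]
    med_neg = neg.median()
    med_pos = pos.median()
    with np.errstate(divide="ignore", invalid="ignore"):
        effect = np.log2(med_pos / med_neg)
    effect_missing = (med_neg == 0) | ~np.isfinite(effect)
    effect = effect.where(~effect_missing)
    pv = pd.Series({p: wilcoxon_rank_sum(pos[p].dropna(), neg[p].dropna())[1]
                    for p in matrix.columns})
    out = pd.DataFrame({
        "effect_log2_median_ratio": effect,
        "effect_missing": effect_missing,
        "p": pv,
        "q": bh_adjust(pv.to_numpy()),
    })
    out["significant"] = out["q"] < SIGNIFICANCE_Q
    out.index.name = "protein"
    return out.sort_values("q", kind="stable")
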