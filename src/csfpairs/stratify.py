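"""AT-status assignment, analysis-group selection and demographics.

Individuals are classified on CSF markers into the four AT groups
(A-T-, A-T+, A+T-, A+T+): amyloid positive when the amyloid metric falls
strictly below its cutoff, tau positive when p-tau reaches its cutoff.
The discovery rule uses the Abeta42/40 ratio (x10) with an inclusive
p-tau cutoff (>= 58 pg/ml); the validation rule uses Abeta42 alone with a
strict p-tau cutoff (> 55 pg/ml). Only A-T- and A+T+ individuals enter
the analyses, optionally restricting the A-T- group to SCD.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .diffstats import wilcoxon_rank_sum

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class ATRule:
    amyloid_metric: str = "abeta_ratio_x10"   # or "abeta42"
    amyloid_cutoff: float = 0.68
    ptau_cutoff: float = 58.0
    ptau_inclusive: bool = True               # T+ at ptau >= cutoff (else >)

    def __post_init__(self) -> None:
        if self.amyloid_metric not in ("abeta_ratio_x10", "abeta42"):
            raise ValueError(f"unknown amyloid metric {self.amyloid_metric!r}")
        if self.amyloid_cutoff <= 0 or self.ptau_cutoff <= 0:
            raise ValueError("cutoffs must be positive")


DISCOVERY_RULE = ATRule("abeta_ratio_x10", 0.68, 58.0, ptau_inclusive=True)
VALIDATION_RULE = ATRule("abeta42", 813.0, 55.0, ptau_inclusive=False)


def assign_at_status(markers: pd.DataFrame, rule: ATRule) -> pd.Series:
    """Pure function markers -> AT status per sample.

    A+ iff the amyloid metric is strictly below the cutoff; T+ iff p-tau
    reaches the cutoff (inclusive or strict per the rule). Samples missing
    a required marker get a missing status (logged).
    """
    amyloid = markers[rule.amyloid_metric]
    ptau = markers["ptau"]
    a_pos = amyloid < rule.amyloid_cutoff
    t_pos = ptau >= rule.ptau_cutoff if rule.ptau_inclusive else ptau > rule.ptau_cutoff
    status = pd.Series(
        np.where(a_pos, "A+", "A-") + np.where(t_pos, "T+", "T-"),
        index=markers.index, name="at_status", dtype=object)
    incomplete = amyloid.isna() | ptau.isna()
    if incomplete.any():
        log.warning("%d samples missing required markers; status left missing",
                    int(incomplete.sum()))
        status[incomplete] = np.nan
    return status


def select_analysis_groups(samples: pd.DataFrame, statuses: pd.Series,
                           scd_only: bool = True) -> pd.Series:
    """Keep A-T- (optionally SCD-only) and A+T+ samples; drop the rest.

    Returns a Series mapping retained sample ids to their group label and
    logs the counts of excluded statuses.
    """
    statuses = statuses.reindex(samples.index)
    if "pool_flag" in samples:
        statuses = statuses[~samples["pool_flag"]]
    neg = statuses.index[statuses == "A-T-"]
    pos = statuses.index[statuses == "A+T+"]
    n_excluded = int(statuses.isin(["A-T+", "A+T-"]).sum())
    if scd_only:
        neg = neg[samples.loc[neg, "diagnosis"] == "SCD"]
    if len(neg) == 0 or len(pos) == 0:
        raise ValueError(
            f"empty analysis group (A-T-: {len(neg)}, A+T+: {len(pos)})")
    log.info("selected %d A-T- and %d A+T+ samples (%d A-T+/A+T- excluded)",
             len(neg), len(pos), n_excluded)
    groups = pd.concat([pd.Series("A-T-", index=neg),
                        pd.Series("A+T+", index=pos)])
    groups.name = "group"
    return groups


def fisher_exact_2x2(table) -> float:
    """Two-sided Fisher exact p for a 2x2 table (margins fixed; the p-value
    sums hypergeometric probabilities <= the observed table's)."""
    table = np.asarray(table)
    if table.shape != (2, 2):
        raise ValueError("table must be 2x2")
    if (table < 0).any() or not np.issubdtype(table.dtype, np.integer):
        raise ValueError("table must contain non-negative integers")
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        log.warning("zero margin in 2x2 table; p = 1 by convention")
        return 1.0
    return float(stats.fisher_exact(table, alternative="two-sided")[1])


def _median_range(values: pd.Series) -> str:
    values = values.dropna()
    if values.empty:
        return ""
    return f"{values.median():g} ({values.min():g}–{values.max():g})"


def summarize_demographics(samples: pd.DataFrame, markers: pd.DataFrame,
                           cognition: pd.DataFrame,
                           groups: pd.Series) -> dict:
    """Per-group medians (ranges), availability counts and the group tests
    (Wilcoxon rank-sum for age, Fisher's exact for sex; complete cases)."""
    levels = ["A-T-", "A+T+"]
    rows = {}
    rows["n"] = {g: int((groups == g).sum()) for g in levels}
    for g in levels:
        ids = groups.index[groups == g]
        diag = samples.loc[ids, "diagnosis"].value_counts()
        rows.setdefault("diagnosis_scd_mci_ad", {})[g] = "/".join(
            str(int(diag.get(k, 0))) for k in ("SCD", "MCI", "AD"))
        rows.setdefault("age", {})[g] = _median_range(samples.loc[ids, "age"])
        sex = samples.loc[ids, "sex"].value_counts()
        rows.setdefault("sex_f_m", {})[g] = (
            f"{int(sex.get('F', 0))}/{int(sex.get('M', 0))}")
        for var in markers.columns:
            vals = markers.loc[markers.index.intersection(ids), var]
            rows.setdefault(var, {})[g] = _median_range(vals)
            rows.setdefault(f"{var}_n", {})[g] = int(vals.notna().sum())
        for var in cognition.columns:
            vals = cognition.loc[cognition.index.intersection(ids), var]
            rows.setdefault(var, {})[g] = _median_range(vals)
            rows.setdefault(f"{var}_n", {})[g] = int(vals.notna().sum())
    table = pd.DataFrame(rows).T[levels]

    neg_ids = groups.index[groups == "A-T-"]
    pos_ids = groups.index[groups == "A+T+"]
    age_p = wilcoxon_rank_sum(samples.loc[neg_ids, "age"].dropna(),
                              samples.loc[pos_ids, "age"].dropna())[1]
    sex_tab = np.array(
        [[int((samples.loc[ids, "sex"] == "F").sum()),
          int((samples.loc[ids, "sex"] == "M").sum())]
         for ids in (neg_ids, pos_ids)]).T
    sex_p = fisher_exact_2x2(sex_tab)
    return {"table": table, "age_wilcoxon_p": float(age_p),
            "sex_fisher_p": float(sex_p)}
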