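"""Protein ratios and their correlation to cognitive scores.

Cross-cluster ratios are always oriented tau-associated protein over
amyloid-associated protein; within-cluster ratios get a seeded random
orientation. Because both proteins of a cross pair share the individual's
global CSF concentration factor, the ratio cancels it, which is the
mechanism by which ratios track pathology and cognition more tightly than
single proteins. Ratios and single proteins are correlated (Pearson) with
the five cognitive scores on pairwise-complete samples, correlation
strength is compared between categories with Wilcoxon rank-sum tests on
|R|, and ratios/proteins are compared between diagnosis strata within
each AT group (unadjusted).
"""
from __future__ import annotations

import logging
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .diffstats import wilcoxon_rank_sum

log = logging.getLogger(__name__)

MARKER_RATIOS = (("ttau", "abeta42"), ("ptau", "abeta42"))


def compute_ratios(matrix: pd.DataFrame, pairs, seed: int = 0,
                   markers: pd.DataFrame | None = None
                   ) -> tuple[pd.DataFrame, pd.Series]:
    """Ratio columns "numerator/denominator" on the linear scale.

    Cross pairs keep the tau protein in the numerator; within-cluster
    pairs are oriented by a seeded coin flip. When a marker panel is
    supplied, t-tau/Abeta42 and p-tau/Abeta42 are appended (category
    ``marker``). Returns (ratio matrix, category per column).
    """
    rng = np.random.default_rng(seed)
    cols, cats = {}, {}
    for pair in pairs:
        if pair.protein_b is None:
            continue
        num, den = pair.protein_a, pair.protein_b
        if pair.category != "cross" and rng.random() < 0.5:
            num, den = den, num
        denom = matrix[den]
        assert (denom > 0).all(), "denominator must be strictly positive"
        cols[f"{num}/{den}"] = matrix[num] / denom
        cats[f"{num}/{den}"] = pair.category
    if markers is not None:
        for num, den in MARKER_RATIOS:
            name = f"{num}/{den}"
            cols[name] = markers[num] / markers[den]
            cats[name] = "marker"
    ratios = pd.DataFrame(cols, index=matrix.index)
    return ratios, pd.Series(cats, name="category")


def cognition_correlations(values: pd.DataFrame, cognition: pd.DataFrame,
                           sample_ids=None, min_n: int = 3) -> pd.DataFrame:
    """Pearson R per (entity, score) over pairwise-complete samples."""
    if sample_ids is not None:
        values = values.loc[values.index.intersection(sample_ids)]
    cognition = cognition.reindex(values.index)
    rows = []
    for entity in values.columns:
        v = values[entity]
        for score in cognition.columns:
            c = cognition[score]
            mask = v.notna() & c.notna()
            n = int(mask.sum())
            if n < min_n:
                rows.append((entity, score, np.nan, n))
                continue
            r = stats.pearsonr(v[mask], c[mask]).statistic
            rows.append((entity, score, float(r), n))
    return pd.DataFrame(rows, columns=["entity", "score", "r", "n"])


def compare_correlation_categories(table: pd.DataFrame,
                                   categories: pd.Series,
                                   reference: str = "cross") -> pd.DataFrame:
    """Per score, two-sided Wilcoxon rank-sum on |R| between the reference
    category and every other category (>= 2 entities each)."""
    table = table.copy()
    table["category"] = table["entity"].map(categories)
    rows = []
    for score, sub in table.groupby("score"):
        ref = sub.loc[sub["category"] == reference, "r"].abs().dropna()
        for cat in sorted(sub["category"].dropna().unique()):
            if cat == reference:
                continue
            other = sub.loc[sub["category"] == cat, "r"].abs().dropna()
            if len(ref) < 2 or len(other) < 2:
                log.info("|R| comparison %s vs %s for %s skipped",
                         reference, cat, score)
                continue
            _, p = wilcoxon_rank_sum(ref, other)
            rows.append((score, reference, cat, float(ref.median()),
                         float(other.median()), p))
    return pd.DataFrame(rows, columns=["score", "category_a", "category_b",
                                       "median_abs_r_a", "median_abs_r_b",
                                       "p"])


def diagnosis_stratified_tests(values: pd.DataFrame, diagnosis: pd.Series,
                               statuses: pd.Series,
                               strata: tuple = ("A-T-", "A+T+"),
                               diagnoses: tuple = ("SCD", "MCI", "AD")
                               ) -> pd.DataFrame:
    """Within each AT stratum, pairwise Wilcoxon rank-sum between diagnosis
    groups for every entity column; unadjusted p-values. Cells with fewer
    than 2 samples are skipped."""
    rows = []
    for stratum in strata:
        ids = statuses.index[statuses == stratum]
        diag = diagnosis.reindex(ids)
        for entity in values.columns:
            v = values[entity].reindex(ids)
            for d1, d2 in combinations(diagnoses, 2):
                a = v[diag == d1].dropna()
                b = v[diag == d2].dropna()
                if len(a) < 2 or len(b) < 2:
                    continue
                _, p = wilcoxon_rank_sum(a, b)
                rows.append((entity, stratum, d1, d2, len(a), len(b), p))
    return pd.DataFrame(rows, columns=["entity", "stratum", "diag_a",
                                       "diag_b", "n_a", "n_b", "p"])
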