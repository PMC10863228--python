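"""Exhaustive cluster-matched protein-pair SVM screen.

Every protein pair within and between the tau- and amyloid-associated
clusters (the peripheral cluster is excluded) is evaluated as a two-feature
linear soft-margin SVM separating A-T- from A+T+ individuals:

* the majority class is undersampled once (seeded) to the minority size;
* 101 stratified 70/30 train/test splits are drawn with fixed seeds,
  shared across all pairs;
* per split, the cost parameter is tuned on the training part by
  stratified 10-fold cross-validation over the grid {0.1, 1, 10, 100}
  (mean fold accuracy, ties to the smallest cost), the model is refit on
  the full training part and scored on the test part by ROC AUC;
* the pair's summary is the median of the 101 AUCs — an order statistic,
  so it identifies one concrete fitted model ("median model") whose test
  AUC gets a stratified bootstrap percentile CI (1000 iterations);
* the median model's weights are transferred to the validation cohort
  (features re-standardized there, all samples used, no undersampling).

Features are natural-log transformed, centred to the training median and
scaled to unit SD; statistics are estimated on training data only.
"""
from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from itertools import combinations, product

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.model_selection import StratifiedKFold, train_test_split
from sklearn.svm import SVC

from .diffstats import wilcoxon_rank_sum

log = logging.getLogger(__name__)

MAX_SEED = 2**31 - 1


@dataclass(frozen=True)
class PairSpec:
    protein_a: str
    protein_b: str | None
    category: str   # cross | within_tau | within_amyloid | single_tau | single_amyloid

    def __post_init__(self) -> None:
        if self.protein_b is not None and self.protein_a == self.protein_b:
            raise ValueError("pair must consist of two distinct proteins")

    @property
    def features(self) -> tuple[str, ...]:
        if self.protein_b is None:
            return (self.protein_a,)
        return (self.protein_a, self.protein_b)

    @property
    def name(self) -> str:
        return self.protein_a if self.protein_b is None \
            else f"{self.protein_a}+{self.protein_b}"


@dataclass(frozen=True)
class SVMConfig:
    cost_grid: tuple = (0.1, 1.0, 10.0, 100.0)
    cv_folds: int = 10
    n_repeats: int = 101
    train_fraction: float = 0.7
    undersample_seed: int = 0
    split_seeds: tuple = ()
    bootstrap_iters: int = 1000
    bootstrap_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_repeats % 2 == 0:
            raise ValueError("n_repeats must be odd (median is an element)")
        if not (0.0 < self.train_fraction < 1.0):
            raise ValueError("train_fraction must lie in (0, 1)")
        if len(self.split_seeds) not in (0, self.n_repeats):
            raise ValueError("split_seeds must have n_repeats entries")

    @classmethod
    def from_seed(cls, seed: int, **overrides) -> "SVMConfig":
        """Derive all internal seeds deterministically from one integer."""
        n = overrides.get("n_repeats", 101)
        ss = np.random.SeedSequence([int(seed), 2])
        state = ss.generate_state(n + 2) % MAX_SEED
        return cls(undersample_seed=int(state[0]),
                   bootstrap_seed=int(state[1]),
                   split_seeds=tuple(int(s) for s in state[2:]),
                   **overrides)

    def seeds(self) -> tuple:
        if self.split_seeds:
            return self.split_seeds
        return tuple(range(1, self.n_repeats + 1))


@dataclass
class LinearSVMModel:
    features: tuple
    weights: np.ndarray
    bias: float
    C: float
    center: np.ndarray   # per-feature median of log intensities
    scale: np.ndarray    # per-feature SD of log intensities

    def decision(self, X_raw: np.ndarray) -> np.ndarray:
        """Decision score for raw (linear-scale) feature values."""
        z = (np.log(np.asarray(X_raw, dtype=float)) - self.center) / self.scale
        return z @ self.weights + self.bias

    def to_dict(self) -> dict:
        return {"features": list(self.features),
                "weights": [float(w) for w in self.weights],
                "bias": float(self.bias), "C": float(self.C),
                "center": [float(c) for c in self.center],
                "scale": [float(s) for s in self.scale]}


@dataclass
class PairScreenResult:
    pair: PairSpec
    auc_per_repeat: np.ndarray
    median_auc: float
    median_index: int
    median_model: LinearSVMModel
    ci_low: float
    ci_high: float
    validation_auc: float | None = None
    validation_ci: tuple | None = None


def enumerate_pairs(block_labels: pd.Series, scope: str = "pairs"
                    ) -> list[PairSpec]:
    """Pair specs from semantic cluster labels.

    ``pairs``: tau x amyloid cross pairs plus unordered within-cluster
    pairs (peripheral excluded). ``singles``: one singleton spec per tau-
    and amyloid-cluster protein.
    """
    tau = sorted(block_labels.index[block_labels == "tau_associated"])
    amy = sorted(block_labels.index[block_labels == "amyloid_associated"])
    if not tau or not amy:
        warnings.warn("empty tau or amyloid cluster; pair set reduced",
                      stacklevel=2)
    if scope == "pairs":
        out = [PairSpec(a, b, "cross") for a, b in product(tau, amy)]
        out += [PairSpec(a, b, "within_tau") for a, b in combinations(tau, 2)]
        out += [PairSpec(a, b, "within_amyloid")
                for a, b in combinations(amy, 2)]
        return out
    if scope == "singles":
        return ([PairSpec(p, None, "single_tau") for p in tau]
                + [PairSpec(p, None, "single_amyloid") for p in amy])
    raise ValueError(f"unknown scope {scope!r}")


def undersample_majority(labels: pd.Series, seed: int) -> pd.Index:
    """Reduce the majority class by seeded sampling without replacement to
    the minority size; returns the retained sample ids (original order)."""
    counts = labels.value_counts()
    if len(counts) != 2:
        raise ValueError("undersampling expects exactly two classes")
    minority, majority = counts.index[-1], counts.index[0]
    if counts[minority] == counts[majority]:
        return labels.index
    rng = np.random.default_rng(seed)
    maj_ids = labels.index[labels == majority]
    keep = rng.choice(len(maj_ids), size=int(counts[minority]), replace=False)
    kept = set(maj_ids[np.sort(keep)]) | set(labels.index[labels == minority])
    return labels.index[labels.index.isin(kept)]


def roc_auc(scores, labels) -> float:
    """AUC as the probability that a random positive outscores a random
    negative, ties counted 1/2 (Mann-Whitney form)."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    pos = labels == 1
    n_pos, n_neg = int(pos.sum()), int((~pos).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present")
    ranks = rankdata(scores)
    u = ranks[pos].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def bootstrap_auc_ci(scores, labels, iters: int = 1000,
                     seed: int = 0) -> tuple[float, float]:
    """Stratified bootstrap percentile CI (2.5/97.5) for the ROC AUC."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    rng = np.random.default_rng(seed)
    pos_scores = scores[labels == 1]
    neg_scores = scores[labels != 1]
    if len(pos_scores) == 0 or len(neg_scores) == 0:
        raise ValueError("both classes must be present")
    aucs = np.empty(iters)
    for i in range(iters):
        p = pos_scores[rng.integers(0, len(pos_scores), len(pos_scores))]
        n = neg_scores[rng.integers(0, len(neg_scores), len(neg_scores))]
        s = np.concatenate([p, n])
        y = np.concatenate([np.ones(len(p), dtype=int),
                            np.zeros(len(n), dtype=int)])
        aucs[i] = roc_auc(s, y)
    lo, hi = np.percentile(aucs, [2.5, 97.5])
    return float(lo), float(hi)


def _log_stats(X_log: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    center = np.median(X_log, axis=0)
    scale = np.std(X_log - center, axis=0, ddof=1)
    if (scale == 0).any():
        warnings.warn("constant feature on training data; scale set to 1",
                      stacklevel=2)
        scale = np.where(scale == 0, 1.0, scale)
    return center, scale


def fit_linear_svm(X_raw: np.ndarray, y: np.ndarray, C: float,
                   stats: tuple | None = None) -> LinearSVMModel:
    """Fit the linear soft-margin SVM on log/median-centred/SD-scaled
    features (statistics from the provided training data unless given)."""
    X_log = np.log(np.asarray(X_raw, dtype=float))
    if not np.all(np.isfinite(X_log)):
        raise ValueError("features must be positive and finite")
    y = np.asarray(y)
    if min((y == 1).sum(), (y != 1).sum()) < 2:
        raise ValueError("need >= 2 samples per class")
    center, scale = stats if stats is not None else _log_stats(X_log)
    z = (X_log - center) / scale
    svc = SVC(kernel="linear", C=C)
    svc.fit(z, y)
    return LinearSVMModel(features=(), weights=svc.coef_[0].copy(),
                          bias=float(svc.intercept_[0]), C=float(C),
                          center=center, scale=scale)


def tune_cost(X_raw: np.ndarray, y: np.ndarray, config: SVMConfig,
              seed: int) -> float:
    """Stratified k-fold CV accuracy over the cost grid; ties -> smallest C."""
    y = np.asarray(y)
    for attempt in range(5):
        skf = StratifiedKFold(n_splits=config.cv_folds, shuffle=True,
                              random_state=(seed + attempt * 7919) % MAX_SEED)
        folds = list(skf.split(X_raw, y))
        if all(len(np.unique(y[tr])) == 2 for tr, _ in folds):
            break
    else:  # pragma: no cover
        raise ValueError("could not draw folds with both classes")
    best_c, best_acc = None, -np.inf
    for C in config.cost_grid:
        correct = 0
        for tr, te in folds:
            model = fit_linear_svm(X_raw[tr], y[tr], C)
            pred = (model.decision(X_raw[te]) > 0).astype(int)
            correct += int((pred == y[te]).sum())
        acc = correct / len(y)
        if acc > best_acc:   # strict: ties keep the earlier (smaller) C
            best_c, best_acc = C, acc
    return float(best_c)


def make_splits(y: pd.Series, config: SVMConfig) -> list:
    """The 101 seeded stratified 70/30 splits, shared across all pairs."""
    idx = np.arange(len(y))
    splits = []
    for seed in config.seeds():
        tr, te = train_test_split(idx, train_size=config.train_fraction,
                                  stratify=np.asarray(y),
                                  random_state=seed % MAX_SEED)
        splits.append((tr, te))
    return splits


def run_pair_screen(pair: PairSpec, matrix: pd.DataFrame, labels: pd.Series,
                    config: SVMConfig, splits: list | None = None
                    ) -> PairScreenResult:
    """Full repeated-holdout protocol for one pair on a balanced sample set."""
    feats = list(pair.features)
    X_df = matrix.loc[labels.index, feats]
    X = X_df.to_numpy(dtype=float)
    if len(feats) == 2 and np.array_equal(X[:, 0], X[:, 1]):
        warnings.warn(f"pair {pair.name}: identical feature columns",
                      stacklevel=2)
    if splits is None:
        splits = make_splits(labels, config)
    return _run_screen_features(pair, X_df, labels, config, splits)


def screen_pairs(pairs: list, matrix: pd.DataFrame, labels: pd.Series,
                 config: SVMConfig) -> dict:
    """Run the screen for a list of pair specs with shared undersampling
    and shared splits; returns {pair name: PairScreenResult}."""
    kept_ids = undersample_majority(labels, config.undersample_seed)
    balanced = labels.loc[kept_ids]
    y = (balanced == "A+T+").astype(int) if balanced.dtype == object \
        else balanced.astype(int)
    splits = make_splits(y, config)
    results = {}
    for pair in pairs:
        results[pair.name] = run_pair_screen(pair, matrix, y, config, splits)
    return results


def transfer_model(result: PairScreenResult, val_matrix: pd.DataFrame,
                   val_labels: pd.Series, config: SVMConfig,
                   recompute_stats: bool = True):
    """Apply the median model to the validation cohort (all samples, no
    undersampling); feature statistics are recomputed on the validation
    cohort by default because intensities are relative per assay run."""
    feats = list(result.median_model.features)
    missing = [f for f in feats if f not in val_matrix.columns]
    if missing:
        raise ValueError(f"validation matrix lacks protein(s): {missing}")
    y = (val_labels == "A+T+").astype(int) if val_labels.dtype == object \
        else val_labels.astype(int)
    X_log = np.log(val_matrix.loc[y.index, feats].to_numpy(dtype=float))
    if recompute_stats:
        center, scale = _log_stats(X_log)
    else:
        center, scale = result.median_model.center, result.median_model.scale
    z = (X_log - center) / scale
    scores = z @ result.median_model.weights + result.median_model.bias
    auc = roc_auc(scores, y.to_numpy())
    ci = bootstrap_auc_ci(scores, y.to_numpy(), config.bootstrap_iters,
                          seed=config.bootstrap_seed)
    result.validation_auc = auc
    result.validation_ci = ci
    return auc, ci


def covariate_variant(pair: PairSpec, matrix: pd.DataFrame,
                      qalb: pd.Series, labels: pd.Series,
                      config: SVMConfig) -> PairScreenResult:
    """Identical protocol with log Q-Alb as a third predictor; samples with
    missing Q-Alb are dropped (requires >= 90% availability)."""
    qalb = qalb.reindex(labels.index)
    if qalb.notna().sum() == 0:
        raise ValueError("albumin quotient entirely missing")
    frac = qalb.notna().mean()
    if frac < 0.9:
        raise ValueError(f"albumin quotient available for only {frac:.0%} "
                         "of samples (need >= 90%)")
    keep = qalb.notna()
    aug = matrix.loc[labels.index[keep], list(pair.features)].copy()
    aug["qalb"] = qalb[keep]
    spec = PairSpec(pair.protein_a, pair.protein_b,
                    category=pair.category + "_qalb")
    sub_labels = labels[keep]
    y = (sub_labels == "A+T+").astype(int) if sub_labels.dtype == object \
        else sub_labels.astype(int)
    splits = make_splits(y, config)
    X = aug[list(pair.features) + ["qalb"]]
    return _run_screen_features(spec, X, y, config, splits)


def _run_screen_features(spec, X_df, y, config, splits):
    X = X_df.to_numpy(dtype=float)
    yv = np.asarray(y, dtype=int)
    seeds = config.seeds()
    aucs = np.empty(config.n_repeats)
    kept = []
    for i, (tr, te) in enumerate(splits):
        C = tune_cost(X[tr], yv[tr], config, seed=seeds[i])
        model = fit_linear_svm(X[tr], yv[tr], C)
        scores = model.decision(X[te])
        aucs[i] = roc_auc(scores, yv[te])
        kept.append((model, scores, yv[te]))
    order = np.argsort(aucs, kind="stable")
    med_pos = order[(config.n_repeats - 1) // 2]
    median_auc = float(aucs[med_pos])
    median_index = int(np.flatnonzero(aucs == median_auc)[0])
    model, scores, y_te = kept[median_index]
    model.features = tuple(X_df.columns)
    ci = bootstrap_auc_ci(scores, y_te, config.bootstrap_iters,
                          seed=config.bootstrap_seed)
    return PairScreenResult(spec, aucs, median_auc, median_index, model,
                            ci[0], ci[1])


def compare_categories(results: dict) -> pd.DataFrame:
    """Pairwise two-sided Wilcoxon rank-sum tests on the sets of median
    AUCs between pair categories (unadjusted)."""
    by_cat = {}
    for res in results.values():
        by_cat.setdefault(res.pair.category, []).append(res.median_auc)
    cats = sorted(by_cat)
    rows = []
    for a, b in combinations(cats, 2):
        if len(by_cat[a]) < 2 or len(by_cat[b]) < 2:
            log.info("category comparison %s vs %s skipped (<2 results)", a, b)
            continue
        _, p = wilcoxon_rank_sum(by_cat[a], by_cat[b])
        rows.append((a, b, float(np.median(by_cat[a])),
                     float(np.median(by_cat[b])), p))
    return pd.DataFrame(rows, columns=["category_a", "category_b",
                                       "median_auc_a", "median_auc_b", "p"])


def results_table(results: dict) -> pd.DataFrame:
    """One row per pair: category, discovery median AUC with CI, validation
    AUC with CI where available."""
    rows = []
    for name, r in results.items():
        rows.append({
            "pair": name, "category": r.pair.category,
            "median_auc": r.median_auc,
            "ci_low": r.ci_low, "ci_high": r.ci_high,
            "validation_auc": r.validation_auc,
            "validation_ci_low": r.validation_ci[0] if r.validation_ci else np.nan,
            "validation_ci_high": r.validation_ci[1] if r.validation_ci else np.nan,
        })
    return pd.DataFrame(rows).sort_values("median_auc", ascending=False,
                                          kind="stable").reset_index(drop=True)
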