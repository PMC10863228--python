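"""The repeated-holdout SVM protocol: pair enumeration, undersampling,
ROC/bootstrap machinery with counting oracles, tuning and transfer."""
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from csfpairs.pairscreen import PairSpec, SVMConfig, bootstrap_auc_ci, \
    compare_categories, covariate_variant, enumerate_pairs, fit_linear_svm, \
    make_splits, roc_auc, run_pair_screen, screen_pairs, transfer_model, \
    tune_cost, undersample_majority


def _labels(n_tau=11, n_amy=16, n_per=5):
    labels = (["tau_associated"] * n_tau + ["amyloid_associated"] * n_amy
              + ["peripheral"] * n_per)
    idx = ([f"T{i}" for i in range(n_tau)] + [f"A{i}" for i in range(n_amy)]
           + [f"P{i}" for i in range(n_per)])
    return pd.Series(labels, index=idx)


def test_enumerate_pair_counts():
    pairs = enumerate_pairs(_labels(), scope="pairs")
    by_cat = pd.Series([p.category for p in pairs]).value_counts()
    assert by_cat["cross"] == 11 * 16
    assert by_cat["within_tau"] == 55          # C(11, 2)
    assert by_cat["within_amyloid"] == 120     # C(16, 2)
    assert all("P" not in p.protein_a[0] for p in pairs)
    for p in pairs:
        if p.category == "cross":
            assert p.protein_a.startswith("T") and p.protein_b.startswith("A")


def test_enumerate_singles_scope():
    singles = enumerate_pairs(_labels(n_tau=4), scope="singles")
    tau_singles = [s for s in singles if s.category == "single_tau"]
    assert len(tau_singles) == 4
    assert all(s.protein_b is None for s in singles)
    with pytest.raises(ValueError):
        enumerate_pairs(_labels(), scope="bogus")
    with pytest.raises(ValueError):
        PairSpec("X", "X", "cross")


def test_undersampling_matches_minority_and_is_deterministic():
    idx = [f"S{i}" for i in range(213)]
    labels = pd.Series(["A-T-"] * 148 + ["A+T+"] * 65, index=idx)
    kept = undersample_majority(labels, seed=3)
    counts = labels.loc[kept].value_counts()
    assert counts.to_dict() == {"A-T-": 65, "A+T+": 65}
    assert kept.equals(undersample_majority(labels, seed=3))
    balanced = pd.Series(["a"] * 10 + ["b"] * 10)
    assert undersample_majority(balanced, seed=1).equals(balanced.index)


def roc_oracle(scores, labels):
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    pos = scores[labels == 1]
    neg = scores[labels != 1]
    total = 0.0
    for p in pos:
        for n in neg:
            total += 1.0 if p > n else (0.5 if p == n else 0.0)
    return total / (len(pos) * len(neg))


def test_roc_auc_known_values():
    assert roc_auc([1, 2, 3, 4], [0, 0, 1, 1]) == 1.0
    assert roc_auc([5, 5, 5, 5], [0, 1, 0, 1]) == 0.5
    assert roc_auc([0.1, 0.4, 0.35, 0.8], [0, 0, 1, 1]) == 0.75
    with pytest.raises(ValueError):
        roc_auc([1, 2], [1, 1])


@given(st.lists(st.integers(0, 4), min_size=2, max_size=10),
       st.data())
def test_roc_auc_matches_pair_counting_oracle(scores, data):
    n = len(scores)
    labels = data.draw(st.lists(st.integers(0, 1), min_size=n, max_size=n))
    if len(set(labels)) < 2:
        labels[0], labels[-1] = 0, 1
    assert roc_auc(scores, labels) == pytest.approx(
        roc_oracle(scores, labels), abs=1e-12)


def test_roc_auc_invariant_under_monotone_transform():
    rng = np.random.default_rng(0)
    scores = rng.normal(size=40)
    labels = rng.integers(0, 2, 40)
    labels[:2] = [0, 1]
    base = roc_auc(scores, labels)
    assert roc_auc(np.exp(scores), labels) == pytest.approx(base)
    assert roc_auc(3 * scores - 7, labels) == pytest.approx(base)


def test_bootstrap_ci_properties():
    scores = np.concatenate([np.zeros(20), np.ones(20)])
    labels = scores.astype(int)
    assert bootstrap_auc_ci(scores, labels, iters=200, seed=1) == (1.0, 1.0)
    rng = np.random.default_rng(2)
    s = rng.normal(size=60) + np.repeat([0, 1.0], 30)
    y = np.repeat([0, 1], 30)
    lo, hi = bootstrap_auc_ci(s, y, iters=500, seed=5)
    assert lo <= roc_auc(s, y) <= hi
    assert (lo, hi) == bootstrap_auc_ci(s, y, iters=500, seed=5)


def _separable(n=60, gap=4.0, seed=0, features=1):
    rng = np.random.default_rng(seed)
    y = np.repeat([0, 1], n // 2)
    X = np.exp(rng.normal(0, 0.3, size=(n, features))
               + gap * y[:, None])
    return X, y


def test_svm_separates_separable_data():
    X, y = _separable()
    model = fit_linear_svm(X, y, C=1.0)
    assert roc_auc(model.decision(X), y) == 1.0
    assert np.all(np.isfinite(model.weights))


def test_svm_shuffled_labels_near_chance():
    rng = np.random.default_rng(3)
    X, y = _separable(n=130, gap=2.0)
    y_shuffled = rng.permutation(y)
    tr = np.arange(0, 130, 2)
    te = np.arange(1, 130, 2)
    model = fit_linear_svm(X[tr], y_shuffled[tr], C=1.0)
    auc = roc_auc(model.decision(X[te]), y_shuffled[te])
    assert abs(auc - 0.5) < 0.15


def test_svm_duplicated_features_keep_ranking():
    X, y = _separable(n=80, gap=1.0, features=2, seed=4)
    m1 = fit_linear_svm(X, y, C=1.0)
    m2 = fit_linear_svm(np.hstack([X, X]), y, C=1.0)
    s1 = m1.decision(X)
    s2 = m2.decision(np.hstack([X, X]))
    assert np.corrcoef(s1, s2)[0, 1] > 0.99


def test_svm_constant_feature_guard():
    X, y = _separable(n=40)
    X = np.hstack([X, np.full((40, 1), 7.0)])
    with pytest.warns(UserWarning, match="constant feature"):
        model = fit_linear_svm(X, y, C=1.0)
    assert model.scale[1] == 1.0


def test_tune_cost_tie_break_and_determinism():
    X, y = _separable(n=60, gap=5.0, seed=6)
    cfg = SVMConfig.from_seed(9)
    # perfectly separable: every cost reaches the same CV accuracy
    assert tune_cost(X, y, cfg, seed=11) == 0.1
    one = SVMConfig.from_seed(9, cost_grid=(10.0,))
    assert tune_cost(X, y, one, seed=11) == 10.0
    assert tune_cost(X, y, cfg, seed=11) == tune_cost(X, y, cfg, seed=11)


@pytest.fixture(scope="module")
def tiny_screen():
    rng = np.random.default_rng(12)
    n = 60
    idx = pd.Index([f"S{i}" for i in range(n)])
    y = pd.Series([0] * (n // 2) + [1] * (n // 2), index=idx)
    s = np.exp(rng.normal(0, 0.5, n))
    tau = s * np.exp(0.9 * y.to_numpy() + rng.normal(0, 0.2, n))
    amy = s * np.exp(rng.normal(0, 0.2, n))
    matrix = pd.DataFrame({"TAU": tau, "AMY": amy, "TAU2": tau.copy()},
                          index=idx)
    cfg = SVMConfig.from_seed(21)
    pair = PairSpec("TAU", "AMY", "cross")
    res = run_pair_screen(pair, matrix, y, cfg)
    return matrix, y, cfg, res


def test_screen_structural_invariants(tiny_screen):
    _, _, cfg, res = tiny_screen
    assert len(res.auc_per_repeat) == 101
    assert res.median_auc in res.auc_per_repeat
    assert res.median_auc == np.sort(res.auc_per_repeat)[50]
    assert res.auc_per_repeat[res.median_index] == res.median_auc
    first = int(np.flatnonzero(res.auc_per_repeat == res.median_auc)[0])
    assert res.median_index == first
    assert res.ci_low <= res.ci_high


def test_screen_is_deterministic(tiny_screen):
    matrix, y, cfg, res = tiny_screen
    res2 = run_pair_screen(PairSpec("TAU", "AMY", "cross"), matrix, y, cfg)
    np.testing.assert_array_equal(res.auc_per_repeat, res2.auc_per_repeat)
    assert (res.ci_low, res.ci_high) == (res2.ci_low, res2.ci_high)


def test_identical_columns_pair_warns_and_matches_single(tiny_screen):
    matrix, y, cfg, _ = tiny_screen
    with pytest.warns(UserWarning, match="identical feature columns"):
        dup = run_pair_screen(PairSpec("TAU", "TAU2", "within_tau"),
                              matrix, y, cfg)
    single = run_pair_screen(PairSpec("TAU", None, "single_tau"),
                             matrix, y, cfg)
    assert abs(dup.median_auc - single.median_auc) < 0.1


def test_transfer_consistency_on_own_test_fold(tiny_screen):
    matrix, y, cfg, res = tiny_screen
    splits = make_splits(y, cfg)
    _, te = splits[res.median_index]
    val_matrix = matrix.iloc[te]
    val_labels = y.iloc[te]
    auc, ci = transfer_model(res, val_matrix, val_labels, cfg,
                             recompute_stats=False)
    assert auc == pytest.approx(res.auc_per_repeat[res.median_index])
    assert ci[0] <= auc <= ci[1]


def test_transfer_shuffled_labels_near_chance(tiny_screen):
    matrix, y, cfg, res = tiny_screen
    rng = np.random.default_rng(33)
    shuffled = pd.Series(rng.permutation(y.to_numpy()), index=y.index)
    auc, _ = transfer_model(res, matrix, shuffled, cfg)
    assert abs(auc - 0.5) < 0.2


def test_transfer_missing_protein_raises(tiny_screen):
    matrix, y, cfg, res = tiny_screen
    with pytest.raises(ValueError, match="AMY"):
        transfer_model(res, matrix[["TAU"]], y, cfg)


def test_covariate_variant_contracts(tiny_screen):
    matrix, y, cfg, res = tiny_screen
    pair = PairSpec("TAU", "AMY", "cross")
    qalb_const = pd.Series(5.7, index=y.index)
    with pytest.warns(UserWarning, match="constant feature"):
        with_const = covariate_variant(pair, matrix, qalb_const, y, cfg)
    assert abs(with_const.median_auc - res.median_auc) < 0.1
    qalb_leak = pd.Series(np.where(y == 1, 50.0, 2.0), index=y.index)
    leak = covariate_variant(pair, matrix, qalb_leak, y, cfg)
    assert leak.median_auc > 0.95
    too_missing = qalb_const.copy()
    too_missing.iloc[: len(y) // 2] = np.nan
    with pytest.raises(ValueError, match="90%"):
        covariate_variant(pair, matrix, too_missing, y, cfg)


def test_compare_categories_identical_sets():
    res_a = []
    results = {}

    class Dummy:
        def __init__(self, cat, auc):
            self.pair = PairSpec("X", "Y", cat)
            self.median_auc = auc

    for i, auc in enumerate([0.7, 0.8, 0.9]):
        results[f"a{i}"] = Dummy("cross", auc)
        results[f"b{i}"] = Dummy("within_tau", auc)
    table = compare_categories(results)
    assert (table["p"] == 1.0).all()


def test_screen_pairs_shares_undersampling(tiny_screen):
    matrix, y, cfg, _ = tiny_screen
    labels = pd.Series(np.where(y == 1, "A+T+", "A-T-"), index=y.index)
    results = screen_pairs([PairSpec("TAU", "AMY", "cross"),
                            PairSpec("TAU", None, "single_tau")],
                           matrix, labels, cfg)
    assert set(results) == {"TAU+AMY", "TAU"}
    assert results["TAU+AMY"].median_auc >= results["TAU"].median_auc - 0.05
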