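"""Normalization and QC behaviour: drift removal, median preservation,
MA normalization fixed points, CV arithmetic and the QC filter."""
import warnings

import numpy as np
import pandas as pd
import pytest
from scipy.stats import spearmanr

from csfpairs import preprocess
from csfpairs.preprocess import QCThresholds, adjust_position_drift, \
    apply_qc_filter, build_qc_report, compute_inter_assay_correlation, \
    compute_intra_assay_cv, ma_normalize
from csfpairs.pipeline import preprocess_cohort
from csfpairs.synthgen import CohortConfig, generate_cohort, \
    inject_technical_effects


def _drifted_matrix(n=200, slope=0.002, seed=0):
    rng = np.random.default_rng(seed)
    pos = pd.Series(np.arange(1, n + 1),
                    index=[f"S{i}" for i in range(n)])
    base = 500.0 * np.exp(rng.normal(0, 0.3, n))
    vals = base * np.exp(slope * pos.to_numpy())
    mat = pd.DataFrame({"P1": vals, "P2": np.full(n, 100.0)},
                       index=pos.index)
    return mat, pos


def test_constant_column_is_unchanged():
    mat, pos = _drifted_matrix()
    adj, params = adjust_position_drift(mat, pos)
    np.testing.assert_allclose(adj["P2"], 100.0)


def test_drift_removed_and_ols_oracle_agrees():
    mat, pos = _drifted_matrix()
    adj, params = adjust_position_drift(mat, pos)
    rho = spearmanr(adj["P1"], pos).statistic
    assert abs(rho) < 0.05
    # independent OLS oracle: the least-squares slope of the adjusted
    # values on position is essentially zero
    x = pos.to_numpy(dtype=float)
    y = adj["P1"].to_numpy()
    slope = np.polyfit(x, y, 1)[0]
    raw_slope = np.polyfit(x, mat["P1"].to_numpy(), 1)[0]
    assert abs(slope) < 0.05 * abs(raw_slope)


def test_adjustment_preserves_protein_medians_exactly():
    mat, pos = _drifted_matrix()
    plates = pd.Series(np.where(np.arange(len(mat)) < 100, "A", "B"),
                       index=mat.index)
    adj, _ = adjust_position_drift(mat, pos, plates)
    for col in mat.columns:
        assert np.median(adj[col]) == np.median(mat[col])


def test_position_permutation_equivariance():
    mat, pos = _drifted_matrix(n=60)
    adj, _ = adjust_position_drift(mat, pos)
    perm = np.random.default_rng(1).permutation(len(mat))
    adj_p, _ = adjust_position_drift(mat.iloc[perm], pos.iloc[perm])
    pd.testing.assert_frame_equal(adj_p.sort_index(), adj.sort_index())


def test_small_plate_skipped_with_warning():
    mat, pos = _drifted_matrix(n=12)
    plates = pd.Series(["A"] * 10 + ["B"] * 2, index=mat.index)
    with pytest.warns(UserWarning, match="skipped"):
        adj, _ = adjust_position_drift(mat, pos, plates)


def test_ma_normalize_constant_multiple_recovers_reference():
    rng = np.random.default_rng(2)
    ref_profile = np.exp(rng.normal(6, 1, 20))
    rows = {f"S{i}": ref_profile for i in range(9)}
    rows["S9"] = 4.0 * ref_profile
    mat = pd.DataFrame.from_dict(rows, orient="index",
                                 columns=[f"P{j}" for j in range(20)])
    adj, params = ma_normalize(mat)
    np.testing.assert_allclose(adj.loc["S9"], ref_profile, rtol=1e-9)
    assert params.loc["S9", "ma_intercept"] == pytest.approx(2.0, abs=1e-9)


def test_ma_normalize_identity_and_idempotence():
    rng = np.random.default_rng(3)
    profile = np.exp(rng.normal(6, 1, 15))
    mat = pd.DataFrame(np.tile(profile, (8, 1)),
                       index=[f"S{i}" for i in range(8)],
                       columns=[f"P{j}" for j in range(15)])
    adj, _ = ma_normalize(mat)
    np.testing.assert_allclose(adj.to_numpy(), mat.to_numpy(), rtol=1e-12)
    # idempotence on realistic data with a fixed reference
    noisy = mat * np.exp(rng.normal(0, 0.3, mat.shape))
    ref = noisy.median(axis=0)
    once, _ = ma_normalize(noisy, reference=ref)
    twice, _ = ma_normalize(once, reference=ref)
    np.testing.assert_allclose(twice.to_numpy(), once.to_numpy(), atol=1e-6)


def test_ma_normalize_removes_plate_offsets():
    cfg = CohortConfig(n_neg=60, n_pos=40, n_peripheral=4, n_amyloid=4,
                       n_tau=3, plates=2, positions_per_plate=56, seed=13)
    c = generate_cohort(cfg)
    offsets = {"PLATE_1": 0.3, "PLATE_2": -0.3}
    inj = inject_technical_effects(c, drift_slopes=pd.Series(
        0.0, index=c.proteins.columns), plate_offsets=offsets)
    adj, _ = ma_normalize(inj.proteins)
    l2 = np.log2(adj)
    med = l2.groupby(inj.samples["plate_id"]).median()
    diff = (med.loc["PLATE_1"] - med.loc["PLATE_2"]).median()
    raw_diff = (np.log2(inj.proteins).groupby(inj.samples["plate_id"])
                .median().diff().iloc[-1].median())
    assert abs(raw_diff) > 0.5   # offsets really were injected
    assert abs(diff) < 0.05


def test_intra_assay_cv_arithmetic():
    mat = pd.DataFrame({"P1": [100.0, 100.0, 100.0],
                        "P2": [90.0, 100.0, 110.0]},
                       index=["a", "b", "c"])
    plates = pd.Series("PLATE_1", index=mat.index)
    cv = compute_intra_assay_cv(mat, plates)
    assert cv.loc["P1", "cv_median"] == 0.0
    assert cv.loc["P2", "cv_median"] == pytest.approx(10.0)
    # median across two plates: 2% and 6% -> 4%
    mat2 = pd.concat([mat, mat.assign(P1=[100, 102, 98],
                                      P2=[100, 106, 94.0])])
    mat2.index = list("abcdef")
    plates2 = pd.Series(["PLATE_1"] * 3 + ["PLATE_2"] * 3, index=mat2.index)
    cv2 = compute_intra_assay_cv(mat2, plates2)
    assert (cv2["cv_median"] == cv2[["cv_PLATE_1", "cv_PLATE_2"]]
            .median(axis=1)).all()


def test_single_replicate_plate_excluded():
    mat = pd.DataFrame({"P1": [100.0, 110.0, 90.0, 105.0]},
                       index=list("abcd"))
    plates = pd.Series(["A", "A", "A", "B"], index=mat.index)
    with pytest.warns(UserWarning, match="single pool replicate"):
        cv = compute_intra_assay_cv(mat, plates)
    assert "cv_B" not in cv.columns


def test_inter_assay_correlation_monotone_and_reversed():
    rng = np.random.default_rng(4)
    run1 = pd.DataFrame(rng.uniform(10, 100, size=(12, 3)),
                        index=[f"S{i}" for i in range(12)],
                        columns=list("XYZ"))
    rho = compute_inter_assay_correlation(run1, 2.0 * run1)
    np.testing.assert_allclose(rho, 1.0)
    reversed_ranks = run1.rank().apply(lambda c: c.max() + 1 - c)
    rho_rev = compute_inter_assay_correlation(run1, reversed_ranks)
    np.testing.assert_allclose(rho_rev, -1.0)
    with pytest.warns(UserWarning, match="shared samples"):
        rho_few = compute_inter_assay_correlation(run1.iloc[:3],
                                                  run1.iloc[:3])
    assert rho_few.isna().all()


def test_noisy_duplicate_flagged_below_cutoff():
    rng = np.random.default_rng(5)
    run1 = pd.DataFrame(np.exp(rng.normal(5, 0.1, size=(40, 2))),
                        index=[f"S{i}" for i in range(40)],
                        columns=["good", "bad"])
    run2 = run1.copy()
    run2["good"] *= np.exp(rng.normal(0, 0.02, 40))
    run2["bad"] *= np.exp(rng.normal(0, 2.0, 40))
    rho = compute_inter_assay_correlation(run1, run2)
    report = build_qc_report(
        pd.DataFrame({"cv_median": [1.0, 1.0]}, index=["good", "bad"]), rho)
    assert bool(report.loc["good", "pass_rho"])
    assert not bool(report.loc["bad", "pass_rho"])


def test_qc_filter_drops_failing_proteins(small_prep, small_cohort):
    mat = small_prep["matrix"]
    qc = small_prep["qc"]
    assert small_prep["dropped"] == []
    qc2 = qc.copy()
    qc2.loc[mat.columns[0], "pass_rho"] = False
    filtered, dropped = apply_qc_filter(mat, qc2)
    assert dropped == [mat.columns[0]]
    assert filtered.shape[1] == mat.shape[1] - 1
    qc3 = qc.copy()
    qc3["pass_cv"] = False
    with pytest.raises(ValueError, match="every protein"):
        apply_qc_filter(mat, qc3)


def test_engineered_qc_failures_are_removed():
    """73 assayed proteins with 24 engineered failures leave 49 analysable."""
    cfg = CohortConfig(n_neg=40, n_pos=30, n_qc_fail=24, plates=2,
                       positions_per_plate=40, seed=17)
    assert cfg.n_proteins == 73
    c = inject_technical_effects(generate_cohort(cfg), duplicate_run=True)
    prep = preprocess_cohort(c, QCThresholds())
    assert prep["matrix"].shape[1] == 49
    assert sorted(prep["dropped"]) == sorted(
        c.gt_proteins.index[c.gt_proteins.qc_fail])


def test_outputs_strictly_positive(small_prep):
    assert (small_prep["matrix"].to_numpy() > 0).all()
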