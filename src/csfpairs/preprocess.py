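"""Technical adjustment and QC of the protein intensity matrix.

Two fixed adjustment steps, in this order:

1. readout-drift adjustment — per protein and per plate, a robust linear
   model (Huber M-estimation) of raw intensity on within-plate readout
   position; the residuals plus the protein's median intensity replace the
   raw values, so a delayed-readout trend is removed while each protein's
   median is preserved exactly;
2. MA-individual normalization — per sample, a robust line of M (log2
   sample/reference) on A (mean log2 of sample and reference) against the
   global median profile is subtracted, removing sample- and plate-level
   multiplicative offsets and intensity-dependent bias.

QC afterwards: intra-assay CV% from pool replicates, inter-assay Spearman
correlation between duplicate runs (pass at rho >= 0.7), and an optional
background-ratio check; proteins failing any check are dropped.
"""
from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

log = logging.getLogger(__name__)

HUBER_T = 1.345
RLM_MAXITER = 50
RLM_TOL = 1e-8


def robust_line(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Huber M-estimated line ``y = a + b x`` (IRLS, tuning constant 1.345).

    Degenerate inputs (fewer than 3 points, constant x or y, an exact
    linear fit) fall back to the least-squares / trivial solution.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(y) < 3 or np.ptp(y) == 0.0 or np.ptp(x) == 0.0:
        slope = 0.0
        if np.ptp(x) > 0.0 and np.ptp(y) > 0.0 and len(y) == 2:
            slope = (y[1] - y[0]) / (x[1] - x[0])
        return float(np.median(y) - slope * np.median(x)), float(slope)
    X = sm.add_constant(x)
    ols = sm.OLS(y, X).fit()
    resid = y - X @ ols.params
    scale = np.median(np.abs(resid - np.median(resid)))
    if scale <= 1e-12 * max(1.0, float(np.abs(y).max())):
        return float(ols.params[0]), float(ols.params[1])  # (near-)exact line
    rlm = sm.RLM(y, X, M=sm.robust.norms.HuberT(HUBER_T))
    res = rlm.fit(maxiter=RLM_MAXITER, tol=RLM_TOL)
    if not np.all(np.isfinite(res.params)):  # pragma: no cover
        return float(ols.params[0]), float(ols.params[1])
    return float(res.params[0]), float(res.params[1])


def adjust_position_drift(matrix: pd.DataFrame, positions: pd.Series,
                          plates: pd.Series | None = None
                          ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Remove within-plate readout-order drift from every protein.

    Per protein and plate, intensity is regressed on position with a Huber
    line; the adjusted value is the residual plus the protein's (global)
    median raw intensity, re-centred so the median is preserved exactly.
    Plates with fewer than 3 samples are left unadjusted (warning).
    """
    if (matrix.to_numpy() <= 0).any():
        raise ValueError("intensities must be strictly positive")
    positions = positions.reindex(matrix.index)
    if positions.isna().any():
        raise ValueError("every sample needs a readout position")
    if (positions < 0).any():
        raise ValueError("positions must be non-negative")
    if plates is None:
        plates = pd.Series("all", index=matrix.index)
    else:
        plates = plates.reindex(matrix.index)

    adjusted = matrix.copy()
    records = []
    for plate, idx in matrix.groupby(plates, observed=True).groups.items():
        pos = positions.loc[idx].to_numpy(dtype=float)
        if len(idx) < 3:
            warnings.warn(f"plate {plate!r} has {len(idx)} samples; "
                          "drift adjustment skipped", stacklevel=2)
            for prot in matrix.columns:
                records.append((prot, plate, np.nan, np.nan))
            continue
        sub = matrix.loc[idx]
        for prot in matrix.columns:
            a, bslope = robust_line(pos, sub[prot].to_numpy())
            resid = sub[prot].to_numpy() - (a + bslope * pos)
            adjusted.loc[idx, prot] = resid  # median added below
            records.append((prot, plate, a, bslope))

    params = pd.DataFrame(records,
                          columns=["protein", "plate", "drift_intercept",
                                   "drift_slope"])
    medians = matrix.median(axis=0)
    params = params.merge(medians.rename("protein_median"),
                          left_on="protein", right_index=True)
    small = plates.value_counts() < 3
    small_plates = set(small.index[small])
    adj = adjusted.to_numpy(dtype=float)
    is_small = plates.isin(small_plates).to_numpy()
    med = medians.to_numpy()
    adj[~is_small] += med[None, :]
    # exact median preservation (Huber residuals need not have zero median)
    adj += med - np.median(adj, axis=0)
    # an adjusted value can dip below zero when the fitted line exceeds a
    # low-intensity sample by more than the median; clamp to half the
    # protein's smallest positive value so order statistics stay sane
    for j in range(adj.shape[1]):
        bad = adj[:, j] <= 0
        if bad.any():
            positive = adj[~bad, j]
            floor = 0.5 * positive.min() if positive.size else 1e-9 * med[j]
            adj[bad, j] = floor
    return pd.DataFrame(adj, index=matrix.index, columns=matrix.columns), params


def ma_normalize(matrix: pd.DataFrame, reference: pd.Series | None = None,
                 epsilon: float = 1e-9, scope: str = "sample",
                 plates: pd.Series | None = None
                 ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """MA normalization against a median reference profile.

    The reference is the per-protein median of log2 intensities over all
    samples. With ``scope="sample"`` (MA-individual normalization), a
    robust line ``M = a + b A`` is fitted per sample, with ``M =
    log2(sample) - reference`` and ``A = (log2(sample) + reference)/2``,
    and its fit subtracted from that sample's log2 values; this removes
    every per-sample multiplicative offset, including genuine
    inter-individual concentration differences.

    With ``scope="plate"`` the robust line is fitted on each plate's
    median log2 profile instead and the plate's fit is subtracted from all
    samples of that plate: plate-level offsets and intensity-dependent
    plate bias are removed while inter-individual variation is preserved.
    """
    vals = matrix.to_numpy(dtype=float)
    n_floored = int((vals <= 0).sum())
    if n_floored:
        log.warning("%d non-positive values floored at %g before log",
                    n_floored, epsilon)
        vals = np.maximum(vals, epsilon)
    l2 = np.log2(vals)
    if reference is None:
        ref = np.median(l2, axis=0)
    else:
        ref = np.log2(np.maximum(reference.reindex(matrix.columns).to_numpy(),
                                 epsilon))
    out = np.empty_like(l2)
    params = []
    if scope == "sample":
        for i in range(l2.shape[0]):
            m = l2[i] - ref
            a_val = 0.5 * (l2[i] + ref)
            a, b = robust_line(a_val, m)
            out[i] = l2[i] - (a + b * a_val)
            params.append((matrix.index[i], a, b))
        params = pd.DataFrame(params, columns=["unit", "ma_intercept",
                                               "ma_slope"]).set_index("unit")
    elif scope == "plate":
        if plates is None:
            raise ValueError("scope='plate' requires plate ids")
        plates = plates.reindex(matrix.index)
        for plate, idx in matrix.groupby(plates, observed=True).groups.items():
            rows = matrix.index.get_indexer(idx)
            profile = np.median(l2[rows], axis=0)
            m = profile - ref
            a_val = 0.5 * (profile + ref)
            a, b = robust_line(a_val, m)
            arow = 0.5 * (l2[rows] + ref)
            out[rows] = l2[rows] - (a + b * arow)
            params.append((plate, a, b))
        params = pd.DataFrame(params, columns=["unit", "ma_intercept",
                                               "ma_slope"]).set_index("unit")
    else:
        raise ValueError(f"unknown scope {scope!r}")
    adjusted = pd.DataFrame(np.exp2(out), index=matrix.index,
                            columns=matrix.columns)
    return adjusted, params


def compute_intra_assay_cv(pool_matrix: pd.DataFrame,
                           plate_ids: pd.Series) -> pd.DataFrame:
    """Per-protein intra-assay CV% from pool replicates.

    CV% = 100 * sd / mean (sample SD, n-1) over each plate's pool
    replicates; plates with a single replicate are excluded. The summary
    column ``cv_median`` is the median over plates.
    """
    plate_ids = plate_ids.reindex(pool_matrix.index)
    per_plate = {}
    for plate, sub in pool_matrix.groupby(plate_ids, observed=True):
        if len(sub) < 2:
            warnings.warn(f"plate {plate!r} has a single pool replicate; "
                          "CV undefined", stacklevel=2)
            continue
        per_plate[f"cv_{plate}"] = 100.0 * sub.std(ddof=1) / sub.mean()
    if not per_plate:
        raise ValueError("no plate has >= 2 pool replicates")
    out = pd.DataFrame(per_plate)
    out["cv_median"] = out.median(axis=1)
    return out


def compute_inter_assay_correlation(run1: pd.DataFrame,
                                    run2: pd.DataFrame,
                                    min_shared: int = 5) -> pd.Series:
    """Per-protein Spearman rho between two assay runs on shared samples."""
    shared = run1.index.intersection(run2.index)
    prots = run1.columns.intersection(run2.columns)
    rho = pd.Series(np.nan, index=run1.columns, name="inter_assay_rho")
    if len(shared) < min_shared:
        warnings.warn(f"only {len(shared)} shared samples; "
                      "inter-assay rho reported as missing", stacklevel=2)
        return rho
    a = run1.loc[shared, prots]
    b = run2.loc[shared, prots]
    for prot in prots:
        rho[prot] = stats.spearmanr(a[prot], b[prot]).statistic
    return rho


@dataclass(frozen=True)
class QCThresholds:
    cv_max: float = 20.0            # % — generous; assays are typically <11%
    rho_min: float = 0.7            # inter-assay Spearman rho
    background_min: float = 3.0     # median signal / blank signal


def build_qc_report(cv: pd.DataFrame, rho: pd.Series,
                    background_ratio: pd.Series | None = None,
                    thresholds: QCThresholds = QCThresholds()) -> pd.DataFrame:
    """Combine QC metrics into a per-protein pass/fail report."""
    report = pd.DataFrame({"cv_median": cv["cv_median"],
                           "inter_assay_rho": rho})
    report["pass_cv"] = report["cv_median"] <= thresholds.cv_max
    report["pass_rho"] = report["inter_assay_rho"] >= thresholds.rho_min
    if background_ratio is not None:
        report["background_ratio"] = background_ratio
        report["pass_background"] = (report["background_ratio"]
                                     >= thresholds.background_min)
    else:
        report["background_ratio"] = np.nan
        report["pass_background"] = True  # no blank column supplied
    return report


def apply_qc_filter(matrix: pd.DataFrame,
                    qc: pd.DataFrame) -> tuple[pd.DataFrame, list[str]]:
    """Drop proteins failing any QC flag; returns (matrix, dropped ids)."""
    missing = matrix.columns.difference(qc.index)
    if len(missing):
        raise ValueError(f"QC report does not cover: {list(missing)}")
    flags = qc.loc[matrix.columns, ["pass_cv", "pass_rho", "pass_background"]]
    keep = flags.all(axis=1)
    dropped = list(matrix.columns[~keep])
    if not keep.any():
        raise ValueError("QC filter would drop every protein")
    if dropped:
        log.info("QC filter dropped %d proteins: %s", len(dropped), dropped)
    return matrix.loc[:, keep], dropped
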