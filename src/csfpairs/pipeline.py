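"""End-to-end orchestration: simulate -> preprocess -> stratify -> cluster
-> univariate stats -> pair screen -> validation transfer -> ratios.

One global seed deterministically derives every stage seed, so a single
integer reproduces a full run bit-identically. All thresholds (AT cutoffs,
QC rho 0.7, network |rho| 0.5, q 0.05) default to their standard values
but are plain config entries.
"""
from __future__ import annotations

import dataclasses
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import clusterlab, diffstats, pairscreen, preprocess, ratiocog, stratify
from .synthgen import Cohort, CohortConfig, generate_cohort, \
    inject_technical_effects, validation_config, write_dataset

log = logging.getLogger(__name__)

STAGES = ("simulate", "preprocess", "stratify", "cluster", "diffstats",
          "pairscreen", "transfer", "ratios")


def derive_seeds(seed: int) -> dict:
    """Deterministic per-stage seeds from one global seed (all < 2^31)."""
    names = ("synth_discovery", "synth_validation", "screen", "subset",
             "ratio_orientation")
    state = np.random.SeedSequence([int(seed), 7]).generate_state(len(names))
    return {name: int(s % (2**31 - 1)) for name, s in zip(names, state)}


DEFAULT_CONFIG = {
    "seed": 1,
    "synth": {"discovery": {}, "validation": {}},
    "qc": {"cv_max": 20.0, "rho_min": 0.7, "background_min": 3.0},
    "cluster": {"k": 3, "network_threshold": 0.5},
    "screen": {"n_cross": 20, "n_within_tau": 10, "n_within_amyloid": 10,
               "n_singles": 4, "n_repeats": 101},
    "scd_only": True,
    "stages": list(STAGES),
}


def _merge(base: dict, override: dict | None) -> dict:
    out = {k: (dict(v) if isinstance(v, dict) else v) for k, v in base.items()}
    for k, v in (override or {}).items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k].update(v)
        else:
            out[k] = v
    return out


def preprocess_cohort(cohort: Cohort, thresholds: preprocess.QCThresholds
                      ) -> dict:
    """Drift adjustment, MA normalization and QC filtering for one cohort.

    Returns the adjusted real-sample matrix plus the QC report and the
    normalization parameter records.
    """
    samples = cohort.samples
    # drift is fitted across the whole run: per-plate fits on ~45 samples
    # of widely dispersed linear intensities carry enough slope noise to
    # push low-intensity samples' adjusted values non-positive
    drifted, drift_params = preprocess.adjust_position_drift(
        cohort.proteins, samples["position_index"])
    normalized, ma_params = preprocess.ma_normalize(
        drifted, scope="plate", plates=samples["plate_id"])
    pool_mask = samples["pool_flag"].to_numpy()
    # CV on raw pool intensities: intra-assay reproducibility is a property
    # of the measurement, and the position-drift fit would otherwise leak
    # estimation noise into the replicates
    cv = preprocess.compute_intra_assay_cv(
        cohort.proteins.loc[pool_mask], samples.loc[pool_mask, "plate_id"])
    if cohort.proteins_run2 is not None:
        # the duplicate run goes through the same adjustment before QC
        drifted2, _ = preprocess.adjust_position_drift(
            cohort.proteins_run2, samples["position_index"])
        normalized2, _ = preprocess.ma_normalize(
            drifted2, scope="plate", plates=samples["plate_id"])
        rho = preprocess.compute_inter_assay_correlation(
            normalized, normalized2)
    else:
        rho = pd.Series(1.0, index=normalized.columns, name="inter_assay_rho")
    qc = preprocess.build_qc_report(cv, rho, thresholds=thresholds)
    filtered, dropped = preprocess.apply_qc_filter(normalized, qc)
    return {"matrix": filtered.loc[~pool_mask], "qc": qc, "cv": cv,
            "rho": rho, "dropped": dropped,
            "drift_params": drift_params, "ma_params": ma_params}


def _select_pairs(labels: pd.Series, screen_cfg: dict, seed: int,
                  volcano: pd.DataFrame) -> tuple[list, list]:
    """Seeded subset of the exhaustive pair list plus single baselines.

    The single-protein baselines are the tau-cluster proteins with the
    strongest univariate evidence, mirroring the usual choice of the
    best-established synaptic markers.
    """
    all_pairs = pairscreen.enumerate_pairs(labels, scope="pairs")
    rng = np.random.default_rng(seed)
    chosen = []
    for cat, n in (("cross", screen_cfg["n_cross"]),
                   ("within_tau", screen_cfg["n_within_tau"]),
                   ("within_amyloid", screen_cfg["n_within_amyloid"])):
        cands = [p for p in all_pairs if p.category == cat]
        if n is None or n >= len(cands):
            chosen += cands
        else:
            idx = rng.choice(len(cands), size=n, replace=False)
            chosen += [cands[i] for i in sorted(idx)]
    tau_prots = labels.index[labels == "tau_associated"]
    ranked = volcano.loc[volcano.index.intersection(tau_prots)]
    ranked = ranked.sort_values(["q", "effect_log2_median_ratio"],
                                ascending=[True, False], kind="stable")
    singles = [pairscreen.PairSpec(p, None, "single_tau")
               for p in ranked.index[:screen_cfg["n_singles"]]]
    return chosen, singles


def run_pipeline(config: dict | None = None, outdir=None) -> dict:
    """Execute the full analysis on synthetic cohorts; returns a dict with
    every stage product and (when outdir is given) writes TSV/JSON outputs
    plus a machine-readable run report."""
    cfg = _merge(DEFAULT_CONFIG, config)
    seed = int(cfg["seed"])
    seeds = derive_seeds(seed)
    t0 = time.time()
    out: dict = {"config": cfg, "seeds": seeds}
    manifest: list[str] = []
    outdir = Path(outdir) if outdir is not None else None
    if outdir is not None:
        outdir.mkdir(parents=True, exist_ok=True)

    enabled = list(cfg["stages"])
    unknown = [s for s in enabled if s not in STAGES]
    if unknown:
        raise ValueError(f"unknown stage(s): {unknown}")

    def active(stage: str) -> bool:
        """Stage gate: every stage consumes its predecessors' outputs, so a
        requested stage with a disabled prerequisite refuses to run."""
        if stage not in enabled:
            return False
        missing = [s for s in STAGES[:STAGES.index(stage)] if s not in enabled]
        if missing:
            raise RuntimeError(
                f"stage {stage!r} requires output of disabled stage(s) "
                f"{missing}; enable them or run them first")
        return True

    def emit(df: pd.DataFrame, name: str, index=True):
        if outdir is None:
            return
        path = outdir / name
        df.to_csv(path, sep="\t", index=index)
        manifest.append(name)

    # --- simulate --------------------------------------------------------
    disc = val = None
    if active("simulate"):
        disc_cfg = CohortConfig(**{"seed": seeds["synth_discovery"],
                                   **cfg["synth"]["discovery"]})
        val_cfg = validation_config(
            **{"seed": seeds["synth_validation"], **cfg["synth"]["validation"]})
        disc = inject_technical_effects(generate_cohort(disc_cfg),
                                        duplicate_run=True)
        val = inject_technical_effects(generate_cohort(val_cfg),
                                       duplicate_run=True)
        out["discovery"], out["validation"] = disc, val
        if outdir is not None:
            for cohort, sub in ((disc, "data/discovery"),
                                (val, "data/validation")):
                for p in write_dataset(cohort, outdir / sub):
                    manifest.append(str(p.relative_to(outdir)))

    # --- preprocess -------------------------------------------------------
    prep_d = prep_v = None
    if active("preprocess"):
        thresholds = preprocess.QCThresholds(**cfg["qc"])
        prep_d = preprocess_cohort(disc, thresholds)
        prep_v = preprocess_cohort(val, thresholds)
        out["prep_discovery"], out["prep_validation"] = prep_d, prep_v
        emit(prep_d["qc"], "qc_discovery.tsv")
        emit(prep_v["qc"], "qc_validation.tsv")

    # --- stratify ---------------------------------------------------------
    disc_status = disc_groups = val_groups = None
    if active("stratify"):
        disc_status = stratify.assign_at_status(disc.markers,
                                                stratify.DISCOVERY_RULE)
        val_status = stratify.assign_at_status(val.markers,
                                               stratify.VALIDATION_RULE)
        disc_groups = stratify.select_analysis_groups(
            disc.samples, disc_status, scd_only=cfg["scd_only"])
        val_groups = stratify.select_analysis_groups(
            val.samples, val_status, scd_only=False)
        demo = stratify.summarize_demographics(disc.samples, disc.markers,
                                               disc.cognition, disc_groups)
        out.update(disc_status=disc_status, val_status=val_status,
                   disc_groups=disc_groups, val_groups=val_groups,
                   demographics=demo)
        emit(demo["table"], "demographics.tsv")

    # --- cluster (on the A+T+ group, where the subclusters exist) ----------
    assignment = None
    if active("cluster"):
        matrix = prep_d["matrix"]
        pos_ids = disc_groups.index[disc_groups == "A+T+"]
        neg_ids = disc_groups.index[disc_groups == "A-T-"]
        corr_pos, qalb_pos = clusterlab.marker_correlations(
            matrix, disc.markers, pos_ids)
        corr_neg, _ = clusterlab.marker_correlations(matrix, disc.markers,
                                                     neg_ids)
        assignment = clusterlab.label_clusters(
            clusterlab.ward_cluster(corr_pos, cfg["cluster"]["k"]), corr_pos)
        k2 = clusterlab.ward_cluster(corr_pos, 2)   # peripheral vs CNS cut
        edges = clusterlab.correlation_network(
            matrix, pos_ids, threshold=cfg["cluster"]["network_threshold"])
        out.update(marker_corr_pos=corr_pos, marker_corr_neg=corr_neg,
                   qalb_corr=qalb_pos, assignment=assignment, k2=k2,
                   network_edges=edges)
        emit(corr_pos.join(qalb_pos), "marker_correlations_atpos.tsv")
        emit(pd.DataFrame({"cluster_id": assignment.cluster_id,
                           "block": assignment.semantic}),
             "cluster_assignment.tsv")
        emit(edges, "network_edges.tsv", index=False)
        if outdir is not None:
            clusterlab.export_graphml(edges, outdir / "network.graphml")
            manifest.append("network.graphml")

    # --- univariate ---------------------------------------------------------
    volcano = None
    if active("diffstats"):
        volcano = diffstats.volcano_table(matrix, disc_groups)
        volcano["block"] = assignment.semantic.reindex(volcano.index)
        out["volcano"] = volcano
        emit(volcano, "volcano.tsv")

    # --- pair screen ----------------------------------------------------------
    results = svm_config = None
    if active("pairscreen"):
        screen_cfg = cfg["screen"]
        svm_config = pairscreen.SVMConfig.from_seed(
            seeds["screen"], n_repeats=screen_cfg["n_repeats"])
        pairs, singles = _select_pairs(assignment.semantic, screen_cfg,
                                       seeds["subset"], volcano)
        results = pairscreen.screen_pairs(pairs + singles, matrix,
                                          disc_groups, svm_config)
        category_tests = pairscreen.compare_categories(
            {k: r for k, r in results.items()
             if r.pair.category in ("cross", "within_tau", "within_amyloid")})
        out.update(svm_config=svm_config, screen_results=results,
                   category_tests=category_tests)
        emit(category_tests, "auc_category_tests.tsv", index=False)

    # --- validation transfer ---------------------------------------------------
    if active("transfer"):
        val_matrix = prep_v["matrix"]
        for res in results.values():
            missing = [f for f in res.pair.features
                       if f not in val_matrix.columns]
            if missing:
                log.warning("pair %s not transferable (missing %s)",
                            res.pair.name, missing)
                continue
            pairscreen.transfer_model(res, val_matrix, val_groups, svm_config)
        table = pairscreen.results_table(results)
        out["results_table"] = table
        emit(table, "pair_screen.tsv", index=False)

    # --- ratios & cognition -------------------------------------------------
    if active("ratios"):
        ratio_pairs = [r.pair for r in results.values()
                       if r.pair.protein_b is not None]
        ratios, ratio_cats = ratiocog.compute_ratios(
            matrix, ratio_pairs, seed=seeds["ratio_orientation"],
            markers=disc.markers.loc[matrix.index])
        single_cols = matrix[assignment.semantic.index[
            assignment.semantic != "peripheral"]]
        single_cats = assignment.semantic.map(
            {"tau_associated": "single_tau",
             "amyloid_associated": "single_amyloid"}).dropna()
        entities = pd.concat([ratios, single_cols], axis=1)
        categories = pd.concat([ratio_cats, single_cats])
        corr_table = ratiocog.cognition_correlations(entities, disc.cognition,
                                                     disc_groups.index)
        corr_tests = ratiocog.compare_correlation_categories(corr_table,
                                                             categories)
        diag_tests = ratiocog.diagnosis_stratified_tests(
            entities, disc.samples["diagnosis"], disc_status)
        out.update(ratios=ratios, ratio_categories=categories,
                   cognition_corr=corr_table, corr_category_tests=corr_tests,
                   diagnosis_tests=diag_tests)
        emit(corr_table, "cognition_correlations.tsv", index=False)
        emit(corr_tests, "correlation_category_tests.tsv", index=False)
        emit(diag_tests, "diagnosis_stratified_tests.tsv", index=False)

    # --- report -----------------------------------------------------------
    report = {"seed": seed, "stage_seeds": seeds,
              "stages_run": enabled, "runtime_s": round(time.time() - t0, 2),
              "manifest": manifest}
    if svm_config is not None:
        report["svm_config"] = {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in dataclasses.asdict(svm_config).items()}
    if disc_groups is not None:
        report["n_discovery_selected"] = {
            "A-T-": int((disc_groups == "A-T-").sum()),
            "A+T+": int((disc_groups == "A+T+").sum())}
        report["n_validation_selected"] = {
            "A-T-": int((val_groups == "A-T-").sum()),
            "A+T+": int((val_groups == "A+T+").sum())}
    if prep_d is not None:
        report["dropped_proteins"] = prep_d["dropped"]
    out["report"] = report
    if outdir is not None:
        if results is not None:
            models = {name: r.median_model.to_dict()
                      for name, r in results.items()}
            (outdir / "median_models.json").write_text(
                json.dumps(models, indent=1))
            manifest.append("median_models.json")
        (outdir / "report.json").write_text(json.dumps(report, indent=1))
    return out


def validate_tables(directory) -> list[str]:
    """Schema and cross-reference checks on a written dataset directory;
    returns a list of human-readable violations (empty = valid)."""
    directory = Path(directory)
    violations: list[str] = []
    required = {
        "samples.csv": ["cohort_tag", "diagnosis", "age", "sex", "plate_id",
                        "position_index", "pool_flag"],
        "proteins.csv": None,
        "markers.csv": ["abeta40", "abeta42", "abeta_ratio_x10", "ttau",
                        "ptau", "nfl", "qalb"],
        "cognition.csv": ["mmse", "moca", "kod", "ravlt", "rcf"],
    }
    frames = {}
    for fname, cols in required.items():
        path = directory / fname
        if not path.exists():
            violations.append(f"{fname}: missing file")
            continue
        df = pd.read_csv(path, index_col=0)
        frames[fname] = df
        if cols:
            for col in cols:
                if col not in df.columns:
                    violations.append(f"{fname}: missing column {col!r}")
    samples = frames.get("samples.csv")
    proteins = frames.get("proteins.csv")
    if proteins is not None:
        vals = proteins.select_dtypes(include=[np.number])
        bad = vals <= 0
        if bad.any().any():
            for sid, row in bad.iterrows():
                for prot in row.index[row]:
                    violations.append(
                        f"proteins.csv: non-positive intensity for sample "
                        f"{sid}, protein {prot}")
        if proteins.index.duplicated().any():
            violations.append("proteins.csv: duplicated sample ids")
    if samples is not None:
        if samples.index.duplicated().any():
            violations.append("samples.csv: duplicated sample ids")
        dup = samples.duplicated(subset=["plate_id", "position_index"])
        if dup.any():
            violations.append("samples.csv: duplicate plate/position pairs")
    if samples is not None and proteins is not None:
        orphans = proteins.index.difference(samples.index)
        for sid in orphans:
            violations.append(
                f"proteins.csv: sample {sid} absent from samples.csv")
    for fname in ("markers.csv", "cognition.csv"):
        df = frames.get(fname)
        if df is None or samples is None:
            continue
        orphans = df.index.difference(samples.index)
        for sid in orphans:
            violations.append(f"{fname}: sample {sid} absent from samples.csv")
    return violations
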