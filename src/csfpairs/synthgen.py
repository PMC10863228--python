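"""Synthetic CSF proteomics cohorts with known ground truth.

The generator emulates the statistical structure of multiplex bead-array
CSF proteomics in a two-group memory-clinic setting: a per-individual
global CSF concentration factor that induces strong positive correlations
among all CNS-derived proteins, a tau-associated protein block elevated
with amyloid/tau pathology, an amyloid-associated block whose levels do
not respond to pathology, a peripheral block tracking the albumin
CSF/serum quotient, CSF AD markers calibrated to realistic group medians,
cognitive scores declining with pathology burden, and plate/readout-order
technical effects with pool replicates for QC.

Everything is multiplicative (log-normal): bead-array MFI values are
positive, right-skewed relative intensities.
"""
from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

BLOCKS = ("peripheral", "amyloid_associated", "tau_associated")

#: calibration constants for the CSF marker panel (group medians of the
#: A-T- group; pathology effects move the A+T+ medians onto their targets)
MARKER_BASE = {
    "abeta40": 11340.0,   # pg/ml, median ~1134 on the /10 scale
    "abeta42": 1160.0,    # pg/ml; A+T+ target ~540 via exp(-0.75*b)
    "ptau": 32.0,         # pg/ml; A+T+ target ~82 via exp(0.95*b)
    "ttau_per_ptau": 6.7, # ttau ~ 214 / ~550
    "nfl": 670.0,         # pg/ml; weakly increasing with burden
    "qalb": 5.7,          # albumin CSF/serum quotient (reported scale)
}

PTAU_SLOPE = 0.95
ABETA42_SLOPE = -0.75
NFL_SLOPE = 0.5

COG_SCORES = ("mmse", "moca", "kod", "ravlt", "rcf")
#: (baseline at age 60 and zero burden, age slope per decade, burden slope,
#:  noise sd, lower clip, upper clip)
COG_MODEL = {
    "mmse": (28.5, 1.0, 5.5, 1.5, 0.0, 30.0),
    "moca": (26.5, 1.0, 6.5, 2.0, 0.0, 30.0),
    "kod": (56.0, 5.0, 12.0, 8.0, 0.0, None),
    "ravlt": (50.0, 4.0, 19.0, 6.0, 0.0, None),
    "rcf": (18.0, 2.0, 9.0, 4.0, 0.0, 36.0),
}


@dataclass(frozen=True)
class CohortConfig:
    """Parameters of the synthetic cohort.

    Counts default to the discovery design (106 A-T- SCD + 65 A+T+,
    22 peripheral + 16 amyloid-associated + 11 tau-associated proteins);
    effect sizes are calibrated so group marker medians land near their
    real-cohort targets and stratification by the marker cutoffs
    reproduces the intended groups for the vast majority of samples.
    """

    n_neg: int = 106
    n_pos: int = 65
    n_peripheral: int = 22
    n_amyloid: int = 16
    n_tau: int = 11
    n_qc_fail: int = 0
    sigma_scale: float = 0.6    # SD of log individual concentration factor
    sigma_noise: float = 0.25   # per-measurement log-noise SD (proteins)
    sigma_marker: float = 0.08  # assay noise of the CSF marker panel
    sigma_impair: float = 0.25  # AT-independent impairment latent (half-normal scale)
    sigma_tech: float = 0.04    # pool-replicate / duplicate-run technical noise
    beta_tau: float = 1.0       # pathology -> tau-block log effect size
    beta_cog: float = 1.0       # pathology -> cognition effect multiplier
    plates: int = 4
    positions_per_plate: int = 48
    pool_reps_per_plate: int = 3
    missing_cog_frac: float = 0.3
    nfl_missing_frac: float = 0.04
    qalb_missing_frac: float = 0.07
    drift_slope_sd: float = 0.001
    plate_offset_sd: float = 0.15
    cohort_tag: str = "discovery"
    enforce_at_rule: bool = False   # redraw samples whose markers contradict
                                    # the intended AT group (border-case-free
                                    # cohort, as in pre-selected validation sets)
    neg_diagnosis_mix: tuple | None = None          # (SCD, MCI, AD) fractions; None = all SCD
    pos_diagnosis_mix: tuple = (11 / 65, 19 / 65, 35 / 65)
    seed: int = 1

    def __post_init__(self) -> None:
        counts = {
            "n_neg": self.n_neg, "n_pos": self.n_pos,
            "n_peripheral": self.n_peripheral, "n_amyloid": self.n_amyloid,
            "n_tau": self.n_tau, "plates": self.plates,
            "positions_per_plate": self.positions_per_plate,
        }
        for name, v in counts.items():
            if not (isinstance(v, (int, np.integer)) and v >= 1):
                raise ValueError(f"{name} must be an integer >= 1, got {v!r}")
        if not (isinstance(self.pool_reps_per_plate, (int, np.integer))
                and self.pool_reps_per_plate >= 0):
            raise ValueError("pool_reps_per_plate must be an integer >= 0")
        if self.n_qc_fail < 0:
            raise ValueError("n_qc_fail must be >= 0")
        sigmas = (self.sigma_scale, self.sigma_noise, self.sigma_marker,
                  self.sigma_impair, self.sigma_tech, self.drift_slope_sd,
                  self.plate_offset_sd)
        if any((not math.isfinite(s)) or s < 0 for s in sigmas):
            raise ValueError("all sigma parameters must be finite and >= 0")
        for f in (self.beta_tau, self.beta_cog):
            if not math.isfinite(f):
                raise ValueError("effect sizes must be finite")
        for frac in (self.missing_cog_frac, self.nfl_missing_frac,
                     self.qalb_missing_frac):
            if not (0.0 <= frac < 1.0):
                raise ValueError("missing fractions must lie in [0, 1)")

    @property
    def n_samples(self) -> int:
        return self.n_neg + self.n_pos

    @property
    def n_proteins(self) -> int:
        return self.n_peripheral + self.n_amyloid + self.n_tau + self.n_qc_fail


def validation_config(seed: int = 1, **overrides) -> CohortConfig:
    """Default configuration of the independent 26 + 26 validation cohort."""
    base = dict(n_neg=26, n_pos=26, plates=1, positions_per_plate=56,
                cohort_tag="validation", enforce_at_rule=True, seed=seed)
    base.update(overrides)   # overrides win, including the seed
    return CohortConfig(**base)


@dataclass
class Cohort:
    """One generated cohort: metadata, markers, proteins, cognition, truth."""

    samples: pd.DataFrame
    markers: pd.DataFrame
    proteins: pd.DataFrame
    cognition: pd.DataFrame
    gt_samples: pd.DataFrame
    gt_proteins: pd.DataFrame
    gt_plates: pd.DataFrame | None = None
    proteins_run2: pd.DataFrame | None = None
    config: CohortConfig | None = None

    @property
    def real_ids(self) -> pd.Index:
        return self.samples.index[~self.samples["pool_flag"]]


def _protein_ids(config: CohortConfig) -> tuple[list[str], list[str]]:
    ids, blocks = [], []
    for prefix, n, block in (("PER", config.n_peripheral, "peripheral"),
                             ("AMY", config.n_amyloid, "amyloid_associated"),
                             ("TAU", config.n_tau, "tau_associated"),
                             ("QCF", config.n_qc_fail, "peripheral")):
        ids += [f"{prefix}_{i + 1:02d}" for i in range(n)]
        blocks += [block] * n
    return ids, blocks


def generate_cohort(config: CohortConfig) -> Cohort:
    """Draw one cohort from the generative model.

    Per sample: a concentration factor ``s = exp(N(0, sigma_scale^2))``, a
    pathology burden ``b`` (0 for intended A-T-, |N(1, 0.25^2)| for intended
    A+T+), an AT-independent impairment latent ``d = |N(0, sigma_impair^2)|``
    and an albumin quotient ``q``. Markers are log-normal around calibrated
    medians; tau-block proteins scale with ``exp(beta_p * (b + d))`` on top
    of ``s``, amyloid-block proteins with ``s`` alone, peripheral proteins
    with ``q``. Cognition declines linearly in ``beta_cog * (b + d)`` and
    age, clipped to the score range. Identical config => identical output.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0]))
    n, n_neg, n_pos = config.n_samples, config.n_neg, config.n_pos
    tag = config.cohort_tag
    prefix = tag[:3].upper()
    ids = pd.Index([f"{prefix}_{i + 1:04d}" for i in range(n)], name="sample_id")
    intended = np.array(["A-T-"] * n_neg + ["A+T+"] * n_pos)

    def draw(m: int) -> dict:
        """Latent factors and markers for m samples (group set by caller)."""
        out = {
            "s": np.exp(rng.normal(0.0, config.sigma_scale, m)),
            "b_raw": np.abs(rng.normal(1.0, 0.25, m)),
            "d": np.abs(rng.normal(0.0, config.sigma_impair, m)),
            "q": np.exp(rng.normal(np.log(MARKER_BASE["qalb"]), 0.3, m)),
            "eps40": rng.normal(0.0, config.sigma_marker, m),
            "eps42": rng.normal(0.0, config.sigma_marker, m),
            "epsp": rng.normal(0.0, config.sigma_marker, m),
            "epst": rng.normal(0.0, config.sigma_marker, m),
            "epsn": rng.normal(0.0, 0.4, m),
        }
        return out

    lat = draw(n)
    pos_mask = intended == "A+T+"
    lat["b"] = np.where(pos_mask, lat.pop("b_raw"), 0.0)

    def marker_frame(lat: dict) -> pd.DataFrame:
        s, b, q = lat["s"], lat["b"], lat["q"]
        abeta40 = MARKER_BASE["abeta40"] * s * np.exp(lat["eps40"])
        abeta42 = MARKER_BASE["abeta42"] * s * np.exp(ABETA42_SLOPE * b
                                                      + lat["eps42"])
        ptau = MARKER_BASE["ptau"] * np.exp(PTAU_SLOPE * b + lat["epsp"])
        ttau = MARKER_BASE["ttau_per_ptau"] * ptau * np.exp(lat["epst"])
        nfl = MARKER_BASE["nfl"] * np.exp(NFL_SLOPE * b + lat["epsn"])
        return pd.DataFrame({
            "abeta40": abeta40, "abeta42": abeta42,
            "abeta_ratio_x10": 10.0 * abeta42 / abeta40,
            "ttau": ttau, "ptau": ptau, "nfl": nfl, "qalb": q,
        })

    markers = marker_frame(lat)
    if config.enforce_at_rule:
        # border-case-free cohort: redraw any sample whose markers would
        # stratify against its intended group (pre-selected cohorts exclude
        # such cases by design)
        from .stratify import DISCOVERY_RULE, VALIDATION_RULE, assign_at_status
        rule = VALIDATION_RULE if config.cohort_tag == "validation" \
            else DISCOVERY_RULE
        for _ in range(200):
            status = assign_at_status(markers.set_axis(ids), rule)
            bad = (status.to_numpy() != intended)
            if not bad.any():
                break
            redraw = draw(int(bad.sum()))
            redraw["b"] = np.where(pos_mask[bad], redraw.pop("b_raw"), 0.0)
            for key in lat:
                lat[key][bad] = redraw[key]
            markers = marker_frame(lat)
        else:  # pragma: no cover
            raise RuntimeError("could not satisfy the AT rule; check cutoffs")
    markers.index = ids
    s, b, d, q = lat["s"], lat["b"], lat["d"], lat["q"]

    age = np.round(rng.uniform(45.0, 80.0, n), 1)
    sex = np.where(rng.random(n) < 0.6, "F", "M")
    for col, frac in (("nfl", config.nfl_missing_frac),
                      ("qalb", config.qalb_missing_frac)):
        markers.loc[rng.random(n) < frac, col] = np.nan

    prot_ids, blocks = _protein_ids(config)
    base = np.exp(rng.uniform(np.log(500.0), np.log(5000.0), len(prot_ids)))
    # per-protein pathology slope: heterogeneous within the tau block so
    # within-tau ratios retain (weak) signal, zero elsewhere
    beta_p = np.where(np.array(blocks) == "tau_associated",
                      config.beta_tau * rng.uniform(0.8, 1.2, len(prot_ids)), 0.0)
    qc_fail = np.array([pid.startswith("QCF") for pid in prot_ids])

    burden = b + d
    log_q_dev = np.log(q / MARKER_BASE["qalb"])
    log_s = np.log(s)
    cols = {}
    for j, (pid, block) in enumerate(zip(prot_ids, blocks)):
        if qc_fail[j]:
            logx = np.log(base[j]) + 0.5 * log_q_dev + rng.normal(0.0, 0.4, n)
        elif block == "peripheral":
            logx = np.log(base[j]) + log_q_dev + rng.normal(0.0, config.sigma_noise, n)
        elif block == "amyloid_associated":
            logx = np.log(base[j]) + log_s + rng.normal(0.0, config.sigma_noise, n)
        else:
            logx = (np.log(base[j]) + log_s + beta_p[j] * burden
                    + rng.normal(0.0, config.sigma_noise, n))
        cols[pid] = np.exp(logx)
    proteins = pd.DataFrame(cols, index=ids)

    u = config.beta_cog * burden
    age_dec = (age - 60.0) / 10.0
    cog = {}
    for score in COG_SCORES:
        base0, a_sl, b_sl, sd, lo, hi = COG_MODEL[score]
        vals = base0 - a_sl * age_dec - b_sl * u + rng.normal(0.0, sd, n)
        vals = np.clip(vals, lo, hi if hi is not None else np.inf)
        vals = np.round(vals, 1)
        vals[rng.random(n) < config.missing_cog_frac] = np.nan
        cog[score] = vals
    cognition = pd.DataFrame(cog, index=ids)

    diagnosis = _assign_diagnosis(config, intended, burden, rng)
    samples = pd.DataFrame({
        "cohort_tag": tag,
        "diagnosis": diagnosis,
        "age": age,
        "sex": sex,
        "plate_id": "",
        "position_index": 0,
        "pool_flag": False,
    }, index=ids)

    gt_samples = pd.DataFrame({
        "s": s, "b": b, "d": d,
        "intended_group": intended,
    }, index=ids)
    gt_proteins = pd.DataFrame({
        "true_block": blocks,
        "base_level": base,
        "beta": beta_p,
        "qc_fail": qc_fail,
        "drift_slope": 0.0,
    }, index=pd.Index(prot_ids, name="protein"))
    return Cohort(samples, markers, proteins, cognition,
                  gt_samples, gt_proteins, config=config)


def _assign_diagnosis(config, intended, burden, rng):
    """SCD/MCI/AD labels: within each intended group, the mix is assigned by
    burden quantile (most impaired -> AD), mirroring a clinical work-up."""
    diagnosis = np.array(["SCD"] * len(intended), dtype=object)
    for group, mix in (("A-T-", config.neg_diagnosis_mix),
                       ("A+T+", config.pos_diagnosis_mix)):
        idx = np.flatnonzero(intended == group)
        if mix is None or len(idx) == 0:
            continue
        order = idx[np.argsort(burden[idx], kind="stable")]
        n_scd = int(round(mix[0] * len(idx)))
        n_mci = int(round(mix[1] * len(idx)))
        diagnosis[order[n_scd:n_scd + n_mci]] = "MCI"
        diagnosis[order[n_scd + n_mci:]] = "AD"
    return diagnosis


def inject_technical_effects(cohort: Cohort, config: CohortConfig | None = None,
                             drift_slopes: pd.Series | None = None,
                             plate_offsets: dict | None = None,
                             duplicate_run: bool = False) -> Cohort:
    """Assign plates/positions, multiply in readout drift and plate offsets,
    append pool replicates and (optionally) emit a duplicate assay run.

    Each measurement is multiplied by ``exp(slope_p * position + offset_plate)``.
    The pool is the geometric-mean profile of all real samples plus
    technical noise; ``pool_reps_per_plate`` replicates are placed on every
    plate. The duplicate run re-measures the injected matrix with fresh
    technical noise (inflated for QC-fail proteins), for inter-assay QC.
    """
    config = config or cohort.config
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    n_pool = config.pool_reps_per_plate
    capacity = config.positions_per_plate - n_pool
    if capacity < 1:
        raise ValueError("positions_per_plate leaves no room for real samples")
    real_ids = list(cohort.proteins.index)
    if len(real_ids) > capacity * config.plates:
        raise ValueError(
            f"{len(real_ids)} samples exceed plate capacity "
            f"{capacity * config.plates}")

    prot = cohort.proteins
    pool_profile = np.exp(np.log(prot.to_numpy()).mean(axis=0))
    tech_sd = np.where(cohort.gt_proteins["qc_fail"].to_numpy(),
                       12.0 * config.sigma_tech, config.sigma_tech)

    order = rng.permutation(len(real_ids))
    plate_of = {}
    for k, i in enumerate(order):
        plate_of[real_ids[i]] = k % config.plates

    rows, meta_rows = [], []
    for p in range(config.plates):
        members = [sid for sid in real_ids if plate_of[sid] == p]
        pool_ids = [f"POOL_{config.cohort_tag[:3].upper()}_P{p + 1}_{r + 1}"
                    for r in range(n_pool)]
        all_ids = members + pool_ids
        positions = rng.permutation(len(all_ids)) + 1
        for sid, pos in zip(all_ids, positions):
            if sid in pool_ids:
                vals = pool_profile * np.exp(rng.normal(0.0, 1.0, len(tech_sd)) * tech_sd)
            else:
                vals = prot.loc[sid].to_numpy()
            rows.append((sid, f"PLATE_{p + 1}", int(pos), sid in pool_ids, vals))

    if drift_slopes is None:
        slopes = rng.normal(0.0, config.drift_slope_sd, prot.shape[1])
        drift_slopes = pd.Series(slopes, index=prot.columns)
    else:
        drift_slopes = pd.Series(drift_slopes, index=prot.columns).fillna(0.0)
    if plate_offsets is None:
        plate_offsets = {f"PLATE_{p + 1}": o for p, o in enumerate(
            rng.normal(0.0, config.plate_offset_sd, config.plates))}

    ids = [r[0] for r in rows]
    mat = np.vstack([r[4] for r in rows])
    pos = np.array([r[2] for r in rows])
    if (pos < 0).any():
        raise ValueError("negative position index")
    offs = np.array([plate_offsets[r[1]] for r in rows])
    mat = mat * np.exp(np.outer(pos, drift_slopes.to_numpy()) + offs[:, None])
    proteins = pd.DataFrame(mat, index=pd.Index(ids, name="sample_id"),
                            columns=prot.columns)

    samples = cohort.samples.copy()
    pool_meta = []
    for sid, plate, position, is_pool, _ in rows:
        if is_pool:
            pool_meta.append((sid, plate, position))
        else:
            samples.loc[sid, ["plate_id", "position_index"]] = (plate, position)
    pool_df = pd.DataFrame(
        {"cohort_tag": config.cohort_tag, "diagnosis": "POOL", "age": np.nan,
         "sex": "", "plate_id": [m[1] for m in pool_meta],
         "position_index": [m[2] for m in pool_meta], "pool_flag": True},
        index=pd.Index([m[0] for m in pool_meta], name="sample_id"))
    samples = pd.concat([samples, pool_df])
    samples["position_index"] = samples["position_index"].astype(int)
    # keep sample order aligned with the protein matrix
    samples = samples.loc[proteins.index]

    gt_proteins = cohort.gt_proteins.copy()
    gt_proteins["drift_slope"] = drift_slopes
    gt_plates = pd.DataFrame({"plate_offset": pd.Series(plate_offsets)})
    gt_plates.index.name = "plate_id"

    run2 = None
    if duplicate_run:
        noise = rng.normal(0.0, 1.0, proteins.shape) * tech_sd[None, :]
        run2 = proteins * np.exp(noise)

    return Cohort(samples, cohort.markers, proteins, cohort.cognition,
                  cohort.gt_samples, gt_proteins, gt_plates, run2, config)


_FILES = {
    "samples": "samples.csv",
    "markers": "markers.csv",
    "proteins": "proteins.csv",
    "cognition": "cognition.csv",
    "gt_samples": "ground_truth.csv",
    "gt_proteins": "ground_truth_proteins.csv",
    "gt_plates": "ground_truth_plates.csv",
    "proteins_run2": "proteins_run2.csv",
}


def write_dataset(cohort: Cohort, directory) -> list[Path]:
    """Write the cohort as UTF-8 CSV files (ground truth clearly marked as
    synthetic-only by filename); returns the written paths."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    written = []
    for attr, fname in _FILES.items():
        df = getattr(cohort, attr)
        if df is None:
            continue
        path = directory / fname
        try:
            df.to_csv(path)
        except OSError as exc:  # pragma: no cover
            raise OSError(f"failed to write {path}: {exc}") from exc
        written.append(path)
    if cohort.config is not None:
        path = directory / "config.json"
        path.write_text(json.dumps(dataclasses.asdict(cohort.config), indent=1))
        written.append(path)
    return written


def read_dataset(directory) -> Cohort:
    """Read a cohort written by :func:`write_dataset`."""
    directory = Path(directory)
    frames = {}
    for attr, fname in _FILES.items():
        path = directory / fname
        if not path.exists():
            frames[attr] = None
            continue
        df = pd.read_csv(path, index_col=0)
        frames[attr] = df
    config = None
    cfg_path = directory / "config.json"
    if cfg_path.exists():
        raw = json.loads(cfg_path.read_text())
        for key in ("neg_diagnosis_mix", "pos_diagnosis_mix"):
            if raw.get(key) is not None:
                raw[key] = tuple(raw[key])
        config = CohortConfig(**raw)
    if frames["samples"] is not None:
        frames["samples"]["pool_flag"] = frames["samples"]["pool_flag"].astype(bool)
        frames["samples"] = frames["samples"].fillna({"diagnosis": "", "sex": ""})
    return Cohort(frames["samples"], frames["markers"], frames["proteins"],
                  frames["cognition"], frames["gt_samples"],
                  frames["gt_proteins"], frames["gt_plates"],
                  frames["proteins_run2"], config)
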