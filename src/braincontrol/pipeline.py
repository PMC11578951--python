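"""End-to-end orchestration: simulate → connect → control → stats → predict.

The stage functions operate on in-memory objects so they can be composed
programmatically (the acceptance and calibration scripts do); `run_pipeline`
wraps them with flat-file artifacts (TSV/CSV + JSON manifest with sha256
checksums) for a reproducible disk run.  Identical seeds give byte-identical
manifests: wall-clock timings go to the log stream, never into artifacts.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import control as nc
from . import signal as sig
from . import stats as st
from .atlas import split_label
from .prediction import FeatureSpec, assemble_features, svr_loocv
from .synthetic import Cohort, CohortConfig, generate_cohort, make_base_network, write_cohort

logger = logging.getLogger("braincontrol")

__all__ = [
    "ProcessingConfig",
    "NetworkConfig",
    "RunConfig",
    "validate_config",
    "compute_connectivity",
    "compute_profiles",
    "screen_cohort",
    "correlate_cohort",
    "predict_cohort",
    "run_pipeline",
]


@dataclass
class ProcessingConfig:
    band_low_hz: float = 0.01
    band_high_hz: float = 0.08
    filter_method: str = "ideal"  # or "butterworth"
    order: str = "filter_then_regress"  # or "regress_then_filter"
    regress_motion: bool = True
    include_global_signal: bool = True
    use_scrubbing: bool = True
    scrub_threshold_mm: float = 0.5
    scrub_remove_following: bool = True


@dataclass
class NetworkConfig:
    n_nodes: int = 90
    n_modules: int = 6
    within_strength: float = 0.6
    between_strength: float = 0.1
    perturbation_scale: float = 0.3


@dataclass
class RunConfig:
    seed: int = 0
    out_dir: str = "braincontrol_run"
    cohort: CohortConfig = field(default_factory=CohortConfig)
    network: NetworkConfig = field(default_factory=NetworkConfig)
    processing: ProcessingConfig = field(default_factory=ProcessingConfig)
    alpha: float = 0.05
    stabilization_c: float = 1.0
    svr: dict = field(default_factory=lambda: dict(kernel="rbf", C=1.0, epsilon=0.1))

    def resolved(self) -> dict:
        d = dataclasses.asdict(self)
        d["cohort"]["seed"] = self.seed
        return d


def _build(cls, section: dict, errors: list[str], name: str):
    valid = {f.name for f in dataclasses.fields(cls)}
    unknown = set(section) - valid
    for k in sorted(unknown):
        errors.append(f"{name}: unknown key {k!r}")
    try:
        return cls(**{k: v for k, v in section.items() if k in valid})
    except (ValueError, TypeError) as exc:
        errors.append(f"{name}: {exc}")
        return cls()


def validate_config(raw: dict | None) -> RunConfig:
    """Resolve a (possibly empty) config mapping into a RunConfig.

    All violations are collected and reported together in one ValueError.
    """
    raw = dict(raw or {})
    errors: list[str] = []
    cohort = _build(CohortConfig, raw.pop("cohort", {}), errors, "cohort")
    network = _build(NetworkConfig, raw.pop("network", {}), errors, "network")
    processing = _build(ProcessingConfig, raw.pop("processing", {}), errors, "processing")
    top = {k: raw.pop(k) for k in list(raw) if k in {"seed", "out_dir", "alpha", "stabilization_c", "svr"}}
    for k in sorted(raw):
        errors.append(f"unknown top-level key {k!r}")
    cfg = RunConfig(cohort=cohort, network=network, processing=processing, **top)
    if not 0.0 <= cfg.alpha <= 1.0:
        errors.append(f"alpha={cfg.alpha} outside [0, 1]")
    if not 0.0 < cfg.stabilization_c <= 1.0:
        errors.append(f"stabilization_c={cfg.stabilization_c} outside (0, 1]")
    p = cfg.processing
    nyq = 1.0 / (2.0 * cfg.cohort.tr_seconds)
    if not 0 <= p.band_low_hz < p.band_high_hz:
        errors.append(
            f"band ({p.band_low_hz}, {p.band_high_hz}) invalid: "
            "need 0 <= low < high"
        )
    elif p.band_high_hz > nyq:
        errors.append(f"band high {p.band_high_hz} Hz above Nyquist {nyq} Hz")
    if errors:
        raise ValueError("invalid configuration:\n  " + "\n  ".join(errors))
    cfg.cohort = dataclasses.replace(cfg.cohort, seed=cfg.seed)
    return cfg


def load_config(path: str | Path | None, seed: int | None = None, out_dir: str | None = None) -> RunConfig:
    raw = {}
    if path is not None:
        raw = yaml.safe_load(Path(path).read_text()) or {}
    if seed is not None:
        raw["seed"] = seed
    if out_dir is not None:
        raw["out_dir"] = out_dir
    return validate_config(raw)


# ---------------------------------------------------------------- stages


def simulate_stage(cfg: RunConfig) -> Cohort:
    net = make_base_network(
        n_nodes=cfg.network.n_nodes,
        n_modules=cfg.network.n_modules,
        within_strength=cfg.network.within_strength,
        between_strength=cfg.network.between_strength,
        seed=cfg.seed,
        perturbation_scale=cfg.network.perturbation_scale,
    )
    return generate_cohort(cfg.cohort, net)


def _clean_session(ts: sig.RoiTimeSeries, motion, proc: ProcessingConfig) -> sig.RoiTimeSeries:
    def _filter(x: sig.RoiTimeSeries) -> sig.RoiTimeSeries:
        return sig.bandpass(x, proc.band_low_hz, proc.band_high_hz, method=proc.filter_method)

    def _confounds(reference: sig.RoiTimeSeries) -> np.ndarray | None:
        cols = []
        if proc.include_global_signal:
            cols.append(reference.values.mean(axis=1, keepdims=True))
        if proc.regress_motion and motion is not None:
            cols.append(sig.friston24(motion))
        if not cols:
            return None
        return np.hstack(cols)

    if proc.order == "filter_then_regress":
        ts = _filter(ts)
        conf = _confounds(ts)
        if conf is not None:
            # confounds pass through the same filter so regression cannot
            # reintroduce out-of-band noise
            conf_ts = sig.RoiTimeSeries(
                values=conf,
                tr_seconds=ts.tr_seconds,
                node_labels=[f"c{i}" for i in range(conf.shape[1])],
            )
            conf = _filter(conf_ts).values
            ts = sig.regress_confounds(ts, conf)
    elif proc.order == "regress_then_filter":
        conf = _confounds(ts)
        if conf is not None:
            ts = sig.regress_confounds(ts, conf)
        ts = _filter(ts)
    else:
        raise ValueError(f"unknown processing order {proc.order!r}")

    if proc.use_scrubbing and motion is not None:
        fd = sig.framewise_displacement(motion)
        res = sig.scrub(
            ts, fd, threshold_mm=proc.scrub_threshold_mm,
            remove_following=proc.scrub_remove_following,
        )
        if not res.usable:
            logger.warning(
                "session %s/%s unusable after scrubbing (%.0f%% removed)",
                ts.subject_id, ts.session, 100 * res.fraction_removed,
            )
        ts = res.ts
    return ts


def compute_connectivity(cohort: Cohort, proc: ProcessingConfig | None = None) -> dict:
    """Clean every session and return {(subject, session): ConnectivityMatrix}."""
    proc = proc or ProcessingConfig()
    out = {}
    for key, ts in cohort.sessions.items():
        out[key] = sig.pearson_fc(_clean_session(ts, cohort.motion.get(key), proc))
    return out


def compute_profiles(
    fcs: dict, stabilization_c: float = 1.0
) -> tuple[dict, dict[str, nc.DeltaProfile]]:
    """Controllability profiles per session plus on−off deltas per patient."""
    profiles = {}
    for (sid, sess), fc in fcs.items():
        dyn = nc.stabilize(fc, c=stabilization_c)
        profiles[(sid, sess)] = nc.controllability_profile(dyn, subject_id=sid, session=sess)
    deltas = {}
    for (sid, sess) in profiles:
        if sess == "on" and (sid, "off") in profiles:
            deltas[sid] = nc.delta_profile(profiles[(sid, "on")], profiles[(sid, "off")])
    return profiles, deltas


def _metric_matrix(profiles: dict, keys: list, metric: str) -> np.ndarray:
    return np.vstack([getattr(profiles[k], metric) for k in keys])


def screen_cohort(
    cohort: Cohort, profiles: dict, alpha: float = 0.05
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Region screen: group ANCOVA (patient-off vs control, age+sex adjusted)
    and paired medication t-test, then the intersection rule.

    Returns (ancova_frame, paired_frame, responsive_frame) over every region
    × metric.
    """
    recs = {s.subject_id: s for s in cohort.subjects}
    off_keys = [k for k in profiles if k[1] == "off"]
    hc_keys = [k for k in profiles if k[1] == "single"]
    paired_ids = sorted(k[0] for k in profiles if k[1] == "on" and (k[0], "off") in profiles)
    labels = cohort.network.node_labels
    parts = []
    for lab in labels:
        try:
            parts.append(split_label(lab))
        except ValueError:  # generic (non-atlas) node names
            parts.append((lab, ""))

    ages = np.array([recs[k[0]].age for k in off_keys] + [recs[k[0]].age for k in hc_keys])
    sexes = np.array([recs[k[0]].sex for k in off_keys] + [recs[k[0]].sex for k in hc_keys])

    anc_rows, par_rows = [], []
    for metric in ("ac", "mc"):
        pd_vals = _metric_matrix(profiles, off_keys, metric)
        hc_vals = _metric_matrix(profiles, hc_keys, metric)
        F, p, direction = st.ancova_table(pd_vals, hc_vals, ages, sexes)
        if len(paired_ids) >= 3:
            on_vals = np.vstack([getattr(profiles[(s, "on")], metric) for s in paired_ids])
            offp_vals = np.vstack([getattr(profiles[(s, "off")], metric) for s in paired_ids])
            t, tp = st.paired_t_table(on_vals, offp_vals)
        else:
            logger.warning("fewer than 3 complete on/off pairs: medication test undefined")
            t = np.full(len(labels), np.nan)
            tp = np.full(len(labels), np.nan)
        for j, (region, hemi) in enumerate(parts):
            anc_rows.append(
                dict(region=region, hemisphere=hemi, metric=metric,
                     group_F=F[j], group_p=p[j], direction=direction[j])
            )
            par_rows.append(
                dict(region=region, hemisphere=hemi, metric=metric,
                     med_t=t[j], med_p=tp[j], n_pairs=len(paired_ids))
            )
    ancova_frame = pd.DataFrame(anc_rows)
    paired_frame = pd.DataFrame(par_rows)
    responsive = st.select_responsive_regions(ancova_frame, paired_frame, alpha=alpha)
    return ancova_frame, paired_frame, responsive


def _group_outcomes(cohort: Cohort, target: str) -> dict[str, float]:
    return {
        s.subject_id: s.improvement_rate
        for s in cohort.subjects
        if s.target == target and s.improvement_rate is not None
    }


def correlate_cohort(
    cohort: Cohort, deltas: dict, alpha: float = 0.05
) -> pd.DataFrame:
    """Motor-ROI delta-vs-improvement correlations for each surgical group."""
    frames = []
    for target in ("STN", "GPi"):
        outcomes = _group_outcomes(cohort, target)
        grp_deltas = {s: d for s, d in deltas.items() if s in outcomes}
        if len(grp_deltas) < 5:
            continue
        df = st.correlate_delta_outcome(grp_deltas, outcomes, alpha=alpha)
        df.insert(0, "target", target)
        frames.append(df)
    if not frames:
        return pd.DataFrame(
            columns=["target", "region", "hemisphere", "metric", "r", "p", "n",
                     "significant", "undefined"]
        )
    return pd.concat(frames, ignore_index=True)


def predict_cohort(cohort: Cohort, deltas: dict, svr_params: dict | None = None, seed: int = 0) -> dict:
    """LOOCV-SVR improvement prediction per surgical group (a-priori features)."""
    svr_params = svr_params or {}
    results = {}
    for target in ("STN", "GPi"):
        outcomes = _group_outcomes(cohort, target)
        grp_deltas = {s: d for s, d in deltas.items() if s in outcomes}
        if len(grp_deltas) < 5:
            logger.warning("skipping %s prediction: fewer than 5 usable subjects", target)
            continue
        spec = FeatureSpec(group=target)
        try:
            X, y, dropped = assemble_features(grp_deltas, outcomes, spec)
        except ValueError as exc:
            logger.warning("skipping %s prediction: %s", target, exc)
            continue
        if dropped:
            logger.info("%s: dropped %d subject(s) without both sessions", target, len(dropped))
        results[target] = svr_loocv(X, y, seed=seed, **svr_params)
    return results


# ---------------------------------------------------------------- disk run


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_csv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, index=False, float_format="%.10g")


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute every stage, writing flat-file artifacts plus a manifest.

    Returns the manifest dictionary (also written to ``manifest.json`` in
    the output directory).  Any stage failure aborts with the stage name in
    the raised error.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, str] = {}
    notices: list[str] = []
    stage = "simulate"
    try:
        t0 = time.monotonic()
        cohort = simulate_stage(cfg)
        write_cohort(cohort, out / "data")
        artifacts["data/manifest.json"] = _sha256(out / "data" / "manifest.json")
        logger.info("simulate: %d subjects, %d sessions (%.1fs)",
                    len(cohort.subjects), len(cohort.sessions), time.monotonic() - t0)

        stage = "connect"
        fcs = compute_connectivity(cohort, cfg.processing)
        fcdir = out / "connectivity"
        fcdir.mkdir(exist_ok=True)
        for (sid, sess), fc in sorted(fcs.items()):
            p = fcdir / f"{sid}_{sess}_fc.csv"
            pd.DataFrame(fc.values, index=fc.node_labels, columns=fc.node_labels).to_csv(
                p, float_format="%.8f"
            )
            artifacts[str(p.relative_to(out))] = _sha256(p)

        stage = "control"
        profiles, deltas = compute_profiles(fcs, cfg.stabilization_c)
        prof_rows = []
        for (sid, sess), prof in sorted(profiles.items()):
            df = prof.to_frame()
            df.insert(0, "session", sess)
            df.insert(0, "subject_id", sid)
            prof_rows.append(df)
        p = out / "controllability.csv"
        _write_csv(pd.concat(prof_rows, ignore_index=True), p)
        artifacts[p.name] = _sha256(p)
        delta_rows = []
        for sid, d in sorted(deltas.items()):
            df = pd.DataFrame({
                "subject_id": sid,
                "label": d.node_labels,
                "delta_ac": d.delta_ac,
                "delta_mc": d.delta_mc,
            })
            delta_rows.append(df)
        p = out / "delta_controllability.csv"
        _write_csv(pd.concat(delta_rows, ignore_index=True), p)
        artifacts[p.name] = _sha256(p)

        stage = "stats"
        ancova_frame, paired_frame, responsive = screen_cohort(cohort, profiles, cfg.alpha)
        corr = correlate_cohort(cohort, deltas, cfg.alpha)
        for name, df in [
            ("screen_group_ancova.csv", ancova_frame),
            ("screen_paired_medication.csv", paired_frame),
            ("responsive_regions.csv", responsive),
            ("delta_outcome_correlations.csv", corr),
        ]:
            p = out / name
            _write_csv(df, p)
            artifacts[name] = _sha256(p)

        stage = "predict"
        if responsive.empty:
            notices.append("no responsive regions at alpha=%g; prediction stage skipped" % cfg.alpha)
            logger.warning(notices[-1])
            predictions = {}
        else:
            predictions = predict_cohort(cohort, deltas, cfg.svr, seed=cfg.seed)
        summary_rows = []
        for target, res in sorted(predictions.items()):
            p = out / f"predictions_{target}.csv"
            _write_csv(res.table, p)
            artifacts[p.name] = _sha256(p)
            summary_rows.append(
                dict(target=target, n=res.n_subjects, r=res.r, p=res.p,
                     **{f"svr_{k}": v for k, v in res.hyperparameters.items()})
            )
        p = out / "prediction_summary.csv"
        _write_csv(pd.DataFrame(summary_rows), p)
        artifacts[p.name] = _sha256(p)
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    manifest = {
        "config": cfg.resolved(),
        "artifacts": dict(sorted(artifacts.items())),
        "notices": notices,
        "n_responsive_regions": int(len(responsive)),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest
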