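"""Synthetic study generator: ground-truth networks, sessions, outcomes.

Emulates the structure of a two-target DBS cohort study: patients scanned in
medication-off and medication-on states plus single-session healthy
controls.  Disease is planted as attenuated covariance between designated
striato-pallido-thalamo-cortical nodes and the rest of the network, which
lowers average controllability and raises modal controllability at those
nodes; medication moves each patient's covariance a subject-specific
fraction ("recovery") back toward the healthy base network, and surgical
motor improvement is a linear function of that same recovery fraction plus
noise.  The downstream pipeline therefore has to recover the
delta-controllability → outcome association through the latent cause, a
stricter test than planting the association on measured features directly.

Every draw is routed through ``numpy.random.default_rng`` seeded from the
config, so cohorts are bit-reproducible.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .atlas import AAL90_LABELS, DISEASE_STRUCTURES, structure_indices
from .signal import MotionTrace, RoiTimeSeries

__all__ = [
    "GroundTruthNetwork",
    "CohortConfig",
    "SubjectRecord",
    "Cohort",
    "make_base_network",
    "state_covariance",
    "simulate_session",
    "simulate_motion",
    "generate_cohort",
    "make_candidate_pool",
    "write_cohort",
]

# Demographic anchors (means/SDs and sex counts) matching the magnitudes of
# a typical advanced-PD DBS cohort and its control group.
_PATIENT_AGE = (59.21, 9.61)
_CONTROL_AGE = (53.48, 8.40)
_UPDRS_PRE = (55.95, 16.37)
_MEAN_IMPROVEMENT = 68.65  # percent, anchors the outcome intercept
_SEX_MALE_FRACTION = {"STN": 12 / 24, "GPi": 9 / 15, "control": 8 / 29}


@dataclass
class GroundTruthNetwork:
    """Healthy base covariance plus the disease perturbation recipe."""

    n_nodes: int
    base_cov: np.ndarray
    module_assignment: np.ndarray
    perturbed_nodes: list[int]
    perturbation_scale: float
    seed: int
    node_labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        c = np.asarray(self.base_cov, dtype=float)
        if np.max(np.abs(c - c.T)) > 1e-12:
            raise ValueError("base_cov not symmetric within 1e-12")
        w = np.linalg.eigvalsh(c)
        if w.min() <= 0:
            raise ValueError(f"base_cov not positive definite (min eig {w.min():.3g})")
        if self.perturbed_nodes and not all(
            0 <= i < self.n_nodes for i in self.perturbed_nodes
        ):
            raise ValueError("perturbed_nodes outside [0, n_nodes)")
        if not self.node_labels:
            self.node_labels = (
                list(AAL90_LABELS)
                if self.n_nodes == 90
                else [f"node_{i:03d}" for i in range(self.n_nodes)]
            )


@dataclass
class CohortConfig:
    """Study-design knobs; defaults are the emulated study's conditions."""

    n_patients_stn: int = 24
    n_patients_gpi: int = 15
    n_controls: int = 29
    n_timepoints: int = 223
    tr_seconds: float = 2.0
    medication_recovery_mean: float = 0.5
    recovery_concentration: float = 2.0
    outcome_slope: float = 40.0  # percent improvement per unit recovery
    outcome_intercept: float | None = None  # default: anchor mean improvement
    outcome_noise_sd: float = 5.0  # percent
    ar_coef: float = 0.3
    n_drop_on: int = 5
    n_drop_off: int = 2
    include_motion: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_patients_stn, self.n_patients_gpi, self.n_controls) <= 0:
            raise ValueError("cohort counts must be positive")
        if self.n_timepoints <= 0 or self.tr_seconds <= 0:
            raise ValueError("n_timepoints and tr_seconds must be positive")
        if not 0.0 <= self.medication_recovery_mean <= 1.0:
            raise ValueError("medication_recovery_mean must lie in [0, 1]")
        if self.outcome_noise_sd < 0:
            raise ValueError("outcome_noise_sd must be >= 0")
        if not 0.0 <= self.ar_coef < 1.0:
            raise ValueError("ar_coef must lie in [0, 1)")

    @property
    def resolved_intercept(self) -> float:
        if self.outcome_intercept is not None:
            return self.outcome_intercept
        return _MEAN_IMPROVEMENT - self.outcome_slope * self.medication_recovery_mean


@dataclass
class SubjectRecord:
    """One clinical-table row."""

    subject_id: str
    cohort: str  # patient | control
    target: str  # STN | GPi | none
    age: float
    sex: str  # male | female
    updrs3_pre_off: float | None = None
    updrs3_post_off_stim_on: float | None = None
    improvement_rate: float | None = None
    has_on_session: bool = False
    has_off_session: bool = False
    exclusion_reason: str | None = None

    def __post_init__(self) -> None:
        if (self.target == "none") != (self.cohort == "control"):
            raise ValueError("target is 'none' iff cohort is 'control'")
        for v in (self.updrs3_pre_off, self.updrs3_post_off_stim_on):
            if v is not None and v < 0:
                raise ValueError("UPDRS scores must be >= 0")


@dataclass
class Cohort:
    """Everything one synthetic run produces."""

    subjects: list[SubjectRecord]
    sessions: dict[tuple[str, str], RoiTimeSeries]
    motion: dict[tuple[str, str], MotionTrace]
    ground_truth: pd.DataFrame  # subject_id, recovery, linear predictor
    network: GroundTruthNetwork
    config: CohortConfig

    def clinical_frame(self) -> pd.DataFrame:
        return pd.DataFrame([asdict(s) for s in self.subjects]).drop(
            columns=["exclusion_reason"]
        )


def make_base_network(
    n_nodes: int = 90,
    n_modules: int = 6,
    within_strength: float = 0.6,
    between_strength: float = 0.1,
    seed: int = 0,
    min_eigenvalue: float = 0.1,
    variance_jitter: float = 0.1,
    perturbed_nodes: list[int] | None = None,
    perturbation_scale: float = 0.3,
) -> GroundTruthNetwork:
    """Modular covariance: dense within-community blocks, weak between.

    Communities are contiguous, nearly equal blocks of nodes.  Unit
    variances receive a small seeded jitter (diagonal only, so a zero
    between-strength still gives exactly block-diagonal covariance).  If the
    smallest eigenvalue falls below ``min_eigenvalue`` the diagonal is
    loaded up to it.
    """
    if not 0 <= between_strength < within_strength:
        raise ValueError("need within_strength > between_strength >= 0")
    if not 1 <= n_modules <= n_nodes:
        raise ValueError("n_modules must partition n_nodes")
    rng = np.random.default_rng(seed)
    modules = np.array_split(np.arange(n_nodes), n_modules)
    assignment = np.empty(n_nodes, dtype=int)
    cov = np.full((n_nodes, n_nodes), between_strength, dtype=float)
    for m, idx in enumerate(modules):
        assignment[idx] = m
        cov[np.ix_(idx, idx)] = within_strength
    np.fill_diagonal(cov, 1.0 + variance_jitter * rng.uniform(-1, 1, size=n_nodes))
    w = np.linalg.eigvalsh(cov)
    if w.min() < min_eigenvalue:
        cov[np.diag_indices(n_nodes)] += min_eigenvalue - w.min()
    w = np.linalg.eigvalsh(cov)
    if w.min() < min_eigenvalue - 1e-9:
        raise ValueError(
            f"covariance not positive definite after loading "
            f"(min eigenvalue {w.min():.3g})"
        )
    if perturbed_nodes is None:
        perturbed_nodes = (
            structure_indices(DISEASE_STRUCTURES) if n_nodes == 90 else []
        )
    return GroundTruthNetwork(
        n_nodes=n_nodes,
        base_cov=cov,
        module_assignment=assignment,
        perturbed_nodes=list(perturbed_nodes),
        perturbation_scale=perturbation_scale,
        seed=seed,
    )


def state_covariance(
    net: GroundTruthNetwork,
    cohort: str,
    session: str,
    recovery: float = 0.0,
    seed: int | None = None,
) -> np.ndarray:
    """Generating covariance for one subject-session.

    control/single → base covariance; patient/off → off-diagonal rows and
    columns of the perturbed nodes shrunk by ``perturbation_scale``;
    patient/on → convex combination (1−recovery)·off + recovery·base.
    The construction D·C·D with the original diagonal restored keeps the
    matrix positive definite for any scale in (0, 1].
    """
    del seed  # the transformation is deterministic; kept for API symmetry
    if cohort == "control" or session == "single":
        return net.base_cov.copy()
    if not 0.0 <= recovery <= 1.0:
        raise ValueError(f"recovery={recovery} outside [0, 1]")
    d = np.ones(net.n_nodes)
    d[net.perturbed_nodes] = net.perturbation_scale
    off = net.base_cov * np.outer(d, d)
    np.fill_diagonal(off, np.diag(net.base_cov))
    if session == "off":
        return off
    if session == "on":
        return (1.0 - recovery) * off + recovery * net.base_cov
    raise ValueError(f"unknown session {session!r}")


def simulate_session(
    cov: np.ndarray,
    n_timepoints: int,
    tr_seconds: float = 2.0,
    seed: int = 0,
    ar_coef: float = 0.3,
    node_labels: list[str] | None = None,
    subject_id: str | None = None,
    session: str = "single",
) -> RoiTimeSeries:
    """Draw a stationary Gaussian BOLD-like series with the given covariance.

    With ar_coef φ > 0 the series follows x_t = φ x_{t−1} + √(1−φ²) L z_t
    (L the Cholesky factor), whose stationary covariance is exactly ``cov``;
    φ = 0 gives independent frames.
    """
    cov = np.asarray(cov, dtype=float)
    n = cov.shape[0]
    try:
        L = np.linalg.cholesky(cov)
    except np.linalg.LinAlgError as exc:
        raise ValueError("covariance not positive definite") from exc
    if n_timepoints < n + 2:
        warnings.warn(
            f"{n_timepoints} time points for {n} nodes: sample FC will be "
            "rank-deficient",
            stacklevel=2,
        )
    rng = np.random.default_rng(seed)
    z = rng.standard_normal((n_timepoints, n)) @ L.T
    if ar_coef > 0:
        x = np.empty_like(z)
        x[0] = z[0]
        scale = np.sqrt(1.0 - ar_coef**2)
        for t in range(1, n_timepoints):
            x[t] = ar_coef * x[t - 1] + scale * z[t]
    else:
        x = z
    if node_labels is None:
        node_labels = (
            list(AAL90_LABELS) if n == 90 else [f"node_{i:03d}" for i in range(n)]
        )
    return RoiTimeSeries(
        values=x,
        tr_seconds=tr_seconds,
        node_labels=node_labels,
        subject_id=subject_id,
        session=session,
    )


def simulate_motion(
    n_timepoints: int,
    seed: int = 0,
    drift_sd: float = 0.02,
    spike_prob: float = 0.01,
    spike_mm: float = 1.0,
) -> MotionTrace:
    """Rigid-body motion: slow random-walk drift plus occasional spikes."""
    rng = np.random.default_rng(seed)
    steps = rng.normal(0.0, drift_sd, size=(n_timepoints, 6))
    steps[:, 3:] /= 50.0  # rotations in radians, same arc-length scale
    spikes = rng.random(n_timepoints) < spike_prob
    steps[spikes, 0] += spike_mm
    params = np.cumsum(steps, axis=0)
    params[0] = 0.0
    return MotionTrace(params=params)


def _draw_sexes(rng: np.random.Generator, n: int, male_fraction: float) -> list[str]:
    n_male = int(round(n * male_fraction))
    sexes = ["male"] * n_male + ["female"] * (n - n_male)
    return list(rng.permutation(sexes))


def generate_cohort(cfg: CohortConfig, net: GroundTruthNetwork) -> Cohort:
    """Generate subjects, sessions and ground truth for one synthetic study.

    Per-patient medication recovery is Beta-distributed around
    ``medication_recovery_mean``; percent improvement is
    intercept + slope·recovery + Gaussian noise, truncated to [0, 100], and
    the postoperative score is backed out from the preoperative score so the
    improvement-rate identity holds exactly.  A seeded subset of patients
    loses the on- or off-session to emulate scan exclusions.
    """
    ss = np.random.SeedSequence(cfg.seed)
    rng = np.random.default_rng(ss.spawn(1)[0])
    n_pat = cfg.n_patients_stn + cfg.n_patients_gpi
    targets = ["STN"] * cfg.n_patients_stn + ["GPi"] * cfg.n_patients_gpi

    # recovery fractions
    m, k = cfg.medication_recovery_mean, cfg.recovery_concentration
    if k > 0 and 0 < m < 1:
        recoveries = rng.beta(m * k, (1 - m) * k, size=n_pat)
    else:
        recoveries = np.full(n_pat, m)

    # scan exclusions: disjoint seeded subsets lose one session each
    order = rng.permutation(n_pat)
    drop_on = set(order[: cfg.n_drop_on].tolist())
    drop_off = set(order[cfg.n_drop_on : cfg.n_drop_on + cfg.n_drop_off].tolist())

    sexes_stn = _draw_sexes(rng, cfg.n_patients_stn, _SEX_MALE_FRACTION["STN"])
    sexes_gpi = _draw_sexes(rng, cfg.n_patients_gpi, _SEX_MALE_FRACTION["GPi"])
    sexes_hc = _draw_sexes(rng, cfg.n_controls, _SEX_MALE_FRACTION["control"])
    sexes = sexes_stn + sexes_gpi

    subjects: list[SubjectRecord] = []
    sessions: dict[tuple[str, str], RoiTimeSeries] = {}
    motion: dict[tuple[str, str], MotionTrace] = {}
    gt_rows = []
    child_seeds = iter(s.generate_state(1)[0] % (2**31) for s in ss.spawn(4 * n_pat + 2 * cfg.n_controls + 64))

    intercept = cfg.resolved_intercept
    for i in range(n_pat):
        sid = f"P{i + 1:03d}"
        rec = float(recoveries[i])
        pre = float(np.clip(rng.normal(*_UPDRS_PRE), 20.0, 108.0))
        linpred = intercept + cfg.outcome_slope * rec
        imp = float(
            np.clip(linpred + rng.normal(0.0, cfg.outcome_noise_sd), 0.0, 100.0)
        )
        post = pre * (1.0 - imp / 100.0)
        age = float(np.clip(rng.normal(*_PATIENT_AGE), 35.0, 80.0))
        has_off, has_on = i not in drop_off, i not in drop_on
        subjects.append(
            SubjectRecord(
                subject_id=sid,
                cohort="patient",
                target=targets[i],
                age=age,
                sex=sexes[i],
                updrs3_pre_off=pre,
                updrs3_post_off_stim_on=post,
                improvement_rate=imp,
                has_on_session=has_on,
                has_off_session=has_off,
            )
        )
        gt_rows.append(
            {"subject_id": sid, "recovery": rec, "linear_predictor": linpred}
        )
        for sess, present in (("off", has_off), ("on", has_on)):
            if not present:
                continue
            cov = state_covariance(net, "patient", sess, recovery=rec)
            sessions[(sid, sess)] = simulate_session(
                cov,
                cfg.n_timepoints,
                cfg.tr_seconds,
                seed=next(child_seeds),
                ar_coef=cfg.ar_coef,
                node_labels=net.node_labels,
                subject_id=sid,
                session=sess,
            )
            if cfg.include_motion:
                motion[(sid, sess)] = simulate_motion(
                    cfg.n_timepoints, seed=next(child_seeds)
                )

    for i in range(cfg.n_controls):
        sid = f"C{i + 1:03d}"
        age = float(np.clip(rng.normal(*_CONTROL_AGE), 30.0, 75.0))
        subjects.append(
            SubjectRecord(
                subject_id=sid,
                cohort="control",
                target="none",
                age=age,
                sex=sexes_hc[i],
            )
        )
        cov = state_covariance(net, "control", "single")
        sessions[(sid, "single")] = simulate_session(
            cov,
            cfg.n_timepoints,
            cfg.tr_seconds,
            seed=next(child_seeds),
            ar_coef=cfg.ar_coef,
            node_labels=net.node_labels,
            subject_id=sid,
            session="single",
        )
        if cfg.include_motion:
            motion[(sid, "single")] = simulate_motion(
                cfg.n_timepoints, seed=next(child_seeds)
            )

    return Cohort(
        subjects=subjects,
        sessions=sessions,
        motion=motion,
        ground_truth=pd.DataFrame(gt_rows),
        network=net,
        config=cfg,
    )


def make_candidate_pool(
    n_total: int = 50,
    n_no_surgery: int = 5,
    n_unilateral: int = 2,
    n_lesion: int = 1,
    n_missing: int = 3,
    seed: int = 0,
) -> list[SubjectRecord]:
    """Recruitment pool with exclusion flags for the enrolment cascade.

    Defaults mirror a 50-candidate pool losing 5 (no surgery), 2 (unilateral
    implantation), 1 (radio-frequency lesion) and 3 (missing data), leaving
    39 enrolled.
    """
    reasons = (
        ["no_surgery"] * n_no_surgery
        + ["unilateral_dbs"] * n_unilateral
        + ["rf_lesion"] * n_lesion
        + ["missing_data"] * n_missing
    )
    if len(reasons) > n_total:
        raise ValueError("more flagged candidates than the pool size")
    reasons += [None] * (n_total - len(reasons))
    rng = np.random.default_rng(seed)
    reasons = list(rng.permutation(np.array(reasons, dtype=object)))
    return [
        SubjectRecord(
            subject_id=f"R{i + 1:03d}",
            cohort="patient",
            target="STN",
            age=float(np.clip(rng.normal(*_PATIENT_AGE), 35.0, 80.0)),
            sex="male" if rng.random() < 0.5 else "female",
            exclusion_reason=reasons[i],
        )
        for i in range(n_total)
    ]


def write_cohort(cohort: Cohort, out_dir: str | Path) -> Path:
    """Write sessions as TSV, clinical + ground truth as CSV, plus a manifest.

    Returns the manifest path.  Session tables have time points as rows and
    atlas labels as columns; motion tables carry the six rigid-body columns.
    """
    out = Path(out_dir)
    (out / "sessions").mkdir(parents=True, exist_ok=True)
    paths: dict[str, str] = {}
    for (sid, sess), ts in sorted(cohort.sessions.items()):
        p = out / "sessions" / f"{sid}_{sess}.tsv"
        pd.DataFrame(ts.values, columns=ts.node_labels).to_csv(
            p, sep="\t", index=False, float_format="%.6f"
        )
        paths[f"session:{sid}:{sess}"] = str(p.relative_to(out))
    for (sid, sess), mt in sorted(cohort.motion.items()):
        p = out / "sessions" / f"{sid}_{sess}_motion.tsv"
        pd.DataFrame(
            mt.params,
            columns=["trans_x", "trans_y", "trans_z", "rot_x", "rot_y", "rot_z"],
        ).to_csv(p, sep="\t", index=False, float_format="%.6f")
        paths[f"motion:{sid}:{sess}"] = str(p.relative_to(out))
    clin = out / "clinical.csv"
    cohort.clinical_frame().to_csv(clin, index=False)
    paths["clinical"] = clin.name
    gt = out / "ground_truth.csv"
    cohort.ground_truth.to_csv(gt, index=False)
    paths["ground_truth"] = gt.name
    manifest = {
        "seed": cohort.config.seed,
        "tr_seconds": cohort.config.tr_seconds,
        "n_timepoints": cohort.config.n_timepoints,
        "node_labels": cohort.network.node_labels,
        "paths": paths,
    }
    mpath = out / "manifest.json"
    mpath.write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return mpath
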