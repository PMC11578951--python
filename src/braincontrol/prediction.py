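"""Epsilon-SVR prediction of percent motor improvement under LOOCV.

Features are per-region delta-controllability values (on − off) for a small
a-priori set per surgical target; each leave-one-subject-out fold
standardizes features *and* the outcome with training-fold statistics only,
fits an epsilon-SVR, and predicts the held-out subject.  Performance is the
Pearson correlation between predicted and actual improvement across folds,
with the p-value from the standard correlation t-test or a
label-permutation null.

Two prediction columns are reported per subject: ``predicted`` is the
model's output mapped back to the percent scale through the training-fold
transform (what a deployed model would emit), and ``score`` is the raw
standardized-space output.  The evaluation correlation uses ``score``:
re-adding the training-fold mean injects a −y_i/(n−1) mean-reversion term
into every LOOCV prediction, which biases the predicted-vs-actual
correlation negative at small n even when the features are pure noise; the
standardized output is free of that artifact.

Hyperparameter defaults follow the LIBSVM convention: RBF kernel, C = 1,
ε = 0.1, γ = 1/n_features.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats
from sklearn.svm import SVR

from .control import DeltaProfile

__all__ = [
    "FeatureSpec",
    "PredictionResult",
    "STN_FEATURES",
    "GPI_FEATURES",
    "assemble_features",
    "svr_loocv",
    "evaluate_prediction",
    "permutation_null",
]

#: a-priori feature sets per surgical target: (structure, hemisphere, metric)
STN_FEATURES: tuple[tuple[str, str, str], ...] = (
    ("Thalamus", "L", "ac"),
    ("Thalamus", "R", "ac"),
)
GPI_FEATURES: tuple[tuple[str, str, str], ...] = (
    ("Postcentral", "L", "ac"),
    ("Postcentral", "R", "ac"),
    ("Postcentral", "L", "mc"),
    ("Caudate", "L", "mc"),
)


@dataclass
class FeatureSpec:
    """Delta-controllability features used for one surgical group."""

    group: str  # STN | GPi
    features: tuple[tuple[str, str, str], ...] = ()

    def __post_init__(self) -> None:
        if not self.features:
            if self.group == "STN":
                self.features = STN_FEATURES
            elif self.group == "GPi":
                self.features = GPI_FEATURES
            else:
                raise ValueError("no features given and group has no default")
        if len(set(self.features)) != len(self.features):
            raise ValueError("duplicate feature triples")

    @property
    def column_names(self) -> list[str]:
        return [f"{s}_{h}_{m}" for s, h, m in self.features]


@dataclass
class PredictionResult:
    """Per-subject LOOCV predictions plus the correlation-based evaluation."""

    table: pd.DataFrame  # subject_id, actual, predicted, score, fold
    r: float
    p: float
    hyperparameters: dict
    seed: int
    X: np.ndarray = field(repr=False, default=None)
    y: np.ndarray = field(repr=False, default=None)

    @property
    def n_subjects(self) -> int:
        return len(self.table)


def assemble_features(
    deltas: dict[str, DeltaProfile],
    improvements: dict[str, float],
    spec: FeatureSpec,
) -> tuple[pd.DataFrame, pd.Series, list[str]]:
    """Build the subject × feature matrix and outcome vector for one group.

    Subjects missing a session (hence a delta profile) or an outcome are
    dropped and listed.  Rows are ordered by subject id.
    """
    subjects = sorted(improvements)
    dropped = [s for s in subjects if s not in deltas]
    used = [s for s in subjects if s in deltas]
    if not used:
        raise ValueError("no subjects with both delta profile and outcome")
    rows = []
    for sid in used:
        prof = deltas[sid]
        rows.append(
            [prof.value(f"{s}_{h}", metric) for s, h, metric in spec.features]
        )
    X = pd.DataFrame(rows, index=used, columns=spec.column_names)
    y = pd.Series([improvements[s] for s in used], index=used, name="improvement")
    return X, y, dropped


def svr_loocv(
    X,
    y,
    kernel: str = "rbf",
    C: float = 1.0,
    epsilon: float = 0.1,
    gamma: float | None = None,
    tol: float = 1e-6,
    seed: int = 0,
) -> PredictionResult:
    """Leave-one-subject-out epsilon-SVR.

    γ defaults to 1/n_features (LIBSVM convention).  Standardization
    statistics for both features and outcome come from the training fold
    only, so no information about the held-out subject leaks into its own
    prediction.  The solver tolerance is tightened well below the library
    default so predictions do not depend on subject ordering.
    """
    ids = list(X.index) if isinstance(X, pd.DataFrame) else [str(i) for i in range(len(X))]
    Xa = np.asarray(X, dtype=float)
    ya = np.asarray(y, dtype=float)
    n = len(ya)
    if n < 5:
        raise ValueError(f"need >= 5 subjects for LOOCV, got {n}")
    if np.ptp(ya) == 0.0:
        raise ValueError("constant outcome: downstream correlation undefined")
    g = 1.0 / Xa.shape[1] if gamma is None else gamma
    scores = np.empty(n)
    preds = np.empty(n)
    for i in range(n):
        train = np.delete(np.arange(n), i)
        mu, sd = Xa[train].mean(axis=0), Xa[train].std(axis=0)
        sd[sd == 0.0] = 1.0
        ym, ys = ya[train].mean(), ya[train].std()
        if ys == 0.0:
            ys = 1.0
        model = SVR(kernel=kernel, C=C, epsilon=epsilon, gamma=g, tol=tol)
        model.fit((Xa[train] - mu) / sd, (ya[train] - ym) / ys)
        scores[i] = model.predict((Xa[[i]] - mu) / sd)[0]
        preds[i] = scores[i] * ys + ym
    hyper = dict(kernel=kernel, C=C, epsilon=epsilon, gamma=g, tol=tol)
    table = pd.DataFrame(
        {
            "subject_id": ids,
            "actual": ya,
            "predicted": preds,
            "score": scores,
            "fold": np.arange(n),
        }
    )
    result = PredictionResult(
        table=table, r=np.nan, p=np.nan, hyperparameters=hyper, seed=seed, X=Xa, y=ya
    )
    result.r, result.p = evaluate_prediction(result)
    return result


def evaluate_prediction(
    result: PredictionResult,
    method: str = "t-test",
    n_perm: int = 1000,
    seed: int = 0,
) -> tuple[float, float]:
    """Pearson r between predicted and actual improvement, with a p-value.

    The correlation uses the fold-standardized model output (see module
    docstring).  ``t-test`` uses the exact null distribution of the
    correlation coefficient (t = r√(n−2)/√(1−r²), df = n−2);
    ``permutation`` refits the whole LOOCV under ``n_perm`` outcome
    permutations and reports the two-sided tail frequency.
    """
    actual = result.table["actual"].to_numpy()
    score = result.table["score"].to_numpy()
    if len(actual) < 5:
        raise ValueError("need >= 5 folds")
    if np.ptp(score) == 0.0:
        raise ValueError("zero variance in predictions: r undefined")
    r, p_t = scipy.stats.pearsonr(score, actual)
    if method == "t-test":
        return float(r), float(p_t)
    if method == "permutation":
        null = permutation_null(
            result.X, result.y, n_perm=n_perm, seed=seed, **result.hyperparameters
        )
        p = (1 + np.sum(np.abs(null) >= abs(r))) / (n_perm + 1)
        return float(r), float(p)
    raise ValueError(f"unknown method {method!r}")


def permutation_null(
    X, y, n_perm: int = 500, seed: int = 0, **hyper
) -> np.ndarray:
    """Null distribution of the LOOCV r under outcome-label permutation."""
    rng = np.random.default_rng(seed)
    ya = np.asarray(y, dtype=float)
    out = np.empty(n_perm)
    for b in range(n_perm):
        perm = rng.permutation(ya)
        res = svr_loocv(X, perm, seed=seed, **hyper)
        out[b] = res.r
    return out
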