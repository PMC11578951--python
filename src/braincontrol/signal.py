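"""ROI time-series cleaning and functional-connectivity estimation.

The temporal pipeline mirrors resting-state convention: linear detrend +
band-pass (0.01–0.08 Hz), nuisance regression (Friston-24 motion expansion
plus any global/tissue signals supplied as confounds), motion scrubbing by
framewise displacement, then pairwise Pearson correlation over the 90 atlas
nodes.  Each step preserves node count and labels.

The default filter is an ideal frequency-domain filter (REST-family
convention); a Butterworth filtfilt alternative is available via
``method="butterworth"``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
import scipy.signal

__all__ = [
    "RoiTimeSeries",
    "ConnectivityMatrix",
    "MotionTrace",
    "ScrubResult",
    "bandpass",
    "friston24",
    "regress_confounds",
    "framewise_displacement",
    "scrub",
    "pearson_fc",
]


@dataclass
class RoiTimeSeries:
    """Time × node signal table for one subject-session.

    values has shape (T, N); node_labels has length N; tr_seconds is the
    sampling interval (repetition time).
    """

    values: np.ndarray
    tr_seconds: float
    node_labels: list[str]
    subject_id: str | None = None
    session: str = "single"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError(f"values must be 2-D, got shape {self.values.shape}")
        if self.values.shape[0] < 2:
            raise ValueError("need at least 2 time points")
        if self.values.shape[1] != len(self.node_labels):
            raise ValueError(
                f"{self.values.shape[1]} columns but {len(self.node_labels)} labels"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValueError("values contain missing or non-finite entries")
        if self.tr_seconds <= 0:
            raise ValueError("tr_seconds must be positive")

    @property
    def n_timepoints(self) -> int:
        return self.values.shape[0]

    @property
    def n_nodes(self) -> int:
        return self.values.shape[1]


@dataclass
class ConnectivityMatrix:
    """Symmetric node × node Pearson correlation matrix, zero diagonal."""

    values: np.ndarray
    node_labels: list[str]
    n_timepoints_used: int = 0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = self.values.shape[0]
        if self.values.shape != (n, n) or n != len(self.node_labels):
            raise ValueError("connectivity matrix / label shape mismatch")
        if np.max(np.abs(self.values - self.values.T)) > 1e-12:
            raise ValueError("connectivity matrix not symmetric within 1e-12")
        if np.any(np.diag(self.values) != 0.0):
            raise ValueError("connectivity diagonal must be exactly 0")
        off = self.values[~np.eye(n, dtype=bool)]
        if off.size and (off.min() < -1 - 1e-12 or off.max() > 1 + 1e-12):
            raise ValueError("off-diagonal correlations outside [-1, 1]")


@dataclass
class MotionTrace:
    """Six rigid-body parameters per frame: 3 translations (mm), 3 rotations (rad)."""

    params: np.ndarray

    def __post_init__(self) -> None:
        self.params = np.asarray(self.params, dtype=float)
        if self.params.ndim != 2 or self.params.shape[1] != 6:
            raise ValueError(f"motion params must be (T, 6), got {self.params.shape}")

    @property
    def n_timepoints(self) -> int:
        return self.params.shape[0]


@dataclass
class ScrubResult:
    ts: RoiTimeSeries
    kept_mask: np.ndarray
    fraction_removed: float
    usable: bool


def bandpass(
    ts: RoiTimeSeries,
    low_hz: float = 0.01,
    high_hz: float = 0.08,
    method: str = "ideal",
) -> RoiTimeSeries:
    """Linear detrend, then band-pass each node signal to [low_hz, high_hz].

    The ideal filter zeroes all DFT bins whose frequency lies outside the
    band (inclusive); output length equals input length.
    """
    nyquist = 1.0 / (2.0 * ts.tr_seconds)
    if not (0 <= low_hz < high_hz):
        raise ValueError(f"need 0 <= low_hz < high_hz, got ({low_hz}, {high_hz})")
    if high_hz > nyquist + 1e-12:
        raise ValueError(
            f"high_hz={high_hz} exceeds Nyquist frequency {nyquist} Hz "
            f"at TR={ts.tr_seconds} s"
        )
    x = scipy.signal.detrend(ts.values, axis=0, type="linear")
    if method == "ideal":
        n = x.shape[0]
        freqs = np.fft.rfftfreq(n, d=ts.tr_seconds)
        keep = (freqs >= low_hz) & (freqs <= high_hz)
        spec = np.fft.rfft(x, axis=0)
        spec[~keep, :] = 0.0
        y = np.fft.irfft(spec, n=n, axis=0)
    elif method == "butterworth":
        sos = scipy.signal.butter(
            4, [low_hz, high_hz], btype="bandpass", fs=1.0 / ts.tr_seconds, output="sos"
        )
        y = scipy.signal.sosfiltfilt(sos, x, axis=0)
    else:
        raise ValueError(f"unknown filter method {method!r}")
    return replace(ts, values=y)


def friston24(motion: MotionTrace) -> np.ndarray:
    """Friston 24-parameter motion expansion.

    Block order: the 6 parameters p, their one-step lags (first row 0),
    their squares p², and the squared lags.
    """
    p = motion.params
    if p.shape[0] < 2:
        raise ValueError("need at least 2 time points")
    lag = np.zeros_like(p)
    lag[1:, :] = p[:-1, :]
    return np.hstack([p, lag, p**2, lag**2])


def regress_confounds(ts: RoiTimeSeries, confounds: np.ndarray) -> RoiTimeSeries:
    """Residualize every node signal against the confound columns.

    An intercept column is always appended internally; linearly dependent
    confound columns are dropped with a warning.  Residuals are orthogonal
    to every retained confound column.
    """
    X = np.asarray(confounds, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if X.shape[0] != ts.n_timepoints:
        raise ValueError(
            f"confounds have {X.shape[0]} rows, time series has {ts.n_timepoints}"
        )
    X = np.hstack([np.ones((X.shape[0], 1)), X])
    if np.linalg.matrix_rank(X) < X.shape[1]:
        # greedy rank filter: keep columns that increase the design rank
        keep: list[int] = []
        rank = 0
        for j in range(X.shape[1]):
            cand = X[:, keep + [j]]
            if np.linalg.matrix_rank(cand) > rank:
                keep.append(j)
                rank += 1
        warnings.warn(
            f"dropping {X.shape[1] - len(keep)} linearly dependent confound column(s)",
            stacklevel=2,
        )
        X = X[:, keep]
    beta, *_ = np.linalg.lstsq(X, ts.values, rcond=None)
    resid = ts.values - X @ beta
    return replace(ts, values=resid)


def framewise_displacement(motion: MotionTrace, head_radius_mm: float = 50.0) -> np.ndarray:
    """Power-style framewise displacement.

    FD_t = Σ|Δ translation| + r·Σ|Δ rotation| with rotations converted to arc
    length at head radius r (default 50 mm); FD_0 = 0 by convention.
    """
    p = motion.params
    if p.shape[0] < 2:
        raise ValueError("need at least 2 time points")
    d = np.abs(np.diff(p, axis=0))
    fd = np.zeros(p.shape[0])
    fd[1:] = d[:, :3].sum(axis=1) + head_radius_mm * d[:, 3:].sum(axis=1)
    return fd


def scrub(
    ts: RoiTimeSeries,
    fd: np.ndarray,
    threshold_mm: float = 0.5,
    remove_following: bool = True,
    max_removed_fraction: float = 0.5,
) -> ScrubResult:
    """Censor high-motion frames.

    Frames with FD > threshold are removed, plus (by default) the frame
    immediately following each, since motion corrupts the subsequent volume
    too.  A session losing more than ``max_removed_fraction`` of its frames
    is flagged unusable.
    """
    fd = np.asarray(fd, dtype=float)
    if fd.shape[0] != ts.n_timepoints:
        raise ValueError("FD length does not match time series")
    bad = fd > threshold_mm
    if remove_following:
        follow = np.zeros_like(bad)
        follow[1:] = bad[:-1]
        bad = bad | follow
    keep = ~bad
    frac = float(bad.mean())
    usable = frac <= max_removed_fraction
    if keep.sum() < 2:  # keep the container valid even for degenerate input
        keep = np.ones_like(keep)
        usable = False
    new_ts = replace(ts, values=ts.values[keep, :])
    return ScrubResult(ts=new_ts, kept_mask=keep, fraction_removed=frac, usable=usable)


def pearson_fc(ts: RoiTimeSeries) -> ConnectivityMatrix:
    """Pairwise Pearson correlation matrix with the diagonal zeroed.

    Zero-variance nodes get zero correlations with a warning rather than
    NaNs, so one flat regressor cannot poison a whole session.
    """
    if ts.n_timepoints < 3:
        raise ValueError("need at least 3 time points for correlation")
    x = ts.values
    sd = x.std(axis=0)
    flat = sd == 0.0
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.corrcoef(x, rowvar=False)
    if flat.any():
        warnings.warn(
            f"{int(flat.sum())} zero-variance node(s); correlations set to 0",
            stacklevel=2,
        )
        r[flat, :] = 0.0
        r[:, flat] = 0.0
    r = np.clip((r + r.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(r, 0.0)
    return ConnectivityMatrix(
        values=r, node_labels=list(ts.node_labels), n_timepoints_used=ts.n_timepoints
    )
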