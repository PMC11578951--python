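"""Linear network-control metrics on functional connectivity.

The brain is modelled as a noise-free discrete-time linear time-invariant
system x_{t+1} = A x_t + B_K u_K(t), where A is the (stabilized) weighted
symmetric adjacency derived from functional connectivity and B_K selects the
control node(s).  Two node-wise diagnostics are computed with every atlas
node serving as a single control point in turn:

* average controllability (AC) — the trace of the infinite-horizon
  controllability Gramian W_K = Σ_τ A^τ B_K B_Kᵀ A^τ.  For symmetric Schur-
  stable A this has the closed form Σ_j v_ij² / (1 − λ_j²) for control node
  i, with (λ_j, v_j) the eigenpairs of A.  High-AC nodes can push the system
  into nearby, easy-to-reach states at low input energy.
* modal controllability (MC) — φ_i = Σ_j (1 − λ_j²) v_ij², which weights the
  node's participation in each eigenmode by how fast that mode decays.
  High-MC nodes preferentially steer the system into fast-decaying,
  hard-to-reach states.

Convergence of the infinite Gramian sum requires spectral radius < 1, which
functional connectivity matrices do not satisfy on their own; `stabilize`
rescales by 1/(1 + σ_max) following the convention of the reference network-
controllability codebase.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "DynamicsMatrix",
    "ControllabilityProfile",
    "DeltaProfile",
    "stabilize",
    "average_controllability",
    "modal_controllability",
    "controllability_profile",
    "delta_profile",
]

_SYM_TOL = 1e-8


@dataclass
class DynamicsMatrix:
    """Stabilized symmetric dynamics matrix with cached eigendecomposition."""

    A: np.ndarray
    eigenvalues: np.ndarray
    eigenvectors: np.ndarray  # columns orthonormal, A = V diag(λ) Vᵀ
    node_labels: list[str] | None = None
    source: str = ""

    @property
    def n_nodes(self) -> int:
        return self.A.shape[0]

    @property
    def spectral_radius(self) -> float:
        return float(np.max(np.abs(self.eigenvalues)))


@dataclass
class ControllabilityProfile:
    """Per-node AC and MC for one subject-session."""

    ac: np.ndarray
    mc: np.ndarray
    node_labels: list[str] | None = None
    subject_id: str | None = None
    session: str = "single"

    def to_frame(self) -> pd.DataFrame:
        from .atlas import split_label

        labels = self.node_labels or [f"node_{i:03d}" for i in range(len(self.ac))]
        try:
            parts = [split_label(lab) for lab in labels]
            regions = [p[0] for p in parts]
            hemis = [p[1] for p in parts]
        except ValueError:
            regions, hemis = labels, [""] * len(labels)
        return pd.DataFrame(
            {"region": regions, "hemisphere": hemis, "ac": self.ac, "mc": self.mc}
        )


@dataclass
class DeltaProfile:
    """Per-node on−off controllability change for one patient."""

    delta_ac: np.ndarray
    delta_mc: np.ndarray
    node_labels: list[str] | None = None
    subject_id: str | None = None

    def value(self, label: str, metric: str) -> float:
        idx = self.node_labels.index(label)
        arr = self.delta_ac if metric == "ac" else self.delta_mc
        return float(arr[idx])


def _as_matrix(fc) -> tuple[np.ndarray, list[str] | None]:
    if hasattr(fc, "values") and hasattr(fc, "node_labels"):
        return np.asarray(fc.values, dtype=float), list(fc.node_labels)
    return np.asarray(fc, dtype=float), None


def stabilize(fc, c: float = 1.0) -> DynamicsMatrix:
    """Rescale a connectivity matrix into a Schur-stable dynamics matrix.

    A = c·C / (1 + σ_max(C)), with σ_max the largest singular value; for
    symmetric C this equals max|eigenvalue|, so the spectral radius of A is
    c·σ_max/(1+σ_max) < 1 whenever c ≤ 1.

    Parameters
    ----------
    fc : ConnectivityMatrix or (n, n) array
        Symmetric matrix with zero diagonal.
    c : float
        Optional extra shrinkage, 0 < c ≤ 1.
    """
    C, labels = _as_matrix(fc)
    if C.ndim != 2 or C.shape[0] != C.shape[1]:
        raise ValueError(f"expected square matrix, got shape {C.shape}")
    if not (0 < c <= 1):
        raise ValueError(f"stabilization constant c={c} outside (0, 1]")
    asym = float(np.max(np.abs(C - C.T))) if C.size else 0.0
    if asym > 1e-6:
        raise ValueError(f"input matrix asymmetric (max |C - Cᵀ| = {asym:.3g})")
    if asym > 0:
        warnings.warn(
            f"symmetrizing numerically asymmetric input (max dev {asym:.3g})",
            stacklevel=2,
        )
        C = (C + C.T) / 2.0
    w, V = np.linalg.eigh(C)
    sigma_max = float(np.max(np.abs(w))) if C.size else 0.0
    scale = c / (1.0 + sigma_max)
    return DynamicsMatrix(
        A=C * scale,
        eigenvalues=w * scale,
        eigenvectors=V,
        node_labels=labels,
        source=f"stabilized c/(1+sigma_max), c={c}, sigma_max={sigma_max:.6g}",
    )


def _check_stable(dyn: DynamicsMatrix) -> None:
    if dyn.spectral_radius >= 1.0:
        raise ValueError(
            f"spectral radius {dyn.spectral_radius:.6g} >= 1: "
            "infinite-horizon Gramian diverges"
        )


def average_controllability(dyn: DynamicsMatrix, node: int) -> float:
    """Trace of the single-node infinite-horizon controllability Gramian.

    Closed form for symmetric stable A: Σ_j v_{node,j}² / (1 − λ_j²).
    Always ≥ 1 because the τ=0 term of the Gramian trace is B_KᵀB_K = 1.
    """
    _check_stable(dyn)
    v_row = dyn.eigenvectors[node, :]
    return float(np.sum(v_row**2 / (1.0 - dyn.eigenvalues**2)))


def modal_controllability(dyn: DynamicsMatrix, node: int) -> float:
    """φ_i = Σ_j (1 − λ_j²) v_ij², in (0, 1] for Schur-stable A."""
    _check_stable(dyn)
    v_row = dyn.eigenvectors[node, :]
    return float(np.sum((1.0 - dyn.eigenvalues**2) * v_row**2))


def controllability_profile(
    dyn: DynamicsMatrix, subject_id: str | None = None, session: str = "single"
) -> ControllabilityProfile:
    """AC and MC for every node, reusing one eigendecomposition."""
    _check_stable(dyn)
    V2 = dyn.eigenvectors**2
    lam2 = dyn.eigenvalues**2
    ac = V2 @ (1.0 / (1.0 - lam2))
    mc = V2 @ (1.0 - lam2)
    return ControllabilityProfile(
        ac=ac, mc=mc, node_labels=dyn.node_labels, subject_id=subject_id, session=session
    )


def delta_profile(on: ControllabilityProfile, off: ControllabilityProfile) -> DeltaProfile:
    """Medication-induced controllability change, fixed sign convention on − off."""
    if on.subject_id != off.subject_id:
        raise ValueError(
            f"subject mismatch: on={on.subject_id!r} vs off={off.subject_id!r}"
        )
    if on.node_labels != off.node_labels:
        raise ValueError("node label mismatch between sessions")
    return DeltaProfile(
        delta_ac=on.ac - off.ac,
        delta_mc=on.mc - off.mc,
        node_labels=on.node_labels,
        subject_id=on.subject_id,
    )
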