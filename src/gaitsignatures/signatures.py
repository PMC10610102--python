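"""From internal-state traces to gait signatures.

A *gait signature* is the phase-averaged trajectory of the dominant principal
components of a trial's internal states: a P x K matrix (uniform phase grid x
components) that represents one canonical cycle of that trial's dynamics and
is the unit of all inter-individual comparison.

Pipeline: a single PCA over the concatenated states of all trials gives a
common basis (global centering, no per-feature scaling — the states share
units); each trial's scores are assigned a continuous phase in [0, 2pi)
estimated from the leading score components; scores are then averaged as a
function of phase with a von Mises kernel.

Phase estimation follows the protophase-then-correction recipe for rhythmic
systems: the analytic-signal angle of each centered score channel gives a
protophase; channels are combined by amplitude-weighted circular averaging;
a Fourier-series correction of the protophase density makes the rotation
rate uniform; and zero phase is anchored at the circular mean of the phases
of the per-cycle maxima of the first principal component, so phases align
across trials sharing a basis.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from typing import Sequence

import h5py
import numpy as np
import pandas as pd
from scipy.signal import hilbert

from .errors import ComparabilityError, InsufficientDataError, ValidationError
from .dynamics import InternalStateTrace, TrainedDynamicsModel
from .io import JointTrial

TWO_PI = 2.0 * np.pi


# --------------------------------------------------------------------------
# common PCA basis
# --------------------------------------------------------------------------

@dataclass
class PCABasis:
    mean: np.ndarray                      # (D,)
    loadings: np.ndarray                  # (D, K_max), orthonormal columns
    explained_variance_ratio: np.ndarray  # (K_max,), nonincreasing
    basis_id: str = ""

    @property
    def k_max(self) -> int:
        return self.loadings.shape[1]


def fit_basis(
    traces: Sequence[InternalStateTrace] | Sequence[np.ndarray], k_max: int
) -> PCABasis:
    """Single PCA over the row-concatenation of all traces.

    Centered by the global mean, no per-feature scaling; loadings signed so
    each column's largest-magnitude entry is positive (reproducibility).
    """
    mats = [t.states if isinstance(t, InternalStateTrace) else np.asarray(t) for t in traces]
    X = np.concatenate(mats, axis=0)
    if X.shape[0] < 2:
        raise ValidationError("need at least 2 total samples to fit a basis")
    mean = X.mean(axis=0)
    Xc = X - mean
    total_var = float(np.sum(Xc**2))
    if total_var == 0.0:
        raise ValidationError("zero-variance input: cannot fit a PCA basis")
    _, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    k = min(k_max, Vt.shape[0])
    loadings = Vt[:k].T
    signs = np.sign(loadings[np.argmax(np.abs(loadings), axis=0), np.arange(k)])
    signs[signs == 0] = 1.0
    loadings = loadings * signs
    ratios = (s[:k] ** 2) / total_var
    basis_id = hashlib.md5(loadings.tobytes() + mean.tobytes()).hexdigest()[:12]
    return PCABasis(mean=mean, loadings=loadings,
                    explained_variance_ratio=ratios, basis_id=basis_id)


def project_states(
    trace: InternalStateTrace | np.ndarray, basis: PCABasis, k: int
) -> np.ndarray:
    """Scores (T' x k) of a trace in the common basis."""
    X = trace.states if isinstance(trace, InternalStateTrace) else np.asarray(trace)
    if X.shape[1] != basis.mean.shape[0]:
        raise ComparabilityError(
            f"trace width {X.shape[1]} != basis dimension {basis.mean.shape[0]}"
        )
    if k > basis.k_max:
        raise ComparabilityError(f"k={k} exceeds basis K_max={basis.k_max}")
    return (X - basis.mean) @ basis.loadings[:, :k]


def reconstruct_states(scores: np.ndarray, basis: PCABasis) -> np.ndarray:
    """Inverse of :func:`project_states` for the leading columns provided."""
    k = scores.shape[1]
    return scores @ basis.loadings[:, :k].T + basis.mean


# --------------------------------------------------------------------------
# phase estimation
# --------------------------------------------------------------------------

@dataclass
class PhaseTrace:
    phase: np.ndarray       # (T',) in [0, 2pi)
    unwrapped: np.ndarray   # (T',) nondecreasing

    @property
    def n_cycles(self) -> float:
        return float(self.unwrapped[-1] - self.unwrapped[0]) / TWO_PI


def _protophase_correction(
    theta: np.ndarray, theta_complete: np.ndarray, n_harmonics: int = 10
) -> np.ndarray:
    """Map a protophase to a uniformly rotating phase via the Fourier series
    of the observed protophase density (phi(theta) = theta +
    sum_n (2/n) Im[S_n (e^{i n theta} - 1)], S_n = <e^{-i n theta}>).

    ``theta_complete`` is the slice spanning whole cycles only, so the S_n
    estimates are not biased by a trailing partial cycle."""
    phi = theta.astype(float).copy()
    for n in range(1, n_harmonics + 1):
        Sn = np.mean(np.exp(-1j * n * theta_complete))
        phi = phi + (2.0 / n) * np.imag(Sn * (np.exp(1j * n * theta) - 1.0))
    return phi


def _analytic_angle(Xc: np.ndarray) -> np.ndarray:
    """Analytic-signal angle with mirror padding to suppress Hilbert
    edge leakage on finite, non-periodic windows."""
    T = Xc.shape[0]
    padded = np.concatenate([Xc[::-1], Xc, Xc[::-1]], axis=0)
    analytic = hilbert(padded, axis=0)[T : 2 * T]
    return np.angle(analytic)


def _repair_edges(proto: np.ndarray) -> np.ndarray:
    """Replace the first/last three-quarter cycle of an unwrapped protophase
    by linear extrapolation from the adjacent 1.5 cycles (the analytic
    signal stalls near the window boundaries, even with mirror padding)."""
    T = proto.size
    slope = (proto[-1] - proto[0]) / max(T - 1, 1)
    if slope <= 0:
        return proto
    k = int(np.ceil(1.5 * np.pi / slope))
    if 3 * k >= T:
        return proto
    out = proto.copy()
    t = np.arange(T, dtype=float)
    head = np.polyfit(t[k : 3 * k], proto[k : 3 * k], 1)
    out[:k] = np.polyval(head, t[:k])
    tail = np.polyfit(t[T - 3 * k : T - k], proto[T - 3 * k : T - k], 1)
    out[T - k :] = np.polyval(tail, t[T - k :])
    return out


def estimate_phase(scores: np.ndarray, n_harmonics: int = 10) -> PhaseTrace:
    """Continuous phase of a quasi-periodic score trajectory (T' x >=3).

    Analytic-signal protophase per channel, amplitude-weighted circular
    combination, Fourier density correction, and zero-phase anchoring at the
    circular mean of per-cycle maxima of the first component.  The unwrapped
    phase is returned nondecreasing regardless of traversal direction.
    """
    X = np.asarray(scores, dtype=float)
    if X.ndim != 2 or X.shape[1] < 3:
        raise ValidationError(f"scores must be T' x >=3, got shape {X.shape}")
    Xc = X - X.mean(axis=0)
    angles = _analytic_angle(Xc)              # (T', K) protophases
    unwrapped = np.unwrap(angles, axis=0)
    slopes = (unwrapped[-1] - unwrapped[0]) / max(len(X) - 1, 1)
    weights = np.sqrt(np.mean(Xc**2, axis=0))
    weights = weights / weights.sum()
    ref_slope = float(np.sum(weights * slopes))
    if ref_slope < 0:  # traverse orientation so phase advances forward
        unwrapped = -unwrapped
        slopes = -slopes
        ref_slope = -ref_slope
    # drop channels rotating at a different harmonic than the consensus
    keep = np.abs(slopes / ref_slope - 1.0) < 0.3 if ref_slope != 0 else slopes == slopes
    if not np.any(keep):
        keep = np.ones_like(slopes, dtype=bool)
    w = weights[keep] / weights[keep].sum()
    aligned = unwrapped[:, keep] - unwrapped[0, keep]
    proto_unwrapped = aligned @ w + float(np.mean(unwrapped[0, keep]))
    proto_unwrapped = _repair_edges(proto_unwrapped)
    if (proto_unwrapped[-1] - proto_unwrapped[0]) < 2 * TWO_PI:
        raise InsufficientDataError(
            "fewer than 2 cycles detected: trajectory is not sufficiently periodic"
        )
    theta = np.mod(proto_unwrapped, TWO_PI)
    # density correction estimated over whole cycles only
    start_cycle = np.ceil(proto_unwrapped[0] / TWO_PI)
    stop_cycle = np.floor(proto_unwrapped[-1] / TWO_PI)
    a, b = np.searchsorted(proto_unwrapped, TWO_PI * np.array([start_cycle, stop_cycle]))
    phi = _protophase_correction(theta, theta[a:b], n_harmonics)
    # rebuild a continuous phase: correction is 2pi-periodic, so apply the
    # same offset per cycle of the protophase
    phi_unwrapped = proto_unwrapped + (phi - theta)
    phi_unwrapped = np.maximum.accumulate(phi_unwrapped)

    # anchor: circular mean of phases at per-cycle maxima of component 1
    anchor = _pc1_max_anchor(X[:, 0], phi_unwrapped)
    phi_unwrapped = phi_unwrapped - anchor
    return PhaseTrace(phase=np.mod(phi_unwrapped, TWO_PI), unwrapped=phi_unwrapped)


def _pc1_max_anchor(pc1: np.ndarray, unwrapped: np.ndarray) -> float:
    start = np.ceil(unwrapped[0] / TWO_PI)
    stop = np.floor(unwrapped[-1] / TWO_PI)
    edges = np.searchsorted(unwrapped, TWO_PI * np.arange(start, stop + 1))
    maxima_phases = []
    bounds = np.concatenate([[0], edges, [len(pc1)]])
    for a, b in zip(bounds[:-1], bounds[1:]):
        if b - a < 3:
            continue
        t = a + int(np.argmax(pc1[a:b]))
        maxima_phases.append(unwrapped[t])
    if not maxima_phases:
        return 0.0
    z = np.mean(np.exp(1j * np.asarray(maxima_phases)))
    return float(np.angle(z))


def circular_rmse(a: np.ndarray, b: np.ndarray, allow_offset: bool = True) -> float:
    """Root-mean-square circular difference between two phase traces, after
    removing the best constant offset when ``allow_offset``."""
    d = np.asarray(a) - np.asarray(b)
    if allow_offset:
        d = d - np.angle(np.mean(np.exp(1j * d)))
    d = np.angle(np.exp(1j * d))
    return float(np.sqrt(np.mean(d**2)))


# --------------------------------------------------------------------------
# von Mises phase averaging
# --------------------------------------------------------------------------

@dataclass
class PhaseAverageConfig:
    grid_size: int = 100     # P frames per cycle
    kappa: float = 50.0      # kernel concentration (angular sd ~ 1/sqrt(kappa))

    @property
    def grid(self) -> np.ndarray:
        return TWO_PI * np.arange(self.grid_size) / self.grid_size


def phase_average(
    series: np.ndarray, phase: PhaseTrace | np.ndarray, cfg: PhaseAverageConfig
) -> np.ndarray:
    """Von Mises kernel average of a T' x K series onto a uniform phase grid:
    out(g, k) = sum_t w_t series(t, k) / sum_t w_t, w_t = exp(kappa cos(phi_t
    - grid_g)).  Weights are computed as exp(kappa (cos - 1)) for overflow
    safety; the normalized average is identical."""
    X = np.atleast_2d(np.asarray(series, dtype=float))
    if X.shape[0] == 1 and X.shape[1] > 1 and np.ndim(series) == 1:
        X = X.T
    phi = phase.phase if isinstance(phase, PhaseTrace) else np.asarray(phase)
    if X.shape[0] != phi.shape[0]:
        raise ValidationError(
            f"series length {X.shape[0]} != phase length {phi.shape[0]}"
        )
    if X.shape[0] == 0:
        raise ValidationError("empty series")
    W = np.exp(cfg.kappa * (np.cos(phi[:, None] - cfg.grid[None, :]) - 1.0))
    denom = W.sum(axis=0)
    if np.any(denom == 0.0):
        g = int(np.argmax(denom == 0.0))
        raise InsufficientDataError(
            f"phase coverage gap near grid point {cfg.grid[g]:.3f} rad: "
            "no samples contribute weight"
        )
    return (W.T @ X) / denom[:, None]


def phase_average_kinematics(
    angles: np.ndarray, cfg: PhaseAverageConfig | None = None
) -> np.ndarray:
    """One canonical cycle (P x J) of raw kinematics, using the same phase
    machinery applied to the kinematics' own leading principal components."""
    cfg = cfg or PhaseAverageConfig()
    basis = fit_basis([np.asarray(angles)], k_max=3)
    scores = project_states(np.asarray(angles), basis, 3)
    phase = estimate_phase(scores)
    return phase_average(np.asarray(angles), phase, cfg)


# --------------------------------------------------------------------------
# gait signatures
# --------------------------------------------------------------------------

@dataclass
class GaitSignature:
    """Phase-averaged principal-component trajectories of one trial."""

    values: np.ndarray                 # (P, K)
    basis_id: str = ""
    subject_id: str = ""
    group: str = ""
    speed: float = float("nan")
    kappa: float = 50.0
    event_phases: dict = field(default_factory=dict)

    @property
    def grid_size(self) -> int:
        return self.values.shape[0]

    @property
    def n_components(self) -> int:
        return self.values.shape[1]

    @property
    def phase_grid(self) -> np.ndarray:
        return TWO_PI * np.arange(self.grid_size) / self.grid_size

    def flatten(self) -> np.ndarray:
        """Column-major flattening (all phases of PC1, then PC2, ...)."""
        return self.values.flatten(order="F")


def compute_signature(
    trial: JointTrial,
    model: TrainedDynamicsModel,
    basis: PCABasis,
    k: int = 6,
    cfg: PhaseAverageConfig | None = None,
) -> GaitSignature:
    """drive -> project -> estimate_phase -> phase_average, with provenance."""
    cfg = cfg or PhaseAverageConfig()
    _, trace = model.drive(trial)
    scores = project_states(trace, basis, max(k, 3))
    phase = estimate_phase(scores[:, :3])
    scores = scores[:, :k]
    values = phase_average(scores, phase, cfg)
    ev = {}
    if trial.events:
        ev = event_phases(trial.events, phase, cfg.grid_size)
    return GaitSignature(
        values=values,
        basis_id=basis.basis_id,
        subject_id=trial.subject_id,
        group=trial.group.value,
        speed=trial.speed,
        kappa=cfg.kappa,
        event_phases=ev,
    )


def compute_cohort_signatures(
    trials: Sequence[JointTrial],
    model: TrainedDynamicsModel,
    k: int = 6,
    k_max: int | None = None,
    cfg: PhaseAverageConfig | None = None,
) -> tuple[list[GaitSignature], PCABasis]:
    """Drive every trial, fit the single common basis, and compute all
    signatures on it."""
    traces = [model.drive(t)[1] for t in trials]
    basis = fit_basis(traces, k_max=k_max or k)
    cfg = cfg or PhaseAverageConfig()
    sigs = []
    for trial, trace in zip(trials, traces):
        scores = project_states(trace, basis, k)
        phase = estimate_phase(scores[:, :3])
        values = phase_average(scores, phase, cfg)
        ev = event_phases(trial.events, phase, cfg.grid_size) if trial.events else {}
        sigs.append(
            GaitSignature(
                values=values,
                basis_id=basis.basis_id,
                subject_id=trial.subject_id,
                group=trial.group.value,
                speed=trial.speed,
                kappa=cfg.kappa,
                event_phases=ev,
            )
        )
    return sigs, basis


# --------------------------------------------------------------------------
# event phases
# --------------------------------------------------------------------------

def event_phases(
    events: Sequence[tuple[int, str]], phase: PhaseTrace, grid_size: int
) -> dict[str, float]:
    """Modal phase-bin center per event label.

    Occurrence phases are binned into ``grid_size`` uniform bins; the modal
    bin's center is returned, ties broken toward the circular mean of the
    occurrences.  Labels with no occurrences are simply absent.
    """
    T = len(phase.phase)
    out: dict[str, float] = {}
    by_label: dict[str, list[float]] = {}
    for sample, label in events:
        idx = min(int(sample), T - 1)
        by_label.setdefault(label, []).append(float(phase.phase[idx]))
    width = TWO_PI / grid_size
    for label, phis in by_label.items():
        bins = (np.asarray(phis) // width).astype(int) % grid_size
        counts = np.bincount(bins, minlength=grid_size)
        best = counts.max()
        tied = np.flatnonzero(counts == best)
        if len(tied) == 1:
            out[label] = float((tied[0] + 0.5) * width)
        else:
            cmean = np.angle(np.mean(np.exp(1j * np.asarray(phis)))) % TWO_PI
            centers = (tied + 0.5) * width
            d = np.abs(np.angle(np.exp(1j * (centers - cmean))))
            out[label] = float(centers[np.argmin(d)])
    return out


# --------------------------------------------------------------------------
# persistence
# --------------------------------------------------------------------------

def save_signature(sig: GaitSignature, path) -> None:
    with h5py.File(path, "w") as f:
        ds = f.create_dataset("signature", data=sig.values)
        f.create_dataset("phase_grid", data=sig.phase_grid)
        ds.attrs["basis_id"] = sig.basis_id
        ds.attrs["subject_id"] = sig.subject_id
        ds.attrs["speed"] = sig.speed
        ds.attrs["kappa"] = sig.kappa


def load_signature(path) -> GaitSignature:
    with h5py.File(path, "r") as f:
        ds = f["signature"]
        return GaitSignature(
            values=ds[...],
            basis_id=str(ds.attrs["basis_id"]),
            subject_id=str(ds.attrs["subject_id"]),
            speed=float(ds.attrs["speed"]),
            kappa=float(ds.attrs["kappa"]),
        )


def signature_to_csv(sig: GaitSignature, path) -> None:
    """Long-format export: columns phase, component, value."""
    P, K = sig.values.shape
    grid = sig.phase_grid
    rows = [
        dict(phase=grid[p], component=k + 1, value=sig.values[p, k])
        for k in range(K)
        for p in range(P)
    ]
    pd.DataFrame(rows).to_csv(path, index=False)
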