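"""Generative uses of the trained dynamics model.

All operations here manipulate phase-averaged principal-component score
trajectories (signatures) on a common phase grid, map them back to the hidden
state block H by inverse PCA, and decode kinematics through the model's
affine output map — one canonical cycle per manipulation:

* isolate a single component's contribution to the kinematics,
* swap components between individuals ("gait sculpting"),
* interpolate signatures of one individual across speeds to predict
  kinematics at an unseen speed, with a direct kinematic-interpolation
  baseline, and
* score any predicted cycle against a reference with the coefficient of
  determination.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .errors import ComparabilityError, ValidationError
from .dynamics import TrainedDynamicsModel
from .io import JointTrial
from .signatures import (
    GaitSignature,
    PCABasis,
    PhaseAverageConfig,
    phase_average,
    phase_average_kinematics,
)


@dataclass
class SculptRequest:
    recipient_id: str
    donor_id: str
    pc_indices: tuple[int, ...]
    grid_size: int = 100


def reconstruct_hidden_from_pcs(
    scores: np.ndarray, basis: PCABasis, keep: Sequence[int]
) -> np.ndarray:
    """Inverse PCA with only the kept components' scores retained (1-based
    indices); other components' scores are zeroed, the global mean is added,
    and the hidden-state block (first U coordinates) is returned."""
    scores = np.asarray(scores, dtype=float)
    K = scores.shape[1]
    keep = sorted(set(int(i) for i in keep))
    if not keep:
        raise ValidationError("keep must name at least one component")
    if any(i < 1 or i > K for i in keep):
        raise ValidationError(f"component indices {keep} outside [1..{K}]")
    kept = np.zeros_like(scores)
    idx = [i - 1 for i in keep]
    kept[:, idx] = scores[:, idx]
    states = kept @ basis.loadings[:, :K].T + basis.mean
    U = basis.mean.shape[0] // 2
    return states[:, :U]


def _decode_scores(
    scores: np.ndarray,
    model: TrainedDynamicsModel,
    basis: PCABasis,
    keep: Sequence[int] | None = None,
) -> np.ndarray:
    K = scores.shape[1]
    H = reconstruct_hidden_from_pcs(scores, basis, keep or range(1, K + 1))
    return model.decode_hidden(H)


def full_reconstruction(
    sig: GaitSignature, model: TrainedDynamicsModel, basis: PCABasis
) -> np.ndarray:
    """Decode a signature's full K-component cycle into P x J kinematics."""
    return _decode_scores(sig.values, model, basis)


def isolate_component_kinematics(
    sig: GaitSignature,
    model: TrainedDynamicsModel,
    basis: PCABasis,
    pc: int,
) -> np.ndarray:
    """Kinematic cycle generated by a single principal component: all other
    components' scores are zeroed before inverse PCA and decoding."""
    return _decode_scores(sig.values, model, basis, keep=[pc])


def sculpt_swap(
    recipient: GaitSignature,
    donor: GaitSignature,
    model: TrainedDynamicsModel,
    basis: PCABasis,
    pc_indices: Sequence[int],
) -> np.ndarray:
    """Replace the recipient's chosen component trajectories with the
    donor's (already phase-aligned on the common grid) and decode the hybrid
    cycle."""
    if recipient.values.shape != donor.values.shape:
        raise ComparabilityError(
            f"signature shapes differ: {recipient.values.shape} vs "
            f"{donor.values.shape}"
        )
    if (
        recipient.basis_id
        and donor.basis_id
        and recipient.basis_id != donor.basis_id
    ):
        raise ComparabilityError(
            f"signatures come from different bases: {recipient.basis_id} vs "
            f"{donor.basis_id}"
        )
    K = recipient.n_components
    pc_indices = sorted(set(int(i) for i in pc_indices))
    if not pc_indices or any(i < 1 or i > K for i in pc_indices):
        raise ValidationError(f"pc_indices {pc_indices} outside [1..{K}]")
    hybrid = recipient.values.copy()
    idx = [i - 1 for i in pc_indices]
    hybrid[:, idx] = donor.values[:, idx]
    return _decode_scores(hybrid, model, basis)


def _check_weights(weights: Sequence[float], n: int) -> np.ndarray:
    w = np.asarray(weights, dtype=float)
    if w.shape != (n,):
        raise ValidationError(f"need {n} weights, got shape {w.shape}")
    if np.any(w < 0):
        raise ValidationError("weights must be nonnegative")
    if abs(w.sum() - 1.0) > 1e-9:
        raise ValidationError(f"weights must sum to 1, got {w.sum()!r}")
    return w


def interpolate_signatures_to_kinematics(
    signatures: Sequence[GaitSignature],
    weights: Sequence[float],
    model: TrainedDynamicsModel,
    basis: PCABasis,
) -> np.ndarray:
    """Convex combination of one subject's signatures at surrounding speeds,
    decoded into a predicted kinematic cycle at the interpolated speed."""
    w = _check_weights(weights, len(signatures))
    for s in signatures[1:]:
        if s.values.shape != signatures[0].values.shape:
            raise ComparabilityError("signatures must share grid and K")
        if s.basis_id != signatures[0].basis_id:
            raise ComparabilityError("signatures must share the PCA basis")
    combined = np.tensordot(w, np.stack([s.values for s in signatures]), axes=1)
    return _decode_scores(combined, model, basis)


def interpolate_kinematics_baseline(
    trials: Sequence[JointTrial],
    weights: Sequence[float],
    cfg: PhaseAverageConfig | None = None,
    phases=None,
) -> np.ndarray:
    """Direct kinematic interpolation baseline: phase-average each trial's
    raw kinematics (same phase machinery) and combine with the weights.

    ``phases`` may supply per-trial :class:`PhaseTrace` objects (e.g. phases
    estimated from the trials' internal states, for anchor consistency with
    the signature route); each trial's trace may be one sample shorter than
    the trial, in which case the trailing kinematic sample is dropped.
    """
    w = _check_weights(weights, len(trials))
    cfg = cfg or PhaseAverageConfig()
    cycles = []
    for i, t in enumerate(trials):
        if phases is not None:
            ph = phases[i]
            n = len(ph.phase)
            cycles.append(phase_average(t.angles[:n], ph, cfg))
        else:
            cycles.append(phase_average_kinematics(t.angles, cfg))
    return np.tensordot(w, np.stack(cycles), axes=1)


def r2_score(
    predicted: np.ndarray, reference: np.ndarray
) -> tuple[np.ndarray, float]:
    """Coefficient of determination per channel and pooled.

    R^2 = 1 - SSE/SST with SST about the reference per-channel mean; may be
    negative; a channel with SST = 0 is reported as NaN and excluded from
    the pooled value's SST only if every channel is degenerate.
    """
    pred = np.asarray(predicted, dtype=float)
    ref = np.asarray(reference, dtype=float)
    if pred.shape != ref.shape:
        raise ComparabilityError(f"shape mismatch: {pred.shape} vs {ref.shape}")
    sse = np.sum((pred - ref) ** 2, axis=0)
    sst = np.sum((ref - ref.mean(axis=0)) ** 2, axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        per_channel = np.where(sst > 0, 1.0 - sse / np.where(sst > 0, sst, 1.0), np.nan)
    total_sst = float(sst.sum())
    pooled = float(1.0 - sse.sum() / total_sst) if total_sst > 0 else float("nan")
    return per_channel, pooled


def speed_interpolation_comparison(
    seed: int,
    duration_s: float = 8.0,
    n_units: int = 48,
    lookback: int = 199,
    max_epochs: int = 250,
    learning_rate: float = 5e-3,
    curvature: float = -0.8,
) -> dict:
    """Signature-space vs direct kinematic interpolation to unseen speeds.

    One synthetic individual walks at six speeds with a nonlinear
    (non-monotonic) amplitude-speed relationship; a model is trained on the
    two slowest and two fastest speeds only, and the two middle speeds are
    predicted by convex combination of the flanking trained speeds — once in
    signature space (combine phase-averaged PC scores, decode), once directly
    on phase-averaged kinematics.  Both predictions are scored against the
    held-out trials' measured cycles by pooled R^2.
    """
    from .dynamics import ModelConfig, Normalize, train_model
    from .signatures import (
        compute_cohort_signatures,
        estimate_phase,
        project_states,
    )
    from .synthetic import SyntheticCohortSpec, generate_cohort

    speeds = (0.6, 0.8, 1.0, 1.2, 1.4, 1.6)
    spec = SyntheticCohortSpec(
        n_individuals=1,
        speeds=speeds,
        duration_s=duration_s,
        amp_speed_slope=0.3,
        amp_speed_curvature=curvature,
        seed=seed,
    )
    trials, _ = generate_cohort(spec)
    train_trials = [trials[i] for i in (0, 1, 4, 5)]
    cfg = ModelConfig(
        n_units=n_units,
        lookback=lookback,
        learning_rate=learning_rate,
        max_epochs=max_epochs,
        convergence_tol=1e-5,
        init_seed=seed,
        normalize=Normalize.ZSCORE,
    )
    model = train_model(train_trials, cfg)
    sigs, basis = compute_cohort_signatures(train_trials, model, k=6)
    pa = PhaseAverageConfig()
    lo_trial, hi_trial = trials[1], trials[4]          # flanking speeds
    lo_sig, hi_sig = sigs[1], sigs[2]
    flank_phases = []
    for t in (lo_trial, hi_trial):
        _, tr = model.drive(t)
        flank_phases.append(estimate_phase(project_states(tr, basis, 3)))

    sig_r2, kin_r2 = [], []
    for h in (2, 3):                                    # held-out middle speeds
        v = speeds[h]
        w_hi = (v - lo_trial.speed) / (hi_trial.speed - lo_trial.speed)
        w = [1.0 - w_hi, w_hi]
        _, tr_h = model.drive(trials[h])
        ph_h = estimate_phase(project_states(tr_h, basis, 3))
        ref = phase_average(trials[h].angles[:-1], ph_h, pa)
        pred_sig = interpolate_signatures_to_kinematics(
            [lo_sig, hi_sig], w, model, basis
        )
        pred_kin = interpolate_kinematics_baseline(
            [lo_trial, hi_trial], w, pa, phases=flank_phases
        )
        sig_r2.append(r2_score(pred_sig, ref)[1])
        kin_r2.append(r2_score(pred_kin, ref)[1])
    return dict(
        signature_r2=float(np.mean(sig_r2)),
        kinematic_r2=float(np.mean(kin_r2)),
        per_speed_signature_r2=[float(x) for x in sig_r2],
        per_speed_kinematic_r2=[float(x) for x in kin_r2],
    )


def cycle_to_time_series(
    cycle: np.ndarray, stride_period_s: float, duration_s: float, sample_rate: float
) -> np.ndarray:
    """Repeat a P x J cycle at a chosen cadence into a time series (movie-style
    output); phase is sampled at the uniform rate 2*pi/stride_period_s."""
    P = cycle.shape[0]
    n = int(round(duration_s * sample_rate))
    t = np.arange(n) / sample_rate
    phase = (2.0 * np.pi * t / stride_period_s) % (2.0 * np.pi)
    pos = phase / (2.0 * np.pi) * P
    i0 = np.floor(pos).astype(int) % P
    i1 = (i0 + 1) % P
    frac = (pos - np.floor(pos))[:, None]
    return cycle[i0] * (1.0 - frac) + cycle[i1] * frac
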