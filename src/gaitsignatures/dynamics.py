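"""Stateful recurrent gait-dynamics model.

The generative engine of the package: a sequence-to-sequence recurrent
network with one hidden layer of U long short-term memory (LSTM) units and an
affine output map, trained to predict joint kinematics one time step ahead
for all trials of a cohort simultaneously (the batch dimension is the trial).
Training is *stateful*: each trial's hidden state is zero-initialized at the
trial start, carried across that trial's consecutive lookback segments within
an epoch, and reset between epochs.  Weights are updated after each training
segment (truncated backpropagation through time over the segment) with Adam
on the mean-squared error in degrees squared.

The per-time-step activation coefficients H and memory cell states C —
2U numbers per step — are the model's internal states; downstream modules
reduce them with a common PCA and phase-average them into gait signatures.

Everything here is plain numpy: forward pass, backpropagation and the Adam
optimizer are written out explicitly, which keeps the model deterministic,
dependency-light and easy to introspect.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path
from typing import Sequence

import h5py
import numpy as np
import pandas as pd

from .errors import (
    ComparabilityError,
    ConfigurationError,
    DivergenceError,
    InsufficientDataError,
    ValidationError,
)
from .io import JointTrial, N_CHANNELS

logger = logging.getLogger(__name__)


# --------------------------------------------------------------------------
# configuration and mini-batch plan
# --------------------------------------------------------------------------

class Normalize(str, Enum):
    NONE = "NONE"
    ZSCORE = "ZSCORE"


@dataclass
class ModelConfig:
    """Hyperparameters of the gait dynamics model.

    ``lookback`` must be one less than a divisor of the common trial length,
    so that segments of length lookback+1 tile each trial exactly.
    """

    n_units: int = 512
    lookback: int = 499
    learning_rate: float = 1e-3
    max_epochs: int = 5000
    convergence_tol: float = 0.03      # deg^2 plateau tolerance
    convergence_window: int = 50       # epochs
    init_seed: int = 0
    normalize: Normalize = Normalize.NONE


class SegmentRole(str, Enum):
    TRAIN = "TRAIN"
    VALIDATION = "VALIDATION"


@dataclass
class Segment:
    index: int
    start: int            # block start sample; block covers [start, start+L+1)
    lookback: int
    role: SegmentRole

    @property
    def input_samples(self) -> np.ndarray:
        return np.arange(self.start, self.start + self.lookback)

    @property
    def target_samples(self) -> np.ndarray:
        return self.input_samples + 1


@dataclass
class MiniBatchPlan:
    """Contiguous blocks of length L+1 tiling each trial, with a one-step
    shift between input and target inside each block.  The same block
    structure applies to every trial of a uniform-length cohort; the last
    segment of each trial is the validation segment when there are >= 2."""

    n_trials: int
    trial_length: int
    lookback: int
    segments: list[Segment]

    @property
    def n_train(self) -> int:
        return sum(1 for s in self.segments if s.role is SegmentRole.TRAIN)

    @property
    def n_validation(self) -> int:
        return sum(1 for s in self.segments if s.role is SegmentRole.VALIDATION)


def valid_lookbacks(trial_length: int) -> list[int]:
    """All lookbacks valid for a trial length: divisors of T, minus one."""
    divs = [d for d in range(2, trial_length + 1) if trial_length % d == 0]
    return [d - 1 for d in divs]


def build_minibatches(
    trials: Sequence[JointTrial] | int, lookback: int
) -> MiniBatchPlan:
    """Tile uniform-length trials into lookback segments.

    ``trials`` may be the trial list or just the common trial length.
    """
    if isinstance(trials, int):
        T, n_trials = trials, 1
    else:
        lengths = {t.n_samples for t in trials}
        if len(lengths) != 1:
            raise ConfigurationError(
                f"trials must share a common length, got lengths {sorted(lengths)}"
            )
        T, n_trials = lengths.pop(), len(trials)
    block = lookback + 1
    if lookback < 1 or T % block != 0:
        raise ConfigurationError(
            f"lookback {lookback} invalid for trial length {T}: lookback+1 must "
            f"divide the trial length; valid lookbacks are {valid_lookbacks(T)}"
        )
    n_seg = T // block
    segments = []
    for s in range(n_seg):
        role = (
            SegmentRole.VALIDATION
            if (s == n_seg - 1 and n_seg >= 2)
            else SegmentRole.TRAIN
        )
        segments.append(Segment(index=s, start=s * block, lookback=lookback, role=role))
    return MiniBatchPlan(
        n_trials=n_trials, trial_length=T, lookback=lookback, segments=segments
    )


# --------------------------------------------------------------------------
# LSTM primitives
# --------------------------------------------------------------------------

def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(x, -60.0, 60.0)))


def _init_weights(n_inputs: int, n_units: int, seed: int) -> dict[str, np.ndarray]:
    """Glorot-style uniform init scaled by fan-in/fan-out; forget bias +1."""
    rng = np.random.default_rng(abs(seed) % (2**31))
    U = n_units

    def glorot(fan_in: int, fan_out: int, shape: tuple[int, ...]) -> np.ndarray:
        limit = np.sqrt(6.0 / (fan_in + fan_out))
        return rng.uniform(-limit, limit, size=shape)

    w = {
        "Wx": glorot(n_inputs, 4 * U, (n_inputs, 4 * U)),
        "Wh": glorot(U, 4 * U, (U, 4 * U)),
        "b": np.zeros(4 * U),
        "Wy": glorot(U, n_inputs, (U, n_inputs)),
        "by": np.zeros(n_inputs),
    }
    w["b"][U : 2 * U] = 1.0  # open the forget gate initially
    return w


def _forward(
    w: dict[str, np.ndarray],
    x: np.ndarray,
    h: np.ndarray,
    c: np.ndarray,
    keep_cache: bool = False,
):
    """Run the LSTM over x (B, L, J) from state (h, c); returns predictions,
    final state, per-step H and C, and (optionally) the BPTT cache."""
    B, L, _ = x.shape
    U = h.shape[1]
    Wx, Wh, b, Wy, by = w["Wx"], w["Wh"], w["b"], w["Wy"], w["by"]
    ys = np.empty((B, L, Wy.shape[1]))
    Hs = np.empty((B, L, U))
    Cs = np.empty((B, L, U))
    cache = [] if keep_cache else None
    for t in range(L):
        xt = x[:, t]
        z = xt @ Wx + h @ Wh + b
        i = _sigmoid(z[:, :U])
        f = _sigmoid(z[:, U : 2 * U])
        g = np.tanh(z[:, 2 * U : 3 * U])
        o = _sigmoid(z[:, 3 * U :])
        c_new = f * c + i * g
        # keep |H| strictly below 1 even when tanh saturates to 1.0 in float
        tc = np.clip(np.tanh(c_new), -1.0 + 1e-12, 1.0 - 1e-12)
        h_new = o * tc
        ys[:, t] = h_new @ Wy + by
        if keep_cache:
            cache.append((xt, h, c, i, f, g, o, tc))
        h, c = h_new, c_new
        Hs[:, t] = h
        Cs[:, t] = c
    return ys, h, c, Hs, Cs, cache


def _backward(
    w: dict[str, np.ndarray],
    cache: list,
    Hs: np.ndarray,
    dys: np.ndarray,
) -> dict[str, np.ndarray]:
    """Backpropagation through one segment (state at segment entry treated as
    constant: truncated BPTT)."""
    Wh, Wy = w["Wh"], w["Wy"]
    U = Wh.shape[0]
    grads = {k: np.zeros_like(v) for k, v in w.items()}
    L = dys.shape[1]
    dh_next = np.zeros((dys.shape[0], U))
    dc_next = np.zeros_like(dh_next)
    for t in range(L - 1, -1, -1):
        xt, h_prev, c_prev, i, f, g, o, tc = cache[t]
        dy = dys[:, t]
        grads["Wy"] += Hs[:, t].T @ dy
        grads["by"] += dy.sum(axis=0)
        dh = dy @ Wy.T + dh_next
        do = dh * tc
        dc = dh * o * (1.0 - tc * tc) + dc_next
        df = dc * c_prev
        di = dc * g
        dg = dc * i
        dc_next = dc * f
        dz = np.concatenate(
            [
                di * i * (1.0 - i),
                df * f * (1.0 - f),
                dg * (1.0 - g * g),
                do * o * (1.0 - o),
            ],
            axis=1,
        )
        grads["Wx"] += xt.T @ dz
        grads["Wh"] += h_prev.T @ dz
        grads["b"] += dz.sum(axis=0)
        dh_next = dz @ Wh.T
    return grads


class _Adam:
    def __init__(self, params: dict[str, np.ndarray], lr: float,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, params: dict[str, np.ndarray], grads: dict[str, np.ndarray]):
        self.t += 1
        for k in params:
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * grads[k]
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * grads[k] ** 2
            mhat = self.m[k] / (1 - self.b1 ** self.t)
            vhat = self.v[k] / (1 - self.b2 ** self.t)
            params[k] -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


# --------------------------------------------------------------------------
# trained model container
# --------------------------------------------------------------------------

@dataclass
class InternalStateTrace:
    """Per-time-step model memory: columns 0..U-1 are activation coefficients
    H, columns U..2U-1 are memory cell states C."""

    states: np.ndarray           # (T', 2U)
    trial_id: str = ""

    @property
    def n_units(self) -> int:
        return self.states.shape[1] // 2

    @property
    def H(self) -> np.ndarray:
        return self.states[:, : self.n_units]

    @property
    def C(self) -> np.ndarray:
        return self.states[:, self.n_units :]


@dataclass
class TrainedDynamicsModel:
    """Recurrent weights, affine output map and training history."""

    weights: dict[str, np.ndarray]
    config: ModelConfig
    history: dict[str, list[float]] = field(
        default_factory=lambda: {"train": [], "val": []}
    )
    norm_mean: np.ndarray | None = None    # ZSCORE stats, in degrees
    norm_sd: np.ndarray | None = None

    # -- normalization helpers -------------------------------------------
    def _to_model(self, angles: np.ndarray) -> np.ndarray:
        if self.config.normalize is Normalize.ZSCORE:
            return (angles - self.norm_mean) / self.norm_sd
        return angles

    def _to_degrees(self, y: np.ndarray) -> np.ndarray:
        if self.config.normalize is Normalize.ZSCORE:
            return y * self.norm_sd + self.norm_mean
        return y

    # -- core operations --------------------------------------------------
    def drive(self, trial: JointTrial | np.ndarray) -> tuple[np.ndarray, InternalStateTrace]:
        """Teacher-forced pass: feed measured kinematics, return one-step
        predictions ((T-1) x J, degrees) and the internal-state trace
        ((T-1) x 2U).  Hidden state is zero-initialized at the trial start."""
        angles = trial.angles if isinstance(trial, JointTrial) else np.asarray(trial)
        if angles.shape[1] != self.weights["Wx"].shape[0]:
            raise ComparabilityError(
                f"trial has {angles.shape[1]} channels, model expects "
                f"{self.weights['Wx'].shape[0]}"
            )
        x = self._to_model(angles)[None, :-1]
        U = self.config.n_units
        h = np.zeros((1, U))
        c = np.zeros((1, U))
        _, _, _, Hs, Cs, _ = _forward(self.weights, x, h, c)
        # decode from the recorded H with the same single matmul as
        # decode_hidden, so the decode identity holds bit-exactly
        preds = self._to_degrees(Hs[0] @ self.weights["Wy"] + self.weights["by"])
        trace = InternalStateTrace(
            states=np.concatenate([Hs[0], Cs[0]], axis=1),
            trial_id=trial.subject_id if isinstance(trial, JointTrial) else "",
        )
        return preds, trace

    def decode_hidden(self, H: np.ndarray) -> np.ndarray:
        """Affine output map applied row-wise to hidden activations H."""
        H = np.asarray(H)
        if H.shape[-1] != self.config.n_units:
            raise ComparabilityError(
                f"H has width {H.shape[-1]}, model has {self.config.n_units} units"
            )
        return self._to_degrees(H @ self.weights["Wy"] + self.weights["by"])

    def rollout(
        self, h0: np.ndarray, c0: np.ndarray, x0: np.ndarray, n_steps: int
    ) -> tuple[np.ndarray, np.ndarray]:
        """Closed-loop generation from an explicit state: consume x0 (degrees),
        then feed each predicted posture back as the next input.  Returns
        (predictions n_steps x J in degrees, states n_steps x 2U)."""
        if n_steps <= 0:
            raise ValueError(f"n_steps must be positive, got {n_steps}")
        U = self.config.n_units
        h = np.asarray(h0, dtype=float).reshape(1, U).copy()
        c = np.asarray(c0, dtype=float).reshape(1, U).copy()
        x = self._to_model(np.asarray(x0, dtype=float)).reshape(1, 1, -1)
        ys = np.empty((n_steps, x.shape[2]))
        states = np.empty((n_steps, 2 * U))
        for t in range(n_steps):
            y, h, c, Hs, Cs, _ = _forward(self.weights, x, h, c)
            ys[t] = y[0, 0]
            states[t] = np.concatenate([Hs[0, 0], Cs[0, 0]])
            x = y.reshape(1, 1, -1)  # feed prediction back as next input
        return self._to_degrees(ys), states

    def self_drive(
        self,
        priming: JointTrial | np.ndarray,
        initial_posture: np.ndarray | None = None,
        n_steps: int = 1500,
        return_states: bool = False,
    ):
        """Prime the hidden state with measured kinematics, then generate
        ``n_steps`` postures closed-loop starting from ``initial_posture``
        (defaults to the last priming sample)."""
        if n_steps <= 0:
            raise ValueError(f"n_steps must be positive, got {n_steps}")
        angles = priming.angles if isinstance(priming, JointTrial) else np.asarray(priming)
        x = self._to_model(angles)[None]
        U = self.config.n_units
        h = np.zeros((1, U))
        c = np.zeros((1, U))
        _, h, c, _, _, _ = _forward(self.weights, x, h, c)
        if initial_posture is None:
            initial_posture = angles[-1]
        ys, states = self.rollout(h[0], c[0], initial_posture, n_steps)
        return (ys, states) if return_states else ys

    # -- persistence -------------------------------------------------------
    def save(self, path: str | Path) -> None:
        with h5py.File(path, "w") as f:
            wg = f.create_group("weights")
            for k, v in self.weights.items():
                wg.create_dataset(k, data=v)
            cfg = {
                k: (v.value if isinstance(v, Enum) else v)
                for k, v in vars(self.config).items()
            }
            f.create_group("config").attrs["json"] = json.dumps(cfg)
            hg = f.create_group("history")
            hg.create_dataset("train", data=np.asarray(self.history["train"]))
            hg.create_dataset("val", data=np.asarray(self.history["val"]))
            if self.norm_mean is not None:
                ng = f.create_group("normalization")
                ng.create_dataset("mean", data=self.norm_mean)
                ng.create_dataset("sd", data=self.norm_sd)

    @classmethod
    def load(cls, path: str | Path) -> "TrainedDynamicsModel":
        with h5py.File(path, "r") as f:
            weights = {k: f["weights"][k][...] for k in f["weights"]}
            cfg = json.loads(f["config"].attrs["json"])
            cfg["normalize"] = Normalize(cfg["normalize"])
            config = ModelConfig(**cfg)
            history = {
                "train": list(f["history"]["train"][...]),
                "val": list(f["history"]["val"][...]),
            }
            norm_mean = norm_sd = None
            if "normalization" in f:
                norm_mean = f["normalization"]["mean"][...]
                norm_sd = f["normalization"]["sd"][...]
        return cls(weights, config, history, norm_mean, norm_sd)


def save_state_trace(trace: InternalStateTrace, path: str | Path) -> None:
    with h5py.File(path, "w") as f:
        ds = f.create_dataset("states", data=trace.states)
        ds.attrs["trial_id"] = trace.trial_id


def load_state_trace(path: str | Path) -> InternalStateTrace:
    with h5py.File(path, "r") as f:
        return InternalStateTrace(
            states=f["states"][...], trial_id=str(f["states"].attrs["trial_id"])
        )


# --------------------------------------------------------------------------
# training
# --------------------------------------------------------------------------

def train_model(
    trials: Sequence[JointTrial], config: ModelConfig
) -> TrainedDynamicsModel:
    """Fit the gait dynamics model on a uniform-length cohort.

    All trials advance together (batch dimension = trials); hidden state is
    carried across each trial's segments within an epoch and reset between
    epochs; Adam updates follow every training segment.  History records the
    per-epoch mean training and validation MSE in degrees squared.  Training
    stops at ``max_epochs`` or when both histories change by less than
    ``convergence_tol`` over a ``convergence_window``-epoch window.
    """
    plan = build_minibatches(trials, config.lookback)
    X = np.stack([np.asarray(t.angles, dtype=float) for t in trials])  # (N,T,J)
    norm_mean = norm_sd = None
    if config.normalize is Normalize.ZSCORE:
        norm_mean = X.mean(axis=(0, 1))
        norm_sd = X.std(axis=(0, 1))
        norm_sd = np.where(norm_sd > 0, norm_sd, 1.0)
        Xn = (X - norm_mean) / norm_sd
        scale2 = norm_sd**2
    else:
        Xn = X
        scale2 = np.ones(X.shape[2])

    w = _init_weights(X.shape[2], config.n_units, config.init_seed)
    adam = _Adam(w, config.learning_rate)
    history: dict[str, list[float]] = {"train": [], "val": []}
    N, U = X.shape[0], config.n_units
    L = config.lookback

    for epoch in range(config.max_epochs):
        h = np.zeros((N, U))
        c = np.zeros((N, U))
        train_losses, val_losses = [], []
        for seg in plan.segments:
            x = Xn[:, seg.start : seg.start + L]
            target = Xn[:, seg.start + 1 : seg.start + L + 1]
            is_train = seg.role is SegmentRole.TRAIN
            ys, h, c, Hs, _, cache = _forward(w, x, h, c, keep_cache=is_train)
            err = ys - target
            mse_deg2 = float(np.mean(err**2 * scale2))
            if is_train:
                dys = 2.0 * err / err.size
                grads = _backward(w, cache, Hs, dys)
                adam.step(w, grads)
                train_losses.append(mse_deg2)
            else:
                val_losses.append(mse_deg2)
        tr = float(np.mean(train_losses))
        va = float(np.mean(val_losses)) if val_losses else tr
        if not (np.isfinite(tr) and np.isfinite(va)):
            raise DivergenceError(
                f"non-finite loss at epoch {epoch} "
                f"(learning_rate={config.learning_rate})"
            )
        history["train"].append(tr)
        history["val"].append(va)
        win = config.convergence_window
        if epoch + 1 >= 2 * win:
            recent_tr = history["train"][-win:]
            recent_va = history["val"][-win:]
            if (
                max(recent_tr) - min(recent_tr) < config.convergence_tol
                and max(recent_va) - min(recent_va) < config.convergence_tol
            ):
                logger.info(
                    "converged at epoch %d (train %.4f, val %.4f deg^2)",
                    epoch, tr, va,
                )
                break
    return TrainedDynamicsModel(
        weights=w,
        config=config,
        history=history,
        norm_mean=norm_mean,
        norm_sd=norm_sd,
    )


# --------------------------------------------------------------------------
# convenience wrappers (functional spelling of the model methods)
# --------------------------------------------------------------------------

def drive(model: TrainedDynamicsModel, trial) -> tuple[np.ndarray, InternalStateTrace]:
    return model.drive(trial)


def decode_hidden(model: TrainedDynamicsModel, H: np.ndarray) -> np.ndarray:
    return model.decode_hidden(H)


def self_drive(model: TrainedDynamicsModel, priming, initial_posture=None,
               n_steps: int = 1500, return_states: bool = False):
    return model.self_drive(priming, initial_posture, n_steps, return_states)


# --------------------------------------------------------------------------
# model-selection scores
# --------------------------------------------------------------------------

def _pooled_r2(pred: np.ndarray, ref: np.ndarray) -> float:
    """R^2 pooled over all columns, SST about per-column reference means."""
    resid = pred - ref
    sse = float(np.sum(resid**2))
    sst = float(np.sum((ref - ref.mean(axis=0)) ** 2))
    if sst == 0.0:
        return 1.0 if sse == 0.0 else -np.inf
    return 1.0 - sse / sst


def _stride_onsets_from_states(trace: InternalStateTrace) -> np.ndarray:
    """Phase-zero crossings of the trace's own leading principal components."""
    from . import signatures as sig

    basis = sig.fit_basis([trace], k_max=3)
    scores = sig.project_states(trace, basis, 3)
    phase = sig.estimate_phase(scores)
    start = np.ceil(phase.unwrapped[0] / (2 * np.pi))
    stop = np.floor(phase.unwrapped[-1] / (2 * np.pi))
    targets = 2 * np.pi * np.arange(start, stop + 1)
    onsets = np.searchsorted(phase.unwrapped, targets)
    return np.unique(onsets[(onsets > 0) & (onsets < len(phase.unwrapped) - 1)])


def short_time_score(
    model,
    trial: JointTrial,
    reference_states: InternalStateTrace | None = None,
    stride_onsets: np.ndarray | None = None,
) -> float:
    """Mean single-stride prediction R^2 on internal states.

    For each stride, the latent state is initialized from the reference trace
    at the stride onset, the model self-drives to the next onset, and the
    simulated states are scored against the reference states over that
    stride; the mean over strides is returned.
    """
    if reference_states is None:
        _, reference_states = model.drive(trial)
    S = reference_states.states
    U = reference_states.n_units
    if stride_onsets is None:
        onsets = [s for s, lab in trial.events if lab == "LHS"]
        if len(onsets) >= 2:
            stride_onsets = np.asarray(onsets)
        else:
            stride_onsets = _stride_onsets_from_states(reference_states)
    stride_onsets = np.asarray(stride_onsets, dtype=int)
    stride_onsets = stride_onsets[(stride_onsets >= 0) & (stride_onsets < len(S) - 1)]
    if len(stride_onsets) < 2:
        raise InsufficientDataError(
            f"need at least 2 stride onsets, got {len(stride_onsets)}"
        )
    angles = trial.angles
    r2s = []
    for t0, t1 in zip(stride_onsets[:-1], stride_onsets[1:]):
        n = int(t1 - t0)
        _, sim = model.rollout(S[t0, :U], S[t0, U:], angles[t0 + 1], n)
        r2s.append(_pooled_r2(sim, S[t0 + 1 : t1 + 1]))
    return float(np.mean(r2s))


def long_time_score(
    model,
    trial: JointTrial,
    reference_states: InternalStateTrace | None = None,
    n_components: int = 6,
    grid_size: int = 100,
    kappa: float = 50.0,
) -> float:
    """Similarity of phase-averaged latent states after a full-trial rollout.

    The model self-drives for the trial length starting from the last
    reference state; reference and simulated state trajectories are projected
    on a common per-trial PCA basis, phase-averaged, and compared by pooled
    R^2.  A simulation whose phase cannot be estimated (e.g. collapse to a
    fixed point) scores -inf.
    """
    from . import signatures as sig

    if reference_states is None:
        _, reference_states = model.drive(trial)
    S = reference_states.states
    U = reference_states.n_units
    T = trial.n_samples
    _, sim = model.rollout(S[-1, :U], S[-1, U:], trial.angles[-1], T)
    cfg = sig.PhaseAverageConfig(grid_size=grid_size, kappa=kappa)
    try:
        basis = sig.fit_basis([reference_states], k_max=n_components)
        ref_scores = sig.project_states(reference_states, basis, n_components)
        sim_scores = sig.project_states(InternalStateTrace(sim), basis, n_components)
        ref_phase = sig.estimate_phase(ref_scores[:, :3])
        sim_phase = sig.estimate_phase(sim_scores[:, :3])
        ref_sig = sig.phase_average(ref_scores, ref_phase, cfg)
        sim_sig = sig.phase_average(sim_scores, sim_phase, cfg)
    except (InsufficientDataError, ValidationError) as exc:
        logger.warning("long-time score: phase estimation failed (%s)", exc)
        return float("-inf")
    return _pooled_r2(sim_sig, ref_sig)


# --------------------------------------------------------------------------
# hyperparameter search and leave-one-subject-out evaluation
# --------------------------------------------------------------------------

def hyperparameter_search(
    trials: Sequence[JointTrial],
    unit_grid: Sequence[int],
    lookback_grid: Sequence[int],
    n_inits: int = 1,
    base_config: ModelConfig | None = None,
) -> pd.DataFrame:
    """Train a model per (units, lookback, init) and tabulate losses and
    short-/long-time scores; summary rows give mean and sd per pair."""
    base = base_config or ModelConfig()
    T = trials[0].n_samples
    bad = [L for L in lookback_grid if T % (L + 1) != 0 or L < 1]
    if bad:
        raise ConfigurationError(
            f"invalid lookbacks {bad} for trial length {T}; "
            f"valid lookbacks are {valid_lookbacks(T)}"
        )
    rows = []
    for units in unit_grid:
        for L in lookback_grid:
            for init in range(n_inits):
                cfg = replace(
                    base, n_units=units, lookback=L, init_seed=base.init_seed + init
                )
                model = train_model(trials, cfg)
                shorts, longs = [], []
                for t in trials:
                    _, ref = model.drive(t)
                    try:
                        shorts.append(short_time_score(model, t, ref))
                    except InsufficientDataError:
                        shorts.append(np.nan)
                    longs.append(long_time_score(model, t, ref))
                rows.append(
                    dict(
                        kind="run",
                        units=units,
                        lookback=L,
                        init=init,
                        train_mse=model.history["train"][-1],
                        val_mse=model.history["val"][-1],
                        short_r2=float(np.nanmean(shorts)),
                        long_r2=float(np.mean(longs)),
                    )
                )
    df = pd.DataFrame(rows)
    summaries = []
    for (units, L), grp in df.groupby(["units", "lookback"], sort=False):
        rec = dict(kind="summary", units=units, lookback=L, init=-1)
        for col in ("train_mse", "val_mse", "short_r2", "long_r2"):
            rec[col] = float(grp[col].mean())
            rec[col + "_sd"] = float(grp[col].std(ddof=0))
        summaries.append(rec)
    return pd.concat([df, pd.DataFrame(summaries)], ignore_index=True)


def loso_evaluate(
    trials: Sequence[JointTrial],
    config: ModelConfig,
    grid_size: int = 100,
    kappa: float = 50.0,
) -> pd.DataFrame:
    """Leave-one-subject-out generalization: one model per held-out subject,
    scored on that subject's trials (held-out loss, externally driven R^2 on
    kinematics, self-driven phase-averaged R^2 on kinematics)."""
    from . import signatures as sig

    subjects = list(dict.fromkeys(t.subject_id for t in trials))
    if len(subjects) < 2:
        raise ConfigurationError("leave-one-subject-out needs at least 2 subjects")
    rows = []
    for held in subjects:
        train_set = [t for t in trials if t.subject_id != held]
        test_set = [t for t in trials if t.subject_id == held]
        model = train_model(train_set, config)
        for t in test_set:
            preds, ref = model.drive(t)
            heldout_mse = float(np.mean((preds - t.angles[1:]) ** 2))
            external_r2 = _pooled_r2(preds, t.angles[1:])
            sd = model.self_drive(t, n_steps=t.n_samples)
            cfg = sig.PhaseAverageConfig(grid_size=grid_size, kappa=kappa)
            try:
                ref_cyc = sig.phase_average_kinematics(t.angles, cfg)
                sd_cyc = sig.phase_average_kinematics(sd, cfg)
                selfdrive_r2 = _pooled_r2(sd_cyc, ref_cyc)
            except InsufficientDataError:
                selfdrive_r2 = float("-inf")
            rows.append(
                dict(
                    held_out_subject=held,
                    speed=t.speed,
                    heldout_mse=heldout_mse,
                    external_r2=external_r2,
                    selfdrive_r2=selfdrive_r2,
                    train_mse=model.history["train"][-1],
                    val_mse=model.history["val"][-1],
                )
            )
    return pd.DataFrame(rows)
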