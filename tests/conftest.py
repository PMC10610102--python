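"""Shared fixtures.

Trained models are expensive, so they are session-scoped and shared across
test modules; sizes are kept small (short trials, few units) while remaining
large enough for the dynamics to be learnable.
"""

from __future__ import annotations

import numpy as np
import pytest

import gaitsignatures as gs
from gaitsignatures.dynamics import ModelConfig, Normalize, TrainedDynamicsModel
from gaitsignatures.dynamics import _init_weights


@pytest.fixture(scope="session")
def noisy_cohort():
    """Small multi-individual cohort with default noise/jitter (no model)."""
    spec = gs.SyntheticCohortSpec(
        n_individuals=2, speeds=(0.8, 1.2), duration_s=6.0, seed=3
    )
    trials, truths = gs.generate_cohort(spec)
    return spec, trials, truths


@pytest.fixture(scope="session")
def clean_bundle():
    """One individual at three speeds, near-noiseless single-harmonic gait,
    plus a model trained to low loss on those trials."""
    spec = gs.SyntheticCohortSpec(
        n_individuals=1,
        speeds=(0.8, 1.0, 1.2),
        duration_s=6.0,
        fourier_order=1,
        noise_sd_deg=0.05,
        period_jitter_cv=0.0,
        seed=11,
    )
    trials, truths = gs.generate_cohort(spec)
    cfg = ModelConfig(
        n_units=48,
        lookback=149,
        learning_rate=5e-3,
        max_epochs=250,
        convergence_tol=1e-5,
        init_seed=11,
        normalize=Normalize.ZSCORE,
    )
    model = gs.train_model(trials, cfg)
    return dict(spec=spec, trials=trials, truths=truths, model=model, config=cfg)


def make_random_model(n_units: int = 8, seed: int = 0, n_inputs: int = 6):
    """Untrained model with seeded random weights (decode/sculpt tests only
    need the affine output map, not a fitted model)."""
    cfg = ModelConfig(n_units=n_units, lookback=1, init_seed=seed)
    return TrainedDynamicsModel(
        weights=_init_weights(n_inputs, n_units, seed), config=cfg
    )


def make_zero_model(n_units: int = 8, n_inputs: int = 6, bias=None):
    cfg = ModelConfig(n_units=n_units, lookback=1)
    w = {k: np.zeros_like(v) for k, v in _init_weights(n_inputs, n_units, 0).items()}
    if bias is not None:
        w["by"] = np.asarray(bias, dtype=float)
    return TrainedDynamicsModel(weights=w, config=cfg)
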