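"""Comparing gait signatures: distances, centroids, MDS maps, dispersion,
normative bands and a cross-validated classifier harness.

All geometry operates on signatures flattened column-major to P*K vectors, so
two signatures are comparable only when they share the phase grid, component
count and PCA basis.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from .errors import ComparabilityError, InsufficientDataError, ValidationError
from .signatures import GaitSignature


def _check_comparable(a: GaitSignature, b: GaitSignature) -> None:
    if a.values.shape != b.values.shape:
        raise ComparabilityError(
            f"signature shapes differ: {a.values.shape} vs {b.values.shape}"
        )
    if a.basis_id and b.basis_id and a.basis_id != b.basis_id:
        raise ComparabilityError(
            f"signatures come from different bases: {a.basis_id} vs {b.basis_id}"
        )


def signature_distance(a: GaitSignature, b: GaitSignature) -> float:
    """Euclidean distance between flattened signatures."""
    _check_comparable(a, b)
    return float(np.linalg.norm(a.flatten() - b.flatten()))


def distance_matrix(signatures: Sequence[GaitSignature]) -> np.ndarray:
    """Symmetric zero-diagonal pairwise distance matrix."""
    X = np.stack([s.flatten() for s in signatures])
    for s in signatures[1:]:
        _check_comparable(signatures[0], s)
    diff = X[:, None, :] - X[None, :, :]
    D = np.sqrt(np.sum(diff**2, axis=2))
    return (D + D.T) / 2.0


@dataclass
class GaitMap:
    trial_ids: list[str]
    distances: np.ndarray
    embedding: np.ndarray
    stress: float


def embed_mds(D: np.ndarray, dim: int = 3) -> tuple[np.ndarray, float]:
    """Classical (Torgerson) MDS: double-center -D^2/2, take the top ``dim``
    positive eigenpairs.  Returns (coordinates n x dim, residual stress).
    If fewer positive eigenvalues exist, the effective dimension is reduced
    (remaining coordinates zero) with a warning."""
    D = np.asarray(D, dtype=float)
    n = D.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (D**2) @ J
    evals, evecs = np.linalg.eigh((B + B.T) / 2.0)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    pos = evals > max(evals.max(), 0) * 1e-12
    n_pos = int(pos.sum())
    eff = min(dim, n_pos)
    if eff < dim:
        import warnings

        warnings.warn(
            f"only {n_pos} positive eigenvalues; embedding dimension reduced "
            f"from {dim} to {eff}",
            stacklevel=2,
        )
    coords = np.zeros((n, dim))
    if eff > 0:
        coords[:, :eff] = evecs[:, :eff] * np.sqrt(evals[:eff])
    diff = coords[:, None, :] - coords[None, :, :]
    D_emb = np.sqrt(np.sum(diff**2, axis=2))
    denom = float(np.sum(D**2))
    stress = float(np.sqrt(np.sum((D - D_emb) ** 2) / denom)) if denom > 0 else 0.0
    return coords, stress


def build_map(signatures: Sequence[GaitSignature], dim: int = 3) -> GaitMap:
    D = distance_matrix(signatures)
    coords, stress = embed_mds(D, dim)
    ids = [f"{s.subject_id}@{s.speed:g}" for s in signatures]
    return GaitMap(trial_ids=ids, distances=D, embedding=coords, stress=stress)


def group_centroid(signatures: Sequence[GaitSignature]) -> np.ndarray:
    """Arithmetic mean of flattened signatures."""
    if len(signatures) == 0:
        raise ValidationError("cannot compute the centroid of an empty group")
    for s in signatures[1:]:
        _check_comparable(signatures[0], s)
    return np.mean([s.flatten() for s in signatures], axis=0)


def distance_to_centroid(sig: GaitSignature, centroid: np.ndarray) -> float:
    v = sig.flatten()
    if v.shape != np.asarray(centroid).shape:
        raise ComparabilityError(
            f"signature vector length {v.shape} != centroid {np.asarray(centroid).shape}"
        )
    return float(np.linalg.norm(v - centroid))


@dataclass
class DispersionResult:
    radii: list[float]
    mean: float
    se: float


def percentile_radius(distances: np.ndarray, q: float = 95.0) -> float:
    """Percentile of member distances by linear order-statistic interpolation."""
    return float(np.percentile(np.asarray(distances, dtype=float), q))


def dispersion_95(
    signatures: Sequence[GaitSignature],
    n_repeats: int = 100,
    seed: int = 0,
    q: float = 95.0,
) -> DispersionResult:
    """Radius of the hypersphere (centered at the group centroid) enclosing
    95% of a group's signatures, with a drop-one resampling spread.

    Per repeat one member is dropped at random (with replacement across
    repeats), the centroid is recomputed from the remainder, and the qth
    percentile of member-to-centroid distances is recorded; mean and standard
    error over repeats are reported.
    """
    if len(signatures) < 3:
        raise InsufficientDataError(
            f"dispersion needs a group of >= 3, got {len(signatures)}"
        )
    X = np.stack([s.flatten() for s in signatures])
    rng = np.random.default_rng(seed)
    radii = []
    for _ in range(n_repeats):
        drop = rng.integers(len(signatures))
        sub = np.delete(X, drop, axis=0)
        centroid = sub.mean(axis=0)
        d = np.linalg.norm(sub - centroid, axis=1)
        radii.append(percentile_radius(d, q))
    radii_arr = np.asarray(radii)
    return DispersionResult(
        radii=[float(r) for r in radii],
        mean=float(radii_arr.mean()),
        se=float(radii_arr.std(ddof=1) / np.sqrt(n_repeats)) if n_repeats > 1 else 0.0,
    )


@dataclass
class ConfidenceBand:
    lower: np.ndarray   # (P, K)
    upper: np.ndarray   # (P, K)
    mean: np.ndarray    # (P, K)
    level: float


def ab_confidence_band(
    signatures: Sequence[GaitSignature], level: float = 0.95
) -> ConfidenceBand:
    """Pointwise normative envelope: mean +/- z * sd across the group at each
    (phase, component)."""
    if len(signatures) < 3:
        raise InsufficientDataError(
            f"confidence band needs >= 3 signatures, got {len(signatures)}"
        )
    for s in signatures[1:]:
        _check_comparable(signatures[0], s)
    stack = np.stack([s.values for s in signatures])
    mu = stack.mean(axis=0)
    sd = stack.std(axis=0, ddof=0)
    z = float(norm.ppf(0.5 + level / 2.0))
    return ConfidenceBand(lower=mu - z * sd, upper=mu + z * sd, mean=mu, level=level)


def out_of_band_fraction(sig: GaitSignature, band: ConfidenceBand) -> np.ndarray:
    """Per-component fraction of phase-grid points outside the band."""
    v = sig.values
    if v.shape != band.mean.shape:
        raise ComparabilityError(
            f"signature shape {v.shape} != band shape {band.mean.shape}"
        )
    outside = (v < band.lower) | (v > band.upper)
    return outside.mean(axis=0)


def classify_cv(
    features: np.ndarray,
    labels: Sequence,
    k_folds: int = 5,
    seed: int = 0,
) -> tuple[float, float]:
    """Linear maximum-margin classification accuracy under stratified k-fold
    cross-validation; returns (mean, sd) of fold accuracies."""
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ValidationError("classification needs at least 2 classes")
    if counts.min() < k_folds:
        raise ValidationError(
            f"stratification impossible: smallest class has {counts.min()} "
            f"members < {k_folds} folds"
        )
    skf = StratifiedKFold(n_splits=k_folds, shuffle=True, random_state=seed)
    accs = []
    for tr, te in skf.split(X, y):
        clf = SVC(kernel="linear", C=1.0)
        clf.fit(X[tr], y[tr])
        accs.append(float(np.mean(clf.predict(X[te]) == y[te])))
    return float(np.mean(accs)), float(np.std(accs, ddof=0))


def map_to_csv(gait_map: GaitMap, signatures: Sequence[GaitSignature], path) -> None:
    rows = []
    for tid, sig, xyz in zip(gait_map.trial_ids, signatures, gait_map.embedding):
        rows.append(
            dict(
                trial_id=tid,
                subject=sig.subject_id,
                group=sig.group,
                speed=sig.speed,
                dim1=xyz[0],
                dim2=xyz[1] if len(xyz) > 1 else 0.0,
                dim3=xyz[2] if len(xyz) > 2 else 0.0,
            )
        )
    pd.DataFrame(rows).to_csv(path, index=False)
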