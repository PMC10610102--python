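"""Reading, validating and writing joint-angle trials and cohort manifests.

A *trial* is one subject x speed treadmill recording: a T x 6 matrix of
sagittal joint angles in degrees, sampled at ``sample_rate`` Hz, with channel
order (paretic hip, paretic knee, paretic ankle, nonparetic hip, nonparetic
knee, nonparetic ankle).  For able-bodied subjects the right leg occupies the
"paretic" slots by convention, so signatures of impaired and unimpaired
individuals stay directly comparable.

On-disk formats are plain CSV:

* trial:    header ``time,phip,pknee,pankle,nphip,npknee,npankle``
* events:   sidecar ``<stem>_events.csv`` with header ``sample,label``
* manifest: CSV with columns
  ``file,subject,group,speed_mps,sample_rate_hz,paretic_side`` (or an
  equivalent YAML list of mappings).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .errors import FormatError, ValidationError

logger = logging.getLogger(__name__)

#: fixed channel order; "p" = paretic side, "np" = nonparetic side
CHANNELS = ("phip", "pknee", "pankle", "nphip", "npknee", "npankle")
N_CHANNELS = len(CHANNELS)

#: gait-event labels: left heel strike, right toe off, right heel strike,
#: left toe off
EVENT_LABELS = ("LHS", "RTO", "RHS", "LTO")


class Group(str, Enum):
    AB = "AB"
    HF_STROKE = "HF_STROKE"
    LF_STROKE = "LF_STROKE"
    UNKNOWN = "UNKNOWN"


class PareticSide(str, Enum):
    LEFT = "LEFT"
    RIGHT = "RIGHT"
    CONVENTION_RIGHT = "CONVENTION_RIGHT"


@dataclass
class JointTrial:
    """One subject x speed trial of bilateral sagittal joint angles."""

    subject_id: str
    group: Group
    speed: float                      # treadmill speed, m/s
    angles: np.ndarray                # (T, 6) degrees
    sample_rate: float = 100.0        # Hz
    events: list[tuple[int, str]] = field(default_factory=list)
    paretic_side: PareticSide = PareticSide.CONVENTION_RIGHT

    @property
    def n_samples(self) -> int:
        return int(self.angles.shape[0])

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.sample_rate

    def events_for(self, label: str) -> np.ndarray:
        return np.array([s for s, lab in self.events if lab == label], dtype=int)

    def copy(self) -> "JointTrial":
        return replace(self, angles=self.angles.copy(), events=list(self.events))


@dataclass
class ManifestEntry:
    file_path: Path
    subject_id: str
    group: Group
    speed: float
    sample_rate: float = 100.0
    paretic_side: PareticSide = PareticSide.CONVENTION_RIGHT


@dataclass
class CohortManifest:
    entries: list[ManifestEntry]


def validate_trial(trial: JointTrial) -> list[str]:
    """Return a list of human-readable invariant violations (empty iff valid)."""
    report: list[str] = []
    a = np.asarray(trial.angles)
    if a.ndim != 2 or a.shape[1] != N_CHANNELS:
        report.append(
            f"angles must be a T x {N_CHANNELS} matrix, got shape {a.shape}"
        )
        return report
    if not np.all(np.isfinite(a)):
        bad = np.argwhere(~np.isfinite(a))[0]
        report.append(f"non-finite angle at row {bad[0]}, column {CHANNELS[bad[1]]}")
    if trial.speed is None or not trial.speed > 0:
        report.append(f"speed must be positive, got {trial.speed}")
    if not trial.sample_rate > 0:
        report.append(f"sample_rate must be positive, got {trial.sample_rate}")
    elif trial.n_samples < 2 * trial.sample_rate:
        report.append(
            f"trial too short: {trial.n_samples} samples "
            f"< 2 s at {trial.sample_rate} Hz"
        )
    per_label: dict[str, int] = {}
    for sample, label in trial.events:
        if label not in EVENT_LABELS:
            report.append(f"unknown event label {label!r}")
            continue
        if not (0 <= sample < trial.n_samples):
            report.append(
                f"event {label}@{sample} outside [0, {trial.n_samples})"
            )
        if label in per_label and sample <= per_label[label]:
            report.append(
                f"event {label}@{sample} not strictly after previous "
                f"{label}@{per_label[label]}"
            )
        per_label[label] = sample
    return report


def _events_path(path: Path) -> Path:
    return path.with_name(path.stem + "_events.csv")


def read_trial_csv(path: str | Path, meta: ManifestEntry) -> JointTrial:
    """Parse a trial CSV (plus events sidecar if present) into a JointTrial."""
    path = Path(path)
    df = pd.read_csv(path)
    expected = ["time", *CHANNELS]
    got = list(df.columns)
    if got != expected:
        missing = [c for c in expected if c not in got]
        extra = [c for c in got if c not in expected]
        raise FormatError(
            f"{path}: expected columns {expected}; "
            f"missing {missing or 'none'}, unexpected {extra or 'none'}"
        )
    body = df[list(CHANNELS)].to_numpy(dtype=float)
    if not np.all(np.isfinite(body)):
        row = int(np.argwhere(~np.isfinite(body))[0, 0])
        raise ValidationError(f"{path}: non-finite angle value at row {row}")

    events: list[tuple[int, str]] = []
    ev_path = _events_path(path)
    if ev_path.exists():
        ev = pd.read_csv(ev_path)
        if list(ev.columns) != ["sample", "label"]:
            raise FormatError(
                f"{ev_path}: expected columns ['sample', 'label'], got {list(ev.columns)}"
            )
        events = [(int(s), str(lab)) for s, lab in zip(ev["sample"], ev["label"])]

    trial = JointTrial(
        subject_id=meta.subject_id,
        group=meta.group,
        speed=meta.speed,
        angles=body,
        sample_rate=meta.sample_rate,
        events=events,
        paretic_side=meta.paretic_side,
    )
    problems = validate_trial(trial)
    if problems:
        raise ValidationError(f"{path}: " + "; ".join(problems))
    return trial


def write_trial_csv(trial: JointTrial, path: str | Path, force: bool = False) -> Path:
    """Write a trial (and events sidecar, if any) to CSV.

    Angles are printed with 17 significant digits so that a write -> read
    round trip reproduces them to well under 1e-9 degrees.
    """
    path = Path(path)
    if path.exists() and not force:
        raise FileExistsError(f"{path} exists; pass force=True to overwrite")
    t = np.arange(trial.n_samples) / trial.sample_rate
    df = pd.DataFrame(
        np.column_stack([t, trial.angles]), columns=["time", *CHANNELS]
    )
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False, float_format="%.17g")
    if trial.events:
        ev = pd.DataFrame(trial.events, columns=["sample", "label"])
        ev.to_csv(_events_path(path), index=False)
    return path


_MANIFEST_COLS = ["file", "subject", "group", "speed_mps", "sample_rate_hz", "paretic_side"]


def _entry_from_record(rec: dict, base: Path) -> ManifestEntry:
    return ManifestEntry(
        file_path=base / str(rec["file"]),
        subject_id=str(rec["subject"]),
        group=Group(str(rec.get("group", "UNKNOWN"))),
        speed=float(rec["speed_mps"]),
        sample_rate=float(rec.get("sample_rate_hz", 100.0)),
        paretic_side=PareticSide(str(rec.get("paretic_side", "CONVENTION_RIGHT"))),
    )


def read_manifest(manifest_path: str | Path) -> CohortManifest:
    """Load a cohort manifest (CSV or YAML); paths resolve relative to it."""
    manifest_path = Path(manifest_path)
    base = manifest_path.parent
    if manifest_path.suffix.lower() in (".yaml", ".yml"):
        with open(manifest_path) as fh:
            records = yaml.safe_load(fh) or []
    else:
        df = pd.read_csv(manifest_path)
        missing = [c for c in ("file", "subject", "speed_mps") if c not in df.columns]
        if missing:
            raise FormatError(f"{manifest_path}: manifest missing columns {missing}")
        records = df.to_dict("records")
    entries = [_entry_from_record(r, base) for r in records]
    seen: set[tuple[str, float]] = set()
    for e in entries:
        key = (e.subject_id, e.speed)
        if key in seen:
            raise ValidationError(
                f"{manifest_path}: duplicate subject/speed pair {key}"
            )
        seen.add(key)
    return CohortManifest(entries=entries)


def read_cohort(
    manifest_path: str | Path, require_uniform: bool = False
) -> list[JointTrial]:
    """Read every trial referenced by a manifest, in manifest order.

    With ``require_uniform=True`` all trials must share length and sample
    rate (the form the dynamics model needs); offenders are named.
    """
    manifest = read_manifest(manifest_path)
    if not manifest.entries:
        logger.warning("manifest %s is empty", manifest_path)
        return []
    trials = []
    for entry in manifest.entries:
        if not Path(entry.file_path).exists():
            raise FileNotFoundError(f"manifest references missing file {entry.file_path}")
        trials.append(read_trial_csv(entry.file_path, entry))
    if require_uniform:
        ref_len, ref_sr = trials[0].n_samples, trials[0].sample_rate
        bad = [
            f"{t.subject_id}@{t.speed}"
            for t in trials
            if t.n_samples != ref_len or t.sample_rate != ref_sr
        ]
        if bad:
            raise ValidationError(
                "cohort not uniform in length/sample_rate; offending trials: "
                + ", ".join(bad)
            )
    return trials


def write_cohort(
    trials: Sequence[JointTrial], out_dir: str | Path, force: bool = False
) -> Path:
    """Write trials plus a ``manifest.csv`` into a directory; returns manifest path."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for i, t in enumerate(trials):
        name = f"{t.subject_id}_v{t.speed:.2f}.csv".replace(" ", "_")
        write_trial_csv(t, out_dir / name, force=force)
        rows.append(
            dict(
                file=name,
                subject=t.subject_id,
                group=t.group.value,
                speed_mps=t.speed,
                sample_rate_hz=t.sample_rate,
                paretic_side=t.paretic_side.value,
            )
        )
    manifest = out_dir / "manifest.csv"
    pd.DataFrame(rows, columns=_MANIFEST_COLS).to_csv(manifest, index=False)
    return manifest
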