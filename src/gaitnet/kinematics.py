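"""Kinematic preprocessing: cohort I/O, zero-phase filtering, magnitudes, IQR features.

The processing order is fixed: low-pass filter each Cartesian axis, then form the
Euclidean magnitude ``m_i(t) = sqrt(x^2 + y^2 + z^2)`` per body segment, derive the
speed ``v_i(t)`` from the filtered axes, and summarise each signal by its
interquartile range (IQR = Q3 - Q1), a dispersion descriptor robust to outliers.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import signal as sps

__all__ = [
    "CANONICAL_SEGMENTS",
    "SegmentRecording",
    "MagnitudeSet",
    "KinematicFeatures",
    "read_cohort",
    "write_cohort",
    "lowpass_zero_phase",
    "magnitude",
    "speed",
    "iqr",
    "extract_features",
    "CohortReadError",
]

#: The 23 tracked body segments: axial chain plus bilateral upper/lower limbs.
CANONICAL_SEGMENTS: tuple[str, ...] = (
    "Pelvis", "L5", "L3", "T12", "T8", "Neck", "Head",
    "Right Shoulder", "Right Upper Arm", "Right Forearm", "Right Hand",
    "Left Shoulder", "Left Upper Arm", "Left Forearm", "Left Hand",
    "Right Upper Leg", "Right Lower Leg", "Right Foot", "Right Toe",
    "Left Upper Leg", "Left Lower Leg", "Left Foot", "Left Toe",
)

#: Columns required in the tidy kinematics CSV.
KINEMATIC_COLUMNS = ("subject", "time", "segment", "x", "y", "z")


class CohortReadError(ValueError):
    """Raised when the tidy kinematics/metadata CSVs violate their schema."""


@dataclass
class SegmentRecording:
    """One subject's labelled 3D position series plus demographics.

    ``series`` maps segment name -> (T, 3) array of positions in metres sampled
    at ``fs`` Hz.  ``clinical`` holds optional severity scores (cases only).
    """

    subject_id: str
    group: str
    age: float
    sex: int
    fs: float
    series: dict[str, np.ndarray]
    clinical: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        lengths = {name: arr.shape[0] for name, arr in self.series.items()}
        if len(set(lengths.values())) > 1:
            raise ValueError(f"segments differ in length: {lengths}")
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        for name, arr in self.series.items():
            if arr.ndim != 2 or arr.shape[1] != 3:
                raise ValueError(f"segment {name!r}: expected (T, 3) array")
            if not np.all(np.isfinite(arr)):
                raise ValueError(f"segment {name!r}: non-finite values")

    @property
    def n_samples(self) -> int:
        return next(iter(self.series.values())).shape[0]


@dataclass
class MagnitudeSet:
    """Per-segment position magnitude and speed signals at a common rate."""

    fs: float
    position: dict[str, np.ndarray]
    speed: dict[str, np.ndarray]


@dataclass
class KinematicFeatures:
    """Per-segment dispersion descriptors of magnitude and speed signals."""

    subject_id: str
    pos_iqr: dict[str, float]
    vel_iqr: dict[str, float]
    pos_mean: dict[str, float] = field(default_factory=dict)
    pos_sd: dict[str, float] = field(default_factory=dict)
    vel_mean: dict[str, float] = field(default_factory=dict)
    vel_sd: dict[str, float] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# signal primitives
# ---------------------------------------------------------------------------

def lowpass_zero_phase(series: np.ndarray, fs: float, cutoff: float = 10.0,
                       order: int = 4) -> np.ndarray:
    """Zero-phase Butterworth low-pass filter applied forward and backward.

    The two-pass application squares the magnitude response and cancels the
    phase, so passband signals keep their timing.  Requires ``fs > 2 * cutoff``
    and enough samples for the odd-extension padding.
    """
    series = np.asarray(series, dtype=float)
    if fs <= 2 * cutoff:
        raise ValueError(f"fs={fs} must exceed twice the cutoff {cutoff}")
    b, a = sps.butter(order, cutoff, btype="low", fs=fs)
    padlen = 3 * max(len(a), len(b))
    if series.shape[0] <= padlen:
        raise ValueError(
            f"signal length {series.shape[0]} too short for zero-phase "
            f"filtering (needs > {padlen} samples)")
    return sps.filtfilt(b, a, series, axis=0)


def magnitude(series: np.ndarray) -> np.ndarray:
    """Euclidean magnitude sqrt(x^2 + y^2 + z^2) of a (T, 3) position series."""
    series = np.asarray(series, dtype=float)
    return np.linalg.norm(series, axis=-1)


def speed(series: np.ndarray, fs: float) -> np.ndarray:
    """Speed |dr/dt| from per-axis derivatives of a (T, 3) position series.

    Central differences in the interior and one-sided differences at the ends;
    differentiating per axis before taking the norm makes the result invariant
    to rotations of the coordinate frame.
    """
    series = np.asarray(series, dtype=float)
    if series.shape[0] < 3:
        raise ValueError("speed needs at least 3 samples")
    deriv = np.gradient(series, 1.0 / fs, axis=0)
    return np.linalg.norm(deriv, axis=-1)


def iqr(samples: np.ndarray) -> float:
    """Interquartile range Q3 - Q1 with linear-interpolation quantiles."""
    samples = np.asarray(samples, dtype=float)
    if samples.size < 4:
        raise ValueError("iqr needs at least 4 samples")
    q1, q3 = np.percentile(samples, [25.0, 75.0], method="linear")
    return float(q3 - q1)


# ---------------------------------------------------------------------------
# cohort-level processing
# ---------------------------------------------------------------------------

def compute_magnitudes(rec: SegmentRecording, cutoff: float = 10.0,
                       order: int = 4) -> MagnitudeSet:
    """Filter each axis, then derive magnitude and speed per segment."""
    pos: dict[str, np.ndarray] = {}
    vel: dict[str, np.ndarray] = {}
    for name, arr in rec.series.items():
        filt = lowpass_zero_phase(arr, rec.fs, cutoff=cutoff, order=order)
        pos[name] = magnitude(filt)
        vel[name] = speed(filt, rec.fs)
    return MagnitudeSet(fs=rec.fs, position=pos, speed=vel)


def extract_features(rec: SegmentRecording, mags: MagnitudeSet | None = None,
                     with_moments: bool = True) -> KinematicFeatures:
    """IQR (and optionally mean/SD) of each segment's magnitude and speed."""
    if mags is None:
        mags = compute_magnitudes(rec)
    feats = KinematicFeatures(subject_id=rec.subject_id, pos_iqr={}, vel_iqr={})
    for name in rec.series:
        m, v = mags.position[name], mags.speed[name]
        feats.pos_iqr[name] = iqr(m)
        feats.vel_iqr[name] = iqr(v)
        if with_moments:
            feats.pos_mean[name] = float(np.mean(m))
            feats.pos_sd[name] = float(np.std(m, ddof=1))
            feats.vel_mean[name] = float(np.mean(v))
            feats.vel_sd[name] = float(np.std(v, ddof=1))
    return feats


# ---------------------------------------------------------------------------
# tidy CSV I/O (schema shared with the synthetic cohort generator)
# ---------------------------------------------------------------------------

_CLINICAL_COLUMNS = (
    "mds_updrs_total", "mds_updrs_iii", "hy_stage", "disease_duration",
    "disease_onset", "bradykinesia_left", "bradykinesia_right",
    "rigidity_left", "rigidity_right", "tremor_left", "tremor_right",
    "total_left", "total_right",
)


def write_cohort(recordings: list[SegmentRecording], kinematics_path: str | Path,
                 metadata_path: str | Path) -> None:
    """Write the tidy kinematics CSV (subject, time, segment, x, y, z) + metadata."""
    frames = []
    meta_rows = []
    for rec in recordings:
        t = np.arange(rec.n_samples) / rec.fs
        for seg, arr in rec.series.items():
            frames.append(pd.DataFrame({
                "subject": rec.subject_id, "time": t, "segment": seg,
                "x": arr[:, 0], "y": arr[:, 1], "z": arr[:, 2],
            }))
        row: dict[str, object] = {
            "subject": rec.subject_id, "group": rec.group,
            "age": rec.age, "sex": rec.sex, "fs": rec.fs,
        }
        for col in _CLINICAL_COLUMNS:
            row[col] = rec.clinical.get(col, np.nan)
        meta_rows.append(row)
    pd.concat(frames, ignore_index=True).to_csv(kinematics_path, index=False,
                                                float_format="%.9g")
    pd.DataFrame(meta_rows).to_csv(metadata_path, index=False, float_format="%.9g")


def read_cohort(kinematics_path: str | Path,
                metadata_path: str | Path) -> list[SegmentRecording]:
    """Read a cohort from the tidy kinematics CSV and its metadata table.

    Validates segment names against :data:`CANONICAL_SEGMENTS`, rejects
    duplicate (subject, time, segment) rows, and requires every subject in the
    kinematics file to appear in the metadata (and vice versa).
    """
    kin = pd.read_csv(kinematics_path)
    missing_cols = set(KINEMATIC_COLUMNS) - set(kin.columns)
    if missing_cols:
        raise CohortReadError(
            f"kinematics file missing columns: {sorted(missing_cols)}")
    unknown = set(kin["segment"].unique()) - set(CANONICAL_SEGMENTS)
    if unknown:
        raise CohortReadError(
            f"unknown segment names: {sorted(map(repr, unknown))}")
    dups = kin.duplicated(subset=["subject", "time", "segment"])
    if dups.any():
        first = kin.loc[dups.idxmax()]
        raise CohortReadError(
            "duplicate (subject, time, segment) rows, first at subject="
            f"{first['subject']!r} time={first['time']} segment={first['segment']!r}")

    meta = pd.read_csv(metadata_path)
    for col in ("subject", "group", "age", "sex", "fs"):
        if col not in meta.columns:
            raise CohortReadError(f"metadata file missing column: {col!r}")
    meta = meta.set_index("subject")
    kin_subjects = list(dict.fromkeys(kin["subject"]))
    missing_meta = [s for s in kin_subjects if s not in meta.index]
    if missing_meta:
        raise CohortReadError(f"subjects missing from metadata: {missing_meta}")
    extra_meta = [s for s in meta.index if s not in set(kin_subjects)]
    if extra_meta:
        raise CohortReadError(f"metadata subjects missing kinematics: {extra_meta}")

    recordings = []
    for subj, sub in kin.groupby("subject", sort=False):
        row = meta.loc[subj]
        series: dict[str, np.ndarray] = {}
        for seg, segdf in sub.groupby("segment", sort=False):
            segdf = segdf.sort_values("time")
            series[str(seg)] = segdf[["x", "y", "z"]].to_numpy(dtype=float)
        clinical = {c: float(row[c]) for c in _CLINICAL_COLUMNS
                    if c in row.index and pd.notna(row[c])}
        recordings.append(SegmentRecording(
            subject_id=str(subj), group=str(row["group"]),
            age=float(row["age"]), sex=int(row["sex"]), fs=float(row["fs"]),
            series=series, clinical=clinical))
    return recordings
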