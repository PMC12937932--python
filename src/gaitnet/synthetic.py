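"""Synthetic gait cohort generator with controllable Parkinsonian-like effects.

Each body segment's 3D position is modelled as a segment-specific anatomical
offset plus a gait oscillator (1 Hz fundamental with two harmonics,
segment-specific amplitude and phase, left/right limbs in anti-phase), shared
latent oscillators that implement inter-segment coupling, white sensor noise,
and an optional random-walk postural drift.  Group differences are injected
through an :class:`EffectSpec`, each field of which moves one feature family:

* ``distal_speed_scale`` (< 1) shrinks the oscillation amplitude of feet, toes
  and hands in the affected group — a bradykinesia-like reduction of distal
  speed.
* ``positional_drift_sd`` adds a whole-body random-walk drift — postural
  variability, inflating position IQRs.
* ``proximal_coupling_gain`` strengthens a shared trunk/head latent oscillator
  — more centralized proximal coupling, raising trunk/head adjacency weights.
* ``interlimb_decoupling`` weakens the arm-leg shared-phase component —
  loss of interlimb coordination, lowering arm-leg adjacency weights.

Every affected subject carries a latent severity (mean 1) that modulates the
effect magnitude and generates correlated clinical scores; with every effect
at zero the two groups' signals are exchangeable in distribution.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .kinematics import CANONICAL_SEGMENTS, SegmentRecording

__all__ = ["EffectSpec", "CohortSpec", "generate_cohort", "generate_clinical_scores",
           "DISTAL_SEGMENTS", "PROXIMAL_SEGMENTS", "ARM_SEGMENTS", "LEG_SEGMENTS"]


class ConfigurationError(ValueError):
    """Invalid cohort or effect specification."""


DISTAL_SEGMENTS = frozenset({
    "Right Foot", "Right Toe", "Left Foot", "Left Toe",
    "Right Hand", "Left Hand",
})
PROXIMAL_SEGMENTS = frozenset({
    "Pelvis", "L5", "L3", "T12", "T8", "Neck", "Head",
    "Right Shoulder", "Left Shoulder",
})
ARM_SEGMENTS = frozenset({
    "Right Upper Arm", "Right Forearm", "Right Hand",
    "Left Upper Arm", "Left Forearm", "Left Hand",
})
LEG_SEGMENTS = frozenset({
    "Right Upper Leg", "Right Lower Leg", "Right Foot", "Right Toe",
    "Left Upper Leg", "Left Lower Leg", "Left Foot", "Left Toe",
})

# Offset directions (x forward, y lateral, z up).  Directions follow rough
# anatomy; norms are set separately and closely spaced so that the magnitude
# distributions of different segments overlap and the similarity weights span
# the threshold window instead of collapsing to 0 or 1.
_DIRECTIONS: dict[str, tuple[float, float, float]] = {
    "Pelvis": (0.0, 0.0, 1.00), "L5": (0.0, 0.0, 1.10), "L3": (0.0, 0.0, 1.20),
    "T12": (0.0, 0.0, 1.30), "T8": (0.0, 0.0, 1.40), "Neck": (0.0, 0.0, 1.55),
    "Head": (0.0, 0.0, 1.70),
    "Right Shoulder": (0.0, -0.20, 1.50), "Left Shoulder": (0.0, 0.20, 1.50),
    "Right Upper Arm": (0.0, -0.25, 1.35), "Left Upper Arm": (0.0, 0.25, 1.35),
    "Right Forearm": (0.05, -0.28, 1.10), "Left Forearm": (0.05, 0.28, 1.10),
    "Right Hand": (0.10, -0.30, 0.95), "Left Hand": (0.10, 0.30, 0.95),
    "Right Upper Leg": (0.0, -0.10, 0.75), "Left Upper Leg": (0.0, 0.10, 0.75),
    "Right Lower Leg": (0.05, -0.10, 0.40), "Left Lower Leg": (0.05, 0.10, 0.40),
    "Right Foot": (0.10, -0.10, 0.08), "Left Foot": (0.10, 0.10, 0.08),
    "Right Toe": (0.20, -0.10, 0.04), "Left Toe": (0.20, 0.10, 0.04),
}

# Offset norms (metres): 4 mm steps along the canonical order.
_RADII: dict[str, float] = {
    seg: 1.0 + 0.004 * k for k, seg in enumerate(CANONICAL_SEGMENTS)
}

_OFFSETS: dict[str, np.ndarray] = {
    seg: _RADII[seg] * np.asarray(d) / np.linalg.norm(d)
    for seg, d in _DIRECTIONS.items()
}

# Baseline oscillation amplitudes (metres) by segment.
_AMPLITUDES: dict[str, float] = {
    "Pelvis": 0.025, "L5": 0.025, "L3": 0.028, "T12": 0.030, "T8": 0.030,
    "Neck": 0.025, "Head": 0.025,
    "Right Shoulder": 0.030, "Left Shoulder": 0.030,
    "Right Upper Arm": 0.045, "Left Upper Arm": 0.045,
    "Right Forearm": 0.070, "Left Forearm": 0.070,
    "Right Hand": 0.100, "Left Hand": 0.100,
    "Right Upper Leg": 0.055, "Left Upper Leg": 0.055,
    "Right Lower Leg": 0.085, "Left Lower Leg": 0.085,
    "Right Foot": 0.120, "Left Foot": 0.120,
    "Right Toe": 0.140, "Left Toe": 0.140,
}

_GAIT_F0 = 1.0          # stride fundamental, Hz
_HARMONIC_WEIGHTS = (1.0, 0.35, 0.15)
_AXIS_WEIGHTS = np.array([0.80, 0.25, 0.40])   # forward / lateral / vertical mix
_SENSOR_NOISE_SD = 0.004                        # metres, per axis
_TRUNK_LATENT_AMPLITUDE = 0.012
_INTERLIMB_LATENT_AMPLITUDE = 0.030

# Affected/control group labels and Table-style demographic anchors.
GROUP_CASE = "PD"
GROUP_CONTROL = "HC"
_AGE_CASE = (69.6, 8.67)
_AGE_CONTROL = (51.3, 17.03)
_MALE_FRACTION_CASE = 37 / 51
_MALE_FRACTION_CONTROL = 19 / 53


@dataclass(frozen=True)
class EffectSpec:
    """Magnitudes of the group-difference mechanisms (all >= 0; 0 = no effect)."""

    distal_speed_scale: float = 1.0
    positional_drift_sd: float = 0.0
    proximal_coupling_gain: float = 0.0
    interlimb_decoupling: float = 0.0
    severity_noise_sd: float = 0.25

    def __post_init__(self) -> None:
        for name in ("distal_speed_scale", "positional_drift_sd",
                     "proximal_coupling_gain", "interlimb_decoupling",
                     "severity_noise_sd"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0")

    @property
    def is_null(self) -> bool:
        """True when every group-difference mechanism is switched off."""
        return (self.distal_speed_scale == 1.0 and self.positional_drift_sd == 0.0
                and self.proximal_coupling_gain == 0.0
                and self.interlimb_decoupling == 0.0)

    @classmethod
    def null(cls) -> "EffectSpec":
        return cls()

    @classmethod
    def reference(cls) -> "EffectSpec":
        """Moderate disease-like condition: 40% distal slowing, mild postural
        drift, moderate proximal coupling gain."""
        return cls(distal_speed_scale=0.6, positional_drift_sd=0.01,
                   proximal_coupling_gain=0.5)


@dataclass(frozen=True)
class CohortSpec:
    """Size and sampling parameters of a synthetic cohort."""

    n_group_a: int = 25
    n_group_b: int = 25
    n_segments: int = 23
    fs: float = 100.0
    duration: float = 15.0
    effect: EffectSpec = field(default_factory=EffectSpec)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_group_a < 1 or self.n_group_b < 1:
            raise ConfigurationError("group sizes must be >= 1")
        if not 2 <= self.n_segments <= len(CANONICAL_SEGMENTS):
            raise ConfigurationError(
                f"n_segments must be in [2, {len(CANONICAL_SEGMENTS)}]")
        if self.fs <= 20.0:
            raise ConfigurationError("fs must exceed 20 Hz (2x the 10 Hz cutoff)")
        if self.duration * self.fs < 256:
            raise ConfigurationError("duration x fs must be >= 256 samples")

    @property
    def segments(self) -> tuple[str, ...]:
        return CANONICAL_SEGMENTS[: self.n_segments]


def _simulate_subject(rng: np.random.Generator, segments: Sequence[str],
                      fs: float, duration: float, effect: EffectSpec,
                      severity: float, affected: bool) -> dict[str, np.ndarray]:
    n = int(round(duration * fs))
    t = np.arange(n) / fs
    # subject-level gait cadence and latent phases
    f0 = _GAIT_F0 * rng.uniform(0.9, 1.1)
    trunk_phase = rng.uniform(0, 2 * np.pi)
    interlimb_phase = rng.uniform(0, 2 * np.pi)

    # latent frequencies are non-harmonic multiples of the cadence so their
    # variance adds incoherently to the segment's own gait harmonics
    trunk_latent = np.sin(2 * np.pi * 1.37 * f0 * t + trunk_phase)
    interlimb_latent = np.sin(2 * np.pi * 0.63 * f0 * t + interlimb_phase)

    if affected and effect.positional_drift_sd > 0:
        step_sd = effect.positional_drift_sd * severity / np.sqrt(fs)
        drift = np.cumsum(rng.normal(0.0, step_sd, size=(n, 3)), axis=0)
    else:
        drift = np.zeros((n, 3))

    series: dict[str, np.ndarray] = {}
    for seg in segments:
        amp = _AMPLITUDES[seg]
        f_seg = f0
        if affected and seg in DISTAL_SEGMENTS:
            # bradykinesia-like distal slowing: the oscillation is stretched
            # in time, which scales speed down while leaving the position
            # amplitude distribution (the network substrate) unchanged;
            # mild severity modulation preserves a clinical correlation
            f_seg = f0 * effect.distal_speed_scale ** (0.5 + 0.5 * severity)
        phase = np.pi if seg.startswith("Left") else 0.0
        phase += rng.normal(0.0, 0.15)
        osc = np.zeros(n)
        for k, w in enumerate(_HARMONIC_WEIGHTS, start=1):
            osc += w * np.sin(2 * np.pi * k * f_seg * t + k * phase)
        sig = amp * osc[:, None] * _AXIS_WEIGHTS[None, :]

        trunk_w = 1.0
        if affected and seg in PROXIMAL_SEGMENTS:
            trunk_w += effect.proximal_coupling_gain * severity
        if seg in PROXIMAL_SEGMENTS:
            sig += _TRUNK_LATENT_AMPLITUDE * trunk_w * trunk_latent[:, None] \
                * _AXIS_WEIGHTS[None, :]

        if seg in ARM_SEGMENTS or seg in LEG_SEGMENTS:
            w = 1.0
            # decoupling suppresses the coupled oscillation on the arm side
            # only (reduced arm swing), so arm and leg amplitude
            # distributions drift apart
            if affected and seg in ARM_SEGMENTS:
                w = max(0.0, 1.0 - effect.interlimb_decoupling * severity)
            sig += _INTERLIMB_LATENT_AMPLITUDE * w * interlimb_latent[:, None] \
                * _AXIS_WEIGHTS[None, :]

        sig += rng.normal(0.0, _SENSOR_NOISE_SD, size=(n, 3))
        sig += drift
        sig += np.asarray(_OFFSETS[seg])
        series[seg] = sig
    return series


def generate_clinical_scores(latent_severity: np.ndarray, spec: EffectSpec,
                             rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Clinical score table as monotone affine functions of latent severity.

    Score anchors are chosen so that a severity of 1 reproduces typical
    moderate-stage values (MDS-UPDRS total ~30, H-Y ~1.5).  Noise of standard
    deviation ``spec.severity_noise_sd`` is added to the severity seen by each
    score column independently, then scores are clipped to plausible ranges.
    """
    latent_severity = np.asarray(latent_severity, dtype=float)
    if not np.all(np.isfinite(latent_severity)):
        raise ConfigurationError("latent severity must be finite")
    if rng is None:
        rng = np.random.default_rng(0)
    anchors = {
        "mds_updrs_total": (29.9, 0.0, 132.0),
        "mds_updrs_iii": (17.0, 0.0, 132.0),
        "hy_stage": (1.54, 0.0, 5.0),
        "disease_duration": (7.6, 0.0, 40.0),
        "disease_onset": (62.0, 18.0, 95.0),
        "bradykinesia_left": (2.91, 0.0, 44.0),
        "bradykinesia_right": (3.08, 0.0, 44.0),
        "rigidity_left": (0.94, 0.0, 20.0),
        "rigidity_right": (1.13, 0.0, 20.0),
        "tremor_left": (0.61, 0.0, 40.0),
        "tremor_right": (0.74, 0.0, 40.0),
        "total_left": (4.46, 0.0, 60.0),
        "total_right": (4.95, 0.0, 60.0),
    }
    out: dict[str, np.ndarray] = {}
    for col, (coeff, lo, hi) in anchors.items():
        noisy = latent_severity + rng.normal(0.0, spec.severity_noise_sd,
                                             size=latent_severity.shape)
        out[col] = np.clip(coeff * noisy, lo, hi)
    return pd.DataFrame(out)


def generate_cohort(spec: CohortSpec) -> tuple[list[SegmentRecording], pd.DataFrame]:
    """Simulate a two-group cohort; deterministic for a fixed spec (incl. seed).

    Returns the list of :class:`SegmentRecording` (group A = affected cases
    first, then controls) and the cohort metadata table (group, age, sex,
    clinical scores for cases).
    """
    rng = np.random.default_rng(spec.seed)
    segments = spec.segments

    n_a, n_b = spec.n_group_a, spec.n_group_b
    severity_a = np.clip(rng.normal(1.0, 0.35, size=n_a), 0.2, 2.0)

    ages_a = np.clip(rng.normal(*_AGE_CASE, size=n_a), 18, 95)
    ages_b = np.clip(rng.normal(*_AGE_CONTROL, size=n_b), 18, 95)
    sex_a = (rng.random(n_a) < _MALE_FRACTION_CASE).astype(int)
    sex_b = (rng.random(n_b) < _MALE_FRACTION_CONTROL).astype(int)

    scores_a = generate_clinical_scores(severity_a, spec.effect, rng)

    recordings: list[SegmentRecording] = []
    meta_rows: list[dict[str, object]] = []
    for i in range(n_a + n_b):
        affected = i < n_a
        if affected:
            subj, group = f"PD{i + 1:03d}", GROUP_CASE
            age, sex, sev = float(ages_a[i]), int(sex_a[i]), float(severity_a[i])
            clinical = {c: float(scores_a.iloc[i][c]) for c in scores_a.columns}
        else:
            j = i - n_a
            subj, group = f"HC{j + 1:03d}", GROUP_CONTROL
            age, sex, sev = float(ages_b[j]), int(sex_b[j]), 0.0
            clinical = {}
        series = _simulate_subject(rng, segments, spec.fs, spec.duration,
                                   spec.effect, sev, affected)
        recordings.append(SegmentRecording(
            subject_id=subj, group=group, age=age, sex=sex, fs=spec.fs,
            series=series, clinical=clinical))
        row: dict[str, object] = {"subject": subj, "group": group, "age": age,
                                  "sex": sex, "fs": spec.fs}
        row.update(clinical)
        meta_rows.append(row)
    metadata = pd.DataFrame(meta_rows)
    return recordings, metadata
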