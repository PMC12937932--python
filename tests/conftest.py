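"""Shared fixtures: small deterministic recordings and cohorts."""

from __future__ import annotations

import numpy as np
import pytest

from gaitnet.kinematics import SegmentRecording
from gaitnet.synthetic import CohortSpec, EffectSpec, generate_cohort


def make_recording(subject_id: str = "S1", group: str = "HC", *,
                   n: int = 400, fs: float = 100.0, seed: int = 0,
                   segments: tuple[str, ...] = ("Pelvis", "Head", "Left Foot"),
                   age: float = 50.0, sex: int = 0,
                   clinical: dict | None = None) -> SegmentRecording:
    """A small hand-built recording with sinusoid-plus-noise segments."""
    rng = np.random.default_rng(seed)
    t = np.arange(n) / fs
    series = {}
    for k, seg in enumerate(segments):
        base = 1.0 + 0.05 * k
        sig = np.stack([
            base + 0.05 * np.sin(2 * np.pi * (1.0 + 0.1 * k) * t),
            0.03 * np.cos(2 * np.pi * 1.3 * t + k),
            base + 0.02 * np.sin(2 * np.pi * 0.7 * t + 2 * k),
        ], axis=1)
        sig += rng.normal(0, 0.002, size=sig.shape)
        series[seg] = sig
    return SegmentRecording(subject_id=subject_id, group=group, age=age,
                            sex=sex, fs=fs, series=series,
                            clinical=clinical or {})


@pytest.fixture(scope="session")
def tiny_null_cohort():
    """4+4 subjects, 6 segments, no group effect; used across modules."""
    spec = CohortSpec(n_group_a=4, n_group_b=4, n_segments=6, fs=60.0,
                      duration=5.0, effect=EffectSpec.null(), seed=11)
    return generate_cohort(spec)
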