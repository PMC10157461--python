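"""Shared fixtures: small deterministic recordings, windows and the
study-scale synthetic cohort runs (computed once per session)."""

import numpy as np
import pytest

from tremorglyc import (AccelRecording, TREMOR_AMP_HIGH, TremorModelSpec,
                        Window, attach_magnitude, make_windows, run_study)

#: the study-scale experiment: 12 subjects, 3 days each, LOSO CV
STUDY_KW = dict(n_subjects=12, days=3.0, seed=1, scheme="loso")


@pytest.fixture(scope="session")
def study_high():
    """LOSO study at the high-separability tremor amplitude."""
    return run_study(tremor=TremorModelSpec(tremor_amp_hypo=TREMOR_AMP_HIGH),
                     **STUDY_KW)


@pytest.fixture(scope="session")
def study_high_permuted():
    """The same study under the label-permutation null."""
    return run_study(tremor=TremorModelSpec(tremor_amp_hypo=TREMOR_AMP_HIGH),
                     permute_labels=True, **STUDY_KW)


@pytest.fixture(scope="session")
def study_moderate():
    """LOSO study at the default (moderate, Bayes-error ~0.15) amplitude."""
    return run_study(**STUDY_KW)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


def make_recording(xyz: np.ndarray, rate: float = 64.0,
                   subject_id: str = "T01",
                   t: np.ndarray | None = None) -> AccelRecording:
    """Recording from a raw (n, 3) array on a regular time grid."""
    xyz = np.asarray(xyz, dtype=float)
    if t is None:
        t = np.arange(xyz.shape[0]) / rate
    return AccelRecording(subject_id, t, xyz, rate)


def tone_recording(freq: float, duration: float, rate: float = 64.0,
                   amplitude: float = 1.0) -> AccelRecording:
    """A pure sinusoid on the x axis (y, z zero)."""
    t = np.arange(int(round(duration * rate))) / rate
    xyz = np.zeros((t.size, 3))
    xyz[:, 0] = amplitude * np.sin(2 * np.pi * freq * t)
    return make_recording(xyz, rate)


def window_from_channels(x, y=None, z=None, mag=None, rate: float = 64.0) -> Window:
    """Build a Window directly from channel arrays (defaults: zeros)."""
    x = np.asarray(x, dtype=float)
    n = x.size
    y = np.zeros(n) if y is None else np.asarray(y, dtype=float)
    z = np.zeros(n) if z is None else np.asarray(z, dtype=float)
    if mag is None:
        mag = np.sqrt(x ** 2 + y ** 2 + z ** 2)
    samples = np.column_stack([x, y, z, np.asarray(mag, dtype=float)])
    return Window("T01", 0.0, samples, rate)


@pytest.fixture
def windows_of():
    """Factory: windows of a gap-free zero recording of given duration."""
    def _build(duration: float, rate: float = 64.0):
        n = int(round(duration * rate))
        rec = make_recording(np.zeros((n, 3)), rate)
        return make_windows(attach_magnitude(rec))
    return _build
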