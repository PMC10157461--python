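"""Raw accelerometer conditioning: low-pass filtering, magnitude, windowing.

The wrist stream is nominally 64 Hz triaxial acceleration in units of g.
Wear gaps (the watch off the wrist) appear as missing rows; every operation
here is gap-aware: filtering runs independently per contiguous segment and
windows never span a gap.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal

log = logging.getLogger(__name__)

#: standard gravity, m/s^2 per g — used when readers convert SI input
G_MS2 = 9.80665

ACCEL_CSV_COLUMNS = ("timestamp", "x_g", "y_g", "z_g")

#: ISO origin used when serialising second-based cohort time to timestamps
TIME_ORIGIN = "2024-01-01T00:00:00"


# ---------------------------------------------------------------------------
# recordings
# ---------------------------------------------------------------------------

@dataclass
class AccelRecording:
    """A subject's timestamped triaxial acceleration stream.

    Parameters
    ----------
    subject_id : str
        Stable subject identifier.
    t : ndarray of float
        Sample times in seconds, strictly increasing.  Gaps (spacing much
        larger than ``1/rate``) mark unworn periods.
    xyz : ndarray, shape (n, 3)
        Acceleration along x, y, z in g.
    rate : float
        Nominal sampling rate in Hz.
    mag : ndarray or None
        Per-sample magnitude, attached by :func:`attach_magnitude`.
    """

    subject_id: str
    t: np.ndarray
    xyz: np.ndarray
    rate: float
    mag: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.xyz = np.asarray(self.xyz, dtype=float)
        if self.xyz.ndim != 2 or self.xyz.shape[1] != 3:
            raise ValueError("xyz must have shape (n, 3)")
        if self.t.shape[0] != self.xyz.shape[0]:
            raise ValueError("timestamps and channels must have equal length")
        if self.t.size > 1 and not np.all(np.diff(self.t) > 0):
            raise ValueError("timestamps must be strictly increasing")
        if not self.rate > 0:
            raise ValueError("sampling rate must be positive")
        if self.mag is not None:
            self.mag = np.asarray(self.mag, dtype=float)
            if self.mag.shape[0] != self.t.shape[0]:
                raise ValueError("magnitude length mismatch")

    def __len__(self) -> int:
        return self.t.shape[0]

    @property
    def nyquist(self) -> float:
        return self.rate / 2.0


def segment_slices(t: np.ndarray, rate: float, gap_factor: float = 2.0) -> list[slice]:
    """Split a timestamp vector into contiguous (gap-free) slices.

    A new segment starts wherever the inter-sample interval exceeds
    ``gap_factor / rate`` — tolerant of jitter, but split at wear gaps.
    """
    n = len(t)
    if n == 0:
        return []
    breaks = np.flatnonzero(np.diff(t) > gap_factor / rate) + 1
    bounds = np.concatenate([[0], breaks, [n]])
    return [slice(int(a), int(b)) for a, b in zip(bounds[:-1], bounds[1:])]


# ---------------------------------------------------------------------------
# filtering and magnitude
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FilterSpec:
    """Low-pass filter applied to each axis before windowing.

    Defaults: second-order Butterworth, 30 Hz cutoff.  At a 64 Hz sampling
    rate that cutoff sits at 93.75% of Nyquist — legal, but nearly
    degenerate; the constructor only rejects cutoffs at or above Nyquist.
    ``zero_phase=False`` applies the filter causally (single forward pass),
    matching a real-time deployment; set True for forward-backward filtering.
    """

    order: int = 2
    cutoff: float = 30.0
    zero_phase: bool = False

    def __post_init__(self) -> None:
        if self.order < 1:
            raise ValueError("filter order must be >= 1")
        if not self.cutoff > 0:
            raise ValueError("cutoff must be positive")


def butterworth_lowpass(recording: AccelRecording, spec: FilterSpec | None = None) -> AccelRecording:
    """Low-pass filter each axis independently, per contiguous segment.

    Output length equals input length and the DC gain is exactly 1.
    Raises ``ValueError`` if the cutoff is at or above the recording's
    Nyquist frequency.
    """
    spec = spec or FilterSpec()
    if spec.cutoff >= recording.nyquist:
        raise ValueError(
            f"cutoff {spec.cutoff} Hz >= Nyquist {recording.nyquist} Hz "
            f"of a {recording.rate} Hz recording"
        )
    if len(recording) == 0:
        return AccelRecording(recording.subject_id, recording.t.copy(),
                              recording.xyz.copy(), recording.rate)
    sos = signal.butter(spec.order, spec.cutoff, btype="low", fs=recording.rate,
                        output="sos")
    out = np.empty_like(recording.xyz)
    for sl in segment_slices(recording.t, recording.rate):
        seg = recording.xyz[sl]
        if spec.zero_phase and seg.shape[0] > 3 * spec.order * 2:
            out[sl] = signal.sosfiltfilt(sos, seg, axis=0)
        else:
            # seed the filter state at the segment's first sample so short
            # segments and DC inputs are not distorted by a zero-state start
            zi = signal.sosfilt_zi(sos)
            for c in range(3):
                out[sl, c], _ = signal.sosfilt(sos, seg[:, c], zi=zi * seg[0, c])
    return AccelRecording(recording.subject_id, recording.t.copy(), out,
                          recording.rate)


def magnitude(recording: AccelRecording) -> np.ndarray:
    """Per-sample Euclidean magnitude sqrt(x^2 + y^2 + z^2), in g."""
    return np.sqrt(np.sum(recording.xyz ** 2, axis=1))


def attach_magnitude(recording: AccelRecording) -> AccelRecording:
    """Return the recording with the magnitude channel attached."""
    return AccelRecording(recording.subject_id, recording.t, recording.xyz,
                          recording.rate, mag=magnitude(recording))


# ---------------------------------------------------------------------------
# windowing
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class WindowSpec:
    """Sliding-window geometry: 3-second windows with 50% overlap."""

    length: float = 3.0
    overlap: float = 0.5

    def __post_init__(self) -> None:
        if not self.length > 0:
            raise ValueError("window length must be positive")
        if not 0 <= self.overlap < 1:
            raise ValueError("overlap must be in [0, 1)")

    @property
    def hop(self) -> float:
        """Hop between window starts, seconds."""
        return self.length * (1.0 - self.overlap)

    def n_samples(self, rate: float) -> int:
        return int(round(self.length * rate))

    def hop_samples(self, rate: float) -> int:
        h = int(round(self.hop * rate))
        if h < 1:
            raise ValueError("hop shorter than one sample at this rate")
        return h


@dataclass
class Window:
    """One fixed-length acceleration segment with channels x, y, z, magnitude."""

    subject_id: str
    start_time: float
    samples: np.ndarray  # shape (n_samples, 4)
    rate: float

    def channel(self, name: str) -> np.ndarray:
        from .features import CHANNELS  # local import to avoid a cycle
        return self.samples[:, CHANNELS.index(name)]


@dataclass
class WindowSet:
    """All windows of one recording, stored without duplicating samples.

    Window payloads are materialised lazily through :meth:`samples` /
    :meth:`window`, because study-scale streams yield hundreds of thousands
    of windows of which only a subsample is ever featurised.
    """

    subject_id: str
    rate: float
    spec: WindowSpec
    starts: np.ndarray                      # (n,) window start times, seconds
    _segments: list[np.ndarray] = field(repr=False, default_factory=list)
    _seg_index: np.ndarray = field(repr=False, default=None)
    _offsets: np.ndarray = field(repr=False, default=None)

    def __len__(self) -> int:
        return int(self.starts.shape[0])

    @property
    def n_samples(self) -> int:
        return self.spec.n_samples(self.rate)

    @property
    def hop_seconds(self) -> float:
        return self.spec.hop_samples(self.rate) / self.rate

    @property
    def centers(self) -> np.ndarray:
        return self.starts + self.spec.length / 2.0

    def samples(self, indices: np.ndarray | None = None) -> np.ndarray:
        """Materialise window payloads, shape (k, n_samples, 4)."""
        if indices is None:
            indices = np.arange(len(self))
        indices = np.asarray(indices, dtype=int)
        n = self.n_samples
        out = np.empty((indices.shape[0], n, 4))
        for j, i in enumerate(indices):
            seg = self._segments[self._seg_index[i]]
            off = self._offsets[i]
            out[j] = seg[off:off + n]
        return out

    def window(self, i: int) -> Window:
        return Window(self.subject_id, float(self.starts[i]),
                      self.samples(np.array([i]))[0], self.rate)

    def __iter__(self):
        for i in range(len(self)):
            yield self.window(i)


def make_windows(recording: AccelRecording, spec: WindowSpec | None = None) -> WindowSet:
    """Cut a (filtered) recording into fixed windows with 50% overlap.

    Windows are emitted only inside contiguous segments; any leftover
    samples at a segment end that cannot fill a whole window are dropped.
    A recording shorter than one window yields an empty set.
    """
    spec = spec or WindowSpec()
    n = spec.n_samples(recording.rate)
    hop = spec.hop_samples(recording.rate)
    mag = recording.mag if recording.mag is not None else magnitude(recording)

    segments: list[np.ndarray] = []
    seg_index: list[np.ndarray] = []
    offsets: list[np.ndarray] = []
    starts: list[np.ndarray] = []
    for sl in segment_slices(recording.t, recording.rate):
        m = sl.stop - sl.start
        if m < n:
            continue
        count = (m - n) // hop + 1
        seg = np.column_stack([recording.xyz[sl], mag[sl]])
        offs = np.arange(count) * hop
        segments.append(seg)
        seg_index.append(np.full(count, len(segments) - 1))
        offsets.append(offs)
        starts.append(recording.t[sl.start] + offs / recording.rate)

    if not segments:
        return WindowSet(recording.subject_id, recording.rate, spec,
                         np.empty(0), [], np.empty(0, int), np.empty(0, int))
    return WindowSet(
        recording.subject_id, recording.rate, spec,
        np.concatenate(starts),
        segments,
        np.concatenate(seg_index).astype(int),
        np.concatenate(offsets).astype(int),
    )


def expected_window_count(duration: float, spec: WindowSpec | None = None) -> int:
    """Window count for a contiguous segment of ``duration`` seconds.

    ``floor((T - length)/hop) + 1`` for T >= length, else 0.  A 60-second
    segment therefore holds 39 three-second windows at 50% overlap, a 30-
    second segment 19, and a 15-second segment 9.
    """
    spec = spec or WindowSpec()
    if duration < spec.length:
        return 0
    return int(np.floor((duration - spec.length) / spec.hop + 1e-9)) + 1


def coverage_minutes(n_windows: int, spec: WindowSpec | None = None) -> float:
    """Minutes of stream accounted for by ``n_windows`` half-overlapping
    windows: each window past the first contributes one hop of fresh signal,
    so at scale the total is ``n_windows * hop`` seconds."""
    spec = spec or WindowSpec()
    return n_windows * spec.hop / 60.0


# ---------------------------------------------------------------------------
# CSV reader (dialect written by tremorglyc.synthetic)
# ---------------------------------------------------------------------------

def read_accel_csv(path, subject_id: str | None = None, unit: str = "g",
                   rate: float | None = None) -> AccelRecording:
    """Read an accelerometer CSV (columns timestamp, x_g, y_g, z_g).

    Malformed rows (unparseable timestamps or non-numeric values) are
    dropped with a logged count.  ``unit='ms2'`` converts m/s^2 input to g.
    The sampling rate is inferred from the median inter-sample interval
    unless given.
    """
    df = pd.read_csv(path)
    missing = [c for c in ACCEL_CSV_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"accelerometer CSV missing columns: {missing}")
    ts = pd.to_datetime(df["timestamp"], errors="coerce", format="ISO8601")
    vals = df[["x_g", "y_g", "z_g"]].apply(pd.to_numeric, errors="coerce")
    ok = ts.notna() & vals.notna().all(axis=1)
    n_bad = int((~ok).sum())
    if n_bad:
        log.warning("%s: dropped %d malformed row(s)", path, n_bad)
    ts, vals = ts[ok], vals[ok]
    t = ts.astype("int64").to_numpy() / 1e9
    xyz = vals.to_numpy(dtype=float)
    if unit == "ms2":
        xyz = xyz / G_MS2
    elif unit != "g":
        raise ValueError(f"unknown acceleration unit {unit!r}")
    if rate is None:
        if len(t) < 2:
            raise ValueError("cannot infer sampling rate from < 2 samples")
        rate = 1.0 / float(np.median(np.diff(t)))
    sid = subject_id if subject_id is not None else str(path)
    return AccelRecording(sid, t, xyz, rate)
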