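"""Synthetic cohort generator: paired wrist-accelerometer and CGM streams.

The study regime this emulates: adults with type 1 diabetes wearing a watch
intermittently (~40% of the day) and a CGM sampling every 5 minutes, with on
average about one hypoglycemic event per day lasting tens of minutes.  A
4-14 Hz tremor component in the acceleration grows in amplitude during
hypoglycemia; everything downstream (windowing, band-power features,
classifiers, subject-aware cross-validation) is exercised against the known
ground-truth event log.

Signal model, per worn block:

    a(t) = g_vec + motion(t) + tremor(t) + noise(t)

* ``g_vec`` — a unit gravity vector, randomly tilted per block (a resting
  wrist reports magnitude ~1 g);
* ``motion`` — band-limited (< 4 Hz) Gaussian motion, the voluntary
  component;
* ``tremor`` — narrow-band filtered white noise centred near 8 Hz with a
  slow log-normal amplitude modulation, at RMS amplitude
  ``tremor_amp_hypo`` inside true hypoglycemic intervals and
  ``tremor_amp_normal`` outside;
* ``noise`` — white sensor noise.

Blood glucose between events follows a mean-reverting (OU) process around
the baseline, clipped to plausible physiology; during an event it ramps to
a nadir below 70 mg/dL and is strictly < 70 mg/dL throughout, so the event
log is the exact ground truth.  Events arrive as a Poisson process with
log-normal durations.  All randomness flows from one root seed through
per-subject substreams.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal

from .preprocess import AccelRecording, TIME_ORIGIN

log = logging.getLogger(__name__)

DAY_S = 86_400.0


# ---------------------------------------------------------------------------
# specs
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CohortSpec:
    """Cohort geometry: how many subjects, for how long, at what rates."""

    n_subjects: int = 12
    days_per_subject: float = 3.0
    accel_rate: float = 64.0
    cgm_interval: float = 300.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        if not self.accel_rate > 0:
            raise ValueError("accel_rate must be positive")
        if not self.cgm_interval > 0:
            raise ValueError("cgm_interval must be positive")
        if not self.days_per_subject > 0:
            raise ValueError("days_per_subject must be positive")


@dataclass(frozen=True)
class GlycemicModelSpec:
    """Blood-glucose dynamics and hypoglycemic event regime.

    Defaults reflect the study regime being emulated: baseline glucose in
    the nonhypoglycemic band, 1.06 events/day, mean event duration 27.31
    minutes.  ``event_duration_sd`` is a free parameter (minutes).
    ``hypo_depth`` sets the nadir at ``70 - hypo_depth`` mg/dL.
    """

    baseline_bg: float = 110.0
    bg_sd: float = 10.0
    mean_events_per_day: float = 1.06
    mean_event_duration: float = 27.31
    event_duration_sd: float = 15.0
    hypo_depth: float = 15.0
    mean_reversion_minutes: float = 30.0

    def __post_init__(self) -> None:
        if not 90.0 < self.baseline_bg < 140.0:
            raise ValueError("baseline_bg must lie in (90, 140) mg/dL")
        if self.mean_events_per_day < 0:
            raise ValueError("mean_events_per_day must be >= 0")
        if not self.mean_event_duration > 0:
            raise ValueError("mean_event_duration must be positive")


@dataclass(frozen=True)
class TremorModelSpec:
    """Tremor, motion and wear-time model for the accelerometer stream.

    Amplitudes are RMS accelerations in g of the full tremor vector.
    ``wear_fraction`` is the proportion of each day the watch is worn;
    unworn periods are emitted as gaps (missing rows) in contiguous blocks.
    """

    band_low: float = 4.0
    band_high: float = 14.0
    tremor_amp_hypo: float = 0.018
    tremor_amp_normal: float = 0.005
    motion_amp: float = 0.05
    noise_sd: float = 0.01
    wear_fraction: float = 0.4
    #: carrier band of the synthesised tremor (noise-like, centred ~8 Hz)
    carrier_low: float = 6.0
    carrier_high: float = 10.0
    #: log-amplitude SD of the slow (< 0.05 Hz) tremor modulation
    mod_sd: float = 0.35
    #: log-amplitude SD of the very slow (< 0.02 Hz) activity modulation of
    #: the voluntary-motion component: wrists alternate between rest and
    #: activity, and activity leaks broadband power into the tremor band
    motion_mod_sd: float = 0.5

    def __post_init__(self) -> None:
        if not 0 < self.band_low < self.band_high:
            raise ValueError("need 0 < band_low < band_high")
        if not (self.tremor_amp_hypo >= self.tremor_amp_normal >= 0):
            raise ValueError("need tremor_amp_hypo >= tremor_amp_normal >= 0")
        if not 0 < self.wear_fraction <= 1:
            raise ValueError("wear_fraction must be in (0, 1]")


@dataclass
class GroundTruthLog:
    """Per-subject hypoglycemic intervals, seconds from stream start."""

    subject_id: str
    events: list[tuple[float, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.events = [(float(a), float(b)) for a, b in self.events]
        for a, b in self.events:
            if not b > a:
                raise ValueError("event end must exceed start")
        for (_, b0), (a1, _) in zip(self.events[:-1], self.events[1:]):
            if a1 < b0:
                raise ValueError("events must be non-overlapping and sorted")

    def in_event(self, t: np.ndarray) -> np.ndarray:
        """Boolean mask: which times fall inside a ground-truth event."""
        t = np.asarray(t, dtype=float)
        mask = np.zeros(t.shape, dtype=bool)
        for a, b in self.events:
            mask |= (t >= a) & (t < b)
        return mask

    @property
    def n_events(self) -> int:
        return len(self.events)


@dataclass
class CgmTrace:
    """A subject's CGM readings: time in seconds, glucose in mg/dL."""

    subject_id: str
    t: np.ndarray
    bg: np.ndarray

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.bg = np.asarray(self.bg, dtype=float)
        if self.t.shape != self.bg.shape:
            raise ValueError("t and bg must have equal length")
        if self.t.size > 1 and not np.all(np.diff(self.t) > 0):
            raise ValueError("timestamps must be strictly increasing")
        if self.t.size and not np.all(self.bg > 0):
            raise ValueError("bg must be positive")


@dataclass
class SubjectRecord:
    """One subject's paired streams plus ground truth."""

    subject_id: str
    accel: AccelRecording
    cgm: CgmTrace
    truth: GroundTruthLog


# ---------------------------------------------------------------------------
# blood glucose + events
# ---------------------------------------------------------------------------

def _draw_events(rng: np.random.Generator, duration_s: float,
                 rate_per_day: float, mean_min: float, sd_min: float,
                 max_tries: int = 100) -> list[tuple[float, float]]:
    """Poisson event arrivals with log-normal durations, non-overlapping.

    Overlapping placements are re-drawn (up to ``max_tries``) rather than
    dropped, so the empirical event rate stays unbiased.
    """
    lam = rate_per_day * duration_s / DAY_S
    n = int(rng.poisson(lam)) if lam > 0 else 0
    if n == 0:
        return []
    sigma2 = np.log1p((sd_min / mean_min) ** 2)
    mu = np.log(mean_min) - sigma2 / 2.0
    events: list[tuple[float, float]] = []
    for _ in range(n):
        for _try in range(max_tries):
            dur = float(rng.lognormal(mu, np.sqrt(sigma2))) * 60.0
            dur = min(dur, duration_s * 0.9)
            start = float(rng.uniform(0.0, max(duration_s - dur, 1e-9)))
            end = start + dur
            if all(end <= a or start >= b for a, b in events):
                events.append((start, end))
                break
        else:
            log.warning("could not place a non-overlapping event; dropped")
    events.sort()
    return events


def generate_bg_trace(spec: GlycemicModelSpec, duration_days: float,
                      interval: float = 300.0,
                      seed: int | np.random.Generator = 0,
                      subject_id: str = "S") -> tuple[CgmTrace, GroundTruthLog]:
    """Simulate a CGM trace with known ground-truth hypoglycemic events.

    Between events glucose follows an OU process around ``baseline_bg``
    (stationary SD ``bg_sd``), clipped to [75, 400] mg/dL so that every
    sub-70 sample is attributable to an event.  Inside an event glucose
    ramps to ``70 - hypo_depth`` and is clipped strictly below 70 mg/dL.
    """
    if not duration_days > 0:
        raise ValueError("duration must be positive")
    if not interval > 0:
        raise ValueError("interval must be positive")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    duration_s = duration_days * DAY_S
    t = np.arange(0.0, duration_s, interval)
    events = _draw_events(rng, duration_s, spec.mean_events_per_day,
                          spec.mean_event_duration, spec.event_duration_sd)
    truth = GroundTruthLog(subject_id, events)

    # OU baseline path
    tau = spec.mean_reversion_minutes * 60.0
    a = np.exp(-interval / tau)
    innov_sd = spec.bg_sd * np.sqrt(1.0 - a * a)
    bg = np.empty_like(t)
    x = spec.baseline_bg + spec.bg_sd * rng.standard_normal()
    for i in range(t.size):
        bg[i] = x
        x = spec.baseline_bg + a * (x - spec.baseline_bg) + innov_sd * rng.standard_normal()
    bg = np.clip(bg, 75.0, 400.0)

    # event excursions: half-sine dip to the nadir, strictly below threshold
    for start, end in events:
        mask = (t >= start) & (t < end)
        if not mask.any():
            continue
        phase = (t[mask] - start) / (end - start)
        dip = spec.hypo_depth * np.sin(np.pi * phase) ** 0.5
        ev = 69.0 - dip + 1.5 * rng.standard_normal(mask.sum())
        bg[mask] = np.clip(ev, 40.0, 69.5)

    return CgmTrace(subject_id, t, bg), truth


# ---------------------------------------------------------------------------
# accelerometer
# ---------------------------------------------------------------------------

def _wear_blocks(rng: np.random.Generator, duration_s: float,
                 wear_fraction: float) -> list[tuple[float, float]]:
    """Contiguous worn intervals covering ~wear_fraction of each day."""
    if wear_fraction >= 1.0:
        return [(0.0, duration_s)]
    blocks: list[tuple[float, float]] = []
    day_starts = np.arange(0.0, duration_s, DAY_S)
    for d0 in day_starts:
        day_len = min(DAY_S, duration_s - d0)
        worn = wear_fraction * day_len
        nb = int(rng.integers(2, 5))
        worn_parts = worn * rng.dirichlet(np.full(nb, 2.0))
        gap_parts = (day_len - worn) * rng.dirichlet(np.full(nb + 1, 2.0))
        cursor = d0
        for k in range(nb):
            cursor += gap_parts[k]
            blocks.append((cursor, cursor + worn_parts[k]))
            cursor += worn_parts[k]
    return blocks


def _shaped_noise(rng: np.random.Generator, n: int, sos) -> np.ndarray:
    """Filtered white noise normalised to unit RMS (zeros if degenerate)."""
    x = signal.sosfilt(sos, rng.standard_normal(n))
    s = x.std()
    if s < 1e-12:
        return np.zeros(n)
    return x / s


def generate_accel(bg: CgmTrace, truth: GroundTruthLog, tremor: TremorModelSpec,
                   rate: float = 64.0,
                   seed: int | np.random.Generator = 0) -> AccelRecording:
    """Synthesise the triaxial accelerometer stream paired with a CGM trace.

    The stream spans the CGM trace's duration; unworn periods are emitted
    as gaps in the timestamp vector.  Raises ``ValueError`` if the sampling
    rate cannot represent the tremor band (``rate <= 2 * band_high``).
    """
    if rate <= 2.0 * tremor.band_high:
        raise ValueError(
            f"rate {rate} Hz must exceed twice the tremor band edge "
            f"({tremor.band_high} Hz) to avoid aliasing"
        )
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if bg.t.size >= 2:
        duration_s = float(bg.t[-1] + (bg.t[1] - bg.t[0]))
    else:
        duration_s = float(bg.t[-1]) + 300.0 if bg.t.size else 0.0

    sos_motion = signal.butter(4, min(3.5, tremor.band_low * 0.875),
                               btype="low", fs=rate, output="sos")
    sos_tremor = signal.butter(4, [tremor.carrier_low, tremor.carrier_high],
                               btype="band", fs=rate, output="sos")
    sos_slow = signal.butter(2, 0.05, btype="low", fs=rate, output="sos")
    sos_very_slow = signal.butter(2, 0.02, btype="low", fs=rate, output="sos")

    def slow_envelope(n: int, sd: float, sos) -> np.ndarray | float:
        if sd <= 0:
            return 1.0
        m = signal.sosfilt(sos, rng.standard_normal(n))
        s = m.std()
        if s < 1e-12:
            return 1.0
        return np.exp(m / s * sd - sd ** 2 / 2.0)

    t_parts: list[np.ndarray] = []
    a_parts: list[np.ndarray] = []
    for start, end in _wear_blocks(rng, duration_s, tremor.wear_fraction):
        k0 = int(np.ceil(start * rate - 1e-9))
        k1 = int(np.floor(end * rate - 1e-9))
        n = k1 - k0 + 1
        if n < 2:
            continue
        t = (k0 + np.arange(n)) / rate

        # gravity: unit vector tilted away from z by up to ~30 degrees
        theta = rng.uniform(0.0, 0.5)
        phi = rng.uniform(0.0, 2.0 * np.pi)
        gvec = np.array([np.sin(theta) * np.cos(phi),
                         np.sin(theta) * np.sin(phi),
                         np.cos(theta)])
        a = np.tile(gvec, (n, 1))

        if tremor.motion_amp > 0:
            activity = slow_envelope(n, tremor.motion_mod_sd, sos_very_slow)
            for c in range(3):
                a[:, c] += (tremor.motion_amp * activity
                            * _shaped_noise(rng, n, sos_motion))

        amp = np.where(truth.in_event(t), tremor.tremor_amp_hypo,
                       tremor.tremor_amp_normal)
        if amp.max() > 0:
            envelope = slow_envelope(n, tremor.mod_sd, sos_slow)
            for c in range(3):
                a[:, c] += (amp * envelope / np.sqrt(3.0)
                            * _shaped_noise(rng, n, sos_tremor))

        if tremor.noise_sd > 0:
            a += rng.normal(0.0, tremor.noise_sd, size=(n, 3))

        t_parts.append(t)
        a_parts.append(a)

    if not t_parts:
        return AccelRecording(bg.subject_id, np.empty(0), np.empty((0, 3)), rate)
    return AccelRecording(bg.subject_id, np.concatenate(t_parts),
                          np.vstack(a_parts), rate)


# ---------------------------------------------------------------------------
# cohort assembly
# ---------------------------------------------------------------------------

def generate_cohort(spec: CohortSpec,
                    gly: GlycemicModelSpec | None = None,
                    tremor: TremorModelSpec | None = None) -> dict[str, SubjectRecord]:
    """Generate independent paired streams for every subject.

    Deterministic given ``spec.seed``: each subject draws from its own
    substream spawned from the root seed, so adding subjects never perturbs
    existing ones.
    """
    gly = gly or GlycemicModelSpec()
    tremor = tremor or TremorModelSpec()
    children = np.random.SeedSequence(spec.seed).spawn(spec.n_subjects)
    cohort: dict[str, SubjectRecord] = {}
    for i, child in enumerate(children):
        sid = f"S{i + 1:02d}"
        rng_bg, rng_acc = (np.random.default_rng(s) for s in child.spawn(2))
        cgm, truth = generate_bg_trace(gly, spec.days_per_subject,
                                       spec.cgm_interval, rng_bg, sid)
        accel = generate_accel(cgm, truth, tremor, spec.accel_rate, rng_acc)
        cohort[sid] = SubjectRecord(sid, accel, cgm, truth)
    return cohort


# ---------------------------------------------------------------------------
# disk round trip
# ---------------------------------------------------------------------------

def _iso(seconds: np.ndarray) -> pd.Series:
    origin = pd.Timestamp(TIME_ORIGIN)
    return pd.Series(origin + pd.to_timedelta(seconds, unit="s")).dt.strftime(
        "%Y-%m-%dT%H:%M:%S.%f")


def write_accel_csv(rec: AccelRecording, path) -> None:
    """Accelerometer CSV: iso-timestamp, x_g, y_g, z_g."""
    pd.DataFrame({
        "timestamp": _iso(rec.t),
        "x_g": rec.xyz[:, 0], "y_g": rec.xyz[:, 1], "z_g": rec.xyz[:, 2],
    }).to_csv(path, index=False)


def write_cgm_csv(cgm: CgmTrace, path) -> None:
    """CGM CSV: iso-timestamp, bg_mgdl."""
    pd.DataFrame({"timestamp": _iso(cgm.t), "bg_mgdl": cgm.bg}).to_csv(
        path, index=False)


def write_truth_json(truth: GroundTruthLog, path) -> None:
    """Ground-truth event log as JSON (seconds from the cohort origin)."""
    with open(path, "w") as fh:
        json.dump({"subject_id": truth.subject_id,
                   "events": [[a, b] for a, b in truth.events]}, fh, indent=1)


def read_truth_json(path) -> GroundTruthLog:
    with open(path) as fh:
        obj = json.load(fh)
    return GroundTruthLog(obj["subject_id"],
                          [tuple(e) for e in obj["events"]])
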