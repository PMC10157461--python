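"""CGM-aligned window labeling, sequence assembly and class rebalancing.

Each 3-second acceleration window is matched to the CGM reading nearest its
center; windows farther than 150 s from any reading are unlabeled.  Glucose
below 70 mg/dL labels a window hypoglycemic, 90-140 mg/dL (inclusive)
nonhypoglycemic, and anything else — the 70-90 buffer and readings above
140 — is excluded from analysis.  Only runs of at least 9 consecutive
same-label windows enter the final data set; runs are cut into
non-overlapping 9-window sequence blocks.  Training partitions (never
validation/test) may be rebalanced by random oversampling of the
hypoglycemic minority to a 3:1 majority:minority ratio.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .preprocess import WindowSet
from .synthetic import CgmTrace

log = logging.getLogger(__name__)

# glycemic labels
HYPO = 1
NONHYPO = 0
EXCLUDED = -1

CGM_CSV_COLUMNS = ("timestamp", "bg_mgdl")


@dataclass(frozen=True)
class AlignmentSpec:
    """Window-to-CGM matching and glycemic thresholds (mg/dL)."""

    halfwidth: float = 150.0
    hypo_threshold: float = 70.0
    normal_low: float = 90.0
    normal_high: float = 140.0

    def __post_init__(self) -> None:
        if not self.halfwidth > 0:
            raise ValueError("halfwidth must be positive")
        if not (self.hypo_threshold <= self.normal_low < self.normal_high):
            raise ValueError("need hypo_threshold <= normal_low < normal_high")


@dataclass
class LabeledWindows:
    """Glycemic labels for every window of a :class:`WindowSet`.

    Arrays are parallel to ``windows.starts``.  ``bg`` and ``cgm_time`` hold
    the matched reading (NaN where no reading fell within the half-width).
    """

    windows: WindowSet
    labels: np.ndarray     # int8: HYPO / NONHYPO / EXCLUDED
    bg: np.ndarray
    cgm_time: np.ndarray

    def __len__(self) -> int:
        return int(self.labels.shape[0])

    def manifest(self) -> pd.DataFrame:
        """Audit table: subject, start_time, label, bg, cgm_time."""
        names = {HYPO: "hypo", NONHYPO: "nonhypo", EXCLUDED: "excluded"}
        return pd.DataFrame({
            "subject": self.windows.subject_id,
            "start_time": self.windows.starts,
            "label": [names[int(v)] for v in self.labels],
            "bg": self.bg,
            "cgm_time": self.cgm_time,
        })


def label_windows(windows: WindowSet, cgm: CgmTrace,
                  spec: AlignmentSpec | None = None) -> LabeledWindows:
    """Label each window from the CGM reading nearest its center.

    The nearest reading within ±``halfwidth`` seconds of the window center
    decides the label (ties broken toward the earlier reading).  With the
    usual 300-second CGM cadence the ±150 s half-width tiles time exactly,
    so every in-wear window maps to one reading.  An empty trace labels
    everything excluded with a warning.
    """
    spec = spec or AlignmentSpec()
    n = len(windows)
    labels = np.full(n, EXCLUDED, dtype=np.int8)
    bg = np.full(n, np.nan)
    cgm_time = np.full(n, np.nan)
    if cgm.t.size == 0:
        log.warning("empty CGM trace for %s: all windows excluded",
                    windows.subject_id)
        return LabeledWindows(windows, labels, bg, cgm_time)

    centers = windows.centers
    right = np.searchsorted(cgm.t, centers)
    left = np.clip(right - 1, 0, cgm.t.size - 1)
    right = np.clip(right, 0, cgm.t.size - 1)
    d_left = np.abs(centers - cgm.t[left])
    d_right = np.abs(cgm.t[right] - centers)
    pick = np.where(d_left <= d_right, left, right)  # tie -> earlier reading
    dist = np.minimum(d_left, d_right)
    matched = dist <= spec.halfwidth

    mbg = cgm.bg[pick]
    bg[matched] = mbg[matched]
    cgm_time[matched] = cgm.t[pick][matched]
    labels[matched & (mbg < spec.hypo_threshold)] = HYPO
    labels[matched & (mbg >= spec.normal_low) & (mbg <= spec.normal_high)] = NONHYPO
    return LabeledWindows(windows, labels, bg, cgm_time)


@dataclass
class SequenceExample:
    """A block of consecutive same-label windows (indices into the set)."""

    indices: np.ndarray
    label: int

    def __len__(self) -> int:
        return int(self.indices.shape[0])


def build_sequences(labeled: LabeledWindows, seq_len: int = 9) -> list[SequenceExample]:
    """Cut maximal same-label runs of consecutive windows into blocks.

    Windows are consecutive when each starts one hop after the previous.
    Runs shorter than ``seq_len`` are discarded; longer runs yield
    ``floor(run/seq_len)`` non-overlapping blocks (no window is shared
    between sequences).  Excluded windows break runs.
    """
    if seq_len < 1:
        raise ValueError("seq_len must be >= 1")
    n = len(labeled)
    if n == 0:
        return []
    hop = labeled.windows.hop_seconds
    starts = labeled.windows.starts
    labels = labeled.labels

    consecutive = np.abs(np.diff(starts) - hop) < 0.25 * hop
    same_label = labels[1:] == labels[:-1]
    chain = consecutive & same_label

    out: list[SequenceExample] = []
    run_start = 0
    for i in range(n):
        end_of_run = i == n - 1 or not chain[i]
        if not end_of_run:
            continue
        run = np.arange(run_start, i + 1)
        run_start = i + 1
        lab = int(labels[run[0]])
        if lab == EXCLUDED:
            continue
        for b in range(len(run) // seq_len):
            out.append(SequenceExample(run[b * seq_len:(b + 1) * seq_len], lab))
    return out


@dataclass(frozen=True)
class ResampleSpec:
    """Random-oversampling policy for training partitions only."""

    ratio_major_to_minor: float = 3.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.ratio_major_to_minor >= 1:
            raise ValueError("ratio must be >= 1")


def oversample_training(labels: np.ndarray,
                        spec: ResampleSpec | None = None,
                        rng: np.random.Generator | None = None) -> np.ndarray:
    """Index vector rebalancing a training set to the configured ratio.

    Hypoglycemic examples are duplicated uniformly at random (with
    replacement, seeded) until nonhypo:hypo equals
    ``ratio_major_to_minor``; majority examples are untouched, and a set
    already at or below the ratio is returned unchanged.  Apply to training
    partitions only — the evaluation harness enforces that contract.
    """
    spec = spec or ResampleSpec()
    rng = rng or np.random.default_rng(spec.seed)
    labels = np.asarray(labels)
    idx = np.arange(labels.shape[0])
    hypo_idx = idx[labels == HYPO]
    n_non = int((labels == NONHYPO).sum())
    n_hypo = hypo_idx.shape[0]
    if n_hypo == 0:
        log.warning("no hypoglycemic examples to oversample; set unchanged")
        return idx
    target = int(round(n_non / spec.ratio_major_to_minor))
    if target <= n_hypo:
        return idx
    extra = rng.choice(hypo_idx, size=target - n_hypo, replace=True)
    return np.concatenate([idx, extra])


def read_cgm_csv(path, subject_id: str | None = None) -> CgmTrace:
    """Read a CGM CSV (columns timestamp, bg_mgdl) into a trace.

    Malformed rows are dropped with a logged count.
    """
    df = pd.read_csv(path)
    missing = [c for c in CGM_CSV_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"CGM CSV missing columns: {missing}")
    ts = pd.to_datetime(df["timestamp"], errors="coerce", format="ISO8601")
    bg = pd.to_numeric(df["bg_mgdl"], errors="coerce")
    ok = ts.notna() & bg.notna()
    n_bad = int((~ok).sum())
    if n_bad:
        log.warning("%s: dropped %d malformed row(s)", path, n_bad)
    t = ts[ok].astype("int64").to_numpy() / 1e9
    sid = subject_id if subject_id is not None else str(path)
    return CgmTrace(sid, t, bg[ok].to_numpy(dtype=float))
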