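"""CGM alignment, sequence blocking and oversampling."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tremorglyc import (EXCLUDED, HYPO, NONHYPO, AlignmentSpec, CgmTrace,
                        ResampleSpec, attach_magnitude, build_sequences,
                        label_windows, make_windows, oversample_training,
                        read_cgm_csv, write_cgm_csv)

from conftest import make_recording


def windows_for(duration: float, rate: float = 64.0):
    n = int(round(duration * rate))
    rec = make_recording(np.zeros((n, 3)), rate)
    return make_windows(attach_magnitude(rec))


def trace(times, bgs):
    return CgmTrace("T01", np.asarray(times, float), np.asarray(bgs, float))


class TestLabelWindows:
    @pytest.mark.parametrize("bg,expected", [
        (65.0, HYPO),        # below 70 -> hypoglycemic
        (100.0, NONHYPO),    # inside [90, 140] -> nonhypoglycemic
        (80.0, EXCLUDED),    # buffer zone [70, 90)
        (150.0, EXCLUDED),   # above 140
    ])
    def test_thresholds_decide_the_label(self, bg, expected):
        # single window centered at 1.5 s; reading 100 s later (within 150 s)
        ws = windows_for(3.0)
        lab = label_windows(ws, trace([101.5], [bg]))
        assert lab.labels[0] == expected
        if expected != EXCLUDED or 70 <= bg <= 200:
            assert lab.bg[0] == bg

    def test_inclusive_band_edges(self):
        ws = windows_for(3.0)
        assert label_windows(ws, trace([1.5], [90.0])).labels[0] == NONHYPO
        assert label_windows(ws, trace([1.5], [140.0])).labels[0] == NONHYPO
        assert label_windows(ws, trace([1.5], [70.0])).labels[0] == EXCLUDED

    def test_reading_beyond_halfwidth_excludes(self):
        ws = windows_for(3.0)
        lab = label_windows(ws, trace([160.0], [65.0]))
        assert lab.labels[0] == EXCLUDED
        assert np.isnan(lab.bg[0])

    def test_tie_breaks_toward_earlier_reading(self):
        ws = windows_for(3.0)  # center 1.5
        lab = label_windows(ws, trace([-98.5, 101.5], [65.0, 100.0]))
        assert lab.labels[0] == HYPO
        assert lab.cgm_time[0] == -98.5

    def test_empty_cgm_excludes_everything_with_warning(self, caplog):
        ws = windows_for(30.0)
        with caplog.at_level("WARNING"):
            lab = label_windows(ws, trace([], []))
        assert np.all(lab.labels == EXCLUDED)
        assert "empty CGM" in caplog.text

    def test_regular_cadence_tiles_time_exactly(self):
        """With 300-s cadence, every window maps to exactly one reading."""
        ws = windows_for(1200.0)
        times = np.arange(150.0, 1200.0, 300.0)
        lab = label_windows(ws, trace(times, np.full(times.size, 100.0)))
        assert np.all(lab.labels == NONHYPO)
        # the matched reading is the nearest one
        expect = times[np.argmin(np.abs(ws.centers[:, None] - times[None, :]),
                                 axis=1)]
        assert np.allclose(lab.cgm_time, expect)

    def test_label_invariants_on_generated_cohort(self):
        from tremorglyc import CohortSpec, generate_cohort, preprocess_subject
        rec = generate_cohort(CohortSpec(1, 0.5, seed=3))["S01"]
        ws = preprocess_subject(rec.accel)
        lab = label_windows(ws, rec.cgm)
        assert np.all(lab.bg[lab.labels == HYPO] < 70)
        non = lab.bg[lab.labels == NONHYPO]
        assert np.all((non >= 90) & (non <= 140))


def brute_force_blocks(labels, consecutive, seq_len=9):
    """Oracle: walk runs of same-label consecutive windows, cut blocks."""
    blocks = []
    i, n = 0, len(labels)
    while i < n:
        j = i
        while j + 1 < n and consecutive[j] and labels[j + 1] == labels[i]:
            j += 1
        if labels[i] != EXCLUDED:
            run = list(range(i, j + 1))
            for b in range(len(run) // seq_len):
                blocks.append((run[b * seq_len:(b + 1) * seq_len], labels[i]))
        i = j + 1
    return blocks


class TestBuildSequences:
    @pytest.mark.parametrize("n_windows,label,expected", [
        (9, HYPO, 1), (8, HYPO, 0), (18, NONHYPO, 2), (26, NONHYPO, 2),
    ])
    def test_blocking_counts(self, n_windows, label, expected):
        duration = 3.0 + 1.5 * (n_windows - 1)
        ws = windows_for(duration)
        assert len(ws) == n_windows
        bg = 65.0 if label == HYPO else 100.0
        times = np.arange(0.0, duration + 300, 300.0)
        lab = label_windows(ws, trace(times, np.full(times.size, bg)))
        seqs = build_sequences(lab)
        assert len(seqs) == expected
        for s in seqs:
            assert s.label == label
            assert len(s) == 9

    def test_label_change_breaks_runs(self):
        ws = windows_for(3.0 + 1.5 * 17)  # 18 windows
        lab = label_windows(ws, trace([0.0], [100.0]))
        # force a label flip halfway: 9 hypo then 9 nonhypo
        lab.labels[:9] = HYPO
        lab.labels[9:] = NONHYPO
        seqs = build_sequences(lab)
        assert [s.label for s in seqs] == [HYPO, NONHYPO]

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(st.lists(st.sampled_from([HYPO, NONHYPO, EXCLUDED]),
                    min_size=1, max_size=60),
           st.integers(0, 2 ** 20))
    def test_blocking_agrees_with_brute_force_oracle(self, labels, gap_seed):
        """Random label runs with random gaps match the enumerator."""
        n = len(labels)
        rng = np.random.default_rng(gap_seed)
        gaps = rng.random(max(n - 1, 0)) < 0.15
        ws = windows_for(3.0 + 1.5 * (n - 1))
        starts = ws.starts.copy()
        starts += np.concatenate([[0.0], np.cumsum(gaps) * 50.0])
        ws.starts = starts
        lab = label_windows(ws, trace([0.0], [100.0]))
        lab.labels = np.asarray(labels, dtype=np.int8)
        got = build_sequences(lab)
        want = brute_force_blocks(labels, ~gaps)
        assert [(list(s.indices), s.label) for s in got] == \
               [(w[0], w[1]) for w in want]


class TestOversampling:
    def test_duplicates_minority_to_the_ratio(self):
        labels = np.array([NONHYPO] * 900 + [HYPO] * 100)
        idx = oversample_training(labels, ResampleSpec(3.0, seed=0))
        assert (labels[idx] == HYPO).sum() == 300
        assert (labels[idx] == NONHYPO).sum() == 900

    def test_already_at_ratio_is_unchanged(self):
        labels = np.array([NONHYPO] * 300 + [HYPO] * 100)
        idx = oversample_training(labels, ResampleSpec(3.0, seed=0))
        assert np.array_equal(idx, np.arange(400))

    def test_one_to_one_ratio(self):
        labels = np.array([NONHYPO] * 100 + [HYPO] * 25)
        idx = oversample_training(labels, ResampleSpec(1.0, seed=0))
        assert (labels[idx] == HYPO).sum() == 100
        assert (labels[idx] == NONHYPO).sum() == 100

    def test_majority_examples_never_duplicated(self):
        labels = np.array([NONHYPO] * 90 + [HYPO] * 10)
        idx = oversample_training(labels, ResampleSpec(3.0, seed=1))
        non_idx = idx[labels[idx] == NONHYPO]
        assert np.array_equal(np.sort(non_idx), np.arange(90))

    def test_no_minority_examples_warns_and_keeps_set(self, caplog):
        labels = np.array([NONHYPO] * 50)
        with caplog.at_level("WARNING"):
            idx = oversample_training(labels, ResampleSpec(3.0, seed=0))
        assert np.array_equal(idx, np.arange(50))
        assert "no hypoglycemic" in caplog.text

    def test_ratio_below_one_rejected(self):
        with pytest.raises(ValueError):
            ResampleSpec(0.5)


class TestCgmCsv:
    def test_round_trip(self, tmp_path):
        cgm = trace(np.arange(0.0, 3000.0, 300.0), np.linspace(80, 120, 10))
        path = tmp_path / "cgm.csv"
        write_cgm_csv(cgm, path)
        back = read_cgm_csv(path, subject_id="T01")
        assert np.allclose(back.bg, cgm.bg)
        assert np.allclose(np.diff(back.t), 300.0, atol=1e-5)
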