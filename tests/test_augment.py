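"""Window augmentation: counts, labels, composition, sampler distributions."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from szdetect.augment import (
    NEGATIVE,
    POSITIVE,
    AugmentationConfig,
    Segment,
    WindowSet,
    boundary_windows,
    expected_window_count,
    extract_segments,
    random_contiguous_windows,
    random_noncontiguous_windows,
    sequential_windows,
)
from szdetect.io import NONSEIZURE, SEIZURE, ValidationError


def _segment(rng, n, label, seg_id=0, channels=2):
    return Segment(rng.standard_normal((channels, n)), label, seg_id, 0)


class TestExtractSegments:
    def test_one_seizure_two_flanks(self, small_recording):
        rec, ann = small_recording
        seiz, nonseiz = extract_segments(rec, ann)
        assert len(seiz) == 1 and len(nonseiz) == 2
        assert seiz[0].data.shape == (4, 200)

    def test_half_open_arithmetic(self, small_recording, rng):
        from szdetect.io import AnnotationSet, Interval, Recording

        rec = Recording(rng.standard_normal((2, 30)), fs_hz=100.0)
        ann = AnnotationSet([Interval(10, 20, SEIZURE)])
        seiz, _ = extract_segments(rec, ann)
        assert seiz[0].data.shape[1] == 10

    def test_tiling_intervals_reconstruct_recording(self, small_recording):
        rec, ann = small_recording
        seiz, nonseiz = extract_segments(rec, ann)
        ordered = sorted(seiz + nonseiz, key=lambda s: s.start)
        np.testing.assert_array_equal(np.concatenate([s.data for s in ordered], axis=1), rec.data)

    def test_annotation_beyond_end_rejected(self, small_recording):
        from szdetect.io import AnnotationSet, Interval

        rec, _ = small_recording
        bad = AnnotationSet([Interval(0, rec.n_samples + 1, SEIZURE)])
        with pytest.raises(ValidationError):
            extract_segments(rec, bad)


class TestExpectedWindowCount:
    @pytest.mark.parametrize(
        "seg_len,L,stride,expected",
        [(100, 100, 1, 1), (199, 100, 50, 2), (99, 100, 1, 0), (200, 100, 50, 3)],
    )
    def test_worked_examples(self, seg_len, L, stride, expected):
        assert expected_window_count(seg_len, L, stride) == expected

    @given(st.integers(1, 500), st.integers(1, 200), st.integers(1, 60))
    @settings(max_examples=100, deadline=None)
    def test_matches_enumeration_of_valid_starts(self, seg_len, L, stride):
        starts = [s for s in range(0, seg_len, stride) if s + L <= seg_len]
        assert expected_window_count(seg_len, L, stride) == len(starts)


class TestSequentialWindows:
    def test_seizure_segment_stride_one(self, rng):
        segs = [_segment(rng, 150, SEIZURE)]
        cfg = AugmentationConfig(window_len=100, stride_seizure=1)
        ws = sequential_windows(segs, [], cfg)
        assert len(ws) == ws.n_positive == 51

    def test_nonseizure_default_stride_fifty(self, rng):
        cfg = AugmentationConfig(window_len=100)
        assert cfg.stride_nonseizure == 50
        ws = sequential_windows([], [_segment(rng, 200, NONSEIZURE)], cfg)
        assert len(ws) == ws.n_negative == 3
        assert [p["start"] for p in ws.provenance] == [0, 50, 100]

    def test_count_conservation_over_segments(self, rng):
        cfg = AugmentationConfig(window_len=100, stride_seizure=3, stride_nonseizure=17)
        seiz = [_segment(rng, n, SEIZURE, i) for i, n in enumerate([100, 137, 99, 460])]
        nonseiz = [_segment(rng, n, NONSEIZURE, i) for i, n in enumerate([550, 101])]
        ws = sequential_windows(seiz, nonseiz, cfg)
        assert ws.n_positive == sum(expected_window_count(n, 100, 3) for n in [100, 137, 99, 460])
        assert ws.n_negative == sum(expected_window_count(n, 100, 17) for n in [550, 101])

    def test_window_shape_and_content(self, rng):
        seg = _segment(rng, 120, SEIZURE, channels=3)
        ws = sequential_windows([seg], [], AugmentationConfig(window_len=100, stride_seizure=10))
        assert ws.data.shape == (3, 3, 100)
        np.testing.assert_array_equal(ws.data[1], seg.data[:, 10:110].astype(np.float32))


class TestRandomContiguous:
    def test_zero_requests_empty(self, rng):
        ws = random_contiguous_windows(
            [_segment(rng, 200, SEIZURE)], [_segment(rng, 200, NONSEIZURE)],
            0, 0, AugmentationConfig()
        )
        assert len(ws) == 0

    def test_start_offsets_uniform(self, rng):
        """1000 draws from a 150-sample segment: starts uniform on [0, 50]."""
        seg = _segment(rng, 150, SEIZURE)
        cfg = AugmentationConfig(window_len=100, seed=11)
        ws = random_contiguous_windows([seg], [_segment(rng, 100, NONSEIZURE)], 1000, 0, cfg)
        starts = np.array([p["start"] for p in ws.provenance])
        assert starts.min() >= 0 and starts.max() <= 50
        counts = np.bincount(starts, minlength=51)
        assert stats.chisquare(counts).pvalue > 0.01

    def test_determinism_under_seed(self, rng):
        segs = ([_segment(rng, 300, SEIZURE)], [_segment(rng, 300, NONSEIZURE)])
        cfg = AugmentationConfig(seed=5)
        a = random_contiguous_windows(*segs, 50, 50, cfg)
        b = random_contiguous_windows(*segs, 50, 50, cfg)
        np.testing.assert_array_equal(a.data, b.data)
        assert a.provenance == b.provenance

    def test_no_eligible_segment_names_class(self, rng):
        with pytest.raises(ValidationError, match="seizure"):
            random_contiguous_windows(
                [_segment(rng, 50, SEIZURE)], [_segment(rng, 200, NONSEIZURE)],
                1, 1, AugmentationConfig(window_len=100)
            )


class TestRandomNoncontiguous:
    def test_all_positive_with_L_columns(self, rng):
        ws = random_noncontiguous_windows(
            [_segment(rng, 200, SEIZURE)], [_segment(rng, 200, NONSEIZURE)],
            25, AugmentationConfig(window_len=100)
        )
        assert len(ws) == 25
        assert np.all(ws.labels == POSITIVE)
        assert ws.data.shape[2] == 100

    def test_m_max_one_gives_single_nonseizure_column(self, rng):
        ws = random_noncontiguous_windows(
            [_segment(rng, 200, SEIZURE)], [_segment(rng, 200, NONSEIZURE)],
            10, AugmentationConfig(window_len=100, m_max=1)
        )
        assert all(p["m"] == 1 for p in ws.provenance)

    def test_m_uniform_on_1_to_39(self, rng):
        ws = random_noncontiguous_windows(
            [_segment(rng, 500, SEIZURE)], [_segment(rng, 500, NONSEIZURE)],
            10_000, AugmentationConfig(window_len=100, m_max=39, seed=3)
        )
        ms = np.array([p["m"] for p in ws.provenance])
        assert ms.min() >= 1 and ms.max() <= 39
        assert stats.chisquare(np.bincount(ms, minlength=40)[1:]).pvalue > 0.01

    def test_columns_time_aligned_across_channels(self, rng):
        """The spliced window equals [nonseizure run | seizure run] on every channel."""
        seiz, nonseiz = _segment(rng, 300, SEIZURE, 1), _segment(rng, 300, NONSEIZURE, 2)
        ws = random_noncontiguous_windows([seiz], [nonseiz], 5,
                                          AugmentationConfig(window_len=100, seed=8))
        for w, p in zip(ws.data, ws.provenance):
            m = p["m"]
            np.testing.assert_array_equal(
                w[:, :m], nonseiz.data[:, p["nonseizure_start"]:p["nonseizure_start"] + m
                                       ].astype(np.float32))
            np.testing.assert_array_equal(
                w[:, m:], seiz.data[:, p["seizure_start"]:p["seizure_start"] + 100 - m
                                    ].astype(np.float32))


class TestBoundaryWindows:
    def test_label_threshold_at_61_seizure_columns(self, small_recording):
        rec, ann = small_recording
        cfg = AugmentationConfig(window_len=100, m_max=39)
        ws = boundary_windows(rec, ann, cfg)
        for w, lab, p in zip(ws.data, ws.labels, ws.provenance):
            assert lab == (POSITIVE if p["seizure_cols"] >= 61 else NEGATIVE)
        assert ws.n_positive and ws.n_negative  # both labels occur across the onset


class TestWindowSetContainer:
    def test_save_load_round_trip(self, rng, tmp_path):
        ws = random_contiguous_windows(
            [_segment(rng, 200, SEIZURE)], [_segment(rng, 200, NONSEIZURE)],
            10, 10, AugmentationConfig(seed=2)
        )
        back = WindowSet.load(ws.save(tmp_path / "w.h5"))
        np.testing.assert_array_equal(back.data, ws.data)
        np.testing.assert_array_equal(back.labels, ws.labels)
        assert back.provenance == ws.provenance
        assert back.config == ws.config
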