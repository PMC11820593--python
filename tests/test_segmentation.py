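import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ecgfusion.balance import SMOTEConfig
from ecgfusion.io_wfdb import ECGRecord
from ecgfusion.segmentation import (
    EmptySliceError,
    LabeledSegment,
    SegmentSet,
    SliceConfig,
    label_slice,
    make_segments,
    partition,
    slice_record,
    validation_split,
)


def _record(n_samples: int, annotations, fs: float = 360.0) -> ECGRecord:
    return ECGRecord(
        signal=np.arange(n_samples, dtype=float)[None, :], fs=fs,
        annotations=annotations, name="seg",
    )


class TestSliceRecord:
    def test_half_overlap_window_starts(self):
        rec = _record(3600, [(10, "N"), (1000, "N"), (2000, "V")])
        windows = slice_record(rec, SliceConfig(5.0, 0.5, 360.0))
        assert [start for _, _, start in windows] == [0, 900, 1800]
        assert all(len(w) == 1800 for w, _, _ in windows)

    def test_single_window_record(self):
        rec = _record(1800, [(5, "N")])
        assert len(slice_record(rec)) == 1

    def test_boundary_annotation_half_open(self):
        rec = _record(3600, [(1800, "V")])
        windows = slice_record(rec, SliceConfig(5.0, 0.5, 360.0))
        memberships = [labels for _, labels, _ in windows]
        assert memberships == [[], ["V"], ["V"]]  # windows [0,1800), [900,2700), [1800,3600)

    def test_trailing_partial_window_dropped(self):
        rec = _record(2000, [(5, "N")])
        windows = slice_record(rec, SliceConfig(5.0, 0.0, 360.0))
        assert len(windows) == 1

    def test_short_record_rejected(self):
        with pytest.raises(ValueError, match="shorter"):
            slice_record(_record(100, []))

    def test_non_beat_symbols_skipped(self):
        rec = _record(1800, [(5, "~"), (100, "N"), (200, "+")])
        _, labels, _ = slice_record(rec)[0]
        assert labels == ["N"]


class TestLabelSlice:
    @pytest.mark.parametrize(
        "beats,expected",
        [
            (["N", "N", "N", "N"], "N"),            # rule 1
            (["N", "N", "V"], "V"),                  # rule 2
            (["N", "S", "S", "V"], "S"),             # rule 3
            (["V", "N", "S"], "V"),                  # rule 4 tie: first abnormal
            (["S", "V", "S", "V"], "S"),             # rule 4 tie with counts 2-2
            (["Q"], "Q"),
        ],
    )
    def test_rules(self, beats, expected):
        assert label_slice(beats) == expected

    def test_empty_slice_rejected(self):
        with pytest.raises(EmptySliceError):
            label_slice([])

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(st.lists(st.sampled_from("NSVFQ"), min_size=1, max_size=12),
           st.randoms(use_true_random=False))
    def test_permutation_invariant_without_ties(self, beats, rnd):
        from collections import Counter

        abnormal = Counter(b for b in beats if b != "N")
        counts = sorted(abnormal.values(), reverse=True)
        tie = len(counts) >= 2 and counts[0] == counts[1]
        label = label_slice(beats)
        shuffled = beats.copy()
        rnd.shuffle(shuffled)
        if not tie:
            assert label_slice(shuffled) == label
        else:  # tie: decided by first occurrence among tied types
            tied = {c for c, n in abnormal.items() if n == counts[0]}
            first = next(b for b in shuffled if b in tied)
            assert label_slice(shuffled) == first


def _toy_segments(counts: dict[str, int], dim: int = 12) -> SegmentSet:
    rng = np.random.default_rng(0)
    X, y = [], []
    for i, (label, c) in enumerate(sorted(counts.items())):
        X.append(rng.standard_normal((c, dim)) + 3.0 * i)
        y.append(np.full(c, label))
    return SegmentSet(np.concatenate(X), np.concatenate(y))


class TestPartition:
    def test_twenty_percent_test(self):
        data = _toy_segments({"N": 40, "V": 30, "S": 30})
        train, val, test = partition(data, seed=1, smote=SMOTEConfig(k_neighbors=3, seed=1))
        assert len(test) == 20

    def test_validation_rounding_is_ceil(self):
        # balanced 47,015 samples -> ceil(0.3 * 47015) = 14,105 validation
        y = np.repeat(np.array(list("NSVFQ")), 9403)
        data = SegmentSet(np.zeros((47015, 2), dtype=np.float32), y)
        train, val = validation_split(data, 0.3, seed=0)
        assert len(val) == 14105
        assert len(train) == 32910

    def test_no_test_leakage_into_smote(self):
        data = _toy_segments({"N": 40, "V": 30})
        train, val, test = partition(data, seed=3, smote=SMOTEConfig(k_neighbors=3, seed=3))
        pool = np.concatenate([train.X, val.X])
        pool_rows = {r.tobytes() for r in pool}
        # test rows never appear among SMOTE inputs/outputs
        assert all(r.tobytes() not in pool_rows for r in test.X)
        # every original (non-synthetic) train/val row comes from the rest split
        originals = np.concatenate([train.X[~train.synthetic], val.X[~val.synthetic]])
        assert len(originals) + len(test) == len(data)

    def test_balanced_after_partition(self):
        data = _toy_segments({"N": 40, "V": 25, "S": 20})
        train, val, test = partition(data, seed=5, smote=SMOTEConfig(k_neighbors=3, seed=5))
        merged = np.concatenate([train.y, val.y])
        _, counts = np.unique(merged, return_counts=True)
        assert len(set(counts.tolist())) == 1

    def test_deterministic(self):
        data = _toy_segments({"N": 40, "V": 30})
        cfg = dict(seed=7, smote=SMOTEConfig(k_neighbors=3, seed=7))
        a = partition(data, **cfg)
        b = partition(data, **cfg)
        for sa, sb in zip(a, b):
            assert np.array_equal(sa.X, sb.X)
            assert np.array_equal(sa.y, sb.y)

    def test_singleton_class_rejected(self):
        data = _toy_segments({"N": 10, "V": 1})
        with pytest.raises(ValueError, match="stratified"):
            partition(data, seed=0)


class TestMakeSegments:
    def test_windows_without_beats_skipped(self):
        rec = _record(5400, [(2000, "V")])
        segs = make_segments(rec, SliceConfig(5.0, 0.5, 360.0))
        assert all(isinstance(s, LabeledSegment) for s in segs)
        starts = {s.source for s in segs}
        assert starts == {"seg@900", "seg@1800"}
        assert {s.label for s in segs} == {"V"}
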