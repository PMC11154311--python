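"""Decision-cascade classifier, smoothing, occupancy, and transitions."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rasstates.classify import (
    LABEL_CODE,
    LABELS,
    ClassifierConfig,
    StateLabelSeries,
    classify_frame,
    classify_series,
    mode_filter,
    occupancy,
    transitions,
)
from rasstates.errors import ConfigError, DataError
from rasstates.features import FeatureFrame, FeatureSeries
from rasstates.io import FEATURE_COLUMNS


def frame(d_mg=2.0, d_og=2.7, d_o18=13.0, d_o12=5.3, d_oh40=11.6):
    return FeatureFrame(
        frame=0,
        d_O12_Og=d_o12,
        d_OH32_O18=d_o18,
        d_OG35_Mg=d_mg,
        d_OH32_Og=d_og,
        d_OH32_OH40=d_oh40,
        rc_angle=45.0,
    )


def series_from_distances(d_mg, d_og, d_o18):
    n = len(d_mg)
    table = pd.DataFrame(
        {
            "frame": np.arange(n),
            "time_ns": np.nan,
            "d_O12_Og": 5.3,
            "d_OH32_O18": np.asarray(d_o18, dtype=float),
            "d_OG35_Mg": np.asarray(d_mg, dtype=float),
            "d_OH32_Og": np.asarray(d_og, dtype=float),
            "d_OH32_OH40": 11.6,
            "rc_angle_deg": 45.0,
            "rc_dist_A": np.nan,
        },
        columns=FEATURE_COLUMNS,
    )
    return FeatureSeries(table=table)


class TestClassifyFrame:
    @pytest.mark.parametrize(
        "kwargs, expected",
        [
            (dict(d_mg=2.0, d_og=2.7, d_o18=13.0), "S2_OX"),
            (dict(d_mg=2.0, d_og=11.3, d_o18=4.3), "S2_OY"),
            (dict(d_mg=2.0, d_og=7.5, d_o18=13.0), "S2_OZ"),
            (dict(d_mg=6.0, d_og=14.0, d_o18=13.0), "S1"),
            (dict(d_mg=2.0, d_og=12.5, d_o18=13.0), "UNASSIGNED"),
        ],
    )
    def test_characteristic_centers(self, kwargs, expected):
        assert classify_frame(frame(**kwargs)) == expected

    @settings(max_examples=200, deadline=None)
    @given(
        d_mg=st.floats(0, 30, allow_nan=False),
        d_og=st.floats(0, 30, allow_nan=False),
        d_o18=st.floats(0, 30, allow_nan=False),
    )
    def test_total_and_deterministic_on_finite_inputs(self, d_mg, d_og, d_o18):
        f = frame(d_mg=d_mg, d_og=d_og, d_o18=d_o18)
        label = classify_frame(f)
        assert label in LABELS
        assert classify_frame(f) == label

    def test_config_invariants_enforced(self):
        with pytest.raises(ConfigError):
            ClassifierConfig(t_mg=5.0, t_ox=4.5)
        with pytest.raises(ConfigError):
            ClassifierConfig(smoothing_window=4)
        with pytest.raises(ConfigError):
            ClassifierConfig(t_oy=0.0)


class TestClassifySeries:
    def test_constant_state_single_segment(self):
        feats = series_from_distances([2.0] * 100, [2.7] * 100, [13.0] * 100)
        labels = classify_series(feats)
        assert len(labels.segments) == 1
        assert labels.segments[0] == ("S2_OX", 0, 100, 100)
        assert labels.transitions == []

    def test_spike_removed_by_window_3(self):
        # raw labels OX OX OY OX OX -> single OX segment
        feats = series_from_distances(
            [2.0] * 5, [2.7, 2.7, 11.3, 2.7, 2.7], [13.0, 13.0, 4.3, 13.0, 13.0]
        )
        labels = classify_series(feats, ClassifierConfig(smoothing_window=3))
        assert list(labels.raw) == ["S2_OX", "S2_OX", "S2_OY", "S2_OX", "S2_OX"]
        assert list(labels.labels) == ["S2_OX"] * 5
        assert len(labels.segments) == 1

    def test_window_1_is_identity(self):
        rng = np.random.default_rng(4)
        feats = series_from_distances(
            rng.uniform(1.5, 8.0, 60), rng.uniform(1.0, 14.0, 60), rng.uniform(3.0, 14.0, 60)
        )
        labels = classify_series(feats, ClassifierConfig(smoothing_window=1))
        assert (labels.raw == labels.labels).all()

    def test_empty_series_rejected(self):
        feats = series_from_distances([2.0], [2.7], [13.0])
        empty = FeatureSeries(table=feats.table.iloc[:0])
        with pytest.raises(DataError, match="empty"):
            classify_series(empty)

    @settings(max_examples=60, deadline=None)
    @given(
        codes=st.lists(st.integers(0, len(LABELS) - 1), min_size=1, max_size=40),
        window=st.sampled_from([3, 5, 7]),
    )
    def test_mode_filter_matches_enumeration_oracle(self, codes, window):
        codes = np.array(codes)
        got = mode_filter(codes, window)
        # oracle: explicit window enumeration with the documented tie rule
        half = window // 2
        expected = np.empty_like(codes)
        for i in range(len(codes)):
            win = codes[max(0, i - half) : i + half + 1]
            counts = np.bincount(win, minlength=len(LABELS))
            winners = np.flatnonzero(counts == counts.max())
            prev = expected[i - 1] if i > 0 else codes[i]
            if prev in winners:
                expected[i] = prev
            elif codes[i] in winners:
                expected[i] = codes[i]
            else:
                expected[i] = winners[0]
        np.testing.assert_array_equal(got, expected)

    def test_raising_t_mg_never_decreases_state2(self):
        rng = np.random.default_rng(1)
        feats = series_from_distances(
            rng.uniform(1.5, 8.0, 500), rng.uniform(1.0, 14.0, 500), rng.uniform(3.0, 14.0, 500)
        )
        prev_s2 = -1.0
        for t_mg in (2.0, 2.6, 3.5, 4.4):
            labels = classify_series(feats, ClassifierConfig(t_mg=t_mg, smoothing_window=1))
            occ = occupancy(labels)
            s2 = sum(occ.fractions[s] for s in ("S2_OX", "S2_OY", "S2_OZ"))
            assert s2 >= prev_s2
            prev_s2 = s2


def label_series(seq):
    codes = np.array([LABEL_CODE[s] for s in seq])
    from rasstates.classify import _segments_from_codes

    segments = _segments_from_codes(codes)
    trans = [
        (segments[k - 1][0], segments[k][0], segments[k][1])
        for k in range(1, len(segments))
    ]
    arr = np.asarray(seq, dtype=object)
    return StateLabelSeries(raw=arr, labels=arr, segments=segments, transitions=trans)


class TestOccupancy:
    def test_simple_fractions(self):
        labels = label_series(["S1"] * 40 + ["S2_OX"] * 60)
        occ = occupancy(labels)
        assert occ.fractions["S1"] == pytest.approx(0.40)
        assert occ.fractions["S2_OX"] == pytest.approx(0.60)

    def test_all_unassigned(self):
        occ = occupancy(label_series(["UNASSIGNED"] * 10))
        assert occ.fractions["UNASSIGNED"] == 1.0

    def test_pooling_is_frame_weighted(self):
        # oracle: (100*1 + 300*0) / 400 for S1
        a = label_series(["S1"] * 100)
        b = label_series(["S2_OX"] * 300)
        occ = occupancy([a, b])
        assert occ.fractions["S1"] == pytest.approx(0.25)
        assert occ.fractions["S2_OX"] == pytest.approx(0.75)
        assert occ.n_trajectories == 2

    def test_fractions_sum_to_one_and_match_weighted_average(self):
        rng = np.random.default_rng(8)
        series = [
            label_series(rng.choice(LABELS, size=n).tolist())
            for n in (37, 211, 95)
        ]
        pooled = occupancy(series)
        assert sum(pooled.fractions.values()) == pytest.approx(1.0, abs=1e-12)
        total = sum(len(s) for s in series)
        for lab in LABELS:
            weighted = sum(occupancy(s).fractions[lab] * len(s) for s in series) / total
            assert pooled.fractions[lab] == pytest.approx(weighted, abs=1e-12)

    def test_zero_frames_rejected(self):
        with pytest.raises(DataError):
            occupancy([])


class TestTransitions:
    def test_single_segment_zero_matrix(self):
        mat = transitions(label_series(["S1"] * 20))
        assert mat.sum() == 0

    def test_round_trip_two_transitions(self):
        mat = transitions(label_series(["S1", "S2_OX", "S1"]))
        assert mat[LABEL_CODE["S1"], LABEL_CODE["S2_OX"]] == 1
        assert mat[LABEL_CODE["S2_OX"], LABEL_CODE["S1"]] == 1
        assert mat.sum() == 2

    @settings(max_examples=40, deadline=None)
    @given(codes=st.lists(st.integers(0, 4), min_size=1, max_size=60))
    def test_total_transitions_equal_segments_minus_one(self, codes):
        labels = label_series([LABELS[c] for c in codes])
        assert transitions(labels).sum() == len(labels.segments) - 1
        assert np.all(np.diag(transitions(labels)) == 0)
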