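"""Derived endpoints, weighted log-rank scores and cluster aggregation."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from saddleperm import (
    SubjectRecord,
    build_pooled_sample,
    cluster_scores,
    derive_logproduct_endpoint,
    derive_ratio_endpoint,
    km_left_continuous,
    scores_from_arrays,
    scores_from_records,
    weighted_scores,
)


class TestDerivedEndpoints:
    def test_ratio_is_quotient(self):
        assert derive_ratio_endpoint(6.0, 3.0) == 2.0
        assert derive_ratio_endpoint(7.3, 7.3) == 1.0

    def test_ratio_scale_cancellation(self):
        assert derive_ratio_endpoint(2.5 * 7, 2.5 * 3) == pytest.approx(7 / 3)

    @pytest.mark.parametrize("num,den", [(-1.0, 2.0), (1.0, 0.0), (0.0, 1.0)])
    def test_ratio_rejects_nonpositive(self, num, den):
        with pytest.raises(ValueError):
            derive_ratio_endpoint(num, den)

    def test_logproduct_values(self):
        assert derive_logproduct_endpoint([1, 1, 1]) == 0.0
        assert derive_logproduct_endpoint([math.e, math.e]) == pytest.approx(2.0)
        assert derive_logproduct_endpoint([2, 3, 4]) == pytest.approx(
            math.log(24), abs=1e-12
        )

    def test_logproduct_rejects_nonpositive(self):
        with pytest.raises(ValueError, match="component 2"):
            derive_logproduct_endpoint([1.0, -2.0])


class TestWeightedScores:
    def test_logrank_three_events(self, three_event_records):
        sample = build_pooled_sample(three_event_records)
        w = weighted_scores(sample, "logrank")
        assert w == pytest.approx([2 / 3, 1 / 6, -5 / 6])

    def test_gehan_three_events(self, three_event_records):
        sample = build_pooled_sample(three_event_records)
        w = weighted_scores(sample, "gehan")
        assert w == pytest.approx([2.0, 0.0, -2.0])

    def test_all_censored_scores_zero(self):
        recs = [SubjectRecord("A", 1, t, 0) for t in (1.0, 2.0, 3.0)]
        sample = build_pooled_sample(recs)
        assert weighted_scores(sample, "logrank") == pytest.approx([0, 0, 0])

    def test_tied_event_times_pooled_into_one_risk_row(self):
        recs = [
            SubjectRecord("A", 1, 1.0, 1),
            SubjectRecord("A", 1, 1.0, 1),
            SubjectRecord("B", 2, 2.0, 1),
        ]
        sample = build_pooled_sample(recs)
        assert sample.unique_event_times.tolist() == [1.0, 2.0]
        assert sample.d.tolist() == [2.0, 1.0]
        assert sample.n.tolist() == [3.0, 1.0]

    def test_censored_at_event_time_still_at_risk(self):
        recs = [
            SubjectRecord("A", 1, 1.0, 1),
            SubjectRecord("B", 2, 1.0, 0),  # censored exactly at the event time
            SubjectRecord("B", 2, 2.0, 1),
        ]
        sample = build_pooled_sample(recs)
        assert sample.n.tolist() == [3.0, 1.0]

    @settings(max_examples=30, deadline=None)
    @given(
        st.lists(
            st.tuples(
                st.floats(0.01, 100, allow_nan=False), st.integers(0, 1)
            ),
            min_size=2,
            max_size=40,
        ),
        st.sampled_from(["logrank", "gehan", "prentice"]),
    )
    def test_scores_sum_to_zero(self, data, scheme):
        recs = [SubjectRecord("c", 1, t, d) for t, d in data]
        sample = build_pooled_sample(recs)
        w = weighted_scores(sample, scheme)
        assert abs(w.sum()) <= 1e-10 * max(1.0, np.abs(w).max()) * len(recs)

    @pytest.mark.parametrize("scheme", ["logrank", "gehan", "prentice"])
    def test_rank_invariance_under_monotone_transform(self, scheme, rng):
        t = rng.exponential(size=25) + 0.05
        d = rng.integers(0, 2, size=25)
        d[0] = 1
        recs = [SubjectRecord("c", 1, ti, di) for ti, di in zip(t, d)]
        w1 = weighted_scores(build_pooled_sample(recs), scheme)
        recs2 = [SubjectRecord("c", 1, ti**3 + 2 * ti, di) for ti, di in zip(t, d)]
        w2 = weighted_scores(build_pooled_sample(recs2), scheme)
        assert w1 == pytest.approx(w2, rel=1e-10)

    def test_flipping_one_event_to_censored_is_local(self, rng):
        """Only terms at/after the flipped subject's time may change."""
        t = np.sort(rng.exponential(size=12) + 0.1)
        recs = [SubjectRecord("c", 1, ti, 1) for ti in t]
        w_before = weighted_scores(build_pooled_sample(recs), "logrank")
        flip = 7
        recs[flip] = SubjectRecord("c", 1, t[flip], 0)
        w_after = weighted_scores(build_pooled_sample(recs), "logrank")
        # subjects whose observed time is strictly before the flipped time
        # keep their score
        assert w_after[:flip] == pytest.approx(w_before[:flip], rel=1e-12)
        assert w_after[flip] != pytest.approx(w_before[flip])


class TestKaplanMeier:
    def test_left_continuous_values(self, three_event_records):
        s = km_left_continuous(build_pooled_sample(three_event_records))
        assert s(1.0) == 1.0
        assert s(2.0) == pytest.approx(2 / 3)
        assert s(3.0) == pytest.approx(1 / 3)
        assert s(0.5) == 1.0

    def test_all_censored_is_constant_one(self):
        recs = [SubjectRecord("A", 1, t, 0) for t in (1.0, 2.0)]
        s = km_left_continuous(build_pooled_sample(recs))
        assert s(5.0) == 1.0

    def test_against_lifelines(self, rng):
        lifelines = pytest.importorskip("lifelines")
        t = rng.exponential(size=60) + 0.01
        d = rng.integers(0, 2, size=60)
        d[:3] = 1
        kmf = lifelines.KaplanMeierFitter().fit(t, d)
        recs = [SubjectRecord("c", 1, ti, di) for ti, di in zip(t, d)]
        s = km_left_continuous(build_pooled_sample(recs))
        for tj in np.sort(t[d == 1])[1:]:
            expected = float(
                kmf.survival_function_at_times(tj - 1e-9).iloc[0]
            )
            assert s(tj) == pytest.approx(expected, rel=1e-6)


class TestClusterScores:
    def test_direct_summation(self):
        c = cluster_scores(np.array([2.0, 0.0, -2.0]), ["A", "A", "B"])
        assert c.scores == pytest.approx([2.0, -2.0])
        assert c.s2 == pytest.approx(4.0)
        assert c.cluster_ids == ["A", "B"]

    def test_identity_aggregation(self):
        w = np.array([1.0, -0.5, -0.5])
        c = cluster_scores(w, ["x", "y", "z"])
        assert c.scores == pytest.approx(w)

    def test_single_cluster_rejected(self):
        with pytest.raises(ValueError, match="two distinct clusters"):
            cluster_scores(np.array([1.0, -1.0]), ["A", "A"])

    def test_aggregation_conserves_total(self, rng):
        w = rng.normal(size=30)
        ids = rng.integers(0, 7, size=30)
        c = cluster_scores(w, list(ids))
        assert c.scores.sum() == pytest.approx(w.sum(), abs=1e-12)

    def test_array_path_matches_record_path(self, rng):
        t = rng.exponential(size=40) + 0.01
        d = rng.integers(0, 2, size=40)
        d[:2] = 1
        cl = rng.integers(0, 8, size=40)
        recs = [
            SubjectRecord(int(ci), 1, ti, int(di))
            for ci, ti, di in zip(cl, t, d)
        ]
        c_rec = scores_from_records(recs, "prentice")
        c_arr = scores_from_arrays(t, d, cl, "prentice")
        assert np.sort(c_rec.scores) == pytest.approx(np.sort(c_arr.scores))


class TestSubjectRecordValidation:
    def test_rejects_nonpositive_time(self):
        with pytest.raises(ValueError):
            SubjectRecord("A", 1, -1.0, 1)

    def test_rejects_bad_delta(self):
        with pytest.raises(ValueError):
            SubjectRecord("A", 1, 1.0, 2)

    def test_rejects_nonpositive_component(self):
        with pytest.raises(ValueError, match="component 2"):
            SubjectRecord("A", 1, 1.0, 1, components=(1.0, 0.0))
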