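import numpy as np
import pandas as pd
import pytest

from aquapos.evaluation import (
    EvalDomainError,
    ReferenceTrack,
    accuracy_report,
    inside_mesh,
    interpolate_track,
    match_space,
    match_spacetime,
    match_time,
    reconstruction_rate,
    threshold_distance,
)
from aquapos.geo import LocalPoint
from aquapos.tdoa import PositionFix


def fixes_frame(times, xy):
    xy = np.asarray(xy, dtype=float)
    return pd.DataFrame({"time": np.asarray(times, float),
                         "x": xy[:, 0], "y": xy[:, 1]})


def straight_ref(n=100, dt=5.0, speed=2.0):
    t = np.arange(n) * dt
    xy = np.column_stack([t * speed, np.zeros(n)])
    return ReferenceTrack(t, xy)


class TestMatchers:
    def test_identical_tracks_zero_error(self):
        ref = straight_ref()
        fx = fixes_frame(ref.times, ref.xy)
        for matcher in (match_space, match_time, match_spacetime):
            m = matcher(fx, ref)
            assert m["matched"].all()
            np.testing.assert_allclose(m["spatial_error"], 0.0)
            np.testing.assert_allclose(m["time_difference"], 0.0)

    def test_no_candidate_within_window_is_unmatched(self):
        ref = straight_ref(n=5, dt=5.0)
        fx = fixes_frame([1000.0], [[0.0, 0.0]])
        m = match_space(fx, ref, window=30.0)
        assert not m["matched"].iloc[0]

    def test_time_tie_goes_to_earlier_sample(self):
        ref = ReferenceTrack(np.array([0.0, 10.0]),
                             np.array([[0.0, 0.0], [100.0, 0.0]]))
        fx = fixes_frame([5.0], [[100.0, 0.0]])  # exactly between samples
        m = match_time(fx, ref)
        assert m["ref_index"].iloc[0] == 0

    def test_spacetime_combined_metric_arithmetic(self):
        # candidate (dd, dt) = (3, 4) combined 5 beats (6, 0) combined 6
        ref = ReferenceTrack(np.array([0.0, 4.0]),
                             np.array([[6.0, 0.0], [0.0, 3.0]]))
        fx = fixes_frame([0.0], [[0.0, 0.0]])
        m = match_spacetime(fx, ref)
        assert m["ref_index"].iloc[0] == 1

    def test_crossing_path_disambiguated_by_window(self):
        """At a self-intersection the spatially-nearest sample on the
        wrong pass lies outside the 30 s window, so the correct segment
        wins."""
        t = np.array([0.0, 50.0, 100.0, 150.0, 200.0])
        xy = np.array([[0.0, -100.0], [0.0, 0.0], [0.0, 100.0],
                       [-100.0, 0.0], [5.0, 0.0]])  # returns near origin at t=200
        ref = ReferenceTrack(t, xy)
        fx = fixes_frame([45.0], [[1.0, 0.0]])
        m = match_space(fx, ref, window=30.0)
        # nearest-in-space overall is the t=200 sample (1 m vs 4 m), but it
        # is 155 s away; the window restricts to the first pass
        assert m["ref_index"].iloc[0] == 1

    def test_dominance_ordering(self, rng):
        """space <= spacetime <= time on spatial error; reversed on time."""
        ref = straight_ref(n=200, dt=5.0)
        times = rng.uniform(0.0, ref.times[-1], 150)
        xy = np.column_stack([times * 2.0, np.zeros(150)])
        xy += rng.normal(0, 15.0, xy.shape)
        times_fix = times + rng.normal(0, 10.0, times.shape)
        fx = fixes_frame(times_fix, xy)
        ms = match_space(fx, ref, window=30.0)
        mt = match_time(fx, ref)
        mst = match_spacetime(fx, ref)
        # space vs spacetime are comparable only where the space-time match
        # itself lies inside the space window (same candidate set)
        both = ms["matched"] & (mst["time_difference"] <= 30.0)
        assert (ms.loc[both, "spatial_error"]
                <= mst.loc[both, "spatial_error"] + 1e-9).all()
        assert (mst["spatial_error"] <= mt["spatial_error"] + 1e-9).all()
        assert (mt["time_difference"]
                <= mst["time_difference"] + 1e-9).all()
        assert (mst.loc[both, "time_difference"]
                <= ms.loc[both, "time_difference"] + 1e-9).all()

    def test_empty_reference_rejected(self):
        with pytest.raises(EvalDomainError):
            ReferenceTrack(np.array([]), np.empty((0, 2)))


class TestAccuracyReport:
    def test_hand_arithmetic(self, triangle):
        ref = ReferenceTrack(np.array([0.0, 1.0, 2.0]), np.zeros((3, 2)))
        fx = fixes_frame([0.0, 1.0, 2.0], [[3, 0], [4, 0], [5, 0]])
        reports = accuracy_report(match_time(fx, ref), triangle)
        overall = reports["overall"]
        assert overall.mean_error_m == pytest.approx(4.0)
        assert overall.median_error_m == pytest.approx(4.0)
        assert overall.sd_error_m == pytest.approx(1.0)  # sample SD, n-1

    def test_centroid_fixes_all_inside(self, triangle):
        ref = ReferenceTrack(np.array([0.0, 1.0]), np.zeros((2, 2)))
        fx = fixes_frame([0.0, 1.0], [[0.0, 0.0], [1.0, 1.0]])
        reports = accuracy_report(match_time(fx, ref), triangle)
        assert reports["inside"].n == 2
        assert reports["outside"].n == 0

    def test_overall_mean_is_count_weighted_mixture(self, triangle, rng):
        n = 100
        xy = np.column_stack([rng.uniform(-400, 400, n),
                              rng.uniform(-400, 400, n)])
        ref = ReferenceTrack(np.arange(n, dtype=float),
                             xy + rng.normal(0, 5, xy.shape))
        fx = fixes_frame(np.arange(n, dtype=float), xy)
        reports = accuracy_report(match_time(fx, ref), triangle)
        o, i, u = reports["overall"], reports["inside"], reports["outside"]
        mix = (i.n * i.mean_error_m + u.n * u.mean_error_m) / (i.n + u.n)
        assert o.mean_error_m == pytest.approx(mix)

    def test_mesh_membership_boundary_inside(self, triangle):
        verts = np.array([[r.position.x, r.position.y] for r in triangle])
        edge_mid = (verts[0] + verts[1]) / 2.0
        assert inside_mesh(edge_mid, triangle).all()
        assert not inside_mesh(np.array([[1000.0, 1000.0]]), triangle).any()


class TestReconstructionRate:
    def test_lossless_pinger_rate_one(self, triangle):
        """One fix every 3 s fills each 21 s segment: rate exactly 1."""
        t = np.arange(0.0, 210.0, 3.0)
        ref = ReferenceTrack(np.array([0.0, 210.0]),
                             np.array([[0.0, 0.0], [420.0, 0.0]]))
        fx = fixes_frame(t, np.column_stack([t * 2.0, np.zeros(len(t))]))
        curve = reconstruction_rate(fx, ref, triangle)
        assert (curve["expected"] == 7).all()
        np.testing.assert_allclose(curve["rate"], 1.0)

    def test_dropping_to_three_per_segment(self, triangle):
        t = np.arange(0.0, 210.0, 3.0)
        keep = (t % 21.0) < 9.0  # 3 of every 7 emissions
        ref = ReferenceTrack(np.array([0.0, 210.0]),
                             np.array([[0.0, 0.0], [420.0, 0.0]]))
        fx = fixes_frame(t[keep], np.zeros((keep.sum(), 2)))
        curve = reconstruction_rate(fx, ref, triangle)
        np.testing.assert_allclose(curve["rate"], 3.0 / 7.0)

    def test_zero_fixes_zero_rate(self, triangle):
        ref = ReferenceTrack(np.array([0.0, 210.0]),
                             np.array([[0.0, 0.0], [420.0, 0.0]]))
        fx = fixes_frame([], np.empty((0, 2)))
        curve = reconstruction_rate(fx, ref, triangle)
        np.testing.assert_allclose(curve["rate"], 0.0)

    def test_segment_must_be_multiple_of_period(self, triangle):
        ref = ReferenceTrack(np.array([0.0, 210.0]), np.zeros((2, 2)))
        with pytest.raises(EvalDomainError):
            reconstruction_rate(fixes_frame([], np.empty((0, 2))), ref,
                                triangle, period=3.0, segment=20.0)

    def test_distance_is_to_farthest_receiver(self, triangle):
        ref = ReferenceTrack(np.array([0.0, 21.0]), np.zeros((2, 2)))
        curve = reconstruction_rate(fixes_frame([], np.empty((0, 2))),
                                    ref, triangle)
        rpos = np.array([[r.position.x, r.position.y] for r in triangle])
        dmax = np.max(np.linalg.norm(rpos, axis=1))
        assert curve["distance"].iloc[0] == pytest.approx(dmax, abs=1.0)

    def test_interpolation_step(self):
        ref = ReferenceTrack(np.array([0.0, 10.0]),
                             np.array([[0.0, 0.0], [10.0, 0.0]]))
        hi = interpolate_track(ref, step=1.0)
        assert len(hi.times) == 11
        np.testing.assert_allclose(hi.xy[:, 0], np.arange(11.0))


class TestThresholdDistance:
    def test_exact_linear_curve_closed_form(self):
        """rate(d) = 1 - d/500 crosses 1/3 at exactly 1000/3 m."""
        d = np.linspace(0.0, 450.0, 50)
        curve = pd.DataFrame({"distance": d, "rate": 1.0 - d / 500.0})
        res = threshold_distance(curve, threshold=1.0 / 3.0)
        assert res.crossed
        assert res.distance_m == pytest.approx(1000.0 / 3.0, abs=1e-6)

    def test_constant_rate_flagged(self):
        curve = pd.DataFrame({"distance": np.linspace(0, 400, 20),
                              "rate": np.ones(20)})
        res = threshold_distance(curve)
        assert not res.crossed
        assert np.isnan(res.distance_m)

    def test_noisy_linear_curve_recovered(self, rng):
        d = np.linspace(0.0, 450.0, 50)
        rate = 1.0 - d / 500.0 + rng.normal(0, 0.05, len(d))
        curve = pd.DataFrame({"distance": d, "rate": rate})
        res = threshold_distance(curve, threshold=1.0 / 3.0)
        assert res.crossed
        assert res.distance_m == pytest.approx(1000.0 / 3.0, rel=0.05)
        assert res.ci_low_m < res.distance_m < res.ci_high_m

    def test_fit_range_restricts_points(self):
        d = np.concatenate([np.linspace(0, 400, 40), [2000.0]])
        rate = np.concatenate([1.0 - np.linspace(0, 400, 40) / 500.0, [0.9]])
        curve = pd.DataFrame({"distance": d, "rate": rate})
        res = threshold_distance(curve, fit_range=(0.0, 429.5))
        assert res.distance_m == pytest.approx(1000.0 / 3.0, abs=1e-6)

    def test_too_few_points_rejected(self):
        curve = pd.DataFrame({"distance": [10.0], "rate": [1.0]})
        with pytest.raises(EvalDomainError):
            threshold_distance(curve)
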