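import itertools

import numpy as np
import pytest

from finwake.fields import vorticity
from finwake.synth import (gen_lamb_oseen, gen_solid_body_rotation,
                           gen_uniform_flow, gen_vortex_dipole,
                           lamb_oseen_partial_circulation)
from finwake.wake import (VortexCore, circulation, detect_cores, jet_angle,
                          pair_cores_to_ring, track_cores)


def _cores_from_series(series, frame=0, threshold=0.2):
    om = vorticity(series)
    return detect_cores(om.values[frame], om.valid[frame], series.x, series.y,
                        threshold, frame_index=frame)


class TestDetectCores:
    def test_single_vortex_partial_circulation(self):
        gamma, rc = 1e-3, None
        s, _ = gen_lamb_oseen([{"gamma": 1e-3, "rc": 4 * (0.15 / 127),
                                "centre": (0.0, 0.0)}], n=128, extent=0.15)
        rc = 4 * (0.15 / 127)
        cores = _cores_from_series(s, threshold=0.1)
        assert len(cores) == 1
        # |omega| >= 0.1 max falls at r_t with exp(-r_t^2/rc^2) = 0.1
        r_t = rc * np.sqrt(np.log(10.0))
        expected = lamb_oseen_partial_circulation(r_t, gamma, rc)
        assert abs(cores[0].circulation - expected) < 0.10 * expected

    def test_opposite_pair_detected_with_signs(self):
        s, _ = gen_lamb_oseen([
            {"gamma": 1e-3, "rc": 0.006, "centre": (-0.03, 0.0)},
            {"gamma": -1e-3, "rc": 0.006, "centre": (0.03, 0.0)},
        ], n=128, extent=0.15)
        cores = _cores_from_series(s)
        assert len(cores) == 2
        assert sorted(np.sign(c.circulation) for c in cores) == [-1, 1]

    def test_uniform_flow_yields_nothing(self):
        s, _ = gen_uniform_flow(0.05, n=64)
        assert _cores_from_series(s) == []

    def test_background_flow_invariance(self):
        core = {"gamma": 1e-3, "rc": 0.006, "centre": (0.0, 0.0)}
        s0, _ = gen_lamb_oseen([core], n=96, extent=0.15, background_U=0.0)
        s1, _ = gen_lamb_oseen([core], n=96, extent=0.15, background_U=0.08)
        c0 = _cores_from_series(s0)
        c1 = _cores_from_series(s1)
        assert len(c0) == len(c1) == 1
        assert c0[0].circulation == pytest.approx(c1[0].circulation, rel=1e-9)

    def test_threshold_fraction_contract(self):
        s, _ = gen_uniform_flow(0.05, n=32)
        om = vorticity(s)
        with pytest.raises(ValueError, match="threshold_fraction"):
            detect_cores(om.values[0], om.valid[0], s.x, s.y, 1.5)


class TestCirculation:
    def test_lamb_oseen_disk(self):
        gamma, rc = 1e-3, 0.015
        s, _ = gen_lamb_oseen([{"gamma": gamma, "rc": rc, "centre": (0, 0)}],
                              n=128, extent=0.15)
        om = vorticity(s).values[0]
        X, Y = np.meshgrid(s.x, s.y)
        region = np.hypot(X, Y) <= 2 * rc
        expected = gamma * (1 - np.exp(-4.0))
        assert circulation(om, region, s.dx, s.dy) == pytest.approx(
            expected, rel=0.02)

    def test_uniform_flow_zero(self):
        s, _ = gen_uniform_flow(0.05, n=32)
        om = vorticity(s).values[0]
        region = np.ones_like(om, bool)
        assert circulation(om, region, s.dx, s.dy) == 0.0

    def test_solid_body_disk(self):
        omega_rate, R = 2.0, 0.03
        s, _ = gen_solid_body_rotation(omega_rate, n=128, extent=0.1)
        om = vorticity(s).values[0]
        X, Y = np.meshgrid(s.x, s.y)
        region = np.hypot(X, Y) <= R
        expected = 2 * omega_rate * np.pi * R**2
        assert circulation(om, region, s.dx, s.dy) == pytest.approx(
            expected, rel=0.02)

    def test_additive_over_partition(self):
        rng = np.random.default_rng(0)
        om = rng.normal(size=(32, 32))
        left = np.zeros((32, 32), bool)
        left[:, :16] = True
        whole = np.ones((32, 32), bool)
        total = circulation(om, whole, 1e-3, 1e-3)
        parts = (circulation(om, left, 1e-3, 1e-3)
                 + circulation(om, ~left, 1e-3, 1e-3))
        assert total == pytest.approx(parts, abs=1e-15 * abs(total) + 1e-18)


def _core(x, y, gamma, frame=0):
    return VortexCore(centroid=np.array([x, y], dtype=float),
                      circulation=gamma, area=1e-5, peak_vorticity=1.0,
                      frame_index=frame)


class TestPairing:
    def test_pair_within_reach(self):
        rings, unpaired = pair_cores_to_ring(
            [_core(0, 0, 1e-3), _core(0.005, 0, -1e-3)], max_separation=0.01)
        assert len(rings) == 1 and not unpaired
        assert rings[0].separation == pytest.approx(0.005)

    def test_pair_beyond_reach(self):
        rings, unpaired = pair_cores_to_ring(
            [_core(0, 0, 1e-3), _core(0.005, 0, -1e-3)], max_separation=0.002)
        assert rings == [] and len(unpaired) == 2

    def test_three_colinear_matches_brute_force(self):
        cores = [_core(0, 0, 1e-3), _core(0.004, 0, -1e-3), _core(0.01, 0, 1e-3)]
        rings, unpaired = pair_cores_to_ring(cores, max_separation=0.02)
        # brute force over the two feasible (+,-) pairings
        pos = [c for c in cores if c.circulation > 0]
        neg = [c for c in cores if c.circulation < 0]
        best = min(itertools.product(pos, neg),
                   key=lambda ab: np.hypot(*(ab[0].centroid - ab[1].centroid)))
        assert len(rings) == 1 and len(unpaired) == 1
        assert rings[0].core_pair[0] is best[0]
        assert rings[0].core_pair[1] is best[1]


class TestJetAngle:
    @pytest.mark.parametrize("angle", [-45.0, 0.0])
    def test_prescribed_angle_recovered(self, angle):
        x, y, u, v, truth = gen_vortex_dipole(angle, seed=5, noise_frac=0.0)
        omega = (np.gradient(v, x[1] - x[0], axis=1)
                 - np.gradient(u, y[1] - y[0], axis=0))
        cores = detect_cores(omega, np.ones_like(omega, bool), x, y, 0.2)
        rings, _ = pair_cores_to_ring(cores, truth["separation"] * 2)
        assert len(rings) == 1
        got = jet_angle(u, v, x, y, rings[0], truth["body_axis"],
                        truth["medial_dir"])
        tol = 1.0 if angle == 0.0 else 2.0
        assert abs(got - angle) < tol

    def test_medial_jet_is_negative(self):
        x, y, u, v, truth = gen_vortex_dipole(-43.8, seed=0)
        omega = (np.gradient(v, x[1] - x[0], axis=1)
                 - np.gradient(u, y[1] - y[0], axis=0))
        cores = detect_cores(omega, np.ones_like(omega, bool), x, y, 0.2)
        rings, _ = pair_cores_to_ring(cores, truth["separation"] * 2)
        got = jet_angle(u, v, x, y, rings[0], truth["body_axis"],
                        truth["medial_dir"])
        assert got < 0

    def test_reflection_negates_angle(self):
        x, y, u, v, truth = gen_vortex_dipole(-30.0, seed=2, noise_frac=0.0)
        omega = (np.gradient(v, x[1] - x[0], axis=1)
                 - np.gradient(u, y[1] - y[0], axis=0))
        cores = detect_cores(omega, np.ones_like(omega, bool), x, y, 0.2)
        rings, _ = pair_cores_to_ring(cores, truth["separation"] * 2)
        a1 = jet_angle(u, v, x, y, rings[0], truth["body_axis"],
                       truth["medial_dir"])
        # mirror about the body axis (y -> -y), keep the medial convention
        um, vm = u[::-1].copy(), -v[::-1].copy()
        om_m = (np.gradient(vm, x[1] - x[0], axis=1)
                - np.gradient(um, y[1] - y[0], axis=0))
        cores_m = detect_cores(om_m, np.ones_like(om_m, bool), x, y, 0.2)
        rings_m, _ = pair_cores_to_ring(cores_m, truth["separation"] * 2)
        a2 = jet_angle(um, vm, x, y, rings_m[0], truth["body_axis"],
                       truth["medial_dir"])
        assert abs(a1 + a2) < 0.5

    def test_narrow_ring_rejected(self):
        x, y, u, v, truth = gen_vortex_dipole(-45.0, seed=0)
        rings, _ = pair_cores_to_ring(
            [_core(0, 0, 1e-3), _core(0.001, 0, -1e-3)], max_separation=0.01)
        with pytest.raises(ValueError, match="separation"):
            jet_angle(u, v, x, y, rings[0], truth["body_axis"],
                      truth["medial_dir"])


class TestTracking:
    def test_advected_core_velocity(self):
        adv = (0.01, 0.0)
        s, _ = gen_lamb_oseen(
            [{"gamma": 1e-3, "rc": 0.005, "centre": (-0.03, 0.0), "advect": adv}],
            n=128, extent=0.15, nt=10, frame_rate=100.0)
        om = vorticity(s)
        lists = [detect_cores(om.values[k], om.valid[k], s.x, s.y, 0.2,
                              frame_index=k) for k in range(10)]
        tracks, _ = track_cores(lists, max_step=0.002, frame_rate=100.0)
        assert len(tracks) == 1
        vel = tracks[0].mean_velocity(100.0)
        assert abs(vel[0] - 0.01) < 0.05 * 0.01
        assert abs(vel[1]) < 0.05 * 0.01

    def test_stationary_core(self):
        lists = [[_core(0.01, 0.02, 1e-3, frame=k)] for k in range(5)]
        tracks, _ = track_cores(lists, max_step=0.001, frame_rate=100.0)
        assert len(tracks) == 1
        assert np.abs(tracks[0].mean_velocity(100.0)).max() < 1e-12

    def test_crossing_opposite_cores_keep_identity(self):
        # +core moves right, -core moves left; they cross at frame 5
        lists = []
        for k in range(11):
            xp = -0.01 + k * 0.002
            xn = 0.01 - k * 0.002
            lists.append([_core(xp, 0.0, 1e-3, k), _core(xn, 1e-4, -1e-3, k)])
        tracks, _ = track_cores(lists, max_step=0.005, frame_rate=100.0)
        assert len(tracks) == 2
        for t in tracks:
            assert len(t.frames) == 11
            steps = np.diff(np.asarray(t.centroids)[:, 0])
            assert np.all(steps > 0) if t.sign > 0 else np.all(steps < 0)

    def test_interception_event(self):
        lists = [[_core(-0.02 + k * 0.005, 0.0, 1e-3, k)] for k in range(9)]
        tail = [np.array([[0.0, 0.0]])] * 9
        tracks, events = track_cores(lists, max_step=0.01, frame_rate=100.0,
                                     tail_points_per_frame=tail,
                                     interception_radius=0.002)
        assert len(events) == 1
        assert events[0]["frame"] == 4  # first within 2 mm of the tail point
        assert events[0]["interval_s"] == pytest.approx(0.04)

    def test_two_frames_required(self):
        with pytest.raises(ValueError, match="2 frames"):
            track_cores([[_core(0, 0, 1e-3)]], max_step=0.01)
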