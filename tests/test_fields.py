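import numpy as np
import pytest

from finwake.fields import (material_acceleration, read_velocity_series,
                            subtract_freestream, vorticity, divergence,
                            write_velocity_series)
from finwake.synth import (gen_lamb_oseen, gen_solid_body_rotation,
                           gen_uniform_flow, lamb_oseen_velocity, make_grid)


def _tiny_series(seed=0, nt=2, n=4):
    rng = np.random.default_rng(seed)
    s, _ = gen_uniform_flow(0.0, n=n, extent=0.01, nt=nt)
    s.u[:] = rng.normal(size=s.u.shape)
    s.v[:] = rng.normal(size=s.v.shape)
    s.mask[0, 1, 1] = True
    return s


class TestIO:
    @pytest.mark.parametrize("fmt", ["ascii", "csv", "h5"])
    def test_round_trip_lossless(self, tmp_path, fmt):
        s = _tiny_series()
        target = tmp_path / ("series.h5" if fmt == "h5" else "frames")
        paths = write_velocity_series(s, target, fmt=fmt)
        back = read_velocity_series(paths, {"frame_rate": s.frame_rate}, fmt=fmt)
        assert np.array_equal(back.u, s.u)
        assert np.array_equal(back.v, s.v)
        assert np.array_equal(back.mask, s.mask)
        assert np.array_equal(back.x, s.x)

    def test_reads_uniform_ascii_frames(self, tmp_path):
        for k in range(2):
            lines = ["x y u v"]
            for j in range(4):
                for i in range(4):
                    lines.append(f"{i*0.001} {j*0.001} 1.0 0.0")
            (tmp_path / f"f{k}.dat").write_text("\n".join(lines))
        s = read_velocity_series(
            [tmp_path / "f0.dat", tmp_path / "f1.dat"],
            {"frame_rate": 100.0}, fmt="ascii")
        assert s.nt == 2 and s.u.shape == (2, 4, 4)
        assert np.all(s.u == 1.0) and np.all(s.v == 0.0)

    def test_inconsistent_grid_rejected(self, tmp_path):
        def frame(nx, ny):
            lines = ["x y u v"]
            for j in range(ny):
                for i in range(nx):
                    lines.append(f"{i*0.001} {j*0.001} 0 0")
            return "\n".join(lines)

        (tmp_path / "a.dat").write_text(frame(4, 4))
        (tmp_path / "b.dat").write_text(frame(5, 4))
        with pytest.raises(ValueError, match="inconsistent grid"):
            read_velocity_series([tmp_path / "a.dat", tmp_path / "b.dat"],
                                 {"frame_rate": 100.0}, fmt="ascii")

    def test_missing_metadata_rejected(self, tmp_path):
        (tmp_path / "a.dat").write_text("x y u v\n0 0 0 0\n0.001 0 0 0\n"
                                        "0 0.001 0 0\n0.001 0.001 0 0")
        with pytest.raises(ValueError, match="frame_rate"):
            read_velocity_series([tmp_path / "a.dat"], {}, fmt="ascii")


class TestFreestream:
    def test_uniform_field_removed_exactly(self):
        s, _ = gen_uniform_flow(0.05, n=32, extent=0.05)
        out = subtract_freestream(s, (-0.02, -0.02, 0.02, 0.02))
        assert np.abs(out.u).max() < 1e-15
        assert np.abs(out.v).max() < 1e-15
        assert out.freestream_estimate == pytest.approx([-0.05, 0.0])

    def test_vortex_pair_survives_subtraction(self):
        # counter-rotating pair: far field decays like 1/r^2, so a distant
        # upstream window sees almost none of the structure
        rc = 2.5 * (0.15 / 127)
        sep = 4 * rc
        cores = [
            {"gamma": 1e-3, "rc": rc, "centre": (0.05, sep / 2)},
            {"gamma": -1e-3, "rc": rc, "centre": (0.05, -sep / 2)},
        ]
        s, _ = gen_lamb_oseen(cores, n=128, extent=0.15, background_U=0.05)
        out = subtract_freestream(s, (-0.074, -0.074, -0.055, 0.074))
        X, Y = np.meshgrid(s.x, s.y)
        ut = np.zeros_like(X)
        vt = np.zeros_like(X)
        for c in cores:
            du, dv = lamb_oseen_velocity(X, Y, c["gamma"], c["rc"], c["centre"])
            ut += du
            vt += dv
        peak = np.hypot(ut, vt).max()
        err = max(np.abs(out.u[0] - ut).max(), np.abs(out.v[0] - vt).max())
        assert err < 0.01 * peak

    def test_idempotent(self):
        s, _ = gen_lamb_oseen([{"gamma": 1e-3, "rc": 0.01, "centre": (0.03, 0)}],
                              n=64, extent=0.15, background_U=0.05)
        win = (-0.074, -0.074, -0.05, 0.074)
        once = subtract_freestream(s, win)
        twice = subtract_freestream(once, win)
        assert np.abs(twice.freestream_estimate).max() < 1e-12 * 0.05

    def test_masked_window_rejected(self):
        s, _ = gen_uniform_flow(0.05, n=32, extent=0.05)
        s.mask[:, :16, :16] = True
        with pytest.raises(ValueError, match="masked"):
            subtract_freestream(s, (-0.024, -0.024, -0.01, -0.01))

    def test_window_outside_grid_rejected(self):
        s, _ = gen_uniform_flow(0.05, n=32, extent=0.05)
        with pytest.raises(ValueError, match="outside"):
            subtract_freestream(s, (1.0, 1.0, 2.0, 2.0))


class TestVorticity:
    def test_solid_body_rotation_gives_twice_omega(self):
        s, _ = gen_solid_body_rotation(2.0, n=64, extent=0.1)
        om = vorticity(s)
        interior = om.values[0][1:-1, 1:-1]
        assert np.abs(interior - 4.0).max() < 1e-10

    def test_uniform_flow_is_irrotational(self):
        s, _ = gen_uniform_flow(0.05, n=32)
        assert np.abs(vorticity(s).values).max() == 0.0

    def test_lamb_oseen_matches_closed_form(self):
        rc = 0.15 / 8  # domain spans +-4 rc
        s, truth = gen_lamb_oseen(
            [{"gamma": 1e-3, "rc": rc, "centre": (0.0, 0.0)}], n=128, extent=0.15)
        om = vorticity(s)
        X, Y = np.meshgrid(s.x, s.y)
        r = np.hypot(X, Y)
        expected = truth["omega"](r, 1e-3, rc)
        sel = r <= 2 * rc
        err = np.abs(om.values[0][sel] - expected[sel]) / expected.max()
        assert err.max() < 0.02

    def test_linearity(self):
        a, b = 2.5, -1.3
        s1 = _tiny_series(seed=1, n=16)
        s2 = _tiny_series(seed=2, n=16)
        s3 = _tiny_series(seed=3, n=16)
        s3.u = a * s1.u + b * s2.u
        s3.v = a * s1.v + b * s2.v
        lhs = vorticity(s3).values
        rhs = a * vorticity(s1).values + b * vorticity(s2).values
        assert np.abs(lhs - rhs).max() < 1e-12 * max(1.0, np.abs(rhs).max())

    def test_small_grid_rejected(self):
        s, _ = gen_uniform_flow(0.0, n=4, extent=0.01)
        s2, _ = gen_uniform_flow(0.0, n=4, extent=0.01)
        small = type(s)(x=s.x[:2], y=s.y, times=s.times, u=s.u[:, :, :2],
                        v=s.v[:, :, :2], mask=s.mask[:, :, :2],
                        frame_rate=s.frame_rate)
        with pytest.raises(ValueError, match="3x3"):
            vorticity(small)

    def test_mask_neighbourhood_invalidated(self):
        s = _tiny_series(n=16)
        om = vorticity(s)
        assert not om.valid[0, 1, 1]
        assert not om.valid[0, 2, 2]  # diagonal neighbour
        assert om.valid[0, 5, 5]

    def test_incompressible_flow_divergence_small(self):
        rc = 0.15 / 8
        s, _ = gen_lamb_oseen(
            [{"gamma": 1e-3, "rc": rc, "centre": (0.0, 0.0)}], n=128, extent=0.15)
        dv = divergence(s).values
        om = vorticity(s).values
        assert np.sqrt((dv**2).mean()) < 0.02 * np.sqrt((om**2).mean())


class TestMaterialAcceleration:
    def test_steady_uniform_flow_has_none(self):
        s, _ = gen_uniform_flow(0.05, n=32)
        acc = material_acceleration(s, 1)
        assert np.abs(acc.values).max() < 1e-14

    def test_solid_body_rotation_centripetal(self):
        omega = 2.0
        s, _ = gen_solid_body_rotation(omega, n=64, extent=0.1)
        acc = material_acceleration(s, 1)
        X, Y = np.meshgrid(s.x, s.y)
        r = np.hypot(X, Y)
        mag = np.hypot(acc.values[..., 0], acc.values[..., 1])
        sel = (r > 0.002) & (r < 0.025)  # within half-domain, off-centre
        rel = np.abs(mag[sel] - omega**2 * r[sel]) / (omega**2 * r[sel])
        assert rel.max() < 0.02
        # inward: a . r_hat < 0
        dots = (acc.values[..., 0] * X + acc.values[..., 1] * Y)[sel]
        assert np.all(dots < 0)

    def test_translating_vortex_matches_analytic_oracle(self):
        adv = (0.02, 0.0)
        gamma, rc = 1e-3, 0.008
        s, truth = gen_lamb_oseen(
            [{"gamma": gamma, "rc": rc, "centre": (0.0, 0.0), "advect": adv}],
            n=128, extent=0.12, nt=3, frame_rate=2000.0)
        acc = material_acceleration(s, 1)
        # oracle: for a structure translating at c, Du/Dt = ((u - c).grad) u,
        # evaluated by high-precision differencing of the analytic closure
        t1 = 1.0 / 2000.0
        X, Y = np.meshgrid(s.x, s.y)
        h = 1e-7

        def vel(Xq, Yq):
            return truth["velocity"](Xq, Yq, t=t1)

        u0, v0 = vel(X, Y)
        ux = (vel(X + h, Y)[0] - vel(X - h, Y)[0]) / (2 * h)
        uy = (vel(X, Y + h)[0] - vel(X, Y - h)[0]) / (2 * h)
        vx = (vel(X + h, Y)[1] - vel(X - h, Y)[1]) / (2 * h)
        vy = (vel(X, Y + h)[1] - vel(X, Y - h)[1]) / (2 * h)
        ax = (u0 - adv[0]) * ux + (v0 - adv[1]) * uy
        ay = (u0 - adv[0]) * vx + (v0 - adv[1]) * vy
        amax = np.hypot(ax, ay).max()
        inner = np.zeros(ax.shape, bool)
        inner[2:-2, 2:-2] = True
        err = np.hypot(acc.values[..., 0] - ax, acc.values[..., 1] - ay)
        assert err[inner].max() / amax < 0.03

    def test_first_frame_needs_one_sided(self):
        s, _ = gen_uniform_flow(0.05, n=16)
        with pytest.raises(ValueError, match="one.sided"):
            material_acceleration(s, 0, one_sided=False)
        acc = material_acceleration(s, 0, one_sided=True)
        assert np.abs(acc.values).max() < 1e-14
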