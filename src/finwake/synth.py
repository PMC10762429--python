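"""Synthetic flows, bodies and fin traces with analytic ground truth.

Every input the analysis chain consumes can be generated here, together with
the exact quantity the corresponding pipeline stage should recover:

* uniform flow and solid-body rotation (trivial derivative oracles);
* Lamb–Oseen vortices, whose swirl, vorticity, partial circulation and
  radial pressure profile have closed forms;
* potential flow past a circular cylinder, whose pressure coefficient
  Cp(r,θ) = 2(R/r)²cos2θ − (R/r)⁴ (→ 1 − 4sin²θ on the surface) is the
  standard oracle for pressure solvers, with d'Alembert's zero net drag as a
  force-integration identity;
* counter-rotating vortex pairs with a prescribed central-jet direction;
* fin-tip traces with prescribed frequencies, amplitudes and phases;
* a "virtual swimmer": a rigid elliptical body with a pitching tail plate
  whose surface pressure pattern is prescribed analytically, so that tail
  thrust, lateral power and hydrodynamic efficiency have quadrature truths.

Default acquisition geometry emulates a high-speed PIV experiment on a
~9 cm fish: 128 × 128 vectors per frame at 1000 frames/s, swimming at
0.3–2.0 body lengths per second. Regenerating any scenario with the same
seed and parameters reproduces bitwise-identical fields.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import integrate, ndimage

from .fields import VelocityFrameSeries, _DILATE_STRUCT
from .gait import FinTrace
from .pressure import PressureField
from .surface import BodyOutline, outline_from_points

__all__ = [
    "make_grid",
    "gen_uniform_flow",
    "gen_solid_body_rotation",
    "gen_lamb_oseen",
    "lamb_oseen_velocity",
    "lamb_oseen_vorticity",
    "lamb_oseen_partial_circulation",
    "lamb_oseen_pressure",
    "gen_cylinder_potential_flow",
    "gen_vortex_dipole",
    "gen_fin_traces",
    "gen_swimmer_scenario",
    "SwimmerScenario",
]

DEFAULT_N = 128
DEFAULT_FPS = 1000.0
DEFAULT_BL = 0.09  # metres


def make_grid(n: int = DEFAULT_N, extent: float = 0.15, centre=(0.0, 0.0)):
    """Uniform node-centred grid: n × n nodes spanning ``extent`` metres."""
    x = centre[0] + np.linspace(-extent / 2, extent / 2, n)
    y = centre[1] + np.linspace(-extent / 2, extent / 2, n)
    return x, y


def _series(x, y, u, v, mask=None, frame_rate=DEFAULT_FPS, U=0.0,
            body_length=DEFAULT_BL) -> VelocityFrameSeries:
    nt = u.shape[0]
    if mask is None:
        mask = np.zeros_like(u, dtype=bool)
    return VelocityFrameSeries(
        x=x, y=y, times=np.arange(nt) / frame_rate, u=u, v=v, mask=mask,
        frame_rate=frame_rate, swim_axis=np.array([1.0, 0.0]),
        freestream_speed=U, body_length=body_length)


# ---------------------------------------------------------------------------
# Elementary flows
# ---------------------------------------------------------------------------

def gen_uniform_flow(U: float, n: int = DEFAULT_N, extent: float = 0.15,
                     nt: int = 3, frame_rate: float = DEFAULT_FPS):
    """Uniform free stream of speed U toward −x (the fish faces +x).

    Truth: p ≡ 0, ω ≡ 0.
    """
    if not np.isfinite(U):
        raise ValueError("U must be finite")
    x, y = make_grid(n, extent)
    u = np.full((nt, n, n), -U)
    v = np.zeros((nt, n, n))
    truth = {"u": lambda X, Y: np.full_like(X, -U),
             "v": lambda X, Y: np.zeros_like(X),
             "omega": lambda X, Y: np.zeros_like(X),
             "p": lambda X, Y: np.zeros_like(X)}
    return _series(x, y, u, v, frame_rate=frame_rate, U=U), truth


def gen_solid_body_rotation(omega_rate: float, n: int = DEFAULT_N,
                            extent: float = 0.15, nt: int = 3,
                            frame_rate: float = DEFAULT_FPS):
    """Solid-body rotation at rate Ω about the origin: ω ≡ 2Ω."""
    x, y = make_grid(n, extent)
    X, Y = np.meshgrid(x, y)
    u = np.broadcast_to(-omega_rate * Y, (nt, n, n)).copy()
    v = np.broadcast_to(omega_rate * X, (nt, n, n)).copy()
    truth = {"omega": lambda X, Y: np.full_like(X, 2 * omega_rate),
             "accel_mag": lambda X, Y: omega_rate**2 * np.hypot(X, Y)}
    return _series(x, y, u, v, frame_rate=frame_rate), truth


# ---------------------------------------------------------------------------
# Lamb–Oseen vortices
# ---------------------------------------------------------------------------

def lamb_oseen_velocity(X, Y, gamma, rc, centre=(0.0, 0.0)):
    """Velocity components of a Lamb–Oseen vortex (Γ, core radius r_c)."""
    dxv = X - centre[0]
    dyv = Y - centre[1]
    r2 = dxv**2 + dyv**2
    with np.errstate(divide="ignore", invalid="ignore"):
        vt_over_r = gamma / (2 * np.pi * r2) * (1.0 - np.exp(-r2 / rc**2))
    vt_over_r = np.where(r2 == 0, 0.0, vt_over_r)
    return -vt_over_r * dyv, vt_over_r * dxv


def lamb_oseen_vorticity(r, gamma, rc):
    """ω(r) = Γ/(π r_c²) exp(−r²/r_c²)."""
    return gamma / (np.pi * rc**2) * np.exp(-np.asarray(r) ** 2 / rc**2)


def lamb_oseen_partial_circulation(r, gamma, rc):
    """Circulation enclosed within radius r: Γ(1 − exp(−r²/r_c²))."""
    return gamma * (1.0 - np.exp(-np.asarray(r) ** 2 / rc**2))


def lamb_oseen_pressure(r, gamma, rc, rho=998.0):
    """Radial pressure profile p(r) = −ρ ∫_r^∞ v_θ(s)²/s ds (quadrature).

    Gauge: p → 0 as r → ∞. Accepts scalars or arrays.
    """
    def vt(s):
        return gamma / (2 * np.pi * s) * (1.0 - np.exp(-s**2 / rc**2))

    def one(ri):
        val, _ = integrate.quad(lambda s: vt(s) ** 2 / s, max(ri, 1e-12 * rc),
                                np.inf, limit=200)
        return -rho * val

    return np.vectorize(one)(r)


def gen_lamb_oseen(cores, n: int = DEFAULT_N, extent: float = 0.15,
                   nt: int = 3, frame_rate: float = DEFAULT_FPS,
                   background_U: float = 0.0):
    """Superposed Lamb–Oseen vortices, optionally advected frame to frame.

    ``cores`` is a list of dicts with keys ``gamma`` (m²/s), ``rc`` (m),
    ``centre`` (x, y) and optional ``advect`` (velocity (cx, cy), m/s).
    Background free stream (toward −x) of speed ``background_U`` is added.
    """
    x, y = make_grid(n, extent)
    X, Y = np.meshgrid(x, y)
    u = np.empty((nt, n, n))
    v = np.empty((nt, n, n))
    for k in range(nt):
        t = k / frame_rate
        uk = np.full((n, n), -background_U)
        vk = np.zeros((n, n))
        for c in cores:
            adv = np.asarray(c.get("advect", (0.0, 0.0)), dtype=float)
            ctr = np.asarray(c["centre"], dtype=float) + adv * t
            du, dv = lamb_oseen_velocity(X, Y, c["gamma"], c["rc"], ctr)
            uk += du
            vk += dv
        u[k] = uk
        v[k] = vk

    def u_fn(Xq, Yq, t=0.0):
        uq = np.full_like(np.asarray(Xq, dtype=float), -background_U)
        vq = np.zeros_like(uq)
        for c in cores:
            adv = np.asarray(c.get("advect", (0.0, 0.0)), dtype=float)
            ctr = np.asarray(c["centre"], dtype=float) + adv * t
            du, dv = lamb_oseen_velocity(Xq, Yq, c["gamma"], c["rc"], ctr)
            uq += du
            vq += dv
        return uq, vq

    truth = {
        "velocity": u_fn,
        "omega": lamb_oseen_vorticity,
        "partial_circulation": lamb_oseen_partial_circulation,
        "pressure": lamb_oseen_pressure,
        "cores": cores,
    }
    return _series(x, y, u, v, frame_rate=frame_rate, U=background_U), truth


# ---------------------------------------------------------------------------
# Cylinder potential flow
# ---------------------------------------------------------------------------

def gen_cylinder_potential_flow(U: float, D: float, n: int = DEFAULT_N,
                                extent: float | None = None, nt: int = 3,
                                rho: float = 998.0,
                                flow_axis: str = "x"):
    """Steady potential flow (speed U toward −x) past a masked cylinder.

    Truth: p(x, y) = ½ρ(U² − |V|²) with gauge zero at infinity, i.e.
    Cp = 2(R/r)²cos2θ − (R/r)⁴, which is 1 − 4 sin²θ on the surface.
    ``flow_axis="y"`` rotates the whole scenario by 90° (for equivariance
    checks). The domain defaults to 8 diameters so the boundary is far from
    the body.
    """
    R = D / 2.0
    if extent is None:
        extent = 8.0 * D
    x, y = make_grid(n, extent)
    dx = x[1] - x[0]
    if D < 8 * dx:
        raise ValueError("cylinder must span at least 8 grid cells")
    if extent / 2 - R < 1.5 * D:
        raise ValueError("cylinder needs at least 1.5 D clearance to the boundary")
    X, Y = np.meshgrid(x, y)

    def vel(Xq, Yq):
        if flow_axis == "y":
            Xr, Yr = Yq, -Xq  # rotate coordinates by -90°
        else:
            Xr, Yr = Xq, Yq
        r2 = Xr**2 + Yr**2
        with np.errstate(divide="ignore", invalid="ignore"):
            ur = -U * (1 - R**2 * (Xr**2 - Yr**2) / r2**2)
            vr = -U * (-2 * R**2 * Xr * Yr / r2**2)
        inside = r2 < R**2
        ur = np.where(inside, 0.0, ur)
        vr = np.where(inside, 0.0, vr)
        if flow_axis == "y":
            return -vr, ur  # rotate the vector field back by +90°
        return ur, vr

    def p_fn(Xq, Yq):
        uq, vq = vel(Xq, Yq)
        return 0.5 * rho * (U**2 - (uq**2 + vq**2))

    u1, v1 = vel(X, Y)
    mask1 = X**2 + Y**2 < R**2
    u = np.broadcast_to(u1, (nt, n, n)).copy()
    v = np.broadcast_to(v1, (nt, n, n)).copy()
    mask = np.broadcast_to(mask1, (nt, n, n)).copy()
    series = _series(x, y, u, v, mask=mask, U=U)
    truth = {
        "velocity": vel,
        "pressure": p_fn,
        "cp_surface": lambda theta: 1 - 4 * np.sin(theta) ** 2,
        "cp": lambda Xq, Yq: p_fn(Xq, Yq) / (0.5 * rho * U**2),
        "R": R, "rho": rho, "U": U,
    }
    return series, truth


# ---------------------------------------------------------------------------
# Vortex-pair jets
# ---------------------------------------------------------------------------

def gen_vortex_dipole(jet_angle_deg: float, seed: int = 0, n: int = DEFAULT_N,
                      extent: float = 0.06, gamma: float = 1.0e-3,
                      rc: float | None = None, separation: float | None = None,
                      noise_frac: float = 0.02, side: int = 1):
    """Counter-rotating Lamb–Oseen pair with a prescribed central-jet angle.

    The angle is measured from the caudal direction (−x for a fish facing
    +x), negative = medial. The structure sits on the ``side`` (+1 = above)
    of the midline y = 0, so medial is −side·ŷ. Per-seed randomisation:
    centre jitter and additive velocity noise (``noise_frac`` of the peak jet
    speed). Truth carries the prescribed angle, axis conventions and core
    placement.
    """
    rng = np.random.default_rng(seed)
    x, y = make_grid(n, extent)
    dx = x[1] - x[0]
    if rc is None:
        rc = 4 * dx
    if separation is None:
        separation = 10 * dx
    caudal = np.array([-1.0, 0.0])
    medial = np.array([0.0, -float(side)])
    lateral = -medial
    ang = np.radians(jet_angle_deg)
    jet_dir = np.cos(ang) * caudal + np.sin(ang) * lateral
    n_hat = np.array([-jet_dir[1], jet_dir[0]])
    centre = (np.array([0.0, side * 0.02 * extent / 0.06])
              + rng.uniform(-1.5, 1.5, 2) * dx)
    c_pos = centre + (separation / 2) * n_hat  # +Γ on the +n̂ side → jet along ĵ
    c_neg = centre - (separation / 2) * n_hat
    X, Y = np.meshgrid(x, y)
    u, v = lamb_oseen_velocity(X, Y, gamma, rc, c_pos)
    du, dv = lamb_oseen_velocity(X, Y, -gamma, rc, c_neg)
    u += du
    v += dv
    peak_jet = gamma / (np.pi * separation / 2) if separation > 0 else 1.0
    u += rng.normal(0.0, noise_frac * peak_jet, u.shape)
    v += rng.normal(0.0, noise_frac * peak_jet, v.shape)
    truth = {
        "jet_angle_deg": jet_angle_deg,
        "body_axis": np.array([1.0, 0.0]),
        "medial_dir": medial,
        "centre": centre,
        "separation": separation,
        "gamma": gamma, "rc": rc,
    }
    return x, y, u, v, truth


# ---------------------------------------------------------------------------
# Fin traces
# ---------------------------------------------------------------------------

def gen_fin_traces(freq_pectoral: float = 2.5, freq_caudal: float | None = None,
                   amp_pectoral: float = 0.008, amp_caudal: float = 0.007,
                   phase_lr_deg: float = 180.0, phase_pc_deg: float = 70.0,
                   noise_sd: float = 0.0, duration: float = 4.0,
                   fs: float = 200.0, seed: int = 0,
                   body_length: float = DEFAULT_BL):
    """Sinusoidal left/right pectoral and caudal fin-tip traces.

    ``phase_lr_deg`` is the right fin's lag behind the left (anti-phase =
    180°); ``phase_pc_deg`` the caudal fin's lag behind the left pectoral.
    Additive Gaussian displacement noise with sd ``noise_sd`` metres.
    Truth records the prescribed phases, frequencies and amplitudes.
    """
    if freq_caudal is None:
        freq_caudal = freq_pectoral
    rng = np.random.default_rng(seed)
    t = np.arange(int(round(duration * fs))) / fs
    wp = 2 * np.pi * freq_pectoral
    wc = 2 * np.pi * freq_caudal
    left = amp_pectoral * np.sin(wp * t)
    right = amp_pectoral * np.sin(wp * t - np.radians(phase_lr_deg))
    caudal = amp_caudal * np.sin(wc * t - np.radians(phase_pc_deg))
    if noise_sd > 0:
        left = left + rng.normal(0, noise_sd, t.shape)
        right = right + rng.normal(0, noise_sd, t.shape)
        caudal = caudal + rng.normal(0, noise_sd, t.shape)
    traces = (
        FinTrace(times=t, displacement=left, fin_id="pectoral_left",
                 body_length=body_length),
        FinTrace(times=t, displacement=right, fin_id="pectoral_right",
                 body_length=body_length),
        FinTrace(times=t, displacement=caudal, fin_id="caudal",
                 body_length=body_length),
    )
    truth = {
        "phase_lr_deg": phase_lr_deg % 360.0,
        "phase_pc_deg": phase_pc_deg % 360.0,
        "freq_pectoral": freq_pectoral,
        "freq_caudal": freq_caudal,
        "amp_pectoral": amp_pectoral,
        "amp_caudal": amp_caudal,
    }
    return traces, truth


# ---------------------------------------------------------------------------
# Virtual swimmer
# ---------------------------------------------------------------------------

@dataclass
class SwimmerScenario:
    """A kinematically scripted swimmer with analytic surface pressure.

    The body is a rigid ellipse; the tail is a thin plate pitching about the
    caudal peduncle with angle θ(t) = θ₀ sin(ωt). Surface pressure on the
    plate is prescribed as ±P₀ cos(ωt − ψ) sin²(πξ) on the two faces (ξ the
    normalised chordwise coordinate), extruded as a constant along the plate
    normal over a band wider than the sampling offset, so that sampled face
    pressures equal the prescribed closure exactly. All resultants in
    ``truth`` (net thrust, positive-thrust mean, lateral power, efficiency)
    are computed by fine quadrature of the same closures over the analytic
    plate faces — independent of the gridded/outline pipeline under test.
    """

    x: np.ndarray
    y: np.ndarray
    times: np.ndarray
    frame_rate: float
    freestream_speed: float
    body_length: float
    outlines: list
    masks: np.ndarray
    pressure_fields: list
    fin_traces: tuple | None
    truth: dict
    params: dict = field(default_factory=dict)


def _swimmer_geometry(params, t):
    """Plate geometry at time t: returns dict of instantaneous vectors."""
    th = params["theta0"] * np.sin(params["omega"] * t)
    thd = params["theta0"] * params["omega"] * np.cos(params["omega"] * t)
    d_hat = np.array([-np.cos(th), -np.sin(th)])
    n_hat = np.array([-np.sin(th), np.cos(th)])
    P0 = params["P0"]
    Lp = params["Lp"]
    w = params["w"]
    Tp = P0 + Lp * d_hat + (w / 2) * n_hat
    Tm = P0 + Lp * d_hat - (w / 2) * n_hat
    dT_common = Lp * thd * np.array([np.sin(th), -np.cos(th)])
    dT_cross = (w / 2) * thd * np.array([-np.cos(th), -np.sin(th)])
    return {
        "theta": th, "theta_dot": thd, "d_hat": d_hat, "n_hat": n_hat,
        "Tp": Tp, "Tm": Tm, "dTp": dT_common + dT_cross,
        "dTm": dT_common - dT_cross,
        "S": np.cos(params["omega"] * t - params["psi"]),
    }


def _swimmer_quadrature(params, n_t=1024, n_s=512):
    """Cycle-average thrust and lateral power of the plate by quadrature."""
    omega = params["omega"]
    T = 2 * np.pi / omega
    ts = (np.arange(n_t) + 0.5) * T / n_t
    lam = (np.arange(n_s) + 0.5) / n_s
    Fax = np.empty(n_t)
    Plat = np.empty(n_t)
    Lp = params["Lp"]
    amp = params["pressure_amp"]
    Jp, Jm = params["Jp"], params["Jm"]
    for i, t in enumerate(ts):
        g = _swimmer_geometry(params, t)
        fax = 0.0
        plat = 0.0
        for sgn, J, Tt, dT in ((1.0, Jp, g["Tp"], g["dTp"]),
                               (-1.0, Jm, g["Tm"], g["dTm"])):
            e = Tt - J
            ds = np.hypot(*e) / n_s
            e_hat = e / np.hypot(*e)
            nf = np.array([e_hat[1], -e_hat[0]])
            if np.dot(nf, sgn * g["n_hat"]) < 0:
                nf = -nf
            r = J[None, :] + lam[:, None] * e[None, :]
            xi = np.clip(((r - params["P0"]) @ g["d_hat"]) / Lp, 0.0, 1.0)
            p = sgn * amp * g["S"] * np.sin(np.pi * xi) ** 2
            vel = lam[:, None] * dT[None, :]
            f = -p[:, None] * nf[None, :] * ds  # N/m per quadrature segment
            fax += f[:, 0].sum()
            plat += np.abs(f[:, 1] * vel[:, 1]).sum()
        Fax[i] = fax
        Plat[i] = plat
    return {
        "thrust_mean": float(Fax.mean()),
        "thrust_pos_mean": float(np.maximum(Fax, 0.0).mean()),
        "p_lat_mean": float(Plat.mean()),
        "thrust_peak": float(Fax.max()),
    }


def gen_swimmer_scenario(seed: int = 0, eta_star: float | None = None,
                         body_length: float = DEFAULT_BL, n: int = DEFAULT_N,
                         extent: float = 0.15, frames_per_cycle: int = 64,
                         n_cycles: int = 1, tail_freq: float | None = None,
                         theta0: float | None = None,
                         pressure_amp: float | None = None,
                         psi_deg: float | None = None,
                         phase_lr_deg: float = 180.0,
                         phase_pc_deg: float = 70.0) -> SwimmerScenario:
    """Generate a virtual swimmer with a prescribed tail efficiency η*.

    Unspecified kinematic parameters are drawn from realistic ranges using
    ``seed``; the free-stream (swimming) speed is then solved so that the
    quadrature efficiency equals ``eta_star`` (drawn from [0.1, 0.6] when
    None). Emits per-frame outlines with landmarks, body masks, gridded
    pressure fields, fin traces and the quadrature truth record.
    """
    rng = np.random.default_rng(seed)
    if eta_star is None:
        eta_star = float(rng.uniform(0.1, 0.6))
    if tail_freq is None:
        tail_freq = float(rng.uniform(2.0, 4.0))
    if theta0 is None:
        theta0 = float(rng.uniform(0.20, 0.38))
    if pressure_amp is None:
        pressure_amp = float(rng.uniform(2.0, 8.0))
    if psi_deg is None:
        psi_deg = float(rng.uniform(40.0, 80.0))

    x, y = make_grid(n, extent)
    dx = float(x[1] - x[0])
    # body ellipse: snout at +x, peduncle at -x vertex
    a_body = 0.375 * body_length
    b_body = 0.12 * body_length
    cx = 0.012
    P0 = np.array([cx - a_body, 0.0])
    Lp = 0.25 * body_length
    w = 3.5 * dx
    # fixed junction points on the ellipse at y = ±w/2
    xj = cx - a_body * np.sqrt(max(0.0, 1.0 - (w / (2 * b_body)) ** 2))
    Jp = np.array([xj, +w / 2])
    Jm = np.array([xj, -w / 2])

    params = {
        "P0": P0, "Lp": Lp, "w": w, "Jp": Jp, "Jm": Jm,
        "theta0": theta0, "omega": 2 * np.pi * tail_freq,
        "psi": np.radians(psi_deg), "pressure_amp": pressure_amp,
        "a_body": a_body, "b_body": b_body, "cx": cx,
        "band_flat": w / 2 + 5 * dx, "band_out": w / 2 + 9 * dx,
    }
    quad = _swimmer_quadrature(params)
    A = quad["thrust_pos_mean"]
    B = quad["p_lat_mean"]
    U = eta_star * B / ((1.0 - eta_star) * A) if A > 0 else 0.0

    frame_rate = frames_per_cycle * tail_freq
    nt = frames_per_cycle * n_cycles
    times = np.arange(nt) / frame_rate
    X, Y = np.meshgrid(x, y)

    outlines = []
    masks = np.empty((nt, n, n), dtype=bool)
    pressure_fields = []
    # ellipse boundary vertices (excluding the tail gap between junctions)
    phi_j = np.arctan2((w / 2) / b_body, (xj - cx) / a_body)
    # long way round: upper junction -> snout (phi = 0) -> lower junction
    phis = np.linspace(phi_j, -phi_j, 220)
    ell = np.column_stack([cx + a_body * np.cos(phis),
                           b_body * np.sin(phis)])
    snout_xy = np.array([cx + a_body, 0.0])
    ellipse_interior = ((X - cx) / a_body) ** 2 + (Y / b_body) ** 2 < 1.0

    n_seg = None  # fixed after frame 0 so all outlines correspond segmentwise
    for k, t in enumerate(times):
        g = _swimmer_geometry(params, t)
        tip_mid = P0 + Lp * g["d_hat"]
        # closed polyline: upper junction -> ellipse (over snout) -> lower
        # junction -> lower face -> tip cap -> upper face -> close
        pts = np.vstack([
            Jp, ell, Jm, g["Tm"], g["Tp"], Jp,
        ])
        outline = outline_from_points(
            pts, spacing=dx,
            landmarks_xy={
                "snout": snout_xy,
                "caudal_peduncle": Jp,
                "superior_lobe_tip": tip_mid,
            },
            frame_index=k,
            n_points=n_seg,
        )
        if n_seg is None:
            n_seg = outline.n_segments
        outlines.append(outline)

        xi = ((X - P0[0]) * g["d_hat"][0] + (Y - P0[1]) * g["d_hat"][1]) / Lp
        dn = (X - P0[0]) * g["n_hat"][0] + (Y - P0[1]) * g["n_hat"][1]
        in_chord = (xi >= -0.05) & (xi <= 1.02)
        plate_interior = (xi >= 0.0) & (xi <= 1.0) & (np.abs(dn) <= w / 2)
        mask = ellipse_interior | plate_interior
        masks[k] = mask

        adn = np.abs(dn)
        decay = np.where(
            adn <= params["band_flat"], 1.0,
            np.where(adn >= params["band_out"], 0.0,
                     0.5 * (1 + np.cos(np.pi * (adn - params["band_flat"])
                                       / (params["band_out"] - params["band_flat"])))))
        p = (pressure_amp * g["S"] * np.sign(dn)
             * np.sin(np.pi * np.clip(xi, 0.0, 1.0)) ** 2
             * decay * in_chord)
        valid = ~ndimage.binary_dilation(mask, structure=_DILATE_STRUCT)
        pressure_fields.append(PressureField(
            x=x, y=y, p=np.where(valid, p, 0.0), valid=valid, frame_index=k))

    trace_duration = max(4.0 / tail_freq, nt / frame_rate)
    fin_traces, trace_truth = gen_fin_traces(
        freq_pectoral=tail_freq, amp_pectoral=0.09 * body_length,
        amp_caudal=float(Lp * np.sin(theta0)), phase_lr_deg=phase_lr_deg,
        phase_pc_deg=phase_pc_deg, duration=trace_duration, fs=frame_rate,
        seed=seed, body_length=body_length)

    eta_truth = (U * A) / (U * A + B) if (U * A + B) > 0 else 0.0
    truth = {
        "eta_star": float(eta_star),
        "eta_quadrature": float(eta_truth),
        "thrust_mean": quad["thrust_mean"],
        "thrust_pos_mean": A,
        "p_lat_mean": B,
        "U": float(U),
        "theta0": theta0, "tail_freq": tail_freq,
        "pressure_amp": pressure_amp, "psi_deg": psi_deg,
        **trace_truth,
        "gait_label": "PCF" if theta0 > 0 else "MPF",
    }
    return SwimmerScenario(
        x=x, y=y, times=times, frame_rate=frame_rate, freestream_speed=float(U),
        body_length=body_length, outlines=outlines, masks=masks,
        pressure_fields=pressure_fields, fin_traces=fin_traces, truth=truth,
        params=params)
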