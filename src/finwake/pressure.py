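"""Gauge pressure from 2D velocity fields by multi-path gradient integration.

The pressure gradient is evaluated from the 2D Navier–Stokes momentum balance,

    ∇p = −ρ Du/Dt + μ ∇²u,

on every node clear of the (dilated) body mask, and pressure is recovered by
integrating ∇p along straight rays from the domain boundary — where gauge
pressure is taken as the zero reference — toward each node. Eight rays per
node (the compass directions of the grid) are integrated; rays that cross the
dilated body mask are discarded, and the node's pressure is the median of the
surviving ray integrals. Median polling makes the estimate robust to locally
corrupted gradients. Nodes shadowed on all eight directions are filled by
relaxation from valid neighbours, consistent with the local gradient.

This mirrors the multi-directional integration strategy of validated
pressure-from-PIV codes; it is verified here against closed-form pressure
fields (potential flow past a cylinder, Lamb–Oseen vortex quadrature).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .fields import VelocityFrameSeries, material_acceleration, _DILATE_STRUCT

__all__ = ["PressureField", "solve_pressure", "pressure_gradient"]

#: eight ray propagation directions (di, dj): boundary -> node sweep direction
_DIRECTIONS = [
    (0, 1), (0, -1), (1, 0), (-1, 0),
    (1, 1), (1, -1), (-1, 1), (-1, -1),
]


@dataclass
class PressureField:
    """Gauge pressure (Pa) on the velocity grid for one frame."""

    x: np.ndarray
    y: np.ndarray
    p: np.ndarray  # (ny, nx), Pa, gauge (ambient = 0 at the boundary reference)
    valid: np.ndarray  # (ny, nx) boolean
    frame_index: int
    rho: float = 998.0
    mu: float = 1.0e-3

    @property
    def dx(self) -> float:
        return float(self.x[1] - self.x[0])

    @property
    def dy(self) -> float:
        return float(self.y[1] - self.y[0])


def _laplacian(f: np.ndarray, dx: float, dy: float) -> np.ndarray:
    """5-point Laplacian with edge replication (edges are excluded anyway)."""
    fp = np.pad(f, 1, mode="edge")
    d2x = (fp[1:-1, 2:] - 2 * f + fp[1:-1, :-2]) / dx**2
    d2y = (fp[2:, 1:-1] - 2 * f + fp[:-2, 1:-1]) / dy**2
    return d2x + d2y


def pressure_gradient(
    series: VelocityFrameSeries, frame_index: int, rho: float, mu: float,
    one_sided: bool = True,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Return (gpx, gpy, valid): ∇p from momentum balance at one frame."""
    acc = material_acceleration(series, frame_index, one_sided=one_sided)
    u, v, _ = series.frame(frame_index)
    lap_u = _laplacian(u, series.dx, series.dy)
    lap_v = _laplacian(v, series.dx, series.dy)
    gpx = -rho * acc.values[..., 0] + mu * lap_u
    gpy = -rho * acc.values[..., 1] + mu * lap_v
    return gpx, gpy, acc.valid


def _sweep(gpx, gpy, blocked, di, dj, dx, dy):
    """Cumulative trapezoid line integral of ∇p·dl along direction (di, dj).

    Integration starts at the boundary edge the sweep enters from (p = 0
    reference) and propagates node by node. Returns (p, valid) where a node is
    valid when the whole ray back to the boundary avoids blocked nodes.
    """
    ny, nx = gpx.shape
    # reduce to di, dj in {0, 1} by flipping axes (and gradient signs)
    flip_y, flip_x = di < 0, dj < 0
    sx = -1.0 if flip_x else 1.0
    sy = -1.0 if flip_y else 1.0
    gx = gpx[::-1] if flip_y else gpx
    gx = gx[:, ::-1] if flip_x else gx
    gy = gpy[::-1] if flip_y else gpy
    gy = gy[:, ::-1] if flip_x else gy
    blk = blocked[::-1] if flip_y else blocked
    blk = blk[:, ::-1] if flip_x else blk
    adi, adj = abs(di), abs(dj)
    step_x = adj * dx * sx
    step_y = adi * dy * sy
    g_proj = gx * step_x + gy * step_y  # ∇p·Δl at each node
    p = np.zeros((ny, nx))
    ok = ~blk

    if adi == 0:  # pure x sweep: cumulative along axis 1
        inc = 0.5 * (g_proj[:, 1:] + g_proj[:, :-1])
        p[:, 1:] = np.cumsum(inc, axis=1)
        valid = np.logical_and.accumulate(ok, axis=1)
    elif adj == 0:
        inc = 0.5 * (g_proj[1:, :] + g_proj[:-1, :])
        p[1:, :] = np.cumsum(inc, axis=0)
        valid = np.logical_and.accumulate(ok, axis=0)
    else:  # diagonal sweep, row-by-row recurrence
        valid = np.zeros((ny, nx), dtype=bool)
        valid[0] = ok[0]
        for i in range(1, ny):
            p[i, 1:] = p[i - 1, :-1] + 0.5 * (g_proj[i, 1:] + g_proj[i - 1, :-1])
            valid[i, 1:] = valid[i - 1, :-1] & ok[i, 1:]
            valid[i, 0] = ok[i, 0]

    if flip_x:
        p, valid = p[:, ::-1], valid[:, ::-1]
    if flip_y:
        p, valid = p[::-1], valid[::-1]
    return p, valid


def _ray_pressure_stack(gpx, gpy, blocked, dx, dy, n_paths):
    """Per-direction boundary-anchored integrals; (n_paths, ny, nx) + validity."""
    dirs = _DIRECTIONS[:n_paths]
    ps, vs = [], []
    for di, dj in dirs:
        p_d, v_d = _sweep(gpx, gpy, blocked, di, dj, dx, dy)
        ps.append(p_d)
        vs.append(v_d)
    return np.stack(ps), np.stack(vs)


def _relax_fill(p, known, target, gpx, gpy, dx, dy, max_iter=500, tol=1e-10):
    """Fill ``target`` nodes by gradient-consistent relaxation from neighbours."""
    p = p.copy()
    filled = known.copy()
    todo = target & ~known
    if not todo.any():
        return p, filled
    scale = max(1.0, np.nanmax(np.abs(p[known])) if known.any() else 1.0)
    for _ in range(max_iter):
        pn = np.pad(p, 1, mode="edge")
        fn = np.pad(filled, 1, mode="constant")
        est = np.zeros_like(p)
        wsum = np.zeros_like(p)
        # 4-neighbour predictions: p_i = p_j + 0.5 (g_i + g_j)·(x_i − x_j)
        for oi, oj in ((0, 1), (0, -1), (1, 0), (-1, 0)):
            pj = pn[1 + oi:1 + oi + p.shape[0], 1 + oj:1 + oj + p.shape[1]]
            fj = fn[1 + oi:1 + oi + p.shape[0], 1 + oj:1 + oj + p.shape[1]]
            gj_x = np.roll(gpx, (-oi, -oj), axis=(0, 1))
            gj_y = np.roll(gpy, (-oi, -oj), axis=(0, 1))
            step_x = -oj * dx  # x_i − x_j
            step_y = -oi * dy
            pred = pj + 0.5 * ((gpx + gj_x) * step_x + (gpy + gj_y) * step_y)
            w = fj.astype(float)
            est += pred * w
            wsum += w
        upd = todo & (wsum > 0)
        if not upd.any():
            break
        new = est[upd] / wsum[upd]
        delta = np.max(np.abs(new - p[upd])) if filled[todo].any() else np.inf
        p[upd] = new
        newly = upd & ~filled
        filled |= upd
        if not newly.any() and delta < tol * scale:
            break
    return p, filled


def solve_pressure(
    series: VelocityFrameSeries,
    frame_index: int,
    rho: float = 998.0,
    mu: float = 1.0e-3,
    n_paths: int = 8,
    p_ref: float = 0.0,
    one_sided_time: bool = True,
) -> PressureField:
    """Solve for the gauge pressure field at one frame.

    Parameters
    ----------
    rho, mu : fluid density (kg/m³) and dynamic viscosity (Pa·s); defaults are
        fresh water at ~21 °C.
    n_paths : number of boundary rays polled per node (4–8; default 8).
    p_ref : pressure assigned to the boundary reference (gauge zero by
        default); added uniformly to the result.

    Raises
    ------
    ValueError if rho is nonpositive, n_paths < 4, or the geometry leaves more
    than 20% of fluid nodes with no unobstructed ray.
    """
    if rho <= 0:
        raise ValueError("rho must be positive")
    if not 4 <= n_paths <= 8:
        raise ValueError("n_paths must be between 4 and 8")
    gpx, gpy, grad_valid = pressure_gradient(series, frame_index, rho, mu, one_sided_time)
    mask = series.mask[frame_index]
    blocked = ndimage.binary_dilation(mask, structure=_DILATE_STRUCT)
    fluid = ~blocked
    # gradient is untrusted wherever blocked; zero it there for the arithmetic
    gpx = np.where(blocked, 0.0, gpx)
    gpy = np.where(blocked, 0.0, gpy)

    stack, vstack = _ray_pressure_stack(gpx, gpy, blocked, series.dx, series.dy, n_paths)
    n_ok = vstack.sum(axis=0)
    no_ray = fluid & (n_ok == 0)
    if fluid.sum() and no_ray.sum() > 0.2 * fluid.sum():
        raise ValueError("geometry unsuitable: all rays obstructed for >20% of fluid nodes")
    import warnings
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN shadow nodes
        pm = np.where(vstack, stack, np.nan)
        p = np.nanmedian(pm, axis=0)
    p = np.where(n_ok > 0, p, 0.0)

    if no_ray.any():
        p, filled = _relax_fill(p, fluid & (n_ok > 0), no_ray, gpx, gpy,
                                series.dx, series.dy)
        valid = fluid & filled
    else:
        valid = fluid & (n_ok > 0)
    p = np.where(valid, p + p_ref, 0.0)
    return PressureField(x=series.x, y=series.y, p=p, valid=valid,
                         frame_index=frame_index, rho=rho, mu=mu)
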