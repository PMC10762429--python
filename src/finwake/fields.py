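"""Gridded 2D velocity-field series: I/O, free-stream subtraction, derived fields.

The central container is :class:`VelocityFrameSeries`, a time-resolved pair of
velocity components (u, v) on a uniform node-centred Cartesian grid, with a
per-frame boolean mask marking body/invalid nodes. Physical units are SI
throughout (metres, seconds). The swimming axis points rostrally (the
direction the fish faces), so in a flume the free stream has a negative
projection on ``swim_axis`` and thrust is positive along it.
"""

from __future__ import annotations

import io
import os
from dataclasses import dataclass, field, replace

import h5py
import numpy as np
from scipy import ndimage

__all__ = [
    "VelocityFrameSeries",
    "FieldSeries",
    "read_velocity_series",
    "write_velocity_series",
    "subtract_freestream",
    "vorticity",
    "divergence",
    "material_acceleration",
]

_DILATE_STRUCT = np.ones((3, 3), dtype=bool)  # 8-connected, 1-node band


@dataclass
class VelocityFrameSeries:
    """Time series of 2D velocity fields on a uniform grid.

    Attributes
    ----------
    x, y : (nx,), (ny,) arrays, metres, strictly increasing, uniform spacing.
    times : (nt,) array, seconds, spacing 1/frame_rate.
    u, v : (nt, ny, nx) arrays, m/s.
    mask : (nt, ny, nx) boolean, True = body/invalid node.
    frame_rate : frames per second.
    swim_axis : unit vector (2,) in grid coordinates, pointing rostrally.
    freestream_speed : magnitude of the free-stream/swimming speed, m/s.
    body_length : fish body length, metres (optional, for normalisation).
    """

    x: np.ndarray
    y: np.ndarray
    times: np.ndarray
    u: np.ndarray
    v: np.ndarray
    mask: np.ndarray
    frame_rate: float
    swim_axis: np.ndarray = field(default_factory=lambda: np.array([1.0, 0.0]))
    freestream_speed: float = 0.0
    body_length: float | None = None
    freestream_estimate: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        self.u = np.asarray(self.u, dtype=float)
        self.v = np.asarray(self.v, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        self.swim_axis = np.asarray(self.swim_axis, dtype=float)
        nt, ny, nx = self.u.shape
        if self.v.shape != (nt, ny, nx) or self.mask.shape != (nt, ny, nx):
            raise ValueError("u, v and mask must share one (nt, ny, nx) shape")
        if self.x.shape != (nx,) or self.y.shape != (ny,):
            raise ValueError("x/y coordinate lengths inconsistent with fields")
        if self.times.shape != (nt,):
            raise ValueError("times length inconsistent with fields")
        for name, c in (("x", self.x), ("y", self.y)):
            d = np.diff(c)
            if c.size > 1:
                if not np.all(d > 0):
                    raise ValueError(f"{name} coordinates must be strictly increasing")
                if np.max(np.abs(d - d[0])) > 1e-9 * abs(d[0]):
                    raise ValueError(f"non-uniform {name} grid spacing")
        if nt > 1:
            dt = np.diff(self.times)
            if not np.all(dt > 0):
                raise ValueError("times must be strictly increasing")
            if np.max(np.abs(dt - 1.0 / self.frame_rate)) > 1e-6 / self.frame_rate:
                raise ValueError("time spacing inconsistent with frame_rate")
        n = float(np.hypot(*self.swim_axis))
        if not np.isclose(n, 1.0, atol=1e-9):
            raise ValueError("swim_axis must be a unit vector")

    @property
    def nx(self) -> int:
        return self.x.size

    @property
    def ny(self) -> int:
        return self.y.size

    @property
    def nt(self) -> int:
        return self.times.size

    @property
    def dx(self) -> float:
        return float(self.x[1] - self.x[0]) if self.x.size > 1 else 1.0

    @property
    def dy(self) -> float:
        return float(self.y[1] - self.y[0]) if self.y.size > 1 else 1.0

    def frame(self, k: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Return (u, v, mask) for frame ``k``."""
        return self.u[k], self.v[k], self.mask[k]


@dataclass
class FieldSeries:
    """A derived scalar/vector field series with a per-node validity flag."""

    values: np.ndarray  # (nt, ny, nx) or (nt, ny, nx, 2)
    valid: np.ndarray  # (nt, ny, nx) boolean


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

_COLUMN_ALIASES = {"x": "x", "y": "y", "u": "u", "v": "v", "mask": "mask"}


def _parse_frame_table(text: str, delim: str | None) -> dict[str, np.ndarray]:
    lines = text.strip().splitlines()
    if not lines:
        raise ValueError("empty velocity file")
    header = lines[0].replace(",", " ").split()
    cols = [h.strip().lower() for h in header]
    for required in ("x", "y", "u", "v"):
        if required not in cols:
            raise ValueError(f"header must name column '{required}', got {cols}")
    body = "\n".join(lines[1:])
    data = np.loadtxt(io.StringIO(body.replace(",", " ")))
    data = np.atleast_2d(data)
    if data.shape[1] != len(cols):
        raise ValueError("column count does not match header")
    return {c: data[:, i] for i, c in enumerate(cols)}


def _frame_from_columns(cols: dict[str, np.ndarray]):
    x = np.unique(cols["x"])
    y = np.unique(cols["y"])
    nx, ny = x.size, y.size
    if nx * ny != cols["x"].size:
        raise ValueError("scattered (non-gridded) points in velocity file")
    # row-major y-then-x ordering
    order = np.lexsort((cols["x"], cols["y"]))
    u = cols["u"][order].reshape(ny, nx)
    v = cols["v"][order].reshape(ny, nx)
    if "mask" in cols:
        m = cols["mask"][order].reshape(ny, nx) > 0.5
    else:
        m = np.zeros((ny, nx), dtype=bool)
    return x, y, u, v, m


def read_velocity_series(paths, meta: dict, fmt: str | None = None) -> VelocityFrameSeries:
    """Read a velocity series from per-frame ASCII/CSV files or a single HDF5.

    Parameters
    ----------
    paths : list of file paths (one per frame) for ascii/csv, or a single
        HDF5 path (string or 1-list) written by :func:`write_velocity_series`.
    meta : dict with at least ``frame_rate`` (Hz) for delimited formats;
        optional keys ``swim_axis``, ``freestream_speed``, ``body_length``,
        ``t0``. Ignored keys present in the HDF5 attributes win for h5 input.
    fmt : "ascii", "csv" or "h5"; inferred from the extension when None.
    """
    if isinstance(paths, (str, os.PathLike)):
        paths = [paths]
    paths = [os.fspath(p) for p in paths]
    if not paths:
        raise ValueError("no input files")
    if fmt is None:
        ext = os.path.splitext(paths[0])[1].lower()
        fmt = {"h5": "h5", "hdf5": "h5", "csv": "csv"}.get(ext.lstrip("."), "ascii")
    for p in paths:
        if not os.path.exists(p):
            raise FileNotFoundError(p)

    if fmt == "h5":
        with h5py.File(paths[0], "r") as f:
            x = f["x"][()]
            y = f["y"][()]
            t = f["t"][()]
            u = f["u"][()]
            v = f["v"][()]
            m = f["mask"][()].astype(bool)
            attrs = dict(f.attrs)
        return VelocityFrameSeries(
            x=x, y=y, times=t, u=u, v=v, mask=m,
            frame_rate=float(attrs.get("frame_rate", meta.get("frame_rate", 1.0))),
            swim_axis=np.asarray(attrs.get("swim_axis", meta.get("swim_axis", (1.0, 0.0)))),
            freestream_speed=float(attrs.get("freestream_speed", meta.get("freestream_speed", 0.0))),
            body_length=attrs.get("body_length", meta.get("body_length", None)),
        )

    if "frame_rate" not in meta:
        raise ValueError("missing scaling metadata: frame_rate is required")
    frames = []
    grid = None
    for p in paths:
        with open(p) as fh:
            cols = _parse_frame_table(fh.read(), "," if fmt == "csv" else None)
        x, y, u, v, m = _frame_from_columns(cols)
        if grid is None:
            grid = (x, y)
        else:
            if x.shape != grid[0].shape or y.shape != grid[1].shape or \
                    not (np.allclose(x, grid[0]) and np.allclose(y, grid[1])):
                raise ValueError(f"inconsistent grid across frames: {p}")
        frames.append((u, v, m))
    u = np.stack([f[0] for f in frames])
    v = np.stack([f[1] for f in frames])
    m = np.stack([f[2] for f in frames])
    fr = float(meta["frame_rate"])
    t0 = float(meta.get("t0", 0.0))
    times = t0 + np.arange(len(paths)) / fr
    return VelocityFrameSeries(
        x=grid[0], y=grid[1], times=times, u=u, v=v, mask=m, frame_rate=fr,
        swim_axis=np.asarray(meta.get("swim_axis", (1.0, 0.0)), dtype=float),
        freestream_speed=float(meta.get("freestream_speed", 0.0)),
        body_length=meta.get("body_length", None),
    )


def write_velocity_series(series: VelocityFrameSeries, target, fmt: str = "h5") -> list[str]:
    """Write a series; returns the list of files written.

    ``fmt="h5"`` writes one file (``target`` is its path); "ascii"/"csv"
    write one file per frame under directory ``target``
    (``frame_0000.dat``/``.csv``).
    """
    if fmt == "h5":
        with h5py.File(target, "w") as f:
            f["x"] = series.x
            f["y"] = series.y
            f["t"] = series.times
            f["u"] = series.u
            f["v"] = series.v
            f["mask"] = series.mask.astype(np.uint8)
            f.attrs["dx"] = series.dx
            f.attrs["dy"] = series.dy
            f.attrs["frame_rate"] = series.frame_rate
            f.attrs["freestream_speed"] = series.freestream_speed
            f.attrs["swim_axis"] = series.swim_axis
            if series.body_length is not None:
                f.attrs["body_length"] = series.body_length
        return [os.fspath(target)]
    os.makedirs(target, exist_ok=True)
    sep = "," if fmt == "csv" else " "
    ext = "csv" if fmt == "csv" else "dat"
    X, Y = np.meshgrid(series.x, series.y)
    written = []
    for k in range(series.nt):
        path = os.path.join(target, f"frame_{k:04d}.{ext}")
        with open(path, "w") as fh:
            fh.write(sep.join(["x", "y", "u", "v", "mask"]) + "\n")
            rows = np.column_stack([
                X.ravel(), Y.ravel(), series.u[k].ravel(), series.v[k].ravel(),
                series.mask[k].ravel().astype(float),
            ])
            for r in rows:
                fh.write(sep.join(f"{val:.17g}" for val in r) + "\n")
        written.append(path)
    return written


# ---------------------------------------------------------------------------
# Free-stream subtraction
# ---------------------------------------------------------------------------

def _window_slices(series: VelocityFrameSeries, window) -> tuple[slice, slice]:
    x0, y0, x1, y1 = window
    if x1 < x0:
        x0, x1 = x1, x0
    if y1 < y0:
        y0, y1 = y1, y0
    ix = np.flatnonzero((series.x >= x0) & (series.x <= x1))
    iy = np.flatnonzero((series.y >= y0) & (series.y <= y1))
    if ix.size == 0 or iy.size == 0:
        raise ValueError("upstream window lies outside the grid")
    return slice(iy[0], iy[-1] + 1), slice(ix[0], ix[-1] + 1)


def subtract_freestream(series: VelocityFrameSeries, upstream_window) -> VelocityFrameSeries:
    """Subtract the time-average mean velocity over an upstream window.

    ``upstream_window`` is a physical rectangle (x0, y0, x1, y1) in metres.
    The subtracted vector is stored on the returned copy as
    ``freestream_estimate`` and its magnitude as ``freestream_speed``.
    """
    sy, sx = _window_slices(series, upstream_window)
    uw = series.u[:, sy, sx]
    vw = series.v[:, sy, sx]
    mw = series.mask[:, sy, sx]
    n_unmasked = (~mw).reshape(series.nt, -1).sum(axis=1)
    if np.any(n_unmasked == 0):
        raise ValueError("upstream window fully masked in at least one frame")
    if np.any(n_unmasked < 10):
        raise ValueError("upstream window has fewer than 10 unmasked nodes in a frame")
    free = ~mw
    mean_u = float(uw[free].mean())
    mean_v = float(vw[free].mean())
    est = np.array([mean_u, mean_v])
    out = replace(
        series,
        u=series.u - mean_u,
        v=series.v - mean_v,
        freestream_speed=float(np.hypot(mean_u, mean_v)),
    )
    out.freestream_estimate = est
    return out


# ---------------------------------------------------------------------------
# Derived fields
# ---------------------------------------------------------------------------

def _derived_valid(mask: np.ndarray) -> np.ndarray:
    """Valid region for derivative-based fields: 1 node clear of the mask."""
    if mask.ndim == 2:
        return ~ndimage.binary_dilation(mask, structure=_DILATE_STRUCT)
    return np.stack([
        ~ndimage.binary_dilation(mask[k], structure=_DILATE_STRUCT)
        for k in range(mask.shape[0])
    ])


def vorticity(series: VelocityFrameSeries) -> FieldSeries:
    """ω = ∂v/∂x − ∂u/∂y, central differences interior, one-sided at edges.

    Nodes within one node of the body mask are flagged invalid.
    """
    if series.nx < 3 or series.ny < 3:
        raise ValueError("grid must be at least 3x3 for vorticity")
    dvdx = np.gradient(series.v, series.dx, axis=2)
    dudy = np.gradient(series.u, series.dy, axis=1)
    return FieldSeries(values=dvdx - dudy, valid=_derived_valid(series.mask))


def divergence(series: VelocityFrameSeries) -> FieldSeries:
    """∂u/∂x + ∂v/∂y with the same stencils as :func:`vorticity` (diagnostic)."""
    dudx = np.gradient(series.u, series.dx, axis=2)
    dvdy = np.gradient(series.v, series.dy, axis=1)
    return FieldSeries(values=dudx + dvdy, valid=_derived_valid(series.mask))


def material_acceleration(
    series: VelocityFrameSeries, frame_index: int, one_sided: bool = False
) -> FieldSeries:
    """Du/Dt = ∂u/∂t + (u·∇)u at one frame, m/s².

    Central in time; the first/last frame require ``one_sided=True`` and use a
    first-order one-sided time difference (lower confidence). Returns a
    vector FieldSeries with values shaped (ny, nx, 2).
    """
    k = frame_index
    nt = series.nt
    if k < 0 or k >= nt:
        raise IndexError("frame_index out of range")
    fr = series.frame_rate
    if 1 <= k <= nt - 2:
        dudt = (series.u[k + 1] - series.u[k - 1]) * (fr / 2.0)
        dvdt = (series.v[k + 1] - series.v[k - 1]) * (fr / 2.0)
    elif nt == 1:
        dudt = np.zeros_like(series.u[0])
        dvdt = np.zeros_like(series.v[0])
    elif one_sided:
        if k == 0:
            dudt = (series.u[1] - series.u[0]) * fr
            dvdt = (series.v[1] - series.v[0]) * fr
        else:
            dudt = (series.u[-1] - series.u[-2]) * fr
            dvdt = (series.v[-1] - series.v[-2]) * fr
    else:
        raise ValueError(
            "central time difference unavailable at first/last frame; "
            "pass one_sided=True to use a one-sided fallback"
        )
    u, v, mask = series.frame(k)
    dudy, dudx = np.gradient(u, series.dy, series.dx)
    dvdy, dvdx = np.gradient(v, series.dy, series.dx)
    ax = dudt + u * dudx + v * dudy
    ay = dvdt + u * dvdx + v * dvdy
    return FieldSeries(values=np.stack([ax, ay], axis=-1), valid=_derived_valid(mask))
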