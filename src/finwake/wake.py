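"""Vortex-core detection, circulation, ring pairing, jet angles and tracking.

Cores are connected components of |ω| above a fraction of the per-frame peak
vorticity, excluding the boundary-layer band along the body (the dilated
mask): wall shear produces measurable vorticity that is not a shed vortex.
A counter-rotating core pair is the planar cross-section of a vortex ring;
the central jet between the cores carries the ring's momentum. Jet angles
are measured relative to the rostro-caudal axis and signed negative when the
jet points medially (toward the body midline) — the convention in which a
pectoral-fin jet aimed at the tail has a negative angle.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

__all__ = [
    "VortexCore",
    "VortexRingSection",
    "detect_cores",
    "circulation",
    "pair_cores_to_ring",
    "jet_angle",
    "track_cores",
]


@dataclass
class VortexCore:
    centroid: np.ndarray  # (x, y) metres, |ω|-weighted
    circulation: float  # m²/s, signed
    area: float  # m²
    peak_vorticity: float  # s⁻¹, max |ω| in the region
    frame_index: int = 0
    id: int = -1


@dataclass
class VortexRingSection:
    core_pair: tuple  # (positive core, negative core)
    midpoint: np.ndarray
    separation: float
    jet_angle_deg: float | None = None
    mean_jet_speed: float | None = None


@dataclass
class Track:
    id: int
    frames: list = field(default_factory=list)
    centroids: list = field(default_factory=list)
    sign: int = 0

    def mean_velocity(self, frame_rate: float) -> np.ndarray:
        if len(self.centroids) < 2:
            return np.zeros(2)
        c = np.asarray(self.centroids)
        dt = (self.frames[-1] - self.frames[0]) / frame_rate
        return (c[-1] - c[0]) / dt if dt > 0 else np.zeros(2)


def detect_cores(
    omega: np.ndarray,
    valid: np.ndarray,
    x: np.ndarray,
    y: np.ndarray,
    threshold_fraction: float = 0.2,
    frame_index: int = 0,
    min_cells: int = 4,
) -> list[VortexCore]:
    """Detect vortex cores as thresholded connected components of |ω|.

    ``valid`` should already exclude the dilated body mask so that
    boundary-layer vorticity along the body is not reported as a core.
    """
    if not 0 < threshold_fraction < 1:
        raise ValueError("threshold_fraction must be in (0, 1)")
    omega = np.asarray(omega, dtype=float)
    if omega.size == 0:
        raise ValueError("empty vorticity field")
    dx = float(x[1] - x[0])
    dy = float(y[1] - y[0])
    absw = np.where(valid, np.abs(omega), 0.0)
    peak = absw.max()
    if peak == 0:
        return []
    above = absw >= threshold_fraction * peak
    # split by sign so touching counter-rotating cores stay distinct
    cores: list[VortexCore] = []
    for sign in (1, -1):
        lab, nlab = ndimage.label(above & (np.sign(omega) == sign))
        for i in range(1, nlab + 1):
            reg = lab == i
            if reg.sum() < min_cells:
                continue
            w = omega[reg]
            aw = np.abs(w)
            rows, cols = np.nonzero(reg)
            cx = float(np.average(x[cols], weights=aw))
            cy = float(np.average(y[rows], weights=aw))
            cores.append(VortexCore(
                centroid=np.array([cx, cy]),
                circulation=float(w.sum() * dx * dy),
                area=float(reg.sum() * dx * dy),
                peak_vorticity=float(aw.max()),
                frame_index=frame_index,
            ))
    cores.sort(key=lambda c: -abs(c.circulation))
    for i, c in enumerate(cores):
        c.id = i
    return cores


def circulation(omega: np.ndarray, region: np.ndarray, dx: float, dy: float) -> float:
    """Area integral of ω over a boolean region, m²/s."""
    region = np.asarray(region, dtype=bool)
    if region.shape != omega.shape:
        raise ValueError("region must match the vorticity field shape")
    return float(omega[region].sum() * dx * dy)


def pair_cores_to_ring(
    cores: list[VortexCore], max_separation: float
) -> tuple[list[VortexRingSection], list[VortexCore]]:
    """Greedy nearest-first pairing of opposite-sign cores.

    Returns (ring sections, unpaired cores).
    """
    pos = [c for c in cores if c.circulation > 0]
    neg = [c for c in cores if c.circulation < 0]
    pairs = []
    for i, cp in enumerate(pos):
        for j, cn in enumerate(neg):
            d = float(np.hypot(*(cp.centroid - cn.centroid)))
            if d <= max_separation:
                pairs.append((d, i, j))
    pairs.sort()
    used_p, used_n = set(), set()
    rings = []
    for d, i, j in pairs:
        if i in used_p or j in used_n:
            continue
        used_p.add(i)
        used_n.add(j)
        rings.append(VortexRingSection(
            core_pair=(pos[i], neg[j]),
            midpoint=0.5 * (pos[i].centroid + neg[j].centroid),
            separation=d,
        ))
    unpaired = [c for k, c in enumerate(pos) if k not in used_p]
    unpaired += [c for k, c in enumerate(neg) if k not in used_n]
    return rings, unpaired


def jet_angle(
    u: np.ndarray,
    v: np.ndarray,
    x: np.ndarray,
    y: np.ndarray,
    ring: VortexRingSection,
    body_axis=(1.0, 0.0),
    medial_dir=(0.0, -1.0),
    speed_gate: float = 0.5,
) -> float:
    """Signed jet angle (degrees) of a ring's central jet.

    The jet region is the disk of radius separation/2 about the ring midpoint,
    gated to nodes with speed ≥ ``speed_gate`` × the regional maximum. The
    angle is the circular mean of velocity-vector angles measured from the
    caudal direction (−body_axis, the direction of the free-stream drift),
    signed negative when the jet's cross-axis component points along
    ``medial_dir`` (toward the body midline). Velocities must already be
    free-stream-subtracted. Returns degrees in (−180, 180].
    """
    dx = float(x[1] - x[0])
    if ring.separation < 3 * dx:
        raise ValueError("ring separation below 3 grid cells")
    X, Y = np.meshgrid(x, y)
    r = np.hypot(X - ring.midpoint[0], Y - ring.midpoint[1])
    disk = r <= ring.separation / 2
    if not disk.any():
        raise ValueError("empty jet region")
    speed = np.hypot(u, v)
    smax = speed[disk].max()
    sel = disk & (speed >= speed_gate * smax)
    if not sel.any():
        raise ValueError("empty jet region after speed gating")
    a = np.asarray(body_axis, dtype=float)
    caudal = -a / np.hypot(*a)
    m = np.asarray(medial_dir, dtype=float)
    m = m / np.hypot(*m)
    lateral = -m  # positive cross-axis component = away from the midline
    uc = u[sel] * caudal[0] + v[sel] * caudal[1]
    ul = u[sel] * lateral[0] + v[sel] * lateral[1]
    theta = np.arctan2(ul, uc)
    mean = np.arctan2(np.sin(theta).mean(), np.cos(theta).mean())
    ring.jet_angle_deg = float(np.degrees(mean))
    ring.mean_jet_speed = float(speed[sel].mean())
    return ring.jet_angle_deg


def track_cores(
    core_lists: list[list[VortexCore]],
    max_step: float,
    frame_rate: float = 1.0,
    tail_points_per_frame: list[np.ndarray] | None = None,
    interception_radius: float | None = None,
) -> tuple[list[Track], list[dict]]:
    """Link cores across frames by nearest neighbour with a same-sign constraint.

    Returns (tracks, events). When per-frame tail points are given, an
    ``interception`` event is emitted the first time a track's centroid comes
    within ``interception_radius`` (default 2 grid cells — pass it explicitly
    in metres) of any tail point, reporting the shed-to-interception interval.
    """
    if len(core_lists) < 2:
        raise ValueError("tracking needs at least 2 frames")
    tracks: list[Track] = []
    active: dict[int, Track] = {}
    next_id = 0
    for c in core_lists[0]:
        t = Track(id=next_id, frames=[0], centroids=[c.centroid.copy()],
                  sign=int(np.sign(c.circulation)))
        tracks.append(t)
        active[t.id] = t
        next_id += 1
    for k in range(1, len(core_lists)):
        cores = core_lists[k]
        cand = []
        for t in active.values():
            for ci, c in enumerate(cores):
                if int(np.sign(c.circulation)) != t.sign:
                    continue
                d = float(np.hypot(*(c.centroid - t.centroids[-1])))
                if d <= max_step:
                    cand.append((d, t.id, ci))
        cand.sort()
        used_t, used_c = set(), set()
        for d, tid, ci in cand:
            if tid in used_t or ci in used_c:
                continue
            used_t.add(tid)
            used_c.add(ci)
            active[tid].frames.append(k)
            active[tid].centroids.append(cores[ci].centroid.copy())
        # drop tracks that missed this frame; start tracks for unmatched cores
        active = {tid: t for tid, t in active.items() if tid in used_t}
        for ci, c in enumerate(cores):
            if ci in used_c:
                continue
            t = Track(id=next_id, frames=[k], centroids=[c.centroid.copy()],
                      sign=int(np.sign(c.circulation)))
            tracks.append(t)
            active[t.id] = t
            next_id += 1

    events = []
    if tail_points_per_frame is not None:
        if interception_radius is None:
            raise ValueError("interception_radius required with tail points")
        for t in tracks:
            for f, c in zip(t.frames, t.centroids):
                pts = tail_points_per_frame[f]
                if pts is None or len(pts) == 0:
                    continue
                d = np.hypot(pts[:, 0] - c[0], pts[:, 1] - c[1]).min()
                if d <= interception_radius:
                    events.append({
                        "type": "interception",
                        "track_id": t.id,
                        "frame": f,
                        "interval_s": (f - t.frames[0]) / frame_rate,
                    })
                    break
    return tracks, events
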