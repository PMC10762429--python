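"""Surface forces per unit depth, tail thrust, power decomposition, efficiency.

The pressure force exerted by the fluid on outline segment i is

    f_i = − p̄_i L_i n̂_i        [N/m, per unit depth]

with p̄_i the sampled gauge pressure, L_i the segment length and n̂_i the
outward unit normal. Thrust and drag are the projections of f_i on the
swimming axis (positive = thrust, along ``swim_axis``). The tail's useful
power is thrust times the free-stream (swimming) speed; the lateral cost is
the pressure work rate of lateral surface motion. Hydrodynamic efficiency is

    η = ⟨P_ax⟩ / (⟨P_ax⟩ + ⟨P_lat⟩)

averaged over an integer number of tail-beat cycles; instantaneous negative
thrust contributes zero useful power (clipped), which keeps η within [0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .surface import BodyOutline, SurfaceSampleSeries, tail_region_segments

__all__ = [
    "SegmentForceSeries",
    "PowerBalance",
    "segment_forces",
    "net_axial_force",
    "power_decomposition",
    "hydrodynamic_efficiency",
]


def _lateral_axis(swim_axis: np.ndarray) -> np.ndarray:
    a = np.asarray(swim_axis, dtype=float)
    return np.array([-a[1], a[0]])


@dataclass
class SegmentForceSeries:
    """Per-segment pressure force per unit depth for one frame."""

    forces: np.ndarray  # (n, 2) N/m
    axial: np.ndarray  # signed projection on swim_axis, (n,)
    lateral: np.ndarray  # signed projection on the lateral axis, (n,)
    valid: np.ndarray  # (n,) boolean (invalid segments carry zero force)
    swim_axis: np.ndarray
    frame_index: int = 0


@dataclass
class PowerBalance:
    """Axial/lateral power per unit depth over a cycle window."""

    p_axial: np.ndarray  # W/m per frame
    p_lateral: np.ndarray  # W/m per frame
    eta_cycle: float
    eta_peak: float
    window: tuple[int, int]  # [start, stop) frame indices of the cycle window


def segment_forces(
    samples: SurfaceSampleSeries,
    outline: BodyOutline,
    swim_axis=(1.0, 0.0),
) -> SegmentForceSeries:
    """f_i = −p̄_i·L_i·n̂_i; invalid samples give zero force and a flag."""
    if samples.pressure.shape[0] != outline.n_segments:
        raise ValueError("samples do not match outline segment count")
    p = np.where(samples.valid, samples.pressure, 0.0)
    f = -(p * outline.segment_lengths)[:, None] * outline.outward_normals
    a = np.asarray(swim_axis, dtype=float)
    lat = _lateral_axis(a)
    return SegmentForceSeries(
        forces=f,
        axial=f @ a,
        lateral=f @ lat,
        valid=samples.valid.copy(),
        swim_axis=a,
        frame_index=samples.frame_index,
    )


def net_axial_force(
    forces: SegmentForceSeries,
    outline: BodyOutline,
    region: tuple[str, str] = ("caudal_peduncle", "superior_lobe_tip"),
) -> float:
    """Net axial force (N/m) summed over the tail region; positive = thrust.

    The region is an arc-length interval between the two landmarks (order
    irrelevant), covering both flanks of the tail.
    """
    sel = tail_region_segments(outline, region)
    if not sel.any():
        raise ValueError("empty tail region")
    return float(forces.axial[sel].sum())


def power_decomposition(
    forces_per_frame: list[SegmentForceSeries],
    surface_velocities: list[np.ndarray],
    freestream_speed: float,
    outlines: list[BodyOutline],
    region: tuple[str, str] = ("caudal_peduncle", "superior_lobe_tip"),
) -> tuple[np.ndarray, np.ndarray]:
    """Per-frame axial (useful) and lateral (cost) power, W/m.

    P_ax(t) = max(net axial tail force, 0) · U;
    P_lat(t) = Σ over tail segments of |f_lat,i · v_lat,i|.
    """
    if freestream_speed is None:
        raise ValueError("missing freestream_speed")
    if not (len(forces_per_frame) == len(surface_velocities) == len(outlines)):
        raise ValueError("forces, velocities and outlines must align per frame")
    p_ax = np.empty(len(forces_per_frame))
    p_lat = np.empty(len(forces_per_frame))
    for k, (fr, sv, ol) in enumerate(zip(forces_per_frame, surface_velocities, outlines)):
        if sv.shape[0] != ol.n_segments:
            raise ValueError("surface velocities do not align with outline segments")
        sel = tail_region_segments(ol, region)
        thrust = fr.axial[sel].sum()
        p_ax[k] = max(thrust, 0.0) * freestream_speed
        lat = _lateral_axis(fr.swim_axis)
        v_lat = sv @ lat
        p_lat[k] = np.abs(fr.lateral[sel] * v_lat[sel]).sum()
    return p_ax, p_lat


def hydrodynamic_efficiency(
    p_axial: np.ndarray,
    p_lateral: np.ndarray,
    window: tuple[int, int] | None = None,
) -> PowerBalance:
    """Cycle-average and peak efficiency over ``window`` ([start, stop) frames).

    η = ⟨P_ax⟩ / (⟨P_ax⟩ + ⟨P_lat⟩); peak η is the maximum instantaneous
    ratio over frames with positive total power. Raises when the window mean
    total power is not positive.
    """
    p_axial = np.asarray(p_axial, dtype=float)
    p_lateral = np.asarray(p_lateral, dtype=float)
    if window is None:
        window = (0, p_axial.size)
    a, b = window
    if b - a < 2:
        raise ValueError("cycle window shorter than one tail-beat cycle")
    pa = p_axial[a:b]
    pl = p_lateral[a:b]
    denom = pa.mean() + pl.mean()
    if denom <= 0:
        raise ValueError("zero total power in window: efficiency undefined")
    eta = pa.mean() / denom
    tot = pa + pl
    pos = tot > 0
    eta_peak = float(np.max(pa[pos] / tot[pos])) if pos.any() else 0.0
    return PowerBalance(p_axial=pa, p_lateral=pl, eta_cycle=float(eta),
                        eta_peak=eta_peak, window=(a, b))
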