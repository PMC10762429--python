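"""Fin-beat kinematics and gait classification from fin-tip traces.

Traces are lateral fin-tip displacements relative to the body midline.
Amplitude and frequency follow the convention of averaging over the last
three complete beat cycles. Phase relationships use circular statistics on
per-cycle peak-time offsets, which stay robust on short, nonstationary
traces where spectral phase is unreliable.

Gaits: PCF (pectoral–caudal coordination) requires anti-phase pectoral fins,
pectoral and caudal frequencies matching, and an active caudal fin sustained
over at least three consecutive tail beats; MPF has active pectorals with a
quiet caudal fin; BCF the reverse.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import find_peaks

__all__ = [
    "FinTrace",
    "GaitBout",
    "GaitParams",
    "beat_amplitude",
    "beat_frequency",
    "phase_difference",
    "classify_gait",
    "pcf_time_fraction",
]


@dataclass
class FinTrace:
    """Lateral displacement (m) of one fin tip, uniformly sampled."""

    times: np.ndarray
    displacement: np.ndarray
    fin_id: str  # pectoral_left | pectoral_right | caudal
    body_length: float

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.displacement = np.asarray(self.displacement, dtype=float)
        if self.times.shape != self.displacement.shape:
            raise ValueError("times/displacement length mismatch")
        if self.body_length <= 0:
            raise ValueError("body_length must be positive")
        dt = np.diff(self.times)
        if dt.size and (np.any(dt <= 0) or np.ptp(dt) > 1e-6 * dt[0]):
            raise ValueError("trace must be uniformly sampled")
        if not np.all(np.isfinite(self.displacement)):
            raise ValueError("non-finite displacement values")

    @property
    def fs(self) -> float:
        return 1.0 / float(self.times[1] - self.times[0])


@dataclass
class GaitBout:
    start: float
    end: float
    label: str  # MPF | PCF | BCF | other
    n_tail_beats: int = 0
    phase_pectoral_deg: float | None = None
    phase_pc_deg: float | None = None

    @property
    def duration(self) -> float:
        return self.end - self.start


@dataclass
class GaitParams:
    """Classification thresholds (the observed pectoral anti-phase spread is
    ~180 ± 22°, so ±45° encloses about two standard deviations)."""

    tol_antiphase_deg: float = 45.0
    tol_freq: float = 0.15
    activity_threshold_bl: float = 0.02  # peak-to-peak, body lengths
    min_beats: int = 3


def _detrend(x: np.ndarray, fs: float, f_hint: float | None = None) -> np.ndarray:
    """Moving-average detrend with a window of roughly 1.5 beat periods."""
    if f_hint and f_hint > 0:
        w = int(round(1.5 * fs / f_hint))
    else:
        w = max(int(len(x) / 4), 3)
    w = max(min(w, len(x)), 3)
    kernel = np.ones(w) / w
    pad = np.pad(x, (w // 2, w - 1 - w // 2), mode="edge")
    return x - np.convolve(pad, kernel, mode="valid")


def _dominant_freq(x: np.ndarray, fs: float) -> float | None:
    """Dominant frequency from the amplitude spectrum (DC excluded)."""
    x = x - x.mean()
    if not np.any(x):
        return None
    spec = np.abs(np.fft.rfft(x))
    spec[0] = 0.0
    k = int(np.argmax(spec))
    return k * fs / len(x) if k > 0 else None


def _smooth(x: np.ndarray, w: int) -> np.ndarray:
    if w < 3 or w >= len(x):
        return x
    kernel = np.ones(w) / w
    pad = np.pad(x, (w // 2, w - 1 - w // 2), mode="edge")
    return np.convolve(pad, kernel, mode="valid")


def _ma_gain(f: float, w: int, fs: float) -> float:
    """Amplitude gain of a width-w moving average at frequency f."""
    if w < 2:
        return 1.0
    num = np.sin(np.pi * f * w / fs)
    den = w * np.sin(np.pi * f / fs)
    return float(num / den) if den != 0 else 1.0


def _conditioned(trace: FinTrace, with_gain: bool = False):
    """Detrended, band-limited displacement for peak picking.

    The trace is high-passed by subtracting a 1.5-beat-period moving average
    and low-passed by a 1/8-period moving average. With ``with_gain=True``
    also returns the net amplitude gain of this filter pair at the dominant
    frequency, so excursions can be corrected back to physical scale.
    """
    fs = trace.fs
    f0 = _dominant_freq(trace.displacement, fs)
    if not f0:
        x = trace.displacement - trace.displacement.mean()
        return (x, 1.0) if with_gain else x
    x = _detrend(trace.displacement, fs, f_hint=f0)
    w_d = max(min(int(round(1.5 * fs / f0)), len(x)), 3)
    w_s = int(round(fs / (8 * f0)))
    x = _smooth(x, w_s)
    gain = (1.0 - _ma_gain(f0, w_d, fs)) * _ma_gain(f0, max(w_s, 1), fs)
    if abs(gain) < 0.2:
        gain = 1.0  # filter degenerate at this frequency; leave uncorrected
    return (x, gain) if with_gain else x


def _peaks(trace: FinTrace):
    """Indices of maxima and minima with prominence 25% of the half range."""
    x = _conditioned(trace)
    amp = 0.5 * (np.max(x) - np.min(x))
    if amp == 0:
        return np.array([], dtype=int), np.array([], dtype=int)
    prom = 0.25 * amp
    hi, _ = find_peaks(x, prominence=prom)
    lo, _ = find_peaks(-x, prominence=prom)
    return hi, lo


def _refine(x: np.ndarray, idx: np.ndarray, times: np.ndarray, dt: float) -> np.ndarray:
    out = []
    for i in idx:
        if 0 < i < len(x) - 1:
            denom = x[i - 1] - 2 * x[i] + x[i + 1]
            shift = 0.5 * (x[i - 1] - x[i + 1]) / denom if denom != 0 else 0.0
            out.append(times[i] + np.clip(shift, -1, 1) * dt)
        else:
            out.append(times[i])
    return np.asarray(out)


def _peak_times(trace: FinTrace) -> tuple[np.ndarray, np.ndarray]:
    """Sub-sample (maxima, minima) times via parabolic refinement."""
    x = _conditioned(trace)
    hi, lo = _peaks(trace)
    dt = 1.0 / trace.fs
    return (_refine(x, hi, trace.times, dt), _refine(-x, lo, trace.times, dt))


def _require_cycles(trace: FinTrace, n_peaks: int = 4) -> np.ndarray:
    hi, _ = _peaks(trace)
    if len(hi) < n_peaks:
        raise ValueError("fewer than 3 cycles in trace")
    return hi


def beat_amplitude(trace: FinTrace) -> float:
    """Mean peak-to-peak excursion over the last three full cycles, / BL.

    Excursions are measured on the band-limited signal and corrected for the
    smoothing attenuation at the beat frequency, so tracker noise neither
    inflates the extremes nor the smoothing deflates them.
    """
    hi = _require_cycles(trace)
    x, gain = _conditioned(trace, with_gain=True)
    p2p = []
    for a, b in zip(hi[-4:-1], hi[-3:]):
        seg = x[a:b + 1]
        p2p.append((np.max(seg) - np.min(seg)) / gain)
    return float(np.mean(p2p) / trace.body_length)


def beat_frequency(trace: FinTrace) -> float:
    """Reciprocal of the mean inter-peak interval over the last three cycles."""
    hi = _require_cycles(trace)
    t = trace.times[hi[-4:]]
    return float(1.0 / np.mean(np.diff(t)))


def _circular_mean_deg(angles_deg: np.ndarray) -> float:
    a = np.radians(angles_deg)
    return float(np.degrees(np.arctan2(np.sin(a).mean(), np.cos(a).mean())))


def phase_difference(a: FinTrace, b: FinTrace) -> float:
    """Circular-mean phase of b relative to a, degrees in [0, 360).

    Per-cycle peak-time offsets (each a-peak against its nearest b-peak) are
    converted to degrees of the shared beat period. Requires overlapping
    traces with ≥ 3 cycles each and frequencies within 15%.
    """
    fa, fb = beat_frequency(a), beat_frequency(b)
    if abs(fa - fb) > 0.15 * max(fa, fb):
        raise ValueError("incommensurate frequencies (beyond 15%)")
    period = 2.0 / (fa + fb)
    hi_a, lo_a = _peak_times(a)
    hi_b, lo_b = _peak_times(b)
    offsets = []
    for ta, tb in ((hi_a, hi_b), (lo_a, lo_b)):
        for t0 in ta:
            dt = tb - t0
            if dt.size:
                offsets.append(dt[np.argmin(np.abs(dt))])
    phases = (np.asarray(offsets) / period) * 360.0
    return float(np.mod(_circular_mean_deg(phases), 360.0))


# ---------------------------------------------------------------------------
# Gait classification
# ---------------------------------------------------------------------------

def _windowed_p2p(x: np.ndarray, i0: int, i1: int) -> float:
    seg = x[i0:i1 + 1]
    return float(np.max(seg) - np.min(seg)) if seg.size else 0.0


def classify_gait(
    left: FinTrace,
    right: FinTrace,
    caudal: FinTrace,
    params: GaitParams | None = None,
) -> list[GaitBout]:
    """Label the record with gait bouts (PCF / MPF / BCF / other).

    Tail-beat cycles (consecutive caudal maxima) are evaluated individually;
    a run of at least ``min_beats`` cycles satisfying the PCF conditions
    (anti-phase pectorals, matched pectoral/caudal frequencies, active caudal
    fin) forms a PCF bout. Intervals without caudal activity are MPF when the
    pectorals are active, otherwise "other".
    """
    if params is None:
        params = GaitParams()
    if not (left.times.shape == right.times.shape == caudal.times.shape):
        raise ValueError("traces must share sampling (equal lengths)")
    bl = caudal.body_length
    thr = params.activity_threshold_bl * bl
    t0, t1 = float(caudal.times[0]), float(caudal.times[-1])

    hi_c, _ = _peaks(caudal)
    # pectoral phase/frequency, when measurable
    try:
        phase_lr = phase_difference(left, right)
    except ValueError:
        phase_lr = None
    pec_freq = None
    for tr in (left, right):
        try:
            pec_freq = beat_frequency(tr)
            break
        except ValueError:
            continue

    def pec_active(i0, i1):
        return (_windowed_p2p(left.displacement, i0, i1) >= thr
                or _windowed_p2p(right.displacement, i0, i1) >= thr)

    labels = []  # (start, end, label) per tail cycle
    cycles = list(zip(hi_c[:-1], hi_c[1:]))
    for a, b in cycles:
        caud_ok = _windowed_p2p(caudal.displacement, a, b) >= thr
        cyc_freq = 1.0 / (caudal.times[b] - caudal.times[a])
        pecs = pec_active(a, b)
        if caud_ok and pecs:
            anti = (phase_lr is not None
                    and abs(((phase_lr - 180.0) + 180.0) % 360.0 - 180.0)
                    <= params.tol_antiphase_deg)
            fmatch = (pec_freq is not None
                      and abs(pec_freq - cyc_freq) <= params.tol_freq
                      * max(pec_freq, cyc_freq))
            lab = "pcf_candidate" if (anti and fmatch) else "other"
        elif caud_ok:
            lab = "BCF"
        elif pecs:
            lab = "MPF"
        else:
            lab = "other"
        labels.append((float(caudal.times[a]), float(caudal.times[b]), lab))

    # enforce the >= min_beats run rule for PCF
    resolved = []
    i = 0
    while i < len(labels):
        if labels[i][2] != "pcf_candidate":
            resolved.append(labels[i])
            i += 1
            continue
        j = i
        while j < len(labels) and labels[j][2] == "pcf_candidate":
            j += 1
        run = labels[i:j]
        lab = "PCF" if len(run) >= params.min_beats else "other"
        for s, e, _ in run:
            resolved.append((s, e, lab))
        i = j

    # cover head/tail intervals outside caudal cycles
    segments = []
    if resolved:
        if resolved[0][0] > t0:
            segments.append((t0, resolved[0][0], None))
        segments.extend(resolved)
        if resolved[-1][1] < t1:
            segments.append((resolved[-1][1], t1, None))
    else:
        segments.append((t0, t1, None))
    dt = 1.0 / caudal.fs
    out = []
    for s, e, lab in segments:
        if lab is None:
            i0 = int(round((s - t0) / dt))
            i1 = int(round((e - t0) / dt))
            lab = "MPF" if pec_active(i0, i1) else "other"
        out.append((s, e, lab))

    # merge adjacent same-label segments into bouts
    bouts: list[GaitBout] = []
    for s, e, lab in out:
        if bouts and bouts[-1].label == lab and abs(bouts[-1].end - s) < dt / 2:
            bouts[-1].end = e
            if lab in ("PCF", "BCF"):
                bouts[-1].n_tail_beats += 1
        else:
            bouts.append(GaitBout(start=s, end=e, label=lab,
                                  n_tail_beats=1 if lab in ("PCF", "BCF") else 0,
                                  phase_pectoral_deg=phase_lr))
    return bouts


def pcf_time_fraction(
    bouts: list[GaitBout],
    duration: float,
    excluded: list[tuple[float, float]] | None = None,
) -> float:
    """Percent of ``duration`` spent in PCF bouts.

    ``excluded`` intervals (repositioning, wall-swimming) are removed from the
    numerator only — they still count toward the total observation time.
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    total = 0.0
    for b in bouts:
        if b.label != "PCF":
            continue
        if b.start < -1e-9 or b.end > duration + 1e-9:
            raise ValueError("bout outside the observation window")
        s, e = b.start, b.end
        cut = 0.0
        if excluded:
            for (xs, xe) in excluded:
                cut += max(0.0, min(e, xe) - max(s, xs))
        total += max(0.0, (e - s) - cut)
    return 100.0 * total / duration
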