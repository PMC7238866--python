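"""Conditioning of raw video-oculography traces.

Raw eye traces arrive at 220 Hz from the eye tracker while the platform is
recorded at 200 Hz; analysis happens on the platform grid, so eye traces
are first downsampled (polyphase, anti-aliased) onto an exact 200 Hz grid
sharing t = 0 with the platform record (the acquisition hardware
synchronizes the two clocks).

Blinks corrupt the vertical eye-position channel with large, fast
transients.  They are detected by a two-threshold velocity rule — find all
samples whose absolute eye velocity exceeds 25 deg/s, then extend each such
interval backward and forward to the nearest samples below 10 deg/s — and
the flagged samples are replaced by linear interpolation between the
interval's boundary samples.  Velocity is a two-point central difference at
the trace's own sampling rate; the thresholds sit far above the velocity
content of both compensatory eye movements (< ~10 deg/s with this
geometry) and band-limited sensor noise, so no pre-smoothing is applied.

Head pitch angle is obtained from the tracker's pitch-velocity channel by
cumulative trapezoidal integration (initial angle 0, no detrending).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy import signal, integrate

__all__ = [
    "EyeTrace",
    "resample_to_200",
    "velocity",
    "detect_blinks",
    "remove_blinks",
    "highpass",
    "integrate_head_pitch",
]

BLINK_V_HI_DEG_S = 25.0
BLINK_V_LO_DEG_S = 10.0
BLINK_MERGE_GAP_S = 0.05    # a blink's apex splits it into rise+fall intervals


@dataclass(frozen=True)
class EyeTrace:
    """Uniformly sampled vertical eye position (deg, positive up)."""

    t: np.ndarray
    eye_deg: np.ndarray
    fs: float
    head_pitch_vel: np.ndarray | None = None
    blink_intervals: tuple = field(default_factory=tuple)
    provenance: str = "raw"

    @property
    def duration_s(self) -> float:
        return len(self.t) / self.fs


def resample_to_200(trace: EyeTrace, target_fs: float = 200.0) -> EyeTrace:
    """Downsample an eye trace onto the platform's 200 Hz grid.

    Polyphase FIR resampling (anti-aliased); the output grid starts at
    t = 0 like the input, and the duration is preserved to within one
    sample.  Upsampling is out of contract.
    """
    if trace.fs < target_fs:
        raise ValueError(f"fs={trace.fs} below target {target_fs}: upsampling "
                         "is out of contract")
    if trace.fs == target_fs:
        return replace(trace, provenance="resampled")
    # rational approximation of target/source rate ratio
    from fractions import Fraction
    frac = Fraction(target_fs / trace.fs).limit_denominator(1000)
    up, down = frac.numerator, frac.denominator
    eye = signal.resample_poly(trace.eye_deg, up, down, padtype="line")
    hp = None
    if trace.head_pitch_vel is not None:
        hp = signal.resample_poly(trace.head_pitch_vel, up, down, padtype="line")
    t = np.arange(len(eye)) / target_fs
    return EyeTrace(t=t, eye_deg=eye, fs=target_fs, head_pitch_vel=hp,
                    provenance="resampled")


def velocity(x: np.ndarray, fs: float) -> np.ndarray:
    """Two-point central-difference velocity (same length; one-sided ends)."""
    return np.gradient(np.asarray(x, dtype=float), 1.0 / fs)


def detect_blinks(trace: EyeTrace,
                  v_hi: float = BLINK_V_HI_DEG_S,
                  v_lo: float = BLINK_V_LO_DEG_S,
                  merge_gap_s: float = BLINK_MERGE_GAP_S) -> list[tuple[float, float]]:
    """Detect blink intervals by the two-threshold velocity rule.

    Returns maximal intervals (start_s, end_s) where |velocity| exceeds
    ``v_hi``, each extended to the nearest flanking samples with
    |velocity| below ``v_lo``; overlapping extensions are merged.  An
    interval whose extension never drops below ``v_lo`` before the trace
    boundary extends to that boundary.

    Because eye velocity passes through zero at a blink's apex, the rule
    naturally yields a rise and a fall interval per blink with the apex
    samples between them; intervals separated by less than
    ``merge_gap_s`` are therefore merged so the substitution spans the
    whole transient.
    """
    if not v_hi > v_lo > 0:
        raise ValueError("need v_hi > v_lo > 0")
    v = np.abs(velocity(trace.eye_deg, trace.fs))
    hi = v > v_hi
    if not hi.any():
        return []
    lo = v < v_lo
    n = len(v)
    # indices of nearest low-velocity sample at or before / after each sample
    prev_lo = np.where(lo, np.arange(n), -1)
    np.maximum.accumulate(prev_lo, out=prev_lo)
    next_lo = np.where(lo, np.arange(n), n)
    next_lo = np.minimum.accumulate(next_lo[::-1])[::-1]

    edges = np.flatnonzero(np.diff(np.concatenate(([0], hi.view(np.int8), [0]))))
    starts, ends = edges[0::2], edges[1::2] - 1   # inclusive sample indices
    intervals: list[list[int]] = []
    for s, e in zip(starts, ends):
        s_ext = prev_lo[s] if prev_lo[s] >= 0 else 0
        e_ext = next_lo[e] if next_lo[e] < n else n - 1
        gap = int(round(merge_gap_s * trace.fs))
        if intervals and s_ext <= intervals[-1][1] + gap:
            intervals[-1][1] = max(intervals[-1][1], e_ext)
        else:
            intervals.append([s_ext, e_ext])
    return [(trace.t[s], trace.t[e]) for s, e in intervals]


def remove_blinks(trace: EyeTrace,
                  intervals: Sequence[tuple[float, float]]) -> EyeTrace:
    """Replace samples inside each blink interval by linear interpolation
    between the interval's boundary samples (nearest-value hold at trace
    edges).  Samples outside the intervals are untouched bitwise."""
    eye = np.array(trace.eye_deg, copy=True)
    n = len(eye)
    for t0, t1 in intervals:
        i0 = int(np.searchsorted(trace.t, t0 - 1e-12))
        i1 = int(np.searchsorted(trace.t, t1 + 1e-12)) - 1
        i0, i1 = max(i0, 0), min(i1, n - 1)
        lo, hi = i0 - 1, i1 + 1
        if lo < 0 and hi > n - 1:
            continue
        if lo < 0:                      # interval at leading edge: hold
            eye[i0:i1 + 1] = eye[hi]
        elif hi > n - 1:                # interval at trailing edge: hold
            eye[i0:i1 + 1] = eye[lo]
        else:
            eye[i0:i1 + 1] = np.interp(np.arange(i0, i1 + 1), [lo, hi],
                                       [eye[lo], eye[hi]])
    merged = tuple(trace.blink_intervals) + tuple((float(a), float(b))
                                                  for a, b in intervals)
    return replace(trace, eye_deg=eye, blink_intervals=merged,
                   provenance="deblinked")


def highpass(x: np.ndarray, fs: float, cutoff_hz: float) -> np.ndarray:
    """Zero-phase 4th-order Butterworth high-pass.

    Used to band-limit analyzed traces to the wavelet analysis band:
    slow postural drift below the band otherwise perturbs phase
    estimates at the lowest analyzed frequencies.  Zero-phase filtering
    leaves in-band phase untouched; applying the identical filter to
    every trace entering a ratio or cross-spectrum cancels the (sub-1%)
    in-band amplitude droop.
    """
    sos = signal.butter(4, cutoff_hz / (fs / 2.0), btype="highpass",
                        output="sos")
    return signal.sosfiltfilt(sos, np.asarray(x, dtype=float))


def integrate_head_pitch(vel_deg_s: np.ndarray, fs: float) -> np.ndarray:
    """Head pitch angle (deg) from pitch velocity: cumulative trapezoidal
    integral with initial angle 0; no detrending."""
    v = np.asarray(vel_deg_s, dtype=float)
    return integrate.cumulative_trapezoid(v, dx=1.0 / fs, initial=0.0)
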