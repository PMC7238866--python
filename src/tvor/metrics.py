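"""Per-cycle time delay and gain of the compensatory eye response.

For every stimulus cycle (Experiment A) or half-cycle (Experiment B) the
pipeline reduces the wavelet coherency between the eye trace and the
inverted platform trace to two numbers:

* **time delay** — the circular mean of the coherency phase over the
  window's significant, in-cone pixels at the scale nearest the nominal
  stimulus frequency, converted to ms (positive = eye lags the platform);
* **gain** — the amplitude of a frequency-locked sinusoid least-squares
  fit (offset as nuisance) to the band-limited eye trace over the
  window, divided by the same fit to the required eye trace.  The
  locked fit is delay-invariant, and on a half-sine window — where a
  peak-to-peak amplitude would be ill-defined — it remains exact.

Windows whose significant in-cone coverage is below 50% yield a missing
estimate rather than a biased one.

Leakage-corrected phase demixing
--------------------------------
The wavelet's temporal support and the coherency smoothing blend the
phases of neighbouring cycles into each window, which biases a naive
window-mean phase by several ms wherever the delay changes between
cycles (the first/last cycles of a sequence, and every half-cycle of a
frequency ladder).  The blending is predictable: the smoothed cross
spectrum is ``X(j, t) = sum_w b_w K_w(j, t)`` where ``b_w = g_w
exp(-i 2 pi f_w d_w)`` is window ``w``'s complex response and the kernel
``K_w`` — the smoothed cross spectrum of the required eye waveform
restricted to window ``w`` against the full inverted platform — depends
only on the known stimulus layout and analysis settings, never on the
data.

Rather than solving the raw pixel-level least-squares system — whose
near-collinear columns amplify small smooth contaminations (postural
drift, blink-substitution residue) into large phase errors at the
lowest-frequency windows — the correction works *through the robust
statistic itself*: the leakage bias of the window-mean phase is
predicted by applying the same circular-mean reduction to the kernel
model populated with the measured window means, and subtracted in one
explicit pass.  A single pass removes most of the bias while keeping
the window mean's noise immunity; a full fixed-point inversion of the
phase-mixing map is deliberately avoided because it amplifies small
kernel-model errors at the heavily-blended lowest-frequency windows.
This is the pipeline's default delay estimator
(``phase_method='demix'``); the uncorrected circular window mean
remains available as ``'window_mean'``.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd

from .preprocess import EyeTrace
from .stimulus import CycleWindow
from .wavelet import CoherenceField, phase_to_delay

__all__ = [
    "CycleEstimate",
    "MIN_SIGNIF_COVERAGE",
    "estimate_delay",
    "estimate_gain",
    "estimates_to_frame",
    "summarize",
]

MIN_SIGNIF_COVERAGE = 0.5
MIN_REQUIRED_AMPLITUDE_DEG = 0.1
KERNEL_FADE_S = 0.05        # partition-of-unity fade at kernel joins


@dataclass(frozen=True)
class CycleEstimate:
    """Delay/gain estimate for one (subject, repetition, window) cell."""

    subject_id: int
    experiment: str
    start_condition: str
    half_trial: str
    frequency_hz: float
    cycle_index: int
    delay_ms: float
    gain: float
    signif_coverage: float
    repetition: int = 1

    @property
    def valid(self) -> bool:
        return self.signif_coverage >= MIN_SIGNIF_COVERAGE


def _window_slice(t: np.ndarray, window: CycleWindow) -> np.ndarray:
    idx = np.flatnonzero((t >= window.start_s - 1e-12) & (t < window.end_s - 1e-12))
    if len(idx) == 0:
        raise ValueError("window outside the record")
    return idx


def estimate_delay(field: CoherenceField, window: CycleWindow,
                   frequency_hz: float | None = None) -> tuple[float, float]:
    """Window delay (ms) from the coherency phase at the nearest scale.

    Requires ``field.signif_mask`` (see :func:`tvor.wavelet.significance_mask`).
    Returns ``(delay_ms, signif_coverage)``; the delay is NaN when the
    significant in-cone coverage is below 50% (no estimate, not zero).
    The field's phase is eye-relative-to-inverted-platform (positive =
    eye leads), so the sign is flipped to report positive lags.
    """
    if field.signif_mask is None:
        raise ValueError("field has no significance mask")
    f = frequency_hz if frequency_hz is not None else window.frequency_hz
    j = field.nearest_scale(f)
    idx = _window_slice(field.t, window)
    sig = field.signif_mask[j, idx]
    coverage = float(sig.mean())
    if coverage < MIN_SIGNIF_COVERAGE:
        return float("nan"), coverage
    phases = np.angle(field.coherency[j, idx][sig])
    mean_phase = float(np.angle(np.mean(np.exp(1j * phases))))
    return phase_to_delay(-mean_phase, f), coverage


def demix_kernels(platform, omega0: float | None = None, dj: float | None = None,
                  f_range=None, time_scales: float | None = None,
                  scale_bins: int | None = None,
                  highpass_hz: float | None = None) -> dict:
    """Per-window demixing kernels for a platform run.

    For every cycle window ``w`` the kernel is the smoothed cross
    spectrum of (required eye waveform restricted to ``w``, zero delay,
    unit gain) against the full inverted platform, evaluated at the
    scale rows used by any window.  Kernels depend only on the stimulus
    layout and the analysis settings, so they are computed once per
    record geometry and reused across subjects.  Identical for the two
    Experiment B start conditions (both factors change sign).

    Returns a dict with the scale-row map and one complex (rows x time)
    array per window key.
    """
    from . import wavelet as wv
    from .geometry import required_eye_trace
    from .stimulus import invert_platform

    kw = {"omega0": omega0 if omega0 is not None else wv.OMEGA0,
          "dj": dj if dj is not None else wv.DJ,
          "f_range": f_range if f_range is not None else wv.F_RANGE_HZ}
    ts = time_scales if time_scales is not None else wv.TIME_SMOOTH_SCALES
    sb = scale_bins if scale_bins is not None else wv.SCALE_SMOOTH_BINS

    from .preprocess import highpass

    pinv = platform if platform.inverted else invert_platform(platform)
    plat_sig = pinv.angle_deg
    req = required_eye_trace(platform).eye_deg
    if highpass_hz:
        plat_sig = highpass(plat_sig, platform.fs, highpass_hz)
        req = highpass(req, platform.fs, highpass_hz)
    Wp = wv.morlet_cwt(plat_sig, platform.fs, **kw)
    t = platform.t

    j_of = {}
    for w in platform.cycle_windows:
        j_of[w.key] = int(np.argmin(np.abs(np.log(Wp.freqs_hz / w.frequency_hz))))
    rows = sorted(set(j_of.values()))
    row_of = {j: r for r, j in enumerate(rows)}

    from scipy import ndimage as _ndi

    from .wavelet import _smooth

    kfade = max(int(round(KERNEL_FADE_S * platform.fs)), 1)

    def kernel_for(t0, t1, shift_s=0.0):
        # smooth partition-of-unity window: faded indicators still sum to 1,
        # so abutting kernels carry no artificial steps at the joins
        chi = _ndi.uniform_filter1d(((t >= t0) & (t < t1)).astype(float),
                                    size=kfade, mode="nearest")
        xfull = np.interp(t - shift_s, t, req) if shift_s else req
        Wx = wv.morlet_cwt(chi * xfull, platform.fs, **kw)
        C = _smooth(Wx.W * np.conj(Wp.W), Wp.scales_s, platform.fs, ts, sb)
        return C[rows, :]

    kernels = {w.key: kernel_for(w.start_s, w.end_s)
               for w in platform.cycle_windows}
    # hold pieces carry the constant required-eye baseline; without them the
    # windowed kernels would imply spurious steps at hold boundaries.  Each
    # hold is split at its midpoint with independent amplitudes because the
    # baseline tracks the neighbouring windows' (generally different) gains.
    holds = []
    for p in platform.plan.pieces:
        if p.frequency_hz is not None:
            continue
        mid = 0.5 * (p.t0 + p.t1)
        if mid - p.t0 > 2.0 * KERNEL_FADE_S:
            holds.extend([kernel_for(p.t0, mid), kernel_for(mid, p.t1)])
        else:
            holds.append(kernel_for(p.t0, p.t1))
    return {"rows": rows, "row_of": row_of, "j_of": j_of, "K": kernels,
            "holds": holds, "kernel_for": kernel_for}


def _window_pixels(field: CoherenceField, windows, j_of) -> dict:
    """In-cone pixel indices per window at its own scale row."""
    out = {}
    for w in windows:
        j = j_of[w.key]
        out[w.key] = np.flatnonzero((field.t >= w.start_s) & (field.t < w.end_s)
                                    & field.coi[j])
    return out


def _wmean_phase(X_row: np.ndarray, idx: np.ndarray) -> float:
    """Circular mean phase of a cross-spectrum row over pixel indices."""
    return float(np.angle(np.mean(np.exp(1j * np.angle(X_row[idx])))))


def demix_delays(field: CoherenceField, windows, kernels: dict,
                 gains: dict | None = None) -> dict:
    """Leakage-corrected per-window delays (ms) by forward-model bias
    subtraction.

    The observed statistic is the circular-mean phase of the cross
    spectrum over each window's in-cone pixels at its own scale (the
    window mean, converted to a delay).  Its leakage bias is predicted
    by evaluating the *same* statistic on the kernel model populated
    with the window-mean estimates themselves, and subtracted once:

        d_hat_w = wm_w - [ wm(model at wm) - wm ]_w

    A single explicit pass removes most of the bias while inheriting
    the window mean's noise immunity; iterating the correction to a
    fixed point is deliberately avoided — the full inversion of the
    phase-mixing map amplifies small kernel-model errors at the
    heavily-blended lowest-frequency windows.  ``gains`` supplies the
    per-window model amplitudes (defaults to 1; the phase prediction
    is nearly amplitude-invariant).  Returns ``{window.key: delay_ms}``
    (positive = eye lags); validity gating stays with the significance
    coverage.
    """
    if field.cross is None:
        raise ValueError("field carries no cross spectrum")
    keys = [w.key for w in windows]
    freqs = {w.key: w.frequency_hz for w in windows}
    j_of = kernels["j_of"]
    row_of = kernels["row_of"]
    holds = kernels.get("holds", [])
    K = kernels["K"]
    pixels = _window_pixels(field, windows, j_of)
    g = {k: (gains or {}).get(k, 1.0) for k in keys}
    g_hold = float(np.median(list(g.values()))) if g else 1.0

    obs = {k: _wmean_phase(field.cross[j_of[k]], pixels[k]) for k in keys}
    wm = {k: phase_to_delay(-obs[k], freqs[k]) for k in keys}

    # model cross spectrum populated with the window-mean estimates
    rows = {j: np.zeros_like(field.cross[j]) for j in set(j_of.values())}
    for k in keys:
        d_k = wm[k] if np.isfinite(wm[k]) else 0.0
        b = g[k] * np.exp(-2j * np.pi * freqs[k] * d_k / 1000.0)
        for j, r in row_of.items():
            rows[j] += b * K[k][r]
    for H in holds:
        for j, r in row_of.items():
            rows[j] += g_hold * H[r]

    out = {}
    for k in keys:
        pred = _wmean_phase(rows[j_of[k]], pixels[k])
        bias_ms = phase_to_delay(-pred, freqs[k]) - wm[k]
        out[k] = wm[k] - bias_ms
    return out


def _locked_amplitude(t: np.ndarray, x: np.ndarray, f: float) -> float:
    """Amplitude of the best-fit ``a cos + b sin`` at frequency ``f`` with
    an offset nuisance term.

    No trend term: over a half-cycle window the locked cosine is itself
    monotone, so a linear trend would be nearly collinear with it and
    steal amplitude; slow drift is removed upstream by the analysis-band
    high-pass instead."""
    w = 2.0 * np.pi * f
    design = np.column_stack([np.cos(w * t), np.sin(w * t), np.ones_like(t)])
    coef, *_ = np.linalg.lstsq(design, x, rcond=None)
    return float(np.hypot(coef[0], coef[1]))


def estimate_gain(eye: EyeTrace, required: EyeTrace, window: CycleWindow,
                  frequency_hz: float | None = None) -> float:
    """Eye amplitude over required amplitude from frequency-locked fits
    over the window; NaN when the required amplitude is degenerate."""
    if len(eye.t) != len(required.t) or eye.fs != required.fs:
        raise ValueError("eye and required traces must share the grid")
    f = frequency_hz if frequency_hz is not None else window.frequency_hz
    idx = _window_slice(eye.t, window)
    t = eye.t[idx]
    amp_req = _locked_amplitude(t, required.eye_deg[idx], f)
    if amp_req < MIN_REQUIRED_AMPLITUDE_DEG:
        return float("nan")
    amp_eye = _locked_amplitude(t, eye.eye_deg[idx], f)
    return amp_eye / amp_req


def estimates_to_frame(estimates) -> pd.DataFrame:
    """Long table of cycle estimates (one row per subject x window)."""
    rows = []
    for e in estimates:
        d = asdict(e)
        d["valid"] = e.valid
        rows.append(d)
    return pd.DataFrame(rows)


def summarize(estimates: pd.DataFrame, by) -> pd.DataFrame:
    """Group means and SEMs over subjects.

    Valid rows are first averaged within subject for each group, then the
    across-subject mean and SEM are taken (matching a mean +/- SEM, N =
    subjects report).  Groups with no valid estimate are absent from the
    output; a single-subject group has SEM NaN.
    """
    by = list(by)
    df = estimates[estimates["valid"]].copy()
    per_subject = (df.groupby(by + ["subject_id"], sort=True)
                     .agg(delay_ms=("delay_ms", "mean"), gain=("gain", "mean"))
                     .reset_index())
    out = (per_subject.groupby(by, sort=True)
           .agg(delay_ms_mean=("delay_ms", "mean"),
                delay_ms_sem=("delay_ms", "sem"),
                gain_mean=("gain", "mean"),
                gain_sem=("gain", "sem"),
                n_subjects=("subject_id", "nunique"))
           .reset_index())
    return out
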