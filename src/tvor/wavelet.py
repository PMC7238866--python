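"""Morlet wavelet coherence between eye and (inverted) platform motion.

The analysis core: a continuous wavelet transform with the analytic Morlet
mother wavelet, the smoothed cross-wavelet coherency between two signals,
a surrogate-based pointwise significance test, and the phase -> time-delay
conversion.

Conventions
-----------
* Mother wavelet ``psi(t) = pi^{-1/4} exp(i w0 t) exp(-t^2/2)`` with
  ``w0 = 6`` by default; scale-to-frequency conversion uses the standard
  equivalent-Fourier-period relation ``f = (w0 + sqrt(2 + w0^2)) / (4 pi s)``.
* Scales are log-spaced with ``dj`` octaves^-1 resolution (default 1/20)
  covering ``f_range`` (default 0.2-2.0 Hz, two octaves around the
  stimulus band).
* Coherency ``c = S(W_a conj(W_b)) / sqrt(S(|W_a|^2) S(|W_b|^2))`` with a
  smoothing operator S that is a boxcar over time of one scale-length and
  a boxcar over 0.6 octave of adjacent scales (12 bins at dj = 1/20, the
  decorrelation width conventional for Morlet coherence).  Narrower scale
  smoothing leaves the coherency nearly degenerate (unit modulus
  everywhere), which would void the significance test.  ``|c|^2`` is the coherence, bounded in
  [0, 1]; ``arg c`` is the phase of signal *a* relative to signal *b*
  (positive phase = *a* leads).
* The cone of influence excludes points closer than ``sqrt(2) * scale``
  (the wavelet's e-folding time) to either record edge.
* Significance: the null distribution of coherence is sampled from seeded
  white-noise surrogate pairs of the same length, rate and analysis
  settings; the pointwise threshold per scale is the ``1 - alpha/m``
  quantile with Bonferroni divisor ``m`` = number of analyzed scales.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import ndimage

__all__ = [
    "MorletCwt",
    "CoherenceField",
    "morlet_cwt",
    "cwt_amplitude",
    "cross_coherency",
    "coherence_null_thresholds",
    "significance_mask",
    "phase_to_delay",
]

OMEGA0 = 6.0
DJ = 1.0 / 20.0
F_RANGE_HZ = (0.2, 2.0)
TIME_SMOOTH_SCALES = 1.0     # boxcar length over time, in units of the scale
SCALE_SMOOTH_BINS = 12       # boxcar over adjacent scales: 0.6 octave at dj=1/20
ALPHA = 0.01
N_SURROGATES = 100


def _fourier_factor(omega0: float) -> float:
    """Equivalent Fourier period per unit scale."""
    return 4.0 * np.pi / (omega0 + np.sqrt(2.0 + omega0 ** 2))


def _scales_for_range(f_range, omega0: float, dj: float) -> np.ndarray:
    """Log-spaced scales (s) covering ``f_range``, finest scale first."""
    ff = _fourier_factor(omega0)
    s_min = 1.0 / (ff * f_range[1])
    n = int(np.floor(np.log2(f_range[1] / f_range[0]) / dj)) + 1
    return s_min * 2.0 ** (dj * np.arange(n))


@dataclass(frozen=True)
class MorletCwt:
    """Complex CWT coefficients on a (scale x time) grid."""

    W: np.ndarray               # complex, shape (n_scales, n_times)
    t: np.ndarray
    freqs_hz: np.ndarray        # descending (finest scale first)
    scales_s: np.ndarray
    fs: float
    omega0: float


def morlet_cwt(x: np.ndarray, fs: float, omega0: float = OMEGA0,
               dj: float = DJ, f_range=F_RANGE_HZ) -> MorletCwt:
    """Analytic-Morlet continuous wavelet transform (FFT implementation).

    L2-normalized coefficients: a unit sinusoid at an analyzed frequency
    has ``|W| = sqrt(s) * pi^{-1/4} * sqrt(2 pi) / 2`` at the matching
    scale (see :func:`cwt_amplitude` for the inverse normalization).
    """
    x = np.asarray(x, dtype=float)
    n = len(x)
    if f_range[1] > fs / 2.0:
        raise ValueError("f_range exceeds the Nyquist frequency")
    if n / fs < 2.0 / f_range[0]:
        raise ValueError("record shorter than two periods of the lowest "
                         "analyzed frequency")
    scales = _scales_for_range(f_range, omega0, dj)
    freqs = 1.0 / (_fourier_factor(omega0) * scales)

    xhat = np.fft.fft(x)
    w = 2.0 * np.pi * np.fft.fftfreq(n, d=1.0 / fs)   # rad/s
    W = np.empty((len(scales), n), dtype=complex)
    norm = np.pi ** -0.25 * np.sqrt(2.0 * np.pi)
    for j, s in enumerate(scales):
        psi_hat = np.where(w > 0, norm * np.exp(-0.5 * (s * w - omega0) ** 2), 0.0)
        W[j] = np.fft.ifft(xhat * np.sqrt(s) * psi_hat)
    t = np.arange(n) / fs
    return MorletCwt(W=W, t=t, freqs_hz=freqs, scales_s=scales, fs=fs,
                     omega0=omega0)


def cwt_amplitude(cwt: MorletCwt) -> np.ndarray:
    """Convert coefficient moduli to instantaneous sinusoid amplitude."""
    norm = np.pi ** -0.25 * np.sqrt(2.0 * np.pi)
    return 2.0 * np.abs(cwt.W) / (np.sqrt(cwt.scales_s)[:, None] * norm)


def _coi_mask(t: np.ndarray, scales: np.ndarray) -> np.ndarray:
    """Boolean (scale x time) mask: True inside the cone of influence."""
    dist = np.minimum(t - t[0], t[-1] - t)
    return dist[None, :] >= np.sqrt(2.0) * scales[:, None]


def _smooth(A: np.ndarray, scales: np.ndarray, fs: float,
            time_scales: float = TIME_SMOOTH_SCALES,
            scale_bins: int = SCALE_SMOOTH_BINS) -> np.ndarray:
    """Smoothing operator S: scale-proportional boxcar over time, then a
    short boxcar over adjacent scales.  Preserves complex input."""
    def run(M):
        out = np.empty_like(M)
        for j, s in enumerate(scales):
            k = max(int(round(time_scales * s * fs)), 1)
            out[j] = ndimage.uniform_filter1d(M[j], size=k, mode="nearest")
        if scale_bins > 1:
            out = ndimage.uniform_filter1d(out, size=scale_bins, axis=0,
                                           mode="nearest")
        return out

    if np.iscomplexobj(A):
        return run(A.real) + 1j * run(A.imag)
    return run(A)


@dataclass(frozen=True)
class CoherenceField:
    """Time x frequency coherency with significance metadata."""

    t: np.ndarray
    freqs_hz: np.ndarray
    scales_s: np.ndarray
    coherency: np.ndarray           # complex (n_scales, n_times)
    coi: np.ndarray                 # True inside the cone of influence
    fs: float
    cross: np.ndarray | None = None  # smoothed (unnormalized) cross spectrum
    signif_mask: np.ndarray | None = None
    flags: tuple = ()

    @property
    def coherence(self) -> np.ndarray:
        return np.abs(self.coherency) ** 2

    @property
    def phase(self) -> np.ndarray:
        return np.angle(self.coherency)

    def nearest_scale(self, frequency_hz: float) -> int:
        return int(np.argmin(np.abs(np.log(self.freqs_hz / frequency_hz))))


def cross_coherency(a: MorletCwt, b: MorletCwt,
                    time_scales: float = TIME_SMOOTH_SCALES,
                    scale_bins: int = SCALE_SMOOTH_BINS) -> CoherenceField:
    """Smoothed cross-wavelet coherency between two transforms.

    ``arg c > 0`` means *a* leads *b* at that time/frequency.  Regions
    where either signal has (numerically) zero smoothed power get
    coherency 0.  Self-coherency is identically 1 under any smoothing.
    """
    if a.W.shape != b.W.shape or a.fs != b.fs:
        raise ValueError("transforms must share grid and sampling rate")
    scales, fs = a.scales_s, a.fs
    cross = _smooth(a.W * np.conj(b.W), scales, fs, time_scales, scale_bins)
    pa = np.maximum(_smooth(np.abs(a.W) ** 2, scales, fs, time_scales, scale_bins), 0.0)
    pb = np.maximum(_smooth(np.abs(b.W) ** 2, scales, fs, time_scales, scale_bins), 0.0)
    denom = np.sqrt(pa * pb)
    tiny = np.finfo(float).tiny ** 0.5
    with np.errstate(invalid="ignore", divide="ignore"):
        c = np.where(denom > tiny, cross / np.where(denom > tiny, denom, 1.0), 0.0)
    # clip |c| to 1 against roundoff so coherence stays in [0, 1]
    mod = np.abs(c)
    c = np.where(mod > 1.0, c / np.where(mod > 1.0, mod, 1.0), c)
    return CoherenceField(t=a.t, freqs_hz=a.freqs_hz, scales_s=scales,
                          coherency=c, coi=_coi_mask(a.t, scales), fs=fs,
                          cross=cross)


def coherence_null_thresholds(n: int, fs: float, omega0: float = OMEGA0,
                              dj: float = DJ, f_range=F_RANGE_HZ,
                              time_scales: float = TIME_SMOOTH_SCALES,
                              scale_bins: int = SCALE_SMOOTH_BINS,
                              alpha: float = ALPHA,
                              n_surrogates: int = N_SURROGATES,
                              correction: str = "bonferroni",
                              seed: int = 0) -> np.ndarray:
    """Per-scale coherence thresholds from white-noise surrogate pairs.

    Pools in-coi coherence values over time and surrogates per scale and
    returns the Bonferroni-corrected ``1 - alpha/m`` quantile (``m`` =
    number of scales; ``correction='none'`` uses ``1 - alpha``).  The
    thresholds depend only on the record geometry and analysis settings,
    so they can be cached across trials of identical length.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    rng = np.random.default_rng(seed)
    pooled: list[np.ndarray] | None = None
    coi = None
    for _ in range(n_surrogates):
        ca = morlet_cwt(rng.standard_normal(n), fs, omega0, dj, f_range)
        cb = morlet_cwt(rng.standard_normal(n), fs, omega0, dj, f_range)
        field = cross_coherency(ca, cb, time_scales, scale_bins)
        if pooled is None:
            pooled = [[] for _ in field.scales_s]
            coi = field.coi
        coh = field.coherence
        for j in range(len(field.scales_s)):
            pooled[j].append(coh[j][coi[j]])
    m = len(pooled)
    q = 1.0 - (alpha / m if correction == "bonferroni" else alpha)
    out = np.empty(m)
    for j, vals in enumerate(pooled):
        allv = np.concatenate(vals) if vals else np.empty(0)
        # scales with no in-coi support can never be significant
        out[j] = np.quantile(allv, q) if allv.size else np.inf
    return out


def significance_mask(field: CoherenceField, alpha: float = ALPHA,
                      n_surrogates: int = N_SURROGATES,
                      correction: str = "bonferroni", seed: int = 0,
                      thresholds: np.ndarray | None = None) -> np.ndarray:
    """Pointwise significance mask for a coherence field.

    True where the observed coherence exceeds the (Bonferroni-corrected)
    surrogate-null quantile at that scale *and* the point lies inside the
    cone of influence.  Pass precomputed ``thresholds`` (from
    :func:`coherence_null_thresholds`) to reuse a cached null.
    """
    flags = ()
    if thresholds is None:
        if n_surrogates < 20:
            flags = ("few_surrogates",)
        thresholds = coherence_null_thresholds(
            len(field.t), field.fs, dj=np.log2(field.scales_s[-1] /
                                               field.scales_s[0]) /
            max(len(field.scales_s) - 1, 1),
            f_range=(field.freqs_hz.min(), field.freqs_hz.max()),
            alpha=alpha, n_surrogates=n_surrogates, correction=correction,
            seed=seed)
    mask = (field.coherence > thresholds[:, None]) & field.coi
    object.__setattr__(field, "signif_mask", mask)
    object.__setattr__(field, "flags", flags)
    return mask


def phase_to_delay(phase_rad, frequency_hz: float):
    """Convert a phase difference (rad) at ``frequency_hz`` into a time
    delay in ms: ``1000 * phase / (2 pi f)``, with the phase wrapped to
    (-pi, pi] first.  Positive = the lagging-signal convention of the
    caller (the pipeline reports positive when the eye lags the inverted
    platform)."""
    if frequency_hz <= 0:
        raise ValueError("frequency_hz must be positive")
    phase = np.asarray(phase_rad, dtype=float)
    wrapped = np.angle(np.exp(1j * phase))
    out = 1000.0 * wrapped / (2.0 * np.pi * frequency_hz)
    return out if out.ndim else float(out)
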