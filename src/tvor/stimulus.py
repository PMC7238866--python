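"""Platform stimulus waveforms and their cycle-window bookkeeping.

Two paradigms are supported:

* **Experiment A** — five sinusoidal sequences at 0.8, 1.6, 1.0, 1.4 and
  1.2 Hz (in that order), six full cycles each, separated by 2-s holds at
  the +6 deg starting position.  The whole record is exactly 40.96 s
  (8192 samples at 200 Hz); the surplus hold time is split equally between
  a leading and a trailing flank.
* **Experiment B** — 22 consecutive half-sine excursions between -6 and
  +6 deg, with the half-cycle frequency stepping through an 11-value
  logarithmic ladder (0.254 ... 1.589 Hz) first ascending and then the same
  ladder descending.  The record starts at -6 deg for a plantarflexion
  start and +6 deg for a dorsiflexion start, and carries 6-s lead/tail
  holds so the lowest-frequency half-cycles sit clear of wavelet edge
  effects.

Every generated trace records one analysis window per stimulus cycle
(Experiment A: 30 full cycles) or half-cycle (Experiment B: 22), which is
the granularity at which phase and gain are later estimated.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal, Sequence

import numpy as np

from .geometry import GeometryParams

__all__ = [
    "EXPA_FREQUENCIES_HZ",
    "EXPB_FREQUENCIES_HZ",
    "CycleWindow",
    "StimulusPlan",
    "PlatformTrace",
    "build_experiment_a",
    "build_experiment_b",
    "invert_platform",
]

#: Experiment A sequence frequencies, in presentation order (Hz).
EXPA_FREQUENCIES_HZ = (0.8, 1.6, 1.0, 1.4, 1.2)
#: Experiment B ascending frequency ladder (Hz); the descending half replays it in reverse.
EXPB_FREQUENCIES_HZ = (0.254, 0.308, 0.362, 0.445, 0.529,
                       0.631, 0.764, 0.927, 1.093, 1.330, 1.589)

EXPA_CYCLES_PER_FREQUENCY = 6
EXPA_PAUSE_S = 2.0
EXPA_DURATION_S = 40.96          # 8192 samples at 200 Hz
EXPB_PAD_S = 6.0                 # lead/tail hold, clears the 0.254 Hz cone of influence


@dataclass(frozen=True)
class CycleWindow:
    """One analysis window: a full stimulus cycle (A) or half-cycle (B)."""

    frequency_hz: float
    cycle_index: int            # A: 1..6 within the sequence; B: 1..22 overall
    start_s: float
    end_s: float
    half_trial: Literal["ascending", "descending", "n/a"] = "n/a"

    @property
    def key(self) -> tuple[float, int]:
        """Profile/lookup key, unique within a plan."""
        return (round(self.frequency_hz, 4), self.cycle_index)


@dataclass(frozen=True)
class _Piece:
    """A time span that is either a hold or a cosine arc from ``level``."""

    t0: float
    t1: float
    level_deg: float
    frequency_hz: float | None = None   # None -> hold at level_deg


@dataclass(frozen=True)
class StimulusPlan:
    """Declarative description of a platform run, with a continuous evaluator."""

    experiment: Literal["A", "B"]
    segments: tuple                      # (frequency_hz, n_half_cycles, start_level_deg)
    start_condition: Literal["dorsiflexion", "plantarflexion"]
    fs: float = 200.0
    pause_s: float = EXPA_PAUSE_S
    total_samples: int = 0
    pieces: tuple = field(default_factory=tuple, repr=False)

    @property
    def duration_s(self) -> float:
        return self.total_samples / self.fs

    def angle_at(self, t) -> np.ndarray:
        """Platform angle (deg) at arbitrary times ``t`` (vectorized).

        Times before the first / after the last piece evaluate to that
        piece's boundary level, so delayed evaluation near the record edges
        stays well defined.
        """
        t = np.asarray(t, dtype=float)
        out = np.full(t.shape, self.pieces[0].level_deg, dtype=float)
        for p in self.pieces:
            m = (t >= p.t0) & (t < p.t1) if p is not self.pieces[-1] else (t >= p.t0)
            if not m.any():
                continue
            if p.frequency_hz is None:
                out[m] = p.level_deg
            else:
                out[m] = p.level_deg * np.cos(2 * np.pi * p.frequency_hz * (t[m] - p.t0))
        return out


@dataclass(frozen=True)
class PlatformTrace:
    """Uniformly sampled platform inclination with cycle-window metadata."""

    t: np.ndarray
    angle_deg: np.ndarray
    fs: float
    plan: StimulusPlan
    cycle_windows: tuple
    inverted: bool = False

    @property
    def duration_s(self) -> float:
        return len(self.t) / self.fs


def _sample(plan: StimulusPlan, windows: Sequence[CycleWindow]) -> PlatformTrace:
    t = np.arange(plan.total_samples) / plan.fs
    return PlatformTrace(t=t, angle_deg=plan.angle_at(t), fs=plan.fs,
                         plan=plan, cycle_windows=tuple(windows))


def build_experiment_a(params: GeometryParams = GeometryParams(),
                       fs: float = 200.0) -> PlatformTrace:
    """Build the Experiment A platform trace (40.96 s, 30 cycle windows).

    Five sequences of six cosine-phase cycles starting and ending at the
    +6 deg hold level, with 2-s holds between sequences and the remaining
    time split equally into lead and tail holds.
    """
    n_total = EXPA_DURATION_S * fs
    if abs(n_total - round(n_total)) > 1e-9:
        raise ValueError(f"fs={fs} does not divide the {EXPA_DURATION_S}-s record "
                         "into an integer number of samples")
    n_total = int(round(n_total))
    amp = params.platform_amplitude_deg

    active = EXPA_CYCLES_PER_FREQUENCY * sum(1.0 / f for f in EXPA_FREQUENCIES_HZ)
    n_pauses = len(EXPA_FREQUENCIES_HZ) - 1
    surplus = EXPA_DURATION_S - active - n_pauses * EXPA_PAUSE_S
    if surplus < 0:
        raise ValueError("stimulus does not fit in the record")
    lead = surplus / 2.0

    pieces: list[_Piece] = [_Piece(0.0, lead, amp)]
    windows: list[CycleWindow] = []
    t0 = lead
    for i, f in enumerate(EXPA_FREQUENCIES_HZ):
        seq_dur = EXPA_CYCLES_PER_FREQUENCY / f
        pieces.append(_Piece(t0, t0 + seq_dur, amp, f))
        for c in range(EXPA_CYCLES_PER_FREQUENCY):
            windows.append(CycleWindow(f, c + 1, t0 + c / f, t0 + (c + 1) / f))
        t0 += seq_dur
        if i < n_pauses:
            pieces.append(_Piece(t0, t0 + EXPA_PAUSE_S, amp))
            t0 += EXPA_PAUSE_S
    pieces.append(_Piece(t0, EXPA_DURATION_S, amp))

    plan = StimulusPlan(experiment="A",
                        segments=tuple((f, 2 * EXPA_CYCLES_PER_FREQUENCY, amp)
                                       for f in EXPA_FREQUENCIES_HZ),
                        start_condition="dorsiflexion", fs=fs,
                        total_samples=n_total, pieces=tuple(pieces))
    return _sample(plan, windows)


def build_experiment_b(params: GeometryParams = GeometryParams(),
                       start_condition: Literal["dorsiflexion", "plantarflexion"]
                       = "plantarflexion",
                       fs: float = 200.0) -> PlatformTrace:
    """Build the Experiment B platform trace (22 half-cycle windows).

    The i-th half-cycle is a half-cosine arc lasting ``1/(2 f_i)`` that
    carries the platform from its current extreme to the opposite one; the
    frequency ladder ascends through the 11 printed values and then
    descends through the same list reversed.  A dorsiflexion start departs
    from +6 deg, a plantarflexion start from -6 deg.
    """
    if start_condition not in ("dorsiflexion", "plantarflexion"):
        raise ValueError(f"invalid start_condition: {start_condition!r}")
    amp = params.platform_amplitude_deg
    level = amp if start_condition == "dorsiflexion" else -amp
    freqs = list(EXPB_FREQUENCIES_HZ) + list(reversed(EXPB_FREQUENCIES_HZ))

    pieces: list[_Piece] = [_Piece(0.0, EXPB_PAD_S, level)]
    windows: list[CycleWindow] = []
    t0 = EXPB_PAD_S
    for i, f in enumerate(freqs):
        dur = 0.5 / f
        pieces.append(_Piece(t0, t0 + dur, level, f))
        half = "ascending" if i < len(EXPB_FREQUENCIES_HZ) else "descending"
        windows.append(CycleWindow(f, i + 1, t0, t0 + dur, half))
        t0 += dur
        level = -level
    end = t0 + EXPB_PAD_S
    pieces.append(_Piece(t0, end, level))

    plan = StimulusPlan(experiment="B",
                        segments=tuple((f, 1, amp) for f in freqs),
                        start_condition=start_condition, fs=fs,
                        total_samples=int(round(end * fs)), pieces=tuple(pieces))
    return _sample(plan, windows)


def invert_platform(trace: PlatformTrace) -> PlatformTrace:
    """Sign-invert a platform trace (metadata flagged), so that in-phase
    compensatory eye movement yields a coherency of +1."""
    return replace(trace, angle_deg=-trace.angle_deg, inverted=not trace.inverted)
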