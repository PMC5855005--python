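"""Synthetic two-channel ground contact force generator with ground truth.

Emulates the statistical structure a treadmill acquisition produces: each
gait cycle (period ``1/cadence_hz``) begins with a stance interval during
which the heel force traces a raised-cosine hump over the first ~75 % of
stance and the ball force a raised-cosine hump over the last ~75 %
(overlapping at mid-stance), followed by a swing interval at baseline.
Seeded Gaussian noise is added and the result clamped at zero.

The peak force grows linearly with walking speed,

    peak = mass_kg * 9.81 * peak_scale * (0.4 + 0.1 * (speed_kmh - 2)),

so that with the defaults the per-cycle maxima at 2-6 km/h fall inside the
300-1300 N band typical of adult walking while per-cycle minima stay in
0-5 N.  Only the monotone speed-force relationship is physiological; the
slope and the hump timing are fixture choices (see docs/methods.md).

Ground-truth labels come from thresholding each channel's *noise-free*
waveform at 50 % of its peak and applying the heel/ball rule table, which
yields the canonical per-cycle event order heel_strike -> stance ->
heel_off -> swing.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .gpda import detect_sequence
from .signal_io import Channel, GcfRecording

__all__ = [
    "GaitProfileParams",
    "generate_walk",
    "generate_speed_change",
    "cycle_slices",
]

_G = 9.81
#: fraction of the stance interval each hump spans
_HUMP_SPAN = 0.75


@dataclass(frozen=True)
class GaitProfileParams:
    """Controls of the synthetic gait generator.

    Parameters
    ----------
    speed_kmh : float
        Walking speed; sets the peak force through the linear speed law.
    cadence_hz : float
        Gait cycles per second for one foot (default 1.0, a typical
        stride rate on a treadmill).
    stance_fraction : float
        Fraction of the cycle spent in stance, 0 < value < 1 (default 0.6).
    mass_kg : float
        Wearer mass (default 67.3 kg, an adult-cohort mean).
    peak_scale : float
        Dimensionless gain of the speed law (default 1.3).
    noise_sd : float
        Per-sample Gaussian noise, newtons (default 2 N — small next to
        the 15 N initial low threshold so cold start is untouched).
    baseline : float
        Unloaded sensor offset, newtons (default 1 N).
    seed : int
        RNG seed; identical seeds give bitwise-identical recordings.
    """

    speed_kmh: float = 4.0
    cadence_hz: float = 1.0
    stance_fraction: float = 0.6
    mass_kg: float = 67.3
    peak_scale: float = 1.3
    noise_sd: float = 2.0
    baseline: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.stance_fraction < 1.0:
            raise ValueError(
                f"stance_fraction must be in (0, 1), got {self.stance_fraction}"
            )
        if self.noise_sd < 0:
            raise ValueError(f"noise_sd must be >= 0, got {self.noise_sd}")
        if self.mass_kg <= 0 or self.cadence_hz <= 0 or self.peak_scale <= 0:
            raise ValueError("mass_kg, cadence_hz and peak_scale must be > 0")
        if self.baseline < 0:
            raise ValueError(f"baseline must be >= 0, got {self.baseline}")
        if self.peak_force <= 0:
            raise ValueError(
                f"speed {self.speed_kmh} km/h yields a nonpositive peak force"
            )

    @property
    def peak_force(self) -> float:
        """Hump peak amplitude (above baseline) in newtons."""
        return (
            self.mass_kg
            * _G
            * self.peak_scale
            * (0.4 + 0.1 * (self.speed_kmh - 2.0))
        )

    def with_peak(self, peak_n: float) -> "GaitProfileParams":
        """Copy with ``peak_scale`` back-solved to hit an exact peak force."""
        factor = self.mass_kg * _G * (0.4 + 0.1 * (self.speed_kmh - 2.0))
        return replace(self, peak_scale=peak_n / factor)


def _clean_channels(
    phase: np.ndarray, peak: np.ndarray | float, stance_fraction: float
) -> tuple[np.ndarray, np.ndarray]:
    """Noise-free ball/heel humps for cycle phases in [0, 1)."""
    sf = stance_fraction
    width = _HUMP_SPAN * sf

    def hump(start: float) -> np.ndarray:
        x = (phase - start) / width
        inside = (x >= 0.0) & (x < 1.0)
        out = np.zeros_like(phase)
        out[inside] = 0.5 * (1.0 - np.cos(2.0 * np.pi * x[inside]))
        return out

    heel = peak * hump(0.0)
    ball = peak * hump(sf - width)
    return ball, heel


def _assemble(
    params: GaitProfileParams,
    phase: np.ndarray,
    peak: np.ndarray | float,
    fs: float,
) -> tuple[GcfRecording, GcfRecording, np.ndarray]:
    ball_clean, heel_clean = _clean_channels(phase, peak, params.stance_fraction)
    ball_clean = ball_clean + params.baseline
    heel_clean = heel_clean + params.baseline

    # truth from the noise-free waveforms at half peak (above baseline)
    half = 0.5 * np.asarray(peak) + params.baseline
    truth, _ = detect_sequence(heel_clean >= half, ball_clean >= half)

    if params.noise_sd > 0:
        rng = np.random.default_rng(params.seed)
        ball_f = ball_clean + rng.normal(0.0, params.noise_sd, phase.size)
        heel_f = heel_clean + rng.normal(0.0, params.noise_sd, phase.size)
        ball_f = np.clip(ball_f, 0.0, None)
        heel_f = np.clip(heel_f, 0.0, None)
    else:
        ball_f, heel_f = ball_clean, heel_clean

    ball = GcfRecording.from_force(ball_f, fs=fs, channel=Channel.BALL)
    heel = GcfRecording.from_force(heel_f, fs=fs, channel=Channel.HEEL)
    return ball, heel, truth


def generate_walk(
    params: GaitProfileParams,
    duration_s: float = 30.0,
    fs: float = 2000.0,
) -> tuple[GcfRecording, GcfRecording, np.ndarray]:
    """Simulate a constant-speed walk.

    Returns
    -------
    ball, heel : GcfRecording
        The two noisy force channels (``round(duration_s * fs)`` samples).
    truth : numpy.ndarray of int8
        Per-sample ground-truth gait label codes.
    """
    if duration_s <= 0 or fs <= 0:
        raise ValueError("duration_s and fs must be positive")
    n = int(round(duration_s * fs))
    t = np.arange(n) / fs
    phase = (t * params.cadence_hz) % 1.0
    return _assemble(params, phase, params.peak_force, fs)


def generate_speed_change(
    params: GaitProfileParams,
    speeds: list[tuple[float, float]],
    fs: float = 2000.0,
) -> tuple[GcfRecording, GcfRecording, np.ndarray]:
    """Simulate a walk whose speed switches between constant segments.

    ``speeds`` is a list of ``(speed_kmh, duration_s)`` pairs.  Each
    segment is rounded to a whole number of gait cycles (at least one) so
    the amplitude switches exactly at a cycle start; a single segment is
    identical to :func:`generate_walk` at the rounded duration.
    """
    if not speeds:
        raise ValueError("need at least one (speed_kmh, duration_s) segment")
    cadence = params.cadence_hz
    phases = []
    peaks = []
    for speed, dur in speeds:
        if dur <= 0:
            raise ValueError("segment durations must be positive")
        n_cycles = max(1, int(round(dur * cadence)))
        n_seg = int(round(n_cycles / cadence * fs))
        t_seg = np.arange(n_seg) / fs
        phases.append((t_seg * cadence) % 1.0)
        peak = replace(params, speed_kmh=float(speed)).peak_force
        peaks.append(np.full(n_seg, peak))
    phase = np.concatenate(phases)
    peak_arr = np.concatenate(peaks)
    return _assemble(params, phase, peak_arr, fs)


def cycle_slices(n: int, fs: float, cadence_hz: float) -> list[slice]:
    """Index ranges of the whole gait cycles in an n-sample trace."""
    period = fs / cadence_hz
    out = []
    k = 0
    while True:
        start = int(round(k * period))
        stop = int(round((k + 1) * period))
        if stop > n:
            break
        out.append(slice(start, stop))
        k += 1
    return out
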