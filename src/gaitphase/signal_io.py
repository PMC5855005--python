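"""Force-trace I/O, sensor calibration, and low-pass filtering.

Ground contact forces (GCFs) are measured by two force sensitive resistors
(FSRs) under the ball and heel of one foot and sampled uniformly (2000 Hz in
the reference acquisition setup).  This module covers everything upstream of
the detectors: the plain-CSV interchange format, conversion of amplifier
voltages (0-5 V spanning 0-200 kg) to newtons, and the second-order
Butterworth low-pass filter (10 Hz cut-off) used to condition raw signals.

The CSV schema is ``time_s,ball_N,heel_N`` for calibrated forces, or
``time_s,ball_V,heel_V`` for raw voltages.  Label output uses
``time_s,ball_status,heel_status,gait_label``.
"""

from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import signal as _sig

__all__ = [
    "Channel",
    "GcfRecording",
    "voltage_to_force",
    "read_gcf_csv",
    "write_gcf_csv",
    "lowpass_filter",
    "write_labels_csv",
]

#: Full-scale load of one FSR channel, kg (0-5 V spans 0-200 kg).
FULL_SCALE_KG = 200.0
#: Amplifier output span, volts.
FULL_SCALE_V = 5.0
#: Default gravitational acceleration, m/s^2.
DEFAULT_G = 9.81

# Serialization precision: sub-microsecond times and millinewton forces
# already exceed the FSR accuracy (+/-0.5 % FS).
_TIME_FMT = "%.6f"
_FORCE_FMT = "%.3f"


class Channel(str, enum.Enum):
    """Which sensor a recording comes from."""

    BALL = "ball"
    HEEL = "heel"


@dataclass(frozen=True)
class GcfRecording:
    """One channel's uniformly sampled force trace.

    Attributes
    ----------
    channel : Channel
        Sensor role (ball or heel of the foot).
    fs : float
        Sampling rate in Hz.
    t : numpy.ndarray
        Sample times in seconds, strictly increasing with spacing ``1/fs``.
    f : numpy.ndarray
        Forces in newtons.  May be slightly negative from sensor noise
        before clamping.
    """

    channel: Channel
    fs: float
    t: np.ndarray = field(repr=False)
    f: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        t = np.asarray(self.t, dtype=float)
        f = np.asarray(self.f, dtype=float)
        object.__setattr__(self, "channel", Channel(self.channel))
        object.__setattr__(self, "t", t)
        object.__setattr__(self, "f", f)
        if not self.fs > 0:
            raise ValueError(f"sampling rate must be positive, got {self.fs}")
        if t.ndim != 1 or f.ndim != 1 or t.size != f.size:
            raise ValueError("t and f must be 1-D arrays of equal length")
        if t.size == 0:
            raise ValueError("recording must contain at least one sample")
        if not (np.all(np.isfinite(t)) and np.all(np.isfinite(f))):
            raise ValueError("times and forces must be finite")
        if t.size >= 2:
            dt = np.diff(t)
            if np.any(dt <= 0):
                raise ValueError("sample times must be strictly increasing")
            step = 1.0 / self.fs
            # Absolute slack absorbs 6-decimal serialization rounding.
            if not np.allclose(dt, step, rtol=1e-6, atol=2e-6):
                raise ValueError(
                    f"sample spacing is not uniform at 1/fs = {step:g} s"
                )

    @property
    def n(self) -> int:
        """Number of samples."""
        return int(self.t.size)

    @property
    def duration(self) -> float:
        """Trace duration in seconds (n / fs)."""
        return self.n / self.fs

    @classmethod
    def from_force(
        cls,
        f: np.ndarray,
        fs: float,
        channel: Channel | str,
        t0: float = 0.0,
    ) -> "GcfRecording":
        """Build a recording from a force array with implicit time base."""
        f = np.asarray(f, dtype=float)
        t = t0 + np.arange(f.size) / float(fs)
        return cls(channel=Channel(channel), fs=float(fs), t=t, f=f)

    def with_force(self, f: np.ndarray) -> "GcfRecording":
        """Copy of the recording with a replacement force array."""
        return replace(self, f=np.asarray(f, dtype=float))


def voltage_to_force(v, g: float = DEFAULT_G):
    """Convert amplifier output volts to ground contact force in newtons.

    The amplified FSR output spans 0-5 V for 0-200 kg of applied mass, so
    ``F = (v / 5) * 200 * g``.  Values outside [0, 5] V are clamped with a
    warning (sensor saturation is expected; losing a trial is not).

    Parameters
    ----------
    v : float or array_like
        Voltage(s) in the nominal 0-5 V range.
    g : float
        Gravitational acceleration in m/s^2 (default 9.81).

    Returns
    -------
    float or numpy.ndarray
        Force in newtons, same shape as ``v``.
    """
    arr = np.asarray(v, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise ValueError("voltage must be finite")
    if np.any(arr < 0.0) or np.any(arr > FULL_SCALE_V):
        warnings.warn(
            "voltage outside the 0-5 V range clamped to full scale",
            stacklevel=2,
        )
        arr = np.clip(arr, 0.0, FULL_SCALE_V)
    force = arr / FULL_SCALE_V * FULL_SCALE_KG * g
    if np.isscalar(v) or np.ndim(v) == 0:
        return float(force)
    return force


def _require_columns(df: pd.DataFrame, names: tuple[str, ...]) -> bool:
    return all(name in df.columns for name in names)


def read_gcf_csv(
    path, g: float = DEFAULT_G
) -> tuple[GcfRecording, GcfRecording]:
    """Read a two-channel force CSV into (ball, heel) recordings.

    The header must name ``time_s`` plus either ``ball_N,heel_N``
    (calibrated forces) or ``ball_V,heel_V`` (raw voltages, converted with
    :func:`voltage_to_force`).  The sampling rate is inferred from the
    median time step.

    Raises
    ------
    ValueError
        On a missing column, non-monotone time, or fewer than 2 rows.
    """
    df = pd.read_csv(path)
    if "time_s" not in df.columns:
        raise ValueError("schema error: missing required column 'time_s'")
    if _require_columns(df, ("ball_N", "heel_N")):
        ball_f = df["ball_N"].to_numpy(dtype=float)
        heel_f = df["heel_N"].to_numpy(dtype=float)
    elif _require_columns(df, ("ball_V", "heel_V")):
        ball_f = voltage_to_force(df["ball_V"].to_numpy(dtype=float), g=g)
        heel_f = voltage_to_force(df["heel_V"].to_numpy(dtype=float), g=g)
    else:
        raise ValueError(
            "schema error: need columns ball_N,heel_N or ball_V,heel_V"
        )
    if len(df) < 2:
        raise ValueError("format error: need at least 2 rows to infer fs")
    t = df["time_s"].to_numpy(dtype=float)
    dt = np.diff(t)
    if np.any(dt <= 0):
        raise ValueError("format error: time column is not strictly increasing")
    fs = 1.0 / float(np.median(dt))
    ball = GcfRecording(channel=Channel.BALL, fs=fs, t=t, f=ball_f)
    heel = GcfRecording(channel=Channel.HEEL, fs=fs, t=t, f=heel_f)
    return ball, heel


def write_gcf_csv(path, ball: GcfRecording, heel: GcfRecording) -> None:
    """Write (ball, heel) recordings to the shared CSV schema.

    Times carry 6 decimal places and forces 3; a write/read/write round
    trip is byte-identical.
    """
    if ball.n != heel.n:
        raise ValueError("ball and heel recordings must have equal length")
    data = np.column_stack([ball.t, ball.f, heel.f])
    np.savetxt(
        path,
        data,
        fmt=[_TIME_FMT, _FORCE_FMT, _FORCE_FMT],
        delimiter=",",
        header="time_s,ball_N,heel_N",
        comments="",
    )


def lowpass_filter(
    rec: GcfRecording,
    cutoff: float = 10.0,
    order: int = 2,
    mode: str = "causal",
) -> GcfRecording:
    """Butterworth low-pass filter a recording.

    ``mode='causal'`` (the default) applies the filter in a single forward
    pass, so the output at sample ``k`` depends only on samples ``<= k`` —
    the contract a real-time detector needs.  ``mode='zero_phase'`` applies
    it forward and backward (no phase delay, but acausal; the effective
    magnitude response is squared) for offline analysis.

    Raises
    ------
    ValueError
        If ``cutoff`` is not inside (0, fs/2).
    """
    nyq = rec.fs / 2.0
    if not 0.0 < cutoff < nyq:
        raise ValueError(
            f"cutoff must lie in (0, {nyq:g}) Hz for fs = {rec.fs:g} Hz"
        )
    sos = _sig.butter(order, cutoff, btype="low", fs=rec.fs, output="sos")
    if mode == "causal":
        out = _sig.sosfilt(sos, rec.f)
    elif mode == "zero_phase":
        out = _sig.sosfiltfilt(sos, rec.f)
    else:
        raise ValueError(f"mode must be 'causal' or 'zero_phase', got {mode!r}")
    return rec.with_force(out)


def write_labels_csv(path, t, ball_on, heel_on, labels) -> None:
    """Write per-sample statuses and gait labels.

    Columns: ``time_s,ball_status,heel_status,gait_label`` with statuses in
    {on, off} and labels in {stance, swing, heel_strike, heel_off}.
    """
    from .gpda import GaitLabel  # local import avoids a cycle

    t = np.asarray(t, dtype=float)
    ball_on = np.asarray(ball_on, dtype=bool)
    heel_on = np.asarray(heel_on, dtype=bool)
    labels = np.asarray(labels)
    if not (t.size == ball_on.size == heel_on.size == labels.size):
        raise ValueError("all columns must have equal length")
    status = np.array(["off", "on"])
    names = np.array([GaitLabel(c).label for c in range(4)])
    df = pd.DataFrame(
        {
            "time_s": [(_TIME_FMT % x) for x in t],
            "ball_status": status[ball_on.astype(int)],
            "heel_status": status[heel_on.astype(int)],
            "gait_label": names[labels.astype(int)],
        }
    )
    df.to_csv(path, index=False)
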