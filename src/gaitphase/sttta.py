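"""Self-tuning triple-threshold detection of foot-ground contact.

A single fixed threshold on a ground contact force (GCF) trace cannot track
different wearers or walking speeds, and a single *adaptive* threshold can
retune itself twice in one gait cycle when the force re-crosses it after an
update.  The self-tuning triple-threshold algorithm (STTTA) avoids both
problems with three ordered thresholds per sensor channel:

* ``t_h`` (high) bounds the per-cycle *maximum* search region and is the
  main threshold splitting samples into on-ground (``f >= t_h``) and
  off-ground statuses;
* ``t_m`` (middle) marks the *time points* at which ``t_h`` and ``t_l`` are
  retuned (its rising and falling crossings), keeping each retune away from
  the region whose extremum feeds it;
* ``t_l`` (low) bounds the per-cycle *minimum* search region and marks the
  point at which ``t_m`` is retuned.

Once per gait cycle, with ``T_max`` / ``T_min`` the extrema captured in the
regions above ``t_h`` and below ``t_l``:

* at the falling ``t_m`` crossing:  ``t_h <- beta  * (T_max - t_l) + t_l``
* at the falling ``t_l`` crossing:  ``t_m <- gamma * (T_max - t_l) + t_l``
* at the next rising ``t_m`` crossing:  ``t_l <- lam * T_min + (1 - lam) * t_m``

``beta``, ``gamma``, ``lam`` are dimensionless proportions with
``0 < gamma < beta < 1``; because each update fires at a distinct,
ordered point of the cycle, every threshold is recomputed exactly once per
complete cycle, and the triple stays ordered ``t_l < t_m < t_h``.

The state machine is strictly causal: the contact status emitted for sample
``k`` depends only on samples ``<= k``.  It expects a low-pass-filtered
input (see :func:`gaitphase.signal_io.lowpass_filter`); raw wide-band noise
comparable to the threshold gaps can fake crossings.
"""

from __future__ import annotations

import enum
import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from .signal_io import GcfRecording

__all__ = [
    "StttaParams",
    "ThresholdTriple",
    "ContactStatus",
    "CyclePoint",
    "StttaState",
    "ThresholdUpdate",
    "ThresholdTrace",
    "init_state",
    "classify_sample",
    "step",
    "run_sttta",
    "fixed_point_thresholds",
]


class ContactStatus(enum.Enum):
    """Binary per-sample contact state of one sensor."""

    ON_GROUND = "on_ground"
    OFF_GROUND = "off_ground"

    @property
    def is_on(self) -> bool:
        return self is ContactStatus.ON_GROUND


@dataclass(frozen=True)
class StttaParams:
    """Tuning constants of the triple-threshold detector.

    Parameters
    ----------
    beta, gamma : float
        Proportions placing ``t_h`` and ``t_m`` between the low threshold
        and the per-cycle maximum; require ``0 < gamma < beta < 1``.
        Defaults 0.071 and 0.042 (grid-searched for maximum reliability
        against post-hoc reference methods).
    lam : float
        Mixing weight placing ``t_l`` between the per-cycle minimum and
        ``t_m``; ``0 < lam < 1``, default 0.5.
    t_l0, t_m0, t_h0 : float
        Initial thresholds in newtons, ``t_l0 < t_m0 < t_h0``.  Defaults
        (15, 20, 25) N sit between typical swing minima (0-5 N) and stance
        maxima (300-1300 N), so the same initial triple serves any wearer.
    """

    beta: float = 0.071
    gamma: float = 0.042
    lam: float = 0.5
    t_l0: float = 15.0
    t_m0: float = 20.0
    t_h0: float = 25.0

    def __post_init__(self) -> None:
        if not 0.0 < self.gamma < self.beta < 1.0:
            raise ValueError(
                f"require 0 < gamma < beta < 1, got gamma={self.gamma}, "
                f"beta={self.beta}"
            )
        if not 0.0 < self.lam < 1.0:
            raise ValueError(f"require 0 < lam < 1, got {self.lam}")
        if not self.t_l0 < self.t_m0 < self.t_h0:
            raise ValueError(
                f"initial thresholds must satisfy t_l0 < t_m0 < t_h0, got "
                f"({self.t_l0}, {self.t_m0}, {self.t_h0})"
            )


@dataclass(frozen=True)
class ThresholdTriple:
    """Ordered (t_l, t_m, t_h) threshold values in newtons."""

    t_l: float
    t_m: float
    t_h: float

    def __post_init__(self) -> None:
        if not self.t_l < self.t_m < self.t_h:
            raise ValueError(
                f"thresholds must satisfy t_l < t_m < t_h, got "
                f"({self.t_l}, {self.t_m}, {self.t_h})"
            )

    def as_tuple(self) -> tuple[float, float, float]:
        return (self.t_l, self.t_m, self.t_h)


class CyclePoint(enum.Enum):
    """Derived phase of the per-cycle point machinery (for introspection)."""

    UNSYNCED = "unsynced"
    ABOVE_TM_RISING = "above_tm_rising"
    IN_MAX_REGION = "in_max_region"
    AFTER_MAX = "after_max"
    BELOW_TM = "below_tm"
    IN_MIN_REGION = "in_min_region"
    AFTER_MIN = "after_min"


@dataclass(frozen=True)
class ThresholdUpdate:
    """One accepted threshold retune event."""

    index: int  # sample index at which the new value took effect
    name: str  # "t_l" | "t_m" | "t_h"
    old: float
    new: float
    cycle_i: int  # completed-cycle counter at the time of the update


@dataclass(slots=True)
class StttaState:
    """Mutable per-channel online state of the detector.

    ``i`` counts completed gait cycles (incremented when the minimum search
    region closes); ``j`` counts finalized per-cycle maxima.  They may
    differ when incomplete cycles occur at the trace boundaries.
    """

    params: StttaParams
    t_l: float = 0.0
    t_m: float = 0.0
    t_h: float = 0.0
    max_acc: float | None = None  # running per-cycle maximum (region above t_h)
    min_acc: float | None = None  # running per-cycle minimum (region below t_l)
    last_tmax: float | None = None
    last_tmin: float | None = None
    i: int = 0
    j: int = 0
    k: int = 0  # samples consumed
    prev_f: float = -math.inf  # pre-stream treated as "below everything"
    synced: bool = False  # first rising t_m crossing seen
    in_max: bool = False
    in_min: bool = False
    rejected_updates: int = 0
    events: list = field(default_factory=list)
    # per-cycle one-shot latches, reset when a cycle completes (point g)
    _tl_done: bool = False
    _e_done: bool = False
    _f_done: bool = False
    _g_since_b: bool = False  # cycle completed, rising t_m crossing pending
    _cycle_tmax: float | None = None  # T_max finalized in the current cycle

    @property
    def thresholds(self) -> ThresholdTriple:
        return ThresholdTriple(self.t_l, self.t_m, self.t_h)

    @property
    def phase_point(self) -> CyclePoint:
        if not self.synced:
            return CyclePoint.UNSYNCED
        if self.in_max:
            return CyclePoint.IN_MAX_REGION
        if self.in_min:
            return CyclePoint.IN_MIN_REGION
        if self.max_acc is not None:
            return CyclePoint.AFTER_MAX
        if self._e_done:
            return CyclePoint.BELOW_TM
        if self._g_since_b:
            return CyclePoint.AFTER_MIN
        return CyclePoint.ABOVE_TM_RISING


def init_state(params: StttaParams) -> StttaState:
    """Fresh detector state with thresholds at their initial values."""
    return StttaState(
        params=params, t_l=params.t_l0, t_m=params.t_m0, t_h=params.t_h0
    )


def classify_sample(f: float, t_h: float) -> ContactStatus:
    """On-ground iff ``f >= t_h`` (the boundary sample counts as contact)."""
    if not (math.isfinite(f) and math.isfinite(t_h)):
        raise ValueError("force and threshold must be finite")
    return ContactStatus.ON_GROUND if f >= t_h else ContactStatus.OFF_GROUND


def _try_update(state: StttaState, name: str, new: float) -> bool:
    """Apply a retune if it keeps t_l < t_m < t_h; otherwise keep and warn."""
    triple = {"t_l": state.t_l, "t_m": state.t_m, "t_h": state.t_h}
    old = triple[name]
    triple[name] = new
    if not triple["t_l"] < triple["t_m"] < triple["t_h"]:
        state.rejected_updates += 1
        warnings.warn(
            f"rejected {name} update {old:.3f} -> {new:.3f} N at sample "
            f"{state.k}: would violate threshold ordering",
            stacklevel=3,
        )
        return False
    setattr(state, name, new)
    state.events.append(
        ThresholdUpdate(
            index=state.k, name=name, old=old, new=new, cycle_i=state.i
        )
    )
    return True


def step(state: StttaState, f: float) -> ContactStatus:
    """Consume one force sample; return its contact status.

    The state is advanced in place.  The status is judged against the
    ``t_h`` in effect when the sample arrives; retunes computed at this
    sample take effect from this sample onward (their computation points
    precede the comparison regions they serve).

    Crossings are detected between the previous and current sample, and a
    falling sample that crosses several thresholds at once fires its points
    in cycle order (maximum close, then the ``t_h`` retune, then the
    ``t_m`` retune / minimum open); likewise for rising samples.
    """
    if not math.isfinite(f):
        raise ValueError(f"force must be finite, got {f!r}")
    p = state.params
    prev = state.prev_f
    status = (
        ContactStatus.ON_GROUND if f >= state.t_h else ContactStatus.OFF_GROUND
    )

    # ---- rising machinery: cycle end (g), rising t_m crossing (b/h),
    #      maximum search region entry/extension ----
    if state.in_min and f > state.t_l:
        # point g: the minimum search region closes; the cycle is complete
        state.last_tmin = state.min_acc
        state.min_acc = None
        state.in_min = False
        state.i += 1
        state._tl_done = False
        state._e_done = False
        state._f_done = False
        state._cycle_tmax = None
        state._g_since_b = True

    if (not state.synced or state._g_since_b) and prev < state.t_m <= f:
        # point b (== point h of the previous cycle): rising t_m crossing.
        # Retune t_l from the minimum of the cycle that just completed; on
        # a cold start no T_min exists yet and the retune is skipped.
        state._g_since_b = False
        if (
            state.synced
            and state.last_tmin is not None
            and not state._tl_done
            and not state._e_done
        ):
            new_tl = p.lam * state.last_tmin + (1.0 - p.lam) * state.t_m
            _try_update(state, "t_l", new_tl)
            state._tl_done = True
        state.synced = True

    if state.synced and not state._e_done and f >= state.t_h:
        # region [c, d]: track the per-cycle maximum.  On re-entry within
        # the same cycle the accumulator is kept, never re-initialized, so
        # a double-humped stance cannot shrink T_max; after the t_h retune
        # has fired, further excursions are ignored until the next cycle.
        if state.max_acc is None or f > state.max_acc:
            state.max_acc = f
        state.in_max = True
    elif state.in_max:
        state.in_max = False  # fell below t_h; T_max pending until point e

    # ---- falling machinery: t_h retune (e), t_m retune / minimum region
    #      open (point f), minimum extension ----
    if (
        state.max_acc is not None
        and not state._e_done
        and prev >= state.t_m > f
    ):
        # point e: falling t_m crossing finalizes T_max and retunes t_h
        state.last_tmax = state.max_acc
        state._cycle_tmax = state.max_acc
        state.max_acc = None
        state.in_max = False
        state.j += 1
        new_th = p.beta * (state._cycle_tmax - state.t_l) + state.t_l
        _try_update(state, "t_h", new_th)
        state._e_done = True

    if (
        state.synced
        and not state._g_since_b
        and not state.in_min
        and prev > state.t_l >= f
    ):
        # point f: falling t_l crossing retunes t_m and opens the minimum
        # search region.  Without a finalized T_max this cycle (incomplete
        # cycle) the retune is skipped but the minimum is still tracked.
        if state._cycle_tmax is not None and not state._f_done:
            new_tm = p.gamma * (state._cycle_tmax - state.t_l) + state.t_l
            _try_update(state, "t_m", new_tm)
            state._f_done = True
        if state.min_acc is None or f < state.min_acc:
            state.min_acc = f
        state.in_min = True
    elif state.in_min and f <= state.t_l:
        # region [f, g]: track the per-cycle minimum
        if f < state.min_acc:
            state.min_acc = f

    state.prev_f = f
    state.k += 1
    return status


@dataclass(frozen=True)
class ThresholdTrace:
    """Per-sample thresholds in effect plus the retune event log.

    The arrays hold the values in effect *after* each sample was processed
    (thresholds are piecewise-constant between events).
    """

    fs: float
    t0: float
    t_l: np.ndarray = field(repr=False)
    t_m: np.ndarray = field(repr=False)
    t_h: np.ndarray = field(repr=False)
    events: tuple[ThresholdUpdate, ...] = ()

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.t_l.size) / self.fs

    def event_time(self, ev: ThresholdUpdate) -> float:
        return self.t0 + ev.index / self.fs

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "time_s": self.times,
                "t_l": self.t_l,
                "t_m": self.t_m,
                "t_h": self.t_h,
            }
        )

    def events_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "time_s": [self.event_time(ev) for ev in self.events],
                "threshold": [ev.name for ev in self.events],
                "old_N": [ev.old for ev in self.events],
                "new_N": [ev.new for ev in self.events],
                "cycle_i": [ev.cycle_i for ev in self.events],
            }
        )

    def write_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False, float_format="%.6f")

    def write_events_csv(self, path) -> None:
        self.events_frame().to_csv(path, index=False, float_format="%.6f")


def run_sttta(
    rec: GcfRecording, params: StttaParams
) -> tuple[np.ndarray, ThresholdTrace]:
    """Run the detector over a whole recording.

    Equivalent to folding :func:`step` over the samples (the streaming and
    batch paths share the same state machine).

    Returns
    -------
    status : numpy.ndarray of bool
        Per-sample contact status, ``True`` = on-ground.
    trace : ThresholdTrace
        Thresholds in effect per sample and the retune event log.
    """
    if rec.n == 0:
        raise ValueError("recording must be non-empty")
    state = init_state(params)
    n = rec.n
    status = np.empty(n, dtype=bool)
    tl = np.empty(n)
    tm = np.empty(n)
    th = np.empty(n)
    forces = rec.f.tolist()
    for k, f in enumerate(forces):
        status[k] = step(state, f) is ContactStatus.ON_GROUND
        tl[k] = state.t_l
        tm[k] = state.t_m
        th[k] = state.t_h
    trace = ThresholdTrace(
        fs=rec.fs,
        t0=float(rec.t[0]),
        t_l=tl,
        t_m=tm,
        t_h=th,
        events=tuple(state.events),
    )
    return status, trace


def fixed_point_thresholds(
    M: float, m: float, params: StttaParams
) -> ThresholdTriple:
    """Stationary thresholds for constant per-cycle extrema ``M`` and ``m``.

    With the per-cycle maximum fixed at ``M`` and minimum at ``m``, the
    three retune rules form a linear system whose unique fixed point is

    .. math::

        t_l^* = \\frac{\\lambda m + (1-\\lambda)\\gamma M}
                      {\\lambda + (1-\\lambda)\\gamma},
        \\qquad
        t_m^* = t_l^* + \\gamma (M - t_l^*),
        \\qquad
        t_h^* = t_l^* + \\beta (M - t_l^*).

    The detector converges to this triple geometrically, contracting the
    ``t_l`` error by a factor ``(1 - lam) * (1 - gamma)`` per cycle.  Used
    as the analytic oracle for convergence and adaptation tests.
    """
    if not m < M:
        raise ValueError(f"require m < M, got m={m}, M={M}")
    lam, gamma, beta = params.lam, params.gamma, params.beta
    t_l = (lam * m + (1.0 - lam) * gamma * M) / (lam + (1.0 - lam) * gamma)
    t_m = t_l + gamma * (M - t_l)
    t_h = t_l + beta * (M - t_l)
    return ThresholdTriple(t_l=t_l, t_m=t_m, t_h=t_h)
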