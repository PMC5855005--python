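"""Gait phase detection from paired heel/ball contact statuses.

With each sensor reduced to a binary on/off-ground status, the pair
(heel, ball) maps to one of four gait labels for a single foot:

=========  =========  ==========  ============
heel       ball       category    label
=========  =========  ==========  ============
on-ground  on-ground  phase       stance
off        off        phase       swing
on-ground  off        event       heel_strike
off        on-ground  event       heel_off
=========  =========  ==========  ============

The two event labels describe combined states that persist over samples
(heel down before the ball lands; heel up while the ball still bears load),
so every sample in such a state carries the event label, and the discrete
event timestamp is the first sample of each maximal run.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

import numpy as np

from .sttta import ContactStatus

__all__ = ["GaitLabel", "GaitEvent", "label_sample", "detect_sequence"]


class GaitLabel(enum.IntEnum):
    """Per-sample gait classification (integer-coded for array use)."""

    SWING = 0
    STANCE = 1
    HEEL_STRIKE = 2
    HEEL_OFF = 3

    @property
    def category(self) -> str:
        """'phase' for stance/swing, 'event' for heel_strike/heel_off."""
        return "phase" if self in (GaitLabel.SWING, GaitLabel.STANCE) else "event"

    @property
    def label(self) -> str:
        return self.name.lower()


# row index = 2*heel_on + ball_on
_CODE_TO_LABEL = np.array(
    [GaitLabel.SWING, GaitLabel.HEEL_OFF, GaitLabel.HEEL_STRIKE, GaitLabel.STANCE],
    dtype=np.int8,
)


@dataclass(frozen=True)
class GaitEvent:
    """A discrete gait event (first sample of a heel_strike/heel_off run)."""

    label: GaitLabel
    index: int
    t: float
    cycle_index: int


def _as_on_array(statuses) -> np.ndarray:
    """Normalize a status sequence to a boolean on-ground array."""
    arr = np.asarray(statuses)
    if arr.dtype == object or (arr.size and isinstance(arr.flat[0], ContactStatus)):
        return np.array([ContactStatus(s).is_on for s in statuses], dtype=bool)
    return arr.astype(bool)


def label_sample(
    heel: ContactStatus | bool, ball: ContactStatus | bool
) -> GaitLabel:
    """Map one (heel, ball) status pair to its gait label (total function)."""
    h = heel.is_on if isinstance(heel, ContactStatus) else bool(heel)
    b = ball.is_on if isinstance(ball, ContactStatus) else bool(ball)
    return GaitLabel(_CODE_TO_LABEL[2 * h + b])


def _merge_short_runs(labels: np.ndarray, min_run: int) -> np.ndarray:
    """Absorb runs shorter than ``min_run`` into the preceding run's label."""
    out = labels.copy()
    n = out.size
    start = 0
    prev_label = None
    while start < n:
        stop = start + 1
        while stop < n and out[stop] == out[start]:
            stop += 1
        if stop - start < min_run and prev_label is not None:
            out[start:stop] = prev_label
        else:
            prev_label = out[start]
        start = stop
    return out


def detect_sequence(
    heel_statuses,
    ball_statuses,
    fs: float | None = None,
    t0: float = 0.0,
    min_run: int = 0,
) -> tuple[np.ndarray, list[GaitEvent]]:
    """Label a status stream and extract discrete gait events.

    Parameters
    ----------
    heel_statuses, ball_statuses : sequence of ContactStatus or bool array
        Per-sample contact statuses (``True`` = on-ground); equal lengths.
    fs, t0 : float, optional
        Sampling rate and start time used to timestamp events.  Without
        ``fs`` event times are sample indices.
    min_run : int
        Optional debounce: label runs shorter than this many samples are
        merged into the preceding run (default 0 = off).

    Returns
    -------
    labels : numpy.ndarray of int8
        Per-sample :class:`GaitLabel` codes, same length as the input.
    events : list of GaitEvent
        One event per maximal heel_strike/heel_off run, at its first
        sample, in time order.  ``cycle_index`` counts heel strikes; a
        heel_off belongs to the cycle opened by the preceding heel strike.
    """
    heel = _as_on_array(heel_statuses)
    ball = _as_on_array(ball_statuses)
    if heel.size != ball.size:
        raise ValueError(
            f"status sequences differ in length: {heel.size} vs {ball.size}"
        )
    code = 2 * heel.astype(np.int8) + ball.astype(np.int8)
    labels = _CODE_TO_LABEL[code]
    if min_run > 0:
        labels = _merge_short_runs(labels, min_run)

    events: list[GaitEvent] = []
    cycle = 0
    n = labels.size
    boundaries = np.flatnonzero(np.diff(labels)) + 1
    starts = np.concatenate(([0], boundaries)) if n else np.array([], dtype=int)
    for s in starts:
        lab = GaitLabel(labels[s])
        if lab.category != "event":
            continue
        if lab is GaitLabel.HEEL_STRIKE:
            cycle += 1
        t = t0 + (s / fs if fs else float(s))
        events.append(GaitEvent(label=lab, index=int(s), t=t, cycle_index=cycle))
    return labels, events
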