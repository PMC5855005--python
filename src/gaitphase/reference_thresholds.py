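"""Reference (constant-threshold) contact detection methods.

Three established ways of choosing the single threshold ``T`` that splits a
ground contact force trace into on-ground (``f >= T``) and off-ground
samples:

* **Mariani** — 5 % of body weight, ``T = 0.05 * m * g``.  Usable in real
  time but fixed per subject, so it cannot track walking speed.
* **TAM** (timing analysis module) — 10 % of the span between the global
  extrema of the whole recording, ``T = T_min + 0.1 * (T_max - T_min)``,
  computed per channel per trial in post-processing.
* **Lopez-Meyer** — like TAM but using the *averages* of the per-cycle
  local maxima and minima, ``T = TMIN + alpha * (TMAX - TMIN)`` with
  ``alpha = 0.084`` by default.

The two span-based methods need the whole recording, so they serve as
post-hoc references against which a real-time detector is scored.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .signal_io import DEFAULT_G, GcfRecording

__all__ = [
    "ExtremaSummary",
    "mariani_threshold",
    "tam_threshold",
    "find_cycle_extrema",
    "lopez_meyer_threshold",
    "classify_with_threshold",
]

DEFAULT_ALPHA = 0.084  # Lopez-Meyer inter-individual compensation factor


@dataclass(frozen=True)
class ExtremaSummary:
    """Per-cycle local extrema of one recording.

    The counts of maxima and minima may differ by one when the trace starts
    or ends inside an incomplete gait cycle.
    """

    local_maxima: tuple[float, ...]
    local_minima: tuple[float, ...]
    global_max: float
    global_min: float


def mariani_threshold(mass_kg: float, g: float = DEFAULT_G) -> float:
    """Body-weight threshold: 5 % of ``mass_kg * g`` newtons."""
    if not mass_kg > 0:
        raise ValueError(f"mass must be positive, got {mass_kg}")
    return 0.05 * mass_kg * g


def tam_threshold(rec: GcfRecording) -> float:
    """Global-extrema threshold: minimum plus 10 % of the force span."""
    if rec.n == 0:
        raise ValueError("recording must be non-empty")
    fmax = float(np.max(rec.f))
    fmin = float(np.min(rec.f))
    return fmin + (fmax - fmin) * 10.0 / 100.0


def find_cycle_extrema(rec: GcfRecording, split_level: float) -> ExtremaSummary:
    """Locate one local extremum per gait half-cycle.

    The trace is segmented into maximal runs at-or-above and below
    ``split_level`` (the same ``>=`` convention as contact
    classification); each above-run contributes its maximum and each
    below-run its minimum.  Leading/trailing incomplete runs contribute an
    extremum only to their own list, so the counts may differ.

    ``split_level`` must lie within the data range.
    """
    if rec.n == 0:
        raise ValueError("recording must be non-empty")
    gmax = float(np.max(rec.f))
    gmin = float(np.min(rec.f))
    if not gmin <= split_level <= gmax:
        raise ValueError(
            f"split level {split_level} outside data range [{gmin}, {gmax}]"
        )
    above = rec.f >= split_level
    boundaries = np.flatnonzero(np.diff(above)) + 1
    starts = np.concatenate(([0], boundaries, [rec.n]))
    maxima: list[float] = []
    minima: list[float] = []
    for s, e in zip(starts[:-1], starts[1:]):
        seg = rec.f[s:e]
        if above[s]:
            maxima.append(float(seg.max()))
        else:
            minima.append(float(seg.min()))
    return ExtremaSummary(
        local_maxima=tuple(maxima),
        local_minima=tuple(minima),
        global_max=gmax,
        global_min=gmin,
    )


def lopez_meyer_threshold(
    ext: ExtremaSummary, alpha: float = DEFAULT_ALPHA
) -> float:
    """Averaged-extrema threshold ``TMIN + alpha * (TMAX - TMIN)``."""
    if not ext.local_maxima or not ext.local_minima:
        raise ValueError("need at least one local maximum and one minimum")
    tmax = float(np.mean(ext.local_maxima))
    tmin = float(np.mean(ext.local_minima))
    return tmin + alpha * (tmax - tmin)


def classify_with_threshold(rec: GcfRecording, t: float) -> np.ndarray:
    """Per-sample contact status: ``True`` (on-ground) iff ``f >= t``."""
    if rec.n == 0:
        raise ValueError("recording must be non-empty")
    return rec.f >= t
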