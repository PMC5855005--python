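"""Reliability scoring of gait-label streams and beta/gamma tuning.

Reliability is defined here as the per-sample gait-label agreement
percentage between two methods run on the same recording: the fraction of
samples at which both pipelines emit the same :class:`~gaitphase.gpda.GaitLabel`,
times 100.  The score is symmetric, bounded in [0, 100], and equals 100
exactly when the label streams are identical.

The adaptive detector starts from fixed initial thresholds and needs about
one cycle before its thresholds are informative, while the span-based
reference methods see the whole trace; an optional burn-in (in samples)
excludes that cold-start transient from scoring.

:func:`grid_search` reproduces the tuning procedure for the proportion
factors: for each (beta, gamma) pair with ``gamma < beta``, run the
adaptive detector plus phase rules on every training recording, score
against a reference method's labels, and average; the best cell (ties
broken toward the smallest beta, then gamma) is returned together with the
whole reliability surface.
"""

from __future__ import annotations

from dataclasses import dataclass, replace as _dc_replace

import numpy as np
import pandas as pd

from .gpda import GaitLabel, detect_sequence
from .reference_thresholds import (
    classify_with_threshold,
    find_cycle_extrema,
    lopez_meyer_threshold,
    mariani_threshold,
    tam_threshold,
)
from .signal_io import GcfRecording
from .sttta import StttaParams, run_sttta

__all__ = [
    "ReliabilityReport",
    "GridSearchResult",
    "agreement",
    "labels_for_method",
    "grid_search",
]

_N_LABELS = len(GaitLabel)


@dataclass(frozen=True)
class ReliabilityReport:
    """Sample-wise agreement between two label streams."""

    percent_agreement: float
    n_samples: int
    confusion: np.ndarray  # rows = method_a label, cols = method_b label
    method_a: str = "a"
    method_b: str = "b"

    def to_dict(self) -> dict:
        labels = [lab.label for lab in GaitLabel]
        return {
            "method_a": self.method_a,
            "method_b": self.method_b,
            "percent_agreement": self.percent_agreement,
            "n_samples": self.n_samples,
            "confusion": {
                la: {
                    lb: int(self.confusion[ia, ib])
                    for ib, lb in enumerate(labels)
                }
                for ia, la in enumerate(labels)
            },
        }


def agreement(
    labels_a, labels_b, method_a: str = "a", method_b: str = "b"
) -> ReliabilityReport:
    """Score two equal-length gait-label sequences.

    Returns the match percentage and the 4x4 confusion counts (which sum
    to the number of samples).
    """
    a = np.asarray(labels_a, dtype=np.int64)
    b = np.asarray(labels_b, dtype=np.int64)
    if a.size == 0:
        raise ValueError("label sequences must be non-empty")
    if a.size != b.size:
        raise ValueError(f"length mismatch: {a.size} vs {b.size}")
    confusion = np.bincount(
        a * _N_LABELS + b, minlength=_N_LABELS * _N_LABELS
    ).reshape(_N_LABELS, _N_LABELS)
    pct = 100.0 * float(np.trace(confusion)) / a.size
    return ReliabilityReport(
        percent_agreement=pct,
        n_samples=int(a.size),
        confusion=confusion,
        method_a=method_a,
        method_b=method_b,
    )


def labels_for_method(
    ball: GcfRecording,
    heel: GcfRecording,
    method: str,
    sttta_params: StttaParams | None = None,
    mass_kg: float | None = None,
    alpha: float = 0.084,
    g: float = 9.81,
) -> tuple[np.ndarray, dict]:
    """Run one detection method end to end and return its gait labels.

    ``method`` is one of ``sttta``, ``mariani``, ``tam``, ``lopez_meyer``.
    The Mariani method needs ``mass_kg``.  Returns the per-sample label
    codes plus an info dict (constant thresholds, or the adaptive
    threshold traces for the triple-threshold detector).
    """
    if ball.n != heel.n:
        raise ValueError("ball and heel recordings must have equal length")
    info: dict = {"method": method}
    if method == "sttta":
        params = sttta_params or StttaParams()
        ball_on, ball_trace = run_sttta(ball, params)
        heel_on, heel_trace = run_sttta(heel, params)
        info["ball_trace"] = ball_trace
        info["heel_trace"] = heel_trace
    elif method == "mariani":
        if mass_kg is None:
            raise ValueError("the Mariani method requires mass_kg")
        t = mariani_threshold(mass_kg, g=g)
        ball_on = classify_with_threshold(ball, t)
        heel_on = classify_with_threshold(heel, t)
        info["thresholds"] = {"ball": t, "heel": t}
    elif method == "tam":
        tb = tam_threshold(ball)
        th = tam_threshold(heel)
        ball_on = classify_with_threshold(ball, tb)
        heel_on = classify_with_threshold(heel, th)
        info["thresholds"] = {"ball": tb, "heel": th}
    elif method == "lopez_meyer":
        # per-cycle extrema located with a self-contained 10 %-of-span
        # split level (the recording's own TAM threshold)
        tb = lopez_meyer_threshold(
            find_cycle_extrema(ball, tam_threshold(ball)), alpha=alpha
        )
        th = lopez_meyer_threshold(
            find_cycle_extrema(heel, tam_threshold(heel)), alpha=alpha
        )
        ball_on = classify_with_threshold(ball, tb)
        heel_on = classify_with_threshold(heel, th)
        info["thresholds"] = {"ball": tb, "heel": th}
    else:
        raise ValueError(f"unknown method {method!r}")
    labels, events = detect_sequence(heel_on, ball_on, fs=ball.fs, t0=ball.t[0])
    info["events"] = events
    info["ball_on"] = ball_on
    info["heel_on"] = heel_on
    return labels, info


@dataclass(frozen=True)
class GridSearchResult:
    """Outcome of the beta/gamma reliability sweep."""

    best_beta: float
    best_gamma: float
    best_reliability_pct: float
    surface: pd.DataFrame  # columns: beta, gamma, reliability_pct


def grid_search(
    recordings: list[tuple[GcfRecording, GcfRecording]],
    reference: str = "tam",
    beta_grid=(0.071,),
    gamma_grid=(0.042,),
    lam: float = 0.5,
    base_params: StttaParams | None = None,
    burn_in_samples: int = 0,
) -> GridSearchResult:
    """Sweep (beta, gamma) for maximum mean reliability against a reference.

    Parameters
    ----------
    recordings : list of (ball, heel) recording pairs
        Training trials.
    reference : {'tam', 'lopez_meyer'}
        Post-hoc method providing the reference labels.
    beta_grid, gamma_grid : sequences of float
        Candidate proportions; pairs with ``gamma >= beta`` are skipped.
    lam : float
        Fixed low-threshold mixing weight.
    base_params : StttaParams, optional
        Source of the initial thresholds (defaults used otherwise).
    burn_in_samples : int
        Leading samples excluded from scoring (cold-start transient).

    Raises
    ------
    ValueError
        If no recording or no valid (beta, gamma) pair is given.
    """
    if not recordings:
        raise ValueError("need at least one recording")
    if reference not in ("tam", "lopez_meyer"):
        raise ValueError(f"unknown reference method {reference!r}")
    base = base_params or StttaParams()

    ref_labels = [
        labels_for_method(ball, heel, reference)[0][burn_in_samples:]
        for ball, heel in recordings
    ]

    rows = []
    best: tuple[float, float, float] | None = None
    pairs = [
        (float(b), float(gm))
        for b in sorted(beta_grid)
        for gm in sorted(gamma_grid)
        if gm < b
    ]
    if not pairs:
        raise ValueError("no (beta, gamma) pair satisfies gamma < beta")
    for beta, gamma in pairs:
        params = _dc_replace(base, beta=beta, gamma=gamma, lam=lam)
        scores = []
        for (ball, heel), ref in zip(recordings, ref_labels):
            labels, _ = labels_for_method(ball, heel, "sttta", sttta_params=params)
            scores.append(
                agreement(labels[burn_in_samples:], ref).percent_agreement
            )
        pct = float(np.mean(scores))
        rows.append({"beta": beta, "gamma": gamma, "reliability_pct": pct})
        if best is None or pct > best[2]:
            best = (beta, gamma, pct)
    surface = pd.DataFrame(rows, columns=["beta", "gamma", "reliability_pct"])
    return GridSearchResult(
        best_beta=best[0],
        best_gamma=best[1],
        best_reliability_pct=best[2],
        surface=surface,
    )
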