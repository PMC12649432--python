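"""Dispersion-threshold (I-DT) fixation detection and trial data quality.

The detector is the classic I-DT algorithm: a window of consecutive valid
samples is grown while its spatial dispersion, ``max(range_x, range_y)``,
stays within the threshold; a window whose wall-clock span reaches the
minimum duration is emitted as a fixation anchored at its first and last
valid samples.  Short runs of invalid samples (blinks, dropouts) inside a
candidate window are bridged up to a gap tolerance; longer gaps terminate
the window.  Saccades are never materialised as events.

Trial reliability follows the two-ratio rule used in mobile eye-tracking
work: a trial is unreliable when the *tracking ratio* (valid samples /
total samples) falls below 0.85 or the *fixation ratio* (time covered by
fixations / trial span) falls below 0.60.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from quieteye.gaze_io import GazeTrace

__all__ = [
    "Fixation",
    "TraceQuality",
    "detect_fixations",
    "compute_quality",
    "DEFAULT_DISPERSION_DEG",
    "DEFAULT_MIN_DURATION_MS",
    "DEFAULT_GAP_TOLERANCE_MS",
    "TRACKING_RATIO_MIN",
    "FIXATION_RATIO_MIN",
]

DEFAULT_DISPERSION_DEG = 1.0
DEFAULT_MIN_DURATION_MS = 100.0
DEFAULT_GAP_TOLERANCE_MS = 75.0
TRACKING_RATIO_MIN = 0.85
FIXATION_RATIO_MIN = 0.60


@dataclass(frozen=True)
class Fixation:
    """One detected fixation.

    ``onset_ms``/``offset_ms`` are the times of the first and last valid
    member samples; ``duration_ms`` is their wall-clock difference (bridged
    invalid gaps therefore count toward duration but not toward the
    centroid).
    """

    onset_ms: float
    offset_ms: float
    cx_deg: float
    cy_deg: float
    n_samples: int

    def __post_init__(self) -> None:
        if self.offset_ms <= self.onset_ms:
            raise ValueError("fixation offset must be after onset")

    @property
    def duration_ms(self) -> float:
        return self.offset_ms - self.onset_ms

    def distance_to(self, point_deg: tuple[float, float]) -> float:
        """Euclidean distance from the centroid to a point, in degrees."""
        return float(np.hypot(self.cx_deg - point_deg[0], self.cy_deg - point_deg[1]))


@dataclass(frozen=True)
class TraceQuality:
    """Per-trial signal quality. ``reliable`` applies the two-ratio rule."""

    tracking_ratio: float
    fixation_ratio: float
    reliable: bool


def detect_fixations(
    trace: GazeTrace,
    dispersion_deg: float = DEFAULT_DISPERSION_DEG,
    min_duration_ms: float = DEFAULT_MIN_DURATION_MS,
    gap_tolerance_ms: float = DEFAULT_GAP_TOLERANCE_MS,
) -> list[Fixation]:
    """Detect fixations in a gaze trace with I-DT.

    Parameters
    ----------
    trace
        Gaze trace; invalid samples are skipped (and bridged if the time gap
        between neighbouring valid samples is at most ``gap_tolerance_ms``).
    dispersion_deg
        Maximum window dispersion ``max(range_x, range_y)``, degrees.
    min_duration_ms
        Minimum wall-clock span (first to last member sample) of a fixation.

    Returns
    -------
    list of Fixation, time-ordered and non-overlapping.  A trace with no
    valid samples yields an empty list.
    """
    if dispersion_deg <= 0:
        raise ValueError("dispersion_deg must be > 0")
    if min_duration_ms <= 0:
        raise ValueError("min_duration_ms must be > 0")

    idx = np.flatnonzero(trace.valid)
    if idx.size == 0:
        return []
    t = trace.t_ms[idx]
    x = trace.x_deg[idx]
    y = trace.y_deg[idx]

    # split valid samples into segments separated by gaps > gap_tolerance_ms
    breaks = np.flatnonzero(np.diff(t) > gap_tolerance_ms) + 1
    fixations: list[Fixation] = []
    for seg in np.split(np.arange(t.size), breaks):
        _idt_segment(
            t[seg], x[seg], y[seg], dispersion_deg, min_duration_ms, fixations
        )
    return fixations


def _idt_segment(
    t: np.ndarray,
    x: np.ndarray,
    y: np.ndarray,
    dispersion_deg: float,
    min_duration_ms: float,
    out: list[Fixation],
) -> None:
    """Greedy maximal-window I-DT over one gap-free run of valid samples."""
    n = t.size
    i = 0
    while i < n:
        xmin = xmax = x[i]
        ymin = ymax = y[i]
        j = i + 1
        while j < n:
            nxmin = min(xmin, x[j])
            nxmax = max(xmax, x[j])
            nymin = min(ymin, y[j])
            nymax = max(ymax, y[j])
            if max(nxmax - nxmin, nymax - nymin) > dispersion_deg:
                break
            xmin, xmax, ymin, ymax = nxmin, nxmax, nymin, nymax
            j += 1
        # window [i, j) is maximal under the dispersion threshold
        if t[j - 1] - t[i] >= min_duration_ms:
            out.append(
                Fixation(
                    onset_ms=float(t[i]),
                    offset_ms=float(t[j - 1]),
                    cx_deg=float(np.mean(x[i:j])),
                    cy_deg=float(np.mean(y[i:j])),
                    n_samples=int(j - i),
                )
            )
            i = j
        else:
            i += 1


def compute_quality(
    trace: GazeTrace,
    fixations: list[Fixation],
    tracking_min: float = TRACKING_RATIO_MIN,
    fixation_min: float = FIXATION_RATIO_MIN,
) -> TraceQuality:
    """Compute tracking and fixation ratios and the reliability flag.

    ``tracking_ratio`` = valid samples / total samples;
    ``fixation_ratio`` = summed fixation duration / trace span (first to
    last sample).  Raises on an empty or zero-span trace.
    """
    if len(trace) == 0:
        raise ValueError("cannot compute quality of an empty trace")
    tracking = trace.n_valid / len(trace)
    span = trace.span_ms
    if span <= 0:
        raise ValueError("trace span is zero; fixation ratio undefined")
    covered = sum(f.duration_ms for f in fixations)
    fixation_ratio = covered / span
    return TraceQuality(
        tracking_ratio=float(tracking),
        fixation_ratio=float(fixation_ratio),
        reliable=bool(tracking >= tracking_min and fixation_ratio >= fixation_min),
    )
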