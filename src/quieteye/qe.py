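"""Quiet-eye and fixation metrics for the pre-throw window.

The quiet eye (QE) is the last fixation whose centroid lies within a 1°
radius of the virtual wall target and whose onset strictly precedes
movement initiation.  Per trial the module reports:

* ``qe_onset_ms`` — initiation minus QE fixation onset (positive lead);
* ``qe_duration_ms`` — full duration of the QE fixation, *not* truncated at
  movement initiation (QE may extend past initiation);
* ``n_fixations`` and ``total_fixation_ms`` (TT) — count and summed
  duration of fixations overlapping the 2000 ms pre-release window, with
  boundary fixations clipped to the window so TT never exceeds the width.

Participant-level means are taken over reliable trials only; QE means are
additionally restricted to trials that actually contain a QE fixation (no
zero-imputation).  A participant with fewer reliable trials than a minimum
(default 5 of 10) is excluded outright.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from quieteye.events import SyncOffset, TrialEvents, pre_throw_window, to_eye_clock
from quieteye.fixation import Fixation, TraceQuality

__all__ = [
    "QETrialMetrics",
    "ParticipantEyeMetrics",
    "window_fixations",
    "find_qe_fixation",
    "trial_metrics",
    "aggregate_participant",
    "DEFAULT_QE_RADIUS_DEG",
    "DEFAULT_MIN_VALID_TRIALS",
]

DEFAULT_QE_RADIUS_DEG = 1.0
DEFAULT_MIN_VALID_TRIALS = 5


@dataclass(frozen=True)
class QETrialMetrics:
    """Quiet-eye and fixation metrics for one throw.

    ``qe_onset_ms``/``qe_duration_ms`` are ``None`` when no fixation meets
    the QE criterion; window counts are still reported.
    """

    participant_id: str
    trial_id: str
    reliable: bool
    qe_onset_ms: float | None
    qe_duration_ms: float | None
    n_fixations: int
    total_fixation_ms: float
    catch: bool


@dataclass(frozen=True)
class ParticipantEyeMetrics:
    """Participant-level means of the four eye variables over reliable trials."""

    participant_id: str
    qe_onset_ms: float | None
    qe_duration_ms: float | None
    n_fixations: float
    total_fixation_ms: float
    n_valid_trials: int
    n_catches: int
    included: bool


def window_fixations(
    fixations: list[Fixation], window: tuple[float, float]
) -> list[Fixation]:
    """Fixations overlapping a half-open window, clipped to its bounds.

    Clipping affects only duration accounting; order is preserved.
    """
    start, end = window
    out: list[Fixation] = []
    for f in fixations:
        if f.offset_ms <= start or f.onset_ms >= end:
            continue
        onset = max(f.onset_ms, start)
        offset = min(f.offset_ms, end)
        if offset <= onset:
            continue
        out.append(
            Fixation(
                onset_ms=onset,
                offset_ms=offset,
                cx_deg=f.cx_deg,
                cy_deg=f.cy_deg,
                n_samples=f.n_samples,
            )
        )
    return out


def find_qe_fixation(
    fixations: list[Fixation],
    target_deg: tuple[float, float],
    initiation_eye_ms: float,
    radius_deg: float = DEFAULT_QE_RADIUS_DEG,
) -> Fixation | None:
    """Select the quiet-eye fixation, or ``None`` if no fixation qualifies.

    A candidate must have its centroid within ``radius_deg`` of the target
    and start strictly before movement initiation; among candidates the one
    with the latest onset wins.  Candidates are evaluated on *unclipped*
    fixations so the QE duration reflects the full fixation.
    """
    best: Fixation | None = None
    for f in fixations:
        if f.onset_ms >= initiation_eye_ms:
            continue
        if f.distance_to(target_deg) > radius_deg:
            continue
        if best is None or f.onset_ms > best.onset_ms:
            best = f
    return best


def trial_metrics(
    fixations: list[Fixation],
    events: TrialEvents,
    offset: SyncOffset,
    quality: TraceQuality,
    window_ms: float = 2000.0,
    qe_radius_deg: float = DEFAULT_QE_RADIUS_DEG,
    participant_id: str = "",
    trial_id: str = "",
) -> QETrialMetrics:
    """Compute all per-trial eye metrics for one throw.

    ``fixations`` must come from the same trial as ``events``; when both
    carry identifiers they are cross-checked.
    """
    pid = participant_id or events.participant_id
    tid = trial_id or events.trial_id
    if events.trial_id and trial_id and events.trial_id != trial_id:
        raise ValueError(
            f"trial identifier mismatch: events {events.trial_id!r} vs {trial_id!r}"
        )

    window = pre_throw_window(events, offset, window_ms)
    clipped = window_fixations(fixations, window)
    total = sum(f.duration_ms for f in clipped)

    initiation_eye = to_eye_clock(events.initiation_ms, offset)
    qe = find_qe_fixation(fixations, events.target_deg, initiation_eye, qe_radius_deg)
    qe_onset = initiation_eye - qe.onset_ms if qe is not None else None
    qe_duration = qe.duration_ms if qe is not None else None

    return QETrialMetrics(
        participant_id=pid,
        trial_id=tid,
        reliable=quality.reliable,
        qe_onset_ms=qe_onset,
        qe_duration_ms=qe_duration,
        n_fixations=len(clipped),
        total_fixation_ms=float(total),
        catch=events.catch,
    )


def aggregate_participant(
    trials: list[QETrialMetrics],
    min_valid: int = DEFAULT_MIN_VALID_TRIALS,
) -> ParticipantEyeMetrics:
    """Aggregate a participant's trials to mean eye metrics.

    Means use reliable trials only; QE means use reliable trials with a QE
    fixation.  ``included`` is False when fewer than ``min_valid`` reliable
    trials exist (the participant is then excluded from cohort analyses).
    """
    if not trials:
        raise ValueError("no trials to aggregate")
    pids = {t.participant_id for t in trials}
    if len(pids) > 1:
        raise ValueError(f"trials from multiple participants: {sorted(pids)}")
    pid = trials[0].participant_id

    good = [t for t in trials if t.reliable]
    n_valid = len(good)
    included = n_valid >= min_valid
    if n_valid == 0:
        return ParticipantEyeMetrics(
            participant_id=pid,
            qe_onset_ms=None,
            qe_duration_ms=None,
            n_fixations=math.nan,
            total_fixation_ms=math.nan,
            n_valid_trials=0,
            n_catches=sum(t.catch for t in trials),
            included=False,
        )

    qe_on = [t.qe_onset_ms for t in good if t.qe_onset_ms is not None]
    qe_dur = [t.qe_duration_ms for t in good if t.qe_duration_ms is not None]
    return ParticipantEyeMetrics(
        participant_id=pid,
        qe_onset_ms=float(np.mean(qe_on)) if qe_on else None,
        qe_duration_ms=float(np.mean(qe_dur)) if qe_dur else None,
        n_fixations=float(np.mean([t.n_fixations for t in good])),
        total_fixation_ms=float(np.mean([t.total_fixation_ms for t in good])),
        n_valid_trials=n_valid,
        n_catches=sum(t.catch for t in good),
        included=included,
    )
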