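"""Per-trial kinematic landmarks and clock synchronisation.

The eye tracker and the external (arm-movement) camera run on separate
clocks.  A single optical flash recorded by both cameras anchors the two
streams; the model is a constant per-recording offset (no drift term).
Kinematic landmarks — movement initiation (first frame of elbow-angle
increase) and ball release (first frame with the ball off the hand) — are
annotated on the external clock and mapped onto the eye clock before any
gaze analysis.  The analysis window is the 2000 ms interval ending at ball
release, half-open ``[release − width, release)``.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass
from typing import IO, Union

__all__ = [
    "TrialEvents",
    "SyncOffset",
    "SyncError",
    "estimate_sync_offset",
    "to_eye_clock",
    "pre_throw_window",
    "read_events",
    "write_events",
    "DEFAULT_WINDOW_MS",
]

DEFAULT_WINDOW_MS = 2000.0


class SyncError(ValueError):
    """Raised when clock synchronisation is impossible (missing flash mark)."""


@dataclass(frozen=True)
class TrialEvents:
    """Kinematic landmarks and annotations for one throwing trial.

    ``flash_t_eye_ms`` / ``flash_t_ext_ms`` are the optical flash times on
    the eye-tracker and external-camera clocks; ``initiation_ms`` and
    ``release_ms`` are on the external clock.  ``target_deg`` is the virtual
    wall target (ball-rebound location) in scene-camera degrees.
    """

    flash_t_eye_ms: float | None
    flash_t_ext_ms: float | None
    initiation_ms: float
    release_ms: float
    target_deg: tuple[float, float]
    catch: bool
    participant_id: str = ""
    trial_id: str = ""

    def __post_init__(self) -> None:
        if not self.initiation_ms < self.release_ms:
            raise ValueError("movement initiation must precede ball release")
        span = self.release_ms - self.initiation_ms
        if not (100.0 <= span <= 2000.0):
            warnings.warn(
                f"initiation-to-release span {span:.0f} ms outside the "
                "plausible [100, 2000] ms range",
                stacklevel=2,
            )


@dataclass(frozen=True)
class SyncOffset:
    """Constant clock offset: external-clock time minus eye-clock time."""

    offset_ms: float

    def __post_init__(self) -> None:
        if not math.isfinite(self.offset_ms):
            raise SyncError("sync offset must be finite")


def estimate_sync_offset(events: TrialEvents) -> SyncOffset:
    """Estimate the external−eye clock offset from the shared flash mark."""
    if events.flash_t_eye_ms is None or events.flash_t_ext_ms is None:
        raise SyncError(
            f"trial {events.trial_id or '?'}: flash timestamp missing on "
            f"{'eye' if events.flash_t_eye_ms is None else 'external'} clock"
        )
    return SyncOffset(offset_ms=float(events.flash_t_ext_ms - events.flash_t_eye_ms))


def to_eye_clock(t_ext_ms: float, offset: SyncOffset) -> float:
    """Map an external-clock timestamp onto the eye-tracker clock."""
    return t_ext_ms - offset.offset_ms


def pre_throw_window(
    events: TrialEvents,
    offset: SyncOffset,
    width_ms: float = DEFAULT_WINDOW_MS,
) -> tuple[float, float]:
    """Half-open pre-throw interval ``[release − width, release)``, eye clock."""
    if width_ms <= 0:
        raise ValueError("window width must be > 0")
    release_eye = to_eye_clock(events.release_ms, offset)
    return (release_eye - width_ms, release_eye)


# -- serialisation -----------------------------------------------------------

_EVENT_FIELDS = (
    "flash_t_eye_ms",
    "flash_t_ext_ms",
    "initiation_ms",
    "release_ms",
    "target_deg",
    "catch",
    "participant_id",
    "trial_id",
)


def write_events(events: TrialEvents, dest: Union[str, IO[str]]) -> None:
    """Write trial events as JSON."""
    payload = {k: getattr(events, k) for k in _EVENT_FIELDS}
    payload["target_deg"] = list(payload["target_deg"])
    if hasattr(dest, "write"):
        json.dump(payload, dest)
    else:
        with open(dest, "w", encoding="utf-8") as fh:
            json.dump(payload, fh)


def read_events(source: Union[str, IO[str]]) -> TrialEvents:
    """Read trial events from JSON."""
    if hasattr(source, "read"):
        payload = json.load(source)
    else:
        with open(source, "r", encoding="utf-8") as fh:
            payload = json.load(fh)
    payload["target_deg"] = tuple(payload["target_deg"])
    return TrialEvents(**{k: payload.get(k) for k in _EVENT_FIELDS})
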