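"""Gaze sample streams and scene-camera geometry.

Gaze positions are expressed in *scene-camera degrees*: a head-fixed frame
with the origin at the centre of the scene-camera image, x positive to the
right and y positive upward.  The conversion from scene-camera pixels is a
constant degrees-per-pixel map (no tangent correction); at the eccentricities
relevant for a wall-target task (≲ 30°) the linearisation error is small and
the choice is isolated in :func:`pixels_to_degrees`.

Invalid samples (lost pupil, blink) are retained in the trace with undefined
coordinates so that downstream quality metrics keep the full denominator.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import IO, Union

import numpy as np
import pandas as pd

__all__ = [
    "CameraSpec",
    "GazeTrace",
    "GazeFormatError",
    "GazeValidationError",
    "pixels_to_degrees",
    "read_gaze_table",
    "write_gaze_table",
]

#: Columns of the gaze CSV dialect, in order.
GAZE_COLUMNS = ("t_ms", "x", "y", "valid", "pupil_mm")


class GazeFormatError(ValueError):
    """Raised when a gaze table does not parse as the documented dialect."""


class GazeValidationError(ValueError):
    """Raised when a parsed gaze table violates a trace invariant."""


@dataclass(frozen=True)
class CameraSpec:
    """Scene-camera geometry and gaze-stream sampling rate.

    Defaults describe a head-mounted eye tracker with a 1280 × 960 px scene
    camera covering a 60° × 46° field of view and a 60 Hz gaze stream.
    """

    width_px: int = 1280
    height_px: int = 960
    hfov_deg: float = 60.0
    vfov_deg: float = 46.0
    sample_rate_hz: float = 60.0

    def __post_init__(self) -> None:
        for name in ("width_px", "height_px", "hfov_deg", "vfov_deg", "sample_rate_hz"):
            if getattr(self, name) <= 0:
                raise ValueError(f"CameraSpec.{name} must be > 0")

    @property
    def nominal_dt_ms(self) -> float:
        """Nominal inter-sample interval of the gaze stream in ms."""
        return 1000.0 / self.sample_rate_hz


@dataclass
class GazeTrace:
    """A single trial's gaze samples as parallel arrays.

    ``x_deg`` / ``y_deg`` are NaN where ``valid`` is False; invalid samples
    are kept so that the tracking ratio (valid / total) can be computed.
    """

    t_ms: np.ndarray
    x_deg: np.ndarray
    y_deg: np.ndarray
    valid: np.ndarray
    pupil_mm: np.ndarray | None = None
    camera: CameraSpec = field(default_factory=CameraSpec)
    participant_id: str = ""
    trial_id: str = ""

    def __post_init__(self) -> None:
        self.t_ms = np.asarray(self.t_ms, dtype=float)
        self.x_deg = np.asarray(self.x_deg, dtype=float)
        self.y_deg = np.asarray(self.y_deg, dtype=float)
        self.valid = np.asarray(self.valid, dtype=bool)
        if self.pupil_mm is not None:
            self.pupil_mm = np.asarray(self.pupil_mm, dtype=float)
        n = len(self.t_ms)
        if not (len(self.x_deg) == len(self.y_deg) == len(self.valid) == n):
            raise GazeValidationError("gaze arrays must have equal length")
        if n > 1:
            dt = np.diff(self.t_ms)
            if np.any(dt <= 0):
                i = int(np.argmax(dt <= 0)) + 1
                raise GazeValidationError(
                    f"timestamps must be strictly increasing (row {i}, "
                    f"t={self.t_ms[i]} after t={self.t_ms[i - 1]})"
                )

    def __len__(self) -> int:
        return len(self.t_ms)

    @property
    def span_ms(self) -> float:
        """Wall-clock span from first to last sample."""
        if len(self) < 2:
            return 0.0
        return float(self.t_ms[-1] - self.t_ms[0])

    @property
    def n_valid(self) -> int:
        return int(self.valid.sum())

    def check_sampling(self) -> None:
        """Verify the median inter-sample interval is within ±20% of nominal."""
        if len(self) < 3:
            return
        med = float(np.median(np.diff(self.t_ms)))
        nom = self.camera.nominal_dt_ms
        if not (0.8 * nom <= med <= 1.2 * nom):
            raise GazeValidationError(
                f"median inter-sample interval {med:.2f} ms deviates more than "
                f"20% from nominal {nom:.2f} ms"
            )

    def to_frame(self) -> pd.DataFrame:
        pupil = self.pupil_mm if self.pupil_mm is not None else np.full(len(self), np.nan)
        return pd.DataFrame(
            {
                "t_ms": self.t_ms,
                "x": self.x_deg,
                "y": self.y_deg,
                "valid": self.valid.astype(int),
                "pupil_mm": pupil,
            }
        )


def pixels_to_degrees(
    px: tuple[float, float] | np.ndarray, camera: CameraSpec
) -> tuple[float, float] | np.ndarray:
    """Map scene-camera pixel coordinates to head-fixed degrees.

    The map is affine with a constant degrees-per-pixel factor per axis:
    ``deg_x = (px_x − width/2) · hfov/width`` and
    ``deg_y = (height/2 − px_y) · vfov/height`` (image y grows downward,
    degree y grows upward).  Out-of-frame pixels extrapolate linearly.

    Accepts a single ``(x, y)`` pair or an ``(n, 2)`` array.
    """
    arr = np.asarray(px, dtype=float)
    dx = (arr[..., 0] - camera.width_px / 2.0) * (camera.hfov_deg / camera.width_px)
    dy = (camera.height_px / 2.0 - arr[..., 1]) * (camera.vfov_deg / camera.height_px)
    out = np.stack([dx, dy], axis=-1)
    if np.ndim(px) == 1 or isinstance(px, tuple):
        return (float(out[0]), float(out[1]))
    return out


def read_gaze_table(
    source: Union[str, IO[str], IO[bytes]],
    camera: CameraSpec | None = None,
    units: str = "deg",
    participant_id: str = "",
    trial_id: str = "",
) -> GazeTrace:
    """Read a gaze CSV stream into a :class:`GazeTrace`.

    Dialect: header ``t_ms,x,y,valid,pupil_mm``; decimal point, comma
    separator, UTF-8.  ``x``/``y`` are degrees by default or scene-camera
    pixels with ``units='px'``.  Rows with empty gaze fields or a false
    validity flag become invalid samples (coordinates NaN).

    Raises :class:`GazeFormatError` for a malformed header and
    :class:`GazeValidationError` for non-monotone timestamps.
    """
    if units not in ("deg", "px"):
        raise ValueError(f"units must be 'deg' or 'px', got {units!r}")
    camera = camera or CameraSpec()
    try:
        df = pd.read_csv(source, sep=",", dtype=str, keep_default_na=False)
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise GazeFormatError(f"gaze table does not parse as CSV: {exc}") from exc
    if tuple(df.columns[: len(GAZE_COLUMNS)]) != GAZE_COLUMNS:
        raise GazeFormatError(
            f"malformed header: expected {','.join(GAZE_COLUMNS)}, "
            f"got {','.join(map(str, df.columns))}"
        )

    t = pd.to_numeric(df["t_ms"], errors="raise").to_numpy(dtype=float)
    # empty fields coerce to NaN, which marks the sample invalid below
    x = pd.to_numeric(df["x"], errors="coerce").to_numpy(dtype=float)
    y = pd.to_numeric(df["y"], errors="coerce").to_numpy(dtype=float)
    flag = df["valid"].str.strip().str.lower().isin(["1", "true", "t", "yes"]).to_numpy()
    pupil = pd.to_numeric(df["pupil_mm"], errors="coerce").to_numpy(dtype=float)

    valid = flag & np.isfinite(x) & np.isfinite(y)
    if units == "px":
        deg = pixels_to_degrees(np.column_stack([x, y]), camera)
        x, y = deg[:, 0], deg[:, 1]
    x = np.where(valid, x, np.nan)
    y = np.where(valid, y, np.nan)
    return GazeTrace(
        t_ms=t,
        x_deg=x,
        y_deg=y,
        valid=valid,
        pupil_mm=pupil,
        camera=camera,
        participant_id=participant_id,
        trial_id=trial_id,
    )


def write_gaze_table(trace: GazeTrace, dest: Union[str, IO[str]]) -> None:
    """Write a trace in the gaze CSV dialect (degrees).

    Invalid samples are written with empty gaze fields so that a read →
    write → read round trip reproduces the trace.
    """
    df = trace.to_frame()
    # empty fields, not NaN text, for invalid coordinates
    for col in ("x", "y", "pupil_mm"):
        df[col] = df[col].map(lambda v: "" if not np.isfinite(v) else repr(float(v)))
    df["t_ms"] = df["t_ms"].map(lambda v: repr(float(v)))
    df.to_csv(dest, index=False)
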