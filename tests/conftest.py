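import numpy as np
import pytest

from quieteye.gaze_io import CameraSpec, GazeTrace


@pytest.fixture
def camera() -> CameraSpec:
    return CameraSpec()


def make_trace(t, x, y, valid=None, rate=60.0, **kw) -> GazeTrace:
    t = np.asarray(t, dtype=float)
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if valid is None:
        valid = np.isfinite(x) & np.isfinite(y)
    return GazeTrace(
        t_ms=t, x_deg=x, y_deg=y, valid=np.asarray(valid, dtype=bool),
        camera=CameraSpec(sample_rate_hz=rate), **kw,
    )


@pytest.fixture
def stationary_trace():
    """31 samples at (0, 0), 60 Hz: one 500 ms fixation."""
    n = 31
    t = np.arange(n) * (1000.0 / 60.0)
    return make_trace(t, np.zeros(n), np.zeros(n))
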