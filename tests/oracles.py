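"""Independent reference implementations used to cross-check the package.

These deliberately take different computational routes from the library:
the fixation oracle recomputes window dispersions from scratch with
cumulative extrema per start index, and the CCA oracle solves the
generalised eigenproblem of the covariance product matrix directly.
"""

from __future__ import annotations

import numpy as np
import scipy.linalg


def idt_oracle(
    t: np.ndarray,
    x: np.ndarray,
    y: np.ndarray,
    valid: np.ndarray,
    dispersion_deg: float,
    min_duration_ms: float,
    gap_tolerance_ms: float,
) -> list[tuple[float, float, float, float, int]]:
    """Brute-force I-DT: (onset, offset, cx, cy, n_samples) tuples.

    For every candidate start the dispersion of *all* windows from that
    start is evaluated at once via cumulative maxima/minima of the suffix;
    the maximal admissible window is emitted when long enough, else the
    start advances by one sample.
    """
    idx = np.flatnonzero(np.asarray(valid, dtype=bool))
    t, x, y = np.asarray(t, float)[idx], np.asarray(x, float)[idx], np.asarray(y, float)[idx]
    out = []
    # gap-free runs of valid samples
    cuts = np.flatnonzero(np.diff(t) > gap_tolerance_ms) + 1
    for run in np.split(np.arange(t.size), cuts):
        tr, xr, yr = t[run], x[run], y[run]
        n = tr.size
        i = 0
        while i < n:
            disp = np.maximum(
                np.maximum.accumulate(xr[i:]) - np.minimum.accumulate(xr[i:]),
                np.maximum.accumulate(yr[i:]) - np.minimum.accumulate(yr[i:]),
            )
            over = np.flatnonzero(disp > dispersion_deg)
            j = i + (int(over[0]) if over.size else n - i)  # window is [i, j)
            if tr[j - 1] - tr[i] >= min_duration_ms:
                out.append(
                    (
                        float(tr[i]),
                        float(tr[j - 1]),
                        float(np.mean(xr[i:j])),
                        float(np.mean(yr[i:j])),
                        int(j - i),
                    )
                )
                i = j
            else:
                i += 1
    return out


def cca_oracle(X: np.ndarray, Y: np.ndarray) -> np.ndarray:
    """Canonical correlations via the covariance product eigenproblem."""
    Xc = X - X.mean(axis=0)
    Yc = Y - Y.mean(axis=0)
    n = X.shape[0]
    Sxx = Xc.T @ Xc / (n - 1)
    Syy = Yc.T @ Yc / (n - 1)
    Sxy = Xc.T @ Yc / (n - 1)
    M = np.linalg.solve(Sxx, Sxy) @ np.linalg.solve(Syy, Sxy.T)
    eig = scipy.linalg.eigvals(M)
    eig = np.sort(np.real(eig))[::-1]
    s = min(X.shape[1], Y.shape[1])
    return np.sqrt(np.clip(eig[:s], 0.0, 1.0))


def random_trace_arrays(
    rng: np.random.Generator, max_samples: int = 200
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """A random piecewise-stationary gaze trace for equivalence testing."""
    n = int(rng.integers(5, max_samples + 1))
    dt = 1000.0 / 60.0
    t = np.arange(n) * dt
    x = np.empty(n)
    y = np.empty(n)
    pos = rng.uniform(-10, 10, size=2)
    i = 0
    while i < n:
        seg = int(rng.integers(1, 25))
        jitter = rng.choice([0.05, 0.2, 0.8])
        x[i : i + seg] = pos[0] + rng.normal(0, jitter, size=min(seg, n - i))
        y[i : i + seg] = pos[1] + rng.normal(0, jitter, size=min(seg, n - i))
        pos = pos + rng.uniform(-4, 4, size=2)
        i += seg
    valid = rng.random(n) > 0.15
    x[~valid] = np.nan
    y[~valid] = np.nan
    return t, x, y, valid
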