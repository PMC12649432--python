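"""Synthetic cohort generator with a planted eye-attention dependence.

The generator emulates the four raw input streams of the study — per-trial
gaze traces, kinematic event annotations, d2-R mark sheets and RTA trial
logs — for a cohort of children performing 10 throw-and-catch trials each.

Cohort model
------------
A single latent factor ``G`` (standard normal per participant; large ``G``
means slow/error-prone processing) couples the two domains.  Participant-
level propensities are affine in correlated standard-normal scores that
each load on ``G``:

* mean quiet-eye onset and duration (ms; marginals anchored to the study descriptives),
* fixation count in the 2000 ms pre-throw window,
* d2-R omission/commission probabilities and processing speed,
* RTA reaction-time mean/SD and lapse probability,
* catch probability.

Per trial, a gaze trace is built as alternating fixations (gamma-distributed
durations, Gaussian within-fixation jitter) and short saccade gaps, with
occasional blink segments of invalid samples, one target-anchored fixation
planted so its onset precedes movement initiation by the participant's QE
onset draw.  Trial-level QE variation is multiplicative log-normal, which
keeps draws positive without truncation.

Planted dependence
------------------
``r_target`` is the *population correlation between the measured
participant-level QE onset and the d2-R %errors standard score* — i.e. the
quantity the analysis pipeline actually estimates.  Because trial averaging
and binomial mark noise attenuate any latent correlation, the generator
calibrates its latent coupling by simulating a large fixed-seed reference
population through its own score-level noise model and root-finding the
coupling that yields ``r_target`` (a classical-test-theory disattenuation,
computed rather than assumed).  The same reference population defines the
surrogate d2-R norm tables.
"""

from __future__ import annotations

import json
import math
import os
from dataclasses import dataclass
from typing import Any

import numpy as np
from scipy.optimize import brentq

from quieteye.attention import (
    D2Marks,
    D2Sheet,
    NormTable,
    RTATrialLog,
    standard_sheet,
)
from quieteye.events import TrialEvents
from quieteye.gaze_io import CameraSpec, GazeTrace

__all__ = [
    "CohortConfig",
    "ParticipantState",
    "PlantedFixation",
    "CohortBundle",
    "simulate_trial",
    "simulate_attention",
    "simulate_cohort",
    "write_bundle",
    "read_bundle",
]


@dataclass(frozen=True)
class CohortConfig:
    """Study conditions for the synthetic cohort.

    Marginal means/SDs are calibrated to the participant-level descriptives
    of the modelled study (n = 57 children, 10 test throws each, 60 Hz
    eye tracker, 2000 ms pre-release window).
    """

    n_participants: int = 57
    trials_per_participant: int = 10
    sample_rate_hz: float = 60.0
    window_ms: float = 2000.0
    seed: int = 0

    #: population correlation between measured participant-level QE onset
    #: and the d2-R %errors standard score (the planted dependence)
    r_target: float = -0.417

    # participant-level marginals (ms / counts)
    qe_onset_mean: float = 474.14
    qe_onset_sd: float = 226.73
    qe_duration_mean: float = 754.49
    qe_duration_sd: float = 289.25
    n_fix_mean: float = 3.95
    n_fix_sd: float = 1.10
    rt_mean: float = 356.63
    rt_mean_sd: float = 54.44
    sdrt_mean: float = 55.86
    sdrt_sd: float = 18.95

    # trial-level noise (log-normal coefficient of variation)
    qe_onset_trial_cv: float = 0.17
    qe_duration_trial_cv: float = 0.15

    # trace construction
    jitter_deg: float = 0.15
    invalid_rate: float = 0.015
    blink_prob: float = 0.10
    blink_ms: tuple[float, float] = (100.0, 250.0)
    saccade_gap_ms: float = 50.0
    saccade_jump_deg: tuple[float, float] = (4.5, 9.0)
    fixation_gamma_shape: float = 2.0

    # d2-R response model
    p_omission_base: float = 0.115
    p_omission_slope: float = 0.05
    p_commission_base: float = 0.032
    p_commission_slope: float = 0.012
    d2_speed_mean: float = 50.0
    d2_speed_sd: float = 5.0

    # RTA response model
    lapse_base: float = 0.03
    lapse_slope: float = 0.02
    anticipation_prob: float = 0.01

    # secondary latent loadings on G (slow/error-prone direction)
    loading_qe_duration: float = 0.6  # share of QE-onset score, not of G
    loading_n_fix: float = -0.35
    loading_sdrt: float = -0.25
    loading_rt: float = 0.08
    loading_speed: float = -0.30
    loading_lapse: float = 0.5
    loading_catch: float = -0.5

    # norm-table anchor: cohort SS centre/scale for (CP, %errors)
    ss_center: tuple[float, float] = (89.98, 89.95)
    ss_scale: tuple[float, float] = (9.64, 11.03)

    # reference population used for calibration and surrogate norms
    reference_size: int = 200_000
    reference_seed: int = 193_713_001

    def __post_init__(self) -> None:
        if not abs(self.r_target) < 1:
            raise ValueError("|r_target| must be < 1")
        for name in ("qe_onset_sd", "qe_duration_sd", "n_fix_sd", "rt_mean_sd", "sdrt_sd"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")

    @property
    def dt_ms(self) -> float:
        return 1000.0 / self.sample_rate_hz


# ---------------------------------------------------------------------------
# calibration: latent coupling and surrogate norms
# ---------------------------------------------------------------------------

def _reference_scores(
    config: CohortConfig, rho: float, rng: np.random.Generator
) -> dict[str, np.ndarray]:
    """Score-level reference model: measured QE onset and d2 raw scores.

    Approximates the full pipeline (no gaze traces): the 10-trial mean of
    log-normal QE-onset draws and binomially marked d2 sheets.  Used only
    to calibrate the latent coupling and to anchor the surrogate norms.
    """
    n = config.reference_size
    g = rng.standard_normal(n)
    b = math.sqrt(max(rho, 0.0))
    z_qe = b * g + math.sqrt(1.0 - b * b) * rng.standard_normal(n)
    sgn = -1.0 if config.r_target > 0 else 1.0  # errors co-move with QE onset?
    z_err = sgn * (b * g) + math.sqrt(1.0 - b * b) * rng.standard_normal(n)
    z_sp = config.loading_speed * g + math.sqrt(
        1.0 - config.loading_speed**2
    ) * rng.standard_normal(n)

    mu_qe = np.clip(
        config.qe_onset_mean + config.qe_onset_sd * z_qe, 140.0, 1400.0
    )
    m = config.trials_per_participant
    cv = config.qe_onset_trial_cv
    lognorm = rng.lognormal(-0.5 * cv * cv, cv, size=(n, m))
    qe_meas = mu_qe * lognorm.mean(axis=1)

    p_om = np.clip(
        config.p_omission_base + config.p_omission_slope * z_err, 0.005, 0.6
    )
    p_com = np.clip(
        config.p_commission_base + config.p_commission_slope * z_err, 0.002, 0.5
    )
    speed = np.clip(
        config.d2_speed_mean + config.d2_speed_sd * z_sp, 35.0, 57.0
    )
    frac = speed / 57.0
    n_targets = np.maximum(np.rint(308.0 * frac).astype(int), 1)
    n_distract = np.rint(376.0 * frac).astype(int)
    om = rng.binomial(n_targets, p_om)
    com = rng.binomial(n_distract, p_com)
    pct_errors = 100.0 * (om + com) / n_targets
    cp = (n_targets - om) - com
    return {"qe": qe_meas, "pct_errors": pct_errors, "cp": cp.astype(float)}


@dataclass(frozen=True)
class _Calibration:
    rho: float
    norms: NormTable
    err_mean: float
    err_sd: float
    cp_mean: float
    cp_sd: float


def _calibrate(config: CohortConfig) -> _Calibration:
    """Solve for the latent coupling that realises ``r_target``.

    Uses common random numbers (fixed reference seed) so the measured-score
    correlation is a smooth, deterministic, monotone function of the latent
    coupling ``rho`` and a scalar root-find applies.
    """
    def corr_at(rho: float) -> float:
        rng = np.random.default_rng(config.reference_seed)
        ref = _reference_scores(config, rho, rng)
        # %errors SS is a decreasing linear map of the raw score, so the
        # measured correlation with SS is minus the raw-score correlation
        return -float(np.corrcoef(ref["qe"], ref["pct_errors"])[0, 1])

    target = -abs(config.r_target)
    if config.r_target == 0.0:
        rho = 0.0
    else:
        attainable = corr_at(0.95)
        if target < attainable:
            raise ValueError(
                f"|r_target|={abs(config.r_target):.3f} exceeds the maximum "
                f"attainable measured correlation {-attainable:.3f} under the "
                "configured noise model"
            )
        rho = float(brentq(lambda r: corr_at(r) - target, 0.0, 0.95, xtol=1e-4))

    rng = np.random.default_rng(config.reference_seed)
    ref = _reference_scores(config, rho, rng)
    err_mean = float(np.mean(ref["pct_errors"]))
    err_sd = float(np.std(ref["pct_errors"], ddof=1))
    cp_mean = float(np.mean(ref["cp"]))
    cp_sd = float(np.std(ref["cp"], ddof=1))
    norms = NormTable.surrogate(
        cp_mean=cp_mean,
        cp_sd=cp_sd,
        err_mean=err_mean,
        err_sd=err_sd,
        ss_center=config.ss_center,
        ss_scale=config.ss_scale,
    )
    return _Calibration(
        rho=rho, norms=norms, err_mean=err_mean, err_sd=err_sd,
        cp_mean=cp_mean, cp_sd=cp_sd,
    )


_calibration_cache: dict[tuple, _Calibration] = {}


def get_calibration(config: CohortConfig) -> _Calibration:
    key = tuple(
        getattr(config, f)
        for f in (
            "r_target", "trials_per_participant", "qe_onset_mean", "qe_onset_sd",
            "qe_onset_trial_cv", "p_omission_base", "p_omission_slope",
            "p_commission_base", "p_commission_slope", "d2_speed_mean",
            "d2_speed_sd", "loading_speed", "ss_center", "ss_scale",
            "reference_size", "reference_seed",
        )
    )
    if key not in _calibration_cache:
        _calibration_cache[key] = _calibrate(config)
    return _calibration_cache[key]


# ---------------------------------------------------------------------------
# participant state
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ParticipantState:
    """Latent and propensity parameters of one simulated participant."""

    participant_id: str
    g: float
    mu_qe_onset: float
    mu_qe_duration: float
    n_fix_target: float
    filler_fix_mean_ms: float
    p_omission: float
    p_commission: float
    d2_speed: float
    rt_mu: float
    rt_sd: float
    lapse_p: float
    catch_p: float
    age: int
    sync_offset_ms: float


def _draw_participant(
    config: CohortConfig, calib: _Calibration, pid: str, rng: np.random.Generator
) -> ParticipantState:
    g = rng.standard_normal()
    b = math.sqrt(calib.rho)
    sgn = -1.0 if config.r_target > 0 else 1.0

    def mix(load_on_g: float) -> float:
        return load_on_g * g + math.sqrt(max(0.0, 1.0 - load_on_g**2)) * rng.standard_normal()

    z_qe = mix(b)
    z_err = sgn * b * g + math.sqrt(max(0.0, 1.0 - b * b)) * rng.standard_normal()
    # QE duration loads on the QE-onset score (slow gaze style), not fresh G
    z_dur = config.loading_qe_duration * z_qe + math.sqrt(
        1.0 - config.loading_qe_duration**2
    ) * rng.standard_normal()
    z_nf = mix(config.loading_n_fix)
    z_sp = mix(config.loading_speed)
    z_rt = mix(config.loading_rt)
    z_sd = mix(config.loading_sdrt)

    mu_qe = float(np.clip(config.qe_onset_mean + config.qe_onset_sd * z_qe, 140.0, 1400.0))
    mu_dur = float(np.clip(config.qe_duration_mean + config.qe_duration_sd * z_dur, 200.0, 1600.0))
    nf = float(np.clip(config.n_fix_mean + config.n_fix_sd * z_nf, 1.8, 7.5))
    filler = float(np.clip((config.window_ms - 650.0) / max(nf - 1.0, 0.8) - 100.0, 140.0, 900.0))

    sdrt = float(np.clip(config.sdrt_mean + config.sdrt_sd * z_sd, 18.0, 110.0))
    rt_mu = float(np.clip(config.rt_mean + config.rt_mean_sd * z_rt, 220.0, 520.0))
    lapse = float(np.clip(config.lapse_base + config.lapse_slope * config.loading_lapse * g, 0.002, 0.2))
    catch_p = float(1.0 / (1.0 + math.exp(-(0.3 + 0.5 * config.loading_catch * g))))

    return ParticipantState(
        participant_id=pid,
        g=g,
        mu_qe_onset=mu_qe,
        mu_qe_duration=mu_dur,
        n_fix_target=nf,
        filler_fix_mean_ms=filler,
        p_omission=float(np.clip(config.p_omission_base + config.p_omission_slope * z_err, 0.005, 0.6)),
        p_commission=float(np.clip(config.p_commission_base + config.p_commission_slope * z_err, 0.002, 0.5)),
        d2_speed=float(np.clip(config.d2_speed_mean + config.d2_speed_sd * z_sp, 35.0, 57.0)),
        rt_mu=rt_mu,
        rt_sd=sdrt,
        lapse_p=lapse,
        catch_p=catch_p,
        age=int(rng.integers(9, 13)),
        sync_offset_ms=float(rng.uniform(-800.0, 800.0)),
    )


# ---------------------------------------------------------------------------
# trial simulation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PlantedFixation:
    """Ground-truth fixation: realised (sample-grid) boundaries and centroid."""

    onset_ms: float
    offset_ms: float
    cx_deg: float
    cy_deg: float
    is_qe: bool


def _random_centroid(
    rng: np.random.Generator,
    anchor: np.ndarray,
    target: np.ndarray,
    jump_range: tuple[float, float],
) -> np.ndarray:
    """Centroid one saccade away from ``anchor``, clear of the target."""
    for _ in range(30):
        jump = rng.uniform(*jump_range)
        ang = rng.uniform(0.0, 2.0 * math.pi)
        c = anchor + jump * np.array([math.cos(ang), math.sin(ang)])
        if abs(c[0]) <= 12.0 and abs(c[1]) <= 9.0 and np.hypot(*(c - target)) >= 1.8:
            return c
    return np.array([anchor[0], -anchor[1]])  # fallback: mirror vertically


def simulate_trial(
    state: ParticipantState,
    config: CohortConfig,
    rng: np.random.Generator,
    trial_id: str = "t01",
    noise_free: bool = False,
) -> tuple[GazeTrace, TrialEvents, list[PlantedFixation]]:
    """Simulate one throwing trial: gaze trace, events, planted fixations.

    ``noise_free=True`` disables within-fixation jitter, invalid samples and
    blinks, for exact-recovery checks.
    """
    dt = config.dt_ms
    jitter = 0.0 if noise_free else config.jitter_deg
    invalid_rate = 0.0 if noise_free else config.invalid_rate
    blink_prob = 0.0 if noise_free else config.blink_prob

    release = rng.uniform(2550.0, 2950.0)
    initiation = release - max(rng.normal(600.0, 40.0), 350.0)
    t_end = release + rng.uniform(120.0, 250.0)

    cv_on = config.qe_onset_trial_cv
    cv_du = config.qe_duration_trial_cv
    onset_lead = state.mu_qe_onset * rng.lognormal(-0.5 * cv_on**2, cv_on)
    onset_lead = float(np.clip(onset_lead, 60.0, initiation - 140.0))
    qe_dur = state.mu_qe_duration * rng.lognormal(-0.5 * cv_du**2, cv_du)
    qe_dur = float(np.clip(qe_dur, 140.0, 1700.0))
    qe_on = initiation - onset_lead
    qe_off = qe_on + qe_dur
    t_end = max(t_end, qe_off + 100.0)

    target = np.array([rng.uniform(-4.0, 4.0), rng.uniform(-2.0, 4.0)])
    qe_centroid = target + np.clip(rng.normal(0.0, 0.2, size=2), -0.4, 0.4)

    # segment chain: (t0, t1, kind, centroid) with kind fix|gap|blink
    segments: list[tuple[float, float, str, np.ndarray | None]] = [
        (qe_on, qe_off, "fix", qe_centroid)
    ]
    shape = config.fixation_gamma_shape

    def filler_duration() -> float:
        d = rng.gamma(shape, state.filler_fix_mean_ms / shape)
        return float(np.clip(d, 130.0, 900.0))

    # backward from QE onset to trace start
    t_cursor = qe_on
    anchor = qe_centroid
    while t_cursor > 0.0:
        g0 = t_cursor - config.saccade_gap_ms
        segments.insert(0, (g0, t_cursor, "gap", None))
        t_cursor = g0
        if blink_prob and rng.random() < blink_prob:
            b0 = t_cursor - rng.uniform(*config.blink_ms)
            segments.insert(0, (b0, t_cursor, "blink", None))
            t_cursor = b0
            continue
        dur = filler_duration()
        c = _random_centroid(rng, anchor, target, config.saccade_jump_deg)
        segments.insert(0, (t_cursor - dur, t_cursor, "fix", c))
        t_cursor -= dur
        anchor = c

    # forward from QE offset to trace end
    t_cursor = qe_off
    anchor = qe_centroid
    while t_cursor < t_end:
        g1 = t_cursor + config.saccade_gap_ms
        segments.append((t_cursor, g1, "gap", None))
        t_cursor = g1
        if blink_prob and rng.random() < blink_prob:
            b1 = t_cursor + rng.uniform(*config.blink_ms)
            segments.append((t_cursor, b1, "blink", None))
            t_cursor = b1
            continue
        dur = filler_duration()
        c = _random_centroid(rng, anchor, target, config.saccade_jump_deg)
        segments.append((t_cursor, t_cursor + dur, "fix", c))
        t_cursor += dur
        anchor = c

    # sample the chain on the regular grid
    n_samples = int(math.floor(t_end / dt)) + 1
    t = np.arange(n_samples) * dt
    x = np.full(n_samples, np.nan)
    y = np.full(n_samples, np.nan)
    valid = np.zeros(n_samples, dtype=bool)
    planted: list[PlantedFixation] = []

    centroids = [s[3] for s in segments]
    for k, (t0, t1, kind, c) in enumerate(segments):
        lo = int(math.ceil(max(t0, 0.0) / dt - 1e-9))
        hi = min(int(math.ceil(t1 / dt - 1e-9)), n_samples)
        if hi <= lo:
            continue
        tk = t[lo:hi]
        if kind == "fix":
            x[lo:hi] = c[0] + rng.normal(0.0, jitter, size=hi - lo)
            y[lo:hi] = c[1] + rng.normal(0.0, jitter, size=hi - lo)
            valid[lo:hi] = True
            planted.append(
                PlantedFixation(
                    onset_ms=float(tk[0]),
                    offset_ms=float(tk[-1]),
                    cx_deg=float(c[0]),
                    cy_deg=float(c[1]),
                    is_qe=bool(np.array_equal(c, qe_centroid) and t0 == qe_on),
                )
            )
        elif kind == "gap":
            prev_c = next((centroids[j] for j in range(k - 1, -1, -1) if centroids[j] is not None), None)
            next_c = next((centroids[j] for j in range(k + 1, len(segments)) if centroids[j] is not None), None)
            if prev_c is None or next_c is None:
                continue  # gap at the trace edge: leave samples invalid
            frac = (tk - t0) / max(t1 - t0, 1e-9)
            band = 0.3 + 0.4 * frac  # keep saccade samples clear of both endpoints
            x[lo:hi] = prev_c[0] + band * (next_c[0] - prev_c[0])
            y[lo:hi] = prev_c[1] + band * (next_c[1] - prev_c[1])
            valid[lo:hi] = True
        # blink: stays invalid

    if invalid_rate > 0:
        drop = rng.random(n_samples) < invalid_rate
        valid &= ~drop
        x[drop] = np.nan
        y[drop] = np.nan

    trace = GazeTrace(
        t_ms=t,
        x_deg=x,
        y_deg=y,
        valid=valid,
        camera=CameraSpec(sample_rate_hz=config.sample_rate_hz),
        participant_id=state.participant_id,
        trial_id=trial_id,
    )
    flash_eye = 20.0
    events = TrialEvents(
        flash_t_eye_ms=flash_eye,
        flash_t_ext_ms=flash_eye + state.sync_offset_ms,
        initiation_ms=initiation + state.sync_offset_ms,
        release_ms=release + state.sync_offset_ms,
        target_deg=(float(target[0]), float(target[1])),
        catch=bool(rng.random() < state.catch_p),
        participant_id=state.participant_id,
        trial_id=trial_id,
    )
    return trace, events, planted


def simulate_attention(
    state: ParticipantState,
    config: CohortConfig,
    rng: np.random.Generator,
    sheet: D2Sheet,
) -> tuple[D2Marks, RTATrialLog]:
    """Simulate the d2-R response record and the RTA non-signal log."""
    marks = D2Marks()
    for row in range(1, 15):
        span = int(np.clip(round(state.d2_speed + rng.uniform(-3.0, 3.0)), 25, 57))
        marks.last_processed[row] = span
        targets = set(sheet.targets_in(row, span))
        chosen: set[int] = set()
        for pos in range(1, span + 1):
            if pos in targets:
                if rng.random() >= state.p_omission:
                    chosen.add(pos)
            elif rng.random() < state.p_commission:
                chosen.add(pos)
        if chosen:
            marks.marked[row] = chosen

    n = 28
    isi = rng.uniform(2500.0, 6500.0, size=n)
    tau = 0.5 * state.rt_sd
    sigma = math.sqrt(max(state.rt_sd**2 - tau**2, 1.0))
    rt = state.rt_mu - tau + rng.normal(0.0, sigma, size=n) + rng.exponential(tau, size=n)
    rt = np.maximum(rt, 120.0)
    responded = np.ones(n, dtype=bool)
    # anticipations: premature presses with very short apparent RT
    antic = rng.random(n) < config.anticipation_prob
    rt[antic] = rng.uniform(30.0, 95.0, size=int(antic.sum()))
    # lapses: no response inside the window
    lapse = rng.random(n) < state.lapse_p
    responded[lapse] = False
    # the stimulus disappears at 1000 ms: later presses are not registered
    too_late = rt > 1000.0
    responded[too_late] = False
    rt[~responded] = np.nan
    return marks, RTATrialLog(isi_ms=isi, rt_ms=rt, responded=responded)


# ---------------------------------------------------------------------------
# cohort simulation
# ---------------------------------------------------------------------------

@dataclass
class CohortBundle:
    """Raw pipeline-ready synthetic dataset for one cohort."""

    config: CohortConfig
    traces: dict[tuple[str, str], GazeTrace]
    events: dict[tuple[str, str], TrialEvents]
    sheet: D2Sheet
    marks: dict[str, D2Marks]
    rta: dict[str, RTATrialLog]
    ages: dict[str, int]
    norms: NormTable
    ground_truth: dict[str, Any]


def simulate_cohort(
    config: CohortConfig | None = None,
    seed: int | None = None,
    noise_free: bool = False,
) -> CohortBundle:
    """Generate a full cohort bundle plus ground truth.

    ``seed`` overrides ``config.seed``.  The bundle is writable to the
    pipeline's on-disk input formats via :func:`write_bundle` and directly
    consumable in memory by :mod:`quieteye.pipeline`.
    """
    config = config or CohortConfig()
    calib = get_calibration(config)
    rng = np.random.default_rng(config.seed if seed is None else seed)
    sheet = standard_sheet()

    traces: dict[tuple[str, str], GazeTrace] = {}
    events: dict[tuple[str, str], TrialEvents] = {}
    marks: dict[str, D2Marks] = {}
    rta: dict[str, RTATrialLog] = {}
    ages: dict[str, int] = {}
    gt_participants: dict[str, Any] = {}

    for i in range(config.n_participants):
        pid = f"p{i + 1:03d}"
        state = _draw_participant(config, calib, pid, rng)
        ages[pid] = state.age
        trial_gt = {}
        for j in range(config.trials_per_participant):
            tid = f"t{j + 1:02d}"
            trace, ev, planted = simulate_trial(
                state, config, rng, trial_id=tid, noise_free=noise_free
            )
            traces[(pid, tid)] = trace
            events[(pid, tid)] = ev
            qe = next(f for f in planted if f.is_qe)
            initiation_eye = ev.initiation_ms - state.sync_offset_ms
            trial_gt[tid] = {
                "fixations": [
                    [f.onset_ms, f.offset_ms, f.cx_deg, f.cy_deg, f.is_qe]
                    for f in planted
                ],
                "initiation_eye_ms": initiation_eye,
                "release_eye_ms": ev.release_ms - state.sync_offset_ms,
                "target_deg": list(ev.target_deg),
                "qe_onset_ms": initiation_eye - qe.onset_ms,
                "qe_duration_ms": qe.offset_ms - qe.onset_ms,
            }
        m, log = simulate_attention(state, config, rng, sheet)
        marks[pid] = m
        rta[pid] = log
        gt_participants[pid] = {
            "g": state.g,
            "mu_qe_onset": state.mu_qe_onset,
            "mu_qe_duration": state.mu_qe_duration,
            "n_fix_target": state.n_fix_target,
            "p_omission": state.p_omission,
            "p_commission": state.p_commission,
            "age": state.age,
            "sync_offset_ms": state.sync_offset_ms,
            "trials": trial_gt,
        }

    ground_truth = {
        "r_target": config.r_target,
        "latent_rho": calib.rho,
        "participants": gt_participants,
    }
    return CohortBundle(
        config=config,
        traces=traces,
        events=events,
        sheet=sheet,
        marks=marks,
        rta=rta,
        ages=ages,
        norms=calib.norms,
        ground_truth=ground_truth,
    )


# ---------------------------------------------------------------------------
# on-disk bundle
# ---------------------------------------------------------------------------

def write_bundle(bundle: CohortBundle, outdir: str) -> None:
    """Write a cohort bundle in the pipeline's input formats."""
    from quieteye.events import write_events
    from quieteye.gaze_io import write_gaze_table

    for sub in ("gaze", "events", "d2", "rta"):
        os.makedirs(os.path.join(outdir, sub), exist_ok=True)
    for (pid, tid), trace in bundle.traces.items():
        write_gaze_table(trace, os.path.join(outdir, "gaze", f"{pid}_{tid}.csv"))
    for (pid, tid), ev in bundle.events.items():
        write_events(ev, os.path.join(outdir, "events", f"{pid}_{tid}.json"))
    bundle.sheet.to_csv(os.path.join(outdir, "d2", "sheet.csv"))
    for pid, m in bundle.marks.items():
        m.to_csv(os.path.join(outdir, "d2", f"{pid}_marks.csv"))
    for pid, log in bundle.rta.items():
        log.to_csv(os.path.join(outdir, "rta", f"{pid}.csv"))
    bundle.norms.to_csv(os.path.join(outdir, "norms.csv"))
    with open(os.path.join(outdir, "ages.json"), "w", encoding="utf-8") as fh:
        json.dump(bundle.ages, fh)
    with open(os.path.join(outdir, "ground_truth.json"), "w", encoding="utf-8") as fh:
        json.dump(bundle.ground_truth, fh)


def read_bundle(
    indir: str, config: CohortConfig | None = None, gaze_units: str = "deg"
) -> CohortBundle:
    """Read a bundle previously written with :func:`write_bundle`.

    ``gaze_units`` selects the coordinate dialect of the gaze CSVs
    (``'deg'`` head-fixed degrees, ``'px'`` scene-camera pixels).
    """
    from quieteye.events import read_events
    from quieteye.gaze_io import read_gaze_table

    config = config or CohortConfig()
    traces: dict[tuple[str, str], GazeTrace] = {}
    events: dict[tuple[str, str], TrialEvents] = {}
    for name in sorted(os.listdir(os.path.join(indir, "gaze"))):
        pid, tid = name[: -len(".csv")].split("_")
        traces[(pid, tid)] = read_gaze_table(
            os.path.join(indir, "gaze", name),
            CameraSpec(sample_rate_hz=config.sample_rate_hz),
            units=gaze_units,
            participant_id=pid,
            trial_id=tid,
        )
    for name in sorted(os.listdir(os.path.join(indir, "events"))):
        pid, tid = name[: -len(".json")].split("_")
        events[(pid, tid)] = read_events(os.path.join(indir, "events", name))
    sheet = D2Sheet.from_csv(os.path.join(indir, "d2", "sheet.csv"))
    marks = {
        name[: -len("_marks.csv")]: D2Marks.from_csv(os.path.join(indir, "d2", name))
        for name in sorted(os.listdir(os.path.join(indir, "d2")))
        if name.endswith("_marks.csv")
    }
    rta = {
        name[: -len(".csv")]: RTATrialLog.from_csv(os.path.join(indir, "rta", name))
        for name in sorted(os.listdir(os.path.join(indir, "rta")))
    }
    norms = NormTable.from_csv(os.path.join(indir, "norms.csv"))
    with open(os.path.join(indir, "ages.json"), "r", encoding="utf-8") as fh:
        ages = {k: int(v) for k, v in json.load(fh).items()}
    gt_path = os.path.join(indir, "ground_truth.json")
    ground_truth: dict[str, Any] = {}
    if os.path.exists(gt_path):
        with open(gt_path, "r", encoding="utf-8") as fh:
            ground_truth = json.load(fh)
    return CohortBundle(
        config=config,
        traces=traces,
        events=events,
        sheet=sheet,
        marks=marks,
        rta=rta,
        ages=ages,
        norms=norms,
        ground_truth=ground_truth,
    )
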