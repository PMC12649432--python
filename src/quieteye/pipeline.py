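"""Extract → score → link orchestration.

Stages
------
``extract``
    Gaze traces + event annotations → per-trial QE metrics (with the
    two-ratio reliability rule) → participant-level eye metrics.  Every
    exclusion is logged with the rule that fired.
``score``
    d2-R marks and RTA logs → per-participant attention scores.
``link``
    Joined cohort table → descriptives, correlation/R² table
    with bootstrap double checks, and the CCA with sequential Wilks
    permutation p-values.

All stages operate on an in-memory :class:`~quieteye.simulate.CohortBundle`
(or one read from disk) and return plain pandas/dict structures that the CLI
serialises to CSV/JSON.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from typing import Any

import numpy as np
import pandas as pd
import yaml

from quieteye import stats as qstats
from quieteye.attention import score_d2, score_rta
from quieteye.events import estimate_sync_offset
from quieteye.fixation import compute_quality, detect_fixations
from quieteye.qe import QETrialMetrics, aggregate_participant, trial_metrics
from quieteye.simulate import CohortBundle

__all__ = [
    "PipelineParams",
    "LinkReport",
    "extract_trials",
    "extract_participants",
    "score_attention",
    "build_cohort_table",
    "link_stats",
    "run_pipeline",
    "EYE_VARS",
    "ATTENTION_VARS",
]

log = logging.getLogger("quieteye")

EYE_VARS = ("n_fixations", "tt_ms", "qe_onset_ms", "qe_duration_ms")
ATTENTION_VARS = ("pct_errors_ss", "cp_ss", "rt_mean", "sdrt", "cvrt", "corr_resp")


@dataclass(frozen=True)
class PipelineParams:
    """All tunable pipeline parameters (flat, YAML-serialisable)."""

    dispersion_deg: float = 1.0
    min_duration_ms: float = 100.0
    gap_tolerance_ms: float = 75.0
    window_ms: float = 2000.0
    qe_radius_deg: float = 1.0
    tracking_ratio_min: float = 0.85
    fixation_ratio_min: float = 0.60
    min_valid_trials: int = 5
    anticipation_ms: float = 100.0
    gaze_units: str = "deg"
    B_boot: int = 9999
    B_perm: int = 999
    seed: int = 0

    def __post_init__(self) -> None:
        if self.gaze_units not in ("deg", "px"):
            raise ValueError("gaze_units must be 'deg' or 'px'")
        if not (0 < self.tracking_ratio_min <= 1 and 0 < self.fixation_ratio_min <= 1):
            raise ValueError("reliability thresholds must lie in (0, 1]")
        if self.B_boot < 99 or self.B_perm < 99:
            raise ValueError("bootstrap/permutation B must be at least 99")

    def to_yaml(self, path: str) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path: str, **overrides: Any) -> "PipelineParams":
        with open(path, "r", encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**data)


# ---------------------------------------------------------------------------
# extract
# ---------------------------------------------------------------------------

def extract_trials(
    bundle: CohortBundle, params: PipelineParams | None = None
) -> tuple[list[QETrialMetrics], list[dict[str, Any]]]:
    """Run detection, synchronisation and QE extraction on every trial.

    Returns the per-trial metrics and a structured exclusion log (one record
    per unreliable trial with the rule that fired).
    """
    params = params or PipelineParams()
    out: list[QETrialMetrics] = []
    exclusions: list[dict[str, Any]] = []
    for (pid, tid), trace in sorted(bundle.traces.items()):
        ev = bundle.events[(pid, tid)]
        offset = estimate_sync_offset(ev)
        fixations = detect_fixations(
            trace,
            dispersion_deg=params.dispersion_deg,
            min_duration_ms=params.min_duration_ms,
            gap_tolerance_ms=params.gap_tolerance_ms,
        )
        quality = compute_quality(
            trace,
            fixations,
            tracking_min=params.tracking_ratio_min,
            fixation_min=params.fixation_ratio_min,
        )
        tm = trial_metrics(
            fixations,
            ev,
            offset,
            quality,
            window_ms=params.window_ms,
            qe_radius_deg=params.qe_radius_deg,
            participant_id=pid,
            trial_id=tid,
        )
        out.append(tm)
        if not quality.reliable:
            rule = (
                f"tracking_ratio {quality.tracking_ratio:.2f} < {params.tracking_ratio_min}"
                if quality.tracking_ratio < params.tracking_ratio_min
                else f"fixation_ratio {quality.fixation_ratio:.2f} < {params.fixation_ratio_min}"
            )
            exclusions.append(
                {"stage": "extract", "participant": pid, "trial": tid, "rule": rule}
            )
            log.info("excluded trial %s/%s: %s", pid, tid, rule)
    return out, exclusions


def trials_to_frame(trials: list[QETrialMetrics]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "participant_id": t.participant_id,
                "trial_id": t.trial_id,
                "reliable": t.reliable,
                "qe_onset_ms": t.qe_onset_ms,
                "qe_duration_ms": t.qe_duration_ms,
                "n_fixations": t.n_fixations,
                "tt_ms": t.total_fixation_ms,
                "catch": t.catch,
            }
            for t in trials
        ]
    )


def extract_participants(
    trials: list[QETrialMetrics], params: PipelineParams | None = None
) -> tuple[pd.DataFrame, list[dict[str, Any]]]:
    """Aggregate trials to participant eye metrics, applying the trial minimum."""
    params = params or PipelineParams()
    by_pid: dict[str, list[QETrialMetrics]] = {}
    for t in trials:
        by_pid.setdefault(t.participant_id, []).append(t)
    rows = []
    exclusions: list[dict[str, Any]] = []
    for pid in sorted(by_pid):
        pm = aggregate_participant(by_pid[pid], min_valid=params.min_valid_trials)
        rows.append(
            {
                "participant_id": pid,
                "qe_onset_ms": pm.qe_onset_ms,
                "qe_duration_ms": pm.qe_duration_ms,
                "n_fixations": pm.n_fixations,
                "tt_ms": pm.total_fixation_ms,
                "n_valid_trials": pm.n_valid_trials,
                "n_catches": pm.n_catches,
                "included": pm.included,
            }
        )
        if not pm.included:
            rule = f"reliable trials {pm.n_valid_trials} < {params.min_valid_trials}"
            exclusions.append({"stage": "extract", "participant": pid, "trial": None, "rule": rule})
            log.info("excluded participant %s: %s", pid, rule)
    return pd.DataFrame(rows), exclusions


# ---------------------------------------------------------------------------
# score
# ---------------------------------------------------------------------------

def score_attention(
    bundle: CohortBundle, params: PipelineParams | None = None
) -> pd.DataFrame:
    """Score d2-R and RTA for every participant in the bundle."""
    params = params or PipelineParams()
    rows = []
    for pid in sorted(bundle.marks):
        d2 = score_d2(bundle.sheet, bundle.marks[pid], bundle.norms, bundle.ages[pid])
        rta = score_rta(bundle.rta[pid], anticipation_ms=params.anticipation_ms)
        rows.append(
            {
                "participant_id": pid,
                "pct_errors_ss": d2.pct_errors_ss,
                "cp_ss": d2.cp_ss,
                "pct_errors_raw": d2.pct_errors_raw,
                "cp_raw": d2.cp_raw,
                "rt_mean": rta.rt_mean_ms,
                "sdrt": rta.sdrt_ms,
                "cvrt": rta.cvrt_pct,
                "corr_resp": rta.corr_resp,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# link
# ---------------------------------------------------------------------------

def build_cohort_table(eye: pd.DataFrame, attention: pd.DataFrame) -> pd.DataFrame:
    """Join eye and attention variables into the participant × variable table.

    Keeps included participants with complete eye metrics (participants
    whose reliable trials never contained a QE fixation drop out listwise).
    """
    table = eye[eye["included"]].merge(attention, on="participant_id", how="inner")
    cols = ["participant_id", *EYE_VARS, *ATTENTION_VARS, "n_catches"]
    table = table[cols].dropna(subset=list(EYE_VARS))
    return table.reset_index(drop=True)


@dataclass
class LinkReport:
    descriptives: pd.DataFrame
    correlations: pd.DataFrame
    cca: dict[str, Any]
    n: int


def link_stats(
    table: pd.DataFrame,
    params: PipelineParams | None = None,
    include_bootstrap: bool = True,
    include_cca: bool = True,
) -> LinkReport:
    """Run the full statistical layer on a cohort table.

    The correlation table has one row per attention variable (plus catch
    count): Pearson r against each eye variable with t-based and bootstrap
    p-values, and the shared-variance R² of that variable on the four-column
    eye block with its F-test p-value.
    """
    params = params or PipelineParams()
    rng = np.random.default_rng(params.seed)

    desc_rows = []
    for var in (*ATTENTION_VARS, *EYE_VARS):
        d = qstats.descriptives(table[var].to_numpy(dtype=float))
        desc_rows.append({"variable": var, **dataclasses.asdict(d)})
    desc = pd.DataFrame(desc_rows)

    X = table[list(EYE_VARS)].to_numpy(dtype=float)
    corr_rows = []
    for var in (*ATTENTION_VARS, "n_catches"):
        y = table[var].to_numpy(dtype=float)
        row: dict[str, Any] = {"variable": var}
        for ev in EYE_VARS:
            x = table[ev].to_numpy(dtype=float)
            rep = qstats.pearson_with_t(x, y)
            row[f"r_{ev}"] = rep.r
            row[f"p_{ev}"] = rep.p_t
            if include_bootstrap:
                row[f"p_boot_{ev}"] = qstats.bootstrap_p(x, y, B=params.B_boot, seed=rng)
        sv = qstats.shared_variance(y, X)
        row["r_squared"] = sv.r_squared
        row["p_r_squared"] = sv.p_f
        corr_rows.append(row)
    corr = pd.DataFrame(corr_rows)

    cca_out: dict[str, Any] = {}
    if include_cca:
        Y = table[list(ATTENTION_VARS)].to_numpy(dtype=float)
        res = qstats.cca(X, Y)
        p_perm = qstats.permutation_p(X, Y, B=params.B_perm, seed=rng)
        cca_out = {
            "canonical_correlations": res.canonical_correlations.tolist(),
            "wilks": res.wilks.tolist(),
            "p_perm": p_perm.tolist(),
            "loadings_X": {
                var: res.loadings_X[i].tolist() for i, var in enumerate(EYE_VARS)
            },
            "loadings_Y": {
                var: res.loadings_Y[i].tolist() for i, var in enumerate(ATTENTION_VARS)
            },
        }
    return LinkReport(descriptives=desc, correlations=corr, cca=cca_out, n=len(table))


# ---------------------------------------------------------------------------
# all-in-one
# ---------------------------------------------------------------------------

@dataclass
class PipelineReport:
    trials: pd.DataFrame
    participants: pd.DataFrame
    attention: pd.DataFrame
    cohort: pd.DataFrame
    link: LinkReport | None
    exclusions: list[dict[str, Any]] = field(default_factory=list)


def run_pipeline(
    bundle: CohortBundle,
    params: PipelineParams | None = None,
    include_bootstrap: bool = True,
    include_cca: bool = True,
    include_link: bool = True,
) -> PipelineReport:
    """Run extract → score → link on a bundle and collect every output."""
    params = params or PipelineParams()
    trials, excl_t = extract_trials(bundle, params)
    eye, excl_p = extract_participants(trials, params)
    attention = score_attention(bundle, params)
    cohort = build_cohort_table(eye, attention)
    report = None
    if include_link:
        report = link_stats(
            cohort, params, include_bootstrap=include_bootstrap, include_cca=include_cca
        )
    return PipelineReport(
        trials=trials_to_frame(trials),
        participants=eye,
        attention=attention,
        cohort=cohort,
        link=report,
        exclusions=excl_t + excl_p,
    )
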