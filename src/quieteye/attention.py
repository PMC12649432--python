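"""Scoring of the two attention instruments.

d2-R test of attention
    A paper-and-pencil cancellation test: 14 rows of 57 characters, each a
    letter ``d`` or ``p`` carrying one to four dashes.  Targets are ``d``
    with exactly two dashes.  Rows 1 and 14 are warm-up/cool-down and are
    excluded from scoring; rows 2–13 of the standard sheet contain 308
    targets and 376 distractors.  Each row is worked for 20 s (280 s total).
    Scores: concentration performance ``CP`` (correctly marked targets minus
    commission errors) and ``%errors`` ((commissions + omissions) as a
    percentage of processed target characters), both mapped to standard
    scores through an age-banded norm table.  Real d2-R norms are
    proprietary; a surrogate linear norm table is provided and any table in
    the documented CSV layout can be substituted.

Reaction Test of Alertness (RTA)
    28 non-signal simple-reaction trials (the signal set is not analysed).
    A response is correct when it falls inside the 1000 ms response window
    and is not an anticipation (< 100 ms by default).  Scores: mean RT,
    intraindividual SD of RT (sample SD, n−1), its coefficient of variation
    ``CVRT = 100·SDRT/RT`` and the number of correct responses.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import IO, Union

import numpy as np
import pandas as pd

__all__ = [
    "D2Char",
    "D2Sheet",
    "D2Marks",
    "D2Scores",
    "NormTable",
    "RTATrialLog",
    "RTAScores",
    "standard_sheet",
    "score_d2",
    "score_rta",
    "N_ROWS",
    "ROW_LENGTH",
    "SCORED_ROWS",
    "ROW_TIME_S",
    "RTA_N_TRIALS",
    "RTA_RESPONSE_WINDOW_MS",
    "DEFAULT_ANTICIPATION_MS",
]

N_ROWS = 14
ROW_LENGTH = 57
#: 1-based scored rows (first and last row excluded).
SCORED_ROWS = tuple(range(2, 14))
ROW_TIME_S = 20.0

RTA_N_TRIALS = 28
RTA_RESPONSE_WINDOW_MS = 1000.0
DEFAULT_ANTICIPATION_MS = 100.0

_SHEET_SEED = 684_308  # fixes the standard sheet arrangement


@dataclass(frozen=True)
class D2Char:
    """One stimulus character: a letter with a dash count."""

    letter: str
    dashes: int

    def __post_init__(self) -> None:
        if self.letter not in ("d", "p"):
            raise ValueError("letter must be 'd' or 'p'")
        if not 1 <= self.dashes <= 4:
            raise ValueError("dash count must be in 1..4")

    @property
    def is_target(self) -> bool:
        return self.letter == "d" and self.dashes == 2


@dataclass
class D2Sheet:
    """A full 14 × 57 stimulus sheet."""

    rows: list[list[D2Char]]

    def __post_init__(self) -> None:
        if len(self.rows) != N_ROWS or any(len(r) != ROW_LENGTH for r in self.rows):
            raise ValueError(f"sheet must be {N_ROWS} rows × {ROW_LENGTH} characters")

    def targets_in(self, row: int, last_position: int = ROW_LENGTH) -> list[int]:
        """1-based positions of targets within the processed span of a row."""
        chars = self.rows[row - 1][:last_position]
        return [i + 1 for i, c in enumerate(chars) if c.is_target]

    def count_scored(self) -> tuple[int, int]:
        """(targets, distractors) over the scored rows 2–13."""
        n_t = sum(len(self.targets_in(r)) for r in SCORED_ROWS)
        return n_t, len(SCORED_ROWS) * ROW_LENGTH - n_t

    @property
    def total_time_s(self) -> float:
        """Instrument administration time: 20 s per row."""
        return N_ROWS * ROW_TIME_S

    def to_csv(self, dest: Union[str, IO[str]]) -> None:
        rec = [
            {"row": r + 1, "position": p + 1, "letter": c.letter, "dashes": c.dashes}
            for r, row in enumerate(self.rows)
            for p, c in enumerate(row)
        ]
        pd.DataFrame(rec).to_csv(dest, index=False)

    @classmethod
    def from_csv(cls, source: Union[str, IO[str]]) -> "D2Sheet":
        df = pd.read_csv(source)
        rows: list[list[D2Char]] = [[None] * ROW_LENGTH for _ in range(N_ROWS)]  # type: ignore[list-item]
        for rec in df.itertuples():
            rows[int(rec.row) - 1][int(rec.position) - 1] = D2Char(str(rec.letter), int(rec.dashes))
        if any(c is None for row in rows for c in row):
            raise ValueError("sheet CSV does not cover all 14 × 57 positions")
        return cls(rows=rows)


def standard_sheet() -> D2Sheet:
    """The bundled standard sheet (synthetic, deterministically generated).

    Rows 2–13 contain exactly 308 targets and 376 distractors in a fixed
    pseudo-random arrangement; rows 1 and 14 carry 26 targets each.  The
    arrangement stands in for the copyrighted instrument sheet: structure
    matches (letters d/p, 1–4 dashes, target = d with two dashes) but the
    specific character order is this package's own.
    """
    rng = np.random.default_rng(_SHEET_SEED)

    def distractor() -> D2Char:
        if rng.random() < 0.5:
            return D2Char("p", int(rng.integers(1, 5)))
        return D2Char("d", int(rng.choice([1, 3, 4])))

    def build_block(n_chars: int, n_targets: int) -> list[D2Char]:
        chars = [D2Char("d", 2)] * n_targets + [distractor() for _ in range(n_chars - n_targets)]
        order = rng.permutation(n_chars)
        return [chars[i] for i in order]

    scored = build_block(len(SCORED_ROWS) * ROW_LENGTH, 308)
    first = build_block(ROW_LENGTH, 26)
    last = build_block(ROW_LENGTH, 26)
    rows = [first]
    for r in range(len(SCORED_ROWS)):
        rows.append(scored[r * ROW_LENGTH : (r + 1) * ROW_LENGTH])
    rows.append(last)
    return D2Sheet(rows=rows)


@dataclass
class D2Marks:
    """A participant's response record: marks and per-row progress.

    ``marked`` maps 1-based row → set of 1-based marked positions;
    ``last_processed`` maps row → rightmost processed position (defaults to
    the rightmost mark when not recorded explicitly).
    """

    marked: dict[int, set[int]] = field(default_factory=dict)
    last_processed: dict[int, int] = field(default_factory=dict)

    def span(self, row: int) -> int:
        if row in self.last_processed:
            return self.last_processed[row]
        marks = self.marked.get(row, set())
        return max(marks) if marks else 0

    def validate(self) -> None:
        for row, marks in self.marked.items():
            if not 1 <= row <= N_ROWS:
                raise ValueError(f"mark in nonexistent row {row}")
            span = self.span(row)
            for p in marks:
                if not 1 <= p <= ROW_LENGTH:
                    raise ValueError(f"mark at impossible position {p} in row {row}")
                if p > span:
                    raise ValueError(
                        f"mark at position {p} beyond processed span {span} in row {row}"
                    )

    def to_csv(self, dest: Union[str, IO[str]]) -> None:
        rec = [
            {"row": r, "position": p}
            for r in sorted(self.marked)
            for p in sorted(self.marked[r])
        ]
        rec += [
            {"row": r, "position": -self.last_processed[r]}
            for r in sorted(self.last_processed)
        ]
        pd.DataFrame(rec, columns=["row", "position"]).to_csv(dest, index=False)

    @classmethod
    def from_csv(cls, source: Union[str, IO[str]]) -> "D2Marks":
        # negative positions encode the explicit end-of-progress marker
        df = pd.read_csv(source)
        marks = cls()
        for rec in df.itertuples():
            row, pos = int(rec.row), int(rec.position)
            if pos < 0:
                marks.last_processed[row] = -pos
            else:
                marks.marked.setdefault(row, set()).add(pos)
        return marks


@dataclass(frozen=True)
class D2Scores:
    processed_targets: int
    commission: int
    omission: int
    cp_raw: int
    pct_errors_raw: float
    cp_ss: float
    pct_errors_ss: float


class NormTable:
    """Age-banded raw → standard-score lookup for the d2-R variables.

    Backed by a long-format table (instrument, age_lo, age_hi, raw, ss);
    lookups interpolate linearly between raw grid points within the matching
    age band and clamp outside the grid.  The mapping must be monotone in
    the raw score within each band (increasing for CP, decreasing for
    %errors).
    """

    def __init__(self, table: pd.DataFrame):
        required = {"instrument", "age_lo", "age_hi", "raw", "ss"}
        if not required.issubset(table.columns):
            raise ValueError(f"norm table must have columns {sorted(required)}")
        self.table = table.sort_values(["instrument", "age_lo", "raw"]).reset_index(drop=True)
        for (_, _, _), grp in self.table.groupby(["instrument", "age_lo", "age_hi"]):
            d = np.diff(grp["ss"].to_numpy())
            if not (np.all(d >= 0) or np.all(d <= 0)):
                raise ValueError("norm table must be monotone in raw score within a band")

    def lookup(self, instrument: str, age: float, raw: float) -> float:
        band = self.table[
            (self.table["instrument"] == instrument)
            & (self.table["age_lo"] <= age)
            & (age <= self.table["age_hi"])
        ]
        if band.empty:
            raise ValueError(f"age {age} outside the norm bands for {instrument!r}")
        # raw grid is ascending; ss may ascend (CP) or descend (%errors)
        x = band["raw"].to_numpy(dtype=float)
        y = band["ss"].to_numpy(dtype=float)
        return float(np.interp(raw, x, y))

    @classmethod
    def surrogate(
        cls,
        cp_mean: float,
        cp_sd: float,
        err_mean: float,
        err_sd: float,
        ss_center: tuple[float, float] = (100.0, 100.0),
        ss_scale: tuple[float, float] = (10.0, 10.0),
        age_band: tuple[float, float] = (9.0, 12.0),
    ) -> "NormTable":
        """Linear surrogate norms: SS = centre ± scale · (raw − mean)/sd.

        CP maps increasingly (higher CP → higher SS), %errors decreasingly.
        Stands in for the proprietary instrument norms; drop in a real table
        via the CSV layout to replace it.
        """
        lo, hi = age_band
        rows = []
        for raw in np.linspace(cp_mean - 6 * cp_sd, cp_mean + 6 * cp_sd, 25):
            ss = ss_center[0] + ss_scale[0] * (raw - cp_mean) / cp_sd
            rows.append(("cp", lo, hi, raw, ss))
        for raw in np.linspace(max(0.0, err_mean - 6 * err_sd), err_mean + 6 * err_sd, 25):
            ss = ss_center[1] - ss_scale[1] * (raw - err_mean) / err_sd
            rows.append(("pct_errors", lo, hi, raw, ss))
        return cls(pd.DataFrame(rows, columns=["instrument", "age_lo", "age_hi", "raw", "ss"]))

    def to_csv(self, dest: Union[str, IO[str]]) -> None:
        self.table.to_csv(dest, index=False)

    @classmethod
    def from_csv(cls, source: Union[str, IO[str]]) -> "NormTable":
        return cls(pd.read_csv(source))


def score_d2(
    sheet: D2Sheet,
    marks: D2Marks,
    norms: NormTable,
    age: float,
    literal_cp: bool = False,
) -> D2Scores:
    """Score a d2-R response record over rows 2–13.

    ``processed_targets`` counts targets within each row's processed span;
    ``commission`` counts marked distractors, ``omission`` unmarked processed
    targets.  ``cp_raw`` is correctly marked targets minus commissions (the
    standard concentration-performance score); with ``literal_cp=True`` it is
    instead all processed targets minus commissions, an alternative reading
    of "processed targets minus commission errors".
    ``pct_errors_raw = 100 · (commission + omission) / processed_targets``.
    """
    marks.validate()
    processed_targets = 0
    hits = 0
    commission = 0
    for row in SCORED_ROWS:
        span = marks.span(row)
        targets = set(sheet.targets_in(row, span))
        marked = marks.marked.get(row, set())
        processed_targets += len(targets)
        hits += len(targets & marked)
        commission += len(marked - targets)
    omission = processed_targets - hits
    cp_raw = (processed_targets if literal_cp else hits) - commission
    if processed_targets == 0:
        raise ValueError("no processed target characters; %errors undefined")
    pct_errors_raw = 100.0 * (commission + omission) / processed_targets
    return D2Scores(
        processed_targets=processed_targets,
        commission=commission,
        omission=omission,
        cp_raw=cp_raw,
        pct_errors_raw=pct_errors_raw,
        cp_ss=norms.lookup("cp", age, cp_raw),
        pct_errors_ss=norms.lookup("pct_errors", age, pct_errors_raw),
    )


@dataclass
class RTATrialLog:
    """Raw log of the 28 non-signal simple-reaction trials.

    ``rt_ms`` is NaN where no response occurred inside the window.
    """

    isi_ms: np.ndarray
    rt_ms: np.ndarray
    responded: np.ndarray

    def __post_init__(self) -> None:
        self.isi_ms = np.asarray(self.isi_ms, dtype=float)
        self.rt_ms = np.asarray(self.rt_ms, dtype=float)
        self.responded = np.asarray(self.responded, dtype=bool)
        n = len(self.isi_ms)
        if not (len(self.rt_ms) == len(self.responded) == n):
            raise ValueError("RTA log arrays must have equal length")
        if n != RTA_N_TRIALS:
            raise ValueError(f"RTA non-signal set has {RTA_N_TRIALS} trials, got {n}")

    def to_csv(self, dest: Union[str, IO[str]]) -> None:
        pd.DataFrame(
            {
                "trial": np.arange(1, len(self.isi_ms) + 1),
                "isi_ms": self.isi_ms,
                "rt_ms": self.rt_ms,
                "responded": self.responded.astype(int),
            }
        ).to_csv(dest, index=False)

    @classmethod
    def from_csv(cls, source: Union[str, IO[str]]) -> "RTATrialLog":
        df = pd.read_csv(source)
        return cls(
            isi_ms=df["isi_ms"].to_numpy(dtype=float),
            rt_ms=df["rt_ms"].to_numpy(dtype=float),
            responded=df["responded"].to_numpy(dtype=bool),
        )


@dataclass(frozen=True)
class RTAScores:
    rt_mean_ms: float
    sdrt_ms: float
    cvrt_pct: float
    corr_resp: int


def score_rta(
    log: RTATrialLog,
    anticipation_ms: float = DEFAULT_ANTICIPATION_MS,
    window_ms: float = RTA_RESPONSE_WINDOW_MS,
) -> RTAScores:
    """Score the RTA non-signal set.

    Correct responses fall within ``[anticipation_ms, window_ms]``;
    anticipations (faster than ``anticipation_ms``) and missed trials count
    as incorrect.  RT statistics use correct responses only, with the sample
    SD (n−1); at least two correct responses are required.
    """
    rt = log.rt_ms
    correct = log.responded & np.isfinite(rt) & (rt >= anticipation_ms) & (rt <= window_ms)
    n_correct = int(correct.sum())
    if n_correct < 2:
        raise ValueError(f"only {n_correct} correct responses; RT variability undefined")
    r = rt[correct]
    mean = float(np.mean(r))
    sd = float(np.std(r, ddof=1))
    return RTAScores(
        rt_mean_ms=mean,
        sdrt_ms=sd,
        cvrt_pct=100.0 * sd / mean,
        corr_resp=n_correct,
    )
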