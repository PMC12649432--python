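import io

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from quieteye.attention import (
    D2Marks,
    D2Sheet,
    NormTable,
    RTATrialLog,
    SCORED_ROWS,
    score_d2,
    score_rta,
    standard_sheet,
)


@pytest.fixture(scope="module")
def sheet() -> D2Sheet:
    return standard_sheet()


@pytest.fixture(scope="module")
def norms() -> NormTable:
    return NormTable.surrogate(cp_mean=250.0, cp_sd=30.0, err_mean=12.0, err_sd=6.0)


def full_span_marks(sheet: D2Sheet, omit=(), commit=()) -> D2Marks:
    """Marks covering all rows fully: every target marked, modulated."""
    marks = D2Marks()
    for row in range(1, 15):
        marks.last_processed[row] = 57
        marks.marked[row] = set(sheet.targets_in(row))
    for row, pos in omit:
        marks.marked[row].discard(pos)
    for row, pos in commit:
        marks.marked[row].add(pos)
    return marks


class TestSheetStructure:
    def test_scored_rows_have_308_targets_376_distractors(self, sheet):
        assert sheet.count_scored() == (308, 376)

    def test_administration_time_is_280_seconds(self, sheet):
        assert sheet.total_time_s == 280.0

    def test_sheet_is_deterministic_and_round_trips(self, sheet):
        assert standard_sheet().rows == sheet.rows
        buf = io.StringIO()
        sheet.to_csv(buf)
        again = D2Sheet.from_csv(io.StringIO(buf.getvalue()))
        assert again.rows == sheet.rows


class TestScoreD2:
    def test_perfect_marking_has_zero_errors(self, sheet, norms):
        scores = score_d2(sheet, full_span_marks(sheet), norms, age=10)
        assert scores.processed_targets == 308
        assert scores.commission == 0 and scores.omission == 0
        assert scores.pct_errors_raw == 0.0
        assert scores.cp_raw == 308

    def test_error_counts_and_percentage(self, sheet, norms):
        # omit 10 targets, mark 5 distractors, all within scored rows
        targets = [(r, p) for r in SCORED_ROWS for p in sheet.targets_in(r)]
        distractors = [
            (r, p)
            for r in SCORED_ROWS
            for p in range(1, 58)
            if p not in sheet.targets_in(r)
        ]
        marks = full_span_marks(sheet, omit=targets[:10], commit=distractors[:5])
        s = score_d2(sheet, marks, norms, age=10)
        assert (s.omission, s.commission) == (10, 5)
        assert s.pct_errors_raw == pytest.approx(100.0 * 15 / 308)
        assert s.cp_raw == (308 - 10) - 5

    def test_first_and_last_rows_are_ignored(self, sheet, norms):
        base = score_d2(sheet, full_span_marks(sheet), norms, age=10)
        noisy = full_span_marks(sheet)
        noisy.marked[1] = set()       # omit everything in row 1
        noisy.marked[14] = set(range(1, 58))  # mark everything in row 14
        assert score_d2(sheet, noisy, norms, age=10) == base

    def test_partial_span_shrinks_denominator(self, sheet, norms):
        marks = D2Marks()
        for row in range(1, 15):
            marks.last_processed[row] = 30
            marks.marked[row] = set(sheet.targets_in(row, 30))
        s = score_d2(sheet, marks, norms, age=10)
        assert s.processed_targets == sum(len(sheet.targets_in(r, 30)) for r in SCORED_ROWS)
        assert s.pct_errors_raw == 0.0

    def test_literal_cp_variant(self, sheet, norms):
        targets = [(r, p) for r in SCORED_ROWS for p in sheet.targets_in(r)]
        marks = full_span_marks(sheet, omit=targets[:10])
        strict = score_d2(sheet, marks, norms, age=10)
        literal = score_d2(sheet, marks, norms, age=10, literal_cp=True)
        assert strict.cp_raw == 298
        assert literal.cp_raw == 308  # processed targets minus 0 commissions

    def test_mark_beyond_span_rejected(self, sheet, norms):
        marks = full_span_marks(sheet)
        marks.last_processed[5] = 20
        with pytest.raises(ValueError, match="span"):
            score_d2(sheet, marks, norms, age=10)

    def test_age_outside_bands_rejected(self, sheet, norms):
        with pytest.raises(ValueError, match="age"):
            score_d2(sheet, full_span_marks(sheet), norms, age=35)

    def test_row_permutation_invariance(self, sheet, norms):
        marks = full_span_marks(sheet)
        # permute the scored rows 2–13 (rows 1 and 14 stay put)
        perm = [0] + [1 + i for i in (5, 2, 9, 0, 7, 4, 11, 6, 1, 8, 3, 10)] + [13]
        sheet2 = D2Sheet(rows=[sheet.rows[i] for i in perm])
        marks2 = D2Marks(
            marked={r + 1: set(marks.marked[perm[r] + 1]) for r in range(14)},
            last_processed={r + 1: marks.last_processed[perm[r] + 1] for r in range(14)},
        )
        assert score_d2(sheet2, marks2, norms, age=10) == score_d2(sheet, marks, norms, age=10)


class TestNormTable:
    def test_surrogate_maps_mean_to_center_and_is_directional(self, norms):
        assert norms.lookup("cp", 10, 250.0) == pytest.approx(100.0)
        assert norms.lookup("cp", 10, 280.0) == pytest.approx(110.0)
        assert norms.lookup("pct_errors", 10, 12.0) == pytest.approx(100.0)
        # more errors → lower standard score
        assert norms.lookup("pct_errors", 10, 18.0) == pytest.approx(90.0)

    def test_csv_round_trip(self, norms):
        buf = io.StringIO()
        norms.to_csv(buf)
        again = NormTable.from_csv(io.StringIO(buf.getvalue()))
        assert again.lookup("cp", 10, 260.0) == norms.lookup("cp", 10, 260.0)

    def test_non_monotone_table_rejected(self):
        import pandas as pd

        bad = pd.DataFrame(
            {
                "instrument": ["cp"] * 3,
                "age_lo": [9] * 3,
                "age_hi": [12] * 3,
                "raw": [0, 1, 2],
                "ss": [90, 110, 100],
            }
        )
        with pytest.raises(ValueError, match="monotone"):
            NormTable(bad)


def rta_log(rts, responded=None, n=28):
    rt = np.full(n, np.nan)
    resp = np.zeros(n, bool)
    rt[: len(rts)] = rts
    resp[: len(rts)] = True
    if responded is not None:
        resp[: len(responded)] = responded
    return RTATrialLog(
        isi_ms=np.linspace(2500, 6500, n), rt_ms=rt, responded=resp
    )


class TestScoreRTA:
    def test_constant_rts(self):
        s = score_rta(rta_log([300.0, 300.0, 300.0]))
        assert (s.rt_mean_ms, s.sdrt_ms, s.cvrt_pct) == (300.0, 0.0, 0.0)
        assert s.corr_resp == 3

    def test_sample_sd_and_cv(self):
        s = score_rta(rta_log([300.0, 400.0]))
        assert s.rt_mean_ms == pytest.approx(350.0)
        assert s.sdrt_ms == pytest.approx(70.7107, abs=1e-3)
        assert s.cvrt_pct == pytest.approx(20.2030, abs=1e-3)

    def test_anticipations_count_as_incorrect(self):
        s = score_rta(rta_log([60.0, 300.0, 400.0, 350.0]))
        assert s.corr_resp == 3
        assert s.rt_mean_ms == pytest.approx(350.0)

    def test_too_few_correct_responses_is_an_error(self):
        with pytest.raises(ValueError, match="correct"):
            score_rta(rta_log([300.0]))

    def test_wrong_trial_count_rejected(self):
        with pytest.raises(ValueError, match="28"):
            RTATrialLog(isi_ms=np.ones(20), rt_ms=np.ones(20), responded=np.ones(20, bool))

    @settings(max_examples=40, deadline=None)
    @given(
        scale=st.floats(0.5, 2.4),
        rts=st.lists(st.floats(210.0, 400.0), min_size=3, max_size=20),
    )
    def test_cvrt_is_scale_invariant(self, scale, rts):
        base = score_rta(rta_log(rts))
        scaled = score_rta(rta_log([r * scale for r in rts]))
        assert scaled.cvrt_pct == pytest.approx(base.cvrt_pct, abs=1e-8)
        assert scaled.corr_resp == base.corr_resp

    def test_csv_round_trip(self):
        log = rta_log([300.0, 350.0, 280.0])
        buf = io.StringIO()
        log.to_csv(buf)
        again = RTATrialLog.from_csv(io.StringIO(buf.getvalue()))
        np.testing.assert_array_equal(log.responded, again.responded)
        np.testing.assert_allclose(log.rt_ms[log.responded], again.rt_ms[again.responded])
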