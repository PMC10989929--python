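"""Steady-state synthesis-rate calculus and report reconstruction."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ribochase.model import (
    CompartmentMeasurement,
    decay_fc_from_half_lives,
    round_fold_change,
    round_percent,
    synthesis_ratio,
    synthesis_report_from_measurements,
    synthesis_rate_report,
    termination_fraction,
)
from ribochase.simulate import SimulationParams, steady_state_abundance

LN2 = np.log(2.0)


class TestSynthesisRatio:
    def test_printed_mock_column(self):
        assert synthesis_ratio(11, 2.2).fc_synthesis == pytest.approx(24.2)

    def test_identity(self):
        assert synthesis_ratio(1, 1).fc_synthesis == 1.0

    def test_printed_uv_column_from_half_lives(self):
        res = synthesis_ratio(6.5, decay_fc_from_half_lives(17.1, 7.5))
        assert res.fc_synthesis == pytest.approx(2.8509, abs=1e-4)
        assert round_fold_change(res.fc_synthesis) == 2.9

    def test_nonpositive_inputs_rejected(self):
        with pytest.raises(ValueError):
            synthesis_ratio(0.0, 1.0)


class TestTerminationFraction:
    def test_printed_mock_value(self):
        f = termination_fraction(24.2)
        assert f.fraction == pytest.approx(0.95868, abs=1e-5)
        assert round_percent(f.percent) == 95.9

    def test_unit_ratio_means_no_termination(self):
        assert termination_fraction(1.0).fraction == 0.0

    def test_uv_value_from_unrounded_product(self):
        f = termination_fraction(2.851)
        assert f.fraction == pytest.approx(0.6493, abs=1e-4)
        assert round_percent(f.percent) == 64.9

    def test_ratio_below_one_flags_no_evidence(self):
        f = termination_fraction(0.5)
        assert f.fraction == 0.0 and not f.evidence

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(fc=st.floats(1.0, 1e6), bump=st.floats(1e-6, 10.0))
    def test_monotone_increasing_and_bounded(self, fc, bump):
        lo = termination_fraction(fc).fraction
        hi = termination_fraction(fc + bump).fraction
        assert 0.0 <= lo < 1.0 and lo <= hi < 1.0

    @pytest.mark.parametrize("f", [0.0, 0.25, 0.653, 0.959, 0.99])
    def test_round_trip_with_simulator(self, f):
        p = SimulationParams(alpha=1.3, f_term=f, lambda_utr=LN2 / 3.1,
                             lambda_orf=LN2 / 7.2)
        ss = steady_state_abundance(p)
        res = synthesis_ratio(ss.int_utr / ss.int_orf,
                              p.lambda_utr / p.lambda_orf)
        assert res.termination.fraction == pytest.approx(f, abs=1e-12)


class TestDecayFcFromHalfLives:
    def test_uv_utr_orf_prints_point_four(self):
        assert round_fold_change(decay_fc_from_half_lives(17.1, 7.5)) == 0.44
        assert round(decay_fc_from_half_lives(17.1, 7.5), 1) == 0.4

    def test_utr_uv_mock_prints_point_one_eight(self):
        assert round_fold_change(decay_fc_from_half_lives(17.1, 3.1)) == 0.18

    def test_equal_half_lives_give_unity(self):
        assert decay_fc_from_half_lives(4.2, 4.2) == 1.0

    def test_stability_increase_is_five_point_five_fold(self):
        assert round_fold_change(17.1 / 3.1) == 5.5


class TestSynthesisRateReport:
    @pytest.fixture
    def printed(self):
        return synthesis_rate_report(
            fc_int_mock=11, fc_decay_mock=2.2,
            fc_int_uv=6.5, uv_half_lives=(17.1, 7.5),
            fc_int_utr_uv_mock=2.52, utr_half_lives=(17.1, 3.1),
        )

    def test_synthesis_row_matches_print(self, printed):
        row = printed.formatted().loc["FC of synthesis rate"]
        assert list(row) == [24.2, 2.9, 0.46]

    def test_transcription_rate_reduction(self, printed):
        assert round_fold_change(printed.transcription_rate_reduction) == 2.2

    def test_mock_readthrough_is_4_1_percent(self, printed):
        assert round_percent(printed.mock.termination.readthrough * 100) == 4.1

    def test_all_equal_inputs_are_null_result(self):
        r = synthesis_rate_report(
            fc_int_mock=1, fc_decay_mock=1, fc_int_uv=1, fc_decay_uv=1,
            fc_int_utr_uv_mock=1, fc_decay_utr_uv_mock=1,
        )
        row = r.formatted().loc["FC of synthesis rate"]
        assert list(row) == [1.0, 1.0, 1.0]
        assert r.mock.termination.fraction == 0.0

    def test_missing_cells_listed_in_error(self):
        with pytest.raises(ValueError) as exc:
            synthesis_rate_report(fc_int_mock=11)
        msg = str(exc.value)
        assert "mock UTR/ORF: FC of decay" in msg
        assert "UV UTR/ORF" in msg and "UTR UV/mock" in msg

    def test_intensity_rescaling_invariance(self):
        p = SimulationParams(f_term=0.8, lambda_utr=0.2, lambda_orf=0.1)
        ss = steady_state_abundance(p)
        for scale in (1.0, 137.0):
            res = synthesis_ratio(
                (scale * ss.int_utr) / (scale * ss.int_orf),
                p.lambda_utr / p.lambda_orf,
            )
            assert res.termination.fraction == pytest.approx(0.8, abs=1e-12)

    def test_from_measurements_agrees_with_fold_change_route(self):
        ms = {
            (c, k): CompartmentMeasurement(f"{k}-{c}", intensity=i, t_half=t)
            for (c, k), (i, t) in {
                ("mock", "UTR"): (10.5, 3.1), ("mock", "ORF"): (1.0, 7.2),
                ("uv", "UTR"): (26.5, 17.1), ("uv", "ORF"): (4.1, 7.5),
            }.items()
        }
        r = synthesis_report_from_measurements(ms)
        expect = (10.5 / 1.0) * (7.2 / 3.1)
        assert r.mock.fc_synthesis == pytest.approx(expect, rel=1e-12)
        # absolute synthesis rates come along for free
        assert ms[("mock", "UTR")].alpha_hat == pytest.approx(10.5 * LN2 / 3.1)


class TestRounding:
    @pytest.mark.parametrize(
        "x,expect",
        [(24.2, 24.2), (2.8509, 2.9), (0.45684, 0.46), (0.4386, 0.44),
         (1.05, 1.1), (0.185, 0.19), (10.50136, 10.5)],
    )
    def test_fold_change_rounding_half_away_from_zero(self, x, expect):
        assert round_fold_change(x) == expect

    def test_unrounded_internal_arithmetic(self):
        # rounding first would give 6.5 * 0.4 = 2.6, not the printed 2.9
        res = synthesis_ratio(6.5, decay_fc_from_half_lives(17.1, 7.5))
        assert round_fold_change(res.fc_synthesis) == 2.9
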