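"""TEQ/EDI/MOE chain: reported values, unit coherence, monotonicity."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pahrisk import reference
from pahrisk.compounds import COMPOUNDS, UnknownCompoundError
from pahrisk.risk import (
    UNBOUNDED_MOE,
    RiskParams,
    TEFTable,
    assess_commodity,
    classify_moe,
    compute_edi,
    compute_moe,
    compute_teq,
    critical_intake,
    round_half_away,
    run_risk_table,
)

pos = st.floats(min_value=1e-3, max_value=1e3, allow_nan=False)


class TestTEQ:
    def test_cinnamon_means_give_reported_teq(self):
        means = {"BaA": 3.39, "CHR": 6.98, "BbF": 2.78, "BaP": 6.18}
        teq = compute_teq(means)
        assert teq == pytest.approx(6.8668)
        assert round_half_away(teq) == 6.87

    def test_all_reported_teq_cells_within_rounding(self):
        means = reference.survey_means()
        for commodity, (teq_bap, teq_sum4) in reference.TEQ_REPORTED.items():
            got_sum4 = compute_teq({c: means.loc[commodity, c] for c in COMPOUNDS})
            got_bap = compute_teq({"BaP": means.loc[commodity, "BaP"]})
            assert got_sum4 == pytest.approx(teq_sum4, abs=0.0101), commodity
            assert got_bap == pytest.approx(teq_bap, abs=0.0101), commodity

    def test_exact_two_decimal_cells(self):
        means = reference.survey_means()
        for commodity, expected in [("Cinnamon", 6.87), ("Sichuan pepper", 1.70), ("Mustard", 0.33)]:
            teq = compute_teq({c: means.loc[commodity, c] for c in COMPOUNDS})
            assert round_half_away(teq) == expected

    def test_zero_and_bap_alone(self):
        assert compute_teq({c: 0.0 for c in COMPOUNDS}) == 0.0
        assert compute_teq({"BaP": 7.13}) == pytest.approx(7.13)

    def test_unknown_compound_and_negative_rejected(self):
        with pytest.raises(UnknownCompoundError):
            compute_teq({"BkF": 1.0})
        with pytest.raises(ValueError):
            compute_teq({"BaP": -1.0})

    @settings(deadline=None, max_examples=50)
    @given(st.floats(min_value=0, max_value=10), st.floats(min_value=0.1, max_value=5))
    def test_linearity_and_monotonicity(self, bap, alpha):
        base = {"BaA": 1.0, "CHR": 2.0, "BbF": 0.5, "BaP": bap}
        t = compute_teq(base)
        assert compute_teq({k: alpha * v for k, v in base.items()}) == pytest.approx(alpha * t)
        bumped = dict(base, CHR=base["CHR"] + 1.0)
        assert compute_teq(bumped) >= t

    def test_tef_table_requires_bap_reference(self):
        with pytest.raises(ValueError):
            TEFTable({"BaA": 0.1, "BaP": 0.5})
        with pytest.raises(ValueError):
            TEFTable({"BaA": -0.1, "BaP": 1.0})


class TestEDIandMOE:
    def test_hand_computed_edi(self):
        assert compute_edi(6.87, 1.0, 66.83) == pytest.approx(0.10280, abs=5e-5)

    def test_zero_intake_gives_zero_edi(self):
        assert compute_edi(6.87, 0.0, 66.83) == 0.0

    def test_hand_computed_moe(self):
        edi = compute_edi(6.87, 1.0, 66.83)
        assert compute_moe(0.07, edi) == pytest.approx(6.809e5, rel=1e-3)

    def test_zero_exposure_is_unbounded_sentinel(self):
        moe = compute_moe(0.07, 0.0)
        assert moe is UNBOUNDED_MOE
        assert repr(moe) == ">1e12"
        assert moe > 1e300 and not moe < 1e300

    def test_doubling_edi_halves_moe(self):
        assert compute_moe(0.07, 0.2) == pytest.approx(compute_moe(0.07, 0.1) / 2)

    @pytest.mark.parametrize(
        "moe,expected",
        [(2e6, "low"), (9_999, "elevated"), (1e4, "low"), (UNBOUNDED_MOE, "low")],
    )
    def test_classification_boundary_inclusive(self, moe, expected):
        assert classify_moe(moe, 1e4) == expected


class TestCriticalIntake:
    def test_reported_cinnamon_scenario(self):
        g = critical_intake(6.87, 0.07, 66.83, 1e4)
        assert g == pytest.approx(68.09, abs=0.01)
        assert round(g) == 68

    def test_reciprocal_in_teq(self):
        one = critical_intake(3.0, 0.07, 66.83, 1e4)
        assert critical_intake(6.0, 0.07, 66.83, 1e4) == pytest.approx(one / 2)

    def test_zero_teq_has_no_finite_solution(self):
        with pytest.raises(ValueError):
            critical_intake(0.0, 0.07, 66.83, 1e4)

    @settings(deadline=None, max_examples=250)
    @given(teq=pos, bmdl=pos, bw=pos, threshold=st.floats(min_value=10, max_value=1e6))
    def test_moe_at_critical_intake_equals_threshold(self, teq, bmdl, bw, threshold):
        intake = critical_intake(teq, bmdl, bw, threshold)
        moe = compute_moe(bmdl, compute_edi(teq, intake, bw))
        assert moe == pytest.approx(threshold, rel=1e-9)

    @settings(deadline=None, max_examples=50)
    @given(teq=pos, bmdl=pos, bw=pos, intake=pos, factor=st.floats(min_value=1.01, max_value=10))
    def test_moe_strictly_decreasing_in_intake_and_teq(self, teq, bmdl, bw, intake, factor):
        moe = compute_moe(bmdl, compute_edi(teq, intake, bw))
        assert compute_moe(bmdl, compute_edi(teq, intake * factor, bw)) < moe
        assert compute_moe(bmdl, compute_edi(teq * factor, intake, bw)) < moe


class TestRiskTable:
    params = RiskParams(intake_mean=0.5, intake_p95=1.5)

    def test_cinnamon_row_carries_reported_teqs(self):
        res = assess_commodity(
            "Cinnamon", {"BaA": 3.39, "CHR": 6.98, "BbF": 2.78, "BaP": 6.18}, self.params
        )
        assert round_half_away(res.teq_bap) == 6.18
        assert round_half_away(res.teq_sum4) == 6.87
        assert res.teq_bap <= res.teq_sum4

    def test_p95_moe_never_exceeds_mean_moe(self):
        res = assess_commodity(
            "Cinnamon", {"BaA": 3.39, "CHR": 6.98, "BbF": 2.78, "BaP": 6.18}, self.params
        )
        for idx in ("bap", "sum4"):
            assert res.moe[(idx, "p95")] <= res.moe[(idx, "mean")]

    def test_zero_teq_row_is_unbounded_and_low(self):
        res = assess_commodity("Blank", {c: 0.0 for c in COMPOUNDS}, self.params)
        assert res.moe[("bap", "mean")] is UNBOUNDED_MOE
        assert all(v == "low" for v in res.concern.values())
        assert res.critical_intake_bap is None

    def test_row_count_matches_commodities_and_missing_params_rejected(self):
        means = {
            "A": {c: 1.0 for c in COMPOUNDS},
            "B": {c: 2.0 for c in COMPOUNDS},
        }
        results = run_risk_table(means, {"A": self.params, "B": self.params})
        assert [r.commodity for r in results] == ["A", "B"]
        with pytest.raises(KeyError):
            run_risk_table(means, {"A": self.params})

    def test_teq_bap_bounded_by_teq_sum4_across_survey(self):
        means = reference.survey_means()
        for commodity in reference.COMMODITIES:
            res = assess_commodity(
                commodity, {c: float(means.loc[commodity, c]) for c in COMPOUNDS}, self.params
            )
            assert res.teq_bap <= res.teq_sum4
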