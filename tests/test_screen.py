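"""Pearson anchor screen: r, p-from-r, strength classes, reporting."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import integrate, stats

from maternalome.datasets import StageProfile
from maternalome.errors import ValidationError
from maternalome.reference import (
    FBXW_SCMC_N_STAGES,
    WORKED_EXAMPLES,
    fbxw_scmc_records,
)
from maternalome.screen import (
    ScreenConfig,
    classify_strength,
    correlation_report,
    p_from_r,
    pearson_correlation,
    report_to_records,
    records_to_frame,
    screen_against_anchors,
)

STAGES = ("PN", "2C", "4C", "8C", "MO", "BL")


class TestPearsonCorrelation:
    def test_affine_positive(self):
        r, n = pearson_correlation([1, 2, 3, 4, 5, 6], [2, 4, 6, 8, 10, 12])
        assert r == pytest.approx(1.0) and n == 6

    def test_affine_negative(self):
        r, _ = pearson_correlation([1, 2, 3, 4, 5, 6], [6, 5, 4, 3, 2, 1])
        assert r == pytest.approx(-1.0)

    def test_hand_computed_value(self):
        r, n = pearson_correlation([0, 1, 2], [0, 1, 3])
        assert round(r, 4) == 0.9820 and n == 3

    def test_pairwise_complete(self):
        x = [1, 2, np.nan, 4, 5, 6]
        y = [2, 4, 6, 8, np.nan, 12]
        r, n = pearson_correlation(x, y)
        assert n == 4 and r == pytest.approx(1.0)

    def test_undefined_on_zero_spread_or_short(self):
        r, n = pearson_correlation([1, 1, 1, 1], [1, 2, 3, 4])
        assert math.isnan(r) and n == 4
        r, n = pearson_correlation([1, np.nan, np.nan, 4], [1, 2, 3, 4])
        assert math.isnan(r) and n == 2

    @given(
        seed=st.integers(0, 5000),
        a=st.floats(0.1, 10),
        b=st.floats(-5, 5),
    )
    def test_affine_invariance_and_antisymmetry(self, seed, a, b):
        rng = np.random.default_rng(seed)
        x, y = rng.normal(size=6), rng.normal(size=6)
        r0, _ = pearson_correlation(x, y)
        r1, _ = pearson_correlation(a * x + b, y)
        r2, _ = pearson_correlation(-x, y)
        assert r1 == pytest.approx(r0, abs=1e-9)
        assert r2 == pytest.approx(-r0, abs=1e-9)


class TestPFromR:
    def test_published_worked_examples_reproduce_at_4dp(self):
        for gene, dataset, anchor, p_printed, r_printed in WORKED_EXAMPLES:
            p = p_from_r(r_printed, FBXW_SCMC_N_STAGES)
            assert round(p, 4) == p_printed, (gene, dataset, anchor)

    def test_r_zero_gives_p_one(self):
        for n in (3, 6, 30):
            assert p_from_r(0.0, n) == pytest.approx(1.0)

    def test_half_at_n6_closed_form(self):
        assert p_from_r(0.5, 6) == pytest.approx(0.3125, abs=1e-10)

    def test_abs_r_one_gives_zero(self):
        assert p_from_r(1.0, 6) == 0.0
        assert p_from_r(-1.0, 4) == 0.0

    def test_n6_closed_form_grid(self):
        for r in np.round(np.arange(-1.0, 1.001, 0.01), 2):
            closed = 1 - 1.5 * abs(r) + 0.5 * abs(r) ** 3
            assert abs(p_from_r(float(r), 6) - closed) < 1e-10

    def test_closed_form_validated_by_numerical_integration(self):
        # the df=4 two-sided tail integral, computed independently
        for r in (0.3, 0.7062, 0.9128):
            t_val = r * math.sqrt(4 / (1 - r * r))
            tail, _ = integrate.quad(lambda u: stats.t.pdf(u, 4), t_val, np.inf)
            assert abs(2 * tail - (1 - 1.5 * r + 0.5 * r**3)) < 1e-10

    def test_small_n_is_error(self):
        with pytest.raises(ValidationError):
            p_from_r(0.5, 2)

    @given(r=st.floats(0.01, 0.99), n=st.integers(3, 50))
    def test_symmetry_and_monotonicity(self, r, n):
        assert p_from_r(r, n) == pytest.approx(p_from_r(-r, n), abs=1e-12)
        assert p_from_r(min(r + 0.01, 0.999), n) < p_from_r(r, n)
        assert p_from_r(r, n + 1) < p_from_r(r, n)


class TestClassifyStrength:
    CFG = ScreenConfig()

    @pytest.mark.parametrize(
        "r,p,expected",
        [
            (0.9755, 0.0009, "strong_positive"),
            (-0.9325, 0.0067, "strong_negative"),
            (0.69, 0.001, "none"),
            (0.71, 0.06, "none"),
            (-0.70, 0.05, "strong_negative"),  # thresholds inclusive
            (float("nan"), 0.01, "undefined"),
        ],
    )
    def test_threshold_logic(self, r, p, expected):
        assert classify_strength(r, p, self.CFG) == expected

    def test_reference_table_strengths_are_threshold_consistent(self):
        for rec in fbxw_scmc_records():
            assert rec.strength == classify_strength(rec.r, rec.p, self.CFG)


def _profile(pid, values):
    return StageProfile(pid, np.asarray(values, dtype=float), STAGES)


class TestScreenAgainstAnchors:
    def _profiles(self):
        anchor = np.array([5.0, 4.0, 3.0, 2.5, 1.5, 1.0])
        return [
            _profile("A1", anchor),
            _profile("A2", anchor + 0.1),
            _profile("pos", anchor * 2 + 1),
            _profile("neg", -anchor),
            _profile("flat", np.zeros(6) + [0, 0.001, -0.001, 0, 0.001, -0.001]),
        ]

    def test_rule_all_consistent_sign(self):
        cfg = ScreenConfig(anchors=("A1", "A2"), combination_rule="all")
        res = screen_against_anchors(self._profiles(), cfg, "D")
        verdict = dict(zip(res.verdicts["protein_id"], res.verdicts["verdict"]))
        assert verdict["pos"] == "strong_positive"
        assert verdict["neg"] == "strong_negative"
        assert verdict["flat"] == "none"

    def test_anchors_excluded_from_candidates(self):
        cfg = ScreenConfig(anchors=("A1", "A2"))
        res = screen_against_anchors(self._profiles(), cfg, "D")
        assert set(res.verdicts["protein_id"]) == {"pos", "neg", "flat"}

    def test_partial_strength_excluded_under_all_kept_under_any(self):
        anchor1 = np.array([5.0, 4.0, 3.0, 2.5, 1.5, 1.0])
        anchor2 = np.array([1.0, 5.0, 2.0, 4.0, 2.5, 3.0])  # unrelated shape
        profiles = [
            _profile("A1", anchor1),
            _profile("A2", anchor2),
            _profile("cand", anchor1 + 0.01),
        ]
        res_all = screen_against_anchors(
            profiles, ScreenConfig(anchors=("A1", "A2"), combination_rule="all"), "D"
        )
        res_any = screen_against_anchors(
            profiles, ScreenConfig(anchors=("A1", "A2"), combination_rule="any"), "D"
        )
        assert res_all.verdicts.loc[0, "verdict"] == "none"
        assert res_all.verdicts.loc[0, "reason"] == "not_strong_vs_all_anchors"
        assert res_any.verdicts.loc[0, "verdict"] == "strong_positive"

    def test_sign_conflict_excluded(self):
        up = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
        profiles = [
            _profile("A1", up),
            _profile("A2", -up),
            _profile("cand", up + 0.001),
        ]
        res = screen_against_anchors(
            profiles, ScreenConfig(anchors=("A1", "A2"), combination_rule="any"), "D"
        )
        assert res.verdicts.loc[0, "verdict"] == "none"
        assert res.verdicts.loc[0, "reason"] == "sign_conflict"

    def test_mean_profile_rule(self):
        cfg = ScreenConfig(anchors=("A1", "A2"), combination_rule="mean_profile")
        res = screen_against_anchors(self._profiles(), cfg, "D")
        assert {rec.anchor for rec in res.records} == {"mean_anchor"}
        verdict = dict(zip(res.verdicts["protein_id"], res.verdicts["verdict"]))
        assert verdict["pos"] == "strong_positive"

    def test_missing_anchor_named_in_error(self):
        cfg = ScreenConfig(anchors=("A1", "Zbed3"))
        with pytest.raises(ValidationError, match="Zbed3"):
            screen_against_anchors(self._profiles(), cfg, "D")


class TestCorrelationReport:
    def test_rounding_and_dashes(self):
        from maternalome.screen import CorrelationRecord

        cfg = ScreenConfig(anchors=("Ooep",))
        records = [
            CorrelationRecord("PA", "Ooep", "Fbxw15", -0.86866, 0.02468, 6, "strong_negative"),
        ]
        report = correlation_report(records, cfg)
        assert report.loc[0, "Ooep_r"] == "-0.8687"
        assert report.loc[0, "Ooep_p"] == "0.0247"
        # a second protein with no record in this dataset renders dashes
        records.append(
            CorrelationRecord("PA", "Ooep", "Fbxw8", float("nan"), float("nan"), 0, "undefined")
        )
        report = correlation_report(records, cfg)
        row = report.set_index("protein_id").loc["Fbxw8"]
        assert row["Ooep_p"] == "—" and row["Ooep_r"] == "—"

    def test_round_trip_on_reference_table(self):
        cfg = ScreenConfig()
        records = fbxw_scmc_records()
        report = correlation_report(records, cfg)
        back = report_to_records(report, n=FBXW_SCMC_N_STAGES)
        key = lambda rec: (rec.protein, rec.dataset_id, rec.anchor)
        orig = {key(r): (round(r.r, 4), round(r.p, 4)) for r in records}
        parsed = {key(r): (round(r.r, 4), round(r.p, 4)) for r in back}
        assert orig == parsed

    def test_records_frame_columns(self):
        frame = records_to_frame(fbxw_scmc_records())
        assert list(frame.columns) == [
            "dataset_id", "anchor", "protein", "n", "r", "p", "strength",
        ]
        assert len(frame) == 102
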