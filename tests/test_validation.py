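"""Validation batteries: arithmetic, thresholds, and report assembly."""

import json
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import mrmquant as mq
from mrmquant.assay import PeakRecord, Role
from mrmquant.errors import (
    ConfigError,
    DesignIncompleteError,
    InsufficientReplicatesError,
    InvalidReferenceError,
    PairingError,
    UndefinedProportionError,
)
from mrmquant.validation import (
    Thresholds,
    ValidationReport,
    assess_carryover,
    assess_selectivity,
    build_validation_report,
    check_lloq,
    dilution_integrity,
    interconversion_assessment,
    matrix_effect_recovery,
    replicate_stats,
    stability_assessment,
)

from conftest import make_fit, qc_record


def blank(analyte_area, is_area=0.5, lot="lot1", analyte="X"):
    return PeakRecord(
        sample_id=f"blank-{lot}", analyte=analyte, role=Role.DOUBLE_BLANK,
        analyte_area=analyte_area, is_area=is_area, matrix_lot=lot,
    )


def lloq_recs(mean_area=100.0, n=6, analyte="X"):
    return [
        qc_record(analyte, 0.5, mean_area, is_area=1.0, i=i) for i in range(n)
    ]


def is_refs(mean_is=100.0, n=6, analyte="X"):
    return [
        PeakRecord(
            sample_id=f"isref-{i}", analyte=analyte, role=Role.BLANK_WITH_IS,
            analyte_area=0.0, is_area=mean_is,
        )
        for i in range(n)
    ]


class TestReplicateStats:
    def test_constant_replicates(self):
        st_ = replicate_stats([44.55, 44.55, 44.55], 45.0)
        assert st_.accuracy_pct == pytest.approx(99.0)
        assert st_.cv_pct == 0.0

    def test_two_point_closed_form(self):
        # mean 1.5, sd = |1.8-1.2|/sqrt(2) -> CV = sd/mean*100
        st_ = replicate_stats([1.2, 1.8], 1.5)
        assert st_.accuracy_pct == pytest.approx(100.0)
        sd = abs(1.8 - 1.2) / math.sqrt(2.0)
        assert st_.cv_pct == pytest.approx(sd / 1.5 * 100.0)

    def test_requires_two_replicates(self):
        with pytest.raises(InsufficientReplicatesError):
            replicate_stats([1.0], 1.0)

    @settings(max_examples=30, derandomize=True, deadline=None)
    @given(
        c=st.floats(min_value=1e-3, max_value=1e3),
        vals=st.lists(st.floats(min_value=0.5, max_value=2.0), min_size=2, max_size=8),
    )
    def test_scale_equivariance(self, c, vals):
        """Scaling measurements and nominal together changes nothing."""
        a = replicate_stats(vals, 1.0)
        b = replicate_stats([v * c for v in vals], c)
        assert b.accuracy_pct == pytest.approx(a.accuracy_pct, rel=1e-9)
        assert b.cv_pct == pytest.approx(a.cv_pct, rel=1e-9, abs=1e-9)


class TestSelectivity:
    def test_interference_arithmetic(self):
        res = assess_selectivity([blank(11.0)], lloq_recs(100.0), is_refs(100.0))
        assert res.per_lot_analyte_pct["lot1"] == pytest.approx(11.0)
        assert res.passed

    def test_twenty_percent_boundary_is_strict(self):
        res = assess_selectivity([blank(20.0)], lloq_recs(100.0), is_refs(100.0))
        assert res.per_lot_analyte_pct["lot1"] == pytest.approx(20.0)
        assert not res.passed

    def test_is_interference(self):
        res = assess_selectivity([blank(0.0, is_area=0.9)], lloq_recs(), is_refs(100.0))
        assert res.per_lot_is_pct["lot1"] == pytest.approx(0.9)
        assert res.passed
        res = assess_selectivity([blank(0.0, is_area=5.0)], lloq_recs(), is_refs(100.0))
        assert not res.passed  # exactly 5% fails the strict rule

    def test_needs_six_lloq_replicates(self):
        with pytest.raises(InvalidReferenceError):
            assess_selectivity([blank(1.0)], lloq_recs(n=5), is_refs())


class TestCarryover:
    def make_blank(self, analyte_area, is_area=0.1):
        return PeakRecord(
            sample_id="co", analyte="X", role=Role.CARRYOVER_BLANK,
            analyte_area=analyte_area, is_area=is_area,
        )

    def test_arithmetic_pass(self):
        res = assess_carryover(self.make_blank(6.2), 100.0, 100.0)
        assert res.analyte_pct == pytest.approx(6.2)
        assert res.passed

    def test_zero_carryover_passes(self):
        assert assess_carryover(self.make_blank(0.0), 100.0, 100.0).passed

    def test_fail_above_threshold(self):
        assert not assess_carryover(self.make_blank(25.0), 100.0, 100.0).passed

    def test_boundary_exactly_twenty_fails(self):
        assert not assess_carryover(self.make_blank(20.0), 100.0, 100.0).passed

    def test_is_carryover_boundary_exactly_five_fails(self):
        assert not assess_carryover(self.make_blank(0.0, is_area=5.0), 100.0, 100.0).passed


class TestLloqCheck:
    def test_ratio_five_passes(self):
        res = check_lloq(lloq_recs(500.0), [blank(100.0)])
        assert res.ratio == pytest.approx(5.0)
        assert res.passed  # >= is inclusive

    def test_just_below_fails(self):
        res = check_lloq(lloq_recs(499.0), [blank(100.0)])
        assert res.ratio == pytest.approx(4.99)
        assert not res.passed

    def test_clean_blank_gives_infinite_ratio(self):
        res = check_lloq(lloq_recs(500.0), [blank(0.0)])
        assert math.isinf(res.ratio)
        assert res.passed


class TestMatrixEffect:
    def _records(self, analyte_by_lot, is_by_lot, pre_scale=0.95):
        neat = [
            PeakRecord(sample_id=f"neat-{i}", analyte="X", role=Role.NEAT_SOLUTION,
                       nominal_conc=1.5, analyte_area=100.0, is_area=100.0)
            for i in range(3)
        ]
        post, pre = [], []
        for lot, a in analyte_by_lot.items():
            i = is_by_lot[lot]
            post.append(PeakRecord(sample_id=f"post-{lot}", analyte="X",
                                   role=Role.POST_EXTRACTION_SPIKED, nominal_conc=1.5,
                                   analyte_area=a, is_area=i, matrix_lot=lot))
            pre.append(PeakRecord(sample_id=f"pre-{lot}", analyte="X",
                                  role=Role.PRE_EXTRACTION_SPIKED, nominal_conc=1.5,
                                  analyte_area=a * pre_scale, is_area=i * pre_scale,
                                  matrix_lot=lot))
        return neat, post, pre

    def test_me_arithmetic(self):
        neat, post, pre = self._records({"lot1": 110.0}, {"lot1": 105.0})
        res = matrix_effect_recovery(neat, post, pre)
        assert res.per_lot_me[0] == pytest.approx(110.0)
        assert res.per_lot_is_me[0] == pytest.approx(105.0)
        assert res.is_normalised_me[0] == pytest.approx(110.0 / 105.0 * 100.0)

    def test_common_lot_factor_cancels_in_is_normalised_me(self):
        factors = {"lot1": 0.8, "lot2": 1.1, "lot3": 0.95, "lot4": 1.0, "lot5": 1.2, "lot6": 0.9}
        neat, post, pre = self._records(
            {k: 100.0 * v for k, v in factors.items()},
            {k: 100.0 * v for k, v in factors.items()},
        )
        res = matrix_effect_recovery(neat, post, pre)
        assert all(v == pytest.approx(100.0) for v in res.is_normalised_me)
        assert res.cv_pct == pytest.approx(0.0, abs=1e-9)
        assert res.passed

    def test_recovery_ratio(self):
        neat, post, pre = self._records({"lot1": 100.0}, {"lot1": 100.0}, pre_scale=0.95)
        res = matrix_effect_recovery(neat, post, pre)
        assert res.recovery_per_lot[0] == pytest.approx(95.0)

    def test_unmatched_lots_raise(self):
        neat, post, pre = self._records({"lot1": 100.0}, {"lot1": 100.0})
        pre[0] = pre[0].model_copy(update={"matrix_lot": "lot9"})
        with pytest.raises(PairingError):
            matrix_effect_recovery(neat, post, pre)


class TestStability:
    def _stressed(self, pct, nominal=1.5, n=6, high_nominal=95.0):
        fit = make_fit(a0=0.0, a1=1.0)
        recs = [
            qc_record("X", nominal, nominal * pct / 100.0, i=i, role=Role.STABILITY)
            for i in range(n)
        ] + [
            qc_record("X", high_nominal, high_nominal, i=i, role=Role.STABILITY)
            for i in range(n)
        ]
        return recs, fit

    def test_exact_nominal_passes(self):
        recs, fit = self._stressed(100.0)
        res = stability_assessment("benchtop_4h", recs, fit)
        assert res.pct_nominal["low"] == pytest.approx(100.0)
        assert res.passed

    def test_within_fifteen_percent_passes(self):
        recs, fit = self._stressed(114.3)
        assert stability_assessment("benchtop_4h", recs, fit).passed

    def test_boundary_115_inclusive(self):
        # boundary checked on the stored number itself, free of the float
        # artefacts a constructed concentration ratio would introduce
        recs, fit = self._stressed(100.0)
        res = stability_assessment("benchtop_4h", recs, fit)
        at_bound = res.model_copy(update={"pct_nominal": {"low": 115.0, "high": 85.0}})
        assert at_bound.recompute_pass(Thresholds())
        past_bound = res.model_copy(update={"pct_nominal": {"low": 115.01, "high": 100.0}})
        assert not past_bound.recompute_pass(Thresholds())

    def test_outside_window_fails(self):
        recs, fit = self._stressed(84.0)
        assert not stability_assessment("freeze_thaw_3", recs, fit).passed


class TestInterconversion:
    def test_lactone_proportion_at_bound(self):
        res = interconversion_assessment(99.7, 0.3, baseline_proportion_pct=0.0)
        assert res.lactone_proportion_pct == pytest.approx(0.3)
        assert res.within_bound  # <= 0.3 is inclusive

    def test_no_change_is_zero_conversion(self):
        res = interconversion_assessment(99.7, 0.3, baseline_proportion_pct=0.3)
        assert res.conversion_pct == pytest.approx(0.0)

    def test_lactone_to_acid_direction(self):
        # acid proportion rose from 2% to 6.5% -> 4.5 points, under the 5% bound
        res = interconversion_assessment(
            6.5, 93.5, baseline_proportion_pct=2.0, direction="lactone_to_acid"
        )
        assert res.product_proportion_pct == pytest.approx(6.5)
        assert res.conversion_pct == pytest.approx(4.5)
        assert res.within_bound

    def test_on_ice_bound_is_tighter(self):
        res = interconversion_assessment(
            6.5, 93.5, baseline_proportion_pct=2.0, direction="lactone_to_acid", on_ice=True
        )
        assert res.bound_pct == 1.5
        assert not res.within_bound

    def test_both_zero_is_undefined(self):
        with pytest.raises(UndefinedProportionError):
            interconversion_assessment(0.0, 0.0)


class TestDilutionIntegrity:
    def _records(self, measured_mean, nominal=30000.0, factor=20.0, n=6):
        fit = make_fit(a0=0.0, a1=1.0, lloq=15.0, uloq=3750.0)
        # response corresponding to measured diluted concentration
        recs = [
            qc_record("X", nominal, measured_mean / factor, i=i, role=Role.DILUTION)
            for i in range(n)
        ]
        return recs, fit

    def test_diluted_nominal_in_range(self):
        recs, fit = self._records(30000.0)
        res = dilution_integrity(recs, 20.0, fit)
        assert res.stats.accuracy_pct == pytest.approx(100.0)
        assert res.stats.cv_pct == pytest.approx(0.0, abs=1e-12)
        assert res.passed

    def test_accuracy_arithmetic(self):
        recs, fit = self._records(28920.0)  # mean 1446 after 20x dilution vs 1500
        res = dilution_integrity(recs, 20.0, fit)
        assert res.stats.accuracy_pct == pytest.approx(96.4)

    def test_out_of_range_dilution_is_design_error(self):
        recs, fit = self._records(30000.0)
        with pytest.raises(ConfigError):
            dilution_integrity(recs, 2.0, fit)  # 15000 ng/mL > ULOQ


class TestAccuracyPrecisionBattery:
    def _runs(self, spec, sim, seeds=(1, 2, 3), bias=None):
        runs, fits = {}, {}
        for k, seed in enumerate(seeds):
            rid = f"run{k + 1}"
            recs = mq.simulate_validation_run(spec, sim, seed=seed, run_id=rid)
            if bias is not None and k == bias[0]:
                level, factor = bias[1], bias[2]
                recs = [
                    r.model_copy(update={"analyte_area": r.analyte_area * factor})
                    if r.role is Role.QC and r.nominal_conc == level
                    else r
                    for r in recs
                ]
            runs[rid] = recs
            fits[rid] = mq.fit_calibration(recs, spec)
        return runs, fits

    def test_exact_replicates_all_pass(self, specs, noiseless_sim):
        spec = specs["ATV"]
        runs, fits = self._runs(spec, noiseless_sim)
        res = mq.accuracy_precision_battery(runs, fits, spec)
        for st_ in res.between_run.values():
            assert st_.accuracy_pct == pytest.approx(100.0, abs=1e-9)
            assert st_.cv_pct == pytest.approx(0.0, abs=1e-9)
        assert res.passed

    def test_five_percent_cv_passes(self, specs, default_sim):
        spec = specs["ATV"]
        runs, fits = self._runs(spec, default_sim)
        res = mq.accuracy_precision_battery(runs, fits, spec)
        assert res.passed
        assert all(st_.n == 18 for st_ in res.between_run.values())

    def test_biased_run_fails_within_run_accuracy(self, specs, noiseless_sim):
        spec = specs["ATV"]
        runs, fits = self._runs(spec, noiseless_sim, bias=(0, spec.qc_mid, 1.30))
        res = mq.accuracy_precision_battery(runs, fits, spec)
        assert not res.passed
        assert res.within_run["run1"]["medium"].accuracy_pct == pytest.approx(130.0, abs=1e-6)

    def test_missing_cells_reported(self, specs, noiseless_sim):
        spec = specs["ATV"]
        runs, fits = self._runs(spec, noiseless_sim)
        runs["run1"] = [
            r for r in runs["run1"]
            if not (r.role is Role.QC and r.nominal_conc == spec.qc_mid)
        ]
        with pytest.raises(DesignIncompleteError) as exc:
            mq.accuracy_precision_battery(runs, fits, spec)
        assert any("medium" in gap for gap in exc.value.gaps)


class TestValidationReport:
    def test_report_round_trips_through_json(self, specs, noiseless_sim):
        spec = specs["BSP"]
        runs = mq.simulate_validation_study(spec, noiseless_sim, seed=5)
        rep = mq.run_validation_battery(runs, spec)
        restored = ValidationReport.model_validate(json.loads(rep.model_dump_json()))
        assert restored == rep

    def test_flags_recomputable_from_stored_numbers(self, specs, default_sim):
        spec = specs["2-OH ATV"]
        runs = mq.simulate_validation_study(spec, default_sim, seed=6)
        rep = mq.run_validation_battery(runs, spec)
        th = rep.thresholds
        assert rep.selectivity.passed == rep.selectivity.recompute_pass(th)
        assert rep.carryover.passed == rep.carryover.recompute_pass(th)
        assert rep.lloq_check.passed == rep.lloq_check.recompute_pass(th)
        assert rep.accuracy_precision.passed == rep.accuracy_precision.recompute_pass(th)
        assert rep.matrix_effect_low.passed == rep.matrix_effect_low.recompute_pass(th)
        assert rep.dilution.passed == rep.dilution.recompute_pass(th)

    def test_failing_carryover_invalidates_report(self, specs, noiseless_sim):
        spec = specs["ATV"]
        runs = mq.simulate_validation_study(spec, noiseless_sim, seed=7)
        rep = mq.run_validation_battery(runs, spec)
        bad_carry = rep.carryover.model_copy(update={"analyte_pct": 25.0, "passed": False})
        rep_bad = rep.model_copy(update={"carryover": bad_carry})
        assert rep.validated and not rep_bad.validated

    def test_partial_report_lists_gaps(self):
        rep = build_validation_report("X")
        assert "selectivity" in rep.missing
        assert not rep.validated

    def test_text_rendering_mentions_overall_verdict(self, specs, noiseless_sim):
        spec = specs["ATV"]
        runs = mq.simulate_validation_study(spec, noiseless_sim, seed=8)
        rep = mq.run_validation_battery(runs, spec)
        text = rep.to_text()
        assert "Overall validated" in text and "True" in text
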