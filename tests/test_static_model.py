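"""Mechanistic static model: fe, [I2], screening ratios, fold-AUC, concordance."""

import math

import pytest
from hypothesis import given
from hypothesis import strategies as st

from transddi.static_model import (
    ObservedDDI,
    Perpetrator,
    VictimDisposition,
    cmax_free,
    compare_to_observed,
    concordance_range,
    derive_fe,
    fold_auc,
    i2_gut,
    predict_all,
    ratio_screen,
    round_sig,
)


class TestDeriveFe:
    @pytest.mark.parametrize(
        "renal,active,expected",
        [(0.88, 0.75, 0.66), (0.52, 0.75, 0.39), (1.0, 1.0, 1.0)],
    )
    def test_products(self, renal, active, expected):
        assert derive_fe(renal, active) == pytest.approx(expected)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            derive_fe(1.2, 0.5)


class TestCmaxFree:
    @pytest.mark.parametrize(
        "cmax,fu,expected", [(9.6, 0.80, 7.68), (2.29, 0.13, 0.2977), (5.0, 1.0, 5.0)]
    )
    def test_unbound(self, cmax, fu, expected):
        assert cmax_free(cmax, fu) == pytest.approx(expected, rel=1e-3)


class TestI2:
    @pytest.mark.parametrize(
        "dose,mw,expected",
        [(400.0, 252.34, 6341), (200.0, 290.32, 2756), (50.0, 248.71, 804), (0.0, 100.0, 0)],
    )
    def test_luminal_concentration(self, dose, mw, expected):
        assert round(i2_gut(dose, mw)) == expected

    def test_zero_mw_rejected(self):
        with pytest.raises(ValueError):
            i2_gut(100.0, 0.0)


class TestRatioScreen:
    @pytest.mark.parametrize(
        "i,ki,cutoff,ratio,flag",
        [
            (6341.0, 275.0, 10.0, 23, True),  # gut screen, integer reporting
            (7.68, 207.0, 0.1, 0.037, False),  # systemic, 2 s.f.
            (7.68, 1.22, 0.1, 6.30, True),
        ],
    )
    def test_screens(self, i, ki, cutoff, ratio, flag):
        r, f = ratio_screen(i, ki, cutoff)
        if cutoff >= 10:
            assert round(r) == ratio
        else:
            assert round_sig(r, 2 if r < 1 else 3) == pytest.approx(ratio)
        assert f is flag

    def test_intestinal_ratios_for_all_three_perpetrators(self):
        # [I2]/Ki = 23, 99, 180 from printed [I2] and OCT1 Ki values
        cases = [(6341.0, 275.0, 23), (2756.0, 27.7, 99), (804.0, 4.46, 180)]
        for i2, ki, expected in cases:
            r, flag = ratio_screen(i2, ki, 10.0)
            assert round(r) == expected
            assert flag

    def test_nonpositive_ki_rejected(self):
        with pytest.raises(ValueError):
            ratio_screen(1.0, 0.0, 0.1)


class TestFoldAuc:
    @pytest.mark.parametrize(
        "fe,i,ki,expected",
        [
            (0.66, 7.68, 1.22, 2.32),
            (0.39, 0.298, 0.131, 1.37),
            (0.5, 0.0, 1.0, 1.00),
        ],
    )
    def test_printed_values(self, fe, i, ki, expected):
        assert round(fold_auc(fe, i, ki), 2) == pytest.approx(expected)

    def test_no_pathway_identity(self):
        assert fold_auc(0.0, 100.0, 1.0) == 1.0

    def test_saturation_limit(self):
        fe = 0.66
        assert fold_auc(fe, 1e12, 1.0) == pytest.approx(1.0 / (1.0 - fe), rel=1e-6)

    @given(
        fe=st.floats(0.0, 0.95),
        i1=st.floats(0.0, 1e3),
        i2=st.floats(0.0, 1e3),
        ki=st.floats(1e-3, 1e3),
    )
    def test_monotone_in_inhibitor_and_bounded(self, fe, i1, i2, ki):
        lo, hi = sorted([i1, i2])
        f_lo, f_hi = fold_auc(fe, lo, ki), fold_auc(fe, hi, ki)
        assert 1.0 <= f_lo <= f_hi <= 1.0 / (1.0 - fe) + 1e-9

    @given(fe1=st.floats(0.0, 0.9), fe2=st.floats(0.0, 0.9))
    def test_monotone_in_fe(self, fe1, fe2):
        lo, hi = sorted([fe1, fe2])
        assert fold_auc(lo, 5.0, 1.0) <= fold_auc(hi, 5.0, 1.0) + 1e-12

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            fold_auc(1.5, 1.0, 1.0)
        with pytest.raises(ValueError):
            fold_auc(0.5, 1.0, 0.0)


class TestPredictAll:
    def test_full_grid_reproduces_published_predictions(self, ddi_inputs):
        pset = predict_all(
            ddi_inputs.perpetrators, ddi_inputs.ki_table, ddi_inputs.dispositions
        )
        by_key = {
            (p.perpetrator, p.transporter, p.cmax_total, p.fe_used): p.fold_auc_reported
            for p in pset.predictions
        }
        # MATE1, fe=0.66 then fe=0.39
        expected = {
            ("cimetidine", "MATE1", 9.6, 0.66): 2.32,
            ("cimetidine", "MATE1", 5.1, 0.66): 2.03,
            ("trimethoprim", "MATE1", 14.0, 0.66): 1.98,
            ("trimethoprim", "MATE1", 7.6, 0.66): 1.69,
            ("pyrimethamine", "MATE1", 2.29, 0.66): 1.85,
            ("cimetidine", "MATE1", 9.6, 0.39): 1.51,
            ("cimetidine", "MATE1", 5.1, 0.39): 1.43,
            ("trimethoprim", "MATE1", 14.0, 0.39): 1.41,
            ("trimethoprim", "MATE1", 7.6, 0.39): 1.32,
            ("pyrimethamine", "MATE1", 2.29, 0.39): 1.37,
            # OCT2 grid
            ("cimetidine", "OCT2", 9.6, 0.66): 1.02,
            ("cimetidine", "OCT2", 5.1, 0.66): 1.01,
            ("trimethoprim", "OCT2", 14.0, 0.66): 1.04,
            ("trimethoprim", "OCT2", 7.6, 0.66): 1.02,
            ("pyrimethamine", "OCT2", 2.29, 0.66): 1.04,
            ("cimetidine", "OCT2", 9.6, 0.39): 1.01,
            ("cimetidine", "OCT2", 5.1, 0.39): 1.01,
            ("trimethoprim", "OCT2", 14.0, 0.39): 1.02,
            ("trimethoprim", "OCT2", 7.6, 0.39): 1.01,
            ("pyrimethamine", "OCT2", 2.29, 0.39): 1.02,
        }
        for key, value in expected.items():
            assert by_key[key] == pytest.approx(value), key

    def test_screening_flags_match_transporter_roles(self, ddi_inputs):
        pset = predict_all(
            ddi_inputs.perpetrators, ddi_inputs.ki_table, ddi_inputs.dispositions
        )
        for p in pset.predictions:
            if p.transporter == "OCT2":
                assert p.ratio_systemic < 0.1 and not p.flag_systemic
            if p.transporter == "MATE1":
                assert p.ratio_systemic >= 0.1 and p.flag_systemic

    def test_missing_ki_produces_error_not_crash(self, ddi_inputs):
        pset = predict_all(
            ddi_inputs.perpetrators,
            ddi_inputs.ki_table,
            ddi_inputs.dispositions,
            transporters=("MATE2-K",),
        )
        assert any("pyrimethamine" in e for e in pset.errors)
        assert any(p.perpetrator == "cimetidine" for p in pset.predictions)

    def test_empty_perpetrators_empty_set(self, ddi_inputs):
        pset = predict_all([], ddi_inputs.ki_table, ddi_inputs.dispositions)
        assert pset.predictions == []


class TestConcordance:
    def test_single_pair_deltas(self, ddi_inputs):
        pset = predict_all(
            ddi_inputs.perpetrators, ddi_inputs.ki_table, ddi_inputs.dispositions
        )
        mate1 = [p for p in pset.predictions if p.transporter == "MATE1"]
        comp = compare_to_observed(mate1, ddi_inputs.observed)
        row = comp[
            (comp.perpetrator == "cimetidine") & (comp.cmax_total == 9.6) & (comp.fe == 0.66)
        ].iloc[0]
        assert row["delta"] == pytest.approx(86.0)  # |132 - 46|
        row = comp[
            (comp.perpetrator == "cimetidine") & (comp.cmax_total == 5.1) & (comp.fe == 0.39)
        ].iloc[0]
        assert row["delta"] == pytest.approx(11.0)  # |43 - 54|

    def test_identical_prediction_zero_delta(self):
        from transddi.static_model import StaticPrediction

        p = StaticPrediction(
            perpetrator="x", transporter="MATE1", ki=1.0, cmax_total=1.0,
            i_unbound=1.0, ratio_systemic=1.0, flag_systemic=True,
            fe_used=0.66, route_label="iv", fold_auc=1.46,
        )
        obs = [ObservedDDI(perpetrator="x", cmax_total=1.0, observed_fold_auc=1.46)]
        comp = compare_to_observed([p], obs)
        assert comp["delta"].iloc[0] == pytest.approx(0.0)

    def test_unmatched_prediction_flagged_and_excluded(self, ddi_inputs):
        pset = predict_all(
            ddi_inputs.perpetrators, ddi_inputs.ki_table, ddi_inputs.dispositions
        )
        oct2 = [p for p in pset.predictions if p.transporter == "OCT2"]
        comp = compare_to_observed(oct2, [])
        assert not comp["matched"].any()
        assert concordance_range(comp) == {}

    def test_alternate_metric_available(self, ddi_inputs):
        pset = predict_all(
            ddi_inputs.perpetrators, ddi_inputs.ki_table, ddi_inputs.dispositions
        )
        mate1 = [p for p in pset.predictions if p.transporter == "MATE1"]
        comp = compare_to_observed(mate1, ddi_inputs.observed, metric="relative_fold_error")
        assert (comp.loc[comp["matched"], "delta"] >= 0).all()


class TestDomainTypes:
    def test_perpetrator_validation(self):
        with pytest.raises(ValueError):
            Perpetrator(name="x", dose_mg=100.0, mw=100.0, fu=0.0, cmax_total=(1.0,))
        with pytest.raises(ValueError):
            Perpetrator(name="x", dose_mg=100.0, mw=-1.0, fu=0.5, cmax_total=(1.0,))

    def test_disposition_derives_fe(self):
        d = VictimDisposition(
            renal_fraction_of_total_clearance=0.88,
            active_fraction_of_renal_clearance=0.75,
            route_label="iv",
        )
        assert d.fe == pytest.approx(0.66)
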