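"""Michaelis-Menten and logistic fitting, Cheng-Prusoff, occasion pooling."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from transddi.kinetics import (
    FitError,
    InhibitionResult,
    aggregate_occasions,
    cheng_prusoff_ki,
    fit_inhibition_from_wells,
    fit_logistic,
    fit_michaelis_menten,
    percent_control,
)
from transddi.synthetic import (
    AssayTruth,
    InhibitionTruth,
    gen_inhibition_plate,
    logistic_percent,
)


def mm(s, vmax, km):
    return vmax * s / (km + s)


class TestMichaelisMenten:
    CONCS = np.array([10.0, 30.0, 100.0, 300.0, 1000.0, 3000.0, 10_000.0])

    @pytest.mark.parametrize("km,vmax", [(1608.0, 32918.0), (5422.0, 9370.0), (4565.0, 141000.0)])
    def test_noiseless_recovery(self, km, vmax):
        fit = fit_michaelis_menten(self.CONCS, mm(self.CONCS, vmax, km))
        assert fit.km == pytest.approx(km, rel=1e-3)
        assert fit.vmax == pytest.approx(vmax, rel=1e-3)

    def test_half_saturation_on_fitted_curve(self):
        fit = fit_michaelis_menten(self.CONCS, mm(self.CONCS, 32918.0, 1608.0))
        assert fit.rate(fit.km) == pytest.approx(fit.vmax / 2.0)

    def test_saturating_only_design_flagged(self):
        s = np.array([50_000.0, 80_000.0, 100_000.0, 200_000.0])
        v = np.full_like(s, 1000.0)  # flat at Vmax
        fit = fit_michaelis_menten(s, v)
        assert any("unidentifiable" in w or "bracket" in w for w in fit.warnings)

    def test_few_concentrations_warn(self):
        s = np.array([100.0, 1000.0, 10_000.0])
        fit = fit_michaelis_menten(s, mm(s, 100.0, 500.0))
        assert any("fewer than 4" in w for w in fit.warnings)

    def test_reports_standard_errors_under_noise(self):
        rng = np.random.default_rng(0)
        v = mm(self.CONCS, 32918.0, 1608.0) * rng.lognormal(0, 0.05, self.CONCS.size)
        fit = fit_michaelis_menten(self.CONCS, v)
        assert fit.km_se > 0 and fit.vmax_se > 0


class TestPercentControl:
    @pytest.mark.parametrize("inhibited,vehicle,expected", [(5.0, 5.0, 100.0), (0.0, 5.0, 0.0), (2.5, 5.0, 50.0)])
    def test_identities(self, inhibited, vehicle, expected):
        assert percent_control(inhibited, vehicle) == pytest.approx(expected)

    def test_nonpositive_vehicle_rejected(self):
        with pytest.raises(ValueError):
            percent_control(1.0, 0.0)


class TestLogisticFit:
    CONCS = np.array([0.01, 0.03, 0.1, 0.3, 1.0, 3.0, 10.0, 30.0, 100.0])

    @pytest.mark.parametrize("ic50", [0.131, 1.22, 27.7])
    def test_noiseless_4pl_recovery(self, ic50):
        scale = ic50 / 1.22  # center the series on the truth
        x = self.CONCS * scale
        y = np.array([logistic_percent(c, InhibitionTruth(ic50_true=ic50)) for c in x])
        res = fit_logistic(x, y, model="4PL")
        assert res.ic50 == pytest.approx(ic50, rel=1e-3)

    def test_symmetric_xmid_equals_ic50(self):
        y = np.array([logistic_percent(c, InhibitionTruth(ic50_true=1.0)) for c in self.CONCS])
        res = fit_logistic(self.CONCS, y, model="4PL")
        assert res.asymmetry == 1.0
        assert res.ic50 == pytest.approx(1.0, rel=1e-3)

    def test_5pl_ic50_from_curve_not_xmid(self):
        truth = InhibitionTruth(ic50_true=1.0, hill_true=1.0, asymmetry_true=2.0)
        y = np.array([logistic_percent(c, truth) for c in self.CONCS])
        res = fit_logistic(self.CONCS, y, model="5PL")
        # the asymmetric curve's inflection is not the half-inhibition point
        assert res.ic50 == pytest.approx(1.0, rel=1e-2)

    def test_flat_response_censored(self):
        y = np.full(self.CONCS.size, 100.0)
        res = fit_logistic(self.CONCS, y)
        assert res.ic50 is None
        assert res.censored_above == pytest.approx(100.0)

    def test_unit_rescaling_invariance(self):
        y = np.array([logistic_percent(c, InhibitionTruth(ic50_true=1.0)) for c in self.CONCS])
        res_umol = fit_logistic(self.CONCS, y, model="4PL")
        res_nmol = fit_logistic(self.CONCS * 1000.0, y, model="4PL")
        assert res_nmol.ic50 == pytest.approx(res_umol.ic50 * 1000.0, rel=1e-6)

    def test_grid_search_oracle_agreement(self):
        # brute-force (ic50, hill) grid on a 3-concentration toy set must agree
        # with the least-squares optimum to grid resolution
        x = np.array([0.3, 1.0, 3.0])
        y = np.array([75.0, 52.0, 30.0])
        ic50_grid = np.linspace(0.5, 2.0, 301)
        hill_grid = np.linspace(0.3, 3.0, 271)
        best, best_sse = None, np.inf
        for ic in ic50_grid:
            for h in hill_grid:
                pred = 100.0 / (1.0 + (x / ic) ** h)
                sse = float(np.sum((pred - y) ** 2))
                if sse < best_sse:
                    best, best_sse = (ic, h), sse
        res = fit_logistic(
            x, y, model="4PL", bounds={"bottom": (-1e-9, 1e-9), "top": (100.0 - 1e-9, 100.0 + 1e-9)}
        )
        assert res.ic50 == pytest.approx(best[0], abs=(ic50_grid[1] - ic50_grid[0]) * 2)
        assert res.hill == pytest.approx(best[1], abs=(hill_grid[1] - hill_grid[0]) * 2)

    def test_vehicle_anchors_top_off_log_axis(self):
        x = np.concatenate([[0.0], self.CONCS])
        y = np.concatenate(
            [[100.0], [logistic_percent(c, InhibitionTruth(ic50_true=1.0)) for c in self.CONCS]]
        )
        res = fit_logistic(x, y, model="4PL")
        assert res.ic50 == pytest.approx(1.0, rel=1e-3)


class TestChengPrusoff:
    def test_mate1_probe_correction_is_negligible(self):
        # S=100 far below Km=4565: Ki = 1.22/1.0219 = 1.194, condition satisfied
        cp = cheng_prusoff_ki(1.22, 100.0, 4565.0)
        assert cp.ki == pytest.approx(1.22 / (1 + 100.0 / 4565.0))
        assert cp.ic50_equals_ki

    @pytest.mark.parametrize("s,expected_frac", [(0.0, 1.0), (1608.0, 0.5)])
    def test_limits(self, s, expected_frac):
        cp = cheng_prusoff_ki(10.0, s, 1608.0)
        assert cp.ki == pytest.approx(10.0 * expected_frac)

    @given(s1=st.floats(0.0, 1e4), s2=st.floats(0.0, 1e4))
    def test_monotone_decreasing_in_probe_conc(self, s1, s2):
        lo, hi = sorted([s1, s2])
        k_lo = cheng_prusoff_ki(5.0, lo, 1000.0).ki
        k_hi = cheng_prusoff_ki(5.0, hi, 1000.0).ki
        assert k_hi <= k_lo <= 5.0

    def test_rejects_bad_km(self):
        with pytest.raises(ValueError):
            cheng_prusoff_ki(1.0, 10.0, 0.0)


class TestOccasions:
    def _res(self, ic50, **kw):
        base = dict(
            inhibitor="cimetidine", transporter="MATE1", model="4PL",
            hill=1.0, bottom=0.0, top=100.0, asymmetry=1.0,
        )
        base.update(kw)
        return InhibitionResult(ic50=ic50, **base)

    def test_mean_and_sd(self):
        agg = aggregate_occasions([self._res(1.0), self._res(1.2), self._res(1.4)])
        assert agg.ic50_mean == pytest.approx(1.2)
        assert agg.ic50_sd == pytest.approx(0.2)

    def test_single_occasion_sd_none(self):
        agg = aggregate_occasions([self._res(1.0)])
        assert agg.ic50_sd is None

    def test_mixed_conditions_rejected(self):
        with pytest.raises(ValueError, match="mixed"):
            aggregate_occasions([self._res(1.0), self._res(1.0, transporter="OCT2")])

    def test_three_noiseless_occasions_sd_zero(self, sa22):
        assay = AssayTruth(
            transporter="MATE1", km_true=4565.0, vmax_true=141_000.0, protein_cv=0.0
        )
        inh = InhibitionTruth(ic50_true=1.22, occasions=3)
        wells = gen_inhibition_plate(
            assay, inh, "cimetidine",
            [0.1, 0.3, 1.0, 3.0, 10.0, 30.0, 100.0], probe_conc=100.0, time=1.5,
        )
        res = fit_inhibition_from_wells(wells, sa22, km=4565.0)
        assert len(res.per_occasion_ic50s) == 3
        assert res.ic50_sd == pytest.approx(0.0, abs=1e-6)
        assert res.ic50_mean == pytest.approx(1.22, rel=1e-3)
        assert res.ki == pytest.approx(1.22 / (1 + 100.0 / 4565.0), rel=1e-3)
        assert res.ic50_equals_ki


class TestEndToEndInhibition:
    def test_noiseless_plate_recovers_printed_ic50(self, sa22):
        # generating IC50 0.131 (pyrimethamine vs MATE1) recovered to <=0.1%
        assay = AssayTruth(
            transporter="MATE1", km_true=4565.0, vmax_true=141_000.0, protein_cv=0.0
        )
        inh = InhibitionTruth(ic50_true=0.131)
        wells = gen_inhibition_plate(
            assay, inh, "pyrimethamine",
            [0.003, 0.01, 0.03, 0.1, 0.3, 1.0], probe_conc=100.0, time=1.5,
        )
        res = fit_inhibition_from_wells(wells, sa22)
        assert res.ic50 == pytest.approx(0.131, rel=1e-3)
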