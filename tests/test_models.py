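import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.optimize import brentq

import thermosol as ts
from thermosol import refdata
from thermosol.synthetic import GeneratorSpec, generate_mixture_grid, generate_temperature_series

from conftest import STUDY_TEMPERATURES, vanthoff_series


def bkm_root_oracle(lam, h, Tm, T):
    """Independent oracle: solve the implicit λh relation numerically."""
    rhs = lam * h * (1.0 / T - 1.0 / Tm)

    def f(x):
        return np.log1p(lam * (1.0 - x) / x) - rhs

    return brentq(f, 1e-300, 1.0, xtol=1e-300, rtol=1e-15)


# ---------------------------------------------------------------------------
# evaluation
# ---------------------------------------------------------------------------


class TestEval:
    def test_apelblat_with_zero_C_matches_vanthoff_everywhere(self):
        ap = ts.ApelblatParams(A=-2.5, B=-3000.0, C=0.0)
        vh = ts.VantHoffParams(a=-2.5, b=-3000.0)
        T = np.linspace(250, 400, 31)
        np.testing.assert_allclose(
            ts.eval_apelblat(ap, T), ts.eval_vanthoff(vh, T), rtol=1e-15
        )

    def test_apelblat_water_reproduces_published_solubility(self):
        # published Apelblat parameters for ABN401 in water; the reported
        # lowest solubility is 2.8e-6 at 298.15 K (2 s.f.)
        ap = refdata.apelblat_params("water")
        x = np.exp(ts.eval_apelblat(ap, 298.15))
        assert f"{x:.1e}" == "2.8e-06"

    def test_apelblat_transcutol_high_precision_value(self):
        # frozen from 50-digit evaluation of A + B/T + C ln T
        ap = refdata.apelblat_params("transcutol HP")
        assert ts.eval_apelblat(ap, 308.15) == pytest.approx(
            -5.8181864100778275, abs=1e-12
        )

    def test_vanthoff_water_reproduces_published_solubility(self, water_vanthoff):
        x = np.exp(ts.eval_vanthoff(water_vanthoff, 298.15))
        assert f"{x:.1e}" == "2.8e-06"

    def test_vanthoff_zero_slope_is_temperature_independent(self):
        p = ts.VantHoffParams(a=-4.2, b=0.0)
        assert ts.eval_vanthoff(p, 250.0) == ts.eval_vanthoff(p, 400.0) == -4.2

    def test_vanthoff_transcutol_hand_arithmetic(self):
        p = refdata.vanthoff_params("transcutol HP")
        assert ts.eval_vanthoff(p, 298.15) == pytest.approx(
            3.92 - 3010.37 / 298.15, rel=1e-14
        )

    def test_bkm_melting_point_limit_is_unity(self):
        p = ts.BKMParams(lam=0.02, h=5e4, Tm=413.09)
        assert ts.eval_bkm(p, 413.09) == pytest.approx(1.0, abs=1e-14)

    def test_bkm_water_matches_root_finder_oracle(self):
        p = refdata.bkm_params("water")
        x = ts.eval_bkm(p, 298.15)
        assert x == pytest.approx(bkm_root_oracle(p.lam, p.h, p.Tm, 298.15), rel=1e-10)
        assert x == pytest.approx(3.41e-6, rel=5e-3)

    def test_bkm_rejects_temperatures_above_melting(self):
        p = refdata.bkm_params("water")
        with pytest.raises(ts.OutOfDomainError):
            ts.eval_bkm(p, 450.0)

    @given(
        lam=st.floats(min_value=1e-4, max_value=1.0),
        lam_h=st.floats(min_value=1e2, max_value=1e4),
        Tm=st.floats(min_value=350.0, max_value=500.0),
        frac=st.floats(min_value=0.5, max_value=1.0),
    )
    @settings(max_examples=200, deadline=None)
    def test_bkm_inversion_satisfies_defining_identity(self, lam, lam_h, Tm, frac):
        T = frac * Tm
        p = ts.BKMParams(lam=lam, h=lam_h / lam, Tm=Tm)
        x = ts.eval_bkm(p, T)
        resid = np.log1p(lam * (1.0 - x) / x) - lam_h * (1.0 / T - 1.0 / Tm)
        assert abs(resid) < 1e-10

    def test_yalkowsky_endpoint_identity_and_golden_cells(self):
        lnx1, lnx2 = refdata.yalkowsky_endpoints()[298.15]
        assert ts.eval_yalkowsky(lnx1, lnx2, 0.0) == lnx1
        assert round(ts.eval_yalkowsky(lnx1, lnx2, 0.2), 2) == -11.46
        l1, l2 = refdata.yalkowsky_endpoints()[318.15]
        assert round(ts.eval_yalkowsky(l1, l2, 0.3), 2) == -10.16

    @given(
        lnx1=st.floats(min_value=-20, max_value=0),
        lnx2=st.floats(min_value=-20, max_value=0),
        w=st.floats(min_value=0, max_value=1),
    )
    @settings(max_examples=100, deadline=None)
    def test_yalkowsky_is_affine_in_composition(self, lnx1, lnx2, w):
        mid = ts.eval_yalkowsky(lnx1, lnx2, 0.5 * w)
        mean = 0.5 * (ts.eval_yalkowsky(lnx1, lnx2, 0.0) + ts.eval_yalkowsky(lnx1, lnx2, w))
        assert mid == pytest.approx(mean, abs=1e-12)

    def test_eval_rejects_nonphysical_inputs(self):
        with pytest.raises(ts.InvalidInputError):
            ts.eval_vanthoff(ts.VantHoffParams(a=0, b=0), -1.0)
        with pytest.raises(ts.InvalidInputError):
            ts.eval_yalkowsky(-1.0, -2.0, 1.5)


# ---------------------------------------------------------------------------
# fit metrics
# ---------------------------------------------------------------------------


class TestMetrics:
    def test_mrd_is_zero_for_perfect_fit(self):
        assert ts.mrd([1e-5, 2e-5], [1e-5, 2e-5]) == 0.0

    def test_mrd_signed_deviations_cancel(self):
        assert ts.mrd([2.0, 2.0], [1.0, 3.0]) == pytest.approx(0.0, abs=1e-12)
        assert ts.mrd_abs([2.0, 2.0], [1.0, 3.0]) == pytest.approx(50.0)

    def test_mrd_hand_arithmetic(self):
        val = ts.mrd([1.0, 2.0, 4.0], [1.1, 1.8, 4.4])
        assert val == pytest.approx(100.0 / 3.0 * (-0.1 + 0.1 - 0.1), rel=1e-12)

    def test_rmsd_hand_arithmetic_and_single_pair(self):
        assert ts.rmsd([0.0, 0.0], [3.0, 4.0]) == pytest.approx(5.0 / np.sqrt(2))
        assert ts.rmsd([0.3], [0.7]) == pytest.approx(0.4)

    def test_metric_input_validation(self):
        with pytest.raises(ts.InvalidInputError):
            ts.mrd([1.0, 2.0], [1.0])
        with pytest.raises(ts.InvalidInputError):
            ts.rmsd([], [])
        with pytest.raises(ts.InvalidInputError):
            ts.mrd([0.0, 1.0], [1.0, 1.0])


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------


class TestFitVantHoff:
    def test_noiseless_recovery_is_exact(self, water_vanthoff):
        series = vanthoff_series(water_vanthoff)
        fit, quality = ts.fit_vanthoff(series)
        assert fit.a == pytest.approx(water_vanthoff.a, rel=1e-10)
        assert fit.b == pytest.approx(water_vanthoff.b, rel=1e-10)
        assert quality.rmsd == pytest.approx(0.0, abs=1e-15)

    def test_two_points_rejected(self, water_vanthoff):
        series = vanthoff_series(water_vanthoff, temps=np.array([298.15, 308.15]))
        with pytest.raises(ts.InsufficientDataError):
            ts.fit_vanthoff(series)

    def test_seeded_noisy_slope_recovery(self, water_vanthoff):
        spec = GeneratorSpec(model="vanthoff", params=water_vanthoff,
                             noise_cv=0.02, seed=7)
        fit, _ = ts.fit_vanthoff(generate_temperature_series(spec))
        assert fit.b == pytest.approx(water_vanthoff.b, rel=0.10)


class TestFitApelblat:
    @pytest.mark.parametrize("solvent", ["water", "ethanol", "transcutol HP"])
    def test_noiseless_recovery(self, solvent):
        ap = refdata.apelblat_params(solvent)
        x = np.exp(ts.eval_apelblat(ap, STUDY_TEMPERATURES))
        fit, quality = ts.fit_apelblat(
            ts.TemperatureSeries(solvent, STUDY_TEMPERATURES, x)
        )
        for got, want in zip(dataclasses.astuple(fit), dataclasses.astuple(ap)):
            assert got == pytest.approx(want, rel=1e-6)
        assert quality.rmsd < 1e-12

    def test_nested_vanthoff_data_gives_zero_C(self, water_vanthoff):
        fit, quality = ts.fit_apelblat(vanthoff_series(water_vanthoff))
        assert abs(fit.C) < 1e-6
        assert quality.rmsd == pytest.approx(0.0, abs=1e-12)

    def test_noisy_predictions_track_generating_curve(self):
        ap = refdata.apelblat_params("water")
        spec = GeneratorSpec(model="apelblat", params=ap, noise_cv=0.01, seed=42)
        fit, _ = ts.fit_apelblat(generate_temperature_series(spec))
        pred = np.exp(ts.eval_apelblat(fit, STUDY_TEMPERATURES))
        true = np.exp(ts.eval_apelblat(ap, STUDY_TEMPERATURES))
        assert np.max(np.abs(pred / true - 1.0)) < 0.03

    def test_too_few_points_rejected(self, water_vanthoff):
        series = vanthoff_series(water_vanthoff, temps=STUDY_TEMPERATURES[:3])
        with pytest.raises(ts.InsufficientDataError):
            ts.fit_apelblat(series)

    def test_linear_objective_also_interpolates_noiseless_data(self):
        ap = refdata.apelblat_params("ethanol")
        x = np.exp(ts.eval_apelblat(ap, STUDY_TEMPERATURES))
        fit, quality = ts.fit_apelblat(
            ts.TemperatureSeries("ethanol", STUDY_TEMPERATURES, x),
            objective="linear",
        )
        assert quality.rmsd < 1e-12


class TestFitBKM:
    @pytest.mark.parametrize("solvent", ["water", "acetonitrile", "transcutol HP"])
    def test_noiseless_recovery(self, solvent):
        p = refdata.bkm_params(solvent)
        x = np.asarray(ts.eval_bkm(p, STUDY_TEMPERATURES))
        fit, quality = ts.fit_bkm(
            ts.TemperatureSeries(solvent, STUDY_TEMPERATURES, x), Tm=p.Tm
        )
        assert fit.lam == pytest.approx(p.lam, rel=1e-4)
        assert fit.h == pytest.approx(p.h, rel=1e-4)

    def test_small_lambda_limit_matches_vanthoff_slope(self):
        # in the λ→0 regime ln x ≈ ln λ − λh(1/T − 1/Tm), so λh ≈ −b; the
        # expansion is valid when exp(−b(1/T−1/Tm)) >> 1, hence the
        # steep-slope ethanol parameters
        vh = refdata.vanthoff_params("ethanol")
        fit, _ = ts.fit_bkm(vanthoff_series(vh), Tm=413.09)
        assert fit.lam * fit.h == pytest.approx(-vh.b, rel=0.05)

    def test_contract_errors(self, water_vanthoff):
        short = vanthoff_series(water_vanthoff, temps=np.array([298.15, 308.15]))
        with pytest.raises(ts.InsufficientDataError):
            ts.fit_bkm(short, Tm=413.09)
        full = vanthoff_series(water_vanthoff)
        with pytest.raises(ts.InvalidInputError):
            ts.fit_bkm(full, Tm=310.0)  # Tm below the data range


class TestFitJAVH:
    def test_noiseless_recovery_is_exact(self):
        params = refdata.javh_params()
        grid = generate_mixture_grid(
            GeneratorSpec(model="javh", params=params, noise_cv=0.0, seed=0)
        )
        fit, quality = ts.fit_javh(grid)
        for got, want in zip(dataclasses.astuple(fit), dataclasses.astuple(params)):
            assert got == pytest.approx(want, rel=1e-8)
        assert quality.rmsd == pytest.approx(0.0, abs=1e-12)

    def test_zero_interaction_reduces_to_pure_vanthoff_curves(self):
        params = ts.JAVHParams(alpha1=-2.72, alpha2=-2997.05,
                               alpha3=3.92, alpha4=-3010.37,
                               J0=0.0, J1=0.0, J2=0.0)
        T = STUDY_TEMPERATURES
        np.testing.assert_allclose(
            ts.eval_javh(params, 0.0, T),
            ts.eval_vanthoff(ts.VantHoffParams(-2.72, -2997.05), T), rtol=1e-14)
        np.testing.assert_allclose(
            ts.eval_javh(params, 1.0, T),
            ts.eval_vanthoff(ts.VantHoffParams(3.92, -3010.37), T), rtol=1e-14)

    def test_noisy_grid_refit_deviation_is_small(self):
        grid = generate_mixture_grid(
            GeneratorSpec(model="javh", params=refdata.javh_params(),
                          noise_cv=0.03, seed=3)
        )
        _, quality = ts.fit_javh(grid)
        assert quality.mrd_abs_percent <= 10.0

    def test_sparse_grid_rejected(self):
        grid = generate_mixture_grid(
            GeneratorSpec(model="javh", params=refdata.javh_params(),
                          noise_cv=0.0, seed=0, compositions=(0.0, 1.0))
        )
        with pytest.raises(ts.InsufficientDataError):
            ts.fit_javh(grid)


class TestNesting:
    @given(a=st.floats(min_value=-6, max_value=2),
           b=st.floats(min_value=-6000, max_value=-500),
           seed=st.integers(min_value=0, max_value=2**20))
    @settings(max_examples=25, deadline=None)
    def test_apelblat_never_fits_worse_than_nested_vanthoff(self, a, b, seed):
        # both models minimise residuals in ln x, and the van't Hoff line is
        # the C = 0 special case of the Apelblat form, so the Apelblat
        # residual norm in the objective space can never be larger
        params = ts.VantHoffParams(a=a, b=b)
        spec = GeneratorSpec(model="vanthoff", params=params, noise_cv=0.02,
                             seed=seed)
        series = generate_temperature_series(spec)
        fit_ap, _ = ts.fit_apelblat(series)
        fit_vh, _ = ts.fit_vanthoff(series)
        lnx = np.log(series.x)
        sse_ap = np.sum((ts.eval_apelblat(fit_ap, series.temperatures) - lnx) ** 2)
        sse_vh = np.sum((ts.eval_vanthoff(fit_vh, series.temperatures) - lnx) ** 2)
        assert sse_ap <= sse_vh * (1 + 1e-9) + 1e-15


# ---------------------------------------------------------------------------
# anti-solvent design
# ---------------------------------------------------------------------------


class TestAntisolventDesign:
    def test_matches_brute_force_enumeration(self):
        params = refdata.javh_params()
        grid = np.round(np.arange(0.0, 1.01, 0.1), 10)
        lnx = {w: ts.eval_javh(params, w, 298.15) for w in grid if w <= 0.2}
        expected_w2 = min(sorted(lnx), key=lambda w: lnx[w])
        w2_star, x_pred = ts.select_antisolvent_composition(params, 298.15, 0.2)
        assert w2_star == pytest.approx(expected_w2)
        assert x_pred == pytest.approx(np.exp(lnx[expected_w2]), rel=1e-12)

    def test_monotone_surface_selects_smallest_feasible_point(self):
        # zero interaction and increasing ln x in w2 -> smallest grid point
        params = ts.JAVHParams(-12.0, 0.0, -6.0, 0.0, 0.0, 0.0, 0.0)
        w2_star, _ = ts.select_antisolvent_composition(params, 298.15, 0.2)
        assert w2_star == 0.0

    def test_unit_cap_returns_global_argmin(self):
        params = refdata.javh_params()
        grid = np.round(np.arange(0.0, 1.01, 0.1), 10)
        lnx = {w: ts.eval_javh(params, w, 298.15) for w in grid}
        expected = min(sorted(lnx), key=lambda w: lnx[w])
        w2_star, _ = ts.select_antisolvent_composition(params, 298.15, 1.0)
        assert w2_star == pytest.approx(expected)

    def test_empty_feasible_grid_rejected(self):
        params = refdata.javh_params()
        with pytest.raises(ts.InvalidInputError):
            ts.select_antisolvent_composition(
                params, 298.15, 0.05, grid=np.array([0.1, 0.2, 0.5])
            )


def test_series_container_invariants():
    with pytest.raises(ts.InvalidInputError):
        ts.TemperatureSeries("bad", np.array([300.0, 299.0, 310.0]),
                             np.array([1e-4, 1e-4, 1e-4]))
    with pytest.raises(ts.InvalidInputError):
        ts.TemperatureSeries("bad", np.array([298.0, 308.0]), np.array([0.0, 1e-4]))
    with pytest.raises(ts.InvalidInputError):
        ts.MixtureGrid(np.array([0.5, 1.2]), np.array([298.0, 298.0]),
                       np.array([1e-4, 1e-4]))
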