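"""Closed-form kinetics vs the ODE oracle, limits, and conservation laws."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lgesim.kinetics import (ExponentialMixture, assemble_curves, body_rates,
                             body_ees_curve, catenary_curves, diffusion_length,
                             diffusion_time, myocardial_ees_curve, ode_oracle,
                             plasma_curve, renal_cleared)
from lgesim.params import (CatenaryParams, ScenarioPreset, TissueParams,
                           load_preset)

from conftest import ALL_PRESETS


class TestExponentialMixture:
    def test_value_at_zero_is_amplitude_sum(self):
        mix = ExponentialMixture((1.5, -0.5, 2.0), (0.1, 0.2, 0.3))
        assert mix(0.0) == pytest.approx(3.0)
        assert mix.at0() == pytest.approx(3.0)

    def test_running_integral_matches_trapezoid(self):
        mix = ExponentialMixture((1.0, 0.5), (0.3, 0.01))
        t = np.linspace(0, 40, 4001)
        numeric = np.trapezoid(mix(t), t)
        assert mix.integral(40.0) == pytest.approx(numeric, rel=1e-6)

    def test_confluent_term_integral(self):
        mix = ExponentialMixture((2.0,), (0.5,), (1,))  # 2 t exp(-t/2)
        t = np.linspace(0, 30, 3001)
        assert mix.integral(30.0) == pytest.approx(
            np.trapezoid(mix(t), t), rel=1e-5)


class TestBodyRates:
    def test_approximate_rates_table2(self, normal):
        m1, m2 = body_rates(normal.body, "approximate")
        assert m1 == pytest.approx(0.306, abs=5e-4)
        assert m2 == pytest.approx(0.0087, abs=5e-5)

    def test_exact_rates_are_characteristic_roots(self, normal):
        m1, m2 = body_rates(normal.body, "exact")
        # roots of lambda^2 + 0.3284 lambda + 0.00266 = 0
        assert m1 == pytest.approx(0.320, abs=5e-4)
        assert m2 == pytest.approx(0.0083, abs=5e-5)
        b = (normal.body.k + normal.body.gfr) / normal.body.v_p \
            + normal.body.k / normal.body.v_e
        c = normal.body.k * normal.body.gfr / (normal.body.v_p * normal.body.v_e)
        for m in (m1, m2):
            assert m * m - b * m + c == pytest.approx(0.0, abs=1e-12)

    def test_no_clearance_gives_zero_slow_rate(self, normal):
        body = normal.body.model_copy(update={"gfr_total": 0.0})
        _, m2 = body_rates(body, "exact")
        assert m2 == 0.0


class TestPlasmaCurve:
    def test_initial_value_is_dose_over_vp(self, normal):
        mix = plasma_curve(normal.body)
        assert mix.at0() == pytest.approx(normal.body.dose / normal.body.v_p)
        assert mix.at0() == pytest.approx(1.724, abs=1e-3)

    def test_decoupled_limit_is_monoexponential(self, normal):
        body = normal.body.model_copy(update={"k": 0.0})
        t = np.linspace(0, 60, 61)
        expected = (body.dose / body.v_p) * np.exp(-body.gfr * t / body.v_p)
        assert plasma_curve(body)(t) == pytest.approx(expected, rel=1e-12)

    def test_no_clearance_equilibrium(self, normal):
        body = normal.body.model_copy(update={"gfr_total": 0.0})
        eq = body.dose / (body.v_p + body.v_e)
        assert eq == pytest.approx(0.676, abs=1e-3)
        assert plasma_curve(body)(1e5) == pytest.approx(eq, rel=1e-8)
        assert body_ees_curve(body)(1e5) == pytest.approx(eq, rel=1e-8)

    def test_plasma_strictly_decreasing(self, grid_0_60):
        for name in ALL_PRESETS:
            c_p = plasma_curve(load_preset(name).body)(grid_0_60)
            assert np.all(np.diff(c_p) < 0)

    def test_body_ees_starts_at_zero_and_is_unimodal(self, normal, grid_0_60):
        c_e = body_ees_curve(normal.body)(grid_0_60)
        assert c_e[0] == pytest.approx(0.0, abs=1e-12)
        diffs = np.diff(c_e)
        sign_changes = np.sum(np.diff(np.sign(diffs)) != 0)
        assert sign_changes == 1  # rises then falls


class TestMyocardialEes:
    def test_zero_permeability_gives_zero_curve(self, normal, grid_0_60):
        tissue = normal.tissues["myocardium"].model_copy(update={"ps": 0.0})
        mix = myocardial_ees_curve(tissue, plasma_curve(normal.body))
        assert np.all(mix(grid_0_60) == 0.0)

    def test_fast_exchange_limit_tracks_plasma(self, normal, grid_0_60):
        tissue = normal.tissues["myocardium"].model_copy(update={"ps": 1e6})
        plasma = plasma_curve(normal.body)
        c_me = myocardial_ees_curve(tissue, plasma)(grid_0_60[1:])
        assert c_me == pytest.approx(plasma(grid_0_60[1:]), rel=1e-3)

    def test_starts_at_zero(self, normal):
        mix = myocardial_ees_curve(normal.tissues["myocardium"],
                                   plasma_curve(normal.body))
        assert mix.at0() == pytest.approx(0.0, abs=1e-12)


class TestOracleAgreement:
    @pytest.mark.parametrize("name", ALL_PRESETS)
    def test_closed_form_matches_ode_oracle(self, name, grid_0_60):
        preset = load_preset(name)
        cf = assemble_curves(preset, grid_0_60)
        oo = ode_oracle(preset, grid_0_60)
        assert np.max(np.abs(cf.c_p - oo.c_p)) < 1e-8
        assert np.max(np.abs(cf.c_e - oo.c_e)) < 1e-8
        for tname in preset.tissues:
            assert np.max(np.abs(cf.tissues[tname].c_t
                                 - oo.tissues[tname].c_t)) < 1e-8

    def test_zero_dose_gives_zero_everywhere(self, normal, grid_0_60):
        preset = normal.model_copy(deep=True)
        preset.body = preset.body.model_copy(update={"dose": 0.0})
        oo = ode_oracle(preset, grid_0_60)
        assert np.max(np.abs(oo.c_p)) == 0.0

    def test_mass_conserved_without_clearance(self, normal, grid_0_60):
        preset = normal.model_copy(deep=True)
        preset.body = preset.body.model_copy(update={"gfr_total": 0.0})
        oo = ode_oracle(preset, grid_0_60)
        mass = preset.body.v_p * oo.c_p + preset.body.v_e * oo.c_e
        assert mass == pytest.approx(preset.body.dose, abs=1e-9)


class TestMassBalance:
    @pytest.mark.parametrize("name", ALL_PRESETS)
    def test_dose_partition_closes(self, name, grid_0_60):
        body = load_preset(name).body
        c_p = plasma_curve(body)(grid_0_60)
        c_e = body_ees_curve(body)(grid_0_60)
        total = body.v_p * c_p + body.v_e * c_e + renal_cleared(body, grid_0_60)
        assert np.max(np.abs(total - body.dose)) < 1e-8

    def test_renal_cleared_monotone_to_dose(self, normal):
        t = np.linspace(0, 2000, 200)
        cleared = renal_cleared(normal.body, t)
        assert cleared[0] == 0.0
        assert np.all(np.diff(cleared) > 0)
        assert cleared[-1] == pytest.approx(normal.body.dose, abs=1e-6)


class TestAssembledCurves:
    def test_blood_concentration_at_injection(self, normal):
        curves = assemble_curves(normal, np.array([0.0, 1.0]))
        # (1-Hct) D / (V_b (1-Hct)) = D / V_b = 1.000 mmol/L
        assert curves.c_b[0] == pytest.approx(1.000)

    def test_tissue_concentration_bound(self, grid_0_60):
        for name in ALL_PRESETS:
            preset = load_preset(name)
            curves = assemble_curves(preset, grid_0_60)
            for tname, t in preset.tissues.items():
                bound = (t.v_mb * (1 - t.hct_m) + t.v_e) * curves.c_p[0]
                assert np.all(curves.tissues[tname].c_t <= bound + 1e-12)

    def test_scar_retains_more_contrast_late(self, grid_0_60):
        curves = assemble_curves(load_preset("scar"), grid_0_60)
        late = grid_0_60 >= 15
        assert np.all(curves.tissues["scar"].c_t[late]
                      > curves.tissues["myocardium"].c_t[late])

    def test_empty_grid_rejected(self, normal):
        with pytest.raises(ValueError, match="empty"):
            assemble_curves(normal, np.array([]))


class TestCatenary:
    @pytest.fixture
    def cat_tissue(self):
        return TissueParams(v_mb=0.04, hct_m=0.24, v_e=0.96, ps=0.44,
                            t1_0=1100.0,
                            catenary=CatenaryParams(f_peri=0.25, ps_ee=0.1))

    def test_decoupled_remote_pool(self, normal, cat_tissue, grid_0_60):
        tissue = cat_tissue.model_copy(
            update={"catenary": CatenaryParams(f_peri=0.25, ps_ee=0.0)})
        plasma = plasma_curve(normal.body)
        c1, c2 = catenary_curves(tissue, plasma)
        assert np.all(c2(grid_0_60) == 0.0)
        sub = tissue.model_copy(update={"v_e": 0.25 * tissue.v_e,
                                        "catenary": None})
        assert c1(grid_0_60) == pytest.approx(
            myocardial_ees_curve(sub, plasma)(grid_0_60), abs=1e-12)

    def test_full_pericapillary_reduces_to_well_stirred(self, normal,
                                                        cat_tissue, grid_0_60):
        tissue = cat_tissue.model_copy(
            update={"catenary": CatenaryParams(f_peri=1.0, ps_ee=0.1)})
        plasma = plasma_curve(normal.body)
        c1, c2 = catenary_curves(tissue, plasma)
        well = myocardial_ees_curve(cat_tissue.model_copy(
            update={"catenary": None}), plasma)
        assert c2 is None
        assert c1(grid_0_60) == pytest.approx(well(grid_0_60), abs=1e-12)

    def test_matches_ode_oracle(self, cat_tissue, grid_0_60):
        preset = load_preset("amyloid_subendo").model_copy(deep=True)
        preset.tissues["subendo"] = cat_tissue
        cf = assemble_curves(preset, grid_0_60)
        oo = ode_oracle(preset, grid_0_60)
        assert np.max(np.abs(cf.tissues["subendo"].c_t
                             - oo.tissues["subendo"].c_t)) < 1e-8

    def test_catenary_washout_slower_than_well_stirred(self, normal,
                                                       cat_tissue):
        """Diffusion-limited access prolongs late tissue retention."""
        late = np.linspace(30.0, 60.0, 31)
        plasma = plasma_curve(normal.body)
        c1, c2 = catenary_curves(cat_tissue, plasma)
        f = cat_tissue.catenary.f_peri
        cat_total = (f * c1(late) + (1 - f) * c2(late)) * cat_tissue.v_e
        well = myocardial_ees_curve(
            cat_tissue.model_copy(update={"catenary": None}), plasma)
        assert np.all(cat_total >= well(late) * cat_tissue.v_e)


class TestDiffusion:
    def test_intercapillary_distance_is_subsecond(self):
        assert diffusion_time(0.02, 2e-4) == pytest.approx(0.5)

    def test_ratio_between_200um_and_20um_is_100(self):
        assert diffusion_time(0.2) / diffusion_time(0.02) == \
            pytest.approx(100.0, rel=1e-12)

    @given(st.floats(1e-3, 10.0), st.floats(1e-6, 1e-2))
    @settings(max_examples=50, deadline=None)
    def test_time_and_length_are_mutually_inverse(self, d, dcoef):
        assert diffusion_length(diffusion_time(d, dcoef), dcoef) == \
            pytest.approx(d, rel=1e-12)


@given(k=st.floats(1e-4, 0.1), v_e=st.floats(0.01, 0.5),
       gfr=st.floats(0.0, 200.0))
@settings(max_examples=50, deadline=None)
def test_mass_balance_holds_across_parameter_space(k, v_e, gfr):
    """Dose = plasma + body EES + cleared, for arbitrary valid body params."""
    from lgesim.params import BodyParams
    body = BodyParams(k=k, v_e=v_e, gfr_total=gfr)
    t = np.linspace(0.0, 60.0, 31)
    total = (body.v_p * plasma_curve(body)(t)
             + body.v_e * body_ees_curve(body)(t)
             + renal_cleared(body, t))
    assert total == pytest.approx(body.dose, abs=1e-8)
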