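"""Sweep drivers, threshold detection, flux decomposition, titrations."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sdhrev.experiments import (
    eout_sweep,
    flux_decomposition,
    fumarate_titration,
    redox_profile,
    ros_scan,
    threshold_detect,
)
from sdhrev.kinetics import ClampedEnvironment
from sdhrev.params import make_variant, zero_ros_variant
from sdhrev.variants import (
    SCAN_DEFINITIONS,
    build_catalog_parameter_sets,
    variant_by_label,
    variant_catalog,
)

COARSE = np.arange(100.0, -400.0 - 1e-9, -20.0)


@pytest.fixture(scope="module")
def basal_sweep(base_ps):
    return eout_sweep(base_ps, grid=COARSE)


@pytest.fixture(scope="module")
def tunnel_sweep(suc_release_variant):
    # finer around the interior maximum
    grid = np.concatenate([np.arange(0.0, -50.0, -10.0), np.arange(-50.0, -301.0, -5.0)])
    return eout_sweep(suc_release_variant, grid=grid)


class TestEoutSweep:
    def test_basal_succinate_flux_is_monotone(self, basal_sweep):
        v = basal_sweep.sort_values("E_out", ascending=False)["V_suc_tot"].to_numpy()
        assert np.all(np.diff(v) > 0)
        assert basal_sweep["converged"].all()

    def test_tunnel_diode_variant_has_interior_maximum(self, tunnel_sweep):
        v = tunnel_sweep.sort_values("E_out", ascending=False)["V_rev_tot"].to_numpy()
        i = int(np.argmax(v))
        assert 0 < i < len(v) - 1
        assert v[i] > v[-1] * 10  # strong drop beyond the threshold

    def test_single_point_sweep(self, base_ps):
        sw = eout_sweep(base_ps, grid=np.array([-100.0]))
        assert len(sw) == 1
        assert threshold_detect(sw)[0]["E_threshold_mV"] is None

    def test_empty_grid_rejected(self, base_ps):
        with pytest.raises(ValueError):
            eout_sweep(base_ps, grid=np.array([]))

    def test_ros_off_identity_per_row(self, ros_off_ps):
        sw = eout_sweep(ros_off_ps, grid=np.array([-50.0, -150.0, -250.0]))
        assert np.allclose(sw["V_rev_tot"], 2.0 * sw["V_suc_tot"], rtol=1e-6)
        assert np.allclose(sw["V_rev_tot"], sw["V1"], rtol=1e-6)


class TestThresholdDetect:
    def test_tunnel_variant_threshold_near_minus_80(self, tunnel_sweep):
        rep = threshold_detect(tunnel_sweep, "V_rev_tot")[0]
        assert rep["E_threshold_mV"] == pytest.approx(-80.0, abs=20.0)
        assert rep["reliable"]

    def test_monotone_curve_reports_none(self, basal_sweep):
        rep = threshold_detect(basal_sweep, "V_suc_tot")[0]
        assert rep["E_threshold_mV"] is None

    @settings(deadline=None, max_examples=25)
    @given(E0=st.floats(-350.0, 50.0))
    def test_planted_quadratic_maximum_recovered(self, E0):
        grid = np.arange(100.0, -400.0 - 1e-9, -10.0)
        df = pd.DataFrame(
            {
                "label": "synthetic",
                "E_out": grid,
                "f": -((grid - E0) ** 2),
                "converged": True,
            }
        )
        rep = threshold_detect(df, "f")[0]
        assert rep["E_threshold_mV"] == pytest.approx(E0, abs=10.0)

    def test_unconverged_bracket_flagged(self):
        grid = np.arange(0.0, -100.0 - 1e-9, -10.0)
        df = pd.DataFrame(
            {
                "label": "synthetic",
                "E_out": grid,
                "f": -((grid + 50.0) ** 2),
                "converged": [abs(E + 60.0) > 1.0 for E in grid],
            }
        )
        rep = threshold_detect(df, "f")[0]
        assert not rep["reliable"]

    def test_threshold_ordering_across_release_constants(self, base_ps):
        """Slower succinate release moves the drop to less negative E_out."""
        thresholds = []
        for k in (0.1, 0.01, 0.001):
            ps = make_variant(base_ps, {"k14": k, "k16": k})
            grid = np.arange(-20.0, -200.0 - 1e-9, -5.0)
            rep = threshold_detect(eout_sweep(ps, grid=grid))[0]
            thresholds.append(rep["E_threshold_mV"])
        assert all(t is not None for t in thresholds)
        assert thresholds[0] < thresholds[1] < thresholds[2]


class TestFluxDecomposition:
    def test_components_sum_exactly(self, tunnel_sweep):
        dec = flux_decomposition(tunnel_sweep)
        assert np.allclose(
            dec["V_suc_tot"], tunnel_sweep["V8"] + tunnel_sweep["V14"] + tunnel_sweep["V16"]
        )
        assert np.allclose(dec["V_suc_tot"], tunnel_sweep["V_suc_tot"], rtol=1e-12)

    def test_v8_dominates_near_threshold_for_slow_release(self, tunnel_sweep):
        near = tunnel_sweep[tunnel_sweep["E_out"].between(-150.0, -60.0)]
        frac = (near["V8"] / near["V_suc_tot"]).max()
        assert frac > 0.5

    def test_v16_dominates_basal_tail(self, basal_sweep):
        tail = basal_sweep[basal_sweep["E_out"] <= -300.0]
        assert (tail["V16"] > 0.9 * tail["V_suc_tot"]).all()
        assert (tail["V14"] < 0.05 * tail["V_suc_tot"]).all()


class TestRedoxProfile:
    def test_concentrations_bounded_by_pool(self, basal_sweep, base_ps):
        prof = redox_profile(basal_sweep)
        for col in ("fadh", "fadh2", "fes3_red", "fes2_red"):
            assert (prof[col] <= 235.0 + 1e-9).all()
            assert (prof[col] >= -1e-9).all()

    def test_fes3_reduced_saturates_by_minus_60(self, basal_sweep):
        row = basal_sweep[basal_sweep["E_out"] == -60.0].iloc[0]
        assert row["fes3_red"] > 0.9 * 235.0

    def test_fes2_reduction_needs_much_lower_potential(self, basal_sweep):
        """[2Fe-2S]- trails [3Fe-4S]- and saturates only near -200 mV."""
        row_60 = basal_sweep[basal_sweep["E_out"] == -60.0].iloc[0]
        row_200 = basal_sweep[basal_sweep["E_out"] == -200.0].iloc[0]
        gap2_60, gap3_60 = 235.0 - row_60["fes2_red"], 235.0 - row_60["fes3_red"]
        assert gap2_60 > 5.0 * gap3_60
        assert row_60["fes2_red"] < 220.0
        assert row_200["fes2_red"] > 0.99 * 235.0


class TestRosScan:
    def test_high_ros_variant_exceeds_1000_specific(self, slow_fum_binding_variant):
        sw = ros_scan(
            slow_fum_binding_variant, grid=np.arange(-200.0, -401.0, -50.0)
        )
        assert sw["VH2O2_specific"].max() > 1000.0

    def test_h2o2_equals_efflux_per_row(self, slow_fum_binding_variant):
        sw = ros_scan(slow_fum_binding_variant, grid=np.array([-250.0]))
        row = sw.iloc[0]
        assert row["VH2O2"] == pytest.approx(row["V22"], rel=1e-6)
        assert row["VH2O2_specific"] == pytest.approx(220.0 * row["VH2O2"], rel=1e-12)

    def test_ros_off_scan_is_zero(self, ros_off_ps):
        sw = ros_scan(ros_off_ps, grid=np.array([-100.0, -300.0]))
        assert np.allclose(sw["VH2O2"], 0.0, atol=1e-12)

    def test_slow_release_variants_produce_much_less_ros(
        self, suc_release_variant, slow_fum_binding_variant, base_ps
    ):
        grid = np.arange(-200.0, -401.0, -100.0)
        high = ros_scan(slow_fum_binding_variant, grid=grid)["VH2O2_specific"].max()
        low_c = ros_scan(suc_release_variant, grid=grid)["VH2O2_specific"].max()
        low_d = ros_scan(
            make_variant(base_ps, {"kminus14": 4e3, "kminus16": 4e3}), grid=grid
        )["VH2O2_specific"].max()
        assert low_c < high / 10
        assert low_d < high / 10


@pytest.fixture(scope="module")
def titration(suc_release_variant):
    return fumarate_titration(
        suc_release_variant,
        fum_grid=np.logspace(0, 5, 11),
        eout_set=(-50.0, -150.0),
    )


class TestFumarateTitration:
    def test_flux_nondecreasing_and_saturating(self, titration):
        for E, sub in titration.groupby("E_out"):
            sub = sub.sort_values("fum")
            v = sub["V_suc_tot"].to_numpy()
            assert np.all(np.diff(v) > -1e-9)
            # saturation: last decade gains < 10% of the total span
            span = v[-1] - v[0]
            assert v[-1] - v[-3] < 0.1 * span

    def test_slow_release_caps_saturating_rate_at_low_potential(self, titration):
        vmax = titration.groupby("E_out")["V_suc_tot"].max()
        assert vmax[-150.0] < vmax[-50.0]

    def test_no_net_reduction_without_fumarate(self, base_ps):
        df = fumarate_titration(
            zero_ros_variant(base_ps),
            fum_grid=np.array([0.0, 1.0, 1000.0]),
            eout_set=(0.0,),
        )
        v0 = df[df["fum"] == 0.0]["V_suc_tot"].iloc[0]
        assert v0 <= 1e-9

    def test_narrow_grid_rejected(self, base_ps):
        with pytest.raises(ValueError):
            fumarate_titration(base_ps, fum_grid=np.array([100.0, 500.0]))


class TestVariantCatalog:
    def test_row_count_matches_captioned_curves(self):
        # figs 2-9: 2A:5 2B:4 2C:5 2D:5; figs 3-6: 4 panels x 1; fig 7:
        # A-D 5 each + E,F 1 each; fig 8: 5+4+4+5; fig 9: 4 panels x 1
        expected = (5 + 4 + 5 + 5) + 4 * 4 + (4 * 5 + 2) + (5 + 4 + 4 + 5) + 4
        assert len(variant_catalog()) == expected

    def test_fig2c_curve4_overrides(self):
        cv = [
            c for c in variant_catalog() if (c.figure, c.panel, c.curve) == (2, "C", 4)
        ][0]
        assert cv.overrides == {"k14": 1e-2, "k16": 1e-2}

    def test_fig2d_curve4_overrides(self):
        cv = [
            c for c in variant_catalog() if (c.figure, c.panel, c.curve) == (2, "D", 4)
        ][0]
        assert cv.overrides == {"kminus14": 4e3, "kminus16": 4e3}

    def test_every_set_is_balanced(self):
        from sdhrev.params import cycle_residuals

        sets = build_catalog_parameter_sets()
        n_curves = sum(len(v[1]) for v in SCAN_DEFINITIONS.values())
        assert len(sets) == n_curves
        for ps in sets.values():
            for prod in cycle_residuals(ps):
                assert prod == pytest.approx(1.0, rel=1e-10)

    def test_variant_by_label(self):
        ps = variant_by_label("suc_off_4")
        assert ps.keq[13] == pytest.approx(0.24)
        assert variant_by_label("basal").label == "basal"
        with pytest.raises(KeyError):
            variant_by_label("nope")
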