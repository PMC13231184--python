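import numpy as np
import pytest

from pavasc import synthetic as syn
from pavasc.core import STUDY_WAVELENGTHS


class TestExtinctionTable:
    def test_hb_dominates_at_700(self):
        assert syn.tabulated_extinction("Hb", 700) > syn.tabulated_extinction("HbO2", 700)

    def test_hbo2_dominates_at_900(self):
        assert syn.tabulated_extinction("HbO2", 900) > syn.tabulated_extinction("Hb", 900)

    @pytest.mark.parametrize("wl", [1200, 450, 250])
    def test_out_of_range(self, wl):
        with pytest.raises(ValueError, match="range"):
            syn.tabulated_extinction("Hb", wl)

    def test_unknown_chromophore(self):
        with pytest.raises(ValueError, match="chromophore"):
            syn.tabulated_extinction("melanin", 700)

    def test_interpolation_between_grid_points(self):
        lo = syn.tabulated_extinction("HbO2", 850)
        hi = syn.tabulated_extinction("HbO2", 875)
        mid = syn.tabulated_extinction("HbO2", 862.5)
        assert mid == pytest.approx((lo + hi) / 2)


class TestUSGeneration:
    def test_noiseless_step_is_exact(self, flat_phantom):
        us = syn.generate_us_volume(flat_phantom, seed=0)
        truth = flat_phantom.truth_masks()
        np.testing.assert_array_equal(us.values > 0, truth["tissue"])
        assert np.all(us.values[truth["tissue"]] == flat_phantom.tissue_echogenicity)

    def test_deterministic_for_seed(self, noisy_phantom):
        a = syn.generate_us_volume(noisy_phantom, seed=7)
        b = syn.generate_us_volume(noisy_phantom, seed=7)
        np.testing.assert_array_equal(a.values, b.values)

    def test_water_tissue_separation(self, noisy_phantom):
        us = syn.generate_us_volume(noisy_phantom, seed=3)
        truth = noisy_phantom.truth_masks()
        water_mean = us.values[truth["water"]].mean()
        tissue_mean = us.values[truth["tissue"]].mean()
        assert tissue_mean - water_mean > 5 * noisy_phantom.noise_us

    def test_surface_outside_grid_rejected(self, flat_phantom):
        from dataclasses import replace

        bad = replace(flat_phantom, surface_depth_mm=100.0)
        with pytest.raises(ValueError, match="surface"):
            syn.generate_us_volume(bad, seed=0)


class TestPAGeneration:
    def test_zero_concentration_gives_zero_vessels(self, flat_phantom):
        from dataclasses import replace

        spec = replace(
            flat_phantom,
            vessels=tuple(
                replace(v, c_hb=0.0, c_hbo2=0.0) for v in flat_phantom.vessels
            ),
        )
        stack = syn.generate_pa_stack(spec, seed=0)
        tissue = spec.truth_masks()["tissue"]
        for wl in STUDY_WAVELENGTHS:
            assert np.all(stack[wl].values[tissue] == 0)

    def test_linearity_in_concentration(self, flat_phantom):
        from dataclasses import replace

        doubled = replace(
            flat_phantom,
            vessels=tuple(
                replace(v, c_hb=2 * v.c_hb, c_hbo2=2 * v.c_hbo2)
                for v in flat_phantom.vessels
            ),
        )
        s1 = syn.generate_pa_stack(flat_phantom, seed=0)
        s2 = syn.generate_pa_stack(doubled, seed=0)
        tissue = flat_phantom.truth_masks()["tissue"]
        for wl in STUDY_WAVELENGTHS:
            np.testing.assert_allclose(
                s2[wl].values[tissue], 2 * s1[wl].values[tissue], rtol=1e-12
            )

    def test_pure_hb_spectral_ratio(self):
        from dataclasses import replace

        spec = syn.default_phantom(n_vessels=1, c_hb=1e-3, c_hbo2=0.0)
        spec = replace(spec, water_pa_amplitude=0.0)
        stack = syn.generate_pa_stack(spec, seed=0)
        v700 = stack[700].values.max()
        v900 = stack[900].values.max()
        expected = (
            syn.tabulated_extinction("Hb", 700)
            * spec.fluence[700]
            / (syn.tabulated_extinction("Hb", 900) * spec.fluence[900])
        )
        assert v700 / v900 == pytest.approx(expected, rel=1e-9)

    def test_water_reference_amplitude_present(self, flat_phantom):
        stack = syn.generate_pa_stack(flat_phantom, seed=0)
        water = flat_phantom.truth_masks()["water"]
        assert np.all(stack[532].values[water] == flat_phantom.water_pa_amplitude)

    def test_ridge_is_depth_extended_in_tissue(self):
        from dataclasses import replace

        spec = syn.default_phantom(n_vessels=0)
        ridge = syn.Ridge(x_mm=3.2, y0_mm=1.0, y1_mm=5.0, amplitude=2.0)
        spec = replace(spec, ridges=(ridge,))
        stack = syn.generate_pa_stack(spec, seed=0)
        masks = spec.truth_masks()
        col = stack[532].values[32, 30, :]  # x=3.25 mm, y=3.05 mm
        tissue_col = masks["tissue"][32, 30, :]
        assert np.all(col[tissue_col] > 1.0)
        assert np.all(col[~tissue_col] == spec.water_pa_amplitude)


class TestCohorts:
    def test_decline_reaches_configured_fraction(self):
        c = syn.CohortSpec(decline_fraction=0.5)
        assert c.decline(12) == pytest.approx(0.5)
        assert c.decline(0) == 1.0

    def test_zero_lag_score_onset_matches_decline_onset(self):
        c = syn.CohortSpec(lag_weeks=0, onset_week=2)
        assert c.score(0, exposed=True) == 5
        assert c.score(2, exposed=True) == 4  # decline begins at onset

    def test_lag_shifts_score_onset(self):
        c = syn.CohortSpec(lag_weeks=4, onset_week=2)
        assert c.score(4, exposed=True) == 5
        assert c.score(6, exposed=True) == 4

    def test_scores_clipped_to_floor(self):
        c = syn.CohortSpec(lag_weeks=0, onset_week=0)
        assert c.score(12, exposed=True) == 1

    def test_flat_cohort_indistinguishable(self):
        flat = syn.CohortSpec(decline_fraction=1.0, noise_sigma=0.0)
        df, _ = syn.generate_biomarker_cohort(flat, seed=0)
        assert df.groupby("group")["normalized"].mean().nunique() == 1
        assert (df["score"] == 5).all()

    def test_fixed_seed_bit_identical(self):
        c = syn.CohortSpec(n_healthy=2, n_exposed=2)
        a, _ = syn.generate_biomarker_cohort(c, seed=11)
        b, _ = syn.generate_biomarker_cohort(c, seed=11)
        assert a.equals(b)

    def test_rendered_cohort_week12_concentration(self):
        c = syn.CohortSpec(n_healthy=1, n_exposed=1, noise_sigma=0.0)
        phantom = syn.default_phantom(shape=(24, 24, 20))
        manifest, sessions, truth = syn.generate_longitudinal_cohort(
            c, seed=5, phantom=phantom
        )
        s0 = sessions[("e01", 0)].pa[532].values
        s12 = sessions[("e01", 12)].pa[532].values
        tissue = phantom.truth_masks()["tissue"]
        np.testing.assert_allclose(s12[tissue], 0.5 * s0[tissue], rtol=1e-9)
        assert truth["subjects"]["e01"]["decline"][12] == pytest.approx(0.5)

    def test_lag_must_align_with_sampling(self):
        with pytest.raises(ValueError, match="multiple"):
            syn.CohortSpec(lag_weeks=3)


class TestLaggedSeriesPair:
    def test_noiseless_shift_is_exact(self):
        w, b, s = syn.lagged_series_pair(lead_weeks=4, noise_sigma=0.0)
        np.testing.assert_allclose(s[2:], b[:-2], atol=1e-12)

    def test_deterministic(self):
        a = syn.lagged_series_pair(4, 0.1, seed=3)
        b = syn.lagged_series_pair(4, 0.1, seed=3)
        for x, y in zip(a, b):
            np.testing.assert_array_equal(x, y)


class TestDehiscenceScenario:
    def test_structure_and_scores(self):
        sc = syn.generate_dehiscence_scenario(seed=0, shape=(40, 40, 20))
        assert sc["score_drop_week"] == sc["drop_week"] + 2
        assert sc["scores"][sc["drop_week"]] == 5  # drop precedes the score
        assert sc["scores"][sc["score_drop_week"]] == 4
        assert sc["truth_region"].any()

    def test_thb_drops_only_inside_site(self):
        sc = syn.generate_dehiscence_scenario(seed=1, shape=(40, 40, 20), noise_sigma=0.0)
        before = sc["pa_stacks"][sc["drop_week"] - 2][800].values
        after = sc["pa_stacks"][sc["drop_week"]][800].values
        changed = (~np.isclose(before, after)).any(axis=2)
        assert changed.any()
        phantom = sc["phantom"]
        ex, ey, _ = phantom.extent_mm
        x, y = phantom.lateral_coords()
        xx, yy = np.meshgrid(x, y, indexing="ij")
        disc = np.hypot(xx - ex / 2, yy - ey / 2) <= 1.6
        assert np.all(disc[changed])
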