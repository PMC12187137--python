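"""Gaussian decompositions, asymmetry statistics, particle localization,
fusion classification, rate estimators and principal-component regression."""

import numpy as np
import pandas as pd
import pytest

from polyseg import (GaussianComponent, SynthConfig,
                     asymmetry_stats, classify_fusion, fit_nucleoid_gaussians,
                     fit_polysome_gaussians, gaussian_area,
                     generate_fusion_series, generate_particle_image,
                     generate_profile_series, localize_particle,
                     localize_particles, nucleoid_distance_series,
                     pc_regression, rate_estimators)
from polyseg.gaussians import GaussianDecomposition
from polyseg.profiles import Profile


def profile_from_components(components, baseline=100.0, nb=120, length=3.0,
                            channel="polysome"):
    pos = np.linspace(-1 + 1 / nb, 1 - 1 / nb, nb)
    vals = np.full(nb, baseline)
    for A, mu, sig in components:
        vals += A * np.exp(-0.5 * ((mu - pos) / sig) ** 2)
    return Profile(positions=pos, values=vals, cell_length_um=length,
                   channel=channel)


class TestGaussianFits:
    def test_polysome_triplet_recovered_within_one_percent(self):
        truth = [(120.0, -0.82, 0.11), (60.0, 0.05, 0.16), (150.0, 0.85, 0.12)]
        fit = fit_polysome_gaussians(profile_from_components(truth))
        assert fit.ok
        for comp, (A, mu, sig) in zip(fit.components, truth):
            assert comp.A == pytest.approx(A, rel=0.01)
            assert comp.l == pytest.approx(mu, abs=0.01)
            assert comp.sigma == pytest.approx(sig, rel=0.01)

    def test_mirror_symmetric_profile_gives_symmetric_fit(self):
        truth = [(100.0, -0.8, 0.12), (40.0, 0.0, 0.15), (100.0, 0.8, 0.12)]
        fit = fit_polysome_gaussians(profile_from_components(truth))
        assert abs(fit.old.l) == pytest.approx(fit.new.l, abs=0.01)
        assert fit.old.A == pytest.approx(fit.new.A, rel=0.02)

    def test_zero_mid_amplitude_recovered_as_zero(self):
        truth = [(100.0, -0.8, 0.12), (0.0, 0.0, 0.15), (100.0, 0.8, 0.12)]
        fit = fit_polysome_gaussians(profile_from_components(truth))
        assert fit.mid.A < 1.0  # ≈0 against amplitudes of 100

    def test_nucleoid_pair_recovered_within_one_percent(self):
        truth = [(200.0, -0.45, 0.17), (250.0, 0.40, 0.15)]
        prof = profile_from_components(truth, channel="nucleoid")
        fit = fit_nucleoid_gaussians(prof)
        assert fit.ok
        for comp, (A, mu, sig) in zip(fit.components, truth):
            assert comp.A == pytest.approx(A, rel=0.01)
            assert comp.l == pytest.approx(mu, abs=0.01)
            assert comp.sigma == pytest.approx(sig, rel=0.01)

    def test_symmetric_lobes_give_unit_compaction_ratio(self):
        truth = [(220.0, -0.5, 0.15), (220.0, 0.5, 0.15)]
        fit = fit_nucleoid_gaussians(profile_from_components(
            truth, channel="nucleoid"))
        assert fit.new.A / fit.old.A == pytest.approx(1.0, abs=0.02)

    def test_recovery_from_generated_population(self):
        """End-to-end: generator profiles → fits → scripted asymmetries."""
        bundle = generate_profile_series(SynthConfig(seed=3, n_founders=1,
                                                     generations=1))
        cell = 0
        prof = bundle.cell(cell, "polysome")[0]
        nuc = bundle.cell(cell, "nucleoid")[-1]
        pf = fit_polysome_gaussians(prof)
        nf = fit_nucleoid_gaussians(nuc)
        stats = asymmetry_stats(pf, nf, prof.cell_length_um)
        truth = bundle.truth["cells"][cell]
        assert stats["poly_asym"] == pytest.approx(
            truth["poly_asym_target"], abs=0.01)
        assert stats["nuc_comp"] == pytest.approx(
            truth["nuc_comp_target"], rel=0.03)

    def test_noisy_recovery_at_moderate_snr(self):
        """With additive noise at ~10:1 signal-to-noise the decomposition
        still recovers amplitudes and positions to a few percent."""
        rng = np.random.default_rng(42)
        truth = [(120.0, -0.82, 0.11), (60.0, 0.0, 0.16), (150.0, 0.85, 0.12)]
        prof = profile_from_components(truth)
        prof.values = prof.values + rng.normal(0.0, 12.0, prof.values.size)
        fit = fit_polysome_gaussians(prof)
        for comp, (A, mu, sig) in zip(fit.components, truth):
            assert comp.A == pytest.approx(A, rel=0.15)
            assert comp.l == pytest.approx(mu, abs=0.05)

    def test_summary_is_readable(self):
        fit = fit_nucleoid_gaussians(profile_from_components(
            [(200.0, -0.45, 0.17), (250.0, 0.4, 0.15)], channel="nucleoid"))
        text = fit.summary()
        assert "old" in text and "new" in text and "baseline" in text


class TestClosedFormStatistics:
    def test_gaussian_area_closed_form(self):
        assert gaussian_area(1.0, 1.0) == pytest.approx(np.sqrt(2 * np.pi))
        assert gaussian_area(0.0, 1.0) == 0.0
        assert gaussian_area(2.0, 3.0) == pytest.approx(2 * gaussian_area(2.0, 1.5))
        with pytest.raises(ValueError):
            gaussian_area(1.0, 0.0)

    def _poly(self, comps):
        return GaussianDecomposition(
            components=[GaussianComponent(*c) for c in comps],
            baseline=0.0, channel="polysome", residual_rms=0.0)

    def _nuc(self, comps):
        return GaussianDecomposition(
            components=[GaussianComponent(*c) for c in comps],
            baseline=0.0, channel="nucleoid", residual_rms=0.0)

    def test_equal_areas_give_zero_polar_asymmetry(self):
        poly = self._poly([(10, -0.8, 0.1), (5, 0, 0.2), (10, 0.8, 0.1)])
        assert asymmetry_stats(poly, None, 3.0)["poly_asym"] == pytest.approx(0.0)

    def test_mirror_lobes_give_zero_nucleoid_offset(self):
        nuc = self._nuc([(10, -0.5, 0.2), (12, 0.5, 0.2)])
        assert asymmetry_stats(None, nuc, 3.0)["nuc_pos_um"] == pytest.approx(0.0)

    def test_equal_gaps_give_unit_space_ratio(self):
        poly = self._poly([(10, -0.8, 0.1), (5, 0.0, 0.2), (10, 0.8, 0.1)])
        assert asymmetry_stats(poly, None, 3.0)["poly_space"] == pytest.approx(1.0)

    def test_offset_statistics_scale_with_cell_length(self):
        nuc = self._nuc([(10, -0.3, 0.2), (10, 0.5, 0.2)])
        s3 = asymmetry_stats(None, nuc, 3.0)["nuc_pos_um"]
        s6 = asymmetry_stats(None, nuc, 6.0)["nuc_pos_um"]
        assert s3 == pytest.approx(0.1 * 1.5) and s6 == pytest.approx(2 * s3)

    def test_nonpositive_denominators_are_undefined(self):
        poly = self._poly([(0.0, -0.8, 0.1), (5, 0.0, 0.2), (10, 0.8, 0.1)])
        out = asymmetry_stats(poly, None, 3.0)
        assert np.isnan(out["poly_asym"])


class TestParticleLocalization:
    def test_noiseless_center_recovered_to_twentieth_pixel(self):
        img, truth = generate_particle_image(center=(7.33, 6.61), A=180.0,
                                             sigmas=(1.2, 1.8), theta=0.6)
        fit = localize_particle(img, (7, 7))
        cx, cy = fit.center
        tx, ty = truth["centers"][0]
        assert abs(cx - tx) < 0.05 and abs(cy - ty) < 0.05

    def test_isotropic_spot_invariant_to_quarter_rotation(self):
        img, _ = generate_particle_image(center=(7.2, 7.1), A=150.0,
                                         sigmas=(1.5, 1.5), theta=0.0)
        fit1 = localize_particle(img, (7, 7))
        fit2 = localize_particle(np.rot90(img).copy(), (7, 7))
        # rotating the window by 90° maps (x, y) -> (y, nx-1-x)
        cx1, cy1 = fit1.center
        cx2, cy2 = fit2.center
        assert cx2 == pytest.approx(cy1, abs=0.05)
        assert cy2 == pytest.approx(img.shape[1] - 1 - cx1, abs=0.05)

    def test_merged_mask_split_into_two_fits(self):
        img, truth = generate_particle_image(center=(6.0, 7.0), A=200.0,
                                             sigmas=(1.4, 1.4), theta=0.0,
                                             shape=(15, 20),
                                             second_center=(11.0, 7.0))
        mask = img > 2.0
        assert mask.sum() > 90
        fits = localize_particles(img, mask, area_threshold=90)
        assert len(fits) == 2
        got = sorted(f.center[0] for f in fits)
        want = sorted(c[0] for c in truth["centers"])
        assert got == pytest.approx(want, abs=0.3)

    def test_small_mask_fits_single_particle(self):
        img, _ = generate_particle_image(center=(7.0, 7.0), A=100.0)
        mask = img > 30.0
        fits = localize_particles(img, mask)
        assert len(fits) == 1


class TestFusion:
    def test_scripted_fusion_detected_at_script_frame(self):
        profiles, script = generate_fusion_series(fusing=True, fusion_frame=6)
        series = nucleoid_distance_series(profiles)
        result = classify_fusion(series)
        assert result["classification"] == "fusing"
        assert abs(result["fusion_frame"] - script["fusion_frame"]) <= 1

    def test_constant_two_peak_series_is_non_fusing(self):
        profiles, _ = generate_fusion_series(fusing=False)
        result = classify_fusion(nucleoid_distance_series(profiles))
        assert result["classification"] == "non-fusing"
        assert result["initial_count"] == result["final_count"] == 2

    def test_initial_minimum_distance_matches_script(self):
        profiles, script = generate_fusion_series(fusing=False)
        result = classify_fusion(nucleoid_distance_series(profiles))
        assert result["min_initial_distance_um"] == pytest.approx(
            script["initial_separation_um"], rel=0.05)

    def test_sub_threshold_peaks_flagged_empty(self):
        profiles, _ = generate_fusion_series(fusing=False, amplitude=50.0,
                                             baseline=5.0)
        series = nucleoid_distance_series(profiles, threshold=125.0)
        assert all(f.flagged_empty for f in series)

    def test_classification_matches_scripts_across_seeds(self):
        for seed in range(6):
            fusing = seed % 2 == 0
            profiles, _ = generate_fusion_series(fusing=fusing, seed=seed)
            got = classify_fusion(nucleoid_distance_series(profiles))
            assert got["classification"] == ("fusing" if fusing else "non-fusing")


class TestRateEstimators:
    def _cycle_frame(self, n=24, elong_rate=0.01, noise=0.0, seed=0):
        rng = np.random.default_rng(seed)
        t = np.linspace(0.0, 60.0, n)
        return pd.DataFrame({
            "time_min": t,
            "cycle_fraction": np.linspace(0, 1, n),
            "split_to_div_fraction": np.linspace(0, 1, n),
            "mid_nucleoid_polysome": 100 + 0.5 * t + rng.normal(0, noise, n),
            "mid_nucleoid_nucleoid": 200 - 0.8 * t + rng.normal(0, noise, n),
            "mid_cell_polysome": np.full(n, 140.0) + rng.normal(0, noise, n),
            "internucleoid_distance_um": 1.2 * np.exp(0.02 * t),
            "cell_length_um": 2.5 * np.exp(elong_rate * t),
        })

    def test_scripted_exponential_elongation_rate_recovered(self):
        out = rate_estimators(self._cycle_frame())
        lengths = [r for r in out if r.quantity == "ln_cell_length" and r.ok]
        assert lengths and all(r.slope == pytest.approx(0.01, rel=1e-6)
                               for r in lengths)
        dists = [r for r in out if r.quantity == "ln_internucleoid_distance"
                 and r.ok]
        assert all(r.slope == pytest.approx(0.02, rel=1e-6) for r in dists)

    def test_constant_midcell_signal_gives_zero_slope(self):
        out = rate_estimators(self._cycle_frame())
        mids = [r for r in out if r.quantity == "mid_cell_polysome" and r.ok]
        assert mids and all(abs(r.slope) < 1e-9 for r in mids)

    def test_cycle_window_slopes_match_script(self):
        out = rate_estimators(self._cycle_frame())
        by_name = {r.quantity: r for r in out if r.window == "cycle_40_90"}
        assert by_name["mid_nucleoid_polysome"].slope == pytest.approx(0.5)
        assert by_name["mid_nucleoid_nucleoid"].slope == pytest.approx(-0.8)

    def test_short_interval_excluded(self):
        df = self._cycle_frame(n=24)
        sparse = df.iloc[:3]
        out = rate_estimators(sparse)
        assert all(not r.ok for r in out)
        assert any("timepoints" in r.reason for r in out)

    def test_negative_elongation_voids_division_cycle_rates(self):
        out = rate_estimators(self._cycle_frame(elong_rate=-0.01))
        quart = [r for r in out if r.window.startswith("quartile")]
        assert quart and all(not r.ok for r in quart)
        assert all("elongation" in r.reason for r in quart)

    def test_two_nucleoid_birth_excluded(self):
        out = rate_estimators(self._cycle_frame(),
                              born_with_two_nucleoids=True)
        assert len(out) == 1 and not out[0].ok


class TestPCRegression:
    def test_noiseless_line_recovered_exactly(self):
        x = np.linspace(0, 10, 25)
        slope, intercept = pc_regression(x, 2 * x + 1)
        assert slope == pytest.approx(2.0)
        assert intercept == pytest.approx(1.0)

    def test_axis_exchange_inverts_slope(self):
        x = np.linspace(0, 10, 25)
        y = 2 * x + 1
        m, _ = pc_regression(x, y)
        m_inv, _ = pc_regression(y, x)
        assert m_inv == pytest.approx(1 / m)

    def test_bivariate_gaussian_axis_matches_analytic_value(self, rng):
        """Monte-Carlo check against the closed form: the first principal
        axis of z-transformed 2D data, mapped back to the original plane,
        has slope sign(ρ)·σy/σx."""
        n = 20000
        u = rng.normal(0, 3.0, n)
        v = rng.normal(0, 0.5, n)
        theta = 0.35
        x = u * np.cos(theta) - v * np.sin(theta)
        y = u * np.sin(theta) + v * np.cos(theta) + 2.0
        sx2 = 9 * np.cos(theta) ** 2 + 0.25 * np.sin(theta) ** 2
        sy2 = 9 * np.sin(theta) ** 2 + 0.25 * np.cos(theta) ** 2
        expected = np.sqrt(sy2 / sx2)  # correlation is positive here
        slope, intercept = pc_regression(x, y)
        assert slope == pytest.approx(expected, rel=0.03)
        assert intercept == pytest.approx(2.0, abs=0.05)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            pc_regression(np.ones(10), np.linspace(0, 1, 10))
        with pytest.raises(ValueError):
            pc_regression([1.0, 2.0], [1.0, 2.0])
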