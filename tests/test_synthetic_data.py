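import math

import numpy as np
import pandas as pd
import pytest
from numpy.testing import assert_allclose
from pydantic import ValidationError
from scipy.integrate import quad
from scipy.stats import norm

from recruitkit.hdx_diff import DEUTERON_MASS_SHIFT_DA
from recruitkit.synthetic_data import (
    ArcCurve,
    FilamentSimSpec,
    GuvSimSpec,
    HdxPeptide,
    HdxSimSpec,
    LineCurve,
    RecruitmentKinetics,
    SinusoidCurve,
    disc_outlines,
    simulate_bead_image,
    simulate_filament,
    simulate_guv_timelapse,
    simulate_hdx_experiment,
    simulate_isotope_envelope,
    uptake_fraction,
)


class TestGuvSimulation:
    def test_zero_recruitment_uniform_background_gives_flat_protein_channel(self):
        spec = GuvSimSpec(
            image_shape=(80, 80),
            vesicles=[(40.0, 40.0, 15.0)],
            membrane_sigma=3.0,
            kinetics=RecruitmentKinetics(model="constant", value=0.0),
            lumen_background=4.0,
            exterior_background=4.0,
            noise_sigma=0.0,
            frame_times_min=[0.0, 5.0],
        )
        res = simulate_guv_timelapse(spec)
        assert_allclose(res.stack.protein, 4.0)
        assert_allclose(res.truth["truth_value"], 0.0)

    def test_full_recruitment_truth_is_ring_mask_mean_of_profile(self):
        spec = GuvSimSpec(
            image_shape=(80, 80),
            vesicles=[(40.0, 40.0, 15.0)],
            membrane_sigma=3.0,
            protein_amplitude=50.0,
            kinetics=RecruitmentKinetics(model="constant", value=1.0),
            lumen_background=0.0,
            exterior_background=0.0,
            noise_sigma=0.0,
            frame_times_min=[0.0, 10.0],
        )
        res = simulate_guv_timelapse(spec)
        ring = res.ring_labels == 1
        expected = res.stack.protein[0][ring].mean()
        assert_allclose(res.truth["truth_value"], expected, rtol=1e-12)
        # constant kinetics: trajectory flat
        v = res.truth.groupby("frame")["truth_value"].first()
        assert_allclose(v.iloc[0], v.iloc[1], rtol=1e-12)

    def test_exponential_rise_truth_matches_brute_force_pixel_loop(self):
        spec = GuvSimSpec(
            image_shape=(72, 72),
            vesicles=[(36.0, 36.0, 15.0)],
            membrane_sigma=3.0,
            protein_amplitude=80.0,
            kinetics=RecruitmentKinetics(model="exponential_rise", rate_per_min=0.1),
            lumen_background=1.0,
            exterior_background=3.0,
            noise_sigma=0.0,
            frame_times_min=[0.0, 5.0, 10.0, 15.0, 20.0, 25.0, 30.0, 35.0],
        )
        res = simulate_guv_timelapse(spec)
        for t, time in enumerate(spec.frame_times_min):
            frac = 1.0 - math.exp(-0.1 * time)
            total, count = 0.0, 0
            for i in range(72):
                for j in range(72):
                    d = math.hypot(i - 36.0, j - 36.0)
                    if abs(d - 15.0) <= 6.0:
                        ring_val = 80.0 * frac * math.exp(-((d - 15.0) ** 2) / 18.0)
                        bg = 1.0 if d < 15.0 else 3.0
                        total += ring_val + bg
                        count += 1
            expected = total / count - 2.0
            got = res.truth[
                (res.truth["vesicle_id"] == 1) & (res.truth["frame"] == t)
            ]["truth_value"].iloc[0]
            assert got == pytest.approx(expected, rel=1e-10)

    def test_truth_proportional_to_exponential_rise(self):
        spec = GuvSimSpec(
            kinetics=RecruitmentKinetics(model="exponential_rise", rate_per_min=0.1),
            lumen_background=2.0,
            exterior_background=2.0,
            noise_sigma=0.0,
        )
        res = simulate_guv_timelapse(spec)
        t = np.asarray(spec.frame_times_min)
        expected_shape = 1.0 - np.exp(-0.1 * t)
        v = res.truth.sort_values("frame")["truth_value"].to_numpy()
        scale = v[-1] / expected_shape[-1]
        assert_allclose(v, scale * expected_shape, rtol=1e-10, atol=1e-12)

    def test_same_seed_bit_identical(self):
        spec = GuvSimSpec(noise_sigma=5.0, seed=42)
        a = simulate_guv_timelapse(spec)
        b = simulate_guv_timelapse(spec)
        assert np.array_equal(a.stack.membrane, b.stack.membrane)
        assert np.array_equal(a.stack.protein, b.stack.protein)
        pd.testing.assert_frame_equal(a.truth, b.truth)

    def test_noiseless_total_intensity_matches_analytic_integral(self):
        r, sigma = 20.0, 3.0
        spec = GuvSimSpec(
            image_shape=(128, 128),
            vesicles=[(64.0, 64.0, r)],
            membrane_sigma=sigma,
            protein_amplitude=100.0,
            kinetics=RecruitmentKinetics(model="constant", value=1.0),
            lumen_background=2.0,
            exterior_background=6.0,
            noise_sigma=0.0,
            frame_times_min=[0.0],
        )
        res = simulate_guv_timelapse(spec)
        total = res.stack.protein[0].sum()
        ring_integral = 2 * np.pi * (
            sigma**2 * np.exp(-(r**2) / (2 * sigma**2))
            + r * sigma * np.sqrt(2 * np.pi) * norm.cdf(r / sigma)
        )
        lumen_area = np.pi * r**2
        analytic = (
            100.0 * ring_integral
            + 2.0 * lumen_area
            + 6.0 * (128 * 128 - lumen_area)
        )
        assert total == pytest.approx(analytic, rel=0.005)

    def test_overlapping_vesicles_rejected(self):
        with pytest.raises(ValidationError, match="overlap"):
            GuvSimSpec(
                image_shape=(128, 128),
                vesicles=[(40.0, 40.0, 15.0), (40.0, 70.0, 15.0)],
                membrane_sigma=3.0,
            )

    def test_recruitment_fraction_outside_unit_interval_rejected(self):
        with pytest.raises(ValidationError):
            RecruitmentKinetics(model="constant", value=1.5)

    def test_radius_below_three_sigma_rejected(self):
        with pytest.raises(ValidationError, match="membrane_sigma"):
            GuvSimSpec(vesicles=[(64.0, 64.0, 9.0)], membrane_sigma=3.5)


class TestBeadSimulation:
    def test_noiseless_two_level_image(self):
        outlines = disc_outlines([(30.0, 30.0)], 10.0, (64, 64))
        sim = simulate_bead_image(10.0, 2.0, outlines, (64, 64))
        assert sim.true_means == {1: 10.0}
        assert not sim.degenerate
        assert_allclose(sim.image[outlines[0].mask], 10.0)
        assert_allclose(sim.image[~outlines[0].mask], 2.0)

    def test_no_contrast_sets_degenerate_flag(self):
        outlines = disc_outlines([(30.0, 30.0)], 8.0, (64, 64))
        sim = simulate_bead_image(5.0, 5.0, outlines, (64, 64))
        assert sim.degenerate

    def test_noisy_bead_means_within_standard_error_bound(self):
        shape = (96, 200)
        outlines = disc_outlines([(48.0, 35.0), (48.0, 100.0), (48.0, 165.0)], 12.0, shape)
        sim = simulate_bead_image(10.0, 2.0, outlines, shape, noise_sigma=0.5, seed=7)
        for o in outlines:
            n = o.mask.sum()
            assert sim.image[o.mask].mean() == pytest.approx(
                10.0, abs=3 * 0.5 / np.sqrt(n)
            )

    def test_outline_beyond_image_rejected(self):
        with pytest.raises(ValueError, match="beyond"):
            disc_outlines([(5.0, 5.0)], 10.0, (64, 64))


class TestHdxSimulation:
    def _spec(self, **kwargs):
        defaults = dict(
            peptides=[
                HdxPeptide(
                    protein="P", start=10, end=20, n_sites=5, base_mass_da=1200.0
                )
            ],
            site_rates={"apo": [0.01]},
            retention=0.8,
            timepoints_s=[0.0, 60.0, 60000.0],
            replicate_noise_sigma_da=0.0,
            n_replicates=3,
        )
        defaults.update(kwargs)
        return HdxSimSpec(**defaults)

    def test_time_zero_masses_equal_base_mass(self):
        res = simulate_hdx_experiment(self._spec())
        rows = res.records[
            (res.records["condition"] == "apo") & (res.records["timepoint_s"] == 0.0)
        ]
        assert_allclose(rows["centroid_mass_da"], 1200.0)
        un = res.records[res.records["condition"] == "unexchanged"]
        assert_allclose(un["centroid_mass_da"], 1200.0)

    def test_saturation_reaches_full_label(self):
        spec = self._spec(site_rates={"apo": [1.0]})
        res = simulate_hdx_experiment(spec)
        truth = res.truth[
            (res.truth["timepoint_s"] == 60000.0) & (res.truth["condition"] == "apo")
        ]
        assert_allclose(truth["percentD_true"], 100.0)
        rows = res.records[
            (res.records["condition"] == "apo")
            & (res.records["timepoint_s"] == 60000.0)
        ]
        assert_allclose(
            rows["centroid_mass_da"], 1200.0 + 5 * 0.8 * DEUTERON_MASS_SHIFT_DA
        )

    def test_closed_form_uptake_fraction_matches_numeric_site_sum(self):
        # N=5 identical sites at k=0.01/s, t=60 s: f = 1 - exp(-0.6)
        f_closed = 1.0 - math.exp(-0.6)
        f_numeric = sum(1.0 - math.exp(-0.01 * 60.0) for _ in range(5)) / 5.0
        assert uptake_fraction(np.full(5, 0.01), 60.0) == pytest.approx(f_closed)
        assert f_numeric == pytest.approx(f_closed)
        res = simulate_hdx_experiment(self._spec())
        got = res.truth[
            (res.truth["condition"] == "apo") & (res.truth["timepoint_s"] == 60.0)
        ]["percentD_true"].iloc[0]
        assert got == pytest.approx(45.1188, abs=1e-3)

    def test_missing_maxlabel_timepoint_rejected(self):
        with pytest.raises(ValidationError, match="maximally-labeled"):
            self._spec(timepoints_s=[6.0, 60.0])

    def test_replicate_noise_deterministic_under_seed(self):
        spec = self._spec(replicate_noise_sigma_da=0.05, seed=3)
        a = simulate_hdx_experiment(spec)
        b = simulate_hdx_experiment(spec)
        pd.testing.assert_frame_equal(a.records, b.records)


class TestIsotopeEnvelope:
    @pytest.mark.parametrize("p,expected_peaks", [(0.0, 1), (1.0, 1)])
    def test_degenerate_incorporation_gives_single_peak(self, p, expected_peaks):
        env = simulate_isotope_envelope(1000.0, 8, p)
        assert np.count_nonzero(env.weights > 1e-12) == expected_peaks
        expected_centroid = 1000.0 + p * 8 * DEUTERON_MASS_SHIFT_DA
        assert env.true_centroid_mass_da == pytest.approx(expected_centroid)

    def test_binomial_mean_centroid(self):
        env = simulate_isotope_envelope(1000.0, 10, 0.3)
        assert env.true_centroid_mass_da == pytest.approx(
            1000.0 + 3 * DEUTERON_MASS_SHIFT_DA
        )
        assert env.true_centroid_mass_da == pytest.approx(1003.019, abs=1e-3)

    def test_binomial_weights_normalized(self):
        env = simulate_isotope_envelope(800.0, 12, 0.42)
        assert env.weights.sum() == pytest.approx(1.0, abs=1e-12)


class TestFilamentSimulation:
    def test_straight_line_length(self):
        spec = FilamentSimSpec(
            curve=LineCurve(start=(64.0, 14.0), end=(64.0, 114.0)),
            pixel_size_nm=1.0,
        )
        res = simulate_filament(spec)
        assert res.arc_length_nm == pytest.approx(100.0)
        assert res.end_to_end_nm == pytest.approx(100.0)

    def test_semicircular_arc_length(self):
        spec = FilamentSimSpec(
            curve=ArcCurve(center=(50.0, 64.0), radius=50.0, theta_start=0.0,
                           theta_end=np.pi),
            pixel_size_nm=0.88,
        )
        res = simulate_filament(spec)
        assert res.arc_length_nm == pytest.approx(np.pi * 50.0 * 0.88, rel=1e-12)
        assert res.arc_length_nm == pytest.approx(138.23, abs=0.01)

    def test_sinusoid_length_matches_quadrature(self):
        curve = SinusoidCurve(
            origin=(64.0, 14.0), amplitude_px=10.0, wavelength_px=100.0, span_px=100.0
        )
        spec = FilamentSimSpec(curve=curve, image_shape=(128, 160))
        res = simulate_filament(spec)
        c = 2 * np.pi * 10.0 / 100.0
        integral, _ = quad(
            lambda x: np.sqrt(1 + c**2 * np.cos(2 * np.pi * x / 100.0) ** 2),
            0.0,
            100.0,
        )
        assert res.arc_length_nm == pytest.approx(integral * 0.88, rel=1e-6)

    def test_curve_outside_margin_rejected(self):
        spec = FilamentSimSpec(
            curve=LineCurve(start=(2.0, 2.0), end=(64.0, 64.0)), tube_sigma=2.0
        )
        with pytest.raises(ValueError, match="margin"):
            simulate_filament(spec)

    def test_peak_intensity_on_centerline(self):
        spec = FilamentSimSpec(
            curve=LineCurve(start=(64.0, 20.0), end=(64.0, 100.0)), amplitude=100.0
        )
        res = simulate_filament(spec)
        assert res.image[64, 60] == pytest.approx(100.0, rel=1e-6)
        assert res.image.max() <= 100.0 + 1e-9
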