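"""Three-cube FRET quantification and FA summaries."""

import numpy as np
import pytest

from tsmod.errors import EstimationError, InvalidInputError
from tsmod.quantify import (ACCEPTOR_GATES, CorrectionSet, ImageTriplet,
                            corrected_fret, efficiency_map,
                            estimate_bleedthrough, estimate_g_factor,
                            extract_axial_profiles, line_scan_slope,
                            summarize_fas, threshold_segment)
from tsmod.synth import (ImagingSpec, make_bleedthrough_reference,
                         make_gradient_fa_image, make_image_triplet)


def flat_triplet(ia, i_f, i_d, shape=(16, 16)):
    mk = lambda v: np.full(shape, float(v))
    return ImageTriplet(mk(ia), mk(i_f), mk(i_d))


class TestBleedthrough:
    def test_constructed_donor_ratio(self):
        rng = np.random.default_rng(0)
        i_d = rng.uniform(100, 5000, (64, 64))
        trip = ImageTriplet(np.zeros_like(i_d), 0.6 * i_d, i_d)
        assert estimate_bleedthrough([trip], "donor") == pytest.approx(0.6)

    def test_acceptor_ratio_noise_free_limit(self):
        spec = ImagingSpec(abt=0.25)
        trip = make_bleedthrough_reference(spec, "acceptor")
        assert estimate_bleedthrough([trip], "acceptor") == pytest.approx(
            0.25, abs=1e-12)

    def test_zero_fret_channel_gives_zero(self):
        trip = flat_triplet(0.0, 0.0, 1000.0)
        assert estimate_bleedthrough([trip], "donor") == 0.0

    def test_empty_reference_rejected(self):
        trip = flat_triplet(0.0, 10.0, 0.0)
        with pytest.raises(EstimationError):
            estimate_bleedthrough([trip], "donor")


class TestCorrectedFret:
    def test_zero_corrections_identity(self):
        trip = flat_triplet(300.0, 120.0, 500.0)
        np.testing.assert_array_equal(
            corrected_fret(trip, CorrectionSet(0.0, 0.0, 1.0)), trip.fret)

    def test_pure_bleedthrough_cancels_exactly(self):
        dbt, abt = 0.12, 0.08
        trip = flat_triplet(400.0, dbt * 600.0 + abt * 400.0, 600.0)
        fc = corrected_fret(trip, CorrectionSet(dbt, abt, 1.0))
        np.testing.assert_allclose(fc, 0.0, atol=1e-9)

    def test_generator_ground_truth_recovered(self):
        spec = ImagingSpec()
        trip, _, truth = make_image_triplet(spec)
        fc = corrected_fret(trip, CorrectionSet(spec.dbt, spec.abt, 1.0))
        np.testing.assert_allclose(fc, truth["fc_true"], atol=1e-8)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(InvalidInputError):
            ImageTriplet(np.zeros((4, 4)), np.zeros((4, 5)), np.zeros((4, 4)))


class TestEfficiencyMap:
    def test_algebraic_midpoints(self):
        g = 2.0
        trip = flat_triplet(100.0, 0.0, 500.0)
        # Fc = 0 -> E = 0
        emap = efficiency_map(trip, CorrectionSet(0.0, 0.0, g))
        np.testing.assert_allclose(emap.efficiency, 0.0)
        # Fc = G*Id -> E = 0.5
        trip2 = flat_triplet(0.0, g * 500.0, 500.0)
        emap2 = efficiency_map(trip2, CorrectionSet(0.0, 0.0, g))
        np.testing.assert_allclose(emap2.efficiency, 0.5)

    def test_noiseless_round_trip(self):
        spec = ImagingSpec()
        trip, _, truth = make_image_triplet(spec)
        emap = efficiency_map(trip, CorrectionSet(spec.dbt, spec.abt,
                                                  spec.g_factor))
        np.testing.assert_allclose(emap.efficiency,
                                   truth["efficiency_field"], atol=1e-6)

    def test_gates_invalidate_pixels(self):
        spec = ImagingSpec(acceptor_scale=500.0)
        trip, _, _ = make_image_triplet(spec)
        emap = efficiency_map(trip, CorrectionSet(spec.dbt, spec.abt,
                                                  spec.g_factor),
                              gates=ACCEPTOR_GATES["clover-mruby2"])
        assert not emap.valid_mask.any()
        assert np.isnan(emap.efficiency).all()

    def test_negative_fc_flagged_not_clipped(self):
        trip = flat_triplet(1000.0, 10.0, 1000.0)
        emap = efficiency_map(trip, CorrectionSet(0.2, 0.2, 2.0))
        assert emap.negative_mask.all()
        assert np.all(emap.efficiency < 0)


class TestGFactor:
    def test_three_construct_recovery(self):
        spec = ImagingSpec()
        constructs = []
        for i, e in enumerate((0.15, 0.3, 0.45)):
            t, _, _ = make_image_triplet(
                ImagingSpec(efficiencies=(e,), background_efficiency=e,
                            seed=i))
            constructs.append((t, e))
        g = estimate_g_factor(constructs,
                              CorrectionSet(spec.dbt, spec.abt, 1.0))
        assert g == pytest.approx(spec.g_factor, rel=0.01)

    def test_identical_efficiencies_rejected(self):
        t, _, _ = make_image_triplet(ImagingSpec(efficiencies=(0.3,),
                                                 background_efficiency=0.3))
        with pytest.raises(EstimationError):
            estimate_g_factor([(t, 0.3), (t, 0.3)],
                              CorrectionSet(0.12, 0.08, 1.0))


class TestFaSummaries:
    @pytest.fixture(scope="class")
    def labelled_map(self):
        spec = ImagingSpec()
        trip, labels, truth = make_image_triplet(spec)
        emap = efficiency_map(trip, CorrectionSet(spec.dbt, spec.abt,
                                                  spec.g_factor))
        return trip, labels, emap, truth

    def test_uniform_blob_mean(self, labelled_map):
        trip, labels, emap, truth = labelled_map
        recs = summarize_fas(emap, labels, trip)
        by_label = {r.label: r for r in recs}
        for lbl in np.unique(labels[labels > 0]):
            expected = truth["efficiency_field"][labels == lbl].mean()
            assert by_label[int(lbl)].mean_efficiency == pytest.approx(
                expected, abs=1e-9)

    def test_area_filter_drops_small_fas(self, labelled_map):
        trip, labels, emap, _ = labelled_map
        areas = [r.area_um2 for r in summarize_fas(emap, labels, trip)]
        cut = sorted(areas)[1]  # keep all but the smallest
        kept = summarize_fas(emap, labels, trip, min_area_um2=cut + 1e-9)
        assert len(kept) == len(areas) - sum(a <= cut for a in areas)

    def test_above_unloaded_flag(self, labelled_map):
        trip, labels, emap, truth = labelled_map
        recs = summarize_fas(emap, labels, trip, e_unloaded=0.25)
        flagged = {r.label for r in recs if r.flag_above_unloaded}
        expected = {i + 1 for i, e in enumerate((0.1, 0.2, 0.3)) if e > 0.25}
        assert flagged == expected

    def test_empty_mask_warns(self, labelled_map):
        trip, labels, emap, _ = labelled_map
        with pytest.warns(UserWarning):
            recs = summarize_fas(emap, np.zeros_like(labels), trip)
        assert recs == []

    def test_threshold_segmenter_finds_blobs(self):
        spec = ImagingSpec(donor_scale=1000.0)
        trip, labels, _ = make_image_triplet(spec)
        found = threshold_segment(trip.donor.max() - trip.donor + 1.0)
        assert found.max() >= 1


class TestLineScanSlope:
    def test_uniform_profile_zero_slope(self):
        assert line_scan_slope([np.full(20, 0.2)]) == pytest.approx(0.0,
                                                                    abs=1e-9)

    def test_constructed_linear_gradient(self):
        profs = [np.linspace(0.10, 0.25, n) for n in (10, 20, 35)]
        assert line_scan_slope(profs) == pytest.approx(15.0, abs=1e-6)

    def test_sign_convention(self):
        rising = line_scan_slope([np.linspace(0.1, 0.2, 15)])
        falling = line_scan_slope([np.linspace(0.2, 0.1, 15)])
        assert rising > 0 > falling

    def test_short_profiles_skipped_with_warning(self):
        with pytest.warns(UserWarning):
            slope = line_scan_slope([np.array([0.1, 0.2]),
                                     np.linspace(0.1, 0.2, 10)])
        assert slope == pytest.approx(10.0, abs=1e-6)

    def test_gradient_phantom_round_trip(self):
        emap, labels, truth = make_gradient_fa_image(
            n_fas=8, slope_percent_per_fa=15.0, seed=2)
        profs = extract_axial_profiles(emap, labels)
        assert len(profs) == 8
        assert line_scan_slope(profs) == pytest.approx(15.0, abs=0.1)
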