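import numpy as np
import pytest

from duospot.optics import CameraGeometry
from duospot.simulate import (DetectionSlab, FilterConfig, N_A, NoiseSpec,
                              cluster_fraction, cluster_spec, default_species,
                              er_streptavidin_spec, expected_emitters,
                              render_frame, sample_spot_intensities,
                              simulate_dilution_series, simulate_dose_response,
                              simulate_stack, tm_biotin_spec, true_pair_counts)

from conftest import conc_for_mean


class TestExpectedEmitters:
    def test_ten_picomolar_in_a_picoliter_is_six_particles(self):
        assert expected_emitters(10e-12, 1000.0) == pytest.approx(6.02, abs=0.01)

    def test_one_nanomolar_in_a_femtoliter(self):
        assert expected_emitters(1e-9, 1.0) == pytest.approx(0.602, abs=0.001)

    def test_zero_concentration_gives_zero(self):
        assert expected_emitters(0.0, 12345.0) == 0.0

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            expected_emitters(-1e-12, 100.0)
        with pytest.raises(ValueError):
            expected_emitters(1e-12, 0.0)


class TestSpeciesPatterns:
    def test_longpass_spot_multiplicities(self, lp_filter):
        # under the 600 nm long-pass: singles have 1 spot, the cluster 2
        assert tm_biotin_spec(lp_filter).n_spots == 1
        assert er_streptavidin_spec(lp_filter).n_spots == 1
        cl = cluster_spec(lp_filter)
        assert cl.n_spots == 2
        (r1, c1, _), (r2, c2, _) = cl.spot_offsets_px
        assert np.hypot(r2 - r1, c2 - c1) == pytest.approx(6.5)

    def test_full_spectrum_patterns(self):
        full = FilterConfig("full")
        assert tm_biotin_spec(full).n_spots == 2
        assert er_streptavidin_spec(full).n_spots == 2
        assert cluster_spec(full).n_spots == 4
        (r1, c1, _), (r2, c2, _) = tm_biotin_spec(full).spot_offsets_px
        assert np.hypot(r2 - r1, c2 - c1) == pytest.approx(30.2)

    def test_invalid_species_parameters_rejected(self, lp_filter):
        with pytest.raises(ValueError):
            tm_biotin_spec(lp_filter, monomer_fraction=1.5)

    def test_filter_passband(self):
        lp = FilterConfig("longpass", cutoff_nm=600.0)
        assert lp.passes(660) and lp.passes(802) and not lp.passes(554)
        bp = FilterConfig("bandpass", center_nm=475, half_width_nm=25,
                          cutoff_nm=None)
        assert bp.passes(460) and not bp.passes(560)
        with pytest.raises(ValueError):
            FilterConfig("bandpass", center_nm=475, half_width_nm=-1)


class TestDetectionSlab:
    def test_default_slab_volume_matches_disc_arithmetic(self):
        slab = DetectionSlab()
        assert slab.volume_fL == pytest.approx(6774, abs=1)

    def test_slab_for_geometry_uses_field_width(self, small_geom):
        slab = DetectionSlab.for_geometry(small_geom)
        assert slab.disc_diameter_um == pytest.approx(256 * 6.5 / 60)


class TestRenderFrame:
    def test_blank_frame_is_pure_background(self, small_geom, lp_filter,
                                            small_slab):
        spec = cluster_spec(lp_filter)
        frame, truth = render_frame([(spec, 0.0)], small_slab, small_geom,
                                    lp_filter, rng=1)
        assert len(truth) == 0
        assert frame.mean() == pytest.approx(100.0, abs=1.0)
        assert frame.std() == pytest.approx(np.sqrt(100 + 4), rel=0.1)

    def test_photon_conservation_truth_vs_rendered_signal(self, small_geom,
                                                          lp_filter,
                                                          small_slab):
        # the truth photon column must equal the pre-noise signal sum exactly
        spec = cluster_spec(lp_filter)
        c = conc_for_mean(10.0, small_slab.volume_fL)
        _, truth, signal = render_frame([(spec, c)], small_slab, small_geom,
                                        lp_filter, rng=3, return_signal=True)
        assert len(truth) > 0
        assert (truth.photons >= 0).all()
        assert signal.sum() == pytest.approx(truth.photons.sum(), rel=1e-12)

    def test_emitters_confined_to_field_disc(self, small_geom, lp_filter,
                                             small_slab):
        spec = cluster_spec(lp_filter)
        c = conc_for_mean(30.0, small_slab.volume_fL)
        _, truth = render_frame([(spec, c)], small_slab, small_geom,
                                lp_filter, rng=5)
        center = (small_geom.frame_size_px - 1) / 2
        r = np.hypot(truth.row - center, truth.col - center)
        assert (r <= small_geom.frame_size_px / 2 + 1e-9).all()

    def test_negative_concentration_rejected(self, small_geom, lp_filter,
                                             small_slab):
        with pytest.raises(ValueError):
            render_frame([(cluster_spec(lp_filter), -1e-12)], small_slab,
                         small_geom, lp_filter, rng=0)


class TestStackStatistics:
    def test_same_seed_gives_bit_identical_stacks(self, small_geom, lp_filter,
                                                  small_slab):
        spec = cluster_spec(lp_filter)
        c = conc_for_mean(5.0, small_slab.volume_fL)
        s1, t1 = simulate_stack([(spec, c)], 4, small_slab, small_geom,
                                lp_filter, seed=7)
        s2, t2 = simulate_stack([(spec, c)], 4, small_slab, small_geom,
                                lp_filter, seed=7)
        assert np.array_equal(s1.frames, s2.frames)
        assert t1.photons.tolist() == t2.photons.tolist()

    def test_per_frame_counts_are_poisson(self, small_geom, lp_filter,
                                          small_slab):
        # index of dispersion (variance/mean) of true counts near 1
        spec = cluster_spec(lp_filter)
        mean_target = 6.0
        c = conc_for_mean(mean_target, small_slab.volume_fL)
        stack, truth = simulate_stack([(spec, c)], 400, small_slab,
                                      small_geom, lp_filter, seed=11)
        counts = true_pair_counts(truth, 400)
        assert counts.mean() == pytest.approx(mean_target, rel=0.15)
        iod = counts.var(ddof=1) / counts.mean()
        assert 0.8 <= iod <= 1.2

    def test_doubling_concentration_doubles_mean_count(self, small_geom,
                                                       lp_filter, small_slab):
        spec = cluster_spec(lp_filter)
        c = conc_for_mean(5.0, small_slab.volume_fL)
        _, t1 = simulate_stack([(spec, c)], 150, small_slab, small_geom,
                               lp_filter, seed=21)
        _, t2 = simulate_stack([(spec, 2 * c)], 150, small_slab, small_geom,
                               lp_filter, seed=22)
        m1 = true_pair_counts(t1, 150).mean()
        m2 = true_pair_counts(t2, 150).mean()
        se = np.sqrt(10.0 / 150 + 4 * 5.0 / 150)
        assert abs(m2 - 2 * m1) < 3 * se

    def test_monomer_fraction_of_rendered_emitters(self, small_geom,
                                                   lp_filter, small_slab):
        spec = er_streptavidin_spec(lp_filter)  # monomer fraction 0.81
        c = conc_for_mean(20.0, small_slab.volume_fL)
        _, truth = simulate_stack([(spec, c)], 100, small_slab, small_geom,
                                  lp_filter, seed=31)
        frac = (truth.n_mer == 1).mean()
        assert frac == pytest.approx(0.81, abs=0.03)


class TestDilutionSeries:
    def test_counts_proportional_to_concentration(self, small_geom,
                                                  small_slab):
        c1 = conc_for_mean(2.0, small_slab.volume_fL)
        series = simulate_dilution_series(
            [0.0, c1, 2 * c1, 4 * c1], 80, geom=small_geom, seed=3)
        means = [true_pair_counts(t, s.n_frames).mean() for s, t in series]
        assert means[0] == 0
        assert means[2] == pytest.approx(2 * means[1], rel=0.25)
        assert means[3] == pytest.approx(4 * means[1], rel=0.25)

    def test_zero_frames_gives_empty_stack_with_metadata(self, small_geom):
        series = simulate_dilution_series([0.0, 1e-12], 0, geom=small_geom)
        for stack, truth in series:
            assert stack.n_frames == 0
            assert len(truth) == 0
            assert "concentration_mol_per_L" in stack.metadata


class TestDoseResponse:
    def test_cluster_fraction_logistic_identities(self):
        p_max, p_bg, ic50, s = 0.9, 0.05, 17e-9, 1.5
        assert cluster_fraction(0.0, p_max, p_bg, ic50, s) == p_max
        assert cluster_fraction(1.0, p_max, p_bg, ic50, s) \
            == pytest.approx(p_bg, abs=1e-6)
        assert cluster_fraction(ic50, p_max, p_bg, ic50, s) \
            == pytest.approx((p_max + p_bg) / 2)

    def test_invalid_logistic_parameters_rejected(self):
        with pytest.raises(ValueError):
            cluster_fraction(1e-9, 0.5, 0.8, 17e-9, 1.5)  # p_bg > p_max
        with pytest.raises(ValueError):
            cluster_fraction(1e-9, 0.9, 0.1, -1.0, 1.5)

    def test_simulated_dose_response_suppresses_clusters(self, small_geom):
        levels = [0.0, 17e-9, 1e-5]
        out = simulate_dose_response(levels, frames_per_level=50,
                                     geom=small_geom, seed=9,
                                     base_concentration_mol_per_L=15e-12)
        counts = [true_pair_counts(t, s.n_frames).mean() for s, t in out]
        assert counts[0] > counts[1] > counts[2]
        assert out[0][0].metadata["cluster_fraction"] == pytest.approx(0.9)
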