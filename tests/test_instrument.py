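"""Virtual microscope: polarization physics, spectral synthesis, grid
scans and orientation handling."""

import numpy as np
import pytest

from ramandose import (Composition, GridSpec, make_axis, oriented_config,
                       polarization_factor, scan_roi, synthesize_spectrum)
from ramandose.instrument import (MicroscopeConfig, line_profile,
                                  noise_free_signal)
from ramandose.phantom import DomainError, ParameterError


class TestPolarizationFactor:
    def test_aligned_linear_is_unity(self):
        assert polarization_factor("linear", 0.7, 0.6, pol_angle=0.7) == \
            pytest.approx(1.0)

    def test_alpha_zero_isotropic(self):
        for angle in (0.0, 0.4, 1.5):
            assert polarization_factor("linear", angle, 0.0) == 1.0
            assert polarization_factor("circular", angle, 0.0) == 1.0

    def test_circular_closed_form(self):
        alpha = 0.37
        for angle in (0.0, 1.0, 3.0):
            assert polarization_factor("circular", angle, alpha) == \
                pytest.approx(1.0 - alpha / 2.0)

    def test_bounds(self):
        angles = np.linspace(0, np.pi, 50)
        f = polarization_factor("linear", angles, 0.8, pol_angle=0.3)
        assert np.all(f >= 0.2 - 1e-12) and np.all(f <= 1.0 + 1e-12)


class TestSynthesize:
    def test_zero_composition_zero_baseline_is_silent(self, bare_config):
        # laminate bands are composition-independent, so silence requires a
        # crystal-band-only table
        from dataclasses import replace
        from ramandose.instrument import PeakTable
        table = PeakTable(tuple(p for p in bare_config.peaks
                                if p.role != "laminate"))
        cfg = replace(bare_config, peaks=table)
        stack = synthesize_spectrum(Composition(0.0, 0.0, ()), 0.0,
                                    cfg, seed=0)
        assert np.all(stack.counts == 0.0)

    def test_noiseless_replicates_identical(self, bare_config):
        comp = Composition(0.001, 2.0, ((0.2, 2.0),))
        stack = synthesize_spectrum(comp, 1.0, bare_config, seed=0)
        assert stack.counts.shape[0] == bare_config.replicate_count
        assert np.all(stack.counts == stack.counts[0])
        assert np.allclose(stack.counts[0],
                           noise_free_signal(comp, bare_config))

    def test_expected_1445_count_formula_oracle(self, cfg_clean):
        # independent recomputation of the band sum at the 1445 channel
        comp = Composition(0.003, 2.5, ((0.4, 1.5), (1.2, 1.0)))
        signal = noise_free_signal(comp, cfg_clean)
        axis = cfg_clean.axis
        ch = int(np.argmin(np.abs(axis - 1445.0)))
        nu = axis[ch]
        total = comp.total_overlap
        angles = np.array([0.4, 1.2])
        weights = np.array([1.5, 1.0])
        alpha = cfg_clean.depol_contrast
        f = (1 - alpha) + alpha / 2.0  # circular
        mean_f = float(np.sum(f * weights) / total)
        expected = 0.0
        for pk in cfg_clean.peaks:
            if pk.role == "polymer":
                amp = pk.gain * comp.polymer_weight * mean_f
            elif pk.role == "monomer":
                amp = pk.gain * comp.monomer_weight * mean_f
            else:
                amp = pk.gain
            expected += amp * np.exp(
                -np.log(2.0) * ((nu - pk.center) / pk.half_width) ** 2)
        expected *= cfg_clean.photon_scale
        expected += cfg_clean.baseline_amplitude * np.exp(
            -(nu - axis[0]) / cfg_clean.baseline_decay)
        expected *= cfg_clean.response.sensitivity(np.array([nu]))[0]
        assert signal[ch] == pytest.approx(expected, rel=1e-9)

    def test_poisson_noise_variance_matches_mean(self):
        cfg = MicroscopeConfig(axis=make_axis(614.0, 2313.0, 2.0),
                               replicate_count=400, baseline_amplitude=0.0)
        comp = Composition(0.001, 2.0, ((0.2, 2.0),))
        stack = synthesize_spectrum(comp, 1.0, cfg, seed=3)
        mean = stack.counts.mean(axis=0)
        var = stack.counts.var(axis=0, ddof=1)
        big = mean > 100
        assert big.any()
        # variance/mean ratio ~ 1 for Poisson counts
        ratio = var[big].sum() / mean[big].sum()
        assert ratio == pytest.approx(1.0, abs=0.05)

    def test_cosmic_rays_are_large_and_seeded(self, bare_config):
        from dataclasses import replace
        cfg = replace(bare_config, cosmic_ray_rate=2.0, shot_noise=False)
        comp = Composition(0.001, 2.0, ((0.2, 2.0),))
        clean = noise_free_signal(comp, cfg)
        a = synthesize_spectrum(comp, 1.0, cfg, seed=5)
        b = synthesize_spectrum(comp, 1.0, cfg, seed=5)
        assert np.array_equal(a.counts, b.counts)
        spikes = a.counts - clean
        hit = spikes > 0
        assert hit.any()
        floor = np.maximum(clean, max(clean.mean(), 1.0))
        assert np.all(spikes[hit] >= 10.0 * np.broadcast_to(
            floor, a.counts.shape)[hit] * (1 - 1e-12))

    def test_negative_weights_rejected(self, bare_config):
        with pytest.raises(ParameterError):
            noise_free_signal(Composition(-1.0, 0.0, ()), bare_config)


class TestScanRoi:
    def test_spectra_count_10x10(self, film, cfg_clean):
        grid = GridSpec(nx=10, ny=10, pitch=11.0, origin=(11.0, 11.0))
        scan = scan_roi(film, cfg_clean, grid, 1.0, seed=1)
        assert scan.total_spectra == 500
        # node positions are origin + index * pitch
        px = scan.pixel(3, 7)
        assert (px.x, px.y) == (11.0 + 3 * 11.0, 11.0 + 7 * 11.0)

    def test_single_pixel_grid(self, film, cfg_clean):
        grid = GridSpec(nx=1, ny=1, pitch=5.0, origin=(50.0, 50.0))
        scan = scan_roi(film, cfg_clean, grid, 0.5, seed=2)
        assert scan.total_spectra == cfg_clean.replicate_count
        assert scan.pixels[0].x == 50.0

    def test_grid_exceeding_film_rejected(self, film, cfg_clean):
        grid = GridSpec(nx=30, ny=30, pitch=11.0)
        with pytest.raises(DomainError):
            scan_roi(film, cfg_clean, grid, 1.0, seed=0)

    def test_scan_determinism(self, film, cfg_noisy):
        grid = GridSpec(nx=2, ny=2, pitch=11.0, origin=(40.0, 40.0))
        a = scan_roi(film, cfg_noisy, grid, 1.0, seed=7)
        b = scan_roi(film, cfg_noisy, grid, 1.0, seed=7)
        for pa, pb in zip(a.pixels, b.pixels):
            assert np.array_equal(pa.counts, pb.counts)


class TestOrientation:
    def test_involution(self, cfg_noisy):
        from dataclasses import replace
        cfg = replace(cfg_noisy, polarization="linear", pol_angle=0.0)
        port = oriented_config(cfg, "portrait")
        assert port.pol_angle == pytest.approx(np.pi / 2)
        back = oriented_config(port, "portrait")
        assert back.pol_angle == pytest.approx(cfg.pol_angle)

    def test_circular_polarization_orientation_invariance(self, film,
                                                          cfg_clean):
        grid = GridSpec(nx=3, ny=3, pitch=11.0, origin=(40.0, 40.0))
        land = scan_roi(film, cfg_clean, grid, 2.0, seed=1,
                        orientation="landscape")
        port = scan_roi(film, cfg_clean, grid, 2.0, seed=1,
                        orientation="portrait")
        m_land = np.mean([p.counts.mean() for p in land.pixels])
        m_port = np.mean([p.counts.mean() for p in port.pixels])
        assert m_land == pytest.approx(m_port, rel=1e-3)

    def test_linear_polarization_landscape_exceeds_portrait(self, film,
                                                            cfg_clean):
        from dataclasses import replace
        cfg = replace(cfg_clean, polarization="linear", pol_angle=0.0)
        grid = GridSpec(nx=4, ny=4, pitch=11.0, origin=(30.0, 30.0))
        ch = int(np.argmin(np.abs(cfg.axis - 1445.0)))
        land = scan_roi(film, cfg, grid, 2.0, seed=1)
        port = scan_roi(film, cfg, grid, 2.0, seed=1,
                        orientation="portrait")
        m_land = np.mean([p.counts[0, ch] for p in land.pixels])
        m_port = np.mean([p.counts[0, ch] for p in port.pixels])
        assert m_land > m_port


def test_line_profiles_unit_height_and_width():
    axis = np.linspace(1400.0, 1500.0, 2001)
    for kind in ("gaussian", "lorentzian"):
        prof = line_profile(axis, 1445.0, 8.0, kind)
        assert prof.max() == pytest.approx(1.0, abs=1e-6)
        # half maximum at +- half_width
        at_hw = line_profile(np.array([1453.0]), 1445.0, 8.0, kind)[0]
        assert at_hw == pytest.approx(0.5, abs=1e-9)
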