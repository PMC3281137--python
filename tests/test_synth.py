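"""Phantom generator: basis construction, composition curves, forward model
statistics, and reference rendering."""

import logging

import numpy as np
import pytest

from cartchem.synth import (AcquisitionConfig, PhantomConfig,
                            make_basis_spectra, make_composition_phantom,
                            make_study_samples, render_od_reference,
                            render_spectral_image)


class TestBasisSpectra:
    def test_empty_component_gives_zero_absorptivity(self):
        basis = make_basis_spectra({"pg": [], "collagen": [], "paraffin": []})
        assert np.all(basis.pg_epsilon == 0)
        assert np.all(basis.collagen_epsilon == 0)
        assert np.all(basis.paraffin_epsilon == 0)

    def test_single_collagen_gaussian_argmax(self):
        grid = np.arange(900.0, 1801.0, 5.0)  # grid containing 1655 exactly
        basis = make_basis_spectra({"pg": [], "paraffin": [],
                                    "collagen": [(1655.0, 30.0, 1.0)]},
                                   wavenumbers=grid)
        assert grid[np.argmax(basis.collagen_epsilon)] == 1655.0

    def test_default_pg_carbohydrate_mass_matches_quadrature(self, basis, wavenumbers):
        # independent trapezoid quadrature of the Gaussian sum over 984-1140
        sel = (wavenumbers >= 984.0) & (wavenumbers <= 1140.0)
        wn = wavenumbers[sel]
        expected = 0.0
        vals = np.zeros_like(wn)
        for c, s, h in [(1062.0, 14.0, 1.0), (1374.0, 10.0, 0.5), (1080.0, 45.0, 0.5)]:
            vals = vals + h * np.exp(-0.5 * ((wn - c) / s) ** 2)
        for i in range(len(wn) - 1):
            expected += 0.5 * (vals[i] + vals[i + 1]) * (wn[i + 1] - wn[i])
        observed = np.trapezoid(basis.pg_epsilon[sel], wn)
        assert observed == pytest.approx(expected, rel=1e-12)

    def test_default_basis_invariants(self, basis, wavenumbers):
        for target in (1062.0, 1374.0):
            win = np.abs(wavenumbers - target) <= 8.0
            inner = basis.pg_epsilon[win]
            assert inner.max() > 0
        amide = (wavenumbers >= 1584.0) & (wavenumbers <= 1720.0)
        assert wavenumbers[np.argmax(basis.collagen_epsilon)] in wavenumbers[amide]
        carb = (wavenumbers >= 984.0) & (wavenumbers <= 1140.0)
        assert basis.collagen_epsilon[carb].sum() > 0
        outside = (wavenumbers < 1440.0) | (wavenumbers > 1480.0)
        assert np.all(basis.paraffin_epsilon[outside] == 0)
        assert basis.paraffin_epsilon.max() > 0

    def test_pg_without_required_peaks_rejected(self):
        with pytest.raises(ValueError, match="1374"):
            make_basis_spectra({"pg": [(1062.0, 10.0, 1.0)]})
        with pytest.raises(ValueError, match="1062"):
            make_basis_spectra({"pg": [(1374.0, 10.0, 1.0)]})

    def test_paraffin_outside_band_rejected(self):
        with pytest.raises(ValueError, match="paraffin"):
            make_basis_spectra({"paraffin": [(1500.0, 8.0, 1.0)]})


class TestCompositionPhantom:
    def test_zero_depletion_identical_to_control(self):
        a = make_composition_phantom(40, group="control", seed=3)
        b = make_composition_phantom(40, group="depleted", depletion_fraction=0.0, seed=3)
        np.testing.assert_array_equal(a.pg_profile, b.pg_profile)
        np.testing.assert_array_equal(a.collagen_profile, b.collagen_profile)

    def test_full_depletion_zero_pg(self):
        phantom = make_composition_phantom(40, group="depleted",
                                           depletion_fraction=1.0, seed=3)
        assert np.all(phantom.pg_profile == 0)

    def test_depleted_matches_control_below_boundary(self):
        control = make_composition_phantom(40, group="control", seed=11)
        depleted = make_composition_phantom(40, group="depleted",
                                            depletion_fraction=0.4, seed=11)
        deep = depleted.pg_profile > 0
        np.testing.assert_array_equal(depleted.pg_profile[deep],
                                      control.pg_profile[deep])
        assert deep.sum() < 40

    def test_control_plateau_surface_ratio_matches_parametric_curve(self):
        cfg = PhantomConfig(pg_level_sd=0.0, midpoint_jitter_um=0.0)
        phantom = make_composition_phantom(60, seed=0, config=cfg)
        depth = phantom.depth_um
        expected = cfg.pg_surface + (cfg.pg_plateau - cfg.pg_surface) / (
            1.0 + np.exp(-(depth - cfg.pg_midpoint_um) / cfg.pg_width_um))
        np.testing.assert_allclose(phantom.pg_profile, expected, rtol=1e-12)
        # rises from a depleted surface to a plateau
        assert phantom.pg_profile[-1] / phantom.pg_profile[0] > 4

    def test_collagen_nondecreasing_into_deep_zone(self, control_phantom):
        mid = len(control_phantom.collagen_profile) // 2
        assert np.all(np.diff(control_phantom.collagen_profile[mid:]) >= 0)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            make_composition_phantom(5)
        with pytest.raises(ValueError):
            make_composition_phantom(40, depletion_fraction=1.5)


class TestRenderSpectralImage:
    def test_zero_concentrations_zero_image(self, basis):
        phantom = make_composition_phantom(40, seed=0)
        phantom.pg_profile[:] = 0
        phantom.collagen_profile[:] = 0
        acq = AcquisitionConfig(noise_sd_single_scan=0.0, thickness_cv=0.0,
                                paraffin_level_max=0.0)
        image = render_spectral_image(phantom, basis, acq)
        assert np.all(image.absorbance == 0)

    def test_beer_lambert_linearity(self, basis, control_phantom, noiseless_acq):
        """Superposition: absorbance is linear in each concentration profile."""
        image = render_spectral_image(control_phantom, basis, noiseless_acq)
        doubled = make_composition_phantom(40, seed=7, sample_id="C01")
        doubled.pg_profile = 2.0 * doubled.pg_profile
        doubled.collagen_profile = 2.0 * doubled.collagen_profile
        image2 = render_spectral_image(doubled, basis, noiseless_acq)
        np.testing.assert_allclose(image2.absorbance, 2.0 * image.absorbance,
                                   rtol=1e-12, atol=1e-15)

    def test_scan_averaging_noise_ratio(self, basis):
        """Empirical noise SD for 8 vs 1 averaged scans ~ 1/sqrt(8) within 5%."""
        phantom = make_composition_phantom(50, seed=1)
        sds = {}
        for scans in (8, 1):
            acq = AcquisitionConfig(scans_per_pixel=scans, thickness_cv=0.0,
                                    paraffin_level_max=0.0,
                                    strip_width_um=25.0 * 16, seed=42)
            clean_acq = AcquisitionConfig(scans_per_pixel=scans,
                                          noise_sd_single_scan=0.0,
                                          thickness_cv=0.0, paraffin_level_max=0.0,
                                          strip_width_um=25.0 * 16)
            noisy = render_spectral_image(phantom, basis, acq).absorbance
            clean = render_spectral_image(phantom, basis, clean_acq).absorbance
            residual = (noisy - clean).ravel()[:10000]
            sds[scans] = residual.std()
        assert sds[8] / sds[1] == pytest.approx(1.0 / np.sqrt(8.0), rel=0.05)

    def test_seed_determinism(self, basis, control_phantom):
        acq = AcquisitionConfig(seed=9)
        a = render_spectral_image(control_phantom, basis, acq)
        b = render_spectral_image(control_phantom, basis, acq)
        np.testing.assert_array_equal(a.absorbance, b.absorbance)

    def test_ground_truth_recoverable_by_ols(self, basis, control_phantom, noiseless_acq):
        """With no noise or thickness variation, least squares onto the basis
        recovers the PG profile exactly (the oracle for downstream models)."""
        image = render_spectral_image(control_phantom, basis, noiseless_acq)
        spectra = image.absorbance[:, 0, :]
        A = np.stack([basis.pg_epsilon, basis.collagen_epsilon], axis=1)
        coefs, *_ = np.linalg.lstsq(A, spectra.T, rcond=None)
        np.testing.assert_allclose(coefs[0], control_phantom.pg_profile,
                                   rtol=1e-10, atol=1e-12)


class TestRenderODReference:
    def test_zero_pg_zero_od(self):
        phantom = make_composition_phantom(40, group="depleted",
                                           depletion_fraction=1.0, seed=0)
        od = render_od_reference(phantom, seed=0)
        assert np.all(od.od == 0)

    def test_noiseless_proportionality(self, control_phantom):
        od = render_od_reference(control_phantom, thickness_cv=0.0,
                                 od_scale=1.5, seed=0)
        expected = 1.5 * np.interp(od.depth_um, control_phantom.depth_um,
                                   control_phantom.pg_profile)
        np.testing.assert_allclose(od.od, np.clip(expected, 0, 3), rtol=1e-12)

    def test_section_averaging_residual_ratio(self, control_phantom):
        """Averaging 3 sections shrinks residual SD by ~1/sqrt(3) within 10%."""
        truth = render_od_reference(control_phantom, thickness_cv=0.0,
                                    od_scale=1.2, seed=0).od
        root = np.random.SeedSequence(77)
        resid = {}
        for n_sections in (3, 1):
            reps = []
            for child in root.spawn(600):
                od = render_od_reference(control_phantom, n_sections=n_sections,
                                         thickness_cv=0.10, od_scale=1.2,
                                         seed=np.random.default_rng(child))
                reps.append(od.od[-1] - truth[-1])
            resid[n_sections] = np.std(reps)
        assert resid[3] / resid[1] == pytest.approx(1 / np.sqrt(3), rel=0.10)

    def test_overrange_od_logged_and_clipped(self, control_phantom, caplog):
        with caplog.at_level(logging.WARNING, logger="cartchem.synth"):
            od = render_od_reference(control_phantom, thickness_cv=0.0,
                                     od_scale=10.0, seed=0)
        assert np.all(od.od <= 3.0)
        assert any("clipping" in rec.message for rec in caplog.records)


def test_study_samples_seed_determinism_and_layout():
    a = make_study_samples(n_per_group=2, seed=4, n_depth=15)
    b = make_study_samples(n_per_group=2, seed=4, n_depth=15)
    assert [s.image.sample_id for s in a] == ["C01", "C02", "E01", "E02"]
    for x, y in zip(a, b):
        np.testing.assert_array_equal(x.image.absorbance, y.image.absorbance)
        np.testing.assert_array_equal(x.od.od, y.od.od)
    depleted = a[2]
    n_sup = int(0.35 * 15)
    assert np.all(depleted.phantom.pg_profile[:n_sup] == 0)
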