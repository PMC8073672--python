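"""The synthetic phantom generator: contrast sign structure, analytic
iso-point, depth monotonicity, determinism, and fixture output."""

import numpy as np
import pytest

from conftest import render
from hsdepth import (
    AbsorberSpec,
    AcquisitionSpec,
    InclusionGeometry,
    analytic_iso_wavelength,
    canonical_scene,
    contrast,
    make_fixture_suite,
    simulate_cube,
)
from hsdepth.errors import InvalidGeometryError
from hsdepth.phantom import BOUNDARY_CONCENTRATION, DEPTH_SENTINEL


def centre_line(truth):
    """(x, y) pixel indices of the inclusion axis, one per scan line."""
    out = []
    for y in range(truth.inclusion_mask.shape[1]):
        xs = np.nonzero(truth.inclusion_mask[:, y])[0]
        if len(xs):
            out.append((xs[len(xs) // 2], y))
    return out


class TestContrast:
    def test_water_filling_never_crosses_zero(self):
        inc = InclusionGeometry(absorber=AbsorberSpec(concentration=0.0))
        lam = np.linspace(407, 670, 200)
        assert np.all(contrast(inc, lam) > 0)
        assert analytic_iso_wavelength(inc, (407, 670)) is None

    def test_strong_ink_crosses_once_near_575(self):
        inc = InclusionGeometry(absorber=AbsorberSpec(concentration=0.10))
        lam = np.linspace(407, 670, 2000)
        c = contrast(inc, lam)
        assert np.sum(c[:-1] * c[1:] < 0) == 1
        iso = analytic_iso_wavelength(inc, (407, 670))
        assert 560 < iso < 590

    def test_boundary_concentration_touches_without_crossing(self):
        inc = InclusionGeometry(absorber=AbsorberSpec(concentration=BOUNDARY_CONCENTRATION))
        lam = np.linspace(407, 670, 2000)
        c = contrast(inc, lam)
        assert np.min(np.abs(c)) < 1e-12
        assert np.all(c > -1e-12)
        assert analytic_iso_wavelength(inc, (407, 670)) is None


class TestSimulateCube:
    def test_water_inclusion_brighter_than_background_everywhere(self, clear_nf):
        """With no absorber the inclusion only scatters: brighter at all bands."""
        raw, _, truth = clear_nf
        assert truth.iso_wavelength_analytic is None
        (xc, yc) = centre_line(truth)[2]
        background_pixel = raw.values[0, yc, :]
        assert np.all(raw.values[xc, yc, :] > background_pixel)

    def test_iso_band_reflectance_depth_invariant(self):
        """At the analytic crossover, noise-free reflectance over the
        inclusion does not vary with cover depth."""
        raw, _, truth = render("absorbing", noise=0.0, seed=0)
        iso = truth.iso_wavelength_analytic
        band = int(np.argmin(np.abs(raw.wavelengths - iso)))
        vals = np.array([raw.values[x, y, band] for x, y in centre_line(truth)])
        assert np.std(vals) / np.mean(vals) < 2e-4

    def test_sign_structure_around_crossover(self, absorbing_nf):
        """Absorption side: darker when closer (reflectance rises with
        depth); scattering side: brighter when closer (falls with depth)."""
        raw, _, truth = absorbing_nf
        line = centre_line(truth)
        depths = np.array([truth.depth_map[x, y] for x, y in line])
        order = np.argsort(depths)
        shallow, deep = line[order[5]], line[order[40]]
        band_abs = int(np.argmin(np.abs(raw.wavelengths - 530)))
        band_sct = int(np.argmin(np.abs(raw.wavelengths - 650)))
        assert raw.values[shallow[0], shallow[1], band_abs] < raw.values[deep[0], deep[1], band_abs]
        assert raw.values[shallow[0], shallow[1], band_sct] > raw.values[deep[0], deep[1], band_sct]

    def test_perturbation_decays_with_depth(self, absorbing_nf):
        """|R − R0| strictly decreases with cover depth at a contrasted band."""
        raw, _, truth = absorbing_nf
        band = int(np.argmin(np.abs(raw.wavelengths - 530)))
        r0 = raw.values[0, 0, band]  # background pixel, noise-free
        line = centre_line(truth)
        depths = np.array([truth.depth_map[x, y] for x, y in line])
        keep = depths <= 6.0
        perturb = np.array([abs(raw.values[x, y, band] - r0) for x, y in line])[keep]
        order = np.argsort(depths[keep])
        assert np.all(np.diff(perturb[order]) < 0)

    def test_no_inclusion_gives_uniform_background(self):
        raw, _, truth = render("none", noise=0.0)
        assert not truth.inclusion_mask.any()
        assert np.all(truth.depth_map == DEPTH_SENTINEL)
        # every pixel carries the identical background spectrum
        assert np.all(raw.values == raw.values[0, 0, :][None, None, :])

    def test_depth_map_matches_affine_ramp(self, absorbing_nf):
        _, _, truth = absorbing_nf
        line = centre_line(truth)
        depths = np.array([truth.depth_map[x, y] for x, y in line])
        ys = np.array([y for _, y in line])
        resid = np.polyval(np.polyfit(ys, depths, 1), ys) - depths
        assert np.max(np.abs(resid)) < 1e-6

    def test_generator_determinism(self):
        a = render("absorbing", noise=0.01, seed=7)[0]
        b = render("absorbing", noise=0.01, seed=7)[0]
        assert np.array_equal(a.values, b.values)

    def test_seed_changes_noise(self):
        a = render("absorbing", noise=0.01, seed=7)[0]
        b = render("absorbing", noise=0.01, seed=8)[0]
        assert not np.array_equal(a.values, b.values)

    def test_inclusion_outside_scene_rejected(self):
        substrate, _, acq = canonical_scene("absorbing", n_x=31, n_y=60)
        bad = InclusionGeometry(entry_point=(-5.0, 0.0, 0.0), exit_point=(1.0, 1.0, 5.0))
        with pytest.raises(InvalidGeometryError):
            simulate_cube(substrate, bad, acq)

    def test_cube_shape_follows_acquisition_spec(self):
        raw, ref, _ = render("absorbing", n_x=17, n_y=40, band_sampling_nm=2.0)
        n_bands = int(round((670 - 407) / 2.0)) + 1
        assert raw.shape == (17, 40, n_bands)
        assert ref.shape == raw.shape

    def test_native_spec_has_950_bands(self):
        acq = AcquisitionSpec()
        assert len(acq.wavelengths) == 950
        assert acq.wavelengths[0] == 407.0 and acq.wavelengths[-1] == 670.0


class TestFixtureSuite:
    def test_suite_is_deterministic_and_complete(self, tmp_path):
        kw = dict(n_x=17, n_y=48, band_sampling_nm=4.0)
        first = make_fixture_suite(3, tmp_path / "a", **kw)
        second = make_fixture_suite(3, tmp_path / "b", **kw)
        assert set(first) == {"clear", "boundary", "absorbing"}
        for kind in first:
            for key in ("cube", "cube_header", "reference", "truth", "config"):
                assert first[kind][key].read_bytes() == second[kind][key].read_bytes()

    def test_boundary_scene_contrast_touches_zero(self, tmp_path):
        paths = make_fixture_suite(0, tmp_path, n_x=17, n_y=48, band_sampling_nm=4.0)
        cfg = dict(
            line.split(" = ")
            for line in paths["boundary"]["config"].read_text().strip().splitlines()
        )
        assert cfg["iso_wavelength_analytic"] == "none"
        inc = InclusionGeometry(absorber=AbsorberSpec(concentration=float(cfg["concentration"])))
        lam = np.linspace(407, 670, 1000)
        assert np.min(np.abs(contrast(inc, lam))) < 1e-12
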