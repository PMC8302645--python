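"""Generator geometry, kernels, rendering physics, packing and fringes."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.spatial.distance import pdist, squareform

from crystalcal import LatticeSpec, NoiseSpec, OpticsModel, ParticleSet
from crystalcal import synthgen


# ---------------------------------------------------------------- lattice


class TestBuildCrystal:
    def test_layer_spacing_matches_close_packing_form(self):
        spec = LatticeSpec(nn_growth=538.0, compression=1.0, n_layers=3,
                           layers_extent=5, stacking="ABC")
        ps = synthgen.build_crystal(spec)
        z = np.unique(np.round(ps.centers[:, 0], 6))
        expected = math.sqrt(6) / 3 * 538.0
        assert np.allclose(np.diff(z), expected, atol=1e-5)

    @given(nn=st.floats(min_value=100.0, max_value=2000.0))
    @settings(max_examples=20, deadline=None)
    def test_layer_spacing_scales_with_nn_distance(self, nn):
        spec = LatticeSpec(nn_growth=nn, compression=1.0, n_layers=2,
                           layers_extent=3, stacking="AB")
        ps = synthgen.build_crystal(spec)
        z = np.unique(ps.centers[:, 0])
        assert np.diff(z)[0] == pytest.approx(math.sqrt(6) / 3 * nn, rel=1e-6)

    def test_uncompressed_hexagon_has_six_equal_neighbours(self):
        spec = LatticeSpec(nn_growth=538.0, compression=1.0, n_layers=1,
                           layers_extent=7, stacking="A")
        ps = synthgen.build_crystal(spec)
        coords = ps.centers
        centre = coords[np.argmin(np.linalg.norm(coords - coords.mean(0), axis=1))]
        d = np.linalg.norm(coords - centre, axis=1)
        nn = np.sort(d)[1:7]
        assert np.allclose(nn, 538.0, rtol=1e-9)

    def test_compression_shortens_growth_bonds_only(self):
        # exhaustive pairwise scan on a 5x5x3 lattice
        spec = LatticeSpec(nn_growth=538.0, compression=0.96, n_layers=3,
                           layers_extent=5, stacking="ABC")
        ps = synthgen.build_crystal(spec)
        layer0 = ps.centers[ps.layer_index == 0]
        D = squareform(pdist(layer0))
        np.fill_diagonal(D, np.inf)
        shortest = D.min()
        assert shortest == pytest.approx(538.0, rel=1e-9)
        # oblique first-shell bonds are longer by 1/compression
        first_shell = np.sort(np.unique(np.round(D, 6).ravel()))[:2]
        assert first_shell[1] == pytest.approx(538.0 / 0.96, rel=1e-6)

    def test_stacking_validation(self):
        with pytest.raises(ValueError):
            LatticeSpec(stacking="AAB")
        with pytest.raises(ValueError):
            LatticeSpec(n_layers=0)
        with pytest.raises(ValueError):
            LatticeSpec(nn_growth=-1.0)

    def test_fault_free_stacking_cycles_abc(self):
        assert synthgen.generate_stacking(6, 0.0, 0) == "ABCABC"

    def test_faulted_stacking_never_repeats_consecutively(self):
        for seed in range(20):
            s = synthgen.generate_stacking(12, 0.5, seed)
            assert all(a != b for a, b in zip(s, s[1:]))

    def test_same_seed_reproduces_particles(self):
        spec = LatticeSpec(fault_prob=0.3, seed=42, n_layers=6, layers_extent=6)
        a = synthgen.build_crystal(spec)
        b = synthgen.build_crystal(spec)
        assert np.array_equal(a.centers, b.centers)
        assert a.stacking == b.stacking


class TestAssignCores:
    def test_zero_fraction_gives_no_gold(self):
        ps = synthgen.build_crystal(LatticeSpec(n_layers=2, layers_extent=5))
        out = synthgen.assign_cores(ps, 0.0, seed=1)
        assert not np.any(out.core_type == "gold")
        assert np.all(out.core_diameter[out.core_type == "fluorescent"] == 45.0)

    def test_gold_count_binomial(self):
        ps = synthgen.build_crystal(
            LatticeSpec(n_layers=10, layers_extent=32, stacking="ABCABCABCA")
        )
        n = len(ps)
        assert n >= 10100 - 300
        out = synthgen.assign_cores(ps, 1.0 / 101.0, seed=7)
        n_gold = int(np.sum(out.core_type == "gold"))
        p = 1.0 / 101.0
        tol = 3.0 * math.sqrt(n * p * (1 - p))
        assert abs(n_gold - n * p) <= tol

    def test_determinism(self):
        ps = synthgen.build_crystal(LatticeSpec(n_layers=3, layers_extent=8))
        a = synthgen.assign_cores(ps, 0.3, seed=5)
        b = synthgen.assign_cores(ps, 0.3, seed=5)
        assert np.array_equal(a.core_type, b.core_type)


# ---------------------------------------------------------------- kernels


class TestPsfKernel:
    def test_gaussian_kernel_normalised_and_centred(self):
        k = synthgen.psf_kernel(OpticsModel(mode="confocal"))
        assert k.sum() == pytest.approx(1.0, abs=1e-12)
        assert np.unravel_index(np.argmax(k), k.shape) == tuple(s // 2 for s in k.shape)

    def test_doughnut_has_zero_on_axis(self):
        k = synthgen.psf_kernel(
            OpticsModel(mode="depletion2d_refl", fwhm_lateral=250, fwhm_axial=600,
                        voxel=(100.0, 40.0, 40.0))
        )
        cz, cy, cx = (s // 2 for s in k.shape)
        assert k[cz, cy, cx] == 0.0
        assert k.sum() == pytest.approx(1.0)

    def test_bottle_beam_lobes_symmetric_and_separated(self):
        opt = OpticsModel(mode="depletionz_refl", fwhm_lateral=250, fwhm_axial=300,
                          lobe_sep=700.0, lobe_asymmetry=1.0, voxel=(50.0, 50.0, 50.0))
        k = synthgen.psf_kernel(opt)
        cz, cy, cx = (s // 2 for s in k.shape)
        prof = k[:, cy, cx]
        # symmetric about the centre plane
        assert np.allclose(prof, prof[::-1], rtol=1e-9)
        # peak positions at +- lobe_sep/2 within one voxel
        peaks = np.sort(np.argsort(prof)[-2:])
        z = (np.arange(len(prof)) - cz) * 50.0
        assert abs(z[peaks[0]] + 350.0) <= 50.0
        assert abs(z[peaks[1]] - 350.0) <= 50.0
        # oracle: analytic two-lobe model on a fine grid peaks at the same z
        zf = np.linspace(-1000, 1000, 20001)
        s = 300.0 / (2 * math.sqrt(2 * math.log(2)))
        fine = np.exp(-0.5 * ((zf - 350) / s) ** 2) + np.exp(-0.5 * ((zf + 350) / s) ** 2)
        assert abs(zf[np.argmax(fine)]) == pytest.approx(350.0, abs=0.2)

    def test_nonpositive_fwhm_rejected(self):
        with pytest.raises(ValueError):
            OpticsModel(fwhm_lateral=-10.0)

    def test_subvoxel_fwhm_warns(self):
        with pytest.warns(UserWarning):
            synthgen.psf_kernel(
                OpticsModel(fwhm_lateral=30.0, fwhm_axial=600.0, voxel=(100.0, 45.0, 45.0))
            )


# ---------------------------------------------------------------- rendering


def _single_bead(z=1500.0, y=1500.0, x=1500.0):
    return ParticleSet(
        centers=np.array([[z, y, x]]),
        core_type=np.array(["fluorescent"], dtype=object),
        core_diameter=np.array([45.0]),
    )


class TestRenderVolume:
    OPT = OpticsModel(mode="confocal", fwhm_lateral=230.0, fwhm_axial=600.0,
                      voxel=(100.0, 60.0, 60.0), axial_scaling=1.0)

    def test_single_core_peaks_at_its_position(self):
        stack = synthgen.render_volume(_single_bead(), self.OPT, None,
                                       extent=(3000.0, 3000.0, 3000.0))
        peak = np.unravel_index(np.argmax(stack.data), stack.shape)
        pos_nm = np.array(peak) * np.array(stack.voxel)
        assert np.all(np.abs(pos_nm - 1500.0) <= np.array(stack.voxel))

    def test_rendering_is_linear_in_the_particle_set(self):
        a = _single_bead(1200.0, 1000.0, 1000.0)
        b = _single_bead(1800.0, 2000.0, 2000.0)
        both = ParticleSet(
            centers=np.vstack([a.centers, b.centers]),
            core_type=np.concatenate([a.core_type, b.core_type]),
            core_diameter=np.concatenate([a.core_diameter, b.core_diameter]),
        )
        kw = dict(extent=(3000.0, 3000.0, 3000.0))
        sa = synthgen.render_volume(a, self.OPT, None, **kw)
        sb = synthgen.render_volume(b, self.OPT, None, **kw)
        sab = synthgen.render_volume(both, self.OPT, None, **kw)
        assert np.allclose(sab.data, sa.data + sb.data, atol=1e-12)

    def test_total_intensity_conserved(self):
        # noiseless, interior core: total = per-core deposited sphere mass
        stack = synthgen.render_volume(_single_bead(), self.OPT, None,
                                       extent=(3000.0, 3000.0, 3000.0))
        vz, vy, vx = stack.voxel
        expected = (math.pi / 6.0) * 45.0**3 / (vz * vy * vx)
        assert stack.data.sum() == pytest.approx(expected, rel=5e-3)

    def test_axial_scaling_shifts_apparent_depth(self):
        opt = OpticsModel(mode="confocal", fwhm_lateral=230.0, fwhm_axial=600.0,
                          voxel=(50.0, 60.0, 60.0), axial_scaling=0.9)
        stack = synthgen.render_volume(_single_bead(z=1350.0), opt, None,
                                       extent=(3000.0, 3000.0, 3000.0))
        peak_z = np.unravel_index(np.argmax(stack.data), stack.shape)[0] * 50.0
        assert peak_z == pytest.approx(1350.0 / 0.9, abs=50.0)

    def test_noise_deterministic_under_seed(self):
        noise = NoiseSpec(photons_per_unit=1000.0, read_sigma=1.0, seed=9)
        kw = dict(extent=(3000.0, 3000.0, 3000.0))
        a = synthgen.render_volume(_single_bead(), self.OPT, noise, **kw)
        b = synthgen.render_volume(_single_bead(), self.OPT, noise, **kw)
        assert np.array_equal(a.data, b.data)

    def test_empty_particle_set_gives_background(self):
        empty = ParticleSet(centers=np.empty((0, 3)),
                            core_type=np.array([], dtype=object),
                            core_diameter=np.array([]))
        stack = synthgen.render_volume(empty, self.OPT, None,
                                       extent=(3000.0, 3000.0, 3000.0))
        assert np.all(stack.data == 0)

    def test_extent_smaller_than_kernel_rejected(self):
        with pytest.raises(ValueError):
            synthgen.render_volume(_single_bead(), self.OPT, None,
                                   extent=(400.0, 400.0, 400.0))


# ---------------------------------------------------------------- sparse sample


class TestSparseSample:
    def test_probe_ratio_and_no_overlap(self):
        ps = synthgen.sparse_sample(box=(6000.0, 6000.0, 6000.0),
                                    ratio=(400.0, 5.0, 1.0), seed=1, n_particles=400)
        D = squareform(pdist(ps.centers))
        R = ps.diameter / 2.0
        np.fill_diagonal(D, np.inf)
        assert np.all(D >= R[:, None] + R[None, :] - 1e-9)

    def test_probe_scaffold_ratio_counts_binomial(self):
        ps = synthgen.sparse_sample(box=(26000.0, 26000.0, 26000.0),
                                    ratio=(85000.0, 99.0, 1.0), seed=4,
                                    n_particles=85100)
        n = len(ps)
        n_fluor = int(np.sum(ps.core_type == "fluorescent"))
        n_gold = int(np.sum(ps.core_type == "gold"))
        p_f = 99.0 / 85100.0
        assert abs(n_fluor - n * p_f) <= 3.0 * math.sqrt(n * p_f * (1 - p_f))
        assert n_gold <= 6  # expectation ~1

    def test_zero_pdi_fixes_scaffold_diameter(self):
        ps = synthgen.sparse_sample(box=(4000.0, 4000.0, 4000.0), scaffold_pdi=0.0,
                                    ratio=(1.0, 0.0, 0.0), seed=2, n_particles=40)
        assert np.all(ps.diameter == 310.0)

    def test_packing_failure_reports_fill(self):
        with pytest.raises(RuntimeError, match="placed"):
            synthgen.sparse_sample(box=(1500.0, 1500.0, 1500.0),
                                   ratio=(1.0, 0.0, 0.0), seed=3, n_particles=200,
                                   max_attempts_per_particle=20)

    def test_determinism(self):
        kw = dict(box=(5000.0, 5000.0, 5000.0), ratio=(50.0, 5.0, 1.0),
                  seed=11, n_particles=60)
        a = synthgen.sparse_sample(**kw)
        b = synthgen.sparse_sample(**kw)
        assert np.array_equal(a.centers, b.centers)
        assert np.array_equal(a.core_type, b.core_type)


# ---------------------------------------------------------------- fringes


class TestFringeSpectrum:
    def test_fringe_period_matches_reciprocal_relation(self):
        # oracle: count maxima of the noiseless spectrum over a known span
        nu = np.linspace(2000.0, 3000.0, 20001)
        _, intensity = synthgen.fringe_spectrum(94.257, 1.0, wavenumber_grid=nu)
        from scipy.signal import find_peaks

        peaks, _ = find_peaks(intensity)
        measured_period = (nu[peaks[-1]] - nu[peaks[0]]) / (len(peaks) - 1)
        expected = 1.0 / (2.0 * 94.257e-4)  # ~53.05 cm^-1
        assert measured_period == pytest.approx(expected, rel=1e-3)

    def test_zero_visibility_is_flat(self):
        _, intensity = synthgen.fringe_spectrum(94.257, 1.0, visibility=0.0)
        assert np.ptp(intensity) == 0.0

    def test_doubling_height_halves_period(self):
        nu = np.linspace(2000.0, 2500.0, 40001)
        from scipy.signal import find_peaks

        def period(h):
            _, ii = synthgen.fringe_spectrum(h, 1.0, wavenumber_grid=nu)
            p, _ = find_peaks(ii)
            return (nu[p[-1]] - nu[p[0]]) / (len(p) - 1)

        assert period(50.0) == pytest.approx(2 * period(100.0), rel=1e-3)

    def test_coarse_grid_rejected(self):
        with pytest.raises(ValueError, match="coarse"):
            synthgen.fringe_spectrum(94.257, 1.0,
                                     wavenumber_grid=np.linspace(2000, 8000, 100))
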