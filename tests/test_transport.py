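"""Monte Carlo transport: analytic benchmarks, statistics, conservation."""

import numpy as np
import pytest

import bnctcheck as bc
from bnctcheck.groups import DEFAULT_GROUPS
from bnctcheck.transport import TransportParameterError
from bnctcheck.xs import uniform_library


class TestRelativeError:
    def test_constant_batches_zero(self):
        assert bc.relative_error(np.array([5.0, 5.0, 5.0, 5.0])) == 0.0

    def test_stated_formula_123(self):
        """sd([1,2,3]) / (mean * sqrt(3)) = 1 / (2 sqrt(3)) ~ 0.2887."""
        assert bc.relative_error(np.array([1.0, 2.0, 3.0])) == pytest.approx(
            1.0 / (2.0 * np.sqrt(3.0))
        )

    def test_zero_mean_flagged_nan(self):
        out = bc.relative_error(np.array([[0.0, 1.0], [0.0, 3.0]]))
        assert np.isnan(out[0]) and np.isfinite(out[1])

    def test_requires_two_batches(self):
        with pytest.raises(TransportParameterError):
            bc.relative_error(np.array([1.0]))

    def test_error_shrinks_with_more_batches(self, rng):
        """Relative error scales roughly as 1/sqrt(n) on iid batch means."""
        big = rng.normal(10.0, 1.0, 400)
        r_few = np.mean(
            [bc.relative_error(big[i : i + 10]) for i in range(0, 400, 10)]
        )
        r_many = np.mean(
            [bc.relative_error(big[i : i + 40]) for i in range(0, 400, 40)]
        )
        assert r_many == pytest.approx(r_few / 2.0, rel=0.35)


def _axial_spectrum():
    return bc.BeamSpectrum(
        DEFAULT_GROUPS,
        np.array([0, 0, 1.0, 0, 0]),
        np.array([1.0 - 1e-9, 1.0]),
        np.array([1.0]),
    )


class TestAnalyticBenchmarks:
    def test_absorbing_slab_beer_lambert(self, water_phantom_coarse):
        """Uncollided axial flux in a pure absorber follows exp(-sigma_a z).

        Compared in absolute normalization (per-slab track length over
        voxel volume) within 3 batch standard errors at every depth with
        usable statistics.
        """
        sigma = 0.3  # cm^-1
        lib = uniform_library(sigma, 0.0)
        tally = bc.run_transport(
            water_phantom_coarse, _axial_spectrum(), bc.CollimatorField(12.0),
            100_000, 10, seed=3, library=lib,
        )
        ph = tally.phantom
        h = ph.voxel_size[2] / 10.0  # cm
        nz = ph.grid_shape[2]
        z_edges = h * np.arange(nz + 1)
        flux = tally.flux[:, :, :, 2]
        rel = np.nan_to_num(tally.relative_error[:, :, :, 2], nan=0.0)
        slab = flux.sum(axis=(0, 1))
        slab_err = np.sqrt(((flux * rel) ** 2).sum(axis=(0, 1)))
        analytic = (
            (np.exp(-sigma * z_edges[:-1]) - np.exp(-sigma * z_edges[1:]))
            / sigma / ph.voxel_volume_cm3
        )
        usable = (slab_err > 0) & (analytic > 1e-4 * analytic.max())
        z_scores = np.abs(slab - analytic)[usable] / slab_err[usable]
        assert usable.sum() >= 10
        assert z_scores.max() < 3.0

    def test_void_phantom_all_leak_constant_column(self, water_phantom_coarse):
        """With zero cross sections every history leaks and the beam-column
        fluence is flat in depth within statistics."""
        lib = uniform_library(0.0, 0.0)
        tally = bc.run_transport(
            water_phantom_coarse, _axial_spectrum(), bc.CollimatorField(12.0),
            40_000, 10, seed=11, library=lib,
        )
        assert tally.balance["absorbed"] == 0
        assert tally.balance["leaked"] == tally.balance["launched"]
        slab = tally.flux[:, :, :, 2].sum(axis=(0, 1))
        spread = slab.std() / slab.mean()
        assert spread < 0.05

    def test_infinite_medium_balance(self):
        """Uniform volumetric source in a large absorber: integrated flux
        approaches 1/sigma_a per source particle (one-group balance)."""
        sigma = 5.0  # cm^-1 -> mfp 2 mm, grid 200 mm: leakage ~1%
        lib = uniform_library(sigma, 0.0)
        from bnctcheck.materials import MATERIAL_INDEX
        from bnctcheck.phantoms import VoxelPhantom

        shape = (20, 20, 20)
        ph = VoxelPhantom(
            (10.0, 10.0, 10.0), (5.0, 5.0, 5.0),
            np.full(shape, MATERIAL_INDEX["water"], dtype=np.int16),
            np.ones(shape), np.zeros(shape),
        )
        tally = bc.run_transport(
            ph, _axial_spectrum(), None, 40_000, 10, seed=13,
            library=lib, source="volume",
        )
        integral = tally.flux[:, :, :, 2].sum() * ph.voxel_volume_cm3
        rel = np.nan_to_num(tally.relative_error[:, :, :, 2], nan=0.0)
        err = np.sqrt(
            (((tally.flux[:, :, :, 2] * rel) ** 2).sum())
        ) * ph.voxel_volume_cm3
        # surface voxels leak a little; allow 3 SE plus a 2.5% leakage margin
        assert integral == pytest.approx(
            1.0 / sigma, rel=0.025 + 3 * err * sigma
        )


class TestConservationAndReproducibility:
    def test_particle_balance_exact(self, water_phantom_coarse,
                                    reference_spectrum):
        tally = bc.run_transport(
            water_phantom_coarse, reference_spectrum, bc.CollimatorField(12.0),
            5000, 5, seed=21,
        )
        b = tally.balance
        assert b["launched"] == b["absorbed"] + b["leaked"]

    def test_identical_seed_bit_identical(self, water_phantom_coarse,
                                          reference_spectrum):
        kw = dict(n_histories=3000, n_batches=3, seed=42)
        a = bc.run_transport(water_phantom_coarse, reference_spectrum,
                             bc.CollimatorField(12.0), **kw)
        b = bc.run_transport(water_phantom_coarse, reference_spectrum,
                             bc.CollimatorField(12.0), **kw)
        assert np.array_equal(a.flux, b.flux)
        assert np.array_equal(a.photon_flux, b.photon_flux)

    def test_parameter_validation(self, water_phantom_coarse,
                                  reference_spectrum):
        with pytest.raises(TransportParameterError):
            bc.run_transport(water_phantom_coarse, reference_spectrum,
                             bc.CollimatorField(12.0), 5, 10)


class TestDepthProfiles:
    def test_absorber_profile_decreasing(self, water_phantom_coarse):
        lib = uniform_library(0.5, 0.0)
        tally = bc.run_transport(
            water_phantom_coarse, _axial_spectrum(), bc.CollimatorField(15.0),
            50_000, 10, seed=5, library=lib,
        )
        prof = bc.depth_profile(tally, "epithermal", axis=2)
        f = prof["flux"]
        lead = f[:8]  # region with usable counts (beyond is flux ~ 0)
        assert np.all(lead > 0)
        assert np.all(np.diff(lead) < 0)

    def test_offaxis_symmetry(self, water_phantom_coarse):
        lib = uniform_library(0.3, 0.0)
        tally = bc.run_transport(
            water_phantom_coarse, _axial_spectrum(), bc.CollimatorField(15.0),
            50_000, 10, seed=6, library=lib,
        )
        prof = bc.depth_profile(tally, "epithermal", axis=0)
        f, re = prof["flux"], prof["relative_error"]
        n = f.size
        for i in range(n // 2 - 4, n // 2):
            j = n - 1 - i
            if f[i] > 0 and f[j] > 0:
                err = np.hypot(f[i] * np.nan_to_num(re[i]),
                               f[j] * np.nan_to_num(re[j]))
                assert abs(f[i] - f[j]) < 4 * max(err, 1e-12)

    def test_unknown_band_rejected(self, water_phantom_coarse,
                                   reference_spectrum):
        tally = bc.run_transport(
            water_phantom_coarse, reference_spectrum, bc.CollimatorField(12.0),
            2000, 2, seed=1,
        )
        with pytest.raises(TransportParameterError):
            bc.depth_profile(tally, "ultracold")


class TestThermalization:
    def test_subsurface_thermal_buildup(self):
        """In water with scattering on, the thermal flux has its maximum
        at a depth greater than zero (build-up), a shape property of
        epithermal-beam moderation."""
        spec = bc.build_reference_spectrum(0.05, 0.85, 0.10)
        ph = bc.set_boron(bc.build_water_qa_phantom(5.0), 25.0)
        tally = bc.run_transport(ph, spec, bc.CollimatorField(12.0),
                                 60_000, 10, seed=7)
        prof = bc.depth_profile(tally, "thermal", axis=2)
        f = prof["flux"]
        peak = int(np.argmax(f))
        assert peak > 0
        assert f[peak] > 1.15 * f[0]
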