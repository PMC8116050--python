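"""Two-lobe geometry, masked diffusion, ROI readout, neck slowdown."""

import numpy as np
import pytest

from mcaspol.frap3d import (
    BleachSpec,
    build_geometry,
    masked_laplacian,
    measure_roi,
    neck_slowdown,
    simulate_frap,
)

VOX = 0.25  # coarse voxels keep these tests fast; production runs use 0.15


@pytest.fixture(scope="module")
def geometry():
    return build_geometry(voxel=VOX)


@pytest.fixture(scope="module")
def trajectory(geometry):
    times = np.arange(0.0, 2.0 + 1e-9, 0.25)
    return simulate_frap(geometry, D=1.0, bleach=BleachSpec(), times=times, dt=0.01)


class TestGeometry:
    def test_volume_against_analytic_union(self, geometry):
        fine = build_geometry(voxel=0.1)
        # discrete volume converges: coarse within 2% of the fine estimate
        assert geometry.volume == pytest.approx(fine.volume, rel=0.02)

    def test_sphere_volume_within_2_percent(self):
        # degenerate two-lobe with a tiny daughter: mother dominates
        g = build_geometry(voxel=0.1)
        sphere_vox = (g.compartments == 1).sum() * g.voxel**3
        # mother lobe = sphere truncated at the neck plane: analytic cap
        R, xn = 3.0, g.neck_plane_x
        cap = np.pi * (R - xn) ** 2 * (2 * R + xn) / 3.0
        expected = 4.0 / 3.0 * np.pi * R**3 - cap
        assert sphere_vox == pytest.approx(expected, rel=0.02)

    def test_two_compartments_split_at_neck(self, geometry):
        assert set(np.unique(geometry.compartments)) == {0, 1, 2}
        x_mother = geometry.x[np.any(geometry.compartments == 1, axis=(1, 2))]
        x_daughter = geometry.x[np.any(geometry.compartments == 2, axis=(1, 2))]
        assert x_mother.max() <= geometry.neck_plane_x + geometry.voxel
        assert x_daughter.min() >= geometry.neck_plane_x - geometry.voxel

    def test_neck_diameter_estimate_converges(self):
        errs = [abs(build_geometry(voxel=v).measured_neck_diameter() - 2.0)
                for v in (0.3, 0.2, 0.1)]
        assert errs[-1] <= errs[0]
        assert errs[-1] < 0.15

    def test_impossible_neck_rejected(self):
        with pytest.raises(ValueError):
            build_geometry(voxel=0.2, neck_diameter=4.0, ellipsoid_width=3.0)

    def test_mask_is_connected(self, geometry):
        from scipy import ndimage
        _, n = ndimage.label(geometry.mask)
        assert n == 1


class TestDiffusion:
    def test_total_intensity_conserved(self, trajectory):
        assert trajectory.conservation_drift < 1e-8

    def test_equilibrates_to_uniform(self, geometry):
        times = np.array([0.0, 60.0])
        traj = simulate_frap(geometry, D=10.0, bleach=BleachSpec(), times=times,
                             dt=0.05)
        depth = geometry.mask.sum(axis=2) * geometry.voxel
        img = traj.images[-1]
        conc = img[depth > 0] / depth[depth > 0]
        assert conc.max() - conc.min() < 1e-4 * conc.mean()

    def test_point_spread_matches_3d_heat_kernel(self):
        """On a cube (no boundary effects), the masked-grid solver
        reproduces the free-space Gaussian kernel."""
        n, h = 24, 0.25
        mask = np.ones((n, n, n), dtype=bool)
        L = masked_laplacian(mask, h)
        import scipy.sparse as sp
        from scipy.sparse.linalg import splu
        D, dt, steps = 0.5, 0.005, 40
        lu = splu((sp.identity(L.shape[0], format="csc") - dt * D * L).tocsc())
        ax = (np.arange(n) + 0.5) * h
        c0 = ax[n // 2]
        X, Y, Z = np.meshgrid(ax, ax, ax, indexing="ij")
        sig0 = 0.3
        f = np.exp(-((X - c0) ** 2 + (Y - c0) ** 2 + (Z - c0) ** 2) / (2 * sig0**2))
        c = f.ravel()
        for _ in range(steps):
            c = lu.solve(c)
        t = dt * steps
        sig2 = sig0**2 + 2 * D * t
        ref = (sig0**2 / sig2) ** 1.5 * np.exp(
            -((X - c0) ** 2 + (Y - c0) ** 2 + (Z - c0) ** 2) / (2 * sig2))
        assert np.sqrt(np.mean((c.reshape(n, n, n) - ref) ** 2)) < 1e-3

    def test_intensities_stay_in_range(self, trajectory):
        assert trajectory.images.min() >= -1e-12
        depth = trajectory.geometry.mask.sum(axis=2) * trajectory.geometry.voxel
        assert trajectory.images.max() <= depth.max() * 1.0 + 1e-9


class TestRoi:
    def test_uniform_field_reads_mean_column_depth(self, geometry):
        times = np.array([0.0])
        traj = simulate_frap(geometry, D=1.0, bleach=None, times=times, dt=0.01)
        roi = measure_roi(traj, (0.0, 0.0), 3.0)
        depth = geometry.mask.sum(axis=2) * geometry.voxel
        r = 1.5
        sel = ((geometry.x[:, None]) ** 2 + (geometry.y[None, :]) ** 2 <= r * r) \
            & (depth > 0)
        assert roi.intensity[0] == pytest.approx(depth[sel].mean(), rel=1e-12)

    def test_bleach_roi_recovers(self, trajectory):
        roi = measure_roi(trajectory, (0.0, 0.0), 1.0)
        assert roi.intensity[-1] > roi.intensity[0]

    def test_mirror_symmetric_rois_are_identical(self, trajectory):
        """ROIs mirrored in y about the bleach axis see identical kinetics
        (the symmetric null of the slowdown measure)."""
        up = measure_roi(trajectory, (0.0, 1.5), 2.0)
        down = measure_roi(trajectory, (0.0, -1.5), 2.0)
        assert np.allclose(up.intensity, down.intensity, rtol=1e-10)

    def test_empty_roi_rejected(self, trajectory):
        with pytest.raises(ValueError):
            measure_roi(trajectory, (50.0, 50.0), 2.0)


class TestNeckSlowdown:
    def test_roi_slowing_is_positive(self, geometry):
        """The constricted neck slows daughter-side recovery relative to the
        equidistant in-mother site."""
        assert neck_slowdown(geometry, D=1.0).slowing > 0

    def test_equilibration_rate_monotone_in_constriction(self):
        """The mother-daughter equalization rate falls as the neck narrows
        (sweep of three geometries at coarse voxels)."""
        from mcaspol.frap3d import compartment_equilibration_rate
        rates = [compartment_equilibration_rate(
                     build_geometry(voxel=0.25, neck_diameter=neck), D=1.0)
                 for neck in (3.0, 2.0, 1.5)]
        assert rates[0] > rates[1] > rates[2] > 0

    def test_doubling_diffusivity_halves_half_times(self):
        g = build_geometry(voxel=0.25)
        r1 = neck_slowdown(g, D=1.0)
        r2 = neck_slowdown(g, D=2.0, t_end=2.625, sample_dt=0.175)
        # pure diffusion scaling: rates double, ratio unchanged within 5%
        assert r2.k_mother == pytest.approx(2 * r1.k_mother, rel=0.05)
        assert r2.slowing == pytest.approx(r1.slowing, abs=0.05)

    def test_fit_quality_on_default_protocol(self):
        g = build_geometry(voxel=0.25)
        res = neck_slowdown(g, D=1.0)
        assert res.fits["mother"].r_squared > 0.98
        assert res.fits["daughter"].r_squared > 0.98
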