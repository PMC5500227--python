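"""Image pipeline: distance maps, box counting, watershed, scaling fits."""

import numpy as np
import pytest

from cortexmesh.errors import EmptyInputError, InvalidDataError, InvalidParameterError
from cortexmesh.image_analysis import (
    box_count_dimension,
    branching_ratio,
    cross_section_profile,
    euclidean_distance_map,
    fit_lognormal_areas,
    msd_vs_actin_distance,
    perimeter_area_scaling,
    sliding_reconstruction,
    watershed_compartments,
)
from cortexmesh.meshwork_synthesis import (
    MeshImage,
    make_reference_fractals,
    meshwork_to_localizations,
    render_localizations,
)
from cortexmesh.trajectory import Trajectory, TrajectoryEnsemble


class TestDistanceMap:
    def test_three_four_five(self):
        pixels = np.zeros((10, 10))
        pixels[2, 2] = 1.0
        dmap = euclidean_distance_map(MeshImage(pixels, 20.0), threshold=0.5)
        assert dmap.values[2, 2] == 0.0
        assert dmap.values[5, 6] == pytest.approx(5 * 20.0)

    def test_matches_brute_force_on_random_masks(self, rng):
        for _ in range(5):
            mask = rng.random((32, 32)) < 0.05
            if not mask.any():
                mask[0, 0] = True
            dmap = euclidean_distance_map(MeshImage(mask.astype(float), 10.0), 0.5)
            feat = np.argwhere(mask)
            rr, cc = np.mgrid[0:32, 0:32]
            d2 = (rr[..., None] - feat[:, 0]) ** 2 + (cc[..., None] - feat[:, 1]) ** 2
            brute = np.sqrt(d2.min(axis=-1)) * 10.0
            np.testing.assert_allclose(dmap.values, brute, atol=1e-9)

    def test_lipschitz_neighbors(self, rng):
        mask = rng.random((40, 40)) < 0.02
        mask[5, 5] = True
        dmap = euclidean_distance_map(MeshImage(mask.astype(float), 20.0), 0.5)
        dv = dmap.values
        assert np.max(np.abs(np.diff(dv, axis=0))) <= np.sqrt(2) * 20.0 + 1e-9
        assert np.max(np.abs(np.diff(dv, axis=1))) <= np.sqrt(2) * 20.0 + 1e-9

    def test_no_features_rejected(self):
        with pytest.raises(EmptyInputError):
            euclidean_distance_map(MeshImage(np.zeros((4, 4)), 20.0), 0.5)


class TestSlidingReconstruction:
    def test_window_count_and_conservation(self, grid_mesh):
        locs = meshwork_to_localizations(grid_mesh, linear_density=30, n_frames=300, seed=1)
        images = sliding_reconstruction(locs, window_frames=100, stride_frames=10)
        assert len(images) == 21
        for img in images:
            first, last = img.frame_window
            n_in = ((locs.frame >= first) & (locs.frame <= last)).sum()
            assert img.pixels.sum() == n_in

    def test_single_full_window(self, grid_mesh):
        locs = meshwork_to_localizations(grid_mesh, linear_density=30, n_frames=100, seed=2)
        images = sliding_reconstruction(locs, window_frames=100, stride_frames=10)
        assert len(images) == 1
        assert images[0].pixels.sum() == len(locs)

    def test_window_longer_than_recording_rejected(self, grid_mesh):
        locs = meshwork_to_localizations(grid_mesh, n_frames=50, seed=3)
        with pytest.raises(InvalidDataError):
            sliding_reconstruction(locs, window_frames=100, stride_frames=10)


class TestBoxCounting:
    def test_counts_match_brute_force(self, rng):
        """Reshape-based counting equals a per-box scan exactly."""
        mask = rng.random((64, 64)) < 0.2
        img = MeshImage(mask.astype(np.uint8), 20.0)
        res = box_count_dimension(img, box_sizes=[2, 4, 8, 16])
        for eps, count in zip(res.box_sizes, res.counts):
            brute = 0
            for r0 in range(0, 64, eps):
                for c0 in range(0, 64, eps):
                    if mask[r0:r0 + eps, c0:c0 + eps].any():
                        brute += 1
            assert count == brute

    def test_counts_non_increasing(self, rng):
        mask = rng.random((128, 128)) < 0.1
        res = box_count_dimension(MeshImage(mask.astype(np.uint8), 20.0), [2, 4, 8, 16, 32])
        assert np.all(np.diff(res.counts) <= 0)

    def test_translation_stability_with_offset_averaging(self):
        """d_f is stable (±0.02) under sub-box image translations when
        grid-offset averaging is enabled."""
        img = make_reference_fractals("percolation_cluster", 256, seed=3)
        shifted = np.zeros((259, 259), dtype=np.uint8)
        shifted[3:259, 2:258] = img.pixels
        d0 = box_count_dimension(img, [4, 8, 16, 32, 64], offset_average=True)
        d1 = box_count_dimension(
            MeshImage(shifted, 20.0), [4, 8, 16, 32, 64], offset_average=True
        )
        assert abs(d0.fractal_dimension - d1.fractal_dimension) <= 0.02

    def test_empty_image_rejected(self):
        with pytest.raises(EmptyInputError):
            box_count_dimension(MeshImage(np.zeros((16, 16)), 20.0))


class TestWatershed:
    def test_grid_mesh_recovers_nine_cells(self, grid_mesh):
        locs = meshwork_to_localizations(grid_mesh, linear_density=300, seed=1)
        img = render_localizations(locs, pixel_size=20.0, region=grid_mesh.region)
        seg = watershed_compartments(img, min_area=0.1, exclude_border=False)
        assert len(seg.areas) == 9
        np.testing.assert_allclose(seg.areas, 4.0, rtol=0.05)

    def test_labels_partition_image(self, grid_mesh):
        locs = meshwork_to_localizations(grid_mesh, linear_density=300, seed=2)
        img = render_localizations(locs, pixel_size=20.0, region=grid_mesh.region)
        seg = watershed_compartments(img, exclude_border=False)
        ids, counts = np.unique(seg.labels, return_counts=True)
        assert counts.sum() == img.pixels.size
        # each label is one 4-connected blob
        from scipy import ndimage

        for i in seg.label_ids:
            _, n = ndimage.label(seg.labels == i)
            assert n == 1

    def test_uniform_image_rejected(self):
        with pytest.raises(InvalidDataError):
            watershed_compartments(MeshImage(np.ones((32, 32)), 20.0))


class TestLognormalFit:
    def test_parameter_recovery(self, rng):
        """MLE on n = 2500 log-normal areas recovers (μ, σ) within the
        standard-error scale σ/√n."""
        areas = np.exp(rng.normal(0.0, 1.0, size=2500))
        mu, sigma, p = fit_lognormal_areas(areas)
        assert abs(mu) < 0.06
        assert abs(sigma - 1.0) < 0.05
        assert p > 0.01

    def test_equal_areas_zero_sigma(self):
        mu, sigma, p = fit_lognormal_areas([2.0, 2.0, 2.0, 2.0])
        assert sigma == 0.0 and mu == pytest.approx(np.log(2.0))

    def test_nonpositive_area_rejected(self):
        with pytest.raises(InvalidDataError):
            fit_lognormal_areas([1.0, 0.0, 2.0])


class TestPerimeterAreaScaling:
    def test_family_of_squares(self):
        sides = np.linspace(0.5, 5.0, 20)
        a, b, rho = perimeter_area_scaling((sides**2, 4 * sides))
        assert b == pytest.approx(0.5, abs=1e-12)
        assert a == pytest.approx(4.0, rel=1e-12)
        assert rho == pytest.approx(1.0, abs=1e-12)

    def test_family_of_circles(self):
        radii = np.linspace(0.2, 3.0, 15)
        a, b, rho = perimeter_area_scaling((np.pi * radii**2, 2 * np.pi * radii))
        assert b == pytest.approx(0.5, abs=1e-12)
        assert a == pytest.approx(2 * np.sqrt(np.pi), rel=1e-12)

    def test_degenerate_rejected(self):
        with pytest.raises(InvalidDataError):
            perimeter_area_scaling((np.array([1.0, 0.0, 2.0]), np.array([1.0, 1.0, 1.0])))


@pytest.fixture(scope="module")
def filament_image():
    """A single vertical zero-width filament rendered at 20 nm precision."""
    from cortexmesh.meshwork_synthesis import Compartment, MeshworkModel

    mesh = MeshworkModel(
        (4.0, 4.0),
        [(0, 0, 4, 0), (4, 0, 4, 4), (4, 4, 0, 4), (0, 4, 0, 0), (2.0, 0.2, 2.0, 3.8)],
        [Compartment(0, 0, 4, 4)],
    )
    locs = meshwork_to_localizations(
        mesh, linear_density=1500, precision_mean=20.0, precision_sd=0.001,
        seed=3, include_boundary=False,
    )
    return render_localizations(locs, pixel_size=10.0, shape=(400, 400), origin=(0, 0))


class TestCrossSection:
    def test_filament_width_matches_precision(self, filament_image):
        """A zero-width filament rendered at 20 nm precision shows a
        Gaussian cross-section of SD 20 nm within 10%."""
        lines = [((2000.0, 800.0 + 250 * i), (2000.0, 1000.0 + 250 * i)) for i in range(9)]
        prof = cross_section_profile(filament_image, lines, half_width=120.0)
        assert abs(prof.gaussian_sd - 20.0) / 20.0 < 0.10

    def test_profile_symmetric_and_scale_invariant(self, filament_image):
        lines = [((2000.0, 800.0 + 250 * i), (2000.0, 1000.0 + 250 * i)) for i in range(9)]
        prof = cross_section_profile(filament_image, lines, half_width=100.0)
        mid = prof.intensity
        asym = np.abs(mid - mid[::-1]).max() / mid.max()
        assert asym < 0.3  # symmetric about the aligned centre within sampling noise
        doubled = MeshImage(
            filament_image.pixels * 2.0, filament_image.pixel_size, filament_image.origin
        )
        prof2 = cross_section_profile(doubled, lines, half_width=100.0)
        assert prof2.gaussian_sd == pytest.approx(prof.gaussian_sd, rel=1e-6)

    def test_line_outside_image_rejected(self, filament_image):
        with pytest.raises(InvalidParameterError):
            cross_section_profile(filament_image, [((9000.0, 100.0), (9000.0, 400.0))])


class TestMSDvsDistance:
    def test_single_segment_single_bin(self):
        pixels = np.zeros((50, 50))
        pixels[0, :] = 10.0
        img = MeshImage(pixels, 20.0)
        pos = np.array([[0.5, 0.5], [0.5, 0.5], [0.5, 0.5], [0.5, 0.5], [0.5, 0.5],
                        [0.5, 0.5], [0.5, 0.5], [0.5, 0.5], [0.5, 0.5], [0.5, 0.5], [0.7, 0.5]])
        traj = Trajectory("s", np.arange(11) * 0.02, pos)
        ens = TrajectoryEnsemble([traj], 0.02)
        res = msd_vs_actin_distance(
            ens, [img], threshold=5.0, distance_bins=np.array([0.0, 2000.0])
        )
        assert res.n_segments[0] == 1
        assert res.msd[0] == pytest.approx(0.2**2)
        assert np.isnan(res.sem[0])


class TestBranchingRatio:
    def test_paper_style_values(self):
        assert branching_ratio(1.75, 2.0) == pytest.approx(1.486, abs=5e-3)
        assert round(branching_ratio(1.75, 2.0), 1) == 1.5
        assert branching_ratio(2.0, 4.0) == pytest.approx(2.0)

    def test_invalid_inputs(self):
        with pytest.raises(InvalidParameterError):
            branching_ratio(0.0, 2.0)
        with pytest.raises(InvalidParameterError):
            branching_ratio(1.75, 1.0)
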