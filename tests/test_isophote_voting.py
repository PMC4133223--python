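import numpy as np
import pytest
from scipy import ndimage

import oracles
from conftest import smooth_random_patch
from pupilloc import isophote_voting as iso
from pupilloc import synthetic_fixtures as synth
from pupilloc.roi import DegenerateInputError


def paraboloid(size=41):
    c = (size - 1) / 2
    x = np.arange(size)[None, :] - c
    y = np.arange(size)[:, None] - c
    return x**2 + y**2 + 0.0 * x, c


class TestGaussianDerivatives:
    def test_exact_on_linear_ramp(self):
        x = np.arange(41, dtype=float)
        d = iso.gaussian_derivatives(np.tile(x, (41, 1)), sigma=2.0)
        interior = (slice(10, 31), slice(10, 31))
        assert np.allclose(d.Lx[interior], 1.0, atol=1e-6)
        assert np.allclose(d.Ly[interior], 0.0, atol=1e-6)
        for g in (d.Lxx, d.Lyy, d.Lxy):
            assert np.allclose(g[interior], 0.0, atol=1e-6)

    def test_exact_on_paraboloid(self):
        img, _ = paraboloid()
        d = iso.gaussian_derivatives(img, sigma=1.5)
        interior = (slice(12, 29), slice(12, 29))
        assert np.allclose(d.Lxx[interior], 2.0, atol=1e-6)
        assert np.allclose(d.Lyy[interior], 2.0, atol=1e-6)
        assert np.allclose(d.Lxy[interior], 0.0, atol=1e-6)

    def test_agrees_with_finite_differences_of_smoothed_field(self):
        # band-limited enough that the oracle's own central-difference
        # truncation error stays below the comparison tolerance
        img = smooth_random_patch(seed=9, size=41, blur=6.0)
        sigma = 1.8
        d = iso.gaussian_derivatives(img, sigma)
        smoothed = ndimage.gaussian_filter(img, sigma, mode="reflect", truncate=6.0)
        fd_x = (smoothed[:, 2:] - smoothed[:, :-2]) / 2.0
        fd_y = (smoothed[2:, :] - smoothed[:-2, :]) / 2.0
        assert np.max(np.abs(d.Lx[5:-5, 6:-6] - fd_x[5:-5, 5:-5])) < 1e-3
        assert np.max(np.abs(d.Ly[6:-6, 5:-5] - fd_y[5:-5, 5:-5])) < 1e-3

    def test_too_small_image_rejected(self):
        with pytest.raises(DegenerateInputError):
            iso.gaussian_derivatives(np.zeros((4, 4)), sigma=3.0)


class TestIsophoteCurvature:
    def test_circle_radius_from_curvature_closed_form(self):
        # isophotes of x^2 + y^2 are circles; at offset (3,4), |1/kappa| = 5
        img, c = paraboloid()
        d = iso.gaussian_derivatives(img, sigma=1.0)
        curv = iso.isophote_curvature(d)
        y, x = int(c + 4), int(c + 3)
        assert curv.valid_mask[y, x]
        assert abs(1.0 / curv.kappa[y, x]) == pytest.approx(5.0, rel=1e-3)

    def test_linear_ramp_has_zero_curvature(self):
        img = np.tile(np.arange(41, dtype=float), (41, 1))
        d = iso.gaussian_derivatives(img, sigma=1.0)
        curv = iso.isophote_curvature(d)
        interior = curv.valid_mask[8:-8, 8:-8]
        assert interior.all()
        assert np.allclose(curv.kappa[8:-8, 8:-8], 0.0, atol=1e-9)

    def test_blurred_disk_edge_radius_recovered(self):
        p = synth.EyeSceneParams(center=(32.0, 24.0), pupil_radius=10.0,
                                 iris_radius=20.0, noise_sigma=0.01, seed=4)
        img = ndimage.gaussian_filter(synth.render_eye(p).image, 1.0)
        d = iso.gaussian_derivatives(img, sigma=1.0)
        curv = iso.isophote_curvature(d)
        # radius measured at the maximal-gradient pixel of the pupil edge
        # (searching between the two boundaries so the iris edge is excluded)
        grad = np.hypot(d.Lx, d.Ly)
        edge_x = 16 + int(np.argmax(grad[24, 16:28]))
        r_est = abs(1.0 / curv.kappa[24, edge_x])
        assert r_est == pytest.approx(10.0, rel=0.10)

    def test_flat_region_masked_not_nan(self):
        d = iso.gaussian_derivatives(np.full((30, 30), 0.4), sigma=1.0)
        curv = iso.isophote_curvature(d)
        assert not curv.valid_mask.any()
        assert np.all(np.isfinite(curv.kappa))


class TestDisplacementVectors:
    def test_paraboloid_displaces_to_origin(self):
        img, c = paraboloid()
        d = iso.gaussian_derivatives(img, sigma=1.0)
        curv = iso.isophote_curvature(d)
        field = iso.displacement_vectors(d, curv, max_displacement=40.0)
        y, x = int(c + 4), int(c + 3)
        assert field.valid_mask[y, x]
        assert field.dx[y, x] == pytest.approx(-3.0, abs=1e-6)
        assert field.dy[y, x] == pytest.approx(-4.0, abs=1e-6)
        # every interior valid pixel's vote lands on the center
        ys, xs = np.nonzero(field.valid_mask[8:-8, 8:-8])
        ys, xs = ys + 8, xs + 8
        land_x = xs + field.dx[ys, xs] - c
        land_y = ys + field.dy[ys, xs] - c
        assert np.max(np.hypot(land_x, land_y)) < 1e-6

    def test_ramp_has_no_valid_displacements(self):
        img = np.tile(np.arange(41, dtype=float), (41, 1))
        d = iso.gaussian_derivatives(img, sigma=1.0)
        field = iso.displacement_vectors(d, iso.isophote_curvature(d),
                                         max_displacement=40.0)
        assert not field.valid_mask[8:-8, 8:-8].any()

    def test_disk_edge_votes_near_center(self):
        p = synth.EyeSceneParams(center=(32.0, 24.0), pupil_radius=8.0,
                                 iris_radius=16.0)
        img = ndimage.gaussian_filter(synth.render_eye(p).image, 1.0)
        d = iso.gaussian_derivatives(img, sigma=1.0)
        curv = iso.isophote_curvature(d)
        field = iso.displacement_vectors(d, curv, max_displacement=40.0)
        dist = np.hypot(np.arange(64)[None, :] - 32, np.arange(48)[:, None] - 24)
        ring = field.valid_mask & (np.abs(dist - 8.0) < 1.0)
        ys, xs = np.nonzero(ring)
        land = np.hypot(xs + field.dx[ys, xs] - 32, ys + field.dy[ys, xs] - 24)
        assert (land <= 1.5).mean() >= 0.9

    def test_contrast_scaling_leaves_geometry_unchanged(self):
        img = smooth_random_patch(seed=3, size=41)
        d1 = iso.gaussian_derivatives(img, sigma=1.5)
        d2 = iso.gaussian_derivatives(3.0 * img, sigma=1.5)
        c1 = iso.isophote_curvature(d1)
        c2 = iso.isophote_curvature(d2)
        both = c1.valid_mask & c2.valid_mask
        assert np.allclose(c1.kappa[both], c2.kappa[both], atol=1e-9)
        f1 = iso.displacement_vectors(d1, c1, 60.0)
        f2 = iso.displacement_vectors(d2, c2, 60.0)
        ok = f1.valid_mask & f2.valid_mask
        assert np.allclose(f1.dx[ok], f2.dx[ok], atol=1e-9)
        assert np.allclose(f2.weight[ok], 3.0 * f1.weight[ok], atol=1e-9)

    def test_dark_only_keeps_dark_centered_votes(self):
        img, c = paraboloid()  # dark center at the middle
        d = iso.gaussian_derivatives(img, sigma=1.0)
        curv = iso.isophote_curvature(d)
        dark = iso.displacement_vectors(d, curv, 40.0, dark_only=True)
        assert dark.valid_mask[int(c) + 4, int(c) + 3]
        # inverted paraboloid has a bright center: dark-only suppresses it
        d_inv = iso.gaussian_derivatives(-img, sigma=1.0)
        inv = iso.displacement_vectors(d_inv, iso.isophote_curvature(d_inv), 40.0,
                                       dark_only=True)
        assert not inv.valid_mask[8:-8, 8:-8].any()


class TestAccumulateVotes:
    def _single_vote_field(self, shape, at, d, weight=1.0):
        h, w = shape
        valid = np.zeros(shape, bool)
        valid[at[1], at[0]] = True
        dx = np.zeros(shape)
        dy = np.zeros(shape)
        wgt = np.zeros(shape)
        dx[at[1], at[0]] = d[0]
        dy[at[1], at[0]] = d[1]
        wgt[at[1], at[0]] = weight
        return iso.DisplacementField(dx=dx, dy=dy, weight=wgt, valid_mask=valid)

    def test_integer_landing_vote(self):
        f = self._single_vote_field((12, 12), at=(5, 5), d=(2, 0))
        votes = iso.accumulate_votes(f, (12, 12))
        assert votes[5, 7] == 1.0 and votes.sum() == 1.0

    def test_half_integer_landing_splits_mass(self):
        f = self._single_vote_field((12, 12), at=(5, 5), d=(2.5, 0))
        votes = iso.accumulate_votes(f, (12, 12))
        assert votes[5, 7] == pytest.approx(0.5) and votes[5, 8] == pytest.approx(0.5)

    def test_empty_mask_gives_zero_accumulator(self):
        f = self._single_vote_field((12, 12), at=(5, 5), d=(0, 0), weight=0.0)
        f = iso.DisplacementField(dx=f.dx, dy=f.dy, weight=f.weight,
                                  valid_mask=np.zeros((12, 12), bool))
        assert iso.accumulate_votes(f, (12, 12)).sum() == 0.0

    def test_out_of_bounds_votes_dropped(self):
        f = self._single_vote_field((12, 12), at=(11, 5), d=(5, 0))
        assert iso.accumulate_votes(f, (12, 12)).sum() == 0.0

    def test_mass_conservation_matches_python_oracle(self):
        img = synth.render_eye(synth.EyeSceneParams(noise_sigma=0.03, seed=11)).image
        d = iso.gaussian_derivatives(img, sigma=1.0)
        field = iso.displacement_vectors(d, iso.isophote_curvature(d),
                                         max_displacement=40.0)
        votes = iso.accumulate_votes(field, img.shape)
        want, dropped = oracles.splat_votes(field.dx.tolist(), field.dy.tolist(),
                                            field.weight.tolist(),
                                            field.valid_mask.tolist(), *img.shape)
        assert votes.sum() == pytest.approx(field.weight[field.valid_mask].sum() - dropped,
                                            abs=1e-9)
        assert np.max(np.abs(votes - np.array(want))) < 1e-9


class TestDogPyramid:
    def test_level_count_and_scales(self):
        img = smooth_random_patch(seed=2, size=64)
        cfg = iso.PyramidConfig(n_octaves=2, n_intervals=2)
        levels = iso.dog_pyramid(img, cfg)
        assert [s for _, s in levels] == [1, 1, 2, 2]

    def test_constant_image_gives_zero_levels(self):
        cfg = iso.PyramidConfig(n_octaves=2, n_intervals=2)
        for level, _ in iso.dog_pyramid(np.full((64, 64), 0.7), cfg):
            assert np.all(level == 0.0)

    def test_levels_are_zero_mean_unit_max(self):
        img = smooth_random_patch(seed=6, size=64)
        for level, _ in iso.dog_pyramid(img, iso.PyramidConfig(n_octaves=2)):
            assert abs(level.mean()) < 1e-12
            assert np.abs(level).max() == pytest.approx(1.0)

    def test_too_small_image_raises(self):
        with pytest.raises(DegenerateInputError):
            iso.dog_pyramid(np.zeros((8, 8)), iso.PyramidConfig())

    def test_octaves_reduced_with_warning_on_small_image(self, caplog):
        img = smooth_random_patch(seed=2, size=40)
        with caplog.at_level("WARNING", logger="pupilloc"):
            levels = iso.dog_pyramid(img, iso.PyramidConfig(n_octaves=4, n_intervals=1))
        assert "stopping pyramid" in caplog.text
        assert max(s for _, s in levels) < 8


class TestMultiscaleVoteSpace:
    def test_dark_disk_argmax_at_center(self):
        p = synth.EyeSceneParams(center=(30.0, 22.0), pupil_radius=6.0,
                                 iris_radius=12.0)
        votes = iso.multiscale_vote_space(synth.render_eye(p).image)
        iy, ix = np.unravel_index(np.argmax(votes), votes.shape)
        assert abs(ix - 30) <= 1 and abs(iy - 22) <= 1

    def test_constant_patch_gives_zero_votes(self):
        votes = iso.multiscale_vote_space(np.full((48, 64), 0.6))
        assert np.all(votes == 0.0)

    def test_sum_of_levels_equals_total(self):
        img = synth.render_eye(synth.EyeSceneParams(noise_sigma=0.02, seed=8)).image
        cfg = iso.PyramidConfig()
        total = iso.multiscale_vote_space(img, cfg)
        max_disp = 0.5 * float(np.hypot(*img.shape))
        ys, xs = np.mgrid[0:img.shape[0], 0:img.shape[1]].astype(float)
        partial = np.zeros(img.shape)
        for level, scale in iso.dog_pyramid(img, cfg):
            acc = iso.vote_space_for_level(level, scale, cfg, max_disp)
            if acc.shape != img.shape:
                acc = ndimage.map_coordinates(acc, [ys / scale, xs / scale],
                                              order=1, mode="nearest")
            partial += acc
        assert np.max(np.abs(total - partial)) < 1e-9

    def test_rotation_covariance_on_square_disk_patch(self):
        p = synth.EyeSceneParams(patch_w=48, patch_h=48, center=(20.0, 26.0),
                                 pupil_radius=5.0, iris_radius=10.0)
        img = synth.render_eye(p).image
        votes = iso.multiscale_vote_space(img)
        votes_rot = iso.multiscale_vote_space(np.rot90(img))
        iy, ix = np.unravel_index(np.argmax(votes), votes.shape)
        ry, rx = np.unravel_index(np.argmax(votes_rot), votes_rot.shape)
        # np.rot90 maps (x, y) -> (y, N-1-x)
        assert abs(rx - iy) <= 1 and abs(ry - (47 - ix)) <= 1
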