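"""Colocalization, linescan extraction and spline-averaging tests."""

import numpy as np
import pytest

from cortifilo import (
    Micrograph,
    SceneParams,
    cytofluorogram,
    extract_linescan,
    longest_axis_profile,
    make_cell_scene,
    make_two_channel_scene,
    max_project,
    normalize_profile,
)
from cortifilo.profiles import (
    LinescanProfile,
    average_profiles_spline,
    pseudopod_costaining_correlation,
    rcs_basis,
)
from cortifilo.segment import CellRecord

from conftest import noiseless


def flat_image(shape=(32, 32), value=5.0, px=0.212):
    return Micrograph(np.full(shape, value), px)


class TestCytofluorogram:
    @pytest.fixture()
    def noisy_pair(self):
        rng = np.random.default_rng(50)
        a = Micrograph(rng.uniform(1, 100, (64, 64)), 0.212)
        mask = np.zeros((64, 64), bool)
        mask[8:56, 8:56] = True
        return a, mask

    def test_identical_channels_r_one(self, noisy_pair):
        a, mask = noisy_pair
        assert cytofluorogram(a, a, mask).pearson_r == pytest.approx(1.0)

    def test_negated_channel_r_minus_one(self, noisy_pair):
        a, mask = noisy_pair
        b = Micrograph(a.pixels.max() - a.pixels, a.pixel_size_um)
        assert cytofluorogram(a, b, mask).pearson_r == pytest.approx(-1.0)

    def test_constant_channel_errors(self, noisy_pair):
        a, mask = noisy_pair
        with pytest.raises(ValueError, match="constant"):
            cytofluorogram(a, flat_image((64, 64)), mask)

    def test_small_mask_flagged_unstable(self, noisy_pair):
        a, _ = noisy_pair
        small = np.zeros((64, 64), bool)
        small[0:5, 0:5] = True
        assert cytofluorogram(a, Micrograph(a.pixels[::-1], 0.212), small).unstable

    def test_affine_rescale_invariance(self, noisy_pair):
        a, mask = noisy_pair
        rng = np.random.default_rng(51)
        b = Micrograph(rng.uniform(1, 50, (64, 64)), 0.212)
        r0 = cytofluorogram(a, b, mask).pearson_r
        b2 = Micrograph(3.0 * b.pixels + 7.0, 0.212)
        assert cytofluorogram(a, b2, mask).pearson_r == pytest.approx(r0, abs=1e-12)

    def test_simulated_correlation_with_covariance_oracle(self):
        p = SceneParams(
            image_shape=(480, 480), pixel_size_um=0.1, cell_radius_um=19.0,
            nucleus_radius_um=3.0, nucleus_offset_um=2.0, n_slices=1, seed=52,
        )
        (sa, sb), truth = make_two_channel_scene(p, rho=0.8)
        a, b = max_project(sa), max_project(sb)
        mask = truth.cells[0].body_mask
        assert mask.sum() >= 1e5
        res = cytofluorogram(a, b, mask)
        va = a.pixels[mask]
        vb = b.pixels[mask]
        oracle = ((va - va.mean()) * (vb - vb.mean())).mean() / (va.std() * vb.std())
        assert res.pearson_r == pytest.approx(oracle, abs=1e-12)
        assert res.pearson_r == pytest.approx(0.8, abs=0.02)


class TestExtractLinescan:
    def test_constant_image_constant_profile(self):
        prof = extract_linescan(flat_image(), (5.0, 2.0), (25.0, 28.0))
        assert np.allclose(prof.intensities, 5.0)

    def test_axis_aligned_exact_raster_values(self):
        rng = np.random.default_rng(53)
        img = Micrograph(rng.uniform(0, 10, (20, 20)), 0.5)
        prof = extract_linescan(img, (7.0, 2.0), (7.0, 17.0), width_px=1)
        assert np.allclose(prof.intensities, img.pixels[7, 2:18])
        assert np.allclose(np.diff(prof.positions_um), 0.5)

    def test_step_edge_transition_location(self):
        img = np.full((40, 60), 10.0)
        img[:, 30:] = 100.0  # edge between cols 29 and 30
        prof = extract_linescan(Micrograph(img, 0.2), (20.0, 5.0), (20.0, 55.0))
        mid = (10 + 100) / 2
        crossing = np.interp(mid, prof.intensities, prof.positions_um)
        true_edge_um = (29.5 - 5.0) * 0.2
        assert abs(crossing - true_edge_um) <= 2 * 0.2

    def test_zero_length_errors(self):
        with pytest.raises(ValueError):
            extract_linescan(flat_image(), (3.0, 3.0), (3.0, 3.0))


class TestLongestAxis:
    @staticmethod
    def _cell_from_mask(mask, px=0.212):
        com = np.argwhere(mask).mean(axis=0)
        return CellRecord(1, mask, np.zeros_like(mask), tuple(com),
                          np.empty((0, 2)), 0.0, 1.0, px)

    def test_ellipse_axis_orientation(self):
        from skimage.draw import ellipse

        for rot in (0.0, 0.5, 1.0, 2.0):
            m = np.zeros((220, 220), bool)
            rr, cc = ellipse(110, 110, 60, 30, rotation=rot)
            m[rr, cc] = True
            img = Micrograph(m * 100.0, 0.212)
            prof = longest_axis_profile(img, self._cell_from_mask(m), margin_um=0.0)
            # length within a few percent of the major axis = 120 px
            assert prof.positions_um[-1] == pytest.approx(120 * 0.212, rel=0.03)

    def test_circle_profile_length_is_diameter(self):
        rr, cc = np.mgrid[0:120, 0:120]
        m = np.hypot(rr - 60, cc - 60) <= 40
        img = Micrograph(m * 100.0, 0.212)
        cell = self._cell_from_mask(m)
        prof = longest_axis_profile(img, cell, margin_um=0.0)
        assert prof.positions_um[-1] == pytest.approx(80 * 0.212, rel=0.02)
        assert "near_circular" in cell.flags

    def test_cortically_enriched_cell_has_two_peripheral_peaks(self):
        p = noiseless(enrichment_factor=1.8, seed=54)
        stack, truth = make_cell_scene(p)
        img = max_project(stack)
        from cortifilo.simulate import truth_to_cell_record

        cell, part = truth_to_cell_record(truth.cells[0], p.pixel_size_um)
        prof = longest_axis_profile(img, cell, width_px=3, margin_um=0.0)
        n = prof.intensities.size
        third = n // 3
        first_peak = prof.positions_um[np.argmax(prof.intensities[:third])]
        last_peak = prof.positions_um[2 * third + np.argmax(prof.intensities[2 * third :])]
        interior = np.median(prof.intensities[third : 2 * third])
        assert prof.intensities.max() > 1.3 * interior
        # peaks sit within ~1 um of the band center at each end
        band_center = 0.4  # um inside the boundary
        assert first_peak - prof.positions_um[0] < band_center + 1.0
        assert prof.positions_um[-1] - last_peak < band_center + 1.0


class TestNormalize:
    def test_simple_example(self):
        prof = LinescanProfile(np.array([0.0, 1, 2]), np.array([2.0, 4, 6]),
                               ((0, 0), (0, 2)), 1)
        out = normalize_profile(prof)
        assert np.allclose(out.intensities, [0, 0.5, 1])

    def test_idempotent_and_order_preserving(self):
        rng = np.random.default_rng(55)
        y = rng.uniform(0, 9, 50)
        prof = LinescanProfile(np.arange(50.0), y, ((0, 0), (0, 49)), 1)
        once = normalize_profile(prof)
        twice = normalize_profile(once)
        assert np.allclose(once.intensities, twice.intensities)
        assert once.intensities.min() == 0.0 and once.intensities.max() == 1.0
        assert np.array_equal(np.argsort(once.intensities), np.argsort(y))

    def test_constant_profile_errors(self):
        prof = LinescanProfile(np.arange(5.0), np.full(5, 3.0), ((0, 0), (0, 4)), 1)
        with pytest.raises(ValueError):
            normalize_profile(prof)


def sigmoid_profiles(rng, n=10, sigma=0.05):
    x = np.linspace(0, 1, 100)
    true = 1 / (1 + np.exp(-(x - 0.5) * 8))
    profs = [
        LinescanProfile(x.copy(), true + rng.normal(0, sigma, x.size),
                        ((0, 0), (0, 1)), 1)
        for _ in range(n)
    ]
    return x, true, profs


class TestSplineAveraging:
    def test_rcs_basis_linear_beyond_boundary_knots(self):
        knots = np.array([0.1, 0.3, 0.5, 0.7, 0.9])
        x = np.linspace(1.0, 2.0, 50)  # beyond the last knot
        X = rcs_basis(x, knots)
        for j in range(X.shape[1]):
            resid = np.polyfit(x, X[:, j], 1, full=True)[1]
            assert resid[0] < 1e-18  # every basis column is linear out there

    def test_identical_profiles_recovered(self):
        x = np.linspace(0, 1, 100)
        true = 1 / (1 + np.exp(-(x - 0.5) * 8))
        profs = [LinescanProfile(x.copy(), true.copy(), ((0, 0), (0, 1)), 1)
                 for _ in range(10)]
        s = average_profiles_spline(profs, n_knots=5, grid=x)
        assert np.max(np.abs(s.mean_curve - true)) < 0.01

    def test_noisy_sigmoid_rmse(self):
        x, true, profs = sigmoid_profiles(np.random.default_rng(56))
        s = average_profiles_spline(profs, n_knots=5, grid=x)
        rmse = np.sqrt(np.mean((s.mean_curve - true) ** 2))
        assert rmse < 0.03

    def test_sem_equals_sd_over_sqrt_n(self):
        x, true, profs = sigmoid_profiles(np.random.default_rng(57))
        s = average_profiles_spline(profs, grid=x)
        assert np.allclose(s.sem_band, s.sd_band / np.sqrt(10))

    def test_order_invariance(self):
        x, true, profs = sigmoid_profiles(np.random.default_rng(58))
        s1 = average_profiles_spline(profs, grid=x)
        s2 = average_profiles_spline(profs[::-1], grid=x)
        assert np.allclose(s1.mean_curve, s2.mean_curve)

    def test_too_few_knots_or_profiles_error(self):
        x, true, profs = sigmoid_profiles(np.random.default_rng(59))
        with pytest.raises(ValueError):
            average_profiles_spline(profs, n_knots=2)
        with pytest.raises(ValueError):
            average_profiles_spline(profs[:1])


class TestCostaining:
    def test_duplicated_channel_r_one(self):
        x, true, profs = sigmoid_profiles(np.random.default_rng(60))
        res = pseudopod_costaining_correlation(profs, profs)
        assert np.allclose(res["per_line_r"], 1.0)

    def test_shuffled_null_mean_near_zero(self):
        rng = np.random.default_rng(61)
        x = np.linspace(0, 1, 100)
        a, b = [], []
        for _ in range(20):
            ya = rng.uniform(0, 1, x.size)
            yb = rng.permutation(ya)
            a.append(LinescanProfile(x.copy(), ya, ((0, 0), (0, 1)), 1))
            b.append(LinescanProfile(x.copy(), yb, ((0, 0), (0, 1)), 1))
        res = pseudopod_costaining_correlation(a, b)
        assert abs(res["mean_r"]) < 0.1

    def test_shared_front_high_correlation(self):
        rng = np.random.default_rng(62)
        x, true, profs_a = sigmoid_profiles(rng)
        _, _, profs_b = sigmoid_profiles(rng)
        res = pseudopod_costaining_correlation(profs_a, profs_b)
        assert res["mean_r"] > 0.9

    def test_unpaired_inputs_error(self):
        x, true, profs = sigmoid_profiles(np.random.default_rng(63))
        with pytest.raises(ValueError):
            pseudopod_costaining_correlation(profs, profs[:5])
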