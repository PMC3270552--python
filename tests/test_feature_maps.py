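"""Gaussian scale-space derivatives, the MLvv valley operator and probability maps."""

import numpy as np
import pytest
from scipy import ndimage

import echoreg as er
from echoreg import BinaryMask, ParameterError, ScaleParam, Volume3D


def grid(n):
    x = np.arange(n, dtype=float) - (n - 1) / 2
    return np.meshgrid(x, x, x, indexing="ij")


class TestGaussianDerivative:
    def test_ramp_first_derivative_is_slope(self):
        X, _, _ = grid(25)
        v = Volume3D(3.5 * X)
        out = er.gaussian_derivative(v, 2.0, (1, 0, 0)).data
        assert np.allclose(out[9:16, 9:16, 9:16], 3.5, atol=1e-9)

    def test_ramp_second_derivative_is_zero(self):
        X, _, _ = grid(25)
        out = er.gaussian_derivative(Volume3D(3.5 * X), 2.0, (2, 0, 0)).data
        assert np.allclose(out[9:16, 9:16, 9:16], 0.0, atol=1e-9)

    def test_sine_derivative_matches_fourier_attenuation(self):
        # d/dx of the Gaussian-filtered sin(kx) is k*cos(kx)*exp(-sigma^2 k^2/2)
        n, sigma = 64, 2.0
        k = 2 * np.pi / 32
        x = np.arange(n, dtype=float)
        v = Volume3D(np.tile(np.sin(k * x)[:, None, None], (1, 8, 8)))
        out = er.gaussian_derivative(v, sigma, (1, 0, 0)).data
        expected = k * np.cos(k * x) * np.exp(-(sigma**2) * k**2 / 2)
        interior = slice(12, -12)
        assert np.max(np.abs(out[interior, 4, 4] - expected[interior])) < 1e-3

    @pytest.mark.parametrize("orders", [(3, 0, 0), (1, 1, 1), (2, 1, 0)])
    def test_unsupported_orders_rejected(self, orders):
        with pytest.raises(ParameterError):
            er.gaussian_derivative(Volume3D(np.zeros((5, 5, 5))), 1.0, orders)


class TestMlvv:
    def test_constant_volume_gives_exact_zero(self):
        out = er.compute_mlvv(Volume3D(np.full((16, 16, 16), 5.0)))
        assert np.all(out.data == 0)

    def test_dark_tube_valley_is_plus_one(self):
        # continuous oracle: V = x^2 + y^2 has MLvv magnitude exactly 1
        # (bracket 8r^2, gradient norm^2 4r^2), positive under the
        # valley-positive convention
        X, Y, Z = grid(41)
        out = er.compute_mlvv(Volume3D(X**2 + Y**2), ScaleParam(2.0)).data
        r = np.sqrt(X**2 + Y**2)
        sel = (np.abs(X) <= 10) & (np.abs(Y) <= 10) & (np.abs(Z) <= 10) & (r >= 5)
        assert np.max(np.abs(out[sel] - 1.0)) < 0.05

    def test_bright_tube_crest_is_minus_one(self):
        X, Y, Z = grid(41)
        out = er.compute_mlvv(Volume3D(-(X**2) - Y**2), ScaleParam(2.0)).data
        r = np.sqrt(X**2 + Y**2)
        sel = (np.abs(X) <= 10) & (np.abs(Y) <= 10) & (np.abs(Z) <= 10) & (r >= 5)
        assert np.max(np.abs(out[sel] + 1.0)) < 0.05

    def test_additive_shift_invariance(self, rng):
        data = ndimage.gaussian_filter(rng.normal(size=(20, 20, 20)), 2)
        a = er.compute_mlvv(Volume3D(data)).data
        b = er.compute_mlvv(Volume3D(data + 57.0)).data
        assert np.allclose(a, b, atol=1e-9)

    def test_linear_in_positive_scaling(self, rng):
        data = ndimage.gaussian_filter(rng.normal(size=(20, 20, 20)), 2)
        a = er.compute_mlvv(Volume3D(data)).data
        b = er.compute_mlvv(Volume3D(3.0 * data)).data
        assert np.allclose(b, 3.0 * a, atol=1e-8 * np.max(np.abs(a)))

    def test_approximate_rotation_equivariance(self):
        X, Y, Z = grid(41)
        v = Volume3D(np.exp(-((X - 3) ** 2 + Y**2) / 30.0))
        T = er.RigidTransform((0, 0, 0), (0, 0, 25), center=(20, 20, 20))
        rotated = er.resample(v, T, v)
        a = er.resample(er.compute_mlvv(v), T, v).data  # rotate the response
        b = er.compute_mlvv(rotated).data  # respond to the rotated image
        interior = (slice(10, -10),) * 3
        scale = np.max(np.abs(a[interior]))
        assert np.mean(np.abs(a[interior] - b[interior])) < 0.05 * scale


@pytest.fixture(scope="module")
def mr_and_lesion():
    spec = er.PhantomSpec(seed=9, shape=(40, 40, 40), mr_noise_sigma=0.0)
    mr, truth = er.generate_mr_phantom(spec)
    return mr, truth


class TestMrProbabilityMap:

    def test_lesion_voxels_have_probability_psi_one(self, mr_and_lesion):
        mr, truth = mr_and_lesion
        pmap = er.mr_probability_map(mr, truth.lesion_mask, psi=1.0)
        assert np.all(pmap.data[truth.lesion_mask.bool_data] == 1.0)

    def test_crest_voxels_outside_lesion_are_zero(self, mr_and_lesion):
        mr, truth = mr_and_lesion
        mlvv = er.compute_mlvv(mr)
        pmap = er.mr_probability_map(mr, truth.lesion_mask, psi=1.0)
        crest = (mlvv.data < 0) & ~truth.lesion_mask.bool_data
        assert crest.any()
        assert np.all(pmap.data[crest] == 0.0)

    def test_max_mlvv_voxel_maps_to_one(self, mr_and_lesion):
        mr, truth = mr_and_lesion
        pmap = er.mr_probability_map(mr, lesion=None)
        mlvv = er.compute_mlvv(mr)
        assert pmap.data[np.unravel_index(np.argmax(mlvv.data), mlvv.shape)] == 1.0

    def test_values_in_unit_interval(self, mr_and_lesion):
        mr, truth = mr_and_lesion
        pmap = er.mr_probability_map(mr, truth.lesion_mask, psi=0.7)
        assert pmap.data.min() >= 0.0 and pmap.data.max() <= 1.0

    def test_psi_scales_lesion_probability(self, mr_and_lesion):
        mr, truth = mr_and_lesion
        pmap = er.mr_probability_map(mr, truth.lesion_mask, psi=0.6)
        inside = truth.lesion_mask.bool_data
        assert np.all(pmap.data[inside] >= 0.6 - 1e-12)

    def test_invalid_psi_rejected(self, mr_and_lesion):
        mr, truth = mr_and_lesion
        with pytest.raises(ParameterError):
            er.mr_probability_map(mr, truth.lesion_mask, psi=1.5)

    def test_valley_response_covers_centerlines(self, mr_and_lesion):
        # strong responses sit on true valleys (precision) and true valleys
        # respond (recall); the global max-scaling makes absolute response
        # levels uneven along structures, so thresholds are one-sided
        mr, truth = mr_and_lesion
        scaled = er.scaled_positive_mlvv(er.compute_mlvv(mr)).data
        strong = scaled > 0.5
        skel = ndimage.binary_dilation(truth.valley_mask.bool_data, iterations=2)
        assert strong.any()
        precision = np.sum(strong & skel) / np.sum(strong)
        recall = np.mean(scaled[truth.valley_mask.bool_data] > 0.1)
        assert precision > 0.9
        assert recall > 0.8


class TestUsProbabilityMap:
    def test_linear_rescale_of_intensities(self):
        v = Volume3D(np.array([0.0, 128.0, 255.0]).reshape(3, 1, 1))
        out = er.us_probability_map(v).data.ravel()
        assert np.allclose(out, [0.0, 128 / 255, 1.0])

    def test_constant_volume_maps_to_zero(self):
        assert np.all(er.us_probability_map(Volume3D(np.full((4, 4, 4), 9.0))).data == 0)

    def test_shadow_zeros_stay_zero(self, rng):
        data = rng.uniform(0.0, 200.0, size=(8, 8, 8))
        data[:, :, :3] = 0.0  # acoustic shadow
        out = er.us_probability_map(Volume3D(data)).data
        assert np.all(out[:, :, :3] == 0.0)
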