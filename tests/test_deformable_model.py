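"""Hypernetwork conditioning, SVF symmetrization, and diffeomorphic integration."""

import numpy as np
import pytest
from scipy.linalg import expm
from scipy.ndimage import gaussian_filter

from synthreg import geometry as geo
from synthreg.autodiff import Tensor
from synthreg.deformable_model import (HyperNetConfig, UNetConfig,
                                       hypernet_forward, init_hypernet_params,
                                       integrate_svf, joint_register,
                                       symmetrize_svf, unet_layer_shapes,
                                       unet_svf)
from synthreg.metrics import folding_fraction


@pytest.fixture(scope="module")
def configs():
    return UNetConfig.desk_2d(), HyperNetConfig()


@pytest.fixture(scope="module")
def xi(configs):
    un, hy = configs
    return init_hypernet_params(un, hy, seed=0)


def random_eta(config, rng):
    """Kernels with a non-silent output head, for asymmetry checks."""
    return [Tensor(0.3 * rng.standard_normal(s))
            for s in unet_layer_shapes(config)]


class TestHypernet:
    def test_output_matches_declared_parameter_count(self, configs, xi):
        un, _ = configs
        eta = hypernet_forward(0.5, xi, un)
        shapes = unet_layer_shapes(un)
        assert [tuple(e.shape) for e in eta] == [tuple(s) for s in shapes]

    def test_deterministic(self, configs, xi):
        un, _ = configs
        a = hypernet_forward(0.3, xi, un)
        b = hypernet_forward(0.3, xi, un)
        assert all(np.array_equal(x.value, y.value) for x, y in zip(a, b))

    def test_lambda_changes_kernels(self, configs):
        un, hy = configs
        rng = np.random.default_rng(5)
        params = init_hypernet_params(un, hy, seed=2)
        # perturb so the map is generic, not the silent-head initialization
        for p in params:
            p.value = p.value + 0.1 * rng.standard_normal(p.value.shape)
        a = hypernet_forward(0.1, params, un)
        b = hypernet_forward(0.9, params, un)
        diff = sum(float(np.abs(x.value - y.value).sum()) for x, y in zip(a, b))
        assert diff > 0

    def test_lambda_out_of_range_rejected(self, configs, xi):
        un, _ = configs
        for bad in (-0.1, 1.1):
            with pytest.raises(ValueError):
                hypernet_forward(bad, xi, un)

    def test_silent_head_initialization(self, configs, xi, rng):
        un, _ = configs
        img = rng.uniform(0, 1, (32, 32))
        eta = [Tensor(e.value) for e in hypernet_forward(0.7, xi, un)]
        v = unet_svf(img, img * 0.3, eta, un)
        assert np.abs(v.values).max() == 0.0


class TestUnetSvf:
    def test_output_shape_and_semantics(self, configs, rng):
        un, _ = configs
        eta = random_eta(un, rng)
        m, f = rng.uniform(0, 1, (2, 32, 32))
        v = unet_svf(m, f, eta, un)
        assert v.semantics == "svf" and v.values.shape == (32, 32, 2)

    def test_deterministic_given_eta(self, configs, rng):
        un, _ = configs
        eta = random_eta(un, rng)
        m, f = rng.uniform(0, 1, (2, 32, 32))
        assert np.array_equal(unet_svf(m, f, eta, un).values,
                              unet_svf(m, f, eta, un).values)

    def test_concatenation_order_matters_before_symmetrization(self, configs, rng):
        un, _ = configs
        eta = random_eta(un, rng)
        m, f = rng.uniform(0, 1, (2, 32, 32))
        assert not np.allclose(unet_svf(m, f, eta, un).values,
                               unet_svf(f, m, eta, un).values)

    def test_grid_mismatch_rejected(self, configs, rng):
        un, _ = configs
        eta = random_eta(un, rng)
        with pytest.raises(ValueError):
            unet_svf(rng.uniform(0, 1, (32, 32)),
                     rng.uniform(0, 1, (16, 16)), eta, un)


class TestSymmetrize:
    def test_equal_inputs_give_zero(self, rng):
        v = geo.VectorField(rng.standard_normal((8, 8, 2)), "svf")
        out = symmetrize_svf(v, v)
        assert np.all(out.values == 0)

    def test_antisymmetry_is_exact(self, rng):
        a = geo.VectorField(rng.standard_normal((8, 8, 2)), "svf")
        b = geo.VectorField(rng.standard_normal((8, 8, 2)), "svf")
        assert np.array_equal(symmetrize_svf(a, b).values,
                              -symmetrize_svf(b, a).values)

    def test_linear_in_inputs(self, rng):
        a = geo.VectorField(rng.standard_normal((8, 8, 2)), "svf")
        b = geo.VectorField(rng.standard_normal((8, 8, 2)), "svf")
        scaled = symmetrize_svf(geo.VectorField(3 * a.values, "svf"),
                                geo.VectorField(3 * b.values, "svf"))
        assert np.allclose(scaled.values, 3 * symmetrize_svf(a, b).values)


class TestIntegrateSvf:
    def test_zero_field_gives_exact_identity(self):
        v = geo.VectorField(np.zeros((16, 16, 2)), "svf")
        phi, phi_inv = integrate_svf(v, steps=10)
        grid = geo.identity_grid((16, 16))
        assert np.array_equal(phi.values, grid)
        assert np.array_equal(phi_inv.values, grid)

    def test_constant_field_integrates_to_translation(self):
        c = np.array([1.3, -0.7])
        v = geo.VectorField(np.broadcast_to(c, (24, 24, 2)).copy(), "svf")
        phi, phi_inv = integrate_svf(v, steps=10)
        interior = (slice(4, -4),) * 2
        u = (phi.values - geo.identity_grid((24, 24)))[interior]
        assert np.abs(u - c).max() < 1e-4
        u_inv = (phi_inv.values - geo.identity_grid((24, 24)))[interior]
        assert np.abs(u_inv + c).max() < 1e-4

    def test_linear_field_matches_matrix_exponential(self):
        m = np.array([[0.05, 0.02], [-0.03, 0.04]])
        grid = geo.identity_grid((24, 24))
        v = geo.VectorField(grid @ m.T, "svf")
        phi, _ = integrate_svf(v, steps=10)
        exact = grid @ expm(m).T
        interior = (slice(4, -4),) * 2
        assert np.abs((phi.values - exact)[interior]).max() < 1e-3

    def test_forward_backward_composition_near_identity(self, rng):
        shape = (32, 32)
        # smooth field: FWHM ~9 voxels, peak displacement 3 voxels
        nu = np.stack([gaussian_filter(rng.standard_normal(shape), 4.0)
                       for _ in range(2)], axis=-1)
        nu *= 3.0 / np.abs(nu).max()
        phi, phi_inv = integrate_svf(geo.VectorField(nu, "svf"), steps=10)
        comp = geo._warp_lookup(phi_inv, phi.values)
        grid = geo.identity_grid(shape)
        interior = (slice(4, -4),) * 2
        err = np.linalg.norm((comp - grid)[interior], axis=-1).mean()
        assert err < 1e-2

    def test_smooth_field_never_folds(self, rng):
        shape = (32, 32)
        for seed in range(5):
            r = np.random.default_rng(seed)
            nu = np.stack([gaussian_filter(r.standard_normal(shape), 3.0)
                           for _ in range(2)], axis=-1)
            nu *= 3.0 / np.abs(nu).max()
            phi, _ = integrate_svf(geo.VectorField(nu, "svf"), steps=10)
            assert folding_fraction(phi) == 0.0

    def test_non_svf_semantics_rejected(self):
        disp = geo.VectorField(np.zeros((8, 8, 2)), "displacement")
        with pytest.raises(ValueError, match="svf"):
            integrate_svf(disp, steps=10)


@pytest.fixture(scope="module")
def theta():
    from synthreg.affine_model import DetectorConfig, init_detector_params
    cfg = DetectorConfig.desk_2d()
    return cfg, init_detector_params(cfg, seed=0)


class TestJointRegister:
    def test_silent_deformable_reduces_to_dense_affine(self, theta, configs,
                                                       xi, rng):
        det, params = theta
        un, _ = configs
        m = rng.uniform(0, 1, (32, 32))
        f = np.clip(m + 0.05 * rng.standard_normal((32, 32)), 0, 1)
        out = joint_register(m, f, 0.5, params, xi, det, un)
        dense = geo.affine_to_warp(out["T"], (32, 32))
        interior = (slice(4, -4),) * 2
        assert np.abs(out["svf"].values).max() == 0.0
        assert np.abs((out["psi"].values - dense.values)[interior]).max() < 1e-6

    def test_self_registration_near_identity(self, theta, configs, xi, rng):
        det, params = theta
        un, _ = configs
        m = rng.uniform(0, 1, (32, 32))
        out = joint_register(m, m, 0.5, params, xi, det, un)
        grid = geo.identity_grid((32, 32))
        interior = (slice(4, -4),) * 2
        assert np.abs((out["psi"].values - grid)[interior]).max() < 1e-4

    def test_invalid_mode_rejected(self, theta, configs, xi, rng):
        det, params = theta
        un, _ = configs
        m = rng.uniform(0, 1, (32, 32))
        with pytest.raises(ValueError, match="mode"):
            joint_register(m, m, 0.5, params, xi, det, un, mode="sideways")
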