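"""Registration: LCC metric, spectral reconstruction, energy, descent."""

import numpy as np
import pytest
from scipy import ndimage

from hectorvi import (
    DivCurlField,
    LungMask,
    RegistrationConfig,
    ScalarVolume,
    lcc_similarity,
    reconstruct_displacement,
    register,
)
from hectorvi.registration import _EnergyModel, divergence, grad_axis, grad_axis_adjoint


def _sine_field(n, m=2):
    """Analytic potential phi = sin(kx) sin(ky) sin(kz) on the DST-I grid."""
    k = np.pi * m / (n + 1)
    i = np.arange(n) + 1.0
    s, c = np.sin(k * i), np.cos(k * i)
    phi = s[:, None, None] * s[None, :, None] * s[None, None, :]
    f1 = -3 * k ** 2 * phi
    u = np.stack([
        k * c[:, None, None] * s[None, :, None] * s[None, None, :],
        k * s[:, None, None] * c[None, :, None] * s[None, None, :],
        k * s[:, None, None] * s[None, :, None] * c[None, None, :],
    ])
    return f1, u


class TestLCC:
    def test_self_similarity_is_one(self, rng):
        vals = ndimage.gaussian_filter(rng.normal(size=(16, 16, 16)), 1.0)
        vol = ScalarVolume(vals)
        sim, grid = lcc_similarity(vol, vol, sigma=1.5)
        assert sim == pytest.approx(1.0, abs=1e-6)
        assert grid.shape == vals.shape

    def test_affine_intensity_invariance(self, rng):
        vals = ndimage.gaussian_filter(rng.normal(size=(16, 16, 16)), 1.0)
        a = ScalarVolume(vals)
        b = ScalarVolume(2.0 * vals + 5.0)
        sim, _ = lcc_similarity(a, b, sigma=1.5)
        assert sim == pytest.approx(1.0, abs=1e-6)

    def test_independent_noise_uncorrelated(self):
        sims = []
        for seed in range(5):
            r = np.random.default_rng(seed)
            a = ScalarVolume(r.normal(size=(20, 20, 20)))
            b = ScalarVolume(r.normal(size=(20, 20, 20)))
            sims.append(lcc_similarity(a, b, sigma=1.5)[0])
        assert max(sims) < 0.2

    def test_locally_constant_windows_contribute_zero(self):
        a = ScalarVolume(np.zeros((10, 10, 10)))
        b = ScalarVolume(np.zeros((10, 10, 10)))
        sim, grid = lcc_similarity(a, b, sigma=1.5)
        assert sim == 0.0
        assert np.all(grid == 0.0)


class TestGradOperators:
    def test_adjoint_identity(self, rng):
        """<D x, y> == <x, D^T y> exactly, per axis."""
        x = rng.normal(size=(7, 8, 9))
        y = rng.normal(size=(7, 8, 9))
        for axis in range(3):
            lhs = float((grad_axis(x, axis) * y).sum())
            rhs = float((x * grad_axis_adjoint(y, axis)).sum())
            assert lhs == pytest.approx(rhs, rel=1e-12)


class TestReconstruction:
    def test_zero_field_gives_zero_displacement(self):
        dc = DivCurlField.zeros((12, 12, 12))
        u = reconstruct_displacement(dc).u
        np.testing.assert_allclose(u, 0.0, atol=1e-14)

    def test_potential_flow_oracle_and_convergence_order(self):
        errs = {}
        for n in (16, 32):
            f1, u_true = _sine_field(n)
            z = np.zeros_like(f1)
            u = reconstruct_displacement(DivCurlField(f1, z, z, z)).u
            errs[n] = np.abs(u - u_true).max() / np.abs(u_true).max()
        assert errs[16] < 0.06
        # O(h^2): doubling resolution should shrink the error ~4x
        assert errs[16] / errs[32] > 2.5

    def test_divergence_consistency(self):
        n = 32
        f1, _ = _sine_field(n)
        z = np.zeros_like(f1)
        u = reconstruct_displacement(DivCurlField(f1, z, z, z)).u
        rel = np.abs(divergence(u) - f1).max() / np.abs(f1).max()
        assert rel < 0.06

    def test_rigid_rotation_data_is_divergence_free(self):
        n = 24
        z = np.zeros((n, n, n))
        dc = DivCurlField(z.copy(), z.copy(), z.copy(), np.full((n, n, n), 0.2))
        u = reconstruct_displacement(dc).u
        assert np.abs(divergence(u)).max() < 1e-12


class TestEnergy:
    def _model(self, F, M, mask=None, **kw):
        if mask is None:
            mask = np.ones(F.shape, bool)
        return _EnergyModel(F, M, mask, RegistrationConfig(mask_dilation=0, **kw))

    def test_zero_field_identical_images_is_global_minimum(self, rng):
        F = ndimage.gaussian_filter(rng.random((12, 12, 12)), 1.0)
        model = self._model(F, F.copy())
        f = np.zeros((4, 12, 12, 12))
        assert model.energy(f) == pytest.approx(0.0, abs=1e-6)

    def test_zero_field_energy_equals_data_term(self, rng):
        F = ndimage.gaussian_filter(rng.random((12, 12, 12)), 1.0)
        M = ndimage.gaussian_filter(rng.random((12, 12, 12)), 1.0)
        model = self._model(F, M)
        f = np.zeros((4, 12, 12, 12))
        sim, _ = lcc_similarity(ScalarVolume(F), ScalarVolume(M), sigma=1.5)
        assert model.energy(f) == pytest.approx(1.0 - sim, abs=1e-9)

    def test_constant_divergence_penalty_closed_form(self, rng):
        """Constant f1 = c, zero curl: regularizer adds exactly alpha1 c^2."""
        F = ndimage.gaussian_filter(rng.random((12, 12, 12)), 1.0)
        M = ndimage.gaussian_filter(rng.random((12, 12, 12)), 1.0)
        c = 0.3
        f = np.zeros((4, 12, 12, 12))
        f[0] = c
        model = self._model(F, M)
        f0 = np.zeros_like(f)
        # isolate the penalty: same data term requires same displacement, so
        # compare against an explicit evaluation with the data term removed
        from hectorvi.registration import _reg_terms
        cfg = RegistrationConfig()
        n = f[0].size  # whole-grid integration domain
        assert _reg_terms(f, cfg, n) == pytest.approx(cfg.alpha1 * c ** 2, rel=1e-9)
        assert _reg_terms(f0, cfg, n) == 0.0

    def test_analytic_gradient_matches_finite_differences(self, rng):
        F = ndimage.gaussian_filter(rng.random((12, 12, 12)), 1.5)
        M = ndimage.gaussian_filter(rng.random((12, 12, 12)), 1.5)
        mask = np.zeros((12, 12, 12), bool)
        mask[3:9, 3:9, 3:9] = True
        model = self._model(F, M, mask)
        f = 0.03 * rng.standard_normal((4, 12, 12, 12))
        _, g, _ = model.energy_grad(f)
        d = rng.standard_normal((4, 12, 12, 12))
        eps = 1e-6
        fd = (model.energy(f + eps * d) - model.energy(f - eps * d)) / (2 * eps)
        assert float((g * d).sum()) == pytest.approx(fd, rel=0.1)


@pytest.fixture(scope="module")
def identity_result(small_case):
    from hectorvi import preprocess_pair

    pair = preprocess_pair(small_case.inhale, small_case.inhale,
                           small_case.inhale_mask, small_case.inhale_mask,
                           grid_size=32, margin=6)
    cfg = RegistrationConfig(n_levels=2, iters_per_level=15)
    return register(pair.inhale_norm, pair.exhale_norm, pair.inhale_mask, cfg)


class TestRegister:
    def test_identity_registration_recovers_zero_field(self, identity_result):
        res = identity_result
        assert np.abs(res.displacement.u).max() < 0.1
        assert np.abs(res.divcurl.f1).max() < 0.01

    def test_energy_trace_non_increasing_per_level(self, identity_result):
        for level_trace in identity_result.energy_trace:
            diffs = np.diff(level_trace)
            assert np.all(diffs <= 1e-12)

    def test_divergence_bound_respected(self, small_case):
        from hectorvi import preprocess_pair

        pair = preprocess_pair(small_case.inhale, small_case.exhale,
                               small_case.inhale_mask, small_case.exhale_mask,
                               grid_size=32, margin=6)
        cfg = RegistrationConfig(n_levels=2, iters_per_level=10, div_bound=0.5)
        res = register(pair.inhale_norm, pair.exhale_norm, pair.inhale_mask, cfg)
        assert np.abs(res.divcurl.f1).max() <= 0.5
        assert np.isfinite(res.displacement.u).all()

    def test_deterministic(self, small_case):
        from hectorvi import preprocess_pair

        pair = preprocess_pair(small_case.inhale, small_case.exhale,
                               small_case.inhale_mask, small_case.exhale_mask,
                               grid_size=32, margin=6)
        cfg = RegistrationConfig(n_levels=1, iters_per_level=5)
        a = register(pair.inhale_norm, pair.exhale_norm, pair.inhale_mask, cfg)
        b = register(pair.inhale_norm, pair.exhale_norm, pair.inhale_mask, cfg)
        np.testing.assert_array_equal(a.divcurl.f1, b.divcurl.f1)
        np.testing.assert_array_equal(a.displacement.u, b.displacement.u)


class TestConfig:
    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            RegistrationConfig(alpha1=-1)
        with pytest.raises(ValueError):
            RegistrationConfig(div_bound=0.0)
        with pytest.raises(ValueError):
            RegistrationConfig(n_levels=0)
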