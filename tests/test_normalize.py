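"""Spherical harmonics, Jacobians, and reorienting warps."""

import numpy as np
import pytest

from tractdissect.core import ScalarVolume, VolumeGrid
from tractdissect.normalize import (DisplacementField, SHCoefficients, Shell,
                                    fibonacci_hemisphere, fibonacci_sphere,
                                    jacobian_from_displacement,
                                    n_sh_coefficients, reorient_shell,
                                    sh_basis, sh_eval, sh_fit,
                                    warp_scalar_volume)
from tractdissect.synthetic import (AXIAL_DIFFUSIVITY, RADIAL_DIFFUSIVITY,
                                    make_warp)


def small_grid(n=8, vox=2.0, origin=None):
    aff = np.diag([vox, vox, vox, 1.0])
    aff[:3, 3] = origin if origin is not None else -vox * (n - 1) / 2.0
    return VolumeGrid((n, n, n), aff)


def tensor_signal(dirs, axis, b=1000.0):
    """Axially symmetric single-tensor attenuation along ``axis``."""
    dots = dirs @ axis
    adc = RADIAL_DIFFUSIVITY + (AXIAL_DIFFUSIVITY - RADIAL_DIFFUSIVITY) * dots**2
    return np.exp(-b * adc)


class TestSH:
    def test_coefficient_count(self):
        assert n_sh_coefficients(8) == 45
        with pytest.raises(ValueError):
            n_sh_coefficients(5)

    def test_constant_projects_to_l0(self):
        dirs = fibonacci_hemisphere(90)
        c = sh_fit(dirs, np.full(90, 2.5), lmax=8)
        assert c.coefficients[0] == pytest.approx(2.5 * np.sqrt(4 * np.pi), rel=1e-7)
        assert np.abs(c.coefficients[1:]).max() < 1e-6

    def test_bandlimited_round_trip_exact(self, rng):
        dirs = fibonacci_hemisphere(90)
        true = SHCoefficients(8, rng.normal(size=45))
        fit = sh_fit(dirs, sh_eval(true, dirs), lmax=8)
        np.testing.assert_allclose(fit.coefficients, true.coefficients, atol=1e-6)

    def test_basis_is_even(self, rng):
        dirs = fibonacci_sphere(50)
        np.testing.assert_allclose(sh_basis(dirs, 8), sh_basis(-dirs, 8),
                                   atol=1e-12)

    def test_antipodal_symmetrization_identical_fit(self, rng):
        dirs = fibonacci_hemisphere(60)
        vals = rng.normal(size=60)
        both = np.concatenate([vals, vals])
        dirs2 = np.vstack([dirs, -dirs])
        np.testing.assert_allclose(
            sh_fit(dirs, vals, 6).coefficients,
            sh_fit(dirs2, both, 6).coefficients, atol=1e-9)

    def test_zero_coefficients_evaluate_to_zero(self):
        z = SHCoefficients(4, np.zeros(15))
        assert np.all(sh_eval(z, fibonacci_hemisphere(10)) == 0)

    def test_too_few_directions_rejected(self):
        with pytest.raises(ValueError, match="directions"):
            sh_fit(fibonacci_hemisphere(20), np.zeros(20), lmax=8)


class TestJacobian:
    def test_identity_field(self):
        g = small_grid()
        f = make_warp("identity", g)
        np.testing.assert_allclose(f.J, np.broadcast_to(np.eye(3), f.J.shape))
        J = jacobian_from_displacement(f.w, g)
        np.testing.assert_allclose(J, f.J, atol=1e-12)

    def test_affine_field_exact_interior(self, rng):
        g = small_grid()
        A = np.eye(3) + 0.1 * rng.normal(size=(3, 3))
        w = g.world_grid() @ A.T + np.array([1.0, -2.0, 0.5])
        J = jacobian_from_displacement(w, g)
        interior = J[1:-1, 1:-1, 1:-1]
        np.testing.assert_allclose(
            interior, np.broadcast_to(A, interior.shape), atol=1e-10)

    def test_sinusoid_matches_analytic_second_order(self):
        errs = []
        for n, vox in ((9, 4.0), (17, 2.0)):
            g = small_grid(n, vox)
            f = make_warp("sinusoid", g, amplitude=(2, 1, 1.5),
                          frequency=(0.2, 0.15, 0.1))
            J_fd = jacobian_from_displacement(f.w, g)
            err = np.abs(J_fd[2:-2, 2:-2, 2:-2] - f.J[2:-2, 2:-2, 2:-2]).max()
            errs.append(err)
        # halving h should shrink the error ~4x
        assert errs[1] < errs[0] / 2.5

    def test_degenerate_grid_rejected(self):
        aff = np.eye(4)
        g = VolumeGrid((2, 5, 5), aff)
        with pytest.raises(ValueError):
            jacobian_from_displacement(np.zeros((2, 5, 5, 3)), g)


class TestWarpScalar:
    def test_identity_preserves_values(self, rng):
        g = small_grid()
        vol = ScalarVolume(g, rng.random(g.shape))
        out = warp_scalar_volume(vol, make_warp("identity", g))
        np.testing.assert_allclose(out.values, vol.values, atol=1e-12)

    def test_translation_shifts_array(self, rng):
        g = small_grid(8, 2.0)
        vals = rng.random(g.shape)
        vol = ScalarVolume(g, vals)
        # pull-back by +1 voxel: out[i] = vol[i+1]
        out = warp_scalar_volume(vol, make_warp("translation", g, offset=(2.0, 0, 0)))
        np.testing.assert_allclose(out.values[:-1], vals[1:], atol=1e-12)

    def test_trilinear_bounded_by_source_range(self, rng):
        g = small_grid()
        vol = ScalarVolume(g, rng.random(g.shape))
        out = warp_scalar_volume(vol, make_warp("sinusoid", g,
                                                amplitude=(0.5, 0.5, 0.5),
                                                frequency=(0.3, 0.3, 0.3)))
        assert out.values.min() >= 0.0 - 1e-12
        assert out.values.max() <= vol.values.max() + 1e-12


def bandlimited_shell(grid, rng, lmax=4, ndirs=45, b=1000.0):
    """Shell whose angular content is exactly representable at lmax."""
    dirs = fibonacci_hemisphere(ndirs)
    basis = sh_basis(dirs, lmax)
    nvox = int(np.prod(grid.shape))
    coef = rng.normal(size=(nvox, basis.shape[1]))
    data = (coef @ basis.T).reshape(grid.shape + (ndirs,))
    return Shell(b, dirs, data)


class TestReorient:
    def test_identity_reproduces_bandlimited_input(self, rng):
        g = small_grid(6, 2.0)
        shell = bandlimited_shell(g, rng, lmax=4)
        out = reorient_shell(shell, g, make_warp("identity", g),
                             target_dirs=shell.directions, lmax=8)
        np.testing.assert_allclose(out.data, shell.data, atol=1e-6)

    def test_translation_shifts_without_angular_change(self, rng):
        g = small_grid(8, 2.0)
        shell = bandlimited_shell(g, rng, lmax=4)
        out = reorient_shell(shell, g,
                             make_warp("translation", g, offset=(2.0, 0, 0)),
                             target_dirs=shell.directions, lmax=8)
        np.testing.assert_allclose(out.data[:-1], shell.data[1:], atol=1e-6)

    def test_rotation_moves_signal_minimum(self):
        """S'(x, n) = S(Rx, Rn): a fiber along v appears along R^-1 v."""
        g = small_grid(6, 2.0)
        v = np.array([0.0, 0.0, 1.0])
        dirs = fibonacci_hemisphere(90)
        sig = tensor_signal(dirs, v)
        data = np.broadcast_to(sig, g.shape + (90,)).copy()
        shell = Shell(1000.0, dirs, data)
        field = make_warp("rotation", g, axis=(1, 0, 0), angle_deg=40.0)
        out = reorient_shell(shell, g, field, target_dirs=dirs, lmax=8)
        R = field.J[0, 0, 0]
        probe = fibonacci_sphere(2000)
        vals = sh_eval(sh_fit(dirs, out.data[3, 3, 3], 8), probe)
        argmin = probe[np.argmin(vals)]
        predicted = R.T @ v  # signal minimum transported to R^-1 v
        ang = np.degrees(np.arccos(min(1.0, abs(float(argmin @ predicted)))))
        assert ang < 2.0

    def _uniform_shell(self, g, rng, lmax=4, ndirs=90):
        """Spatially constant band-limited shell: spatial interpolation is
        then exact everywhere, isolating the angular transport."""
        dirs = fibonacci_hemisphere(ndirs)
        vals = sh_basis(dirs, lmax) @ rng.normal(size=(lmax + 1) * (lmax + 2) // 2)
        return Shell(1000.0, dirs,
                     np.broadcast_to(vals, g.shape + (ndirs,)).copy())

    def test_rotation_composition(self, rng):
        """Reorienting by R1 then R2 equals reorienting by R1 R2 (pull-back:
        the second warp is applied to the output of the first)."""
        g = small_grid(7, 2.0)
        shell = self._uniform_shell(g, rng)
        dirs = shell.directions
        r1 = make_warp("rotation", g, axis=(0, 0, 1), angle_deg=25.0)
        r2 = make_warp("rotation", g, axis=(1, 0, 0), angle_deg=35.0)
        once = reorient_shell(shell, g, r1, target_dirs=dirs, lmax=8)
        twice = reorient_shell(once, g, r2, target_dirs=dirs, lmax=8)
        R1, R2 = r1.J[0, 0, 0], r2.J[0, 0, 0]
        combo = R1 @ R2
        combo_field = DisplacementField(
            g, (g.world_grid().reshape(-1, 3) @ combo.T).reshape(g.shape + (3,)),
            np.broadcast_to(combo, g.shape + (3, 3)).copy())
        direct = reorient_shell(shell, g, combo_field, target_dirs=dirs, lmax=8)
        center = tuple(n // 2 for n in g.shape)
        np.testing.assert_allclose(twice.data[center], direct.data[center],
                                   atol=2e-5)

    def test_l0_transported_unchanged_under_rotation(self, rng):
        """No angular modulation: the angular mean is rotation-invariant."""
        g = small_grid(7, 2.0)
        shell = self._uniform_shell(g, rng)
        field = make_warp("rotation", g, axis=(0, 1, 0), angle_deg=30.0)
        out = reorient_shell(shell, g, field, target_dirs=shell.directions, lmax=8)
        c = tuple(n // 2 for n in g.shape)
        before = sh_fit(shell.directions, shell.data[c], 8).coefficients[0]
        after = sh_fit(shell.directions, out.data[c], 8).coefficients[0]
        assert after == pytest.approx(before, rel=1e-6)

    def test_unit_directions_after_anisotropic_jacobian(self, rng):
        g = small_grid(6, 2.0)
        shell = bandlimited_shell(g, rng, lmax=2, ndirs=30)
        # anisotropic stretch: J != rotation, ||J n|| != 1
        X = g.world_grid()
        w = X * np.array([1.5, 0.7, 1.0])
        J = np.broadcast_to(np.diag([1.5, 0.7, 1.0]), g.shape + (3, 3)).copy()
        out = reorient_shell(shell, g, DisplacementField(g, w, J),
                             target_dirs=shell.directions, lmax=4)
        assert np.all(np.isfinite(out.data))
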