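"""Spatial normalization of diffusion-weighted data with angular reorientation.

Warping raw diffusion MRI into template (MNI) space must reorient the
angular coordinate as well as the spatial one: with ``w(x)`` the displacement
field mapping template to subject coordinates and ``J(x)`` its local Jacobian
matrix, the normalized signal is

    S'(x, n) = S(w(x), J(x) n)

with no modulation in the angular domain.  Angular interpolation goes through
an intermediate real, antipodally symmetric (even-order) spherical-harmonic
representation: per-voxel SH coefficients are fitted in source space,
trilinearly interpolated at ``w(x)``, and evaluated along the reoriented
(unit-normalized) directions ``J(x) n / ||J(x) n||``.

Default output sampling is 90 directions per b-shell on a symmetrized sphere
design; the SH order defaults to lmax = 8.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List

import numpy as np
from scipy import ndimage
from scipy.special import sph_harm_y

from .core import ScalarVolume, VolumeGrid

__all__ = [
    "Shell",
    "ShellData",
    "DisplacementField",
    "SHCoefficients",
    "fibonacci_hemisphere",
    "sh_basis",
    "n_sh_coefficients",
    "sh_fit",
    "sh_eval",
    "jacobian_from_displacement",
    "reorient_shell",
    "warp_scalar_volume",
]

DEFAULT_LMAX = 8
DEFAULT_RIDGE = 1e-8  # relative Tikhonov weight; numerical safeguard only
DEFAULT_N_DIRECTIONS = 90


# ---------------------------------------------------------------------------
# sphere sampling and SH basis
# ---------------------------------------------------------------------------

def fibonacci_hemisphere(n: int) -> np.ndarray:
    """``n`` roughly uniform unit vectors on the upper hemisphere (z >= 0).

    A hemispheric design suffices for antipodally symmetric signals; the
    golden-angle spiral gives a well-conditioned SH design matrix for
    n >> (lmax+1)(lmax+2)/2.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    k = np.arange(n)
    z = (k + 0.5) / n  # upper hemisphere only
    phi = k * np.pi * (3.0 - np.sqrt(5.0))
    r = np.sqrt(1.0 - z**2)
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


def fibonacci_sphere(n: int) -> np.ndarray:
    """``n`` roughly uniform unit vectors over the full sphere."""
    k = np.arange(n)
    z = 1.0 - (2.0 * k + 1.0) / n
    phi = k * np.pi * (3.0 - np.sqrt(5.0))
    r = np.sqrt(np.maximum(0.0, 1.0 - z**2))
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


def n_sh_coefficients(lmax: int) -> int:
    """Number of even-order real SH coefficients, (lmax+1)(lmax+2)/2."""
    if lmax < 0 or lmax % 2:
        raise ValueError("lmax must be a non-negative even integer")
    return (lmax + 1) * (lmax + 2) // 2


def sh_basis(directions: np.ndarray, lmax: int) -> np.ndarray:
    """Real even-order SH design matrix, shape ``(n_dirs, n_coef)``.

    Basis ordering is (l, m) with l = 0, 2, ..., lmax and m = -l..l.  The
    basis is orthonormal on the sphere and even (antipodally symmetric), so
    B(n) == B(-n).
    """
    dirs = np.atleast_2d(np.asarray(directions, dtype=np.float64))
    norms = np.linalg.norm(dirs, axis=-1, keepdims=True)
    if np.any(norms < 1e-12):
        raise ValueError("zero-length direction")
    dirs = dirs / norms
    theta = np.arccos(np.clip(dirs[..., 2], -1.0, 1.0))
    phi = np.arctan2(dirs[..., 1], dirs[..., 0])
    cols = []
    for l in range(0, lmax + 1, 2):
        for m in range(-l, l + 1):
            y = sph_harm_y(l, abs(m), theta, phi)
            if m < 0:
                cols.append(np.sqrt(2.0) * (-1.0) ** m * y.imag)
            elif m == 0:
                cols.append(y.real)
            else:
                cols.append(np.sqrt(2.0) * (-1.0) ** m * y.real)
    return np.stack(cols, axis=-1)


@dataclass
class SHCoefficients:
    """Real even-order SH coefficients of an antipodally symmetric function."""

    lmax: int
    coefficients: np.ndarray

    def __post_init__(self):
        c = np.asarray(self.coefficients, dtype=np.float64)
        want = n_sh_coefficients(self.lmax)
        if c.shape[-1] != want:
            raise ValueError(f"expected {want} coefficients for lmax={self.lmax}, "
                             f"got {c.shape[-1]}")
        if not np.all(np.isfinite(c)):
            raise ValueError("non-finite SH coefficients")
        self.coefficients = c


def sh_fit(directions: np.ndarray, values: np.ndarray, lmax: int,
           ridge: float = DEFAULT_RIDGE) -> SHCoefficients:
    """Least-squares SH fit with a relative Tikhonov (ridge) penalty.

    ``values`` may be 1-D (one function) or ``(..., n_dirs)`` for a batch;
    the ridge weight is relative to ``mean(diag(B^T B))``.  Because the basis
    is even, fitting the antipodally symmetrized data gives the same result.
    """
    B = sh_basis(directions, lmax)
    vals = np.asarray(values, dtype=np.float64)
    if vals.shape[-1] != B.shape[0]:
        raise ValueError("values last axis must match number of directions")
    if B.shape[0] < B.shape[1]:
        raise ValueError(f"need >= {B.shape[1]} directions for lmax={lmax}, "
                         f"got {B.shape[0]}")
    gram = B.T @ B
    lam = ridge * float(np.trace(gram)) / gram.shape[0]
    A = gram + lam * np.eye(gram.shape[0])
    batch_shape = vals.shape[:-1]
    rhs = B.T @ vals.reshape(-1, vals.shape[-1]).T  # (ncoef, nbatch)
    try:
        coef = np.linalg.solve(A, rhs)
    except np.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError(f"SH design rank-deficient after ridge: {exc}")
    coef = coef.T.reshape(batch_shape + (B.shape[1],))
    return SHCoefficients(lmax, coef)


def sh_eval(coeffs: SHCoefficients, directions: np.ndarray) -> np.ndarray:
    """Evaluate an SH expansion at unit directions (linear in coefficients)."""
    B = sh_basis(directions, coeffs.lmax)
    return coeffs.coefficients @ B.T if coeffs.coefficients.ndim > 1 else B @ coeffs.coefficients


# ---------------------------------------------------------------------------
# shells and displacement fields
# ---------------------------------------------------------------------------

@dataclass
class Shell:
    """One b-shell: b-value, unit directions, and a 4-D data block.

    ``data`` has shape ``grid.shape + (n_directions,)``.
    """

    b_value: float
    directions: np.ndarray
    data: np.ndarray

    def __post_init__(self):
        dirs = np.asarray(self.directions, dtype=np.float64)
        if dirs.ndim != 2 or dirs.shape[1] != 3:
            raise ValueError("directions must be (n, 3)")
        if dirs.shape[0] < 6:
            raise ValueError("a shell needs at least 6 directions")
        if np.any(np.abs(np.linalg.norm(dirs, axis=1) - 1.0) > 1e-6):
            raise ValueError("directions must be unit vectors")
        self.directions = dirs
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.shape[-1] != dirs.shape[0]:
            raise ValueError("data last axis must match directions")


@dataclass
class ShellData:
    """Multi-shell diffusion data on one grid.

    ``S(x, n)`` is the value of the direction-``n`` volume at ``x``; shells
    are indexed by b-value.  An optional ``b0`` mean volume is carried for
    tensor-signal normalization and is warped spatially with no angular step.
    """

    grid: VolumeGrid
    shells: List[Shell]
    b0: np.ndarray | None = None

    def __post_init__(self):
        for sh in self.shells:
            if sh.data.shape[:-1] != self.grid.shape:
                raise ValueError("shell data does not match grid shape")
        if self.b0 is not None:
            self.b0 = np.asarray(self.b0, dtype=np.float64)
            if self.b0.shape != self.grid.shape:
                raise ValueError("b0 does not match grid shape")


@dataclass
class DisplacementField:
    """Dense template -> source world-coordinate map with Jacobians.

    ``w`` has shape ``grid.shape + (3,)`` (source world mm per target voxel);
    ``J`` has shape ``grid.shape + (3, 3)`` and is computed by finite
    differences when not supplied.  For the identity field ``w(x) = x`` and
    ``J = I``.
    """

    grid: VolumeGrid
    w: np.ndarray
    J: np.ndarray | None = None

    def __post_init__(self):
        self.w = np.asarray(self.w, dtype=np.float64)
        if self.w.shape != self.grid.shape + (3,):
            raise ValueError("w must have shape grid.shape + (3,)")
        if not np.all(np.isfinite(self.w)):
            raise ValueError("non-finite displacement field")
        if self.J is None:
            self.J = jacobian_from_displacement(self.w, self.grid)
        else:
            self.J = np.asarray(self.J, dtype=np.float64)
            if self.J.shape != self.grid.shape + (3, 3):
                raise ValueError("J must have shape grid.shape + (3, 3)")
            if not np.all(np.isfinite(self.J)):
                raise ValueError("non-finite Jacobian")


def jacobian_from_displacement(w: np.ndarray, grid: VolumeGrid) -> np.ndarray:
    """Finite-difference Jacobian dw/dx of a displacement field, per voxel.

    Central differences in the interior, one-sided at the boundary, chained
    through the grid affine so the result is a dimensionless world-to-world
    derivative.  Exact for affine fields at interior voxels.
    """
    w = np.asarray(w, dtype=np.float64)
    if any(n < 3 for n in grid.shape):
        raise ValueError("grid must have >= 3 voxels along every axis for "
                         "finite differences")
    # dw/dindex: (X, Y, Z, 3 components, 3 index axes)
    grads = np.stack(
        [np.stack(np.gradient(w[..., c], axis=(0, 1, 2)), axis=-1) for c in range(3)],
        axis=-2,
    )
    # chain rule: dindex/dworld = inv(A[:3,:3])
    ainv = np.linalg.inv(grid.affine[:3, :3])
    return grads @ ainv


# ---------------------------------------------------------------------------
# warping
# ---------------------------------------------------------------------------

def _sample_trilinear(vol: np.ndarray, vox_coords: np.ndarray, order: int = 1) -> np.ndarray:
    """Sample a 3-D array at continuous voxel coordinates, zero outside."""
    return ndimage.map_coordinates(vol, vox_coords.T, order=order,
                                   mode="constant", cval=0.0)


def warp_scalar_volume(vol: ScalarVolume, field: DisplacementField,
                       interp: str = "trilinear") -> ScalarVolume:
    """Pull-back resampling of a scalar volume through a displacement field.

    ``out(x) = vol(w(x))``; use ``interp="nearest"`` for label volumes.
    """
    if interp not in ("trilinear", "nearest"):
        raise ValueError(f"interp must be 'trilinear' or 'nearest', got {interp!r}")
    order = 1 if interp == "trilinear" else 0
    src = vol.grid.world_to_voxel(field.w.reshape(-1, 3))
    out = _sample_trilinear(vol.values, src, order=order)
    return ScalarVolume(field.grid, out.reshape(field.grid.shape), units=vol.units)


def reorient_shell(
    shell: Shell,
    source_grid: VolumeGrid,
    field: DisplacementField,
    target_dirs: np.ndarray | None = None,
    lmax: int = DEFAULT_LMAX,
    ridge: float = DEFAULT_RIDGE,
) -> Shell:
    """Warp one b-shell to the field's grid with angular reorientation.

    Per target voxel ``x``: the source SH coefficient maps are trilinearly
    interpolated at ``w(x)`` and evaluated along ``J(x) n / ||J(x) n||`` for
    every requested output direction ``n``.  Voxels where ``||J(x) n||``
    collapses below 1e-6 are zero-filled and counted.
    """
    if target_dirs is None:
        target_dirs = fibonacci_hemisphere(DEFAULT_N_DIRECTIONS)
    target_dirs = np.asarray(target_dirs, dtype=np.float64)

    # per-voxel SH fit in source space (single shared design matrix)
    flat = shell.data.reshape(-1, shell.data.shape[-1])
    coeffs = sh_fit(shell.directions, flat, lmax=lmax, ridge=ridge)
    ncoef = coeffs.coefficients.shape[-1]
    coef_maps = coeffs.coefficients.reshape(source_grid.shape + (ncoef,))

    # spatial interpolation of each coefficient map at w(x)
    tgt_shape = field.grid.shape
    src_vox = source_grid.world_to_voxel(field.w.reshape(-1, 3))
    interp_coef = np.empty((src_vox.shape[0], ncoef))
    for c in range(ncoef):
        interp_coef[:, c] = _sample_trilinear(coef_maps[..., c], src_vox)

    # per-voxel reoriented directions J(x) n, renormalized to the sphere
    Jflat = field.J.reshape(-1, 3, 3)
    out = np.zeros((src_vox.shape[0], len(target_dirs)))
    rotated = np.einsum("vij,dj->vdi", Jflat, target_dirs)
    norms = np.linalg.norm(rotated, axis=-1)
    bad = norms < 1e-6
    n_singular = int(bad.any(axis=1).sum())
    norms_safe = np.where(bad, 1.0, norms)
    unit = rotated / norms_safe[..., None]

    # evaluate: value(v, d) = B(v, d, :) . coef(v, :)
    B = sh_basis(unit.reshape(-1, 3), lmax).reshape(len(Jflat), len(target_dirs), ncoef)
    out = np.einsum("vdc,vc->vd", B, interp_coef)
    out[bad] = 0.0
    if n_singular:
        import warnings
        warnings.warn(f"reorient_shell: {n_singular} voxels with singular "
                      f"Jacobian were zero-filled")
    return Shell(shell.b_value, target_dirs, out.reshape(tgt_shape + (len(target_dirs),)))


def reorient_shell_data(
    data: ShellData,
    field: DisplacementField,
    target_dirs: np.ndarray | None = None,
    lmax: int = DEFAULT_LMAX,
    ridge: float = DEFAULT_RIDGE,
) -> ShellData:
    """Apply :func:`reorient_shell` to every shell; b0 is warped spatially."""
    shells = [reorient_shell(sh, data.grid, field, target_dirs, lmax, ridge)
              for sh in data.shells]
    b0 = None
    if data.b0 is not None:
        b0 = warp_scalar_volume(ScalarVolume(data.grid, data.b0), field).values
    return ShellData(field.grid, shells, b0=b0)
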