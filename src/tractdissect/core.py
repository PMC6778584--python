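"""Streamline and volume data model, TCK/NIfTI I/O, and geometric primitives.

Streamlines are ordered 3-D point sequences in world millimetres (RAS); a
:class:`Tractogram` bundles them with a coordinate-space tag.  Volumes are
3-D grids with a voxel-index -> world-mm affine (0-based indices, voxel-center
convention).  TCK is the canonical on-disk streamline format because its
coordinates are world mm with no affine ambiguity.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import nibabel as nib
import numpy as np
from nibabel import streamlines as nib_streamlines

__all__ = [
    "FormatError",
    "Streamline",
    "Tractogram",
    "VolumeGrid",
    "ScalarVolume",
    "ParcelAtlas",
    "as_streamline",
    "read_tractogram",
    "write_tractogram",
    "read_scalar_volume",
    "write_scalar_volume",
    "read_parcel_atlas",
    "write_parcel_atlas",
    "streamline_length",
    "cumulative_arclength",
    "resample_streamline",
    "distal_segment",
]


class FormatError(ValueError):
    """Raised when an on-disk file violates its declared format."""


# ---------------------------------------------------------------------------
# data model
# ---------------------------------------------------------------------------

def as_streamline(points: Sequence) -> np.ndarray:
    """Validate and return a streamline as a float64 ``(n, 3)`` array.

    A streamline must have at least two points and all-finite coordinates;
    consecutive points need not be equispaced.
    """
    pts = np.asarray(points, dtype=np.float64)
    if pts.ndim != 2 or pts.shape[1] != 3:
        raise ValueError(f"streamline must be (n, 3), got shape {pts.shape}")
    if pts.shape[0] < 2:
        raise ValueError("streamline needs at least 2 points")
    if not np.all(np.isfinite(pts)):
        raise ValueError("streamline contains non-finite coordinates")
    return pts


Streamline = np.ndarray  # (n, 3) float64 world mm; validated by as_streamline


@dataclass
class Tractogram:
    """A sequence of streamlines sharing one coordinate space.

    Parameters
    ----------
    streamlines
        Iterable of ``(n_i, 3)`` world-mm point arrays.
    space
        Coordinate-space tag, ``"subject"`` or ``"MNI"``.
    provenance
        Free-text metadata recorded in the TCK header on write.
    """

    streamlines: list = field(default_factory=list)
    space: str = "subject"
    provenance: str = ""

    def __post_init__(self) -> None:
        self.streamlines = [as_streamline(s) for s in self.streamlines]

    def __len__(self) -> int:
        return len(self.streamlines)

    def __iter__(self) -> Iterator[np.ndarray]:
        return iter(self.streamlines)

    def __getitem__(self, i):
        if isinstance(i, (slice, list, np.ndarray)):
            idx = np.arange(len(self))[i] if isinstance(i, slice) else np.asarray(i)
            return Tractogram([self.streamlines[j] for j in idx],
                              space=self.space, provenance=self.provenance)
        return self.streamlines[i]

    def subset(self, mask_or_indices) -> "Tractogram":
        """Subset preserving order; accepts a boolean mask or index array."""
        arr = np.asarray(mask_or_indices)
        if arr.dtype == bool:
            arr = np.flatnonzero(arr)
        return self[list(arr)]


@dataclass(frozen=True)
class VolumeGrid:
    """A 3-D voxel grid with a voxel-index -> world-mm affine.

    Voxel indices are 0-based and the affine maps *integer* indices to the
    world position of the voxel center.
    """

    shape: tuple
    affine: np.ndarray

    def __post_init__(self) -> None:
        shape = tuple(int(n) for n in self.shape)
        if len(shape) != 3 or any(n <= 0 for n in shape):
            raise ValueError(f"shape must be 3 positive ints, got {shape}")
        aff = np.asarray(self.affine, dtype=np.float64)
        if aff.shape != (4, 4):
            raise ValueError("affine must be 4x4")
        if abs(np.linalg.det(aff[:3, :3])) < 1e-12:
            raise ValueError("affine is singular")
        object.__setattr__(self, "shape", shape)
        object.__setattr__(self, "affine", aff)

    @property
    def inverse_affine(self) -> np.ndarray:
        return np.linalg.inv(self.affine)

    @property
    def voxel_sizes(self) -> np.ndarray:
        """Per-axis voxel edge lengths in mm."""
        return np.linalg.norm(self.affine[:3, :3], axis=0)

    def world_to_voxel(self, points: np.ndarray) -> np.ndarray:
        """Map world-mm points to continuous voxel coordinates."""
        pts = np.atleast_2d(np.asarray(points, dtype=np.float64))
        inv = self.inverse_affine
        return pts @ inv[:3, :3].T + inv[:3, 3]

    def voxel_to_world(self, vox: np.ndarray) -> np.ndarray:
        vox = np.atleast_2d(np.asarray(vox, dtype=np.float64))
        return vox @ self.affine[:3, :3].T + self.affine[:3, 3]

    def contains_voxel(self, vox: np.ndarray) -> np.ndarray:
        """True where rounded voxel coordinates fall inside the grid."""
        v = np.rint(np.atleast_2d(vox)).astype(int)
        return np.all((v >= 0) & (v < np.asarray(self.shape)), axis=1)

    def world_grid(self) -> np.ndarray:
        """World coordinates of every voxel center, shape ``shape + (3,)``."""
        idx = np.stack(np.meshgrid(*[np.arange(n) for n in self.shape],
                                   indexing="ij"), axis=-1).astype(float)
        return idx @ self.affine[:3, :3].T + self.affine[:3, 3]


@dataclass
class ScalarVolume:
    """A real-valued volume on a grid with a unit tag.

    ``units`` is one of ``mm-per-voxel``, ``percent``, ``probability``,
    ``arbitrary``.  Percent values must lie in [0, 100].
    """

    grid: VolumeGrid
    values: np.ndarray
    units: str = "arbitrary"

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=np.float64)
        if vals.shape != self.grid.shape:
            raise ValueError(f"values shape {vals.shape} != grid shape {self.grid.shape}")
        if not np.all(np.isfinite(vals)):
            raise ValueError("volume contains non-finite values")
        if self.units == "percent" and (vals.min() < 0 or vals.max() > 100):
            raise ValueError("percent values must lie in [0, 100]")
        self.values = vals


@dataclass
class ParcelAtlas:
    """Integer label volume plus a label -> parcel-name map (0 = background)."""

    grid: VolumeGrid
    labels: np.ndarray
    names: Mapping[int, str]

    def __post_init__(self) -> None:
        lab = np.asarray(self.labels)
        if not np.issubdtype(lab.dtype, np.integer):
            lab = lab.astype(np.int32)
        if lab.shape != self.grid.shape:
            raise ValueError("labels shape does not match grid")
        if lab.min() < 0:
            raise ValueError("labels must be non-negative")
        present = set(np.unique(lab).tolist()) - {0}
        missing = present - set(int(k) for k in self.names)
        if missing:
            raise ValueError(f"labels without names: {sorted(missing)}")
        self.labels = lab
        self.names = {int(k): str(v) for k, v in self.names.items()}

    def mask(self, name: str) -> np.ndarray:
        """Boolean mask of the parcel with the given name."""
        for lab, nm in self.names.items():
            if nm == name:
                return self.labels == lab
        raise KeyError(name)


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_tractogram(path, space: str = "subject") -> Tractogram:
    """Read a TCK file into a :class:`Tractogram` (world mm, RAS).

    Raises :class:`FormatError` on a malformed header, truncated data, or
    non-finite coordinates, naming the byte offset where available.
    """
    path = Path(path)
    try:
        tck = nib_streamlines.load(str(path), lazy_load=False)
    except Exception as exc:  # nibabel raises several header/dataclass errors
        size = path.stat().st_size if path.exists() else 0
        raise FormatError(f"{path}: not a valid TCK file (byte 0..{size}): {exc}") from exc
    sls = []
    for i, s in enumerate(tck.streamlines):
        arr = np.asarray(s, dtype=np.float64)
        if not np.all(np.isfinite(arr)):
            raise FormatError(
                f"{path}: streamline {i} has non-finite coordinates "
                f"(data section starting at byte {int(tck.header.get('_offset_data', -1))})")
        sls.append(arr)
    prov = str(tck.header.get("provenance", ""))
    return Tractogram(sls, space=space, provenance=prov)


def write_tractogram(t: Tractogram, path) -> None:
    """Write a :class:`Tractogram` to TCK (world mm); re-readable by
    :func:`read_tractogram`."""
    path = Path(path)
    nt = nib_streamlines.Tractogram(t.streamlines, affine_to_rasmm=np.eye(4))
    header = {"provenance": t.provenance, "space": t.space}
    try:
        nib_streamlines.save(nt, str(path), header=header)
    except OSError as exc:
        raise OSError(f"cannot write tractogram to {path}: {exc}") from exc


def _nifti_img(values: np.ndarray, grid: VolumeGrid) -> nib.Nifti1Image:
    return nib.Nifti1Image(np.asarray(values), grid.affine)


def write_scalar_volume(vol: ScalarVolume, path) -> None:
    img = _nifti_img(vol.values.astype(np.float32), vol.grid)
    img.header["descrip"] = vol.units.encode()[:79]
    nib.save(img, str(path))


def read_scalar_volume(path, units: str | None = None) -> ScalarVolume:
    img = nib.load(str(path))
    data = np.asarray(img.get_fdata(), dtype=np.float64)
    if data.ndim != 3:
        raise FormatError(f"{path}: expected a 3-D volume, got {data.ndim}-D")
    if units is None:
        units = img.header["descrip"].tobytes().split(b"\x00")[0].decode() or "arbitrary"
    grid = VolumeGrid(data.shape, img.affine)
    return ScalarVolume(grid, data, units=units)


def write_parcel_atlas(atlas: ParcelAtlas, path, names_path=None) -> None:
    """Write labels as integer NIfTI plus a TSV name sidecar (label, name)."""
    nib.save(_nifti_img(atlas.labels.astype(np.int16), atlas.grid), str(path))
    if names_path is None:
        names_path = Path(str(path)).with_suffix("").with_suffix(".tsv")
    with open(names_path, "w") as fh:
        for lab in sorted(atlas.names):
            fh.write(f"{lab}\t{atlas.names[lab]}\n")


def read_parcel_atlas(path, names_path=None) -> ParcelAtlas:
    img = nib.load(str(path))
    lab = np.asarray(img.get_fdata()).astype(np.int32)
    if names_path is None:
        names_path = Path(str(path)).with_suffix("").with_suffix(".tsv")
    names = {}
    with open(names_path) as fh:
        for line in fh:
            if line.strip():
                k, v = line.rstrip("\n").split("\t")
                names[int(k)] = v
    return ParcelAtlas(VolumeGrid(lab.shape, img.affine), lab, names)


# ---------------------------------------------------------------------------
# geometry
# ---------------------------------------------------------------------------

def streamline_length(s: Streamline) -> float:
    """Arc length in mm: sum of consecutive-point Euclidean distances."""
    pts = as_streamline(s)
    return float(np.linalg.norm(np.diff(pts, axis=0), axis=1).sum())


def cumulative_arclength(s: Streamline) -> np.ndarray:
    """Cumulative arc length at each point, starting at 0."""
    pts = as_streamline(s)
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    return np.concatenate([[0.0], np.cumsum(seg)])


def resample_streamline(s: Streamline, step: float) -> Streamline:
    """Resample to arc-length-uniform points at approximately ``step`` mm.

    First and last points are preserved exactly.  The number of intervals is
    ``max(1, round(length / step))``, so a straight 10 mm line at step 1
    yields 11 points.
    """
    if step <= 0:
        raise ValueError(f"step must be positive, got {step}")
    pts = as_streamline(s)
    cum = cumulative_arclength(pts)
    total = cum[-1]
    if total == 0.0:
        return pts[[0, -1]].copy()
    n_int = max(1, int(round(total / step)))
    targets = np.linspace(0.0, total, n_int + 1)
    out = np.empty((n_int + 1, 3))
    for d in range(3):
        out[:, d] = np.interp(targets, cum, pts[:, d])
    out[0], out[-1] = pts[0], pts[-1]
    return out


def distal_segment(s: Streamline, which_end: str, L: float) -> Streamline:
    """Sub-polyline of arc length ``L`` measured from one endpoint.

    ``which_end`` is ``"head"`` (start of the point sequence) or ``"tail"``
    (its end).  If the streamline is shorter than ``L`` the whole streamline
    is returned.  The cut point is linearly interpolated at arc length
    exactly ``L``.
    """
    if which_end not in ("head", "tail"):
        raise ValueError(f"which_end must be 'head' or 'tail', got {which_end!r}")
    if L <= 0:
        raise ValueError(f"L must be positive, got {L}")
    pts = as_streamline(s)
    if which_end == "tail":
        pts = pts[::-1]
    cum = cumulative_arclength(pts)
    if cum[-1] <= L:
        out = pts
    else:
        k = int(np.searchsorted(cum, L))  # first index with cum >= L
        if cum[k] == L:
            out = pts[: k + 1]
        else:
            frac = (L - cum[k - 1]) / (cum[k] - cum[k - 1])
            cut = pts[k - 1] + frac * (pts[k] - pts[k - 1])
            out = np.vstack([pts[:k], cut])
    if which_end == "tail":
        out = out[::-1]
    return out.copy()
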