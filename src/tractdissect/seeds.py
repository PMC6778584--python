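"""Spherical seed catalog and attachment-based streamline selection.

The motorMFB — the sensorimotor branch of the medial forebrain bundle — is
dissected from a whole-brain tractogram by conjunction of spherical seeds in
MNI space: a lateral-VTA seed and a posterior-limb-of-internal-capsule (PLIC)
seed define the bundle; additional ALIC / mammillary-body / pontine seeds
split it into PFC, MB, and BC sub-bundles.  The dentato-rubro-thalamic tract
(DRT) serves as an anatomical control, selected via dentate, superior
cerebellar peduncle, and *contralateral* ventro-lateral thalamus seeds (its
decussation is enforced by laterality, never by passage order).

"Attached" means the streamline's continuous piecewise-linear path intersects
the closed ball — a pass-through counts as well as an endpoint inside.  The
test is an exact segment–sphere distance computation and therefore
independent of how densely the streamline is sampled.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, replace
from types import MappingProxyType
from typing import Dict, Mapping, Sequence

import numpy as np

from .core import Streamline, Tractogram, as_streamline

__all__ = [
    "SphericalSeed",
    "BundleDefinition",
    "DEFAULT_SEEDS",
    "mirror_seed",
    "streamline_intersects_sphere",
    "segment_sphere_distance",
    "select_attached",
    "attachment_mask",
    "decompose_motor_mfb",
    "select_drt",
    "save_seed_catalog",
    "load_seed_catalog",
]


@dataclass(frozen=True)
class SphericalSeed:
    """A named sphere in MNI mm.

    Bilateral seeds are stored with ``|x|`` and mirrored by negating x
    (MNI convention: x > 0 is the right hemisphere); midline seeds are
    shared by both sides.
    """

    name: str
    center: tuple
    radius: float
    laterality: str = "bilateral"  # bilateral | midline

    def __post_init__(self):
        if self.radius <= 0:
            raise ValueError(f"seed {self.name}: radius must be positive")
        if self.laterality not in ("bilateral", "midline"):
            raise ValueError(f"seed {self.name}: bad laterality {self.laterality!r}")
        object.__setattr__(self, "center", tuple(float(c) for c in self.center))


@dataclass(frozen=True)
class BundleDefinition:
    """A conjunction of named seeds defining a bundle."""

    name: str
    required_seeds: frozenset
    hemisphere_rule: str = "same-side"

    def __post_init__(self):
        if not self.required_seeds:
            raise ValueError("bundle needs at least one seed")
        object.__setattr__(self, "required_seeds", frozenset(self.required_seeds))


#: Seed catalog (MNI mm).  latVTA sits in the triangle between red nucleus,
#: STN/substantia nigra, and the mammillo-thalamic tract; PLIC/ALIC are the
#: posterior/anterior limbs of the internal capsule; the DRT seeds follow
#: the dentate nucleus, superior cerebellar peduncle, and ventro-lateral
#: thalamus.  Immutable.
DEFAULT_SEEDS: Mapping[str, SphericalSeed] = MappingProxyType({
    "latVTA": SphericalSeed("latVTA", (6.0, -12.0, -8.0), 3.0),
    "PLIC": SphericalSeed("PLIC", (22.0, -20.0, 10.0), 15.0),
    "ALIC": SphericalSeed("ALIC", (14.0, 13.0, -2.0), 8.0),
    "MB": SphericalSeed("MB", (4.0, -7.5, -12.5), 3.0),
    "Pons": SphericalSeed("Pons", (0.0, -33.0, -25.0), 10.0, laterality="midline"),
    "DRT_dentate": SphericalSeed("DRT_dentate", (17.0, -58.0, -29.0), 8.0),
    "DRT_scp": SphericalSeed("DRT_scp", (8.5, -40.0, -30.0), 4.0),
    "DRT_vl": SphericalSeed("DRT_vl", (18.5, -16.0, 5.0), 5.0),
})


def mirror_seed(seed: SphericalSeed, side: str) -> SphericalSeed:
    """Concrete-hemisphere instance of a seed.

    Bilateral seeds get ``x = +|x|`` for ``side="right"`` and ``-|x|`` for
    ``side="left"``; midline seeds are returned unchanged.
    """
    if side not in ("left", "right"):
        raise ValueError(f"side must be 'left' or 'right', got {side!r}")
    if seed.laterality == "midline":
        return seed
    x = abs(seed.center[0])
    if side == "left":
        x = -x
    return replace(seed, center=(x, seed.center[1], seed.center[2]))


def segment_sphere_distance(points: np.ndarray, center: np.ndarray) -> float:
    """Minimum Euclidean distance from a piecewise-linear path to a point.

    Exact per-segment point-to-segment distance, so the result does not
    depend on sampling density.
    """
    pts = np.asarray(points, dtype=np.float64)
    c = np.asarray(center, dtype=np.float64)
    a = pts[:-1]
    d = pts[1:] - a
    denom = np.einsum("ij,ij->i", d, d)
    t = np.zeros(len(a))
    nz = denom > 0
    t[nz] = np.einsum("ij,ij->i", c - a[nz], d[nz]) / denom[nz]
    t = np.clip(t, 0.0, 1.0)
    closest = a + t[:, None] * d
    return float(np.min(np.linalg.norm(closest - c, axis=1)))


def streamline_intersects_sphere(s: Streamline, seed: SphericalSeed) -> bool:
    """True iff the continuous path intersects the closed ball of the seed."""
    pts = as_streamline(s)
    return segment_sphere_distance(pts, np.asarray(seed.center)) <= seed.radius


def attachment_mask(t: Tractogram, seeds: Sequence[SphericalSeed]) -> np.ndarray:
    """Boolean mask: streamline attached to *every* seed in ``seeds``."""
    if not seeds:
        raise ValueError("seed set must be nonempty")
    mask = np.ones(len(t), dtype=bool)
    for seed in seeds:
        c = np.asarray(seed.center)
        for i in np.flatnonzero(mask):
            if segment_sphere_distance(t.streamlines[i], c) > seed.radius:
                mask[i] = False
    return mask


def select_attached(t: Tractogram, seeds: Sequence[SphericalSeed]) -> Tractogram:
    """Streamlines attached to every seed (conjunction); order preserved."""
    return t.subset(attachment_mask(t, list(seeds)))


def decompose_motor_mfb(
    t: Tractogram,
    side: str,
    catalog: Mapping[str, SphericalSeed] = DEFAULT_SEEDS,
) -> Dict[str, Tractogram]:
    """Select the motorMFB and split it into PFC / MB / BC sub-bundles.

    motorMFB = streamlines attached to both latVTA and PLIC (mirrored to
    ``side``); PFC / MB / BC additionally attach to the ALIC / MB / Pons
    seed.  Sub-bundles need not be disjoint.
    """
    if t.space != "MNI":
        raise ValueError(f"tractogram must be in MNI space, got {t.space!r}")
    get = lambda name: mirror_seed(catalog[name], side)
    mfb_mask = attachment_mask(t, [get("latVTA"), get("PLIC")])
    mfb = t.subset(mfb_mask)
    out = {"motorMFB": mfb}
    for bundle, seed_name in (("PFC", "ALIC"), ("MB", "MB"), ("BC", "Pons")):
        if len(mfb):
            out[bundle] = mfb.subset(attachment_mask(mfb, [get(seed_name)]))
        else:
            out[bundle] = Tractogram([], space=t.space)
    return out


def select_drt(
    t: Tractogram,
    dentate_side: str,
    catalog: Mapping[str, SphericalSeed] = DEFAULT_SEEDS,
) -> Tractogram:
    """Select the dentato-rubro-thalamic tract.

    Requires attachment to dentate and superior-cerebellar-peduncle seeds on
    ``dentate_side`` and to the ventro-lateral thalamus seed on the opposite
    side, which enforces the tract's decussation purely by laterality.
    """
    if t.space != "MNI":
        raise ValueError(f"tractogram must be in MNI space, got {t.space!r}")
    other = "left" if dentate_side == "right" else "right"
    if dentate_side not in ("left", "right"):
        raise ValueError(f"dentate_side must be 'left' or 'right', got {dentate_side!r}")
    seeds = [
        mirror_seed(catalog["DRT_dentate"], dentate_side),
        mirror_seed(catalog["DRT_scp"], dentate_side),
        mirror_seed(catalog["DRT_vl"], other),
    ]
    return select_attached(t, seeds)


# ---------------------------------------------------------------------------
# catalog I/O (plain-text override)
# ---------------------------------------------------------------------------

def save_seed_catalog(catalog: Mapping[str, SphericalSeed], path) -> None:
    """Write a seed catalog as CSV: name, x, y, z, radius, laterality."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["name", "x", "y", "z", "radius", "laterality"])
        for seed in catalog.values():
            w.writerow([seed.name, *seed.center, seed.radius, seed.laterality])


def load_seed_catalog(path) -> Dict[str, SphericalSeed]:
    with open(path, newline="") as fh:
        rows = list(csv.DictReader(fh))
    out = {}
    for r in rows:
        out[r["name"]] = SphericalSeed(
            r["name"], (float(r["x"]), float(r["y"]), float(r["z"])),
            float(r["radius"]), r["laterality"])
    return out
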