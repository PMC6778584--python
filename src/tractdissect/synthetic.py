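"""Synthetic phantoms with known ground truth for every pipeline stage.

The generators emulate, at desk scale, the data this pipeline consumes:

* labeled streamline bundles threading specified spherical waypoints, with
  controlled terminations inside cortical parcels;
* box-parcel atlases mimicking the gyral (Desikan–Killiany-style) parcels
  and the HMAT motor-area masks used for projection quantification;
* multi-tensor diffusion signals on b-shells along phantom bundles, plus a
  white-matter probability map;
* displacement fields with analytic Jacobians for warp oracles.

The default scene grid is 40 x 48 x 40 voxels at 2.5 mm with an MNI-like
origin, so the real seed catalog (latVTA, PLIC, ALIC, ...) applies to the
phantoms unchanged.  Streamline curves are natural cubic splines through the
waypoints with a constant per-streamline lateral jitter offset (Gaussian,
truncated at 3 sd, applied in the plane normal to the local tangent), so
every streamline is guaranteed to pass within ``3 * jitter_sd`` of every
waypoint.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.interpolate import CubicSpline
from scipy.ndimage import gaussian_filter

from .core import (ParcelAtlas, ScalarVolume, Tractogram, VolumeGrid,
                   resample_streamline)
from .normalize import DisplacementField, Shell, ShellData, fibonacci_hemisphere

__all__ = [
    "BundleSpec",
    "SceneSpec",
    "Scene",
    "default_grid",
    "make_parcel_atlas",
    "make_bundle",
    "make_motor_mfb_scene",
    "make_crossing_scene",
    "simulate_dmri",
    "make_warp",
    "AXIAL_DIFFUSIVITY",
    "RADIAL_DIFFUSIVITY",
]

# axially symmetric tensor eigenvalues, mm^2/s
AXIAL_DIFFUSIVITY = 1.7e-3
RADIAL_DIFFUSIVITY = 0.3e-3
ISOTROPIC_DIFFUSIVITY = 0.8e-3

CURVE_STEP_MM = 0.5


def default_grid() -> VolumeGrid:
    """40 x 48 x 40 voxels at 2.5 mm, MNI-like origin (RAS mm).

    Voxel centers span x in [-48.75, 48.75], y in [-68.75, 48.75],
    z in [-38.75, 58.75]; every seed of the catalog falls inside.
    """
    aff = np.diag([2.5, 2.5, 2.5, 1.0])
    aff[:3, 3] = (-48.75, -68.75, -38.75)
    return VolumeGrid((40, 48, 40), aff)


# ---------------------------------------------------------------------------
# specs
# ---------------------------------------------------------------------------

@dataclass
class BundleSpec:
    """One phantom bundle.

    ``terminations`` maps parcel name -> fraction of streamlines steered to
    end inside that parcel (exactly ``round(fraction * n)`` streamlines
    each, assigned deterministically); the remainder end at the last
    waypoint.  ``track_x`` gives the medial/lateral cortical-approach x
    positions used to split terminating streamlines between overlapping
    motor-area (HMAT-style) masks.
    """

    name: str
    waypoints: np.ndarray
    n_streamlines: int
    jitter_sd: float = 0.5
    terminations: Mapping[str, float] = field(default_factory=dict)
    track_x: Tuple[float, float] = (9.0, 23.0)  # (medial, lateral)

    def __post_init__(self):
        wp = np.asarray(self.waypoints, dtype=np.float64)
        if wp.ndim != 2 or wp.shape[0] < 2 or wp.shape[1] != 3:
            raise ValueError("waypoints must be (>=2, 3)")
        if self.n_streamlines < 1:
            raise ValueError("n_streamlines must be >= 1")
        for p, f in self.terminations.items():
            if not 0.0 <= f <= 1.0:
                raise ValueError(f"termination fraction for {p} outside [0,1]")
        if sum(self.terminations.values()) > 1.0 + 1e-9:
            raise ValueError("termination fractions sum above 1")
        self.waypoints = wp


@dataclass
class SceneSpec:
    """Grid, bundles, and axis-aligned box parcels of a phantom scene.

    ``gyral_boxes`` / ``hmat_boxes`` map parcel name -> (label, lo, hi)
    world-mm corners.  Gyral boxes must be pairwise disjoint; HMAT boxes may
    overlap gyral ones (they are a separate atlas) but not each other.
    """

    grid: VolumeGrid
    bundles: List[BundleSpec]
    gyral_boxes: Dict[str, Tuple[int, np.ndarray, np.ndarray]] = field(default_factory=dict)
    hmat_boxes: Dict[str, Tuple[int, np.ndarray, np.ndarray]] = field(default_factory=dict)
    rng_seed: int = 0


@dataclass
class Scene:
    """A generated scene plus its complete ground truth."""

    spec: SceneSpec
    tractogram: Tractogram
    gyral: ParcelAtlas
    hmat: ParcelAtlas
    truth: pd.DataFrame           # per-streamline: bundle, parcel, track
    truth_table: pd.DataFrame     # bundle x parcel ground-truth percentages


# ---------------------------------------------------------------------------
# parcel atlases
# ---------------------------------------------------------------------------

def _boxes_to_labels(grid: VolumeGrid,
                     boxes: Mapping[str, Tuple[int, np.ndarray, np.ndarray]],
                     check_disjoint: bool) -> Tuple[np.ndarray, Dict[int, str]]:
    centers = grid.world_grid()
    labels = np.zeros(grid.shape, dtype=np.int32)
    names = {}
    for name, (lab, lo, hi) in boxes.items():
        lo = np.asarray(lo, float)
        hi = np.asarray(hi, float)
        if np.any(lo >= hi):
            raise ValueError(f"box {name}: lo must be < hi")
        inside = np.all((centers >= lo) & (centers < hi), axis=-1)
        if not inside.any():
            raise ValueError(f"box {name} contains no voxel center")
        if check_disjoint and np.any(labels[inside] != 0):
            raise ValueError(f"gyral box {name} overlaps another box")
        labels[inside] = lab
        names[lab] = name
    return labels, names


def make_parcel_atlas(scene: SceneSpec) -> Dict[str, ParcelAtlas]:
    """Deterministic gyral and HMAT label volumes from the scene's boxes."""
    gy_lab, gy_names = _boxes_to_labels(scene.grid, scene.gyral_boxes, True)
    hm_lab, hm_names = _boxes_to_labels(scene.grid, scene.hmat_boxes, True) \
        if scene.hmat_boxes else (np.zeros(scene.grid.shape, np.int32), {})
    return {"gyral": ParcelAtlas(scene.grid, gy_lab, gy_names),
            "hmat": ParcelAtlas(scene.grid, hm_lab, hm_names)}


# ---------------------------------------------------------------------------
# bundles
# ---------------------------------------------------------------------------

def _spline_curve(waypoints: np.ndarray, step: float = CURVE_STEP_MM) -> np.ndarray:
    """Natural cubic spline through waypoints, sampled at ~``step`` mm."""
    wp = np.asarray(waypoints, float)
    chord = np.concatenate([[0.0], np.cumsum(np.linalg.norm(np.diff(wp, axis=0), axis=1))])
    if chord[-1] == 0:
        raise ValueError("degenerate waypoints")
    if len(wp) == 2:
        n = max(2, int(round(chord[-1] / step)) + 1)
        return np.linspace(0, 1, n)[:, None] * (wp[1] - wp[0]) + wp[0]
    cs = CubicSpline(chord, wp, axis=0, bc_type="natural")
    n = max(2, int(round(chord[-1] / step)) + 1)
    dense = cs(np.linspace(0.0, chord[-1], 4 * n))
    return resample_streamline(dense, step)


def _truncated_gaussian_offset(rng: np.random.Generator, sd: float) -> np.ndarray:
    """3-D Gaussian offset with norm truncated at 3 sd."""
    if sd == 0:
        return np.zeros(3)
    v = rng.normal(scale=sd, size=3)
    nrm = np.linalg.norm(v)
    if nrm > 3.0 * sd:
        v *= 3.0 * sd / nrm
    return v


def _apply_lateral_jitter(curve: np.ndarray, offset: np.ndarray) -> np.ndarray:
    """Project a constant offset onto the plane normal to the local tangent."""
    tang = np.gradient(curve, axis=0)
    tang /= np.maximum(np.linalg.norm(tang, axis=1, keepdims=True), 1e-12)
    lateral = offset - (tang @ offset)[:, None] * tang
    return curve + lateral


def _termination_assignment(spec: BundleSpec) -> List[Tuple[Optional[str], str]]:
    """Per-streamline (parcel or None, 'medial'|'lateral') assignment.

    Counts are ``round(fraction * n)`` per parcel in declaration order;
    within a parcel the medial track gets ``ceil(count/2)`` streamlines.
    """
    n = spec.n_streamlines
    out: List[Tuple[Optional[str], str]] = []
    for parcel, frac in spec.terminations.items():
        cnt = int(round(frac * n))
        n_med = (cnt + 1) // 2
        out.extend([(parcel, "medial")] * n_med)
        out.extend([(parcel, "lateral")] * (cnt - n_med))
    if len(out) > n:
        raise ValueError("termination counts exceed n_streamlines")
    out.extend([(None, "medial")] * (n - len(out)))
    return out


def make_bundle(spec: BundleSpec, rng: np.random.Generator,
                parcel_boxes: Optional[Mapping[str, Tuple[int, np.ndarray, np.ndarray]]] = None,
                grid: Optional[VolumeGrid] = None,
                space: str = "MNI") -> Tuple[Tractogram, pd.DataFrame]:
    """Generate one bundle plus its per-streamline ground-truth record.

    Terminating streamlines get three extra collinear waypoints steering
    vertically (+z) into the target parcel box at the assigned medial or
    lateral x track, ending at the box's z center; the vertical approach is
    long enough that the distal 20 mm lies on it.
    """
    if grid is not None:
        lo = grid.voxel_to_world([0, 0, 0])[0] - grid.voxel_sizes / 2
        hi = grid.voxel_to_world(np.asarray(grid.shape) - 1)[0] + grid.voxel_sizes / 2
        for w in spec.waypoints:
            if np.any(w < np.minimum(lo, hi)) or np.any(w > np.maximum(lo, hi)):
                raise ValueError(f"bundle {spec.name}: waypoint {w} outside grid")
    assignment = _termination_assignment(spec)
    sls, records = [], []
    for k, (parcel, track) in enumerate(assignment):
        wps = spec.waypoints
        if parcel is not None:
            if parcel_boxes is None or parcel not in parcel_boxes:
                raise ValueError(f"bundle {spec.name}: no box for parcel {parcel}")
            _, blo, bhi = parcel_boxes[parcel]
            blo, bhi = np.asarray(blo, float), np.asarray(bhi, float)
            x = spec.track_x[0] if track == "medial" else spec.track_x[1]
            y = 0.5 * (blo[1] + bhi[1])
            z_end = 0.5 * (blo[2] + bhi[2])
            approach = np.array([
                [x, y, blo[2] - 17.5],
                [x, y, 0.5 * (blo[2] - 17.5 + z_end)],
                [x, y, z_end],
            ])
            wps = np.vstack([wps, approach])
        curve = _spline_curve(wps)
        curve = _apply_lateral_jitter(curve, _truncated_gaussian_offset(rng, spec.jitter_sd))
        sls.append(curve)
        records.append({"bundle": spec.name, "parcel": parcel, "track": track})
    return Tractogram(sls, space=space), pd.DataFrame(records)


# ---------------------------------------------------------------------------
# the default motorMFB scene
# ---------------------------------------------------------------------------

def _default_boxes():
    """Right-hemisphere cortical box parcels (world mm).

    Four disjoint gyral slabs side by side along y at the top of the grid,
    and three disjoint HMAT-style motor masks that overlap the gyral slabs:
    SMA / dPMC split the precentral + caudal-middle-frontal footprint
    medially/laterally, pre-SMA covers the medial superior-frontal strip.
    """
    z = (37.5, 52.5)
    gyral = {
        "superior-frontal": (1, (2.5, 20.0, z[0]), (30.0, 40.0, z[1])),
        "caudal-middle-frontal": (2, (2.5, 5.0, z[0]), (30.0, 20.0, z[1])),
        "precentral": (3, (2.5, -10.0, z[0]), (30.0, 5.0, z[1])),
        "postcentral": (4, (2.5, -25.0, z[0]), (30.0, -10.0, z[1])),
    }
    hmat = {
        "SMA": (1, (2.5, -10.0, z[0]), (16.0, 20.0, z[1])),
        "pre-SMA": (2, (2.5, 20.0, z[0]), (16.0, 40.0, z[1])),
        "dPMC": (3, (16.0, -10.0, z[0]), (30.0, 20.0, z[1])),
    }
    return gyral, hmat

#: Default per-bundle termination fractions of the scene generator
#: (gyral parcel -> fraction), echoing the relative distribution of the
#: motor-MFB sub-bundle projections.
DEFAULT_TERMINATIONS = {
    "PFC": {"superior-frontal": 0.18, "caudal-middle-frontal": 0.08,
            "precentral": 0.31, "postcentral": 0.22},
    "MB": {"superior-frontal": 0.12, "caudal-middle-frontal": 0.06,
           "precentral": 0.57, "postcentral": 0.23},
    "BC": {"superior-frontal": 0.30, "caudal-middle-frontal": 0.17,
           "precentral": 0.31, "postcentral": 0.10},
    "DRT": {"superior-frontal": 0.17, "caudal-middle-frontal": 0.08,
            "precentral": 0.59, "postcentral": 0.16},
}

# seed-threading trunks (MNI mm); seed centers are literal waypoints
_LATVTA = (6.0, -12.0, -8.0)
_PLIC = (22.0, -20.0, 10.0)
_TRUNKS = {
    "PFC": [(14.0, 25.0, -2.0), (14.0, 13.0, -2.0), _LATVTA, _PLIC],
    "MB": [(4.0, -7.5, -12.5), _LATVTA, _PLIC],
    "BC": [(-2.0, -45.0, -32.0), (0.0, -33.0, -25.0), _LATVTA, _PLIC],
    "DRT": [(-17.0, -58.0, -29.0), (-8.5, -40.0, -30.0), (18.5, -16.0, 5.0)],
    "slMFB": [(6.0, -12.0, -8.0), (12.0, 15.0, 2.0), (12.0, 32.0, 15.0)],
}


def make_motor_mfb_scene(
    n_per_bundle: Mapping[str, int] | int = 100,
    jitter_sd: float = 0.5,
    rng_seed: int = 0,
    terminations: Optional[Mapping[str, Mapping[str, float]]] = None,
) -> Scene:
    """Default phantom: PFC / MB / BC sub-bundles, a decussating DRT, and an
    slMFB-like distractor that threads latVTA but not PLIC.

    All sub-bundle trunks pass exactly through the latVTA and PLIC seed
    centers plus their distinguishing third seed (ALIC / MB / Pons); the
    DRT runs left dentate -> left SCP -> right VL (decussating).  Returns
    the merged tractogram, both atlases, the per-streamline truth record,
    and the ground-truth projection table.
    """
    if isinstance(n_per_bundle, int):
        n_per_bundle = {b: n_per_bundle for b in ("PFC", "MB", "BC", "DRT")}
    terminations = dict(DEFAULT_TERMINATIONS if terminations is None else terminations)
    grid = default_grid()
    gyral_boxes, hmat_boxes = _default_boxes()
    bundles = []
    for name in ("PFC", "MB", "BC", "DRT"):
        bundles.append(BundleSpec(
            name, np.asarray(_TRUNKS[name]), n_per_bundle[name],
            jitter_sd=jitter_sd, terminations=terminations.get(name, {})))
    bundles.append(BundleSpec("slMFB", np.asarray(_TRUNKS["slMFB"]),
                              max(10, min(n_per_bundle.values()) // 3),
                              jitter_sd=jitter_sd))
    spec = SceneSpec(grid, bundles, gyral_boxes, hmat_boxes, rng_seed)
    rng = np.random.default_rng(rng_seed)
    all_sl, frames = [], []
    for b in bundles:
        t, rec = make_bundle(b, rng, gyral_boxes, grid)
        all_sl.extend(t.streamlines)
        frames.append(rec)
    truth = pd.concat(frames, ignore_index=True)
    atlases = make_parcel_atlas(spec)
    table = _ground_truth_table(truth, gyral_boxes, hmat_boxes,
                                {b.name: b for b in bundles})
    return Scene(spec, Tractogram(all_sl, space="MNI"), atlases["gyral"],
                 atlases["hmat"], truth, table)


def _ground_truth_table(truth: pd.DataFrame, gyral_boxes, hmat_boxes,
                        specs: Mapping[str, BundleSpec]) -> pd.DataFrame:
    """Bundle x parcel percentages implied by the termination assignment.

    A terminating streamline's distal approach runs vertically at
    ``(track_x, y_center(parcel))`` into its gyral parcel, so it hits an
    HMAT mask iff that (x, y) footprint lies inside the mask's box.
    """
    bundles = [b for b in specs if specs[b].terminations or b in
               ("PFC", "MB", "BC", "DRT")]
    cols = list(gyral_boxes) + list(hmat_boxes)
    rows = {}
    for b in bundles:
        sub = truth[truth.bundle == b]
        n = len(sub)
        row = {}
        for parcel in gyral_boxes:
            row[parcel] = 100.0 * (sub.parcel == parcel).sum() / n
        for hname, (_, lo, hi) in hmat_boxes.items():
            cnt = 0
            for parcel in gyral_boxes:
                _, plo, phi = gyral_boxes[parcel]
                y = 0.5 * (plo[1] + phi[1])
                for track, xi in (("medial", specs[b].track_x[0]),
                                  ("lateral", specs[b].track_x[1])):
                    if lo[0] <= xi < hi[0] and lo[1] <= y < hi[1]:
                        cnt += ((sub.parcel == parcel) & (sub.track == track)).sum()
            row[hname] = 100.0 * cnt / n
        rows[b] = row
    return pd.DataFrame(rows).T[cols]


# ---------------------------------------------------------------------------
# crossing phantom for the tracker
# ---------------------------------------------------------------------------

@dataclass
class CrossingScene:
    """Two-bundle crossing phantom with endpoint ground truth."""

    grid: VolumeGrid
    tractogram: Tractogram
    bundle_ids: np.ndarray          # per-streamline bundle index (0/1)
    endpoints: List[Tuple[np.ndarray, np.ndarray]]  # per bundle, ball centers
    ball_radius: float
    angle_deg: float


def make_crossing_scene(angle_deg: float = 60.0, length: float = 32.0,
                        n_streamlines: int = 30, jitter_sd: float = 1.2,
                        ball_radius: float = 6.5,
                        rng_seed: int = 0) -> CrossingScene:
    """Two straight bundles crossing at ``angle_deg`` in the x-y plane.

    Bundle axes are at +/- angle/2 from x; endpoint balls of radius
    ``ball_radius`` sit at the bundle ends (different-bundle ball surfaces
    are >= 3 mm apart at the defaults).  The default streamline count and
    jitter give each bundle a tube a little over two voxels across — a
    bundle narrower than the grid resolution is not resolvable by any
    tracker operating on that grid.
    """
    half = np.deg2rad(angle_deg / 2.0)
    axes = [np.array([np.cos(half), np.sin(half), 0.0]),
            np.array([np.cos(half), -np.sin(half), 0.0])]
    aff = np.diag([2.0, 2.0, 2.0, 1.0])
    aff[:3, 3] = (-23.0, -13.0, -4.0)
    grid = VolumeGrid((24, 14, 5), aff)
    rng = np.random.default_rng(rng_seed)
    sls, ids, endpoints = [], [], []
    for bi, u in enumerate(axes):
        a, b = -0.5 * length * u, 0.5 * length * u
        endpoints.append((a.copy(), b.copy()))
        spec = BundleSpec(f"bundle{bi}", np.vstack([a, b]), n_streamlines,
                          jitter_sd=jitter_sd)
        t, _ = make_bundle(spec, rng, grid=grid, space="subject")
        sls.extend(t.streamlines)
        ids.extend([bi] * len(t))
    return CrossingScene(grid, Tractogram(sls, space="subject"),
                         np.asarray(ids), endpoints, ball_radius, angle_deg)


# ---------------------------------------------------------------------------
# diffusion simulation
# ---------------------------------------------------------------------------

def simulate_dmri(
    t: Tractogram,
    grid: VolumeGrid,
    b_values: Sequence[float] = (1000.0, 2000.0),
    directions: Optional[np.ndarray] = None,
    S0: float = 1.0,
    noise_sd: float = 0.0,
    rng: Optional[np.random.Generator] = None,
    bundle_ids: Optional[np.ndarray] = None,
) -> Tuple[ShellData, ScalarVolume]:
    """Multi-tensor signal along the tractogram plus a WM probability map.

    Per voxel, the tangents of traversing streamlines are clustered (one
    cluster per bundle id, or a single cluster if ids are absent) into
    axially symmetric tensors with eigenvalues (1.7, 0.3, 0.3) x 1e-3
    mm^2/s, volume-fraction-weighted by traversed length:
    ``S = S0 * sum_i f_i * exp(-b n^T D_i n)``.  Untraversed voxels carry an
    isotropic tensor.  Optional Rician noise (two Gaussian channels of scale
    ``noise_sd``); the WM probability is 1 on traversed voxels with a
    smoothed edge.
    """
    if directions is None:
        directions = fibonacci_hemisphere(90)
    directions = np.asarray(directions, float)
    rng = rng or np.random.default_rng(0)
    nvox = int(np.prod(grid.shape))
    if bundle_ids is None:
        bundle_ids = np.zeros(len(t), dtype=int)
    n_clusters = int(bundle_ids.max()) + 1 if len(t) else 1
    # per (voxel, cluster): accumulated oriented tangent and length weight
    tang_sum = np.zeros((nvox, n_clusters, 3))
    w_sum = np.zeros((nvox, n_clusters))
    shape = np.asarray(grid.shape)
    for sl, bid in zip(t.streamlines, bundle_ids):
        pts = resample_streamline(sl, CURVE_STEP_MM)
        mids = 0.5 * (pts[:-1] + pts[1:])
        segs = pts[1:] - pts[:-1]
        lens = np.linalg.norm(segs, axis=1)
        ok = lens > 0
        tangs = segs[ok] / lens[ok][:, None]
        vox = np.rint(grid.world_to_voxel(mids[ok])).astype(int)
        inside = np.all((vox >= 0) & (vox < shape), axis=1)
        flat = np.ravel_multi_index(vox[inside].T, grid.shape)
        for fv, tg, ln in zip(flat, tangs[inside], lens[ok][inside]):
            ref = tang_sum[fv, bid]
            sgn = 1.0 if ref @ tg >= 0 or not ref.any() else -1.0
            tang_sum[fv, bid] += sgn * ln * tg
            w_sum[fv, bid] += ln
    traversed = w_sum.sum(axis=1) > 0
    shells = []
    for b in b_values:
        S = np.empty((nvox, len(directions)))
        iso = S0 * np.exp(-b * ISOTROPIC_DIFFUSIVITY)
        S[:] = iso
        idx = np.flatnonzero(traversed)
        if len(idx):
            f = w_sum[idx] / w_sum[idx].sum(axis=1, keepdims=True)
            norms = np.linalg.norm(tang_sum[idx], axis=2)
            safe = np.where(norms[..., None] > 0, tang_sum[idx] / np.maximum(norms, 1e-12)[..., None], 0.0)
            # n^T D n = lam_perp + (lam_par - lam_perp) (n . d)^2
            dots2 = np.einsum("vcj,dj->vcd", safe, directions) ** 2
            adc = RADIAL_DIFFUSIVITY + (AXIAL_DIFFUSIVITY - RADIAL_DIFFUSIVITY) * dots2
            sig = np.einsum("vc,vcd->vd", f, np.exp(-b * adc))
            S[idx] = S0 * sig
        if noise_sd > 0:
            g1 = rng.normal(scale=noise_sd, size=S.shape)
            g2 = rng.normal(scale=noise_sd, size=S.shape)
            S = np.sqrt((S + g1) ** 2 + g2 ** 2)
        shells.append(Shell(b, directions, S.reshape(grid.shape + (len(directions),))))
    wm = traversed.reshape(grid.shape).astype(float)
    if not traversed.any():
        import warnings
        warnings.warn("simulate_dmri: no streamline traverses the grid; "
                      "signal is all-isotropic")
    wm_smooth = np.maximum(wm, gaussian_filter(wm, sigma=0.6))
    b0 = np.full(grid.shape, S0)
    return (ShellData(grid, shells, b0=b0),
            ScalarVolume(grid, wm_smooth, units="probability"))


# ---------------------------------------------------------------------------
# warp fields
# ---------------------------------------------------------------------------

def make_warp(kind: str, grid: VolumeGrid, **params) -> DisplacementField:
    """Displacement fields with analytic Jacobians for oracle tests.

    ``identity``; ``translation`` (``offset``); ``rotation`` (``axis``,
    ``angle_deg``, optional ``center``); ``sinusoid``
    (``amplitude`` a, ``frequency`` k: ``w_c = x_c + a_c sin(k_c x_{c+1})``,
    indices mod 3).  ``w`` maps target to source coordinates (pull-back).
    """
    X = grid.world_grid()
    flatX = X.reshape(-1, 3)
    shape = grid.shape
    if kind == "identity":
        w = flatX.copy()
        J = np.broadcast_to(np.eye(3), (len(flatX), 3, 3)).copy()
    elif kind == "translation":
        off = np.asarray(params.get("offset", (0.0, 0.0, 0.0)), float)
        w = flatX + off
        J = np.broadcast_to(np.eye(3), (len(flatX), 3, 3)).copy()
    elif kind == "rotation":
        axis = np.asarray(params.get("axis", (0.0, 0.0, 1.0)), float)
        axis = axis / np.linalg.norm(axis)
        ang = np.deg2rad(params.get("angle_deg", 0.0))
        c = np.asarray(params.get("center", (0.0, 0.0, 0.0)), float)
        K = np.array([[0, -axis[2], axis[1]],
                      [axis[2], 0, -axis[0]],
                      [-axis[1], axis[0], 0]])
        R = np.eye(3) + np.sin(ang) * K + (1 - np.cos(ang)) * (K @ K)
        w = (flatX - c) @ R.T + c
        J = np.broadcast_to(R, (len(flatX), 3, 3)).copy()
    elif kind == "sinusoid":
        a = np.asarray(params.get("amplitude", (1.0, 1.0, 1.0)), float)
        k = np.asarray(params.get("frequency", (0.1, 0.1, 0.1)), float)
        w = flatX.copy()
        J = np.broadcast_to(np.eye(3), (len(flatX), 3, 3)).copy()
        for c_ in range(3):
            m = (c_ + 1) % 3
            w[:, c_] += a[c_] * np.sin(k[c_] * flatX[:, m])
            J[:, c_, m] += a[c_] * k[c_] * np.cos(k[c_] * flatX[:, m])
    else:
        raise ValueError(f"unknown warp kind {kind!r}")
    return DisplacementField(grid, w.reshape(shape + (3,)),
                             J.reshape(shape + (3, 3)))
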