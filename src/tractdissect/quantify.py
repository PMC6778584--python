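"""Parcel-wise quantification of cortical projections.

For each bundle the percentage of streamlines whose terminal projection —
the distal 20 mm at either end — reaches each cortical parcel is tabulated
(the projection table).  A streamline may hit several parcels and is then
counted in every one of them, and many streamlines end outside all parcels,
so columns need not (and generally do not) sum to 100%.  The denominator is
always the streamline count of the selected bundle.

Gyral (Desikan–Killiany-style) parcels and motor-area (HMAT-style) masks are
quantified independently against their own atlas; the masks may overlap the
gyral parcels.
"""

from __future__ import annotations

from typing import Mapping, Set

import numpy as np
import pandas as pd

from .core import ParcelAtlas, Streamline, Tractogram, distal_segment, \
    resample_streamline, streamline_length

__all__ = [
    "terminal_hits",
    "projection_percentages",
    "build_table",
    "EmptyBundleError",
    "TERMINAL_SAMPLE_STEP_MM",
]

TERMINAL_SAMPLE_STEP_MM = 0.25


class EmptyBundleError(ValueError):
    """Raised when percentages are requested for a bundle with no streamlines."""


def _distal_pieces(s: Streamline, L: float):
    if streamline_length(s) <= 2 * L:
        yield np.asarray(s)
    else:
        yield distal_segment(s, "head", L)
        yield distal_segment(s, "tail", L)


def terminal_hits(s: Streamline, atlas: ParcelAtlas, L: float = 20.0,
                  terminal_rule: str = "distal") -> Set[str]:
    """Parcel names reached by the streamline's terminal projections.

    With the default ``terminal_rule="distal"`` both distal-L segments are
    resampled at 0.25 mm and any sample point inside a parcel mask
    (nearest-voxel lookup) counts as a hit; ``terminal_rule="endpoint"``
    tests only the two endpoints.
    """
    if terminal_rule not in ("distal", "endpoint"):
        raise ValueError(f"terminal_rule must be 'distal' or 'endpoint', "
                         f"got {terminal_rule!r}")
    pts_list = []
    if terminal_rule == "endpoint":
        s = np.asarray(s)
        pts_list.append(s[[0, -1]])
    else:
        for piece in _distal_pieces(s, L):
            pts_list.append(resample_streamline(piece, TERMINAL_SAMPLE_STEP_MM))
    grid = atlas.grid
    shape = np.asarray(grid.shape)
    labels: Set[int] = set()
    for pts in pts_list:
        vox = np.rint(grid.world_to_voxel(pts)).astype(int)
        inside = np.all((vox >= 0) & (vox < shape), axis=1)
        if inside.any():
            labels.update(np.unique(atlas.labels[tuple(vox[inside].T)]).tolist())
    labels.discard(0)
    return {atlas.names[int(l)] for l in labels}


def projection_percentages(bundle: Tractogram, atlas: ParcelAtlas,
                           L: float = 20.0,
                           terminal_rule: str = "distal") -> pd.Series:
    """One projection-table row: percent of bundle streamlines per parcel.

    ``cell(parcel) = 100 * |{s : parcel in terminal_hits(s)}| / |bundle|``.
    Raises :class:`EmptyBundleError` for an empty bundle rather than
    returning silent NaNs.
    """
    if len(bundle) == 0:
        raise EmptyBundleError("cannot quantify an empty bundle")
    parcels = [atlas.names[k] for k in sorted(atlas.names)]
    counts = {p: 0 for p in parcels}
    for s in bundle:
        for p in terminal_hits(s, atlas, L, terminal_rule):
            counts[p] += 1
    return pd.Series({p: 100.0 * counts[p] / len(bundle) for p in parcels})


def build_table(bundles: Mapping[str, Tractogram],
                atlases: Mapping[str, ParcelAtlas],
                L: float = 20.0,
                terminal_rule: str = "distal") -> pd.DataFrame:
    """Bundle x parcel projection table over gyral and HMAT atlases.

    Rows follow the order of ``bundles``; gyral columns come first, then
    the HMAT mask columns, each block computed independently against its
    own atlas.
    """
    if set(atlases) - {"gyral", "hmat"}:
        raise ValueError("atlases must be keyed 'gyral' and 'hmat'")
    rows = {}
    for name, t in bundles.items():
        parts = []
        for key in ("gyral", "hmat"):
            if key in atlases and atlases[key].names:
                parts.append(projection_percentages(t, atlases[key], L, terminal_rule))
        rows[name] = pd.concat(parts) if parts else pd.Series(dtype=float)
    return pd.DataFrame(rows).T
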