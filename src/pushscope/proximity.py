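"""Proximity of substrate-deformation maxima to actin-intensity maxima.

Cells pulling or pushing on a fibrous matrix create local deformation hot
spots; the question is how close these sit to actin accumulations.  Local
maxima are detected independently in the deformation-magnitude field and the
actin field within a neighborhood radius, then each deformation maximum is
assigned the distance to its nearest actin maximum, per Z-slice and
timepoint.  Deformation fields are inputs (computed upstream by PIV).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree


@dataclass
class MaximaSet:
    """Retained local maxima per (z, t) slice."""

    coordinates: dict[tuple[int, int], np.ndarray]  # (z, t) -> (n, 2) of (y, x)
    neighborhood_radius_px: float
    min_prominence: float | None


@dataclass
class MaximaDistances:
    """Nearest-actin distance for each deformation maximum, per (z, t)."""

    distances_um: dict[tuple[int, int], np.ndarray]
    missing_counterpart: list[tuple[int, int]] = field(default_factory=list)

    def pooled(self) -> np.ndarray:
        vals = [v for v in self.distances_um.values() if v.size]
        return np.concatenate(vals) if vals else np.array([])

    def summary(self) -> dict[str, float]:
        pooled = self.pooled()
        if pooled.size == 0:
            return {"median_um": np.nan, "iqr_um": np.nan, "n": 0}
        q1, q3 = np.percentile(pooled, [25, 75])
        return {
            "median_um": float(np.median(pooled)),
            "iqr_um": float(q3 - q1),
            "n": int(pooled.size),
        }


def local_maxima(
    field_yx: np.ndarray,
    radius_px: float = 5.0,
    min_prominence: float | None = None,
) -> np.ndarray:
    """Coordinates (y, x) of strict local maxima within a circular radius.

    A pixel is retained when it is the maximum of its radius-neighborhood and
    exceeds ``min_prominence`` above the field median; the default prominence
    is 3 scaled median absolute deviations.  When candidates tie within one
    neighborhood, the lexicographically smallest coordinate wins.  A constant
    field has no maxima.
    """
    if radius_px < 1:
        raise ValueError("radius must be >= 1 pixel")
    f = np.asarray(field_yx, dtype=float)
    if f.max() == f.min():
        return np.empty((0, 2), dtype=int)
    if min_prominence is None:
        med = np.median(f)
        mad = np.median(np.abs(f - med))
        # MAD collapses on fields that are mostly flat background; the
        # dynamic-range floor keeps ripples in the far tails from qualifying
        min_prominence = max(3.0 * 1.4826 * mad, 0.05 * (f.max() - med))
    r = int(np.ceil(radius_px))
    yy, xx = np.mgrid[-r : r + 1, -r : r + 1]
    footprint = (yy**2 + xx**2) <= radius_px**2
    maxfilt = ndimage.maximum_filter(f, footprint=footprint, mode="nearest")
    cand = np.argwhere((f == maxfilt) & (f > np.median(f) + min_prominence))
    if cand.size == 0:
        return np.empty((0, 2), dtype=int)
    # resolve plateaus/ties: scan in lexicographic order, keep a candidate only
    # if no already-kept maximum of >= value lies within the radius
    cand = cand[np.lexsort((cand[:, 1], cand[:, 0]))]
    kept: list[np.ndarray] = []
    for p in cand:
        if all(np.hypot(*(p - q)) > radius_px for q in kept):
            kept.append(p)
    return np.array(kept, dtype=int)


def detect_maxima_stack(
    fields: dict[tuple[int, int], np.ndarray] | np.ndarray,
    radius_px: float = 5.0,
    min_prominence: float | None = None,
) -> MaximaSet:
    """Run :func:`local_maxima` over a (z, t)-indexed collection of slices.

    ``fields`` may be a mapping ``(z, t) -> 2D array`` or a ``T x Z x Y x X``
    array.
    """
    if isinstance(fields, np.ndarray):
        if fields.ndim != 4:
            raise ValueError("array input must be T x Z x Y x X")
        items = {
            (z, t): fields[t, z]
            for t in range(fields.shape[0])
            for z in range(fields.shape[1])
        }
    else:
        items = dict(fields)
    coords = {
        zt: local_maxima(f, radius_px, min_prominence) for zt, f in items.items()
    }
    return MaximaSet(
        coordinates=coords,
        neighborhood_radius_px=radius_px,
        min_prominence=min_prominence,
    )


def min_distances(
    def_maxima: MaximaSet,
    actin_maxima: MaximaSet,
    pixel_size_um: float = 1.0,
) -> MaximaDistances:
    """Distance from each deformation maximum to its nearest actin maximum.

    Distances are directed (deformation -> actin), per matching (z, t) slice,
    in micrometers.  Slices with deformation maxima but no actin maxima are
    flagged in ``missing_counterpart`` and contribute no distances (absent,
    not infinite).  No deformation maxima anywhere is an error.
    """
    if def_maxima.coordinates.keys() != actin_maxima.coordinates.keys():
        raise ValueError("maxima sets cover different (z, t) grids")
    if all(c.size == 0 for c in def_maxima.coordinates.values()):
        raise ValueError("no deformation maxima anywhere")
    out = MaximaDistances(distances_um={})
    for zt, dpts in def_maxima.coordinates.items():
        apts = actin_maxima.coordinates[zt]
        if dpts.size == 0:
            out.distances_um[zt] = np.array([])
            continue
        if apts.size == 0:
            out.distances_um[zt] = np.array([])
            out.missing_counterpart.append(zt)
            continue
        tree = cKDTree(apts.astype(float))
        d, _ = tree.query(dpts.astype(float))
        out.distances_um[zt] = np.atleast_1d(d) * pixel_size_um
    return out
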