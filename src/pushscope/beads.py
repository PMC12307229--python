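"""Bead detection and vertical (Z) displacement tracking.

Sub-resolution fluorescent beads embedded in an elastic layer report the
vertical force a passing cell exerts: the cell lifts the gel and with it the
beads.  The readout is built in three steps: detect stationary, well-isolated
beads on the Z-and-time maximum projection; extract a Z x T intensity
kymograph from a fixed small XY window around each bead; track the bead's
intensity edge through the kymograph with a single global Otsu threshold and
sub-step linear interpolation.  Displacement is the tracked edge minus a
no-cell baseline.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu
from skimage.measure import label as cc_label
from skimage.measure import regionprops


@dataclass
class BeadRecord:
    """One segmented bead candidate and its accept/reject verdict."""

    id: int
    xy_centroid_px: tuple[float, float]  # (y, x)
    area_px: int
    accepted: bool
    rejection_reason: str = "none"  # none | nonstationary | aggregate | too_small | edge

    def __post_init__(self) -> None:
        if self.accepted and self.rejection_reason != "none":
            raise ValueError("accepted bead cannot carry a rejection reason")


@dataclass
class Kymograph:
    """Bead intensity as a Z x T matrix, mean over a fixed XY window."""

    values: np.ndarray  # (Z, T), non-negative
    z_step_um: float
    frame_interval_s: float
    bead_id: int

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[0] < 3:
            raise ValueError("kymograph must be Z x T with Z >= 3")
        if (self.values < 0).any():
            raise ValueError("kymograph intensities must be non-negative")


@dataclass
class DisplacementTrace:
    """Tracked bead-edge Z position per frame and its no-cell baseline."""

    edge_z_um: np.ndarray  # length T; NaN where invalid
    baseline_um: float
    valid_frames: np.ndarray  # bool mask, length T
    bead_id: int = -1

    @property
    def displacement_um(self) -> np.ndarray:
        return self.edge_z_um - self.baseline_um

    def with_baseline(self, baseline_um: float) -> "DisplacementTrace":
        return DisplacementTrace(
            self.edge_z_um, float(baseline_um), self.valid_frames, self.bead_id
        )


# ---------------------------------------------------------------------------


def detect_beads(
    bead_channel: np.ndarray,
    min_area_px: int = 2,
    max_area_px: int = 60,
    stationarity_max_shift_px: float = 2.0,
    analysis_halfwidth_px: int = 10,
    smooth_sigma_px: float = 1.0,
) -> list[BeadRecord]:
    """Segment candidate beads and filter to stationary, isolated singles.

    Candidates are connected components of the Otsu-thresholded maximum
    intensity projection over Z and time (lightly smoothed to suppress
    pixel noise amplified by the max projection).  A component is rejected as

    - ``aggregate`` when its area exceeds ``max_area_px`` (fused beads),
    - ``too_small`` when below ``min_area_px`` (hot pixels),
    - ``nonstationary`` when its per-frame intensity-weighted centroid
      (on per-frame Z-max projections) deviates from its time-mean position
      by more than ``stationarity_max_shift_px`` at any frame,
    - ``edge`` when closer than ``analysis_halfwidth_px`` to the image border
      (the later analysis windows would leave the image).

    An all-zero channel yields an empty list with a warning, not an error.
    """
    bead_channel = np.asarray(bead_channel)
    if bead_channel.ndim != 4:
        raise ValueError("bead channel must be T x Z x Y x X")
    if min_area_px <= 0 or max_area_px <= 0 or stationarity_max_shift_px <= 0:
        raise ValueError("thresholds must be positive")
    if not np.any(bead_channel):
        warnings.warn("bead channel is all zero; no beads detected", stacklevel=2)
        return []

    proj = bead_channel.max(axis=(0, 1))  # max over T and Z
    if smooth_sigma_px > 0:
        proj = ndimage.gaussian_filter(proj, smooth_sigma_px)
    thr = threshold_otsu(proj)
    lab = cc_label(proj > thr)
    t_n = bead_channel.shape[0]
    y_n, x_n = proj.shape
    frame_proj = bead_channel.max(axis=1)  # (T, Y, X)

    records: list[BeadRecord] = []
    for rp in regionprops(lab, intensity_image=proj):
        cy, cx = rp.centroid_weighted
        area = int(rp.area)
        reason = "none"
        if area > max_area_px:
            reason = "aggregate"
        elif area < min_area_px:
            reason = "too_small"
        elif (
            cy < analysis_halfwidth_px
            or cx < analysis_halfwidth_px
            or cy >= y_n - analysis_halfwidth_px
            or cx >= x_n - analysis_halfwidth_px
        ):
            reason = "edge"
        else:
            # per-frame centroid within the component's bounding box
            sl = rp.slice
            mask = lab[sl] == rp.label
            per_frame = np.empty((t_n, 2))
            for t in range(t_n):
                # local background removal keeps noise in the component's
                # bounding box from diluting the intensity-weighted centroid
                win = frame_proj[t][sl]
                img = np.clip(win - np.median(win), 0, None) * mask
                tot = img.sum()
                if tot <= 0:
                    per_frame[t] = (cy, cx)
                    continue
                yy, xx = np.mgrid[sl[0], sl[1]]
                per_frame[t] = ((img * yy).sum() / tot, (img * xx).sum() / tot)
            dev = np.hypot(*(per_frame - per_frame.mean(axis=0)).T)
            if dev.max() > stationarity_max_shift_px:
                reason = "nonstationary"
        records.append(
            BeadRecord(
                id=rp.label,
                xy_centroid_px=(float(cy), float(cx)),
                area_px=area,
                accepted=reason == "none",
                rejection_reason=reason,
            )
        )
    return records


def extract_kymograph(
    bead_channel: np.ndarray,
    bead: BeadRecord,
    xy_halfwidth_px: int = 2,
    z_step_um: float = 0.1,
    frame_interval_s: float = 30.0,
) -> Kymograph:
    """Mean bead intensity over a fixed (2h+1)^2 XY window, per (z, t).

    The window is centered on the bead's rounded centroid and spans the whole
    Z-stack; the default half-width 2 gives the 5 x 5 px window.  A window
    that would leave the image is an error — silent clipping would bias the
    mean toward whatever lies beyond the border.
    """
    if not bead.accepted:
        raise ValueError(f"bead {bead.id} was rejected ({bead.rejection_reason})")
    bead_channel = np.asarray(bead_channel)
    t_n, z_n, y_n, x_n = bead_channel.shape
    cy, cx = (int(round(c)) for c in bead.xy_centroid_px)
    h = xy_halfwidth_px
    if cy - h < 0 or cx - h < 0 or cy + h >= y_n or cx + h >= x_n:
        raise ValueError(
            f"analysis window of bead {bead.id} at ({cy}, {cx}) with half-width "
            f"{h} exceeds the image bounds"
        )
    window = bead_channel[:, :, cy - h : cy + h + 1, cx - h : cx + h + 1]
    values = window.mean(axis=(2, 3)).T  # (Z, T)
    return Kymograph(
        values=np.clip(values, 0, None),
        z_step_um=z_step_um,
        frame_interval_s=frame_interval_s,
        bead_id=bead.id,
    )


def track_edge(
    kym: Kymograph,
    edge_side: str = "away_from_substrate",
    baseline_frames: int = 3,
    smooth_sigma_zt: tuple[float, float] = (1.5, 1.5),
) -> DisplacementTrace:
    """Track the bead's intensity edge through the kymograph.

    One Otsu threshold is computed on the whole kymograph (a per-frame
    threshold would jitter with noise).  Per frame, the edge is the Z where
    the bead's intensity profile crosses that threshold on the requested side
    — by default the side away from the substrate (larger Z, deeper into the
    gel), because the cell pushes beads away from the coverslip — located by
    walking outward from the profile peak and linearly interpolating between
    the bracketing samples.  Walking from the peak (rather than taking the
    outermost above-threshold sample) makes the crossing immune to isolated
    noise excursions far from the bead.  Frames whose peak never reaches the
    threshold are flagged invalid.

    The kymograph is lightly Gaussian-smoothed (``smooth_sigma_zt`` in
    (z, t) samples; pass ``(0, 0)`` to disable) before thresholding; with a
    0.1 um z-step, discretization and single-voxel noise dominate the error
    budget otherwise.

    The returned baseline is the mean edge over the first and last
    ``baseline_frames`` valid frames (no cell near the bead at the movie's
    ends); when contribution labels are available, prefer re-baselining on
    the frames labeled ``none`` via :meth:`DisplacementTrace.with_baseline`.
    """
    if edge_side not in ("away_from_substrate", "toward_substrate"):
        raise ValueError(f"unknown edge side {edge_side!r}")
    v = kym.values
    if v.max() == v.min():
        raise ValueError("kymograph has zero dynamic range; threshold degenerate")
    if any(s > 0 for s in smooth_sigma_zt):
        v = ndimage.gaussian_filter(v, smooth_sigma_zt, mode="nearest")
    uniq = np.unique(v)
    # a two-level kymograph makes Otsu's criterion flat over the whole gap;
    # the midpoint is the only defensible split
    thr = float(uniq.mean()) if uniq.size == 2 else threshold_otsu(v)
    z_n, t_n = v.shape
    edge = np.full(t_n, np.nan)
    valid = np.zeros(t_n, dtype=bool)
    step = 1 if edge_side == "away_from_substrate" else -1
    for t in range(t_n):
        col = v[:, t]
        k = int(col.argmax())
        if col[k] < thr:
            continue
        while 0 <= k + step < z_n and col[k + step] >= thr:
            k += step
        if not 0 <= k + step < z_n:
            edge[t] = float(k)  # edge clipped at the stack boundary
        else:
            frac = (col[k] - thr) / (col[k] - col[k + step])
            edge[t] = k + step * float(frac)
        valid[t] = True
    edge_um = edge * kym.z_step_um
    vi = np.nonzero(valid)[0]
    if vi.size == 0:
        raise ValueError("no frame crosses the threshold; cannot track edge")
    nb = min(baseline_frames, vi.size)
    baseline = float(np.concatenate([edge_um[vi[:nb]], edge_um[vi[-nb:]]]).mean())
    return DisplacementTrace(
        edge_z_um=edge_um, baseline_um=baseline, valid_frames=valid, bead_id=kym.bead_id
    )


def max_displacement(trace: DisplacementTrace) -> float:
    """Maximum absolute displacement (um) over the valid frames."""
    if not trace.valid_frames.any():
        raise ValueError("trace has no valid frames")
    return float(np.nanmax(np.abs(trace.displacement_um[trace.valid_frames])))
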