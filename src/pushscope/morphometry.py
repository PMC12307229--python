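"""Single-cell segmentation, tracking and shape/intensity descriptors.

Covers the 2D under-gel migration readouts: threshold-based cell and
central-pool segmentation (external masks from a trained pixel classifier may
be supplied instead), greedy nearest-centroid track linking with an
interaction/length filter, center-of-mass speed, protrusion/retraction area
decomposition, background-corrected integrated intensities, central-pool and
lamellipodial intensity ratios, MTOC-vs-nucleus orientation calls, and the
pooling of retraction events onto a common onset-aligned time axis.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu
from skimage.measure import label as cc_label
from skimage.measure import regionprops
from skimage.morphology import disk


@dataclass
class CellFrame:
    """One tracked frame of one cell."""

    time_index: int
    cell_mask: np.ndarray
    centroid_px: tuple[float, float]  # (y, x)
    area_px: int
    central_pool_mask: np.ndarray | None = None
    nucleus_mask: np.ndarray | None = None


@dataclass
class CellTrack:
    frames: list[CellFrame]
    frame_interval_s: float = 30.0
    pixel_size_um: float = 1.0

    def __post_init__(self) -> None:
        if not self.frames:
            raise ValueError("a track needs at least one frame")
        ts = [f.time_index for f in self.frames]
        if any(b - a != 1 for a, b in zip(ts, ts[1:])):
            raise ValueError("track time indices must be consecutive")

    def __len__(self) -> int:
        return len(self.frames)

    @property
    def centroids_px(self) -> np.ndarray:
        return np.array([f.centroid_px for f in self.frames])


@dataclass
class ProtrusionDecomposition:
    """Areas gained and lost between consecutive segmentations."""

    gained_mask: np.ndarray
    lost_mask: np.ndarray
    gained_area_um2: float
    lost_area_um2: float


@dataclass
class OrientationCall:
    """MTOC-first vs nucleus-first along the polarization axis."""

    value: str  # mtoc_first | nucleus_first
    axis_vector: np.ndarray  # unit 2-vector (y, x)
    projection_um: float
    tie: bool = False


# ---------------------------------------------------------------------------
# segmentation (threshold stand-in for a trained pixel classifier)
# ---------------------------------------------------------------------------


def segment_cell(
    actin_frame: np.ndarray,
    nucleus_frame: np.ndarray | None = None,
    smooth_sigma_px: float = 2.0,
    pool_quantile: float = 0.75,
    rim_width_px: int = 2,
    external_masks: tuple[np.ndarray, np.ndarray | None, np.ndarray | None]
    | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Segment the cell body, its central actin pool and the nucleus.

    The cell mask is the largest connected component of the Otsu-thresholded,
    Gaussian-smoothed actin frame.  The central pool is the brightest region
    inside the cell: pixels above a second, higher threshold (Otsu of the
    in-cell intensities, floored at the ``pool_quantile`` in-cell quantile),
    eroded away from the cell's boundary rim so the lamellipodial band is not
    picked up.  The nucleus mask comes from Otsu on the nucleus frame.

    ``external_masks`` (cell, pool, nucleus) bypasses all computation and is
    returned unchanged — use this when a trained pixel classifier produced
    the masks.  Empty/blank frames yield empty masks, not an exception.
    """
    if external_masks is not None:
        cell_m, pool_m, nuc_m = external_masks
        empty = np.zeros_like(np.asarray(cell_m), dtype=bool)
        return (
            np.asarray(cell_m, dtype=bool),
            empty if pool_m is None else np.asarray(pool_m, dtype=bool),
            empty if nuc_m is None else np.asarray(nuc_m, dtype=bool),
        )
    actin_frame = np.asarray(actin_frame, dtype=float)
    empty = np.zeros(actin_frame.shape, dtype=bool)
    if actin_frame.max() == actin_frame.min():
        return empty, empty.copy(), empty.copy()
    sm = ndimage.gaussian_filter(actin_frame, smooth_sigma_px)
    thr = threshold_otsu(sm)
    fg = sm > thr
    lab = cc_label(fg)
    if lab.max() == 0:
        return empty, empty.copy(), empty.copy()
    sizes = np.bincount(lab.ravel())
    sizes[0] = 0
    cell_mask = lab == sizes.argmax()

    inner = cell_mask & ~ndimage.binary_dilation(~cell_mask, disk(rim_width_px))
    in_cell = sm[cell_mask]
    pool_thr = max(threshold_otsu(in_cell), np.quantile(in_cell, pool_quantile))
    pool_cand = (sm > pool_thr) & inner
    pool_lab = cc_label(pool_cand)
    if pool_lab.max() > 0:
        psizes = np.bincount(pool_lab.ravel())
        psizes[0] = 0
        pool_mask = pool_lab == psizes.argmax()
    else:
        pool_mask = empty.copy()

    if nucleus_frame is None:
        nuc_mask = empty.copy()
    else:
        nucleus_frame = np.asarray(nucleus_frame, dtype=float)
        if nucleus_frame.max() == nucleus_frame.min():
            nuc_mask = empty.copy()
        else:
            nsm = ndimage.gaussian_filter(nucleus_frame, smooth_sigma_px)
            nuc_mask = nsm > threshold_otsu(nsm)
    return cell_mask, pool_mask, nuc_mask


# ---------------------------------------------------------------------------
# tracking
# ---------------------------------------------------------------------------


def link_tracks(
    masks_per_frame: list[np.ndarray],
    max_step_px: float = 20.0,
    min_track_length: int = 10,
    frame_interval_s: float = 30.0,
    pixel_size_um: float = 1.0,
) -> list[CellTrack]:
    """Greedy nearest-centroid linking of per-frame label masks.

    Each element of ``masks_per_frame`` is a label image (0 = background).
    Centroids are linked frame-to-frame, closest pair first, with links
    longer than ``max_step_px`` refused.  Frames in which two cell masks
    touch terminate both tracks at the previous frame — only noninteracting,
    well-isolated cells are analyzable.  Tracks of length
    <= ``min_track_length`` frames are discarded (the filter is strict:
    length 11 survives, length 10 does not).
    """
    active: list[list[CellFrame]] = []
    done: list[list[CellFrame]] = []

    for t, lab in enumerate(masks_per_frame):
        lab = np.asarray(lab)
        props = regionprops(lab)
        # which labels touch another label? (interaction -> unusable)
        touching: set[int] = set()
        if len(props) > 1:
            for rp in props:
                m = lab == rp.label
                neigh = lab[ndimage.binary_dilation(m, disk(1)) & ~m]
                if np.any((neigh != 0) & (neigh != rp.label)):
                    touching.add(rp.label)
        frames_now = [
            CellFrame(
                time_index=t,
                cell_mask=lab == rp.label,
                centroid_px=(float(rp.centroid[0]), float(rp.centroid[1])),
                area_px=int(rp.area),
            )
            for rp in props
            if rp.label not in touching
        ]
        # greedy closest-pair assignment between active track heads and detections
        links: dict[int, int] = {}
        if active and frames_now:
            heads = np.array([tr[-1].centroid_px for tr in active])
            dets = np.array([f.centroid_px for f in frames_now])
            d = np.linalg.norm(heads[:, None, :] - dets[None, :, :], axis=2)
            order = np.dstack(np.unravel_index(np.argsort(d, axis=None), d.shape))[0]
            used_tr: set[int] = set()
            used_det: set[int] = set()
            for i, j in order:
                if d[i, j] > max_step_px:
                    break
                if i in used_tr or j in used_det:
                    continue
                if active[i][-1].time_index == t - 1:
                    links[int(j)] = int(i)
                    used_tr.add(int(i))
                    used_det.add(int(j))
        extended: set[int] = set()
        for j, f in enumerate(frames_now):
            if j in links:
                active[links[j]].append(f)
                extended.add(links[j])
            else:
                active.append([f])
                extended.add(len(active) - 1)
        still_active = []
        for i, tr in enumerate(active):
            if i in extended:
                still_active.append(tr)
            else:
                done.append(tr)
        active = still_active
    done.extend(active)

    return [
        CellTrack(frames=tr, frame_interval_s=frame_interval_s,
                  pixel_size_um=pixel_size_um)
        for tr in done
        if len(tr) > min_track_length
    ]


def cell_speed(track: CellTrack) -> tuple[np.ndarray, float]:
    """Per-step center-of-mass speed (um/min) and its mean over the track."""
    if len(track) < 2:
        raise ValueError("speed needs at least two frames")
    steps = np.diff(track.centroids_px, axis=0)
    dist_um = np.linalg.norm(steps, axis=1) * track.pixel_size_um
    speed = dist_um / (track.frame_interval_s / 60.0)
    return speed, float(speed.mean())


# ---------------------------------------------------------------------------
# protrusion / intensity descriptors
# ---------------------------------------------------------------------------


def protrusion_regions(
    mask_t: np.ndarray, mask_t1: np.ndarray, pixel_size_um: float = 1.0
) -> ProtrusionDecomposition:
    """Nonoverlapping regions of consecutive segmentations.

    ``gained`` is in the t+1 mask only (protrusion), ``lost`` in the t mask
    only (retraction); areas in um^2.
    """
    mask_t = np.asarray(mask_t, dtype=bool)
    mask_t1 = np.asarray(mask_t1, dtype=bool)
    if mask_t.shape != mask_t1.shape:
        raise ValueError("masks must share a shape")
    gained = mask_t1 & ~mask_t
    lost = mask_t & ~mask_t1
    a = pixel_size_um**2
    return ProtrusionDecomposition(
        gained_mask=gained,
        lost_mask=lost,
        gained_area_um2=float(gained.sum() * a),
        lost_area_um2=float(lost.sum() * a),
    )


def integrated_intensity(
    frame: np.ndarray,
    mask: np.ndarray,
    background_estimate: float | None = None,
    all_cell_masks: np.ndarray | None = None,
) -> float:
    """Integrated intensity over ``mask``, background-corrected.

    ``background_estimate`` defaults to the median intensity outside
    ``all_cell_masks`` (or outside ``mask`` itself when no global cell mask
    is given).  Negative corrected totals are clipped to 0 with a warning —
    they indicate a background estimate brighter than the region.
    """
    frame = np.asarray(frame, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("mask is empty")
    if background_estimate is None:
        outside = ~(np.asarray(all_cell_masks, dtype=bool) if all_cell_masks
                    is not None else mask)
        background_estimate = float(np.median(frame[outside])) if outside.any() else 0.0
    total = float(frame[mask].sum() - background_estimate * mask.sum())
    if total < 0:
        warnings.warn(
            f"background-corrected intensity {total:.3g} < 0; clipping to 0",
            stacklevel=2,
        )
        total = 0.0
    return total


def normalized_central_intensity(
    track: CellTrack,
    actin_frames: list[np.ndarray] | np.ndarray,
    background_estimate: float | None = None,
) -> tuple[np.ndarray, float]:
    """Central-pool mean intensity normalized to the cell's time-integrated mean.

    Per frame: (corrected mean intensity in the pool mask) divided by the
    per-frame average of the corrected mean cell intensity over the whole
    track.  Dimensionless; insensitive to camera gain and uniform offset.
    """
    per_frame_cell_mean = []
    per_frame_pool_mean = []
    for f, img in zip(track.frames, actin_frames):
        cell_tot = integrated_intensity(
            img, f.cell_mask, background_estimate, all_cell_masks=f.cell_mask
        )
        per_frame_cell_mean.append(cell_tot / f.cell_mask.sum())
        if f.central_pool_mask is not None and f.central_pool_mask.any():
            pool_tot = integrated_intensity(
                img, f.central_pool_mask, background_estimate,
                all_cell_masks=f.cell_mask,
            )
            per_frame_pool_mean.append(pool_tot / f.central_pool_mask.sum())
        else:
            per_frame_pool_mean.append(np.nan)
    if np.all(np.isnan(per_frame_pool_mean)):
        raise ValueError("no frame has a central pool mask")
    global_mean = float(np.mean(per_frame_cell_mean))
    if global_mean <= 0:
        raise ValueError("zero global cell intensity; cannot normalize")
    ratio = np.asarray(per_frame_pool_mean) / global_mean
    return ratio, float(np.nanmean(ratio))


def lamellipodium_fraction(
    frame: np.ndarray,
    lamellipodium_mask: np.ndarray,
    cell_mask: np.ndarray,
    background_estimate: float | None = None,
) -> float:
    """Actin density in the lamellipodium relative to the whole-cell density."""
    lamellipodium_mask = np.asarray(lamellipodium_mask, dtype=bool)
    cell_mask = np.asarray(cell_mask, dtype=bool)
    if not lamellipodium_mask.any() or not cell_mask.any():
        raise ValueError("masks must be non-empty")
    if (lamellipodium_mask & ~cell_mask).any():
        raise ValueError("lamellipodium mask must lie inside the cell mask")
    lam = integrated_intensity(
        frame, lamellipodium_mask, background_estimate, all_cell_masks=cell_mask
    ) / lamellipodium_mask.sum()
    cell = integrated_intensity(
        frame, cell_mask, background_estimate, all_cell_masks=cell_mask
    ) / cell_mask.sum()
    if cell == 0:
        raise ValueError("zero cell density")
    return float(lam / cell)


def default_lamellipodium_mask(
    mask_t: np.ndarray, mask_t1: np.ndarray
) -> np.ndarray:
    """Gained-region band, dilated by 1 px and clipped to the cell."""
    gained = np.asarray(mask_t1, dtype=bool) & ~np.asarray(mask_t, dtype=bool)
    return ndimage.binary_dilation(gained, disk(1)) & np.asarray(mask_t1, dtype=bool)


# ---------------------------------------------------------------------------
# orientation
# ---------------------------------------------------------------------------


def classify_orientation(
    mtoc_px: tuple[float, float],
    nucleus_centroid_px: tuple[float, float],
    axis_vector: tuple[float, float],
    pixel_size_um: float = 1.0,
    tie_epsilon_px: float = 1.0,
) -> OrientationCall:
    """Is the MTOC ahead of the nucleus along the polarization axis?

    The signed projection of (MTOC - nucleus centroid) onto the unit axis
    decides: positive = ``mtoc_first``.  Projections smaller in magnitude
    than one pixel-equivalent are reported ``nucleus_first`` with a tie flag.
    """
    axis = np.asarray(axis_vector, dtype=float)
    norm = np.linalg.norm(axis)
    if norm == 0:
        raise ValueError("axis vector must be nonzero")
    if not (np.all(np.isfinite(mtoc_px)) and np.all(np.isfinite(nucleus_centroid_px))):
        raise ValueError("positions must be finite")
    axis = axis / norm
    delta = np.asarray(mtoc_px, dtype=float) - np.asarray(nucleus_centroid_px)
    proj_px = float(delta @ axis)
    tie = abs(proj_px) < tie_epsilon_px
    value = "mtoc_first" if (proj_px > 0 and not tie) else "nucleus_first"
    return OrientationCall(
        value=value,
        axis_vector=axis,
        projection_um=proj_px * pixel_size_um,
        tie=tie,
    )


def velocity_axis(track: CellTrack, frame_index: int, window: int = 2) -> np.ndarray:
    """Polarization axis from centroid displacement over +-``window`` frames."""
    c = track.centroids_px
    a = max(0, frame_index - window)
    b = min(len(track) - 1, frame_index + window)
    v = c[b] - c[a]
    n = np.linalg.norm(v)
    if n == 0:
        raise ValueError("cell did not move in the window; axis undefined")
    return v / n


# ---------------------------------------------------------------------------
# retraction-event pooling
# ---------------------------------------------------------------------------


def pool_retraction_events(
    events: list[tuple[np.ndarray, int]],
) -> dict[str, np.ndarray]:
    """Align events at their onset, normalize to the onset value, and average.

    Each event is a ``(series, onset_index)`` pair.  Every series is divided
    by its value at the onset (events with zero onset value are excluded with
    a warning) and shifted so the onset sits at lag 0; the pooled mean, SEM
    and per-lag event count are returned on the common lag grid.  Lags
    covered by fewer than two events carry ``sem = nan`` and are flagged.
    """
    normed: list[tuple[np.ndarray, int]] = []
    for i, (series, onset) in enumerate(events):
        series = np.asarray(series, dtype=float)
        if not 0 <= onset < series.size:
            raise ValueError(f"event {i}: onset {onset} outside the series")
        if series[onset] == 0:
            warnings.warn(f"event {i} has zero intensity at onset; excluded",
                          stacklevel=2)
            continue
        normed.append((series / series[onset], onset))
    if not normed:
        raise ValueError("no usable events")
    lag_min = min(-onset for _, onset in normed)
    lag_max = max(s.size - 1 - onset for s, onset in normed)
    lags = np.arange(lag_min, lag_max + 1)
    table = np.full((len(normed), lags.size), np.nan)
    for row, (s, onset) in enumerate(normed):
        start = -onset - lag_min
        table[row, start : start + s.size] = s
    n = np.sum(~np.isnan(table), axis=0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        mean = np.nanmean(table, axis=0)
        sd = np.nanstd(table, axis=0, ddof=1)
    sem = np.where(n >= 2, sd / np.sqrt(np.maximum(n, 1)), np.nan)
    return {
        "lags": lags,
        "mean": mean,
        "sem": sem,
        "n_events": n,
        "undersampled": n < 2,
    }


__all__ = [
    "CellFrame", "CellTrack", "ProtrusionDecomposition", "OrientationCall",
    "segment_cell", "link_tracks", "cell_speed", "protrusion_regions",
    "integrated_intensity", "normalized_central_intensity",
    "lamellipodium_fraction", "default_lamellipodium_mask",
    "classify_orientation", "velocity_axis", "pool_retraction_events",
]
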