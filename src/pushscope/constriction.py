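"""Actin accumulation at channel constrictions.

Cells squeezing through a narrowed channel section accumulate actin there.
The readout: average the signal vertically inside the segmented channel lumen
to get a longitudinal density profile per frame, take the per-column maximum
over time, and compare the peak inside the constriction interval with the
peak outside it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu
from skimage.measure import label as cc_label


@dataclass
class DensityProfile:
    """Per-frame and time-max longitudinal density profiles of a channel."""

    x_positions_px: np.ndarray  # columns where the mask has >= 1 pixel
    profiles: np.ndarray  # (T, X_valid)
    time_max_profile: np.ndarray  # (X_valid,)
    channel_mask: np.ndarray
    constriction_interval_px: tuple[int, int] | None = None  # half-open [x0, x1)


def segment_channel(
    brightfield_frame: np.ndarray | None = None,
    mask: np.ndarray | None = None,
    smooth_sigma_px: float = 1.0,
) -> np.ndarray:
    """Binary mask of the channel lumen.

    Threshold the brightfield frame (Otsu after light smoothing), keep the
    largest connected component, and fill holes.  A user-supplied ``mask``
    bypasses the computation entirely.
    """
    if mask is not None:
        return np.asarray(mask, dtype=bool)
    if brightfield_frame is None:
        raise ValueError("need a brightfield frame or an explicit mask")
    frame = np.asarray(brightfield_frame, dtype=float)
    if frame.size == 0 or frame.max() == frame.min():
        raise ValueError("blank frame: no channel found")
    sm = ndimage.gaussian_filter(frame, smooth_sigma_px) if smooth_sigma_px else frame
    lab = cc_label(sm > threshold_otsu(sm))
    if lab.max() == 0:
        raise ValueError("no connected component above threshold")
    sizes = np.bincount(lab.ravel())
    sizes[0] = 0
    return ndimage.binary_fill_holes(lab == sizes.argmax())


def density_profile(
    signal_frames: np.ndarray,
    mask: np.ndarray,
    constriction_interval_px: tuple[int, int] | None = None,
    background_subtract: bool = True,
    cell_presence: np.ndarray | None = None,
) -> DensityProfile:
    """Vertically averaged signal per column, per frame, and its time-max.

    Per frame and column, the profile is the mean of the signal over the mask
    pixels of that column (mean, not sum, so the channel height does not
    enter).  Columns with no mask pixel are absent from the profile, not
    zero.  The final profile is the per-column maximum over frames.

    ``cell_presence`` (bool, per frame and column) restricts the time-max of
    each column to the frames in which the cell actually covers it, so empty
    channel frames do not dilute the statistic.  With
    ``background_subtract`` (default on) the per-column median over the
    frames *without* the cell is removed first; without presence information
    the per-column minimum over time is used as the background.
    """
    signal_frames = np.asarray(signal_frames, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    if signal_frames.ndim != 3 or signal_frames.shape[1:] != mask.shape:
        raise ValueError("signal must be T x Y x X matching the mask")
    col_counts = mask.sum(axis=0)
    valid_cols = np.nonzero(col_counts > 0)[0]
    if valid_cols.size == 0:
        raise ValueError("mask is empty")
    t_n = signal_frames.shape[0]
    masked = np.where(mask[None], signal_frames, 0.0)
    profiles = masked[:, :, valid_cols].sum(axis=1) / col_counts[valid_cols]

    if background_subtract:
        if cell_presence is not None:
            absent = ~cell_presence[:, valid_cols]
            bg = np.full(valid_cols.size, 0.0)
            for j in range(valid_cols.size):
                if absent[:, j].any():
                    bg[j] = np.median(profiles[absent[:, j], j])
        else:
            bg = profiles.min(axis=0)
        profiles = profiles - bg[None, :]

    if cell_presence is not None:
        present = cell_presence[:, valid_cols]
        masked_prof = np.where(present, profiles, -np.inf)
        time_max = masked_prof.max(axis=0)
        # columns never visited fall back to the plain max
        never = ~present.any(axis=0)
        time_max[never] = profiles[:, never].max(axis=0)
    else:
        time_max = profiles.max(axis=0)

    return DensityProfile(
        x_positions_px=valid_cols,
        profiles=profiles,
        time_max_profile=time_max,
        channel_mask=mask,
        constriction_interval_px=constriction_interval_px,
    )


def constriction_ratio(profile: DensityProfile) -> float:
    """Peak time-max density inside the constriction over the peak outside."""
    if profile.constriction_interval_px is None:
        raise ValueError("profile carries no constriction interval")
    x0, x1 = profile.constriction_interval_px
    inside = (profile.x_positions_px >= x0) & (profile.x_positions_px < x1)
    if not inside.any() or inside.all():
        raise ValueError("need non-empty profiles both inside and outside")
    peak_in = float(profile.time_max_profile[inside].max())
    peak_out = float(profile.time_max_profile[~inside].max())
    if peak_out == 0:
        raise ValueError("zero outside maximum; ratio undefined")
    return peak_in / peak_out
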