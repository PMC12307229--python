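"""Classify which cell compartment lies under each bead, frame by frame.

The actin reporter intensity summed in a small window around a bead rises in
steps as the cell passes: background only, plain cytoplasm, then the bright
central actin pool.  One-dimensional K-means on the per-frame actin sums
separates these regimes; clusters are mapped to labels by ascending mean
(lowest = ``none``, highest = ``central_actin``).  Two clusters are used for
cells that lack a central pool, three for cells that have one.  The DNA-stain
channel overrides: frames where the nucleus sits over the bead are labeled
``nucleus`` regardless of the actin level, since actin is present beneath the
nucleus as well.

Clustering is per bead: absolute intensities vary bead to bead with depth and
labeling, so each trace defines its own levels.  A pooled mode is available
for cohorts imaged under identical conditions.
"""

from __future__ import annotations

import numpy as np
from dataclasses import dataclass, field

from sklearn.cluster import KMeans

from .beads import BeadRecord, DisplacementTrace
from .synth import LABELS


@dataclass
class ChannelTraces:
    """Per-frame total actin and nucleus intensity in a window around a bead."""

    actin: np.ndarray
    nucleus: np.ndarray
    window_halfwidth_px: int = 10
    bead_id: int = -1

    def __post_init__(self) -> None:
        self.actin = np.asarray(self.actin, dtype=float)
        self.nucleus = np.asarray(self.nucleus, dtype=float)
        if self.actin.shape != self.nucleus.shape or self.actin.ndim != 1:
            raise ValueError("actin and nucleus traces must be equal-length 1D")
        if (self.actin < 0).any() or (self.nucleus < 0).any():
            raise ValueError("intensity traces must be non-negative")


@dataclass
class ContributionLabels:
    """Per-frame compartment labels for one bead."""

    labels: np.ndarray  # dtype '<U13', values in LABELS
    k_used: int
    cluster_means: np.ndarray  # ascending actin cluster means
    bead_id: int = -1

    def __post_init__(self) -> None:
        bad = set(np.unique(self.labels)) - set(LABELS)
        if bad:
            raise ValueError(f"unknown labels {bad}")
        if self.k_used == 2 and "central_actin" in self.labels:
            raise ValueError("central_actin cannot be assigned with k=2")
        if not np.all(np.diff(self.cluster_means) > 0):
            raise ValueError("cluster means must be strictly increasing")


@dataclass
class RegionDisplacementSummary:
    """Baseline-subtracted mean displacement per compartment.

    Regions with zero frames are absent from the mappings, not reported as 0.
    """

    mean_displacement_um: dict[str, float] = field(default_factory=dict)
    frame_counts: dict[str, int] = field(default_factory=dict)
    baseline_um: float = float("nan")


# ---------------------------------------------------------------------------


def extract_channel_traces(
    actin_channel: np.ndarray,
    nucleus_channel: np.ndarray,
    bead: BeadRecord,
    halfwidth_px: int = 10,
) -> ChannelTraces:
    """Sum each channel over Z and a (2h+1)^2 XY window, per frame.

    The default half-width 10 gives the 20 x 20 px (21 px wide, centered)
    window.  A window leaving the image is an error, as for kymographs.
    """
    if not bead.accepted:
        raise ValueError(f"bead {bead.id} was rejected ({bead.rejection_reason})")
    actin_channel = np.asarray(actin_channel)
    nucleus_channel = np.asarray(nucleus_channel)
    if actin_channel.shape != nucleus_channel.shape or actin_channel.ndim != 4:
        raise ValueError("channels must be equal-shape T x Z x Y x X")
    _, _, y_n, x_n = actin_channel.shape
    cy, cx = (int(round(c)) for c in bead.xy_centroid_px)
    h = halfwidth_px
    if cy - h < 0 or cx - h < 0 or cy + h >= y_n or cx + h >= x_n:
        raise ValueError(
            f"trace window of bead {bead.id} at ({cy}, {cx}) with half-width {h} "
            f"exceeds the image bounds"
        )
    sl = np.s_[:, :, cy - h : cy + h + 1, cx - h : cx + h + 1]
    return ChannelTraces(
        actin=np.clip(actin_channel[sl].sum(axis=(1, 2, 3)), 0, None),
        nucleus=np.clip(nucleus_channel[sl].sum(axis=(1, 2, 3)), 0, None),
        window_halfwidth_px=h,
        bead_id=bead.id,
    )


def _nucleus_frames(nucleus: np.ndarray, min_separation_factor: float) -> np.ndarray:
    """Frames assigned to the upper of a two-cluster split of the nucleus trace.

    A split is only trusted when the two cluster means are separated by more
    than ``min_separation_factor`` times the pooled within-cluster spread —
    otherwise the trace is flat (nucleus never over the bead) and no frame is
    flagged.
    """
    if np.unique(nucleus).size < 2:
        return np.zeros(nucleus.size, dtype=bool)
    km = KMeans(n_clusters=2, n_init=10, random_state=0).fit(nucleus.reshape(-1, 1))
    means = km.cluster_centers_.ravel()
    hi = int(means.argmax())
    assign = km.labels_ == hi
    within_sd = np.sqrt(
        np.mean((nucleus - km.cluster_centers_.ravel()[km.labels_]) ** 2)
    )
    if abs(means.max() - means.min()) <= min_separation_factor * max(
        within_sd, 1e-12 * max(abs(means).max(), 1.0)
    ):
        return np.zeros(nucleus.size, dtype=bool)
    return assign


def _suppress_flicker(labels: np.ndarray, min_dwell: int) -> np.ndarray:
    """Reassign runs shorter than ``min_dwell`` to the preceding run's label."""
    if min_dwell <= 1 or labels.size == 0:
        return labels
    out = labels.copy()
    # run-length encode
    runs: list[tuple[int, int, str]] = []
    start = 0
    for i in range(1, out.size + 1):
        if i == out.size or out[i] != out[start]:
            runs.append((start, i, out[start]))
            start = i
    for idx, (a, b, lab) in enumerate(runs):
        if b - a < min_dwell:
            if idx > 0:
                out[a:b] = out[a - 1]
            elif idx + 1 < len(runs):
                out[a:b] = runs[idx + 1][2]
    return out


def classify_frames(
    traces: ChannelTraces,
    k: int = 3,
    nucleus_min_separation: float = 4.0,
    seed: int = 0,
    min_dwell_frames: int = 2,
) -> ContributionLabels:
    """K-means the actin trace into intensity regimes and map them to labels.

    ``k=3`` (cells with a central pool) maps ascending cluster means to
    ``none`` < ``cytoplasm`` < ``central_actin``; ``k=2`` (cells without a
    pool) to ``none`` < ``cytoplasm``.  Frames in the upper cluster of the
    nucleus trace (see :func:`_nucleus_frames`) are relabeled ``nucleus``,
    overriding the actin label.  Runs shorter than ``min_dwell_frames`` are
    absorbed into their neighbor: at 30 s sampling, compartment passages last
    minutes, so single-frame flicker is noise.
    """
    if k not in (2, 3):
        raise ValueError("k must be 2 or 3")
    actin = traces.actin
    if actin.size < k:
        raise ValueError(f"need at least {k} frames for k={k}")
    if np.unique(actin).size < k:
        raise ValueError(
            f"actin trace has fewer than {k} distinct values; clustering degenerate"
        )
    km = KMeans(n_clusters=k, n_init=10, random_state=seed).fit(actin.reshape(-1, 1))
    order = np.argsort(km.cluster_centers_.ravel())
    level_names = ("none", "cytoplasm", "central_actin")[:k]
    cluster_to_label = {int(c): level_names[rank] for rank, c in enumerate(order)}
    labels = np.array([cluster_to_label[c] for c in km.labels_], dtype="<U13")
    labels[_nucleus_frames(traces.nucleus, nucleus_min_separation)] = "nucleus"
    labels = _suppress_flicker(labels, min_dwell_frames)
    means = np.sort(km.cluster_centers_.ravel())
    return ContributionLabels(
        labels=labels, k_used=k, cluster_means=means, bead_id=traces.bead_id
    )


def summarize_region_displacement(
    trace: DisplacementTrace,
    labels: ContributionLabels,
    external_baseline_um: float | None = None,
) -> RegionDisplacementSummary:
    """Mean baseline-subtracted bead position per compartment.

    The baseline is the mean tracked edge over valid frames labeled ``none``
    (no cell over the bead); by construction the ``none`` region then reports
    a mean displacement of 0.  Scenes where the bead is never free of the
    cell have no internal baseline — supply ``external_baseline_um``.
    """
    lab = labels.labels
    if lab.size != trace.edge_z_um.size:
        raise ValueError("trace and labels must cover the same frames")
    valid = trace.valid_frames
    none_frames = (lab == "none") & valid
    if external_baseline_um is not None:
        baseline = float(external_baseline_um)
    elif none_frames.any():
        baseline = float(trace.edge_z_um[none_frames].mean())
    else:
        raise ValueError(
            "no 'none'-labeled valid frames: baseline undefined, supply "
            "external_baseline_um"
        )
    out = RegionDisplacementSummary(baseline_um=baseline)
    for region in LABELS:
        sel = (lab == region) & valid
        n = int(sel.sum())
        if n == 0:
            continue
        out.mean_displacement_um[region] = float(
            trace.edge_z_um[sel].mean() - baseline
        )
        out.frame_counts[region] = n
    return out
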