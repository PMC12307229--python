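"""End-to-end orchestration of the three analyses.

Each pipeline chains the module operations on an :class:`ImageStack` and
returns tidy pandas tables (one row per entity and frame, plus summaries);
the pipelines add bookkeeping and logging but no computation of their own, so
every number in an output table is reproducible by calling the underlying
operations directly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import beads as B
from . import contribution as C
from . import correlation as X
from . import morphometry as M
from .stack import ImageStack

log = logging.getLogger("pushscope")

#: process exit codes for the CLI
EXIT_OK, EXIT_CONFIG_ERROR, EXIT_EMPTY_RESULT = 0, 2, 3


@dataclass
class PushforceResult:
    traces: pd.DataFrame  # one row per (bead, frame)
    summary: pd.DataFrame  # one row per (bead, region)
    rejected: pd.DataFrame  # bead-level rejection log
    n_accepted: int = 0
    warnings: list[str] = field(default_factory=list)


def run_pushforce_pipeline(
    stack: ImageStack,
    bead_channel: str = "bead",
    actin_channel: str = "actin",
    nucleus_channel: str = "nucleus",
    k: int = 3,
    seed: int = 0,
    detect_kwargs: dict | None = None,
) -> PushforceResult:
    """Bead displacement analysis end to end.

    Detect stationary beads, track each bead's Z edge through its kymograph,
    classify the per-frame compartment under the bead from the actin and
    nucleus traces, re-baseline each trace on its ``none``-labeled frames,
    and summarize per-region displacement.  Deterministic for a fixed seed.
    """
    bead_ch = stack.channel(bead_channel)
    actin_ch = stack.channel(actin_channel)
    nuc_ch = stack.channel(nucleus_channel)

    records = B.detect_beads(bead_ch, **(detect_kwargs or {}))
    accepted = [r for r in records if r.accepted]
    rejected_df = pd.DataFrame(
        [
            {
                "bead_id": r.id,
                "y_px": r.xy_centroid_px[0],
                "x_px": r.xy_centroid_px[1],
                "area_px": r.area_px,
                "accepted": r.accepted,
                "rejection_reason": r.rejection_reason,
            }
            for r in records
        ]
    )
    log.info(
        "bead detection: %d candidates, %d accepted", len(records), len(accepted)
    )

    trace_rows, summary_rows, warn = [], [], []
    for rec in accepted:
        kym = B.extract_kymograph(
            bead_ch, rec, z_step_um=stack.z_step_um,
            frame_interval_s=stack.frame_interval_s,
        )
        trace = B.track_edge(kym)
        traces = C.extract_channel_traces(actin_ch, nuc_ch, rec)
        try:
            labels = C.classify_frames(traces, k=k, seed=seed)
        except ValueError as e:
            warn.append(f"bead {rec.id}: {e}")
            continue
        none_frames = (labels.labels == "none") & trace.valid_frames
        if none_frames.any():
            trace = trace.with_baseline(float(trace.edge_z_um[none_frames].mean()))
        try:
            summary = C.summarize_region_displacement(trace, labels)
        except ValueError as e:
            warn.append(f"bead {rec.id}: {e}")
            continue
        for t in range(trace.edge_z_um.size):
            trace_rows.append(
                {
                    "bead_id": rec.id,
                    "frame": t,
                    "edge_z_um": trace.edge_z_um[t],
                    "displacement_um": trace.displacement_um[t],
                    "valid": bool(trace.valid_frames[t]),
                    "label": labels.labels[t],
                }
            )
        max_disp = B.max_displacement(trace)
        for region, mean in summary.mean_displacement_um.items():
            summary_rows.append(
                {
                    "bead_id": rec.id,
                    "region": region,
                    "mean_displacement_um": mean,
                    "n_frames": summary.frame_counts[region],
                    "max_displacement_um": max_disp,
                }
            )
    result = PushforceResult(
        traces=pd.DataFrame(trace_rows),
        summary=pd.DataFrame(summary_rows),
        rejected=rejected_df,
        n_accepted=len(accepted),
        warnings=warn,
    )
    if not accepted:
        result.warnings.append("zero accepted beads")
    return result


@dataclass
class CouplingResult:
    per_cell: pd.DataFrame  # one row per (cell, lag)
    pooled: pd.DataFrame  # one row per lag
    cells: pd.DataFrame  # per-cell summary (speed, area, peak lag, p)
    warnings: list[str] = field(default_factory=list)


def run_coupling_pipeline(
    stack: ImageStack,
    actin_channel: str = "actin",
    nucleus_channel: str = "nucleus",
    max_lag: int = 10,
    n_permutations: int = 500,
    seed: int = 0,
    min_track_length: int = 10,
) -> CouplingResult:
    """Central-pool vs protrusion actin coupling for one movie.

    Segments and tracks cells, extracts background-corrected central-pool and
    protrusion-band intensity series per tracked cell, and cross-correlates
    them with permutation significance; per-cell curves are pooled.
    """
    actin = stack.channel_2d(actin_channel)
    nucleus = stack.channel_2d(nucleus_channel)
    t_n = actin.shape[0]

    label_frames = []
    pool_masks: list[np.ndarray] = []
    for t in range(t_n):
        cell_m, pool_m, _ = M.segment_cell(actin[t], nucleus[t])
        label_frames.append(cell_m.astype(np.int32))
        pool_masks.append(pool_m)
    tracks = M.link_tracks(
        label_frames,
        min_track_length=min_track_length,
        frame_interval_s=stack.frame_interval_s,
        pixel_size_um=stack.pixel_size_um,
    )
    warnings_: list[str] = []
    per_cell_rows, cell_rows, curves = [], [], []
    for ci, track in enumerate(tracks):
        pool_series, prot_series = [], []
        for f, nxt in zip(track.frames[:-1], track.frames[1:]):
            t = f.time_index
            pm = pool_masks[t] & f.cell_mask
            lam = M.default_lamellipodium_mask(f.cell_mask, nxt.cell_mask)
            bg = float(np.median(actin[t][~f.cell_mask]))
            pool_series.append(
                M.integrated_intensity(actin[t], pm, bg) if pm.any() else np.nan
            )
            prot_series.append(
                M.integrated_intensity(actin[nxt.time_index], lam, bg)
                if lam.any()
                else np.nan
            )
        pool_s = np.asarray(pool_series)
        prot_s = np.asarray(prot_series)
        ok = ~(np.isnan(pool_s) | np.isnan(prot_s))
        if ok.sum() < 2 * max_lag + 4 or pool_s[ok].std() == 0 or prot_s[ok].std() == 0:
            warnings_.append(f"cell {ci}: series too short or degenerate; skipped")
            continue
        pool_s, prot_s = pool_s[ok], prot_s[ok]
        cc = X.cross_correlate(pool_s, prot_s, max_lag=max_lag)
        sig = X.lag_significance(
            pool_s, prot_s, max_lag=max_lag, n_permutations=n_permutations,
            seed=seed + ci,
        )
        curves.append(cc)
        speeds, mean_speed = M.cell_speed(track)
        for lag, r in zip(cc.lags, cc.r):
            per_cell_rows.append({"cell": ci, "lag": int(lag), "r": r})
        cell_rows.append(
            {
                "cell": ci,
                "n_frames": len(track),
                "mean_speed_um_per_min": mean_speed,
                "peak_lag": cc.peak_lag,
                "peak_r": cc.peak_r,
                "p_value": sig.p_value,
            }
        )
    pooled_df = pd.DataFrame()
    if curves:
        pooled = X.pool_cross_correlations(curves)
        pooled_df = pd.DataFrame(
            {
                "lag": pooled["lags"],
                "mean_r": pooled["mean"],
                "sem": pooled["sem"],
                "n": pooled["n"],
            }
        )
    else:
        warnings_.append("no analyzable cells")
    return CouplingResult(
        per_cell=pd.DataFrame(per_cell_rows),
        pooled=pooled_df,
        cells=pd.DataFrame(cell_rows),
        warnings=warnings_,
    )
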