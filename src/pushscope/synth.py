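"""Ground-truthed synthetic microscopy scenes.

Every assay geometry the pipeline consumes can be generated here with a known
answer attached: beads embedded in an elastic layer and pushed vertically by a
passing cell, a migrating 2D cell with coupled central-pool/protrusion actin
dynamics, a microfluidic channel with a constriction, and paired smooth 2D
fields with planted local maxima.  The generators are deliberately geometric
rather than mechanical — they are oracles for parameter recovery, not models
of agarose elasticity or optics (blur is Gaussian, beads are sub-resolution
Gaussian spots).

Determinism contract: identical parameters and seed give byte-identical
output.  Each scene draws from one ``numpy`` Generator seeded from the scene
seed, with independent child streams per channel so partial regenerations
reproduce.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .stack import ImageStack

#: the contribution alphabet, ordered by actin-intensity regime
LABELS = ("none", "cytoplasm", "central_actin", "nucleus")


# ---------------------------------------------------------------------------
# parameter containers
# ---------------------------------------------------------------------------


@dataclass
class NoiseModel:
    """Additive Gaussian camera noise, optionally on top of Poisson shot noise."""

    gaussian_sd: float = 20.0
    poisson_on: bool = False

    def apply(self, clean: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        out = clean.astype(np.float32)
        if self.poisson_on:
            out = rng.poisson(np.clip(out, 0, None)).astype(np.float32)
        if self.gaussian_sd > 0:
            out = out + rng.normal(0.0, self.gaussian_sd, size=out.shape).astype(
                np.float32
            )
        return out


@dataclass
class BeadSceneParams:
    """Conditions for a bead-displacement (pushing-force) scene.

    Geometry: the coverslip is at z = 0; beads rest at ``bead_baseline_z_um``
    inside the gel and are pushed to larger z (deeper into the gel) while the
    cell footprint passes underneath.  A cell disk with a bright central actin
    pool and a trailing nucleus translates along +x at constant speed; beads
    sit on its path so each experiences the full passage sequence
    none -> cytoplasm -> central pool -> nucleus -> cytoplasm -> none.

    Defaults mirror the acquisition this emulates: 0.1 um Z-step, one frame
    every 30 s, ~1 um beads rendered as Gaussians.
    """

    image_shape: tuple[int, int, int, int] = (40, 28, 96, 240)  # T, Z, Y, X
    voxel_size_um: tuple[float, float, float] = (0.1, 0.325, 0.325)  # z, y, x
    frame_interval_s: float = 30.0
    n_beads: int = 20
    bead_sigma_um: float = 0.45
    bead_baseline_z_um: float = 1.0
    displacement_amplitude_um: float = 0.8
    cell_speed_um_per_s: float = 0.05
    cell_radius_um: float = 10.0
    central_pool_radius_um: float = 4.0
    nucleus_radius_um: float = 2.0
    pool_offset_um: float = -1.0  # pool center relative to cell center, along x
    nucleus_offset_um: float = -8.0
    cytoplasm_push_fraction: float = 0.15  # push under plain cytoplasm, vs pool/nucleus
    envelope_rolloff_um: float = 4.0  # shoulder beyond the pool/nucleus footprints
    cytoplasm_rolloff_um: float = 1.5  # the thin cytoplasm sheet deforms locally
    bead_peak_intensity: float = 100.0
    intensity_levels: tuple[float, float, float, float] = (10.0, 60.0, 200.0, 180.0)
    noise_model: NoiseModel = field(default_factory=NoiseModel)
    bead_drift_px_per_frame: float = 0.0  # nonzero makes every bead nonstationary
    seed: int = 0

    def validate(self) -> None:
        t, z, y, x = self.image_shape
        if min(t, z, y, x) < 1 or self.n_beads < 1:
            raise ValueError("all counts must be >= 1")
        if any(v <= 0 for v in self.voxel_size_um) or self.frame_interval_s <= 0:
            raise ValueError("physical scales must be positive")
        if self.bead_sigma_um <= 0 or self.central_pool_radius_um <= 0:
            raise ValueError("physical scales must be positive")
        if self.displacement_amplitude_um < 0:
            raise ValueError("displacement amplitude must be >= 0")
        bg, cyt, pool, _ = self.intensity_levels
        if not (bg < cyt < pool):
            raise ValueError(
                "intensity_levels must increase strictly from background to "
                "central pool"
            )
        # the bead must fit in Z with room for the full excursion
        z_extent = (self.bead_baseline_z_um + self.displacement_amplitude_um
                    + 2 * self.bead_sigma_um)
        if z_extent >= z * self.voxel_size_um[0]:
            raise ValueError(
                f"Z extent {z * self.voxel_size_um[0]:.2f} um cannot contain a bead "
                f"pushed to {z_extent:.2f} um"
            )
        if 4 * self.bead_sigma_um / self.voxel_size_um[2] > min(y, x) / 4:
            raise ValueError("image too small to contain a bead footprint")


@dataclass
class MigrationSceneParams:
    """Conditions for a 2D under-gel migration movie (actin + nucleus channels)."""

    image_shape: tuple[int, int, int] = (120, 96, 192)  # T, Y, X
    pixel_size_um: float = 0.65
    frame_interval_s: float = 30.0
    cell_speed_um_per_s: float = 0.02
    cell_radius_um: float = 9.0
    central_pool_radius_um: float = 3.0
    pool_offset_um: float = -1.5
    nucleus_radius_um: float = 3.5
    nucleus_offset_um: float = -5.0
    band_width_um: float = 2.0  # lamellipodial band beyond the cell-body radius
    modulation_depth: float = 0.3  # fractional intensity swing driven by the latents
    latent_smooth_frames: float = 1.5
    intensity_levels: tuple[float, float, float, float] = (10.0, 60.0, 200.0, 180.0)
    noise_model: NoiseModel = field(default_factory=lambda: NoiseModel(gaussian_sd=3.0))
    seed: int = 0


@dataclass
class ConstrictionSceneParams:
    """Conditions for a cell traversing a straight channel with a constriction."""

    image_shape: tuple[int, int, int] = (40, 64, 200)  # T, Y, X
    pixel_size_um: float = 0.4
    frame_interval_s: float = 60.0
    channel_halfwidth_px: int = 10
    constriction_interval_px: tuple[int, int] = (90, 110)  # half-open [x0, x1)
    constriction_halfwidth_px: int = 3
    cell_length_px: int = 40
    actin_level: float = 100.0
    background_level: float = 0.0
    noise_model: NoiseModel = field(default_factory=lambda: NoiseModel(gaussian_sd=2.0))
    seed: int = 0


@dataclass
class GroundTruth:
    """Everything a scene knows about itself; the oracle for recovery tests.

    Fields not applicable to a scene type are left ``None``.
    """

    # bead scenes
    edge_z_um: np.ndarray | None = None  # (n_beads, T) true bead-center Z, um
    labels: list[list[str]] | None = None  # (n_beads, T) contribution labels
    bead_xy_px: np.ndarray | None = None  # (n_beads, 2) as (y, x)
    # cell scenes
    cell_centroid_px: np.ndarray | None = None  # (T, 2) as (y, x)
    cell_masks: np.ndarray | None = None  # (T, Y, X) bool
    pool_masks: np.ndarray | None = None
    nucleus_masks: np.ndarray | None = None
    # coupled-trace scenes
    latent_pool: np.ndarray | None = None
    latent_protrusion: np.ndarray | None = None
    coupling_lag_frames: int | None = None
    coupling_sign: int | None = None
    # constriction scenes
    enrichment_factor: float | None = None
    channel_mask: np.ndarray | None = None
    constriction_interval_px: tuple[int, int] | None = None
    # field-pair scenes
    maxima_a_px: np.ndarray | None = None  # (n, 2) as (y, x), subpixel
    maxima_b_px: np.ndarray | None = None
    pair_distances_um: np.ndarray | None = None
    offset_um: float | None = None
    pixel_size_um: float | None = None
    warnings: list[str] = field(default_factory=list)

    def to_jsonable(self) -> dict:
        out = {}
        for k, v in self.__dict__.items():
            if v is None:
                continue
            if isinstance(v, np.ndarray):
                out[k] = v.tolist()
            else:
                out[k] = v
        return out


# ---------------------------------------------------------------------------
# helpers
# ---------------------------------------------------------------------------


def _child_rngs(seed: int, n: int) -> list[np.random.Generator]:
    """Independent child streams keyed by the scene seed."""
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


def _plateau_rolloff(d: np.ndarray, radius: float, shoulder: float) -> np.ndarray:
    """1 inside ``radius``, raised-cosine decay to 0 over ``shoulder``, 0 beyond.

    Smoothness of the shoulder gives the gradual rise and relaxation seen when
    a footprint approaches and leaves a bead; the plateau guarantees that a
    directly overrun bead reaches the full displacement amplitude exactly.
    """
    w = np.zeros_like(d, dtype=float)
    w[d <= radius] = 1.0
    on_shoulder = (d > radius) & (d < radius + shoulder)
    w[on_shoulder] = np.cos(0.5 * np.pi * (d[on_shoulder] - radius) / shoulder) ** 2
    return w


def _disk_mask(shape_yx, center_yx, radius_px) -> np.ndarray:
    yy, xx = np.ogrid[: shape_yx[0], : shape_yx[1]]
    return (yy - center_yx[0]) ** 2 + (xx - center_yx[1]) ** 2 <= radius_px**2


def _render_gaussian_spot(
    volume: np.ndarray,
    center_zyx: tuple[float, float, float],
    sigma_vox: tuple[float, float, float],
    peak: float,
) -> None:
    """Add a 3D Gaussian into ``volume`` in-place, windowed to +-4 sigma."""
    lo, hi, coords = [], [], []
    for ax, (c, s, n) in enumerate(zip(center_zyx, sigma_vox, volume.shape)):
        a = max(0, int(math.floor(c - 4 * s)))
        b = min(n, int(math.ceil(c + 4 * s)) + 1)
        if a >= b:
            return
        lo.append(a)
        hi.append(b)
        coords.append(np.arange(a, b, dtype=float) - c)
    gz = np.exp(-0.5 * (coords[0] / sigma_vox[0]) ** 2)
    gy = np.exp(-0.5 * (coords[1] / sigma_vox[1]) ** 2)
    gx = np.exp(-0.5 * (coords[2] / sigma_vox[2]) ** 2)
    volume[lo[0] : hi[0], lo[1] : hi[1], lo[2] : hi[2]] += (
        peak * gz[:, None, None] * gy[None, :, None] * gx[None, None, :]
    ).astype(volume.dtype)


def _smooth_series(n: int, sigma: float, rng: np.random.Generator) -> np.ndarray:
    """Standardized Gaussian-filtered white noise of length ``n``."""
    from scipy.ndimage import gaussian_filter1d

    s = gaussian_filter1d(rng.normal(size=n), sigma, mode="wrap")
    s -= s.mean()
    sd = s.std()
    return s / sd if sd > 0 else s


# ---------------------------------------------------------------------------
# bead scene
# ---------------------------------------------------------------------------


def generate_bead_stack(params: BeadSceneParams) -> tuple[ImageStack, GroundTruth]:
    """Render a 3-channel (bead, actin, nucleus) pushing-force scene.

    Each bead's true Z-center follows ``baseline + amplitude * envelope(t)``
    where the envelope is a plateau with raised-cosine shoulders in the
    distance between the bead and the central-pool / nucleus / cell footprints
    of the passing cell.  The central pool and nucleus push with full weight;
    plain cytoplasm pushes with ``cytoplasm_push_fraction``.

    Returns the stack and a :class:`GroundTruth` holding exact bead-center Z
    series, per-frame contribution labels, centroid path and footprint masks.
    """
    params.validate()
    t_n, z_n, y_n, x_n = params.image_shape
    dz, dy, dx = params.voxel_size_um
    rng_geom, rng_bead, rng_actin, rng_nuc = _child_rngs(params.seed, 4)

    px = dx  # in-plane pixel size (isotropic)
    r_cell = params.cell_radius_um / px
    r_pool = params.central_pool_radius_um / px
    r_nuc = params.nucleus_radius_um / px
    shoulder = params.envelope_rolloff_um / px
    cyt_shoulder = params.cytoplasm_rolloff_um / px

    # --- cell path: enters from the left, moves along +x at constant speed
    step_px = params.cell_speed_um_per_s * params.frame_interval_s / px
    path_y = y_n / 2.0
    x0 = -r_cell
    centroids = np.stack(
        [np.full(t_n, path_y), x0 + step_px * np.arange(t_n)], axis=1
    )

    # --- beads on the path, inside the pool's traversal range and clear of
    # the image border by the widest analysis window (10 px half-width)
    margin = 12.0
    pool_x_end = centroids[-1, 1] + params.pool_offset_um / px
    lo, hi_x = margin, min(x_n - 1 - margin, pool_x_end - r_pool)
    if hi_x - lo < params.n_beads:
        raise ValueError(
            "scene too small/slow for the requested bead count: the pool "
            f"traverses only x in [{lo:.0f}, {hi_x:.0f}] px"
        )
    xs = np.linspace(lo, hi_x, params.n_beads)
    if params.n_beads > 1:
        jitter = (xs[1] - xs[0]) * 0.15
        xs = xs + rng_geom.uniform(-jitter, jitter, size=params.n_beads)
    # two staggered rows inside the pool's swath: beads stay under the pool's
    # plateau (full envelope guaranteed) but remain mutually resolvable
    stagger = min(0.55 * r_pool, y_n / 2.0 - margin)
    ys = path_y + stagger * np.where(np.arange(params.n_beads) % 2 == 0, 1.0, -1.0)
    bead_xy = np.stack([ys, xs], axis=1)

    # --- per-bead envelope and labels
    frames = np.arange(t_n)
    edge_z = np.empty((params.n_beads, t_n))
    labels: list[list[str]] = []
    for b in range(params.n_beads):
        yb, xb = bead_xy[b]
        d_cell = np.hypot(centroids[:, 0] - yb, centroids[:, 1] - xb)
        d_pool = np.hypot(
            centroids[:, 0] - yb, centroids[:, 1] + params.pool_offset_um / px - xb
        )
        d_nuc = np.hypot(
            centroids[:, 0] - yb, centroids[:, 1] + params.nucleus_offset_um / px - xb
        )
        w = np.maximum(
            _plateau_rolloff(d_pool, r_pool, shoulder),
            _plateau_rolloff(d_nuc, r_nuc, shoulder),
        )
        w = np.maximum(
            w,
            params.cytoplasm_push_fraction
            * _plateau_rolloff(d_cell, r_cell, cyt_shoulder),
        )
        edge_z[b] = params.bead_baseline_z_um + params.displacement_amplitude_um * w
        lab = []
        for t in frames:
            if d_nuc[t] <= r_nuc:
                lab.append("nucleus")
            elif d_pool[t] <= r_pool:
                lab.append("central_actin")
            elif d_cell[t] <= r_cell:
                lab.append("cytoplasm")
            else:
                lab.append("none")
        labels.append(lab)

    # --- footprint masks (2D, per frame)
    cell_masks = np.zeros((t_n, y_n, x_n), dtype=bool)
    pool_masks = np.zeros_like(cell_masks)
    nuc_masks = np.zeros_like(cell_masks)
    for t in range(t_n):
        cy, cx = centroids[t]
        cell_masks[t] = _disk_mask((y_n, x_n), (cy, cx), r_cell)
        pool_masks[t] = _disk_mask(
            (y_n, x_n), (cy, cx + params.pool_offset_um / px), r_pool
        )
        nuc_masks[t] = _disk_mask(
            (y_n, x_n), (cy, cx + params.nucleus_offset_um / px), r_nuc
        )
        pool_masks[t] &= cell_masks[t]
        nuc_masks[t] &= cell_masks[t]

    # --- render channels
    bg, cyt_lvl, pool_lvl, nuc_lvl = params.intensity_levels
    sigma_vox = (
        params.bead_sigma_um / dz,
        params.bead_sigma_um / dy,
        params.bead_sigma_um / dx,
    )
    if params.bead_drift_px_per_frame:
        drift_dir = rng_geom.normal(size=(params.n_beads, 2))
        drift_dir /= np.linalg.norm(drift_dir, axis=1, keepdims=True)

    bead_ch = np.zeros((t_n, z_n, y_n, x_n), dtype=np.float32)
    actin_ch = np.full_like(bead_ch, bg)
    nuc_ch = np.full_like(bead_ch, bg)
    z_cell_top = max(1, int(round(params.bead_baseline_z_um / dz / 2)))
    for t in range(t_n):
        for b in range(params.n_beads):
            yb, xb = bead_xy[b]
            if params.bead_drift_px_per_frame:
                yb += drift_dir[b, 0] * params.bead_drift_px_per_frame * t
                xb += drift_dir[b, 1] * params.bead_drift_px_per_frame * t
            _render_gaussian_spot(
                bead_ch[t],
                (edge_z[b, t] / dz, yb, xb),
                sigma_vox,
                params.bead_peak_intensity,
            )
        # the cell occupies the slices just above the coverslip
        actin_plane = np.full((y_n, x_n), bg, dtype=np.float32)
        actin_plane[cell_masks[t]] = cyt_lvl
        actin_plane[pool_masks[t]] = pool_lvl
        nuc_plane = np.full((y_n, x_n), bg, dtype=np.float32)
        nuc_plane[nuc_masks[t]] = nuc_lvl
        actin_ch[t, :z_cell_top] = actin_plane
        nuc_ch[t, :z_cell_top] = nuc_plane

    nm = params.noise_model
    data = np.stack(
        [
            nm.apply(bead_ch, rng_bead),
            nm.apply(actin_ch, rng_actin),
            nm.apply(nuc_ch, rng_nuc),
        ],
        axis=2,
    )
    stack = ImageStack(
        data=data,
        channel_names=("bead", "actin", "nucleus"),
        voxel_size_um=params.voxel_size_um,
        frame_interval_s=params.frame_interval_s,
    )
    truth = GroundTruth(
        edge_z_um=edge_z,
        labels=labels,
        bead_xy_px=bead_xy,
        cell_centroid_px=centroids,
        cell_masks=cell_masks,
        pool_masks=pool_masks,
        nucleus_masks=nuc_masks,
    )
    return stack, truth


# ---------------------------------------------------------------------------
# migration scene
# ---------------------------------------------------------------------------


def generate_coupled_series(
    n_frames: int,
    coupling_coefficient: float,
    coupling_lag_frames: int,
    seed: int,
    smooth_frames: float = 1.5,
) -> tuple[np.ndarray, np.ndarray]:
    """Latent (protrusion, pool) series with a planted coupling and lag.

    The pool series is ``coupling * protrusion`` delayed by
    ``coupling_lag_frames`` (circularly), plus an independent smooth residual
    scaled so both series have unit variance; at ``|coupling| = 1`` the
    relation is exact.  This is the construction behind
    :func:`generate_migration_movie`, exposed for cohort-level simulations
    that do not need rendered images.
    """
    if abs(coupling_coefficient) > 1:
        raise ValueError("|coupling_coefficient| must be <= 1")
    rng_lat, _ = _child_rngs(seed, 2)
    base = _smooth_series(n_frames, smooth_frames, rng_lat)
    indep = _smooth_series(n_frames, smooth_frames, rng_lat)
    pool = coupling_coefficient * np.roll(base, coupling_lag_frames)
    resid = math.sqrt(max(0.0, 1.0 - coupling_coefficient**2))
    return base, pool + resid * indep


def generate_migration_movie(
    params: MigrationSceneParams,
    coupling_coefficient: float = -0.8,
    coupling_lag_frames: int = 0,
    seed: int | None = None,
) -> tuple[ImageStack, GroundTruth]:
    """Render a 2-channel (actin, nucleus) movie of a migrating cell.

    The central-pool intensity series is constructed to correlate with the
    lamellipodial-band series at ``coupling_lag_frames`` with the sign and
    magnitude of ``coupling_coefficient``: with positive lag the pool follows
    the protrusion.  Both latent series are returned in the ground truth.
    """
    if abs(coupling_coefficient) > 1:
        raise ValueError("|coupling_coefficient| must be <= 1")
    t_n, y_n, x_n = params.image_shape
    if t_n < 4 * abs(coupling_lag_frames) + 10:
        raise ValueError(
            f"T={t_n} too short for lag {coupling_lag_frames}; need "
            f">= {4 * abs(coupling_lag_frames) + 10}"
        )
    if seed is None:
        seed = params.seed
    _, rng_noise = _child_rngs(seed, 2)

    # latent series: protrusion drives, pool follows at +lag with the given sign
    protrusion, pool = generate_coupled_series(
        t_n, coupling_coefficient, coupling_lag_frames, seed,
        params.latent_smooth_frames,
    )

    px = params.pixel_size_um
    r_cell = params.cell_radius_um / px
    r_pool = params.central_pool_radius_um / px
    r_nuc = params.nucleus_radius_um / px
    band = params.band_width_um / px
    step_px = params.cell_speed_um_per_s * params.frame_interval_s / px

    cy = y_n / 2.0
    cx0 = max(r_cell + band + 2, x_n / 2.0 - step_px * t_n / 2.0)
    centroids = np.stack([np.full(t_n, cy), cx0 + step_px * np.arange(t_n)], axis=1)
    if centroids[-1, 1] + r_cell + band + 2 > x_n:
        raise ValueError("cell leaves the field of view; enlarge X or slow the cell")

    bg, cyt_lvl, pool_lvl, nuc_lvl = params.intensity_levels
    actin = np.full((t_n, y_n, x_n), bg, dtype=np.float32)
    nucleus = np.full_like(actin, bg)
    cell_masks = np.zeros((t_n, y_n, x_n), dtype=bool)
    pool_masks = np.zeros_like(cell_masks)
    nuc_masks = np.zeros_like(cell_masks)
    yy, xx = np.mgrid[0:y_n, 0:x_n]
    depth = params.modulation_depth
    for t in range(t_n):
        ccy, ccx = centroids[t]
        d = np.hypot(yy - ccy, xx - ccx)
        body = d <= r_cell
        # lamellipodial band: annulus sector facing the direction of motion
        in_annulus = (d > r_cell) & (d <= r_cell + band)
        front = (xx - ccx) > 0.2 * d
        band_mask = in_annulus & front
        cell = body | band_mask
        pmask = _disk_mask((y_n, x_n), (ccy, ccx + params.pool_offset_um / px), r_pool)
        pmask &= body
        nmask = _disk_mask(
            (y_n, x_n), (ccy, ccx + params.nucleus_offset_um / px), r_nuc
        )
        nmask &= body
        frame = np.full((y_n, x_n), bg, dtype=np.float32)
        frame[cell] = cyt_lvl
        frame[band_mask] = cyt_lvl + (pool_lvl - cyt_lvl) * 0.6 * (
            1.0 + depth * protrusion[t]
        )
        frame[pmask] = cyt_lvl + (pool_lvl - cyt_lvl) * (1.0 + depth * pool[t])
        actin[t] = frame
        nucleus[t][nmask] = nuc_lvl
        cell_masks[t] = cell
        pool_masks[t] = pmask
        nuc_masks[t] = nmask

    nm = params.noise_model
    data = np.stack([nm.apply(actin, rng_noise), nm.apply(nucleus, rng_noise)], axis=1)
    data = data[:, None, :, :, :].astype(np.float32)
    stack = ImageStack(
        data=data,
        channel_names=("actin", "nucleus"),
        voxel_size_um=(1.0, px, px),
        frame_interval_s=params.frame_interval_s,
    )
    truth = GroundTruth(
        cell_centroid_px=centroids,
        cell_masks=cell_masks,
        pool_masks=pool_masks,
        nucleus_masks=nuc_masks,
        latent_pool=pool,
        latent_protrusion=protrusion,
        coupling_lag_frames=coupling_lag_frames,
        coupling_sign=int(np.sign(coupling_coefficient)),
    )
    return stack, truth


# ---------------------------------------------------------------------------
# constriction scene
# ---------------------------------------------------------------------------


def generate_constriction_movie(
    params: ConstrictionSceneParams,
    enrichment_factor: float = 3.0,
    seed: int | None = None,
) -> tuple[ImageStack, np.ndarray, GroundTruth]:
    """Render an (actin, brightfield) movie of a cell traversing a channel.

    The actin level inside the constriction interval is ``enrichment_factor``
    times the plateau outside it; outside the channel mask everything is
    background.  The cell traverses the full channel so the time-max profile
    covers every column.  Returns the stack, the true channel mask, and truth.
    """
    if enrichment_factor < 0:
        raise ValueError("enrichment_factor must be >= 0")
    t_n, y_n, x_n = params.image_shape
    x0, x1 = params.constriction_interval_px
    if not (0 <= x0 < x1 <= x_n):
        raise ValueError(f"constriction interval [{x0}, {x1}) outside image X={x_n}")
    if seed is None:
        seed = params.seed
    (rng,) = _child_rngs(seed, 1)

    ycen = y_n // 2
    hw, chw = params.channel_halfwidth_px, params.constriction_halfwidth_px
    cols = np.arange(x_n)
    halfwidths = np.where((cols >= x0) & (cols < x1), chw, hw)
    channel_mask = np.zeros((y_n, x_n), dtype=bool)
    for x in range(x_n):
        channel_mask[ycen - halfwidths[x] : ycen + halfwidths[x] + 1, x] = True

    # cell footprint: a segment of the channel, swept left to right so that
    # every column is covered at some frame
    travel = x_n + params.cell_length_px
    cx = -params.cell_length_px + travel * np.arange(t_n) / (t_n - 1)
    level = np.where(
        (cols >= x0) & (cols < x1),
        params.actin_level * enrichment_factor,
        params.actin_level,
    )

    actin = np.full((t_n, y_n, x_n), params.background_level, dtype=np.float32)
    for t in range(t_n):
        incell = (cols >= cx[t]) & (cols < cx[t] + params.cell_length_px)
        frame = np.full((y_n, x_n), params.background_level, dtype=np.float32)
        frame[:, incell] = level[incell]
        frame[~channel_mask] = params.background_level
        actin[t] = frame

    # brightfield: bright lumen on a dark substrate, constant in time
    bright = np.where(channel_mask, 200.0, 40.0).astype(np.float32)
    brightfield = np.broadcast_to(bright, (t_n, y_n, x_n)).copy()

    nm = params.noise_model
    data = np.stack([nm.apply(actin, rng), nm.apply(brightfield, rng)], axis=1)
    data = data[:, None, :, :, :].astype(np.float32)
    stack = ImageStack(
        data=data,
        channel_names=("actin", "brightfield"),
        voxel_size_um=(1.0, params.pixel_size_um, params.pixel_size_um),
        frame_interval_s=params.frame_interval_s,
    )
    truth = GroundTruth(
        enrichment_factor=float(enrichment_factor),
        channel_mask=channel_mask,
        constriction_interval_px=(x0, x1),
    )
    return stack, channel_mask, truth


# ---------------------------------------------------------------------------
# field pair
# ---------------------------------------------------------------------------


def generate_field_pair(
    n_maxima_a: int,
    n_maxima_b: int,
    offset_um: float,
    field_shape: tuple[int, int] = (128, 128),
    seed: int = 0,
    pixel_size_um: float = 0.5,
    peak_sigma_px: float = 3.0,
    min_separation_px: float = 18.0,
) -> tuple[np.ndarray, np.ndarray, GroundTruth]:
    """Two smooth 2D fields with planted, paired local maxima.

    Field A ("deformation") has ``n_maxima_a`` isolated Gaussian peaks; the
    first ``min(n_a, n_b)`` peaks of field B ("actin") sit ``offset_um`` away
    from their A partners in a random direction, extra B peaks are placed
    independently.  All peaks sit on the integer pixel grid and pair offsets
    are integer displacement vectors (norm within half a pixel of the nominal
    offset, exact when the nominal offset is an axis-aligned integer), so the
    recorded truth is exactly the argmax of the rendered field; realized pair
    distances are recorded in ``pair_distances_um``.  Peaks closer together
    than ``min_separation_px`` could confuse downstream neighborhood
    detection, so violations raise a warning flag in the ground truth rather
    than an error.
    """
    (rng,) = _child_rngs(seed, 1)
    h, w = field_shape
    margin = 4 * peak_sigma_px + offset_um / pixel_size_um + 2

    def _place(n: int, existing: list[np.ndarray]) -> list[np.ndarray]:
        pts: list[np.ndarray] = []
        attempts = 0
        while len(pts) < n:
            attempts += 1
            if attempts > 2000 * max(n, 1):
                raise ValueError("cannot place that many separated maxima")
            p = np.round(rng.uniform([margin, margin], [h - margin, w - margin]))
            if all(np.hypot(*(p - q)) >= min_separation_px for q in existing + pts):
                pts.append(p)
        return pts

    def _integer_offset(offset_px: float, theta: float) -> np.ndarray:
        """Integer vector with norm closest to ``offset_px``, near angle theta."""
        if offset_px == 0:
            return np.zeros(2)
        r = int(np.ceil(offset_px)) + 1
        best, best_key = None, None
        target = np.array([np.sin(theta), np.cos(theta)])
        for dy in range(-r, r + 1):
            for dx in range(-r, r + 1):
                v = np.array([dy, dx], dtype=float)
                nv = np.hypot(dy, dx)
                if nv == 0:
                    continue
                key = (abs(nv - offset_px), -float(v @ target) / nv)
                if best_key is None or key < best_key:
                    best, best_key = v, key
        return best

    pts_a = _place(n_maxima_a, [])
    n_paired = min(n_maxima_a, n_maxima_b)
    pts_b: list[np.ndarray] = []
    for i in range(n_paired):
        theta = rng.uniform(0, 2 * np.pi)
        pts_b.append(pts_a[i] + _integer_offset(offset_um / pixel_size_um, theta))
    pts_b += _place(n_maxima_b - n_paired, pts_b) if n_maxima_b > n_paired else []

    warnings: list[str] = []
    for name, pts in (("a", pts_a), ("b", pts_b)):
        for i in range(len(pts)):
            for j in range(i + 1, len(pts)):
                if np.hypot(*(pts[i] - pts[j])) < min_separation_px:
                    warnings.append(
                        f"maxima {i} and {j} in field {name} closer than the "
                        f"detection radius"
                    )

    yy, xx = np.mgrid[0:h, 0:w]

    def _field(pts: list[np.ndarray]) -> np.ndarray:
        f = np.zeros((h, w))
        for i, (py, px_) in enumerate(pts):
            amp = 1.0 + 0.05 * i  # distinct amplitudes avoid exact ties
            f += amp * np.exp(
                -((yy - py) ** 2 + (xx - px_) ** 2) / (2 * peak_sigma_px**2)
            )
        return f

    pair_d = np.array(
        [np.hypot(*(pts_a[i] - pts_b[i])) for i in range(n_paired)]
    ) * pixel_size_um
    truth = GroundTruth(
        maxima_a_px=np.array(pts_a).reshape(-1, 2),
        maxima_b_px=np.array(pts_b).reshape(-1, 2),
        pair_distances_um=pair_d,
        offset_um=float(offset_um),
        pixel_size_um=float(pixel_size_um),
        warnings=warnings,
    )
    return _field(pts_a), _field(pts_b), truth
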