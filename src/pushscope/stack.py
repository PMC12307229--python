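"""Canonical in-memory representation of a multichannel time-lapse stack.

All raster data in this package flows through :class:`ImageStack`, a thin
wrapper over a ``T x Z x C x Y x X`` float array with physical calibrations
attached.  2D time-lapse movies are represented with a singleton Z axis so
every downstream operation can assume the same five axes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: canonical axis order on disk and in memory
AXES = "TZCYX"


@dataclass
class ImageStack:
    """A multichannel, optionally Z-resolved time-lapse.

    Parameters
    ----------
    data
        Array of shape ``(T, Z, C, Y, X)``; float32 preferred.
    channel_names
        One name per channel, e.g. ``("bead", "actin", "nucleus")``.
    voxel_size_um
        Physical voxel size ``(z, y, x)`` in micrometers.
    frame_interval_s
        Time between consecutive frames, in seconds.
    """

    data: np.ndarray
    channel_names: tuple[str, ...]
    voxel_size_um: tuple[float, float, float]
    frame_interval_s: float
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 5:
            raise ValueError(
                f"ImageStack data must be 5D (T, Z, C, Y, X); got {self.data.ndim}D"
            )
        if len(self.channel_names) != self.data.shape[2]:
            raise ValueError(
                f"{len(self.channel_names)} channel names for "
                f"{self.data.shape[2]} channels"
            )
        if any(v <= 0 for v in self.voxel_size_um) or self.frame_interval_s <= 0:
            raise ValueError("physical calibrations must be positive")

    # -- convenience accessors -------------------------------------------------

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def n_z(self) -> int:
        return self.data.shape[1]

    @property
    def shape_yx(self) -> tuple[int, int]:
        return self.data.shape[3], self.data.shape[4]

    @property
    def pixel_size_um(self) -> float:
        """In-plane pixel size; Y and X are assumed isotropic."""
        return float(self.voxel_size_um[2])

    @property
    def z_step_um(self) -> float:
        return float(self.voxel_size_um[0])

    def channel(self, name: str) -> np.ndarray:
        """Return one channel as a ``(T, Z, Y, X)`` view."""
        try:
            idx = self.channel_names.index(name)
        except ValueError:
            raise KeyError(
                f"no channel {name!r}; have {self.channel_names}"
            ) from None
        return self.data[:, :, idx]

    def channel_2d(self, name: str) -> np.ndarray:
        """Return one channel as ``(T, Y, X)``, max-projecting Z if present."""
        ch = self.channel(name)
        return ch[:, 0] if ch.shape[1] == 1 else ch.max(axis=1)
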