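"""Reading and writing stacks, ground truth and run configuration.

On-disk raster format is OME-TIFF with TZCYX axes; ground truth travels in a
JSON sidecar next to the stack.  Configuration is one YAML file that maps
channel roles to indices and carries the physical calibrations plus
per-module parameter blocks; it is echoed into the output directory so every
run is reproducible from its own artifacts.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile
import yaml

from .stack import AXES, ImageStack
from .synth import GroundTruth


@dataclass
class RunConfig:
    """Everything one pipeline run needs, resolvable from a YAML file."""

    input_path: str = ""
    axis_spec: str | None = None  # e.g. "TZCYX" or "TCYX"; None = from metadata
    channels: dict[str, int] = field(default_factory=dict)  # role -> index
    pixel_size_um: float = 0.325
    z_step_um: float = 0.1
    frame_interval_s: float = 30.0
    seed: int = 0
    out_dir: str = "pushscope_out"
    params: dict = field(default_factory=dict)  # per-module parameter blocks

    def validate(self, n_channels: int | None = None) -> None:
        if self.pixel_size_um <= 0 or self.z_step_um <= 0 or self.frame_interval_s <= 0:
            raise ValueError("calibrations must be positive")
        if n_channels is not None:
            bad = {k: v for k, v in self.channels.items() if not 0 <= v < n_channels}
            if bad:
                raise ValueError(
                    f"channel indices {bad} out of range for {n_channels} channels"
                )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def echo(self, out_dir: str | Path) -> Path:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        dest = out / "config_used.yaml"
        with open(dest, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=False)
        return dest


# ---------------------------------------------------------------------------


def write_stack(path: str | Path, stack: ImageStack) -> None:
    """Write an :class:`ImageStack` as OME-TIFF with TZCYX axes."""
    pz, py, px = stack.voxel_size_um
    tifffile.imwrite(
        str(path),
        stack.data.astype(np.float32),
        ome=True,
        metadata={
            "axes": AXES,
            "PhysicalSizeZ": pz,
            "PhysicalSizeY": py,
            "PhysicalSizeX": px,
            "TimeIncrement": stack.frame_interval_s,
            "Channel": {"Name": list(stack.channel_names)},
        },
    )


def read_stack(
    path: str | Path,
    axis_spec: str | None = None,
    channel_names: tuple[str, ...] | None = None,
    voxel_size_um: tuple[float, float, float] = (1.0, 1.0, 1.0),
    frame_interval_s: float = 30.0,
) -> ImageStack:
    """Read a TIFF stack into canonical T, Z, C, Y, X order.

    Axes are taken from the file's OME/series metadata or, failing that, from
    ``axis_spec``.  Missing T, Z or C axes become singletons; an axis that is
    neither present nor inferable is an explicit error naming it.  Physical
    calibrations are read from OME metadata when available, otherwise from
    the arguments.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with tifffile.TiffFile(str(path)) as tf:
        series = tf.series[0]
        data = series.asarray()
        axes = axis_spec or series.axes
        if tf.ome_metadata:
            import xml.etree.ElementTree as ET

            root = ET.fromstring(tf.ome_metadata)
            ns = {"ome": root.tag.split("}")[0].strip("{")}
            px_el = root.find(".//ome:Pixels", ns)
            if px_el is not None:
                voxel_size_um = (
                    float(px_el.get("PhysicalSizeZ", voxel_size_um[0])),
                    float(px_el.get("PhysicalSizeY", voxel_size_um[1])),
                    float(px_el.get("PhysicalSizeX", voxel_size_um[2])),
                )
                frame_interval_s = float(
                    px_el.get("TimeIncrement", frame_interval_s)
                )
                if channel_names is None:
                    names = [
                        ch.get("Name") or f"ch{i}"
                        for i, ch in enumerate(root.findall(".//ome:Channel", ns))
                    ]
                    if names:
                        channel_names = tuple(names)
    axes = axes.upper().replace("S", "C").replace("Q", "")
    if len(axes) != data.ndim:
        raise ValueError(
            f"axis spec {axes!r} does not match data with {data.ndim} dimensions"
        )
    for needed in "YX":
        if needed not in axes:
            raise ValueError(f"cannot resolve the {needed} axis of {path.name}")
    for missing in (ax for ax in "TZC" if ax not in axes):
        data = data[np.newaxis]
        axes = missing + axes
    order = [axes.index(ax) for ax in AXES]
    data = np.transpose(data, order)
    if channel_names is None:
        channel_names = tuple(f"ch{i}" for i in range(data.shape[2]))
    if len(channel_names) != data.shape[2]:
        raise ValueError(
            f"{len(channel_names)} channel names for {data.shape[2]} channels"
        )
    return ImageStack(
        data=data.astype(np.float32),
        channel_names=tuple(channel_names),
        voxel_size_um=voxel_size_um,
        frame_interval_s=frame_interval_s,
    )


def write_ground_truth(path: str | Path, truth: GroundTruth) -> None:
    with open(path, "w") as fh:
        json.dump(truth.to_jsonable(), fh)


def read_ground_truth(path: str | Path) -> GroundTruth:
    with open(path) as fh:
        raw = json.load(fh)
    kwargs = {}
    for f in dataclasses.fields(GroundTruth):
        if f.name not in raw:
            continue
        v = raw[f.name]
        if f.name in ("labels", "warnings", "constriction_interval_px"):
            kwargs[f.name] = tuple(v) if f.name == "constriction_interval_px" else v
        elif isinstance(v, list):
            arr = np.asarray(v)
            if f.name in ("cell_masks", "pool_masks", "nucleus_masks",
                          "channel_mask"):
                arr = arr.astype(bool)
            kwargs[f.name] = arr
        else:
            kwargs[f.name] = v
    return GroundTruth(**kwargs)
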