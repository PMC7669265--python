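"""Image-stack I/O with physical voxel spacing, plus pipeline configuration.

Conventions used throughout the package (stated once, here):

* Arrays are indexed ``(Z, Y, X)``; ``spacing`` is ``(dz, dy, dx)`` in µm.
* Coordinate *triples* held in ndarrays follow the same ``(z, y, x)`` order.
  Tabular outputs spell coordinates out as explicit ``x_um`` / ``y_um`` /
  ``z_um`` columns.
* Voxel indices are 0-based; the physical position of a voxel is its centre,
  ``index * spacing``.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from xml.etree import ElementTree

import numpy as np
import tifffile
import yaml

from .errors import ConfigurationError

__all__ = [
    "VolumeStack",
    "PipelineConfig",
    "read_stack",
    "write_stack",
    "load_config",
    "write_table",
    "write_json",
]


@dataclass
class VolumeStack:
    """A 3D scalar intensity grid with per-axis physical spacing.

    Parameters
    ----------
    data
        3D array in (Z, Y, X) order, non-negative intensities.
    spacing
        (dz, dy, dx) voxel spacing in µm, each strictly positive.
    channel_name
        Free-text label, e.g. ``"EdU"`` or ``"AHA"``.
    axis_aligned
        True once the proximodistal axis coincides with the X grid axis.
    """

    data: np.ndarray
    spacing: tuple[float, float, float]
    channel_name: str = ""
    axis_aligned: bool = False

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"data must be 3D (Z, Y, X); got ndim={self.data.ndim}")
        if any(s < 1 for s in self.data.shape):
            raise ValueError(f"every dimension must be >= 1; got shape={self.data.shape}")
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or not all(np.isfinite(s) and s > 0 for s in self.spacing):
            raise ValueError(f"spacing must be three positive finite values; got {self.spacing}")
        if self.data.size and float(self.data.min()) < 0:
            raise ValueError("intensity values must be non-negative")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def voxel_volume_um3(self) -> float:
        return float(np.prod(self.spacing))

    def physical_extent_um(self) -> np.ndarray:
        """Physical size of the grid per axis (distance between extreme voxel centres)."""
        return (np.array(self.shape) - 1) * np.array(self.spacing)


def read_stack(path, channel: int | None = None, spacing=None, channel_name: str = "") -> VolumeStack:
    """Read a TIFF / OME-TIFF stack into a :class:`VolumeStack`.

    Spacing is taken from OME ``PhysicalSize*`` metadata when present;
    otherwise the explicit ``spacing`` override is required.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such image file: {path}")
    with tifffile.TiffFile(str(path)) as tf:
        series = tf.series[0]
        data = series.asarray()
        axes = series.axes
        meta_spacing = _ome_spacing(tf)

    # Collapse singleton leading axes that are not Z/Y/X/C (e.g. T, S).
    while data.ndim > 3 and "C" not in axes:
        if data.shape[0] != 1:
            raise ValueError(f"cannot interpret axes {axes!r} with shape {data.shape}")
        data = data[0]
        axes = axes[1:]
    if "C" in axes:
        c_ax = axes.index("C")
        n_ch = data.shape[c_ax]
        if channel is None:
            if n_ch == 1:
                channel = 0
            else:
                raise ValueError(f"multi-channel image ({n_ch} channels): pass channel=")
        if not 0 <= channel < n_ch:
            raise ValueError(f"channel {channel} out of range for {n_ch}-channel image")
        data = np.take(data, channel, axis=c_ax)
    if data.ndim == 2:
        data = data[np.newaxis]
    if data.ndim != 3:
        raise ValueError(f"cannot reduce image of axes {axes!r} to a 3D stack")

    if spacing is None:
        spacing = meta_spacing
    if spacing is None:
        raise ConfigurationError(
            f"{path} carries no PhysicalSizeZ/Y/X metadata; pass spacing=(dz, dy, dx) explicitly"
        )
    return VolumeStack(data=data, spacing=tuple(spacing), channel_name=channel_name)


def _ome_spacing(tf: tifffile.TiffFile) -> tuple[float, float, float] | None:
    if not tf.ome_metadata:
        return None
    try:
        root = ElementTree.fromstring(tf.ome_metadata)
    except ElementTree.ParseError:
        return None
    for el in root.iter():
        if el.tag.endswith("Pixels"):
            try:
                return (
                    float(el.attrib["PhysicalSizeZ"]),
                    float(el.attrib["PhysicalSizeY"]),
                    float(el.attrib["PhysicalSizeX"]),
                )
            except KeyError:
                return None
    return None


def write_stack(stack: VolumeStack, path) -> None:
    """Write a stack as OME-TIFF, embedding voxel spacing so a round-trip is lossless."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    dz, dy, dx = stack.spacing
    tifffile.imwrite(
        str(path),
        stack.data,
        ome=True,
        metadata={
            "axes": "ZYX",
            "PhysicalSizeZ": dz,
            "PhysicalSizeZUnit": "µm",
            "PhysicalSizeY": dy,
            "PhysicalSizeYUnit": "µm",
            "PhysicalSizeX": dx,
            "PhysicalSizeXUnit": "µm",
        },
    )


@dataclass
class PipelineConfig:
    """All tunable pipeline parameters with their defaults.

    The three geometry parameters mirror the published protocol: cells are
    profiled in 50 µm slabs along the proximodistal axis, and the paired-limb
    comparison uses a 175 µm cube whose distal face sits 250 µm from the
    distal tip.
    """

    # slab / cube geometry (µm)
    cell_slab_thickness_um: float = 50.0
    cube_side_um: float = 175.0
    cube_offset_um: float = 250.0

    # organ segmentation
    organ_smooth_sigma_um: float = 2.0
    organ_threshold: float | str = "otsu"
    organ_closing_radius_um: float = 4.0

    # cell enhancement & segmentation
    background_method: str = "gaussian"  # "gaussian" high-pass or "tophat"
    background_radius_um: float = 15.0
    blur_sigma_um: float = 2.0
    cell_threshold: float | str = "otsu"
    min_cell_volume_um3: float = 30.0
    max_cell_volume_um3: float = 1.0e5
    watershed_split: bool = True
    seed_min_separation_um: float = 4.0

    # histograms
    histogram_bins: int = 256

    # alignment
    distal_polarity: str = "positive_x"  # or "negative_x"
    align_padding_um: float = 0.0

    rng_seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "cell_slab_thickness_um",
            "cube_side_um",
            "organ_smooth_sigma_um",
            "organ_closing_radius_um",
            "background_radius_um",
            "blur_sigma_um",
            "seed_min_separation_um",
        ):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be > 0")
        if self.cube_offset_um < 0:
            raise ConfigurationError("cube_offset_um must be >= 0")
        if self.distal_polarity not in ("positive_x", "negative_x"):
            raise ConfigurationError("distal_polarity must be 'positive_x' or 'negative_x'")
        if self.background_method not in ("gaussian", "tophat"):
            raise ConfigurationError("background_method must be 'gaussian' or 'tophat'")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def load_config(path=None, **overrides) -> PipelineConfig:
    """Load a YAML configuration file, falling back to defaults for missing keys.

    Unknown keys raise :class:`ConfigurationError` so that typos (e.g.
    ``cube_side`` for ``cube_side_um``) do not silently fall back to defaults.
    """
    values: dict = {}
    if path is not None:
        path = Path(path)
        try:
            with open(path) as fh:
                loaded = yaml.safe_load(fh)
        except yaml.YAMLError as exc:
            raise ConfigurationError(f"malformed config {path}: {exc}") from exc
        if loaded is None:
            loaded = {}
        if not isinstance(loaded, dict):
            raise ConfigurationError(f"config {path} must be a mapping of key: value")
        values.update(loaded)
    values.update(overrides)

    known = {f.name for f in dataclasses.fields(PipelineConfig)}
    unknown = sorted(set(values) - known)
    if unknown:
        raise ConfigurationError(f"unknown configuration key(s): {', '.join(unknown)}")
    return PipelineConfig(**values)


def write_table(df, path) -> Path:
    """Write a DataFrame as CSV, creating parent directories."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)
    return path


def write_json(obj, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, default=_json_default)
    return path


def _json_default(o):
    if isinstance(o, np.ndarray):
        return o.tolist()
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    raise TypeError(f"not JSON serializable: {type(o)}")
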