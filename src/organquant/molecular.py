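"""Molecular-level quantification: intensity profiles, the distal-tip cube
ROI, and the paired innervated/denervated comparison.

All statistics are computed over raw intensities; voxels outside the organ
mask are excluded by mask membership (not by being zero), so genuinely dark
in-mask voxels still count.  Histogram bin edges are shared across slices
(and between paired cubes) so histograms can be compared and summed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import AlignmentStateError, GeometryError
from .io import VolumeStack
from .morphology import OrganMask

__all__ = [
    "IntensityProfile",
    "CubeROI",
    "PairComparison",
    "intensity_profile",
    "find_distal_tip",
    "extract_cube",
    "compare_pair",
]


def _default_bin_edges(data: np.ndarray, bins: int) -> np.ndarray:
    """Shared histogram edges: the full dtype range for integer data."""
    if np.issubdtype(data.dtype, np.integer):
        top = float(np.iinfo(data.dtype).max) + 1.0
    else:
        top = float(data.max()) if data.size and data.max() > 0 else 1.0
    return np.linspace(0.0, top, bins + 1)


@dataclass
class IntensityProfile:
    """Per-cross-section intensity statistics of a masked, aligned channel."""

    x_um: np.ndarray
    mean: np.ndarray  # NaN for slices with no in-mask voxels
    voxel_count: np.ndarray
    bin_edges: np.ndarray
    slice_histograms: np.ndarray  # (n_slices, n_bins)

    @property
    def organ_histogram(self) -> np.ndarray:
        return self.slice_histograms.sum(axis=0)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"x_um": self.x_um, "mean_intensity": self.mean, "voxel_count": self.voxel_count}
        )


def intensity_profile(masked: VolumeStack, mask: OrganMask, bins: int = 256) -> IntensityProfile:
    """Slice-by-slice mean intensity and histograms over in-mask voxels."""
    if not masked.axis_aligned:
        raise AlignmentStateError("intensity_profile requires an axis-aligned stack")
    if masked.shape != mask.data.shape:
        raise ValueError("stack and mask must share a grid")
    if not mask.data.any():
        raise ValueError("mask has no foreground voxels")
    edges = _default_bin_edges(masked.data, bins)
    dx = masked.spacing[2]
    nx = masked.shape[2]
    means = np.full(nx, np.nan)
    counts = np.zeros(nx, dtype=np.int64)
    hists = np.zeros((nx, bins), dtype=np.int64)
    for k in range(nx):
        vals = masked.data[:, :, k][mask.data[:, :, k]]
        counts[k] = vals.size
        if vals.size:
            means[k] = float(vals.mean())
            hists[k] = np.histogram(vals, bins=edges)[0]
    return IntensityProfile(
        x_um=np.arange(nx) * dx,
        mean=means,
        voxel_count=counts,
        bin_edges=edges,
        slice_histograms=hists,
    )


def find_distal_tip(mask: OrganMask, polarity: str = "positive_x") -> np.ndarray:
    """Distal tip of an aligned mask, (z, y, x) µm.

    The tip X is the extreme foreground X in the distal direction; the tip
    (z, y) is the foreground centroid of the most-distal slab spanning 10%
    of the foreground length, which approximates where the organ axis
    pierces the tip.
    """
    if not mask.axis_aligned:
        raise AlignmentStateError("find_distal_tip requires an axis-aligned mask")
    if polarity not in ("positive_x", "negative_x"):
        raise ValueError("polarity must be 'positive_x' or 'negative_x'")
    coords = np.argwhere(mask.data)
    if coords.size == 0:
        raise ValueError("empty mask")
    spacing = np.asarray(mask.spacing, float)
    xs = coords[:, 2] * spacing[2]
    x_lo, x_hi = xs.min(), xs.max()
    length = max(x_hi - x_lo, spacing[2])
    if polarity == "positive_x":
        tip_x = x_hi
        in_slab = xs >= x_hi - 0.1 * length
    else:
        tip_x = x_lo
        in_slab = xs <= x_lo + 0.1 * length
    zy = coords[in_slab, :2] * spacing[:2]
    tip_z, tip_y = zy.mean(axis=0)
    return np.array([tip_z, tip_y, tip_x])


@dataclass
class CubeROI:
    """An axis-aligned cubic subvolume with its placement provenance."""

    data: np.ndarray
    spacing: tuple[float, float, float]
    side_um: float  # requested side
    offset_um: float  # requested tip-to-distal-face gap
    tip_um: np.ndarray
    center_um: np.ndarray  # (z, y, x) of the achieved cube centre
    index_bounds: tuple  # ((z0, z1), (y0, y1), (x0, x1)), half-open
    achieved_side_um: np.ndarray  # per axis, from the voxelized bounds
    bin_edges: np.ndarray = field(repr=False, default=None)
    histogram: np.ndarray = field(repr=False, default=None)

    @property
    def mean(self) -> float:
        return float(self.data.mean())

    @property
    def median(self) -> float:
        return float(np.median(self.data))

    @property
    def sd(self) -> float:
        return float(self.data.std())

    def provenance(self) -> dict:
        return {
            "side_um": self.side_um,
            "offset_um": self.offset_um,
            "tip_um": self.tip_um.tolist(),
            "center_um": self.center_um.tolist(),
            "index_bounds": [list(b) for b in self.index_bounds],
            "achieved_side_um": self.achieved_side_um.tolist(),
        }


def extract_cube(
    stack: VolumeStack,
    tip_um: np.ndarray,
    side_um: float = 175.0,
    offset_um: float = 250.0,
    polarity: str = "positive_x",
    bins: int = 256,
) -> CubeROI:
    """Cut the quantification cube proximal to the distal tip.

    The cube's distal face sits ``offset_um`` from the tip along the P-D
    axis (so it spans ``[tip - offset - side, tip - offset]`` in X for
    distal-at-positive-X) and is centred on the tip's (y, z) — the axis
    position — laterally.  Voxel bounds are the rounded physical bounds,
    trimmed to the closest achievable size; the achieved extents are
    recorded in the provenance.
    """
    if not stack.axis_aligned:
        raise AlignmentStateError("extract_cube requires an axis-aligned stack")
    tip = np.asarray(tip_um, float)
    if polarity == "positive_x":
        x_hi = tip[2] - offset_um
        x_lo = x_hi - side_um
    else:
        x_lo = tip[2] + offset_um
        x_hi = x_lo + side_um
    z_lo, z_hi = tip[0] - side_um / 2, tip[0] + side_um / 2
    y_lo, y_hi = tip[1] - side_um / 2, tip[1] + side_um / 2

    spacing = np.asarray(stack.spacing, float)
    lows = np.array([z_lo, y_lo, x_lo])
    bounds = []
    overhang = []
    for ax in range(3):
        n = max(1, int(round(side_um / spacing[ax])))
        i0 = int(round(lows[ax] / spacing[ax]))
        i1 = i0 + n
        bounds.append((i0, i1))
        over_lo = max(0.0, -i0 * spacing[ax])
        over_hi = max(0.0, (i1 - stack.shape[ax]) * spacing[ax])
        overhang.append(max(over_lo, over_hi))
    if any(o > 0 for o in overhang):
        raise GeometryError(
            "cube does not fit inside the stack; overhang (z, y, x) = "
            f"({overhang[0]:.1f}, {overhang[1]:.1f}, {overhang[2]:.1f}) µm"
        )
    (z0, z1), (y0, y1), (x0, x1) = bounds
    sub = stack.data[z0:z1, y0:y1, x0:x1]
    edges = _default_bin_edges(stack.data, bins)
    hist = np.histogram(sub, bins=edges)[0]
    center = np.array(
        [(b[0] + b[1] - 1) / 2 * s for b, s in zip(bounds, spacing)]
    )
    achieved = np.array([(b[1] - b[0]) * s for b, s in zip(bounds, spacing)])
    return CubeROI(
        data=sub,
        spacing=stack.spacing,
        side_um=side_um,
        offset_um=offset_um,
        tip_um=tip,
        center_um=center,
        index_bounds=tuple(bounds),
        achieved_side_um=achieved,
        bin_edges=edges,
        histogram=hist,
    )


@dataclass
class PairComparison:
    """Innervated vs denervated cube comparison of one animal."""

    innervated: CubeROI
    denervated: CubeROI
    ratio: float  # mean(denervated) / mean(innervated)

    def summary(self) -> pd.DataFrame:
        rows = []
        for limb, cube in (("innervated", self.innervated), ("denervated", self.denervated)):
            rows.append(
                {
                    "limb": limb,
                    "mean": cube.mean,
                    "median": cube.median,
                    "sd": cube.sd,
                    "voxel_count": cube.data.size,
                }
            )
        return pd.DataFrame(rows)

    def to_long_dataframe(self) -> pd.DataFrame:
        """Violin-plot-ready long format: one row per voxel, (limb, intensity)."""
        return pd.DataFrame(
            {
                "limb": np.repeat(
                    ["innervated", "denervated"],
                    [self.innervated.data.size, self.denervated.data.size],
                ),
                "intensity": np.concatenate(
                    [self.innervated.data.ravel(), self.denervated.data.ravel()]
                ),
            }
        )

    def plot_violin(self, ax=None):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(4, 4))
        data = [self.innervated.data.ravel(), self.denervated.data.ravel()]
        ax.violinplot(data, showmeans=True)
        ax.set_xticks([1, 2], ["innervated", "denervated"])
        ax.set_ylabel("pixel intensity")
        return ax


def compare_pair(innervated: CubeROI, denervated: CubeROI) -> PairComparison:
    """Mean-intensity ratio (denervated/innervated) of two matched cubes."""
    if abs(innervated.side_um - denervated.side_um) > 1e-9:
        raise ValueError("cubes must have the same side length")
    if innervated.mean == 0:
        raise ValueError("innervated cube mean is zero; ratio undefined")
    return PairComparison(
        innervated=innervated,
        denervated=denervated,
        ratio=denervated.mean / innervated.mean,
    )
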