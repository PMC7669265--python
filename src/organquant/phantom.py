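"""Synthetic light-sheet phantoms with exact ground truth.

The phantom emulates the two channels of a cleared regenerating limb imaged
by light-sheet microscopy:

* an **organ channel**: a tapered elliptical cylinder whose surface shell is
  bright (nascent-protein staining outlines the cartilage surface) over a
  dimmer interior and noisy background;
* a **cell channel**: isotropic Gaussian nuclei (proliferating, EdU-like
  cells) seeded inside the organ at a configurable count or density.

The organ axis may be tilted by arbitrary rotations about Y and Z to emulate
an arbitrarily mounted specimen.  Rather than rotating a pre-rendered volume
and resampling, the analytic organ model is evaluated directly at the
rotated voxel coordinates (and blob centres are rotated; the blobs are
isotropic in physical space), so the misaligned volume is exact and carries
no interpolation blur.  Ground truth (axis, tip, per-cell positions, the
noise-free intensity fields) is recorded before noise and quantization.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .errors import GeometryError
from .geometry import X_AXIS, rotation_about_yz
from .io import VolumeStack

__all__ = [
    "PhantomSpec",
    "TrueCell",
    "GroundTruth",
    "generate_phantom",
    "generate_limb_pair",
    "detection_scenario_spec",
    "density_scenario_spec",
    "limb_pair_scenario_spec",
]


@dataclass
class PhantomSpec:
    """Full description of a synthetic specimen.

    Lengths in µm, intensities in arbitrary camera units.  The organ is a
    tapered elliptical cylinder of length ``length_um`` centred in the grid;
    semi-axes interpolate linearly from the proximal pair ``(a0, b0)`` to the
    distal pair ``(a1, b1)`` (a along Y, b along Z).  ``rotation_*_deg`` tilt
    the proximodistal axis away from +X.
    """

    shape: tuple[int, int, int] = (96, 260, 400)  # (Z, Y, X) voxels
    spacing: tuple[float, float, float] = (2.0, 1.0, 1.0)  # (dz, dy, dx) µm

    # organ model
    length_um: float = 320.0
    proximal_semi_axes_um: tuple[float, float] = (48.0, 40.0)
    distal_semi_axes_um: tuple[float, float] = (34.0, 28.0)
    shell_thickness_um: float = 6.0
    shell_intensity: float = 200.0
    interior_intensity: float = 40.0
    distal_cap: bool = False  # round the distal end with an ellipsoidal cap

    # cell model
    n_cells: int = 60
    cell_density_per_mm3: float | None = None  # overrides n_cells when set
    cell_radius_um: float = 6.0
    cell_radius_sd_um: float = 0.5
    cell_peak_intensity: float = 150.0
    cell_peak_sd: float = 15.0
    min_cell_separation_um: float = 15.0
    doublet_pairs: int = 0  # deliberately touching pairs (for split testing)
    doublet_separation_radii: float = 1.5  # centre distance in units of cell radius

    # misalignment
    rotation_y_deg: float = 0.0
    rotation_z_deg: float = 0.0

    # sensor model
    background: float = 20.0
    noise_sd: float = 0.0  # Gaussian read noise, intensity units
    shot_noise: bool = False  # Poisson noise with the noise-free mean
    dtype: type = np.uint16

    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.length_um <= 0:
            raise ValueError("length_um must be > 0")
        for pair in (self.proximal_semi_axes_um, self.distal_semi_axes_um):
            if any(s <= 0 for s in pair):
                raise ValueError("all semi-axes must be > 0")
        if self.n_cells < 0:
            raise ValueError("n_cells must be >= 0")
        if self.cell_density_per_mm3 is not None and self.cell_density_per_mm3 < 0:
            raise ValueError("cell_density_per_mm3 must be >= 0")
        for ang in (self.rotation_y_deg, self.rotation_z_deg):
            if not -90.0 < ang < 90.0:
                raise ValueError("rotation angles must lie in (-90°, 90°)")

    # ---- analytic organ geometry -------------------------------------------------

    def semi_axes_at(self, t: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Semi-axes (a, b) at normalized axial position t in [0, 1] (0 = proximal)."""
        a0, b0 = self.proximal_semi_axes_um
        a1, b1 = self.distal_semi_axes_um
        t = np.asarray(t, float)
        return a0 + (a1 - a0) * t, b0 + (b1 - b0) * t

    def analytic_volume_um3(self) -> float:
        """Exact volume of the tapered elliptical cylinder (cap excluded)."""
        a0, b0 = self.proximal_semi_axes_um
        a1, b1 = self.distal_semi_axes_um
        da, db = a1 - a0, b1 - b0
        core = np.pi * self.length_um * (a0 * b0 + (a0 * db + b0 * da) / 2.0 + da * db / 3.0)
        if self.distal_cap:
            core += 2.0 / 3.0 * np.pi * a1 * b1 * min(a1, b1)
        return float(core)

    @property
    def grid_center_um(self) -> np.ndarray:
        """Physical centre of the grid, (z, y, x) µm."""
        return (np.array(self.shape) - 1) * np.array(self.spacing) / 2.0

    @property
    def rotation(self) -> np.ndarray:
        return rotation_about_yz(self.rotation_y_deg, self.rotation_z_deg)


@dataclass
class TrueCell:
    centroid_um: np.ndarray  # (z, y, x), lab frame
    radius_um: float
    peak_intensity: float


@dataclass
class GroundTruth:
    """Everything the generator knows exactly, recorded pre-noise."""

    axis_direction: np.ndarray  # unit (z, y, x), proximal -> distal
    axis_point_um: np.ndarray  # a point on the axis (the organ centre)
    tip_um: np.ndarray  # distal tip, lab frame (z, y, x) µm
    cells: list[TrueCell]
    spec: PhantomSpec
    organ_noise_free: np.ndarray  # float64, lab grid
    cell_noise_free: np.ndarray
    intensity_ratio: float | None = None  # set by generate_limb_pair

    def cell_centroids_um(self) -> np.ndarray:
        if not self.cells:
            return np.empty((0, 3))
        return np.array([c.centroid_um for c in self.cells])


# ---------------------------------------------------------------------------------


def _organ_frame_coords(spec: PhantomSpec) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Organ-frame coordinates (u along axis, v along a/Y, w along b/Z) per voxel."""
    nz, ny, nx = spec.shape
    dz, dy, dx = spec.spacing
    z = np.arange(nz) * dz
    y = np.arange(ny) * dy
    x = np.arange(nx) * dx
    zz, yy, xx = np.meshgrid(z, y, x, indexing="ij")
    c = spec.grid_center_um
    p = np.stack([zz - c[0], yy - c[1], xx - c[2]])  # (3, Z, Y, X), zyx components
    rt = spec.rotation.T  # lab -> organ frame
    q = np.einsum("ij,jzyx->izyx", rt, p)
    # organ frame: u = along-axis (x comp), v = Y (a), w = Z (b)
    return q[2], q[1], q[0]


def _render_organ(spec: PhantomSpec) -> np.ndarray:
    u, v, w = _organ_frame_coords(spec)
    half = spec.length_um / 2.0
    t = (u + half) / spec.length_um
    a, b = spec.semi_axes_at(np.clip(t, 0.0, 1.0))
    rho = np.sqrt((v / a) ** 2 + (w / b) ** 2)
    inside_body = (t >= 0.0) & (t <= 1.0) & (rho <= 1.0)
    inside = inside_body
    cap_surface = np.zeros(u.shape, bool)
    if spec.distal_cap:
        a1, b1 = spec.distal_semi_axes_um
        c1 = min(a1, b1)
        s = (u - half) / c1
        rho_cap = np.sqrt((v / a1) ** 2 + (w / b1) ** 2 + np.clip(s, 0, None) ** 2)
        in_cap = (s > 0) & (s <= 1.0) & (rho_cap <= 1.0)
        inside = inside_body | in_cap
        cap_surface = in_cap & ((1.0 - rho_cap) * c1 <= spec.shell_thickness_um)

    # approximate distance to the lateral surface and to the end faces
    d_lat = (1.0 - rho) * np.minimum(a, b)
    near_lateral = inside_body & (d_lat <= spec.shell_thickness_um)
    near_proximal = inside_body & (u + half <= spec.shell_thickness_um)
    near_distal = np.zeros_like(near_proximal) if spec.distal_cap else (
        inside_body & (half - u <= spec.shell_thickness_um)
    )
    shell = near_lateral | near_proximal | near_distal | cap_surface

    vol = np.full(spec.shape, float(spec.background))
    vol[inside] = spec.background + spec.interior_intensity
    vol[shell] = spec.background + spec.shell_intensity
    return vol


def _check_containment(spec: PhantomSpec) -> None:
    """Raise GeometryError if the rotated organ surface leaves the grid."""
    half = spec.length_um / 2.0
    ts = np.linspace(0.0, 1.0, 33)
    phis = np.linspace(0.0, 2 * np.pi, 49)
    a, b = spec.semi_axes_at(ts)
    u = (-half + ts * spec.length_um)[:, None]
    v = a[:, None] * np.cos(phis)[None, :]
    w = b[:, None] * np.sin(phis)[None, :]
    pts_organ = np.stack(
        [w.ravel(), v.ravel(), np.broadcast_to(u, v.shape).ravel()], axis=1
    )  # (n, 3) zyx
    if spec.distal_cap:
        a1, b1 = spec.distal_semi_axes_um
        c1 = min(a1, b1)
        tip = np.array([0.0, 0.0, half + c1])
        pts_organ = np.vstack([pts_organ, tip])
    pts_lab = pts_organ @ spec.rotation.T + spec.grid_center_um
    extent = (np.array(spec.shape) - 1) * np.array(spec.spacing)
    under = np.clip(-pts_lab, 0, None).max(axis=0)
    over = np.clip(pts_lab - extent, 0, None).max(axis=0)
    pad = np.maximum(under, over)
    if pad.max() > 0:
        raise GeometryError(
            "organ exceeds the grid after rotation; pad the grid by at least "
            f"(z, y, x) = ({pad[0]:.1f}, {pad[1]:.1f}, {pad[2]:.1f}) µm"
        )


def _sample_cells(spec: PhantomSpec, rng: np.random.Generator) -> list[TrueCell]:
    if spec.cell_density_per_mm3 is not None:
        n = int(round(spec.cell_density_per_mm3 * spec.analytic_volume_um3() / 1e9))
    else:
        n = spec.n_cells
    half = spec.length_um / 2.0
    cells: list[TrueCell] = []
    accepted = np.empty((0, 3))  # organ-frame (u, v, w)

    def try_place(min_sep: float, margin_r: float) -> np.ndarray | None:
        for _ in range(200):
            u = rng.uniform(-half + margin_r, half - margin_r)
            t = (u + half) / spec.length_um
            a, b = spec.semi_axes_at(t)
            v = rng.uniform(-a, a)
            w = rng.uniform(-b, b)
            shrink = 1.0 - margin_r / min(a, b)
            if shrink <= 0:
                continue
            if (v / a) ** 2 + (w / b) ** 2 > shrink**2:
                continue
            pos = np.array([u, v, w])
            if len(accepted) and np.min(np.linalg.norm(accepted - pos, axis=1)) < min_sep:
                continue
            return pos
        return None

    for _ in range(n):
        r = max(1.0, rng.normal(spec.cell_radius_um, spec.cell_radius_sd_um))
        pos = try_place(spec.min_cell_separation_um, r + spec.shell_thickness_um)
        if pos is None:
            raise GeometryError(
                f"could not place {n} cells with min separation "
                f"{spec.min_cell_separation_um} µm; lower the density or separation"
            )
        accepted = np.vstack([accepted, pos])
        peak = max(1.0, rng.normal(spec.cell_peak_intensity, spec.cell_peak_sd))
        cells.append(TrueCell(pos, r, peak))  # organ frame for now

    for _ in range(spec.doublet_pairs):
        r = spec.cell_radius_um
        pos = try_place(2 * spec.min_cell_separation_um, r + spec.shell_thickness_um)
        if pos is None:
            raise GeometryError("could not place doublet pair; grid too crowded")
        direction = rng.normal(size=3)
        direction /= np.linalg.norm(direction)
        partner = pos + direction * spec.doublet_separation_radii * r
        peak = spec.cell_peak_intensity
        accepted = np.vstack([accepted, pos, partner])
        cells.append(TrueCell(pos, r, peak))
        cells.append(TrueCell(partner, r, peak))

    # organ frame (u, v, w) -> lab frame (z, y, x)
    rot = spec.rotation
    c = spec.grid_center_um
    for cell in cells:
        u, v, w = cell.centroid_um
        cell.centroid_um = rot @ np.array([w, v, u]) + c
    return cells


def _render_cells(spec: PhantomSpec, cells: list[TrueCell], scale: float = 1.0) -> np.ndarray:
    vol = np.full(spec.shape, float(spec.background))
    dz, dy, dx = spec.spacing
    nz, ny, nx = spec.shape
    for cell in cells:
        sigma = cell.radius_um / 2.0
        reach = 4.0 * sigma
        cz, cy, cx = cell.centroid_um
        z0, z1 = max(0, int(np.floor((cz - reach) / dz))), min(nz, int(np.ceil((cz + reach) / dz)) + 1)
        y0, y1 = max(0, int(np.floor((cy - reach) / dy))), min(ny, int(np.ceil((cy + reach) / dy)) + 1)
        x0, x1 = max(0, int(np.floor((cx - reach) / dx))), min(nx, int(np.ceil((cx + reach) / dx)) + 1)
        if z0 >= z1 or y0 >= y1 or x0 >= x1:
            continue
        z = np.arange(z0, z1) * dz - cz
        y = np.arange(y0, y1) * dy - cy
        x = np.arange(x0, x1) * dx - cx
        r2 = (
            z[:, None, None] ** 2 + y[None, :, None] ** 2 + x[None, None, :] ** 2
        )
        vol[z0:z1, y0:y1, x0:x1] += scale * cell.peak_intensity * np.exp(-r2 / (2 * sigma**2))
    return vol


def _apply_noise(noise_free: np.ndarray, spec: PhantomSpec, rng: np.random.Generator) -> np.ndarray:
    out = noise_free
    if spec.shot_noise:
        out = rng.poisson(np.clip(out, 0, None)).astype(float)
    if spec.noise_sd > 0:
        out = out + rng.normal(0.0, spec.noise_sd, size=out.shape)
    out = np.clip(out, 0, None)
    if np.issubdtype(np.dtype(spec.dtype), np.integer):
        info = np.iinfo(spec.dtype)
        out = np.clip(np.rint(out), info.min, info.max)
    return out.astype(spec.dtype)


def _true_axis(spec: PhantomSpec) -> tuple[np.ndarray, np.ndarray]:
    direction = spec.rotation @ X_AXIS  # proximal -> distal
    half = spec.length_um / 2.0
    tip_len = half + (min(spec.distal_semi_axes_um) if spec.distal_cap else 0.0)
    tip = spec.grid_center_um + direction * tip_len
    return direction, tip


def generate_phantom(spec: PhantomSpec) -> tuple[VolumeStack, VolumeStack, GroundTruth]:
    """Render the two channels and their ground truth.

    Deterministic given ``spec`` (including ``rng_seed``).  Independent random
    streams are used for cell placement and for each channel's noise, so that
    e.g. switching noise off does not change cell positions.
    """
    _check_containment(spec)
    ss = np.random.SeedSequence(spec.rng_seed)
    rng_place, rng_norgan, rng_ncell = (np.random.default_rng(s) for s in ss.spawn(3))

    organ_nf = _render_organ(spec)
    cells = _sample_cells(spec, rng_place)
    cell_nf = _render_cells(spec, cells)

    direction, tip = _true_axis(spec)
    truth = GroundTruth(
        axis_direction=direction,
        axis_point_um=spec.grid_center_um,
        tip_um=tip,
        cells=cells,
        spec=spec,
        organ_noise_free=organ_nf,
        cell_noise_free=cell_nf,
    )
    organ = VolumeStack(_apply_noise(organ_nf, spec, rng_norgan), spec.spacing, "organ")
    cell = VolumeStack(_apply_noise(cell_nf, spec, rng_ncell), spec.spacing, "cells")
    return organ, cell, truth


def detection_scenario_spec(
    seed: int = 0,
    n_cells: int = 50,
    snr: float = 5.0,
    rotation_y_deg: float = 0.0,
    rotation_z_deg: float = 0.0,
) -> PhantomSpec:
    """Standard nuclei-detection conditions: well-separated blobs at a given SNR.

    SNR is defined as blob peak intensity over the Gaussian read-noise sd.
    The grid is sized so the organ also fits when tilted up to ~25°.
    """
    peak = 150.0
    return PhantomSpec(
        shape=(88, 220, 320),
        spacing=(2.0, 1.0, 1.0),
        length_um=280.0,
        proximal_semi_axes_um=(42.0, 36.0),
        distal_semi_axes_um=(30.0, 26.0),
        n_cells=n_cells,
        cell_peak_intensity=peak,
        cell_peak_sd=0.0,
        noise_sd=peak / snr,
        rotation_y_deg=rotation_y_deg,
        rotation_z_deg=rotation_z_deg,
        rng_seed=seed,
    )


def density_scenario_spec(seed: int = 0, density_per_mm3: float = 5.0e4) -> PhantomSpec:
    """Uniform-density seeding in a straight cylinder, for slab-density checks."""
    return PhantomSpec(
        shape=(70, 70, 262),
        spacing=(2.0, 2.0, 2.0),
        length_um=500.0,
        proximal_semi_axes_um=(60.0, 60.0),
        distal_semi_axes_um=(60.0, 60.0),
        n_cells=0,
        cell_density_per_mm3=density_per_mm3,
        cell_peak_intensity=150.0,
        cell_peak_sd=0.0,
        noise_sd=30.0,
        rng_seed=seed,
    )


def limb_pair_scenario_spec(seed: int = 0, noisy: bool = True) -> PhantomSpec:
    """Standard paired-limb conditions for the distal-tip cube statistic.

    A thick blastema-like organ (the 175 µm cube fits inside), dense EdU+
    seeding (50–150 cells fall inside the cube), zero background in the cell
    channel, and — in the noisy variant — shot (Poisson) noise whose sd at
    blob peaks is one fifth of the peak (SNR 5).  The noise-free variant
    keeps float voxels so ratio recovery can be checked to numerical
    precision without quantization.
    """
    return PhantomSpec(
        shape=(120, 120, 240),
        spacing=(2.5, 2.5, 2.5),
        length_um=500.0,
        proximal_semi_axes_um=(130.0, 130.0),
        distal_semi_axes_um=(110.0, 110.0),
        n_cells=0,
        cell_density_per_mm3=1.5e4,
        cell_radius_um=6.0,
        cell_radius_sd_um=0.5,
        cell_peak_intensity=25.0,
        cell_peak_sd=3.0,
        min_cell_separation_um=15.0,
        background=0.0,
        noise_sd=0.0,
        shot_noise=noisy,
        dtype=np.uint16 if noisy else np.float64,
        rng_seed=seed,
    )


def generate_limb_pair(
    spec: PhantomSpec, intensity_ratio: float
) -> tuple[VolumeStack, VolumeStack, tuple[GroundTruth, GroundTruth]]:
    """Paired innervated / denervated cell channels.

    Geometry and cell placement are identical (same seed); the denervated limb
    scales every per-cell peak intensity by ``intensity_ratio``, emulating the
    slowdown of DNA synthesis after nerve transection.  Noise is drawn
    independently for the two limbs.
    """
    if not 0.0 < intensity_ratio <= 1.0:
        raise ValueError(f"intensity_ratio must lie in (0, 1]; got {intensity_ratio}")
    _check_containment(spec)
    ss = np.random.SeedSequence(spec.rng_seed)
    rng_place, _, rng_inn, rng_den = (np.random.default_rng(s) for s in ss.spawn(4))

    cells = _sample_cells(spec, rng_place)
    nf_inn = _render_cells(spec, cells)
    nf_den = _render_cells(spec, cells, scale=intensity_ratio)

    direction, tip = _true_axis(spec)
    organ_nf = _render_organ(spec)

    def make_truth(nf: np.ndarray, cell_list: list[TrueCell]) -> GroundTruth:
        return GroundTruth(
            axis_direction=direction,
            axis_point_um=spec.grid_center_um,
            tip_um=tip,
            cells=cell_list,
            spec=spec,
            organ_noise_free=organ_nf,
            cell_noise_free=nf,
            intensity_ratio=intensity_ratio,
        )

    den_cells = [TrueCell(c.centroid_um.copy(), c.radius_um, c.peak_intensity * intensity_ratio) for c in cells]
    truth_inn = make_truth(nf_inn, cells)
    truth_den = make_truth(nf_den, den_cells)
    inn = VolumeStack(_apply_noise(nf_inn, spec, rng_inn), spec.spacing, "EdU innervated")
    den = VolumeStack(_apply_noise(nf_den, spec, rng_den), spec.spacing, "EdU denervated")
    return inn, den, (truth_inn, truth_den)
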