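import numpy as np
import pytest

import organquant as oq
from organquant.phantom import (
    density_scenario_spec,
    detection_scenario_spec,
)


def rasterize_ellipse(a_um, b_um, spacing=(1.0, 1.0), angle_deg=0.0, pad_um=3.0):
    """Rasterize a filled ellipse (semi-axes a along y, b along z) rotated in-plane.

    Evaluates the implicit equation at pixel centres, so rotated shapes carry
    no interpolation artifacts.  Returns a 2D bool array in (z, y) order.
    """
    d0, d1 = spacing
    r_max = max(a_um, b_um) + pad_um
    n0 = 2 * int(np.ceil(r_max / d0)) + 1
    n1 = 2 * int(np.ceil(r_max / d1)) + 1
    z = (np.arange(n0) - n0 // 2) * d0
    y = (np.arange(n1) - n1 // 2) * d1
    zz, yy = np.meshgrid(z, y, indexing="ij")
    th = np.deg2rad(angle_deg)
    yr = yy * np.cos(th) + zz * np.sin(th)
    zr = -yy * np.sin(th) + zz * np.cos(th)
    return (yr / a_um) ** 2 + (zr / b_um) ** 2 <= 1.0


def rasterize_rectangle(w_um, h_um, spacing=(1.0, 1.0), pad_um=2.0):
    """Axis-aligned filled rectangle, w along y, h along z; (z, y) bool array."""
    d0, d1 = spacing
    n0 = int(np.ceil((h_um + 2 * pad_um) / d0))
    n1 = int(np.ceil((w_um + 2 * pad_um) / d1))
    z = (np.arange(n0) - (n0 - 1) / 2) * d0
    y = (np.arange(n1) - (n1 - 1) / 2) * d1
    zz, yy = np.meshgrid(z, y, indexing="ij")
    return (np.abs(yy) < w_um / 2) & (np.abs(zz) < h_um / 2)


@pytest.fixture(scope="session")
def snr5_phantom():
    """50 well-separated nuclei at SNR 5, unrotated."""
    spec = detection_scenario_spec(seed=42)
    organ, cell, truth = oq.generate_phantom(spec)
    return organ, cell, truth, spec


@pytest.fixture(scope="session")
def rotated_z25_phantom():
    spec = detection_scenario_spec(seed=7, rotation_z_deg=25.0)
    organ, cell, truth = oq.generate_phantom(spec)
    return organ, cell, truth, spec


@pytest.fixture(scope="session")
def rotated_y15_phantom():
    spec = detection_scenario_spec(seed=9, rotation_y_deg=15.0)
    organ, cell, truth = oq.generate_phantom(spec)
    return organ, cell, truth, spec


@pytest.fixture(scope="session")
def density_phantom():
    """Uniform seeding at 5×10⁴ cells/mm³ in a straight cylinder."""
    spec = density_scenario_spec(seed=11)
    organ, cell, truth = oq.generate_phantom(spec)
    return organ, cell, truth, spec


def doublet_spec(seed=3):
    return oq.PhantomSpec(
        shape=(48, 80, 160),
        spacing=(2.0, 1.0, 1.0),
        length_um=120.0,
        proximal_semi_axes_um=(30.0, 26.0),
        distal_semi_axes_um=(26.0, 22.0),
        n_cells=0,
        doublet_pairs=1,
        cell_peak_intensity=150.0,
        cell_peak_sd=0.0,
        noise_sd=0.0,
        rng_seed=seed,
    )


@pytest.fixture(scope="session")
def doublet_phantom():
    spec = doublet_spec()
    organ, cell, truth = oq.generate_phantom(spec)
    return organ, cell, truth, spec


@pytest.fixture(scope="session")
def detected_snr5(snr5_phantom):
    """Full detection chain run once on the SNR-5 phantom."""
    organ, cell, truth, spec = snr5_phantom
    enhanced = oq.enhance_cells(cell)
    labels = oq.segment_cells(enhanced)
    objects = oq.count_objects(labels, cell.spacing, cell.data)
    return labels, objects, truth, spec
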