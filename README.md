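# organquant

Multiscale quantification of 3D light-sheet fluorescence volumes of
regenerating organs — at the **organ** level (morphology segmentation, axis
alignment, per-cross-section geometry), the **cellular** level (nuclei
detection, 3D object counting, axial density profiles), and the
**molecular** level (intensity profiles, histograms, and a paired-limb cube
comparison).

The package is written for researchers quantifying nascent-macromolecule
labelling (e.g. EdU for DNA synthesis, AHA for protein synthesis) in cleared
whole-mount specimens such as regenerating axolotl limbs, where the organ of
interest — a humerus, a blastema — is elongated along an anatomical
proximodistal (P–D) axis and all profiles are reported along that axis.

## What it computes

Given an organ-outline channel and a cell/molecular channel with voxel
spacing in µm:

1. **Segment** the organ: smooth → threshold (Otsu or fixed) → morphological
   closing → 3D hole fill → largest 26-connected component.
2. **Align**: the P–D axis is estimated as the dominant principal component
   of the mask's foreground voxel positions (in physical coordinates) and
   the stack is rigidly rotated so that axis coincides with +X, resampled to
   isotropic spacing.
3. **Slice geometry** per cross-section: area *A*, centroid, principal angle
   θ, second moments of area about the principal axes (I_max, I_min, µm⁴),
   maximum chord lengths along the principal directions (2R₂ major,
   2R₁ minor), and the circularity index 2R₁/2R₂ ∈ (0, 1].
4. **Cells**: background subtraction → 3D Gaussian blur → threshold → hole
   fill → distance-transform watershed split → 26-connected labelling →
   volume filtering; each nucleus is reported with centroid (µm), voxel
   count, physical volume and mean intensity.  Centroids are counted in
   half-open 50 µm slabs along the axis and divided by the slab mask volume
   to give a density in cells/mm³.
5. **Molecular**: per-slice mean intensity and histograms over in-mask
   voxels; a 175 µm quantification cube whose distal face sits 250 µm from
   the distal tip, centred on the axis; and the paired statistic
   ratio = mean(denervated cube) / mean(innervated cube).

All defaults (50 µm slabs, 175 µm cube side, 250 µm tip offset) live in
`PipelineConfig` and a YAML config can override any of them.

Because raw light-sheet volumes are tens of gigabytes, the package ships a
**phantom generator** (`organquant.phantom`) that renders tapered-cylinder
organs with bright surface shells, Gaussian-blob nuclei, arbitrary axis
misalignment and sensor noise — with exact ground truth — so every stage is
testable at desk scale.

## Worked example

```python
import organquant as oq
from organquant.phantom import limb_pair_scenario_spec

# paired limbs: identical geometry, denervated per-cell intensity x 0.7
spec = limb_pair_scenario_spec(seed=0, noisy=True)
inn, den, (truth, _) = oq.generate_limb_pair(spec, intensity_ratio=0.7)
inn.axis_aligned = den.axis_aligned = True  # generated pre-aligned

cfg = oq.load_config(None)  # defaults: 175 um cube, 250 um offset
ci = oq.extract_cube(inn, truth.tip_um, cfg.cube_side_um, cfg.cube_offset_um)
cd = oq.extract_cube(den, truth.tip_um, cfg.cube_side_um, cfg.cube_offset_um)
pair = oq.compare_pair(ci, cd)
print(f"{len(truth.cells)} cells; cube mean ratio = {pair.ratio:.4f}")
```

prints

```
340 cells; cube mean ratio = 0.6989
```

i.e. with 340 nuclei seeded in the blastema-like phantom and shot noise at
SNR 5, the cube statistic recovers the simulated 0.7 synthesis-rate ratio to
within ~0.002.  A full end-to-end run on a generated specimen:

```bash
organquant demo --seed 0 --out demo_out
```

writes the geometry profile, cell table, density profile, intensity profile,
cube report, STL surface mesh and a run manifest under `demo_out/`.

## Layout

| module | contents |
|---|---|
| `organquant.io` | `VolumeStack`, OME-TIFF read/write, `PipelineConfig`, YAML loading |
| `organquant.phantom` | `PhantomSpec`, ground-truth phantom and paired-limb generators |
| `organquant.axis` | principal-axis estimation, rigid alignment, reslicing |
| `organquant.morphology` | organ segmentation, slice geometry, geometry profile, STL export |
| `organquant.cells` | enhancement, nuclei segmentation, object counting, density profile |
| `organquant.molecular` | intensity profiles, distal-tip cube ROI, paired comparison |
| `organquant.pipeline` / `organquant.cli` | end-to-end orchestration and the `organquant` command |

See `docs/methods.md` for the models, parameter choices, and limitations.
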