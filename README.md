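# gapct

3D quantification of interfacial gaps between dental adhesive and tooth
substrate in phase-contrast-enhanced micro-CT (PCE-CT) volumes.

## The problem

Bonded dental restorations fail at the interface: voids ("interfacial gaps")
between the polymer adhesive layer and the conditioned dentin act as leakage
paths for fluids and bacteria, and mechanically as cracks that grow under
mastication. The adhesive is a thin, low-density polymer, so conventional
absorption micro-CT cannot resolve gaps of a few micrometres; inline
propagation-based phase contrast can, because Fresnel edge fringes make
low-density discontinuities visible at sub-micrometre pixel sizes.

`gapct` implements a reproducible, operator-independent analysis of such
volumes for researchers in dental biomaterials and X-ray imaging:

1. **Phase retrieval** (`gapct.paganin`) — single-distance Paganin filtering
   of flat-field-normalized projections,
   `T = -ln F⁻¹[ F(I/I₀) / (1 + (δ/β)·λz/(4π)·|k|²) ]`,
   defaulting to a typical dental configuration (34 keV, 33 mm propagation,
   0.65 µm pixel, δ/β = 200).
2. **Gap segmentation** (`gapct.gapseg`) — grey-range thresholding from the
   volume histogram, 3D connected-component labelling (6/18/26
   connectivity), selection of interface components by label id, seed point
   or a radial annulus predicate, and a red-tint QC overlay.
3. **Local thickness** (`gapct.thickmap`) — the largest-inscribed-sphere
   thickness τ(p) = max{2r : p ∈ B_r ⊆ structure}, computed via Euclidean
   distance transform, distance ridge and sphere painting, with exact
   integer-squared-distance sphere tests.
4. **Footprint areas** (`gapct.areas`) — the axial gap footprint (binary
   minimum-intensity projection), the bonded/conditioned footprint
   (maximum-intensity projection split at a grey threshold inside the
   interface annulus), and the headline ratio
   `percent gap = 100 · area(gap ∩ bonded) / area(bonded)`.
5. **Azimuthal sectors** (`gapct.sectors`) — with the restoration post axis
   as pivot, footprints are divided into n equal sectors (default 18 × 20°)
   and per-sector gap percentages are tabulated and plotted against azimuth.

Because real tooth scans of this kind are rarely shareable, the package
ships a first-class phantom generator (`gapct.phantom`): synthetic
reconstructed cross-sections of a post-and-core restored tooth (fibreglass
post, resin cement, crown composite, adhesive annulus, dentin) with planted
annular-sector gaps of exactly known angular occupancy and thickness,
Gaussian noise per material and Laplacian-of-Gaussian edge-fringe emulation.
Every stage is validated against this exact ground truth and against
independent brute-force oracles.

## Worked example

Analyse a synthetic restored tooth (256 × 256 × 64 voxels at 0.65 µm) with a
single 120°, 8 µm gap planted at the adhesive–dentin interface:

```python
import json
from gapct.pipeline import RunConfig, run_analysis

phantom = {
    "shape": [64, 256, 256],
    "voxel_um": 0.65,
    "gaps": [{"angle_start": 37.0, "angle_extent": 120.0,
              "z_start": 0, "z_end": 64, "thickness_um": 8.0}],
    "interface_band_um": 8.0,
}
cfg = RunConfig(outdir="example_run", phantom=phantom,
                grey_range=[0.0, 0.2], annulus_um="truth",
                center="auto", seed=42)
print(json.dumps(run_analysis(cfg), indent=2))
```

prints (abridged):

```json
{
  "config_hash": "1ce6b97cc9585f6a",
  "center": [128.19676470588234, 128.08132352941178],
  "annulus_um": [54.0, 62.0],
  "gap_voxels": 147200,
  "percent_gap": 32.97022512708787,
  "thickness_um": {"median_um": 8.125, "p5_um": 8.125, "p95_um": 8.775},
  "n_sectors": 18
}
```

The planted truth is a 120°/360° = 33.3 % gap of 8 µm thickness: the
pipeline recovers 32.97 % bonded-interface debonding (0.4 percentage points
low, from sub-pixel discretization of the arc) and a median local thickness
of 8.125 µm (+0.125 µm, within the half-voxel resolution at 0.65 µm voxels).
`example_run/` also receives the gap mask and thickness TIFF stacks, the
footprints, `profile.csv`/`profile.png` with the 18-sector debonding
profile, the verbatim `config.yaml` and a stage log.

The same run is available from the shell:

```bash
gapct run config.yaml          # full pipeline from a YAML config
gapct simulate spec.yaml -o phantom/
gapct retrieve --energy-kev 34 --distance-mm 33 --pixel-um 0.65 --delta-beta 200 in.tif out.tif
gapct segment stack.tif --lo 0 --hi 0.2 --keep-annulus 54,62 --center 128,128 -o seg/
gapct thickness seg/gap_mask.tif --voxel-um 0.65 -o thick.tif --summary thick.csv
gapct sectors gap_fp.tif bonded_fp.tif --n 18 --center auto -o profile.csv --plot profile.png
gapct recover -o recovery/     # simulate-and-recover grid
```

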