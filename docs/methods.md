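# Methods

This note documents the models, conventions and numerical choices behind
`gapct`, and what the synthetic validation does and does not demonstrate.

## Coordinate and angle conventions

Volumes are indexed `(z, y, x)` with z along the tooth/post long axis;
voxels are isotropic (µm). Azimuth is measured in the (x, y) slice plane,
0° at the +x axis, counter-clockwise, in [0, 360). Radial intervals and
arcs are half-open (`r_in ≤ r < r_out`, `start ≤ θ < start + extent`), so
annuli and sector partitions tile the plane without double counting.
Sectors are the n half-open intervals [k·360/n, (k+1)·360/n); a pixel lying
exactly at the pivot (radius 0) has no defined angle and is excluded from
all sectors. Sectors with zero bonded area report an undefined (NaN)
percentage rather than 0 or 100, since either substitute would fabricate a
bond-quality statement. The angular origin is a package convention — real
samples carry no anatomical angular registration, so profiles from
different samples are comparable in distribution but not sector-by-sector.

## Phantom: what it emulates

The generator renders an axial field of view through the cervical region of
a restored tooth as concentric annuli: fibreglass post, self-adhesive resin
cement, crown composite, adhesive, dentin, surrounded by air. Default grey
levels (air/gap 0.05, adhesive 0.35, dentin 0.55, composite 0.70, cement
0.80, post 0.90, on [0, 1]) are conventions — instruments report arbitrary
grey scales — chosen so that neighbouring materials are separated by many
noise standard deviations (default per-material SD 0.02). The default
geometry scales radii (25/38/48/58/78 µm) to fit a 256-pixel field at the
0.65 µm voxel size typical of high-resolution synchrotron imaging; this is
a deliberately desk-scale stand-in for real reconstructions that run to
thousands of slices and tens of gigabytes.

Gaps are annular-sector voids centred radially on the adhesive–dentin
radius, the paper-thin interface where debonding occurs; each has an
angular start/extent, a z range and a radial thickness. Gaps overlapping in
both angle and z are rejected; thickness below one voxel is rejected with a
hint to reduce `voxel_um`. Ground truth (`PhantomTruth`) records the carved
voxel mask, per-gap thicknesses, the bonded interface band and the
analytic per-sector occupancy computed from the gap angles alone by
circular interval arithmetic.

**Bonded-area convention.** In a real tooth the conditioned (etched) dentin
surface is an irregular shoulder whose axial projection has a finite
annular footprint. The phantom's interface is an exact cylinder, whose
projection would be a zero-width circle, so the bonded footprint is defined
as the interface annulus band of radial width `interface_band_um`
(default: the largest planted gap thickness; 8 µm if no gaps). With gap and
bonded band sharing the same radial bounds, the area ratio equals the
angular occupancy, which is what the per-sector profile measures.

**Edge fringes.** Propagation contrast is emulated as
`v − strength · (LoG_σ(v) − k₀·v)` with σ = 1 voxel: a signed
second-derivative term that overshoots on the bright side and undershoots
on the dark side of every boundary. `k₀` is the truncated discrete kernel's
DC response; subtracting it makes constant fields exactly invariant. The
LoG convolution runs in float32 because piecewise-constant volumes generate
denormal intermediates that slow float64 filtering ~20×; the ≲1e-7 values
difference is far below the noise floor. This is an emulation of the
*appearance* of inline phase contrast, not Fresnel wave optics: no
propagation distance, partial coherence, polychromaticity or detector PSF
is modelled. Passing tests therefore show the pipeline is robust to
fringe-like edge artefacts of the modelled amplitude, not that it handles
every real fringe morphology.

**Noise** is additive Gaussian per material (clipped to [0, 1]), drawn from
`numpy.random.default_rng(noise_seed)`, so a spec is bit-reproducible. Real
reconstructions also carry ring artefacts, cutting-line ("star") shadows
and beam-hardening residues that the phantom omits; the pipeline exposes an
explicit grey range, label selection and annulus bounds precisely so that
an operator can handle those on real data.

## Phase retrieval

`paganin_filter` implements the single-distance homogeneous-object filter
with `λ[Å] = 12.3984/E[keV]` and angular frequencies from the pixel pitch.
Defaults follow a typical dental PCE-CT configuration (34 keV, 33 mm,
0.65 µm, δ/β = 200). Symmetric reflect padding of half the image size per
edge suppresses FFT wraparound and is recorded as part of the call; `pad=0`
gives the exact periodic operator (used by the equivariance tests). The
filter reduces identically to −ln(I/I₀) at zero distance or zero δ/β.
Production codes often append an unsharp-mask sharpening step to the
canonical filter; this is available (`unsharp_sigma`, `unsharp_weight`) but
off by default since its parameters are site-specific. Inputs must be
strictly positive (flat-field normalized); non-positive filtered
intensities raise rather than silently clip. The low-pass guarantee
(denominator ≥ 1) holds on the intensity spectrum; the −ln output inherits
it only to first order in the contrast, which is why the tests assert the
intensity-domain form.

## Gap segmentation

Thresholding uses a closed grey interval so integer volumes behave
predictably at the bounds. `suggest_range` proposes [data minimum, first
valley of the smoothed histogram] between the two lowest-grey modes
(256 bins, Gaussian smoothing σ = 3 bins, peak prominence 1 % of the modal
count, flat valleys resolved to their middle bin); it errors on unimodal
histograms instead of guessing. The suggestion is advisory and the pipeline
records whether a manual or suggested range was used.

Connected components use scipy's labelling with the requested 6/18/26
structuring element, renumbered into raster-scan order of first voxels so
results are deterministic across library versions. Default connectivity is
26: interfacial gaps are thin sheets that may touch only diagonally after
thresholding. Selection offers the manual route (explicit ids), seed
points, and two automated annulus predicates: `centroid` (label centroid
radius inside the annulus — the natural reading for compact spurious pores)
and `overlap` (≥ 50 % of label voxels inside the annulus). The pipeline
default is `overlap` because the centroid of an extended arc-shaped
interfacial sheet migrates toward the axis — a near-full debonding ring has
centroid radius ≈ 0 and would evade any centroid band.

## Local thickness

τ(p) is the diameter of the largest sphere containing p that fits in the
structure (the standard largest-inscribed-sphere definition). Radii come
from the Euclidean distance transform as exact squared integers; sphere
membership is the strict test `d² < r²`, so painting is bit-reproducible. A
distance-ridge prune drops centres whose sphere a 26-neighbour's sphere
provably contains (`r_n ≥ r + d`, triangle inequality), which cannot change
the painted maximum; remaining spheres are painted in descending radius
order with first-write-wins. The implementation crops to the structure
bounding box (padded by 2 voxels — nearest background voxels always lie
within bbox+1) purely for speed.

Numerical conventions: radii are centre-to-nearest-background distances, so
an n-voxel slab reads n for even n and n + 1 for odd n — the inherent
one-voxel quantization of this family of algorithms, covered by the ±1
voxel tolerance used throughout. Reported maps are rounded to the
achievable half-voxel resolution (`quantize=True`), an honesty measure at
0.65 µm voxels against 2–16 µm gaps. The volume border does not truncate
spheres; voxels whose sphere would cross the border are flagged
`edge_affected` because their τ is a lower bound when the structure
continues outside the field of view. An empty mask yields an empty map and
a null summary row, not an error.

## Footprints, percentage, sectors

The gap footprint is column-wise existence of gap voxels over the z range —
the exact binary analogue of a minimum-intensity projection of a volume
whose gaps are darkest. The bonded footprint is the maximum-intensity
projection thresholded at `split_threshold` (darker = conditioned tooth,
brighter = cement-covered) and intersected with the interface annulus; the
annulus bounds are explicit inputs (or the phantom truth band) because real
interfaces need operator knowledge of where the bond lies. The global
percentage intersects the gap footprint with the bonded footprint before
dividing, so stray segmentation outside the interface cannot inflate it,
and an empty bonded area yields NaN rather than a fake 0 or 100. Per-sector
areas are pixel-exact partitions of the global areas (bincount over sector
indices), so the profile sums reproduce the global numbers identically.

## Pipeline and provenance

All parameters live in one `RunConfig` (YAML-serialisable); the config is
written verbatim into the output directory, its SHA-256 prefix is stamped
into the run log, and every stage logs its voxel counts — an audit trail in
place of the visual verification used in manual workflows. Stage failures
re-raise with the stage name and leave earlier artefacts for debugging.
CSVs are written with `%.17g` floats so values round-trip exactly and
reruns are byte-identical.

The recovery experiment runs the identical stage sequence over a grid of
planted gap fractions (0, 1/3, 2/3 at 8 µm) and thicknesses (3.25, 6.5,
13 µm at 1/3 occupancy), three seeds per cell, at 256 × 256 × 64 voxels and
0.65 µm — sizes chosen so the whole grid runs in a few minutes on one CPU
while keeping ≥ 5 voxels across the thinnest gap and ≳ 500 pixels of
interface circumference. The automated grey range [0, 0.2] is the histogram
valley between the air/gap and adhesive modes (what `suggest_range`
returns on these phantoms), mirroring histogram-based range selection on
real data rather than a ±kσ band.

## Known limitations

- The phantom's interface is a perfect cylinder; real interfaces are 3D
  surfaces, so real bonded footprints need the annulus/threshold inputs and
  possibly an exclusion mask for cutting-line artefacts.
- Fringe emulation is phenomenological (see above); the Paganin module
  filters projections but tomographic reconstruction itself is out of
  scope.
- Local thickness assumes isotropic voxels and carries the ±1 voxel parity
  quantization; thickness statistics within a voxel of the value are not
  distinguishable.
- Whether a reported 2–16 µm-style range refers to per-voxel extremes or
  per-gap summaries is ambiguous in practice; the summary row reports min,
  max, median, mean, p5 and p95 so either reading is available.
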