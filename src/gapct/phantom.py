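"""Synthetic reconstructed PCE-CT volumes of a restored tooth cross-section.

The phantom emulates an axial field of view through the cervical region of a
post-and-core restored tooth: concentric annuli of fibreglass post,
self-adhesive resin cement, crown composite, a thin adhesive layer and
dentin, surrounded by air. Interfacial gaps are carved as annular-sector
voids of known thickness centred radially on the adhesive-dentin boundary,
so every downstream measurement can be checked against exact ground truth.

Propagation (Fresnel) edge enhancement is emulated by a signed
Laplacian-of-Gaussian term that puts bright/dark rims at material
boundaries; noise is additive Gaussian per material.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy.ndimage import gaussian_laplace

from .geometry import (
    angle_map_deg,
    arc_mask,
    circular_union,
    interval_overlap_deg,
    radius_map_um,
)
from .volio import Volume3D

#: material roles, innermost first; "gap" and "background" are both air.
ROLES = ("post", "cement", "composite", "adhesive", "dentin", "gap", "background")

#: radial width of the bonded (conditioned) interface band when no gaps are
#: planted, µm; with gaps the band defaults to the largest planted thickness.
DEFAULT_BAND_UM = 8.0


@dataclasses.dataclass
class MaterialSpec:
    """Grey-level model of one material: mean value and noise SD, both on [0, 1]."""

    name: str
    grey_mean: float
    grey_sd: float = 0.0

    def __post_init__(self):
        if not 0.0 <= self.grey_mean <= 1.0:
            raise ValueError(f"grey_mean must be in [0, 1], got {self.grey_mean}")
        if self.grey_sd < 0:
            raise ValueError(f"grey_sd must be >= 0, got {self.grey_sd}")


def default_materials(noise_sd: float = 0.02) -> dict[str, MaterialSpec]:
    """Conventional grey levels: air/gaps darkest, dentin mid, filled resins bright.

    The real scans' grey ranges are instrument-specific; these are package
    conventions chosen so every pair of materials is separated by many noise
    SDs at the default ``noise_sd``.
    """
    greys = {
        "post": 0.90,
        "cement": 0.80,
        "composite": 0.70,
        "dentin": 0.55,
        "adhesive": 0.35,
        "gap": 0.05,
        "background": 0.05,
    }
    return {k: MaterialSpec(k, v, noise_sd) for k, v in greys.items()}


@dataclasses.dataclass
class GapSpec:
    """One planted interfacial gap: an annular-sector void at the adhesive-dentin interface.

    ``angle_start``/``angle_extent`` are degrees (see :mod:`gapct.geometry`
    conventions); ``z_start``/``z_end`` are half-open slice indices;
    ``thickness_um`` is the radial thickness of the void.
    """

    angle_start: float
    angle_extent: float
    z_start: int
    z_end: int
    thickness_um: float

    def __post_init__(self):
        if not 0.0 <= self.angle_start < 360.0:
            raise ValueError(f"angle_start must be in [0, 360), got {self.angle_start}")
        if not 0.0 < self.angle_extent <= 360.0:
            raise ValueError(f"angle_extent must be in (0, 360], got {self.angle_extent}")
        if self.z_start >= self.z_end:
            raise ValueError(f"need z_start < z_end, got [{self.z_start}, {self.z_end})")
        if self.thickness_um <= 0:
            raise ValueError(f"thickness_um must be > 0, got {self.thickness_um}")


@dataclasses.dataclass
class Radii:
    """Outer radii (µm) of the concentric material annuli, strictly increasing.

    ``composite_outer`` doubles as the adhesive inner radius and
    ``adhesive_outer`` as the dentin inner radius (= the bonded interface).
    """

    post_outer: float
    cement_outer: float
    composite_outer: float
    adhesive_outer: float
    dentin_outer: float

    def as_tuple(self):
        return (
            self.post_outer,
            self.cement_outer,
            self.composite_outer,
            self.adhesive_outer,
            self.dentin_outer,
        )

    def __post_init__(self):
        vals = self.as_tuple()
        if any(b <= a for a, b in zip(vals, vals[1:])) or vals[0] <= 0:
            raise ValueError(f"radii must be strictly increasing and positive: {vals}")


@dataclasses.dataclass
class PhantomSpec:
    """Full parametric description of a synthetic restored-tooth volume."""

    shape: tuple[int, int, int]  # (nz, ny, nx)
    voxel_um: float = 0.65  # matches the 650 nm effective pixel of the scans emulated
    center: tuple[float, float] | None = None  # (cy, cx); default = image middle
    radii_um: Radii | None = None
    materials: dict[str, MaterialSpec] | None = None
    gaps: list[GapSpec] = dataclasses.field(default_factory=list)
    fringe_strength: float = 0.5
    fringe_sigma: float = 1.0
    noise_seed: int = 0
    interface_band_um: float | None = None  # bonded-band width; None -> max gap thickness

    def __post_init__(self):
        if len(self.shape) != 3 or any(s < 1 for s in self.shape):
            raise ValueError(f"shape must be 3 positive ints, got {self.shape}")
        if self.voxel_um <= 0:
            raise ValueError(f"voxel_um must be > 0, got {self.voxel_um}")
        if self.fringe_strength < 0:
            raise ValueError("fringe_strength must be >= 0")
        nz, ny, nx = self.shape
        if self.center is None:
            self.center = (ny / 2.0, nx / 2.0)
        if self.radii_um is None:
            # default geometry: a scaled-down cervical cross-section that fits
            # a 256 px field at 0.65 µm/voxel
            scale = min(ny, nx) * self.voxel_um / (256 * 0.65)
            self.radii_um = Radii(*(r * scale for r in (25.0, 38.0, 48.0, 58.0, 78.0)))
        if self.materials is None:
            self.materials = default_materials()
        missing = set(ROLES) - set(self.materials)
        if missing:
            raise ValueError(f"materials missing roles: {sorted(missing)}")
        cy, cx = self.center
        margin_um = self.radii_um.dentin_outer + self.voxel_um
        lim = min(cy, cx, ny - 1 - cy, nx - 1 - cx) * self.voxel_um
        if margin_um > lim:
            raise ValueError(
                f"dentin_outer + 1 voxel ({margin_um:.2f} µm) does not fit inside "
                f"the field of view ({lim:.2f} µm from center to nearest edge)"
            )

    @classmethod
    def from_dict(cls, data: dict) -> "PhantomSpec":
        """Build a spec from plain mappings (YAML/JSON configs)."""
        kw = dict(data)
        kw["shape"] = tuple(kw["shape"])
        if kw.get("center") is not None:
            kw["center"] = tuple(kw["center"])
        if isinstance(kw.get("radii_um"), dict):
            kw["radii_um"] = Radii(**kw["radii_um"])
        if isinstance(kw.get("materials"), dict):
            kw["materials"] = {
                k: MaterialSpec(**m) if isinstance(m, dict) else m
                for k, m in kw["materials"].items()
            }
        kw["gaps"] = [
            GapSpec(**g) if isinstance(g, dict) else g for g in kw.get("gaps", [])
        ]
        return cls(**kw)

    @property
    def interface_radius_um(self) -> float:
        return self.radii_um.adhesive_outer

    def band_um(self) -> float:
        """Radial width of the bonded interface band (µm)."""
        if self.interface_band_um is not None:
            return self.interface_band_um
        if self.gaps:
            return max(g.thickness_um for g in self.gaps)
        return DEFAULT_BAND_UM


@dataclasses.dataclass
class PhantomTruth:
    """Exact ground truth of the carved geometry."""

    gap_mask: np.ndarray  # 3D bool
    gap_thickness_um: list[float]
    bonded_mask_2d: np.ndarray  # 2D bool, interface annulus band
    sector_occupancy: np.ndarray  # per-sector true gap fraction (n = sector_n)
    sector_n: int = 18
    band_bounds_um: tuple[float, float] = (0.0, 0.0)


def _check_gap_overlaps(gaps: list[GapSpec]) -> None:
    for i in range(len(gaps)):
        for j in range(i + 1, len(gaps)):
            a, b = gaps[i], gaps[j]
            if a.z_start < b.z_end and b.z_start < a.z_end:
                # z ranges intersect: the angular arcs must be disjoint (mod 360)
                union = circular_union(
                    [(a.angle_start, a.angle_extent), (b.angle_start, b.angle_extent)]
                )
                if sum(e - s for s, e in union) < a.angle_extent + b.angle_extent - 1e-9:
                    raise ValueError(
                        f"gaps {i} and {j} overlap in both angle and z; "
                        "adjust angle_start/extent or z ranges"
                    )


def true_sector_occupancy(spec: PhantomSpec, n: int) -> np.ndarray:
    """Analytic per-sector gap fraction from the GapSpec angles alone.

    For each of ``n`` equal azimuthal sectors, the fraction of the sector's
    angular span covered by the union of planted gap arcs (no voxels
    involved).
    """
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    segments = circular_union([(g.angle_start, g.angle_extent) for g in spec.gaps])
    width = 360.0 / n
    occ = np.array(
        [interval_overlap_deg(k * width, (k + 1) * width, segments) / width for k in range(n)]
    )
    return occ


def _log_dc_response(sigma: float, ndim: int) -> float:
    """Response of the truncated discrete LoG kernel to a unit constant field."""
    half = int(4.0 * sigma + 0.5)
    ones = np.ones((2 * half + 1,) * ndim, dtype=np.float32)
    return float(gaussian_laplace(ones, sigma)[(half,) * ndim])


def add_edge_fringes(volume, strength: float, sigma: float = 1.0):
    """Add propagation-style bright/dark rims at material boundaries.

    ``out = v - strength * LoG(v, sigma)``: an unsharp-like signed
    second-derivative term that overshoots on the bright side of each edge
    and undershoots on the dark side, the visual signature of inline phase
    contrast. ``strength = 0`` returns the input unchanged; constant fields
    are unchanged for any strength.
    """
    if strength < 0:
        raise ValueError("strength must be >= 0")
    arr = volume.voxels if isinstance(volume, Volume3D) else np.asarray(volume, float)
    if strength == 0:
        out = arr.copy()
    else:
        # float32 convolution: piecewise-constant volumes generate denormal
        # intermediates in float64 that slow the filter ~20x
        log = gaussian_laplace(arr.astype(np.float32), sigma).astype(float)
        # the truncated discrete kernel has a small non-zero DC response;
        # subtract it so constant fields are exactly invariant
        log -= _log_dc_response(sigma, arr.ndim) * arr
        out = arr - strength * log
    if isinstance(volume, Volume3D):
        return Volume3D(out, volume.voxel_um, dict(volume.meta))
    return out


def generate_phantom(spec: PhantomSpec) -> tuple[Volume3D, PhantomTruth]:
    """Render the phantom volume and its exact ground truth.

    Deterministic for a given spec (noise is drawn from
    ``numpy.random.default_rng(spec.noise_seed)``). Raises on gaps that
    overlap in both angle and z, and on gap thickness below one voxel.
    """
    _check_gap_overlaps(spec.gaps)
    for g in spec.gaps:
        if g.thickness_um < spec.voxel_um:
            raise ValueError(
                f"gap thickness {g.thickness_um} µm is below one voxel "
                f"({spec.voxel_um} µm); reduce voxel_um to resolve it"
            )

    nz, ny, nx = spec.shape
    r = radius_map_um((ny, nx), spec.center, spec.voxel_um)
    bounds = spec.radii_um.as_tuple()
    role_idx = np.digitize(r, bounds)  # 0=post .. 4=dentin, 5=background
    role_names = ["post", "cement", "composite", "adhesive", "dentin", "background"]

    grey2d = np.empty((ny, nx))
    sd2d = np.empty((ny, nx))
    for i, name in enumerate(role_names):
        m = spec.materials[name]
        sel = role_idx == i
        grey2d[sel] = m.grey_mean
        sd2d[sel] = m.grey_sd

    vol = np.broadcast_to(grey2d, (nz, ny, nx)).copy()
    sd3d = np.broadcast_to(sd2d, (nz, ny, nx)).copy()

    gap_mask = np.zeros((nz, ny, nx), dtype=bool)
    r_i = spec.interface_radius_um
    for g in spec.gaps:
        band = (r >= r_i - g.thickness_um / 2.0) & (r < r_i + g.thickness_um / 2.0)
        sector = arc_mask((ny, nx), spec.center, g.angle_start, g.angle_extent)
        gap_mask[g.z_start : g.z_end] |= band & sector

    gap_mat = spec.materials["gap"]
    vol[gap_mask] = gap_mat.grey_mean
    sd3d[gap_mask] = gap_mat.grey_sd

    if spec.fringe_strength > 0:
        vol = add_edge_fringes(vol, spec.fringe_strength, spec.fringe_sigma)
    if np.any(sd3d > 0):
        rng = np.random.default_rng(spec.noise_seed)
        vol = vol + rng.standard_normal(vol.shape) * sd3d
    vol = np.clip(vol, 0.0, 1.0)

    band = spec.band_um()
    bonded = (r >= r_i - band / 2.0) & (r < r_i + band / 2.0)
    truth = PhantomTruth(
        gap_mask=gap_mask,
        gap_thickness_um=[g.thickness_um for g in spec.gaps],
        bonded_mask_2d=bonded,
        sector_occupancy=true_sector_occupancy(spec, 18),
        sector_n=18,
        band_bounds_um=(r_i - band / 2.0, r_i + band / 2.0),
    )
    meta = {"phantom_seed": spec.noise_seed, "rescale": "none"}
    return Volume3D(vol, spec.voxel_um, meta), truth
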