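"""Single-distance (Paganin) phase retrieval for flat-field-normalized projections.

For a homogeneous object with a fixed ratio delta/beta of the refractive
index decrement, the retrieved projected thickness image is

    T = -ln( IFFT[ FFT(I/I0) / (1 + (delta/beta) * lambda * z / (4 pi) * |k|^2) ] )

with |k| the angular spatial frequency magnitude, lambda the wavelength and
z the propagation distance. At z = 0 or delta/beta = 0 the filter reduces
exactly to Beer-Lambert absorption, -ln(I/I0).

The filter is a pure low pass (the denominator is >= 1 everywhere), which is
what makes propagation-fringed projections reconstructible with area
contrast instead of edge contrast.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy.ndimage import gaussian_filter

#: hc in keV·Å, so lambda[Å] = 12.3984 / E[keV]
_HC_KEV_ANGSTROM = 12.3984


@dataclasses.dataclass
class AcquisitionGeometry:
    """Inline propagation geometry of a synchrotron microtomography scan.

    Defaults are a typical high-resolution dental configuration: 34 keV,
    33 mm sample-to-detector distance, 650 nm effective pixel and
    delta/beta = 200.
    """

    energy_keV: float = 34.0
    distance_mm: float = 33.0
    pixel_um: float = 0.65
    delta_beta: float = 200.0

    def __post_init__(self):
        if self.energy_keV <= 0:
            raise ValueError("energy_keV must be > 0")
        if self.pixel_um <= 0:
            raise ValueError("pixel_um must be > 0")
        if self.distance_mm < 0 or self.delta_beta < 0:
            raise ValueError("distance_mm and delta_beta must be >= 0")

    @property
    def wavelength_m(self) -> float:
        return _HC_KEV_ANGSTROM / self.energy_keV * 1e-10


def paganin_filter(
    projection: np.ndarray,
    geometry: AcquisitionGeometry,
    pad: int | str = "half",
    unsharp_sigma: float | None = None,
    unsharp_weight: float = 0.0,
) -> np.ndarray:
    """Apply single-distance phase retrieval to one normalized projection.

    Parameters
    ----------
    projection : 2D ndarray
        Flat-field normalized intensities I/I0; must be finite and > 0.
    geometry : AcquisitionGeometry
    pad : "half" or int
        Symmetric reflect padding width per edge before the FFT (anti
        wraparound); "half" pads by half the image size per axis, 0 disables
        padding (periodic boundaries).
    unsharp_sigma, unsharp_weight :
        Optional post-retrieval unsharp-mask sharpening
        ``out + w * (out - G_sigma(out))``, off by default.

    Returns
    -------
    2D ndarray of retrieved values, same shape as the input.
    """
    proj = np.asarray(projection, dtype=float)
    if proj.ndim != 2:
        raise ValueError(f"projection must be 2D, got {proj.ndim}D")
    if not np.all(np.isfinite(proj)):
        raise ValueError("projection contains NaN/Inf")
    if np.any(proj <= 0):
        raise ValueError("projection must be strictly positive (I/I0); log undefined")

    ny, nx = proj.shape
    if pad == "half":
        pw = (ny // 2, nx // 2)
    else:
        pw = (int(pad), int(pad))
    if any(p < 0 for p in pw):
        raise ValueError("pad must be >= 0")
    if any(pw):
        proj_p = np.pad(proj, ((pw[0], pw[0]), (pw[1], pw[1])), mode="reflect")
    else:
        proj_p = proj

    pix_m = geometry.pixel_um * 1e-6
    z_m = geometry.distance_mm * 1e-3
    lam = geometry.wavelength_m
    ky = 2.0 * np.pi * np.fft.fftfreq(proj_p.shape[0], d=pix_m)
    kx = 2.0 * np.pi * np.fft.fftfreq(proj_p.shape[1], d=pix_m)
    k2 = ky[:, None] ** 2 + kx[None, :] ** 2
    denom = 1.0 + geometry.delta_beta * lam * z_m / (4.0 * np.pi) * k2

    filtered = np.fft.ifft2(np.fft.fft2(proj_p) / denom).real
    if np.any(filtered <= 0):
        raise ValueError("filtered intensity has non-positive values; log undefined")
    out = -np.log(filtered)
    out = out[pw[0] : pw[0] + ny, pw[1] : pw[1] + nx]

    if unsharp_sigma is not None and unsharp_weight != 0.0:
        out = out + unsharp_weight * (out - gaussian_filter(out, unsharp_sigma))
    return out
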