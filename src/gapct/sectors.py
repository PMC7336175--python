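"""Azimuthal sector analysis around the restoration/post axis.

With the post centre as pivot, the bonded and gap footprints are divided
into n equal azimuthal sectors (18 sectors of 20 degrees by default) and the
per-sector ratio of gap to bonded area is reported against the angular axis.
Angles follow the package convention: 0 deg at +x, counter-clockwise in the
(x, y) slice plane, half-open sectors [k*360/n, (k+1)*360/n).
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
import pandas as pd

from .areas import Footprint2D

__all__ = [
    "SectorProfile",
    "estimate_center",
    "sector_partition",
    "sector_profile",
    "profile_plot",
]


@dataclasses.dataclass
class SectorProfile:
    """Per-sector bonded area, gap area and gap percentage.

    ``percent_gap`` is NaN for sectors with no bonded area (undefined rather
    than 0 or 100). Per-sector areas partition the global footprint areas
    exactly; only a pixel lying exactly at the centre (radius 0, undefined
    angle) is excluded.
    """

    n: int
    center: tuple[float, float]
    pixel_um: float
    bonded_area_um2: np.ndarray
    gap_area_um2: np.ndarray
    percent_gap: np.ndarray

    @property
    def starts_deg(self) -> np.ndarray:
        return np.arange(self.n) * 360.0 / self.n

    def to_frame(self) -> pd.DataFrame:
        width = 360.0 / self.n
        return pd.DataFrame(
            {
                "sector": np.arange(self.n),
                "start_deg": self.starts_deg,
                "end_deg": self.starts_deg + width,
                "bonded_area_um2": self.bonded_area_um2,
                "gap_area_um2": self.gap_area_um2,
                "percent_gap": self.percent_gap,
            }
        )


def estimate_center(mask: np.ndarray) -> tuple[float, float]:
    """Centroid (cy, cx) of a post mask's axial footprint.

    Accepts a 2D footprint or a 3D mask (projected along z first). An
    explicit user-supplied centre always takes precedence over this estimate
    in the pipeline; this is the automated fallback.
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.ndim == 3:
        mask = mask.any(axis=0)
    if mask.ndim != 2:
        raise ValueError("mask must be 2D or 3D")
    if not mask.any():
        raise ValueError("empty mask: cannot estimate a centre, supply one explicitly")
    ys, xs = np.nonzero(mask)
    return float(ys.mean()), float(xs.mean())


def sector_partition(n: int) -> np.ndarray:
    """n half-open angular intervals [k*360/n, (k+1)*360/n), shape (n, 2)."""
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    edges = np.arange(n + 1) * 360.0 / n
    return np.column_stack([edges[:-1], edges[1:]])


def _sector_index(shape, center, n) -> tuple[np.ndarray, np.ndarray]:
    ny, nx = shape
    cy, cx = center
    y = np.arange(ny, dtype=float)[:, None] - cy
    x = np.arange(nx, dtype=float)[None, :] - cx
    r = np.hypot(y, x)
    theta = np.mod(np.degrees(np.arctan2(y, x)), 360.0)
    idx = np.minimum((theta * n / 360.0).astype(int), n - 1)
    return idx, r


def sector_profile(gap: Footprint2D, bonded: Footprint2D, center, n: int = 18) -> SectorProfile:
    """Assign footprint pixels to azimuthal sectors and form per-sector ratios."""
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    if gap.mask.shape != bonded.mask.shape:
        raise ValueError("footprints must share the same grid")
    if gap.pixel_um != bonded.pixel_um:
        raise ValueError("footprints must share the same pixel size")
    ny, nx = bonded.mask.shape
    cy, cx = center
    if not (0 <= cy <= ny - 1 and 0 <= cx <= nx - 1):
        raise ValueError(f"center ({cy}, {cx}) lies outside the image")

    idx, r = _sector_index((ny, nx), center, n)
    valid = r > 0  # the exact-centre pixel has no defined angle
    px2 = bonded.pixel_um**2
    bonded_counts = np.bincount(idx[bonded.mask & valid], minlength=n)
    gap_counts = np.bincount(idx[gap.mask & bonded.mask & valid], minlength=n)
    with np.errstate(divide="ignore", invalid="ignore"):
        pct = np.where(bonded_counts > 0, 100.0 * gap_counts / bonded_counts, np.nan)
    return SectorProfile(
        n=n,
        center=(float(cy), float(cx)),
        pixel_um=bonded.pixel_um,
        bonded_area_um2=bonded_counts * px2,
        gap_area_um2=gap_counts * px2,
        percent_gap=pct,
    )


def profile_plot(profile: SectorProfile, path, csv_path=None) -> Path:
    """Bar plot of percent gap vs sector start angle, plus a CSV twin.

    Undefined (no-bonded-area) sectors are drawn as hatched full-height bars.
    The CSV (default: same name with .csv suffix) holds the numeric profile
    and round-trips exactly.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    path = Path(path)
    csv_path = Path(csv_path) if csv_path is not None else path.with_suffix(".csv")
    frame = profile.to_frame()
    # %.17g guarantees an exact float round trip through the CSV
    frame.to_csv(csv_path, index=False, float_format="%.17g")

    width = 360.0 / profile.n
    fig, ax = plt.subplots(figsize=(7, 3.2))
    defined = ~np.isnan(profile.percent_gap)
    ax.bar(
        profile.starts_deg[defined],
        profile.percent_gap[defined],
        width=width * 0.92,
        align="edge",
        color="#b22222",
    )
    if (~defined).any():
        ax.bar(
            profile.starts_deg[~defined],
            np.full((~defined).sum(), 100.0),
            width=width * 0.92,
            align="edge",
            fill=False,
            hatch="//",
            edgecolor="grey",
            label="no bonded area",
        )
        ax.legend(frameon=False)
    ax.set_xlabel("azimuth (deg, 0 deg = +x, CCW)")
    ax.set_ylabel("gaps / bonded area (%)")
    ax.set_xlim(0, 360)
    ax.set_ylim(0, 105)
    ax.set_xticks(np.arange(0, 361, 60))
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return path
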