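"""Regional multispectral images: band-power topographies on a 40x40 RGB grid.

For one region, each band's per-electrode features are min-max normalized to
[0, 1], interpolated onto a regular grid over the projection plane with the
piecewise-cubic Clough-Tocher scheme, and stacked as color channels:
R = theta, G = alpha, B = beta. Pixels outside the convex hull of the
projected electrodes (where triangulated interpolation is undefined) are 0.

Pixel convention: row 0 holds the maximal v coordinate (nose-up), column 0
the minimal u (left ear to the left). All regions share one grid window —
the padded bounding square of the full-montage projection — so regional
images are spatially commensurable before fusion.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.interpolate import CloughTocher2DInterpolator

from .montage import Projection2D
from .spectral import BAND_ORDER, BandPowerFeatures

__all__ = [
    "MultispectralImage",
    "TopomapError",
    "grid_bounds_for",
    "make_region_image",
    "save_image_archive",
    "load_image_archive",
    "save_png",
]

GRID_N = 40


class TopomapError(ValueError):
    """Raised for degenerate electrode geometry or invalid image data."""


@dataclass(frozen=True)
class MultispectralImage:
    """A ``grid_n x grid_n x 3`` image of band-power topographies in [0, 1]."""

    pixels: np.ndarray
    region: str
    grid_bounds: tuple[float, float, float, float]  # (u_min, u_max, v_min, v_max)

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels, dtype=float)
        object.__setattr__(self, "pixels", px)
        object.__setattr__(self, "grid_bounds", tuple(float(b) for b in self.grid_bounds))
        if px.ndim != 3 or px.shape[2] != 3 or px.shape[0] != px.shape[1]:
            raise TopomapError(f"pixels must be n x n x 3, got {px.shape}")
        if not np.all(np.isfinite(px)):
            raise TopomapError("non-finite pixel values")
        if px.min() < -1e-12 or px.max() > 1 + 1e-12:
            raise TopomapError("pixel values outside [0, 1]")

    @property
    def grid_n(self) -> int:
        return self.pixels.shape[0]


def grid_bounds_for(proj: Projection2D, pad: float = 0.05) -> tuple[float, float, float, float]:
    """Bounding square of a projection, padded by ``pad`` of the side length.

    Typically called on the full-montage projection so that every regional
    image shares the same window.
    """
    uv = proj.coords2d
    u_min, v_min = uv.min(axis=0)
    u_max, v_max = uv.max(axis=0)
    side = max(u_max - u_min, v_max - v_min)
    cu, cv = (u_min + u_max) / 2, (v_min + v_max) / 2
    half = side / 2 * (1 + 2 * pad)
    return (cu - half, cu + half, cv - half, cv + half)


def _grid_axes(bounds: tuple[float, float, float, float], grid_n: int):
    u_min, u_max, v_min, v_max = bounds
    u = np.linspace(u_min, u_max, grid_n)
    v = np.linspace(v_max, v_min, grid_n)  # row 0 = max v (nose up)
    return u, v


def make_region_image(
    features: BandPowerFeatures,
    proj: Projection2D,
    grid_bounds: tuple[float, float, float, float] | None = None,
    grid_n: int = GRID_N,
    region: str = "",
) -> MultispectralImage:
    """Interpolate one region's band features into a multispectral image.

    ``features`` rows must match ``proj`` electrode order. Each band is
    min-max normalized over the region's electrodes before interpolation;
    a constant band (max == min) renders as 0.5 inside the hull so the
    image stays a valid color map. Requires at least three non-collinear
    projected points.
    """
    pts = proj.coords2d
    if features.values.shape[0] != pts.shape[0]:
        raise TopomapError("feature rows do not match projected electrode count")
    if pts.shape[0] < 3:
        raise TopomapError(f"need at least 3 electrodes to interpolate, got {pts.shape[0]}")
    # collinearity check: rank of centered points < 2 means no triangle
    centered = pts - pts.mean(axis=0)
    if np.linalg.matrix_rank(centered, tol=1e-10) < 2:
        raise TopomapError("projected electrodes are collinear; cannot triangulate")

    if grid_bounds is None:
        grid_bounds = grid_bounds_for(proj)
    u, v = _grid_axes(grid_bounds, grid_n)
    uu, vv = np.meshgrid(u, v)

    channels = []
    for j in range(len(BAND_ORDER)):
        vals = features.values[:, j]
        lo, hi = vals.min(), vals.max()
        if hi - lo < 1e-300:
            norm = np.full_like(vals, 0.5)
        else:
            norm = (vals - lo) / (hi - lo)
        interp = CloughTocher2DInterpolator(pts, norm)
        grid = interp(uu, vv)
        grid = np.where(np.isnan(grid), 0.0, grid)
        # cubic interpolation can overshoot the data range slightly
        channels.append(np.clip(grid, 0.0, 1.0))
    return MultispectralImage(np.dstack(channels), region or "region", grid_bounds)


# --- persistence -----------------------------------------------------------

def save_image_archive(img: MultispectralImage, path: str | Path) -> None:
    """Write exact float pixels as ``.npy`` plus a JSON metadata sidecar.

    The sidecar (``<path>.json``) records the region tag, grid bounds, and
    pixel convention. Plain ``.npy`` output is byte-stable across reruns.
    """
    path = Path(path)
    np.save(path, img.pixels.astype(np.float64))
    meta = {
        "region": img.region,
        "grid_bounds": list(img.grid_bounds),
        "grid_n": img.grid_n,
        "pixel_convention": "row 0 = max v (nose up), column 0 = min u",
        "channels": list(BAND_ORDER),
    }
    sidecar = path.with_suffix(path.suffix + ".json") if path.suffix != ".npy" else Path(str(path) + ".json")
    sidecar.write_text(json.dumps(meta, sort_keys=True, indent=1) + "\n")


def load_image_archive(path: str | Path) -> MultispectralImage:
    path = Path(path)
    pixels = np.load(path)
    sidecar = Path(str(path) + ".json")
    if not sidecar.exists() and path.suffix == ".npy":
        sidecar = Path(str(path.with_suffix("")) + ".npy.json")
    meta = json.loads(sidecar.read_text())
    return MultispectralImage(pixels, meta["region"], tuple(meta["grid_bounds"]))


def save_png(img: MultispectralImage, path: str | Path) -> None:
    """8-bit PNG for visual inspection (lossy quantization of the float image)."""
    import imageio.v3 as iio

    iio.imwrite(Path(path), (np.round(img.pixels * 255)).astype(np.uint8))
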