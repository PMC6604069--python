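"""Geometric validation models and image binarization for box counting.

Provides the reference objects whose fractal dimensions are known at every
length scale: a 1-D chain of spheres rasterised into a 3-D voxel grid
(volume-like at scales below the sphere radius, line-like far above it,
and dot-like in between when the radius is below the sphere spacing), and
simple 2-D box/line rasters.  Also a thresholding helper to turn grayscale
micrographs into binary occupancy maps.
"""

from __future__ import annotations

from dataclasses import dataclass
import warnings

import numpy as np

from .relaxation_models import DomainError, ParameterError

_MAX_VOXELS = int(1e8)


@dataclass(frozen=True)
class SphereChainSpec:
    """Chain of ``n_spheres`` spheres of radius ``radius_R`` whose centres
    sit on a line with spacing ``spacing_d`` (all in model units);
    ``voxel_size`` is the rasterisation pitch."""

    n_spheres: int = 100
    spacing_d: float = 1.5
    radius_R: float = 1.0
    voxel_size: float = 0.1

    def __post_init__(self) -> None:
        if self.n_spheres < 1:
            raise ParameterError("n_spheres must be >= 1")
        if not self.spacing_d > 0:
            raise ParameterError("spacing_d must be > 0")
        if not 0.05 <= self.radius_R <= 20.0:
            raise ParameterError("radius_R supported range is [0.05, 20]")
        if not self.voxel_size > 0:
            raise ParameterError("voxel_size must be > 0")


@dataclass(frozen=True)
class BinaryImage2D:
    """2-D boolean occupancy raster with a physical cell size."""

    occupancy: np.ndarray
    cell_size: float = 1.0

    def __post_init__(self) -> None:
        occ = np.asarray(self.occupancy, dtype=bool)
        if occ.ndim != 2 or min(occ.shape) < 1:
            raise DomainError("occupancy must be a non-empty 2-D array")
        object.__setattr__(self, "occupancy", occ)

    @property
    def shape(self) -> tuple[int, ...]:
        return self.occupancy.shape

    @property
    def occupied_fraction(self) -> float:
        return float(self.occupancy.mean())


@dataclass(frozen=True)
class VoxelGrid3D:
    """3-D boolean occupancy raster with a physical cell size."""

    occupancy: np.ndarray
    cell_size: float = 1.0

    def __post_init__(self) -> None:
        occ = np.asarray(self.occupancy, dtype=bool)
        if occ.ndim != 3 or min(occ.shape) < 1:
            raise DomainError("occupancy must be a non-empty 3-D array")
        object.__setattr__(self, "occupancy", occ)

    @property
    def shape(self) -> tuple[int, ...]:
        return self.occupancy.shape


def make_sphere_chain(spec: SphereChainSpec, pad_radii: float = 1.0) -> VoxelGrid3D:
    """Rasterise the sphere chain into a voxel grid.

    Sphere centres sit at ``i * spacing_d`` (i = 0..n-1) along the last
    axis, on the transverse midline.  A voxel is occupied iff its centre
    lies within ``radius_R`` of any sphere centre (centre-inclusion: fast
    and deterministic, no partial-volume weighting).  The grid extends
    ``pad_radii`` sphere radii beyond the geometry on every side.
    """
    if pad_radii < 1.0:
        raise ParameterError("grid must be padded by at least one radius")
    n, d, R, h = spec.n_spheres, spec.spacing_d, spec.radius_R, spec.voxel_size
    if h > R / 2:
        warnings.warn(
            f"voxel_size {h} is coarse relative to radius {R}; "
            "expect strong rasterisation error",
            stacklevel=2,
        )
    pad = pad_radii * R
    ax_lo, ax_hi = -R - pad, (n - 1) * d + R + pad
    tr_lo, tr_hi = -R - pad, R + pad
    n_ax = int(np.ceil((ax_hi - ax_lo) / h))
    n_tr = int(np.ceil((tr_hi - tr_lo) / h))
    if n_tr * n_tr * n_ax > _MAX_VOXELS:
        raise MemoryError(
            f"grid would need {n_tr * n_tr * n_ax:.2e} voxels (> {_MAX_VOXELS:.0e})"
        )
    # Voxel-centre coordinates.
    z = ax_lo + (np.arange(n_ax) + 0.5) * h
    t = tr_lo + (np.arange(n_tr) + 0.5) * h
    # Squared distance to the nearest sphere centre along the axis: the
    # centres form a uniform lattice, so the nearest is found by rounding
    # (checking the two neighbours guards the clamped ends).
    idx = np.clip(np.round(z / d), 0, n - 1)
    dz2 = np.minimum.reduce(
        [(z - np.clip(idx + k, 0, n - 1) * d) ** 2 for k in (-1, 0, 1)]
    )
    r2 = t[:, None] ** 2 + t[None, :] ** 2
    occ = (r2[:, :, None] + dz2[None, None, :]) <= R * R
    return VoxelGrid3D(occupancy=occ, cell_size=h)


def make_box_model(
    kind: str, size: int = 512, line_width: int = 2, orientation: str = "horizontal"
) -> BinaryImage2D:
    """The 2-D reference rasters: full box, half box, or a solid line.

    ``full``: every pixel occupied (dimension 2).  ``half``: the left half
    occupied (same dimension, shifted intercept).  ``line``: a solid
    axis-aligned line of ``line_width`` pixels through the image centre,
    spanning the full width (dimension 1 above the line width, 2 below).
    """
    if size < 64:
        raise ParameterError("size must be >= 64")
    occ = np.zeros((size, size), dtype=bool)
    if kind == "full":
        occ[:, :] = True
    elif kind == "half":
        occ[:, : size // 2] = True
    elif kind == "line":
        if not 1 <= line_width < size:
            raise ParameterError("line_width must be in [1, size)")
        lo = size // 2
        if orientation == "horizontal":
            occ[lo : lo + line_width, :] = True
        elif orientation == "vertical":
            occ[:, lo : lo + line_width] = True
        else:
            raise ParameterError(f"unknown orientation {orientation!r}")
    else:
        raise ParameterError(f"unknown kind {kind!r}: use full, half or line")
    return BinaryImage2D(occupancy=occ)


def binarize(
    image: np.ndarray,
    threshold: float | str = "auto",
    dark_foreground: bool = True,
) -> BinaryImage2D:
    """Threshold a single-channel grayscale image into a binary raster.

    ``threshold="auto"`` uses Otsu's criterion (maximal between-class
    variance, the standard histogram-valley method).  With
    ``dark_foreground=True`` (default, matching stained fibrous tissue on
    a bright background) pixels *below* the threshold become foreground.
    """
    img = np.asarray(image, dtype=float)
    if img.ndim != 2:
        raise DomainError("binarize expects a single-channel 2-D image")
    if isinstance(threshold, str):
        if threshold != "auto":
            raise ParameterError(f"unknown threshold mode {threshold!r}")
        if np.ptp(img) == 0:
            raise DomainError("constant image: automatic threshold undefined")
        thr = _otsu(img)
    else:
        thr = float(threshold)
    occ = img < thr if dark_foreground else img >= thr
    return BinaryImage2D(occupancy=occ)


def _otsu(img: np.ndarray, nbins: int = 256) -> float:
    hist, edges = np.histogram(img.ravel(), bins=nbins)
    centers = 0.5 * (edges[:-1] + edges[1:])
    w = hist.astype(float)
    p = w / w.sum()
    w0 = np.cumsum(p)
    w1 = 1.0 - w0
    mu = np.cumsum(p * centers)
    mu_t = mu[-1]
    with np.errstate(divide="ignore", invalid="ignore"):
        var_between = (mu_t * w0 - mu) ** 2 / (w0 * w1)
    var_between[~np.isfinite(var_between)] = -1.0
    k = int(np.argmax(var_between))
    return float(edges[k + 1])


def analytic_sphere_chain_volume(spec: SphereChainSpec) -> float:
    """Volume of the union of the chain spheres (model units cubed).

    Exact when at most consecutive spheres overlap (``spacing_d >=
    radius_R``): inclusion-exclusion with one spherical lens per
    consecutive pair.  For strongly overlapping chains (``spacing_d <
    radius_R``) the union is capsule-like and the capsule volume
    ``pi R^2 L + 4/3 pi R^3`` (L = chain length) is returned -- an upper
    bound accurate to O((d/R)^2), adequate for convergence checks.
    """
    n, d, R = spec.n_spheres, spec.spacing_d, spec.radius_R
    v_sphere = 4.0 / 3.0 * np.pi * R**3
    if n == 1 or d >= 2 * R:
        return float(n * v_sphere)
    if d >= R:
        # spherical lens (intersection of two spheres at distance d)
        lens = np.pi * (2 * R - d) ** 2 * (d**2 + 4 * d * R) / (12 * d)
        return float(n * v_sphere - (n - 1) * lens)
    return float(np.pi * R**2 * (n - 1) * d + v_sphere)
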