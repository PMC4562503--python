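"""Display geometry, pixel-exact shape masks, and filling-in features.

The display is a square random-dot matrix of ``matrix_px`` pixels per side
subtending ``matrix_deg`` degrees of visual angle (the default 600 px /
19.15 deg gives 0.0319 deg per pixel).  Annuli and disks are rasterized on a
pixel-center grid with a half-open radial interval ``[r, R)`` so that nested
shapes never double-count a boundary pixel.

Annulus size conventions
------------------------
The printed annulus numbers (outer diameter 100 or 200 px, "thickness" 25 or
75 px) cannot all be read as diameter plus ring width: a 100-px-diameter
annulus cannot have a 75-px ring.  Two self-consistent readings are supported:

``DIAMETER_DIFF`` (default)
    size = outer diameter, thickness = outer minus inner diameter, so the ring
    width is thickness / 2.  All four annuli then fit a central 300 x 300 px
    region, and the small/thick annulus has exactly the same area as the
    large/thin one.
``RADIUS_WIDTH``
    size = outer radius, thickness = ring width.  Also equal-area, but the
    large annuli would span 400 px.
``DIAMETER_WIDTH``
    the naive reading (size = outer diameter, thickness = ring width); it is
    geometrically impossible for the small/thick annulus and exists so that
    constructing it fails loudly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Optional, Tuple, Union

import numpy as np

__all__ = [
    "AnnulusConvention",
    "DisplayGeometry",
    "AnnulusSpec",
    "DiskSpec",
    "FillInFeatures",
    "px_to_deg",
    "deg_to_px",
    "shape_mask",
    "fillin_features",
]


class AnnulusConvention(str, Enum):
    """How the printed (size, thickness) pair maps to inner/outer radii."""

    DIAMETER_DIFF = "diameter_diff"
    RADIUS_WIDTH = "radius_width"
    DIAMETER_WIDTH = "diameter_width"


@dataclass(frozen=True)
class DisplayGeometry:
    """Square pixel matrix and the visual angle it subtends."""

    matrix_px: int = 600
    matrix_deg: float = 19.15

    def __post_init__(self) -> None:
        if self.matrix_px <= 0:
            raise ValueError(f"matrix_px must be positive, got {self.matrix_px}")
        if self.matrix_deg <= 0:
            raise ValueError(f"matrix_deg must be positive, got {self.matrix_deg}")

    @property
    def deg_per_px(self) -> float:
        return self.matrix_deg / self.matrix_px

    @property
    def center(self) -> Tuple[float, float]:
        """Continuous (row, col) coordinates of the matrix center, 0-based."""
        c = (self.matrix_px - 1) / 2.0
        return (c, c)


def px_to_deg(n_px, geom: DisplayGeometry):
    """Convert a pixel length to degrees of visual angle.

    Accepts scalars or arrays; negative lengths are a domain error.
    """
    n_px = np.asarray(n_px, dtype=float)
    if np.any(n_px < 0):
        raise ValueError("pixel length must be non-negative")
    out = n_px * geom.deg_per_px
    return float(out) if out.ndim == 0 else out


def deg_to_px(deg, geom: DisplayGeometry):
    """Convert degrees of visual angle to a pixel length (inverse of px_to_deg)."""
    deg = np.asarray(deg, dtype=float)
    if np.any(deg < 0):
        raise ValueError("visual angle must be non-negative")
    out = deg / geom.deg_per_px
    return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class AnnulusSpec:
    """An annulus given by the printed size/thickness numbers plus a convention.

    ``center`` is a continuous (row, col) pixel coordinate; None means the
    matrix center.
    """

    size_value_px: float
    thickness_value_px: float
    convention: AnnulusConvention = AnnulusConvention.DIAMETER_DIFF
    center: Optional[Tuple[float, float]] = None

    def __post_init__(self) -> None:
        if self.size_value_px <= 0 or self.thickness_value_px <= 0:
            raise ValueError("size and thickness must be positive")
        r, R = self.radii_px  # validates the convention
        if r < 0:
            raise ValueError(
                f"annulus (size={self.size_value_px}, thickness="
                f"{self.thickness_value_px}) under convention "
                f"{self.convention.value} yields negative inner radius {r}"
            )
        if R <= r:
            raise ValueError("outer radius must exceed inner radius")

    @property
    def radii_px(self) -> Tuple[float, float]:
        """(inner, outer) radius in pixels under the chosen convention."""
        s, t = self.size_value_px, self.thickness_value_px
        if self.convention is AnnulusConvention.DIAMETER_DIFF:
            R = s / 2.0
            r = (s - t) / 2.0
        elif self.convention is AnnulusConvention.RADIUS_WIDTH:
            R = s
            r = s - t
        elif self.convention is AnnulusConvention.DIAMETER_WIDTH:
            R = s / 2.0
            r = R - t
        else:  # pragma: no cover - enum is closed
            raise ValueError(f"unknown convention {self.convention!r}")
        return (r, R)


@dataclass(frozen=True)
class DiskSpec:
    """A disk given in degrees: diameter, eccentricity, displacement direction."""

    diameter_deg: float
    eccentricity_deg: float = 0.0
    direction_rad: float = 0.0

    def __post_init__(self) -> None:
        if self.diameter_deg <= 0:
            raise ValueError("diameter_deg must be positive")
        if self.eccentricity_deg < 0:
            raise ValueError("eccentricity_deg must be non-negative")


@dataclass(frozen=True)
class FillInFeatures:
    """Contour length C and filling-in distance D_fill, both in pixels."""

    contour_len_px: float
    fill_dist_px: float

    def __post_init__(self) -> None:
        if self.contour_len_px < 0 or self.fill_dist_px < 0:
            raise ValueError("features must be non-negative")


def _disk_center_px(spec: DiskSpec, geom: DisplayGeometry) -> Tuple[float, float]:
    cy, cx = geom.center
    ecc_px = deg_to_px(spec.eccentricity_deg, geom)
    # direction 0 = rightward; rows grow downward so sin() displaces down
    return (cy + ecc_px * math.sin(spec.direction_rad),
            cx + ecc_px * math.cos(spec.direction_rad))


def _resolve(spec: Union[AnnulusSpec, DiskSpec], geom: DisplayGeometry):
    """Return (center, inner radius, outer radius) in pixels."""
    if isinstance(spec, AnnulusSpec):
        center = spec.center if spec.center is not None else geom.center
        r, R = spec.radii_px
    elif isinstance(spec, DiskSpec):
        center = _disk_center_px(spec, geom)
        r, R = 0.0, deg_to_px(spec.diameter_deg, geom) / 2.0
    else:
        raise TypeError(f"expected AnnulusSpec or DiskSpec, got {type(spec)!r}")
    return center, r, R


def shape_mask(
    spec: Union[AnnulusSpec, DiskSpec],
    geom: DisplayGeometry,
    *,
    allow_clip: bool = False,
) -> np.ndarray:
    """Rasterize an annulus or disk as a boolean pixel mask.

    A pixel belongs to the mask iff its center lies at radial distance d from
    the shape center with r <= d < R (annulus) or d < R (disk).  If the shape
    extends beyond the matrix an error reporting the overflow in pixels is
    raised unless ``allow_clip`` is set.
    """
    (cy, cx), r, R = _resolve(spec, geom)
    n = geom.matrix_px
    # pixel centers occupy [-0.5, n - 0.5) in continuous coordinates
    overflow = max(R - 0.5 - cy, R - 0.5 - cx,
                   cy + R - (n - 0.5), cx + R - (n - 0.5))
    if overflow > 0 and not allow_clip:
        raise ValueError(
            f"shape extends {overflow:.2f} px beyond the {n}x{n} matrix "
            "(pass allow_clip=True to clip)"
        )
    yy, xx = np.ogrid[:n, :n]
    d2 = (yy - cy) ** 2 + (xx - cx) ** 2
    mask = d2 < R ** 2
    if r > 0:
        mask &= d2 >= r ** 2
    return mask


def fillin_features(
    spec: Union[AnnulusSpec, DiskSpec],
    geom: DisplayGeometry,
    *,
    use_printed_thickness: bool = False,
) -> FillInFeatures:
    """Contour length and filling-in distance for the filling-in regression.

    Disk: the contour is the outer circumference 2*pi*R and the filling-in
    distance the radius R (diffusive spread from the edge to the center).
    Annulus: both edges emit the edge signal, so C = 2*pi*(R + r), and the
    distance to fill is the physical ring width R - r.  With
    ``use_printed_thickness`` the printed thickness number is used as the
    distance instead of the derived ring width (they differ by a factor of two
    under the DIAMETER_DIFF convention).
    """
    _, r, R = _resolve(spec, geom)
    if isinstance(spec, DiskSpec):
        return FillInFeatures(2 * math.pi * R, R)
    dist = spec.thickness_value_px if use_printed_thickness else (R - r)
    return FillInFeatures(2 * math.pi * (R + r), dist)
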