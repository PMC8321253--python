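"""Region of interest: domain boundary, inward contraction, field preparation.

Reconstructed microwave images frequently carry spurious artefacts on the
periphery of the imaging domain (near the skin/immersion interface).  The
segmentation therefore operates on a region of interest ℛ obtained by
uniformly contracting the imaging-domain boundary inward by a few
millimetres (3.5 mm by default elsewhere in the package), which excludes
those peripheral artefacts from analysis.  Elements outside ℛ are set to
a sentinel value far below any tissue permittivity so that the background
always forms the lowest-valued cluster.

Grid convention: row-major, 0-based; x = col·spacing, y = row·spacing (mm).
Contours are reported in mm as ordered closed loops of pixel-corner
points ("crack" boundary), so a one-pixel region yields its four corners.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

__all__ = [
    "RegionMask",
    "PreparedField",
    "DEFAULT_SENTINEL",
    "domain_boundary",
    "contract_roi",
    "prepare_field",
    "trace_crack_boundaries",
]

DEFAULT_SENTINEL = -100.0

_STRUCT8 = np.ones((3, 3), dtype=bool)  # 8-connectivity


@dataclass(frozen=True)
class RegionMask:
    """A binary mask on the image grid with physical pixel spacing."""

    grid: np.ndarray
    pixel_spacing_mm: float

    def __post_init__(self) -> None:
        arr = np.asarray(self.grid)
        if arr.ndim != 2:
            raise ValueError(f"mask must be 2D, got shape {arr.shape}")
        if not np.isin(arr, (0, 1, False, True)).all():
            raise ValueError("mask values must be binary (0/1)")
        if not self.pixel_spacing_mm > 0:
            raise ValueError("pixel_spacing_mm must be positive")
        object.__setattr__(self, "grid", arr.astype(np.uint8))

    @property
    def shape(self) -> tuple[int, int]:
        return self.grid.shape

    def as_bool(self) -> np.ndarray:
        return self.grid.astype(bool)

    def count(self) -> int:
        return int(self.grid.sum())

    def __and__(self, other: "RegionMask") -> "RegionMask":
        return RegionMask(self.grid & other.grid, self.pixel_spacing_mm)


@dataclass(frozen=True)
class PreparedField:
    """Clustering input ℬ = ℛ ∪ ℛᶜ: image values inside ℛ, sentinel outside."""

    values: np.ndarray
    roi_mask: RegionMask
    sentinel: float = DEFAULT_SENTINEL

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=float)
        if vals.shape != self.roi_mask.shape:
            raise ValueError("values and mask shapes must match")
        inside = self.roi_mask.as_bool()
        if not np.all(vals[~inside] == self.sentinel):
            raise ValueError("values outside the ROI must equal the sentinel")
        if inside.any() and not self.sentinel < vals[inside].min():
            raise ValueError("sentinel must lie strictly below all ROI values")
        object.__setattr__(self, "values", vals)

    def interior_values(self) -> np.ndarray:
        """Flat array of the values inside ℛ."""
        return self.values[self.roi_mask.as_bool()]


# ---------------------------------------------------------------------------
# Crack-boundary tracing
# ---------------------------------------------------------------------------

def trace_crack_boundaries(mask: np.ndarray, pixel_spacing_mm: float
                           ) -> list[list[tuple[float, float]]]:
    """Trace the boundary of a binary mask as closed loops of corner points.

    Each loop follows the "cracks" between mask and non-mask pixels, so a
    single pixel yields its four corner points and every contour point of
    a digitized disk lies within spacing/√2 of the true circle.  Points
    are (x, y) in mm; loops are ordered and closed (last edge returns to
    the first point, which is not repeated).
    """
    arr = np.asarray(mask).astype(bool)
    nrows, ncols = arr.shape
    # Directed crack edges, region kept on a consistent side; keys are
    # corner coordinates doubled to stay integral.
    edges: dict[tuple[int, int], list[tuple[int, int]]] = {}

    def add(r0: float, c0: float, r1: float, c1: float) -> None:
        start = (int(round(2 * r0)), int(round(2 * c0)))
        end = (int(round(2 * r1)), int(round(2 * c1)))
        edges.setdefault(start, []).append(end)

    rs, cs = np.nonzero(arr)
    for r, c in zip(rs.tolist(), cs.tolist()):
        if r == 0 or not arr[r - 1, c]:          # top: +col
            add(r - 0.5, c - 0.5, r - 0.5, c + 0.5)
        if c == ncols - 1 or not arr[r, c + 1]:  # right: +row
            add(r - 0.5, c + 0.5, r + 0.5, c + 0.5)
        if r == nrows - 1 or not arr[r + 1, c]:  # bottom: -col
            add(r + 0.5, c + 0.5, r + 0.5, c - 0.5)
        if c == 0 or not arr[r, c - 1]:          # left: -row
            add(r + 0.5, c - 0.5, r - 0.5, c - 0.5)

    loops: list[list[tuple[int, int]]] = []
    while edges:
        start = min(edges)
        loop = [start]
        prev_dir: tuple[int, int] | None = None
        current = start
        while True:
            candidates = edges[current]
            if len(candidates) == 1 or prev_dir is None:
                nxt = candidates[0]
            else:
                # Diagonal-touch corner: take the sharpest turn that keeps
                # the traversal on the same pixel (min cross product).
                def cross(end: tuple[int, int]) -> int:
                    d = (end[0] - current[0], end[1] - current[1])
                    return prev_dir[0] * d[1] - prev_dir[1] * d[0]
                nxt = min(candidates, key=cross)
            candidates.remove(nxt)
            if not candidates:
                del edges[current]
            prev_dir = (nxt[0] - current[0], nxt[1] - current[1])
            current = nxt
            if current == start:
                break
            loop.append(current)
        loops.append(loop)

    s = pixel_spacing_mm
    return [[(c / 2.0 * s, r / 2.0 * s) for r, c in loop] for loop in loops]


def _loop_area(loop: list[tuple[float, float]]) -> float:
    pts = np.asarray(loop, dtype=float)
    x, y = pts[:, 0], pts[:, 1]
    return 0.5 * float(np.abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1))))


def domain_boundary(image_support: RegionMask) -> list[tuple[float, float]]:
    """Ordered closed contour of the outer boundary of the imaging domain.

    The support must be a single 8-connected region; for a full-grid
    support the contour is the grid perimeter.

    Raises
    ------
    ValueError
        If the support is empty or disconnected.
    """
    arr = image_support.as_bool()
    if not arr.any():
        raise ValueError("imaging-domain support is empty")
    _, ncomp = ndimage.label(arr, structure=_STRUCT8)
    if ncomp != 1:
        raise ValueError(
            f"imaging-domain support is disconnected ({ncomp} components)"
        )
    loops = trace_crack_boundaries(arr, image_support.pixel_spacing_mm)
    return max(loops, key=_loop_area)


# ---------------------------------------------------------------------------
# ROI contraction and field preparation
# ---------------------------------------------------------------------------

def _disk_footprint(radius_px: int) -> np.ndarray:
    r = np.arange(-radius_px, radius_px + 1)
    yy, xx = np.meshgrid(r, r, indexing="ij")
    return (yy ** 2 + xx ** 2) <= radius_px ** 2


def contract_roi(domain_mask: RegionMask, distance_mm: float) -> RegionMask:
    """Contract the imaging domain uniformly inward by ``distance_mm``.

    Implemented as morphological erosion by a discrete disk of radius
    ``round(distance_mm / pixel_spacing_mm)`` pixels, the standard
    equivalent of a uniform inward boundary contraction.  The result is a
    subset of the input, and larger distances give nested subsets.

    Raises
    ------
    ValueError
        If ``distance_mm`` is negative or the erosion empties the mask.
    """
    if distance_mm < 0:
        raise ValueError("contraction distance must be nonnegative")
    radius_px = int(round(distance_mm / domain_mask.pixel_spacing_mm))
    if radius_px == 0:
        return RegionMask(domain_mask.grid.copy(), domain_mask.pixel_spacing_mm)
    eroded = ndimage.binary_erosion(
        domain_mask.as_bool(), structure=_disk_footprint(radius_px),
        border_value=0,
    )
    if not eroded.any():
        raise ValueError(
            f"ROI vanished: contracting by {distance_mm} mm "
            f"({radius_px} px) emptied the mask"
        )
    return RegionMask(eroded, domain_mask.pixel_spacing_mm)


def prepare_field(component_image: np.ndarray, roi_mask: RegionMask,
                  sentinel: float = DEFAULT_SENTINEL) -> PreparedField:
    """Build the clustering input: ROI values untouched, sentinel outside.

    The sentinel must lie strictly below the minimum value inside the
    ROI, which guarantees that the background forms its own, lowest
    cluster downstream.
    """
    img = np.asarray(component_image, dtype=float)
    if img.shape != roi_mask.shape:
        raise ValueError(
            f"image shape {img.shape} does not match mask shape {roi_mask.shape}"
        )
    inside = roi_mask.as_bool()
    if not inside.any():
        raise ValueError("ROI mask is empty")
    interior_min = img[inside].min()
    if sentinel >= interior_min:
        raise ValueError(
            f"sentinel {sentinel} is not below the ROI minimum "
            f"{interior_min}; choose a lower sentinel"
        )
    values = np.where(inside, img, sentinel)
    return PreparedField(values=values, roi_mask=roi_mask, sentinel=sentinel)
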