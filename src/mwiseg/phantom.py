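"""Synthetic dielectric breast phantoms and reconstruction-style degradation.

The generator emulates the inputs the segmentation framework consumes: a
2D complex-permittivity image of a breast cross-section with immersion
background, a thin skin ring, a fatty interior, a blobby fibroglandular
region wrapped in a fixed-width transition shell, and one or more
malignant (tumor) inclusions.  Tissue dielectric values are drawn from
ordered, partially overlapping ranges — fat < transition <
fibroglandular < malignant — mirroring the large-scale tissue-property
studies that motivate permittivity-based tissue discrimination.

Within the transition and fibroglandular ranges, values are drawn from
two sub-populations rather than a single uniform band.  Real breast
tissue shows considerable within-type heterogeneity of reconstructed
properties, and this multi-modal structure is what lets a value-based
clusterer allocate more than one cluster per heterogeneous tissue.

The degradation operator emulates the range of reconstruction quality an
inverse solver produces: blurred tissue interfaces (in-breast Gaussian
smoothing), per-element noise, a smooth multiplicative bias field, and
bright peripheral artefacts near the skin — the degradations the ROI
contraction and statistical termination are designed to tolerate.
Degradation never alters the ground-truth tissue map.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dataclass_field
from typing import Mapping, Sequence

import numpy as np
from scipy import ndimage

from .io import PermittivityImage
from .roi import RegionMask
from .segmentation import Tissue, TissueSegmentation

__all__ = [
    "PhantomSpec",
    "DegradationSpec",
    "GroundTruth",
    "DEFAULT_TISSUE_RANGES",
    "generate_phantom",
    "degrade",
]

#: Default complex-permittivity value ranges per tissue, (low, high) for the
#: real component; the loss (imaginary) component uses the same relative
#: draw scaled to a range one quarter the size.  Simulation defaults, not
#: claims about specific tissue measurements.
DEFAULT_TISSUE_RANGES: dict[Tissue, tuple[float, float]] = {
    Tissue.BACKGROUND: (2.0, 3.0),
    Tissue.FATTY: (4.0, 12.0),
    Tissue.TRANSITION: (12.0, 25.0),
    Tissue.FIBROGLANDULAR: (25.0, 45.0),
    Tissue.MALIGNANT: (50.0, 60.0),
    Tissue.SKIN: (30.0, 40.0),
}

#: Sub-population structure per tissue: (mode position, mode sd, weight)
#: in units relative to the tissue's range width.  Transition and
#: fibroglandular tissue are bimodal (within-type heterogeneity); fat,
#: tumor and skin are unimodal.
_TISSUE_MODES: dict[Tissue, tuple[tuple[float, float, float], ...]] = {
    Tissue.BACKGROUND: ((0.5, 0.20, 1.0),),
    Tissue.FATTY: ((0.125, 0.04, 1.0),),
    Tissue.TRANSITION: ((0.69, 0.04, 0.5), (0.92, 0.04, 0.5)),
    Tissue.FIBROGLANDULAR: ((0.45, 0.04, 0.5), (0.75, 0.04, 0.5)),
    Tissue.MALIGNANT: ((0.15, 0.08, 1.0),),
    Tissue.SKIN: ((0.5, 0.20, 1.0),),
}

#: Ratio of the loss-component range to the real-component range.
IMAG_SCALE = 0.25


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry, tissue ranges, and seed of a synthetic breast phantom.

    Tumor centers are (x, y) offsets in mm from the breast center;
    a tumor must lie fully inside the breast interior and its center
    inside the fibroglandular region.
    """

    grid_shape: tuple[int, int] = (120, 120)
    pixel_spacing_mm: float = 1.0
    breast_radius_mm: float = 50.0
    skin_thickness_mm: float = 2.0
    gland_blob_count: int = 6
    gland_fraction: float = 0.28
    tumor_centers_mm: tuple[tuple[float, float], ...] = ((0.0, 0.0),)
    tumor_radii_mm: tuple[float, ...] = (6.0,)
    transition_width_mm: float = 3.0
    tissue_value_ranges: Mapping[Tissue, tuple[float, float]] = dataclass_field(
        default_factory=lambda: dict(DEFAULT_TISSUE_RANGES)
    )
    range_overlap_fraction: float = 0.25
    seed: int = 0

    def __post_init__(self) -> None:
        rows, cols = self.grid_shape
        if rows <= 0 or cols <= 0:
            raise ValueError("grid_shape entries must be positive")
        for name in ("pixel_spacing_mm", "breast_radius_mm",
                     "skin_thickness_mm"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive")
        if self.gland_blob_count < 0:
            raise ValueError("gland_blob_count must be nonnegative")
        if not 0 < self.gland_fraction < 1:
            raise ValueError("gland_fraction must lie in (0, 1)")
        if len(self.tumor_centers_mm) != len(self.tumor_radii_mm):
            raise ValueError("tumor centers and radii counts differ")
        if any(r <= 0 for r in self.tumor_radii_mm):
            raise ValueError("tumor radii must be positive")
        interior_radius = self.breast_radius_mm - self.skin_thickness_mm
        for (cx, cy), r in zip(self.tumor_centers_mm, self.tumor_radii_mm):
            if np.hypot(cx, cy) + r > interior_radius:
                raise ValueError(
                    f"tumor at ({cx}, {cy}) mm radius {r} mm extends outside "
                    f"the breast interior (radius {interior_radius} mm)"
                )
        self._check_range_order()
        object.__setattr__(self, "tumor_centers_mm",
                           tuple((float(x), float(y))
                                 for x, y in self.tumor_centers_mm))
        object.__setattr__(self, "tumor_radii_mm",
                           tuple(float(r) for r in self.tumor_radii_mm))

    def _check_range_order(self) -> None:
        order = (Tissue.FATTY, Tissue.TRANSITION, Tissue.FIBROGLANDULAR,
                 Tissue.MALIGNANT)
        ranges = self.tissue_value_ranges
        for tissue in order:
            lo, hi = ranges[tissue]
            if not lo < hi:
                raise ValueError(f"empty value range for {tissue.name}")
        for lower, upper in zip(order, order[1:]):
            lo1, hi1 = ranges[lower]
            lo2, hi2 = ranges[upper]
            allowed = self.range_overlap_fraction * (hi1 - lo1)
            if hi1 > lo2 + allowed:
                raise ValueError(
                    f"{lower.name} range {ranges[lower]} overlaps "
                    f"{upper.name} range {ranges[upper]} by more than the "
                    f"allowed fraction {self.range_overlap_fraction}"
                )

    def config_dict(self) -> dict[str, object]:
        """Flat key/value form for config-file serialization."""
        out: dict[str, object] = {
            "grid_rows": self.grid_shape[0],
            "grid_cols": self.grid_shape[1],
            "pixel_spacing_mm": self.pixel_spacing_mm,
            "breast_radius_mm": self.breast_radius_mm,
            "skin_thickness_mm": self.skin_thickness_mm,
            "gland_blob_count": self.gland_blob_count,
            "gland_fraction": self.gland_fraction,
            "transition_width_mm": self.transition_width_mm,
            "range_overlap_fraction": self.range_overlap_fraction,
            "seed": self.seed,
            "tumors": ";".join(f"{x},{y},{r}" for (x, y), r in
                               zip(self.tumor_centers_mm, self.tumor_radii_mm)),
        }
        for tissue, (lo, hi) in self.tissue_value_ranges.items():
            out[f"range_{tissue.name.lower()}"] = f"{lo},{hi}"
        return out


@dataclass(frozen=True)
class DegradationSpec:
    """Reconstruction-style degradation; all parameters zero = identity."""

    blur_sigma_mm: float = 0.0
    noise_sd: float = 0.0
    bias_amplitude: float = 0.0
    artefact_count: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("blur_sigma_mm", "noise_sd", "bias_amplitude"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        if self.artefact_count < 0:
            raise ValueError("artefact_count must be nonnegative")

    def is_identity(self) -> bool:
        return (self.blur_sigma_mm == 0 and self.noise_sd == 0
                and self.bias_amplitude == 0 and self.artefact_count == 0)


@dataclass(frozen=True)
class GroundTruth:
    """A phantom: complex image, tissue map, and imaging-domain mask."""

    image: PermittivityImage
    tissue_map: TissueSegmentation
    domain_boundary_mask: RegionMask  # breast support incl. skin (𝒟)
    spec: PhantomSpec

    def reference_segmentation(self) -> TissueSegmentation:
        """Tissue map with skin folded into background.

        The segmenter treats skin and immersion as background (both sit
        outside the contracted ROI), so reference masks for metric
        comparison use this view.
        """
        labels = self.tissue_map.labels.copy()
        labels[labels == int(Tissue.SKIN)] = int(Tissue.BACKGROUND)
        return TissueSegmentation(labels=labels,
                                  source_component=self.tissue_map.source_component)


def _grid_coords_mm(spec: PhantomSpec) -> tuple[np.ndarray, np.ndarray]:
    """(x, y) offsets in mm of every pixel center from the grid center."""
    rows, cols = spec.grid_shape
    s = spec.pixel_spacing_mm
    y = (np.arange(rows) - (rows - 1) / 2.0) * s
    x = (np.arange(cols) - (cols - 1) / 2.0) * s
    xx, yy = np.meshgrid(x, y)
    return xx, yy


def _sample_tissue_values(tissue: Tissue, n: int,
                          ranges: Mapping[Tissue, tuple[float, float]],
                          rng: np.random.Generator
                          ) -> tuple[np.ndarray, np.ndarray]:
    """Draw n (real, imag) value pairs for a tissue.

    A relative position in [0, 1] is drawn from the tissue's mode mixture
    and mapped into both the real range and the quarter-scale loss range,
    so the two components share one cluster structure.
    """
    modes = _TISSUE_MODES[tissue]
    weights = np.array([w for _, _, w in modes])
    weights = weights / weights.sum()
    which = rng.choice(len(modes), size=n, p=weights)
    rel = np.empty(n)
    for i, (center, sd, _) in enumerate(modes):
        sel = which == i
        rel[sel] = rng.normal(center, sd, size=int(sel.sum()))
    rel = np.clip(rel, 0.0, 1.0)
    lo, hi = ranges[tissue]
    real = lo + rel * (hi - lo)
    lo_im, hi_im = lo * IMAG_SCALE, hi * IMAG_SCALE
    imag = lo_im + rel * (hi_im - lo_im)
    return real, imag


def generate_phantom(spec: PhantomSpec) -> GroundTruth:
    """Generate a ground-truth phantom; bit-deterministic given the seed.

    Geometry: a circular breast of the specified radius centered on the
    grid, a skin ring of the stated thickness, a fibroglandular region
    built as the union of random Gaussian bumps thresholded to hit
    ``gland_fraction`` of the interior, a fixed-width transition shell
    around the gland, and circular tumors at the requested positions.

    Raises
    ------
    ValueError
        If a tumor extends outside the breast interior (spec validation)
        or its center misses the fibroglandular support.
    """
    rng = np.random.default_rng(spec.seed)
    xx, yy = _grid_coords_mm(spec)
    rr = np.hypot(xx, yy)
    s = spec.pixel_spacing_mm

    breast = rr <= spec.breast_radius_mm
    interior_radius = spec.breast_radius_mm - spec.skin_thickness_mm
    interior = rr <= interior_radius
    skin = breast & ~interior

    labels = np.full(spec.grid_shape, int(Tissue.BACKGROUND), dtype=np.int8)
    labels[skin] = int(Tissue.SKIN)
    labels[interior] = int(Tissue.FATTY)

    gland = np.zeros(spec.grid_shape, dtype=bool)
    if spec.gland_blob_count > 0:
        bump_field = np.zeros(spec.grid_shape, dtype=float)
        # First bump anchored at the first tumor center (or the breast
        # center) so that the gland support covers the default tumor.
        anchor = (spec.tumor_centers_mm[0] if spec.tumor_centers_mm
                  else (0.0, 0.0))
        centers = [anchor]
        for _ in range(spec.gland_blob_count - 1):
            ang = rng.uniform(0, 2 * np.pi)
            rad = rng.uniform(0, 0.55 * interior_radius)
            centers.append((rad * np.cos(ang), rad * np.sin(ang)))
        for cx, cy in centers:
            sigma = rng.uniform(0.18, 0.30) * interior_radius
            bump_field += np.exp(-((xx - cx) ** 2 + (yy - cy) ** 2)
                                 / (2 * sigma ** 2))
        inside_vals = bump_field[interior]
        cut = np.quantile(inside_vals, 1.0 - spec.gland_fraction)
        gland = interior & (bump_field >= cut)
        labels[gland] = int(Tissue.FIBROGLANDULAR)

        width_px = max(1, int(round(spec.transition_width_mm / s)))
        r = np.arange(-width_px, width_px + 1)
        fy, fx = np.meshgrid(r, r, indexing="ij")
        footprint = (fy ** 2 + fx ** 2) <= width_px ** 2
        shell = ndimage.binary_dilation(gland, structure=footprint)
        shell = shell & interior & ~gland
        labels[shell] = int(Tissue.TRANSITION)

    for (cx, cy), radius in zip(spec.tumor_centers_mm, spec.tumor_radii_mm):
        if spec.gland_blob_count > 0:
            row = int(round(cy / s + (spec.grid_shape[0] - 1) / 2.0))
            col = int(round(cx / s + (spec.grid_shape[1] - 1) / 2.0))
            if not gland[row, col]:
                raise ValueError(
                    f"tumor center ({cx}, {cy}) mm lies outside the "
                    "fibroglandular support"
                )
        disk = np.hypot(xx - cx, yy - cy) <= radius
        labels[disk] = int(Tissue.MALIGNANT)

    real = np.zeros(spec.grid_shape)
    imag = np.zeros(spec.grid_shape)
    for tissue in Tissue:
        sel = labels == int(tissue)
        n = int(sel.sum())
        if n == 0:
            continue
        re_vals, im_vals = _sample_tissue_values(
            tissue, n, spec.tissue_value_ranges, rng)
        real[sel] = re_vals
        imag[sel] = im_vals

    image = PermittivityImage(real, imag, s)
    tissue_map = TissueSegmentation(labels=labels, source_component="real")

    lo_f, hi_f = spec.tissue_value_ranges[Tissue.FIBROGLANDULAR]
    fibro_mid = 0.5 * (lo_f + hi_f) * np.hypot(1.0, IMAG_SCALE)
    malignant = labels == int(Tissue.MALIGNANT)
    if malignant.any():
        magnitudes = np.hypot(real[malignant], imag[malignant])
        if not np.all(magnitudes > fibro_mid):
            raise RuntimeError(
                "phantom invariant violated: a malignant element's |eps| "
                "does not exceed the fibroglandular range midpoint"
            )

    return GroundTruth(
        image=image,
        tissue_map=tissue_map,
        domain_boundary_mask=RegionMask(breast, s),
        spec=spec,
    )


def _masked_blur(component: np.ndarray, support: np.ndarray,
                 sigma_px: float) -> np.ndarray:
    """Gaussian blur restricted to the support (no bleed across its edge)."""
    m = support.astype(float)
    num = ndimage.gaussian_filter(component * m, sigma_px)
    den = ndimage.gaussian_filter(m, sigma_px)
    out = component.copy()
    inside = support & (den > 0)
    out[inside] = num[inside] / den[inside]
    return out


def degrade(truth: GroundTruth, deg: DegradationSpec) -> PermittivityImage:
    """Degrade a phantom image; the ground-truth tissue map is untouched.

    Order of application: in-breast blur, smooth multiplicative bias,
    additive per-element noise, then bright peripheral artefacts placed
    within 5 mm of the skin (the nuisance the ROI contraction exists to
    exclude).  An all-zero spec returns the input values exactly.
    """
    real = truth.image.real_part.copy()
    imag = truth.image.imag_part.copy()
    s = truth.image.pixel_spacing_mm
    if deg.is_identity():
        return PermittivityImage(real, imag, s)

    rng = np.random.default_rng(deg.seed)
    support = truth.domain_boundary_mask.as_bool()

    if deg.blur_sigma_mm > 0:
        sigma_px = deg.blur_sigma_mm / s
        real = _masked_blur(real, support, sigma_px)
        imag = _masked_blur(imag, support, sigma_px)

    if deg.bias_amplitude > 0:
        rough = rng.standard_normal(real.shape)
        smooth = ndimage.gaussian_filter(rough, 8.0 / s)
        peak = np.max(np.abs(smooth))
        bias = 1.0 + deg.bias_amplitude * (smooth / peak if peak > 0 else smooth)
        real = np.where(support, real * bias, real)
        imag = np.where(support, imag * bias, imag)

    if deg.noise_sd > 0:
        real = real + np.where(support,
                               rng.normal(0, deg.noise_sd, real.shape), 0.0)
        imag = imag + np.where(support,
                               rng.normal(0, deg.noise_sd, imag.shape), 0.0)

    if deg.artefact_count > 0:
        spec = truth.spec
        xx, yy = _grid_coords_mm(spec)
        lo_m, hi_m = spec.tissue_value_ranges[Tissue.MALIGNANT]
        amplitude = 0.5 * (lo_m + hi_m)
        for _ in range(deg.artefact_count):
            ang = rng.uniform(0, 2 * np.pi)
            rad = spec.breast_radius_mm - rng.uniform(0.5, 5.0)
            cx, cy = rad * np.cos(ang), rad * np.sin(ang)
            sigma_mm = rng.uniform(1.0, 2.0)
            bump = amplitude * np.exp(-((xx - cx) ** 2 + (yy - cy) ** 2)
                                      / (2 * sigma_mm ** 2))
            real = real + np.where(support, bump, 0.0)
            imag = imag + np.where(support, IMAG_SCALE * bump, 0.0)

    return PermittivityImage(real, imag, s)
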