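"""Region- and distance-based metrics comparing segmentations.

The framework compares the tissue masks segmented from a reconstructed
image (``recmask``) against those segmented from the ground-truth
forward model (``refmask``), per tissue region and per image component:

* **Fidelity** — normalized cross-correlation of the vectorized binary
  masks: refmaskᵀ·recmask / (‖refmask‖‖recmask‖), in [0, 1].
* **xcorrDiel** — the same correlation applied to the masked dielectric
  property values (``reftissue`` vs ``rectissue``); sensitive to both
  geometry and reconstructed property accuracy, scale-invariant.
* **Dice** — 2|ref∩rec| / (|ref|+|rec|), spatial overlap.
* **RD** (ratio detected) — |ref∩rec| / |ref|, a sensitivity proxy.
* **AR** (artefact rejection) — 1 − (|rec|−|ref∩rec|) / |ref|, a
  specificity proxy; negative when false positives exceed the reference
  tumor area.
* **average Hausdorff distance H_A** (mm) — the max of the two directed
  mean nearest-neighbor distances between boundary point sets, after
  translating each so the centroid of its enclosed region is at the
  origin (shape comparison, insensitive to position).

Per-tumor evaluation splits the reference malignant mask into connected
components and assigns each reconstructed malignant component to the
reference tumor with the nearest centroid.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dataclass_field

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.spatial.distance import cdist

from .roi import RegionMask, trace_crack_boundaries
from .segmentation import Tissue, TissueSegmentation

__all__ = [
    "ContourPointSet",
    "TissueValues",
    "MetricReport",
    "METRIC_NAMES",
    "fidelity",
    "xcorr_diel",
    "dice",
    "ratio_detected",
    "artefact_rejection",
    "extract_contour",
    "average_hausdorff",
    "evaluate",
]

METRIC_NAMES = ("fidelity", "xcorr_diel", "dice", "rd", "ar", "hausdorff_mm")

_STRUCT8 = np.ones((3, 3), dtype=bool)


@dataclass(frozen=True)
class ContourPointSet:
    """An ordered set of boundary points in mm; closed loops omit the repeat."""

    points: np.ndarray
    closed: bool = True

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float).reshape(-1, 2)
        if pts.shape[0] == 0:
            raise ValueError("contour point set must be nonempty")
        if pts.shape[0] > 1:
            dupes = np.all(pts[1:] == pts[:-1], axis=1)
            if dupes.any():
                raise ValueError("duplicate consecutive contour points")
        object.__setattr__(self, "points", pts)

    def centroid(self) -> np.ndarray:
        """Center of the enclosed region (shoelace), or the vertex mean
        for open or degenerate (zero-area) point sets."""
        pts = self.points
        if self.closed and pts.shape[0] >= 3:
            x, y = pts[:, 0], pts[:, 1]
            xn, yn = np.roll(x, -1), np.roll(y, -1)
            cross = x * yn - xn * y
            area6 = 3.0 * np.sum(cross)
            if abs(area6) > 1e-12:
                cx = np.sum((x + xn) * cross) / area6
                cy = np.sum((y + yn) * cross) / area6
                return np.array([cx, cy])
        return pts.mean(axis=0)


@dataclass(frozen=True)
class TissueValues:
    """Property values under a mask (zero elsewhere), e.g. reftissue."""

    values: np.ndarray
    mask: RegionMask

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=float)
        if vals.shape != self.mask.shape:
            raise ValueError("values and mask shapes must match")
        vals = np.where(self.mask.as_bool(), vals, 0.0)
        object.__setattr__(self, "values", vals)

    @classmethod
    def from_image(cls, image: np.ndarray, mask: RegionMask) -> "TissueValues":
        return cls(values=np.asarray(image, dtype=float), mask=mask)


# ---------------------------------------------------------------------------
# Region metrics
# ---------------------------------------------------------------------------

def _as_bool(mask: RegionMask | np.ndarray) -> np.ndarray:
    if isinstance(mask, RegionMask):
        return mask.as_bool()
    return np.asarray(mask).astype(bool)


def fidelity(ref: RegionMask | np.ndarray, rec: RegionMask | np.ndarray) -> float:
    """Normalized cross-correlation of the vectorized binary masks."""
    a, b = _as_bool(ref), _as_bool(rec)
    if a.shape != b.shape:
        raise ValueError("mask shapes must match")
    na, nb = a.sum(), b.sum()
    if na == 0 or nb == 0:
        raise ValueError("fidelity requires two nonempty masks")
    return float((a & b).sum() / np.sqrt(na * nb))


def xcorr_diel(ref: TissueValues, rec: TissueValues) -> float:
    """Fidelity applied to masked property values instead of binary masks."""
    a = ref.values.ravel()
    b = rec.values.ravel()
    if a.shape != b.shape:
        raise ValueError("value-image shapes must match")
    norm = np.linalg.norm(a) * np.linalg.norm(b)
    if norm == 0:
        raise ValueError("xcorr_diel requires two nonzero value images")
    return float(np.dot(a, b) / norm)


def dice(ref: RegionMask | np.ndarray, rec: RegionMask | np.ndarray) -> float:
    """Dice similarity coefficient 2|ref∩rec| / (|ref|+|rec|)."""
    a, b = _as_bool(ref), _as_bool(rec)
    if a.shape != b.shape:
        raise ValueError("mask shapes must match")
    total = a.sum() + b.sum()
    if total == 0:
        raise ValueError("Dice undefined for two empty masks")
    return float(2.0 * (a & b).sum() / total)


def ratio_detected(ref: RegionMask | np.ndarray, rec: RegionMask | np.ndarray) -> float:
    """Fraction of the reference region captured by the reconstruction."""
    a, b = _as_bool(ref), _as_bool(rec)
    if a.shape != b.shape:
        raise ValueError("mask shapes must match")
    if a.sum() == 0:
        raise ValueError("ratio_detected requires a nonempty reference mask")
    return float((a & b).sum() / a.sum())


def artefact_rejection(ref: RegionMask | np.ndarray, rec: RegionMask | np.ndarray) -> float:
    """1 − (false-positive area) / (reference area); may be negative."""
    a, b = _as_bool(ref), _as_bool(rec)
    if a.shape != b.shape:
        raise ValueError("mask shapes must match")
    if a.sum() == 0:
        raise ValueError("artefact_rejection requires a nonempty reference mask")
    false_pos = b.sum() - (a & b).sum()
    return float(1.0 - false_pos / a.sum())


# ---------------------------------------------------------------------------
# Contours and the average Hausdorff distance
# ---------------------------------------------------------------------------

def extract_contour(mask: RegionMask) -> list[ContourPointSet]:
    """Closed outer contour of each 8-connected component, in mm.

    Contours follow the pixel-corner ("crack") convention, so a
    one-pixel region yields its four corner points.
    """
    arr = mask.as_bool()
    if not arr.any():
        raise ValueError("cannot extract contours from an empty mask")
    labeled, ncomp = ndimage.label(arr, structure=_STRUCT8)
    contours = []
    for comp in range(1, ncomp + 1):
        loops = trace_crack_boundaries(labeled == comp, mask.pixel_spacing_mm)
        outer = max(loops, key=lambda lp: _polygon_area(lp))
        contours.append(ContourPointSet(points=np.asarray(outer), closed=True))
    return contours


def _polygon_area(loop) -> float:
    pts = np.asarray(loop, dtype=float)
    x, y = pts[:, 0], pts[:, 1]
    return 0.5 * abs(float(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1))))


def average_hausdorff(ref: ContourPointSet, rec: ContourPointSet,
                      ref_center: np.ndarray | None = None,
                      rec_center: np.ndarray | None = None) -> float:
    """Average Hausdorff distance in mm between centroid-aligned contours.

    Each point set is translated so the center of its enclosed region is
    at the origin (removing position, keeping shape); the result is
    max{h(rec→ref), h(ref→rec)} where h(A→B) is the mean over A of the
    nearest-neighbor distance to B.
    """
    a = ref.points - (ref.centroid() if ref_center is None else np.asarray(ref_center))
    b = rec.points - (rec.centroid() if rec_center is None else np.asarray(rec_center))
    d = cdist(a, b)
    h_ab = float(d.min(axis=1).mean())
    h_ba = float(d.min(axis=0).mean())
    return max(h_ab, h_ba)


def _mask_hausdorff(ref_mask: np.ndarray, rec_mask: np.ndarray,
                    spacing: float) -> float:
    """H_A between two masks: all boundary points, mask-centroid alignment.

    Using the pixel centroid of the mask as the enclosing-region center
    keeps the alignment well defined for multi-component masks and makes
    integer-pixel translation invariance exact.
    """
    ref_pts = np.vstack([c.points for c in
                         extract_contour(RegionMask(ref_mask, spacing))])
    rec_pts = np.vstack([c.points for c in
                         extract_contour(RegionMask(rec_mask, spacing))])
    ref_c = _mask_centroid_mm(ref_mask, spacing)
    rec_c = _mask_centroid_mm(rec_mask, spacing)
    return average_hausdorff(ContourPointSet(ref_pts, closed=False),
                             ContourPointSet(rec_pts, closed=False),
                             ref_center=ref_c, rec_center=rec_c)


def _mask_centroid_mm(mask: np.ndarray, spacing: float) -> np.ndarray:
    r, c = ndimage.center_of_mass(np.asarray(mask).astype(float))
    return np.array([c * spacing, r * spacing])


# ---------------------------------------------------------------------------
# Whole-segmentation evaluation
# ---------------------------------------------------------------------------

@dataclass
class MetricReport:
    """Per-region metric values for one image component.

    ``regions`` maps a region name (``"glandular"``, ``"tumor_1"``, …) to
    a dict over :data:`METRIC_NAMES`; a value of ``None`` marks a metric
    that is undefined for that region (e.g. H_A with no reconstructed
    tumor), and an ``{"absent": True}`` entry marks a region missing
    from the reference.
    """

    component: str
    regions: dict[str, dict] = dataclass_field(default_factory=dict)

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for region, metrics in self.regions.items():
            row = {"region": region, "component": self.component}
            row.update(metrics)
            rows.append(row)
        return pd.DataFrame(rows)


def _region_metrics(ref_mask: np.ndarray, rec_mask: np.ndarray,
                    ref_img: np.ndarray, rec_img: np.ndarray,
                    spacing: float) -> dict:
    """All six metrics for one region; handles an empty reconstruction."""
    out: dict[str, float | None] = {}
    ref_n = int(ref_mask.sum())
    rec_n = int(rec_mask.sum())
    if rec_n == 0:
        return {"fidelity": 0.0, "xcorr_diel": None, "dice": 0.0,
                "rd": 0.0, "ar": 1.0, "hausdorff_mm": None}
    rm = RegionMask(ref_mask, spacing)
    cm = RegionMask(rec_mask, spacing)
    out["fidelity"] = fidelity(rm, cm)
    out["xcorr_diel"] = xcorr_diel(TissueValues.from_image(ref_img, rm),
                                   TissueValues.from_image(rec_img, cm))
    out["dice"] = dice(rm, cm)
    out["rd"] = ratio_detected(rm, cm)
    out["ar"] = artefact_rejection(rm, cm)
    out["hausdorff_mm"] = _mask_hausdorff(ref_mask, rec_mask, spacing)
    return out


def evaluate(ref_seg: TissueSegmentation, rec_seg: TissueSegmentation,
             ref_img: np.ndarray, rec_img: np.ndarray,
             pixel_spacing_mm: float = 1.0,
             component: str | None = None) -> MetricReport:
    """Evaluate a reconstructed segmentation against a reference.

    The glandular region is the fibroglandular mask; each 8-connected
    component of the reference malignant mask is reported as its own
    tumor, with reconstructed malignant components assigned to the
    nearest reference tumor by centroid distance (so stray malignant
    blobs count against the AR of the closest tumor).  ``ref_img`` and
    ``rec_img`` are the scalar component images the segmentations came
    from; they feed the dielectric-value correlation.
    """
    if ref_seg.labels.shape != rec_seg.labels.shape:
        raise ValueError("segmentation grids must match")
    comp_name = component or rec_seg.source_component
    report = MetricReport(component=comp_name)
    ref_img = np.asarray(ref_img, dtype=float)
    rec_img = np.asarray(rec_img, dtype=float)
    s = pixel_spacing_mm

    ref_gland = ref_seg.mask(Tissue.FIBROGLANDULAR)
    rec_gland = rec_seg.mask(Tissue.FIBROGLANDULAR)
    if not ref_gland.any():
        report.regions["glandular"] = {"absent": True}
    else:
        report.regions["glandular"] = _region_metrics(
            ref_gland, rec_gland, ref_img, rec_img, s)

    ref_tumor = ref_seg.mask(Tissue.MALIGNANT)
    rec_tumor = rec_seg.mask(Tissue.MALIGNANT)
    if not ref_tumor.any():
        report.regions["tumor"] = {"absent": True}
        return report

    ref_lab, n_ref = ndimage.label(ref_tumor, structure=_STRUCT8)
    ref_centroids = np.array(
        [_mask_centroid_mm(ref_lab == i, s) for i in range(1, n_ref + 1)])

    assigned = [np.zeros_like(ref_tumor) for _ in range(n_ref)]
    if rec_tumor.any():
        rec_lab, n_rec = ndimage.label(rec_tumor, structure=_STRUCT8)
        for j in range(1, n_rec + 1):
            comp_mask = rec_lab == j
            c = _mask_centroid_mm(comp_mask, s)
            nearest = int(np.argmin(np.linalg.norm(ref_centroids - c, axis=1)))
            assigned[nearest] = assigned[nearest] | comp_mask

    for i in range(n_ref):
        report.regions[f"tumor_{i + 1}"] = _region_metrics(
            ref_lab == i + 1, assigned[i], ref_img, rec_img, s)
    return report


def report_to_nested_dict(reports: dict[str, MetricReport]) -> dict:
    """Assemble component-keyed reports into region→component→metric form,
    mirroring a table with regions as rows and components as columns."""
    nested: dict[str, dict[str, dict]] = {}
    for comp, rep in reports.items():
        for region, metrics in rep.regions.items():
            nested.setdefault(region, {})[comp] = metrics
    return nested
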