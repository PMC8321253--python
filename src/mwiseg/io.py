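"""Image containers, contrast→permittivity conversion, and file formats.

Microwave tomography reconstructs a complex permittivity profile over a
discrete 2D grid.  Inverse solvers typically work with the *contrast*
profile χ(r) = (ϵ(r) − ϵ_b(r)) / ϵ_b(r) relative to an assumed background
ϵ_b(r) inside the imaging domain 𝒟; the permittivity is recovered as
ϵ = ϵ_b·(χ + 1).  This module provides:

* :class:`PermittivityImage` — the complex field plus its pixel spacing,
  and the derived scalar component images (real part, loss magnitude,
  complex magnitude) that are segmented independently downstream;
* :class:`ContrastProfile` and :func:`contrast_to_permittivity`;
* plain-text matrix I/O (CSV with ``# key=value`` header lines), binary
  mask PNG I/O, contour CSV, JSON metric reports, and contour-overlay
  rendering.

Grid convention (shared package-wide): row-major, 0-based indices;
physical coordinates x = col·spacing, y = row·spacing, in millimetres.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from PIL import Image

__all__ = [
    "PermittivityImage",
    "ContrastProfile",
    "contrast_to_permittivity",
    "component_images",
    "COMPONENTS",
    "read_matrix",
    "write_matrix",
    "read_mask_png",
    "write_mask_png",
    "write_report_json",
    "read_report_json",
    "write_contours_csv",
    "read_contours_csv",
    "write_overlay_png",
]

#: Scalar component images derived from a complex permittivity field.
COMPONENTS = ("real", "imaginary", "magnitude")

REPORT_SCHEMA_VERSION = 1


@dataclass(frozen=True)
class PermittivityImage:
    """A 2D complex permittivity field with physical pixel spacing.

    ``real_part`` stores Re{ϵ}; ``imag_part`` stores the loss component.
    The sign convention of Im{ϵ} differs between the e^{jωt} and e^{−jωt}
    time conventions, so consumers work with the loss magnitude |Im{ϵ}|
    (see :func:`component_images`).
    """

    real_part: np.ndarray
    imag_part: np.ndarray
    pixel_spacing_mm: float

    def __post_init__(self) -> None:
        re = np.asarray(self.real_part, dtype=float)
        im = np.asarray(self.imag_part, dtype=float)
        if re.ndim != 2:
            raise ValueError(f"expected a 2D array, got shape {re.shape}")
        if re.shape != im.shape:
            raise ValueError(
                f"real/imaginary shapes differ: {re.shape} vs {im.shape}"
            )
        if not self.pixel_spacing_mm > 0:
            raise ValueError("pixel_spacing_mm must be positive")
        object.__setattr__(self, "real_part", re)
        object.__setattr__(self, "imag_part", im)

    @property
    def shape(self) -> tuple[int, int]:
        return self.real_part.shape

    @property
    def complex_field(self) -> np.ndarray:
        return self.real_part + 1j * self.imag_part


@dataclass(frozen=True)
class ContrastProfile:
    """Contrast χ and background ϵ_b over an imaging domain 𝒟.

    The contrast is identically zero outside the imaging domain; the
    constructor zeroes it there so the invariant always holds.
    """

    contrast: np.ndarray
    background: np.ndarray
    imaging_domain: np.ndarray  # binary mask of 𝒟
    pixel_spacing_mm: float = 1.0

    def __post_init__(self) -> None:
        chi = np.asarray(self.contrast, dtype=complex)
        bg = np.asarray(self.background, dtype=complex)
        dom = np.asarray(self.imaging_domain).astype(bool)
        if chi.shape != bg.shape or chi.shape != dom.shape:
            raise ValueError("contrast, background and domain shapes must match")
        chi = np.where(dom, chi, 0.0)
        object.__setattr__(self, "contrast", chi)
        object.__setattr__(self, "background", bg)
        object.__setattr__(self, "imaging_domain", dom)


def contrast_to_permittivity(cp: ContrastProfile) -> PermittivityImage:
    """Recover the complex permittivity from a contrast profile.

    Elementwise ϵ = ϵ_b·(χ + 1) inside the imaging domain; outside it the
    permittivity equals the background (χ = 0 there by construction).

    Raises
    ------
    ValueError
        If the background vanishes anywhere inside the imaging domain
        (the contrast is undefined relative to a zero background).
    """
    inside = cp.imaging_domain
    if np.any(np.abs(cp.background[inside]) == 0):
        raise ValueError("background permittivity is zero inside the imaging domain")
    eps = cp.background * (cp.contrast + 1.0)
    return PermittivityImage(
        real_part=eps.real,
        imag_part=eps.imag,
        pixel_spacing_mm=cp.pixel_spacing_mm,
    )


def permittivity_to_contrast(
    img: PermittivityImage, background: np.ndarray, imaging_domain: np.ndarray
) -> ContrastProfile:
    """Inverse of :func:`contrast_to_permittivity` (χ = (ϵ − ϵ_b)/ϵ_b in 𝒟)."""
    bg = np.asarray(background, dtype=complex)
    dom = np.asarray(imaging_domain).astype(bool)
    if np.any(np.abs(bg[dom]) == 0):
        raise ValueError("background permittivity is zero inside the imaging domain")
    eps = img.complex_field
    with np.errstate(divide="ignore", invalid="ignore"):
        chi = np.where(dom, (eps - bg) / np.where(bg == 0, 1.0, bg), 0.0)
    return ContrastProfile(chi, bg, dom, img.pixel_spacing_mm)


def component_images(img: PermittivityImage) -> dict[str, np.ndarray]:
    """Return the three scalar images segmented independently downstream.

    ``real`` is Re{ϵ}; ``imaginary`` is the loss magnitude |Im{ϵ}| so that
    lossier (malignant) tissue is always highest-valued regardless of the
    time-harmonic sign convention; ``magnitude`` is |ϵ| = √(Re² + Im²).
    """
    re = img.real_part
    im = np.abs(img.imag_part)
    return {
        "real": re.copy(),
        "imaginary": im,
        "magnitude": np.hypot(re, im),
    }


# ---------------------------------------------------------------------------
# Plain-text matrix I/O
# ---------------------------------------------------------------------------

def write_matrix(path: str | Path, array: np.ndarray,
                 header: Mapping[str, object] | None = None) -> None:
    """Write a 2D real matrix as CSV, one row per line, full precision.

    Optional metadata goes into leading ``# key=value`` lines (used for
    the pixel spacing).  The roundtrip through :func:`read_matrix` is
    bit-exact for finite doubles.
    """
    arr = np.asarray(array, dtype=float)
    if arr.ndim != 2:
        raise ValueError(f"expected a 2D array, got shape {arr.shape}")
    path = Path(path)
    with path.open("w") as fh:
        for key, value in (header or {}).items():
            fh.write(f"# {key}={value}\n")
        for row in arr:
            fh.write(",".join(repr(float(v)) for v in row) + "\n")


def read_matrix(path: str | Path) -> tuple[np.ndarray, dict[str, str]]:
    """Read a matrix written by :func:`write_matrix`; returns (array, header)."""
    path = Path(path)
    header: dict[str, str] = {}
    rows: list[list[float]] = []
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line[1:].strip()
                if "=" not in body:
                    raise ValueError(
                        f"{path}:{lineno}: malformed header line {line!r}"
                    )
                key, _, value = body.partition("=")
                header[key.strip()] = value.strip()
                continue
            try:
                rows.append([float(tok) for tok in line.split(",")])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: malformed row: {exc}") from exc
    if not rows:
        raise ValueError(f"{path}: no data rows")
    width = len(rows[0])
    if any(len(r) != width for r in rows):
        raise ValueError(f"{path}: ragged rows (expected width {width})")
    return np.array(rows, dtype=float), header


def write_permittivity(path_stem: str | Path, img: PermittivityImage) -> tuple[Path, Path]:
    """Write a complex image as paired ``<stem>_re.csv`` / ``<stem>_im.csv``."""
    stem = Path(path_stem)
    header = {"pixel_spacing_mm": img.pixel_spacing_mm}
    re_path = stem.with_name(stem.name + "_re.csv")
    im_path = stem.with_name(stem.name + "_im.csv")
    write_matrix(re_path, img.real_part, header)
    write_matrix(im_path, img.imag_part, header)
    return re_path, im_path


def read_permittivity(re_path: str | Path, im_path: str | Path | None = None,
                      pixel_spacing_mm: float | None = None) -> PermittivityImage:
    """Read a complex image from paired CSV matrices (imaginary optional)."""
    re, header = read_matrix(re_path)
    if im_path is not None:
        im, _ = read_matrix(im_path)
    else:
        im = np.zeros_like(re)
    if pixel_spacing_mm is None:
        pixel_spacing_mm = float(header.get("pixel_spacing_mm", 1.0))
    return PermittivityImage(re, im, pixel_spacing_mm)


# ---------------------------------------------------------------------------
# Mask PNG I/O
# ---------------------------------------------------------------------------

def write_mask_png(path: str | Path, mask: np.ndarray) -> None:
    """Write a binary mask as an 8-bit PNG with values {0, 255}."""
    arr = np.asarray(mask)
    if arr.ndim != 2:
        raise ValueError(f"expected a 2D mask, got shape {arr.shape}")
    if not np.isin(arr, (0, 1)).all():
        raise ValueError("mask values must be 0/1")
    Image.fromarray((arr.astype(np.uint8) * 255)).save(Path(path), format="PNG")


def read_mask_png(path: str | Path) -> np.ndarray:
    """Read a binary mask PNG; any value > 127 maps to 1."""
    img = Image.open(Path(path)).convert("L")
    arr = np.asarray(img)
    values = np.unique(arr)
    if not np.isin(values, (0, 255)).all():
        raise ValueError(f"{path}: not strictly binary (values {values[:8]})")
    return (arr > 127).astype(np.uint8)


# ---------------------------------------------------------------------------
# Reports, contours, overlays
# ---------------------------------------------------------------------------

def write_report_json(path: str | Path, report: Mapping[str, object]) -> None:
    """Write a metric report keyed region→component→metric, with schema tag."""
    payload = {"schema_version": REPORT_SCHEMA_VERSION, "report": dict(report)}
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True,
                                     default=_json_default) + "\n")


def read_report_json(path: str | Path) -> dict:
    payload = json.loads(Path(path).read_text())
    if payload.get("schema_version") != REPORT_SCHEMA_VERSION:
        raise ValueError(f"{path}: unsupported report schema {payload.get('schema_version')!r}")
    return payload["report"]


def _json_default(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)!r}")


def write_contours_csv(path: str | Path,
                       contours: Iterable[Sequence[tuple[float, float]]]) -> None:
    """Write contours as CSV with header ``x_mm,y_mm``; blank line between contours."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write("x_mm,y_mm\n")
        first = True
        for contour in contours:
            if not first:
                fh.write("\n")
            first = False
            for x, y in contour:
                fh.write(f"{float(x)!r},{float(y)!r}\n")


def read_contours_csv(path: str | Path) -> list[list[tuple[float, float]]]:
    lines = Path(path).read_text().splitlines()
    if not lines or lines[0].strip() != "x_mm,y_mm":
        raise ValueError(f"{path}: missing 'x_mm,y_mm' header")
    contours: list[list[tuple[float, float]]] = [[]]
    for line in lines[1:]:
        if not line.strip():
            if contours[-1]:
                contours.append([])
            continue
        x, _, y = line.partition(",")
        contours[-1].append((float(x), float(y)))
    if contours and not contours[-1]:
        contours.pop()
    return contours


def write_overlay_png(path: str | Path, background_image: np.ndarray,
                      pixel_spacing_mm: float,
                      contours: Mapping[str, Sequence[Sequence[tuple[float, float]]]],
                      title: str | None = None) -> None:
    """Render contours superimposed on an image and save as PNG.

    ``contours`` maps a legend label (e.g. ``"reference tumor"``) to a list
    of closed contours in mm coordinates.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    arr = np.asarray(background_image, dtype=float)
    nrows, ncols = arr.shape
    s = pixel_spacing_mm
    extent = (-0.5 * s, (ncols - 0.5) * s, (nrows - 0.5) * s, -0.5 * s)
    fig, ax = plt.subplots(figsize=(5, 5))
    im = ax.imshow(arr, extent=extent, cmap="viridis")
    fig.colorbar(im, ax=ax, shrink=0.8)
    colors = ["k", "r", "w", "m", "c"]
    for i, (label, group) in enumerate(contours.items()):
        color = colors[i % len(colors)]
        for j, contour in enumerate(group):
            pts = np.asarray(contour, dtype=float)
            if pts.size == 0:
                continue
            closed = np.vstack([pts, pts[:1]])
            ax.plot(closed[:, 0], closed[:, 1], color=color, lw=1.2,
                    label=label if j == 0 else None)
    if contours:
        ax.legend(loc="lower right", fontsize=7)
    if title:
        ax.set_title(title)
    ax.set_xlabel("x (mm)")
    ax.set_ylabel("y (mm)")
    fig.savefig(Path(path), dpi=120, bbox_inches="tight")
    plt.close(fig)
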