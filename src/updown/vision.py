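"""Scan ingestion: rasterisation, fiducial-frame location, perspective
correction, and per-cell patch extraction.

The printed template carries a thick solid border.  The reader
binarises each page, takes the largest connected ink component as that
border, recovers its eight corners (outer and inner edge), and fits a
projective transform from layout millimetres to scan pixels.  Cells are
then cropped from the perspective-corrected page at the layout's
coordinates, shrunk by an inner margin to exclude printed grid lines.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np
from PIL import Image
from scipy import ndimage
from skimage.filters import threshold_otsu
from skimage.transform import ProjectiveTransform, warp

from .layout import Rect, SheetLayout, TableBox, mm_to_px
from .pdfio import PdfReadError, read_image_pdf

__all__ = [
    "PageImage",
    "WarpResult",
    "FrameNotFoundError",
    "InputError",
    "rasterize",
    "locate_frame",
    "extract_cells",
    "ink_fraction",
    "DEFAULT_DPI",
    "CELL_MARGIN_FRAC",
]

DEFAULT_DPI = 300

#: Fraction of the cell size trimmed from each side before measuring
#: ink, removing the printed grid lines.
CELL_MARGIN_FRAC = 0.12

#: The border component's bounding box must cover at least this fraction
#: of the page for the frame to count as found.
MIN_FRAME_AREA_FRAC = 0.30


class InputError(ValueError):
    pass


class FrameNotFoundError(RuntimeError):
    pass


@dataclass(frozen=True)
class PageImage:
    image: np.ndarray  # grayscale uint8
    dpi: float
    page_index: int  # 1-based within the source document
    source: str = ""

    def __post_init__(self) -> None:
        if self.image.ndim != 2:
            raise ValueError("page image must be single-channel")
        if self.dpi <= 0:
            raise ValueError("dpi must be positive")


@dataclass
class WarpResult:
    """Projective map from layout millimetres into source-scan pixels,
    plus the page resampled onto the canonical layout grid."""

    transform: ProjectiveTransform  # (x_mm, y_mm) -> (x_px, y_px)
    warped: np.ndarray  # canonical grayscale uint8, at `dpi`
    residual_px: float
    dpi: float

    def mm_to_scan_px(self, points_mm: np.ndarray) -> np.ndarray:
        return self.transform(np.asarray(points_mm, dtype=float))


def _load_image_file(path: Path, dpi: float) -> list[PageImage]:
    with Image.open(path) as im:
        frames = []
        index = 0
        file_dpi = None
        if "dpi" in im.info:
            file_dpi = float(im.info["dpi"][0]) or None
        while True:
            frames.append(
                np.asarray(im.convert("L"), dtype=np.uint8).copy()
            )
            index += 1
            try:
                im.seek(index)
            except EOFError:
                break
    use_dpi = file_dpi or dpi
    return [
        PageImage(f, use_dpi, i + 1, str(path)) for i, f in enumerate(frames)
    ]


def rasterize(path: str | Path, dpi: float = DEFAULT_DPI) -> list[PageImage]:
    """Load a scanned document (PDF, PNG or TIFF) as one grayscale
    image per page.

    PDF support covers raster-backed documents (one full-page image per
    page, as produced by this package); other PDFs raise ``InputError``.
    """
    path = Path(path)
    if not path.is_file():
        raise InputError(f"input file not found: {path}")
    suffix = path.suffix.lower()
    if suffix == ".pdf":
        try:
            pages, native_dpi = read_image_pdf(path)
        except PdfReadError as e:
            raise InputError(str(e)) from None
        return [
            PageImage(p, native_dpi, i + 1, str(path))
            for i, p in enumerate(pages)
        ]
    if suffix in (".png", ".tif", ".tiff"):
        return _load_image_file(path, dpi)
    raise InputError(f"unsupported input format: {path.suffix!r}")


def _mask_corners(rows: np.ndarray, cols: np.ndarray) -> np.ndarray:
    """Quadrilateral corners (x, y) of a pixel set, ordered TL TR BR BL.

    Uses the extremal x+y / x-y pixels; exact for rotations well below
    45 degrees, which covers any plausibly scanned sheet.
    """
    s = cols + rows
    d = cols - rows
    pick = [int(np.argmin(s)), int(np.argmax(d)), int(np.argmax(s)), int(np.argmin(d))]
    return np.array([[cols[i], rows[i]] for i in pick], dtype=float)


def _frame_corners_mm(layout: SheetLayout) -> np.ndarray:
    pts = []
    for rect in (layout.frame_outer, layout.frame_inner):
        pts.extend(
            [
                [rect.x0, rect.y0],
                [rect.x1, rect.y0],
                [rect.x1, rect.y1],
                [rect.x0, rect.y1],
            ]
        )
    return np.array(pts, dtype=float)


def locate_frame(page: PageImage, layout: SheetLayout) -> WarpResult:
    """Find the fiducial border and fit the layout-to-scan homography.

    Raises
    ------
    FrameNotFoundError
        If no ink component plausibly covering the page is present.
    """
    img = page.image
    sample = img[::4, ::4]  # threshold estimate does not need full res
    thr = threshold_otsu(sample) if sample.min() < sample.max() else -1
    ink = img <= thr  # <=: Otsu returns the lower class value on clean
    # two-valued images
    if not ink.any():
        raise FrameNotFoundError("page contains no ink")
    labels, n = ndimage.label(ink)
    if n == 0:
        raise FrameNotFoundError("page contains no ink")
    sizes = np.bincount(labels.ravel())[1:]
    border_label = int(np.argmax(sizes)) + 1
    comp = labels == border_label
    rows, cols = np.nonzero(comp)
    bbox_area = (rows.max() - rows.min() + 1) * (cols.max() - cols.min() + 1)
    if bbox_area < MIN_FRAME_AREA_FRAC * img.size:
        raise FrameNotFoundError(
            "largest ink component does not cover enough of the page"
        )

    outer = _mask_corners(rows, cols)
    interior = ndimage.binary_fill_holes(comp) & ~comp
    if not interior.any():
        raise FrameNotFoundError("fiducial border has no interior")
    irows, icols = np.nonzero(interior)
    inner = _mask_corners(irows, icols)

    src_mm = _frame_corners_mm(layout)
    dst_px = np.vstack([outer, inner])
    if hasattr(ProjectiveTransform, "from_estimate"):
        tform = ProjectiveTransform.from_estimate(src_mm, dst_px)
        if not tform:
            raise FrameNotFoundError("homography estimation failed")
    else:  # older scikit-image
        tform = ProjectiveTransform()
        if not tform.estimate(src_mm, dst_px):
            raise FrameNotFoundError("homography estimation failed")
    residual = float(np.max(np.linalg.norm(tform(src_mm) - dst_px, axis=1)))

    dpi = page.dpi
    w_px = round(mm_to_px(layout.page_mm[0], dpi))
    h_px = round(mm_to_px(layout.page_mm[1], dpi))
    scale = 25.4 / dpi  # canonical px -> mm
    canon_to_scan = ProjectiveTransform(
        matrix=tform.params @ np.diag([scale, scale, 1.0])
    )
    warped = warp(
        img.astype(float) / 255.0,
        inverse_map=canon_to_scan,
        output_shape=(h_px, w_px),
        cval=1.0,
        preserve_range=True,
    )
    warped_u8 = np.clip(warped * 255.0, 0, 255).astype(np.uint8)
    return WarpResult(tform, warped_u8, residual, dpi)


def _crop(
    image: np.ndarray, rect: Rect, dpi: float, margin_frac: float
) -> np.ndarray:
    mx = rect.w * margin_frac
    my = rect.h * margin_frac
    x0 = round(mm_to_px(rect.x0 + mx, dpi))
    x1 = round(mm_to_px(rect.x1 - mx, dpi))
    y0 = round(mm_to_px(rect.y0 + my, dpi))
    y1 = round(mm_to_px(rect.y1 - my, dpi))
    return image[max(y0, 0) : y1, max(x0, 0) : x1]


def extract_cells(
    warp_result: WarpResult,
    layout: SheetLayout,
    margin_frac: float = CELL_MARGIN_FRAC,
    threshold: Optional[float] = None,
) -> dict[int, list[list[np.ndarray]]]:
    """Binarised ink patches for every cell of every table.

    Returns a mapping from 1-based table index to a 5 x n_cols nested
    list of boolean arrays (True = ink).  *threshold* overrides the
    page-level Otsu level.
    """
    page = warp_result.warped
    if threshold is None:
        sample = page[::4, ::4]
        threshold = (
            float(threshold_otsu(sample)) if sample.min() < sample.max() else -1.0
        )
    out: dict[int, list[list[np.ndarray]]] = {}
    for table in layout.tables:
        grid = [
            [
                _crop(page, cell, warp_result.dpi, margin_frac) <= threshold
                for cell in row
            ]
            for row in table.cells
        ]
        out[table.index] = grid
    return out


def ink_fraction(cell_image: np.ndarray) -> float:
    """Foreground pixel proportion of a binarised patch."""
    if cell_image.size == 0:
        return 0.0
    return float(np.count_nonzero(cell_image)) / cell_image.size
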