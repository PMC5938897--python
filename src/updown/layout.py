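"""Printable scoring-sheet geometry and template rendering.

All coordinates are millimetres on an A4 portrait page, origin at the
top-left corner, y increasing downward.  Boxes are half-open
``[x0, x1) x [y0, y1)``.  The reader and the generator share this
layout, so the geometry itself is a free design choice; what matters is
that it is deterministic and that a sidecar file describes it exactly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
from PIL import Image, ImageDraw, ImageFont

from .ladder import Assay, build_ladder
from .staircase import N_ROWS

__all__ = [
    "Rect",
    "TableBox",
    "SheetLayout",
    "SheetKind",
    "build_layout",
    "save_layout",
    "load_layout",
    "render_layout",
    "generate_template",
    "mm_to_px",
    "LayoutParseError",
]

LAYOUT_VERSION = 1

PAGE_MM = (210.0, 297.0)  # A4 portrait
FRAME_MARGIN_MM = 8.0
BORDER_MM = 2.0
CELL_W_MM = 4.8
HEADER_MM = 4.0
GRID_LINE_MM = 0.25

SheetKind = str  # "mouse" | "rat" | "human"
SHEET_KINDS = ("mouse", "rat", "human")

#: Tables per sheet: 20 individual animal tables, or 10 subject rows of
#: two tables (MDT + MPT) for humans.
ANIMAL_TABLES = 20
HUMAN_SUBJECTS = 10


class LayoutParseError(ValueError):
    pass


@dataclass(frozen=True)
class Rect:
    x0: float
    y0: float
    x1: float
    y1: float

    @property
    def w(self) -> float:
        return self.x1 - self.x0

    @property
    def h(self) -> float:
        return self.y1 - self.y0

    @property
    def center(self) -> tuple[float, float]:
        return ((self.x0 + self.x1) / 2.0, (self.y0 + self.y1) / 2.0)

    def contains(self, other: "Rect") -> bool:
        return (
            self.x0 <= other.x0
            and self.y0 <= other.y0
            and other.x1 <= self.x1
            and other.y1 <= self.y1
        )

    def overlaps(self, other: "Rect") -> bool:
        return not (
            other.x1 <= self.x0
            or self.x1 <= other.x0
            or other.y1 <= self.y0
            or self.y1 <= other.y0
        )

    def as_list(self) -> list[float]:
        return [self.x0, self.y0, self.x1, self.y1]


@dataclass(frozen=True)
class TableBox:
    """One 5-row response grid, including its header label strip."""

    index: int  # 1-based, row-major over the sheet
    assay: Assay
    rect: Rect  # header + grid
    cells: tuple[tuple[Rect, ...], ...]  # [5 rows][n cols]
    subject_row: Optional[int] = None  # 1-based, human sheets only

    @property
    def n_cols(self) -> int:
        return len(self.cells[0])

    @property
    def grid_rect(self) -> Rect:
        return Rect(
            self.rect.x0, self.cells[0][0].y0, self.rect.x1, self.rect.y1
        )


@dataclass(frozen=True)
class SheetLayout:
    kind: SheetKind
    page_mm: tuple[float, float]
    frame_outer: Rect
    border_mm: float
    tables: tuple[TableBox, ...]
    version: int = LAYOUT_VERSION

    @property
    def frame_inner(self) -> Rect:
        b = self.border_mm
        f = self.frame_outer
        return Rect(f.x0 + b, f.y0 + b, f.x1 - b, f.y1 - b)

    def validate(self) -> None:
        if self.kind == "human":
            if len(self.tables) != 2 * HUMAN_SUBJECTS:
                raise ValueError("human sheet must hold 10 subject rows x 2")
            rows = {t.subject_row for t in self.tables}
            if rows != set(range(1, HUMAN_SUBJECTS + 1)):
                raise ValueError("bad subject rows")
        else:
            if len(self.tables) != ANIMAL_TABLES:
                raise ValueError("animal sheet must hold 20 tables")
        inner = self.frame_inner
        for t in self.tables:
            if len(t.cells) != N_ROWS:
                raise ValueError("table must have 5 rows")
            n = build_ladder(t.assay).n_filaments
            if any(len(r) != n for r in t.cells):
                raise ValueError("cell columns must match the ladder")
            if not inner.contains(t.rect):
                raise ValueError("table outside the fiducial frame")
        for i, a in enumerate(self.tables):
            for b in self.tables[i + 1 :]:
                if a.rect.overlaps(b.rect):
                    raise ValueError(
                        f"tables {a.index} and {b.index} overlap"
                    )


def _build_table(
    index: int,
    assay: Assay,
    x0: float,
    y0: float,
    cell_w: float,
    cell_h: float,
    subject_row: Optional[int] = None,
) -> TableBox:
    n = build_ladder(assay).n_filaments
    grid_y0 = y0 + HEADER_MM
    cells = tuple(
        tuple(
            Rect(
                x0 + c * cell_w,
                grid_y0 + r * cell_h,
                x0 + (c + 1) * cell_w,
                grid_y0 + (r + 1) * cell_h,
            )
            for c in range(n)
        )
        for r in range(N_ROWS)
    )
    rect = Rect(x0, y0, x0 + n * cell_w, grid_y0 + N_ROWS * cell_h)
    return TableBox(index, assay, rect, cells, subject_row)


def build_layout(kind: SheetKind) -> SheetLayout:
    if kind not in SHEET_KINDS:
        raise ValueError(f"unknown sheet kind {kind!r}; expected {SHEET_KINDS}")
    w, h = PAGE_MM
    frame = Rect(FRAME_MARGIN_MM, FRAME_MARGIN_MM, w - FRAME_MARGIN_MM, h - FRAME_MARGIN_MM)
    inner_pad = 3.0
    cx0 = FRAME_MARGIN_MM + BORDER_MM + inner_pad
    cy0 = FRAME_MARGIN_MM + BORDER_MM + inner_pad
    cx1 = w - FRAME_MARGIN_MM - BORDER_MM - inner_pad
    cy1 = h - FRAME_MARGIN_MM - BORDER_MM - inner_pad

    tables: list[TableBox] = []
    if kind in ("mouse", "rat"):
        assay = Assay.MOUSE if kind == "mouse" else Assay.RAT
        ncols, nrows = 4, 5
        cell_h = 5.2
        tbl_w = build_ladder(assay).n_filaments * CELL_W_MM
        tbl_h = HEADER_MM + N_ROWS * cell_h
        gx = (cx1 - cx0 - ncols * tbl_w) / (ncols - 1)
        gy = (cy1 - cy0 - nrows * tbl_h) / (nrows - 1)
        idx = 1
        for r in range(nrows):
            for c in range(ncols):
                tables.append(
                    _build_table(
                        idx,
                        assay,
                        cx0 + c * (tbl_w + gx),
                        cy0 + r * (tbl_h + gy),
                        CELL_W_MM,
                        cell_h,
                    )
                )
                idx += 1
    else:
        cell_h = 4.4
        tbl_h = HEADER_MM + N_ROWS * cell_h
        gap_x = 12.0
        mdt_w = build_ladder(Assay.HUMAN_MDT).n_filaments * CELL_W_MM
        mpt_w = build_ladder(Assay.HUMAN_MPT).n_filaments * CELL_W_MM
        total_w = mdt_w + gap_x + mpt_w
        x_start = cx0 + (cx1 - cx0 - total_w) / 2.0
        gy = (cy1 - cy0 - HUMAN_SUBJECTS * tbl_h) / (HUMAN_SUBJECTS - 1)
        idx = 1
        for s in range(1, HUMAN_SUBJECTS + 1):
            y0 = cy0 + (s - 1) * (tbl_h + gy)
            tables.append(
                _build_table(idx, Assay.HUMAN_MDT, x_start, y0, CELL_W_MM, cell_h, s)
            )
            idx += 1
            tables.append(
                _build_table(
                    idx, Assay.HUMAN_MPT, x_start + mdt_w + gap_x, y0, CELL_W_MM, cell_h, s
                )
            )
            idx += 1

    layout = SheetLayout(kind, PAGE_MM, frame, BORDER_MM, tuple(tables))
    layout.validate()
    return layout


# --- sidecar serialisation ------------------------------------------------

def _table_to_json(t: TableBox) -> dict:
    return {
        "index": t.index,
        "assay": t.assay.value,
        "subject_row": t.subject_row,
        "rect": t.rect.as_list(),
        "cells": [[c.as_list() for c in row] for row in t.cells],
    }


def save_layout(layout: SheetLayout, path: str | Path) -> None:
    doc = {
        "format": "updown-layout",
        "version": layout.version,
        "kind": layout.kind,
        "page_mm": list(layout.page_mm),
        "frame_outer": layout.frame_outer.as_list(),
        "border_mm": layout.border_mm,
        "tables": [_table_to_json(t) for t in layout.tables],
    }
    Path(path).write_text(
        json.dumps(doc, indent=1, sort_keys=True), encoding="utf-8"
    )


def load_layout(path: str | Path) -> SheetLayout:
    try:
        doc = json.loads(Path(path).read_text(encoding="utf-8"))
    except json.JSONDecodeError as e:
        raise LayoutParseError(f"{path}: line {e.lineno}: {e.msg}") from None
    if not isinstance(doc, dict) or doc.get("format") != "updown-layout":
        raise LayoutParseError(f"{path}: not an updown layout sidecar")
    try:
        tables = tuple(
            TableBox(
                index=t["index"],
                assay=Assay.coerce(t["assay"]),
                subject_row=t.get("subject_row"),
                rect=Rect(*t["rect"]),
                cells=tuple(
                    tuple(Rect(*c) for c in row) for row in t["cells"]
                ),
            )
            for t in doc["tables"]
        )
        layout = SheetLayout(
            kind=doc["kind"],
            page_mm=tuple(doc["page_mm"]),
            frame_outer=Rect(*doc["frame_outer"]),
            border_mm=doc["border_mm"],
            tables=tables,
            version=doc["version"],
        )
    except (KeyError, TypeError) as e:
        raise LayoutParseError(f"{path}: malformed layout field: {e}") from None
    layout.validate()
    return layout


# --- rendering ------------------------------------------------------------

def mm_to_px(mm: float, dpi: int) -> float:
    return mm * dpi / 25.4


def _force_label(force_g: float) -> str:
    return f"{force_g:g}"


def render_layout(layout: SheetLayout, dpi: int = 300) -> np.ndarray:
    """Rasterise the blank template to a grayscale uint8 page image
    (255 = paper, 0 = ink)."""
    w_px = round(mm_to_px(layout.page_mm[0], dpi))
    h_px = round(mm_to_px(layout.page_mm[1], dpi))
    img = Image.new("L", (w_px, h_px), 255)
    draw = ImageDraw.Draw(img)

    def px(v: float) -> int:
        return round(mm_to_px(v, dpi))

    f, b = layout.frame_outer, layout.border_mm
    draw.rectangle([px(f.x0), px(f.y0), px(f.x1) - 1, px(f.y1) - 1], fill=0)
    draw.rectangle(
        [px(f.x0 + b), px(f.y0 + b), px(f.x1 - b) - 1, px(f.y1 - b) - 1],
        fill=255,
    )

    line = max(1, round(mm_to_px(GRID_LINE_MM, dpi)))
    try:
        font = ImageFont.load_default(size=mm_to_px(2.0, dpi))
    except TypeError:  # Pillow < 10.1
        font = ImageFont.load_default()

    for t in layout.tables:
        ladder = build_ladder(t.assay)
        for r, row in enumerate(t.cells):
            for c, cell in enumerate(row):
                draw.rectangle(
                    [px(cell.x0), px(cell.y0), px(cell.x1), px(cell.y1)],
                    outline=0,
                    width=line,
                )
                if r == 0:
                    label = _force_label(ladder.forces_g[c])
                    cx = mm_to_px((cell.x0 + cell.x1) / 2.0, dpi)
                    cy = mm_to_px(t.rect.y0 + HEADER_MM / 2.0, dpi)
                    draw.text(
                        (cx, cy), label, fill=0, font=font, anchor="mm"
                    )
    return np.asarray(img, dtype=np.uint8)


def generate_template(
    kind: SheetKind,
    pdf_path: Optional[str | Path] = None,
    layout_path: Optional[str | Path] = None,
    dpi: int = 300,
) -> tuple[bytes, SheetLayout]:
    """Render the template for *kind* and return (PDF bytes, layout).

    The PDF embeds the page raster at *dpi*; the sidecar describes the
    geometry the reader needs.  Output is byte-stable for a fixed
    version, kind and dpi.
    """
    from .pdfio import write_image_pdf

    layout = build_layout(kind)
    page = render_layout(layout, dpi)
    pdf = write_image_pdf([page], dpi=dpi)
    if pdf_path is not None:
        Path(pdf_path).write_bytes(pdf)
    if layout_path is not None:
        save_layout(layout, layout_path)
    return pdf, layout
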