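"""Synthetic subjects, protocol execution, and filled-sheet rendering.

A simulated subject responds to a force via a cumulative-Gaussian
psychometric function in log10 force (a step function when the spread
is zero).  The protocol runner executes the recording grammar exactly,
producing a table and trial sequence with a known expected threshold;
the sheet renderer draws those tables onto a template page with
handwriting jitter, optional strike-outs, and scan-like page noise.
All randomness flows from explicit seeds.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
from PIL import Image, ImageDraw
from skimage.transform import AffineTransform, warp as _warp

from .kappa import KappaTable
from .ladder import Assay, FilamentLadder, build_ladder
from .layout import SheetLayout, build_layout, mm_to_px, render_layout
from .staircase import (
    N_ROWS,
    POST_CHANGE_TRIALS,
    CellMark,
    ResponseTable,
    Termination,
    ThresholdResult,
    TrialSequence,
    _next_index,
    compute_threshold,
)
from .glyphs import GlyphStyle, draw_glyph

__all__ = [
    "SimulatedSubject",
    "ScanNoise",
    "TableTruth",
    "GroundTruthRecord",
    "respond",
    "run_protocol",
    "render_filled_sheet",
    "strike_out",
]


@dataclass(frozen=True)
class SimulatedSubject:
    """Psychometric responder: P(response) = Phi((log f - log t) / sigma)."""

    true_threshold_g: float
    slope_sigma: float = 0.0  # log10 units; 0 = deterministic step
    seed: int = 0

    def __post_init__(self) -> None:
        if self.true_threshold_g <= 0:
            raise ValueError("true threshold must be positive")
        if self.slope_sigma < 0:
            raise ValueError("slope sigma must be non-negative")


def respond(
    subject: SimulatedSubject, force_g: float, rng: np.random.Generator
) -> CellMark:
    """One Bernoulli trial of the subject at *force_g*.

    With zero spread the subject responds exactly when the force reaches
    the threshold (boundary counts as a response).
    """
    if force_g <= 0:
        raise ValueError("force must be positive")
    if subject.slope_sigma == 0:
        positive = force_g >= subject.true_threshold_g
    else:
        z = (
            math.log10(force_g) - math.log10(subject.true_threshold_g)
        ) / subject.slope_sigma
        p = 0.5 * (1.0 + math.erf(z / math.sqrt(2.0)))
        positive = rng.random() < p
    return CellMark.POSITIVE if positive else CellMark.NEGATIVE


def run_protocol(
    subject: SimulatedSubject,
    ladder: FilamentLadder,
    rng: Optional[np.random.Generator] = None,
) -> tuple[TrialSequence, ResponseTable]:
    """Execute the up-down protocol and record it on a fresh table.

    Trials run until four responses follow the first change, or until
    the next required filament would fall outside the ladder.
    """
    if rng is None:
        rng = np.random.default_rng(subject.seed)
    n = ladder.n_filaments
    grid = [[CellMark.EMPTY] * n for _ in range(N_ROWS)]

    trials: list[tuple[int, CellMark]] = []
    index = ladder.start_index
    change: Optional[int] = None
    termination: Optional[Termination] = None
    while termination is None:
        resp = respond(subject, ladder.force(index), rng)
        trials.append((index, resp))
        if change is None and resp is not trials[0][1] and len(trials) > 1:
            change = len(trials)
        row = 0 if change is None or len(trials) <= change else len(trials) - change
        grid[row][index - 1] = resp
        if change is not None and len(trials) - change == POST_CHANGE_TRIALS:
            termination = Termination.COMPLETED
        else:
            nxt = _next_index(index, resp)
            if nxt > n:
                termination = Termination.OOR_HIGH
            elif nxt < 1:
                termination = Termination.OOR_LOW
            else:
                index = nxt
    seq = TrialSequence(tuple(trials), change, termination)
    table = ResponseTable(ladder.assay, tuple(tuple(r) for r in grid))
    return seq, table


# --- sheet rendering ------------------------------------------------------

@dataclass(frozen=True)
class ScanNoise:
    """Page-level degradation applied after drawing."""

    rotation_max_deg: float = 0.0
    scale_base: float = 1.0
    scale_jitter: float = 0.0
    translation_max_px: float = 0.0
    gaussian_sigma: float = 0.0  # gray levels
    glyph_jitter: float = 1.0

    PRESETS = ("none", "nominal", "rough")

    @classmethod
    def preset(cls, name: str) -> "ScanNoise":
        if name == "none":
            return cls(glyph_jitter=0.0)
        if name == "nominal":
            return cls(
                rotation_max_deg=3.0,
                scale_base=0.94,
                scale_jitter=0.02,
                translation_max_px=12.0,
                gaussian_sigma=8.0,
                glyph_jitter=1.0,
            )
        if name == "rough":
            return cls(
                rotation_max_deg=5.0,
                scale_base=0.92,
                scale_jitter=0.03,
                translation_max_px=20.0,
                gaussian_sigma=12.0,
                glyph_jitter=1.6,
            )
        raise ValueError(f"unknown noise preset {name!r}")


@dataclass(frozen=True)
class TableTruth:
    table_index: int  # layout slot, 1-based
    assay: Assay
    table_string: Optional[str]  # None for an empty slot
    expected: Optional[ThresholdResult]
    struck: bool = False

    def to_json(self) -> dict:
        exp = None
        if self.expected is not None:
            exp = {
                "threshold_g": self.expected.threshold_g,
                "status": self.expected.status.value,
                "kappa": self.expected.kappa_used,
                "pattern": self.expected.pattern,
                "final_force_g": self.expected.final_force_g,
            }
        return {
            "table_index": self.table_index,
            "assay": self.assay.value,
            "table_string": self.table_string,
            "expected": exp,
            "struck": self.struck,
        }


@dataclass(frozen=True)
class GroundTruthRecord:
    kind: str
    seed: int
    dpi: int
    tables: tuple[TableTruth, ...] = field(default_factory=tuple)

    def to_json(self) -> dict:
        return {
            "kind": self.kind,
            "seed": self.seed,
            "dpi": self.dpi,
            "tables": [t.to_json() for t in self.tables],
        }

    def save(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(self.to_json(), indent=1), encoding="utf-8"
        )


def strike_out(
    draw: ImageDraw.ImageDraw,
    table_rect_px: tuple[float, float, float, float],
    rng: np.random.Generator,
    dpi: int = 300,
) -> None:
    """Cross a table out: both diagonals plus a horizontal slash, thick
    enough that well over 12 cell boxes collect ink."""
    x0, y0, x1, y1 = table_rect_px
    width = max(2, round(mm_to_px(0.9, dpi)))

    def jit(v: float) -> float:
        return v + rng.uniform(-mm_to_px(1.0, dpi), mm_to_px(1.0, dpi))

    ym = (y0 + y1) / 2
    for a, b in (
        ((x0, y0), (x1, y1)),
        ((x1, y0), (x0, y1)),
        ((x0, ym), (x1, ym)),
        ((x0, y1), (x1, y0 + (y1 - y0) * 0.25)),
    ):
        draw.line(
            [(jit(a[0]), jit(a[1])), (jit(b[0]), jit(b[1]))],
            fill=0,
            width=width,
        )


def _apply_scan_noise(
    page: np.ndarray, noise: ScanNoise, rng: np.random.Generator
) -> np.ndarray:
    out = page
    if (
        noise.rotation_max_deg
        or noise.scale_base != 1.0
        or noise.scale_jitter
        or noise.translation_max_px
    ):
        angle = math.radians(
            rng.uniform(-noise.rotation_max_deg, noise.rotation_max_deg)
        )
        scale = noise.scale_base + rng.uniform(
            -noise.scale_jitter, noise.scale_jitter
        )
        t = noise.translation_max_px
        shift = (rng.uniform(-t, t), rng.uniform(-t, t))
        center = np.array(page.shape[::-1], dtype=float) / 2
        composed = (
            AffineTransform(translation=-center)
            + AffineTransform(rotation=angle, scale=scale)
            + AffineTransform(translation=center + np.array(shift))
        )
        # rebuild from the matrix: composed transforms take a slow
        # generic path inside skimage.transform.warp
        tform = AffineTransform(matrix=composed.params)
        out = _warp(
            out.astype(float) / 255.0,
            tform.inverse,
            cval=1.0,
            preserve_range=True,
        )
        out = out * 255.0
    else:
        out = out.astype(float)
    if noise.gaussian_sigma > 0:
        out = out + rng.normal(0.0, noise.gaussian_sigma, out.shape)
    return np.clip(out, 0, 255).astype(np.uint8)


def render_filled_sheet(
    kind: str,
    tables: Sequence[Optional[ResponseTable]],
    noise: ScanNoise = ScanNoise.preset("none"),
    seed: int = 0,
    dpi: int = 300,
    strike_indices: Sequence[int] = (),
    kappa: Optional[KappaTable] = None,
    glyph_style: GlyphStyle = GlyphStyle(),
    layout: Optional[SheetLayout] = None,
) -> tuple[np.ndarray, GroundTruthRecord]:
    """Draw *tables* into the template for *kind* and degrade the page.

    *tables* fills layout slots in order; None leaves a slot blank.
    ``strike_indices`` are 1-based slot indices crossed out after
    drawing.  Returns the page raster and the ground truth (expected
    thresholds are computed from the drawn tables; struck tables carry
    no expectation).
    """
    if layout is None:
        layout = build_layout(kind)
    if len(tables) > len(layout.tables):
        raise ValueError(
            f"{len(tables)} tables exceed sheet capacity {len(layout.tables)}"
        )
    if kappa is None:
        from .kappa import load_bundled

        kappa = load_bundled()
    rng = np.random.default_rng(np.random.SeedSequence([seed, dpi]))
    style = glyph_style.scaled(noise.glyph_jitter)

    base = render_layout(layout, dpi)
    img = Image.fromarray(base)
    draw = ImageDraw.Draw(img)
    struck = set(strike_indices)
    truths: list[TableTruth] = []

    from .staircase import table_to_sequence  # local import, cycle-free

    padded: list[Optional[ResponseTable]] = list(tables)
    padded += [None] * (len(layout.tables) - len(tables))
    for slot, table in zip(layout.tables, padded):
        if table is not None:
            if table.n_cols != slot.n_cols:
                raise ValueError(
                    f"table shape does not fit slot {slot.index}"
                )
            inset = 0.16
            for r, row in enumerate(table.cells):
                for c, mark in enumerate(row):
                    if mark is CellMark.EMPTY:
                        continue
                    cell = slot.cells[r][c]
                    box = (
                        mm_to_px(cell.x0 + cell.w * inset, dpi),
                        mm_to_px(cell.y0 + cell.h * inset, dpi),
                        mm_to_px(cell.x1 - cell.w * inset, dpi),
                        mm_to_px(cell.y1 - cell.h * inset, dpi),
                    )
                    draw_glyph(draw, mark, box, rng, style)
        if slot.index in struck:
            rect = (
                mm_to_px(slot.grid_rect.x0, dpi),
                mm_to_px(slot.grid_rect.y0, dpi),
                mm_to_px(slot.grid_rect.x1, dpi),
                mm_to_px(slot.grid_rect.y1, dpi),
            )
            strike_out(draw, rect, rng, dpi)
            truths.append(
                TableTruth(
                    slot.index,
                    slot.assay,
                    table.to_string() if table else None,
                    None,
                    struck=True,
                )
            )
        elif table is not None:
            ladder = build_ladder(slot.assay)
            seq = table_to_sequence(table, ladder)
            expected = compute_threshold(seq, ladder, kappa)
            truths.append(
                TableTruth(slot.index, slot.assay, table.to_string(), expected)
            )
        else:
            truths.append(TableTruth(slot.index, slot.assay, None, None))

    page = _apply_scan_noise(np.asarray(img), noise, rng)
    record = GroundTruthRecord(kind, seed, dpi, tuple(truths))
    return page, record
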