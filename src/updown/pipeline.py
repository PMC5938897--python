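"""End-to-end document processing and CSV export.

Per page: rasterize -> locate frame -> extract cells -> classify ->
encode -> validity gate -> repair -> threshold.  Every table slot on
every page yields exactly one result row; pages whose fiducial frame
cannot be found produce rows flagged ``frame_not_found`` rather than
aborting the document.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .glyphs import (
    DEFAULT_INK_THRESHOLD,
    ClassifierEnsemble,
    generate_glyphs,
    train_ensemble,
)
from .kappa import KappaTable, load_bundled
from .ladder import Assay, build_ladder
from .layout import SheetLayout, build_layout
from .repair import DEFAULT_REPAIR_CUTOFF, Lexicon, repair_table
from .staircase import (
    MAX_VALID_MARKS,
    CellMark,
    ResponseTable,
    ResultStatus,
    UngrammaticalTableError,
    compute_threshold,
    table_to_sequence,
)
from .vision import (
    DEFAULT_DPI,
    FrameNotFoundError,
    InputError,
    PageImage,
    extract_cells,
    ink_fraction,
    locate_frame,
    rasterize,
)

__all__ = ["ResultRow", "ReaderContext", "process_document", "process_page", "write_csv"]

log = logging.getLogger("updown")

NA = "N/A"

#: Seed for the default on-the-fly training set, fixed so repeated runs
#: produce byte-identical output.
DEFAULT_TRAIN_SEED = 1405
DEFAULT_TRAIN_N = 150


@dataclass(frozen=True)
class ResultRow:
    file: str
    page: int  # 1-based
    table: int  # 1-based layout slot
    assay: str
    raw: str
    repaired: str
    repair_distance: Optional[int]
    status: ResultStatus
    threshold_g: Optional[float]  # None iff status INVALID
    kappa: Optional[float]
    final_force_g: Optional[float]
    flags: str = ""

    def as_csv(self) -> list[str]:
        def num(v: Optional[float]) -> str:
            return NA if v is None else f"{v:.4g}"

        return [
            self.file,
            str(self.page),
            str(self.table),
            self.assay,
            self.raw,
            self.repaired,
            "" if self.repair_distance is None else str(self.repair_distance),
            self.status.value,
            num(self.threshold_g),
            "" if self.kappa is None else f"{self.kappa:.4g}",
            "" if self.final_force_g is None else f"{self.final_force_g:.4g}",
            self.flags,
        ]


CSV_HEADER = [
    "file", "page", "table", "assay", "raw", "repaired", "repair_distance",
    "status", "threshold_g", "kappa", "final_force_g", "flags",
]


@dataclass
class ReaderContext:
    """Everything the pipeline needs to read one kind of sheet."""

    kind: str
    layout: SheetLayout
    ensemble: ClassifierEnsemble
    kappa: KappaTable
    lexicons: dict[Assay, Lexicon] = field(default_factory=dict)
    ink_threshold: float = DEFAULT_INK_THRESHOLD
    repair_cutoff: int = DEFAULT_REPAIR_CUTOFF

    @classmethod
    def default(
        cls,
        kind: str,
        ensemble: Optional[ClassifierEnsemble] = None,
        ink_threshold: float = DEFAULT_INK_THRESHOLD,
        repair_cutoff: int = DEFAULT_REPAIR_CUTOFF,
    ) -> "ReaderContext":
        layout = build_layout(kind)
        if ensemble is None:
            ensemble = train_ensemble(
                generate_glyphs(DEFAULT_TRAIN_N, DEFAULT_TRAIN_SEED)
            )
        assays = {t.assay for t in layout.tables}
        lexicons = {a: Lexicon.build(a) for a in assays}
        return cls(
            kind, layout, ensemble, load_bundled(), lexicons,
            ink_threshold, repair_cutoff,
        )


def _invalid_row(
    file: str, page: int, table: int, assay: Assay, raw: str, flags: str,
    repaired: str = "", distance: Optional[int] = None,
) -> ResultRow:
    return ResultRow(
        file, page, table, assay.value, raw, repaired, distance,
        ResultStatus.INVALID, None, None, None, flags,
    )


def _process_table(
    ctx: ReaderContext,
    file: str,
    page_no: int,
    slot_index: int,
    assay: Assay,
    marks: list[CellMark],
    confidences: list[float],
) -> ResultRow:
    ladder = build_ladder(assay)
    n = ladder.n_filaments
    raw = "".join(m.char for m in marks)
    n_marks = sum(m is not CellMark.EMPTY for m in marks)
    if n_marks == 0:
        return _invalid_row(file, page_no, slot_index, assay, raw, "empty")
    if n_marks > MAX_VALID_MARKS:
        return _invalid_row(file, page_no, slot_index, assay, raw, "overmarked")

    outcome = repair_table(
        raw, ctx.lexicons[assay], ctx.repair_cutoff, confidences
    )
    flags = []
    if outcome.distance > 0:
        flags.append("repaired")
    if outcome.ambiguous:
        flags.append("ambiguous")
    if not outcome.accepted:
        return _invalid_row(
            file, page_no, slot_index, assay, raw, "unrepairable",
            outcome.corrected, outcome.distance,
        )
    table = ResponseTable.from_string(
        assay, outcome.corrected, (page_no, slot_index)
    )
    try:
        seq = table_to_sequence(table, ladder)
    except UngrammaticalTableError:  # pragma: no cover - lexicon guards this
        return _invalid_row(
            file, page_no, slot_index, assay, raw, "ungrammatical",
            outcome.corrected, outcome.distance,
        )
    res = compute_threshold(seq, ladder, ctx.kappa, (page_no, slot_index))
    return ResultRow(
        file, page_no, slot_index, assay.value, raw, outcome.corrected,
        outcome.distance, res.status, res.threshold_g, res.kappa_used,
        res.final_force_g, ",".join(flags),
    )


def process_page(
    ctx: ReaderContext, page: PageImage, file: str = ""
) -> list[ResultRow]:
    """Read every table slot of one page."""
    warp_result = locate_frame(page, ctx.layout)
    log.info(
        "page %d: frame residual %.2f px", page.page_index,
        warp_result.residual_px,
    )
    cells = extract_cells(warp_result, ctx.layout)
    rows: list[ResultRow] = []
    for slot in ctx.layout.tables:
        grid = cells[slot.index]
        patches = [p for row in grid for p in row]
        inked = [
            i for i, p in enumerate(patches)
            if ink_fraction(p) >= ctx.ink_threshold
        ]
        marks = [CellMark.EMPTY] * len(patches)
        confs = [1.0] * len(patches)
        if inked:
            results = ctx.ensemble.predict_batch([patches[i] for i in inked])
            for i, (mark, conf) in zip(inked, results):
                marks[i] = mark
                confs[i] = conf
                if conf < 1.0:
                    log.debug(
                        "page %d table %d cell %d: split vote (%s, %.2f)",
                        page.page_index, slot.index, i, mark.char, conf,
                    )
        rows.append(
            _process_table(
                ctx, file, page.page_index, slot.index, slot.assay,
                marks, confs,
            )
        )
    return rows


def process_document(
    path: str | Path,
    kind: str,
    ctx: Optional[ReaderContext] = None,
    dpi: float = DEFAULT_DPI,
) -> tuple[list[ResultRow], int]:
    """Process every page of a scanned document.

    Returns (rows, failed_page_count).  Unreadable pages contribute one
    INVALID row per table slot, flagged with the failure, so the row
    count is always pages x tables-per-sheet.
    """
    path = Path(path)
    if ctx is None:
        ctx = ReaderContext.default(kind)
    elif ctx.kind != kind:
        raise ValueError(f"context built for {ctx.kind!r}, not {kind!r}")
    pages = rasterize(path, dpi)
    if not pages:
        raise InputError(f"{path}: document has no pages")
    rows: list[ResultRow] = []
    failed = 0
    for page in pages:
        try:
            rows.extend(process_page(ctx, page, path.name))
        except FrameNotFoundError as e:
            failed += 1
            log.warning("page %d skipped: %s", page.page_index, e)
            for slot in ctx.layout.tables:
                rows.append(
                    _invalid_row(
                        path.name, page.page_index, slot.index, slot.assay,
                        "", "frame_not_found",
                    )
                )
    return rows, failed


def write_csv(rows: Sequence[ResultRow], out_path: str | Path) -> Path:
    """RFC-4180 CSV export; returns the written path."""
    out_path = Path(out_path)
    with out_path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(CSV_HEADER)
        for row in rows:
            writer.writerow(row.as_csv())
    return out_path


def default_csv_path(input_path: str | Path) -> Path:
    """Results land beside the input document."""
    return Path(input_path).with_suffix(".csv")
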