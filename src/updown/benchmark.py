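"""Synthetic end-to-end benchmark: exact-threshold recovery rate.

Generates ground-truthed filled sheets, runs the full reading pipeline
on the rendered pages, and counts tables whose recovered threshold
matches the expectation exactly (status and value).  This is the
desk-scale analog of benchmarking the reader against hand-scored
scanned sheets.
"""

from __future__ import annotations

from typing import Optional

import numpy as np

from .ladder import build_ladder
from .pipeline import ReaderContext, process_page
from .simulate import ScanNoise, SimulatedSubject, render_filled_sheet, run_protocol
from .vision import PageImage

__all__ = ["end_to_end_recovery"]


def end_to_end_recovery(
    kind: str,
    sheets: int,
    noise: str | ScanNoise,
    seed: int,
    dpi: int = 300,
    sigma: float = 0.1,
    ctx: Optional[ReaderContext] = None,
) -> tuple[int, int]:
    """Run *sheets* full sheets through render + read; return
    (exactly recovered tables, total truthed tables)."""
    if isinstance(noise, str):
        noise = ScanNoise.preset(noise)
    if ctx is None:
        ctx = ReaderContext.default(kind)
    layout = ctx.layout
    n_ok = n_total = 0
    for s in range(sheets):
        rng = np.random.default_rng(np.random.SeedSequence([seed, s]))
        tables = []
        for slot in layout.tables:
            ladder = build_ladder(slot.assay)
            lo, hi = ladder.forces_g[1], ladder.forces_g[-2]
            t = 10 ** rng.uniform(np.log10(lo), np.log10(hi))
            _, tab = run_protocol(SimulatedSubject(t, sigma), ladder, rng)
            tables.append(tab)
        page, record = render_filled_sheet(
            kind, tables, noise, seed=seed * 9973 + s, dpi=dpi
        )
        rows = process_page(ctx, PageImage(page, dpi, s + 1), "synthetic")
        for row, truth in zip(rows, record.tables):
            expected = truth.expected
            if expected is None:
                continue
            n_total += 1
            n_ok += int(
                row.threshold_g is not None
                and abs(row.threshold_g - expected.threshold_g) < 1e-9
                and row.status.value == expected.status.value
            )
    return n_ok, n_total
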