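# updown

Automated scoring of handwritten von Frey up–down sheets.

The package covers the full workflow around the up–down (staircase)
estimation of 50% mechanical thresholds:

- **Templates** — printable A4 scoring sheets (PDF + JSON layout
  sidecar) for mouse, rat, and human (MDT/MPT) filament ladders.
- **Reading** — scanned sheets (raster-backed PDF, PNG, TIFF) are
  deskewed via the sheet's fiducial border, split into cells, and each
  cell is classified as X / O / empty by a majority-voting k-NN
  ensemble.
- **Validation & repair** — classifier output is checked against the
  exhaustive lexicon of recordings legal under the up–down grammar and
  rectified by Levenshtein closest match; crossed-out tables (more than
  12 marked boxes) are reported as `N/A`.
- **Thresholds** — the Dixon formula `10^(Xf + κδ) / 10000` g, with κ
  looked up from the response pattern near the threshold and δ the
  per-assay log step (0.25 mouse, 0.17 rat, 0.25 MDT, 0.21 MPT).
  Out-of-range runs are capped at the extreme filament and flagged.
- **Simulation** — psychometric subjects, exact protocol execution, and
  ground-truthed synthetic "scans" (handwriting jitter, rotation,
  scale, noise, strike-outs) for end-to-end testing without data.

## CLI

```sh
# printable template + layout sidecar
updown template --assay mouse --out sheet.pdf --layout sheet.json

# ground-truthed synthetic scan
updown synth --assay mouse --tables 20 --noise nominal --seed 42 \
    --out scan.pdf --truth truth.json

# read a scanned document into per-table thresholds (CSV lands beside
# the input unless --out is given)
updown read scan.pdf --assay mouse

# persist a glyph model / benchmark the pipeline end to end
updown train --out model.npz --n 150 --seed 1405
updown eval --assay mouse --sheets 10 --noise nominal
```

`updown read` accepts `--config file.toml` to override reader defaults
(dpi, ink threshold, repair cutoff, training parameters); all defaults
are embedded.

Exit codes: 0 success, 2 partial (some pages unreadable), 1 fatal.

### CSV schema

One row per table slot per page, always `pages × tables-per-sheet`
rows: `file, page, table, assay, raw, repaired, repair_distance,
status, threshold_g, kappa, final_force_g, flags`. `threshold_g` is
`N/A` exactly when the status is `invalid` (empty slot, crossed-out,
or unrepairable table); out-of-range runs carry the capped extreme
force plus an `oor_high`/`oor_low` status.

## Notes

- The κ table is bundled at `src/updown/data/kappa_table.txt`,
  generated by `python -m updown.kappa` (maximum-likelihood probit
  values, spread = ladder step); X↔O antisymmetry is validated at load.
- PDF I/O is deliberately minimal: the package writes deterministic
  raster-backed PDFs and reads back that same subset. Arbitrary vector
  PDFs are out of scope; use PNG/TIFF page images for scans from other
  producers.
- Filament forces are fixed per assay by design; the sheets and the
  reader share the bundled layout.
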