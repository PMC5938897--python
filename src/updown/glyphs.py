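"""Handwritten-looking X/O glyphs and the k-NN ensemble that reads them.

Empty cells are decided by ink fraction before any classifier runs; the
ensemble only separates X from O.  Three k-NN members vote by majority:
raw 20x20 pixels (k=3), 4x4 zone densities (k=5), and an 8-bin stroke
orientation histogram (k=3).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
from PIL import Image, ImageDraw
from sklearn.neighbors import KNeighborsClassifier

from .staircase import CellMark
from .vision import ink_fraction

__all__ = [
    "GlyphSample",
    "GlyphStyle",
    "ClassifierEnsemble",
    "generate_glyphs",
    "extract_features",
    "train_ensemble",
    "classify_cell",
    "draw_glyph",
    "CANONICAL_SIZE",
    "DEFAULT_INK_THRESHOLD",
    "FEATURE_SCHEMES",
]

CANONICAL_SIZE = 20
DEFAULT_INK_THRESHOLD = 0.02
FEATURE_SCHEMES = ("raw", "zones", "orient")

#: Ensemble members: (feature scheme, neighbour count).  Odd membership
#: makes majority ties impossible on a two-class problem.
DEFAULT_MEMBERS = (("raw", 3), ("zones", 5), ("orient", 3))


@dataclass(frozen=True)
class GlyphStyle:
    """Stroke-variation parameters; ``jitter`` scales all randomness."""

    jitter: float = 1.0
    thickness_frac: float = 0.09  # stroke width as fraction of glyph size
    gap_probability: float = 0.25  # chance an O is left slightly open

    def scaled(self, jitter: float) -> "GlyphStyle":
        return GlyphStyle(jitter, self.thickness_frac, self.gap_probability)


@dataclass(frozen=True)
class GlyphSample:
    patch: np.ndarray  # canonical 20x20 bool, True = ink
    label: CellMark  # POSITIVE or NEGATIVE
    style_seed: int


def _x_strokes(
    rng: np.random.Generator, j: float
) -> list[list[tuple[float, float]]]:
    """Two crossing polylines in the unit square, with endpoint and
    midpoint jitter."""

    def pt(x: float, y: float, amp: float) -> tuple[float, float]:
        return (
            x + rng.uniform(-amp, amp) * j,
            y + rng.uniform(-amp, amp) * j,
        )

    strokes = []
    for (x0, y0), (x1, y1) in (((0.12, 0.12), (0.88, 0.88)),
                               ((0.88, 0.12), (0.12, 0.88))):
        a = pt(x0, y0, 0.10)
        b = pt(x1, y1, 0.10)
        mid = (
            (a[0] + b[0]) / 2 + rng.uniform(-0.06, 0.06) * j,
            (a[1] + b[1]) / 2 + rng.uniform(-0.06, 0.06) * j,
        )
        strokes.append([a, mid, b])
    return strokes


def _o_stroke(
    rng: np.random.Generator, j: float, gap_probability: float
) -> list[list[tuple[float, float]]]:
    """A perturbed ellipse, optionally left open over a small arc."""
    cx = 0.5 + rng.uniform(-0.07, 0.07) * j
    cy = 0.5 + rng.uniform(-0.07, 0.07) * j
    rx = 0.33 * (1 + rng.uniform(-0.18, 0.18) * j)
    ry = 0.33 * (1 + rng.uniform(-0.18, 0.18) * j)
    tilt = rng.uniform(-0.5, 0.5) * j
    phase = rng.uniform(0, 2 * math.pi)
    span = 2 * math.pi
    if rng.random() < gap_probability * j:
        span -= rng.uniform(0.2, 0.7)
    pts = []
    for k in range(25):
        a = phase + span * k / 24
        x = rx * math.cos(a)
        y = ry * math.sin(a)
        xr = x * math.cos(tilt) - y * math.sin(tilt)
        yr = x * math.sin(tilt) + y * math.cos(tilt)
        wob = 1 + rng.uniform(-0.05, 0.05) * j
        pts.append((cx + xr * wob, cy + yr * wob))
    return [pts]


def glyph_strokes(
    label: CellMark, rng: np.random.Generator, style: GlyphStyle
) -> list[list[tuple[float, float]]]:
    """Polylines of one glyph instance, in unit-square coordinates."""
    if label is CellMark.POSITIVE:
        return _x_strokes(rng, style.jitter)
    if label is CellMark.NEGATIVE:
        return _o_stroke(rng, style.jitter, style.gap_probability)
    raise ValueError("no strokes for EMPTY")


def draw_glyph(
    draw: ImageDraw.ImageDraw,
    label: CellMark,
    box_px: tuple[float, float, float, float],
    rng: np.random.Generator,
    style: GlyphStyle,
    ink: int = 0,
) -> None:
    """Draw one glyph into a pixel box of a PIL canvas."""
    x0, y0, x1, y1 = box_px
    w, h = x1 - x0, y1 - y0
    size = min(w, h)
    width = max(1, round(size * style.thickness_frac
                         * (1 + rng.uniform(-0.3, 0.3) * style.jitter)))
    for stroke in glyph_strokes(label, rng, style):
        pts = [(x0 + px * w, y0 + py * h) for px, py in stroke]
        draw.line(pts, fill=ink, width=width, joint="curve")


def _render_canonical(
    label: CellMark, rng: np.random.Generator, style: GlyphStyle
) -> np.ndarray:
    big = CANONICAL_SIZE * 4
    img = Image.new("L", (big, big), 255)
    draw_glyph(ImageDraw.Draw(img), label, (0, 0, big, big), rng, style)
    small = img.resize((CANONICAL_SIZE, CANONICAL_SIZE), Image.BILINEAR)
    return np.asarray(small) < 128


def generate_glyphs(
    n_per_class: int,
    seed: int,
    style: GlyphStyle = GlyphStyle(),
) -> list[GlyphSample]:
    """Balanced synthetic training set: *n_per_class* of each of X and
    O, deterministic for a given seed and style."""
    if n_per_class < 1:
        raise ValueError("n_per_class must be >= 1")
    samples = []
    for i in range(n_per_class):
        for label in (CellMark.POSITIVE, CellMark.NEGATIVE):
            sub = np.random.default_rng(
                np.random.SeedSequence([seed, i, label is CellMark.POSITIVE])
            )
            samples.append(
                GlyphSample(_render_canonical(label, sub, style), label, i)
            )
    return samples


def _to_canonical(patch: np.ndarray) -> np.ndarray:
    patch = np.asarray(patch)
    if patch.shape == (CANONICAL_SIZE, CANONICAL_SIZE):
        return patch.astype(bool)
    img = Image.fromarray((patch.astype(np.uint8)) * 255)
    small = img.resize((CANONICAL_SIZE, CANONICAL_SIZE), Image.BILINEAR)
    return np.asarray(small) >= 128


def extract_features(patch: np.ndarray, scheme: str) -> np.ndarray:
    """Feature vector of a canonical (or resizable) boolean ink patch.

    ``raw``: flattened binary pixels (400-d).  ``zones``: 4x4 block ink
    densities (16-d).  ``orient``: 8-bin edge-orientation histogram.
    """
    p = _to_canonical(patch).astype(float)
    if scheme == "raw":
        return p.ravel()
    if scheme == "zones":
        z = CANONICAL_SIZE // 4
        return p.reshape(4, z, 4, z).mean(axis=(1, 3)).ravel()
    if scheme == "orient":
        gy, gx = np.gradient(p)
        mag = np.hypot(gx, gy)
        ang = np.mod(np.arctan2(gy, gx), math.pi)  # orientation, not direction
        bins = np.minimum((ang / math.pi * 8).astype(int), 7)
        hist = np.bincount(bins.ravel(), weights=mag.ravel(), minlength=8)
        total = hist.sum()
        return hist / total if total > 0 else hist
    raise ValueError(f"unknown feature scheme {scheme!r}")


@dataclass
class ClassifierEnsemble:
    """Majority vote over independently trained k-NN members."""

    members: list[tuple[str, KNeighborsClassifier]]
    training_fingerprint: str = ""
    _label_order: tuple[str, ...] = field(default=("O", "X"))

    def predict(self, patch: np.ndarray) -> CellMark:
        votes = 0
        for scheme, knn in self.members:
            feat = extract_features(patch, scheme).reshape(1, -1)
            votes += int(knn.predict(feat)[0] == "X")
        return (
            CellMark.POSITIVE
            if votes * 2 > len(self.members)
            else CellMark.NEGATIVE
        )

    def predict_with_confidence(
        self, patch: np.ndarray
    ) -> tuple[CellMark, float]:
        return self.predict_batch([patch])[0]

    def predict_batch(
        self, patches: Sequence[np.ndarray]
    ) -> list[tuple[CellMark, float]]:
        """Classify many patches at once; one sklearn call per member."""
        if not len(patches):
            return []
        votes = np.zeros(len(patches), dtype=int)
        for scheme, knn in self.members:
            feats = np.array(
                [extract_features(p, scheme) for p in patches]
            )
            votes += knn.predict(feats) == "X"
        n = len(self.members)
        return [
            (
                CellMark.POSITIVE if v * 2 > n else CellMark.NEGATIVE,
                max(v, n - v) / n,
            )
            for v in votes
        ]

    def save(self, path: str | Path) -> None:
        arrays: dict[str, np.ndarray] = {
            "version": np.array([1]),
            "n_members": np.array([len(self.members)]),
        }
        for i, (scheme, knn) in enumerate(self.members):
            arrays[f"scheme_{i}"] = np.array([scheme])
            arrays[f"k_{i}"] = np.array([knn.n_neighbors])
            arrays[f"X_{i}"] = knn._fit_X  # noqa: SLF001 - re-fit on load
            arrays[f"y_{i}"] = np.array(
                [self._label_order[c] for c in knn._y]
            )
        np.savez_compressed(path, **arrays)

    @classmethod
    def load(cls, path: str | Path) -> "ClassifierEnsemble":
        with np.load(path, allow_pickle=False) as data:
            members = []
            for i in range(int(data["n_members"][0])):
                scheme = str(data[f"scheme_{i}"][0])
                knn = KNeighborsClassifier(n_neighbors=int(data[f"k_{i}"][0]))
                knn.fit(data[f"X_{i}"], data[f"y_{i}"])
                members.append((scheme, knn))
        return cls(members)


def train_ensemble(
    samples: Sequence[GlyphSample],
    members: Sequence[tuple[str, int]] = DEFAULT_MEMBERS,
) -> ClassifierEnsemble:
    """Fit the voting ensemble on labelled glyphs.

    Training rows are sorted canonically before fitting, so the result
    is invariant to the order samples are supplied in.
    """
    labels = {s.label for s in samples}
    if len(labels) < 2:
        raise ValueError("training requires both X and O samples")
    if len(members) < 3 or len(members) % 2 == 0:
        raise ValueError("ensemble needs an odd number of members >= 3")
    fitted = []
    for scheme, k in members:
        feats = np.array(
            [extract_features(s.patch, scheme) for s in samples]
        )
        ys = np.array([s.label.char for s in samples])
        order = np.lexsort(np.vstack([feats.T, ys == "X"]))
        knn = KNeighborsClassifier(n_neighbors=k)
        knn.fit(feats[order], ys[order])
        fitted.append((scheme, knn))
    return ClassifierEnsemble(fitted)


def classify_cell(
    cell_image: np.ndarray,
    ensemble: ClassifierEnsemble,
    ink_threshold: float = DEFAULT_INK_THRESHOLD,
) -> CellMark:
    """X / O / EMPTY decision for one binarised cell patch."""
    mark, _ = classify_cell_with_confidence(
        cell_image, ensemble, ink_threshold
    )
    return mark


def classify_cell_with_confidence(
    cell_image: np.ndarray,
    ensemble: ClassifierEnsemble,
    ink_threshold: float = DEFAULT_INK_THRESHOLD,
) -> tuple[CellMark, float]:
    if ink_fraction(cell_image) < ink_threshold:
        return CellMark.EMPTY, 1.0
    return ensemble.predict_with_confidence(cell_image)
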