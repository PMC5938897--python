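"""Canonical table strings and closest-match rectification.

Classifier output for a table is flattened to a fixed-length string over
``{X, O, .}`` and, when it is not itself a legal recording, replaced by
the nearest entry of the exhaustive lexicon of legal recordings under
Levenshtein distance.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .ladder import Assay, build_ladder
from .staircase import N_ROWS, ResponseTable, enumerate_valid_tables

__all__ = [
    "ALPHABET",
    "DEFAULT_REPAIR_CUTOFF",
    "Lexicon",
    "RepairOutcome",
    "edit_distance",
    "encode_table",
    "decode_table",
    "repair_table",
]

ALPHABET = "XO."

#: Maximum accepted repair distance; beyond it a table is unrepairable.
DEFAULT_REPAIR_CUTOFF = 3


def encode_table(table: ResponseTable) -> str:
    """Row-major flattening of a table over the {X, O, .} alphabet."""
    return table.to_string()


def decode_table(
    assay: Assay | str,
    text: str,
    source: Optional[tuple[int, int]] = None,
) -> ResponseTable:
    return ResponseTable.from_string(assay, text, source)


def edit_distance(a: str, b: str) -> int:
    """Levenshtein distance with unit insert/delete/substitute costs."""
    if a == b:
        return 0
    if not a:
        return len(b)
    if not b:
        return len(a)
    prev = list(range(len(b) + 1))
    for i, ca in enumerate(a, start=1):
        cur = [i]
        for j, cb in enumerate(b, start=1):
            cur.append(
                min(
                    prev[j] + 1,
                    cur[j - 1] + 1,
                    prev[j - 1] + (ca != cb),
                )
            )
        prev = cur
    return prev[-1]


def _batch_levenshtein(query: str, matrix: np.ndarray) -> np.ndarray:
    """Levenshtein distance from *query* to every row of *matrix*
    (uint8-coded equal-length strings), vectorised across rows."""
    k, n = matrix.shape
    q = np.frombuffer(query.encode("ascii"), dtype=np.uint8)
    m = len(q)
    prev = np.broadcast_to(np.arange(n + 1), (k, n + 1)).astype(np.int32)
    for i in range(1, m + 1):
        cur = np.empty_like(prev)
        cur[:, 0] = i
        sub = prev[:, :-1] + (matrix != q[i - 1])
        np.minimum(sub, prev[:, 1:] + 1, out=sub)
        # insertion column requires a left-to-right scan
        for j in range(1, n + 1):
            cur[:, j] = np.minimum(sub[:, j - 1], cur[:, j - 1] + 1)
        prev = cur
    return prev[:, -1]


@dataclass(frozen=True)
class RepairOutcome:
    corrected: str
    distance: int
    ambiguous: bool
    accepted: bool


class Lexicon:
    """Sorted set of every legal table string for one assay."""

    def __init__(self, assay: Assay | str, entries: Sequence[str]):
        self.assay = Assay.coerce(assay)
        self.entries: tuple[str, ...] = tuple(sorted(set(entries)))
        if not self.entries:
            raise ValueError("empty lexicon")
        n = len(self.entries[0])
        if any(len(e) != n for e in self.entries):
            raise ValueError("lexicon entries differ in length")
        self._set = frozenset(self.entries)
        self._matrix = np.array(
            [np.frombuffer(e.encode("ascii"), dtype=np.uint8) for e in self.entries]
        )

    @classmethod
    def build(cls, assay: Assay | str) -> "Lexicon":
        assay = Assay.coerce(assay)
        return cls(assay, enumerate_valid_tables(build_ladder(assay)))

    def __contains__(self, text: str) -> bool:
        return text in self._set

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries)

    @property
    def fingerprint(self) -> str:
        h = hashlib.sha256()
        for e in self.entries:
            h.update(e.encode("ascii"))
            h.update(b"\n")
        return h.hexdigest()[:16]

    def save(self, path: str | Path) -> None:
        lines = [
            f"# updown lexicon assay={self.assay.value} "
            f"entries={len(self)} fingerprint={self.fingerprint}"
        ]
        lines.extend(self.entries)
        Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")

    @classmethod
    def load(cls, path: str | Path) -> "Lexicon":
        lines = Path(path).read_text(encoding="utf-8").splitlines()
        if not lines or not lines[0].startswith("# updown lexicon"):
            raise ValueError(f"{path}: not a lexicon file")
        header = dict(
            kv.split("=", 1) for kv in lines[0].removeprefix("# ").split()[2:]
        )
        lex = cls(header["assay"], [ln for ln in lines[1:] if ln])
        if header.get("fingerprint") not in (None, lex.fingerprint):
            raise ValueError(f"{path}: fingerprint mismatch")
        return lex


def repair_table(
    observed: str,
    lexicon: Lexicon,
    cutoff: int = DEFAULT_REPAIR_CUTOFF,
    confidences: Optional[Sequence[float]] = None,
) -> RepairOutcome:
    """Closest-match rectification of a classified table string.

    Lexicon members pass through unchanged.  Otherwise the entry with
    minimal Levenshtein distance wins; among equidistant candidates the
    one disturbing the fewest confidently-classified cells is preferred
    (*confidences*, one value per cell, higher = more trusted), with any
    remaining tie broken lexicographically.  ``accepted`` is False when
    the distance exceeds *cutoff*.
    """
    if set(observed) - set(ALPHABET):
        raise ValueError("observed string contains characters outside {X,O,.}")
    if observed in lexicon:
        return RepairOutcome(observed, 0, ambiguous=False, accepted=True)

    dists = _batch_levenshtein(observed, lexicon._matrix)
    best = int(dists.min())
    idx = np.flatnonzero(dists == best)
    candidates = [lexicon.entries[i] for i in idx]
    ambiguous = len(candidates) > 1
    if ambiguous and confidences is not None and len(observed) == len(
        lexicon.entries[0]
    ):
        conf = np.asarray(confidences, dtype=float)

        def trust_cost(entry: str) -> float:
            return float(
                sum(c for ch, e, c in zip(observed, entry, conf) if ch != e)
            )

        lo = min(trust_cost(e) for e in candidates)
        candidates = [e for e in candidates if trust_cost(e) == lo]
    corrected = min(candidates)
    return RepairOutcome(
        corrected, best, ambiguous=ambiguous, accepted=best <= cutoff
    )
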