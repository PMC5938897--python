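"""Kappa correction factors for the Dixon 50% threshold.

Each completed test contributes a six-response pattern (the trial before
the first change, the change trial, and the four trials after it).  The
pattern fixes the relative filament levels of those trials, so the
maximum-likelihood estimate of the threshold given the pattern can be
written as ``final level + kappa`` in units of the ladder step delta.

Kappa is computed here by maximising the probit likelihood of the six
responses over the threshold location, with the response-probability
spread taken equal to the ladder step (the classical working assumption
of the staircase method).  Values are bundled as a plain-text resource
and validated for X<->O antisymmetry at load time.
"""

from __future__ import annotations

import itertools
import math
from importlib import resources
from pathlib import Path
from typing import Iterator, Mapping

from scipy.optimize import minimize_scalar
from scipy.stats import norm

__all__ = [
    "KappaTable",
    "compute_kappa",
    "generate_patterns",
    "generate_resource_text",
    "load_bundled",
]

PATTERN_LEN = 6
_RESOURCE = "kappa_table.txt"
_ANTISYMMETRY_TOL = 1e-6


def _complement(pattern: str) -> str:
    return pattern.translate(str.maketrans("XO", "OX"))


def _levels(pattern: str) -> list[int]:
    """Relative filament levels of the windowed trials, in delta units.

    The step rule determines each level from the previous response:
    down one after X, up one after O.
    """
    levels = [0]
    for resp in pattern[:-1]:
        levels.append(levels[-1] + (-1 if resp == "X" else 1))
    return levels


def generate_patterns() -> Iterator[str]:
    """All grammatical six-response windows: the second response is the
    first change, so it must differ from the first; the rest are free."""
    for first in "XO":
        second = "O" if first == "X" else "X"
        for tail in itertools.product("XO", repeat=PATTERN_LEN - 2):
            yield first + second + "".join(tail)


def _neg_log_likelihood(mu: float, pattern: str) -> float:
    nll = 0.0
    for level, resp in zip(_levels(pattern), pattern):
        p = norm.cdf(level - mu)
        p = min(max(p, 1e-300), 1.0 - 1e-16)
        nll -= math.log(p if resp == "X" else 1.0 - p)
    return nll


def compute_kappa(pattern: str) -> float:
    """Kappa for one response pattern, in ladder-step units.

    Antisymmetry (kappa of the X<->O complement is the exact negation)
    is enforced by computing only the O-leading member of each pair.
    """
    if len(pattern) != PATTERN_LEN or set(pattern) - set("XO"):
        raise ValueError(f"malformed pattern {pattern!r}")
    if pattern[1] == pattern[0]:
        raise ValueError(f"pattern {pattern!r} has no change at trial two")
    if pattern[0] == "X":
        return -compute_kappa(_complement(pattern))
    levels = _levels(pattern)
    lo, hi = min(levels) - 6.0, max(levels) + 6.0
    res = minimize_scalar(
        _neg_log_likelihood,
        bounds=(lo, hi),
        args=(pattern,),
        method="bounded",
        options={"xatol": 1e-10},
    )
    return float(res.x) - levels[-1]


class KappaTable(Mapping[str, float]):
    """Pattern -> kappa lookup with antisymmetry validated on load."""

    def __init__(self, values: Mapping[str, float]):
        self._values = dict(values)
        self._validate()

    def _validate(self) -> None:
        for pattern, k in self._values.items():
            comp = _complement(pattern)
            if comp not in self._values:
                raise ValueError(f"complement of {pattern} missing")
            if abs(self._values[comp] + k) > _ANTISYMMETRY_TOL:
                raise ValueError(
                    f"kappa antisymmetry violated for {pattern}/{comp}"
                )

    def __getitem__(self, pattern: str) -> float:
        return self._values[pattern]

    def __iter__(self) -> Iterator[str]:
        return iter(self._values)

    def __len__(self) -> int:
        return len(self._values)

    @property
    def max_abs_kappa(self) -> float:
        return max(abs(v) for v in self._values.values())

    @classmethod
    def compute(cls) -> "KappaTable":
        """Recompute the full table from scratch (slow path)."""
        return cls({p: compute_kappa(p) for p in generate_patterns()})

    @classmethod
    def from_text(cls, text: str) -> "KappaTable":
        values = {}
        for lineno, line in enumerate(text.splitlines(), start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) != 2:
                raise ValueError(f"malformed kappa line {lineno}: {line!r}")
            values[parts[0]] = float(parts[1])
        return cls(values)

    @classmethod
    def from_file(cls, path: str | Path) -> "KappaTable":
        return cls.from_text(Path(path).read_text(encoding="utf-8"))


def load_bundled() -> KappaTable:
    """Load the kappa resource shipped with the package."""
    text = (
        resources.files("updown.data").joinpath(_RESOURCE).read_text("utf-8")
    )
    return KappaTable.from_text(text)


def generate_resource_text() -> str:
    lines = [
        "# kappa correction factors, keyed by the six-response window",
        "# (pre-change trial, first change, four subsequent trials).",
        "# Maximum-likelihood values, probit model, spread = ladder step.",
        "# Regenerate with: python -m updown.kappa",
    ]
    table = KappaTable.compute()
    for pattern in sorted(table):
        lines.append(f"{pattern}\t{table[pattern]:+.6f}")
    return "\n".join(lines) + "\n"


def _main() -> None:  # pragma: no cover
    import sys

    out = Path(sys.argv[1]) if len(sys.argv) > 1 else (
        Path(__file__).parent / "data" / _RESOURCE
    )
    out.write_text(generate_resource_text(), encoding="utf-8")
    print(f"wrote {out}")


if __name__ == "__main__":  # pragma: no cover
    _main()
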