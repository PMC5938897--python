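"""Up-down protocol model: tables, the recording grammar, and the Dixon
50% threshold.

A scoring table has 5 rows and one column per filament.  Row one holds
the opening run of trials — every trial up to and including the first
response change — written outward from the starting column.  Each later
row holds exactly one trial.  Testing ends after four trials beyond the
first change, or early when the subject fails to respond to the
strongest filament (or responds to the weakest one), in which case the
remaining rows stay empty.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Iterator, Optional

from .ladder import Assay, FilamentLadder, build_ladder, grams_to_log_units

__all__ = [
    "CellMark",
    "ResponseTable",
    "TrialSequence",
    "Termination",
    "ResultStatus",
    "ThresholdResult",
    "UngrammaticalTableError",
    "MissingKappaError",
    "N_ROWS",
    "table_to_sequence",
    "kappa_pattern",
    "compute_threshold",
    "count_marks",
    "validity_gate",
    "ValidityVerdict",
    "enumerate_valid_tables",
]

N_ROWS = 5

#: Count of trials recorded after the first response change in a
#: completed test ("two more rounds" after rows two and three).
POST_CHANGE_TRIALS = 4

#: Length of the response pattern used for the kappa lookup: the trial
#: before the first change, the change trial, and the four that follow.
KAPPA_PATTERN_LEN = POST_CHANGE_TRIALS + 2


class UngrammaticalTableError(ValueError):
    """The marks in a table cannot be produced by the recording grammar."""


class MissingKappaError(KeyError):
    """A completed response pattern has no kappa entry."""


class CellMark(enum.Enum):
    POSITIVE = "X"
    NEGATIVE = "O"
    EMPTY = "."

    @property
    def char(self) -> str:
        return self.value

    @classmethod
    def from_char(cls, c: str) -> "CellMark":
        try:
            return cls(c.upper() if c != "." else c)
        except ValueError:
            raise ValueError(f"invalid cell mark {c!r}") from None

    @property
    def complement(self) -> "CellMark":
        if self is CellMark.POSITIVE:
            return CellMark.NEGATIVE
        if self is CellMark.NEGATIVE:
            return CellMark.POSITIVE
        return self


class Termination(enum.Enum):
    COMPLETED = "completed"
    OOR_HIGH = "oor_high"
    OOR_LOW = "oor_low"


class ResultStatus(enum.Enum):
    OK = "ok"
    OOR_HIGH = "oor_high"
    OOR_LOW = "oor_low"
    INVALID = "invalid"


@dataclass(frozen=True)
class ResponseTable:
    """5 x n_filaments grid of marks for one subject/test."""

    assay: Assay
    cells: tuple[tuple[CellMark, ...], ...]
    source: Optional[tuple[int, int]] = None  # (page index, table index), 1-based

    def __post_init__(self) -> None:
        if len(self.cells) != N_ROWS:
            raise ValueError(f"expected {N_ROWS} rows, got {len(self.cells)}")
        widths = {len(r) for r in self.cells}
        if len(widths) != 1:
            raise ValueError("ragged table rows")

    @property
    def n_cols(self) -> int:
        return len(self.cells[0])

    def to_string(self) -> str:
        """Row-major flattening over the {X, O, .} alphabet."""
        return "".join(c.char for row in self.cells for c in row)

    @classmethod
    def from_string(
        cls,
        assay: Assay | str,
        text: str,
        source: Optional[tuple[int, int]] = None,
    ) -> "ResponseTable":
        assay = Assay.coerce(assay)
        n = build_ladder(assay).n_filaments
        if len(text) != N_ROWS * n:
            raise ValueError(
                f"table string length {len(text)} != {N_ROWS}x{n}"
            )
        rows = tuple(
            tuple(CellMark.from_char(c) for c in text[i * n : (i + 1) * n])
            for i in range(N_ROWS)
        )
        return cls(assay, rows, source)

    def complemented(self) -> "ResponseTable":
        return ResponseTable(
            self.assay,
            tuple(tuple(c.complement for c in row) for row in self.cells),
            self.source,
        )


@dataclass(frozen=True)
class TrialSequence:
    """Ordered (filament index, response) trials recovered from a table.

    ``first_change_pos`` is the 1-based position of the first trial whose
    response differs from the opening response, or None if every response
    agrees (possible only for out-of-range runs).
    """

    trials: tuple[tuple[int, CellMark], ...]
    first_change_pos: Optional[int]
    termination: Termination

    @property
    def completed(self) -> bool:
        return self.termination is Termination.COMPLETED

    @property
    def final_index(self) -> int:
        return self.trials[-1][0]

    def responses(self) -> str:
        return "".join(r.char for _, r in self.trials)


@dataclass(frozen=True)
class ThresholdResult:
    threshold_g: Optional[float]
    status: ResultStatus
    kappa_used: Optional[float] = None
    pattern: Optional[str] = None
    final_force_g: Optional[float] = None
    provenance: Optional[tuple[int, int]] = None
    reason: Optional[str] = None


def _next_index(index: int, response: CellMark) -> int:
    """Step rule: weaker after a positive response, stronger after a
    negative one (1-based index; may fall outside the ladder)."""
    return index - 1 if response is CellMark.POSITIVE else index + 1


def table_to_sequence(
    table: ResponseTable, ladder: FilamentLadder
) -> TrialSequence:
    """Reconstruct the trial order from a marked table.

    Raises
    ------
    UngrammaticalTableError
        If the marks cannot have been produced by the recording rules
        (multiple marks in a lower row, gap rows, a first row not
        anchored at the start column, steps that contradict responses,
        or an incomplete sequence with no out-of-range excuse).
    """
    n = ladder.n_filaments
    if table.n_cols != n:
        raise ValueError("table width does not match ladder")
    s = ladder.start_index  # 1-based

    row1 = [
        (c + 1, mark)
        for c, mark in enumerate(table.cells[0])
        if mark is not CellMark.EMPTY
    ]
    if not row1:
        raise UngrammaticalTableError("first row is empty")
    cols1 = [c for c, _ in row1]
    if s not in (cols1[0], cols1[-1]):
        raise UngrammaticalTableError("first row not anchored at start column")
    if cols1 != list(range(cols1[0], cols1[-1] + 1)):
        raise UngrammaticalTableError("first row marks not contiguous")
    if len(cols1) > 1 and cols1[-1] == s:
        row1.reverse()  # opening run moved toward weaker filaments

    trials: list[tuple[int, CellMark]] = list(row1)

    for r in range(1, N_ROWS):
        marks = [
            (c + 1, mark)
            for c, mark in enumerate(table.cells[r])
            if mark is not CellMark.EMPTY
        ]
        if len(marks) > 1:
            raise UngrammaticalTableError(f"row {r + 1} has multiple marks")
        if marks:
            trials.append(marks[0])
        else:
            for r2 in range(r + 1, N_ROWS):
                if any(m is not CellMark.EMPTY for m in table.cells[r2]):
                    raise UngrammaticalTableError("gap row before later marks")
            break

    # Step consistency over the whole sequence.
    for (i0, r0), (i1, _) in zip(trials, trials[1:]):
        if i1 != _next_index(i0, r0):
            raise UngrammaticalTableError(
                "filament step contradicts the preceding response"
            )

    first_resp = trials[0][1]
    change = next(
        (k + 1 for k, (_, r) in enumerate(trials) if r is not first_resp), None
    )
    n_row1 = len(row1)
    if change is None:
        if len(trials) > n_row1:
            raise UngrammaticalTableError(
                "lower rows marked before the first response change"
            )
    elif change != n_row1:
        raise UngrammaticalTableError(
            "first response change must close the first row"
        )

    n_post = len(trials) - change if change is not None else 0
    if change is not None and n_post == POST_CHANGE_TRIALS:
        term = Termination.COMPLETED
    else:
        last_index, last_resp = trials[-1]
        nxt = _next_index(last_index, last_resp)
        if nxt > n:
            term = Termination.OOR_HIGH
        elif nxt < 1:
            term = Termination.OOR_LOW
        else:
            raise UngrammaticalTableError("sequence is incomplete")

    return TrialSequence(tuple(trials), change, term)


def kappa_pattern(seq: TrialSequence) -> str:
    """Response pattern keying the kappa lookup: the last six responses
    of a completed sequence (pre-change trial, change trial, and the
    four subsequent trials)."""
    if not seq.completed:
        raise ValueError("no kappa pattern for a non-completed sequence")
    return "".join(r.char for _, r in seq.trials[-KAPPA_PATTERN_LEN:])


def compute_threshold(
    seq: TrialSequence,
    ladder: FilamentLadder,
    kappa: "KappaTable",
    provenance: Optional[tuple[int, int]] = None,
) -> ThresholdResult:
    """Dixon 50% threshold: ``10**(Xf + kappa*delta) / 10000`` grams.

    Out-of-range runs report the extreme filament force, flagged
    OOR_HIGH / OOR_LOW.
    """
    final_force = ladder.force(seq.final_index)
    if seq.termination is Termination.OOR_HIGH:
        return ThresholdResult(
            max(ladder.forces_g), ResultStatus.OOR_HIGH,
            final_force_g=final_force, provenance=provenance,
        )
    if seq.termination is Termination.OOR_LOW:
        return ThresholdResult(
            min(ladder.forces_g), ResultStatus.OOR_LOW,
            final_force_g=final_force, provenance=provenance,
        )
    pattern = kappa_pattern(seq)
    try:
        k = kappa[pattern]
    except KeyError:
        raise MissingKappaError(pattern) from None
    xf = grams_to_log_units(final_force)
    threshold = 10.0 ** (xf + k * ladder.delta) / 10000.0
    return ThresholdResult(
        threshold, ResultStatus.OK, kappa_used=k, pattern=pattern,
        final_force_g=final_force, provenance=provenance,
    )


def count_marks(table: ResponseTable) -> int:
    return sum(
        1 for row in table.cells for c in row if c is not CellMark.EMPTY
    )


#: Largest number of marked cells still processed as a real recording;
#: tables with more are treated as deliberately crossed out.
MAX_VALID_MARKS = 12


class ValidityVerdict(enum.Enum):
    VALID = "valid"
    INVALID_OVERMARKED = "invalid_overmarked"


def validity_gate(table: ResponseTable) -> ValidityVerdict:
    """Crossed-out detection: over 12 marked boxes invalidates a table."""
    if count_marks(table) > MAX_VALID_MARKS:
        return ValidityVerdict.INVALID_OVERMARKED
    return ValidityVerdict.VALID


def _trials_to_table(
    trials: list[tuple[int, CellMark]],
    n_row1: int,
    assay: Assay,
    n_cols: int,
) -> ResponseTable:
    grid = [[CellMark.EMPTY] * n_cols for _ in range(N_ROWS)]
    for idx, resp in trials[:n_row1]:
        grid[0][idx - 1] = resp
    for r, (idx, resp) in enumerate(trials[n_row1:], start=1):
        grid[r][idx - 1] = resp
    return ResponseTable(assay, tuple(tuple(row) for row in grid))


def _enumerate_trials(
    ladder: FilamentLadder,
) -> Iterator[tuple[list[tuple[int, CellMark]], int]]:
    """Depth-first walk of every outcome branch of the protocol,
    yielding (trials, row-one length) for each terminal state."""
    n = ladder.n_filaments

    def walk(
        trials: list[tuple[int, CellMark]], index: int, change: Optional[int]
    ) -> Iterator[tuple[list[tuple[int, CellMark]], int]]:
        for resp in (CellMark.POSITIVE, CellMark.NEGATIVE):
            new = trials + [(index, resp)]
            new_change = change
            if change is None and resp is not new[0][1]:
                new_change = len(new)
            n_row1 = new_change if new_change is not None else len(new)
            if new_change is not None and len(new) - new_change == POST_CHANGE_TRIALS:
                yield new, n_row1
                continue
            nxt = _next_index(index, resp)
            if nxt < 1 or nxt > n:
                yield new, n_row1
            else:
                yield from walk(new, nxt, new_change)

    yield from walk([], ladder.start_index, None)


def enumerate_valid_tables(ladder: FilamentLadder) -> frozenset[str]:
    """Every table string reachable under the recording grammar: all
    completed tables plus all out-of-range-terminated ones."""
    out = set()
    for trials, n_row1 in _enumerate_trials(ladder):
        table = _trials_to_table(
            trials, n_row1, ladder.assay, ladder.n_filaments
        )
        out.add(table.to_string())
    return frozenset(out)
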