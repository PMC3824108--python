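"""Sequential binary partitions (SBP) and their orthonormal ilr bases.

An SBP is an ordered (D-1) x D matrix of contrast codes {+1, -1, 0} that
splits a D-part composition into nested binary groups until every group is a
singleton.  Each row defines one *balance*: a scaled log-ratio of the
geometric means of its +1 group and its -1 group.  The rows compile to an
orthonormal contrast matrix ``psi`` whose rows are the clr coefficients of
the D-1 ilr coordinates.

Balance labels follow the "[denominator | numerator]" convention: the -1
group is written left of the bar, so a negative balance value leans toward
the parts on the left.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np
import pandas as pd


class SBPError(ValueError):
    """Raised when contrast codes do not form a valid sequential binary partition."""


@dataclass(frozen=True)
class SBPMatrix:
    """A validated sequential binary partition.

    Attributes
    ----------
    part_labels : tuple of str
        The D part names, in column order (includes the filling value part
        when present).
    codes : ndarray of shape (D-1, D)
        Integer contrast codes in {+1, -1, 0}; row order is significant and
        ilr coordinate ``i`` always corresponds to row ``i``.
    """

    part_labels: tuple[str, ...]
    codes: np.ndarray = field(repr=False)

    @property
    def n_parts(self) -> int:
        return len(self.part_labels)

    @property
    def n_balances(self) -> int:
        return self.codes.shape[0]

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, SBPMatrix)
            and self.part_labels == other.part_labels
            and np.array_equal(self.codes, other.codes)
        )


@dataclass(frozen=True)
class BalanceBasis:
    """Orthonormal ilr basis compiled from an SBP.

    ``psi`` is the (D-1) x D real contrast matrix; row i carries
    ``+sqrt(n_minus / (n_plus * (n_plus + n_minus)))`` on +1 parts and
    ``-sqrt(n_plus / (n_minus * (n_plus + n_minus)))`` on -1 parts, so that
    ``psi @ psi.T = I`` and every row sums to zero.
    """

    part_labels: tuple[str, ...]
    psi: np.ndarray = field(repr=False)
    names: tuple[str, ...] = ()

    @property
    def n_parts(self) -> int:
        return len(self.part_labels)

    @property
    def n_balances(self) -> int:
        return self.psi.shape[0]


def validate_sbp(codes, part_labels: Sequence[str]) -> SBPMatrix:
    """Validate contrast codes as a sequential binary partition.

    Enforces, in order: shape (D-1, D); entries in {+1, -1, 0}; unique part
    labels; every row holding at least one +1 and one -1; the hierarchy
    property (row 1 spans all parts, every later row's support equals the
    +1 group or the -1 group of exactly one earlier row); and termination
    (every group of size > 1 is split by exactly one later row).

    Raises
    ------
    SBPError
        With a message naming the offending row or label.
    """
    codes = np.asarray(codes, dtype=int)
    labels = tuple(str(p) for p in part_labels)
    if len(set(labels)) != len(labels):
        raise SBPError("duplicate part labels")
    d = len(labels)
    if codes.ndim != 2 or codes.shape != (d - 1, d):
        raise SBPError(
            f"expected {d - 1} rows x {d} columns for {d} parts, got {codes.shape}"
        )
    if not np.isin(codes, (-1, 0, 1)).all():
        raise SBPError("codes must be +1, -1 or 0")

    for i, row in enumerate(codes):
        if not (row == 1).any() or not (row == -1).any():
            raise SBPError(f"row {i + 1} must contain at least one +1 and one -1")

    # Hierarchy: track the groups each row creates; a later row must split
    # exactly one previously created group, and every non-singleton group
    # must eventually be split.
    open_groups: list[frozenset[int]] = []  # size>1 groups awaiting a split
    support0 = frozenset(np.flatnonzero(codes[0] != 0))
    if support0 != frozenset(range(d)):
        raise SBPError("row 1 must involve all parts")

    def _emit(row_idx: int, row: np.ndarray) -> None:
        for side in (1, -1):
            grp = frozenset(np.flatnonzero(row == side))
            if len(grp) > 1:
                open_groups.append(grp)

    _emit(0, codes[0])
    for i in range(1, d - 1):
        support = frozenset(np.flatnonzero(codes[i] != 0))
        matches = [g for g in open_groups if g == support]
        if not matches:
            raise SBPError(
                f"row {i + 1} support is not a group created by an earlier row"
            )
        if len(matches) > 1:  # impossible under the invariants
            raise SBPError(f"row {i + 1} support matches multiple earlier groups")
        open_groups.remove(matches[0])
        _emit(i, codes[i])
    if open_groups:
        raise SBPError("partition does not terminate in singletons")
    return SBPMatrix(part_labels=labels, codes=codes)


def balance_name(row: np.ndarray, part_labels: Sequence[str]) -> str:
    """Label one SBP row as "[minus group | plus group]" in column order."""
    minus = ",".join(p for p, c in zip(part_labels, row) if c == -1)
    plus = ",".join(p for p, c in zip(part_labels, row) if c == +1)
    return f"[{minus} | {plus}]"


def build_basis(sbp: SBPMatrix) -> BalanceBasis:
    """Compile a validated SBP into its orthonormal ilr basis.

    Row i of ``psi`` has coefficient ``+sqrt(n-/(n+ (n+ + n-)))`` on +1
    parts and ``-sqrt(n+/(n- (n+ + n-)))`` on -1 parts, where n+ and n- are
    the group sizes of that row.  Balance names are generated from the codes
    (never trusted from input text).
    """
    codes = sbp.codes
    psi = np.zeros(codes.shape, dtype=float)
    names = []
    for i, row in enumerate(codes):
        n_plus = int((row == 1).sum())
        n_minus = int((row == -1).sum())
        tot = n_plus + n_minus
        psi[i, row == 1] = math.sqrt(n_minus / (n_plus * tot))
        psi[i, row == -1] = -math.sqrt(n_plus / (n_minus * tot))
        names.append(balance_name(row, sbp.part_labels))
    return BalanceBasis(part_labels=sbp.part_labels, psi=psi, names=tuple(names))


def balance_sign_interpretation(value: float, name: str = "") -> str:
    """Read the lean of one balance value.

    Negative values lean toward the denominator (-1, left-of-bar) group,
    positive toward the numerator (+1) group, zero is neutral.
    """
    if value < 0:
        return "leans_to_denominator"
    if value > 0:
        return "leans_to_numerator"
    return "neutral"


def count_sbps(d: int) -> int:
    """Number of distinct SBPs of a D-part composition: D! (D-1)! / 2^(D-1).

    Counts ordered row sequences with unordered (+/-) group assignment.
    """
    if d < 2:
        raise ValueError("need at least 2 parts")
    return math.factorial(d) * math.factorial(d - 1) // 2 ** (d - 1)


def enumerate_sbps(d: int) -> Iterator[np.ndarray]:
    """Exhaustively enumerate SBP code matrices for small D (oracle for count_sbps).

    Yields one canonical code matrix per distinct SBP: each row splits one
    currently open group into an unordered pair, the lexicographically
    smallest member of each split carrying +1.
    """
    if d < 2:
        raise ValueError("need at least 2 parts")

    def bipartitions(group: tuple[int, ...]):
        # unordered two-block partitions; fix the first element in block A
        rest = group[1:]
        for mask in range(2 ** len(rest)):
            a = [group[0]]
            b = []
            for k, el in enumerate(rest):
                (a if mask >> k & 1 else b).append(el)
            if b:
                yield tuple(a), tuple(b)

    def recurse(rows: list[np.ndarray], open_groups: list[tuple[int, ...]]):
        if not open_groups:
            yield np.array(rows, dtype=int)
            return
        for gi, group in enumerate(open_groups):
            for a, b in bipartitions(group):
                row = np.zeros(d, dtype=int)
                row[list(a)] = 1
                row[list(b)] = -1
                nxt = open_groups[:gi] + open_groups[gi + 1 :]
                nxt += [g for g in (a, b) if len(g) > 1]
                yield from recurse(rows + [row], nxt)

    yield from recurse([], [tuple(range(d))])


# ---------------------------------------------------------------------------
# File formats: CSV (header = part labels, one code row per balance) and the
# equivalent JSON {"parts": [...], "rows": [[...], ...]}.

def read_sbp_csv(path) -> SBPMatrix:
    df = pd.read_csv(path)
    return validate_sbp(df.to_numpy(dtype=int), list(df.columns))


def write_sbp_csv(sbp: SBPMatrix, path) -> None:
    pd.DataFrame(sbp.codes, columns=list(sbp.part_labels)).to_csv(path, index=False)


def read_sbp_json(path) -> SBPMatrix:
    with open(path) as fh:
        obj = json.load(fh)
    return validate_sbp(np.array(obj["rows"], dtype=int), obj["parts"])


def write_sbp_json(sbp: SBPMatrix, path) -> None:
    obj = {"parts": list(sbp.part_labels), "rows": sbp.codes.tolist()}
    Path(path).write_text(json.dumps(obj, indent=1))


def read_sbp(path) -> SBPMatrix:
    """Read an SBP from CSV or JSON, dispatching on the file suffix."""
    path = Path(path)
    if path.suffix.lower() == ".json":
        return read_sbp_json(path)
    return read_sbp_csv(path)
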