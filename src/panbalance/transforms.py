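"""Closure, filling value, and the alr/clr/ilr log-ratio transforms.

Compositions live on the simplex: strictly positive parts closed to a
constant kappa (default 1e6, the mg kg^-1 dry-mass scale).  Tissue data are
closed after appending a filling value Fv = kappa - sum(nutrients), the
C/H/O-dominated remainder that lets ilr coordinates back-transform to
familiar concentration units.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .sbp import BalanceBasis

#: default closure constant: 10^6 mg kg^-1 on a dry-mass basis
KAPPA_MG_KG = 1e6

#: relative tolerance for the row-sum invariant (accommodates CSV rounding)
CLOSURE_RTOL = 1e-6


@dataclass(frozen=True)
class CompositionTable:
    """Specimens x parts table of strictly positive values closed to kappa."""

    part_labels: tuple[str, ...]
    values: np.ndarray = field(repr=False)  # (n, D)
    kappa: float = KAPPA_MG_KG

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[1] != len(self.part_labels):
            raise ValueError("values must be n x D matching part_labels")
        if not (v > 0).all():
            raise ValueError("composition parts must be strictly positive")
        if not np.allclose(v.sum(axis=1), self.kappa, rtol=CLOSURE_RTOL, atol=0):
            raise ValueError(f"rows must sum to kappa={self.kappa}")
        object.__setattr__(self, "values", v)

    @property
    def n_parts(self) -> int:
        return len(self.part_labels)

    def __len__(self) -> int:
        return self.values.shape[0]

    def to_frame(self, index=None) -> pd.DataFrame:
        return pd.DataFrame(self.values, columns=list(self.part_labels), index=index)


@dataclass(frozen=True)
class BalanceSet:
    """Specimens x (D-1) ilr coordinates under a named SBP basis."""

    balance_names: tuple[str, ...]
    values: np.ndarray = field(repr=False)  # (n, D-1)
    basis_id: str = ""

    def __post_init__(self):
        v = np.atleast_2d(np.asarray(self.values, dtype=float))
        if v.shape[1] != len(self.balance_names):
            raise ValueError("column count must match balance_names")
        object.__setattr__(self, "values", v)

    def __len__(self) -> int:
        return self.values.shape[0]

    def to_frame(self, index=None) -> pd.DataFrame:
        return pd.DataFrame(self.values, columns=list(self.balance_names), index=index)


def closure(raw, kappa: float = KAPPA_MG_KG, part_labels: Sequence[str] | None = None) -> CompositionTable:
    """Rescale each row of a strictly positive table to sum to kappa."""
    raw = np.atleast_2d(np.asarray(raw, dtype=float))
    if not (raw > 0).all():
        raise ValueError("closure requires strictly positive entries")
    vals = kappa * raw / raw.sum(axis=1, keepdims=True)
    if part_labels is None:
        part_labels = tuple(f"part_{i + 1}" for i in range(raw.shape[1]))
    return CompositionTable(tuple(part_labels), vals, kappa)


def add_filling_value(
    nutrients,
    kappa: float = KAPPA_MG_KG,
    part_labels: Sequence[str] | None = None,
    fv_label: str = "Fv",
) -> CompositionTable:
    """Append Fv = kappa - sum(nutrients) and close.

    Nutrient values must already be on the kappa scale (mg kg^-1 for the
    default kappa = 1e6); a row whose nutrients sum to kappa or more has no
    room left for the C/H/O remainder and is rejected.
    """
    if isinstance(nutrients, pd.DataFrame):
        part_labels = part_labels or tuple(nutrients.columns)
        nutrients = nutrients.to_numpy(dtype=float)
    nutrients = np.atleast_2d(np.asarray(nutrients, dtype=float))
    if not (nutrients > 0).all():
        raise ValueError("nutrient concentrations must be strictly positive")
    fv = kappa - nutrients.sum(axis=1, keepdims=True)
    if (fv <= 0).any():
        bad = int(np.flatnonzero(fv <= 0)[0])
        raise ValueError(
            f"row {bad}: nutrient sum {nutrients[bad].sum():g} >= kappa {kappa:g}"
        )
    if part_labels is None:
        part_labels = tuple(f"part_{i + 1}" for i in range(nutrients.shape[1]))
    labels = tuple(part_labels) + (fv_label,)
    return CompositionTable(labels, np.hstack([nutrients, fv]), kappa)


def clr(x: CompositionTable) -> np.ndarray:
    """Centred log-ratio: ln(c_i / g(c)); rows sum to zero."""
    logs = np.log(x.values)
    return logs - logs.mean(axis=1, keepdims=True)


def alr(x: CompositionTable, denominator_part: str) -> np.ndarray:
    """Additive log-ratio against one common denominator part (column dropped)."""
    if denominator_part not in x.part_labels:
        raise KeyError(f"unknown denominator part {denominator_part!r}")
    j = x.part_labels.index(denominator_part)
    logs = np.log(x.values)
    keep = [k for k in range(x.n_parts) if k != j]
    return logs[:, keep] - logs[:, [j]]


def _check_parts(x_parts: Sequence[str], basis: BalanceBasis) -> None:
    if tuple(x_parts) != tuple(basis.part_labels):
        raise ValueError(
            f"part labels {tuple(x_parts)} do not match basis parts {basis.part_labels}"
        )


def ilr(x: CompositionTable, basis: BalanceBasis) -> BalanceSet:
    """Isometric log-ratio coordinates: clr(x) @ psi.T.

    Identical (to rounding) to computing each balance directly as
    sqrt(n+ n- / (n+ + n-)) * ln(g(c+) / g(c-)) row by row.
    """
    _check_parts(x.part_labels, basis)
    vals = clr(x) @ basis.psi.T
    return BalanceSet(basis.names, vals, basis_id=",".join(basis.names))


def ilr_inverse(z, basis: BalanceBasis, kappa: float = KAPPA_MG_KG) -> CompositionTable:
    """Map ilr coordinates back to the simplex: closure(exp(z @ psi), kappa)."""
    if isinstance(z, BalanceSet):
        z = z.values
    z = np.atleast_2d(np.asarray(z, dtype=float))
    if z.shape[1] != basis.n_balances:
        raise ValueError(
            f"expected {basis.n_balances} ilr columns, got {z.shape[1]}"
        )
    return closure(np.exp(z @ basis.psi), kappa, part_labels=basis.part_labels)
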