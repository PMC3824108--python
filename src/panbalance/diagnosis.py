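"""Pan-balance diagnostic reports.

The pan-balance (mobile) view hangs the D-1 balances of an SBP at fulcrums,
with back-transformed concentrations in the weighing pans.  A specimen is
diagnosed twice, because the two verdicts answer different questions:

* per balance, against univariate confidence ranges of the reference (TN)
  group — which fulcrums lean out of range, and toward which side;
* globally, by its Mahalanobis distance against the calibrated critical
  distance — whether the ionome as a whole is out of balance (this verdict
  is SBP-invariant, the univariate ranges are not).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .distance import ReferenceNorms, mahalanobis
from .sbp import BalanceBasis
from .transforms import BalanceSet, CompositionTable, ilr, ilr_inverse


@dataclass(frozen=True)
class BalanceVerdict:
    name: str
    value: float
    ref_lower: float
    ref_median: float
    ref_upper: float
    verdict: str  # below | within | above


@dataclass(frozen=True)
class DiagnosisReport:
    """Per-balance verdicts plus the global multivariate verdict for one specimen."""

    balances: tuple[BalanceVerdict, ...]
    pan_concentrations: pd.DataFrame = field(repr=False)  # rows: specimen, reference
    global_distance: float = 0.0
    critical_distance: float = float("nan")
    balanced: bool = True

    def to_dict(self) -> dict:
        return {
            "balances": [vars(b) for b in self.balances],
            "pan_concentrations": {
                row: {c: float(v) for c, v in rec.items()}
                for row, rec in self.pan_concentrations.to_dict(orient="index").items()
            },
            "global_distance": self.global_distance,
            "critical_distance": self.critical_distance,
            "balanced": self.balanced,
        }

    def save(self, path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([vars(b) for b in self.balances])


def balance_ci(reference_balances, alpha: float = 0.05, balance_names=None) -> pd.DataFrame:
    """Univariate reference ranges per balance: median +/- t_{1-a/2, n-1} s/sqrt(n).

    Centred on the median (consistent with median-based norms) with the
    usual standard-error half-width.
    """
    if isinstance(reference_balances, BalanceSet):
        balance_names = balance_names or reference_balances.balance_names
        z = reference_balances.values
    else:
        z = np.atleast_2d(np.asarray(reference_balances, dtype=float))
    n = z.shape[0]
    if n < 3:
        raise ValueError("need at least 3 reference specimens for confidence ranges")
    med = np.median(z, axis=0)
    half = stats.t.ppf(1 - alpha / 2, df=n - 1) * z.std(axis=0, ddof=1) / np.sqrt(n)
    if balance_names is None:
        balance_names = [f"ilr{i + 1}" for i in range(z.shape[1])]
    return pd.DataFrame(
        {"lower": med - half, "median": med, "upper": med + half},
        index=list(balance_names),
    )


def diagnose(
    specimen: CompositionTable,
    norms: ReferenceNorms,
    ci: pd.DataFrame,
    basis: BalanceBasis,
) -> DiagnosisReport:
    """Diagnose one specimen against reference norms and univariate ranges.

    ``specimen`` must be a single-row composition on the basis' parts.  Pan
    concentrations are the back-transformed balances of the specimen and of
    the reference medians, each closed to the specimen's kappa.
    """
    if tuple(specimen.part_labels) != tuple(basis.part_labels):
        raise ValueError("specimen parts do not match the basis")
    if len(specimen) != 1:
        raise ValueError("diagnose one specimen at a time")
    if norms.critical_distance is None:
        raise ValueError("norms carry no critical distance; run the calibration first")

    z = ilr(specimen, basis)
    values = z.values[0]
    verdicts = []
    for name, value in zip(z.balance_names, values):
        row = ci.loc[name]
        verdict = "below" if value < row["lower"] else "above" if value > row["upper"] else "within"
        verdicts.append(
            BalanceVerdict(
                name=name,
                value=float(value),
                ref_lower=float(row["lower"]),
                ref_median=float(row["median"]),
                ref_upper=float(row["upper"]),
                verdict=verdict,
            )
        )

    d = float(mahalanobis(values, norms)[0])
    pans = pd.DataFrame(
        np.vstack(
            [
                specimen.values[0],
                ilr_inverse(norms.center, basis, kappa=specimen.kappa).values[0],
            ]
        ),
        index=["specimen", "reference"],
        columns=list(basis.part_labels),
    )
    return DiagnosisReport(
        balances=tuple(verdicts),
        pan_concentrations=pans,
        global_distance=d,
        critical_distance=float(norms.critical_distance),
        balanced=bool(d <= norms.critical_distance),
    )


def _holm(pvals: np.ndarray) -> np.ndarray:
    """Holm step-down adjusted p-values (family-wise error control).

    Undefined (NaN) inputs — e.g. from zero-variance balances — stay NaN and
    are excluded from the family.
    """
    adj = np.full(pvals.shape, np.nan)
    valid = np.flatnonzero(~np.isnan(pvals))
    m = valid.size
    order = valid[np.argsort(pvals[valid])]
    running = 0.0
    for rank, i in enumerate(order):
        running = max(running, (m - rank) * pvals[i])
        adj[i] = min(running, 1.0)
    return adj


def compare_groups(balances, group_mask, alpha: float = 0.05, balance_names=None) -> pd.DataFrame:
    """Per-balance TP-vs-TN comparison: mean difference (TP - TN) and p-values.

    ``group_mask`` is True for the TP group.  The per-balance test is the
    studentized-range (Tukey) comparison, which for two groups reduces
    exactly to the pooled two-sample t-test; the raw p-value is reported
    per balance.  Because the D-1 balances are examined simultaneously, the
    ``significant_at_0.05`` flag controls the family-wise error across
    balances through Holm's step-down adjustment.  A negative difference
    means the denominator (left-of-bar) parts load more in TP specimens.
    """
    if isinstance(balances, BalanceSet):
        balance_names = balance_names or balances.balance_names
        z = balances.values
    else:
        z = np.atleast_2d(np.asarray(balances, dtype=float))
    mask = np.asarray(group_mask, dtype=bool)
    if mask.sum() < 2 or (~mask).sum() < 2:
        raise ValueError("both groups need at least 2 specimens")
    tp, tn = z[mask], z[~mask]
    diff = tp.mean(axis=0) - tn.mean(axis=0)
    pvals = np.array(
        [stats.ttest_ind(tp[:, j], tn[:, j], equal_var=True).pvalue for j in range(z.shape[1])]
    )
    adj = _holm(pvals)
    if balance_names is None:
        balance_names = [f"ilr{i + 1}" for i in range(z.shape[1])]
    return pd.DataFrame(
        {
            "difference": diff,
            "p_value": pvals,
            "p_value_adjusted": adj,
            f"significant_at_{alpha:g}": adj < alpha,
        },
        index=list(balance_names),
    )
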