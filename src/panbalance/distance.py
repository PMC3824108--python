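"""Robust Mahalanobis imbalance index and reference-norm estimation.

The imbalance index of a specimen is its Mahalanobis distance, in balance
space, from the median of a reference population of balanced high-yielders.
The covariance is inverted by Moore-Penrose pseudo-inversion so that
rank-deficient references (n < D, or degenerate scatter) never blow up.
Reference norms are fitted after discarding multivariate outliers with a
two-pass median-centred chi-square rule.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from scipy import stats

from .transforms import BalanceSet

#: relative cut-off for singular values in the pseudo-inverse
PINV_RCOND = 1e-10


@dataclass(frozen=True)
class ReferenceNorms:
    """Centre (median balances), covariance and calibration of a reference group."""

    balance_names: tuple[str, ...]
    center: np.ndarray = field(repr=False)
    covariance: np.ndarray = field(repr=False)
    n_ref: int = 2
    critical_distance: float | None = None
    yield_cutoff: float | None = None

    def __post_init__(self):
        c = np.asarray(self.center, dtype=float)
        s = np.asarray(self.covariance, dtype=float)
        if s.shape != (c.size, c.size):
            raise ValueError("covariance shape must match center length")
        if not np.allclose(s, s.T, atol=1e-10):
            raise ValueError("covariance must be symmetric")
        if np.linalg.eigvalsh(s).min() < -1e-8:
            raise ValueError("covariance must be positive semi-definite (up to noise)")
        if self.n_ref < 2:
            raise ValueError("reference must contain at least 2 specimens")
        object.__setattr__(self, "center", c)
        object.__setattr__(self, "covariance", s)

    @property
    def n_balances(self) -> int:
        return self.center.size

    def with_calibration(self, critical_distance: float, yield_cutoff: float) -> "ReferenceNorms":
        return replace(
            self, critical_distance=float(critical_distance), yield_cutoff=float(yield_cutoff)
        )

    # -- JSON round trip ---------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "balance_names": list(self.balance_names),
            "center": self.center.tolist(),
            "covariance": self.covariance.tolist(),
            "n_ref": int(self.n_ref),
            "critical_distance": self.critical_distance,
            "yield_cutoff": self.yield_cutoff,
        }

    @classmethod
    def from_dict(cls, obj: dict) -> "ReferenceNorms":
        return cls(
            balance_names=tuple(obj["balance_names"]),
            center=np.array(obj["center"], dtype=float),
            covariance=np.array(obj["covariance"], dtype=float),
            n_ref=int(obj.get("n_ref", 2)),
            critical_distance=obj.get("critical_distance"),
            yield_cutoff=obj.get("yield_cutoff"),
        )

    def save(self, path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1))

    @classmethod
    def load(cls, path) -> "ReferenceNorms":
        return cls.from_dict(json.loads(Path(path).read_text()))


def _as_matrix(z) -> np.ndarray:
    if isinstance(z, BalanceSet):
        z = z.values
    return np.atleast_2d(np.asarray(z, dtype=float))


def spatial_median(z, tol: float = 1e-12, max_iter: int = 1000) -> np.ndarray:
    """Spatial (geometric) median: argmin_c sum_i ||z_i - c||.

    The multivariate median.  Unlike the coordinate-wise median it is
    equivariant under orthogonal rotations, which is what makes the
    median-centred Mahalanobis distance independent of the SBP chosen to
    express the balances.  Computed by Weiszfeld iteration with the
    Vardi-Zhang correction for iterates landing on a data point.
    """
    zm = _as_matrix(z)
    c = np.median(zm, axis=0)
    scale = max(1.0, float(np.abs(zm).max()))
    for _ in range(max_iter):
        diff = zm - c
        d = np.linalg.norm(diff, axis=1)
        nz = d > 1e-15 * scale
        if not nz.any():
            return c
        w = 1.0 / d[nz]
        t = (zm[nz] * w[:, None]).sum(axis=0) / w.sum()
        n_coincident = int((~nz).sum())
        if n_coincident:
            r = (diff[nz] * w[:, None]).sum(axis=0)
            r_norm = float(np.linalg.norm(r))
            if r_norm <= n_coincident:
                return c
            gamma = min(1.0, n_coincident / r_norm)
            t = (1.0 - gamma) * t + gamma * c
        if np.linalg.norm(t - c) <= tol * scale:
            return t
        c = t
    return c


def mahalanobis(z, norms: ReferenceNorms) -> np.ndarray:
    """Mahalanobis distance(s) of balance vector(s) from the reference centre.

    d = sqrt((z - centre)^T pinv(COV) (z - centre)); a scalar input returns a
    length-1 array.
    """
    zm = _as_matrix(z)
    if zm.shape[1] != norms.n_balances:
        raise ValueError(
            f"expected {norms.n_balances} balance columns, got {zm.shape[1]}"
        )
    return _mahalanobis_raw(zm, norms.center, norms.covariance)


def _mahalanobis_raw(zm: np.ndarray, center: np.ndarray, cov: np.ndarray) -> np.ndarray:
    inv = np.linalg.pinv(cov, rcond=PINV_RCOND, hermitian=True)
    diff = zm - center
    d2 = np.einsum("ij,jk,ik->i", diff, inv, diff)
    return np.sqrt(np.clip(d2, 0.0, None))


def flag_outliers(balances, alpha: float = 0.01) -> np.ndarray:
    """Flag multivariate outliers with a two-pass median-centred chi-square rule.

    Pass 1 computes distances about the spatial median with the classical
    covariance of all rows; rows beyond sqrt(chi2_{1-alpha, p}) are dropped
    and centre/covariance are re-estimated once before the final flags.
    """
    zm = _as_matrix(balances)
    n, p = zm.shape
    if n <= 2:
        raise ValueError("need more than 2 rows to flag outliers")
    cut = np.sqrt(stats.chi2.ppf(1 - alpha, df=p))
    keep = np.ones(n, dtype=bool)
    for _ in range(2):
        center = spatial_median(zm[keep])
        cov = _safe_cov(zm[keep])
        d = _mahalanobis_raw(zm, center, cov)
        # a point with displacement outside the covariance column space is
        # infinitely far in the metric (pinv alone would score it zero)
        diff = zm - center
        resid = diff - diff @ (np.linalg.pinv(cov, rcond=PINV_RCOND, hermitian=True) @ cov)
        scale = max(1.0, float(np.abs(diff).max()))
        outside = np.linalg.norm(resid, axis=1) > 1e-8 * scale
        new_keep = (d <= cut) & ~outside
        if new_keep.sum() < max(2, p // 2):
            break  # refuse to discard the bulk of the data
        keep = new_keep
    return ~keep


def _safe_cov(zm: np.ndarray) -> np.ndarray:
    if zm.shape[0] < 2:
        return np.zeros((zm.shape[1], zm.shape[1]))
    return np.cov(zm, rowvar=False, ddof=1)


def fit_norms(balances, outlier_alpha: float = 0.01, balance_names=None) -> ReferenceNorms:
    """Estimate reference norms: median centre and classical covariance of
    the outlier-cleaned rows.

    The centre is the spatial (geometric) median — robust to the extreme
    values usual in survey ionomes and rotation-equivariant, so the fitted
    imbalance index does not depend on the SBP expressing the balances; the
    covariance is the plain n-1 estimator on the retained rows.  With n < D
    the covariance is rank-deficient — allowed, the pseudo-inverse copes —
    but a warning is emitted.
    """
    if isinstance(balances, BalanceSet) and balance_names is None:
        balance_names = balances.balance_names
    zm = _as_matrix(balances)
    n, p = zm.shape
    if n < 2:
        raise ValueError("need at least 2 rows to fit reference norms")
    if n <= p:
        warnings.warn(
            f"reference size {n} <= dimension {p}: covariance is rank-deficient",
            stacklevel=2,
        )
    if n > max(2, p + 1):
        keep = ~flag_outliers(zm, alpha=outlier_alpha)
    else:
        keep = np.ones(n, dtype=bool)
    if balance_names is None:
        balance_names = tuple(f"ilr{i + 1}" for i in range(p))
    return ReferenceNorms(
        balance_names=tuple(balance_names),
        center=spatial_median(zm[keep]),
        covariance=_safe_cov(zm[keep]),
        n_ref=int(keep.sum()),
    )
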