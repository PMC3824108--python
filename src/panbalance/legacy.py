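"""Legacy comparator diagnostics: log-concentration distance, DRIS, CND-clr.

These are the methods the balance approach replaces.  They are reproduced
here to demonstrate their biases on synthetic data: redundancy of
information, subcompositional incoherence and the resulting noisy ranking
of specimens relative to the SBP-invariant ilr Mahalanobis distance.

DRIS has no canonical formulation; the Walworth-Sumner piecewise ratio
function with k = 1 is implemented as one representative member of the
family (the comparator only needs to exhibit the bias pattern).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .distance import _mahalanobis_raw, _safe_cov


def log_mahalanobis(concentrations, reference_mask) -> np.ndarray:
    """Mahalanobis distance over ln(concentrations), no closure, no filling value.

    Centre is the column median of the reference rows; covariance the
    classical estimator on the reference rows, pseudo-inverted.
    """
    x = np.atleast_2d(np.asarray(concentrations, dtype=float))
    if not (x > 0).all():
        raise ValueError("concentrations must be strictly positive")
    mask = np.asarray(reference_mask, dtype=bool)
    logs = np.log(x)
    center = np.median(logs[mask], axis=0)
    cov = _safe_cov(logs[mask])
    return _mahalanobis_raw(logs, center, cov)


@dataclass(frozen=True)
class DRISNorms:
    """Dual-ratio norms: mean and CV (%) of A/B for each nutrient pair.

    Pairs are stored in one fixed orientation (lexicographic by the nutrient
    order given at fit time); the reverse ratio function is supplied by
    antisymmetry, f(B/A) = -f(A/B).
    """

    nutrient_labels: tuple[str, ...]
    ratio_mean: dict = field(repr=False, default_factory=dict)  # (A,B) -> mean A/B
    ratio_cv: dict = field(repr=False, default_factory=dict)  # (A,B) -> CV %

    @classmethod
    def fit(cls, reference, nutrient_labels) -> "DRISNorms":
        """Estimate pair norms from a reference table (rows = specimens)."""
        ref = np.atleast_2d(np.asarray(reference, dtype=float))
        if not (ref > 0).all():
            raise ValueError("reference concentrations must be strictly positive")
        labels = tuple(nutrient_labels)
        means, cvs = {}, {}
        for i, a in enumerate(labels):
            for j in range(i + 1, len(labels)):
                r = ref[:, i] / ref[:, j]
                mu = float(r.mean())
                sd = float(r.std(ddof=1)) if ref.shape[0] > 1 else 0.0
                if mu <= 0 or sd <= 0:
                    raise ValueError(f"degenerate ratio norm for ({a},{labels[j]})")
                means[(a, labels[j])] = mu
                cvs[(a, labels[j])] = 100.0 * sd / mu
        return cls(labels, means, cvs)


def _dris_function(ratio: float, norm_mean: float, cv: float, k: float) -> float:
    # Walworth-Sumner piecewise form; antisymmetric in the ratio about the norm
    if ratio >= norm_mean:
        return 100.0 * (k / cv) * (ratio / norm_mean - 1.0)
    return 100.0 * (k / cv) * (1.0 - norm_mean / ratio)


def dris_functions(specimen, norms: DRISNorms, k: float = 1.0) -> dict:
    """Ratio functions f(A/B) for every stored pair of one specimen.

    f = 100 (k/CV) (r/R - 1) when the observed ratio r exceeds the norm R,
    and 100 (k/CV) (1 - R/r) (negative) otherwise; CV is in percent.
    """
    x = np.asarray(specimen, dtype=float).ravel()
    if (x <= 0).any():
        raise ValueError("specimen concentrations must be strictly positive")
    idx = {lab: i for i, lab in enumerate(norms.nutrient_labels)}
    out = {}
    for (a, b), mu in norms.ratio_mean.items():
        r = x[idx[a]] / x[idx[b]]
        out[(a, b)] = _dris_function(r, mu, norms.ratio_cv[(a, b)], k)
    return out


def dris_indices(specimen, norms: DRISNorms, k: float = 1.0) -> tuple[pd.Series, float]:
    """Per-nutrient DRIS indices and the nutrient imbalance index NII.

    index_X averages f(X/Y) over the other nutrients, pulling reversed pairs
    in by antisymmetry; NII is the sum of absolute indices.
    """
    funcs = dris_functions(specimen, norms, k=k)
    labels = norms.nutrient_labels
    dprime = len(labels)
    idxs = {}
    for xlab in labels:
        total = 0.0
        for ylab in labels:
            if ylab == xlab:
                continue
            if (xlab, ylab) in funcs:
                total += funcs[(xlab, ylab)]
            else:
                total -= funcs[(ylab, xlab)]
        idxs[xlab] = total / (dprime - 1)
    series = pd.Series(idxs)
    return series, float(series.abs().sum())


def cnd_clr_indices(specimen, ref_clr_mean, ref_clr_sd) -> np.ndarray:
    """CND-clr standardized indices: (clr_i - mean clr_i(ref)) / SD clr_i(ref).

    ``specimen`` is a raw positive part vector; its clr is taken over the
    parts supplied, so adding or removing a part (Fv, water...) shifts every
    index — the subcompositional incoherence the balance approach avoids.
    """
    x = np.asarray(specimen, dtype=float).ravel()
    if (x <= 0).any():
        raise ValueError("specimen parts must be strictly positive")
    mu = np.asarray(ref_clr_mean, dtype=float)
    sd = np.asarray(ref_clr_sd, dtype=float)
    if (sd <= 0).any():
        raise ValueError("reference clr SDs must be positive")
    logs = np.log(x)
    clr_vec = logs - logs.mean()
    return (clr_vec - mu) / sd


def clr_reference_stats(reference) -> tuple[np.ndarray, np.ndarray]:
    """Mean and SD of clr coordinates over a reference table of raw parts."""
    ref = np.atleast_2d(np.asarray(reference, dtype=float))
    if not (ref > 0).all():
        raise ValueError("reference parts must be strictly positive")
    logs = np.log(ref)
    clr_mat = logs - logs.mean(axis=1, keepdims=True)
    return clr_mat.mean(axis=0), clr_mat.std(axis=0, ddof=1)
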