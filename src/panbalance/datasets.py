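"""Packaged reference data: the mango foliar SBP and TN balance norms."""

from __future__ import annotations

import json
from importlib import resources

import numpy as np
import pandas as pd

from .distance import ReferenceNorms
from .sbp import BalanceBasis, SBPMatrix, build_basis, validate_sbp


def _data(name: str):
    return resources.files("panbalance.data").joinpath(name)


def mango_sbp() -> SBPMatrix:
    """The 11-balance foliar SBP for mango ionomes (S, N, P, K, Ca, Mg, B,
    Cu, Zn, Mn, Fe plus the filling value), designed from prior knowledge of
    nutrient interactions."""
    with _data("mango_sbp.csv").open() as fh:
        df = pd.read_csv(fh)
    return validate_sbp(df.to_numpy(dtype=int), list(df.columns))


def mango_basis() -> BalanceBasis:
    return build_basis(mango_sbp())


def mango_norms() -> ReferenceNorms:
    """TN reference norms for mango: median balances and covariance of the
    20 balanced high-yielding orchards, with the calibrated critical
    Mahalanobis distance (4.08) and yield cut-off (128.5 kg fruit tree^-1)."""
    obj = json.loads(_data("mango_norms.json").read_text())
    return ReferenceNorms.from_dict(obj)


def mango_reference_ci() -> pd.DataFrame:
    """Published univariate confidence ranges (lower, median, upper) of the
    TN balances."""
    obj = json.loads(_data("mango_norms.json").read_text())
    return pd.DataFrame(
        {
            "lower": np.array(obj["ci_lower"], dtype=float),
            "median": np.array(obj["center"], dtype=float),
            "upper": np.array(obj["ci_upper"], dtype=float),
        },
        index=list(obj["balance_names"]),
    )
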