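"""Regressions between sequence features and ln(KD).

Affinities enter the regression as natural log of KD in molar, so slope units
are "ln(M) per feature unit".  Duplicate affinities for the same ligand are
averaged first (arithmetic on the KD scale by default, geometric optional).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import statsmodels.api as sm

from .errors import DegenerateRegressionError


@dataclass(frozen=True)
class RegressionResult:
    slope: float
    intercept: float
    r_squared: float
    p_value: float
    n_points: int
    feature: str = ""
    transform: str = "ln KD, KD in M"


def average_affinities(
    records: Mapping[str, Sequence[float]], method: str = "arithmetic"
) -> dict[str, float]:
    """One KD per ligand from possibly replicated measurements."""
    out: dict[str, float] = {}
    for ligand, kds in records.items():
        kds = np.asarray(list(kds), dtype=float)
        if len(kds) == 0:
            raise ValueError(f"{ligand}: no affinities")
        if (kds <= 0).any():
            raise ValueError(f"{ligand}: KD must be positive")
        if method == "arithmetic":
            out[ligand] = float(kds.mean())
        elif method == "geometric":
            out[ligand] = float(np.exp(np.log(kds).mean()))
        else:
            raise ValueError(f"unknown averaging method {method!r}")
    return out


def feature_affinity_regression(
    features: Sequence[float],
    kds: Sequence[float],
    feature_name: str = "",
) -> RegressionResult:
    """OLS of ln(KD in M) on a sequence feature.

    The p-value is the two-sided test on the slope (equivalently the F test
    of the single-regressor model); R^2 is symmetric under exchanging
    regressor and response.
    """
    x = np.asarray(features, dtype=float)
    kds = np.asarray(kds, dtype=float)
    if len(x) != len(kds):
        raise ValueError("features and KDs differ in length")
    if len(x) < 3:
        raise DegenerateRegressionError("need >= 3 points")
    if (kds <= 0).any():
        raise ValueError("KD must be positive")
    y = np.log(kds)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise DegenerateRegressionError("zero variance in a variable")
    model = sm.OLS(y, sm.add_constant(x)).fit()
    return RegressionResult(
        slope=float(model.params[1]),
        intercept=float(model.params[0]),
        r_squared=float(model.rsquared),
        p_value=float(model.pvalues[1]),
        n_points=len(x),
        feature=feature_name,
    )


def lnkd(kd_molar: float) -> float:
    """Natural log of KD in molar (regression response scale)."""
    if kd_molar <= 0:
        raise ValueError("KD must be positive")
    return float(np.log(kd_molar))


def kd_from_lnkd(ln_kd: float) -> float:
    return float(np.exp(ln_kd))
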