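"""Soil multinutrient cycling (MNC) index.

The index averages, per sample, the Z-score-standardized values of eight
available-nutrient properties (DOC, AN, NO3, NH4, AP, AK, AS, AFe) —
the multifunctionality-style averaging index.  Variables are log-transformed
"as needed": by default natural log is applied when a variable's sample
skewness exceeds 1 (explicit per-variable overrides are accepted), a
reproducible stand-in for the usual normalize-then-standardize step.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .data_io import MNC_NUTRIENTS

__all__ = ["MncIndex", "multinutrient_index"]


@dataclass
class MncIndex:
    values: pd.Series            # per-sample index, NaN where excluded
    transforms: dict             # variable -> "log" | "none"
    variables: list[str]
    n_available: pd.Series       # nutrients entering each sample's mean


def multinutrient_index(
    nutrients: pd.DataFrame,
    log_rule: str | dict = "skewness",
    skew_threshold: float = 1.0,
    min_available: int = 6,
    variables=MNC_NUTRIENTS,
) -> MncIndex:
    """Standardize each nutrient column and average across them per sample.

    ``log_rule`` is "skewness" (log when sample skewness > threshold),
    "none", or a dict mapping variable -> "log"/"none".  Samples missing a
    value average over the available standardized values, provided at least
    ``min_available`` of the 8 are present; otherwise the sample's index is
    NaN.  Errors: a missing or zero-variance column, or non-positive values
    under a log transform.
    """
    variables = list(variables)
    missing = [v for v in variables if v not in nutrients.columns]
    if missing:
        raise ValueError(f"missing nutrient column(s): {missing}")
    data = nutrients[variables].astype(float)

    transforms: dict[str, str] = {}
    standardized = pd.DataFrame(index=data.index, columns=variables, dtype=float)
    for var in variables:
        col = data[var]
        obs = col.dropna()
        if len(obs) < 3:
            raise ValueError(f"nutrient {var!r} has fewer than 3 observations")
        if isinstance(log_rule, dict):
            action = log_rule.get(var, "none")
        elif log_rule == "skewness":
            action = "log" if sps.skew(obs, bias=False) > skew_threshold else "none"
        elif log_rule == "none":
            action = "none"
        else:
            raise ValueError(f"unknown log_rule {log_rule!r}")
        if action == "log":
            if (obs <= 0).any():
                bad = obs.index[obs <= 0][0]
                raise ValueError(
                    f"non-positive value of {var!r} in sample {bad!r} under log"
                )
            col = np.log(col)
            obs = col.dropna()
        elif action != "none":
            raise ValueError(f"unknown transform {action!r} for {var!r}")
        transforms[var] = action
        sd = obs.std(ddof=1)
        if sd == 0 or not np.isfinite(sd):
            raise ValueError(f"nutrient {var!r} has zero variance")
        standardized[var] = (col - obs.mean()) / sd

    n_avail = standardized.notna().sum(axis=1)
    index = standardized.mean(axis=1, skipna=True)
    index[n_avail < min_available] = np.nan
    return MncIndex(
        values=index,
        transforms=transforms,
        variables=variables,
        n_available=n_avail,
    )
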