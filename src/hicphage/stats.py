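"""Statistical comparisons: pre/post group tests and VPH-abundance regression."""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, asdict
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps

__all__ = ["GroupComparison", "RegressionResult", "two_group_ttest",
           "vph_abundance_regression"]

ALPHA = 0.05


@dataclass
class GroupComparison:
    metric: str
    pre: list
    post: list
    t_statistic: float
    p_value: float
    significant: bool
    note: str = ""

    def as_dict(self) -> dict:
        return asdict(self)


def two_group_ttest(
    pre: Sequence[float], post: Sequence[float], metric: str = "",
    equal_var: bool = False,
) -> GroupComparison:
    """Two-sided t-test between two groups (Welch by default).

    Groups with fewer than two finite values give an explicit NA result
    rather than an error. Degenerate zero-variance groups are handled
    directly: identical means give t = 0, p = 1; separated constant
    groups give p = 0.
    """
    a = np.asarray([x for x in pre if math.isfinite(x)], dtype=float)
    b = np.asarray([x for x in post if math.isfinite(x)], dtype=float)
    if len(a) < 2 or len(b) < 2:
        return GroupComparison(metric, list(a), list(b), math.nan, math.nan,
                               False, note="insufficient group size")
    if a.var(ddof=1) == 0.0 and b.var(ddof=1) == 0.0:
        if a.mean() == b.mean():
            t, p = 0.0, 1.0
        else:
            t = math.inf if a.mean() > b.mean() else -math.inf
            p = 0.0
        return GroupComparison(metric, list(a), list(b), t, p, p < ALPHA,
                               note="zero variance in both groups")
    with warnings.catch_warnings():
        # nearly-identical groups trigger a harmless precision-loss warning
        warnings.filterwarnings("ignore", message="Precision loss occurred")
        t, p = sps.ttest_ind(a, b, equal_var=equal_var)
    return GroupComparison(metric, list(a), list(b), float(t), float(p), p < ALPHA)


@dataclass
class RegressionResult:
    slope: float
    intercept: float
    adj_r_squared: float
    f_pvalue: float
    slope_ci_low: float
    slope_ci_high: float
    n: int
    transform: str

    def as_dict(self) -> dict:
        return asdict(self)


def vph_abundance_regression(
    table: pd.DataFrame, transform: str = "log10"
) -> RegressionResult:
    """OLS of (transformed) VPH on (transformed) host abundance.

    ``table`` needs columns ``vph`` and ``host_abundance``. The default
    log10-log10 scale reflects that both quantities are ratio-scaled and
    span orders of magnitude; ``transform="none"`` fits on raw values.
    Non-positive values under the log transform are rejected with an
    itemized report. Returns the slope, adjusted R^2, the F-test p-value
    and the 95% confidence interval of the slope.
    """
    if transform not in ("log10", "none"):
        raise ValueError(f"unknown transform {transform!r}")
    df = table[["vph", "host_abundance"]].astype(float).dropna()
    if len(df) < 3:
        raise ValueError(f"regression needs at least 3 pairs, got {len(df)}")
    if transform == "log10":
        bad = df[(df["vph"] <= 0) | (df["host_abundance"] <= 0)]
        if len(bad):
            raise ValueError(
                "non-positive values under log transform: "
                + "; ".join(
                    f"(vph={r.vph:g}, host_abundance={r.host_abundance:g})"
                    for r in bad.itertuples()
                )
            )
        y = np.log10(df["vph"].to_numpy())
        x = np.log10(df["host_abundance"].to_numpy())
    else:
        y = df["vph"].to_numpy()
        x = df["host_abundance"].to_numpy()
    model = sm.OLS(y, sm.add_constant(x)).fit()
    ssr = float(model.ssr)
    f_p = 0.0 if ssr <= 1e-300 else float(model.f_pvalue)
    ci = model.conf_int(alpha=ALPHA)
    return RegressionResult(
        slope=float(model.params[1]),
        intercept=float(model.params[0]),
        adj_r_squared=float(model.rsquared_adj),
        f_pvalue=f_p,
        slope_ci_low=float(ci[1][0]),
        slope_ci_high=float(ci[1][1]),
        n=len(df),
        transform=transform,
    )
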