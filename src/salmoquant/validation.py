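"""Method-validation metrics: deviation, RSD, dynamic range, LOD/LOQ,
repeatability/reproducibility, and one-way ANOVA for treatment effects.

The decision rules follow standard molecular-method validation practice:

* **LOD** — the lowest adulterant mass fraction *stably* detected,
  operationalised as 100% positive replicates at that level and at every
  higher tested level.
* **LOQ** — the lowest fraction quantified within acceptable uncertainty
  (|relative deviation| ≤ 25% per CAC/GL 74-2010), again requiring every
  higher tested level to pass so a single mid-range failure below the answer
  does not mask instability above it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InputError

#: CAC/GL 74-2010 acceptable-uncertainty bound for the LOQ rule.
DEFAULT_MAX_ABS_DEVIATION_PCT = 25.0


def relative_deviation(measured: float, actual: float) -> float:
    """Signed percent deviation of a measurement from the true value."""
    if actual == 0:
        raise InputError("relative deviation undefined for actual = 0")
    return 100.0 * (measured - actual) / actual


def rsd(values: Sequence[float]) -> float:
    """Relative standard deviation: 100 × sample SD (ddof=1) / mean."""
    arr = np.asarray(values, dtype=float)
    if arr.size < 2:
        raise InputError("RSD needs at least two values")
    mean = arr.mean()
    if mean == 0:
        raise InputError("RSD undefined for zero mean")
    return float(100.0 * arr.std(ddof=1) / mean)


def dynamic_range_fit(
    actual_pcts: Sequence[float], measured_pcts: Sequence[float]
) -> tuple[float, float, float]:
    """OLS of measured on actual mass fraction: (slope, intercept, R²).

    R² is the squared Pearson correlation; a wide linear dynamic range shows
    as slope ≈ 1, intercept ≈ 0, R² ≈ 1.
    """
    x = np.asarray(actual_pcts, dtype=float)
    y = np.asarray(measured_pcts, dtype=float)
    if x.size != y.size or x.size < 2:
        raise InputError("need at least two matched (actual, measured) points")
    if np.ptp(x) == 0:
        raise InputError("degenerate fit: no variance in actual values")
    res = stats.linregress(x, y)
    return float(res.slope), float(res.intercept), float(res.rvalue**2)


def _lowest_stable_level(
    levels: Sequence[tuple[float, float]], passes
) -> float | None:
    """Smallest fraction that passes with every larger tested fraction passing."""
    if not levels:
        return None
    fracs = [f for f, _ in levels]
    if sorted(fracs) != list(fracs):
        raise InputError("levels must be sorted ascending by fraction")
    answer = None
    for frac, value in reversed(levels):
        if passes(value):
            answer = frac
        else:
            break
    return answer


def determine_lod(levels: Sequence[tuple[float, float]]) -> float | None:
    """Limit of detection from (fraction %, detection rate %) pairs.

    Returns the smallest fraction with a 100% detection rate such that all
    larger tested fractions also reach 100%; None if no level qualifies.
    """
    return _lowest_stable_level(levels, lambda rate: rate >= 100.0)


def determine_loq(
    levels: Sequence[tuple[float, float]],
    max_abs_deviation: float = DEFAULT_MAX_ABS_DEVIATION_PCT,
) -> float | None:
    """Limit of quantification from (fraction %, deviation %) pairs.

    Returns the smallest fraction whose |deviation| is within the bound such
    that all larger tested fractions also comply; None if none qualifies.
    """
    return _lowest_stable_level(
        levels, lambda dev: abs(dev) <= max_abs_deviation
    )


@dataclass(frozen=True)
class AnovaResult:
    f_statistic: float
    df_between: int
    df_within: int
    p_value: float
    degenerate: bool = False  # zero within-group variance with nonzero between


def one_way_anova(groups: Sequence[Sequence[float]]) -> AnovaResult:
    """Classical one-way ANOVA from the between/within decomposition."""
    if len(groups) < 2:
        raise InputError("ANOVA needs at least two groups")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if any(a.size < 2 for a in arrays):
        raise InputError("each group needs at least two observations")
    n_total = sum(a.size for a in arrays)
    grand = np.concatenate(arrays).mean()
    ss_between = sum(a.size * (a.mean() - grand) ** 2 for a in arrays)
    ss_within = sum(((a - a.mean()) ** 2).sum() for a in arrays)
    df1 = len(arrays) - 1
    df2 = n_total - len(arrays)
    if ss_within == 0:
        if ss_between == 0:
            return AnovaResult(0.0, df1, df2, 1.0)
        return AnovaResult(math.inf, df1, df2, 0.0, degenerate=True)
    f = (ss_between / df1) / (ss_within / df2)
    p = float(stats.f.sf(f, df1, df2))
    return AnovaResult(float(f), df1, df2, p)


def precision_summary(data: pd.DataFrame) -> pd.DataFrame:
    """Repeatability and reproducibility RSDs per mixture level.

    ``data`` needs columns ``level`` (mass fraction %), ``run`` (one
    day × operator cell) and ``value`` (measured fraction). Per level:

    * repeatability = mean over runs of the within-run replicate RSD;
    * reproducibility = RSD across the run means.

    A final ``average`` row holds the across-level means of both metrics.
    """
    required = {"level", "run", "value"}
    if not required.issubset(data.columns):
        raise InputError(f"precision data needs columns {sorted(required)}")
    rows = []
    for level, sub in data.groupby("level", sort=True):
        within = [
            rsd(run_vals["value"].to_numpy())
            for _, run_vals in sub.groupby("run")
            if len(run_vals) >= 2
        ]
        if not within:
            raise InputError(f"level {level}: no run has >=2 replicates")
        run_means = sub.groupby("run")["value"].mean().to_numpy()
        if len(run_means) < 2:
            raise InputError(f"level {level}: need >=2 runs for reproducibility")
        rows.append(
            {
                "level": level,
                "repeatability_rsd_pct": float(np.mean(within)),
                "reproducibility_rsd_pct": rsd(run_means),
            }
        )
    out = pd.DataFrame(rows)
    avg = {
        "level": "average",
        "repeatability_rsd_pct": out["repeatability_rsd_pct"].mean(),
        "reproducibility_rsd_pct": out["reproducibility_rsd_pct"].mean(),
    }
    return pd.concat([out, pd.DataFrame([avg])], ignore_index=True)
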