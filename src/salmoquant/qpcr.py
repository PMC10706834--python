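"""qPCR comparator pipeline: standard curves, Ct interpolation, and the
relative quantity P_O.

qPCR quantifies against a dilution series: Ct is linear in log10 of template
concentration over the dynamic range, and the amplification efficiency
follows from the slope as 10^(−1/slope) − 1 (a slope of −3.32 is perfect
doubling). The relative quantity of rainbow trout,

    P_O (%) = 100 × C_O / (C_O + C_S),

treats the DNA-concentration share directly as the mass-fraction estimate,
with no transfer-coefficient correction — the systematic bias this induces
relative to the ddPCR route is part of what the comparison measures.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .errors import InputError, QuantificationFailure


@dataclass(frozen=True)
class StandardCurve:
    """Fitted Ct = slope·log10(conc) + intercept for one species assay."""

    species_label: str
    slope: float
    intercept: float
    r_squared: float
    efficiency_pct: float
    positive_slope_warning: bool = False


def efficiency_from_slope(slope: float) -> float:
    """Amplification efficiency (%) implied by a standard-curve slope."""
    if slope == 0:
        raise InputError("slope must be nonzero")
    return 100.0 * (10.0 ** (-1.0 / slope) - 1.0)


def dilution_series(
    start_ng_ul: float = 50.0, fold: float = 4.0, n_points: int = 6
) -> np.ndarray:
    """Serial dilution concentrations, e.g. the standard 50–0.05 ng/µL
    four-fold series."""
    if start_ng_ul <= 0 or fold <= 1 or n_points < 2:
        raise InputError("need start > 0, fold > 1 and at least two points")
    return start_ng_ul / fold ** np.arange(n_points)


def fit_standard_curve(
    concentrations_ng_ul: Sequence[float],
    ct_values: Sequence[float],
    species_label: str = "",
) -> StandardCurve:
    """OLS fit of Ct on log10(concentration) for one dilution series."""
    conc = np.asarray(concentrations_ng_ul, dtype=float)
    ct = np.asarray(ct_values, dtype=float)
    if conc.size != ct.size or conc.size < 3:
        raise InputError("need at least three matched (concentration, Ct) points")
    if np.any(conc <= 0):
        raise InputError("concentrations must be positive")
    res = stats.linregress(np.log10(conc), ct)
    slope = float(res.slope)
    return StandardCurve(
        species_label=species_label,
        slope=slope,
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
        efficiency_pct=efficiency_from_slope(slope),
        positive_slope_warning=slope > 0,
    )


def interpolate_concentration(ct: float, curve: StandardCurve) -> float:
    """Template concentration (ng/µL) whose expected Ct equals ``ct``."""
    if curve.slope == 0:
        raise InputError("cannot interpolate on a flat curve")
    return 10.0 ** ((ct - curve.intercept) / curve.slope)


def relative_quantity(c_o: float, c_s: float) -> float:
    """P_O (%): rainbow trout share of the summed DNA concentrations."""
    if c_o < 0 or c_s < 0:
        raise InputError("concentrations must be nonnegative")
    if c_o == 0 and c_s == 0:
        raise QuantificationFailure("no template detected on either assay")
    return 100.0 * c_o / (c_o + c_s)


def quantify_by_qpcr(
    ct_trout: Sequence[float],
    ct_salmon: Sequence[float],
    curve_trout: StandardCurve,
    curve_salmon: StandardCurve,
) -> tuple[float, float, np.ndarray]:
    """Replicate P_O estimates from paired Ct values.

    Returns (mean, sample SD, per-replicate P_O array). Replicates are
    paired positionally, as measured in the same run.
    """
    if len(ct_trout) != len(ct_salmon) or not ct_trout:
        raise InputError("need equal, nonzero numbers of Ct replicates")
    p = np.array(
        [
            relative_quantity(
                interpolate_concentration(co, curve_trout),
                interpolate_concentration(cs, curve_salmon),
            )
            for co, cs in zip(ct_trout, ct_salmon)
        ]
    )
    sd = float(p.std(ddof=1)) if p.size > 1 else 0.0
    return float(p.mean()), sd, p
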