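"""Transfer-coefficient (K) estimation and verification.

Absolute DNA copy numbers do not translate directly into meat mass because
the amplifiable copies of a single-copy gene per unit mass (C_O for rainbow
trout, C_S for Atlantic salmon) differ between species. For a binary mixture

    M_O / M_S = (C_S / C_O) × (Q_O / Q_S) = K × (Q_O / Q_S)

so the constant K = C_S/C_O converts the measured copy ratio Q_O/Q_S into a
mass ratio in one step. K is estimated from mixtures of known composition:
each calibration mixture with trout mass fraction f yields

    K = (f / (100 − f)) / (Q_O / Q_S)

and K estimates from several fractions are averaged; their relative standard
deviation measures how constant K really is across the composition range.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .errors import InputError
from . import quantification, validation

RoundingMode = Literal["raw", "two_decimals"]

#: Published transfer coefficient for the trout/salmon myoglobin duplex;
#: usable for quantification without recalibration.
PUBLISHED_K = 0.43


@dataclass(frozen=True)
class CalibrationPoint:
    """One calibration mixture: known fraction plus replicate-mean copies."""

    trout_mass_fraction_pct: float
    q_o: float
    q_s: float

    def __post_init__(self) -> None:
        if not 0 < self.trout_mass_fraction_pct < 100:
            raise InputError("calibration fraction must lie strictly in (0, 100)")
        if self.q_o <= 0 or self.q_s <= 0:
            raise InputError("calibration concentrations must be positive")

    @property
    def k_value(self) -> float:
        return k_from_mixture(self.trout_mass_fraction_pct, self.q_o, self.q_s)


@dataclass(frozen=True)
class CalibrationResult:
    k_mean: float
    k_rsd_pct: float
    points: tuple[CalibrationPoint, ...]
    k_values: tuple[float, ...]
    rounding_mode: RoundingMode


def k_from_mixture(trout_fraction_pct: float, q_o: float, q_s: float) -> float:
    """K implied by one mixture of known composition.

    K = (f/(100−f)) × (q_s/q_o): the mass ratio the mixture is known to have,
    divided by the copy ratio that was measured.
    """
    if not 0 < trout_fraction_pct < 100:
        raise InputError(
            "K is undefined at 0% or 100% trout (mass ratio is 0 or infinite)"
        )
    if q_o <= 0 or q_s <= 0:
        raise InputError("copy concentrations must be positive")
    mass_ratio = trout_fraction_pct / (100.0 - trout_fraction_pct)
    return mass_ratio * q_s / q_o


def estimate_K(
    points: Sequence[CalibrationPoint],
    rounding_mode: RoundingMode = "raw",
) -> CalibrationResult:
    """Average the per-mixture K values and report their RSD.

    ``rounding_mode="two_decimals"`` rounds each per-point K to two decimals
    before averaging — the convention of published report tables, whose RSD
    refers to the printed K column. Default is full precision.
    """
    if len(points) < 2:
        raise InputError("need at least two calibration points")
    ks = np.array([p.k_value for p in points], dtype=float)
    if rounding_mode == "two_decimals":
        ks = np.round(ks, 2)
    elif rounding_mode != "raw":
        raise InputError(f"unknown rounding_mode {rounding_mode!r}")
    mean = float(ks.mean())
    rsd = validation.rsd(ks)
    return CalibrationResult(
        k_mean=mean,
        k_rsd_pct=rsd,
        points=tuple(points),
        k_values=tuple(float(k) for k in ks),
        rounding_mode=rounding_mode,
    )


def points_from_pooled(
    fractions_pct: Sequence[float],
    pooled_trout,
    pooled_salmon,
) -> list[CalibrationPoint]:
    """Build calibration points from replicate-pooled channel estimates.

    K is computed from replicate-mean concentrations per mixture (not
    per-replicate then averaged), matching how calibration tables are
    reported.
    """
    if not len(fractions_pct) == len(pooled_trout) == len(pooled_salmon):
        raise InputError("fractions and pooled estimates must align")
    return [
        CalibrationPoint(
            trout_mass_fraction_pct=f,
            q_o=po.mean_copies_per_ul,
            q_s=ps.mean_copies_per_ul,
        )
        for f, po, ps in zip(fractions_pct, pooled_trout, pooled_salmon)
    ]


def verify_K(
    known_fractions_pct: Sequence[float],
    measured_ratios: Sequence[float],
    k: float,
) -> pd.DataFrame:
    """Apply a calibrated K to mixtures of known composition.

    ``measured_ratios`` are the observed Q_O/Q_S copy ratios. Returns a table
    with the measured mass fraction and its signed relative deviation (%)
    from the declared value — the accuracy check run on independent mixtures
    after calibration.
    """
    if len(known_fractions_pct) != len(measured_ratios):
        raise InputError("fraction and ratio lists must have equal length")
    if k <= 0:
        raise InputError("K must be positive")
    rows = []
    for actual, ratio in zip(known_fractions_pct, measured_ratios):
        measured = quantification.mass_fraction_percent(ratio, 1.0, k)
        rows.append(
            {
                "actual_pct": actual,
                "measured_pct": measured,
                "deviation_pct": validation.relative_deviation(measured, actual),
            }
        )
    return pd.DataFrame(rows)
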