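"""Plate-level convenience workflows shared by the CLI, tests and scripts.

These glue functions run the standard analysis path on an in-memory plate
table: pool replicate wells per (sample, channel), build calibration points
against declared fractions, or quantify every sample with a given K.
"""

from __future__ import annotations

from typing import Mapping

import pandas as pd

from . import calibration, plates, quantification, validation
from .config import DEFAULT_MIN_DROPLETS
from .droplets import PooledEstimate, WellReading, estimate_concentration, pool_replicates
from .errors import InputError
from .quantification import DEFAULT_LOD_PCT


def _usable_readings(plate_df: pd.DataFrame, min_droplets: int) -> list[WellReading]:
    readings = [
        w for w in plates.to_well_readings(plate_df) if w.n_total >= min_droplets
    ]
    if not readings:
        raise InputError(f"no wells with at least {min_droplets} droplets")
    return readings


def pool_plate(
    plate_df: pd.DataFrame, min_droplets: int = DEFAULT_MIN_DROPLETS
) -> dict[tuple[str, str], PooledEstimate]:
    """Replicate-pooled concentrations keyed by (sample_id, channel).

    Saturated wells are excluded from pooling; a (sample, channel) with no
    usable well is simply absent from the result.
    """
    readings = _usable_readings(plate_df, min_droplets)
    pooled: dict[tuple[str, str], PooledEstimate] = {}
    order = list(dict.fromkeys(w.sample_id for w in readings))
    for sample in order:
        for channel in ("FAM", "HEX"):
            ests = [
                estimate_concentration(w, allow_saturated=True)
                for w in readings
                if w.sample_id == sample and w.channel == channel
            ]
            ests = [e for e in ests if not e.saturated]
            if ests:
                pooled[(sample, channel)] = pool_replicates(ests)
    return pooled


def calibrate_plate(
    plate_df: pd.DataFrame,
    fractions_by_sample: Mapping[str, float],
    rounding_mode: calibration.RoundingMode = "raw",
    min_droplets: int = DEFAULT_MIN_DROPLETS,
) -> calibration.CalibrationResult:
    """Estimate K from a plate of mixtures with declared trout fractions.

    K is computed from replicate-mean concentrations per mixture.
    """
    pooled = pool_plate(plate_df, min_droplets)
    samples = list(dict.fromkeys(s for s, _ in pooled))
    points = []
    for sample in samples:
        if sample not in fractions_by_sample:
            raise InputError(f"sample {sample!r} missing a declared fraction")
        po = pooled.get((sample, "FAM"))
        ps = pooled.get((sample, "HEX"))
        if po is None or ps is None:
            raise InputError(f"sample {sample!r}: missing a usable channel")
        points.append(
            calibration.CalibrationPoint(
                trout_mass_fraction_pct=float(fractions_by_sample[sample]),
                q_o=po.mean_copies_per_ul,
                q_s=ps.mean_copies_per_ul,
            )
        )
    return calibration.estimate_K(points, rounding_mode=rounding_mode)


def quantify_plate(
    plate_df: pd.DataFrame,
    k: float,
    lod_pct: float = DEFAULT_LOD_PCT,
    min_droplets: int = DEFAULT_MIN_DROPLETS,
) -> list[quantification.QuantResult]:
    """Quantify every sample on a plate in first-appearance order."""
    readings = _usable_readings(plate_df, min_droplets)
    order = list(dict.fromkeys(w.sample_id for w in readings))
    return [
        quantification.quantify_sample(
            [w for w in readings if w.sample_id == sample], k, lod_pct=lod_pct
        )
        for sample in order
    ]


def measure_levels(
    plate_df: pd.DataFrame,
    fractions_by_sample: Mapping[str, float],
    k: float,
    min_droplets: int = DEFAULT_MIN_DROPLETS,
) -> pd.DataFrame:
    """Per-level measured fractions, detection rates and deviations.

    The table feeding dynamic-range regression and the LOD/LOQ rules:
    one row per sample, sorted by actual fraction. Detection rate is the
    percentage of FAM (trout) replicates with at least one positive droplet.
    """
    readings = _usable_readings(plate_df, min_droplets)
    rows = []
    for sample in dict.fromkeys(w.sample_id for w in readings):
        if sample not in fractions_by_sample:
            raise InputError(f"sample {sample!r} missing a declared fraction")
        wells = [w for w in readings if w.sample_id == sample]
        fams = [w for w in wells if w.channel == "FAM"]
        if not fams:
            raise InputError(f"sample {sample!r}: no FAM wells")
        rate = 100.0 * sum(w.n_positive > 0 for w in fams) / len(fams)
        res = quantification.quantify_sample(wells, k, lod_pct=0.0)
        actual = float(fractions_by_sample[sample])
        rows.append(
            {
                "sample_id": sample,
                "actual_pct": actual,
                "measured_pct": res.trout_fraction_pct,
                "rsd_pct": res.rsd_pct,
                "detection_rate_pct": rate,
                "deviation_pct": (
                    validation.relative_deviation(res.trout_fraction_pct, actual)
                    if actual
                    else float("nan")
                ),
            }
        )
    return (
        pd.DataFrame(rows).sort_values("actual_pct").reset_index(drop=True)
    )
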