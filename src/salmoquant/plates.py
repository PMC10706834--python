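"""Plate-table IO and report rendering.

The plate format is plain CSV with header
``well_id,sample_id,channel,n_total,n_positive[,droplet_volume_nl]`` and
channel values FAM (trout target) or HEX (salmon target). Reports can be
written in ``machine`` mode (full-precision CSV) or ``paper`` mode (numbers
rendered at two decimals, as in published report tables); both are
deterministic byte-for-byte for identical inputs.
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .calibration import CalibrationResult
from .droplets import DEFAULT_DROPLET_VOLUME_NL, WellReading
from .errors import FormatError
from .quantification import QuantResult

REQUIRED_COLUMNS = ("well_id", "sample_id", "channel", "n_total", "n_positive")


def read_plate(path) -> pd.DataFrame:
    """Read and validate a plate CSV.

    Raises :class:`FormatError` naming the missing column or the 1-based file
    line of the first offending row.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, dtype={"well_id": str, "sample_id": str, "channel": str})
    except Exception as exc:  # malformed CSV
        raise FormatError(f"{path}: cannot parse CSV ({exc})") from exc
    for col in REQUIRED_COLUMNS:
        if col not in df.columns:
            raise FormatError(f"{path}: missing required column {col!r}")
    if "droplet_volume_nl" not in df.columns:
        df["droplet_volume_nl"] = DEFAULT_DROPLET_VOLUME_NL

    def _line(i: int) -> int:
        return i + 2  # header is line 1

    for col in ("n_total", "n_positive"):
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = vals.isna() | (vals < 0) | (vals != vals.round())
        if bad.any():
            i = int(np.flatnonzero(bad)[0])
            raise FormatError(
                f"{path}: line {_line(i)}: {col!r} must be a nonnegative integer"
            )
        df[col] = vals.astype(int)
    over = df["n_positive"] > df["n_total"]
    if over.any():
        i = int(np.flatnonzero(over)[0])
        raise FormatError(f"{path}: line {_line(i)}: n_positive exceeds n_total")
    bad_chan = ~df["channel"].isin(["FAM", "HEX"])
    if bad_chan.any():
        i = int(np.flatnonzero(bad_chan)[0])
        raise FormatError(f"{path}: line {_line(i)}: channel must be FAM or HEX")
    dup = df.duplicated(subset=["well_id", "channel"])
    if dup.any():
        i = int(np.flatnonzero(dup)[0])
        raise FormatError(
            f"{path}: line {_line(i)}: duplicate (well_id, channel) pair"
        )
    return df


def to_well_readings(df: pd.DataFrame) -> list[WellReading]:
    return [
        WellReading(
            well_id=row.well_id,
            sample_id=row.sample_id,
            channel=row.channel,
            n_total=int(row.n_total),
            n_positive=int(row.n_positive),
            droplet_volume_nl=float(row.droplet_volume_nl),
        )
        for row in df.itertuples()
    ]


def write_plate(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)


def calibration_report(result: CalibrationResult) -> pd.DataFrame:
    """Calibration table: fraction, per-channel copies, K, K mean, RSD."""
    rows = []
    for point, k in zip(result.points, result.k_values):
        rows.append(
            {
                "trout_mass_fraction_pct": point.trout_mass_fraction_pct,
                "trout_copies_per_ul": point.q_o,
                "salmon_copies_per_ul": point.q_s,
                "k_value": k,
            }
        )
    df = pd.DataFrame(rows)
    df["k_mean"] = result.k_mean
    df["k_rsd_pct"] = result.k_rsd_pct
    return df


def quantification_report(results: Sequence[QuantResult]) -> pd.DataFrame:
    """Per-sample quantification table (declared-product survey layout).

    Samples called ``not_detected`` are rendered with a measured value of 0,
    and ``pure_trout`` with 100, following reporting convention.
    """
    if not results:
        raise FormatError("no quantification results to report")
    rows = []
    for r in results:
        if r.call == "not_detected":
            shown = 0.0
        elif r.call == "pure_trout":
            shown = 100.0
        else:
            shown = r.trout_fraction_pct
        rows.append(
            {
                "sample_id": r.sample_id,
                "trout_fraction_pct": shown,
                "replicate_sd": r.replicate_sd,
                "rsd_pct": r.rsd_pct,
                "n_replicates": r.n_replicates,
                "call": r.call,
            }
        )
    return pd.DataFrame(rows)


def write_report(df: pd.DataFrame, path, mode: str = "machine") -> None:
    """Write a report table; ``paper`` mode rounds numerics to two decimals."""
    path = Path(path)
    if mode == "machine":
        df.to_csv(path, index=False)
    elif mode == "paper":
        shown = df.copy()
        for col in shown.columns:
            if pd.api.types.is_float_dtype(shown[col]):
                shown[col] = shown[col].map(
                    lambda v: "" if pd.isna(v) else f"{v:.2f}"
                )
        path.write_text(shown.to_string(index=False) + "\n")
    else:
        raise FormatError(f"unknown report mode {mode!r}")
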