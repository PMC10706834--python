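"""One-step mass-fraction quantification of unknown samples.

Given a calibrated transfer coefficient K, a sample's trout/salmon mass
ratio is M_O/M_S = K × (Q_O/Q_S), and its trout mass fraction (percent of
total meat mass) is 100·r/(1+r) with r the mass ratio. Replicate duplex
wells are quantified individually and summarised as mean ± SD with a
detection call.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np

from .droplets import WellReading, estimate_concentration
from .errors import InputError, QuantificationFailure

Call = Literal["not_detected", "adulterated", "pure_trout"]

#: Default limit of detection (% mass) used for the detection call.
DEFAULT_LOD_PCT = 0.2


@dataclass(frozen=True)
class QuantResult:
    sample_id: str
    mass_ratio: float  # math.inf flags a pure-trout sample (no salmon copies)
    trout_fraction_pct: float
    replicate_mean: float
    replicate_sd: float
    rsd_pct: float
    n_replicates: int
    call: Call


def mass_ratio(q_o: float, q_s: float, k: float) -> float:
    """Trout/salmon mass ratio M_O/M_S = K × Q_O/Q_S.

    Zero trout copies give 0; zero salmon copies with trout present give
    ``math.inf`` (a pure-trout sample). Both zero means no template at all.
    """
    if k <= 0:
        raise InputError("K must be positive")
    if q_o < 0 or q_s < 0:
        raise InputError("copy concentrations must be nonnegative")
    if q_o == 0 and q_s == 0:
        raise QuantificationFailure("no template detected on either channel")
    if q_s == 0:
        return math.inf
    return k * q_o / q_s


def mass_fraction_percent(q_o: float, q_s: float, k: float) -> float:
    """Trout mass fraction in percent: 100·Kr/(1+Kr) with r = Q_O/Q_S."""
    r = mass_ratio(q_o, q_s, k)
    if math.isinf(r):
        return 100.0
    return 100.0 * r / (1.0 + r)


def _pair_replicates(wells: Sequence[WellReading]) -> list[tuple[WellReading, WellReading]]:
    """Group wells into duplex (FAM, HEX) pairs by well id."""
    by_well: dict[str, dict[str, WellReading]] = {}
    for w in wells:
        by_well.setdefault(w.well_id, {})[w.channel] = w
    pairs = []
    for well_id, chans in sorted(by_well.items()):
        if set(chans) != {"FAM", "HEX"}:
            raise InputError(
                f"well {well_id!r} is not a complete duplex (channels {sorted(chans)})"
            )
        pairs.append((chans["FAM"], chans["HEX"]))
    return pairs


def quantify_sample(
    wells: Sequence[WellReading],
    k: float,
    lod_pct: float = DEFAULT_LOD_PCT,
) -> QuantResult:
    """Quantify one sample from its replicate duplex wells.

    Each well pair (trout on FAM, salmon on HEX) yields one mass-fraction
    estimate; replicates are summarised as mean ± sample SD. Saturated or
    template-free replicates are dropped; if none remain the sample cannot
    be quantified. The call thresholds the mean fraction at the LOD on both
    ends: below it the sample is reported as not_detected, above 100 − LOD
    as pure_trout.
    """
    if not wells:
        raise InputError("need at least one well")
    sample_ids = {w.sample_id for w in wells}
    if len(sample_ids) > 1:
        raise InputError(f"wells from multiple samples: {sorted(sample_ids)}")
    fractions = []
    for fam, hex_ in _pair_replicates(wells):
        est_o = estimate_concentration(fam, allow_saturated=True)
        est_s = estimate_concentration(hex_, allow_saturated=True)
        if est_o.saturated or est_s.saturated:
            continue
        if est_o.copies_per_ul == 0 and est_s.copies_per_ul == 0:
            continue
        fractions.append(
            mass_fraction_percent(est_o.copies_per_ul, est_s.copies_per_ul, k)
        )
    if not fractions:
        raise QuantificationFailure(
            f"sample {wells[0].sample_id!r}: every replicate saturated or empty"
        )
    arr = np.array(fractions)
    mean = float(arr.mean())
    sd = float(arr.std(ddof=1)) if len(arr) > 1 else 0.0
    if mean <= lod_pct:
        call: Call = "not_detected"
    elif mean >= 100.0 - lod_pct:
        call = "pure_trout"
    else:
        call = "adulterated"
    ratio = math.inf if mean >= 100.0 else mean / (100.0 - mean)
    return QuantResult(
        sample_id=wells[0].sample_id,
        mass_ratio=ratio,
        trout_fraction_pct=mean,
        replicate_mean=mean,
        replicate_sd=sd,
        rsd_pct=100.0 * sd / mean if mean else math.nan,
        n_replicates=len(arr),
        call=call,
    )
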