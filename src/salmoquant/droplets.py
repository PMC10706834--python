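"""Poisson partition statistics for droplet digital PCR.

A ddPCR reaction is partitioned into ~20,000 droplets of known volume
(0.85 nL for the QX200 workflow). Template molecules distribute across
droplets approximately Poisson, so the mean occupancy lambda is recovered
from the fraction of negative droplets:

    lambda = -ln(n_negative / n_total)

and the absolute concentration is lambda divided by the droplet volume in
microlitres. Confidence intervals are obtained by putting a Wilson score
interval on the positive fraction p and pushing its endpoints through
lambda = -ln(1 - p); the Wilson interval stays well-behaved at the extreme
counts (few positives, few negatives) where digital PCR actually operates.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from statsmodels.stats.proportion import proportion_confint

from .errors import InputError, SaturationError

#: QX200 droplet volume in nanolitres; overridable per well.
DEFAULT_DROPLET_VOLUME_NL = 0.85

CHANNELS = ("FAM", "HEX")


@dataclass(frozen=True)
class WellReading:
    """Droplet counts for one well on one fluorescence channel."""

    well_id: str
    sample_id: str
    channel: str
    n_total: int
    n_positive: int
    droplet_volume_nl: float = DEFAULT_DROPLET_VOLUME_NL

    def __post_init__(self) -> None:
        if self.channel not in CHANNELS:
            raise InputError(f"channel must be one of {CHANNELS}, got {self.channel!r}")
        if self.n_total <= 0:
            raise InputError("n_total must be positive")
        if not 0 <= self.n_positive <= self.n_total:
            raise InputError("n_positive must lie in [0, n_total]")
        if self.droplet_volume_nl <= 0:
            raise InputError("droplet_volume_nl must be positive")


@dataclass(frozen=True)
class CopyEstimate:
    """Absolute concentration estimate for one well/channel."""

    lambda_hat: float
    copies_per_ul: float
    ci_low: float
    ci_high: float
    confidence: float = 0.95
    saturated: bool = False
    channel: str | None = None
    sample_id: str | None = None


@dataclass(frozen=True)
class PooledEstimate:
    """Replicate-pooled concentration: mean ± sample SD of copies/µL."""

    mean_copies_per_ul: float
    sd_copies_per_ul: float
    n: int
    channel: str | None = None
    sample_id: str | None = None
    rsd_pct: float = field(init=False)

    def __post_init__(self) -> None:
        rsd = (
            100.0 * self.sd_copies_per_ul / self.mean_copies_per_ul
            if self.mean_copies_per_ul
            else math.nan
        )
        object.__setattr__(self, "rsd_pct", rsd)


def estimate_lambda(n_total: int, n_positive: int) -> float:
    """Mean copies per droplet from droplet counts.

    Raises :class:`SaturationError` when every droplet is positive, since the
    negative fraction is zero and lambda is unbounded.
    """
    if n_total <= 0:
        raise InputError("n_total must be positive")
    if not 0 <= n_positive <= n_total:
        raise InputError("n_positive must lie in [0, n_total]")
    if n_positive == n_total:
        raise SaturationError(
            f"all {n_total} droplets positive: lambda is unbounded"
        )
    if n_positive == 0:
        return 0.0
    return -math.log((n_total - n_positive) / n_total)


def estimate_concentration(
    reading: WellReading,
    confidence: float = 0.95,
    allow_saturated: bool = False,
) -> CopyEstimate:
    """Point estimate and CI for copies/µL from one well.

    A saturated well (all droplets positive) raises unless
    ``allow_saturated`` is set, in which case an infinite estimate is
    returned with ``saturated=True`` so downstream stages can flag and
    exclude it rather than crash.
    """
    vol_ul = reading.droplet_volume_nl * 1e-3
    if reading.n_positive == reading.n_total:
        if not allow_saturated:
            estimate_lambda(reading.n_total, reading.n_positive)  # raises
        return CopyEstimate(
            lambda_hat=math.inf,
            copies_per_ul=math.inf,
            ci_low=math.inf,
            ci_high=math.inf,
            confidence=confidence,
            saturated=True,
            channel=reading.channel,
            sample_id=reading.sample_id,
        )
    lam = estimate_lambda(reading.n_total, reading.n_positive)
    p_low, p_high = proportion_confint(
        reading.n_positive, reading.n_total, alpha=1 - confidence, method="wilson"
    )
    # lambda = -ln(1-p) is monotone in p, so endpoints map directly
    lam_low = -math.log1p(-min(p_low, 1.0 - 1e-15))
    lam_high = -math.log1p(-min(p_high, 1.0 - 1e-15))
    return CopyEstimate(
        lambda_hat=lam,
        copies_per_ul=lam / vol_ul,
        ci_low=lam_low / vol_ul,
        ci_high=lam_high / vol_ul,
        confidence=confidence,
        channel=reading.channel,
        sample_id=reading.sample_id,
    )


def pool_replicates(estimates: list[CopyEstimate]) -> PooledEstimate:
    """Mean ± sample SD (ddof=1) of copies/µL across replicate wells.

    All estimates must share a channel; saturated replicates are rejected
    because their concentration is not finite.
    """
    if not estimates:
        raise InputError("need at least one estimate")
    channels = {e.channel for e in estimates}
    if len(channels) > 1:
        raise InputError(f"mixed channels in replicate pool: {sorted(channels)}")
    samples = {e.sample_id for e in estimates}
    if len(samples) > 1:
        raise InputError(f"mixed samples in replicate pool: {sorted(samples)}")
    if any(e.saturated for e in estimates):
        raise InputError("saturated wells cannot be pooled")
    values = np.array([e.copies_per_ul for e in estimates], dtype=float)
    sd = float(values.std(ddof=1)) if len(values) > 1 else 0.0
    return PooledEstimate(
        mean_copies_per_ul=float(values.mean()),
        sd_copies_per_ul=sd,
        n=len(values),
        channel=estimates[0].channel,
        sample_id=estimates[0].sample_id,
    )
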