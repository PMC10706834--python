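"""Seeded synthetic duplex ddPCR experiments and qPCR Ct data.

The generator emulates the statistical structure the downstream analysis
relies on:

* **Copies-per-mass constants.** Each species contributes myoglobin-gene
  copies proportional to its mass in the mixture; the ratio of the two
  per-mass constants is the true transfer coefficient K that calibration must
  recover.
* **Shared extraction noise.** DNA extraction efficiency varies between
  tubes, not between the two channels of a duplex well, so one lognormal
  draw per replicate scales both species jointly. This is precisely why the
  copy-number *ratio* is more precise than either concentration alone.
* **Degradation.** Thermal/freezing treatment is modelled as a
  species-symmetric retention factor on amplifiable copies, which leaves the
  ratio (and hence the estimated mass fraction) unchanged — matching the
  observed robustness of ratio-based quantification to processing.
* **Droplet partitioning.** Each of ~20,000 droplets holds Poisson(lambda)
  templates; positive/negative calls can be corrupted by per-droplet
  false-positive/false-negative rates ("rain").
* **qPCR comparator.** Ct values follow a linear Ct-vs-log10(concentration)
  model with Gaussian cycle noise.

One global seed per study; per-well substreams are derived by counter so a
well's data does not depend on design order.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .droplets import DEFAULT_DROPLET_VOLUME_NL, WellReading
from .errors import InputError

#: Copies/µL of reaction contributed per percent mass, rainbow trout (FAM).
#: Magnitude matches the pure-meat concentrations implied by the published
#: calibration table (~10² copies/µL per channel at mid fractions).
DEFAULT_C_O = 9.4
#: Same for Atlantic salmon (HEX); ratio c_s/c_o gives a true K of 0.43.
DEFAULT_C_S = 9.4 * 0.43

#: Published qPCR standard-curve parameters (Ct per log10 ng/µL; Ct at 1 ng/µL).
QPCR_SLOPE_TROUT, QPCR_INTERCEPT_TROUT = -3.506, 31.88
QPCR_SLOPE_SALMON, QPCR_INTERCEPT_SALMON = -3.231, 31.57


@dataclass(frozen=True)
class SpeciesConstants:
    """Per-mass amplifiable-copy constants for the two species.

    Units: copies/µL of reaction contributed per percent of mixture mass at
    the standard DNA input. Only the ratio matters for quantification.
    """

    c_o: float = DEFAULT_C_O
    c_s: float = DEFAULT_C_S

    def __post_init__(self) -> None:
        if self.c_o <= 0 or self.c_s <= 0:
            raise InputError("copies-per-mass constants must be positive")

    @property
    def true_k(self) -> float:
        return self.c_s / self.c_o


@dataclass(frozen=True)
class SimConfig:
    """Knobs of the synthetic experiment."""

    n_droplets: int = 20000
    droplet_volume_nl: float = DEFAULT_DROPLET_VOLUME_NL
    fp_rate: float = 0.0
    fn_rate: float = 0.0
    extraction_cv: float = 0.05
    degradation_factor: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("fp_rate", "fn_rate"):
            r = getattr(self, name)
            if not 0 <= r < 1:
                raise InputError(f"{name} must lie in [0, 1)")
        if not 0 < self.degradation_factor <= 1:
            raise InputError("degradation_factor must lie in (0, 1]")
        if self.extraction_cv < 0:
            raise InputError("extraction_cv must be nonnegative")
        if self.n_droplets <= 0 or self.droplet_volume_nl <= 0:
            raise InputError("n_droplets and droplet_volume_nl must be positive")


@dataclass(frozen=True)
class MixtureSample:
    """A binary trout/salmon meat mixture with a declared trout mass fraction."""

    sample_id: str
    trout_mass_fraction_pct: float
    total_mass_mg: float = 100.0

    def __post_init__(self) -> None:
        if not 0 <= self.trout_mass_fraction_pct <= 100:
            raise InputError("trout_mass_fraction_pct must lie in [0, 100]")
        if self.total_mass_mg <= 0:
            raise InputError("total_mass_mg must be positive")


def _lognormal_factor(rng: np.random.Generator, cv: float) -> float:
    """Unit-mean lognormal multiplier with coefficient of variation cv."""
    if cv == 0:
        return 1.0
    sigma2 = math.log1p(cv * cv)
    return float(rng.lognormal(mean=-sigma2 / 2, sigma=math.sqrt(sigma2)))


def simulate_mixture_copies(
    mix: MixtureSample,
    consts: SpeciesConstants = SpeciesConstants(),
    cfg: SimConfig = SimConfig(),
    rng: np.random.Generator | None = None,
) -> tuple[float, float]:
    """True per-species template concentrations (copies/µL) for one replicate.

    Both species are scaled by a single shared extraction draw and the
    degradation factor; a 0% mixture yields exactly zero trout copies.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    f = mix.trout_mass_fraction_pct
    shared = _lognormal_factor(rng, cfg.extraction_cv) * cfg.degradation_factor
    scale = mix.total_mass_mg / 100.0
    conc_o = consts.c_o * f * scale * shared
    conc_s = consts.c_s * (100.0 - f) * scale * shared
    return conc_o, conc_s


def simulate_well(
    conc_copies_per_ul: float,
    cfg: SimConfig = SimConfig(),
    channel: str = "FAM",
    well_id: str = "A01",
    sample_id: str = "sample",
    rng: np.random.Generator | None = None,
) -> WellReading:
    """Partition a template concentration into droplet counts for one channel.

    Each droplet holds Poisson(lambda) templates with
    lambda = conc × droplet volume (µL), so a droplet is truly positive with
    probability 1 − exp(−lambda); false-negative and false-positive rates then
    corrupt the calls independently per droplet.
    """
    if conc_copies_per_ul < 0:
        raise InputError("concentration must be nonnegative")
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    lam = conc_copies_per_ul * cfg.droplet_volume_nl * 1e-3
    p_occupied = -math.expm1(-lam)
    n_true_pos = int(rng.binomial(cfg.n_droplets, p_occupied))
    kept = n_true_pos - int(rng.binomial(n_true_pos, cfg.fn_rate)) if cfg.fn_rate else n_true_pos
    flipped = (
        int(rng.binomial(cfg.n_droplets - n_true_pos, cfg.fp_rate)) if cfg.fp_rate else 0
    )
    return WellReading(
        well_id=well_id,
        sample_id=sample_id,
        channel=channel,
        n_total=cfg.n_droplets,
        n_positive=kept + flipped,
        droplet_volume_nl=cfg.droplet_volume_nl,
    )


def simulate_qpcr_ct(
    conc_ng_per_ul: float,
    slope: float,
    intercept: float,
    noise_sd: float = 0.0,
    rng: np.random.Generator | None = None,
    seed: int | None = None,
) -> float:
    """Ct value from the linear Ct-vs-log10(concentration) model plus noise."""
    if conc_ng_per_ul <= 0:
        raise InputError("concentration must be positive for a Ct to exist")
    if rng is None:
        rng = np.random.default_rng(seed)
    ct = slope * math.log10(conc_ng_per_ul) + intercept
    if noise_sd > 0:
        ct += float(rng.normal(0.0, noise_sd))
    return ct


@dataclass(frozen=True)
class StudyData:
    """Output of :func:`generate_study`: plate table plus ground truth."""

    plate: pd.DataFrame
    truth: pd.DataFrame
    consts: SpeciesConstants
    cfg: SimConfig


def generate_study(
    design: Sequence[tuple[MixtureSample, int]],
    consts: SpeciesConstants = SpeciesConstants(),
    cfg: SimConfig = SimConfig(),
) -> StudyData:
    """Simulate a full duplex plate for a list of (mixture, n_replicates).

    Each replicate is one duplex well: the trout target read on FAM and the
    salmon target on HEX share the well id, the extraction draw, and the
    droplet count. The plate table uses the package CSV dialect
    (well_id,sample_id,channel,n_total,n_positive,droplet_volume_nl); the
    truth table records the simulated concentrations and the true mass
    fraction per replicate. Fully deterministic under ``cfg.seed``, with
    per-well substreams derived by counter.
    """
    if not design:
        raise InputError("design must be non-empty")
    plate_rows = []
    truth_rows = []
    well_counter = 0
    for mix, n_reps in design:
        if n_reps <= 0:
            raise InputError("replicate count must be positive")
        for rep in range(n_reps):
            rng = np.random.default_rng(
                np.random.SeedSequence(entropy=cfg.seed, spawn_key=(well_counter,))
            )
            well_id = f"W{well_counter + 1:03d}"
            conc_o, conc_s = simulate_mixture_copies(mix, consts, cfg, rng=rng)
            for channel, conc in (("FAM", conc_o), ("HEX", conc_s)):
                w = simulate_well(
                    conc, cfg, channel=channel, well_id=well_id,
                    sample_id=mix.sample_id, rng=rng,
                )
                plate_rows.append(
                    {
                        "well_id": w.well_id,
                        "sample_id": w.sample_id,
                        "channel": w.channel,
                        "n_total": w.n_total,
                        "n_positive": w.n_positive,
                        "droplet_volume_nl": w.droplet_volume_nl,
                    }
                )
            truth_rows.append(
                {
                    "well_id": well_id,
                    "sample_id": mix.sample_id,
                    "replicate": rep + 1,
                    "trout_mass_fraction_pct": mix.trout_mass_fraction_pct,
                    "conc_trout_copies_per_ul": conc_o,
                    "conc_salmon_copies_per_ul": conc_s,
                }
            )
            well_counter += 1
    return StudyData(
        plate=pd.DataFrame(plate_rows),
        truth=pd.DataFrame(truth_rows),
        consts=consts,
        cfg=cfg,
    )


def calibration_design(
    fractions_pct: Sequence[float] = (10, 30, 50, 70, 90),
    replicates: int = 6,
) -> list[tuple[MixtureSample, int]]:
    """The K-estimation design: five fractions spanning the range, n=6 each."""
    return [
        (MixtureSample(sample_id=f"mix_{f:g}pct", trout_mass_fraction_pct=f), replicates)
        for f in fractions_pct
    ]


def verification_design(
    fractions_pct: Sequence[float] = (20, 40, 60, 80),
    replicates: int = 4,
) -> list[tuple[MixtureSample, int]]:
    """The K-verification design: four interleaved fractions in quadruplicate."""
    return calibration_design(fractions_pct, replicates)
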