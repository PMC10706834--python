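# Methods

## Poisson copy estimation

Template molecules partition across droplets approximately independently, so
the number of copies in one droplet is Poisson with mean λ and the negative
fraction estimates e^−λ. The estimator λ̂ = −ln(N₋/N) is the MLE; the
concentration is λ̂/v with v the droplet volume in µL. The droplet volume is
not part of the instrument export and is taken as the QX200 convention of
0.85 nL (configurable per well); every ratio-based quantity in the pipeline
(K, mass fraction) is volume-independent because the volume cancels.

Confidence intervals put a Wilson score interval on the positive fraction
p̂ = 1 − N₋/N and map its endpoints through λ = −ln(1−p), which is monotone.
Wilson was preferred over Wald because digital PCR routinely operates at
extreme counts (a handful of positives near the LOD) where the Wald interval
collapses or escapes [0, 1]. A well with every droplet positive carries no
finite estimate: it raises a saturation error, or with `allow_saturated` is
returned flagged and infinite, and flagged wells are excluded from pooling
and calibration.

Replicates are pooled as mean ± sample SD (n−1 denominator) of copies/µL,
matching how replicate tables are reported.

## Transfer-coefficient calibration

For a binary mixture with trout mass fraction f (percent), the known mass
ratio is f/(100−f) and the measured copy ratio is Q_O/Q_S, so each
calibration mixture yields K = (f/(100−f))·(Q_S/Q_O). K is computed from
replicate-mean concentrations per mixture — not per replicate and then
averaged — because the replicate means are the stable quantity at the
calibration design's droplet counts, and this matches reporting convention.
The calibration result carries the mean K and the RSD of the per-mixture K
values, which measures constancy of K across the composition range.

Two rounding modes exist because published calibration tables print K at two
decimals: `raw` (default) averages full-precision K values; `two_decimals`
rounds each per-mixture K before averaging, reproducing table-derived
statistics. The packaged default K = 0.43 is the published constant for the
bundled myoglobin panel; any calibration file overrides it.

## Quantification and calls

Mass fraction is 100·Kr/(1+Kr) with r = Q_O/Q_S; it maps [0, ∞] onto
[0, 100] monotonically, with exact endpoints when one channel is empty (a
sample with no salmon signal is flagged infinite/pure-trout rather than
erroring). Per-replicate fractions are summarised as mean ± SD and RSD. The
detection call thresholds the mean at the configured LOD (default 0.2%):
below it `not_detected` (the numeric estimate is still reported), above
100 − LOD `pure_trout`, else `adulterated`. Wells with fewer than 10,000
droplets (configurable) are discarded before analysis, a conventional
quality floor for 20,000-droplet chemistry.

## Validation rules

* Signed relative deviation: 100·(measured − actual)/actual, computed from
  unrounded means internally; report renderers emit two-decimal versions.
* Dynamic range: OLS of measured on actual fraction (scipy), R² as squared
  Pearson correlation.
* LOD: the smallest tested fraction with a 100% positive-replicate rate such
  that every larger tested fraction also reaches 100% — "stably detected"
  demands an unbroken run of stability from the top of the range down.
* LOQ: same monotone scan with the pass criterion |deviation| ≤ 25%
  (CAC/GL 74-2010). A failing level *below* the smallest unbroken passing run
  does not block the answer; a failure above any candidate does.
* Repeatability is the mean over runs of the within-run replicate RSD;
  reproducibility is the RSD of run (day × operator) means; both are
  reported per level plus an across-level average.
* One-way ANOVA is the classical between/within decomposition with the p
  value from the F upper tail; zero within-group variance with nonzero
  between-group variance returns an infinite F flagged `degenerate` rather
  than dividing by zero. The implementation is cross-checked against
  scipy.stats.f_oneway in the test suite.

## qPCR comparator

Standard curves are OLS fits of Ct on log₁₀(ng/µL) over a four-fold dilution
series from 50 ng/µL (six points); efficiency is 100·(10^(−1/slope) − 1).
Unknown Ct values are interpolated as 10^((Ct − intercept)/slope) and the
relative quantity P_O = 100·C_O/(C_O + C_S) is reported as the mass-fraction
estimate *without* any K-style correction — deliberately, since quantifying
the systematic and dispersion penalty of that shortcut relative to the
ddPCR route is the point of the comparison.

## In-silico PCR

Primer matching is Hamming distance only (no indels), with the 3′-terminal
base of each primer required to match exactly because a 3′ mismatch blocks
extension; the default tolerance is 2 mismatches elsewhere. IUPAC ambiguity
codes in primers match their expansion sets; templates may contain only
ACGTN and N matches nothing. Products are enumerated for every
forward/reverse site pair up to a 2 kb cap, and probe presence (either
orientation) is annotated per product. This is a hybridisation-free
approximation: it ignores melting temperature, secondary structure and
polymerase kinetics, so it supports but does not replace wet-lab specificity
panels. The wet-lab tolerance underlying published specificity figures is
not stated anywhere; 2 mismatches with a strict 3′ anchor is this package's
choice of a conservative screening default.

### Reference templates

The bundled templates used in tests and the acceptance script are
**synthetic**: deterministic random sequence carrying each assay's real
forward-primer, probe and reverse-primer sites spaced to give the documented
product lengths (93 bp salmon, 141 bp trout). The true GenBank mRNA records
(NM_001140642, NM_001171862) are not redistributed; against those records
the amplicon lengths are a genuine prediction, whereas on the synthetic
carriers they hold by construction. Record ids are prefixed `synthetic:` to
keep this visible in every output.

## Synthetic-data generator

The generator emulates the study conditions end to end: mixtures at declared
fractions; per-species copies-per-mass constants whose ratio is the true K;
one lognormal extraction draw per replicate shared by both channels of the
duplex well; an optional species-symmetric degradation factor; Poisson
droplet partitioning over 20,000 droplets with optional per-droplet
false-positive/false-negative ("rain") rates; and Gaussian-noise Ct values
from the linear qPCR model.

Defaults, chosen once: c_o = 9.4 and c_s = 4.042 copies/µL per percent mass,
giving pure-meat concentrations of order 10²–10³ copies/µL — the magnitude
implied by the bundled calibration table — and a true K of exactly 0.43;
extraction CV 0.05 (a few-percent tube-to-tube spread, consistent with the
observed replicate RSDs < 5%); fp = fn = 0 (the published assays show clean
cluster separation); degradation 1.0. Two modelling commitments matter
downstream and are asserted in tests: the extraction draw is shared across
channels, so it cancels exactly in the copy ratio (this is *why* the ratio
method is precise), and degradation multiplies both species equally, so the
estimated mass fraction is invariant to it (reproducing the observed
robustness of quantification to thermal/freezing processing, where total
copies drop but the ratio does not).

Randomness uses one seed per study; per-well substreams are derived with
`SeedSequence(seed, spawn_key=(well_index,))` so a well's counts do not
depend on the design order around it.

What the generator does not emulate: amplitude distributions and threshold
setting (counts are taken as given), PCR inhibition, species-asymmetric
matrix effects, or cross-hybridisation. Passing recovery tests therefore
demonstrates the statistical machinery under the assumed noise structure,
not robustness to assay-chemistry failures.

## Problem sizes

Test and acceptance runs use the study designs natively: five levels × six
replicates for calibration (30 duplex wells), quadruplicate verification and
sensitivity designs, 50-seed recovery loops, 200-well estimator-consistency
checks, 1,000-well CI-coverage checks and 2,000-run ANOVA null simulations.
These sizes give Monte-Carlo error comfortably inside the asserted bounds;
the full suite runs in a few seconds on one core.

## Known limitations

* K is assay- and protocol-specific; the packaged 0.43 applies to the
  bundled myoglobin duplex under its published protocol, and recalibration
  is expected for any change of chemistry, species pair or target.
* The Poisson model assumes monodisperse droplets and independent
  partitioning; droplet-volume dispersion biases concentrations slightly but
  cancels in ratios.
* The LOD/LOQ rules are decision procedures over tested levels; they cannot
  return values below the lowest level present in the input design.
* The qPCR comparator ignores inter-run Ct calibration drift; its curves are
  assumed valid for the unknowns interpolated on them.
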