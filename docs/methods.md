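# Methods

## Scope and model

`aerodep` quantifies regional deposition of a ⁹⁹ᵐTc-labeled polydisperse
aerosol from two measurement modalities and joins them into dose fractions:

1. **Activity size distribution** from a cascade impactor: each stage k
   collects the activity of particles whose aerodynamic diameter falls in
   [d_k, d_{k+1}); the empirical cumulative activity distribution is the
   normalized cumulative sum over stages evaluated at the cut-points. The
   underlying aerosol is treated as approximately lognormal — activity
   fraction below d is Φ((ln d − ln AMAD)/ln σ_g) — but none of the
   estimators require exact lognormality.
2. **Regional deposited activity** from a single static planar gamma view:
   after smoothing, background subtraction, decay correction and
   attenuation correction, the summed ROI counts are proportional to the
   deposited activity in that region, with the camera sensitivity
   (counts·s⁻¹·MBq⁻¹) as the proportionality constant.

The dose accounting assumes a well-mixed exposure stream: the subject
inhales a fraction V̇_E/Q of the emitted aerosol, where V̇_E is minute
ventilation and Q the nebulizer flow, neglecting inhalability losses. No
mechanistic deposition model is involved anywhere — the pipeline measures,
it does not predict.

## Estimators and conventions

**Interpolation.** All percentile and sub-cutoff queries interpolate
linearly in (ln d, cumulative fraction). This is the standard treatment for
aerodynamic distributions and is applied uniformly; queries never
extrapolate beyond the outermost cut-points, and sub-cutoff fractions clamp
to 0/1 outside the ladder.

**d16/d84 and GSD.** d16 and d84 are read at the one-sigma cumulative
fractions Φ(∓1) = 15.87 % / 84.13 % (the field's usual meaning of the
"16 %/84 % cut-offs"), so that √(d84/d16) equals σ_g exactly for a
lognormal and d84 = AMAD·σ_g. Reading them at literal 16.00 %/84.00 %
would introduce a systematic ≈0.6 % offset against the lognormal closed
form for broad aerosols.

**Two GSD estimators.** The percentile estimator √(d84/d16) is primary but
carries discretization bias when the stage ladder is coarse relative to the
distribution width: on the default 12-stage ladder the bias reaches −0.34
for σ_g = 3.2 (whose upper tail also exceeds the 10 µm ladder top) and
+0.07 for σ_g = 1.6–2.1, shrinking roughly quadratically with stage count.
A probit least-squares fit — regress Φ⁻¹(cumulative fraction) on ln d over
interior knots — is reported alongside; it is exact on noiseless knots at
any stage count and is the estimator of choice at 12-stage resolution.
Fewer than two interior knots yields NaN fit parameters.

**Stage ladder.** Commercial impactor cut-point tables are
instrument-specific, so the ladder is always an explicit input; the shipped
default is a geometric ladder of 12 stages from 0.007 to 10 µm (constant
ratio in log space), mirroring a low-pressure impactor's nominal range.
Aerosol mass outside the ladder is clamped into the end stages, with a
warning when the ladder misses the central ±3 ln σ_g span.

**Emitted fraction.** (throat-model deposit + Σ stage deposits) /
(syringe activity before charging − residue after). The throat deposit
counts toward emission but never toward the size distribution (it sits
upstream of aerodynamic classification). An explicit counts-per-MBq
calibration factor bridges impactor counting units and gamma-counter MBq;
there is no hidden normalization.

**Image chain.** The 9-point filter is a uniform 3×3 mean with reflection
padding (any 3×3 kernel can be supplied; it is normalized to unit sum).
Background rate is the mean counts/pixel/s over a dedicated background ROI
of the same smoothed image; net ROI counts clamp at zero with a warning.
Decay correction multiplies by 2^(Δt/T½) with T½ = 6.0067 h, referencing
all acquisitions to the start of nebulization; the correction is exactly
invertible and commutes with the (also multiplicative) attenuation factor —
the suite asserts both. Attenuation factors come from calibration
acquisitions of known activity quantified with the same chain minus
attenuation: factor = expected counts / observed corrected counts. Factors
below 1 are physically suspect and accepted with a warning. Reported
relative accuracy is √(1/N_net + ε_att²), i.e. Poisson counting error plus
the attenuation-factor uncertainty in quadrature.

**Normalizations.** Internally every quantity is a fraction in [0, 1];
percent appears only in explicitly `pct_`-named fields and rendered tables
(one-decimal display rounding). ET and TH shares of total deposited sum to
1 by construction. Because mean-of-shares and ratio-of-means differ
whenever deposition varies across inhalations (e.g. 74/26 vs 72/28 from the
same data), group aggregation computes both, labeled explicitly, instead of
silently choosing one.

**Statistics.** The pairwise comparison is a two-sided t test with the p
value multiplied by the number of pairs k(k−1)/2 and clamped at 1. Welch
(unequal-variance) unpaired is the default; a paired mode is provided
because small crossover designs — every subject inhaling every aerosol —
are normally analysed paired, and at n = 6 the unpaired test on summary
statistics like 72 ± 17 vs 49 ± 8 does not reach p < 0.001 while a paired
design plausibly does. Identical constant groups short-circuit to p = 1
rather than dividing by zero variance.

## Synthetic data: what it emulates, what it does not

The generator reproduces the *measurement physics* the pipeline must
invert, with known truth:

- impactor runs: exact lognormal stage masses, optional per-stage Poisson
  draws, a throat-model deposit (default 15 % of emitted activity — the
  value is arbitrary and only the throat+stages total matters for the
  emitted fraction), and nebulizer charge readings (74 MBq default charge);
- phantoms: two elliptical uniform sources on a 128×128 field (head/ET
  above, thorax/TH below; ROI masks dilated 7 px beyond the sources so
  point-spread and smoothing spill is captured), per-region attenuation
  divisors (defaults 1.4 ET, 2.0 TH), Gaussian PSF (σ = 1.5 px), uniform
  background (0.002 counts·px⁻¹·s⁻¹), 120 s acquisitions, Poisson counts.
  The default camera sensitivity (600 cps/MBq) puts the weakest study ROI
  near 1100 net counts, i.e. ≈3 % Poisson relative accuracy — the count
  regime the quantification is designed for;
- the default study: 3 subjects × 2 replicates × 3 aerosols
  (AMAD/σ_g = 2.8 µm/3.2, 550 nm/2.1, 230 nm/1.6; emitted fractions
  44.5 %, 9.3 %, 4.2 %; regional percent-of-emitted truths ET/TH =
  3.7/1.3, 3.45/3.3, 0.75/3.5). Per-inhalation activities jitter
  lognormally around these truths with CV = 0.15, a spread comparable to
  (slightly below) the inter-inhalation variability such studies report;
  the jittered values are what the truth ledger records.

It deliberately does **not** emulate: anatomical ROI shapes or manual
delineation variability, scatter, septal penetration, breathing-motion
blur, hygroscopic growth or evaporation of droplets in transit through the
impactor, swallowed-activity kinetics, or any size-dependence of the
ET/TH split beyond what the truth tables encode. Passing recovery tests
therefore demonstrates that the *correction arithmetic and estimators* are
unbiased at realistic count levels — not that real-image segmentation or
real-impactor artifacts are handled.

All generators are pure functions of (parameters, seed); the study
generator derives per-item seeds from a single master seed.

## Numerical choices and degenerate inputs

- Percentile queries at an exact knot fraction return that knot's diameter
  exactly (round-trip property); plateaus from zero-activity stages
  resolve to the first matching knot.
- Zero total stage activity, non-contiguous ladders, p outside the knot
  span, non-positive cutoffs, zero observed calibration counts, both-zero
  regional activities: all rejected with explicit errors rather than NaNs.
- Filtering can leave −1e−17-scale residue on empty image regions; smoothed
  images clamp at 0.
- Cumulative round-off at the top knot is pinned to exactly 1.

## Problem sizes

Default test and reproduction sizes: 96-stage dense ladders for
closed-form comparisons (interpolation error ≪ 0.5 %), 12 vs 48 stages for
convergence checks, 50 phantom seeds per aerosol for bias/spread estimates
(share bias < 0.05 points, max error < 1 point at default counts), 1000
Monte-Carlo replicates for the power check of the Bonferroni t, and the
3×2×3 default study for end-to-end runs. The whole suite runs in a few
seconds on one CPU.

## Known limitations

- Single static planar view: no anterior/posterior geometric mean, no
  scatter correction, no tomography. View (anterior vs posterior) is
  carried as metadata only and selects which calibration factors apply.
- The percentile GSD at 12-stage resolution is biased for broad aerosols
  (see above); use the fit estimator there.
- The micron-mode aerosol (AMAD 2.8 µm, σ_g 3.2) genuinely exceeds a
  0.007–10 µm ladder: ~14 % of its activity lies beyond 10 µm, so its
  reduced d84 reflects clamped tail mass. This is a property of the
  instrument range, not of the reduction.
- Stomach/swallowed activity, when a STOMACH ROI is supplied, is
  quantified but excluded from the ET/TH balance.
- No mg/kg or surface-dose conversion; activities stay in MBq-equivalents.
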