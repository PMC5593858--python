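# Methods

## The calibration problem

A canopy water-content calibration relates per-sample reflectance spectra
R(λ) ∈ (0, 1], λ = 350…2500 nm at 1 nm, to gravimetric water-content fractions
W = (m₁ − m₂)/m₁ ∈ (0, 1). Water content is held internally as a fraction
everywhere; summary tables conventionally print means as percentages while
leaving standard deviations as fractions, so every report states its units and
conversion happens only at the formatting boundary.

## Spectral cleaning

Three closed wavelength windows — 1350–1410, 1820–1940 and 2390–2500 nm — are
removed before any other operation. They cover the strong atmospheric
water-vapour absorptions and the long-wave detector edge, where field spectra
carry noise that no smoothing rescues. Removal is by closed interval (both
endpoints dropped), the conservative reading of a printed range. The surviving
columns form contiguous *segments* (three of them on the full default grid,
since the last window reaches the grid end) and every subsequent windowed
operation — smoothing, differencing — works strictly within a segment, never
across an excised gap.

Smoothing uses a 7-point weighted moving average with symmetric kernel
(0.15, 0.15, 0.15, 0.10, 0.15, 0.15, 0.15) over offsets −3…+3. The centre
weight 0.10 makes the weights sum to one exactly, the unique symmetric reading
consistent with a 7-point window. Within three points of a segment edge the
kernel is truncated to the available window and renormalised to unit sum —
chosen over dropping edge points so grid length is stable for the later
differencing. The implementation accumulates weighted neighbour *differences*
(out = x + Σ wₖ(xₖ − x)/Wᵢ), mathematically the renormalised weighted mean but
with the useful numerical property that a constant series passes through
bit-identically.

## Transforms

The absorbance-like transform log₁₀(1/R) converts a per-sample multiplicative
illumination factor c·R into the additive offset −log₁₀c; the per-segment
first derivative then removes that offset exactly, along with any baseline
component constant in the log domain. These two cancellations are the entire
motivation for the chain and are enforced by tests to ~10⁻¹² (machine
precision for values of this scale; exact bit-identity is not attainable in
floating point because logarithm and subtraction round differently on scaled
inputs).

Numerical choices, where convention rather than necessity decides:

* **Log base** — base 10 (spectroscopy convention for "log of the
  reciprocal"). The base only rescales derivatives uniformly; correlations and
  selected wavelengths are base-invariant.
* **Derivative scheme** — forward first difference on the 1 nm grid, exactly
  linear and cheap; a central-difference variant is available via
  `scheme="central"`. Each segment loses its final point; a difference is
  labelled by its left endpoint, so "the value at 760 nm" is the difference
  between the 760 and 761 nm log-reciprocal values. Segments too short to
  difference are dropped with a warning.
* **Correlation** — Pearson, per wavelength, against water content; columns
  whose spread is at rounding level relative to their magnitude are reported
  as undefined (NaN) and excluded from selection.

Sensitive-wavelength selection is primarily user-specified: the canonical
quartet 760 nm (red edge), 821 nm (smooth NIR shoulder), 967 nm and 1174 nm
(water-absorption trough flanks) mixes correlation strength with
physiological criteria that no scan reproduces. A greedy fallback picks the k
largest |r| subject to a minimum pairwise separation, breaking ties toward the
shorter wavelength.

## Cross variables

Cross variables are elementwise products of the *transformed* (derivative of
log-reciprocal) values at two wavelengths — not of raw reflectance. The
dimensional argument fixes this choice: fitted coefficients of order 10⁵–10⁶
against a response near 0.5 are only consistent with products of
derivative-scale values (~10⁻³ each, products ~10⁻⁷–10⁻⁶), not with products
of raw reflectance (~10⁻²–10⁻¹). For the canonical quartet, the six unordered
pairs are ordered Z₁=(760,821), Z₂=(760,967), Z₃=(821,967), Z₄=(821,1174),
Z₅=(967,1174), Z₆=(760,1174). All six always enter selection as candidates;
the stepwise procedure alone decides which survive.

## Partitioning

**Equidistant (systematic) sampling** sorts samples ascending by water content
(ties broken by original order), forms consecutive blocks of (ratio + 1), and
sends the block element at a fixed offset to validation; a leftover partial
block goes wholly to calibration. For n = 90 at ratio 4 this yields exactly
72/18, and every complete block contributes exactly one validation sample, so
the hold-out set interleaves the calibration set across the entire response
range. The default offset is the last block position — which places the global
maximum in the validation set, matching the convention that the validation
maximum equals the overall maximum — and a seeded random-start mode implements
the classic systematic-sampling variant. **Random sampling** holds out n_val
samples uniformly without replacement, reproducibly under a seed.

Split summaries report N, max, min, mean, sample SD (n − 1 denominator;
convention, as the source tables do not say) and CV = SD/mean. One published
consistency check fails as printed: the random-sampling validation row implies
CV = 100·0.091/0.536 = 17.0 %, not the printed 16.9 % — that row is excluded
from the arithmetic checks; the Total (16.6), Calibration (16.3) and
systematic-validation (17.6) rows all reproduce at 1 d.p.

## Stepwise regression

Selection alternates entry and removal moves. Entry: among candidates outside
the model the largest partial F (drop in residual SS from adding the
candidate, over the augmented model's residual mean square with n − l − 2 df)
enters if P < α_in. Removal: among members the smallest partial F (rise in
residual SS from deletion, over the full model's residual mean square with
n − l − 1 df) leaves while P > α_out. Both statistics equal the classic
nested-model F; the implementation literally performs the paired fits (SVD
least squares, never normal equations) and an oracle test asserts equality to
10⁻⁸ relative. Defaults α_in = α_out = 0.05; a fixed-critical-F mode exists
because some software is driven by F_in/F_out constants rather than P-values.

Degenerate cases are handled explicitly: a candidate inside the current span
contributes F = 0; a numerically exact fit (residual SS below 10⁻¹² of total
SS) caps F and stops further entries, since later tests would only compare
rounding noise; deleting the last variable returns to the intercept-only
model; an enter/remove cycle on the same variable terminates selection with a
warning, and a step budget (default 50) bounds the loop. Ties on F break
toward the lowest column index, and a shuffled-candidate test asserts the
selected set is order-invariant.

Model diagnosis follows the conventional rules: the overall F-test must reach
P ≤ 0.05 for the model to be flagged usable; per-variable partial F and P are
reported; the Durbin–Watson statistic Σ(eᵢ − eᵢ₋₁)²/Σeᵢ² is reported with a
1.5–2.5 comfort band for "no first-order residual autocorrelation".

## Metrics

RMSE = √(Σ(yᵢ − ŷᵢ)²/n), RE = (1/n)Σ|yᵢ − ŷᵢ|/|yᵢ|, and
R² = Σ(ŷᵢ − ȳ)²/Σ(yᵢ − ȳ)², all on the fraction scale. The R² ratio form is
implemented literally: on in-sample OLS predictions with an intercept it
equals 1 − SSE/SST (asserted numerically), but on held-out predictions the two
differ and the ratio can exceed 1 for biased predictions — it is reported
as-is, with the complement form available via `form="complement"`. Cross-model
comparisons use the percent difference 100·(a − b)/b, positive meaning the
first model exceeds the reference; metrics are rendered to 4 d.p. and percent
differences to 2 d.p.

## Synthetic data: what it emulates, and what it does not

The spectra generator draws water contents from a truncated normal (mean
0.525, SD 0.087, bounds [0.32, 0.753]) matching the summary moments of a
90-tree orchard campaign, a uniform mode being available. Spectra are a smooth
parametric vegetation template — green peak near 546 nm, red valley near
667 nm, sigmoid red edge to an NIR plateau, declining SWIR with local peaks
near 1660 and 2220 nm — attenuated by Beer–Lambert water-absorption troughs at
981, 1196, 1456, 1780 and 1950 nm whose absorbances grow linearly with water
content. The exponential attenuation form is both the physical choice
(absorbance proportional to absorber) and makes the log-domain water signal
exactly linear in W, so a noiseless campaign is exactly recoverable by the
pipeline — a useful end-to-end sanity limit. On top of the clean signal the
generator applies the two nuisances the transform chain exists to remove — a
per-sample illumination scale (±5 %) and an additive baseline line (offset
±0.01, slope ±1.5·10⁻⁵ per nm) — plus white noise of SD 0.0015 reflectance
units, a realistic post-averaging field-instrument level. At these defaults
the derivative-transformed values at the 967/1174 nm trough flanks correlate
with water content at |r| ≈ 0.6, the strength a field campaign reports for its
sensitive bands.

The generator is deliberately not a radiative-transfer model: it has no leaf
or canopy structure parameters, no atmospheric water-vapour coupling (the
excised bands are noisy only through the generic white-noise term), and
samples are i.i.d. — real campaigns have within-orchard correlation the
analysis also ignores. Passing tests therefore demonstrate that the pipeline
recovers what this structural model plants, not that the fitted coefficients
transfer to any particular orchard.

The cross-variable-level generator draws the six Z columns from a one-factor
model (pairwise correlation 0.3 — moderate, as products sharing a wavelength
are correlated in real data) with means ~3–4·10⁻⁷ and dispersions ~10⁻⁷, and
builds Y = 0.4613 − 480610.4213·Z₂ − 552189.0450·Z₅ − 1006181.8358·Z₆ + ε by
default. The dispersions of the three active columns are set inversely
proportional to their coefficient magnitudes so each term contributes equally
to the response: in the published models all three retained variables are
decisively significant, and a generator in which one of them hovered at the
detection edge would not mimic data on which stepwise credibly retained it.
The noise SD is derived from a target signal-to-total variance ratio (default
0.7, the calibration-R² scale of such campaigns) through the factor-model
covariance; a fixed noise SD can be passed instead. Under these conditions
stepwise recovers the exact active set in ~85 % of replicates; the ceiling is
set by the family-wise false-entry rate of forward selection at α = 0.05
(~15 % with three inert candidates), not by missed actives.

## Problem sizes used in simulations

Stochastic properties are checked at the sizes the method is designed around:
90-sample campaigns split 72/18; 200 replicates for active-set recovery; 500+
replicates for the split-balance and hold-out-error comparisons (the
validation-RMSE difference between the two split methods is small relative to
its replicate spread, so several hundred replicates are needed for a stable
sign); 100 random instances for the partial-F oracle; 1000 seeds for the
random-split uniformity check.

## Known limitations

* Sensitive-wavelength auto-selection is a fallback; the canonical quartet is
  a judgment call no correlation scan fully reproduces.
* The equidistant offset convention changes which samples are held out;
  results are reported for the default (last position) and the choice is
  configurable rather than optimised.
* R² in ratio form can exceed 1 off-sample; consumers comparing models should
  use one form consistently.
* The generator's SWIR tail beyond ~2300 nm is brighter than real vegetation;
  immaterial here because the 2390–2500 nm band is excised, but worth fixing
  before using the template for other purposes.
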