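# Methods

## Model and assumptions

The enhancement treats a radiograph `I(x, y)` as primary (diagnostic)
signal plus a smooth scatter background, and estimates that background
with a spatially varying low-pass kernel whose shape follows the local
attenuation. Two kernel families are provided:

- **Cream (exponential)** `F₁ ∝ exp(−μ r)`, `r = √(i² + j² + d²)`:
  models the short-range, roughly exponential decay of scattered photon
  intensity with distance, appropriate where dense/thick tissue produces
  localized scatter.
- **Bosso (Gaussian)** `F₂ ∝ exp(−s (i² + j² + d²))`: models diffuse,
  low-frequency scatter and system blur. Under unit-sum normalisation the
  constant factor `exp(−s d²)` cancels, so the *normalised* Bosso kernel
  depends only on `s`; `d` still acts through the per-pixel estimate of
  `s` itself.

Both shape parameters are estimated per pixel by inverse attenuation,
`param = −(1/d) · ln(clamp(I/I₀, ε, 1))`: a pixel that attenuated the
beam strongly (dark) is assumed to sit under thick tissue with strong
local scatter and gets a peaked kernel; a bright pixel gets a nearly
uniform one. The same formula serves both `μ` and `s`; no separate
texture-adaptive estimator is defined, so the two filters differ only in
their kernel family.

Assumptions inherited from this model: degradation is dominated by
*additive* scatter (not blur of the primary), so the enhanced image is the
positive residual `I − I_s` clipped at zero and never exceeds the input;
the incident beam is spatially uniform, so a single scalar `I₀` (image
maximum by default) is meaningful; and attenuation is monochromatic
Beer–Lambert, with `d`, `i`, `j` all dimensionless. No physically
calibrated attenuation coefficients or energy dependence are modelled.

## Parameters

| parameter | meaning | default | rationale |
|---|---|---|---|
| `d` | effective propagation distance (dimensionless); scales both `r` and the estimator | 1.4 | centre of the useful range; the sweep module exists to choose it per image class |
| `h` | window half-width; kernel is `(2h+1)²` | 3 (7×7) | balances detail enhancement vs noise suppression at radiographic pixel pitches |
| `I₀` | reference incident intensity | image maximum | brightest pixel ≈ unattenuated beam; overridable for cropped or saturated images |
| `ε` | ratio floor in the estimator | 1e−6 | keeps `ln` finite at zero-intensity pixels while bounding `param` by `−ln(ε)/d` |
| padding | border handling for the window | symmetric reflection | no intensity invented at borders; residual stays unbiased near edges |

Metric conventions: contrast is span-to-mean `(max − min)/mean` (the
convention used in the radiography-enhancement literature that motivated
this package, which sometimes labels it "Michelson"; classical Michelson
is `(max − min)/(max + min)` and is *not* what is computed). Entropy uses
256 bins over the **nominal** bit-depth range rather than the empirical
min–max, so values are comparable across `d`; published entropy tables
from other pipelines may use a different, unstated normalisation and are
not directly comparable in absolute value — the analytics here only ever
use entropy *ratios* between adjacent grid points. SSIM uses the standard
Gaussian-weighted 11×11 window, σ = 1.5, K₁ = 0.01, K₂ = 0.03. SNR
requires an explicit noise variance, a reference image, or a flat-region
mask; there is no blind estimator.

## Numerical choices

- The convolution is evaluated as a direct per-pixel weighted sum (the
  kernels vary by pixel, so FFT factorisation does not apply), vectorised
  as an `(H, W, 49)` tensor contraction. The sum is taken relative to the
  window's centre value, which makes locally constant windows exact fixed
  points (no 1-ulp normalisation drift), so constant images enhance to an
  exactly zero residual.
- The kernel at pixel `(x, y)` uses the parameter estimated from that
  pixel's own intensity (centre-pixel convention). The formula's summand
  `I(x−i, y−j) F(i, j)` equals the direct correlation because the kernels
  are symmetric under sign flips of the offsets.
- Zero-mean images make contrast undefined; this is raised/flagged (NaN in
  sweep tables), never silently reported as 0. Identical images give
  infinite PSNR, signalled as `inf`.
- Curve analytics tie-breaks all favour smaller `d` (less aggressive
  filtering). The crossover detector returns the *final* dominance onset
  (smallest grid point from which the Cream curve strictly exceeds the
  Bosso curve through the end of the grid), because measured sweep tables
  show transient early crossings that are later undone; the optimal-`d`
  selector judges each grid point `k ≥ 1` by its relative entropy step
  from the previous point (`|ΔH|/H_prev ≤ tol`, default 2 %) — the first
  grid point has no step and is not a candidate, so a zero tolerance with
  drifting entropy is infeasible rather than trivially satisfied.
- The elbow detector maximises the absolute discrete second difference of
  the contrast column. It is a generic curvature statistic; a clinical
  operating point additionally weighs reader preference, which no curve
  statistic captures.
- The optional `enhance_sequential` cascade (Cream residual fed into the
  Bosso stage) is an exploratory extra behind an explicit flag; the
  standard evaluation applies the two filters independently and compares
  them. The second stage reuses the first input's `I₀` so a small
  residual maximum cannot inflate the parameter estimates.

## Synthetic phantoms

The phantom generator emulates exactly the degradations the filters
address: Beer–Lambert projection of overlapping-ellipse thickness maps
(`I_p = I₀ e^{−T}`), additive scatter as `k ·` (Gaussian-blurred primary)
with fraction `k = 0.3` and blur σ = 12 px by default, then Poisson noise
on the detected signal and rounding to the bit depth. Presets sketch the
geometry of the anatomies of interest — knee (two long bones, joint gap,
condyles, patella), wrist (radius/ulna, carpals, metacarpals), breast
(low-contrast blobs plus point microcalcifications) — at thickness
products giving realistic 8-bit attenuation spans (bone interiors around
35–60 of 255). They are deliberately simple: no Monte-Carlo photon
transport, no energy spectra, no anatomical texture, no detector MTF.
Passing the recovery tests on these phantoms therefore demonstrates that
the pipeline removes an additive smooth background under quantum noise —
the mechanism the method claims — not that it improves any particular
clinical image class.

Default study conditions for the recovery checks: 256×256 knee preset,
`k = 0.3`, σ = 12, Poisson noise, seed 42; enhancement must raise
span-to-mean contrast over the degraded input at every
`d ∈ {0.2, 0.4, …, 3.0}` for both filters. These sizes keep the whole
suite and the acceptance script fast while leaving ≥ 4 scatter lengths
inside the field of view.

## Bundled data

Three measured contrast/entropy sweep tables (knee, breast and wrist
radiograph series; 15–20 `d` grid points each) and one expert
Likert-rating table (three readers, 1–5 scale, 32 image/d rows, one
blank pair) are shipped as CSV under `creambosso/data/`. They serve as
worked inputs for the *analytics* (crossover, optimal-`d`, elbow, rating
aggregation) — the images behind them are clinical and not
redistributable, so the enhancement stages themselves are validated on
phantoms and against a brute-force reference instead.

The rating aggregate implements the d-weighted form
`Σ cᵢ dᵢ / Σ dᵢ` verbatim. Note this is a weighted mean *rating* (it
returns `c` for constant ratings), not a mean `d`; the alternative
reading `Σ cᵢ dᵢ / Σ cᵢ`, which *is* a mean `d`, is available as
`mode="rating-weighted"`. Neither reading reproduces previously published
summary values for this table, so none are asserted.

## Known limitations

- The residual output is a scatter-corrected *structure* image, not a
  display-ready radiograph; its span-to-mean contrast is not comparable
  with the input's (the mean collapses). Compare enhanced images with
  each other.
- `I₀ =` image maximum is brittle when the field of view contains no
  unattenuated region or contains saturated artefacts; pass an explicit
  `i0` then.
- A single global `d` per run: no per-region adaptation.
- Entropy values depend on the binning convention (see above) and should
  be compared only within one pipeline.
- CLAHE and SSIM are delegated to scikit-image; Cohen's kappa is computed
  from the exact marginal formula and cross-checked against scikit-learn
  in the test suite.
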