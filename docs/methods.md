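# Methods

This document gives a complete account of the models, the synthetic-image
generator, all fixed parameters, and the numerical conventions used
throughout `kidneystrip`. All generator and model parameters were fixed up
front from the study design and from qualitative properties of colorimetric
creatinine assays; none were tuned against downstream metric values.

## 1. Study design

### 1.1 Concentration grid

The default grid covers 0–60 mg/dL serum creatinine (S_Cr) with density
matched to where the colorimetric response changes fastest:

| range (mg/dL) | step | concentrations |
|---|---|---|
| 0.0 – 4.0 | 0.1 | 41 |
| 4.5 – 7.5 | 0.5 | 7 |
| 8.0 – 19.0 | 1.0 | 12 |
| 20.0 – 60.0 | 10.0 | 5 |

Total: 65 concentrations. With 3 replicates and 4 development time points
(0, 2, 12, 22 minutes) the design yields 65 × 3 × 4 = 780 captures, and
after tiling 3120 tiles. `build_concentration_grid` validates any custom
grid: ranges must be non-overlapping, ascending, with positive steps;
endpoints are rounded to 9 decimals to keep the grid exact under binary
floating point.

### 1.2 Demographics

Each capture is assigned one synthetic subject drawn from census-derived
marginals, sampled independently per capture:

* age bands (probability): 1–4 (0.061), 5–24 (0.256), 25–44 (0.265),
  45–64 (0.254), 65–84 (0.146), 85–99 (0.018). Age is drawn uniformly
  (integer) within the band. The lowest band starts at 1 year because the
  eGFR equation used here requires a positive age and is not defined for
  infants under one year.
* female with probability 0.510;
* African-born with probability 0.134.

Age, sex and African-born status are sampled independently (marginals only —
no joint structure).

## 2. Synthetic image generator

`render_strip_image` is a statistical stand-in for lightbox photographs of a
reagent strip's detection zone — not a physical model of Jaffe reaction
kinetics or camera optics.

### 2.1 Geometry

Each capture is a 256 × 128 RGB image. The central 160 × 80 region carries
the uniform reaction color; the border is a dark background (RGB 25, 22, 20)
emulating the imaging enclosure. Preprocessing center-crops to 128 × 64 —
comfortably inside the reaction zone at low noise — and splits into four
64 × 32 quadrant tiles (top-left, top-right, bottom-left, bottom-right).

### 2.2 Color law

The reaction color is an HSV interpolation between a pre-reaction cream,
(H, S, V) = (68°, 0.68, 0.965), and a saturated reddish-orange end point,
(32°, 0.98, 0.935), mimicking the cream → yellow → orange progression of a
Jaffe-like chromogen. The interpolation progress is

    p = T(t) · c / (c + K_SAT)

where `c` is the concentration in mg/dL, `K_SAT = 4.0` mg/dL is the
half-saturation constant, and `T(t)` is the development-time factor:
T(0) = 0, T(2) = 0.55, T(12) = 0.85, T(22) = 1.0.

Rationale for the fixed values:

* **K_SAT = 4.0 mg/dL** places the steepest part of the saturating response
  over the densely sampled 0–4 mg/dL portion of the grid, which is also the
  clinically relevant range; by 60 mg/dL the response has essentially
  saturated (p ≈ 0.94 · T(t)), reproducing the hard-to-resolve high end.
* **T(0) = 0** makes the 0-minute capture show the pre-reaction color for
  every concentration, so early time points carry genuinely less signal.
* The hue span (68° → 32°) keeps every rendered color inside the default
  HSV mask's hue window (20–60 on the 0–255 scale ≈ 28°–85°) except under
  extreme noise, so masking removes the background but retains ≥ 95% of the
  reaction zone at all concentrations (verified empirically on the default
  grid).

The law is strictly monotone in concentration at fixed t > 0 and injective
before noise, so concentration is in principle recoverable from color.

### 2.3 Noise model

Two additive Gaussian components, both on the 0–255 intensity scale:

* per-pixel sensor noise, σ = 3.0 (`noise_sigma`), independent across
  pixels and channels;
* per-capture scalar illumination offset, σ = 2.0 (`illum_sigma`), one draw
  shared by every pixel of a capture — emulating exposure drift between
  photographs.

Pixels are clipped to [0, 255] after noise. Both σ values are moderate
relative to the ~0.15 hue-degree minimum step between adjacent grid
concentrations at 22 minutes: fine discrimination is noisy at the tile
level, but not hopeless, which is what makes the partitioned model's
advantage measurable.

### 2.4 What the generator does not emulate

Perspective and lens distortion, specular highlights, spatial gradients of
reaction progress across the pad, chemical interferents, strip-to-strip
manufacturing variation, JPEG artifacts, and any correlation between subject
demographics and concentration. Severity labels come from the *true*
concentration and the sampled subject, so label noise is zero by
construction.

## 3. Imaging conventions

* **Pixel storage.** Images are float64 on the 0–255 scale end to end;
  quantization to uint8 happens only at the PNG boundary. This keeps color
  space round-trips within 8-bit quantization error (≤ 2 intensity levels)
  and makes masking/feature extraction exact.
* **Channel ranges.** Every color space is affinely remapped to 0–255 per
  channel from its native range (HSV hue 0–360°, LAB L 0–100 and a,b ±127,
  YCrCb Y 16–235 and Cr,Cb 16–240, channel order Y, Cr, Cb). The remap is
  the affine map `x ↦ (x − s_min)(t_max − t_min)/(s_max − s_min) + t_min`;
  a degenerate source range raises `DomainError`.
* **HSV mask.** Inclusive triple range test H ∈ [20, 60], S ∈ [150, 255],
  V ∈ [230, 255] on the remapped 0–255 scale. An alternative
  `hue_convention="deg179"` interprets the hue bounds on the half-degree
  0–179 scale used by some imaging libraries. Masking updates only the
  boolean mask (ANDed with any existing mask); pixel values are never
  modified, so masking is idempotent and order-independent with cropping.
* **Cropping and tiling.** Center crop uses floor offsets
  `(H − h)//2, (W − w)//2`; tiling requires even dimensions and returns the
  four quadrants in reading order.
* **Convolution.** `convolve_channel` is discrete 2-D convolution
  `I'(x,y) = Σ_s Σ_t h(s,t) · I(x−s, y−t)` with zero padding and odd kernel
  dimensions, delegated to `scipy.signal.convolve2d(mode="same")` and
  verified against a quadruple-loop oracle in the tests.

## 4. Features

* **HOC (histogram of colors).** Per channel, counts over half-open
  unit-width bins `[b, b+1)` spanning `[0, 255)`; the default is 255 bins ×
  3 channels = 765 features. Values outside a channel's configured range
  (and masked-out pixels) are dropped. With `normalize=True` (default) each
  channel's histogram is divided by the number of valid pixels, making
  features comparable across tiles with different mask coverage. A fully
  masked tile with normalization raises `DegenerateInputError` rather than
  silently yielding zeros.
* **Masked-range HOC preset.** `HOCConfig.masked_range_hsv()` restricts the
  histograms to the mask's own HSV ranges with unit-width bins: 40 + 105 +
  25 = 170 features.
* **Pixel features.** Channel-major flattening of a 64 × 32 tile = 6144
  features; masked pixels are zeroed.
* **Default feature space** is HOC over LAB: LAB separates lightness from
  chromaticity, which decouples the illumination offset (mostly L) from the
  reaction color (mostly a, b).

## 5. The SPR model

* **Binning convention.** Bin k is `[e_k, e_{k+1})`, except the last bin,
  which is closed at the top edge so the maximum concentration belongs to a
  bin. Concentrations outside `[e_0, e_χ]` raise `DomainError`.
* **Default partition.** Edges (0, 4, 7.5, 19, 60) mg/dL, i.e. the grid's
  own density breakpoints — the natural partition of the design.
* **Phase 1** is trained on (features, bin index); it is skipped entirely
  when χ = 1, where `predict_bin` returns zeros and the model is bitwise
  identical to the matched global regressor.
* **Phase 2** trains one regressor per bin on that bin's samples only. An
  empty bin is a configuration/data mismatch and raises `FitError` naming
  the offending bin, rather than silently fitting a constant.
* **Matched families by default.** Unless overridden, the phase-2 regressor
  family equals the phase-1 classifier family, so "SPR vs global" comparisons
  isolate the effect of partitioning from the effect of the estimator class.
* **Clamping** of predictions to the partition span is available but **off
  by default**: out-of-range predictions are informative during evaluation,
  and clamping would silently mask regressor pathologies.
* **Determinism.** All estimators are constructed with an explicit
  `random_state` and single-threaded (`n_jobs=1`) where the library exposes
  parallelism, so fits are reproducible.

## 6. eGFR and severity

The eGFR (mL/min/1.73 m²) is

    eGFR = 175 · S_Cr^−1.154 · age^−0.203 · (0.742 if female) · (1.212 if African-born)

Conventions:

* S_Cr must be positive; with `floor=True`, values below 0.1 mg/dL are
  floored to 0.1 before evaluation. This exists solely so the 0 mg/dL
  *blank* strips of the study design receive a severity label (a true zero
  has no defined eGFR); 0.1 mg/dL is below any physiological creatinine, so
  the blank maps to the healthiest attainable class for every subject.
* Severity thresholds: **healthy** iff eGFR ≥ 60 (boundary inclusive),
  **critical** iff eGFR < 15 (boundary exclusive, 15 is intermediate),
  **intermediate** otherwise.

## 7. Evaluation protocol

* **Cross-validation**: `StratifiedGroupKFold` with severity as the
  stratification label and capture id as the group, so the four tiles of a
  photograph never straddle a train/test split (tile leakage would inflate
  scores). If any severity class has fewer captures than folds,
  `StratificationError` is raised instead of producing degenerate folds.
* **Repeated experiments** (default N = 10): each experiment redraws the
  subject population (one subject per capture), recomputes severity labels,
  re-splits, refits and rescores. This propagates demographic sampling
  variability into the reported spread.
* **Metrics**: weighted F1 over the three severity classes (weighted is the
  default because class prevalence is highly unbalanced under the census
  population); concentration RMSE in mg/dL; decision score
  `α·F1 + (1−α)/RMSE` with α = 0.75. A fold with RMSE = 0 (possible only
  for a perfect oracle) is scored +∞ internally so rankings still sort.
* **Default time point**: 22 minutes — the fully developed color, i.e. the
  intended reading time; earlier time points carry attenuated signal by
  construction (section 2.2) and can be selected explicitly.
* **Seeding**: one master seed feeds a `numpy.random.SeedSequence`; per
  experiment, per population draw and per fit, child seeds are spawned.
  Identical master seeds reproduce every number, including the byte content
  of `ranking.csv` (timing columns are kept out of that file for exactly
  this reason).

## 8. Numerical choices, summarized

| choice | value | why |
|---|---|---|
| pixel dtype | float64, 0–255 | exact preprocessing, uint8 only at PNG I/O |
| histogram bins | half-open `[b, b+1)` | every integer level counted once |
| last SPR bin | closed at top edge | max concentration must belong to a bin |
| empty bin | `FitError` | silent constant fits would corrupt comparisons |
| clamp | off by default | out-of-range predictions are diagnostic |
| F1 averaging | weighted | strongly unbalanced severity prevalence |
| eGFR floor | ε = 0.1 mg/dL, opt-in | label the blank without redefining eGFR |
| CV grouping | by capture | prevent tile leakage |
| RMSE = 0 decision | +∞ internally | keep rankings totally ordered |

## 9. Limitations

The synthetic generator supports controlled, reproducible experiments on the
*pipeline* — masking, features, partitioned regression, evaluation — but
conclusions about absolute accuracy do not transfer to real strip
photographs: the flat-zone color law, independent Gaussian noise and
zero label noise are all optimistic simplifications. The demographic sampler
reproduces marginals only, and the eGFR equation embeds its published
demographic coefficients; both should be revisited before any use beyond
benchmarking. The grid's sparse high end (10 mg/dL steps above 20) means
high-range RMSE is dominated by a handful of support points.
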