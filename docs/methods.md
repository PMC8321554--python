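# Methods

This note records the models, estimators and numerical choices behind
`patchdyn`, and what its validation does and does not establish.

## The measurement problem

Presynaptic actin assembles in transient, sub-micron patches. Two
complementary read-outs are implemented: particle tracking (detect → link →
filter → per-track statistics) and a tracking-free per-pixel coefficient of
variation (CoV) over time. Both are validated on synthetic movies whose
generative parameters are known exactly, because for in-vivo data no ground
truth exists: a tracker's acceptance rate there can only be bounded, not
measured.

## Spot detection

Candidates are local maxima of the scale-normalized LoG response
`R = −σ²∇²(G_σ * I)` with `σ = d/(2√2)` (d = 0.6 µm, the standard
blob-radius relation), computed with a wide kernel truncation (8σ) so the
kernel's DC leakage stays below floating-point noise and flat regions
yield no candidates. Sub-pixel positions come from a per-axis parabolic fit
on the 3×3 response neighbourhood (offsets clamped to ±0.5 px).

Retention combines three rules:

1. **Probe-mean intensity rule.** A spot's raw peak intensity must reach
   `threshold_factor × probe mean` (default 0.32), where the probe mean is
   the movie-wide mean masked intensity — one global threshold per movie.
   A config switch (`threshold_on: quality`) applies the same factor to the
   LoG response instead, since legacy trackers threshold a quality feature;
   intensity is the default reading.
2. **Extension floor.** The response must exceed `k_ext` robust noise SDs
   (default 3), with the noise SD estimated as 1.4826×MAD of the response
   over the *eroded* mask interior — the boundary band carries the
   baseline's step-edge response, which is structure, not noise, and
   inflates a naive estimate several-fold.
3. **Track seed floor (hysteresis).** After linking, a track is kept only
   if at least one of its spots exceeds `k_seed` noise SDs (default 6).
   A single per-spot floor cannot do both jobs: at 3 SD, noise maxima are
   dense enough to chain into spurious multi-frame tracks; at 6 SD, the dim
   rise-and-fall tails of real patches are lost and short patches fragment
   below the 4-detection acceptance floor. Hysteresis keeps the dim tails
   while the seed requirement removes noise chains — on event-free default
   movies the false accepted-track rate is zero.

## Linking and filtering

Per consecutive frame pair, links minimize
`Σ d² + b·(#unmatched)` with the no-link alternative `b` just above the
0.5 µm² squared linking limit, solved as a single linear assignment over an
augmented matrix. This prefers every feasible link and minimizes total
squared displacement — verified against exhaustive enumeration over all
partial matchings for up to 4 spots per frame. No gap closing (a one-frame
dropout terminates a track), no splitting or merging.

Filtering rejects tracks with < 4 detections (`too_short`) and resolves
path overlap: when two concurrent tracks ever come within the linking
distance, the shorter (tie → lower mean LoG quality) is rejected
(`overlap`); rejecting both is available by config. The rejection census is
retained because the merged-frequency upper bound re-adds every rejected
track.

## Patch statistics

- **Duration** uses the spot-count convention `n_spots × Δt` — the only
  convention consistent with a 16 s floor / 356 s ceiling for 4–89
  detections at Δt = 4 s and 4 s / 139 s at Δt = 1 s.
- **Censoring.** Tracks touching the first or last frame have truncated
  durations; they count toward frequency but are excluded from duration
  histograms and means, which the truncation would bias downward.
- **Histogram** bins are half-open `[0,20), [20,40), …` s with centres
  reported at 10, 30, … s.
- **Merged two-rate estimate.** With duration censuses from a 0.25 Hz and
  a 1 Hz regime expressed in events/10 µm²/min, the merged value averages
  the two frequencies over the shared detectable range [20, 150) s and adds
  the regime-specific brackets: [4, 20) s from 1 Hz (the 16–20 s sliver
  between the 0.25 Hz floor and the shared range is carried here) and
  [150, 360) s from 0.25 Hz. The accepted-track value is the lower bound;
  the upper bound recomputes the same brackets with all rejected tracks
  included (at their measured durations) plus any rejected mass falling
  outside a regime's detectable brackets. The estimator works on duration
  lists, not on the 20 s histogram, because 150 s is not a bin edge.

## CoV analysis

Per masked pixel, CoV = population SD over time / mean over time (ddof = 0,
a documented constant; immaterial at ≥ 80 frames but fixed for exactness).
Pixels with non-positive temporal mean get CoV 0 and are flagged and
excluded from the mean. Thresholds are computed per movie on the pooled
masked CoV values, using 256-bin histograms spanning the data range:

- **Li** (minimum cross-entropy): the criterion is scanned exhaustively
  over all cut points — the classic fixed-point iteration alone can stall
  in a secondary minimum on multimodal histograms — then the Li–Tam update
  refines the cut to sub-bin precision when it stays within the minimizing
  bin. Empty bins between modes make the criterion exactly flat, so the
  deterministic convention is the middle of the minimal plateau.
- **Moments** (Tsai): the closed-form three-moment-preserving fraction,
  converted to a threshold by a cumulative-histogram percentile lookup.

Both are tested against independent oracles (criterion scan; numerical
solution of the moment equations) and both variant-area fractions are
always reported — the two algorithms genuinely differ on skewed data.

## Synthetic movies

The generator emulates the study conditions: a chain of disc-shaped boutons
(default 3 × r = 2 µm ≈ 35 µm², 0.13 µm/px) with a diffuse baseline
(default 100 counts) blurred by 0.5 µm (PSF/out-of-focus scale — a
hard-edged baseline would put a strong static LoG ridge at the mask
boundary that real optics never produce); Poisson patch events at
`f` events/10 µm²/min (default 6) placed uniformly in the mask and in time;
lognormal durations (mean 48 s, SD 45.6 s) rounded to ≥ 1 frame and clipped
at the movie end; an isotropic Gaussian spatial profile (σ = 0.255 µm ≈
0.6 µm FWHM / 2.355); Poisson shot noise, Gaussian read noise (σ = 4), and
optional exponential photobleaching (default off; it exists to emulate the
1 Hz regime's caveat).

**Temporal profile.** Events rise and fall as a raised-cosine (Hann) bump
by default; `rect` is available and is used in duration-truth tests. The
smooth profile is essential for realism of the amplitude metric: a
rectangular event has constant tracked peak intensity, so its relative
amplitude is ~0 regardless of contrast, while real patches show ~68%. The
ground-truth duration of a smooth event is the support of its profile; its
*detectable* lifetime is shorter (the tails sit below the detection floor),
which the validation accounts for explicitly (below).

**Amplitude default.** `amplitude_ratio` (peak added intensity as a
multiple of baseline) defaults to 1.9, calibrated once so that tracked
patches under the default imaging conditions show a mean relative amplitude
near the ~0.68 typical of in-vivo patches; the underlying event contrast is
not observable in vivo, only the tracked amplitude is.

**Pixel-flicker mode** replaces spatial events with an exact fraction `p`
of mask pixels blinking independently (Poisson streams of square-wave
events whose union is "on", started before frame 0 so the process is
approximately stationary). It is the ground-truth model for the
variant-area fraction: with well-behaved duty cycles the Li fraction
recovers `p` to within a few percent of area.

**What the generator does not emulate:** patch motion (events are static),
active-zone substructure, 3-D PSF effects, spatially varying background,
or probe-specific photophysics. Passing validation therefore shows the
estimators are correct for temporally transient, spatially stationary
events on a diffuse baseline — not that tracking parameters are optimal
for any particular microscope.

## Parameter-recovery validation

Twenty seeded movies at the default conditions are pushed through the full
pipeline (mask from the blurred time-max projection via Otsu; detection,
linking, filtering as above). The recovered event count is
`accepted + overlap-rejected + n_subfloor`, where `n_subfloor` counts
ground-truth events undetectable in principle: fewer than 4 frames with
rendered LoG quality above the extension floor, or a peak never clearing
the seed floor — computed from the forward model (event amplitude, profile
weights, the movie's measured noise SD), never from per-event detection
outcomes. For rectangular events this reduces to the literal duration
floor `n_frames < 4`. Typical result: recovered frequency ≈ 0.87–0.90 of
the generated rate (the residual deficit is concurrent events closer than
~2 spot σ, which render as a single LoG maximum and are irrecoverable by
any single-particle linker), mean accepted duration ≈ 42 s for a generated
48 s mean, mean relative amplitude ≈ 0.70.

## CoV-to-frequency calibration

The curve simulates `n_reps` movies per frequency multiplier from a base
spec matched to the experiment's imaging regime (for the genotype
comparison: 1 Hz, 240-frame movies), records the statistic (default:
mean CoV; variant fractions by config), and fits isotonic regression
followed by piecewise-linear interpolation; a tied (non-strict) fit raises
an error, signalling a noise-dominated base spec. Inversion of two
statistics gives `100×(m_test/m_control − 1)`.

Two coupled-simulation designs reduce Monte-Carlo variance without changing
any marginal distribution:

- **Nested thinning** within each curve replicate: one master event stream
  is drawn at the largest multiplier and thinned per multiplier with
  independent uniform marks, so each grid point is exactly Poisson at its
  rate but shares randomness across the grid.
- **Paired evaluation**: each control/test pair shares its base event
  stream, with the test movie receiving an independent extra stream at
  `(m−1)f` (Poisson superposition), so the test group's frequency is
  exactly `m×` the control's.

With 10 replicates × 6 multipliers and 12 evaluation pairs, a generated
+43% change is inferred as +41 ± 4 percentage points across master seeds
(uncoupled designs gave ±10, occasionally outside a ±15 band).

## FRAP and colocalization

FRAP traces are double-normalized, `N(t) = [(bleach−bg)/(ref−bg)] /
prebleach mean`, which exactly cancels any multiplicative decay shared by
the bleached and reference ROIs. Recovery is fitted post-bleach as
`N(t) = N0 + (M−N0)(1−e^{−(t−t0)/τ})` with bounded least squares; mobile
fraction `(M−N0)/(1−N0)`. Fits with τ at a bound or no bleach depth are
flagged, never silently returned; a flat post-bleach curve reports mobile
fraction 0 with τ marked unidentifiable. The single-exponential model is
the default (and currently only) recovery model. Colocalization is the
Pearson correlation of voxel pairs within a 2-D/3-D mask, invariant to
per-channel affine intensity transforms; rolling-ball background
subtraction (radius 50 px) is applied upstream.

## Numerical and design notes

- All randomness flows from integer seeds through `numpy` `SeedSequence`;
  identical config + inputs give byte-identical outputs.
- Registration is translation-only (fixed specimen), estimated by
  upsampled cross-correlation against frame 0, clamped at a configured
  maximum shift, applied with linear interpolation and median fill.
- The rolling-ball background is bounded by the input, maps flat images to
  zero, and preserves features much smaller than the ball; exact
  equivalence with any legacy implementation is not promised.
- The presynaptic mask is computed once from the time-max projection —
  patch events must not move the mask, since frequency normalization needs
  one stable area. Blur sigma (default 2 px) is a config knob, as mask
  settings are tuned per experiment in practice.
- Whether CoV runs on raw registered or background-subtracted movies is a
  config switch (default: raw registered).
- Group comparison reports `100×(mean_test/mean_control − 1)` on group
  means plus the raw per-movie table; hypothesis testing is deliberately
  left to downstream statistical software.

## Known limitations

- Frequency recovery is bounded (~±10–15%) by blob merging at high event
  density; the merged/corrected estimator brackets, but cannot remove,
  this bias.
- The Moments threshold characteristically cuts zero-inflated histograms
  higher than Li; on mask-generation tasks it trims dim rims (its
  geometry-recovery bound is looser in the tests for this reason).
- Calibration curves are regime-specific: a curve built at one frame
  interval, movie length or noise level is never reused across regimes.
- Durations are not treated with survival analysis; censored tracks are
  simply excluded from duration summaries.
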