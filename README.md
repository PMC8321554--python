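# patchdyn

Quantification of discrete presynaptic **actin patch** dynamics from
fluorescence timelapse movies of neuromuscular junctions (NMJs).

Genetically encoded F-actin reporters (GMA, Lifeact, GFP::actin) label
transient, ~0.6 µm foci of actin assembly at the presynaptic membrane.
`patchdyn` turns registered timelapse movies of these probes into the
field's standard per-synapse statistics, and provides the synthetic-movie
machinery needed to validate every step against known ground truth.

## What it computes

**Particle-based metrics.** Spots are detected per frame as local maxima of
a scale-normalized Laplacian-of-Gaussian response at σ = d/(2√2) for an
estimated patch diameter d = 0.6 µm, localized to sub-pixel precision, and
retained when the raw peak intensity exceeds 0.32× the mean probe intensity
in the presynaptic mask. Frame-to-frame linking is a global linear
assignment minimizing summed squared displacement with a 0.5 µm limit and
no gap closing; tracks shorter than 4 detections or overlapping a
concurrent neighbour's path are rejected (with the rejection census kept).
Per movie this yields

- patch **frequency** `n / (A/10 µm²) / minutes` (events / 10 µm² / min),
- patch **duration** `n_spots × Δt` (so at Δt = 4 s the observable range is
  16–356 s for an 89-frame movie, and 4–139 s at 1 Hz), binned in 20 s bins,
- **relative amplitude** `(I_max − I_min) / I_mean` of each track's
  per-frame peak intensities,
- a **merged two-rate frequency estimate**: movies sampled at 0.25 Hz and
  1 Hz see complementary duration ranges, so the shared range (20–150 s) is
  averaged and each rate contributes the durations only it can observe;
  re-adding every rejected track gives the upper correction bound.

**Tracking-free metric.** The per-pixel temporal coefficient of variation
CoV = SD/mean, with "highly variant" pixels segmented by Li's minimum
cross-entropy threshold and Tsai's moment-preserving threshold on the
pooled CoV histogram (256 bins).

**Calibration.** A seeded synthetic-movie generator (bouton-chain geometry,
Poisson patch events with lognormal durations, shot + read noise, optional
photobleaching, or a per-pixel flicker mode) serves as the forward model: a
curve of CoV statistic versus event-frequency multiplier, fitted
isotonically, converts a measured CoV difference between genotypes into an
inferred percent change in patch frequency.

Also included: translation registration, rolling-ball background
subtraction, mask generation, masked 3-D Pearson colocalization, and FRAP
double-normalization with single-exponential recovery fitting.

## Worked example

```python
import json
from patchdyn import SyntheticSpec, simulate_movie
from patchdyn.core import RunConfig
from patchdyn.pipeline import run_pipeline

sim = simulate_movie(SyntheticSpec(rng_seed=1))   # 89 frames at 0.25 Hz
manifest = run_pipeline(RunConfig(), sim.movie, "out_demo")
print(json.load(open("out_demo/stats.json")))
```

With the default generator conditions (3 boutons ≈ 35 µm², 6 events /
10 µm² / min, 48 s mean duration) this movie contains 128 ground-truth
events and the pipeline reports:

```
accepted: 78   rejected: {'too_short': 27, 'overlap': 2}
frequency_per10um2_min  3.776
mean_duration_s         39.733   (sd 26.887)
mean_rel_amplitude      0.641
mean_cov                0.2908
variant_fraction_li     0.5777
variant_fraction_moments 0.4354
```

The accepted-track frequency (3.8) undercounts the generated rate (6)
because sub-floor events (< 4 detections) and merged concurrent neighbours
are invisible to any tracker with these parameters — exactly the bias the
merged/corrected frequency estimate and the rejection census are there to
bound. The same pipeline is available from the shell:

```bash
patchdyn simulate --seed 1 --out movie.tif --truth truth.csv
patchdyn run-all --in movie.tif --out-dir out_demo
patchdyn calibrate --multipliers 0.5,0.75,1,1.25,1.5,2 --reps 10 --out curve.json
```

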