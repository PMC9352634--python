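# Methods

This note documents the models and procedures implemented in `smartline`, the
conventions and numerical choices they rest on, what the synthetic sessions do
and do not emulate, and the known limitations.

## Conventions

Coordinates are 0-based `(row, col)`, row-major, origin at the top-left pixel;
all distances are Euclidean between pixel centers. Segmentation weight
matrices are vectorised row-major by default; a flag accepts column-major
matrices from Matlab-heritage tools. Acquisition metadata (pixel size µm,
frame period s, line period s, dwell time µs) travels as sidecar JSON.
"Below the 25th/50th percentile" is read as *strictly* below the linearly
interpolated empirical percentile, and the SNR denominator is the population
standard deviation; these choices are fixed so that independent oracles and
the implementation agree exactly.

## Trace statistics and deconvolution

The SNR of a trace is `(max f − mean(f25)) / std(f25)` with `f25` the
sub-25th-percentile sample: the peak response measured against the
fluorescence floor. It is undefined (a typed error) for constant traces and
for traces whose floor has zero spread — which genuinely happens after
clipped subtractions, so aggregate metrics exclude such traces rather than
fabricate a value. dF/F₀ divides by the mean of the sub-median sample and
requires that baseline to be positive.

Deconvolution models dF/F₀ as an autoregressive process: order 1 below 2 Hz
sampling, order 2 at higher rates (an AR(1) kernel cannot represent a rise
time shorter than the decay once frames are fast enough to see it).
Coefficients come from the Yule–Walker equations on the centered sample
autocovariance; activity is the rectified one-step prediction error, and the
denoised trace re-convolves the activity with the fitted kernel. On noiseless
AR(2) calcium the kernel is recovered to ~0.004 absolute error; with
observation noise the Yule–Walker coefficients are biased toward zero
(classical errors-in-variables), which spreads each event over a few samples
but leaves event *detection* intact — the acceptance script measures a 100%
event hit rate at a transient peak-to-noise ratio of 5. A constrained sparse
solver could replace this estimator behind the same interface.

## Registration

All shift estimation uses one primitive: overlap-masked normalised
cross-correlation. For every integer lag within `max_shift`, the Pearson
correlation between image and template is computed over the actually
overlapping region (the Padfield masked-NCC identities evaluated with FFTs),
and the integer peak is refined to subpixel by quadratic interpolation of the
correlation surface, capped at ±0.5 px per axis. This estimator was chosen
after comparing three candidates (circular FFT correlation,
overlap-normalised covariance, interior-cropped NCC) on two hard cases —
patch registration, where content flows in and out of the window, and small
noisy reference boxes — and it was the only one accurate on both (≤ 0.1 px
patch error, ≤ 0.11 px median box error at the default noise).

Rigid registration aligns each frame to the temporal mean of the first
`n_template` frames (default 10). Piecewise-rigid mode splits the FOV into a
4×4 grid of ~50%-overlapping patches, estimates one rigid shift per patch and
blends a per-pixel shift field bilinearly between patch centers; frames are
resampled bilinearly with zero fill. Longitudinal segmentation alignment grid
searches integer shifts (default ±20 px, evaluated for all shifts at once via
FFT under cyclic shifting) × rotations (default ±10° in 0.5° steps about the
FOV center) and minimises the image MSE; the winning transform is applied to
ROI pixels with nearest-pixel rounding, dropping pixels that leave the FOV.

## Trajectory design

The ROI visiting order is a closed tour over ROI centroids (the trajectory is
re-scanned cyclically, so the last→first jump is physically traversed; the
closed-tour search space has (n−1)!/2 distinct solutions). The genetic
algorithm keeps a population of 100 permutations for 1000 generations: each
generation evaluates all tour lengths, retains the global best, randomly
partitions the population into groups of 4, and replaces each group with four
variants of its winner — the winner itself, a flip (reversal of a random
subsegment), a swap (exchange of two random positions) and a slide (one-step
rotation of a random subsegment). There is no crossover and no elitism beyond
the retained global best. On 20 random 7-city instances the GA matches
exhaustive enumeration 20/20 (acceptance script); for n ≤ 3 the tour is
returned directly.

Within each ROI, pixels are chained greedily: start at the pixel nearest the
entry point (the previous ROI's last pixel; the first ROI enters at its own
centroid), then repeatedly append the nearest unvisited pixel; all ties break
by (row, col) ascending, making the path fully deterministic. Each ROI's
surround (Euclidean dilation by the chosen width, minus every ROI's pixels,
ties between ROIs resolved toward the nearer, then lower-id ROI) is scanned
contiguously after the ROI's own pixels. Reference-box pixels are appended
last in row-major order. The effective line rate is
`1 / (n_pixels × dwell + flyback)` with an ideal-galvo default of zero flyback.

## SLS processing

**Classification.** Each trajectory pixel is classified by its minimum
distance to each reference ROI: [0, 1] ROI, (1, 2] outer ring, (2, 4]
surround, > 4 from all ROIs background; a pixel claimed by two or more ROIs is
discarded. Interval endpoints are closed on the right; the bands are disjoint
per ROI, so "multiple claims" can only involve distinct ROIs. The set of
pixels classified as a ROI — its *operational footprint* — is what every later
stage treats as "the ROI": trace extraction averages it, the SNR correction
assigns exactly that many pixels per line, and the reference-box correction
displaces it. (Using the raster segmentation's pixel count instead would
shrink the footprint whenever the trajectory carries a surround, and the
footprint change itself — not motion — would then dominate the metrics.)

**Large-artefact detection.** The recording (pixels centered) is reduced to
its first principal component; the score series is fitted with an AR(2) model
by ordinary least squares on the two lagged scores (no intercept — PC1 scores
are zero-mean; OLS rather than Yule–Walker because the scores are a single
realisation, not an assumed-stationary process; the first two fitted values
are the model's free predictions). The Pearson correlation between scores and
one-step predictions is evaluated in a trailing window of
`round(10 s / line period)` lines at every line; the first crossing below 0.3
becomes the crop index and all later lines are discarded, not corrected. On
simulated recordings whose PC1 is AR(2)-consistent the detector fired 0/100
times; with every pixel switching to white noise at a random line it cropped
within one window of the onset 100/100 times (acceptance script).

**Background subtraction.** Background-pixel activity is reduced to its rank-1
PCA reconstruction (per-pixel centering, means re-added, component sign fixed
so the mean loading is non-negative — the sign of a principal component is
otherwise arbitrary), averaged across pixels into one series b(t), scaled by
the contamination ratio 0.7 and subtracted from *all* pixels; negatives are
clipped to zero. When all pixels share one trace the output is exactly 0.3×
that trace (rank-1 is exact on identical series), which the acceptance script
verifies to ~1e-15.

**Motion corrections.** The SNR method pools each ROI's footprint, outer ring
and surround; at every line it ranks the pool by the SNR computed over the
*forward* window [t, t + 10 s] (truncated at the recording end; degenerate
windows rank last; ties break by (row, col)) and assigns the top n pixels,
n being the footprint size. The reference-box method reshapes the box pixels
of every line into a small image, optionally smooths the sequence with a
sliding mean (and optionally decimates to window centers), registers it
rigidly to its first-frames template, negates the corrections into tissue
displacements, interpolates them back to all lines by nearest assignment, and
shifts each footprint by the rounded displacement — shifted pixels that are
not on the trajectory (or not in the ROI's pool) are dropped for that line
rather than substituted.

One interaction worth knowing: smoothing the box sequence with a window
*shorter* than the neuropil correlation time (~1 s in the simulator) removes
shot noise but not the fluctuating neuropil gradient, and registration can
lock onto that gradient as apparent motion; windows of 10 s (or none) behave
well, and boxes should contain clear static contrast in the first place.

**Neuropil decontamination.** Local: per ROI,
`trace = mean(assigned pixels) − 0.7 × mean(neuropil pixels)` per line,
clipped at zero; the neuropil pixels are the surround class, or — after
line-by-line reassignment — the per-line unassigned pool pixels; a ROI with no
neuropil pixels passes through, flagged in the provenance. Global: per-ROI
signals (assigned ∪ surround pixel means) are reduced to their rank-1 PCA
reconstruction, which is subtracted from each ROI's plain footprint trace and
clipped. Identical ROI signals are zeroed exactly; a ROI orthogonal to the
leading component changes only by clipping.

**Pipeline and metrics.** `run_pipeline` applies a user-ordered subset of
{crop, background, one motion method, one neuropil method}; classification is
computed first and feature requirements (background pixels, reference box) are
checked before any computation. Quality metrics compare the final traces with
raw traces (static classification on the raw recording): Δ mean per-ROI SNR
and Δ mean pairwise Pearson correlation. On the standard synthetic session the
subtraction pipelines move the mean pairwise correlation by −0.4 to −0.8 while
the motion-only pipelines stay within ±0.07 of zero — decontamination removes
shared signal, pixel reassignment does not — and the full
background → SNR-motion → local-neuropil pipeline raises the mean correlation
between extracted traces and the true somatic signals from ≈ 0.46 to ≈ 0.88
(both from `scripts/acceptance.py`, seed 1). The "essentially unchanged" band
for motion-only pipelines is ±0.1, small against the subtraction effects.

## The synthetic session

The simulator draws disk somata (radius 3 px, 29 pixels) with a smooth
per-pixel gain, blurred by a 0.8 px Gaussian PSF so that fluorescence bleeds
~1 px beyond the anatomical disk — without this, pixels adjacent to a soma
carry no somatic signal at all, which no real microscope produces. Somata have
a resting brightness (soma_baseline = 40, in the arbitrary fluorescence units
of the renderer) above the anatomical texture of the surrounding tissue
(mean 20, sd 10, 1.5 px grain), since indicator-filled somata are the
brightest features in a GCaMP field. Spikes are Poisson at 0.3 Hz, filtered by
the stable AR(2) kernel (1.6, −0.64) with amplitude 60; the background
(spatially uniform, amplitude 20) and the shared neuropil (amplitude 28,
routed through a smooth spatial field, plus 20% per-ROI jitter) are
unit-variance Gaussian series smoothed to ~1 s correlation time. Noise is
additive Gaussian (sd 4). Motion is rigid planar only — a per-line random walk
(default 0.02 px/√line over a 45 s, 30 Hz session) plus optional abrupt
shifts — matching the assumption that fast line scanning sees negligible
non-rigid deformation. Within-line time is collapsed: all pixels of a line
share one timestamp. The background/neuropil amplitudes put the raw pairwise
correlations near 0.5, the regime in which decontamination is the point of
the pipeline.

The raster and line-scan renderers share their noise stream (one full-FOV
field per time index) and motion series, so they agree *exactly* on trajectory
coordinates — the embedding, classification and decontamination tests rely on
this bookkeeping. Everything is reproducible from the scene seed via numpy
PCG64 streams with a fixed draw order.

What the simulator does not emulate: photon (Poisson) statistics, optical
sectioning and depth-dependent blur, non-rigid deformation, within-line
motion, behaviourally structured activity, and indicator nonlinearity.
Passing tests therefore demonstrate the correctness and the qualitative
behaviour of the algorithms under controlled contamination and motion, not
performance bounds on any particular real preparation.

## Problem sizes

The test suite and acceptance script run the genetic algorithm at its full
defaults (100×1000) on 7-city instances, 100-seed batteries for detection
rates and oracle agreement, and a 45 s, 30 Hz session (1350 lines, ~900
trajectory pixels, 6 ROIs) for the pipeline properties — sizes chosen so the
whole battery completes in a few minutes on one CPU while every rate is
estimated from ≥ 100 trials where a rate is claimed.

## Known limitations

- The SNR motion correction is windowed-ranking, not tracking: it needs a
  transient inside most windows to rank somatic pixels above the pool; with
  silent cells the assignment drifts with noise.
- The reference-box correction rounds displacements to integers; sub-pixel
  drift near a rounding boundary toggles the assignment between two pixel
  sets.
- Yule–Walker deconvolution is bias-prone under noise (see above) and is not
  a spike-count estimator; only event support is claimed.
- The rank-1 background/neuropil models remove one shared component; multiple
  independent contamination sources leave residual correlation.
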