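# Methods

## The mapping model

The package treats a wide-field calcium movie as a linear superposition of
spatially fixed sources modulated in time, observed through a slow
indicator and multiplicative optical artifacts. Reverse correlation
against a point process (spike times) estimates the cortical pattern that
covaries with one neuron's firing:

1. For each event at time t₀, the per-pixel baseline F₀(x) is the mean
   fluorescence over t₀ − 3 s … t₀, and the event window is
   ΔF/F₀(t, x) = (F − F₀)/F₀ over t₀ − 3 s … t₀ + 3 s. Windows that cross
   a recording edge are dropped (never zero-padded) and counted; dropped
   events therefore cannot bias the baseline.
2. The STA movie is the frame-wise mean across event windows; the STM is
   the per-pixel peak of that movie within ±1 s of the event.
3. STM temporal dynamics (STMTD) are the full −3…+3 s trace of the pixel
   with the largest |ΔF/F₀| (within ±1 s) inside a region of interest.

Reliability is quantified by the Pearson r between STMs built from
disjoint random spike subsets: r rises with subset size as averaging
defeats single-event variability, and the smallest count whose median r
clears 0.9 is the unit's minimum stable spike count.

### Peak polarity

The peak of the STA movie can be taken two ways, and the package exposes
both because they answer different questions:

- `signed_extremum` (default for STMs) — the value of largest magnitude,
  sign retained. Required to map *depression*: units whose spiking is
  followed by, or embedded in, reduced cortical activity produce negative
  maps that a literal maximum would hide.
- `max` — the literal per-pixel maximum. This is the faithful reduction
  for single-event analyses of a positive-going indicator: with a
  per-event baseline, a single window preceded by strong activity has
  predominantly negative values, and the signed extremum then flips the
  motif's sign event by event. The sub-network analysis (below) therefore
  uses `max` for its per-spike maps.

## Preprocessing

- **Band-pass** — zero-phase 4th-order Butterworth (``sosfiltfilt``); the
  default seed-pixel-map band is 0.3–3 Hz. Zero-phase filtering preserves
  event timing, which matters for peri-event windows.
- **Global-signal removal** — per-pixel least-squares regression against
  the mask-mean trace (β fitted per pixel), reducing to plain subtraction
  when β = 1; a `subtract` mode is provided. Regression is used by default
  because it leaves pixels orthogonal to the global mode untouched.
- **Hemodynamic correction** — ratiometric: corrected ΔF/F₀ =
  (F_g/F₀_g)/(F_b/F₀_b) − 1 with a short-blue reflectance channel as the
  blood-volume surrogate. Any purely multiplicative common-mode signal
  cancels exactly (algebra, verified analytically in the tests); on
  synthetic sessions with a planted 2% artifact the residual artifact
  power is <10% (in practice ≈ 0).
- **Deconvolution** — the calcium trace is modelled as an AR(p) process
  (p ∈ {1, 2}, Yule-Walker estimated or user-supplied); applying the
  inverse AR filter recovers per-frame activity, clipped at zero under
  the non-negativity flag, with the reconvolution residual reported.
  This is an exact inversion on noiseless AR-generated input. It is a
  deliberately simple formulation: mapping results do not depend on it,
  so the package does not carry a sparse constrained solver.
- **Spike detection** — robust threshold k·median(|x|)/0.6745 on a
  high-pass trace (k = 4.5 for single units, 4 for multi-unit pooling).
  The 0.6745 constant is Φ⁻¹(0.75): for Gaussian noise the estimator
  recovers σ exactly, and a ≤5% spike contamination moves it by at most
  a few percent (median robustness), where a plain SD would explode.

## Seed-pixel map matching

An SPM is the zero-lag Pearson-r map of one pixel against all others,
computed on ΔF/F₀ that has been band-passed then global-signal-regressed
(in that order; the reverse ordering gives near-identical maps since both
operations are linear time-invariant per pixel up to the shared
regressor). Libraries default to a stride-2 seed grid — seeding every
pixel is quadratic in pixel count and changes best-match results by less
than the seed spacing. Best match is the argmax of the masked map
correlation, ties broken in scan order and logged. Two-seed fits solve a
non-negative least squares over the mask (`scipy.optimize.nnls`); a
nearly collinear pair triggers a condition-number warning because the
weight split is then not identifiable even when the fit is good.

## Temporal-pattern classification

Population STMTDs are peak-normalised to [−1, 1], linearly resampled onto
a 100 Hz grid (600 samples for a 6 s window), projected onto 3 principal
components and clustered by k-means (k = 3, k-means++, 20 restarts, fixed
seed). Clusters are mapped to pattern ids by the structure of their mean
trace: a negative pre-trigger mean (beyond 5% of the trace extremum) is
pattern 3; otherwise a negative post-trigger extremum is pattern 2 and a
positive one pattern 1. Raw cluster ids are always retained alongside the
mapping. Classification on normalised traces is the default (a `normalize`
flag exposes raw-amplitude clustering): normalisation makes the labels
invariant to common positive rescaling, which the tests assert.

## Sub-network analysis

Per-spike single-event peak maps (dimension H·W, e.g. 4096 for 64×64) are
partitioned by k-means in full pixel space (k = 4 default; PCA only for
display). Spontaneous motifs — a sliding window at every frame where the
full window fits, T − W + 1 of them — are assigned to the *same* centers
by nearest-Euclidean distance without refitting, and each partition's
spontaneous mean is subtracted from its spike-triggered mean. Because the
spontaneous partitions capture the ongoing network states, the difference
maps all converge on the unit's own component map. Two exact identities
anchor the analysis: the spike-count-weighted mean of partition means
equals the all-spike mean map (conservation, to float precision), and
identical spike/spontaneous sets give identically zero differences.

## Quiescence gating

Movement density is the mean absolute frame-to-frame difference inside a
face/forepaw ROI of the behavior video, low-passed at 0.1 Hz (zero-phase).
With median m and standard deviation σ of the smoothed profile, quiet
epochs are runs ≤ m + σ/10 and movement epochs runs > m + σ; quiet runs
are trimmed by 10 s at each end and kept only if >10 s survive. The σ is
computed on the smoothed profile (a flag moves it before smoothing).
Thresholds are median/σ-relative, so the segmentation is invariant to
affine rescaling of the density; a relative epsilon keeps a perfectly
constant profile (σ = 0 up to filter round-off) classified as quiet. A
120 s constant-density record yields exactly the quiet interval
[10, 110] s.

## The synthetic generator

`synthgen` emulates the structure the mapping assumes:

    F_g(t,x) = F0(x) · (1 + Σ_u c_u m_u(x)(k_u ∗ s_u)(t)
                          + Σ_b a_b m_b(x)(k_b ∗ o_b)(t) + ε(t,x)) · (1 + a·h(t))
    F_b(t,x) = B0(x) · (1 + a·h(t) + ε_b(t,x))

with Gaussian-blob motifs m (peak 1), homogeneous Poisson spike trains s
and background occurrences o, a difference-of-exponentials indicator
kernel k (rise τ = 80 ms, decay τ = 400 ms, peaking ~150 ms after the
spike — a fast genetically encoded indicator), i.i.d. Gaussian pixel noise
ε, and a shared multiplicative artifact a·h with h unit-variance noise
low-passed below 0.3 Hz, also driving the reflectance channel. Default
study conditions: coupling 0.05 ΔF/F₀ per spike, noise SD 0.01 per
pixel-frame, artifact amplitude 0.02. A fixed seed makes the session
bit-reproducible.

Three closed-form temporal prototypes generate classification test
populations: (1) causal positive transient peaking ~0.15 s after the
event; (2) causal slow depression lasting ~3 s; (3) pre-event depression,
brief rebound at the event, renewed depression.

The behavior generator plants movement epochs as a jittering textured
patch on an otherwise constant frame, so the gradient density is exactly
zero in quiet epochs.

What the generator does **not** model: photon shot noise and camera gain,
spatially correlated noise (optional extension point), vascular/pathlength
spectroscopy, indicator nonlinearity and saturation, burst-dependent
calcium summation, and non-stationary firing. Passing tests therefore
demonstrate correctness of the estimators under the model's assumptions —
additivity, stationarity, multiplicative common mode — not robustness to
every artifact of real recordings; the animal-data group statistics
reported alongside the original method are not reproduction targets here.

## Problem sizes and numerical choices

Verification runs use a 64×64, 30 Hz, 300 s session (one 2 Hz unit) for
map recovery, reliability curves and null controls, and a 32×32, 30 Hz,
300 s session (1 Hz unit, coupling 0.06, four background motifs at 0.2 Hz,
amplitude 0.04, noise 0.003) for the sub-network analysis — sizes at
which the estimates are stable while a full run stays in the minutes
range on one CPU. Stability subsampling uses disjoint subset pairs drawn
without replacement. Spike→frame alignment uses floor (the frame during
which the spike occurred; `nearest` available), with no sub-frame
interpolation. Event tensors are float32; all reductions accumulate in
float64. Ties — equal |peak| in a window, equidistant cluster centers,
equal library correlations — resolve to the first index in scan order and
are logged. Degenerate inputs (empty ROIs or masks, zero baselines with
the offending pixels named, all-zero traces, unstable AR roots, bands
outside Nyquist) raise errors rather than propagate NaNs.

## Known limitations

- The quadrant boundary for burst/tonic labeling defaults to 0.1 s, a
  conventional burst ISI; the log-scatter display it mimics has no single
  printed boundary.
- Percentage overlap of FWHM contours is Jaccard (|A∩B|/|A∪B|), chosen
  for symmetry and boundedness; |A∩B|/min(|A|,|B|) is provided as an
  alternative, and absolute overlap values depend on this choice.
- Putative excitatory/inhibitory classification by spike-waveform width
  is out of scope (no published thresholds); `spikes` carries no stub for
  it beyond the filter metadata.
- No atlas registration: ROI masks are supplied by the user or generated
  synthetically.
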