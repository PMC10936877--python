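# Methods

This note documents the models, parameter choices, and numerical decisions
behind `duetseg`, and what its synthetic benchmark does and does not show.

## The segmentation model

Each network is a per-sample window classifier: the probability that the
center sample of a raw-audio window belongs to each song class. The
architecture is deliberately minimal — one 1-D convolution (16 filters,
kernel 9, zero padding 4), ReLU, max pooling of width 2 along time, flatten,
one dense layer, softmax. "2 × 2 pooling" on a one-dimensional signal is
read as pooling of size 2 along the time axis. Windows are 4001 samples
(400.1 ms at 10 kHz) for the four-class network and 2001 samples (200.1 ms)
for the two-class network; both see enough context to cover several
interpulse intervals, which is what lets a center-sample classifier use
train rhythm, not just local energy.

Training hyperparameters: batch size 128; six epochs (four-class) or three
(two-class); a uniformly random 10% of the annotated samples as window
centers, each labeled by its center sample's class; symmetric signal padding
at the recording edges. Choices the published description leaves open are
exposed in `SegNetConfig` with these defaults: Adam optimizer at learning
rate 1e-3 with softmax cross-entropy (any stochastic gradient method would
do; Adam converges reliably within the fixed epoch budget), inference stride
of 10 samples (1 ms) with nearest-center fill (stride 1 reproduces literal
per-sample classification; at the default stride the two differ on well
under 2% of samples), and optional inverse-frequency class weighting (off by
default). Everything is seeded: config + seed + data fix the trained
parameters exactly.

The conv/pool forward and backward passes are fused numba kernels operating
per window position, with the dense layer on BLAS. This is purely an
implementation choice for single-CPU tractability; the computation is the
standard one.

## Fusion and heuristics

The fusion stage follows the published recipe exactly, with thresholds in
`FusionConfig`: 10 ms median filter per class (window forced odd, shrinking
at the track edges, vectors renormalized; implemented with a rolling-median
whose edge behavior matches the brute-force definition, verified in tests);
averaging of the bilateral/no-song probabilities of the two networks except
where the four-class argmax is unilateral or no song; gated argmax
(bilateral ≥ 1.25× unilateral; overlap ≥ 0.85); then the 40 ms-before /
10 ms-after adjacency rule and the 4 ms minimum bilateral duration, in that
order.

Decisions the published description leaves open:

* "classification probability of 1" for bilateral song adjacent to
  unilateral song cannot survive median filtering in floating point; it is
  implemented as `p ≥ prob_one_threshold` (default 0.999, configurable).
* The adjacency rule tests the *minimum* bilateral probability over the
  segment (the most conservative reading); the threshold and rule order are
  configurable.
* A candidate class that fails its gate falls back to the
  highest-probability class that passes its own gate (no-song always
  passes), keeping the output total and deterministic; ties break toward
  NONE < UNILATERAL < BILATERAL < OVERLAP.
* Discarded sub-4 ms bilateral segments become no-song.
* "Portions identified as unilateral or no song by the four-class network"
  is read per sample as the argmax of the (filtered) four-class track.

## Pulse splitting and song statistics

The envelope difference is upper minus lower peak envelope, each a cubic
spline through local extrema separated by at least 5 ms (the first and last
samples anchor the splines), clipped at zero. Pulse peaks are local maxima
of this difference with prominence at least 0.1 of its global maximum (an
artifact default; no peak-detection parameters are published). Within a
labeled segment, pulse boundaries sit at the envelope minimum between
consecutive peaks; the first pulse starts at the segment onset and the last
ends at its offset, so pulses tile the segment exactly. A segment with no
detected peak yields one pulse spanning it (peak at the envelope argmax).
Segments labeled overlap count as both song types for pulse extraction,
scoring, and song amounts.

IPIs are differences of consecutive envelope-peak times within contiguous
same-class song; bout grouping (unilateral: ≥4 pulses, IPIs ≤60 ms;
bilateral: any count, IPIs ≤100 ms) is greedy left-to-right, which for this
rule equals exhaustive enumeration of maximal runs (property-tested). A
bilateral pulse's "center" is the midpoint of onset and offset. Pulses from
discarded sub-minimum unilateral groups still count toward the 10-pulse
inclusion rule, which speaks of pulses, not bouts. Summary medians of IPIs
are taken over within-bout intervals; pulse-duration medians are over all
pulses of the class.

## The synthetic generator

`synth_duet` emulates the statistical structure of a duet, not its
acoustics. Unilateral bouts are placed by a renewal process (near-normal
inter-onset intervals, mean 1/rate, sd 15%); each bout draws its pulse
count, within-bout IPIs, per-pulse durations, amplitudes, and carrier
phases; each bout elicits one bilateral response train whose first pulse
center follows the bout onset by a normal response delay, except that with
probability `overlap_prob` the response instead begins inside the ongoing
bout. Broadband Hann-windowed noise bursts stand in for grooming/jumping
/rolling transients, and Gaussian background noise sets the floor. A single
RNG stream seeded from the config, with a fixed draw order (noise → per-bout
events → transients), makes output bit-reproducible.

Timing defaults are anchored to the published corpus summary (585 unilateral
bouts and ~10,450 bilateral pulses in 31.6 min at 4.9% / 25.4% / 1.3%
composition): 0.31 bouts/s; 8 pulses × 20 ms ≈ 160 ms of unilateral song per
bout (IPI 32 ± 3 ms); 18 bilateral pulses of 46 ± 6 ms per response (IPI
75 ± 12 ms); response delay 500 ± 80 ms; `overlap_prob` 0.15, so overlap is
occasional (~0.3–0.6% of samples), consistent with a duet being an
alternating exchange. Long recordings realize ≈4.7% unilateral and ≈26%
bilateral song. Pulses are Hann-windowed sinusoids; carriers (250 Hz
unilateral, 180 Hz bilateral) are arbitrary-but-distinct artifact defaults —
no spectral model of *D. virilis* wing song is available to copy, and every
spectral property of the generator should be read as a stand-in. A Hann
envelope (rather than a Gaussian) keeps the entire labeled pulse extent
above the noise floor, so truth boundaries are acoustically meaningful.

Ground-truth labels cover exactly the pulse extents; samples where a
unilateral and a bilateral pulse coincide are OVERLAP; gaps between pulses
within a bout are no-song. The two-class training split removes
unilateral/overlap-labeled samples from the timeline (splice
discontinuities accepted, as when portions are cut from a real training
recording) and appends noise-only recordings at 0.68 min per training
minute, matching the published ratio of extra noise to base training audio.

**What passing synthetic tests does not show.** The generator's pulses are
spectrally clean and its noise is stationary; real recordings have
nonstationary backgrounds, varying pulse shapes, sensor artifacts, and
behavior-driven amplitude changes. Benchmark scores here demonstrate that
the implementation is faithful and trainable, not that the published
performance transfers to any particular real corpus.

## The synthetic benchmark

`run_synthetic_benchmark(seed)` generates 3 minutes of training audio (three
60 s recordings), trains both networks at the published configuration,
segments one held-out minute, and reports sample-wise sensitivity, PPV, and
F per song type (overlap counting toward both classes, in either track).
Problem sizes — 3 train minutes, 1 test minute, 60 s recordings — are the
package's benchmark conditions, chosen so a single-CPU run finishes in
minutes while every published hyperparameter (window sizes, epochs, batch
size, training fraction, fusion thresholds) is exercised unchanged. At seed
1 this yields sensitivity/PPV between 0.92 and 0.98 for both song types;
scores are stochastic across seeds at the few-percent level.

## Numerical notes and limitations

* Network arithmetic is float32 (with float64 softmax); probability vectors
  are validated to sum to 1 within 1e-6.
* The median filter renormalizes after filtering; a degenerate all-zero
  median row (constructible, never observed in practice) becomes uniform.
* Sample-wise (not event-wise) scoring is the default; `tolerance_ms`
  dilates positives symmetrically to forgive pure boundary shifts.
* Undefined ratios (0/0 sensitivity or PPV) are NaN, never silently 0 or 1.
* Only pool size 2 is implemented; multi-channel WAVs are rejected rather
  than mixed; no resampling — input is assumed 10 kHz-like throughout.
* `pulses_from_labels` detects peaks once per recording with a global
  prominence reference; a recording whose two song types differ in amplitude
  by more than ~10× would need a per-segment prominence reference instead.
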