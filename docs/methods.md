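# Methods

## Model

The decomposition treats a set of per-subject ERP difference waveforms
as the output of a latent generative process: a small number of neural
sources, each with a fixed scalp projection (a static orientation and
polarity, hence a constant per-electrode weight vector) and a
non-negative time-varying magnitude. The network is a sequence map
from a condition indicator to the waveform: the input at instance k is
a binary tensor `X_k (T × n_conditions)` carrying a unit step pulse on
the channel of k's condition, high from 0 to 0.2 s (endpoints
inclusive; 21 samples at 100 Hz — the endpoint convention is
configurable via `inclusive=`, since a half-open reading is equally
defensible), and the label is that subject's difference waveform
`Y_k (T × n_channels)` in microvolts. All instances of a condition
share the same input, so the network can at best reproduce each
condition's mean waveform — exactly the grand-average difference wave
it is meant to decompose.

Four simple recurrent (Elman) layers with ReLU activations feed a
linear output layer; the last hidden layer and the output layer carry
no bias, so last-layer activations are non-negative source waveforms
that vanish without input drive, and each unit's row of `W_out` is its
scalp map. Hidden state is initialised to zero at t = −1 (the
convention of the deep-learning frameworks this architecture mirrors).

## Training

Two phases of full-batch Adam (learning rate 1e-3, β₁ = 0.9,
β₂ = 0.999, ε = 1e-7), at most `max_iterations` per phase with early
stop after `patience` = 250 iterations without loss reduction; the
weights of the best-loss iteration are restored on stop. At full batch
one iteration equals one epoch. Forward pass, backpropagation through
time, and Adam are implemented in numpy; gradient correctness is
established against central finite differences on a tiny network
(relative agreement better than 1e-4; in practice ~1e-6).

Phase 1 minimises the reconstruction error alone. The implementation
uses the element-wise mean over instances, time AND channels
(`loss_reduction="mean"`); the alternative convention that sums the
squared error across channels before averaging (`"channel_sum"`)
differs by the constant factor `n_channels` and changes no optimum,
but it does change the effective weight of the phase-2 penalties
relative to the data term, which is why the penalty coefficients are
treated as quantities to calibrate per convention rather than
universal constants.

Phase 2 continues from the phase-1 weights minimising

    L = MSE + α_L1 · (1/K) Σ |Z⁽⁴⁾| + α_L2 · Σ W_out²

(the L1 reduction sums within an instance and averages over the batch;
the L2 term is a plain sum of squares). Reference coefficients for the
channel-sum convention at full scale are α_L1 = 1e-4 and α_L2 = 1e-2.
For the element-wise-mean convention and the synthetic study scale
used throughout the tests, α_L1 was calibrated once on synthetic data
(see below); α_L2 = 1e-2 is kept.

A unit counts as active when its peak activation across conditions and
time exceeds 1e-6 × the largest activation of any unit. Exact zeros
are only guaranteed when ReLU pre-activations are strictly negative,
so a relative threshold is more robust than a literal non-zero test;
the threshold is an explicit argument everywhere it is used.
Reconstruction is exact by construction: the projections of all units
(threshold 0) sum to the network output for every condition.

Source ordering for presentation is by descending |r| between each
source's concatenated per-condition projection (flattened over time
and channels) and the concatenated grand-average difference waves.

## Group-ICA baseline

All instances are concatenated along time into a (K·T × n_channels)
matrix. PCA (fitted on the concatenated, mean-centred data, components
ordered by explained variance) removes the trailing component:
common-average-referenced data have rank n_channels − 1, and running
ICA at full channel count on rank-deficient data produces spurious
"ghost components". If the detected rank is lower still (e.g.
noise-free synthetic data of rank n_sources), the decomposition
proceeds at the detected rank with a warning. Extended-infomax ICA is
delegated to the established MNE-Python implementation; the package
implements the surrounding group procedure: stacking, rank reduction,
per-condition averaging of component time courses, and reconstruction.
"Rank-reduced data" below always means the centred data projected onto
the retained PCA subspace; that — not the raw input — is what the full
component set reconstructs exactly, and the per-condition sums of
component projections equal its per-condition grand averages.

## Comparison metrics

Projection fits use Pearson r and MSE on flattened (T × n_channels)
arrays per condition (the flattening is a documented package-wide
definition; per-channel-then-average is a defensible alternative).
A zero-variance signal (an inactive condition's all-zero waveform)
makes r undefined; it is reported as 0 with a warning flag so tables
stay rectangular.

Shannon entropy of a source's correlation profile uses absolute
correlations normalised to a probability vector, natural log (nats;
`base=2` available). Mutual information uses the k-nearest-neighbour
estimator for continuous variables (k = 3) with seeded tie-breaking
jitter, computed on raw (unstandardised) concatenated signals, and
clipped at zero — the estimator is noisy around independence and can
go slightly negative. The similarity-score matrix omits its diagonal,
and each source's most-similar source is the argmax of SS over the
remaining columns.

## Synthetic generator

The generator emulates what the decomposition assumes: truncated
Gaussian bumps in time (smooth, unimodal, non-negative, zero
throughout the pre-stimulus baseline) as source waveforms, with peak
latencies spread over the post-stimulus window at a guaranteed minimum
separation (default 0.1 s — "well-separated" sources), one
characteristic peak/width per source, and condition-specific
amplitudes drawn from 2–5 µV. Scalp maps are random low-spatial-
frequency patterns (sums of three Gaussian blobs over the 2-D montage
positions), zero-mean across channels so that the forward-projected
labels are consistent with common-average referencing, and scaled to
unit peak. A binary activity mask assigns each source to 1–2
conditions and guarantees every condition at least one source.
Subject variability: multiplicative lognormal amplitude jitter with
exact mean 1 (default sd 0.2), Gaussian peak-latency jitter (default
sd 0.02 s), and additive spatio-temporally smooth noise (temporal
Gaussian smoothing, spatial mixing through a Gaussian distance kernel;
default per-sample sd 0.5 µV — about 15% of a typical peak amplitude
after projection). What the generator does NOT emulate: volume-
conduction physics (no lead field), oscillatory background EEG,
correlated artifact sources (blinks), non-stationary scalp coverage,
or sources with non-unimodal time courses. Passing recovery tests on
these data therefore demonstrates correctness of the machinery under
the model's own assumptions, not robustness to model violation on
real recordings.

Ground-truth matching solves the exact optimal linear assignment on
the |r| matrix of concatenated projections (small matrices; removes
greedy tie-break ambiguity).

## Study conditions and calibration

The study configuration used by the acceptance script and the slow
acceptance tests: 6 ground-truth sources, 4 conditions, 20 subjects
per condition (K = 80), T = 101 at 100 Hz with a 20-sample baseline,
28-channel montage, default jitters and noise; network of 4 × 32
hidden units, up to 2500 iterations per phase — a deliberate scale-
down (half the units, half the iterations) of the full-scale reference
configuration, sized so a complete run fits in a few minutes on one
CPU.

α_L1 calibration (done once, on the element-wise-mean convention at
study scale, then frozen): phase-2 runs from a common phase-1 fit at
α_L1 ∈ {1e-4, 2e-4, 3e-4}. At 1e-4 pruning is weak (22 of 32 units
retain non-trivial amplitude); 2e-4 prunes to 9 units and 3e-4 to the
planted 6, all with per-condition reconstruction r > 0.97 and all six
sources recovered at |r| > 0.98. The study default is the
middle value α_L1 = 2e-4 (`PipelineConfig.rnn`), which leaves margin
on both sides rather than sitting at the edge of over-pruning.

An earlier generator revision allowed scalp maps with pairwise
|r| up to ~0.9; sources co-active in the same conditions with
near-collinear maps then merged under any α_L1 strong enough to prune
the redundant units — a genuine identifiability failure, not an
optimiser artifact, which is why the generator now guarantees map
distinctness rather than leaving it to chance.

## Numerical choices and edge cases

- Weight init: Glorot-uniform kernels, orthogonal recurrent matrices,
  zero biases, all from one seeded generator; training is seeded and
  reproducible on a fixed platform, but bit-identical results across
  BLAS builds are not promised — tests use statistical tolerances.
- ReLU subgradient at 0 is taken as 0.
- Training aborts with a diagnostic on a non-finite loss.
- K < 2 instances, or a declared condition with no instances, is
  rejected at model construction.
- An empty active-source set is returned (with a warning) rather than
  raised, so thresholds can be explored safely.
- The pulse-window sample test uses a relative 1e-9 tolerance on the
  time stamps so floating-point time vectors do not drop endpoint
  samples.

## Known limitations

- The L1 path shrinks activations smoothly; "zero amplitude" units are
  zero only to the activity threshold. When early stopping triggers
  mid-decay, a tail of small slowly-decaying units can remain above
  the conservative 1e-6 relative threshold, so the active count can
  vary by several units across seeds even when the set of
  substantially active units is stable.
- Group ICA at study scale (8080 samples, 27 components) sits below
  the usual ≥ 20 · n_channels² sample recommendation for ICA, as it
  does at full scale; no mitigation is applied.
- The similarity battery is descriptive: no inferential statistics on
  SE/MI differences between methods are computed.
- Only the ReLU activation is implemented for the recurrence; the
  config field exists so alternatives could be added, but nothing else
  is tested.
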