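# Methods

This note records the modelling assumptions, parameter choices and numerical
decisions behind `ecgfusion`, and what the synthetic-data validation does and
does not establish.

## Signal model and synthetic data

The generator emulates a single-lead ECG sampled at 360 Hz. Each beat is a sum
of Gaussian bumps standing in for the P wave, QRS complex and T wave; the five
AAMI classes differ in bump widths, amplitudes and timing (S beats are
premature with a flattened P wave; V beats are wide, tall and P-less; F beats
are intermediate; Q beats are a low, wide hump). Beat classes are drawn i.i.d.
from a configurable mix, and the annotation index is the exact R-peak sample.
The record is mean-subtracted, reflecting the AC coupling of real ECG
front-ends: a recorded lead carries no DC, and the frequency-routing rule
below would otherwise delete a fictitious DC pedestal and distort every
similarity measure.

Noise is additive and comes in the three families that dominate practice:
sinusoidal baseline wander (frequency constrained below 1.5 Hz so the cutoff
rule can address it), white Gaussian noise rescaled so the realized SNR equals
the requested value exactly, and 50/60 Hz powerline interference.

What this generator does *not* model: beat-to-beat waveform variability beyond
a 5 % amplitude jitter, rhythm structure (bigeminy, runs), multi-lead
correlation, electrode-motion artefacts, and non-stationary noise. Tests that
pass on these signals therefore establish the correctness and internal
consistency of each algorithm, not clinical performance; headline accuracies
from the literature on real Holter corpora are out of scope here.

The default beat-level class mix for pipeline runs (90 % N, 4 % V, 3 % S,
2 % F, 1 % Q) mirrors the strong normal-beat dominance of ambulatory
recordings; after slice labeling it leaves roughly half the windows labeled N,
comparable to the slice-count ratios reported for real data.

## ICEEMDAN

EMD internals are the standard ones the method presumes: cubic-spline envelopes
through strict local extrema, two extrema mirrored across each end to tame
boundary swings, sifting stopped when the normalized squared envelope-mean
(SD) drops below 0.2 or after 10 sifts, decomposition stopped when the
residual has fewer than three extrema.

ICEEMDAN specifics, none of which are fixed by the method's published
description:

* ensemble size 50 (default; smaller ensembles are noticeably worse at
  separating the slow trend from the cardiac band — at ensemble 8 the
  clean-signal pass-through correlation drops from 0.991 to about 0.986);
* added-noise scale `a = 0.2 * std(signal)`, constant across stages;
* per-realization noise seeded by spawning from the master seed, so the
  decomposition is bit-reproducible;
* stage k perturbs the residual with the k-th EMD mode of each noise
  realization (precomputed once per realization); when a realization has no
  k-th mode its unperturbed local mean is used.

The mode `IIMF_k = r_{k-1} - r_k` is defined as a difference of residuals, so
reconstruction (`sum + residual = input`) is a telescoping identity that holds
to machine precision on every call — the test suite asserts 1e-8 but the error
is ~1e-16.

## Frequency routing and the 1.5 Hz rule

Each component (residual included) is kept or discarded by its FFT-peak
frequency against the 1.5 Hz baseline-wander cutoff. Two consequences are
worth stating plainly:

* 1.5 Hz equals 90 bpm. A heart rate below 90 bpm puts the cardiac
  fundamental *below* the cutoff, and any decomposition mode that isolates the
  beat-rate periodicity is removed by construction. This is a property of the
  rule itself. The denoising validation therefore runs at 96 bpm, inside the
  rule's validity region; at 72 bpm the pipeline still improves SNR markedly
  because the beat-rate mode carries little energy, but exact clean-signal
  pass-through is unattainable.
* The residual is subjected to the same frequency test rather than being
  dropped unconditionally; for zero-mean inputs the two policies coincide in
  practice.

## Wavelet shrinkage

Retained components pass through a sym8, 5-level DWT with symmetric padding.
Detail coefficients are shrunk by the improved threshold function; the
approximation band is untouched. The printed form of the threshold function in
circulation is typographically garbled; the implementation here is fixed by its
stated limit behaviour — `f(T) = 0` with `f(x) → sign(x)(|x|-T)` just above T
(soft limit) and `f(x)/x → 1` as `|x| → ∞` (hard limit) — which admits exactly

    f(x) = sign(x) (|x| - 2T / (exp((|x|-T)/T) + 1)).

The threshold is the universal one, `T = sigma * sqrt(2 ln n)`, with a single
noise estimate `sigma = median(|d1|)/0.6745` taken from the finest detail
level. An earlier variant estimated sigma per level; on noise-free,
band-limited components (exactly what ICEEMDAN produces) the deep-level
details *are* the signal, the per-level estimate mistakes them for noise, and
the shrinkage destroys 5-8 % of clean-signal energy. The finest level is
noise-dominated whenever broadband noise is present at all, so it is the only
defensible scale source. `T = 0` is allowed and documented as a pass-through.

## Slicing, labeling, splits

Windows are half-open `[start, start + 1800)` with 0-based indices; the
trailing partial window is dropped. The overlap fraction defaults to 0.5
(overlap is part of the method; its amount is not, so it is configurable).
The tie-break rule (first-occurring abnormal type) makes the slice label
order-dependent only when abnormal counts tie; a property test checks
permutation invariance in all other cases.

Splitting order matters: 20 % of slices are held out (stratified) *before*
SMOTE, so no held-out slice ever participates in neighbour search; the
balanced remainder is then split 30/70 into validation/training, with the
fractional sample rounding into validation (`ceil`), matching the published
counts (47,015 balanced → 14,105 validation) exactly.

SMOTE uses k = 5 Euclidean nearest neighbours on raw 1800-sample vectors and
uniform interpolation weights; synthetic rows carry a provenance flag so that
evaluation can exclude them.

## Image encoding

Segments are PAA-compressed to 100 points (mean over 18-sample frames) so each
encoding is natively 100 × 100; a "resize" mode (encode at full length,
bilinear downscale, re-binarize RP at 0.5) exists for comparison. GADF and MTF
normalize internally. RP runs non-embedded (m = 1, tau = 1) on
amplitude-scaled values: the published recurrence threshold eps = 30 is only
meaningful against raw ADC amplitudes, so the pipeline multiplies
physical-unit signals by the ADC gain (200 counts/mV) before thresholding;
both the gain and eps are configurable, which records rather than resolves the
normalized-vs-raw ambiguity in the method description. Channel order is fixed:
GADF→R, MTF→G, RP→B, with linear maps to 8-bit and half-up rounding.

MTF edge cases: empty quantile bins (duplicate edges) are merged; a state that
never appears as a transition source (only the final sample's state can) gets
a self-transition of 1 so the transition matrix stays row-stochastic.

## Network

Design points not fixed by the published layer table:

* channel-attention reduction ratio r = 4 (widths 32-256 make 16 too
  aggressive); spatial-attention kernel 7 with padding 3;
* the spatial-attention equation omits the sigmoid present in the prose and
  the residual re-add of the module input; both are included, the re-add
  being what distinguishes the "improved" attention module;
* the first residual stage maps 64 → 32 channels at stride 1 inside the block
  (1 × 1 projection shortcut);
* the 2-D branch lists no activations: ReLU after each convolution, no batch
  norm;
* dropout 0.5 before the fusion head;
* Kaiming-style initialization; the second BN scale in each residual block
  starts at zero so a fresh block is identity-plus-shortcut (this also means
  attention cannot influence a freshly initialized block — tests that probe
  attention activate that branch first).

The autodiff engine computes exact gradients (finite-difference checked to
~1e-7 relative) in float64. Training defaults follow the published recipe
(Adam, lr 0.0007, batch 256, cross-entropy, no schedule, no weight decay,
fixed epoch budget); when a validation set is given, the best-validation-OA
parameters are restored, and optional early stopping is off by default.

Within the one-vs-rest reduction used for reporting, per-class "Acc" is
`(TP+TN)/total`; published per-class accuracy columns that coincide with
sensitivity are an artefact of computing Acc on the class-restricted subset,
which this package does not do.

## Problem sizes used in validation

CPU-friendly sizes, chosen once: denoising oracles run on 3-4 s records
(ensemble 50 for the reference checks, 6-16 for repeated-trial suites);
decomposition cardinality is checked on a 3,000-sample record; training
sanity checks (separability, one-batch memorization) use a width-reduced
network (stages 8-8-16-16, 48 × 48 images, 360-point windows) whose
architecture is otherwise identical; the balancing/split counts run at the
full published scale (27,956 → 47,015 samples of dimension 1800). The
end-to-end pipeline smoke configuration uses two 90 s synthetic records,
ensemble 4 and two epochs.

## Known limitations

* Clinical-scale accuracy claims are not reproducible here by design: they
  require the external Holter corpus and long GPU training.
* EMD-family decompositions are sensitive to end effects; the mirrored-extrema
  envelope keeps them small but a slow residual arc of ~1-2 % energy on short
  spiky records remains typical.
* The numpy network is exact but slow compared to GPU frameworks; the default
  full-width architecture is practical for probing and small studies, not for
  200-epoch runs at batch 256.
* The WFDB writer emits the common header/212/annotation subset (single
  segment, format 212, standard beat codes); exotic dialect features
  (multi-frequency signals, AUX strings) are out of scope.
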