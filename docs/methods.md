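# Methods

This note documents the models, the synthetic data they are trained and
evaluated on, the numerical choices, and what the shipped tests do and do
not establish.

## Signal model and features

All audio is mono float at 16 kHz. STFT analysis uses 512-sample (32 ms)
periodic Hann windows with a 256-sample hop and a 512-point FFT (257 bins);
synthesis uses the dual-window inverse (scipy's `ShortTimeFFT`), so an
unmodified analysis/synthesis roundtrip is exact to ~1e−7 relative RMS.
The denoiser representation is the log power spectrum,
`LPS = log max(|STFT|², 1e−12)` (natural log). The floor is the only
guard against `−inf`; no NaN/Inf can leave the feature module. Inversion is
`magnitude = exp(LPS/2)`, combined with the *unmodified noisy phase* —
phase is never estimated. The classifier representation is 13 MFCCs from a
26-band mel filterbank over the same STFT frames (so classifier and
denoiser always see aligned frame grids); coefficient 0 carries log energy.

LPS frames are z-scored per training corpus (per-bin mean/std stored with
each model and inverted on output); unnormalized LPS stalls small-network
training. MFCCs are z-scored the same way.

## Networks

Both networks are plain multilayer perceptrons trained with mini-batch Adam
(β₁ 0.9, β₂ 0.999, ε 1e−8), implemented in numpy with hand-written
backpropagation — the per-layer trainable mask at the heart of the transfer
scheme needs direct control over which parameters the optimizer touches,
and the networks are small enough that this is fast on one CPU. Gradients
are verified against central differences (< 1e−4 relative) in the tests.

* **Noise classifier (NC):** [13, 100, 100, 100, K] with logistic hidden
  units and softmax output (max-subtraction for overflow safety), trained by
  cross-entropy on per-frame MFCCs (frames inherit their utterance's class).
  Defaults: lr 1e−3, batch 128, 50 epochs. An utterance is classified by
  the argmax of its frame-averaged posterior (ties → lowest class id); the
  maximum of that mean posterior is the routing confidence. The confidence
  statistic is deliberately the simplest one consistent with threshold
  gating; the default threshold is 0.9. Decisions are made per utterance,
  not per frame — frame-level routing would switch denoisers mid-utterance.
* **Denoising autoencoder (DDAE):** [257, 256, 256, 256, 256, 257] — five
  weight layers (L = 5), ReLU hidden units, linear output — regressing
  noisy LPS onto clean LPS by mean squared error (per-sample error summed
  over bins, averaged over frames). The 256-unit width is chosen so one
  denoiser is ≈ 0.33 M parameters and a 13-model deployment ≈ 4.3 M, the
  scale regime the transfer scheme is designed to collapse. Context window
  is a single frame (input width = output width); He initialization.

## Knowledge transfer

Weight layers are numbered 1..L from the input. The substituted layer is
`L − r`; the default r = 3 selects layer 2 of the 5-layer network. (The
source convention is ambiguous between "second layer" and "middle layer";
the index is a config knob, and `layer_sweep` evaluates r ∈ {0..4}, which
covers every layer exactly once, r = 0 being the output layer.)

`derive_nd_layer` copies the trained NI model, freezes all layers except
the substituted one, fine-tunes on single-environment (noisy, clean) LPS
pairs — defaults lr 1e−4 (an order below base training; single-layer
adaptation is a small-step correction) — and returns only that layer's
(W, b). Frozen parameters are bit-identical before and after by
construction (the optimizer never touches them), and the base model is
never mutated; a SHA-256 checksum binds each transfer store to its base
model. `apply_transfer` reconstructs the ND model exactly, so the
"explicit ND models" and "store" views of the system are the same object.

## Parameter accounting

`count_system_parameters` compares `full = nc + (C+1)·ddae` (C explicit ND
models plus the NI) against `transfer = nc + ddae + C·layer`. The
classifier is counted identically on both sides (a flag excludes it from
both), so the ratio is conservative. With equal layer sizes the ratio tends
to `(L+C)/(L(C+1))`; at L = 5, C = 12 that is 17/65 ≈ 0.26. With default
widths the reduction is ≈ 74% and the full deployment ≈ 4.3 M parameters.
The report also exposes the incremental store size (C × substituted layer)
since "cost of adding one more environment" is the quantity a deployment
actually budgets.

## Synthetic corpus

The generator emulates the *properties the pipeline depends on*, not any
recorded corpus:

* **Speech:** harmonic source with a piecewise-linear F0 contour
  (100–250 Hz), per-syllable vowel formant filtering (3 resonators),
  raised-cosine syllable envelopes at 2.5–5.5 Hz with 75% voicing, plus
  −24 dB formant-shaped aspiration noise. Clean speech is RMS-normalized to
  0.05 before mixing so peaks stay below 1 even at −10 dB SNR.
* **Noise bank (12 classes):** two spectrally contrasted babble pairs, a
  two-talker masker, a cafeteria scene (babble + clatter + broadband), an
  impulsive jackhammer, low-frequency transit rumble, a fan, a squeaky toy,
  speech-shaped noise (filter designed on a long-term-speech-spectrum
  curve), a siren sweep, and two composite scenes. Each class's output is
  RMS-normalized and carries a −50 dB broadband recording floor (real
  captures are never digitally silent). Distinctness is a designed
  invariant: all pairwise correlations of mean log-spectra are below 0.95,
  and a trivial nearest-centroid classifier exceeds 90% — so classifier
  results are never artifacts of an impossible fixture.
* **Mixing:** `noisy = clean + g·noise` with
  `g = sqrt(P_c / (P_n·10^(SNR/10)))`; the achieved SNR is exact to
  < 1e−6 dB. Noise is truncated from sample 0 (deterministic). Corpus
  grids (class × SNR × split) carry per-entry seeds derived from one master
  seed; resolving an entry twice is bit-identical. Default SNR grids:
  {−10, −7, −4, −1, 1, 4, 7, 10} dB for training,
  {−6, −3, 0, 3, 6} dB for testing.

What the generator does *not* emulate: linguistic content, speaker
variability, reverberation, channel effects, or non-stationary real-world
noise statistics. Passing tests therefore demonstrate that the machinery
(routing, transfer, reconstruction, accounting) behaves as designed and
that the method's orderings hold on matched synthetic conditions — not
that any particular intelligibility gain transfers to recorded speech.

## Evaluation

* **STOI** is implemented in-package (classic variant: 10 kHz resampling,
  removal of frames 40 dB below the loudest clean frame, 15 one-third-octave
  bands from 150 Hz, 384 ms segments, −15 dB distortion clipping, band-wise
  correlation). The test suite carries a second, independently coded
  loop-based implementation of the published algorithm; both must agree to
  1e−6 on fixtures.
* **PESQ** is a licensed ITU standard and is only ever consumed from the
  optional `pesq` package; without it, `eval_pesq` raises and batch tables
  report NaN. No acceptance-level result depends on PESQ.
* **WCR** (word correct rate, 100·correct/total) is provided for scoring
  listening-test transcripts; no human data ships with the package.
* **Layer separability** quantifies how strongly each layer's activations
  separate clean-input from noisy-input frames: seeded subsampling to a cap
  per population, then a two-class silhouette per layer. A t-SNE embedding
  is available for plots but never feeds the statistic — a 2-D projection's
  visual overlap is not a measurement.

## Study-scale choices in the shipped tests

The transfer study in the acceptance tests trains the NI model on ten of
the twelve classes (2 utterances per class × SNR cell, 2 s each, ≈ 20k
frames; 250 epochs) and holds out the jackhammer and two-talker classes —
impulsive machinery and competing speech, the two classic hard deployment
environments — as the "new environment" targets, each fine-tuned on ≈ 8k
matched frames for 100 epochs. This mirrors the intended deployment: a broadly trained base model
specialized by one layer to environments it has not seen. Evaluation
utterances are 3 s (sentence length); shorter clips make STOI estimates
noticeably noisy. Measured at 0 dB with the fixed seeds in the test file:
NI enhancement lifts mean STOI by ≈ +0.05 on matched conditions, and the
single-layer ND variants beat the NI model on every held-out utterance
(mean ≈ +0.19 on jackhammer, ≈ +0.15 on two-talker).

## Known limitations and an honest negative result

* The **separability profile does not peak at an interior layer** on these
  fixtures. Across every configuration tried (hidden widths 128/256/512,
  80–250 training epochs, matched and held-out noise classes, with and
  without silence frames, euclidean and cosine silhouette) the
  clean-vs-noisy silhouette decreases monotonically, ≈ 0.43 at h(1) down to
  ≈ 0.03 at h(5). The reason is structural: with corpus z-scored LPS
  inputs, clean and noisy frames differ most at the input itself, so the
  first hidden layer inherits the largest separation, and a denoiser's job
  is precisely to merge the two populations toward the output. The
  "representations converge again in the late layers" half of the expected
  picture holds robustly (h(5) is always far below the peak); the
  "divergence peaks mid-network" half appears to be an artifact of judging
  overlap in 2-D embeddings rather than measuring it. The corresponding
  test asserts the interior-peak expectation as stated and is expected to
  fail, with the measured profile in the assertion message.
* Training is CPU-numpy; minutes, not seconds, at the shipped scales.
* The confidence gate is a plain max-posterior threshold; it cannot flag a
  noise type that is genuinely outside the bank (open-set detection is out
  of scope).
* Single-frame context limits the denoiser. `stack_context` builds
  odd-width context inputs (center-frame prediction) for wider
  architectures, but the default — and everything measured here — is
  context 1.
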