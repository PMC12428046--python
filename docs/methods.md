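# Methods

## Problem and pipeline

`seedspectra` classifies seed varieties from near-infrared hyperspectral
imagery. A push-broom camera records a cube of digital numbers (DN) over 512
bands spanning 870–1709 nm; seeds of one variety are laid out in a grid
(5 × 6 by default) and each seed contributes one mean reflectance spectrum.
The pipeline is:

1. **Reflectance calibration.** `R = (I_raw − I_dark) / (I_white − I_dark)`
   per element, with a white (PTFE panel) and dark (closed-shutter)
   reference. References may be full cubes or single line frames broadcast
   across scan lines, both common push-broom practices. The denominator is
   floored at `epsilon` (default 1e-6, with a warning counting affected
   elements); the guard only matters for defective pixels where the white
   and dark references coincide.
2. **Segmentation and extraction.** Seeds are segmented on the band-mean
   image by a global threshold (Otsu refined by an isodata
   midpoint-of-class-means iteration — plain Otsu's binned threshold can
   land inside the extremely narrow background peak that band-averaging
   produces), 4-connected labelling, and an area filter. Regions are ordered
   into grid positions by clustering centroid rows with a 1-D gap heuristic
   (split where the sorted-centroid gap exceeds 1.5 × the median seed
   diameter proxy √area) and sorting by column within rows. The region of
   interest is the whole seed footprint and its spectrum is the unweighted
   per-band mean over the region's pixels. Discriminating the embryo face
   from the endosperm automatically is not attempted; this is a documented
   limitation relative to hand-drawn embryo ROIs.
3. **Preprocessing.** Seven row-wise operators: identity, first and second
   derivative, Savitzky–Golay smoothing, Gaussian, median and moving-average
   filters. Derivatives are central differences with one-sided edges in band
   units (`numpy.gradient`), keeping all 512 bands; the second derivative is
   the first applied twice. Smoothers default to window 5 / polynomial
   order 2 / sigma 2 bands — common chemometrics choices, all overridable.
   MF/MA/GF use reflect padding; SG uses a polynomial edge fit so that
   polynomials up to the fit order are reproduced exactly at every band
   (reflect padding would break this at the edges). A Savitzky–Golay
   derivative is available as a configurable alternative to plain
   differences.
4. **Split.** One stratified 4:1 train/test partition: per class,
   ⌊n·4/5⌋ seeded-shuffled rows train, the rest test (90 per class → 72/18;
   2700 total → 2160/540). A stricter replicate-holdout alternative
   (`split_by_replicate`) holds out one whole acquisition capture per
   variety instead; the random stratified split is the default. k-fold
   machinery is deliberately absent.
5. **Classifiers.** See below.
6. **Metrics.** Confusion matrix; accuracy = trace/total; precision and
   recall macro-averaged over per-class one-vs-rest counts (the classes are
   exactly balanced, so macro averaging is the natural choice; a never-
   predicted class contributes precision 0 with a warning). Loss is mean
   cross-entropy in natural log units.

## Classifiers

**KNN** (from scratch): majority vote over the k nearest training spectra
under Euclidean, Manhattan, Spearman (1 − rank correlation) or Pearson
correlation (1 − r) distance; ties break by smaller mean distance among the
tied labels, then smaller label. An undefined correlation (constant
spectrum) becomes the maximal distance 2 with a warning. Feature
normalisations for the KNN grid (standardise / min–max / log(x − min + 1))
are fitted on training rows only.

**ELM** (from scratch): single hidden layer with weights and biases drawn
uniform[−1, 1] from a seed and frozen; sigmoid activations; output weights
are the ridge least-squares solution onto one-hot labels (λ default 1e-6
for conditioning; λ=0 falls back to a pseudoinverse with a warning).
Hidden-node grid {100, 150, 200}, default 150.

**Random forest**: delegated to scikit-learn (it is an off-the-shelf
baseline, not a contribution); grids {50, 100, 150} trees × {1, 2, 4}
minimum leaf size, defaults 100/1, seeded.

**Deep models.** The 1DCNN baseline and the full CNN–LSTM–attention–ECA
model are implemented in NumPy with hand-written backward passes (the LSTM
recurrence is numba-compiled); every layer's gradient is verified against
central finite differences to 1e-4 relative in the test suite. The
architecture, in sequence form `(batch, positions, channels)`:

- Conv1d (1 → C channels, kernel 3, stride 1, padding 1) + ReLU + max-pool.
  C = 32 for the plain baseline, 64 for the full model.
- Optional 3-layer LSTM, hidden width 64 (gates ordered input/forget/cell/
  output, forget bias initialised to 1, states start at zero).
- Optional 8-head scaled-dot-product self-attention (no positional encoding:
  the bands are already ordered and the LSTM carries order; no residual or
  layer norm — the plain block suffices at this depth).
- Optional ECA gate: global average pool over positions → 1-D convolution of
  adaptive odd width k across the channel axis (zero-padded, kernel
  initialised to zero so gates start at sigmoid(0) = ½) → sigmoid → per-
  channel rescaling. k = |log₂C/γ + b/γ| truncated to an integer and bumped
  to the next odd number (γ = 2, b = 1): C = 64 → k = 3.
- Global average pool over positions, then a linear head to the class
  logits.

The four ablation variants are exactly the flag combinations
(LSTM, attention, ECA) = (F,F,F), (T,F,F), (T,T,F), (T,T,T), named 1DCNN,
1DCNN-LSTM, 1DCNN-LSTM-ATTENTION and CLA-CA.

Training: Adam (lr 1e-3, β 0.9/0.999), batch 16, mean cross-entropy, seeded
shuffling, metrics reported at the final epoch (no early stopping or
validation split). Inputs are standardised per band with training-set
statistics stored on the model and re-applied at prediction; derivative
spectra have ~1e-3 amplitude and the optimisation stalls at chance without
this conditioning. Default float32; float64 available (used by the gradient
checks).

## Synthetic data generator

No public dataset accompanies the acquisition design this package targets,
so the generator is a first-class module. A variety template is
`baseline + Σ aⱼ exp(−½((λ−cⱼ)/wⱼ)²)`: a fixed species-level envelope (four
broad features on a 0.45 baseline, staying well inside (0, 1)) plus 8
variety-specific Gaussian bumps (centers uniform over the range, widths
30–120 nm, amplitudes N(0, 0.03²)) scaled by the separability dial δ.
δ = 0 makes all templates identical — a pure no-signal control — and
inter-template L2 distance is exactly linear in δ. Real NIR reflectance
curves are smooth with broad absorption features; sums of Gaussians
reproduce that geometry without attempting real seed biochemistry (no
water/starch band physics, no radiative transfer).

A seed's spectrum is `gain·T_v + offset + noise` with gain ~ N(1, 0.05),
offset ~ N(0, 0.02), and i.i.d. per-band noise N(0, 0.005) — multiplicative
scatter and additive baseline are exactly the artifact families derivative
preprocessing removes, so the generator lets tests show the derivatives
earning their keep. The defaults (30 varieties × 90 seeds × 512 bands,
δ = 1) mirror the emulated study design; the noise scales are realistic for
a cooled NIR line camera (≈ 5% scatter between seed surfaces, ≈ 2% baseline
drift, per-band SNR ≈ 100).

Cube scenes place elliptical seeds (semi-axes 6 × 5 px, 16 px cell pitch,
8 px margins) of a single variety on a 0.05-reflectance background and
encode `dn = dark + R·(white − dark)` (white 12000 DN, dark 800 DN,
float32), emitting line-frame references. Ground-truth masks, per-seed
spectra and the encoded reflectance field are returned for oracle tests.
What the generator does **not** emulate: spatial within-seed texture,
spectral smile/keystone, stray light, touching seeds, embryo-vs-endosperm
contrast. Passing tests therefore demonstrate the pipeline's correctness
and its behaviour under the stated noise families, not performance on real
corn seeds.

## Reference conditions and problem sizes

The shipped reference study (`seedspectra.pipeline`) pins seed 7 and the
generator defaults above, acquires all 90 captures (30 varieties × 3
captures of 5 × 6 seeds), and runs first-derivative preprocessing, the 4:1
split and the deep ablation. The reference training regime keeps the stated
architecture but uses max-pool width 8 (sequence length 64) and 15 epochs —
sizes chosen so a full ablation trains in minutes on a single CPU core; the
synthetic task converges well within that budget. `DeepConfig` defaults
remain kernel 3 / stride 1 / padding 1, pool width 2, 200 epochs for users
who want the full-length regime.

## Numerical choices and degenerate inputs

- Calibration floors its denominator at 1e-6 and warns; monotonicity in the
  raw DNs is preserved.
- Zero-variance features under standardisation are floored at 1e-12 with a
  warning; min–max uses the same guard for constant features.
- Vote and argmax ties resolve to the smaller label everywhere.
- Cross-entropy clips probabilities at 1e-12 and validates that rows sum to
  1 within 1e-6.
- An empty segmentation returns an empty list with a warning rather than
  raising; ragged grids warn and are ordered best-effort.
- All randomness flows through explicit integer seeds (`numpy` Generators);
  identical configurations reproduce bit-identical outputs.

## Known limitations

- Whole-seed ROIs, not embryo-only; single global threshold, no watershed
  splitting of touching seeds.
- The synthetic separability dial is a stand-in for real varietal contrast;
  absolute accuracies on synthetic data say nothing about real-world
  accuracy.
- The deep stack is CPU-oriented NumPy: correct and reproducible, but not
  fast at GPU scales; stride ≠ 1 convolutions are not implemented.
- Timing columns in grid reports are wall-clock and hardware-dependent;
  nothing asserts on them.
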