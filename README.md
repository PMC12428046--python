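# seedspectra

Variety identification of seeds from near-infrared hyperspectral images.

Seed lots of different varieties look nearly identical to the eye, but their
reflectance spectra over 870–1709 nm differ in small, repeatable ways.
`seedspectra` implements the full desk side of a line-scan (push-broom)
hyperspectral phenotyping experiment for a 30-variety × 90-seed design with
512 spectral bands:

- **Calibration** of ENVI-style cubes (text header + binary, BIL/BIP/BSQ) to
  reflectance: `R = (I_raw − I_dark) / (I_white − I_dark)` against white-panel
  and dark-current references.
- **Per-seed spectra**: automatic segmentation of the seed grid on the
  band-mean image and one mean spectrum per seed footprint.
- **Chemometric preprocessing**: first/second derivative, Savitzky–Golay,
  Gaussian, median and moving-average filters.
- **Classifiers** under one fit/predict contract: KNN (four distances, three
  normalisations, the odd-k grid), an extreme learning machine (frozen random
  hidden layer, ridge least-squares output), a random forest, and a deep
  **CNN–LSTM–attention–ECA** sequence model ("CLA-CA") with its three
  ablation ancestors (1DCNN, +LSTM, +attention).
- **Metrics and reports**: confusion matrices, accuracy, macro precision and
  recall, mean cross-entropy (nats), grid/ablation runners, loss-curve and
  confusion-heatmap figures, and a `seedspectra` CLI.
- A **synthetic data generator** that emulates the study design (class
  templates as Gaussian-bump spectra with a separability dial δ,
  multiplicative scatter, baseline offsets, band noise, and full camera
  scenes with references and ground-truth masks), so the entire pipeline is
  testable end to end without proprietary data.

The deep model is implemented from scratch in NumPy (numba-compiled LSTM
recurrence) with hand-written, finite-difference-verified backward passes:

    x ∈ R^512 → Conv1d(k=3,s=1,p=1) + ReLU + max-pool
              → 3-layer LSTM (h=64)
              → 8-head self-attention
              → ECA channel gate, k = |log₂C/γ + b/γ|_odd
              → global average pool → linear → softmax (30 classes)

trained with Adam (lr 1e-3, batch 16) on mean cross-entropy
`L = −(1/N) Σᵢ Σ_c y_ic log p_ic`.

## Worked example

Generate a small synthetic study, preprocess with the first derivative,
split 4:1 and train the full model:

```python
from seedspectra import SynthSpec, SplitSpec, make_spectrum_table, split
from seedspectra.preprocess import PreprocessSpec, apply_preprocess
from seedspectra.deepnet import DeepConfig, build_model, predict, train
from seedspectra.evalrep import evaluate_predictions

spec = SynthSpec(n_varieties=30, seeds_per_variety=30, noise_sd=0.0005, rng_seed=7)
table = apply_preprocess(make_spectrum_table(spec), PreprocessSpec(method="D1"))
train_t, test_t = split(table, SplitSpec(rng_seed=7))      # 720 / 180 rows

cfg = DeepConfig(n_classes=30, n_bands=512, pool_width=8, epochs=10, rng_seed=7)
net, trace = train(build_model(cfg), train_t)
labels, probs = predict(net, test_t.spectra)
rep = evaluate_predictions(test_t.labels, labels, 30, probs)
print(f"epoch 0 loss {trace[0]['loss']:.3f} -> epoch 9 loss {trace[-1]['loss']:.3f}")
print(f"test accuracy {rep.accuracy:.3f}  macro P {rep.macro_precision:.3f}  "
      f"macro R {rep.macro_recall:.3f}  loss {rep.mean_loss:.3f}")
```

Output:

```
epoch 0 loss 3.371 -> epoch 9 loss 0.011
test accuracy 1.000  macro P 1.000  macro R 1.000  loss 0.014
```

The first epoch starts at the 30-class chance loss (ln 30 ≈ 3.40) and the
model separates the 30 synthetic varieties completely; with the
separability dial at δ = 0 the same run stays at chance (accuracy ≈ 1/30),
which is the package's no-leakage control.

The same flow is available from the shell:

```bash
seedspectra synth --varieties 30 --seeds-per 90 --bands 512 --delta 1.0 --seed 7 --out work/
seedspectra preprocess --method d1 --in work/table.csv --out work/d1.csv
seedspectra split --in work/d1.csv --out work/ --seed 7
seedspectra ablation --train work/train.csv --test work/test.csv --report work/ablation.csv --seed 7
```

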