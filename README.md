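# emgaug

Data augmentation for surface-electromyography (sEMG) gesture datasets.

Gesture-recognition models trained on sEMG are chronically data-starved:
recording sessions are short, fatiguing for subjects, and hard to merge
across labs. `emgaug` inflates a labelled training set with synthetic,
label-preserving variants of the recorded signals, and provides the
bookkeeping (windowing, balancing, leak-free splits) and audit metrics
needed to use them responsibly.

## What it implements

All methods operate on RMS-envelope records `x` of shape
`(n_samples, C)` (C electrodes) and never change the gesture label.

- **GN — additive Gaussian noise.** `x* = x + n`,
  `n ~ N(0, sigma^2)` with `sigma^2 = mean(x_c^2) / SNR` per channel
  (linear SNR; default 30).
- **MW — magnitude warping.** `x* = x . CubicSpline(r)` with knot values
  `r(t_i) ~ N(1, sigma^2)` at T equidistant points (default T=4,
  sigma=0.1); one smooth curve multiplies all channels.
- **WD — wavelet detail scaling.** `x* = IDWT(cA, b . cD)`: an l-level
  DWT per channel, every detail band scaled by `b`, approximation
  untouched (defaults `sym4, l=5, b=3`; the `db7, l=5, b=0` raw-data
  variant is a parameter away). The DWT (Daubechies db1–db20, Symlets
  sym2–sym10, symmetric or periodized boundaries) is built in.
- **SS1 — covariance-matched simulation.** `x* = (w * g) . a + n` with
  `w` multivariate Gaussian matching the record's channel covariance,
  `g` a shaping filter realizing
  `PSD_g(f) = fh^2 f^2 / ((f^2+fl^2)(f^2+fh^2)^2)`, `a` the 15 ms
  moving-average envelope of the record, `n ~ N(0, 0.1^2)`.
- **SS2 — inverse-gamma variance simulation.** Per channel, samples are
  modelled `x_t ~ N(0, s2_t)`, `s2_t ~ IG(alpha, beta)`; `(alpha, beta)`
  are fitted by EM and a fresh variance envelope drawn from the fit
  modulates a unit-variance shaped carrier.
- **Augmentor policies.** `one` (a single uniformly-chosen method),
  `all` (all methods in SSx-WD-MW-GN order), `random` (method k applied
  iff `u_k > p_k`, default `p_k = 0.5`).
- **Sliding windows, ratio R, balancing, splits.** `L x C` images with
  step `tau in [1, L]`; augmentation ratio R = generated/original
  records; per-gesture segment counts balanced by seeded removal;
  train/val/test splits assigned per gesture *repetition* so overlapping
  windows never leak across sets.
- **Cluster metrics.** Silhouette Coefficient and Davies–Bouldin index
  with per-point / per-cluster intermediates, for auditing how augmented
  data sit in a feature space.

## Worked example

```python
import emgaug as ea

ds = ea.generate_fixture(ea.FixtureConfig(rng_seed=7))   # 8 gestures x 10 reps
train, val, test = ea.split_by_repetition(
    ds, train_reps={1, 2, 3, 6, 7, 8, 9, 10}, val_reps={4}, test_reps={5})

aug = ea.build_augmented_dataset(
    train, ea.AugmentationSpec("mw", {"sigma": 0.1}), ratio=9, master_seed=1)
print(len(train), "->", len(aug))

segs = ea.segment(aug, ea.WindowingConfig(L=15, tau=15))
balanced = ea.balance_classes(segs, rng_seed=2)
print(len(segs), "windows,", len(balanced), "after balancing")
```

prints

```
64 -> 640
12800 windows, 12800 after balancing
```

64 training records at R=9 become 64 + 576 = 640; each 300-sample record
yields 20 non-overlapping 15x10 windows; the fixture's gestures are
equally long, so balancing removes nothing here (on real data it trims
the over-represented gestures to the minimum count).

The same pipeline is available from a shell:

```bash
emgaug fixtures --gestures 8 --channels 10 --reps 10 --seed 7 --out data/
emgaug augment data/manifest.json --method mw --ratio 9 --seed 1 --out aug/
emgaug segment aug/manifest.json --window-samples 15 --step 1 --out segs/
emgaug evaluate-clusters features.csv --label-col label --out report.json
```

Every command writes a JSON run-record with the seeds it used.

## Acceptance script

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

recomputes a complete pipeline run from scratch — synthetic dataset,
repetition split, composed SS2-WD-MW-GN augmentation at R=2, overlapping
windows, balancing, and cluster metrics on the flattened windows — and
prints the run summary before writing the results file.

See `docs/methods.md` for the modelling assumptions, parameter defaults
and known limitations.
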