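# Methods

This note records the models behind each augmentation, the parameter
defaults and why they were chosen, the numerical decisions that were
genuinely open, and what the synthetic test data does and does not
establish.

## Signal model and preprocessing

A record is a `(n_samples, C)` matrix at a common sampling rate; the
augmentations assume it is an **RMS envelope** — smooth, non-negative,
slowly varying — not raw interference-pattern sEMG. Two conditioning
presets produce such envelopes: the envelope-style chain (100 ms sliding
RMS, 1st-order 1 Hz Butterworth low-pass) and the raw-style chain that
prepends a 50 Hz notch (2nd-order IIR, Q=30; the quality factor is our
choice — only the notch frequency is standard) and a 5th-order 20–700 Hz
band-pass, then subsamples to 100 Hz.

Filtering is zero-phase (forward–backward). Augmentation cares about
envelope *shape*, not causal latency, and zero-phase keeps the envelope
aligned with the gesture; a streaming implementation would need causal
filters and is out of scope. The RMS window is centered with truncated
edges so every operation is length-preserving, which keeps the windowing
arithmetic exact. Subsampling refuses to upsample; decimation goes
through a polyphase FIR with its standard anti-aliasing.

## The five augmentations

**GN.** Noise variance is `signal power / SNR` with SNR a linear power
ratio, computed *per channel*: channel activations within one gesture
differ by an order of magnitude, and a pooled noise floor would drown
quiet channels (a pooling flag exists). A dB interpretation of SNR sits
behind `snr_is_db` because grid values around 25–35 read naturally as
dB. Defaults: SNR 30 (envelope-style data), 35 suits noisier raw-style
data.

**MW.** T equidistant knots spanning the record (endpoints included) get
values `N(1, sigma^2)`; a *natural* cubic spline through them multiplies
all channels. One shared curve preserves inter-channel amplitude ratios
— the spatial signature that encodes the gesture — with a per-channel
mode available. T is nowhere standardized; the default T=4 over a
record is deliberately conservative (a gentler, lower-frequency warp)
and is a documented, mandatory-to-think-about configuration value.
sigma defaults to 0.1; larger values risk warping one gesture into
another.

**WD.** An l-level DWT per channel; *all* detail bands at all levels are
scaled by b (the alternative reading — only the deepest — is not
implemented), approximation untouched, inverse transform, trim to input
length. A level deeper than the signal supports raises instead of
silently reducing l. Because no wavelet library is available at run
time, the transform is built in: Daubechies filters via spectral
factorization of the binomial half-band polynomial, Symlets via the
least-asymmetric root selection (validated against the published sym4
coefficients to 1e-10). Coiflets are not included: their construction
requires solving nonlinear moment conditions with no factorization
closed form, and neither selected configuration uses them.
Boundary handling is symmetric extension by default; an exactly
orthogonal `periodization` mode exists, and all energy-accounting checks
use it because Parseval holds only for an orthogonal transform —
symmetric extension carries redundant boundary coefficients whose energy
slightly exceeds the signal's.

**SS1.** The carrier is white Gaussian noise, correlated across channels
through the Cholesky factor of the record's channel covariance
(diagonally loaded by `1e-8 * trace/C` to tolerate short, rank-deficient
records), then convolved with the shaping filter g; modulated by the
15 ms moving-average envelope; plus `N(0, 0.1^2)` sensor noise. The PSD
formula fixes only the *shape* of g; the corners are free parameters.
Defaults scale with the rate — `fl = fs/50`, `fh = fs/5`, i.e. 2 and
20 Hz at the 100 Hz envelope rate — keeping the spectral peak inside
the band; for raw 2 kHz sEMG the literature preset is fl=60, fh=120.
g is realized as a 129-tap linear-phase FIR sampled from `sqrt(PSD)` on
a dense grid with a mild Kaiser taper (beta=1): heavier windows
over-smooth the steep low-frequency edge and miss the PSD by >5%,
while beta=1 stays within ~3% across the tested corner configurations.
Filters longer than the record are handled by centered full
convolution.

**SS2.** Per channel, the marginal model `x_t ~ N(0, s2_t)`,
`s2_t ~ IG(alpha, beta)` is fitted by EM using the conjugate posterior
`s2_t | x_t ~ IG(alpha + 1/2, beta + x_t^2/2)`:
the E-step takes `E[1/s2]` and `E[log s2]` in closed form; the M-step
solves `log(alpha) - digamma(alpha) = mean E[log s2] + log mean E[1/s2]`
by Brent root-finding (the left side is strictly decreasing, the right
side non-negative by Jensen, so the root exists) and sets
`beta = alpha / mean E[1/s2]`. The marginal log-likelihood (a scaled
Student-t) is tracked per iteration and is monotone by EM theory; the
fit stops when it improves by less than `tol` (1e-8) or at `max_iter`.
Near the optimum EM crawls, so hitting `max_iter` with `converged=False`
is common and harmless — parameter recovery at N=20000 is within a few
percent after 200 iterations.

Two open readings were settled as follows. The variance multiplier: a
unit-variance carrier times the *square root* of the drawn variance
gives instantaneous variance equal to the drawn value
(`variance_consistent=True`, default); the literal product with the
variance itself is available behind the flag. The variance sequence has
no stated temporal model, so it is drawn i.i.d. per sample and smoothed
with the same 15 ms moving average as SS1's envelope. The IG is fitted
per channel per record (per-gesture pooling would be a different,
unstated model).

## Composition and bookkeeping

`random` mode applies method k iff a uniform draw exceeds `p_k` — i.e.
`p_k` is a **skip** probability, the literal reading of the rule; since
the phrase "with probability p_k" suggests the complement, the
constructor also accepts `apply_probabilities` (stored as `1 - p`). At
the default 0.5 the two coincide. Selection draws come from a stream
separate from the per-method seeds, so `random` with nothing skipped is
bit-identical to `all`. Each (record, copy) pair derives its RNG stream
from `(master_seed, record_index, copy_index)`, making dataset-level
output invariant to processing order.

Windows start at multiples of tau and never cross record boundaries, so
repetition-based splits are leak-free structurally; trailing samples are
dropped, not padded. Balancing removes surplus segments of
over-represented gestures uniformly at random under a seed, down to the
minimum per-gesture count. The default split (test = repetition 5,
validation = 4, rest train) is a convention, not a law; the exact
assignment is user-configurable because published assignments vary.

## Cluster metrics

Silhouette and Davies–Bouldin are computed from their definitions with
Euclidean distance (the standard choice; nothing in the definitions
fixes it) and the singleton-silhouette convention `s = 0`. Reports carry
per-point silhouettes, centroids, dispersions and centroid distances so
a surprising value can be audited. Both agree with scikit-learn to 1e-9
on randomized instances; scikit-learn is used only as a cross-check in
the tests, never as the implementation. Feature vectors are
caller-supplied: typically CNN features in a full study, or raw
flattened windows here. Raw windows of bursty envelopes separate poorly
(quiet stretches of different gestures look identical), so absolute
SC/DB values from the demo pipeline are weak by construction; the
metrics' job in this package is comparative auditing, and no published
feature-space values are reproduction targets (they would require the
original trained networks and datasets).

## Synthetic data

The fixture generator produces what the augmentations consume: per
gesture a non-negative channel-gain row, per repetition a sum of 2–3
Gaussian bursts scaled by that row, plus a small rectified-noise floor
(std 0.02, ~2% of burst amplitude). Defaults — 8 gestures, 10 channels,
10 repetitions, 3 s at 100 Hz — mirror a single putEMG-style subject at
the common envelope rate. What it does **not** emulate: raw
interference patterns, electrode shift, fatigue drift, inter-subject
variability, or realistic gesture-duration imbalance. A green test
therefore establishes the *mechanics* (shapes, determinism, statistical
calibration of the generators, bookkeeping identities), not
classification benefit on real data.

## Numerical conventions

- Sample indexing is 0-based; windows are half-open `[start, start+L)`.
- Seeds are numpy `SeedSequence`-derived and kept below 2^31.
- Manifest CSVs print 17 significant digits and are parsed with
  round-trip float precision, so dataset I/O is lossless.
- DWT coefficient lengths follow `(n + filter_len - 1) // 2`
  (symmetric) and `ceil(n/2)` (periodization); multi-level
  reconstruction replays the forward length bookkeeping.
- Statistical tests use seeded draws with explicitly derived tolerance
  bands (chi-square concentration for SNR; Bartlett's formula, with a
  multiplicity allowance, for autocorrelation of filtered noise).

## Known limitations

- No raw-sEMG physiological simulation (motor units, conduction
  velocity); SS1/SS2 are phenomenological envelope models.
- Coiflet wavelets unavailable (see above).
- Single-rate datasets only; no parsers for proprietary acquisition
  formats — datasets enter via the CSV + JSON manifest.
- `periodization` energy identities are exact for even lengths at every
  level; odd lengths carry one duplicated boundary sample.
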