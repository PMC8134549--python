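# Methods

This note documents the models and procedures implemented in `mielm`, the
parameter choices that matter, what the synthetic generator does and does not
emulate, and the package's known limitations. Nothing here states an
empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## Signal model and preprocessing

A trial is a `channels × samples` segment of EEG (microvolts) cut from a
continuous recording at a cue event. The retained window is assumed to
contain only the imagination phase; defaults are 0.5 s after the cue, 3.0 s
long (the typical Graz-paradigm interval — the competition protocols do not
fix this, so both numbers are configurable). Sample indexing is 0-based and
windows are half-open `[start, start + length)`.

Preprocessing is a band-pass to 0.5–30 Hz: a 4th-order Butterworth applied
forward–backward (`sosfiltfilt`), i.e. zero-phase, which preserves ERD/ERS
latencies. Numerical detail: epochs are short relative to the 0.5 Hz
corner's settling time, and odd-reflection padding of oscillatory trials
excites the near-DC poles into a slow in-band transient; the filter therefore
uses even-reflection padding with `padlen ≈ 3·fs/low_hz` (capped at the trial
length), which measures ≈30 dB stopband attenuation at 50 Hz on 3 s trials
versus ≈11 dB with the default padding.

## Channel selection ("contribution rate")

Each channel is scored by the Fisher discriminant ratio of its per-trial log
band power in 8–30 Hz (mu + beta): between-class variance of the class means
over pooled within-class variance. This is a simple, label-aware proxy for
how much task information a lead carries. Ties break toward lower channel
indices; an all-zero channel scores 0. The top `n_lcd` channels (default 4)
feed the LCD branch, the remainder the CSP branch — the "4 + 18" split on a
22-channel montage. Montages with `n_channels ≤ n_lcd + 1` (e.g. 3-lead
recordings) cannot be split; both branches then use every channel, flagged on
the result (strict mode turns this into an error instead). Ranking is
computed on training folds only inside cross-validation.

## Local characteristic-scale decomposition (LCD)

LCD splits a signal into intrinsic scale components (ISCs), fastest scale
first, by iterated sifting. One sift: for each interior extremum
`(τ_k, X_k)` with neighbours `(τ_{k−1}, X_{k−1})`, `(τ_{k+1}, X_{k+1})`,
the chord value

    A_k = X_{k−1} + (τ_k − τ_{k−1})/(τ_{k+1} − τ_{k−1}) · (X_{k+1} − X_{k−1})

is mixed with the extremum into a baseline knot `L_k = a·A_k + (1 − a)·X_k`;
the knots are interpolated into a baseline, which is subtracted. Choices:

- **Mixing constant** `a = 0.5` (the LCD literature's default), configurable.
- **Knot interpolation**: piecewise linear (default; the simplest scheme that
  preserves the reconstruction invariant), cubic spline behind a flag.
  Boundaries are handled by mirror-extending the outermost two extrema and
  linearly extrapolating the baseline to the signal ends.
- **Stopping**: a component is accepted when its baseline RMS falls below
  `stop_tol = 0.01` × input RMS, or after `max_sifts = 30`; decomposition
  stops at `max_components = 8` or when the residual has fewer than 3
  interior extrema. Signals too short or too smooth to sift (< 5 samples or
  < 4 interior extrema) are returned whole as the residual.
- **Extrema**: strict interior extrema; plateaus count once, at their
  midpoint.

Components plus residual re-sum to the input by construction (subtraction
bookkeeping only); the tests verify max error < 1e−8 on broadband noise.

The feature per component is the time–frequency energy `E = Σ_t |ISC(t)|²`.
Per trial, each selected channel contributes the energies of its first
`n_layers = 3` ISCs, channel-major — 12 values for 4 leads. A channel that
yields fewer components contributes zero-filled energies, keeping the feature
length fixed (the "first three layers" convention does not define this case;
zero-fill is this package's rule).

## Common spatial patterns (CSP)

Per-trial covariances are trace-normalized (`C = XXᵀ/tr(XXᵀ)`) and averaged
per class — the standard Graz formulation. For two classes the generalized
eigenproblem of `(C₁, C₁+C₂)` is solved; the `m` largest- and `m`
smallest-eigenvalue filters are kept (default `m = 2` → 4 filters), and the
filter matrix satisfies `W(C₁+C₂)Wᵀ = I` (verified to 1e−6). For `C > 2`
classes the fit is one-vs-rest — each class against the pooled rest — with
`2m` filters per class (16 features for 4 classes at `m = 2`); pairwise
schemes are not implemented. Filter signs are fixed by making each filter's
largest-magnitude coefficient positive, so output is reproducible across
eigensolvers. Optional scalar shrinkage toward the identity (default off)
regularizes small-trial fits; a singular pooled covariance otherwise raises
an error advising it.

Features are log normalized variances, `f_j = log(var(w_jᵀX)/Σ_k var(w_kᵀX))`;
a zero-variance projection is floored at 1e−12 with a warning.

## Serial feature fusion

The fused vector is `V = [V1, V2]` with each block first scaled to unit
Euclidean norm. The elementwise alternative (every entry mapped to `x/|x|`,
i.e. its sign) is implemented behind `normalization="sign"` for fidelity
experiments, but it discards all magnitude information and is not the
default. A zero block passes through unchanged with a warning. Single-block
modes (`feature_mode="lcd"` / `"csp"`) apply the same normalization to the
one block they use, so ablation comparisons isolate the fusion itself.

## Extreme learning machine (ELM)

A single-hidden-layer network whose input weights and biases are drawn once
from U[−1, 1] (any continuous distribution works; uniform is the
convention here) and never adjusted. With sigmoid activation the hidden
output matrix `H[n,i] = g(w_iᵀx_n + b_i)` is fixed, and the output weights
are the minimal-norm least-squares solution `β̂ = H⁺T` with one-hot targets,
computed by SVD pseudoinverse with `rcond = 1e−12` (not normal equations,
for numerical faithfulness to the Moore–Penrose definition). This solution
attains the global minimum of `‖Hβ − T‖`, has minimal `‖β‖` among
minimizers, and is unique — properties the tests verify against dense
least-squares and null-space perturbation oracles. Prediction is the argmax
of `Hβ`, ties to the lowest class index.

Defaults: `n_hidden = min(100, N)` hidden units (N = training samples),
sigmoid activation, features standardized to training-fold mean/variance
before entering the network (sigmoid saturation control; toggleable). An
optional ridge term exists but defaults to 0 (classic formulation). Note
that at `n_hidden ≈ N` the network interpolates its training set exactly,
which on small noisy feature sets overfits; the end-to-end experiments below
therefore fix `n_hidden = 40`, chosen by the monotone-capacity sweep the
test suite performs (training error is non-increasing in `n_hidden`; held-out
accuracy peaks well below `N`).

## Evaluation protocol

Stratified 5-fold cross-validation, repeated 5 times with fresh fold
assignments. Every stage with fitted state — channel ranking, CSP,
standardization, ELM — is refitted per training fold (LCD energies are
label-free per (trial, channel) and are cached across folds; this leaks
nothing). Reported: Ā = mean fold accuracy, K̄ = mean per-fold kappa with
κ_i = (acc_i − 1/N)/(1 − 1/N). Kappa is averaged over folds, not applied to
Ā — the two differ in general, which is why a published mean kappa need not
equal the kappa of the published mean accuracy. Kappa is negative below
chance (its [0, 1] range presumes at-or-above-chance accuracy).

All randomness flows from one master seed through numpy `SeedSequence`
spawning (per-repetition fold seeds, per-fold ELM seeds), so an `EvalResult`
and every serialized artifact are byte-reproducible from (config, seed).

## Synthetic ERD generator

Each trial is, per channel, 1/f^α noise (α = 1) plus a white floor at −20 dB
relative power, normalized to unit RMS, plus one mu-band and one beta-band
sinusoid with random in-band frequency and phase, each of RMS `snr`
(default 1.0). On the channels informative for the trial's class the
oscillation amplitudes are multiplied by `(1 − erd_depth)` — the ERD
signature, sustained over the whole trial (the epoching step is assumed to
retain only the imagination phase; an onset ramp is available behind a
flag). Defaults: 60 trials per class, 22 channels, 250 Hz, 3 s trials,
`erd_depth = 0.5`; classes claim disjoint channel blocks (4 per class for 2
classes, 2 per class for 4). Under these defaults the full chain scores
Ā ≈ 0.86–0.99 depending on hidden-layer size — separable but not degenerate.

For the end-to-end recovery experiments the difficulty is calibrated
independently of the pipeline: `erd_depth = 0.2` is the depth at which a
single-channel band-power threshold classifier (log 8–30 Hz power of one
informative channel, class-midpoint threshold) scores ≈ 0.9. At that
difficulty the fused pipeline scores Ā ≈ 0.92–0.97 (two-class, 120 trials)
and ≈ 0.75–0.79 (four-class, 240 trials), both far above chance, while a
label-permuted control stays inside the binomial chance interval. Chance
tests use `n = n_trials` independent decisions (one repetition's worth);
repeated CV passes reuse the same trials and add no independent Bernoulli
evidence.

**A finding about these conditions**: fusing V1 and V2 reliably beats the
LCD block alone (5/5 repetition averages in every run observed), but the CSP
block alone typically edges the fused vector by ~1–3 accuracy points here.
This is structural, not numerical: the generator gives the CSP branch 18
channels of which 4 are class-informative and 14 are pure noise, and
supervised spatial filtering isolates that contrast slightly better alone
than when serially concatenated with the weaker unsupervised 4-lead energy
block. On real montages ERD topographies are spatially graded rather than
block-structured, and on very small montages (the 3-lead two-class
competition set) the two branches are of comparable strength — the regime in
which fusion is reported to win. Passing the synthetic recovery tests
therefore demonstrates that the chain extracts the ERD contrast correctly,
not that fusion dominates every ablation on every montage.

What the generator does **not** emulate: volume conduction / spatially
correlated sources, eye-blink and EMG artifacts, non-stationary rhythms,
inter-subject variability. Conclusions about artifact robustness or
cross-subject transfer cannot be drawn from these tests.

## Degenerate inputs and numerical conventions

- Zero-power channels: ranking score 0 with a warning.
- Zero-variance CSP projections: feature floored at `log(1e−12)`.
- Zero feature blocks: passed through fusion unnormalized, with a warning.
- Feature standardization floors the per-feature standard deviation at 1e−12.
- Pseudoinverse `rcond = 1e−12`; whitening and optimality tolerances 1e−6 /
  1e−9 as asserted in the tests.
- Epoch windows that exceed the recording are dropped with a warning; an
  epoch set with no usable events is an error.

## Known limitations

- The 4-class CSP scheme is one-vs-rest only.
- No artifact rejection beyond the band-pass; no online/streaming operation.
- GDF reading requires the optional `mne` dependency; there is no GDF
  writer (round-trip fixtures use the package's MAT and NPZ writers).
- The ELM is the classic batch formulation: no kernel, sequential, or pruned
  variants.
- Published competition-data accuracies depend on unstated epoch windows and
  hyperparameters; `scripts/competition_protocol.py` reproduces the protocol
  but qualitative agreement is all that can be expected.
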