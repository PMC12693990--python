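# Methods

## Problem and scope

A voltammetric electronic tongue drives an array of six dissimilar metal
electrodes (Ag, Au, Ti, Pd, Pt, W) with a shared multi-frequency
large-amplitude pulse voltammetry (MLAPV) excitation and records each
electrode's current response. The multichannel "fingerprint" is then used to
discriminate the production year (vintage) of a liquor sample among five
consecutive years (2016–2020). This package implements the *analysis* side of
that instrument: waveform construction, a statistical simulator of the array's
responses, normalization, per-pulse feature extraction, three classifiers
(linear SVM, random forest, 1D-CNN), and evaluation/visualization. Hardware
control, the wet-chemistry protocol, and electrochemical fidelity of the
simulator are all out of scope.

## Excitation waveform

The MLAPV protocol steps from −1 V to +1 V in 0.1 V increments, holding each
level for 0.1 s, sampled 40 times per plateau (400 Hz nominal), with a 2 s
0 V hold after the train for electrode desorption. The published counts are
42 plateaus and 42 × 40 = 1680 samples per electrode; 21 ascending levels with
a 0 V recovery plateau after each level is the simplest ladder consistent with
those counts, and is the convention adopted here (`paired_with_recovery`).
The exact plateau ordering of the original instrument cannot be recovered from
the text, so the ladder is configurable (`ladder_scheme="custom"` with an
explicit level list). The hold is modeled but unsampled, matching the
1680-point count. Indexing is 0-based with half-open ranges throughout.

## Signal simulator

The instrument's dataset is not public, so the package generates a synthetic
stand-in with the structure the signals are described to have, per electrode
`e`, class `c`, plateau `p` (level `V_p`, previous level `V_{p-1}`, with
`V_{-1} = 0`), and in-plateau time `t` seconds from the plateau edge:

    I(t) = baseline_e + g_{e,c} · V_p
           + a_e · (V_p − V_{p-1}) · exp(−t / τ_{e,c}) + ε,
    ε ~ Normal(0, σ_e²) i.i.d. per sample

* `baseline_e` = 28 mA on every channel — the uniform non-Faradaic offset of
  the two-electrode front end. It is deliberately class-invariant so the
  pipeline's offset-insensitivity is a testable claim.
* `g_{e,c}` (mA/V) — ohmic conductance; the dominant, predominantly linear
  current–voltage component.
* the transient term — a first-order step response at each plateau edge
  (interfacial charging/polarization), with electrode-specific amplitude
  `a_e` (mA/V) and time constant `τ_{e,c}` (s).
* `σ_e` — per-sample measurement noise, default 0.05 mA.

Default per-electrode values (conductance 3.5–7.0 mA/V, transient amplitudes
1.5–3.0 mA/V, time constants 15–40 ms) were chosen once so that currents span
roughly 21–35 mA over the ±1 V ladder and transients decay well inside a
0.1 s plateau; they are package defaults, not fitted constants.

Vintage classes modulate only `g` and `τ`, multiplicatively:
`mult = 1 + delta · u`, `u ~ Uniform(−1, 1)`, drawn once per
(electrode, class) from a generator seeded by
`(modulation_seed, electrode_index, class_index)`. Two independent seed
streams — `modulation_seed` for class structure, `noise_seed` for per-sample
noise — allow regenerating the same "population" with fresh noise. `delta` is
the separability dial: `delta = 0` makes classes statistically identical
(multipliers exactly 1); the default `delta = 0.2` with 0.05 mA noise gives
near-separable classes; `delta ≈ 0.02` produces the partial overlap seen
between adjacent vintages in real measurements.

What the simulator does **not** emulate: Faradaic peaks, drift/fouling,
temperature effects, non-Gaussian or temporally correlated noise, and any
within-class structure beyond i.i.d. noise around a fixed class template.
Passing tests therefore demonstrate that the *pipeline* behaves correctly and
recovers class structure of this form — not that the published real-data
accuracies are reproducible (they are explicitly not targets; the instrument
data are unavailable).

## Preprocessing

Min–max normalization per feature (column): `x ↦ (x − x_min)/(x_max − x_min)`
with statistics from the fitted data. Design choices where the protocol is
silent: statistics are fitted on the **training split only** by default (an
`all` scope is retained for literal reproduction); constant columns map to 0
(the 0/0 case); held-out values outside the fitted range are not clipped.
Because the statistics are per-column, adding any constant to a column or
rescaling it by a positive factor leaves the output invariant after refit —
this operationalizes the claim that the uniform ~28 mA instrument baseline is
non-informative. Normalization is applied to raw signals *before* both
feature extraction and CNN input.

## Feature extraction

Three per-plateau descriptors per electrode (6 × 42 = 252 columns each):

* **AREA** — trapezoid-rule integral of the first 20 samples after the pulse
  edge, with unit (sample-index) spacing. "The 20 points following each
  pulse" is read as samples 0–19 of each plateau, where the transient lives;
  the window start/length are configurable since the original placement is
  ambiguous. Unit spacing keeps examples exact (constant c → area 19c);
  scale constants are irrelevant to classifiers.
* **MAX / MIN** — extrema over the full 40-sample plateau (the descriptors
  are deliberately separated from the 20-point window).
* **ORIGINAL** — the untouched normalized 10,080-vector.

Columns are ordered electrode-major (Ag, Au, Ti, Pd, Pt, W), then
plateau-ascending.

## Classifiers

* **SVM** — linear kernel, C = 6 (the tuned values), one-vs-rest multiclass
  (the protocol is silent; configurable). Grid search is exhaustive stratified
  5-fold cross-validation with ties broken toward the first-listed candidate;
  default grids bracket the tuned optima (C ∈ {0.1, 1, 6, 10, 100},
  kernel ∈ {linear, rbf}; RF trees ∈ {16, 32, 64, 128}, depth ∈ {4, 8, 16},
  features ∈ {4, 8, 16, √d}).
* **Random forest** — 64 trees, depth 8, 8 features per split. Prediction is
  a hard majority vote among trees (ties toward the lowest class label), with
  per-tree votes exposed for audit, matching the described voting mechanism.
* **1D-CNN** — four convolution stages (32 kernels of 16, 32 of 8, 64 of 4,
  64 of 2), all stride 2, ReLU, each followed by max pooling of size 2 and
  stride 1; flatten; dropout 0.3; dense softmax head with 5 units.
  Categorical cross-entropy, Adam at 0.001, batch size 32, 100 epochs by
  default. The engine is a self-contained NumPy implementation (im2col
  convolutions on BLAS, explicit backprop) with one seeded generator driving
  initialization (uniform fan-in), shuffling and dropout, so identical
  config + data + seed give bit-identical weights.

CNN numerical choices where the protocol is silent: 'same' padding for
convolutions and 'valid' for pooling, so every layer length follows a simple
rule (halve with ceiling, then shrink by one) and no sequence tail is dropped;
for a 10080 × 1 input the lengths run
10080 → 5040 → 5039 → 2520 → 2519 → 1260 → 1259 → 630 → 629 and the static
audit table (shapes + parameter counts, e.g. conv1 = 16·1·32 + 32 = 544) is
the artifact's ground truth. The size-2/stride-1 pooling is retained verbatim
even though it is a near-no-op. One-hot class order is ascending year; argmax
ties resolve to the lowest class index. Within each minibatch the gradient is
accumulated over small cache-resident chunks (default 4 samples); this is a
memory-locality device only — the per-batch update is the exact batch mean
gradient either way (weights agree to float32 summation order).

Input layout default is the horizontally concatenated single-channel sequence
(`concat_1ch`, 10080 × 1); a `multi_6ch` layout (1680 × 6) is retained as the
alternative multichannel reading.

## Evaluation

Accuracy and confusion matrices (rows = true, columns = predicted, classes in
ascending year order); model comparison sorted by accuracy with ties broken by
name. The LDA map solves the Fisher generalized eigenproblem on between- and
within-class scatter, adding a ridge `1e-6 · tr(Sw)/d · I` to the
within-class scatter when it is singular (d ≫ N). LDA consumes the AREA
table by default (d = 252, well-conditioned at N = 500); the original study
does not state what its LDA consumed, so the choice is labeled in outputs.
Class centroids are exact means of projected scores; the "95% confidence"
regions are covariance ellipses scaled by the χ²(2 dof) 0.95 quantile.
Degenerate covariances floor the semi-axes at machine epsilon with a warning.

## Verification study sizes

The statistical acceptance checks run the full 5 × 100 design with 0.8/0.2
stratified splits (100-sample test sets):

* Null control (`delta = 0`): SVM and RF over 10 replicate seeds, the
  20-epoch CNN over 3 replicate seeds; each model's mean test accuracy must
  lie inside the central 99% binomial band around 0.20 for n = 100
  ([0.10, 0.31]).
* Signal recovery (`delta = 0.2`, 0.05 mA noise): SVM on AREA over 10 seeds
  (mean ≥ 0.85); the 20-epoch CNN over 3 seeds (every replicate > 0.35).
* Offset control: +5 mA added to every raw current changes zero test-set
  predictions for all three classifiers.

Twenty epochs is the desk-scale CNN training length used throughout the
verification suite (one 20-epoch run on 400 signals takes roughly two minutes
on a single CPU core); the 100-epoch default remains available for full
training runs. Replicate counts (10 classical / 3 CNN) are the package's
verification study size.

## Known limitations

* The simulator is a statistical stand-in; none of its accuracies transfer to
  real instrument data, and the published real-data accuracies (94.0/91.0/
  78.0%) are not reproduction targets.
* Within-class variability is i.i.d. Gaussian around a fixed class template;
  real inter-sample variability within a vintage is undocumented.
* The plateau ordering of the original excitation and the exact placement of
  the 20-point integration window are documented conventions, not recovered
  facts.
* The CNN engine is CPU-only and sized for this architecture family; it is
  not a general deep-learning framework.
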