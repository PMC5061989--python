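# Methods

## Signal model and feature pipeline

Input is a 14-channel EEG time series sampled at 128 Hz, treated as
unitless amplitudes (consumer headsets do not expose a calibrated scale;
nothing downstream depends on one). The pipeline cuts each recording into
2-s windows (256 samples) hopped by 50%, so a T-second recording yields
⌊(128·T − 256)/128⌋ + 1 windows and trailing partial windows are dropped —
a fixed-size transform needs whole windows.

Within a window each channel is mean-centred, multiplied by the Hamming
taper h(t) = 0.54 − 0.46·cos(2πt/(W−1)) to limit spectral leakage, and
transformed; the DFT magnitude at bins 0–63 (0–31.5 Hz, 0.5 Hz spacing)
of every channel is concatenated into one 896-long feature row. Only the
first 64 of the 128 unique bins are kept: that covers the delta-through-
gamma EEG range, and the DC bin is ≈0 after centring. Magnitude rather
than power keeps features on the amplitude scale; the choice is absorbed
by the later min–max scaling.

Features are ranked by information gain of the class given the feature,
in bits. Continuous features are discretised into 10 equal-frequency bins
whose edges are order statistics (`method="lower"`), which makes scores
invariant under any strictly monotone rescaling of a feature — relevant
because headset units are arbitrary. Ties rank by ascending feature index
so selection is deterministic. The top k = 100 features are kept (a fixed
count, not a score threshold, so the input dimension of the classifier is
stable), then min–max scaled to [0, 1] with bounds from training data
only; out-of-range application data is clipped. Inside cross-validation
the bounds are re-fit on each fold's training portion.

## The TSK fuzzy network

r rules over m inputs and n outputs. Per rule j: Gaussian memberships
μ1ⱼ(xᵢ) = exp(−(xᵢ−cᵢⱼ)²/σᵢⱼ²) (note: σ², not 2σ², in the exponent — the
widths are fitted, so the convention is absorbed), product-t-norm firing
strength μⱼ = Πᵢ μ1ⱼ(xᵢ), linear consequent yⱼ = Σᵢ aᵢⱼxᵢ + bⱼ, and
outputs u_k = Σⱼ w_jk μⱼ yⱼ / Σⱼ μⱼ. The product conjunction is the
default because it is smooth — the analytic gradients below require it; a
`min` conjunction is available for inference only. The mixing weights
w_jk on top of per-rule linear consequents are a deliberate part of this
architecture (they let n outputs share r rule responses) even though
classic TSK systems omit them.

Numerics: with m = 100 scaled inputs, Σᵢ((xᵢ−cᵢⱼ)/σᵢⱼ)² routinely exceeds
700 and every raw μⱼ underflows to zero. Since u and every gradient
depend on the μⱼ only through ratios μⱼ/Σμ, all forward and gradient
paths subtract the per-sample minimum rule exponent before exponentiating
(the largest μ becomes exactly 1). This is exact, not an approximation.

Classification is argmax over the n outputs, ties to the lowest index.

## Training

Antecedent initialisation: fuzzy c-means (fuzzifier 2.0, tolerance 1e-6
on centre movement) is run once on the joint scaled feature space with
r clusters — one rule per cluster. Centres are seeded with r distinct
data points: seeding from random memberships places every initial centre
at the grand mean, a degenerate FCM fixed point that high-dimensional
data does not escape. Rule widths are α = 0.5 times the distance to the
nearest *distinct* other centre, floored at 0.01. Distinct matters: when
r exceeds the number of natural clusters FCM parks surplus centres on the
same point, and measuring against such a duplicate would create zero-
width rules that never fire and cannot recover (their gradients scale
with μⱼ). If all centres coincide, or with a single rule, widths fall
back to the per-dimension data standard deviation.

Consequents and mixing weights start i.i.d. uniform on [−1, 1].

All five parameter groups are updated per sample (index t) with momentum:

    p(t+1) = p(t) − γ ∂E/∂p + λ(p(t) − p(t−1)),  E = ½ Σ_k (u_k^d − u_k)²

against one-hot targets, in a seeded shuffled order each epoch; a
full-batch mode (mean gradient, one update per epoch) is available. The
partials are the exact derivatives through the normalised mixing — in
particular ∂u_k/∂μⱼ = (w_jk·yⱼ − u_k)/Σμ, including the mixing weight —
and are verified in the test suite against central finite differences to
1e-5. Widths are clamped at the width floor during updates so no
membership degenerates.

Learning-rate schedule (bold driver with reset): after each epoch the
RMSE of the updated parameters on the training portion is compared with
the previous epoch's. Improvement grows γ by 1.05; a regression within
4% is accepted but shrinks γ by 0.7; a larger (or non-finite) regression
rolls the epoch back, zeroes the momentum and shrinks γ. Acceptance is
judged on the post-epoch RMSE, not the online within-epoch average — an
epoch can average well while ending in a ruined state, and accepting it
on the average leaves the optimiser stuck. If γ falls below 1e-15 while
still regressing, training aborts with `TrainingDivergedError`.

Defaults: 1000 epochs, r = 6 rules, initial γ = 0.001, momentum λ = 0.9.
The conservative initial rate is deliberate: per-sample steps at
γ ≈ 0.05 on 100 inputs are violently unstable — single epochs kill rules
(μ ≈ 0 on all data) and inflate weights past recovery while still
*lowering* RMSE from its random start, so no RMSE-based rollback can
catch it. Starting low costs only ~30 epochs of bold-driver growth and
removes that failure mode entirely.

Reported quantities: "training RMSE" is the post-epoch RMSE over the
training portion; "evaluation RMSE" is a stratified 10% slice held out
from the updates and monitored per epoch (skipped when the data cannot
support a stratified slice); "test RMSE" is the held-out cross-validation
fold. RMSE is √(mean over all samples and outputs of squared error), and
per-fold values are averaged across folds. Cross-validation is
stratified k-fold (default 10), each window tested exactly once; if the
smallest class has fewer windows than folds, a warning is issued and the
fold count drops to that size.

A single run seed fans out (via seed sequences) to independent seeds for
FCM, parameter initialisation, epoch shuffling, the evaluation split and
the fold split, so runs are bitwise reproducible and components are
independently reproducible.

## Synthetic data

The generator emulates the measurement protocol — six command classes,
10 s (default) of 14-channel 128 Hz signal per class — with each class a
set of sinusoidal tones (random phase per channel) on a class-specific
channel subset plus white Gaussian noise (σ = 0.05 default) on all
channels. The neutral pose is a faint 10 Hz posterior rhythm; command
classes carry distinct frequency pairs with ~25× neutral's tone power,
mirroring the empirical observation that gesture EEG fluctuates far more
than a resting pose. All tone frequencies sit on exact 0.5 Hz bins below
32 Hz so they land inside the feature band.

What this validates: windowing, spectral extraction, ranking, selection,
scaling, training, cross-validation and the safety layer, end to end,
with known ground truth. What it does not emulate: 1/f background
spectra, blink/EMG artefacts, non-stationarity, electrode drift or
inter-subject variability — so perfect accuracy here demonstrates
pipeline correctness, not expected performance on real EEG.

The six default classes are forward, backward, left, right, switch_on
and neutral. Neutral is included (rather than switch_off, for which a
class recipe still exists) because the safety layer can only stop the
chair via
a classified neutral; a protocol without it could never leave a motion
state.

## Safety layer

Classified commands pass a debouncer (k = 3 identical consecutive
windows, counter resets on change, a held command keeps driving) and a
total transition function: off → neutral only via switch_on; neutral
accepts any motion; a motion state accepts only neutral, its own command
or switch_off; switch_off is an emergency stop from any state. Left↔right
is guarded exactly like forward↔backward — the reversal hazard is
symmetric. The no-direct-reversal property is checked by exhaustive
enumeration of all state × command pairs.

## Problem sizes and experiment designs used by the tests

The headline check runs the full pipeline on 60 s per class (354 windows
of 100 features) with 10-fold CV at the complete 1000-epoch budget for
r ∈ {6, 9, 16}; with the JIT-compiled update loop this takes on the
order of a minute. The function-recovery experiment fits data generated
by a known same-shape network (m = 5, r = 3, n = 2, noise-free targets)
whose rules sit on a three-cluster input structure; the clusters make
the rule partition identifiable — with uniformly distributed inputs the
teacher's partition is unidentifiable and gradient descent demonstrably
plateaus in antecedent local minima, which says nothing about the
training machinery being tested.

## Known limitations

- Per-sample gradient descent with momentum is sensitive to the initial
  rate; the bold driver recovers from oscillation but cannot resurrect a
  rule whose firing strength has collapsed on all data. The conservative
  default rate avoids this; users raising γ should watch for dead rules.
- FCM in ~100 dimensions with fuzzifier 2.0 yields nearly uniform
  memberships; it is used only to place centres, and widths come from
  centre geometry, not membership spread.
- Information gain is computed feature-by-feature; jointly informative
  but marginally weak feature pairs can be dropped.
- The min t-norm option cannot be gradient-trained (non-differentiable
  at the switching points); it is inference-only.
- The time-domain (no-FFT) feature path is exposed (`spectral=False`,
  CLI `--no-fft`) but is not part of the evaluated protocol.
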