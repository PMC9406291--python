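# Methods

This note documents the models, numerical choices and known limitations of
`utfbssp`, in the spirit of a methods appendix.

## Decoding model

The decoder assumes two-class epoched EEG in which class information is
carried by *band-limited variance differences* (event-related
desynchronization/synchronization): in some frequency band, some spatial
projection of the data has systematically different power between movement
imagery and rest. Three components operationalize this assumption.

### Upper-triangle filter bank

Sub-bands are enumerated as all pairs (L, U) with
L ∈ {f_min, f_min + lower_step, …}, U = L + min_width + k·width_step ≤ f_max,
ordered row-major by (L, U). With the defaults
(f_min=4, f_max=42, lower_step=2, width_step=4, min_width=4) this yields
exactly 90 bands, from 4–8 Hz up to 38–42 Hz; widths range over
{4, 8, …, 36} Hz. The overlapping widths matter: discriminative rhythms do
not respect canonical band edges, and wide bands let a single group capture
structure that spans α and β.

Filtering is a Butterworth band-pass of order 4 (configurable), realized in
cascaded second-order sections for numerical stability of the narrow bands,
and applied forward–backward by default (zero phase, effective order 8,
squared magnitude response). Offline decoding justifies non-causal
filtering; a causal single-pass mode exists for simulated-online use. Edge
effects are handled by odd-reflection padding of length
3·(2·n_sections + 1) samples by default (configurable); epochs must exceed
the pad length.

### CSP per sub-band

Per-trial covariances are computed as X·Xᵀ and, for class means only,
trace-normalized (each trial contributes unit total power, which removes
trial-to-trial gain differences). Mean-centering of trials is off by
default — band-passed signals are already zero-mean up to edge effects —
and both choices are configurable. Class means are the unweighted
arithmetic means over each class's trials.

The CSP eigenproblem C₁w = λC₂w is solved through the symmetric-definite
form C₁w = μ(C₁+C₂)w with λ = μ/(1−μ), which LAPACK handles stably and
which yields the conventional normalization wᵀ(C₁+C₂)w = 1. A diagonal
shrinkage (1−γ)C + γ·(tr C/N)·I with γ = 1e−6 guards against singular
class sums; γ is configurable and purely numerical at its default.
For Nₛ filters the ⌈Nₛ/2⌉ eigenvectors of largest and ⌊Nₛ/2⌋ of smallest
eigenvalue are kept (odd Nₛ favours the large end); ties in eigenvalues
keep solver order via a stable sort.

Features are z = diag(WᵀXXᵀW) from the *unnormalized* scatter. By default
they are log-normalized, z ← log(z/Σz), which makes them invariant to
global scale and much better conditioned for the downstream linear model;
the raw-variance mode is retained as an option. Under the log, components
are floored at 1e−15 of the trial's total projected variance; a trial with
zero total variance is an error.

### Group lasso over sub-band groups

The selection model is

min_a Σᵢ (yᵢ − aᵀuᵢ)² + λ Σ_g ‖a_G‖₂,

with the plain (unscaled) residual sum of squares, unweighted group norms
(all groups have equal size Nₛ, so √|G| weights would only rescale λ), and
labels coded y ∈ {−1, +1}. There is no intercept in the model; instead y
and the columns of U are centered before fitting and the intercept is
reconstituted for prediction. Columns are scaled to unit variance by
default so that selection is not driven by raw feature scale; a literal
mode with no centering/scaling exists and is what the closed-form and
oracle tests exercise. λ_max = max_g 2‖U_Gᵀy‖₂ follows from the
subgradient condition at a = 0 under this scaling.

The solver is cyclic block coordinate descent with **exact block updates**:
each group subproblem min_b ‖r − U_G b‖² + λ‖b‖ is solved via the
eigendecomposition of U_GᵀU_G and a one-dimensional Brent root find on
t = ‖b‖ (the function ‖(tΛ + λ/2)⁻¹q‖/t − 1 is strictly decreasing, so the
root is unique; components of U_Gᵀr on numerically null eigendirections
are clipped since they are round-off). Convergence is declared when the
largest blockwise KKT violation falls below `tol` (default 1e−8);
non-convergence returns the model with `converged=False` and a warning
rather than raising. An active-set schedule (full sweeps alternating with
sweeps over the nonzero groups, the active phase solved only to a fraction
of the current global violation) avoids wasting iterations polishing a
support that is about to change. The residual vector is refreshed from
scratch at every full sweep because thousands of in-place updates
accumulate drift. Groups count as selected when ‖a_G‖₂ > 1e−10.

Inside the pipeline the tolerance is scaled by λ (`gl_tol`, default 1e−3
per unit λ): the zero-group KKT condition compares a correlation against
λ, so a λ-relative tolerance is the dimensionally meaningful stopping rule
there, and the heavily correlated overlapping-band features otherwise
produce long convergence tails that change the selected support by
nothing. The standalone solver keeps its strict absolute default.

### Cross-validation and classification

Nₛ (default grid {2, 4, 6}) and λ (default fractions
{0.5, 0.3, 0.2, 0.1, 0.05} of the fold's λ_max, warm-started descending)
are chosen by stratified k-fold CV (default 5 folds, seeded). All fitted
state — per-band CSP, feature standardization, group-lasso selection, SVM
— is computed from training folds only; a unit test corrupts
validation-fold data and asserts the fold extractors are bit-identical.
The selection rule is pooled validation accuracy with ties broken toward
smaller Nₛ, then larger λ (simpler models). The SVM is a linear-kernel
SVC; its cost grid defaults to the single value C = 1, keeping model
selection focused on Nₛ and λ, and is configurable (an RBF kernel is a
config switch away). The final model is refit on all training trials at
the chosen hyperparameters. If the group lasso selects nothing, the single
group with the largest screening correlation 2‖U_Gᵀy‖ is kept with a
warning.

The trial time window (start, end in seconds) is a required configuration
field: decoding accuracy depends strongly on it and no universal default
is defensible.

Prediction filters only the selected sub-bands, making it roughly
selected/90 the cost of training-time feature extraction.

## Synthetic data

The generator emulates the statistical structure the decoder exploits and
nothing more: each source is white noise band-passed to its rhythm
(filtered with generous padding so transients do not leak into trials),
normalized to unit variance and scaled per trial by a class-dependent
standard deviation; sources are mixed into channels by a random orthogonal
matrix and buried in i.i.d. broadband Gaussian sensor noise. Defaults
describe the study condition used throughout testing: 250 Hz, 2 s trials,
10 channels, 60 trials per class, ERD depth 0.5 (class-1/class-2 std
ratio, i.e. a 4× band-power ratio) in α (8–13 Hz) and β (14–30 Hz),
source std 1 against noise std 0.5. Mixing and trial noise have separate
seeds so "same head, new session" held-out data is one seed change away.

What it deliberately does **not** model: time-resolved desynchronization
(class variance is static within a trial), 1/f background spectra,
artifacts (blinks, EMG), volume-conduction head geometry, non-stationarity
across trials, or class imbalance. Passing tests on this generator
therefore demonstrate that the machinery — band decomposition, variance
contrast extraction, group-level selection — is correct and recovers
planted structure at realistic SNR; they do not certify accuracy levels on
real recordings, where those unmodeled factors dominate difficulty. The
near-ceiling accuracies on the default condition reflect the generator's
cleanliness, not an expected field result.

The band-recovery score is interval arithmetic: the union of selected
sub-band intervals is intersected with the union of planted rhythm
intervals, and the covered fraction of the planted length is reported.

## Diagnostics

Time-frequency maps use Morlet wavelets (via MNE, default 5 cycles,
default 1 Hz resolution over 4–42 Hz), averaged over trials then expressed
per frequency row in dB relative to a baseline window; trials are
mean-detrended first so DC offsets cannot leak into low frequencies. The
rhythm breakdown runs the plain single-band CSP+SVM baseline per canonical
rhythm inside a stratified k-fold. Spatial topographies report both the
filters W and the activation patterns A = C̄W(WᵀC̄W)⁻¹ with C̄ the pooled
covariance — patterns, not filters, are the physiologically interpretable
scalp projections. All diagnostics return arrays/DataFrames; rendering is
left to the caller.

## Problem sizes used in the shipped checks

The automated checks run the default study condition (10 channels,
120 trials, 90 bands) for ten generator seeds for rhythm recovery, one
seed for the null control, 50 random matrix pairs for the CSP oracle, and
50 random instances (m ≤ 40, p ≤ 20, k ≤ 6) for the group-lasso
certificates, with the proximal-gradient oracle run on half of them.
Property tests use further scaled-down variants (6 channels, ≤ 48 trials,
1 s windows) of the same condition.

## Known limitations

- Binary classification only; multi-class would need one-vs-rest wrapping.
- The group lasso is the plain variant: no sparse-group or overlapping
  extensions, no √|G| weights.
- The CSP covariance pipeline assumes epochs are clean; there is no
  artifact rejection or robust covariance option.
- The GDF/EDF import adapter is a thin convenience over MNE and inherits
  its event-annotation semantics; it is not exercised by the test suite
  beyond its interface.
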