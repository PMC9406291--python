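# utfbssp — sparse filter-bank CSP decoding of motor-imagery EEG

`utfbssp` decodes two-class motor-imagery EEG (movement imagery vs. rest)
by combining an **upper-triangle filter bank**, per-band **common spatial
patterns** (CSP), **group-lasso** sub-band selection and an SVM classifier.
It is aimed at BCI researchers who want a decoder that not only classifies
well but also *identifies which frequency sub-bands* carry the
event-related desynchronization (ERD) driving the decision — e.g. to
compare stimulation conditions or subjects by the rhythms they recruit.

## Method

1. **Filter bank.** The range 4–42 Hz is decomposed into every sub-band
   with lower edge L ∈ {4, 6, …, 38} Hz and width 4 + 4k Hz whose upper
   edge stays ≤ 42 Hz — an "upper triangle" of (edge, width) combinations
   containing exactly 90 overlapping bands, covering the θ (4–8), α (8–13),
   β (14–30) and γ (30–42 Hz) rhythms. Each band is a zero-phase
   Butterworth band-pass.

2. **CSP per sub-band.** For each band *i*, with class-mean covariances
   C₁, C₂, CSP maximizes/minimizes J(w) = (wᵀC₁w)/(wᵀC₂w). The spatial
   filter matrix Wⁱ ∈ ℝ^(N×Nₛ) collects the generalized eigenvectors of
   (C₁, C₂) — equivalently eigenvectors of C₂⁻¹C₁ — with the ⌈Nₛ/2⌉
   largest and ⌊Nₛ/2⌋ smallest eigenvalues. Per trial the features are the
   filtered variances zⁱ = diag(WⁱᵀXXᵀWⁱ), log-normalized by default.

3. **Group lasso.** All bands' features are concatenated into
   u = [z¹, …, z⁹⁰] and a sparse linear model is fit by minimizing

       Σᵢ (yᵢ − aᵀuᵢ)² + λ Σ_g ‖a_G‖₂ ,   y ∈ {−1, +1},

   with one coefficient group per sub-band. The L2 group penalty zeroes
   out whole sub-bands; the surviving groups are the selected bands. The
   solver is block coordinate descent with exact block minimization
   (certified by KKT residuals); λ_max = max_g 2‖U_Gᵀy‖ is the path
   endpoint.

4. **Classification.** A linear SVM on the selected features. The filter
   count Nₛ and the penalty λ are chosen by stratified cross-validation
   carried out entirely inside training folds (no leakage into validation
   trials).

A synthetic generator plants band-limited sources with class-dependent
variance (ERD) under orthogonal spatial mixing and broadband noise, so
every stage is testable without recordings, including whether the selected
sub-bands recover the planted rhythms.

## Worked example

`python examples/04_full_pipeline.py` trains the decoder on synthetic
120-trial, 10-channel EEG with ERD of depth 0.5 planted in α and β and
prints:

```
training data: 120 trials, 10 channels, 250 Hz
cross-validated accuracy: 100.0%
chosen Ns=2, lambda fraction=0.5
selected sub-bands:
  band  8: 4-40 Hz
  band 17: 6-42 Hz
  band 39: 12-36 Hz
  band 40: 12-40 Hz
  band 47: 14-42 Hz
overlap with planted alpha+beta rhythms: 1.00
held-out accuracy: 100.0% on 120 new trials
confusion counts:
[[60  0]
 [ 0 60]]
```

The five selected sub-bands jointly cover the planted 8–13 Hz and
14–30 Hz rhythms (overlap score 1.00), and the model decodes unseen trials
from the same condition perfectly. The other examples walk through the
filter bank (`01`), CSP features (`02`), the regularization path (`03`)
and the ERD diagnostics (`05`).

A thin CLI mirrors the library:

```sh
utfbssp simulate --out epochs.npz
utfbssp train --data epochs.npz --config pipeline.yaml --out model.joblib
utfbssp predict --model model.joblib --data epochs.npz --out pred.csv
utfbssp evaluate --model model.joblib --data epochs.npz
```

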