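"""Fit CSP on one sub-band of synthetic ERD data and look at the features.

CSP solves the generalized eigenproblem C1 w = lambda C2 w on the two
class-mean covariance matrices; the extreme eigenvalues give the spatial
projections along which the class variance ratio is most distorted by the
planted desynchronization.
"""

import numpy as np

from utfbssp import (
    FrequencyBand,
    SyntheticConfig,
    bandpass_epochs,
    class_covariances,
    extract_features,
    fit_csp,
    generate,
)

ds = generate(SyntheticConfig(mixing_seed=0, trial_seed=0))
alpha = bandpass_epochs(ds.epochs, FrequencyBand(8.0, 13.0))

cov = class_covariances(alpha)
filt = fit_csp(cov, n_filters=4)
print("generalized eigenvalue spectrum (descending):")
print(np.round(filt.eigvals, 3))
print(f"kept filters correspond to eigenvalues {np.round(filt.selected_eigvals, 3)}")

feats = extract_features(filt, alpha, log_transform=True)
z = feats.values
for label in (1, 2):
    mean = z[ds.epochs.labels == label].mean(axis=0)
    print(f"class {label} mean log-variance features: {np.round(mean, 2)}")
# The imagery class (1) carries *less* alpha power than rest (2): ERD.
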