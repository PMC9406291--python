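"""Trace the group-lasso regularization path over sub-band feature groups.

Each of the 90 sub-bands contributes one group of CSP features; the group
penalty lambda * sum_g ||a_g|| zeroes out whole sub-bands.  Sweeping lambda
from lambda_max (everything zero) downward shows the informative bands
entering the model first.
"""

import numpy as np

from utfbssp import (
    GroupedFeatureMatrix,
    SyntheticConfig,
    apply_filterbank,
    build_utfb,
    class_covariances,
    extract_features,
    fit_csp,
    generate,
    lambda_max,
    regularization_path,
)

ds = generate(SyntheticConfig(n_channels=6, n_trials_per_class=30,
                              trial_duration=1.0, mixing_seed=2, trial_seed=2))
spec = build_utfb()
ns = 2

blocks = []
for banded in apply_filterbank(ds.epochs, spec):
    filt = fit_csp(class_covariances(banded), ns)
    blocks.append(extract_features(filt, banded).values)
U = np.hstack(blocks)
groups = [np.arange(i * ns, (i + 1) * ns) for i in range(len(spec))]
y = np.where(ds.epochs.labels == 1, 1.0, -1.0)
feat = GroupedFeatureMatrix(U, groups, y, band_indices=np.arange(len(spec)))

lmax = lambda_max(feat)
print(f"lambda_max = {lmax:.2f} (smallest penalty with an all-zero solution)")
grid = lmax * np.array([1.1, 0.7, 0.5, 0.3, 0.15])
for model in regularization_path(feat, grid):
    bands = [f"{spec[int(g)].low_hz:g}-{spec[int(g)].high_hz:g}Hz"
             for g in model.selected[:4]]
    more = "..." if model.selected.size > 4 else ""
    print(f"lambda={model.lam:8.2f}  selected groups={model.selected.size:2d}  "
          f"{bands}{more}")
# The first groups to enter cover the planted alpha/beta desynchronization.
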