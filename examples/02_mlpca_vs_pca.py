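"""Compare subspace recovery of error-weighted MLPCA against classical PCA.

Builds rank-2 data corrupted by correlated (scatter-like) noise whose exact
covariance is known, fits both the weighted (case D) and unweighted (case A)
models, and prints the principal angle between each fitted plane and the
true one — smaller is better.
"""

import numpy as np
from scipy.linalg import subspace_angles

from mlpcalr import ErrorCovariance, default_bone_config, fit_mlpca, ground_truth_ecm
from mlpcalr.synthetic import clean_spectrum

cfg = default_bone_config("micronir", n_channels=40, seed=0)
sigma = ground_truth_ecm(cfg, clean_spectrum(cfg, 0)).sigma_cov
chol = np.linalg.cholesky(sigma + 1e-12 * np.eye(40))

rng = np.random.default_rng(2)
true_plane = np.linalg.qr(rng.normal(size=(40, 2)))[0]
scores = rng.normal(scale=[1.0, 0.5], size=(200, 2))
x = scores @ true_plane.T + rng.normal(size=(200, 40)) @ chol.T

weighted = fit_mlpca(x, ErrorCovariance(sigma), p=2, case_id="D")
unweighted = fit_mlpca(x, None, p=2, case_id="A")

ang_d = np.degrees(subspace_angles(weighted.loadings, true_plane)).max()
ang_a = np.degrees(subspace_angles(unweighted.loadings, true_plane)).max()
print(f"principal angle to the true plane, case D (error-weighted): {ang_d:.2f} deg")
print(f"principal angle to the true plane, case A (classical PCA):  {ang_a:.2f} deg")
print()
print("Whitening by the error covariance downweights the directions the noise")
print("inflates, so the weighted fit tracks the true subspace more closely.")
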