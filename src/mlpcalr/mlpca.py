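"""Maximum-likelihood PCA for error structures solvable by whitening + SVD.

Classical PCA minimises the plain squared orthogonal residual and is the
maximum-likelihood subspace estimate only under iid noise. When replicate
measurements reveal a non-trivial error covariance Sigma, the ML estimate
instead minimises the error-weighted objective

    S^2 = sum_i (x_i - xhat_i) Sigma^{-1} (x_i - xhat_i)^T

over rank-p reconstructions xhat_i. Three error structures admit a direct
(non-iterative) solution and are implemented here:

* case A — homoscedastic uncorrelated errors: reduces exactly to PCA;
* case B — heteroscedastic uncorrelated errors with a structure common to
  all rows: whiten by the diagonal of Sigma;
* case D — correlated errors with a common (wavelength-wise) structure
  shared by all rows: whiten by the full Sigma.

The fit whitens the rows, takes the best rank-p subspace by SVD, and maps
loadings and reconstructions back to the original variable space. New
samples are projected by maximum likelihood (generalised least squares
against Sigma), not orthogonally.

Solutions are not nested across ranks except in case A, so each rank in a
grid is fitted independently.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .error_model import ErrorCovariance, regularized_whitener

__all__ = ["MlpcaModel", "fit_mlpca", "objective_s2", "ml_project", "fit_rank_grid"]

_DIRECT_CASES = ("A", "B", "D")


@dataclass
class MlpcaModel:
    """A fitted rank-p ML subspace.

    ``loadings`` (m x p) live in the original variable space; the
    W-transformed loadings ``whitened_loadings`` are orthonormal. ``s2`` is
    the weighted objective at the optimum, using the same ridge-adjusted
    inverse as the fit.
    """

    case_id: str
    p: int
    loadings: np.ndarray
    scores: np.ndarray
    center: np.ndarray | None
    whitener: np.ndarray
    whitened_loadings: np.ndarray
    ecm: ErrorCovariance | None
    ridge: float
    s2: float

    @property
    def m(self) -> int:
        return self.loadings.shape[0]


def _whitener_for_case(
    case_id: str, ecm: ErrorCovariance | None, m: int, ridge: float | None
) -> tuple[np.ndarray, float]:
    if case_id not in _DIRECT_CASES:
        raise NotImplementedError(
            f"MLPCA case {case_id!r} requires iterative optimisation and is not "
            "implemented; only the directly solvable cases A, B and D are."
        )
    if case_id == "A":
        return np.eye(m), 0.0
    if ecm is None:
        raise ValueError(f"case {case_id} requires an error covariance matrix")
    if ecm.m != m:
        raise ValueError(f"ECM dimension {ecm.m} does not match data dimension {m}")
    if case_id == "B":
        ecm = ErrorCovariance(
            np.diag(np.diag(ecm.sigma_cov)),
            n_samples_pooled=ecm.n_samples_pooled,
            replicates_per_sample=ecm.replicates_per_sample,
            stratum=ecm.stratum,
        )
    return regularized_whitener(ecm, ridge)


def fit_mlpca(
    xbar: np.ndarray,
    ecm: ErrorCovariance | None,
    p: int,
    case_id: str = "D",
    center: bool = True,
    ridge: float | None = None,
) -> MlpcaModel:
    """Fit a rank-p maximum-likelihood subspace to replicate-mean spectra.

    Parameters
    ----------
    xbar : (n, m) array
        One replicate-mean spectrum per row.
    ecm : ErrorCovariance or None
        Pooled error covariance shared by all rows. Ignored for case A
        (identity assumed); only its diagonal is used for case B.
    p : int
        Subspace rank, 1 <= p <= min(n - center, m).
    case_id : {"A", "B", "D"}
        Error-structure case; see the module docstring.
    center : bool
        Subtract the column mean before fitting (default). The mean is stored
        and re-applied at projection time.
    ridge : float, optional
        Explicit ridge for the whitener; default auto-escalates from
        1e-8 x mean error variance until positive definite.
    """
    x = np.atleast_2d(np.asarray(xbar, dtype=float))
    n, m = x.shape
    p_max = min(n - (1 if center else 0), m)
    if not 1 <= p <= p_max:
        raise ValueError(f"rank p={p} out of range 1..{p_max} for n={n}, m={m}, center={center}")

    w, ridge_used = _whitener_for_case(case_id, ecm, m, ridge)

    mu = x.mean(axis=0) if center else None
    xc = x - mu if center else x
    z = xc @ w
    u, s, vt = np.linalg.svd(z, full_matrices=False)
    q = vt[:p].T  # orthonormal loadings in whitened space
    scores = u[:, :p] * s[:p]
    s2 = float(np.sum(s[p:] ** 2))

    if case_id == "A":
        loadings = q.copy()
    else:
        loadings = np.linalg.solve(w, q)  # back to original variable space

    # sign convention: largest-magnitude element of each original-space loading positive
    flip = np.sign(loadings[np.abs(loadings).argmax(axis=0), np.arange(p)])
    flip[flip == 0] = 1.0
    loadings *= flip
    q = q * flip
    scores = scores * flip

    return MlpcaModel(
        case_id=case_id,
        p=p,
        loadings=loadings,
        scores=scores,
        center=mu,
        whitener=w,
        whitened_loadings=q,
        ecm=ecm if case_id != "A" else None,
        ridge=ridge_used,
        s2=s2,
    )


def reconstruct(model: MlpcaModel, scores: np.ndarray) -> np.ndarray:
    """Map scores back to the original variable space: t P^T (+ center)."""
    t = np.atleast_2d(np.asarray(scores, dtype=float))
    xhat = t @ model.loadings.T
    if model.center is not None:
        xhat = xhat + model.center
    return xhat


def ml_project(model: MlpcaModel, x: np.ndarray) -> np.ndarray:
    """Maximum-likelihood projection of new spectra onto the fitted subspace.

    t = (P^T Sigma^{-1} P)^{-1} P^T Sigma^{-1} (x - center) — generalised
    least squares against the ridge-adjusted error covariance, computed here
    as the orthogonal projection in whitened coordinates (the two coincide
    because the whitened loadings are orthonormal).
    """
    xa = np.asarray(x, dtype=float)
    single = xa.ndim == 1
    xa = np.atleast_2d(xa)
    if xa.shape[1] != model.m:
        raise ValueError(f"input has {xa.shape[1]} channels, model has {model.m}")
    xc = xa - model.center if model.center is not None else xa
    t = (xc @ model.whitener) @ model.whitened_loadings
    return t[0] if single else t


def objective_s2(model: MlpcaModel, xbar: np.ndarray, ecm: ErrorCovariance | None) -> float:
    """Evaluate the weighted objective S^2 of a model on data, term by term.

    Uses the same ridge-adjusted inverse as the fit (case A: identity), so
    the value on the training data equals ``model.s2``.
    """
    x = np.atleast_2d(np.asarray(xbar, dtype=float))
    if x.shape[1] != model.m:
        raise ValueError("dimension mismatch between data and model")
    t = ml_project(model, x)
    resid = x - reconstruct(model, t)
    if model.case_id == "A" or ecm is None:
        return float(np.sum(resid**2))
    sigma = ecm.sigma_cov
    if model.case_id == "B":
        sigma = np.diag(np.diag(sigma))
    sigma_r = sigma + model.ridge * np.eye(model.m)
    sol = np.linalg.solve(sigma_r, resid.T)
    return float(np.sum(resid.T * sol))


def fit_rank_grid(
    xbar: np.ndarray,
    ecm: ErrorCovariance | None,
    p_max: int = 5,
    case_id: str = "D",
    center: bool = True,
    ridge: float | None = None,
) -> list[MlpcaModel]:
    """Fit one model per rank p = 1..p_max, each from scratch.

    ML subspaces are not nested across ranks (outside case A), so no
    truncation shortcut is taken. The returned ``s2`` sequence is
    non-increasing in p.
    """
    x = np.atleast_2d(np.asarray(xbar, dtype=float))
    n, m = x.shape
    if p_max > min(n - (1 if center else 0), m):
        raise ValueError(f"p_max={p_max} exceeds min(n-{int(center)}, m) = {min(n - int(center), m)}")
    return [
        fit_mlpca(x, ecm, p, case_id=case_id, center=center, ridge=ridge)
        for p in range(1, p_max + 1)
    ]
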