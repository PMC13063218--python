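"""Multivariate measurement-error estimation from replicate spectra.

The experimental error covariance matrix (ECM) of one specimen is the sample
covariance of its replicate residuals around the replicate mean; per-specimen
ECMs are then pooled (averaged) within a stratum — one (instrument, bone type)
combination, over specimens of both classes — to stabilise the estimate.
The error correlation matrix is the diagonal-normalised, scale-free view.

``iid_score`` quantifies how far an error structure is from the iid ideal
(flat diagonal, zero off-diagonal) that classical PCA and PLS assume; it
drives the preprocessing search in :mod:`mlpcalr.plsda`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "ErrorCovariance",
    "ErrorCorrelation",
    "ecm_single",
    "pool_ecms",
    "pooled_ecm_from_groups",
    "correlation_from_covariance",
    "iid_score",
    "regularized_whitener",
]

_SYM_TOL = 1e-10
_PSD_TOL = 1e-8


@dataclass(frozen=True)
class ErrorCovariance:
    """Channel x channel error covariance (absorbance^2 units) with provenance."""

    sigma_cov: np.ndarray
    n_samples_pooled: int = 1
    replicates_per_sample: int = 0
    stratum: tuple[str, str] | None = None  # (instrument_id, bone_type); all classes

    def __post_init__(self) -> None:
        s = np.asarray(self.sigma_cov, dtype=float)
        if s.ndim != 2 or s.shape[0] != s.shape[1]:
            raise ValueError("sigma_cov must be square")
        scale = max(1.0, float(np.abs(s).max(initial=0.0)))
        if np.abs(s - s.T).max(initial=0.0) > _SYM_TOL * scale:
            raise ValueError("sigma_cov must be symmetric")
        s = 0.5 * (s + s.T)
        eigmin = float(np.linalg.eigvalsh(s).min())
        if eigmin < -_PSD_TOL * scale:
            raise ValueError(f"sigma_cov not positive semi-definite (min eigenvalue {eigmin:g})")
        object.__setattr__(self, "sigma_cov", s)

    @property
    def m(self) -> int:
        return self.sigma_cov.shape[0]


@dataclass(frozen=True)
class ErrorCorrelation:
    """Scale-free error structure; entries of masked (zero-variance) channels are NaN."""

    sigma_corr: np.ndarray
    mask: np.ndarray  # True where the channel has zero error variance (undefined)

    @property
    def m(self) -> int:
        return self.sigma_corr.shape[0]

    def defined(self) -> np.ndarray:
        """Boolean vector of channels with a defined correlation row."""
        return ~self.mask


def ecm_single(replicates: np.ndarray, stratum: tuple[str, str] | None = None) -> ErrorCovariance:
    """Experimental ECM of one specimen from its r x m replicate matrix.

    Sigma = sum_k (X_k - Xbar)^T (X_k - Xbar) / (r - 1), the sample covariance
    of the residuals around the replicate-mean spectrum.
    """
    x = np.atleast_2d(np.asarray(replicates, dtype=float))
    r = x.shape[0]
    if r < 2:
        raise ValueError("need at least 2 replicates to estimate an ECM")
    resid = x - x.mean(axis=0)
    sigma = resid.T @ resid / (r - 1)
    return ErrorCovariance(sigma, n_samples_pooled=1, replicates_per_sample=r, stratum=stratum)


def pool_ecms(ecms: list[ErrorCovariance]) -> ErrorCovariance:
    """Element-wise mean of per-specimen ECMs (unweighted)."""
    if not ecms:
        raise ValueError("cannot pool an empty list of ECMs")
    m = ecms[0].m
    if any(e.m != m for e in ecms):
        raise ValueError("ECMs have mixed dimensions")
    strata = {e.stratum for e in ecms}
    if len(strata) > 1:
        raise ValueError(f"cannot pool ECMs across strata: {sorted(map(str, strata))}")
    sigma = np.mean([e.sigma_cov for e in ecms], axis=0)
    reps = {e.replicates_per_sample for e in ecms}
    return ErrorCovariance(
        sigma,
        n_samples_pooled=len(ecms),
        replicates_per_sample=reps.pop() if len(reps) == 1 else 0,
        stratum=ecms[0].stratum,
    )


def pooled_ecm_from_groups(
    groups: dict, stratum: tuple[str, str] | None = None
) -> ErrorCovariance:
    """Pooled ECM from replicate groups (as returned by ``SpectraSet.groups``).

    Groups with fewer than 2 replicates cannot contribute and raise.
    """
    ecms = []
    for key, records in groups.items():
        mat = np.vstack([r.absorbance for r in records])
        if mat.shape[0] < 2:
            raise ValueError(f"group {key} has fewer than 2 replicates")
        ecms.append(ecm_single(mat, stratum=stratum))
    return pool_ecms(ecms)


def correlation_from_covariance(ecm: ErrorCovariance) -> ErrorCorrelation:
    """Normalise an ECM by its diagonal: corr(i,j) = cov(i,j)/sqrt(var_i var_j).

    Channels with zero error variance get NaN rows/columns and are flagged in
    the mask rather than silently treated as uncorrelated.
    """
    var = np.diag(ecm.sigma_cov).copy()
    mask = var <= 0
    sd = np.sqrt(np.where(mask, np.nan, var))
    corr = ecm.sigma_cov / np.outer(sd, sd)
    defined = ~mask
    # clip rounding excursions beyond +/-1 on defined entries
    block = np.outer(defined, defined)
    corr[block] = np.clip(corr[block], -1.0, 1.0)
    return ErrorCorrelation(corr, mask)


def iid_score(corr: ErrorCorrelation, cov: ErrorCovariance) -> tuple[float, float, float]:
    """Distance of an error structure from the iid ideal. Lower is closer.

    Returns ``(score, off_diag_term, diag_cv_term)`` where the first term is
    the mean absolute off-diagonal correlation and the second the coefficient
    of variation of the error-variance diagonal; the score is their 1:1 sum.
    iid noise (sigma^2 I) scores exactly 0.
    """
    defined = corr.defined()
    if defined.sum() < 2:
        raise ValueError("need at least 2 defined channels")
    c = corr.sigma_corr[np.ix_(defined, defined)]
    off = c[~np.eye(c.shape[0], dtype=bool)]
    off_term = float(np.mean(np.abs(off)))
    var = np.diag(cov.sigma_cov)[defined]
    diag_cv = float(var.std(ddof=0) / var.mean()) if var.mean() > 0 else 0.0
    return off_term + diag_cv, off_term, diag_cv


def regularized_whitener(
    ecm: ErrorCovariance, ridge: float | None = None
) -> tuple[np.ndarray, float]:
    """Symmetric whitening matrix W with W^T (Sigma + ridge*I) W = I.

    Built from the symmetric eigendecomposition, so W is itself symmetric and
    deterministic. ``ridge=None`` starts at 1e-8 x mean diagonal and escalates
    by decades until the regularised matrix is numerically positive definite.

    Returns ``(W, ridge_used)``.
    """
    sigma = ecm.sigma_cov
    m = sigma.shape[0]
    mean_diag = float(np.trace(sigma)) / m
    if mean_diag <= 0:
        mean_diag = 1.0
    if ridge is None:
        candidates = [1e-8 * mean_diag * 10**k for k in range(12)]
    else:
        if ridge < 0:
            raise ValueError("ridge must be >= 0")
        candidates = [ridge]
    floor = 1e-14 * mean_diag
    for rg in candidates:
        vals, vecs = np.linalg.eigh(sigma + rg * np.eye(m))
        if vals.min() > floor:
            w = vecs @ np.diag(1.0 / np.sqrt(vals)) @ vecs.T
            return 0.5 * (w + w.T), rg
    raise np.linalg.LinAlgError(
        "error covariance remains singular after ridge escalation"
    )
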