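"""Logistic regression on autoscaled ML-PCA scores, and the two-step pipeline.

The classifier models the log-odds of the positive (historical = 1) class as
a linear function of the autoscaled subspace scores:

    log(P_i / (1 - P_i)) = beta_0 + beta_1 t_i1 + ... + beta_p t_ip

Scores are autoscaled first so that high-variance components (typically the
first, scatter-dominated one) cannot dominate the coefficients; the
regression then weighs components by discriminative power alone.

Perfect class separation — the expected regime here — makes the unpenalised
maximum-likelihood estimate diverge, so a small ridge penalty on the slopes
(never the intercept) keeps coefficients finite and reproducible while
leaving the decision boundary essentially untouched.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .error_model import ErrorCovariance, pooled_ecm_from_groups
from .mlpca import MlpcaModel, fit_mlpca, ml_project
from .spectra import SpectraSet, average_replicates

__all__ = [
    "ScoreScaler",
    "LogisticModel",
    "MlpcaLrPipeline",
    "autoscale_fit",
    "autoscale_apply",
    "fit_logistic",
    "predict_prob",
    "classify_labels",
    "train_mlpcalr",
]

DEFAULT_RIDGE_LAMBDA = 1e-4


@dataclass(frozen=True)
class ScoreScaler:
    """Frozen column means and sample standard deviations of training scores."""

    means: np.ndarray
    stds: np.ndarray


def autoscale_fit(scores: np.ndarray) -> ScoreScaler:
    """Fit per-column standardisation statistics on training scores."""
    t = np.atleast_2d(np.asarray(scores, dtype=float))
    if t.shape[0] < 2:
        raise ValueError("need at least 2 rows to autoscale")
    means = t.mean(axis=0)
    stds = t.std(axis=0, ddof=1)
    if np.any(stds <= 0):
        raise ValueError("zero-variance score column; cannot autoscale")
    return ScoreScaler(means, stds)


def autoscale_apply(scaler: ScoreScaler, scores: np.ndarray) -> np.ndarray:
    """Standardise scores with frozen training statistics."""
    t = np.asarray(scores, dtype=float)
    if t.shape[-1] != scaler.means.size:
        raise ValueError("score dimension does not match the fitted scaler")
    return (t - scaler.means) / scaler.stds


@dataclass
class LogisticModel:
    """Fitted logistic coefficients with their convergence record."""

    beta0: float
    beta: np.ndarray
    ridge_lambda: float
    converged: bool
    n_iter: int


def _sigmoid(eta: np.ndarray) -> np.ndarray:
    # numerically safe on both tails
    out = np.empty_like(eta)
    pos = eta >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-eta[pos]))
    e = np.exp(eta[~pos])
    out[~pos] = e / (1.0 + e)
    return out


def _penalized_ll(y: np.ndarray, eta: np.ndarray, beta: np.ndarray, lam: float) -> float:
    # log-likelihood written to avoid log(0): log sigma(eta) = -log(1+exp(-eta))
    ll = float(-np.sum(np.logaddexp(0.0, -eta) * y + np.logaddexp(0.0, eta) * (1 - y)))
    return ll - 0.5 * lam * float(beta @ beta)


def fit_logistic(
    t: np.ndarray,
    y: np.ndarray,
    ridge_lambda: float = DEFAULT_RIDGE_LAMBDA,
    max_iter: int = 100,
    tol: float = 1e-10,
) -> LogisticModel:
    """Ridge-penalised logistic regression by damped Newton / IRLS.

    Maximises sum_i [y_i log P_i + (1-y_i) log(1-P_i)] - (lambda/2) ||beta||^2
    with the penalty on the slopes only. Deterministic: coefficients start at
    zero; steps are halved whenever the penalised log-likelihood would
    decrease; convergence when its relative change falls below ``tol``.
    """
    x = np.atleast_2d(np.asarray(t, dtype=float))
    yv = np.asarray(y, dtype=float).ravel()
    if x.shape[0] != yv.size:
        raise ValueError("score matrix and labels have different lengths")
    if not set(np.unique(yv)) <= {0.0, 1.0}:
        raise ValueError("labels must be 0/1")
    if np.unique(yv).size < 2:
        raise ValueError("both classes must be present to fit logistic regression")
    if ridge_lambda < 0:
        raise ValueError("ridge_lambda must be >= 0")

    n, p = x.shape
    xd = np.column_stack([np.ones(n), x])
    pen = np.diag([0.0] + [ridge_lambda] * p)  # intercept unpenalised
    coef = np.zeros(p + 1)
    eta = xd @ coef
    ll = _penalized_ll(yv, eta, coef[1:], ridge_lambda)

    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        mu = _sigmoid(eta)
        wdiag = np.clip(mu * (1 - mu), 1e-12, None)
        grad = xd.T @ (yv - mu) - pen @ coef
        hess = (xd * wdiag[:, None]).T @ xd + pen
        try:
            step = np.linalg.solve(hess, grad)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(hess, grad, rcond=None)[0]
        # damped update: halve until the penalised log-likelihood does not drop
        alpha = 1.0
        for _ in range(30):
            cand = coef + alpha * step
            eta_c = xd @ cand
            ll_c = _penalized_ll(yv, eta_c, cand[1:], ridge_lambda)
            if ll_c >= ll - 1e-14 * abs(ll):
                break
            alpha *= 0.5
        coef, eta = cand, eta_c
        rel = abs(ll_c - ll) / max(1.0, abs(ll))
        ll = ll_c
        if rel < tol:
            converged = True
            break

    if not np.all(np.isfinite(coef)):
        raise FloatingPointError("logistic fit produced non-finite coefficients")
    return LogisticModel(
        beta0=float(coef[0]),
        beta=coef[1:].copy(),
        ridge_lambda=float(ridge_lambda),
        converged=converged,
        n_iter=it,
    )


def predict_prob(model: LogisticModel, t: np.ndarray) -> np.ndarray:
    """Class-1 probability 1/(1+exp(-(beta0 + t.beta))) on autoscaled scores."""
    x = np.asarray(t, dtype=float)
    single = x.ndim == 1
    x = np.atleast_2d(x)
    if x.shape[1] != model.beta.size:
        raise ValueError("score dimension does not match model")
    prob = _sigmoid(model.beta0 + x @ model.beta)
    return prob[0] if single else prob


def classify_labels(prob: np.ndarray, threshold: float = 0.5) -> np.ndarray:
    """Threshold probabilities; ties at the threshold go to the positive class."""
    if not 0 < threshold < 1:
        raise ValueError("threshold must be in (0, 1)")
    return (np.asarray(prob, dtype=float) >= threshold).astype(int)


@dataclass
class MlpcaLrPipeline:
    """Frozen end-to-end model: pooled ECM -> ML subspace -> scaler -> logistic."""

    ecm: ErrorCovariance
    mlpca: MlpcaModel
    scaler: ScoreScaler
    lr: LogisticModel
    threshold: float = 0.5

    def __post_init__(self) -> None:
        p = self.mlpca.p
        if self.scaler.means.size != p or self.lr.beta.size != p:
            raise ValueError("component dimensions are inconsistent")

    def predict_scores(self, spectra: SpectraSet) -> tuple[list[str], np.ndarray]:
        """Replicate-average new spectra and ML-project them; returns (ids, scores)."""
        means = average_replicates(spectra)
        ids = [r.specimen_id for r in means.records]
        t = ml_project(self.mlpca, means.to_matrix())
        return ids, np.atleast_2d(t)

    def predict_proba(self, spectra: SpectraSet) -> tuple[list[str], np.ndarray]:
        ids, t = self.predict_scores(spectra)
        return ids, predict_prob(self.lr, autoscale_apply(self.scaler, t))

    def predict(self, spectra: SpectraSet) -> tuple[list[str], np.ndarray, np.ndarray]:
        """Returns (specimen ids, probabilities, 0/1 labels)."""
        ids, prob = self.predict_proba(spectra)
        return ids, prob, classify_labels(prob, self.threshold)


def train_mlpcalr(
    train: SpectraSet,
    stratum: tuple[str, str],
    p: int,
    case_id: str = "D",
    ridge_lambda: float = DEFAULT_RIDGE_LAMBDA,
    ridge: float | None = None,
    center: bool = True,
    threshold: float = 0.5,
) -> MlpcaLrPipeline:
    """Train the two-step pipeline on one (instrument, bone type) stratum.

    The pooled ECM comes from the training replicates only; the ML subspace is
    fitted on training replicate means; the logistic model on their autoscaled
    scores. All statistics are frozen for prediction, so test replicates never
    touch the whitener.
    """
    instrument_id, bone_type = stratum
    sub = train.select_stratum(instrument_id, bone_type)
    if not sub.records:
        raise ValueError(f"no records in stratum {stratum}")
    labels = {r.class_label for r in sub.records}
    if not {0, 1} <= labels:
        raise ValueError(f"stratum {stratum} does not contain both classes")

    ecm = pooled_ecm_from_groups(sub.groups(), stratum=stratum)
    means = average_replicates(sub)
    x = means.to_matrix()
    y = means.labels()
    model = fit_mlpca(x, ecm, p, case_id=case_id, center=center, ridge=ridge)
    scaler = autoscale_fit(model.scores)
    lr = fit_logistic(autoscale_apply(scaler, model.scores), y, ridge_lambda=ridge_lambda)
    return MlpcaLrPipeline(ecm=ecm, mlpca=model, scaler=scaler, lr=lr, threshold=threshold)


def mlpcalr_trainer(**kwargs):
    """Trainer factory for the validation machinery.

    Returns ``trainer(train_set, stratum, p) -> MlpcaLrPipeline`` with any
    keyword overrides (case_id, ridge_lambda, ridge, center) baked in.
    """

    def trainer(train_set: SpectraSet, stratum: tuple[str, str], p: int) -> MlpcaLrPipeline:
        return train_mlpcalr(train_set, stratum, p, **kwargs)

    return trainer
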