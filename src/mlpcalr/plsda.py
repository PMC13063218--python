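"""PLS-DA baseline and error-structure-driven preprocessing selection.

PLS-DA regresses a 0/1 dummy response on the spectra (single-response NIPALS)
and thresholds the prediction at 0.5. Unlike MLPCA-LR it ignores the
measurement-error covariance, so its performance hinges on preprocessing
that makes the errors as iid-like as possible. The search here makes that
selection quantitative: every candidate pipeline is applied to the replicate
spectra, the pooled error covariance/correlation is recomputed on the
preprocessed replicates, and candidates are ranked by
:func:`mlpcalr.error_model.iid_score` (ascending — closer to iid first).

Pipelines are ordered smoothing -> scatter correction (SNV/MSC) ->
derivative, with mean-centering applied last inside the PLS fit itself
(centering subtracts a per-channel constant across samples, so it leaves
replicate residuals — hence the ECM — unchanged).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .error_model import correlation_from_covariance, iid_score, pool_ecms, ecm_single
from .spectra import SpectraSet, average_replicates, mean_center, msc, savgol, snv
from .validation import specimen_table

__all__ = [
    "PreprocPipeline",
    "PreprocSearchResult",
    "PlsModel",
    "PlsdaPipeline",
    "fit_pls",
    "pls_predict",
    "plsda_predict",
    "default_preprocessing_grid",
    "preprocessing_search",
    "train_plsda",
]

SG_POLYORDER = 2
SG_WINDOWS = tuple(range(7, 22, 2))


@dataclass
class PreprocPipeline:
    """One ordered spectral preprocessing recipe with frozen fit statistics.

    ``smooth_window``: Savitzky-Golay smoothing window (None = skip);
    ``scatter``: None, "snv" or "msc"; ``deriv``: None, 1 or 2 with
    ``deriv_window`` (defaults to the smoothing window when both present).
    """

    smooth_window: int | None = None
    scatter: str | None = None
    deriv: int | None = None
    deriv_window: int | None = None
    msc_reference_: np.ndarray | None = None  # frozen training MSC reference

    def __post_init__(self) -> None:
        if self.scatter not in (None, "snv", "msc"):
            raise ValueError("scatter must be None, 'snv' or 'msc'")
        if self.deriv not in (None, 1, 2):
            raise ValueError("deriv must be None, 1 or 2")
        if self.deriv is not None and self.deriv_window is None:
            self.deriv_window = self.smooth_window if self.smooth_window else 9

    @property
    def n_operators(self) -> int:
        return sum(x is not None for x in (self.smooth_window, self.scatter, self.deriv))

    def describe(self) -> str:
        parts = []
        if self.smooth_window:
            parts.append(f"smooth({self.smooth_window})")
        if self.scatter:
            parts.append(self.scatter)
        if self.deriv:
            parts.append(f"sg{self.deriv}d({self.deriv_window})")
        return "+".join(parts) if parts else "none"

    def _rowwise(self, x: np.ndarray, window: int, deriv: int) -> np.ndarray:
        return np.vstack([savgol(row, window, SG_POLYORDER, deriv) for row in x])

    def fit_transform(self, x: np.ndarray) -> np.ndarray:
        """Apply to training spectra, freezing the MSC reference."""
        return self._apply(np.atleast_2d(np.asarray(x, dtype=float)), fit=True)

    def transform(self, x: np.ndarray) -> np.ndarray:
        """Apply to new spectra with frozen training statistics."""
        return self._apply(np.atleast_2d(np.asarray(x, dtype=float)), fit=False)

    def _apply(self, x: np.ndarray, fit: bool) -> np.ndarray:
        if self.smooth_window:
            x = self._rowwise(x, self.smooth_window, 0)
        if self.scatter == "snv":
            x = np.vstack([snv(row) for row in x])
        elif self.scatter == "msc":
            if fit:
                x, ref = msc(x, "mean")
                self.msc_reference_ = ref
            else:
                if self.msc_reference_ is None:
                    raise ValueError("MSC pipeline not fitted")
                x, _ = msc(x, self.msc_reference_)
        if self.deriv:
            x = self._rowwise(x, self.deriv_window, self.deriv)
        return x


@dataclass(frozen=True)
class PreprocSearchResult:
    pipeline: PreprocPipeline
    score: float
    off_diag_term: float
    diag_cv_term: float
    rank: int


@dataclass
class PlsModel:
    """Single-response NIPALS PLS with stored centering and preprocessing."""

    n_lv: int
    weights: np.ndarray  # m x a
    loadings: np.ndarray  # m x a
    y_loadings: np.ndarray  # a
    x_mean: np.ndarray
    y_mean: float
    coef_: np.ndarray  # regression vector in centered space
    preprocessing: PreprocPipeline | None = None


def fit_pls(x: np.ndarray, y: np.ndarray, n_lv: int) -> PlsModel:
    """Fit single-y PLS by the NIPALS deflation sequence.

    Centers X and y internally (the pipeline's final mean-centering step);
    deterministic: components extracted in NIPALS order.
    """
    x = np.atleast_2d(np.asarray(x, dtype=float))
    yv = np.asarray(y, dtype=float).ravel()
    n, m = x.shape
    if yv.size != n:
        raise ValueError("x and y lengths differ")
    if not 1 <= n_lv <= min(n - 1, m):
        raise ValueError(f"n_lv={n_lv} out of range 1..{min(n - 1, m)}")
    xc, x_mean = mean_center(x)
    y_mean = yv.mean()
    yc = yv - y_mean

    ws, ps, qs = [], [], []
    xd, yd = xc.copy(), yc.copy()
    for _ in range(n_lv):
        w = xd.T @ yd
        norm = np.linalg.norm(w)
        if norm == 0:
            raise np.linalg.LinAlgError("residual y uncorrelated with X; reduce n_lv")
        w /= norm
        t = xd @ w
        tt = t @ t
        p = xd.T @ t / tt
        q = yd @ t / tt
        xd = xd - np.outer(t, p)
        yd = yd - q * t
        ws.append(w)
        ps.append(p)
        qs.append(q)
    weights = np.column_stack(ws)
    loadings = np.column_stack(ps)
    y_loadings = np.array(qs)
    coef = weights @ np.linalg.solve(loadings.T @ weights, y_loadings)
    return PlsModel(
        n_lv=n_lv,
        weights=weights,
        loadings=loadings,
        y_loadings=y_loadings,
        x_mean=x_mean,
        y_mean=float(y_mean),
        coef_=coef,
    )


def pls_predict(model: PlsModel, x_new: np.ndarray) -> np.ndarray:
    """Continuous prediction yhat = (x - x_mean) b + y_mean."""
    x = np.atleast_2d(np.asarray(x_new, dtype=float))
    if x.shape[1] != model.x_mean.size:
        raise ValueError("channel count does not match the fitted model")
    return (x - model.x_mean) @ model.coef_ + model.y_mean


def plsda_predict(model: PlsModel, x_new: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Apply the model's frozen preprocessing, predict, threshold at 0.5.

    Ties at exactly 0.5 go to the positive (historical) class, matching the
    logistic arm's rule.
    """
    x = np.atleast_2d(np.asarray(x_new, dtype=float))
    if model.preprocessing is not None:
        x = model.preprocessing.transform(x)
    yhat = pls_predict(model, x)
    return yhat, (yhat >= 0.5).astype(int)


def default_preprocessing_grid() -> list[PreprocPipeline]:
    """The searched candidate space.

    {none, SNV, MSC} x {no smoothing, SG smoothing w in 7..21 odd} x
    {none, 1st, 2nd SG derivative}; the derivative window equals the
    smoothing window when both are present, otherwise it is enumerated over
    the same window range. Includes e.g. "msc+sg1d" and
    "smooth(15)+msc+sg1d(15)".
    """
    grid: list[PreprocPipeline] = []
    for scatter in (None, "snv", "msc"):
        # no smoothing: derivative window free
        grid.append(PreprocPipeline(None, scatter, None))
        for d in (1, 2):
            for w in SG_WINDOWS:
                grid.append(PreprocPipeline(None, scatter, d, w))
        # with smoothing: derivative inherits the smoothing window
        for w in SG_WINDOWS:
            for d in (None, 1, 2):
                grid.append(PreprocPipeline(w, scatter, d, w if d else None))
    return grid


def preprocessing_search(
    train: SpectraSet,
    stratum: tuple[str, str],
    grid: list[PreprocPipeline] | None = None,
) -> list[PreprocSearchResult]:
    """Rank candidate pipelines by how iid the preprocessed errors become.

    For each candidate: preprocess every training replicate spectrum (MSC
    reference frozen on the training replicates), recompute the pooled ECM
    and error correlation per specimen group, and score the structure.
    Sorted ascending by score; ties broken by fewer operators, then smaller
    smoothing/derivative window.
    """
    if grid is None:
        grid = default_preprocessing_grid()
    if not grid:
        raise ValueError("empty preprocessing grid")
    sub = train.select_stratum(*stratum)
    if not sub.records:
        raise ValueError(f"no records in stratum {stratum}")
    groups = sub.groups()
    raw = {key: np.vstack([r.absorbance for r in recs]) for key, recs in groups.items()}
    sizes = [mat.shape[0] for mat in raw.values()]
    if min(sizes) < 2:
        raise ValueError("every replicate group needs >= 2 replicates")
    all_rows = np.vstack(list(raw.values()))

    scored = []
    for pipe in grid:
        pipe.fit_transform(all_rows)  # freeze MSC reference on all training replicates
        ecms = []
        for mat in raw.values():
            ecms.append(ecm_single(pipe.transform(mat), stratum=stratum))
        pooled = pool_ecms(ecms)
        corr = correlation_from_covariance(pooled)
        score, off_term, diag_term = iid_score(corr, pooled)
        scored.append((pipe, score, off_term, diag_term))

    def sort_key(item):
        pipe, score, _, _ = item
        return (score, pipe.n_operators, pipe.smooth_window or 0, pipe.deriv_window or 0)

    scored.sort(key=sort_key)
    return [
        PreprocSearchResult(pipe, score, off_term, diag_term, rank)
        for rank, (pipe, score, off_term, diag_term) in enumerate(scored, start=1)
    ]


@dataclass
class PlsdaPipeline:
    """Trained PLS-DA classifier over a SpectraSet, trainer-contract compatible."""

    model: PlsModel
    stratum: tuple[str, str]
    threshold: float = 0.5

    def predict(self, spectra: SpectraSet):
        means = average_replicates(spectra)
        ids = [r.specimen_id for r in means.records]
        yhat, labels = plsda_predict(self.model, means.to_matrix())
        return ids, yhat, labels


def train_plsda(
    train: SpectraSet,
    stratum: tuple[str, str],
    n_lv: int,
    preprocessing: PreprocPipeline | None = None,
) -> PlsdaPipeline:
    """Fit PLS-DA on replicate-mean spectra of one stratum.

    The preprocessing descriptor is refitted on the training replicate means
    (frozen for prediction); dummy response is historical=1 / modern=0.
    """
    sub, ids, y = specimen_table(train, stratum)
    means = average_replicates(sub)
    x = means.to_matrix()
    pipe = None
    if preprocessing is not None:
        pipe = PreprocPipeline(
            preprocessing.smooth_window,
            preprocessing.scatter,
            preprocessing.deriv,
            preprocessing.deriv_window,
        )
        x = pipe.fit_transform(x)
    model = fit_pls(x, y.astype(float), n_lv)
    model.preprocessing = pipe
    return PlsdaPipeline(model=model, stratum=stratum)
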