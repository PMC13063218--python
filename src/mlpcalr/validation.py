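"""Partitioning, cross-validation, bootstrap/OOB validation, and metrics.

All resampling operates at specimen level: a specimen's replicates always
travel together, so no replicate of a held-out specimen ever leaks into the
pooled error covariance or any other training statistic. The positive class
is historical (label 1) throughout.

Trainers are callables ``trainer(train_set, stratum, p) -> model`` where the
model exposes ``predict(SpectraSet) -> (ids, probabilities, labels)``; both
the MLPCA-LR and the PLS-DA pipelines satisfy this contract.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
from sklearn.metrics import roc_auc_score

from .spectra import SpectraSet, average_replicates

__all__ = [
    "ConfusionMatrix",
    "MetricsReport",
    "confusion",
    "metrics",
    "auc",
    "round_half_up",
    "stratified_split",
    "stratified_kfold",
    "cross_validate",
    "select_parsimonious",
    "bootstrap_validate",
    "specimen_table",
]

METRIC_NAMES = (
    "accuracy",
    "sensitivity",
    "specificity",
    "precision",
    "npv",
    "fpr",
    "fnr",
    "auc",
)


@dataclass(frozen=True)
class ConfusionMatrix:
    """2x2 counts with historical (1) as the positive class."""

    tp: int
    fn: int
    fp: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fn, self.fp, self.tn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def n(self) -> int:
        return self.tp + self.fn + self.fp + self.tn


@dataclass
class MetricsReport:
    """Panel of classification quality parameters; None where undefined.

    For bootstrap summaries the metric fields hold per-iteration means and
    ``std``/``n_effective`` carry the spread and the number of iterations in
    which each metric was defined.
    """

    accuracy: float | None = None
    sensitivity: float | None = None
    specificity: float | None = None
    precision: float | None = None
    npv: float | None = None
    fpr: float | None = None
    fnr: float | None = None
    auc: float | None = None
    std: dict[str, float] = field(default_factory=dict)
    n_effective: dict[str, int] = field(default_factory=dict)
    oob_fraction_mean: float | None = None

    def as_dict(self) -> dict[str, float | None]:
        return {name: getattr(self, name) for name in METRIC_NAMES}


def confusion(y_true, y_pred) -> ConfusionMatrix:
    """Count the 2x2 table of 0/1 truths against 0/1 predictions."""
    yt = np.asarray(y_true).astype(int).ravel()
    yp = np.asarray(y_pred).astype(int).ravel()
    if yt.size == 0:
        raise ValueError("empty input")
    if yt.size != yp.size:
        raise ValueError("length mismatch")
    if not (set(yt) <= {0, 1} and set(yp) <= {0, 1}):
        raise ValueError("labels must be 0/1")
    return ConfusionMatrix(
        tp=int(np.sum((yt == 1) & (yp == 1))),
        fn=int(np.sum((yt == 1) & (yp == 0))),
        fp=int(np.sum((yt == 0) & (yp == 1))),
        tn=int(np.sum((yt == 0) & (yp == 0))),
    )


def _ratio(num: int, den: int) -> float | None:
    return num / den if den > 0 else None


def metrics(cm: ConfusionMatrix) -> MetricsReport:
    """Accuracy, sensitivity, specificity, precision, NPV, FPR, FNR.

    A metric with a zero denominator is reported as None (flagged undefined),
    never silently zero-filled. AUC needs probabilities and is added by the
    caller where available.
    """
    return MetricsReport(
        accuracy=_ratio(cm.tp + cm.tn, cm.n),
        sensitivity=_ratio(cm.tp, cm.tp + cm.fn),
        specificity=_ratio(cm.tn, cm.tn + cm.fp),
        precision=_ratio(cm.tp, cm.tp + cm.fp),
        npv=_ratio(cm.tn, cm.tn + cm.fn),
        fpr=_ratio(cm.fp, cm.fp + cm.tn),
        fnr=_ratio(cm.fn, cm.fn + cm.tp),
    )


def auc(y_true, prob) -> float:
    """Rank-based AUC (probability a positive outranks a negative, ties 1/2)."""
    yt = np.asarray(y_true).astype(int).ravel()
    if np.unique(yt).size < 2:
        raise ValueError("AUC needs both classes present")
    return float(roc_auc_score(yt, np.asarray(prob, dtype=float).ravel()))


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Decimal half-up rounding for display (0.005 -> 0.01 at 2 digits)."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def stratified_split(
    labels, n_train: int, seed: int | np.random.Generator = 0
) -> tuple[np.ndarray, np.ndarray]:
    """Random class-stratified train/test split by largest-remainder allocation.

    Per-class training counts are the largest-remainder apportionment of
    ``n_train`` proportional to class sizes; membership within a class is
    random given the seed. Returns (train_idx, test_idx), disjoint and
    exhaustive, both sorted.
    """
    y = np.asarray(labels).astype(int).ravel()
    n = y.size
    if not 0 < n_train < n:
        raise ValueError("n_train must be strictly between 0 and n")
    classes, counts = np.unique(y, return_counts=True)
    if classes.size < 2:
        raise ValueError("both classes must be present")

    quotas = counts * n_train / n
    alloc = np.floor(quotas).astype(int)
    remainder = n_train - alloc.sum()
    order = np.argsort(-(quotas - alloc), kind="stable")  # largest fractional part first
    for j in order[:remainder]:
        alloc[j] += 1
    if np.any(alloc == 0) or np.any(alloc == counts):
        raise ValueError("allocation would leave a class empty in train or test")

    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    train_idx: list[int] = []
    for cls, k in zip(classes, alloc):
        members = np.flatnonzero(y == cls)
        chosen = rng.choice(members, size=k, replace=False)
        train_idx.extend(chosen.tolist())
    train = np.array(sorted(train_idx))
    test = np.setdiff1d(np.arange(n), train)
    return train, test


def stratified_kfold(
    labels, k: int = 10, seed: int | np.random.Generator = 0
) -> list[np.ndarray]:
    """Class-stratified k folds: sizes differ by <= 1, per-class counts too.

    Members of each class are shuffled and dealt cyclically across folds,
    carrying the dealing offset from class to class so total fold sizes stay
    balanced. ``k = n`` gives leave-one-out. Returns the k test-index arrays
    (disjoint, exhaustive).
    """
    y = np.asarray(labels).astype(int).ravel()
    n = y.size
    if not 1 < k <= n:
        raise ValueError(f"k must be in 2..n (n={n})")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    folds: list[list[int]] = [[] for _ in range(k)]
    offset = 0
    for cls in np.unique(y):
        members = rng.permutation(np.flatnonzero(y == cls))
        for i, idx in enumerate(members):
            folds[(offset + i) % k].append(int(idx))
        offset = (offset + members.size) % k
    if any(len(f) == 0 for f in folds):
        raise ValueError("produced an empty fold")  # unreachable for k <= n
    return [np.array(sorted(f)) for f in folds]


def specimen_table(spectra: SpectraSet, stratum: tuple[str, str]):
    """Specimen ids and labels of one stratum, in first-appearance order."""
    sub = spectra.select_stratum(*stratum)
    means = average_replicates(sub)
    ids = [r.specimen_id for r in means.records]
    y = np.array([r.class_label for r in means.records])
    if np.any(y == None):  # noqa: E711 — None entries in an object array
        raise ValueError("stratum contains unlabeled specimens")
    return sub, ids, y.astype(int)


def _subset_by_specimens(spectra: SpectraSet, keep: set[str]) -> SpectraSet:
    return spectra.subset(lambda r: r.specimen_id in keep)


def cross_validate(
    trainer,
    data: SpectraSet,
    stratum: tuple[str, str],
    p_grid=range(1, 6),
    k: int = 10,
    seed: int = 0,
) -> dict[int, MetricsReport]:
    """Stratified k-fold CV of a trainer over a rank grid, one stratum.

    Every training statistic (ECM, subspace, scaler, classifier or the
    PLS-DA preprocessing) is re-derived inside each training fold. Out-of-
    fold probabilities are pooled over the k folds and one metric panel is
    computed per rank, with AUC on the pooled probabilities.
    """
    sub, ids, y = specimen_table(data, stratum)
    folds = stratified_kfold(y, k=k, seed=seed)
    p_list = list(p_grid)
    oof_prob = {p: np.full(len(ids), np.nan) for p in p_list}
    for fold in folds:
        test_ids = {ids[i] for i in fold}
        train_set = _subset_by_specimens(sub, set(ids) - test_ids)
        test_set = _subset_by_specimens(sub, test_ids)
        fold_y = y[np.setdiff1d(np.arange(len(ids)), fold)]
        if np.unique(fold_y).size < 2:
            raise ValueError("a CV training fold contains a single class; reduce k")
        for p in p_list:
            model = trainer(train_set, stratum, p)
            pred_ids, prob, _ = model.predict(test_set)
            pos = {s: j for j, s in enumerate(ids)}
            for s, pr in zip(pred_ids, prob):
                oof_prob[p][pos[s]] = pr
    out: dict[int, MetricsReport] = {}
    for p in p_list:
        prob = oof_prob[p]
        assert not np.any(np.isnan(prob))
        labels = (prob >= 0.5).astype(int)
        rep = metrics(confusion(y, labels))
        rep.auc = auc(y, prob)
        out[p] = rep
    return out


def select_parsimonious(reports: dict[int, MetricsReport]) -> int:
    """Smallest rank achieving the best accuracy (ties broken by AUC, then p).

    Among ranks whose accuracy equals the maximum, those with the highest AUC
    are kept and the smallest rank wins.
    """
    if not reports:
        raise ValueError("empty report table")
    tol = 1e-12
    best_acc = max(r.accuracy for r in reports.values())
    tied = {p: r for p, r in reports.items() if r.accuracy >= best_acc - tol}
    aucs = {p: (r.auc if r.auc is not None else -1.0) for p, r in tied.items()}
    best_auc = max(aucs.values())
    winners = [p for p in tied if aucs[p] >= best_auc - tol]
    return min(winners)


def _clone_with_multiplicity(
    spectra: SpectraSet, ids: list[str], draw: np.ndarray
) -> SpectraSet:
    """Bootstrap-sample specimens with replacement; copies get suffixed ids."""
    count: dict[str, int] = {}
    records = []
    by_specimen: dict[str, list] = {}
    for r in spectra.records:
        by_specimen.setdefault(r.specimen_id, []).append(r)
    for i in draw:
        sid = ids[i]
        c = count.get(sid, 0)
        count[sid] = c + 1
        for r in by_specimen[sid]:
            rec = r if c == 0 else replace(r, specimen_id=f"{sid}#b{c}")
            records.append(rec)
    return SpectraSet(spectra.grid, records)


def bootstrap_validate(
    trainer,
    train: SpectraSet,
    stratum: tuple[str, str],
    p: int,
    B: int = 1000,
    seed: int = 0,
) -> MetricsReport:
    """Bootstrap/OOB assessment of the full model-building process.

    Each iteration resamples training specimens with replacement (replicates
    travel with their specimen), refits the whole pipeline on the resample,
    and evaluates the metric panel on the out-of-bag specimens. Draws whose
    resample lacks a class are redrawn so B effective iterations remain.
    Per-metric means and standard deviations are taken over the iterations
    in which the metric is defined (``n_effective`` records how many).
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    sub, ids, y = specimen_table(train, stratum)
    n = len(ids)
    rng = np.random.default_rng(seed)
    values: dict[str, list[float]] = {name: [] for name in METRIC_NAMES}
    oob_fractions = []
    for _ in range(B):
        for _attempt in range(1000):
            draw = rng.integers(0, n, size=n)
            in_bag = np.unique(draw)
            oob = np.setdiff1d(np.arange(n), in_bag)
            if np.unique(y[draw]).size == 2 and oob.size > 0:
                break
        else:  # pragma: no cover — probability ~0 for any workable n
            raise RuntimeError("could not draw a two-class bootstrap sample")
        oob_fractions.append(oob.size / n)
        boot_set = _clone_with_multiplicity(sub, ids, draw)
        model = trainer(boot_set, stratum, p)
        oob_ids = {ids[i] for i in oob}
        pred_ids, prob, labels = model.predict(_subset_by_specimens(sub, oob_ids))
        truth = np.array([y[ids.index(s)] for s in pred_ids])
        rep = metrics(confusion(truth, labels))
        for name in METRIC_NAMES[:-1]:
            v = getattr(rep, name)
            if v is not None:
                values[name].append(v)
        if np.unique(truth).size == 2:
            values["auc"].append(auc(truth, prob))
    report = MetricsReport()
    for name in METRIC_NAMES:
        vals = values[name]
        report.n_effective[name] = len(vals)
        if vals:
            setattr(report, name, float(np.mean(vals)))
            report.std[name] = float(np.std(vals, ddof=1)) if len(vals) > 1 else 0.0
    report.oob_fraction_mean = float(np.mean(oob_fractions))
    return report
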