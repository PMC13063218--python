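"""End-to-end study workflow for one (instrument, bone type) stratum.

Mirrors the full validation protocol: stratified train/test partition,
10-fold stratified cross-validation over a rank grid with parsimonious rank
selection, refit on the whole training set with external-test evaluation,
and bootstrap/OOB assessment — separately per stratum, since skulls and
mandibles carry distinct error structures.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from typing import Any

import numpy as np

from .classify import mlpcalr_trainer
from .plsda import PreprocPipeline, preprocessing_search, default_preprocessing_grid
from .spectra import SpectraSet
from .validation import (
    MetricsReport,
    auc,
    bootstrap_validate,
    confusion,
    cross_validate,
    metrics,
    select_parsimonious,
    specimen_table,
    stratified_split,
)

__all__ = ["StratumReport", "run_stratum", "plsda_trainer_from_search", "report_to_json"]


@dataclass
class StratumReport:
    """All results of one stratum's workflow, JSON-serialisable via ``to_dict``."""

    stratum: tuple[str, str]
    method: str
    seed: int
    n_train: int
    n_test: int
    train_composition: dict[str, int]
    test_composition: dict[str, int]
    cv: dict[int, MetricsReport]
    selected_p: int
    test: MetricsReport
    bootstrap: MetricsReport | None
    preprocessing: str | None = None
    extras: dict[str, Any] = field(default_factory=dict)

    def to_dict(self) -> dict:
        def rep(r: MetricsReport | None):
            if r is None:
                return None
            d = r.as_dict()
            d["std"] = r.std or None
            d["n_effective"] = r.n_effective or None
            d["oob_fraction_mean"] = r.oob_fraction_mean
            return d

        return {
            "stratum": list(self.stratum),
            "method": self.method,
            "seed": self.seed,
            "n_train": self.n_train,
            "n_test": self.n_test,
            "train_composition": self.train_composition,
            "test_composition": self.test_composition,
            "cv": {str(p): rep(r) for p, r in self.cv.items()},
            "selected_p": self.selected_p,
            "test": rep(self.test),
            "bootstrap": rep(self.bootstrap),
            "preprocessing": self.preprocessing,
            "extras": self.extras,
        }


def plsda_trainer_from_search(
    train_set: SpectraSet,
    stratum: tuple[str, str],
    grid: list[PreprocPipeline] | None = None,
):
    """Pick the most iid-compliant preprocessing on the training set, return
    a PLS-DA trainer that uses it (and the winning descriptor)."""
    from .plsda import train_plsda  # local to avoid cycle at import time

    results = preprocessing_search(train_set, stratum, grid)
    best = results[0].pipeline

    def trainer(tr: SpectraSet, st: tuple[str, str], p: int):
        return train_plsda(tr, st, n_lv=p, preprocessing=best)

    return trainer, best, results


def run_stratum(
    data: SpectraSet,
    stratum: tuple[str, str],
    method: str = "mlpcalr",
    p_grid=range(1, 6),
    k: int = 10,
    B: int = 1000,
    n_train: int | None = None,
    seed: int = 0,
    preprocessing_grid: list[PreprocPipeline] | None = None,
    trainer_kwargs: dict | None = None,
    run_bootstrap: bool = True,
) -> StratumReport:
    """Run partition -> CV -> rank selection -> external test -> bootstrap.

    ``n_train`` defaults to two thirds of the specimens (rounded), the usual
    train/test proportion; pass it explicitly to reproduce a fixed design.
    Sub-seeds for the partition, CV folds and bootstrap are derived from
    ``seed`` so the whole report is reproducible from one integer.
    """
    sub, ids, y = specimen_table(data, stratum)
    n = len(ids)
    if n_train is None:
        n_train = int(round(2 * n / 3))
    ss = np.random.SeedSequence(seed)
    seed_split, seed_cv, seed_boot = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(3)]

    train_idx, test_idx = stratified_split(y, n_train, seed=seed_split)
    train_ids = {ids[i] for i in train_idx}
    test_ids = {ids[i] for i in test_idx}
    train_set = sub.subset(lambda r: r.specimen_id in train_ids)
    test_set = sub.subset(lambda r: r.specimen_id in test_ids)

    preproc_desc = None
    if method == "mlpcalr":
        trainer = mlpcalr_trainer(**(trainer_kwargs or {}))
    elif method == "plsda":
        trainer, best, _ = plsda_trainer_from_search(train_set, stratum, preprocessing_grid)
        preproc_desc = best.describe()
    else:
        raise ValueError(f"unknown method {method!r}")

    cv = cross_validate(trainer, train_set, stratum, p_grid=p_grid, k=k, seed=seed_cv)
    p_star = select_parsimonious(cv)

    final = trainer(train_set, stratum, p_star)
    pred_ids, prob, labels = final.predict(test_set)
    truth = np.array([y[ids.index(s)] for s in pred_ids])
    test_rep = metrics(confusion(truth, labels))
    if np.unique(truth).size == 2:
        test_rep.auc = auc(truth, prob)

    boot = None
    if run_bootstrap:
        boot = bootstrap_validate(trainer, train_set, stratum, p_star, B=B, seed=seed_boot)

    comp = lambda idx: {  # noqa: E731
        "historical": int(np.sum(y[idx] == 1)),
        "modern": int(np.sum(y[idx] == 0)),
    }
    return StratumReport(
        stratum=stratum,
        method=method,
        seed=seed,
        n_train=len(train_idx),
        n_test=len(test_idx),
        train_composition=comp(train_idx),
        test_composition=comp(test_idx),
        cv=cv,
        selected_p=p_star,
        test=test_rep,
        bootstrap=boot,
        preprocessing=preproc_desc,
    )


def report_to_json(report: StratumReport, path, config: dict | None = None) -> None:
    """Write a stratum report; the payload carries a hash of its own config."""
    payload = report.to_dict()
    if config is not None:
        blob = json.dumps(config, sort_keys=True).encode()
        payload["config"] = config
        payload["config_hash"] = hashlib.sha256(blob).hexdigest()[:16]
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2)
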