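"""Candidate-model enumeration and repeated cross-validated comparison.

All non-empty subsets (up to four variables) of the top-ranked list are
compared by out-of-fold discrimination under three resampling schemes —
leave-one-out, 5-fold and 10-fold — each repeated 10 times with a fresh
random re-ordering of the records.  Candidates are fitted unpenalized
inside the folds.  AUC-ROC and cross-entropy are computed on the pooled
out-of-fold probabilities of each repetition and averaged; AIC, BIC and the
Hosmer-Lemeshow statistic come from the full-data fit.  Leave-one-out folds
do not depend on the re-ordering, so its repetitions are identical by
construction.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np

from .cohort import Cohort, covariate_frame
from .stats import (MetricSet, aic_bic, auc_roc, cross_entropy, fit_logistic,
                    hosmer_lemeshow, predict_proba)

__all__ = ["CandidateModel", "CVReport", "enumerate_candidates",
           "cross_validate", "rank_models", "reports_frame", "DEFAULT_SCHEMES"]

logger = logging.getLogger(__name__)

DEFAULT_SCHEMES = ("loo", "5fold", "10fold")
_FOLD_COUNTS = {"5fold": 5, "10fold": 10}


@dataclass(frozen=True)
class CandidateModel:
    variables: tuple[str, ...]

    def __post_init__(self):
        if not self.variables:
            raise ValueError("a candidate model needs at least one variable")

    @property
    def size(self) -> int:
        return len(self.variables)

    def __str__(self) -> str:
        return "+".join(self.variables)


@dataclass
class CVReport:
    candidate: CandidateModel
    per_run_auc: dict = field(default_factory=dict)   # (scheme, rep) -> AUC
    per_run_ce: dict = field(default_factory=dict)
    full_fit_metrics: MetricSet | None = None

    @property
    def mean_auc(self) -> float:
        """Unweighted mean out-of-fold AUC over every scheme x repetition."""
        return float(np.mean(list(self.per_run_auc.values())))

    @property
    def mean_ce(self) -> float:
        return float(np.mean(list(self.per_run_ce.values())))


def enumerate_candidates(top: list[str], max_size: int = 4) -> list[CandidateModel]:
    """All non-empty subsets of ``top`` with at most ``max_size`` members,
    ordered by size then lexicographically within the declared order."""
    if not top:
        raise ValueError("top variable list is empty")
    out = []
    for size in range(1, min(max_size, len(top)) + 1):
        for combo in itertools.combinations(top, size):
            out.append(CandidateModel(combo))
    return out


def _make_folds(order: np.ndarray, k: int) -> list[np.ndarray]:
    return [np.asarray(f) for f in np.array_split(order, k)]


def _merge_single_class_folds(folds: list[np.ndarray], y: np.ndarray) -> list[np.ndarray]:
    """Merge any fold whose complement (the training set) is single-class
    into its neighbor, logging the event."""
    changed = True
    while changed and len(folds) > 1:
        changed = False
        for i, f in enumerate(folds):
            train_y = y[np.concatenate([g for j, g in enumerate(folds) if j != i])]
            if np.unique(train_y).size < 2:
                j = i - 1 if i > 0 else i + 1
                logger.info("merging single-class-training fold %d into fold %d", i, j)
                folds[j] = np.concatenate([folds[j], f])
                del folds[i]
                changed = True
                break
    return folds


def _oof_probabilities(X: np.ndarray, y: np.ndarray, folds: list[np.ndarray]) -> np.ndarray:
    probs = np.empty(len(y))
    for f in folds:
        mask = np.ones(len(y), dtype=bool)
        mask[f] = False
        model = fit_logistic(X[mask], y[mask])
        probs[f] = predict_proba(model, X[f])
    return probs


def cross_validate(
    candidate: CandidateModel,
    cohort: Cohort,
    schemes: tuple[str, ...] = DEFAULT_SCHEMES,
    n_repetitions: int = 10,
    seed: int | np.random.SeedSequence = 0,
) -> CVReport:
    """Repeated out-of-fold evaluation of one candidate."""
    frame = covariate_frame(cohort)
    for v in candidate.variables:
        if v not in frame.columns:
            raise KeyError(f"candidate variable '{v}' absent from the cohort")
    sub = frame[list(candidate.variables) + ["rion"]].dropna()
    X = sub[list(candidate.variables)].to_numpy()
    y = sub["rion"].to_numpy()
    n = len(y)
    if y.sum() < 2:
        raise ValueError("need at least 2 events for cross-validation")

    rng = np.random.default_rng(seed)
    report = CVReport(candidate=candidate)

    loo_probs: np.ndarray | None = None
    for rep in range(n_repetitions):
        order = rng.permutation(n)
        for scheme in schemes:
            if scheme == "loo":
                if loo_probs is None:  # fold set is order-independent
                    loo_probs = _oof_probabilities(X, y, [np.array([i]) for i in range(n)])
                probs = loo_probs
            else:
                k = _FOLD_COUNTS[scheme]
                folds = _merge_single_class_folds(_make_folds(order, k), y)
                probs = _oof_probabilities(X, y, folds)
            report.per_run_auc[(scheme, rep)] = auc_roc(probs, y)
            report.per_run_ce[(scheme, rep)] = cross_entropy(probs, y)

    full = fit_logistic(X, y, list(candidate.variables))
    p_full = predict_proba(full, X)
    aic, bic = aic_bic(full)
    try:
        hl_stat, hl_p = hosmer_lemeshow(p_full, y)
    except ValueError:
        hl_stat, hl_p = float("nan"), float("nan")
    report.full_fit_metrics = MetricSet(
        auc_roc=auc_roc(p_full, y),
        cross_entropy=cross_entropy(p_full, y),
        aic=aic, bic=bic, hl_statistic=hl_stat, hl_pvalue=hl_p,
    )
    return report


def reports_frame(reports: list[CVReport]):
    """Candidate x scheme x repetition metric matrix, one row per run."""
    import pandas as pd

    rows = []
    for r in reports:
        for (scheme, rep), auc in r.per_run_auc.items():
            rows.append({
                "candidate": str(r.candidate), "scheme": scheme,
                "repetition": rep, "auc_roc": auc,
                "cross_entropy": r.per_run_ce[(scheme, rep)],
            })
    return pd.DataFrame(rows)


def rank_models(reports: list[CVReport]) -> list[tuple[CandidateModel, float]]:
    """Candidates by descending mean out-of-fold AUC; ties go to the smaller
    model, then to the lower mean cross-entropy."""
    if not reports:
        raise ValueError("no reports to rank")
    ordered = sorted(reports, key=lambda r: (-r.mean_auc, r.candidate.size, r.mean_ce))
    return [(r.candidate, r.mean_auc) for r in ordered]
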