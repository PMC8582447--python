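"""Univariable screening and rank-correlation collinearity elimination.

Before any multivariable modeling, each candidate variable is tested
individually against the neuropathy event indicator — a single-covariate
logistic fit (Wald p on the slope) for continuous variables, a Pearson
chi-square on the 2x2 table for categorical ones, with the surgery count
additionally screened through its >1, >2, >3, >4 dichotomizations.  Strongly
cross-correlated variables (|Spearman| above 0.8 by default) are then
thinned: of each such pair, the member with the weaker rank correlation to
the outcome is eliminated.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .cohort import (CATEGORICAL_VARIABLES, CONTINUOUS_VARIABLES,
                     SURGERY_DICHOTOMIES, Cohort, covariate_frame)
from .stats import DegenerateFitError, chi_square_test, fit_logistic, spearman_rcc

__all__ = [
    "ScreenResult",
    "screen_results_frame",
    "CollinearityDecision",
    "univariable_screen",
    "collinearity_filter",
    "SCREENING_VARIABLES",
    "POST_FILTER_NINE",
    "ALPHA",
]

logger = logging.getLogger(__name__)

ALPHA = 0.05

#: full screening set: clinical and dosimetric variables plus surgery dichotomies
SCREENING_VARIABLES = [
    "age", "tumor_type", "hypertension", "tumor_involvement", "sex",
    "n_surgeries", "gtv_volume", "prescription_dose", "photon_dose",
    "proton_dose", "optic_dmean", "optic_dmax", "optic_dmin", "optic_d1",
    "optic_d99",
]

#: the nine variables surviving collinearity elimination in the reference
#: configuration, shipped as a preset for reproducing that setup verbatim
POST_FILTER_NINE = [
    "age", "hypertension", "tumor_involvement", "sex", "n_surgeries",
    "gtv_volume", "prescription_dose", "optic_dmean", "optic_dmax",
]


@dataclass
class ScreenResult:
    variable: str
    test_used: str          # univariable_logistic | chi_square | untestable
    p_value: float | None
    significant: bool

    @classmethod
    def make(cls, variable: str, test: str, p: float | None) -> "ScreenResult":
        return cls(variable, test, p, p is not None and p < ALPHA)


def screen_results_frame(results: list["ScreenResult"]):
    """Screen results as a table (variable, test, p-value, significance)."""
    import pandas as pd

    return pd.DataFrame([{
        "variable": r.variable, "test": r.test_used,
        "p_value": r.p_value, "significant": r.significant,
    } for r in results])


@dataclass
class CollinearityDecision:
    retained: list[str]
    eliminated: list[tuple[str, str, float, float]]  # (var, partner, pair srcc, srcc to outcome)
    srcc_matrix: dict


def _screen_one(x: np.ndarray, y: np.ndarray, name: str, categorical: bool) -> ScreenResult:
    ok = ~np.isnan(x)
    x, y = x[ok], y[ok]
    if len(np.unique(y)) < 2 or len(np.unique(x)) < 2:
        return ScreenResult.make(name, "untestable", None)
    if categorical:
        table = np.array([
            [np.sum((x == 0) & (y == 0)), np.sum((x == 0) & (y == 1))],
            [np.sum((x == 1) & (y == 0)), np.sum((x == 1) & (y == 1))],
        ])
        if np.any(table.sum(axis=0) == 0) or np.any(table.sum(axis=1) == 0):
            return ScreenResult.make(name, "untestable", None)
        return ScreenResult.make(name, "chi_square", chi_square_test(table))
    try:
        model = fit_logistic(x[:, None], y, [name])
    except DegenerateFitError:
        return ScreenResult.make(name, "untestable", None)
    return ScreenResult.make(name, "univariable_logistic", float(model.p_values[1]))


def univariable_screen(cohort: Cohort, variables: list[str] | None = None) -> list[ScreenResult]:
    """Per-variable association tests against the event indicator, with
    complete-case filtering applied independently per variable.  The raw
    surgery count expands into its four dichotomizations as extra rows."""
    if variables is None:
        variables = list(SCREENING_VARIABLES)
    frame = covariate_frame(cohort)
    y_all = frame["rion"].to_numpy()

    expanded: list[str] = []
    for v in variables:
        expanded.append(v)
        if v == "n_surgeries":
            expanded.extend(SURGERY_DICHOTOMIES)

    results = []
    for v in expanded:
        if v not in frame.columns:
            raise KeyError(f"unknown variable '{v}'")
        categorical = v in CATEGORICAL_VARIABLES
        results.append(_screen_one(frame[v].to_numpy(), y_all, v, categorical))
    return results


def collinearity_filter(
    cohort: Cohort,
    variables: list[str],
    threshold: float = 0.8,
) -> CollinearityDecision:
    """Greedy pairwise elimination of cross-correlated variables.

    Pairs with |Spearman| above ``threshold`` are processed in descending
    pair-correlation order; in each pair the variable with the lower
    |Spearman| to the event indicator is eliminated (ties fall to the
    variable later in the declared order, which is logged).  Eliminated
    variables take no part in later pairs.  Constant variables are excluded
    from the matrix with a warning.
    """
    if len(variables) < 2:
        raise ValueError("collinearity filtering needs at least two variables")
    frame = covariate_frame(cohort)
    y = frame["rion"].to_numpy()

    usable = []
    for v in variables:
        col = frame[v].to_numpy()
        vals = col[~np.isnan(col)]
        if np.unique(vals).size < 2:
            logger.warning("variable %s is constant; excluded from collinearity matrix", v)
            continue
        usable.append(v)

    def pairwise_srcc(a: str, b: str) -> float:
        xa, xb = frame[a].to_numpy(), frame[b].to_numpy()
        ok = ~np.isnan(xa) & ~np.isnan(xb)
        try:
            return spearman_rcc(xa[ok], xb[ok])
        except ValueError:
            return 0.0

    srcc_out = {}
    for v in usable:
        col = frame[v].to_numpy()
        ok = ~np.isnan(col)
        try:
            srcc_out[v] = spearman_rcc(col[ok], y[ok])
        except ValueError:
            srcc_out[v] = 0.0

    matrix = {}
    pairs = []
    for i, a in enumerate(usable):
        for b in usable[i + 1:]:
            rho = pairwise_srcc(a, b)
            matrix[(a, b)] = rho
            if abs(rho) > threshold:
                pairs.append((abs(rho), a, b, rho))
    pairs.sort(key=lambda t: -t[0])

    eliminated: list[tuple[str, str, float, float]] = []
    dropped: set[str] = set()
    for _, a, b, rho in pairs:
        if a in dropped or b in dropped:
            continue
        sa, sb = abs(srcc_out[a]), abs(srcc_out[b])
        if sa == sb:
            loser = b if usable.index(b) > usable.index(a) else a
            logger.info("outcome-SRCC tie between %s and %s; eliminating %s (later in order)",
                        a, b, loser)
        else:
            loser = a if sa < sb else b
        winner = b if loser == a else a
        eliminated.append((loser, winner, rho, srcc_out[loser]))
        dropped.add(loser)

    retained = [v for v in usable if v not in dropped]
    return CollinearityDecision(
        retained=retained,
        eliminated=eliminated,
        srcc_matrix={f"{a}|{b}": v for (a, b), v in matrix.items()},
    )
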