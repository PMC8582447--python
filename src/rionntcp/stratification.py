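"""Risk-group segmentation by NTCP threshold.

Patients whose predicted complication probability reaches the threshold
(inclusive, so borderline patients err toward the high-risk group) are
classified high-risk; the sweep over a threshold grid characterizes the
available operating points.  The default threshold of 6% follows the
published proposal for this endpoint.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .cohort import Cohort, covariate_frame
from .stats import FittedLogisticModel, predict_proba

__all__ = ["RiskStratification", "stratify", "threshold_sweep", "DEFAULT_THRESHOLD",
           "DEFAULT_GRID"]

DEFAULT_THRESHOLD = 0.06
#: 0.5% steps spanning 1%..20%
DEFAULT_GRID = np.round(np.arange(0.01, 0.2001, 0.005), 4)


@dataclass
class RiskStratification:
    threshold: float
    patient_ids: list[str]
    ntcp: np.ndarray
    high_risk: np.ndarray          # boolean per patient
    tp: int
    fp: int
    tn: int
    fn: int
    excluded_ids: list[str]

    @property
    def n(self) -> int:
        return len(self.patient_ids)

    @property
    def sensitivity(self) -> float:
        return self.tp / (self.tp + self.fn) if (self.tp + self.fn) else float("nan")

    @property
    def specificity(self) -> float:
        return self.tn / (self.tn + self.fp) if (self.tn + self.fp) else float("nan")

    @property
    def proportion_high(self) -> float:
        return (self.tp + self.fp) / self.n

    def to_frame(self):
        """Per-patient classification table."""
        import pandas as pd

        return pd.DataFrame({
            "patient_id": self.patient_ids,
            "ntcp": self.ntcp,
            "risk_group": np.where(self.high_risk, "high", "low"),
        })


def stratify(
    model: FittedLogisticModel,
    cohort: Cohort,
    threshold: float = DEFAULT_THRESHOLD,
) -> RiskStratification:
    """Classify each patient as low/high risk at the given NTCP threshold.

    Patients with missing model covariates are excluded and reported in
    ``excluded_ids``.  NTCP exactly at the threshold counts as high-risk.
    """
    if not 0.0 < threshold < 1.0:
        raise ValueError("threshold must lie strictly inside (0, 1)")
    frame = covariate_frame(cohort)
    cols = list(model.covariate_names)
    ok = frame[cols].notna().all(axis=1)
    excluded = list(frame.index[~ok])
    sub = frame[ok]
    p = predict_proba(model, sub[cols].to_numpy())
    y = sub["rion"].to_numpy().astype(bool)
    high = p >= threshold
    return RiskStratification(
        threshold=float(threshold),
        patient_ids=list(sub.index),
        ntcp=p,
        high_risk=high,
        tp=int(np.sum(high & y)),
        fp=int(np.sum(high & ~y)),
        tn=int(np.sum(~high & ~y)),
        fn=int(np.sum(~high & y)),
        excluded_ids=excluded,
    )


def threshold_sweep(
    model: FittedLogisticModel,
    cohort: Cohort,
    grid: np.ndarray = DEFAULT_GRID,
) -> list[dict]:
    """One operating-point summary per grid threshold.

    The proportion classified high-risk and the sensitivity are
    non-increasing in the threshold; specificity is non-decreasing.
    """
    grid = np.asarray(grid, dtype=float)
    if grid.size == 0:
        raise ValueError("threshold grid is empty")
    out = []
    for t in grid:
        s = stratify(model, cohort, float(t))
        out.append({
            "threshold": float(t),
            "proportion_high": s.proportion_high,
            "sensitivity": s.sensitivity,
            "specificity": s.specificity,
            "tp": s.tp, "fp": s.fp, "tn": s.tn, "fn": s.fn,
        })
    return out
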