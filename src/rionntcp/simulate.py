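"""Synthetic cohort generation.

The clinical cohort behind this pipeline (289 skull-base chordoma /
chondrosarcoma patients from two proton-therapy institutions) is not
public, so the generator here emulates its covariate margins — age,
hypertension prevalence and missingness, sex ratio, institutional split,
tumor mix, surgery counts, GTV volume, optic-apparatus dose metrics and
prescription doses — and draws binary neuropathy outcomes from the logistic
NTCP mechanism with configurable ground-truth coefficients.  The default
ground truth is the published bivariable model (offset -5.07, age slope
0.031 per year, hypertension 1.21), which puts the simulation in the same
rare-event regime (incidence in the low single-digit percent) as the study.

Covariates are mutually independent apart from two conditionings present in
the study design: tumor type depends on institution (one institution treated
only chondrosarcoma) and prescription dose depends on tumor type.  An
optional age-hypertension logistic link is available for stress tests and is
off by default.  Missingness is completely at random.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Mapping

import numpy as np
from scipy import optimize
from scipy.stats import truncnorm

from .cohort import Cohort, PatientRecord, covariate_frame

__all__ = ["SimulationConfig", "generate_cohort", "assign_outcomes", "preset_config"]

# empirical CTCAE grade distribution among cases (grades 1..4 in ratio 3:1:3:5)
GRADE_WEIGHTS = np.array([3.0, 1.0, 3.0, 5.0]) / 12.0

DEFAULT_TRUE_BETA = {"offset": -5.07, "age": 0.031, "hypertension": 1.21}


def _trunc_geom_p(mean: float, kmax: int) -> float:
    """Success probability of a geometric on 1..kmax matching ``mean``."""

    def m(q: float) -> float:
        k = np.arange(1, kmax + 1)
        w = (1 - q) ** (k - 1) * q
        return float(np.sum(k * w) / np.sum(w))

    return optimize.brentq(lambda q: m(q) - mean, 1e-6, 1 - 1e-6)


@dataclass
class SimulationConfig:
    """Ground truth and covariate margins for cohort simulation.

    Defaults reproduce the published cohort's margins: n=289 across two
    institutions (143 PSI / 146 CPO), ~35/65 chordoma/chondrosarcoma with
    all chordomas at PSI, age truncated-normal (mean 44, sd 13) on [18, 80],
    hypertension prevalence 0.19 with 16/289 missing, tumor involvement
    112/286 with 3/289 missing, 152/289 female, surgery counts on 1..8 with
    mean 1.6, GTV log-normal with median 27.2 cc on [0.2, 130], maximum
    optic dose truncated-normal centred at 59.6 Gy_RBE on [45, 76], and
    prescription doses by tumor type (chordoma median 74 on [68, 76],
    chondrosarcoma median 70 on [67, 76]).
    """

    n: int = 289
    seed: int = 0
    true_beta: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_TRUE_BETA))

    age_mean: float = 44.0
    age_sd: float = 13.0
    age_bounds: tuple[float, float] = (18.0, 80.0)

    hbp_prevalence: float = 0.19
    hbp_missing_rate: float = 16.0 / 289.0
    involvement_prevalence: float = 112.0 / 286.0
    involvement_missing_rate: float = 3.0 / 289.0
    sex_female_prob: float = 152.0 / 289.0

    psi_prob: float = 143.0 / 289.0
    psi_chordoma_prob: float = 101.0 / 143.0   # CPO treats chondrosarcoma only
    cpo_protons_only_prob: float = 52.0 / 146.0

    surgeries_mean: float = 1.6
    surgeries_max: int = 8

    gtv_median: float = 27.2
    gtv_log_sd: float = 0.9
    gtv_bounds: tuple[float, float] = (0.2, 130.0)

    dmax_mean: float = 59.6
    dmax_sd: float = 7.0
    dmax_bounds: tuple[float, float] = (45.0, 76.0)

    dmin_median: float = 2.0
    dmin_log_sd: float = 1.2

    rx_chordoma: tuple[float, float, float, float] = (74.0, 2.0, 68.0, 76.0)  # mean, sd, lo, hi
    rx_chondrosarcoma: tuple[float, float, float, float] = (70.0, 2.0, 67.0, 76.0)

    followup_median: float = 73.8
    followup_log_sd: float = 0.5
    followup_bounds: tuple[float, float] = (5.0, 197.0)

    photon_share_range: tuple[float, float] = (0.2, 0.5)  # mixed regimens only

    # optional realism hook: hypertension probability rising with age
    hbp_age_link: bool = False
    hbp_age_slope: float = 0.05  # per year on the logit scale

    def validate(self) -> None:
        if self.n < 1:
            raise ValueError("cohort size must be at least 1")
        for name in ("hbp_prevalence", "hbp_missing_rate", "involvement_prevalence",
                     "involvement_missing_rate", "sex_female_prob", "psi_prob",
                     "psi_chordoma_prob", "cpo_protons_only_prob"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        for name in ("age_bounds", "gtv_bounds", "dmax_bounds", "followup_bounds"):
            lo, hi = getattr(self, name)
            if not lo < hi:
                raise ValueError(f"{name} bounds inverted: ({lo}, {hi})")
        if not 1.0 <= self.surgeries_mean <= self.surgeries_max:
            raise ValueError("surgeries_mean outside the 1..surgeries_max support")
        if "offset" not in self.true_beta:
            raise ValueError("true_beta must include an 'offset' entry")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["true_beta"] = dict(self.true_beta)
        return d


def preset_config(name: str, **overrides) -> SimulationConfig:
    """Named cohort presets: ``combined`` (both institutions), ``psi_like``
    and ``cpo_like`` (single-institution margins)."""
    if name == "combined":
        cfg = SimulationConfig()
    elif name == "psi_like":
        cfg = SimulationConfig(n=143, psi_prob=1.0)
    elif name == "cpo_like":
        cfg = SimulationConfig(n=146, psi_prob=0.0)
    else:
        raise KeyError(f"unknown preset '{name}'")
    for k, v in overrides.items():
        setattr(cfg, k, v)
    cfg.validate()
    return cfg


def _trunc_normal(rng, mean, sd, lo, hi, size):
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return truncnorm.rvs(a, b, loc=mean, scale=sd, size=size, random_state=rng)


def _trunc_lognormal(rng, median, log_sd, lo, hi, size):
    # rejection sampling; acceptance is high for the margins used here
    out = np.empty(size)
    filled = 0
    mu = math.log(median)
    while filled < size:
        draw = rng.lognormal(mu, log_sd, size=2 * (size - filled) + 8)
        ok = draw[(draw >= lo) & (draw <= hi)]
        take = min(len(ok), size - filled)
        out[filled:filled + take] = ok[:take]
        filled += take
    return out


def generate_cohort(config: SimulationConfig) -> Cohort:
    """Draw a reproducible synthetic cohort and assign outcomes from the
    configured ground-truth logistic model."""
    config.validate()
    ss = np.random.SeedSequence(config.seed)
    cov_ss, outcome_ss = ss.spawn(2)
    rng = np.random.default_rng(cov_ss)
    n = config.n

    age = _trunc_normal(rng, config.age_mean, config.age_sd, *config.age_bounds, size=n)

    if config.hbp_age_link:
        base = math.log(config.hbp_prevalence / (1 - config.hbp_prevalence))
        logit = base + config.hbp_age_slope * (age - config.age_mean)
        p_hbp = 1.0 / (1.0 + np.exp(-logit))
    else:
        p_hbp = np.full(n, config.hbp_prevalence)
    hbp = rng.random(n) < p_hbp
    hbp_missing = rng.random(n) < config.hbp_missing_rate

    involvement = rng.random(n) < config.involvement_prevalence
    involvement_missing = rng.random(n) < config.involvement_missing_rate

    female = rng.random(n) < config.sex_female_prob
    psi = rng.random(n) < config.psi_prob
    chordoma = np.where(psi, rng.random(n) < config.psi_chordoma_prob, False)

    q = _trunc_geom_p(config.surgeries_mean, config.surgeries_max)
    k = np.arange(1, config.surgeries_max + 1)
    pk = (1 - q) ** (k - 1) * q
    surgeries = rng.choice(k, size=n, p=pk / pk.sum())

    gtv = _trunc_lognormal(rng, config.gtv_median, config.gtv_log_sd, *config.gtv_bounds, size=n)
    dmax = _trunc_normal(rng, config.dmax_mean, config.dmax_sd, *config.dmax_bounds, size=n)
    dmin = np.minimum(
        _trunc_lognormal(rng, config.dmin_median, config.dmin_log_sd, 0.0, np.inf, size=n),
        0.8 * dmax,
    )
    # three ordered interior metrics between dmin and dmax: d99 <= dmean <= d1
    inner = np.sort(rng.random((n, 3)), axis=1)
    d99 = dmin + inner[:, 0] * (dmax - dmin)
    dmean = dmin + inner[:, 1] * (dmax - dmin)
    d1 = dmin + inner[:, 2] * (dmax - dmin)

    rx = np.where(
        chordoma,
        _trunc_normal(rng, config.rx_chordoma[0], config.rx_chordoma[1],
                      config.rx_chordoma[2], config.rx_chordoma[3], size=n),
        _trunc_normal(rng, config.rx_chondrosarcoma[0], config.rx_chondrosarcoma[1],
                      config.rx_chondrosarcoma[2], config.rx_chondrosarcoma[3], size=n),
    )

    protons_only = np.where(psi, True, rng.random(n) < config.cpo_protons_only_prob)
    share = rng.uniform(*config.photon_share_range, size=n)
    photon = np.where(protons_only, 0.0, share * rx)
    proton = rx - photon

    followup = _trunc_lognormal(rng, config.followup_median, config.followup_log_sd,
                                *config.followup_bounds, size=n)

    records = []
    for i in range(n):
        records.append(PatientRecord(
            patient_id=f"S{i:05d}",
            institution="PSI" if psi[i] else "CPO",
            tumor_type="chordoma" if chordoma[i] else "chondrosarcoma",
            age=float(age[i]),
            sex="F" if female[i] else "M",
            hypertension=None if hbp_missing[i] else ("yes" if hbp[i] else "no"),
            n_surgeries=int(surgeries[i]),
            gtv_volume=float(gtv[i]),
            tumor_involvement=None if involvement_missing[i] else ("yes" if involvement[i] else "no"),
            prescription_dose=float(rx[i]),
            proton_dose=float(proton[i]),
            photon_dose=float(photon[i]),
            optic_dmin=float(dmin[i]),
            optic_dmean=float(dmean[i]),
            optic_dmax=float(dmax[i]),
            optic_d1=float(d1[i]),
            optic_d99=float(d99[i]),
            followup_months=float(followup[i]),
            rion_grade=0,
            modality_protons_only=bool(protons_only[i]),
            modality_pbs=bool(psi[i]),
        ))
    cohort = Cohort(records, provenance=f"synthetic(seed={config.seed}, n={n})")
    return assign_outcomes(cohort, config.true_beta, seed=outcome_ss)


def assign_outcomes(cohort: Cohort, true_beta: Mapping[str, float], seed) -> Cohort:
    """Draw Bernoulli neuropathy events at each record's NTCP under
    ``true_beta`` and assign CTCAE grades among cases from the 3:1:3:5
    empirical grade distribution.

    ``true_beta`` maps ``"offset"`` plus covariate names to coefficients.
    Records missing a value for an active covariate get that term omitted
    from their linear predictor and their ids are flagged in
    ``meta['outcome_flagged_missing']``.
    """
    rng = np.random.default_rng(seed)
    frame = covariate_frame(cohort)
    active = [k for k in true_beta if k != "offset" and true_beta[k] != 0.0]
    for name in active:
        if name not in frame.columns:
            raise KeyError(f"true_beta references unknown covariate '{name}'")

    eta = np.full(cohort.n, float(true_beta["offset"]))
    flagged: list[str] = []
    for name in active:
        col = frame[name].to_numpy()
        miss = np.isnan(col)
        contrib = np.where(miss, 0.0, col) * float(true_beta[name])
        eta += contrib
        flagged.extend(frame.index[miss])
    p = 1.0 / (1.0 + np.exp(-eta))
    events = rng.random(cohort.n) < p
    grades = rng.choice([1, 2, 3, 4], size=cohort.n, p=GRADE_WEIGHTS)

    records = []
    for rec, ev, g in zip(cohort.records, events, grades):
        new = PatientRecord(**{f: getattr(rec, f) for f in rec.__dataclass_fields__})
        new.rion_grade = int(g) if ev else 0
        records.append(new)
    out = Cohort(records, provenance=cohort.provenance, meta=dict(cohort.meta))
    if flagged:
        out.meta["outcome_flagged_missing"] = sorted(set(flagged))
    out.meta["true_ntcp_mean"] = float(p.mean())
    return out
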