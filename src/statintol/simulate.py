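"""Seeded synthetic EMR cohorts and trial datasets for statin-intolerance analyses.

The observational generator emulates a Tayside-like prescribing database:
each patient gets a Hardy-Weinberg genotype at the rs12975366 T>C variant,
covariates (age, sex, type-2 diabetes, interacting co-medication), a latent
intolerance class, and prescription/laboratory trajectories constructed so
that the phenotyping rules deterministically recover the planted class.

The latent class is drawn from per-patient category probabilities

    P(GSI case)  = k_g * OR_gsi^d * exp(x'gamma_g)
    P(LDI case)  = k_l * OR_ldi^d * exp(x'gamma_l)
    P(tolerant)  = constant
    P(other)     = remainder (messy records, unclassifiable)

where ``d`` is the dominant genotype code (T/T = 1). Because tolerant
probability is constant, the conditional log-odds of case vs tolerant
control is exactly ``ln(k/p_tol) + ln(OR) * d + x'gamma``, so a logistic
case/control fit targets the planted odds ratio without collider bias, and
the constants ``k`` are calibrated so each case class hits its target
prevalence. Trajectory construction is fully vectorised; identical config
(including seed) yields byte-identical tables.

The trial generator emulates a 1:1 randomized placebo-controlled statin
trial with exponential myalgia times whose rate is the baseline rate times
the genotype-stratum hazard ratio in the treated arm, administrative
censoring uniform within +/-0.4 years of the median follow-up, and a final
CK measure that depends on genotype only (so adjusting for it is harmless).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .association import VARIANT_RSID
from .config import RulesConfig, SimulationConfig, ValidationError

logger = logging.getLogger(__name__)

#: Observation window of the synthetic prescribing database.
RECORDS_START = pd.Timestamp("1990-01-01")
RECORDS_END = pd.Timestamp("2013-07-31")

_EPOCH = np.datetime64("1970-01-01")
_REC_END_D = int((RECORDS_END - pd.Timestamp("1970-01-01")).days)

# covariate log-odds effects on the intolerance classes (shared scheme;
# magnitudes chosen as plausible EMR-cohort associations: co-medication and
# female sex raise intolerance odds, later age at start lowers GSI odds)
GSI_COVARIATE_EFFECTS = {"comedication": np.log(1.5), "female": np.log(1.33), "age_dec": np.log(0.85)}
LDI_COVARIATE_EFFECTS = {"comedication": np.log(1.5)}

_SCRIPT_DAYS = 56  # standard 8-week dispensing interval

TRUTH_TO_PHENOTYPE = {
    "GSI": ("case", "unclassified"),
    "LDI": ("unclassified", "case"),
    "ST1": ("control", "control"),
    "ST2": ("unclassified", "control"),
    "OTHER": ("unclassified", "unclassified"),
}


@dataclass
class CohortBundle:
    """The five linked tables of a synthetic observational cohort."""

    patients: pd.DataFrame
    prescriptions: pd.DataFrame
    labs: pd.DataFrame
    genotypes: pd.DataFrame
    truth: pd.DataFrame
    records_end: pd.Timestamp = field(default=RECORDS_END)

    def validate(self) -> None:
        ids = set(self.patients["patient_id"])
        for name in ("prescriptions", "labs", "genotypes", "truth"):
            tbl = getattr(self, name)
            orphans = set(tbl["patient_id"]) - ids
            if orphans:
                raise ValidationError(f"{name} references unknown patients: {sorted(orphans)[:5]}")
        dup = self.genotypes.duplicated(subset=["patient_id", "rsid"])
        if dup.any():
            raise ValidationError("more than one genotype per patient per variant")


def _rng(seed_or_rng) -> np.random.Generator:
    if isinstance(seed_or_rng, np.random.Generator):
        return seed_or_rng
    return np.random.default_rng(seed_or_rng)


def _days(ts: str | pd.Timestamp) -> int:
    return int((pd.Timestamp(ts) - pd.Timestamp("1970-01-01")).days)


def _draw_genotypes(rng: np.random.Generator, n: int, maf: float) -> np.ndarray:
    """Hardy-Weinberg draw; returns genotype strings with C as the alternate allele."""
    q = maf
    probs = np.array([(1 - q) ** 2, 2 * q * (1 - q), q**2])
    codes = rng.choice(3, size=n, p=probs / probs.sum())
    return np.array(["T/T", "T/C", "C/C"])[codes]


def simulate_genotypes(n: int, maf: float, seed=0) -> pd.DataFrame:
    """Simulate ``n`` biallelic genotype calls under Hardy-Weinberg proportions."""
    if not 0.0 <= maf <= 1.0:
        raise ValidationError(f"maf must be in [0, 1], got {maf}")
    if n < 1:
        raise ValidationError("n must be >= 1")
    rng = _rng(seed)
    return pd.DataFrame(
        {
            "patient_id": [f"P{i:06d}" for i in range(n)],
            "rsid": VARIANT_RSID,
            "genotype": _draw_genotypes(rng, n, maf),
        }
    )


def _ragged_offsets(counts: np.ndarray, intervals: np.ndarray) -> np.ndarray:
    """Exclusive per-group cumulative sum for ragged per-patient script rows."""
    if len(intervals) == 0:
        return intervals
    cs = np.cumsum(intervals)
    ex = cs - intervals
    first = np.concatenate([[0], np.cumsum(counts)[:-1]])
    idx = np.repeat(np.arange(len(counts)), counts)
    return ex - ex[first][idx]


def _truncnorm(rng, n, mean, sd, lo, hi):
    from scipy.stats import truncnorm

    a, b = (lo - mean) / sd, (hi - mean) / sd
    return truncnorm.rvs(a, b, loc=mean, scale=sd, size=n, random_state=rng)


def simulate_observational_cohort(
    config: SimulationConfig, rules: Optional[RulesConfig] = None
) -> CohortBundle:
    """Generate a seeded synthetic observational statin cohort.

    Trajectories are built per latent class against the supplied phenotyping
    ``rules`` so that, on these noise-free records, classification recovers
    the planted class exactly:

    * **GSI** — three statin courses (two countable switches), total
      discontinuation well before the records end, and one on-statin CK
      spike at ``ck_uln_multiplier_cases`` x ULN; every discontinued dose is
      above the drug's lowest approved starting dose.
    * **LDI** — a first statin at its lowest approved starting dose
      discontinued after ~7 months, a second statin later, all CK normal.
    * **ST1 / ST2** — a single simvastatin course (>=40 mg/day) tiled with
      gaps of at most four days from therapy start to the records end; ST2
      patients additionally carry one incidental on-statin CK elevation.
    * **OTHER** — a short (<6 months) single-statin course, CK normal.
    """
    rules = rules or RulesConfig()
    cfg = config
    rng = _rng(cfg.seed)
    n = cfg.n_patients
    ids = np.array([f"P{i:06d}" for i in range(n)])

    genotype = _draw_genotypes(rng, n, cfg.maf)
    dom = (genotype == "T/T").astype(int)

    age = _truncnorm(rng, n, 60.0, 10.0, 35.0, 90.0)
    female = rng.random(n) < 0.5
    sex = np.where(female, "F", "M")
    t2d = (rng.random(n) < cfg.t2d_prob).astype(int)
    comed = (rng.random(n) < cfg.comedication_prob).astype(int)

    x_gsi = (
        GSI_COVARIATE_EFFECTS["comedication"] * comed
        + GSI_COVARIATE_EFFECTS["female"] * female
        + GSI_COVARIATE_EFFECTS["age_dec"] * (age - 60.0) / 10.0
    )
    x_ldi = LDI_COVARIATE_EFFECTS["comedication"] * comed

    rr_gsi = cfg.planted_or_gsi**dom * np.exp(x_gsi)
    rr_ldi = cfg.planted_or_ldi**dom * np.exp(x_ldi)
    p_gsi = cfg.intolerance_prevalence * rr_gsi / rr_gsi.mean()
    p_ldi = cfg.intolerance_prevalence * rr_ldi / rr_ldi.mean()
    p_tol = np.full(n, cfg.tolerant_fraction)
    total = p_gsi + p_ldi + p_tol
    if total.max() >= 1.0:
        raise ValidationError("class probabilities exceed 1; lower prevalence or effects")
    if n * cfg.intolerance_prevalence < 10:
        warnings.warn("expected case count below 10; estimates will be unstable")

    u = rng.random(n)
    latent = np.where(
        u < p_gsi,
        "GSI",
        np.where(u < p_gsi + p_ldi, "LDI", np.where(u < total, "TOL", "OTHER")),
    )
    st2_only = rng.random(n) < cfg.st2_only_fraction
    latent = np.where(latent == "TOL", np.where(st2_only, "ST2", "ST1"), latent)

    uln = np.where(female, rules.ck_uln_female, rules.ck_uln_male)
    mu_log_ck = np.where(female, np.log10(70.0), np.log10(100.0))

    rx_parts, lab_parts = [], []

    def add_labs(pids, dates_d, values):
        lab_parts.append(
            pd.DataFrame(
                {"patient_id": pids, "date": dates_d, "analyte": "CK", "value": values}
            )
        )

    # therapy start day per patient (set per class below)
    start_d = np.zeros(n, dtype=int)

    # ---- tolerant controls: simvastatin tiled to the records end ----------
    m_tol = np.isin(latent, ["ST1", "ST2"])
    idx_tol = np.flatnonzero(m_tol)
    if len(idx_tol):
        lo = _days("1993-01-01")
        hi = _REC_END_D - int((rules.min_years + 1.5) * 365.25)
        s = rng.integers(lo, hi + 1, size=len(idx_tol))
        start_d[idx_tol] = s
        window = _REC_END_D - s
        counts = window // _SCRIPT_DAYS + 2
        pid_rep = np.repeat(ids[idx_tol], counts)
        gaps = rng.integers(0, 5, size=counts.sum())
        offsets = _ragged_offsets(counts, _SCRIPT_DAYS + gaps)
        starts = np.repeat(s, counts) + offsets
        keep = starts < _REC_END_D
        # mostly simvastatin with some atorvastatin courses, 40/80 mg
        # simvastatin-equivalent, so drug and dose overlap with the case classes
        regimen = rng.choice(4, p=[0.60, 0.20, 0.15, 0.05], size=len(idx_tol))
        drug = np.array(["simvastatin", "simvastatin", "atorvastatin", "atorvastatin"])[regimen]
        dose = np.array([40.0, 80.0, 20.0, 40.0])[regimen]
        rx_parts.append(
            pd.DataFrame(
                {
                    "patient_id": pid_rep[keep],
                    "drug": np.repeat(drug, counts)[keep],
                    "daily_dose_mg": np.repeat(dose, counts)[keep],
                    "start_date": starts[keep],
                    "days_supply": _SCRIPT_DAYS,
                }
            )
        )
        # incidental on-statin CK elevation for ST2-only controls
        m_st2 = latent[idx_tol] == "ST2"
        if m_st2.any():
            sel = idx_tol[m_st2]
            add_labs(
                ids[sel],
                start_d[sel] + rng.integers(60, 500, size=len(sel)),
                uln[sel] * rng.uniform(1.1, 1.4, size=len(sel)),
            )

    # ---- GSI cases: three courses, two switches, CK spike, full stop ------
    idx_gsi = np.flatnonzero(latent == "GSI")
    if len(idx_gsi):
        s = rng.integers(_days("1995-01-01"), _days("2005-12-31"), size=len(idx_gsi))
        start_d[idx_gsi] = s
        # drug sequences: three courses, every discontinued dose above the
        # drug's lowest starting dose, equivalent dose constant (40 or 80 mg)
        seq_drugs = np.array(
            [
                ["simvastatin", "pravastatin", "fluvastatin"],
                ["simvastatin", "atorvastatin", "rosuvastatin"],
                ["atorvastatin", "simvastatin", "fluvastatin"],
                ["atorvastatin", "simvastatin", "rosuvastatin"],
            ]
        )
        seq_doses = np.array(
            [[40.0, 80.0, 80.0], [80.0, 40.0, 20.0], [20.0, 40.0, 80.0], [40.0, 80.0, 20.0]]
        )
        seq = rng.choice(4, p=[0.45, 0.15, 0.30, 0.10], size=len(idx_gsi))
        per = 6  # scripts per course
        j = np.tile(np.arange(3 * per), len(idx_gsi))
        pid_rep = np.repeat(ids[idx_gsi], 3 * per)
        starts = np.repeat(s, 3 * per) + j * _SCRIPT_DAYS
        phase = j // per
        drug = seq_drugs[np.repeat(seq, 3 * per), phase]
        dose = seq_doses[np.repeat(seq, 3 * per), phase]
        rx_parts.append(
            pd.DataFrame(
                {
                    "patient_id": pid_rep,
                    "drug": drug,
                    "daily_dose_mg": dose,
                    "start_date": starts,
                    "days_supply": _SCRIPT_DAYS,
                }
            )
        )
        add_labs(
            ids[idx_gsi],
            s + rng.integers(60, 500, size=len(idx_gsi)),
            uln[idx_gsi]
            * cfg.ck_uln_multiplier_cases
            * rng.uniform(1.0, 1.3, size=len(idx_gsi)),
        )

    # ---- LDI cases: lowest-dose course discontinued, second statin later --
    idx_ldi = np.flatnonzero(latent == "LDI")
    if len(idx_ldi):
        s = rng.integers(_days("1995-01-01"), _days("2009-06-30"), size=len(idx_ldi))
        start_d[idx_ldi] = s
        combo = rng.integers(0, 3, size=len(idx_ldi))
        d1 = np.choose(combo, ["simvastatin", "rosuvastatin", "atorvastatin"])
        dose1 = np.array(
            [rules.lowest_start_dose[d] for d in ("simvastatin", "rosuvastatin", "atorvastatin")]
        )[combo]
        d2 = np.choose(combo, ["atorvastatin", "simvastatin", "rosuvastatin"])
        dose2 = np.choose(combo, [20.0, 20.0, 10.0])
        gap = rng.integers(120, 401, size=len(idx_ldi))
        per = 4
        j = np.tile(np.arange(2 * per), len(idx_ldi))
        phase = j // per
        pid_rep = np.repeat(ids[idx_ldi], 2 * per)
        starts = (
            np.repeat(s, 2 * per)
            + j * _SCRIPT_DAYS
            + phase * np.repeat(gap, 2 * per)
        )
        drug = np.where(phase == 0, np.repeat(d1, 2 * per), np.repeat(d2, 2 * per))
        dose = np.where(phase == 0, np.repeat(dose1, 2 * per), np.repeat(dose2, 2 * per))
        rx_parts.append(
            pd.DataFrame(
                {
                    "patient_id": pid_rep,
                    "drug": drug,
                    "daily_dose_mg": dose,
                    "start_date": starts,
                    "days_supply": _SCRIPT_DAYS,
                }
            )
        )

    # ---- unclassifiable remainder: short single-statin course -------------
    idx_oth = np.flatnonzero(latent == "OTHER")
    if len(idx_oth):
        s = rng.integers(_days("1995-01-01"), _days("2010-12-31"), size=len(idx_oth))
        start_d[idx_oth] = s
        drug1 = np.where(rng.random(len(idx_oth)) < 0.6, "simvastatin", "atorvastatin")
        per = 3
        pid_rep = np.repeat(ids[idx_oth], per)
        starts = np.repeat(s, per) + np.tile(np.arange(per), len(idx_oth)) * _SCRIPT_DAYS
        rx_parts.append(
            pd.DataFrame(
                {
                    "patient_id": pid_rep,
                    "drug": np.repeat(drug1, per),
                    "daily_dose_mg": 20.0,
                    "start_date": starts,
                    "days_supply": _SCRIPT_DAYS,
                }
            )
        )

    # ---- shared laboratory background -------------------------------------
    def normal_ck(size, idx):
        v = 10 ** rng.normal(mu_log_ck[idx], 0.18, size=size)
        return np.minimum(v, 0.95 * uln[idx])

    add_labs(ids, start_d - rng.integers(30, 400, size=n), normal_ck(n, np.arange(n)))
    for _ in range(2):
        add_labs(ids, start_d + rng.integers(30, 700, size=n), normal_ck(n, np.arange(n)))
    ldl = pd.DataFrame(
        {
            "patient_id": ids,
            "date": start_d - rng.integers(10, 200, size=n),
            "analyte": "LDL",
            "value": np.clip(rng.normal(3.3, 0.8, size=n), 0.5, 9.0),
        }
    )

    prescriptions = pd.concat(rx_parts, ignore_index=True)
    prescriptions["start_date"] = pd.to_datetime(prescriptions["start_date"], unit="D")
    prescriptions = prescriptions.sort_values(
        ["patient_id", "start_date", "drug"], kind="mergesort"
    ).reset_index(drop=True)

    labs = pd.concat(lab_parts + [ldl], ignore_index=True)
    labs["date"] = pd.to_datetime(labs["date"], unit="D")
    labs = labs.sort_values(["patient_id", "date", "analyte"], kind="mergesort").reset_index(
        drop=True
    )

    patients = pd.DataFrame(
        {
            "patient_id": ids,
            "age": np.round(age, 1),
            "sex": sex,
            "t2d": t2d,
            "comedication": comed,
        }
    )
    genotypes = pd.DataFrame({"patient_id": ids, "rsid": VARIANT_RSID, "genotype": genotype})
    gsi_truth = np.array([TRUTH_TO_PHENOTYPE[c][0] for c in latent])
    ldi_truth = np.array([TRUTH_TO_PHENOTYPE[c][1] for c in latent])
    truth = pd.DataFrame(
        {
            "patient_id": ids,
            "latent_class": latent,
            "gsi_truth": gsi_truth,
            "ldi_truth": ldi_truth,
        }
    )
    bundle = CohortBundle(
        patients=patients,
        prescriptions=prescriptions,
        labs=labs,
        genotypes=genotypes,
        truth=truth,
    )
    bundle.validate()
    logger.info("simulated cohort: %s", dict(zip(*np.unique(latent, return_counts=True))))
    return bundle


def simulate_trial_cohort(config: SimulationConfig) -> pd.DataFrame:
    """Simulate a 1:1 randomized two-arm statin trial with myalgia times.

    Event times are exponential with rate ``baseline_myalgia_rate`` times
    the genotype-stratum hazard ratio for the treated arm; censoring is
    administrative, uniform within +/-0.4 years of the median follow-up.
    Returns one row per participant: arm (1 statin / 0 placebo), genotype,
    dominant code, observed time in years, event indicator and final CK.
    """
    cfg = config
    rng = _rng(cfg.seed)
    n = cfg.n_patients
    ids = np.array([f"T{i:06d}" for i in range(n)])
    genotype = _draw_genotypes(rng, n, cfg.maf)
    dom = (genotype == "T/T").astype(int)

    arm = np.zeros(n, dtype=int)
    arm[: n - n // 2] = 1
    arm = arm[rng.permutation(n)]

    hr = np.where(dom == 1, cfg.trial_hr_tt, cfg.trial_hr_carrier)
    rate = cfg.baseline_myalgia_rate * np.where(arm == 1, hr, 1.0)
    t_event = rng.exponential(1.0 / rate)
    censor = rng.uniform(
        cfg.followup_years_median - 0.4, cfg.followup_years_median + 0.4, size=n
    )
    time = np.minimum(t_event, censor)
    event = (t_event <= censor).astype(int)

    final_ck = 10 ** rng.normal(1.95 + 0.06 * dom, 0.22, size=n)
    return pd.DataFrame(
        {
            "patient_id": ids,
            "arm": arm,
            "genotype": genotype,
            "genotype_dom": dom,
            "time": time,
            "event": event,
            "final_ck": final_ck,
        }
    )
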