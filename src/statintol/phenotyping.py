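"""EMR-based statin-intolerance phenotyping.

Classifies statin users from longitudinal prescription and laboratory
records into two case/control phenotype pairs:

* **GSI** (general statin intolerance): on-statin CK above the upper limit
  of normal plus either two or more statin switches or discontinuation of
  all therapy; contrasted with tolerant controls (**ST1**) who maintained
  >90% prescription coverage for at least five years at a mean daily dose of
  at least 40 mg simvastatin-equivalent, never switched, never discontinued,
  and had consistently normal on-statin CK.
* **LDI** (low-dose intolerance): used two or more distinct statins and
  discontinued at least one of them at its lowest approved starting dose,
  irrespective of CK; contrasted with **ST2** controls, who meet all ST1
  criteria except the CK one.

All rule thresholds live in :class:`~statintol.config.RulesConfig`.
Operations accept pandas DataFrames (the cohort-scale API) and the
single-patient wrapper :func:`classify_patient` delegates to the same code
path, so classification is a pure function of (records, rules).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from datetime import date
from typing import Iterable, Optional

import numpy as np
import pandas as pd

from .config import STATINS, RulesConfig, ValidationError

logger = logging.getLogger(__name__)

PRESCRIPTION_COLUMNS = ["patient_id", "drug", "daily_dose_mg", "start_date", "days_supply"]
LAB_COLUMNS = ["patient_id", "date", "analyte", "value"]


@dataclass
class PrescriptionEvent:
    """One dispensed statin script covering ``[start_date, start_date + days_supply)``."""

    patient_id: str
    drug: str
    daily_dose_mg: float
    start_date: date
    days_supply: int


@dataclass
class LabResult:
    """One laboratory result (CK in IU/L, LDL in mmol/L)."""

    patient_id: str
    date: date
    analyte: str
    value: float


@dataclass
class CKFlags:
    """Tri-state on-statin CK flags; all ``None`` when no on-statin CK exists."""

    any_on_statin_above_uln: Optional[bool]
    any_on_statin_ge_4x_uln: Optional[bool]
    all_on_statin_normal: Optional[bool]
    max_on_statin_ck: Optional[float] = None


@dataclass
class PhenotypeAssignment:
    """Per-patient classification with the rule-evaluation audit trail."""

    patient_id: str
    gsi: str  # case | control | unclassified | excluded
    ldi: str
    flags: dict


def _as_prescription_frame(prescriptions) -> pd.DataFrame:
    if isinstance(prescriptions, pd.DataFrame):
        df = prescriptions.copy()
    else:
        df = pd.DataFrame(
            [
                {
                    "patient_id": p.patient_id,
                    "drug": p.drug,
                    "daily_dose_mg": p.daily_dose_mg,
                    "start_date": p.start_date,
                    "days_supply": p.days_supply,
                }
                for p in prescriptions
            ],
            columns=PRESCRIPTION_COLUMNS,
        )
    if len(df):
        unknown = sorted(set(df["drug"]) - set(STATINS))
        if unknown:
            raise ValidationError(f"unknown statin drug codes: {unknown}")
        if (df["daily_dose_mg"] <= 0).any():
            raise ValidationError("daily_dose_mg must be positive")
        if (df["days_supply"] < 1).any():
            raise ValidationError("days_supply must be >= 1")
    df["start_date"] = pd.to_datetime(df["start_date"])
    df["end_date"] = df["start_date"] + pd.to_timedelta(df["days_supply"], unit="D")
    return df.sort_values(["patient_id", "start_date", "drug"], kind="mergesort").reset_index(
        drop=True
    )


def _as_lab_frame(labs) -> pd.DataFrame:
    if isinstance(labs, pd.DataFrame):
        df = labs.copy()
    else:
        df = pd.DataFrame(
            [
                {"patient_id": l.patient_id, "date": l.date, "analyte": l.analyte, "value": l.value}
                for l in labs
            ],
            columns=LAB_COLUMNS,
        )
    df["date"] = pd.to_datetime(df["date"])
    return df


def dose_equivalent(drug: str, daily_dose_mg: float, rules: RulesConfig) -> float:
    """Convert a daily statin dose to its simvastatin-equivalent in mg/day."""
    if drug not in rules.dose_equivalence:
        raise ValidationError(f"unknown statin drug: {drug!r}")
    if daily_dose_mg <= 0:
        raise ValidationError("daily_dose_mg must be positive")
    return daily_dose_mg * rules.dose_equivalence[drug]


def compute_coverage(prescriptions, window: tuple) -> tuple[float, float]:
    """Fraction of a half-open date window covered by dispensed scripts.

    Overlapping scripts are unioned, never double-counted. Returns
    ``(coverage_fraction, window_years)`` with years on the 365.25-day scale.
    """
    start, end = (pd.Timestamp(window[0]), pd.Timestamp(window[1]))
    if end <= start:
        raise ValidationError("coverage window must be non-empty")
    window_days = (end - start).days
    df = _as_prescription_frame(prescriptions)
    covered = 0
    if len(df):
        s = df["start_date"].clip(lower=start).to_numpy()
        e = df["end_date"].clip(upper=end).to_numpy()
        running_end = np.datetime64(start.to_datetime64())
        for si, ei in zip(s, e):
            lo = max(si, running_end)
            if ei > lo:
                covered += (ei - lo).astype("timedelta64[D]").astype(int)
                running_end = ei
            running_end = max(running_end, ei)
    return covered / window_days, window_days / 365.25


def count_switches(prescriptions, rules: RulesConfig) -> tuple[int, int]:
    """Count statin switch events and distinct statins used.

    A switch is a drug change between chronologically consecutive scripts
    (same-day ties broken by drug name). A simvastatin-to-atorvastatin change
    whose atorvastatin script starts on/after the atorvastatin patent-expiry
    date is a systemic formulary shift and is not counted, although
    atorvastatin still counts as a distinct statin.
    """
    df = _as_prescription_frame(prescriptions)
    if df.empty:
        return 0, 0
    drugs = df["drug"].to_numpy()
    starts = df["start_date"].to_numpy()
    patent = np.datetime64(rules.atorvastatin_patent_date)
    changed = drugs[1:] != drugs[:-1]
    exempt = (
        (drugs[:-1] == "simvastatin")
        & (drugs[1:] == "atorvastatin")
        & (starts[1:] >= patent)
    )
    return int((changed & ~exempt).sum()), int(len(np.unique(drugs)))


def detect_discontinuations(prescriptions, records_end, rules: RulesConfig) -> pd.DataFrame:
    """Find per-drug discontinuation events.

    A drug is discontinued at script *s* when no script of the same drug
    starts within ``discontinuation_gap_days`` (strict ``>``) after *s*'s
    covered interval ends, unless the course is still covered within the gap
    at the end of records. Returns one row per event with the drug, the daily
    dose at *s* and the date coverage ended.
    """
    df = _as_prescription_frame(prescriptions)
    records_end = pd.Timestamp(records_end)
    if df.empty:
        return pd.DataFrame(columns=["patient_id", "drug", "daily_dose_mg", "date"])
    gap = pd.Timedelta(days=rules.discontinuation_gap_days)
    df = df.sort_values(["patient_id", "drug", "start_date"], kind="mergesort")
    grp = df.groupby(["patient_id", "drug"], sort=False)
    cov_end = grp["end_date"].cummax()
    next_start = grp["start_date"].shift(-1)
    last_of_course = next_start.isna()
    gap_after = np.where(last_of_course, records_end - cov_end, next_start - cov_end)
    is_event = pd.Series(gap_after, index=df.index) > gap
    ev = df.loc[is_event, ["patient_id", "drug", "daily_dose_mg"]].copy()
    ev["date"] = cov_end[is_event].to_numpy()
    return ev.reset_index(drop=True)


def flag_ck(labs, therapy_start, sex: str, rules: RulesConfig) -> CKFlags:
    """Evaluate on-statin CK flags for one patient.

    Only CK results dated on/after therapy start contribute. "Above ULN" is
    a strict comparison; the myopathy-candidate flag uses an inclusive
    >= ``sim_fold_uln`` x ULN. With no on-statin CK at all, every flag is
    ``None`` (undetermined) and the patient cannot qualify as an ST1 control.
    """
    df = _as_lab_frame(labs)
    uln = rules.ck_uln(sex)
    on = df[(df["analyte"] == "CK") & (df["date"] >= pd.Timestamp(therapy_start))]
    if on.empty:
        return CKFlags(None, None, None, None)
    v = on["value"].to_numpy(dtype=float)
    above = bool((v > uln).any())
    return CKFlags(
        any_on_statin_above_uln=above,
        any_on_statin_ge_4x_uln=bool((v >= rules.sim_fold_uln * uln).any()),
        all_on_statin_normal=not above,
        max_on_statin_ck=float(v.max()),
    )


def _interval_union_days(df: pd.DataFrame, window_end: pd.Series) -> pd.Series:
    """Vectorised per-patient union of covered days, clipped to the window end."""
    end_clip = df[["patient_id"]].join(window_end, on="patient_id")["window_end"]
    e = df["end_date"].where(df["end_date"] <= end_clip, end_clip)
    grp = df.groupby("patient_id", sort=False)
    prev_max_end = grp["end_date"].cummax().groupby(df["patient_id"], sort=False).shift(1)
    lo = df["start_date"].where(df["start_date"] > prev_max_end, prev_max_end)
    lo = lo.fillna(df["start_date"])
    days = (e - lo).dt.days.clip(lower=0)
    return days.groupby(df["patient_id"], sort=False).sum()


def classify_cohort(
    prescriptions,
    labs,
    patients: pd.DataFrame,
    rules: RulesConfig,
    records_end,
) -> pd.DataFrame:
    """Classify every patient in a cohort; returns the assignments table.

    ``patients`` must carry ``patient_id`` and ``sex`` ("M"/"F"). Patients
    with fewer than two statin prescriptions fail the study entry criterion
    and are marked ``excluded`` for both phenotypes (count logged). The
    output has one row per patient with the GSI and LDI status and every
    rule flag (audit trail): coverage, years on therapy, time-weighted mean
    simvastatin-equivalent dose, switch and distinct-statin counts,
    discontinuation flags, tri-state CK flags, and first/last statin.

    A patient meeting both a case rule and a control rule (possible for LDI
    when the only drug change is the exempt formulary shift) is classified
    as a case: case rules take precedence.
    """
    rx = _as_prescription_frame(prescriptions)
    lab = _as_lab_frame(labs)
    records_end = pd.Timestamp(records_end)
    out = patients[["patient_id", "sex"]].drop_duplicates("patient_id").set_index("patient_id")

    n_scripts = rx.groupby("patient_id")["drug"].size().reindex(out.index, fill_value=0)
    first_start = rx.groupby("patient_id")["start_date"].min()
    last_end = rx.groupby("patient_id")["end_date"].max()
    window_end = last_end.clip(upper=records_end).rename("window_end")
    window_days = (window_end - first_start).dt.days.clip(lower=1)

    covered = _interval_union_days(rx, window_end).reindex(out.index, fill_value=0)
    coverage = (covered / window_days).reindex(out.index)
    years = (window_days / 365.25).reindex(out.index)

    # time-weighted simvastatin-equivalent dose over dispensed days
    eq = rx["drug"].map(rules.dose_equivalence) * rx["daily_dose_mg"]
    w = rx["days_supply"].astype(float)
    by = rx.assign(eqd=eq * w, w=w).groupby("patient_id")[["eqd", "w"]].sum()
    mean_equiv = (by["eqd"] / by["w"]).reindex(out.index)
    min_equiv = eq.groupby(rx["patient_id"]).min().reindex(out.index)
    dose_stat = mean_equiv if rules.dose_summary == "mean" else min_equiv

    # switches / distinct statins (patent-exempt simvastatin->atorvastatin)
    patent = np.datetime64(rules.atorvastatin_patent_date)
    prev_drug = rx.groupby("patient_id")["drug"].shift(1)
    changed = rx["drug"].ne(prev_drug) & prev_drug.notna()
    exempt = (
        (prev_drug == "simvastatin")
        & (rx["drug"] == "atorvastatin")
        & (rx["start_date"].to_numpy() >= patent)
    )
    switches = (changed & ~exempt).groupby(rx["patient_id"]).sum().reindex(out.index, fill_value=0)
    distinct = rx.groupby("patient_id")["drug"].nunique().reindex(out.index, fill_value=0)

    first_statin = rx.groupby("patient_id")["drug"].first().reindex(out.index)
    last_statin = rx.groupby("patient_id")["drug"].last().reindex(out.index)

    ev = detect_discontinuations(rx, records_end, rules)
    lowest = ev["drug"].map(rules.lowest_start_dose)
    ev_lowest = ev[ev["daily_dose_mg"] <= lowest]
    any_lowest_disc = (
        ev_lowest.groupby("patient_id").size().gt(0).reindex(out.index, fill_value=False)
    )
    gap = pd.Timedelta(days=rules.discontinuation_gap_days)
    total_disc = ((records_end - last_end) > gap).reindex(out.index, fill_value=False)

    # on-statin CK flags (tri-state)
    ck = lab[lab["analyte"] == "CK"].copy()
    ck["therapy_start"] = ck["patient_id"].map(first_start)
    ck = ck[ck["date"] >= ck["therapy_start"]]
    uln = out["sex"].map({"M": rules.ck_uln_male, "F": rules.ck_uln_female})
    ck_max = ck.groupby("patient_id")["value"].max().reindex(out.index)
    has_ck = ck_max.notna()
    ck_above = pd.Series(ck_max > uln, dtype="boolean")
    ck_above[~has_ck] = pd.NA
    ck_ge4 = pd.Series(ck_max >= rules.sim_fold_uln * uln, dtype="boolean")
    ck_ge4[~has_ck] = pd.NA
    ck_normal = ~ck_above

    eligible = n_scripts >= 2
    n_excluded = int((~eligible).sum())
    if n_excluded:
        logger.info(
            "%d patient(s) excluded: fewer than two statin prescriptions", n_excluded
        )

    switch_metric = switches if rules.gsi_switch_metric == "switches" else distinct
    gsi_case = ck_above.fillna(False).astype(bool) & (
        (switch_metric >= rules.min_switches_gsi) | total_disc
    )
    st_base = (
        (coverage > rules.coverage_threshold)
        & (years >= rules.min_years)
        & (dose_stat >= rules.min_equiv_dose)
        & (switches == 0)
        & ~total_disc
    ).fillna(False)
    st1 = st_base & ck_normal.fillna(False).astype(bool)
    ldi_case = (distinct >= rules.min_distinct_statins_ldi) & any_lowest_disc

    gsi = np.select([~eligible, gsi_case, st1], ["excluded", "case", "control"], "unclassified")
    ldi = np.select(
        [~eligible, ldi_case, st_base], ["excluded", "case", "control"], "unclassified"
    )

    res = pd.DataFrame(
        {
            "patient_id": out.index,
            "gsi": gsi,
            "ldi": ldi,
            "n_scripts": n_scripts.to_numpy(),
            "coverage": coverage.to_numpy(),
            "years_on_therapy": years.to_numpy(),
            "mean_equiv_dose": mean_equiv.to_numpy(),
            "switches_n": switches.to_numpy(),
            "distinct_statins": distinct.to_numpy(),
            "first_statin": first_statin.to_numpy(),
            "last_statin": last_statin.to_numpy(),
            "total_discontinued": total_disc.to_numpy(),
            "discontinued_lowest_dose": any_lowest_disc.to_numpy(),
            "ck_elevated_on_statin": ck_above.reset_index(drop=True),
            "ck_ge_4x_uln": ck_ge4.reset_index(drop=True),
            "ck_all_normal": ck_normal.reset_index(drop=True),
            "max_on_statin_ck": ck_max.to_numpy(),
        }
    ).reset_index(drop=True)
    for name in ("gsi", "ldi"):
        counts = res[name].value_counts().to_dict()
        logger.info("%s classification counts: %s", name.upper(), counts)
    return res


def classify_patient(
    prescriptions, labs, sex: str, rules: RulesConfig, records_end
) -> PhenotypeAssignment:
    """Classify a single patient (thin wrapper over :func:`classify_cohort`)."""
    rx = _as_prescription_frame(prescriptions)
    if rx.empty:
        raise ValidationError("patient has no prescriptions")
    pid = rx["patient_id"].iloc[0]
    patients = pd.DataFrame({"patient_id": [pid], "sex": [sex]})
    res = classify_cohort(rx, _as_lab_frame(labs), patients, rules, records_end)
    row = res.iloc[0]
    flags = row.drop(["patient_id", "gsi", "ldi"]).to_dict()
    return PhenotypeAssignment(patient_id=pid, gsi=row["gsi"], ldi=row["ldi"], flags=flags)


def build_analysis_table(
    assignments: pd.DataFrame,
    genotypes: pd.DataFrame,
    covariates: pd.DataFrame,
    phenotype: str,
) -> pd.DataFrame:
    """Join classification, dominant genotype coding and covariates.

    One row per patient classified for the chosen phenotype (``"gsi"`` or
    ``"ldi"``), with ``outcome`` 1 for cases and 0 for controls, the dominant
    genotype code (T/T homozygote = 1, Gly carrier = 0), covariates, simple
    first/last-statin indicators and log10 of the maximum on-statin CK.
    Unclassified/excluded patients and patients without a genotype call are
    dropped, with counts logged.
    """
    from .association import encode_dominant

    if phenotype not in ("gsi", "ldi"):
        raise ValidationError("phenotype must be 'gsi' or 'ldi'")
    if assignments["patient_id"].duplicated().any():
        raise ValidationError("duplicated patient_id in assignments")
    if genotypes["patient_id"].duplicated().any():
        raise ValidationError("duplicated patient_id in genotypes")

    keep = assignments[assignments[phenotype].isin(["case", "control"])].copy()
    n_dropped = len(assignments) - len(keep)
    if n_dropped:
        logger.info(
            "%d patient(s) unclassified for %s and dropped", n_dropped, phenotype.upper()
        )
    keep["outcome"] = (keep[phenotype] == "case").astype(int)
    keep["genotype_dom"] = np.nan

    g = genotypes.set_index("patient_id")["genotype"]
    dom = keep["patient_id"].map(g).map(lambda s: encode_dominant(s) if isinstance(s, str) else np.nan)
    keep["genotype_dom"] = dom
    n_nogeno = int(keep["genotype_dom"].isna().sum())
    if n_nogeno:
        logger.info("%d patient(s) dropped for missing genotype", n_nogeno)
    keep = keep.dropna(subset=["genotype_dom"])
    keep["genotype_dom"] = keep["genotype_dom"].astype(int)

    cov = covariates.drop_duplicates("patient_id").copy()
    if "sex" in cov.columns and cov["sex"].dtype == object:
        cov["female"] = (cov["sex"] == "F").astype(int)
    tbl = keep.merge(cov, on="patient_id", how="left", validate="1:1")
    tbl["first_statin_simva"] = (tbl["first_statin"] == "simvastatin").astype(int)
    tbl["last_statin_simva"] = (tbl["last_statin"] == "simvastatin").astype(int)
    with np.errstate(divide="ignore"):
        tbl["log10_ck"] = np.log10(tbl["max_on_statin_ck"].astype(float))
    cols = [
        "patient_id",
        "outcome",
        "genotype_dom",
        "age",
        "female",
        "t2d",
        "comedication",
        "first_statin_simva",
        "last_statin_simva",
        "mean_equiv_dose",
        "log10_ck",
    ]
    return tbl[[c for c in cols if c in tbl.columns]].reset_index(drop=True)
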