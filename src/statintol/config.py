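"""Configuration objects for the phenotyping rules and the cohort simulator.

Two frozen-ish dataclasses hold every tunable threshold:

* :class:`RulesConfig` — the EMR phenotyping rules (CK upper limits of
  normal, statin dose-equivalence ladder, lowest approved starting doses,
  coverage/duration/dose thresholds, switch and discontinuation conventions).
* :class:`SimulationConfig` — the synthetic-cohort generator (sample size,
  minor allele frequency, planted dominant odds ratios, trial hazard ratios,
  follow-up and event-rate calibration).

Both can be loaded from a YAML file with :func:`load_config`.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from datetime import date
from typing import Mapping

import yaml

#: Controlled vocabulary of statin drug names.
STATINS: tuple[str, ...] = (
    "simvastatin",
    "atorvastatin",
    "rosuvastatin",
    "pravastatin",
    "fluvastatin",
    "lovastatin",
    "pitavastatin",
)

#: mg of simvastatin with LDL-lowering potency comparable to 1 mg of drug.
#: Standard potency ladder: simvastatin 40 ≈ atorvastatin 20 ≈ rosuvastatin 10
#: ≈ pravastatin 80 ≈ fluvastatin 80 ≈ lovastatin 80 ≈ pitavastatin 4.
DEFAULT_DOSE_EQUIVALENCE: dict[str, float] = {
    "simvastatin": 1.0,
    "atorvastatin": 2.0,
    "rosuvastatin": 4.0,
    "pravastatin": 0.5,
    "fluvastatin": 0.5,
    "lovastatin": 0.5,
    "pitavastatin": 10.0,
}

#: Lowest approved daily starting dose (mg/day) per statin (NLA 2014 values).
DEFAULT_LOWEST_START_DOSE: dict[str, float] = {
    "simvastatin": 10.0,
    "atorvastatin": 10.0,
    "rosuvastatin": 5.0,
    "pravastatin": 40.0,
    "fluvastatin": 20.0,
    "lovastatin": 20.0,
    "pitavastatin": 2.0,
}


class ValidationError(ValueError):
    """Raised when an input value or configuration fails validation."""


@dataclass
class RulesConfig:
    """Thresholds and conventions of the statin-intolerance phenotyping rules.

    Parameters
    ----------
    ck_uln_male, ck_uln_female
        Sex-specific creatine-kinase upper limit of normal, IU/L. Laboratory
        reference ranges vary by assay; defaults are typical adult values.
    sim_fold_uln
        Fold-over-ULN threshold flagging candidate statin-induced myopathy
        (inclusive comparison, default 4x ULN).
    dose_equivalence
        Map drug -> mg simvastatin-equivalent per mg of drug.
    lowest_start_dose
        Map drug -> lowest approved daily starting dose, mg/day.
    coverage_threshold
        Minimum prescription coverage fraction for tolerant controls
        (strict ``>``, i.e. "over 90%").
    min_years
        Minimum years on statin therapy for tolerant controls (``>=``).
    min_equiv_dose
        Minimum mean simvastatin-equivalent daily dose, mg/day (``>=``).
    discontinuation_gap_days
        A course is discontinued when no further script of the same drug
        starts within this many days after coverage ends (strict ``>``).
    atorvastatin_patent_date
        Simvastatin->atorvastatin changes on or after this date are treated
        as systemic formulary shifts and do not count as switches.
    min_switches_gsi
        Switch-count threshold in the general-intolerance case rule.
    min_distinct_statins_ldi
        Distinct-statin threshold in the low-dose-intolerance case rule.
    gsi_switch_metric
        Whether the general-intolerance rule counts switch events
        (``"switches"``, default) or distinct statins used (``"distinct"``).
    dose_summary
        Whether the control dose criterion uses the time-weighted ``"mean"``
        (default) or the ``"min"`` maintained equivalent dose.
    """

    ck_uln_male: float = 320.0
    ck_uln_female: float = 200.0
    sim_fold_uln: float = 4.0
    dose_equivalence: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_DOSE_EQUIVALENCE)
    )
    lowest_start_dose: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_LOWEST_START_DOSE)
    )
    coverage_threshold: float = 0.90
    min_years: float = 5.0
    min_equiv_dose: float = 40.0
    discontinuation_gap_days: int = 90
    atorvastatin_patent_date: date = date(2012, 5, 1)
    min_switches_gsi: int = 2
    min_distinct_statins_ldi: int = 2
    gsi_switch_metric: str = "switches"
    dose_summary: str = "mean"

    def __post_init__(self) -> None:
        for name in (
            "ck_uln_male",
            "ck_uln_female",
            "sim_fold_uln",
            "coverage_threshold",
            "min_years",
            "min_equiv_dose",
            "discontinuation_gap_days",
        ):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be positive")
        missing = [d for d in STATINS if d not in self.dose_equivalence]
        if missing:
            raise ValidationError(f"dose_equivalence missing drugs: {missing}")
        missing = [d for d in STATINS if d not in self.lowest_start_dose]
        if missing:
            raise ValidationError(f"lowest_start_dose missing drugs: {missing}")
        if self.gsi_switch_metric not in ("switches", "distinct"):
            raise ValidationError("gsi_switch_metric must be 'switches' or 'distinct'")
        if self.dose_summary not in ("mean", "min"):
            raise ValidationError("dose_summary must be 'mean' or 'min'")
        if isinstance(self.atorvastatin_patent_date, str):
            self.atorvastatin_patent_date = date.fromisoformat(
                self.atorvastatin_patent_date
            )

    def ck_uln(self, sex: str) -> float:
        """Sex-specific CK upper limit of normal (``sex`` is ``"M"``/``"F"``)."""
        if sex not in ("M", "F"):
            raise ValidationError(f"sex must be 'M' or 'F', got {sex!r}")
        return self.ck_uln_male if sex == "M" else self.ck_uln_female


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic cohort and trial generators.

    Observational defaults emulate a Tayside-like EMR cohort of statin users:
    MAF 0.37 for the rs12975366 T>C variant, planted dominant odds ratios of
    1.96 (general statin intolerance) and 1.43 (low-dose intolerance), each
    case class at ~5% prevalence among users and tolerant controls at ~3.7%,
    of whom 20% carry an incidental on-statin CK elevation (so tolerant-2
    membership exceeds tolerant-1, as in the source cohorts).

    Trial defaults emulate a two-arm placebo-controlled rosuvastatin trial:
    genotype-stratified treatment hazard ratios 0.87 (T/T homozygotes) and
    1.23 (Gly carriers), administrative censoring around a 1.9-year median
    follow-up, and a baseline myalgia rate calibrated so the overall event
    fraction is ~837/8749 = 0.096 at n = 8749 with MAF 0.40.
    """

    n_patients: int = 5000
    maf: float = 0.37
    planted_or_gsi: float = 1.96
    planted_or_ldi: float = 1.43
    intolerance_prevalence: float = 0.05
    tolerant_fraction: float = 0.037
    st2_only_fraction: float = 0.20
    ck_uln_multiplier_cases: float = 2.0
    trial_hr_tt: float = 0.87
    trial_hr_carrier: float = 1.23
    baseline_myalgia_rate: float = 0.0505
    followup_years_median: float = 1.9
    comedication_prob: float = 0.47
    t2d_prob: float = 0.85
    seed: int = 0

    def __post_init__(self) -> None:
        fractions = (
            "maf",
            "intolerance_prevalence",
            "tolerant_fraction",
            "st2_only_fraction",
            "comedication_prob",
            "t2d_prob",
        )
        for name in fractions:
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValidationError(f"{name} must be in [0, 1], got {v}")
        positives = (
            "planted_or_gsi",
            "planted_or_ldi",
            "ck_uln_multiplier_cases",
            "trial_hr_tt",
            "trial_hr_carrier",
            "baseline_myalgia_rate",
            "followup_years_median",
        )
        for name in positives:
            v = getattr(self, name)
            if not v > 0:
                raise ValidationError(f"{name} must be strictly positive, got {v}")
        if self.n_patients < 1:
            raise ValidationError("n_patients must be >= 1")
        self.seed = int(self.seed)


def _from_mapping(cls, mapping: Mapping):
    known = {f.name for f in dataclasses.fields(cls)}
    unknown = set(mapping) - known
    if unknown:
        raise ValidationError(
            f"unknown {cls.__name__} keys: {sorted(unknown)}"
        )
    return cls(**mapping)


def load_config(path) -> tuple[SimulationConfig, RulesConfig]:
    """Load ``simulation:`` and ``rules:`` sections from a YAML file.

    Missing sections or keys fall back to the defaults above.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    sim = _from_mapping(SimulationConfig, raw.get("simulation", {}) or {})
    rules = _from_mapping(RulesConfig, raw.get("rules", {}) or {})
    return sim, rules


def dump_config(sim: SimulationConfig, rules: RulesConfig) -> str:
    """Serialize the two config sections to canonical YAML (for hashing)."""
    payload = {
        "simulation": dataclasses.asdict(sim),
        "rules": dataclasses.asdict(rules),
    }
    payload["rules"]["atorvastatin_patent_date"] = str(
        rules.atorvastatin_patent_date
    )
    return yaml.safe_dump(payload, sort_keys=True)
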