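"""Inverse-variance fixed-effects meta-analysis of per-study odds ratios.

Per-study log odds ratios beta_i = ln(OR_i) are pooled with weights
w_i = 1/SE_i^2, where each SE is reconstructed from the printed 95%
confidence interval as (ln U - ln L) / (2 * 1.959964). The pooled effect is

    beta = sum(w_i * beta_i) / sum(w_i),   SE = 1 / sqrt(sum(w_i)),

with a two-sided z-test and Cochran's Q heterogeneity statistic
Q = sum(w_i * (beta_i - beta)^2) reported descriptively (fixed effects
only; no random-effects model). A packaged four-study fixture carries the
adjusted per-study estimates of the Asp247Gly statin-intolerance
association, whose pooled value is OR 1.34 (95% CI 1.16-1.54).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from importlib import resources
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .association import Z95, EffectEstimate
from .config import ValidationError

logger = logging.getLogger(__name__)


def round_half_up(x: float, nd: int = 2) -> float:
    """Round half away from zero to ``nd`` decimals (display convention)."""
    q = Decimal(1).scaleb(-nd)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


@dataclass
class StudyEffect:
    """One study's odds ratio with its 95% confidence interval."""

    study: str
    or_point: float
    ci_lo: float
    ci_hi: float
    n: Optional[int] = None

    def __post_init__(self) -> None:
        if not (0 < self.ci_lo <= self.or_point <= self.ci_hi):
            raise ValidationError(
                f"{self.study}: require 0 < ci_lo <= OR <= ci_hi, got "
                f"{self.or_point} ({self.ci_lo}-{self.ci_hi})"
            )


@dataclass
class MetaResult:
    """Pooled effect with per-study weights and heterogeneity."""

    pooled: EffectEstimate
    studies: list[StudyEffect]
    betas: np.ndarray
    ses: np.ndarray
    weights: np.ndarray
    weight_fractions: np.ndarray
    q_stat: float
    q_df: int
    q_p: float
    i2: float
    z: float

    def to_dict(self) -> dict:
        return {
            "pooled": self.pooled.to_dict(),
            "studies": [s.study for s in self.studies],
            "betas": self.betas.tolist(),
            "ses": self.ses.tolist(),
            "weights": self.weights.tolist(),
            "weight_fractions": self.weight_fractions.tolist(),
            "q_stat": self.q_stat,
            "q_df": self.q_df,
            "q_p": self.q_p,
            "i2": self.i2,
            "z": self.z,
        }


def se_from_ci(or_point: float, ci_lo: float, ci_hi: float, level: float = 0.95) -> float:
    """Standard error of the log OR reconstructed from a confidence interval.

    Warns when the point estimate deviates from the geometric mean of the
    bounds by more than 2%, which indicates rounding or a non-Wald interval.
    """
    if ci_lo <= 0 or ci_hi <= 0 or ci_lo >= ci_hi:
        raise ValidationError("confidence bounds must satisfy 0 < lo < hi")
    if not 0 < level < 1:
        raise ValidationError("level must be in (0, 1)")
    z = stats.norm.ppf(0.5 + level / 2.0)
    se = (np.log(ci_hi) - np.log(ci_lo)) / (2.0 * z)
    centre = float(np.sqrt(ci_lo * ci_hi))
    if abs(or_point - centre) / or_point > 0.02:
        logger.warning(
            "CI asymmetric around OR %.3f (geometric centre %.3f); "
            "SE reconstruction may be approximate",
            or_point,
            centre,
        )
    return float(se)


def pool_fixed_effects(effects: Sequence[StudyEffect], level: float = 0.95) -> MetaResult:
    """Inverse-variance fixed-effects pooling of study odds ratios.

    Each study's beta is ln(or_point) (the CI supplies only the SE), pooled
    with weights 1/SE^2. Returns the pooled :class:`EffectEstimate` together
    with weights, Cochran's Q, I^2 and the pooled z statistic.
    """
    if len(effects) == 0:
        raise ValidationError("need at least one study to pool")
    betas = np.array([np.log(e.or_point) for e in effects])
    ses = np.array([se_from_ci(e.or_point, e.ci_lo, e.ci_hi, level) for e in effects])
    w = 1.0 / ses**2
    beta = float(np.sum(w * betas) / np.sum(w))
    se = float(1.0 / np.sqrt(np.sum(w)))
    n_total = sum(e.n for e in effects) if all(e.n is not None for e in effects) else len(effects)
    pooled = EffectEstimate(
        label="pooled (fixed effects)", scale="log-odds", beta=beta, se=se, n=int(n_total)
    )
    q = float(np.sum(w * (betas - beta) ** 2))
    q_df = len(effects) - 1
    q_p = float(stats.chi2.sf(q, q_df)) if q_df > 0 else 1.0
    i2 = float(max(0.0, (q - q_df) / q)) if q > 0 else 0.0
    return MetaResult(
        pooled=pooled,
        studies=list(effects),
        betas=betas,
        ses=ses,
        weights=w,
        weight_fractions=w / w.sum(),
        q_stat=q,
        q_df=q_df,
        q_p=q_p,
        i2=i2,
        z=beta / se,
    )


def make_forest_table(effects: Sequence[StudyEffect], pooled: MetaResult) -> pd.DataFrame:
    """Forest-plot table: one row per study (input order) plus the pooled row."""
    rows = []
    for e, wf in zip(effects, pooled.weight_fractions):
        rows.append(
            {
                "study": e.study,
                "n": e.n,
                "or": e.or_point,
                "ci_lo": e.ci_lo,
                "ci_hi": e.ci_hi,
                "weight_pct": 100.0 * wf,
            }
        )
    p = pooled.pooled
    rows.append(
        {
            "study": "Pooled (fixed effects)",
            "n": p.n,
            "or": p.point,
            "ci_lo": p.ci_lo,
            "ci_hi": p.ci_hi,
            "weight_pct": 100.0,
        }
    )
    return pd.DataFrame(rows)


def load_studies(path=None) -> list[StudyEffect]:
    """Read a studies CSV (study, or, ci_lo, ci_hi, n).

    With no path, loads the packaged four-study fixture of adjusted
    per-study estimates for the Asp247Gly / statin-intolerance association.
    """
    if path is None:
        ref = resources.files("statintol.data") / "forest_studies.csv"
        with resources.as_file(ref) as p:
            df = pd.read_csv(p)
    else:
        df = pd.read_csv(path)
    required = {"study", "or", "ci_lo", "ci_hi"}
    missing = required - set(df.columns)
    if missing:
        raise ValidationError(f"studies file missing columns: {sorted(missing)}")
    return [
        StudyEffect(
            study=row["study"],
            or_point=float(row["or"]),
            ci_lo=float(row["ci_lo"]),
            ci_hi=float(row["ci_hi"]),
            n=int(row["n"]) if "n" in df.columns and pd.notna(row.get("n")) else None,
        )
        for _, row in df.iterrows()
    ]
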