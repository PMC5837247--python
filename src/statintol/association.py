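"""Dominant-model genetic association for the rs12975366 T>C (Asp247Gly) variant.

The exposure contrast throughout is Asp247 homozygotes (T/T, coded 1)
versus Gly247 carriers (T/C or C/C, coded 0). Provides:

* crude 2x2 odds ratios with Woolf confidence intervals (Haldane-Anscombe
  0.5 correction for a single zero cell),
* allele-frequency and exact Hardy-Weinberg equilibrium tests,
* covariate-adjusted maximum-likelihood logistic regression with Wald
  inference and backwards stepwise elimination (genotype always forced),
* the genotype x treatment interaction model for two-arm trial data, and
* genotype-stratified Cox proportional-hazards fits of the treatment effect.

Model fitting is delegated to statsmodels (logistic) and lifelines (Cox);
this module owns the study-specific coding, rules and reporting.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from scipy.special import gammaln

from .config import ValidationError

logger = logging.getLogger(__name__)

#: Normal quantile for two-sided 95% intervals.
Z95 = 1.959964

VARIANT_RSID = "rs12975366"
GENOTYPES = ("T/T", "T/C", "C/C")


@dataclass
class GenotypeCall:
    """Biallelic genotype for one patient at one variant."""

    patient_id: str
    rsid: str
    genotype: str


@dataclass
class EffectEstimate:
    """A labelled effect on the log-odds or log-hazard scale.

    ``point`` is exp(beta) (an OR or HR) and the 95% CI is
    exp(beta -/+ 1.959964 * se); ``p`` is the two-sided Wald p-value.
    """

    label: str
    scale: str
    beta: float
    se: float
    n: int
    point: float = field(init=False)
    ci_lo: float = field(init=False)
    ci_hi: float = field(init=False)
    p: float = field(init=False)

    def __post_init__(self) -> None:
        if self.se <= 0:
            raise ValidationError(f"{self.label}: standard error must be positive")
        self.point = float(np.exp(self.beta))
        self.ci_lo = float(np.exp(self.beta - Z95 * self.se))
        self.ci_hi = float(np.exp(self.beta + Z95 * self.se))
        z = self.beta / self.se
        self.p = float(2.0 * stats.norm.sf(abs(z)))

    def rounded(self, nd: int = 2) -> tuple[float, float, float]:
        """(point, ci_lo, ci_hi) rounded half-up to ``nd`` decimals for display."""
        from .meta_analysis import round_half_up

        return tuple(round_half_up(v, nd) for v in (self.point, self.ci_lo, self.ci_hi))

    def to_dict(self) -> dict:
        return {
            "label": self.label,
            "scale": self.scale,
            "beta": self.beta,
            "se": self.se,
            "point": self.point,
            "ci_lo": self.ci_lo,
            "ci_hi": self.ci_hi,
            "p": self.p,
            "n": self.n,
        }


def encode_dominant(genotype: str) -> Optional[int]:
    """Dominant coding: T/T (Asp247 homozygote) -> 1; T/C or C/C carrier -> 0.

    Unknown or missing codes return ``None`` and are excluded downstream.
    """
    if genotype in ("T/T",):
        return 1
    if genotype in ("T/C", "C/T", "C/C"):
        return 0
    return None


def _genotype_counts(calls) -> tuple[int, int, int]:
    if isinstance(calls, pd.DataFrame):
        geno = calls["genotype"]
    elif isinstance(calls, pd.Series):
        geno = calls
    else:
        geno = pd.Series([c.genotype if hasattr(c, "genotype") else c for c in calls])
    geno = geno.replace({"C/T": "T/C"})
    bad = sorted(set(geno) - set(GENOTYPES))
    if bad:
        raise ValidationError(f"unknown genotype codes: {bad}")
    vc = geno.value_counts()
    return int(vc.get("T/T", 0)), int(vc.get("T/C", 0)), int(vc.get("C/C", 0))


def hwe_exact_p(n_hom_ref: int, n_het: int, n_hom_alt: int) -> float:
    """Exact Hardy-Weinberg test conditional on the observed allele counts.

    Sums the conditional probability of every heterozygote count at least as
    improbable as the observed one (the standard two-sided exact test).
    """
    n = n_hom_ref + n_het + n_hom_alt
    if n == 0:
        raise ValidationError("no genotype calls")
    n_minor = min(2 * n_hom_ref + n_het, 2 * n_hom_alt + n_het)
    if n_minor == 0:
        return 1.0

    def log_prob(h: int) -> float:
        a = (n_minor - h) // 2  # minor-allele homozygotes
        b = n - a - h
        return (
            gammaln(n + 1)
            - gammaln(a + 1)
            - gammaln(h + 1)
            - gammaln(b + 1)
            + h * np.log(2.0)
            + gammaln(n_minor + 1)
            + gammaln(2 * n - n_minor + 1)
            - gammaln(2 * n + 1)
        )

    hets = np.arange(n_minor % 2, min(n_minor, 2 * n - n_minor) + 1, 2)
    logp = np.array([log_prob(int(h)) for h in hets])
    probs = np.exp(logp - logp.max())
    probs /= probs.sum()
    p_obs = probs[np.searchsorted(hets, n_het)]
    return float(min(1.0, probs[probs <= p_obs * (1 + 1e-12)].sum()))


def estimate_maf_and_hwe(calls) -> tuple[float, float]:
    """Alternate (C) allele frequency and exact HWE p-value for a call set."""
    hom_ref, het, hom_alt = _genotype_counts(calls)
    n = hom_ref + het + hom_alt
    if n == 0:
        raise ValidationError("no genotype calls")
    maf = (het + 2 * hom_alt) / (2 * n)
    return maf, hwe_exact_p(hom_ref, het, hom_alt)


def contingency_or(a: int, b: int, c: int, d: int, label: str = "exposure") -> EffectEstimate:
    """Crude odds ratio from a 2x2 table with a Woolf confidence interval.

    Cell layout: ``a`` case-exposed, ``b`` case-unexposed, ``c``
    control-exposed, ``d`` control-unexposed. If exactly one cell is zero the
    Haldane-Anscombe 0.5 correction is added to all four cells (logged).
    """
    cells = np.array([a, b, c, d], dtype=float)
    if (cells < 0).any():
        raise ValidationError("cell counts must be non-negative")
    if a + b == 0 or c + d == 0 or a + c == 0 or b + d == 0:
        raise ValidationError("a row or column total of the 2x2 table is zero")
    if (cells == 0).sum() == 1:
        logger.warning("single zero cell: applying Haldane-Anscombe 0.5 correction")
        cells = cells + 0.5
    aa, bb, cc, dd = cells
    beta = float(np.log(aa * dd / (bb * cc)))
    se = float(np.sqrt(1 / aa + 1 / bb + 1 / cc + 1 / dd))
    return EffectEstimate(label=label, scale="log-odds", beta=beta, se=se, n=int(a + b + c + d))


@dataclass
class LogisticFit:
    """A fitted logistic model: per-term estimates plus the raw result."""

    estimates: dict[str, EffectEstimate]
    terms: list[str]
    n: int
    llf: float
    result: object

    def to_dict(self) -> dict:
        return {
            "terms": self.terms,
            "n": self.n,
            "llf": self.llf,
            "estimates": {k: v.to_dict() for k, v in self.estimates.items()},
        }


def _check_design(X: pd.DataFrame) -> None:
    rank = np.linalg.matrix_rank(X.to_numpy(dtype=float))
    if rank < X.shape[1]:
        # identify columns whose removal restores full rank
        collinear = [
            c
            for c in X.columns
            if np.linalg.matrix_rank(X.drop(columns=c).to_numpy(dtype=float)) == rank
        ]
        raise ValidationError(f"design matrix is rank deficient; collinear terms: {collinear}")


def _check_separation(y: np.ndarray, X: pd.DataFrame) -> None:
    # complete separation on a single term: predictor ranges of the two
    # outcome classes do not overlap
    for col in X.columns:
        if col == "const":
            continue
        v = X[col].to_numpy(dtype=float)
        lo = v[y == 1]
        hi = v[y == 0]
        if len(lo) and len(hi) and (lo.min() > hi.max() or hi.min() > lo.max()):
            raise ValidationError(f"perfect separation on term {col!r}")


def fit_logistic(
    table: pd.DataFrame,
    terms: Sequence[str] = (),
    outcome: str = "outcome",
    genotype_term: str = "genotype_dom",
    include_genotype: bool = True,
) -> LogisticFit:
    """Maximum-likelihood logistic regression with Wald inference.

    Fits ``outcome ~ genotype + terms`` (intercept always included; the
    genotype term can be disabled for pure covariate models). Rows with any
    missing value among the used columns are dropped. Raises on a
    single-class outcome, rank-deficient design, or perfect separation.
    """
    cols = ([genotype_term] if include_genotype else []) + [t for t in terms if t != genotype_term]
    data = table[[outcome] + cols].dropna()
    y = data[outcome].to_numpy(dtype=float)
    if len(np.unique(y)) < 2:
        raise ValidationError("outcome has a single class")
    X = sm.add_constant(data[cols].astype(float), has_constant="add")
    _check_design(X)
    _check_separation(y, X)
    try:
        res = sm.Logit(y, X).fit(disp=0, maxiter=200)
    except Exception as exc:  # pragma: no cover - statsmodels-internal failures
        raise ValidationError(f"logistic fit failed: {exc}") from exc
    if not res.mle_retvals.get("converged", True):
        raise ValidationError("logistic fit did not converge")
    estimates = {}
    for name in X.columns:
        if name == "const":
            continue
        estimates[name] = EffectEstimate(
            label=name,
            scale="log-odds",
            beta=float(res.params[name]),
            se=float(res.bse[name]),
            n=len(data),
        )
    return LogisticFit(
        estimates=estimates, terms=list(X.columns[1:]), n=len(data), llf=float(res.llf), result=res
    )


def lr_test(full: LogisticFit, reduced: LogisticFit) -> tuple[float, float]:
    """Likelihood-ratio test of nested logistic fits -> (statistic, p)."""
    df = len(full.terms) - len(reduced.terms)
    if df <= 0:
        raise ValidationError("models are not nested (full must have more terms)")
    lr = 2.0 * (full.llf - reduced.llf)
    return lr, float(stats.chi2.sf(lr, df))


def _block_wald_p(fit: LogisticFit, cols: Sequence[str]) -> float:
    """Joint Wald chi-square p-value for a block of coefficients."""
    res = fit.result
    params = np.array([res.params[c] for c in cols])
    V = pd.DataFrame(res.cov_params(), index=res.params.index, columns=res.params.index)
    Vb = V.loc[list(cols), list(cols)].to_numpy()
    w = float(params @ np.linalg.solve(Vb, params))
    return float(stats.chi2.sf(w, len(cols)))


def backward_eliminate(
    table: pd.DataFrame,
    full_terms: Sequence,
    forced_terms: Sequence[str] = ("genotype_dom",),
    alpha: float = 0.05,
    outcome: str = "outcome",
) -> tuple[list, LogisticFit, list[tuple[str, float]]]:
    """Backwards stepwise elimination of non-significant covariates.

    Starting from the full model, repeatedly drop the non-forced term with
    the largest Wald p-value above ``alpha`` (one term per iteration,
    largest-p first; deterministic) and refit, until every removable term is
    significant. The genotype term is always forced. A term may be a column
    name or a ``(name, [columns])`` block, removed on its joint Wald p-value.

    Returns ``(retained_terms, final_fit, trace)`` where ``trace`` lists the
    removed terms and their p-values at removal.
    """
    forced = list(forced_terms)

    def term_cols(t):
        return list(t[1]) if isinstance(t, tuple) else [t]

    def term_name(t):
        return t[0] if isinstance(t, tuple) else t

    terms = [t for t in full_terms if term_name(t) not in forced]
    trace: list[tuple[str, float]] = []
    while True:
        flat = [c for t in terms for c in term_cols(t)]
        fit = fit_logistic(
            table,
            terms=[c for c in forced if c != "genotype_dom"] + flat,
            outcome=outcome,
            genotype_term="genotype_dom",
            include_genotype="genotype_dom" in forced,
        )
        if not terms:
            break
        pvals = [(t, _block_wald_p(fit, term_cols(t))) for t in terms]
        worst, worst_p = max(pvals, key=lambda tp: tp[1])
        if worst_p <= alpha:
            break
        logger.info("stepwise: removing %s (p=%.4g)", term_name(worst), worst_p)
        trace.append((term_name(worst), worst_p))
        terms = [t for t in terms if term_name(t) != term_name(worst)]
    return forced + terms, fit, trace


def fit_interaction_model(trial: pd.DataFrame) -> dict[str, EffectEstimate]:
    """Genotype x treatment logistic model for a two-arm trial.

    ``trial`` needs columns ``event`` (0/1 myalgia), ``arm`` (1 statin /
    0 placebo), ``genotype_dom`` and ``final_ck``. Fits
    ``event ~ genotype_dom + arm + log10(final_ck) + genotype_dom:arm``.
    """
    if trial["arm"].nunique() < 2:
        raise ValidationError("interaction model requires both trial arms")
    df = trial.copy()
    df["log10_ck"] = np.log10(df["final_ck"].astype(float))
    df["geno_x_arm"] = df["genotype_dom"] * df["arm"]
    fit = fit_logistic(
        df,
        terms=["arm", "log10_ck", "geno_x_arm"],
        outcome="event",
        genotype_term="genotype_dom",
    )
    return fit.estimates


def fit_stratified_hazard(trial: pd.DataFrame, stratum: int) -> EffectEstimate:
    """Treatment hazard ratio within one genotype stratum (Cox PH).

    ``stratum`` is the dominant genotype code (1 = T/T homozygotes,
    0 = Gly carriers). The fit is adjusted for log10 final CK; returns the
    treatment-arm effect as a log-hazard :class:`EffectEstimate`.
    """
    from lifelines import CoxPHFitter

    sub = trial[trial["genotype_dom"] == stratum].copy()
    if sub.empty:
        raise ValidationError(f"empty genotype stratum {stratum}")
    events_by_arm = sub.groupby("arm")["event"].sum()
    if len(events_by_arm) < 2 or (events_by_arm == 0).any():
        raise ValidationError("stratum must have events in both arms")
    sub["log10_ck"] = np.log10(sub["final_ck"].astype(float))
    cph = CoxPHFitter()
    cph.fit(
        sub[["time", "event", "arm", "log10_ck"]],
        duration_col="time",
        event_col="event",
    )
    return EffectEstimate(
        label=f"treatment|genotype_dom={stratum}",
        scale="log-hazard",
        beta=float(cph.params_["arm"]),
        se=float(cph.standard_errors_["arm"]),
        n=len(sub),
    )
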