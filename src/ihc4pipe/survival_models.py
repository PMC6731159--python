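"""Cox model fitting and comparison for 10-year cancer-specific survival.

Thin, contract-enforcing layer over lifelines: Cox proportional-hazards
fits with Efron (default) or Breslow tie handling, per-SD hazard ratios
for continuous scores, likelihood-ratio chi-square against the null,
nested-model ΔLRχ² comparisons, Kaplan–Meier / logrank suites,
proportional-hazards diagnostics, and a subtype-heterogeneity
interaction test.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test, proportional_hazard_test
from scipy import stats

from .scores import standardize_per_sd

__all__ = [
    "CoxFitResult",
    "ModelComparison",
    "KMResult",
    "apply_exclusions",
    "truncate_at_10y",
    "fit_cox",
    "compare_nested",
    "km_logrank",
    "ph_check",
    "heterogeneity_test",
]

HORIZON_YEARS = 10.0


@dataclass
class CoxFitResult:
    """One fitted Cox model plus the pieces needed for model comparison."""

    terms: list[str]
    coefficients: dict[str, float]
    hazard_ratios: dict[str, float]
    ci_lower: dict[str, float]
    ci_upper: dict[str, float]
    p_values: dict[str, float]
    loglik: float
    loglik_null: float
    lr_chisq: float
    n: int
    n_events: int
    sample_signature: str
    _fitter: CoxPHFitter | None = field(default=None, repr=False, compare=False)
    _data: pd.DataFrame | None = field(default=None, repr=False, compare=False)

    def summary_frame(self) -> pd.DataFrame:
        """Tidy per-term table (term, coef, HR, CI, p)."""
        return pd.DataFrame(
            {
                "term": self.terms,
                "coef": [self.coefficients[t] for t in self.terms],
                "hr": [self.hazard_ratios[t] for t in self.terms],
                "ci_lower": [self.ci_lower[t] for t in self.terms],
                "ci_upper": [self.ci_upper[t] for t in self.terms],
                "p": [self.p_values[t] for t in self.terms],
            }
        )


@dataclass(frozen=True)
class ModelComparison:
    """ΔLRχ² between nested Cox models."""

    delta_lr_chisq: float
    df: int
    p_value: float


@dataclass
class KMResult:
    """Kaplan–Meier curves per group plus the logrank test across groups."""

    curves: dict[str, pd.DataFrame]
    logrank_stat: float
    logrank_p: float
    group_sizes: dict[str, int]
    group_events: dict[str, int]


# ---------------------------------------------------------------------------
# cohort preparation
# ---------------------------------------------------------------------------


def apply_exclusions(
    df: pd.DataFrame, covariates: list[str] | None = None
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Drop chemotherapy recipients, then incomplete rows (complete case).

    Returns the analysis cohort and a per-stage exclusion log.
    """
    if "chemotherapy" not in df.columns:
        raise ValueError("cohort lacks a chemotherapy column")
    log = {"input": len(df)}
    out = df.loc[df["chemotherapy"].astype(float) != 1.0]
    log["excluded_chemotherapy"] = log["input"] - len(out)
    if covariates:
        missing = [c for c in covariates if c not in out.columns]
        if missing:
            raise ValueError(f"missing covariate columns: {missing}")
        before = len(out)
        out = out.dropna(subset=covariates)
        log["excluded_incomplete"] = before - len(out)
    else:
        log["excluded_incomplete"] = 0
    log["analyzed"] = len(out)
    if len(out) == 0:
        raise ValueError("all rows excluded: empty analysis cohort")
    return out, log


def truncate_at_10y(
    df: pd.DataFrame,
    time_col: str = "time_years",
    event_col: str = "event",
    horizon: float = HORIZON_YEARS,
) -> pd.DataFrame:
    """Administratively censor at the horizon: time := min(time, horizon),
    events after the horizon recoded as censored."""
    t = df[time_col].to_numpy(dtype=float)
    if np.any(t <= 0):
        raise ValueError("non-positive follow-up time")
    out = df.copy()
    late = t > horizon
    out[time_col] = np.minimum(t, horizon)
    out[event_col] = np.where(late, 0, df[event_col].to_numpy(dtype=int))
    return out


# ---------------------------------------------------------------------------
# Cox fitting
# ---------------------------------------------------------------------------


def _sample_signature(df: pd.DataFrame, time_col: str, event_col: str) -> str:
    h = hashlib.sha1()
    h.update(np.ascontiguousarray(df[time_col].to_numpy(dtype=float)).tobytes())
    h.update(np.ascontiguousarray(df[event_col].to_numpy(dtype=float)).tobytes())
    return h.hexdigest()


def fit_cox(
    df: pd.DataFrame,
    terms: list[str],
    per_sd: list[str] | None = None,
    time_col: str = "time_years",
    event_col: str = "event",
    ties: str = "efron",
) -> CoxFitResult:
    """Fit a Cox PH model; per-SD terms are standardized before fitting.

    ``per_sd`` names continuous columns to scale by the analysis-cohort
    sample SD, so their hazard ratios are per 1 SD.  Ties are handled by
    the Efron correction of the partial likelihood (the only method the
    lifelines backend implements; other ``ties`` values raise).
    """
    if not terms:
        raise ValueError("need at least one model term")
    missing = [c for c in terms if c not in df.columns]
    if missing:
        raise ValueError(f"missing model columns: {missing}")
    sub = df[terms + [time_col, event_col]].copy()
    if sub.isna().any().any():
        raise ValueError("NaN in model frame: apply exclusions first")
    n_events = int(sub[event_col].sum())
    if n_events == 0:
        raise ValueError("no events: Cox model is not identified")
    for c in terms:
        col = sub[c].to_numpy(dtype=float)
        if np.std(col, ddof=1) == 0.0:
            raise ValueError(f"covariate {c!r} is constant: no information")
    for c in per_sd or []:
        if c not in terms:
            raise ValueError(f"per_sd column {c!r} is not a model term")
        sub[c] = standardize_per_sd(sub[c].to_numpy(dtype=float))

    if ties != "efron":
        # lifelines' CoxPHFitter implements Efron tie handling only
        raise NotImplementedError(f"unsupported ties method {ties!r}; use 'efron'")
    cph = CoxPHFitter(baseline_estimation_method="breslow")
    try:
        cph.fit(sub, duration_col=time_col, event_col=event_col,
                fit_options={"step_size": 0.95, "precision": 1e-14})
    except Exception as exc:  # convergence / separation
        raise ValueError(f"Cox fit failed (separation or non-convergence): {exc}") from exc

    llr = cph.log_likelihood_ratio_test()
    loglik = float(cph.log_likelihood_)
    lr_chisq = float(llr.test_statistic)
    summ = cph.summary
    return CoxFitResult(
        terms=list(terms),
        coefficients={t: float(summ.loc[t, "coef"]) for t in terms},
        hazard_ratios={t: float(summ.loc[t, "exp(coef)"]) for t in terms},
        ci_lower={t: float(summ.loc[t, "exp(coef) lower 95%"]) for t in terms},
        ci_upper={t: float(summ.loc[t, "exp(coef) upper 95%"]) for t in terms},
        p_values={t: float(summ.loc[t, "p"]) for t in terms},
        loglik=loglik,
        loglik_null=loglik - lr_chisq / 2.0,
        lr_chisq=lr_chisq,
        n=len(sub),
        n_events=n_events,
        sample_signature=_sample_signature(sub, time_col, event_col),
        _fitter=cph,
        _data=sub,
    )


def compare_nested(full: CoxFitResult, reduced: CoxFitResult) -> ModelComparison:
    """Likelihood-ratio comparison of nested Cox models on the same rows.

    delta = 2*(loglik_full - loglik_reduced), df = difference in number
    of terms, p from the chi-square upper tail.
    """
    if not set(reduced.terms) <= set(full.terms):
        raise ValueError("models are not nested (reduced terms not a subset)")
    if full.sample_signature != reduced.sample_signature or full.n != reduced.n:
        raise ValueError("models were fitted on different samples")
    delta = 2.0 * (full.loglik - reduced.loglik)
    if delta < -1e-6:
        raise ValueError(f"nested comparison produced negative delta {delta}")
    delta = max(delta, 0.0)
    df = len(full.terms) - len(reduced.terms)
    if df == 0:
        p = 1.0 if delta < 1e-9 else 0.0
    else:
        p = float(stats.chi2.sf(delta, df))
    return ModelComparison(delta_lr_chisq=delta, df=df, p_value=p)


# ---------------------------------------------------------------------------
# Kaplan-Meier / logrank
# ---------------------------------------------------------------------------


def km_logrank(
    df: pd.DataFrame,
    group_col: str,
    strata_col: str | None = None,
    time_col: str = "time_years",
    event_col: str = "event",
) -> KMResult | dict[str, KMResult]:
    """KM curves and a logrank test across the levels of ``group_col``.

    With ``strata_col`` the analysis is repeated within each stratum and
    a dict keyed by stratum is returned.
    """
    if strata_col is not None:
        out: dict[str, KMResult] = {}
        for level, part in df.groupby(strata_col, sort=True):
            out[str(level)] = km_logrank(part, group_col, None, time_col, event_col)
        return out

    groups = df.groupby(group_col, sort=True, observed=True)
    if groups.ngroups < 2:
        raise ValueError(f"need >= 2 nonempty groups in {group_col!r}")
    curves: dict[str, pd.DataFrame] = {}
    sizes: dict[str, int] = {}
    events: dict[str, int] = {}
    for level, part in groups:
        if len(part) == 0:  # pragma: no cover - groupby never yields empty
            raise ValueError(f"group {level!r} is empty")
        kmf = KaplanMeierFitter()
        kmf.fit(part[time_col], part[event_col], label=str(level))
        tbl = kmf.survival_function_.join(kmf.confidence_interval_)
        tbl.columns = ["survival", "ci_lower", "ci_upper"]
        curves[str(level)] = tbl.reset_index().rename(columns={"timeline": "time"})
        sizes[str(level)] = len(part)
        events[str(level)] = int(part[event_col].sum())
    lr = multivariate_logrank_test(df[time_col], df[group_col], df[event_col])
    return KMResult(
        curves=curves,
        logrank_stat=float(lr.test_statistic),
        logrank_p=float(lr.p_value),
        group_sizes=sizes,
        group_events=events,
    )


# ---------------------------------------------------------------------------
# diagnostics
# ---------------------------------------------------------------------------


def ph_check(fit: CoxFitResult) -> dict[str, float]:
    """Proportional-hazards check via term x ln(time) interactions.

    Implemented as the score test for adding a ``term * log(t)``
    time-varying interaction to the fitted model (scaled Schoenfeld
    residual test with the log time transform); small p flags a
    violation.
    """
    if fit._fitter is None or fit._data is None:
        raise ValueError("fit does not carry its fitter/data (deserialized?)")
    res = proportional_hazard_test(fit._fitter, fit._data, time_transform="log")
    summ = res.summary  # indexed by (term, transform) or term
    pvals: dict[str, float] = {}
    for t in fit.terms:
        row = summ.loc[t]
        if isinstance(row, pd.DataFrame):
            row = row.iloc[0]
        pvals[t] = float(row["p"])
    return pvals


def heterogeneity_test(
    df: pd.DataFrame,
    score_col: str,
    subtype_col: str = "subtype",
    adjust: list[str] | None = None,
    per_sd: bool = True,
    time_col: str = "time_years",
    event_col: str = "event",
) -> ModelComparison:
    """1-df LR test of a score x subtype interaction.

    Fits score + subtype(+adjustments) with and without the interaction
    on the two-subtype cohort; both subtypes must contribute events.
    """
    sub = df[df[subtype_col].isin(["A_LIKE", "B_LIKE"])].copy()
    counts = sub.groupby(subtype_col)[event_col].agg(["size", "sum"])
    if len(counts) < 2 or (counts["sum"] == 0).any():
        raise ValueError("both subtypes must be present with events")
    sub["_subtype_b"] = (sub[subtype_col] == "B_LIKE").astype(float)
    score = sub[score_col].to_numpy(dtype=float)
    sub["_score"] = standardize_per_sd(score) if per_sd else score
    sub["_interaction"] = sub["_score"] * sub["_subtype_b"]
    adjust = [a for a in (adjust or []) if a in sub.columns]
    base_terms = ["_score", "_subtype_b"] + adjust
    reduced = fit_cox(sub, base_terms, time_col=time_col, event_col=event_col)
    full = fit_cox(sub, base_terms + ["_interaction"], time_col=time_col,
                   event_col=event_col)
    return compare_nested(full, reduced)
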