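"""Reproducible synthetic luminal breast-cancer cohorts.

No patient-level data from the motivating studies are public, so this
module generates cohorts whose marker, clinical, and survival structure
matches the published summary statistics: scaled-beta marker
distributions hitting the reported medians/SDs, categorical clinical
margins, and a Weibull proportional-hazards survival generator whose
baseline is calibrated to the reported 10-year event fraction.

Presets ``overall``, ``pbcs`` and ``search`` encode the published
per-study margins.
"""

from __future__ import annotations

import functools
import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import optimize, stats

from . import scores
from .scores import ScoreOptions, standardize_per_sd

__all__ = [
    "MarkerTarget",
    "CohortConfig",
    "HazardConfig",
    "generate_markers",
    "generate_clinical",
    "simulate_survival",
    "generate_cohort",
    "get_preset",
    "PRESETS",
]


@dataclass(frozen=True)
class MarkerTarget:
    """Median / SD target for a bounded marker distribution, percent scale."""

    median: float
    sd: float

    def __post_init__(self) -> None:
        if not (0.0 < self.median < 100.0) or self.sd <= 0:
            raise ValueError(f"infeasible marker target {self}")


@dataclass(frozen=True)
class CohortConfig:
    """Targets for marker and clinical margins of a generated cohort."""

    n_patients: int = 2498
    study_mix: float = 558.0 / 2498.0  # proportion PBCS (remainder SEARCH)
    er: MarkerTarget = MarkerTarget(62.0, 34.0)
    pr: MarkerTarget = MarkerTarget(57.0, 38.0)
    ki67: MarkerTarget = MarkerTarget(9.0, 11.0)
    her2_pos_prevalence: float = 0.09
    # 0 / 1+ / 2+ split among HER2-negative patients (unreported; fixed)
    her2_negative_split: tuple[float, float, float] = (0.5, 0.3, 0.2)
    # age brackets <35 / 35-50 / 50-65 / >65
    age_cat_probs: tuple[float, ...] = (0.016, 0.322, 0.537, 0.124)
    age_cat_bounds: tuple[tuple[float, float], ...] = (
        (25.0, 35.0), (35.0, 50.0), (50.0, 65.0), (65.0, 75.0),
    )
    grade_probs: tuple[float, float, float] = (0.261, 0.557, 0.182)
    # size brackets <2 cm / 2-5 cm / >5 cm, with uniform mm draws inside
    size_cat_probs: tuple[float, float, float] = (0.655, 0.321, 0.024)
    size_cat_bounds: tuple[tuple[float, float], ...] = (
        (3.0, 20.0), (20.0, 50.0), (50.0, 80.0),
    )
    node_negative_prob: float = 0.609
    nodes_1_3_given_positive: float = 0.75  # unreported split; fixed
    endocrine_prob: float = 0.804
    chemo_prob: float = 0.07
    er_pr_positivity_threshold: float = 10.0
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_patients < 1:
            raise ValueError("n_patients must be >= 1")
        for name in ("study_mix", "her2_pos_prevalence", "node_negative_prob",
                     "nodes_1_3_given_positive", "endocrine_prob", "chemo_prob"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name}={v!r} outside [0, 1]")
        for name in ("her2_negative_split", "age_cat_probs", "grade_probs",
                     "size_cat_probs"):
            p = np.asarray(getattr(self, name))
            # small slack: published margins are rounded percentages
            if np.any(p < 0) or abs(p.sum() - 1.0) > 5e-3:
                raise ValueError(f"{name} must be non-negative and sum to 1, got {p}")


@dataclass(frozen=True)
class HazardConfig:
    """Weibull proportional-hazards survival generator settings.

    The scale is calibrated at simulation time so the realized event
    fraction (given the drawn linear predictor and censoring times)
    matches ``target_event_fraction``.
    """

    shape: float = 1.2
    log_hr_per_sd: float = math.log(1.32)
    admin_censor_years: float = 10.0
    followup_entry_window_years: float = 6.0
    target_event_fraction: float = 316.0 / 2498.0

    def __post_init__(self) -> None:
        if self.shape <= 0:
            raise ValueError("shape must be > 0")
        if self.admin_censor_years <= 0:
            raise ValueError("admin_censor_years must be > 0")
        if not (0.0 < self.target_event_fraction < 1.0):
            raise ValueError("target_event_fraction must be in (0, 1)")
        if not (0.0 <= self.followup_entry_window_years < self.admin_censor_years):
            raise ValueError("followup_entry_window_years must be in [0, admin)")


# ---------------------------------------------------------------------------
# marker generation
# ---------------------------------------------------------------------------


@functools.lru_cache(maxsize=64)
def _beta_params(median: float, sd: float) -> tuple[float, float]:
    """Beta(a, b) on [0, 1] matching a target median and SD.

    Method-of-moments start (treating the median as the mean), then exact
    root-finding on (log a, log b).
    """
    m, s = median, sd
    var = s * s
    if var >= m * (1.0 - m):
        raise ValueError(f"infeasible beta target: median={m}, sd={s}")
    k = max(m * (1.0 - m) / var - 1.0, 1e-3)
    x0 = np.log([max(m * k, 1e-3), max((1.0 - m) * k, 1e-3)])

    def _residual(log_ab: np.ndarray) -> list[float]:
        a, b = np.exp(log_ab)
        dist = stats.beta(a, b)
        return [dist.median() - m, dist.std() - s]

    sol = optimize.root(_residual, x0, method="hybr")
    if not sol.success:
        raise ValueError(f"beta calibration failed for median={m}, sd={s}: {sol.message}")
    a, b = np.exp(sol.x)
    return float(a), float(b)


def generate_markers(cfg: CohortConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Draw ER/PR/KI67 percentages and HER2 Herceptest categories.

    ER/PR/KI67 come from scaled-beta distributions calibrated to the
    configured median/SD targets.  Rows where both receptors are negative
    at the configured threshold are redrawn (the cohort is luminal by
    construction).  Clinical binary statuses are derived from the
    quantitative scores.
    """
    n = cfg.n_patients
    er_a, er_b = _beta_params(cfg.er.median / 100.0, cfg.er.sd / 100.0)
    pr_a, pr_b = _beta_params(cfg.pr.median / 100.0, cfg.pr.sd / 100.0)
    ki_a, ki_b = _beta_params(cfg.ki67.median / 100.0, cfg.ki67.sd / 100.0)

    er = 100.0 * rng.beta(er_a, er_b, size=n)
    pr = 100.0 * rng.beta(pr_a, pr_b, size=n)
    thr = cfg.er_pr_positivity_threshold
    # rejection step: keep ER+ and/or PR+ only
    for _ in range(1000):
        bad = ~(scores._receptor_positive(er, thr) | scores._receptor_positive(pr, thr))
        if not bad.any():
            break
        k = int(bad.sum())
        er[bad] = 100.0 * rng.beta(er_a, er_b, size=k)
        pr[bad] = 100.0 * rng.beta(pr_a, pr_b, size=k)
    else:  # pragma: no cover
        raise RuntimeError("luminality rejection sampling did not converge")

    ki67 = 100.0 * rng.beta(ki_a, ki_b, size=n)
    p_pos = cfg.her2_pos_prevalence
    neg = np.asarray(cfg.her2_negative_split, dtype=float)
    neg = neg / neg.sum()
    her2_probs = list(neg * (1.0 - p_pos)) + [p_pos]
    her2 = rng.choice(np.arange(4), size=n, p=her2_probs).astype(float)

    return pd.DataFrame(
        {
            "er_pct": er,
            "pr_pct": pr,
            "ki67_pct": ki67,
            "her2_herceptest": her2,
            "er_clinical_pos": scores._receptor_positive(er, thr).astype(int),
            "pr_clinical_pos": scores._receptor_positive(pr, thr).astype(int),
            "her2_clinical_pos": (her2 == 3.0).astype(int),
        }
    )


# ---------------------------------------------------------------------------
# clinical generation
# ---------------------------------------------------------------------------


def _draw_in_category(rng, cat_idx, bounds):
    lows = np.array([b[0] for b in bounds])
    highs = np.array([b[1] for b in bounds])
    return rng.uniform(lows[cat_idx], highs[cat_idx])


def generate_clinical(cfg: CohortConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Draw clinical covariates matching the configured category margins."""
    n = cfg.n_patients
    def _p(probs):
        probs = np.asarray(probs, dtype=float)
        return probs / probs.sum()

    age_cat = rng.choice(len(cfg.age_cat_probs), size=n, p=_p(cfg.age_cat_probs))
    age = _draw_in_category(rng, age_cat, cfg.age_cat_bounds)
    grade = rng.choice([1, 2, 3], size=n, p=_p(cfg.grade_probs))
    size_cat = rng.choice(len(cfg.size_cat_probs), size=n, p=_p(cfg.size_cat_probs))
    size = _draw_in_category(rng, size_cat, cfg.size_cat_bounds)

    node_pos = rng.random(n) >= cfg.node_negative_prob
    nodes = np.zeros(n, dtype=int)
    few = rng.random(n) < cfg.nodes_1_3_given_positive
    nodes[node_pos & few] = rng.integers(1, 4, size=int((node_pos & few).sum()))
    many = node_pos & ~few
    nodes[many] = 4 + rng.poisson(3.0, size=int(many.sum()))

    return pd.DataFrame(
        {
            "age_years": age,
            "tumor_size_mm": size,
            "grade": grade,
            "positive_nodes": nodes,
            "endocrine_therapy": (rng.random(n) < cfg.endocrine_prob).astype(int),
            "chemotherapy": (rng.random(n) < cfg.chemo_prob).astype(int),
            "study": np.where(rng.random(n) < cfg.study_mix, "PBCS", "SEARCH"),
        }
    )


# ---------------------------------------------------------------------------
# survival generation
# ---------------------------------------------------------------------------


def _predictor_z(df: pd.DataFrame, predictor) -> np.ndarray:
    """Standardized linear predictor: a column name, or a {column: weight}
    combination of standardized columns (re-standardized after mixing)."""
    if isinstance(predictor, str):
        if predictor not in df.columns:
            raise ValueError(f"predictor column {predictor!r} not in cohort")
        x = df[predictor].to_numpy(dtype=float)
    else:
        x = np.zeros(len(df))
        for col, w in dict(predictor).items():
            if col not in df.columns:
                raise ValueError(f"predictor column {col!r} not in cohort")
            part = df[col].to_numpy(dtype=float)
            if np.any(~np.isfinite(part)):
                raise ValueError(f"predictor {col!r} contains non-finite values")
            x = x + float(w) * standardize_per_sd(part)
    if np.any(~np.isfinite(x)):
        raise ValueError(f"predictor {predictor!r} contains non-finite values")
    return standardize_per_sd(x) if np.std(x, ddof=1) > 0 else np.zeros_like(x)


def simulate_survival(
    df: pd.DataFrame,
    hz: HazardConfig,
    rng: np.random.Generator,
    predictor="ihc4",
) -> pd.DataFrame:
    """Simulate event/censoring times under a Weibull PH model.

    The hazard is ``h0(t) * exp(beta * z)`` with ``z`` the standardized
    predictor (a column name or a weighted combination, see
    :func:`_predictor_z`) and ``beta = hz.log_hr_per_sd``.  Censoring is
    ``min(admin_censor_years, U)`` with U uniform over the entry window;
    the Weibull scale is solved so the expected event fraction equals
    ``hz.target_event_fraction`` given the realized z and censoring draws.
    """
    z = _predictor_z(df, predictor)
    relh = np.exp(hz.log_hr_per_sd * z)

    admin = hz.admin_censor_years
    censor = rng.uniform(admin - hz.followup_entry_window_years, admin, size=len(df))

    shape = hz.shape

    def _expected_event_fraction(scale: float) -> float:
        return float(np.mean(-np.expm1(-((censor / scale) ** shape) * relh)))

    scale = optimize.brentq(
        lambda s: _expected_event_fraction(s) - hz.target_event_fraction, 1e-3, 1e6
    )

    u = rng.uniform(size=len(df))
    t_event = scale * (-np.log(u) / relh) ** (1.0 / shape)
    time = np.minimum(t_event, censor)
    event = (t_event <= censor).astype(int)

    out = df.copy()
    out["time_years"] = time
    out["event"] = event
    out["latent_lp"] = hz.log_hr_per_sd * z
    out.attrs["weibull_scale"] = scale
    return out


# ---------------------------------------------------------------------------
# composition
# ---------------------------------------------------------------------------


def generate_cohort(
    cfg: CohortConfig,
    hz: HazardConfig = HazardConfig(),
    seed: int | None = None,
    predictor="ihc4",
    score_options: ScoreOptions | None = None,
) -> pd.DataFrame:
    """Markers + clinical + scores + simulated survival, deterministic in seed."""
    if seed is None:
        seed = cfg.seed
    if seed is None:
        raise ValueError("a seed is required (CohortConfig.seed or the seed argument)")
    ss = np.random.SeedSequence(seed)
    rng_markers, rng_clinical, rng_survival = (
        np.random.default_rng(s) for s in ss.spawn(3)
    )
    opts = score_options or ScoreOptions(
        er_pr_positivity_threshold=cfg.er_pr_positivity_threshold
    )
    markers = generate_markers(cfg, rng_markers)
    clinical = generate_clinical(cfg, rng_clinical)
    df = pd.concat([markers, clinical], axis=1)
    df.insert(0, "patient_id", [f"P{i:06d}" for i in range(1, len(df) + 1)])
    df = scores.score_cohort(df, opts, derive_categories=False)
    df = simulate_survival(df, hz, rng_survival, predictor=predictor)
    return df


# ---------------------------------------------------------------------------
# presets (published per-study margins)
# ---------------------------------------------------------------------------


def _norm(*probs: float) -> tuple[float, ...]:
    t = sum(probs)
    return tuple(p / t for p in probs)


PRESETS: dict[str, tuple[CohortConfig, HazardConfig]] = {
    "overall": (
        CohortConfig(
            n_patients=2498,
            study_mix=558.0 / 2498.0,
            age_cat_probs=_norm(0.016, 0.322, 0.537, 0.124),
            grade_probs=_norm(0.261, 0.557, 0.182),
            size_cat_probs=_norm(0.655, 0.321, 0.024),
            node_negative_prob=0.609,
            endocrine_prob=0.804,
        ),
        HazardConfig(target_event_fraction=316.0 / 2498.0),
    ),
    "pbcs": (
        CohortConfig(
            n_patients=558,
            study_mix=1.0,
            age_cat_probs=_norm(0.005, 0.265, 0.487, 0.242),
            grade_probs=_norm(0.265, 0.613, 0.122),
            size_cat_probs=_norm(0.593, 0.376, 0.030),
            node_negative_prob=0.560,
            endocrine_prob=0.644,
        ),
        HazardConfig(target_event_fraction=61.0 / 558.0,
                     followup_entry_window_years=9.5),
    ),
    "search": (
        CohortConfig(
            n_patients=1940,
            study_mix=0.0,
            age_cat_probs=_norm(0.020, 0.338, 0.552, 0.091),
            grade_probs=_norm(0.260, 0.538, 0.202),
            size_cat_probs=_norm(0.674, 0.304, 0.022),
            node_negative_prob=0.625,
            endocrine_prob=0.862,
        ),
        HazardConfig(target_event_fraction=255.0 / 1940.0,
                     followup_entry_window_years=4.0),
    ),
}


def get_preset(name: str) -> tuple[CohortConfig, HazardConfig]:
    try:
        return PRESETS[name]
    except KeyError:
        raise KeyError(
            f"unknown preset {name!r}; available: {sorted(PRESETS)}"
        ) from None
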