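"""Prognostic scores for luminal breast cancer.

Implements the quantitative IHC4-score (Cuzick et al.), the clinical
treatment score (C-score), the PREDICT (ER+) prognostic index, the
St Gallen-style luminal A-like / B-like surrogate subtype rules, and the
derived categorical transforms (per-SD standardization, mean + 1 SD
dichotomization, quartile binning).

All score functions are vectorized: they accept scalars or numpy arrays
and return the same shape.  Dataclass wrappers (:class:`MarkerPanel`,
:class:`ClinicalFactors`) provide the validated per-patient API, and
:func:`score_cohort` applies everything to a cohort ``DataFrame``.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Subtype",
    "CoreMeasurement",
    "MarkerPanel",
    "ClinicalFactors",
    "ScoreOptions",
    "ScoreSet",
    "aggregate_cores",
    "ihc4_score",
    "c_score",
    "predict_score",
    "compute_ihc4",
    "compute_c_score",
    "compute_predict_score",
    "classify_subtype",
    "classify_subtypes",
    "standardize_per_sd",
    "dichotomize_mean_plus_sd",
    "assign_quartiles",
    "score_cohort",
]

IHC4_SCALE = 94.7
IHC4_ER10_COEF = -0.100
IHC4_PR10_COEF = -0.079
IHC4_HER2_COEF = 0.586
IHC4_KI67_COEF = 0.240

KI67_LOW_CUTOFF = 12.0  # image-analysis KI67 %, A-like requires <= cutoff
HER2_ORDINAL_POSITIVE_CUTOFF = 2.5  # averaged Herceptest >= 2.5 counts as 3+


class Subtype(str, enum.Enum):
    """Surrogate immunohistochemistry subtype labels."""

    A_LIKE = "A_LIKE"
    B_LIKE = "B_LIKE"
    UNCLASSIFIED = "UNCLASSIFIED"
    NON_LUMINAL = "NON_LUMINAL"  # only emitted by the vectorized classifier


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CoreMeasurement:
    """Marker scores for a single tissue-microarray core.

    Percentages are percent positively staining malignant nuclei in
    [0, 100]; HER2 is the ordinal Herceptest category 0/1/2/3.  Missing
    markers are ``None``.
    """

    core_id: str
    er_pct: float | None = None
    pr_pct: float | None = None
    ki67_pct: float | None = None
    her2_herceptest: int | None = None

    def __post_init__(self) -> None:
        for name in ("er_pct", "pr_pct", "ki67_pct"):
            v = getattr(self, name)
            if v is not None and not (0.0 <= v <= 100.0):
                raise ValueError(f"{name}={v!r} outside [0, 100] on core {self.core_id}")
        h = self.her2_herceptest
        if h is not None and h not in (0, 1, 2, 3):
            raise ValueError(f"her2_herceptest={h!r} not in {{0, 1, 2, 3}} on core {self.core_id}")
        if all(
            getattr(self, n) is None
            for n in ("er_pct", "pr_pct", "ki67_pct", "her2_herceptest")
        ):
            raise ValueError(f"core {self.core_id} has no marker measurement")


@dataclass(frozen=True)
class MarkerPanel:
    """Patient-level marker measurements (per-core averages).

    ``her2_herceptest`` is the real-valued mean of the ordinal core
    scores, hence lives in [0, 3].  Clinical-record binary statuses are
    optional and, when present, take precedence for subtype calls.
    """

    er_pct: float | None = None
    pr_pct: float | None = None
    ki67_pct: float | None = None
    her2_herceptest: float | None = None
    er_clinical_pos: bool | None = None
    pr_clinical_pos: bool | None = None
    her2_clinical_pos: bool | None = None

    def __post_init__(self) -> None:
        for name in ("er_pct", "pr_pct", "ki67_pct"):
            v = getattr(self, name)
            if v is not None and not (0.0 <= v <= 100.0):
                raise ValueError(f"{name}={v!r} outside [0, 100]")
        h = self.her2_herceptest
        if h is not None and not (0.0 <= h <= 3.0):
            raise ValueError(f"her2_herceptest={h!r} outside [0, 3]")


@dataclass(frozen=True)
class ClinicalFactors:
    """Clinical covariates used by the C-score and PREDICT-score."""

    age_years: float
    tumor_size_mm: float
    grade: int
    positive_nodes: int
    endocrine_therapy: bool = False
    chemotherapy: bool = False
    aromatase_inhibitor: bool | None = None
    screen_detected: bool | None = None
    study: str | None = None

    def __post_init__(self) -> None:
        if self.grade not in (1, 2, 3):
            raise ValueError(f"grade={self.grade!r} not in {{1, 2, 3}}")
        if self.positive_nodes < 0:
            raise ValueError(f"positive_nodes={self.positive_nodes!r} must be >= 0")
        if self.tumor_size_mm <= 0:
            raise ValueError(f"tumor_size_mm={self.tumor_size_mm!r} must be > 0")
        if self.age_years <= 0:
            raise ValueError(f"age_years={self.age_years!r} must be > 0")


@dataclass(frozen=True)
class ScoreOptions:
    """Conventions for score computation and subtype calls.

    ki67_unit
        ``"percent"`` (default): the KI67 value enters ``ln(1 + 10*KI67)``
        on the 0-100 scale.  ``"fraction"`` divides by 100 first.
    her2_coding
        ``"herceptest_ordinal"`` (default): the averaged 0-3 Herceptest
        score enters the IHC4 linear predictor.  ``"clinical_binary"``
        uses the 0/1 clinical HER2 status instead.
    er_pr_positivity_threshold
        Receptor-positivity cut point for subtype definition: 10
        (positive iff % > 10, Allred > 2 convention) or 1 (positive
        iff % >= 1, the modern guideline convention).
    c_score_bracket_convention
        ``"as_printed"`` applies the 0.930 multiplier to the 0.497*T(1-2)
        term only; ``"whole_bracket"`` applies it to the whole
        size/grade/age bracket.
    """

    ki67_unit: str = "percent"
    her2_coding: str = "herceptest_ordinal"
    er_pr_positivity_threshold: float = 10.0
    c_score_bracket_convention: str = "as_printed"

    def __post_init__(self) -> None:
        if self.ki67_unit not in ("percent", "fraction"):
            raise ValueError(f"ki67_unit={self.ki67_unit!r}")
        if self.her2_coding not in ("herceptest_ordinal", "clinical_binary"):
            raise ValueError(f"her2_coding={self.her2_coding!r}")
        if self.er_pr_positivity_threshold not in (10.0, 1.0):
            raise ValueError(
                "er_pr_positivity_threshold must be 10 or 1, got "
                f"{self.er_pr_positivity_threshold!r}"
            )
        if self.c_score_bracket_convention not in ("as_printed", "whole_bracket"):
            raise ValueError(
                f"c_score_bracket_convention={self.c_score_bracket_convention!r}"
            )


@dataclass
class ScoreSet:
    """Scores and derived categories for one patient."""

    ihc4: float
    c_score: float
    predict_score: float
    ihc4_z: float | None = None
    subtype: Subtype | None = None
    ihc4_quartile: int | None = None
    ihc4_high: bool | None = None


# ---------------------------------------------------------------------------
# core aggregation
# ---------------------------------------------------------------------------


def aggregate_cores(cores: Sequence[CoreMeasurement]) -> MarkerPanel:
    """Average per-core marker scores into a patient-level panel.

    Each marker is the arithmetic mean over the cores on which it is
    non-missing; HER2 ordinal categories are averaged as reals.  A marker
    missing on every core is left missing on the panel.
    """
    if len(cores) == 0:
        raise ValueError("cannot aggregate an empty core list")

    def _mean(name: str) -> float | None:
        vals = [getattr(c, name) for c in cores if getattr(c, name) is not None]
        return float(np.mean(vals)) if vals else None

    return MarkerPanel(
        er_pct=_mean("er_pct"),
        pr_pct=_mean("pr_pct"),
        ki67_pct=_mean("ki67_pct"),
        her2_herceptest=_mean("her2_herceptest"),
    )


# ---------------------------------------------------------------------------
# score formulas (vectorized)
# ---------------------------------------------------------------------------


def ihc4_score(er_pct, pr_pct, her2, ki67, *, ki67_unit: str = "percent"):
    """Quantitative IHC4-score.

    ``94.7 * (-0.100*ER10 - 0.079*PR10 + 0.586*HER2 + 0.240*ln(1 + 10*KI67))``
    with ``ER10 = er_pct / 10`` and ``PR10 = pr_pct / 10``.  ``her2`` is
    either the averaged Herceptest ordinal (0-3) or a 0/1 clinical
    status, per the caller's coding choice.  Higher is worse.
    """
    er_pct, pr_pct, her2, ki67 = (
        np.asarray(x, dtype=float) for x in (er_pct, pr_pct, her2, ki67)
    )
    for name, v in (("er_pct", er_pct), ("pr_pct", pr_pct), ("her2", her2), ("ki67", ki67)):
        if np.any(np.isnan(v)):
            raise ValueError(f"IHC4 component {name} is missing")
    if np.any(ki67 < 0):
        raise ValueError("ki67 must be non-negative")
    if ki67_unit == "fraction":
        ki67 = ki67 / 100.0
    elif ki67_unit != "percent":
        raise ValueError(f"ki67_unit={ki67_unit!r}")
    lin = (
        IHC4_ER10_COEF * (er_pct / 10.0)
        + IHC4_PR10_COEF * (pr_pct / 10.0)
        + IHC4_HER2_COEF * her2
        + IHC4_KI67_COEF * np.log1p(10.0 * ki67)
    )
    out = IHC4_SCALE * lin
    return float(out) if out.ndim == 0 else out


def c_score(positive_nodes, tumor_size_mm, grade, age_years, *,
            aromatase_inhibitor=0, bracket_convention: str = "as_printed"):
    """Clinical treatment score (C-score).

    ``100 * {0.417*N(1-3) + 1.566*N(4+) + [0.930*(0.497*T(1-2)) + 0.882*T(2-3)
    + 1.838*T(>3) + 0.559*Gr2 + 0.970*Gr3 + 0.130*Age(>=65) + 0.149*AI]}``

    Node categories 0 (reference) / 1-3 / 4+; size categories <=1 cm
    (reference) / >1-<=2 / >2-<=3 / >3 cm (sizes in mm); grade 1 is the
    reference.  The AI (aromatase inhibitor vs tamoxifen) term defaults
    to 0 — treatment-regimen data are assumed unavailable.
    """
    nodes, size, grade, age = (
        np.asarray(x, dtype=float)
        for x in (positive_nodes, tumor_size_mm, grade, age_years)
    )
    if np.any(size <= 0):
        raise ValueError("tumor_size_mm must be > 0")
    if np.any(nodes < 0):
        raise ValueError("positive_nodes must be >= 0")
    ai = np.asarray(aromatase_inhibitor, dtype=float)

    n13 = (nodes >= 1) & (nodes <= 3)
    n4 = nodes >= 4
    t12 = (size > 10.0) & (size <= 20.0)
    t23 = (size > 20.0) & (size <= 30.0)
    t3 = size > 30.0
    gr2 = grade == 2
    gr3 = grade == 3
    age65 = age >= 65.0

    if bracket_convention == "as_printed":
        bracket = (
            0.930 * (0.497 * t12)
            + 0.882 * t23
            + 1.838 * t3
            + 0.559 * gr2
            + 0.970 * gr3
            + 0.130 * age65
            + 0.149 * ai
        )
    elif bracket_convention == "whole_bracket":
        bracket = 0.930 * (
            0.497 * t12
            + 0.882 * t23
            + 1.838 * t3
            + 0.559 * gr2
            + 0.970 * gr3
            + 0.130 * age65
            + 0.149 * ai
        )
    else:
        raise ValueError(f"bracket_convention={bracket_convention!r}")

    out = 100.0 * (0.417 * n13 + 1.566 * n4 + bracket)
    return float(out) if out.ndim == 0 else out


def predict_score(age_years, tumor_size_mm, positive_nodes, grade):
    """PREDICT (ER+) prognostic index, screen-detection term omitted.

    ``(34.53*(Age/10)^-2 - 0.0287) + (-34.20*(Age/10)^-2*ln(Age/10) - 0.0510)
    + (0.7531*ln(Size/100) + 1.5452) + (0.7069*ln((Nodes+1)/10) + 1.3876)
    + 0.7467*Grade`` with Size in mm, Grade numeric 1-3, natural logs.
    """
    age, size, nodes, grade = (
        np.asarray(x, dtype=float)
        for x in (age_years, tumor_size_mm, positive_nodes, grade)
    )
    if np.any(age <= 0):
        raise ValueError("age_years must be > 0")
    if np.any(size <= 0):
        raise ValueError("tumor_size_mm must be > 0")
    a = age / 10.0
    out = (
        (34.53 * a**-2 - 0.0287)
        + (-34.20 * a**-2 * np.log(a) - 0.0510)
        + (0.7531 * np.log(size / 100.0) + 1.5452)
        + (0.7069 * np.log((nodes + 1.0) / 10.0) + 1.3876)
        + 0.7467 * grade
    )
    return float(out) if out.ndim == 0 else out


# ---------------------------------------------------------------------------
# dataclass-level wrappers
# ---------------------------------------------------------------------------


def compute_ihc4(panel: MarkerPanel, opts: ScoreOptions = ScoreOptions()) -> float:
    """IHC4-score for a validated patient panel, per ``opts`` conventions."""
    for name in ("er_pct", "pr_pct", "ki67_pct"):
        if getattr(panel, name) is None:
            raise ValueError(f"IHC4 component {name} is missing")
    if opts.her2_coding == "herceptest_ordinal":
        if panel.her2_herceptest is None:
            raise ValueError("IHC4 component her2_herceptest is missing")
        her2 = panel.her2_herceptest
    else:
        if panel.her2_clinical_pos is None:
            raise ValueError("IHC4 component her2_clinical_pos is missing")
        her2 = float(panel.her2_clinical_pos)
    return ihc4_score(
        panel.er_pct, panel.pr_pct, her2, panel.ki67_pct, ki67_unit=opts.ki67_unit
    )


def compute_c_score(cf: ClinicalFactors, opts: ScoreOptions = ScoreOptions()) -> float:
    """C-score for a patient; the AI component is forced to 0."""
    return c_score(
        cf.positive_nodes,
        cf.tumor_size_mm,
        cf.grade,
        cf.age_years,
        aromatase_inhibitor=0,
        bracket_convention=opts.c_score_bracket_convention,
    )


def compute_predict_score(cf: ClinicalFactors) -> float:
    """PREDICT-score for a patient; screen-detection term omitted (0)."""
    return predict_score(cf.age_years, cf.tumor_size_mm, cf.positive_nodes, cf.grade)


# ---------------------------------------------------------------------------
# subtype classification
# ---------------------------------------------------------------------------


def _receptor_positive(pct, threshold: float):
    # > 10% under the Allred-derived convention, >= 1% under the modern one
    pct = np.asarray(pct, dtype=float)
    return pct >= threshold if threshold <= 1.0 else pct > threshold


def _resolve_status(clinical, pct, threshold: float):
    """Prefer the clinical-record binary status; fall back to image %."""
    clinical = np.asarray(clinical, dtype=float)
    image = _receptor_positive(pct, threshold)
    return np.where(np.isnan(clinical), image, clinical > 0.5)


def classify_subtype(panel: MarkerPanel, opts: ScoreOptions = ScoreOptions()) -> Subtype:
    """Classify one luminal patient as A-like, B-like or unclassified.

    A-like: ER+ and PR+ and HER2- and KI67 <= 12%.  B-like: (ER+ or PR+)
    and (KI67 > 12% or HER2+).  Luminal patients matching neither rule
    (HER2-, KI67 <= 12%, only one receptor positive) are UNCLASSIFIED.
    ER-/PR- (non-luminal) input is an error.
    """
    thr = opts.er_pr_positivity_threshold

    def _status(clinical: bool | None, pct: float | None, name: str) -> bool:
        if clinical is not None:
            return bool(clinical)
        if pct is None:
            raise ValueError(f"cannot determine {name} status: no clinical flag or image %")
        return bool(_receptor_positive(pct, thr))

    er_pos = _status(panel.er_clinical_pos, panel.er_pct, "ER")
    pr_pos = _status(panel.pr_clinical_pos, panel.pr_pct, "PR")
    if not (er_pos or pr_pos):
        raise ValueError("non-luminal tumor (ER- and PR-): subtype undefined")
    if panel.her2_clinical_pos is not None:
        her2_pos = bool(panel.her2_clinical_pos)
    elif panel.her2_herceptest is not None:
        her2_pos = panel.her2_herceptest >= HER2_ORDINAL_POSITIVE_CUTOFF
    else:
        raise ValueError("cannot determine HER2 status")
    if panel.ki67_pct is None:
        raise ValueError("cannot classify subtype: ki67_pct missing")
    high_ki67 = panel.ki67_pct > KI67_LOW_CUTOFF

    if high_ki67 or her2_pos:
        return Subtype.B_LIKE
    if er_pos and pr_pos:
        return Subtype.A_LIKE
    return Subtype.UNCLASSIFIED


def classify_subtypes(df: pd.DataFrame, opts: ScoreOptions = ScoreOptions()) -> pd.Series:
    """Vectorized subtype call on a cohort table.

    Unlike :func:`classify_subtype`, ER-/PR- rows are labeled
    ``NON_LUMINAL`` instead of raising, so sensitivity re-classification
    can cross-tabulate threshold conventions over a whole cohort.
    """
    thr = opts.er_pr_positivity_threshold
    er_clin = df.get("er_clinical_pos", pd.Series(np.nan, index=df.index))
    pr_clin = df.get("pr_clinical_pos", pd.Series(np.nan, index=df.index))
    her2_clin = df.get("her2_clinical_pos", pd.Series(np.nan, index=df.index))

    er_pos = _resolve_status(er_clin, df["er_pct"], thr)
    pr_pos = _resolve_status(pr_clin, df["pr_pct"], thr)
    her2_img = np.asarray(df["her2_herceptest"], dtype=float) >= HER2_ORDINAL_POSITIVE_CUTOFF
    her2_clin = np.asarray(her2_clin, dtype=float)
    her2_pos = np.where(np.isnan(her2_clin), her2_img, her2_clin > 0.5)
    high_ki67 = np.asarray(df["ki67_pct"], dtype=float) > KI67_LOW_CUTOFF

    luminal = er_pos | pr_pos
    b_like = luminal & (high_ki67 | her2_pos)
    a_like = er_pos & pr_pos & ~her2_pos & ~high_ki67

    out = np.full(len(df), Subtype.UNCLASSIFIED.value, dtype=object)
    out[b_like] = Subtype.B_LIKE.value
    out[a_like] = Subtype.A_LIKE.value
    out[~luminal] = Subtype.NON_LUMINAL.value
    return pd.Series(out, index=df.index, name="subtype")


# ---------------------------------------------------------------------------
# categorical transforms
# ---------------------------------------------------------------------------


def _check_spread(values: np.ndarray) -> tuple[float, float]:
    if values.size < 2:
        raise ValueError("need at least 2 values")
    if np.any(~np.isfinite(values)):
        raise ValueError("values must be finite")
    mean = float(np.mean(values))
    sd = float(np.std(values, ddof=1))
    if sd == 0.0:
        raise ValueError("zero variance: cannot standardize")
    return mean, sd


def standardize_per_sd(values: Iterable[float]) -> np.ndarray:
    """Center and scale by the sample SD (n-1 denominator)."""
    values = np.asarray(list(values) if not isinstance(values, np.ndarray) else values,
                        dtype=float)
    mean, sd = _check_spread(values)
    return (values - mean) / sd


def dichotomize_mean_plus_sd(values: Iterable[float]) -> tuple[np.ndarray, float]:
    """Label high iff value > mean + 1 sample SD; also return the threshold."""
    values = np.asarray(list(values) if not isinstance(values, np.ndarray) else values,
                        dtype=float)
    mean, sd = _check_spread(values)
    threshold = mean + sd
    return values > threshold, threshold


def assign_quartiles(values: Iterable[float]) -> np.ndarray:
    """Quartile labels 1-4 cut at the empirical 25/50/75 percentiles.

    Percentiles use linear interpolation; a value exactly equal to a
    boundary goes to the lower bin.
    """
    values = np.asarray(list(values) if not isinstance(values, np.ndarray) else values,
                        dtype=float)
    if np.unique(values[np.isfinite(values)]).size < 4:
        raise ValueError("need at least 4 distinct values for quartiles")
    q25, q50, q75 = np.percentile(values, [25, 50, 75])
    out = np.full(values.shape, 4, dtype=int)
    out[values <= q75] = 3
    out[values <= q50] = 2
    out[values <= q25] = 1
    return out


# ---------------------------------------------------------------------------
# cohort-level scoring
# ---------------------------------------------------------------------------


def score_cohort(df: pd.DataFrame, opts: ScoreOptions = ScoreOptions(),
                 derive_categories: bool = True) -> pd.DataFrame:
    """Attach ihc4 / c_score / predict_score / subtype columns to a cohort.

    With ``derive_categories`` the cohort-level transforms (``ihc4_z``,
    ``ihc4_quartile``, ``ihc4_high``) are computed on the full input
    table; recompute them after exclusions when needed.
    """
    out = df.copy()
    if opts.her2_coding == "herceptest_ordinal":
        her2 = out["her2_herceptest"]
    else:
        her2 = out["her2_clinical_pos"].astype(float)
    out["ihc4"] = ihc4_score(
        out["er_pct"], out["pr_pct"], her2, out["ki67_pct"], ki67_unit=opts.ki67_unit
    )
    out["c_score"] = c_score(
        out["positive_nodes"], out["tumor_size_mm"], out["grade"], out["age_years"],
        bracket_convention=opts.c_score_bracket_convention,
    )
    out["predict_score"] = predict_score(
        out["age_years"], out["tumor_size_mm"], out["positive_nodes"], out["grade"]
    )
    out["subtype"] = classify_subtypes(out, opts)
    if derive_categories:
        out["ihc4_z"] = standardize_per_sd(out["ihc4"].to_numpy())
        out["ihc4_quartile"] = assign_quartiles(out["ihc4"].to_numpy())
        high, thr = dichotomize_mean_plus_sd(out["ihc4"].to_numpy())
        out["ihc4_high"] = high.astype(int)
        out.attrs["ihc4_high_threshold"] = thr
    return out
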