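"""End-to-end analysis orchestration.

Generate or load a cohort, compute scores and subtypes, apply
exclusions, truncate follow-up at 10 years, fit the univariable /
multivariable / subtype-specific / dichotomized Cox model suite with
nested ΔLRχ² comparisons, and run the Kaplan–Meier suites — writing a
deterministic report directory keyed by (config, seed).
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import cohort_io, survival_models as sm
from .scores import ScoreOptions, score_cohort
from .synthetic_cohort import CohortConfig, HazardConfig, generate_cohort, get_preset

__all__ = [
    "AnalysisConfig",
    "AnalysisReport",
    "run_full_analysis",
    "sensitivity_reclassification",
    "read_cohort",
    "write_cohort",
]

log = logging.getLogger("ihc4pipe")

read_cohort = cohort_io.read_cohort
write_cohort = cohort_io.write_cohort

ADJUST_BASE = ["age_years", "endocrine_therapy"]


@dataclass
class AnalysisConfig:
    """Inputs and switches for one analysis run.

    Exactly one of ``cohort_csv`` / ``preset`` must be set; synthetic
    runs additionally honour ``n_patients`` / ``hazard`` overrides.
    """

    cohort_csv: str | None = None
    preset: str | None = None
    n_patients: int | None = None
    seed: int = 0
    score_options: ScoreOptions = field(default_factory=ScoreOptions)
    hazard: HazardConfig | None = None
    stratify_by_study: bool = True
    stratify_km_by_nodes: bool = True
    exclude_stage_iv: bool = False  # stage is not modelled; retained for config parity
    make_plots: bool = False
    outdir: str | None = None

    def __post_init__(self) -> None:
        if (self.cohort_csv is None) == (self.preset is None):
            raise ValueError("set exactly one of cohort_csv or preset")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if "score_options" in raw:
            raw["score_options"] = ScoreOptions(**raw["score_options"])
        if "hazard" in raw and raw["hazard"] is not None:
            raw["hazard"] = HazardConfig(**raw["hazard"])
        return cls(**raw)


@dataclass
class AnalysisReport:
    """Tidy result tables plus the run manifest."""

    score_models: pd.DataFrame
    dichotomized_models: pd.DataFrame
    km_tables: dict[str, pd.DataFrame]
    exclusion_log: dict
    manifest: dict
    cohort: pd.DataFrame


# ---------------------------------------------------------------------------
# model suite
# ---------------------------------------------------------------------------


def _adjust_terms(stratum: str) -> list[str]:
    return ADJUST_BASE + (["_study_b"] if stratum == "combined" else [])


def _blank_row(stratum, block, parameter, reason):
    return {
        "stratum": stratum, "block": block, "parameter": parameter,
        "hr": np.nan, "ci_lower": np.nan, "ci_upper": np.nan, "p": np.nan,
        "lr_chisq": np.nan, "n": 0, "n_events": 0, "note": reason,
    }


def _row_from_fit(stratum, block, parameter, fit, term, lr_chisq):
    return {
        "stratum": stratum, "block": block, "parameter": parameter,
        "hr": fit.hazard_ratios[term], "ci_lower": fit.ci_lower[term],
        "ci_upper": fit.ci_upper[term], "p": fit.p_values[term],
        "lr_chisq": lr_chisq, "n": fit.n, "n_events": fit.n_events, "note": "",
    }


def _fit_score_models(df: pd.DataFrame, stratum: str, manifest_models: list[dict]) -> list[dict]:
    """The univariable / multivariable / subtype-specific model blocks for one stratum's analysis cohort."""
    rows: list[dict] = []
    adjust = _adjust_terms(stratum)

    def _register(model_id, fit):
        manifest_models.append(
            {"model": model_id, "stratum": stratum, "terms": fit.terms,
             "loglik": fit.loglik, "lr_chisq": fit.lr_chisq,
             "n": fit.n, "n_events": fit.n_events}
        )

    def _try(block, parameter, fn):
        try:
            rows.append(fn())
        except (ValueError, KeyError) as exc:
            log.warning("%s / %s / %s inestimable: %s", stratum, block, parameter, exc)
            rows.append(_blank_row(stratum, block, parameter, str(exc)))

    ab = df[df["subtype"].isin(["A_LIKE", "B_LIKE"])].copy()
    ab["_subtype_b"] = (ab["subtype"] == "B_LIKE").astype(float)

    # --- univariable ------------------------------------------------------
    def _uni_subtype():
        fit = sm.fit_cox(ab, ["_subtype_b"])
        _register("uni_subtype", fit)
        return _row_from_fit(stratum, "univariable", "subtype_b_vs_a", fit,
                             "_subtype_b", fit.lr_chisq)

    _try("univariable", "subtype_b_vs_a", _uni_subtype)

    for score in ("ihc4", "c_score", "predict_score"):
        def _uni(score=score):
            fit = sm.fit_cox(df, [score], per_sd=[score])
            _register(f"uni_{score}", fit)
            return _row_from_fit(stratum, "univariable", f"{score}_per_sd", fit,
                                 score, fit.lr_chisq)

        _try("univariable", f"{score}_per_sd", _uni)

    # --- multivariable pairs (LRχ² cell = ΔLRχ² on removal) ---------------
    pairs = [
        ("multivariable_ihc4_c", "ihc4", "c_score"),
        ("multivariable_ihc4_predict", "ihc4", "predict_score"),
    ]
    for block, s1, s2 in pairs:
        def _pair(block=block, s1=s1, s2=s2):
            out = []
            full = sm.fit_cox(df, [s1, s2] + adjust, per_sd=[s1, s2])
            _register(f"{block}_full", full)
            for target, other in ((s1, s2), (s2, s1)):
                reduced = sm.fit_cox(df, [other] + adjust, per_sd=[other])
                delta = sm.compare_nested(full, reduced)
                out.append(_row_from_fit(stratum, block, f"{target}_per_sd", full,
                                         target, delta.delta_lr_chisq))
            return out

        try:
            rows.extend(_pair())
        except (ValueError, KeyError) as exc:
            log.warning("%s / %s inestimable: %s", stratum, block, exc)
            rows.append(_blank_row(stratum, block, "pair", str(exc)))

    def _subtype_predict():
        out = []
        full = sm.fit_cox(ab, ["_subtype_b", "predict_score"] + adjust,
                          per_sd=["predict_score"])
        _register("multivariable_subtype_predict_full", full)
        red_no_subtype = sm.fit_cox(ab, ["predict_score"] + adjust,
                                    per_sd=["predict_score"])
        delta_subtype = sm.compare_nested(full, red_no_subtype)
        out.append(_row_from_fit(stratum, "multivariable_subtype_predict",
                                 "subtype_b_vs_a", full, "_subtype_b",
                                 delta_subtype.delta_lr_chisq))
        red_no_predict = sm.fit_cox(ab, ["_subtype_b"] + adjust)
        delta_predict = sm.compare_nested(full, red_no_predict)
        out.append(_row_from_fit(stratum, "multivariable_subtype_predict",
                                 "predict_score_per_sd", full, "predict_score",
                                 delta_predict.delta_lr_chisq))
        return out

    try:
        rows.extend(_subtype_predict())
    except (ValueError, KeyError) as exc:
        log.warning("%s / multivariable_subtype_predict inestimable: %s", stratum, exc)
        rows.append(_blank_row(stratum, "multivariable_subtype_predict", "pair", str(exc)))

    # --- subtype-specific IHC4 + PREDICT ----------------------------------
    for label in ("A_LIKE", "B_LIKE"):
        part = df[df["subtype"] == label]

        def _spec(part=part, label=label):
            out = []
            full = sm.fit_cox(part, ["ihc4", "predict_score"] + adjust,
                              per_sd=["ihc4", "predict_score"])
            _register(f"subtype_specific_{label}", full)
            for score in ("ihc4", "predict_score"):
                other = "predict_score" if score == "ihc4" else "ihc4"
                reduced = sm.fit_cox(part, [other] + adjust, per_sd=[other])
                delta = sm.compare_nested(full, reduced)
                out.append(_row_from_fit(stratum, f"subtype_specific_{label.lower()}",
                                         f"{score}_per_sd", full, score,
                                         delta.delta_lr_chisq))
            return out

        try:
            rows.extend(_spec())
        except (ValueError, KeyError) as exc:
            log.warning("%s / subtype_specific_%s inestimable: %s", stratum, label, exc)
            rows.append(_blank_row(stratum, f"subtype_specific_{label.lower()}",
                                   "pair", str(exc)))

    return rows


def _fit_dichotomized_models(df: pd.DataFrame, stratum: str, manifest_models: list[dict]) -> list[dict]:
    """High vs low IHC4 within each subtype, PREDICT-adjusted."""
    rows: list[dict] = []
    adjust = ["predict_score"] + _adjust_terms(stratum)
    for label in ("A_LIKE", "B_LIKE"):
        part = df[df["subtype"] == label]
        counts = {
            "cases_low": int((part["ihc4_high"] == 0).sum()),
            "events_low": int(part.loc[part["ihc4_high"] == 0, "event"].sum()),
            "cases_high": int((part["ihc4_high"] == 1).sum()),
            "events_high": int(part.loc[part["ihc4_high"] == 1, "event"].sum()),
        }
        try:
            fit = sm.fit_cox(part, ["ihc4_high"] + adjust, per_sd=["predict_score"])
            manifest_models.append(
                {"model": f"dichot_{label}", "stratum": stratum, "terms": fit.terms,
                 "loglik": fit.loglik, "lr_chisq": fit.lr_chisq,
                 "n": fit.n, "n_events": fit.n_events}
            )
            rows.append(
                {"stratum": stratum, "subtype": label,
                 "hr_high_vs_low": fit.hazard_ratios["ihc4_high"],
                 "ci_lower": fit.ci_lower["ihc4_high"],
                 "ci_upper": fit.ci_upper["ihc4_high"],
                 "p": fit.p_values["ihc4_high"], **counts, "note": ""}
            )
        except (ValueError, KeyError) as exc:
            log.warning("%s / dichotomized %s inestimable: %s", stratum, label, exc)
            rows.append(
                {"stratum": stratum, "subtype": label, "hr_high_vs_low": np.nan,
                 "ci_lower": np.nan, "ci_upper": np.nan, "p": np.nan,
                 **counts, "note": str(exc)}
            )
    return rows


def _km_suite(df: pd.DataFrame, stratify_by_nodes: bool) -> dict[str, pd.DataFrame]:
    """Kaplan–Meier step tables: subtype, IHC4 quartiles (optionally by
    nodal status), and high/low IHC4."""
    out: dict[str, pd.DataFrame] = {}

    def _flatten(res, name):
        parts = []
        for group, tbl in res.curves.items():
            t = tbl.copy()
            t.insert(0, "group", group)
            parts.append(t)
        flat = pd.concat(parts, ignore_index=True)
        flat.attrs["logrank_stat"] = res.logrank_stat
        flat.attrs["logrank_p"] = res.logrank_p
        out[name] = flat

    ab = df[df["subtype"].isin(["A_LIKE", "B_LIKE"])]
    try:
        _flatten(sm.km_logrank(ab, "subtype"), "km_subtype")
    except ValueError as exc:
        log.warning("KM subtype skipped: %s", exc)
    _flatten(sm.km_logrank(df, "ihc4_quartile"), "km_ihc4_quartile")
    _flatten(sm.km_logrank(df, "ihc4_high"), "km_ihc4_high")
    if stratify_by_nodes:
        df = df.assign(_node_pos=(df["positive_nodes"] > 0).astype(int))
        for level, part in df.groupby("_node_pos"):
            name = "node_positive" if level else "node_negative"
            try:
                _flatten(sm.km_logrank(part, "ihc4_quartile"), f"km_ihc4_quartile_{name}")
            except ValueError as exc:
                log.warning("KM quartile (%s) skipped: %s", name, exc)
    return out


# ---------------------------------------------------------------------------
# orchestration
# ---------------------------------------------------------------------------


def _load_or_generate(cfg: AnalysisConfig) -> pd.DataFrame:
    if cfg.cohort_csv is not None:
        log.info("loading cohort from %s", cfg.cohort_csv)
        return read_cohort(cfg.cohort_csv)
    ccfg, hz = get_preset(cfg.preset)
    if cfg.n_patients is not None:
        ccfg = dataclasses.replace(ccfg, n_patients=cfg.n_patients)
    if cfg.hazard is not None:
        hz = cfg.hazard
    log.info("generating preset %r cohort (n=%d, seed=%d)",
             cfg.preset, ccfg.n_patients, cfg.seed)
    return generate_cohort(ccfg, hz, seed=cfg.seed,
                           score_options=cfg.score_options)


def _prepare(cfg: AnalysisConfig, df: pd.DataFrame):
    """Score -> classify -> exclude -> truncate -> derive categories."""
    df = score_cohort(df, cfg.score_options, derive_categories=False)
    covars = ["ihc4", "c_score", "predict_score", "age_years",
              "endocrine_therapy", "time_years", "event"]
    analysis, excl = sm.apply_exclusions(df, covariates=covars)
    analysis = sm.truncate_at_10y(analysis)
    # categorical transforms on the analysis cohort (post-exclusion)
    analysis = score_cohort(analysis, cfg.score_options, derive_categories=True)
    analysis["_study_b"] = (analysis["study"] == "SEARCH").astype(float)
    excl["unclassified_dropped_in_subtype_models"] = int(
        (~analysis["subtype"].isin(["A_LIKE", "B_LIKE"])).sum()
    )
    return analysis, excl


def run_full_analysis(cfg: AnalysisConfig) -> AnalysisReport:
    """Execute the full pipeline; write the report directory if configured."""
    raw = _load_or_generate(cfg)
    analysis, excl = _prepare(cfg, raw)

    strata = [("combined", analysis)]
    if cfg.stratify_by_study and analysis["study"].nunique() > 1:
        for s in sorted(analysis["study"].unique()):
            strata.append((str(s), analysis[analysis["study"] == s]))

    models: list[dict] = []
    t2_rows: list[dict] = []
    t3_rows: list[dict] = []
    for name, part in strata:
        log.info("fitting model suite for stratum %r (n=%d)", name, len(part))
        t2_rows.extend(_fit_score_models(part, name, models))
        t3_rows.extend(_fit_dichotomized_models(part, name, models))

    km_tables = _km_suite(analysis, cfg.stratify_km_by_nodes)

    manifest = {
        "config": _config_echo(cfg),
        "seed": cfg.seed,
        "n_input": int(excl["input"]),
        "exclusions": excl,
        "models": models,
        "km": {
            name: {"logrank_stat": tbl.attrs["logrank_stat"],
                   "logrank_p": tbl.attrs["logrank_p"]}
            for name, tbl in km_tables.items()
        },
    }
    report = AnalysisReport(
        score_models=pd.DataFrame(t2_rows),
        dichotomized_models=pd.DataFrame(t3_rows),
        km_tables=km_tables,
        exclusion_log=excl,
        manifest=manifest,
        cohort=analysis,
    )
    if cfg.outdir is not None:
        _write_report(cfg, report)
    return report


def sensitivity_reclassification(cfg: AnalysisConfig) -> AnalysisReport:
    """Re-run subtype-dependent analyses with the >=1% ER/PR threshold.

    The returned report carries the 1%-threshold model suite; a 10%-vs-1%
    subtype cross-tabulation is attached as ``manifest["crosstab"]`` and
    written alongside the report.
    """
    from .scores import classify_subtypes

    raw = _load_or_generate(cfg)
    opts10 = dataclasses.replace(cfg.score_options, er_pr_positivity_threshold=10.0)
    opts1 = dataclasses.replace(cfg.score_options, er_pr_positivity_threshold=1.0)
    lab10 = classify_subtypes(raw, opts10)
    lab1 = classify_subtypes(raw, opts1)
    crosstab = pd.crosstab(
        lab10.rename("threshold_10pct"), lab1.rename("threshold_1pct"), dropna=False
    )

    cfg1 = dataclasses.replace(cfg, score_options=opts1)
    report = run_full_analysis(cfg1)
    report.manifest["crosstab"] = {
        str(r): {str(c): int(v) for c, v in row.items()}
        for r, row in crosstab.to_dict(orient="index").items()
    }
    if cfg.outdir is not None:
        crosstab.to_csv(Path(cfg.outdir) / "subtype_crosstab.csv")
        _write_manifest(Path(cfg.outdir) / "manifest.json", report.manifest)
    return report


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------


def _config_echo(cfg: AnalysisConfig) -> dict:
    def _plain(obj):
        if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
            return {k: _plain(v) for k, v in dataclasses.asdict(obj).items()}
        if isinstance(obj, (np.integer, np.floating)):
            return obj.item()
        return obj

    echo = _plain(cfg)
    echo.pop("outdir", None)  # incidental: keeps reruns bit-identical anywhere
    return echo


def _write_manifest(path: Path, manifest: dict) -> None:
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True, default=str) + "\n")


def _write_report(cfg: AnalysisConfig, report: AnalysisReport) -> None:
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_cohort(report.cohort.drop(columns=["_study_b"]), outdir / "cohort_scored.csv")
    report.score_models.to_csv(outdir / "score_models.csv", index=False)
    report.dichotomized_models.to_csv(outdir / "dichotomized_models.csv", index=False)
    kmdir = outdir / "km"
    kmdir.mkdir(exist_ok=True)
    for name, tbl in report.km_tables.items():
        tbl.to_csv(kmdir / f"{name}.csv", index=False)
    (outdir / "exclusions.json").write_text(
        json.dumps(report.exclusion_log, indent=2, sort_keys=True) + "\n"
    )
    _write_manifest(outdir / "manifest.json", report.manifest)
    if cfg.make_plots:
        _plot_km(report.km_tables, outdir)
    log.info("report written to %s", outdir)


def _plot_km(km_tables: dict[str, pd.DataFrame], outdir: Path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    for name, tbl in km_tables.items():
        fig, ax = plt.subplots(figsize=(5, 4))
        for group, part in tbl.groupby("group"):
            ax.step(part["time"], part["survival"], where="post", label=str(group))
        ax.set_xlabel("years")
        ax.set_ylabel("breast cancer-specific survival")
        ax.set_ylim(0, 1.02)
        ax.legend(fontsize=8)
        ax.set_title(f"{name} (logrank p={tbl.attrs['logrank_p']:.3g})")
        fig.tight_layout()
        fig.savefig(outdir / f"{name}.png", dpi=120)
        plt.close(fig)
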