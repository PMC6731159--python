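# ihc4pipe

Quantitative prognostic scoring for luminal breast cancer: computes the
**IHC4-score** (from image-analysis ER / PR / KI67 percentages and HER2
Herceptest categories), the **clinical treatment score (C-score)** and the
**PREDICT (ER+) index**, classifies **luminal A-like / B-like** surrogate
subtypes, and compares the prognostic information of continuous scores
against categorical subtypes for 10-year breast-cancer-specific survival
(Cox models, per-SD hazard ratios, LRχ² / ΔLRχ² nested comparisons,
Kaplan–Meier + logrank suites, PH diagnostics, subtype-heterogeneity test).

Because no patient-level data from the motivating studies are public, the
package includes a first-class synthetic-cohort generator whose marker
distributions, clinical margins and event rates are calibrated to the
published cohort summaries, so every downstream stage is fully testable.

## Layout

- `src/ihc4pipe/scores.py` — score formulas, subtype rules, categorical
  transforms (standardization, mean+1SD dichotomization, quartiles)
- `src/ihc4pipe/synthetic_cohort.py` — calibrated scaled-beta marker
  generator, clinical-margin generator, Weibull proportional-hazards
  survival simulator, presets `overall` / `pbcs` / `search`
- `src/ihc4pipe/survival_models.py` — Cox fits (Efron ties, per-SD HRs),
  nested ΔLRχ², KM/logrank, PH check, heterogeneity test
- `src/ihc4pipe/pipeline.py` + `cli.py` — end-to-end orchestration,
  deterministic report directories, CLI
- `src/ihc4pipe/cohort_io.py` — validated CSV dialect (patient- or
  core-level; core files are averaged to patient level on read)

## CLI

```sh
ihc4pipe simulate --preset overall --n 2498 --seed 1 --out cohort.csv
ihc4pipe score    --cohort cohort.csv --out scored.csv
ihc4pipe analyze  --cohort cohort.csv --seed 1 --outdir report/
ihc4pipe analyze  --preset overall --seed 1 --outdir report/ --plots
ihc4pipe analyze  --preset overall --seed 1 --outdir sens/ --sensitivity
ihc4pipe report   --outdir report/
```

`analyze` writes `score_models.csv` (univariable / multivariable / subtype-specific
model matrix), `dichotomized_models.csv` (high vs low IHC4 within subtype), KM step tables
under `km/`, an exclusion log, and a `manifest.json` that echoes the config —
the whole directory is byte-identical across reruns with the same config and
seed. `--sensitivity` re-runs subtype analyses with the ≥1% ER/PR positivity
threshold and writes a 10%-vs-1% subtype cross-tabulation.

## Conventions (defaults, all configurable via `ScoreOptions`)

- KI67 enters `ln(1 + 10·KI67)` on the percent (0–100) scale.
- HER2 enters IHC4 as the averaged Herceptest ordinal (0–3); a clinical
  0/1 coding is available.
- ER/PR positivity for subtyping: clinical record status when present,
  else image % **> 10** (or **≥ 1** for the sensitivity convention).
- C-score: the 0.930 multiplier applies to the `0.497·T(1–2)` term as
  printed; a whole-bracket variant is available. The AI term and the
  PREDICT screen-detection term are fixed at 0 (data unavailable).
- Sample SDs use the n−1 denominator; times are administratively censored
  at 10 years; chemotherapy recipients are excluded from survival models.
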