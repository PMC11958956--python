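"""End-to-end analysis pipeline on a conforming cohort (synthetic by default).

Stages run in a fixed order -- exclusions, clocks, exposure preprocessing,
weighted descriptives, adjustment models 1-3 (continuous + quartile
exposures with trend tests), restricted-cubic-spline dose-response curves,
subgroup/interaction tables, two sensitivity analyses (covariate-adjusted
creatinine standardization; unweighted refit), WQS in both directions, and
BKMR summaries -- and emit delimited-text tables plus a machine-readable
manifest (seeds, row counts through the exclusion cascade, per-stage n).
Identical configuration and seed give a byte-identical report bundle.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import bkmr as bkmr_mod
from . import synthdata
from .clocks import fit_kdm, kdm_biological_age, phenoage_table
from .exposure import build_exposures
from .surveyreg import (
    COVARIATE_SETS,
    SurveyDesign,
    rcs_fit,
    design_matrix,
    run_model,
    subgroup_interaction,
    weighted_descriptives,
)
from .wqs import WQSConfig, run_both_directions

__all__ = ["RunConfig", "run"]

logger = logging.getLogger(__name__)

_VERSION = "0.1.0"

MANDATORY_COLUMNS = (
    ["age", "stratum", "psu", "weight", "urinary_creatinine"]
    + list(synthdata.KDM_BIOMARKERS)
    + [c for c in synthdata.PHENO_BIOMARKER_COLUMNS if c != "ph_lncrp"]
    + ["ph_crp"]
)


@dataclass
class RunConfig:
    """Configuration of one pipeline run."""

    outdir: str = "results"
    input_path: str | None = None          # CSV cohort; None -> simulate
    sim: synthdata.SimConfig = field(default_factory=synthdata.SimConfig)
    seed: int = 0
    analytes: tuple = synthdata.ANALYTES
    outcomes: tuple = synthdata.OUTCOMES
    min_age: float = 20.0
    stages: dict = field(default_factory=lambda: {
        "descriptives": True, "models": True, "rcs": True,
        "subgroups": True, "sensitivity": True, "wqs": True, "bkmr": True,
    })
    subgroup_modifiers: tuple = ("sex", "smoke")
    standardize_covariates: tuple = ("age", "sex", "race", "bmi_cat")
    wqs: WQSConfig = field(default_factory=lambda: WQSConfig(n_bootstrap=100))
    bkmr: bkmr_mod.BKMRConfig = field(
        default_factory=lambda: bkmr_mod.BKMRConfig(n_iterations=500, n_cap=300)
    )
    rcs_knots: int = 4
    weighted_quartiles: bool = True


def _check_columns(table: pd.DataFrame, analytes) -> None:
    needed = list(MANDATORY_COLUMNS)
    for a in analytes:
        needed += [f"{a}_conc", f"{a}_below_lod", f"{a}_lod"]
    missing = [c for c in needed if c not in table.columns]
    if missing:
        raise ValueError(f"input cohort is missing mandatory columns: {missing}")


def _exclusion_cascade(table: pd.DataFrame, config: RunConfig):
    """Complete-case exclusion steps with per-step counts."""
    steps = [("initial", np.ones(len(table), dtype=bool))]
    mask = table["age"].to_numpy(dtype=float) >= config.min_age
    steps.append((f"age>={config.min_age:g}", steps[-1][1] & mask))

    expo_cols = ["urinary_creatinine"] + [f"{a}_below_lod" for a in config.analytes]
    ok = ~table[expo_cols].isna().any(axis=1)
    for a in config.analytes:
        # measured value may be absent only when flagged below LOD
        ok &= table[f"{a}_conc"].notna() | (table[f"{a}_below_lod"] == 1)
    steps.append(("exposures_complete", steps[-1][1] & ok.to_numpy()))

    bio = list(synthdata.KDM_BIOMARKERS) + [
        c for c in synthdata.PHENO_BIOMARKER_COLUMNS if c != "ph_lncrp"
    ] + ["ph_crp"]
    ok = ~table[bio].isna().any(axis=1)
    steps.append(("biomarkers_complete", steps[-1][1] & ok.to_numpy()))

    covars = [c for c in COVARIATE_SETS["model3"] if c in table.columns]
    ok = ~table[covars].isna().any(axis=1)
    steps.append(("covariates_complete", steps[-1][1] & ok.to_numpy()))
    return steps


def run(config: RunConfig) -> dict:
    """Execute all enabled stages; returns a dict of written file paths."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: list[tuple[str, object]] = [
        ("package_version", _VERSION), ("seed", config.seed),
    ]
    paths: dict[str, Path] = {}

    def emit(name: str, frame: pd.DataFrame):
        path = outdir / f"{name}.csv"
        frame.to_csv(path, index=False)
        paths[name] = path
        logger.info("stage output %s (%d rows)", path, len(frame))

    # ---- input -----------------------------------------------------------
    if config.input_path is None:
        sim = replace(config.sim, seed=config.seed)
        table, truth = synthdata.generate_cohort(sim)
        synthdata.write_cohort(table, outdir / "cohort.csv", truth)
        paths["cohort"] = outdir / "cohort.csv"
        manifest.append(("input", "synthetic"))
    else:
        table = synthdata.read_cohort(config.input_path)
        manifest.append(("input", str(config.input_path)))
    _check_columns(table, config.analytes)

    # ---- exclusion cascade ----------------------------------------------
    steps = _exclusion_cascade(table, config)
    for name, mask in steps:
        manifest.append((f"n_after.{name}", int(mask.sum())))
    table = table.loc[steps[-1][1]].reset_index(drop=True)

    # ---- clocks ----------------------------------------------------------
    kdm_panel = table[list(synthdata.KDM_BIOMARKERS)]
    training = fit_kdm(kdm_panel, table["age"],
                       names=list(synthdata.KDM_BIOMARKERS))
    (outdir / "kdm_training.txt").write_text(training.to_text(),
                                             encoding="utf-8")
    paths["kdm_training"] = outdir / "kdm_training.txt"
    table["kdm_biological_age"] = kdm_biological_age(
        kdm_panel, table["age"], training)
    table = pd.concat(
        [table, phenoage_table(table)[["phenotypic_age"]]], axis=1)

    # ---- exposures -------------------------------------------------------
    table = build_exposures(
        table, config.analytes,
        standardize_covariates=list(config.standardize_covariates),
        weighted_quartiles=config.weighted_quartiles,
    )
    emit("analysis_table", table)
    design = SurveyDesign.from_table(table)
    manifest.append(("n_analysis", len(table)))
    manifest.append(("design_df", design.degrees_of_freedom()))

    # ---- descriptives ----------------------------------------------------
    if config.stages.get("descriptives", True):
        cont = (["age", "phenotypic_age", "kdm_biological_age",
                 "energy_kcal", "diet_score"]
                + [f"{a}_cc" for a in config.analytes])
        cat = [c for c in ("race", "pir", "bmi_cat", "marital", "education",
                           "home", "smoke", "drinks", "activity",
                           "hypertension", "dm", "cvd", "cancer", "cycle")
               if c in table.columns]
        emit("table1_descriptives",
             weighted_descriptives(table, cont, cat, design, by="sex"))

    # ---- models 1-3 ------------------------------------------------------
    if config.stages.get("models", True):
        rows = []
        for outcome in config.outcomes:
            for a in config.analytes:
                for cset in ("model1", "model2", "model3"):
                    for form, col in (("continuous", f"{a}_ln"),
                                      ("quartiles", f"{a}_q")):
                        fit = run_model(table, outcome, col, form, cset, design)
                        rows.append(fit.tidy())
        emit("table2_models", pd.concat(rows, ignore_index=True))

    # ---- restricted cubic splines ---------------------------------------
    if config.stages.get("rcs", True):
        curves, tests = [], []
        covars = design_matrix(table, COVARIATE_SETS["model3"],
                               add_const=False)
        for outcome in config.outcomes:
            for a in config.analytes:
                fit = rcs_fit(table[outcome], table[f"{a}_ln"], covars,
                              design, n_knots=config.rcs_knots)
                c = fit.curve.copy()
                c.insert(0, "outcome", outcome)
                c.insert(1, "exposure", a)
                curves.append(c)
                tests.append({"outcome": outcome, "exposure": a,
                              "p_overall": fit.p_overall,
                              "p_nonlinear": fit.p_nonlinear})
        emit("rcs_curves", pd.concat(curves, ignore_index=True))
        emit("rcs_tests", pd.DataFrame(tests))

    # ---- subgroups -------------------------------------------------------
    if config.stages.get("subgroups", True):
        rows = []
        for outcome in config.outcomes:
            for a in config.analytes:
                for mod in config.subgroup_modifiers:
                    res = subgroup_interaction(table, outcome, f"{a}_ln",
                                               "model3", mod, design)
                    t = res.table.copy()
                    t.insert(0, "outcome", outcome)
                    t.insert(1, "exposure", a)
                    t.insert(2, "modifier", mod)
                    t["p_interaction"] = res.p_interaction
                    rows.append(t)
        emit("subgroup_analysis", pd.concat(rows, ignore_index=True))

    # ---- sensitivity analyses -------------------------------------------
    if config.stages.get("sensitivity", True):
        rows = []
        for outcome in config.outcomes:
            for a in config.analytes:
                fit = run_model(table, outcome, f"{a}_std_ln", "continuous",
                                "model3", design)
                t = fit.tidy()
                t.insert(0, "analysis", "covariate_adjusted_creatinine")
                rows.append(t)
                unweighted = SurveyDesign(design.strata, design.psu,
                                          np.ones(len(table)),
                                          design.lonely_psu)
                fit = run_model(table, outcome, f"{a}_ln", "continuous",
                                "model3", unweighted)
                t = fit.tidy()
                t.insert(0, "analysis", "unweighted")
                rows.append(t)
        emit("sensitivity_models", pd.concat(rows, ignore_index=True))

    # ---- WQS -------------------------------------------------------------
    if config.stages.get("wqs", True):
        coefs, wrows = [], []
        exposures = [f"{a}_ln" for a in config.analytes]
        for outcome in config.outcomes:
            cfg = replace(config.wqs, seed=config.seed + 1)
            pos, neg = run_both_directions(table, outcome, exposures, cfg,
                                           design)
            for res in (pos, neg):
                coefs.append({
                    "outcome": outcome, "direction": res.direction,
                    "beta": res.beta, "se": res.se, "ci_low": res.ci_low,
                    "ci_high": res.ci_high, "p": res.pvalue,
                    "n_train": res.n_train, "n_test": res.n_test,
                })
                for name, w in res.weights.items():
                    wrows.append({"outcome": outcome,
                                  "direction": res.direction,
                                  "exposure": name.replace("_ln", ""),
                                  "weight": w})
        emit("wqs_coefficients", pd.DataFrame(coefs))
        emit("wqs_weights", pd.DataFrame(wrows))

    # ---- BKMR ------------------------------------------------------------
    if config.stages.get("bkmr", True):
        conpips, unis, overalls, singles = [], [], [], []
        covars = design_matrix(table, COVARIATE_SETS["model3"])
        for outcome in config.outcomes:
            cfg = replace(config.bkmr, seed=config.seed + 2)
            post = bkmr_mod.fit_bkmr(
                table[[f"{a}_ln" for a in config.analytes]],
                covars.to_numpy(dtype=float),
                table[outcome].to_numpy(dtype=float), cfg)
            pips = post.conpip
            for a in config.analytes:
                conpips.append({"outcome": outcome, "exposure": a,
                                "conpip": float(pips[f"{a}_ln"])})
            for a in config.analytes:
                u = bkmr_mod.univariate_response(post, f"{a}_ln",
                                                 seed=config.seed + 3)
                u.insert(0, "outcome", outcome)
                unis.append(u)
                s = bkmr_mod.single_exposure_effect(post, f"{a}_ln",
                                                    seed=config.seed + 4)
                s.insert(0, "outcome", outcome)
                singles.append(s)
            o = bkmr_mod.overall_effect(post, seed=config.seed + 5)
            o.insert(0, "outcome", outcome)
            overalls.append(o)
        emit("bkmr_conpip", pd.DataFrame(conpips))
        emit("bkmr_univariate", pd.concat(unis, ignore_index=True))
        emit("bkmr_overall_effect", pd.concat(overalls, ignore_index=True))
        emit("bkmr_single_exposure", pd.concat(singles, ignore_index=True))

    # ---- manifest --------------------------------------------------------
    for name, p in sorted(paths.items()):
        manifest.append((f"output.{name}", p.name))
    manifest_text = "\n".join(f"{k} = {v}" for k, v in manifest) + "\n"
    (outdir / "manifest.txt").write_text(manifest_text, encoding="utf-8")
    paths["manifest"] = outdir / "manifest.txt"
    return paths
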