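"""Synthetic survey-cohort generator with known ground truth.

Emulates the structure of a national examination-survey cohort so that every
downstream stage (clocks, exposure preprocessing, design-based regression,
mixture models) can be exercised against known parameters:

* ages uniform on a configurable range, with each clinical biomarker drawn
  as ``intercept + slope * age + Gaussian noise``;
* three urinary anions (perchlorate, nitrate, thiocyanate) drawn jointly
  log-normal with configurable positive correlation, multiplied by a
  simulated urinary-creatinine dilution factor to produce the measured
  concentration, then left-censored at a limit of detection (LOD);
* a stratified, clustered, unequal-weight sampling design (round-robin
  strata/PSUs, log-normal examination weights rescaled to sum to n);
* independent categorical covariates with configurable prevalences, with
  optional injectable confounding (covariate -> exposure and covariate ->
  outcome paths);
* configurable true exposure effects (years of aging outcome per ln-unit of
  creatinine-standardized analyte), injected by inverting the clock
  transforms onto one biomarker per clock so that downstream recomputation
  of the clocks reproduces ``biomarker-implied score + effect`` exactly
  (phenotypic age) or to first order (KDM).

All randomness flows through a single ``numpy`` generator seeded from
``SimConfig.seed``; identical configs give byte-identical tables.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .clocks import fit_kdm, load_phenoage_coefficients

__all__ = [
    "BiomarkerSpec",
    "AnalyteSpec",
    "ConfoundingSpec",
    "SimConfig",
    "GroundTruth",
    "generate_cohort",
    "apply_lod_censoring",
    "write_cohort",
    "read_cohort",
    "KDM_BIOMARKERS",
    "PHENO_BIOMARKER_COLUMNS",
    "ANALYTES",
    "OUTCOMES",
]

ANALYTES = ("perchlorate", "nitrate", "thiocyanate")
OUTCOMES = ("phenotypic_age", "kdm_biological_age")

# Biomarker columns feeding each clock.  The panels are generated as
# disjoint synthetic columns (kdm_* / ph_*) even though some real assays
# overlap; this keeps effect injection on one clock from leaking into the
# other.
KDM_BIOMARKERS = (
    "kdm_lncrp", "kdm_creatinine", "kdm_hba1c", "kdm_albumin",
    "kdm_totchol", "kdm_bun", "kdm_alp", "kdm_sbp",
)
PHENO_BIOMARKER_COLUMNS = (
    "ph_albumin", "ph_creatinine", "ph_glucose", "ph_lncrp",
    "ph_lymphpct", "ph_mcv", "ph_rdw", "ph_alp", "ph_wbc",
)


@dataclass(frozen=True)
class BiomarkerSpec:
    """Linear age trend of one biomarker: value = intercept + slope*age + N(0, sd)."""

    slope: float
    intercept: float
    sd: float


@dataclass(frozen=True)
class AnalyteSpec:
    """Log-normal urinary analyte.

    ``log_mean``/``log_sd`` parameterize the creatinine-standardized
    excretion (ug/g creatinine); the measured concentration (ug/L) is the
    excretion times the simulated creatinine in g/L, and ``lod`` applies on
    that concentration scale.
    """

    log_mean: float
    log_sd: float
    lod: float


@dataclass(frozen=True)
class ConfoundingSpec:
    """Inject covariate -> exposure and covariate -> outcome paths.

    Rows with ``covariate == level`` get each analyte's ln excretion shifted
    by ``exposure_ln_shift[analyte]`` and each outcome shifted additively by
    ``outcome_shift[outcome]`` years.
    """

    covariate: str
    level: str
    exposure_ln_shift: dict = field(default_factory=dict)
    outcome_shift: dict = field(default_factory=dict)


def _default_biomarkers() -> dict:
    # Plausible adult trends per year of age (units noted per panel).
    return {
        # KDM panel
        "kdm_lncrp": BiomarkerSpec(0.012, -1.8, 1.00),        # ln mg/dL
        "kdm_creatinine": BiomarkerSpec(0.002, 0.75, 0.18),   # mg/dL serum
        "kdm_hba1c": BiomarkerSpec(0.012, 5.0, 0.55),         # %
        "kdm_albumin": BiomarkerSpec(-0.004, 4.6, 0.30),      # g/dL
        "kdm_totchol": BiomarkerSpec(0.50, 160.0, 38.0),      # mg/dL
        "kdm_bun": BiomarkerSpec(0.10, 9.0, 4.0),             # mg/dL
        "kdm_alp": BiomarkerSpec(0.25, 55.0, 18.0),           # U/L
        "kdm_sbp": BiomarkerSpec(0.55, 95.0, 13.0),           # mmHg
        # Phenotypic-age panel (Levine units)
        "ph_albumin": BiomarkerSpec(-0.06, 48.0, 2.8),        # g/L
        "ph_creatinine": BiomarkerSpec(0.25, 60.0, 14.0),     # umol/L
        "ph_glucose": BiomarkerSpec(0.012, 4.6, 0.90),        # mmol/L
        "ph_lncrp": BiomarkerSpec(0.012, -2.0, 1.00),         # ln mg/dL
        "ph_lymphpct": BiomarkerSpec(-0.08, 36.0, 8.0),       # %
        "ph_mcv": BiomarkerSpec(0.035, 88.0, 4.5),            # fL
        "ph_rdw": BiomarkerSpec(0.008, 12.6, 0.90),           # %
        "ph_alp": BiomarkerSpec(0.25, 55.0, 18.0),            # U/L
        "ph_wbc": BiomarkerSpec(-0.002, 7.2, 1.8),            # 1000/uL
    }


def _default_analytes() -> dict:
    # Medians in the ballpark of U.S. adult urinary levels; LODs at the
    # laboratory values for these assays (detection ~100%).
    return {
        "perchlorate": AnalyteSpec(np.log(3.5), 0.90, 0.05),
        "nitrate": AnalyteSpec(np.log(44000.0), 0.65, 700.0),
        "thiocyanate": AnalyteSpec(np.log(1400.0), 1.00, 20.0),
    }


def _default_correlation() -> np.ndarray:
    # Positive pairwise association of the three anions on the ln scale.
    c = np.full((3, 3), 0.37)
    np.fill_diagonal(c, 1.0)
    return c


def _default_prevalences() -> dict:
    return {
        "sex": {"Female": 0.52, "Male": 0.48},
        "race": {"NH White": 0.45, "NH Black": 0.21, "Mexican American": 0.18,
                 "Other": 0.16},
        "pir": {"Low": 0.25, "Middle": 0.38, "High": 0.37},
        "bmi_cat": {"Normal": 0.31, "Overweight": 0.34, "Obese": 0.35},
        "marital": {"Never married": 0.18, "Married/partner": 0.60,
                    "Widowed/Div/Sep": 0.22},
        "education": {"College or more": 0.50, "High school": 0.38,
                      "Middle school or lower": 0.12},
        "home": {"Owned": 0.65, "Rented": 0.35},
        "smoke": {"Never": 0.52, "Former": 0.25, "Now": 0.23},
        "drinks": {"Nondrinker": 0.29, "Moderate": 0.55, "Heavy": 0.16},
        "activity": {"Active": 0.37, "Inactive": 0.27, "Moderate": 0.14,
                     "Others": 0.22},
        "cycle": {"2005-2006": 0.34, "2007-2008": 0.33, "2009-2010": 0.33},
    }


@dataclass
class SimConfig:
    """Full specification of one synthetic cohort."""

    n_participants: int = 2000
    n_strata: int = 45           # ~ three 2-year survey cycles of 15 strata
    psus_per_stratum: int = 2
    seed: int = 0
    age_range: tuple = (20.0, 80.0)
    biomarker_specs: dict = field(default_factory=_default_biomarkers)
    analyte_specs: dict = field(default_factory=_default_analytes)
    analyte_log_correlation: np.ndarray = field(default_factory=_default_correlation)
    # analyte -> outcome -> years of outcome per ln-unit of exposure
    exposure_effects: dict = field(
        default_factory=lambda: {a: {o: 0.0 for o in OUTCOMES} for a in ANALYTES}
    )
    weight_dispersion: float = 0.5
    creatinine_log_mean: float = float(np.log(110.0))  # mg/dL
    creatinine_log_sd: float = 0.60
    # optional covariate-dependence of ln creatinine, e.g.
    # {"sex=Male": 0.30, "age": -0.004} (age term is per year, centered at 50)
    creatinine_covariate_effects: dict = field(default_factory=dict)
    categorical_prevalences: dict = field(default_factory=_default_prevalences)
    binary_prevalences: dict = field(
        default_factory=lambda: {"hypertension": 0.36, "dm": 0.13,
                                 "cvd": 0.08, "cancer": 0.09}
    )
    confounding: list = field(default_factory=list)

    def validate(self) -> None:
        if self.n_participants < 1:
            raise ValueError("n_participants must be positive")
        if self.n_strata < 1:
            raise ValueError("n_strata must be positive")
        if self.psus_per_stratum < 2:
            raise ValueError(
                "psus_per_stratum must be >= 2 (Taylor variance is undefined "
                "for single-PSU strata)"
            )
        if self.n_participants < self.n_strata * self.psus_per_stratum:
            raise ValueError(
                "n_participants too small to fill every stratum with "
                f"{self.psus_per_stratum} PSUs"
            )
        lo, hi = self.age_range
        if not hi > lo:
            raise ValueError("age_range must be (min, max) with max > min")
        if self.weight_dispersion < 0:
            raise ValueError("weight_dispersion must be nonnegative")
        for name, spec in self.biomarker_specs.items():
            if spec.sd <= 0:
                raise ValueError(f"residual SD for biomarker {name!r} must be > 0")
        for name, spec in self.analyte_specs.items():
            if spec.lod <= 0:
                raise ValueError(f"LOD for analyte {name!r} must be > 0")
            if spec.log_sd <= 0:
                raise ValueError(f"log-SD for analyte {name!r} must be > 0")
        C = np.asarray(self.analyte_log_correlation, dtype=float)
        k = len(self.analyte_specs)
        if C.shape != (k, k):
            raise ValueError(
                f"analyte_log_correlation must be {k}x{k}, got {C.shape}"
            )
        if not np.allclose(C, C.T, atol=1e-12):
            raise ValueError("analyte_log_correlation is not symmetric")
        if not np.allclose(np.diag(C), 1.0, atol=1e-12):
            raise ValueError("analyte_log_correlation must have unit diagonal")
        try:
            np.linalg.cholesky(C)
        except np.linalg.LinAlgError:
            raise ValueError(
                "analyte_log_correlation is not positive definite"
            ) from None


@dataclass
class GroundTruth:
    """Realized generator parameters, serialized alongside every cohort."""

    seed: int
    exposure_effects: dict       # analyte -> outcome -> float
    biomarker_slopes: dict       # name -> float
    biomarker_intercepts: dict
    biomarker_sds: dict
    analyte_log_means: dict
    analyte_log_sds: dict
    analyte_lods: dict
    mixture_weights: dict        # outcome -> analyte -> |effect| normalized
    weight_dispersion: float

    def to_text(self) -> str:
        lines = ["# ground truth for a synthetic cohort",
                 f"seed = {self.seed}",
                 f"weight_dispersion = {self.weight_dispersion!r}"]
        for a, d in sorted(self.exposure_effects.items()):
            for o, v in sorted(d.items()):
                lines.append(f"effect.{a}.{o} = {float(v)!r}")
        for prefix, dct in (
            ("slope", self.biomarker_slopes),
            ("intercept", self.biomarker_intercepts),
            ("sd", self.biomarker_sds),
            ("log_mean", self.analyte_log_means),
            ("log_sd", self.analyte_log_sds),
            ("lod", self.analyte_lods),
        ):
            for k, v in sorted(dct.items()):
                lines.append(f"{prefix}.{k} = {float(v)!r}")
        for o, d in sorted(self.mixture_weights.items()):
            for a, v in sorted(d.items()):
                lines.append(f"mixture_weight.{o}.{a} = {float(v)!r}")
        return "\n".join(lines) + "\n"

    @classmethod
    def from_text(cls, text: str) -> "GroundTruth":
        flat: dict[str, str] = {}
        for line in text.splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            k, _, v = line.partition("=")
            flat[k.strip()] = v.strip()
        effects: dict = {}
        mixture: dict = {}
        groups: dict[str, dict] = {p: {} for p in
                                   ("slope", "intercept", "sd", "log_mean",
                                    "log_sd", "lod")}
        for key, val in flat.items():
            if key.startswith("effect."):
                _, a, o = key.split(".", 2)
                effects.setdefault(a, {})[o] = float(val)
            elif key.startswith("mixture_weight."):
                _, o, a = key.split(".", 2)
                mixture.setdefault(o, {})[a] = float(val)
            else:
                prefix, _, rest = key.partition(".")
                if prefix in groups:
                    groups[prefix][rest] = float(val)
        return cls(
            seed=int(flat["seed"]),
            exposure_effects=effects,
            biomarker_slopes=groups["slope"],
            biomarker_intercepts=groups["intercept"],
            biomarker_sds=groups["sd"],
            analyte_log_means=groups["log_mean"],
            analyte_log_sds=groups["log_sd"],
            analyte_lods=groups["lod"],
            mixture_weights=mixture,
            weight_dispersion=float(flat["weight_dispersion"]),
        )


def apply_lod_censoring(values, lod: float):
    """Left-censor a concentration vector at a limit of detection.

    Values >= ``lod`` pass through with flag ``False``; values below are
    withheld (NaN) with flag ``True``.  Imputation is the exposure module's
    job, not the generator's.
    """
    if not lod > 0:
        raise ValueError(f"LOD must be positive, got {lod}")
    values = np.asarray(values, dtype=float)
    flags = values < lod
    censored = values.copy()
    censored[flags] = np.nan
    return censored, flags


def _draw_categorical(rng, levels_probs: dict, n: int) -> np.ndarray:
    levels = list(levels_probs)
    p = np.array([levels_probs[l] for l in levels], dtype=float)
    p = p / p.sum()
    return rng.choice(levels, size=n, p=p)


def generate_cohort(config: SimConfig):
    """Generate one synthetic cohort; returns ``(table, ground_truth)``."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_participants
    analytes = list(config.analyte_specs)

    lo, hi = config.age_range
    age = rng.uniform(lo, hi, size=n)

    # clinical biomarkers: linear age trend + Gaussian noise
    biomarkers = {}
    for name, spec in config.biomarker_specs.items():
        biomarkers[name] = spec.intercept + spec.slope * age + rng.normal(
            0.0, spec.sd, size=n
        )

    # covariates: independent categoricals / binaries
    covars = {}
    for name, probs in config.categorical_prevalences.items():
        covars[name] = _draw_categorical(rng, probs, n)
    for name, p in config.binary_prevalences.items():
        covars[name] = (rng.uniform(size=n) < p).astype(int)
    energy = np.clip(rng.normal(2050.0, 600.0, size=n), 600.0, None)
    diet = np.clip(rng.normal(51.5, 12.0, size=n), 0.0, 100.0)

    # correlated ln excretions (ug/g creatinine scale)
    C = np.asarray(config.analyte_log_correlation, dtype=float)
    L = np.linalg.cholesky(C)
    z = rng.standard_normal((n, len(analytes))) @ L.T
    ln_excretion = np.column_stack(
        [config.analyte_specs[a].log_mean + config.analyte_specs[a].log_sd * z[:, j]
         for j, a in enumerate(analytes)]
    )

    # confounding: covariate -> exposure shifts
    conf_delta = {o: np.zeros(n) for o in OUTCOMES}
    for spec in config.confounding:
        mask = np.asarray(covars[spec.covariate]) == spec.level
        for j, a in enumerate(analytes):
            shift = spec.exposure_ln_shift.get(a, 0.0)
            if shift:
                ln_excretion[mask, j] += shift
        for o, shift in spec.outcome_shift.items():
            conf_delta[o][mask] += shift

    # urinary creatinine (mg/dL): a random dilution component plus optional
    # covariate effects (muscle-mass-like determinants).  Only the dilution
    # component concentrates the analytes; the covariate part raises measured
    # creatinine without touching exposure, so the plain ratio correction
    # over-adjusts exactly when those effects are switched on.
    ln_dilution = config.creatinine_log_mean + rng.normal(
        0.0, config.creatinine_log_sd, size=n
    )
    ln_creat = ln_dilution.copy()
    for key, eff in config.creatinine_covariate_effects.items():
        if key == "age":
            ln_creat += eff * (age - 50.0)
        else:
            cov, _, level = key.partition("=")
            ln_creat += eff * (np.asarray(covars[cov]) == level)
    creatinine = np.exp(ln_creat)

    # measured concentration = excretion (ug/g) * dilution creatinine (g/L);
    # with no covariate effects the ratio correction recovers the excretion
    # exactly
    conc = np.exp(ln_excretion) * (np.exp(ln_dilution)[:, None] * 0.01)

    # sampling design: round-robin strata/PSUs, log-normal weights
    idx = np.arange(n)
    stratum = idx % config.n_strata + 1
    psu = (idx // config.n_strata) % config.psus_per_stratum + 1
    if config.weight_dispersion > 0:
        w = rng.lognormal(0.0, config.weight_dispersion, size=n)
    else:
        w = np.ones(n)
    weight = w * (n / w.sum())

    # true injected effects on the aging outcomes (years), from the
    # centered ln excretion
    delta = {o: conf_delta[o].copy() for o in OUTCOMES}
    for j, a in enumerate(analytes):
        eff = config.exposure_effects.get(a, {})
        centered = ln_excretion[:, j] - config.analyte_specs[a].log_mean
        for o in OUTCOMES:
            beta = eff.get(o, 0.0)
            if beta:
                delta[o] += beta * centered

    # inject onto one biomarker per clock by inverting the clock transform
    if np.any(delta["phenotypic_age"] != 0.0):
        coeffs = load_phenoage_coefficients()
        # phenotypic age is affine in xb with slope 1/pa_c3, and xb is
        # linear in RDW; the inversion is therefore exact
        biomarkers["ph_rdw"] = biomarkers["ph_rdw"] + (
            delta["phenotypic_age"] * coeffs.pa_c3 / coeffs.terms["rdw"]
        )
    if np.any(delta["kdm_biological_age"] != 0.0):
        panel = np.column_stack([biomarkers[b] for b in KDM_BIOMARKERS])
        training = fit_kdm(panel, age, names=list(KDM_BIOMARKERS))
        j_sbp = list(KDM_BIOMARKERS).index("kdm_sbp")
        denom = float(
            (training.k**2 / training.s**2).sum() + 1.0 / training.s_ba2
        )
        scale = denom * training.s[j_sbp] ** 2 / training.k[j_sbp]
        biomarkers["kdm_sbp"] = biomarkers["kdm_sbp"] + (
            delta["kdm_biological_age"] * scale
        )

    data = {"participant_id": idx + 1, "age": age}
    data.update(covars)
    data["energy_kcal"] = energy
    data["diet_score"] = diet
    data["stratum"] = stratum
    data["psu"] = psu
    data["weight"] = weight
    data["urinary_creatinine"] = creatinine
    for name in config.biomarker_specs:
        data[name] = biomarkers[name]
    # phenotypic-age scoring reads CRP on the concentration scale
    if "ph_lncrp" in biomarkers:
        data["ph_crp"] = np.exp(biomarkers["ph_lncrp"])
    for j, a in enumerate(analytes):
        censored, flags = apply_lod_censoring(conc[:, j], config.analyte_specs[a].lod)
        data[f"{a}_conc"] = censored
        data[f"{a}_below_lod"] = flags.astype(int)
        data[f"{a}_lod"] = np.full(n, config.analyte_specs[a].lod)
    table = pd.DataFrame(data)

    abs_effects = {
        o: {a: abs(config.exposure_effects.get(a, {}).get(o, 0.0)) for a in analytes}
        for o in OUTCOMES
    }
    mixture = {}
    for o, d in abs_effects.items():
        total = sum(d.values())
        mixture[o] = {a: (v / total if total > 0 else 0.0) for a, v in d.items()}
    truth = GroundTruth(
        seed=config.seed,
        exposure_effects={
            a: {o: config.exposure_effects.get(a, {}).get(o, 0.0) for o in OUTCOMES}
            for a in analytes
        },
        biomarker_slopes={k: v.slope for k, v in config.biomarker_specs.items()},
        biomarker_intercepts={k: v.intercept for k, v in config.biomarker_specs.items()},
        biomarker_sds={k: v.sd for k, v in config.biomarker_specs.items()},
        analyte_log_means={k: v.log_mean for k, v in config.analyte_specs.items()},
        analyte_log_sds={k: v.log_sd for k, v in config.analyte_specs.items()},
        analyte_lods={k: v.lod for k, v in config.analyte_specs.items()},
        mixture_weights=mixture,
        weight_dispersion=config.weight_dispersion,
    )
    return table, truth


def write_cohort(table: pd.DataFrame, path, truth: GroundTruth | None = None) -> None:
    """Write a cohort as UTF-8 comma-separated text (plus a truth sidecar)."""
    table.to_csv(path, index=False)
    if truth is not None:
        sidecar = str(path).rsplit(".", 1)[0] + "_truth.txt"
        with open(sidecar, "w", encoding="utf-8") as fh:
            fh.write(truth.to_text())


def read_cohort(path) -> pd.DataFrame:
    return pd.read_csv(path)
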