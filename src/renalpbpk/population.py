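"""Virtual population generation for Chinese renal-impairment PBPK modelling.

Chronic kidney disease (CKD) populations are generated from recalibrated
demographic and physiological covariate equations: a quadratic height-versus-age
polynomial per sex, an exponential weight-versus-height relation, age-banded
lognormal serum creatinine, and lognormal hematocrit / alpha-1-acid glycoprotein
(AGP) with an age-dependent human serum albumin (HSA) relation.  Glomerular
filtration rate (GFR) is obtained from serum creatinine with the
Cockcroft-Gault equation and normalised to 1.73 m^2 body surface area (BSA,
DuBois-DuBois); subjects are accepted only if their normalised GFR falls inside
the band that defines their renal-function category (mild 60-89, moderate
30-59, severe 15-29 mL/min/1.73 m^2).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Callable, Literal, Optional, Sequence

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, model_validator

__all__ = [
    "MG_DL_PER_UMOL_L",
    "UMOL_L_PER_MG_DL",
    "ConfigurationError",
    "ScrBand",
    "SexParameters",
    "PopulationParameters",
    "VirtualSubject",
    "CovariateValidationReport",
    "sample_age",
    "height_from_age",
    "weight_from_height",
    "sample_serum_creatinine",
    "bsa_dubois",
    "gfr_cockcroft_gault",
    "sample_blood_params",
    "kidney_volume",
    "generate_population",
    "derive_caucasian_mild",
    "validate_population",
    "subjects_to_frame",
]

#: serum creatinine unit conversion: 1 mg/dL = 88.42 umol/L
UMOL_L_PER_MG_DL = 88.42
MG_DL_PER_UMOL_L = 1.0 / UMOL_L_PER_MG_DL

#: normalised-GFR bands (mL/min/1.73 m^2) defining the renal categories.
#: The healthy band's upper edge is a generator-side cap, not a clinical
#: definition; healthy is conventionally ">= 90".
GFR_BANDS = {
    "healthy": (90.0, 160.0),
    "mild": (60.0, 89.0),
    "moderate": (30.0, 59.0),
    "severe": (15.0, 29.0),
}

Category = Literal["healthy", "mild", "moderate", "severe"]
Sex = Literal["male", "female"]


class ConfigurationError(ValueError):
    """A population parameter set is internally inconsistent or incomplete."""


class ScrBand(BaseModel):
    """One age band of the serum-creatinine distribution (umol/L, CV fraction)."""

    age_min: float
    age_max: float
    mean: float = Field(gt=0)
    cv: float = Field(gt=0, lt=1)


class SexParameters(BaseModel):
    """Per-sex covariate model coefficients."""

    age_range: tuple[float, float]
    height_age_coeffs: tuple[float, float, float]  # cm: c0 + c1*age + c2*age^2
    height_residual_sd: float = Field(ge=0)  # cm
    weight_height_coeffs: tuple[float, float]  # kg: exp(a + b*height_cm)
    scr_bands: list[ScrBand]
    hematocrit: tuple[float, float]  # (mean %, CV fraction)
    agp: tuple[float, float]  # (mean g/L, CV fraction)
    hsa_coeffs: tuple[float, float, float]  # g/L, age relation

    @model_validator(mode="after")
    def _check(self) -> "SexParameters":
        lo, hi = self.age_range
        if not (18 <= lo <= hi):
            raise ValueError(f"age range [{lo}, {hi}] must be adult and ordered")
        bands = sorted(self.scr_bands, key=lambda b: b.age_min)
        if not bands:
            raise ValueError("at least one serum-creatinine band is required")
        if bands[0].age_min > lo or bands[-1].age_max < hi:
            raise ValueError("serum-creatinine bands do not cover the age range")
        for a, b in zip(bands, bands[1:]):
            if a.age_max != b.age_min:
                raise ValueError(
                    f"serum-creatinine bands overlap or leave a gap at age {a.age_max}"
                )
        for pair in (self.hematocrit, self.agp):
            if pair[0] <= 0 or not (0 < pair[1] < 1):
                raise ValueError("blood parameter means must be > 0 with CV in (0,1)")
        return self


class PopulationParameters(BaseModel):
    """System (population) model: the per-category, per-sex coefficient set."""

    category: Category
    sex_ratio_f: float = Field(ge=0.0, le=1.0)  # females / total
    male: SexParameters
    female: SexParameters
    kidney_volume_coeffs: tuple[float, float, float]  # mL: base + bw*BW_kg + bh*BH_m
    kidney_density_g_L: float = 1050.0
    gfr_band: Optional[tuple[float, float]] = None  # mL/min/1.73 m^2
    hsa_form: Literal["quadratic_decade", "quadratic"] = "quadratic_decade"
    scr_scale_applied: Optional[float] = None  # provenance of derive_caucasian_mild
    name: str = ""
    provenance: str = ""

    def sex_params(self, sex: Sex) -> SexParameters:
        return self.male if sex == "male" else self.female

    @property
    def band(self) -> tuple[float, float]:
        return self.gfr_band if self.gfr_band is not None else GFR_BANDS[self.category]


@dataclass
class VirtualSubject:
    """One sampled individual."""

    id: int
    sex: Sex
    age: float  # years
    height: float  # cm
    weight: float  # kg
    scr_umol_L: float
    scr_mg_dL: float
    bsa: float  # m^2
    gfr_abs: float  # mL/min
    gfr_norm: float  # mL/min/1.73 m^2
    hematocrit: float  # fraction
    agp: float  # g/L
    hsa: float  # g/L
    kidney_volume: float  # mL
    renal_category: Category


@dataclass
class CovariateValidationReport:
    """Age-binned simulated envelopes and observed-point coverage per covariate."""

    envelopes: dict[str, pd.DataFrame]
    coverage: dict[str, float]  # NaN when no observed points for the covariate
    n_observed: dict[str, int]


# ---------------------------------------------------------------------------
# elementary covariate operations
# ---------------------------------------------------------------------------

def sample_age(
    params: PopulationParameters,
    sex: Sex,
    rng: np.random.Generator,
    age_dist: Optional[Callable[[np.random.Generator], float]] = None,
) -> float:
    """Sample an age (years), uniform over the category age range by default.

    ``age_dist`` may supply an empirical distribution (callable taking the RNG);
    the returned value must still fall inside the configured range.
    """
    lo, hi = params.sex_params(sex).age_range
    if hi < lo:
        raise ConfigurationError(f"empty age range [{lo}, {hi}]")
    if age_dist is not None:
        age = float(age_dist(rng))
        if not (lo <= age <= hi):
            raise ConfigurationError(
                f"empirical age {age} outside configured range [{lo}, {hi}]"
            )
        return age
    if lo == hi:
        return float(lo)
    return float(rng.uniform(lo, hi))


def height_from_age(
    age: float,
    sex: Sex,
    params: PopulationParameters,
    rng: Optional[np.random.Generator] = None,
    residual_sd: Optional[float] = None,
    max_retries: int = 100,
) -> float:
    """Body height (cm) from the per-sex quadratic age polynomial.

    A zero-mean Gaussian residual (SD defaulting to the category/sex height SD)
    is added when an RNG is given; draws outside the physiological range
    [130, 210] cm are redrawn (bounded retries).
    """
    sp = params.sex_params(sex)
    c0, c1, c2 = sp.height_age_coeffs
    mean = c0 + c1 * age + c2 * age * age
    sd = sp.height_residual_sd if residual_sd is None else residual_sd
    if rng is None or sd == 0:
        if mean <= 0:
            raise ConfigurationError(f"non-positive height {mean} at age {age}")
        return float(mean)
    for _ in range(max_retries):
        h = mean + rng.normal(0.0, sd)
        if 130.0 <= h <= 210.0:
            return float(h)
    raise ConfigurationError(
        f"could not draw a height in [130, 210] cm around mean {mean:.1f}"
    )


def weight_from_height(
    height_cm: float,
    sex: Sex,
    params: PopulationParameters,
    rng: Optional[np.random.Generator] = None,
    residual_cv: float = 0.0,
) -> float:
    """Body weight (kg) from the exponential weight-height relation.

    BW = exp(a + b * BH_cm).  An optional lognormal residual (CV fraction) is
    off by default: weight inherits its variability through height.
    """
    if height_cm <= 0:
        raise ValueError("height must be positive")
    a, b = params.sex_params(sex).weight_height_coeffs
    bw = math.exp(a + b * height_cm)
    if rng is not None and residual_cv > 0:
        sigma = math.sqrt(math.log1p(residual_cv**2))
        bw *= float(rng.lognormal(-0.5 * sigma * sigma, sigma))
    return float(bw)


def _lognormal_from_mean_cv(
    mean: float, cv: float, rng: np.random.Generator
) -> float:
    """Draw from a lognormal with the given arithmetic mean and CV."""
    if cv <= 0:
        return float(mean)
    sigma2 = math.log1p(cv * cv)
    mu = math.log(mean) - 0.5 * sigma2
    return float(rng.lognormal(mu, math.sqrt(sigma2)))


def _find_scr_band(sp: SexParameters, age: float) -> ScrBand:
    bands = sorted(sp.scr_bands, key=lambda b: b.age_min)
    for band in bands:
        if band.age_min <= age < band.age_max:
            return band
    if bands and age == bands[-1].age_max:
        return bands[-1]
    covered = ", ".join(f"[{b.age_min}, {b.age_max})" for b in bands)
    raise ConfigurationError(
        f"no serum-creatinine band covers age {age}; bands cover {covered}"
    )


def sample_serum_creatinine(
    age: float, sex: Sex, params: PopulationParameters, rng: np.random.Generator
) -> float:
    """Serum creatinine (umol/L): lognormal draw from the covering age band."""
    band = _find_scr_band(params.sex_params(sex), age)
    return _lognormal_from_mean_cv(band.mean, band.cv, rng)


def bsa_dubois(weight_kg: float, height_cm: float) -> float:
    """Body surface area (m^2), DuBois-DuBois: 0.007184 * BW^0.425 * BH^0.725."""
    if weight_kg <= 0 or height_cm <= 0:
        raise ValueError("weight and height must be positive")
    return 0.007184 * weight_kg**0.425 * height_cm**0.725


def gfr_cockcroft_gault(
    age: float, weight_kg: float, scr_mg_dL: float, sex: Sex, bsa: float
) -> tuple[float, float]:
    """Cockcroft-Gault creatinine clearance as a GFR estimate.

    Returns ``(gfr_abs mL/min, gfr_norm mL/min/1.73 m^2)`` where
    CLcr = (140 - age) * BW / (72 * Scr), multiplied by 0.85 for females, and
    gfr_norm = CLcr * 1.73 / BSA.
    """
    if age >= 140:
        raise ValueError("Cockcroft-Gault is undefined for age >= 140")
    if scr_mg_dL <= 0:
        raise ValueError("serum creatinine must be positive")
    clcr = (140.0 - age) * weight_kg / (72.0 * scr_mg_dL)
    if sex == "female":
        clcr *= 0.85
    return float(clcr), float(clcr * 1.73 / bsa)


def _hsa_from_age(
    coeffs: tuple[float, float, float], age: float, form: str
) -> float:
    c0, c1, c2 = coeffs
    if form == "quadratic_decade":
        return c0 + c1 * age + c2 * (age / 10.0) ** 2
    if form == "quadratic":
        return c0 + c1 * age + c2 * age * age
    raise ConfigurationError(f"unknown HSA age-relation form {form!r}")


def sample_blood_params(
    age: float, sex: Sex, params: PopulationParameters, rng: np.random.Generator
) -> tuple[float, float, float]:
    """Sample (hematocrit fraction, AGP g/L, HSA g/L) for one subject.

    Hematocrit and AGP are lognormal with the configured arithmetic mean / CV;
    HSA is a deterministic function of age (the configured quadratic form, with
    the coefficients taken verbatim from the parameter file).
    """
    sp = params.sex_params(sex)
    hct = _lognormal_from_mean_cv(sp.hematocrit[0], sp.hematocrit[1], rng) / 100.0
    agp = _lognormal_from_mean_cv(sp.agp[0], sp.agp[1], rng)
    hsa = _hsa_from_age(sp.hsa_coeffs, age, params.hsa_form)
    return float(hct), float(agp), float(hsa)


def kidney_volume(
    weight_kg: float, height_cm: float, params: PopulationParameters
) -> float:
    """Total kidney volume (mL): baseline + bw_coeff*BW(kg) + bh_coeff*BH(m)."""
    base, cbw, cbh = params.kidney_volume_coeffs
    vol = base + cbw * weight_kg + cbh * (height_cm / 100.0)
    if vol <= 0:
        raise ValueError(f"non-positive kidney volume {vol:.1f} mL")
    return float(vol)


# ---------------------------------------------------------------------------
# population generation
# ---------------------------------------------------------------------------

def _sample_subject(
    idx: int,
    params: PopulationParameters,
    sex_ratio_f: float,
    rng: np.random.Generator,
    age_dist: Optional[Callable[[np.random.Generator], float]],
    max_scr_retries: int,
    max_subject_retries: int,
) -> tuple[VirtualSubject, int, int]:
    """Rejection-sample a single subject into the category's GFR band.

    Returns the subject plus (accepted, attempted) creatinine draw counts so
    the caller can police the overall acceptance rate.
    """
    lo, hi = params.band
    sex: Sex = "female" if rng.uniform() < sex_ratio_f else "male"
    attempted = 0
    for _ in range(max_subject_retries):
        age = sample_age(params, sex, rng, age_dist)
        height = height_from_age(age, sex, params, rng)
        weight = weight_from_height(height, sex, params)
        bsa = bsa_dubois(weight, height)
        for _ in range(max_scr_retries):
            attempted += 1
            scr = sample_serum_creatinine(age, sex, params, rng)
            scr_mgdl = scr * MG_DL_PER_UMOL_L
            gfr_abs, gfr_norm = gfr_cockcroft_gault(age, weight, scr_mgdl, sex, bsa)
            if lo <= gfr_norm <= hi:
                hct, agp, hsa = sample_blood_params(age, sex, params, rng)
                kv = kidney_volume(weight, height, params)
                return (
                    VirtualSubject(
                        id=idx,
                        sex=sex,
                        age=age,
                        height=height,
                        weight=weight,
                        scr_umol_L=scr,
                        scr_mg_dL=scr_mgdl,
                        bsa=bsa,
                        gfr_abs=gfr_abs,
                        gfr_norm=gfr_norm,
                        hematocrit=hct,
                        agp=agp,
                        hsa=hsa,
                        kidney_volume=kv,
                        renal_category=params.category,
                    ),
                    1,
                    attempted,
                )
    raise ConfigurationError(
        f"subject {idx} ({sex}, category {params.category}): could not reach the "
        f"GFR band [{lo}, {hi}] mL/min/1.73 m^2 after {max_subject_retries} "
        "age resamples; the covariate and creatinine parameters are likely "
        "inconsistent with the band"
    )


def generate_population(
    params: PopulationParameters,
    n: int,
    sex_ratio_override: Optional[float] = None,
    seed: int = 0,
    age_dist: Optional[Callable[[np.random.Generator], float]] = None,
    max_scr_retries: int = 100,
    max_subject_retries: int = 100,
) -> list[VirtualSubject]:
    """Generate ``n`` virtual subjects of the parameter set's renal category.

    Each subject draws from an independent child stream of ``seed`` keyed by
    subject index, so populations are reproducible and order-independent.
    Serum creatinine is rejection-sampled until the Cockcroft-Gault normalised
    GFR falls inside the category band (bounded retries, then the age is also
    resampled).  An overall creatinine acceptance rate below 1% aborts with a
    configuration error.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    ratio = params.sex_ratio_f if sex_ratio_override is None else sex_ratio_override
    if not (0.0 <= ratio <= 1.0):
        raise ValueError("sex ratio must lie in [0, 1]")
    streams = np.random.SeedSequence(seed).spawn(n)
    subjects: list[VirtualSubject] = []
    accepted = 0
    attempted = 0
    for i, ss in enumerate(streams):
        subj, acc, att = _sample_subject(
            i, params, ratio, np.random.default_rng(ss), age_dist,
            max_scr_retries, max_subject_retries,
        )
        subjects.append(subj)
        accepted += acc
        attempted += att
        if attempted >= 1000 and accepted / attempted < 0.01:
            raise ConfigurationError(
                f"creatinine acceptance rate {accepted / attempted:.2%} < 1%; "
                "covariate equations and GFR band appear inconsistent"
            )
    return subjects


def derive_caucasian_mild(healthy_params: PopulationParameters) -> PopulationParameters:
    """Build a Caucasian mild renal-impairment model from a healthy model.

    Every serum-creatinine band mean is multiplied by 1.5 (the mild GFR cutoff,
    60, is ~1.5-fold below the healthy 90 mL/min/1.73 m^2); CVs and all other
    demographic and physiological parameters are untouched.  A provenance flag
    records the applied scale so that a second application (yielding x2.25) is
    visible rather than silent.
    """
    if healthy_params.scr_scale_applied is not None:
        warnings.warn(
            "serum-creatinine scaling applied to an already-scaled parameter set; "
            f"cumulative scale is {healthy_params.scr_scale_applied * 1.5:g}",
            stacklevel=2,
        )
    derived = healthy_params.model_copy(deep=True)
    for sp in (derived.male, derived.female):
        for band in sp.scr_bands:
            band.mean *= 1.5
    derived.category = "mild"
    derived.gfr_band = GFR_BANDS["mild"]
    derived.scr_scale_applied = (healthy_params.scr_scale_applied or 1.0) * 1.5
    derived.name = (healthy_params.name or "healthy") + "-derived-mild"
    return derived


# ---------------------------------------------------------------------------
# tabulation and internal validation
# ---------------------------------------------------------------------------

_COVARIATE_GETTERS = {
    "height": lambda s: s.height,
    "weight": lambda s: s.weight,
    "scr": lambda s: s.scr_umol_L,
    "gfr": lambda s: s.gfr_norm,
}


def subjects_to_frame(subjects: Sequence[VirtualSubject]) -> pd.DataFrame:
    """Subject list as a DataFrame, one row per subject."""
    return pd.DataFrame([vars(s) for s in subjects])


def validate_population(
    subjects: Sequence[VirtualSubject],
    observed_table: pd.DataFrame,
    covariates: Sequence[str] = ("height", "weight", "scr", "gfr"),
    age_bin_width: float = 10.0,
) -> CovariateValidationReport:
    """Compare observed covariate points against simulated 90% envelopes.

    ``observed_table`` needs columns ``(age, sex, variable, value)``; variables
    must be among height (cm), weight (kg), scr (umol/L), gfr
    (mL/min/1.73 m^2).  For each covariate an age-binned 5th-95th percentile
    envelope (per sex) is computed from the simulated subjects, and the
    fraction of observed points falling inside the envelope of their (sex, age)
    bin is reported.  An empty observed table still yields envelopes, with
    coverage flagged as NaN.
    """
    for col in ("age", "sex", "variable", "value"):
        if len(observed_table) and col not in observed_table.columns:
            raise ValueError(f"observed table lacks required column {col!r}")
    unknown = set(covariates) - set(_COVARIATE_GETTERS)
    if unknown:
        raise ValueError(
            f"unknown covariates {sorted(unknown)}; "
            f"available: {sorted(_COVARIATE_GETTERS)}"
        )
    if len(observed_table):
        bad = set(observed_table["variable"].unique()) - set(_COVARIATE_GETTERS)
        if bad:
            raise ValueError(
                f"observed table names unknown covariates {sorted(bad)}; "
                f"available: {sorted(_COVARIATE_GETTERS)}"
            )

    sim = subjects_to_frame(subjects)
    ages = sim["age"].to_numpy()
    edges = np.arange(
        math.floor(ages.min()), math.ceil(ages.max()) + age_bin_width, age_bin_width
    )
    sim = sim.assign(age_bin=pd.cut(sim["age"], edges, include_lowest=True))

    envelopes: dict[str, pd.DataFrame] = {}
    coverage: dict[str, float] = {}
    n_observed: dict[str, int] = {}
    for cov in covariates:
        col = {"height": "height", "weight": "weight",
               "scr": "scr_umol_L", "gfr": "gfr_norm"}[cov]
        env = (
            sim.groupby(["sex", "age_bin"], observed=True)[col]
            .agg(
                mean="mean",
                sd="std",
                p5=lambda x: np.percentile(x, 5),
                p95=lambda x: np.percentile(x, 95),
                n="count",
            )
            .reset_index()
        )
        envelopes[cov] = env
        if len(observed_table) == 0:
            coverage[cov] = float("nan")
            n_observed[cov] = 0
            continue
        obs = observed_table[observed_table["variable"] == cov]
        n_observed[cov] = len(obs)
        if len(obs) == 0:
            coverage[cov] = float("nan")
            continue
        inside = 0
        for _, row in obs.iterrows():
            abin = pd.cut([row["age"]], edges, include_lowest=True)[0]
            match = env[(env["sex"] == row["sex"]) & (env["age_bin"] == abin)]
            if len(match) == 0:  # age outside simulated range: counted outside
                continue
            if match["p5"].iloc[0] <= row["value"] <= match["p95"].iloc[0]:
                inside += 1
        coverage[cov] = inside / len(obs)
    return CovariateValidationReport(envelopes, coverage, n_observed)
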