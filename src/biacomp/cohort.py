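"""Seeded synthetic cohorts with a known body-water generating model.

The study population this generator emulates — 86 boys and 92 girls aged
11.5–14.5 y from a stunting-prevalent rural Malawian cohort — deposited
no individual-level data, so every downstream stage of the package is
exercised on synthetic cohorts with the published covariate structure:
per-sex means and SDs of age, height, BMI, waist circumference,
resistance at 50 kHz and reactance at five frequencies, plus Tanner-stage
and behavioural-flag frequencies.

The ground truth is a linear model on the percentage scale: true TBW%% is
the published percentage equation (resistance index, height, BMI, sex)
evaluated on the generated covariates plus Gaussian residual noise
(default SD 2.0 percentage points, matching the reported out-of-sample
error of 1.99 points), and true TBW (kg) = TBW%% × weight / 100.
Covariates are drawn independently per sex and resistance directly from
its configured distribution, so the regressors are exogenous, the
generating process is exactly linear in the candidate set, and every
covariate's sample mean is calibrated to its configured mean.

Matching deuterium assays are constructed by inverting the dilution
formula, so that at zero enrichment noise the dilution module recovers
the generator's truth exactly (a round-trip identity used throughout the
tests), and :func:`inject_artifacts` plants implausible or missing TBW%%
values with ground-truth flags to exercise the plausibility filter.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, field_validator, model_validator

from . import dilution
from .dilution import D2O_DENSITY_G_PER_ML, EXCHANGE_CORRECTION
from .published import TBW_PCT_COEFFICIENTS

MeanSD = tuple[float, float]

#: age band outside which draws are rejected (hydration factors and the
#: study population are defined on 11-14 y)
_AGE_BOUNDS = (11.0, 14.99)

#: generated true TBW% is kept inside this open interval (the plausible
#: physiological band); values outside only enter via inject_artifacts
_PCT_BOUNDS = dilution.TBW_PCT_BOUNDS


class SexParams(BaseModel):
    """Per-sex covariate distributions, as (mean, SD) pairs."""

    age_y: MeanSD
    height_cm: MeanSD
    height_z: MeanSD
    bmi: MeanSD
    waist_cm: MeanSD
    weight_loss_kg: MeanSD
    resistance_50: MeanSD
    reactance_1: MeanSD
    reactance_15: MeanSD
    reactance_50: MeanSD
    reactance_200: MeanSD
    reactance_1000: MeanSD
    tanner_probs: tuple[float, float, float, float, float]
    transport_p: float = Field(ge=0.0, le=1.0)
    fasted_p: float = Field(ge=0.0, le=1.0)
    bladder_p: float = Field(ge=0.0, le=1.0)
    transport_missing_p: float = Field(default=0.0, ge=0.0, le=1.0)
    fasted_missing_p: float = Field(default=0.0, ge=0.0, le=1.0)
    bladder_missing_p: float = Field(default=0.0, ge=0.0, le=1.0)

    @field_validator("age_y", "height_cm", "height_z", "bmi", "waist_cm",
                     "weight_loss_kg", "resistance_50", "reactance_1",
                     "reactance_15", "reactance_50", "reactance_200",
                     "reactance_1000")
    @classmethod
    def _sd_nonnegative(cls, value: MeanSD, info) -> MeanSD:
        if value[1] < 0:
            raise ValueError(f"{info.field_name}: SD must be >= 0, "
                             f"got {value[1]}")
        return value

    @field_validator("tanner_probs")
    @classmethod
    def _probs(cls, value):
        if any(p < 0 for p in value) or abs(sum(value) - 1.0) > 1e-8:
            raise ValueError("tanner_probs must be non-negative and sum to 1")
        return value


def _boys_defaults() -> SexParams:
    return SexParams(
        age_y=(13.0, 0.8), height_cm=(141.0, 8.0), height_z=(-2.05, 0.85),
        bmi=(16.0, 1.4), waist_cm=(61.7, 4.2), weight_loss_kg=(0.31, 0.21),
        resistance_50=(440.0, 56.0), reactance_1=(6.11, 1.19),
        reactance_15=(24.3, 3.5), reactance_50=(35.9, 4.8),
        reactance_200=(38.1, 5.7), reactance_1000=(44.2, 11.3),
        tanner_probs=(78 / 86, 6 / 86, 2 / 86, 0.0, 0.0),
        transport_p=0.071, fasted_p=0.447, bladder_p=0.582,
        transport_missing_p=1 / 86, fasted_missing_p=1 / 86,
        bladder_missing_p=7 / 86)


def _girls_defaults() -> SexParams:
    return SexParams(
        age_y=(12.9, 0.8), height_cm=(146.0, 8.0), height_z=(-1.30, 0.95),
        bmi=(16.7, 1.9), waist_cm=(63.6, 5.0), weight_loss_kg=(0.32, 0.24),
        resistance_50=(419.0, 44.0), reactance_1=(6.44, 1.2),
        reactance_15=(24.9, 3.6), reactance_50=(35.0, 4.3),
        reactance_200=(35.4, 4.6), reactance_1000=(40.0, 8.4),
        tanner_probs=(26 / 92, 34 / 92, 19 / 92, 13 / 92, 0.0),
        transport_p=0.176, fasted_p=0.565, bladder_p=0.588,
        transport_missing_p=1 / 92, fasted_missing_p=0.0,
        bladder_missing_p=7 / 92)


class GeneratorConfig(BaseModel):
    """Full specification of one synthetic cohort.

    The defaults reproduce the study conditions: 86 boys + 92 girls, the
    published per-sex covariate distributions, the published percentage
    equation as the generating model (coefficients on the fraction scale)
    and a residual SD of 2.0 percentage points.
    """

    n_boys: int = Field(default=86, ge=1)
    n_girls: int = Field(default=92, ge=1)
    seed: int = 0
    boys: SexParams = Field(default_factory=_boys_defaults)
    girls: SexParams = Field(default_factory=_girls_defaults)
    tbw_coefficients: dict[str, float] = Field(
        default_factory=lambda: dict(TBW_PCT_COEFFICIENTS))
    residual_sd_pct: float = Field(default=2.0, ge=0.0)
    fraction_implausible: float = Field(default=0.0, ge=0.0, lt=0.5)
    enrichment_noise_sd_ppm: float = Field(default=5.0, ge=0.0)
    baseline_ppm_mean: float = Field(default=150.0, gt=0.0)
    baseline_ppm_sd: float = Field(default=2.0, ge=0.0)
    d2o_density_g_per_ml: float = Field(default=D2O_DENSITY_G_PER_ML, gt=0.0)
    exchange_correction: float = Field(default=EXCHANGE_CORRECTION, gt=0.0)

    @model_validator(mode="after")
    def _coef_names(self) -> "GeneratorConfig":
        expected = set(TBW_PCT_COEFFICIENTS)
        if set(self.tbw_coefficients) != expected:
            raise ValueError(
                f"tbw_coefficients must have keys {sorted(expected)}")
        return self


def default_config(**overrides) -> GeneratorConfig:
    """The study-condition configuration, optionally with field overrides."""
    return GeneratorConfig(**overrides)


def _truncated_normal(rng: np.random.Generator, mean: float, sd: float,
                      size: int, lower: float | None = None,
                      upper: float | None = None) -> np.ndarray:
    """Normal draws with out-of-range values resampled (not clipped)."""
    x = rng.normal(mean, sd, size)
    if lower is None and upper is None:
        return x
    for _ in range(1000):
        bad = np.zeros(size, dtype=bool)
        if lower is not None:
            bad |= x <= lower
        if upper is not None:
            bad |= x > upper
        if not bad.any():
            return x
        x[bad] = rng.normal(mean, sd, int(bad.sum()))
    raise RuntimeError(
        f"truncated draw N({mean}, {sd}) failed to stay in "
        f"({lower}, {upper}]")


def _flag(rng: np.random.Generator, p: float, missing_p: float,
          size: int) -> np.ndarray:
    x = (rng.random(size) < p).astype(float)
    x[rng.random(size) < missing_p] = np.nan
    return x


def _generate_sex(rng: np.random.Generator, params: SexParams, n: int,
                  sex: int, config: GeneratorConfig) -> pd.DataFrame:
    df = pd.DataFrame({"sex": np.full(n, sex, dtype=float)})
    df["age_y"] = _truncated_normal(rng, *params.age_y, n, *_AGE_BOUNDS)
    df["height_cm"] = _truncated_normal(rng, *params.height_cm, n, lower=0.0)
    df["height_z"] = rng.normal(*params.height_z, n)
    df["bmi"] = _truncated_normal(rng, *params.bmi, n, lower=0.0)
    df["waist_cm"] = _truncated_normal(rng, *params.waist_cm, n, lower=0.0)
    # weight change over the visit may legitimately be negative (fluid
    # intake), so it is exempt from positivity truncation
    df["weight_loss_kg"] = rng.normal(*params.weight_loss_kg, n)
    for chan in ("resistance_50", "reactance_1", "reactance_15",
                 "reactance_50", "reactance_200", "reactance_1000"):
        df[chan] = _truncated_normal(rng, *getattr(params, chan), n,
                                     lower=0.0)
    df["tanner"] = rng.choice(np.arange(1, 6), size=n,
                              p=np.asarray(params.tanner_probs)).astype(float)
    df["transport"] = _flag(rng, params.transport_p,
                            params.transport_missing_p, n)
    df["fasted"] = _flag(rng, params.fasted_p, params.fasted_missing_p, n)
    df["bladder_emptied"] = _flag(rng, params.bladder_p,
                                  params.bladder_missing_p, n)

    df["weight_kg"] = df["bmi"] * (df["height_cm"] / 100.0) ** 2
    df["ri_50"] = df["height_cm"] ** 2 / df["resistance_50"]

    c = config.tbw_coefficients
    structural = 100.0 * (c["const"] + c["ri_50"] * df["ri_50"]
                          + c["height_m"] * df["height_cm"] / 100.0
                          + c["bmi"] * df["bmi"] + c["sex"] * sex)
    pct = structural + rng.normal(0.0, config.residual_sd_pct, n)
    # keep generated truth inside the physiological band; implausible
    # values are planted only via inject_artifacts
    lo, hi = _PCT_BOUNDS
    for _ in range(100):
        bad = (pct <= lo) | (pct >= hi)
        if not bad.any():
            break
        pct[bad] = (structural[bad]
                    + rng.normal(0.0, config.residual_sd_pct,
                                 int(bad.sum())))
    df["true_tbw_pct"] = pct
    df["true_tbw_kg"] = pct * df["weight_kg"] / 100.0
    return df


def generate_cohort(config: GeneratorConfig) -> pd.DataFrame:
    """Generate one cohort table, fully reproducible from ``config.seed``.

    Returns one row per participant with covariates, impedance channels,
    behavioural flags (NaN where the answer is missing), the derived
    weight (= BMI × height_m²) and resistance index, the generator truth
    columns ``true_tbw_pct`` / ``true_tbw_kg`` and an ``artifact`` flag
    (all False here; see :func:`inject_artifacts`).
    """
    rng = np.random.default_rng(config.seed)
    boys = _generate_sex(rng, config.boys, config.n_boys, 0, config)
    girls = _generate_sex(rng, config.girls, config.n_girls, 1, config)
    cohort = pd.concat([boys, girls], ignore_index=True)
    cohort.insert(0, "id", np.arange(1, len(cohort) + 1))
    cohort["artifact"] = False
    return cohort


def generate_dilution_assays(cohort: pd.DataFrame,
                             config: GeneratorConfig) -> pd.DataFrame:
    """Deuterium assays consistent with the cohort's true body water.

    The dose volume follows the weight bands, dose mass = volume × D₂O
    density, and the plateau enrichment is set by inverting the dilution
    formula so that at zero enrichment noise the dilution module recovers
    ``true_tbw_kg`` exactly.  The 3 h and 4 h samples get independent
    Gaussian noise of ``enrichment_noise_sd_ppm``.
    """
    if cohort["true_tbw_kg"].isna().any():
        raise ValueError(
            "cohort has rows without true TBW; generate assays before "
            "injecting missing-value artifacts")
    rng = np.random.default_rng([config.seed, 1])
    n = len(cohort)
    dose_ml = cohort["weight_kg"].map(dilution.assign_dose_volume)
    dose_mg = dose_ml * config.d2o_density_g_per_ml * 1000.0
    plateau = dose_mg / (cohort["true_tbw_kg"]
                         * config.exchange_correction)
    baseline = _truncated_normal(rng, config.baseline_ppm_mean,
                                 config.baseline_ppm_sd, n, lower=0.0)
    noise_sd = config.enrichment_noise_sd_ppm
    return pd.DataFrame({
        "id": cohort["id"].to_numpy(),
        "weight_kg": cohort["weight_kg"].to_numpy(),
        "dose_ml": dose_ml.to_numpy(),
        "dose_mg": dose_mg.to_numpy(),
        "baseline_ppm": baseline,
        "e3h_ppm": baseline + plateau + rng.normal(0.0, noise_sd, n),
        "e4h_ppm": baseline + plateau + rng.normal(0.0, noise_sd, n),
    })


def inject_artifacts(cohort: pd.DataFrame,
                     config: GeneratorConfig) -> pd.DataFrame:
    """Plant implausible or missing TBW%% values in a copy of the cohort.

    round(fraction_implausible × n) rows are modified to carry either a
    missing TBW%% or a value outside the plausible 35–80%% band, with the
    ``artifact`` column recording ground truth for filter-recovery tests.
    """
    cohort = cohort.copy()
    n = len(cohort)
    n_flag = int(round(config.fraction_implausible * n))
    if n_flag == 0:
        return cohort
    rng = np.random.default_rng([config.seed, 2])
    rows = rng.choice(n, size=n_flag, replace=False)
    modes = rng.choice(["missing", "high", "low"], size=n_flag)
    lo, hi = _PCT_BOUNDS
    for row, mode in zip(rows, modes):
        if mode == "missing":
            pct = np.nan
        elif mode == "high":
            pct = rng.uniform(hi + 0.5, 95.0)
        else:
            pct = rng.uniform(20.0, lo - 0.5)
        cohort.iloc[row, cohort.columns.get_loc("true_tbw_pct")] = pct
        cohort.iloc[row, cohort.columns.get_loc("true_tbw_kg")] = (
            pct * cohort.iloc[row]["weight_kg"] / 100.0)
        cohort.iloc[row, cohort.columns.get_loc("artifact")] = True
    return cohort


def participants_frame(cohort: pd.DataFrame) -> pd.DataFrame:
    """Participant-record view of a cohort (anthropometrics + flags)."""
    return cohort[["id", "sex", "age_y", "height_cm", "height_z",
                   "weight_kg", "bmi", "waist_cm", "weight_loss_kg",
                   "tanner", "transport", "fasted",
                   "bladder_emptied"]].copy()


def bia_frame(cohort: pd.DataFrame) -> pd.DataFrame:
    """Bioimpedance-measurement view of a cohort."""
    return cohort[["id", "resistance_50", "reactance_1", "reactance_15",
                   "reactance_50", "reactance_200",
                   "reactance_1000"]].copy()
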