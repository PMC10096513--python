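"""Frozen Seca m515 prediction equations for Malawian young adolescents.

The study behind this package fitted, by repeated cross-validated variable
selection against deuterium-dilution reference measurements, three linear
prediction equations for total body water (TBW) in 11–14-year-olds:

(a)  TBW (kg) = -3.5202 + 0.00950*R + 0.231103*RI + 0.27658*weight - 0.9182*sex
(b)  TBW (%)  = 100*(1.11373 + 0.0037049*RI - 0.25778*height - 0.01812*BMI - 0.02614*sex)
(c)  TBW (kg) = weight * (b)/100

with R the resistance (Ω) at 50 kHz, RI the resistance index
height(cm)²/R (cm²/Ω), weight in kg, height in m, BMI in kg/m², and sex
coded boys = 0 / girls = 1.  Equation (c) — percentage equation times
weight — had the best out-of-sample performance and is the recommended
route to TBW (kg).

These coefficients are stored here at full printed precision as a frozen,
unit-checked calculator for field use and as the golden reference for the
model-building pipeline.  They were derived in a stunting-prevalent rural
population aged 11.5–14.5 y using the Seca m515 analyser; outside those
conditions the equations are extrapolations.
"""

from __future__ import annotations

import math
import warnings

import numpy as np
import pandas as pd
from pydantic import BaseModel, model_validator

#: equation (b) coefficients on the *fraction* scale (multiply by 100 for %)
TBW_PCT_COEFFICIENTS: dict[str, float] = {
    "const": 1.11373,
    "ri_50": 0.0037049,
    "height_m": -0.25778,
    "bmi": -0.01812,
    "sex": -0.02614,
}

#: equation (a) coefficients, TBW in kg
TBW_KG_DIRECT_COEFFICIENTS: dict[str, float] = {
    "const": -3.5202,
    "resistance_50": 0.00950,
    "ri_50": 0.231103,
    "weight_kg": 0.27658,
    "sex": -0.9182,
}

#: TBW%% outside this band is physiologically implausible and gets flagged
PLAUSIBLE_TBW_PCT = (20.0, 90.0)


class ImplausiblePredictionWarning(UserWarning):
    """Predicted body-water value outside the plausible physiological band."""


class SecaEquationInput(BaseModel):
    """Predictor set for the frozen equations, with unit bookkeeping.

    ``ri_50`` (cm²/Ω) is derived from height and resistance when omitted;
    when both are supplied they are cross-checked and a >1% inconsistency
    raises a warning, guarding against a cm/m mix-up.
    """

    sex: int
    height_m: float | None = None
    weight_kg: float | None = None
    bmi: float | None = None
    resistance_50: float | None = None
    ri_50: float | None = None

    @model_validator(mode="after")
    def _check(self) -> "SecaEquationInput":
        if self.sex not in (0, 1):
            raise ValueError("sex must be coded boys = 0, girls = 1")
        for name in ("height_m", "weight_kg", "bmi", "resistance_50", "ri_50"):
            v = getattr(self, name)
            if v is not None and v < 0:
                raise ValueError(f"{name} must be non-negative, got {v}")
        if self.ri_50 is None and self.height_m is not None \
                and self.resistance_50 is not None and self.resistance_50 > 0:
            self.ri_50 = (100.0 * self.height_m) ** 2 / self.resistance_50
        elif (self.ri_50 is not None and self.ri_50 > 0
                and self.height_m is not None
                and self.resistance_50 is not None
                and self.resistance_50 > 0):
            implied = (100.0 * self.height_m) ** 2 / self.resistance_50
            if abs(implied - self.ri_50) > 0.01 * self.ri_50:
                warnings.warn(
                    f"supplied resistance index {self.ri_50:.2f} deviates "
                    f"more than 1% from height²/resistance = {implied:.2f}; "
                    "check units (height in m, RI in cm²/Ω)",
                    UserWarning, stacklevel=2)
        return self


def _require(inp: SecaEquationInput, fields: tuple[str, ...], eq: str) -> None:
    missing = [f for f in fields if getattr(inp, f) is None]
    if missing:
        raise ValueError(f"equation ({eq}) needs {missing}")


def _flag_pct(pct: float) -> None:
    lo, hi = PLAUSIBLE_TBW_PCT
    if not (lo <= pct <= hi):
        warnings.warn(
            f"predicted TBW {pct:.1f}% outside the plausible band "
            f"[{lo:.0f}, {hi:.0f}]%",
            ImplausiblePredictionWarning, stacklevel=3)


def tbw_pct_published(inp: SecaEquationInput) -> float:
    """Equation (b): total body water as % of body weight."""
    _require(inp, ("ri_50", "height_m", "bmi"), "b")
    c = TBW_PCT_COEFFICIENTS
    pct = 100.0 * (c["const"] + c["ri_50"] * inp.ri_50
                   + c["height_m"] * inp.height_m
                   + c["bmi"] * inp.bmi + c["sex"] * inp.sex)
    _flag_pct(pct)
    return pct


def tbw_kg_direct_published(inp: SecaEquationInput) -> float:
    """Equation (a): total body water in kg, modelled directly."""
    _require(inp, ("resistance_50", "ri_50", "weight_kg"), "a")
    c = TBW_KG_DIRECT_COEFFICIENTS
    kg = (c["const"] + c["resistance_50"] * inp.resistance_50
          + c["ri_50"] * inp.ri_50 + c["weight_kg"] * inp.weight_kg
          + c["sex"] * inp.sex)
    if inp.weight_kg > 0:
        _flag_pct(100.0 * kg / inp.weight_kg)
    return kg


def tbw_kg_via_pct_published(inp: SecaEquationInput) -> float:
    """Equation (c): weight times the percentage equation — the recommended
    route to TBW (kg)."""
    _require(inp, ("weight_kg",), "c")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ImplausiblePredictionWarning)
        pct = tbw_pct_published(inp)
    if inp.weight_kg > 0:
        _flag_pct(pct)
    return inp.weight_kg * pct / 100.0


_EQUATIONS = {"a": tbw_kg_direct_published,
              "b": tbw_pct_published,
              "c": tbw_kg_via_pct_published}


def predict_frame(df: pd.DataFrame, equation: str = "c") -> np.ndarray:
    """Apply one frozen equation to every row of a predictor DataFrame.

    Expects columns named as in :class:`SecaEquationInput`; ``ri_50`` is
    derived from ``height_m`` and ``resistance_50`` when absent.
    """
    if equation not in _EQUATIONS:
        raise ValueError(f"equation must be one of {sorted(_EQUATIONS)}")
    func = _EQUATIONS[equation]
    out = np.empty(len(df))
    cols = [c for c in SecaEquationInput.model_fields if c in df.columns]
    for i, (_, row) in enumerate(df[cols].iterrows()):
        vals = {k: (None if pd.isna(v) else v) for k, v in row.items()}
        if "sex" in vals and vals["sex"] is not None:
            vals["sex"] = int(vals["sex"])
        out[i] = func(SecaEquationInput(**vals))
    return out
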