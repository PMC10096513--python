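"""Total body water, fat-free mass and fat mass from deuterium dilution.

The deuterium-dilution protocol modelled here: each participant drinks a
weight-banded dose of D₂O, saliva is sampled at baseline and at 3 h and
4 h post-dose, and the enrichment rise above baseline (ppm, measured by
FTIR) at the two post-dose times is averaged as the plateau.  Total body
water follows the standard dilution principle

    TBW (kg) = dose (mg) / plateau (ppm) / 1.041,

where 1.041 corrects for the in-vivo exchange of deuterium with
non-aqueous hydrogen.  Fat-free mass is TBW divided by an age- and
sex-specific hydration factor (the water fraction of fat-free mass,
~0.75 at these ages), and fat mass is weight minus fat-free mass.

Assays with missing or implausible TBW%% (outside 35–80% of body weight)
are excluded by :func:`plausibility_filter` with machine-readable reason
codes rather than silently dropped.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: density of deuterium oxide at room temperature, g/ml (dose volume -> mass)
D2O_DENSITY_G_PER_ML = 1.107

#: correction for deuterium exchange with non-aqueous hydrogen
EXCHANGE_CORRECTION = 1.041

#: plausible band for TBW as % of body weight; values outside are excluded
TBW_PCT_BOUNDS = (35.0, 80.0)

#: default height-for-age z-score floor for inclusion
MIN_HEIGHT_Z = -4.0

#: relative disagreement between the 3 h and 4 h enrichment rises that
#: triggers a quality flag (not an exclusion)
PLATEAU_DISAGREEMENT_TOL = 0.05

#: water fraction of fat-free mass by sex (boys=0, girls=1) and age band
_HYDRATION = {
    0: {"11-12": 0.754, "13-14": 0.747},
    1: {"11-12": 0.766, "13-14": 0.755},
}


def _sex_code(sex) -> int:
    """Normalise sex coding to boys = 0, girls = 1."""
    if isinstance(sex, str):
        s = sex.strip().lower()
        if s in ("male", "boy", "boys", "m"):
            return 0
        if s in ("female", "girl", "girls", "f"):
            return 1
        raise ValueError(f"unrecognised sex {sex!r}")
    if sex in (0, 1):
        return int(sex)
    raise ValueError(f"unrecognised sex code {sex!r}")


@dataclass(frozen=True)
class DilutionAssay:
    """One participant's deuterium dose and saliva enrichments (ppm)."""

    participant_id: object
    weight_kg: float          # clothing-adjusted body weight
    dose_volume_ml: float
    dose_mass_mg: float
    baseline_ppm: float
    e3h_ppm: float
    e4h_ppm: float
    non_fasting: bool = False
    fluid_intake_ml: float = 0.0
    urine_passed: bool = False

    def __post_init__(self) -> None:
        if self.dose_mass_mg <= 0:
            raise ValueError("dose mass must be positive")
        for name in ("baseline_ppm", "e3h_ppm", "e4h_ppm"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


@dataclass(frozen=True)
class DilutionResult:
    """Body-composition summary for one participant."""

    participant_id: object
    tbw_kg: float
    tbw_pct: float
    hydration_factor: float
    ffm_kg: float
    fm_kg: float
    fm_pct: float
    flags: tuple[str, ...] = field(default_factory=tuple)


def assign_dose_volume(weight_kg: float) -> float:
    """D₂O dose volume (ml) by weight band: 10 below 30 kg, 20 for
    30–50 kg inclusive, 30 above 50 kg."""
    if weight_kg <= 0:
        raise ValueError(f"weight must be positive, got {weight_kg}")
    if weight_kg < 30.0:
        return 10.0
    if weight_kg <= 50.0:
        return 20.0
    return 30.0


def compute_enrichment(post_ppm: float, baseline_ppm: float) -> float:
    """Enrichment rise above the participant's own baseline (ppm).

    A negative rise means the assay is unusable (evaporation, swapped
    samples); it raises rather than being clipped to zero.
    """
    if post_ppm < 0 or baseline_ppm < 0:
        raise ValueError("enrichments must be non-negative")
    rise = post_ppm - baseline_ppm
    if rise < 0:
        raise ValueError(
            f"negative enrichment ({post_ppm} - {baseline_ppm} ppm); "
            "assay unusable")
    return rise


def tbw_from_dilution(assay: DilutionAssay,
                      exchange_correction: float = EXCHANGE_CORRECTION
                      ) -> tuple[float, tuple[str, ...]]:
    """Total body water (kg) from the plateau dilution of the dose.

    The plateau is the mean of the 3 h and 4 h enrichment rises.  Returns
    (tbw_kg, flags); a >5% relative disagreement between the two rises
    adds a ``"plateau_disagreement"`` quality flag without excluding the
    assay.
    """
    r3 = compute_enrichment(assay.e3h_ppm, assay.baseline_ppm)
    r4 = compute_enrichment(assay.e4h_ppm, assay.baseline_ppm)
    plateau = 0.5 * (r3 + r4)
    if plateau <= 0:
        raise ValueError("non-positive plateau enrichment; assay unusable")
    flags: tuple[str, ...] = ()
    if abs(r3 - r4) > PLATEAU_DISAGREEMENT_TOL * plateau:
        flags = ("plateau_disagreement",)
    return assay.dose_mass_mg / plateau / exchange_correction, flags


def hydration_factor(sex, age_years: float) -> float:
    """Water fraction of fat-free mass for 11–14-year-olds.

    Ages below 13 use the 11–12-year band; 13 and above use 13–14.  Ages
    outside [11, 15) raise rather than extrapolate.
    """
    code = _sex_code(sex)
    if not 11.0 <= age_years < 15.0:
        raise ValueError(
            f"hydration factors are defined for ages 11-14 y, got "
            f"{age_years}")
    band = "11-12" if age_years < 13.0 else "13-14"
    return _HYDRATION[code][band]


def derive_composition(tbw_kg: float, weight_kg: float, sex=None,
                       age_years: float | None = None,
                       hf: float | None = None) -> DilutionResult:
    """Fat-free mass, fat mass and TBW%% from TBW and body weight.

    FFM = TBW / hydration factor, FM = weight − FFM.  The hydration
    factor is looked up from sex and age unless ``hf`` overrides it.
    Negative fat mass (TBW exceeding hydrated FFM) is flagged, not
    clipped, so conservation FFM + FM = weight always holds exactly.
    """
    if weight_kg <= 0:
        raise ValueError("weight must be positive")
    if tbw_kg <= 0:
        raise ValueError("TBW must be positive")
    if hf is None:
        if sex is None or age_years is None:
            raise ValueError("either hf or (sex, age_years) is required")
        hf = hydration_factor(sex, age_years)
    ffm = tbw_kg / hf
    fm = weight_kg - ffm
    flags = ("negative_fat_mass",) if fm < 0 else ()
    return DilutionResult(
        participant_id=None,
        tbw_kg=tbw_kg,
        tbw_pct=100.0 * tbw_kg / weight_kg,
        hydration_factor=hf,
        ffm_kg=ffm,
        fm_kg=fm,
        fm_pct=100.0 * fm / weight_kg,
        flags=flags)


def plausibility_filter(results: pd.DataFrame,
                        min_pct: float = TBW_PCT_BOUNDS[0],
                        max_pct: float = TBW_PCT_BOUNDS[1],
                        min_height_z: float | None = MIN_HEIGHT_Z
                        ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Split dilution results into kept and excluded rows with reasons.

    Excludes rows whose ``tbw_pct`` is missing, strictly above ``max_pct``
    or strictly below ``min_pct``, and — when a ``height_z`` column is
    present and ``min_height_z`` is given — rows with a height-for-age
    z-score below the floor (extreme short stature, outside the
    population the equations target).  The excluded frame carries a
    ``reason`` column; boundary values 35.0 and 80.0 are kept.
    """
    if min_pct >= max_pct:
        raise ValueError("min_pct must be below max_pct")
    results = results.copy()
    reason = pd.Series(pd.NA, index=results.index, dtype="object")
    pct = results["tbw_pct"]
    reason[pct.isna()] = "missing_tbw"
    reason[pct > max_pct] = "tbw_pct_above_max"
    reason[pct < min_pct] = "tbw_pct_below_min"
    if min_height_z is not None and "height_z" in results.columns:
        short = results["height_z"] < min_height_z
        reason[short & reason.isna()] = "height_z_below_min"
    excluded = results[reason.notna()].assign(reason=reason[reason.notna()])
    kept = results[reason.isna()]
    return kept, excluded


def process_assays(assays: pd.DataFrame, participants: pd.DataFrame,
                   exchange_correction: float = EXCHANGE_CORRECTION
                   ) -> pd.DataFrame:
    """Batch dilution pipeline: assay table + participant table → results.

    ``assays`` needs columns id, weight_kg, dose_ml, dose_mg,
    baseline_ppm, e3h_ppm, e4h_ppm; ``participants`` supplies sex and
    age_y (and optionally height_z, carried through for filtering).
    Unusable assays (negative enrichment, non-positive plateau) come back
    with missing TBW and a reason flag instead of raising, so one bad
    sample never aborts a batch.
    """
    cols = ["id", "sex", "age_y"]
    if "height_z" in participants.columns:
        cols.append("height_z")
    merged = assays.merge(participants[cols], on="id", validate="1:1")
    records = []
    for row in merged.itertuples(index=False):
        rec = {"id": row.id, "tbw_kg": np.nan, "tbw_pct": np.nan,
               "hydration_factor": np.nan, "ffm_kg": np.nan,
               "fm_kg": np.nan, "fm_pct": np.nan, "flags": "",
               "usable": False}
        if "height_z" in merged.columns:
            rec["height_z"] = row.height_z
        numeric = (row.weight_kg, row.dose_ml, row.dose_mg,
                   row.baseline_ppm, row.e3h_ppm, row.e4h_ppm)
        if any(pd.isna(v) for v in numeric):
            rec["flags"] = "unusable: missing assay value"
            records.append(rec)
            continue
        try:
            assay = DilutionAssay(
                participant_id=row.id, weight_kg=row.weight_kg,
                dose_volume_ml=row.dose_ml, dose_mass_mg=row.dose_mg,
                baseline_ppm=row.baseline_ppm, e3h_ppm=row.e3h_ppm,
                e4h_ppm=row.e4h_ppm)
            tbw, flags = tbw_from_dilution(assay, exchange_correction)
            comp = derive_composition(tbw, row.weight_kg, sex=row.sex,
                                      age_years=row.age_y)
        except ValueError as err:
            rec["flags"] = f"unusable: {err}"
            records.append(rec)
            continue
        rec.update(tbw_kg=comp.tbw_kg, tbw_pct=comp.tbw_pct,
                   hydration_factor=comp.hydration_factor,
                   ffm_kg=comp.ffm_kg, fm_kg=comp.fm_kg,
                   fm_pct=comp.fm_pct,
                   flags=";".join(flags + comp.flags), usable=True)
        records.append(rec)
    return pd.DataFrame.from_records(records)
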