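"""Candidate-predictor construction for the prediction equations.

The modelling stage considers exactly 23 candidate variables per
participant: eleven anthropometric/behavioural variables, resistance at
50 kHz, reactance at five frequencies, the resistance index
height(cm)²/resistance, and the five analogous reactance indices.  This
module assembles that table from the raw participant, bioimpedance and
dilution-result records, applying the study's codings:

* sex coded boys = 0, girls = 1;
* height enters equations in metres but the indices in centimetres —
  both representations are carried and named explicitly;
* the three behavioural dichotomies (transport to clinic, overnight
  fasting, bladder emptied) code a missing answer as 0.5;
* any other missing value is an error naming the offending column.
"""

from __future__ import annotations

import pandas as pd

#: the 23 candidate predictors, in the fixed order used for subset
#: enumeration and tie-breaking throughout the package
CANDIDATE_COLUMNS: tuple[str, ...] = (
    "sex", "age_y", "height_m", "weight_kg", "bmi", "waist_cm",
    "weight_loss_kg", "tanner", "transport", "fasted", "bladder_emptied",
    "resistance_50",
    "reactance_1", "reactance_15", "reactance_50", "reactance_200",
    "reactance_1000",
    "ri_50", "xci_1", "xci_15", "xci_50", "xci_200", "xci_1000",
)

#: behavioural yes/no variables whose missing values are coded 0.5
DICHOTOMOUS_COLUMNS: tuple[str, ...] = ("transport", "fasted",
                                        "bladder_emptied")

#: impedance channels: raw column -> index column
_CHANNELS: dict[str, str] = {
    "resistance_50": "ri_50",
    "reactance_1": "xci_1",
    "reactance_15": "xci_15",
    "reactance_50": "xci_50",
    "reactance_200": "xci_200",
    "reactance_1000": "xci_1000",
}

#: weight automatically deducted by the analyser for light clothing, kg
CLOTHING_DEDUCTION_KG = 0.5

FEATURE_TABLE_VERSION = "biacomp-feature-table-v1"


def adjust_weight_for_clothing(scale_weight_kg: float,
                               deduction: float = CLOTHING_DEDUCTION_KG
                               ) -> float:
    """Clothing-adjusted body weight: scale reading minus the deduction."""
    if scale_weight_kg < deduction:
        raise ValueError(
            f"scale weight {scale_weight_kg} kg below the clothing "
            f"deduction {deduction} kg")
    return scale_weight_kg - deduction


def resistance_index(height_cm: float, value_ohm: float) -> float:
    """height(cm)² / resistance (or reactance), in cm²/Ω.

    Theoretically proportional to the conductive (water) volume; the same
    construction applied to a reactance channel gives a reactance index.
    """
    if height_cm <= 0:
        raise ValueError("height must be positive")
    if value_ohm <= 0:
        raise ValueError("resistance/reactance must be positive")
    return height_cm ** 2 / value_ohm


def assemble_feature_table(participants: pd.DataFrame, bia: pd.DataFrame,
                           dilution_results: pd.DataFrame) -> pd.DataFrame:
    """Join raw records into the 23-candidate modelling table.

    Parameters
    ----------
    participants
        Columns: id, sex, age_y, height_cm, weight_kg, bmi, waist_cm,
        weight_loss_kg, tanner, transport, fasted, bladder_emptied.
    bia
        Columns: id, resistance_50, reactance_{1,15,50,200,1000}.
    dilution_results
        Columns: id, tbw_kg, tbw_pct — only rows that survived the
        plausibility filter should be passed in.

    Returns
    -------
    DataFrame with id, the 23 candidates in :data:`CANDIDATE_COLUMNS`
    order, height_cm (kept for index reconstruction) and the outcome
    columns tbw_kg and tbw_pct.
    """
    for name, frame in (("participants", participants), ("bia", bia),
                        ("dilution_results", dilution_results)):
        if frame["id"].duplicated().any():
            dup = frame.loc[frame["id"].duplicated(), "id"].iloc[0]
            raise ValueError(f"duplicate id {dup!r} in {name}")
    merged = dilution_results[["id", "tbw_kg", "tbw_pct"]].merge(
        participants, on="id", how="left", validate="1:1")
    merged = merged.merge(bia, on="id", how="left", validate="1:1")
    unmatched = merged["id"][merged["height_cm"].isna()
                             | merged["resistance_50"].isna()]
    if len(unmatched):
        missing_ids = list(unmatched.iloc[:5])
        raise ValueError(
            f"ids without matching participant/bia records: {missing_ids}")

    for col in DICHOTOMOUS_COLUMNS:
        merged[col] = merged[col].astype(float).fillna(0.5)

    merged["height_m"] = merged["height_cm"] / 100.0
    for raw, index_col in _CHANNELS.items():
        merged[index_col] = [
            resistance_index(h, v)
            for h, v in zip(merged["height_cm"], merged[raw])
        ]

    table = merged[["id", *CANDIDATE_COLUMNS, "height_cm",
                    "tbw_kg", "tbw_pct"]].copy()
    incomplete = table.columns[table.isna().any()]
    if len(incomplete):
        raise ValueError(
            "missing values are only allowed in the behavioural "
            f"dichotomies; offending columns: {list(incomplete)}")
    return table.reset_index(drop=True)


def write_feature_table(table: pd.DataFrame, path) -> None:
    """Write the table as CSV under a versioned header comment."""
    with open(path, "w") as fh:
        fh.write(f"# {FEATURE_TABLE_VERSION}\n")
        table.to_csv(fh, index=False)


def read_feature_table(path) -> pd.DataFrame:
    """Read a CSV written by :func:`write_feature_table`."""
    with open(path) as fh:
        first = fh.readline()
        if FEATURE_TABLE_VERSION not in first:
            raise ValueError(
                f"{path} is not a {FEATURE_TABLE_VERSION} file")
        return pd.read_csv(fh)
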