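"""Nested cross-validation, representative split, agreement statistics."""

import numpy as np
import pandas as pd
import pytest

import biacomp as bc
from biacomp.model import ModelFamily, TbwModel
from biacomp.validation import (CVReport, bland_altman,
                                compare_model_families, nested_cv,
                                representative_split)
from conftest import build_feature_table


@pytest.fixture(scope="module")
def noise_free_report():
    table = build_feature_table(seed=21, n_boys=30, n_girls=30,
                                residual_sd_pct=0.0,
                                enrichment_noise_sd_ppm=0.0)
    report = nested_cv(table, ModelFamily("tbw_pct"), n_repeat_sets=2,
                       inner_repeats=2, seed=0)
    return report


@pytest.fixture(scope="module")
def noisy_report(small_table):
    return nested_cv(small_table, ModelFamily("tbw_pct"), n_repeat_sets=3,
                     inner_repeats=2, seed=1)


def test_noise_free_data_predicted_perfectly(noise_free_report):
    """When the outcome is an exact linear function of the candidates,
    nested CV prediction error vanishes."""
    assert noise_free_report.avg_rmse_pe <= 1e-6
    assert noise_free_report.r2_pe == pytest.approx(1.0, abs=1e-9)


def test_out_of_sample_bookkeeping(noisy_report):
    """Every participant is predicted exactly once per repeat."""
    counts = noisy_report.predictions.groupby(["repeat", "id"]).size()
    assert (counts == 1).all()
    reps = noisy_report.predictions["repeat"].nunique()
    assert reps == noisy_report.n_repeat_sets == 3
    assert len(noisy_report.rmse_per_repeat) == 3
    assert noisy_report.r2_pe <= 1.0
    assert set(noisy_report.rmse_by_sex()) == {0, 1}


def test_nested_cv_seed_determinism(small_table):
    a = nested_cv(small_table, ModelFamily("tbw_pct"), n_repeat_sets=1,
                  inner_repeats=2, seed=5)
    b = nested_cv(small_table, ModelFamily("tbw_pct"), n_repeat_sets=1,
                  inner_repeats=2, seed=5)
    pd.testing.assert_frame_equal(a.predictions, b.predictions)


def test_in_sample_fit_is_optimistic():
    """Across seeds, the in-sample RMSE of the full-data fit
    underestimates the nested-CV out-of-sample error."""
    in_sample, out_sample = [], []
    for seed in range(12):
        table = build_feature_table(seed=200 + seed, n_boys=30, n_girls=30)
        report = nested_cv(table, ModelFamily("tbw_pct"), n_repeat_sets=2,
                           inner_repeats=2, seed=seed)
        fit = TbwModel(table, ModelFamily("tbw_pct")).fit(
            "rcv", repeats=2, seed=seed)
        resid = table["tbw_pct"].to_numpy() - fit.predict(table)
        in_sample.append(float(np.sqrt(np.mean(resid ** 2))))
        out_sample.append(report.avg_rmse_pe)
    in_sample, out_sample = np.asarray(in_sample), np.asarray(out_sample)
    assert in_sample.mean() < out_sample.mean()
    assert (in_sample < out_sample).sum() >= 10


def test_nested_cv_bias_near_zero(noisy_report):
    """On well-specified synthetic data the out-of-sample predictions
    are unbiased to within Monte-Carlo resolution."""
    rep = representative_split(noisy_report)
    stats = bland_altman(rep["y_true"], rep["y_pred"], rep["sex"])
    for _, row in stats.iterrows():
        assert abs(row["bias"]) < 3 * row["sd_diff"] / np.sqrt(row["n"])


def _fake_report(rmses):
    blocks = [pd.DataFrame({"repeat": i, "id": [1, 2], "sex": [0, 1],
                            "weight_kg": 30.0, "y_true": [1.0, 2.0],
                            "y_pred": [1.0, 2.0]})
              for i in range(len(rmses))]
    cols = ["repeat", "id", "sex", "weight_kg", "y_true", "y_pred"]
    preds = (pd.concat(blocks, ignore_index=True) if blocks
             else pd.DataFrame(columns=cols))
    return CVReport(family=ModelFamily("tbw_pct"), selection="rcv", k=10,
                    n_repeat_sets=len(rmses), seed=0, predictions=preds,
                    rmse_per_repeat=np.asarray(rmses, dtype=float))


def test_representative_split_selection_rule():
    assert representative_split(_fake_report([1.5]))["repeat"].iloc[0] == 0
    # mean 2.0 matches repeat index 1 exactly
    assert representative_split(
        _fake_report([1.0, 2.0, 3.0]))["repeat"].iloc[0] == 1
    # mean ~2.333: the 2.9 repeat is closest
    assert representative_split(
        _fake_report([1.0, 2.9, 3.1]))["repeat"].iloc[0] == 1
    with pytest.raises(ValueError, match="empty"):
        representative_split(_fake_report([]))


def test_bland_altman_hand_values():
    identical = bland_altman([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
    assert identical.iloc[0]["bias"] == 0.0
    assert identical.iloc[0]["loa_lower"] == identical.iloc[0]["loa_upper"] == 0.0

    offset = bland_altman([1.0, 2.0, 3.0], [0.5, 1.5, 2.5])
    assert offset.iloc[0]["bias"] == pytest.approx(0.5)
    assert offset.iloc[0]["sd_diff"] == 0.0
    assert offset.iloc[0]["loa_lower"] == pytest.approx(0.5)

    hand = bland_altman([1, 2, 3, 4], [1.1, 1.9, 3.2, 3.8])
    assert hand.iloc[0]["bias"] == pytest.approx(0.0, abs=1e-12)
    assert hand.iloc[0]["sd_diff"] == pytest.approx(0.18257, abs=1e-4)
    assert hand.iloc[0]["loa_upper"] == pytest.approx(0.35785, abs=1e-4)
    assert hand.iloc[0]["loa_lower"] == pytest.approx(-0.35785, abs=1e-4)


def test_bland_altman_errors_and_groups():
    with pytest.raises(ValueError, match="equal length"):
        bland_altman([1.0, 2.0], [1.0])
    with pytest.raises(ValueError, match="at least 3"):
        bland_altman([1, 2, 3, 4], [1, 2, 3, 4], ["a", "a", "a", "b"])
    grouped = bland_altman([1, 2, 3, 4, 5, 6], [1, 2, 3, 5, 6, 7],
                           [0, 0, 0, 1, 1, 1])
    assert grouped.loc[0, "bias"] == 0.0
    assert grouped.loc[1, "bias"] == pytest.approx(-1.0)


def test_compare_model_families_structure(small_table):
    table = compare_model_families(small_table, n_repeat_sets=1,
                                   inner_repeats=2, seed=0)
    assert len(table) == 6
    assert set(table["outcome"]) == {"tbw_kg_direct", "tbw_pct",
                                     "tbw_kg_via_pct"}
    assert set(table["scope"]) == {"joint", "sex_specific"}
    assert table["rmse_pe"].notna().all()
    assert {"rmse_pe_sex0", "rmse_pe_sex1", "r2_pe_sex0",
            "r2_pe_sex1"} <= set(table.columns)
    # exactly one kg-scale winner flagged
    assert table["best"].sum() == 1
    assert table.loc[table["best"], "outcome"].iloc[0] != "tbw_pct"
    # via-percentage rows carry no in-sample fit statistics
    via = table[table["outcome"] == "tbw_kg_via_pct"]
    assert via["rsquared"].isna().all()


def test_compare_model_families_single_sex(small_table):
    boys = small_table[small_table["sex"] == 0]
    with pytest.warns(UserWarning, match="single-sex"):
        table = compare_model_families(boys, n_repeat_sets=1,
                                       inner_repeats=2, seed=0)
    assert set(table["scope"]) == {"joint"}
    assert len(table) == 3
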