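"""Out-of-sample validation: nested repeated cross-validation, model-family
comparison and Bland–Altman agreement.

The estimator of external performance works as the study's protocol
prescribes: the data are split into k folds; for each fold the *entire*
variable-selection procedure is rerun on the other k−1 folds (nested
cross-validation) and the held-out fold is predicted, giving one
out-of-sample prediction per participant per repeat; the per-repeat root
mean squared prediction errors RMSE(PE) are averaged over many repeated
fold sets.  r²(PE) is the variance fraction explained by the pooled
out-of-sample predictions, 1 − Σ(yᵢ−ŷᵢ)²/Σ(yᵢ−ȳ)².

For scatterplots and agreement analysis one *representative* repeat is
selected — the one whose RMSE(PE) is closest to the average — and
agreement between measured and predicted values is summarised per sex as
bias ± 1.96·SD limits (Bland–Altman), with differences oriented
measured − predicted.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import selection as _sel
from .features import CANDIDATE_COLUMNS
from .linreg import SubsetOLS
from .model import ModelFamily, TbwModel

__all__ = [
    "CVReport", "nested_cv", "representative_split",
    "compare_model_families", "bland_altman", "AgreementStats",
    "plot_bland_altman",
]


@dataclass(frozen=True)
class CVReport:
    """Out-of-sample predictions and error summaries from nested CV.

    ``predictions`` has one row per participant per repeat with columns
    repeat, id, sex, weight_kg, y_true, y_pred (on the family's target
    scale).
    """

    family: ModelFamily
    selection: str
    k: int
    n_repeat_sets: int
    seed: int
    predictions: pd.DataFrame
    rmse_per_repeat: np.ndarray

    @property
    def avg_rmse_pe(self) -> float:
        """Average RMSE(PE) across the repeated fold sets."""
        return float(np.mean(self.rmse_per_repeat))

    @property
    def r2_pe(self) -> float:
        return self._r2(self.predictions)

    @staticmethod
    def _r2(frame: pd.DataFrame) -> float:
        y = frame["y_true"].to_numpy()
        resid = y - frame["y_pred"].to_numpy()
        denom = float(np.sum((y - y.mean()) ** 2))
        return 1.0 - float(resid @ resid) / denom if denom > 0 else np.nan

    def rmse_by_sex(self) -> dict[int, float]:
        """RMSE(PE) on the sex-restricted residuals, pooled over repeats."""
        out = {}
        for code, grp in self.predictions.groupby("sex"):
            resid = grp["y_true"] - grp["y_pred"]
            out[int(code)] = float(np.sqrt(np.mean(resid ** 2)))
        return out

    def r2_by_sex(self) -> dict[int, float]:
        return {int(code): self._r2(grp)
                for code, grp in self.predictions.groupby("sex")}


def _select_indices(X: np.ndarray, y: np.ndarray, names, selection: str,
                    rng: np.random.Generator, inner_k: int,
                    inner_repeats: int, one_se: bool,
                    max_size: int | None) -> np.ndarray:
    if selection == "rcv":
        idx, _ = _sel.rcv_select_engine(X, y, names, k=inner_k,
                                        repeats=inner_repeats, rng=rng,
                                        one_se=one_se)
        return idx
    if selection in ("bic", "aic"):
        engine = SubsetOLS(X, y, names)
        idx, _ = _sel.best_subsets_engine(engine, criterion=selection,
                                          max_size=max_size)
        return np.asarray(idx, dtype=int)
    raise ValueError(f"unknown selection method {selection!r}")


def _nested_cv_core(data: pd.DataFrame, fit_column: str, scope: str,
                    candidates, selection: str, k: int, n_repeat_sets: int,
                    seed: int, inner_k: int, inner_repeats: int,
                    one_se: bool, max_size: int | None) -> pd.DataFrame:
    """Nested-CV predictions on the *fit* scale, one block per repeat."""
    if candidates is None:
        candidates = [c for c in CANDIDATE_COLUMNS
                      if not (scope == "sex_specific" and c == "sex")]
    candidates = list(candidates)
    n = len(data)
    if n < 2 * k:
        raise ValueError(f"n = {n} too small for {k}-fold nested CV")
    X = data[candidates].to_numpy(dtype=float)
    y = data[fit_column].to_numpy(dtype=float)
    sex = data["sex"].to_numpy(dtype=float)
    rng = np.random.default_rng(seed)
    blocks = []
    for rep in range(n_repeat_sets):
        pred = np.full(n, np.nan)
        for fold in _sel.kfold_indices(n, k, rng):
            train = np.ones(n, dtype=bool)
            train[fold] = False
            if scope == "joint":
                groups = [(train, fold)]
            else:
                groups = []
                for code in np.unique(sex):
                    tr = train & (sex == code)
                    te = fold[sex[fold] == code]
                    if len(te):
                        groups.append((tr, te))
            for tr, te in groups:
                try:
                    idx = _select_indices(X[tr], y[tr], candidates,
                                          selection, rng, inner_k,
                                          inner_repeats, one_se, max_size)
                    engine = SubsetOLS(X[tr], y[tr], candidates)
                    beta, _ = engine.slopes(idx)
                    pred[te] = engine.predict(X[te], idx, beta)
                except Exception as err:
                    raise RuntimeError(
                        f"selection failed in repeat {rep}, fold with "
                        f"{len(te)} held-out rows: {err}") from err
        blocks.append(pd.DataFrame({
            "repeat": rep,
            "id": data["id"].to_numpy() if "id" in data.columns
            else data.index.to_numpy(),
            "sex": sex,
            "weight_kg": data["weight_kg"].to_numpy(dtype=float),
            "tbw_kg": data["tbw_kg"].to_numpy(dtype=float),
            "tbw_pct": data["tbw_pct"].to_numpy(dtype=float),
            "pred_fit": pred,
        }))
    return pd.concat(blocks, ignore_index=True)


def _report_from_core(core: pd.DataFrame, family: ModelFamily,
                      selection: str, k: int, n_repeat_sets: int,
                      seed: int) -> CVReport:
    if family.outcome == "tbw_pct":
        y_true = core["tbw_pct"]
        y_pred = core["pred_fit"]
    elif family.outcome == "tbw_kg_direct":
        y_true = core["tbw_kg"]
        y_pred = core["pred_fit"]
    else:  # via percentage
        y_true = core["tbw_kg"]
        y_pred = core["pred_fit"] * core["weight_kg"] / 100.0
    predictions = pd.DataFrame({
        "repeat": core["repeat"], "id": core["id"], "sex": core["sex"],
        "weight_kg": core["weight_kg"],
        "y_true": y_true.to_numpy(), "y_pred": y_pred.to_numpy()})
    rmse = (predictions.assign(sq=(predictions["y_true"]
                                   - predictions["y_pred"]) ** 2)
            .groupby("repeat")["sq"].mean() ** 0.5)
    return CVReport(family=family, selection=selection, k=k,
                    n_repeat_sets=n_repeat_sets, seed=seed,
                    predictions=predictions,
                    rmse_per_repeat=rmse.to_numpy())


def nested_cv(data: pd.DataFrame, family: ModelFamily | None = None,
              selection: str = "rcv", k: int = 10,
              n_repeat_sets: int = 100, seed: int = 0, inner_k: int = 10,
              inner_repeats: int = 10, one_se: bool = True,
              candidates=None, max_size: int | None = None) -> CVReport:
    """Nested repeated k-fold cross-validation of one model family.

    For each of ``n_repeat_sets`` random k-fold splits, the full variable
    selection (``"rcv"``, ``"bic"`` or ``"aic"``) is rerun on each
    training part and the held-out fold predicted, so no participant's
    outcome influences the model that predicts it.
    """
    family = family or ModelFamily()
    core = _nested_cv_core(data, family.fit_column, family.scope,
                           candidates, selection, k, n_repeat_sets, seed,
                           inner_k, inner_repeats, one_se, max_size)
    return _report_from_core(core, family, selection, k, n_repeat_sets,
                             seed)


def representative_split(report: CVReport) -> pd.DataFrame:
    """Predictions of the repeat whose RMSE(PE) is closest to the average.

    Ties resolve to the lowest repeat index.  This is the repeat used for
    scatterplots and Bland–Altman agreement.
    """
    if len(report.rmse_per_repeat) == 0:
        raise ValueError("empty CV report")
    gap = np.abs(report.rmse_per_repeat - report.avg_rmse_pe)
    rep = int(np.argmin(gap))
    out = report.predictions[report.predictions["repeat"] == rep]
    return out.reset_index(drop=True)


_FAMILY_ROWS = (("tbw_kg_direct", "a"), ("tbw_pct", "b"),
                ("tbw_kg_via_pct", "c"))


def compare_model_families(data: pd.DataFrame, selection: str = "rcv",
                           k: int = 10, n_repeat_sets: int = 10,
                           seed: int = 0, inner_k: int = 10,
                           inner_repeats: int = 10, one_se: bool = True
                           ) -> pd.DataFrame:
    """Head-to-head comparison of the model families.

    One row per outcome (direct kg / % / kg via %) × scope (joint /
    sex-specific) with the variables selected on the full data, the
    in-sample r² and max(p) of that fit, and the nested-CV RMSE(PE) and
    r²(PE) overall and per sex.  The kg-scale row with the lowest overall
    RMSE(PE) is flagged ``best``.  The via-percentage rows reuse the
    percentage-model CV runs (they are the same fitted equations), so
    their in-sample columns are NaN, mirroring how such comparisons are
    usually tabulated.
    """
    sexes = sorted(data["sex"].unique())
    scopes = ["joint", "sex_specific"]
    if len(sexes) < 2:
        warnings.warn("single-sex data: sex-specific rows suppressed",
                      UserWarning, stacklevel=2)
        scopes = ["joint"]
    rows = []
    for s_i, scope in enumerate(scopes):
        cores = {}
        for fit_column, j in (("tbw_pct", 0), ("tbw_kg", 1)):
            cores[fit_column] = _nested_cv_core(
                data, fit_column, scope, None, selection, k,
                n_repeat_sets, int(np.random.default_rng(
                    [seed, s_i, j]).integers(2 ** 31)),
                inner_k, inner_repeats, one_se, None)
        for outcome, label in _FAMILY_ROWS:
            family = ModelFamily(outcome, scope)
            core = cores[family.fit_column]
            report = _report_from_core(core, family, selection, k,
                                       n_repeat_sets, seed)
            row = {"equation": label, "outcome": outcome, "scope": scope,
                   "rmse_pe": report.avg_rmse_pe, "r2_pe": report.r2_pe}
            for code, val in report.rmse_by_sex().items():
                row[f"rmse_pe_sex{code}"] = val
            for code, val in report.r2_by_sex().items():
                row[f"r2_pe_sex{code}"] = val
            if outcome == "tbw_kg_via_pct":
                row.update(variables=None, rsquared=np.nan, max_p=np.nan)
            else:
                fitted = TbwModel(data, family=family).fit(
                    method=selection, k=inner_k, repeats=inner_repeats,
                    seed=np.random.default_rng([seed, s_i, 7]),
                    one_se=one_se)
                if scope == "joint":
                    row.update(variables=", ".join(fitted.variables),
                               rsquared=fitted.rsquared, max_p=fitted.max_p)
                else:
                    row.update(variables=" | ".join(
                        ", ".join(res.variables)
                        for _, res in sorted(fitted.by_sex.items())),
                        rsquared=np.nan, max_p=np.nan)
            rows.append(row)
    table = pd.DataFrame(rows)
    kg_mask = table["outcome"] != "tbw_pct"
    best_idx = table.loc[kg_mask, "rmse_pe"].idxmin()
    table["best"] = False
    table.loc[best_idx, "best"] = True
    return table


# ---------------------------------------------------------------------------
# agreement

@dataclass(frozen=True)
class AgreementStats:
    """Bland–Altman summary: bias ± 1.96·SD limits of agreement."""

    group: object
    n: int
    bias: float
    sd_diff: float
    loa_lower: float
    loa_upper: float


def bland_altman(measured, predicted, group_labels=None
                 ) -> pd.DataFrame:
    """Bland–Altman agreement per group, differences measured − predicted.

    Returns a frame indexed by group with n, bias (mean difference), SD
    of the differences, and the 95% limits of agreement bias ± 1.96·SD.
    """
    measured = np.asarray(measured, dtype=float)
    predicted = np.asarray(predicted, dtype=float)
    if measured.shape != predicted.shape:
        raise ValueError("measured and predicted must have equal length")
    if group_labels is None:
        group_labels = np.zeros(len(measured), dtype=int)
    group_labels = np.asarray(group_labels)
    diffs = measured - predicted
    records = []
    for group in pd.unique(group_labels):
        d = diffs[group_labels == group]
        if len(d) < 3:
            raise ValueError(
                f"group {group!r} has {len(d)} pairs; need at least 3")
        bias = float(np.mean(d))
        sd = float(np.std(d, ddof=1))
        records.append(AgreementStats(
            group=group, n=len(d), bias=bias, sd_diff=sd,
            loa_lower=bias - 1.96 * sd, loa_upper=bias + 1.96 * sd))
    return pd.DataFrame([r.__dict__ for r in records]).set_index("group")


def plot_bland_altman(measured, predicted, group_labels=None, ax=None):
    """Bland–Altman plot: difference against mean, with bias and limits."""
    import matplotlib.pyplot as plt

    stats = bland_altman(measured, predicted, group_labels)
    measured = np.asarray(measured, dtype=float)
    predicted = np.asarray(predicted, dtype=float)
    if ax is None:
        _, ax = plt.subplots()
    mean = (measured + predicted) / 2.0
    diff = measured - predicted
    if group_labels is None:
        ax.scatter(mean, diff, s=14, alpha=0.7)
    else:
        group_labels = np.asarray(group_labels)
        for group in pd.unique(group_labels):
            m = group_labels == group
            ax.scatter(mean[m], diff[m], s=14, alpha=0.7,
                       label=str(group))
        ax.legend(title="group")
    pooled = bland_altman(measured, predicted).iloc[0]
    ax.axhline(pooled["bias"], color="k", lw=1)
    for key in ("loa_lower", "loa_upper"):
        ax.axhline(pooled[key], color="k", lw=1, ls="--")
    ax.set_xlabel("mean of measured and predicted")
    ax.set_ylabel("measured − predicted")
    return ax
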