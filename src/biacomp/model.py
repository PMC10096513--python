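"""Prediction-equation models over the candidate feature table.

The central objects follow the Model/Results convention: a
:class:`TbwModel` is constructed from a feature table (see
:mod:`biacomp.features`) together with a :class:`ModelFamily`, and its
:meth:`TbwModel.fit` returns a :class:`TbwResults` carrying the selected
variables, coefficients with classical standard errors and p-values, the
in-sample r², and a ``summary()`` table.

Model families
--------------
Three outcomes are supported:

* ``"tbw_kg_direct"`` — a linear equation for TBW in kg;
* ``"tbw_pct"`` — a linear equation for TBW as % of body weight;
* ``"tbw_kg_via_pct"`` — the percentage equation evaluated and multiplied
  by body weight / 100, which is how the best-performing published
  equation predicts kg.

combined with a scope: ``"joint"`` (both sexes, sex as a candidate) or
``"sex_specific"`` (separate equations per sex, sex dropped from the
candidate list).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd

from . import selection as _sel
from .features import CANDIDATE_COLUMNS
from .linreg import LinearFit, SubsetOLS

Outcome = Literal["tbw_kg_direct", "tbw_pct", "tbw_kg_via_pct"]
Scope = Literal["joint", "sex_specific"]


@dataclass(frozen=True)
class ModelFamily:
    """One cell of the model-type comparison: outcome × scope."""

    outcome: Outcome = "tbw_pct"
    scope: Scope = "joint"

    def __post_init__(self) -> None:
        if self.outcome not in ("tbw_kg_direct", "tbw_pct",
                                "tbw_kg_via_pct"):
            raise ValueError(f"unknown outcome {self.outcome!r}")
        if self.scope not in ("joint", "sex_specific"):
            raise ValueError(f"unknown scope {self.scope!r}")

    @property
    def fit_column(self) -> str:
        """Column the regression is fitted on."""
        return "tbw_kg" if self.outcome == "tbw_kg_direct" else "tbw_pct"

    @property
    def target_column(self) -> str:
        """Column predictions are evaluated against."""
        return "tbw_pct" if self.outcome == "tbw_pct" else "tbw_kg"

    @property
    def via_weight(self) -> bool:
        return self.outcome == "tbw_kg_via_pct"


def _check_table(data: pd.DataFrame, candidates: Sequence[str],
                 fit_column: str) -> None:
    missing = [c for c in (*candidates, fit_column) if c not in data.columns]
    if missing:
        raise ValueError(f"feature table lacks columns {missing}")
    bad = [c for c in (*candidates, fit_column) if data[c].isna().any()]
    if bad:
        raise ValueError(f"missing values in columns {bad}; assemble the "
                         "feature table first (dichotomies code missing "
                         "as 0.5)")


@dataclass(frozen=True)
class TbwResults:
    """A fitted prediction equation with classical inference.

    Attributes mirror the statsmodels results surface where it makes
    sense: ``params``/``bse``/``tvalues``/``pvalues`` are Series indexed
    by ``const`` + variable names, ``rsquared`` and ``nobs`` describe the
    in-sample fit, and ``max_p`` is the largest non-intercept p-value.
    """

    family: ModelFamily
    variables: tuple[str, ...]
    params: pd.Series
    bse: pd.Series
    tvalues: pd.Series
    pvalues: pd.Series
    rsquared: float
    nobs: int
    selection: dict = field(default_factory=dict)

    @property
    def max_p(self) -> float:
        slopes = self.pvalues.drop("const")
        return float(slopes.max()) if len(slopes) else float("nan")

    def _linear(self, data: pd.DataFrame | Mapping) -> np.ndarray:
        if isinstance(data, Mapping) and not isinstance(data, pd.DataFrame):
            data = pd.DataFrame([data])
        missing = [v for v in self.variables if v not in data.columns]
        if missing:
            raise ValueError(f"prediction input lacks variables {missing}")
        X = data[list(self.variables)].to_numpy(dtype=float)
        return self.params["const"] + X @ self.params[
            list(self.variables)].to_numpy()

    def predict(self, data: pd.DataFrame | Mapping) -> np.ndarray:
        """Predict on the family's target scale (kg or %).

        For the via-percentage family the linear predictor is a
        percentage and the return value is weight × %/100, so the input
        must also carry ``weight_kg``.
        """
        if isinstance(data, Mapping) and not isinstance(data, pd.DataFrame):
            data = pd.DataFrame([data])
        lin = self._linear(data)
        if self.family.via_weight:
            if "weight_kg" not in data.columns:
                raise ValueError(
                    "via-percentage prediction needs weight_kg")
            return data["weight_kg"].to_numpy(dtype=float) * lin / 100.0
        return lin

    def summary(self) -> str:
        """Plain-text coefficient table in the style of statsmodels."""
        lines = [
            f"TBW prediction equation  [{self.family.outcome}, "
            f"{self.family.scope}]",
            f"n = {self.nobs}    r² = {self.rsquared:.4f}    "
            f"max(p) = {self.max_p:.3g}",
        ]
        if self.selection.get("method"):
            lines.append(f"selection: {self.selection['method']}"
                         + (f" (size {self.selection['chosen_size']})"
                            if "chosen_size" in self.selection else ""))
        lines.append("-" * 64)
        lines.append(f"{'variable':<18}{'coef':>12}{'std err':>12}"
                     f"{'t':>10}{'P>|t|':>10}")
        for name in self.params.index:
            lines.append(
                f"{name:<18}{self.params[name]:>12.5g}"
                f"{self.bse[name]:>12.3g}{self.tvalues[name]:>10.2f}"
                f"{self.pvalues[name]:>10.3g}")
        return "\n".join(lines)

    def to_dict(self) -> dict:
        """JSON-ready description of the equation (for the CLI)."""
        return {
            "family": {"outcome": self.family.outcome,
                       "scope": self.family.scope},
            "variables": list(self.variables),
            "coefficients": {k: float(v) for k, v in self.params.items()},
            "bse": {k: float(v) for k, v in self.bse.items()},
            "pvalues": {k: float(v) for k, v in self.pvalues.items()},
            "rsquared": float(self.rsquared),
            "max_p": float(self.max_p),
            "nobs": int(self.nobs),
            "selection": {k: v for k, v in self.selection.items()
                          if np.isscalar(v) or isinstance(v, (str, bool))},
        }


@dataclass(frozen=True)
class SexStratifiedResults:
    """Separate fitted equations per sex (boys = 0, girls = 1)."""

    family: ModelFamily
    by_sex: dict[int, TbwResults]

    def predict(self, data: pd.DataFrame) -> np.ndarray:
        out = np.full(len(data), np.nan)
        sex = data["sex"].to_numpy()
        for code, res in self.by_sex.items():
            mask = sex == code
            if mask.any():
                out[mask] = res.predict(data[mask])
        if np.isnan(out).any():
            raise ValueError("rows with a sex code absent from the fit")
        return out

    def summary(self) -> str:
        parts = []
        for code in sorted(self.by_sex):
            label = "boys" if code == 0 else "girls"
            parts.append(f"== {label} ==\n{self.by_sex[code].summary()}")
        return "\n\n".join(parts)


def _results_from_fit(fit: LinearFit, family: ModelFamily,
                      selection: dict | None = None) -> TbwResults:
    index = ["const", *fit.variables]
    return TbwResults(
        family=family,
        variables=fit.variables,
        params=pd.Series(fit.params, index=index),
        bse=pd.Series(fit.bse, index=index),
        tvalues=pd.Series(fit.tvalues, index=index),
        pvalues=pd.Series(fit.pvalues, index=index),
        rsquared=fit.rsquared,
        nobs=fit.nobs,
        selection=selection or {})


class TbwModel:
    """Prediction-equation model over a candidate feature table.

    Parameters
    ----------
    data
        Feature table from :func:`biacomp.features.assemble_feature_table`
        (or any frame with the candidate and outcome columns).
    family
        Outcome × scope cell; defaults to the joint percentage model.
    candidates
        Candidate predictors; defaults to the fixed 23-variable list,
        with ``sex`` removed automatically for sex-specific scope.
    """

    def __init__(self, data: pd.DataFrame,
                 family: ModelFamily | None = None,
                 candidates: Sequence[str] | None = None) -> None:
        self.family = family or ModelFamily()
        if candidates is None:
            candidates = list(CANDIDATE_COLUMNS)
        if self.family.scope == "sex_specific":
            candidates = [c for c in candidates if c != "sex"]
        _check_table(data, candidates, self.family.fit_column)
        self.data = data.reset_index(drop=True)
        self.candidates = tuple(candidates)

    @classmethod
    def from_tables(cls, participants: pd.DataFrame, bia: pd.DataFrame,
                    dilution_results: pd.DataFrame, **kwargs) -> "TbwModel":
        """Build the feature table from raw records, then the model."""
        from .features import assemble_feature_table
        table = assemble_feature_table(participants, bia, dilution_results)
        return cls(table, **kwargs)

    # -- fitting ----------------------------------------------------------

    def _fit_frame(self, data: pd.DataFrame, method: str,
                   variables: Sequence[str] | None, k: int, repeats: int,
                   rng: np.random.Generator, one_se: bool,
                   max_size: int | None) -> TbwResults:
        y = data[self.family.fit_column].to_numpy(dtype=float)
        X = data[list(self.candidates)].to_numpy(dtype=float)
        engine = SubsetOLS(X, y, self.candidates)
        if method == "ols":
            if variables is None:
                variables = self.candidates
            idx = [self.candidates.index(v) for v in variables]
            fit = engine.full_fit(idx)
            info = {"method": "ols"}
        elif method in ("bic", "aic"):
            idx, score = _sel.best_subsets_engine(engine, criterion=method,
                                                 max_size=max_size)
            fit = engine.full_fit(idx)
            info = {"method": method, "criterion_value": score,
                    "chosen_size": len(idx)}
        elif method == "rcv":
            idx, info = _sel.rcv_select_engine(
                X, y, self.candidates, k=k, repeats=repeats, rng=rng,
                one_se=one_se)
            fit = engine.full_fit(idx)
            info = {"method": "rcv", **{k_: v for k_, v in info.items()
                                        if k_ != "sizes"}}
        else:
            raise ValueError(f"unknown selection method {method!r}")
        return _results_from_fit(fit, self.family, info)

    def fit(self, method: str = "rcv",
            variables: Sequence[str] | None = None, k: int = 10,
            repeats: int = 10, seed: int | np.random.Generator = 0,
            one_se: bool = True, max_size: int | None = None
            ) -> TbwResults | SexStratifiedResults:
        """Fit the equation, selecting variables by the given method.

        ``method`` is one of ``"rcv"`` (repeated k-fold CV over the
        backward path, the study's preferred route), ``"bic"``/``"aic"``
        (exhaustive best subsets) or ``"ols"`` (no selection; fit
        ``variables``, defaulting to all candidates).
        """
        rng = (seed if isinstance(seed, np.random.Generator)
               else np.random.default_rng(seed))
        if self.family.scope == "joint":
            return self._fit_frame(self.data, method, variables, k,
                                   repeats, rng, one_se, max_size)
        by_sex = {}
        for code in sorted(self.data["sex"].unique()):
            sub = self.data[self.data["sex"] == code]
            by_sex[int(code)] = self._fit_frame(
                sub, method, variables, k, repeats, rng, one_se, max_size)
        return SexStratifiedResults(family=self.family, by_sex=by_sex)


# ---------------------------------------------------------------------------
# operation-style wrappers

def fit_ols(feature_rows: pd.DataFrame, variables: Sequence[str],
            outcome: str = "tbw_pct",
            family: ModelFamily | None = None) -> TbwResults:
    """Least-squares fit of a fixed variable set (no selection)."""
    family = family or ModelFamily(
        "tbw_pct" if outcome == "tbw_pct" else "tbw_kg_direct")
    model = TbwModel(feature_rows, family=family, candidates=variables)
    return model.fit(method="ols", variables=variables)


def best_subsets(feature_rows: pd.DataFrame, candidates: Sequence[str],
                 outcome: str = "tbw_pct", criterion: str = "bic",
                 max_size: int | None = None) -> TbwResults:
    """Exhaustive best-subsets selection under AIC or BIC."""
    family = ModelFamily(
        "tbw_pct" if outcome == "tbw_pct" else "tbw_kg_direct")
    model = TbwModel(feature_rows, family=family, candidates=candidates)
    return model.fit(method=criterion, max_size=max_size)


def backward_path(feature_rows: pd.DataFrame, candidates: Sequence[str],
                  outcome: str = "tbw_pct") -> list[TbwResults]:
    """Backward-elimination path: full fits at sizes p, p-1, ..., 1."""
    family = ModelFamily(
        "tbw_pct" if outcome == "tbw_pct" else "tbw_kg_direct")
    model = TbwModel(feature_rows, family=family, candidates=candidates)
    y = model.data[family.fit_column].to_numpy(dtype=float)
    X = model.data[list(model.candidates)].to_numpy(dtype=float)
    engine = SubsetOLS(X, y, model.candidates)
    path = _sel.backward_path_indices(engine)
    return [_results_from_fit(engine.full_fit(idx), family,
                              {"method": "backward", "size": len(idx)})
            for idx in path]


def rcv_select(feature_rows: pd.DataFrame, candidates: Sequence[str],
               outcome: str = "tbw_pct", k: int = 10, repeats: int = 10,
               seed: int = 0, one_se: bool = True) -> TbwResults:
    """Repeated-CV selection of the model size with the one-SE rule."""
    family = ModelFamily(
        "tbw_pct" if outcome == "tbw_pct" else "tbw_kg_direct")
    model = TbwModel(feature_rows, family=family, candidates=candidates)
    return model.fit(method="rcv", k=k, repeats=repeats, seed=seed,
                     one_se=one_se)


def predict(results: TbwResults | SexStratifiedResults,
            rows: pd.DataFrame | Mapping) -> np.ndarray:
    """Evaluate a fitted equation on new rows (target scale)."""
    return results.predict(rows)
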