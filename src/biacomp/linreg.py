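"""Ordinary-least-squares machinery used by the variable-selection algorithms.

Every selection procedure in this package (backward elimination, exhaustive
best subsets, repeated cross-validation) refits many subsets of the columns
of one fixed design matrix.  Refitting each subset from the precomputed
centred Gram matrix ``Xc'Xc`` makes a subset fit an O(p^3) solve with
p <= 23, so a full backward path — and hence nested repeated
cross-validation — stays tractable in pure Python.

Centring the design before forming the Gram matrix removes the intercept
column and conditions the normal equations on the covariance scale; the
intercept and its standard error are recovered analytically afterwards.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats


class RankDeficientError(ValueError):
    """Design matrix subset is (numerically) rank deficient."""


@dataclass(frozen=True)
class LinearFit:
    """One ordinary-least-squares fit: a variable subset with full inference.

    ``params`` holds the intercept first, then one coefficient per entry of
    ``variables``; ``bse``/``tvalues``/``pvalues`` are aligned with it.
    """

    variables: tuple[str, ...]
    params: np.ndarray
    bse: np.ndarray
    tvalues: np.ndarray
    pvalues: np.ndarray
    rss: float
    tss: float
    nobs: int

    @property
    def df_resid(self) -> int:
        return self.nobs - len(self.params)

    @property
    def rsquared(self) -> float:
        if self.tss <= 0:
            return float("nan")
        return 1.0 - self.rss / self.tss

    @property
    def max_p(self) -> float:
        """Largest p-value among the non-intercept coefficients."""
        if len(self.pvalues) < 2:
            return float("nan")
        return float(np.max(self.pvalues[1:]))

    def linear_predictor(self, X: np.ndarray) -> np.ndarray:
        """Evaluate intercept + X @ slopes; X columns follow ``variables``."""
        X = np.asarray(X, dtype=float)
        return self.params[0] + X @ self.params[1:]


def _safe_solve(A: np.ndarray, b: np.ndarray) -> tuple[np.ndarray, bool]:
    """Solve A x = b, falling back to the pseudo-inverse when singular.

    Returns (solution, exact) where ``exact`` is False on the fallback path.
    """
    try:
        x = np.linalg.solve(A, b)
        if np.all(np.isfinite(x)):
            return x, True
    except np.linalg.LinAlgError:
        pass
    return np.linalg.pinv(A) @ b, False


def _collinear_names(Xc: np.ndarray, names: tuple[str, ...]) -> list[str]:
    """Name the columns implicated in a rank deficiency via pivoted scale."""
    _, r = np.linalg.qr(Xc)
    diag = np.abs(np.diag(r))
    tol = diag.max() * max(Xc.shape) * np.finfo(float).eps if diag.size else 0.0
    return [names[i] for i in np.nonzero(diag <= tol)[0]]


class SubsetOLS:
    """Refit arbitrary column subsets of one design matrix from its Gram matrix.

    Parameters
    ----------
    X : (n, p) array
        Candidate columns, without an intercept (one is always implied).
    y : (n,) array
        Response.
    names : sequence of str
        Column names, used only for error messages and reporting.
    """

    def __init__(self, X: np.ndarray, y: np.ndarray, names) -> None:
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        if X.ndim != 2:
            raise ValueError("X must be 2-dimensional")
        if len(y) != X.shape[0]:
            raise ValueError("X and y have different lengths")
        if not (np.all(np.isfinite(X)) and np.all(np.isfinite(y))):
            raise ValueError("design matrix and response must be finite")
        self.n = X.shape[0]
        self.p = X.shape[1]
        self.names = tuple(names)
        if len(self.names) != self.p:
            raise ValueError("names do not match the number of columns")
        self.xbar = X.mean(axis=0)
        self.ybar = float(y.mean())
        Xc = X - self.xbar
        yc = y - self.ybar
        self.G = Xc.T @ Xc
        self.g = Xc.T @ yc
        self.tss = float(yc @ yc)
        self._Xc = Xc  # kept for collinearity diagnostics only

    # -- core subset operations ------------------------------------------

    def slopes(self, idx: np.ndarray) -> tuple[np.ndarray, float]:
        """Slope vector and residual sum of squares for column subset idx."""
        idx = np.asarray(idx, dtype=int)
        A = self.G[np.ix_(idx, idx)]
        b = self.g[idx]
        beta, _ = _safe_solve(A, b)
        rss = self.tss - float(beta @ b)
        return beta, max(rss, 0.0)

    def slope_tvalues(self, idx: np.ndarray, beta: np.ndarray, rss: float
                      ) -> np.ndarray:
        """t statistics of the slopes in subset idx (intercept excluded)."""
        idx = np.asarray(idx, dtype=int)
        dof = self.n - len(idx) - 1
        if dof <= 0:
            raise ValueError("no residual degrees of freedom")
        sigma2 = rss / dof
        A = self.G[np.ix_(idx, idx)]
        try:
            Ainv = np.linalg.inv(A)
        except np.linalg.LinAlgError:
            Ainv = np.linalg.pinv(A)
        var = sigma2 * np.clip(np.diag(Ainv), 0.0, np.inf)
        se = np.sqrt(var)
        with np.errstate(divide="ignore", invalid="ignore"):
            t = np.where(se > 0, beta / se, 0.0)
        return t

    def predict(self, Xnew: np.ndarray, idx: np.ndarray, beta: np.ndarray
                ) -> np.ndarray:
        """Predict for new rows; Xnew has the full candidate column layout."""
        idx = np.asarray(idx, dtype=int)
        Xnew = np.asarray(Xnew, dtype=float)
        return self.ybar + (Xnew[:, idx] - self.xbar[idx]) @ beta

    def full_fit(self, idx) -> LinearFit:
        """Complete fit (intercept, SEs, t, p) for column subset idx.

        Raises
        ------
        RankDeficientError
            naming the collinear columns, when the subset is singular.
        """
        idx = np.asarray(sorted(idx), dtype=int)
        k = len(idx)
        if self.n <= k + 1:
            raise ValueError(
                f"n = {self.n} observations cannot fit {k} variables "
                "plus an intercept")
        A = self.G[np.ix_(idx, idx)]
        b = self.g[idx]
        names = tuple(self.names[i] for i in idx)
        diag = np.diag(A)
        if np.any(diag <= 0):
            bad = [names[i] for i in np.nonzero(diag <= 0)[0]]
            raise RankDeficientError(f"constant columns: {bad}")
        # scale-invariant singularity check on the correlation-scaled Gram
        scale = np.sqrt(diag)
        corr = A / np.outer(scale, scale)
        if np.linalg.cond(corr) > 1e10:
            bad = _collinear_names(self._Xc[:, idx], names)
            raise RankDeficientError(
                f"design matrix is rank deficient; collinear columns: "
                f"{bad or list(names)}")
        beta, exact = _safe_solve(A, b)
        if not exact:
            raise RankDeficientError(
                "design matrix is numerically singular")
        rss = max(self.tss - float(beta @ b), 0.0)
        dof = self.n - k - 1
        sigma2 = rss / dof
        Ainv = np.linalg.inv(A)
        intercept = self.ybar - float(self.xbar[idx] @ beta)
        var_slopes = sigma2 * np.clip(np.diag(Ainv), 0.0, np.inf)
        var_inter = sigma2 * (1.0 / self.n
                              + float(self.xbar[idx] @ Ainv @ self.xbar[idx]))
        params = np.concatenate(([intercept], beta))
        bse = np.sqrt(np.concatenate(([max(var_inter, 0.0)], var_slopes)))
        with np.errstate(divide="ignore", invalid="ignore"):
            tvals = np.where(bse > 0, params / bse, np.inf * np.sign(params))
        pvals = 2.0 * stats.t.sf(np.abs(tvals), dof)
        return LinearFit(
            variables=tuple(self.names[i] for i in idx),
            params=params, bse=bse, tvalues=tvals, pvalues=pvals,
            rss=rss, tss=self.tss, nobs=self.n)


def ols_fit(X: np.ndarray, y: np.ndarray, names) -> LinearFit:
    """Fit y on all columns of X (plus intercept) with classical inference."""
    engine = SubsetOLS(X, y, names)
    return engine.full_fit(np.arange(engine.p))
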