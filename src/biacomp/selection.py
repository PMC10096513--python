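"""Variable-selection procedures for linear prediction equations.

Three routes to a prediction equation, all built on :class:`~biacomp.linreg.SubsetOLS`:

* :func:`best_subsets` — exhaustive search minimising AIC or BIC;
* :func:`backward_path` — backward elimination ranked by |t|, recording the
  fit at every model size;
* :func:`rcv_select` — repeated k-fold cross-validation over the backward
  path to pick the model *size*, optionally with the one-standard-error
  rule, then a refit of that size on all data.

These operate on numpy arrays; the DataFrame-facing wrappers live in
:mod:`biacomp.model`.
"""

from __future__ import annotations

import math
import warnings
from itertools import combinations

import numpy as np

from .linreg import LinearFit, SubsetOLS

#: refuse exhaustive enumeration beyond this many candidate subsets
MAX_EXHAUSTIVE_SUBSETS = 5_000_000


# ---------------------------------------------------------------------------
# information criteria

def _ic_from_rss(rss: float, nobs: int, n_params: int, which: str) -> float:
    """Gaussian AIC/BIC from the residual sum of squares.

    ``n_params`` counts the regression coefficients including the intercept;
    the error variance adds one more estimated parameter, so the penalty
    uses k = n_params + 1.  The additive constant n*(ln(2*pi) + 1) is
    omitted consistently, so values are comparable across fits on the same
    data but are not likelihood-scale.
    """
    k = n_params + 1
    if rss <= 0.0:
        warnings.warn("zero residual sum of squares; criterion is -inf",
                      RuntimeWarning, stacklevel=3)
        return -math.inf
    base = nobs * math.log(rss / nobs)
    if which == "aic":
        return base + 2.0 * k
    if which == "bic":
        return base + k * math.log(nobs)
    raise ValueError(f"unknown information criterion {which!r}")


def information_criterion(fit: LinearFit, which: str) -> float:
    """AIC or BIC of a fitted equation (lower is better)."""
    return _ic_from_rss(fit.rss, fit.nobs, len(fit.params), which.lower())


# ---------------------------------------------------------------------------
# exhaustive best subsets

def best_subsets_engine(engine: SubsetOLS, criterion: str = "bic",
                        max_size: int | None = None) -> tuple[tuple[int, ...], float]:
    """Criterion-minimising subset by exhaustive enumeration.

    Ties are broken toward fewer variables, then lexicographic column
    order, because sizes are scanned in increasing order and combinations
    in lexicographic order with strict improvement required.
    """
    p = engine.p
    criterion = criterion.lower()
    if max_size is None:
        max_size = p
    max_size = min(max_size, p)
    total = sum(math.comb(p, s) for s in range(1, max_size + 1))
    if total > MAX_EXHAUSTIVE_SUBSETS:
        raise ValueError(
            f"exhaustive best-subsets over {p} candidates up to size "
            f"{max_size} needs {total} fits; use the backward-elimination "
            "path (rcv selection) instead")
    best_idx: tuple[int, ...] | None = None
    best_score = math.inf
    for size in range(1, max_size + 1):
        if engine.n <= size + 1:
            break
        for idx in combinations(range(p), size):
            beta, rss = engine.slopes(np.asarray(idx))
            score = _ic_from_rss(rss, engine.n, size + 1, criterion)
            if score < best_score:
                best_score = score
                best_idx = idx
    if best_idx is None:
        raise ValueError("no admissible subset (too few observations)")
    return best_idx, best_score


# ---------------------------------------------------------------------------
# backward elimination

def backward_path_indices(engine: SubsetOLS,
                          start: np.ndarray | None = None) -> list[np.ndarray]:
    """Backward-elimination path: index sets of sizes p, p-1, ..., 1.

    At each step the slope with the smallest absolute t statistic is
    dropped.  A numerically collinear column gets t = 0 from the
    pseudo-inverse fallback and is therefore eliminated first, with a
    warning.
    """
    idx = np.arange(engine.p) if start is None else np.asarray(start, int)
    if engine.n <= len(idx) + 1:
        raise ValueError(
            f"cannot start backward elimination with {len(idx)} variables "
            f"and n = {engine.n}")
    path = []
    while len(idx) >= 1:
        beta, rss = engine.slopes(idx)
        path.append(idx.copy())
        if len(idx) == 1:
            break
        t = engine.slope_tvalues(idx, beta, rss)
        if np.any(t == 0.0):
            warnings.warn(
                "collinear column dropped from backward path: "
                f"{engine.names[idx[int(np.argmin(np.abs(t)))]]}",
                RuntimeWarning, stacklevel=2)
        drop = int(np.argmin(np.abs(t)))
        idx = np.delete(idx, drop)
    return path


# ---------------------------------------------------------------------------
# repeated cross-validation of the model size

def kfold_indices(n: int, k: int, rng: np.random.Generator) -> list[np.ndarray]:
    """Random partition of range(n) into k nearly equal folds."""
    if k < 2:
        raise ValueError("k must be at least 2")
    if k > n:
        raise ValueError(f"k = {k} folds exceed n = {n} observations")
    perm = rng.permutation(n)
    return [np.sort(f) for f in np.array_split(perm, k)]


def rcv_size_curve(X: np.ndarray, y: np.ndarray, names, k: int, repeats: int,
                   rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Validation RMSE per model size from repeated k-fold cross-validation.

    Returns
    -------
    sizes : (p,) array of model sizes 1..p
    rmse : (repeats*k, p) array
        Per-split validation RMSE at each size of that split's backward path.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    if n < 2 * k:
        raise ValueError(f"n = {n} too small for {k}-fold cross-validation")
    rows = []
    for _ in range(repeats):
        for fold in kfold_indices(n, k, rng):
            mask = np.ones(n, dtype=bool)
            mask[fold] = False
            engine = SubsetOLS(X[mask], y[mask], names)
            path = backward_path_indices(engine)
            rmse_by_size = np.full(p, np.nan)
            for idx in path:
                beta, _ = engine.slopes(idx)
                pred = engine.predict(X[fold], idx, beta)
                rmse_by_size[len(idx) - 1] = math.sqrt(
                    float(np.mean((y[fold] - pred) ** 2)))
            rows.append(rmse_by_size)
    return np.arange(1, p + 1), np.asarray(rows)


def choose_size(rmse_matrix: np.ndarray, one_se: bool = True) -> int:
    """Model size from the per-split RMSE matrix.

    Without the one-SE rule, the size minimising the mean RMSE.  With it,
    the smallest size whose mean RMSE is within one standard error of that
    minimum, where SE = SD of the per-split RMSEs at the minimising size
    divided by sqrt(number of splits).
    """
    mean = np.nanmean(rmse_matrix, axis=0)
    best = int(np.nanargmin(mean))
    if not one_se:
        return best + 1
    col = rmse_matrix[:, best]
    col = col[np.isfinite(col)]
    se = float(np.std(col, ddof=1)) / math.sqrt(len(col)) if len(col) > 1 else 0.0
    threshold = mean[best] + se
    for size0 in range(best + 1):
        if mean[size0] <= threshold:
            return size0 + 1
    return best + 1


def rcv_select_engine(X: np.ndarray, y: np.ndarray, names, k: int = 10,
                      repeats: int = 10, rng: np.random.Generator | None = None,
                      one_se: bool = True) -> tuple[np.ndarray, dict]:
    """Select a variable subset by repeated CV over the backward path.

    Returns the chosen column indices (from the full-data backward path at
    the cross-validated size) and a diagnostics dict.
    """
    if rng is None:
        rng = np.random.default_rng()
    sizes, rmse_matrix = rcv_size_curve(X, y, names, k, repeats, rng)
    size = choose_size(rmse_matrix, one_se=one_se)
    engine = SubsetOLS(X, y, names)
    path = backward_path_indices(engine)
    idx = next(p for p in path if len(p) == size)
    info = {
        "sizes": sizes,
        "mean_rmse_by_size": np.nanmean(rmse_matrix, axis=0),
        "chosen_size": size,
        "k": k,
        "repeats": repeats,
        "one_se": one_se,
    }
    return np.sort(idx), info
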