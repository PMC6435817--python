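"""Attribution of soil function to community predictors.

Two complementary routes, mirroring each other:

* a regression random forest with out-of-bag (OOB) permutation importance
  (the "accuracy importance" convention: increase in OOB mean squared error
  when a predictor is permuted, averaged over trees), with significance
  from a response-permutation null; and
* a multiple linear regression with LMG variance decomposition — each
  predictor's share of the model R^2, averaged over all orderings in which
  predictors can enter the model.  Shares are non-negative and sum exactly
  to the full-model R^2.

The forest is built from scikit-learn regression trees with explicit
bootstrap bookkeeping so the OOB sets are available; mtry defaults to
ceil(p/3), the regression-forest convention.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg as sla
from scipy import stats as sps
from sklearn import config_context
from sklearn.tree import DecisionTreeRegressor

from .stats_core import spearman

__all__ = [
    "RfImportanceResult",
    "VarianceDecomposition",
    "rf_importance",
    "variance_decomposition",
    "class_level_contributions",
]

log = logging.getLogger(__name__)


@dataclass
class RfImportanceResult:
    importance: pd.Series        # mean increase in OOB MSE per predictor
    p_values: pd.Series          # response-permutation null exceedance
    n_trees: int
    n_null: int
    seed: int
    oob_r2: float

    def ranking(self) -> list[str]:
        return list(self.importance.sort_values(ascending=False).index)


@dataclass
class VarianceDecomposition:
    shares: pd.Series            # LMG share of explained variance per predictor
    total_r2: float
    signs: pd.Series             # Spearman sign of predictor vs response
    flagged_small: list[str] = field(default_factory=list)


# ---------------------------------------------------------------------------
# Random forest with OOB permutation importance
# ---------------------------------------------------------------------------

def _fit_forest(x: np.ndarray, y: np.ndarray, n_trees: int, mtry: int, rng):
    # float32 design matrix + check_input=False hit the fast path of the
    # underlying tree builder; bootstrap bookkeeping stays explicit so the
    # OOB sets are known exactly
    x32 = np.ascontiguousarray(x, dtype=np.float32)
    y64 = np.ascontiguousarray(y, dtype=np.float64)
    n = x.shape[0]
    trees, oob_masks = [], []
    state = np.random.RandomState(int(rng.integers(0, 2**31 - 1)))
    with config_context(skip_parameter_validation=True, assume_finite=True):
        for _ in range(n_trees):
            boot = rng.integers(0, n, n)
            oob = np.ones(n, dtype=bool)
            oob[boot] = False
            tree = DecisionTreeRegressor(max_features=mtry, random_state=state)
            tree.fit(x32[boot], y64[boot], check_input=False)
            trees.append(tree)
            oob_masks.append(oob)
    return trees, oob_masks


def _oob_importance(trees, oob_masks, x: np.ndarray, y: np.ndarray, rng) -> tuple[np.ndarray, float]:
    """Mean over trees of (permuted-OOB MSE - OOB MSE) per predictor,
    plus the forest-level OOB R^2."""
    p = x.shape[1]
    x = np.ascontiguousarray(x, dtype=np.float32)
    inc = np.zeros(p)
    used = np.zeros(p)
    oob_pred_sum = np.zeros(x.shape[0])
    oob_pred_cnt = np.zeros(x.shape[0])
    for tree, oob in zip(trees, oob_masks):
        if not oob.any():
            continue
        xo = x[oob]
        yo = y[oob]
        m = xo.shape[0]
        # one traversal per tree: [original; permuted predictor 1; ...; p]
        stacked = np.tile(xo, (p + 1, 1))
        for j in range(p):
            rows = slice((j + 1) * m, (j + 2) * m)
            stacked[rows, j] = xo[rng.permutation(m), j]
        pred = tree.tree_.predict(stacked).reshape(p + 1, m)
        mse0 = np.mean((yo - pred[0]) ** 2)
        oob_pred_sum[oob] += pred[0]
        oob_pred_cnt[oob] += 1
        inc += np.mean((yo[None, :] - pred[1:]) ** 2, axis=1) - mse0
        used += 1
    inc = inc / np.maximum(used, 1)
    seen = oob_pred_cnt > 0
    oob_pred = oob_pred_sum[seen] / oob_pred_cnt[seen]
    ss_res = np.sum((y[seen] - oob_pred) ** 2)
    ss_tot = np.sum((y[seen] - y[seen].mean()) ** 2)
    oob_r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else math.nan
    return inc, float(oob_r2)


def rf_importance(
    predictors: pd.DataFrame,
    response,
    n_trees: int = 5000,
    n_null: int = 100,
    seed: int = 0,
) -> RfImportanceResult:
    """OOB permutation importance of each predictor for a numeric response.

    Significance: the forest is refit on ``n_null`` response-permuted
    datasets and each predictor's p-value is the null exceedance
    (1 + #{null >= observed}) / (1 + n_null).
    """
    x = predictors.to_numpy(dtype=float)
    y = np.asarray(response, dtype=float)
    n, p = x.shape
    if n < 20:
        raise ValueError(f"need >= 20 samples, got {n}")
    if np.ptp(y) == 0:
        raise ValueError("response is constant")
    mtry = max(1, math.ceil(p / 3))
    rng = np.random.default_rng(seed)
    trees, oobs = _fit_forest(x, y, n_trees, mtry, rng)
    obs, oob_r2 = _oob_importance(trees, oobs, x, y, rng)
    exceed = np.ones(p)
    for _ in range(n_null):
        yp = y[rng.permutation(n)]
        t_null, o_null = _fit_forest(x, yp, n_trees, mtry, rng)
        null_imp, _ = _oob_importance(t_null, o_null, x, yp, rng)
        exceed += null_imp >= obs - 1e-15
    pvals = exceed / (1.0 + n_null)
    names = list(predictors.columns)
    return RfImportanceResult(
        importance=pd.Series(obs, index=names),
        p_values=pd.Series(pvals, index=names),
        n_trees=n_trees,
        n_null=n_null,
        seed=seed,
        oob_r2=oob_r2,
    )


# ---------------------------------------------------------------------------
# LMG variance decomposition
# ---------------------------------------------------------------------------

def _subset_r2(x: np.ndarray, y: np.ndarray) -> dict[frozenset, float]:
    """R^2 of OLS for every subset of predictor columns."""
    n, p = x.shape
    xc = x - x.mean(axis=0)
    yc = y - y.mean()
    ss_tot = float(yc @ yc)
    cache: dict[frozenset, float] = {frozenset(): 0.0}
    for size in range(1, p + 1):
        for subset in itertools.combinations(range(p), size):
            xs = xc[:, subset]
            beta, *_ = np.linalg.lstsq(xs, yc, rcond=None)
            fitted = xs @ beta
            cache[frozenset(subset)] = float(fitted @ fitted) / ss_tot
    return cache


def variance_decomposition(predictors: pd.DataFrame, response) -> VarianceDecomposition:
    """LMG shares: sequential R^2 of each predictor averaged over all
    orderings (computed by the equivalent subset-average formula)."""
    x = predictors.to_numpy(dtype=float)
    y = np.asarray(response, dtype=float)
    n, p = x.shape
    if p > 10:
        raise ValueError("LMG enumeration limited to <= 10 predictors")
    if n <= p + 2:
        raise ValueError(f"need n > p + 2 (n={n}, p={p})")
    names = list(predictors.columns)
    sd = x.std(axis=0, ddof=1)
    if np.any(sd == 0):
        bad = [names[j] for j in np.where(sd == 0)[0]]
        raise ValueError(f"constant predictor(s): {bad}")
    # R^2 is invariant to per-column affine maps; standardizing makes the
    # aliasing check scale-free
    x = (x - x.mean(axis=0)) / sd
    _check_aliased(x, names)
    r2 = _subset_r2(x, y)
    shares = np.zeros(p)
    for j in range(p):
        others = [k for k in range(p) if k != j]
        for size in range(0, p):
            weight = 1.0 / (p * math.comb(p - 1, size))
            for subset in itertools.combinations(others, size):
                s = frozenset(subset)
                shares[j] += weight * (r2[s | {j}] - r2[s])
    total = r2[frozenset(range(p))]
    signs = pd.Series(
        [np.sign(spearman(x[:, j], y)[0]) for j in range(p)], index=names
    )
    return VarianceDecomposition(
        shares=pd.Series(shares, index=names),
        total_r2=total,
        signs=signs,
    )


def _check_aliased(x: np.ndarray, names) -> None:
    xc = np.column_stack([np.ones(x.shape[0]), x])
    _, r, piv = sla.qr(xc, mode="economic", pivoting=True)
    diag = np.abs(np.diag(r))
    tol = diag[0] * max(xc.shape) * np.finfo(float).eps * 1e3
    bad = [piv[i] for i in range(len(diag)) if diag[i] < tol]
    aliased = sorted(names[i - 1] for i in bad if i > 0)
    if aliased:
        raise ValueError(f"design is singular; aliased columns: {aliased}")


# ---------------------------------------------------------------------------
# Class-level contributions to individual nutrients
# ---------------------------------------------------------------------------

def _forward_select_adjr2(
    x: pd.DataFrame, y: np.ndarray, alpha_enter: float, max_predictors: int
) -> list[str]:
    """Forward selection by adjusted R^2, entry gated on the partial-F p."""
    selected: list[str] = []
    n = len(y)
    ss_tot = float(np.sum((y - y.mean()) ** 2))

    def rss(cols):
        if not cols:
            return ss_tot
        xs = x[cols].to_numpy()
        xs = np.column_stack([np.ones(n), xs])
        beta, *_ = np.linalg.lstsq(xs, y, rcond=None)
        resid = y - xs @ beta
        return float(resid @ resid)

    current_rss = ss_tot
    while len(selected) < min(max_predictors, x.shape[1]):
        best = None
        for name in x.columns:
            if name in selected:
                continue
            r = rss(selected + [name])
            if best is None or r < best[1]:
                best = (name, r)
        name, new_rss = best
        df_res = n - len(selected) - 2
        if df_res < 1 or new_rss <= 0:
            break
        f = (current_rss - new_rss) / (new_rss / df_res)
        p_val = float(sps.f.sf(f, 1, df_res))
        adj_now = 1 - (current_rss / (n - len(selected) - 1)) / (ss_tot / (n - 1))
        adj_new = 1 - (new_rss / df_res) / (ss_tot / (n - 1))
        if p_val > alpha_enter or adj_new <= adj_now:
            break
        selected.append(name)
        current_rss = new_rss
    return selected


def class_level_contributions(
    class_ra: pd.DataFrame,
    nutrients: pd.DataFrame,
    alpha_enter: float = 0.05,
    max_predictors: int = 10,
    small_share: float = 0.005,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Share of explained variance per (taxonomic class, nutrient).

    For each nutrient a best multiple-regression model is chosen by forward
    selection (adjusted R^2 with partial-F entry at ``alpha_enter``), then
    LMG-decomposed.  Returns ``(shares, signs)`` matrices, classes x
    nutrients; shares below ``small_share`` are reported as 0.  Classes
    with zero variance are dropped (logged).
    """
    keep = [c for c in class_ra.columns if class_ra[c].nunique() > 1]
    dropped = [c for c in class_ra.columns if c not in keep]
    if dropped:
        log.info("dropping zero-variance class(es): %s", dropped)
    x = class_ra[keep]
    shares = pd.DataFrame(0.0, index=keep, columns=nutrients.columns)
    signs = pd.DataFrame(0.0, index=keep, columns=nutrients.columns)
    for nutrient in nutrients.columns:
        y = nutrients[nutrient].to_numpy(dtype=float)
        selected = _forward_select_adjr2(x, y, alpha_enter, max_predictors)
        if not selected:
            continue
        vd = variance_decomposition(x[selected], y)
        for cls in selected:
            share = vd.shares[cls]
            shares.loc[cls, nutrient] = 0.0 if share < small_share else share
            signs.loc[cls, nutrient] = vd.signs[cls]
    return shares, signs
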