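"""Distance-matrix statistics: ANOSIM, PERMANOVA (ADONIS), constrained
analysis of principal coordinates (CAP), redundancy reduction of
environmental variables, and the distance-based linear model (DistLM) with
forward selection.

All permutation p-values use the (1 + #{perm >= obs}) / (1 + B) estimator
with an explicit seed, so results are reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .community import DistanceMatrix
from .stats_core import spearman

__all__ = [
    "PermutationTestResult",
    "CapResult",
    "VariableSelection",
    "anosim",
    "permanova",
    "cap",
    "reduce_redundant_variables",
    "distlm_forward",
]


@dataclass(frozen=True)
class PermutationTestResult:
    statistic: float
    p_perm: float
    n_permutations: int
    seed: int
    method: str
    r_squared: float | None = None
    df: tuple | None = None
    term: str | None = None
    degenerate: bool = False


@dataclass
class CapResult:
    sample_ids: list[str]
    coordinates: np.ndarray       # samples x constrained axes
    eigenvalues: np.ndarray       # constrained eigenvalues
    proportion_constrained: float
    pseudo_f: float
    p_model: float
    p_axes: list[float]
    n_permutations: int
    seed: int


@dataclass
class VariableSelection:
    retained: list[str]
    removed_pairs: list[tuple[str, str, float]] = field(default_factory=list)
    order: list[str] = field(default_factory=list)
    marginal_r2: dict = field(default_factory=dict)
    cumulative_r2: list[float] = field(default_factory=list)
    p_values: list[float] = field(default_factory=list)


def _perm_p(obs: float, null: np.ndarray) -> float:
    return (1.0 + np.sum(null >= obs - 1e-12)) / (1.0 + null.size)


def _gower_center(d: np.ndarray) -> np.ndarray:
    a = -0.5 * d**2
    n = d.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    return j @ a @ j


def anosim(dist: DistanceMatrix, groups, n_perm: int = 999, seed: int = 0) -> PermutationTestResult:
    """ANOSIM: R = (mean between-group rank - mean within-group rank) / (M/2),
    M = n(n-1)/2; significance by permuting group labels."""
    groups = np.asarray(groups)
    n = dist.n
    if groups.shape[0] != n:
        raise ValueError("groups length must match distance matrix")
    labels, counts = np.unique(groups, return_counts=True)
    if labels.size < 2:
        raise ValueError("need >= 2 groups")
    if np.any(counts < 2):
        small = labels[counts < 2][0]
        raise ValueError(f"group {small!r} has fewer than 2 samples")
    condensed = dist.condensed()
    ranks = sps.rankdata(condensed)
    iu, ju = np.triu_indices(n, k=1)
    m = condensed.size

    def r_stat(g):
        within = g[iu] == g[ju]
        return (ranks[~within].mean() - ranks[within].mean()) / (m / 2.0)

    obs = r_stat(groups)
    rng = np.random.default_rng(seed)
    null = np.empty(n_perm)
    for b in range(n_perm):
        null[b] = r_stat(groups[rng.permutation(n)])
    return PermutationTestResult(
        statistic=float(obs),
        p_perm=_perm_p(obs, null),
        n_permutations=n_perm,
        seed=seed,
        method="anosim",
    )


def _design_matrices(factors: pd.DataFrame) -> list[tuple[str, np.ndarray]]:
    """One design block per term: dummy coding for categoricals (no
    intercept column; the intercept is added separately), raw column for
    numerics."""
    out = []
    for name in factors.columns:
        col = factors[name]
        if col.dtype.kind in "ifu" and col.nunique() > 2:
            x = col.to_numpy(dtype=float)[:, None]
        else:
            levels = pd.unique(col)
            if len(levels) < 2:
                raise ValueError(f"factor {name!r} has a single level")
            x = np.column_stack(
                [(col == lv).to_numpy(dtype=float) for lv in levels[1:]]
            )
        out.append((name, x))
    return out


def _hat(x: np.ndarray) -> np.ndarray:
    q, r = np.linalg.qr(x)
    rank = np.sum(np.abs(np.diag(r)) > 1e-10 * max(1.0, abs(r[0, 0])))
    q = q[:, : int(rank)]
    return q @ q.T


def permanova(
    dist: DistanceMatrix,
    factors,
    n_perm: int = 999,
    seed: int = 0,
) -> list[PermutationTestResult]:
    """Permutational MANOVA (ADONIS) with sequential sums of squares.

    ``factors`` is a DataFrame (or Series for one term) over the same
    samples; categorical columns are dummy-coded, numeric columns enter as
    covariates.  Returns one result per term, in order.
    """
    if isinstance(factors, pd.Series):
        factors = factors.to_frame()
    factors = factors.loc[dist.sample_ids]
    n = dist.n
    g = _gower_center(dist.values)
    ss_total = float(np.trace(g))
    terms = _design_matrices(factors)
    if ss_total <= 1e-12:
        return [
            PermutationTestResult(np.nan, np.nan, n_perm, seed, "permanova",
                                  r_squared=np.nan, term=name, degenerate=True)
            for name, _ in terms
        ]
    ones = np.ones((n, 1))

    def term_stats(gm: np.ndarray):
        """Sequential SS per term and residual SS for a permuted G."""
        cum = ones
        h_prev = _hat(cum)
        ss, dfs = [], []
        for _, x in terms:
            cum = np.hstack([cum, x])
            h = _hat(cum)
            ss.append(float(np.sum((h - h_prev) * gm.T)))
            dfs.append(int(round(np.trace(h - h_prev))))
            h_prev = h
        ss_res = float(np.sum((np.eye(n) - h_prev) * gm.T))
        df_res = n - int(round(np.trace(h_prev)))
        return ss, dfs, ss_res, df_res

    ss_terms, dfs, ss_res, df_res = term_stats(g)
    if df_res < 1:
        raise ValueError("model saturates the data (no residual df)")
    f_obs = [
        (ss / df_) / (ss_res / df_res) if df_ > 0 else np.nan
        for ss, df_ in zip(ss_terms, dfs)
    ]
    rng = np.random.default_rng(seed)
    null = np.empty((n_perm, len(terms)))
    for b in range(n_perm):
        perm = rng.permutation(n)
        gp = g[np.ix_(perm, perm)]
        ss_p, _, ss_res_p, _ = term_stats(gp)
        null[b] = [
            (s / df_) / (ss_res_p / df_res) if df_ > 0 else np.nan
            for s, df_ in zip(ss_p, dfs)
        ]
    results = []
    for k, (name, _) in enumerate(terms):
        results.append(
            PermutationTestResult(
                statistic=float(f_obs[k]),
                p_perm=_perm_p(f_obs[k], null[:, k]),
                n_permutations=n_perm,
                seed=seed,
                method="permanova",
                r_squared=float(ss_terms[k] / ss_total),
                df=(dfs[k], df_res),
                term=name,
            )
        )
    return results


def cap(
    dist: DistanceMatrix,
    constraints: pd.DataFrame,
    n_perm: int = 999,
    seed: int = 0,
    negative_eigenvalue_correction: str = "truncate",
) -> CapResult:
    """Constrained analysis of principal coordinates.

    Principal-coordinate axes of the distance matrix (negative eigenvalues
    truncated by default; "lingoes" adds the Lingoes constant) are regressed
    on the constraints; the fitted values are eigen-decomposed to give
    constrained axes.  Model significance and per-axis significance come
    from permutation of the rows of the constraint table.
    """
    if isinstance(constraints, pd.Series):
        constraints = constraints.to_frame()
    constraints = constraints.loc[dist.sample_ids]
    n = dist.n
    d = dist.values
    if negative_eigenvalue_correction == "lingoes":
        g0 = _gower_center(d)
        w = np.linalg.eigvalsh(g0)
        c = max(0.0, -float(w.min()))
        if c > 0:
            d = np.sqrt(d**2 + 2 * c)
            np.fill_diagonal(d, 0.0)
    elif negative_eigenvalue_correction != "truncate":
        raise ValueError(f"unknown correction {negative_eigenvalue_correction!r}")
    g = _gower_center(d)
    w, v = np.linalg.eigh(g)
    order = np.argsort(w)[::-1]
    w, v = w[order], v[:, order]
    pos = w > max(1e-10, 1e-10 * abs(w[0]))
    scores = v[:, pos] * np.sqrt(w[pos])      # site scores, n x m

    blocks = _design_matrices(constraints)
    x = np.hstack([np.ones((n, 1))] + [b for _, b in blocks])
    # collinearity check, naming aliased terms
    q, r = np.linalg.qr(x)
    diag = np.abs(np.diag(r))
    if np.any(diag < 1e-10 * max(1.0, diag[0])):
        cols = ["(intercept)"]
        for name, b in blocks:
            cols.extend([name] * b.shape[1])
        aliased = sorted({cols[i] for i in np.where(diag < 1e-10 * max(1.0, diag[0]))[0]})
        raise ValueError(f"constraints collinear to machine precision: {aliased}")
    q_model = int(np.linalg.matrix_rank(x)) - 1  # rank of the non-intercept part

    ss_total = float((scores**2).sum())

    def fit_stats(xmat):
        h = _hat(xmat)
        fitted = h @ scores
        ss_fit = float((fitted**2).sum())
        return fitted, ss_fit

    fitted, ss_fit = fit_stats(x)
    ss_res = ss_total - ss_fit
    df_res = n - 1 - q_model
    f_obs = (ss_fit / q_model) / (ss_res / df_res) if df_res > 0 else np.nan

    # constrained axes: eigen-decomposition of fitted cross-products
    fw, fv = np.linalg.eigh(fitted @ fitted.T)
    forder = np.argsort(fw)[::-1]
    fw, fv = fw[forder], fv[:, forder]
    keep = fw > max(1e-10, 1e-10 * abs(fw[0])) if fw.size else fw > 0
    eig = fw[keep]
    axes = fv[:, keep] * np.sqrt(eig)

    rng = np.random.default_rng(seed)
    null_f = np.empty(n_perm)
    null_ax = np.empty((n_perm, min(2, max(1, eig.size))))
    for b in range(n_perm):
        perm = rng.permutation(n)
        fitted_p, ss_fit_p = fit_stats(x[perm])
        ss_res_p = ss_total - ss_fit_p
        null_f[b] = (ss_fit_p / q_model) / (ss_res_p / df_res)
        pw = np.linalg.eigvalsh(fitted_p @ fitted_p.T)
        pw = np.sort(pw)[::-1]
        for k in range(null_ax.shape[1]):
            null_ax[b, k] = pw[k] if k < pw.size else 0.0
    p_model = _perm_p(f_obs, null_f)
    p_axes = [
        _perm_p(eig[k], null_ax[:, k]) if k < null_ax.shape[1] else np.nan
        for k in range(eig.size)
    ]
    return CapResult(
        sample_ids=list(dist.sample_ids),
        coordinates=axes,
        eigenvalues=eig,
        proportion_constrained=float(ss_fit / ss_total) if ss_total > 0 else 0.0,
        pseudo_f=float(f_obs),
        p_model=p_model,
        p_axes=p_axes,
        n_permutations=n_perm,
        seed=seed,
    )


def reduce_redundant_variables(
    env: pd.DataFrame,
    rho_threshold: float = 0.6,
    priority: tuple = (),
) -> VariableSelection:
    """Drop one member of every redundant pair (|Spearman rho| > threshold).

    Greedy and deterministic: the most correlated offending pair is resolved
    first.  Within a pair the keeper is the member appearing earlier in the
    ``priority`` list; if neither (or both equally) is prioritized, the
    member with the larger mean |rho| against all other variables is
    removed; exact ties resolve alphabetically.
    """
    names = list(env.columns)
    if len(names) < 2:
        raise ValueError("need >= 2 variables")
    k = len(names)
    rho = np.eye(k)
    for i in range(k):
        for j in range(i + 1, k):
            r, _ = spearman(env.iloc[:, i], env.iloc[:, j])
            rho[i, j] = rho[j, i] = 0.0 if np.isnan(r) else r
    absrho = np.abs(rho)
    prio = {name: i for i, name in enumerate(priority)}
    active = list(range(k))
    removed_pairs: list[tuple[str, str, float]] = []
    while True:
        best = None
        for ai, i in enumerate(active):
            for j in active[ai + 1:]:
                if absrho[i, j] > rho_threshold:
                    if best is None or absrho[i, j] > absrho[best]:
                        best = (i, j)
        if best is None:
            break
        i, j = best
        pi, pj = prio.get(names[i], np.inf), prio.get(names[j], np.inf)
        if pi < pj:
            drop = j
        elif pj < pi:
            drop = i
        else:
            others_i = [absrho[i, a] for a in active if a not in (i, j)]
            others_j = [absrho[j, a] for a in active if a not in (i, j)]
            mi = float(np.mean(others_i)) if others_i else 0.0
            mj = float(np.mean(others_j)) if others_j else 0.0
            if mi > mj:
                drop = i
            elif mj > mi:
                drop = j
            else:
                drop = max(i, j, key=lambda a: names[a])
        keep = j if drop == i else i
        removed_pairs.append((names[keep], names[drop], float(rho[i, j])))
        active.remove(drop)
    return VariableSelection(
        retained=[names[i] for i in active],
        removed_pairs=removed_pairs,
    )


def distlm_forward(
    dist: DistanceMatrix,
    env: pd.DataFrame,
    n_perm: int = 999,
    alpha_enter: float = 0.05,
    seed: int = 0,
) -> VariableSelection:
    """Distance-based linear model with forward selection.

    Variables are standardized internally.  At each step the candidate with
    the largest conditional R-squared enters if its permutation p-value
    (conditional pseudo-F; residuals of the candidate on the selected set
    are permuted, Freedman-Lane style) is <= ``alpha_enter``.
    """
    env = env.loc[dist.sample_ids]
    names = list(env.columns)
    n = dist.n
    x_raw = env.to_numpy(dtype=float)
    sd = x_raw.std(axis=0, ddof=1)
    if np.any(sd == 0):
        bad = [names[i] for i in np.where(sd == 0)[0]]
        raise ValueError(f"constant environmental variable(s): {bad}")
    x_all = (x_raw - x_raw.mean(axis=0)) / sd
    g = _gower_center(dist.values)
    ss_total = float(np.trace(g))
    ones = np.ones((n, 1))
    rng = np.random.default_rng(seed)

    def r2_of(cols: list[int], extra: np.ndarray | None = None) -> float:
        mats = [ones]
        if cols:
            mats.append(x_all[:, cols])
        if extra is not None:
            mats.append(extra.reshape(n, -1))
        h = _hat(np.hstack(mats))
        return float(np.sum(h * g.T) / ss_total) - float(
            np.sum(_hat(ones) * g.T) / ss_total
        )

    marginal = {name: r2_of([j]) for j, name in enumerate(names)}
    selected: list[int] = []
    order, cum_r2, p_path = [], [], []
    current_r2 = 0.0
    while len(selected) < len(names):
        candidates = [j for j in range(len(names)) if j not in selected]
        gains = {j: r2_of(selected + [j]) - current_r2 for j in candidates}
        j_best = max(gains, key=lambda j: (gains[j], -j))
        df_model = len(selected) + 1
        df_res = n - 1 - df_model
        if df_res < 1:
            break
        gain = gains[j_best]
        resid_r2 = 1.0 - (current_r2 + gain)
        f_obs = (gain / 1.0) / (resid_r2 / df_res)
        # Freedman-Lane: permute the candidate's residuals on the selected set
        h_sel = _hat(np.hstack([ones] + ([x_all[:, selected]] if selected else [])))
        resid = (np.eye(n) - h_sel) @ x_all[:, j_best]
        fitted_part = h_sel @ x_all[:, j_best]
        null = np.empty(n_perm)
        for b in range(n_perm):
            xp = fitted_part + resid[rng.permutation(n)]
            gain_p = r2_of(selected, extra=xp) - current_r2
            null[b] = (gain_p / 1.0) / ((1.0 - (current_r2 + gain_p)) / df_res)
        p = _perm_p(f_obs, null)
        if p > alpha_enter:
            break
        selected.append(j_best)
        current_r2 += gain
        order.append(names[j_best])
        cum_r2.append(current_r2)
        p_path.append(p)
    return VariableSelection(
        retained=[names[j] for j in selected],
        order=order,
        marginal_r2=marginal,
        cumulative_r2=cum_r2,
        p_values=p_path,
    )
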