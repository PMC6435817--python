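"""Community-level summaries: rarefaction, relative abundance, alpha
diversity, Bray-Curtis dissimilarity, and non-metric multidimensional
scaling (NMDS).

Rarefaction draws without replacement (multivariate hypergeometric), one
draw per sample, which is the standard single-rarefaction workflow.  NMDS
minimizes Kruskal stress-1 by SMACOF majorization with monotone (isotonic)
regression of the dissimilarities, restarted from several configurations;
axes are post-rotated to their principal orientation with a positive-skew
sign rule so they are deterministic given the seed.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from sklearn.isotonic import isotonic_regression

from .data_io import OtuTable, ValidationError

__all__ = [
    "RelAbundanceTable",
    "DistanceMatrix",
    "AlphaDiversity",
    "Ordination",
    "rarefy",
    "relative_abundance",
    "alpha_diversity",
    "bray_curtis",
    "nmds",
]

log = logging.getLogger(__name__)


@dataclass
class RelAbundanceTable:
    """Row-normalized abundance matrix; every row sums to 1."""

    sample_ids: list[str]
    otu_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        sums = self.values.sum(axis=1)
        if np.any(np.abs(sums - 1.0) > 1e-9):
            raise ValidationError("relative-abundance rows must sum to 1")
        if np.any(self.values < 0):
            raise ValidationError("relative abundances must be >= 0")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_otus(self) -> int:
        return len(self.otu_ids)

    def mean_ra(self) -> pd.Series:
        """Mean relative abundance of each OTU across samples."""
        return pd.Series(self.values.mean(axis=0), index=self.otu_ids)

    def occupancy(self) -> pd.Series:
        """Fraction of samples in which each OTU is present (value > 0)."""
        return pd.Series((self.values > 0).mean(axis=0), index=self.otu_ids)

    def select_otus(self, otu_ids) -> "RelAbundanceTable":
        """Subset columns without renormalizing (values keep their scale)."""
        pos = {o: k for k, o in enumerate(self.otu_ids)}
        idx = [pos[o] for o in otu_ids]
        out = object.__new__(RelAbundanceTable)
        out.sample_ids = list(self.sample_ids)
        out.otu_ids = list(otu_ids)
        out.values = self.values[:, idx]
        return out

    def select_samples(self, sample_ids) -> "RelAbundanceTable":
        idx = [self.sample_ids.index(s) for s in sample_ids]
        out = object.__new__(RelAbundanceTable)
        out.sample_ids = list(sample_ids)
        out.otu_ids = list(self.otu_ids)
        out.values = self.values[idx]
        return out

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.sample_ids, columns=self.otu_ids)


@dataclass
class DistanceMatrix:
    sample_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValidationError("distance matrix must be square")
        if not np.allclose(v, v.T, atol=1e-12):
            raise ValidationError("distance matrix must be symmetric")
        if np.any(np.abs(np.diag(v)) > 1e-12):
            raise ValidationError("distance matrix diagonal must be zero")
        self.values = (v + v.T) / 2.0
        np.fill_diagonal(self.values, 0.0)

    @property
    def n(self) -> int:
        return len(self.sample_ids)

    def condensed(self) -> np.ndarray:
        return squareform(self.values, checks=False)


@dataclass
class AlphaDiversity:
    """Per-sample OTU richness and Shannon index."""

    table: pd.DataFrame  # index sample_id, columns ["richness", "shannon"]
    base: str = "e"

    @property
    def richness(self) -> pd.Series:
        return self.table["richness"]

    @property
    def shannon(self) -> pd.Series:
        return self.table["shannon"]


@dataclass
class Ordination:
    sample_ids: list[str]
    coordinates: np.ndarray  # samples x k
    stress: float | None = None
    eigenvalues: np.ndarray | None = None
    converged: bool = True
    stress_path: list[float] = field(default_factory=list)

    def axis(self, k: int) -> pd.Series:
        return pd.Series(self.coordinates[:, k], index=self.sample_ids)


def rarefy(table: OtuTable, depth: int, seed: int) -> OtuTable:
    """Subsample every sample to exactly ``depth`` reads without replacement.

    Samples whose total falls below the depth are dropped (and logged).
    Raises if no sample survives.
    """
    if depth < 1:
        raise ValueError("depth must be >= 1")
    rng = np.random.default_rng(seed)
    sums = table.sample_sums()
    keep = sums >= depth
    n_dropped = int((~keep).sum())
    if n_dropped:
        dropped = [s for s, k in zip(table.sample_ids, keep) if not k]
        log.info("rarefy: dropped %d sample(s) below depth %d: %s",
                 n_dropped, depth, dropped[:10])
    if keep.sum() < 2:
        raise ValidationError(
            f"fewer than 2 samples reach rarefaction depth {depth}"
        )
    out_rows = []
    kept_ids = []
    for i, sid in enumerate(table.sample_ids):
        if not keep[i]:
            continue
        row = table.counts[i]
        if sums[i] == depth:
            out_rows.append(row.copy())
        else:
            out_rows.append(
                rng.multivariate_hypergeometric(row, depth, method="marginals")
            )
        kept_ids.append(sid)
    return OtuTable(kept_ids, list(table.otu_ids), np.asarray(out_rows))


def relative_abundance(table: OtuTable) -> RelAbundanceTable:
    sums = table.sample_sums().astype(float)
    if np.any(sums == 0):
        raise ValidationError("cannot normalize a zero-sum sample")
    return RelAbundanceTable(
        list(table.sample_ids), list(table.otu_ids), table.counts / sums[:, None]
    )


def alpha_diversity(table: OtuTable, base: str = "e") -> AlphaDiversity:
    """Richness (# OTUs with count > 0) and Shannon entropy per sample.

    Shannon is in nats by default; base "2" rescales to bits.
    """
    counts = table.counts.astype(float)
    richness = (counts > 0).sum(axis=1)
    p = counts / counts.sum(axis=1, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(p > 0, p * np.log(p), 0.0)
    shannon = -plogp.sum(axis=1)
    if base == "2":
        shannon = shannon / math.log(2)
    elif base != "e":
        raise ValueError(f"unknown Shannon base {base!r}")
    df = pd.DataFrame(
        {"richness": richness, "shannon": shannon}, index=table.sample_ids
    )
    return AlphaDiversity(df, base=base)


def bray_curtis(relab: RelAbundanceTable) -> DistanceMatrix:
    """Bray-Curtis dissimilarity: 1 - 2*sum(min)/sum(total), in [0, 1]."""
    if relab.n_samples < 2:
        raise ValidationError("need >= 2 samples")
    d = squareform(pdist(relab.values, metric="braycurtis"))
    return DistanceMatrix(list(relab.sample_ids), d)


# ---------------------------------------------------------------------------
# NMDS
# ---------------------------------------------------------------------------

def _stress1(dhat: np.ndarray, dist: np.ndarray) -> float:
    denom = (dist**2).sum()
    if denom == 0:
        return 0.0
    return math.sqrt(((dhat - dist) ** 2).sum() / denom)


def _smacof_run(delta: np.ndarray, x0: np.ndarray, max_iter: int, tol: float):
    """One SMACOF descent with isotonic disparities.  Returns (X, stress,
    converged, stress_path)."""
    n = x0.shape[0]
    order = np.argsort(delta, kind="stable")
    x = x0.copy()
    dist = pdist(x)
    stress_path = []
    prev = np.inf
    converged = False
    for _ in range(max_iter):
        # monotone regression of distances on the dissimilarity order
        dhat = np.empty_like(dist)
        dhat[order] = isotonic_regression(dist[order])
        # normalize disparities to the scale of the distances
        ss = (dhat**2).sum()
        if ss > 0:
            dhat = dhat * math.sqrt((dist**2).sum() / ss)
        stress = _stress1(dhat, dist)
        stress_path.append(stress)
        if prev - stress < tol:
            converged = True
            break
        prev = stress
        # Guttman transform
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = np.where(dist > 0, dhat / dist, 0.0)
        b_flat = -squareform(ratio, checks=False)
        np.fill_diagonal(b_flat, -b_flat.sum(axis=1))
        x = b_flat @ x / n
        x = x - x.mean(axis=0)
        dist = pdist(x)
    return x, stress_path[-1], converged, stress_path


def _principal_orient(x: np.ndarray) -> np.ndarray:
    """Center, rotate to principal axes, and fix signs (positive skew,
    falling back to a positive largest-|value| entry)."""
    x = x - x.mean(axis=0)
    _, _, vt = np.linalg.svd(x, full_matrices=False)
    x = x @ vt.T
    for k in range(x.shape[1]):
        col = x[:, k]
        m3 = ((col - col.mean()) ** 3).mean()
        if abs(m3) > 1e-12:
            if m3 < 0:
                x[:, k] = -col
        elif col[np.argmax(np.abs(col))] < 0:
            x[:, k] = -col
    return x


def nmds(
    dist: DistanceMatrix,
    k: int = 2,
    n_starts: int = 4,
    max_iter: int = 300,
    tol: float = 1e-7,
    seed: int = 0,
) -> Ordination:
    """Non-metric MDS of a distance matrix into k axes.

    Best of ``n_starts`` runs (the first initialized from classical scaling,
    the rest random); reports Kruskal stress-1.
    """
    n = dist.n
    if n < k + 1:
        raise ValueError(f"need at least k+1 = {k + 1} samples")
    delta = dist.condensed()
    rng = np.random.default_rng(seed)

    # classical-scaling (PCoA) initialization
    d2 = squareform(delta) ** 2
    j = np.eye(n) - np.ones((n, n)) / n
    g = -0.5 * j @ d2 @ j
    w, v = np.linalg.eigh(g)
    idx = np.argsort(w)[::-1][:k]
    init = v[:, idx] * np.sqrt(np.clip(w[idx], 0, None))

    best = None
    for s in range(n_starts):
        x0 = init if s == 0 else rng.standard_normal((n, k))
        x, stress, conv, path = _smacof_run(delta, x0, max_iter, tol)
        if best is None or stress < best[1]:
            best = (x, stress, conv, path)
    x, stress, conv, path = best
    if not conv:
        log.warning("NMDS did not converge in %d iterations", max_iter)
    # stress-1 is scale-free, so the configuration scale can drift during
    # majorization; pin it to the dissimilarity scale
    ms = (pdist(x) ** 2).mean()
    if ms > 0:
        x = x * math.sqrt((delta**2).mean() / ms)
    return Ordination(
        list(dist.sample_ids),
        _principal_orient(x),
        stress=stress,
        converged=conv,
        stress_path=path,
    )
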