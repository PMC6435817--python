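"""Core-microbiota identification and ecological-cluster assignment.

A taxon is core when it is simultaneously highly abundant — in the top
decile of OTUs ranked by mean relative abundance across all samples — and
ubiquitous — present in more than 80% of samples.  Core taxa are then
grouped into ecological clusters by their habitat preference: the Spearman
correlation of their relative abundance with soil pH and with mean annual
temperature (MAT).  Among significant correlations the driver with the
larger |rho| wins (pH on an exact tie); the sign of rho gives the high/low
polarity.  Taxa with no significant correlation stay unassigned.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .community import RelAbundanceTable
from .stats_core import linear_regression, spearman

__all__ = [
    "CoreSet",
    "CLUSTERS",
    "identify_core",
    "assign_ecological_clusters",
    "cluster_relative_abundance",
    "cluster_env_regression",
]

log = logging.getLogger(__name__)

CLUSTERS = ("high_pH", "low_pH", "high_MAT", "low_MAT")
UNASSIGNED = "unassigned"


@dataclass
class CoreSet:
    """Per-OTU core membership, occupancy/abundance statistics, and (after
    assignment) driver correlations and ecological-cluster labels."""

    table: pd.DataFrame  # index otu_id; columns mean_ra, occupancy, is_core,
    #                      rho_pH, p_pH, rho_MAT, p_MAT, cluster
    abundance_quantile: float
    occupancy_min: float

    @property
    def core_otus(self) -> list[str]:
        return list(self.table.index[self.table["is_core"]])

    @property
    def n_core(self) -> int:
        return int(self.table["is_core"].sum())

    def members(self, cluster: str) -> list[str]:
        return list(self.table.index[self.table["cluster"] == cluster])


def identify_core(
    relab: RelAbundanceTable,
    abundance_quantile: float = 0.90,
    occupancy_min: float = 0.80,
    strict_occupancy: bool = True,
) -> CoreSet:
    """Apply the two occupancy-abundance criteria to every OTU.

    The abundance criterion takes the top ``ceil((1 - quantile) * n_otus)``
    OTUs by mean relative abundance (ties broken by OTU id for
    determinism); the occupancy criterion requires presence in more than
    ``occupancy_min`` of samples (``>=`` when ``strict_occupancy=False``).
    """
    if relab.n_samples < 5:
        raise ValueError("need >= 5 samples to define a core")
    mean_ra = relab.mean_ra()
    occupancy = relab.occupancy()
    n = relab.n_otus
    k = int(math.ceil((1.0 - abundance_quantile) * n))
    ranked = mean_ra.to_frame("mean_ra")
    ranked["otu"] = ranked.index
    ranked = ranked.sort_values(["mean_ra", "otu"], ascending=[False, True])
    top = set(ranked.index[:k])
    if strict_occupancy:
        ubiquitous = occupancy > occupancy_min
    else:
        ubiquitous = occupancy >= occupancy_min
    is_core = mean_ra.index.isin(top) & ubiquitous.to_numpy()
    if not is_core.any():
        log.warning("core set is empty under the given thresholds")
    table = pd.DataFrame(
        {
            "mean_ra": mean_ra,
            "occupancy": occupancy,
            "is_core": is_core,
            "rho_pH": np.nan,
            "p_pH": np.nan,
            "rho_MAT": np.nan,
            "p_MAT": np.nan,
            "cluster": UNASSIGNED,
        }
    )
    return CoreSet(table, abundance_quantile, occupancy_min)


def assign_ecological_clusters(
    core_set: CoreSet,
    relab: RelAbundanceTable,
    pH,
    MAT,
    alpha: float = 0.05,
) -> CoreSet:
    """Label each core OTU with its preferred driver and polarity.

    Candidates are the drivers whose Spearman correlation with the OTU's
    relative abundance has p < alpha; the candidate with the larger |rho|
    is assigned (pH wins an exact tie), its sign giving high/low.
    """
    pH = np.asarray(pH, dtype=float)
    MAT = np.asarray(MAT, dtype=float)
    if np.ptp(pH[~np.isnan(pH)]) == 0 or np.ptp(MAT[~np.isnan(MAT)]) == 0:
        raise ValueError("driver variable is constant")
    tbl = core_set.table.copy()
    pos = {o: j for j, o in enumerate(relab.otu_ids)}
    for otu in core_set.core_otus:
        x = relab.values[:, pos[otu]]
        rho_ph, p_ph = spearman(x, pH)
        rho_mat, p_mat = spearman(x, MAT)
        tbl.loc[otu, ["rho_pH", "p_pH", "rho_MAT", "p_MAT"]] = (
            rho_ph, p_ph, rho_mat, p_mat,
        )
        candidates = []
        if not np.isnan(p_ph) and p_ph < alpha:
            candidates.append(("pH", rho_ph))
        if not np.isnan(p_mat) and p_mat < alpha:
            candidates.append(("MAT", rho_mat))
        if not candidates:
            tbl.loc[otu, "cluster"] = UNASSIGNED
            continue
        # larger |rho| wins; candidates[] order makes pH win exact ties
        driver, rho = max(candidates, key=lambda c: abs(c[1]))
        tbl.loc[otu, "cluster"] = ("high_" if rho > 0 else "low_") + driver
    return CoreSet(tbl, core_set.abundance_quantile, core_set.occupancy_min)


def cluster_relative_abundance(
    relab: RelAbundanceTable, core_set: CoreSet
) -> pd.DataFrame:
    """Per-sample summed relative abundance of each ecological cluster."""
    out = pd.DataFrame(0.0, index=relab.sample_ids, columns=list(CLUSTERS))
    pos = {o: j for j, o in enumerate(relab.otu_ids)}
    for cluster in CLUSTERS:
        members = [o for o in core_set.members(cluster) if o in pos]
        if members:
            idx = [pos[o] for o in members]
            out[cluster] = relab.values[:, idx].sum(axis=1)
    return out


def cluster_env_regression(cluster_ra: pd.DataFrame, drivers: pd.DataFrame) -> pd.DataFrame:
    """OLS of each cluster's summed relative abundance on its defining driver.

    ``drivers`` must hold columns "pH" and "MAT" over the same samples.
    Returns one row per cluster with slope, intercept, R^2 and p; clusters
    with constant abundance are flagged with R^2 = 0 and p = NaN.
    """
    drivers = drivers.loc[cluster_ra.index]
    rows = {}
    for cluster in cluster_ra.columns:
        driver = "pH" if cluster.endswith("pH") else "MAT"
        y = cluster_ra[cluster].to_numpy(dtype=float)
        x = drivers[driver].to_numpy(dtype=float)
        if np.ptp(y) == 0:
            rows[cluster] = {
                "driver": driver, "slope": 0.0, "intercept": float(y[0]),
                "r2": 0.0, "p": np.nan, "constant": True,
            }
            continue
        slope, intercept, r2, p = linear_regression(x, y)
        rows[cluster] = {
            "driver": driver, "slope": slope, "intercept": intercept,
            "r2": r2, "p": p, "constant": False,
        }
    return pd.DataFrame.from_dict(rows, orient="index")
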