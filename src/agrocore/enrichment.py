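"""Habitat-enrichment classification of OTUs.

Each OTU's relative abundance is compared between the maize and rice
members of the complete site pairs with a paired t test; the sign of the
mean difference classifies significant OTUs as maize- or rice-enriched,
everything else is "other".  Classifications are verified with a
Kruskal-Wallis test, and per-sample summaries (number of detected enriched
OTUs, their summed relative abundance) feed the trend-versus-MAT
regressions.

The default follows the construction rule literally (raw p < 0.05, no
multiplicity correction); pass ``fdr=True`` for BH-corrected
classification, which is the statistically safer choice.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .community import RelAbundanceTable
from .data_io import SampleMetadata
from .stats_core import bh_fdr, linear_regression

__all__ = ["EnrichmentResult", "paired_enrichment", "enriched_trend_vs_env"]

CLASSES = ("maize", "rice", "other")


@dataclass
class EnrichmentResult:
    per_otu: pd.DataFrame       # index otu_id: class, t, p, q, kw_p, mean_diff
    per_sample: pd.DataFrame    # index sample_id: n_maize_enriched, ra_maize_enriched, ...
    n_pairs: int
    alpha: float
    fdr: bool

    def members(self, cls: str) -> list[str]:
        return list(self.per_otu.index[self.per_otu["class"] == cls])


def paired_enrichment(
    relab: RelAbundanceTable,
    metadata: SampleMetadata,
    alpha: float = 0.05,
    fdr: bool = False,
    log_transform: bool = False,
) -> EnrichmentResult:
    """Classify every OTU as maize-enriched, rice-enriched, or other.

    ``log_transform=True`` runs the paired t on log(RA + pseudocount)
    instead of raw relative abundances.
    """
    pairs = metadata.complete_pairs()
    pairs = pairs[
        pairs["maize"].isin(relab.sample_ids) & pairs["rice"].isin(relab.sample_ids)
    ]
    n_pairs = len(pairs)
    if n_pairs < 3:
        raise ValueError(f"need >= 3 complete maize-rice pairs, got {n_pairs}")
    maize = relab.select_samples(list(pairs["maize"])).values
    rice = relab.select_samples(list(pairs["rice"])).values
    if log_transform:
        pseudo = relab.values[relab.values > 0].min() / 2.0
        maize = np.log(maize + pseudo)
        rice = np.log(rice + pseudo)

    d = maize - rice                     # pairs x OTUs
    mean_d = d.mean(axis=0)
    sd_d = d.std(axis=0, ddof=1)
    absent = (maize == 0).all(axis=0) & (rice == 0).all(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean_d / (sd_d / np.sqrt(n_pairs))
    undefined = (sd_d == 0) | absent
    p = np.where(
        undefined, np.nan, 2.0 * sps.t.sf(np.abs(np.where(undefined, 0.0, t)), df=n_pairs - 1)
    )
    q = np.full_like(p, np.nan)
    tested = ~np.isnan(p)
    if tested.any():
        q[tested] = bh_fdr(p[tested])
    crit = q if fdr else p
    classes = np.full(relab.n_otus, "other", dtype=object)
    sig = tested & (crit < alpha)
    classes[sig & (mean_d > 0)] = "maize"
    classes[sig & (mean_d < 0)] = "rice"

    # Kruskal-Wallis verification on the classified OTUs
    kw_p = np.full(relab.n_otus, np.nan)
    for j in np.where(classes != "other")[0]:
        a, b = maize[:, j], rice[:, j]
        if np.ptp(np.concatenate([a, b])) > 0:
            kw_p[j] = sps.kruskal(a, b).pvalue

    per_otu = pd.DataFrame(
        {
            "class": classes,
            "t": np.where(undefined, np.nan, t),
            "p": p,
            "q": q,
            "kw_p": kw_p,
            "mean_diff": mean_d,
            "undefined": undefined,
        },
        index=relab.otu_ids,
    )
    per_sample = _per_sample_summaries(relab, per_otu)
    return EnrichmentResult(per_otu, per_sample, n_pairs, alpha, fdr)


def _per_sample_summaries(relab: RelAbundanceTable, per_otu: pd.DataFrame) -> pd.DataFrame:
    out = pd.DataFrame(index=relab.sample_ids)
    otu_pos = {o: j for j, o in enumerate(relab.otu_ids)}
    for cls in ("maize", "rice"):
        members = [otu_pos[o] for o in per_otu.index[per_otu["class"] == cls]]
        if members:
            block = relab.values[:, members]
            out[f"n_{cls}_enriched"] = (block > 0).sum(axis=1)
            out[f"ra_{cls}_enriched"] = block.sum(axis=1)
        else:
            out[f"n_{cls}_enriched"] = 0
            out[f"ra_{cls}_enriched"] = 0.0
    return out


def enriched_trend_vs_env(
    result: EnrichmentResult,
    metadata: SampleMetadata,
    env_var: str = "MAT",
) -> pd.DataFrame:
    """Regress each per-sample enrichment summary on an environmental
    variable, separately per habitat.

    Returns one row per (habitat, summary column) with slope, R^2 and p.
    """
    rows = []
    for habitat in ("maize", "rice"):
        samples = [
            s for s in result.per_sample.index
            if s in metadata.table.index and metadata.table.loc[s, "habitat"] == habitat
        ]
        if len(samples) < 3:
            continue
        x = metadata.variable(env_var, samples).to_numpy()
        for col in result.per_sample.columns:
            y = result.per_sample.loc[samples, col].to_numpy(dtype=float)
            if np.ptp(y) == 0 or np.ptp(x) == 0:
                rows.append({
                    "habitat": habitat, "summary": col, "slope": 0.0,
                    "r2": 0.0, "p": np.nan, "n": len(samples),
                })
                continue
            slope, _, r2, p = linear_regression(x, y)
            rows.append({
                "habitat": habitat, "summary": col, "slope": slope,
                "r2": r2, "p": p, "n": len(samples),
            })
    return pd.DataFrame(rows)
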