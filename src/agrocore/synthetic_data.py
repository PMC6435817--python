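"""Synthetic paired-site surveys with known ground truth.

The generator emulates the study design the analysis pipeline expects: a
continental transect of paired maize/rice fields spanning latitude (hence
mean annual temperature, MAT) and an independent pH gradient, with

* planted core OTUs of high mean abundance and near-complete occupancy,
* log-linear OTU niche responses to pH or MAT (signed effect sizes),
* habitat-enrichment log-fold-changes on a subset of OTUs,
* correlated OTU blocks (a shared latent factor per block and sample)
  whose members also share a niche driver — co-occurring taxa share
  habitat preferences, and
* nutrient variables statistically coupled, per habitat, either to
  alpha diversity (Shannon) or to the first latent composition factor.

Counts are drawn multinomially per sample from log-linear expected
abundances (log-normal baseline), at a sample-specific sequencing depth.
Everything is keyed on one seed; the same seed reproduces the data
bit-for-bit.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data_io import (
    MNC_NUTRIENTS,
    OtuTable,
    SampleMetadata,
    TaxonomyTable,
    TAXONOMY_RANKS,
)

__all__ = [
    "SimulationParams",
    "SimulationTruth",
    "generate_metadata",
    "generate_community",
    "generate_nutrients",
    "generate_taxonomy",
    "generate_dataset",
]

DRIVER_LABELS = ("high_pH", "low_pH", "high_MAT", "low_MAT")

# Per-nutrient output scaling: (transform, location, scale).  "exp" yields
# right-skewed mg/kg-style values (log-recoverable), "linear" stays Gaussian.
NUTRIENT_SCALES = {
    "DOC": ("linear", 150.0, 30.0),
    "AN": ("linear", 100.0, 25.0),
    "NO3": ("exp", 2.5, 0.6),
    "NH4": ("exp", 2.0, 0.5),
    "AP": ("exp", 2.8, 0.7),
    "AK": ("linear", 120.0, 30.0),
    "AS": ("linear", 25.0, 6.0),
    "AFe": ("exp", 3.3, 0.6),
}


@dataclass
class SimulationParams:
    """Knobs of the generative model; defaults are the study conditions."""

    n_sites: int = 60
    fraction_paired: float = 1.0
    lat_range: tuple = (18.30, 48.35)
    lon_range: tuple = (87.61, 99.91)
    mat_intercept: float = 36.0       # MAT = a - b * latitude + noise (degC)
    mat_slope: float = 0.8
    mat_noise_sd: float = 1.0
    map_intercept: float = 2800.0     # MAP in mm
    map_slope: float = 50.0
    map_noise_sd: float = 150.0
    ph_base: float = 4.5              # pH rises along the longitude gradient
    ph_gradient: float = 3.5
    ph_noise_sd: float = 0.5
    pair_jitter_deg: float = 0.02     # < 5 km equivalent

    n_otus: int = 400
    n_core: int = 40
    base_mu: float = 0.0              # log-normal baseline, non-core
    base_sigma: float = 1.0
    core_base_mu: float = 2.8         # planted core: high, tight baseline
    core_base_sigma: float = 0.3
    # niche slopes on the log scale, in absolute units; the reference noise
    # scale is idio_sd, so the core default is a 2-sigma effect
    beta_core: float = 1.0
    beta_other: float = 0.5
    other_niche_fraction: float = 0.5
    enrich_fraction: float = 0.2      # of non-core OTUs
    enrich_lfc: float = 1.5
    n_blocks: int = 4
    block_size: int = 8
    rho_block: float = 0.9
    sigma_block: float = 1.0
    idio_sd: float = 0.5              # idiosyncratic log-abundance noise
    core_share_mean: float = 0.68     # fraction of sequences in core taxa
    core_share_sd: float = 0.04
    evenness_sd: float = 0.0          # per-sample evenness jitter (log-scale)
    unimodal_niche: bool = False      # Gaussian instead of log-linear response
    depth_mean: float = 20000.0
    depth_sd: float = 2000.0
    depth_min: int = 5000

    coupling_modes: dict = field(
        default_factory=lambda: {"maize": "alpha", "rice": "beta"}
    )
    gamma: float = 1.0                # nutrient-community coupling strength
    nutrient_noise_sd: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("mat_noise_sd", "map_noise_sd", "ph_noise_sd",
                     "base_sigma", "core_base_sigma", "idio_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not (0 < self.fraction_paired <= 1):
            raise ValueError("fraction_paired must be in (0, 1]")
        if self.n_core > self.n_otus:
            raise ValueError("n_core cannot exceed n_otus")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class SimulationTruth:
    """Ground truth of one simulated survey."""

    per_otu: pd.DataFrame        # is_core, niche (cluster label or 'none'),
    #                              beta (signed), enrich_lfc, block_id
    coupling_modes: dict         # habitat -> 'alpha' | 'beta'
    gamma: float
    seed: int
    latent_factors: dict = field(default_factory=dict)  # habitat -> pd.Series
    shannon_latent: dict = field(default_factory=dict)  # habitat -> pd.Series

    @property
    def core_otus(self) -> list[str]:
        return list(self.per_otu.index[self.per_otu["is_core"]])

    def independent_otus(self) -> list[str]:
        """OTUs with no planted structure at all."""
        t = self.per_otu
        mask = (
            ~t["is_core"]
            & (t["niche"] == "none")
            & (t["enrich_lfc"] == 0.0)
            & t["block_id"].isna()
        )
        return list(t.index[mask])

    def to_json_dict(self) -> dict:
        return {
            "per_otu": self.per_otu.reset_index().to_dict(orient="list"),
            "coupling_modes": self.coupling_modes,
            "gamma": self.gamma,
            "seed": self.seed,
        }


def _site_frame(params: SimulationParams, rng) -> pd.DataFrame:
    n = params.n_sites
    lat = rng.uniform(*params.lat_range, n)
    lon = rng.uniform(*params.lon_range, n)
    mat = params.mat_intercept - params.mat_slope * lat + rng.normal(
        0, params.mat_noise_sd, n
    )
    map_ = np.maximum(
        params.map_intercept - params.map_slope * lat
        + rng.normal(0, params.map_noise_sd, n),
        50.0,
    )
    lo, hi = params.lon_range
    ph = params.ph_base + params.ph_gradient * (lon - lo) / (hi - lo) + rng.normal(
        0, params.ph_noise_sd, n
    )
    ph = np.clip(ph, 3.5, 9.5)
    soil = np.where(lat >= 40, "black", np.where(lat >= 30, "brown", "red"))
    return pd.DataFrame(
        {"latitude": lat, "longitude": lon, "MAT": mat, "MAP": map_,
         "pH": ph, "soil_type": soil}
    )


def generate_metadata(params: SimulationParams) -> SampleMetadata:
    """Paired maize/rice samples along the latitude (MAT) and pH gradients.

    Paired samples share site coordinates up to a < 5 km jitter; nutrient
    columns are created empty (NA) and filled by ``generate_nutrients``.
    """
    if params.n_sites < 3:
        raise ValueError("need n_sites >= 3")
    rng = np.random.default_rng(params.seed)
    sites = _site_frame(params, rng)
    n_paired = int(round(params.fraction_paired * params.n_sites))
    rows = []
    for i in range(params.n_sites):
        site = sites.iloc[i]
        site_id = f"S{i + 1:03d}"
        paired = i < n_paired
        habs = ("maize", "rice") if paired else (("maize",) if i % 2 == 0 else ("rice",))
        for hab in habs:
            jit = rng.uniform(-params.pair_jitter_deg, params.pair_jitter_deg, 2)
            rows.append({
                "sample_id": f"{site_id}{'M' if hab == 'maize' else 'R'}",
                "site_id": site_id,
                "pair_id": f"P{i + 1:03d}" if paired else None,
                "habitat": hab,
                "latitude": site["latitude"] + jit[0],
                "longitude": site["longitude"] + jit[1],
                "MAT": site["MAT"],
                "MAP": site["MAP"],
                "soil_type": site["soil_type"],
                "pH": site["pH"],
            })
    df = pd.DataFrame(rows).set_index("sample_id")
    for nutrient in MNC_NUTRIENTS:
        df[nutrient] = np.nan
    return SampleMetadata(df)


def _assign_truth(params: SimulationParams, rng) -> pd.DataFrame:
    n, n_core = params.n_otus, params.n_core
    otu_ids = [f"OTU{j + 1:04d}" for j in range(n)]
    is_core = np.zeros(n, dtype=bool)
    is_core[:n_core] = True

    niche = np.array(["none"] * n, dtype=object)
    beta = np.zeros(n)
    # core OTUs: drivers round-robin across the four clusters
    for j in range(n_core):
        label = DRIVER_LABELS[j % 4]
        niche[j] = label
        beta[j] = params.beta_core if label.startswith("high") else -params.beta_core
    # a fraction of the others get weaker niche preferences
    others = np.arange(n_core, n)
    n_niche_other = int(round(params.other_niche_fraction * others.size))
    chosen = rng.choice(others, n_niche_other, replace=False)
    for j in chosen:
        label = DRIVER_LABELS[rng.integers(0, 4)]
        niche[j] = label
        sign = 1.0 if label.startswith("high") else -1.0
        beta[j] = sign * abs(rng.normal(params.beta_other, params.beta_other / 3))

    # correlated blocks share a niche driver; up to three core blocks, the
    # fourth among (non-enriched) other OTUs kept above the rare filter
    block_id = np.full(n, np.nan)
    n_core_blocks = min(3, params.n_blocks)
    for b in range(n_core_blocks):
        drv = DRIVER_LABELS[b]
        members = [j for j in range(n_core) if niche[j] == drv][: params.block_size]
        block_id[members] = b
    noncore_members = np.array([], dtype=int)
    if params.n_blocks > 3:
        other_pool = [j for j in others if j not in set(chosen)]
        noncore_members = rng.choice(other_pool, params.block_size, replace=False)
        block_id[noncore_members] = n_core_blocks
        drv = DRIVER_LABELS[3]
        for j in noncore_members:
            niche[j] = drv
            beta[j] = -params.beta_other

    # habitat enrichment on non-core, non-block OTUs
    enrich = np.zeros(n)
    pool = [j for j in others if np.isnan(block_id[j])]
    n_enriched = int(round(params.enrich_fraction * len(others)))
    enriched = rng.choice(pool, min(n_enriched, len(pool)), replace=False)
    signs = rng.permutation(
        np.repeat([1.0, -1.0], [enriched.size - enriched.size // 2, enriched.size // 2])
    )
    enrich[enriched] = signs * params.enrich_lfc  # >0 = rice-enriched

    base = rng.normal(params.base_mu, params.base_sigma, n)
    base[:n_core] = rng.normal(params.core_base_mu, params.core_base_sigma, n_core)
    if noncore_members.size:
        # keep the non-core block comfortably above the 0.01% filter
        base[noncore_members] = rng.normal(1.5, 0.3, noncore_members.size)

    return pd.DataFrame(
        {
            "is_core": is_core,
            "niche": niche,
            "beta": beta,
            "enrich_lfc": enrich,
            "block_id": block_id,
            "base": base,
        },
        index=otu_ids,
    )


def _zscore_vec(v: np.ndarray) -> np.ndarray:
    return (v - v.mean()) / v.std(ddof=1)


def generate_community(
    metadata: SampleMetadata, params: SimulationParams
) -> tuple[OtuTable, SimulationTruth]:
    """Draw the count table and record the ground truth.

    The latent log abundance of OTU j in sample i is
    ``base_j + beta_j * driver_z_i + enrich_j * 1[rice] + block term``,
    plus idiosyncratic noise; an optional per-sample evenness jitter
    rescales the (centered) log abundances.  Composition is hierarchical:
    a per-sample core share (stable around ``core_share_mean``, emulating
    the large, stable fraction of sequences the core carries) is divided
    within the core by softmax of the latent log abundances, and the
    remainder likewise within the non-core group, so group-level abundance
    swings do not leak compositional correlation into unrelated taxa.
    Counts are multinomial at the sample's sequencing depth.
    """
    rng = np.random.default_rng(params.seed + 1)
    truth_tbl = _assign_truth(params, rng)
    meta = metadata.table
    n_s = len(meta)
    n_o = params.n_otus

    z_ph = _zscore_vec(meta["pH"].to_numpy(dtype=float))
    z_mat = _zscore_vec(meta["MAT"].to_numpy(dtype=float))
    driver_z = np.zeros((n_s, n_o))
    for j, (niche, _) in enumerate(zip(truth_tbl["niche"], truth_tbl["beta"])):
        if niche == "none":
            continue
        z = z_ph if niche.endswith("pH") else z_mat
        driver_z[:, j] = z
    beta = truth_tbl["beta"].to_numpy()
    if params.unimodal_niche:
        # Gaussian response centred where the log-linear one is largest
        opt = np.sign(beta) * 1.5
        resp = -np.abs(beta)[None, :] * (driver_z - opt[None, :]) ** 2 / 2.0
        niche_term = np.where(beta[None, :] != 0, resp, 0.0)
    else:
        niche_term = beta[None, :] * driver_z

    is_rice = (meta["habitat"] == "rice").to_numpy(dtype=float)
    enrich_term = is_rice[:, None] * truth_tbl["enrich_lfc"].to_numpy()[None, :]

    block_term = np.zeros((n_s, n_o))
    block_ids = truth_tbl["block_id"].to_numpy()
    for b in np.unique(block_ids[~np.isnan(block_ids)]):
        members = np.where(block_ids == b)[0]
        f = rng.standard_normal(n_s)
        eps = rng.standard_normal((n_s, members.size))
        block_term[:, members] = params.sigma_block * (
            np.sqrt(params.rho_block) * f[:, None]
            + np.sqrt(1.0 - params.rho_block) * eps
        )

    log_lambda = (
        truth_tbl["base"].to_numpy()[None, :]
        + niche_term
        + enrich_term
        + block_term
        + rng.normal(0, params.idio_sd, (n_s, n_o))
    )
    tau = np.exp(rng.normal(0, params.evenness_sd, n_s))
    log_lambda = (log_lambda - log_lambda.mean(axis=1, keepdims=True)) * tau[:, None]

    core_mask = truth_tbl["is_core"].to_numpy()
    share = np.clip(
        rng.normal(params.core_share_mean, params.core_share_sd, n_s), 0.2, 0.95
    )
    probs = np.empty((n_s, n_o))
    for mask, frac in ((core_mask, share), (~core_mask, 1.0 - share)):
        block = log_lambda[:, mask]
        w = np.exp(block - block.max(axis=1, keepdims=True))
        probs[:, mask] = frac[:, None] * w / w.sum(axis=1, keepdims=True)
    depths = np.maximum(
        rng.normal(params.depth_mean, params.depth_sd, n_s), params.depth_min
    ).astype(int)
    if np.any(depths < 100):
        import warnings

        warnings.warn("sequencing depth < 100; rarefaction will be degenerate")
    counts = np.empty((n_s, n_o), dtype=np.int64)
    for i in range(n_s):
        counts[i] = rng.multinomial(depths[i], probs[i])

    table = OtuTable(list(meta.index), list(truth_tbl.index), counts)

    # latent composition factor per habitat: first left singular vector of
    # the centred latent log-abundance matrix
    latent_factors = {}
    shannon_latent = {}
    log_probs = np.log(probs)
    for hab in ("maize", "rice"):
        rows = np.where((meta["habitat"] == hab).to_numpy())[0]
        block = log_probs[rows]
        centred = block - block.mean(axis=0, keepdims=True)
        u, s, _ = np.linalg.svd(centred, full_matrices=False)
        pc1 = u[:, 0] * s[0]
        # deterministic sign: positive correlation with its largest loading
        if pc1[np.argmax(np.abs(pc1))] < 0:
            pc1 = -pc1
        latent_factors[hab] = pd.Series(
            _zscore_vec(pc1), index=meta.index[rows]
        )
        p = probs[rows]
        with np.errstate(divide="ignore", invalid="ignore"):
            sh = -np.nansum(np.where(p > 0, p * np.log(p), 0.0), axis=1)
        shannon_latent[hab] = pd.Series(sh, index=meta.index[rows])

    truth = SimulationTruth(
        per_otu=truth_tbl,
        coupling_modes=dict(params.coupling_modes),
        gamma=params.gamma,
        seed=params.seed,
        latent_factors=latent_factors,
        shannon_latent=shannon_latent,
    )
    return table, truth


def generate_nutrients(
    metadata: SampleMetadata,
    otu_table: OtuTable,
    truth: SimulationTruth,
    params: SimulationParams,
) -> SampleMetadata:
    """Fill the eight nutrient columns, coupled to the community.

    In an alpha-mode habitat every nutrient tracks standardized Shannon
    diversity of the realized counts; in a beta-mode habitat it tracks the
    first latent composition factor.  Coupling strength is ``gamma`` and
    the noise standard deviation ``nutrient_noise_sd``; raw signals are then
    mapped to realistic per-nutrient units (some log-normal, some linear).
    """
    rng = np.random.default_rng(params.seed + 2)
    meta = metadata.table.copy()
    counts = otu_table.counts.astype(float)
    p = counts / counts.sum(axis=1, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        shannon = -np.nansum(np.where(p > 0, p * np.log(p), 0.0), axis=1)
    shannon = pd.Series(shannon, index=otu_table.sample_ids)

    for hab, mode in params.coupling_modes.items():
        samples = [s for s in meta.index if meta.loc[s, "habitat"] == hab]
        if not samples:
            continue
        if mode == "alpha":
            signal = _zscore_vec(shannon.loc[samples].to_numpy())
        elif mode == "beta":
            signal = truth.latent_factors[hab].loc[samples].to_numpy()
        else:
            raise ValueError(f"unknown coupling mode {mode!r}")
        for nutrient in MNC_NUTRIENTS:
            raw = params.gamma * signal + rng.normal(
                0, params.nutrient_noise_sd, len(samples)
            )
            kind, loc, scale = NUTRIENT_SCALES[nutrient]
            if kind == "exp":
                vals = np.exp(loc + scale * _zscore_vec(raw))
            else:
                vals = np.maximum(loc + scale * _zscore_vec(raw), loc * 0.05)
            meta.loc[samples, nutrient] = vals
    return SampleMetadata(meta)


def generate_taxonomy(truth: SimulationTruth, params: SimulationParams) -> TaxonomyTable:
    """Arbitrary but structured lineage labels.

    Core OTUs of one ecological cluster share a class (so class-level
    aggregates inherit the cluster's environmental coupling); the rest are
    spread over four further classes.
    """
    rng = np.random.default_rng(params.seed + 3)
    core_class = {
        "high_pH": "HighPHCoreClass",
        "low_pH": "LowPHCoreClass",
        "high_MAT": "HighMATCoreClass",
        "low_MAT": "LowMATCoreClass",
    }
    other_classes = [f"OtherClass{k}" for k in range(1, 5)]
    rows = {}
    for otu, row in truth.per_otu.iterrows():
        if row["is_core"] and row["niche"] in core_class:
            cls = core_class[row["niche"]]
        else:
            cls = other_classes[rng.integers(0, len(other_classes))]
        rows[otu] = {
            "kingdom": "Bacteria",
            "phylum": f"Phylum{sum(map(ord, cls)) % 4 + 1}",
            "class": cls,
            "order": None,
            "family": None,
            "genus": None,
        }
    df = pd.DataFrame.from_dict(rows, orient="index")[list(TAXONOMY_RANKS)]
    return TaxonomyTable(df)


def generate_dataset(params: SimulationParams):
    """Convenience wrapper: metadata -> community -> nutrients -> taxonomy.

    Returns ``(otu_table, metadata, taxonomy, truth)`` with nutrients
    filled.
    """
    metadata = generate_metadata(params)
    table, truth = generate_community(metadata, params)
    metadata = generate_nutrients(metadata, table, truth, params)
    taxonomy = generate_taxonomy(truth, params)
    return table, metadata, taxonomy, truth
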