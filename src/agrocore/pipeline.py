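"""End-to-end orchestration of the survey analysis.

Stages, in order: validate, rarefy, diversity, drivers, core, clusters,
mnc, networks, enrichment, attribution, kriging.  Habitats (maize, rice)
are analyzed separately wherever the study does so; only the enrichment
stage consumes both habitats jointly through the site pairs.  Every stage
writes its outputs under ``out_dir/<stage>/`` and the run manifest records
the config, seeds, per-file checksums, and the sample/OTU counts surviving
each filter, so a run can be reproduced bit-for-bit.
"""

from __future__ import annotations

import hashlib
import logging
import platform
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import attribution as attr
from . import community as comm
from . import core_microbiota as corem
from . import enrichment as enrich
from . import mnc as mnc_mod
from . import multivariate as mv
from . import networks as net
from . import spatial
from .data_io import (
    AnalysisConfig,
    HABITATS,
    OtuTable,
    SampleMetadata,
    TaxonomyTable,
    write_metadata,
    write_network,
    write_otu_table,
    write_results,
)

__all__ = ["RunManifest", "STAGES", "run_pipeline"]

log = logging.getLogger(__name__)

STAGES = (
    "validate", "rarefy", "diversity", "drivers", "core", "clusters",
    "mnc", "networks", "enrichment", "attribution", "kriging",
)


@dataclass
class RunManifest:
    config: dict
    seed: int
    stages: list = field(default_factory=list)       # {name, status, outputs, info}
    checksums: dict = field(default_factory=dict)    # path -> sha256
    counts: dict = field(default_factory=dict)
    warnings: list = field(default_factory=list)
    versions: dict = field(default_factory=dict)

    def record(self, name: str, outputs: list, **info) -> None:
        self.stages.append({"name": name, "status": "ok",
                            "outputs": [str(p) for p in outputs], "info": info})
        for p in outputs:
            self.checksums[str(p)] = _sha256(p)

    def to_dict(self) -> dict:
        return {
            "config": self.config,
            "seed": self.seed,
            "stages": self.stages,
            "checksums": self.checksums,
            "counts": self.counts,
            "warnings": self.warnings,
            "versions": self.versions,
        }


def _sha256(path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def _versions() -> dict:
    import networkx
    import scipy
    import sklearn

    return {
        "python": platform.python_version(),
        "numpy": np.__version__,
        "pandas": pd.__version__,
        "scipy": scipy.__version__,
        "scikit-learn": sklearn.__version__,
        "networkx": networkx.__version__,
    }


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def run_pipeline(
    otu_table: OtuTable,
    metadata: SampleMetadata,
    config: AnalysisConfig,
    out_dir,
    taxonomy: TaxonomyTable | None = None,
    stages=None,
    nmds_starts: int = 2,
    rf_n_null: int = 50,
    kriging_grid_step: float = 2.0,
) -> RunManifest:
    """Run the full analysis and return the manifest.

    ``stages`` restricts execution to a subset (in canonical order);
    downstream stages needing a skipped stage's output are skipped too.
    """
    enabled = set(STAGES if stages is None else stages)
    unknown = enabled - set(STAGES)
    if unknown:
        raise ValueError(f"unknown stage(s): {sorted(unknown)}")
    out_dir = Path(out_dir)
    manifest = RunManifest(config=config.to_dict(), seed=config.rng_seed,
                           versions=_versions())
    state: dict = {}

    def _dir(stage: str) -> Path:
        d = out_dir / stage
        d.mkdir(parents=True, exist_ok=True)
        return d

    def _run(stage, fn):
        if stage not in enabled:
            return
        try:
            fn()
        except StageError:
            raise
        except Exception as e:  # noqa: BLE001 - abort with stage context
            raise StageError(stage, e) from e

    # -- validate ----------------------------------------------------------
    def stage_validate():
        missing = [s for s in otu_table.sample_ids if s not in metadata.table.index]
        if missing:
            raise ValueError(f"metadata missing sample {missing[0]!r}")
        otu_table.validate()
        manifest.counts["samples_in"] = otu_table.n_samples
        manifest.counts["otus_in"] = otu_table.n_otus
        d = _dir("validate")
        write_results(
            {"n_samples": otu_table.n_samples, "n_otus": otu_table.n_otus},
            d / "summary.json",
        )
        manifest.record("validate", [d / "summary.json"])

    _run("validate", stage_validate)

    # -- rarefy ------------------------------------------------------------
    def stage_rarefy():
        rare = comm.rarefy(otu_table, config.rarefaction_depth, config.rng_seed)
        state["rare"] = rare
        state["meta"] = metadata.align_to(rare.sample_ids)
        state["relab"] = comm.relative_abundance(rare)
        manifest.counts["samples_after_rarefaction"] = rare.n_samples
        d = _dir("rarefy")
        write_otu_table(rare, d / "rarefied_counts.tsv")
        manifest.record(
            "rarefy", [d / "rarefied_counts.tsv"],
            depth=config.rarefaction_depth,
            dropped=otu_table.n_samples - rare.n_samples,
        )

    _run("rarefy", stage_rarefy)

    def _habitat_split():
        out = {}
        for hab in HABITATS:
            ids = [s for s in state["rare"].sample_ids
                   if state["meta"].table.loc[s, "habitat"] == hab]
            out[hab] = ids
        return out

    # -- diversity ---------------------------------------------------------
    def stage_diversity():
        rare = state["rare"]
        alpha = comm.alpha_diversity(rare, base=config.shannon_base)
        state["alpha"] = alpha
        state["ord"] = {}
        state["bray"] = {}
        hab_ids = _habitat_split()
        for hab, ids in hab_ids.items():
            relab_h = state["relab"].select_samples(ids)
            bray = comm.bray_curtis(relab_h)
            state["bray"][hab] = bray
            state["ord"][hab] = comm.nmds(
                bray, k=2, n_starts=nmds_starts, seed=config.rng_seed
            )
        d = _dir("diversity")
        write_results(alpha.table, d / "alpha_diversity.tsv")
        outs = [d / "alpha_diversity.tsv"]
        for hab in HABITATS:
            ordn = state["ord"][hab]
            df = pd.DataFrame(
                ordn.coordinates, index=ordn.sample_ids, columns=["NMDS1", "NMDS2"]
            )
            df["stress"] = ordn.stress
            p = d / f"nmds_{hab}.tsv"
            write_results(df, p)
            outs.append(p)
        manifest.record("diversity", outs)

    _run("diversity", stage_diversity)

    # -- drivers -----------------------------------------------------------
    def stage_drivers():
        meta = state["meta"]
        env_cols = ["pH", "MAT", "MAP"] + [
            v for v in config.nutrient_variables if v in meta.table.columns
        ]
        d = _dir("drivers")
        outs = []
        state["drivers"] = {}
        hab_ids = _habitat_split()
        # habitat effect on the pooled community
        bray_all = comm.bray_curtis(state["relab"])
        habitats = meta.table.loc[bray_all.sample_ids, "habitat"]
        state["anosim_habitat"] = mv.anosim(
            bray_all, habitats.to_numpy(), n_perm=config.n_permutations,
            seed=config.rng_seed,
        )
        for hab, ids in hab_ids.items():
            env = meta.table.loc[ids, env_cols].astype(float).dropna(axis=1, how="any")
            n_before = env.shape[1]
            env = env.loc[:, env.std(ddof=1) > 0]
            if env.shape[1] < n_before:
                manifest.warnings.append(
                    f"drivers[{hab}]: dropped {n_before - env.shape[1]} constant/NA variable(s)"
                )
            red = mv.reduce_redundant_variables(
                env, rho_threshold=config.redundancy_rho_max,
                priority=config.driver_priority,
            )
            sel = mv.distlm_forward(
                state["bray"][hab], env[red.retained],
                n_perm=config.n_permutations, seed=config.rng_seed,
            )
            state["drivers"][hab] = {"redundancy": red, "selection": sel}
            write_results(
                {
                    "retained_after_redundancy": red.retained,
                    "removed_pairs": [list(t) for t in red.removed_pairs],
                    "forward_order": sel.order,
                    "cumulative_r2": sel.cumulative_r2,
                    "p_values": sel.p_values,
                    "marginal_r2": sel.marginal_r2,
                },
                d / f"selection_{hab}.json",
            )
            outs.append(d / f"selection_{hab}.json")
        write_results(
            {
                "anosim_habitat_R": state["anosim_habitat"].statistic,
                "anosim_habitat_p": state["anosim_habitat"].p_perm,
            },
            d / "anosim.json",
        )
        outs.append(d / "anosim.json")
        manifest.record("drivers", outs)

    _run("drivers", stage_drivers)

    # -- core --------------------------------------------------------------
    def stage_core():
        d = _dir("core")
        outs = []
        state["core"] = {}
        hab_ids = _habitat_split()
        for hab, ids in hab_ids.items():
            relab_h = state["relab"].select_samples(ids)
            cs = corem.identify_core(
                relab_h,
                abundance_quantile=config.core_abundance_quantile,
                occupancy_min=config.core_occupancy_min,
                strict_occupancy=config.occupancy_strict,
            )
            state["core"][hab] = cs
            manifest.counts[f"core_otus_{hab}"] = cs.n_core
            p = d / f"core_{hab}.tsv"
            write_results(cs.table, p)
            outs.append(p)
        manifest.record("core", outs)

    _run("core", stage_core)

    # -- clusters ----------------------------------------------------------
    def stage_clusters():
        d = _dir("clusters")
        outs = []
        state["cluster_ra"] = {}
        hab_ids = _habitat_split()
        for hab, ids in hab_ids.items():
            relab_h = state["relab"].select_samples(ids)
            meta_h = state["meta"].table.loc[ids]
            cs = corem.assign_ecological_clusters(
                state["core"][hab], relab_h,
                meta_h["pH"].to_numpy(dtype=float),
                meta_h["MAT"].to_numpy(dtype=float),
                alpha=config.alpha,
            )
            state["core"][hab] = cs
            cra = corem.cluster_relative_abundance(relab_h, cs)
            state["cluster_ra"][hab] = cra
            reg = corem.cluster_env_regression(
                cra, meta_h[["pH", "MAT"]].astype(float)
            )
            for name, obj in (("core", cs.table), ("cluster_ra", cra),
                              ("cluster_regression", reg)):
                p = d / f"{name}_{hab}.tsv"
                write_results(obj, p)
                outs.append(p)
        manifest.record("clusters", outs)

    _run("clusters", stage_clusters)

    # -- mnc ---------------------------------------------------------------
    def stage_mnc():
        d = _dir("mnc")
        outs = []
        state["mnc"] = {}
        hab_ids = _habitat_split()
        for hab, ids in hab_ids.items():
            nutrients = state["meta"].table.loc[ids, list(config.nutrient_variables)]
            idx = mnc_mod.multinutrient_index(
                nutrients.astype(float),
                log_rule=config.mnc_log_rule,
                skew_threshold=config.mnc_skew_threshold,
                variables=config.nutrient_variables,
            )
            state["mnc"][hab] = idx
            df = idx.values.to_frame("mnc")
            df["n_available"] = idx.n_available
            p = d / f"mnc_{hab}.tsv"
            write_results(df, p)
            outs.append(p)
            write_results(idx.transforms, d / f"transforms_{hab}.json")
            outs.append(d / f"transforms_{hab}.json")
        manifest.record("mnc", outs)

    _run("mnc", stage_mnc)

    # -- networks ----------------------------------------------------------
    def stage_networks():
        d = _dir("networks")
        outs = []
        state["net"] = {}
        hab_ids = _habitat_split()
        for hab, ids in hab_ids.items():
            relab_h = state["relab"].select_samples(ids)
            filtered = net.filter_rare(relab_h, min_mean_ra=config.rare_ra_min)
            manifest.counts[f"network_otus_{hab}"] = filtered.n_otus
            edges = net.correlation_edges(
                filtered, rho_min=config.network_rho_min,
                q_max=config.network_q_max,
                absolute=config.network_absolute_rho,
            )
            core_set = state["core"][hab]
            attrs = pd.DataFrame(index=filtered.otu_ids)
            attrs["mean_ra"] = filtered.mean_ra()
            attrs["subcommunity"] = [
                "core" if o in set(core_set.core_otus) else "other"
                for o in filtered.otu_ids
            ]
            g = net.build_network(edges, attrs)
            state["net"][hab] = g
            metrics = net.network_metrics(g, seed=config.rng_seed)
            nm = net.node_metrics(g)
            labels = dict(attrs["subcommunity"])
            inner, external = net.partition_edge_counts(g, labels)
            groups = attrs["subcommunity"]
            comparison = (
                net.compare_node_metrics(nm, groups, alpha=config.alpha)
                if groups.nunique() > 1 else None
            )
            p_edges = d / f"network_{hab}.tsv"
            write_network(g, p_edges)
            outs += [p_edges, p_edges.with_suffix(".graphml")]
            p_nm = d / f"node_metrics_{hab}.tsv"
            write_results(nm, p_nm)
            outs.append(p_nm)
            payload = {
                "network_metrics": metrics.as_dict(),
                "inner_edges": {str(k): v for k, v in inner.items()},
                "external_edges": {" | ".join(k): v for k, v in external.items()},
            }
            if comparison is not None:
                payload["core_vs_other_p"] = {
                    m: comparison.loc[m, "p"] for m in comparison.index
                }
            p_json = d / f"topology_{hab}.json"
            write_results(payload, p_json)
            outs.append(p_json)
        manifest.record("networks", outs)

    _run("networks", stage_networks)

    # -- enrichment --------------------------------------------------------
    def stage_enrichment():
        d = _dir("enrichment")
        res = enrich.paired_enrichment(
            state["relab"], state["meta"], alpha=config.alpha
        )
        state["enrichment"] = res
        trends = enrich.enriched_trend_vs_env(res, state["meta"], env_var="MAT")
        outs = []
        for name, obj in (("classes", res.per_otu), ("per_sample", res.per_sample),
                          ("trends_vs_MAT", trends)):
            p = d / f"{name}.tsv"
            write_results(obj, p)
            outs.append(p)
        manifest.counts["maize_enriched"] = len(res.members("maize"))
        manifest.counts["rice_enriched"] = len(res.members("rice"))
        manifest.record("enrichment", outs)

    _run("enrichment", stage_enrichment)

    # -- attribution -------------------------------------------------------
    def stage_attribution():
        d = _dir("attribution")
        outs = []
        state["attribution"] = {}
        hab_ids = _habitat_split()
        for hab, ids in hab_ids.items():
            alpha_tbl = state["alpha"].table.loc[ids]
            ordn = state["ord"][hab]
            predictors = pd.DataFrame(
                {
                    "richness": alpha_tbl["richness"].astype(float),
                    "shannon": alpha_tbl["shannon"],
                    "NMDS1": ordn.axis(0).loc[ids],
                    "NMDS2": ordn.axis(1).loc[ids],
                },
                index=ids,
            )
            response = state["mnc"][hab].values.loc[ids]
            ok = response.notna()
            rf = attr.rf_importance(
                predictors[ok], response[ok].to_numpy(),
                n_trees=config.rf_n_trees, n_null=rf_n_null,
                seed=config.rng_seed,
            )
            vd = attr.variance_decomposition(predictors[ok], response[ok].to_numpy())
            state["attribution"][hab] = {"rf": rf, "lmg": vd}
            df = pd.DataFrame({
                "importance": rf.importance,
                "rf_p": rf.p_values,
                "lmg_share": vd.shares,
                "sign": vd.signs,
            })
            df.attrs["total_r2"] = vd.total_r2
            p = d / f"mnc_predictors_{hab}.tsv"
            write_results(df, p)
            outs.append(p)
            if taxonomy is not None:
                relab_h = state["relab"].select_samples(ids)
                core_ids = [o for o in state["core"][hab].core_otus]
                if core_ids:
                    classes = taxonomy.rank("class").reindex(core_ids)
                    core_vals = relab_h.select_otus(core_ids).values
                    class_ra = (
                        pd.DataFrame(core_vals, index=ids, columns=core_ids)
                        .T.groupby(classes).sum().T
                    )
                    nutrients = state["meta"].table.loc[
                        ids, list(config.nutrient_variables)
                    ].astype(float)
                    shares, signs = attr.class_level_contributions(
                        class_ra, nutrients
                    )
                    p1 = d / f"class_shares_{hab}.tsv"
                    write_results(shares, p1)
                    outs.append(p1)
        manifest.record("attribution", outs)

    _run("attribution", stage_attribution)

    # -- kriging -----------------------------------------------------------
    def stage_kriging():
        d = _dir("kriging")
        outs = []
        state["kriging"] = {}
        hab_ids = _habitat_split()
        for hab, ids in hab_ids.items():
            meta_h = state["meta"].table.loc[ids]
            targets = _grid_targets(meta_h, kriging_grid_step)
            coords = targets["data_xy"]
            rows = {}
            for col in list(state["cluster_ra"][hab].columns) + ["richness"]:
                if col == "richness":
                    values = state["alpha"].table.loc[ids, "richness"].to_numpy(dtype=float)
                else:
                    values = state["cluster_ra"][hab][col].to_numpy(dtype=float)
                if np.ptp(values) == 0:
                    manifest.warnings.append(
                        f"kriging[{hab}]: {col} constant, skipped")
                    continue
                r, p, model = spatial.loo_cv(coords, values)
                res = spatial.ordinary_krige(model, coords, values, targets["xy"])
                grid = res.grid.copy()
                grid["lon"] = targets["lon"]
                grid["lat"] = targets["lat"]
                pth = d / f"grid_{hab}_{col}.tsv"
                write_results(grid[["lon", "lat", "predicted", "variance"]], pth)
                outs.append(pth)
                rows[col] = {"cv_r": r, "cv_p": p, "variogram": model.form,
                             "nugget": model.nugget, "sill": model.sill,
                             "range_km": model.range_}
            state["kriging"][hab] = rows
            pj = d / f"cv_{hab}.json"
            write_results(rows, pj)
            outs.append(pj)
        manifest.record("kriging", outs)

    _run("kriging", stage_kriging)

    write_results(manifest.to_dict(), out_dir / "manifest.json")
    return manifest


def _grid_targets(meta_h: pd.DataFrame, step: float) -> dict:
    lons = np.arange(meta_h["longitude"].min(), meta_h["longitude"].max() + step, step)
    lats = np.arange(meta_h["latitude"].min(), meta_h["latitude"].max() + step, step)
    lon_g, lat_g = np.meshgrid(lons, lats)
    lon_flat, lat_flat = lon_g.ravel(), lat_g.ravel()
    # project jointly with the data so the local projection is shared
    all_lon = np.concatenate([meta_h["longitude"].to_numpy(dtype=float), lon_flat])
    all_lat = np.concatenate([meta_h["latitude"].to_numpy(dtype=float), lat_flat])
    xy_all = spatial.project_coordinates(all_lon, all_lat)
    n_data = len(meta_h)
    return {
        "xy": xy_all[n_data:],
        "data_xy": xy_all[:n_data],
        "lon": lon_flat,
        "lat": lat_flat,
    }
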