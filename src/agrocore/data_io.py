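"""Typed tabular I/O with strict validation.

All tables are TSV with a header row.  OTU tables are stored OTUs-as-rows
(the common dialect); ``orientation`` overrides this.  Missing metadata
values are encoded as "NA".  Floats are written with 6 significant digits so
write-then-read round-trips are byte-stable.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "FormatError",
    "ValidationError",
    "OtuTable",
    "TaxonomyTable",
    "SampleMetadata",
    "AnalysisConfig",
    "read_otu_table",
    "write_otu_table",
    "read_taxonomy",
    "write_taxonomy",
    "read_metadata",
    "write_metadata",
    "write_network",
    "read_network",
    "write_results",
]

FLOAT_FMT = "%.6g"
NA_TOKEN = "NA"
HABITATS = ("maize", "rice")
TAXONOMY_RANKS = ("kingdom", "phylum", "class", "order", "family", "genus")
#: The eight available-nutrient variables entering the multinutrient index.
MNC_NUTRIENTS = ("DOC", "AN", "NO3", "NH4", "AP", "AK", "AS", "AFe")


class FormatError(ValueError):
    """A file does not conform to the expected table dialect."""


class ValidationError(ValueError):
    """A table violates a structural invariant; the message names the record."""


def _check_unique(ids, what: str) -> None:
    seen: set[str] = set()
    for i in ids:
        if i in seen:
            raise FormatError(f"duplicate {what} id: {i!r}")
        seen.add(i)


@dataclass
class OtuTable:
    """Integer count matrix, samples x OTUs."""

    sample_ids: list[str]
    otu_ids: list[str]
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if not np.issubdtype(self.counts.dtype, np.integer):
            as_int = np.asarray(self.counts, dtype=float)
            if np.any(np.isnan(as_int)) or np.any(as_int != np.round(as_int)):
                raise ValidationError("counts must be integers without NaN")
            self.counts = as_int.astype(np.int64)
        self.counts = self.counts.astype(np.int64, copy=False)
        self.validate()

    def validate(self) -> None:
        _check_unique(self.sample_ids, "sample")
        _check_unique(self.otu_ids, "OTU")
        n_s, n_o = len(self.sample_ids), len(self.otu_ids)
        if self.counts.shape != (n_s, n_o):
            raise ValidationError(
                f"counts shape {self.counts.shape} != ({n_s}, {n_o})"
            )
        if n_s < 2 or n_o < 2:
            raise ValidationError("need at least 2 samples and 2 OTUs")
        if np.any(self.counts < 0):
            i, j = np.argwhere(self.counts < 0)[0]
            raise ValidationError(
                f"negative count for sample {self.sample_ids[i]!r}, "
                f"OTU {self.otu_ids[j]!r}"
            )
        sums = self.counts.sum(axis=1)
        if np.any(sums == 0):
            i = int(np.argmax(sums == 0))
            raise ValidationError(f"sample {self.sample_ids[i]!r} has zero total count")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_otus(self) -> int:
        return len(self.otu_ids)

    def sample_sums(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    def select_samples(self, sample_ids) -> "OtuTable":
        idx = [self.sample_ids.index(s) for s in sample_ids]
        return OtuTable(list(sample_ids), list(self.otu_ids), self.counts[idx])

    def select_otus(self, otu_ids) -> "OtuTable":
        pos = {o: k for k, o in enumerate(self.otu_ids)}
        idx = [pos[o] for o in otu_ids]
        return OtuTable(list(self.sample_ids), list(otu_ids), self.counts[:, idx])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.sample_ids, columns=self.otu_ids)

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, OtuTable)
            and self.sample_ids == other.sample_ids
            and self.otu_ids == other.otu_ids
            and np.array_equal(self.counts, other.counts)
        )


@dataclass
class TaxonomyTable:
    """OTU id -> ranked lineage (kingdom..genus); missing ranks are None."""

    lineages: pd.DataFrame  # index = otu_id, columns = TAXONOMY_RANKS

    def __post_init__(self) -> None:
        df = self.lineages
        if df.index.has_duplicates:
            dup = df.index[df.index.duplicated()][0]
            raise FormatError(f"duplicate OTU id: {dup!r}")
        missing = [r for r in TAXONOMY_RANKS if r not in df.columns]
        if missing:
            raise ValidationError(f"taxonomy missing rank columns: {missing}")
        bad = df.index[df["kingdom"].isna() | (df["kingdom"] == "")]
        if len(bad):
            raise ValidationError(f"empty kingdom for OTU {bad[0]!r}")

    def rank(self, rank: str) -> pd.Series:
        if rank not in TAXONOMY_RANKS:
            raise ValueError(f"unknown rank {rank!r}")
        return self.lineages[rank]


@dataclass
class SampleMetadata:
    """Per-sample design and environmental variables.

    ``table`` is indexed by sample_id and carries at least site_id, pair_id
    (nullable), habitat, latitude, longitude, MAT, MAP, soil_type, pH, and
    whatever edaphic variables the study measured.
    """

    table: pd.DataFrame

    REQUIRED = ("site_id", "pair_id", "habitat", "latitude", "longitude")

    def __post_init__(self) -> None:
        df = self.table
        if df.index.has_duplicates:
            dup = df.index[df.index.duplicated()][0]
            raise FormatError(f"duplicate sample id: {dup!r}")
        missing = [c for c in self.REQUIRED if c not in df.columns]
        if missing:
            raise ValidationError(f"metadata missing columns: {missing}")
        bad_hab = df.index[~df["habitat"].isin(HABITATS)]
        if len(bad_hab):
            raise ValidationError(
                f"sample {bad_hab[0]!r} has unknown habitat "
                f"{df.loc[bad_hab[0], 'habitat']!r}"
            )
        lat = df["latitude"].astype(float)
        lon = df["longitude"].astype(float)
        bad = df.index[(lat.abs() > 90) | (lon.abs() > 180) | lat.isna() | lon.isna()]
        if len(bad):
            raise ValidationError(f"sample {bad[0]!r} has invalid coordinates")
        paired = df[df["pair_id"].notna()]
        for pid, grp in paired.groupby("pair_id"):
            counts = grp["habitat"].value_counts()
            for hab in HABITATS:
                if counts.get(hab, 0) > 1:
                    raise ValidationError(
                        f"pair {pid!r} has {counts[hab]} {hab} samples (max 1)"
                    )

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table.index)

    def habitat_samples(self, habitat: str) -> list[str]:
        if habitat not in HABITATS:
            raise ValueError(f"unknown habitat {habitat!r}")
        return list(self.table.index[self.table["habitat"] == habitat])

    def complete_pairs(self) -> pd.DataFrame:
        """Pairs with exactly one maize and one rice sample.

        Returns a frame indexed by pair_id with columns 'maize' and 'rice'
        holding the member sample ids.
        """
        paired = self.table[self.table["pair_id"].notna()]
        rows = {}
        for pid, grp in paired.groupby("pair_id"):
            by_hab = dict(zip(grp["habitat"], grp.index))
            if set(by_hab) == set(HABITATS):
                rows[pid] = by_hab
        out = pd.DataFrame.from_dict(rows, orient="index")
        return out.sort_index()

    def variable(self, name: str, samples=None) -> pd.Series:
        col = self.table[name] if samples is None else self.table.loc[list(samples), name]
        return col.astype(float)

    def align_to(self, sample_ids) -> "SampleMetadata":
        unknown = [s for s in sample_ids if s not in self.table.index]
        if unknown:
            raise ValidationError(f"metadata missing sample {unknown[0]!r}")
        return SampleMetadata(self.table.loc[list(sample_ids)].copy())


@dataclass
class AnalysisConfig:
    """Every fixed threshold of the analysis, in one place.

    Defaults are the study's published choices: rarefaction at 27,812 reads,
    core = top decile of mean relative abundance with >80% occupancy,
    network edges at Spearman rho > 0.6 with BH q < 0.01 over OTUs of mean
    relative abundance >= 0.01%, 5,000-tree random forests, 999 permutations.
    """

    rarefaction_depth: int = 27812
    core_abundance_quantile: float = 0.90
    core_occupancy_min: float = 0.80
    occupancy_strict: bool = True
    network_rho_min: float = 0.60
    network_q_max: float = 0.01
    network_absolute_rho: bool = False
    rare_ra_min: float = 1e-4
    rf_n_trees: int = 5000
    n_permutations: int = 999
    alpha: float = 0.05
    rng_seed: int = 0
    mnc_log_rule: str = "skewness"
    mnc_skew_threshold: float = 1.0
    nutrient_variables: tuple = MNC_NUTRIENTS
    driver_priority: tuple = ("pH", "MAT")
    redundancy_rho_max: float = 0.60
    shannon_base: str = "e"  # "e" (nats) or "2"

    def __post_init__(self) -> None:
        for name in (
            "core_abundance_quantile",
            "core_occupancy_min",
            "network_rho_min",
            "network_q_max",
            "alpha",
            "redundancy_rho_max",
        ):
            v = getattr(self, name)
            if not (0 < v <= 1):
                raise ValueError(f"{name} must be in (0, 1], got {v}")
        if self.rarefaction_depth < 1:
            raise ValueError("rarefaction_depth must be >= 1")
        if self.rf_n_trees < 1 or self.n_permutations < 1:
            raise ValueError("rf_n_trees and n_permutations must be >= 1")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["nutrient_variables"] = list(self.nutrient_variables)
        d["driver_priority"] = list(self.driver_priority)
        return d


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------

def read_otu_table(path, orientation: str = "otus_as_rows") -> OtuTable:
    """Read a TSV count table.

    ``orientation`` is "otus_as_rows" (default), "samples_as_rows", or
    "auto", which keys on the header flag of the id column: a first header
    cell beginning with "#sample" selects samples-as-rows.
    """
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    header_flag = str(df.index.name or "")
    if orientation == "auto":
        orientation = (
            "samples_as_rows"
            if header_flag.lower().lstrip("#").startswith("sample")
            else "otus_as_rows"
        )
    if orientation not in ("otus_as_rows", "samples_as_rows"):
        raise ValueError(f"unknown orientation {orientation!r}")
    try:
        values = df.astype(float)
    except ValueError as e:
        raise FormatError(f"non-numeric count cell in {path}: {e}") from e
    if np.any(values.isna().to_numpy()):
        raise ValidationError(f"NaN count in {path}")
    arr = values.to_numpy()
    if np.any(arr != np.round(arr)):
        raise FormatError(f"non-integer count cell in {path}")
    _check_unique(list(df.index), "row")
    _check_unique(list(df.columns), "column")
    if orientation == "otus_as_rows":
        return OtuTable(list(df.columns), list(df.index), arr.astype(np.int64).T)
    return OtuTable(list(df.index), list(df.columns), arr.astype(np.int64))


def write_otu_table(table: OtuTable, path, orientation: str = "otus_as_rows") -> None:
    df = table.to_frame()
    if orientation == "otus_as_rows":
        df = df.T
        df.index.name = "#otu_id"
    else:
        df.index.name = "#sample_id"
    df.to_csv(path, sep="\t")


def read_taxonomy(path) -> TaxonomyTable:
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str, na_values=[NA_TOKEN])
    return TaxonomyTable(df)


def write_taxonomy(tax: TaxonomyTable, path) -> None:
    df = tax.lineages.copy()
    df.index.name = "#otu_id"
    df.to_csv(path, sep="\t", na_rep=NA_TOKEN)


def read_metadata(path) -> SampleMetadata:
    df = pd.read_csv(
        path, sep="\t", index_col=0, dtype={0: str}, na_values=[NA_TOKEN],
        keep_default_na=False,
    )
    for col in ("site_id", "pair_id", "habitat", "soil_type"):
        if col in df.columns:
            df[col] = df[col].astype(object).where(df[col].notna(), None)
    return SampleMetadata(df)


def write_metadata(meta: SampleMetadata, path) -> None:
    df = meta.table.copy()
    df.index.name = "#sample_id"
    df.to_csv(path, sep="\t", na_rep=NA_TOKEN, float_format=FLOAT_FMT)


def write_network(net: nx.Graph, path) -> None:
    """Write a co-occurrence network as edge-list TSV plus GraphML.

    ``path`` is the edge-list file; the GraphML twin sits next to it with a
    .graphml suffix.  Edge columns: source, target, rho, q.
    """
    path = Path(path)
    rows = [
        {
            "source": u,
            "target": v,
            "rho": FLOAT_FMT % d["rho"],
            "q": FLOAT_FMT % d["q"],
        }
        for u, v, d in sorted(net.edges(data=True))
    ]
    pd.DataFrame(rows, columns=["source", "target", "rho", "q"]).to_csv(
        path, sep="\t", index=False
    )
    clean = nx.Graph()
    clean.add_nodes_from(
        (n, {k: v for k, v in d.items() if v is not None})
        for n, d in net.nodes(data=True)
    )
    clean.add_edges_from(net.edges(data=True))
    nx.write_graphml(clean, path.with_suffix(".graphml"))


def read_network(path) -> nx.Graph:
    df = pd.read_csv(path, sep="\t", dtype={"source": str, "target": str})
    g = nx.Graph()
    for row in df.itertuples(index=False):
        g.add_edge(row.source, row.target, rho=float(row.rho), q=float(row.q))
    return g


def write_results(obj, path) -> None:
    """Write a DataFrame as TSV or any JSON-serializable object as JSON,
    keyed on the file suffix."""
    path = Path(path)
    if path.suffix == ".json":
        with open(path, "w") as fh:
            json.dump(obj, fh, indent=2, sort_keys=True, default=_json_default)
            fh.write("\n")
    else:
        if not isinstance(obj, pd.DataFrame):
            obj = pd.DataFrame(obj)
        obj.to_csv(path, sep="\t", na_rep=NA_TOKEN, float_format=FLOAT_FMT)


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON-serializable: {type(o)}")
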