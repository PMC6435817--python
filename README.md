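# agrocore

Core-microbiota and multinutrient-cycling analysis of paired agricultural
soil surveys.

Continental soil surveys of cropping systems (e.g. adjacent maize/dryland
and rice/wetland fields sampled in pairs along climate and pH gradients)
ask a recurring set of questions: which bacterial taxa form the *core
microbiota*; what environmental preferences do those taxa share; how
central are they in the community's co-occurrence network; and how is
community diversity linked to belowground nutrient cycling?  `agrocore`
implements that analysis chain as a tested, reusable Python library with a
thin command-line interface, plus a synthetic survey generator with known
ground truth so every stage has a recovery test that runs without any
sequencing data.

## The methods at the core

* **Core microbiota** — an OTU is core when it is in the top decile of
  mean relative abundance across samples *and* present in more than 80% of
  samples.  Core taxa are grouped into four ecological clusters (high pH,
  low pH, high MAT, low MAT) by the Spearman correlation of their
  abundance with soil pH and mean annual temperature: among significant
  correlations, the driver with the larger |ρ| wins and the sign sets the
  polarity.
* **Multinutrient cycling (MNC) index** — per sample, the mean of
  Z-score-standardized values of eight available nutrients (DOC, AN, NO₃,
  NH₄, AP, AK, AS, AFe), log-transforming right-skewed variables first;
  the averaging multifunctionality index applied to nutrient cycling.
* **Co-occurrence networks** — after removing OTUs below 0.01% mean
  relative abundance, edges are OTU pairs with Spearman ρ > 0.6 and
  Benjamini–Hochberg q < 0.01 over all tested pairs.  Node metrics
  (degree, betweenness, harmonic closeness, eigenvector centrality) and
  network metrics (average degree, density, clustering, average path
  length, diameter, modularity) quantify the topology of core vs. other
  subcommunities.
* **Community statistics** — rarefaction, richness and Shannon diversity,
  Bray–Curtis dissimilarity, non-metric multidimensional scaling (SMACOF
  with isotonic regression), ANOSIM, PERMANOVA with sequential sums of
  squares, constrained analysis of principal coordinates (CAP),
  redundancy reduction of environmental variables at |ρ| > 0.6, and a
  distance-based linear model with permutation-gated forward selection.
* **Attribution** — random-forest out-of-bag permutation importance
  (with a response-permutation significance test) and LMG variance
  decomposition (per-predictor share of R², averaged over all predictor
  orderings) relate α-diversity (richness, Shannon) and β-diversity
  (NMDS1/NMDS2) to the MNC index, and taxonomic-class abundances to
  individual nutrients.
* **Spatial prediction** — ordinary kriging with automatic variogram
  fitting (Matheron estimator, Cressie-weighted least squares over
  exponential/spherical/Gaussian forms) and leave-one-out Pearson
  cross-validation.
* **Enrichment** — paired t tests of each OTU's relative abundance across
  maize–rice site pairs classify taxa as maize-enriched, rice-enriched or
  other, verified by Kruskal–Wallis, with abundance trends along MAT.

## Worked example

Generate a synthetic paired survey at the default study design (60 paired
sites, 400 OTUs of which 40 are planted core taxa) and analyze the maize
habitat:

```python
import pandas as pd
import agrocore as ac
from agrocore.data_io import MNC_NUTRIENTS

params = ac.SimulationParams(seed=42)
table, meta, taxonomy, truth = ac.generate_dataset(params)
rare = ac.rarefy(table, 10_000, seed=42)
relab = ac.relative_abundance(rare)

maize = [s for s in rare.sample_ids if meta.table.loc[s, "habitat"] == "maize"]
relab_m = relab.select_samples(maize)
core = ac.identify_core(relab_m)
m = meta.table.loc[maize]
core = ac.assign_ecological_clusters(
    core, relab_m, m["pH"].astype(float), m["MAT"].astype(float))
print(f"core OTUs (maize): {core.n_core}")
print(core.table[core.table.is_core]["cluster"].value_counts().to_dict())
print(f"fraction of sequences in core taxa: "
      f"{core.table.loc[core.table.is_core, 'mean_ra'].sum():.3f}")
```

prints

```
core OTUs (maize): 40
{'high_MAT': 11, 'high_pH': 10, 'low_MAT': 10, 'low_pH': 9}
fraction of sequences in core taxa: 0.687
```

— the 40 identified core taxa (all 4 planted clusters recovered) carry
~69% of the sequences despite being 10% of the OTUs.  Continuing with the
network and the diversity–function link:

```python
filt = ac.filter_rare(relab_m)
edges = ac.correlation_edges(filt)
attrs = pd.DataFrame({"mean_ra": filt.mean_ra()})
attrs["subcommunity"] = [
    "core" if o in set(core.core_otus) else "other" for o in filt.otu_ids]
g = ac.build_network(edges, attrs)
nm = ac.network_metrics(g)
print(f"network: {g.number_of_nodes()} nodes, {g.number_of_edges()} edges, "
      f"avg degree {nm.average_degree:.2f}, modularity {nm.modularity:.2f}")

mi = ac.multinutrient_index(m[list(MNC_NUTRIENTS)].astype(float))
alpha = ac.alpha_diversity(rare)
ordn = ac.nmds(ac.bray_curtis(relab_m), n_starts=2, seed=42)
X = pd.DataFrame({
    "richness": alpha.table.loc[maize, "richness"].astype(float),
    "shannon": alpha.table.loc[maize, "shannon"],
    "NMDS1": ordn.axis(0), "NMDS2": ordn.axis(1)}, index=maize)
vd = ac.variance_decomposition(X, mi.values.loc[maize].to_numpy())
print({k: round(v, 3) for k, v in vd.shares.items()},
      "total R2:", round(vd.total_r2, 3))
```

```
network: 375 nodes, 479 edges, avg degree 2.55, modularity 0.78
{'richness': 0.205, 'shannon': 0.717, 'NMDS1': 0.002, 'NMDS2': 0.038} total R2: 0.962
```

In this simulated maize habitat the nutrients are coupled to α-diversity,
and the LMG decomposition correctly attributes most of the explained MNC
variance to the Shannon index rather than to the NMDS (β-diversity) axes.

The same analyses are available from the shell
(`agrocore simulate / validate / diversity / drivers / core / mnc /
network / enrich / krige / run`), and `agrocore run --config` executes the
full eleven-stage pipeline, writing per-stage outputs and a reproducible
run manifest.

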