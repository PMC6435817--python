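"""The paired-site survey generator: design, determinism, planted truth."""

import numpy as np
import pytest

from agrocore import (
    SimulationParams,
    alpha_diversity,
    generate_community,
    generate_dataset,
    generate_metadata,
    generate_nutrients,
    multinutrient_index,
    spearman,
)
from agrocore.data_io import MNC_NUTRIENTS
from agrocore.stats_core import linear_regression


class TestMetadata:
    def test_paired_counting(self):
        meta = generate_metadata(SimulationParams(n_sites=10, seed=0))
        assert len(meta.table) == 20
        assert meta.table["pair_id"].nunique() == 10
        assert len(meta.complete_pairs()) == 10

    def test_mat_slope_recovered_within_2se(self):
        params = SimulationParams(n_sites=80, seed=1)
        meta = generate_metadata(params)
        import scipy.stats as sps

        res = sps.linregress(meta.table["latitude"], meta.table["MAT"])
        assert res.slope < 0
        assert abs(res.slope - (-params.mat_slope)) < 2 * res.stderr + 1e-12

    def test_zero_noise_exact_line(self):
        params = SimulationParams(n_sites=10, mat_noise_sd=0.0, seed=2)
        meta = generate_metadata(params)
        expected = params.mat_intercept - params.mat_slope * meta.table["latitude"]
        # paired samples share the site's MAT (coordinates carry the jitter)
        sites = meta.table.groupby("site_id").first()
        site_expected = params.mat_intercept - params.mat_slope * (
            meta.table.groupby("site_id")["latitude"].mean()
        )
        # jitter moves latitude by < 0.02 deg -> MAT differs by < 0.02*b
        assert np.allclose(sites["MAT"], site_expected, atol=0.05)

    def test_pairs_share_location_within_5km(self):
        meta = generate_metadata(SimulationParams(n_sites=20, seed=3))
        for pid, grp in meta.table.groupby("pair_id"):
            assert len(grp) == 2
            dlat = np.ptp(grp["latitude"].to_numpy()) * 111.0
            dlon = np.ptp(grp["longitude"].to_numpy()) * 111.0
            assert np.hypot(dlat, dlon) < 5.0

    def test_too_few_sites_rejected(self):
        with pytest.raises(ValueError):
            generate_metadata(SimulationParams(n_sites=2))


class TestCommunity:
    def test_same_seed_bit_identical_different_seed_not(self):
        p = SimulationParams(n_sites=10, n_otus=50, n_core=8, seed=4)
        t1, _ = generate_community(generate_metadata(p), p)
        t2, _ = generate_community(generate_metadata(p), p)
        assert np.array_equal(t1.counts, t2.counts)
        p2 = SimulationParams(n_sites=10, n_otus=50, n_core=8, seed=5)
        t3, _ = generate_community(generate_metadata(p2), p2)
        assert not np.array_equal(t1.counts, t3.counts)

    def test_output_passes_validators(self, default_survey):
        default_survey["table"].validate()  # raises on any breach

    def test_planted_core_occupancy_and_abundance(self):
        occs = []
        in_top_decile = []
        for seed in range(5):
            p = SimulationParams(seed=30 + seed)
            table, meta, tax, truth = generate_dataset(p)
            relab = table.counts / table.counts.sum(axis=1, keepdims=True)
            core_idx = [table.otu_ids.index(o) for o in truth.core_otus]
            occ = (table.counts[:, core_idx] > 0).mean(axis=0)
            occs.append(occ.min())
            mean_ra = relab.mean(axis=0)
            cutoff = np.quantile(mean_ra, 0.90)
            in_top_decile.append((mean_ra[core_idx] >= cutoff).mean())
        assert np.mean([o >= 0.8 for o in occs]) >= 0.95 or min(occs) >= 0.8
        assert np.mean(in_top_decile) >= 0.9

    def test_niche_effect_produces_positive_correlation(self):
        p = SimulationParams(seed=6)
        table, meta, tax, truth = generate_dataset(p)
        relab = table.counts / table.counts.sum(axis=1, keepdims=True)
        ph = meta.table["pH"].to_numpy(dtype=float)
        hits = tot = 0
        for otu in truth.core_otus:
            if truth.per_otu.loc[otu, "niche"] == "high_pH":
                j = table.otu_ids.index(otu)
                rho, _ = spearman(relab[:, j], ph)
                tot += 1
                hits += rho > 0
        assert tot > 0 and hits == tot

    def test_null_community_driver_correlations_centered(self):
        p = SimulationParams(
            n_sites=30, n_otus=60, n_core=8, beta_core=0.0, beta_other=0.0,
            other_niche_fraction=0.0, enrich_fraction=0.0, n_blocks=0,
            seed=7,
        )
        meta = generate_metadata(p)
        table, truth = generate_community(meta, p)
        relab = table.counts / table.counts.sum(axis=1, keepdims=True)
        ph = meta.table["pH"].to_numpy(dtype=float)
        sig = 0
        tested = 0
        for j in range(table.n_otus):
            if relab[:, j].std() == 0:
                continue
            rho, pval = spearman(relab[:, j], ph)
            if not np.isnan(pval):
                tested += 1
                sig += pval < 0.05
        assert sig / tested == pytest.approx(0.05, abs=0.06)

    def test_zero_block_count_supported(self):
        p = SimulationParams(n_sites=10, n_otus=40, n_core=8, n_blocks=0, seed=8)
        table, truth = generate_community(generate_metadata(p), p)
        assert truth.per_otu["block_id"].isna().all()


class TestNutrients:
    def test_alpha_mode_strong_coupling(self):
        p = SimulationParams(seed=9, gamma=1.0, nutrient_noise_sd=0.5)
        table, meta, tax, truth = generate_dataset(p)
        maize = [s for s in table.sample_ids
                 if meta.table.loc[s, "habitat"] == "maize"]
        mi = multinutrient_index(
            meta.table.loc[maize, list(MNC_NUTRIENTS)].astype(float)
        )
        sh = truth.shannon_latent["maize"].loc[maize]
        rho, _ = spearman(mi.values.to_numpy(), sh.to_numpy())
        assert rho > 0.7

    def test_noise_free_alpha_mode_is_monotone_in_shannon(self):
        p = SimulationParams(seed=10, nutrient_noise_sd=1e-12)
        meta = generate_metadata(p)
        table, truth = generate_community(meta, p)
        meta = generate_nutrients(meta, table, truth, p)
        maize = [s for s in table.sample_ids
                 if meta.table.loc[s, "habitat"] == "maize"]
        mi = multinutrient_index(
            meta.table.loc[maize, list(MNC_NUTRIENTS)].astype(float),
            log_rule="none",
        )
        alpha = alpha_diversity(table.select_samples(maize))
        order = np.argsort(alpha.shannon.to_numpy())
        vals = mi.values.to_numpy()[order]
        assert np.all(np.diff(vals) > -1e-9)

    def test_unknown_coupling_mode_rejected(self):
        p = SimulationParams(seed=11, coupling_modes={"maize": "alpha",
                                                      "rice": "nonsense"})
        meta = generate_metadata(p)
        table, truth = generate_community(meta, p)
        with pytest.raises(ValueError):
            generate_nutrients(meta, table, truth, p)


class TestTaxonomy:
    def test_cluster_core_share_class(self, default_survey):
        truth = default_survey["truth"]
        tax = default_survey["taxonomy"]
        core = truth.per_otu[truth.per_otu["is_core"]]
        for niche, grp in core.groupby("niche"):
            classes = tax.rank("class").loc[grp.index].unique()
            assert len(classes) == 1


class TestUnimodalOption:
    def test_unimodal_niche_flag_generates_valid_counts(self):
        p = SimulationParams(n_sites=10, n_otus=60, n_core=8,
                             unimodal_niche=True, seed=12)
        table, truth = generate_community(generate_metadata(p), p)
        table.validate()
        assert table.counts.sum() > 0
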