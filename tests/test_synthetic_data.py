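"""Generators: dendritic networks, sites, presence, two-epoch coalescent."""

import numpy as np
import pytest

from ampexp import popgen_core as pg
from ampexp import synthetic_data as syn
from ampexp.stream_geometry import SiteRecord, site_slope


class TestStreamNetworkGenerator:
    def test_single_source_is_a_path(self):
        net = syn.generate_stream_network(1, seed=0)
        assert len(net.sources) == 1
        assert len(net.outlets) == 1
        assert sum(1 for v in net.graph if net.graph.in_degree(v) >= 2) == 0

    def test_binary_tree_counts(self):
        net = syn.generate_stream_network(8, seed=1)
        assert len(net.sources) == 8
        assert len(net.outlets) == 1
        confluences = sum(1 for v in net.graph if net.graph.in_degree(v) >= 2)
        assert confluences == 7

    def test_deterministic_under_seed(self):
        a = syn.generate_stream_network(8, seed=1)
        b = syn.generate_stream_network(8, seed=1)
        assert list(a.graph.edges(data=True)) == list(b.graph.edges(data=True))
        assert dict(a.graph.nodes(data=True)) == dict(b.graph.nodes(data=True))

    def test_elevation_non_increasing_downstream(self):
        net = syn.generate_stream_network(16, seed=3)
        for u, v in net.graph.edges:
            zu = net.graph.nodes[u]["elevation"]
            zv = net.graph.nodes[v]["elevation"]
            assert zv <= zu
            zs = [p[2] for p in net.graph.edges[u, v]["geometry"]]
            assert all(a >= b for a, b in zip(zs, zs[1:]))

    def test_degenerate_extent_rejected(self):
        with pytest.raises(ValueError):
            syn.generate_stream_network(4, extent=(0, 0, -100, 100), seed=0)
        with pytest.raises(ValueError):
            syn.generate_stream_network(0, seed=0)


class TestSiteGenerator:
    def test_zero_sites_rejected(self):
        net = syn.generate_stream_network(4, seed=0)
        with pytest.raises(ValueError):
            syn.generate_sites(net, 0)

    def test_slope_column_matches_recomputation(self):
        net = syn.generate_stream_network(6, seed=2)
        sites = syn.generate_sites(net, 30, seed=3)
        for row in sites.itertuples():
            rec = SiteRecord(site_id=row.site_id,
                             edge=(row.edge_u, row.edge_v),
                             dist_along=row.dist_along)
            assert site_slope(net, rec).slope_pct == pytest.approx(row.slope_pct)

    def test_identical_positions_get_identical_covariates(self):
        net = syn.generate_stream_network(6, seed=2)
        sites = syn.generate_sites(net, 10, seed=3)
        dup = sites.iloc[[0]].copy()
        both = __import__("pandas").concat([sites.iloc[[0]], dup])
        cov = ["slope_pct", "order", "drainage_cat", "elevation", "temperature"]
        assert both[cov].iloc[0].tolist() == both[cov].iloc[1].tolist()

    def test_covariates_finite(self):
        net = syn.generate_stream_network(10, seed=4)
        sites = syn.generate_sites(net, 100, seed=5)
        assert np.isfinite(sites[["slope_pct", "elevation", "temperature"]]
                           .to_numpy()).all()
        assert set(sites["drainage_cat"]).issubset(
            {"spring", "<10", "10-100", "100-1000", ">1000"})


@pytest.fixture(scope="module")
def sites():
    net = syn.generate_stream_network(8, seed=6)
    return syn.generate_sites(net, 200, seed=7)


class TestPresenceModel:
    def test_saturated_negative_slope_effect_kills_presence(self, sites):
        subset = sites[sites["slope_pct"] >= 1.0]
        model = syn.PresenceModel(intercept=0.0, coef_slope=-1000.0,
                                  coef_temp=0.0, coef_order=0.0)
        out = syn.simulate_presence(subset, model, seed=0)
        assert out["presence"].sum() == 0

    def test_huge_intercept_means_all_present(self, sites):
        model = syn.PresenceModel(intercept=50.0, coef_slope=0.0,
                                  coef_temp=0.0, coef_order=0.0)
        out = syn.simulate_presence(sites, model, seed=0)
        assert out["presence"].all()

    def test_null_model_presence_fraction_half(self, sites):
        import pandas as pd
        big = pd.concat([sites] * 50, ignore_index=True)   # n = 10000
        model = syn.PresenceModel(intercept=0.0, coef_slope=0.0,
                                  coef_temp=0.0, coef_order=0.0)
        out = syn.simulate_presence(big, model, seed=1)
        assert out["presence"].mean() == pytest.approx(0.5, abs=0.02)

    def test_non_finite_covariate_reported_with_site_id(self, sites):
        bad = sites.copy()
        bad.loc[bad.index[3], "temperature"] = np.nan
        with pytest.raises(ValueError, match=str(bad.iloc[3]["site_id"])):
            syn.simulate_presence(bad, syn.PresenceModel(), seed=0)


class TestCoalescent:
    def test_constant_size_mean_pairwise_diff_is_theta(self):
        rng = np.random.default_rng(0)
        for theta in (1.0, 5.0):
            d = syn.simulate_pair_differences(theta, theta, 0.0, 40000, rng=rng)
            se = d.std() / np.sqrt(len(d))
            assert abs(d.mean() - theta) < 4 * se

    def test_watterson_segregating_sites(self):
        """Mean S ~ theta * sum 1/i within 3 Monte-Carlo SE (n=30)."""
        n, reps = 30, 2000
        a1 = sum(1.0 / i for i in range(1, n))
        rng = np.random.default_rng(1)
        for theta in (1.0, 5.0, 20.0):
            S = np.array([syn.simulate_neutral_summaries(n, theta, rng)[0]
                          for _ in range(reps)])
            se = S.std() / np.sqrt(reps)
            assert abs(S.mean() - theta * a1) < 3 * se

    def test_tau_zero_equals_constant_size_distribution(self):
        rng = np.random.default_rng(2)
        a = syn.simulate_pair_differences(5.0, 5.0, 0.0, 30000, rng=rng)
        b = syn.simulate_pair_differences(5.0, 5.0, 7.0, 30000, rng=rng)
        # same model either way: compare distribution means and tails
        assert abs(a.mean() - b.mean()) < 4 * np.hypot(a.std(), b.std()) / np.sqrt(30000)

    def test_bottleneck_to_zero_theta_makes_pairs_identical(self):
        params = syn.ExpansionParams(theta0=1e-12, theta1=1e-9, tau=50.0, n=2)
        aln = syn.simulate_coalescent_expansion(params, seed=3)
        assert pg.nucleotide_diversity(aln) == 0.0

    def test_expansion_mismatch_mode_near_tau(self):
        """Mean mismatch over 500 expansion replicates is unimodal, mode ~ tau."""
        from ampexp.expansion_fit import simulate_mismatch
        tau, reps = 2.0, 500
        rng = np.random.default_rng(4)
        acc = np.zeros(200)
        for _ in range(reps):
            mm = simulate_mismatch(50, 1.0, 100.0, tau, rng)
            f = mm.freqs
            acc[:len(f)] += f
        acc /= reps
        mode = int(acc.argmax())
        assert abs(mode - tau) <= 1
        # unimodal: rises to the mode then falls (tolerating tiny MC jitter)
        trimmed = acc[:30]
        assert all(np.diff(trimmed[:mode + 1]) > -0.01)
        assert all(np.diff(trimmed[mode:]) < 0.01)

    def test_infinite_sites_overflow_raises(self):
        params = syn.ExpansionParams(theta0=50.0, theta1=50.0, tau=0.0,
                                     n=40, seq_len=20)
        with pytest.raises(syn.SimulationError, match="seq_len"):
            syn.simulate_coalescent_expansion(params, seed=5)

    def test_alignment_reproducible_under_seed(self):
        params = syn.ExpansionParams(theta0=1.0, theta1=30.0, tau=2.0, n=20)
        a = syn.simulate_coalescent_expansion(params, seed=6)
        b = syn.simulate_coalescent_expansion(params, seed=6)
        assert a.sequences() == b.sequences()

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            syn.ExpansionParams(theta0=-1.0, theta1=1.0, tau=0.0, n=5)
        with pytest.raises(ValueError):
            syn.ExpansionParams(theta0=0.0, theta1=1.0, tau=0.0, n=1)
        flagged = syn.ExpansionParams(theta0=5.0, theta1=1.0, tau=1.0, n=5)
        assert any("contraction" in f for f in flagged.flags)


@pytest.fixture(scope="module")
def setting():
    net = syn.generate_stream_network(8, seed=8)
    st = syn.generate_sites(net, 80, seed=9)
    st = syn.simulate_presence(st, syn.PresenceModel(intercept=-13.0), seed=10)
    params = syn.ExpansionParams(theta0=0.5, theta1=30.0, tau=2.0, n=40)
    aln = syn.simulate_coalescent_expansion(params, seed=11)
    return st, aln


class TestSequencePlacement:
    def test_every_sample_mapped_exactly_once(self, setting):
        sites, aln = setting
        placed = syn.assign_sequences_to_sites(aln, sites, n_centroids=3,
                                               seed=12)
        assert sorted(placed["sample_id"]) == sorted(aln.sample_ids)
        pres = set(sites.loc[sites["presence"] == 1, "site_id"])
        assert set(placed["site_id"]).issubset(pres)

    def test_single_centroid_placement_ignores_haplotype(self, setting):
        sites, aln = setting
        placed = syn.assign_sequences_to_sites(aln, sites, n_centroids=1,
                                               seed=13)
        assert placed["cluster"].nunique() == 1

    def test_zero_decay_confines_cluster_to_centroid_site(self, setting):
        sites, aln = setting
        placed = syn.assign_sequences_to_sites(aln, sites, n_centroids=2,
                                               decay_scale=0.0, seed=14)
        per_cluster = placed.groupby("cluster")["site_id"].nunique()
        assert (per_cluster == 1).all()

    def test_no_presence_sites_is_an_error(self, setting):
        sites, aln = setting
        empty = sites.copy()
        empty["presence"] = 0
        with pytest.raises(ValueError, match="presence"):
            syn.assign_sequences_to_sites(aln, empty, seed=15)


class TestStudyBundle:
    def test_bundle_is_self_consistent(self):
        net, sites, aln, samples, truth = syn.simulate_study(
            n_sources=6, n_sites=60, seed=1,
            groups=[syn.ExpansionParams(theta0=0.5, theta1=30.0, tau=2.0, n=30),
                    syn.ExpansionParams(theta0=0.2, theta1=20.0, tau=1.0, n=20)])
        assert aln.n == 50
        assert len(samples) == 50
        assert aln.site_ids is not None
        site_ids = set(sites["site_id"])
        assert set(samples["site_id"]).issubset(site_ids)
        assert [g["tau"] for g in truth.groups] == [2.0, 1.0]
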