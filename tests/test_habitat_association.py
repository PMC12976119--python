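"""Randomization habitat tests, species contrasts, thinning, VIF selection."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from ampexp import habitat_association as ha


def make_sites(rng, n=200, k_cats=4):
    return pd.DataFrame({
        "site_id": np.arange(n),
        "x": rng.uniform(0, 50_000, n),
        "y": rng.uniform(0, 50_000, n),
        "cat": rng.integers(0, k_cats, n).astype(str),
        "slope_pct": rng.uniform(0, 50, n),
        "presence": (rng.random(n) < 0.2).astype(int),
    })


class TestCategoryRandomization:
    def test_presence_equals_population_gives_p_one(self):
        rng = np.random.default_rng(0)
        sites = make_sites(rng)
        sites["presence"] = 1
        res = ha.category_randomization_test(sites, "presence", "cat",
                                             ha.TestConfig(B=200, seed=1))
        # every subset is the whole population: no draw is more extreme
        assert all(p == 0.0 for p in res.p_low.values())
        assert all(p == 0.0 for p in res.p_high.values())
        assert all(t == 1.0 for t in res.p_tie.values())

    def test_absent_common_category_flagged_low(self):
        """Observed count 0 in a category carried by ~40% of sites."""
        rng = np.random.default_rng(2)
        sites = make_sites(rng, n=300)
        sites["cat"] = np.where(rng.random(300) < 0.4, "common", "other")
        sites["presence"] = 0
        eligible = sites.index[sites["cat"] == "other"]
        sites.loc[rng.choice(eligible, 40, replace=False), "presence"] = 1
        res = ha.category_randomization_test(sites, "presence", "cat",
                                             ha.TestConfig(B=1000, seed=3))
        assert res.observed["common"] == 0
        assert res.p_low["common"] < 0.025
        # oracle: hypergeometric lower tail P(X < 1) is astronomically small
        assert stats.hypergeom.cdf(0, 300, (sites["cat"] == "common").sum(),
                                   40) < 1e-6

    def test_counts_sum_to_subset_size(self):
        rng = np.random.default_rng(4)
        sites = make_sites(rng)
        res = ha.category_randomization_test(sites, "presence", "cat",
                                             ha.TestConfig(B=50, seed=5))
        total = np.zeros(50, dtype=int)
        for null in res.null.values():
            total += null
        assert (total == res.subset_size).all()

    def test_no_presence_rejected(self):
        rng = np.random.default_rng(6)
        sites = make_sites(rng)
        sites["presence"] = 0
        with pytest.raises(ValueError):
            ha.category_randomization_test(sites, "presence", "cat")


class TestContinuousRandomization:
    def test_constant_column_all_ties(self):
        rng = np.random.default_rng(0)
        sites = make_sites(rng)
        sites["slope_pct"] = 3.0
        res = ha.continuous_randomization_test(sites, "presence", "slope_pct",
                                               ha.TestConfig(B=100, seed=1))
        assert all(v == 0.0 for v in res.p_low.values())
        assert all(v == 0.0 for v in res.p_high.values())

    def test_planted_low_slope_preference_detected(self):
        rng = np.random.default_rng(2)
        sites = make_sites(rng, n=400)
        sites["presence"] = (sites["slope_pct"] < 1.0).astype(int)
        assert sites["presence"].sum() >= 3
        res = ha.continuous_randomization_test(sites, "presence", "slope_pct",
                                               ha.TestConfig(B=1000, seed=3))
        assert res.p_low["mean"] < 0.025
        assert res.p_low["median"] < 0.025
        assert res.p_low["max"] < 0.025

    def test_null_presence_near_median_gives_balanced_tails(self):
        rng = np.random.default_rng(4)
        sites = make_sites(rng, n=500)
        res = ha.continuous_randomization_test(sites, "presence", "slope_pct",
                                               ha.TestConfig(B=2000, seed=5))
        # uninformative labels: both directions should be comfortably non-sig
        assert res.p_low["mean"] > 0.025 and res.p_high["mean"] > 0.025

    def test_nan_value_rejected(self):
        rng = np.random.default_rng(6)
        sites = make_sites(rng)
        sites.loc[0, "slope_pct"] = np.nan
        with pytest.raises(ValueError):
            ha.continuous_randomization_test(sites, "presence", "slope_pct")


class TestSpeciesChisq:
    @staticmethod
    def sites_from_rows(row_a, row_b):
        """Build a site table realising given per-category presence counts."""
        rows = []
        for k, (na, nb) in enumerate(zip(row_a, row_b)):
            for _ in range(na):
                rows.append({"cat": str(k), "A": 1, "B": 0})
            for _ in range(nb):
                rows.append({"cat": str(k), "A": 0, "B": 1})
        return pd.DataFrame(rows)

    def test_hand_computed_2x2(self):
        sites = self.sites_from_rows([10, 0], [0, 10])
        x2, p = ha.species_category_chisq(sites, "A", "B", "cat",
                                          B_mc=200, seed=0)
        assert x2 == pytest.approx(20.0)
        assert p < 0.02

    def test_identical_rows_give_zero_statistic(self):
        sites = self.sites_from_rows([5, 5, 5], [5, 5, 5])
        x2, p = ha.species_category_chisq(sites, "A", "B", "cat",
                                          B_mc=200, seed=1)
        assert x2 == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_monte_carlo_matches_asymptotic_on_large_table(self):
        rng = np.random.default_rng(2)
        row_a = rng.integers(40, 80, 5)
        row_b = rng.integers(40, 80, 5)
        sites = self.sites_from_rows(row_a, row_b)
        x2, p_mc = ha.species_category_chisq(sites, "A", "B", "cat",
                                             B_mc=4000, seed=3)
        table = np.stack([row_a, row_b])
        p_asym = stats.chi2_contingency(table, correction=False).pvalue
        assert p_mc == pytest.approx(p_asym, abs=0.02)

    def test_empty_species_rejected(self):
        sites = self.sites_from_rows([5, 5], [0, 0])
        with pytest.raises(ValueError):
            ha.species_category_chisq(sites, "A", "B", "cat")


class TestRankSum:
    def test_identical_groups_p_near_one(self):
        a = [1.0, 2.0, 3.0, 4.0]
        w, p = ha.rank_sum_test(a, list(a))
        assert p > 0.8

    def test_fully_separated_small_groups_exact(self):
        w, p = ha.rank_sum_test([1.0, 2.0, 3.0], [4.0, 5.0, 6.0],
                                alternative="less")
        assert w == 0.0
        assert p == pytest.approx(1 / 20)     # exact enumeration: 1 of C(6,3)

    def test_shift_alternative_power(self):
        rng = np.random.default_rng(0)
        a = rng.normal(0.0, 1.0, 200)
        b = rng.normal(1.0, 1.0, 200)
        _, p = ha.rank_sum_test(a, b)
        assert p < 1e-6

    def test_nan_rejected(self):
        with pytest.raises(ValueError):
            ha.rank_sum_test([1.0, np.nan], [2.0])


class TestSpatialThin:
    def test_sparse_input_unchanged(self):
        rng = np.random.default_rng(0)
        sites = make_sites(rng, n=20)
        sites["x"] = np.arange(20) * 10_000.0
        sites["y"] = 0.0
        out = ha.spatial_thin(sites, "presence", min_dist=2000.0, seed=1)
        assert len(out) == len(sites)

    def test_two_close_presences_keep_one(self):
        sites = pd.DataFrame({
            "site_id": [0, 1], "x": [0.0, 1000.0], "y": [0.0, 0.0],
            "presence": [1, 1],
        })
        out = ha.spatial_thin(sites, "presence", min_dist=2000.0, seed=2)
        assert len(out) == 1

    def test_absences_near_presences_removed_first(self):
        sites = pd.DataFrame({
            "site_id": [0, 1, 2],
            "x": [0.0, 500.0, 10_000.0], "y": [0.0, 0.0, 0.0],
            "presence": [1, 0, 0],
        })
        out = ha.spatial_thin(sites, "presence", min_dist=2000.0, seed=3)
        assert set(out["site_id"]) == {0, 2}

    def test_no_violating_pairs_remain_and_beats_greedy(self):
        rng = np.random.default_rng(4)
        for trial in range(10):
            centers = rng.uniform(0, 20_000, (5, 2))
            pts = np.vstack([c + rng.normal(0, 1500, (20, 2)) for c in centers])
            sites = pd.DataFrame({
                "site_id": np.arange(len(pts)),
                "x": pts[:, 0], "y": pts[:, 1],
                "presence": rng.integers(0, 2, len(pts)),
            })
            out = ha.spatial_thin(sites, "presence", min_dist=2000.0,
                                  reps=30, seed=trial)
            for flag in (0, 1):
                sub = out[out["presence"] == flag][["x", "y"]].to_numpy()
                if len(sub) > 1:
                    from scipy.spatial.distance import pdist
                    assert pdist(sub).min() >= 2000.0
            # randomized restarts retain at least as many presences as a
            # single deterministic greedy pass over the same points
            pres = sites[sites["presence"] == 1][["x", "y"]].to_numpy()
            greedy = ha.greedy_thin_baseline(pres, 2000.0).sum()
            assert (out["presence"] == 1).sum() >= greedy

    def test_invalid_distance(self):
        rng = np.random.default_rng(5)
        with pytest.raises(ValueError):
            ha.spatial_thin(make_sites(rng), "presence", min_dist=0.0)


class TestSelectPredictors:
    def test_independent_variables_all_kept(self):
        rng = np.random.default_rng(0)
        table = pd.DataFrame(rng.normal(size=(200, 5)),
                             columns=list("abcde"))
        sel = ha.select_predictors(table)
        assert sel.selected == list("abcde")
        assert all(v < 3 for v in sel.vif.values())

    def test_duplicated_variable_collapsed(self):
        rng = np.random.default_rng(1)
        table = pd.DataFrame({"a": rng.normal(size=100)})
        table["b"] = table["a"]
        table["c"] = rng.normal(size=100)
        sel = ha.select_predictors(table)
        assert sel.selected == ["a", "c"]

    def test_planted_correlation_blocks_recovered(self):
        """19 variables in 5 blocks -> exactly 5 clusters."""
        rng = np.random.default_rng(2)
        sizes = [5, 4, 4, 3, 3]
        cols, data = [], []
        for b, size in enumerate(sizes):
            base = rng.normal(size=400)
            for i in range(size):
                data.append(base + rng.normal(0, 0.1, 400))
                cols.append(f"v{b}_{i}")
        table = pd.DataFrame(np.column_stack(data), columns=cols)
        sel = ha.select_predictors(table)
        assert len(sel.clusters) == 5
        assert sorted(len(c) for c in sel.clusters) == sorted(sizes)

    def test_constant_variable_excluded_with_warning(self):
        rng = np.random.default_rng(3)
        table = pd.DataFrame({"a": rng.normal(size=50),
                              "b": np.ones(50),
                              "c": rng.normal(size=50)})
        with pytest.warns(UserWarning, match="constant"):
            sel = ha.select_predictors(table)
        assert sel.excluded_constant == ["b"]
        assert "b" not in sel.selected


class TestCalibration:
    def test_randomization_p_values_valid_under_null(self):
        """Uniform-random presence: rejection at 0.025/tail ~ 5% two-sided."""
        rng = np.random.default_rng(10)
        n, reject, runs = 250, 0, 120
        for rep in range(runs):
            sites = pd.DataFrame({
                "cat": rng.integers(0, 3, n).astype(str),
                "presence": 0,
            })
            sites.loc[rng.choice(n, 40, replace=False), "presence"] = 1
            res = ha.category_randomization_test(
                sites, "presence", "cat",
                ha.TestConfig(B=400, seed=int(rng.integers(2 ** 31))))
            level = "0"
            if res.p_low[level] < 0.025 or res.p_high[level] < 0.025:
                reject += 1
        rate = reject / runs
        assert rate < 0.11        # 5% nominal + Monte-Carlo slack
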