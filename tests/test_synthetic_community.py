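import numpy as np
import pandas as pd
import pytest

from genspec import (
    SyntheticScenario,
    gaussian_field,
    levins_niche_breadth,
    simulate_environment,
    simulate_neutral_table,
    simulate_phylogeny,
    simulate_response,
    simulate_structured_table,
    sloan_predicted_frequency,
)


class TestScenario:
    def test_grid_product_must_match(self):
        with pytest.raises(ValueError, match="grid_shape"):
            SyntheticScenario(n_samples=100, grid_shape=(12, 10))

    def test_planted_classes_bounded(self):
        with pytest.raises(ValueError, match="exceeds"):
            SyntheticScenario(n_otus=10, n_generalists=8, n_specialists=5)

    def test_zero_depth_rejected(self):
        with pytest.raises(ValueError, match="community_size"):
            SyntheticScenario(community_size=0)


class TestStructuredTable:
    def test_row_sums_equal_depth(self, mini_scenario, mini_community):
        table, _, _ = mini_community
        assert (table.counts.sum(axis=1) == mini_scenario.community_size).all()
        assert np.issubdtype(table.counts.dtype, np.integer)

    def test_fixed_seed_reproducible(self, mini_scenario):
        t1, _, _ = simulate_structured_table(mini_scenario)
        t2, _, _ = simulate_structured_table(mini_scenario)
        np.testing.assert_array_equal(t1.counts, t2.counts)

    def test_generalists_occupy_nearly_all_samples(self):
        # no specialists, no background heterogeneity: every OTU near-uniform
        sc = SyntheticScenario(
            n_samples=24, grid_shape=(6, 4), n_otus=50, n_generalists=50,
            n_specialists=0, community_size=10_000, seed=1,
        )
        table, truth, _ = simulate_structured_table(sc)
        occupancy = (table.counts > 0).mean(axis=0)
        assert (occupancy >= 0.95).all()

    def test_point_kernel_confines_specialist(self):
        sc = SyntheticScenario(
            n_samples=24, grid_shape=(6, 4), n_otus=20, n_generalists=2,
            n_specialists=1, community_size=5000, sigma=0.0, seed=2,
        )
        # optimum exactly at one sample's gradient value
        probe, _, meta = simulate_structured_table(sc)
        env = meta.data["env_gradient"].to_numpy()
        table, truth, meta = simulate_structured_table(sc, specialist_optima=np.array([env[7]]))
        spec_id = truth.labels.index[truth.labels == "specialist"][0]
        col = table.counts[:, table.otu_ids.index(spec_id)]
        assert (col[env != env[7]] == 0).all()
        assert col[7] > 0

    def test_off_grid_point_optimum_flagged_all_zero(self):
        sc = SyntheticScenario(
            n_samples=24, grid_shape=(6, 4), n_otus=20, n_generalists=2,
            n_specialists=1, community_size=1000, sigma=0.0, seed=2,
        )
        table, truth, _ = simulate_structured_table(sc, specialist_optima=np.array([99.0]))
        spec_id = truth.labels.index[truth.labels == "specialist"][0]
        assert spec_id in truth.all_zero_otus

    @pytest.mark.parametrize("seed", [11, 12, 13, 14, 15])
    def test_generalists_wider_niche_than_specialists(self, seed):
        sc = SyntheticScenario(
            n_samples=24, grid_shape=(6, 4), n_otus=150, n_generalists=15,
            n_specialists=45, community_size=2000, seed=seed,
        )
        table, truth, _ = simulate_structured_table(sc)
        table = table.drop_empty_otus()
        b = levins_niche_breadth(table)
        labels = truth.labels.loc[table.otu_ids]
        assert b[labels == "generalist"].mean() > b[labels == "specialist"].mean()


class TestNeutralTable:
    def test_fixed_seed_reproducible(self):
        sc = SyntheticScenario(n_samples=24, grid_shape=(6, 4), n_otus=100,
                               n_generalists=0, n_specialists=0,
                               community_size=1000, seed=3)
        t1 = simulate_neutral_table(sc)
        t2 = simulate_neutral_table(sc)
        np.testing.assert_array_equal(t1.counts, t2.counts)

    def test_occurrence_tracks_sloan_prediction(self):
        sc = SyntheticScenario(n_samples=60, grid_shape=(10, 6), n_otus=500,
                               n_generalists=0, n_specialists=0,
                               community_size=1000, migration_rate_m=0.1, seed=4)
        table = simulate_neutral_table(sc).drop_empty_otus()
        p = table.relative_abundance().mean(axis=0)
        f_obs = (table.counts > 0).mean(axis=0)
        f_pred = sloan_predicted_frequency(
            p, sc.migration_rate_m, sc.community_size, np.log(2) / sc.community_size
        )
        assert np.corrcoef(f_obs, f_pred)[0, 1] >= 0.9

    def test_large_m_converges_to_metacommunity(self):
        meta_p = np.full(50, 1 / 50)
        sc_lo = SyntheticScenario(n_samples=24, grid_shape=(6, 4), n_otus=50,
                                  n_generalists=0, n_specialists=0,
                                  community_size=5000, migration_rate_m=0.01, seed=5)
        sc_hi = SyntheticScenario(n_samples=24, grid_shape=(6, 4), n_otus=50,
                                  n_generalists=0, n_specialists=0,
                                  community_size=5000, migration_rate_m=100.0, seed=5)
        tv = {}
        for name, sc in (("lo", sc_lo), ("hi", sc_hi)):
            t = simulate_neutral_table(sc, meta_p)
            rel = t.relative_abundance()
            tv[name] = np.abs(rel - meta_p).sum(axis=1).mean() / 2
        assert tv["hi"] < tv["lo"]
        assert tv["hi"] < 0.05

    def test_zero_frequency_otus_dropped(self, caplog):
        meta_p = np.array([0.5, 0.5, 0.0])
        sc = SyntheticScenario(n_samples=24, grid_shape=(6, 4), n_otus=3,
                               n_generalists=0, n_specialists=0,
                               community_size=100, seed=6)
        with caplog.at_level("WARNING", logger="genspec"):
            t = simulate_neutral_table(sc, meta_p)
        assert t.n_otus == 2

    def test_nonpositive_m_rejected(self):
        sc = SyntheticScenario(n_samples=4, grid_shape=(2, 2), n_otus=10,
                               n_generalists=0, n_specialists=0,
                               community_size=100, migration_rate_m=0.1, seed=0)
        sc.migration_rate_m = 0.0
        with pytest.raises(ValueError, match="migration_rate_m"):
            simulate_neutral_table(sc)


class TestPhylogeny:
    def test_two_tips_is_a_cherry(self):
        tree, optima = simulate_phylogeny(2, 0.5, seed=1)
        tips = list(tree.tips())
        assert len(tips) == 2
        d = tree.tip_tip_distances()
        expected = tips[0].length + tips[1].length
        assert d[(tips[0].name, tips[1].name)] == pytest.approx(expected)

    def test_fixed_seed_reproducible(self):
        t1, o1 = simulate_phylogeny(30, 0.7, seed=9)
        t2, o2 = simulate_phylogeny(30, 0.7, seed=9)
        assert str(t1) == str(t2)
        pd.testing.assert_series_equal(o1, o2)

    def test_signal_partitions_variance_by_clade(self):
        tree, optima = simulate_phylogeny(40, 1.0, seed=3)
        clades = tree.children
        groups = [[t.name for t in c.tips()] if not c.is_tip() else [c.name] for c in clades]
        groups = [g for g in groups if len(g) >= 2]
        within = np.mean([optima.loc[g].var() for g in groups])
        overall = optima.var()
        assert within < overall

    def test_zero_signal_uncorrelated_with_brownian(self):
        tree1, o_sig = simulate_phylogeny(60, 1.0, seed=4)
        tree0, o_null = simulate_phylogeny(60, 0.0, seed=4)
        # same topology/BM seed: zero-signal optima should not reproduce them
        assert abs(np.corrcoef(o_sig, o_null.loc[o_sig.index])[0, 1]) < 0.5

    def test_too_few_tips_rejected(self):
        with pytest.raises(ValueError, match="at least 2"):
            simulate_phylogeny(1, 0.5, seed=0)


def _morans_i(values: np.ndarray, coords: np.ndarray, max_dist: float) -> float:
    d = np.linalg.norm(coords[:, None] - coords[None, :], axis=-1)
    w = ((d > 0) & (d <= max_dist)).astype(float)
    z = values - values.mean()
    n = len(values)
    return n / w.sum() * (z @ w @ z) / (z @ z)


class TestEnvironment:
    def test_positive_spatial_autocorrelation(self):
        sc = SyntheticScenario()
        coords = sc.grid_coords()
        meta = simulate_environment(coords, autocorr_range=60.0, seed=1)
        i = _morans_i(meta.data["CC"].to_numpy(), coords, max_dist=20.0)
        assert i > 0

    def test_huge_range_gives_near_constant_field(self):
        sc = SyntheticScenario()
        rng = np.random.default_rng(0)
        field = gaussian_field(sc.grid_coords(), autocorr_range=1e6, rng=rng)
        assert field.var() < 0.05  # marginal variance is 1

    def test_nonpositive_range_warns_white_noise(self, caplog):
        sc = SyntheticScenario()
        with caplog.at_level("WARNING", logger="genspec"):
            meta = simulate_environment(sc.grid_coords(), autocorr_range=0.0, seed=1)
        assert "white noise" in caplog.text

    def test_fixed_seed_reproducible(self):
        sc = SyntheticScenario()
        m1 = simulate_environment(sc.grid_coords(), seed=2)
        m2 = simulate_environment(sc.grid_coords(), seed=2)
        pd.testing.assert_frame_equal(m1.data, m2.data)

    def test_duplicate_coordinates_rejected(self):
        with pytest.raises(ValueError, match="distinct"):
            simulate_environment(np.zeros((4, 2)), seed=0)

    def test_block_indicators_correlate_within_block(self):
        sc = SyntheticScenario()
        meta = simulate_environment(sc.grid_coords(), seed=3)
        r = np.corrcoef(meta.data["CC"], meta.data["SR"])[0, 1]
        assert r > 0.3

    def test_response_effects_require_known_source(self):
        sc = SyntheticScenario()
        meta = simulate_environment(sc.grid_coords(), seed=4)
        with pytest.raises(KeyError):
            simulate_response(meta, {"nope": 0.5}, seed=0)
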