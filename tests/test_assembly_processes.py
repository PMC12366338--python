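import io
import itertools

import numpy as np
import pandas as pd
import pytest
from skbio import TreeNode

from genspec import (
    OtuTable,
    SyntheticScenario,
    beta_mntd,
    beta_nti,
    c_score,
    c_score_ses,
    fit_sloan_ncm,
    partition_processes,
    raup_crick_bray,
    sequential_swap_nulls,
    simulate_neutral_table,
    simulate_structured_table,
    sloan_predicted_frequency,
)


def tree_from(newick: str) -> TreeNode:
    t = TreeNode.read(io.StringIO(newick))
    for n in t.traverse():
        if n.length is None:
            n.length = 0.0
    return t


class TestBetaMntd:
    def test_identical_communities_score_zero(self):
        tree = tree_from("((x:1,y:1):1,z:2);")
        counts = np.array([[3, 2, 1], [3, 2, 1]])
        table = OtuTable(counts, ["A", "B"], ["x", "y", "z"])
        m = beta_mntd(table, tree)
        assert m.loc["A", "B"] == pytest.approx(0.0)

    def test_single_tip_samples_give_patristic_distance(self):
        tree = tree_from("(x:1,y:1);")
        table = OtuTable(np.array([[5, 0], [0, 3]]), ["A", "B"], ["x", "y"])
        assert beta_mntd(table, tree).loc["A", "B"] == pytest.approx(2.0)

    def test_symmetric_zero_diagonal(self, mini_community, mini_tree):
        table, _, _ = mini_community
        m = beta_mntd(table, mini_tree).to_numpy()
        np.testing.assert_allclose(m, m.T)
        np.testing.assert_allclose(np.diag(m), 0.0)

    def test_scales_linearly_with_branch_lengths(self):
        t1 = tree_from("((x:1,y:2):1,z:3);")
        t2 = tree_from("((x:2,y:4):2,z:6);")
        table = OtuTable(np.array([[3, 1, 0], [0, 2, 5]]), ["A", "B"], ["x", "y", "z"])
        m1 = beta_mntd(table, t1).loc["A", "B"]
        m2 = beta_mntd(table, t2).loc["A", "B"]
        assert m2 == pytest.approx(2 * m1)


class TestBetaNti:
    def test_star_tree_flagged_undefined(self, caplog):
        tree = tree_from("(x:1,y:1,z:1);")
        table = OtuTable(np.array([[3, 1, 0], [0, 2, 5]]), ["A", "B"], ["x", "y", "z"])
        with caplog.at_level("WARNING", logger="genspec"):
            z = beta_nti(table, tree, n_null=29, seed=0)
        assert np.isnan(z.loc["A", "B"])
        assert "undefined" in caplog.text

    def test_invariant_to_sample_relabeling(self, mini_community, mini_tree):
        table, _, _ = mini_community
        z1 = beta_nti(table, mini_tree, n_null=29, seed=3)
        perm = np.random.default_rng(0).permutation(table.n_samples)
        shuffled = OtuTable(
            table.counts[perm], [table.sample_ids[i] for i in perm], table.otu_ids
        )
        z2 = beta_nti(shuffled, mini_tree, n_null=29, seed=3)
        np.testing.assert_allclose(
            z1.loc[shuffled.sample_ids, shuffled.sample_ids].to_numpy(),
            z2.to_numpy(),
            atol=1e-9,
        )

    def test_invariant_to_branch_length_scaling(self):
        t1 = tree_from("((x:1,y:2):1,(z:1,w:3):2);")
        t2 = tree_from("((x:3,y:6):3,(z:3,w:9):6);")
        table = OtuTable(
            np.array([[3, 1, 0, 1], [0, 2, 5, 1], [1, 1, 1, 1]]),
            ["A", "B", "C"],
            ["x", "y", "z", "w"],
        )
        z1 = beta_nti(table, t1, n_null=49, seed=1).to_numpy()
        z2 = beta_nti(table, t2, n_null=49, seed=1).to_numpy()
        np.testing.assert_allclose(z1, z2, atol=1e-9)

    def test_deterministic_for_fixed_seed(self, mini_community, mini_tree):
        table, _, _ = mini_community
        z1 = beta_nti(table, mini_tree, n_null=19, seed=5).to_numpy()
        z2 = beta_nti(table, mini_tree, n_null=19, seed=5).to_numpy()
        np.testing.assert_array_equal(z1, z2)


class TestRaupCrick:
    def test_bounded(self, mini_community):
        table, _, _ = mini_community
        rc = raup_crick_bray(table, n_null=49, seed=0).to_numpy()
        assert np.nanmin(rc) >= -1.0 and np.nanmax(rc) <= 1.0

    def test_identical_samples_near_minus_one(self, mini_community):
        table, _, _ = mini_community
        counts = table.counts.copy()
        counts[1] = counts[0]  # plant an identical pair in a heterogeneous table
        dup = OtuTable(counts, table.sample_ids, table.otu_ids)
        rc = raup_crick_bray(dup, n_null=99, seed=1)
        assert rc.iloc[0, 1] <= -0.95

    def test_seed_deterministic(self, mini_community):
        table, _, _ = mini_community
        a = raup_crick_bray(table, n_null=19, seed=7).to_numpy()
        b = raup_crick_bray(table, n_null=19, seed=7).to_numpy()
        np.testing.assert_array_equal(a, b)


def _pair_frame(values, ids=("A", "B", "C")):
    n = len(ids)
    m = np.zeros((n, n))
    iu = np.triu_indices(n, 1)
    m[iu] = values
    m += m.T
    return pd.DataFrame(m, index=list(ids), columns=list(ids))


class TestPartition:
    def test_all_heterogeneous(self):
        b = _pair_frame([3.0, 3.0, 3.0])
        r = _pair_frame([0.0, 0.0, 0.0])
        res = partition_processes(b, r)
        assert res.process_fractions["heterogeneous_selection"] == 1.0
        assert res.deterministic_fraction == 1.0

    def test_all_drift(self):
        b = _pair_frame([0.0, 0.0, 0.0])
        r = _pair_frame([0.0, 0.0, 0.0])
        res = partition_processes(b, r)
        assert res.process_fractions["drift"] == 1.0
        assert res.stochastic_fraction == 1.0

    def test_fractions_partition_unity(self, mini_community, mini_tree):
        table, _, _ = mini_community
        b = beta_nti(table, mini_tree, n_null=29, seed=2)
        r = raup_crick_bray(table, n_null=29, seed=3)
        res = partition_processes(b, r)
        assert res.process_fractions.sum() == pytest.approx(1.0, abs=1e-12)
        assert res.stochastic_fraction + res.deterministic_fraction == pytest.approx(1.0)

    def test_raising_cut_weakly_decreases_determinism(self, mini_community, mini_tree):
        table, _, _ = mini_community
        b = beta_nti(table, mini_tree, n_null=29, seed=2)
        r = raup_crick_bray(table, n_null=29, seed=3)
        dets = [
            partition_processes(b, r, bnti_cut=cut).deterministic_fraction
            for cut in (1.0, 2.0, 3.0)
        ]
        assert dets[0] >= dets[1] >= dets[2]

    def test_undefined_pairs_excluded(self):
        b = _pair_frame([3.0, np.nan, 0.0])
        r = _pair_frame([0.0, 0.0, 0.0])
        res = partition_processes(b, r)
        assert res.n_pairs == 2 and res.n_excluded == 1


class TestSloanNcm:
    def test_noiseless_self_consistency(self):
        rng = np.random.default_rng(0)
        p = rng.lognormal(0, 2, 400)
        p /= p.sum()
        true_m = 0.07
        f = sloan_predicted_frequency(p, true_m, 10_000, 1e-4)
        fit = fit_sloan_ncm((p, f), detection_limit=1e-4, n_samples=120, N=10_000)
        assert fit.m == pytest.approx(true_m, rel=1e-4)
        assert fit.r_squared >= 0.999

    def test_prediction_monotone_in_p_and_m(self):
        p_grid = np.linspace(1e-5, 0.05, 40)
        for m in (0.05, 0.2, 1.0):
            f = sloan_predicted_frequency(p_grid, m, 10_000, 1e-4)
            assert (np.diff(f) > -1e-12).all()
        for p in (1e-4, 1e-3, 1e-2):
            f = [sloan_predicted_frequency(np.array([p]), m, 10_000, 1e-4)[0]
                 for m in (0.01, 0.05, 0.2, 1.0)]
            assert (np.diff(f) > -1e-12).all()

    def test_filtered_table_fits_worse_than_neutral(self):
        r2 = {"neutral": [], "filtered": []}
        for seed in (1, 2, 3):
            sc = SyntheticScenario(
                n_samples=24, grid_shape=(6, 4), n_otus=300, n_generalists=0,
                n_specialists=0, community_size=2000, migration_rate_m=0.1, seed=seed,
            )
            r2["neutral"].append(fit_sloan_ncm(simulate_neutral_table(sc).drop_empty_otus()).r_squared)
            sc_f = SyntheticScenario(
                n_samples=24, grid_shape=(6, 4), n_otus=300, n_generalists=10,
                n_specialists=200, community_size=2000, seed=seed,
            )
            table, _, _ = simulate_structured_table(sc_f)
            r2["filtered"].append(fit_sloan_ncm(table.drop_empty_otus()).r_squared)
        assert all(f < n for f, n in zip(r2["filtered"], r2["neutral"]))

    def test_too_few_otus_rejected(self):
        table = OtuTable(np.eye(3, dtype=int) + 1, ["A", "B", "C"], ["x", "y", "z"])
        with pytest.raises(ValueError, match="at least 10"):
            fit_sloan_ncm(table)

    def test_constant_frequency_flags_r2(self, caplog):
        p = np.linspace(0.01, 0.05, 20)
        f = np.ones(20)
        with caplog.at_level("WARNING", logger="genspec"):
            fit = fit_sloan_ncm((p, f), detection_limit=1e-4, n_samples=10, N=1000)
        assert np.isnan(fit.r_squared)


def brute_force_c_score(pa: np.ndarray) -> float:
    total, pairs = 0.0, 0
    for i, j in itertools.combinations(range(pa.shape[0]), 2):
        shared = int(np.sum(pa[i] & pa[j]))
        total += (pa[i].sum() - shared) * (pa[j].sum() - shared)
        pairs += 1
    return total / pairs


class TestCScore:
    def test_hand_cases(self):
        assert c_score(np.array([[1, 0], [0, 1]])) == 1.0
        assert c_score(np.array([[1, 1], [1, 0]])) == 0.0
        assert c_score(np.array([[1, 1, 0], [1, 1, 0]])) == 0.0  # identical rows

    def test_matches_brute_force_on_random_matrices(self):
        rng = np.random.default_rng(1)
        for _ in range(25):
            pa = rng.integers(0, 2, size=(5, 6))
            assert c_score(pa) == pytest.approx(brute_force_c_score(pa))

    def test_needs_two_rows(self):
        with pytest.raises(ValueError):
            c_score(np.array([[1, 0, 1]]))


class TestSequentialSwap:
    def test_nulls_preserve_marginals(self, mini_community):
        table, _, _ = mini_community
        pa = table.presence_absence().T
        nulls = sequential_swap_nulls(table, n_sim=20, seed=0, burn_in=2000, thin=200)
        assert len(nulls) == 20
        for null in nulls:
            np.testing.assert_array_equal(null.sum(1), pa.sum(1))
            np.testing.assert_array_equal(null.sum(0), pa.sum(0))

    def test_segregated_matrix_gives_positive_ses(self):
        pa = np.kron(np.eye(2, dtype=int), np.ones((5, 5), dtype=int))
        counts = pa.T  # samples x otus
        table = OtuTable(counts, [f"S{i}" for i in range(10)], [f"O{j}" for j in range(10)])
        res = c_score_ses(table, n_sim=100, seed=1, burn_in=1000, thin=100)
        assert res.ses > 0
        assert res.observed_c >= res.sim_mean

    def test_random_matrix_ses_calibrated(self):
        hits = 0
        for seed in range(20):
            rng = np.random.default_rng(100 + seed)
            pa = rng.integers(0, 2, size=(20, 15))
            pa[pa.sum(1) == 0, 0] = 1
            table = OtuTable(pa.T, [f"S{i}" for i in range(15)], [f"O{j}" for j in range(20)])
            res = c_score_ses(table, n_sim=100, seed=seed, burn_in=2000, thin=100)
            if np.isfinite(res.ses) and abs(res.ses) <= 2:
                hits += 1
        assert hits >= 18

    def test_checkerboard_free_matrix_flagged(self, caplog):
        counts = np.array([[1, 1], [1, 1], [1, 0]])
        table = OtuTable(counts, ["A", "B", "C"], ["x", "y"])
        with caplog.at_level("WARNING", logger="genspec"):
            res = c_score_ses(table, n_sim=10, seed=0, burn_in=10, thin=5)
        assert not np.isfinite(res.ses)
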