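"""Simulator: tree shape, branch-time calibration, missing-data generation."""

import numpy as np
import pytest

from pmmtree.data import MISSING, SILENT
from pmmtree.simulate import (
    CONDITIONS,
    SimConfig,
    expected_mutation_count,
    simulate_characters,
    simulate_dataset,
    simulate_tree,
    subsample,
)
from pmmtree.tree import LineageTree, Node


class TestTree:
    def test_ten_generations_gives_1024_leaves(self):
        t = simulate_tree(SimConfig(generations=10, seed=0))
        assert t.n_leaves() == 1024

    def test_one_generation(self):
        t = simulate_tree(SimConfig(generations=1, subsample_n=2, seed=0))
        assert t.n_leaves() == 2
        assert len(t.edges()) == 3                # root edge + two leaf edges
        t.validate(binary=True)

    def test_branch_time_distribution_calibrated(self):
        """Natural-scale lognormal: mean 1, sd 0.1."""
        rng = np.random.default_rng(1)
        times = []
        cfg = SimConfig(generations=6, subsample_n=2)
        for _ in range(3):
            t = simulate_tree(cfg, rng)
            times += [n.time for n in t.postorder() if n.parent is not None]
        times = np.asarray(times)
        assert len(times) >= 1e4 * 0.03           # 3*(2^7-1) edges
        assert abs(times.mean() - 1.0) < 0.01
        assert abs(times.std() - 0.1) < 0.02

    def test_seed_reproducibility(self):
        cfg = SimConfig(generations=4, K=10, nu=0.1, phi=0.1, subsample_n=4,
                        seed=9)
        d1, d2 = simulate_dataset(cfg), simulate_dataset(cfg)
        assert d1.tree.to_newick() == d2.tree.to_newick()
        assert d1.observed.to_frame().equals(d2.observed.to_frame())
        assert d1.causes.equals(d2.causes)


class TestCharacters:
    def test_no_missing_mechanisms_no_missing(self):
        cfg = SimConfig(generations=5, K=20, nu=0.0, phi=0.0, subsample_n=8,
                        seed=2)
        ds = simulate_dataset(cfg)
        assert ds.observed.n_missing == 0
        assert ds.causes.isna().all().all() or (ds.causes == None).all().all()  # noqa: E711

    def test_pure_heritable_condition_all_heritable(self):
        cfg = SimConfig.condition("h100d0", generations=6, K=20, lam=0.15,
                                  subsample_n=8, seed=3)
        ds = simulate_dataset(cfg)
        causes = ds.causes.to_numpy().ravel()
        causes = causes[causes != None]  # noqa: E711
        assert len(causes) > 0
        assert set(causes) == {"heritable"}

    def test_pure_dropout_condition_all_dropout(self):
        cfg = SimConfig.condition("h0d100", generations=6, K=20, lam=0.15,
                                  subsample_n=8, seed=3)
        ds = simulate_dataset(cfg)
        causes = ds.causes.to_numpy().ravel()
        causes = causes[causes != None]  # noqa: E711
        assert set(causes) == {"dropout"}

    def test_latent_and_observed_consistent(self):
        cfg = SimConfig.condition("h50d50", generations=5, K=15, lam=0.2,
                                  subsample_n=8, seed=4)
        ds = simulate_dataset(cfg)
        lat = ds.latent.to_numpy()
        obs = ds.observed.to_frame().to_numpy()
        for i in range(lat.shape[0]):
            for k in range(lat.shape[1]):
                if lat[i, k] == SILENT:
                    assert obs[i, k] == MISSING
                    assert ds.causes.iat[i, k] == "heritable"
                elif obs[i, k] == MISSING:
                    assert ds.causes.iat[i, k] == "dropout"
                else:
                    assert int(obs[i, k]) == lat[i, k]

    def test_missing_fraction_near_calibration(self):
        """Every named condition is calibrated to about 25% missing."""
        for cond in CONDITIONS:
            fracs = [
                simulate_dataset(
                    SimConfig.condition(cond, generations=7, K=30, lam=0.095,
                                        subsample_n=16, seed=s)
                ).missing_fraction
                for s in (10, 11, 12)
            ]
            # 7 generations + root edge: height ~8, depth lam*8 = 0.76
            nu, phi = CONDITIONS[cond]
            depth = 0.095 * 8.0
            silent = 1 - np.exp(-nu * depth)
            expect = silent + (1 - silent) * phi
            assert np.mean(fracs) == pytest.approx(expect, abs=0.05)


class TestExpectedMutationCount:
    def test_root_edge_no_silencing(self):
        assert expected_mutation_count(0.7, 0.0, 0.0) == pytest.approx(
            1 - np.exp(-0.7)
        )

    def test_printed_value(self):
        got = expected_mutation_count(0.5, 0.1, 1.0)
        assert got == pytest.approx((1 - np.exp(-0.55)) * np.exp(-1.1), abs=1e-9)
        assert got == pytest.approx(0.1408212, abs=1e-6)

    def test_monotone_decreasing_in_root_distance(self):
        vals = [expected_mutation_count(0.5, 0.1, d) for d in (0, 0.5, 1, 2)]
        assert all(b < a for a, b in zip(vals, vals[1:]))

    def test_matches_monte_carlo_on_fixed_tree(self):
        """Per-edge fresh-edit frequency agrees with the closed form within
        three Monte-Carlo standard errors across replicate sites."""
        reps = 600
        cfg = SimConfig(generations=3, K=reps, lam=0.3, nu=0.15, phi=0.0,
                        subsample_n=4, seed=8)
        tree = simulate_tree(cfg, np.random.default_rng(8))
        rng = np.random.default_rng(9)
        from pmmtree.simulate import default_priors

        priors = default_priors(cfg, rng)
        _, _, _, states = simulate_characters(tree, cfg, priors, rng,
                                              return_node_states=True)
        dist = tree.root_distances("delta")
        for node in tree.postorder():
            if node.parent is None:
                continue
            parent_s = states[node.parent.name]
            child_s = states[node.name]
            fresh = ((parent_s == 0) & (child_s > 0)).mean()
            expect = expected_mutation_count(
                node.delta, cfg.nu, dist[node.parent.name]
            )
            se = np.sqrt(max(expect * (1 - expect), 1e-6) / reps)
            assert abs(fresh - expect) <= 3.5 * se


class TestSubsample:
    def test_identity_restriction(self):
        cfg = SimConfig(generations=4, K=10, nu=0.05, phi=0.1, subsample_n=16,
                        seed=5)
        ds = simulate_dataset(cfg)
        (rt, lat, obs, causes), = subsample(
            ds.tree, (ds.latent, ds.observed, ds.causes), 16, seed=0
        )
        assert sorted(rt.leaf_names) == sorted(ds.tree.leaf_names)

    def test_restriction_preserves_leaf_depths_and_pairwise_paths(self):
        cfg = SimConfig(generations=5, K=5, subsample_n=10, seed=6)
        ds = simulate_dataset(cfg)
        full_depth = _leaf_depths(ds.tree)
        (rt, *_), = subsample(ds.tree, (ds.latent, ds.observed, ds.causes),
                              10, seed=1)
        rt_depth = _leaf_depths(rt)
        for name, d in rt_depth.items():
            assert d == pytest.approx(full_depth[name], abs=1e-9)
        # pairwise path lengths via depths + LCA depth
        full_pairs = _pairwise_paths(ds.tree, list(rt_depth))
        rest_pairs = _pairwise_paths(rt, list(rt_depth))
        for key, d in rest_pairs.items():
            assert d == pytest.approx(full_pairs[key], abs=1e-9)

    def test_oversample_rejected(self):
        cfg = SimConfig(generations=3, K=5, subsample_n=8, seed=7)
        ds = simulate_dataset(cfg)
        with pytest.raises(ValueError):
            subsample(ds.tree, (ds.latent, ds.observed, ds.causes), 9)


def _leaf_depths(tree):
    out = {}
    for leaf in tree.leaves():
        d, n = 0.0, leaf
        while n.parent is not None:
            d += n.time
            n = n.parent
        out[leaf.name] = d
    return out


def _pairwise_paths(tree, names):
    import itertools

    paths = {}
    anc = {}
    for name in names:
        chain = []
        n = tree.find(name)
        d = 0.0
        while n is not None:
            chain.append((n.name, d))
            d += n.time if n.time is not None else 0.0
            n = n.parent
        anc[name] = dict(chain)
    for a, b in itertools.combinations(names, 2):
        shared = [v for k, v in anc[a].items() if k in anc[b]]
        paths[(a, b)] = min(anc[a][k] + anc[b][k] for k in anc[a] if k in anc[b])
    return paths
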