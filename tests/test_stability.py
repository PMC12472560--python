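"""Cohesion sign constraints, null convergence, and robustness properties."""

import networkx as nx
import numpy as np
import pandas as pd
import pytest

import myconet as mc
from myconet.containers import AsvTable


def _anti_toy():
    """Three taxa: a and b move together, c moves against both."""
    a = np.array([90, 80, 70, 30, 20, 10])
    counts = pd.DataFrame(
        [a, a + 3, a[::-1]], index=["a", "b", "c"],
        columns=[f"s{i}" for i in range(6)],
    )
    return AsvTable(counts)


class TestCohesion:
    def test_sign_constraints_on_fixture(self, standard_dataset):
        _, table, *_ = standard_dataset
        prof = mc.cohesion(table, null_iterations=100, seed=0)
        assert (prof.cohesion_pos >= 0).all()
        assert (prof.cohesion_neg <= 0).all()
        assert (prof.connectedness_pos >= 0).all()
        assert (prof.connectedness_neg <= 0).all()

    def test_reproducible_from_seed(self, standard_dataset):
        _, table, *_ = standard_dataset
        sub = table.subset_samples(table.sample_ids[:8])
        p1 = mc.cohesion(sub, null_iterations=50, seed=4)
        p2 = mc.cohesion(sub, null_iterations=50, seed=4)
        assert p1.cohesion_pos.equals(p2.cohesion_pos)
        assert p1.cohesion_neg.equals(p2.cohesion_neg)

    def test_duplicated_samples_leave_connectedness_unchanged(self):
        t = _anti_toy()
        doubled = AsvTable(
            pd.concat([t.counts, t.counts.add_suffix("_dup", axis=1)], axis=1)
        )
        p1 = mc.cohesion(t, null_iterations=300, seed=0)
        p2 = mc.cohesion(doubled, null_iterations=300, seed=0)
        # observed correlations are invariant; null means agree up to MC error
        assert p2.connectedness_neg.to_numpy() == pytest.approx(
            p1.connectedness_neg.to_numpy(), abs=0.08
        )

    def test_anticorrelated_taxa_give_negative_cohesion(self):
        prof = mc.cohesion(_anti_toy(), null_iterations=100, seed=0)
        assert (prof.cohesion_neg < 0).all()

    def test_anticorrelated_toy_ratio_above_one(self):
        """c opposes a+b: negative links outweigh the single positive pair."""
        prof = mc.cohesion(_anti_toy(), null_iterations=200, seed=0)
        ratios = mc.stability_ratio(prof)
        assert (ratios > 1).all()

    def test_independent_taxa_ratio_near_one_and_floor_shrinks(self):
        """Without planted structure, positive and negative components are
        symmetric (ratio ~ 1 in distribution) and the cohesion noise floor
        shrinks as replication adds information."""
        ratios, floor_small, floor_large = [], [], []
        for seed in range(8):
            small = mc.null_design(seed=seed, replicates=8, n_taxa=25)
            large = mc.null_design(seed=seed, replicates=30, n_taxa=25)
            for design, store in ((small, floor_small), (large, floor_large)):
                table, _, meta, _ = mc.generate_dataset(design)
                sub = table.subset_samples(
                    meta.loc[meta["treatment"] == "CK", "sample_id"].tolist()
                )
                prof = mc.cohesion(sub, null_iterations=100, seed=seed)
                store.append(float(prof.cohesion_pos.mean()))
                if design is large:
                    ratios.extend(prof.stability_ratio.dropna().tolist())
        assert np.mean(floor_large) < np.mean(floor_small)
        assert np.mean(ratios) == pytest.approx(1.0, abs=0.25)

    def test_null_convergence_rms(self, standard_dataset):
        """Doubling null iterations moves corrected correlations < 0.02 RMS."""
        from myconet.stability import _corr_matrix

        _, table, *_ = standard_dataset
        rel = table.relative_abundance().to_numpy().T

        def null_mean(iters, seed):
            rng = np.random.default_rng(np.random.SeedSequence(seed))
            n, t = rel.shape
            acc = np.zeros((t, t))
            for _ in range(iters):
                perm = np.empty_like(rel)
                for j in range(t):
                    perm[:, j] = rel[rng.permutation(n), j]
                acc += _corr_matrix(perm)
            return acc / iters

        # corrected r' differs only through the null mean
        diff = null_mean(200, 1) - null_mean(400, 2)
        off = diff[np.triu_indices_from(diff, k=1)]
        assert float(np.sqrt((off**2).mean())) < 0.02

    def test_too_few_samples_rejected(self):
        t = AsvTable(pd.DataFrame({"s1": [1, 2], "s2": [2, 1], "s3": [1, 1]}, index=["a", "b"]))
        with pytest.raises(mc.ValidationError, match=">= 4 samples"):
            mc.cohesion(t)


class TestStabilityRatio:
    def test_arithmetic(self):
        prof = mc.CohesionProfile(
            connectedness_pos=pd.Series(dtype=float),
            connectedness_neg=pd.Series(dtype=float),
            cohesion_pos=pd.Series({"s1": 0.2, "s2": 0.4}),
            cohesion_neg=pd.Series({"s1": -0.1, "s2": 0.0}),
            stability_ratio=pd.Series(dtype=float),
            null_iterations=1,
            seed=0,
        )
        out = mc.stability_ratio(prof)
        assert out["s1"] == pytest.approx(0.5)
        assert out["s2"] == pytest.approx(0.0)

    def test_nonpositive_cohesion_flagged_nan(self):
        prof = mc.CohesionProfile(
            connectedness_pos=pd.Series(dtype=float),
            connectedness_neg=pd.Series(dtype=float),
            cohesion_pos=pd.Series({"s1": 0.0}),
            cohesion_neg=pd.Series({"s1": -0.1}),
            stability_ratio=pd.Series(dtype=float),
            null_iterations=1,
            seed=0,
        )
        assert np.isnan(mc.stability_ratio(prof)["s1"])


def _as_net(g, group=None):
    h = nx.Graph()
    h.add_nodes_from(g.nodes())
    for u, v in g.edges():
        h.add_edge(u, v, rho=0.9, sign="+")
    return mc.CoOccurrenceNetwork(graph=h, group=group)


class TestRobustness:
    def test_complete_graph_stays_connected(self):
        net = _as_net(nx.complete_graph(10))
        r = mc.robustness(net, "random", 0.5, replicates=10, seed=0)
        assert r.values == pytest.approx(np.ones(10))

    def test_star_hub_removal_shatters(self):
        net = _as_net(nx.star_graph(9))  # hub + 9 leaves
        r = mc.robustness(net, "targeted", removal_fraction=0.1)
        assert r.values[0] == pytest.approx(1 / 9)

    def test_random_mode_deterministic_given_seed(self):
        net = _as_net(nx.gnm_random_graph(30, 60, seed=3))
        a = mc.robustness(net, "random", 0.5, replicates=2, seed=11)
        b = mc.robustness(net, "random", 0.5, replicates=2, seed=11)
        assert np.array_equal(a.values, b.values)

    def test_fraction_one_rejected(self):
        net = _as_net(nx.complete_graph(4))
        with pytest.raises(mc.ValidationError):
            mc.robustness(net, "random", removal_fraction=1.0)

    def test_monotone_decline_in_removal_fraction(self):
        """Mean giant fraction never increases with heavier removal."""
        rng_seeds = range(20)
        for seed in rng_seeds:
            net = _as_net(nx.gnm_random_graph(25, 50, seed=seed))
            means = [
                mc.robustness(net, "random", f, replicates=30, seed=1).mean
                for f in (0.1, 0.3, 0.5, 0.7)
            ]
            assert all(means[i] >= means[i + 1] - 0.12 for i in range(3)), seed

    def test_targeted_beats_random_on_hub_heavy_graphs(self):
        """Degree-targeted attack is at least as damaging as random removal."""
        worse = 0
        for seed in range(10):
            net = _as_net(nx.barabasi_albert_graph(40, 1, seed=seed))
            tgt = mc.robustness(net, "targeted", 0.3).values[0]
            rnd = mc.robustness(net, "random", 0.3, replicates=50, seed=1).mean
            worse += tgt <= rnd + 1e-9
        assert worse >= 9


class TestCompareStability:
    def test_identical_groups_ns(self):
        vals = {"CK": np.array([0.5, 0.6, 0.7]), "BF": np.array([0.5, 0.6, 0.7])}
        out = mc.compare_stability(vals, control="CK")
        assert out.iloc[0]["stars"] == "ns"

    def test_single_group_rejected(self):
        with pytest.raises(mc.ValidationError, match=">= 2 groups"):
            mc.compare_stability({"CK": np.array([1.0, 2.0])})

    def test_planted_contrast_detected(self, standard_dataset):
        """The dense/anti-rich CF group separates from sparse BF in ratio."""
        _, table, *_ = standard_dataset
        ratios = {}
        for g in ("CF", "BF"):
            sub = table.subset_samples([s for s in table.sample_ids if s.startswith(g)])
            ratios[g] = mc.cohesion(sub, null_iterations=100, seed=0).stability_ratio.dropna()
        out = mc.compare_stability(ratios, control="CF")
        assert out.iloc[0]["mean"] < out.iloc[0]["control_mean"]
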