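"""Spearman matrices, bootstrap ensembles, edge filters, density, degrees."""

from itertools import combinations

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from nutnet import networks, simulate


def _frame(array):
    arr = np.asarray(array, dtype=float)
    return pd.DataFrame(arr, columns=[f"g{j}" for j in range(arr.shape[1])])


class TestSpearmanMatrix:
    def test_monotone_pair_is_one(self):
        frame = _frame(np.column_stack([np.arange(10), np.arange(10) ** 3]))
        cm = networks.spearman_matrix(frame)
        assert cm.rho[0, 1] == pytest.approx(1.0)

    def test_constant_column_degenerate(self):
        frame = _frame(np.column_stack([np.arange(8), np.full(8, 3.0)]))
        cm = networks.spearman_matrix(frame)
        assert cm.degenerate.tolist() == [False, True]
        assert cm.rho[0, 1] == 0.0
        assert cm.p[0, 1] == 1.0

    def test_toy_matches_brute_force_rank_formula(self, rng):
        # independent oracle: average ranks by hand + Pearson on ranks +
        # two-sided t-approximation
        X = rng.normal(size=(9, 4))
        X[3, 1] = X[5, 1]  # introduce a tie
        cm = networks.spearman_matrix(_frame(X))
        for i, j in combinations(range(4), 2):
            r_i = pd.Series(X[:, i]).rank().to_numpy()
            r_j = pd.Series(X[:, j]).rank().to_numpy()
            rho = np.corrcoef(r_i, r_j)[0, 1]
            t = rho * np.sqrt((9 - 2) / (1 - rho**2))
            p = 2 * sps.t.sf(abs(t), 9 - 2)
            assert cm.rho[i, j] == pytest.approx(rho, abs=1e-12)
            assert cm.p[i, j] == pytest.approx(p, rel=1e-9)

    def test_too_few_subjects(self):
        with pytest.raises(networks.NetworkError):
            networks.spearman_matrix(_frame(np.ones((3, 3))))


class TestBootstrap:
    def test_seed_determinism(self, rng):
        data = _frame(rng.normal(size=(30, 5)))
        a = networks.bootstrap_ensemble(data, n_boot=10, seed=42)
        b = networks.bootstrap_ensemble(data, n_boot=10, seed=42)
        np.testing.assert_array_equal(a.indices, b.indices)
        for ra, rb in zip(a.replicates, b.replicates):
            np.testing.assert_array_equal(ra.rho, rb.rho)

    def test_single_subject_degenerates(self):
        data = _frame([[1.0, 2.0, 3.0]])
        ens = networks.bootstrap_ensemble(data, n_boot=5, seed=0)
        assert all(rep.degenerate.all() for rep in ens.replicates)

    def test_invalid_b(self):
        with pytest.raises(networks.NetworkError):
            networks.bootstrap_ensemble(_frame(np.ones((5, 2))), n_boot=0)

    def test_planted_edge_concentrates(self, rng):
        cov = np.array([[1.0, 0.8], [0.8, 1.0]])
        data = _frame(rng.multivariate_normal([0, 0], cov, size=400))
        ens = networks.bootstrap_ensemble(data, n_boot=50, seed=1)
        rhos = np.array([rep.rho[0, 1] for rep in ens.replicates])
        q1, q3 = np.percentile(rhos, [25, 75])
        assert 0.7 < q1 < q3 < 0.88


def _ensemble_from_counts(n_qualifying, n_boot=100, rho=0.8, n_sub=200):
    """Hand-built ensemble for one pair: a replicate either clearly
    qualifies (tiny p, |rho| above threshold) or clearly does not."""
    reps = []
    for r in range(n_boot):
        hit = r < n_qualifying
        rho_val = rho if hit else 0.05
        p_val = 1e-8 if hit else 0.9
        rho_m = np.array([[1.0, rho_val], [rho_val, 1.0]])
        p_m = np.array([[0.0, p_val], [p_val, 0.0]])
        reps.append(
            networks.CorrelationMatrix(
                rho=rho_m, p=p_m, nodes=["a", "b"], degenerate=np.zeros(2, bool)
            )
        )
    return networks.BootstrapEnsemble(
        replicates=reps, indices=np.zeros((n_boot, n_sub), int), nodes=["a", "b"]
    )


class TestStableEdges:
    def test_persistence_boundary_50_of_100(self):
        kept = networks.stable_edges(_ensemble_from_counts(50))
        assert kept.n_edges == 1
        assert kept.edges.loc[0, "persistence"] == pytest.approx(0.5)

    def test_persistence_boundary_49_of_100(self):
        dropped = networks.stable_edges(_ensemble_from_counts(49))
        assert dropped.n_edges == 0

    def test_negative_edge_sign_and_median(self):
        net = networks.stable_edges(_ensemble_from_counts(80, rho=-0.7))
        assert net.n_edges == 1
        assert net.edges.loc[0, "sign"] == -1
        assert net.edges.loc[0, "median_rho"] == pytest.approx(-0.7)

    def test_identity_structure_yields_empty_network(self):
        cfg = simulate.GeneratorConfig(
            n_subjects=300,
            dmpw_proportions=(1.0, 0.0, 0.0),
            n_patterns=1,
            pattern_mixture_weights=(1.0,),
            correlation_spec={
                name: np.eye(14) for name in ("Agreed", "Underestimated", "Overestimated")
            },
            n_clusters=6,
            seed=11,
        )
        cohort, truth = simulate.generate_cohort(cfg)
        intakes = simulate.generate_ffq_intakes(cohort, cfg, truth)
        ens = networks.bootstrap_ensemble(intakes, n_boot=30, seed=2)
        net = networks.stable_edges(ens)
        assert net.n_edges == 0
        assert net.density == 0.0

    def test_filter_monotonicity(self, rng):
        cov = np.eye(4)
        cov[0, 1] = cov[1, 0] = 0.62
        cov[2, 3] = cov[3, 2] = 0.55
        data = _frame(rng.multivariate_normal(np.zeros(4), cov, size=120))
        ens = networks.bootstrap_ensemble(data, n_boot=40, seed=3)

        def edge_set(**kw):
            net = networks.stable_edges(ens, **kw)
            return {tuple(sorted((r.node1, r.node2))) for r in net.edges.itertuples()}

        base = edge_set()
        assert edge_set(persistence=0.8) <= base
        assert edge_set(rho_threshold=0.6) <= base
        assert edge_set(alpha=0.001) <= base


class TestDensityAndDegrees:
    def test_density_worked_examples(self):
        assert networks.network_density(0, 14) == 0.0
        assert networks.network_density(91, 14) == 1.0
        assert networks.network_density(14, 14) == pytest.approx(14 / 91)

    def test_density_matches_pair_enumeration(self):
        for n_nodes in range(2, 21):
            total = len(list(combinations(range(n_nodes), 2)))
            for L in range(total + 1):
                assert networks.network_density(L, n_nodes) == pytest.approx(L / total)

    def test_density_bounds_enforced(self):
        with pytest.raises(networks.NetworkError):
            networks.network_density(92, 14)
        with pytest.raises(networks.NetworkError):
            networks.network_density(-1, 14)

    def _star(self):
        edges = pd.DataFrame(
            {
                "node1": ["c"] * 4,
                "node2": ["l1", "l2", "l3", "l4"],
                "sign": [1] * 4,
                "median_rho": [0.6] * 4,
                "persistence": [1.0] * 4,
            }
        )
        return networks.StableNetwork(
            nodes=["c", "l1", "l2", "l3", "l4"],
            edges=edges,
            n_boot=100,
            rho_threshold=0.5,
            alpha=0.05,
            persistence=0.5,
        )

    def test_star_degrees(self):
        deg = networks.node_degrees(self._star())
        assert deg["c"] == 4
        assert set(deg[deg.index != "c"]) == {1}

    def test_handshake_identity(self, rng):
        data = _frame(rng.multivariate_normal(np.zeros(6), np.eye(6), size=80))
        ens = networks.bootstrap_ensemble(data, n_boot=20, seed=4)
        net = networks.stable_edges(ens, rho_threshold=0.1, alpha=0.5, adjust=False)
        assert networks.node_degrees(net).sum() == 2 * net.n_edges

    def test_networkx_export(self):
        g = self._star().to_networkx()
        assert g.number_of_edges() == 4
        assert g["c"]["l1"]["sign"] == 1


class TestCompareDensities:
    def test_identical_samples_dunn_p_one(self):
        d = {"a": np.full(10, 0.2), "b": np.full(10, 0.2)}
        res = networks.compare_densities(d)
        assert res.pvalue == 1.0
        assert (res.pairwise["p_holm"] == 1.0).all()

    def test_shifted_group_detected(self, rng):
        d = {
            "a": rng.uniform(0.10, 0.14, 100),
            "b": rng.uniform(0.10, 0.14, 100),
            "c": rng.uniform(0.02, 0.05, 100),
        }
        res = networks.compare_densities(d)
        pairs = res.pairwise.set_index(["group1", "group2"])["p_holm"]
        assert pairs[("a", "c")] < 0.05 and pairs[("b", "c")] < 0.05

    def test_requires_two_groups(self):
        with pytest.raises(networks.NetworkError):
            networks.compare_densities({"a": np.ones(5)})
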