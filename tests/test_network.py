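"""Signed network construction, TOM, module detection, eigengenes,
trait correlation and cross-network overlap."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import kstest

from brainage import network
from brainage.network import NetworkParams
from brainage.simulate import SimConfig, simulate_module_expression


def _df(arr, prefix="g"):
    arr = np.asarray(arr, dtype=float)
    return pd.DataFrame(arr, index=[f"{prefix}{i}" for i in range(arr.shape[0])],
                        columns=[f"s{j}" for j in range(arr.shape[1])])


@pytest.fixture(scope="module")
def planted():
    cfg = SimConfig(seed=1, n_genes=400, pattern_counts={}, n_modules=3,
                    module_size_range=(50, 60), module_cor=0.8,
                    preserved_fraction=0.34)
    ea, eb, ortho, truth = simulate_module_expression(cfg)
    return ea, eb, ortho, truth


class TestAdjacency:
    def test_endpoints(self):
        x = np.arange(6.0)
        expr = _df(np.vstack([x, 2 * x + 1, -x]))  # cor +1 and -1
        a = network.signed_adjacency(expr, beta=14)
        assert a.iloc[0, 1] == pytest.approx(1.0)
        assert a.iloc[0, 2] == pytest.approx(0.0, abs=1e-12)
        assert a.iloc[0, 0] == 1.0

    def test_zero_correlation_closed_form(self):
        expr = _df([[1, -1, 1, -1], [1, 1, -1, -1]])
        a = network.signed_adjacency(expr, beta=14)
        assert a.iloc[0, 1] == pytest.approx(0.5 ** 14, rel=1e-12)

    def test_matches_bruteforce_double_loop(self):
        rng = np.random.default_rng(0)
        expr = _df(rng.standard_normal((6, 10)))
        a = network.signed_adjacency(expr, beta=14).to_numpy()
        x = expr.to_numpy()
        for i in range(6):
            for j in range(6):
                if i == j:
                    expected = 1.0
                else:
                    c = np.corrcoef(x[i], x[j])[0, 1]
                    expected = ((1 + c) / 2) ** 14
                assert a[i, j] == pytest.approx(expected, abs=1e-12)

    def test_constant_gene_rejected(self):
        expr = _df([[1, 1, 1, 1], [1, 2, 3, 4]])
        with pytest.raises(ValueError, match="constant"):
            network.signed_adjacency(expr)


class TestTOM:
    def test_identical_neighbourhoods_full_overlap(self):
        n = 5
        a = np.ones((n, n))
        tom = network.topological_overlap(pd.DataFrame(a))
        assert np.allclose(tom, 1.0)

    def test_disjoint_neighbourhoods_zero(self):
        # two components, no connecting edge
        a = np.eye(4)
        a[0, 1] = a[1, 0] = 0.8
        a[2, 3] = a[3, 2] = 0.8
        tom = network.topological_overlap(pd.DataFrame(a))
        assert tom.iloc[0, 2] == 0.0
        assert tom.iloc[1, 3] == 0.0

    def test_matches_triple_loop_bruteforce(self):
        rng = np.random.default_rng(1)
        c = rng.uniform(0.0, 1.0, size=(6, 6))
        a = (c + c.T) / 2
        np.fill_diagonal(a, 1.0)
        tom = network.topological_overlap(pd.DataFrame(a)).to_numpy()
        a0 = a.copy()
        np.fill_diagonal(a0, 0.0)
        k = a0.sum(axis=1)
        for i in range(6):
            for j in range(6):
                if i == j:
                    continue
                l_ij = sum(a0[i, u] * a0[u, j] for u in range(6)
                           if u not in (i, j))
                expected = (l_ij + a0[i, j]) / (min(k[i], k[j]) + 1 - a0[i, j])
                assert tom[i, j] == pytest.approx(expected, abs=1e-12)

    def test_bounds_symmetry_and_diagonal(self):
        rng = np.random.default_rng(2)
        expr = _df(rng.standard_normal((30, 8)))
        tom = network.topological_overlap(
            network.signed_adjacency(expr)).to_numpy()
        assert np.allclose(tom, tom.T)
        assert np.all((tom >= 0) & (tom <= 1))
        assert np.allclose(np.diag(tom), 1.0)

    def test_asymmetric_input_rejected(self):
        a = np.eye(3)
        a[0, 1] = 0.5
        with pytest.raises(ValueError, match="symmetric"):
            network.topological_overlap(pd.DataFrame(a))


class TestConnectivityFilter:
    def test_all_tied_connectivities_lose_nothing(self):
        # four genes with identical pairwise structure
        x = np.arange(8.0)
        expr = _df(np.vstack([x + 0.01 * np.random.default_rng(i).standard_normal(8)
                              for i in range(4)]))
        out = network.connectivity_filter(expr)
        # near-ties: the midpoint percentile keeps at-threshold genes
        assert len(out) >= 3

    def test_isolated_gene_removed(self):
        rng = np.random.default_rng(3)
        base = rng.standard_normal(10)
        block = [base + 0.1 * rng.standard_normal(10) for _ in range(9)]
        isolated = rng.standard_normal(10)
        expr = _df(np.vstack(block + [isolated]))
        out = network.connectivity_filter(expr)
        assert "g9" not in out.index

    def test_second_pass_removes_no_more_than_first(self):
        rng = np.random.default_rng(4)
        expr = _df(rng.standard_normal((50, 10)))
        once = network.connectivity_filter(expr)
        twice = network.connectivity_filter(once)
        assert len(once) - len(twice) <= len(expr) - len(once)


class TestCutModules:
    def test_planted_recovery(self, planted):
        from sklearn.metrics import adjusted_rand_score
        ea, _, _, truth = planted
        tom = network.topological_overlap(network.signed_adjacency(ea, 14))
        asg = network.cut_modules(1 - tom, NetworkParams())
        ari = adjusted_rand_score(truth.modules["a"], asg.labels)
        assert asg.labels.max() >= 2
        assert ari >= 0.8
        assert (asg.module_sizes() >= NetworkParams().min_module_size).all()

    def test_all_noise_mostly_unassigned(self):
        rng = np.random.default_rng(5)
        expr = _df(rng.standard_normal((300, 12)))
        tom = network.topological_overlap(network.signed_adjacency(expr, 14))
        asg = network.cut_modules(1 - tom, NetworkParams())
        assert (asg.labels == 0).mean() >= 0.9

    def test_deterministic(self, planted):
        ea, _, _, _ = planted
        tom = network.topological_overlap(network.signed_adjacency(ea, 14))
        a1 = network.cut_modules(1 - tom, NetworkParams())
        a2 = network.cut_modules(1 - tom, NetworkParams())
        pd.testing.assert_series_equal(a1.labels, a2.labels)

    def test_too_few_genes_all_grey(self):
        rng = np.random.default_rng(6)
        expr = _df(rng.standard_normal((10, 6)))
        tom = network.topological_overlap(network.signed_adjacency(expr))
        with pytest.warns(UserWarning, match="min_module_size"):
            asg = network.cut_modules(1 - tom, NetworkParams())
        assert (asg.labels == 0).all()


class TestEigengene:
    def test_identical_genes_give_profile_and_full_variance(self):
        prof = np.array([1.0, 3.0, -2.0, 0.5, 2.0, -1.0])
        expr = _df(np.vstack([prof, prof, prof]))
        labels = pd.Series([1, 1, 1], index=expr.index)
        eig, varexp = network.module_eigengene(expr, labels)
        assert varexp["ME1"] == pytest.approx(1.0)
        z = (prof - prof.mean()) / prof.std()
        got = eig["ME1"].to_numpy()
        assert np.allclose(np.abs(np.corrcoef(got, z)[0, 1]), 1.0)
        # sign convention: positively correlated with module mean
        assert np.corrcoef(got, prof)[0, 1] > 0

    def test_matches_svd_bruteforce(self):
        rng = np.random.default_rng(7)
        expr = _df(rng.standard_normal((5, 12)))
        labels = pd.Series(1, index=expr.index)
        eig, varexp = network.module_eigengene(expr, labels)
        x = expr.to_numpy()
        xs = (x - x.mean(1, keepdims=True)) / x.std(1, keepdims=True)
        u, s, vt = np.linalg.svd(xs, full_matrices=False)
        expected = vt[0] if vt[0] @ xs.mean(0) >= 0 else -vt[0]
        assert np.allclose(eig["ME1"], expected, atol=1e-10)
        assert varexp["ME1"] == pytest.approx(s[0] ** 2 / (s ** 2).sum())

    def test_sign_flip_of_module_flips_eigengene(self):
        rng = np.random.default_rng(8)
        expr = _df(rng.standard_normal((4, 10)))
        labels = pd.Series(1, index=expr.index)
        eig1, _ = network.module_eigengene(expr, labels)
        eig2, _ = network.module_eigengene(-expr, labels)
        assert np.allclose(eig1["ME1"], -eig2["ME1"], atol=1e-10)


class TestTraitCorrelation:
    def test_perfect_indicator(self):
        eig = pd.DataFrame({"ME1": [0, 0, 0, 1, 1, 1.0]})
        traits = pd.DataFrame({"cond": [0, 0, 0, 1, 1, 1]})
        out = network.module_trait_correlation(eig, traits)
        row = out.iloc[0]
        assert row["cor"] == pytest.approx(1.0)
        assert row["p"] < 1e-6

    def test_bicor_close_to_pearson_on_clean_gaussian(self):
        rng = np.random.default_rng(9)
        x = rng.standard_normal(200)
        y = 0.6 * x + 0.8 * rng.standard_normal(200)
        b = network.bicor(x, y)
        p = np.corrcoef(x, y)[0, 1]
        assert abs(b - p) < 0.02

    def test_null_permutation_pvalues_uniform(self):
        rng = np.random.default_rng(10)
        eig = pd.DataFrame({"ME1": rng.standard_normal(12)})
        pvals = []
        for _ in range(1000):
            t = np.zeros(12)
            t[rng.choice(12, 6, replace=False)] = 1
            out = network.module_trait_correlation(
                eig, pd.DataFrame({"t": t}))
            pvals.append(out["p"].iloc[0])
        assert kstest(pvals, "uniform").pvalue > 0.01

    def test_non_binary_trait_rejected(self):
        eig = pd.DataFrame({"ME1": [0.1, 0.2, 0.3, 0.4]})
        with pytest.raises(ValueError, match="binary"):
            network.module_trait_correlation(
                eig, pd.DataFrame({"t": [1, 2, 3, 4]}))


class TestModuleOverlap:
    def test_identity_map_gives_diagonal(self):
        labels = pd.Series([1, 1, 2, 2, 3], index=list("abcde"))
        ortho = pd.DataFrame({"x": list("abcde"), "y": list("abcde")})
        tab, fisher, sankey = network.module_overlap(labels, labels, ortho)
        off_diag = tab.to_numpy().sum() - np.trace(tab.to_numpy())
        assert off_diag == 0

    def test_link_weights_conserve_orthologs(self):
        rng = np.random.default_rng(11)
        genes = [f"g{i}" for i in range(40)]
        la = pd.Series(rng.integers(1, 4, 40), index=genes)
        lb = pd.Series(rng.integers(1, 4, 40), index=genes)
        ortho = pd.DataFrame({"x": genes, "y": genes})
        tab, _, sankey = network.module_overlap(la, lb, ortho)
        assert sum(link["value"] for link in sankey["links"]) == 40

    def test_empty_intersection_rejected(self):
        la = pd.Series([1], index=["a"])
        lb = pd.Series([1], index=["b"])
        ortho = pd.DataFrame({"x": ["zz"], "y": ["ww"]})
        with pytest.raises(ValueError, match="no ortholog"):
            network.module_overlap(la, lb, ortho)
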