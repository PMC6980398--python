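"""Differential-expression core: filtering, TMM, RUV, moderated t, BH."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.optimize import brentq
from scipy.special import digamma, polygamma
from scipy.stats import kstest

from brainage import de


def _df(arr, genes=None, samples=None):
    arr = np.asarray(arr)
    genes = genes or [f"g{i}" for i in range(arr.shape[0])]
    samples = samples or [f"s{j}" for j in range(arr.shape[1])]
    return pd.DataFrame(arr, index=genes, columns=samples)


# ---------------------------------------------------------------- filtering

class TestCpmFilter:
    def test_all_zero_gene_removed(self):
        counts = _df([[10, 10], [0, 0]])
        kept = de.filter_by_cpm(counts, min_cpm=1.5, min_samples=1)
        assert list(kept.index) == ["g0"]

    def test_toy_hand_cpm(self):
        # library sizes are column sums (10, 10); gene 0 has cpm 1e6 > 1.5
        counts = _df([[10, 10], [0, 0]])
        cpm = de.cpm(counts)
        assert cpm.iloc[0, 0] == pytest.approx(1e6)
        assert cpm.iloc[1, 0] == 0.0

    def test_threshold_is_strict_and_min_samples_inclusive(self):
        # one gene at exactly the threshold count in 6 of 12 samples
        n = 12
        lib = 1_000_000
        filler = np.full((1, n), lib - 2)
        target = np.array([[1.6 if j < 6 else 1.0 for j in range(n)]])
        counts = _df(np.vstack([filler, target]))
        # cpm of target gene ~ 1.6 in 6 samples -> retained at (1.5, 6)
        kept = de.filter_by_cpm(counts, 1.5, 6)
        assert "g1" in kept.index
        # but not at min_samples = 7
        assert "g1" not in de.filter_by_cpm(counts, 1.5, 7).index

    def test_order_preserved(self):
        rng = np.random.default_rng(0)
        counts = _df(rng.integers(0, 500, size=(50, 4)))
        kept = de.filter_by_cpm(counts, 1.0, 2)
        assert list(kept.index) == [g for g in counts.index if g in kept.index]


# --------------------------------------------------------------------- TMM

def _tmm_bruteforce(counts: np.ndarray, j: int, ref: int) -> float:
    """Independent trim-and-weight evaluation of the pairwise TMM factor."""
    obs, refv = counts[:, j].astype(float), counts[:, ref].astype(float)
    n_o, n_r = obs.sum(), refv.sum()
    pos = (obs > 0) & (refv > 0)
    obs, refv = obs[pos], refv[pos]
    m = np.log2((obs / n_o) / (refv / n_r))
    a = 0.5 * (np.log2(obs / n_o) + np.log2(refv / n_r))
    w = (n_o - obs) / (n_o * obs) + (n_r - refv) / (n_r * refv)
    if np.max(np.abs(m)) < 1e-6:
        return 1.0
    n = m.size
    lo_m, hi_m = np.floor(n * 0.3) + 1, n - np.floor(n * 0.3)
    lo_a, hi_a = np.floor(n * 0.05) + 1, n - np.floor(n * 0.05)
    rm = pd.Series(m).rank().to_numpy()
    ra = pd.Series(a).rank().to_numpy()
    keep = (rm >= lo_m) & (rm <= hi_m) & (ra >= lo_a) & (ra <= hi_a)
    return 2.0 ** (np.sum(m[keep] / w[keep]) / np.sum(1.0 / w[keep]))


class TestTmm:
    def test_identical_samples_give_unit_factors(self):
        counts = _df(np.tile([[100], [200], [50], [400], [10]], (1, 2)))
        f = de.tmm_factors(counts)
        assert np.allclose(f, 1.0)

    def test_pure_depth_difference_absorbed(self):
        base = np.array([100, 200, 50, 400, 10, 33, 77])
        counts = _df(np.column_stack([base, 2 * base]))
        f = de.tmm_factors(counts)
        assert np.allclose(f, 1.0, atol=1e-12)

    def test_matches_bruteforce_on_de_gene_toy(self):
        # 5 genes, one 10-fold DE, forces a non-trivial trim
        rng = np.random.default_rng(3)
        counts = rng.integers(50, 2000, size=(25, 3))
        counts[0, 0] *= 10
        cdf = _df(counts)
        f = de.tmm_factors(cdf)
        lib = counts.sum(axis=0)
        f75 = np.quantile(counts, 0.75, axis=0) / lib
        ref = int(np.argmin(np.abs(f75 - f75.mean())))
        raw = np.array([_tmm_bruteforce(counts, j, ref) for j in range(3)])
        expected = raw / np.exp(np.mean(np.log(raw)))
        assert np.allclose(f.to_numpy(), expected, atol=1e-10)

    def test_log_factors_sum_to_zero_and_gene_permutation_invariant(self):
        rng = np.random.default_rng(5)
        counts = _df(rng.integers(0, 1000, size=(200, 6)))
        f = de.tmm_factors(counts)
        assert np.log(f).sum() == pytest.approx(0.0, abs=1e-12)
        perm = rng.permutation(200)
        f2 = de.tmm_factors(counts.iloc[perm])
        assert np.allclose(f, f2)


# --------------------------------------------------------------------- RUV

class TestRuv:
    def test_group_centring_removes_condition_signal(self):
        # pure condition signal, no batch: regressing on W leaves the
        # group means untouched
        rng = np.random.default_rng(0)
        n_g = 100
        groups = pd.Series(["a"] * 3 + ["b"] * 3, index=[f"s{j}" for j in range(6)])
        signal = np.outer(rng.standard_normal(n_g),
                          [1, 1, 1, -1, -1, -1])
        expr = _df(signal + 1e-6 * rng.standard_normal((n_g, 6)),
                   samples=list(groups.index))
        w = de.ruv_factors(expr, groups, k=1)
        # W is orthogonal to the group-mean structure
        contrast = np.array([1, 1, 1, -1, -1, -1]) / 6
        assert abs(w.to_numpy()[:, 0] @ contrast) < 1e-6

    def test_recovers_planted_batch(self):
        rng = np.random.default_rng(1)
        n_g = 500
        groups = pd.Series(["a", "a", "b", "b", "c", "c"],
                           index=[f"s{j}" for j in range(6)])
        batch = np.array([1.0, -1.0, 1.0, -1.0, 1.0, -1.0])
        loading = rng.standard_normal(n_g)
        expr = _df(np.outer(loading, batch) + 0.05 * rng.standard_normal((n_g, 6)),
                   samples=list(groups.index))
        w = de.ruv_factors(expr, groups, k=1)
        r = np.corrcoef(w.to_numpy()[:, 0], batch)[0, 1]
        assert abs(r) > 0.99

    def test_deterministic_with_sign_convention(self):
        rng = np.random.default_rng(2)
        groups = pd.Series(["a"] * 3 + ["b"] * 3, index=[f"s{j}" for j in range(6)])
        expr = _df(rng.standard_normal((50, 6)), samples=list(groups.index))
        w1 = de.ruv_factors(expr, groups, k=2)
        w2 = de.ruv_factors(expr, groups, k=2)
        pd.testing.assert_frame_equal(w1, w2)
        assert (w1.iloc[0] >= 0).all()
        gram = w1.to_numpy().T @ w1.to_numpy()
        assert np.allclose(gram, np.eye(2), atol=1e-10)

    def test_small_groups_rejected(self):
        expr = _df(np.random.default_rng(0).standard_normal((10, 3)))
        groups = pd.Series(["a", "a", "b"], index=expr.columns)
        with pytest.raises(ValueError, match="fewer than 2"):
            de.ruv_factors(expr, groups, k=1)


# ------------------------------------------------------------- moderated t

class TestModeratedFit:
    @staticmethod
    def _toy():
        rng = np.random.default_rng(7)
        y = _df(rng.standard_normal((40, 8)))
        X = pd.DataFrame({"a": [1] * 4 + [0] * 4, "b": [0] * 4 + [1] * 4},
                         index=y.columns)
        return y, X, {"c": np.array([1.0, -1.0])}

    def test_d0_zero_limit_is_ordinary_t(self):
        y, X, cons = self._toy()
        res = de.fit_moderated(y, X, cons, prior=(1.0, 1e-12))
        # ordinary t computed directly
        g = y.to_numpy()
        means = g[:, :4].mean(1) - g[:, 4:].mean(1)
        ss = (g[:, :4] - g[:, :4].mean(1, keepdims=True)) ** 2
        ss2 = (g[:, 4:] - g[:, 4:].mean(1, keepdims=True)) ** 2
        s2 = (ss.sum(1) + ss2.sum(1)) / 6
        t_ord = means / np.sqrt(s2 * (1 / 4 + 1 / 4))
        assert np.allclose(res.tables["c"]["t"], t_ord, atol=1e-6)

    def test_d0_infinite_limit_shares_variance(self):
        y, X, cons = self._toy()
        res = de.fit_moderated(y, X, cons, prior=(0.7, np.inf))
        assert np.allclose(res.params.posterior_var, 0.7)

    def test_moment_estimates_match_root_finding_oracle(self):
        # frozen residual variances, d = 4
        s2 = np.array([0.05, 0.2, 3.0, 0.5, 8.0, 0.9, 0.02, 1.5, 6.0, 0.1])
        d = 4.0
        s0_sq, d0 = de.fit_f_dist(s2, d)
        e = np.log(s2) - digamma(d / 2) + np.log(d / 2)
        evar = e.var(ddof=1) - polygamma(1, d / 2)
        assert evar > 0
        d0_oracle = 2.0 * brentq(
            lambda x: polygamma(1, x) - evar, 1e-3, 1e6, xtol=1e-12)
        s0_oracle = np.exp(e.mean() + digamma(d0_oracle / 2)
                           - np.log(d0_oracle / 2))
        assert d0 == pytest.approx(d0_oracle, abs=1e-8)
        assert s0_sq == pytest.approx(s0_oracle, abs=1e-8)
        post = de.squeeze_var(s2, d, s0_sq, d0)
        oracle_post = (d0_oracle * s0_oracle + d * s2) / (d0_oracle + d)
        assert np.allclose(post, oracle_post, atol=1e-8)

    def test_posterior_var_between_sample_and_prior(self):
        y, X, cons = self._toy()
        res = de.fit_moderated(y, X, cons)
        p = res.params
        lo = np.minimum(p.posterior_var * 0 + p.prior_var,
                        (y.to_numpy().var(axis=1) * 0 + p.posterior_var))
        s2 = ((y.to_numpy() - (y.to_numpy() @ np.linalg.pinv(
            X.to_numpy().astype(float)).T) @ X.to_numpy().T) ** 2
        ).sum(axis=1) / p.residual_df
        assert np.all(p.posterior_var >= np.minimum(s2, p.prior_var) - 1e-12)
        assert np.all(p.posterior_var <= np.maximum(s2, p.prior_var) + 1e-12)

    def test_singular_design_names_aliased_columns(self):
        y, X, cons = self._toy()
        X2 = X.copy()
        X2["dup"] = X2["a"]
        with pytest.raises(ValueError, match="aliased"):
            de.fit_moderated(y, X2, {"c": np.array([1.0, -1.0, 0.0])})

    def test_full_design_returns_four_contrasts_same_genes(self, study):
        res = study["de"]
        names = res.contrast_names()
        assert len(names) == 4
        idx = res[names[0]].index
        for n in names[1:]:
            assert res[n].index.equals(idx)

    def test_null_pvalues_uniform(self, null_study):
        for name, tab in null_study["de"].tables.items():
            assert kstest(tab["p"], "uniform").pvalue > 0.01

    def test_null_fdr_calls_within_binomial_bound(self, null_study):
        # expected false positives at FDR < 0.05 stay below the 99%
        # binomial bound for 2000 independent null genes
        from scipy.stats import binom
        bound = binom.ppf(0.99, 2000, 0.05)
        for tab in null_study["de"].tables.values():
            assert (tab["FDR"] < 0.05).sum() <= bound


# ---------------------------------------------------------------------- BH

def _bh_bruteforce(p):
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    out = np.empty(m)
    prev = 1.0
    for rank_from_top in range(m, 0, -1):
        i = order[rank_from_top - 1]
        val = min(prev, p[i] * m / rank_from_top)
        out[i] = val
        prev = val
    return out


class TestBH:
    def test_single_p_identity(self):
        assert de.bh_adjust(np.array([0.03]))[0] == pytest.approx(0.03)

    def test_hand_stepup(self):
        p = np.array([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(de.bh_adjust(p), [0.04, 0.04, 0.04, 0.04])

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            de.bh_adjust(np.array([0.5, 1.5]))

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1,
                    max_size=60))
    def test_matches_bruteforce_and_dominates_input(self, p):
        p = np.asarray(p)
        adj = de.bh_adjust(p)
        assert np.allclose(adj, _bh_bruteforce(p), atol=1e-12)
        assert np.all(adj >= p - 1e-15)
        assert np.all((adj >= 0) & (adj <= 1))

    def test_bruteforce_equivalence_many_random_vectors(self):
        rng = np.random.default_rng(11)
        for _ in range(1000):
            p = rng.uniform(size=rng.integers(1, 40))
            assert np.allclose(de.bh_adjust(p), _bh_bruteforce(p), atol=1e-12)


# ----------------------------------------------------------------- markers

class TestMarkers:
    def test_single_marker_profile_is_gene_row(self):
        expr = _df(np.arange(12.0).reshape(3, 4))
        prof, cov = de.celltype_marker_profile(expr, {"ct": ["g1"]})
        assert np.allclose(prof.loc["ct"], expr.loc["g1"])
        assert cov.loc["ct", "n_found"] == 1

    def test_constant_matrix_gives_constant_profiles(self):
        expr = _df(np.full((5, 3), 2.5))
        prof, _ = de.celltype_marker_profile(
            expr, {"a": ["g0", "g1"], "b": ["g2", "g3", "g4"]})
        assert np.allclose(prof, 2.5)

    def test_planted_celltype_shift_recovered(self):
        rng = np.random.default_rng(0)
        expr = _df(rng.standard_normal((100, 6)) * 0.1)
        markers = [f"g{i}" for i in range(20)]
        expr.loc[markers, expr.columns[3:]] += 1.0  # condition shift
        prof, _ = de.celltype_marker_profile(expr, {"microglia": markers})
        shift = (prof.loc["microglia"][3:].mean()
                 - prof.loc["microglia"][:3].mean())
        assert shift == pytest.approx(1.0, abs=0.15)

    def test_absent_set_flagged_not_fatal(self):
        expr = _df(np.ones((3, 2)))
        with pytest.warns(UserWarning, match="no markers"):
            prof, cov = de.celltype_marker_profile(
                expr, {"present": ["g0"], "absent": ["zz"]})
        assert cov.loc["absent", "n_found"] == 0
        assert prof.loc["absent"].isna().all()
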