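import itertools

import numpy as np
import pandas as pd
import pytest

from gutage.ecology import (
    bray_curtis,
    effect_size_decomposition,
    enterotype,
    intragroup_beta,
    permanova_r2,
    shannon,
)


class TestShannon:
    def test_uniform_profile_is_log_s(self):
        assert shannon(np.full(10, 0.1)) == pytest.approx(np.log(10), abs=1e-12)

    def test_single_feature_is_zero(self):
        assert shannon([0.0, 5.0, 0.0]) == 0.0

    def test_hand_value(self):
        assert shannon([0.5, 0.25, 0.25]) == pytest.approx(1.039720770839918, abs=1e-9)

    def test_invariant_under_feature_permutation(self, rng):
        p = rng.dirichlet(np.ones(30))
        assert shannon(p) == pytest.approx(shannon(p[rng.permutation(30)]))

    def test_renormalizes_internally(self):
        assert shannon([2.0, 1.0, 1.0]) == pytest.approx(shannon([0.5, 0.25, 0.25]))

    def test_all_zero_errors(self):
        with pytest.raises(ValueError):
            shannon([0.0, 0.0])


class TestBrayCurtis:
    def test_identical_samples_zero(self, abundance_matrix):
        m = abundance_matrix[["s1", "s1"]].set_axis(["a", "b"], axis=1)
        d = bray_curtis(m)
        assert d.loc["a", "b"] == 0.0

    def test_disjoint_supports_one(self):
        m = pd.DataFrame({"a": [1.0, 0.0], "b": [0.0, 1.0]})
        assert bray_curtis(m).loc["a", "b"] == 1.0

    def test_hand_value(self):
        m = pd.DataFrame({"a": [1.0, 0.0], "b": [0.5, 0.5]})
        assert bray_curtis(m).loc["a", "b"] == pytest.approx(0.5)

    def test_symmetric_zero_diagonal_unit_range(self, small_cohort):
        d = bray_curtis(small_cohort.species_abundance)
        assert np.allclose(d, d.T)
        assert np.allclose(np.diag(d), 0.0)
        assert ((d.values >= 0) & (d.values <= 1)).all()


class TestIntragroupBeta:
    def test_dispersed_group_has_larger_median(self, rng):
        tight = rng.dirichlet(np.full(8, 50.0), 12)
        loose = rng.dirichlet(np.full(8, 1.0), 12)
        m = pd.DataFrame(np.vstack([tight, loose]).T,
                         columns=[f"s{i}" for i in range(24)])
        d = bray_curtis(m)
        groups = ["tight"] * 12 + ["loose"] * 12
        per_group, tests = intragroup_beta(d, groups)
        assert np.median(per_group["loose"]) > np.median(per_group["tight"])
        assert tests.p.iloc[0] < 0.01

    def test_identical_group_structure_not_significant(self, rng):
        m = pd.DataFrame(rng.dirichlet(np.ones(8), 24).T,
                         columns=[f"s{i}" for i in range(24)])
        d = bray_curtis(m)
        _, tests = intragroup_beta(d, ["a"] * 12 + ["b"] * 12)
        assert tests.p.iloc[0] > 0.05

    def test_singleton_group_excluded_with_warning(self, rng):
        m = pd.DataFrame(rng.dirichlet(np.ones(5), 7).T,
                         columns=[f"s{i}" for i in range(7)])
        d = bray_curtis(m)
        with pytest.warns(UserWarning, match="single sample"):
            per_group, _ = intragroup_beta(d, ["a"] * 6 + ["lonely"])
        assert "lonely" not in per_group


class TestEnterotype:
    def _three_communities(self, rng, n_per=20):
        comps = [
            rng.dirichlet([8, 1, 1, 1, 1, 1, 1, 1], n_per),
            rng.dirichlet([1, 8, 1, 1, 1, 1, 1, 1], n_per),
            rng.dirichlet([1, 1, 8, 1, 1, 1, 1, 1], n_per),
        ]
        P = np.vstack(comps).T
        m = pd.DataFrame(P, index=[f"Genus_{i}" for i in range(8)],
                         columns=[f"s{i}" for i in range(3 * n_per)])
        return m, np.repeat([0, 1, 2], n_per)

    def test_three_components_recovered(self, rng):
        from sklearn.metrics import adjusted_rand_score

        m, truth = self._three_communities(rng)
        res = enterotype(m, k_range=(2, 3, 4, 5))
        assert res.k_opt == 3
        assert adjusted_rand_score(truth, res.labels.to_numpy()) >= 0.9

    def test_drivers_are_dominant_taxa(self, rng):
        m, truth = self._three_communities(rng)
        res = enterotype(m, k_range=(3,))
        assert set(res.drivers.values()) == {"Genus_0", "Genus_1", "Genus_2"}

    def test_single_k_skips_index_search(self, rng):
        m, _ = self._three_communities(rng)
        res = enterotype(m, k_range=(2,))
        assert res.k_opt == 2
        assert res.ch_by_k == {}
        assert res.labels.nunique() == 2

    def test_identical_profiles_error(self):
        m = pd.DataFrame(np.tile([[0.5], [0.5]], (1, 12)),
                         columns=[f"s{i}" for i in range(12)])
        with pytest.raises(ValueError, match="identical"):
            enterotype(m, k_range=(2, 3))


def _brute_force_permanova(D, var):
    """Independent oracle: explicit centering matrix + all n! permutations."""
    n = D.shape[0]
    C = np.eye(n) - np.ones((n, n)) / n
    G = C @ (-0.5 * D**2) @ C
    v = np.asarray(var, dtype=float)

    def stat(vp):
        X = np.column_stack([np.ones(n), vp])
        H = X @ np.linalg.inv(X.T @ X) @ X.T
        ssm, sst = np.trace(H @ G), np.trace(G)
        f = (ssm / 1.0) / ((sst - ssm) / (n - 2))
        return ssm / sst, f

    r2, f_obs = stat(v)
    exceed = total = 0
    for perm in itertools.permutations(range(n)):
        _, f_p = stat(v[list(perm)])
        total += 1
        if f_p >= f_obs - 1e-12:
            exceed += 1
    return r2, exceed / total


class TestPermanova:
    def _dist(self, rng, n, shift=None):
        Y = rng.random((n, 5))
        if shift is not None:
            Y += shift[:, None]
        num = np.abs(Y[:, None, :] - Y[None, :, :]).sum(-1)
        den = (Y[:, None, :] + Y[None, :, :]).sum(-1)
        return num / den

    @pytest.mark.parametrize("n", [5, 6, 7])
    def test_matches_exhaustive_brute_force(self, n):
        rng = np.random.default_rng(n)
        D = self._dist(rng, n)
        v = rng.standard_normal(n)
        r2_b, p_b = _brute_force_permanova(D, v)
        r2, p = permanova_r2(pd.DataFrame(D), v, exact=True)
        assert r2 == pytest.approx(r2_b, abs=1e-10)
        assert p == p_b

    def test_disjoint_groups_hit_permutation_floor(self, rng):
        labels = np.repeat(["a", "b"], 10)
        D = self._dist(rng, 20, shift=np.where(labels == "a", 0.0, 5.0))
        r2, p = permanova_r2(pd.DataFrame(D), labels, n_perm=999, seed=1)
        assert p == pytest.approx(1 / 1000)
        assert r2 > 0.5

    def test_reproducible_under_fixed_seed(self, rng):
        D = self._dist(rng, 15)
        v = rng.standard_normal(15)
        assert permanova_r2(D, v, seed=7) == permanova_r2(D, v, seed=7)

    def test_null_pvalues_roughly_uniform(self):
        """Under the null the mean permutation p over replicates sits near
        0.5 (the rejection-rate band itself is asserted in
        test_acceptance)."""
        ps = []
        for i in range(200):
            r = np.random.default_rng(1000 + i)
            D = self._dist(r, 20)
            v = r.standard_normal(20)
            _, p = permanova_r2(pd.DataFrame(D), v, n_perm=199, seed=i)
            ps.append(p)
        assert 0.42 < np.mean(ps) < 0.58

    def test_constant_variable_errors(self, rng):
        D = self._dist(rng, 10)
        with pytest.raises(ValueError, match="constant"):
            permanova_r2(D, np.ones(10))

    def test_pseudo_f_matches_scikit_bio(self, rng):
        """Independent cross-check of the categorical pseudo-F statistic."""
        from skbio.stats.distance import DistanceMatrix
        from skbio.stats.distance import permanova as sk_permanova

        labels = np.repeat(["a", "b"], 10)
        D = self._dist(rng, 20, shift=np.where(labels == "a", 0.0, 0.5))
        res = sk_permanova(DistanceMatrix(D), labels, permutations=99)
        r2, _ = permanova_r2(pd.DataFrame(D), labels, n_perm=99, seed=0)
        f_mine = r2 / ((1 - r2) / (20 - 2))
        assert f_mine == pytest.approx(res["test statistic"], rel=1e-9)


class TestEffectSizeDecomposition:
    def _setting(self, seed=0, n=40):
        rng = np.random.default_rng(seed)
        driver = rng.standard_normal(n)
        Y = np.exp(rng.normal(0, 0.3, (n, 6)) + driver[:, None])
        num = np.abs(Y[:, None, :] - Y[None, :, :]).sum(-1)
        den = (Y[:, None, :] + Y[None, :, :]).sum(-1)
        D = pd.DataFrame(num / den)
        covars = pd.DataFrame({
            "driver": driver,
            "copy": driver + rng.normal(0, 1e-6, n),   # r = 1 duplicate
            "noise": rng.standard_normal(n),
        })
        return D, covars

    def test_duplicate_covariate_deduplicated(self):
        D, covars = self._setting()
        out = effect_size_decomposition(D, covars, n_perm=199, seed=0)
        kept = set(out[out.kept].variable)
        assert len(kept & {"driver", "copy"}) == 1
        dropped = out[out.redundant_with.notna()]
        assert len(dropped) == 1

    def test_nonsignificant_covariate_excluded_before_redundancy(self):
        D, covars = self._setting()
        out = effect_size_decomposition(D, covars, n_perm=199, seed=0)
        noise_row = out[out.variable == "noise"].iloc[0]
        assert not noise_row.kept
        assert noise_row.redundant_with is None

    def test_combined_r2_at_least_max_single(self):
        D, covars = self._setting(seed=3)
        covars["driver2"] = covars.pop("copy") + np.random.default_rng(5).standard_normal(len(covars)) * 2
        out = effect_size_decomposition(D, covars, n_perm=199, seed=0)
        kept = out[out.kept]
        if len(kept):
            assert out.combined_r2.iloc[0] >= kept.r2.max() - 1e-10

    def test_invariant_to_covariate_order(self):
        D, covars = self._setting(seed=1)
        out1 = effect_size_decomposition(D, covars, n_perm=99, seed=0)
        out2 = effect_size_decomposition(
            D, covars[list(covars.columns)[::-1]], n_perm=99, seed=0)
        s1 = out1.set_index("variable")[["kept"]].sort_index()
        s2 = out2.set_index("variable")[["kept"]].sort_index()
        pd.testing.assert_frame_equal(s1, s2)
        assert out1.combined_r2.iloc[0] == pytest.approx(out2.combined_r2.iloc[0])
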