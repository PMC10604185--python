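import numpy as np
import pandas as pd
import pytest

from pstfst.simulate import simulate_landscape
from pstfst.traits import (
    among_population_test,
    elevation_association,
    levene_test,
    pca_population_means,
    refine_traits,
)
from pstfst.types import SiteTable, TraitTable, ValidationError


def make_trait_table(columns, pops_per_group=5, n_groups=None):
    """Build a TraitTable from {trait: (n_groups, n_per_group) array}."""
    first = next(iter(columns.values()))
    k, n = np.asarray(first).shape
    pops = [f"P{i}" for i in range(k) for _ in range(n)]
    samples = [f"s{i}" for i in range(k * n)]
    data = pd.DataFrame({name: np.asarray(v, float).ravel() for name, v in columns.items()})
    return TraitTable(samples=samples, populations=pops, data=data)


class TestLevene:
    def test_identical_groups_give_zero(self):
        vals = [1, 5, 9, 1, 5, 9]
        stat, p = levene_test(vals, ["A"] * 3 + ["B"] * 3)
        assert stat == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_hand_anova_oracle(self):
        """F on |x - group median|: groups {1,2,3},{10,20,30} -> {1,0,1},{10,0,10}."""
        dev = np.array([1.0, 0, 1, 10, 0, 10])
        groups = np.array([0, 0, 0, 1, 1, 1])
        means = np.array([dev[groups == g].mean() for g in (0, 1)])
        grand = dev.mean()
        ss_b = 3 * ((means - grand) ** 2).sum()
        ss_w = sum(((dev[groups == g] - means[g]) ** 2).sum() for g in (0, 1))
        expected_f = (ss_b / 1) / (ss_w / 4)
        stat, p = levene_test([1, 2, 3, 10, 20, 30], ["A"] * 3 + ["B"] * 3)
        assert stat == pytest.approx(expected_f)
        assert 0 < p <= 1

    def test_group_entirely_missing_errors(self):
        with pytest.raises(ValidationError, match="'B'"):
            levene_test([1.0, 2.0, np.nan, np.nan], ["A", "A", "B", "B"])


class TestAmongPopulationTest:
    def test_strong_separation_is_discriminating(self):
        rng = np.random.default_rng(0)
        vals = np.concatenate([np.full(5, 0.0), np.full(5, 10.0), np.full(5, 20.0)])
        vals += 1e-3 * rng.standard_normal(15)
        groups = ["A"] * 5 + ["B"] * 5 + ["C"] * 5
        for flag in (True, False):
            res = among_population_test(vals, groups, homoscedastic=flag)
            assert res.discriminating

    def test_constant_trait_non_discriminating_without_error(self):
        res = among_population_test([3.0] * 8, ["A"] * 4 + ["B"] * 4, True)
        assert not res.discriminating
        assert res.p_value == 1.0

    def test_posthoc_matrix_shape_and_symmetry(self):
        rng = np.random.default_rng(1)
        vals = rng.standard_normal(30)
        groups = np.repeat(["A", "B", "C"], 10)
        for flag in (True, False):
            res = among_population_test(vals, groups, homoscedastic=flag)
            ph = res.posthoc
            assert list(ph.index) == list(ph.columns) == ["A", "B", "C"]
            np.testing.assert_allclose(ph.values, ph.values.T)
            assert ((ph.values > 0) & (ph.values <= 1)).all()

    def test_type_one_error_controlled(self):
        """Identically distributed groups are rarely flagged at alpha=0.01."""
        rng = np.random.default_rng(42)
        hits = 0
        n_rep = 200
        for _ in range(n_rep):
            vals = rng.standard_normal(30)
            res = among_population_test(vals, np.repeat(["A", "B"], 15),
                                        homoscedastic=True, alpha=0.01)
            hits += res.discriminating
        assert hits / n_rep <= 0.05


class TestRefineTraits:
    @staticmethod
    def _structured(rng, k=6, n=10, spread=5.0):
        return spread * rng.standard_normal((k, 1)) + rng.standard_normal((k, n)) + 50.0

    def test_independent_structured_traits_all_retained(self):
        # enough populations that chance pop-mean correlations stay below 0.8
        rng = np.random.default_rng(3)
        t = make_trait_table({f"t{i}": self._structured(rng, k=12) for i in range(4)})
        r = refine_traits(t)
        assert r.retained_traits == ["t0", "t1", "t2", "t3"]
        assert r.dropped_nonsignificant == [] and r.dropped_correlated == []

    def test_duplicate_column_pruned_exactly_once(self):
        rng = np.random.default_rng(4)
        a = self._structured(rng)
        t = make_trait_table({"a": a, "b": a.copy(),
                              "c": self._structured(rng)})
        r = refine_traits(t)
        assert len(r.dropped_correlated) == 1
        assert set(r.dropped_correlated) <= {"a", "b"}

    def test_no_signal_trait_dropped(self):
        rng = np.random.default_rng(5)
        t = make_trait_table({
            "flat": 50.0 + rng.standard_normal((6, 10)),
            "s1": self._structured(rng),
            "s2": self._structured(rng),
        })
        r = refine_traits(t)
        assert "flat" in r.dropped_nonsignificant

    def test_z_columns_normalised_and_pruning_guarantee(self):
        rng = np.random.default_rng(6)
        cols = {f"t{i}": self._structured(rng, k=8) for i in range(5)}
        cols["dup"] = 0.9 * cols["t0"] + 0.1 * rng.standard_normal((8, 10)) + 5
        r = refine_traits(make_trait_table(cols))
        np.testing.assert_allclose(r.pop_means_z.mean(), 0.0, atol=1e-9)
        np.testing.assert_allclose(r.pop_means_z.std(ddof=1), 1.0, atol=1e-9)
        corr = r.pop_means.corr().to_numpy()
        np.fill_diagonal(corr, 0.0)
        assert np.abs(corr).max() <= 0.8
        # anything dropped as correlated had a partner above the cutoff
        means_all = make_trait_table(cols).data.groupby(
            np.repeat([f"P{i}" for i in range(8)], 10)).mean()
        for victim in r.dropped_correlated:
            partners = means_all.corr()[victim].drop(victim).abs()
            assert partners.max() > 0.8

    def test_missing_samples_listwise_deleted(self):
        rng = np.random.default_rng(7)
        cols = {f"t{i}": self._structured(rng) for i in range(3)}
        t = make_trait_table(cols)
        t.data.iloc[0, 1] = np.nan
        r = refine_traits(t)
        assert r.dropped_samples == ["s0"]

    def test_fewer_than_two_retained_errors(self):
        rng = np.random.default_rng(8)
        t = make_trait_table({
            "flat1": 50 + rng.standard_normal((6, 10)),
            "flat2": 50 + rng.standard_normal((6, 10)),
            "s1": self._structured(rng),
        })
        with pytest.raises(ValidationError, match="fewer than 2"):
            refine_traits(t)


class TestPCA:
    @staticmethod
    def _correlated_pair(r_target, n=400, seed=0):
        rng = np.random.default_rng(seed)
        x = rng.standard_normal(n)
        y = r_target * x + np.sqrt(1 - r_target**2) * rng.standard_normal(n)
        df = pd.DataFrame({"a": x, "b": y}, index=[f"P{i}" for i in range(n)])
        return (df - df.mean()) / df.std(ddof=1)

    def test_two_trait_closed_form(self):
        """For two z-scored traits, PC1 explains (1+|r|)/2 of the variance."""
        z = self._correlated_pair(0.6)
        r = z["a"].corr(z["b"])
        res = pca_population_means(z)
        assert res.explained[0] == pytest.approx((1 + abs(r)) / 2, abs=1e-12)

    def test_explained_sums_to_one_and_orthonormal(self):
        rng = np.random.default_rng(9)
        z = pd.DataFrame(rng.standard_normal((7, 5)),
                         index=[f"P{i}" for i in range(7)])
        z = (z - z.mean()) / z.std(ddof=1)
        res = pca_population_means(z)
        assert res.explained.sum() == pytest.approx(1.0)
        L = res.loadings.to_numpy()
        np.testing.assert_allclose(L.T @ L, np.eye(L.shape[1]), atol=1e-9)

    def test_reconstruction(self):
        rng = np.random.default_rng(10)
        z = pd.DataFrame(rng.standard_normal((6, 4)))
        res = pca_population_means(z)
        centered = z.to_numpy() - z.to_numpy().mean(axis=0)
        recon = res.scores.to_numpy() @ res.loadings.to_numpy().T
        np.testing.assert_allclose(recon, centered, atol=1e-8)

    def test_sign_convention(self):
        rng = np.random.default_rng(11)
        z = pd.DataFrame(rng.standard_normal((8, 3)))
        L = pca_population_means(z).loadings.to_numpy()
        for col in L.T:
            assert col[np.abs(col).argmax()] > 0

    def test_rank_zero_errors(self):
        z = pd.DataFrame(np.zeros((4, 3)))
        with pytest.raises(ValidationError, match="rank"):
            pca_population_means(z)


class TestElevationAssociation:
    @staticmethod
    def _sites(elevations):
        n = len(elevations)
        return SiteTable(pd.DataFrame({
            "latitude": np.linspace(43, 44, n),
            "longitude": np.linspace(10, 11, n),
            "elevation": elevations,
        }, index=pd.Index([f"P{i}" for i in range(n)], name="population")))

    @staticmethod
    def _means(values, trait="t"):
        return pd.DataFrame({trait: values},
                            index=[f"P{i}" for i in range(len(values))])

    def test_perfect_monotone_decrease(self):
        sites = self._sites([100, 300, 700, 1100, 1500])
        res = elevation_association(self._means([9, 7, 5, 3, 1]), sites, "t")
        assert res.rho == pytest.approx(-1.0)

    def test_exact_parabola_degree_two(self):
        x = np.array([100.0, 400, 700, 1000, 1300])
        y = 1e-5 * (x - 700) ** 2 + 2.0
        res = elevation_association(self._means(y), self._sites(x), "t", degree=2)
        assert res.adj_r2 == pytest.approx(1.0)
        assert res.fit_p == pytest.approx(0.0, abs=1e-12)

    def test_linear_closed_form(self):
        x = np.array([0.0, 100, 200, 300, 400, 500])
        res = elevation_association(self._means(2 * x + 3), self._sites(x), "t")
        assert res.coefficients[0] == pytest.approx(2.0)
        assert res.adj_r2 == pytest.approx(1.0)

    def test_noise_degrades_fit(self):
        rng = np.random.default_rng(12)
        x = np.linspace(0, 1000, 10)
        base = 2 * x
        r2_clean = elevation_association(self._means(base + 10000), self._sites(x), "t").adj_r2
        noisy = base + 10000 + 500 * rng.standard_normal(10)
        r2_noisy = elevation_association(self._means(noisy), self._sites(x), "t").adj_r2
        assert r2_noisy < r2_clean

    def test_spearman_monotone_invariance(self):
        rng = np.random.default_rng(13)
        x = np.sort(rng.uniform(0, 1800, 8))
        y = rng.uniform(1, 10, 8)
        r1 = elevation_association(self._means(y), self._sites(x), "t").rho
        r2 = elevation_association(self._means(np.exp(y / 3)), self._sites(x), "t").rho
        assert r1 == pytest.approx(r2)

    def test_exclusion_and_degree_guards(self):
        sites = self._sites([100, 300, 700, 1100, 1500])
        means = self._means([1, 2, 3, 4, 5.0])
        with pytest.raises(ValidationError, match="degree"):
            elevation_association(means, sites, "t", degree=3)
        with pytest.raises(ValidationError, match="fewer than 4"):
            elevation_association(means, sites, "t", exclude=("P0", "P1"))
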