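import math

import networkx as nx
import numpy as np
import pytest
from scipy import stats as sps

from malani.annotate import GeneClassLabels
from malani.classifier import ClassifierSpec
from malani.data import ExpressionDataset, GeneSetCollection, MalaniError
from malani.simulate import SimConfig, generate_expression
from malani.stats import (
    adjust_pvalues,
    fisher_hub_class2,
    hypergeom_enrich,
    model_count,
    monte_carlo_ci,
    per_gene_pvalues,
    permutation_test,
    selected_model_statistic,
)


class TestMonteCarloCI:
    def test_alpha_zero_collapses(self):
        assert monte_carlo_ci(0.0, 20) == (0.0, 0.0)

    def test_half_width_formula(self):
        lo, hi = monte_carlo_ci(0.5, 100)
        assert hi - 0.5 == pytest.approx(1.96 * math.sqrt(0.25 / 100), abs=1e-12)
        assert 0.5 - lo == pytest.approx(0.098, abs=1e-3)

    def test_ci_contains_alpha_and_shrinks(self):
        for alpha in (0.1, 0.3, 0.7):
            lo1, hi1 = monte_carlo_ci(alpha, 20)
            lo2, hi2 = monte_carlo_ci(alpha, 2000)
            assert lo1 <= alpha <= hi1
            assert (hi2 - lo2) < (hi1 - lo1)


class TestPermutationTest:
    def test_signal_gives_alpha_zero(self, small_sim):
        _, ds, truth = small_sim
        stat = selected_model_statistic(
            truth.coordinator_pairs, ClassifierSpec(), k=5, fold_seed=1
        )
        res = permutation_test(ds, stat, M=10, seed=0)
        assert res.alpha == 0.0
        assert res.ci_low == res.ci_high == 0.0
        assert res.observed_stat > max(res.permuted_stats)

    def test_alpha_counts_exceedances(self):
        # deterministic toy statistic: permuted values mostly exceed observed
        ds, _ = generate_expression(SimConfig(G=10, n_pairs=0, n_up=0, n_down=0, seed=0))
        calls = {"n": -1}

        def stat(d):
            calls["n"] += 1
            return 0.5 if calls["n"] == 0 else 0.9

        res = permutation_test(ds, stat, M=7, seed=0)
        assert res.alpha == 1.0

    def test_non_finite_statistic_rejected(self):
        ds, _ = generate_expression(SimConfig(G=10, n_pairs=0, n_up=0, n_down=0, seed=0))
        with pytest.raises(MalaniError):
            permutation_test(ds, lambda d: float("nan"), M=2, seed=0)

    def test_screening_statistic_separates_signal_from_null(self):
        from malani.data import normalize_per_sample
        from malani.stats import screening_model_statistic

        spec = ClassifierSpec()
        planted_cfg = SimConfig(G=80, n_up=3, n_down=3, n_pairs=2, seed=5)
        null_cfg = SimConfig(G=80, n_up=0, n_down=0, n_pairs=0, seed=5)
        stat = screening_model_statistic(spec, k=5, fold_seed=2)
        ds_p = normalize_per_sample(generate_expression(planted_cfg)[0])
        ds_n = normalize_per_sample(generate_expression(null_cfg)[0])
        res_p = permutation_test(ds_p, stat, M=8, seed=1)
        res_n = permutation_test(ds_n, stat, M=8, seed=1)
        # signal: the nested-screened model generalises; permutations don't
        assert res_p.alpha == 0.0
        assert res_p.observed_stat > 0.65
        # null: observed is exchangeable with the permuted statistics
        assert res_n.alpha >= 1 / 8


class TestPerGenePvalues:
    def make_ds(self, values):
        G, S = values.shape
        return ExpressionDataset(
            [f"g{i}" for i in range(G)],
            [f"s{i}" for i in range(S)],
            values,
            np.array(["cancer"] * (S // 2) + ["normal"] * (S - S // 2), dtype=object),
        )

    def test_identical_classes_p_near_one(self):
        row = np.tile([1.0, 2.0, 3.0], 4)[None, :]
        ds = self.make_ds(np.abs(row))
        p = per_gene_pvalues(ds)["g0"]
        assert p > 0.9

    def test_strong_separation_tiny_p(self):
        rng = np.random.default_rng(0)
        vals = np.concatenate(
            [10 + rng.normal(0, 0.1, 10), np.abs(rng.normal(0, 0.1, 10))]
        )[None, :]
        ds = self.make_ds(vals)
        assert per_gene_pvalues(ds)["g0"] < 1e-10

    def test_matches_textbook_pooled_t_oracle(self):
        rng = np.random.default_rng(1)
        vals = np.abs(rng.lognormal(size=(100, 24)))
        ds = self.make_ds(vals)
        result = per_gene_pvalues(ds)
        for i in range(100):
            x, y = vals[i, :12], vals[i, 12:]
            nx_, ny_ = len(x), len(y)
            sp2 = ((nx_ - 1) * x.var(ddof=1) + (ny_ - 1) * y.var(ddof=1)) / (
                nx_ + ny_ - 2
            )
            t = (x.mean() - y.mean()) / math.sqrt(sp2 * (1 / nx_ + 1 / ny_))
            p = 2 * sps.t.sf(abs(t), nx_ + ny_ - 2)
            assert result[f"g{i}"] == pytest.approx(p, abs=1e-10)

    def test_zero_variance_warns_p_one(self):
        vals = np.ones((1, 8))
        ds = self.make_ds(vals)
        with pytest.warns(UserWarning, match="zero pooled variance"):
            p = per_gene_pvalues(ds)
        assert p["g0"] == 1.0

    def test_null_pvalues_uniformish(self):
        """Kolmogorov-Smirnov check against uniformity on null data."""
        hits = 0
        for seed in range(5):
            ds, _ = generate_expression(
                SimConfig(G=300, n_pairs=0, n_up=0, n_down=0, seed=seed)
            )
            p = np.array(list(per_gene_pvalues(ds).values()))
            ks = sps.kstest(p, "uniform").statistic
            hits += ks < 0.1
        assert hits >= 4


class TestAdjustPvalues:
    def test_bonferroni_product(self):
        out = adjust_pvalues([0.01] * 5, method="bonferroni")
        np.testing.assert_allclose(out, 0.05)

    def test_bh_step_up_closed_form(self):
        p = np.array([0.01, 0.02, 0.03])
        out = adjust_pvalues(p, method="bh")
        # oracle: step-up recursion min over tail of p*m/i
        m = len(p)
        oracle = [min(min(p[j] * m / (j + 1) for j in range(i, m)), 1.0) for i in range(m)]
        np.testing.assert_allclose(out, oracle)
        np.testing.assert_allclose(out, [0.03, 0.03, 0.03])

    def test_bh_oracle_random(self):
        rng = np.random.default_rng(2)
        p = np.sort(rng.uniform(size=40))
        out = adjust_pvalues(p, method="bh")
        m = len(p)
        oracle = [min(min(p[j] * m / (j + 1) for j in range(i, m)), 1.0) for i in range(m)]
        np.testing.assert_allclose(out, oracle, atol=1e-12)

    def test_adjusted_dominates_raw(self):
        rng = np.random.default_rng(3)
        p = rng.uniform(size=30)
        for method in ("bonferroni", "bh"):
            assert np.all(adjust_pvalues(p, method) >= p - 1e-15)

    def test_out_of_range_rejected(self):
        with pytest.raises(MalaniError):
            adjust_pvalues([0.5, 1.5])


def enumeration_hypergeom_sf(k, m, j, n):
    """Brute-force upper tail P(X >= k) by summing the exact mass."""
    denom = math.comb(m, n)
    total = 0
    for i in range(k, min(j, n) + 1):
        if n - i <= m - j:
            total += math.comb(j, i) * math.comb(m - j, n - i)
    return total / denom


class TestEnrichment:
    def make_sets(self, cats, m):
        return GeneSetCollection(categories=cats, reference_size=m)

    def test_worked_numbers(self):
        universe = [f"g{i}" for i in range(100)]
        cat = set(universe[:20])
        query = set(universe[:6]) | set(universe[90:94])  # n=10, k=6
        sets = self.make_sets({"C": cat}, m=100)
        (res,) = hypergeom_enrich(query, sets)
        assert res.k_expected == pytest.approx(2.0)
        assert res.ratio == pytest.approx(3.0)
        assert res.enriched

    def test_ratio_one_when_k_equals_expected(self):
        universe = [f"g{i}" for i in range(100)]
        sets = self.make_sets({"C": set(universe[:50])}, m=100)
        query = set(universe[48:52])  # n=4, k=2, expected (4/100)*50=2
        (res,) = hypergeom_enrich(query, sets)
        assert res.ratio == pytest.approx(1.0)
        assert not res.enriched

    def test_p_matches_enumeration_oracle(self):
        rng = np.random.default_rng(4)
        universe = [f"g{i}" for i in range(50)]
        for _ in range(25):
            j = int(rng.integers(3, 30))
            n = int(rng.integers(3, 25))
            cat = set(rng.choice(universe, j, replace=False))
            query = set(rng.choice(universe, n, replace=False))
            sets = self.make_sets({"C": cat}, m=50)
            (res,) = hypergeom_enrich(query, sets)
            k = len(cat & query)
            assert res.p_raw == pytest.approx(
                enumeration_hypergeom_sf(k, 50, j, n), abs=1e-12
            )

    def test_query_equal_to_category_tops_ranking(self):
        universe = [f"g{i}" for i in range(40)]
        cats = {"self": set(universe[:8]), "other": set(universe[20:30])}
        sets = self.make_sets(cats, m=40)
        results = hypergeom_enrich(set(universe[:8]), sets)
        assert results[0].category == "self"
        # k = n = j, so r = k / ((n/m) j) = m / n
        assert results[0].ratio == pytest.approx(40 / 8)

    def test_min_mode_filter(self):
        universe = [f"g{i}" for i in range(60)]
        cats = {f"C{i}": set(universe[i * 5 : i * 5 + 5]) for i in range(12)}
        sets = self.make_sets(cats, m=60)
        query = set(universe[:5]) | {universe[6]}
        results = hypergeom_enrich(query, sets, mode="min")
        passing = [r for r in results if r.passes_filter]
        assert all(r.k_obs >= 3 for r in passing)
        assert len(passing) <= 10
        assert passing[0].category == "C0"

    def test_piemin_mode_filter(self):
        universe = [f"g{i}" for i in range(60)]
        cats = {"big": set(universe[:10]), "small": set(universe[10:13])}
        sets = self.make_sets(cats, m=60)
        query = set(universe[:8])
        results = hypergeom_enrich(query, sets, mode="piemin")
        by_name = {r.category: r for r in results}
        assert by_name["big"].passes_filter  # 8 genes, tiny p
        assert not by_name["small"].passes_filter  # k < 5


def enumeration_fisher_two_sided(table):
    """Two-sided Fisher p by enumerating all tables with fixed margins."""
    a, b = table[0]
    c, d = table[1]
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2

    def prob(x):
        return (
            math.comb(r1, x) * math.comb(r2, c1 - x) / math.comb(n, c1)
        )

    p_obs = prob(a)
    total = 0.0
    for x in range(max(0, c1 - r2), min(r1, c1) + 1):
        px = prob(x)
        if px <= p_obs * (1 + 1e-9):
            total += px
    return total


class TestFisherHubClass2:
    def test_no_association_p_one(self):
        _, p = sps.fisher_exact([[5, 5], [5, 5]])
        assert p == pytest.approx(1.0)

    def test_matches_enumeration_oracle(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            table = rng.integers(0, 11, size=(2, 2))
            _, p = sps.fisher_exact(table, alternative="two-sided")
            assert p == pytest.approx(enumeration_fisher_two_sided(table), abs=1e-9)

    def test_hub_class2_pipeline(self):
        # star hub h connected to class-II genes only
        g = nx.star_graph(7)
        g = nx.relabel_nodes(g, lambda i: f"g{i}")
        labels = GeneClassLabels(
            labels={f"g{i}": "class_II" for i in range(1, 8)} | {"g0": "class_I"},
            summary={},
        )
        table, p = fisher_hub_class2(g, labels, background_size=100)
        assert table[0][0] == 7  # all hub neighbors are class II
        assert table.sum() == 100
        assert 0 < p <= 1

    def test_background_too_small_rejected(self):
        g = nx.star_graph(7)
        g = nx.relabel_nodes(g, lambda i: f"g{i}")
        labels = GeneClassLabels(
            labels={f"g{i}": "class_II" for i in range(8)}, summary={}
        )
        with pytest.raises(MalaniError):
            fisher_hub_class2(g, labels, background_size=3)


class TestModelCount:
    def test_small_exact(self):
        assert model_count(21, 10) == 420

    def test_paper_scale(self):
        assert model_count(20075, 10) == 201_693_525
        assert model_count(20075, 10) > 2e8

    def test_preconditions(self):
        with pytest.raises(MalaniError):
            model_count(0, 10)
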