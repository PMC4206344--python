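"""Tip-shuffle null, random-cell sampling, and effectiveness statistics."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest

from phylocover import (
    DiversityProfile,
    GridSpec,
    PresenceLayer,
    SiteSet,
    build_community_matrix,
    effectiveness_average,
    effectiveness_total,
    faith_pd,
    parse_newick,
    percentile_interval,
    sample_random_cells,
    tip_shuffle_null,
    tree_total_length,
)

from conftest import random_trees


class TestPercentileInterval:
    def test_order_statistic_interpolation(self):
        lo, hi = percentile_interval(list(range(1, 1001)))
        assert lo == pytest.approx(25.975)
        assert hi == pytest.approx(975.025)

    def test_constant_values(self):
        assert percentile_interval([4.2] * 7) == (4.2, 4.2)

    def test_endpoints_within_range(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            vals = rng.normal(size=rng.integers(1, 50))
            lo, hi = percentile_interval(vals)
            assert vals.min() - 1e-12 <= lo <= hi <= vals.max() + 1e-12

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            percentile_interval([])


class TestTipShuffleNull:
    def test_all_tips_flagged_is_degenerate(self, cherry_pair_tree):
        res = tip_shuffle_null(cherry_pair_tree, ["A", "B", "C", "D"], n_reps=50, seed=0)
        L = tree_total_length(cherry_pair_tree)
        assert res.observed == pytest.approx(L)
        assert res.lower == pytest.approx(L) and res.upper == pytest.approx(L)
        assert not res.outside

    def test_single_flagged_on_ultrametric_tree(self):
        t = random_trees(1, 10, seed=4)[0]  # unit-height ultrametric
        res = tip_shuffle_null(t, [t.tip_labels[0]], n_reps=30, seed=1)
        np.testing.assert_allclose(res.replicates, 1.0, atol=1e-9)

    def test_reproducible_under_seed(self, cherry_pair_tree):
        a = tip_shuffle_null(cherry_pair_tree, ["A", "C"], n_reps=100, seed=42)
        b = tip_shuffle_null(cherry_pair_tree, ["A", "C"], n_reps=100, seed=42)
        np.testing.assert_array_equal(a.replicates, b.replicates)

    def test_empty_flagged_rejected(self, cherry_pair_tree):
        with pytest.raises(ValueError):
            tip_shuffle_null(cherry_pair_tree, [], n_reps=10, seed=0)

    def test_unknown_flagged_rejected(self, cherry_pair_tree):
        with pytest.raises(KeyError):
            tip_shuffle_null(cherry_pair_tree, ["A", "Z"], n_reps=10, seed=0)

    def test_replicates_match_exhaustive_distribution(self, cherry_pair_tree):
        """On small trees the null equals the exhaustive subset distribution."""
        labels = cherry_pair_tree.tip_labels
        k = 2
        exhaustive = [faith_pd(cherry_pair_tree, s) for s in itertools.combinations(labels, k)]
        support, counts = np.unique(np.round(exhaustive, 9), return_counts=True)
        probs = counts / counts.sum()
        res = tip_shuffle_null(cherry_pair_tree, labels[:k], n_reps=4000, seed=7)
        for v, p in zip(support, probs):
            freq = np.mean(np.isclose(res.replicates, v, atol=1e-9))
            se = math.sqrt(p * (1 - p) / res.n_reps)
            assert abs(freq - p) < 4 * se


class TestRandomCells:
    def test_all_cells(self):
        assert sorted(sample_random_cells(5, 5, 0).cell_ids) == list(range(5))

    def test_deterministic_under_seed(self):
        assert sample_random_cells(100, 10, 3).cell_ids == sample_random_cells(100, 10, 3).cell_ids

    def test_k_too_large(self):
        with pytest.raises(ValueError):
            sample_random_cells(5, 6, 0)

    def test_uniform_inclusion_frequencies(self):
        """Chi-square on per-cell inclusion counts over 20,000 draws."""
        from scipy import stats

        n, k, draws = 30, 5, 20_000
        rng = np.random.default_rng(12)
        counts = np.zeros(n)
        for _ in range(draws):
            counts[list(sample_random_cells(n, k, rng).cell_ids)] += 1
        expected = draws * k / n
        chi2 = ((counts - expected) ** 2 / expected).sum()
        assert stats.chi2.sf(chi2, df=n - 1) > 0.01


def _profile(values, metric="richness", season="breeding"):
    values = np.asarray(values, dtype=float)
    n = len(values)
    rows = 1
    return DiversityProfile(GridSpec(rows, n), season, metric, values)


class TestEffectivenessAverage:
    def test_direct_formula(self):
        # profile engineered so D_site = 100 and every random draw has mean 80
        prof = _profile([100.0, 80.0])
        sites = SiteSet((0,), "focal")
        res = effectiveness_average(prof, sites, n_reps=10, seed=0)
        assert res.observed_site_value == 100.0
        # random draws of one cell give 80 or 100; check the formula on replicates
        assert set(np.round(res.replicate_effectiveness, 6)) <= {0.0, 0.2}

    def test_constant_profile_gives_zero(self):
        prof = _profile([5.0] * 20)
        sites = SiteSet((1, 3, 5), "focal")
        res = effectiveness_average(prof, sites, n_reps=50, seed=1)
        assert res.mean_effectiveness == pytest.approx(0.0)
        assert res.ci == (0.0, 0.0)
        assert not res.significant

    def test_zero_site_mean_rejected(self):
        prof = _profile([0.0, 1.0])
        with pytest.raises(ValueError, match="0"):
            effectiveness_average(prof, SiteSet((0,), "focal"), n_reps=5, seed=0)

    def test_all_sites_undefined_rejected(self):
        prof = _profile([math.nan, 1.0, 2.0], metric="phylo_distinctiveness")
        with pytest.raises(ValueError, match="undefined"):
            effectiveness_average(prof, SiteSet((0,), "focal"), n_reps=5, seed=0)

    def test_undefined_cells_excluded_from_site_mean(self):
        prof = _profile([math.nan, 4.0, 2.0, 2.0], metric="phylo_distinctiveness")
        res = effectiveness_average(prof, SiteSet((0, 1), "focal"), n_reps=10, seed=0)
        assert res.observed_site_value == 4.0

    def test_scale_invariance(self):
        rng = np.random.default_rng(5)
        vals = rng.gamma(2.0, size=50)
        sites = SiteSet(tuple(range(0, 10)), "focal")
        r1 = effectiveness_average(_profile(vals), sites, n_reps=200, seed=9)
        r2 = effectiveness_average(_profile(vals * 37.5), sites, n_reps=200, seed=9)
        np.testing.assert_allclose(
            r1.replicate_effectiveness, r2.replicate_effectiveness, atol=1e-12
        )

    def test_top_k_sites_never_negative(self):
        rng = np.random.default_rng(8)
        vals = rng.gamma(2.0, size=60)
        top = tuple(int(i) for i in np.argsort(-vals)[:8])
        res = effectiveness_average(_profile(vals), SiteSet(top, "focal"), n_reps=300, seed=2)
        assert (res.replicate_effectiveness >= -1e-12).all()
        assert res.significant and res.ci[0] >= 0


def _community(seed, n_taxa=10, rows=3, cols=4):
    rng = np.random.default_rng(seed)
    t = random_trees(1, n_taxa, seed=seed + 600)[0]
    grid = GridSpec(rows, cols)
    layers = [
        PresenceLayer(
            lab, "breeding",
            frozenset(int(c) for c in rng.choice(grid.n_cells, size=rng.integers(1, 9),
                                                 replace=False)),
            grid,
        )
        for lab in sorted(t.tip_labels)
    ]
    cm = build_community_matrix(layers, grid, "breeding")
    flagged = set(rng.choice(cm.taxa, size=3, replace=False))
    table = pd.DataFrame(
        {"rl_flag": [lab in flagged for lab in cm.taxa], "lump_group": None},
        index=pd.Index(cm.taxa, name="taxon"),
    )
    return t, cm, table


class TestEffectivenessTotal:
    def test_all_cells_site_set_gives_zero(self):
        t, cm, table = _community(1)
        sites = SiteSet(tuple(range(cm.grid.n_cells)), "focal")
        res = effectiveness_total(cm, t, table, sites, "richness", n_reps=40, seed=0)
        np.testing.assert_allclose(res.replicate_effectiveness, 0.0, atol=1e-12)

    def test_cell_with_everything_dominates(self):
        t = parse_newick("((A:1,B:1):1,(C:1,D:1):1);")
        grid = GridSpec(1, 3)
        layers = [PresenceLayer(lab, "breeding", frozenset({0}), grid) for lab in "ABCD"]
        cm = build_community_matrix(layers, grid, "breeding")
        table = pd.DataFrame(
            {"rl_flag": [True, False, False, False], "lump_group": None},
            index=pd.Index(list("ABCD"), name="taxon"),
        )
        res = effectiveness_total(cm, t, table, SiteSet((0,), "focal"),
                                  "phylo_richness", n_reps=60, seed=3)
        assert res.observed_site_value == pytest.approx(tree_total_length(t))
        assert (res.replicate_effectiveness >= -1e-12).all()

    def test_empty_union_rejected(self):
        t = parse_newick("((A:1,B:1):1,(C:1,D:1):1);")
        grid = GridSpec(1, 3)
        layers = [PresenceLayer(lab, "breeding", frozenset({0}), grid) for lab in "ABCD"]
        cm = build_community_matrix(layers, grid, "breeding")
        table = pd.DataFrame(
            {"rl_flag": [True, False, False, False], "lump_group": None},
            index=pd.Index(list("ABCD"), name="taxon"),
        )
        with pytest.raises(ValueError, match="union"):
            effectiveness_total(cm, t, table, SiteSet((1, 2), "focal"),
                                "richness", n_reps=5, seed=0)

    @pytest.mark.parametrize("metric", ["richness", "rl_richness", "phylo_richness",
                                        "phylo_distinctiveness"])
    def test_union_values_match_two_pass_oracle(self, metric):
        """Site and replicate values equal a naive union-then-measure recomputation."""
        from phylocover import mean_pairwise_distance
        from conftest import pd_oracle

        t, cm, table = _community(4)
        sites = SiteSet((0, 3, 7), "focal")
        res = effectiveness_total(cm, t, table, sites, metric, n_reps=20, seed=11)
        inc = cm.values()
        union = inc[list(sites.cell_ids)].any(axis=0)
        present = [lab for lab, here in zip(cm.taxa, union) if here]
        flagged = set(table.index[table["rl_flag"]])
        if metric == "richness":
            expect = len(present)
        elif metric == "rl_richness":
            expect = len([p for p in present if p in flagged])
        elif metric == "phylo_richness":
            expect = pd_oracle(t, present)
        else:
            expect = mean_pairwise_distance(t, present)
        assert res.observed_site_value == pytest.approx(expect, abs=1e-9)


class TestCalibration:
    def test_random_sites_mean_effectiveness_near_zero(self):
        """Uniform focal sites should show no systematic effectiveness."""
        rng = np.random.default_rng(77)
        vals = rng.gamma(3.0, size=400)
        prof = _profile(vals)
        means = []
        for rep in range(60):
            sites = sample_random_cells(400, 25, np.random.default_rng(900 + rep))
            res = effectiveness_average(prof, SiteSet(sites.cell_ids, "focal"),
                                        n_reps=200, seed=rng)
            means.append(res.mean_effectiveness)
        se = np.std(means) / math.sqrt(len(means))
        assert abs(np.mean(means)) < 3 * se + 1e-3
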