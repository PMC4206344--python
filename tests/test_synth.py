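"""Synthetic scenario generator: tree, ranges, flags, sites, reproducibility."""

import json
import math

import numpy as np
import pytest

from phylocover import (
    ScenarioConfig,
    assign_flags,
    generate_scenario,
    parse_newick,
    place_sites,
    simulate_ranges,
    simulate_yule_tree,
)
from phylocover.grid import read_presence_raster, read_taxon_table

SMALL = dict(n_species=30, n_rows=15, n_cols=15, range_size=20, n_sites=8, seed=5)


class TestYuleTree:
    def test_two_tips_is_a_cherry(self):
        t = simulate_yule_tree(2, 0)
        assert len(t.tips()) == 2
        d = t.depths()
        for tip in t.tips():
            assert d[tip] == pytest.approx(1.0, abs=1e-9)

    def test_too_few_tips(self):
        with pytest.raises(ValueError):
            simulate_yule_tree(1, 0)

    @pytest.mark.parametrize("n", [5, 37, 120])
    def test_ultrametric_unit_height(self, n):
        t = simulate_yule_tree(n, n)
        d = t.depths()
        for tip in t.tips():
            assert d[tip] == pytest.approx(1.0, abs=1e-9)

    def test_lineage_growth_is_roughly_exponential(self):
        """Under a pure-birth process E[lineages at t] grows like e^t."""
        rng = np.random.default_rng(0)
        n = 64
        ratios = []
        for _ in range(300):
            t = simulate_yule_tree(n, rng)
            # count lineages crossing half the (unscaled) depth: in a unit-height
            # tree, edges spanning depth 0.5
            d = t.depths()
            crossing = sum(
                1
                for v in range(t.n_nodes)
                if t.parent[v] != -1 and d[int(t.parent[v])] <= 0.5 < d[v]
            )
            ratios.append(crossing)
        # strictly between the endpoints, far from linear interpolation (33)
        assert 2 < np.mean(ratios) < 33


class TestRanges:
    def test_range_size_one(self):
        cfg = ScenarioConfig(**{**SMALL, "range_size": 1})
        rng = np.random.default_rng(0)
        layers = simulate_ranges(cfg, rng, [f"s{i}" for i in range(5)])
        for ly in layers:
            if ly.season == "breeding":
                assert len(ly.cells) == 1

    def test_breeding_ranges_are_4_connected(self):
        cfg = ScenarioConfig(**SMALL)
        rng = np.random.default_rng(1)
        layers = simulate_ranges(cfg, rng, [f"s{i}" for i in range(10)])
        C = cfg.n_cols
        for ly in layers:
            if ly.season != "breeding" or not ly.cells:
                continue
            cells = set(ly.cells)
            seen = {next(iter(cells))}
            frontier = list(seen)
            while frontier:
                c = frontier.pop()
                r, k = divmod(c, C)
                for rr, kk in ((r - 1, k), (r + 1, k), (r, k - 1), (r, k + 1)):
                    nb = rr * C + kk
                    if 0 <= rr < cfg.n_rows and 0 <= kk < C and nb in cells and nb not in seen:
                        seen.add(nb)
                        frontier.append(nb)
            assert seen == cells

    def test_wintering_is_southward_translation(self):
        cfg = ScenarioConfig(**{**SMALL, "wintering_shift": 3})
        rng = np.random.default_rng(2)
        layers = simulate_ranges(cfg, rng, ["x"])
        by_season = {ly.season: ly for ly in layers}
        C = cfg.n_cols
        expect = {
            (r + 3) * C + c
            for cell in by_season["breeding"].cells
            for r, c in (divmod(cell, C),)
            if r + 3 < cfg.n_rows
        }
        assert by_season["wintering"].cells == expect

    def test_mean_richness_matches_counting_identity_without_gradient(self):
        cfg = ScenarioConfig(**{**SMALL, "richness_gradient": 0.0})
        totals = []
        for seed in range(10):
            rng = np.random.default_rng(seed)
            layers = simulate_ranges(cfg, rng, [f"s{i}" for i in range(cfg.n_species)])
            breeding = [ly for ly in layers if ly.season == "breeding"]
            totals.append(sum(len(ly.cells) for ly in breeding))
        mean_richness = np.mean(totals) / cfg.grid.n_cells
        assert mean_richness == pytest.approx(
            cfg.n_species * cfg.range_size / cfg.grid.n_cells, rel=1e-9
        )


class TestFlags:
    def test_random_mode_exact_count(self):
        t = simulate_yule_tree(20, 3)
        table = assign_flags(t, 0.951, "random", np.random.default_rng(0))
        assert int(table["rl_flag"].sum()) == math.ceil(0.951 * 20)  # all but one

    def test_clustered_mode_forms_clade(self):
        t = simulate_yule_tree(40, 7)
        table = assign_flags(t, 0.2, "clustered", np.random.default_rng(0))
        flagged = set(table.index[table["rl_flag"]])
        m = len(flagged)
        clades = t.clade_tipsets(min_size=1)
        # flagged tips must sit inside one clade of size < 2m (smallest >= m)
        containing = [cl for cl in clades.values() if flagged <= cl]
        assert containing
        assert min(len(cl) for cl in containing) >= m

    def test_invalid_fraction(self):
        t = simulate_yule_tree(10, 0)
        with pytest.raises(ValueError):
            assign_flags(t, 1.5, "random", np.random.default_rng(0))


class TestSites:
    def _scenario(self, **kw):
        return generate_scenario(ScenarioConfig(**{**SMALL, **kw}))

    def test_top_richness_single_site_is_argmax(self):
        sc = self._scenario(site_mode="top_richness", n_sites=1)
        vals = sc.profiles["breeding"]["richness"].values
        assert sc.sites.cell_ids == (int(np.argmax(vals)),)

    def test_random_mode_reproducible(self):
        a = self._scenario(site_mode="random")
        b = self._scenario(site_mode="random")
        assert a.sites.cell_ids == b.sites.cell_ids

    def test_rl_cells_contain_flagged_taxa(self):
        sc = self._scenario(site_mode="rl_cells")
        rl = sc.profiles["breeding"]["rl_richness"].values
        assert all(rl[c] >= 1 for c in sc.sites.cell_ids)

    def test_rl_cells_enriched_for_flagged_species(self):
        """Site cells average at least the grid-wide RL richness (20 scenarios)."""
        hits = 0
        for seed in range(20):
            sc = generate_scenario(ScenarioConfig(**{**SMALL, "seed": 100 + seed}))
            rl = sc.profiles["breeding"]["rl_richness"].values
            if rl[list(sc.sites.cell_ids)].mean() >= rl.mean():
                hits += 1
        assert hits >= 19

    def test_rl_cells_shortage_rejected(self):
        with pytest.raises(ValueError, match="rl_cells"):
            # 1-cell ranges and 1 flagged species cannot host 8 sites
            generate_scenario(
                ScenarioConfig(**{**SMALL, "range_size": 1, "rl_fraction": 0.034})
            )


class TestScenarioBundle:
    def test_files_roundtrip(self, tmp_path):
        sc = generate_scenario(ScenarioConfig(**SMALL), out_dir=tmp_path)
        tree = parse_newick((tmp_path / "tree.nwk").read_text())
        assert sorted(tree.tip_labels) == sorted(sc.tree.tip_labels)
        table = read_taxon_table(tmp_path / "taxa.csv")
        assert table["rl_flag"].equals(sc.table["rl_flag"])
        grid = sc.config.grid
        for ly in sc.layers[:6]:
            back = read_presence_raster(
                tmp_path / "rasters" / f"{ly.taxon}.{ly.season}.grid", grid, ly.taxon, ly.season
            )
            assert back.cells == ly.cells

    def test_same_config_is_byte_identical(self, tmp_path):
        a, b = tmp_path / "a", tmp_path / "b"
        generate_scenario(ScenarioConfig(**SMALL), out_dir=a)
        generate_scenario(ScenarioConfig(**SMALL), out_dir=b)
        assert (a / "manifest.json").read_bytes() == (b / "manifest.json").read_bytes()
        assert (a / "tree.nwk").read_bytes() == (b / "tree.nwk").read_bytes()
        for f in sorted((a / "rasters").iterdir()):
            assert f.read_bytes() == (b / "rasters" / f.name).read_bytes()

    def test_manifest_counts(self, tmp_path):
        sc = generate_scenario(ScenarioConfig(**SMALL), out_dir=tmp_path)
        manifest = json.loads((tmp_path / "manifest.json").read_text())
        assert manifest["n_taxa"] == SMALL["n_species"]
        assert manifest["n_flagged"] == math.ceil(0.05 * SMALL["n_species"])
        assert manifest["site_cells"] == list(sc.sites.cell_ids)
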