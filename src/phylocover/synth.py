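"""Synthetic scenarios with known structure for end-to-end testing.

Real inputs of this kind — digitised field-guide range maps on a fine
grid plus a large dated phylogeny — are not redistributable, so the
package ships a generator that emulates their salient features:

* a rooted, ultrametric pure-birth (Yule) tree of ``n_species`` tips,
  scaled to unit height;
* spatially contiguous species ranges grown by a spreading-dye process
  (random 4-neighbour accretion from a seed cell) on an R x C grid, with
  seed rows biased southward by ``richness_gradient`` to create a
  latitudinal richness gradient;
* a wintering layer per species, the breeding range translated
  ``wintering_shift`` rows southward (truncated at the grid edge), so
  wintering communities sit south of breeding ones;
* a small red-listed subset of taxa, either a uniform random subset or a
  clade-clustered one (the non-random case the tip-shuffle null should
  detect);
* ``n_sites`` focal cells placed uniformly at random, at the richest
  cells, or uniformly among cells holding at least one red-listed taxon
  (mimicking site designation driven by threatened species).

``generate_scenario`` is a pure function of its config: rerunning with
the same config reproduces every file byte for byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .diversity import DiversityProfile, TreeCommunityMetrics, cell_profiles
from .grid import (
    CommunityMatrix,
    GridSpec,
    PresenceLayer,
    SiteSet,
    build_community_matrix,
    write_presence_raster,
    write_sites_csv,
    write_taxon_table,
)
from .nulls import sample_random_cells
from .tree import Phylogeny, write_newick

__all__ = [
    "ScenarioConfig",
    "Scenario",
    "simulate_yule_tree",
    "simulate_ranges",
    "assign_flags",
    "place_sites",
    "generate_scenario",
]

SITE_MODES = ("random", "top_richness", "rl_cells")
RL_MODES = ("random", "clustered")


@dataclass(frozen=True)
class ScenarioConfig:
    """Knobs of the synthetic study system (defaults = the standard scenario)."""

    n_species: int = 200
    n_rows: int = 60
    n_cols: int = 60
    cell_size: float = 0.03
    range_size: int = 150
    richness_gradient: float = 4.0
    wintering_shift: int = 8
    rl_fraction: float = 0.05
    rl_mode: str = "random"
    site_mode: str = "rl_cells"
    n_sites: int = 40
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_species < 2:
            raise ValueError("n_species must be >= 2")
        if not 0 < self.rl_fraction < 1:
            raise ValueError("rl_fraction must lie in (0, 1)")
        if self.rl_mode not in RL_MODES:
            raise ValueError(f"rl_mode must be one of {RL_MODES}")
        if self.site_mode not in SITE_MODES:
            raise ValueError(f"site_mode must be one of {SITE_MODES}")
        if self.n_sites < 1 or self.n_sites > self.n_rows * self.n_cols:
            raise ValueError("n_sites must be in [1, n_cells]")
        if self.range_size < 1 or self.range_size > self.n_rows * self.n_cols:
            raise ValueError("range_size must be in [1, n_cells]")

    @property
    def grid(self) -> GridSpec:
        return GridSpec(self.n_rows, self.n_cols, 0.0, 0.0, self.cell_size)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass(frozen=True)
class Scenario:
    """A fully generated study system."""

    config: ScenarioConfig
    tree: Phylogeny
    table: pd.DataFrame
    layers: tuple[PresenceLayer, ...]
    communities: dict[str, CommunityMatrix]
    profiles: dict[str, dict[str, DiversityProfile]]  # season -> metric -> profile
    sites: SiteSet
    manifest: dict


def simulate_yule_tree(n_tips: int, seed: int | np.random.Generator) -> Phylogeny:
    """Rooted ultrametric pure-birth tree scaled to unit height.

    Lineages split at rate 1 per lineage; after the n-th tip appears the
    process runs one more exponential waiting time and all pending tips
    are closed at that moment, then every node time is divided by the tree
    height.  Tip labels ``s000..`` are attached in random order so label
    identity carries no topological signal.
    """
    if n_tips < 2:
        raise ValueError("n_tips must be >= 2")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    parent: list[int] = [-1]
    start: list[float] = [0.0]  # birth time of the edge above each node
    label: list[str | None] = [None]
    # active lineages: node ids whose subtree is still a pending tip
    active = [0]
    t = 0.0
    # the root node immediately bifurcates (a rooted tree of >= 2 tips)
    while len(active) < n_tips:
        if len(active) > 1:
            t += rng.exponential(1.0 / len(active))
        i = int(rng.integers(len(active)))
        v = active.pop(i)
        for _ in range(2):
            parent.append(v)
            start.append(t)
            label.append(None)
            active.append(len(parent) - 1)
    t += rng.exponential(1.0 / n_tips)
    height = t if t > 0 else 1.0

    names = [f"s{i:03d}" for i in range(n_tips)]
    order = rng.permutation(n_tips)
    end = [t] * len(parent)
    # internal nodes end where their children start
    for v, p in enumerate(parent):
        if p >= 0:
            end[p] = start[v]
    length = [math.nan] * len(parent)
    for v, p in enumerate(parent):
        if p >= 0:
            length[v] = (end[v] - start[v]) / height
    for k, v in enumerate(active):
        label[v] = names[order[k]]
    return Phylogeny(parent, length, label)


def _grow_range(grid: GridSpec, seed_cell: int, size: int, rng: np.random.Generator) -> frozenset[int]:
    """Spreading dye: uniform random 4-neighbour accretion to ``size`` cells."""
    R, C = grid.n_rows, grid.n_cols
    region = {seed_cell}
    frontier: list[int] = []
    in_frontier: set[int] = set()

    def push_neighbours(cell: int) -> None:
        r, c = divmod(cell, C)
        for rr, cc in ((r - 1, c), (r + 1, c), (r, c - 1), (r, c + 1)):
            if 0 <= rr < R and 0 <= cc < C:
                nb = rr * C + cc
                if nb not in region and nb not in in_frontier:
                    frontier.append(nb)
                    in_frontier.add(nb)

    push_neighbours(seed_cell)
    while len(region) < size:
        if not frontier:
            raise ValueError("range cannot grow further; grid too small")
        i = int(rng.integers(len(frontier)))
        cell = frontier[i]
        frontier[i] = frontier[-1]
        frontier.pop()
        in_frontier.discard(cell)
        region.add(cell)
        push_neighbours(cell)
    return frozenset(region)


def simulate_ranges(config: ScenarioConfig, rng: np.random.Generator, taxa: list[str]) -> list[PresenceLayer]:
    """Contiguous breeding ranges plus southward-shifted wintering ranges.

    Seed rows are drawn with probability proportional to
    ``exp(richness_gradient * row / (n_rows - 1))``, so southern (high-row)
    cells accumulate more ranges and a richness gradient emerges; columns
    are uniform.  The wintering layer is the breeding layer translated
    ``wintering_shift`` rows down, truncated at the boundary.
    """
    grid = config.grid
    R, C = grid.n_rows, grid.n_cols
    rows = np.arange(R)
    w = np.exp(config.richness_gradient * rows / max(R - 1, 1))
    row_p = w / w.sum()

    layers: list[PresenceLayer] = []
    for taxon in taxa:
        r0 = int(rng.choice(R, p=row_p))
        c0 = int(rng.integers(C))
        breeding = _grow_range(grid, r0 * C + c0, config.range_size, rng)
        layers.append(PresenceLayer(taxon=taxon, season="breeding", cells=breeding, grid=grid))
        shifted = frozenset(
            (r + config.wintering_shift) * C + c
            for cell in breeding
            for r, c in (divmod(cell, C),)
            if r + config.wintering_shift < R
        )
        layers.append(PresenceLayer(taxon=taxon, season="wintering", cells=shifted, grid=grid))
    return layers


def assign_flags(
    tree: Phylogeny, rl_fraction: float, rl_mode: str, rng: np.random.Generator
) -> pd.DataFrame:
    """Flag ``ceil(rl_fraction * n)`` tips as red-listed.

    ``random`` draws a uniform subset; ``clustered`` flags the tips of the
    smallest clade holding at least that many tips (truncated to size), so
    the flagged set is phylogenetically aggregated — the situation the
    tip-shuffle null is built to detect.
    """
    if rl_mode not in RL_MODES:
        raise ValueError(f"rl_mode must be one of {RL_MODES}")
    if not 0 < rl_fraction < 1:
        raise ValueError("rl_fraction must lie in (0, 1)")
    tips = tree.tip_labels
    n = len(tips)
    m = math.ceil(rl_fraction * n)
    if rl_mode == "random":
        flagged = {tips[i] for i in rng.choice(n, size=m, replace=False)}
    else:
        clades = tree.clade_tipsets(min_size=1)
        eligible = [(len(cl), v) for v, cl in clades.items() if len(cl) >= m]
        size, v = min(eligible)  # smallest qualifying clade; ties by node index
        members = sorted(clades[v])
        flagged = set(members[:m])
    table = pd.DataFrame(
        {
            "rl_flag": [t in flagged for t in sorted(tips)],
            "lump_group": [None] * n,
        },
        index=pd.Index(sorted(tips), name="taxon"),
    )
    return table


def place_sites(
    profiles: dict[str, DiversityProfile],
    table: pd.DataFrame,
    config: ScenarioConfig,
    rng: np.random.Generator,
) -> SiteSet:
    """Place ``n_sites`` focal cells according to ``site_mode``.

    Placement uses the breeding-season profiles (sites are designated on
    breeding evidence): ``top_richness`` takes the richest cells (ties by
    lowest cell index), ``rl_cells`` samples uniformly among cells holding
    at least one red-listed taxon.
    """
    k = config.n_sites
    if config.site_mode == "random":
        s = sample_random_cells(config.grid.n_cells, k, rng)
        return SiteSet(cell_ids=s.cell_ids, source="focal")
    if config.site_mode == "top_richness":
        vals = profiles["richness"].values
        order = np.lexsort((np.arange(len(vals)), -vals))
        return SiteSet(cell_ids=tuple(int(c) for c in order[:k]), source="focal")
    # rl_cells
    eligible = np.flatnonzero(profiles["rl_richness"].values >= 1)
    if len(eligible) < k:
        raise ValueError(
            f"site_mode='rl_cells' needs >= {k} cells with a red-listed taxon, "
            f"found {len(eligible)}"
        )
    chosen = rng.choice(eligible, size=k, replace=False)
    return SiteSet(cell_ids=tuple(int(c) for c in chosen), source="focal")


def _config_hash(config: ScenarioConfig) -> str:
    blob = json.dumps(config.to_dict(), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()


def generate_scenario(config: ScenarioConfig, out_dir: str | Path | None = None) -> Scenario:
    """Generate a complete scenario; optionally write all input files.

    Files written (when ``out_dir`` is given): ``tree.nwk``, ``taxa.csv``,
    ``sites.csv``, ``rasters/<taxon>.<season>.grid``, and ``manifest.json``
    recording the config and its hash.  Generation is a pure function of
    the config.
    """
    rng = np.random.default_rng(config.seed)
    tree = simulate_yule_tree(config.n_species, rng)
    taxa = sorted(tree.tip_labels)
    layers = tuple(simulate_ranges(config, rng, taxa))
    table = assign_flags(tree, config.rl_fraction, config.rl_mode, rng)

    communities = {
        season: build_community_matrix(layers, config.grid, season)
        for season in ("breeding", "wintering")
    }
    tm = TreeCommunityMetrics(tree, taxa)
    profiles = {
        season: cell_profiles(communities[season], tree, table, metrics=tm)
        for season in ("breeding", "wintering")
    }
    sites = place_sites(profiles["breeding"], table, config, rng)

    manifest = {
        "config": config.to_dict(),
        "config_sha256": _config_hash(config),
        "n_taxa": len(taxa),
        "n_flagged": int(table["rl_flag"].sum()),
        "site_cells": list(sites.cell_ids),
    }

    if out_dir is not None:
        out = Path(out_dir)
        (out / "rasters").mkdir(parents=True, exist_ok=True)
        (out / "tree.nwk").write_text(write_newick(tree) + "\n")
        write_taxon_table(table, out / "taxa.csv")
        write_sites_csv([config.grid.cell_center(c) for c in sites.cell_ids], out / "sites.csv")
        for ly in layers:
            write_presence_raster(ly, out / "rasters" / f"{ly.taxon}.{ly.season}.grid")
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")

    return Scenario(
        config=config,
        tree=tree,
        table=table,
        layers=layers,
        communities=communities,
        profiles=profiles,
        sites=sites,
        manifest=manifest,
    )
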