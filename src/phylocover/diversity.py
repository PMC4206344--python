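"""Per-cell diversity measures on a community matrix and a phylogeny.

Four measures per grid cell and season:

* ``richness`` — number of taxa present;
* ``rl_richness`` — number of red-listed taxa present;
* ``phylo_richness`` — Faith's phylogenetic diversity, here the total
  branch length of the union of *root-to-tip* paths of the taxa present
  (root-inclusive: a single taxon scores its full root-to-tip depth, and
  the full taxon set scores the total tree length);
* ``phylo_distinctiveness`` — mean pairwise patristic distance over all
  unordered pairs of taxa present; undefined (NaN) where fewer than two
  taxa occur.

The root-inclusive PD convention is used everywhere in the package,
including the threatened-subset branch length tested by the tip-shuffle
null, so the two analyses share one definition.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .grid import CommunityMatrix, GridSpec
from .tree import Phylogeny

__all__ = [
    "METRICS",
    "DiversityProfile",
    "TreeCommunityMetrics",
    "faith_pd",
    "mean_pairwise_distance",
    "cell_profiles",
    "write_profiles_tsv",
    "reconcile_taxa",
]

METRICS = ("richness", "rl_richness", "phylo_richness", "phylo_distinctiveness")


@dataclass(frozen=True)
class DiversityProfile:
    """One diversity measure evaluated on every cell of a grid.

    ``values`` has one entry per cell; NaN marks cells where the measure is
    undefined (mean pairwise distance with < 2 taxa).
    """

    grid: GridSpec
    season: str
    metric: str
    values: np.ndarray

    def __post_init__(self) -> None:
        if self.metric not in METRICS:
            raise ValueError(f"unknown metric {self.metric!r}; expected one of {METRICS}")
        if len(self.values) != self.grid.n_cells:
            raise ValueError("profile length must equal the number of grid cells")

    def defined(self) -> np.ndarray:
        return ~np.isnan(self.values)


class TreeCommunityMetrics:
    """Vectorised PD/MPD engine for one tree and a fixed taxon order.

    Precomputes, per tip, the set of edges on its root path (as a boolean
    tips x nodes matrix) and the dense patristic matrix, so that Faith PD
    and MPD of many communities reduce to matrix products.  Used by the
    per-cell profiles, the tip-shuffle null, and the 'total'-mode
    effectiveness statistic, which all need thousands of subset
    evaluations.
    """

    def __init__(self, tree: Phylogeny, taxa: Iterable[str] | None = None) -> None:
        self.tree = tree
        self.taxa = list(taxa) if taxa is not None else tree.tip_labels
        idx = tree.tip_index()
        missing = sorted(set(self.taxa) - idx.keys())
        if missing:
            raise KeyError(f"taxa not on the tree: {missing}")
        nodes = [idx[t] for t in self.taxa]
        n = tree.n_nodes
        A = np.zeros((len(nodes), n), dtype=bool)
        for r, v in enumerate(nodes):
            for u in tree.path_to_root(v):
                if tree.parent[u] != -1:
                    A[r, u] = True
        self.edge_on_root_path = A  # (taxa, nodes)
        self.edge_length = np.where(tree.parent != -1, tree.length, 0.0)
        self.depths = A @ self.edge_length
        self.pairwise = tree.patristic_matrix(self.taxa)
        self.index = {t: i for i, t in enumerate(self.taxa)}

    @property
    def n_taxa(self) -> int:
        return len(self.taxa)

    def subset_vector(self, taxa: Iterable[str]) -> np.ndarray:
        v = np.zeros(self.n_taxa, dtype=bool)
        for t in taxa:
            if t not in self.index:
                raise KeyError(f"unknown taxon {t!r}")
            v[self.index[t]] = True
        return v

    def pd_many(self, incidence: np.ndarray) -> np.ndarray:
        """Faith PD for each row of a (communities, taxa) boolean matrix."""
        inc = np.atleast_2d(np.asarray(incidence, dtype=bool))
        marked = inc @ self.edge_on_root_path  # edge used by >= 1 present taxon
        return (marked > 0) @ self.edge_length

    def mpd_many(self, incidence: np.ndarray) -> np.ndarray:
        """Mean pairwise distance per community row; NaN where < 2 taxa."""
        inc = np.atleast_2d(np.asarray(incidence, dtype=float))
        k = inc.sum(axis=1)
        tot = np.einsum("ij,jk,ik->i", inc, self.pairwise, inc)  # ordered pairs x2? no: full sum
        npairs = k * (k - 1)  # ordered pairs; pairwise has zero diagonal
        with np.errstate(invalid="ignore", divide="ignore"):
            out = np.where(npairs > 0, tot / npairs, np.nan)
        return out


def faith_pd(tree: Phylogeny, taxa: Iterable[str]) -> float:
    """Root-inclusive Faith PD of a taxon set (0 for the empty set).

    Sum of branch lengths over the union of the root-to-tip paths of
    ``taxa``; equals the total tree length when ``taxa`` is every tip.
    """
    taxa = list(taxa)
    if not taxa:
        return 0.0
    idx = tree.tip_index()
    missing = sorted(set(taxa) - idx.keys())
    if missing:
        raise KeyError(f"unknown tip labels: {missing}")
    marked: set[int] = set()
    for t in taxa:
        for u in tree.path_to_root(idx[t]):
            if tree.parent[u] != -1:
                marked.add(u)
    return float(sum(tree.length[u] for u in marked))


def mean_pairwise_distance(tree: Phylogeny, taxa: Iterable[str]) -> float:
    """Mean patristic distance over unordered pairs; NaN with < 2 taxa."""
    taxa = list(dict.fromkeys(taxa))
    idx = tree.tip_index()
    missing = sorted(set(taxa) - idx.keys())
    if missing:
        raise KeyError(f"unknown tip labels: {missing}")
    if len(taxa) < 2:
        return math.nan
    D = tree.patristic_matrix(taxa)
    k = len(taxa)
    return float(D.sum() / (k * (k - 1)))


def reconcile_taxa(
    community_taxa: Iterable[str], tree_taxa: Iterable[str], table_taxa: Iterable[str]
) -> None:
    """Require one shared taxon set across rasters, tree, and table.

    Raises a reconciliation error listing the offending names instead of
    silently dropping taxa present on one side only.
    """
    c, t, b = set(community_taxa), set(tree_taxa), set(table_taxa)
    problems = []
    if c - t:
        problems.append(f"in rasters but not on the tree: {sorted(c - t)}")
    if t - c:
        problems.append(f"on the tree but not in rasters: {sorted(t - c)}")
    if c - b:
        problems.append(f"in rasters but not in the taxon table: {sorted(c - b)}")
    if b - c:
        problems.append(f"in the taxon table but not in rasters: {sorted(b - c)}")
    if problems:
        raise ValueError("taxon sets do not reconcile; " + "; ".join(problems))


def cell_profiles(
    community: CommunityMatrix,
    tree: Phylogeny,
    table: pd.DataFrame,
    metrics: TreeCommunityMetrics | None = None,
) -> dict[str, DiversityProfile]:
    """All four diversity profiles for one season's community matrix."""
    reconcile_taxa(community.taxa, tree.tip_labels, table.index)
    tm = metrics if metrics is not None else TreeCommunityMetrics(tree, community.taxa)
    if tm.taxa != community.taxa:
        raise ValueError("metrics engine taxon order does not match the community matrix")
    inc = community.values()
    flagged = table.loc[community.taxa, "rl_flag"].to_numpy(dtype=bool)

    out = {
        "richness": inc.sum(axis=1).astype(float),
        "rl_richness": inc[:, flagged].sum(axis=1).astype(float),
        "phylo_richness": tm.pd_many(inc),
        "phylo_distinctiveness": tm.mpd_many(inc),
    }
    return {
        m: DiversityProfile(grid=community.grid, season=community.season, metric=m, values=v)
        for m, v in out.items()
    }


def write_profiles_tsv(profiles: Mapping[str, DiversityProfile], path: str | Path) -> None:
    """TSV: cell_id, row, col, metric, season, value (empty = undefined)."""
    rows = []
    for prof in profiles.values():
        for cell, v in enumerate(prof.values):
            r, c = prof.grid.rowcol(cell)
            rows.append(
                (cell, r, c, prof.metric, prof.season, "" if math.isnan(v) else f"{v:.10g}")
            )
    df = pd.DataFrame(rows, columns=["cell_id", "row", "col", "metric", "season", "value"])
    df.to_csv(path, sep="\t", index=False)
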