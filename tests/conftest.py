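"""Shared fixtures and independent brute-force oracles.

The oracles deliberately avoid the package's vectorised code paths: they
walk parent pointers and build explicit edge sets, so metric tests compare
two independent routes to the same quantity.
"""

from __future__ import annotations

import numpy as np
import pytest

from phylocover import Phylogeny, parse_newick, simulate_yule_tree


# ---------------------------------------------------------------------- #
# oracles
# ---------------------------------------------------------------------- #


def root_path_edges(tree: Phylogeny, tip_label: str) -> set[int]:
    """Edge set (as child-node ids) on the path root -> tip."""
    v = tree.tip_index()[tip_label]
    edges = set()
    while tree.parent[v] != -1:
        edges.add(v)
        v = int(tree.parent[v])
    return edges


def pd_oracle(tree: Phylogeny, taxa) -> float:
    """Faith PD by explicit union of root-to-tip edge sets."""
    marked: set[int] = set()
    for t in taxa:
        marked |= root_path_edges(tree, t)
    return sum(float(tree.length[e]) for e in marked)


def pairwise_oracle(tree: Phylogeny, a: str, b: str) -> float:
    """Patristic distance as the symmetric difference of root paths."""
    ea, eb = root_path_edges(tree, a), root_path_edges(tree, b)
    return sum(float(tree.length[e]) for e in ea ^ eb)


def mpd_oracle(tree: Phylogeny, taxa) -> float:
    taxa = list(taxa)
    pairs = [(a, b) for i, a in enumerate(taxa) for b in taxa[i + 1 :]]
    return sum(pairwise_oracle(tree, a, b) for a, b in pairs) / len(pairs)


# ---------------------------------------------------------------------- #
# fixtures
# ---------------------------------------------------------------------- #


@pytest.fixture
def cherry_pair_tree() -> Phylogeny:
    """((A:1,B:1):1,(C:1,D:1):1); — the balanced 4-tip tree."""
    return parse_newick("((A:1,B:1):1,(C:1,D:1):1);")


@pytest.fixture
def caterpillar_tree() -> Phylogeny:
    return parse_newick("((A:1,B:1):1,C:2);")


@pytest.fixture
def star4_tree() -> Phylogeny:
    return parse_newick("(A:1,B:1,C:1,D:1);")


def random_trees(n_trees: int, n_tips: int, seed: int = 0):
    rng = np.random.default_rng(seed)
    return [simulate_yule_tree(n_tips, rng) for _ in range(n_trees)]
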