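"""Randomization nulls: tip-shuffle branch length and random-cell effectiveness.

Two resampling analyses:

* :func:`tip_shuffle_null` asks whether a flagged (red-listed) subset of
  tips spans more or less of the tree than a random subset of the same
  size.  Shuffling all tip labels uniformly and reading off the flagged
  labels' positions is equivalent to drawing a uniform random subset of
  tips of the same size, which is how replicates are generated here.

* :func:`effectiveness_average` / :func:`effectiveness_total` compare a
  focal set of grid cells (e.g. cells holding site centers) against
  repeated uniform draws of the same number of cells.  Per replicate the
  effectiveness statistic is

      E(r) = (D_site - D_rand(r)) / D_site

  summarised by its mean and 2.5%/97.5% quantiles over replicates; the
  focal sites are called effective for a measure when that interval
  excludes 0.  'Average' mode uses the per-cell profile averaged over
  cells (cells with an undefined value are dropped from the mean);
  'total' mode is the complementarity reading — the measure of the union
  of taxa occurring in at least one cell of the set.

All quantiles in the package route through :func:`percentile_interval`
(linear interpolation between order statistics) to prevent convention
drift.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .diversity import DiversityProfile, TreeCommunityMetrics
from .grid import CommunityMatrix, SiteSet
from .tree import Phylogeny

__all__ = [
    "NullCI",
    "EffectivenessResult",
    "percentile_interval",
    "tip_shuffle_null",
    "sample_random_cells",
    "effectiveness_average",
    "effectiveness_total",
    "union_metric_value",
]


def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def percentile_interval(
    values: Sequence[float], probs: tuple[float, float] = (0.025, 0.975)
) -> tuple[float, float]:
    """Quantile pair by linear interpolation between adjacent order statistics."""
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise ValueError("percentile_interval of an empty sample")
    lo, hi = np.quantile(arr, probs, method="linear")
    return float(lo), float(hi)


@dataclass(frozen=True)
class NullCI:
    """Observed statistic with its permutation-null confidence band."""

    observed: float
    replicates: np.ndarray
    lower: float
    upper: float
    n_reps: int
    seed: int | None

    @property
    def outside(self) -> bool:
        return self.observed < self.lower or self.observed > self.upper

    @property
    def below(self) -> bool:
        return self.observed < self.lower


def tip_shuffle_null(
    tree: Phylogeny,
    flagged: Iterable[str],
    n_reps: int = 1000,
    seed: int | np.random.Generator | None = None,
    metrics: TreeCommunityMetrics | None = None,
) -> NullCI:
    """Null for the branch length connecting a flagged tip subset to the root.

    The observed value is the root-inclusive Faith PD of ``flagged``.  Each
    replicate permutes all tip labels uniformly across the fixed tree and
    recomputes the PD of the flagged labels — implemented as the PD of a
    uniform random subset of the same size.  The 2.5% and 97.5% percentiles
    of the replicates form the confidence band under the hypothesis that
    the flagged taxa sit at random positions on the tree.
    """
    flagged = list(dict.fromkeys(flagged))
    if not flagged:
        raise ValueError("flagged subset must be non-empty")
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    tm = metrics if metrics is not None else TreeCommunityMetrics(tree)
    obs_vec = tm.subset_vector(flagged)  # raises on unknown labels
    observed = float(tm.pd_many(obs_vec[None, :])[0])

    rng = _as_rng(seed)
    k, s = len(flagged), tm.n_taxa
    inc = np.zeros((n_reps, s), dtype=bool)
    for r in range(n_reps):
        inc[r, rng.choice(s, size=k, replace=False)] = True
    reps = tm.pd_many(inc)
    lo, hi = percentile_interval(reps)
    return NullCI(
        observed=observed,
        replicates=reps,
        lower=lo,
        upper=hi,
        n_reps=n_reps,
        seed=seed if isinstance(seed, int) else None,
    )


def sample_random_cells(
    n_total_cells: int, k: int, rng: int | np.random.Generator | None = None
) -> SiteSet:
    """k distinct cells, uniform without replacement over the whole grid."""
    if not 1 <= k <= n_total_cells:
        raise ValueError(f"need 1 <= k <= n_total_cells, got k={k}, n={n_total_cells}")
    rng = _as_rng(rng)
    cells = rng.choice(n_total_cells, size=k, replace=False)
    return SiteSet(cell_ids=tuple(int(c) for c in cells), source="random")


@dataclass(frozen=True)
class EffectivenessResult:
    """Effectiveness of a focal cell set for one measure, season, and mode."""

    metric: str
    season: str
    mode: str  # "average" | "total"
    observed_site_value: float
    replicate_effectiveness: np.ndarray
    mean_effectiveness: float
    ci: tuple[float, float]
    n_reps: int
    seed: int | None

    @property
    def significant(self) -> bool:
        """True when the replicate quantile interval excludes 0."""
        return self.ci[0] > 0 or self.ci[1] < 0


def _summarise(
    metric: str,
    season: str,
    mode: str,
    d_site: float,
    d_rand: np.ndarray,
    n_reps: int,
    seed,
) -> EffectivenessResult:
    eff = (d_site - d_rand) / d_site
    # a replicate whose cells are all undefined carries no information; the
    # summary is over the defined replicates (their count is n_reps minus NaNs)
    finite = eff[~np.isnan(eff)]
    if finite.size == 0:
        raise ValueError(f"all replicates undefined for {metric!r} ({mode})")
    return EffectivenessResult(
        metric=metric,
        season=season,
        mode=mode,
        observed_site_value=float(d_site),
        replicate_effectiveness=eff,
        mean_effectiveness=float(finite.mean()),
        ci=percentile_interval(finite),
        n_reps=n_reps,
        seed=seed if isinstance(seed, int) else None,
    )


def effectiveness_average(
    profile: DiversityProfile,
    sites: SiteSet,
    n_reps: int = 1000,
    seed: int | np.random.Generator | None = None,
) -> EffectivenessResult:
    """'Average'-mode effectiveness of ``sites`` for one per-cell profile.

    D_site is the profile averaged over the site cells; each replicate
    draws ``len(sites)`` fresh uniform cells and averages the profile over
    them.  Cells with an undefined (NaN) profile value are excluded from
    both averages; a replicate whose cells are all undefined is recorded
    as NaN and dropped from the summary statistics.
    """
    vals = profile.values
    n_cells = len(vals)
    bad = [c for c in sites.cell_ids if not 0 <= c < n_cells]
    if bad:
        raise ValueError(f"site cells outside the grid: {bad}")
    site_vals = vals[list(sites.cell_ids)]
    site_vals = site_vals[~np.isnan(site_vals)]
    if site_vals.size == 0:
        raise ValueError("all site cells have undefined profile values")
    d_site = float(site_vals.mean())
    if d_site == 0:
        raise ValueError("site average is 0; effectiveness is undefined")

    rng = _as_rng(seed)
    k = len(sites)
    d_rand = np.empty(n_reps)
    for r in range(n_reps):
        draw = vals[rng.choice(n_cells, size=k, replace=False)]
        draw = draw[~np.isnan(draw)]
        d_rand[r] = draw.mean() if draw.size else np.nan
    return _summarise(profile.metric, profile.season, "average", d_site, d_rand, n_reps, seed)


def union_metric_value(
    union: np.ndarray,
    metric: str,
    tm: TreeCommunityMetrics,
    flagged: np.ndarray,
) -> float:
    """One diversity measure evaluated on a boolean taxon-union vector."""
    if metric == "richness":
        return float(union.sum())
    if metric == "rl_richness":
        return float((union & flagged).sum())
    if metric == "phylo_richness":
        return float(tm.pd_many(union[None, :])[0])
    if metric == "phylo_distinctiveness":
        return float(tm.mpd_many(union[None, :].astype(float))[0])
    raise ValueError(f"unknown metric {metric!r}")


def effectiveness_total(
    community: CommunityMatrix,
    tree: Phylogeny,
    table: pd.DataFrame,
    sites: SiteSet,
    metric: str,
    n_reps: int = 1000,
    seed: int | np.random.Generator | None = None,
    tm: TreeCommunityMetrics | None = None,
) -> EffectivenessResult:
    """'Total'-mode (complementarity) effectiveness of ``sites``.

    The measure is evaluated on the union of taxa occurring in at least
    one site cell, and compared per replicate against the union over the
    same number of uniformly drawn cells.
    """
    inc = community.values()
    n_cells = inc.shape[0]
    bad = [c for c in sites.cell_ids if not 0 <= c < n_cells]
    if bad:
        raise ValueError(f"site cells outside the grid: {bad}")
    tm = tm if tm is not None else TreeCommunityMetrics(tree, community.taxa)
    flagged = table.loc[community.taxa, "rl_flag"].to_numpy(dtype=bool)

    site_union = inc[list(sites.cell_ids)].any(axis=0)
    if not site_union.any():
        raise ValueError("no taxon occurs in any site cell; union is empty")
    d_site = union_metric_value(site_union, metric, tm, flagged)
    if d_site == 0 or math.isnan(d_site):
        raise ValueError(f"site union value for {metric!r} is 0 or undefined")

    rng = _as_rng(seed)
    k = len(sites)
    d_rand = np.empty(n_reps)
    for r in range(n_reps):
        cells = rng.choice(n_cells, size=k, replace=False)
        union = inc[cells].any(axis=0)
        d_rand[r] = union_metric_value(union, metric, tm, flagged)
    return _summarise(metric, community.season, "total", d_site, d_rand, n_reps, seed)
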