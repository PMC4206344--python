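# Methods

`phylocover` asks a spatial conservation question: when sites are selected
because threatened species occur there, do those sites — as a side effect —
capture above-average taxonomic and phylogenetic diversity?  The package
implements the full chain of analyses on a grid of species communities and
a dated phylogeny, together with a synthetic-data generator so that every
stage can be exercised, calibrated, and tested without access to real
(non-redistributable) range atlases and megaphylogenies.

## Diversity measures

For each grid cell `c` with community `S_c` (one incidence matrix per
season, breeding and wintering) the package computes:

1. **Taxonomic richness** `|S_c|`.
2. **Red-list richness** `|S_c ∩ RL|`, the number of threatened (flagged)
   taxa present.
3. **Phylogenetic richness** (Faith's PD): the total branch length of the
   union of *root-to-tip* paths of the taxa in `S_c`.  The convention is
   root-inclusive: a single taxon scores its full root-to-tip depth, and
   the complete taxon set scores the total tree length.  Note that some
   software (e.g. picante's `pd` with `include.root=FALSE`) measures only
   the subtree spanning the community; this package applies the
   root-inclusive definition uniformly — both in the per-cell profiles and
   in the threatened-subset branch length tested by the tip-shuffle null —
   so the two analyses share one definition and PD is monotone under taxon
   addition with PD(all tips) = total tree length.
4. **Phylogenetic distinctiveness** (MPD): the mean patristic distance over
   all unordered pairs in `S_c`; undefined for communities of fewer than
   two taxa.  Undefined cells are carried as NaN, excluded from hotspot
   quantiles, and excluded from the averages of the effectiveness analysis
   — dropping them is the only choice that keeps those means well defined.

PD and MPD are evaluated for thousands of communities per run, so both are
implemented as matrix products against precomputed structures (a tip-by-edge
root-path indicator matrix and the dense patristic matrix); the naive
union-of-paths and all-pairs oracles are retained in the test suite and the
two routes are compared to 1e-9.

## Tip-shuffle null for the threatened subset

Whether the flagged taxa are phylogenetically unusual is tested by
shuffling all tip labels uniformly across the fixed tree 1,000 times and
recomputing the flagged subset's branch length each time; the 2.5% and
97.5% percentiles of the replicates form the null band.  A uniform label
shuffle induces a uniform random subset of tips of the flagged size, and
the implementation draws such subsets directly (vectorised through the PD
engine); the equivalence, and agreement with the exhaustive subset
distribution on small trees, are tested.  All percentiles in the package
use linear interpolation between adjacent order statistics (one shared
implementation, `percentile_interval`), so e.g. the 2.5%/97.5% pair of the
values 1..1000 is (25.975, 975.025).

## Effectiveness of focal sites

Focal sites (cells containing site centers; duplicates collapse to one
cell) are compared against 1,000 draws of the same number of cells, uniform
**without replacement** — site cells are distinct, so the matched null
draws distinct cells too.  Per replicate `r` the effectiveness is

    E(r) = (D_site − D_rand(r)) / D_site

with two readings of `D`:

* **average** — the per-cell measure averaged over the cell set;
* **total** (complementarity) — the measure of the union of taxa occurring
  in at least one cell of the set, so a species-poor cell harbouring taxa
  found nowhere else still contributes.

The summary is the mean of `E(r)` and its 2.5%/97.5% quantiles; the sites
are called effective when that interval excludes 0.  No p-values are
reported — significance is interval-exclusion only.  The statistic is
per-replicate (each `E(r)` uses its own `D_rand(r)`), then summarised; it
is invariant under rescaling of the measure, identically 0 for a constant
profile, and when the sites are genuinely random it is one more exchangeable
draw of the same statistic as the replicates, so its 95% interval covers 0
at very close to the nominal rate — a calibration property the acceptance
tests check at 200 scenario repetitions.

## Hotspot masks

The top-`q` mask (default `q = 0.10`) marks cells at or above the `1 − q`
quantile of the defined cell values.  Ties at the threshold are **all**
included — membership is deterministic and order-free, and may exceed
`q·N` under heavy ties; the count is reported rather than trimmed.
Jaccard indices between masks quantify the visual claim that richness and
PD hotspots coincide while MPD hotspots follow a different geography.

## Tree handling

Trees are rooted, with finite non-negative branch lengths on all non-root
edges; Newick explicitly tagged unrooted is rejected because every metric
here is root-dependent.  Parsing is delegated to dendropy; serialization
uses 10 significant digits and numeric comparisons use an absolute
tolerance of 1e-9.  Pruning to a taxon subset collapses degree-2 chains
with lengths summed but **retains the root** (the chain below it is summed
into a single root edge): this preserves both patristic distances and
root-to-tip depths, hence root-inclusive PD, under pruning.

The maximum-clade-credibility consensus scores every tree in a sample by
the sum of log clade frequencies over its internal clades (≥ 2 tips) and
returns the best-scoring sample tree (ties: lowest index).  Node heights —
measured as the maximum path length down to a tip — are then replaced by
the mean height of the matching clade across the sample trees containing
it (the clade-match convention, well defined for any sample).  Rather than
rebuilding lengths from heights directly (which silently distorts
non-ultrametric trees), each branch length is adjusted by the height
*shifts* of its two endpoint clades; on ultrametric samples this is
identical to the direct rebuild, and a sample of identical trees is
returned unchanged.  Incompatible means can still imply negative lengths;
these are clamped to 0, the same pathology the standard mean-heights
annotation tools exhibit.  No burn-in handling is provided: callers pass
the sample they want summarised.

## Synthetic scenarios

The generator emulates the structure of a regional range atlas plus dated
phylogeny, with every feature controllable:

* **Tree** — pure-birth (Yule) tree scaled to unit height, so branch
  lengths are in units of tree height.  Tip labels are attached in random
  order (labels carry no topological signal).
* **Ranges** — each species' breeding range grows from a seed cell by
  spreading-dye accretion (uniform choice among 4-neighbour frontier
  cells) to exactly `range_size` cells, giving contiguous, overlapping,
  irregular ranges.  Seed rows are drawn with probability ∝
  `exp(richness_gradient · row / (n_rows − 1))`, producing a smooth
  south-increasing richness gradient.  Wintering ranges are the breeding
  ranges translated `wintering_shift` rows southward and truncated at the
  boundary — a controlled, testable breeding/wintering contrast.
* **Red-list flags** — `⌈rl_fraction · S⌉` taxa, either a uniform random
  subset (the null-conforming case) or the tips of the smallest clade of
  at least that size, truncated (the clustered case the tip-shuffle null
  must detect).
* **Sites** — `n_sites` distinct cells placed uniformly at random, at the
  richest cells, or uniformly among cells holding at least one flagged
  taxon (`rl_cells`, mimicking threat-driven site designation; placement
  uses the breeding season, as real site designation is dominated by
  breeding evidence).

Defaults: 200 species, 60×60 grid (cell size 0.03°), range size 150 cells,
`richness_gradient = 4.0`, `wintering_shift = 8` rows, 5% flagged at
random, 40 `rl_cells` sites, giving minutes-scale full analyses.  The
gradient default was chosen so that the generator actually embodies the
design premise of threat-driven site placement — cells holding threatened
species lie disproportionately in species-rich terrain, strongly enough
that richness effectiveness of `rl_cells` sites is significantly positive
in nearly all scenario draws, while per-cell richness still spans roughly
an order of magnitude across the grid (a realistic contrast for a
semi-desert-to-mountain region).  `wintering_shift = 8` (~13% of the grid)
moves wintering communities visibly south without pushing most ranges off
the grid.

Scenario generation is a pure function of its config: one seeded generator
drives tree, ranges, flags, and sites in a fixed order, and regenerating
with the same config reproduces every output file byte for byte.

What the generator does **not** emulate: real biogeography (mountain
chains, biome mosaics), range-size heterogeneity across species, seasonal
range-shape change beyond translation, spatial autocorrelation between
related species, and observation error in range maps.  Passing tests
therefore demonstrate that the statistical machinery is correct and
calibrated under known conditions — not that any particular real region
behaves like the synthetic one.

## Pipeline and reproducibility

`run_analysis` drives everything from one JSON config (synthetic scenario
or on-disk Newick/CSV/text-raster inputs): validation first (unknown
metrics, seasons, or config keys fail before any computation; taxon sets
of tree, rasters, and table must reconcile exactly, with offenders listed),
then the tip-shuffle null, the 4 metrics × seasons × 2 modes effectiveness
grid (an undefined statistic — e.g. a site average of 0 — is recorded as an
explicit skip with its reason, never silently dropped), coverage summaries
(species, flagged species, and fraction of total branch length captured by
the site cells), and hotspot masks with Jaccard overlaps.  All randomness
descends from the single config seed via spawned generators; the report
embeds seeds, config echo, and input hashes, and rerunning a config is
byte-identical.  Replicate vectors are serialised in full (NaN as null) so
every summary in the report can be recomputed from the report alone.

## Numerical choices

* Quantiles: linear interpolation between order statistics, everywhere.
* Branch-length tolerance 1e-9 absolute; serialization 10 significant
  digits.
* Cell indexing row-major and 0-based; half-open cell intervals with y
  increasing downward, so boundary points belong to the cell below/right.
* Ties: hotspot thresholds include all tied cells; `top_richness` site
  placement breaks ties by lowest cell index; MCC ties by lowest sample
  index.
* Degenerate inputs are errors, not warnings: empty flagged sets, empty
  site unions, all-undefined site cells, `k` exceeding the cell count.

## Limitations

* The effectiveness null is spatially unstructured (uniform cell draws);
  contiguity- or distance-preserving randomisations are out of scope.
* MPD-based conclusions are sensitive to the undefined-cell rule on sparse
  grids; with very small communities the 'average' mode can rest on few
  defined cells (the report's replicate vectors expose how many).
* The MCC consensus assumes heights are comparable across trees, i.e. an
  ultrametric-ish sample; for wildly non-ultrametric samples the
  mean-height adjustment is only approximate (and clamped at 0).
* Analyses are presence/absence only; abundance-weighted metrics and
  standardised effect sizes (NRI/NTI) are deliberately not implemented.
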