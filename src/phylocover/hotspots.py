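"""Top-quantile hotspot masks of per-cell diversity profiles.

A hotspot mask marks the fraction ``q`` (default 10%) of grid cells with
the highest value of one diversity measure.  The threshold is the
``1 - q`` quantile of the *defined* cell values; ties at the threshold are
all included, so under heavy ties membership may exceed ``q*N`` — the
count is deterministic and order-free.  Cells with an undefined value
(mean pairwise distance with < 2 taxa) are excluded from both the
quantile and membership.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .diversity import DiversityProfile
from .grid import GridSpec, PresenceLayer, write_presence_raster
from .nulls import percentile_interval

__all__ = ["HotspotMask", "hotspot_mask", "mask_overlap", "write_mask_raster"]


@dataclass(frozen=True)
class HotspotMask:
    grid: GridSpec
    metric: str
    season: str
    q: float
    member: np.ndarray  # boolean per cell
    threshold: float

    @property
    def n_members(self) -> int:
        return int(self.member.sum())


def hotspot_mask(profile: DiversityProfile, q: float = 0.10) -> HotspotMask:
    """Mask of the top-``q`` fraction of cells by one profile."""
    if not 0 < q < 1:
        raise ValueError("q must lie strictly between 0 and 1")
    vals = profile.values
    defined = profile.defined()
    if not defined.any():
        raise ValueError("profile has no defined cells")
    # single quantile through the shared order-statistic interpolation
    threshold = percentile_interval(vals[defined], (1.0 - q, 1.0 - q))[0]
    member = np.zeros(len(vals), dtype=bool)
    member[defined] = vals[defined] >= threshold
    return HotspotMask(
        grid=profile.grid,
        metric=profile.metric,
        season=profile.season,
        q=q,
        member=member,
        threshold=float(threshold),
    )


def mask_overlap(a: HotspotMask, b: HotspotMask) -> float:
    """Jaccard index |a & b| / |a | b| of two masks on one grid (1.0 if both empty)."""
    if a.grid != b.grid:
        raise ValueError("masks are on different grids")
    inter = int((a.member & b.member).sum())
    union = int((a.member | b.member).sum())
    return 1.0 if union == 0 else inter / union


def write_mask_raster(mask: HotspotMask, path: str | Path) -> None:
    """Write the mask in the same 0/1 text-raster dialect as presence layers."""
    layer = PresenceLayer(
        taxon=f"hotspot_{mask.metric}",
        season=mask.season,
        cells=frozenset(int(c) for c in np.flatnonzero(mask.member)),
        grid=mask.grid,
    )
    write_presence_raster(layer, path)


def render_mask(mask: HotspotMask, path: str | Path) -> None:  # pragma: no cover
    """Optional PNG rendering for eyeballing (requires matplotlib)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    img = mask.member.reshape(mask.grid.n_rows, mask.grid.n_cols)
    fig, ax = plt.subplots(figsize=(4, 4))
    ax.imshow(img, cmap="Reds", interpolation="nearest")
    ax.set_title(f"{mask.metric} ({mask.season}), top {mask.q:.0%}")
    ax.set_xticks([])
    ax.set_yticks([])
    fig.savefig(path, dpi=120, bbox_inches="tight")
    plt.close(fig)
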