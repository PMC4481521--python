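"""Calling TFBS-clustered regions and partitioning them into HOT and LOT.

The procedure mirrors the standard high-occupancy-target workflow:

1. Pool binding sites of many transcription factors and smooth their
   midpoints with an unnormalised Gaussian kernel (sigma = 3 kb by default),
   so a single isolated site contributes a peak of height exactly 1.
2. Maximal runs of grid positions where the smoothed signal stays at or
   above a fraction (default 0.5) of that single-site height become
   TFBS-clustered regions.
3. Each region's TFBS complexity is the kernel sum evaluated at its density
   peak - a proximity-weighted count of contributing sites that equals the
   plain site count when all midpoints coincide and decreases as they
   disperse.
4. Regions are ranked by increasing complexity; with both axes scaled to
   [0, 1], the point where a slope-1 line is tangent to the rank-complexity
   curve separates LOT (below) from HOT (above).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

from .intervals import GenomeLayout, Interval, RegionSet

logger = logging.getLogger(__name__)

__all__ = [
    "TFBindingSite",
    "HotCallParams",
    "TFBSCluster",
    "HotLotPartition",
    "DensityProfile",
    "estimate_density",
    "call_clusters",
    "complexity_score",
    "split_hot_lot",
    "tangent_cutoff",
    "call_hot_regions",
]


@dataclass(frozen=True)
class TFBindingSite:
    """One binding site of one transcription factor."""

    tf_name: str
    interval: Interval

    @property
    def midpoint(self) -> int:
        return self.interval.midpoint


@dataclass(frozen=True)
class HotCallParams:
    """Tunables of the clustering step.

    bandwidth_sigma
        Gaussian kernel sigma in bp. The conventional "3 kb bandwidth" of
        binding-site smoothing is read as sigma, not FWHM.
    grid_step
        Density evaluation grid spacing in bp; must be << bandwidth.
    cluster_threshold_frac
        Fraction of a single site's peak height (1.0) at which the density
        is thresholded into clusters.
    min_sites
        Clusters with fewer contributing sites are dropped.
    """

    bandwidth_sigma: float = 3000.0
    grid_step: int = 50
    cluster_threshold_frac: float = 0.5
    min_sites: int = 1

    def __post_init__(self) -> None:
        if self.bandwidth_sigma <= 0:
            raise ValueError("bandwidth_sigma must be positive")
        if not (0 < self.cluster_threshold_frac <= 1):
            raise ValueError("cluster_threshold_frac must be in (0, 1]")
        if self.grid_step < 1:
            raise ValueError("grid_step must be >= 1")


@dataclass
class TFBSCluster:
    """A TFBS-clustered region with its contributing sites."""

    span: Interval
    sites: list[TFBindingSite]
    peak_pos: int
    complexity: float

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    @property
    def tf_names(self) -> set[str]:
        return {s.tf_name for s in self.sites}


@dataclass
class HotLotPartition:
    hot: RegionSet
    lot: RegionSet
    cutoff_rank_scaled: float
    cutoff_complexity: float
    hot_clusters: list[TFBSCluster] = field(default_factory=list)
    lot_clusters: list[TFBSCluster] = field(default_factory=list)


class DensityProfile:
    """Per-chromosome kernel density on a uniform grid.

    Grid point i on a chromosome sits at position ``i * grid_step``; the
    stored value is the unnormalised kernel sum there.
    """

    def __init__(self, grid_step: int, values: dict[str, np.ndarray]) -> None:
        self.grid_step = grid_step
        self.values = values

    def at(self, chrom: str, pos: float) -> float:
        """Density at an arbitrary position via the nearest grid point."""
        arr = self.values[chrom]
        i = int(round(pos / self.grid_step))
        return float(arr[min(max(i, 0), len(arr) - 1)])


def kernel_sum(pos: np.ndarray, midpoints: np.ndarray, sigma: float) -> np.ndarray:
    """Unnormalised Gaussian kernel sum: sum_i exp(-(x - m_i)^2 / (2 sigma^2))."""
    pos = np.atleast_1d(np.asarray(pos, dtype=float))
    d = pos[:, None] - np.asarray(midpoints, dtype=float)[None, :]
    return np.exp(-(d * d) / (2.0 * sigma * sigma)).sum(axis=1)


def estimate_density(
    sites: list[TFBindingSite],
    params: HotCallParams,
    genome: GenomeLayout,
) -> DensityProfile:
    """Smoothed binding-site midpoint density per chromosome.

    Each site adds a Gaussian bump of unit height at its midpoint; kernels
    are truncated at 6 sigma, where the contribution (< 2e-8) is far below
    any threshold in use.
    """
    if not sites:
        raise ValueError("estimate_density requires at least one site")
    lengths = genome.lengths
    for s in sites:
        if s.interval.chrom not in lengths:
            raise ValueError(f"site on unknown chromosome {s.interval.chrom!r}")

    step = params.grid_step
    sigma = params.bandwidth_sigma
    halfwin = int(math.ceil(6.0 * sigma / step))
    values: dict[str, np.ndarray] = {
        chrom: np.zeros(length // step + 1) for chrom, length in genome.chromosomes
    }
    by_chrom: dict[str, list[int]] = {}
    for s in sites:
        by_chrom.setdefault(s.interval.chrom, []).append(s.midpoint)
    for chrom, mids in by_chrom.items():
        arr = values[chrom]
        n = len(arr)
        for m in mids:
            c = int(round(m / step))
            lo, hi = max(0, c - halfwin), min(n, c + halfwin + 1)
            x = np.arange(lo, hi, dtype=float) * step
            arr[lo:hi] += np.exp(-((x - m) ** 2) / (2.0 * sigma * sigma))
    return DensityProfile(step, values)


def call_clusters(
    profile: DensityProfile,
    sites: list[TFBindingSite],
    params: HotCallParams,
) -> list[TFBSCluster]:
    """Threshold the density profile into maximal above-threshold runs.

    A cluster's sites are those whose midpoint falls inside the run extended
    by one grid step on each side; its complexity is the kernel sum at the
    density peak, recomputed exactly (off-grid) from the full site list.
    """
    step = profile.grid_step
    thr = params.cluster_threshold_frac
    site_lookup: dict[str, list[TFBindingSite]] = {}
    for s in sites:
        site_lookup.setdefault(s.interval.chrom, []).append(s)
    for chrom in site_lookup:
        site_lookup[chrom].sort(key=lambda s: s.midpoint)

    clusters: list[TFBSCluster] = []
    for chrom, arr in profile.values.items():
        above = arr >= thr
        if not above.any():
            continue
        # run boundaries
        edges = np.flatnonzero(np.diff(above.astype(np.int8)))
        run_starts = ([0] if above[0] else []) + list(edges[~above[edges]] + 1)
        run_ends = list(edges[above[edges]] + 1) + ([len(arr)] if above[-1] else [])
        chrom_sites = site_lookup.get(chrom, [])
        chrom_mids = np.array([s.midpoint for s in chrom_sites], dtype=np.int64)
        for lo, hi in zip(run_starts, run_ends):
            span_start = lo * step
            span_end = min((hi - 1) * step + step, len(arr) * step)
            if chrom_sites:
                sel = (chrom_mids >= span_start - step) & (chrom_mids < span_end + step)
                members = [s for s, keep in zip(chrom_sites, sel) if keep]
            else:
                members = []
            if len(members) < params.min_sites:
                continue
            seg = arr[lo:hi]
            peak_grid = lo + int(np.argmax(seg))
            peak_pos = peak_grid * step
            complexity = float(
                kernel_sum(
                    np.array([peak_pos], dtype=float),
                    np.array([s.midpoint for s in members], dtype=float),
                    params.bandwidth_sigma,
                )[0]
            )
            clusters.append(
                TFBSCluster(
                    span=Interval(chrom, int(span_start), int(span_end)),
                    sites=members,
                    peak_pos=int(peak_pos),
                    complexity=complexity,
                )
            )
    return clusters


def complexity_score(cluster: TFBSCluster, params: HotCallParams) -> float:
    """Kernel sum over the cluster's sites evaluated at its density peak."""
    if not cluster.sites:
        raise ValueError("cluster has no sites")
    mids = np.array([s.midpoint for s in cluster.sites], dtype=float)
    return float(kernel_sum(np.array([cluster.peak_pos], dtype=float), mids,
                            params.bandwidth_sigma)[0])


# ---------------------------------------------------------------------------
# HOT/LOT elbow

def tangent_cutoff(y_sorted: np.ndarray) -> float:
    """Scaled rank where a slope-1 line is tangent to the sorted-score curve.

    The scores, sorted ascending, are plotted against rank with both axes
    scaled to [0, 1]. For a curve with a convex high-score tail the point
    where a unit-slope line is tangent is exactly the point lying furthest
    below the diagonal, i.e. the minimiser of y(x) - x: to its left the
    curve rises slower than 1, to its right faster. That discrete
    formulation is used here because it is insensitive to the local
    plateaus that rank-ordered empirical scores always contain, where a
    finite-difference slope chatters around 1. Ties are resolved toward
    the largest x (fewer calls above the cutoff); a degenerate flat curve
    returns 1.0 (nothing above the cutoff).
    """
    n = len(y_sorted)
    if n < 3:
        raise ValueError("need at least 3 scores for the tangent cutoff")
    y = np.asarray(y_sorted, dtype=float)
    lo, hi = y[0], y[-1]
    if hi <= lo:
        return 1.0
    x = np.arange(n, dtype=float) / (n - 1)
    ys = (y - lo) / (hi - lo)
    ys = np.maximum.accumulate(ys)  # monotone guard (no-op for sorted input)

    gap = ys - x
    best = gap.min()
    # largest x attaining the minimum (within float tolerance) -> fewest HOT
    i = int(np.flatnonzero(gap <= best + 1e-12)[-1])
    return float(x[i])


def split_hot_lot(clusters: list[TFBSCluster]) -> HotLotPartition:
    """Partition clusters into HOT (above the tangent point) and LOT.

    Clusters whose scaled rank lies strictly above the cutoff become HOT;
    if every complexity is identical the curve carries no elbow and the HOT
    set is left empty with a logged warning.
    """
    if len(clusters) < 3:
        raise ValueError("split_hot_lot requires at least 3 clusters")
    order = sorted(range(len(clusters)), key=lambda i: clusters[i].complexity)
    comp = np.array([clusters[i].complexity for i in order], dtype=float)
    if comp[0] == comp[-1]:
        logger.warning("all TFBS complexities identical; HOT set left empty")
        cutoff_x, cutoff_c = 1.0, float(comp[-1])
        hot_idx: list[int] = []
        lot_idx = order
    else:
        cutoff_x = tangent_cutoff(comp)
        n = len(comp)
        x = np.arange(n, dtype=float) / (n - 1)
        above = x > cutoff_x
        hot_idx = [order[i] for i in np.flatnonzero(above)]
        lot_idx = [order[i] for i in np.flatnonzero(~above)]
        cutoff_c = float(comp[~above][-1]) if (~above).any() else float(comp[0])

    def _as_regionset(idx: list[int], label: str) -> RegionSet:
        return RegionSet(
            [clusters[i].span for i in idx],
            label=label,
            scores=[clusters[i].complexity for i in idx] or None,
        )

    return HotLotPartition(
        hot=_as_regionset(hot_idx, "HOT"),
        lot=_as_regionset(lot_idx, "LOT"),
        cutoff_rank_scaled=cutoff_x,
        cutoff_complexity=cutoff_c,
        hot_clusters=[clusters[i] for i in hot_idx],
        lot_clusters=[clusters[i] for i in lot_idx],
    )


def call_hot_regions(
    sites: list[TFBindingSite],
    genome: GenomeLayout,
    params: HotCallParams | None = None,
) -> tuple[list[TFBSCluster], HotLotPartition]:
    """End-to-end: density -> clusters -> HOT/LOT partition."""
    params = params or HotCallParams()
    profile = estimate_density(sites, params, genome)
    clusters = call_clusters(profile, sites, params)
    return clusters, split_hot_lot(clusters)
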