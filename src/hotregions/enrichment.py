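"""Significance machinery for variant-in-region enrichment.

Implements the chromosome-preserving shift-permutation null, one-sided
binomial stage enrichment, the HOT-vs-LOT disproportion chi-square,
Pearson density correlations, interval-level binomial enrichment, and
gene-set chi-square enrichment with nearest-TSS region-to-gene assignment.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .intervals import GenomeLayout, RegionSet
from .variant_mapping import SNP

__all__ = [
    "PermutationParams",
    "PermutationResult",
    "StageEnrichment",
    "shift_permutation_test",
    "stage_enrichment",
    "hot_lot_disproportion",
    "density_correlation",
    "interval_binomial_enrichment",
    "assign_regions_to_genes",
    "geneset_region_enrichment",
]

ShiftMode = Literal["independent", "rigid"]


@dataclass(frozen=True)
class PermutationParams:
    """Shift-permutation settings.

    ``shift_mode='independent'`` relocates every region to a uniform random
    start on its own chromosome each iteration; ``'rigid'`` applies one
    common offset per chromosome per iteration (regions keep their spacing).
    """

    n_iterations: int = 10_000
    seed: int = 0
    shift_mode: ShiftMode = "independent"

    def __post_init__(self) -> None:
        if self.n_iterations < 1:
            raise ValueError("n_iterations must be >= 1")


@dataclass
class PermutationResult:
    observed: int
    null_counts: np.ndarray
    p_value: float

    @property
    def n_iterations(self) -> int:
        return len(self.null_counts)


def _count_unique_covered(
    lo: np.ndarray, hi: np.ndarray
) -> np.ndarray:
    """Per-row count of SNP indices covered by a union of index ranges.

    ``lo``/``hi`` have shape (n_iter, n_regions): half-open index ranges
    into a sorted SNP-position array. Rows are unioned by sorting ranges by
    start and accumulating a running maximum of ends.
    """
    order = np.argsort(lo, axis=1, kind="stable")
    lo_s = np.take_along_axis(lo, order, axis=1)
    hi_s = np.take_along_axis(hi, order, axis=1)
    run_max = np.maximum.accumulate(hi_s, axis=1)
    prev_max = np.concatenate(
        [np.zeros((lo.shape[0], 1), dtype=hi_s.dtype), run_max[:, :-1]], axis=1
    )
    contrib = np.clip(hi_s - np.maximum(lo_s, prev_max), 0, None)
    return contrib.sum(axis=1)


def shift_permutation_test(
    snps: Sequence[SNP],
    regions: RegionSet,
    genome: GenomeLayout,
    params: PermutationParams | None = None,
) -> PermutationResult:
    """Empirical null by relocating regions on their chromosome of origin.

    Each iteration re-places the regions (lengths and chromosomes
    preserved), counts SNPs falling in the union of the relocated regions
    (a SNP covered by several regions counts once), and the p-value is the
    add-one empirical estimator (1 + #{null >= observed}) / (n + 1) - never
    exactly zero, so "no exceedance in 10,000 iterations" reports
    1/10,001 < 1e-4.
    """
    params = params or PermutationParams()
    rng = np.random.default_rng(params.seed)
    n_iter = params.n_iterations

    snp_pos: dict[str, np.ndarray] = {}
    for chrom in {s.chrom for s in snps}:
        snp_pos[chrom] = np.sort(
            np.array([s.pos for s in snps if s.chrom == chrom], dtype=np.int64)
        )

    observed = 0
    null = np.zeros(n_iter, dtype=np.int64)
    for chrom in regions.chroms:
        starts, ends = regions.per_chrom(chrom)
        chrom_len = genome.length_of(chrom)
        lengths = ends - starts
        if (lengths > chrom_len).any():
            raise ValueError(f"region longer than chromosome {chrom}")
        pos = snp_pos.get(chrom)
        if pos is None or len(pos) == 0:
            continue
        obs_lo = np.searchsorted(pos, starts)
        obs_hi = np.searchsorted(pos, ends)
        observed += int(
            _count_unique_covered(obs_lo[None, :], obs_hi[None, :])[0]
        )
        max_start = chrom_len - lengths  # inclusive upper bound for each start
        if params.shift_mode == "independent":
            new_starts = rng.integers(
                0, max_start[None, :] + 1, size=(n_iter, len(lengths))
            )
        else:  # rigid: one offset per chromosome, all regions stay in bounds
            lo_off = -int(starts.min())
            hi_off = int(chrom_len - ends.max())
            offsets = rng.integers(lo_off, hi_off + 1, size=n_iter)
            new_starts = starts[None, :] + offsets[:, None]
        new_ends = new_starts + lengths[None, :]
        lo = np.searchsorted(pos, new_starts)
        hi = np.searchsorted(pos, new_ends)
        null += _count_unique_covered(lo, hi)

    p = (1 + int((null >= observed).sum())) / (n_iter + 1)
    return PermutationResult(observed=observed, null_counts=null, p_value=p)


# ---------------------------------------------------------------------------
# Binomial stage enrichment

@dataclass
class StageEnrichment:
    """Enrichment of a trait's SNPs in one developmental stage's regions.

    x of the trait's n region-mapped SNPs fall in this stage's regions; p is
    the catalog-wide baseline proportion for the stage. The signed
    percentage is ((x/n)/p - 1) * 100 and the binomial p-value is the
    one-sided tail in the direction of the deviation.
    """

    x: int
    n: int
    p: float
    enrichment_pct: float
    binom_p: float


def stage_enrichment(x: int, n: int, p: float, two_sided: bool = False) -> StageEnrichment:
    if n < 1:
        raise ValueError("n must be >= 1")
    if not (0 < p < 1):
        raise ValueError("baseline proportion p must lie strictly in (0, 1)")
    if not (0 <= x <= n):
        raise ValueError("need 0 <= x <= n")
    frac = x / n
    enrichment_pct = (frac / p - 1.0) * 100.0
    if frac >= p:
        tail = float(stats.binom.sf(x - 1, n, p))  # P(X >= x)
    else:
        tail = float(stats.binom.cdf(x, n, p))  # P(X <= x)
    if two_sided:
        tail = min(1.0, 2.0 * tail)
    return StageEnrichment(x=x, n=n, p=p, enrichment_pct=enrichment_pct, binom_p=tail)


# ---------------------------------------------------------------------------
# HOT vs LOT disproportion

def hot_lot_disproportion(
    snp_hot: int, snp_lot: int, bp_hot: int, bp_lot: int
) -> tuple[float, float]:
    """Goodness-of-fit chi-square (1 df): are SNP counts proportional to
    region lengths? Expected counts split the total by base-pair share."""
    total = snp_hot + snp_lot
    if total < 1:
        raise ValueError("need at least one SNP")
    if bp_hot <= 0 or bp_lot <= 0:
        raise ValueError("region lengths must be positive")
    exp_hot = total * bp_hot / (bp_hot + bp_lot)
    exp_lot = total - exp_hot
    if exp_hot == 0 or exp_lot == 0:
        raise ValueError("zero expected count")
    chi2 = (snp_hot - exp_hot) ** 2 / exp_hot + (snp_lot - exp_lot) ** 2 / exp_lot
    p = float(stats.chi2.sf(chi2, df=1))
    return float(chi2), p


def snp_contingency_chi2(
    in_hot: int, in_lot: int, out_hot: int, out_lot: int
) -> tuple[float, float]:
    """Alternative 2x2 contingency formulation (no continuity correction)."""
    table = np.array([[in_hot, in_lot], [out_hot, out_lot]], dtype=float)
    chi2, p, _, _ = stats.chi2_contingency(table, correction=False)
    return float(chi2), float(p)


def density_correlation(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Pearson R between two density vectors with its two-sided t-test p."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 3 or len(x) != len(y):
        raise ValueError("need equal-length vectors with n >= 3")
    if np.var(x) == 0 or np.var(y) == 0:
        raise ValueError("zero variance: correlation undefined")
    r = stats.pearsonr(x, y)
    return float(r.statistic), float(r.pvalue)


def interval_binomial_enrichment(
    regions: RegionSet, targets: RegionSet, genome: GenomeLayout
) -> tuple[int, int, float, float]:
    """Binomial test that regions concentrate inside target territory.

    Of m regions, k have their midpoint inside ``targets``; under the null
    each midpoint lands in targets with probability q = the targets'
    genome fraction. Returns (k, m, q, P(Binomial(m, q) >= k)).
    """
    m = len(regions)
    q = targets.genome_fraction(genome)
    k = sum(
        1 for iv in regions.intervals() if targets.contains(iv.chrom, iv.midpoint)
    )
    p = float(stats.binom.sf(k - 1, m, q)) if m > 0 else 1.0
    return k, m, q, p


# ---------------------------------------------------------------------------
# Region -> gene assignment and gene-set enrichment

def assign_regions_to_genes(regions: RegionSet, tss_table: pd.DataFrame) -> dict[str, str]:
    """Assign each region to the gene whose TSS is nearest its midpoint.

    Ties go to the lexicographically smallest gene id. Returns a map from
    "chrom:start-end" region keys to gene ids. Regions on chromosomes with
    no TSS are left unassigned.
    """
    if tss_table.empty:
        raise ValueError("TSS table is empty")
    out: dict[str, str] = {}
    by_chrom = {
        chrom: grp.sort_values(["tss", "gene_id"]).reset_index(drop=True)
        for chrom, grp in tss_table.groupby("chrom")
    }
    for iv in regions.intervals():
        grp = by_chrom.get(iv.chrom)
        if grp is None:
            continue
        mid = iv.midpoint
        dist = (grp["tss"] - mid).abs()
        best = dist.min()
        winners = sorted(grp.loc[dist == best, "gene_id"])
        out[f"{iv.chrom}:{iv.start}-{iv.end}"] = winners[0]
    return out


def geneset_region_enrichment(
    geneset: set[str], hot_genes: set[str], lot_genes: set[str]
) -> tuple[float, float]:
    """2x2 chi-square: gene-set membership vs HOT/LOT association.

    Table rows are (in set, out of set), columns (HOT, LOT); 1 df, no
    continuity correction. Raises when an expected cell is zero (an exact
    test would be required there).
    """
    a = len(hot_genes & geneset)
    b = len(lot_genes & geneset)
    c = len(hot_genes - geneset)
    d = len(lot_genes - geneset)
    return chi2_2x2(a, b, c, d)


def chi2_2x2(a: int, b: int, c: int, d: int) -> tuple[float, float]:
    """Pearson chi-square for the table ((a, b), (c, d)), no correction."""
    table = np.array([[a, b], [c, d]], dtype=float)
    exp = np.outer(table.sum(axis=1), table.sum(axis=0)) / table.sum()
    if (exp == 0).any():
        raise ValueError("zero expected cell; use an exact test")
    chi2, p, _, _ = stats.chi2_contingency(table, correction=False)
    return float(chi2), float(p)
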