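"""Catalog curation, coding/noncoding classification, region membership,
SNP densities, and linkage-disequilibrium expansion.

Association rows are curated the way reproducibility-minded GWAS summaries
are: a variant must carry a dbSNP-style identifier and be linked to its
trait by at least two independent studies. Curated SNPs are classified as
coding or noncoding against a CDS union, mapped into region sets, and -
for SNPs outside the regions of interest - expanded through LD: a SNP
counts as "LD-flagged" when some panel SNP inside a region, within a fixed
radius of it, shows r-squared above a strong-LD threshold (0.8 by default,
strict inequality).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Literal, Optional, Sequence

import numpy as np
import pandas as pd

from .intervals import RegionSet
from .io import GWASCatalogRow, HaplotypeMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "SNP",
    "TraitAssociation",
    "LDParams",
    "LDPair",
    "filter_catalog",
    "classify_coding",
    "map_snps",
    "snp_density",
    "ld_r2",
    "ld_expand",
]

CodingFlag = Literal["coding", "noncoding", "unknown"]


@dataclass(frozen=True)
class SNP:
    """A curated variant. ``pos`` is 0-based (internal convention)."""

    snp_id: str
    chrom: str
    pos: int
    coding_flag: CodingFlag = "unknown"


@dataclass
class TraitAssociation:
    """A SNP-trait link supported by >= 2 independent studies."""

    snp: SNP
    trait: str
    supporting_studies: frozenset[str]


@dataclass(frozen=True)
class LDParams:
    r2_threshold: float = 0.8
    radius: int = 125_000

    def __post_init__(self) -> None:
        if not (0 < self.r2_threshold <= 1):
            raise ValueError("r2_threshold must be in (0, 1]")
        if self.radius <= 0:
            raise ValueError("radius must be positive")


@dataclass(frozen=True)
class LDPair:
    snp_a: str
    snp_b: str
    p_a: float
    p_b: float
    D: float
    r2: float


class MonomorphicError(ValueError):
    """r-squared is undefined for a monomorphic locus."""


def filter_catalog(rows: Iterable[GWASCatalogRow]) -> list[TraitAssociation]:
    """Keep (SNP, trait) pairs with an identifier and >= 2 distinct studies.

    Catalog positions (1-based) are converted to the internal 0-based
    convention here.
    """
    groups: dict[tuple[str, str], dict] = {}
    for r in rows:
        if not r.snp_id:
            continue
        key = (r.snp_id, r.trait)
        g = groups.setdefault(key, {"chrom": r.chrom, "pos": r.pos, "studies": set()})
        g["studies"].add(r.study_id)
    out = []
    for (snp_id, trait), g in groups.items():
        if len(g["studies"]) < 2:
            continue
        out.append(
            TraitAssociation(
                snp=SNP(snp_id=snp_id, chrom=g["chrom"], pos=g["pos"] - 1),
                trait=trait,
                supporting_studies=frozenset(g["studies"]),
            )
        )
    out.sort(key=lambda a: (a.snp.snp_id, a.trait))
    return out


def classify_coding(snp: SNP, cds: RegionSet) -> SNP:
    """Return the SNP with its coding flag set from CDS membership."""
    flag: CodingFlag = "coding" if cds.contains(snp.chrom, snp.pos) else "noncoding"
    return SNP(snp.snp_id, snp.chrom, snp.pos, flag)


def map_snps(
    snps: Sequence[SNP], regions: RegionSet
) -> tuple[dict[str, bool], int]:
    """Membership of each SNP in a region set.

    Returns (snp_id -> inside?, number of unique SNPs inside). A SNP covered
    by several merged intervals is counted once; duplicate ids are collapsed.
    """
    membership: dict[str, bool] = {}
    for s in snps:
        inside = regions.contains(s.chrom, s.pos)
        membership[s.snp_id] = membership.get(s.snp_id, False) or inside
    return membership, sum(membership.values())


def snp_density(n_snps_in: int, regions: RegionSet) -> float:
    """SNPs per megabase: count / total region length x 1e6."""
    bp = regions.total_length
    if bp == 0:
        raise ValueError("cannot compute SNP density over a zero-length region set")
    return n_snps_in / bp * 1e6


def ld_r2(col_a: np.ndarray, col_b: np.ndarray,
          snp_a: str = "a", snp_b: str = "b") -> LDPair:
    """Haplotype-based r-squared between two biallelic loci.

    With allele-1 frequencies p_a, p_b and joint (1,1) haplotype frequency
    p_ab, D = p_ab - p_a * p_b and r2 = D^2 / (p_a (1-p_a) p_b (1-p_b)).
    Phased haplotypes make this a direct count - no EM step is needed.
    """
    a = np.asarray(col_a, dtype=float)
    b = np.asarray(col_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or len(a) < 2:
        raise ValueError("need two equal-length haplotype vectors of length >= 2")
    p_a = float(a.mean())
    p_b = float(b.mean())
    if p_a in (0.0, 1.0) or p_b in (0.0, 1.0):
        raise MonomorphicError("r2 undefined: monomorphic column")
    p_ab = float((a * b).mean())
    D = p_ab - p_a * p_b
    r2 = D * D / (p_a * (1 - p_a) * p_b * (1 - p_b))
    return LDPair(snp_a, snp_b, p_a, p_b, D, r2)


@dataclass
class LDExpansionResult:
    """Outcome of LD expansion for one catalog SNP."""

    snp_id: str
    in_region: bool
    ld_flagged: bool
    best_r2: float = float("nan")
    witness_snp: Optional[str] = None


def ld_expand(
    catalog_snps: Sequence[SNP],
    panel: HaplotypeMatrix,
    regions: RegionSet,
    params: LDParams | None = None,
) -> tuple[dict[str, LDExpansionResult], int]:
    """Flag catalog SNPs in strong LD with a panel SNP inside a region.

    For each catalog SNP *outside* ``regions``, panel SNPs that (a) lie
    inside a region and (b) sit within ``params.radius`` bp of the catalog
    SNP are examined; the SNP is flagged when any such pair exceeds the
    r2 threshold (strict). Catalog SNPs absent from the panel cannot be
    evaluated and are counted in the returned skip count, not imputed.
    """
    params = params or LDParams()
    panel_pos0 = panel.positions - 1  # panel positions are 1-based
    panel_in_region = np.zeros(panel.n_snps, dtype=bool)
    for chrom in set(panel.chroms):
        sel = panel.chroms == chrom
        panel_in_region[sel] = regions.contains_positions(chrom, panel_pos0[sel])

    results: dict[str, LDExpansionResult] = {}
    n_skipped = 0
    for s in catalog_snps:
        inside = regions.contains(s.chrom, s.pos)
        if inside:
            results[s.snp_id] = LDExpansionResult(s.snp_id, True, False)
            continue
        j = panel.index_of(s.snp_id)
        if j is None:
            n_skipped += 1
            results[s.snp_id] = LDExpansionResult(s.snp_id, False, False)
            continue
        near = (
            (panel.chroms == s.chrom)
            & (np.abs(panel_pos0 - s.pos) <= params.radius)
            & panel_in_region
        )
        near[j] = False
        best_r2, witness = float("nan"), None
        col_a = panel.alleles[:, j]
        if col_a.min() == col_a.max():
            candidates: list[int] = []
        else:
            candidates = list(np.flatnonzero(near))
        for k in candidates:
            col_b = panel.alleles[:, k]
            if col_b.min() == col_b.max():
                continue
            pair = ld_r2(col_a, col_b, s.snp_id, panel.snp_ids[k])
            if not (best_r2 == best_r2) or pair.r2 > best_r2:  # NaN-safe
                best_r2, witness = pair.r2, panel.snp_ids[k]
        flagged = best_r2 == best_r2 and best_r2 > params.r2_threshold
        results[s.snp_id] = LDExpansionResult(s.snp_id, False, bool(flagged), best_r2, witness)
    if n_skipped:
        logger.info("%d catalog SNPs absent from the haplotype panel; not LD-flagged", n_skipped)
    return results, n_skipped


def mapping_table(
    associations: Sequence[TraitAssociation],
    snps_classified: dict[str, SNP],
    expansion: dict[str, LDExpansionResult],
) -> pd.DataFrame:
    """Per-association summary table: snp_id, trait, coding_flag,
    in_region, ld_flagged, best_r2, witness_snp."""
    rows = []
    for a in associations:
        s = snps_classified.get(a.snp.snp_id, a.snp)
        r = expansion.get(a.snp.snp_id)
        rows.append(
            (
                a.snp.snp_id,
                a.trait,
                s.coding_flag,
                r.in_region if r else None,
                r.ld_flagged if r else None,
                r.best_r2 if r else float("nan"),
                r.witness_snp if r else None,
            )
        )
    return pd.DataFrame(
        rows,
        columns=["snp_id", "trait", "coding_flag", "in_region",
                 "ld_flagged", "best_r2", "witness_snp"],
    )
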