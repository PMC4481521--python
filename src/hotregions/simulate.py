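"""Synthetic study generator: toy genomes with planted multi-TF hotspots,
lineage-structured hotspot sets, SNP catalogs with a planted fold
enrichment inside HOT territory, block-structured haplotype panels, and a
toy coding annotation.

Every generator is a pure function of its config (seed included):
re-running with the same config reproduces the outputs exactly. The
returned :class:`GroundTruth` carries the planted labels needed to score
every downstream module without re-deriving them.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .intervals import GenomeLayout, Interval, RegionSet
from .io import GWASCatalogRow, HaplotypeMatrix
from .lineage import LineageTree
from .hot_calling import TFBindingSite
from .variant_mapping import SNP

__all__ = [
    "SimConfig",
    "GroundTruth",
    "make_genome",
    "simulate_peaks",
    "simulate_lineage_peaks",
    "simulate_snp_catalog",
    "simulate_haplotypes",
    "simulate_cds",
    "default_lineage",
]


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for the synthetic pipeline.

    Scale defaults are desk-sized analogues of a multi-cell-type binding
    compendium: a 30 Mb genome (3 x 10 Mb), 20 TFs, and 60 planted hotspot
    loci at which 10-20 distinct TFs each place one site. Background
    binding is sparse (1e-6 sites/bp/TF ~ 10 background sites per TF per
    chromosome) so planted hotspots dominate the kernel density while
    background still produces low-complexity clusters for the elbow to
    separate.
    """

    seed: int = 0
    n_chroms: int = 3
    chrom_length: int = 10_000_000
    n_tfs: int = 20
    n_hotspots: int = 60
    hotspot_tf_min: int = 10
    hotspot_tf_max: int = 20
    background_rate: float = 1e-6  # sites per bp per TF
    site_jitter_sd: float = 500.0  # bp, site midpoint scatter around its locus
    site_halfwidth: int = 75  # bp, emitted site intervals are midpoint +/- this
    enrichment_fold: float = 5.0
    n_snps: int = 2000
    n_haplotypes: int = 100
    ld_block_length: int = 20_000
    panel_snp_spacing: int = 5_000
    flip_prob: float = 0.02
    hot_halfwidth: int = 2_000  # bp, planted ground-truth HOT span = locus +/- this
    lineage_retention: float = 0.7  # per-transition hotspot retention prob
    lineage_gain: int = 20  # new hotspot loci gained per transition
    cds_block: int = 1_000  # bp of coding sequence ...
    cds_every: int = 200_000  # ... at the start of every 200 kb tile

    def __post_init__(self) -> None:
        if self.enrichment_fold < 0:
            raise ValueError("enrichment_fold must be >= 0")
        if self.hotspot_tf_max > self.n_tfs:
            raise ValueError("hotspot_tf_max cannot exceed n_tfs")
        if not (0 <= self.lineage_retention <= 1):
            raise ValueError("lineage_retention must be in [0, 1]")


@dataclass
class GroundTruth:
    """Planted labels sufficient to score every downstream module."""

    hotspot_loci: dict[str, list[tuple[str, int]]] = field(default_factory=dict)
    #: per-stage planted HOT spans (locus +/- hot_halfwidth, merged)
    stage_regions: dict[str, RegionSet] = field(default_factory=dict)
    #: snp_id -> planted in-HOT flag (catalog generator)
    snp_in_hot: dict[str, bool] = field(default_factory=dict)
    #: snp_id -> stage -> planted presence (lineage study)
    snp_presence: dict[str, dict[str, bool]] = field(default_factory=dict)
    #: snp_id -> LD block key "chrom:block_index" (haplotype generator)
    snp_block: dict[str, str] = field(default_factory=dict)


def make_genome(config: SimConfig) -> GenomeLayout:
    return GenomeLayout(
        tuple((f"chr{i + 1}", config.chrom_length) for i in range(config.n_chroms))
    )


def default_lineage() -> LineageTree:
    """The four-stage haematopoietic toy lineage: ESC -> Hemat -> {B, T}."""
    return LineageTree({"ESC": None, "Hemat": "ESC", "B": "Hemat", "T": "Hemat"})


# ---------------------------------------------------------------------------
# Peaks

def _draw_loci(
    rng: np.random.Generator, genome: GenomeLayout, n: int, margin: int
) -> list[tuple[str, int]]:
    """n hotspot loci placed uniformly, away from chromosome ends."""
    chroms = genome.names
    picks = rng.integers(0, len(chroms), size=n)
    loci = []
    for i in range(n):
        chrom = chroms[picks[i]]
        length = genome.length_of(chrom)
        if length <= 2 * margin:
            raise ValueError("chromosome too short for requested hotspot margin")
        loci.append((chrom, int(rng.integers(margin, length - margin))))
    return loci


def _sites_for_stage(
    rng: np.random.Generator,
    config: SimConfig,
    genome: GenomeLayout,
    loci: Sequence[tuple[str, int]],
) -> dict[str, list[TFBindingSite]]:
    """Hotspot + background sites for one stage, keyed by TF name."""
    tf_names = [f"TF{i + 1:02d}" for i in range(config.n_tfs)]
    sites: dict[str, list[TFBindingSite]] = {tf: [] for tf in tf_names}
    hw = config.site_halfwidth
    for chrom, locus in loci:
        k = int(rng.integers(config.hotspot_tf_min, config.hotspot_tf_max + 1))
        chosen = rng.choice(config.n_tfs, size=k, replace=False)
        jitter = rng.normal(0.0, config.site_jitter_sd, size=k)
        length = genome.length_of(chrom)
        for tf_idx, dj in zip(chosen, jitter):
            mid = int(np.clip(round(locus + dj), hw, length - hw - 1))
            sites[tf_names[tf_idx]].append(
                TFBindingSite(tf_names[tf_idx], Interval(chrom, mid - hw, mid + hw))
            )
    # background: Poisson(rate x genome length) uniform sites per TF
    for tf in tf_names:
        n_bg = int(rng.poisson(config.background_rate * genome.total_size))
        for _ in range(n_bg):
            chrom = genome.names[int(rng.integers(0, config.n_chroms))]
            length = genome.length_of(chrom)
            mid = int(rng.integers(hw, length - hw))
            sites[tf].append(TFBindingSite(tf, Interval(chrom, mid - hw, mid + hw)))
    for tf in tf_names:
        sites[tf].sort(key=lambda s: (s.interval.chrom, s.interval.start))
    return sites


def _loci_regions(
    loci: Sequence[tuple[str, int]], genome: GenomeLayout, halfwidth: int, label: str
) -> RegionSet:
    ivs = []
    for chrom, locus in loci:
        length = genome.length_of(chrom)
        ivs.append(
            Interval(chrom, max(0, locus - halfwidth), min(length, locus + halfwidth))
        )
    return RegionSet(ivs, label=label)


def simulate_peaks(
    config: SimConfig,
) -> tuple[dict[str, list[TFBindingSite]], GroundTruth]:
    """Single-stage multi-TF peak sets with planted hotspot loci.

    At each hotspot locus a uniform 10-20 (configurable) distinct TFs place
    one site whose midpoint is the locus plus Normal(0, site_jitter_sd)
    noise; background sites per TF follow a Poisson(rate x genome size)
    count with uniform positions.
    """
    if config.n_hotspots * 4 * config.hot_halfwidth > make_genome(config).total_size:
        raise ValueError("hotspot count infeasible for genome size")
    rng = np.random.default_rng(config.seed)
    genome = make_genome(config)
    loci = _draw_loci(rng, genome, config.n_hotspots, margin=config.hot_halfwidth * 2)
    sites = _sites_for_stage(rng, config, genome, loci)
    gt = GroundTruth(
        hotspot_loci={"stage0": loci},
        stage_regions={
            "stage0": _loci_regions(loci, genome, config.hot_halfwidth, "HOT-truth")
        },
    )
    return sites, gt


def simulate_lineage_peaks(
    config: SimConfig, tree: Optional[LineageTree] = None
) -> tuple[dict[str, dict[str, list[TFBindingSite]]], GroundTruth]:
    """Per-stage peak sets along a lineage with inherited/gained hotspots.

    The root stage gets ``n_hotspots`` loci; each child keeps each parental
    locus with probability ``lineage_retention`` and gains ``lineage_gain``
    fresh loci of its own.
    """
    tree = tree or default_lineage()
    rng = np.random.default_rng(config.seed)
    genome = make_genome(config)
    margin = config.hot_halfwidth * 2

    stage_loci: dict[str, list[tuple[str, int]]] = {}
    order = [tree.root] + [c for _, c in _bfs_edges(tree)]
    for stage in order:
        parent = tree.parent[stage]
        if parent is None:
            stage_loci[stage] = _draw_loci(rng, genome, config.n_hotspots, margin)
        else:
            keep_mask = rng.random(len(stage_loci[parent])) < config.lineage_retention
            kept = [l for l, k in zip(stage_loci[parent], keep_mask) if k]
            gained = _draw_loci(rng, genome, config.lineage_gain, margin)
            stage_loci[stage] = kept + gained

    stage_sites = {
        stage: _sites_for_stage(rng, config, genome, loci)
        for stage, loci in stage_loci.items()
    }
    gt = GroundTruth(
        hotspot_loci=stage_loci,
        stage_regions={
            stage: _loci_regions(loci, genome, config.hot_halfwidth, f"HOT-{stage}")
            for stage, loci in stage_loci.items()
        },
    )
    return stage_sites, gt


def _bfs_edges(tree: LineageTree) -> list[tuple[str, str]]:
    edges = []
    frontier = [tree.root]
    while frontier:
        nxt = []
        for p in frontier:
            for c in tree.children(p):
                edges.append((p, c))
                nxt.append(c)
        frontier = nxt
    return edges


# ---------------------------------------------------------------------------
# SNP catalog

def _sample_positions_in(
    rng: np.random.Generator, regions: RegionSet, n: int
) -> list[tuple[str, int]]:
    """n positions uniform over the bases covered by a region set."""
    ivs = list(regions.intervals())
    if not ivs:
        raise ValueError("cannot sample from an empty region set")
    lengths = np.array([len(iv) for iv in ivs], dtype=float)
    picks = rng.choice(len(ivs), size=n, p=lengths / lengths.sum())
    out = []
    for i in picks:
        iv = ivs[int(i)]
        out.append((iv.chrom, int(rng.integers(iv.start, iv.end))))
    return out


def simulate_snp_catalog(
    config: SimConfig,
    hot: RegionSet,
    genome: Optional[GenomeLayout] = None,
    trait_folds: Optional[dict[str, float]] = None,
    rng: Optional[np.random.Generator] = None,
) -> tuple[list[GWASCatalogRow], list[SNP], GroundTruth]:
    """Association catalog with a planted fold enrichment inside HOT.

    SNP positions follow a two-component mixture with per-bp density f x
    lambda inside HOT and lambda outside, so the expected in-HOT fraction
    is f L_H / (f L_H + L_rest). Each SNP is emitted with two supporting
    studies so it survives catalog curation. ``trait_folds`` maps trait
    name -> fold; by default a single trait uses ``config.enrichment_fold``.
    Returns catalog rows (1-based positions), the curated-style SNP list
    (0-based), and ground truth flags.
    """
    genome = genome or make_genome(config)
    rng = rng if rng is not None else np.random.default_rng(config.seed + 1)
    folds = trait_folds or {"trait1": config.enrichment_fold}
    if hot.total_length == 0 and any(f != 1.0 for f in folds.values()):
        raise ValueError("hot set must be non-empty when a fold differs from 1")
    outside = hot.complement(genome)
    l_hot, l_rest = hot.total_length, outside.total_length

    rows: list[GWASCatalogRow] = []
    snps: list[SNP] = []
    gt = GroundTruth()
    per_trait = max(1, config.n_snps // len(folds))
    idx = 0
    for trait, f in folds.items():
        p_in = (f * l_hot) / (f * l_hot + l_rest) if l_hot else 0.0
        inside_flags = rng.random(per_trait) < p_in
        n_in = int(inside_flags.sum())
        pos_in = _sample_positions_in(rng, hot, n_in) if n_in else []
        pos_out = _sample_positions_in(rng, outside, per_trait - n_in)
        it_in, it_out = iter(pos_in), iter(pos_out)
        for flag in inside_flags:
            chrom, pos0 = next(it_in) if flag else next(it_out)
            idx += 1
            snp_id = f"rs{idx:06d}"
            for study in (f"S{2 * idx - 1}", f"S{2 * idx}"):
                rows.append(GWASCatalogRow(snp_id, chrom, pos0 + 1, trait, study))
            snps.append(SNP(snp_id, chrom, pos0))
            gt.snp_in_hot[snp_id] = bool(flag)
    return rows, snps, gt


# ---------------------------------------------------------------------------
# Haplotypes

def simulate_haplotypes(
    config: SimConfig,
    genome: Optional[GenomeLayout] = None,
    extra_positions: Optional[Sequence[tuple[str, int, str]]] = None,
    rng: Optional[np.random.Generator] = None,
) -> tuple[HaplotypeMatrix, GroundTruth]:
    """Block-structured phased panel: high r-squared within LD blocks.

    The genome is tiled into blocks of ``ld_block_length``; each block has
    two founder haplotypes and every sampled haplotype copies one of them
    (chosen independently per block) with per-SNP flip probability
    ``flip_prob``. Within a block any two loci whose founders differ are in
    near-perfect LD; across blocks founder assignments are independent so
    r-squared is near zero.

    ``extra_positions`` lets callers inject catalog SNPs into the panel as
    (chrom, 0-based pos, snp_id) records so they can be LD-expanded.
    """
    if config.n_haplotypes < 4:
        raise ValueError("need at least 4 haplotypes")
    genome = genome or make_genome(config)
    rng = rng if rng is not None else np.random.default_rng(config.seed + 2)

    chroms: list[str] = []
    positions: list[int] = []  # 0-based here; emitted 1-based
    ids: list[str] = []
    for chrom, length in genome.chromosomes:
        for j, pos in enumerate(range(config.panel_snp_spacing // 2, length,
                                      config.panel_snp_spacing)):
            chroms.append(chrom)
            positions.append(pos)
            ids.append(f"pv_{chrom}_{j:05d}")
    if extra_positions:
        for chrom, pos, snp_id in extra_positions:
            chroms.append(chrom)
            positions.append(pos)
            ids.append(snp_id)
    order = np.lexsort((np.array(positions), np.array(chroms, dtype=object)))
    chroms_a = np.array(chroms, dtype=object)[order]
    pos_a = np.array(positions, dtype=np.int64)[order]
    ids_a = [ids[i] for i in order]

    n_snps = len(ids_a)
    block_key = np.array(
        [f"{c}:{p // config.ld_block_length}" for c, p in zip(chroms_a, pos_a)],
        dtype=object,
    )
    alleles = np.zeros((config.n_haplotypes, n_snps), dtype=np.uint8)
    gt = GroundTruth(snp_block={s: str(b) for s, b in zip(ids_a, block_key)})
    for key in dict.fromkeys(block_key):  # preserves order
        cols = np.flatnonzero(block_key == key)
        founders = rng.integers(0, 2, size=(2, len(cols))).astype(np.uint8)
        assignment = rng.integers(0, 2, size=config.n_haplotypes)
        block = founders[assignment]
        flips = rng.random(block.shape) < config.flip_prob
        alleles[:, cols] = block ^ flips.astype(np.uint8)

    return (
        HaplotypeMatrix(
            snp_ids=ids_a,
            chroms=chroms_a,
            positions=pos_a + 1,
            alleles=alleles,
        ),
        gt,
    )


# ---------------------------------------------------------------------------
# Toy coding annotation

def simulate_cds(config: SimConfig, genome: Optional[GenomeLayout] = None) -> RegionSet:
    """Fixed-size coding blocks at the start of every ``cds_every`` tile."""
    genome = genome or make_genome(config)
    ivs = []
    for chrom, length in genome.chromosomes:
        for start in range(0, length - config.cds_block, config.cds_every):
            ivs.append(Interval(chrom, start, start + config.cds_block))
    return RegionSet(ivs, label="CDS")


# ---------------------------------------------------------------------------
# Lineage study convenience wrapper

def simulate_lineage_study(
    config: SimConfig, tree: Optional[LineageTree] = None
) -> tuple[list[SNP], dict[str, RegionSet], GroundTruth, LineageTree]:
    """Lineage peaks plus a SNP set with planted per-stage presence labels.

    SNPs are drawn against the union of all stages' planted HOT spans with
    the configured fold, and ground-truth presence is recorded per stage by
    direct membership of each SNP in that stage's planted spans - the same
    definition the dynamics classifier must reproduce.
    """
    tree = tree or default_lineage()
    genome = make_genome(config)
    _, gt = simulate_lineage_peaks(config, tree)
    union = RegionSet(
        [iv for rs in gt.stage_regions.values() for iv in rs.intervals()],
        label="HOT-any",
    )
    rng = np.random.default_rng(config.seed + 3)
    _, snps, cat_gt = simulate_snp_catalog(config, union, genome, rng=rng)
    gt.snp_in_hot = cat_gt.snp_in_hot
    for s in snps:
        gt.snp_presence[s.snp_id] = {
            stage: gt.stage_regions[stage].contains(s.chrom, s.pos)
            for stage in tree.stages
        }
    return snps, gt.stage_regions, gt, tree
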