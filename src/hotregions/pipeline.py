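"""Pipeline orchestration and report assembly.

Runs the stages in dependency order (simulate or load inputs -> call HOT ->
map SNPs -> enrichment -> lineage dynamics), writes every table to the
output directory, and records a manifest with parameters, seeds and
sha256 checksums so a re-run with the same config is verifiably identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd

from . import io as hio
from .enrichment import PermutationParams, shift_permutation_test, hot_lot_disproportion
from .hot_calling import HotCallParams, TFBindingSite, call_hot_regions
from .lineage import LineageTree, compute_presence, transition_accounting
from .variant_mapping import (
    LDParams,
    classify_coding,
    filter_catalog,
    ld_expand,
    map_snps,
    mapping_table,
    snp_density,
)

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_pipeline", "summarize_percentages", "pct_round"]


@dataclass
class RunConfig:
    """Paths and parameter blocks for a full pipeline run."""

    chrom_sizes: Path
    peaks_dir: Path  # one BED per TF, or per-stage subdirectories
    catalog: Path
    out_dir: Path
    cds: Optional[Path] = None
    haplotypes: Optional[Path] = None
    lineage_tree: Optional[Path] = None
    hot_params: HotCallParams = field(default_factory=HotCallParams)
    ld_params: LDParams = field(default_factory=LDParams)
    perm_params: PermutationParams = field(default_factory=PermutationParams)
    run_ld: bool = True

    def required_files(self) -> list[Path]:
        req = [self.chrom_sizes, self.peaks_dir, self.catalog]
        if self.cds:
            req.append(self.cds)
        if self.run_ld and self.haplotypes:
            req.append(self.haplotypes)
        if self.lineage_tree:
            req.append(self.lineage_tree)
        return req


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _load_peaks(peaks_dir: Path) -> list[TFBindingSite]:
    sites = []
    for bed in sorted(peaks_dir.glob("*.bed")):
        tf = bed.stem
        for iv, name, _ in hio.read_bed(bed):
            sites.append(TFBindingSite(name or tf, iv))
    if not sites:
        raise FileNotFoundError(f"no .bed peak files in {peaks_dir}")
    return sites


def pct_round(num: int, den: int) -> Union[int, str]:
    """Percentage rounded to the nearest integer, ties away from zero.

    A zero denominator reports "NA" rather than raising.
    """
    if den == 0:
        return "NA"
    x = 100.0 * num / den
    return int(np.floor(x + 0.5)) if x >= 0 else -int(np.floor(-x + 0.5))


def summarize_percentages(
    counts: list[tuple[str, int, int]]
) -> pd.DataFrame:
    """Rows of (label, numerator, denominator) -> report table with the
    rounded percentage alongside the raw counts."""
    rows = [
        {"label": label, "numerator": num, "denominator": den,
         "percent": pct_round(num, den)}
        for label, num, den in counts
    ]
    return pd.DataFrame(rows, columns=["label", "numerator", "denominator", "percent"])


def run_pipeline(config: RunConfig) -> dict:
    """Execute all configured stages; returns the manifest dictionary.

    Fails before any stage runs if a required input is missing. Each output
    file is listed in the manifest with a sha256 checksum; rerunning with
    an identical config reproduces identical checksums.
    """
    missing = [str(p) for p in config.required_files() if not Path(p).exists()]
    if missing:
        raise FileNotFoundError(f"missing input file(s): {', '.join(missing)}")
    if config.run_ld and config.haplotypes is None:
        raise FileNotFoundError("LD stage enabled but no haplotype panel given")

    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "parameters": {
            "hot": asdict(config.hot_params),
            "ld": asdict(config.ld_params),
            "permutation": asdict(config.perm_params),
        },
        "inputs": {str(p): _sha256(Path(p)) for p in config.required_files()
                   if Path(p).is_file()},
        "stages": {},
        "outputs": {},
    }

    genome = hio.read_chrom_sizes(config.chrom_sizes)

    # --- stage: call-hot -------------------------------------------------
    stage_name = "call-hot"
    try:
        peak_dirs = sorted(
            d for d in Path(config.peaks_dir).iterdir() if d.is_dir()
        ) or [Path(config.peaks_dir)]
        stage_partitions: dict[str, tuple] = {}
        for d in peak_dirs:
            sites = _load_peaks(d)
            clusters, partition = call_hot_regions(sites, genome, config.hot_params)
            label = d.name if d != Path(config.peaks_dir) else "all"
            stage_partitions[label] = (clusters, partition)
            hio.write_regionset_bed(partition.hot, out / f"{label}.HOT.bed")
            hio.write_regionset_bed(partition.lot, out / f"{label}.LOT.bed")
        manifest["stages"][stage_name] = {
            label: {
                "n_clusters": len(cl),
                "n_hot": len(p.hot),
                "n_lot": len(p.lot),
                "cutoff_rank_scaled": p.cutoff_rank_scaled,
            }
            for label, (cl, p) in stage_partitions.items()
        }
    except Exception as exc:
        raise RuntimeError(f"stage {stage_name!r} failed: {exc}") from exc

    # convention: with a single pooled peak directory the partition to map
    # against is the sole entry; with per-stage directories the first.
    primary = next(iter(stage_partitions))
    _, partition = stage_partitions[primary]
    hot, lot = partition.hot, partition.lot

    # --- stage: map-snps --------------------------------------------------
    stage_name = "map-snps"
    try:
        rows = hio.read_gwas_catalog(config.catalog)
        associations = filter_catalog(rows)
        snps = {a.snp.snp_id: a.snp for a in associations}
        if config.cds:
            cds = hio.read_cds_annotation(config.cds, format="gtf"
                                          if str(config.cds).endswith((".gtf", ".gff"))
                                          else "bed")
            snps = {sid: classify_coding(s, cds) for sid, s in snps.items()}
        snp_list = list(snps.values())
        membership, n_in_hot = map_snps(snp_list, hot)
        _, n_in_lot = map_snps(snp_list, lot)
        expansion: dict = {}
        if config.run_ld:
            panel = hio.read_haplotypes(config.haplotypes)
            expansion, n_skipped = ld_expand(snp_list, panel, hot, config.ld_params)
            manifest["stages"].setdefault("ld", {})["n_skipped"] = n_skipped
        table = mapping_table(associations, snps, expansion)
        table.to_csv(out / "snp_mapping.tsv", sep="\t", index=False)
        manifest["stages"][stage_name] = {
            "n_catalog_rows": len(rows),
            "n_associations": len(associations),
            "n_unique_snps": len(snp_list),
            "n_in_hot": n_in_hot,
            "n_in_lot": n_in_lot,
        }
    except Exception as exc:
        raise RuntimeError(f"stage {stage_name!r} failed: {exc}") from exc

    # --- stage: enrich ----------------------------------------------------
    stage_name = "enrich"
    try:
        dens_hot = snp_density(n_in_hot, hot) if len(hot) else float("nan")
        dens_lot = snp_density(n_in_lot, lot) if len(lot) else float("nan")
        perm = shift_permutation_test(snp_list, hot, genome, config.perm_params)
        chi2, chi2_p = hot_lot_disproportion(
            n_in_hot, n_in_lot, hot.total_length, lot.total_length
        )
        enrich_row = {
            "n_snps": len(snp_list),
            "in_hot": n_in_hot,
            "in_lot": n_in_lot,
            "density_hot_per_mb": dens_hot,
            "density_lot_per_mb": dens_lot,
            "perm_p_hot": perm.p_value,
            "chi2": chi2,
            "chi2_p": chi2_p,
        }
        pd.DataFrame([enrich_row]).to_csv(out / "enrichment.tsv", sep="\t", index=False)
        manifest["stages"][stage_name] = enrich_row
    except Exception as exc:
        raise RuntimeError(f"stage {stage_name!r} failed: {exc}") from exc

    # --- stage: lineage (optional) ---------------------------------------
    if config.lineage_tree is not None:
        stage_name = "lineage"
        try:
            tree = LineageTree.from_pairs(hio.read_lineage_table(config.lineage_tree))
            stage_regions = {}
            for stage in tree.stages:
                if stage in stage_partitions:
                    stage_regions[stage] = stage_partitions[stage][1].hot
            if set(stage_regions) == set(tree.stages):
                presences = compute_presence(snp_list, stage_regions, tree)
                acct = [
                    transition_accounting(presences, p, c)
                    for p, c in tree.transitions()
                ]
                pd.DataFrame(
                    [
                        {"parent": a.parent, "child": a.child, "lost": a.lost,
                         "gained": a.gained, "shared": a.shared,
                         "absent": a.absent, "net": a.net}
                        for a in acct
                    ]
                ).to_csv(out / "lineage_transitions.tsv", sep="\t", index=False)
                manifest["stages"][stage_name] = {"n_transitions": len(acct)}
            else:
                logger.warning(
                    "lineage tree stages %s lack per-stage HOT calls; skipping",
                    sorted(set(tree.stages) - set(stage_regions)),
                )
        except Exception as exc:
            raise RuntimeError(f"stage {stage_name!r} failed: {exc}") from exc

    for f in sorted(out.iterdir()):
        if f.is_file() and f.name != "manifest.json":
            manifest["outputs"][f.name] = _sha256(f)
    def _jsonable(o):
        if isinstance(o, np.integer):
            return int(o)
        if isinstance(o, np.floating):
            return float(o)
        raise TypeError(f"not JSON serializable: {type(o)}")

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=_jsonable)
    return manifest
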