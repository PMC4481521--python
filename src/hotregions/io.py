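"""Readers and writers for the on-disk formats the pipeline touches.

Formats: BED3/BED5 (region sets, TF peaks), GTF (gene annotation), and
plain TSV for the association catalog, haplotype panel, chromosome sizes
and lineage tree. Readers reject malformed records rather than silently
coercing them; every writer/reader pair round-trips losslessly.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .intervals import GenomeLayout, Interval, RegionSet

logger = logging.getLogger(__name__)

__all__ = [
    "GWASCatalogRow",
    "HaplotypeMatrix",
    "read_bed",
    "write_bed",
    "read_gwas_catalog",
    "read_cds_annotation",
    "read_tss_table",
    "read_haplotypes",
    "write_haplotypes",
    "read_chrom_sizes",
    "write_chrom_sizes",
]

PathLike = Union[str, Path]


class FormatError(ValueError):
    """A file violated the expected on-disk format."""


@dataclass(frozen=True)
class GWASCatalogRow:
    """One association line of a GWAS-catalog-style table.

    Positions are 1-based as printed in the catalog; conversion to the
    internal 0-based convention happens in :mod:`hotregions.variant_mapping`.
    """

    snp_id: str
    chrom: str
    pos: int
    trait: str
    study_id: str


@dataclass
class HaplotypeMatrix:
    """Phased binary haplotype matrix (haplotypes x SNPs).

    ``positions`` are 1-based. Column order matches ``snp_ids``.
    """

    snp_ids: list[str]
    chroms: np.ndarray  # object array of chromosome names, per SNP
    positions: np.ndarray  # int64, 1-based, per SNP
    alleles: np.ndarray  # uint8 matrix, shape (n_haplotypes, n_snps)

    def __post_init__(self) -> None:
        n_snps = len(self.snp_ids)
        if self.alleles.ndim != 2 or self.alleles.shape[1] != n_snps:
            raise ValueError("allele matrix shape inconsistent with SNP ids")
        if len(self.positions) != n_snps or len(self.chroms) != n_snps:
            raise ValueError("positions/chroms length inconsistent with SNP ids")
        self._index = {s: i for i, s in enumerate(self.snp_ids)}

    @property
    def n_haplotypes(self) -> int:
        return self.alleles.shape[0]

    @property
    def n_snps(self) -> int:
        return self.alleles.shape[1]

    def column(self, snp_id: str) -> np.ndarray:
        return self.alleles[:, self._index[snp_id]]

    def index_of(self, snp_id: str) -> Optional[int]:
        return self._index.get(snp_id)


# ---------------------------------------------------------------------------
# BED

def read_bed(path: PathLike) -> list[tuple[Interval, Optional[str], Optional[float]]]:
    """Read a BED3/BED5 file into (interval, name, score) records."""
    records: list[tuple[Interval, Optional[str], Optional[float]]] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"{path}: line {lineno}: fewer than 3 columns")
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError:
                raise FormatError(
                    f"{path}: line {lineno}: non-integer coordinates"
                ) from None
            if start >= end or start < 0:
                raise FormatError(
                    f"{path}: line {lineno}: invalid interval {start}-{end}"
                )
            name = fields[3] if len(fields) > 3 else None
            score: Optional[float] = None
            if len(fields) > 4 and fields[4] not in (".", ""):
                try:
                    score = float(fields[4])
                except ValueError:
                    raise FormatError(
                        f"{path}: line {lineno}: non-numeric score {fields[4]!r}"
                    ) from None
            records.append((Interval(fields[0], start, end), name, score))
    return records


def write_bed(
    records: Iterable[tuple[Interval, Optional[str], Optional[float]]],
    path: PathLike,
) -> None:
    with open(path, "w") as fh:
        for iv, name, score in records:
            cols = [iv.chrom, str(iv.start), str(iv.end)]
            if name is not None or score is not None:
                cols.append(name if name is not None else ".")
            if score is not None:
                cols.append(repr(score) if score != int(score) else str(int(score)))
            fh.write("\t".join(cols) + "\n")


def regionset_from_bed(path: PathLike, label: str = "") -> RegionSet:
    recs = read_bed(path)
    return RegionSet([r[0] for r in recs], label=label,
                     scores=[r[2] if r[2] is not None else np.nan for r in recs] or None)


def write_regionset_bed(regions: RegionSet, path: PathLike) -> None:
    records = []
    for i, (iv, sc) in enumerate(zip(regions.intervals(), regions.scores())):
        name = f"{regions.label or 'region'}_{i + 1}"
        records.append((iv, name, None if np.isnan(sc) else round(sc, 4)))
    write_bed(records, path)


# ---------------------------------------------------------------------------
# GWAS catalog

_REQUIRED_CATALOG_COLUMNS = ("snp_id", "chrom", "pos", "trait", "study_id")


def read_gwas_catalog(
    path: PathLike,
    column_map: Optional[dict[str, str]] = None,
) -> list[GWASCatalogRow]:
    """Read a GWAS-catalog-like association TSV.

    ``column_map`` maps the logical names (snp_id, chrom, pos, trait,
    study_id) to whatever the file's header actually uses, so real catalog
    exports with drifting schemas can be adapted without editing the file.
    Rows without a resolvable position are dropped with a logged count;
    exact duplicate association lines are deduplicated.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if column_map:
        df = df.rename(columns={v: k for k, v in column_map.items()})
    missing = [c for c in _REQUIRED_CATALOG_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(
            f"{path}: missing required column(s): {', '.join(missing)}"
        )
    pos = pd.to_numeric(df["pos"], errors="coerce")
    bad = pos.isna() | (pos < 1) | (df["chrom"] == "")
    if bad.any():
        logger.info("dropped %d catalog rows without a resolvable position", int(bad.sum()))
        df = df[~bad]
        pos = pos[~bad]
    if (df["trait"] == "").any():
        raise FormatError(f"{path}: empty trait field")
    df = df.assign(pos=pos.astype(np.int64))
    df = df.drop_duplicates(subset=["snp_id", "chrom", "pos", "trait", "study_id"])
    return [
        GWASCatalogRow(r.snp_id, r.chrom, int(r.pos), r.trait, r.study_id)
        for r in df.itertuples(index=False)
    ]


def write_gwas_catalog(rows: Sequence[GWASCatalogRow], path: PathLike) -> None:
    pd.DataFrame(
        [(r.snp_id, r.chrom, r.pos, r.trait, r.study_id) for r in rows],
        columns=list(_REQUIRED_CATALOG_COLUMNS),
    ).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Gene annotation (GTF / BED)

_GTF_COLUMNS = [
    "chrom", "source", "feature", "start", "end", "score", "strand", "frame", "attributes",
]
_ATTR_RE = re.compile(r'(\w+) "([^"]*)"')


def _read_gtf(path: PathLike) -> pd.DataFrame:
    df = pd.read_csv(
        path, sep="\t", comment="#", header=None, names=_GTF_COLUMNS,
        dtype={"chrom": str, "feature": str, "strand": str},
    )
    return df


def _gtf_attributes(attr: str) -> dict[str, str]:
    return dict(_ATTR_RE.findall(attr))


def read_cds_annotation(path: PathLike, format: str = "gtf") -> RegionSet:
    """Union of coding (CDS) intervals as a merged 0-based half-open set.

    GTF coordinates are 1-based inclusive; a record start..end becomes the
    half-open interval [start-1, end).
    """
    if format == "bed":
        return regionset_from_bed(path, label="CDS")
    if format != "gtf":
        raise FormatError(f"unknown annotation format {format!r}")
    df = _read_gtf(path)
    cds = df[df["feature"] == "CDS"]
    if cds.empty:
        logger.warning("%s: no CDS features found; coding set is empty", path)
        return RegionSet([], label="CDS")
    ivs = [
        Interval(str(c), int(s) - 1, int(e))
        for c, s, e in zip(cds["chrom"], cds["start"], cds["end"])
    ]
    return RegionSet(ivs, label="CDS")


def read_tss_table(path: PathLike) -> pd.DataFrame:
    """Per-gene transcription start sites from GTF "transcript" features.

    For each gene the most 5' transcript defines the TSS: the smallest start
    on the + strand, the largest end on the - strand. Returned positions are
    0-based. Columns: gene_id, chrom, tss, strand.
    """
    df = _read_gtf(path)
    tx = df[df["feature"] == "transcript"]
    if tx.empty:
        raise FormatError(f"{path}: no transcript features for TSS extraction")
    rows = []
    for _, r in tx.iterrows():
        attrs = _gtf_attributes(r["attributes"])
        gene = attrs.get("gene_id")
        if gene is None:
            raise FormatError(f"{path}: transcript feature lacks gene_id attribute")
        tss = int(r["start"]) - 1 if r["strand"] != "-" else int(r["end"]) - 1
        rows.append((gene, str(r["chrom"]), tss, str(r["strand"])))
    tdf = pd.DataFrame(rows, columns=["gene_id", "chrom", "tss", "strand"])
    # most 5' transcript per gene
    plus = tdf[tdf["strand"] != "-"].groupby("gene_id", as_index=False).agg(
        chrom=("chrom", "first"), tss=("tss", "min"), strand=("strand", "first"))
    minus = tdf[tdf["strand"] == "-"].groupby("gene_id", as_index=False).agg(
        chrom=("chrom", "first"), tss=("tss", "max"), strand=("strand", "first"))
    return pd.concat([plus, minus], ignore_index=True).sort_values("gene_id").reset_index(drop=True)


# ---------------------------------------------------------------------------
# Haplotype panel TSV
#
# Layout: line 1 = tab-separated SNP ids; line 2 = chrom:pos (1-based) per
# SNP; each following line = one haplotype as tab-separated 0/1 calls.

def read_haplotypes(path: PathLike) -> HaplotypeMatrix:
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        posline = fh.readline().rstrip("\n").split("\t")
        if len(posline) != len(header):
            raise FormatError(f"{path}: position line length does not match header")
        chroms, positions = [], []
        for j, tok in enumerate(posline):
            try:
                chrom, p = tok.rsplit(":", 1)
                positions.append(int(p))
                chroms.append(chrom)
            except ValueError:
                raise FormatError(
                    f"{path}: bad position token {tok!r} for SNP {header[j]}"
                ) from None
        rows = []
        for i, raw in enumerate(fh):
            cells = raw.rstrip("\n").split("\t")
            if len(cells) != len(header):
                raise FormatError(
                    f"{path}: haplotype row {i + 1} has {len(cells)} cells, expected {len(header)}"
                )
            for j, c in enumerate(cells):
                if c not in ("0", "1"):
                    raise FormatError(
                        f"{path}: non-binary entry {c!r} at haplotype {i + 1}, SNP {header[j]}"
                    )
            rows.append([int(c) for c in cells])
    return HaplotypeMatrix(
        snp_ids=header,
        chroms=np.array(chroms, dtype=object),
        positions=np.array(positions, dtype=np.int64),
        alleles=np.array(rows, dtype=np.uint8),
    )


def write_haplotypes(panel: HaplotypeMatrix, path: PathLike) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(panel.snp_ids) + "\n")
        fh.write("\t".join(f"{c}:{p}" for c, p in zip(panel.chroms, panel.positions)) + "\n")
        for row in panel.alleles:
            fh.write("\t".join(str(int(v)) for v in row) + "\n")


# ---------------------------------------------------------------------------
# Chromosome sizes & lineage tree TSVs

def read_chrom_sizes(path: PathLike) -> GenomeLayout:
    """Two-column TSV (name, length), standard chrom.sizes layout."""
    chroms: list[tuple[str, int]] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise FormatError(f"{path}: line {lineno}: expected name<TAB>length")
            try:
                chroms.append((fields[0], int(fields[1])))
            except ValueError:
                raise FormatError(f"{path}: line {lineno}: non-integer length") from None
    return GenomeLayout(tuple(chroms))


def write_chrom_sizes(genome: GenomeLayout, path: PathLike) -> None:
    with open(path, "w") as fh:
        for name, length in genome.chromosomes:
            fh.write(f"{name}\t{length}\n")


def read_lineage_table(path: PathLike) -> list[tuple[str, Optional[str]]]:
    """child<TAB>parent rows; the root's parent is written as "-"."""
    out: list[tuple[str, Optional[str]]] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 2:
                raise FormatError(f"{path}: line {lineno}: expected child<TAB>parent")
            child, parent = fields
            out.append((child, None if parent == "-" else parent))
    return out


def write_lineage_table(rows: Sequence[tuple[str, Optional[str]]], path: PathLike) -> None:
    with open(path, "w") as fh:
        for child, parent in rows:
            fh.write(f"{child}\t{parent if parent is not None else '-'}\n")
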