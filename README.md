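# hotregions

Tools for annotating **HOT (high-occupancy target) regions** — genomic
regions bound by unusually many transcription factors — and for
quantifying how disease- and trait-associated variants concentrate inside
them.

The package is aimed at regulatory-genomics analysts who have per-TF
binding-site interval sets (BED), a GWAS-catalog-style association table,
and optionally a phased haplotype panel and a developmental lineage
description, and who want reproducible answers to questions like: *which
parts of the genome are HOT in this cell type, how many trait-associated
SNPs fall inside, is that more than chance, and how does SNP-in-HOT
membership change along a differentiation lineage?*

## What it computes

**HOT/LOT calling.** Binding-site midpoints of many TFs are pooled and
smoothed with an unnormalised Gaussian kernel (σ = 3 kb by default), so an
isolated site contributes a unit-height peak. Maximal runs of grid
positions where the smoothed signal stays ≥ 0.5 become *TFBS-clustered
regions*, each scored with a **TFBS complexity**

> C = Σᵢ exp(−(x* − mᵢ)² / 2σ²),

the kernel sum at the region's density peak x* — a proximity-weighted
count of contributing sites. Regions are ranked by increasing complexity;
with both axes of the rank–complexity curve scaled to [0, 1], the point
where a slope-1 line is tangent to the curve splits **LOT** (below) from
**HOT** (above), the same elbow construction used for super-enhancer
calling.

**Variant mapping.** Catalog rows are curated (dbSNP-style identifier
present, trait supported by ≥ 2 independent studies), classified
coding/noncoding against a CDS union, and mapped into region sets.
SNP densities are reported per megabase (count / region bp × 10⁶). SNPs
outside HOT regions can be *LD-expanded*: a SNP is flagged when some panel
SNP inside a HOT region within a 125 kb radius shows r² > 0.8, with r²
computed by direct haplotype counting (r² = D²/p_a(1−p_a)p_b(1−p_b)).

**Significance.** A chromosome-preserving *shift permutation test*
(regions relocated uniformly on their chromosome of origin, 10,000
iterations by default; add-one empirical p so "no exceedance" reports
p < 10⁻⁴), one-sided binomial tests for stage-specific enrichment, a 1-df
χ² for HOT-vs-LOT disproportion, Pearson density correlations, binomial
interval enrichment, and nearest-TSS region→gene assignment with 2×2 χ²
gene-set enrichment.

**Lineage dynamics.** Along a stage tree (e.g. ESC → haematopoietic
progenitor → {B, T}), each SNP's per-stage HOT membership yields
lost/gained/shared/absent transition classes, stage-of-origin,
stage-specificity, and retained-from-root fractions.

**Synthetic studies.** `hotregions simulate` generates a toy genome with
planted multi-TF hotspot loci, lineage-structured hotspot sets, SNP
catalogs with a planted fold enrichment inside HOT territory, and a
block-structured phased haplotype panel — with full ground-truth labels,
so every stage of the pipeline can be scored without any external data.

## Worked example

```sh
hotregions simulate --seed 11 --out demo
hotregions call-hot --peaks demo/peaks/ESC --chrom-sizes demo/chrom.sizes --out demo/esc
hotregions enrich --snps demo/catalog.tsv --hot demo/esc.HOT.bed --lot demo/esc.LOT.bed \
    --chrom-sizes demo/chrom.sizes --n-perm 10000 --seed 17 --out demo/enrich.tsv
```

prints

```
wrote synthetic study to demo
560 clusters; 64 HOT / 496 LOT (cutoff at scaled rank 0.8855)
enrichment table: demo/enrich.tsv (perm p = 0.0001)
```

and `demo/enrich.tsv` contains

```
n_snps  in_hot  in_lot  density_hot_per_mb  density_lot_per_mb  perm_p_hot  chi2     chi2_p
2000    144     267     129.67              66.34               9.999e-05   43.63    3.98e-11
```

Reading: of 2,000 curated SNPs, 144 fall into the 64 called HOT regions —
a density of ~130 SNP/Mb against ~66 SNP/Mb in LOT regions. None of the
10,000 random relocations of the HOT set produced as many overlapping
SNPs (empirical p = 1/10,001 < 10⁻⁴), and the χ² goodness-of-fit rejects
proportionality of SNP counts to HOT/LOT base-pair shares (χ² = 43.6,
p ≈ 4×10⁻¹¹) — the simulation planted a five-fold SNP density inside HOT
territory, and the pipeline recovers it.

The same operations are available as a library
(`from hotregions import call_hot_regions, shift_permutation_test, ...`);
see `docs/methods.md` for the modelling details and parameter guidance.

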