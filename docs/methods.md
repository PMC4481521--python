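# Methods

This note documents the models, parameter choices and numerical decisions
behind `hotregions`, and what the synthetic test bed does and does not
establish about behaviour on real data.

## Coordinate model

All interval arithmetic is 0-based, half-open (BED convention). 1-based
inputs — GWAS-catalog positions, GTF records, haplotype-panel positions —
are converted at the I/O boundary, never downstream. Strand is ignored
throughout: every analysis here (density smoothing, membership, LD) is
strand-agnostic; the only strand-aware step is TSS extraction from GTF
transcript records (5′-most start on +, 3′-most end on −). Overlapping
intervals within one `RegionSet` are merged at construction because
coverage fractions and per-megabase densities require disjoint bases;
book-ended intervals are left unmerged since they cover disjoint bases
anyway. Merged scored intervals keep the maximum score of their parts.

## HOT/LOT calling

**Density.** Site midpoints are smoothed with an *unnormalised* Gaussian
kernel, `density(x) = Σᵢ exp(−(x−mᵢ)²/2σ²)`, evaluated on a uniform grid.
The unnormalised form makes the scale interpretable: one isolated site
peaks at exactly 1.0, k coincident sites at k. The bandwidth (default
σ = 3,000 bp) is read as the Gaussian σ, the standard KDE meaning of
"bandwidth", not as FWHM. The grid step (default 50 bp) is ≪ σ, so grid
snapping moves boundaries by at most one step; kernels are truncated at
6σ where the contribution (< 2·10⁻⁸) is far below any threshold in use.

**Clustering.** A TFBS-clustered region is a maximal run of grid points
with density ≥ `cluster_threshold_frac` (default 0.5) of the single-site
peak height. The threshold-on-KDE rule was chosen over distance-based
site merging because it is scale-free in the number of TFs and has one
interpretable parameter. At 0.5 an isolated site yields a cluster of
half-width σ√(2 ln 2) ≈ 1.18σ, and two sites ≤ ~2σ apart merge. A
cluster's member sites are those with midpoints inside the run extended
by one grid step each side.

**Complexity.** The complexity score must increase with the number of
contributing sites and decrease as they disperse. The kernel sum at the
cluster's density peak is the simplest statistic with both properties: it
equals the site count when all midpoints coincide, is strictly below it
otherwise, and needs no extra parameters. It is recomputed exactly at the
peak position from the member sites (not read off the grid).

**HOT/LOT split.** Clusters are ranked by increasing complexity and both
axes scaled to [0, 1] (rank → x, complexity min→0/max→1 → y). The
conceptual rule is the classic elbow: the x where a line of slope 1 is
tangent to the curve. Numerically we locate it as the **minimiser of
y(x) − x**, taking the largest x at ties. For a curve with a convex
high-complexity tail this is exactly the slope-1 tangency point (left of
it the curve rises slower than the diagonal, right of it faster), and it
recovers the analytic cutoffs of y = x² (0.5) and y = x⁴ ((1/4)^{1/3} ≈
0.630) to grid resolution. A pointwise finite-difference slope was
rejected: on rank curves from real cluster sets, adjacent clusters in the
tail often have near-equal complexities, the discrete slope chatters
around 1, and a "last crossing" rule lands arbitrarily close to rank 1,
emptying the HOT set. The tie rule (largest x) errs toward fewer HOT
calls. Clusters with scaled rank strictly above the cutoff are HOT; a
completely flat curve has no elbow, and the HOT set is left empty with a
warning. At least 3 clusters with non-identical complexities are
required.

## Catalog curation and variant mapping

Association rows are kept only if the variant has an identifier and the
(SNP, trait) pair is supported by ≥ 2 distinct study ids — reproducible
associations are likelier causal. Grouping is per trait, so a SNP can
survive for one trait and be dropped for another. Rows without a
resolvable position are dropped with a logged count rather than guessed
at. Coding status is membership in the CDS union; the half-open
convention puts a SNP at a CDS end coordinate outside.

**LD expansion.** For a curated SNP outside the region set, candidate
partners are panel SNPs that are *inside* a region and within
`radius` bp (default 125,000) of the query SNP — the radius is anchored
on the query variant. The SNP is flagged when any candidate pair exceeds
the r² threshold (default 0.8, strict inequality). r² is computed by
direct haplotype counting from the phased panel; no EM reconstruction is
needed or offered — unphased input is out of scope. SNPs absent from the
panel are reported in a skip count, never imputed. Monomorphic columns
raise: r² is undefined there, and silently returning 0 would hide a
data-processing error.

## Significance machinery

**Shift permutation test.** Each iteration relocates every region to a
uniform random start on its own chromosome (length and chromosome
preserved; wrap-around disallowed). Regions are placed independently by
default — a literal per-region reading of "randomly shifted on the
chromosome of origin" — with a `rigid` mode (one offset per chromosome,
spacing preserved) for users whose null should keep inter-region
structure. Overlaps between relocated regions are allowed; a SNP covered
by several counts once, via a vectorised union-of-index-ranges count. The
p-value is the add-one estimator (1 + #{null ≥ obs})/(n + 1): never
exactly 0, and "no exceedance in 10,000 iterations" reports 1/10,001 <
10⁻⁴. The Monte-Carlo p agrees with exact enumeration on a tiny fully
enumerable instance (one 10-bp region on a 100-bp chromosome, all 91
placements).

**Binomial stage enrichment.** For a trait with n region-mapped SNPs of
which x fall in one stage's regions, against a baseline proportion p, the
report is the signed percentage ((x/n)/p − 1)·100 and a one-sided
binomial tail in the direction of the deviation (P(X ≥ x) when x/n ≥ p,
else P(X ≤ x)); a two-sided option doubles the tail, capped at 1. Raw
p-values are reported by default (no multiple-testing correction); a
Benjamini–Hochberg column can be added downstream by the caller.

**HOT/LOT disproportion.** The primary statistic is a 1-df goodness-of-fit
χ²: under proportionality the expected SNP counts split the total by the
HOT/LOT base-pair shares. A 2×2 contingency variant
(`snp_contingency_chi2`, no continuity correction) is available where two
SNP classes are compared instead.

**Interval and gene-set enrichment.** Interval enrichment asks whether
region midpoints concentrate inside a target territory: k of m midpoints
inside vs Binomial(m, q) with q the targets' genome fraction, upper tail.
Regions are assigned to the gene with the nearest TSS to the region
midpoint (ties → lexicographically smallest id; no distance cap), and
gene-set enrichment is a 1-df 2×2 χ² without continuity correction,
erroring toward an exact test when an expected cell is zero.

## Lineage dynamics

Dynamics are evaluated at SNP resolution — *is this SNP inside a HOT
region active at this stage?* — rather than by tracking region identity
across stages, which would require an arbitrary region-matching rule.
Transition classes follow directly: lost (parent only), gained (child
only), shared (both), absent (neither); net = gained − lost, which
telescopes along any root-to-leaf path. Stage of origin is the earliest
presence along the root-to-leaf path of the queried cell type (presence
in a sibling branch does not affect it); stage specificity is presence at
exactly one stage of the *whole* tree, so sibling presence does break
specificity. SNPs present at no path stage are reported as origin "none"
without further subdivision.

## Synthetic test bed

The generator emulates, at desk scale, the structure of a multi-TF
binding compendium plus GWAS catalog plus phased panel:

- **Genome**: 3 chromosomes × 10 Mb. Large enough that a 2% HOT
  territory leaves room for permutation placements, small enough that the
  full pipeline runs in seconds.
- **Peaks**: 60 hotspot loci; at each, 10–20 of 20 TFs place one site
  with midpoint jitter N(0, 500 bp) — within-hotspot scatter well inside
  one bandwidth, so planted loci produce single high-complexity clusters
  (complexity ≈ 8–18). Background sites are Poisson per TF at
  10⁻⁶ sites/bp/TF (~300 sites per TF genome-wide pooled over TFs),
  giving a background kernel level around 0.15 — below the 0.5 cluster
  threshold, but dense enough to yield hundreds of low-complexity
  (~1–3) clusters so the elbow has a genuine two-population curve to cut.
- **Lineage**: root stage keeps the 60 loci; each child keeps a parental
  locus with probability 0.7 and gains 20 new loci, mimicking
  inherited/lost/gained regulatory territory along ESC → progenitor →
  {B, T}. Ground-truth per-SNP per-stage presence is recorded from the
  planted spans (locus ± 2 kb) — the same membership definition the
  dynamics classifier uses, so classifier-vs-truth comparisons are exact,
  not statistical.
- **Catalog**: SNP positions follow a two-density mixture, f·λ inside the
  HOT set and λ outside, so the expected in-HOT fraction is
  f·L_H/(f·L_H + L_rest); default f = 5 with n = 2,000 SNPs. Each SNP
  carries two supporting studies (so it survives curation) and a trait
  label; multiple traits with different folds can be planted to exercise
  both binomial tails. Sampling outside the HOT set uses its exact
  complement, so f = 0 yields zero in-HOT SNPs by construction.
- **Haplotypes**: the genome is tiled into 20 kb blocks; each block has
  two founder haplotypes, each of 100 sampled haplotypes copies one
  founder per block (independent across blocks) with per-SNP flip
  probability 0.02. Within a block, loci whose founders differ are in
  near-perfect LD; across blocks r² ≈ 0. Panel SNPs sit every 5 kb, and
  catalog SNPs can be injected so they are LD-expandable.
- **Coding annotation**: a 1 kb CDS block at the start of every 200 kb
  tile (0.5% coding), enough for the noncoding filter to have work to do.

Everything is a pure function of the config (seed included); identical
configs reproduce outputs byte-for-byte.

**What passing tests show — and don't.** The synthetic bed has uniform
background, independent uniform SNP placement, block-diagonal LD and
noiseless region boundaries. Real genomes violate all of these:
binding-site density tracks GC content, mappability and chromatin
accessibility; GWAS SNPs cluster by LD and by study ascertainment; LD
decays continuously rather than in blocks. Tests on this bed therefore
establish *correctness of the machinery* (the caller finds what was
planted, the null is calibrated under the generator's null, labels match
planted truth) — not that the biological effect sizes or p-values
obtained on real data are unbiased. In particular the permutation null
assumes SNP positions are fixed and regions exchangeable along their
chromosome, which real-data users should treat as a lower bound on
confounding.

## Numerical choices and edge cases

- Empirical p-values use the add-one estimator and are in (0, 1] always.
- Elbow ties go to larger rank (fewer HOT); flat curves yield an empty
  HOT set with a warning rather than an arbitrary split.
- `snp_density` raises on zero-length region sets; percentage reports
  print "NA" on zero denominators instead of raising, because report
  tables should render even for empty traits.
- Percentages round to the nearest integer, ties away from zero
  (53.85 → 54).
- r² on monomorphic columns raises `MonomorphicError`; LD expansion
  silently skips monomorphic candidate partners (they carry no
  information) but not monomorphic query SNPs, which simply cannot be
  flagged.
- The permutation test validates region length ≤ chromosome length and
  is deterministic given `PermutationParams.seed`.
- Test-suite and acceptance-script problem sizes (399-iteration
  permutations for calibration sweeps, 1,999 for power runs, 50–200
  replicates, 30 Mb genomes) are the package's chosen desk-scale study
  conditions: large enough for the binomial margins asserted, small
  enough to iterate on quickly. The library default remains 10,000
  iterations.

## Known limitations

- The TFBS-complexity formula here (kernel sum at the peak) is this
  package's own definition satisfying the stated number-and-proximity
  dependencies; other HOT-region catalogues may score complexity
  differently, so absolute complexity values are not comparable across
  tools — only ranks within one run are used.
- LD expansion requires a phased panel; unphased genotypes are not
  supported.
- GTF handling is deliberately minimal: CDS union and per-gene TSS only;
  no transcript models, UTR or splice structure.
- The region→gene assignment is nearest-TSS with no distance cap;
  gene-poor chromosomes assign distant genes rather than none.
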