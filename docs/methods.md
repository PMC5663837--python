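# Methods

## Coordinate and naming conventions

All genomic intervals are held 0-based, half-open (BED convention).
CIRI-style tables report 1-based inclusive regions, so their starts are
decremented on read and incremented on write; every dialect round-trips
exactly. Chromosome names are canonicalized to the `chr`-prefixed form
(`MT`/`M` → `chrM`). The CIRCexplorer dialect targets the BED-like annotated
output (read count in the 13th column, gene name in the 15th); find_circ and
circRNAFinder are read as BED6 with the junction-read count in the score
column.

Host-gene assignment requires both junction endpoints to fall inside a
single gene span. When several genes qualify the tie breaks
deterministically: same-strand gene first, then largest overlap, then
lexicographically smallest gene id.

## Consensus calling

A junction is trusted per cell iff every required tool reports a match
(same chromosome and strand; coordinates equal in `exact` mode, or each
endpoint within ±`window_bp` — default 2 bp — in `window` mode, because
detectors disagree at junction boundaries). The consensus record takes its
coordinates and host gene from the highest-priority supporting tool
(ciri > circexplorer > find_circ > circrnafinder) and summarizes junction
reads as the maximum across tools (mean optional): the tools re-count the
same molecules, so the maximum is the least-lossy single summary. A required
tool that contributed *no* file at all raises a configuration error;
a tool that found nothing in a cell legitimately yields an empty
intersection.

## SNP consensus and hard filters

Variants are kept only when both callers (GATK HaplotypeCaller-style and
samtools mpileup-style input VCFs) report the identical
cell/chromosome/position/ref/alt, then hard-filtered on the GATK record's
annotations: drop QUAL < 30, QD < 20.0, DP < 8, FS > 30.0. Removal
conditions are strict inequalities, so boundary values (QUAL = 30,
QD = 20.0, DP = 8, FS = 30.0) are kept. The QD ≥ 20 rule is far more
stringent than common practice (QD < 2 is the usual removal rule); it is the
convention this pipeline implements verbatim and is configurable via
`snp_consensus_filter(..., thresholds=...)`. Indels and multi-allelic rows
are excluded up front (the analysis concerns SNPs only); records missing an
annotation cannot be checked against the filters and are dropped.

## Expression quantities

`CGR = junction_reads / host_reads` and
`circ_FPKM = junction_reads / (mapped_reads_millions × host_FPKM)`.
The mapped-reads denominator is the library's total mapped reads (from
`library_sizes.tsv`), not circRNA-specific reads. Zero denominators yield
NaN rather than an error, and NaN pairs are dropped from correlations;
correlations default to raw values, with a `log10` pairing option (dropping
non-positive pairs) because both quantities are heavy-tailed.

## Heterogeneity

Presence is binary: a cell carries a circRNA iff it has ≥ 1 consensus
junction read. Manhattan distance between presence rows equals the count of
discordant circRNAs. Clustering uses scipy's agglomerative linkage
(average/complete/ward/single × manhattan/euclidean/correlation; ward
restricted to euclidean). Equal-height merge ties resolve by input
position; the pipeline feeds cells sorted by id, making results
deterministic. Dendrograms export to Newick with merge heights as branch
lengths.

## Chromosome enrichment

Densities are `1e8 × count / length` (circRNA) and `1e6 × count / length`
(SNP); the scale factors only make the numbers readable. The enrichment
null places each of the N observed features on chromosome c with probability
`length_c / Σ lengths`; the default test is the one-sided exact binomial
`P(X ≥ k)` (per-cell counts are small, so a normal or chi-square
approximation would be anticonservative), with a one-sided 1-df chi-square
alternative. q-values are Benjamini–Hochberg across chromosomes.
Chromosomes with zero observations (typically chrY) are retained with
density 0. Per-cell and pooled modes are both available; the pipeline
reports the pooled test and a per-cell heatmap table (column z-scores;
zero-variance columns map to 0, not NaN).

## Host-gene GSEA

Three ranked lists: genes with FPKM > 0 ranked by mean FPKM across cells,
genes with ≥ 1 filtered SNP ranked by SNP count, and genes with ≥ 1 miRNA
association ranked by association count; the query set is the circRNA host
genes present in each list. Ties break by gene id (stable), so scores are
reproducible. The walk adds `w_g / Σ_hits w` at hits and subtracts
`1/(N − N_hits)` at misses; with `weight_p = 0` all hit weights are 1, with
`weight_p = 1` (the default — hit magnitude should reflect the ranking
metric) `w_g = |metric_g|`. ES is the signed running-sum value of maximum
absolute deviation. Significance permutes query-set membership over gene
labels (there is no phenotype axis to permute) with
`perm_p = (1 + #{|ES*| ≥ |ES|}) / (1 + n_perm)`; the pseudo-count keeps
p-values positive. If every hit weight is zero under `weight_p = 1`, the
walk falls back to equal weights rather than dividing by zero.

## Seed matching and sponge networks

Site classes follow the canonical definitions: the target site is the DNA
reverse complement of miRNA seed positions 2–7 (6mer) or 2–8 (7mer-m8),
with an A on the target opposite miRNA position 1 upgrading to 7mer-A1/8mer.
The site is anchored at the reverse complement of the 6mer core and graded
to its best class; overlapping sites are all reported; `N` never matches;
G:U wobble is not allowed (deterministic, stricter); scanning is
sense-strand only, since the mature circle is single-stranded. Because
circRNAs are closed loops, the default pipeline scan uses modular indexing
so sites spanning the back-splice junction are found and reported with
wrapped coordinates; `circ_junction_site_scan` isolates exactly those
sites. Networks are tripartite with typed nodes and edges; duplicate edges
collapse with a multiplicity attribute; gene-layer restriction drops gene
nodes outside the given set without touching the circRNA–miRNA layer. The
association table is user-supplied (e.g. a Miranda/HMDD export), keeping
the pipeline download-free; de novo scanning and precomputed-table joins
are both supported entry points.

## Synthetic cohort

Defaults are the study conditions the pipeline targets: 38 cells, 410 true
circRNAs, hg19 chromosome sizes, no circRNAs on chrY, a 5-fold placement
excess on chr22, per-circRNA presence probabilities uniform on
[0.05, 0.95], a −0.8 Pearson coupling between log10 CGR and log10 host
FPKM, and tool false-positive rates of 1–4 decoys per true call so the
per-tool call counts dwarf the consensus, as real detectors do.

Mechanics worth knowing when interpreting test results:

* True junctions appear in all four dialect files with identical
  coordinates; decoys are drawn independently per tool across ~3 Gb of
  genome, so cross-tool decoy collisions are (deterministically, per seed)
  absent and exact-mode consensus recovery is exact.
* Genes are laid out non-overlapping per chromosome, so host-gene recovery
  from the GTF is unambiguous.
* Host FPKM and CGR are drawn jointly log-normal with the target
  correlation; `junction_reads = round(CGR × host_reads)` (min 1), so the
  CGR formula inverts up to rounding, and host/background genes get higher/
  lower mean log-expression so the expression GSEA list is genuinely
  enriched while SNP rates are identical across genes (a null list).
* SNP annotations are drawn from ranges straddling each hard-filter
  threshold independently (a configurable fraction fails exactly one
  filter); correlated failure modes are not modelled.
* One hub miRNA gets an 8mer site planted in a quarter of the circRNA
  sequences; incidental seed matches in random sequence are common (a 7mer
  occurs once per ~16 kb per miRNA), which is why the hub's planted degree
  is set well above that background.

What the generator does **not** emulate: read-level noise, detector-specific
coordinate jitter, dropout correlated with expression, linked SNPs, real
sequence composition, or annotation errors. Passing recovery tests therefore
demonstrates correctness of the computations on well-formed inputs, not
robustness to every artifact of real single-cell data.

The in-memory `fixture_minimal()` (3 cells × 5 circRNAs, 2 chromosomes,
4 miRNAs) ships with hand-enumerated presence, Manhattan-distance and
seed-match tables for exactness tests.

## Pipeline and determinism

Stages write their tables under the output directory; `summary.json`
contains no timestamps and is dumped with sorted keys, so reruns with the
same inputs and seed are byte-identical. All randomness (generator and GSEA
permutations) flows from explicit seeds; no global RNG state is used. Any
stage failure raises an error naming the stage and offending file. Per-term
host-gene counts from an optional gene→term table are reported as counts
only — no enrichment statistic is claimed for them, since term annotation
quality is outside the pipeline's control.

Problem sizes used in the shipped tests and the acceptance script (38-cell
default cohort; 6–10-cell cohorts for unit-level recovery; 200 replicates
for null-calibration checks; 1000 random instances for oracle equivalence)
were chosen so the whole suite completes in seconds while keeping binomial
sampling error well inside the asserted tolerances.

## Known limitations

* Junction matching is coordinate-based; no re-alignment or re-scoring.
* The window-mode consensus anchors on the highest-priority tool's calls;
  a junction seen only by lower-priority tools within the window of two
  different anchors resolves to the first anchor in sorted order.
* Seed matching ignores binding thermodynamics, conservation and 3'
  supplementary pairing; it grades pattern matches only.
* The GSEA permutation null assumes exchangeable gene labels; strong
  metric autocorrelation (e.g. clustered paralogs) is not modelled.
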