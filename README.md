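# circkit

Single-cell circRNA analysis: consensus back-splice-junction calling across
detector dialects, per-cell heterogeneity statistics, chromosome-level
density and enrichment, circRNA/host-gene expression quantification, ranked
-list (GSEA-style) enrichment of circRNA host genes, and seed-match-based
circRNA–miRNA–mRNA (ceRNA) network construction — plus a synthetic-cohort
generator with full ground truth so the entire pipeline runs and is testable
without any downloads.

## Who this is for

Circular RNAs (circRNAs) are covalently closed transcripts defined by a
back-splice junction. Individual detectors (CIRI, find_circ, CIRCexplorer,
circRNAFinder) disagree heavily — thousands of calls per tool, a few hundred
shared — so single-cell circRNA studies typically keep only junctions called
by *every* tool, then ask how circRNA content varies between cells, where
circRNAs sit on the genome, how their abundance relates to their host gene,
and which miRNAs they could sponge. `circkit` implements that analysis as a
reusable, tested library and CLI operating on detector/caller *outputs*
(running aligners and detectors is out of scope).

## The statistics at the core

* **Consensus calling** — per cell, a junction is kept iff a matching
  junction (same chromosome and strand; identical coordinates, or within
  ±w bp in window mode) exists for every required tool.
* **Heterogeneity** — cells × circRNAs presence/absence matrix
  (1 = detected); the Manhattan distance between two cell rows counts their
  discordant circRNAs; agglomerative clustering summarizes the cohort.
* **Chromosome densities** —
  `circRNA-Freq = 1e8 · count / chromosome length` and
  `SNP-Freq = 1e6 · count / chromosome length`, with a one-sided exact
  binomial test of each chromosome's count against its length-proportional
  expectation and Benjamini–Hochberg correction.
* **SNP hard filters** — variants called by both GATK and samtools, dropping
  QUAL < 30, QD < 20.0, DP < 8, or FS > 30.0 (boundary values kept).
* **Expression** — `CGR = junction reads / host gene reads` and
  `FPKM(circ) = junction reads / (mapped reads in millions · host FPKM)`;
  Pearson correlation (raw or log10) between circRNA and host quantities.
* **Host-gene GSEA** — a running sum over a ranked gene list that rises at
  circRNA host genes and falls otherwise; the enrichment score (ES) is the
  maximum deviation from zero, with a gene-label permutation p-value.
* **Sponge networks** — canonical miRNA seed matching (6mer / 7mer-A1 /
  7mer-m8 / 8mer, reverse complement of miRNA positions 2–8) on circRNA
  sequences, wrapping around the back-splice junction; tripartite
  circRNA–miRNA–gene graphs exported as SIF or GraphML.

## Worked example

```python
from circkit.synthetic import SimConfig, simulate_cohort
from circkit.pipeline import RunConfig, run_pipeline

cfg = SimConfig(seed=1)                       # 38 cells, 410 circRNAs
gt = simulate_cohort(cfg, "cohort/")
summary = run_pipeline(RunConfig(data_dir="cohort/", out_dir="run/", seed=1))

print(summary["correlations"]["log_cgr_vs_log_host_fpkm"])
# {'pcc': -0.7977546701956716, 'p': 0.0, 'n': 7554}
print(summary["chrom_enrichment"]["top_circ_chrom"])
# chr22
print(summary["top_mirnas"][0])
# ['sim-miR-1', 109]
```

The cohort was generated with a −0.8 coupling between log10 CGR and log10
host-gene FPKM; the pipeline recovers −0.798 from the written files (n =
7554 circRNA–cell observations). The 5-fold chr22 placement excess surfaces
as the top enriched chromosome, and the planted hub miRNA (`sim-miR-1`,
seed-matched in a quarter of the circRNAs) tops the regulator ranking with
109 distinct circRNA partners. The same run writes `consensus.tsv`,
`presence.tsv`, `manhattan.tsv`, a Newick dendrogram, per-chromosome
enrichment tables, GSEA running sums, `network.sif`/`network.graphml` and a
deterministic `summary.json` under `run/`.

Equivalent CLI:

```bash
circkit simulate --seed 1 --out cohort/
circkit run --data-dir cohort/ --out run/ --seed 1
circkit sponge --circ-fasta cohort/circ_seqs.fa --mirna-fasta cohort/mirnas.fa \
    --min-class 7mer-m8 --out network.sif
```

## Layout

| module | contents |
| --- | --- |
| `circkit.io` | detector-dialect, VCF, GTF, FASTA, chrom-sizes, SIF/GraphML readers and writers; coordinate normalization; host-gene interval index |
| `circkit.consensus` | per-cell tool intersection; SNP caller consensus + hard filters |
| `circkit.quantify` | CGR, circRNA-FPKM, presence matrix, Manhattan distance, clustering, correlation |
| `circkit.chrom_enrichment` | densities, binomial/chi-square enrichment, heatmap table |
| `circkit.gsea` | running-sum enrichment score, permutation null, ranked-list builders |
| `circkit.sponge` | seed-match scanning (linear and circular), ceRNA network assembly |
| `circkit.synthetic` | cohort generator and hand-enumerable minimal fixture |
| `circkit.pipeline`, `circkit.cli` | end-to-end orchestration and the `circkit` command |

See `docs/methods.md` for the modelling choices and their rationale.
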