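"""Config-driven end-to-end run over a cohort directory.

The pipeline consumes the directory layout the simulator writes (and which
real detector/caller outputs can be arranged into)::

    <data_dir>/
      chrom.sizes  genes.gtf  library_sizes.tsv
      mirnas.fa  circ_seqs.fa  mirna_gene.tsv
      cells/<cell_id>/{ciri.tsv,find_circ.bed,circexplorer.txt,
                       circrnafinder.bed,gatk.vcf,samtools.vcf,expression.tsv}

and runs: ingest -> consensus -> heterogeneity -> chromosome enrichment ->
expression quantification/correlation -> host-gene GSEA -> sponge network,
writing stage TSVs, network exports and a deterministic ``summary.json``
(no timestamps inside, so reruns with the same seed are byte-identical).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import chrom_enrichment as ce
from . import consensus as cons
from . import gsea as gsea_mod
from . import io as cio
from . import quantify as qt
from . import sponge
from .errors import PipelineError

logger = logging.getLogger(__name__)

_TOOL_EXT = {"ciri": "tsv", "circexplorer": "txt", "find_circ": "bed", "circrnafinder": "bed"}


@dataclass
class RunConfig:
    data_dir: str
    out_dir: str
    tools: tuple[str, ...] = cio.TOOLS
    match_mode: str = "exact"
    window_bp: int = 2
    snp_thresholds: dict = field(default_factory=dict)
    gsea_weight_p: int = 1
    gsea_n_perm: int = 1000
    min_class: str = "7mer-m8"
    seed: int = 0
    gene_term_table: str | None = None

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "tools" in raw:
            raw["tools"] = tuple(raw["tools"])
        return cls(**raw)

    def validate(self) -> None:
        root = Path(self.data_dir)
        if not root.is_dir():
            raise PipelineError("validate", f"data_dir {root} does not exist")
        for name in ("chrom.sizes", "genes.gtf", "library_sizes.tsv"):
            if not (root / name).exists():
                raise PipelineError("validate", f"missing input file {root / name}")
        if self.gene_term_table and not Path(self.gene_term_table).exists():
            raise PipelineError("validate", f"missing gene_term_table {self.gene_term_table}")


def _discover_cells(root: Path) -> list[str]:
    cells_dir = root / "cells"
    if not cells_dir.is_dir():
        raise PipelineError("ingest", f"no cells/ directory under {root}")
    return sorted(p.name for p in cells_dir.iterdir() if p.is_dir())


def run_pipeline(cfg: RunConfig) -> dict:
    """Run every stage and return the JSON-serializable summary."""
    cfg.validate()
    root = Path(cfg.data_dir)
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cells = _discover_cells(root)
    if not cells:
        raise PipelineError("ingest", "no cells found")

    # ---- ingest -----------------------------------------------------------
    calls: list[cio.CircCall] = []
    snp_records: list[cio.SnpRecord] = []
    expression: dict[str, dict[str, tuple[int, float]]] = {}
    for cell in cells:
        cdir = root / "cells" / cell
        for tool in cfg.tools:
            path = cdir / f"{tool}.{_TOOL_EXT[tool]}"
            if not path.exists():
                raise PipelineError("ingest", f"cell {cell}: missing {tool} output ({path})")
            calls.extend(cio.read_circ_calls(path, tool, cell))
        for caller in ("gatk", "samtools"):
            vpath = cdir / f"{caller}.vcf"
            if vpath.exists():
                snp_records.extend(cio.read_vcf(vpath, caller, cell))
        epath = cdir / "expression.tsv"
        if epath.exists():
            expression[cell] = {
                e.gene_id: (e.read_count, e.fpkm)
                for e in cio.read_expression(epath, cell)
            }
    chrom_info = cio.read_chrom_info(root / "chrom.sizes")
    chrom_lengths = {c.chrom: c.length for c in chrom_info}
    library_sizes = {}
    with open(root / "library_sizes.tsv") as fh:
        for line in fh:
            if line.strip():
                cell, n = line.split("\t")
                library_sizes[cell] = int(n)
    gene_index = cio.read_gtf_gene_index(root / "genes.gtf")
    logger.info("ingest: %d cells, %d circ calls, %d SNP records",
                len(cells), len(calls), len(snp_records))

    # ---- consensus --------------------------------------------------------
    consensus = cons.intersect_calls(
        calls, set(cfg.tools), match_mode=cfg.match_mode, window_bp=cfg.window_bp
    )
    # fill host genes from the annotation where the detector did not provide one
    filled = []
    for c in consensus:
        if c.host_gene is None:
            host = gene_index.assign_host_gene(c.chrom, c.start, c.end, c.strand)
            if host is not None:
                c = cons.ConsensusCircRNA(
                    circ_id=c.circ_id, cell_id=c.cell_id, chrom=c.chrom,
                    start=c.start, end=c.end, strand=c.strand,
                    junction_reads=c.junction_reads,
                    supporting_tools=c.supporting_tools, host_gene=host,
                )
        filled.append(c)
    consensus = filled
    pd.DataFrame(
        [
            (c.cell_id, c.circ_id, c.chrom, c.start, c.end, c.strand,
             c.junction_reads, ",".join(sorted(c.supporting_tools)), c.host_gene or "")
            for c in consensus
        ],
        columns=["cell_id", "circ_id", "chrom", "start", "end", "strand",
                 "junction_reads", "tools", "host_gene"],
    ).to_csv(out / "consensus.tsv", sep="\t", index=False)
    logger.info("consensus: %d per-cell entries", len(consensus))
    if not consensus:
        raise PipelineError("consensus", "empty consensus set")

    filtered_snps = cons.snp_consensus_filter(snp_records, cfg.snp_thresholds or None)
    logger.info("snp filter: %d of %d records kept", len(filtered_snps), len(snp_records))

    # ---- heterogeneity ----------------------------------------------------
    pm = qt.presence_matrix(consensus, cells)
    pm.to_frame().to_csv(out / "presence.tsv", sep="\t")
    dist = qt.manhattan_distances(pm)
    dist.to_csv(out / "manhattan.tsv", sep="\t")
    newick = None
    if len(cells) >= 2:
        dend = qt.hierarchical_cluster(pm, linkage="average", metric="manhattan")
        newick = dend.to_newick()
        (out / "dendrogram.nwk").write_text(newick + "\n")

    # ---- chromosome enrichment -------------------------------------------
    def _per_chrom_counts(items):
        counts: dict[str, int] = {}
        for chrom in items:
            counts[chrom] = counts.get(chrom, 0) + 1
        return counts

    circ_counts = _per_chrom_counts(c.chrom for c in consensus)
    circ_enrich = ce.chromosome_enrichment(circ_counts, chrom_lengths, feature="circ")
    pd.DataFrame([vars(p) for p in circ_enrich]).to_csv(
        out / "chrom_circ_enrichment.tsv", sep="\t", index=False
    )
    per_cell_profiles = {}
    for cell in cells:
        counts = _per_chrom_counts(c.chrom for c in consensus if c.cell_id == cell)
        if sum(counts.values()) >= 1:
            per_cell_profiles[cell] = ce.chromosome_enrichment(
                counts, chrom_lengths, feature="circ", cell_id=cell
            )
    if per_cell_profiles:
        ce.freq_heatmap_table(per_cell_profiles, zscore=True).to_csv(
            out / "chrom_circ_heatmap.tsv", sep="\t"
        )
    snp_enrich = []
    if filtered_snps:
        snp_counts = _per_chrom_counts(s.chrom for s in filtered_snps)
        snp_enrich = ce.chromosome_enrichment(snp_counts, chrom_lengths, feature="snp")
        pd.DataFrame([vars(p) for p in snp_enrich]).to_csv(
            out / "chrom_snp_enrichment.tsv", sep="\t", index=False
        )

    # ---- expression quantification and correlations -----------------------
    expr_table = qt.circ_expression_table(consensus, expression, library_sizes)
    expr_df = pd.DataFrame([vars(e) for e in expr_table])
    expr_df.to_csv(out / "circ_expression.tsv", sep="\t", index=False)
    correlations = {}
    with_host = expr_df.dropna(subset=["cgr"]).query("host_fpkm > 0")
    if len(with_host) >= 3:
        r, p = qt.pearson_correlation(
            np.log10(with_host["cgr"]), np.log10(with_host["host_fpkm"])
        )
        correlations["log_cgr_vs_log_host_fpkm"] = {"pcc": r, "p": p, "n": len(with_host)}
        r2, p2 = qt.pearson_correlation(with_host["cgr"], with_host["host_fpkm"])
        correlations["cgr_vs_host_fpkm"] = {"pcc": r2, "p": p2, "n": len(with_host)}
    fpkm_ok = expr_df.dropna(subset=["circ_fpkm"]).query("host_fpkm > 0 and circ_fpkm > 0")
    if len(fpkm_ok) >= 3:
        r3, p3 = qt.pearson_correlation(
            np.log10(fpkm_ok["circ_fpkm"]), np.log10(fpkm_ok["host_fpkm"])
        )
        correlations["log_circ_fpkm_vs_log_host_fpkm"] = {"pcc": r3, "p": p3, "n": len(fpkm_ok)}

    # ---- host-gene GSEA ----------------------------------------------------
    host_genes = sorted({c.host_gene for c in consensus if c.host_gene})
    fpkm_by_gene: dict[str, float] = {}
    for cell in cells:
        for gene, (_, fpkm) in expression.get(cell, {}).items():
            fpkm_by_gene[gene] = fpkm_by_gene.get(gene, 0.0) + fpkm / len(cells)
    snp_by_gene: dict[str, int] = {}
    for s in filtered_snps:
        gene = gene_index.assign_host_gene(s.chrom, s.pos, s.pos + 1)
        if gene is not None:
            snp_by_gene[gene] = snp_by_gene.get(gene, 0) + 1
    mirna_gene_rows: list[tuple[str, str]] = []
    mg_path = root / "mirna_gene.tsv"
    if mg_path.exists():
        mg = pd.read_csv(mg_path, sep="\t")
        mirna_gene_rows = list(mg.itertuples(index=False, name=None))
    sites_by_gene: dict[str, int] = {}
    for _, gene in mirna_gene_rows:
        sites_by_gene[gene] = sites_by_gene.get(gene, 0) + 1

    ranked = gsea_mod.build_ranked_lists(fpkm_by_gene, snp_by_gene, sites_by_gene, host_genes)
    gsea_results = {}
    for name, rl in ranked.items():
        try:
            res = gsea_mod.permutation_p(
                rl, n_perm=cfg.gsea_n_perm, seed=cfg.seed, weight_p=cfg.gsea_weight_p
            )
        except Exception as exc:  # degenerate list (e.g. every gene is a host)
            logger.warning("gsea %s skipped: %s", name, exc)
            continue
        gsea_results[name] = {
            "es": res.es, "perm_p": res.perm_p, "n_perm": res.n_perm,
            "n_genes": len(rl.genes), "n_hits": len(res.hit_positions),
        }
        pd.DataFrame(
            {"gene": rl.genes, "metric": rl.metric, "running_sum": res.running_sum}
        ).to_csv(out / f"gsea_{name}.tsv", sep="\t", index=False)

    # ---- sponge network ----------------------------------------------------
    network_summary = {}
    top_mirnas = []
    circ_seq_path = root / "circ_seqs.fa"
    mirna_path = root / "mirnas.fa"
    if circ_seq_path.exists() and mirna_path.exists():
        circ_seqs = cio.read_fasta(circ_seq_path)
        mirnas = [sponge.MiRNA(mid, seq) for mid, seq in cio.read_fasta(mirna_path).items()]
        consensus_ids = {c.circ_id for c in consensus}
        matches = []
        for cid in sorted(consensus_ids & set(circ_seqs)):
            matches.extend(
                sponge.scan_seed_sites(
                    circ_seqs[cid], mirnas, min_class=cfg.min_class,
                    circ_id=cid, circular=True,
                )
            )
        graph = sponge.build_network(matches, mirna_gene_rows)
        cio.write_network(graph, out / "network.sif", "sif")
        cio.write_network(graph, out / "network.graphml", "graphml")
        node_types = [d["node_type"] for _, d in graph.nodes(data=True)]
        network_summary = {
            "nodes": graph.number_of_nodes(),
            "edges": graph.number_of_edges(),
            "n_circ": node_types.count("circRNA"),
            "n_mirna": node_types.count("miRNA"),
            "n_gene": node_types.count("gene"),
            "n_seed_matches": len(matches),
        }
        top_mirnas = sponge.top_regulator_mirnas(matches, k=10)
        pd.DataFrame(top_mirnas, columns=["mirna_id", "n_circ"]).to_csv(
            out / "top_mirnas.tsv", sep="\t", index=False
        )

    # ---- optional per-term host-gene counts --------------------------------
    term_counts = {}
    if cfg.gene_term_table:
        terms = pd.read_csv(cfg.gene_term_table, sep="\t", names=["gene_id", "term"])
        hostset = set(host_genes)
        counts = terms[terms["gene_id"].isin(hostset)].groupby("term").size()
        term_counts = counts.sort_index().to_dict()
        counts.rename("host_gene_count").to_csv(out / "term_counts.tsv", sep="\t")

    # ---- summary -----------------------------------------------------------
    per_cell_counts = {
        cell: int(sum(1 for c in consensus if c.cell_id == cell)) for cell in cells
    }
    summary = {
        "n_cells": len(cells),
        "consensus": {
            "per_cell_counts": per_cell_counts,
            "n_unique_circ": len({c.circ_id for c in consensus}),
            "n_entries": len(consensus),
        },
        "snp": {"n_input_records": len(snp_records), "n_filtered": len(filtered_snps)},
        "heterogeneity": {
            "mean_manhattan": float(
                dist.values[np.triu_indices(len(cells), k=1)].mean()
            ) if len(cells) > 1 else 0.0,
            "dendrogram_newick": newick,
        },
        "chrom_enrichment": {
            "circ_q_values": {p.chrom: p.q_value for p in circ_enrich},
            "top_circ_chrom": min(circ_enrich, key=lambda p: (p.p_value, p.chrom)).chrom,
            "snp_q_values": {p.chrom: p.q_value for p in snp_enrich},
        },
        "correlations": correlations,
        "gsea": gsea_results,
        "network": network_summary,
        "top_mirnas": [list(t) for t in top_mirnas],
        "term_counts": term_counts,
        "config": {
            "tools": list(cfg.tools), "match_mode": cfg.match_mode,
            "window_bp": cfg.window_bp, "gsea_weight_p": cfg.gsea_weight_p,
            "gsea_n_perm": cfg.gsea_n_perm, "min_class": cfg.min_class,
            "seed": cfg.seed,
        },
    }
    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return summary
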