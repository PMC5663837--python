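"""Synthetic single-cell circRNA cohort with fully known ground truth.

The generator emulates the statistical structure of a MATQ-seq-style
single-cell cohort as the pipeline sees it: per-cell circRNA detector
outputs in four dialects (shared true junctions plus tool-specific false
positives), two-caller VCFs whose QUAL/QD/DP/FS annotations straddle the
hard-filter thresholds, expression tables in which log10 CGR and log10 host
FPKM are negatively coupled through a bivariate normal, an optionally
chromosome-biased junction placement, and circRNA sequences with planted
miRNA seed sites including a designated high-degree "hub" miRNA. Every
planted fact is recorded so downstream stages can be tested as parameter
recovery. All randomness flows from one seeded generator; a fixed seed gives
byte-identical output files.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .io import ChromInfo, CircCall, write_circ_calls, write_fasta
from .sponge import MiRNA, reverse_complement

#: hg19 chromosome sizes (UCSC), the coordinate frame the cohort is placed on.
HG19_CHROM_SIZES = {
    "chr1": 249250621, "chr2": 243199373, "chr3": 198022430, "chr4": 191154276,
    "chr5": 180915260, "chr6": 171115067, "chr7": 159138663, "chr8": 146364022,
    "chr9": 141213431, "chr10": 135534747, "chr11": 135006516, "chr12": 133851895,
    "chr13": 115169878, "chr14": 107349540, "chr15": 102531392, "chr16": 90354753,
    "chr17": 81195210, "chr18": 78077248, "chr19": 59128983, "chr20": 63025520,
    "chr21": 48129895, "chr22": 51304566, "chrX": 155270560, "chrY": 59373566,
}

TOOL_ORDER = ("ciri", "find_circ", "circexplorer", "circrnafinder")


@dataclass
class SimConfig:
    """Study conditions for the synthetic cohort.

    Defaults mirror a MATQ-seq-scale study design: 38 single cells, 410 consensus
    circRNAs, a 5-fold circRNA excess on chr22, a -0.8 coupling between
    log10 CGR and log10 host-gene FPKM, and no circRNAs on chrY.
    """

    n_cells: int = 38
    n_circ: int = 410
    chrom_lengths: dict[str, int] = field(default_factory=lambda: dict(HG19_CHROM_SIZES))
    enriched_chrom: tuple[str, float] | None = ("chr22", 5.0)
    presence_prob: np.ndarray | None = None  # per-circ; default U(0.05, 0.95)
    tool_fp_rate: dict[str, float] = field(
        default_factory=lambda: {
            "ciri": 1.0, "find_circ": 3.0, "circexplorer": 2.0, "circrnafinder": 4.0,
        }
    )
    cgr_host_corr: float = -0.8
    snp_rate_per_gene: float = 1.0
    snp_filter_fail_frac: float = 0.3
    snp_both_callers_frac: float = 0.8
    n_mirnas: int = 50
    n_genes_extra: int = 205
    circ_seq_len: tuple[int, int] = (200, 600)
    planted_sites: list[tuple[str, str, str]] | None = None  # (circ, mirna, class)
    seed: int = 0

    def __post_init__(self):
        if not -1 < self.cgr_host_corr < 1:
            raise ValueError("|cgr_host_corr| must be < 1")
        for t, r in self.tool_fp_rate.items():
            if r < 0:
                raise ValueError(f"tool_fp_rate[{t}] must be >= 0")


@dataclass
class GroundTruth:
    """Everything the generator planted, keyed for parameter-recovery tests."""

    config: SimConfig
    circs: pd.DataFrame          # circ_id, chrom, start, end, strand, gene_id, ...
    genes: pd.DataFrame          # gene_id, chrom, start, end, strand, is_host
    presence: pd.DataFrame       # cells x circ_id, 0/1
    expression: pd.DataFrame     # per (cell, circ): cgr, host_fpkm, reads ...
    snps: pd.DataFrame           # per planted SNP with pass/fail bookkeeping
    mirnas: dict[str, str]
    circ_seqs: dict[str, str]
    planted_sites: pd.DataFrame  # circ_id, mirna_id, match_class, site_start
    mirna_gene: pd.DataFrame     # mirna_id, gene_id
    library_sizes: dict[str, int]
    hub_mirna: str


def _site_pattern(mirna_seq: str, match_class: str) -> str:
    seq = mirna_seq.upper().replace("T", "U")
    rc27 = reverse_complement(seq[1:7])
    rc28 = reverse_complement(seq[1:8])
    return {
        "6mer": rc27, "7mer-A1": rc27 + "A", "7mer-m8": rc28, "8mer": rc28 + "A",
    }[match_class]


def _random_seq(rng, length: int, alphabet: str = "ACGT") -> str:
    return "".join(rng.choice(list(alphabet), size=length))


def simulate_cohort(cfg: SimConfig, outdir: str | os.PathLike) -> GroundTruth:
    """Generate the cohort, write every input file, and return the truth.

    Layout under ``outdir``::

        chrom.sizes                      two-column chromosome lengths
        genes.gtf                        gene spans (hosts + background genes)
        library_sizes.tsv                cell_id <TAB> total mapped reads
        mirnas.fa / circ_seqs.fa         mature miRNA / circRNA sequences
        mirna_gene.tsv                   miRNA -> target-gene associations
        cells/<cell>/<tool>.<ext>        per-cell detector outputs (4 dialects)
        cells/<cell>/{gatk,samtools}.vcf per-cell variant calls
        cells/<cell>/expression.tsv      gene_id, read_count, fpkm
        ground_truth/*.tsv               the planted facts
    """
    rng = np.random.default_rng(cfg.seed)
    outdir = Path(outdir)
    (outdir / "cells").mkdir(parents=True, exist_ok=True)
    (outdir / "ground_truth").mkdir(exist_ok=True)

    cells = [f"cell{i + 1:03d}" for i in range(cfg.n_cells)]
    chroms = sorted(cfg.chrom_lengths)

    # --- gene and circRNA placement (chrY carries no circRNAs) -------------
    circ_chrom_pool = [c for c in chroms if c != "chrY"] or chroms
    weights = np.array([cfg.chrom_lengths[c] for c in circ_chrom_pool], dtype=float)
    if cfg.enriched_chrom is not None:
        echrom, fold = cfg.enriched_chrom
        if echrom in circ_chrom_pool:
            weights[circ_chrom_pool.index(echrom)] *= fold
    weights /= weights.sum()
    host_chroms = rng.choice(len(circ_chrom_pool), size=cfg.n_circ, p=weights)

    # lay genes out non-overlapping per chromosome so host assignment is exact
    gene_rows, circ_rows = [], []
    cursor = {c: 10_000 for c in chroms}
    gene_lens = rng.integers(5_000, 200_000, size=cfg.n_circ + cfg.n_genes_extra)
    strands = rng.choice(["+", "-"], size=cfg.n_circ + cfg.n_genes_extra)
    for i in range(cfg.n_circ):
        chrom = circ_chrom_pool[host_chroms[i]]
        glen = int(gene_lens[i])
        gstart = cursor[chrom] + int(rng.integers(1_000, 20_000))
        gend = gstart + glen
        cursor[chrom] = gend
        gene_id = f"HOSTG{i + 1:04d}"
        cstart = gstart + int(rng.integers(0, max(glen - 300, 1)))
        cend = cstart + int(rng.integers(150, 300))
        cend = min(cend, gend)
        strand = strands[i]
        circ_id = f"{chrom}:{cstart}-{cend}:{strand}"
        gene_rows.append((gene_id, chrom, gstart, gend, strand, True))
        circ_rows.append((circ_id, chrom, cstart, cend, strand, gene_id, glen))
    extra_chroms = rng.choice(len(chroms), size=cfg.n_genes_extra)
    for i in range(cfg.n_genes_extra):
        chrom = chroms[extra_chroms[i]]
        glen = int(gene_lens[cfg.n_circ + i])
        gstart = cursor[chrom] + int(rng.integers(1_000, 20_000))
        cursor[chrom] = gstart + glen
        gene_rows.append(
            (f"BKGG{i + 1:04d}", chrom, gstart, gstart + glen, strands[cfg.n_circ + i], False)
        )
    genes = pd.DataFrame(
        gene_rows, columns=["gene_id", "chrom", "start", "end", "strand", "is_host"]
    )
    circs = pd.DataFrame(
        circ_rows, columns=["circ_id", "chrom", "start", "end", "strand", "gene_id", "gene_len"]
    )

    # --- presence/absence ---------------------------------------------------
    pprob = (
        rng.uniform(0.05, 0.95, size=cfg.n_circ)
        if cfg.presence_prob is None
        else np.asarray(cfg.presence_prob, dtype=float)
    )
    circs["presence_prob"] = pprob
    present = rng.random((cfg.n_cells, cfg.n_circ)) < pprob[None, :]
    presence = pd.DataFrame(
        present.astype(int), index=cells, columns=list(circs["circ_id"])
    )

    # --- expression with log-scale negative CGR/host-FPKM coupling ---------
    library_sizes = {c: int(rng.integers(1_500_000, 3_000_000)) for c in cells}
    rho = cfg.cgr_host_corr
    cov = np.array([[1.0, rho], [rho, 1.0]])
    gene_mu = np.where(
        genes["is_host"], rng.normal(1.1, 0.4, len(genes)), rng.normal(0.7, 0.4, len(genes))
    )
    gene_len_kb = (genes["end"] - genes["start"]).to_numpy() / 1000.0
    host_pos = {g: i for i, g in enumerate(genes["gene_id"])}

    expr_rows = []       # per (cell, circ) truth for present circRNAs
    expr_tables = {}     # cell -> DataFrame(gene_id, read_count, fpkm)
    for ci, cell in enumerate(cells):
        mapped_m = library_sizes[cell] / 1e6
        log_fpkm = rng.normal(gene_mu, 0.3)
        fpkm = 10.0 ** log_fpkm
        # couple host FPKM and CGR for the circRNAs present in this cell
        idx = np.nonzero(present[ci])[0]
        z = rng.multivariate_normal([0.0, 0.0], cov, size=len(idx))
        cgr = 10.0 ** (-1.5 + 0.4 * z[:, 1])
        for k, j in enumerate(idx):
            gid = circs.at[j, "gene_id"]
            gpos = host_pos[gid]
            fpkm[gpos] = 10.0 ** (1.0 + 0.5 * z[k, 0])
        reads = np.maximum(np.round(fpkm * gene_len_kb * mapped_m), 1).astype(int)
        for k, j in enumerate(idx):
            gid = circs.at[j, "gene_id"]
            gpos = host_pos[gid]
            jr = max(1, int(round(cgr[k] * reads[gpos])))
            expr_rows.append(
                (cell, circs.at[j, "circ_id"], gid, jr, int(reads[gpos]),
                 float(fpkm[gpos]), float(cgr[k]), mapped_m)
            )
        expr_tables[cell] = pd.DataFrame(
            {"gene_id": genes["gene_id"], "read_count": reads, "fpkm": np.round(fpkm, 6)}
        )
    expression = pd.DataFrame(
        expr_rows,
        columns=["cell_id", "circ_id", "gene_id", "junction_reads", "host_reads",
                 "host_fpkm", "cgr", "mapped_reads_millions"],
    )
    jr_lookup = {
        (r.cell_id, r.circ_id): r.junction_reads for r in expression.itertuples()
    }

    # --- detector call files (true junctions + tool-specific decoys) -------
    for ci, cell in enumerate(cells):
        cell_dir = outdir / "cells" / cell
        cell_dir.mkdir(exist_ok=True)
        idx = np.nonzero(present[ci])[0]
        true_calls = {}
        for tool in TOOL_ORDER:
            true_calls[tool] = [
                CircCall(
                    cell_id=cell,
                    chrom=circs.at[j, "chrom"],
                    start=int(circs.at[j, "start"]),
                    end=int(circs.at[j, "end"]),
                    strand=circs.at[j, "strand"],
                    junction_reads=jr_lookup[(cell, circs.at[j, "circ_id"])],
                    tool=tool,
                    host_gene=circs.at[j, "gene_id"] if tool in ("ciri", "circexplorer") else None,
                )
                for j in idx
            ]
        for tool in TOOL_ORDER:
            n_fp = int(round(cfg.tool_fp_rate.get(tool, 0.0) * len(idx)))
            decoys = []
            for _ in range(n_fp):
                chrom = chroms[int(rng.integers(len(chroms)))]
                start = int(rng.integers(0, cfg.chrom_lengths[chrom] - 1_000))
                decoys.append(
                    CircCall(
                        cell_id=cell, chrom=chrom, start=start,
                        end=start + int(rng.integers(150, 300)),
                        strand="+" if rng.random() < 0.5 else "-",
                        junction_reads=int(rng.integers(1, 10)),
                        tool=tool,
                    )
                )
            ext = {"ciri": "tsv", "circexplorer": "txt"}.get(tool, "bed")
            write_circ_calls(true_calls[tool] + decoys, cell_dir / f"{tool}.{ext}", tool)

    # --- SNPs straddling the hard filters -----------------------------------
    snp_rows = []
    bases = np.array(list("ACGT"))
    annotations = ("qual", "qd", "dp", "fs")
    for cell in cells:
        for g in genes.itertuples():
            n_snp = rng.poisson(cfg.snp_rate_per_gene)
            for _ in range(n_snp):
                pos = int(rng.integers(g.start, g.end))
                ref, alt = rng.choice(bases, size=2, replace=False)
                both = rng.random() < cfg.snp_both_callers_frac
                fail = rng.random() < cfg.snp_filter_fail_frac
                qual = float(np.round(rng.uniform(30, 80), 2))
                qd = float(np.round(rng.uniform(20, 35), 2))
                dp = int(rng.integers(8, 40))
                fs = float(np.round(rng.uniform(0, 29.9), 2))
                failed_field = ""
                if fail:
                    failed_field = annotations[int(rng.integers(4))]
                    if failed_field == "qual":
                        qual = float(np.round(rng.uniform(5, 29.9), 2))
                    elif failed_field == "qd":
                        qd = float(np.round(rng.uniform(5, 19.9), 2))
                    elif failed_field == "dp":
                        dp = int(rng.integers(1, 8))
                    else:
                        fs = float(np.round(rng.uniform(30.5, 60), 2))
                snp_rows.append(
                    (cell, g.chrom, pos, ref, alt, qual, qd, dp, fs,
                     both, failed_field, g.gene_id, bool(both and not fail))
                )
    snps = pd.DataFrame(
        snp_rows,
        columns=["cell_id", "chrom", "pos", "ref", "alt", "qual", "qd", "dp", "fs",
                 "both_callers", "failed_field", "gene_id", "passes"],
    )
    for cell in cells:
        sub = snps[snps["cell_id"] == cell].sort_values(["chrom", "pos"])
        for caller in ("gatk", "samtools"):
            rows = sub if caller == "gatk" else sub[sub["both_callers"]]
            _write_vcf(outdir / "cells" / cell / f"{caller}.vcf", rows, cfg.chrom_lengths)

    # --- expression / annotation / sizes files ------------------------------
    for cell in cells:
        expr_tables[cell].to_csv(
            outdir / "cells" / cell / "expression.tsv", sep="\t", index=False
        )
    with open(outdir / "library_sizes.tsv", "w") as fh:
        for cell in cells:
            fh.write(f"{cell}\t{library_sizes[cell]}\n")
    with open(outdir / "chrom.sizes", "w") as fh:
        for chrom in chroms:
            fh.write(f"{chrom}\t{cfg.chrom_lengths[chrom]}\n")
    with open(outdir / "genes.gtf", "w") as fh:
        for g in genes.itertuples():
            attrs = f'gene_id "{g.gene_id}"; gene_name "{g.gene_id}";'
            fh.write(
                f"{g.chrom}\tcirckit_sim\tgene\t{g.start + 1}\t{g.end}\t.\t{g.strand}\t.\t{attrs}\n"
            )

    # --- miRNAs, circRNA sequences, planted seed sites ----------------------
    mirna_ids = [f"sim-miR-{i + 1}" for i in range(cfg.n_mirnas)]
    mirnas = {m: _random_seq(rng, 22, "ACGU") for m in mirna_ids}
    circ_seqs = {
        cid: _random_seq(rng, int(rng.integers(*cfg.circ_seq_len)))
        for cid in circs["circ_id"]
    }
    hub = mirna_ids[0]
    planted = cfg.planted_sites
    if planted is None:
        planted = []
        circ_ids = list(circs["circ_id"])
        n_hub = max(10, cfg.n_circ // 4)
        hub_targets = rng.choice(len(circ_ids), size=min(n_hub, len(circ_ids)), replace=False)
        for j in hub_targets:
            planted.append((circ_ids[j], hub, "8mer"))
        for mi in range(1, min(6, cfg.n_mirnas)):
            n_sec = max(1, cfg.n_circ // 40)
            for j in rng.choice(len(circ_ids), size=min(n_sec, len(circ_ids)), replace=False):
                planted.append((circ_ids[j], mirna_ids[mi], "7mer-m8"))
    planted_rows = []
    for circ_id, mirna_id, match_class in planted:
        pattern = _site_pattern(mirnas[mirna_id], match_class)
        seq = circ_seqs[circ_id]
        pos = int(rng.integers(0, len(seq) - len(pattern)))
        circ_seqs[circ_id] = seq[:pos] + pattern + seq[pos + len(pattern):]
        planted_rows.append((circ_id, mirna_id, match_class, pos))
    planted_df = pd.DataFrame(
        planted_rows, columns=["circ_id", "mirna_id", "match_class", "site_start"]
    )
    write_fasta(mirnas, outdir / "mirnas.fa")
    write_fasta(circ_seqs, outdir / "circ_seqs.fa")

    # miRNA -> target-gene associations: host genes carry more sites
    assoc_rows = []
    n_assoc = np.where(genes["is_host"], rng.poisson(4.0, len(genes)) + 1,
                       rng.poisson(1.5, len(genes)))
    for g, n in zip(genes["gene_id"], n_assoc):
        if n == 0:
            continue
        for mi in rng.choice(cfg.n_mirnas, size=min(n, cfg.n_mirnas), replace=False):
            assoc_rows.append((mirna_ids[mi], g))
    mirna_gene = pd.DataFrame(sorted(assoc_rows), columns=["mirna_id", "gene_id"])
    mirna_gene.to_csv(outdir / "mirna_gene.tsv", sep="\t", index=False)

    # --- ground truth dump ---------------------------------------------------
    gt_dir = outdir / "ground_truth"
    circs.to_csv(gt_dir / "circs.tsv", sep="\t", index=False)
    genes.to_csv(gt_dir / "genes.tsv", sep="\t", index=False)
    presence.to_csv(gt_dir / "presence.tsv", sep="\t")
    expression.to_csv(gt_dir / "expression.tsv", sep="\t", index=False)
    snps.to_csv(gt_dir / "snps.tsv", sep="\t", index=False)
    planted_df.to_csv(gt_dir / "planted_sites.tsv", sep="\t", index=False)

    return GroundTruth(
        config=cfg, circs=circs, genes=genes, presence=presence,
        expression=expression, snps=snps, mirnas=mirnas, circ_seqs=circ_seqs,
        planted_sites=planted_df, mirna_gene=mirna_gene,
        library_sizes=library_sizes, hub_mirna=hub,
    )


def _write_vcf(path: Path, rows: pd.DataFrame, chrom_lengths: dict[str, int]) -> None:
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##INFO=<ID=QD,Number=1,Type=Float,Description="Qual by depth">\n')
        fh.write('##INFO=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n')
        fh.write('##INFO=<ID=FS,Number=1,Type=Float,Description="Fisher strand bias">\n')
        for chrom in sorted(chrom_lengths):
            fh.write(f"##contig=<ID={chrom},length={chrom_lengths[chrom]}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for r in rows.itertuples():
            info = f"QD={r.qd};DP={r.dp};FS={r.fs}"
            fh.write(
                f"{r.chrom}\t{r.pos + 1}\t.\t{r.ref}\t{r.alt}\t{r.qual}\t.\t{info}\n"
            )


# ---------------------------------------------------------------------------
# Hand-enumerable minimal fixture
# ---------------------------------------------------------------------------

@dataclass
class MinimalFixture:
    """A tiny in-memory cohort whose expected intermediates are hand-checked."""

    cells: list[str]
    circs: pd.DataFrame
    calls: list[CircCall]
    expected_presence: pd.DataFrame
    expected_manhattan: pd.DataFrame
    mirnas: list[MiRNA]
    circ_seqs: dict[str, str]
    expected_seed_matches: list[tuple[str, str, int, str]]
    chrom_lengths: dict[str, int]


def fixture_minimal() -> MinimalFixture:
    """3 cells x 5 circRNAs on 2 chromosomes, 4 miRNAs, all values hand-derived.

    Presence (cells x circA..circE)::

        cell1: 1 1 1 0 0
        cell2: 1 0 1 1 0
        cell3: 1 0 0 0 1

    giving Manhattan distances d12 = 2, d13 = 3, d23 = 3. circA's sequence
    carries an 8mer site for mirA (pattern TGCTGCTA, offset 4); circB's
    carries a 7mer-m8 site for mirB (offset 2); the other sequences and
    miRNAs were chosen seed-disjoint.
    """
    cells = ["cell1", "cell2", "cell3"]
    coords = {
        "circA": ("chr1", 1000, 1250, "+"),
        "circB": ("chr1", 5000, 5200, "-"),
        "circC": ("chr1", 9000, 9300, "+"),
        "circD": ("chr2", 2000, 2260, "+"),
        "circE": ("chr2", 7000, 7180, "-"),
    }
    presence = {
        "cell1": ["circA", "circB", "circC"],
        "cell2": ["circA", "circC", "circD"],
        "cell3": ["circA", "circE"],
    }
    calls = []
    for cell, names in presence.items():
        for name in names:
            chrom, start, end, strand = coords[name]
            for tool in TOOL_ORDER:
                calls.append(
                    CircCall(cell_id=cell, chrom=chrom, start=start, end=end,
                             strand=strand, junction_reads=5, tool=tool)
                )
    circ_ids = {n: f"{c}:{s}-{e}:{st}" for n, (c, s, e, st) in coords.items()}
    feat = [circ_ids[n] for n in ("circA", "circB", "circC", "circD", "circE")]
    assert feat == sorted(feat)  # id order matches presence_matrix's sorted features
    exp_presence = pd.DataFrame(
        [[1, 1, 1, 0, 0], [1, 0, 1, 1, 0], [1, 0, 0, 0, 1]],
        index=cells, columns=feat, dtype=float,
    )
    exp_manhattan = pd.DataFrame(
        [[0, 2, 3], [2, 0, 3], [3, 3, 0]], index=cells, columns=cells, dtype=float
    )
    mirnas = [
        MiRNA("mirA", "UAGCAGCACGUAAAUAUUGGCG"),  # seed 2-8 AGCAGCA -> site TGCTGCT(+A)
        MiRNA("mirB", "UGAGGUAGUAGGUUGUAUAGUU"),  # seed 2-8 GAGGUAG -> site CTACCTC
        MiRNA("mirC", "ACCCGUAGAACCGACCUUGCG"),
        MiRNA("mirD", "UCACAGUGAACCGGUCUCUUU"),
    ]
    circ_seqs = {
        circ_ids["circA"]: "GGGGTGCTGCTACCCGGTTTCC",  # 8mer for mirA at offset 4
        circ_ids["circB"]: "TTCTACCTCGGATTGGGATTAA",  # 7mer-m8 for mirB at offset 2
        circ_ids["circC"]: "GGGGGGGGGGGGGGGGGGGG",
        circ_ids["circD"]: "CCCCCCCCCCCCCCCCCCCC",
        circ_ids["circE"]: "GTGTGTGTGTGTGTGTGTGT",
    }
    expected = [
        (circ_ids["circA"], "mirA", 4, "8mer"),
        (circ_ids["circB"], "mirB", 2, "7mer-m8"),
    ]
    return MinimalFixture(
        cells=cells,
        circs=pd.DataFrame(
            [(n,) + coords[n] + (circ_ids[n],) for n in coords],
            columns=["name", "chrom", "start", "end", "strand", "circ_id"],
        ),
        calls=calls,
        expected_presence=exp_presence,
        expected_manhattan=exp_manhattan,
        mirnas=mirnas,
        circ_seqs=circ_seqs,
        expected_seed_matches=expected,
        chrom_lengths={"chr1": 50_000, "chr2": 20_000},
    )
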