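"""Readers and writers for the external formats the pipeline touches.

All genomic coordinates are normalized to a single internal convention:
0-based, half-open (BED-style). Detector dialects that report 1-based
inclusive regions (CIRI) have their start decremented on input and
incremented on output, so every conversion is an exact inverse bijection.
Chromosome names are canonicalized to the ``chr``-prefixed form.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field

import gffutils
from Bio import SeqIO
from cyvcf2 import VCF
from intervaltree import IntervalTree

from .errors import ConfigurationError, ParseError

logger = logging.getLogger(__name__)

TOOLS = ("ciri", "find_circ", "circexplorer", "circrnafinder")

_NUCLEOTIDES = set("ACGT")


def normalize_chrom(chrom: str) -> str:
    """Canonicalize a chromosome name to the ``chr``-prefixed form."""
    chrom = chrom.strip()
    if not chrom:
        raise ParseError("empty chromosome name")
    if chrom.upper() in ("MT", "M"):
        return "chrM"
    return chrom if chrom.startswith("chr") else "chr" + chrom


@dataclass(frozen=True)
class CircCall:
    """One back-splice junction observed in one cell by one detector.

    Coordinates are internal 0-based half-open; ``junction_reads`` is the
    number of reads spanning the back-splice junction.
    """

    cell_id: str
    chrom: str
    start: int
    end: int
    strand: str
    junction_reads: int
    tool: str
    host_gene: str | None = None

    def __post_init__(self):
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if not self.start < self.end:
            raise ValueError(f"require start < end, got {self.start} >= {self.end}")
        if self.junction_reads < 0:
            raise ValueError("junction_reads must be non-negative")
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"invalid strand {self.strand!r}")
        if self.tool not in TOOLS:
            raise ValueError(f"unknown tool {self.tool!r}")

    @property
    def circ_id(self) -> str:
        return f"{self.chrom}:{self.start}-{self.end}:{self.strand}"


@dataclass(frozen=True)
class SnpRecord:
    """A biallelic SNP call from one caller in one cell (0-based position)."""

    cell_id: str
    chrom: str
    pos: int
    ref: str
    alt: str
    qual: float
    qd: float | None
    dp: int | None
    fs: float | None
    caller: str

    def __post_init__(self):
        for name in ("qual", "qd", "dp", "fs"):
            v = getattr(self, name)
            if v is not None and (v != v or v < 0):  # NaN or negative
                raise ValueError(f"{name} must be finite and non-negative, got {v}")
        if self.caller not in ("gatk", "samtools"):
            raise ValueError(f"unknown caller {self.caller!r}")


@dataclass(frozen=True)
class GeneExpression:
    """Per-cell gene abundance: raw read count and FPKM."""

    cell_id: str
    gene_id: str
    read_count: int
    fpkm: float

    def __post_init__(self):
        if self.read_count < 0:
            raise ValueError("read_count must be non-negative")
        if self.fpkm < 0:
            raise ValueError("fpkm must be non-negative")


@dataclass(frozen=True)
class ChromInfo:
    chrom: str
    length: int

    def __post_init__(self):
        if self.length <= 0:
            raise ValueError("chromosome length must be positive")


# ---------------------------------------------------------------------------
# circRNA detector dialects
# ---------------------------------------------------------------------------
#
# find_circ / circRNAFinder: BED6 (chrom start end name score strand) with the
# junction-read count in the score column; coordinates already 0-based
# half-open.
#
# CIRCexplorer: the BED-like annotated output (18 columns); junction reads in
# the readNumber column (13th), host gene in geneName (15th).
#
# CIRI: headered TSV with 1-based inclusive circRNA_start/circRNA_end and a
# '#junction_reads' column; gene_id carries the host gene ('n/a' when absent).

CIRI_HEADER = (
    "circRNA_ID\tchr\tcircRNA_start\tcircRNA_end\t#junction_reads\tSM_MS_SMS\t"
    "#non_junction_reads\tjunction_reads_ratio\tcircRNA_type\tgene_id\tstrand\t"
    "junction_reads_ID"
)


def _parse_bed6(fields, path, lineno, cell_id, tool):
    if len(fields) < 6:
        raise ParseError(f"expected >=6 BED columns, got {len(fields)}", path, lineno)
    try:
        return CircCall(
            cell_id=cell_id,
            chrom=normalize_chrom(fields[0]),
            start=int(fields[1]),
            end=int(fields[2]),
            strand=fields[5],
            junction_reads=int(round(float(fields[4]))),
            tool=tool,
        )
    except (ValueError, ParseError) as exc:
        raise ParseError(f"malformed BED row: {exc}", path, lineno) from exc


def _parse_circexplorer(fields, path, lineno, cell_id):
    if len(fields) < 13:
        raise ParseError(
            f"expected >=13 CIRCexplorer columns, got {len(fields)}", path, lineno
        )
    try:
        host = fields[14] if len(fields) > 14 and fields[14] not in ("", "n/a") else None
        return CircCall(
            cell_id=cell_id,
            chrom=normalize_chrom(fields[0]),
            start=int(fields[1]),
            end=int(fields[2]),
            strand=fields[5],
            junction_reads=int(fields[12]),
            tool="circexplorer",
            host_gene=host,
        )
    except (ValueError, ParseError) as exc:
        raise ParseError(f"malformed CIRCexplorer row: {exc}", path, lineno) from exc


def _parse_ciri(fields, path, lineno, cell_id):
    if len(fields) < 11:
        raise ParseError(f"expected >=11 CIRI columns, got {len(fields)}", path, lineno)
    try:
        gene = fields[9].rstrip(",")
        return CircCall(
            cell_id=cell_id,
            chrom=normalize_chrom(fields[1]),
            start=int(fields[2]) - 1,  # 1-based inclusive -> 0-based half-open
            end=int(fields[3]),
            strand=fields[10],
            junction_reads=int(fields[4]),
            tool="ciri",
            host_gene=None if gene in ("", "n/a") else gene,
        )
    except (ValueError, ParseError) as exc:
        raise ParseError(f"malformed CIRI row: {exc}", path, lineno) from exc


def read_circ_calls(path: str | os.PathLike, dialect: str, cell_id: str) -> list[CircCall]:
    """Read one detector's output for one cell, normalizing coordinates.

    ``dialect`` is one of ``ciri``, ``find_circ``, ``circexplorer``,
    ``circrnafinder``. Raises :class:`ConfigurationError` for an unknown
    dialect and :class:`ParseError` (naming the line) for malformed rows.
    """
    if dialect not in TOOLS:
        raise ConfigurationError(
            f"unknown dialect {dialect!r}; expected one of {TOOLS}"
        )
    calls: list[CircCall] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#") or line.startswith("track"):
                continue
            fields = line.split("\t")
            if dialect == "ciri":
                if lineno == 1 and fields[0] == "circRNA_ID":
                    continue
                calls.append(_parse_ciri(fields, str(path), lineno, cell_id))
            elif dialect == "circexplorer":
                calls.append(_parse_circexplorer(fields, str(path), lineno, cell_id))
            else:
                calls.append(_parse_bed6(fields, str(path), lineno, cell_id, dialect))
    return calls


def write_circ_calls(calls: list[CircCall], path: str | os.PathLike, dialect: str) -> None:
    """Write calls in a detector dialect (the inverse of :func:`read_circ_calls`)."""
    if dialect not in TOOLS:
        raise ConfigurationError(f"unknown dialect {dialect!r}")
    with open(path, "w") as fh:
        if dialect == "ciri":
            fh.write(CIRI_HEADER + "\n")
        for c in calls:
            if dialect == "ciri":
                gene = c.host_gene if c.host_gene else "n/a"
                row = (
                    f"{c.chrom}:{c.start + 1}|{c.end}\t{c.chrom}\t{c.start + 1}\t{c.end}"
                    f"\t{c.junction_reads}\t0_0_0\t0\t0.0\texon\t{gene}\t{c.strand}\t."
                )
            elif dialect == "circexplorer":
                gene = c.host_gene if c.host_gene else "n/a"
                row = "\t".join(
                    [
                        c.chrom,
                        str(c.start),
                        str(c.end),
                        f"circular/{c.junction_reads}",
                        "0",
                        c.strand,
                        str(c.start),
                        str(c.end),
                        "0,0,0",
                        "1",
                        str(c.end - c.start),
                        "0",
                        str(c.junction_reads),
                        "circRNA",
                        gene,
                        "n/a",
                        "1",
                        "n/a",
                    ]
                )
            else:
                name = f"{c.chrom}:{c.start}-{c.end}"
                row = "\t".join(
                    [c.chrom, str(c.start), str(c.end), name, str(c.junction_reads), c.strand]
                )
            fh.write(row + "\n")


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

def read_vcf(path: str | os.PathLike, caller: str, cell_id: str) -> list[SnpRecord]:
    """Read biallelic SNPs from a VCF 4.x file.

    Indels and multi-allelic rows are skipped (their count is logged); QD, DP
    and FS are taken from INFO and recorded as ``None`` when absent.
    """
    if caller not in ("gatk", "samtools"):
        raise ConfigurationError(f"unknown caller {caller!r}")
    try:
        vcf = VCF(str(path))
    except Exception as exc:  # cyvcf2 raises on missing/invalid header
        raise ParseError(f"cannot open VCF: {exc}", str(path)) from exc
    records: list[SnpRecord] = []
    n_skipped = 0
    for var in vcf:
        alts = var.ALT
        if (
            len(alts) != 1
            or len(var.REF) != 1
            or len(alts[0]) != 1
            or var.REF not in _NUCLEOTIDES
            or alts[0] not in _NUCLEOTIDES
        ):
            n_skipped += 1
            continue
        dp = var.INFO.get("DP")
        records.append(
            SnpRecord(
                cell_id=cell_id,
                chrom=normalize_chrom(var.CHROM),
                pos=var.POS - 1,
                ref=var.REF,
                alt=alts[0],
                qual=float(var.QUAL) if var.QUAL is not None else 0.0,
                qd=var.INFO.get("QD"),
                dp=int(dp) if dp is not None else None,
                fs=var.INFO.get("FS"),
                caller=caller,
            )
        )
    vcf.close()
    if n_skipped:
        logger.info("read_vcf(%s): skipped %d non-SNP/multiallelic rows", path, n_skipped)
    return records


# ---------------------------------------------------------------------------
# Expression, chromosome sizes, FASTA
# ---------------------------------------------------------------------------

def read_expression(path: str | os.PathLike, cell_id: str) -> list[GeneExpression]:
    """Read a per-cell expression TSV with columns gene_id, read_count, fpkm."""
    out: list[GeneExpression] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if fields[0] == "gene_id":
                continue
            if len(fields) < 3:
                raise ParseError("expected 3 columns (gene_id, read_count, fpkm)",
                                 str(path), lineno)
            try:
                out.append(
                    GeneExpression(cell_id, fields[0], int(fields[1]), float(fields[2]))
                )
            except ValueError as exc:
                raise ParseError(f"malformed expression row: {exc}", str(path), lineno) from exc
    return out


def read_chrom_info(path: str | os.PathLike) -> list[ChromInfo]:
    """Read a two-column (chrom, length) TSV, e.g. a UCSC chrom.sizes file."""
    out: list[ChromInfo] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise ParseError("expected 2 columns (chrom, length)", str(path), lineno)
            try:
                out.append(ChromInfo(normalize_chrom(fields[0]), int(fields[1])))
            except ValueError as exc:
                raise ParseError(f"malformed chrom row: {exc}", str(path), lineno) from exc
    return out


def read_fasta(path: str | os.PathLike) -> dict[str, str]:
    """Read a FASTA file into an id -> uppercase sequence map."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(seqs: dict[str, str], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i : i + 70] + "\n")


# ---------------------------------------------------------------------------
# Gene interval index (host-gene assignment)
# ---------------------------------------------------------------------------

@dataclass
class GeneIndex:
    """Interval index over gene spans supporting host-gene assignment.

    A junction is assigned to the gene whose span contains both of its
    endpoints. When several genes qualify the tie is broken deterministically:
    same-strand gene first, then largest overlap with the junction span, then
    lexicographically smallest gene id.
    """

    trees: dict[str, IntervalTree] = field(default_factory=dict)

    def add_gene(self, gene_id: str, chrom: str, start: int, end: int, strand: str) -> None:
        chrom = normalize_chrom(chrom)
        self.trees.setdefault(chrom, IntervalTree())[start:end] = (gene_id, strand)

    def assign_host_gene(
        self, chrom: str, start: int, end: int, strand: str = "."
    ) -> str | None:
        tree = self.trees.get(normalize_chrom(chrom))
        if tree is None:
            return None
        candidates = [
            iv for iv in tree[start] if iv.begin <= start and iv.end >= end
        ]
        if not candidates:
            return None

        def key(iv):
            gene_id, gene_strand = iv.data
            same_strand = strand != "." and gene_strand == strand
            overlap = min(iv.end, end) - max(iv.begin, start)
            return (0 if same_strand else 1, -overlap, gene_id)

        return sorted(candidates, key=key)[0].data[0]


def read_gtf_gene_index(path: str | os.PathLike) -> GeneIndex:
    """Build a :class:`GeneIndex` from a GTF annotation.

    Uses ``gene`` features when present; otherwise gene spans are inferred as
    the union of features sharing a ``gene_id``. GTF coordinates (1-based
    inclusive) are converted to the internal convention.
    """
    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
        disable_infer_genes=True,
        disable_infer_transcripts=True,
    )
    index = GeneIndex()
    genes = list(db.features_of_type("gene"))
    if genes:
        for g in genes:
            gene_id = g.attributes.get("gene_id", [g.id])[0]
            index.add_gene(gene_id, g.seqid, g.start - 1, g.end, g.strand)
        return index
    spans: dict[str, list] = {}
    for feat in db.all_features():
        gid = feat.attributes.get("gene_id", [None])[0]
        if gid is None:
            continue
        cur = spans.get(gid)
        if cur is None:
            spans[gid] = [feat.seqid, feat.start - 1, feat.end, feat.strand]
        else:
            cur[1] = min(cur[1], feat.start - 1)
            cur[2] = max(cur[2], feat.end)
    for gid, (chrom, start, end, strand) in spans.items():
        index.add_gene(gid, chrom, start, end, strand)
    return index


# ---------------------------------------------------------------------------
# Network export
# ---------------------------------------------------------------------------

def write_network(graph, path: str | os.PathLike, format: str = "sif") -> None:
    """Export a network as SIF (Cytoscape) or GraphML.

    SIF rows are ``source<TAB>edge_type<TAB>target`` with a deterministic sort.
    """
    import networkx as nx

    if format == "graphml":
        nx.write_graphml(graph, str(path))
    elif format == "sif":
        rows = sorted(
            (str(u), str(data.get("edge_type", "interacts")), str(v))
            for u, v, data in graph.edges(data=True)
        )
        with open(path, "w") as fh:
            for u, etype, v in rows:
                fh.write(f"{u}\t{etype}\t{v}\n")
    else:
        raise ConfigurationError(f"unknown network format {format!r}")


def read_sif(path: str | os.PathLike):
    """Read a SIF file back into a networkx graph (edge_type on each edge)."""
    import networkx as nx

    g = nx.Graph()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != 3:
                raise ParseError("expected 3 SIF columns", str(path), lineno)
            g.add_edge(fields[0], fields[2], edge_type=fields[1])
    return g
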