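"""Per-cell consensus circRNA calling and SNP caller-consensus filtering.

Detectors disagree wildly on circRNA calls (thousands per tool versus a few
hundred shared), so a junction is trusted only when every requested tool
reports it in the same cell. SNPs are trusted only when both GATK and
samtools call the identical variant and it survives the hard filters
QUAL >= 30, QD >= 20.0, DP >= 8 and FS <= 30.0 (removal conditions are
strict inequalities, so boundary values are kept).
"""

from __future__ import annotations

from dataclasses import dataclass
from collections import defaultdict

from .errors import ConfigurationError
from .io import CircCall, SnpRecord, TOOLS

#: Coordinate-priority order: the consensus entry inherits the coordinates
#: (and host gene, when available) of the highest-priority supporting tool.
TOOL_PRIORITY = ("ciri", "circexplorer", "find_circ", "circrnafinder")

#: Hard-filter thresholds (keep side): QUAL >= 30, QD >= 20, DP >= 8, FS <= 30.
DEFAULT_SNP_FILTERS = {"min_qual": 30.0, "min_qd": 20.0, "min_dp": 8, "max_fs": 30.0}


@dataclass(frozen=True)
class ConsensusCircRNA:
    """A back-splice junction supported by every required tool in one cell."""

    circ_id: str
    cell_id: str
    chrom: str
    start: int
    end: int
    strand: str
    junction_reads: int
    supporting_tools: frozenset
    host_gene: str | None = None

    def __post_init__(self):
        if self.junction_reads < 1:
            raise ValueError("a present consensus junction needs >=1 junction read")


@dataclass(frozen=True)
class FilteredSnp:
    """A SNP called by both callers that survives the hard filters."""

    cell_id: str
    chrom: str
    pos: int
    ref: str
    alt: str
    qual: float
    qd: float
    dp: int
    fs: float
    callers: frozenset

    def __post_init__(self):
        for name in ("qual", "qd", "dp", "fs"):
            v = getattr(self, name)
            if v != v or v < 0:
                raise ValueError(f"{name} must be finite and non-negative")
        if not self.callers >= {"gatk", "samtools"}:
            raise ValueError("FilteredSnp requires both callers")

    def satisfies_hard_filters(self, thresholds: dict | None = None) -> bool:
        th = dict(DEFAULT_SNP_FILTERS)
        if thresholds:
            th.update(thresholds)
        return (
            self.qual >= th["min_qual"]
            and self.qd >= th["min_qd"]
            and self.dp >= th["min_dp"]
            and self.fs <= th["max_fs"]
        )


def _matches(a: CircCall, b: CircCall, mode: str, window_bp: int) -> bool:
    if a.chrom != b.chrom or a.strand != b.strand:
        return False
    if mode == "exact":
        return a.start == b.start and a.end == b.end
    return abs(a.start - b.start) <= window_bp and abs(a.end - b.end) <= window_bp


def intersect_calls(
    calls: list[CircCall],
    required_tools: set[str] | None = None,
    match_mode: str = "exact",
    window_bp: int = 2,
    reads_summary: str = "max",
) -> list[ConsensusCircRNA]:
    """Intersect per-cell calls across detectors.

    A junction is retained, per cell, iff a matching junction (same chrom and
    strand; coordinates equal in ``exact`` mode or within ``window_bp`` in
    ``window`` mode) exists for every required tool. The consensus entry takes
    its coordinates from the highest-priority supporting tool
    (ciri > circexplorer > find_circ > circrnafinder) and summarizes
    junction reads as the maximum (or mean) across supporting tools.

    Raises :class:`ConfigurationError` if a required tool contributed no call
    at all — that distinguishes "tool not provided" from "tool found nothing
    in this cell", which is a legitimate empty intersection.
    """
    if required_tools is None:
        required_tools = set(TOOLS)
    required_tools = set(required_tools)
    if not required_tools:
        raise ConfigurationError("required_tools must be non-empty")
    unknown = required_tools - set(TOOLS)
    if unknown:
        raise ConfigurationError(f"unknown tools {sorted(unknown)}")
    if match_mode not in ("exact", "window"):
        raise ConfigurationError(f"unknown match_mode {match_mode!r}")
    if reads_summary not in ("max", "mean"):
        raise ConfigurationError(f"unknown reads_summary {reads_summary!r}")

    tools_seen = {c.tool for c in calls}
    missing = required_tools - tools_seen
    if missing:
        raise ConfigurationError(
            f"required tool(s) {sorted(missing)} absent from the input entirely"
        )

    by_cell: dict[str, dict[str, list[CircCall]]] = defaultdict(lambda: defaultdict(list))
    for c in calls:
        by_cell[c.cell_id][c.tool].append(c)

    priority = [t for t in TOOL_PRIORITY if t in required_tools]
    anchor_tool = priority[0]
    out: list[ConsensusCircRNA] = []
    for cell_id in sorted(by_cell):
        per_tool = by_cell[cell_id]
        seen_ids = set()
        for anchor in sorted(per_tool.get(anchor_tool, ()),
                             key=lambda c: (c.chrom, c.start, c.end, c.strand)):
            support = {anchor_tool: anchor}
            for tool in required_tools - {anchor_tool}:
                hit = next(
                    (c for c in per_tool.get(tool, ())
                     if _matches(anchor, c, match_mode, window_bp)),
                    None,
                )
                if hit is None:
                    break
                support[tool] = hit
            else:
                # every required tool matched; also collect optional extras
                for tool in tools_seen - set(support):
                    hit = next(
                        (c for c in per_tool.get(tool, ())
                         if _matches(anchor, c, match_mode, window_bp)),
                        None,
                    )
                    if hit is not None:
                        support[tool] = hit
                rep = support[next(t for t in TOOL_PRIORITY if t in support)]
                if rep.circ_id in seen_ids:
                    continue
                seen_ids.add(rep.circ_id)
                reads = [s.junction_reads for s in support.values()]
                jr = max(reads) if reads_summary == "max" else int(round(sum(reads) / len(reads)))
                host = next(
                    (support[t].host_gene for t in TOOL_PRIORITY
                     if t in support and support[t].host_gene),
                    None,
                )
                if jr < 1:
                    continue  # a consensus junction with zero reads is not a presence
                out.append(
                    ConsensusCircRNA(
                        circ_id=rep.circ_id,
                        cell_id=cell_id,
                        chrom=rep.chrom,
                        start=rep.start,
                        end=rep.end,
                        strand=rep.strand,
                        junction_reads=jr,
                        supporting_tools=frozenset(support),
                        host_gene=host,
                    )
                )
    return out


def snp_consensus_filter(
    records: list[SnpRecord], thresholds: dict | None = None
) -> list[FilteredSnp]:
    """Keep SNPs called by both callers that survive the hard filters.

    Consensus key is (cell, chrom, pos, ref, alt). Annotation values (QUAL,
    QD, DP, FS) are taken from the GATK record; records with a missing
    annotation cannot be verified against the filters and are dropped.
    """
    th = dict(DEFAULT_SNP_FILTERS)
    if thresholds:
        th.update(thresholds)
    by_key: dict[tuple, dict[str, SnpRecord]] = defaultdict(dict)
    for r in records:
        by_key[(r.cell_id, r.chrom, r.pos, r.ref, r.alt)][r.caller] = r
    out: list[FilteredSnp] = []
    for key in sorted(by_key):
        callers = by_key[key]
        if not {"gatk", "samtools"} <= set(callers):
            continue
        g = callers["gatk"]
        if g.qd is None or g.dp is None or g.fs is None:
            continue
        if (
            g.qual >= th["min_qual"]
            and g.qd >= th["min_qd"]
            and g.dp >= th["min_dp"]
            and g.fs <= th["max_fs"]
        ):
            out.append(
                FilteredSnp(
                    cell_id=g.cell_id,
                    chrom=g.chrom,
                    pos=g.pos,
                    ref=g.ref,
                    alt=g.alt,
                    qual=g.qual,
                    qd=g.qd,
                    dp=g.dp,
                    fs=g.fs,
                    callers=frozenset(callers),
                )
            )
    return out
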