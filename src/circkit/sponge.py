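"""miRNA seed-match scanning on circRNA sequences and ceRNA network assembly.

A candidate miRNA binding site is the reverse complement of the miRNA seed
(nucleotides 2-7 or 2-8, numbered from the miRNA 5' end) on the circRNA
sequence, graded by the canonical site classes:

* ``6mer``: match to positions 2-7;
* ``7mer-A1``: 6mer plus an A on the target opposite miRNA position 1;
* ``7mer-m8``: match to positions 2-8;
* ``8mer``: 7mer-m8 plus the A1 anchor.

Because a circRNA is a covalently closed loop, scanning optionally wraps
around the back-splice junction. circRNA sequences are scanned in sense
orientation (the mature circle is single-stranded); G:U wobble is not
considered. Networks are tripartite: circRNA-miRNA edges from seed matches,
miRNA-gene edges from a user-supplied association table.
"""

from __future__ import annotations

from dataclasses import dataclass
from collections import Counter, defaultdict

import networkx as nx

from .errors import ConfigurationError

MATCH_CLASSES = ("6mer", "7mer-A1", "7mer-m8", "8mer")
_CLASS_RANK = {c: i for i, c in enumerate(MATCH_CLASSES)}

_COMPLEMENT = str.maketrans("ACGTU", "TGCAA")


def reverse_complement(seq: str) -> str:
    """Reverse complement into the DNA alphabet (U treated as T)."""
    return seq.upper().translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class MiRNA:
    """A mature miRNA, 5'->3', over the RNA alphabet."""

    mirna_id: str
    sequence: str

    def __post_init__(self):
        seq = self.sequence.upper().replace("T", "U")
        object.__setattr__(self, "sequence", seq)
        if len(seq) < 8:
            raise ValueError(f"{self.mirna_id}: mature miRNA must be >=8 nt")
        if set(seq) - set("ACGU"):
            raise ValueError(f"{self.mirna_id}: sequence must be A/C/G/U")

    @property
    def seed(self) -> str:
        """Seed region, miRNA positions 2-8 (1-based), 5'->3'."""
        return self.sequence[1:8]


@dataclass(frozen=True)
class SeedMatch:
    """One predicted miRNA binding site on a circRNA sequence.

    ``site_start`` is the 0-based offset of the matched region's first base
    (modular, i.e. may wrap past the sequence end for junction-spanning
    sites); ``site_len`` the matched-region length on the target.
    """

    circ_id: str
    mirna_id: str
    site_start: int
    site_len: int
    match_class: str

    def __post_init__(self):
        if self.match_class not in MATCH_CLASSES:
            raise ValueError(f"unknown match class {self.match_class!r}")


def _site_patterns(mirna: MiRNA) -> dict[str, str]:
    """Target-strand (5'->3') patterns for each site class.

    Antiparallel pairing puts the complement of miRNA position 8 first on the
    target and the position-1 anchor (an A on the target) last.
    """
    seed27 = mirna.sequence[1:7]
    seed28 = mirna.sequence[1:8]
    rc27 = reverse_complement(seed27)
    rc28 = reverse_complement(seed28)
    return {
        "6mer": rc27,
        "7mer-A1": rc27 + "A",
        "7mer-m8": rc28,
        "8mer": rc28 + "A",
    }


def scan_seed_sites(
    circ_seq: str,
    mirnas: list[MiRNA],
    min_class: str = "7mer-m8",
    circ_id: str = "circ",
    circular: bool = False,
) -> list[SeedMatch]:
    """Scan a circRNA sequence for miRNA seed-match sites.

    Each position where the reverse complement of the miRNA 6mer core
    (positions 2-7) occurs is graded to its best-supported class (does the
    m8 complement precede it? is there an A anchor after it?) and reported if
    that class is at least ``min_class`` in the order
    6mer < 7mer-A1 < 7mer-m8 < 8mer. Overlapping sites are all reported;
    ``N`` positions never match. With ``circular=True`` indexing is modular,
    so sites spanning the back-splice (end -> start) junction are found and
    reported with wrapped coordinates.
    """
    if min_class not in MATCH_CLASSES:
        raise ConfigurationError(f"unknown match class {min_class!r}")
    seq = circ_seq.upper().replace("U", "T")
    L = len(seq)
    wrap = circular and L >= 8
    if L < 6:
        return []
    out: list[SeedMatch] = []
    min_rank = _CLASS_RANK[min_class]
    core_starts = range(L) if wrap else range(L - 5)
    for mir in mirnas:
        patterns = _site_patterns(mir)
        core = patterns["6mer"]
        m8_char = patterns["7mer-m8"][0]
        for j in core_starts:
            if wrap:
                if any(seq[(j + k) % L] != core[k] for k in range(6)):
                    continue
                m8 = seq[(j - 1) % L] == m8_char
                a1 = seq[(j + 6) % L] == "A"
            else:
                if seq[j : j + 6] != core:
                    continue
                m8 = j >= 1 and seq[j - 1] == m8_char
                a1 = j + 6 < L and seq[j + 6] == "A"
            if m8 and a1:
                cls = "8mer"
            elif m8:
                cls = "7mer-m8"
            elif a1:
                cls = "7mer-A1"
            else:
                cls = "6mer"
            if _CLASS_RANK[cls] < min_rank:
                continue
            start = (j - 1) % L if (m8 and wrap) else (j - 1 if m8 else j)
            out.append(SeedMatch(circ_id, mir.mirna_id, start, len(patterns[cls]), cls))
    return sorted(out, key=lambda m: (m.mirna_id, m.site_start))


def circ_junction_site_scan(
    circ_seq: str,
    mirnas: list[MiRNA],
    min_class: str = "7mer-m8",
    circ_id: str = "circ",
) -> list[SeedMatch]:
    """Seed sites that span the back-splice (end -> start) junction only.

    A circular scan finds all sites with modular coordinates; the ones whose
    matched region runs past the sequence end (``site_start + site_len >
    len(circ_seq)``) are exactly those a linear scan misses.
    """
    L = len(circ_seq)
    full = scan_seed_sites(circ_seq, mirnas, min_class, circ_id, circular=True)
    return [m for m in full if m.site_start + m.site_len > L]


def verify_match(circ_seq: str, mirna: MiRNA, match: SeedMatch) -> bool:
    """Re-check a reported site by direct reverse-complement comparison."""
    seq = circ_seq.upper().replace("U", "T")
    L = len(seq)
    site = "".join(seq[(match.site_start + k) % L] for k in range(match.site_len))
    return site == _site_patterns(mirna)[match.match_class]


def build_network(
    seed_matches: list[SeedMatch],
    mirna_gene_table: list[tuple[str, str]],
    restrict_genes: set[str] | None = None,
) -> nx.Graph:
    """Assemble the tripartite circRNA-miRNA-gene (ceRNA) network.

    Nodes carry a ``node_type`` in {circRNA, miRNA, gene}; edges carry an
    ``edge_type`` ('circ-mir' for seed matches, 'mir-gene' for association
    rows) and a ``multiplicity`` counting collapsed duplicates. Only miRNAs
    with at least one seed match enter the network; gene edges attach to
    those miRNAs from the association table, optionally restricted to
    ``restrict_genes`` (an empty set empties the gene layer without touching
    circRNA-miRNA edges).
    """
    g = nx.Graph()
    circ_mir = Counter((m.circ_id, m.mirna_id) for m in seed_matches)
    for (circ, mir), mult in sorted(circ_mir.items()):
        g.add_node(circ, node_type="circRNA")
        g.add_node(mir, node_type="miRNA")
        g.add_edge(circ, mir, edge_type="circ-mir", multiplicity=mult)
    matched_mirnas = {m.mirna_id for m in seed_matches}
    mir_gene = Counter(
        (mir, gene)
        for mir, gene in mirna_gene_table
        if mir in matched_mirnas
        and (restrict_genes is None or gene in restrict_genes)
    )
    for (mir, gene), mult in sorted(mir_gene.items()):
        g.add_node(gene, node_type="gene")
        g.add_edge(mir, gene, edge_type="mir-gene", multiplicity=mult)
    return g


def top_regulator_mirnas(seed_matches: list[SeedMatch], k: int | None = None) -> list[tuple[str, int]]:
    """miRNAs ranked by the number of distinct circRNAs they match.

    Ties are broken by miRNA id; ``k`` larger than the miRNA count (or None)
    returns the full ranking.
    """
    per_mirna = defaultdict(set)
    for m in seed_matches:
        per_mirna[m.mirna_id].add(m.circ_id)
    ranking = sorted(
        ((mir, len(circs)) for mir, circs in per_mirna.items()),
        key=lambda kv: (-kv[1], kv[0]),
    )
    return ranking if k is None else ranking[:k]
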