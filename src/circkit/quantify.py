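"""circRNA expression quantities and cell-level heterogeneity statistics.

Two back-splice-read normalizations are provided:

* the circRNA-gene ratio, ``CGR = junction_reads / host_gene_reads``, and
* a library- and host-normalized FPKM analogue,
  ``circ_FPKM = junction_reads / (mapped_reads_millions * host_gene_FPKM)``.

Zero denominators yield NaN ("not assessable") rather than an error, and
NaN pairs are dropped before correlation. Heterogeneity between cells is the
Manhattan distance between their circRNA presence/absence profiles, i.e. the
number of discordant circRNAs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy as _hier
from scipy.spatial.distance import pdist, squareform
from scipy import stats as _stats

from .consensus import ConsensusCircRNA
from .errors import ConfigurationError, DomainError

NA = float("nan")


def compute_cgr(junction_reads: int, host_reads: int) -> float:
    """circRNA-gene ratio: junction-spanning reads over host-gene reads.

    Returns NaN when the host gene has zero reads.
    """
    if junction_reads < 0 or host_reads < 0:
        raise DomainError("read counts must be non-negative")
    if host_reads == 0:
        return NA
    return junction_reads / host_reads


def compute_circ_fpkm(
    junction_reads: int, mapped_reads_millions: float, host_fpkm: float
) -> float:
    """circRNA FPKM: junction reads over (library size in millions x host FPKM).

    Returns NaN when either denominator term is zero.
    """
    if junction_reads < 0 or mapped_reads_millions < 0 or host_fpkm < 0:
        raise DomainError("inputs must be non-negative")
    if mapped_reads_millions == 0 or host_fpkm == 0:
        return NA
    return junction_reads / (mapped_reads_millions * host_fpkm)


@dataclass(frozen=True)
class CircExpression:
    """One circRNA's abundance in one cell under both normalizations."""

    circ_id: str
    cell_id: str
    junction_reads: int
    cgr: float
    circ_fpkm: float
    host_gene: str | None
    host_fpkm: float
    host_reads: int
    mapped_reads_millions: float


def circ_expression_table(
    consensus: list[ConsensusCircRNA],
    expression: dict[str, dict[str, tuple[int, float]]],
    library_sizes: dict[str, float],
) -> list[CircExpression]:
    """Join consensus circRNAs with host-gene expression per cell.

    ``expression`` maps cell_id -> gene_id -> (read_count, fpkm);
    ``library_sizes`` maps cell_id -> total mapped reads. circRNAs without a
    host-gene assignment get NaN for both normalized quantities.
    """
    out = []
    for c in consensus:
        mapped_millions = library_sizes.get(c.cell_id, 0.0) / 1e6
        host_reads, host_fpkm = 0, 0.0
        if c.host_gene is not None:
            host_reads, host_fpkm = expression.get(c.cell_id, {}).get(c.host_gene, (0, 0.0))
        out.append(
            CircExpression(
                circ_id=c.circ_id,
                cell_id=c.cell_id,
                junction_reads=c.junction_reads,
                cgr=compute_cgr(c.junction_reads, host_reads),
                circ_fpkm=compute_circ_fpkm(c.junction_reads, mapped_millions, host_fpkm),
                host_gene=c.host_gene,
                host_fpkm=host_fpkm,
                host_reads=host_reads,
                mapped_reads_millions=mapped_millions,
            )
        )
    return out


@dataclass
class CellFeatureMatrix:
    """A cells x features matrix (presence/absence or expression values)."""

    cells: list[str]
    features: list[str]
    values: np.ndarray
    kind: str = "presence"  # or "expression"

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.cells), len(self.features)):
            raise ValueError(
                f"matrix shape {self.values.shape} inconsistent with "
                f"{len(self.cells)} cells x {len(self.features)} features"
            )
        if self.kind == "presence" and not np.isin(self.values, (0.0, 1.0)).all():
            raise ValueError("presence matrices may contain only 0/1")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.cells, columns=self.features)


def presence_matrix(
    consensus: list[ConsensusCircRNA], cells: list[str] | None = None
) -> CellFeatureMatrix:
    """Build the cells x circRNAs 0/1 incidence matrix.

    An entry is 1 iff the cell carries at least one consensus junction read
    for that circRNA; features are the union of circRNAs over all cells,
    sorted for determinism.
    """
    if cells is None:
        cells = sorted({c.cell_id for c in consensus})
    features = sorted({c.circ_id for c in consensus})
    m = np.zeros((len(cells), len(features)))
    cell_pos = {c: i for i, c in enumerate(cells)}
    feat_pos = {f: j for j, f in enumerate(features)}
    for c in consensus:
        if c.cell_id in cell_pos and c.junction_reads >= 1:
            m[cell_pos[c.cell_id], feat_pos[c.circ_id]] = 1.0
    return CellFeatureMatrix(list(cells), features, m, kind="presence")


def manhattan_distances(m: CellFeatureMatrix) -> pd.DataFrame:
    """Pairwise Manhattan (cityblock) distance between cell profiles.

    On a presence/absence matrix this is the count of discordant circRNAs
    between two cells. Returned as a symmetric cells x cells DataFrame with
    a zero diagonal.
    """
    if len(m.cells) < 1:
        raise DomainError("need at least one cell")
    d = squareform(pdist(m.values, metric="cityblock")) if len(m.cells) > 1 else np.zeros((1, 1))
    return pd.DataFrame(d, index=m.cells, columns=m.cells)


@dataclass
class Dendrogram:
    """Result of agglomerative clustering: scipy linkage matrix + labels."""

    linkage: np.ndarray
    labels: list[str]
    method: str
    metric: str
    _tree: object = field(default=None, repr=False)

    def merge_heights(self) -> list[float]:
        return [float(h) for h in self.linkage[:, 2]]

    def leaf_order(self) -> list[str]:
        return [self.labels[i] for i in _hier.leaves_list(self.linkage)]

    def to_newick(self) -> str:
        """Serialize the tree as a Newick string with branch lengths."""
        tree = _hier.to_tree(self.linkage)

        def walk(node, parent_height):
            length = parent_height - (0.0 if node.is_leaf() else node.dist)
            if node.is_leaf():
                return f"{self.labels[node.id]}:{parent_height:g}"
            left = walk(node.left, node.dist)
            right = walk(node.right, node.dist)
            return f"({left},{right}):{max(length, 0.0):g}"

        return f"({walk(tree.left, tree.dist)},{walk(tree.right, tree.dist)});"


def hierarchical_cluster(
    m: CellFeatureMatrix, linkage: str = "average", metric: str = "manhattan"
) -> Dendrogram:
    """Agglomerative clustering of cells by their circRNA profiles.

    Ward linkage requires the Euclidean metric. Ties between equal-height
    merges are resolved by input position, so the result is deterministic for
    a fixed cell order; cells are typically supplied sorted by id.
    """
    if len(m.cells) < 2:
        raise DomainError("clustering requires at least 2 cells")
    if linkage not in ("average", "complete", "ward", "single"):
        raise ConfigurationError(f"unknown linkage {linkage!r}")
    if metric not in ("manhattan", "euclidean", "correlation"):
        raise ConfigurationError(f"unknown metric {metric!r}")
    if linkage == "ward" and metric != "euclidean":
        raise ConfigurationError("ward linkage requires the euclidean metric")
    scipy_metric = "cityblock" if metric == "manhattan" else metric
    condensed = pdist(m.values, metric=scipy_metric)
    z = _hier.linkage(condensed, method=linkage)
    return Dendrogram(linkage=z, labels=list(m.cells), method=linkage, metric=metric)


def pearson_correlation(x, y, pairing: str = "raw") -> tuple[float, float]:
    """Sample Pearson r and two-sided p between paired vectors.

    NaN pairs are dropped first; with ``pairing='log10'`` both vectors are
    log10-transformed and non-positive pairs are dropped as well. Requires at
    least 3 complete pairs.
    """
    if pairing not in ("raw", "log10"):
        raise ConfigurationError(f"unknown pairing {pairing!r}")
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise DomainError("x and y must have equal length")
    keep = ~(np.isnan(x) | np.isnan(y))
    if pairing == "log10":
        keep &= (x > 0) & (y > 0)
    x, y = x[keep], y[keep]
    if pairing == "log10":
        x, y = np.log10(x), np.log10(y)
    if x.size < 3:
        raise DomainError(f"need >=3 complete pairs, got {x.size}")
    r, p = _stats.pearsonr(x, y)
    return float(r), float(p)


def circ_count_ttest(counts_a, counts_b=None, popmean: float = 0.0) -> tuple[float, float]:
    """t-test on per-cell circRNA counts.

    Two-sample (Welch) when ``counts_b`` is given, else one-sample against
    ``popmean``. Returns (t, two-sided p).
    """
    a = np.asarray(counts_a, dtype=float)
    if counts_b is None:
        t, p = _stats.ttest_1samp(a, popmean)
    else:
        t, p = _stats.ttest_ind(a, np.asarray(counts_b, dtype=float), equal_var=False)
    return float(t), float(p)


def is_na(x: float) -> bool:
    return isinstance(x, float) and math.isnan(x)
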