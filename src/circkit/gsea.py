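"""Ranked-list enrichment of circRNA host genes (running-sum GSEA).

The statistic walks a ranked gene list from top to bottom, incrementing a
running sum at each query-set ("hit") gene and decrementing it at each miss;
the enrichment score (ES) is the running-sum value of maximum absolute
deviation from zero. With ``weight_p=0`` hits contribute equally (the classic
Kolmogorov-Smirnov walk); with ``weight_p=1`` each hit contributes in
proportion to the absolute value of its ranking metric. Significance comes
from a gene-label permutation null (there is no phenotype axis here).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigurationError, DomainError


@dataclass
class RankedGeneList:
    """Genes ordered by a non-increasing metric, plus a query gene set."""

    genes: list[str]
    metric: np.ndarray
    query_set: frozenset

    def __post_init__(self):
        self.metric = np.asarray(self.metric, dtype=float)
        if len(self.genes) != self.metric.size:
            raise ValueError("genes and metric must have equal length")
        if np.any(np.diff(self.metric) > 0):
            raise ValueError("metric must be sorted non-increasing")
        self.query_set = frozenset(self.query_set)


def make_ranked_list(metric_by_gene: dict[str, float], query_set) -> RankedGeneList:
    """Rank genes by metric, high to low; ties broken by gene id (stable)."""
    items = sorted(metric_by_gene.items(), key=lambda kv: (-kv[1], kv[0]))
    genes = [g for g, _ in items]
    metric = np.array([m for _, m in items], dtype=float)
    return RankedGeneList(genes, metric, frozenset(query_set))


@dataclass
class EnrichmentResult:
    es: float
    running_sum: np.ndarray
    hit_positions: list[int]
    n_perm: int = 0
    perm_p: float | None = None
    weight_p: int = 0
    es_null: np.ndarray | None = field(default=None, repr=False)


def _hit_mask(ranked: RankedGeneList) -> np.ndarray:
    return np.fromiter((g in ranked.query_set for g in ranked.genes), bool,
                       count=len(ranked.genes))


def _running_sum(metric: np.ndarray, hits: np.ndarray, weight_p: int) -> np.ndarray:
    n = metric.size
    n_hit = int(hits.sum())
    if weight_p == 0:
        w = np.ones(n)
    else:
        w = np.abs(metric)
        if w[hits].sum() == 0:  # all-zero hit weights: fall back to equal weights
            w = np.ones(n)
    steps = np.where(hits, w / w[hits].sum(), -1.0 / (n - n_hit))
    return np.cumsum(steps)


def enrichment_score(ranked: RankedGeneList, weight_p: int = 1) -> EnrichmentResult:
    """Compute the running-sum enrichment score of the query set.

    ES is the signed running-sum value at the position of maximum absolute
    deviation from zero; positive ES means the query genes concentrate at the
    top of the list.
    """
    if weight_p not in (0, 1):
        raise ConfigurationError("weight_p must be 0 or 1")
    n = len(ranked.genes)
    if n < 2:
        raise DomainError("ranked list must have length >= 2")
    hits = _hit_mask(ranked)
    n_hit = int(hits.sum())
    if n_hit == 0 or n_hit == n:
        raise DomainError(
            "query set must intersect the list without covering it entirely"
        )
    rs = _running_sum(ranked.metric, hits, weight_p)
    idx = int(np.argmax(np.abs(rs)))
    return EnrichmentResult(
        es=float(rs[idx]),
        running_sum=rs,
        hit_positions=list(np.nonzero(hits)[0]),
        weight_p=weight_p,
    )


def permutation_p(
    ranked: RankedGeneList,
    n_perm: int = 1000,
    seed: int = 0,
    weight_p: int = 1,
) -> EnrichmentResult:
    """Permutation p-value for the enrichment score.

    The null permutes query-set membership over gene labels (set size fixed),
    recomputing ES for each permutation;
    ``perm_p = (1 + #{|ES*| >= |ES|}) / (1 + n_perm)`` — the +1 pseudo-count
    avoids zero p-values. Deterministic for a fixed seed.
    """
    if n_perm < 100:
        raise ConfigurationError("n_perm must be >= 100")
    res = enrichment_score(ranked, weight_p=weight_p)
    n = len(ranked.genes)
    n_hit = len(res.hit_positions)
    rng = np.random.default_rng(seed)
    metric = ranked.metric
    w = np.ones(n) if weight_p == 0 else np.abs(metric)
    if weight_p == 1 and w.sum() == 0:
        w = np.ones(n)
    # vectorized: each row is one permuted hit mask
    masks = np.zeros((n_perm, n), dtype=bool)
    for i in range(n_perm):
        masks[i, rng.choice(n, size=n_hit, replace=False)] = True
    hit_w = np.where(masks, w, 0.0)
    denom = hit_w.sum(axis=1, keepdims=True)
    denom[denom == 0] = 1.0
    steps = hit_w / denom - (~masks) * (1.0 / (n - n_hit))
    rs = np.cumsum(steps, axis=1)
    es_null = rs[np.arange(n_perm), np.argmax(np.abs(rs), axis=1)]
    perm_p = (1.0 + np.sum(np.abs(es_null) >= abs(res.es))) / (1.0 + n_perm)
    res.n_perm = n_perm
    res.perm_p = float(perm_p)
    res.es_null = es_null
    return res


def build_ranked_lists(
    fpkm_by_gene: dict[str, float],
    snp_count_by_gene: dict[str, int],
    mirna_sites_by_gene: dict[str, int],
    host_genes,
) -> dict[str, RankedGeneList]:
    """Build the three ranked lists the host-gene enrichment is run against.

    * ``expression``: genes with FPKM > 0 ranked by FPKM;
    * ``snp``: genes with >=1 filtered SNP ranked by SNP count;
    * ``mirna``: genes with >=1 miRNA seed site ranked by site count.

    Each list's query set is the subset of circRNA host genes present in it.
    """
    host_genes = frozenset(host_genes)
    lists: dict[str, RankedGeneList] = {}
    for name, table in (
        ("expression", {g: v for g, v in fpkm_by_gene.items() if v > 0}),
        ("snp", {g: float(v) for g, v in snp_count_by_gene.items() if v >= 1}),
        ("mirna", {g: float(v) for g, v in mirna_sites_by_gene.items() if v >= 1}),
    ):
        if table:
            lists[name] = make_ranked_list(table, host_genes & set(table))
    return lists
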