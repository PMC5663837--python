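"""Chromosome-level feature densities and length-proportional enrichment.

Feature counts are normalized by chromosome length with fixed scale factors
(1e8 for circRNAs, 1e6 for SNPs) so densities are comparable across
chromosomes. Enrichment is tested per chromosome against the uniform
null that a feature lands on chromosome c with probability
length_c / total_length: a one-sided exact binomial test by default (counts
per cell are small), with a one-sided chi-square approximation as an
alternative, and Benjamini-Hochberg adjustment across chromosomes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as _stats
from statsmodels.stats.multitest import multipletests

from .errors import ConfigurationError, DomainError
from .io import ChromInfo

CIRC_SCALE = 10**8
SNP_SCALE = 10**6


def circrna_freq(count: int, chrom_length: int) -> float:
    """Length-normalized circRNA density: 1e8 x count / chromosome length."""
    if chrom_length <= 0:
        raise DomainError("chrom_length must be positive")
    if count < 0:
        raise DomainError("count must be non-negative")
    return CIRC_SCALE * count / chrom_length


def snp_freq(count: int, chrom_length: int) -> float:
    """Length-normalized SNP density: 1e6 x count / chromosome length."""
    if chrom_length <= 0:
        raise DomainError("chrom_length must be positive")
    if count < 0:
        raise DomainError("count must be non-negative")
    return SNP_SCALE * count / chrom_length


@dataclass(frozen=True)
class ChromProfile:
    cell_id: str
    chrom: str
    feature_count: int
    chrom_length: int
    freq: float
    expected_count: float
    p_value: float
    q_value: float


def chromosome_enrichment(
    counts: dict[str, int],
    chrom_lengths: list[ChromInfo] | dict[str, int],
    feature: str = "circ",
    test: str = "binomial",
    cell_id: str = "pooled",
) -> list[ChromProfile]:
    """Per-chromosome one-sided enrichment against length-proportional expectation.

    Chromosomes present in ``chrom_lengths`` but with no observed feature are
    retained with count 0 (and freq 0). A chromosome with a count but no
    length entry is an error. Returns one :class:`ChromProfile` per
    chromosome, sorted by name, with BH-adjusted q-values.
    """
    if feature not in ("circ", "snp"):
        raise ConfigurationError(f"unknown feature {feature!r}")
    if test not in ("binomial", "chisq"):
        raise ConfigurationError(f"unknown test {test!r}")
    lengths = (
        {c.chrom: c.length for c in chrom_lengths}
        if not isinstance(chrom_lengths, dict)
        else dict(chrom_lengths)
    )
    if len(lengths) < 2:
        raise DomainError("need at least 2 chromosomes")
    missing = set(counts) - set(lengths)
    if missing:
        raise DomainError(f"chromosome(s) with counts but no length: {sorted(missing)}")
    total = sum(counts.values())
    if total < 1:
        raise DomainError("total feature count must be >= 1")
    total_len = sum(lengths.values())
    freq_fn = circrna_freq if feature == "circ" else snp_freq

    chroms = sorted(lengths)
    pvals = []
    rows = []
    for chrom in chroms:
        k = int(counts.get(chrom, 0))
        p0 = lengths[chrom] / total_len
        expected = total * p0
        if test == "binomial":
            p = float(_stats.binom.sf(k - 1, total, p0))  # P(X >= k)
        else:
            # one-sided 1-df chi-square on the 2-cell table (this chrom vs rest)
            stat = (k - expected) ** 2 / (expected * (1 - p0)) if expected > 0 else 0.0
            tail = float(_stats.chi2.sf(stat, df=1)) / 2.0
            p = tail if k >= expected else 1.0 - tail
        pvals.append(min(p, 1.0))
        rows.append((chrom, k, lengths[chrom], freq_fn(k, lengths[chrom]), expected))
    qvals = multipletests(pvals, method="fdr_bh")[1]
    return [
        ChromProfile(cell_id, chrom, k, length, freq, expected, p, float(q))
        for (chrom, k, length, freq, expected), p, q in zip(rows, pvals, qvals)
    ]


def freq_heatmap_table(
    profiles: dict[str, list[ChromProfile]],
    zscore: bool = False,
    cluster: bool = True,
) -> pd.DataFrame:
    """Cells x chromosomes table of densities, optionally z-scored and clustered.

    ``profiles`` maps cell_id -> that cell's :func:`chromosome_enrichment`
    output. Z-scoring is per column; zero-variance columns map to 0. With
    ``cluster=True`` (and >=2 cells) rows and columns are reordered by
    average-linkage euclidean clustering for heatmap display.
    """
    cells = sorted(profiles)
    chroms = sorted({p.chrom for plist in profiles.values() for p in plist})
    mat = pd.DataFrame(0.0, index=cells, columns=chroms)
    for cell, plist in profiles.items():
        for p in plist:
            mat.loc[cell, p.chrom] = p.freq
    if zscore:
        mu = mat.mean(axis=0)
        sd = mat.std(axis=0, ddof=0)
        mat = (mat - mu).div(sd.replace(0.0, np.nan), axis=1).fillna(0.0)
    if cluster and len(cells) >= 2:
        from .quantify import CellFeatureMatrix, hierarchical_cluster

        row_order = hierarchical_cluster(
            CellFeatureMatrix(cells, chroms, mat.values, kind="expression"),
            linkage="average",
            metric="euclidean",
        ).leaf_order()
        mat = mat.loc[row_order]
        if len(chroms) >= 2:
            col_order = hierarchical_cluster(
                CellFeatureMatrix(chroms, cells, mat.values.T, kind="expression"),
                linkage="average",
                metric="euclidean",
            ).leaf_order()
            mat = mat[col_order]
    return mat
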