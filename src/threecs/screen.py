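"""Screen-level arithmetic on count tables.

Gene aggregation (sum guide counts per gene, normalize per sample total),
log2 fold changes between samples, replicate correlation, fold-change
enrichment filtering, and replicate intersection — the bookkeeping layer a
pooled-screen analysis needs before any dedicated hit-calling statistics.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Optional

import numpy as np
import pandas as pd
from scipy import stats

from .readqc import CountTable, CLASS_LIBRARY, CLASS_PATTERN_NOVEL


@dataclass
class GeneTable:
    """Gene -> per-sample summed raw counts; normalization divides each
    sample column by its total so normalized values sum to 1."""

    counts: pd.DataFrame
    unmapped: pd.DataFrame

    @property
    def samples(self) -> list[str]:
        return list(self.counts.columns)

    def normalized(self) -> pd.DataFrame:
        totals = self.counts.sum(axis=0)
        if (totals == 0).any():
            raise ValueError("a sample has zero counts; cannot normalize")
        return self.counts / totals


def aggregate_genes(
    table: CountTable | pd.DataFrame, annotation: Mapping[str, str]
) -> GeneTable:
    """Sum guide counts per gene.

    ``annotation`` maps member id -> gene symbol; members without a mapping
    are tracked in ``unmapped`` (with a warning) and excluded from gene
    totals. A member mapped to two genes is impossible with a mapping input
    by construction; duplicate member rows raise.
    """
    import warnings

    if isinstance(table, CountTable):
        counts = table.of_class(CLASS_LIBRARY, CLASS_PATTERN_NOVEL)
    else:
        counts = table
    if counts.index.has_duplicates:
        raise ValueError("duplicate member ids in count table")
    genes = pd.Series({m: annotation.get(str(m)) for m in counts.index})
    unmapped = counts.loc[genes.isna()]
    if len(unmapped):
        warnings.warn(
            f"{len(unmapped)} member(s) have no gene annotation; excluded "
            "from gene totals",
            stacklevel=2,
        )
    mapped = counts.loc[genes.notna()]
    gene_counts = mapped.groupby(genes.dropna()).sum()
    gene_counts.index.name = "gene"
    return GeneTable(gene_counts, unmapped)


def log2fc(
    table: GeneTable | pd.DataFrame,
    sample_a: str,
    sample_b: str,
    pseudocount: float = 0.5,
) -> pd.Series:
    """Per-member log2 fold change of sample_b over sample_a.

    Computed on normalized values with a depth-scaled pseudocount
    (``pseudocount / sample total``) so the statistic is antisymmetric
    under sample swap and finite for zero counts. ``pseudocount=0`` gives
    exact ratios (with +/-inf where a side is zero).
    """
    counts = table.counts if isinstance(table, GeneTable) else table
    for s in (sample_a, sample_b):
        if s not in counts.columns:
            raise KeyError(f"sample {s!r} not in table")
    totals = counts[[sample_a, sample_b]].sum(axis=0)
    norm = counts[[sample_a, sample_b]] / totals
    eps_a = pseudocount / totals[sample_a] if totals[sample_a] else 0.0
    eps_b = pseudocount / totals[sample_b] if totals[sample_b] else 0.0
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.log2((norm[sample_b] + eps_b) / (norm[sample_a] + eps_a))
    out.name = f"log2fc_{sample_b}_vs_{sample_a}"
    return out


def replicate_correlation(
    counts_rep1: pd.Series | Mapping[str, float],
    counts_rep2: pd.Series | Mapping[str, float],
) -> tuple[float, float, float]:
    """Pearson r, r squared, and Spearman rho between two replicates.

    Computed on normalized values over the intersection of member ids;
    Spearman uses average ranks for ties.
    """
    a = pd.Series(counts_rep1, dtype=float)
    b = pd.Series(counts_rep2, dtype=float)
    shared = a.index.intersection(b.index)
    if len(shared) < 3:
        raise ValueError(f"only {len(shared)} shared members; need >= 3")
    x = a.loc[shared] / a.loc[shared].sum()
    y = b.loc[shared] / b.loc[shared].sum()
    pearson = float(stats.pearsonr(x, y).statistic)
    rho = float(stats.spearmanr(x, y).statistic)
    return pearson, pearson**2, rho


@dataclass(frozen=True)
class EnrichmentResult:
    """Members passing a fold-change filter; ``flagged_infinite`` are those
    with zero control counts (ratio undefined, included by convention)."""

    members: frozenset
    ratios: pd.Series
    flagged_infinite: frozenset


def enrichment_filter(
    table: GeneTable | CountTable | pd.DataFrame,
    treated: str,
    control: str,
    min_fold: float = 2.0,
) -> EnrichmentResult:
    """Members whose normalized treated/control ratio is strictly greater
    than ``min_fold`` (the literal 'more than X-fold' reading: exactly
    min_fold is excluded)."""
    if min_fold <= 0:
        raise ValueError("min_fold must be > 0")
    if isinstance(table, GeneTable):
        counts = table.counts
    elif isinstance(table, CountTable):
        counts = table.of_class(CLASS_LIBRARY, CLASS_PATTERN_NOVEL)
    else:
        counts = table
    for s in (treated, control):
        if s not in counts.columns:
            raise KeyError(f"sample {s!r} not in table")
    norm = counts[[treated, control]] / counts[[treated, control]].sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratios = norm[treated] / norm[control]
    flagged = frozenset(ratios.index[(norm[control] == 0) & (norm[treated] > 0)])
    passing = frozenset(ratios.index[ratios > min_fold]) | flagged
    ratios.name = f"fold_{treated}_vs_{control}"
    return EnrichmentResult(passing, ratios, flagged)


def intersect_replicates(*member_sets: Iterable) -> tuple[frozenset, list[int]]:
    """Exact intersection across replicate hit sets; returns the common set
    and the per-replicate sizes."""
    sets = [frozenset(s) for s in member_sets]
    if len(sets) < 2:
        raise ValueError("need at least two replicate sets")
    common = frozenset.intersection(*sets)
    return common, [len(s) for s in sets]
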