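"""Null-length gene model: recurrence, gene-set enrichment, conservation.

Under the null, a coding mutation lands in a gene with probability
proportional to the length of that gene's capture-targeted coding sequence.
Recurrence (two or more hits in one gene) is assessed by simulation under
this null; gene-set enrichment by an exact two-sided binomial test against
the set's share of targeted length; and conservation differences between
proband and sibling mutations by the Wilcoxon rank-sum test with a
Hodges-Lehmann location-shift estimate.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Sequence, Set

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "GeneModel",
    "gene_targeted_lengths",
    "recurrence_test",
    "gene_set_enrichment",
    "conservation_compare",
]


@dataclass(frozen=True)
class GeneModel:
    """Per-gene capture-targeted lengths defining the null mutation probabilities."""

    lengths: dict  # gene_id -> targeted bp

    def __post_init__(self) -> None:
        if not self.lengths:
            raise ValueError("gene model needs at least one gene")
        if any(l <= 0 for l in self.lengths.values()):
            raise ValueError("targeted lengths must be > 0")

    @property
    def total_length(self) -> int:
        return sum(self.lengths.values())

    def probabilities(self) -> tuple:
        """(gene ids, length-proportional probabilities summing to 1)."""
        genes = sorted(self.lengths)
        p = np.array([self.lengths[g] for g in genes], dtype=float)
        return genes, p / p.sum()


def gene_targeted_lengths(coding: pd.DataFrame, capture: pd.DataFrame) -> GeneModel:
    """Build a GeneModel from coding-sequence and capture BED-style frames.

    ``coding`` needs Chromosome/Start/End/Name columns (Name = gene id);
    ``capture`` needs Chromosome/Start/End.  Overlapping coding intervals are
    merged per gene before intersecting with the capture target; the summed
    overlap is the gene's targeted length.  Genes with no capture overlap are
    dropped.
    """
    import pyranges as pr

    cap = pr.PyRanges(capture[["Chromosome", "Start", "End"]].copy()).merge()
    lengths: dict = {}
    for gene, sub in coding.groupby("Name"):
        merged = pr.PyRanges(sub[["Chromosome", "Start", "End"]].copy()).merge()
        hit = merged.intersect(cap)
        if len(hit) == 0:
            continue
        df = hit.df
        lengths[gene] = int((df.End - df.Start).sum())
    if not lengths:
        raise ValueError("no gene overlaps the capture target")
    return GeneModel(lengths)


def observed_recurrence(gene_hits: Sequence[str]) -> int:
    """Number of genes hit two or more times."""
    return sum(1 for n in Counter(gene_hits).values() if n >= 2)


def recurrence_test(
    gene_hits: Sequence[str],
    genes: GeneModel,
    n_sim: int = 10_000,
    seed: int = 0,
) -> tuple:
    """Expected recurrent-gene count and p-value under the length null.

    Each simulation draws ``len(gene_hits)`` genes with replacement under
    length-proportional probabilities and counts genes drawn at least twice.
    Returns ``(expected_recurrent, p)`` with the add-one-smoothed upper-tail
    p-value (1 + #{sim >= observed}) / (1 + n_sim).
    """
    if len(gene_hits) < 2:
        raise ValueError("need at least two gene hits")
    unknown = set(gene_hits) - set(genes.lengths)
    if unknown:
        raise ValueError(f"hits in genes absent from the model: {sorted(unknown)[:5]}")
    obs = observed_recurrence(gene_hits)
    _, p = genes.probabilities()
    rng = np.random.default_rng(seed)
    draws = rng.multinomial(len(gene_hits), p, size=n_sim)
    recurrent = (draws >= 2).sum(axis=1)
    expected = float(recurrent.mean())
    pval = (1 + int((recurrent >= obs).sum())) / (1 + n_sim)
    return expected, float(pval)


def gene_set_enrichment(
    gene_hits: Sequence[str],
    set_members: Set[str],
    genes: GeneModel,
    unit: str = "genes",
) -> tuple:
    """Enrichment of mutated genes in a gene set under the length null.

    The per-mutation probability of landing in the set is the set's targeted
    length over the total targeted length; expected = n_hits x that
    probability.  ``unit="genes"`` counts distinct mutated genes in the set
    (the default reading); ``unit="mutations"`` counts hits.  The p-value is
    the exact two-sided binomial probability (minimum-likelihood convention)
    of the observed count given n_hits trials.
    Returns ``(expected, observed, p)``.
    """
    if not set(set_members) <= set(genes.lengths):
        raise ValueError("gene set must be a subset of the gene universe")
    set_length = sum(genes.lengths[g] for g in set_members)
    p_set = set_length / genes.total_length
    n = len(gene_hits)
    expected = n * p_set
    if unit == "genes":
        observed = len({g for g in gene_hits if g in set_members})
    elif unit == "mutations":
        observed = sum(1 for g in gene_hits if g in set_members)
    else:
        raise ValueError(f"unknown unit {unit!r}")
    if n == 0 or p_set == 0:
        return float(expected), observed, 1.0
    pval = stats.binomtest(observed, n, p_set, alternative="two-sided").pvalue
    return float(expected), observed, float(pval)


def conservation_compare(
    proband_values: Sequence[float], sibling_values: Sequence[float]
) -> tuple:
    """Rank-sum comparison of conservation annotations between cohorts.

    Returns ``(p, effect)`` where p is the two-sided Wilcoxon rank-sum
    (Mann-Whitney) p-value and effect is the Hodges-Lehmann estimate of the
    proband-minus-sibling location shift (median of all pairwise differences).
    """
    x = np.asarray(proband_values, dtype=float)
    y = np.asarray(sibling_values, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([x, y])
    no_ties = len(np.unique(pooled)) == len(pooled)
    method = "exact" if (no_ties and max(len(x), len(y)) <= 25) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    effect = float(np.median(np.subtract.outer(x, y)))
    return float(res.pvalue), effect
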