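"""Binomial mosaic classification of de novo calls.

A germline heterozygous variant should draw alternate reads at fraction ~0.5
of depth.  A post-zygotic variant is carried by only a fraction of cells, so
its alternate-allele read fraction (AARF) falls below that expectation.  Each
de novo call gets a one-sided exact binomial p-value for "fewer alternate
reads than expected", the p-values are adjusted jointly across the whole
callset with the Benjamini-Hochberg step-up procedure, and a call is labelled
mosaic when its q-value clears the FDR and its AARF lies below a hard ceiling
(the ceiling absorbs reference-capture bias that would otherwise push
high-depth germline hets over the FDR line).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .caller import DeNovoCall

__all__ = [
    "ClassifierParams",
    "MosaicClassification",
    "binomial_mosaic_p",
    "bh_adjust",
    "classify",
    "mosaic_fraction_percent",
    "callset_summary",
]

LABEL_MOSAIC = "mosaic"
LABEL_GERMLINE = "germline_denovo"


@dataclass(frozen=True)
class ClassifierParams:
    expected_fraction: float = 0.5
    fdr: float = 0.05
    aarf_max: float = 0.34

    def __post_init__(self) -> None:
        if not 0 < self.expected_fraction < 1:
            raise ValueError("expected_fraction must lie in (0, 1)")
        if not 0 < self.fdr < 1:
            raise ValueError("fdr must lie in (0, 1)")
        if not 0 < self.aarf_max <= 1:
            raise ValueError("aarf_max must lie in (0, 1]")


@dataclass(frozen=True)
class MosaicClassification:
    call: DeNovoCall
    p_mosaic: float
    q_value: float
    aarf: float
    label: str


def binomial_mosaic_p(alt_depth: int, total_depth: int, expected_fraction: float = 0.5) -> float:
    """Lower-tail exact binomial p-value P(X <= alt_depth | n, p).

    Tests whether the de novo allele is supported by significantly fewer reads
    than expected from the read depth under the heterozygous model.
    """
    if total_depth <= 0:
        raise ValueError("total_depth must be > 0")
    if not 0 <= alt_depth <= total_depth:
        raise ValueError("alt_depth must satisfy 0 <= alt_depth <= total_depth")
    return float(stats.binom.cdf(alt_depth, total_depth, expected_fraction))


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, order-preserving in the input."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def classify(
    calls: Sequence[DeNovoCall], params: ClassifierParams = ClassifierParams()
) -> list:
    """Label each call mosaic or germline de novo.

    The BH adjustment is computed jointly over the entire input (probands and
    siblings together).  A call is mosaic iff q < fdr AND AARF < aarf_max.
    """
    p = np.array(
        [binomial_mosaic_p(c.alt_depth, c.total_depth, params.expected_fraction) for c in calls]
    )
    q = bh_adjust(p)
    out = []
    for i, c in enumerate(calls):
        aarf = c.aarf
        label = (
            LABEL_MOSAIC
            if (q[i] < params.fdr and aarf < params.aarf_max)
            else LABEL_GERMLINE
        )
        out.append(MosaicClassification(c, float(p[i]), float(q[i]), aarf, label))
    return out


def mosaic_fraction_percent(n_mosaic: int, n_total: int) -> float:
    """Mosaic share of the final callset, as a percentage."""
    if n_total <= 0:
        raise ValueError("n_total must be > 0")
    if not 0 <= n_mosaic <= n_total:
        raise ValueError("n_mosaic must satisfy 0 <= n_mosaic <= n_total")
    return 100.0 * n_mosaic / n_total


def callset_summary(classifications: Sequence[MosaicClassification]) -> dict:
    """Counts and mosaic percentage for a classified callset."""
    n_total = len(classifications)
    n_mosaic = sum(1 for c in classifications if c.label == LABEL_MOSAIC)
    return {
        "n_total": n_total,
        "n_mosaic": n_mosaic,
        "n_germline": n_total - n_mosaic,
        "mosaic_percent": mosaic_fraction_percent(n_mosaic, n_total) if n_total else float("nan"),
    }
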