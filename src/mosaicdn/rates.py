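"""Per-child mutation rates from joint high-coverage regions.

Mutation rates are only comparable between children when measured over
territory that was adequately covered in the whole trio: a variant cannot be
called de novo where a parent lacks depth.  For each child the >=40x regions
of child, father and mother are intersected with the capture target ("joint
40x region"), calls are counted inside it, and counts are extrapolated
linearly to the full capture region.  Proband and sibling group means are then
compared with a label-permutation test.

Intervals are 0-based half-open throughout and are merged before measuring.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from itertools import combinations
from typing import Optional, Sequence

import numpy as np

from .caller import DeNovoCall
from .cohort import CoverageTrack

__all__ = [
    "JointRegion",
    "RateEstimate",
    "RateComparison",
    "merge_intervals",
    "intersect_intervals",
    "interval_length",
    "positions_in_intervals",
    "regions_at_depth",
    "joint_region",
    "mutation_rate",
    "compare_rates",
]

logger = logging.getLogger(__name__)

FUNCTIONAL_CLASSES = ("LGD", "missense", "synonymous", "all")

_EMPTY = np.empty((0, 2), dtype=np.int64)


def _as_intervals(iv) -> np.ndarray:
    arr = np.asarray(iv, dtype=np.int64)
    if arr.size == 0:
        return _EMPTY
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise ValueError("intervals must have shape (n, 2)")
    if np.any(arr[:, 1] < arr[:, 0]):
        raise ValueError("interval ends must be >= starts")
    return arr


def merge_intervals(iv) -> np.ndarray:
    """Sort and merge overlapping or adjacent half-open intervals."""
    arr = _as_intervals(iv)
    if len(arr) == 0:
        return arr
    arr = arr[np.lexsort((arr[:, 1], arr[:, 0]))]
    out = [list(arr[0])]
    for s, e in arr[1:]:
        if s <= out[-1][1]:
            out[-1][1] = max(out[-1][1], e)
        else:
            out.append([s, e])
    return np.array(out, dtype=np.int64)


def intersect_intervals(a, b) -> np.ndarray:
    """Intersection of two merged interval sets (two-pointer sweep)."""
    a = merge_intervals(a)
    b = merge_intervals(b)
    out = []
    i = j = 0
    while i < len(a) and j < len(b):
        s = max(a[i, 0], b[j, 0])
        e = min(a[i, 1], b[j, 1])
        if s < e:
            out.append((s, e))
        if a[i, 1] < b[j, 1]:
            i += 1
        else:
            j += 1
    return np.array(out, dtype=np.int64) if out else _EMPTY


def interval_length(iv) -> int:
    arr = _as_intervals(iv)
    return int((arr[:, 1] - arr[:, 0]).sum())


def positions_in_intervals(positions, iv) -> np.ndarray:
    """Boolean mask: which 0-based positions fall inside the merged intervals."""
    arr = merge_intervals(iv)
    pos = np.asarray(positions, dtype=np.int64)
    if len(arr) == 0:
        return np.zeros(pos.shape, dtype=bool)
    idx = np.searchsorted(arr[:, 0], pos, side="right") - 1
    ok = idx >= 0
    ok[ok] &= pos[ok] < arr[idx[ok], 1]
    return ok


def regions_at_depth(track: CoverageTrack, threshold: int = 40) -> np.ndarray:
    """Maximal merged intervals of a piecewise-constant track with depth >= threshold."""
    mask = np.asarray(track.depths) >= threshold
    if not mask.any():
        return _EMPTY
    iv = np.stack([np.asarray(track.starts)[mask], np.asarray(track.ends)[mask]], axis=1)
    return merge_intervals(iv)


@dataclass(frozen=True)
class JointRegion:
    family_id: str
    child_id: str
    intervals: np.ndarray  # merged, 0-based half-open, within the capture target
    total_length: int

    def contains(self, positions) -> np.ndarray:
        return positions_in_intervals(positions, self.intervals)


def joint_region(
    child_iv,
    father_iv,
    mother_iv,
    capture_iv,
    family_id: str = "",
    child_id: str = "",
) -> JointRegion:
    """Four-way intersection of trio >=40x regions with the capture target."""
    iv = intersect_intervals(child_iv, father_iv)
    iv = intersect_intervals(iv, mother_iv)
    iv = intersect_intervals(iv, capture_iv)
    return JointRegion(family_id, child_id, iv, interval_length(iv))


@dataclass(frozen=True)
class RateEstimate:
    child_id: str
    role: str
    mosaic_class: str  # mosaic | germline_denovo
    functional_class: str  # LGD | missense | synonymous | all
    count_in_joint: int
    joint_length: int
    capture_length: int

    @property
    def extrapolated_count(self) -> float:
        """Mutations per exome: joint-region count scaled to the capture size."""
        return self.count_in_joint * self.capture_length / self.joint_length


def mutation_rate(
    labelled_calls: Sequence[tuple],
    region: JointRegion,
    capture_length: int,
    role: str = "proband",
) -> Optional[list]:
    """Per-class extrapolated mutation counts for one child.

    ``labelled_calls`` are ``(DeNovoCall, label)`` pairs for the child, with
    label mosaic or germline_denovo.  Calls are restricted to the joint
    region (variant positions are 1-based; intervals 0-based half-open).
    Children with an empty joint region cannot be rated and yield None with a
    logged warning.
    """
    if region.total_length <= 0:
        logger.warning(
            "child %s has an empty joint region; excluded from rate estimation",
            region.child_id,
        )
        return None
    if labelled_calls:
        pos0 = np.array([c.pos - 1 for c, _ in labelled_calls])
        inside = region.contains(pos0)
    else:
        inside = np.zeros(0, dtype=bool)
    out = []
    for mosaic_class in ("mosaic", "germline_denovo"):
        for fclass in FUNCTIONAL_CLASSES:
            n = sum(
                1
                for keep, (call, label) in zip(inside, labelled_calls)
                if keep
                and label == mosaic_class
                and (fclass == "all" or call.functional_class == fclass)
            )
            out.append(
                RateEstimate(
                    region.child_id,
                    role,
                    mosaic_class,
                    fclass,
                    n,
                    region.total_length,
                    capture_length,
                )
            )
    return out


@dataclass(frozen=True)
class RateComparison:
    proband_mean: float
    sibling_mean: float
    proband_ci: tuple
    sibling_ci: tuple
    p_value: float
    n_proband: int
    n_sibling: int
    exact: bool = False


def _mean_ci(x: np.ndarray) -> tuple:
    m = float(x.mean())
    if len(x) < 2:
        return (math.nan, math.nan)
    half = 1.959963984540054 * float(x.std(ddof=1)) / math.sqrt(len(x))
    return (m - half, m + half)


def compare_rates(
    proband_rates: Sequence[float],
    sibling_rates: Sequence[float],
    n_perm: int = 10_000,
    seed: int = 0,
) -> RateComparison:
    """Group means with 95% CIs and a one-sided permutation p for proband > sibling.

    Child labels are permuted and the mean difference recomputed; the p-value
    is the add-one-smoothed fraction of permutations at least as extreme as
    observed.  When the number of distinct label assignments is small enough,
    all of them are enumerated instead and the p-value is exact.
    """
    x = np.asarray(proband_rates, dtype=float)
    y = np.asarray(sibling_rates, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("need at least two children per group")
    observed = x.mean() - y.mean()
    pooled = np.concatenate([x, y])
    n, k = len(pooled), len(x)
    total = pooled.sum()

    n_assignments = math.comb(n, k)
    if n_assignments <= n_perm:
        hits = 0
        for idx in combinations(range(n), k):
            xs = pooled[list(idx)].sum()
            diff = xs / k - (total - xs) / (n - k)
            if diff >= observed - 1e-12:
                hits += 1
        p = hits / n_assignments
        exact = True
    else:
        rng = np.random.default_rng(seed)
        hits = 0
        for _ in range(n_perm):
            perm = rng.permutation(pooled)
            diff = perm[:k].mean() - perm[k:].mean()
            if diff >= observed - 1e-12:
                hits += 1
        p = (1 + hits) / (1 + n_perm)
        exact = False
    return RateComparison(
        float(x.mean()),
        float(y.mean()),
        _mean_ci(x),
        _mean_ci(y),
        float(p),
        len(x),
        len(y),
        exact,
    )
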