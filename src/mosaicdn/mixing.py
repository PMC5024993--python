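"""In-silico read mixing and subsampling at controlled allele fractions.

Mixing reads from two individuals over regions where one carries a private
variant simulates mosaicism at a known allele fraction: if a fraction f of
reads come from the carrier of a heterozygous variant, the mixture shows the
variant at allele fraction f/2.  Reads are represented tabularly (one row per
read with region / read id / optional pair id / source); per region the
mixture is subsampled without replacement to a target depth with a binomial
split between sources, and realized depths and fractions are reported so the
downstream sensitivity analysis can bin by simulated allele fraction.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence, Set, Union

import numpy as np
import pandas as pd

__all__ = [
    "MixSpec",
    "mix_and_subsample",
    "evaluate_sensitivity",
    "threshold_caller",
]


@dataclass(frozen=True)
class MixSpec:
    target_depth: int
    fraction_a: Union[float, str] = "random"  # in [0,1], or "random" per region
    regions: tuple = ()
    seed: int = 0
    pairs_as_units: bool = True

    def __post_init__(self) -> None:
        if self.target_depth <= 0:
            raise ValueError("target_depth must be > 0")
        if isinstance(self.fraction_a, str):
            if self.fraction_a != "random":
                raise ValueError("fraction_a must be a number or 'random'")
        elif not 0.0 <= self.fraction_a <= 1.0:
            raise ValueError("fraction_a must lie in [0, 1]")


def _units(df: pd.DataFrame, pairs: bool) -> list:
    """Group reads into sampling units (read pairs kept or dropped together)."""
    if pairs and "pair_id" in df.columns:
        return [sub.index.to_numpy() for _, sub in df.groupby("pair_id", sort=True)]
    return [np.array([i]) for i in df.index]


def mix_and_subsample(
    reads_a: pd.DataFrame, reads_b: pd.DataFrame, spec: MixSpec
) -> tuple:
    """Mix two read tables and subsample to the target depth per region.

    Read tables need columns ``region`` and ``read_id`` (plus optional
    ``pair_id``).  Per region, the number of source-A sampling units is
    binomial(target units, fraction_a) and units are drawn without replacement
    within each source, so the expected depth equals the target and the
    expected source-A proportion equals fraction_a.  Raises when a source
    cannot supply its share, naming the region.

    Returns ``(mixed, realized)``: the mixed read table with a ``source``
    column, and a per-region frame with realized depth and fraction.
    """
    rng = np.random.default_rng(spec.seed)
    regions = list(spec.regions) if spec.regions else sorted(
        set(reads_a["region"]) | set(reads_b["region"])
    )
    unit_size = 2 if (spec.pairs_as_units and "pair_id" in reads_a.columns) else 1
    n_units_target = max(1, round(spec.target_depth / unit_size))

    mixed_parts = []
    realized_rows = []
    for region in regions:
        sub_a = reads_a[reads_a["region"] == region]
        sub_b = reads_b[reads_b["region"] == region]
        units_a = _units(sub_a, spec.pairs_as_units)
        units_b = _units(sub_b, spec.pairs_as_units)
        frac = (
            float(rng.uniform())
            if isinstance(spec.fraction_a, str)
            else float(spec.fraction_a)
        )
        n_a = int(rng.binomial(n_units_target, frac))
        n_b = n_units_target - n_a
        if n_a > len(units_a):
            raise ValueError(f"source A cannot supply {n_a} units in region {region!r}")
        if n_b > len(units_b):
            raise ValueError(f"source B cannot supply {n_b} units in region {region!r}")
        pick_a = rng.choice(len(units_a), size=n_a, replace=False) if n_a else []
        pick_b = rng.choice(len(units_b), size=n_b, replace=False) if n_b else []
        part_a = sub_a.loc[np.concatenate([units_a[i] for i in pick_a])] if n_a else sub_a.iloc[:0]
        part_b = sub_b.loc[np.concatenate([units_b[i] for i in pick_b])] if n_b else sub_b.iloc[:0]
        part_a = part_a.assign(source="A")
        part_b = part_b.assign(source="B")
        depth = len(part_a) + len(part_b)
        mixed_parts.extend([part_a, part_b])
        realized_rows.append(
            {
                "region": region,
                "depth": depth,
                "n_a": len(part_a),
                "n_b": len(part_b),
                "fraction_a": len(part_a) / depth if depth else np.nan,
                "requested_fraction_a": frac,
            }
        )
    mixed = pd.concat(mixed_parts, ignore_index=True) if mixed_parts else pd.DataFrame()
    return mixed, pd.DataFrame(realized_rows)


def threshold_caller(
    alt_reads: Sequence[int], min_alt_reads: int = 3
) -> np.ndarray:
    """Minimal variant-caller stand-in: call a site iff alt reads >= threshold."""
    return np.asarray(alt_reads) >= min_alt_reads


def evaluate_sensitivity(
    called_variants: Set,
    truth_private_to_a: Set,
    realized_fractions: dict,
    bin_edges: Sequence[float] = (0.0, 0.1, 0.2, 0.3, 0.4, 0.5),
) -> pd.DataFrame:
    """Sensitivity for source-A-private variants, binned by simulated allele fraction.

    ``realized_fractions`` maps each truth variant key to its simulated
    alternate-allele fraction (source-A proportion / 2 for a het private to
    A).  Sensitivity in a bin is TP / (TP + FN) over truth variants whose
    fraction falls in the bin.
    """
    edges = np.asarray(bin_edges, dtype=float)
    rows = []
    for lo, hi in zip(edges[:-1], edges[1:]):
        in_bin = [
            k
            for k in truth_private_to_a
            if lo <= realized_fractions[k] < hi
            or (hi == edges[-1] and realized_fractions[k] == hi)
        ]
        tp = sum(1 for k in in_bin if k in called_variants)
        rows.append(
            {
                "bin_low": lo,
                "bin_high": hi,
                "n": len(in_bin),
                "sensitivity": tp / len(in_bin) if in_bin else np.nan,
            }
        )
    return pd.DataFrame(rows)
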