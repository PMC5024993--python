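"""Trio de novo calling from multi-sample variant records.

A de novo candidate is an allele genotyped in a child and absent from both
parents.  Six filters gate a call: minimum depth in all trio members, minimum
alternate reads in the child, phred-scaled confidence for the allele's
presence in the child and for its absence in each parent, and a cap on how
many individuals cohort-wide are genotyped with the allele (recurrent alleles
across unrelated families are almost always artifacts).  Families in which
any child accumulates an excessive number of calls are dropped wholesale.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

from .cohort import CHILD_ROLES, ROLE_SUFFIX, SampleCall, TrioVariantRecord

__all__ = [
    "CallerParams",
    "DeNovoCall",
    "find_denovo",
    "exclude_families",
    "intersect_confirmation",
    "abhet",
    "variant_type",
]

_TRANSITIONS = ({"A", "G"}, {"C", "T"})


def variant_type(ref: str, alt: str) -> str:
    if len(ref) < len(alt):
        return "insertion"
    if len(ref) > len(alt):
        return "deletion"
    if len(ref) == 1 and {ref, alt} in _TRANSITIONS:
        return "transition"
    return "transversion"


@dataclass(frozen=True)
class CallerParams:
    min_trio_depth: int = 20
    min_child_alt_reads: int = 3
    min_child_presence_phred: int = 20
    min_parent_absence_phred: int = 20
    max_carriers_in_cohort: int = 2
    family_exclusion_threshold: int = 10

    def __post_init__(self) -> None:
        for name in (
            "min_trio_depth",
            "min_child_alt_reads",
            "min_child_presence_phred",
            "min_parent_absence_phred",
            "max_carriers_in_cohort",
            "family_exclusion_threshold",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")


@dataclass(frozen=True)
class DeNovoCall:
    chrom: str
    pos: int
    ref: str
    alt: str
    family_id: str
    child_id: str
    child_role: str  # proband | sibling
    total_depth: int
    alt_depth: int
    variant_type: str
    functional_class: str = "other"

    @property
    def aarf(self) -> float:
        """Alternate-allele read fraction in the child."""
        return self.alt_depth / self.total_depth

    @property
    def key(self) -> tuple:
        return (self.chrom, self.pos, self.ref, self.alt, self.child_id)


def _require(call: Optional[SampleCall], role: str, rec: TrioVariantRecord) -> SampleCall:
    if call is None:
        raise ValueError(
            f"record {rec.chrom}:{rec.pos} {rec.ref}>{rec.alt} in {rec.family_id} "
            f"is missing evidence for the {role}"
        )
    return call


def _parent_absent(parent: SampleCall, min_phred: int) -> bool:
    """Parent genotype excludes the allele with sufficient confidence.

    The best-supported genotype must be hom-ref and the phred-scaled
    likelihood gap to any alt-bearing genotype must reach ``min_phred``.
    """
    if parent.genotype_index != 0:
        return False
    return min(parent.pl[1], parent.pl[2]) >= min_phred


def find_denovo(
    records: Sequence[TrioVariantRecord], params: CallerParams = CallerParams()
) -> list:
    """Apply the six de novo filters to every (site, child) pair.

    Cohort-wide carrier counts are computed from the full record list first
    (an individual is a carrier when its most likely genotype contains the
    alternate allele).  The returned call list is sorted by site and child and
    is independent of the input record order.
    """
    carriers: Counter = Counter()
    for rec in records:
        for role in ("father", "mother", *CHILD_ROLES):
            sc = _require(rec.sample(role), role, rec)
            if sc.genotype_index != 0:
                carriers[rec.site_key] += 1

    calls = []
    for rec in records:
        father = rec.father
        mother = rec.mother
        for child_role in CHILD_ROLES:
            child = rec.sample(child_role)
            if child is None:
                continue
            if child.genotype_index == 0:
                continue  # allele not genotyped in the child
            if not (
                _parent_absent(father, params.min_parent_absence_phred)
                and _parent_absent(mother, params.min_parent_absence_phred)
            ):
                continue
            if min(father.dp, mother.dp, child.dp) < params.min_trio_depth:
                continue
            if child.ad < params.min_child_alt_reads:
                continue
            # confidence the de novo allele is present: phred gap from hom-ref
            if child.pl[0] < params.min_child_presence_phred:
                continue
            if carriers[rec.site_key] > params.max_carriers_in_cohort:
                continue
            calls.append(
                DeNovoCall(
                    rec.chrom,
                    rec.pos,
                    rec.ref,
                    rec.alt,
                    rec.family_id,
                    f"{rec.family_id}.{ROLE_SUFFIX[child_role]}",
                    child_role,
                    child.dp,
                    child.ad,
                    variant_type(rec.ref, rec.alt),
                    rec.functional_class,
                )
            )
    calls.sort(key=lambda c: (c.chrom, c.pos, c.family_id, c.child_role, c.alt))
    return calls


def exclude_families(calls: Iterable[DeNovoCall], threshold: int = 10) -> tuple:
    """Drop whole families in which any child has more than ``threshold`` calls.

    Returns ``(kept_calls, excluded_family_ids)``; the sibling's calls go with
    the family.
    """
    per_child: Counter = Counter()
    for c in calls:
        per_child[(c.family_id, c.child_id)] += 1
    excluded = sorted({fam for (fam, _), n in per_child.items() if n > threshold})
    excluded_set = set(excluded)
    kept = [c for c in calls if c.family_id not in excluded_set]
    return kept, excluded


def intersect_confirmation(
    calls: Sequence[DeNovoCall],
    confirmation_sets: Sequence[set],
    mosaic_flags: Optional[Sequence[bool]] = None,
    mode: str = "mosaic-only",
) -> list:
    """Keep calls present in at least one external confirmation callset.

    Confirmation sets are keyed by ``(chrom, pos, ref, alt, child_id)``.  In
    the default ``"mosaic-only"`` mode the joint-presence requirement applies
    only to calls flagged as mosaic candidates (``mosaic_flags``); germline
    calls pass unconditionally.  ``"strict-all"`` applies it to every call.
    """
    if mode not in ("mosaic-only", "strict-all"):
        raise ValueError(f"unknown mode {mode!r}")
    if mode == "mosaic-only" and mosaic_flags is None:
        raise ValueError("mosaic-only mode requires mosaic_flags")
    kept = []
    for i, call in enumerate(calls):
        if mode == "mosaic-only" and not mosaic_flags[i]:
            kept.append(call)
            continue
        if any(call.key in s for s in confirmation_sets):
            kept.append(call)
    return kept


def abhet(ref_reads: int, total_reads: int) -> float:
    """Fraction of reads supporting the reference allele (AbHet annotation)."""
    if total_reads <= 0:
        raise ValueError("abhet undefined for total_reads = 0")
    if not 0 <= ref_reads <= total_reads:
        raise ValueError("ref_reads must satisfy 0 <= ref_reads <= total_reads")
    return ref_reads / total_reads
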