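"""Read-backed phasing of de novo variants against nearby inherited heterozygotes.

A post-zygotic (mosaic) variant arises after fertilization, so only a fraction
of cells carry it.  When a de novo variant lies within read range of an
inherited heterozygous variant whose parental origin is resolvable, the reads
spanning both sites reveal the haplotype structure.  A germline de novo variant
co-segregates perfectly with one parental background allele (two haplotypes
observed).  A mosaic variant produces *three* haplotypes: the other parent's
background, plus the mutant parent's background both with and without the de
novo allele.  The fraction of mutant-haplotype reads carrying the de novo
allele estimates the fraction of cells heterozygous for it.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, NamedTuple, Optional, Sequence

__all__ = [
    "PhasedRead",
    "PhaseObservation",
    "PhasingResult",
    "observation_from_reads",
    "select_informative_het",
    "phase_denovo",
    "estimate_mosaic_fraction",
]

PATERNAL = "paternal"
MATERNAL = "maternal"
UNDETERMINED = "undetermined"


class PhasedRead(NamedTuple):
    """One sequencing read spanning a (linked het, de novo) site pair.

    ``background`` is the allele observed at the linked inherited het
    ("alt" or "ref"); ``carries_dn`` says whether the read shows the de novo
    allele; the two base qualities are phred-scaled.
    """

    background: str
    carries_dn: bool
    qual_het: int = 40
    qual_dn: int = 40


@dataclass(frozen=True)
class PhaseObservation:
    """Read counts over the four (inherited allele, de novo allele) configurations."""

    n_ialt_dalt: int  # inherited-alt background, de novo allele present
    n_ialt_dref: int  # inherited-alt background, de novo allele absent
    n_iref_dalt: int
    n_iref_dref: int
    het_pos: Optional[int] = None
    parent_of_inherited_alt: Optional[str] = None  # parent contributing the het ALT allele

    def __post_init__(self) -> None:
        counts = (self.n_ialt_dalt, self.n_ialt_dref, self.n_iref_dalt, self.n_iref_dref)
        if any(c < 0 for c in counts):
            raise ValueError("phase observation counts must be non-negative")

    @property
    def total(self) -> int:
        return self.n_ialt_dalt + self.n_ialt_dref + self.n_iref_dalt + self.n_iref_dref


@dataclass(frozen=True)
class PhasingResult:
    informative: bool
    mosaic: Optional[bool] = None
    mosaic_frac: Optional[float] = None
    parent: str = UNDETERMINED


def observation_from_reads(
    reads: Iterable[PhasedRead],
    het_pos: Optional[int] = None,
    parent_of_inherited_alt: Optional[str] = None,
    min_base_quality: int = 20,
) -> PhaseObservation:
    """Tabulate spanning reads into configuration counts.

    Reads with base quality below ``min_base_quality`` at either site are
    dropped before counting.
    """
    n = [0, 0, 0, 0]
    for read in reads:
        if read.qual_het < min_base_quality or read.qual_dn < min_base_quality:
            continue
        i = 0 if read.background == "alt" else 2
        i += 0 if read.carries_dn else 1
        n[i] += 1
    return PhaseObservation(n[0], n[1], n[2], n[3], het_pos, parent_of_inherited_alt)


def select_informative_het(
    dn_pos: int,
    candidates: Sequence[tuple[int, Mapping[str, str]]],
    window: int = 500,
    *,
    child_key: str = "child",
    father_key: str = "father",
    mother_key: str = "mother",
) -> Optional[tuple[int, str]]:
    """Pick an origin-resolvable inherited het within ``window`` bp of the de novo site.

    ``candidates`` are ``(pos, genotypes)`` pairs where genotypes maps member
    keys to "0/0", "0/1" or "1/1" strings.  A candidate is usable when the
    child is heterozygous and exactly one parent carries the alternate allele,
    which assigns the het's alt allele to that parent's haplotype.  The nearest
    usable candidate is returned as ``(pos, origin_parent)`` with
    ``origin_parent`` in {"paternal", "maternal"}; ties resolve to the lower
    position.  Returns None when no candidate qualifies.
    """
    best: Optional[tuple[int, int, str]] = None
    for pos, gts in candidates:
        if abs(pos - dn_pos) > window or pos == dn_pos:
            continue
        if gts.get(child_key) != "0/1":
            continue
        fa_has = "1" in gts.get(father_key, "0/0")
        mo_has = "1" in gts.get(mother_key, "0/0")
        if fa_has == mo_has:  # absent from both (Mendelian error) or present in both (ambiguous)
            continue
        origin = PATERNAL if fa_has else MATERNAL
        rank = (abs(pos - dn_pos), pos)
        if best is None or rank < (best[0], best[1]):
            best = (abs(pos - dn_pos), pos, origin)
    if best is None:
        return None
    return best[1], best[2]


def phase_denovo(obs: PhaseObservation, min_support: int = 2) -> PhasingResult:
    """Call mosaic status from configuration counts.

    Let X be the inherited-site allele on which the de novo allele is observed
    (with at least ``min_support`` reads).  The three-haplotype signature of
    mosaicism is the additional presence of >= ``min_support`` reads carrying X
    but *not* the de novo allele.  Perfect co-segregation of the de novo allele
    with X is the germline (two-haplotype) pattern.  The observation is
    uninformative when the de novo allele appears on both inherited alleles at
    support (inconsistent phasing) or when no configuration reaches support.
    """
    if min_support < 1:
        raise ValueError("min_support must be >= 1")
    if obs.total == 0:
        return PhasingResult(informative=False)
    on_alt = obs.n_ialt_dalt >= min_support
    on_ref = obs.n_iref_dalt >= min_support
    if on_alt == on_ref:  # both (inconsistent) or neither (no de novo support)
        return PhasingResult(informative=False)
    if on_alt:
        x_dalt, x_dref = obs.n_ialt_dalt, obs.n_ialt_dref
        parent = obs.parent_of_inherited_alt or UNDETERMINED
    else:
        x_dalt, x_dref = obs.n_iref_dalt, obs.n_iref_dref
        if obs.parent_of_inherited_alt is None:
            parent = UNDETERMINED
        else:
            parent = MATERNAL if obs.parent_of_inherited_alt == PATERNAL else PATERNAL
    mosaic = x_dref >= min_support
    frac = x_dalt / (x_dalt + x_dref) if mosaic else None
    return PhasingResult(informative=True, mosaic=mosaic, mosaic_frac=frac, parent=parent)


def estimate_mosaic_fraction(obs: PhaseObservation) -> float:
    """Fraction of cells carrying the variant, from mutant-haplotype read counts.

    The mutant parental haplotype X is the inherited allele with de novo
    support; the estimate is (X and dn-alt) / ((X and dn-alt) + (X and dn-ref)),
    i.e. the fraction of reads from that haplotype that carry the de novo
    allele, interpreted as the fraction of cells heterozygous for it (diploid
    region assumed).  Scale-invariant in the counts.
    """
    if obs.n_ialt_dalt >= obs.n_iref_dalt:
        x_dalt, x_dref = obs.n_ialt_dalt, obs.n_ialt_dref
    else:
        x_dalt, x_dref = obs.n_iref_dalt, obs.n_iref_dref
    denom = x_dalt + x_dref
    if denom == 0:
        raise ValueError("no reads on the mutant haplotype; fraction undefined")
    return x_dalt / denom
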