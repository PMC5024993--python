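"""Synthetic quad-family exome cohort generator.

Emulates the variant-level read evidence of a simplex-collection style study:
quad families (father, mother, affected proband, unaffected sibling) with
exome capture, ~95x depth at variant sites, inherited heterozygous variants,
germline de novo variants at ~0.5 allele fraction with a small reference bias,
and post-zygotic (mosaic) variants at lower allele fractions set by their cell
fraction.  Every planted variant carries a truth label so downstream calling,
classification, phasing and rate estimation can be scored exactly.

The generator works at the level of per-sample read counts and genotype
likelihoods (the representation a joint caller would emit), not raw reads.
Depth is negative-binomial (capture data are overdispersed); alternate read
counts are binomial with success probability (cell_fraction / 2) x
(1 - reference_bias) in carriers and the per-read error rate in non-carriers;
genotype likelihoods come from a symmetric per-read error model over the three
diploid genotypes, phred-scaled and rescaled so the minimum is zero.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Callable, Optional, Sequence, Union

import numpy as np

from .phasing import PhasedRead

__all__ = [
    "ROLES",
    "CHILD_ROLES",
    "CohortConfig",
    "SampleCall",
    "TrioVariantRecord",
    "PlantedVariant",
    "FamilyTruth",
    "CoverageTrack",
    "generate_cohort",
    "generate_phasing_reads",
    "generate_coverage_tracks",
    "generate_conservation_annotations",
    "genotype_likelihoods",
]

ROLES = ("father", "mother", "proband", "sibling")
CHILD_ROLES = ("proband", "sibling")
ROLE_SUFFIX = {"father": "fa", "mother": "mo", "proband": "p1", "sibling": "s1"}

INHERITED_HET = "inherited_het"
GERMLINE_DENOVO = "germline_denovo"
MOSAIC = "mosaic"

# crude exome functional composition used to annotate planted de novo variants
_FUNCTIONAL_CLASSES = ("LGD", "missense", "synonymous", "other")
_FUNCTIONAL_PROBS = (0.08, 0.55, 0.25, 0.12)

_BASES = np.array(["A", "C", "G", "T"])


@dataclass
class CohortConfig:
    """Study conditions for the synthetic cohort.

    Rates are expected variants per child exome; the contributory rates are
    additional proband-only rates.  ``cell_fraction_distribution`` is either a
    ``(low, high)`` tuple for a uniform draw or a callable ``f(rng, n)``
    returning ``n`` fractions in (0, 1].
    """

    n_families: int = 2388
    depth_mean: float = 94.6
    depth_dispersion: float = 10.0
    germline_denovo_rate: float = 0.877
    mosaic_rate: float = 0.104
    contributory_mosaic_rate: float = 0.051
    contributory_germline_rate: float = 0.056
    cell_fraction_distribution: Union[tuple, Callable] = (0.25, 0.75)
    reference_bias: float = 0.05
    sequencing_error: float = 0.001
    inherited_het_density: float = 1.0  # expected linked hets per 500 bp phasing flank
    inherited_sites_per_family: int = 6
    common_variant_sites: int = 3
    common_variant_carrier_families: int = 4
    capture_length: int = 36_000_000
    coverage_bin_size: int = 50_000
    phasing_window: int = 500
    seed: int = 0

    def __post_init__(self) -> None:
        rates = (
            self.germline_denovo_rate,
            self.mosaic_rate,
            self.contributory_mosaic_rate,
            self.contributory_germline_rate,
            self.inherited_het_density,
        )
        for r in rates:
            if not np.isfinite(r) or r < 0:
                raise ValueError(f"rates must be finite and >= 0, got {r}")
        if not np.isfinite(self.depth_mean) or self.depth_mean <= 0:
            raise ValueError("depth_mean must be positive")
        if self.depth_dispersion <= 0:
            raise ValueError("depth_dispersion must be positive")
        if not 0.0 <= self.reference_bias < 0.5:
            raise ValueError("reference_bias must lie in [0, 0.5)")
        if not 0.0 < self.sequencing_error < 0.5:
            raise ValueError("sequencing_error must lie in (0, 0.5)")
        if self.n_families < 1:
            raise ValueError("n_families must be >= 1")
        if isinstance(self.cell_fraction_distribution, tuple):
            lo, hi = self.cell_fraction_distribution
            if not (0.0 < lo <= hi <= 1.0):
                raise ValueError("cell fractions must lie in (0, 1]")

    def draw_cell_fractions(self, rng: np.random.Generator, n: int) -> np.ndarray:
        if callable(self.cell_fraction_distribution):
            out = np.asarray(self.cell_fraction_distribution(rng, n), dtype=float)
        else:
            lo, hi = self.cell_fraction_distribution
            out = rng.uniform(lo, hi, size=n)
        if n and (out.min() <= 0 or out.max() > 1):
            raise ValueError("cell fractions must lie in (0, 1]")
        return out


@dataclass(frozen=True, slots=True)
class SampleCall:
    """Per-sample evidence at one site: depth, alt depth, phred-scaled PLs."""

    dp: int
    ad: int
    pl: tuple  # (PL(0/0), PL(0/1), PL(1/1)), min rescaled to 0

    def __post_init__(self) -> None:
        if not 0 <= self.ad <= self.dp:
            raise ValueError("alt depth must satisfy 0 <= ad <= dp")

    @property
    def genotype_index(self) -> int:
        """Most likely diploid genotype (0: hom-ref, 1: het, 2: hom-alt)."""
        return int(np.argmin(self.pl))


@dataclass(frozen=True, slots=True)
class TrioVariantRecord:
    """One site in one quad family, with evidence for all four members."""

    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str
    family_id: str
    father: Optional[SampleCall]
    mother: Optional[SampleCall]
    proband: Optional[SampleCall]
    sibling: Optional[SampleCall]
    functional_class: str = "other"

    def sample(self, role: str) -> Optional[SampleCall]:
        return getattr(self, role)

    @property
    def site_key(self) -> tuple:
        return (self.chrom, self.pos, self.ref, self.alt)


@dataclass(frozen=True)
class PlantedVariant:
    chrom: str
    pos: int
    ref: str
    alt: str
    child_role: str  # which child carries it; for inherited hets, the carrier child
    truth_class: str  # inherited_het | germline_denovo | mosaic
    cell_fraction: float = 1.0
    parental_haplotype: Optional[str] = None  # paternal/maternal for de novo classes
    functional_class: str = "other"
    contributory: bool = False
    linked_het_pos: Optional[int] = None
    linked_het_origin: Optional[str] = None  # parent contributing the linked het ALT

    def __post_init__(self) -> None:
        if self.truth_class == MOSAIC and not self.cell_fraction < 1.0:
            raise ValueError("mosaic variants must have cell_fraction < 1")
        if self.truth_class == GERMLINE_DENOVO and self.cell_fraction != 1.0:
            raise ValueError("germline de novo variants must have cell_fraction = 1")


@dataclass
class FamilyTruth:
    family_id: str
    family_index: int
    member_ids: dict
    planted_variants: list = field(default_factory=list)


@dataclass(frozen=True)
class CoverageTrack:
    """Piecewise-constant depth: half-open 0-based intervals with one depth each."""

    starts: np.ndarray
    ends: np.ndarray
    depths: np.ndarray


def genotype_likelihoods(dp, ad, error: float = 0.001):
    """Phred-scaled diploid genotype likelihoods from read counts.

    Symmetric per-read error model: the probability a read shows the alternate
    allele is ``error`` under hom-ref, 0.5 under het and ``1 - error`` under
    hom-alt.  Values are rescaled so the best genotype has PL 0.  Vectorized
    over numpy arrays; returns an integer array of shape (..., 3).
    """
    dp = np.asarray(dp, dtype=float)
    ad = np.asarray(ad, dtype=float)
    p = np.array([error, 0.5, 1.0 - error])
    ll = ad[..., None] * np.log(p) + (dp - ad)[..., None] * np.log1p(-p)
    pl = -10.0 / np.log(10.0) * (ll - ll.max(axis=-1, keepdims=True))
    return np.rint(pl).astype(np.int64)


def _family_id(i: int) -> str:
    return f"fam{i:05d}"


def _member_ids(fid: str) -> dict:
    return {role: f"{fid}.{ROLE_SUFFIX[role]}" for role in ROLES}


def _draw_site(rng: np.random.Generator, capture_length: int) -> tuple:
    pos = int(rng.integers(1, capture_length + 1))
    ref_i = int(rng.integers(0, 4))
    alt_i = (ref_i + int(rng.integers(1, 4))) % 4
    return pos, str(_BASES[ref_i]), str(_BASES[alt_i])


def generate_cohort(config: CohortConfig) -> tuple:
    """Generate all variant records and per-family truth for a synthetic cohort.

    Returns ``(records, truths)`` where records are sorted by (chrom, pos,
    family_id) and truths parallel the family list.  Deterministic under
    ``config.seed``.  A handful of cohort-wide recurrent artifact sites (child
    carrier in several unrelated families) are planted to exercise the
    cohort-carrier filter of the de novo caller; these are not listed in the
    truth since they represent technical artifacts rather than real variants.
    """
    rng = np.random.default_rng(config.seed)
    truths: list[FamilyTruth] = []
    # plan rows: (family_index, pos, ref, alt, functional, p_alt per role, carried cf per role)
    plan: list[tuple] = []
    p_het = 0.5 * (1.0 - config.reference_bias)
    err = config.sequencing_error

    for i in range(config.n_families):
        fid = _family_id(i)
        truth = FamilyTruth(fid, i, _member_ids(fid))
        # standalone inherited heterozygous sites (child + one parent)
        for _ in range(config.inherited_sites_per_family):
            pos, ref, alt = _draw_site(rng, config.capture_length)
            child = CHILD_ROLES[int(rng.integers(0, 2))]
            parent = ("father", "mother")[int(rng.integers(0, 2))]
            pv = PlantedVariant(
                "1", pos, ref, alt, child, INHERITED_HET, cell_fraction=1.0
            )
            truth.planted_variants.append(pv)
            probs = {r: err for r in ROLES}
            probs[child] = p_het
            probs[parent] = p_het
            plan.append((i, pos, ref, alt, "other", probs))
        # de novo variants per child: (class, contributory, count)
        for child in CHILD_ROLES:
            extra_g = config.contributory_germline_rate if child == "proband" else 0.0
            extra_m = config.contributory_mosaic_rate if child == "proband" else 0.0
            batches = (
                (GERMLINE_DENOVO, False, rng.poisson(config.germline_denovo_rate)),
                (GERMLINE_DENOVO, True, rng.poisson(extra_g) if extra_g else 0),
                (MOSAIC, False, rng.poisson(config.mosaic_rate)),
                (MOSAIC, True, rng.poisson(extra_m) if extra_m else 0),
            )
            for truth_class, contributory, count in batches:
                for _ in range(int(count)):
                    pos, ref, alt = _draw_site(rng, config.capture_length)
                    cf = (
                        float(config.draw_cell_fractions(rng, 1)[0])
                        if truth_class == MOSAIC
                        else 1.0
                    )
                    hap = (
                        "paternal" if rng.random() < 0.5 else "maternal"
                    )
                    fclass = str(
                        rng.choice(_FUNCTIONAL_CLASSES, p=_FUNCTIONAL_PROBS)
                    )
                    # guarantee a linked, origin-resolvable inherited het in the
                    # phasing window; extra candidates follow the configured density
                    n_linked = max(1, int(rng.poisson(config.inherited_het_density)))
                    het_positions = []
                    for _ in range(n_linked):
                        off = 0
                        while off == 0:
                            off = int(
                                rng.integers(-config.phasing_window, config.phasing_window + 1)
                            )
                        het_positions.append(max(1, pos + off))
                    het_origin = "paternal" if rng.random() < 0.5 else "maternal"
                    pv = PlantedVariant(
                        "1",
                        pos,
                        ref,
                        alt,
                        child,
                        truth_class,
                        cell_fraction=cf,
                        parental_haplotype=hap,
                        functional_class=fclass,
                        contributory=contributory,
                        linked_het_pos=het_positions[0],
                        linked_het_origin=het_origin,
                    )
                    truth.planted_variants.append(pv)
                    probs = {r: err for r in ROLES}
                    probs[child] = 0.5 * cf * (1.0 - config.reference_bias)
                    plan.append((i, pos, ref, alt, fclass, probs))
                    # linked het record(s): het in the child and in the origin parent
                    parent = "father" if het_origin == "paternal" else "mother"
                    for hp in het_positions:
                        hpos, href, halt = hp, *_draw_site(rng, 3)[1:]
                        truth.planted_variants.append(
                            PlantedVariant("1", hpos, href, halt, child, INHERITED_HET)
                        )
                        hprobs = {r: err for r in ROLES}
                        hprobs[child] = p_het
                        hprobs[parent] = p_het
                        plan.append((i, hpos, href, halt, "other", hprobs))
        truths.append(truth)

    # recurrent cohort artifacts: same child-only site in several families
    for _ in range(config.common_variant_sites):
        pos, ref, alt = _draw_site(rng, config.capture_length)
        k = min(config.common_variant_carrier_families, config.n_families)
        fams = rng.choice(config.n_families, size=k, replace=False)
        for fi in np.sort(fams):
            probs = {r: err for r in ROLES}
            probs["proband"] = p_het
            plan.append((int(fi), pos, ref, alt, "other", probs))

    # vectorized read-count and likelihood sampling over the whole plan
    n = len(plan)
    prob_mat = np.array([[row[5][r] for r in ROLES] for row in plan])
    size = config.depth_dispersion
    nb_p = size / (size + config.depth_mean)
    dp = rng.negative_binomial(size, nb_p, size=(n, len(ROLES)))
    ad = rng.binomial(dp, prob_mat)
    pl = genotype_likelihoods(dp, ad, err)

    records = []
    for j, (fi, pos, ref, alt, fclass, _probs) in enumerate(plan):
        calls = {
            role: SampleCall(int(dp[j, k]), int(ad[j, k]), tuple(int(x) for x in pl[j, k]))
            for k, role in enumerate(ROLES)
        }
        records.append(
            TrioVariantRecord(
                "1", pos, ref, alt, _family_id(fi),
                calls["father"], calls["mother"], calls["proband"], calls["sibling"],
                functional_class=fclass,
            )
        )
    records.sort(key=lambda r: (r.chrom, r.pos, r.family_id, r.alt))
    return records, truths


def generate_phasing_reads(
    variant: PlantedVariant,
    config: CohortConfig,
    rng: np.random.Generator,
    n_reads: Optional[int] = None,
    low_quality_fraction: float = 0.05,
) -> list[PhasedRead]:
    """Simulate reads spanning a planted de novo variant and its linked het.

    Each read comes from one of the child's two parental haplotypes with equal
    probability.  Reads from the mutant haplotype carry the de novo allele with
    probability ``cell_fraction`` (1 for germline de novo variants); reads from
    the other haplotype never do.  The linked het's alt allele rides on the
    haplotype of its origin parent.  Per-base sequencing errors flip either
    observation at the configured error rate, and a fraction of reads get a
    low base quality so that read-level QC has something to remove.
    """
    if variant.truth_class == INHERITED_HET:
        raise ValueError("phasing reads are generated for de novo / mosaic variants")
    if variant.linked_het_origin is None or variant.parental_haplotype is None:
        raise ValueError("variant lacks linked-het phasing metadata")
    if n_reads is None:
        size = config.depth_dispersion
        nb_p = size / (size + config.depth_mean)
        n_reads = max(1, int(rng.negative_binomial(size, nb_p)))
    err = config.sequencing_error
    het_alt_on_mutant = variant.linked_het_origin == variant.parental_haplotype

    mutant_hap = rng.random(n_reads) < 0.5
    carries = mutant_hap & (rng.random(n_reads) < variant.cell_fraction)
    background_alt = np.where(mutant_hap, het_alt_on_mutant, not het_alt_on_mutant)
    # per-base sequencing error at each of the two sites
    carries = carries ^ (rng.random(n_reads) < err)
    background_alt = background_alt ^ (rng.random(n_reads) < err)
    low_q = rng.random((n_reads, 2)) < low_quality_fraction
    quals = np.where(low_q, 10, 40)
    return [
        PhasedRead(
            "alt" if background_alt[i] else "ref",
            bool(carries[i]),
            int(quals[i, 0]),
            int(quals[i, 1]),
        )
        for i in range(n_reads)
    ]


def generate_coverage_tracks(
    truth: FamilyTruth, config: CohortConfig
) -> dict:
    """Per-member piecewise-constant coverage over the capture region.

    Depth is drawn per bin of ``config.coverage_bin_size`` bp from the same
    negative-binomial law as variant-site depth.  Deterministic: the stream is
    keyed by (config.seed, family_index) so tracks can be regenerated per
    family without holding the whole cohort in memory.
    """
    rng = np.random.default_rng([config.seed, truth.family_index, 0xC0F])
    nbins = math.ceil(config.capture_length / config.coverage_bin_size)
    starts = np.arange(nbins, dtype=np.int64) * config.coverage_bin_size
    ends = np.minimum(starts + config.coverage_bin_size, config.capture_length)
    size = config.depth_dispersion
    nb_p = size / (size + config.depth_mean)
    tracks = {}
    for role in ROLES:
        depths = rng.negative_binomial(size, nb_p, size=nbins)
        tracks[role] = CoverageTrack(starts, ends, depths)
    return tracks


def generate_conservation_annotations(
    n_proband: int,
    n_sibling: int,
    phylop_shift: float = 0.0,
    seed: int = 0,
) -> "pandas.DataFrame":
    """Synthetic per-variant conservation annotation table.

    Proband variants get a configurable location shift on the PhyloP scale;
    gene-level scores (HomoloGene 0-31 and an ExAC-style pNull probability) are
    drawn from fixed background distributions.
    """
    import pandas as pd

    rng = np.random.default_rng(seed)
    n = n_proband + n_sibling
    cohort = np.array(["proband"] * n_proband + ["sibling"] * n_sibling)
    phylop = rng.normal(1.5, 1.5, size=n)
    phylop[: n_proband] += phylop_shift
    return pd.DataFrame(
        {
            "variant_key": [f"var{i:06d}" for i in range(n)],
            "cohort": cohort,
            "phylop_score": phylop,
            "homologene_score": rng.integers(0, 32, size=n),
            "exac_pnull": rng.uniform(0, 1, size=n),
        }
    )
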