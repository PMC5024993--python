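"""File interfaces: multi-sample VCF, BED/BedGraph, tab-delimited tables.

Variant records travel as VCF 4.2 with per-sample GT:DP:AD:PL; sample columns
follow the ``<family>.<fa|mo|p1|s1>`` naming convention so quad structure is
recoverable from the header alone.  Coverage is BedGraph; intervals are BED
(0-based half-open).  Calls, classifications, truth labels and phasing
results round-trip through tab-delimited tables with stable column names.
"""

from __future__ import annotations

import hashlib
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .caller import DeNovoCall
from .classify import MosaicClassification
from .cohort import (
    ROLE_SUFFIX,
    ROLES,
    CoverageTrack,
    FamilyTruth,
    SampleCall,
    TrioVariantRecord,
)

__all__ = [
    "write_vcf",
    "read_vcf",
    "write_bedgraph",
    "read_bedgraph",
    "write_bed",
    "read_bed",
    "calls_to_frame",
    "frame_to_calls",
    "classifications_to_frame",
    "truth_to_frame",
    "file_sha256",
]

_SUFFIX_TO_ROLE = {v: k for k, v in ROLE_SUFFIX.items()}
_MISSING = "./.:.:.:."
_GT = {0: "0/0", 1: "0/1", 2: "1/1"}


def write_vcf(records: Sequence[TrioVariantRecord], path, contig_length: Optional[int] = None) -> list:
    """Write records as a multi-sample VCF 4.2; returns the sample order.

    Samples absent at a site (families without evidence there) are emitted as
    missing.  One ALT per record (multi-allelic sites are represented as
    decomposed per-allele records).
    """
    families = sorted({r.family_id for r in records})
    samples = [f"{fam}.{ROLE_SUFFIX[role]}" for fam in families for role in ROLES]
    by_site: dict = {}
    for r in records:
        by_site.setdefault((r.chrom, r.pos, r.ref, r.alt), []).append(r)

    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n')
        fh.write(
            '##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">\n'
        )
        fh.write(
            '##FORMAT=<ID=PL,Number=G,Type=Integer,Description="Phred-scaled genotype likelihoods">\n'
        )
        fh.write('##INFO=<ID=FCLASS,Number=1,Type=String,Description="Functional class">\n')
        contigs = sorted({r.chrom for r in records})
        for c in contigs:
            if contig_length:
                fh.write(f"##contig=<ID={c},length={contig_length}>\n")
            else:
                fh.write(f"##contig=<ID={c}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
        fh.write("\t".join(samples) + "\n")
        for (chrom, pos, ref, alt), site_recs in sorted(by_site.items()):
            cells = {s: _MISSING for s in samples}
            fclass = site_recs[0].functional_class
            for r in site_recs:
                for role in ROLES:
                    sc = r.sample(role)
                    if sc is None:
                        continue
                    name = f"{r.family_id}.{ROLE_SUFFIX[role]}"
                    cells[name] = (
                        f"{_GT[sc.genotype_index]}:{sc.dp}:{sc.dp - sc.ad},{sc.ad}:"
                        + ",".join(str(x) for x in sc.pl)
                    )
            fh.write(
                f"{chrom}\t{pos}\t.\t{ref}\t{alt}\t.\tPASS\tFCLASS={fclass}\tGT:DP:AD:PL\t"
                + "\t".join(cells[s] for s in samples)
                + "\n"
            )
    return samples


def read_vcf(path) -> list:
    """Read a multi-sample VCF written by :func:`write_vcf` back into records.

    Requires the ``<family>.<fa|mo|p1|s1>`` sample naming convention; samples
    with missing genotypes at a site are skipped, and a family contributes a
    record only when all four members have evidence.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    fam_of = {}
    for i, s in enumerate(vcf.samples):
        fam, _, suffix = s.rpartition(".")
        if suffix not in _SUFFIX_TO_ROLE:
            raise ValueError(f"sample {s!r} does not follow the family.role convention")
        fam_of.setdefault(fam, {})[_SUFFIX_TO_ROLE[suffix]] = i
    records = []
    for v in vcf:
        fclass = v.INFO.get("FCLASS") or "other"
        depths = v.format("DP")
        ads = v.format("AD")
        pls = v.format("PL")
        for fam, idx in sorted(fam_of.items()):
            calls = {}
            for role, i in idx.items():
                dp = int(depths[i][0])
                if dp < 0:  # missing
                    calls = None
                    break
                ad = int(ads[i][1])
                pl = tuple(int(x) for x in pls[i][:3])
                m = min(pl)
                calls[role] = SampleCall(dp, ad, tuple(x - m for x in pl))
            if calls and len(calls) == len(ROLES):
                records.append(
                    TrioVariantRecord(
                        v.CHROM,
                        v.POS,
                        v.REF,
                        v.ALT[0],
                        fam,
                        calls["father"],
                        calls["mother"],
                        calls["proband"],
                        calls["sibling"],
                        functional_class=fclass,
                    )
                )
    return records


def write_bedgraph(track: CoverageTrack, path, chrom: str = "1") -> None:
    with open(path, "w") as fh:
        for s, e, d in zip(track.starts, track.ends, track.depths):
            fh.write(f"{chrom}\t{s}\t{e}\t{d}\n")


def read_bedgraph(path) -> CoverageTrack:
    df = pd.read_csv(path, sep="\t", header=None, names=["chrom", "start", "end", "depth"])
    return CoverageTrack(
        df["start"].to_numpy(np.int64),
        df["end"].to_numpy(np.int64),
        df["depth"].to_numpy(),
    )


def write_bed(intervals: np.ndarray, path, chrom: str = "1") -> None:
    with open(path, "w") as fh:
        for s, e in np.asarray(intervals, dtype=np.int64).reshape(-1, 2):
            fh.write(f"{chrom}\t{s}\t{e}\n")


def read_bed(path) -> np.ndarray:
    df = pd.read_csv(path, sep="\t", header=None, usecols=[1, 2], names=["start", "end"])
    return df.to_numpy(np.int64)


_CALL_COLUMNS = [
    "chrom",
    "pos",
    "ref",
    "alt",
    "family_id",
    "child_id",
    "child_role",
    "total_depth",
    "alt_depth",
    "variant_type",
    "functional_class",
]


def calls_to_frame(calls: Iterable[DeNovoCall]) -> pd.DataFrame:
    df = pd.DataFrame([[getattr(c, col) for col in _CALL_COLUMNS] for c in calls],
                      columns=_CALL_COLUMNS)
    if len(df):
        df["AARF"] = df["alt_depth"] / df["total_depth"]
    return df


def frame_to_calls(df: pd.DataFrame) -> list:
    return [
        DeNovoCall(**{col: row[col] for col in _CALL_COLUMNS}) for _, row in df.iterrows()
    ]


def classifications_to_frame(classifications: Iterable[MosaicClassification]) -> pd.DataFrame:
    """Call table with p_mosaic / q_value / in_final_callset columns appended."""
    rows = []
    for mc in classifications:
        base = {col: getattr(mc.call, col) for col in _CALL_COLUMNS}
        base.update(
            AARF=mc.aarf,
            p_mosaic=mc.p_mosaic,
            q_value=mc.q_value,
            label=mc.label,
            in_final_callset=True,
        )
        rows.append(base)
    return pd.DataFrame(rows)


def truth_to_frame(truths: Iterable[FamilyTruth]) -> pd.DataFrame:
    rows = []
    for t in truths:
        for pv in t.planted_variants:
            rows.append(
                {
                    "family_id": t.family_id,
                    "chrom": pv.chrom,
                    "pos": pv.pos,
                    "ref": pv.ref,
                    "alt": pv.alt,
                    "child_role": pv.child_role,
                    "truth_class": pv.truth_class,
                    "cell_fraction": pv.cell_fraction,
                    "parental_haplotype": pv.parental_haplotype or "",
                    "functional_class": pv.functional_class,
                    "contributory": pv.contributory,
                    "linked_het_pos": pv.linked_het_pos or -1,
                    "linked_het_origin": pv.linked_het_origin or "",
                }
            )
    return pd.DataFrame(rows)


def file_sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()
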