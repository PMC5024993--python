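"""Validation bookkeeping: detection and classification precision.

Detection precision is the fraction of assay-successful validations in which
the variant was found present in the sample.  Classification precision is
stricter: the variant must be present *and* its observed mosaic/germline
status must match the prediction, with the same denominator, so an absent
variant counts against classification as well.  For read-backed phasing the
"assay success" flag means the phasing was informative.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence, Set

import pandas as pd

__all__ = [
    "ValidationOutcome",
    "detection_precision",
    "classification_precision",
    "summarize_validation",
    "allelic_noise",
]


@dataclass(frozen=True)
class ValidationOutcome:
    variant_key: str
    predicted_label: str  # mosaic | germline_denovo
    assay: str  # sanger | pyro | phasing
    assay_success: bool
    variant_present: Optional[bool] = None  # None when the assay failed
    observed_label: Optional[str] = None  # mosaic | germline_denovo | unknown
    filter_stage: str = "post"  # pre | post


def detection_precision(outcomes: Iterable[ValidationOutcome]) -> float:
    """(# variant present) / (# assay successful)."""
    successful = [o for o in outcomes if o.assay_success]
    if not successful:
        raise ValueError("detection precision undefined with zero successful assays")
    return sum(bool(o.variant_present) for o in successful) / len(successful)


def classification_precision(
    outcomes: Iterable[ValidationOutcome], predicted_label: str
) -> float:
    """(# present and observed label matches) / (# assay-successful with that prediction)."""
    informative = [
        o for o in outcomes if o.assay_success and o.predicted_label == predicted_label
    ]
    if not informative:
        raise ValueError(
            f"classification precision undefined: no informative outcomes "
            f"predicted {predicted_label!r}"
        )
    hits = sum(
        1
        for o in informative
        if o.variant_present is not False and o.observed_label == predicted_label
    )
    return hits / len(informative)


def summarize_validation(outcomes: Sequence[ValidationOutcome]) -> pd.DataFrame:
    """Per (filter stage, predicted label, assay) validation summary table.

    Columns mirror the printed validation tables: chosen, assay successes,
    variants present, detection precision, variants observed mosaic, and
    classification precision.  Empty input yields an empty table.
    """
    cols = [
        "filter_stage",
        "predicted_label",
        "assay",
        "chosen",
        "success",
        "present",
        "detection_precision",
        "observed_mosaic",
        "classification_precision",
    ]
    rows = []
    groups: dict = {}
    for o in outcomes:
        groups.setdefault((o.filter_stage, o.predicted_label, o.assay), []).append(o)
    for (stage, label, assay), grp in sorted(groups.items()):
        successful = [o for o in grp if o.assay_success]
        present = sum(bool(o.variant_present) for o in successful)
        obs_mosaic = sum(
            1
            for o in successful
            if o.variant_present is not False and o.observed_label == "mosaic"
        )
        det = present / len(successful) if successful else float("nan")
        cls = (
            classification_precision(grp, label) if successful else float("nan")
        )
        rows.append((stage, label, assay, len(grp), len(successful), present, det, obs_mosaic, cls))
    return pd.DataFrame(rows, columns=cols)


def allelic_noise(
    site_counts: Mapping[str, tuple],
    hom_ref_samples: Set[str],
    excluded_samples: Set[str] = frozenset(),
) -> float:
    """Maximum per-allele background alt-read fraction over hom-ref samples.

    ``site_counts`` maps sample id to ``(alt_reads_per_allele, total_reads)``
    where ``alt_reads_per_allele`` is a sequence with one count per alternate
    allele.  For each alternate allele the noise is the summed alt reads over
    all non-excluded hom-ref samples divided by their summed total reads; the
    highest allele's noise is returned.
    """
    used = [
        site_counts[s]
        for s in site_counts
        if s in hom_ref_samples and s not in excluded_samples
    ]
    total = sum(t for _, t in used)
    if not used or total == 0:
        raise ValueError("allelic noise undefined without covered hom-ref samples")
    n_alleles = {len(a) for a, _ in used}
    if len(n_alleles) != 1:
        raise ValueError("samples disagree on the number of alternate alleles")
    noises = [
        sum(a[i] for a, _ in used) / total for i in range(n_alleles.pop())
    ]
    return max(noises)
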