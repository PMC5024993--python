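"""End-to-end orchestration: simulate -> call -> classify -> phase -> rates -> contribution.

A single declarative config (YAML, one section per stage) drives the run; all
randomness derives from one root seed through stage-salted substreams, so a
config plus seed pins every output byte.  Each stage communicates with the
next only through its declared tables, which are also written to the output
directory together with a manifest of parameters and file hashes.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import io as mio
from .caller import CallerParams, find_denovo, exclude_families
from .classify import ClassifierParams, callset_summary, classify
from .cohort import (
    CHILD_ROLES,
    ROLE_SUFFIX,
    CohortConfig,
    generate_cohort,
    generate_coverage_tracks,
    generate_phasing_reads,
)
from .contribution import (
    ClassificationErrors,
    ObservedRates,
    credible_interval,
    solve_model,
)
from .phasing import observation_from_reads, phase_denovo
from .rates import compare_rates, joint_region, mutation_rate, regions_at_depth

__all__ = [
    "PhasingStageParams",
    "RatesStageParams",
    "ContributionStageParams",
    "RunConfig",
    "PipelineResult",
    "run_pipeline",
]

logger = logging.getLogger(__name__)

_GERMLINE = "germline_denovo"
_MOSAIC = "mosaic"


@dataclass(frozen=True)
class PhasingStageParams:
    min_support: int = 2
    min_base_quality: int = 20


@dataclass(frozen=True)
class RatesStageParams:
    depth_threshold: int = 40


@dataclass(frozen=True)
class ContributionStageParams:
    n_perm: int = 10_000
    prior: str = "uniform"
    case_model: str = "expected"


_SECTIONS = {
    "cohort": CohortConfig,
    "caller": CallerParams,
    "classifier": ClassifierParams,
    "phasing": PhasingStageParams,
    "rates": RatesStageParams,
    "contribution": ContributionStageParams,
}


@dataclass
class RunConfig:
    cohort: CohortConfig = field(default_factory=CohortConfig)
    caller: CallerParams = field(default_factory=CallerParams)
    classifier: ClassifierParams = field(default_factory=ClassifierParams)
    phasing: PhasingStageParams = field(default_factory=PhasingStageParams)
    rates: RatesStageParams = field(default_factory=RatesStageParams)
    contribution: ContributionStageParams = field(default_factory=ContributionStageParams)
    seed: int = 0
    output_dir: Optional[str] = None
    write_vcf: bool = True
    verbosity: str = "info"

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        """Build and validate a config; unknown keys anywhere are an error."""
        top_known = set(_SECTIONS) | {"seed", "output_dir", "write_vcf", "verbosity"}
        unknown = set(data) - top_known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        kwargs = {}
        for section, klass in _SECTIONS.items():
            block = data.get(section, {})
            fields = {f.name for f in dataclasses.fields(klass)}
            bad = set(block) - fields
            if bad:
                raise ValueError(f"unknown keys in [{section}]: {sorted(bad)}")
            if section == "cohort" and "cell_fraction_distribution" in block:
                block = dict(block)
                block["cell_fraction_distribution"] = tuple(
                    block["cell_fraction_distribution"]
                )
            kwargs[section] = klass(**block)
        for key in ("seed", "output_dir", "write_vcf", "verbosity"):
            if key in data:
                kwargs[key] = data[key]
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)


def _stage_seed(root: int, stage: int) -> int:
    return int(np.random.SeedSequence([root, stage]).generate_state(1)[0] % (2**31))


@dataclass
class PipelineResult:
    records: list
    truths: list
    calls: list
    excluded_families: list
    classifications: list
    phasing_table: pd.DataFrame
    classification_errors: ClassificationErrors
    rate_table: pd.DataFrame
    rate_comparisons: dict
    observed_rates: ObservedRates
    contribution: object
    contribution_ci: dict
    summary: dict
    manifest: dict


def _phase_stage(config: RunConfig, calls, classifications, truths, rng) -> tuple:
    truth_index = {}
    for t in truths:
        for pv in t.planted_variants:
            if pv.truth_class in (_GERMLINE, _MOSAIC):
                truth_index[(t.family_id, pv.pos, pv.child_role)] = pv
    rows = []
    counts = {(c, k): [0, 0] for c in ("proband", "sibling") for k in (_MOSAIC, _GERMLINE)}
    for mc in classifications:
        call = mc.call
        pv = truth_index.get((call.family_id, call.pos, call.child_role))
        if pv is None:
            rows.append(
                dict(
                    child_id=call.child_id, chrom=call.chrom, pos=call.pos,
                    label=mc.label, truth_class="", informative=False,
                    phase_mosaic=None, mosaic_frac=np.nan, parent="undetermined",
                )
            )
            continue
        reads = generate_phasing_reads(pv, config.cohort, rng)
        obs = observation_from_reads(
            reads,
            het_pos=pv.linked_het_pos,
            parent_of_inherited_alt=pv.linked_het_origin,
            min_base_quality=config.phasing.min_base_quality,
        )
        res = phase_denovo(obs, config.phasing.min_support)
        rows.append(
            dict(
                child_id=call.child_id, chrom=call.chrom, pos=call.pos,
                label=mc.label, truth_class=pv.truth_class,
                informative=res.informative, phase_mosaic=res.mosaic,
                mosaic_frac=res.mosaic_frac if res.mosaic_frac is not None else np.nan,
                parent=res.parent,
            )
        )
        if res.informative:
            key = (call.child_role, mc.label)
            counts[key][1] += 1
            refuted = (mc.label == _MOSAIC and res.mosaic is False) or (
                mc.label == _GERMLINE and res.mosaic is True
            )
            if refuted:
                counts[key][0] += 1
    errors = ClassificationErrors(
        proband_mosaic=tuple(counts[("proband", _MOSAIC)]),
        proband_germline=tuple(counts[("proband", _GERMLINE)]),
        sibling_mosaic=tuple(counts[("sibling", _MOSAIC)]),
        sibling_germline=tuple(counts[("sibling", _GERMLINE)]),
    )
    return pd.DataFrame(rows), errors


def _rates_stage(config: RunConfig, classifications, truths, excluded) -> tuple:
    capture = np.array([[0, config.cohort.capture_length]], dtype=np.int64)
    by_child: dict = {}
    for mc in classifications:
        by_child.setdefault(mc.call.child_id, []).append((mc.call, mc.label))
    rows = []
    per_group: dict = {
        (role, klass): []
        for role in CHILD_ROLES
        for klass in (_MOSAIC, _GERMLINE)
    }
    excluded_set = set(excluded)
    for truth in truths:
        if truth.family_id in excluded_set:
            continue
        tracks = generate_coverage_tracks(truth, config.cohort)
        member_iv = {
            role: regions_at_depth(tracks[role], config.rates.depth_threshold)
            for role in tracks
        }
        for role in CHILD_ROLES:
            child_id = f"{truth.family_id}.{ROLE_SUFFIX[role]}"
            jr = joint_region(
                member_iv[role],
                member_iv["father"],
                member_iv["mother"],
                capture,
                truth.family_id,
                child_id,
            )
            ests = mutation_rate(
                by_child.get(child_id, []), jr, config.cohort.capture_length, role
            )
            if ests is None:
                continue
            for est in ests:
                rows.append(
                    dict(
                        child_id=est.child_id,
                        role=est.role,
                        mosaic_class=est.mosaic_class,
                        functional_class=est.functional_class,
                        count_in_joint=est.count_in_joint,
                        joint_length=est.joint_length,
                        extrapolated_count=est.extrapolated_count,
                    )
                )
                if est.functional_class == "all":
                    per_group[(role, est.mosaic_class)].append(est.extrapolated_count)
    comparisons = {}
    for klass in (_MOSAIC, _GERMLINE):
        comparisons[klass] = compare_rates(
            per_group[("proband", klass)],
            per_group[("sibling", klass)],
            seed=_stage_seed(config.seed, 5),
        )
    observed = ObservedRates(
        proband_mosaic=float(np.mean(per_group[("proband", _MOSAIC)])),
        proband_germline=float(np.mean(per_group[("proband", _GERMLINE)])),
        sibling_mosaic=float(np.mean(per_group[("sibling", _MOSAIC)])),
        sibling_germline=float(np.mean(per_group[("sibling", _GERMLINE)])),
    )
    return pd.DataFrame(rows), comparisons, observed


def run_pipeline(config: RunConfig) -> PipelineResult:
    """Run all stages in dependency order and (optionally) write outputs.

    Deterministic: the same config and seed yield identical tables and
    identical manifest hashes.
    """
    logging.basicConfig(level=getattr(logging, config.verbosity.upper(), logging.INFO))
    cohort_cfg = replace(config.cohort, seed=_stage_seed(config.seed, 1))

    logger.info("simulate: %d families", cohort_cfg.n_families)
    records, truths = generate_cohort(cohort_cfg)

    logger.info("call-denovo: %d records", len(records))
    calls = find_denovo(records, config.caller)
    calls, excluded = exclude_families(calls, config.caller.family_exclusion_threshold)
    logger.info("called %d de novo variants; %d families excluded", len(calls), len(excluded))

    classifications = classify(calls, config.classifier)
    summary = callset_summary(classifications)
    summary["excluded_families"] = len(excluded)

    cfg_for_reads = replace(config, cohort=cohort_cfg)
    phasing_table, errors = _phase_stage(
        cfg_for_reads, calls, classifications,
        truths, np.random.default_rng(_stage_seed(config.seed, 2)),
    )
    rate_table, comparisons, observed = _rates_stage(cfg_for_reads, classifications, truths, excluded)
    estimate = solve_model(observed, errors, config.contribution.case_model)
    ci = credible_interval(
        observed,
        errors,
        n_perm=config.contribution.n_perm,
        seed=_stage_seed(config.seed, 3),
        prior=config.contribution.prior,
        case_model=config.contribution.case_model,
    )

    manifest: dict = {
        "seed": config.seed,
        "parameters": {
            name: dataclasses.asdict(getattr(config, name)) for name in _SECTIONS
        },
        "summary": summary,
        "outputs": {},
    }
    # tuples inside cell_fraction_distribution are not JSON-stable; normalise
    cfd = manifest["parameters"]["cohort"]["cell_fraction_distribution"]
    if isinstance(cfd, tuple):
        manifest["parameters"]["cohort"]["cell_fraction_distribution"] = list(cfd)

    if config.output_dir is not None:
        out = Path(config.output_dir)
        out.mkdir(parents=True, exist_ok=True)
        tables = {
            "calls.tsv": mio.calls_to_frame(calls),
            "classifications.tsv": mio.classifications_to_frame(classifications),
            "phasing.tsv": phasing_table,
            "rates.tsv": rate_table,
            "truth.tsv": mio.truth_to_frame(truths),
        }
        for name, df in tables.items():
            df.to_csv(out / name, sep="\t", index=False)
            manifest["outputs"][name] = mio.file_sha256(out / name)
        if config.write_vcf:
            mio.write_vcf(records, out / "cohort.vcf", cohort_cfg.capture_length)
            manifest["outputs"]["cohort.vcf"] = mio.file_sha256(out / "cohort.vcf")
        contrib = {
            "observed_rates": dataclasses.asdict(observed),
            "baseline": estimate.baseline,
            "contributory": estimate.contributory,
            "percent_of_cases": estimate.percent_of_cases,
            "fraction_contributory": estimate.fraction_contributory,
            "decomposition": estimate.decomposition,
            "credible_interval": {f"{q}.{k}": v for (q, k), v in ci.items()},
        }
        with open(out / "contribution.json", "w") as fh:
            json.dump(contrib, fh, indent=2)
        manifest["outputs"]["contribution.json"] = mio.file_sha256(out / "contribution.json")
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2)

    return PipelineResult(
        records=records,
        truths=truths,
        calls=calls,
        excluded_families=excluded,
        classifications=classifications,
        phasing_table=phasing_table,
        classification_errors=errors,
        rate_table=rate_table,
        rate_comparisons=comparisons,
        observed_rates=observed,
        contribution=estimate,
        contribution_ci=ci,
        summary=summary,
        manifest=manifest,
    )
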