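"""Misclassification-aware model of baseline and contributory variation.

Siblings carry a baseline rate of de novo variation; probands carry the same
baseline plus *contributory* variation associated with their diagnosis.  The
mosaic/germline classifier errs in both directions, so observed classified
rates mix the true classes.  With eps_c the fraction of class-c calls that
are truly the other class (measured by phasing validation, per cohort and per
class), the true rates follow from the observed ones:

    B_m = O^s_m (1 - eps^s_m) + O^s_g eps^s_g        (sibling = baseline)
    B_g = O^s_g (1 - eps^s_g) + O^s_m eps^s_m
    T_m = O^p_m (1 - eps^p_m) + O^p_g eps^p_g        (proband = true total)
    T_g = O^p_g (1 - eps^p_g) + O^p_m eps^p_m

Contributory rates are C_x = T_x - B_x; the percent of cases attributed to a
class is 100 x C_x (expected-count reading, with a Poisson P(>=1) variant
available), and the contributory fraction is C_x / T_x.  Uncertainty in the
error rates is propagated by drawing each eps from a Beta posterior given its
validation counts and re-solving; the 2.5th/97.5th percentiles over draws
form a 95% credible interval.  The observed rates themselves are not
resampled.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

__all__ = [
    "ObservedRates",
    "ClassificationErrors",
    "ContributionEstimate",
    "solve_model",
    "credible_interval",
    "forward_observed_rates",
]

CLASSES = ("mosaic", "germline")
COHORTS = ("proband", "sibling")


@dataclass(frozen=True)
class ObservedRates:
    """Mean classified mutations per exome, per cohort and classified class."""

    proband_mosaic: float
    proband_germline: float
    sibling_mosaic: float
    sibling_germline: float

    def __post_init__(self) -> None:
        for name in ("proband_mosaic", "proband_germline", "sibling_mosaic", "sibling_germline"):
            v = getattr(self, name)
            if not np.isfinite(v) or v < 0:
                raise ValueError(f"{name} must be finite and >= 0")

    def observed(self, cohort: str, klass: str) -> float:
        return getattr(self, f"{cohort}_{klass}")


@dataclass(frozen=True)
class ClassificationErrors:
    """Phasing-validation misclassification counts per cohort x classified class.

    Each field is ``(misclassified, informative)``: of the phasing-informative
    calls classified into that class in that cohort, how many the phasing
    showed to be the other class.
    """

    proband_mosaic: tuple
    proband_germline: tuple
    sibling_mosaic: tuple
    sibling_germline: tuple

    def __post_init__(self) -> None:
        for name in ("proband_mosaic", "proband_germline", "sibling_mosaic", "sibling_germline"):
            mis, inf = getattr(self, name)
            if not 0 <= mis <= inf:
                raise ValueError(f"{name}: need 0 <= misclassified <= informative")

    def counts(self, cohort: str, klass: str) -> tuple:
        return getattr(self, f"{cohort}_{klass}")

    def rate(self, cohort: str, klass: str) -> float:
        mis, inf = self.counts(cohort, klass)
        if inf == 0:
            warnings.warn(
                f"no informative phasing validations for {cohort} {klass}; "
                f"error rate treated as 0"
            )
            return 0.0
        return mis / inf


@dataclass
class ContributionEstimate:
    baseline: dict
    proband_true: dict
    contributory: dict
    percent_of_cases: dict
    fraction_contributory: dict
    decomposition: dict  # classified class -> {total, correct, incorrect}
    ci: Optional[dict] = None
    warnings_: list = field(default_factory=list)


def _solve_arrays(obs: ObservedRates, eps: dict, case_model: str = "expected") -> dict:
    """Model solution; eps values may be scalars or aligned numpy arrays."""
    e_pm, e_pg = eps[("proband", "mosaic")], eps[("proband", "germline")]
    e_sm, e_sg = eps[("sibling", "mosaic")], eps[("sibling", "germline")]
    o_pm, o_pg = obs.proband_mosaic, obs.proband_germline
    o_sm, o_sg = obs.sibling_mosaic, obs.sibling_germline

    b_m = o_sm * (1.0 - e_sm) + o_sg * e_sg
    b_g = o_sg * (1.0 - e_sg) + o_sm * e_sm
    t_m = o_pm * (1.0 - e_pm) + o_pg * e_pg
    t_g = o_pg * (1.0 - e_pg) + o_pm * e_pm
    c_m = t_m - b_m
    c_g = t_g - b_g

    if case_model == "expected":
        pc_m, pc_g = 100.0 * c_m, 100.0 * c_g
    elif case_model == "poisson":
        pc_m, pc_g = 100.0 * (1.0 - np.exp(-c_m)), 100.0 * (1.0 - np.exp(-c_g))
    else:
        raise ValueError(f"unknown case_model {case_model!r}")

    with np.errstate(divide="ignore", invalid="ignore"):
        f_m = np.where(t_m != 0, c_m / t_m, np.nan)
        f_g = np.where(t_g != 0, c_g / t_g, np.nan)

    # decomposition of classified-class contributory mass (stacked-bar view):
    # observed classified contributory O_c satisfies [C] = A [O_c] with
    # A = [[1-e_pm, e_pg], [e_pm, 1-e_pg]]; invert, then split each classified
    # class by its own proband error rate into correct/incorrect portions.
    det = 1.0 - e_pm - e_pg
    oc_m = ((1.0 - e_pg) * c_m - e_pg * c_g) / det
    oc_g = ((1.0 - e_pm) * c_g - e_pm * c_m) / det
    return {
        ("baseline", "mosaic"): b_m,
        ("baseline", "germline"): b_g,
        ("proband_true", "mosaic"): t_m,
        ("proband_true", "germline"): t_g,
        ("contributory", "mosaic"): c_m,
        ("contributory", "germline"): c_g,
        ("percent_of_cases", "mosaic"): pc_m,
        ("percent_of_cases", "germline"): pc_g,
        ("fraction_contributory", "mosaic"): f_m,
        ("fraction_contributory", "germline"): f_g,
        ("classified_contributory", "mosaic"): oc_m,
        ("classified_contributory", "germline"): oc_g,
        ("classified_contributory_correct", "mosaic"): (1.0 - e_pm) * oc_m,
        ("classified_contributory_incorrect", "mosaic"): e_pm * oc_m,
        ("classified_contributory_correct", "germline"): (1.0 - e_pg) * oc_g,
        ("classified_contributory_incorrect", "germline"): e_pg * oc_g,
    }


def solve_model(
    observed: ObservedRates,
    errors: ClassificationErrors,
    case_model: str = "expected",
) -> ContributionEstimate:
    """Point estimates of baseline/contributory rates per true class.

    Negative contributory rates (possible under sampling noise) are reported
    as-is with a warning, never clipped.
    """
    eps = {(c, k): errors.rate(c, k) for c in COHORTS for k in CLASSES}
    sol = _solve_arrays(observed, eps, case_model)
    notes = []
    for klass in CLASSES:
        if sol[("contributory", klass)] < 0:
            msg = f"negative contributory {klass} rate (sampling noise); reported as-is"
            warnings.warn(msg)
            notes.append(msg)
    decomposition = {
        klass: {
            "total": float(sol[("classified_contributory", klass)]),
            "correct": float(sol[("classified_contributory_correct", klass)]),
            "incorrect": float(sol[("classified_contributory_incorrect", klass)]),
        }
        for klass in CLASSES
    }
    pick = lambda name: {k: float(sol[(name, k)]) for k in CLASSES}
    return ContributionEstimate(
        baseline=pick("baseline"),
        proband_true=pick("proband_true"),
        contributory=pick("contributory"),
        percent_of_cases=pick("percent_of_cases"),
        fraction_contributory=pick("fraction_contributory"),
        decomposition=decomposition,
        warnings_=notes,
    )


def _beta_params(prior: str) -> tuple:
    if prior == "uniform":
        return 1.0, 1.0
    if prior == "jeffreys":
        return 0.5, 0.5
    raise ValueError(f"unknown prior {prior!r}")


def credible_interval(
    observed: ObservedRates,
    errors: ClassificationErrors,
    n_perm: int = 10_000,
    seed: int = 0,
    prior: str = "uniform",
    case_model: str = "expected",
) -> dict:
    """95% credible intervals for every model output.

    Each error rate is drawn ``n_perm`` times from Beta(mis + a, inf - mis + b)
    (uniform prior a = b = 1 by default), the model is re-solved per draw, and
    the 2.5/97.5 percentiles are returned keyed by ``(quantity, class)``.
    Cohort-class cells with zero informative validations keep a degenerate
    error rate of 0.  Deterministic under the seed.
    """
    a, b = _beta_params(prior)
    rng = np.random.default_rng(seed)
    eps = {}
    for cohort in COHORTS:
        for klass in CLASSES:
            mis, inf = errors.counts(cohort, klass)
            if inf == 0:
                eps[(cohort, klass)] = np.zeros(n_perm)
            else:
                eps[(cohort, klass)] = rng.beta(mis + a, inf - mis + b, size=n_perm)
    sol = _solve_arrays(observed, eps, case_model)
    out = {}
    for key, values in sol.items():
        arr = np.asarray(values, dtype=float)
        if arr.ndim == 0:
            arr = np.full(n_perm, float(arr))
        lo, hi = np.nanpercentile(arr, [2.5, 97.5])
        out[key] = (float(lo), float(hi))
    return out


def forward_observed_rates(
    baseline: dict, contributory: dict, errors: ClassificationErrors
) -> ObservedRates:
    """Map true (baseline, contributory) rates to expected observed classified rates.

    The exact inverse of :func:`solve_model` given the same error rates; used
    for forward-model residual checks and for constructing consistent inputs.
    """
    def invert(cohort: str, t_m: float, t_g: float) -> tuple:
        e_m = errors.rate(cohort, "mosaic")
        e_g = errors.rate(cohort, "germline")
        det = 1.0 - e_m - e_g
        o_m = ((1.0 - e_g) * t_m - e_g * t_g) / det
        o_g = ((1.0 - e_m) * t_g - e_m * t_m) / det
        return o_m, o_g

    o_pm, o_pg = invert(
        "proband",
        baseline["mosaic"] + contributory["mosaic"],
        baseline["germline"] + contributory["germline"],
    )
    o_sm, o_sg = invert("sibling", baseline["mosaic"], baseline["germline"])
    return ObservedRates(o_pm, o_pg, o_sm, o_sg)
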