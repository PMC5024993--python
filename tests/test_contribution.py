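"""Misclassification-aware contribution model: inversion, decomposition, intervals."""

import warnings

import numpy as np
import pytest

from mosaicdn import (
    ClassificationErrors,
    ObservedRates,
    credible_interval,
    forward_observed_rates,
    solve_model,
)

NO_ERRORS = ClassificationErrors((0, 100), (0, 100), (0, 100), (0, 100))


def _forward_oracle(b_m, b_g, c_m, c_g, eps):
    """Independent forward map true -> observed (linear-system solve)."""
    out = {}
    for cohort, (t_m, t_g) in (
        ("proband", (b_m + c_m, b_g + c_g)),
        ("sibling", (b_m, b_g)),
    ):
        e_m, e_g = eps[(cohort, "mosaic")], eps[(cohort, "germline")]
        A = np.array([[1 - e_m, e_g], [e_m, 1 - e_g]])
        o = np.linalg.solve(A, np.array([t_m, t_g]))
        out[cohort] = o
    return ObservedRates(out["proband"][0], out["proband"][1],
                         out["sibling"][0], out["sibling"][1])


class TestSolveModel:
    def test_without_errors_reduces_to_rate_difference(self):
        obs = ObservedRates(0.3, 0.3, 0.2, 0.2)
        est = solve_model(obs, NO_ERRORS)
        for klass in ("mosaic", "germline"):
            assert est.contributory[klass] == pytest.approx(0.1)
            assert est.fraction_contributory[klass] == pytest.approx(1 / 3)
            assert est.percent_of_cases[klass] == pytest.approx(10.0)

    def test_equal_cohorts_have_zero_contribution_for_any_errors(self):
        obs = ObservedRates(0.25, 0.9, 0.25, 0.9)
        errors = ClassificationErrors((4, 30), (31, 468), (4, 30), (31, 468))
        est = solve_model(obs, errors)
        assert est.contributory["mosaic"] == pytest.approx(0.0, abs=1e-12)
        assert est.contributory["germline"] == pytest.approx(0.0, abs=1e-12)

    def test_inverts_forward_map_to_machine_precision(self, rng):
        for _ in range(100):
            b_m, b_g = rng.uniform(0.1, 0.3), rng.uniform(0.5, 1.2)
            c_m, c_g = rng.uniform(0, 0.1), rng.uniform(0, 0.1)
            counts = {}
            eps = {}
            for cohort in ("proband", "sibling"):
                # error magnitudes in the regime the phasing validation measures:
                # mosaic calls err at up to ~25%, germline calls at a few percent
                mis_m = int(rng.integers(0, 9))
                inf_m = int(rng.integers(35, 100))
                mis_g = int(rng.integers(0, 13))
                inf_g = int(rng.integers(300, 500))
                counts[(cohort, "mosaic")] = (mis_m, inf_m)
                counts[(cohort, "germline")] = (mis_g, inf_g)
                eps[(cohort, "mosaic")] = mis_m / inf_m
                eps[(cohort, "germline")] = mis_g / inf_g
            errors = ClassificationErrors(
                counts[("proband", "mosaic")], counts[("proband", "germline")],
                counts[("sibling", "mosaic")], counts[("sibling", "germline")],
            )
            obs = _forward_oracle(b_m, b_g, c_m, c_g, eps)
            est = solve_model(obs, errors)
            assert est.baseline["mosaic"] == pytest.approx(b_m, abs=1e-12)
            assert est.baseline["germline"] == pytest.approx(b_g, abs=1e-12)
            assert est.contributory["mosaic"] == pytest.approx(c_m, abs=1e-12)
            assert est.contributory["germline"] == pytest.approx(c_g, abs=1e-12)
            # package's own forward map agrees with the independent oracle
            own = forward_observed_rates(
                {"mosaic": b_m, "germline": b_g},
                {"mosaic": c_m, "germline": c_g},
                errors,
            )
            assert own.proband_mosaic == pytest.approx(obs.proband_mosaic, abs=1e-12)

    def test_decomposition_sums_back_to_true_contributory(self, rng):
        errors = ClassificationErrors((4, 30), (31, 468), (6, 39), (10, 337))
        obs = ObservedRates(0.15, 0.95, 0.1, 0.88)
        est = solve_model(obs, errors)
        d = est.decomposition
        for klass in ("mosaic", "germline"):
            assert d[klass]["correct"] + d[klass]["incorrect"] == pytest.approx(
                d[klass]["total"]
            )
        # mapping classified contributory mass back through the proband error
        # rates recovers the true contributory rates
        e_m = 4 / 30
        e_g = 31 / 468
        c_m = (1 - e_m) * d["mosaic"]["total"] + e_g * d["germline"]["total"]
        c_g = e_m * d["mosaic"]["total"] + (1 - e_g) * d["germline"]["total"]
        assert c_m == pytest.approx(est.contributory["mosaic"], abs=1e-12)
        assert c_g == pytest.approx(est.contributory["germline"], abs=1e-12)

    def test_negative_contribution_reported_with_warning_not_clipped(self):
        obs = ObservedRates(0.1, 0.8, 0.2, 0.8)
        with pytest.warns(UserWarning, match="negative contributory"):
            est = solve_model(obs, NO_ERRORS)
        assert est.contributory["mosaic"] == pytest.approx(-0.1)

    def test_poisson_case_model_agrees_to_first_order(self):
        obs = ObservedRates(0.25, 0.9, 0.2, 0.85)
        expected = solve_model(obs, NO_ERRORS, case_model="expected")
        poisson = solve_model(obs, NO_ERRORS, case_model="poisson")
        c = expected.contributory["mosaic"]
        assert poisson.percent_of_cases["mosaic"] == pytest.approx(
            100 * (1 - np.exp(-c))
        )
        assert poisson.percent_of_cases["mosaic"] == pytest.approx(
            expected.percent_of_cases["mosaic"], rel=0.05
        )


class TestCredibleInterval:
    OBS = ObservedRates(0.15, 0.95, 0.1, 0.88)
    ERRORS = ClassificationErrors((4, 30), (31, 468), (6, 39), (10, 337))

    def test_deterministic_under_seed(self):
        ci1 = credible_interval(self.OBS, self.ERRORS, n_perm=2000, seed=42)
        ci2 = credible_interval(self.OBS, self.ERRORS, n_perm=2000, seed=42)
        assert ci1 == ci2

    def test_interval_brackets_point_estimate(self):
        est = solve_model(self.OBS, self.ERRORS)
        ci = credible_interval(self.OBS, self.ERRORS, n_perm=5000, seed=1)
        for klass in ("mosaic", "germline"):
            lo, hi = ci[("contributory", klass)]
            assert lo < est.contributory[klass] < hi

    def test_degenerate_posterior_collapses_to_point(self):
        errors = ClassificationErrors((0, 100_000), (0, 100_000), (0, 100_000), (0, 100_000))
        est = solve_model(self.OBS, errors)
        ci = credible_interval(self.OBS, errors, n_perm=2000, seed=3)
        lo, hi = ci[("contributory", "mosaic")]
        assert hi - lo < 0.01
        assert abs((lo + hi) / 2 - est.contributory["mosaic"]) < 0.01

    def test_intervals_widen_as_validation_counts_shrink(self):
        widths = []
        for scale in (40, 4, 1):
            errors = ClassificationErrors(
                (1 * scale, 10 * scale),
                (5 * scale, 100 * scale),
                (1 * scale, 10 * scale),
                (5 * scale, 100 * scale),
            )
            lo, hi = credible_interval(self.OBS, errors, n_perm=5000, seed=5)[
                ("contributory", "mosaic")
            ]
            widths.append(hi - lo)
        assert widths[0] < widths[1] < widths[2]

    def test_zero_informative_counts_warn_and_pin_rate(self):
        errors = ClassificationErrors((0, 0), (31, 468), (0, 0), (10, 337))
        with pytest.warns(UserWarning, match="no informative"):
            est = solve_model(self.OBS, errors)
        assert np.isfinite(est.contributory["mosaic"])


class TestFrequentistCalibration:
    def test_interval_covers_true_value_across_validation_replicates(self, rng):
        """>= 90% coverage of the true contributory rate over 200 replicates.

        The interval propagates classification-error uncertainty only (the
        observed rates are not resampled), so calibration is checked against
        replicated validation experiments at fixed true rates and error rates.
        """
        b = {"mosaic": 0.104, "germline": 0.877}
        c = {"mosaic": 0.051, "germline": 0.056}
        eps_true = {
            ("proband", "mosaic"): 0.10,
            ("proband", "germline"): 0.05,
            ("sibling", "mosaic"): 0.12,
            ("sibling", "germline"): 0.04,
        }
        n_inf = {
            ("proband", "mosaic"): 40,
            ("proband", "germline"): 400,
            ("sibling", "mosaic"): 35,
            ("sibling", "germline"): 380,
        }
        errors_true = ClassificationErrors(
            *[
                (round(eps_true[k] * n_inf[k]), n_inf[k])
                for k in (
                    ("proband", "mosaic"),
                    ("proband", "germline"),
                    ("sibling", "mosaic"),
                    ("sibling", "germline"),
                )
            ]
        )
        obs = forward_observed_rates(b, c, errors_true)
        covered = 0
        n_rep = 200
        for rep in range(n_rep):
            counts = {}
            for k in n_inf:
                mis = int(rng.binomial(n_inf[k], errors_true.rate(*k)))
                counts[k] = (mis, n_inf[k])
            errors_hat = ClassificationErrors(
                counts[("proband", "mosaic")], counts[("proband", "germline")],
                counts[("sibling", "mosaic")], counts[("sibling", "germline")],
            )
            ci = credible_interval(obs, errors_hat, n_perm=1000, seed=rep)
            lo, hi = ci[("contributory", "mosaic")]
            if lo <= c["mosaic"] <= hi:
                covered += 1
        assert covered / n_rep >= 0.90
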