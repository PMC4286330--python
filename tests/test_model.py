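"""Maximum-likelihood fit: LL correctness, argmax, confidence regions, coverage."""

import math

import numpy as np
import pytest

from pettcp.errors import ConfigError
from pettcp.model import (
    GridSpec,
    TumorRecurrenceModel,
    delta_loglik,
    log_likelihood,
    patient_trp,
)
from pettcp.tcp import SigmoidParams, trp


def scalar_loglike(suvr50, gamma50, cohort):
    """Independent pure-python evaluation of the Bernoulli log-likelihood."""
    total = 0.0
    for x, r in cohort:
        p = 0.5 * (1.0 + math.erf(math.sqrt(math.pi) * gamma50 * (x - suvr50)))
        p = min(max(p, 1e-12), 1 - 1e-12)
        total += math.log(p) if r == 1 else math.log(1 - p)
    return total


class TestLogLikelihood:
    def test_clamp_keeps_extreme_probabilities_finite(self):
        params = SigmoidParams(0.5, 500.0)
        p = patient_trp(params, 2.0)
        assert p == pytest.approx(1 - 1e-12)
        ll = log_likelihood(params, [2.0], [0])  # responder far above suvr50
        assert np.isfinite(ll)

    def test_matches_unclamped_sigmoid_at_moderate_arguments(self):
        params = SigmoidParams(0.5, 2.0)
        assert patient_trp(params, 0.62) == pytest.approx(trp(0.62, params), rel=1e-14)

    def test_single_nonresponder_at_suvr50(self):
        assert log_likelihood(SigmoidParams(0.5, 2.0), [0.5], [1]) == pytest.approx(
            math.log(0.5), rel=1e-12
        )

    def test_flat_curve_ll_is_n_log_half(self, toy_model):
        assert toy_model.loglike((0.7, 0.0)) == pytest.approx(4 * math.log(0.5), rel=1e-14)

    def test_vectorized_ll_matches_scalar_oracle(self, toy_cohort):
        cohort = list(zip(toy_cohort["mean_ratio"], toy_cohort["R"]))
        model = TumorRecurrenceModel.from_cohort_table(toy_cohort)
        for s50, g50 in [(0.5, 2.0), (0.3, 0.7), (1.0, 5.5), (0.1, 0.0)]:
            # the two routes use different but equivalent float evaluations
            # (erfc vs 1+erf), so agreement is near machine precision, not exact
            assert model.loglike((s50, g50)) == pytest.approx(
                scalar_loglike(s50, g50, cohort), rel=1e-9
            )

    def test_surface_matches_scalar_oracle_nodewise(self, toy_model, toy_cohort):
        cohort = list(zip(toy_cohort["mean_ratio"], toy_cohort["R"]))
        grid = GridSpec(0.1, 1.0, 7, 0.0, 5.0, 5)
        surface = toy_model.evaluate_surface(grid)
        for i, s in enumerate(surface.suvr50):
            for j, g in enumerate(surface.gamma50):
                assert surface.ll[i, j] == pytest.approx(scalar_loglike(s, g, cohort), rel=1e-9)

    def test_empty_cohort_is_an_error(self):
        with pytest.raises(ValueError):
            TumorRecurrenceModel([], [])

    def test_ll_never_positive(self, toy_model):
        surface = toy_model.evaluate_surface(GridSpec(0.1, 1.0, 25, 0.0, 6.0, 25))
        assert np.all(surface.ll <= 0)


class TestFit:
    def test_grid_argmax_agrees_with_tenfold_refined_brute_force(self, toy_model):
        coarse = GridSpec(0.05, 1.2, 47, 0.0, 6.0, 49)
        fine = coarse.refine(10)
        res = toy_model.fit(coarse)
        fine_surface = toy_model.evaluate_surface(fine)
        i, j = fine_surface.argmax()
        ds = (coarse.suvr50_max - coarse.suvr50_min) / (coarse.n_suvr50 - 1)
        dg = (coarse.gamma50_max - coarse.gamma50_min) / (coarse.n_gamma50 - 1)
        assert abs(res.params.suvr50 - fine_surface.suvr50[i]) <= ds
        assert abs(res.params.gamma50 - fine_surface.gamma50[j]) <= dg

    def test_surface_invariant_to_patient_ordering(self, toy_cohort):
        shuffled = toy_cohort.sample(frac=1.0, random_state=1)
        a = TumorRecurrenceModel.from_cohort_table(toy_cohort).evaluate_surface(
            GridSpec(0.1, 1.0, 13, 0.0, 6.0, 13)
        )
        b = TumorRecurrenceModel.from_cohort_table(shuffled).evaluate_surface(
            GridSpec(0.1, 1.0, 13, 0.0, 6.0, 13)
        )
        # permutation only changes float summation order
        assert np.allclose(a.ll, b.ll, rtol=1e-12, atol=1e-12)

    def test_argmax_stable_under_grid_densification(self):
        rng = np.random.default_rng(8)
        x = rng.uniform(0.1, 1.0, 30)
        r = (rng.random(30) < trp(x, SigmoidParams(0.5, 2.0))).astype(int)
        model = TumorRecurrenceModel(x, r)
        coarse = GridSpec(0.05, 1.2, 61, 0.0, 6.0, 61)
        res1 = model.fit(coarse)
        res2 = model.fit(coarse.refine(2))
        ds = (1.2 - 0.05) / 60
        dg = 6.0 / 60
        assert abs(res1.params.suvr50 - res2.params.suvr50) < ds
        assert abs(res1.params.gamma50 - res2.params.gamma50) < dg

    def test_all_responder_cohort_has_boundary_maximum(self):
        model = TumorRecurrenceModel([0.3, 0.4, 0.5], [0, 0, 0])
        surface = model.evaluate_surface(GridSpec(0.05, 1.2, 30, 0.0, 6.0, 30))
        # pushing the curve's midpoint past the data only helps: LL nondecreasing
        # in suvr50 at fixed positive gamma
        assert np.all(np.diff(surface.ll[:, 10]) >= -1e-12)
        res = model.fit(GridSpec(0.05, 1.2, 30, 0.0, 6.0, 30))
        assert not res.identifiable

    def test_perfect_separation_flags_nonidentifiable(self, toy_model):
        res = toy_model.fit()
        assert not res.identifiable  # slope runs to the gamma50 boundary
        assert res.params.gamma50 == pytest.approx(6.0)

    def test_refinement_polishes_without_leaving_the_cell(self):
        rng = np.random.default_rng(12)
        x = rng.uniform(0.1, 1.0, 40)
        r = (rng.random(40) < trp(x, SigmoidParams(0.5, 2.0))).astype(int)
        model = TumorRecurrenceModel(x, r)
        plain = model.fit()
        polished = model.fit(refine=True)
        assert polished.max_ll >= plain.max_ll
        assert abs(polished.params.suvr50 - plain.params.suvr50) <= (1.2 - 0.05) / 240
        assert abs(polished.params.gamma50 - plain.params.gamma50) <= 6.0 / 240

    def test_parameter_recovery_bias_shrinks_with_n(self):
        """Mean estimates approach the simulating truth as the cohort grows."""
        truth = SigmoidParams(0.5, 2.0)
        rng = np.random.default_rng(99)
        bias = {}
        for n in (100, 500):
            est = []
            for _ in range(15):
                x = rng.uniform(0.05, 1.0, n)
                r = (rng.random(n) < trp(x, truth)).astype(int)
                est.append(TumorRecurrenceModel(x, r).fit().params.suvr50)
            est = np.asarray(est)
            se = est.std(ddof=1) / np.sqrt(len(est))
            assert abs(est.mean() - truth.suvr50) <= 3 * se + 0.01
            bias[n] = abs(est.mean() - truth.suvr50)
        assert bias[500] <= bias[100] + 0.01

    def test_unknown_surrogate_column_rejected(self, toy_cohort):
        with pytest.raises(ConfigError):
            TumorRecurrenceModel.from_cohort_table(toy_cohort, surrogate="nope")

    def test_summary_reports_estimates_and_cis(self, toy_model):
        res = toy_model.fit()
        text = res.summary()
        assert "suvr50" in text and "gamma50" in text and "90% CI" in text


class TestConfidenceRegion:
    def test_delta_at_90_percent_is_chi2_quantile(self):
        # -log(0.1) for a chi-square with 2 dof; independent closed form
        assert delta_loglik(0.90) == pytest.approx(2.3026, abs=5e-5)

    def test_region_contains_the_mle_and_projects_to_cis(self):
        rng = np.random.default_rng(4)
        x = rng.uniform(0.1, 1.0, 50)
        r = (rng.random(50) < trp(x, SigmoidParams(0.5, 2.0))).astype(int)
        res = TumorRecurrenceModel(x, r).fit()
        assert res.ci_suvr50[0] <= res.params.suvr50 <= res.ci_suvr50[1]
        assert res.ci_gamma50[0] <= res.params.gamma50 <= res.ci_gamma50[1]
        assert res.ci_gamma50[0] >= 0.0

    def test_95_region_strictly_contains_90_region(self):
        rng = np.random.default_rng(5)
        x = rng.uniform(0.1, 1.0, 40)
        r = (rng.random(40) < trp(x, SigmoidParams(0.5, 2.0))).astype(int)
        res = TumorRecurrenceModel(x, r).fit()
        r90, _, _ = res.confidence_region(0.90)
        r95, _, _ = res.confidence_region(0.95)
        assert np.all(r95 | ~r90)  # every 90% node is in the 95% region
        assert r95.sum() > r90.sum()

    def test_single_patient_cohort_is_uninformative(self):
        res = TumorRecurrenceModel([0.5], [1]).fit()
        region, ci_s, ci_g = res.confidence_region(0.90)
        # the region covers the bulk of the domain and both marginal CIs
        # project onto the full search range
        assert region.mean() > 0.5
        assert ci_s == [0.05, 1.2]
        assert ci_g == [0.0, 6.0]
        assert res.region_touches_boundary
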