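"""Estimation from trial tables, discretization, and OLS model scoring."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from avcausal.core import (
    VARIANCE_FLOOR,
    CausalPosterior,
    GaussianEstimate,
    MixtureEstimate,
    StimulusPair,
    UnimodalProfile,
)
from avcausal.fit import (
    NoDataError,
    bin_of,
    compare_models,
    compute_unimodal_profiles,
    discretize,
    estimate_p_common,
    fit_model,
    model_estimate,
    observed_counts,
    predict_counts,
    summarize_errors,
    validate_response_table,
)

from conftest import make_response_rows


def unimodal_rows(modality, distance, responses, subject="s1"):
    if modality == "auditory":
        return [(subject, "A", np.nan, distance, np.nan, r, i + 1) for i, r in enumerate(responses)]
    return [(subject, "V", distance, np.nan, r, np.nan, i + 1) for i, r in enumerate(responses)]


class TestBinning:
    def test_half_open_unit_bins_with_absorbing_tails(self):
        resp = np.array([0.0, 0.2, 1.49, 1.5, 4.2, 3.9, 9.49, 9.5, 10.0])
        assert list(bin_of(resp)) == [1, 1, 1, 2, 4, 4, 9, 10, 10]


class TestUnimodalProfiles:
    def test_mean_variance_and_zero_variance_floor(self):
        rows = []
        for d in range(1, 11):
            rows += unimodal_rows("auditory", float(d), [3.0, 3.0, 3.0, 3.0])
        for d in (1, 3, 5, 7, 9):
            rows += unimodal_rows("visual", float(d), [2.0, 4.0])
        profiles = compute_unimodal_profiles(make_response_rows(rows))
        pa = profiles[("auditory", 3.0)]
        assert pa.mean == 3.0 and pa.variance == VARIANCE_FLOOR
        pv = profiles[("visual", 3.0)]
        assert pv.mean == 3.0 and pv.variance == 2.0

    def test_missing_level_is_named(self):
        rows = unimodal_rows("auditory", 1.0, [2.0, 3.0])
        with pytest.raises(NoDataError, match="auditory trials at 2.0 m"):
            compute_unimodal_profiles(make_response_rows(rows))

    def test_recovers_known_moments_at_large_n(self):
        rng = np.random.default_rng(5)
        mu, sigma = 5.0, 1.2
        n = 600
        rows = []
        for d in range(1, 11):
            draws = rng.normal(mu, sigma, n) if d == 5 else rng.normal(d, 0.5, 4)
            rows += unimodal_rows("auditory", float(d), np.clip(draws, 0, 10))
        for d in (1, 3, 5, 7, 9):
            rows += unimodal_rows("visual", float(d), [float(d)] * 2 + [float(d) + 0.1] * 2)
        prof = compute_unimodal_profiles(make_response_rows(rows))[("auditory", 5.0)]
        assert prof.mean == pytest.approx(mu, abs=3 * sigma / np.sqrt(n))
        assert prof.variance == pytest.approx(sigma**2, rel=0.2)


class TestPCommon:
    def pair_rows(self, responses):
        return make_response_rows(
            [("s1", "AV", 3.0, 5.0, rv, ra, i + 1) for i, (rv, ra) in enumerate(responses)]
        )

    def test_proportion_of_matching_answers(self):
        resp = [(4, 4), (3, 3), (5, 5), (3, 6), (2, 7), (4, 8)]
        post = estimate_p_common(self.pair_rows(resp), StimulusPair(3.0, 5.0))
        assert post.p_common == pytest.approx(0.5)
        assert post.n_trials_used == 6

    def test_all_matching(self):
        post = estimate_p_common(self.pair_rows([(4, 4)] * 6), StimulusPair(3.0, 5.0))
        assert post.p_common == 1.0

    def test_same_bin_counts_as_matching_but_exact_does_not(self):
        data = self.pair_rows([(4.2, 3.9)])
        pair = StimulusPair(3.0, 5.0)
        assert estimate_p_common(data, pair, "bin").p_common == 1.0
        assert estimate_p_common(data, pair, "exact").p_common == 0.0

    def test_no_trials_raises(self):
        with pytest.raises(NoDataError):
            estimate_p_common(self.pair_rows([(4, 4)]), StimulusPair(9.0, 9.0))


class TestDiscretize:
    @pytest.mark.parametrize(
        "est",
        [
            GaussianEstimate(5.0, 1.0),
            GaussianEstimate(-2.0, 9.0),   # mass far outside the grid
            MixtureEstimate(((0.3, GaussianEstimate(3.4, 0.8)), (0.7, GaussianEstimate(5.0, 4.0)))),
        ],
    )
    def test_probabilities_sum_to_one(self, est):
        assert discretize(est).sum() == pytest.approx(1.0, abs=1e-9)

    def test_point_mass_lands_in_its_bin(self):
        probs = discretize(GaussianEstimate(5.0, 1e-6))
        assert probs[4] >= 0.999

    def test_matches_normal_cdf_differences(self):
        probs = discretize(GaussianEstimate(5.0, 1.0))
        interior = stats.norm.cdf(np.arange(1.5, 10.5), 5.0, 1.0)
        expected = np.diff(np.concatenate(([0.0], interior, [1.0])))
        np.testing.assert_allclose(probs, expected, atol=1e-12)


class TestPredictCounts:
    def _inputs(self):
        profiles = {
            ("auditory", 5.0): UnimodalProfile("auditory", 5.0, 5.0, 1.0),
            ("auditory", 7.0): UnimodalProfile("auditory", 7.0, 7.0, 1.0),
            ("visual", 3.0): UnimodalProfile("visual", 3.0, 3.0, 1.0),
        }
        posteriors = {
            StimulusPair(3.0, 5.0): CausalPosterior(0.3),
            StimulusPair(3.0, 7.0): CausalPosterior(0.3),
        }
        design = {StimulusPair(3.0, 5.0): 6, StimulusPair(3.0, 7.0): 6}
        return profiles, posteriors, design

    def test_no_interaction_auditory_prediction_ignores_visual(self):
        profiles, posteriors, _ = self._inputs()
        e1 = model_estimate("NoInteraction", StimulusPair(3.0, 5.0), profiles, posteriors, "auditory")
        # same auditory stimulus, different visual stimulus -> same prediction
        profiles2 = dict(profiles) | {("visual", 9.0): UnimodalProfile("visual", 9.0, 9.0, 4.0)}
        e2 = model_estimate("NoInteraction", StimulusPair(9.0, 5.0), profiles2, posteriors, "auditory")
        assert e1 == e2

    def test_mandatory_integration_shares_one_estimate_across_reports(self):
        profiles, posteriors, _ = self._inputs()
        pair = StimulusPair(3.0, 5.0)
        ea = model_estimate("MandatoryIntegration", pair, profiles, posteriors, "auditory")
        ev = model_estimate("MandatoryIntegration", pair, profiles, posteriors, "visual")
        assert ea == ev
        assert ea.mean == pytest.approx(4.0)  # equal variances: midpoint of 3 and 5

    def test_mass_conservation_and_mixture_linearity(self):
        profiles, posteriors, design = self._inputs()
        pm = predict_counts("CausalInferencePM", profiles, posteriors, design)
        totals = pm.groupby(["vis_dist", "aud_dist", "modality"])["count"].sum()
        np.testing.assert_allclose(totals, 6.0, atol=1e-9)
        # PM counts = p * fused-count + (1-p) * segregated-count, cell by cell
        mand = predict_counts("MandatoryIntegration", profiles, posteriors, design)
        noint = predict_counts("NoInteraction", profiles, posteriors, design)
        np.testing.assert_allclose(
            pm["count"], 0.3 * mand["count"] + 0.7 * noint["count"], atol=1e-12
        )

    def test_missing_profile_is_reported(self):
        profiles, posteriors, design = self._inputs()
        del profiles[("visual", 3.0)]
        with pytest.raises(NoDataError, match="missing unimodal profile"):
            predict_counts("MandatoryIntegration", profiles, posteriors, design)


def _count_frame(values, modality="auditory"):
    rows = [
        ("s1", 3.0, 5.0, modality, b + 1, v) for b, v in enumerate(values)
    ]
    return pd.DataFrame(
        rows, columns=["subject", "vis_dist", "aud_dist", "modality", "bin", "count"]
    )


class TestFitModel:
    def test_perfect_prediction_scores_one(self):
        vals = [0, 1, 4, 8, 4, 1, 0, 0, 0, 0]
        fit = fit_model(_count_frame(vals).drop(columns="subject"), _count_frame(vals))
        assert fit.r_squared == pytest.approx(1.0)
        assert fit.n_points == 10

    def test_constant_predictor_scores_zero_with_flag(self):
        pred = _count_frame([2.0] * 10).drop(columns="subject")
        obs = _count_frame([0, 1, 4, 8, 4, 1, 0, 0, 0, 0])
        with pytest.warns(UserWarning, match="constant predictor"):
            fit = fit_model(pred, obs)
        assert fit.r_squared == 0.0 and fit.degenerate

    def test_hand_computed_normal_equations(self):
        # x = 1..6, y = (2,2,4,4,6,6): r^2 = Sxy^2/(Sxx*Syy) = 16^2/(17.5*16)
        pred = _count_frame([1, 2, 3, 4, 5, 6, 0, 0, 0, 0]).drop(columns="subject").iloc[:6]
        obs = _count_frame([2, 2, 4, 4, 6, 6, 0, 0, 0, 0]).iloc[:6]
        fit = fit_model(pred, obs)
        assert fit.r_squared == pytest.approx(16**2 / (17.5 * 16))

    def test_invariant_to_consistent_bin_permutation(self):
        rng = np.random.default_rng(0)
        pred_vals = rng.uniform(size=10)
        obs_vals = rng.integers(0, 6, size=10)
        perm = rng.permutation(10)
        base = fit_model(_count_frame(pred_vals).drop(columns="subject"), _count_frame(obs_vals))
        # permute bins consistently in both tables: same pairing, same r^2
        ppred = _count_frame(pred_vals[perm]).drop(columns="subject")
        ppred["bin"] = np.arange(1, 11)
        pobs = _count_frame(obs_vals[perm])
        pobs["bin"] = np.arange(1, 11)
        permd = fit_model(ppred, pobs)
        assert permd.r_squared == pytest.approx(base.r_squared)


class TestCompareModels:
    def test_reproducible_from_same_table(self, study_data):
        t1 = compare_models(study_data)
        t2 = compare_models(study_data)
        pd.testing.assert_frame_equal(t1, t2)

    def test_segregating_observer_collapses_ci_onto_no_interaction(self):
        from avcausal.simulate import ObserverConfig, simulate

        data = simulate(ObserverConfig(seed=2, strategy="none"))
        table = compare_models(data, match_rule="exact")
        # estimated p_common is 0 almost everywhere; the rare exception is
        # a pair of responses clipped to the same slider edge, which counts
        # as a matching answer, so the tie is near- rather than bit-exact
        for ci in ("CausalInferencePM", "CausalInferenceMA", "CausalInferenceMS"):
            assert table.loc[ci, "All"] == pytest.approx(table.loc["NoInteraction", "All"], abs=0.01)

    def test_observed_counts_layout(self, study_data):
        obs = observed_counts(study_data)
        per_modality = obs.groupby("modality").size()
        # 10 bins x 50 pairs x 6 subjects
        assert (per_modality == 3000).all()
        assert obs["count"].sum() == 2 * 1800  # every trial binned once per modality


class TestSummarizeErrors:
    def test_perfect_and_shifted_responses(self):
        rows = unimodal_rows("auditory", 4.0, [4.0, 4.0]) + unimodal_rows("visual", 3.0, [4.0, 4.0])
        table = summarize_errors(make_response_rows(rows))
        aud = table[table["condition"] == "A"].iloc[0]
        vis = table[table["condition"] == "V"].iloc[0]
        assert aud["mean_abs_error"] == 0.0 and aud["sd"] == 0.0
        assert vis["mean_abs_error"] == 1.0 and vis["sd"] == 0.0

    def test_matches_folded_normal_expectation(self):
        rng = np.random.default_rng(8)
        sigma, n = 1.0, 20000
        rows = unimodal_rows("auditory", 5.0, np.clip(rng.normal(5.0, sigma, n), 0, 10))
        got = summarize_errors(make_response_rows(rows)).iloc[0]
        expected = sigma * np.sqrt(2 / np.pi)  # folded-normal mean, zero-centered
        assert got["mean_abs_error"] == pytest.approx(expected, rel=0.03)


class TestValidation:
    def test_condition_field_consistency(self):
        bad = make_response_rows([("s1", "A", np.nan, 3.0, np.nan, np.nan, 1)])
        with pytest.raises(ValueError, match="A rows need"):
            validate_response_table(bad)

    def test_out_of_range_response(self):
        bad = make_response_rows([("s1", "A", np.nan, 3.0, np.nan, 11.0, 1)])
        with pytest.raises(ValueError, match="outside"):
            validate_response_table(bad)
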