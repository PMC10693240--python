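import math

import numpy as np
import pandas as pd
import pytest

import statsmodels.api as sm

from antiphon.events import PhaseInterval, PhaseLabel, Session, Day
from antiphon.inference import (
    DegenerateFitError,
    FitSpec,
    fit_amplitude_trend,
    fit_categorical_glm,
    fit_latency_model,
    fit_match_model,
    randomization_test,
)

from conftest import make_call


def two_group_df(a, b, outcome="y", predictor="g"):
    return pd.DataFrame(
        {outcome: list(a) + list(b), predictor: ["A"] * len(a) + ["B"] * len(b)}
    )


class TestCountModels:
    def test_two_group_coefficient_is_log_mean_ratio(self):
        df = two_group_df([4, 4, 4, 4], [8, 8, 8, 8])
        res = fit_categorical_glm(df, "y", "g", "NEG_BINOMIAL")
        assert res.terms["B"].beta == pytest.approx(math.log(2.0), abs=1e-6)

    def test_log_mean_ratio_holds_with_dispersion(self):
        # overdispersed groups: coefficient still equals the log mean ratio
        a = [1, 3, 9, 2, 15, 4, 7, 1, 20, 3]
        b = [5, 30, 11, 2, 44, 18, 9, 25, 6, 50]
        df = two_group_df(a, b)
        res = fit_categorical_glm(df, "y", "g", "NEG_BINOMIAL")
        expected = math.log(np.mean(b) / np.mean(a))
        assert res.terms["B"].beta == pytest.approx(expected, abs=1e-6)
        assert res.dispersion is None or res.dispersion > 0

    def test_identical_groups_give_zero(self):
        df = two_group_df([5, 5, 5], [5, 5, 5])
        res = fit_categorical_glm(df, "y", "g", "NEG_BINOMIAL")
        assert res.terms["B"].beta == pytest.approx(0.0, abs=1e-8)

    def test_all_zero_outcome_degenerate(self):
        df = two_group_df([0, 0, 0], [0, 0, 0])
        with pytest.raises(DegenerateFitError):
            fit_categorical_glm(df, "y", "g", "NEG_BINOMIAL")

    def test_sparse_level_flagged_inestimable(self):
        df = pd.DataFrame({"y": [1, 2, 3, 4, 9], "g": ["A", "A", "B", "B", "C"]})
        res = fit_categorical_glm(df, "y", "g", "NEG_BINOMIAL")
        assert res.flags["inestimable"] == ["C"]
        assert set(res.terms) == {"B"}

    def test_too_few_levels_rejected(self):
        df = pd.DataFrame({"y": [1, 2, 3], "g": ["A", "A", "B"]})
        with pytest.raises(ValueError, match="levels"):
            fit_categorical_glm(df, "y", "g", "NEG_BINOMIAL")


class TestLogisticModel:
    def test_two_by_two_odds_ratio_oracle(self):
        counts = pd.DataFrame(
            {
                "phase": ["ENGAGEMENT", "AGITATION"],
                "n_matched": [8, 2],
                "n_unmatched": [2, 8],
            }
        )
        res = fit_match_model(counts, reference="AGITATION")
        assert res.terms["ENGAGEMENT"].beta == pytest.approx(math.log(16.0), abs=1e-6)
        assert res.odds_ratios()["ENGAGEMENT"] == pytest.approx(16.0, abs=1e-4)

    def test_equal_proportions_give_zero(self):
        counts = pd.DataFrame(
            {"phase": ["A", "B"], "n_matched": [5, 5], "n_unmatched": [5, 5]}
        )
        res = fit_match_model(counts)
        assert res.terms["B"].beta == pytest.approx(0.0, abs=1e-8)

    def test_separation_uses_corrected_table(self):
        counts = pd.DataFrame(
            {"phase": ["A", "B"], "n_matched": [10, 2], "n_unmatched": [0, 8]}
        )
        res = fit_match_model(counts, reference="B")
        assert "separation" in res.flags
        beta = res.terms["A"].beta
        # Haldane-Anscombe corrected 2x2: (10.5*8.5)/(0.5*2.5)
        assert beta == pytest.approx(math.log((10.5 * 8.5) / (0.5 * 2.5)), abs=1e-9)
        assert math.isfinite(res.terms["A"].se)

    def test_insufficient_phase_excluded(self):
        counts = pd.DataFrame(
            {
                "phase": ["A", "B", "C"],
                "n_matched": [5, 3, 1],
                "n_unmatched": [5, 7, 0],
                "sufficient": [True, True, False],
            }
        )
        res = fit_match_model(counts)
        assert "C" not in res.terms and res.reference_level != "C"


class TestAmplitudeTrend:
    def test_exact_linear_decline(self):
        calls = [
            make_call(f"t{i}", "SUBJECT", 60.0 * i, 60.0 * i + 1, amplitude=-20.0 - i)
            for i in range(6)
        ]
        res = fit_amplitude_trend(calls, "TIME_MIN")
        assert res.terms["time_min"].beta == pytest.approx(-1.0, abs=1e-10)

    def test_constant_amplitude_zero_slope(self):
        calls = [
            make_call(f"t{i}", "SUBJECT", 10.0 * i, 10.0 * i + 1, amplitude=-25.0)
            for i in range(5)
        ]
        res = fit_amplitude_trend(calls, "TIME_MIN")
        assert res.terms["time_min"].beta == pytest.approx(0.0, abs=1e-10)

    def test_phase_predictor_is_ordinal(self):
        phases = [
            PhaseInterval(label=PhaseLabel.ENGAGEMENT, start_s=0, end_s=100),
            PhaseInterval(label=PhaseLabel.AGITATION, start_s=100, end_s=200),
            PhaseInterval(label=PhaseLabel.DISENGAGEMENT, start_s=200, end_s=300),
        ]
        calls = []
        for i, (t, amp) in enumerate(
            [(10, -20), (50, -20), (110, -26), (150, -26), (210, -32), (250, -32)]
        ):
            calls.append(make_call(f"t{i}", "SUBJECT", t, t + 1, amplitude=amp))
        session = Session(calls=calls, behaviors=[], phases=phases, day=Day.PLAYBACK)
        res = fit_amplitude_trend(session, "PHASE")
        assert res.terms["phase_index"].beta == pytest.approx(-6.0, abs=1e-10)

    def test_no_amplitudes_rejected(self):
        calls = [make_call(f"t{i}", "SUBJECT", i, i + 0.5) for i in range(5)]
        with pytest.raises(ValueError):
            fit_amplitude_trend(calls, "TIME_MIN")


class TestRandomization:
    def test_constant_outcome_gives_p_one(self):
        df = pd.DataFrame({"y": [5] * 12, "g": ["A"] * 6 + ["B"] * 6})
        res = randomization_test(df, FitSpec("y", "g", "NEG_BINOMIAL"), 200, seed=3)
        assert res.beta_observed == pytest.approx(0.0, abs=1e-8)
        assert np.allclose(res.null_betas, 0.0)
        assert res.p_empirical == 1.0

    def test_same_seed_bit_identical(self):
        rng = np.random.default_rng(11)
        df = pd.DataFrame(
            {"y": rng.poisson(6, 40), "g": ["A"] * 20 + ["B"] * 20}
        )
        spec = FitSpec("y", "g", "NEG_BINOMIAL")
        r1 = randomization_test(df, spec, 300, seed=42)
        r2 = randomization_test(df, spec, 300, seed=42)
        assert np.array_equal(r1.null_betas, r2.null_betas)
        assert r1.p_empirical == r2.p_empirical

    def test_p_matches_estimator_identity_and_range(self):
        rng = np.random.default_rng(5)
        df = pd.DataFrame(
            {"y": np.r_[rng.poisson(4, 15), rng.poisson(9, 15)],
             "g": ["A"] * 15 + ["B"] * 15}
        )
        res = randomization_test(df, FitSpec("y", "g", "NEG_BINOMIAL"), 500, seed=9)
        n = res.n_permutations
        b = int(np.sum(np.abs(res.null_betas) >= abs(res.beta_observed)))
        assert res.p_empirical == pytest.approx((1 + b) / (n + 1))
        assert 1 / (n + 1) <= res.p_empirical <= 1.0

    def test_closed_form_matches_full_refit(self):
        """Dual route: permuted coefficients equal a statsmodels refit."""
        rng = np.random.default_rng(17)
        y = np.r_[rng.poisson(4, 12), rng.poisson(8, 12)].astype(float)
        labels = np.array(["A"] * 12 + ["B"] * 12)
        from antiphon.inference import _closed_form_beta

        for _ in range(5):
            perm = rng.permutation(labels)
            X = np.column_stack([np.ones(len(y)), (perm == "B").astype(float)])
            refit = sm.GLM(y, X, family=sm.families.Poisson()).fit()
            fast = _closed_form_beta(y, perm, "B", "A", "POISSON")
            assert fast == pytest.approx(float(refit.params[1]), abs=1e-8)

    def test_excess_failed_permutations_error(self):
        # group of size 2 frequently becomes all-ones/all-zeros when permuted
        df = pd.DataFrame({"y": [1, 0, 1, 1, 0, 0, 1, 0, 1, 0],
                           "g": ["A", "A"] + ["B"] * 8})
        with pytest.raises(RuntimeError, match="failed"):
            randomization_test(df, FitSpec("y", "g", "LOGISTIC"), 400, seed=1)

    def test_zero_permutations_rejected(self):
        df = pd.DataFrame({"y": [1, 2, 3, 4], "g": ["A", "A", "B", "B"]})
        with pytest.raises(ValueError):
            randomization_test(df, FitSpec("y", "g", "NEG_BINOMIAL"), 0, seed=0)


class TestLatencyModelFrontend:
    def test_counter_call_contrast_reference(self):
        df = pd.DataFrame(
            {
                "latency_s": [4.0, 5.0, 4.5, 12.0, 11.0, 13.0],
                "phase": ["ENGAGEMENT"] * 6,
                "day": ["PLAYBACK"] * 6,
                "is_counter_call": [True, True, True, False, False, False],
            }
        )
        res = fit_latency_model(df, "COUNTER_CALL")
        assert res.reference_level == "NOT_COUNTER"
        assert res.terms["COUNTER"].beta < 0

    def test_gamma_alternative_family(self):
        df = pd.DataFrame(
            {
                "latency_s": [4.0, 5.0, 4.5, 12.0, 11.0, 13.0],
                "phase": ["ENGAGEMENT"] * 3 + ["AGITATION"] * 3,
                "day": ["PLAYBACK"] * 6,
                "is_counter_call": [True] * 6,
            }
        )
        res = fit_latency_model(df, "PHASE_DAY", family="gamma")
        assert res.family == "GAMMA"
        expected = math.log(np.mean([4.0, 5.0, 4.5]) / np.mean([12.0, 11.0, 13.0]))
        assert res.terms["ENGAGEMENT"].beta == pytest.approx(expected, abs=1e-6)

    def test_unphased_rows_excluded_from_phase_model(self):
        df = pd.DataFrame(
            {
                "latency_s": [4, 5, 12, 11, 99, 98],
                "phase": ["ENGAGEMENT", "ENGAGEMENT", "AGITATION", "AGITATION",
                          "UNPHASED", "UNPHASED"],
                "day": ["PLAYBACK"] * 6,
                "is_counter_call": [True] * 6,
            }
        )
        res = fit_latency_model(df, "PHASE_DAY")
        assert res.n_obs == 4
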