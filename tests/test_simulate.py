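import dataclasses
import json

import numpy as np
import pytest
from scipy import stats

import antiphon as ap
from antiphon.events import Day, PhaseLabel, Source
from antiphon.matching import PairKind, extract_response_pairs
from antiphon.simulate import (
    FIXED_MEAN,
    SimConfig,
    scenario_library,
    simulate_control_session,
    simulate_playback_session,
)
from antiphon.turn_taking import classify_counter_calls, latency_dataset

from _oracles import brute_force_counter_flags


class TestConfig:
    def test_yaml_round_trip(self, tmp_path):
        cfg = scenario_library()["paper_like"]
        path = tmp_path / "cfg.yaml"
        cfg.to_yaml(path)
        assert SimConfig.from_yaml(path) == cfg

    @pytest.mark.parametrize(
        "bad",
        [
            {"phase_bounds_s": (0.0, 500.0, 400.0, 1200.0)},
            {"phase_bounds_s": (0.0, 400.0, 900.0, 1500.0)},
            {"response_probability": (0.5, 1.2, 0.5)},
            {"latency_mean_s": (8.0, -1.0, 25.0)},
            {"broadcast_latency_policy": "TELEPATHY"},
            {"blows": ((5000.0, "BLOW_NEUTRAL"),)},
            {"control_latency_mean_s": 0.0},
            {"broadcast_cease_s": 2000.0},
        ],
    )
    def test_invalid_configs_rejected(self, bad):
        with pytest.raises(ValueError):
            dataclasses.replace(SimConfig(), **bad)

    def test_presets_exist(self):
        lib = scenario_library()
        assert {"paper_like", "null", "perfect_oscillator"} <= set(lib)


class TestPlaybackGeneration:
    def test_fixed_seed_bit_identical(self):
        cfg = dataclasses.replace(scenario_library()["paper_like"], seed=99)
        s1, g1 = simulate_playback_session(cfg)
        s2, g2 = simulate_playback_session(cfg)
        assert s1.calls == s2.calls
        assert s1.behaviors == s2.behaviors
        assert json.dumps(g1.to_dict(), sort_keys=True) == json.dumps(
            g2.to_dict(), sort_keys=True
        )

    @pytest.mark.parametrize("preset", ["paper_like", "null", "perfect_oscillator"])
    def test_generated_sessions_validate(self, preset):
        cfg = scenario_library()[preset]
        session, truth = simulate_playback_session(cfg)
        # Session construction validates sorting/overlap; re-check key facts
        onsets = [c.onset_s for c in session.calls]
        assert onsets == sorted(onsets)
        assert session.day is Day.PLAYBACK
        assert len(session.phases) == 3
        assert len(truth.operator_latencies) == len(session.calls_from(Source.EXEMPLAR))

    def test_silent_subject_limit(self):
        cfg = dataclasses.replace(
            SimConfig(), response_probability=(0.0, 0.0, 0.0), n_trailing_calls=0
        )
        session, truth = simulate_playback_session(cfg)
        assert session.calls_from(Source.SUBJECT) == []
        assert truth.responses == []
        assert latency_dataset([session]).empty

    def test_perfect_oscillator_pairs_are_even_splits(self):
        session, _ = simulate_playback_session(scenario_library()["perfect_oscillator"])
        pairs, dropped = extract_response_pairs(session, PairKind.E_T)
        assert dropped == 0 and len(pairs) > 10
        for p in pairs:
            assert p.share_small == pytest.approx(50.0, abs=1e-9)
            assert p.matched

    def test_blow_suppression_recorded_and_classified(self):
        # one blow per phase, long delay: suppressed calls must exist and the
        # classifier must agree with both ground truth and the brute oracle
        cfg = dataclasses.replace(SimConfig(), seed=5)
        session, truth = simulate_playback_session(cfg)
        suppressed = {r["event_id"] for r in truth.responses if r["blow_suppressed"]}
        assert suppressed  # default schedule hits at least one response window
        records, _ = classify_counter_calls(session)
        flags = {r.to_event: r.is_counter_call for r in records}
        oracle = brute_force_counter_flags(session)
        for event_id, flag in flags.items():
            assert flag == oracle[event_id]
        for event_id in suppressed & set(flags):
            assert flags[event_id] is False

    def test_trailing_calls_are_succession(self):
        cfg = dataclasses.replace(SimConfig(), seed=3)
        session, truth = simulate_playback_session(cfg)
        tail_ids = [r["event_id"] for r in truth.spontaneous]
        assert len(tail_ids) == cfg.n_trailing_calls
        records, _ = classify_counter_calls(session)
        flags = {r.to_event: r.is_counter_call for r in records}
        # all but possibly the first trailing call follow another subject call
        assert all(flags[i] is False for i in tail_ids[1:])

    def test_uncoupled_latency_draws_follow_gamma_truth(self):
        cfg = scenario_library()["paper_like"]
        draws = {ph.value: [] for ph in
                 (PhaseLabel.ENGAGEMENT, PhaseLabel.AGITATION, PhaseLabel.DISENGAGEMENT)}
        for seed in range(40):
            _, truth = simulate_playback_session(dataclasses.replace(cfg, seed=seed))
            for r in truth.responses:
                if not r["coupled"]:
                    draws[r["param_phase"]].append(r["base_latency_s"])
        for mu, (phase, xs) in zip(cfg.latency_mean_s, draws.items()):
            xs = np.asarray(xs)
            se = xs.std(ddof=1) / np.sqrt(len(xs))
            assert abs(xs.mean() - mu) < 3 * se, phase

    def test_uncoupled_match_rate_approaches_chance_oracle(self):
        """Monte-Carlo chance-match rate vs numeric integration.

        With a fixed-mean operator and zero coupling, an E-T pair matches
        iff the Gamma response latency falls within [41/59, 59/41] of the
        operator gap; the chance rate follows by integrating the Gamma CDF
        over the operator-gap distribution.
        """
        base = scenario_library()["null"]
        cfg = dataclasses.replace(base, operator_mean_latency_s=10.0)
        matches = []
        for seed in range(60):
            session, _ = simulate_playback_session(dataclasses.replace(cfg, seed=seed))
            pairs, _ = extract_response_pairs(session, PairKind.E_T)
            matches += [p.matched for p in pairs]
        mc = np.mean(matches)
        k = cfg.latency_shape[0]
        scale = cfg.latency_mean_s[0] / k
        g_mu, g_sd = cfg.operator_mean_latency_s, cfg.operator_noise_sd

        from scipy.integrate import quad

        def integrand(g):
            lo, hi = g * 41.0 / 59.0, g * 59.0 / 41.0
            return stats.norm.pdf(g, g_mu, g_sd) * (
                stats.gamma.cdf(hi, k, scale=scale) - stats.gamma.cdf(lo, k, scale=scale)
            )

        oracle, _ = quad(integrand, g_mu - 6 * g_sd, g_mu + 6 * g_sd)
        se = np.sqrt(mc * (1 - mc) / len(matches))
        assert abs(mc - oracle) < 2 * se + 0.01


class TestControlGeneration:
    def test_six_calls_five_latencies(self):
        session = simulate_control_session(SimConfig())
        assert len(session.calls) == 6
        df = latency_dataset([session])
        assert len(df) == 5
        assert set(df["phase"]) == {"CONTROL"}
        assert session.day is Day.CONTROL

    def test_zero_sd_gives_identical_latencies(self):
        cfg = dataclasses.replace(SimConfig(), control_latency_sd_s=0.0)
        df = latency_dataset([simulate_control_session(cfg)])
        assert np.ptp(df["latency_s"]) < 1e-9

    def test_day_contrast_recovers_slower_control_calling(self):
        """Control-day latencies exceed playback latencies -> positive
        CONTROL coefficient against the engagement reference."""
        cfg = scenario_library()["paper_like"]
        hits = 0
        n = 100
        for seed in range(n):
            c = dataclasses.replace(cfg, seed=seed)
            playback, _ = simulate_playback_session(c)
            control = simulate_control_session(c)
            data = latency_dataset([playback, control])
            res = ap.fit_latency_model(data, "PHASE_DAY", reference="ENGAGEMENT")
            if res.terms["CONTROL"].beta > 0:
                hits += 1
        assert hits >= 0.95 * n
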