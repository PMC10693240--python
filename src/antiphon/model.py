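"""Top-level model/results interface for a playback exchange.

:class:`PlaybackExchangeModel` bundles one playback session (plus an
optional control-day session) and fits, in one call, the full turn-taking
analysis: the phase/day latency contrasts, the counter-call contrast with
its randomization check, the latency-ratio match and discrepancy contrasts,
and the amplitude trend.  The returned :class:`PlaybackExchangeResults`
carries the stage datasets, every fitted GLM, and a text ``summary()``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import pandas as pd

from .events import Day, Session
from .inference import (
    FitSpec,
    GLMResult,
    RandomizationResult,
    fit_amplitude_trend,
    fit_latency_model,
    fit_match_model,
    randomization_test,
)
from .matching import (
    PairKind,
    ResponsePair,
    discrepancy_dataset,
    extract_response_pairs,
    match_rate_by_phase,
)
from .turn_taking import latency_dataset

__all__ = ["PlaybackExchangeModel", "PlaybackExchangeResults"]


@dataclass
class PlaybackExchangeResults:
    """Fitted results for one playback exchange.

    Any model that could not be estimated from the available data (for
    example the match contrast when fewer than two phases have at least two
    pairs) is ``None``, with the reason recorded in ``warnings``.
    """

    latency_data: pd.DataFrame
    pairs_et: list[ResponsePair]
    pairs_te: list[ResponsePair]
    match_counts: pd.DataFrame | None
    discrepancies: pd.DataFrame | None
    latency_phase_model: GLMResult | None
    counter_call_model: GLMResult | None
    match_model: GLMResult | None
    discrepancy_model: GLMResult | None
    amplitude_model: GLMResult | None
    randomization: RandomizationResult | None
    seed: int | None
    warnings: list[str] = field(default_factory=list)

    def summary(self) -> str:
        """Human-readable analysis summary."""
        lines = ["Playback exchange analysis", "=" * 40]
        lines.append(f"latency records: {len(self.latency_data)}")
        n_cc = int(self.latency_data["is_counter_call"].fillna(False).sum())
        lines.append(f"counter calls:   {n_cc}")
        lines.append(f"E-T pairs: {len(self.pairs_et)}   T-E pairs: {len(self.pairs_te)}")
        if self.match_counts is not None:
            lines.append("\nMatch counts by phase (E-T):")
            lines.append(self.match_counts.to_string(index=False))

        def fmt(name: str, res: GLMResult | None) -> None:
            if res is None:
                lines.append(f"\n{name}: not estimable")
                return
            lines.append(f"\n{name} [{res.family}/{res.link}, n={res.n_obs}, "
                         f"ref={res.reference_level}]")
            for term, est in sorted(res.terms.items()):
                lines.append(
                    f"  {term:>16s}: beta={est.beta:+.3f}  se={est.se:.3f}  p={est.p_value:.4g}"
                )
            if res.dispersion is not None:
                lines.append(f"  dispersion alpha={res.dispersion:.3f}")

        fmt("Latency ~ phase/day", self.latency_phase_model)
        fmt("Latency ~ counter call", self.counter_call_model)
        fmt("Matched ~ phase", self.match_model)
        fmt("Discrepancy ~ phase", self.discrepancy_model)
        fmt("Amplitude trend", self.amplitude_model)
        if self.randomization is not None:
            r = self.randomization
            lines.append(
                f"\nRandomization ({r.n_permutations} permutations, seed {r.seed}): "
                f"beta_obs={r.beta_observed:+.3f}, p_empirical={r.p_empirical:.4f}"
            )
        if self.warnings:
            lines.append("\nWarnings:")
            lines += [f"  - {w}" for w in self.warnings]
        return "\n".join(lines)


class PlaybackExchangeModel:
    """Turn-taking analysis of one playback session.

    Parameters
    ----------
    session
        The playback-day session (exemplars and subject calls).
    control
        Optional control-day session; enables the day contrast.
    latency_family
        ``'nb'`` (negative binomial on whole-second latencies, the default)
        or ``'gamma'`` (Gamma/log on raw latencies) for the latency models.
    pair_strategy
        Response-pair construction strategy (see
        :func:`antiphon.matching.extract_response_pairs`).
    """

    def __init__(
        self,
        session: Session,
        control: Session | None = None,
        *,
        latency_family: str = "nb",
        pair_strategy: str = "response_time",
    ) -> None:
        if session.day is not Day.PLAYBACK:
            raise ValueError("the primary session must be a PLAYBACK session")
        if control is not None and control.day is not Day.CONTROL:
            raise ValueError("the control session must be a CONTROL session")
        self.session = session
        self.control = control
        self.latency_family = latency_family
        self.pair_strategy = pair_strategy

    def fit(
        self, n_randomizations: int = 1000, seed: int | None = 0
    ) -> PlaybackExchangeResults:
        """Run the full pipeline and fit every estimable contrast."""
        warnings: list[str] = []
        sessions = [self.session] + ([self.control] if self.control else [])
        data = latency_dataset(sessions)

        pairs_et, dropped_et = extract_response_pairs(
            self.session, PairKind.E_T, strategy=self.pair_strategy
        )
        pairs_te, dropped_te = extract_response_pairs(
            self.session, PairKind.T_E, strategy=self.pair_strategy
        )
        if dropped_et or dropped_te:
            warnings.append(
                f"dropped {dropped_et} E-T and {dropped_te} T-E pairs with non-positive latency"
            )

        def try_fit(name: str, fn):
            try:
                return fn()
            except Exception as exc:  # record and continue: single-session data is small
                warnings.append(f"{name}: {exc}")
                return None

        latency_phase_model = try_fit(
            "latency phase/day model",
            lambda: fit_latency_model(data, "PHASE_DAY", family=self.latency_family),
        )
        counter_call_model = try_fit(
            "counter-call model",
            lambda: fit_latency_model(data, "COUNTER_CALL", family=self.latency_family),
        )

        match_counts = None
        discrepancies = None
        match_model = None
        discrepancy_model = None
        if pairs_et:
            match_counts = match_rate_by_phase(pairs_et)
            discrepancies = discrepancy_dataset(pairs_et)
            if int(match_counts["sufficient"].sum()) >= 2:
                match_model = try_fit(
                    "match model", lambda: fit_match_model(match_counts)
                )
                ok_phases = set(match_counts[match_counts["sufficient"]]["phase"])
                disc = discrepancies[discrepancies["phase"].isin(ok_phases)]
                discrepancy_model = try_fit(
                    "discrepancy model",
                    lambda: fit_latency_model(
                        disc.rename(columns={"discrepancy_pp": "latency_s"}),
                        "PHASE_DAY",
                        family="nb",
                    ),
                )
            else:
                warnings.append(
                    "match/discrepancy contrasts skipped: fewer than 2 phases with >=2 pairs"
                )
        else:
            warnings.append("no E-T response pairs extracted")

        amplitude_model = None
        if any(c.amplitude_db is not None for c in self.session.calls):
            amplitude_model = try_fit(
                "amplitude trend", lambda: fit_amplitude_trend(self.session, "TIME_MIN")
            )

        randomization = None
        if n_randomizations > 0 and counter_call_model is not None:
            df = data.dropna(subset=["is_counter_call"]).copy()
            df["cc"] = df["is_counter_call"].map({True: "COUNTER", False: "NOT_COUNTER"})
            df["latency_int"] = df["latency_s"].round().astype(int)
            randomization = try_fit(
                "randomization test",
                lambda: randomization_test(
                    df,
                    FitSpec(
                        outcome="latency_int",
                        predictor="cc",
                        family="NEG_BINOMIAL",
                        reference="NOT_COUNTER",
                        term="COUNTER",
                    ),
                    n_permutations=n_randomizations,
                    seed=seed if seed is not None else 0,
                ),
            )

        return PlaybackExchangeResults(
            latency_data=data,
            pairs_et=pairs_et,
            pairs_te=pairs_te,
            match_counts=match_counts,
            discrepancies=discrepancies,
            latency_phase_model=latency_phase_model,
            counter_call_model=counter_call_model,
            match_model=match_model,
            discrepancy_model=discrepancy_model,
            amplitude_model=amplitude_model,
            randomization=randomization,
            seed=seed,
            warnings=warnings,
        )
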