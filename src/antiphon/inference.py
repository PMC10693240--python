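"""GLM contrasts and randomization-based significance.

Count-like outcomes (latencies rounded to whole seconds, integer ratio
discrepancies) are fitted with negative binomial regression, binary
outcomes (matched or not) with logistic regression, and amplitudes with an
ordinary Gaussian linear model.  Because a single 20-minute exchange offers
a small sample, each fitted contrast can additionally be checked with a
randomization test: the predictor labels are permuted, the model refitted,
and the observed coefficient compared against the permutation null.

All categorical fits here are one-way (a single categorical predictor with
treatment coding), for which the maximum-likelihood coefficients have a
closed form — each level's fitted mean equals its sample mean — regardless
of the family's dispersion.  The randomization machinery exploits that
identity to keep thousands of permutation refits cheap while remaining
exactly equivalent to a full refit.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .events import CallEvent, PhaseLabel, Session

__all__ = [
    "TermEstimate",
    "GLMResult",
    "FitSpec",
    "RandomizationResult",
    "DegenerateFitError",
    "fit_categorical_glm",
    "fit_latency_model",
    "fit_match_model",
    "fit_amplitude_trend",
    "randomization_test",
]

logger = logging.getLogger(__name__)

_FAMILY_LINK = {
    "NEG_BINOMIAL": "LOG",
    "POISSON": "LOG",
    "GAMMA": "LOG",
    "LOGISTIC": "LOGIT",
    "GAUSSIAN": "IDENTITY",
}


class DegenerateFitError(RuntimeError):
    """The outcome carries no information the model could fit."""


@dataclass(frozen=True)
class TermEstimate:
    beta: float
    se: float
    p_value: float

    def to_dict(self) -> dict:
        return {"beta": self.beta, "se": self.se, "p_value": self.p_value}


@dataclass
class GLMResult:
    """A fitted one-way GLM contrast set.

    ``terms`` maps each non-reference predictor level to its treatment-coded
    coefficient (log mean ratio, log odds ratio, or mean difference,
    depending on family), standard error and Wald p-value.  ``dispersion``
    is the negative binomial alpha when that family was used.  ``flags``
    records anomalies: levels with too few observations to estimate a
    contrast, separation handled via a corrected contingency table, or a
    Poisson fallback when the dispersion estimate collapses to zero.
    """

    family: str
    link: str
    terms: dict[str, TermEstimate]
    n_obs: int
    reference_level: str
    dispersion: float | None = None
    intercept: float | None = None
    flags: dict = field(default_factory=dict)

    def odds_ratios(self) -> dict[str, float]:
        if self.family != "LOGISTIC":
            raise ValueError("odds ratios are defined for LOGISTIC fits only")
        return {k: math.exp(v.beta) for k, v in self.terms.items()}

    def to_dict(self) -> dict:
        return {
            "family": self.family,
            "link": self.link,
            "reference_level": self.reference_level,
            "terms": {k: v.to_dict() for k, v in self.terms.items()},
            "n_obs": self.n_obs,
            "dispersion": self.dispersion,
            "intercept": self.intercept,
            "flags": self.flags,
        }


@dataclass(frozen=True)
class FitSpec:
    """Specification of a one-way categorical GLM fit.

    ``term`` names the predictor level whose coefficient is of interest for
    a randomization test; when omitted the first non-reference level in
    sorted order is used.
    """

    outcome: str
    predictor: str
    family: str
    reference: str | None = None
    term: str | None = None


@dataclass
class RandomizationResult:
    """Permutation null for one regression coefficient.

    ``p_empirical`` uses the add-one estimator
    ``(1 + #{|beta*| >= |beta_obs|}) / (n_valid + 1)`` with a two-sided tail
    on the coefficient magnitude; permutations whose fit failed (for
    example, a permuted group with zero mean under a log link) are excluded
    from the denominator.
    """

    beta_observed: float
    null_betas: np.ndarray
    p_empirical: float
    n_permutations: int
    n_failed: int
    seed: int
    term: str

    def to_dict(self) -> dict:
        return {
            "beta_observed": self.beta_observed,
            "p_empirical": self.p_empirical,
            "n_permutations": self.n_permutations,
            "n_failed": self.n_failed,
            "seed": self.seed,
            "term": self.term,
            "null_betas": [float(b) for b in self.null_betas],
        }


# ---------------------------------------------------------------------------
# Core one-way categorical fit
# ---------------------------------------------------------------------------

def _design(labels: pd.Series, reference: str) -> tuple[np.ndarray, list[str]]:
    levels = sorted(set(labels.astype(str)))
    if reference not in levels:
        raise ValueError(f"reference level {reference!r} not among levels {levels}")
    others = [lv for lv in levels if lv != reference]
    X = np.column_stack(
        [np.ones(len(labels))] + [(labels.astype(str) == lv).to_numpy(float) for lv in others]
    )
    return X, others


def fit_categorical_glm(
    data: pd.DataFrame,
    outcome: str,
    predictor: str,
    family: str,
    *,
    reference: str | None = None,
    min_obs_per_level: int = 2,
) -> GLMResult:
    """Fit outcome ~ C(predictor) with treatment coding.

    Levels with fewer than ``min_obs_per_level`` observations cannot support
    a contrast; they are excluded from the design and listed under
    ``flags['inestimable']``.  At least two estimable levels are required.
    """
    family = family.upper()
    if family not in _FAMILY_LINK:
        raise ValueError(f"unknown family {family!r}")
    df = data[[outcome, predictor]].dropna().copy()
    df[predictor] = df[predictor].astype(str)

    counts = df[predictor].value_counts()
    inestimable = sorted(counts[counts < min_obs_per_level].index)
    df = df[~df[predictor].isin(inestimable)]
    levels = sorted(df[predictor].unique())
    if len(levels) < 2:
        raise ValueError(
            f"need >=2 predictor levels with >={min_obs_per_level} observations, "
            f"have {levels} (inestimable: {inestimable})"
        )
    if reference is None:
        reference = levels[0]
    reference = str(reference)

    y = df[outcome].to_numpy(float)
    X, others = _design(df[predictor], reference)
    flags: dict = {}
    if inestimable:
        flags["inestimable"] = inestimable

    if family in ("NEG_BINOMIAL", "POISSON"):
        result = _fit_count(y, X, family, flags)
    elif family == "GAMMA":
        result = sm.GLM(y, X, family=sm.families.Gamma(link=sm.families.links.Log())).fit()
        family_out, dispersion = "GAMMA", None
    elif family == "LOGISTIC":
        return _fit_logistic(df, outcome, predictor, reference, others, X, flags)
    else:  # GAUSSIAN
        result = sm.OLS(y, X).fit()
        family_out, dispersion = "GAUSSIAN", None

    if family in ("NEG_BINOMIAL", "POISSON"):
        result, family_out, dispersion = result

    terms = {
        lv: TermEstimate(
            beta=float(result.params[i + 1]),
            se=float(result.bse[i + 1]),
            p_value=float(result.pvalues[i + 1]),
        )
        for i, lv in enumerate(others)
    }
    return GLMResult(
        family=family_out,
        link=_FAMILY_LINK[family_out],
        terms=terms,
        n_obs=len(df),
        reference_level=reference,
        dispersion=dispersion,
        intercept=float(result.params[0]),
        flags=flags,
    )


def _fit_count(y: np.ndarray, X: np.ndarray, family: str, flags: dict):
    """Count-family fit: NB2 with ML dispersion, Poisson fallback.

    The dispersion alpha is estimated by maximum likelihood; the mean
    coefficients are then refitted by IRLS at that alpha (for a one-way
    design the coefficients do not depend on alpha, so this is a numerical
    polish, not a different estimator).  When alpha collapses toward zero
    or the NB likelihood fails, the fit degrades gracefully to Poisson.
    """
    if np.all(y == 0):
        raise DegenerateFitError("all-zero outcome: count model cannot be fitted")
    alpha = None
    if family == "NEG_BINOMIAL":
        try:
            from statsmodels.discrete.discrete_model import NegativeBinomial

            with np.errstate(all="ignore"):
                nb = NegativeBinomial(y, X, loglike_method="nb2").fit(
                    disp=0, maxiter=500, method="bfgs"
                )
            alpha = float(nb.params[-1])
        except Exception:  # boundary dispersion, non-convergence
            alpha = None
        if alpha is None or not np.isfinite(alpha) or alpha < 1e-4:
            flags["poisson_fallback"] = True
            alpha = None
    if alpha is None:
        res = sm.GLM(y, X, family=sm.families.Poisson()).fit()
        return res, "POISSON", None
    res = sm.GLM(y, X, family=sm.families.NegativeBinomial(alpha=alpha)).fit()
    return res, "NEG_BINOMIAL", alpha


def _fit_logistic(
    df: pd.DataFrame,
    outcome: str,
    predictor: str,
    reference: str,
    others: list[str],
    X: np.ndarray,
    flags: dict,
) -> GLMResult:
    """Logistic fit of a binary outcome on a categorical predictor.

    Complete separation (a level with 0% or 100% positive outcomes) makes
    the MLE diverge; affected contrasts are computed from the 2x2 table
    against the reference with the Haldane–Anscombe 0.5 correction and the
    Woolf standard error, and the result is flagged.
    """
    y = df[outcome].astype(float).to_numpy()
    if not set(np.unique(y)) <= {0.0, 1.0}:
        raise ValueError("LOGISTIC family requires a 0/1 outcome")
    rates = df.groupby(predictor)[outcome].mean()
    separated = sorted(rates[(rates == 0.0) | (rates == 1.0)].index)

    def table(level: str) -> np.ndarray:
        sub = df[df[predictor].isin([level, reference])]
        t = np.zeros((2, 2))
        for j, lv in enumerate((reference, level)):
            grp = sub[sub[predictor] == lv][outcome].astype(float)
            t[j, 0] = (grp == 1).sum()
            t[j, 1] = (grp == 0).sum()
        return t

    if separated:
        flags["separation"] = separated
        terms = {}
        for lv in others:
            t = table(lv)
            if (t == 0).any():
                t = t + 0.5
            beta = math.log((t[1, 0] * t[0, 1]) / (t[1, 1] * t[0, 0]))
            se = math.sqrt((1.0 / t).sum())
            z = beta / se
            from scipy.stats import norm

            terms[lv] = TermEstimate(beta=beta, se=se, p_value=float(2 * norm.sf(abs(z))))
        intercept = None
    else:
        res = sm.GLM(y, X, family=sm.families.Binomial()).fit()
        terms = {
            lv: TermEstimate(
                beta=float(res.params[i + 1]),
                se=float(res.bse[i + 1]),
                p_value=float(res.pvalues[i + 1]),
            )
            for i, lv in enumerate(others)
        }
        intercept = float(res.params[0])
    return GLMResult(
        family="LOGISTIC",
        link="LOGIT",
        terms=terms,
        n_obs=len(df),
        reference_level=reference,
        dispersion=None,
        intercept=intercept,
        flags=flags,
    )


# ---------------------------------------------------------------------------
# Named analysis fits
# ---------------------------------------------------------------------------

def fit_latency_model(
    dataset: pd.DataFrame,
    predictor: str = "PHASE_DAY",
    *,
    reference: str | None = None,
    family: str = "nb",
) -> GLMResult:
    """Latency contrasts across phases/day or counter-call status.

    Latencies (continuous seconds) are rounded to the nearest whole second
    so that the declared count family applies; a Gamma/log fit on the raw
    latencies is available via ``family='gamma'`` as a sensitivity check.
    ``predictor='PHASE_DAY'`` contrasts the phase column (control-day rows
    carry phase CONTROL, so the day contrast is included); ``'COUNTER_CALL'``
    contrasts direct-exchange records against the rest.
    """
    df = dataset.copy()
    if predictor == "PHASE_DAY":
        pred_col = "phase"
        df = df[df[pred_col] != "UNPHASED"]
    elif predictor == "COUNTER_CALL":
        pred_col = "is_counter_call"
        df = df.dropna(subset=[pred_col])
        df[pred_col] = df[pred_col].map({True: "COUNTER", False: "NOT_COUNTER"})
        if reference is None:
            reference = "NOT_COUNTER"
    else:
        raise ValueError(f"unknown predictor {predictor!r}")
    if family == "nb":
        df["_outcome"] = df["latency_s"].round().astype(int)
        fam = "NEG_BINOMIAL"
    elif family == "gamma":
        df = df[df["latency_s"] > 0].copy()
        df["_outcome"] = df["latency_s"]
        fam = "GAMMA"
    else:
        raise ValueError(f"latency family must be 'nb' or 'gamma', got {family!r}")
    return fit_categorical_glm(df, "_outcome", pred_col, fam, reference=reference)


def fit_match_model(
    pairs_or_counts, *, reference: str | None = None
) -> GLMResult:
    """Logistic fit of matched-vs-not on phase.

    Accepts either a sequence of response pairs or a per-phase count table
    (columns phase, n_matched, n_unmatched[, sufficient]).  Phases flagged
    insufficient (fewer than two pairs) are excluded before fitting.
    """
    if isinstance(pairs_or_counts, pd.DataFrame):
        counts = pairs_or_counts
    else:
        from .matching import match_rate_by_phase

        counts = match_rate_by_phase(pairs_or_counts)
    if "sufficient" in counts.columns:
        counts = counts[counts["sufficient"]]
    rows = []
    for _, r in counts.iterrows():
        rows += [{"phase": r["phase"], "matched": 1}] * int(r["n_matched"])
        rows += [{"phase": r["phase"], "matched": 0}] * int(r["n_unmatched"])
    long = pd.DataFrame(rows)
    return fit_categorical_glm(long, "matched", "phase", "LOGISTIC", reference=reference)


def fit_amplitude_trend(
    calls: Sequence[CallEvent] | Session,
    predictor: str = "TIME_MIN",
    *,
    phases=None,
) -> GLMResult:
    """Gaussian trend of call amplitude over the encounter.

    ``TIME_MIN`` regresses amplitude (dB) on call onset in minutes;
    ``PHASE`` regresses on the ordinal phase index (engagement 0,
    agitation 1, disengagement 2), giving a per-phase decline in dB.
    """
    if isinstance(calls, Session):
        session = calls
        call_list = session.calls
        phases = session.phases
    else:
        call_list = list(calls)
    call_list = [c for c in call_list if c.amplitude_db is not None]
    if len(call_list) < 3:
        raise ValueError("need >=3 calls with amplitude to fit a trend")

    y = np.array([c.amplitude_db for c in call_list], float)
    if predictor == "TIME_MIN":
        x = np.array([c.onset_s / 60.0 for c in call_list])
    elif predictor == "PHASE":
        if not phases:
            raise ValueError("PHASE predictor requires phase intervals")
        order = {
            PhaseLabel.ENGAGEMENT: 0,
            PhaseLabel.AGITATION: 1,
            PhaseLabel.DISENGAGEMENT: 2,
        }
        from .events import assign_phase

        idx = []
        keep = []
        for i, c in enumerate(call_list):
            lab = assign_phase(c.onset_s, phases)
            if lab in order:
                idx.append(order[lab])
                keep.append(i)
        x = np.array(idx, float)
        y = y[keep]
        if len(y) < 3:
            raise ValueError("fewer than 3 phased calls with amplitude")
    else:
        raise ValueError(f"unknown predictor {predictor!r}")

    X = sm.add_constant(x)
    res = sm.OLS(y, X).fit()
    term = "time_min" if predictor == "TIME_MIN" else "phase_index"
    return GLMResult(
        family="GAUSSIAN",
        link="IDENTITY",
        terms={
            term: TermEstimate(
                beta=float(res.params[1]),
                se=float(res.bse[1]),
                p_value=float(res.pvalues[1]),
            )
        },
        n_obs=len(y),
        reference_level="(slope)",
        intercept=float(res.params[0]),
    )


# ---------------------------------------------------------------------------
# Randomization test
# ---------------------------------------------------------------------------

def _closed_form_beta(
    y: np.ndarray, labels: np.ndarray, level: str, reference: str, family: str
) -> float:
    """Exact one-way MLE contrast for a permuted labelling.

    For log-link count families the treatment coefficient is the log ratio
    of group sample means (independent of dispersion); for logistic it is
    the 2x2 log odds ratio; for Gaussian the mean difference.  Raises
    ArithmeticError when the permuted groups make the contrast undefined.
    """
    mask_l = labels == level
    mask_r = labels == reference
    if not mask_l.any() or not mask_r.any():
        raise ArithmeticError("empty group")
    if family in ("NEG_BINOMIAL", "POISSON", "GAMMA"):
        m_l, m_r = y[mask_l].mean(), y[mask_r].mean()
        if m_l <= 0 or m_r <= 0:
            raise ArithmeticError("zero group mean under log link")
        return math.log(m_l / m_r)
    if family == "LOGISTIC":
        p_l, p_r = y[mask_l].mean(), y[mask_r].mean()
        if p_l in (0.0, 1.0) or p_r in (0.0, 1.0):
            raise ArithmeticError("separation in permuted table")
        return math.log(p_l / (1 - p_l)) - math.log(p_r / (1 - p_r))
    if family == "GAUSSIAN":
        return float(y[mask_l].mean() - y[mask_r].mean())
    raise ValueError(f"unknown family {family!r}")


def randomization_test(
    dataset: pd.DataFrame,
    spec: FitSpec,
    n_permutations: int = 1000,
    seed: int = 0,
    *,
    max_failed_fraction: float = 0.1,
) -> RandomizationResult:
    """Permutation null for the coefficient named by ``spec``.

    The predictor labels are permuted uniformly without replacement each
    iteration (seeded), the model refitted, and the coefficient collected.
    Permutations whose refit is undefined are recorded and excluded from the
    denominator; the procedure aborts if more than ``max_failed_fraction``
    of them fail.
    """
    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    family = spec.family.upper()
    observed = fit_categorical_glm(
        dataset, spec.outcome, spec.predictor, family, reference=spec.reference
    )
    term = spec.term or sorted(observed.terms)[0]
    if term not in observed.terms:
        raise ValueError(f"term {term!r} not among fitted contrasts {sorted(observed.terms)}")
    reference = observed.reference_level

    df = dataset[[spec.outcome, spec.predictor]].dropna()
    y = df[spec.outcome].to_numpy(float)
    labels = df[spec.predictor].astype(str).to_numpy()
    eff_family = observed.family
    # the tail statistic is evaluated by the same exact one-way MLE route for
    # the observed labelling as for every permutation, so ties are exact;
    # the full GLM fit above guarantees the model is estimable un-permuted
    beta_obs = _closed_form_beta(y, labels, term, reference, eff_family)

    rng = np.random.default_rng(seed)
    null_betas = []
    n_failed = 0
    for _ in range(n_permutations):
        perm = rng.permutation(labels)
        try:
            null_betas.append(_closed_form_beta(y, perm, term, reference, eff_family))
        except ArithmeticError:
            n_failed += 1
    if n_failed > max_failed_fraction * n_permutations:
        raise RuntimeError(
            f"{n_failed}/{n_permutations} permutation fits failed "
            f"(> {max_failed_fraction:.0%} allowed)"
        )
    null = np.asarray(null_betas)
    n_valid = len(null)
    p = (1 + int(np.sum(np.abs(null) >= abs(beta_obs)))) / (n_valid + 1)
    return RandomizationResult(
        beta_observed=beta_obs,
        null_betas=null,
        p_empirical=p,
        n_permutations=n_valid,
        n_failed=n_failed,
        seed=seed,
        term=term,
    )
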