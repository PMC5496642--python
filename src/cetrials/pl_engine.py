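"""Cox-type partial-likelihood estimation on counting-process data.

Five risk-set regimes cover the analyses compared throughout the package;
they differ only in which intervals are at risk and which events contribute:

``COX_FIRST_COMPOSITE``
    time to first composite event; at risk only while event-free and alive.
``AG_COMPOSITE``
    Andersen-Gill recurrent-event model on the composite: every event counts
    and every subject alive and uncensored is at risk regardless of history.
``MS_PER_COMPONENT``
    multi-state model: events of one component (fatal or non-fatal) with the
    Andersen-Gill risk set (alive and uncensored); separate effects per
    component.  The joint partial likelihood factorizes over components.
``PWP_STRATIFIED``
    Prentice-Williams-Peterson: events stratified by the number of prior
    non-fatal events; the risk set for a j-th event contains only subjects
    currently at risk for their own j-th event.
``CAUSE_SPECIFIC_FIRST``
    first-event cause-specific hazard for one component; the competing first
    event of the other type censors the subject at that time.

With a single binary treatment covariate the partial likelihood reduces, per
event, to a term depending only on the failing arm and the per-arm risk-set
counts (n0, n1); these counts do not depend on beta, so the log-likelihood,
score and observed information have closed forms once the counts are
tabulated.  Ties are handled by the Breslow convention (the full risk set at
the tied time is used for every tied event).  Newton-Raphson from beta = 0
with step-halving maximizes the log partial likelihood; monotone-likelihood
cases (all events in one arm) are flagged as non-identifiable, never
silently estimated.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from cetrials.trial_data import COMPOSITE, FATAL, NONFATAL, TrialDataset

__all__ = [
    "Regime",
    "RiskSetRule",
    "FitResult",
    "NonIdentifiableError",
    "partial_loglik",
    "fit",
    "fit_multistate",
    "wald_test",
]

MAX_ITER = 25
SCORE_TOL = 1e-8
STEP_TOL = 1e-10
#: |log HR| beyond which the estimate is treated as diverging (infinite MLE:
#: monotone likelihoods have score -> 0 along a runaway path, so a score
#: tolerance alone cannot catch them).
DIVERGE_BOUND = 10.0


class Regime(enum.Enum):
    COX_FIRST_COMPOSITE = "cox-first"
    AG_COMPOSITE = "ag"
    MS_PER_COMPONENT = "ms"
    PWP_STRATIFIED = "pwp"
    CAUSE_SPECIFIC_FIRST = "cs-first"


_COMPOSITE_REGIMES = {
    Regime.COX_FIRST_COMPOSITE,
    Regime.AG_COMPOSITE,
    Regime.PWP_STRATIFIED,
}
_COMPONENT_REGIMES = {Regime.MS_PER_COMPONENT, Regime.CAUSE_SPECIFIC_FIRST}


@dataclass(frozen=True)
class RiskSetRule:
    """A regime plus, for per-component regimes, the component analysed."""

    regime: Regime
    component: str = COMPOSITE

    def __post_init__(self) -> None:
        if self.regime in _COMPOSITE_REGIMES and self.component != COMPOSITE:
            raise ValueError(f"{self.regime} analyses the composite only")
        if self.regime in _COMPONENT_REGIMES and self.component not in (
            FATAL,
            NONFATAL,
        ):
            raise ValueError(
                f"{self.regime} needs component 'fatal' or 'nonfatal'"
            )


class NonIdentifiableError(ValueError):
    """No qualifying events: the partial likelihood carries no information."""


@dataclass(frozen=True)
class FitResult:
    """Maximum partial-likelihood fit of one or two log hazard ratios.

    ``estimates``/``se``/``n_events`` are keyed by component label
    (``"composite"``, ``"fatal"`` or ``"nonfatal"``).  A component that could
    not be estimated is absent from ``estimates`` and explained in
    ``problems``.
    """

    estimates: dict[str, float]
    se: dict[str, float]
    loglik: float
    iterations: int
    converged: bool
    n_events: dict[str, int]
    problems: dict[str, str] = field(default_factory=dict)

    def hazard_ratios(self) -> dict[str, float]:
        return {k: math.exp(b) for k, b in self.estimates.items()}


# --------------------------------------------------------------------------
# risk-set tabulation


def _event_terms(dataset: TrialDataset, rule: RiskSetRule):
    """Tabulate, per qualifying event, the failing arm and per-arm risk counts.

    Returns arrays ``(x, n0, n1)``: treatment of the failing subject and the
    numbers of control/treated risk intervals containing the event time.
    Risk intervals and qualifying events per regime:

    - AG / MS: one interval (0, last_stop] per subject; events are all
      events (AG) or the selected component's events (MS).
    - Cox-first / cause-specific-first: the first interval per subject;
      events are first events (of the selected component for
      cause-specific).
    - PWP: one group per prior-event-count stratum; interval and events of
      that stratum only.
    """
    groups = dataset.by_subject()
    regime = rule.regime

    def _counts(intervals, events):
        # intervals: (starts, stops, x) arrays; events: (times, x) arrays
        starts, stops, ivx = intervals
        times, evx = events
        out_n0 = []
        out_n1 = []
        for arm, holder in ((0, out_n0), (1, out_n1)):
            sel = ivx == arm
            s_sorted = np.sort(starts[sel])
            e_sorted = np.sort(stops[sel])
            # at risk at t iff start < t <= stop
            n_start = np.searchsorted(s_sorted, times, side="left")
            n_stop_lt = np.searchsorted(e_sorted, times, side="left")
            holder.append(n_start - n_stop_lt)
        return evx, out_n0[0], out_n1[0]

    def _build(interval_recs, event_recs):
        intervals = (
            np.array([r.start for r in interval_recs], dtype=float),
            np.array([r.stop for r in interval_recs], dtype=float),
            np.array([r.treatment for r in interval_recs], dtype=int),
        )
        events = (
            np.array([r.stop for r in event_recs], dtype=float),
            np.array([r.treatment for r in event_recs], dtype=int),
        )
        return _counts(intervals, events)

    if regime in (Regime.AG_COMPOSITE, Regime.MS_PER_COMPONENT):
        # full at-risk span per subject; composite type qualifies everywhere
        spans = []
        for recs in groups.values():
            last = recs[-1]
            spans.append(
                type(last)(
                    last.subject_id, last.treatment, 0.0, last.stop, 0, None, 0
                )
            )
        if regime is Regime.AG_COMPOSITE:
            events = [r for r in dataset.records if r.event == 1]
        else:
            events = [
                r
                for r in dataset.records
                if r.event == 1 and r.event_type == rule.component
            ]
        parts = [_build(spans, events)] if events else []
    elif regime in (Regime.COX_FIRST_COMPOSITE, Regime.CAUSE_SPECIFIC_FIRST):
        firsts = [recs[0] for recs in groups.values()]
        if regime is Regime.COX_FIRST_COMPOSITE:
            events = [r for r in firsts if r.event == 1]
        else:
            events = [
                r for r in firsts if r.event == 1 and r.event_type == rule.component
            ]
        parts = [_build(firsts, events)] if events else []
    elif regime is Regime.PWP_STRATIFIED:
        strata: dict[int, list] = {}
        for r in dataset.records:
            strata.setdefault(r.prior_nonfatal_count, []).append(r)
        parts = []
        for recs in strata.values():
            events = [r for r in recs if r.event == 1]
            if events:
                parts.append(_build(recs, events))
    else:  # pragma: no cover
        raise ValueError(f"unknown regime {regime}")

    if not parts:
        return (
            np.empty(0, dtype=int),
            np.empty(0, dtype=int),
            np.empty(0, dtype=int),
        )
    x = np.concatenate([p[0] for p in parts])
    n0 = np.concatenate([p[1] for p in parts])
    n1 = np.concatenate([p[2] for p in parts])
    return x, n0, n1


def _loglik_from_terms(x, n0, n1, beta: float):
    """Closed-form log partial likelihood, score and information for scalar beta."""
    eb = math.exp(beta)
    denom = n0 + n1 * eb
    ll = float(np.sum(beta * x - np.log(denom)))
    mean1 = n1 * eb / denom
    score = float(np.sum(x - mean1))
    info = float(np.sum(n0 * n1 * eb / denom**2))
    return ll, score, info


def partial_loglik(
    dataset: TrialDataset, beta: float, rule: RiskSetRule
) -> tuple[float, float, float]:
    """Log partial likelihood and its first two derivatives at ``beta``.

    Raises :class:`NonIdentifiableError` when no event qualifies under the
    rule (the likelihood is constant).
    """
    x, n0, n1 = _event_terms(dataset, rule)
    if len(x) == 0:
        raise NonIdentifiableError(
            f"no qualifying events under {rule.regime.value}/{rule.component}"
        )
    return _loglik_from_terms(x, n0, n1, float(beta))


def _newton(x, n0, n1) -> tuple[float, float, float, int, bool]:
    """Maximize the 1-D log partial likelihood; returns (beta, se, ll, iters, ok)."""
    beta = 0.0
    ll, score, info = _loglik_from_terms(x, n0, n1, beta)
    converged = False
    it = 0
    for it in range(1, MAX_ITER + 1):
        if abs(score) < SCORE_TOL:
            converged = True
            break
        step = score / info
        # step-halving: never accept a decrease of the log-likelihood
        # (beyond float rounding noise near the optimum)
        slack = 1e-10 * (abs(ll) + 1.0)
        new_beta = beta + step
        new_ll, new_score, new_info = _loglik_from_terms(x, n0, n1, new_beta)
        halvings = 0
        while new_ll < ll - slack and halvings < 30:
            step *= 0.5
            new_beta = beta + step
            new_ll, new_score, new_info = _loglik_from_terms(x, n0, n1, new_beta)
            halvings += 1
        delta = abs(new_beta - beta)
        beta, ll, score, info = new_beta, new_ll, new_score, new_info
        if abs(beta) > DIVERGE_BOUND:
            return beta, math.nan, ll, it, False
        if abs(score) < SCORE_TOL:
            converged = True
            break
        if delta < STEP_TOL:
            break
    se = 1.0 / math.sqrt(info) if info > 0 else math.nan
    return beta, se, ll, it, converged


def fit(dataset: TrialDataset, rule: RiskSetRule) -> FitResult:
    """Newton-Raphson maximum partial-likelihood fit under one risk-set rule.

    Monotone-likelihood data (all qualifying events in one arm, or no events
    at all) yield a non-converged :class:`FitResult` with a diagnostic in
    ``problems`` rather than a runaway estimate.
    """
    label = rule.component
    x, n0, n1 = _event_terms(dataset, rule)
    n_ev = int(len(x))
    if n_ev == 0:
        return FitResult(
            estimates={},
            se={},
            loglik=math.nan,
            iterations=0,
            converged=False,
            n_events={label: 0},
            problems={label: "non-identifiable: no qualifying events"},
        )
    n_treated_events = int(np.sum(x))
    if n_treated_events in (0, n_ev):
        arm = "control" if n_treated_events == 0 else "treated"
        return FitResult(
            estimates={},
            se={},
            loglik=math.nan,
            iterations=0,
            converged=False,
            n_events={label: n_ev},
            problems={
                label: f"non-identifiable: all events in the {arm} arm "
                "(monotone likelihood)"
            },
        )
    beta, se, ll, it, ok = _newton(x, n0, n1)
    if not ok and abs(beta) > DIVERGE_BOUND:
        return FitResult(
            estimates={},
            se={},
            loglik=math.nan,
            iterations=it,
            converged=False,
            n_events={label: n_ev},
            problems={
                label: "non-identifiable: estimate diverging "
                "(monotone likelihood, infinite MLE)"
            },
        )
    return FitResult(
        estimates={label: beta},
        se={label: se},
        loglik=ll,
        iterations=it,
        converged=ok,
        n_events={label: n_ev},
    )


def fit_multistate(dataset: TrialDataset) -> FitResult:
    """Joint multi-state fit: separate log hazard ratios per component.

    The multi-state partial likelihood factorizes over components, so the
    joint maximum is exactly the two independent per-component fits and the
    joint log-likelihood is the sum of the component log-likelihoods.
    """
    parts = {
        comp: fit(dataset, RiskSetRule(Regime.MS_PER_COMPONENT, comp))
        for comp in (FATAL, NONFATAL)
    }
    estimates: dict[str, float] = {}
    se: dict[str, float] = {}
    n_events: dict[str, int] = {}
    problems: dict[str, str] = {}
    loglik = 0.0
    iterations = 0
    any_estimate = False
    all_ok = True
    for comp, res in parts.items():
        n_events[comp] = res.n_events[comp]
        iterations = max(iterations, res.iterations)
        if comp in res.estimates:
            estimates[comp] = res.estimates[comp]
            se[comp] = res.se[comp]
            loglik += res.loglik
            any_estimate = True
            all_ok = all_ok and res.converged
        else:
            problems[comp] = res.problems[comp]
            all_ok = False
    return FitResult(
        estimates=estimates,
        se=se,
        loglik=loglik if any_estimate else math.nan,
        iterations=iterations,
        converged=all_ok,
        n_events=n_events,
        problems=problems,
    )


def wald_test(
    fit_result: FitResult, coefficient: str, alpha: float = 0.05
) -> tuple[float, float, bool]:
    """Two-sided Wald test of H0: beta = 0 for one fitted coefficient.

    Returns ``(z, p, reject)`` with ``z = beta / se`` and the p-value from
    the standard normal law.
    """
    if coefficient not in fit_result.estimates:
        raise ValueError(f"coefficient {coefficient!r} was not estimated")
    if not fit_result.converged:
        raise ValueError("Wald test requires a converged fit")
    se = fit_result.se[coefficient]
    if not se > 0:
        raise ValueError("Wald test requires a positive standard error")
    z = fit_result.estimates[coefficient] / se
    p = float(2.0 * stats.norm.sf(abs(z)))
    return z, p, p < alpha
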