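"""Independent brute-force oracles for the partial-likelihood engine tests.

Everything here enumerates risk sets record-by-record, subject-by-subject,
with no shared code or vectorization tricks from the engine under test.
"""

from __future__ import annotations

import math

from scipy import optimize

from cetrials.pl_engine import Regime, RiskSetRule
from cetrials.trial_data import TrialDataset


def _subject_spans(dataset: TrialDataset):
    """Per subject: (treatment, first-record stop, last-record stop, records)."""
    out = {}
    for sid, recs in dataset.by_subject().items():
        out[sid] = (recs[0].treatment, recs[0].stop, recs[-1].stop, recs)
    return out


def brute_force_loglik(
    dataset: TrialDataset, beta: float, rule: RiskSetRule
) -> float:
    """Log partial likelihood by explicit risk-set materialization."""
    spans = _subject_spans(dataset)
    regime = rule.regime

    def qualifying_events():
        for sid, (_, _, _, recs) in spans.items():
            if regime in (Regime.COX_FIRST_COMPOSITE, Regime.CAUSE_SPECIFIC_FIRST):
                recs = recs[:1]
            for rec in recs:
                if rec.event != 1:
                    continue
                if regime in (Regime.MS_PER_COMPONENT, Regime.CAUSE_SPECIFIC_FIRST):
                    if rec.event_type != rule.component:
                        continue
                yield rec

    def risk_set(event_rec):
        t = event_rec.stop
        members = []
        for sid, (x, first_stop, last_stop, recs) in spans.items():
            if regime in (Regime.AG_COMPOSITE, Regime.MS_PER_COMPONENT):
                at_risk = 0.0 < t <= last_stop
            elif regime in (Regime.COX_FIRST_COMPOSITE, Regime.CAUSE_SPECIFIC_FIRST):
                at_risk = 0.0 < t <= first_stop
            elif regime is Regime.PWP_STRATIFIED:
                at_risk = any(
                    r.prior_nonfatal_count == event_rec.prior_nonfatal_count
                    and r.start < t <= r.stop
                    for r in recs
                )
            else:
                raise AssertionError(regime)
            if at_risk:
                members.append(x)
        return members

    ll = 0.0
    for rec in qualifying_events():
        members = risk_set(rec)
        ll += beta * rec.treatment - math.log(
            sum(math.exp(beta * x) for x in members)
        )
    return ll


def brute_force_fit(
    dataset: TrialDataset, rule: RiskSetRule, lo: float = -5.0, hi: float = 5.0
) -> float:
    """1-D maximizer of the brute-force log partial likelihood (golden section)."""
    res = optimize.minimize_scalar(
        lambda b: -brute_force_loglik(dataset, b, rule),
        bounds=(lo, hi),
        method="bounded",
        options={"xatol": 1e-10},
    )
    return float(res.x)


def numeric_derivatives(f, x: float, h: float = 1e-5) -> tuple[float, float]:
    """Central finite-difference first derivative and negated second derivative."""
    first = (f(x + h) - f(x - h)) / (2 * h)
    second = (f(x + h) - 2 * f(x) + f(x - h)) / h**2
    return first, -second
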