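"""Replicate scenario grids, analytic identities, and empirical power.

``run_scenario`` is the workhorse: it simulates replicate trials, analyses
each with the six standard analyses (first-event Cox on the composite,
first-event cause-specific per component, Andersen-Gill on all composite
events, multi-state per component on all events) and aggregates the log
hazard-ratio estimates on the log scale — reporting exp(mean log-HR) and the
empirical standard error (standard deviation of the estimates across
replicates).  ``reproduce_table`` iterates the standard simulation grid.

Also included: the constant-hazard composite identity
HR_CE = (lambda1*HR1 + lambda2*HR2) / (lambda1 + lambda2), the empirical
power of the first-event composite Wald test under a given trial design, and
the Schoenfeld required-events formula as an internal design cross-check.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import stats

from cetrials.pl_engine import Regime, RiskSetRule, fit, fit_multistate, wald_test
from cetrials.simulator import SimConfig, simulate_trial
from cetrials.trial_data import FATAL, NONFATAL, restrict_to_first_event

__all__ = [
    "ANALYSES",
    "Scenario",
    "ScenarioResult",
    "run_scenario",
    "reproduce_table",
    "analytic_composite_hr",
    "empirical_power",
    "schoenfeld_required_events",
    "expected_first_event_probability",
]

#: The six standard analyses, in the column order of the result tables.
ANALYSES = (
    "first_composite",   # Cox on time to first composite event
    "first_fatal",       # cause-specific first-event, fatal component
    "first_nonfatal",    # cause-specific first-event, non-fatal component
    "all_composite",     # Andersen-Gill on all composite events
    "all_fatal",         # multi-state, fatal component, all events
    "all_nonfatal",      # multi-state, non-fatal component, all events
)

_FIRST_ANALYSES = {"first_composite", "first_fatal", "first_nonfatal"}


@dataclass(frozen=True)
class Scenario:
    """A simulation configuration plus replicate count and base seed."""

    config: SimConfig
    n_replicates: int
    base_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_replicates < 2:
            raise ValueError("need at least 2 replicates (SD undefined below)")


@dataclass(frozen=True)
class AnalysisSummary:
    """Aggregate of one analysis across converged replicates."""

    mean_log_hr: float
    hr: float            # exp(mean_log_hr)
    empirical_se: float  # SD of the log-HR estimates across replicates
    n_converged: int
    n_excluded: int


@dataclass(frozen=True)
class ScenarioResult:
    """Per-analysis aggregates of one scenario run."""

    scenario: Scenario
    summaries: dict[str, AnalysisSummary]

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "analysis": name,
                "hr": s.hr,
                "mean_log_hr": s.mean_log_hr,
                "empirical_se": s.empirical_se,
                "n_converged": s.n_converged,
                "n_excluded": s.n_excluded,
            }
            for name, s in self.summaries.items()
        ]
        return pd.DataFrame(rows)


def _analyse_replicate(dataset, analyses) -> dict[str, float | None]:
    """Log-HR estimate per requested analysis; None marks an excluded fit."""
    out: dict[str, float | None] = {}
    need_first = bool(_FIRST_ANALYSES.intersection(analyses))
    restricted = restrict_to_first_event(dataset) if need_first else None

    def _take(res, label):
        return res.estimates.get(label) if res.converged else None

    if "all_composite" in analyses:
        res = fit(dataset, RiskSetRule(Regime.AG_COMPOSITE))
        out["all_composite"] = _take(res, "composite")
    if "all_fatal" in analyses or "all_nonfatal" in analyses:
        res = fit_multistate(dataset)
        for name, comp in (("all_fatal", FATAL), ("all_nonfatal", NONFATAL)):
            if name in analyses:
                out[name] = res.estimates.get(comp) if comp in res.estimates else None
    if "first_composite" in analyses:
        res = fit(restricted, RiskSetRule(Regime.COX_FIRST_COMPOSITE))
        out["first_composite"] = _take(res, "composite")
    for name, comp in (("first_fatal", FATAL), ("first_nonfatal", NONFATAL)):
        if name in analyses:
            res = fit(restricted, RiskSetRule(Regime.CAUSE_SPECIFIC_FIRST, comp))
            out[name] = _take(res, comp)
    return out


def run_scenario(
    scenario: Scenario, analyses: tuple[str, ...] = ANALYSES
) -> ScenarioResult:
    """Simulate and analyse ``n_replicates`` trials; aggregate on the log scale.

    Replicate r uses the independent seed stream ``(base_seed, r)``, so the
    result is bit-reproducible and invariant to the order in which
    replicates are executed.  Non-converged or non-identifiable fits are
    excluded from the aggregates and counted per analysis.
    """
    unknown = set(analyses) - set(ANALYSES)
    if unknown:
        raise ValueError(f"unknown analyses: {sorted(unknown)}")
    estimates: dict[str, list[float]] = {a: [] for a in analyses}
    excluded: dict[str, int] = {a: 0 for a in analyses}
    for r in range(scenario.n_replicates):
        config = replace(scenario.config, seed=(scenario.base_seed, r))
        dataset = simulate_trial(config)
        for name, value in _analyse_replicate(dataset, analyses).items():
            if value is None:
                excluded[name] += 1
            else:
                estimates[name].append(value)
    summaries: dict[str, AnalysisSummary] = {}
    for name in analyses:
        values = np.asarray(estimates[name])
        if len(values) == 0:
            continue  # analysis absent: every replicate failed
        mean = float(values.mean())
        sd = float(values.std(ddof=1)) if len(values) > 1 else math.nan
        summaries[name] = AnalysisSummary(
            mean_log_hr=mean,
            hr=math.exp(mean),
            empirical_se=sd,
            n_converged=len(values),
            n_excluded=excluded[name],
        )
    return ScenarioResult(scenario=scenario, summaries=summaries)


#: Simulation grid of the standard result tables.
TABLE_RATES = {3: (0.14, 1.17), 4: (0.655, 0.655)}
TABLE_HR1 = (0.75, 0.92)
TABLE_HR2 = 0.75
TABLE_THETAS = (0.0, 0.6)
TABLE_RHOS = (1.0, 1.05, 1.10, 1.15, 1.20, 1.25, 1.30)


def reproduce_table(
    table_id: int,
    n_replicates: int,
    base_seed: int = 0,
    hr1_values: tuple[float, ...] = TABLE_HR1,
    thetas: tuple[float, ...] = TABLE_THETAS,
    rhos: tuple[float, ...] = TABLE_RHOS,
    analyses: tuple[str, ...] = ANALYSES,
) -> pd.DataFrame:
    """Run the standard simulation grid for one of the two rate settings.

    ``table_id`` 3 selects (lambda1, lambda2) = (0.14, 1.17); 4 selects
    (0.655, 0.655).  One row per (hr1, theta, rho) cell with exp(mean
    log-HR) and empirical SE per analysis.  The grid subsets allow cheap
    partial runs.
    """
    if table_id not in TABLE_RATES:
        raise ValueError("table_id must be 3 or 4")
    lambda1, lambda2 = TABLE_RATES[table_id]
    rows = []
    cell = 0
    for hr1 in hr1_values:
        for theta in thetas:
            for rho in rhos:
                config = SimConfig(
                    lambda1=lambda1,
                    lambda2=lambda2,
                    beta1=math.log(hr1),
                    beta2=math.log(TABLE_HR2),
                    theta=theta,
                    rho=rho,
                )
                scenario = Scenario(
                    config=config,
                    n_replicates=n_replicates,
                    base_seed=base_seed + cell,
                )
                result = run_scenario(scenario, analyses)
                row: dict[str, float] = {
                    "exp_beta1": hr1,
                    "exp_beta2": TABLE_HR2,
                    "theta": theta,
                    "rho": rho,
                }
                for name in analyses:
                    s = result.summaries.get(name)
                    row[f"hr_{name}"] = s.hr if s else math.nan
                    row[f"se_{name}"] = s.empirical_se if s else math.nan
                rows.append(row)
                cell += 1
    return pd.DataFrame(rows)


def analytic_composite_hr(
    lambda1: float, lambda2: float, hr1: float, hr2: float
) -> float:
    """Composite hazard ratio under constant component hazards.

    The composite hazard is the sum of the component hazards, so the
    composite hazard ratio is the rate-weighted mean
    (lambda1*hr1 + lambda2*hr2) / (lambda1 + lambda2).
    """
    if lambda1 < 0 or lambda2 < 0 or lambda1 + lambda2 <= 0:
        raise ValueError("rates must be non-negative with a positive sum")
    return (lambda1 * hr1 + lambda2 * hr2) / (lambda1 + lambda2)


def empirical_power(
    n_subjects: int = 465,
    lambda_control: float = 1.31,
    hr: float = 0.75,
    accrual_years: float = 1.0,
    study_years: float = 2.0,
    alpha: float = 0.05,
    n_replicates: int = 1000,
    base_seed: int = 0,
) -> float:
    """Rejection fraction of the first-event composite Wald test.

    Simulates trials whose composite first event is a single exponential
    process per subject (rate lambda_control, scaled by ``hr`` under
    treatment) with uniform accrual and administrative censoring, fits the
    first-event Cox model and tests H0: HR = 1 two-sided at ``alpha``.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    if hr <= 0:
        raise ValueError("hr must be positive")
    rejections = 0
    tested = 0
    for r in range(n_replicates):
        config = SimConfig(
            n_subjects=n_subjects,
            accrual_years=accrual_years,
            study_years=study_years,
            lambda1=lambda_control,  # single terminal process = first event
            lambda2=0.0,
            beta1=math.log(hr),
            beta2=0.0,
            theta=0.0,
            rho=1.0,
            seed=(base_seed, r),
        )
        dataset = simulate_trial(config)
        res = fit(dataset, RiskSetRule(Regime.COX_FIRST_COMPOSITE))
        if not res.converged:
            continue
        _, _, reject = wald_test(res, "composite", alpha)
        tested += 1
        rejections += bool(reject)
    if tested == 0:
        raise RuntimeError("no replicate produced a testable fit")
    return rejections / tested


def schoenfeld_required_events(
    hr: float, alpha: float = 0.05, power: float = 0.8
) -> int:
    """Required event count for a two-sided log-rank/Cox test, balanced arms.

    ceil(4 * (z_{1-alpha/2} + z_{power})^2 / ln(hr)^2).
    """
    if hr <= 0 or hr == 1:
        raise ValueError("hr must be positive and different from 1")
    z_a = stats.norm.ppf(1 - alpha / 2)
    z_b = stats.norm.ppf(power)
    return math.ceil(4 * (z_a + z_b) ** 2 / math.log(hr) ** 2)


def expected_first_event_probability(
    rate: float, accrual_years: float, study_years: float
) -> float:
    """Probability of observing a first event before administrative censoring.

    With recruitment uniform on (0, a) and close-out at S, follow-up is
    C = S - R and the event probability averages to
    1 - (1/a) * int_0^a exp(-rate*(S-r)) dr
      = 1 - exp(-rate*S) * (exp(rate*a) - 1) / (rate*a).
    """
    if rate < 0:
        raise ValueError("rate must be non-negative")
    if not 0 <= accrual_years <= study_years:
        raise ValueError("need 0 <= accrual_years <= study_years")
    if rate == 0:
        return 0.0
    if accrual_years == 0:
        return 1.0 - math.exp(-rate * study_years)
    return 1.0 - math.exp(-rate * study_years) * math.expm1(
        rate * accrual_years
    ) / (rate * accrual_years)
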