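"""Exact discrete-time expected-count examples of the two composite-endpoint biases.

Two failure times t1 < t2 suffice to show both phenomena with expected
counts instead of simulation noise:

*Selection bias* — the study population mixes an (unobserved) low-risk and
high-risk subgroup.  Conditioning on being event-free at t1 (as any
time-to-first-event analysis implicitly does at t2) enriches the treated arm
for high-risk subjects, so the marginal odds ratio at t2 is attenuated
toward 1 relative to the common within-subgroup odds ratio.

*Direct-effect bias* — the treatment lowers the probability of a non-fatal
event at t1, and prior non-fatal events raise the mortality rate at t2.
Within each stratum of prior-event history the treatment has no effect on
mortality (OR = 1), yet the marginal mortality odds ratio is below 1: the
treatment acts on death only indirectly, by keeping subjects out of the
high-mortality stratum.  Stratifying on event history removes exactly this
indirect component.

The odds ratio is the discrete-time analogue of the hazard ratio, so both
constructions transfer to continuous-time proportional-hazards analyses.

All counts are expected values and are kept as exact floats; nothing is
rounded internally.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = [
    "StratumTable",
    "RiskSpec",
    "WorkedExample",
    "treatment_risk_from_or",
    "odds_ratio",
    "collapse_strata",
    "build_selection_example",
    "build_direct_effect_example",
    "render_example",
]


@dataclass(frozen=True)
class StratumTable:
    """Expected 2x2 event table for one stratum (treated/control x event/no event)."""

    label: str
    treated_events: float
    treated_nonevents: float
    control_events: float
    control_nonevents: float

    @property
    def treated_at_risk(self) -> float:
        return self.treated_events + self.treated_nonevents

    @property
    def control_at_risk(self) -> float:
        return self.control_events + self.control_nonevents

    def __post_init__(self) -> None:
        for cell in (
            self.treated_events,
            self.treated_nonevents,
            self.control_events,
            self.control_nonevents,
        ):
            if cell < 0:
                raise ValueError(f"stratum {self.label!r}: negative cell {cell}")


@dataclass(frozen=True)
class RiskSpec:
    """Per-stratum risk specification: control risk, treatment odds ratio, arm size."""

    p_control: float
    odds_ratio: float
    n_per_arm: float

    def __post_init__(self) -> None:
        if not 0 < self.p_control < 1:
            raise ValueError("p_control must lie strictly inside (0, 1)")
        if not self.odds_ratio > 0:
            raise ValueError("odds_ratio must be positive")


@dataclass(frozen=True)
class WorkedExample:
    """Strata with their odds ratios plus the collapsed (marginal) table."""

    strata: tuple[StratumTable, ...]
    stratum_odds_ratios: tuple[float, ...]
    marginal_table: StratumTable
    marginal_odds_ratio: float


def treatment_risk_from_or(p_control: float, odds_ratio: float) -> float:
    """Risk in the treated arm with the stated odds ratio versus control.

    Solves odds(p_t) = OR * odds(p_c); e.g. control risks 1/3 and 2/3 with
    OR 1/2 give treated risks 1/5 and 1/2.
    """
    if not 0 < p_control < 1:
        raise ValueError("p_control must lie strictly inside (0, 1)")
    if not odds_ratio > 0:
        raise ValueError("odds_ratio must be positive")
    odds = odds_ratio * p_control / (1.0 - p_control)
    return odds / (1.0 + odds)


def odds_ratio(table: StratumTable) -> float:
    """Cross-product odds ratio for an event under treatment vs control."""
    cells = (
        table.treated_events,
        table.control_nonevents,
        table.treated_nonevents,
        table.control_events,
    )
    if any(c == 0 for c in cells):
        raise ValueError(
            f"stratum {table.label!r}: odds ratio undefined (zero cell)"
        )
    return (table.treated_events * table.control_nonevents) / (
        table.treated_nonevents * table.control_events
    )


def collapse_strata(tables: list[StratumTable]) -> StratumTable:
    """Cell-wise sum of the strata — the marginal (unstratified) table."""
    if not tables:
        raise ValueError("cannot collapse an empty list of strata")
    return StratumTable(
        label="all (unstratified)",
        treated_events=sum(t.treated_events for t in tables),
        treated_nonevents=sum(t.treated_nonevents for t in tables),
        control_events=sum(t.control_events for t in tables),
        control_nonevents=sum(t.control_nonevents for t in tables),
    )


def build_selection_example(
    n_per_arm_per_stratum: float = 900,
    p_low: float = 1 / 3,
    p_high: float = 2 / 3,
    odds_ratio_value: float = 0.5,
) -> WorkedExample:
    """Expected counts at t2 among subjects event-free at t1, by risk subgroup.

    Each subgroup keeps the same per-time risk (p_low / p_high in control,
    derived via the odds ratio in treatment).  The at-risk sets at t2 are the
    survivors of t1, which is where the collider opens: the treated at-risk
    set retains more high-risk subjects.  Within-stratum odds ratios equal
    the input odds ratio exactly by construction.
    """
    strata = []
    ors = []
    for label, p_c in (("low-risk subgroup", p_low), ("high-risk subgroup", p_high)):
        spec = RiskSpec(p_c, odds_ratio_value, n_per_arm_per_stratum)
        p_t = treatment_risk_from_or(spec.p_control, spec.odds_ratio)
        treated_at_risk = spec.n_per_arm * (1.0 - p_t)
        control_at_risk = spec.n_per_arm * (1.0 - p_c)
        table = StratumTable(
            label=label,
            treated_events=treated_at_risk * p_t,
            treated_nonevents=treated_at_risk * (1.0 - p_t),
            control_events=control_at_risk * p_c,
            control_nonevents=control_at_risk * (1.0 - p_c),
        )
        strata.append(table)
        ors.append(odds_ratio(table))
    marginal = collapse_strata(strata)
    return WorkedExample(
        strata=tuple(strata),
        stratum_odds_ratios=tuple(ors),
        marginal_table=marginal,
        marginal_odds_ratio=odds_ratio(marginal),
    )


def build_direct_effect_example(
    n_per_arm: float = 900,
    p_nonfatal_control: float = 2 / 3,
    p_nonfatal_treated: float = 1 / 3,
    mort_after_event: float = 0.40,
    mort_no_event: float = 0.20,
) -> WorkedExample:
    """Expected death counts at t2 stratified by a prior non-fatal event at t1.

    Mortality depends on the prior-event stratum but, within stratum, not on
    treatment — the within-stratum odds ratios are exactly 1.  The marginal
    odds ratio reflects purely the indirect (mediated) treatment effect.
    """
    for p in (p_nonfatal_control, p_nonfatal_treated, mort_after_event, mort_no_event):
        if not 0 < p < 1:
            raise ValueError("probabilities must lie strictly inside (0, 1)")
    strata = []
    ors = []
    for label, in_stratum_treated, in_stratum_control, mort in (
        ("non-fatal event at t1", p_nonfatal_treated, p_nonfatal_control, mort_after_event),
        ("no non-fatal event at t1", 1 - p_nonfatal_treated, 1 - p_nonfatal_control, mort_no_event),
    ):
        n_treated = n_per_arm * in_stratum_treated
        n_control = n_per_arm * in_stratum_control
        table = StratumTable(
            label=label,
            treated_events=n_treated * mort,
            treated_nonevents=n_treated * (1.0 - mort),
            control_events=n_control * mort,
            control_nonevents=n_control * (1.0 - mort),
        )
        strata.append(table)
        ors.append(odds_ratio(table))
    marginal = collapse_strata(strata)
    return WorkedExample(
        strata=tuple(strata),
        stratum_odds_ratios=tuple(ors),
        marginal_table=marginal,
        marginal_odds_ratio=odds_ratio(marginal),
    )


def render_example(example: WorkedExample, event_label: str = "Events") -> str:
    """Plain-text rendering of the stratum tables and their odds ratios."""
    lines = []
    header = (
        f"{'Stratum':<28}{'Group':<12}{event_label:>10}{'No event':>10}"
        f"{'At risk':>10}{'OR':>8}"
    )
    lines.append(header)
    lines.append("-" * len(header))

    def _fmt(x: float) -> str:
        return f"{x:.0f}" if abs(x - round(x)) < 1e-9 else f"{x:.1f}"

    rows = list(zip(example.strata, example.stratum_odds_ratios)) + [
        (example.marginal_table, example.marginal_odds_ratio)
    ]
    for table, or_value in rows:
        lines.append(
            f"{table.label:<28}{'Treatment':<12}{_fmt(table.treated_events):>10}"
            f"{_fmt(table.treated_nonevents):>10}{_fmt(table.treated_at_risk):>10}"
            f"{or_value:>8.2f}"
        )
        lines.append(
            f"{'':<28}{'Control':<12}{_fmt(table.control_events):>10}"
            f"{_fmt(table.control_nonevents):>10}{_fmt(table.control_at_risk):>10}"
            f"{'':>8}"
        )
    return "\n".join(lines)
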