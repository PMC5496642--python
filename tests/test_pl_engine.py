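import dataclasses
import math

import numpy as np
import pytest

from cetrials.pl_engine import (
    NonIdentifiableError,
    Regime,
    RiskSetRule,
    fit,
    fit_multistate,
    partial_loglik,
    wald_test,
)
from cetrials.simulator import SimConfig, simulate_trial
from cetrials.trial_data import (
    FATAL,
    NONFATAL,
    EpisodeRecord,
    restrict_to_first_event,
)

from _oracles import brute_force_fit, brute_force_loglik, numeric_derivatives
from conftest import dataset, rec

ALL_RULES = [
    RiskSetRule(Regime.COX_FIRST_COMPOSITE),
    RiskSetRule(Regime.AG_COMPOSITE),
    RiskSetRule(Regime.PWP_STRATIFIED),
    RiskSetRule(Regime.MS_PER_COMPONENT, FATAL),
    RiskSetRule(Regime.MS_PER_COMPONENT, NONFATAL),
    RiskSetRule(Regime.CAUSE_SPECIFIC_FIRST, FATAL),
    RiskSetRule(Regime.CAUSE_SPECIFIC_FIRST, NONFATAL),
]

RULE_IDS = [f"{r.regime.value}-{r.component}" for r in ALL_RULES]


def _safe_pair(ds, beta, rule):
    try:
        engine = partial_loglik(ds, beta, rule)[0]
    except NonIdentifiableError:
        engine = None
    return engine


class TestPartialLoglik:
    def test_zero_beta_equals_minus_log_risk_set_sizes(self, toy_dataset):
        # at beta=0 every term is -log |risk set|; AG risk sets at the four
        # event times 0.5, 0.7, 1.0, 1.4 all contain 3, 3, 3, 3 subjects
        ll, _, _ = partial_loglik(toy_dataset, 0.0, RiskSetRule(Regime.AG_COMPOSITE))
        assert ll == pytest.approx(-4 * math.log(3))

    @pytest.mark.parametrize("rule", ALL_RULES, ids=RULE_IDS)
    @pytest.mark.parametrize("beta", [-1.0, 0.0, math.log(2.0)])
    def test_matches_brute_force_on_toy(self, toy_dataset, rule, beta):
        expected = _safe_pair(toy_dataset, beta, rule)
        if expected is None:
            return
        assert expected == pytest.approx(
            brute_force_loglik(toy_dataset, beta, rule), abs=1e-10
        )

    @pytest.mark.parametrize("rule", ALL_RULES, ids=RULE_IDS)
    @pytest.mark.parametrize("beta", [-0.7, 0.4])
    def test_matches_brute_force_on_small_trials(
        self, small_simulated_dataset, rule, beta
    ):
        ds = small_simulated_dataset
        try:
            engine = partial_loglik(ds, beta, rule)[0]
        except NonIdentifiableError:
            return
        assert engine == pytest.approx(
            brute_force_loglik(ds, beta, rule), abs=1e-10
        )

    @pytest.mark.parametrize("rule", ALL_RULES, ids=RULE_IDS)
    def test_score_and_information_match_finite_differences(
        self, small_simulated_dataset, rule
    ):
        ds = small_simulated_dataset
        rng = np.random.default_rng(8)
        for beta in rng.uniform(-1.5, 1.5, size=3):
            try:
                ll, score, info = partial_loglik(ds, beta, rule)
            except NonIdentifiableError:
                return
            fd_score, fd_info = numeric_derivatives(
                lambda b: partial_loglik(ds, b, rule)[0], float(beta)
            )
            assert score == pytest.approx(fd_score, rel=1e-6, abs=1e-8)
            assert info == pytest.approx(fd_info, rel=1e-4, abs=1e-6)

    def test_no_qualifying_events_is_explicit(self):
        ds = dataset([rec("a", 1, 0.0, 1.0), rec("b", 0, 0.0, 1.0)])
        with pytest.raises(NonIdentifiableError):
            partial_loglik(ds, 0.0, RiskSetRule(Regime.AG_COMPOSITE))

    def test_ag_on_restricted_equals_first_event_cox(self, simulated_trial):
        restricted = restrict_to_first_event(simulated_trial)
        for beta in (-0.9, 0.0, 0.55):
            ag = partial_loglik(restricted, beta, RiskSetRule(Regime.AG_COMPOSITE))
            cox = partial_loglik(
                restricted, beta, RiskSetRule(Regime.COX_FIRST_COMPOSITE)
            )
            assert ag == pytest.approx(cox, abs=1e-9)


class TestFit:
    def test_mirror_arms_give_zero_effect(self):
        # two arms that are exact mirror copies of each other
        records = []
        for arm, prefix in ((1, "t"), (0, "c")):
            records += [
                rec(f"{prefix}1", arm, 0.0, 0.5, 1, NONFATAL, 0),
                rec(f"{prefix}1", arm, 0.5, 2.0),
                rec(f"{prefix}2", arm, 0.0, 1.2, 1, FATAL, 0),
                rec(f"{prefix}3", arm, 0.0, 2.0),
            ]
        ds = dataset(records)
        res = fit(ds, RiskSetRule(Regime.AG_COMPOSITE))
        assert res.converged
        assert res.estimates["composite"] == pytest.approx(0.0, abs=1e-10)

    @pytest.mark.parametrize("rule", ALL_RULES, ids=RULE_IDS)
    def test_estimate_matches_brute_force_maximizer(self, toy_dataset, rule):
        res = fit(toy_dataset, rule)
        if not res.estimates:
            return
        oracle = brute_force_fit(toy_dataset, rule)
        assert res.estimates[rule.component] == pytest.approx(oracle, abs=1e-6)

    def test_consistency_on_large_trial(self):
        ds = simulate_trial(SimConfig(n_subjects=20_000, seed=17))
        res = fit(ds, RiskSetRule(Regime.AG_COMPOSITE))
        beta, se = res.estimates["composite"], res.se["composite"]
        assert res.converged
        assert abs(beta - math.log(0.75)) < 3 * se

    def test_monotone_likelihood_is_flagged_not_estimated(self):
        ds = dataset(
            [
                rec("c1", 0, 0.0, 0.4, 1, FATAL, 0),
                rec("c2", 0, 0.0, 1.1, 1, FATAL, 0),
                rec("t1", 1, 0.0, 2.0),
                rec("t2", 1, 0.0, 2.0),
            ]
        )
        res = fit(ds, RiskSetRule(Regime.AG_COMPOSITE))
        assert not res.converged
        assert res.estimates == {}
        assert "monotone" in res.problems["composite"]

    @pytest.mark.parametrize("rule", ALL_RULES, ids=RULE_IDS)
    def test_time_scaling_invariance(self, rule):
        """The partial likelihood depends only on event ordering and risk-set
        membership, so rescaling all times leaves every estimate unchanged."""
        ds = simulate_trial(SimConfig(n_subjects=120, lambda1=0.6, seed=1234))
        scale = 3.7
        scaled = dataset(
            [
                dataclasses.replace(r, start=r.start * scale, stop=r.stop * scale)
                for r in ds.records
            ],
            study=2.0 * scale,
        )
        a = fit(ds, rule)
        b = fit(scaled, rule)
        assert a.estimates.keys() == b.estimates.keys()
        assert a.estimates  # this trial has events of both types in both arms
        for comp in a.estimates:
            assert a.estimates[comp] == pytest.approx(b.estimates[comp], abs=1e-10)

    def test_loglik_never_below_null(self, small_simulated_dataset):
        ds = small_simulated_dataset
        for rule in ALL_RULES:
            res = fit(ds, rule)
            if not res.estimates:
                continue
            null_ll = partial_loglik(ds, 0.0, rule)[0]
            assert res.loglik >= null_ll - 1e-12


class TestMultistate:
    def test_factorizes_into_component_fits(self, simulated_trial):
        joint = fit_multistate(simulated_trial)
        ll_sum = 0.0
        for comp in (FATAL, NONFATAL):
            single = fit(simulated_trial, RiskSetRule(Regime.MS_PER_COMPONENT, comp))
            assert joint.estimates[comp] == pytest.approx(
                single.estimates[comp], abs=1e-10
            )
            assert joint.se[comp] == pytest.approx(single.se[comp], abs=1e-10)
            ll_sum += single.loglik
        assert joint.loglik == pytest.approx(ll_sum, abs=1e-9)

    def test_component_without_events_flagged_other_returned(self):
        ds = dataset(
            [
                rec("c1", 0, 0.0, 0.4, 1, NONFATAL, 0),
                rec("c1", 0, 0.4, 2.0),
                rec("t1", 1, 0.0, 0.9, 1, NONFATAL, 0),
                rec("t1", 1, 0.9, 2.0),
            ]
        )
        res = fit_multistate(ds)
        assert FATAL not in res.estimates
        assert "non-identifiable" in res.problems[FATAL]
        assert NONFATAL in res.estimates

    def test_common_effect_constraint_is_nested(self, simulated_trial):
        """The AG composite fit constrains beta1 = beta2, so its maximized
        likelihood cannot exceed the unconstrained multi-state sum."""
        ag = fit(simulated_trial, RiskSetRule(Regime.AG_COMPOSITE))
        ms = fit_multistate(simulated_trial)
        assert ag.loglik <= ms.loglik + 1e-9


class TestWald:
    def test_null_estimate(self):
        from cetrials.pl_engine import FitResult

        res = FitResult({"composite": 0.0}, {"composite": 0.2}, -1.0, 3, True, {"composite": 10})
        z, p, reject = wald_test(res, "composite")
        assert (z, p, reject) == (0.0, pytest.approx(1.0), False)

    def test_boundary_z(self):
        from cetrials.pl_engine import FitResult

        res = FitResult({"composite": 1.96}, {"composite": 1.0}, -1.0, 3, True, {"composite": 10})
        _, p, _ = wald_test(res, "composite")
        assert p == pytest.approx(0.05, abs=0.001)

    def test_normal_tail(self):
        from cetrials.pl_engine import FitResult

        res = FitResult({"composite": -0.3}, {"composite": 0.1}, -1.0, 3, True, {"composite": 10})
        z, p, reject = wald_test(res, "composite", alpha=0.05)
        assert z == pytest.approx(-3.0)
        assert p == pytest.approx(0.0027, abs=1e-4)
        assert reject

    def test_requires_converged_fit(self):
        from cetrials.pl_engine import FitResult

        res = FitResult({}, {}, math.nan, 0, False, {"composite": 0}, {"composite": "x"})
        with pytest.raises(ValueError):
            wald_test(res, "composite")


def test_lifelines_cross_check_first_event(simulated_trial):
    """Independent route: lifelines' Cox fit on the first-event view must agree
    with the engine (no ties, so Efron and Breslow coincide)."""
    lifelines = pytest.importorskip("lifelines")
    restricted = restrict_to_first_event(simulated_trial)
    frame = restricted.to_frame()[["stop", "event", "treatment"]]
    cph = lifelines.CoxPHFitter()
    cph.fit(frame, duration_col="stop", event_col="event")
    res = fit(restricted, RiskSetRule(Regime.COX_FIRST_COMPOSITE))
    assert res.estimates["composite"] == pytest.approx(
        float(cph.params_["treatment"]), abs=1e-5
    )
    assert res.se["composite"] == pytest.approx(
        float(cph.standard_errors_["treatment"]), rel=1e-4
    )


def test_lifelines_cross_check_andersen_gill(simulated_trial):
    """Independent route for the recurrent-event model: lifelines'
    counting-process Cox fit (start/stop format) must agree with the engine."""
    lifelines = pytest.importorskip("lifelines")
    frame = simulated_trial.to_frame()
    frame["id"] = frame["subject_id"]
    ctv = lifelines.CoxTimeVaryingFitter()
    ctv.fit(
        frame[["id", "start", "stop", "event", "treatment"]],
        id_col="id",
        start_col="start",
        stop_col="stop",
        event_col="event",
    )
    res = fit(simulated_trial, RiskSetRule(Regime.AG_COMPOSITE))
    assert res.estimates["composite"] == pytest.approx(
        float(ctv.params_["treatment"]), abs=1e-5
    )
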