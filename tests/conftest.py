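import pytest

from cetrials.simulator import SimConfig, simulate_trial
from cetrials.trial_data import (
    FATAL,
    NONFATAL,
    EpisodeRecord,
    TrialDataset,
)


def rec(sid, x, start, stop, event=0, etype=None, k=0):
    return EpisodeRecord(sid, x, start, stop, event, etype, k)


def dataset(records, accrual=1.0, study=2.0, provenance="fixture"):
    return TrialDataset(
        records=tuple(records),
        n_subjects=len({r.subject_id for r in records}),
        accrual_years=accrual,
        study_years=study,
        provenance=provenance,
    )


@pytest.fixture
def toy_dataset():
    """Three subjects: a treated subject with recurrent non-fatal events at
    0.5 and 1.0, a control subject with one non-fatal event at 0.7 followed by
    a fatal event at 1.4, and an event-free control censored at 2.0."""
    return dataset(
        [
            rec("t1", 1, 0.0, 0.5, 1, NONFATAL, 0),
            rec("t1", 1, 0.5, 1.0, 1, NONFATAL, 1),
            rec("t1", 1, 1.0, 2.0, 0, None, 2),
            rec("c1", 0, 0.0, 0.7, 1, NONFATAL, 0),
            rec("c1", 0, 0.7, 1.4, 1, FATAL, 1),
            rec("c2", 0, 0.0, 2.0, 0, None, 0),
        ]
    )


@pytest.fixture(
    params=[0, 1, 2, 3], ids=["toy-a", "toy-b", "toy-c", "toy-d"]
)
def small_simulated_dataset(request):
    """Small simulated trials (<=6 subjects) with events of both types."""
    cfg = SimConfig(
        n_subjects=6,
        lambda1=0.6,
        lambda2=1.4,
        theta=[0.0, 0.0, 0.8, 0.8][request.param],
        rho=[1.0, 1.3, 1.0, 1.3][request.param],
        seed=(424200, request.param),
    )
    return simulate_trial(cfg)


@pytest.fixture
def simulated_trial():
    """One base-scenario trial (N=380, seed fixed)."""
    return simulate_trial(SimConfig(seed=20240917))
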