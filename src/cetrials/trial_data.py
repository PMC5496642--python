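"""Counting-process data model for recurrent non-fatal and terminal events.

A trial dataset is a sequence of per-subject episodes in the standard
(start, stop] counting-process layout: each record covers one at-risk
interval and ends either with an event (non-fatal or fatal) or with
administrative censoring.  Fatal events are terminal — nothing follows them.
The module provides the transformations between the three analysis views
used throughout the package ("all events", "first event only", "composite")
and delimited-text I/O.

Conventions
-----------
* Time is measured in years since the subject's own randomization; calendar
  staggering enters only through the censoring time.
* Intervals are half-open (start, stop] and events occur at ``stop``; a
  subject is at risk at time t on an interval iff ``start < t <= stop``.
* Censoring is encoded as ``event=0`` on the final record, never as a third
  event type.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable

import pandas as pd

#: Event-type labels.  ``COMPOSITE`` appears only after
#: :func:`merge_to_composite` has collapsed the component types.
NONFATAL = "nonfatal"
FATAL = "fatal"
COMPOSITE = "composite"

_EVENT_TYPES = (NONFATAL, FATAL, COMPOSITE)

#: Fixed column schema of the delimited episode format.
COLUMNS = (
    "subject_id",
    "treatment",
    "start",
    "stop",
    "event",
    "event_type",
    "prior_nonfatal_count",
)


@dataclass(frozen=True)
class EpisodeRecord:
    """One at-risk interval (start, stop] of one subject.

    Parameters
    ----------
    subject_id
        Opaque subject identifier.
    treatment
        Binary treatment indicator (1 = treated, 0 = control).
    start, stop
        Interval bounds in years since randomization, ``0 <= start < stop``.
    event
        1 if the interval ends with an event, 0 if with censoring.
    event_type
        ``"nonfatal"``, ``"fatal"`` or ``"composite"``; ``None`` when
        ``event == 0``.
    prior_nonfatal_count
        Number of non-fatal events experienced strictly before ``start``.
    """

    subject_id: str
    treatment: int
    start: float
    stop: float
    event: int
    event_type: str | None
    prior_nonfatal_count: int


@dataclass
class TrialDataset:
    """An ordered collection of episode records plus trial metadata.

    ``accrual_years``/``study_years`` may be ``None`` for data of unknown
    design (e.g. read from a file without metadata); the administrative
    censoring bound is then not checked.
    """

    records: tuple[EpisodeRecord, ...]
    n_subjects: int
    accrual_years: float | None = None
    study_years: float | None = None
    provenance: str = ""

    def __post_init__(self) -> None:
        self.records = tuple(self.records)

    def by_subject(self) -> dict[str, list[EpisodeRecord]]:
        """Records grouped by subject, preserving within-subject order."""
        groups: dict[str, list[EpisodeRecord]] = {}
        for rec in self.records:
            groups.setdefault(rec.subject_id, []).append(rec)
        return groups

    def to_frame(self) -> pd.DataFrame:
        """Render the records as a DataFrame with the fixed column schema."""
        return pd.DataFrame(
            [
                (
                    r.subject_id,
                    r.treatment,
                    r.start,
                    r.stop,
                    r.event,
                    r.event_type if r.event else None,
                    r.prior_nonfatal_count,
                )
                for r in self.records
            ],
            columns=list(COLUMNS),
        )


def _dataset_from_records(
    records: Iterable[EpisodeRecord],
    accrual_years: float | None,
    study_years: float | None,
    provenance: str,
) -> TrialDataset:
    recs = tuple(records)
    n = len({r.subject_id for r in recs})
    return TrialDataset(recs, n, accrual_years, study_years, provenance)


def validate(dataset: TrialDataset) -> list[str]:
    """Check every data-model invariant; return a report of violations.

    Returns an empty list iff the dataset is valid.  Each violation names
    the offending subject and the broken rule; nothing is raised.
    """
    report: list[str] = []
    groups = dataset.by_subject()
    if dataset.n_subjects != len(groups):
        report.append(
            f"n_subjects={dataset.n_subjects} but records cover "
            f"{len(groups)} distinct subjects"
        )
    for sid, recs in groups.items():
        if recs[0].start != 0:
            report.append(f"subject {sid}: first record must start at 0")
        prev: EpisodeRecord | None = None
        for rec in recs:
            if not rec.start < rec.stop:
                report.append(
                    f"subject {sid}: interval ({rec.start}, {rec.stop}] "
                    "must satisfy start < stop"
                )
            if rec.event not in (0, 1):
                report.append(f"subject {sid}: event must be 0 or 1")
            if rec.event and rec.event_type not in _EVENT_TYPES:
                report.append(
                    f"subject {sid}: event_type {rec.event_type!r} unknown"
                )
            if prev is not None:
                if prev.event == 1 and prev.event_type == FATAL:
                    report.append(
                        f"subject {sid}: fatal event must be terminal"
                    )
                if rec.start != prev.stop:
                    report.append(
                        f"subject {sid}: records must be contiguous "
                        f"({prev.stop} != {rec.start})"
                    )
                # only non-fatal (or merged composite) events continue the
                # record sequence, and each bumps the prior-event count
                inc = 1 if (prev.event == 1 and prev.event_type != FATAL) else 0
                if rec.prior_nonfatal_count != prev.prior_nonfatal_count + inc:
                    report.append(
                        f"subject {sid}: prior_nonfatal_count must increase "
                        f"by {inc} across the boundary at t={rec.start}"
                    )
            prev = rec
        # a last record ending in a non-fatal event is legal: it is how the
        # first-event-restricted view truncates follow-up at the first event
        last = recs[-1]
        if last.event == 0 and last.event_type is not None:
            report.append(
                f"subject {sid}: censored record must not carry an event_type"
            )
        if dataset.study_years is not None:
            for rec in recs:
                if rec.stop > dataset.study_years + 1e-12:
                    report.append(
                        f"subject {sid}: stop {rec.stop} exceeds "
                        f"study duration {dataset.study_years}"
                    )
    return report


def _require_valid(dataset: TrialDataset) -> None:
    report = validate(dataset)
    if report:
        raise ValueError(
            "invalid TrialDataset: " + "; ".join(report[:5])
            + ("; ..." if len(report) > 5 else "")
        )


def restrict_to_first_event(dataset: TrialDataset) -> TrialDataset:
    """Keep only each subject's first episode (time to first event or censoring).

    The retained record keeps its event indicator and type, so a first-event
    analysis of the result sees exactly the first composite endpoint (or
    censoring) per subject.  Idempotent.
    """
    _require_valid(dataset)
    firsts = [recs[0] for recs in dataset.by_subject().values()]
    return _dataset_from_records(
        firsts,
        dataset.accrual_years,
        dataset.study_years,
        dataset.provenance + " | restricted to first event",
    )


def merge_to_composite(dataset: TrialDataset) -> TrialDataset:
    """Collapse the event types into a single composite label.

    The interval structure is untouched: same times, same event indicators,
    same per-subject record counts.  Fatal events remain terminal because
    the record sequences are unchanged.
    """
    _require_valid(dataset)
    merged = [
        replace(r, event_type=COMPOSITE) if r.event else r
        for r in dataset.records
    ]
    return _dataset_from_records(
        merged,
        dataset.accrual_years,
        dataset.study_years,
        dataset.provenance + " | merged to composite",
    )


def write_episodes(dataset: TrialDataset, path) -> None:
    """Write the dataset as comma-separated text with a header row."""
    # %.17g preserves float64 values exactly across the round-trip
    dataset.to_frame().to_csv(path, index=False, float_format="%.17g")


def read_episodes(
    path,
    accrual_years: float | None = None,
    study_years: float | None = None,
) -> TrialDataset:
    """Read a delimited episode table written by :func:`write_episodes`.

    Raises ``ValueError`` naming the offending column or row on schema
    errors, non-numeric times, or violated data-model invariants.
    """
    frame = pd.read_csv(path, dtype={"subject_id": str}, float_precision="round_trip")
    missing = [c for c in COLUMNS if c not in frame.columns]
    if missing:
        raise ValueError(f"missing columns: {', '.join(missing)}")
    records = []
    for idx, row in frame.iterrows():
        try:
            event = int(row["event"])
            rec = EpisodeRecord(
                subject_id=str(row["subject_id"]),
                treatment=int(row["treatment"]),
                start=float(row["start"]),
                stop=float(row["stop"]),
                event=event,
                event_type=(str(row["event_type"]) if event else None),
                prior_nonfatal_count=int(row["prior_nonfatal_count"]),
            )
        except (TypeError, ValueError) as exc:
            raise ValueError(f"row {idx}: {exc}") from exc
        if not rec.start < rec.stop:
            raise ValueError(
                f"row {idx}: start {rec.start} must be < stop {rec.stop}"
            )
        records.append(rec)
    dataset = _dataset_from_records(
        records, accrual_years, study_years, f"read from {path}"
    )
    report = validate(dataset)
    if report:
        raise ValueError("invalid episode file: " + "; ".join(report[:5]))
    return dataset
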