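"""Patient sequence datasets: JSONL read/write, filtering, alphabet.

A dataset is a collection of patient histories, each an ordered sequence
of (timestamp, diagnosis code) events.  Timestamps are used only to fix
the order of events, never as absolute covariates; simultaneous events
are serialised deterministically by a stable sort on the code string.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

from .codes import Level

__all__ = [
    "PatientHistory",
    "SequenceDataset",
    "read_dataset",
    "write_dataset",
    "filter_min_length",
    "convert_csv",
]

logger = logging.getLogger(__name__)


@dataclass
class PatientHistory:
    """One patient's ordered diagnosis sequence.

    ``events`` is a list of ``(time, code)`` pairs sorted by
    ``(time, code)`` with a stable sort; ``time`` may be an integer or an
    ISO date string (only its ordering is ever used).
    """

    patient_id: str
    events: list[tuple[object, str]]
    presorted: bool = field(default=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        if not self.presorted:
            self.events = sorted(self.events, key=lambda e: (e[0], e[1]))

    @property
    def codes(self) -> tuple[str, ...]:
        return tuple(c for _, c in self.events)

    @property
    def n_h(self) -> int:
        """Length of the medical history (number of recorded events)."""
        return len(self.events)

    def with_codes(self, codes) -> "PatientHistory":
        """Same timestamps/order, new code per slot (projection, shuffling)."""
        codes = list(codes)
        if len(codes) != len(self.events):
            raise ValueError("code list length must match event count")
        events = [(t, c) for (t, _), c in zip(self.events, codes)]
        return PatientHistory(self.patient_id, events, presorted=True)


@dataclass
class SequenceDataset:
    """A cohort of histories sharing one alphabet level."""

    histories: list[PatientHistory]
    level: Level = Level.FULL
    alphabet: frozenset[str] = field(init=False)

    def __post_init__(self) -> None:
        self.alphabet = frozenset(c for ph in self.histories for c in ph.codes)

    def __len__(self) -> int:
        return len(self.histories)

    def __iter__(self):
        return iter(self.histories)

    @property
    def n_events(self) -> int:
        return sum(ph.n_h for ph in self.histories)

    def project(self, hierarchy, target: Level) -> "SequenceDataset":
        """Project every history to ``target`` level (see :mod:`ehrpred.codes`)."""
        from .codes import project_history

        if target is self.level:
            return self
        if self.level is not Level.FULL:
            raise ValueError("can only project a FULL-level dataset")
        return SequenceDataset(
            [project_history(hierarchy, ph, target) for ph in self.histories],
            level=target,
        )


def read_dataset(path, level: Level = Level.FULL) -> SequenceDataset:
    """Read a JSONL dataset, one patient per line.

    Each line is ``{"patient_id": str, "events": [{"t": ..., "code": str}, ...]}``.
    Events are re-sorted by ``(t, code)`` (stable).  Patients with an
    empty event list are skipped with a logged warning; a malformed line
    raises ``ValueError`` naming the line number.
    """
    histories: list[PatientHistory] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            try:
                obj = json.loads(line)
                pid = obj["patient_id"]
                events = [(e["t"], e["code"]) for e in obj["events"]]
            except (json.JSONDecodeError, KeyError, TypeError) as exc:
                raise ValueError(f"malformed dataset line {lineno}: {exc}") from exc
            if not events:
                logger.warning("patient %s has no events; skipped", pid)
                continue
            histories.append(PatientHistory(pid, events))
    return SequenceDataset(histories, level=level)


def write_dataset(d: SequenceDataset, path) -> None:
    """Write a dataset as JSONL (deterministic field order, UTF-8)."""
    with open(path, "w", encoding="utf-8") as fh:
        for ph in d.histories:
            obj = {
                "patient_id": ph.patient_id,
                "events": [{"t": t, "code": c} for t, c in ph.events],
            }
            fh.write(json.dumps(obj, ensure_ascii=False, sort_keys=False) + "\n")


def filter_min_length(d: SequenceDataset, m: int) -> SequenceDataset:
    """Keep only histories with at least ``m`` events; recompute the alphabet."""
    if m < 1:
        raise ValueError("minimum length must be >= 1")
    return SequenceDataset([ph for ph in d.histories if ph.n_h >= m], level=d.level)


def convert_csv(csv_path, jsonl_path) -> SequenceDataset:
    """Convert a long-format CSV ``patient_id,t,code`` into dataset JSONL."""
    import csv as _csv

    by_patient: dict[str, list[tuple[object, str]]] = {}
    order: list[str] = []
    with open(csv_path, encoding="utf-8", newline="") as fh:
        reader = _csv.DictReader(fh)
        for row in reader:
            pid = row["patient_id"]
            if pid not in by_patient:
                by_patient[pid] = []
                order.append(pid)
            t: object = row["t"]
            try:
                t = int(t)  # keep integer timestamps comparable as integers
            except (TypeError, ValueError):
                pass
            by_patient[pid].append((t, row["code"]))
    d = SequenceDataset([PatientHistory(pid, by_patient[pid]) for pid in order])
    write_dataset(d, jsonl_path)
    return d
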