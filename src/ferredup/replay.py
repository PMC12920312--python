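"""Forward-in-time replay of duplication scenarios.

Event scripts regenerate an extant sequence from a short seed motif by
doubling, point mutation, segmental duplication and deletion — the
predictive counterpart of the retrodictive consensus analysis.  All
coordinates are 1-based and inclusive; MUTATE validates the residue it
replaces so that a mis-ordered or mis-transcribed script fails immediately.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

from .sequence_io import SequenceRecord


class ReplayError(ValueError):
    pass


@dataclass(frozen=True)
class DuplicationEvent:
    kind: str  # DOUBLE | MUTATE | SEGDUP | DELETE
    position: Optional[int] = None      # MUTATE
    from_residue: Optional[str] = None  # MUTATE
    to_residue: Optional[str] = None    # MUTATE
    start: Optional[int] = None         # SEGDUP / DELETE
    end: Optional[int] = None           # SEGDUP / DELETE
    insert_after: Optional[int] = None  # SEGDUP

    def __post_init__(self) -> None:
        if self.kind not in {"DOUBLE", "MUTATE", "SEGDUP", "DELETE"}:
            raise ReplayError(f"unknown event kind {self.kind!r}")


@dataclass(frozen=True)
class DuplicationScenario:
    seed_motif: str
    events: tuple[DuplicationEvent, ...]
    label: str = ""


def _apply(seq: str, ev: DuplicationEvent, index: int) -> str:
    L = len(seq)
    if ev.kind == "DOUBLE":
        return seq + seq
    if ev.kind == "MUTATE":
        if not (ev.position and 1 <= ev.position <= L):
            raise ReplayError(f"event {index}: MUTATE position {ev.position} outside 1..{L}")
        if seq[ev.position - 1] != ev.from_residue:
            raise ReplayError(
                f"event {index}: MUTATE expects {ev.from_residue!r} at "
                f"position {ev.position}, found {seq[ev.position - 1]!r}"
            )
        return seq[: ev.position - 1] + ev.to_residue + seq[ev.position :]
    if ev.kind == "SEGDUP":
        if not (ev.start and ev.end and 1 <= ev.start <= ev.end <= L):
            raise ReplayError(f"event {index}: SEGDUP range {ev.start}..{ev.end} outside 1..{L}")
        if ev.insert_after is None or not 0 <= ev.insert_after <= L:
            raise ReplayError(f"event {index}: SEGDUP insert_after {ev.insert_after} outside 0..{L}")
        segment = seq[ev.start - 1 : ev.end]
        return seq[: ev.insert_after] + segment + seq[ev.insert_after :]
    # DELETE
    if not (ev.start and ev.end and 1 <= ev.start <= ev.end <= L):
        raise ReplayError(f"event {index}: DELETE range {ev.start}..{ev.end} outside 1..{L}")
    return seq[: ev.start - 1] + seq[ev.end :]


def apply_events(
    scenario: DuplicationScenario, record_id: str = "replayed"
) -> tuple[SequenceRecord, list[tuple[DuplicationEvent, str]]]:
    """Apply the scenario's events in order; returns the final record and a
    per-step trace of (event, sequence after the event)."""
    seq = scenario.seed_motif
    trace: list[tuple[DuplicationEvent, str]] = []
    for index, ev in enumerate(scenario.events, 1):
        seq = _apply(seq, ev, index)
        trace.append((ev, seq))
    return SequenceRecord(id=record_id, residues=seq, description=scenario.label), trace


def tandem_duplicate(seq: SequenceRecord) -> SequenceRecord:
    """Concatenate a sequence with itself (one DOUBLE event)."""
    if len(seq) == 0:
        raise ValueError("cannot duplicate an empty sequence")
    return SequenceRecord(
        id=f"{seq.id}_x2", residues=seq.residues * 2, description=seq.description
    )


def read_events_tsv(path: str | Path) -> tuple[DuplicationEvent, ...]:
    """Read an event script from a TSV with columns kind, p1, p2, p3, from, to.

    Coordinate columns map as: MUTATE uses p1=position; SEGDUP uses
    p1=start, p2=end, p3=insert_after; DELETE uses p1=start, p2=end.
    """
    events: list[DuplicationEvent] = []
    with open(str(path)) as handle:
        for row in csv.DictReader(handle, delimiter="\t"):
            kind = row["kind"].strip()
            p1 = int(row["p1"]) if row.get("p1", "").strip() else None
            p2 = int(row["p2"]) if row.get("p2", "").strip() else None
            p3 = int(row["p3"]) if row.get("p3", "").strip() else None
            frm = row.get("from", "").strip() or None
            to = row.get("to", "").strip() or None
            if kind == "MUTATE":
                events.append(
                    DuplicationEvent(kind=kind, position=p1, from_residue=frm, to_residue=to)
                )
            elif kind == "SEGDUP":
                events.append(DuplicationEvent(kind=kind, start=p1, end=p2, insert_after=p3))
            elif kind == "DELETE":
                events.append(DuplicationEvent(kind=kind, start=p1, end=p2))
            else:
                events.append(DuplicationEvent(kind=kind))
    return tuple(events)


def load_replay_scenario() -> DuplicationScenario:
    """The packaged forward scenario: seed motif ADSG doubled into a
    27-residue proto-repeat (frame restart at position 15), mutated into the
    pre-duplication ancestor, tandem-duplicated with a one-residue junction
    duplication, and mutated into the extant 55-residue ferredoxin.

    The event list is a synthetic reconstruction: it is constrained to pass
    through the computed ancestral consensus and to end at the transcribed
    extant sequence, not copied from any published figure.
    """
    from .sequence_io import replay_events_path

    return DuplicationScenario(
        seed_motif="ADSG",
        events=read_events_tsv(replay_events_path()),
        label="ADSG doubling scenario (synthetic reconstruction)",
    )
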