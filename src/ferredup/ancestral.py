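"""Ancestral half-consensus, residue periodicities and motif reduction.

The retrodictive step of the duplication analysis: positions where the two
halves agree are taken as ancestral (SHARED); a configurable *rescue* residue
(serine by default) is admitted when it occurs in either half; everything
else is left undetermined and rendered as ``-``.  The consensus is then
mined for residues recurring at fixed periods and reduced against a short
repeating motif (the classic four-letter ADSG repeat).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from enum import Enum

from .sequence_io import AMINO_ACIDS
from .symmetry import HalfAlignment

PLACEHOLDER = "-"


class Provenance(str, Enum):
    SHARED = "SHARED"
    RESCUE = "RESCUE"
    UNDETERMINED = "UNDETERMINED"


@dataclass(frozen=True)
class AncestralConsensus:
    """Per-position reconstruction; ``residues`` uses '-' for undetermined."""

    residues: str
    provenance: tuple[Provenance, ...]
    rescue_set: frozenset[str] = frozenset({"S"})

    def __post_init__(self) -> None:
        if len(self.residues) != len(self.provenance):
            raise ValueError("residues and provenance lengths differ")

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def determined_positions(self) -> tuple[int, ...]:
        return tuple(
            i for i, p in enumerate(self.provenance, 1) if p != Provenance.UNDETERMINED
        )

    @property
    def shared_letter_count(self) -> int:
        """Number of distinct residue types at SHARED positions."""
        return len(
            {
                r
                for r, p in zip(self.residues, self.provenance)
                if p == Provenance.SHARED
            }
        )

    @classmethod
    def from_string(cls, residues: str) -> "AncestralConsensus":
        """Wrap a plain residue string ('-' allowed) as a consensus."""
        prov = tuple(
            Provenance.UNDETERMINED if r == PLACEHOLDER else Provenance.SHARED
            for r in residues
        )
        return cls(residues=residues, provenance=prov)


@dataclass(frozen=True)
class Periodicity:
    residue: str
    period: int
    phase: int  # 1-based position of the first supporting occurrence
    supporting_positions: tuple[int, ...]
    break_positions: tuple[int, ...]

    def segments(self) -> tuple[tuple[int, ...], ...]:
        """Supporting positions split into progressions at the breaks."""
        segs: list[list[int]] = [[]]
        breaks = iter(self.break_positions + (float("inf"),))
        cut = next(breaks)
        for pos in self.supporting_positions:
            while pos >= cut:
                segs.append([])
                cut = next(breaks)
            segs[-1].append(pos)
        return tuple(tuple(s) for s in segs)

    @property
    def longest_run(self) -> int:
        return max(len(s) for s in self.segments())


@dataclass(frozen=True)
class MotifReduction:
    motif: str
    frame: int
    conforming_positions: tuple[int, ...]
    nonconforming_positions: tuple[int, ...]

    def conforming_sequence(self, consensus: AncestralConsensus) -> str:
        return "".join(consensus.residues[i - 1] for i in self.conforming_positions)

    def nonconforming_sequence(self, consensus: AncestralConsensus) -> str:
        return "".join(consensus.residues[i - 1] for i in self.nonconforming_positions)


def reconstruct_ancestor(
    aln: HalfAlignment, rescue_set: frozenset[str] | set[str] = frozenset({"S"})
) -> AncestralConsensus:
    """Build the ancestral consensus, one position per alignment column.

    SHARED where both halves carry the identical residue ('X' never counts);
    RESCUE where a rescue residue occurs in either cell of a non-identical
    column; UNDETERMINED otherwise.  Swapping the halves gives the same
    consensus.
    """
    rescue = frozenset(rescue_set)
    residues: list[str] = []
    provenance: list[Provenance] = []
    for col in aln.columns:
        cells = [r for r in (col.res1, col.res2) if r is not None and r != "X"]
        if col.res1 is not None and col.res1 == col.res2 and col.res1 != "X":
            residues.append(col.res1)
            provenance.append(Provenance.SHARED)
            continue
        hit = sorted(r for r in cells if r in rescue)
        if hit:
            residues.append(hit[0])
            provenance.append(Provenance.RESCUE)
        else:
            residues.append(PLACEHOLDER)
            provenance.append(Provenance.UNDETERMINED)
    return AncestralConsensus(
        residues="".join(residues), provenance=tuple(provenance), rescue_set=rescue
    )


def _runs(positions: list[int], period: int) -> list[list[int]]:
    """Maximal stretches of consecutive occurrences spaced exactly ``period``."""
    runs: list[list[int]] = []
    current = [positions[0]]
    for prev, nxt in zip(positions, positions[1:]):
        if nxt - prev == period:
            current.append(nxt)
        else:
            runs.append(current)
            current = [nxt]
    runs.append(current)
    return runs


def detect_periodicity(
    consensus: AncestralConsensus, min_support: int = 3
) -> list[Periodicity]:
    """Detect residues recurring at a fixed period in the consensus.

    For each residue letter with at least ``min_support`` determined
    occurrences, the period (2..L/2) whose longest arithmetic progression of
    consecutive occurrences is largest wins; ties go to the smallest period,
    so a true period-3 signal is never reported as period 6.  A *break* is
    where the progression's phase shifts, reported as the position
    immediately after the last occurrence of the interrupted run.
    """
    if min_support < 3:
        raise ValueError("min_support must be >= 3")
    L = len(consensus)
    out: list[Periodicity] = []
    occ: dict[str, list[int]] = {}
    for i, (r, p) in enumerate(zip(consensus.residues, consensus.provenance), 1):
        if p != Provenance.UNDETERMINED and r in AMINO_ACIDS:
            occ.setdefault(r, []).append(i)
    for residue in sorted(occ):
        positions = occ[residue]
        if len(positions) < min_support:
            continue
        best_period, best_len = None, 1
        for period in range(2, max(2, L // 2) + 1):
            longest = max(len(run) for run in _runs(positions, period))
            if longest > best_len:
                best_period, best_len = period, longest
        if best_period is None:
            continue  # no progression of length >= 2 at any period
        runs = _runs(positions, best_period)
        breaks = tuple(run[-1] + 1 for run in runs[:-1])
        out.append(
            Periodicity(
                residue=residue,
                period=best_period,
                phase=positions[0],
                supporting_positions=tuple(positions),
                break_positions=breaks,
            )
        )
    return out


def reduce_to_motif(
    consensus: AncestralConsensus, motif: str, frame: int = 1
) -> MotifReduction:
    """Partition determined positions by conformity to a repeating motif.

    Position ``i`` conforms iff its residue equals
    ``motif[(i - frame) mod len(motif)]`` (1-based frame).
    """
    if not motif:
        raise ValueError("motif must be non-empty")
    conforming: list[int] = []
    nonconforming: list[int] = []
    for i in consensus.determined_positions:
        if consensus.residues[i - 1] == motif[(i - frame) % len(motif)]:
            conforming.append(i)
        else:
            nonconforming.append(i)
    return MotifReduction(
        motif=motif,
        frame=frame,
        conforming_positions=tuple(conforming),
        nonconforming_positions=tuple(nonconforming),
    )


def infer_motif(consensus: AncestralConsensus, k: int = 4) -> MotifReduction:
    """Infer the modal repeating motif of length ``k``.

    Positions are grouped by residue class modulo ``k``; each class emits its
    modal determined residue (ties alphabetical).  The frame offset
    maximising the total conforming count is chosen (ties toward frame 1).
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if len(consensus) < k:
        raise ValueError("consensus shorter than motif length")
    determined = consensus.determined_positions
    if not determined:
        raise ValueError("all consensus positions are undetermined")
    best: MotifReduction | None = None
    for frame in range(1, k + 1):
        letters = []
        for slot in range(k):
            members = [
                consensus.residues[i - 1]
                for i in determined
                if (i - frame) % k == slot
            ]
            if members:
                counts = Counter(members)
                top = max(counts.values())
                letters.append(sorted(r for r, c in counts.items() if c == top)[0])
            else:
                letters.append("A")  # empty class: arbitrary but deterministic
        red = reduce_to_motif(consensus, "".join(letters), frame=frame)
        if best is None or len(red.conforming_positions) > len(best.conforming_positions):
            best = red
    return best
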