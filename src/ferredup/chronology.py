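"""Evolutionary chronology of domain families and loop prototypes.

Domain families carry SCOP concise classification strings (ccs,
``class.fold.superfamily.family``) and relative ages as *node distances*
(nd, 0 = origin of proteins, 1 = the present).  A linear clock of folds
converts nd to absolute ages in billions of years (Gy); Venn groups (which
superkingdoms/viruses share a family) place families into time-ordered
evolutionary phases; loop prototypes inherit ages from the domain families
they map to, by default at the first transfer between structural scaffolds.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import NamedTuple, Optional

import numpy as np
import pandas as pd
import yaml

from .sequence_io import families_path, loops_path, phases_path

_VENN_LETTERS = "ABEV"
_CCS_RE = re.compile(r"^([a-z])\.(\d+)\.(\d+)(?:\.(\d+))?$")


class Ccs(NamedTuple):
    protein_class: str
    fold: int
    superfamily: int
    family: Optional[int]

    def __str__(self) -> str:
        parts = [self.protein_class, str(self.fold), str(self.superfamily)]
        if self.family is not None:
            parts.append(str(self.family))
        return ".".join(parts)


def parse_ccs(label: str) -> Ccs:
    """Parse a SCOP concise classification string, e.g. ``d.58.1.1``.

    Superfamily-level prefixes (``d.58.1``) are accepted with family absent.
    """
    if not label:
        raise ValueError("empty ccs label")
    m = _CCS_RE.match(label.strip())
    if not m:
        raise ValueError(f"malformed ccs label {label!r}")
    cls, fold, sf, fam = m.groups()
    return Ccs(cls, int(fold), int(sf), int(fam) if fam is not None else None)


def canonical_venn(group: str) -> str:
    letters = set(group.strip().upper())
    if not letters or not letters <= set(_VENN_LETTERS):
        raise ValueError(f"invalid Venn group {group!r}")
    return "".join(l for l in _VENN_LETTERS if l in letters)


@dataclass(frozen=True)
class DomainFamily:
    ccs: str
    name: str
    nd: float
    venn_group: Optional[str] = None  # sorted letters over {A,B,E,V}; None if unpublished

    def __post_init__(self) -> None:
        parse_ccs(self.ccs)
        if not 0.0 <= self.nd <= 1.0:
            raise ValueError(f"nd {self.nd} outside [0, 1]")
        if self.venn_group is not None:
            object.__setattr__(self, "venn_group", canonical_venn(self.venn_group))


class LoopMapping(NamedTuple):
    ccs: str
    start: Optional[int]
    end: Optional[int]
    structure: Optional[str]


@dataclass(frozen=True)
class LoopPrototype:
    """An ArchDB loop conformation class mapped to domain-family intervals."""

    id: str
    mappings: tuple[LoopMapping, ...]

    def __post_init__(self) -> None:
        tag = self.id.split(".")[0]
        if tag not in {"DS", "MCL"}:
            raise ValueError(f"loop id {self.id!r} must carry a DS or MCL tag")
        for m in self.mappings:
            if m.start is not None and m.end is not None and m.start > m.end:
                raise ValueError(f"interval {m.start}-{m.end} has start > end")


@dataclass(frozen=True)
class ClockModel:
    """Piecewise-linear nd -> Gy interpolation through calibration anchors."""

    anchors: tuple[tuple[float, float], ...] = ((0.0, 3.8), (1.0, 0.0))

    def __post_init__(self) -> None:
        nds = [a for a, _ in self.anchors]
        ages = [g for _, g in self.anchors]
        if len(self.anchors) < 2:
            raise ValueError("clock needs at least two anchors")
        if sorted(nds) != nds or min(nds) < 0 or max(nds) > 1:
            raise ValueError("anchor nds must be sorted within [0, 1]")
        if any(b >= a for a, b in zip(ages, ages[1:])):
            raise ValueError("ages must be strictly decreasing in nd")


def nd_to_gy(nd: float, clock: ClockModel | None = None) -> float:
    """Convert a node distance to an age in Gy under the clock of folds."""
    clock = clock or ClockModel()
    if not 0.0 <= nd <= 1.0:
        raise ValueError(f"nd {nd} outside [0, 1]")
    xs = np.array([a for a, _ in clock.anchors])
    ys = np.array([g for _, g in clock.anchors])
    return float(np.interp(nd, xs, ys))


@dataclass(frozen=True)
class Phase:
    label: str
    nd_min: float
    nd_max: float
    venn_groups: frozenset[str]


@dataclass(frozen=True)
class PhaseConfig:
    phases: tuple[Phase, ...]

    def __post_init__(self) -> None:
        edges = [(p.nd_min, p.nd_max) for p in self.phases]
        if edges[0][0] != 0.0 or edges[-1][1] != 1.0:
            raise ValueError("phase windows must cover [0, 1]")
        for (_, hi), (lo, _) in zip(edges, edges[1:]):
            if hi != lo:
                raise ValueError("phase windows must be contiguous and non-overlapping")


def load_phase_config(path: str | Path | None = None) -> PhaseConfig:
    text = Path(str(path)).read_text() if path else phases_path().read_text()
    raw = yaml.safe_load(text)
    phases = tuple(
        Phase(
            label=p["label"],
            nd_min=float(p["nd_min"]),
            nd_max=float(p["nd_max"]),
            venn_groups=frozenset(canonical_venn(g) for g in p["venn_groups"]),
        )
        for p in raw["phases"]
    )
    return PhaseConfig(phases=phases)


def assign_phase(family: DomainFamily, phases: PhaseConfig | None = None) -> str:
    """Phase label for a family's nd; warns when the family's Venn group is
    not admissible for that window."""
    config = phases or load_phase_config()
    for i, phase in enumerate(config.phases):
        last = i == len(config.phases) - 1
        if phase.nd_min <= family.nd < phase.nd_max or (last and family.nd == phase.nd_max):
            if family.venn_group and family.venn_group not in phase.venn_groups:
                warnings.warn(
                    f"family {family.ccs}: Venn group {family.venn_group} not "
                    f"admissible in {phase.label}",
                    stacklevel=2,
                )
            return phase.label
    raise ValueError(f"no phase window covers nd = {family.nd}")


def loop_age(
    prototype: LoopPrototype,
    families: dict[str, DomainFamily],
    rule: str = "first-transfer",
) -> float:
    """Age (nd) of a loop prototype from its mapped domain families.

    ``first-transfer`` (default): the second-smallest mapped nd — the age at
    which the loop first appears in a second structural scaffold.  ``oldest``:
    the smallest mapped nd.  A single mapping yields that nd with a warning
    under first-transfer.
    """
    nds = sorted(
        families[m.ccs].nd for m in prototype.mappings if m.ccs in families
    )
    if not nds:
        raise ValueError(f"loop {prototype.id}: no mapped family with a known nd")
    if rule == "oldest":
        return nds[0]
    if rule != "first-transfer":
        raise ValueError(f"unknown loop-age rule {rule!r}")
    if len(nds) == 1:
        warnings.warn(
            f"loop {prototype.id}: single mapping; first-transfer age equals its nd",
            stacklevel=2,
        )
        return nds[0]
    return nds[1]


def interval_to_half(start: int, end: int, domain_length: int) -> str:
    """Assign a residue interval to the N-half, C-half, or 'spanning'.

    The midpoint convention matches the half split: the first half ends at
    floor(L/2).
    """
    if not 1 <= start <= end <= domain_length:
        raise ValueError(f"interval {start}-{end} outside 1..{domain_length}")
    mid = domain_length // 2
    if end <= mid:
        return "N-half"
    if start > mid:
        return "C-half"
    return "spanning"


# ---------------------------------------------------------------------------
# Table loaders

def load_families(path: str | Path | None = None) -> dict[str, DomainFamily]:
    df = pd.read_csv(str(path) if path else str(families_path()), sep="\t", dtype=str)
    out: dict[str, DomainFamily] = {}
    for row in df.itertuples(index=False):
        venn = row.venn_group if isinstance(row.venn_group, str) and row.venn_group.strip() else None
        fam = DomainFamily(ccs=row.ccs, name=row.name, nd=float(row.nd), venn_group=venn)
        out[fam.ccs] = fam
    return out


def load_loops(path: str | Path | None = None) -> dict[str, LoopPrototype]:
    df = pd.read_csv(str(path) if path else str(loops_path()), sep="\t", dtype=str)
    grouped: dict[str, list[LoopMapping]] = {}
    for row in df.itertuples(index=False):
        def _num(v):
            return int(v) if isinstance(v, str) and v.strip() not in ("", "-") else None

        structure = row.structure if isinstance(row.structure, str) and row.structure.strip() else None
        grouped.setdefault(row.loop_id, []).append(
            LoopMapping(ccs=row.ccs, start=_num(row.start), end=_num(row.end), structure=structure)
        )
    return {
        loop_id: LoopPrototype(id=loop_id, mappings=tuple(maps))
        for loop_id, maps in grouped.items()
    }
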