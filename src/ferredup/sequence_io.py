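"""FASTA input/output, sequence validation, and packaged fixture loaders.

Residue positions are addressed 1-based throughout the package, matching the
convention of the classic ferredoxin literature.  The packaged fixtures hold
the 55-residue mature 2[4Fe-4S] ferredoxin of *Clostridium pasteurianum*
together with hand-entered companion tables (half-to-half residue pairing,
forward-replay event script, domain-family chronology, loop-prototype
mappings).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioSeqRecord

#: The 20 canonical amino-acid one-letter codes.
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

#: Letters accepted on input; 'X' marks an unknown residue and is never
#: counted as a coincidence nor admitted into a consensus.
ALLOWED_LETTERS = frozenset(AMINO_ACIDS + "X")


class SequenceValidationError(ValueError):
    """A sequence contains a letter outside the amino-acid alphabet."""


@dataclass(frozen=True)
class SequenceRecord:
    """A validated protein sequence with 1-based residue addressing."""

    id: str
    residues: str
    description: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "residues", self.residues.upper())
        for pos, letter in enumerate(self.residues, start=1):
            if letter not in ALLOWED_LETTERS:
                raise SequenceValidationError(
                    f"record {self.id!r}: invalid residue {letter!r} at position {pos}"
                )

    @property
    def length(self) -> int:
        return len(self.residues)

    def __len__(self) -> int:
        return len(self.residues)

    def residue(self, pos: int) -> str:
        """Residue at 1-based position ``pos``."""
        if not 1 <= pos <= len(self.residues):
            raise IndexError(f"position {pos} outside 1..{len(self.residues)}")
        return self.residues[pos - 1]


def read_fasta(path: str | Path) -> list[SequenceRecord]:
    """Read a FASTA file into validated :class:`SequenceRecord` objects.

    Order is preserved; residues are uppercased.  Raises ``FileNotFoundError``
    for a missing file, :class:`SequenceValidationError` naming the record and
    position for a non-amino-acid letter, and ``ValueError`` for an empty file.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    records = [
        SequenceRecord(id=r.id, residues=str(r.seq), description=r.description)
        for r in SeqIO.parse(str(path), "fasta")
    ]
    if not records:
        raise ValueError(f"no FASTA entries found in {path}")
    return records


def write_fasta(records: list[SequenceRecord], path: str | Path, width: int = 60) -> None:
    """Write records as FASTA, wrapping sequence lines at ``width`` columns."""
    bio = [
        _BioSeqRecord(Seq(r.residues), id=r.id, description=r.description)
        for r in records
    ]
    with open(path, "w") as handle:
        writer = SeqIO.FastaIO.FastaWriter(handle, wrap=width)
        writer.write_file(bio)


# ---------------------------------------------------------------------------
# Packaged fixtures

def _data_path(name: str):
    return resources.files("ferredup").joinpath("data", name)


def load_ferredoxin() -> SequenceRecord:
    """The mature *C. pasteurianum* ferredoxin (55 residues).

    Transcribed once into a versioned fixture; the transcription is
    cross-checked by the symmetric 8-cysteine spacing signature
    (CX2CX2CX3C X18 CX2CX2CX3C) that the molecule is known to carry.
    """
    with resources.as_file(_data_path("cp_ferredoxin.fasta")) as p:
        return read_fasta(p)[0]


def load_half_pairing() -> list[tuple[int | None, int | None]]:
    """The prescribed half-to-half column pairing for the worked example.

    Synthetic reconstruction of the historical 1966 half alignment: the
    pairing anchors the four cysteines of each half on one another (a uniform
    offset of two positions of the second half relative to the first), which
    is the unique ungapped register that reproduces the published 12 residue
    coincidences drawn from 7 amino-acid types.  The trailing first-half
    residue is carried as a gap column so that the alignment spans the full
    27-residue half.
    """
    return read_pairing_tsv(_data_path("half_pairing.tsv"))


def read_pairing_tsv(path) -> list[tuple[int | None, int | None]]:
    """Read a two-column TSV of (pos1, pos2); '-' or blank marks a gap."""
    pairs: list[tuple[int | None, int | None]] = []
    text = Path(str(path)).read_text() if not hasattr(path, "read_text") else path.read_text()
    lines = [ln for ln in text.splitlines() if ln.strip()]
    for ln in lines[1:]:  # skip header
        a, b = ln.split("\t")[:2]
        p1 = None if a.strip() in ("-", "") else int(a)
        p2 = None if b.strip() in ("-", "") else int(b)
        if p1 is None and p2 is None:
            raise ValueError("pairing row with gaps on both sides")
        pairs.append((p1, p2))
    return pairs


def replay_events_path():
    """Path to the packaged forward-replay event script (synthetic
    reconstruction of the historical doubling-and-mutation scenario)."""
    return _data_path("replay_events.tsv")


def families_path():
    return _data_path("families.tsv")


def loops_path():
    return _data_path("loops.tsv")


def phases_path():
    return _data_path("phases.yaml")
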