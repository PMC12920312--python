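"""End-to-end retrodictive pipeline: split -> align -> count -> test ->
reconstruct -> periodicity -> motif -> signature, with a serialisable report."""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from typing import Any, Optional

from .ancestral import (
    AncestralConsensus,
    detect_periodicity,
    infer_motif,
    reconstruct_ancestor,
    reduce_to_motif,
)
from .sequence_io import SequenceRecord
from .significance import DEFAULT_SEED, coincidence_pvalue
from .symmetry import (
    align_halves,
    count_coincidences,
    extract_spacing_signature,
    signature_symmetry,
    split_halves,
)


@dataclass(frozen=True)
class PipelineConfig:
    split_index: Optional[int] = None
    mode: str = "ungapped-offset"
    pairing: Optional[tuple[tuple[Optional[int], Optional[int]], ...]] = None
    gap_penalty: float = 1.0
    anchor: str = "C"
    rescue_set: tuple[str, ...] = ("S",)
    motif: Optional[str] = "ADSG"
    motif_length: int = 4
    frame: int = 1
    min_support: int = 3
    n_permutations: int = 10_000
    seed: int = DEFAULT_SEED


class PipelineStageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r}: {cause}")
        self.stage = stage


@dataclass
class PipelineReport:
    record_id: str
    config: dict[str, Any]
    split: dict[str, Any]
    alignment: dict[str, Any]
    coincidences: dict[str, Any]
    significance: dict[str, Any]
    ancestor: dict[str, Any]
    periodicities: list[dict[str, Any]]
    motif_reduction: dict[str, Any]
    inferred_motif: dict[str, Any]
    signature: dict[str, Any]

    def to_json(self, **kwargs: Any) -> str:
        return json.dumps(asdict(self), sort_keys=True, **kwargs)

    @classmethod
    def from_json(cls, text: str) -> "PipelineReport":
        return cls(**json.loads(text))


def run_pipeline(record: SequenceRecord, config: PipelineConfig | None = None) -> PipelineReport:
    """Run the full retrodictive analysis on one sequence.

    Deterministic under a fixed config (the permutation seed is part of the
    config); every stage consumes the previous stage's output and stage
    failures are re-raised with the stage name attached.
    """
    config = config or PipelineConfig()

    def stage(name, fn):
        try:
            return fn()
        except Exception as exc:  # noqa: BLE001 - annotate and re-raise
            raise PipelineStageError(name, exc) from exc

    split = stage("split", lambda: split_halves(record, config.split_index))
    pairing = list(config.pairing) if config.pairing else None
    aln = stage(
        "align",
        lambda: align_halves(
            split, mode=config.mode, gap_penalty=config.gap_penalty, pairing=pairing
        ),
    )
    coin = stage("count", lambda: count_coincidences(aln))
    signif = stage(
        "test",
        lambda: coincidence_pvalue(
            aln, n_permutations=config.n_permutations, seed=config.seed
        ),
    )
    ancestor = stage(
        "reconstruct", lambda: reconstruct_ancestor(aln, frozenset(config.rescue_set))
    )
    periods = stage(
        "periodicity", lambda: detect_periodicity(ancestor, config.min_support)
    )
    motif = config.motif
    reduction = stage(
        "motif",
        lambda: reduce_to_motif(ancestor, motif, config.frame)
        if motif
        else infer_motif(ancestor, config.motif_length),
    )
    inferred = stage("motif", lambda: infer_motif(ancestor, config.motif_length))
    sig = stage("signature", lambda: extract_spacing_signature(record, config.anchor))
    verdict = stage("signature", lambda: signature_symmetry(sig, split))

    return PipelineReport(
        record_id=record.id,
        config=asdict(config),
        split={
            "split_index": split.split_index,
            "half1": split.half1,
            "half2": split.half2,
        },
        alignment={
            "mode": aln.mode,
            "n_columns": aln.n_columns,
            "columns": [list(c) for c in aln.columns],
        },
        coincidences={
            "n_aligned": coin.n_aligned,
            "k": coin.k,
            "shared_types": coin.shared_types,
            "identical_positions": list(coin.identical_positions),
        },
        significance={
            "p_value": signif.p_value,
            "method": signif.method,
            "observed_k": signif.observed_k,
            "expected_k": signif.expected_k,
            "n_permutations": signif.n_permutations,
            "seed": signif.seed,
        },
        ancestor={
            "residues": ancestor.residues,
            "provenance": [p.value for p in ancestor.provenance],
            "length": len(ancestor),
            "shared_letter_count": ancestor.shared_letter_count,
        },
        periodicities=[
            {
                "residue": p.residue,
                "period": p.period,
                "phase": p.phase,
                "supporting_positions": list(p.supporting_positions),
                "break_positions": list(p.break_positions),
            }
            for p in periods
        ],
        motif_reduction={
            "motif": reduction.motif,
            "frame": reduction.frame,
            "n_conforming": len(reduction.conforming_positions),
            "conforming_positions": list(reduction.conforming_positions),
            "nonconforming_positions": list(reduction.nonconforming_positions),
            "conforming_sequence": reduction.conforming_sequence(ancestor),
            "nonconforming_sequence": reduction.nonconforming_sequence(ancestor),
        },
        inferred_motif={
            "motif": inferred.motif,
            "frame": inferred.frame,
            "n_conforming": len(inferred.conforming_positions),
        },
        signature={
            "anchor": sig.anchor,
            "anchor_positions": list(sig.anchor_positions),
            "gaps": list(sig.gaps),
            "notation": str(sig),
            "symmetric": verdict.symmetric,
            "first_half_gaps": list(verdict.first_half_gaps),
            "second_half_gaps": list(verdict.second_half_gaps),
            "cross_gap": verdict.cross_gap,
            "reason": verdict.reason,
        },
    )
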