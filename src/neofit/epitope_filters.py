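"""Epitope admission rules applied before scoring or comparison.

Three nested affinity thresholds are used downstream (all strict ``<``):
a 10,000 nM noise filter on raw predictions, the 500 nM threshold for the
fitness model, and the 200 nM strong-binder cut used in burden analyses.
Neoepitopes whose mutations fall entirely on MHC anchor residues (position
2 and the C-terminal position) are excluded: those side chains are buried
in the binding groove and invisible to the TCR, so the mutation cannot be
recognized as non-self.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Collection, Mapping, Optional, Sequence, Union

from .alignment import AlignmentHit
from .seq_io import EpitopeRecord

#: Default anchor rule: position 2 plus the C-terminal residue, the
#: canonical 9-mer anchors generalized to lengths 8-11.
DEFAULT_ANCHOR_RULE: tuple[Union[int, str], ...] = (2, "C")


@dataclass(frozen=True)
class FilterConfig:
    """Thresholds for every admission rule (all affinities in nM, strict <)."""

    noise_ic50_max: float = 10_000.0
    fitness_ic50_max: float = 500.0
    strong_binder_ic50_max: float = 200.0
    anchor_positions: tuple[Union[int, str], ...] = DEFAULT_ANCHOR_RULE
    homology_evalue_max: float = 10.0

    def __post_init__(self) -> None:
        if not (
            0
            < self.strong_binder_ic50_max
            <= self.fitness_ic50_max
            <= self.noise_ic50_max
        ):
            raise ValueError(
                "require 0 < strong_binder <= fitness <= noise thresholds"
            )


def filter_by_affinity(
    records: Sequence[EpitopeRecord], threshold_nM: float
) -> list[EpitopeRecord]:
    """Keep records with ic50_mt strictly below the threshold, order preserved."""
    return [r for r in records if r.ic50_mt < threshold_nM]


def _anchor_set(
    rule: Collection[Union[int, str]], peptide_length: int
) -> set[int]:
    anchors: set[int] = set()
    for item in rule:
        if item == "C":
            anchors.add(peptide_length)
        else:
            anchors.add(int(item))
    return anchors


def exclude_anchor_mutants(
    records: Sequence[EpitopeRecord],
    anchor_rule: Optional[Collection[Union[int, str]]] = None,
) -> list[EpitopeRecord]:
    """Drop neoepitopes whose mutations all sit on anchor residues.

    A record is excluded only when it has at least one mutated position and
    every mutated position is an anchor; a record with any non-anchor
    mutation is kept.  Viral records (no wild type) pass through untouched.
    """
    rule = DEFAULT_ANCHOR_RULE if anchor_rule is None else anchor_rule
    kept = []
    for r in records:
        if r.peptide_wt is None:
            kept.append(r)
            continue
        anchors = _anchor_set(rule, len(r.peptide_mt))
        positions = set(r.mutated_positions)
        if positions and positions <= anchors:
            continue
        kept.append(r)
    return kept


def call_viral_like(
    patient_records: Mapping[str, Sequence[EpitopeRecord]],
    patient_hits: Mapping[str, Sequence[Sequence[AlignmentHit]]],
    config: Optional[FilterConfig] = None,
) -> dict[str, bool]:
    """Flag patients carrying a viral-like neoepitope.

    A patient is viral-like if at least one neoepitope both binds below the
    fitness threshold (ic50_mt < 500 nM by default) and has significant
    homology with a database epitope (a hit with evalue < 10 by default).
    ``patient_hits[p][i]`` holds the database hits of ``patient_records[p][i]``.
    """
    config = config or FilterConfig()
    calls = {}
    for patient_id, records in patient_records.items():
        hit_lists = patient_hits.get(patient_id, ())
        if len(hit_lists) != len(records):
            raise ValueError(
                f"patient {patient_id}: hits and records must align positionally"
            )
        viral_like = False
        for r, record_hits in zip(records, hit_lists):
            if r.ic50_mt >= config.fitness_ic50_max:
                continue
            if any(h.evalue < config.homology_evalue_max for h in record_hits):
                viral_like = True
                break
        calls[patient_id] = viral_like
    return calls
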