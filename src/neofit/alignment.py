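"""Protein local alignment of neoepitopes against a viral epitope database.

Each neoepitope is aligned with the Smith-Waterman algorithm (affine gaps,
BLOSUM62 by default) against every peptide in the database; the alignment
score |s,e| between neoepitope s and database epitope e feeds the TCR
recognition potential.  Hits are attached a BLAST-style bitscore and
Karlin-Altschul e-value so the database search can be thresholded the way a
protein BLAST would be:

    bitscore = (lambda * score - ln K) / ln 2
    evalue   = m * n * 2 ** (-bitscore)

with m the query length and n the total residue count of the database.
At the scale of short-peptide databases the exhaustive Smith-Waterman
search is exact, so no heuristic seeding step is needed.

Gap convention: a gap of length g is penalized ``gap_open + g * gap_extend``
(the BLAST convention; the default 11/1 is the protein-BLAST default).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from functools import lru_cache
from typing import Optional, Sequence, Union

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices

from .seq_io import AMINO_ACIDS, EpitopeDatabase, EpitopeRecord

#: Gapped BLOSUM62 Karlin-Altschul constants (protein BLAST, gaps 11/1).
DEFAULT_LAMBDA = 0.267
DEFAULT_K = 0.041


@lru_cache(maxsize=8)
def _load_matrix(name: str):
    return substitution_matrices.load(name)


@dataclass(frozen=True)
class AlignParams:
    """Scoring scheme for the Smith-Waterman peptide search.

    gap_open/gap_extend are positive penalties; a gap of length g costs
    ``gap_open + g * gap_extend``.  karlin_lambda and karlin_K parameterize
    the e-value attached to each hit.
    """

    matrix_name: str = "BLOSUM62"
    gap_open: int = 11
    gap_extend: int = 1
    karlin_lambda: float = DEFAULT_LAMBDA
    karlin_K: float = DEFAULT_K

    def __post_init__(self) -> None:
        if not self.gap_open >= self.gap_extend >= 0:
            raise ValueError("require gap_open >= gap_extend >= 0")
        if self.karlin_lambda <= 0 or self.karlin_K <= 0:
            raise ValueError("Karlin-Altschul constants must be positive")

    @property
    def matrix(self):
        return _load_matrix(self.matrix_name)

    def make_aligner(self) -> Align.PairwiseAligner:
        aligner = Align.PairwiseAligner()
        aligner.mode = "local"
        aligner.substitution_matrix = self.matrix
        # Biopython charges the open score on the first gapped column only.
        aligner.open_gap_score = -(self.gap_open + self.gap_extend)
        aligner.extend_gap_score = -self.gap_extend
        return aligner

    def bitscore(self, score: float) -> float:
        return (self.karlin_lambda * score - math.log(self.karlin_K)) / math.log(2)

    def evalue(self, score: float, query_len: int, db_residues: int) -> float:
        return query_len * db_residues * 2.0 ** (-self.bitscore(score))


@dataclass(frozen=True)
class AlignmentHit:
    """A scored local alignment between a query peptide and a database entry.

    ``score`` is the optimal Smith-Waterman score |s,e|; spans are 1-based
    inclusive intervals of the aligned region ((0, 0) when the best score
    is 0 and no alignment exists).
    """

    db_id: str
    score: int
    bitscore: float
    evalue: float
    query_span: tuple[int, int] = (0, 0)
    target_span: tuple[int, int] = (0, 0)


def _check_sequence(seq: str, label: str) -> None:
    bad = set(seq) - AMINO_ACIDS
    if bad:
        raise ValueError(f"{label}: non-standard residue(s) {sorted(bad)} in {seq!r}")


def smith_waterman(
    query: str, target: str, params: Optional[AlignParams] = None
) -> AlignmentHit:
    """Optimal local alignment of two peptides with affine gaps.

    Returns a hit whose bitscore/e-value are computed with m = len(query),
    n = len(target); :func:`search_db` recomputes the e-value against the
    whole database.  An empty sequence, or a pair with no positive-scoring
    alignment, yields a score-0 hit with empty spans.
    """
    params = params or AlignParams()
    _check_sequence(query, "query")
    _check_sequence(target, "target")
    if not query or not target:
        return AlignmentHit(
            db_id="",
            score=0,
            bitscore=params.bitscore(0.0),
            evalue=params.evalue(0.0, len(query), len(target)),
        )
    aligner = params.make_aligner()
    score = aligner.score(query, target)
    if score <= 0:
        return AlignmentHit(
            db_id="",
            score=0,
            bitscore=params.bitscore(0.0),
            evalue=params.evalue(0.0, len(query), len(target)),
        )
    alignment = next(iter(aligner.align(query, target)))
    q_blocks, t_blocks = alignment.aligned
    query_span = (int(q_blocks[0][0]) + 1, int(q_blocks[-1][1]))
    target_span = (int(t_blocks[0][0]) + 1, int(t_blocks[-1][1]))
    score = int(round(score))
    return AlignmentHit(
        db_id="",
        score=score,
        bitscore=params.bitscore(score),
        evalue=params.evalue(score, len(query), len(target)),
        query_span=query_span,
        target_span=target_span,
    )


def search_db(
    query: Union[str, EpitopeRecord],
    db: EpitopeDatabase,
    params: Optional[AlignParams] = None,
    evalue_max: float = 10.0,
    best_hit_only: bool = False,
) -> list[AlignmentHit]:
    """Exhaustive Smith-Waterman search of a neoepitope against the database.

    One hit per database entry passing ``evalue <= evalue_max``, sorted by
    descending score with ties broken by ascending db_id.  E-values use
    n = ``db.total_residues``.  ``best_hit_only`` keeps only the top hit
    (the alternative reading in which a single best match feeds the
    recognition potential).
    """
    params = params or AlignParams()
    peptide = query.peptide_mt if isinstance(query, EpitopeRecord) else query
    _check_sequence(peptide, "query")
    if not peptide:
        return []
    aligner = params.make_aligner()
    m = len(peptide)
    n = db.total_residues
    hits = []
    for db_id, target in db:
        score = aligner.score(peptide, target)
        score = max(0, int(round(score)))
        evalue = params.evalue(score, m, n)
        if evalue <= evalue_max:
            hits.append(
                AlignmentHit(
                    db_id=db_id,
                    score=score,
                    bitscore=params.bitscore(score),
                    evalue=evalue,
                )
            )
    hits.sort(key=lambda h: (-h.score, h.db_id))
    if best_hit_only and hits:
        return hits[:1]
    return hits


def randomize_peptides(
    records: Sequence[EpitopeRecord], seed: int
) -> list[EpitopeRecord]:
    """Negative-control records: residues permuted within each mutant peptide.

    Residue composition (hence length) is preserved per peptide and the
    permutation is deterministic under ``seed``.  The wild-type peptide is
    dropped — the controls exist only as alignment queries.
    """
    rng = np.random.default_rng(seed)
    out = []
    for record in records:
        letters = list(record.peptide_mt)
        rng.shuffle(letters)
        out.append(
            EpitopeRecord(
                patient_id=record.patient_id,
                peptide_mt="".join(letters),
                peptide_wt=None,
                hla_allele=record.hla_allele,
                ic50_mt=record.ic50_mt,
                source="shuffled",
            )
        )
    return out
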