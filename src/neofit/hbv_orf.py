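"""Contig filtering and ORF extraction for the viral antigen-calling stage.

Assembled contigs from reads that failed to map to the human reference are
admitted if they are sufficiently complex (Shannon entropy, to exclude
homopolymer artifacts), at least 100 bp long, and supported by at least 20
reads (both inclusive).  Surviving contigs are scanned in all six reading
frames for open reading frames (ATG .. stop) whose protein products are the
candidate viral antigens.  Assembly itself and external database
validation are upstream/downstream of this module; it consumes a contig
FASTA with ``support=<int>`` annotations.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .seq_io import ParseError

NUCLEOTIDES = frozenset("ACGTN")

#: Default thresholds.  The length/support cutoffs are inclusive
#: ("at least"); entropy below 1 bit flags near-homopolymer sequence
#: (a homopolymer scores 0; typical viral sequence is near 1.9 bits).
MIN_CONTIG_LEN = 100
MIN_READ_SUPPORT = 20
MIN_ENTROPY_BITS = 1.0

#: Minimal ORF protein length.  The 300-aa preset reproduces the stricter
#: excision rule used with long assembled contigs.
MIN_ORF_AA = 100
STRICT_ORF_AA = 300


def shannon_entropy(sequence: str) -> float:
    """Base-composition Shannon entropy in bits (max 2 for nucleotides).

    N's are excluded from the frequency counts; an empty or all-N sequence
    has no defined composition and raises.
    """
    counts = Counter(c for c in sequence.upper() if c in "ACGT")
    total = sum(counts.values())
    if total == 0:
        raise ValueError("sequence has no unambiguous bases")
    return -sum(
        (c / total) * math.log2(c / total) for c in counts.values()
    )


@dataclass(frozen=True)
class Contig:
    """An assembled nucleotide contig with its supporting read count."""

    id: str
    sequence: str
    read_support: int

    def __post_init__(self) -> None:
        bad = set(self.sequence.upper()) - NUCLEOTIDES
        if bad:
            raise ParseError(
                f"contig {self.id!r}: non-nucleotide character(s) {sorted(bad)}"
            )
        if self.read_support < 0:
            raise ParseError(f"contig {self.id!r}: negative read support")

    @property
    def entropy_bits(self) -> float:
        return shannon_entropy(self.sequence)

    def __len__(self) -> int:
        return len(self.sequence)


def read_contig_fasta(path: str | Path) -> list[Contig]:
    """Read contigs from FASTA; read support parsed from ``support=<int>``
    in the description line (0 when absent)."""
    contigs = []
    for record in SeqIO.parse(str(path), "fasta"):
        support = 0
        for token in record.description.split():
            if token.startswith("support="):
                support = int(token.split("=", 1)[1])
        contigs.append(
            Contig(id=record.id, sequence=str(record.seq).upper(), read_support=support)
        )
    if not contigs:
        raise ParseError(f"{path}: no contigs")
    return contigs


def write_contig_fasta(contigs: Sequence[Contig], path: str | Path) -> None:
    records = [
        SeqRecord(Seq(c.sequence), id=c.id, description=f"support={c.read_support}")
        for c in contigs
    ]
    SeqIO.write(records, str(path), "fasta")


def filter_contigs(
    contigs: Sequence[Contig],
    min_len: int = MIN_CONTIG_LEN,
    min_support: int = MIN_READ_SUPPORT,
    min_entropy: float = MIN_ENTROPY_BITS,
) -> list[Contig]:
    """Keep contigs meeting all three thresholds (all inclusive)."""
    return [
        c
        for c in contigs
        if len(c) >= min_len
        and c.read_support >= min_support
        and c.entropy_bits >= min_entropy
    ]


@dataclass(frozen=True)
class OrfCall:
    """One open reading frame on a contig.

    ``start``/``end`` are 1-based inclusive forward-strand coordinates of
    the full codon span including the stop codon; ``protein`` excludes the
    stop.  Frames +1/+2/+3 read the forward strand at offsets 0/1/2,
    -1/-2/-3 the reverse complement likewise.
    """

    contig_id: str
    frame: int
    start: int
    end: int
    protein: str


STOP_CODONS = {"TAA", "TAG", "TGA"}


def _scan_frame(seq: str, offset: int, min_aa: int) -> list[tuple[int, int, str]]:
    """ORFs (codon-index start, stop-codon index, protein) in one frame.

    Among nested ORFs ending at the same stop codon only the longest
    (first ATG) is reported.
    """
    n_codons = (len(seq) - offset) // 3
    orfs = []
    start: Optional[int] = None
    for i in range(n_codons):
        codon = seq[offset + 3 * i : offset + 3 * i + 3]
        if codon in STOP_CODONS:
            if start is not None:
                aa_len = i - start
                if aa_len >= min_aa:
                    sub = seq[offset + 3 * start : offset + 3 * i]
                    protein = str(Seq(sub).translate())
                    if "*" not in protein and "X" not in protein:
                        orfs.append((start, i, protein))
                start = None
        elif codon == "ATG" and start is None:
            start = i
    return orfs


def find_orfs(
    contig: Contig, min_aa: int = MIN_ORF_AA, strict: bool = False
) -> list[OrfCall]:
    """Scan all six frames of a contig for ORFs of at least ``min_aa`` codons.

    An ORF runs from an ATG to the next in-frame stop codon (required;
    truncated reading frames hanging off the contig end are not called).
    ``strict=True`` applies the 300-aa excision preset instead of
    ``min_aa``.  Reverse-strand calls are mapped back to forward-strand
    coordinates.
    """
    if strict:
        min_aa = STRICT_ORF_AA
    seq = contig.sequence.upper()
    length = len(seq)
    rc = str(Seq(seq).reverse_complement())
    calls = []
    for strand_seq, sign in ((seq, 1), (rc, -1)):
        for offset in range(3):
            for start_codon, stop_codon, protein in _scan_frame(
                strand_seq, offset, min_aa
            ):
                s = offset + 3 * start_codon + 1
                e = offset + 3 * (stop_codon + 1)
                if sign == -1:
                    s, e = length - e + 1, length - s + 1
                calls.append(
                    OrfCall(
                        contig_id=contig.id,
                        frame=sign * (offset + 1),
                        start=s,
                        end=e,
                        protein=protein,
                    )
                )
    calls.sort(key=lambda c: (-len(c.protein), c.start, c.frame))
    return calls


def write_protein_fasta(calls: Sequence[OrfCall], path: str | Path) -> None:
    """Write ORF proteins as FASTA, one record per call."""
    records = [
        SeqRecord(
            Seq(c.protein),
            id=f"{c.contig_id}|frame{c.frame:+d}|{c.start}-{c.end}",
            description="",
        )
        for c in calls
    ]
    SeqIO.write(records, str(path), "fasta")
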