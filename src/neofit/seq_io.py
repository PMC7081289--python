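"""Readers, writers and the record-level data model for every external table
and FASTA file the pipeline touches.

The pipeline consumes four kinds of input:

* a database of short viral epitope peptides (FASTA),
* per-patient neoepitope tables with mutant/wild-type peptides, the
  presenting HLA allele and predicted MHC-I binding affinities (ic50, nM),
* per-patient clinical/immune tables (survival time and event, tumor stage,
  tumor mutation burden, cytolytic activity, TIL burden and clonality), and
* MAF-like somatic mutation tables used to count tumor mutation burden.

All tables are plain tab-separated text with a header line.  Coordinates are
1-based inclusive throughout (MAF convention); peptide positions likewise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

#: The 20 standard amino acids; every peptide in the pipeline is restricted
#: to this alphabet.
AMINO_ACIDS = frozenset("ACDEFGHIKLMNPQRSTVWY")

#: Inclusive length bounds for HLA-I processed epitopes.
MIN_PEPTIDE_LEN = 8
MAX_PEPTIDE_LEN = 11


class ParseError(ValueError):
    """Raised when an input file cannot be parsed or fails validation."""


def _check_peptide(peptide: str, label: str) -> None:
    if not peptide:
        raise ParseError(f"{label}: empty peptide")
    bad = set(peptide) - AMINO_ACIDS
    if bad:
        raise ParseError(
            f"{label}: non-standard residue(s) {sorted(bad)} in peptide {peptide!r}"
        )


@dataclass(frozen=True)
class EpitopeDatabase:
    """An in-memory peptide database (IEDB-style viral epitopes).

    Entries are ``(id, peptide)`` pairs with unique ids and peptides over
    the 20 standard amino acids.  ``total_residues`` is the search-space
    size used by the Karlin-Altschul e-value.
    """

    entries: tuple[tuple[str, str], ...]

    def __post_init__(self) -> None:
        if not self.entries:
            raise ParseError("epitope database is empty")
        seen: set[str] = set()
        for rec_id, peptide in self.entries:
            if rec_id in seen:
                raise ParseError(f"duplicate database id {rec_id!r}")
            seen.add(rec_id)
            _check_peptide(peptide, f"database record {rec_id!r}")

    @property
    def total_residues(self) -> int:
        return sum(len(p) for _, p in self.entries)

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries)

    @property
    def ids(self) -> tuple[str, ...]:
        return tuple(i for i, _ in self.entries)

    @property
    def peptides(self) -> tuple[str, ...]:
        return tuple(p for _, p in self.entries)


def read_epitope_fasta(path: str | Path) -> EpitopeDatabase:
    """Read a peptide FASTA file into an :class:`EpitopeDatabase`.

    Raises :class:`ParseError` for an empty file, a file that does not start
    with a FASTA header, or any record containing a residue outside the 20
    standard amino acids (the error names the offending record).
    """
    path = Path(path)
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            if not line.strip():
                continue
            if not line.startswith(">"):
                raise ParseError(
                    f"{path}: line {lineno}: expected FASTA header, got {line.strip()!r}"
                )
            break
        else:
            raise ParseError(f"{path}: empty FASTA file")
    entries = []
    for record in SeqIO.parse(str(path), "fasta"):
        entries.append((record.id, str(record.seq).upper()))
    if not entries:
        raise ParseError(f"{path}: no FASTA records")
    return EpitopeDatabase(tuple(entries))


def write_epitope_fasta(db: EpitopeDatabase, path: str | Path) -> None:
    """Write the database back out as FASTA (inverse of :func:`read_epitope_fasta`)."""
    records = [
        SeqRecord(Seq(peptide), id=rec_id, description="") for rec_id, peptide in db
    ]
    SeqIO.write(records, str(path), "fasta")


def _diff_positions(a: str, b: str) -> list[int]:
    """1-based positions at which two equal-length strings differ."""
    return [i + 1 for i, (x, y) in enumerate(zip(a, b)) if x != y]


@dataclass
class EpitopeRecord:
    """One candidate epitope: the atom of the fitness model.

    For tumor neoepitopes ``peptide_wt``/``ic50_wt`` hold the unmutated
    counterpart; for viral epitopes they are ``None`` and ``source`` is
    ``"viral"``.  ``mutated_positions`` (1-based) is derived from the
    MT/WT comparison when not given explicitly.
    """

    patient_id: str
    peptide_mt: str
    peptide_wt: Optional[str]
    hla_allele: str
    ic50_mt: float
    ic50_wt: Optional[float] = None
    source: str = "neoepitope"
    mutated_positions: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        _check_peptide(self.peptide_mt, f"epitope for {self.patient_id}")
        n = len(self.peptide_mt)
        if not MIN_PEPTIDE_LEN <= n <= MAX_PEPTIDE_LEN:
            raise ParseError(
                f"epitope for {self.patient_id}: peptide length {n} outside "
                f"[{MIN_PEPTIDE_LEN}, {MAX_PEPTIDE_LEN}]: {self.peptide_mt!r}"
            )
        if not (self.ic50_mt > 0 and math.isfinite(self.ic50_mt)):
            raise ParseError(
                f"epitope for {self.patient_id}: ic50_mt must be a positive "
                f"number of nM, got {self.ic50_mt!r}"
            )
        if self.peptide_wt is not None:
            _check_peptide(self.peptide_wt, f"WT epitope for {self.patient_id}")
            if len(self.peptide_wt) != n:
                raise ParseError(
                    f"epitope for {self.patient_id}: MT/WT length mismatch "
                    f"({self.peptide_mt!r} vs {self.peptide_wt!r})"
                )
            if self.ic50_wt is None or not (
                self.ic50_wt > 0 and math.isfinite(self.ic50_wt)
            ):
                raise ParseError(
                    f"epitope for {self.patient_id}: ic50_wt must be a positive "
                    f"number of nM, got {self.ic50_wt!r}"
                )
            derived = _diff_positions(self.peptide_mt, self.peptide_wt)
            if not self.mutated_positions:
                self.mutated_positions = derived
            elif self.mutated_positions != derived:
                raise ParseError(
                    f"epitope for {self.patient_id}: mutated_positions "
                    f"{self.mutated_positions} inconsistent with MT/WT diff {derived}"
                )
        elif self.source == "neoepitope":
            # WT-less rows are viral epitopes unless tagged otherwise
            # (e.g. "shuffled" negative controls).
            self.source = "viral"


NEOEPITOPE_COLUMNS = (
    "patient_id",
    "peptide_mt",
    "peptide_wt",
    "hla_allele",
    "ic50_mt",
    "ic50_wt",
)


def read_neoepitope_table(path: str | Path) -> list[EpitopeRecord]:
    """Read a tab-separated neoepitope table into :class:`EpitopeRecord` rows.

    Viral rows are indicated by an empty ``peptide_wt``/``ic50_wt``.  Any
    validation failure is reported with the 1-based data row number.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in NEOEPITOPE_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing column(s) {missing}")
    records = []
    for i, row in enumerate(df.itertuples(index=False), start=1):
        wt = row.peptide_wt.strip() or None
        try:
            ic50_wt = float(row.ic50_wt) if str(row.ic50_wt).strip() else None
            records.append(
                EpitopeRecord(
                    patient_id=row.patient_id,
                    peptide_mt=row.peptide_mt.strip().upper(),
                    peptide_wt=wt.upper() if wt else None,
                    hla_allele=row.hla_allele,
                    ic50_mt=float(row.ic50_mt),
                    ic50_wt=ic50_wt,
                )
            )
        except (ParseError, ValueError) as exc:
            raise ParseError(f"{path}: row {i}: {exc}") from exc
    return records


def write_neoepitope_table(records: Sequence[EpitopeRecord], path: str | Path) -> None:
    rows = [
        {
            "patient_id": r.patient_id,
            "peptide_mt": r.peptide_mt,
            "peptide_wt": r.peptide_wt or "",
            "hla_allele": r.hla_allele,
            "ic50_mt": r.ic50_mt,
            "ic50_wt": r.ic50_wt if r.ic50_wt is not None else "",
        }
        for r in records
    ]
    pd.DataFrame(rows, columns=list(NEOEPITOPE_COLUMNS)).to_csv(
        path, sep="\t", index=False
    )


@dataclass
class PatientProfile:
    """Per-patient clinical and immune covariates.

    ``time`` is overall survival in days, ``event`` 1 for death and 0 for
    censoring.  ``immunogenicity`` is the maximal clonal immunogenicity
    score (missing until computed, or for patients with no qualifying
    neoepitope).
    """

    patient_id: str
    time: float
    event: int
    stage: int
    tmb: float
    cyt: float
    til_burden: float
    til_clonality: float
    immunogenicity: Optional[float] = None
    gzma_rpkm: Optional[float] = None
    prf1_rpkm: Optional[float] = None

    def __post_init__(self) -> None:
        if self.event not in (0, 1):
            raise ParseError(
                f"patient {self.patient_id}: event must be 0 or 1, got {self.event!r}"
            )
        if not (math.isfinite(self.time) and self.time >= 0):
            raise ParseError(
                f"patient {self.patient_id}: time must be finite and >= 0"
            )
        if not 0.0 <= self.til_clonality <= 1.0:
            raise ParseError(
                f"patient {self.patient_id}: til_clonality outside [0, 1]"
            )


PATIENT_COLUMNS = (
    "patient_id",
    "time",
    "event",
    "stage",
    "tmb",
    "cyt",
    "til_burden",
    "til_clonality",
    "immunogenicity",
)


def read_patient_table(path: str | Path) -> list[PatientProfile]:
    """Read a tab-separated clinical table; ``immunogenicity`` may be blank."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t")
    required = [c for c in PATIENT_COLUMNS if c != "immunogenicity"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing column(s) {missing}")
    profiles = []
    for i, row in df.iterrows():
        imm = row.get("immunogenicity")
        imm = None if imm is None or pd.isna(imm) else float(imm)
        try:
            profiles.append(
                PatientProfile(
                    patient_id=str(row["patient_id"]),
                    time=float(row["time"]),
                    event=int(row["event"]),
                    stage=int(row["stage"]),
                    tmb=float(row["tmb"]),
                    cyt=float(row["cyt"]),
                    til_burden=float(row["til_burden"]),
                    til_clonality=float(row["til_clonality"]),
                    immunogenicity=imm,
                    gzma_rpkm=float(row["gzma_rpkm"]) if "gzma_rpkm" in df.columns else None,
                    prf1_rpkm=float(row["prf1_rpkm"]) if "prf1_rpkm" in df.columns else None,
                )
            )
        except (ParseError, ValueError) as exc:
            raise ParseError(f"{path}: row {i + 1}: {exc}") from exc
    return profiles


def patients_frame(profiles: Iterable[PatientProfile]) -> pd.DataFrame:
    """Tabular view of patient profiles for the statistical stages."""
    return pd.DataFrame(
        [
            {
                "patient_id": p.patient_id,
                "time": p.time,
                "event": p.event,
                "stage": p.stage,
                "tmb": p.tmb,
                "cyt": p.cyt,
                "til_burden": p.til_burden,
                "til_clonality": p.til_clonality,
                "immunogenicity": p.immunogenicity,
            }
            for p in profiles
        ]
    )


def write_patient_table(profiles: Sequence[PatientProfile], path: str | Path) -> None:
    df = patients_frame(profiles)
    df["immunogenicity"] = df["immunogenicity"].fillna("")
    df.to_csv(path, sep="\t", index=False)


@dataclass(frozen=True)
class MutationRecord:
    """One somatic mutation call (MAF-style, 1-based coordinates)."""

    patient_id: str
    chrom: str
    pos: int
    ref: str
    alt: str
    variant_class: str = ""

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ParseError(f"mutation for {self.patient_id}: pos must be >= 1")


MUTATION_COLUMNS = ("patient_id", "chrom", "pos", "ref", "alt", "variant_class")


def read_mutation_table(path: str | Path) -> list[MutationRecord]:
    """Read a MAF-like tab-separated mutation table.

    Any tab-separated table containing the named columns is accepted;
    extra columns are ignored.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in MUTATION_COLUMNS[:5] if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing column(s) {missing}")
    has_class = "variant_class" in df.columns
    return [
        MutationRecord(
            patient_id=row.patient_id,
            chrom=row.chrom,
            pos=int(row.pos),
            ref=row.ref,
            alt=row.alt,
            variant_class=row.variant_class if has_class else "",
        )
        for row in df.itertuples(index=False)
    ]


def write_mutation_table(records: Sequence[MutationRecord], path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "patient_id": r.patient_id,
                "chrom": r.chrom,
                "pos": r.pos,
                "ref": r.ref,
                "alt": r.alt,
                "variant_class": r.variant_class,
            }
            for r in records
        ],
        columns=list(MUTATION_COLUMNS),
    ).to_csv(path, sep="\t", index=False)


def tmb_from_maf(
    records: Iterable[MutationRecord],
    patient_id: str,
    exclude_classes: Optional[set[str]] = None,
) -> int:
    """Tumor mutation burden: distinct somatic variants called for a patient.

    Identical (chrom, pos, ref, alt) rows — e.g. one MAF line per affected
    transcript — are counted once.  ``exclude_classes`` optionally drops
    variant classes (e.g. silent mutations) before counting; the default
    counts every called DNA mutation.
    """
    variants = {
        (r.chrom, r.pos, r.ref, r.alt)
        for r in records
        if r.patient_id == patient_id
        and (exclude_classes is None or r.variant_class not in exclude_classes)
    }
    return len(variants)
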