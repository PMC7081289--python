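"""Synthetic cohorts with the statistical structure the pipeline assumes.

The generator emulates every input of the analysis — a viral epitope
database, per-patient neoepitope and viral-epitope tables with log-normal
ic50 distributions, MAF-like mutation tables, clinical tables with
proportional-hazards survival times, and viral-like contigs with planted
ORFs — so that every stage can be exercised and calibrated without any
protected data:

* neoepitope and viral ic50 are log-normal with separate (mu, sigma) on
  ln(nM); setting mu_neo < mu_viral plants the "neoepitopes bind better"
  dominance direction;
* a configurable fraction of neoepitopes are single-substitution copies of
  database entries, controlling viral-likeness and recognition potential;
* survival times are exponential with hazard lambda0 * exp(beta . z) on
  z-scored covariates (CYT, TMB, immunogenicity, stage), with independent
  uniform censoring tuned to the target censoring rate;
* CYT and TIL burden are tied by a Gaussian copula hitting a planted
  Spearman correlation exactly (Pearson parameter 2 sin(pi rho / 6));
* contigs carry known ORFs plus homopolymer / short / low-support decoys.

Every generator is deterministic under its seed and records its parameters
in the emitted metadata.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .hbv_orf import Contig, write_contig_fasta
from .seq_io import (
    EpitopeDatabase,
    EpitopeRecord,
    MutationRecord,
    PatientProfile,
    patients_frame,
    write_epitope_fasta,
    write_mutation_table,
    write_neoepitope_table,
)

#: Background amino-acid composition (approximate vertebrate protein
#: frequencies) used for random peptides.
AA_ORDER = "ACDEFGHIKLMNPQRSTVWY"
AA_FREQS = np.array(
    [
        0.074, 0.025, 0.054, 0.054, 0.047, 0.074, 0.026, 0.068, 0.058, 0.099,
        0.025, 0.045, 0.039, 0.034, 0.052, 0.057, 0.051, 0.073, 0.013, 0.032,
    ]
)
AA_FREQS = AA_FREQS / AA_FREQS.sum()

HLA_ALLELES = (
    "HLA-A*02:01",
    "HLA-A*01:01",
    "HLA-B*07:02",
    "HLA-B*08:01",
    "HLA-C*07:01",
)

CHROMS = tuple(str(c) for c in range(1, 23))
VARIANT_CLASSES = (
    "Missense_Mutation",
    "Silent",
    "Nonsense_Mutation",
    "Frame_Shift_Del",
    "Splice_Site",
)


@dataclass(frozen=True)
class CohortConfig:
    """Parameters of a synthetic cohort.

    Affinity parameters are (mu, sigma) of ln(ic50 in nM); the defaults
    put the neoepitope distribution one log-unit below the viral one,
    the dominance direction observed in HBV-infected liver tumors.
    Hazard coefficients are per-SD log hazard ratios on the z-scored
    cohort covariates; the defaults encode a protective cytolytic-activity
    effect, a weak protective TMB effect, no immunogenicity effect, and a
    deleterious stage effect — the melanoma-like regime.
    """

    n_patients: int = 300
    epitopes_per_patient: float = 30.0
    viral_per_patient: float = 20.0
    ic50_neo_lognormal: tuple[float, float] = (6.0, 1.5)
    ic50_viral_lognormal: tuple[float, float] = (7.0, 1.5)
    db_size: int = 200
    planted_neighbor_fraction: float = 0.3
    anchor_mutant_fraction: float = 0.2
    baseline_hazard: float = 1.0 / 1500.0  # per day
    beta_cyt: float = -0.8
    beta_tmb: float = -0.2
    beta_imm: float = 0.0
    beta_stage: float = 0.3
    censor_rate: float = 0.3
    planted_rho: float = 0.5
    tmb_lognormal: tuple[float, float] = (math.log(120.0), 0.8)
    n_contigs: int = 8
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("planted_neighbor_fraction", "anchor_mutant_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if not 0.0 <= self.censor_rate < 1.0:
            raise ValueError("censor_rate must be in [0, 1)")
        for name in ("ic50_neo_lognormal", "ic50_viral_lognormal", "tmb_lognormal"):
            if getattr(self, name)[1] <= 0:
                raise ValueError(f"{name}: sigma must be > 0")
        if abs(self.planted_rho) > 0.99:
            raise ValueError("planted_rho must be within (-0.99, 0.99)")


def random_peptide(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list(AA_ORDER), size=length, p=AA_FREQS))


def generate_epitope_db(
    db_size: int,
    length_range: tuple[int, int] = (8, 11),
    seed: int = 0,
) -> EpitopeDatabase:
    """Random peptide database with i.i.d. residues from the background
    composition; deterministic under ``seed``."""
    if db_size < 1:
        raise ValueError("db_size must be >= 1")
    rng = np.random.default_rng(seed)
    lo, hi = length_range
    entries = []
    for i in range(db_size):
        length = int(rng.integers(lo, hi + 1))
        entries.append((f"VIRDB_{i + 1:05d}", random_peptide(rng, length)))
    return EpitopeDatabase(tuple(entries))


def _substitute(rng: np.random.Generator, peptide: str, pos0: int) -> str:
    """Replace the residue at 0-based ``pos0`` with a different one."""
    choices = [a for a in AA_ORDER if a != peptide[pos0]]
    new = rng.choice(choices)
    return peptide[:pos0] + new + peptide[pos0 + 1 :]


def _censoring_tau(hazards: np.ndarray, censor_rate: float) -> float:
    """Upper bound of the uniform censoring window achieving the target
    expected censoring rate for exponential event times."""

    def mean_censored(tau: float) -> float:
        x = hazards * tau
        return float(np.mean((1.0 - np.exp(-x)) / x))

    return brentq(lambda t: mean_censored(t) - censor_rate, 1e-9, 1e12)


@dataclass
class Cohort:
    """All synthetic inputs for one cohort, plus generation metadata."""

    patients: pd.DataFrame
    profiles: list[PatientProfile]
    neoepitopes: list[EpitopeRecord]
    viral_epitopes: list[EpitopeRecord]
    mutations: list[MutationRecord]
    db: EpitopeDatabase
    contigs: list[Contig]
    metadata: dict


def generate_cohort(config: Optional[CohortConfig] = None) -> Cohort:
    """Generate a full synthetic cohort under ``config`` (see class docs)."""
    config = config or CohortConfig()
    rng = np.random.default_rng(config.seed)
    n = config.n_patients
    ids = [f"P{i + 1:04d}" for i in range(n)]

    db = generate_epitope_db(config.db_size, seed=config.seed + 101)

    # --- clinical covariates -------------------------------------------
    # Gaussian copula: Spearman rho_s maps to Pearson r = 2 sin(pi rho_s / 6).
    r = 2.0 * math.sin(math.pi * config.planted_rho / 6.0)
    cov = np.array([[1.0, r], [r, 1.0]])
    z = rng.multivariate_normal([0.0, 0.0], cov, size=n)
    cyt_latent = np.exp(1.0 + 0.8 * z[:, 0])
    til_burden = np.exp(0.5 + 0.7 * z[:, 1])
    # GZMA/PRF1 chosen so their geometric mean reproduces cyt_latent.
    d = rng.normal(0.0, 0.2, size=n)
    gzma = cyt_latent * np.exp(d)
    prf1 = cyt_latent * np.exp(-d)
    til_clonality = rng.beta(2.0, 5.0, size=n)
    stage = rng.choice([1, 2, 3, 4], size=n, p=[0.2, 0.35, 0.3, 0.15])
    mu_t, sd_t = config.tmb_lognormal
    tmb_counts = np.maximum(1, np.round(rng.lognormal(mu_t, sd_t, size=n))).astype(int)
    immunogenicity = rng.lognormal(0.0, 1.0, size=n)

    # --- survival ------------------------------------------------------
    def zscore(x: np.ndarray) -> np.ndarray:
        return (x - x.mean()) / x.std(ddof=0)

    # Effects act on the log scale of the skewed, positive covariates
    # (the scale on which expression-like measures enter survival models);
    # z-scoring makes each beta a per-SD log hazard ratio.
    lp = (
        config.beta_cyt * zscore(np.log(cyt_latent))
        + config.beta_tmb * zscore(np.log(tmb_counts.astype(float)))
        + config.beta_imm * zscore(np.log(immunogenicity))
        + config.beta_stage * zscore(stage.astype(float))
    )
    hazards = config.baseline_hazard * np.exp(lp)
    latent_times = rng.exponential(1.0 / hazards)
    if config.censor_rate > 0:
        tau = _censoring_tau(hazards, config.censor_rate)
        censor_times = rng.uniform(0.0, tau, size=n)
        event = (latent_times <= censor_times).astype(int)
        time = np.minimum(latent_times, censor_times)
    else:
        tau = math.inf
        event = np.ones(n, dtype=int)
        time = latent_times

    profiles = [
        PatientProfile(
            patient_id=ids[i],
            time=float(time[i]),
            event=int(event[i]),
            stage=int(stage[i]),
            tmb=float(tmb_counts[i]),
            cyt=float(cyt_latent[i]),
            til_burden=float(til_burden[i]),
            til_clonality=float(til_clonality[i]),
            immunogenicity=float(immunogenicity[i]),
            gzma_rpkm=float(gzma[i]),
            prf1_rpkm=float(prf1[i]),
        )
        for i in range(n)
    ]
    patients = patients_frame(profiles)
    patients["gzma_rpkm"] = gzma
    patients["prf1_rpkm"] = prf1
    patients["latent_time"] = latent_times

    # --- mutation records ----------------------------------------------
    mutations = []
    for i, pid in enumerate(ids):
        k = tmb_counts[i]
        chroms = rng.choice(CHROMS, size=k)
        positions = rng.integers(1, 200_000_000, size=k)
        refs = rng.choice(list("ACGT"), size=k)
        classes = rng.choice(VARIANT_CLASSES, size=k, p=[0.55, 0.25, 0.08, 0.07, 0.05])
        for j in range(k):
            alt_choices = [b for b in "ACGT" if b != refs[j]]
            mutations.append(
                MutationRecord(
                    patient_id=pid,
                    chrom=str(chroms[j]),
                    pos=int(positions[j]),
                    ref=str(refs[j]),
                    alt=str(rng.choice(alt_choices)),
                    variant_class=str(classes[j]),
                )
            )

    # --- epitope tables -------------------------------------------------
    mu_n, sd_n = config.ic50_neo_lognormal
    mu_v, sd_v = config.ic50_viral_lognormal
    neoepitopes: list[EpitopeRecord] = []
    viral_epitopes: list[EpitopeRecord] = []
    db_peptides = db.peptides
    for pid in ids:
        k_neo = max(1, int(rng.poisson(config.epitopes_per_patient)))
        for _ in range(k_neo):
            planted = rng.random() < config.planted_neighbor_fraction
            if planted:
                base = db_peptides[int(rng.integers(0, len(db_peptides)))]
                mt = _substitute(rng, base, int(rng.integers(0, len(base))))
            else:
                mt = random_peptide(rng, int(rng.integers(8, 12)))
            if rng.random() < config.anchor_mutant_fraction:
                pos0 = 1 if rng.random() < 0.5 else len(mt) - 1
            else:
                interior = [p for p in range(len(mt)) if p not in (1, len(mt) - 1)]
                pos0 = int(rng.choice(interior))
            wt = _substitute(rng, mt, pos0)
            neoepitopes.append(
                EpitopeRecord(
                    patient_id=pid,
                    peptide_mt=mt,
                    peptide_wt=wt,
                    hla_allele=str(rng.choice(HLA_ALLELES)),
                    ic50_mt=float(rng.lognormal(mu_n, sd_n)),
                    ic50_wt=float(rng.lognormal(mu_n + 0.5, sd_n)),
                )
            )
        k_vir = max(1, int(rng.poisson(config.viral_per_patient)))
        for _ in range(k_vir):
            peptide = db_peptides[int(rng.integers(0, len(db_peptides)))]
            viral_epitopes.append(
                EpitopeRecord(
                    patient_id=pid,
                    peptide_mt=peptide,
                    peptide_wt=None,
                    hla_allele=str(rng.choice(HLA_ALLELES)),
                    ic50_mt=float(rng.lognormal(mu_v, sd_v)),
                )
            )

    contigs = generate_contigs(config.n_contigs, seed=config.seed + 202)

    metadata = {
        "generator": "neofit.synthetic_data.generate_cohort",
        "config": dataclasses.asdict(config),
        "censoring_tau_days": None if math.isinf(tau) else tau,
        "n_neoepitopes": len(neoepitopes),
        "n_viral_epitopes": len(viral_epitopes),
        "n_mutations": len(mutations),
    }
    return Cohort(
        patients=patients,
        profiles=profiles,
        neoepitopes=neoepitopes,
        viral_epitopes=viral_epitopes,
        mutations=mutations,
        db=db,
        contigs=contigs,
        metadata=metadata,
    )


#: Codons per amino acid (first codon of each), stops excluded.
_CODON = {
    "A": "GCT", "C": "TGT", "D": "GAT", "E": "GAA", "F": "TTT", "G": "GGT",
    "H": "CAT", "I": "ATT", "K": "AAA", "L": "CTG", "M": "ATG", "N": "AAT",
    "P": "CCT", "Q": "CAA", "R": "CGT", "S": "TCT", "T": "ACT", "V": "GTT",
    "W": "TGG", "Y": "TAT",
}


def generate_contigs(n_contigs: int = 8, seed: int = 0) -> list[Contig]:
    """Viral-like contigs with planted ORFs plus filter decoys.

    Each real contig carries one forward-strand ORF (ATG .. stop) of
    120-350 codons inside random flanks, with read support >= 25.  Decoys:
    a homopolymer (entropy 0), a low-complexity two-base repeat, a short
    contig (< 100 bp), and a low-support contig.
    """
    rng = np.random.default_rng(seed)
    contigs = []
    for i in range(n_contigs):
        n_aa = int(rng.integers(120, 351))
        protein = "M" + "".join(
            rng.choice(list(AA_ORDER), size=n_aa - 1, p=AA_FREQS)
        )
        orf = "".join(_CODON[a] for a in protein) + "TAA"
        left = "".join(rng.choice(list("ACGT"), size=int(rng.integers(20, 61))))
        right = "".join(rng.choice(list("ACGT"), size=int(rng.integers(20, 61))))
        # Keep the planted ORF in a known frame by trimming the left flank,
        # and avoid an upstream in-frame ATG hijacking the call.
        contigs.append(
            Contig(
                id=f"CONTIG_{i + 1:03d}",
                sequence=left + orf + right,
                read_support=int(rng.integers(25, 301)),
            )
        )
    contigs.append(Contig(id="DECOY_HOMOPOLYMER", sequence="A" * 500, read_support=100))
    contigs.append(
        Contig(id="DECOY_LOWENTROPY", sequence="AAAT" * 125, read_support=100)
    )
    contigs.append(
        Contig(
            id="DECOY_SHORT",
            sequence="".join(rng.choice(list("ACGT"), size=80)),
            read_support=100,
        )
    )
    contigs.append(
        Contig(
            id="DECOY_LOWSUPPORT",
            sequence="".join(rng.choice(list("ACGT"), size=400)),
            read_support=5,
        )
    )
    return contigs


def write_cohort(cohort: Cohort, out_dir: str | Path) -> dict[str, Path]:
    """Write all cohort tables/FASTAs plus metadata JSON into a directory."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "patients": out / "patients.tsv",
        "neoepitopes": out / "neo.tsv",
        "viral": out / "viral.tsv",
        "mutations": out / "mutations.tsv",
        "db": out / "db.fasta",
        "contigs": out / "contigs.fasta",
        "metadata": out / "metadata.json",
    }
    df = cohort.patients.copy()
    df.to_csv(paths["patients"], sep="\t", index=False)
    write_neoepitope_table(cohort.neoepitopes, paths["neoepitopes"])
    write_neoepitope_table(cohort.viral_epitopes, paths["viral"])
    write_mutation_table(cohort.mutations, paths["mutations"])
    write_epitope_fasta(cohort.db, paths["db"])
    write_contig_fasta(cohort.contigs, paths["contigs"])
    with open(paths["metadata"], "w") as fh:
        json.dump(cohort.metadata, fh, indent=2)
    return paths


def worked_example() -> Cohort:
    """A tiny fixed cohort (6 patients, 12 epitopes, 5-entry database) with
    hand-checkable fitness values.

    Patient P0001 carries a single neoepitope containing the database
    entry "AACC" as an exact substring; its self-alignment score under
    BLOSUM62 is 4+4+9+9 = 26, exactly the default binding-curve
    displacement alpha, so with that hit alone R = 1/2; with
    ic50_wt = 400, ic50_mt = 100 and one epitope the amplitude is 4 and
    the immunogenicity R*A = 2 (tumor fitness 0.5).  Patient P0002 has no
    neoepitope under the 500 nM threshold and is flagged with zero
    immunogenicity.  (Use evalue_max = 0.1 so that only the planted
    score-26 hit passes the homology filter.)
    """
    db = EpitopeDatabase(
        (
            ("VIRDB_00001", "AACC"),
            ("VIRDB_00002", "SIINFEKL"),
            ("VIRDB_00003", "GILGFVFTL"),
            ("VIRDB_00004", "WWWWW"),
            ("VIRDB_00005", "KLVVVGADV"),
        )
    )
    neo = [
        # P0001: one epitope; only hit (vs AACC) scores exactly alpha=26.
        EpitopeRecord("P0001", "MAACCLLEK", "MAACCILEK", "HLA-A*02:01", 100.0, 400.0),
        # P0002: no epitope under the 500 nM threshold.
        EpitopeRecord("P0002", "YLEPGPVTA", "YLEPGPVSA", "HLA-A*02:01", 9000.0, 9500.0),
        # P0003: a planted single-substitution neighbor of SIINFEKL.
        EpitopeRecord("P0003", "SIINFEKV", "SIANFEKV", "HLA-B*07:02", 50.0, 500.0),
        EpitopeRecord("P0003", "KLNDLSTRK", "KLNDLSTRQ", "HLA-A*01:01", 300.0, 600.0),
        # P0004: anchor-only mutant (position 2).
        EpitopeRecord("P0004", "KMNDLSTRA", "KLNDLSTRA", "HLA-A*01:01", 150.0, 450.0),
        EpitopeRecord("P0004", "GILGFVFTV", "GILGYVFTV", "HLA-A*02:01", 80.0, 320.0),
        # P0005: neighbor of GILGFVFTL plus a weak binder.
        EpitopeRecord("P0005", "GILGFVFSL", "GILGYVFSL", "HLA-A*02:01", 40.0, 200.0),
        EpitopeRecord("P0005", "AVDPIHGEF", "AVDPIHGEY", "HLA-B*08:01", 2000.0, 2400.0),
        # P0006: two mid-range epitopes.
        EpitopeRecord("P0006", "KLVVVGADV", "KLVVVGAGV", "HLA-A*02:01", 120.0, 240.0),
        EpitopeRecord("P0006", "RLMNPTTAK", "RLMNPTSAK", "HLA-A*01:01", 450.0, 900.0),
        EpitopeRecord("P0006", "FLPSDFFPS", "FLPSDYFPS", "HLA-B*07:02", 600.0, 700.0),
        EpitopeRecord("P0006", "HMTEVVRHC", "HMTEVVRRC", "HLA-C*07:01", 350.0, 550.0),
    ]
    profiles = [
        PatientProfile("P0001", 900.0, 1, 2, 120.0, 8.5, 3.1, 0.42),
        PatientProfile("P0002", 1500.0, 0, 1, 45.0, 2.1, 0.8, 0.21),
        PatientProfile("P0003", 400.0, 1, 3, 310.0, 12.0, 5.6, 0.55),
        PatientProfile("P0004", 2200.0, 0, 2, 95.0, 6.3, 2.2, 0.38),
        PatientProfile("P0005", 750.0, 1, 4, 200.0, 1.2, 0.5, 0.15),
        PatientProfile("P0006", 1100.0, 1, 1, 150.0, 9.9, 4.4, 0.47),
    ]
    patients = patients_frame(profiles)
    return Cohort(
        patients=patients,
        profiles=profiles,
        neoepitopes=neo,
        viral_epitopes=[],
        mutations=[],
        db=db,
        contigs=[],
        metadata={"generator": "neofit.synthetic_data.worked_example"},
    )
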