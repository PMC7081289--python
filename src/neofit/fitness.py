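"""The tumor-fitness mathematics.

For each neoepitope a TCR recognition potential R models the probability
that the peptide is bound by a T-cell receptor cross-reactive with a known
viral epitope, as a logistic saturation of its alignment scores |s,e|
against the viral epitope database:

    Z = sum_e exp(-k * (alpha - |s,e|))        R = Z / (1 + Z)

alpha is the binding-curve displacement (the alignment score at which a
single hit gives R = 1/2) and k the curve steepness.  An MHC-I amplitude A
compares mutant and wild-type binding (dissociation constants, ic50 nM):
A > 1 means the mutation improved presentation.  Per patient, the maximal
clonal immunogenicity is

    I'' = max_j (R_j * A_j)

over all qualifying neoepitopes j (ic50_mt below the strict 500 nM
threshold); tumor fitness is its inverse 1 / I'' — the capacity of the
dominant clone to evade immune recognition.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

from .alignment import AlignmentHit
from .seq_io import EpitopeRecord

#: Binding-curve displacement and steepness, the two free constants of the
#: recognition potential.  The values are the melanoma fit of the original
#: fitness model; every run should log the constants it used.
DEFAULT_ALPHA = 26.0
DEFAULT_K = 4.87


@dataclass(frozen=True)
class FitnessParams:
    """Constants of the fitness model.

    ``amplitude_normalization``:

    * ``"none"`` — A is the plain ratio ic50_wt / ic50_mt;
    * ``"reciprocal_max_wt"`` (default) — the ratio is corrected for
      dissociation-constant bias by a second factor
      ic50_wt / max(ic50_wt over the patient's wild-type epitopes),
      down-weighting epitopes whose wild type already binds well.
    """

    alpha: float = DEFAULT_ALPHA
    k: float = DEFAULT_K
    affinity_threshold: float = 500.0
    amplitude_normalization: str = "reciprocal_max_wt"

    def __post_init__(self) -> None:
        if self.k <= 0:
            raise ValueError("curve steepness k must be > 0")
        if self.affinity_threshold <= 0:
            raise ValueError("affinity_threshold must be > 0 nM")
        if self.amplitude_normalization not in ("none", "reciprocal_max_wt"):
            raise ValueError(
                f"unknown amplitude_normalization {self.amplitude_normalization!r}"
            )


def recognition_potential(
    hit_scores: Sequence[float], params: Optional[FitnessParams] = None
) -> float:
    """TCR recognition potential R = Z / (1 + Z), Z = sum exp(-k(alpha - s)).

    R lies in [0, 1): 0 for an empty hit list, 1/2 for a single hit scoring
    exactly alpha, and saturating towards 1 as hits accumulate.
    """
    params = params or FitnessParams()
    z = 0.0
    for s in hit_scores:
        if not math.isfinite(s):
            raise ValueError(f"non-finite alignment score {s!r}")
        exponent = -params.k * (params.alpha - s)
        z += math.exp(exponent) if exponent < 700 else math.inf
    # saturate strictly below 1 even when Z overflows float range
    return min(z / (1.0 + z) if math.isfinite(z) else 1.0, 1.0 - 1e-16)


def amplitude(
    ic50_wt: float,
    ic50_mt: float,
    max_ic50_wt_in_patient: Optional[float] = None,
    params: Optional[FitnessParams] = None,
) -> float:
    """MHC-I binding-affinity amplitude A of a neoepitope.

    Base ratio ic50_wt / ic50_mt (mutant binding stronger => A > 1); under
    ``reciprocal_max_wt`` normalization multiplied by
    ic50_wt / max_ic50_wt_in_patient.  Strictly decreasing in ic50_mt.
    """
    params = params or FitnessParams()
    if ic50_wt <= 0 or ic50_mt <= 0:
        raise ValueError("ic50 values must be positive nM")
    a = ic50_wt / ic50_mt
    if params.amplitude_normalization == "reciprocal_max_wt":
        if max_ic50_wt_in_patient is None or max_ic50_wt_in_patient <= 0:
            raise ValueError(
                "reciprocal_max_wt normalization requires the patient's "
                "maximal wild-type ic50"
            )
        a *= ic50_wt / max_ic50_wt_in_patient
    return a


@dataclass(frozen=True)
class EpitopeScore:
    """Per-epitope components of the fitness model."""

    epitope: EpitopeRecord
    recognition: float
    amplitude: float

    @property
    def product(self) -> float:
        return self.recognition * self.amplitude


@dataclass(frozen=True)
class FitnessResult:
    """Per-patient fitness summary.

    ``immunogenicity`` is the maximum of R*A over qualifying neoepitopes;
    ``tumor_fitness`` its inverse, None (and ``flagged`` True) for patients
    with no qualifying epitope, for whom the inverse is undefined.
    """

    patient_id: str
    per_epitope: tuple[EpitopeScore, ...]
    immunogenicity: float
    argmax_epitope: Optional[EpitopeRecord]
    flagged: bool

    @property
    def tumor_fitness(self) -> Optional[float]:
        if self.immunogenicity <= 0:
            return None
        return 1.0 / self.immunogenicity


def score_patient(
    epitopes: Sequence[EpitopeRecord],
    hits_per_epitope: Sequence[Sequence[AlignmentHit]],
    params: Optional[FitnessParams] = None,
    patient_id: Optional[str] = None,
) -> FitnessResult:
    """Maximal clonal immunogenicity for one patient.

    ``hits_per_epitope`` aligns positionally with ``epitopes`` and carries
    each epitope's database hits (already e-value filtered).  Epitopes
    qualify if they are neoepitopes (wild type present) with
    ic50_mt < ``params.affinity_threshold``.  The wild-type ic50 maximum
    used by the amplitude normalization is taken over all the patient's
    wild-type epitopes as supplied.
    """
    params = params or FitnessParams()
    if len(epitopes) != len(hits_per_epitope):
        raise ValueError("epitopes and hits_per_epitope must align positionally")
    if patient_id is None:
        patient_id = epitopes[0].patient_id if epitopes else ""
    wt_ic50s = [e.ic50_wt for e in epitopes if e.ic50_wt is not None]
    max_wt = max(wt_ic50s) if wt_ic50s else None
    scored = []
    for epitope, hits in zip(epitopes, hits_per_epitope):
        if epitope.peptide_wt is None or epitope.ic50_wt is None:
            continue
        if not epitope.ic50_mt < params.affinity_threshold:
            continue
        r = recognition_potential([h.score for h in hits], params)
        a = amplitude(epitope.ic50_wt, epitope.ic50_mt, max_wt, params)
        scored.append(EpitopeScore(epitope, r, a))
    if not scored:
        return FitnessResult(
            patient_id=patient_id,
            per_epitope=(),
            immunogenicity=0.0,
            argmax_epitope=None,
            flagged=True,
        )
    best = max(scored, key=lambda s: s.product)
    return FitnessResult(
        patient_id=patient_id,
        per_epitope=tuple(scored),
        immunogenicity=best.product,
        argmax_epitope=best.epitope,
        flagged=False,
    )
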