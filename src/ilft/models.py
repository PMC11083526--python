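"""Domain types: patient context, analyte panels, plans, findings and outcomes.

Input-facing types are pydantic models so a malformed record is rejected with
a structured error naming the offending field; engine results are plain frozen
dataclasses.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from typing import Literal, Optional

from pydantic import BaseModel, ConfigDict, field_validator, model_validator

__all__ = [
    "PatientContext",
    "LiverPanel",
    "AetiologyScreen",
    "ElfInputs",
    "Tier",
    "CascadePlan",
    "IndirectBand",
    "ElfBand",
    "FinalCategory",
    "FibrosisAssessment",
    "Aetiology",
    "FindingStatus",
    "AetiologyFinding",
    "GilbertResult",
    "Referral",
    "OutcomeCategory",
    "Outcome",
]


class _StrictModel(BaseModel):
    model_config = ConfigDict(frozen=True, extra="forbid")


def _finite_non_negative(name: str, v: Optional[float]) -> Optional[float]:
    if v is None:
        return v
    if not math.isfinite(v):
        raise ValueError(f"{name} must be finite")
    if v < 0:
        raise ValueError(f"{name} must be non-negative")
    return v


class PatientContext(_StrictModel):
    """Requestor-supplied demographics and tick-box metadata.

    ``alcohol_over_14_units`` is the maximum weekly intake over the previous
    six months exceeding 14 units; ``metabolic_syndrome`` records presence of
    metabolic-syndrome features and doubles as the dysglycaemia proxy in the
    NFS calculation.
    """

    age: int
    sex: Literal["male", "female"]
    bmi: float
    alcohol_over_14_units: bool
    metabolic_syndrome: bool

    @field_validator("age")
    @classmethod
    def _adult(cls, v: int) -> int:
        if v < 18:
            raise ValueError("age must be >= 18 (adult pathway)")
        return v

    @field_validator("bmi")
    @classmethod
    def _bmi_positive(cls, v: float) -> float:
        if not math.isfinite(v) or v <= 0:
            raise ValueError("bmi must be positive and finite")
        return v


class LiverPanel(_StrictModel):
    """First-line liver panel plus the reflex analytes fibrosis scores need.

    AST and platelets are optional at request time (AST is itself a reflex
    addition); fibrosis scoring flags itself not-computable when they are
    absent rather than defaulting.
    """

    alt: float
    alp: float
    ggt: float
    bilirubin_total: float
    albumin: float
    ast: Optional[float] = None
    platelets: Optional[float] = None

    @field_validator("*")
    @classmethod
    def _valid_value(cls, v, info):
        return _finite_non_negative(info.field_name, v)


class AetiologyScreen(_StrictModel):
    """Second-line analytes; a field is ``None`` when the assay never cascaded."""

    transferrin_saturation: Optional[float] = None  # %
    a1at: Optional[float] = None                    # g/L
    hbv_positive: Optional[bool] = None
    hcv_positive: Optional[bool] = None
    autoantibody_positive: Optional[bool] = None
    autoantibody_pattern: Optional[Literal["AIH", "PBC", "SLE"]] = None
    crp: Optional[float] = None                     # mg/L
    caeruloplasmin: Optional[float] = None          # g/L
    direct_bilirubin: Optional[float] = None        # umol/L
    haptoglobin: Optional[float] = None             # g/L

    @field_validator(
        "transferrin_saturation", "a1at", "crp", "caeruloplasmin",
        "direct_bilirubin", "haptoglobin",
    )
    @classmethod
    def _valid_value(cls, v, info):
        return _finite_non_negative(info.field_name, v)


class ElfInputs(_StrictModel):
    """The three direct fibrosis analytes; all strictly positive (logs taken)."""

    ha: float       # hyaluronic acid
    piiinp: float   # procollagen III N-terminal peptide
    timp1: float    # tissue inhibitor of metalloproteinase-1

    @field_validator("*")
    @classmethod
    def _positive(cls, v: float, info):
        if not math.isfinite(v) or v <= 0:
            raise ValueError(f"{info.field_name} must be positive and finite")
        return v


class Tier(str, enum.Enum):
    NONE = "none"
    ALP_ADVISORY = "alp_advisory"
    LIMITED_BILIRUBIN = "limited_bilirubin"
    FULL = "full"


@dataclass(frozen=True)
class CascadePlan:
    tier: Tier
    added_assays: frozenset[str] = frozenset()
    abnormal_analytes: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if self.tier is Tier.NONE and (self.added_assays or self.abnormal_analytes):
            raise ValueError("tier none implies no added assays and no abnormalities")


class IndirectBand(str, enum.Enum):
    LOW = "low"
    INDETERMINATE = "indeterminate"
    HIGH = "high"
    NOT_COMPUTABLE = "not_computable"


class ElfBand(str, enum.Enum):
    ABSENT_MILD = "absent_mild"
    MODERATE = "moderate"
    SEVERE = "severe"
    CIRRHOSIS = "cirrhosis"


class FinalCategory(str, enum.Enum):
    NO_SIGNIFICANT_FIBROSIS = "no_significant_fibrosis"
    INDETERMINATE_RESOLVED_LOW = "indeterminate_resolved_low"
    SIGNIFICANT_FIBROSIS = "significant_fibrosis"
    INDETERMINATE_UNRESOLVED = "indeterminate_unresolved"


@dataclass(frozen=True)
class FibrosisAssessment:
    """Merged indirect + direct fibrosis picture for one record."""

    fib4: Optional[float]
    nfs: Optional[float]
    elf: Optional[float]
    indirect_band: IndirectBand
    elf_band: Optional[ElfBand]
    urgent_prognosis: bool
    final_category: FinalCategory


class Aetiology(str, enum.Enum):
    IRON_OVERLOAD = "iron_overload"
    A1AT_DEFICIENCY = "a1at_deficiency"
    HEPATITIS_B = "hepatitis_b"
    HEPATITIS_C = "hepatitis_c"
    AUTOIMMUNE = "autoimmune"
    WILSON_POSSIBLE = "wilson_possible"
    GILBERT_PATTERN = "gilbert_pattern"
    HAEMOLYSIS_PATTERN = "haemolysis_pattern"


class FindingStatus(str, enum.Enum):
    POSITIVE = "positive"
    NEGATIVE = "negative"
    NOT_TESTED = "not_tested"


@dataclass(frozen=True)
class AetiologyFinding:
    aetiology: Aetiology
    status: FindingStatus
    detail: str = ""


class GilbertResult(str, enum.Enum):
    GILBERT_LIKELY = "gilbert_likely"
    CONJUGATED_PATTERN = "conjugated_pattern"
    HAEMOLYSIS_SUSPECTED = "haemolysis_suspected"
    NOT_APPLICABLE = "not_applicable"


class Referral(str, enum.Enum):
    """Referral advice, ordered by severity for record-level aggregation."""

    NONE = "none"
    PHENOTYPE_DEPENDENT = "phenotype_dependent"
    ROUTINE = "routine"
    URGENT = "urgent"

    @property
    def severity(self) -> int:
        return _REFERRAL_ORDER[self]


_REFERRAL_ORDER = {
    Referral.NONE: 0,
    Referral.PHENOTYPE_DEPENDENT: 1,
    Referral.ROUTINE: 2,
    Referral.URGENT: 3,
}


class OutcomeCategory(str, enum.Enum):
    AETIOLOGICAL = "aetiological"
    DESCRIPTIVE = "descriptive"
    ADVISORY = "advisory"
    ALERT = "alert"


@dataclass(frozen=True)
class Outcome:
    """One coded result: diagnosis/description, referral advice and comment."""

    code: str
    description: str
    referral: Referral
    category: OutcomeCategory
    comment: str = ""
    precedence: int = field(default=99, compare=False)
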