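"""Preoperative risk scoring: CAPRA, D'Amico and their image-adjusted variants.

The image-adjusted (IA) stratifier converts the base risk group into points
(low = 1, intermediate = 2, high = 3), adds points from two mpMRI features —
the lesion apparent diffusion coefficient (ADC, units of 1e-6 mm^2/s, binned
at 650/800/950) and radiological extraprostatic extension (rEPE, positive at
Likert >= 4, worth 2 points) — and re-thresholds the resulting 1–8 composite
into three groups (1–2 low, 3–5 intermediate, 6–8 high).

All scoring functions are pure and deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Optional, Sequence


class InvalidInputError(ValueError):
    """Raised when a clinical or imaging value is outside its valid domain."""


#: Clinical T stages accepted on input.  T3b/T3c occur in pathology-style
#: staging; they are treated as >= T2c by D'Amico and as T3a-equivalent
#: (1 point) by CAPRA.
T_STAGES = ("T1c", "T2a", "T2b", "T2c", "T3a", "T3b", "T3c")

#: Default ADC bin cut-offs, in 1e-6 mm^2/s (ascending).
DEFAULT_ADC_CUTOFFS = (650.0, 800.0, 950.0)

#: Default Likert threshold at or above which rEPE counts as present.
DEFAULT_LIKERT_THRESHOLD = 4


class RiskGroup(Enum):
    """Three-level risk group with its point value on the composite scale."""

    LOW = 1
    INTERMEDIATE = 2
    HIGH = 3

    @property
    def base_points(self) -> int:
        return self.value

    @property
    def label(self) -> str:
        return self.name.lower()

    @classmethod
    def from_label(cls, label: str) -> "RiskGroup":
        try:
            return cls[label.strip().upper()]
        except KeyError:
            raise InvalidInputError(f"unknown risk group label: {label!r}") from None


@dataclass(frozen=True)
class GleasonInfo:
    """Biopsy Gleason primary/secondary patterns, each in 1..5."""

    primary_pattern: int
    secondary_pattern: int

    def __post_init__(self) -> None:
        for name in ("primary_pattern", "secondary_pattern"):
            v = getattr(self, name)
            if not (isinstance(v, (int,)) and 1 <= v <= 5):
                raise InvalidInputError(f"Gleason {name} must be an integer in 1..5, got {v!r}")

    @property
    def total(self) -> int:
        return self.primary_pattern + self.secondary_pattern


@dataclass(frozen=True)
class ClinicalRecord:
    """One patient's preoperative clinical variables (CAPRA / D'Amico inputs).

    Missing data is an input error: every field is required, mirroring a
    complete-case analysis.
    """

    patient_id: str
    age_years: float
    psa_ng_ml: float
    gleason: GleasonInfo
    pct_positive_cores: float
    clinical_t_stage: str

    def __post_init__(self) -> None:
        import math

        if not (math.isfinite(self.psa_ng_ml) and self.psa_ng_ml > 0):
            raise InvalidInputError(f"PSA must be finite and positive, got {self.psa_ng_ml!r}")
        if not self.age_years > 0:
            raise InvalidInputError(f"age must be positive, got {self.age_years!r}")
        if not (0 <= self.pct_positive_cores <= 100):
            raise InvalidInputError(
                f"% positive cores must be in [0, 100], got {self.pct_positive_cores!r}"
            )
        if self.clinical_t_stage not in T_STAGES:
            raise InvalidInputError(
                f"clinical T stage must be one of {T_STAGES}, got {self.clinical_t_stage!r}"
            )


@dataclass(frozen=True)
class ImagingRecord:
    """Index-lesion mpMRI features used by the IA adjustment."""

    adc_value: float  # 1e-6 mm^2/s
    repe_likert: int  # 1..5
    lesion_size_mm: Optional[float] = None

    def __post_init__(self) -> None:
        if not self.adc_value > 0:
            raise InvalidInputError(f"ADC must be positive, got {self.adc_value!r}")
        if self.repe_likert not in (1, 2, 3, 4, 5):
            raise InvalidInputError(f"rEPE Likert must be in 1..5, got {self.repe_likert!r}")
        if self.lesion_size_mm is not None and self.lesion_size_mm < 0:
            raise InvalidInputError("lesion size must be >= 0")


@dataclass(frozen=True)
class IaResult:
    """Full decomposition of one image-adjusted score."""

    base_group: RiskGroup
    adc_points: int
    repe_points: int
    composite_score: int
    adjusted_group: RiskGroup

    def __post_init__(self) -> None:
        assert self.composite_score == (
            self.base_group.base_points + self.adc_points + self.repe_points
        )


def grade_group(gleason: GleasonInfo) -> int:
    """ISUP grade group (1–5) from biopsy Gleason patterns.

    <=6 -> 1; 3+4 -> 2; 4+3 -> 3; 8 -> 4; 9–10 -> 5.
    """
    total = gleason.total
    if total <= 6:
        return 1
    if total == 7:
        return 2 if gleason.primary_pattern == 3 else 3
    if total == 8:
        return 4
    return 5


def capra_score(rec: ClinicalRecord) -> int:
    """UCSF-CAPRA score, 0–10.

    Points: PSA <=6 -> 0, 6.01–10 -> 1, 10.01–20 -> 2, 20.01–30 -> 3,
    >30 -> 4; Gleason primary 4/5 -> 3 else secondary 4/5 -> 1 else 0;
    T3a+ -> 1; >=34% positive cores -> 1; age >=50 -> 1.
    """
    pts = 0
    psa = rec.psa_ng_ml
    if psa > 30:
        pts += 4
    elif psa > 20:
        pts += 3
    elif psa > 10:
        pts += 2
    elif psa > 6:
        pts += 1
    if rec.gleason.primary_pattern >= 4:
        pts += 3
    elif rec.gleason.secondary_pattern >= 4:
        pts += 1
    if rec.clinical_t_stage in ("T3a", "T3b", "T3c"):
        pts += 1
    if rec.pct_positive_cores >= 34:
        pts += 1
    if rec.age_years >= 50:
        pts += 1
    return pts


def capra_group(score: int) -> RiskGroup:
    """CAPRA risk group: 0–2 low, 3–5 intermediate, 6–10 high."""
    if not (isinstance(score, int) and 0 <= score <= 10):
        raise InvalidInputError(f"CAPRA score must be an integer in 0..10, got {score!r}")
    if score <= 2:
        return RiskGroup.LOW
    if score <= 5:
        return RiskGroup.INTERMEDIATE
    return RiskGroup.HIGH


def damico_group(rec: ClinicalRecord) -> RiskGroup:
    """D'Amico risk group from PSA, biopsy Gleason score and clinical T stage.

    High if PSA > 20 or Gleason sum >= 8 or stage >= T2c; intermediate if
    PSA in (10, 20] or Gleason sum = 7 or stage = T2b; else low.
    """
    total = rec.gleason.total
    stage = rec.clinical_t_stage
    if rec.psa_ng_ml > 20 or total >= 8 or stage in ("T2c", "T3a", "T3b", "T3c"):
        return RiskGroup.HIGH
    if rec.psa_ng_ml > 10 or total == 7 or stage == "T2b":
        return RiskGroup.INTERMEDIATE
    return RiskGroup.LOW


def adc_points(
    adc_value: float, cutoffs: Sequence[float] = DEFAULT_ADC_CUTOFFS
) -> int:
    """Points from the lesion ADC value.

    With the default cut-offs (650, 800, 950): > 950 -> 0, [800, 950] -> 1,
    [650, 800) -> 2, < 650 -> 3.  The closed upper bin boundary follows the
    "950–800" bin label; 650 belongs to the +2 bin ("less than 650" being
    strict).  Lower ADC (denser tumour) never earns fewer points.
    """
    if not adc_value > 0:
        raise InvalidInputError(f"ADC must be positive, got {adc_value!r}")
    lo, mid, hi = cutoffs
    if not (lo < mid < hi):
        raise InvalidInputError(f"ADC cut-offs must be strictly increasing, got {cutoffs!r}")
    if adc_value > hi:
        return 0
    if adc_value >= mid:
        return 1
    if adc_value >= lo:
        return 2
    return 3


def repe_points(repe_likert: int, threshold: int = DEFAULT_LIKERT_THRESHOLD) -> int:
    """Points from radiological EPE: 2 if Likert >= threshold (default 4), else 0."""
    if repe_likert not in (1, 2, 3, 4, 5):
        raise InvalidInputError(f"rEPE Likert must be in 1..5, got {repe_likert!r}")
    if not 2 <= threshold <= 5:
        raise InvalidInputError(f"Likert threshold must be in 2..5, got {threshold!r}")
    return 2 if repe_likert >= threshold else 0


def composite_to_group(composite: int) -> RiskGroup:
    """Map the 1–8 composite score to a group: 1–2 low, 3–5 intermediate, 6–8 high."""
    if not 1 <= composite <= 8:
        raise InvalidInputError(f"composite score must be in 1..8, got {composite!r}")
    if composite <= 2:
        return RiskGroup.LOW
    if composite <= 5:
        return RiskGroup.INTERMEDIATE
    return RiskGroup.HIGH


def ia_adjust(
    base_group: RiskGroup,
    img: ImagingRecord,
    adc_cutoffs: Sequence[float] = DEFAULT_ADC_CUTOFFS,
    likert_threshold: int = DEFAULT_LIKERT_THRESHOLD,
) -> IaResult:
    """Image-adjust a base risk group with the lesion's ADC and rEPE points."""
    a = adc_points(img.adc_value, adc_cutoffs)
    r = repe_points(img.repe_likert, likert_threshold)
    composite = base_group.base_points + a + r
    return IaResult(
        base_group=base_group,
        adc_points=a,
        repe_points=r,
        composite_score=composite,
        adjusted_group=composite_to_group(composite),
    )


@dataclass(frozen=True)
class PatientScores:
    """All scores for one patient: both base tools and both IA variants."""

    capra: int
    capra_group: RiskGroup
    damico_group: RiskGroup
    ia_capra: IaResult
    ia_damico: IaResult


def score_patient(
    clinical: ClinicalRecord,
    imaging: ImagingRecord,
    adc_cutoffs: Sequence[float] = DEFAULT_ADC_CUTOFFS,
    likert_threshold: int = DEFAULT_LIKERT_THRESHOLD,
) -> PatientScores:
    """Compute CAPRA, D'Amico and their image-adjusted variants for one patient."""
    c = capra_score(clinical)
    cg = capra_group(c)
    dg = damico_group(clinical)
    return PatientScores(
        capra=c,
        capra_group=cg,
        damico_group=dg,
        ia_capra=ia_adjust(cg, imaging, adc_cutoffs, likert_threshold),
        ia_damico=ia_adjust(dg, imaging, adc_cutoffs, likert_threshold),
    )
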