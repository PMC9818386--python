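"""Pedigree segregation: carrier-status classification and the co-segregation
filter.

Each family member is classified as a case (diagnosed with multiple myeloma,
its precursors MGUS/SMM, or AL amyloidosis), a possible carrier (plasma-cell
anomaly short of a diagnosis, or an unaffected member too young to have
been expected to develop disease), or a confirmed non-carrier.  Under a
dominant model a variant segregates in a family when every case carries it
and every non-carrier does not; possible carriers are unconstrained.
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass, field
from typing import Dict, FrozenSet, List, Mapping, Optional, Sequence, Tuple

from .types import Diagnosis, Family, Individual, VariantRecord

log = logging.getLogger(__name__)

__all__ = [
    "CarrierStatus",
    "SegregationConfig",
    "SegregationResult",
    "classify_member",
    "classify_family",
    "segregates_in_family",
    "filter_segregating",
]


class CarrierStatus(enum.Enum):
    CASE = "CASE"
    POSSIBLE_CARRIER = "POSSIBLE_CARRIER"
    NON_CARRIER = "NON_CARRIER"


DEFAULT_CASE_DIAGNOSES = frozenset(
    {Diagnosis.MM, Diagnosis.SMM, Diagnosis.MGUS, Diagnosis.AL_AMYLOIDOSIS}
)
DEFAULT_POSSIBLE_CARRIER_DIAGNOSES = frozenset(
    {
        Diagnosis.PLASMA_CELL_DYSCRASIA,
        Diagnosis.SOLITARY_PLASMACYTOMA,
        Diagnosis.ABERRANT_PLASMA_CLONE,
    }
)


@dataclass(frozen=True)
class SegregationConfig:
    """Configuration of the carrier classification and segregation predicate.

    ``age_gap_years``: a healthy member more than this many years younger
    (strictly) than the family's earliest diagnosis age cannot be proven a
    non-carrier and is treated as a possible carrier.  ``missing_fails``:
    a missing genotype in a case or non-carrier fails segregation
    (conservative default); set False to ignore missing genotypes.
    SMM is included in the case set by default (the cohort enrolls SMM as
    an MM precursor); the set is configurable.
    """

    case_diagnoses: FrozenSet[Diagnosis] = DEFAULT_CASE_DIAGNOSES
    possible_carrier_diagnoses: FrozenSet[Diagnosis] = DEFAULT_POSSIBLE_CARRIER_DIAGNOSES
    age_gap_years: float = 10.0
    missing_fails: bool = True


def _earliest_diagnosis_age(
    family: Family, cfg: SegregationConfig
) -> Optional[float]:
    ages = [
        m.age_at_diagnosis
        for m in family.members
        if m.diagnosis in cfg.case_diagnoses and m.age_at_diagnosis is not None
    ]
    return min(ages) if ages else None


def classify_member(
    ind: Individual, family: Family, cfg: SegregationConfig = SegregationConfig()
) -> CarrierStatus:
    """Classify one family member as CASE / POSSIBLE_CARRIER / NON_CARRIER.

    Healthy members are non-carriers only when old enough relative to the
    family's earliest diagnosis age; when that age (or the member's own
    follow-up age) is unknown, the member cannot be proven a non-carrier
    and becomes a possible carrier, with a warning.
    """
    if ind.diagnosis in cfg.case_diagnoses:
        return CarrierStatus.CASE
    if ind.diagnosis in cfg.possible_carrier_diagnoses:
        return CarrierStatus.POSSIBLE_CARRIER
    earliest = _earliest_diagnosis_age(family, cfg)
    if earliest is None:
        log.warning(
            "family %s: no case diagnosis age; healthy member %s treated as possible carrier",
            family.family_id,
            ind.individual_id,
        )
        return CarrierStatus.POSSIBLE_CARRIER
    if ind.age_at_last_followup is None:
        log.warning(
            "family %s: member %s has no follow-up age; treated as possible carrier",
            family.family_id,
            ind.individual_id,
        )
        return CarrierStatus.POSSIBLE_CARRIER
    if ind.age_at_last_followup < earliest - cfg.age_gap_years:
        return CarrierStatus.POSSIBLE_CARRIER
    return CarrierStatus.NON_CARRIER


def classify_family(
    family: Family, cfg: SegregationConfig = SegregationConfig()
) -> Dict[str, CarrierStatus]:
    return {m.individual_id: classify_member(m, family, cfg) for m in family.members}


def segregates_in_family(
    variant: VariantRecord,
    family: Family,
    statuses: Mapping[str, CarrierStatus],
    cfg: SegregationConfig = SegregationConfig(),
) -> bool:
    """True iff the variant co-segregates with disease in this family.

    Every case must carry the variant and every non-carrier must not;
    possible carriers may show either.  With the conservative default
    policy a missing genotype in a case or non-carrier fails segregation.
    A family without cases cannot show segregation (warning, False).
    """
    n_cases = sum(1 for s in statuses.values() if s is CarrierStatus.CASE)
    if n_cases == 0:
        log.warning("family %s has no cases; variant %s cannot segregate",
                    family.family_id, variant.key)
        return False
    for member in family.members:
        status = statuses[member.individual_id]
        if status is CarrierStatus.POSSIBLE_CARRIER:
            continue
        g = variant.genotypes.get(member.individual_id)
        if g is None or g.missing or g.alt_count is None:
            if cfg.missing_fails:
                return False
            continue
        if status is CarrierStatus.CASE and g.alt_count < 1:
            return False
        if status is CarrierStatus.NON_CARRIER and g.alt_count >= 1:
            return False
    return True


@dataclass(slots=True)
class SegregationResult:
    """Per-variant segregation verdicts across all families."""

    variant: VariantRecord
    families_segregating: List[str]
    #: family id -> list of (individual_id, status, carries, missing)
    per_family_detail: Dict[str, List[Tuple[str, CarrierStatus, bool, bool]]]


def filter_segregating(
    variants: Sequence[VariantRecord],
    families: Sequence[Family],
    cfg: SegregationConfig = SegregationConfig(),
) -> List[SegregationResult]:
    """Keep variants that segregate with disease in at least one family,
    retaining member-level detail for reporting."""
    statuses = {f.family_id: classify_family(f, cfg) for f in families}
    results: List[SegregationResult] = []
    for v in variants:
        seg_fams: List[str] = []
        detail: Dict[str, List[Tuple[str, CarrierStatus, bool, bool]]] = {}
        for fam in families:
            fam_status = statuses[fam.family_id]
            rows = []
            for m in fam.members:
                g = v.genotypes.get(m.individual_id)
                carries = bool(g is not None and g.carries)
                missing = bool(g is None or g.missing)
                rows.append((m.individual_id, fam_status[m.individual_id], carries, missing))
            detail[fam.family_id] = rows
            if segregates_in_family(v, fam, fam_status, cfg):
                seg_fams.append(fam.family_id)
        if seg_fams:
            results.append(SegregationResult(v, seg_fams, detail))
    return results
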