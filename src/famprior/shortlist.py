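"""Branch-specific top-variant rules and the prioritization funnel report.

The 5' rule formalizes the shared properties of the top upstream/5'UTR
candidates: promoter membership, CpG-island membership, conservation
composite >= 2, and at least one recurrent histone mark.  Promoter and
CpG flags are tri-state; an unknown never counts as passing.  An optional
active-chromatin requirement (TssA/TssAFlnk/TssBiv/EnhBiv/Enh present) is
OFF by default because repressed-chromatin promoter variants can still be
genuine top candidates.

The 3' rule: conservation composite >= 2, an overlapping miRNA target
site, mirSVR < -0.1, and gene-end chromatin context.

Every sub-criterion is independently switchable so that alternative rules
remain auditable through the per-decision flag record.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import pandas as pd

from .regulatory3p import Annotated3p, mirsvr_positive
from .regulatory5p import Annotated5p
from .scores import ConservationComposite

__all__ = [
    "Branch",
    "Shortlist5pConfig",
    "Shortlist3pConfig",
    "ShortlistDecision",
    "FunnelReport",
    "shortlist_5p",
    "shortlist_3p",
    "build_funnel",
]

ACTIVE_CHROMATIN_STATES = frozenset({"TssA", "TssAFlnk", "TssBiv", "EnhBiv", "Enh"})


class Branch(enum.Enum):
    FIVE_PRIME = "5p"
    THREE_PRIME = "3p"


@dataclass(frozen=True)
class Shortlist5pConfig:
    require_promoter: bool = True
    require_cpg: bool = True
    cons_min: int = 2
    require_histone: bool = True
    require_active_chromatin: bool = False


@dataclass(frozen=True)
class Shortlist3pConfig:
    cons_min: int = 2
    require_mirna: bool = True
    require_mirsvr: bool = True
    mirsvr_cutoff: float = -0.1
    require_gene_end: bool = True


@dataclass(slots=True)
class ShortlistDecision:
    """Auditable top-variant decision: every evaluated flag plus the verdict.

    Tri-state flags are ``True``/``False``/``None`` (unknown); a required
    flag passes only when strictly ``True``.
    """

    variant_key: str
    branch: Branch
    criterion_flags: Dict[str, Optional[bool]]
    is_top: bool
    gene: Optional[str] = None


def _decide(required: Dict[str, Optional[bool]]) -> bool:
    return all(v is True for v in required.values())


def shortlist_5p(
    a: Annotated5p,
    cons: ConservationComposite,
    cfg: Shortlist5pConfig = Shortlist5pConfig(),
) -> ShortlistDecision:
    """Apply the 5'-branch top-variant rule to one annotated variant."""
    flags: Dict[str, Optional[bool]] = {
        "promoter": a.in_promoter,
        "cpg": a.in_cpg,
        "conservation": cons.score >= cfg.cons_min,
        "histone": bool(a.histone_summary),
        "active_chromatin": bool(a.chmm_summary & ACTIVE_CHROMATIN_STATES),
    }
    required = {}
    if cfg.require_promoter:
        required["promoter"] = flags["promoter"]
    if cfg.require_cpg:
        required["cpg"] = flags["cpg"]
    required["conservation"] = flags["conservation"]
    if cfg.require_histone:
        required["histone"] = flags["histone"]
    if cfg.require_active_chromatin:
        required["active_chromatin"] = flags["active_chromatin"]
    return ShortlistDecision(
        variant_key=a.variant_key,
        branch=Branch.FIVE_PRIME,
        criterion_flags=flags,
        is_top=_decide(required),
        gene=a.gene,
    )


def shortlist_3p(
    a: Annotated3p,
    cons: ConservationComposite,
    cfg: Shortlist3pConfig = Shortlist3pConfig(),
) -> ShortlistDecision:
    """Apply the 3'-branch top-variant rule to one annotated variant."""
    flags: Dict[str, Optional[bool]] = {
        "conservation": cons.score >= cfg.cons_min,
        "mirna_binding": bool(a.mirna_hits),
        "mirsvr": mirsvr_positive(a.mirsvr, cfg.mirsvr_cutoff),
        "gene_end": a.gene_end,
    }
    required = {"conservation": flags["conservation"]}
    if cfg.require_mirna:
        required["mirna_binding"] = flags["mirna_binding"]
    if cfg.require_mirsvr:
        required["mirsvr"] = flags["mirsvr"]
    if cfg.require_gene_end:
        required["gene_end"] = flags["gene_end"]
    return ShortlistDecision(
        variant_key=a.variant_key,
        branch=Branch.THREE_PRIME,
        criterion_flags=flags,
        is_top=_decide(required),
        gene=a.gene,
    )


@dataclass(slots=True)
class FunnelReport:
    """Ordered per-stage counts of the prioritization funnel."""

    #: list of (stage label, count-in, count-out)
    stages: List[Tuple[str, int, int]]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.stages, columns=["stage", "count_in", "count_out"])


def build_funnel(stage_outputs: Sequence[Tuple[str, int]]) -> FunnelReport:
    """Build the funnel report from successive (label, surviving-count)
    pairs, the first pair being the input stage.

    Counts must be non-increasing; a stage gaining variants indicates a
    pipeline bug and raises.
    """
    if not stage_outputs:
        raise ValueError("funnel needs at least one stage")
    stages: List[Tuple[str, int, int]] = []
    prev = stage_outputs[0][1]
    stages.append((stage_outputs[0][0], prev, prev))
    for label, count in stage_outputs[1:]:
        if count > prev:
            raise ValueError(
                f"funnel stage {label!r} gained variants ({prev} -> {count})"
            )
        stages.append((label, prev, count))
        prev = count
    return FunnelReport(stages=stages)
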