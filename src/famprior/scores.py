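"""Deleteriousness thresholding and the three-score conservation composite.

CADD PHRED >= 15 marks roughly the top 1.5% most deleterious substitutions.
The conservation composite counts how many of three evolutionary measures
pass their thresholds: GERP rejected substitutions strictly above 2,
vertebrate PhastCons element probability at or above 0.3, and vertebrate
PhyloP at or above 3.0, giving an integer score of 0-3.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import FrozenSet, Optional

from .types import ScoreBundle

log = logging.getLogger(__name__)

__all__ = [
    "DeleteriousnessConfig",
    "ConservationComposite",
    "cadd_pass",
    "conservation_composite",
]


@dataclass(frozen=True)
class DeleteriousnessConfig:
    """Thresholds and comparator switches for CADD and conservation.

    ``phastcons_strict`` switches the PhastCons comparator from the default
    inclusive >= 0.3 to a strict > 0.3 (both conventions circulate; the
    inclusive form is the default here).  GERP is always strict (> 2),
    PhyloP inclusive (>= 3.0).
    """

    cadd_min: float = 15.0
    gerp_min: float = 2.0
    phastcons_min: float = 0.3
    phylop_min: float = 3.0
    phastcons_strict: bool = False


_CANONICAL_FLAG_ORDER = ("gerp", "phastcons", "phylop")


@dataclass(frozen=True)
class ConservationComposite:
    """Integer 0-3 conservation score with the names of the passing measures."""

    score: int
    flags: FrozenSet[str]

    def __post_init__(self) -> None:
        if self.score != len(self.flags):
            raise ValueError("composite score must equal the number of passing flags")
        if not self.flags <= frozenset(_CANONICAL_FLAG_ORDER):
            raise ValueError(f"unknown conservation flags: {self.flags}")

    @classmethod
    def from_score(cls, score: int) -> "ConservationComposite":
        """Build a composite from a bare 0-3 score when the individual
        per-measure outcomes are not available (e.g. when encoding a
        published summary table); flags are filled in canonical order."""
        if not 0 <= score <= 3:
            raise ValueError(f"composite score out of 0..3: {score}")
        return cls(score=score, flags=frozenset(_CANONICAL_FLAG_ORDER[:score]))


def cadd_pass(
    bundle: ScoreBundle, threshold: float = 15.0
) -> bool:
    """True iff the CADD PHRED score is at or above the threshold.

    An absent CADD score fails (with a warning): unscored variants cannot
    be shown deleterious.
    """
    if bundle.cadd_phred is None:
        log.warning("CADD score absent; variant fails the CADD filter")
        return False
    return bundle.cadd_phred >= threshold


def conservation_composite(
    bundle: ScoreBundle, cfg: DeleteriousnessConfig = DeleteriousnessConfig()
) -> ConservationComposite:
    """Count passing conservation measures; an absent score does not pass."""
    flags = set()
    if bundle.gerp is not None and bundle.gerp > cfg.gerp_min:
        flags.add("gerp")
    if bundle.phastcons is not None:
        passed = (
            bundle.phastcons > cfg.phastcons_min
            if cfg.phastcons_strict
            else bundle.phastcons >= cfg.phastcons_min
        )
        if passed:
            flags.add("phastcons")
    if bundle.phylop is not None and bundle.phylop >= cfg.phylop_min:
        flags.add("phylop")
    return ConservationComposite(score=len(flags), flags=frozenset(flags))
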