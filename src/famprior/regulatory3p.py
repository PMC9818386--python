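"""Regulatory annotation of 3'UTR variants.

A 3'UTR variant is evidence-positive when it overlaps a predicted miRNA
target site, when the best site has a high context++ efficacy percentile
(>= 90), when the per-variant mirSVR score predicts downregulation
(strictly below -0.1), and when the locus's Segway label and summarized
chromatin states place it at a transcribed gene end.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, FrozenSet, List, Optional, Sequence, Tuple

import pandas as pd

from .regulatory5p import ChromatinProfile, summarize_chromatin
from .types import GenomicInterval, IntervalTrack, VariantRecord

__all__ = [
    "MiRNATargetSite",
    "Annotated3p",
    "match_mirna_sites",
    "context_pp_significant",
    "mirsvr_positive",
    "gene_end_context",
    "annotate_3p",
    "read_mirsvr_table",
]


@dataclass(frozen=True, slots=True)
class MiRNATargetSite:
    """One predicted miRNA target site overlapping a variant."""

    mirna: str
    gene: str
    chrom: str
    start: int
    end: int
    context_pp_percentile: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.context_pp_percentile <= 100.0:
            raise ValueError(
                f"context++ percentile out of [0,100]: {self.context_pp_percentile}"
            )


def match_mirna_sites(
    variant: VariantRecord, atlas: IntervalTrack
) -> List[MiRNATargetSite]:
    """All miRNA target sites in the atlas overlapping the variant, sorted by
    descending context++ percentile (ties broken by miRNA name)."""
    start, end = variant.interval
    sites = [
        MiRNATargetSite(
            mirna=iv.attributes["mirna"],
            gene=iv.attributes.get("gene", ""),
            chrom=iv.chrom,
            start=iv.start,
            end=iv.end,
            context_pp_percentile=float(iv.attributes["context_pp_percentile"]),
        )
        for iv in atlas.overlapping(variant.chrom, start, end)
    ]
    sites.sort(key=lambda s: (-s.context_pp_percentile, s.mirna))
    return sites


def context_pp_significant(
    best_context_pp: Optional[float], cutoff: float = 90.0
) -> bool:
    """True iff the best context++ percentile is at or above the cutoff
    (90 or above counts as a significant site); no hits -> False."""
    return best_context_pp is not None and best_context_pp >= cutoff


def mirsvr_positive(mirsvr: Optional[float], cutoff: float = -0.1) -> bool:
    """True iff the mirSVR score is strictly below the cutoff (-0.1): more
    negative scores predict stronger mRNA downregulation.  Absent -> False."""
    return mirsvr is not None and mirsvr < cutoff


def gene_end_context(segway: Optional[str], chmm_summary: FrozenSet[str]) -> bool:
    """True iff the Segway label is a gene-end class (``GE``-prefixed) and
    the summarized chromatin states include active transcription (Tx or
    TxWk)."""
    return (
        segway is not None
        and segway.startswith("GE")
        and bool(chmm_summary & {"Tx", "TxWk"})
    )


@dataclass(slots=True)
class Annotated3p:
    """Full 3'-branch annotation of one 3'UTR variant."""

    variant_key: str
    gene: Optional[str] = None
    mirna_hits: List[MiRNATargetSite] = field(default_factory=list)
    mirsvr: Optional[float] = None
    segway: Optional[str] = None
    chmm_summary: FrozenSet[str] = frozenset()
    gene_end: bool = False

    @property
    def best_context_pp(self) -> Optional[float]:
        return self.mirna_hits[0].context_pp_percentile if self.mirna_hits else None


def annotate_3p(
    variant: VariantRecord,
    atlas: Optional[IntervalTrack] = None,
    mirsvr: Optional[float | Sequence[float]] = None,
    chromatin: Optional[ChromatinProfile] = None,
) -> Annotated3p:
    """Assemble the 3'-branch annotation for one variant.

    ``mirsvr`` may be a single per-variant score or several; with several,
    the minimum (most negative, strongest predicted downregulation) is used.
    """
    ann = Annotated3p(variant_key=variant.key, gene=variant.gene)
    if atlas is not None:
        ann.mirna_hits = match_mirna_sites(variant, atlas)
    if mirsvr is not None:
        ann.mirsvr = float(mirsvr) if isinstance(mirsvr, (int, float)) else min(mirsvr)
    if chromatin is not None:
        ann.chmm_summary, _ = summarize_chromatin(chromatin)
        ann.segway = chromatin.segway
    ann.gene_end = gene_end_context(ann.segway, ann.chmm_summary)
    return ann


def read_mirsvr_table(path: str | Path) -> Dict[str, float]:
    """Read a per-variant mirSVR TSV (columns ``variant_key, mirsvr``);
    multiple rows for a variant collapse to the minimum score."""
    df = pd.read_csv(path, sep="\t", comment="#")
    out: Dict[str, float] = {}
    for _, row in df.iterrows():
        key = str(row["variant_key"])
        val = float(row["mirsvr"])
        out[key] = min(val, out[key]) if key in out else val
    return out
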