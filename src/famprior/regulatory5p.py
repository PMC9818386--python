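"""Regulatory annotation of upstream / 5'UTR variants.

Evidence layers: promoter and CpG-island membership (interval tracks),
chromatin state across up to 127 cell lines (ChromHMM 15-state model) and
histone marks across up to 14 lines, Segway labels, TF ChIP-seq peak
overlap, and PWM-based ref-vs-alt motif scanning over a +/-10 bp window
around the variant to call transcription-factor binding sites gained or
lost by the alternate allele.

PWM scanning: position frequency matrices are smoothed with a total
pseudocount of 0.8 split by the uniform background (0.2 per base),
converted to log-odds against that background, and every placement on both
strands is scored.  Scores are reported on the relative 0-1 scale
(S - Smin) / (Smax - Smin); a site is called at relative score >= 0.80 by
default (the threshold commonly used with JASPAR matrices).
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, FrozenSet, List, Mapping, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd

from .types import IntervalTrack, PWM, VariantRecord

log = logging.getLogger(__name__)

__all__ = [
    "CHROMHMM_STATES",
    "ChromatinProfile",
    "Annotated5p",
    "MotifCall",
    "MotifDelta",
    "ScanHit",
    "intersect_track",
    "summarize_chromatin",
    "count_tfbs",
    "pwm_relative_score",
    "motif_delta",
    "annotate_5p",
    "read_chromatin_profiles",
    "revcomp",
]

#: ChromHMM 15-state vocabulary
CHROMHMM_STATES = frozenset(
    {
        "TssA", "TssAFlnk", "TxFlnk", "Tx", "TxWk", "EnhG", "Enh", "ZNF/Rpts",
        "Het", "TssBiv", "BivFlnk", "EnhBiv", "ReprPC", "ReprPCWk", "Quies",
    }
)

# aliases seen in annotation exports
_STATE_ALIASES = {
    "RepPC": "ReprPC",
    "RepPCWk": "ReprPCWk",
    "PCWk": "ReprPCWk",
    "TssFlnk": "TssAFlnk",
    "Biv": "BivFlnk",
    "ZNF": "ZNF/Rpts",
}


def normalize_state(label: str) -> str:
    label = label.strip()
    label = _STATE_ALIASES.get(label, label)
    if label not in CHROMHMM_STATES:
        raise ValueError(f"unknown ChromHMM state label: {label!r}")
    return label


@dataclass(slots=True)
class ChromatinProfile:
    """Chromatin context of one locus across profiled cell lines."""

    chmm_states: Dict[str, str] = field(default_factory=dict)  # cell line -> state
    histone_marks: Dict[str, FrozenSet[str]] = field(default_factory=dict)
    segway: Optional[str] = None
    gc_percent: Optional[float] = None

    def __post_init__(self) -> None:
        self.chmm_states = {k: normalize_state(v) for k, v in self.chmm_states.items()}


def summarize_chromatin(
    profile: ChromatinProfile,
    chmm_min_frac: float = 0.20,
    histone_min_frac: float = 0.20,
) -> Tuple[FrozenSet[str], FrozenSet[str]]:
    """Summarize per-cell-line chromatin context.

    Returns the ChromHMM states present in at least ``chmm_min_frac``
    (inclusive, >= 20%) of the cell lines that have a state assigned, and
    the histone marks present in strictly more than ``histone_min_frac``
    (> 20%) of the profiled lines.  The output does not depend on cell-line
    ordering.
    """
    n_states = len(profile.chmm_states)
    n_marks = len(profile.histone_marks)
    if n_states == 0 and n_marks == 0:
        log.warning("chromatin profile with zero profiled cell lines")
        return frozenset(), frozenset()
    chmm: FrozenSet[str] = frozenset()
    if n_states:
        counts: Dict[str, int] = {}
        for state in profile.chmm_states.values():
            counts[state] = counts.get(state, 0) + 1
        chmm = frozenset(s for s, c in counts.items() if c / n_states >= chmm_min_frac)
    marks: FrozenSet[str] = frozenset()
    if n_marks:
        counts = {}
        for mark_set in profile.histone_marks.values():
            for mark in mark_set:
                counts[mark] = counts.get(mark, 0) + 1
        marks = frozenset(m for m, c in counts.items() if c / n_marks > histone_min_frac)
    return chmm, marks


def intersect_track(variant: VariantRecord, track: IntervalTrack) -> bool:
    """True iff the variant's genomic footprint overlaps any track interval
    (>= 1 bp, or point containment for zero-length insertion footprints).
    A chromosome absent from the track simply gives False."""
    start, end = variant.interval
    return bool(track.overlapping(variant.chrom, start, end))


def count_tfbs(
    variant: VariantRecord, chip_track: IntervalTrack, tf_attr: str = "tf_name"
) -> Tuple[int, List[str]]:
    """Count distinct transcription factors whose ChIP-seq peaks overlap the
    variant; returns (count, sorted TF names)."""
    start, end = variant.interval
    names = sorted(
        {
            iv.attributes[tf_attr]
            for iv in chip_track.overlapping(variant.chrom, start, end)
            if tf_attr in iv.attributes
        }
    )
    return len(names), names


# ---------------------------------------------------------------------------
# PWM scanning

_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3}
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.upper().translate(_COMPLEMENT)[::-1]


def _log_odds(pwm: PWM, pseudocount_total: float = 0.8) -> np.ndarray:
    """Column-normalized log2-odds versus the uniform 0.25 background, after
    adding ``pseudocount_total`` split evenly across the four bases."""
    counts = pwm.counts + pseudocount_total / 4.0
    probs = counts / counts.sum(axis=0, keepdims=True)
    return np.log2(probs / 0.25)


@dataclass(frozen=True, slots=True)
class ScanHit:
    """Best-scoring placement of a PWM on a sequence."""

    score: float  # relative score in [0, 1]
    offset: int  # 0-based offset on the forward sequence
    strand: str  # '+' or '-'


def pwm_relative_score(
    pwm: PWM, seq: str, pseudocount_total: float = 0.8
) -> Optional[ScanHit]:
    """Best relative score of ``pwm`` over all placements on both strands.

    The relative score of a placement is (S - Smin) / (Smax - Smin), where
    Smin/Smax are the per-matrix extreme log-odds sums; it is 1.0 on the
    consensus sequence and 0.0 on the anti-consensus.  Placements whose
    window contains ``N`` are unscannable and skipped.  Returns ``None``
    when no placement fits (sequence shorter than the motif, or all
    placements contain N).
    """
    seq = seq.upper()
    L = pwm.length
    if len(seq) < L:
        return None
    lo = _log_odds(pwm, pseudocount_total)
    smin = float(lo.min(axis=0).sum())
    smax = float(lo.max(axis=0).sum())
    span = smax - smin

    best: Optional[ScanHit] = None
    for strand in ("+", "-"):
        scan_seq = seq if strand == "+" else revcomp(seq)
        for off in range(len(scan_seq) - L + 1):
            window = scan_seq[off : off + L]
            if "N" in window:
                continue
            s = sum(lo[_BASE_INDEX[b], j] for j, b in enumerate(window))
            rel = 1.0 if span == 0 else (s - smin) / span
            fwd_off = off if strand == "+" else len(seq) - L - off
            hit = ScanHit(rel, fwd_off, strand)
            if (
                best is None
                or hit.score > best.score + 1e-12
                or (
                    abs(hit.score - best.score) <= 1e-12
                    and (hit.strand, hit.offset) < (best.strand, best.offset)
                )
            ):
                best = hit
    return best


class MotifCall(enum.Enum):
    GAINED = "GAINED"
    LOST = "LOST"
    UNCHANGED = "UNCHANGED"


@dataclass(frozen=True, slots=True)
class MotifDelta:
    """Ref-vs-alt binding-site call for one PWM at one variant."""

    pwm_id: str
    tf_name: str
    strand: Optional[str]
    ref_score: Optional[float]
    alt_score: Optional[float]
    call: MotifCall


def build_alt_window(ref_window: str, ref: str, alt: str, flank: int = 10) -> str:
    """Splice the alternate allele into the reference context window.

    ``ref_window`` must hold the reference allele starting at position
    ``flank`` (i.e. the variant with ``flank`` bp of context on each side);
    indel windows may change length and are scanned fully.
    """
    ref_window = ref_window.upper()
    if ref_window[flank : flank + len(ref)] != ref.upper():
        raise ValueError(
            f"reference allele {ref!r} not found at the center of window "
            f"{ref_window!r} (offset {flank})"
        )
    return ref_window[:flank] + alt.upper() + ref_window[flank + len(ref) :]


def motif_delta(
    variant: VariantRecord,
    ref_window: str,
    pwm_set: Sequence[PWM],
    tau: float = 0.80,
    flank: int = 10,
    pseudocount_total: float = 0.8,
) -> List[MotifDelta]:
    """Call TFBS gain/loss per PWM between the reference and alternate
    windows around a variant.

    GAINED: alt best relative score >= tau while ref best < tau; LOST is
    the mirror image; anything else (including unscannable windows) is
    UNCHANGED.  Swapping the ref and alt windows maps GAINED <-> LOST.
    """
    alt_window = build_alt_window(ref_window, variant.ref, variant.alt, flank)
    out: List[MotifDelta] = []
    for pwm in pwm_set:
        ref_hit = pwm_relative_score(pwm, ref_window, pseudocount_total)
        alt_hit = pwm_relative_score(pwm, alt_window, pseudocount_total)
        ref_s = ref_hit.score if ref_hit else None
        alt_s = alt_hit.score if alt_hit else None
        ref_pass = ref_s is not None and ref_s >= tau
        alt_pass = alt_s is not None and alt_s >= tau
        if alt_pass and not ref_pass:
            call, strand = MotifCall.GAINED, alt_hit.strand
        elif ref_pass and not alt_pass:
            call, strand = MotifCall.LOST, ref_hit.strand
        else:
            call = MotifCall.UNCHANGED
            top = max(
                (h for h in (ref_hit, alt_hit) if h is not None),
                key=lambda h: h.score,
                default=None,
            )
            strand = top.strand if top else None
        out.append(MotifDelta(pwm.id, pwm.tf_name, strand, ref_s, alt_s, call))
    return out


# ---------------------------------------------------------------------------
# Driver


@dataclass(slots=True)
class Annotated5p:
    """Full regulatory annotation of one upstream/5'UTR variant.

    ``in_promoter`` / ``in_cpg`` are tri-state: True/False when the
    corresponding track was supplied, ``None`` (unknown) otherwise.
    """

    variant_key: str
    gene: Optional[str] = None
    in_promoter: Optional[bool] = None
    in_cpg: Optional[bool] = None
    chmm_summary: FrozenSet[str] = frozenset()
    histone_summary: FrozenSet[str] = frozenset()
    segway: Optional[str] = None
    tfbs_count: Optional[int] = None
    tfbs_names: List[str] = field(default_factory=list)
    conserved_tfbs: List[str] = field(default_factory=list)
    motif_deltas: List[MotifDelta] = field(default_factory=list)


def annotate_5p(
    variant: VariantRecord,
    promoter_track: Optional[IntervalTrack] = None,
    cpg_track: Optional[IntervalTrack] = None,
    chip_track: Optional[IntervalTrack] = None,
    chromatin: Optional[ChromatinProfile] = None,
    pwms: Optional[Sequence[PWM]] = None,
    ref_window: Optional[str] = None,
    tau: float = 0.80,
) -> Annotated5p:
    """Assemble the 5'-branch annotation for one variant from whichever
    evidence layers were supplied; unsupplied layers stay unknown/empty."""
    ann = Annotated5p(variant_key=variant.key, gene=variant.gene)
    if promoter_track is not None:
        ann.in_promoter = intersect_track(variant, promoter_track)
    if cpg_track is not None:
        ann.in_cpg = intersect_track(variant, cpg_track)
    if chip_track is not None:
        ann.tfbs_count, ann.tfbs_names = count_tfbs(variant, chip_track)
    if chromatin is not None:
        ann.chmm_summary, ann.histone_summary = summarize_chromatin(chromatin)
        ann.segway = chromatin.segway
    if pwms is not None and ref_window is not None:
        ann.motif_deltas = motif_delta(variant, ref_window, pwms, tau=tau)
    return ann


# ---------------------------------------------------------------------------
# Chromatin profile IO


def read_chromatin_profiles(
    path: str | Path, segway_path: Optional[str | Path] = None
) -> Dict[str, ChromatinProfile]:
    """Read per-variant chromatin context tables.

    ``path``: TSV with columns ``variant_key, cell_line, chmm_state,
    histone_marks``.  The two profiling panels are independent: an empty
    ``chmm_state`` means the line is not state-profiled, an empty
    ``histone_marks`` means the line is not histone-profiled, and the
    sentinel ``-`` means histone-profiled with no mark present (it counts
    in the histone denominator).  ``segway_path``: optional TSV with
    columns ``variant_key, segway`` and optionally ``gc_percent``.
    """
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    profiles: Dict[str, ChromatinProfile] = {}
    for _, row in df.iterrows():
        prof = profiles.setdefault(row["variant_key"], ChromatinProfile())
        line = row["cell_line"]
        state = row.get("chmm_state")
        if isinstance(state, str) and state.strip():
            prof.chmm_states[line] = normalize_state(state)
        marks = row.get("histone_marks")
        if isinstance(marks, str) and marks.strip():
            prof.histone_marks[line] = frozenset(
                m.strip() for m in marks.split(",") if m.strip() and m.strip() != "-"
            )
    if segway_path is not None:
        seg = pd.read_csv(segway_path, sep="\t", comment="#", dtype=str)
        for _, row in seg.iterrows():
            prof = profiles.setdefault(row["variant_key"], ChromatinProfile())
            prof.segway = row["segway"]
            gc = row.get("gc_percent")
            if isinstance(gc, str) and gc.strip():
                prof.gc_percent = float(gc)
    return profiles
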