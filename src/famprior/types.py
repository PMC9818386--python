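"""Core domain types shared across the prioritization pipeline.

All genomic coordinates are 0-based half-open internally; VCF's 1-based
positions are converted at the ingestion boundary (see
:attr:`VariantRecord.interval`).  Chromosome names are normalized by
stripping any leading ``chr`` so that cohorts and annotation tracks with
mixed conventions can be intersected.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Dict, FrozenSet, List, Mapping, Optional, Tuple

import numpy as np
from intervaltree import IntervalTree

__all__ = [
    "Category",
    "Diagnosis",
    "Genotype",
    "VariantRecord",
    "Individual",
    "Family",
    "GenomicInterval",
    "IntervalTrack",
    "PWM",
    "GeneSetCollection",
    "ScoreBundle",
    "normalize_chrom",
]


def normalize_chrom(chrom: str) -> str:
    """Strip a leading ``chr``/``Chr`` prefix from a chromosome name."""
    c = chrom.strip()
    if c.lower().startswith("chr"):
        c = c[3:]
    return c


class Category(enum.Enum):
    """Functional category of a variant, as assigned by gene-model annotation."""

    UTR5 = "UTR5"
    UTR3 = "UTR3"
    UTR5_UTR3 = "UTR5_UTR3"
    UPSTREAM = "upstream"
    DOWNSTREAM = "downstream"
    UPSTREAM_DOWNSTREAM = "upstream_downstream"
    EXONIC = "exonic"
    INTRONIC = "intronic"
    INTERGENIC = "intergenic"
    SPLICING = "splicing"

    @classmethod
    def parse(cls, label: str) -> "Category":
        """Map an annotation label (including the two combined ``;`` labels)
        onto the category vocabulary.  Any other compound label is rejected.
        """
        raw = label.strip()
        norm = (
            raw.replace("′", "'")  # prime -> ASCII apostrophe
            .replace("'", "")
            .replace("-", "")
            .replace(" ", "")
            .lower()
        )
        simple = {
            "utr5": cls.UTR5,
            "5utr": cls.UTR5,
            "utr3": cls.UTR3,
            "3utr": cls.UTR3,
            "upstream": cls.UPSTREAM,
            "downstream": cls.DOWNSTREAM,
            "exonic": cls.EXONIC,
            "intronic": cls.INTRONIC,
            "intergenic": cls.INTERGENIC,
            "splicing": cls.SPLICING,
        }
        if norm in simple:
            return simple[norm]
        if ";" in norm:
            parts = frozenset(norm.split(";"))
            if parts == frozenset({"upstream", "downstream"}):
                return cls.UPSTREAM_DOWNSTREAM
            if parts in (frozenset({"utr5", "utr3"}), frozenset({"5utr", "3utr"})):
                return cls.UTR5_UTR3
        if norm in ("upstream_downstream", "utr5_utr3"):
            return cls.UPSTREAM_DOWNSTREAM if "upstream" in norm else cls.UTR5_UTR3
        raise ValueError(f"unrecognized functional category label: {label!r}")


#: categories annotated on the 5' (upstream / 5'UTR) branch
FIVE_PRIME_CATEGORIES = frozenset(
    {Category.UTR5, Category.UTR5_UTR3, Category.UPSTREAM, Category.UPSTREAM_DOWNSTREAM}
)
#: categories annotated on the 3' (3'UTR) branch
THREE_PRIME_CATEGORIES = frozenset({Category.UTR3, Category.UTR5_UTR3})


class Diagnosis(enum.Enum):
    """Plasma-cell disease status of a pedigree member."""

    MM = "MM"
    SMM = "SMM"
    MGUS = "MGUS"
    AL_AMYLOIDOSIS = "AL_AMYLOIDOSIS"
    PLASMA_CELL_DYSCRASIA = "PLASMA_CELL_DYSCRASIA"
    SOLITARY_PLASMACYTOMA = "SOLITARY_PLASMACYTOMA"
    ABERRANT_PLASMA_CLONE = "ABERRANT_PLASMA_CLONE"
    HEALTHY = "HEALTHY"

    @classmethod
    def parse(cls, label: str) -> "Diagnosis":
        norm = label.strip().upper().replace(" ", "_").replace("-", "_")
        aliases = {
            "AL": cls.AL_AMYLOIDOSIS,
            "AMYLOIDOSIS": cls.AL_AMYLOIDOSIS,
            "UNAFFECTED": cls.HEALTHY,
            "CONTROL": cls.HEALTHY,
        }
        if norm in cls.__members__:
            return cls[norm]
        if norm in aliases:
            return aliases[norm]
        raise ValueError(f"unknown diagnosis: {label!r}")


@dataclass(frozen=True, slots=True)
class Genotype:
    """Per-sample call for one biallelic variant.

    ``alt_count`` is the number of alternate alleles (0/1/2); it is ``None``
    when the call is missing.  ``depth`` is the read depth at the site.
    """

    alt_count: Optional[int]
    depth: Optional[int]
    missing: bool = False

    @property
    def carries(self) -> bool:
        """True when the sample carries >= 1 alternate allele (dominant model)."""
        return (not self.missing) and self.alt_count is not None and self.alt_count >= 1

    def masked(self) -> "Genotype":
        return Genotype(alt_count=None, depth=self.depth, missing=True)


@dataclass(slots=True)
class VariantRecord:
    """One biallelic variant site with per-sample genotypes.

    ``pos`` follows the VCF convention (1-based, indels anchored on the
    preceding reference base).
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    category: Optional[Category] = None
    gene: Optional[str] = None
    genotypes: Dict[str, Genotype] = field(default_factory=dict)
    af_gnomad_exome: Optional[float] = None
    af_gnomad_genome: Optional[float] = None
    local_freq: Optional[float] = None

    def __post_init__(self) -> None:
        self.chrom = normalize_chrom(self.chrom)
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        if self.ref == self.alt:
            raise ValueError(f"ref == alt ({self.ref!r}) at {self.chrom}:{self.pos}")
        for af in (self.af_gnomad_exome, self.af_gnomad_genome, self.local_freq):
            if af is not None and not (0.0 <= af <= 1.0):
                raise ValueError(f"allele frequency out of [0,1]: {af}")

    @property
    def key(self) -> str:
        return f"{self.chrom}_{self.pos}_{self.ref}_{self.alt}"

    @property
    def interval(self) -> Tuple[int, int]:
        """0-based half-open genomic footprint of the variant.

        Length-preserving changes span the reference bases.  For anchored
        indels the shared anchor base is excluded: a deletion spans the
        deleted bases only, an insertion is the zero-length point after the
        anchor.  Unanchored block substitutions span the full ref allele.
        """
        p0 = self.pos - 1
        lr, la = len(self.ref), len(self.alt)
        if lr == la:
            return (p0, p0 + lr)
        anchored = self.ref[0] == self.alt[0]
        if anchored and lr > la:  # deletion
            return (p0 + 1, p0 + lr)
        if anchored and lr < la:  # insertion
            return (p0 + 1, p0 + 1)
        return (p0, p0 + lr)

    def carriers(self) -> List[str]:
        return sorted(s for s, g in self.genotypes.items() if g.carries)


@dataclass(slots=True)
class Individual:
    individual_id: str
    family_id: str
    father: Optional[str] = None
    mother: Optional[str] = None
    sex: Optional[int] = None
    diagnosis: Diagnosis = Diagnosis.HEALTHY
    age_at_diagnosis: Optional[float] = None
    age_at_last_followup: Optional[float] = None


@dataclass(slots=True)
class Family:
    family_id: str
    members: List[Individual] = field(default_factory=list)

    @property
    def member_ids(self) -> List[str]:
        return [m.individual_id for m in self.members]

    def __iter__(self):
        return iter(self.members)

    def __len__(self) -> int:
        return len(self.members)


@dataclass(slots=True)
class GenomicInterval:
    chrom: str
    start: int  # 0-based inclusive
    end: int  # 0-based exclusive
    attributes: Dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.chrom = normalize_chrom(self.chrom)
        if self.start >= self.end:
            raise ValueError(
                f"interval start must be < end: {self.chrom}:{self.start}-{self.end}"
            )


class IntervalTrack:
    """A named set of genomic intervals with verbatim attributes.

    Backed by one interval tree per chromosome for overlap queries.
    """

    def __init__(self, name: str, intervals: Optional[List[GenomicInterval]] = None):
        self.name = name
        self.intervals: List[GenomicInterval] = list(intervals or [])
        self._trees: Optional[Dict[str, IntervalTree]] = None

    def add(self, interval: GenomicInterval) -> None:
        self.intervals.append(interval)
        self._trees = None

    def _tree_for(self, chrom: str) -> Optional[IntervalTree]:
        if self._trees is None:
            trees: Dict[str, IntervalTree] = {}
            for iv in self.intervals:
                trees.setdefault(iv.chrom, IntervalTree()).addi(iv.start, iv.end, iv)
            self._trees = trees
        return self._trees.get(normalize_chrom(chrom))

    def overlapping(self, chrom: str, start: int, end: int) -> List[GenomicInterval]:
        """Intervals overlapping [start, end); a zero-length query (start ==
        end, an insertion point) matches intervals containing that point."""
        tree = self._tree_for(chrom)
        if tree is None:
            return []
        hits = tree.at(start) if start == end else tree.overlap(start, end)
        out = [h.data for h in hits]
        out.sort(key=lambda iv: (iv.start, iv.end))
        return out

    def __len__(self) -> int:
        return len(self.intervals)


_PWM_ALPHABET = "ACGT"


@dataclass(slots=True)
class PWM:
    """Position frequency matrix over A,C,G,T (rows) x motif length (columns)."""

    id: str
    tf_name: str
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.ndim != 2 or self.counts.shape[0] != 4:
            raise ValueError(f"PWM {self.id}: counts must be 4 x L")
        if self.counts.shape[1] < 1:
            raise ValueError(f"PWM {self.id}: motif length must be >= 1")
        if np.any(self.counts < 0):
            raise ValueError(f"PWM {self.id}: negative counts")
        if np.any(self.counts.sum(axis=0) <= 0):
            raise ValueError(f"PWM {self.id}: column with no positive count")

    @property
    def length(self) -> int:
        return int(self.counts.shape[1])

    def consensus(self) -> str:
        return "".join(_PWM_ALPHABET[i] for i in np.argmax(self.counts, axis=0))


@dataclass(slots=True)
class GeneSetCollection:
    """Named gene sets (pathways) with an optional explicit background universe."""

    sets: Dict[str, FrozenSet[str]]
    background: Optional[FrozenSet[str]] = None

    def __post_init__(self) -> None:
        for name, members in self.sets.items():
            if not members:
                raise ValueError(f"gene set {name!r} is empty")

    def universe(self) -> FrozenSet[str]:
        if self.background is not None:
            return self.background
        out: set = set()
        for members in self.sets.values():
            out |= members
        return frozenset(out)


@dataclass(slots=True)
class ScoreBundle:
    """Deleteriousness and conservation scores attached to one variant.

    Absent scores are ``None`` (never imputed to zero).  ``passthrough``
    carries annotation-only scores that take no part in any decision.
    """

    cadd_phred: Optional[float] = None
    gerp: Optional[float] = None
    phylop: Optional[float] = None
    phastcons: Optional[float] = None
    passthrough: Dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.phastcons is not None and not (0.0 <= self.phastcons <= 1.0):
            raise ValueError(f"phastcons out of [0,1]: {self.phastcons}")
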