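"""Cohort-level frequency, depth and category filters, plus the pairwise
relatedness concordance check.

These filters run before pedigree segregation.  The relatedness check is
advisory only (it confirms family structure and flags sample mix-ups); it
never removes variants.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Dict, FrozenSet, List, Sequence, Tuple

import numpy as np
import pandas as pd

from .types import Category, VariantRecord

log = logging.getLogger(__name__)

__all__ = [
    "FilterConfig",
    "filter_frequency",
    "apply_depth_mask",
    "filter_category",
    "fill_local_freq",
    "pairwise_concordance",
]

DEFAULT_CATEGORIES = frozenset(
    {
        Category.UTR5,
        Category.UTR3,
        Category.UTR5_UTR3,
        Category.UPSTREAM,
        Category.UPSTREAM_DOWNSTREAM,
    }
)


@dataclass(frozen=True)
class FilterConfig:
    """Thresholds for the pre-segregation cohort filters.

    ``maf_max`` is compared strictly (< 0.001, i.e. rare means MAF below
    0.1%); ``local_freq_max`` inclusively (<= 2% cohort carrier fraction);
    ``min_depth`` of 11 keeps genotypes with read depth > 10.
    """

    maf_max: float = 0.001
    local_freq_max: float = 0.02
    min_depth: int = 11
    categories_kept: FrozenSet[Category] = DEFAULT_CATEGORIES

    def __post_init__(self) -> None:
        for t in (self.maf_max, self.local_freq_max):
            if not (0.0 < t <= 1.0):
                raise ValueError(f"frequency threshold out of (0,1]: {t}")
        if self.min_depth < 1:
            raise ValueError("min_depth must be >= 1")


def filter_frequency(
    variants: Sequence[VariantRecord], cfg: FilterConfig = FilterConfig()
) -> List[VariantRecord]:
    """Keep rare variants: both gnomAD AFs strictly below ``maf_max`` and the
    cohort carrier fraction at most ``local_freq_max``.  An absent frequency
    counts as rare (0)."""
    return [v for v in variants if frequency_pass(v, cfg)]


def frequency_pass(v: VariantRecord, cfg: FilterConfig) -> bool:
    af_ex = v.af_gnomad_exome or 0.0
    af_ge = v.af_gnomad_genome or 0.0
    local = v.local_freq or 0.0
    return af_ex < cfg.maf_max and af_ge < cfg.maf_max and local <= cfg.local_freq_max


def apply_depth_mask(
    variant: VariantRecord, cfg: FilterConfig = FilterConfig()
) -> VariantRecord:
    """Return a copy of the record with low-coverage genotypes set to missing.

    A genotype is masked when its depth is absent or below ``min_depth``
    (default: depth <= 10 is untrusted).  The record is otherwise unchanged.
    """
    genotypes = {
        sid: (g if (g.depth is not None and g.depth >= cfg.min_depth) else g.masked())
        for sid, g in variant.genotypes.items()
    }
    return replace(variant, genotypes=genotypes)


def filter_category(
    variants: Sequence[VariantRecord], cfg: FilterConfig = FilterConfig()
) -> List[VariantRecord]:
    """Keep variants whose functional category is in ``categories_kept``
    (default: the regulatory branches — 5'UTR, 3'UTR, combined UTRs,
    upstream, upstream+downstream)."""
    return [v for v in variants if v.category in cfg.categories_kept]


def fill_local_freq(
    variants: Sequence[VariantRecord], overwrite: bool = False
) -> List[VariantRecord]:
    """Populate ``local_freq`` as the cohort carrier fraction.

    The denominator is the number of genotyped (non-missing) cohort samples
    for the variant.  Records that already carry an externally supplied
    local frequency are left alone unless ``overwrite`` is set.
    """
    out = []
    for v in variants:
        if v.local_freq is not None and not overwrite:
            out.append(v)
            continue
        genotyped = [g for g in v.genotypes.values() if not g.missing]
        carriers = sum(1 for g in genotyped if g.carries)
        freq = carriers / len(genotyped) if genotyped else 0.0
        out.append(replace(v, local_freq=freq))
    return out


def pairwise_concordance(
    variants: Sequence[VariantRecord], samples: Sequence[str]
) -> pd.DataFrame:
    """Jaccard concordance of carried-variant sets between every sample pair.

    Entry (i, j) is |shared carried variants| / |union of carried variants|;
    the diagonal is 1.  Used to confirm family relatedness and catch sample
    mix-ups — this is a report, never a filter.  A pair in which both
    samples carry nothing gets 0 with a logged warning.
    """
    if len(samples) < 2:
        raise ValueError("pairwise concordance needs >= 2 samples")
    carried: Dict[str, set] = {s: set() for s in samples}
    for v in variants:
        for s in samples:
            g = v.genotypes.get(s)
            if g is not None and g.carries:
                carried[s].add(v.key)
    n = len(samples)
    mat = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            a, b = carried[samples[i]], carried[samples[j]]
            union = len(a | b)
            if union == 0:
                log.warning(
                    "samples %s and %s carry no variants; concordance set to 0",
                    samples[i],
                    samples[j],
                )
                val = 0.0
            else:
                val = len(a & b) / union
            mat[i, j] = mat[j, i] = val
    return pd.DataFrame(mat, index=list(samples), columns=list(samples))
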