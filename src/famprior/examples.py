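"""Worked-example data: the published shortlist tables of a familial
multiple-myeloma cohort.

Two small annotation tables ship with the package, encoding the printed
top-candidate tables of a 14-family whole-genome study: twenty annotated
upstream/5'UTR variants and seven annotated 3'UTR variants, with their
CADD scores, 0-3 conservation composites, CpG/promoter membership, Segway
labels, summarized ChromHMM states, histone marks and mirSVR scores.
Promoter membership is tri-state: it is True for the variants whose
promoter annotation is stated in the study's results narrative and unknown
for the rest.  miRNA site identities are placeholders (synthetic names);
the binding flag and the high/low context++ percentile class are the
encoded facts.

These fixtures drive the documentation example and the end-to-end checks
of the branch shortlist rules.
"""

from __future__ import annotations

from importlib import resources
from typing import List, Tuple

import pandas as pd

from .regulatory3p import Annotated3p, MiRNATargetSite, gene_end_context
from .regulatory5p import Annotated5p, normalize_state
from .scores import ConservationComposite

__all__ = ["load_five_prime_example", "load_three_prime_example"]


def _read(name: str) -> pd.DataFrame:
    with resources.files("famprior.data").joinpath(name).open() as fh:
        return pd.read_csv(fh, sep="\t", dtype=str)


def _states(cell: str) -> frozenset:
    if not isinstance(cell, str) or not cell.strip():
        return frozenset()
    return frozenset(normalize_state(s) for s in cell.split(",") if s.strip())


def load_five_prime_example() -> List[Tuple[Annotated5p, ConservationComposite]]:
    """The twenty annotated upstream/5'UTR variants of the worked example."""
    df = _read("five_prime_example.tsv")
    out: List[Tuple[Annotated5p, ConservationComposite]] = []
    for _, row in df.iterrows():
        promoter = {"yes": True, "no": False}.get(str(row["promoter"]).lower())
        histone = (
            frozenset(m.strip() for m in row["histone"].split(","))
            if isinstance(row["histone"], str) and row["histone"].strip()
            else frozenset()
        )
        n_tfs = None if str(row["n_tfs"]) in ("NA", "nan") else int(row["n_tfs"])
        ann = Annotated5p(
            variant_key=row["variant_key"],
            gene=row["gene"],
            in_promoter=promoter,
            in_cpg=str(row["cpg"]).lower() == "yes",
            chmm_summary=_states(row["chmm"]),
            histone_summary=histone,
            segway=row["segway"],
            tfbs_count=n_tfs,
        )
        out.append((ann, ConservationComposite.from_score(int(row["cons_score"]))))
    return out


def load_three_prime_example() -> List[Tuple[Annotated3p, ConservationComposite]]:
    """The seven annotated 3'UTR variants of the worked example."""
    df = _read("three_prime_example.tsv")
    out: List[Tuple[Annotated3p, ConservationComposite]] = []
    for _, row in df.iterrows():
        chmm = _states(row["chmm"])
        hits: List[MiRNATargetSite] = []
        if str(row["mirna_binding"]).lower() == "yes":
            chrom, pos = row["variant_key"].split("_")[:2]
            percentile = 97.0 if str(row["context_hi"]).lower() == "yes" else 75.0
            hits.append(
                MiRNATargetSite(
                    mirna=f"miR-example-{row['gene']}",
                    gene=row["gene"],
                    chrom=chrom,
                    start=int(pos) - 11,
                    end=int(pos) + 10,
                    context_pp_percentile=percentile,
                )
            )
        ann = Annotated3p(
            variant_key=row["variant_key"],
            gene=row["gene"],
            mirna_hits=hits,
            mirsvr=float(row["mirsvr"]),
            segway=row["segway"],
            chmm_summary=chmm,
            gene_end=gene_end_context(row["segway"], chmm),
        )
        out.append((ann, ConservationComposite.from_score(int(row["cons_score"]))))
    return out
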