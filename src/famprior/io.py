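"""Readers and writers for the external formats the pipeline touches.

Coordinate conventions are handled explicitly at this boundary: VCF
positions are 1-based, BED intervals 0-based half-open; everything
downstream of ingestion is 0-based half-open (see :mod:`famprior.types`).
"""

from __future__ import annotations

import math
import warnings
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from Bio import SeqIO, motifs as bio_motifs
from cyvcf2 import VCF

from .types import (
    Category,
    Diagnosis,
    Family,
    GeneSetCollection,
    GenomicInterval,
    Genotype,
    Individual,
    IntervalTrack,
    PWM,
    ScoreBundle,
    VariantRecord,
    normalize_chrom,
)

__all__ = [
    "FormatError",
    "read_vcf",
    "read_pedigree",
    "read_score_table",
    "read_bed",
    "write_bed",
    "read_pfm_jaspar",
    "read_gmt",
    "read_fasta_windows",
]

ScoreKey = Tuple[str, int, str, str]


class FormatError(ValueError):
    """Raised when an input file violates its format contract."""


# ---------------------------------------------------------------------------
# VCF

#: INFO keys carrying the per-variant annotations the pipeline consumes
INFO_GENE = "GENE"
INFO_CATEGORY = "FUNC"
INFO_AF_EXOME = "AF_GE"
INFO_AF_GENOME = "AF_GG"
INFO_LOCAL_FREQ = "LOCAL_FREQ"


def read_vcf(path: str | Path, sample_ids: Sequence[str]) -> List[VariantRecord]:
    """Read a multi-sample VCF into biallelic :class:`VariantRecord` objects.

    Multi-allelic sites are decomposed into one record per alternate allele,
    with per-sample alt-allele counts re-coded against that allele.  A
    genotype with any missing allele (``./.`` or half-calls) is flagged
    missing.  ``sample_ids`` must all be present in the VCF header.

    Gene symbol, functional category and population frequencies are taken
    from the INFO keys ``GENE``, ``FUNC``, ``AF_GE``, ``AF_GG`` and
    ``LOCAL_FREQ`` when present.
    """
    path = str(path)
    sample_ids = list(sample_ids)
    probe = VCF(path)
    header_samples = set(probe.samples)
    probe.close()
    absent = [s for s in sample_ids if s not in header_samples]
    if absent:
        raise FormatError(f"samples absent from VCF header: {', '.join(absent)}")

    vcf = VCF(path, samples=sample_ids)
    order = {s: i for i, s in enumerate(vcf.samples)}
    records: List[VariantRecord] = []
    try:
        for var in vcf:
            where = f"{var.CHROM}:{var.POS}"
            if "GT" not in (var.FORMAT or []):
                raise FormatError(f"missing GT field at {where}")
            gts = var.genotypes  # [[a0, a1, phased], ...]
            dp = var.format("DP")
            info_gene = var.INFO.get(INFO_GENE)
            info_cat = var.INFO.get(INFO_CATEGORY)
            category = Category.parse(info_cat) if info_cat is not None else None
            af_ex = var.INFO.get(INFO_AF_EXOME)
            af_ge = var.INFO.get(INFO_AF_GENOME)
            local = var.INFO.get(INFO_LOCAL_FREQ)
            for ai, alt in enumerate(var.ALT, start=1):
                genotypes: Dict[str, Genotype] = {}
                for sid in sample_ids:
                    alleles = gts[order[sid]][:-1]
                    depth = None
                    if dp is not None:
                        d = int(dp[order[sid]][0])
                        depth = d if d >= 0 else None
                    if any(a < 0 for a in alleles):
                        genotypes[sid] = Genotype(None, depth, missing=True)
                    else:
                        genotypes[sid] = Genotype(
                            sum(1 for a in alleles if a == ai), depth
                        )
                try:
                    records.append(
                        VariantRecord(
                            chrom=var.CHROM,
                            pos=var.POS,
                            ref=var.REF,
                            alt=alt,
                            category=category,
                            gene=info_gene,
                            genotypes=genotypes,
                            af_gnomad_exome=float(af_ex) if af_ex is not None else None,
                            af_gnomad_genome=float(af_ge) if af_ge is not None else None,
                            local_freq=float(local) if local is not None else None,
                        )
                    )
                except ValueError as exc:
                    raise FormatError(f"invalid record at {where}: {exc}") from exc
    finally:
        vcf.close()
    return records


# ---------------------------------------------------------------------------
# Pedigree + phenotypes


def read_pedigree(ped_path: str | Path, pheno_path: str | Path) -> List[Family]:
    """Assemble families from a 6-column PED file and a phenotype table.

    The phenotype table is a TSV with columns ``individual_id``,
    ``diagnosis``, ``age_at_diagnosis`` and ``age_at_last_followup``.
    Every individual must appear in both files exactly once; unknown
    diagnosis strings are collected and reported together.
    """
    ped = pd.read_csv(
        ped_path,
        sep=r"\s+",
        comment="#",
        header=None,
        names=["family_id", "individual_id", "father", "mother", "sex", "phenotype"],
        dtype=str,
    )
    if ped.empty:
        raise FormatError(f"empty PED file: {ped_path}")
    if ped["individual_id"].duplicated().any():
        dups = sorted(ped.loc[ped["individual_id"].duplicated(), "individual_id"])
        raise FormatError(f"duplicated individual id(s) in PED: {', '.join(dups)}")

    pheno = pd.read_csv(pheno_path, sep="\t", comment="#", dtype=str)
    required = {"individual_id", "diagnosis", "age_at_diagnosis", "age_at_last_followup"}
    if pheno.empty or not required.issubset(pheno.columns):
        raise FormatError(
            f"phenotype table must have columns {sorted(required)}: {pheno_path}"
        )
    if pheno["individual_id"].duplicated().any():
        dups = sorted(pheno.loc[pheno["individual_id"].duplicated(), "individual_id"])
        raise FormatError(f"duplicated individual id(s) in phenotypes: {', '.join(dups)}")

    ped_ids = set(ped["individual_id"])
    ph_ids = set(pheno["individual_id"])
    orphans = sorted(ph_ids - ped_ids)
    if orphans:
        raise FormatError(
            f"individuals in phenotype table absent from PED: {', '.join(orphans)}"
        )
    missing = sorted(ped_ids - ph_ids)
    if missing:
        raise FormatError(
            f"PED individuals missing from phenotype table: {', '.join(missing)}"
        )

    bad: List[str] = []
    diagnoses: Dict[str, Diagnosis] = {}
    for _, row in pheno.iterrows():
        try:
            diagnoses[row["individual_id"]] = Diagnosis.parse(row["diagnosis"])
        except ValueError:
            bad.append(str(row["diagnosis"]))
    if bad:
        raise FormatError(f"unknown diagnosis value(s): {', '.join(sorted(set(bad)))}")

    def _age(value) -> Optional[float]:
        if value is None or (isinstance(value, float) and math.isnan(value)):
            return None
        s = str(value).strip()
        if s in ("", "NA", "nan", "."):
            return None
        return float(s)

    ages = {
        row["individual_id"]: (
            _age(row["age_at_diagnosis"]),
            _age(row["age_at_last_followup"]),
        )
        for _, row in pheno.iterrows()
    }

    families: Dict[str, Family] = {}
    for _, row in ped.iterrows():
        iid = row["individual_id"]
        dx_age, fu_age = ages[iid]
        ind = Individual(
            individual_id=iid,
            family_id=row["family_id"],
            father=None if row["father"] in ("0", None) else row["father"],
            mother=None if row["mother"] in ("0", None) else row["mother"],
            sex=int(row["sex"]) if str(row["sex"]).isdigit() else None,
            diagnosis=diagnoses[iid],
            age_at_diagnosis=dx_age,
            age_at_last_followup=fu_age,
        )
        families.setdefault(row["family_id"], Family(row["family_id"])).members.append(ind)
    return [families[fid] for fid in sorted(families)]


# ---------------------------------------------------------------------------
# Score tables


def read_score_table(path: str | Path) -> Dict[ScoreKey, ScoreBundle]:
    """Read a per-variant score TSV into a ``(chrom,pos,ref,alt) -> ScoreBundle`` map.

    Required columns: ``chrom,pos,ref,alt,cadd_phred``.  Optional columns
    ``gerp``, ``phylop``, ``phastcons``; any further numeric column is kept
    as an annotation-only passthrough score.  An absent optional column
    leaves the field absent (``None``), never zero.
    """
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"chrom": str, "ref": str, "alt": str})
    required = ["chrom", "pos", "ref", "alt", "cadd_phred"]
    for col in required:
        if col not in df.columns:
            raise FormatError(f"score table missing column {col!r}: {path}")
    known_optional = ["gerp", "phylop", "phastcons"]
    numeric_cols = ["cadd_phred"] + [c for c in known_optional if c in df.columns]
    extra = [c for c in df.columns if c not in required + known_optional]
    for col in numeric_cols + extra:
        try:
            df[col] = pd.to_numeric(df[col])
        except (ValueError, TypeError) as exc:
            raise FormatError(f"non-numeric value in score column {col!r}: {exc}") from exc

    out: Dict[ScoreKey, ScoreBundle] = {}
    for _, row in df.iterrows():
        key = (normalize_chrom(row["chrom"]), int(row["pos"]), row["ref"], row["alt"])

        def _get(col: str) -> Optional[float]:
            if col not in df.columns:
                return None
            v = row[col]
            return None if pd.isna(v) else float(v)

        bundle = ScoreBundle(
            cadd_phred=_get("cadd_phred"),
            gerp=_get("gerp"),
            phylop=_get("phylop"),
            phastcons=_get("phastcons"),
            passthrough={c: float(row[c]) for c in extra if not pd.isna(row[c])},
        )
        if key in out:
            if out[key] != bundle:
                raise FormatError(f"conflicting duplicate score rows for {key}")
            continue
        out[key] = bundle
    return out


# ---------------------------------------------------------------------------
# BED


def read_bed(path: str | Path, name: str) -> IntervalTrack:
    """Read BED3+ into an :class:`IntervalTrack` (0-based half-open, verbatim
    attributes).

    Attribute columns beyond the first three may be declared by a leading
    comment line ``#chrom start end attr1 attr2 ...``; otherwise columns
    4..6 get the standard BED names (name, score, strand) and further
    columns ``col7``, ``col8``, ...
    """
    track = IntervalTrack(name)
    attr_names: Optional[List[str]] = None
    default_names = ["name", "score", "strand"]
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith("#"):
                fields = line.lstrip("#").split()
                if attr_names is None and len(fields) > 3:
                    attr_names = fields[3:]
                continue
            parts = line.split("\t") if "\t" in line else line.split()
            if len(parts) < 3:
                raise FormatError(f"{path}:{lineno}: BED line with < 3 fields")
            chrom, start_s, end_s = parts[0], parts[1], parts[2]
            try:
                start, end = int(start_s), int(end_s)
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-integer coordinates") from exc
            if start >= end:
                raise FormatError(
                    f"{path}:{lineno}: start must be < end ({start} >= {end})"
                )
            attrs: Dict[str, str] = {}
            for i, value in enumerate(parts[3:]):
                if attr_names is not None and i < len(attr_names):
                    key = attr_names[i]
                elif i < len(default_names):
                    key = default_names[i]
                else:
                    key = f"col{i + 4}"
                attrs[key] = value
            track.add(GenomicInterval(chrom, start, end, attrs))
    return track


def write_bed(track: IntervalTrack, path: str | Path) -> None:
    """Write an :class:`IntervalTrack` to BED with a declared attribute header
    so that re-reading yields identical intervals and attributes."""
    attr_names: List[str] = []
    for iv in track.intervals:
        for key in iv.attributes:
            if key not in attr_names:
                attr_names.append(key)
    with open(path, "w") as fh:
        fh.write("#chrom start end " + " ".join(attr_names) + "\n" if attr_names else "#chrom start end\n")
        for iv in track.intervals:
            fields = [iv.chrom, str(iv.start), str(iv.end)]
            fields += [iv.attributes.get(k, ".") for k in attr_names]
            fh.write("\t".join(fields) + "\n")


# ---------------------------------------------------------------------------
# JASPAR PFM


def read_pfm_jaspar(path: str | Path) -> List[PWM]:
    """Read JASPAR-format position frequency matrices.

    Both text dialects are accepted: ``A [ 4 0 ... ]`` rows with base labels
    and brackets, and bare whitespace-separated count rows in A,C,G,T order.
    Parsing is delegated to :mod:`Bio.motifs`.
    """
    with open(path) as fh:
        try:
            parsed = bio_motifs.parse(fh, "jaspar")
            pwms = []
            for m in parsed:
                counts = np.array([m.counts[b] for b in "ACGT"], dtype=float)
                pwms.append(PWM(id=m.matrix_id or m.name, tf_name=m.name or m.matrix_id, counts=counts))

        except Exception as exc:
            raise FormatError(f"malformed JASPAR PFM file {path}: {exc}") from exc
    if not pwms:
        raise FormatError(f"no matrices found in {path}")
    return pwms


# ---------------------------------------------------------------------------
# GMT


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Read gene sets from GMT (name, description, members...).

    Member symbols are uppercased and deduplicated; duplicate set names and
    lines with fewer than three fields are errors.
    """
    sets: Dict[str, frozenset] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"{path}:{lineno}: GMT line with < 3 fields")
            name = fields[0].strip()
            if name in sets:
                raise FormatError(f"{path}:{lineno}: duplicated gene set name {name!r}")
            members = frozenset(g.strip().upper() for g in fields[2:] if g.strip())
            if not members:
                raise FormatError(f"{path}:{lineno}: gene set {name!r} has no members")
            sets[name] = members
    return GeneSetCollection(sets=sets)


# ---------------------------------------------------------------------------
# FASTA sequence windows


def read_fasta_windows(path: str | Path) -> Dict[str, str]:
    """Read reference sequence windows keyed by FASTA record id (variant key)."""
    return {
        rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")
    }
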