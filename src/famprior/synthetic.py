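"""Seeded generator of a complete synthetic familial-cancer study.

The generator emulates the study conditions of a familial multiple-myeloma
whole-genome cohort: 14 families, each with 2-4 cases (diagnosed 40-75)
plus unaffected members, including one young unaffected member per family
(more than 10 years below the family's earliest diagnosis age, hence a
possible carrier), and rare variants segregating perfectly within a single
family.  Planted top variants carry every annotation the shortlist rules
require; decoy variants are constructed to fail exactly one designated
pipeline stage.  All randomness flows from a single named generator, so a
fixed seed yields byte-identical output files.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np

from .regulatory5p import revcomp

__all__ = ["SynthConfig", "SyntheticStudy", "generate_study", "generate_cohort", "generate_annotations"]

DEFAULT_DECOYS: Mapping[str, int] = {
    "maf": 1,
    "local_freq": 1,
    "depth": 1,
    "category": 1,
    "segregation": 1,
    "cadd": 1,
    "conservation": 1,
    "promoter": 1,
    "mirna": 1,
    "mirsvr": 1,
    "gene_end": 1,
}

#: (stage, named rule) at which each decoy class must be eliminated; for the
#: shortlist stage the rule is the criterion flag that fails
DECOY_DROP = {
    "maf": ("frequency", "maf"),
    "local_freq": ("frequency", "local_freq"),
    "depth": ("segregation", "depth"),
    "category": ("category", "category"),
    "segregation": ("segregation", "segregation"),
    "cadd": ("cadd", "cadd"),
    "conservation": ("shortlist", "conservation"),
    "promoter": ("shortlist", "promoter"),
    "mirna": ("shortlist", "mirna_binding"),
    "mirsvr": ("shortlist", "mirsvr"),
    "gene_end": ("shortlist", "gene_end"),
}

#: pipeline stage at which each decoy class must be eliminated
DECOY_STAGE = {
    "maf": "frequency",
    "local_freq": "frequency",
    "depth": "segregation",
    "category": "category",
    "segregation": "segregation",
    "cadd": "cadd",
    "conservation": "shortlist",
    "promoter": "shortlist",
    "mirna": "shortlist",
    "mirsvr": "shortlist",
    "gene_end": "shortlist",
}

_5P_DECOYS = {"maf", "local_freq", "depth", "category", "segregation", "cadd", "conservation", "promoter"}
_3P_DECOYS = {"mirna", "mirsvr", "gene_end"}


@dataclass(frozen=True)
class SynthConfig:
    """Study-design parameters of the synthetic cohort.

    Defaults mirror the emulated study: 14 families, 2-4 cases each,
    unaffected members including one young possible carrier, rare variants
    (gnomAD AF below 0.1%) private to one family, read depths above the
    >10 trust threshold except where a decoy plants a low-coverage case.
    """

    seed: int = 0
    n_families: int = 14
    cases_per_family: Tuple[int, int] = (2, 4)
    noncarriers_per_family: Tuple[int, int] = (1, 2)
    possible_carriers_per_family: Tuple[int, int] = (0, 1)
    young_unaffected: bool = True
    n_planted_5p: int = 3
    n_planted_3p: int = 3
    decoy_spec: Mapping[str, int] = field(default_factory=lambda: dict(DEFAULT_DECOYS))
    background_genes: int = 1000
    pathway_size: int = 30
    n_filler_pathways: int = 5

    def __post_init__(self) -> None:
        if self.n_families < 1:
            raise ValueError("need at least one family")
        if self.n_planted_5p < 0 or self.n_planted_3p < 0:
            raise ValueError("planted counts must be >= 0")
        unknown = set(self.decoy_spec) - set(DECOY_STAGE)
        if unknown:
            raise ValueError(f"unknown decoy classes: {sorted(unknown)}")
        if any(c < 0 for c in self.decoy_spec.values()):
            raise ValueError("decoy counts must be >= 0")


@dataclass(slots=True)
class _Member:
    sample_id: str
    diagnosis: str
    age_dx: Optional[int]
    age_fu: Optional[int]
    role: str  # case | noncarrier | young | possible


@dataclass(slots=True)
class _FamilyPlan:
    family_id: str
    members: List[_Member]

    @property
    def cases(self) -> List[_Member]:
        return [m for m in self.members if m.role == "case"]

    @property
    def noncarriers(self) -> List[_Member]:
        return [m for m in self.members if m.role == "noncarrier"]

    @property
    def unconstrained(self) -> List[_Member]:
        return [m for m in self.members if m.role in ("young", "possible")]


@dataclass(slots=True)
class _VariantPlan:
    key: str
    chrom: str
    pos: int
    ref: str
    alt: str
    gene: str
    category: str
    family_idx: int
    fate: str  # planted_5p | planted_3p | decoy:<class>
    window: str
    af_exome: Optional[float] = None
    af_genome: Optional[float] = None
    local_freq: Optional[float] = None
    pwm: Optional[Tuple[str, str, str]] = None  # (id, tf_name, consensus)


def _count_occurrences(motif: str, seq: str) -> int:
    n = 0
    for off in range(len(seq) - len(motif) + 1):
        if seq[off : off + len(motif)] == motif:
            n += 1
    return n


def _site_hits(motif: str, seq: str) -> int:
    return _count_occurrences(motif, seq) + _count_occurrences(revcomp(motif), seq)


class SyntheticStudy:
    """Deterministic in-memory plan of the whole synthetic study.

    Construction consumes the RNG in a fixed order; ``write_cohort`` and
    ``write_annotations`` only serialize the plan.
    """

    MOTIF_LEN = 4  # with a consensus-only PWM, one mismatch scores (L-1)/L = 0.75 < 0.80

    def __init__(self, cfg: SynthConfig):
        self.cfg = cfg
        rng = np.random.default_rng(cfg.seed)
        self.families = self._plan_families(rng)
        self.variants = self._plan_variants(rng)
        self._plan_genotypes(rng)
        self._plan_scores(rng)
        self._plan_pathways(rng)

    # -- cohort -------------------------------------------------------------

    def _plan_families(self, rng: np.random.Generator) -> List[_FamilyPlan]:
        cfg = self.cfg
        fams: List[_FamilyPlan] = []
        for fi in range(cfg.n_families):
            fid = f"F{fi + 1:02d}"
            members: List[_Member] = []
            n_cases = int(rng.integers(cfg.cases_per_family[0], cfg.cases_per_family[1] + 1))
            dx_ages = sorted(int(a) for a in rng.integers(40, 76, size=n_cases))
            for ci, age in enumerate(dx_ages):
                dx = str(rng.choice(["MM", "MM", "MGUS", "SMM", "AL_AMYLOIDOSIS"]))
                members.append(
                    _Member(f"{fid}_C{ci + 1}", dx, age, age + int(rng.integers(0, 6)), "case")
                )
            earliest = min(dx_ages)
            n_nc = int(rng.integers(cfg.noncarriers_per_family[0], cfg.noncarriers_per_family[1] + 1))
            for ni in range(n_nc):
                fu = earliest + int(rng.integers(-5, 21))  # within 10 years of earliest dx
                members.append(_Member(f"{fid}_N{ni + 1}", "HEALTHY", None, max(fu, earliest - 5), "noncarrier"))
            if cfg.young_unaffected:
                fu = max(18, earliest - 11 - int(rng.integers(0, 10)))
                members.append(_Member(f"{fid}_Y1", "HEALTHY", None, fu, "young"))
            n_pc = int(
                rng.integers(cfg.possible_carriers_per_family[0], cfg.possible_carriers_per_family[1] + 1)
            )
            for pi in range(n_pc):
                dx = str(
                    rng.choice(["PLASMA_CELL_DYSCRASIA", "SOLITARY_PLASMACYTOMA", "ABERRANT_PLASMA_CLONE"])
                )
                members.append(
                    _Member(f"{fid}_P{pi + 1}", dx, None, earliest + int(rng.integers(-5, 11)), "possible")
                )
            fams.append(_FamilyPlan(fid, members))
        return fams

    @property
    def samples(self) -> List[str]:
        return [m.sample_id for fam in self.families for m in fam.members]

    # -- variants -----------------------------------------------------------

    def _draw_window(self, rng: np.random.Generator, plant_motif: bool) -> Tuple[str, str, str]:
        """A 21-bp reference window, its center ref base and an alt base.

        When ``plant_motif`` is set the window is rejection-sampled so that
        the 4-mer spanning the variant occurs exactly once (either strand)
        in the reference window and never in the alternate window — the
        consensus-only PWM built on it then scores 1.0 on the reference and
        at most 0.75 on the alternate, forcing a LOST call at tau 0.80.
        """
        bases = np.array(list("ACGT"))
        L = self.MOTIF_LEN
        while True:
            w = "".join(rng.choice(bases, size=21))
            ref = w[10]
            alt = str(rng.choice([b for b in "ACGT" if b != ref]))
            if not plant_motif:
                return w, ref, alt
            motif = w[8 : 8 + L]  # covers the variant base at window offset 10
            wa = w[:10] + alt + w[11:]
            if _site_hits(motif, w) == 1 and _site_hits(motif, wa) == 0:
                return w, ref, alt

    def _plan_variants(self, rng: np.random.Generator) -> List[_VariantPlan]:
        cfg = self.cfg
        fates: List[str] = []
        fates += ["planted_5p"] * cfg.n_planted_5p
        fates += ["planted_3p"] * cfg.n_planted_3p
        for cls in sorted(cfg.decoy_spec):
            fates += [f"decoy:{cls}"] * cfg.decoy_spec[cls]

        plans: List[_VariantPlan] = []
        for i, fate in enumerate(fates):
            chrom = str((i % 22) + 1)
            pos = 500_000 + 100_000 * (i + 1)
            gene = f"GENE{i:03d}"
            cls = fate.split(":", 1)[1] if fate.startswith("decoy:") else None
            plant_motif = fate == "planted_5p"
            window, ref, alt = self._draw_window(rng, plant_motif)
            if fate == "planted_3p" or cls in _3P_DECOYS:
                category = "UTR3"
            elif cls == "category":
                category = "intronic"
            else:
                category = str(rng.choice(["UTR5", "upstream"]))
            plan = _VariantPlan(
                key=f"{chrom}_{pos}_{ref}_{alt}",
                chrom=chrom,
                pos=pos,
                ref=ref,
                alt=alt,
                gene=gene,
                category=category,
                family_idx=i % cfg.n_families,
                fate=fate,
                window=window,
            )
            if cls == "maf":
                plan.af_exome = 0.005
                plan.af_genome = 0.002
            else:
                plan.af_exome = float(round(rng.uniform(0, 0.0005), 6))
                plan.af_genome = float(round(rng.uniform(0, 0.0005), 6))
            # frequency in the emulated local set (a collection much larger
            # than the cohort, so family-private variants stay below 2%)
            plan.local_freq = 0.05 if cls == "local_freq" else float(round(rng.uniform(0, 0.015), 4))
            if plant_motif:
                plan.pwm = (f"SYN{i:03d}", f"TF{i:03d}", window[8 : 8 + self.MOTIF_LEN])
            plans.append(plan)
        return plans

    # -- genotypes ----------------------------------------------------------

    def _plan_genotypes(self, rng: np.random.Generator) -> None:
        self.genotypes: Dict[str, Dict[str, Tuple[str, int]]] = {}
        for plan in self.variants:
            cls = plan.fate.split(":", 1)[1] if plan.fate.startswith("decoy:") else None
            fam = self.families[plan.family_idx]
            calls: Dict[str, Tuple[str, int]] = {}
            for fi, family in enumerate(self.families):
                for m in family.members:
                    depth = int(rng.integers(15, 61))
                    gt = "0/0"
                    if fi == plan.family_idx:
                        if m.role == "case":
                            gt = "0/1"
                        elif m.role in ("young", "possible"):
                            gt = "0/1" if rng.random() < 0.5 else "0/0"
                    calls[m.sample_id] = (gt, depth)
            if cls == "segregation":
                first_case = fam.cases[0].sample_id
                calls[first_case] = ("0/0", calls[first_case][1])
            if cls == "depth":
                first_case = fam.cases[0].sample_id
                calls[first_case] = (calls[first_case][0], 8)
            self.genotypes[plan.key] = calls

    # -- scores and annotations ----------------------------------------------

    def _plan_scores(self, rng: np.random.Generator) -> None:
        self.scores: Dict[str, Tuple[float, float, float, float]] = {}
        for plan in self.variants:
            cls = plan.fate.split(":", 1)[1] if plan.fate.startswith("decoy:") else None
            cadd = float(round(rng.uniform(16, 25), 2))
            gerp = float(round(rng.uniform(3, 5.5), 2))
            phylop = float(round(rng.uniform(3.5, 6), 2))
            phastcons = float(round(rng.uniform(0.5, 0.95), 2))
            if cls == "cadd":
                cadd = 12.0
            if cls == "conservation":
                gerp, phylop, phastcons = 1.0, 1.0, 0.1
            self.scores[plan.key] = (cadd, gerp, phylop, phastcons)

    def _plan_pathways(self, rng: np.random.Generator) -> None:
        cfg = self.cfg
        variant_genes = [p.gene for p in self.variants]
        n_bg = max(cfg.background_genes - len(variant_genes), 0)
        background = variant_genes + [f"BG{i:04d}" for i in range(n_bg)]
        self.background = background
        planted_genes = sorted(
            p.gene for p in self.variants if p.fate in ("planted_5p", "planted_3p")
        )
        fillers = [g for g in background if g.startswith("BG")]
        take = max(cfg.pathway_size - len(planted_genes), 0)
        pathway = planted_genes + fillers[:take]
        self.pathways: Dict[str, List[str]] = {"PLANTED_PATHWAY": pathway}
        pool = fillers[take:]
        for pi in range(cfg.n_filler_pathways):
            members = sorted(rng.choice(pool, size=min(20, len(pool)), replace=False).tolist())
            self.pathways[f"FILLER_{pi + 1:02d}"] = members
        self.planted_genes = planted_genes

    # -- serialization -------------------------------------------------------

    def write_cohort(self, outdir: str | Path) -> Dict[str, str]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        ped_path = outdir / "cohort.ped"
        pheno_path = outdir / "phenotypes.tsv"
        vcf_path = outdir / "cohort.vcf"

        with open(ped_path, "w") as fh:
            for fam in self.families:
                for m in fam.members:
                    fh.write(f"{fam.family_id}\t{m.sample_id}\t0\t0\t0\t0\n")
        with open(pheno_path, "w") as fh:
            fh.write("individual_id\tdiagnosis\tage_at_diagnosis\tage_at_last_followup\n")
            for fam in self.families:
                for m in fam.members:
                    dx_age = "" if m.age_dx is None else str(m.age_dx)
                    fu_age = "" if m.age_fu is None else str(m.age_fu)
                    fh.write(f"{m.sample_id}\t{m.diagnosis}\t{dx_age}\t{fu_age}\n")

        samples = self.samples
        with open(vcf_path, "w") as fh:
            fh.write("##fileformat=VCFv4.2\n")
            for c in range(1, 23):
                fh.write(f"##contig=<ID={c}>\n")
            fh.write('##INFO=<ID=GENE,Number=1,Type=String,Description="Gene symbol">\n')
            fh.write('##INFO=<ID=FUNC,Number=1,Type=String,Description="Functional category">\n')
            fh.write('##INFO=<ID=AF_GE,Number=1,Type=Float,Description="gnomAD exome AF">\n')
            fh.write('##INFO=<ID=AF_GG,Number=1,Type=Float,Description="gnomAD genome AF">\n')
            fh.write('##INFO=<ID=LOCAL_FREQ,Number=1,Type=Float,Description="Local-set carrier fraction">\n')
            fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
            fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n')
            fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(samples) + "\n")
            for plan in sorted(self.variants, key=lambda p: (int(p.chrom), p.pos)):
                info = (
                    f"GENE={plan.gene};FUNC={plan.category};"
                    f"AF_GE={plan.af_exome:.6f};AF_GG={plan.af_genome:.6f};"
                    f"LOCAL_FREQ={plan.local_freq:.4f}"
                )
                calls = self.genotypes[plan.key]
                fields = [
                    plan.chrom, str(plan.pos), ".", plan.ref, plan.alt, ".", "PASS",
                    info, "GT:DP",
                ] + [f"{calls[s][0]}:{calls[s][1]}" for s in samples]
                fh.write("\t".join(fields) + "\n")
        return {"ped": str(ped_path), "phenotypes": str(pheno_path), "vcf": str(vcf_path)}

    def write_annotations(self, outdir: str | Path) -> Dict[str, str]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        files: Dict[str, str] = {}

        def cls_of(plan: _VariantPlan) -> Optional[str]:
            return plan.fate.split(":", 1)[1] if plan.fate.startswith("decoy:") else None

        # score table
        scores_path = outdir / "scores.tsv"
        with open(scores_path, "w") as fh:
            fh.write("chrom\tpos\tref\talt\tcadd_phred\tgerp\tphylop\tphastcons\n")
            for plan in self.variants:
                c, g, p, pc = self.scores[plan.key]
                fh.write(f"{plan.chrom}\t{plan.pos}\t{plan.ref}\t{plan.alt}\t{c}\t{g}\t{p}\t{pc}\n")
        files["scores"] = str(scores_path)

        # interval tracks
        def bed(path: Path, rows: List[Tuple[str, int, int, List[str]]], header: str) -> None:
            with open(path, "w") as fh:
                fh.write(header + "\n")
                for chrom, start, end, extra in rows:
                    fh.write("\t".join([chrom, str(start), str(end)] + extra) + "\n")

        five_prime = [
            p for p in self.variants
            if p.fate == "planted_5p" or cls_of(p) in ("conservation", "promoter", "cadd")
        ]
        promoter_rows = [
            (p.chrom, p.pos - 51, p.pos + 50, [f"prom_{p.gene}"])
            for p in five_prime
            if cls_of(p) != "promoter"
        ]
        bed(outdir / "promoters.bed", promoter_rows, "#chrom start end name")
        files["promoters"] = str(outdir / "promoters.bed")

        cpg_rows = [(p.chrom, p.pos - 101, p.pos + 100, [f"cpg_{p.gene}"]) for p in five_prime]
        bed(outdir / "cpg_islands.bed", cpg_rows, "#chrom start end name")
        files["cpg_islands"] = str(outdir / "cpg_islands.bed")

        chip_rows = []
        for p in self.variants:
            if p.fate == "planted_5p":
                for tf in ("CTCF", "EBF1", "PAX5"):
                    chip_rows.append((p.chrom, p.pos - 26, p.pos + 25, [tf]))
        bed(outdir / "chip_peaks.bed", chip_rows, "#chrom start end tf_name")
        files["chip_peaks"] = str(outdir / "chip_peaks.bed")

        atlas_rows = []
        for p in self.variants:
            if p.fate == "planted_3p" or cls_of(p) in ("mirsvr", "gene_end"):
                mirna = f"miR-{int(p.chrom) * 100 + 7}"
                atlas_rows.append(
                    (p.chrom, p.pos - 11, p.pos + 10, [mirna, p.gene, "95.0"])
                )
        bed(outdir / "mirna_atlas.bed", atlas_rows, "#chrom start end mirna gene context_pp_percentile")
        files["mirna_atlas"] = str(outdir / "mirna_atlas.bed")

        # chromatin profiles + segway
        chrom_path = outdir / "chromatin.tsv"
        with open(chrom_path, "w") as fh:
            fh.write("variant_key\tcell_line\tchmm_state\thistone_marks\n")
            for p in self.variants:
                cls = cls_of(p)
                if p.fate == "planted_5p" or cls in ("conservation", "promoter", "cadd"):
                    states = ["TssA"] * 26 + ["Quies"] * 101
                    marks = ["H3K4Me3,H3K27Ac"] * 4 + ["-"] * 10
                elif p.fate == "planted_3p" or cls in ("mirna", "mirsvr"):
                    states = ["Tx"] * 30 + ["TxWk"] * 20 + ["Quies"] * 77
                    marks = ["-"] * 14
                elif cls == "gene_end":
                    states = ["ReprPC"] * 40 + ["Quies"] * 87
                    marks = ["-"] * 14
                else:
                    states = ["Quies"] * 127
                    marks = ["-"] * 14
                for li, state in enumerate(states):
                    fh.write(f"{p.key}\tCL{li + 1:03d}\t{state}\t\n")
                for li, mark in enumerate(marks):
                    fh.write(f"{p.key}\tHL{li + 1:02d}\t\t{mark}\n")
        files["chromatin"] = str(chrom_path)

        segway_path = outdir / "segway.tsv"
        with open(segway_path, "w") as fh:
            fh.write("variant_key\tsegway\tgc_percent\n")
            for p in self.variants:
                cls = cls_of(p)
                if p.fate == "planted_3p" or cls in ("mirna", "mirsvr"):
                    label = "GE0"
                elif cls == "gene_end":
                    label = "R5"
                elif p.fate == "planted_5p" or cls in ("conservation", "promoter", "cadd"):
                    label = "TSS"
                else:
                    label = "R0"
                fh.write(f"{p.key}\t{label}\t50.0\n")
        files["segway"] = str(segway_path)

        # mirSVR
        mirsvr_path = outdir / "mirsvr.tsv"
        with open(mirsvr_path, "w") as fh:
            fh.write("variant_key\tmirsvr\n")
            for p in self.variants:
                cls = cls_of(p)
                if p.fate == "planted_3p" or cls == "gene_end":
                    fh.write(f"{p.key}\t-0.8\n")
                elif cls == "mirna":
                    fh.write(f"{p.key}\t-0.7\n")
                elif cls == "mirsvr":
                    fh.write(f"{p.key}\t-0.05\n")
        files["mirsvr"] = str(mirsvr_path)

        # PFMs (JASPAR text) and reference windows
        pfm_path = outdir / "motifs.pfm"
        with open(pfm_path, "w") as fh:
            for p in self.variants:
                if p.pwm is None:
                    continue
                pwm_id, tf_name, consensus = p.pwm
                fh.write(f">{pwm_id} {tf_name}\n")
                for base in "ACGT":
                    row = " ".join("12" if b == base else "0" for b in consensus)
                    fh.write(f"{base} [ {row} ]\n")
        files["pfm"] = str(pfm_path)

        fasta_path = outdir / "windows.fasta"
        with open(fasta_path, "w") as fh:
            for p in self.variants:
                fh.write(f">{p.key}\n{p.window}\n")
        files["windows"] = str(fasta_path)

        # pathways and background universe
        gmt_path = outdir / "pathways.gmt"
        with open(gmt_path, "w") as fh:
            for name in self.pathways:
                members = "\t".join(self.pathways[name])
                fh.write(f"{name}\tsynthetic gene set\t{members}\n")
        files["gmt"] = str(gmt_path)

        bg_path = outdir / "background.txt"
        with open(bg_path, "w") as fh:
            fh.write("\n".join(self.background) + "\n")
        files["background"] = str(bg_path)
        return files

    def truth(self) -> Dict[str, str]:
        return {p.key: p.fate for p in self.variants}


def generate_study(cfg: SynthConfig, outdir: str | Path) -> Dict:
    """Generate the full study into ``outdir`` and write a manifest JSON
    listing every file and the planted truth table."""
    study = SyntheticStudy(cfg)
    files = study.write_cohort(outdir)
    files.update(study.write_annotations(outdir))
    # paths relative to the manifest, so identical seeds give identical bytes
    files = {name: Path(path).name for name, path in files.items()}
    manifest = {
        "seed": cfg.seed,
        "files": files,
        "samples": study.samples,
        "truth": study.truth(),
        "planted_pathway": "PLANTED_PATHWAY",
        "planted_genes": study.planted_genes,
    }
    with open(Path(outdir) / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest


def generate_cohort(cfg: SynthConfig, outdir: str | Path) -> Dict[str, str]:
    """Generate only the pedigree/phenotype files and the VCF."""
    return SyntheticStudy(cfg).write_cohort(outdir)


def generate_annotations(cfg: SynthConfig, outdir: str | Path) -> Dict[str, str]:
    """Generate only the annotation resources (scores, tracks, PFMs, atlas,
    mirSVR, pathways, windows); deterministic given the same config."""
    return SyntheticStudy(cfg).write_annotations(outdir)
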