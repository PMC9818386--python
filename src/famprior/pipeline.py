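"""End-to-end orchestration of the prioritization funnel.

Stage order: frequency filter -> category filter -> depth masking ->
pedigree segregation -> CADD threshold -> branch-specific regulatory
annotation (5' and 3') -> shortlist -> pathway over-representation.
Every dropped variant is recorded with the stage and named rule that
removed it, and the funnel report's counts are checked to be monotone
non-increasing.  Identical inputs and configuration produce identical
outputs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import pandas as pd
import yaml

from . import __version__, io
from ._util import config_hash, file_checksum, write_tsv
from .filters import FilterConfig, apply_depth_mask, fill_local_freq, frequency_pass
from .enrichment import EnrichmentRow, enrich, enrichment_frame
from .regulatory3p import annotate_3p, read_mirsvr_table
from .regulatory5p import annotate_5p, read_chromatin_profiles
from .scores import (
    ConservationComposite,
    DeleteriousnessConfig,
    cadd_pass,
    conservation_composite,
)
from .segregation import SegregationConfig, classify_family, segregates_in_family
from .shortlist import (
    Branch,
    FunnelReport,
    Shortlist3pConfig,
    Shortlist5pConfig,
    ShortlistDecision,
    build_funnel,
    shortlist_3p,
    shortlist_5p,
)
from .types import (
    FIVE_PRIME_CATEGORIES,
    THREE_PRIME_CATEGORIES,
    Family,
    ScoreBundle,
    VariantRecord,
)

log = logging.getLogger(__name__)

__all__ = ["RunConfig", "RunResult", "run_all"]


@dataclass
class RunConfig:
    """All inputs and per-stage settings of one pipeline run."""

    vcf: str
    ped: str
    phenotypes: str
    scores: str
    outdir: str
    promoters: Optional[str] = None
    cpg_islands: Optional[str] = None
    chip_peaks: Optional[str] = None
    chromatin: Optional[str] = None
    segway: Optional[str] = None
    mirna_atlas: Optional[str] = None
    mirsvr: Optional[str] = None
    pfm: Optional[str] = None
    windows: Optional[str] = None
    gmt: Optional[str] = None
    background: Optional[str] = None
    seed: int = 0
    tau: float = 0.80
    filter_cfg: FilterConfig = field(default_factory=FilterConfig)
    seg_cfg: SegregationConfig = field(default_factory=SegregationConfig)
    del_cfg: DeleteriousnessConfig = field(default_factory=DeleteriousnessConfig)
    sl5_cfg: Shortlist5pConfig = field(default_factory=Shortlist5pConfig)
    sl3_cfg: Shortlist3pConfig = field(default_factory=Shortlist3pConfig)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        simple = {k: v for k, v in raw.items() if k in {f.name for f in dataclasses.fields(cls)}
                  and not k.endswith("_cfg")}
        cfg = cls(**simple)
        if "filters" in raw:
            cfg.filter_cfg = FilterConfig(**raw["filters"])
        if "segregation" in raw:
            cfg.seg_cfg = SegregationConfig(**raw["segregation"])
        if "deleteriousness" in raw:
            cfg.del_cfg = DeleteriousnessConfig(**raw["deleteriousness"])
        if "shortlist_5p" in raw:
            cfg.sl5_cfg = Shortlist5pConfig(**raw["shortlist_5p"])
        if "shortlist_3p" in raw:
            cfg.sl3_cfg = Shortlist3pConfig(**raw["shortlist_3p"])
        return cfg

    @classmethod
    def from_manifest(cls, manifest_path: str | Path, outdir: str | Path, **overrides) -> "RunConfig":
        """Build a run configuration from a synthetic study's manifest."""
        with open(manifest_path) as fh:
            manifest = json.load(fh)
        root = Path(manifest_path).parent
        files = {
            name: str(root / path) if path else None
            for name, path in manifest["files"].items()
        }
        return cls(
            vcf=files["vcf"],
            ped=files["ped"],
            phenotypes=files["phenotypes"],
            scores=files["scores"],
            promoters=files.get("promoters"),
            cpg_islands=files.get("cpg_islands"),
            chip_peaks=files.get("chip_peaks"),
            chromatin=files.get("chromatin"),
            segway=files.get("segway"),
            mirna_atlas=files.get("mirna_atlas"),
            mirsvr=files.get("mirsvr"),
            pfm=files.get("pfm"),
            windows=files.get("windows"),
            gmt=files.get("gmt"),
            background=files.get("background"),
            outdir=str(outdir),
            seed=manifest.get("seed", 0),
            **overrides,
        )

    def public_dict(self) -> Dict:
        def _plain(v):
            if dataclasses.is_dataclass(v):
                return {f.name: _plain(getattr(v, f.name)) for f in dataclasses.fields(v)}
            if isinstance(v, (frozenset, set, tuple, list)):
                return sorted(str(getattr(x, "value", x)) for x in v)
            return getattr(v, "value", v)

        return {f.name: _plain(getattr(self, f.name)) for f in dataclasses.fields(self)}


@dataclass(slots=True)
class Drop:
    variant_key: str
    stage: str
    reason: str


@dataclass(slots=True)
class RunResult:
    funnel: FunnelReport
    decisions_5p: List[ShortlistDecision]
    decisions_3p: List[ShortlistDecision]
    enrichment: List[EnrichmentRow]
    drops: List[Drop]
    top_keys: List[str]
    surviving_genes: List[str]

    def dropped_at(self, key: str) -> Optional[Drop]:
        for d in self.drops:
            if d.variant_key == key:
                return d
        return None


def _frequency_reason(v: VariantRecord, cfg: FilterConfig) -> str:
    if (v.af_gnomad_exome or 0.0) >= cfg.maf_max or (v.af_gnomad_genome or 0.0) >= cfg.maf_max:
        return "maf"
    return "local_freq"


def run_all(cfg: RunConfig) -> RunResult:
    """Execute all stages and write the report bundle into ``cfg.outdir``.

    Raises on the first stage error, naming the stage.  Returns the
    in-memory result (funnel, shortlist decisions, enrichment rows, and
    the per-variant drop log).
    """
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    drops: List[Drop] = []

    def _stage(name: str):
        log.info("stage: %s", name)

    try:
        _stage("read inputs")
        families = io.read_pedigree(cfg.ped, cfg.phenotypes)
        samples = [m.individual_id for fam in families for m in fam.members]
        variants = io.read_vcf(cfg.vcf, samples)
        score_map = io.read_score_table(cfg.scores)
    except Exception as exc:
        raise RuntimeError(f"stage 'read inputs' failed: {exc}") from exc

    n_input = len(variants)
    variants = fill_local_freq(variants)

    # frequency
    kept = []
    for v in variants:
        if frequency_pass(v, cfg.filter_cfg):
            kept.append(v)
        else:
            drops.append(Drop(v.key, "frequency", _frequency_reason(v, cfg.filter_cfg)))
    n_freq = len(kept)

    # category
    survivors = []
    for v in kept:
        if v.category in cfg.filter_cfg.categories_kept:
            survivors.append(v)
        else:
            drops.append(Drop(v.key, "category", "category"))
    n_cat = len(survivors)

    # depth mask + segregation
    statuses = {f.family_id: classify_family(f, cfg.seg_cfg) for f in families}

    def _segregates(v: VariantRecord) -> List[str]:
        return [
            f.family_id
            for f in families
            if segregates_in_family(v, f, statuses[f.family_id], cfg.seg_cfg)
        ]

    seg_survivors: List[VariantRecord] = []
    seg_families: Dict[str, List[str]] = {}
    for v in survivors:
        masked = apply_depth_mask(v, cfg.filter_cfg)
        fams = _segregates(masked)
        if fams:
            seg_survivors.append(masked)
            seg_families[masked.key] = fams
        else:
            # attribute to the depth mask when unmasked genotypes segregate
            reason = "depth" if _segregates(v) else "segregation"
            drops.append(Drop(v.key, "segregation", reason))
    n_seg = len(seg_survivors)

    # CADD
    cadd_survivors: List[VariantRecord] = []
    bundles: Dict[str, ScoreBundle] = {}
    for v in seg_survivors:
        bundle = score_map.get((v.chrom, v.pos, v.ref, v.alt), ScoreBundle())
        if cadd_pass(bundle, cfg.del_cfg.cadd_min):
            cadd_survivors.append(v)
            bundles[v.key] = bundle
        else:
            drops.append(Drop(v.key, "cadd", "cadd"))
    n_cadd = len(cadd_survivors)

    # annotation resources
    try:
        _stage("annotation")
        promoters = io.read_bed(cfg.promoters, "promoters") if cfg.promoters else None
        cpg = io.read_bed(cfg.cpg_islands, "cpg_islands") if cfg.cpg_islands else None
        chip = io.read_bed(cfg.chip_peaks, "chip_peaks") if cfg.chip_peaks else None
        atlas = io.read_bed(cfg.mirna_atlas, "mirna_atlas") if cfg.mirna_atlas else None
        chromatin = (
            read_chromatin_profiles(cfg.chromatin, cfg.segway) if cfg.chromatin else {}
        )
        mirsvr_map = read_mirsvr_table(cfg.mirsvr) if cfg.mirsvr else {}
        pwms = io.read_pfm_jaspar(cfg.pfm) if cfg.pfm else None
        windows = io.read_fasta_windows(cfg.windows) if cfg.windows else {}
    except Exception as exc:
        raise RuntimeError(f"stage 'annotation' failed: {exc}") from exc

    decisions_5p: List[ShortlistDecision] = []
    decisions_3p: List[ShortlistDecision] = []
    for v in cadd_survivors:
        cons = conservation_composite(bundles[v.key], cfg.del_cfg)
        if v.category in FIVE_PRIME_CATEGORIES:
            ann5 = annotate_5p(
                v,
                promoter_track=promoters,
                cpg_track=cpg,
                chip_track=chip,
                chromatin=chromatin.get(v.key),
                pwms=pwms,
                ref_window=windows.get(v.key),
                tau=cfg.tau,
            )
            decisions_5p.append(shortlist_5p(ann5, cons, cfg.sl5_cfg))
        if v.category in THREE_PRIME_CATEGORIES:
            ann3 = annotate_3p(
                v,
                atlas=atlas,
                mirsvr=mirsvr_map.get(v.key),
                chromatin=chromatin.get(v.key),
            )
            decisions_3p.append(shortlist_3p(ann3, cons, cfg.sl3_cfg))

    top_keys = sorted(
        {d.variant_key for d in decisions_5p + decisions_3p if d.is_top}
    )
    for d in decisions_5p + decisions_3p:
        if not d.is_top and d.variant_key not in top_keys:
            failed = sorted(k for k, f in d.criterion_flags.items() if f is not True)
            if not any(x.variant_key == d.variant_key for x in drops):
                drops.append(Drop(d.variant_key, "shortlist", ",".join(failed)))

    funnel = build_funnel(
        [
            ("input", n_input),
            ("frequency", n_freq),
            ("category", n_cat),
            ("segregation", n_seg),
            ("cadd", n_cadd),
            ("top", len(top_keys)),
        ]
    )

    surviving_genes = sorted({v.gene for v in cadd_survivors if v.gene})
    rows: List[EnrichmentRow] = []
    if cfg.gmt:
        try:
            _stage("enrichment")
            collection = io.read_gmt(cfg.gmt)
            background = None
            if cfg.background:
                with open(cfg.background) as fh:
                    background = {line.strip().upper() for line in fh if line.strip()}
            rows = enrich(surviving_genes, collection, background)
        except Exception as exc:
            raise RuntimeError(f"stage 'enrichment' failed: {exc}") from exc

    result = RunResult(
        funnel=funnel,
        decisions_5p=decisions_5p,
        decisions_3p=decisions_3p,
        enrichment=rows,
        drops=drops,
        top_keys=top_keys,
        surviving_genes=surviving_genes,
    )
    _write_reports(cfg, result, seg_families)
    return result


def decisions_frame(decisions: Sequence[ShortlistDecision]) -> pd.DataFrame:
    flag_names = sorted({k for d in decisions for k in d.criterion_flags})
    data = {
        "variant_key": [d.variant_key for d in decisions],
        "gene": [d.gene for d in decisions],
        "branch": [d.branch.value for d in decisions],
        "is_top": [d.is_top for d in decisions],
    }
    for name in flag_names:
        data[f"flag_{name}"] = [
            {True: "true", False: "false", None: "unknown"}[d.criterion_flags.get(name)]
            for d in decisions
        ]
    return pd.DataFrame(data)


def _write_reports(cfg: RunConfig, result: RunResult, seg_families: Dict[str, List[str]]) -> None:
    outdir = Path(cfg.outdir)
    inputs = {
        name: file_checksum(path)
        for name, path in (
            ("vcf", cfg.vcf), ("ped", cfg.ped), ("phenotypes", cfg.phenotypes),
            ("scores", cfg.scores),
        )
    }
    hashed_cfg = {k: v for k, v in cfg.public_dict().items() if k != "outdir"}
    meta = {
        "config_hash": config_hash(hashed_cfg),
        "inputs": json.dumps(inputs, sort_keys=True),
        "seed": str(cfg.seed),
    }
    with open(outdir / "config.yaml", "w") as fh:
        yaml.safe_dump(cfg.public_dict(), fh, sort_keys=True)

    write_tsv(result.funnel.to_frame(), outdir / "funnel.tsv", meta)
    with open(outdir / "funnel.json", "w") as fh:
        json.dump(
            {
                "tool_version": __version__,
                "config_hash": meta["config_hash"],
                "stages": [
                    {"stage": s, "count_in": ci, "count_out": co}
                    for s, ci, co in result.funnel.stages
                ],
            },
            fh,
            indent=2,
        )
    write_tsv(decisions_frame(result.decisions_5p), outdir / "shortlist_5p.tsv", meta)
    write_tsv(decisions_frame(result.decisions_3p), outdir / "shortlist_3p.tsv", meta)
    write_tsv(
        pd.DataFrame(
            {
                "variant_key": [d.variant_key for d in result.drops],
                "stage": [d.stage for d in result.drops],
                "reason": [d.reason for d in result.drops],
            }
        ),
        outdir / "drops.tsv",
        meta,
    )
    write_tsv(
        pd.DataFrame(
            {
                "variant_key": sorted(seg_families),
                "families_segregating": [
                    ",".join(seg_families[k]) for k in sorted(seg_families)
                ],
            }
        ),
        outdir / "segregation.tsv",
        meta,
    )
    if result.enrichment:
        write_tsv(enrichment_frame(result.enrichment), outdir / "enrichment.tsv", meta)
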